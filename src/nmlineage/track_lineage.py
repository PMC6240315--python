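"""Lineage forests from cell tracking: in-silico photolabelling and fate calls.

A tracked dataset is a forest of cell observations: one node per cell per
timepoint, linked by parent pointers, with a division wherever a node has two
children.  A "track" is a root cell and all of its progeny.  On top of this
model the module implements the study-style analyses:

* clone selection — an in-silico photolabel: pick the cells inside a region
  at a chosen timepoint and keep them plus all their descendants, optionally
  discarding cells on the far side of the embryo from the viewer;
* reporter-based fate classification of terminal cells (mesoderm reporter
  positive → mesoderm; endoderm reporter positive → excluded; survives to the
  end of the movie without either → neural);
* terminal-division scoring — a division none of whose descendants divide
  again is classified N/N, M/M or N/M from its daughters' fates, the readout
  used to count bi-fated neuromesodermal progenitors;
* label summaries: the 90% neural/mesoderm/both rule, polar placement of a
  label on the embryonic sphere, per-somite anterior-posterior contribution
  histograms, clone fold change, and zone-based retrospective fate
  assignment with a k-nearest-neighbour mixing statistic.

Import/export covers a TGMM-style per-timepoint XML dialect (elements with
``id``, ``lineage``, ``parent`` and position attribute ``m="x y z"``) and a
flat CSV.
"""

from __future__ import annotations

import glob
import logging
import math
import os
from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

_TGMM_ATTRS = {"id", "lineage", "parent", "m", "splitScore", "nu", "beta", "alpha"}


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

@dataclass
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    def contains(self, p: np.ndarray) -> bool:
        return float(np.linalg.norm(np.asarray(p) - self.center)) <= self.radius


@dataclass
class Box:
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)

    def contains(self, p: np.ndarray) -> bool:
        p = np.asarray(p)
        return bool(np.all(p >= self.lo) and np.all(p <= self.hi))


@dataclass
class HalfSpace:
    """Viewer's side of a plane: points p with (p - point) · normal >= 0."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)

    def contains(self, p: np.ndarray) -> bool:
        return float(np.dot(np.asarray(p) - self.point, self.normal)) >= 0.0


# ---------------------------------------------------------------------------
# Forest data model
# ---------------------------------------------------------------------------

@dataclass
class CellNode:
    cell_id: int
    parent_id: int | None
    t: int
    position: np.ndarray  # (x, y, z) in µm
    channels: dict = field(default_factory=dict)
    time: float | None = None  # real acquisition time; defaults to t

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.time is None:
            self.time = float(self.t)


class LineageForest:
    """Time-stamped cell graph: parent → children links, positions, channels."""

    def __init__(self, nodes: dict[int, CellNode], stage_labels: dict | None = None):
        self.nodes = dict(nodes)
        self.stage_labels = dict(stage_labels or {})
        self._children: dict[int, list[int]] = {cid: [] for cid in self.nodes}
        for node in self.nodes.values():
            if node.parent_id is not None:
                self._children[node.parent_id].append(node.cell_id)
        for kids in self._children.values():
            kids.sort()
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        for node in self.nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self.nodes:
                    raise ValueError(f"node {node.cell_id}: unknown parent {node.parent_id}")
                parent = self.nodes[node.parent_id]
                if not parent.t < node.t:
                    raise ValueError(
                        f"node {node.cell_id}: parent t {parent.t} not before child t {node.t}"
                    )
        for cid, kids in self._children.items():
            if len(kids) > 2:
                raise ValueError(f"node {cid} has {len(kids)} children (max 2)")

    # -- structure ---------------------------------------------------------
    def children(self, cell_id: int) -> list[int]:
        return self._children[cell_id]

    def roots(self) -> list[int]:
        return sorted(c for c, n in self.nodes.items() if n.parent_id is None)

    def terminals(self, within: set | None = None) -> list[int]:
        """Cells with no children (restricted to ``within`` if given)."""
        ids = within if within is not None else self.nodes.keys()
        return sorted(c for c in ids if not self._children[c])

    def descendants(self, cell_id: int) -> set[int]:
        out = set()
        stack = [cell_id]
        while stack:
            c = stack.pop()
            for k in self._children[c]:
                if k not in out:
                    out.add(k)
                    stack.append(k)
        return out

    def is_division(self, cell_id: int) -> bool:
        return len(self._children[cell_id]) == 2

    @property
    def t_max(self) -> int:
        return max(n.t for n in self.nodes.values())

    @property
    def t_min(self) -> int:
        return min(n.t for n in self.nodes.values())

    @property
    def channel_names(self) -> list[str]:
        names: set = set()
        for n in self.nodes.values():
            names.update(n.channels)
        return sorted(names)

    def path_to_root(self, cell_id: int) -> list[int]:
        """Cell ids from the root down to ``cell_id`` (inclusive), in t order."""
        path = [cell_id]
        while self.nodes[path[-1]].parent_id is not None:
            path.append(self.nodes[path[-1]].parent_id)
        return path[::-1]

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        channels = self.channel_names
        rows = []
        for cid in sorted(self.nodes):
            n = self.nodes[cid]
            row = {
                "cell_id": cid,
                "parent_id": n.parent_id if n.parent_id is not None else -1,
                "t": n.t,
                "x": n.position[0],
                "y": n.position[1],
                "z": n.position[2],
            }
            for ch in channels:
                row[ch] = n.channels.get(ch, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LineageForest":
        channels = [c for c in df.columns if c not in
                    ("cell_id", "parent_id", "t", "x", "y", "z")]
        nodes = {}
        for row in df.itertuples(index=False):
            d = row._asdict()
            parent = int(d["parent_id"])
            nodes[int(d["cell_id"])] = CellNode(
                cell_id=int(d["cell_id"]),
                parent_id=None if parent < 0 else parent,
                t=int(d["t"]),
                position=np.array([d["x"], d["y"], d["z"]], dtype=float),
                channels={ch: float(d[ch]) for ch in channels if not pd.isna(d[ch])},
            )
        return cls(nodes)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "LineageForest":
        return cls.from_dataframe(pd.read_csv(path))


def read_tgmm(directory, voxel_size=(1.0, 1.0, 1.0)) -> LineageForest:
    """Read a TGMM-style directory of per-timepoint XML files.

    One XML file per timepoint (sorted by filename); each cell element carries
    ``id`` (unique within the timepoint), ``lineage``, ``parent`` (an id in
    the previous timepoint, or -1) and the position attribute ``m="x y z"`` in
    voxel coordinates, converted to µm with ``voxel_size``.  Any other
    numeric attribute is read as a reporter channel.  A parent id absent from
    the previous timepoint is logged as an orphan and the cell becomes a new
    root.
    """
    files = sorted(glob.glob(os.path.join(str(directory), "*.xml")))
    if not files:
        raise ValueError(f"no XML files in {directory}")
    voxel = np.asarray(voxel_size, dtype=float)

    nodes: dict[int, CellNode] = {}
    next_id = 0
    prev_map: dict[int, int] = {}
    for t, path in enumerate(files):
        root = etree.parse(path).getroot()
        cur_map: dict[int, int] = {}
        for el in root:
            if "id" not in el.attrib or "m" not in el.attrib:
                continue
            local = int(el.attrib["id"])
            if local in cur_map:
                raise ValueError(f"duplicate id {local} within timepoint {t} ({path})")
            pos = np.fromstring(el.attrib["m"], sep=" ") * voxel
            parent_local = int(el.attrib.get("parent", -1))
            parent_global = None
            if parent_local >= 0:
                parent_global = prev_map.get(parent_local)
                if parent_global is None:
                    logger.warning(
                        "timepoint %d: parent %d not found at t-1; "
                        "track treated as new root", t, parent_local,
                    )
            channels = {}
            for k, val in el.attrib.items():
                if k in _TGMM_ATTRS:
                    continue
                try:
                    channels[k] = float(val)
                except ValueError:
                    pass
            nodes[next_id] = CellNode(
                cell_id=next_id, parent_id=parent_global, t=t,
                position=pos, channels=channels,
            )
            cur_map[local] = next_id
            next_id += 1
        prev_map = cur_map
    return LineageForest(nodes)


def write_tgmm(forest: LineageForest, directory, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write per-timepoint TGMM-style XML files (inverse of :func:`read_tgmm`)."""
    os.makedirs(str(directory), exist_ok=True)
    voxel = np.asarray(voxel_size, dtype=float)
    by_t: dict[int, list[CellNode]] = {}
    for n in forest.nodes.values():
        by_t.setdefault(n.t, []).append(n)
    t_lo, t_hi = forest.t_min, forest.t_max
    for t in range(t_lo, t_hi + 1):
        root = etree.Element("document")
        for n in sorted(by_t.get(t, []), key=lambda n: n.cell_id):
            el = etree.SubElement(root, "GaussianMixtureModel")
            el.set("id", str(n.cell_id))
            el.set("lineage", str(forest.path_to_root(n.cell_id)[0]))
            el.set("parent", str(n.parent_id if n.parent_id is not None else -1))
            coords = np.asarray(n.position) / voxel
            el.set("m", " ".join(f"{c:.10g}" for c in coords))
            for ch, val in sorted(n.channels.items()):
                el.set(ch, f"{val:.10g}")
        tree = etree.ElementTree(root)
        tree.write(
            os.path.join(str(directory), f"GMEMfinalResult_frame{t:04d}.xml"),
            pretty_print=True,
        )


# ---------------------------------------------------------------------------
# In-silico photolabelling
# ---------------------------------------------------------------------------

@dataclass
class ClonalSelection:
    """An in-silico label: selected roots at t0 plus their full progeny."""

    roots: list
    node_ids: set
    t0: int
    region: object
    viewpoint: HalfSpace | None = None

    def __post_init__(self) -> None:
        if not self.roots and self.node_ids:
            raise ValueError("selection nodes without roots")


def select_clone(
    forest: LineageForest, region, t0: int, viewpoint: HalfSpace | None = None
) -> ClonalSelection:
    """Select the cells inside ``region`` at timepoint ``t0`` and all progeny.

    ``viewpoint``, if given, additionally requires the cell to lie on the
    viewer's side of the plane (cells on the opposite side of the embryo that
    project into the same 2D region are eliminated).  Returns an empty
    selection with a warning when nothing falls in the region.
    """
    if not (forest.t_min <= t0 <= forest.t_max):
        raise ValueError(f"t0={t0} outside forest span [{forest.t_min}, {forest.t_max}]")
    roots = []
    for cid in sorted(forest.nodes):
        n = forest.nodes[cid]
        if n.t != t0:
            continue
        if not region.contains(n.position):
            continue
        if viewpoint is not None and not viewpoint.contains(n.position):
            continue
        roots.append(cid)
    if not roots:
        logger.warning("empty clonal selection at t0=%d", t0)
        return ClonalSelection([], set(), t0, region, viewpoint)
    node_ids = set(roots)
    for r in roots:
        node_ids |= forest.descendants(r)
    return ClonalSelection(roots, node_ids, t0, region, viewpoint)


# ---------------------------------------------------------------------------
# Fate classification
# ---------------------------------------------------------------------------

@dataclass
class FateRules:
    """Reporter thresholds for fate scoring.

    A reporter is "on" when its intensity exceeds the threshold on at least
    ``k_frames`` frames (consecutively, for the mesoderm call) — a guard
    against single-frame tracking flicker that replaces the by-eye scoring of
    manual curation.
    """

    mezzo_threshold: float
    sox17_threshold: float
    k_frames: int = 3
    mezzo_channel: str = "mezzo"
    sox17_channel: str = "sox17"


@dataclass
class FateCall:
    cell_id: int
    fate: str  # neural | mesoderm | endoderm_excluded | unassigned
    evidence: dict = field(default_factory=dict)


def _max_consecutive(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def classify_cell_fate(
    forest: LineageForest, terminal_id: int, rules: FateRules
) -> FateCall:
    """Classify a terminal cell from the reporter trace along its track.

    Order of precedence: sustained endoderm reporter → ``endoderm_excluded``;
    sustained (consecutive ≥ k_frames) mesoderm reporter → ``mesoderm``;
    otherwise ``neural`` if the track survives to the end of the observation
    window, else ``unassigned`` (track lost early; excluded from denominators).
    """
    path = forest.path_to_root(terminal_id)
    trace = [forest.nodes[c].channels for c in path]
    for ch in (rules.mezzo_channel, rules.sox17_channel):
        if any(ch not in obs for obs in trace):
            raise ValueError(f"channel {ch!r} missing along track of cell {terminal_id}")
    mezzo = np.array([obs[rules.mezzo_channel] for obs in trace])
    sox17 = np.array([obs[rules.sox17_channel] for obs in trace])

    n_sox = int((sox17 >= rules.sox17_threshold).sum())
    if n_sox >= rules.k_frames:
        return FateCall(terminal_id, "endoderm_excluded", {"sox17_frames": n_sox})
    run = _max_consecutive(mezzo >= rules.mezzo_threshold)
    if run >= rules.k_frames:
        return FateCall(
            terminal_id, "mesoderm",
            {"channel": rules.mezzo_channel, "consecutive_frames": run,
             "threshold": rules.mezzo_threshold},
        )
    if forest.nodes[terminal_id].t >= forest.t_max:
        return FateCall(terminal_id, "neural", {"survived_to_end": True})
    return FateCall(terminal_id, "unassigned", {"lost_at_t": forest.nodes[terminal_id].t})


def classify_selection_fates(
    forest: LineageForest, selection: ClonalSelection, rules: FateRules
) -> dict[int, FateCall]:
    """Fate calls for every terminal cell of a clonal selection."""
    calls = {}
    for cid in sorted(selection.node_ids):
        if not forest.children(cid):
            calls[cid] = classify_cell_fate(forest, cid, rules)
    return calls


# ---------------------------------------------------------------------------
# Terminal-division scoring
# ---------------------------------------------------------------------------

@dataclass
class DivisionSummary:
    """Terminal-division classes and per-track division counts.

    ``class_counts`` holds N/N, M/M, N/M and incomplete terminal divisions;
    ``undivided_fates`` the fates of tracks that never divided (scored
    mono-fated directly); ``divisions_per_track`` the histogram of divisions
    per selected root.
    """

    class_counts: Counter
    undivided_fates: Counter
    divisions_per_track: Counter
    terminal_divisions: list = field(default_factory=list)

    @property
    def n_terminal_divisions(self) -> int:
        return sum(self.class_counts.values())

    @property
    def bifated_fraction(self) -> float:
        scored = sum(v for k, v in self.class_counts.items() if k != "incomplete")
        if scored == 0:
            return float("nan")
        return self.class_counts["N/M"] / scored


_FATE_CODE = {"neural": "N", "mesoderm": "M"}


def terminal_division_fates(
    forest: LineageForest,
    selection: ClonalSelection,
    fate_calls: dict[int, FateCall],
) -> DivisionSummary:
    """Score terminal divisions and the divisions-per-track histogram.

    A terminal division is a division none of whose descendants divide again
    within the observation window; its class comes from the fates of the
    terminal cells its two daughters lead to (N/N, M/M, N/M, or incomplete if
    either daughter's track ends unclassifiable).  Undivided tracks are
    scored mono-fated directly from their single terminal cell.
    """
    ids = selection.node_ids
    class_counts: Counter = Counter()
    per_track: Counter = Counter()
    undivided: Counter = Counter()
    terminal_divs = []

    divisions = {c for c in ids if forest.is_division(c)}
    for root in selection.roots:
        sub = {root} | forest.descendants(root)
        n_div = len(sub & divisions)
        per_track[n_div] += 1
        if n_div == 0:
            terminal = max(sub, key=lambda c: forest.nodes[c].t)
            undivided[fate_calls[terminal].fate] += 1

    for d in sorted(divisions):
        if any(k in divisions for k in forest.descendants(d)):
            continue  # a later division exists downstream
        child_fates = []
        for child in forest.children(d):
            chain = {child} | forest.descendants(child)
            terminal = max(chain, key=lambda c: forest.nodes[c].t)
            child_fates.append(fate_calls[terminal].fate)
        codes = [_FATE_CODE.get(f) for f in child_fates]
        if None in codes:
            cls = "incomplete"
        else:
            cls = "/".join(sorted(codes, reverse=True))  # N/N, M/M or N/M
        class_counts[cls] += 1
        terminal_divs.append({"division": d, "child_fates": child_fates, "class": cls})

    return DivisionSummary(class_counts, undivided, per_track, terminal_divs)


# ---------------------------------------------------------------------------
# Label summaries
# ---------------------------------------------------------------------------

def classify_label(neural_count: int, mesoderm_count: int, cutoff: float = 0.90) -> str:
    """The 90% rule for a photolabel: neural / mesoderm / both.

    A label is called neural (mesoderm) only when strictly more than
    ``cutoff`` of its cells contribute to that tissue; anything else is
    "both".
    """
    if neural_count < 0 or mesoderm_count < 0:
        raise ValueError("counts must be non-negative")
    total = neural_count + mesoderm_count
    if total == 0:
        raise ValueError("label with no classified cells")
    if neural_count / total > cutoff:
        return "neural"
    if mesoderm_count / total > cutoff:
        return "mesoderm"
    return "both"


def label_polar_position(
    label_center, animal_pole, shield_point, embryo_center
) -> tuple[float, float]:
    """Polar placement of a label on the (spherical) embryo.

    Returns ``(arc_from_animal_pole, angle_from_dorsal)`` in degrees: the
    great-circle angle between label and animal pole, and the azimuth of the
    label about the animal-vegetal axis measured from the shield (dorsal)
    meridian, in [−180, 180].  A label at a pole has an undefined azimuth,
    reported as NaN with a warning.
    """
    c = np.asarray(embryo_center, dtype=float)
    u_label = _unit(np.asarray(label_center, dtype=float) - c)
    u_ap = _unit(np.asarray(animal_pole, dtype=float) - c)
    u_shield = _unit(np.asarray(shield_point, dtype=float) - c)

    arc = math.degrees(math.acos(np.clip(np.dot(u_label, u_ap), -1.0, 1.0)))

    p_label = u_label - np.dot(u_label, u_ap) * u_ap
    p_shield = u_shield - np.dot(u_shield, u_ap) * u_ap
    if np.linalg.norm(p_label) < 1e-9 or np.linalg.norm(p_shield) < 1e-9:
        logger.warning("label or shield lies on the animal-vegetal axis; azimuth NA")
        return arc, float("nan")
    p_label, p_shield = _unit(p_label), _unit(p_shield)
    cos_a = np.clip(np.dot(p_label, p_shield), -1.0, 1.0)
    sign = np.sign(np.dot(u_ap, np.cross(p_shield, p_label))) or 1.0
    return arc, float(sign * math.degrees(math.acos(cos_a)))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def ap_contribution(
    cells: list[tuple[int, str]], n_segments: int
) -> dict:
    """Per-somite-segment neural/somite contribution histograms.

    ``cells`` is a list of ``(segment_index, compartment)`` with 1-based
    segment indices and compartment in {"neural", "somite"}.  Returns the two
    count vectors plus the occupied span per compartment (e.g. somites 25th
    to 32nd).
    """
    neural = np.zeros(n_segments, dtype=int)
    somite = np.zeros(n_segments, dtype=int)
    for seg, comp in cells:
        if not (1 <= seg <= n_segments):
            raise ValueError(f"segment index {seg} outside [1, {n_segments}]")
        if comp == "neural":
            neural[seg - 1] += 1
        elif comp == "somite":
            somite[seg - 1] += 1
        else:
            raise ValueError(f"unknown compartment {comp!r}")
    spans = {}
    for name, vec in (("neural", neural), ("somite", somite)):
        occ = np.nonzero(vec)[0]
        spans[name] = (int(occ[0]) + 1, int(occ[-1]) + 1) if occ.size else None
    return {"neural": neural, "somite": somite, "spans": spans}


def clone_fold_change(n_t0: int, n_t1: int) -> float:
    """Fold change in labelled clone cell number between two stages."""
    if n_t0 <= 0:
        raise ValueError("initial clone size must be positive")
    return n_t1 / n_t0


# ---------------------------------------------------------------------------
# Zone-based retrospective fate assignment
# ---------------------------------------------------------------------------

def zone_assign(
    forest: LineageForest,
    selection: ClonalSelection,
    zone_masks: dict,
    k_neighbors: int = 5,
) -> dict:
    """Assign fates from track termination points and score start mixing.

    ``zone_masks`` maps fate names (e.g. "neural", "mesoderm", "unassigned"
    for the sox2+tbxta co-expressing zone) to regions with a ``contains``
    method, checked in insertion order; terminal positions outside every zone
    fall to "other" with a warning.  Fates are mapped back to the tracks'
    start positions, and per-fate mixing is summarized as the mean fraction
    of each cell's ``k_neighbors`` nearest start-position neighbours sharing
    its fate (1.0 = perfectly sorted).
    """
    records = []
    for root in selection.roots:
        sub = {root} | (forest.descendants(root) & selection.node_ids)
        terminal = max(sub, key=lambda c: forest.nodes[c].t)
        tpos = forest.nodes[terminal].position
        fate = "other"
        for name, mask in zone_masks.items():
            if mask.contains(tpos):
                fate = name
                break
        if fate == "other":
            logger.warning("terminal position of root %d outside all zones", root)
        records.append(
            {"root": root, "fate": fate,
             "start": forest.nodes[root].position, "terminal": tpos}
        )

    starts = np.array([r["start"] for r in records]) if records else np.empty((0, 3))
    fates = [r["fate"] for r in records]
    mixing = {}
    if len(records) > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(starts)
        k = min(k_neighbors + 1, len(records))
        _, idx = tree.query(starts, k=k)
        for fate in sorted(set(fates)):
            members = [i for i, f in enumerate(fates) if f == fate]
            fracs = []
            for i in members:
                neigh = [j for j in np.atleast_1d(idx[i]) if j != i]
                if neigh:
                    fracs.append(np.mean([fates[j] == fate for j in neigh]))
            if fracs:
                mixing[fate] = float(np.mean(fracs))
    return {"assignments": records, "mixing": mixing}
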