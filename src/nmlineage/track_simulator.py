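"""Synthetic lineage forests with known fates for recovery testing.

The generator emulates a tracked light-sheet dataset of gastrula-stage cells:
a starting cohort of cells, each with a latent fate — neural (N), mesodermal
(M), bi-fated neuromesodermal (NM), or endodermal — drifts, divides and
switches on fate reporters.  Division waiting times are exponential with a
per-fate-class rate (set the NM rate to 0 to emulate the quiescent tailbud
population); when an NM cell divides, the division is terminal and yields one
N and one M daughter.  The mesoderm reporter (``mezzo``) steps from baseline
to a high plateau a fixed delay after fate commitment, with Gaussian noise;
the endoderm reporter (``sox17``) behaves likewise for endodermal cells.
Track loss is modelled as per-frame censoring, exercising the "unassigned"
pathway of the classifier.

Ground truth (latent fate per cell, true class per division) is returned
alongside the forest so classifier output can be scored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .track_lineage import (
    CellNode,
    ClonalSelection,
    FateRules,
    LineageForest,
    classify_selection_fates,
    terminal_division_fates,
)


@dataclass
class TrackSimParams:
    """Parameters of the synthetic tracked-embryo movie.

    Rates are per frame; with 2.5 min frames the defaults give a ~70% chance
    of a track never dividing over the 60-frame window, matching the regime
    where most tracks are undivided and the rest divide a handful of times.
    """

    n_cells: int = 300
    layout: str = "mixed"  # "mixed" or "sorted" start positions
    p_N: float = 0.35
    p_M: float = 0.35
    p_NM: float = 0.30
    p_endo: float = 0.0
    div_rate: dict = field(
        default_factory=lambda: {"N": 0.006, "M": 0.006, "NM": 0.006, "endo": 0.006}
    )
    n_timepoints: int = 60
    box_size: tuple = (200.0, 200.0, 100.0)
    reporter_baseline: float = 100.0
    reporter_high: float = 1000.0
    reporter_delay: int = 2  # frames between commitment and reporter onset
    noise_sigma: float = 50.0
    drift_velocity: tuple = (0.3, 0.1, 0.0)  # µm per frame
    brownian_sigma: float = 0.5
    track_loss_prob: float = 0.002

    def __post_init__(self) -> None:
        p = self.p_N + self.p_M + self.p_NM + self.p_endo
        if abs(p - 1.0) > 1e-9:
            raise ValueError(f"fate probabilities sum to {p}, not 1")
        if any(r < 0 for r in self.div_rate.values()):
            raise ValueError("division rates must be >= 0")


@dataclass
class TrackTruth:
    """Ground truth of a simulated forest."""

    root_fate: dict  # root cell_id -> latent fate (N/M/NM/endo)
    cell_fate: dict  # terminal cell_id -> committed fate
    division_class: dict  # division cell_id -> true class (N/N, M/M, N/M, ...)
    commitment_t: dict  # cell entity -> commitment frame

    @property
    def true_terminal_classes(self) -> Counter:
        return Counter(self.division_class.values())

    def true_bifated_fraction(self, division_ids=None) -> float:
        """N/M share among true terminal divisions (optionally restricted)."""
        items = self.division_class.items()
        if division_ids is not None:
            items = [(d, c) for d, c in items if d in division_ids]
        classes = [c for _, c in items]
        if not classes:
            return float("nan")
        return sum(c == "N/M" for c in classes) / len(classes)


def _start_positions(params: TrackSimParams, fates: list, rng) -> np.ndarray:
    box = np.asarray(params.box_size)
    pos = rng.uniform(0, 1, size=(len(fates), 3)) * box
    if params.layout == "sorted":
        # sort along x by fate: N low, NM middle, M high, endo at the far end
        order = {"N": 0.15, "NM": 0.5, "M": 0.85, "endo": 0.98}
        for i, f in enumerate(fates):
            pos[i, 0] = np.clip(
                order[f] + rng.normal(0, 0.05), 0, 1
            ) * box[0]
    return pos


def simulate_forest(
    params: TrackSimParams, seed
) -> tuple[LineageForest, TrackTruth]:
    """Simulate a drifting, dividing, fate-committing cell cohort.

    Returns the forest (one node per cell per frame, ``mezzo`` and ``sox17``
    channels on every node) and the ground truth.
    """
    rng = np.random.default_rng(seed)
    T = params.n_timepoints
    fate_names = ["N", "M", "NM", "endo"]
    probs = [params.p_N, params.p_M, params.p_NM, params.p_endo]
    fates = [fate_names[i] for i in rng.choice(4, size=params.n_cells, p=probs)]
    positions = _start_positions(params, fates, rng)

    nodes: dict[int, CellNode] = {}
    next_id = 0
    root_fate: dict[int, str] = {}
    cell_fate: dict[int, str] = {}
    division_class: dict[int, str] = {}
    commitment_t: dict[int, int] = {}

    def _division_frame(fate: str, born: int) -> int:
        rate = params.div_rate.get(fate, 0.0)
        if rate <= 0:
            return T + 1
        wait = rng.exponential(1.0 / rate)
        return born + max(1, int(np.ceil(wait)))

    def _channels(fate: str, commit: int, t: int) -> dict:
        on_m = fate in ("M",) and t >= commit + params.reporter_delay
        on_e = fate == "endo" and t >= commit + params.reporter_delay
        mezzo = params.reporter_high if on_m else params.reporter_baseline
        sox17 = params.reporter_high if on_e else params.reporter_baseline
        if params.noise_sigma > 0:
            mezzo += rng.normal(0, params.noise_sigma)
            sox17 += rng.normal(0, params.noise_sigma)
        return {"mezzo": float(max(mezzo, 0.0)), "sox17": float(max(sox17, 0.0))}

    # live entity: (node_id of latest observation, fate, commit_t, div_frame,
    #               can_divide, position)
    live = []
    for i in range(params.n_cells):
        fate = fates[i]
        commit = 0  # mono-fated cells are committed from the start
        nid = next_id
        next_id += 1
        nodes[nid] = CellNode(
            cell_id=nid, parent_id=None, t=0, position=positions[i].copy(),
            channels=_channels(fate, commit, 0),
        )
        root_fate[nid] = fate
        commitment_t[nid] = commit
        live.append([nid, fate, commit, _division_frame(fate, 0), True,
                     positions[i].copy()])

    drift = np.asarray(params.drift_velocity, dtype=float)
    for t in range(1, T):
        new_live = []
        for nid, fate, commit, div_frame, can_divide, pos in live:
            if rng.random() < params.track_loss_prob:
                continue  # censored: chain ends before the movie does
            pos = pos + drift + rng.normal(0, params.brownian_sigma, size=3)
            if can_divide and div_frame == t:
                if fate == "NM":
                    daughter_fates = ["N", "M"]
                    daughter_can_divide = [False, False]
                    division_class[nid] = "N/M"
                else:
                    daughter_fates = [fate, fate]
                    daughter_can_divide = [True, True]
                    code = {"N": "N/N", "M": "M/M", "endo": "endo/endo"}[fate]
                    division_class[nid] = code
                for df, dc in zip(daughter_fates, daughter_can_divide):
                    dcommit = t if fate == "NM" else commit
                    did = next_id
                    next_id += 1
                    dpos = pos + rng.normal(0, 1.0, size=3)
                    nodes[did] = CellNode(
                        cell_id=did, parent_id=nid, t=t, position=dpos,
                        channels=_channels(df, dcommit, t),
                    )
                    commitment_t[did] = dcommit
                    new_live.append([did, df, dcommit,
                                     _division_frame(df, t) if dc else T + 1,
                                     dc, dpos])
            else:
                cid = next_id
                next_id += 1
                nodes[cid] = CellNode(
                    cell_id=cid, parent_id=nid, t=t, position=pos,
                    channels=_channels(fate, commit, t),
                )
                new_live.append([cid, fate, commit, div_frame, can_divide, pos])
        live = new_live

    forest = LineageForest(nodes)
    for cid in forest.terminals():
        # committed fate of the chain the terminal cell belongs to
        fate = _chain_fate(forest, cid, root_fate, division_class)
        cell_fate[cid] = fate

    # divisions whose descendants divide again are not terminal; restrict the
    # truth table to terminal divisions so classes compare one-to-one
    division_class = {
        d: c for d, c in division_class.items()
        if not any(forest.is_division(k) for k in forest.descendants(d))
    }
    return forest, TrackTruth(root_fate, cell_fate, division_class, commitment_t)


def _chain_fate(forest, terminal_id, root_fate, division_class) -> str:
    """Latent fate of a terminal cell: walk up to the last division (or root)."""
    path = forest.path_to_root(terminal_id)
    fate = root_fate[path[0]]
    for i, cid in enumerate(path):
        if forest.is_division(cid) and division_class.get(cid) == "N/M":
            # NM division: daughters alternate N (first child) / M (second)
            child_on_path = path[i + 1]
            kids = forest.children(cid)
            fate = "N" if child_on_path == kids[0] else "M"
    return fate


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def default_rules(params: TrackSimParams) -> FateRules:
    """Thresholds midway between reporter baseline and plateau."""
    thr = 0.5 * (params.reporter_baseline + params.reporter_high)
    return FateRules(mezzo_threshold=thr, sox17_threshold=thr, k_frames=3)


def select_all_roots(forest: LineageForest) -> ClonalSelection:
    """A selection covering every track (the whole-forest in-silico label)."""
    roots = forest.roots()
    return ClonalSelection(roots, set(forest.nodes), forest.t_min, region=None)


def recovery_report(
    forest: LineageForest,
    truth: TrackTruth,
    rules: FateRules,
) -> dict:
    """Classify the forest and score it against ground truth.

    Returns the confusion matrix over terminal-division classes (true class →
    estimated class), the estimated and true bi-fated fractions, and a 95%
    Clopper–Pearson interval for the estimate.
    """
    selection = select_all_roots(forest)
    calls = classify_selection_fates(forest, selection, rules)
    summary = terminal_division_fates(forest, selection, calls)

    confusion: Counter = Counter()
    for rec in summary.terminal_divisions:
        true_cls = truth.division_class.get(rec["division"], "?")
        confusion[(true_cls, rec["class"])] += 1

    scored = sum(v for k, v in summary.class_counts.items() if k != "incomplete")
    n_bifated = summary.class_counts["N/M"]
    if scored:
        lo, hi = _clopper_pearson(n_bifated, scored)
    else:
        lo = hi = float("nan")
    return {
        "confusion": dict(confusion),
        "estimated_bifated_fraction": summary.bifated_fraction,
        "true_bifated_fraction": truth.true_bifated_fraction(),
        "ci95": (lo, hi),
        "n_terminal_divisions": summary.n_terminal_divisions,
        "class_counts": dict(summary.class_counts),
        "divisions_per_track": dict(summary.divisions_per_track),
        "undivided_fates": dict(summary.undivided_fates),
    }


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)
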