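"""Synthetic ScarTrace generator: embryo division tree, scarring, organ sampling.

The generator emulates the experimental design behind scar-based clonal
analysis: a zygote carrying a tandem array of GFP target copies (8 by
default) is injected with Cas9, and during an early time window each
still-unscarred copy may acquire an irreversible indel "scar" at every
division.  Scars are inherited by all descendants, so cells sharing an early
scar form a clone.  Organs are then "dissected" by sampling leaf cells from
tissue-specific progenitor subtrees, and bulk sequencing is emulated as
multinomial read counts with per-scar dropout.  Which organs share progenitor
subtrees is the ground truth that distance- and tree-based analysis should
recover.

Time is measured in synchronous division rounds; the hpf-based scarring
windows of Cas9 protein (ends around 3 hpf) versus Cas9 RNA (up to about
10 hpf) map to round counts via the ``divisions_per_hour`` constant
(default 1.0, so "protein" scars rounds [0, 3) and "rna" rounds [0, 10)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scar_data import GFP_UNSCARRED, ScarTable


def power_law_probs(alphabet_size: int, exponent: float = 1.0) -> np.ndarray:
    """Truncated power-law scar-identity distribution.

    Heavy-tailed so that, as in the real system, most scars are common
    outcomes of repair but a long tail of rare scars (creation probabilities
    down to ~1e-5) exists to serve as unique clone markers.
    """
    ranks = np.arange(1, alphabet_size + 1, dtype=float)
    p = ranks ** (-exponent)
    return p / p.sum()


@dataclass
class ScarSimParams:
    """Parameters of the synthetic ScarTrace experiment.

    Attributes
    ----------
    n_copies : int
        GFP target-array copies per cell (8, matching the transgenic line
        the protocol assumes).
    scar_rate : float
        Per-copy, per-division scarring probability while inside the window.
    scar_window : tuple[int, int]
        Closed division-round interval [start, end] during which Cas9 is
        active.  Use :func:`window_preset` for the "protein"/"rna" presets.
    scar_alphabet_size : int
        Number of distinct scar identities.
    scar_probs : ndarray or None
        Per-identity creation probabilities (sum to 1); default truncated
        power law with rare identities at ~1e-5.
    n_divisions : int
        Rounds from zygote to the leaf pool (2**n_divisions leaves).
    pool_round : int
        Round at which tissue progenitor pools are defined; ``tissue_map``
        indexes the 2**pool_round ancestors of that round.
    tissue_map : dict[str, set[int]]
        Organ -> set of progenitor indices at ``pool_round``.  Overlapping
        sets encode shared progenitor pools.
    cells_per_organ, n_replicates, dropout_prob, depth
        Dissection and sequencing emulation: leaves sampled per organ,
        technical replicates, per-scar dropout probability, reads per sample.
    divisions_per_hour : float
        Conversion used by the hpf window presets.
    """

    n_copies: int = 8
    scar_rate: float = 0.12
    scar_window: tuple = (0, 11)
    scar_alphabet_size: int = 30000
    scar_probs: np.ndarray | None = None
    n_divisions: int = 12
    pool_round: int = 4
    tissue_map: dict = field(default_factory=dict)
    cells_per_organ: int = 300
    n_replicates: int = 2
    dropout_prob: float = 0.1
    depth: int = 30000
    divisions_per_hour: float = 1.6

    def __post_init__(self) -> None:
        if self.scar_probs is None:
            self.scar_probs = power_law_probs(self.scar_alphabet_size)
        self.scar_probs = np.asarray(self.scar_probs, dtype=float)
        if abs(self.scar_probs.sum() - 1.0) > 1e-9:
            raise ValueError("scar_probs must sum to 1")
        if not (0 <= self.scar_rate <= 1 and 0 <= self.dropout_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        t0, t1 = self.scar_window
        if not (0 <= t0 <= t1 <= self.n_divisions):
            raise ValueError("scar_window must satisfy 0 <= start <= end <= n_divisions")
        if self.pool_round > self.n_divisions:
            raise ValueError("pool_round beyond tree depth")


def window_preset(name: str, params: ScarSimParams) -> tuple[int, int]:
    """Map the Cas9 delivery mode to a division-round scarring window.

    "protein" scarring ends around 3 hpf; "rna" persists until about 10 hpf.
    """
    hours = {"protein": 3.0, "rna": 10.0}[name]
    # rounds 0 .. (hours*dph - 1) happen within the first `hours` of development
    last = min(params.n_divisions, int(round(hours * params.divisions_per_hour)) - 1)
    return (0, max(0, last))


def fig1_params(window: str = "rna", **overrides) -> ScarSimParams:
    """Preset mirroring the whole-organism clonal design.

    Spinal cord and muscle draw from overlapping progenitor subtrees, brain
    and skin from a disjoint ectodermal pool, and the endoderm-derived organs
    (intestine, liver) from a third pool.
    """
    tissue_map = {
        "spinal_cord": set(range(0, 6)),
        "muscle": set(range(2, 8)),
        "brain": set(range(8, 12)),
        "skin": set(range(8, 12)),
        "intestine": set(range(12, 16)),
        "liver": set(range(12, 16)),
    }
    p = ScarSimParams(tissue_map=tissue_map, **overrides)
    if "scar_window" not in overrides:
        p = replace(p, scar_window=window_preset(window, p))
    return p


@dataclass
class ScarredTree:
    """Full binary division tree with per-cell copy states.

    ``levels[t]`` is an int array of shape (2**t, n_copies): entry 0 means the
    copy is unscarred, k > 0 means it carries scar identity k.  The parent of
    cell ``c`` at level t+1 is cell ``c >> 1`` at level t; leaves are
    ``levels[-1]``.
    """

    levels: list

    @property
    def leaves(self) -> np.ndarray:
        return self.levels[-1]

    @property
    def n_divisions(self) -> int:
        return len(self.levels) - 1


def simulate_embryo(params: ScarSimParams, seed) -> ScarredTree:
    """Simulate the scarred division tree.

    At each division round inside the scarring window, every still-unscarred
    copy of every cell scars with probability ``scar_rate``; the identity is
    drawn from ``scar_probs``.  Scars are irreversible and inherited by both
    daughters — descendant scar sets are supersets of ancestral ones.
    """
    rng = np.random.default_rng(seed)
    t0, t1 = params.scar_window
    state = np.zeros((1, params.n_copies), dtype=np.int32)
    levels = []

    def _maybe_scar(state: np.ndarray, t: int) -> np.ndarray:
        if not (t0 <= t <= t1) or params.scar_rate == 0:
            return state
        unscarred = state == 0
        hit = unscarred & (rng.random(state.shape) < params.scar_rate)
        n_hit = int(hit.sum())
        if n_hit:
            ids = rng.choice(
                params.scar_alphabet_size, size=n_hit, p=params.scar_probs
            ) + 1
            state = state.copy()
            state[hit] = ids
        return state

    # round t: scarring acts on the cells present during that cycle, then
    # they divide; scars made at round 0 live in the zygote and mark all leaves
    for t in range(params.n_divisions):
        state = _maybe_scar(state, t)
        levels.append(state)
        state = np.repeat(state, 2, axis=0)
    levels.append(state)
    return ScarredTree(levels)


def _tissue_leaf_slices(params: ScarSimParams, tissue: str) -> np.ndarray:
    """Leaf indices owned by a tissue's progenitor subtrees."""
    h = params.n_divisions - params.pool_round
    block = 1 << h
    pools = sorted(params.tissue_map[tissue])
    if not pools:
        raise ValueError(f"empty progenitor subtree for tissue {tissue!r}")
    idx = [np.arange(a * block, (a + 1) * block) for a in pools]
    return np.concatenate(idx)


def scar_name(identity: int) -> str:
    """Opaque 'position:indel-signature' id for a scar identity."""
    return f"{identity % 97}:d{identity}"


def sample_organs(
    tree: ScarredTree, params: ScarSimParams, seed, fish_id: str = "F1"
) -> ScarTable:
    """Dissect organs from the simulated embryo and emulate bulk sequencing.

    For each organ × technical replicate, ``cells_per_organ`` leaves are drawn
    uniformly from the organ's progenitor subtrees and their copy states
    aggregated.  Read counts are multinomial at ``depth`` over the aggregated
    copy proportions after per-scar Bernoulli dropout; reads from unscarred
    copies (and from fully dropped libraries) report as ``GFP_unscarred``.
    """
    rng = np.random.default_rng(seed)
    if not params.tissue_map:
        raise ValueError("tissue_map is empty")

    leaves = tree.leaves
    rows = []
    meta = []
    all_scars: set[int] = set()
    for organ in params.tissue_map:
        pool = _tissue_leaf_slices(params, organ)
        for rep in range(1, params.n_replicates + 1):
            chosen = rng.choice(pool, size=params.cells_per_organ, replace=True)
            copies = leaves[chosen].ravel()
            ids, copy_counts = np.unique(copies, return_counts=True)
            unscarred = int(copy_counts[ids == 0].sum())
            scar_ids = ids[ids > 0]
            scar_counts = copy_counts[ids > 0].astype(float)
            if params.dropout_prob > 0 and scar_ids.size:
                kept = rng.random(scar_ids.size) >= params.dropout_prob
                scar_ids, scar_counts = scar_ids[kept], scar_counts[kept]
            mass = np.concatenate([[float(unscarred)], scar_counts])
            if mass.sum() == 0:
                mass[0] = 1.0  # fully scarred + fully dropped: reads report unscarred-like
            reads = rng.multinomial(params.depth, mass / mass.sum())
            row = {GFP_UNSCARRED: int(reads[0])}
            for k, c in zip(scar_ids, reads[1:]):
                row[scar_name(int(k))] = int(c)
            all_scars.update(int(k) for k in scar_ids)
            rows.append(row)
            meta.append(
                {
                    "sample_id": f"{fish_id}_{organ}_r{rep}",
                    "fish_id": fish_id,
                    "organ": organ,
                    "axis_position": "NA",
                    "replicate_id": f"r{rep}",
                }
            )

    columns = [GFP_UNSCARRED] + [scar_name(k) for k in sorted(all_scars)]
    counts = pd.DataFrame(rows, columns=columns).fillna(0).astype(np.int64)
    meta_df = pd.DataFrame(meta).set_index("sample_id")
    counts.index = meta_df.index
    return ScarTable(counts, meta_df, provenance=f"simulated fish {fish_id}")


def simulate_fish(params: ScarSimParams, seed, fish_id: str = "F1") -> ScarTable:
    """Simulate one fish end to end (embryo + organ dissection + sequencing)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_embryo, s_sample = ss.spawn(2)
    tree = simulate_embryo(params, s_embryo)
    return sample_organs(tree, params, s_sample, fish_id=fish_id)


def simulate_cohort(
    params: ScarSimParams, n_fish: int, seed
) -> dict[str, ScarTable]:
    """Simulate a cohort of independently scarred fish."""
    ss = np.random.SeedSequence(seed)
    return {
        f"R{i + 1}": simulate_fish(params, s, fish_id=f"R{i + 1}")
        for i, s in enumerate(ss.spawn(n_fish))
    }


def ground_truth(params: ScarSimParams) -> dict[str, int]:
    """Organ partition implied by the tissue map.

    Two organs belong to the same group iff their progenitor pools are
    connected through (transitively) overlapping subtree sets.  Returns
    organ -> group index; group indices follow first appearance in
    ``tissue_map`` order.
    """
    organs = list(params.tissue_map)
    parent = {o: o for o in organs}

    def find(o):
        while parent[o] != o:
            parent[o] = parent[parent[o]]
            o = parent[o]
        return o

    for i, a in enumerate(organs):
        for b in organs[i + 1:]:
            if params.tissue_map[a] & params.tissue_map[b]:
                parent[find(b)] = find(a)

    groups: dict[str, int] = {}
    label = {}
    for o in organs:
        r = find(o)
        if r not in label:
            label[r] = len(label)
        groups[o] = label[r]
    return groups
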