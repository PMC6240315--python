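"""The four-stage scar filter: fraction filter, fish QC, rare-scar filter, binarization.

Stages, in order:

1. ``filter_low_fraction`` — within one fish, zero out scar fractions below
   10× the minimum detected (nonzero) scar fraction; removes likely
   sequencing errors.
2. ``fish_qc`` — keep only fish with a mean unscarred-GFP percentage across
   organs below 50% and more than 100 distinct surviving scars (both strict).
3. ``filter_shared_scars`` — drop any scar seen in two or more fish of the
   cohort, or named on an external blacklist, so only scars rare enough to
   have been created once (creation probability ~1e-5) remain as clone
   markers.
4. ``binarize`` — presence/absence matrix over the surviving scars;
   ``GFP_unscarred`` is QC only and is dropped here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scar_data import (
    GFP_UNSCARRED,
    ScarFractions,
    ScarTable,
    merge_replicates,
    scar_fractions,
)

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Bookkeeping for the filter chain.

    ``stages`` maps stage name -> dict with ``scars_in/scars_out`` and
    ``samples_in/samples_out``; ``fish_qc`` maps fish id -> QC metrics;
    ``blacklist_hits`` lists blacklisted scar ids actually seen; ``flags``
    collects warnings about pathological inputs.
    """

    stages: dict = field(default_factory=dict)
    fish_qc: dict = field(default_factory=dict)
    blacklist_hits: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def record(self, stage: str, scars_in: int, scars_out: int,
               samples_in: int, samples_out: int) -> None:
        if scars_out > scars_in or samples_out > samples_in:
            raise ValueError(f"stage {stage}: out-counts exceed in-counts")
        self.stages[stage] = {
            "scars_in": scars_in,
            "scars_out": scars_out,
            "samples_in": samples_in,
            "samples_out": samples_out,
        }

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "fish_qc": self.fish_qc,
            "blacklist_hits": self.blacklist_hits,
            "flags": self.flags,
        }


@dataclass
class BinaryScarMatrix:
    """Presence/absence matrix over surviving scars, rows = merged samples."""

    presence: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.presence.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("presence values must be 0/1")
        if GFP_UNSCARRED in self.presence.columns:
            raise ValueError(f"{GFP_UNSCARRED} must not appear in a binary matrix")

    @property
    def n_samples(self) -> int:
        return len(self.presence)

    @property
    def n_scars(self) -> int:
        return self.presence.shape[1]


# ---------------------------------------------------------------------------
# Stage 1: sequencing-error fraction filter
# ---------------------------------------------------------------------------

def filter_low_fraction(
    fractions: ScarFractions,
    factor: float = 10.0,
    report: FilterReport | None = None,
    fmin_scope: str = "fish",
) -> tuple[ScarFractions, FilterReport]:
    """Zero out scar fractions below ``factor`` × the minimum detected fraction.

    Scars are kept only when their fraction is at least ``factor`` times the
    smallest nonzero scar fraction (boundary inclusive — "at least").  The
    minimum is taken over all scar entries of the call, which by contract is
    one fish's samples (``fmin_scope='fish'``, the default); ``'sample'``
    computes a per-row minimum instead, ``'global'`` is an alias for ``'fish'``
    on a single-fish call.  ``GFP_unscarred`` is exempt.

    Raises
    ------
    ValueError
        If no scar entry is nonzero ("no detected scars").
    """
    if report is None:
        report = FilterReport()
    scar_cols = fractions.scar_columns
    frac = fractions.fractions[scar_cols].to_numpy(dtype=float)
    nonzero = frac[frac > 0]
    if nonzero.size == 0:
        raise ValueError("no detected scars: all scar fractions are zero")

    if fmin_scope == "sample":
        with np.errstate(invalid="ignore"):
            masked = np.where(frac > 0, frac, np.inf)
            fmin = masked.min(axis=1, keepdims=True)
        threshold = factor * fmin
        keep = frac >= threshold
    else:  # 'fish' or 'global': one minimum over the whole matrix
        fmin = nonzero.min()
        threshold = factor * fmin
        keep = frac >= threshold

    out = frac * keep
    if not (out > 0).any():
        report.flags.append(
            "pathological input: no entry reaches factor x f_min; "
            "all scar fractions removed"
        )
    df = fractions.fractions.copy()
    df[scar_cols] = out
    surviving = int((df[scar_cols].to_numpy() > 0).any(axis=0).sum())
    report.record(
        "low_fraction",
        scars_in=len(scar_cols),
        scars_out=surviving,
        samples_in=len(df),
        samples_out=len(df),
    )
    return FilteredFractions(df, fractions.sample_meta.copy(),
                             fractions.provenance), report


class FilteredFractions(ScarFractions):
    """Fractions after filtering: rows need no longer sum to 1."""

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy(dtype=float)
        if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
            raise ValueError("fractions outside [0, 1]")


def apply_fraction_filter_to_counts(
    table: ScarTable, factor: float = 10.0, fmin_scope: str = "fish",
    report: FilterReport | None = None,
) -> tuple[ScarTable, FilterReport]:
    """Run the fraction filter on a count table, zeroing filtered counts.

    Convenience wrapper: computes fractions, applies
    :func:`filter_low_fraction`, and zeroes the corresponding count entries so
    later stages keep operating on counts.
    """
    if report is None:
        report = FilterReport()
    fr = scar_fractions(table)
    scar_cols = fr.scar_columns
    frac = fr.fractions[scar_cols].to_numpy(dtype=float)
    nonzero = frac[frac > 0]
    if nonzero.size == 0:
        raise ValueError("no detected scars: all scar fractions are zero")
    if fmin_scope == "sample":
        masked = np.where(frac > 0, frac, np.inf)
        fmin = masked.min(axis=1, keepdims=True)
        keep = frac >= factor * fmin
    else:
        fmin = nonzero.min()
        keep = frac >= factor * fmin
    counts = table.counts.copy()
    counts[scar_cols] = counts[scar_cols].to_numpy() * keep
    surviving = int((counts[scar_cols].to_numpy() > 0).any(axis=0).sum())
    report.record(
        "low_fraction",
        scars_in=len(scar_cols),
        scars_out=surviving,
        samples_in=len(counts),
        samples_out=len(counts),
    )
    return ScarTable(counts, table.sample_meta.copy(), table.provenance), report


# ---------------------------------------------------------------------------
# Stage 2: per-fish QC
# ---------------------------------------------------------------------------

def fish_qc(
    tables: dict[str, ScarTable],
    max_unscarred_pct: float = 50.0,
    min_scars: int = 100,
    report: FilterReport | None = None,
) -> tuple[set, FilterReport]:
    """Keep fish with efficient scarring.

    A fish is kept iff the mean over its organs of the unscarred-GFP
    percentage is *below* ``max_unscarred_pct`` (strictly) AND the number of
    distinct surviving scars is *above* ``min_scars`` (strictly) — both
    inequalities strict, as printed ("less than 50% … more than 100").

    Parameters
    ----------
    tables : dict
        fish id -> merged + fraction-filtered :class:`ScarTable`.
    """
    if report is None:
        report = FilterReport()
    kept: set = set()
    for fish_id, table in tables.items():
        if table.n_samples == 0:
            logger.warning("fish %s has zero organs; dropped", fish_id)
            report.flags.append(f"fish {fish_id}: zero organs, dropped")
            continue
        fr = scar_fractions(table)
        unscarred_pct = fr.fractions[GFP_UNSCARRED].to_numpy() * 100.0
        mean_unscarred = float(unscarred_pct.mean())
        scar_present = (table.counts[table.scar_columns].to_numpy() > 0).any(axis=0)
        n_scars = int(scar_present.sum())
        ok = (mean_unscarred < max_unscarred_pct) and (n_scars > min_scars)
        report.fish_qc[fish_id] = {
            "mean_unscarred_pct": mean_unscarred,
            "n_scars_after_filter": n_scars,
            "kept": ok,
        }
        if ok:
            kept.add(fish_id)
    report.record(
        "fish_qc",
        scars_in=sum(len(t.scar_columns) for t in tables.values()),
        scars_out=sum(len(tables[f].scar_columns) for f in kept),
        samples_in=sum(t.n_samples for t in tables.values()),
        samples_out=sum(tables[f].n_samples for f in kept),
    )
    return kept, report


# ---------------------------------------------------------------------------
# Stage 3: cross-fish rare-scar filter
# ---------------------------------------------------------------------------

def filter_shared_scars(
    fish_tables: dict[str, ScarTable],
    blacklist: set | None = None,
    report: FilterReport | None = None,
) -> tuple[dict[str, ScarTable], FilterReport]:
    """Remove scars detected in more than one fish, or on the blacklist.

    A scar column is removed from *every* fish if its count is positive
    anywhere in two or more fish, or if its id is blacklisted (the blacklist
    generalizes the original exclusion of scars seen in unrelated dynamics
    experiments).  Only scars private to a single fish — rare scars, with a
    creation probability around 1e-5 — survive as clone markers.
    """
    if report is None:
        report = FilterReport()
    blacklist = set(blacklist or ())
    presence_fish: dict[str, set] = {}
    all_scars: set = set()
    for fish_id, table in fish_tables.items():
        cols = table.scar_columns
        arr = table.counts[cols].to_numpy()
        present = {c for c, p in zip(cols, arr.any(axis=0)) if p}
        presence_fish[fish_id] = present
        all_scars.update(cols)

    support: dict[str, int] = {s: 0 for s in all_scars}
    for present in presence_fish.values():
        for s in present:
            support[s] += 1

    shared = {s for s, n in support.items() if n >= 2}
    hits = sorted(blacklist & all_scars)
    report.blacklist_hits.extend(hits)
    drop = shared | blacklist
    drop.discard(GFP_UNSCARRED)

    out: dict[str, ScarTable] = {}
    for fish_id, table in fish_tables.items():
        keep = [c for c in table.scar_columns if c not in drop]
        out[fish_id] = table.subset_columns(keep)
    report.record(
        "shared_scars",
        scars_in=len(all_scars),
        scars_out=len(all_scars - drop),
        samples_in=sum(t.n_samples for t in fish_tables.values()),
        samples_out=sum(t.n_samples for t in out.values()),
    )
    return out, report


# ---------------------------------------------------------------------------
# Stage 4: binarization
# ---------------------------------------------------------------------------

def binarize(
    table: ScarTable, report: FilterReport | None = None
) -> tuple[BinaryScarMatrix, FilterReport]:
    """Binarize post-filter counts: presence = 1 iff count > 0.

    ``GFP_unscarred`` is dropped (QC quantity, not a clone marker) and
    all-zero scar columns are dropped with a warning.
    """
    if report is None:
        report = FilterReport()
    cols = table.scar_columns
    arr = (table.counts[cols].to_numpy() > 0).astype(np.int8)
    nonempty = arr.any(axis=0)
    if not nonempty.all():
        dropped = [c for c, ok in zip(cols, nonempty) if not ok]
        logger.warning("dropping %d all-zero scar columns", len(dropped))
        report.flags.append(f"binarize: dropped {len(dropped)} all-zero columns")
    keep_cols = [c for c, ok in zip(cols, nonempty) if ok]
    presence = pd.DataFrame(
        arr[:, nonempty], index=table.counts.index, columns=keep_cols
    )
    report.record(
        "binarize",
        scars_in=len(cols),
        scars_out=len(keep_cols),
        samples_in=len(presence),
        samples_out=len(presence),
    )
    return BinaryScarMatrix(presence, table.sample_meta.copy()), report


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def filter_pipeline(
    fish_tables: dict[str, ScarTable],
    factor: float = 10.0,
    max_unscarred_pct: float = 50.0,
    min_scars: int = 100,
    blacklist: set | None = None,
    fmin_scope: str = "fish",
    qc: bool = True,
) -> tuple[dict[str, BinaryScarMatrix], FilterReport]:
    """Run merge → fraction filter → fish QC → rare-scar filter → binarize.

    Returns one :class:`BinaryScarMatrix` per surviving fish plus the
    consolidated :class:`FilterReport`.  ``qc=False`` skips the fish-level
    QC gate (useful on small synthetic cohorts below the 100-scar bar).
    """
    report = FilterReport()
    merged = {f: merge_replicates(t) for f, t in fish_tables.items()}
    filtered = {}
    for fish_id, table in merged.items():
        ft, _ = apply_fraction_filter_to_counts(
            table, factor=factor, fmin_scope=fmin_scope, report=report
        )
        filtered[fish_id] = ft
    if qc:
        kept, _ = fish_qc(
            filtered, max_unscarred_pct=max_unscarred_pct,
            min_scars=min_scars, report=report,
        )
        filtered = {f: t for f, t in filtered.items() if f in kept}
    rare, _ = filter_shared_scars(filtered, blacklist=blacklist, report=report)
    out = {}
    for fish_id, table in rare.items():
        b, _ = binarize(table, report=report)
        out[fish_id] = b
    return out, report
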