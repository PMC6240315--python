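"""Scar count tables: data model, TSV I/O, replicate merging, fractions.

A ScarTrace experiment dissects many small body structures from an adult fish
and sequences the CRISPR scars carried by each.  The central object here is
:class:`ScarTable`: a sample × scar matrix of read counts with per-sample
metadata (fish, organ, axial position, technical replicate).  One reserved
column, ``GFP_unscarred``, counts reads from unedited target copies and is the
per-organ QC quantity, not a clone marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved scar-column id for reads from unedited GFP target copies.
GFP_UNSCARRED = "GFP_unscarred"

#: Metadata columns expected before the scar columns in a scar TSV.
META_COLUMNS = ["sample_id", "fish_id", "organ", "axis_position", "replicate_id"]

_AXIS_VALUES = {"head", "mid", "tail", "NA"}


@dataclass
class ScarTable:
    """Sample × scar read-count matrix with per-sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, index = sample ids, columns = scar ids
        (strings ``"position:indel-signature"``) including exactly one
        ``GFP_unscarred`` column.
    sample_meta : pandas.DataFrame
        One row per sample (same index as ``counts``) with columns
        ``fish_id``, ``organ``, ``axis_position``, ``replicate_id``.
    provenance : str
        Free-text origin note; unknown metadata columns from input files are
        folded in here.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.counts.index.name = "sample_id"
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        """Check the table invariants, raising ``ValueError`` on violation."""
        if not self.counts.index.is_unique:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample_ids: {dupes}")
        cols = list(self.counts.columns)
        n_gfp = cols.count(GFP_UNSCARRED)
        if n_gfp != 1:
            raise ValueError(
                f"reserved column missing: expected exactly one "
                f"'{GFP_UNSCARRED}' column, found {n_gfp}"
            )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise ValueError(
                    f"non-integer count at row {self.counts.index[bad[0]]!r}, "
                    f"column {cols[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at row {self.counts.index[bad[0]]!r}, "
                f"column {cols[bad[1]]!r}"
            )
        if not self.counts.index.equals(self.sample_meta.index):
            raise ValueError("counts and sample_meta indices differ")
        for col in ("fish_id", "organ"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")
            missing = self.sample_meta[col].isna() | (
                self.sample_meta[col].astype(str) == ""
            )
            if missing.any():
                raise ValueError(
                    f"samples without {col}: "
                    f"{self.sample_meta.index[missing].tolist()}"
                )
        for col in ("axis_position", "replicate_id"):
            if col not in self.sample_meta.columns:
                self.sample_meta[col] = "NA"
        self.sample_meta = self.sample_meta.fillna({"axis_position": "NA"})

    # -- convenience -------------------------------------------------------
    @property
    def scar_columns(self) -> list[str]:
        """Scar ids excluding the reserved ``GFP_unscarred`` column."""
        return [c for c in self.counts.columns if c != GFP_UNSCARRED]

    @property
    def n_samples(self) -> int:
        return len(self.counts)

    def copy(self) -> "ScarTable":
        return ScarTable(
            self.counts.copy(), self.sample_meta.copy(), self.provenance
        )

    def subset_columns(self, columns: list[str]) -> "ScarTable":
        """Restrict to the given scar columns (GFP_unscarred always kept)."""
        keep = [c for c in self.counts.columns if c in set(columns) or c == GFP_UNSCARRED]
        return ScarTable(self.counts[keep].copy(), self.sample_meta.copy(), self.provenance)


@dataclass
class ScarFractions:
    """Per-sample scar fractions: each row of counts divided by its total.

    Rows with a positive total sum to 1; all-zero rows stay all-zero.  The
    paper reports these as scar percentages (fraction × 100).
    """

    fractions: pd.DataFrame
    sample_meta: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy(dtype=float)
        if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
            raise ValueError("fractions outside [0, 1]")
        sums = arr.sum(axis=1)
        ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12)
        if not ok.all():
            raise ValueError(
                f"row sums not in {{0, 1}}: {sums[~ok].tolist()}"
            )

    @property
    def scar_columns(self) -> list[str]:
        return [c for c in self.fractions.columns if c != GFP_UNSCARRED]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_scar_table(path) -> ScarTable:
    """Read a scar count table from TSV.

    The dialect is tab-separated UTF-8 with a header row; metadata columns
    ``sample_id, fish_id, organ, axis_position, replicate_id`` precede the
    scar columns.  Unknown metadata-like columns (non-numeric) are preserved
    in ``provenance``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("first column must be 'sample_id'")
    df = df.set_index("sample_id")
    meta_cols = [c for c in META_COLUMNS[1:] if c in df.columns]
    extra = []
    scar_cols = []
    for c in df.columns:
        if c in meta_cols:
            continue
        try:
            df[c].astype(float)
            scar_cols.append(c)
        except (TypeError, ValueError):
            extra.append(c)
    if GFP_UNSCARRED not in scar_cols:
        raise ValueError(
            f"reserved column missing: '{GFP_UNSCARRED}' not found in {path}"
        )
    counts_f = df[scar_cols].astype(float)
    if not np.allclose(counts_f.to_numpy(), np.round(counts_f.to_numpy())):
        arr = counts_f.to_numpy()
        bad = np.argwhere(arr != np.round(arr))[0]
        raise ValueError(
            f"non-integer count at row {counts_f.index[bad[0]]!r}, "
            f"column {scar_cols[bad[1]]!r}"
        )
    counts = counts_f.astype(np.int64)
    meta = df[meta_cols].copy()
    provenance = f"read from {path}"
    if extra:
        kv = df[extra].to_dict(orient="index")
        provenance += f"; extra columns {extra}: {kv}"
    return ScarTable(counts, meta, provenance)


def write_scar_table(table: ScarTable, path) -> None:
    """Write a :class:`ScarTable` to TSV (inverse of :func:`read_scar_table`)."""
    meta_cols = [c for c in META_COLUMNS[1:] if c in table.sample_meta.columns]
    out = pd.concat([table.sample_meta[meta_cols], table.counts], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def merge_replicates(table: ScarTable) -> ScarTable:
    """Sum counts of technical replicates of the same dissected structure.

    Rows sharing the merging key ``(fish_id, organ, axis_position)`` are summed
    element-wise; the grand total of every scar column is conserved.  The
    merged row takes the sample id ``{fish_id}_{organ}[_{axis}]`` and a cleared
    ``replicate_id``.

    Raises
    ------
    ValueError
        If rows with the same ``sample_id`` disagree on organ labels.
    """
    meta = table.sample_meta
    # same sample_id cannot name two different organs
    if meta.index.has_duplicates:  # pragma: no cover - caught by validate()
        raise ValueError("duplicate sample ids")
    grouped = table.counts.groupby(
        [meta["fish_id"].to_numpy(), meta["organ"].to_numpy(),
         meta["axis_position"].to_numpy()],
        sort=False,
    ).sum()

    new_index, new_meta = [], []
    for fish, organ, axis in grouped.index:
        sid = f"{fish}_{organ}" if axis in ("NA", "", None) else f"{fish}_{organ}_{axis}"
        new_index.append(sid)
        new_meta.append(
            {"fish_id": fish, "organ": organ, "axis_position": axis, "replicate_id": ""}
        )
    counts = grouped.set_axis(pd.Index(new_index, name="sample_id"))
    meta_df = pd.DataFrame(new_meta, index=counts.index)
    return ScarTable(counts, meta_df, table.provenance + "; replicates merged")


def scar_fractions(table: ScarTable) -> ScarFractions:
    """Normalize each sample's counts to fractions of its row total.

    All-zero rows yield all-zero fractions and a logged warning (a dissected
    structure with no reads at all is a failed library, not evidence).
    """
    arr = table.counts.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning(
            "all-zero count rows kept as zero fractions: %s",
            table.counts.index[zero].tolist(),
        )
    safe = np.where(zero, 1.0, totals)
    frac = arr / safe[:, None]
    df = pd.DataFrame(frac, index=table.counts.index, columns=table.counts.columns)
    return ScarFractions(df, table.sample_meta.copy(), table.provenance)
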