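"""Reading, writing and quality filtering of two-channel expression data.

Two in-memory containers are used throughout the package:

* a *spot table* — per-spot foreground/background intensities for one
  hybridization, wrapped in :class:`SpotTable` together with a parse report;
* an *expression matrix* — a plain :class:`pandas.DataFrame` of
  log2(sample/reference) ratios with genes as rows, samples as columns and
  ``NaN`` marking missing measurements.

The filters implement the standard two-color microarray QC cascade: a
background-signal filter (foreground at least 50% above background in both
channels), a presence filter (a gene must be measured in a minimum fraction
of samples) and a fold-variation filter (a gene must deviate from its mean
by a minimum fold change in a minimum number of samples).  All per-gene
statistics use valid (non-missing) entries only; missing values are never
imputed.

The on-disk matrix dialect is a PCL-like TSV: first column the gene id,
optional second column a gene name, remaining columns samples, missing cells
empty.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SpotTable",
    "ExperimentDesign",
    "read_spot_table",
    "spot_log_ratio",
    "qc_filter_spots",
    "filter_presence",
    "filter_variation",
    "mean_center_genes",
    "read_matrix",
    "write_matrix",
]

SPOT_COLUMNS = ("spot_id", "clone_id", "ch1_fg", "ch1_bg", "ch2_fg", "ch2_bg", "flag")
_INTENSITY_COLUMNS = ("ch1_fg", "ch1_bg", "ch2_fg", "ch2_bg")

ROLES = ("monoculture_A", "monoculture_B", "coculture")


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


@dataclass
class SpotTable:
    """Per-spot two-channel intensities for one hybridization.

    Attributes
    ----------
    data
        One row per spot with columns ``spot_id, clone_id, ch1_fg, ch1_bg,
        ch2_fg, ch2_bg, flag``.  Intensities are floats (NaN = unparsable or
        missing), ``flag`` is an integer where nonzero marks a manually
        flagged bad spot.
    parse_report
        List of ``(row_number, column, raw_value)`` for fields that could not
        be parsed as numbers; row numbers are 1-based file lines including
        the header.
    """

    data: pd.DataFrame
    parse_report: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data["spot_id"].duplicated().any():
            dupes = self.data.loc[self.data["spot_id"].duplicated(), "spot_id"]
            raise FormatError(f"duplicate spot_id values: {sorted(set(dupes))[:5]}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class ExperimentDesign:
    """Maps sample ids to culture roles and replicate indices.

    ``roles`` maps each sample id to ``(role, replicate)`` with role one of
    ``monoculture_A``, ``monoculture_B``, ``coculture``.  Replicate indices
    must be unique within a role.
    """

    roles: Mapping[str, tuple[str, int]]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for sample, (role, rep) in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for sample {sample!r}")
            key = (role, rep)
            if key in seen:
                raise ValueError(
                    f"replicate index {rep} duplicated in role {role!r} "
                    f"({seen[key]!r} and {sample!r})"
                )
            seen[key] = sample

    def samples(self, role: str) -> list[str]:
        """Sample ids assigned to ``role``, in replicate order."""
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        members = [(rep, s) for s, (r, rep) in self.roles.items() if r == role]
        return [s for _, s in sorted(members)]

    def require_all_roles(self) -> None:
        for role in ROLES:
            if not self.samples(role):
                raise ValueError(f"design has no sample for role {role!r}")


def read_spot_table(path: str | Path | _io.TextIOBase) -> SpotTable:
    """Read a tab-delimited spot table.

    The file must have a header naming at least the columns in
    :data:`SPOT_COLUMNS`.  Unparsable numeric fields become NaN and are
    recorded in the parse report with their row numbers.
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError("empty spot table file") from None
    missing = [c for c in SPOT_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"spot table missing required column(s): {', '.join(missing)}")
    if len(raw) == 0:
        raise FormatError("spot table has a header but no data rows")

    report: list[tuple[int, str, str]] = []
    out = pd.DataFrame({"spot_id": raw["spot_id"], "clone_id": raw["clone_id"]})
    for col in _INTENSITY_COLUMNS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna()
        for idx in raw.index[bad]:
            # +2: header line plus 1-based numbering
            report.append((int(idx) + 2, col, raw.at[idx, col]))
        if (vals.dropna() < 0).any():
            raise FormatError(f"negative intensity in column {col}")
        out[col] = vals.astype(float)
    flags = pd.to_numeric(raw["flag"], errors="coerce")
    for idx in raw.index[flags.isna()]:
        report.append((int(idx) + 2, "flag", raw.at[idx, "flag"]))
    out["flag"] = flags.fillna(1).astype(int)  # unparsable flag treated as flagged
    return SpotTable(out.reset_index(drop=True), report)


def spot_log_ratio(table: SpotTable) -> pd.Series:
    """Per-spot log2 ratio of background-corrected intensities.

    ``log2((ch1_fg - ch1_bg) / (ch2_fg - ch2_bg))`` where both
    background-corrected values are strictly positive; otherwise NaN.
    """
    d = table.data
    num = d["ch1_fg"] - d["ch1_bg"]
    den = d["ch2_fg"] - d["ch2_bg"]
    valid = (num > 0) & (den > 0)
    out = pd.Series(np.nan, index=d.index, name="log_ratio")
    out[valid] = np.log2(num[valid] / den[valid])
    return out


def qc_filter_spots(table: SpotTable, background_factor: float = 1.5) -> pd.Series:
    """Boolean keep-mask for spots passing flag and background-signal QC.

    A spot is kept iff it is not flagged and its foreground is at least
    ``background_factor`` times the background in *both* channels.  With a
    zero background the foreground must still be positive: a dark spot on a
    dark background carries no signal.
    """
    d = table.data
    keep = d["flag"] == 0
    for fg, bg in (("ch1_fg", "ch1_bg"), ("ch2_fg", "ch2_bg")):
        ok = (d[fg] >= background_factor * d[bg]) & (d[fg] > 0)
        keep &= ok.fillna(False)
    return keep.rename("keep")


def filter_presence(matrix: pd.DataFrame, min_fraction: float = 0.8) -> pd.DataFrame:
    """Retain genes with valid values in at least ``min_fraction`` of samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if matrix.shape[1] == 0:
        return matrix.iloc[0:0]
    frac = matrix.notna().sum(axis=1) / matrix.shape[1]
    return matrix.loc[frac >= min_fraction]


def filter_variation(
    matrix: pd.DataFrame, fold: float = 3.0, min_samples: int = 2
) -> pd.DataFrame:
    """Retain genes deviating >= log2(fold) from their mean in >= min_samples samples.

    Deviation is measured in log2 space against the per-gene mean over valid
    entries, so a "3-fold deviation" means |value - mean| >= log2 3.  Genes
    with fewer than two valid entries are removed.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    cutoff = np.log2(fold)
    dev = (matrix.sub(matrix.mean(axis=1, skipna=True), axis=0)).abs()
    n_hits = (dev >= cutoff).sum(axis=1)
    enough_data = matrix.notna().sum(axis=1) >= 2
    return matrix.loc[(n_hits >= min_samples) & enough_data]


def mean_center_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean (over valid entries); missingness preserved."""
    return matrix.sub(matrix.mean(axis=1, skipna=True), axis=0)


def read_matrix(path: str | Path | _io.TextIOBase) -> pd.DataFrame:
    """Read a PCL-like TSV expression matrix (genes x samples, NaN = empty cell).

    The first column holds gene ids; a second column named ``gene_name`` (or
    ``NAME``) is tolerated and dropped.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError("empty matrix file") from None
    for meta in ("gene_name", "NAME"):
        if meta in df.columns:
            df = df.drop(columns=meta)
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path: str | Path | _io.TextIOBase) -> None:
    """Write a matrix in the PCL-like TSV dialect (empty cell = missing)."""
    out = matrix.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6f", na_rep="")
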