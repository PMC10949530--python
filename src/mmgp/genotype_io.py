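"""Genotype table reading, quality control, recoding and imputation.

SNP genotypes arrive as HapMap-style numeric tables in the TASSEL coding
(1 = homozygous major, 0 = homozygous minor, 0.5 = heterozygous) and are
recoded to the {-1, 0, +1} dosage-deviation scale used by every downstream
relationship-matrix computation.  Markers are filtered on minor allele
frequency and missingness, then mean-imputed per marker column.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "QCReport",
    "read_hapmap_numeric",
    "read_marker_csv",
    "recode_tassel",
    "filter_markers",
    "impute_mean",
    "write_marker_csv",
]

#: coding tags
TASSEL = "tassel_numeric"
RECODED = "recoded"

DEFAULT_MISSING_TOKENS = ("NA", "NaN", "nan", "")

# TASSEL numeric value -> dosage deviation
_TASSEL_MAP = {1.0: -1.0, 0.5: 0.0, 0.0: 1.0}


@dataclasses.dataclass
class MarkerMatrix:
    """Lines x markers genotype grid with missing entries as NaN.

    ``values[i, k]`` is the genotype of line ``line_ids[i]`` at marker
    ``marker_ids[k]``.  ``coding_tag`` records whether entries are still in
    TASSEL numeric coding ({1, 0.5, 0}) or recoded to {-1, 0, +1}.
    """

    values: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]
    coding_tag: str = TASSEL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D lines x markers array")
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line identifiers")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker identifiers")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids)


@dataclasses.dataclass
class QCReport:
    """Bookkeeping for a marker-filtering pass.

    Missingness is evaluated before MAF, so a marker failing both rules is
    counted once, under missingness.
    """

    n_markers_in: int
    n_removed_maf: int
    n_removed_missing: int
    n_markers_out: int
    maf_threshold: float
    missing_threshold: float

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold < 1.0 and 0.0 < self.missing_threshold < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        expected = self.n_markers_in - self.n_removed_maf - self.n_removed_missing
        if self.n_markers_out != expected:
            raise ValueError("QCReport counts are inconsistent")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


class HapmapParseError(ValueError):
    """Raised when a genotype table cannot be parsed."""


def read_hapmap_numeric(
    path: str | Path,
    *,
    orientation: str = "markers_as_rows",
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
    sep: str = "\t",
) -> MarkerMatrix:
    """Read a HapMap-style numeric genotype table in TASSEL coding.

    The file is a delimited table whose header row carries identifiers for the
    columns and whose first column carries identifiers for the rows.  With the
    default ``markers_as_rows`` orientation rows are markers and columns are
    lines (the HapMap convention); ``lines_as_rows`` transposes the reading.
    Entries must be 1, 0.5, 0 or one of ``missing_tokens``.
    """
    if orientation not in ("markers_as_rows", "lines_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise HapmapParseError(f"{path}: empty genotype file")
    header = lines[0].split(sep)
    if len(header) < 2:
        raise HapmapParseError(f"{path}: header must name at least one data column")
    col_ids = [c.strip() for c in header[1:]]
    ncol = len(col_ids)
    row_ids: list[str] = []
    rows: list[list[float]] = []
    missing = set(missing_tokens)
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split(sep)
        if len(fields) != ncol + 1:
            raise HapmapParseError(
                f"{path}:{lineno}: expected {ncol + 1} fields, found {len(fields)}"
            )
        row_ids.append(fields[0].strip())
        parsed = []
        for token in fields[1:]:
            token = token.strip()
            if token in missing:
                parsed.append(np.nan)
                continue
            try:
                value = float(token)
            except ValueError:
                raise HapmapParseError(
                    f"{path}:{lineno}: unknown genotype token {token!r}"
                ) from None
            if value not in (1.0, 0.5, 0.0):
                raise HapmapParseError(
                    f"{path}:{lineno}: genotype value {value} not in {{1, 0.5, 0}}"
                )
            parsed.append(value)
        rows.append(parsed)
    values = np.asarray(rows, dtype=float)
    if orientation == "markers_as_rows":
        return MarkerMatrix(values.T, line_ids=col_ids, marker_ids=row_ids)
    return MarkerMatrix(values, line_ids=row_ids, marker_ids=col_ids)


def read_marker_csv(path: str | Path, *, coding_tag: str = RECODED) -> MarkerMatrix:
    """Read a lines x markers CSV matrix (lines as the index column)."""
    frame = pd.read_csv(path, index_col=0)
    return MarkerMatrix(
        frame.to_numpy(dtype=float),
        line_ids=[str(i) for i in frame.index],
        marker_ids=[str(c) for c in frame.columns],
        coding_tag=coding_tag,
    )


def write_marker_csv(m: MarkerMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path)


def recode_tassel(m: MarkerMatrix) -> MarkerMatrix:
    """Map TASSEL numeric coding to dosage deviations: 1 -> -1, 0.5 -> 0, 0 -> +1.

    Homozygous-major genotypes become -1, heterozygotes 0, homozygous-minor +1,
    so the value counts copies of the minor allele minus one.  Missing cells
    stay missing.  The map is an entrywise bijection on {1, 0.5, 0}.
    """
    if m.coding_tag != TASSEL:
        raise ValueError(f"expected coding {TASSEL!r}, found {m.coding_tag!r}")
    v = m.values
    valid = np.isnan(v) | (v == 1.0) | (v == 0.5) | (v == 0.0)
    if not valid.all():
        bad = v[~valid].flat[0]
        raise ValueError(f"entry {bad!r} outside TASSEL coding {{1, 0.5, 0, missing}}")
    out = np.full_like(v, np.nan)
    for src, dst in _TASSEL_MAP.items():
        out[v == src] = dst
    return MarkerMatrix(out, list(m.line_ids), list(m.marker_ids), coding_tag=RECODED)


def minor_allele_frequency(values: np.ndarray) -> np.ndarray:
    """Folded minor-allele frequency per marker column of a recoded matrix.

    Entries are read as dosage deviations, i.e. dosage d = value + 1 in
    {0, 1, 2} copies of the +1 allele; p = sum(d) / (2 * n_nonmissing), folded
    to min(p, 1 - p).  Columns with no data return NaN.
    """
    dosage = values + 1.0
    n = np.sum(~np.isnan(values), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosage, axis=0) / (2.0 * n)
    p = np.where(n == 0, np.nan, p)
    return np.minimum(p, 1.0 - p)


def filter_markers(
    m: MarkerMatrix,
    maf_threshold: float = 0.05,
    missing_threshold: float = 0.5,
) -> tuple[MarkerMatrix, QCReport]:
    """Remove markers with MAF < ``maf_threshold`` or missingness >= ``missing_threshold``.

    The missingness rule runs first; MAF is then computed on the survivors'
    non-missing entries, so a marker failing both rules is tallied once under
    missingness.  A marker with zero non-missing entries is always removed by
    the missingness rule.  The operation is idempotent.
    """
    if m.coding_tag != RECODED:
        raise ValueError("filter_markers requires a recoded matrix")
    if m.n_lines == 0:
        raise ValueError("at least one line is required")
    if not (0.0 < maf_threshold < 1.0 and 0.0 < missing_threshold < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")

    miss_frac = np.mean(np.isnan(m.values), axis=0)
    fail_missing = miss_frac >= missing_threshold

    maf = minor_allele_frequency(m.values)
    fail_maf = (~fail_missing) & (np.isnan(maf) | (maf < maf_threshold))

    keep = ~(fail_missing | fail_maf)
    kept = MarkerMatrix(
        m.values[:, keep],
        list(m.line_ids),
        [mid for mid, k in zip(m.marker_ids, keep) if k],
        coding_tag=RECODED,
    )
    report = QCReport(
        n_markers_in=m.n_markers,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int(fail_missing.sum()),
        n_markers_out=int(keep.sum()),
        maf_threshold=maf_threshold,
        missing_threshold=missing_threshold,
    )
    return kept, report


def impute_mean(m: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing cell by the mean of its marker column.

    Per-marker means of the non-missing data are preserved exactly.  An
    all-missing column has no mean to impute from and raises.
    """
    if m.coding_tag != RECODED:
        raise ValueError("impute_mean requires a recoded matrix")
    mask = np.isnan(m.values)
    if not mask.any():
        return m
    n_obs = (~mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [mid for mid, n in zip(m.marker_ids, n_obs) if n == 0]
        raise ValueError(
            f"markers {bad[:5]} have no observed genotypes; run filter_markers first"
        )
    col_means = np.nanmean(m.values, axis=0)
    out = np.where(mask, col_means[np.newaxis, :], m.values)
    return MarkerMatrix(out, list(m.line_ids), list(m.marker_ids), coding_tag=RECODED)
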