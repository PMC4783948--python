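"""Expression-matrix ingestion, quantile normalization and group summaries.

The central container is :class:`ExpressionMatrix`: a genes x samples table of
intensity values (linear scale) together with its sample design — for every
array column a condition (``case``/``control``), a time-point label and a
replicate index.  All downstream stages (differential screening, network
fitting, fold-change reporting) consume this container.

Quantile normalization forces every sample column to share one empirical
distribution (the vector of across-column rank means), the standard first step
for multi-array comparisons.  Group summaries (per-gene case/control means and
log2 fold changes) feed the biomarker report tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DesignMismatchError,
    EmptyInputError,
    MissingGroupError,
    ValidationError,
)

CONDITIONS = ("case", "control")

DESIGN_COLUMNS = ("sample_id", "condition", "time_point", "replicate")


def read_design(path, sep: str = "\t", time_points=None) -> pd.DataFrame:
    """Read a sample-design table (columns sample_id, condition, time_point,
    replicate) and validate it."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"design table missing columns: {missing}")
    df = df[list(DESIGN_COLUMNS)].copy()
    df["replicate"] = df["replicate"].astype(int)
    return validate_design(df, time_points=time_points)


def validate_design(design: pd.DataFrame, time_points=None) -> pd.DataFrame:
    """Validate a design frame: unique sample ids, known conditions and,
    when an ordered time-point set is configured, known labels."""
    design = design.reset_index(drop=True)
    if design["sample_id"].duplicated().any():
        dupes = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in design: {dupes}")
    bad = set(design["condition"]) - set(CONDITIONS)
    if bad:
        raise ValidationError(
            f"unknown conditions {sorted(bad)}; expected one of {CONDITIONS}"
        )
    if time_points is not None:
        unknown = set(design["time_point"]) - set(time_points)
        if unknown:
            raise ValidationError(
                f"time points {sorted(unknown)} not in configured set {tuple(time_points)}"
            )
    if (design["replicate"].astype(int) < 1).any():
        raise ValidationError("replicate indices must be >= 1")
    return design


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus sample design.

    ``values`` is a DataFrame with gene ids as index and sample ids as
    columns; column order matches the design row order.  Values must be
    finite with no missing cells (the ingestion missing-value policy is
    applied before construction).
    """

    values: pd.DataFrame
    design: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.design = validate_design(self.design)
        expected = list(self.design["sample_id"])
        if list(self.values.columns) != expected:
            raise DesignMismatchError(
                "expression columns do not match design sample order"
            )
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        self.values = self.values.astype(float)

    # -- introspection -----------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def time_points(self) -> list[str]:
        seen: list[str] = []
        for tp in self.design["time_point"]:
            if tp not in seen:
                seen.append(tp)
        return seen

    def sample_ids(self, condition: str | None = None, time_point: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.design.index)
        if condition is not None:
            mask &= self.design["condition"] == condition
        if time_point is not None:
            mask &= self.design["time_point"] == time_point
        return list(self.design.loc[mask, "sample_id"])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        design = self.design[self.design["sample_id"].isin(sample_ids)]
        design = design.set_index("sample_id").loc[sample_ids].reset_index()
        return ExpressionMatrix(self.values[sample_ids], design)

    def to_tsv(self, path, sep: str = "\t") -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep=sep, float_format="%.12g")


def read_expression_table(
    path,
    design: pd.DataFrame,
    sep: str = "\t",
    collapse: str = "max_mean",
    missing: str = "reject",
) -> ExpressionMatrix:
    """Read a delimited expression table against a sample design.

    The table must carry a header row of sample ids and gene ids in the
    first column.  Columns are reordered to the design order; duplicate gene
    ids are collapsed (``max_mean`` keeps the probe row with the largest
    mean, ``median`` takes the per-cell median across probes); gene symbols
    are upper-cased so they join against PPI edge lists.

    ``missing``: ``reject`` raises on any missing cell, ``drop`` removes
    genes with missing values.
    """
    if collapse not in ("max_mean", "median"):
        raise ValidationError(f"unknown collapse rule {collapse!r}")
    if missing not in ("reject", "drop"):
        raise ValidationError(f"unknown missing policy {missing!r}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise EmptyInputError(f"expression table {path} has no data rows")
    wanted = list(design["sample_id"])
    absent = [s for s in wanted if s not in df.columns]
    if absent:
        raise DesignMismatchError(
            f"design samples missing from expression header: {absent}"
        )
    df = df[wanted]
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric expression cell: {exc}") from exc
    if df.isna().any().any():
        if missing == "reject":
            raise DataError("expression table contains missing values")
        df = df.dropna(axis=0)
        if df.empty:
            raise EmptyInputError("all genes dropped by missing-value policy")
    df.index = df.index.astype(str).str.upper()
    if df.index.duplicated().any():
        if collapse == "max_mean":
            keep = df.assign(_mean=df.mean(axis=1))
            keep = keep.sort_values("_mean", ascending=False)
            keep = keep[~keep.index.duplicated(keep="first")]
            df = keep.drop(columns="_mean").loc[sorted(set(df.index), key=list(df.index).index)]
        else:
            df = df.groupby(level=0, sort=False).median()
    return ExpressionMatrix(df, design)


# -- quantile normalization ------------------------------------------------


def _qn_target(arr: np.ndarray) -> np.ndarray:
    """Across-column means of the within-column sorted values."""
    return np.sort(arr, axis=0).mean(axis=1)


def _qn_column(col: np.ndarray, target: np.ndarray) -> np.ndarray:
    order = np.argsort(col, kind="stable")
    out = np.empty_like(target)
    sorted_vals = col[order]
    n = len(col)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        # ties receive the mean of the rank-mean values they span
        out[order[i : j + 1]] = target[i : j + 1].mean()
        i = j + 1
    return out


def quantile_normalize(x: ExpressionMatrix, scope: str = "pooled") -> ExpressionMatrix:
    """Quantile-normalize sample columns.

    ``scope='pooled'`` normalizes all samples jointly (default, matching a
    whole-accession normalization); ``scope='per_time_point'`` normalizes the
    columns of each time point separately.
    """
    if scope not in ("pooled", "per_time_point"):
        raise ValidationError(f"unknown normalization scope {scope!r}")
    arr = x.values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("cannot quantile-normalize non-finite values")
    if x.n_samples < 2:
        warnings.warn("single-column matrix: quantile normalization is a no-op")
        return ExpressionMatrix(x.values.copy(), x.design)

    def _normalize_block(block: np.ndarray) -> np.ndarray:
        if block.shape[1] < 2:
            return block.copy()
        target = _qn_target(block)
        out = np.empty_like(block)
        for c in range(block.shape[1]):
            out[:, c] = _qn_column(block[:, c], target)
        return out

    if scope == "pooled":
        normalized = _normalize_block(arr)
    else:
        normalized = np.empty_like(arr)
        cols = list(x.values.columns)
        for tp in x.time_points:
            ids = x.sample_ids(time_point=tp)
            idx = [cols.index(s) for s in ids]
            normalized[:, idx] = _normalize_block(arr[:, idx])
    values = pd.DataFrame(normalized, index=x.values.index, columns=x.values.columns)
    return ExpressionMatrix(values, x.design)


# -- group summaries -------------------------------------------------------


def group_means(x: ExpressionMatrix, time_point: str) -> pd.DataFrame:
    """Per-gene case and control means at one time point (linear scale).

    Returns a DataFrame indexed by gene with columns ``case_mean`` and
    ``control_mean``.
    """
    case_ids = x.sample_ids("case", time_point)
    control_ids = x.sample_ids("control", time_point)
    if not case_ids or not control_ids:
        raise MissingGroupError(
            f"time point {time_point!r} lacks case or control samples"
        )
    return pd.DataFrame(
        {
            "case_mean": x.values[case_ids].mean(axis=1),
            "control_mean": x.values[control_ids].mean(axis=1),
        }
    )


def log2_fold_change(case_mean, control_mean, pseudocount: float | None = None):
    """log2(case/control); scalar or elementwise on arrays.

    Non-positive means raise unless a pseudocount is supplied, in which case
    it is added to both numerator and denominator.
    """
    case = np.asarray(case_mean, dtype=float)
    control = np.asarray(control_mean, dtype=float)
    if pseudocount is not None:
        case = case + pseudocount
        control = control + pseudocount
    if np.any(case <= 0) or np.any(control <= 0):
        raise ValidationError(
            "log2 fold change requires positive means (or a pseudocount)"
        )
    out = np.log2(case / control)
    return float(out) if out.ndim == 0 else out
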