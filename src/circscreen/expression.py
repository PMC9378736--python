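"""Abundance matrices, RPM/FPKM scaling and the differential-expression test.

circRNAs are quantified as back-spliced junction reads per million mapped
reads (RPM); genes as fragments per kilobase per million (FPKM).  The
differential test is a deliberate, documented stand-in for negative-binomial
count machinery: a two-sided paired (or Welch) t-test on ``log2(value +
pseudocount)`` with Benjamini–Hochberg adjustment on request.  Features are
called up/down only when both the fold-change cut (|log2FC| >= 1 by default)
and the p-value cut are met.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

VALID_UNITS = ("count", "RPM", "FPKM")


@dataclass
class ExpressionMatrix:
    """Features x samples nonnegative abundances with a unit tag.

    Thin wrapper around a :class:`pandas.DataFrame` (rows = features,
    columns = samples) enforcing nonnegativity and a single unit tag.
    """

    values: pd.DataFrame
    unit: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ParameterError(f"unknown unit tag {self.unit!r}; expected one of {VALID_UNITS}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (np.isnan(arr).any() or (arr < 0).any()):
            raise ParameterError("expression values must be nonnegative and finite")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ParameterError("feature and sample labels must be unique")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path, comments: list[str] | None = None) -> None:
        from .io import write_tsv
        write_tsv(self.values, path, comments=[f"unit: {self.unit}", *(comments or [])])

    @classmethod
    def from_tsv(cls, path, unit: str) -> "ExpressionMatrix":
        from .io import read_tsv
        return cls(read_tsv(path), unit)


@dataclass(frozen=True)
class DEResult:
    """Per-feature differential-expression summary (tumour vs normal)."""

    feature: str
    log2fc: float
    pvalue: float
    padj: float
    call: str  # "up" | "down" | "ns"


def _as_series(totals, samples) -> pd.Series:
    s = pd.Series(totals, dtype=float)
    missing = [x for x in samples if x not in s.index]
    if missing:
        raise ParameterError(f"mapped totals missing for samples: {missing}")
    return s.loc[list(samples)]


def rpm_scale(junction_counts: pd.DataFrame | ExpressionMatrix,
              mapped_totals) -> ExpressionMatrix:
    """Scale junction counts to reads per million mapped reads.

    ``value = count / mapped_total * 1e6`` per sample.
    """
    df = junction_counts.values if isinstance(junction_counts, ExpressionMatrix) else junction_counts
    totals = _as_series(mapped_totals, df.columns)
    zero = totals[totals <= 0]
    if len(zero):
        raise ParameterError(f"zero mapped-read total for sample(s): {list(zero.index)}")
    return ExpressionMatrix(df / totals * 1e6, "RPM")


def fpkm_scale(gene_counts: pd.DataFrame | ExpressionMatrix,
               gene_lengths, mapped_totals) -> ExpressionMatrix:
    """Scale gene counts to fragments per kilobase per million mapped reads.

    ``value = count / (length/1e3) / (mapped_total/1e6)``.
    """
    df = gene_counts.values if isinstance(gene_counts, ExpressionMatrix) else gene_counts
    lengths = pd.Series(gene_lengths, dtype=float).reindex(df.index)
    if lengths.isna().any():
        raise ParameterError(f"lengths missing for features: {list(df.index[lengths.isna()])}")
    if (lengths <= 0).any():
        raise ParameterError(f"non-positive length for features: {list(lengths.index[lengths <= 0])}")
    totals = _as_series(mapped_totals, df.columns)
    zero = totals[totals <= 0]
    if len(zero):
        raise ParameterError(f"zero mapped-read total for sample(s): {list(zero.index)}")
    return ExpressionMatrix(df.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1), "FPKM")


def de_test(matrix: ExpressionMatrix | pd.DataFrame,
            groups: dict[str, str],
            paired: bool = True,
            pseudocount: float = 0.5,
            lfc_cut: float = 1.0,
            p_cut: float = 0.05,
            adjust: bool = False,
            pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Tumour-vs-normal differential test on an abundance matrix.

    log2FC = log2(mean_T + pc) - log2(mean_N + pc) on the raw scale; the
    p-value comes from a two-sided paired (or Welch) t-test on
    log2(value + pc).  Features with degenerate variance get p = 1 with a
    warning rather than an error.  When ``adjust`` is set, the significance
    cut applies to the Benjamini-Hochberg adjusted p.

    Returns a DataFrame indexed by feature with columns
    ``log2fc, pvalue, padj, call``, sorted by ascending p.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    tum = [s for s in df.columns if groups.get(s) == "tumour"]
    nor = [s for s in df.columns if groups.get(s) == "normal"]
    unknown = [s for s in df.columns if s not in groups]
    if unknown:
        raise ParameterError(f"samples without group label: {unknown}")
    if len(tum) < 2 or len(nor) < 2:
        raise ParameterError("need at least 2 samples per group")
    if paired:
        if pairs is None:
            if len(tum) != len(nor):
                raise ParameterError("paired test requires equal group sizes")
            pairs = list(zip(sorted(tum), sorted(nor)))
        tum = [t for t, _ in pairs]
        nor = [n for _, n in pairs]

    vals = df.to_numpy(dtype=float)
    t_idx = [df.columns.get_loc(s) for s in tum]
    n_idx = [df.columns.get_loc(s) for s in nor]
    pc = float(pseudocount)
    lfc = np.log2(vals[:, t_idx].mean(axis=1) + pc) - np.log2(vals[:, n_idx].mean(axis=1) + pc)

    logv = np.log2(vals + pc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            res = stats.ttest_rel(logv[:, t_idx], logv[:, n_idx], axis=1)
        else:
            res = stats.ttest_ind(logv[:, t_idx], logv[:, n_idx], axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(pvals)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} feature(s) with degenerate variance: p set to 1",
                      stacklevel=2)
        pvals[bad] = 1.0

    padj = stats.false_discovery_control(pvals, method="bh") if len(pvals) else pvals
    crit = padj if adjust else pvals
    call = np.where((lfc >= lfc_cut) & (crit < p_cut), "up",
                    np.where((lfc <= -lfc_cut) & (crit < p_cut), "down", "ns"))

    out = pd.DataFrame({"log2fc": lfc, "pvalue": pvals, "padj": padj, "call": call},
                       index=df.index)
    out.index.name = "feature"
    out.attrs["test"] = ("paired t" if paired else "Welch t") + \
        " on log2(x+pc); stand-in for NB count models"
    return out.sort_values("pvalue", kind="mergesort")


def de_results(table: pd.DataFrame) -> list[DEResult]:
    """Typed view of a :func:`de_test` table."""
    return [DEResult(str(ix), float(r.log2fc), float(r.pvalue), float(r.padj), str(r.call))
            for ix, r in table.iterrows()]
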