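"""Correlation-phenotype gene-set enrichment.

Coding genes are ranked by their sample-wise Pearson correlation with a
circRNA's abundance profile (the circRNA acts as a molecular phenotype);
enrichment of a gene set toward either end of that ranking is scored with
the classic weighted Kolmogorov-Smirnov running sum, and significance is
assessed with a gene-set permutation null: random same-size sets drawn
from the ranked universe.  p-values carry the +1 correction and are never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, StageError
from .expression import ExpressionMatrix


@dataclass
class RankedList:
    """Genes sorted by descending ranking metric (Pearson r)."""

    genes: list[str]
    scores: np.ndarray
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ParameterError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ParameterError("duplicate genes in ranked list")
        if not np.all(np.isfinite(self.scores)):
            raise ParameterError("ranking metric must be finite")
        if np.any(np.abs(self.scores) > 1 + 1e-9):
            raise ParameterError("Pearson r must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "r": self.scores}).set_index("gene")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ParameterError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ParameterError(f"gene set {self.name!r} has duplicate members")


@dataclass
class EsResult:
    es: float
    running_sum: np.ndarray
    hit_indices: np.ndarray
    leading_edge: list[str]
    evaluable: bool = True
    note: str = ""


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    pvalue: float
    n_perm: int
    leading_edge: list[str]
    direction: str  # "positive" | "negative"
    evaluable: bool = True


def pearson_profile(circ_profile, genes: ExpressionMatrix | pd.DataFrame) -> RankedList:
    """Rank every gene by Pearson correlation with the circRNA profile.

    Constant genes cannot be correlated; they are assigned r = 0 and
    reported in ``constant_genes``.  Ties are broken lexicographically by
    gene id for determinism.
    """
    df = genes.values if isinstance(genes, ExpressionMatrix) else genes
    circ = pd.Series(circ_profile)
    if not circ.index.equals(pd.Index(df.columns)):
        if circ.index.inferred_type in ("integer", "range"):
            if len(circ) != df.shape[1]:
                raise ParameterError("circ profile length does not match sample count")
            circ.index = df.columns
        else:
            try:
                circ = circ.loc[list(df.columns)]
            except KeyError as exc:
                raise ParameterError(f"sample mismatch between circ profile and matrix: {exc}")
    c = circ.to_numpy(dtype=float)
    if c.size < 4:
        raise ParameterError("need at least 4 samples")
    if np.ptp(c) == 0:
        raise ParameterError("circ profile is constant: correlation undefined")
    X = df.to_numpy(dtype=float)
    xc = X - X.mean(axis=1, keepdims=True)
    cc = c - c.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (cc ** 2).sum())
    constant = denom == 0
    denom[constant] = 1.0
    r = (xc @ cc) / denom
    r[constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    order = sorted(range(len(df.index)), key=lambda i: (-r[i], str(df.index[i])))
    return RankedList([str(df.index[i]) for i in order], r[order],
                      constant_genes=[str(g) for g in df.index[constant]])


def gsea_es(ranked: RankedList, gene_set: GeneSet, weight: float = 1.0) -> EsResult:
    """Weighted KS running-sum enrichment score with full profile.

    Hits increment by |r|^weight normalised over the set's hits; misses
    decrement by 1/(N-n).  ES is the running-sum extremum by absolute
    value (the positive extremum wins an exact tie).  The leading edge
    contains the members up to (positive ES) or after (negative ES) the
    extremum.
    """
    N = len(ranked)
    members = set(gene_set.members)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=N)
    n = int(hit.sum())
    if n == 0:
        return EsResult(np.nan, np.zeros(N), np.array([], dtype=int), [],
                        evaluable=False, note="no overlap with ranked list")
    if n == N:
        return EsResult(np.nan, np.zeros(N), np.flatnonzero(hit), [],
                        evaluable=False, note="set spans the entire list")
    w = np.abs(ranked.scores) ** weight
    w_hit = np.where(hit, w, 0.0)
    W = w_hit.sum()
    if W == 0:  # all hit metrics exactly zero: fall back to unweighted hits
        w_hit = hit.astype(float)
        W = float(n)
    steps = w_hit / W - (~hit) / (N - n)
    rs = np.cumsum(steps)
    imax, imin = int(np.argmax(rs)), int(np.argmin(rs))
    es = rs[imax] if rs[imax] >= -rs[imin] else rs[imin]
    hit_idx = np.flatnonzero(hit)
    if es >= 0:
        lead = [ranked.genes[i] for i in hit_idx if i <= imax]
    else:
        lead = [ranked.genes[i] for i in hit_idx if i >= imin]
    return EsResult(float(es), rs, hit_idx, lead)


def _es_fast(abs_w: np.ndarray, hit_idx: np.ndarray, N: int) -> float:
    """O(n) enrichment score from sorted hit indices (permutation inner loop)."""
    n = hit_idx.size
    w = abs_w[hit_idx]
    W = w.sum()
    if W == 0:
        w = np.ones(n)
        W = float(n)
    cum = np.cumsum(w) / W
    j = np.arange(n)
    d = 1.0 / (N - n)
    after = cum - (hit_idx - j) * d
    before = np.concatenate(([0.0], cum[:-1])) - (hit_idx - j) * d
    hi = after.max()
    lo = before.min()
    return float(hi) if hi >= -lo else float(lo)


def gsea_permutation(ranked: RankedList, gene_set: GeneSet, n_perm: int = 1000,
                     weight: float = 1.0, seed: int | None = 0) -> GseaResult:
    """Permutation GSEA with a gene-set (same-size random set) null.

    ``p = (1 + #{|ES_null| >= |ES|}) / (n_perm + 1)``; NES is the observed
    ES divided by the mean |null ES| of the same sign (all nulls if none
    share the sign).
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    obs = gsea_es(ranked, gene_set, weight=weight)
    if not obs.evaluable:
        return GseaResult(gene_set.name, np.nan, np.nan, 1.0, n_perm, [],
                          "positive", evaluable=False)
    N = len(ranked)
    n = obs.hit_indices.size
    abs_w = np.abs(ranked.scores) ** weight
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = np.sort(rng.choice(N, size=n, replace=False))
        null[i] = _es_fast(abs_w, idx, N)
    p = (1.0 + np.sum(np.abs(null) >= abs(obs.es))) / (n_perm + 1.0)
    same_sign = null[np.sign(null) == np.sign(obs.es)] if obs.es != 0 else null
    denom = np.mean(np.abs(same_sign)) if same_sign.size else np.mean(np.abs(null))
    nes = obs.es / denom if denom > 0 else np.nan
    return GseaResult(gene_set.name, obs.es, float(nes), float(p), n_perm,
                      obs.leading_edge, "negative" if obs.es < 0 else "positive")


def prioritize(de_table: pd.DataFrame,
               orf_records: dict[str, "object"],
               gsea_results: dict[str, GseaResult],
               pathway: GeneSet,
               gsea_p_cut: float = 0.05) -> pd.DataFrame:
    """Final candidate ranking: upregulated, short junction ORF, pathway sign.

    Candidates are circRNAs called "up" by the DE stage whose best ORF
    spans the junction and passes the <100 aa screen; they are ranked by
    descending fold change and annotated with the pathway enrichment sign
    and permutation p.  A *hit* additionally requires negative enrichment
    with p below ``gsea_p_cut``.
    """
    if de_table is None:
        raise StageError("missing stage output: differential expression")
    if orf_records is None:
        raise StageError("missing stage output: circORF annotation")
    if gsea_results is None:
        raise StageError("missing stage output: GSEA")
    up = [str(f) for f in de_table.index[de_table["call"] == "up"]]
    rows = []
    for circ_id in up:
        if circ_id not in orf_records:
            raise StageError(f"missing stage output: circORF annotation for {circ_id}")
        rec = orf_records[circ_id]
        if not (rec.spans_junction and rec.passes_length_filter):
            continue
        if circ_id not in gsea_results:
            raise StageError(f"missing stage output: GSEA for {circ_id}")
        g = gsea_results[circ_id]
        rows.append({
            "circ_id": circ_id,
            "log2fc": float(de_table.loc[circ_id, "log2fc"]),
            "de_pvalue": float(de_table.loc[circ_id, "pvalue"]),
            "orf_aa": rec.best_orf.aa_length,
            "es": g.es,
            "nes": g.nes,
            "gsea_p": g.pvalue,
            "pathway": pathway.name,
            "hit": bool(g.evaluable and g.es < 0 and g.pvalue < gsea_p_cut),
        })
    cols = ["circ_id", "log2fc", "de_pvalue", "orf_aa", "es", "nes",
            "gsea_p", "pathway", "hit"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["log2fc", "circ_id"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
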