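"""Reference-gene stability algorithms on RT-qPCR Cq data.

Implements the four classical appraisal methods and their comprehensive
combination, per tissue:

* **geNorm** — mean pairwise variation *M*: for each gene pair the SD over
  samples of the log2 expression ratio; a gene's M is the mean over its
  partners.  Iteratively excluding the worst gene yields the stability
  ranking; the last two genes cannot be separated and tie at rank 1.5.
* **NormFinder** — a variance-components model on log quantities: samples
  are centered to remove loading differences, intra-group variance and
  inter-group bias are estimated per gene, and the stability value combines
  both (lower = more stable).
* **BestKeeper** — descriptive statistics of raw Cq: SD (the ranking
  statistic), CV%, and correlation with the geometric-mean index of all
  candidates.  Unlike the other three it does not work on ratios, so it is
  the only method sensitive to per-sample loading offsets.
* **comparative ΔCt** — mean over partners of the SD of per-sample Cq
  differences.  With all efficiencies equal to 2 this is algebraically
  identical to geNorm's M (log2 ratios of 2^-Cq quantities are Cq
  differences up to a constant).

The comprehensive rank is the geometric mean of the per-method ranks
(RefFinder convention).  Lower values mean more stable throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CqTable, StabilityReport, ValidationError

__all__ = [
    "QuantityMatrix",
    "to_quantities",
    "genorm",
    "genorm_pairwise_v",
    "normfinder",
    "bestkeeper",
    "delta_ct",
    "comprehensive_rank",
    "rank_stability",
    "ALL_METHODS",
]

ALL_METHODS = ("genorm", "normfinder", "bestkeeper", "deltact")


@dataclass
class QuantityMatrix:
    """Relative quantities Q = E^(minCq − Cq), genes × samples.

    Q is dimensionless with per-gene maximum 1 (the sample with the lowest
    Cq).  ``groups`` labels each sample with its treatment group (the
    between-group factor NormFinder models); ``tissue`` tags provenance.
    """

    q: pd.DataFrame
    groups: pd.Series
    tissue: str = ""

    def __post_init__(self) -> None:
        if (self.q.values <= 0).any():
            raise ValidationError("relative quantities must be positive")
        self.groups = self.groups.loc[self.q.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.q.index)

    @property
    def log2q(self) -> pd.DataFrame:
        return np.log2(self.q)


def to_quantities(
    table: CqTable, tissue: str, default_efficiency: float = 2.0
) -> QuantityMatrix:
    """Convert a complete Cq grid for one tissue to relative quantities.

    Q_gs = E_g^(minCq_g − Cq_gs); with E = 2 this is 2^(−ΔCq to the
    per-gene minimum).  Requires technical replicates to have been
    aggregated; missing cells are an error, never imputed.
    """
    cq, meta = table.cq_matrix(tissue)
    eff = np.array([table.efficiency(g, default_efficiency) for g in cq.index])
    delta = cq.sub(cq.min(axis=1), axis=0)  # Cq − minCq ≥ 0
    q = pd.DataFrame(
        np.power(eff[:, None], -delta.values), index=cq.index, columns=cq.columns
    )
    return QuantityMatrix(q, meta["treatment"], tissue)


# ---------------------------------------------------------------------------
# geNorm


def _pairwise_v(log2q: np.ndarray) -> np.ndarray:
    """V[j, k] = SD over samples of log2(Q_j / Q_k) (sample SD, ddof=1)."""
    n = log2q.shape[0]
    v = np.zeros((n, n))
    for j in range(n):
        diff = log2q[j] - log2q  # broadcast over genes
        v[j] = diff.std(axis=1, ddof=1)
    return v


def genorm(q: QuantityMatrix) -> tuple[pd.Series, pd.Series]:
    """geNorm M values and exclusion-order stability ranks.

    Returns ``(m, rank)``: the full-panel M per gene, and ranks from the
    iterative procedure (repeatedly drop the highest-M gene until two
    remain; those two tie at rank 1.5).  Ties in M during exclusion are
    broken by gene id (the lexicographically last is dropped) so the
    procedure is deterministic.
    """
    genes = q.genes
    if len(genes) < 2:
        raise ValidationError("geNorm needs at least 2 genes")
    if q.q.shape[1] < 2:
        raise ValidationError("geNorm needs at least 2 samples")
    log2q = q.log2q.values
    full_v = _pairwise_v(log2q)
    with np.errstate(invalid="ignore"):
        m_full = full_v.sum(axis=1) / (len(genes) - 1)
    m = pd.Series(m_full, index=genes, name="genorm_m")

    remaining = list(genes)
    rank = pd.Series(np.nan, index=genes, name="genorm_rank")
    while len(remaining) > 2:
        idx = [genes.index(g) for g in remaining]
        sub = full_v[np.ix_(idx, idx)]
        m_now = sub.sum(axis=1) / (len(remaining) - 1)
        worst_m = m_now.max()
        # drop lexicographically-last among M ties for determinism
        candidates = [remaining[i] for i in range(len(remaining)) if m_now[i] == worst_m]
        worst = sorted(candidates)[-1]
        rank[worst] = float(len(remaining))
        remaining.remove(worst)
    for g in remaining:
        rank[g] = 1.5
    return m, rank


def genorm_pairwise_v(q: QuantityMatrix, ranked_genes: list[str]) -> pd.Series:
    """geNorm V_n/n+1 series for deciding how many references to use.

    NF_n per sample is the geometric mean of Q over the n most stable genes
    (per ``ranked_genes``, best first); V_n is the SD over samples of
    log2(NF_n / NF_{n+1}), for n = 2 .. len(ranked_genes) − 1.
    """
    if len(ranked_genes) < 3:
        raise ValidationError("pairwise V needs at least 3 ranked genes")
    missing = set(ranked_genes) - set(q.genes)
    if missing:
        raise ValidationError(f"ranked genes not in matrix: {sorted(missing)}")
    log2q = q.log2q.loc[ranked_genes].values
    out = {}
    for n in range(2, len(ranked_genes)):
        nf_n = log2q[:n].mean(axis=0)  # log2 of geometric mean
        nf_n1 = log2q[: n + 1].mean(axis=0)
        out[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
    return pd.Series(out, name="genorm_v")


# ---------------------------------------------------------------------------
# NormFinder


def _normfinder_variance_components(
    z: np.ndarray, group_sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bias-corrected variance components for sample-centered log data.

    ``z`` is (genes k × groups G) stacked per group elsewhere; here we get,
    per gene × group, the sample mean ``a`` and sample variance ``s2`` of
    the centered values and return the corrected intra-group variances
    ``sigma2``, inter-group differences ``d`` and the inter-group variance
    ``gamma2``.

    Centering each sample across the k genes makes the residuals
    correlated: Var(z_i) = σ²_i(1 − 2/k) + Σσ²/k².  The corrections below
    invert that relation (requires k ≥ 3) and shrink the inter-group
    differences toward zero by their sampling variance (empirical Bayes),
    as in the original variance-components formulation.  Negative variance
    estimates are clipped to zero.
    """
    a, s2 = z
    k, n_groups = a.shape
    if k < 3:
        raise ValidationError("NormFinder needs at least 3 genes")
    # unbiased intra-group variances: invert the centering-induced mixing
    s_tot = s2.sum(axis=0) * k / (k - 1)  # per group, estimate of Σ_i σ²_ig
    sigma2 = (s2 - s_tot / k**2) * k / (k - 2)
    sigma2 = np.clip(sigma2, 0.0, None)
    # inter-group differences per gene (mean over groups removed)
    d = a - a.mean(axis=1, keepdims=True)
    if n_groups < 2:
        return sigma2, np.zeros_like(d), 0.0
    samp_var = sigma2 / group_sizes[None, :]
    gamma2 = d.var(axis=1, ddof=1).mean() - samp_var.mean()
    gamma2 = max(gamma2, 0.0)
    shrink = np.divide(
        gamma2, gamma2 + samp_var, out=np.zeros_like(samp_var), where=(gamma2 + samp_var) > 0
    )
    return sigma2, d * shrink, gamma2


def normfinder(q: QuantityMatrix) -> pd.Series:
    """NormFinder stability value rho per gene (lower = more stable).

    Works on y = log2 Q.  Each sample is centered by its across-gene mean
    (removing loading/abundance offsets), then per gene × treatment group
    the intra-group variance and the shrunken inter-group difference are
    combined: rho_i = mean over groups of (|d̃_ig| + SD(d_ig)).  With a
    single group the model degenerates to the SD of the gene's centered
    values.
    """
    genes = q.genes
    if len(genes) < 3:
        raise ValidationError("NormFinder needs at least 3 genes")
    y = q.log2q.values
    z = y - y.mean(axis=0, keepdims=True)  # sample centering
    labels = pd.unique(q.groups)
    if len(labels) == 1:
        return pd.Series(z.std(axis=1, ddof=1), index=genes, name="normfinder_rho")
    cols = {lab: np.flatnonzero((q.groups == lab).values) for lab in labels}
    sizes = np.array([len(cols[lab]) for lab in labels])
    if (sizes < 2).any():
        raise ValidationError("NormFinder needs >= 2 samples per group")
    a = np.column_stack([z[:, cols[lab]].mean(axis=1) for lab in labels])
    s2 = np.column_stack([z[:, cols[lab]].var(axis=1, ddof=1) for lab in labels])
    sigma2, d_shrunk, _ = _normfinder_variance_components((a, s2), sizes)
    rho = (np.abs(d_shrunk) + np.sqrt(sigma2 / sizes[None, :])).mean(axis=1)
    return pd.Series(rho, index=genes, name="normfinder_rho")


# ---------------------------------------------------------------------------
# BestKeeper


def bestkeeper(
    table: CqTable, tissue: str, use_mad: bool = False
) -> pd.DataFrame:
    """BestKeeper descriptive stability statistics on raw Cq.

    Returns per gene: ``sd`` (sample SD of Cq — the ranking statistic),
    ``cv`` (100·SD/mean), and ``r`` (Pearson correlation with the
    BestKeeper index, the per-sample geometric mean of all candidates' Cq;
    reported, not ranked on).  ``use_mad=True`` substitutes the original
    tool's mean absolute deviation for the SD.
    """
    cq, _ = table.cq_matrix(tissue)
    vals = cq.values
    if use_mad:
        sd = np.abs(vals - vals.mean(axis=1, keepdims=True)).mean(axis=1)
    else:
        sd = vals.std(axis=1, ddof=1)
    mean = vals.mean(axis=1)
    cv = 100.0 * sd / mean
    index = np.exp(np.log(vals).mean(axis=0))  # geometric mean per sample
    r = np.full(len(cq.index), np.nan)
    if np.std(index) > 0:
        for i in range(vals.shape[0]):
            if np.std(vals[i]) > 0:
                r[i] = stats.pearsonr(vals[i], index)[0]
    return pd.DataFrame(
        {"bestkeeper_sd": sd, "bestkeeper_cv": cv, "bestkeeper_r": r}, index=cq.index
    )


# ---------------------------------------------------------------------------
# comparative ΔCt


def delta_ct(table: CqTable, tissue: str) -> pd.Series:
    """Comparative ΔCt stability: mean over partners of SD(Cq_j − Cq_k)."""
    cq, _ = table.cq_matrix(tissue)
    if len(cq.index) < 2:
        raise ValidationError("comparative dCt needs at least 2 genes")
    v = _pairwise_v(cq.values)
    stat = v.sum(axis=1) / (len(cq.index) - 1)
    return pd.Series(stat, index=cq.index, name="deltact_meansd")


# ---------------------------------------------------------------------------
# comprehensive ranking


def comprehensive_rank(
    ranks: pd.DataFrame, values: pd.DataFrame | None = None
) -> pd.Series:
    """Geometric mean of per-method ranks (RefFinder convention).

    ``ranks`` is genes × methods.  All methods must cover the same genes.
    ``values`` (genes × methods raw stability values) is only used to break
    ties in the final ordering (mean z-score, then gene id); the returned
    series holds the geometric-mean rank itself.
    """
    if ranks.shape[1] < 2:
        raise ValidationError("comprehensive rank needs >= 2 methods")
    if ranks.isna().any().any():
        raise ValidationError("method rank sets do not cover the same genes")
    geo = np.exp(np.log(ranks.values).mean(axis=1))
    return pd.Series(geo, index=ranks.index, name="comprehensive_rank")


def _rank(values: pd.Series) -> pd.Series:
    """Ascending average-tie ranks: lower stability value → better (lower) rank."""
    return pd.Series(
        stats.rankdata(values.values, method="average"), index=values.index
    )


def rank_stability(
    table: CqTable,
    tissue: str,
    methods: tuple[str, ...] = ALL_METHODS,
    default_efficiency: float = 2.0,
    use_mad: bool = False,
) -> StabilityReport:
    """Run the selected stability methods on one tissue and assemble a report.

    Samples of the tissue are pooled across varieties and treatments (the
    ranking is per tissue; treatment is the NormFinder group factor).
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValidationError(f"unknown stability methods: {sorted(unknown)}")
    if len(methods) < 1:
        raise ValidationError("at least one method required")
    sub = table.subset(tissue=tissue)
    qm = to_quantities(sub, tissue, default_efficiency)
    out = pd.DataFrame(index=pd.Index(qm.genes, name="gene"))
    if "genorm" in methods:
        m, rank = genorm(qm)
        out["genorm_m"] = m
        out["genorm_rank"] = rank
    if "normfinder" in methods:
        rho = normfinder(qm)
        out["normfinder_rho"] = rho
        out["normfinder_rank"] = _rank(rho)
    if "bestkeeper" in methods:
        bk = bestkeeper(sub, tissue, use_mad=use_mad)
        out = out.join(bk)
        out["bestkeeper_rank"] = _rank(bk["bestkeeper_sd"])
    if "deltact" in methods:
        dct = delta_ct(sub, tissue)
        out["deltact_meansd"] = dct
        out["deltact_rank"] = _rank(dct)
    rank_cols = [c for c in out.columns if c.endswith("_rank")]
    if len(rank_cols) >= 2:
        out["comprehensive_rank"] = comprehensive_rank(out[rank_cols])
    else:
        out["comprehensive_rank"] = out[rank_cols[0]]
    # deterministic row order: most stable first, ties by gene id
    value_cols = [
        c for c in ("genorm_m", "normfinder_rho", "bestkeeper_sd", "deltact_meansd")
        if c in out.columns
    ]
    z = (out[value_cols] - out[value_cols].mean()) / out[value_cols].std(ddof=1).replace(0, 1)
    out["_tie"] = z.mean(axis=1)
    out = out.loc[
        out.assign(_g=out.index).sort_values(["comprehensive_rank", "_tie", "_g"]).index
    ].drop(columns="_tie")
    return StabilityReport(out, tissue=tissue, methods=tuple(methods))
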