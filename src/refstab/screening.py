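"""Candidate reference-gene screening on multi-dataset FPKM panels.

The cascade applies, per dataset:

(i)   abundance — a gene's mean FPKM must exceed a fraction (default 70%)
      of the dataset's grand-mean FPKM over all genes and samples;
(ii)  ratio window — every condition group's mean FPKM, divided by the
      gene's dataset-wide mean, must lie in [0.75, 1.25];
(iii) ANOVA — one-way ANOVA of the gene's FPKM across the dataset's
      condition groups must be non-significant (p > 0.05): the filter
      retains genes whose expression does NOT respond to the design.

Genes passing all three in at least ``min_dataset_presence`` datasets are
kept, and the final selection requires the kept gene's expression profile
(mean log2(FPKM+1) per dataset × tissue × treatment cell) to correlate
strongly and positively with the other kept genes' profiles (r² above a
threshold with a significant best partner).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionPanel, ScreenReport, ValidationError

__all__ = [
    "ScreenCriteria",
    "abundance_filter",
    "ratio_window_filter",
    "anova_filter",
    "presence_count",
    "correlation_rank",
    "screen_candidates",
]


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds for the screening cascade (defaults are the published ones)."""

    abundance_fraction: float = 0.70
    ratio_low: float = 0.75
    ratio_high: float = 1.25
    anova_alpha: float = 0.05
    min_dataset_presence: int = 2
    corr_r2_threshold: float = 0.95
    corr_alpha: float = 0.01
    #: how a gene's r² values over partners collapse to one score.  "max"
    #: (best positively-correlated partner) is the default: the selection
    #: picks a small mutually-correlated subset out of a larger kept pool,
    #: and any averaging aggregation over partners is dominated by the
    #: pool's uncorrelated majority, which would bury exactly the genes the
    #: step exists to find.
    corr_aggregation: str = "max"

    def __post_init__(self) -> None:
        if not (0 < self.ratio_low < 1 < self.ratio_high):
            raise ValidationError("need 0 < ratio_low < 1 < ratio_high")
        for name in ("abundance_fraction", "anova_alpha", "corr_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.corr_r2_threshold <= 1:
            raise ValidationError("corr_r2_threshold must be in [0, 1]")
        if self.corr_aggregation not in {"median", "mean", "max"}:
            raise ValidationError("corr_aggregation must be median, mean or max")


def _per_dataset_frame(panel: ExpressionPanel) -> pd.DataFrame:
    idx = pd.MultiIndex.from_product(
        [panel.genes, panel.dataset_ids], names=["gene", "dataset_id"]
    )
    return pd.DataFrame(index=idx)


def abundance_filter(panel: ExpressionPanel, criteria: ScreenCriteria) -> pd.Series:
    """Criterion (i): per dataset, gene mean FPKM > fraction × grand mean.

    The grand mean is taken over all genes and samples of the dataset (the
    "whole sample's average FPKM").
    """
    out = {}
    for ds in panel.dataset_ids:
        sub = panel.dataset(ds)
        grand = sub.fpkm.values.mean()
        if grand == 0:
            raise ValidationError(f"dataset {ds!r} has an all-zero FPKM matrix")
        gene_means = sub.fpkm.mean(axis=1)
        passed = gene_means > criteria.abundance_fraction * grand
        for g in sub.genes:
            out[(g, ds)] = bool(passed[g])
    s = pd.Series(out, name="abundance_pass")
    s.index.names = ["gene", "dataset_id"]
    return s


def ratio_window_filter(panel: ExpressionPanel, criteria: ScreenCriteria) -> pd.Series:
    """Criterion (ii): every condition-group mean / gene's dataset mean in window.

    Groups are the distinct (variety, tissue, treatment) combinations within
    the dataset; group means (not individual replicates) are compared so
    replicate noise is not conflated with treatment response.  A gene with
    zero dataset-wide mean fails (not expressed) rather than erroring.
    """
    out = {}
    for ds in panel.dataset_ids:
        sub = panel.dataset(ds)
        groups = sub.condition_groups()
        gene_mean = sub.fpkm.mean(axis=1)
        group_means = sub.fpkm.T.groupby(groups).mean().T  # genes × groups
        for g in sub.genes:
            if gene_mean[g] == 0:
                out[(g, ds)] = False
                continue
            ratios = group_means.loc[g] / gene_mean[g]
            out[(g, ds)] = bool(
                ((ratios >= criteria.ratio_low) & (ratios <= criteria.ratio_high)).all()
            )
    s = pd.Series(out, name="ratio_pass")
    s.index.names = ["gene", "dataset_id"]
    return s


def _anova_pvalue(group_values: list[np.ndarray]) -> float:
    """One-way ANOVA p-value with the degenerate-variance convention:
    zero within-group variance everywhere → p = 1 if all group means agree,
    p = 0 otherwise."""
    within = sum(float(((g - g.mean()) ** 2).sum()) for g in group_values)
    means = [float(g.mean()) for g in group_values]
    if within == 0.0:
        return 1.0 if max(means) == min(means) else 0.0
    return float(stats.f_oneway(*group_values).pvalue)


def anova_filter(
    panel: ExpressionPanel, criteria: ScreenCriteria
) -> tuple[pd.Series, pd.Series]:
    """Criterion (iii): one-way ANOVA across condition groups; pass iff p > α.

    Datasets with a single condition group, or without ≥2 replicates in at
    least two groups, are excluded (p = NaN, pass = False): they cannot
    demonstrate within-dataset stability.
    """
    pvals, passes = {}, {}
    for ds in panel.dataset_ids:
        sub = panel.dataset(ds)
        groups = sub.condition_groups()
        labels = pd.unique(groups)
        ok = len(labels) >= 2 and sum((groups == lab).sum() >= 2 for lab in labels) >= 2
        for g in sub.genes:
            if not ok:
                pvals[(g, ds)] = np.nan
                passes[(g, ds)] = False
                continue
            vals = [sub.fpkm.loc[g, groups.index[groups == lab]].values for lab in labels]
            p = _anova_pvalue(vals)
            pvals[(g, ds)] = p
            passes[(g, ds)] = bool(p > criteria.anova_alpha)
    p = pd.Series(pvals, name="anova_p")
    b = pd.Series(passes, name="anova_pass")
    p.index.names = b.index.names = ["gene", "dataset_id"]
    return p, b


def presence_count(
    per_dataset: pd.DataFrame, criteria: ScreenCriteria
) -> tuple[pd.Series, pd.Series]:
    """Datasets in which a gene passes all of (i)–(iii); keep iff ≥ minimum."""
    all_pass = (
        per_dataset["abundance_pass"]
        & per_dataset["ratio_pass"]
        & per_dataset["anova_pass"]
    )
    count = all_pass.groupby(level="gene").sum().astype(int)
    kept = count >= criteria.min_dataset_presence
    return count.rename("presence_count"), kept.rename("kept")


def _profiles(panel: ExpressionPanel, genes: list[str]) -> pd.DataFrame:
    """Mean log2(FPKM+1) per (dataset, tissue, treatment) cell, genes × cells."""
    cells = (
        panel.meta["dataset_id"].astype(str)
        + "|"
        + panel.meta["tissue"].astype(str)
        + "|"
        + panel.meta["treatment"].astype(str)
    )
    logx = np.log2(panel.fpkm.loc[genes] + 1.0)
    return logx.T.groupby(cells).mean().T


def correlation_rank(
    panel: ExpressionPanel, kept_genes: list[str], criteria: ScreenCriteria
) -> pd.DataFrame:
    """Pearson-correlation selection among the kept genes.

    Each gene's profile is its mean log2(FPKM+1) per condition cell.  For
    every gene pair Pearson r is computed; a partner contributes r² if
    r > 0 and 0 otherwise, and the contributions collapse to one score per
    gene (median by default).  Selection requires score ≥ the r² threshold
    and best-partner correlation p-value < α.  Zero-variance profiles get
    score 0 with a reason flag instead of an exception.
    """
    if len(kept_genes) < 3:
        raise ValidationError("correlation ranking needs >= 3 kept genes")
    prof = _profiles(panel, kept_genes)
    if prof.shape[1] < 3:
        raise ValidationError("correlation ranking needs >= 3 condition cells")
    agg = {"median": np.median, "mean": np.mean, "max": np.max}[criteria.corr_aggregation]
    var = prof.var(axis=1)
    rows = []
    for g in kept_genes:
        if var[g] == 0:
            rows.append((g, 0.0, "", np.nan, False, "zero profile variance"))
            continue
        contribs, best_r, best_partner = [], -np.inf, ""
        for h in kept_genes:
            if h == g or var[h] == 0:
                continue
            r = float(stats.pearsonr(prof.loc[g], prof.loc[h])[0])
            contribs.append(r * r if r > 0 else 0.0)
            if r > best_r:
                best_r, best_partner = r, h
        if not contribs:
            rows.append((g, 0.0, "", np.nan, False, "no valid partner"))
            continue
        score = float(agg(contribs))
        best_p = float(stats.pearsonr(prof.loc[g], prof.loc[best_partner])[1])
        selected = score >= criteria.corr_r2_threshold and best_p < criteria.corr_alpha
        rows.append((g, score, best_partner, best_p, bool(selected), ""))
    return pd.DataFrame(
        rows,
        columns=["gene", "correlation_score", "best_partner", "best_partner_p", "selected", "reason"],
    ).set_index("gene")


def screen_candidates(
    panel: ExpressionPanel, criteria: ScreenCriteria | None = None
) -> ScreenReport:
    """Run the full cascade and assemble a :class:`ScreenReport`.

    Composes abundance → ratio window → ANOVA → presence count →
    correlation ranking, recording every intermediate decision.  With an
    empty panel returns an empty report.
    """
    criteria = criteria or ScreenCriteria()
    config = asdict(criteria)
    if len(panel.genes) == 0:
        per_ds = pd.DataFrame(
            columns=["gene", "dataset_id", "abundance_pass", "ratio_pass", "anova_p", "anova_pass"]
        )
        per_gene = pd.DataFrame(
            columns=["presence_count", "kept", "correlation_score", "best_partner",
                     "best_partner_p", "selected", "reason"]
        )
        per_gene.index.name = "gene"
        return ScreenReport(per_ds, per_gene, config)

    ab = abundance_filter(panel, criteria)
    ra = ratio_window_filter(panel, criteria)
    p, ap = anova_filter(panel, criteria)
    per_ds = pd.concat([ab, ra, p, ap], axis=1)
    count, kept = presence_count(per_ds, criteria)
    per_gene = pd.concat([count, kept], axis=1).reindex(panel.genes)

    kept_genes = [g for g in panel.genes if kept.get(g, False)]
    if len(kept_genes) >= 3:
        corr = correlation_rank(panel, kept_genes, criteria)
        per_gene = per_gene.join(corr)
    else:
        per_gene["correlation_score"] = np.nan
        per_gene["best_partner"] = ""
        per_gene["best_partner_p"] = np.nan
        per_gene["selected"] = False
        per_gene["reason"] = "fewer than 3 kept genes"
    per_gene["selected"] = per_gene["selected"].map(lambda v: bool(v) if v == v else False)
    per_gene.index.name = "gene"
    return ScreenReport(per_ds.reset_index(), per_gene, config)
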