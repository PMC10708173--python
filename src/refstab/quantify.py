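"""Standard-curve efficiency estimation and relative expression.

A serial dilution gives the line Cq = intercept + slope · log10(dilution);
the per-cycle amplification efficiency is E = 10^(−1/slope), reported as a
percentage (100% ⇔ E = 2, slope ≈ −3.3219).

Relative expression of a target gene in a sample, normalized by one or
several reference genes and expressed against the tissue's mock (CK)
calibrator, is the efficiency-corrected ratio

    FC = E_t^(Cq_t,cal − Cq_t,s) / ∏_r [ E_r^(Cq_r,cal − Cq_r,s) ]^(1/|refs|)

which reduces to the familiar 2^(−ΔΔCq) when every E = 2.  Per-sample
loading offsets cancel in the ratio; the calibrator is the arithmetic mean
Cq of the tissue's CK biological replicates, which makes the CK geometric
mean fold change exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CqTable, ValidationError

__all__ = [
    "EfficiencyFit",
    "fit_standard_curve",
    "fit_standard_curves",
    "normalization_factor",
    "relative_expression",
    "summarize_fold_changes",
    "compare_normalizations",
]


@dataclass(frozen=True)
class EfficiencyFit:
    """Least-squares Cq-vs-log10(dilution) fit for one primer pair."""

    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float

    @property
    def efficiency(self) -> float:
        """Per-cycle fold amplification E (2.0 = 100%)."""
        return 1.0 + self.efficiency_pct / 100.0


def fit_standard_curve(series: pd.DataFrame) -> EfficiencyFit:
    """Fit one dilution series (columns log10_dilution, cq).

    Requires ≥3 points spanning ≥2 log10 units; the slope must be negative
    (higher dilution → later Cq), otherwise the dilution axis is inverted.
    efficiency_pct = 100·(10^(−1/slope) − 1).
    """
    x = np.asarray(series["log10_dilution"], dtype=float)
    y = np.asarray(series["cq"], dtype=float)
    if len(x) < 3:
        raise ValidationError("standard curve needs >= 3 dilution points")
    if x.max() - x.min() < 2.0:
        raise ValidationError("dilution series must span >= 2 log10 units")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValidationError("positive slope: inverted dilution axis?")
    eff_pct = 100.0 * (10.0 ** (-1.0 / fit.slope) - 1.0)
    return EfficiencyFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency_pct=float(eff_pct),
    )


def fit_standard_curves(dilution_table: pd.DataFrame) -> dict[str, EfficiencyFit]:
    """Fit every gene in a dilution table (columns gene, log10_dilution, cq)."""
    return {
        str(g): fit_standard_curve(sub)
        for g, sub in dilution_table.groupby("gene", sort=False)
    }


def _mean_cq(table: CqTable, tissue: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    cq, meta = table.cq_matrix(tissue)
    return cq, meta


def normalization_factor(
    table: CqTable,
    refs: list[str],
    sample_id: str,
    default_efficiency: float = 2.0,
) -> float:
    """Per-sample normalization factor: geometric mean over refs of E^(−Cq).

    Defined up to a per-gene constant that cancels in calibrated ratios; a
    singleton reference set reduces to the classic single-reference scheme.
    """
    if not refs:
        raise ValidationError("reference gene set must be non-empty")
    df = table.records
    logs = []
    for r in refs:
        rows = df[(df["gene"] == r) & (df["sample_id"] == sample_id)]
        if rows.empty:
            raise ValidationError(f"missing Cq for reference {r!r} in sample {sample_id!r}")
        e = table.efficiency(r, default_efficiency)
        logs.append(-float(rows["cq"].mean()) * np.log(e))
    return float(np.exp(np.mean(logs)))


def relative_expression(
    table: CqTable,
    target: str,
    refs: list[str],
    tissue: str,
    control_treatment: str = "CK",
    efficiency_correction: bool = False,
    default_efficiency: float = 2.0,
    scheme: str | None = None,
) -> pd.DataFrame:
    """Per-replicate fold changes of ``target`` vs the tissue's CK calibrator.

    Returns one row per sample of the tissue with columns
    ``target, tissue, variety, treatment, bio_rep, scheme, fold_change``.
    With ``efficiency_correction=False`` (the default) all E = 2, i.e.
    plain 2^(−ΔΔCq); with True, per-gene efficiencies from the table are
    used where available.
    """
    if not refs:
        raise ValidationError("reference gene set must be non-empty")
    genes = [target] + list(refs)
    sub = table.subset(tissue=tissue, genes=genes)
    missing = set(genes) - set(sub.genes)
    if missing:
        raise ValidationError(f"genes not measured in tissue {tissue!r}: {sorted(missing)}")
    cq, meta = sub.cq_matrix(tissue)
    ck = meta.index[meta["treatment"] == control_treatment]
    if len(ck) == 0:
        raise ValidationError(f"no {control_treatment!r} samples in tissue {tissue!r}")
    calibrator = cq[ck].mean(axis=1)  # per-gene mean Cq of CK replicates

    def eff(g: str) -> float:
        return sub.efficiency(g, default_efficiency) if efficiency_correction else default_efficiency

    log2 = {g: np.log2(eff(g)) * (calibrator[g] - cq.loc[g]) for g in genes}
    # duplicate refs collapse to the singleton result: average the distinct set
    distinct = list(dict.fromkeys(refs))
    ref_term = sum(log2[r] for r in distinct) / len(distinct)
    log2_fc = log2[target] - ref_term
    out = meta.copy()
    out["target"] = target
    out["scheme"] = scheme if scheme is not None else "+".join(distinct)
    out["fold_change"] = np.exp2(log2_fc.loc[out.index])
    out = out.reset_index()
    return out[
        ["target", "tissue", "variety", "treatment", "bio_rep", "scheme", "sample_id", "fold_change"]
    ]


def summarize_fold_changes(fc: pd.DataFrame) -> pd.DataFrame:
    """Per-condition geometric mean and log2-scale SD of fold changes.

    Statistics are computed on log2 fold changes (symmetric errors) and the
    mean is reported back on the linear scale; ``sd_log2`` stays on log2.
    """
    lg = np.log2(fc["fold_change"])
    grouped = fc.assign(_l=lg).groupby(
        ["target", "tissue", "treatment", "scheme"], sort=False
    )["_l"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    out["fold_change_mean"] = np.exp2(out["mean"])
    out = out.rename(columns={"std": "sd_log2", "count": "n"})
    return out[
        ["target", "tissue", "treatment", "scheme", "fold_change_mean", "sd_log2", "n"]
    ]


def compare_normalizations(
    table: CqTable,
    target: str,
    schemes: list[list[str]],
    tissue: str,
    control_treatment: str = "CK",
    efficiency_correction: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-change profiles of ``target`` under several reference schemes.

    The first scheme is the baseline.  Returns ``(fold_changes, divergence)``
    where divergence holds, per scheme, the maximum over conditions of
    |log2 FC_scheme − log2 FC_baseline| on the per-condition mean profiles
    (so the baseline scheme's divergence is 0 and a with-a-bad-reference
    scheme's divergence measures how far normalization distorts the
    response pattern).  A single scheme yields an empty divergence table.
    """
    if len(schemes) < 1:
        raise ValidationError("need at least one normalization scheme")
    tables = []
    for refs in schemes:
        tables.append(
            relative_expression(
                table, target, refs, tissue,
                control_treatment=control_treatment,
                efficiency_correction=efficiency_correction,
            )
        )
    fc = pd.concat(tables, ignore_index=True)
    summary = summarize_fold_changes(fc)
    if len(schemes) < 2:
        return fc, pd.DataFrame(columns=["scheme", "max_abs_log2_divergence"])
    base_name = summary["scheme"].iloc[0]
    base = summary[summary["scheme"] == base_name].set_index("treatment")[
        "fold_change_mean"
    ]
    rows = []
    for name, sub in summary.groupby("scheme", sort=False):
        prof = sub.set_index("treatment")["fold_change_mean"]
        div = float(np.max(np.abs(np.log2(prof / base.loc[prof.index]))))
        rows.append((name, div))
    return fc, pd.DataFrame(rows, columns=["scheme", "max_abs_log2_divergence"])
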