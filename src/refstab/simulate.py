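"""Synthetic FPKM panels and Cq experiments with planted ground truth.

The generators emulate the experimental design the pipeline is built for:
six RNA-seq
datasets spanning varieties, tissues and treatments with replicated FPKM
observations, and a 2-variety × 3-tissue × 3-treatment RT-qPCR experiment
(mock / 30 mM NaCl salt / air-dry drought) with three biological and three
technical replicates.  Every gene's true stability status is known, so the
screening cascade, the stability algorithms and the quantification stage
can all be tested for ground-truth recovery without any external data.

Structure of the FPKM simulation (all on the log2 scale, FPKM = 2^x):

* candidate genes (stable + unstable) share a per-dataset expression
  profile — the across-condition co-movement that makes genuinely stable
  genes mutually correlated, which the Pearson-correlation selection stage
  requires;
* background genes instead get independent per-(gene, dataset) deviations
  — dataset/tissue-specific regulation — so they decorrelate, and a
  low-expression stratum gives the abundance filter something to remove;
* unstable genes additionally get condition-group shifts (zero in the
  control group, random sign elsewhere) of the stated effect size.

The Cq simulation adds a shared per-sample "loading" offset to every gene
of a sample (RNA input / reverse-transcription variation).  This is the
structure that ratio-based methods (geNorm, ΔCt) and sample centering
(NormFinder) cancel and BestKeeper does not — omitting it would make the
four methods indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import CQ_COLUMNS, CqTable, ExpressionPanel, ValidationError

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "simulate_fpkm_panel",
    "simulate_cq_experiment",
    "simulate_dilution_series",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of the simulated study.

    Defaults mirror the target experiment: 6 RNA-seq datasets, 2 varieties,
    leaf/shoot/root, mock (CK) / salt / drought, 3 biological × 3 technical
    replicates.  ``treatment_effect`` is in log2-fold units for FPKM and in
    cycles for Cq; the first treatment in ``treatments`` is the control and
    never receives a planted shift.
    """

    n_datasets: int = 6
    varieties: tuple[str, ...] = ("NPB", "9522")
    tissues: tuple[str, ...] = ("leaf", "shoot", "root")
    treatments: tuple[str, ...] = ("CK", "salt", "drought")
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    n_stable_genes: int = 3
    n_unstable_genes: int = 9
    n_background_genes: int = 40
    stable_noise_sd: float = 0.15
    treatment_effect: float = 1.0
    #: Cq simulation: probability an unstable gene responds to a given
    #: stress treatment in a given tissue (at least one response is
    #: guaranteed, so every unstable gene is genuinely unstable)
    treatment_response_prob: float = 0.7
    #: Cq simulation: shared per-sample loading offset SD (cycles)
    sample_effect_sd: float = 0.3
    #: Cq simulation: technical-replicate noise SD (cycles)
    tech_noise_sd: float = 0.1
    #: Cq simulation: window the per-gene base Cq is drawn from (cycles);
    #: inside the observed assay span so simulated Cq stays well below the
    #: 44-cycle ceiling.
    cq_base_window: tuple[float, float] = (24.0, 34.0)
    #: FPKM simulation: SD of the shared per-dataset profile all candidate
    #: genes follow (log2 units)
    shared_profile_sd: float = 1.0
    #: FPKM simulation: candidate-gene expression level range (log2 FPKM)
    candidate_level_range: tuple[float, float] = (6.5, 8.0)
    #: FPKM simulation: background-gene expression level range (log2 FPKM);
    #: spans a low-expression stratum the abundance filter removes
    background_level_range: tuple[float, float] = (-1.0, 3.5)
    #: FPKM simulation: per-(gene, dataset) deviation SD of background genes
    background_dataset_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stable_genes + self.n_unstable_genes < 3:
            raise ValidationError("need >= 3 candidate genes for meaningful ranking")
        if self.stable_noise_sd < 0:
            raise ValidationError("stable_noise_sd must be >= 0")
        if self.treatment_effect < 0:
            raise ValidationError("treatment_effect must be >= 0")
        if len(self.treatments) < 2 or self.n_bio_reps < 2:
            raise ValidationError(
                "degenerate design: need >= 2 condition groups and >= 2 replicates"
            )

    def with_(self, **kw) -> "SimulationDesign":
        return replace(self, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """Which simulated genes are truly stable, and each gene's effect size."""

    stable_gene_ids: frozenset[str]
    unstable_gene_ids: frozenset[str]
    effect_sizes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stable_gene_ids & self.unstable_gene_ids:
            raise ValidationError("stable and unstable gene sets overlap")


def _gene_names(design: SimulationDesign, background: bool) -> tuple[list[str], list[str], list[str]]:
    stable = [f"STB{i + 1:02d}" for i in range(design.n_stable_genes)]
    unstable = [f"UNS{i + 1:02d}" for i in range(design.n_unstable_genes)]
    bg = [f"BG{i + 1:03d}" for i in range(design.n_background_genes)] if background else []
    return stable, unstable, bg


def simulate_fpkm_panel(design: SimulationDesign) -> tuple[ExpressionPanel, GroundTruth]:
    """Simulate a multi-dataset FPKM panel with planted stable genes.

    Each dataset covers one tissue (cycled through ``design.tissues``), all
    varieties × treatments, with ``n_bio_reps`` replicates per condition
    group.  Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    stable, unstable, bg = _gene_names(design, background=True)
    genes = stable + unstable + bg
    candidates = stable + unstable

    cand_level = rng.uniform(*design.candidate_level_range, size=len(candidates))
    bg_level = rng.uniform(*design.background_level_range, size=len(bg))
    effects: dict[str, float] = {g: 0.0 for g in genes}

    # The shared across-candidate profile is anchored to organ identity:
    # expression context differs systematically between organ types (the
    # dominant axis in plant expression atlases), with smaller per-dataset
    # jitter on top.  Anchoring guarantees the across-dataset spread that
    # genuinely co-expressed genes exhibit; resampling it from scratch per
    # dataset would occasionally produce six near-identical contexts, which
    # no multi-organ compendium shows.
    organ_offset = {
        t: o
        for t, o in zip(
            design.tissues,
            np.linspace(-1.0, 1.0, len(design.tissues)) * design.shared_profile_sd,
        )
    }
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for d in range(design.n_datasets):
        ds = f"DS{d + 1}"
        tissue = design.tissues[d % len(design.tissues)]
        shared = organ_offset[tissue] + rng.normal(0.0, 0.3 * design.shared_profile_sd)
        bg_dev = rng.normal(0.0, design.background_dataset_sd, size=len(bg))
        base = np.concatenate([cand_level + shared, bg_level + bg_dev])
        # planted condition-group shifts for unstable genes: zero in the
        # control treatment, random sign and magnitude up to the stated
        # effect elsewhere (never below half of it, so "unstable" is real)
        shift = {}
        for vi, variety in enumerate(design.varieties):
            for treatment in design.treatments:
                g_shift = np.zeros(len(genes))
                if treatment != design.treatments[0]:
                    mags = rng.uniform(
                        0.5 * design.treatment_effect,
                        design.treatment_effect,
                        size=len(unstable),
                    )
                    signs = rng.choice([-1.0, 1.0], size=len(unstable))
                    g_shift[len(stable):len(stable) + len(unstable)] = mags * signs
                    for g, s in zip(unstable, mags * signs):
                        effects[g] = max(effects[g], abs(float(s)))
                shift[(variety, treatment)] = g_shift
        for variety in design.varieties:
            for treatment in design.treatments:
                for rep in range(1, design.n_bio_reps + 1):
                    sid = f"{ds}.{variety}.{treatment}.r{rep}"
                    noise = rng.normal(0.0, design.stable_noise_sd, size=len(genes))
                    log2x = base + shift[(variety, treatment)] + noise
                    columns[sid] = np.exp2(log2x)
                    meta_rows.append(
                        dict(sample_id=sid, dataset_id=ds, variety=variety,
                             tissue=tissue, treatment=treatment, bio_rep=rep)
                    )
    fpkm = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    panel = ExpressionPanel(fpkm, meta)
    truth = GroundTruth(frozenset(stable), frozenset(unstable), effects)
    return panel, truth


def simulate_cq_experiment(design: SimulationDesign) -> tuple[CqTable, GroundTruth]:
    """Simulate a replicated RT-qPCR Cq experiment with planted ground truth.

    Per gene a base Cq is drawn uniformly in ``cq_base_window``.  Stable
    genes observe base + per-sample loading offset + biological noise;
    unstable genes additionally get treatment × tissue shifts of the stated
    magnitude (zero in the control treatment, sign random per gene × tissue
    × treatment).  Technical replicates add Normal(0, tech_noise_sd)
    cycles.  Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    stable, unstable, _ = _gene_names(design, background=False)
    genes = stable + unstable
    base = rng.uniform(*design.cq_base_window, size=len(genes))
    effects: dict[str, float] = {g: 0.0 for g in genes}

    # Planted instability per gene × tissue.  An unstable candidate is a
    # FAILED reference gene: its expression wanders erratically across
    # condition groups, unlike a coherent stress-response gene.  Each
    # (variety, stress-treatment) group therefore perturbs the gene
    # independently — with probability ``treatment_response_prob`` it shifts
    # by a random sign times [1, 1.5] × the stated effect, and at least one
    # group per tissue is guaranteed to shift so every unstable gene is
    # genuinely unstable.  Independent per-group perturbations also avoid
    # planting accidentally co-regulated gene subsets, which would defeat
    # ratio-based ranking by construction rather than by biology.
    stress = [t for t in design.treatments if t != design.treatments[0]]
    shift: dict[tuple[str, str, str, str], float] = {}
    for g in unstable:
        for tissue in design.tissues:
            groups = [(v, t) for v in design.varieties for t in stress]
            perturbed = rng.random(len(groups)) < design.treatment_response_prob
            if not perturbed.any():
                perturbed[int(rng.integers(len(groups)))] = True
            for variety in design.varieties:
                shift[(g, variety, tissue, design.treatments[0])] = 0.0
            for (variety, treatment), hit in zip(groups, perturbed):
                if not hit:
                    shift[(g, variety, tissue, treatment)] = 0.0
                    continue
                s = float(
                    rng.choice([-1.0, 1.0])
                    * design.treatment_effect
                    * rng.uniform(1.0, 1.5)
                )
                shift[(g, variety, tissue, treatment)] = s
                effects[g] = max(effects[g], abs(s))

    rows = []
    for tissue in design.tissues:
        for variety in design.varieties:
            for treatment in design.treatments:
                for rep in range(1, design.n_bio_reps + 1):
                    sid = f"{variety}.{tissue}.{treatment}.r{rep}"
                    loading = rng.normal(0.0, design.sample_effect_sd)
                    for gi, g in enumerate(genes):
                        bio = rng.normal(0.0, design.stable_noise_sd)
                        cq0 = (
                            base[gi]
                            + loading
                            + bio
                            + shift.get((g, variety, tissue, treatment), 0.0)
                        )
                        for tr in range(1, design.n_tech_reps + 1):
                            cq = cq0 + (
                                rng.normal(0.0, design.tech_noise_sd)
                                if design.tech_noise_sd > 0
                                else 0.0
                            )
                            rows.append(
                                (g, sid, variety, tissue, treatment, rep, tr, cq)
                            )
    records = pd.DataFrame(rows, columns=CQ_COLUMNS)
    truth = GroundTruth(frozenset(stable), frozenset(unstable), effects)
    return CqTable(records), truth


def simulate_dilution_series(
    efficiency: float,
    n_points: int = 5,
    step_log10: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 20.0,
    gene: str = "gene",
) -> pd.DataFrame:
    """Serial-dilution Cq series: Cq(d) = intercept − log10(d)/log10(E) + noise.

    Dilutions run 1, 10^−step, 10^−2·step, …; with E = 2 successive 10-fold
    dilutions differ by 1/log10(2) ≈ 3.32 cycles.  Deterministic given seed.
    """
    if not 1.0 < efficiency < 3.0:
        raise ValidationError(f"efficiency must be in (1, 3), got {efficiency}")
    if n_points < 3:
        raise ValidationError("need >= 3 dilution points")
    rng = np.random.default_rng(seed)
    log10_d = -step_log10 * np.arange(n_points)
    cq = intercept - log10_d / np.log10(efficiency)
    if noise_sd > 0:
        cq = cq + rng.normal(0.0, noise_sd, size=n_points)
    return pd.DataFrame({"gene": gene, "log10_dilution": log10_d, "cq": cq})
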