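"""End-to-end orchestration: simulate → screen → rank stability → quantify.

A :class:`RunConfig` (round-trippable through YAML) drives the four stages;
every source of randomness flows from its single root seed, outputs carry
the seed in their manifest, and reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import quantify, screening, simulate, stability
from .data import (
    CqTable,
    ExpressionPanel,
    ValidationError,
    aggregate_tech_reps,
    write_fold_change_table,
    write_screen_report,
    write_stability_report,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "refstab_run"
    seed: int = 0
    design: dict = field(default_factory=dict)
    criteria: dict = field(default_factory=dict)
    methods: tuple[str, ...] = stability.ALL_METHODS
    #: per-tissue normalization schemes for the validation stage are derived
    #: from the stability ranking: each of the top_n singletons, the top_n
    #: combined, and each of the bottom_m singletons as negative controls
    top_n: int = 3
    bottom_m: int = 2
    target_gene: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(stability.ALL_METHODS)
        if unknown:
            raise ValidationError(f"unknown stability methods: {sorted(unknown)}")
        self.methods = tuple(self.methods)
        # normalize sequence values so a config round-trips YAML losslessly
        self.design = {
            k: list(v) if isinstance(v, (tuple, list)) else v for k, v in self.design.items()
        }

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_yaml(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest.

    Stages: (1) simulate an FPKM panel and a Cq experiment with planted
    ground truth; (2) screen the panel for candidate reference genes;
    (3) rank stability per tissue on the Cq data; (4) quantify a target
    gene under top-ranked, combined and bottom-ranked normalization
    schemes.  Any stage failure aborts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}

    def record(stage: str, rows: int, *paths: Path) -> None:
        manifest["stages"].append({"stage": stage, "rows": rows})
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)

    # stage 1: simulate
    try:
        design = simulate.SimulationDesign(seed=config.seed, **config.design)
        panel, fpkm_truth = simulate.simulate_fpkm_panel(design)
        cq_table, cq_truth = simulate.simulate_cq_experiment(design)
        expr_path = out / "expression.tsv"
        panel.fpkm.to_csv(expr_path, sep="\t", lineterminator="\n")
        meta_path = out / "samples.csv"
        panel.meta.to_csv(meta_path, lineterminator="\n")
        cq_path = out / "cq.csv"
        cq_table.records.to_csv(cq_path, index=False, lineterminator="\n")
        truth_path = out / "ground_truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "fpkm": {
                        "stable": sorted(fpkm_truth.stable_gene_ids),
                        "unstable": sorted(fpkm_truth.unstable_gene_ids),
                    },
                    "cq": {
                        "stable": sorted(cq_truth.stable_gene_ids),
                        "unstable": sorted(cq_truth.unstable_gene_ids),
                        "effect_sizes": cq_truth.effect_sizes,
                    },
                },
                indent=2,
                sort_keys=True,
            ),
            encoding="utf-8",
        )
        record("simulate", len(cq_table.records), expr_path, meta_path, cq_path, truth_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # stage 2: screen
    try:
        criteria = screening.ScreenCriteria(**config.criteria)
        report = screening.screen_candidates(panel, criteria)
        screen_path = out / "screen.tsv"
        write_screen_report(report, screen_path)
        record("screen", len(report.per_gene), screen_path,
               screen_path.with_suffix(".per_dataset.tsv"))
    except Exception as exc:
        raise RuntimeError(f"stage 'screen' failed: {exc}") from exc

    # stage 3: stability per tissue
    try:
        agg = aggregate_tech_reps(cq_table)
        rankings: dict[str, list[str]] = {}
        stab_paths = []
        for tissue in agg.tissues:
            rep = stability.rank_stability(agg, tissue, methods=config.methods)
            path = out / f"stability_{tissue}.tsv"
            write_stability_report(rep, path)
            rankings[tissue] = rep.ordering()
            stab_paths.append(path)
        record("stability", sum(len(r) for r in rankings.values()), *stab_paths)
    except Exception as exc:
        raise RuntimeError(f"stage 'stability' failed: {exc}") from exc

    # stage 4: quantify a target under competing schemes
    try:
        fc_paths = []
        n_rows = 0
        for tissue, ranked in rankings.items():
            target = config.target_gene or ranked[-1]  # least stable = a responsive target
            refs_pool = [g for g in ranked if g != target]
            top = refs_pool[: config.top_n]
            bottom = refs_pool[-config.bottom_m:] if config.bottom_m else []
            schemes = [[g] for g in top] + [top] + [[g] for g in bottom]
            fc, div = quantify.compare_normalizations(agg, target, schemes, tissue)
            path = out / f"fold_change_{tissue}.tsv"
            write_fold_change_table(fc, path)
            div_path = out / f"divergence_{tissue}.tsv"
            div.to_csv(div_path, sep="\t", index=False, lineterminator="\n")
            fc_paths += [path, div_path]
            n_rows += len(fc)
        record("quantify", n_rows, *fc_paths)
    except Exception as exc:
        raise RuntimeError(f"stage 'quantify' failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest
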