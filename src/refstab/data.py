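"""Shared data containers and tabular I/O.

Two substrates flow through the pipeline:

* :class:`ExpressionPanel` — a genes × samples FPKM matrix with per-sample
  metadata, grouped into datasets.  This is what the RNA-seq screening
  cascade consumes.
* :class:`CqTable` — long-format RT-qPCR quantification-cycle (Cq) records
  carrying the experimental design factors (variety, tissue, treatment,
  biological and technical replicate).  This is what the stability
  algorithms and relative quantification consume.

All readers validate and reject malformed input rather than silently
coercing it; all report writers produce deterministic, round-trippable
plain-text tables.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SampleMeta",
    "ExpressionPanel",
    "CqTable",
    "StabilityReport",
    "ScreenReport",
    "DEFAULT_CQ_CEILING",
    "read_expression_panel",
    "read_cq_table",
    "read_dilution_series",
    "aggregate_tech_reps",
    "write_stability_report",
    "read_stability_report",
    "write_screen_report",
    "write_fold_change_table",
]

#: Cq values can never exceed the number of thermal cycles run; the assay
#: protocol runs 44 cycles, so a Cq at or above this is "not detected".
DEFAULT_CQ_CEILING = 44.0

META_COLUMNS = ["sample_id", "dataset_id", "variety", "tissue", "treatment", "bio_rep"]
CQ_COLUMNS = ["gene", "sample_id", "variety", "tissue", "treatment", "bio_rep", "tech_rep", "cq"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Design factors identifying one biological sample."""

    sample_id: str
    dataset_id: str
    variety: str
    tissue: str
    treatment: str
    bio_rep: int

    def __post_init__(self) -> None:
        if int(self.bio_rep) < 1:
            raise ValidationError(f"bio_rep must be >= 1, got {self.bio_rep}")


@dataclass
class ExpressionPanel:
    """A genes × samples FPKM matrix plus sample metadata.

    Parameters
    ----------
    fpkm
        DataFrame indexed by gene identifier with one column per sample_id.
        Values are FPKM (non-negative).
    meta
        DataFrame indexed by sample_id with columns
        ``dataset_id, variety, tissue, treatment, bio_rep``.
    """

    fpkm: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.fpkm = self.fpkm.astype(float)
        if self.fpkm.index.duplicated().any():
            dups = self.fpkm.index[self.fpkm.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if list(self.fpkm.columns) != list(self.meta.index):
            missing = set(self.fpkm.columns) ^ set(self.meta.index)
            if missing:
                raise ValidationError(
                    f"sample columns and metadata rows disagree on: {sorted(missing)}"
                )
            # same set, different order: align metadata to matrix order
            self.meta = self.meta.loc[self.fpkm.columns]
        neg = self.fpkm.lt(0)
        if neg.any().any():
            g = self.fpkm.index[neg.any(axis=1)][0]
            s = self.fpkm.columns[neg.loc[g]][0]
            raise ValidationError(f"negative FPKM for gene {g!r} in sample {s!r}")
        for col in ("dataset_id", "variety", "tissue", "treatment", "bio_rep"):
            if col not in self.meta.columns:
                raise ValidationError(f"metadata missing column {col!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    @property
    def dataset_ids(self) -> list[str]:
        return list(pd.unique(self.meta["dataset_id"]))

    def dataset(self, dataset_id: str) -> "ExpressionPanel":
        """Sub-panel restricted to one dataset."""
        keep = self.meta.index[self.meta["dataset_id"] == dataset_id]
        if len(keep) == 0:
            raise KeyError(dataset_id)
        return ExpressionPanel(self.fpkm[keep], self.meta.loc[keep])

    def condition_groups(self) -> pd.Series:
        """Label each sample with its (variety, tissue, treatment) group."""
        m = self.meta
        return (
            m["variety"].astype(str)
            + "/"
            + m["tissue"].astype(str)
            + "/"
            + m["treatment"].astype(str)
        )

    def equals(self, other: "ExpressionPanel") -> bool:
        return self.fpkm.equals(other.fpkm) and self.meta.equals(
            other.meta[self.meta.columns]
        )


@dataclass
class CqTable:
    """Long-format Cq records with optional per-gene amplification efficiencies.

    ``records`` holds one row per (gene, sample, technical replicate) with
    columns :data:`CQ_COLUMNS`.  ``efficiencies`` maps gene → per-cycle fold
    amplification E (2.0 = 100% efficiency); genes without an entry default
    to E = 2 downstream.
    """

    records: pd.DataFrame
    efficiencies: dict[str, float] | None = None
    cq_ceiling: float = DEFAULT_CQ_CEILING

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in CQ_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"Cq table missing column {col!r}")
        df["cq"] = pd.to_numeric(df["cq"], errors="raise")
        if (df["cq"] <= 0).any():
            row = df.index[df["cq"] <= 0][0]
            raise ValidationError(f"non-positive Cq at row {row}")
        if (df["cq"] > self.cq_ceiling).any():
            row = df.index[df["cq"] > self.cq_ceiling][0]
            raise ValidationError(
                f"Cq above ceiling {self.cq_ceiling} at row {row} "
                "(at-ceiling reactions are not-detected and cannot support a reference gene)"
            )
        if (df["bio_rep"].astype(int) < 1).any() or (df["tech_rep"].astype(int) < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        self.records = df.reset_index(drop=True)
        if self.efficiencies is not None:
            for g, e in self.efficiencies.items():
                if not 1.0 < float(e) < 3.0:
                    raise ValidationError(f"efficiency for {g!r} out of range (1, 3): {e}")

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.records["gene"]))

    @property
    def tissues(self) -> list[str]:
        return list(pd.unique(self.records["tissue"]))

    def efficiency(self, gene: str, default: float = 2.0) -> float:
        if self.efficiencies and gene in self.efficiencies:
            return float(self.efficiencies[gene])
        return default

    def subset(self, tissue: str | None = None, genes: Sequence[str] | None = None) -> "CqTable":
        df = self.records
        if tissue is not None:
            df = df[df["tissue"] == tissue]
            if df.empty:
                raise KeyError(f"no records for tissue {tissue!r}")
        if genes is not None:
            df = df[df["gene"].isin(list(genes))]
        return CqTable(df.reset_index(drop=True), self.efficiencies, self.cq_ceiling)

    def cq_matrix(self, tissue: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Wide gene × sample Cq matrix (requires aggregated technical reps).

        Returns the matrix and a per-sample metadata frame (indexed by the
        synthesized sample key, ordered as the matrix columns).
        Missing (gene, sample) cells are an error: every stability algorithm
        requires a complete grid and silent imputation would bias it.
        """
        table = self.subset(tissue=tissue) if tissue is not None else self
        df = table.records
        dup = df.duplicated(["gene", "sample_id"])
        if dup.any():
            raise ValidationError(
                "multiple Cq records per (gene, sample); aggregate technical replicates first"
            )
        wide = df.pivot(index="gene", columns="sample_id", values="cq")
        if wide.isna().any().any():
            gene = wide.index[wide.isna().any(axis=1)][0]
            sample = wide.columns[wide.loc[gene].isna()][0]
            raise ValidationError(f"missing Cq for gene {gene!r} in sample {sample!r}")
        meta = (
            df.drop_duplicates("sample_id")
            .set_index("sample_id")[["variety", "tissue", "treatment", "bio_rep"]]
            .loc[wide.columns]
        )
        return wide, meta


@dataclass
class StabilityReport:
    """Per-gene stability values and ranks for one tissue.

    ``table`` is indexed by gene with columns
    ``genorm_m, genorm_rank, normfinder_rho, normfinder_rank, bestkeeper_sd,
    bestkeeper_cv, bestkeeper_r, bestkeeper_rank, deltact_meansd,
    deltact_rank, comprehensive_rank`` (methods not run are absent).
    """

    table: pd.DataFrame
    tissue: str
    methods: tuple[str, ...] = ("genorm", "normfinder", "bestkeeper", "deltact")

    def ordering(self) -> list[str]:
        """Genes from most to least stable by comprehensive rank (ties by gene id)."""
        order = self.table.assign(_gene=self.table.index).sort_values(
            ["comprehensive_rank", "_gene"]
        )
        return list(order.index)

    def top(self, n: int) -> list[str]:
        return self.ordering()[:n]


@dataclass
class ScreenReport:
    """Outcome of the candidate-screening cascade.

    ``per_dataset``: one row per (gene, dataset) with the three filter
    outcomes.  ``per_gene``: presence counts, correlation scores and the
    final ``selected`` flag.  ``config`` records the thresholds and the
    correlation aggregation used (so the committed interpretation is
    auditable from the report itself).
    """

    per_dataset: pd.DataFrame
    per_gene: pd.DataFrame
    config: dict = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return list(self.per_gene.index[self.per_gene["selected"]])

    @property
    def kept(self) -> list[str]:
        return list(self.per_gene.index[self.per_gene["kept"]])


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, comment="#")


def read_expression_panel(path: str | Path, meta_path: str | Path) -> ExpressionPanel:
    """Read a gene × sample FPKM matrix (TSV/CSV) plus its sample metadata.

    The matrix file has the gene identifier in the first column and one
    column per sample; the metadata CSV maps every sample column to its
    design factors.  Sample columns without metadata, or metadata rows
    without a matching column, are rejected.
    """
    mat = _read_table(path)
    gene_col = mat.columns[0]
    if mat[gene_col].duplicated().any():
        dups = mat[gene_col][mat[gene_col].duplicated()].tolist()
        raise ValidationError(f"duplicate gene ids in {path}: {dups}")
    fpkm = mat.set_index(gene_col)
    fpkm.index.name = "gene"
    try:
        fpkm = fpkm.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric FPKM value in {path}: {exc}") from exc

    meta = _read_table(meta_path)
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata must have a sample_id column")
    meta = meta.set_index("sample_id")
    unknown = set(fpkm.columns) - set(meta.index)
    if unknown:
        raise ValidationError(f"sample columns without metadata: {sorted(unknown)}")
    orphan = set(meta.index) - set(fpkm.columns)
    if orphan:
        raise ValidationError(f"metadata rows with no matching sample column: {sorted(orphan)}")
    meta = meta.loc[fpkm.columns]
    meta.index.name = "sample_id"
    panel = ExpressionPanel(fpkm, meta)
    _warn_single_group_datasets(panel)
    return panel


def _warn_single_group_datasets(panel: ExpressionPanel) -> list[str]:
    """Datasets with fewer than two condition groups cannot support ANOVA."""
    bad = []
    groups = panel.condition_groups()
    for ds in panel.dataset_ids:
        in_ds = panel.meta["dataset_id"] == ds
        if groups[in_ds].nunique() < 2:
            bad.append(ds)
    if bad:
        warnings.warn(
            f"datasets with a single condition group (excluded from ANOVA filtering): {bad}",
            stacklevel=3,
        )
    return bad


def read_cq_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    cq_ceiling: float = DEFAULT_CQ_CEILING,
    efficiencies: Mapping[str, float] | None = None,
) -> CqTable:
    """Read a long-format Cq CSV.

    Expected columns (renameable via ``column_map`` {file column → canonical
    name}): gene, sample_id, variety, tissue, treatment, bio_rep, tech_rep,
    cq.  ``variety`` and ``sample_id`` may be omitted: a single variety "V1"
    is assumed, and sample ids are synthesized from the design factors.
    Technical replicates are kept as-is; aggregation is an explicit step
    (:func:`aggregate_tech_reps`).
    """
    df = _read_table(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "variety" not in df.columns:
        df["variety"] = "V1"
    if "sample_id" not in df.columns:
        df["sample_id"] = (
            df["variety"].astype(str)
            + "."
            + df["tissue"].astype(str)
            + "."
            + df["treatment"].astype(str)
            + ".r"
            + df["bio_rep"].astype(str)
        )
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"Cq table missing columns {missing}")
    bad = pd.to_numeric(df["cq"], errors="coerce").isna() & df["cq"].notna() | df["cq"].isna()
    if bad.any():
        raise ValidationError(f"non-numeric Cq at row {df.index[bad][0]} of {path}")
    return CqTable(df[CQ_COLUMNS], dict(efficiencies) if efficiencies else None, cq_ceiling)


def read_dilution_series(path: str | Path) -> pd.DataFrame:
    """Read a serial-dilution Cq table with columns gene, log10_dilution, cq."""
    df = _read_table(path)
    need = {"log10_dilution", "cq"}
    if not need <= set(df.columns):
        raise ValidationError(f"dilution series must have columns {sorted(need)}")
    if "gene" not in df.columns:
        df["gene"] = "gene"
    df["log10_dilution"] = pd.to_numeric(df["log10_dilution"], errors="raise")
    df["cq"] = pd.to_numeric(df["cq"], errors="raise")
    return df[["gene", "log10_dilution", "cq"]]


# ---------------------------------------------------------------------------
# transforms


def aggregate_tech_reps(table: CqTable) -> CqTable:
    """Collapse technical replicates to their arithmetic-mean Cq.

    One record per (gene, sample) remains, with tech_rep set to 1.  Mean of
    Cq is the community default for triplicate designs (averaging on the
    cycle scale, i.e. geometric averaging of template quantity).
    """
    df = table.records
    keys = ["gene", "sample_id", "variety", "tissue", "treatment", "bio_rep"]
    agg = df.groupby(keys, sort=False, as_index=False)["cq"].mean()
    agg["tech_rep"] = 1
    return CqTable(agg[CQ_COLUMNS], table.efficiencies, table.cq_ceiling)


# ---------------------------------------------------------------------------
# writers

_STABILITY_COLUMNS = [
    "genorm_m",
    "genorm_rank",
    "normfinder_rho",
    "normfinder_rank",
    "bestkeeper_sd",
    "bestkeeper_cv",
    "bestkeeper_r",
    "bestkeeper_rank",
    "deltact_meansd",
    "deltact_rank",
    "comprehensive_rank",
]


def write_stability_report(report: StabilityReport, path: str | Path) -> None:
    """Write a stability report as TSV: one row per gene, fixed column order,
    rows sorted by comprehensive rank (ties by gene id)."""
    cols = [c for c in _STABILITY_COLUMNS if c in report.table.columns]
    out = report.table[cols].copy()
    out = out.loc[out.assign(_g=out.index).sort_values(["comprehensive_rank", "_g"]).index]
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tissue={report.tissue}\tmethods={','.join(report.methods)}\n")
        out.to_csv(fh, sep="\t", index=True, index_label="gene", lineterminator="\n")


def read_stability_report(path: str | Path) -> StabilityReport:
    """Parse a TSV written by :func:`write_stability_report`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    fields = dict(
        part.split("=", 1) for part in header.lstrip("# ").split("\t") if "=" in part
    )
    table = pd.read_csv(path, sep="\t", comment="#").set_index("gene")
    return StabilityReport(
        table,
        tissue=fields.get("tissue", ""),
        methods=tuple(fields.get("methods", "").split(",")) if fields.get("methods") else (),
    )


def write_screen_report(report: ScreenReport, path: str | Path) -> None:
    """Write the per-gene screening summary as TSV (filter detail alongside)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        cfg = "\t".join(f"{k}={v}" for k, v in sorted(report.config.items()))
        fh.write(f"# {cfg}\n")
        report.per_gene.to_csv(fh, sep="\t", index=True, index_label="gene", lineterminator="\n")
    detail = path.with_suffix(".per_dataset.tsv")
    report.per_dataset.to_csv(detail, sep="\t", index=False, lineterminator="\n")


def write_fold_change_table(fc: pd.DataFrame, path: str | Path) -> None:
    fc.to_csv(Path(path), sep="\t", index=False, lineterminator="\n")
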