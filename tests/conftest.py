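import numpy as np
import pandas as pd
import pytest

from refstab.data import CQ_COLUMNS, CqTable, ExpressionPanel
from refstab.stability import QuantityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230946)


def make_panel(fpkm: dict[str, list[float]], meta_rows: list[dict],
               genes: list[str] | None = None) -> ExpressionPanel:
    """``fpkm`` maps sample_id → per-gene values (column-wise)."""
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    mat = pd.DataFrame(fpkm)[list(meta.index)]
    n_genes = len(next(iter(fpkm.values())))
    mat.index = pd.Index(genes or [f"g{i}" for i in range(n_genes)], name="gene")
    return ExpressionPanel(mat, meta)


def make_cq_table(cq: np.ndarray, genes: list[str], treatments: list[str],
                  tissue: str = "leaf", efficiencies: dict | None = None) -> CqTable:
    """Wide gene × sample Cq matrix -> aggregated long CqTable.

    ``treatments`` labels each sample column (its condition group).
    """
    rows = []
    counters: dict[str, int] = {}
    for s in range(cq.shape[1]):
        trt = treatments[s]
        counters[trt] = counters.get(trt, 0) + 1
        sid = f"V1.{tissue}.{trt}.r{counters[trt]}"
        for g in range(cq.shape[0]):
            rows.append((genes[g], sid, "V1", tissue, trt, counters[trt], 1, cq[g, s]))
    return CqTable(pd.DataFrame(rows, columns=CQ_COLUMNS), efficiencies)


def make_quantity_matrix(cq: np.ndarray, genes: list[str], treatments: list[str],
                         efficiency: float = 2.0) -> QuantityMatrix:
    q = np.power(efficiency, cq.min(axis=1, keepdims=True) - cq)
    cols = [f"s{i}" for i in range(cq.shape[1])]
    return QuantityMatrix(
        pd.DataFrame(q, index=genes, columns=cols),
        pd.Series(treatments, index=cols),
        tissue="leaf",
    )


@pytest.fixture
def random_cq(rng):
    """Random 5-gene × 12-sample Cq layout with 3 treatment groups."""
    cq = rng.uniform(22, 32, size=(5, 12))
    genes = [f"g{i}" for i in range(5)]
    treatments = ["CK"] * 4 + ["salt"] * 4 + ["drought"] * 4
    return cq, genes, treatments
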