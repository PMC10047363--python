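import numpy as np
import pandas as pd
import pytest

from grnkit import ExpressionMatrix, Network


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """2 genes × 3 samples with complete metadata."""
    values = pd.DataFrame(
        {"s1": [1.0, 4.0], "s2": [2.0, 5.0], "s3": [3.0, 6.0]},
        index=pd.Index(["gA", "gB"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "timepoint": ["0h", "0h", "24h"],
            "condition": ["control", "control", "control"],
            "replicate": [1, 2, 1],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return ExpressionMatrix(values, meta)


def make_expr(values: np.ndarray, genes, groups) -> ExpressionMatrix:
    """ExpressionMatrix from an array and (timepoint, condition) per column."""
    sample_ids = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(
        {
            "timepoint": [g[0] for g in groups],
            "condition": [g[1] for g in groups],
            "replicate": list(range(1, len(groups) + 1)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    return ExpressionMatrix(df, meta)


def net_from_edges(edges, extra_nodes=()) -> Network:
    """Network from (regulator, target, sign[, weight]) tuples."""
    records = []
    for e in edges:
        reg, tgt, sign = e[0], e[1], e[2]
        weight = e[3] if len(e) > 3 else 1.0
        records.append(
            {"regulator": reg, "target": tgt, "sign": sign, "weight": weight}
        )
    return Network.from_records(records, extra_nodes=extra_nodes)
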