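import numpy as np
import pandas as pd
import pytest

from orthocorr import (
    ExpressionMatrix,
    OrthologMap,
    SyntheticConfig,
    differential_expression,
    generate_dataset,
)


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic two-species dataset (rho=0.6, seeded)."""
    return generate_dataset(SyntheticConfig(seed=101))


@pytest.fixture(scope="session")
def de_tables(dataset):
    human = differential_expression(dataset.human)
    mouse = differential_expression(dataset.mouse)
    return human, mouse


@pytest.fixture
def tiny_matrix():
    """3 transcripts x 4 samples (2 case, 2 control), with symbols."""
    values = pd.DataFrame(
        [[5.0, 5.2, 3.0, 2.8], [1.0, 1.1, 1.0, 0.9], [7.0, 6.8, 8.0, 8.2]],
        index=pd.Index(["A_1", "A_2", "A_3"], name="transcript_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    design = pd.Series(["case", "case", "control", "control"], index=values.columns)
    symbols = pd.Series(["G1", "G1", "G2"], index=values.index)
    return ExpressionMatrix(
        species="human", values=values, design=design, gene_symbols=symbols
    )


def make_de_table(log2fc, p=None, q=None, genes=None, prefix="T"):
    """Construct a DE table directly from planted columns (test helper)."""
    log2fc = np.asarray(log2fc, dtype=float)
    n = len(log2fc)
    idx = pd.Index([f"{prefix}{i}" for i in range(n)], name="transcript_id")
    p = np.full(n, 0.5) if p is None else np.asarray(p, dtype=float)
    q = p if q is None else np.asarray(q, dtype=float)
    return pd.DataFrame(
        {
            "gene": genes if genes is not None else [f"G{i}" for i in range(n)],
            "log2fc": log2fc,
            "stat": log2fc,
            "p": p,
            "q": q,
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=idx,
    )


def identity_map(ids, mouse_ids=None):
    """1:1 ortholog map between parallel id lists (test helper)."""
    ids = list(ids)
    mouse_ids = list(mouse_ids) if mouse_ids is not None else [f"m_{i}" for i in ids]
    return OrthologMap(
        pairs=pd.DataFrame(
            {
                "human_transcript": ids,
                "human_gene": [f"hg_{i}" for i in ids],
                "mouse_transcript": mouse_ids,
                "mouse_gene": [f"mg_{i}" for i in mouse_ids],
            }
        )
    )
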