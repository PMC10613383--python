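import numpy as np
import pandas as pd
import pytest

from degef.genome import GenomeLayout


@pytest.fixture
def toy_layout() -> GenomeLayout:
    """Two chromosomes: A (1000 bp, centromere [400, 600)), B (500 bp,
    no centromere)."""
    return GenomeLayout(
        chrom_lengths={"A": 1000, "B": 500},
        centromeres={"A": (400, 600)},
    )


def make_genes(records) -> pd.DataFrame:
    """Build a canonical gene frame from (gene_id, chrom, tss, log2fc,
    fdr[, status]) tuples; p_value defaults to fdr."""
    rows = []
    for rec in records:
        gene_id, chrom, tss, log2fc, fdr = rec[:5]
        row = {
            "gene_id": gene_id, "chrom": chrom, "tss": int(tss),
            "strand": ".", "log2fc": float(log2fc),
            "p_value": float(fdr), "fdr": float(fdr),
        }
        if len(rec) > 5:
            row["status"] = rec[5]
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
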