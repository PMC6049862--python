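import numpy as np
import pandas as pd
import pytest

import lncscape as L
from lncscape.io import CONTROL, TUMOR, ExpressionMatrix, GeneAnnotation


@pytest.fixture(scope="session")
def ds19():
    """Microarray-like synthetic dataset (19 tumors / 9 controls)."""
    return L.simulate_dataset(n_tumor=19, n_control=9, seed=11)


@pytest.fixture(scope="session")
def ds150():
    """RNA-Seq-like synthetic dataset (150 tumors / 9 controls)."""
    return L.simulate_dataset(n_tumor=150, n_control=9, seed=11)


def make_matrix(values, n_tumor, feature_ids=None, scale="log2", flags=None):
    """ExpressionMatrix from a 2-D array; first n_tumor columns are tumors."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feature_ids = feature_ids or [f"F{i}" for i in range(n_feat)]
    samples = [f"S{j}" for j in range(n_samp)]
    labels = pd.Series([TUMOR] * n_tumor + [CONTROL] * (n_samp - n_tumor),
                       index=samples)
    flags_df = None
    if flags is not None:
        flags_df = pd.DataFrame(flags, index=feature_ids, columns=samples)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=samples),
        group_labels=labels, scale=scale, flags=flags_df)


def gene(gene_id, chrom, start, end, strand="+", biotype="lncRNA", exons=()):
    return GeneAnnotation(gene_id=gene_id, chrom=chrom, start=start, end=end,
                          strand=strand, biotype=biotype,
                          exons=tuple(exons), symbol=gene_id)
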