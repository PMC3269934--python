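"""Sparse-matrix plumbing shared by the learner modules."""

from __future__ import annotations

import numpy as np
from scipy import sparse


def csr32(X) -> sparse.csr_matrix:
    """liblinear accepts only 32-bit sparse indices; DictVectorizer may
    emit 64-bit ones."""
    X = sparse.csr_matrix(X)
    X.indices = X.indices.astype(np.int32, copy=False)
    X.indptr = X.indptr.astype(np.int32, copy=False)
    return X
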