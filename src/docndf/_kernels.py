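"""Compiled inner loops for the correlation-entropy computation."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _channel_entropy(X: np.ndarray, inv_two_sigma_sq: float) -> np.ndarray:
    """Per-segment correlation entropy for one channel.

    ``X`` is (N segments, K samples). Returns C of length N where
    ``C[n] = (1/K) * sum_i sum_k exp(-(X[n,k]-X[i,k])^2 * inv_two_sigma_sq)``,
    including the i = n self term. Exploits the symmetry of the pairwise
    kernel sums.
    """
    N, K = X.shape
    S = np.empty((N, N))
    for n in range(N):
        for i in range(n, N):
            s = 0.0
            for k in range(K):
                d = X[n, k] - X[i, k]
                s += np.exp(-d * d * inv_two_sigma_sq)
            S[n, i] = s
            S[i, n] = s
    return S.sum(axis=1) / K
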