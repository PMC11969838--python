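import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_hsic(x, y, bw_x, bw_y, scaling="paper"):
    """Independent double-loop HSIC oracle: explicit kernel entries,
    explicit centering, explicit trace."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    if y.shape[0] == 1:
        y = y.T
    n = x.shape[0]
    K = np.zeros((n, n))
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = np.exp(-np.sum((x[i] - x[j]) ** 2) / (2 * bw_x**2))
            L[i, j] = np.exp(-np.sum((y[i] - y[j]) ** 2) / (2 * bw_y**2))
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            H[i, j] = (1.0 if i == j else 0.0) - 1.0 / n
    M = K @ H @ L @ H
    trace = sum(M[i, i] for i in range(n))
    denom = (n - 1) if scaling == "paper" else (n - 1) ** 2
    return trace / denom


def brute_force_causality_map(stack_maps):
    """Entry-wise double-loop oracle for the conditional-probability map."""
    n = stack_maps.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            denom = stack_maps[j].sum()
            if denom == 0:
                out[i, j] = 0.0
            else:
                out[i, j] = stack_maps[i].max() * stack_maps[j].max() / denom
    return out
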