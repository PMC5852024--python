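"""Independent brute-force oracles shared by the test suite."""

import numpy as np


def tom_triple_loop(A: np.ndarray) -> np.ndarray:
    """Topological overlap by explicit triple loop (reference implementation)."""
    n = len(A)
    K = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l_ij + A[i, j]) / (min(K[i], K[j]) + 1 - A[i, j])
    return T
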