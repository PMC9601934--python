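"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain double loops over pairs, deliberately
sharing no code with the package.
"""

import numpy as np


def gv_bruteforce(d2: np.ndarray) -> float:
    n = d2.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += d2[i, j]
    return total / (2.0 * n * n)


def sqeuclidean_bruteforce(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = float(np.sum((X[i] - X[j]) ** 2))
    return out


def mahalanobis_bruteforce(X: np.ndarray, scatter: np.ndarray) -> np.ndarray:
    VI = np.linalg.inv(scatter)
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = X[i] - X[j]
            out[i, j] = float(d @ VI @ d)
    return out


def cityblock_gower_bruteforce(X: np.ndarray) -> np.ndarray:
    n, q = X.shape
    ranges = [X[:, k].max() - X[:, k].min() for k in range(q)]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(q):
                acc += abs(X[i, k] - X[j, k]) / ranges[k]
            out[i, j] = acc / q
    return out


def jaccard_bruteforce(B: np.ndarray) -> np.ndarray:
    n, q = B.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a = b = c = 0
            for k in range(q):
                if B[i, k] == 1 and B[j, k] == 1:
                    a += 1
                elif B[i, k] == 1 and B[j, k] == 0:
                    b += 1
                elif B[i, k] == 0 and B[j, k] == 1:
                    c += 1
            denom = a + b + c
            s = a / denom if denom > 0 else 1.0
            out[i, j] = 1.0 - s
    return out


def hamming_bruteforce(C: np.ndarray) -> np.ndarray:
    n, q = C.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            mismatches = sum(1 for k in range(q) if C[i, k] != C[j, k])
            out[i, j] = mismatches / q
    return out


def five_number_bruteforce(values: np.ndarray) -> tuple:
    """Five-number summary with type-7 (linear interpolation) quantiles."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def quantile(p: float) -> float:
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return v[0], quantile(0.25), quantile(0.5), quantile(0.75), v[-1]
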