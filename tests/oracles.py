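"""Independent brute-force oracles: scalar loops, no vectorization shared
with the implementation under test."""

import math

import numpy as np


def cosine_oracle(y: np.ndarray) -> np.ndarray:
    m, n = y.shape
    s = np.zeros((n, n))
    for j in range(n):
        for jp in range(n):
            num = sum(y[i, j] * y[i, jp] for i in range(m))
            na = math.sqrt(sum(y[i, j] ** 2 for i in range(m)))
            nb = math.sqrt(sum(y[i, jp] ** 2 for i in range(m)))
            s[j, jp] = num / (na * nb) if na > 0 and nb > 0 else 0.0
    return s


def tanimoto_oracle(y: np.ndarray) -> np.ndarray:
    m, n = y.shape
    s = np.zeros((n, n))
    for j in range(n):
        for jp in range(n):
            num = sum(y[i, j] * y[i, jp] for i in range(m))
            den = (
                sum(y[i, j] ** 2 for i in range(m))
                + sum(y[i, jp] ** 2 for i in range(m))
                - num
            )
            s[j, jp] = num / den if den > 0 else 0.0
    return s


def dice_oracle(y: np.ndarray) -> np.ndarray:
    m, n = y.shape
    s = np.zeros((n, n))
    for j in range(n):
        for jp in range(n):
            num = 2 * sum(y[i, j] * y[i, jp] for i in range(m))
            den = sum(y[i, j] ** 2 for i in range(m)) + sum(y[i, jp] ** 2 for i in range(m))
            s[j, jp] = num / den if den > 0 else 0.0
    return s


def ppmi_oracle(y: np.ndarray, co_mode: str = "shared-ones") -> np.ndarray:
    m, n = y.shape
    co = np.zeros((n, n))
    for j in range(n):
        for jp in range(n):
            if co_mode == "shared-ones":
                co[j, jp] = sum(1 for i in range(m) if y[i, j] == 1 and y[i, jp] == 1)
            else:
                co[j, jp] = sum(1 for i in range(m) if y[i, j] == y[i, jp])
    total = co.sum()
    s = np.zeros((n, n))
    for j in range(n):
        for jp in range(n):
            pj = co[j].sum() / total
            pjp = co[jp].sum() / total
            pjoint = co[j, jp] / total
            if pjoint > 0 and pj > 0 and pjp > 0:
                s[j, jp] = max(math.log2(pjoint / (pj * pjp)), 0.0)
    return s


def nbcf_oracle(train: np.ndarray, sim: np.ndarray) -> np.ndarray:
    m, n = train.shape
    out = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            out[i, j] = sum(sim[j, k] for k in range(n) if train[i, k] == 1)
    return out


def blend_oracle(yt, st, sd, alpha, beta, gamma) -> np.ndarray:
    m, n = yt.shape
    out = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            acc = beta * yt[i, j]
            for r in range(m):
                acc += alpha * st[i, r] * yt[r, j]
            for c in range(n):
                acc += gamma * yt[i, c] * sd[c, j]
            out[i, j] = acc
    return out
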