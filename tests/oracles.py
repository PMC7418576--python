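"""Naive scalar-loop reference implementations used as test oracles.

These evaluate every formula element by element with plain Python floats and
stay deliberately independent of the vectorised code paths they check.
"""

import math

import numpy as np


def bandwidth_loop(profiles, lambda_prime=1.0) -> float:
    profiles = np.asarray(profiles, dtype=float)
    total = 0.0
    for row in profiles:
        total += sum(float(x) * float(x) for x in row)
    return lambda_prime / (total / profiles.shape[0])


def gip_loop(profiles, lam) -> np.ndarray:
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d2 = sum((a - b) ** 2 for a, b in zip(profiles[i], profiles[j]))
            out[i, j] = math.exp(-lam * d2)
    return out


def cosine_loop(profiles) -> np.ndarray:
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ni = math.sqrt(sum(x * x for x in profiles[i]))
            nj = math.sqrt(sum(x * x for x in profiles[j]))
            if ni > 0 and nj > 0:
                dot = sum(a * b for a, b in zip(profiles[i], profiles[j]))
                out[i, j] = dot / (ni * nj)
    return out


def ncp_loop(MD, DS, MS) -> np.ndarray:
    """Scalar evaluation of the two projections and their combination."""
    MD = np.asarray(MD, dtype=float)
    DS = np.asarray(DS, dtype=float)
    MS = np.asarray(MS, dtype=float)
    nm, nd = MD.shape
    out = np.zeros((nm, nd))
    for i in range(nm):
        for j in range(nd):
            row_norm = math.sqrt(sum(x * x for x in MD[i, :]))
            col_norm = math.sqrt(sum(x * x for x in MD[:, j]))
            ncpd = sum(MD[i, k] * DS[k, j] for k in range(nd)) / row_norm if row_norm else 0.0
            ncpm = sum(MS[i, k] * MD[k, j] for k in range(nm)) / col_norm if col_norm else 0.0
            ds_norm = math.sqrt(sum(DS[k, j] ** 2 for k in range(nd)))
            ms_norm = math.sqrt(sum(MS[i, k] ** 2 for k in range(nm)))
            den = ds_norm + ms_norm
            out[i, j] = (ncpd + ncpm) / den if den else 0.0
    return out


def roc_auc_brute(pos, neg) -> float:
    """O(P*N) pair count with ties worth 1/2."""
    num = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                num += 1.0
            elif p == q:
                num += 0.5
    return num / (len(pos) * len(neg))
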