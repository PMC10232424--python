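"""Independent brute-force oracles, coded elementwise from the definitions.

These deliberately use explicit Python loops and none of the package's
vectorized code paths, so agreement with the implementation is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- kernels


def pearson_similarity_oracle(rows: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation, negatives clipped, degenerate rows -> 0."""
    n, N = rows.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
                continue
            x, y = rows[i], rows[j]
            xm, ym = x.mean(), y.mean()
            num = sum((x[k] - xm) * (y[k] - ym) for k in range(N))
            den = math.sqrt(
                sum((x[k] - xm) ** 2 for k in range(N))
                * sum((y[k] - ym) ** 2 for k in range(N))
            )
            out[i, j] = max(0.0, num / den) if den > 0 else 0.0
    return out


def functional_similarity_oracle(sets: list[frozenset]) -> np.ndarray:
    n = len(sets)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
            elif sets[i] and sets[j]:
                out[i, j] = len(sets[i] & sets[j]) / (
                    math.sqrt(len(sets[i])) * math.sqrt(len(sets[j]))
                )
    return out


def gip_kernel_oracle(profiles: np.ndarray) -> np.ndarray:
    """exp(-gamma ||x_i - x_j||^2), gamma = 1 / mean squared profile norm."""
    n = len(profiles)
    mean_sq = sum(float(np.dot(p, p)) for p in profiles) / n
    gamma = 1.0 / mean_sq
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2 = sum((profiles[i, k] - profiles[j, k]) ** 2 for k in range(profiles.shape[1]))
            out[i, j] = math.exp(-gamma * d2)
    np.fill_diagonal(out, 1.0)
    return out


def hamming_similarity_oracle(profiles: np.ndarray) -> np.ndarray:
    n, L = profiles.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ndiff = sum(1 for k in range(L) if profiles[i, k] != profiles[j, k])
            out[i, j] = 1.0 - ndiff / L
    np.fill_diagonal(out, 1.0)
    return out


def cosine_similarity_oracle(profiles: np.ndarray) -> np.ndarray:
    n = len(profiles)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
                continue
            ni = math.sqrt(float(np.dot(profiles[i], profiles[i])))
            nj = math.sqrt(float(np.dot(profiles[j], profiles[j])))
            if ni > 0 and nj > 0:
                out[i, j] = float(np.dot(profiles[i], profiles[j])) / (ni * nj)
    return out


# ----------------------------------------------------------------- fusion


def _neighbors_oracle(values: np.ndarray, n_neighbors: int) -> list[list[int]]:
    """N_i = {i} plus the n_neighbors-1 largest others, ties by ascending index."""
    n = len(values)
    hoods = []
    for i in range(n):
        others = sorted((j for j in range(n) if j != i), key=lambda j: (-values[i, j], j))
        hoods.append([i] + others[: n_neighbors - 1])
    return hoods


def skf_fuse_oracle(
    kernels: list[np.ndarray],
    alpha: float,
    n_neighbors: int,
    n_iterations: int,
    tol: float = 0.0,
    legacy_denominator: bool = False,
) -> np.ndarray:
    """Step-by-step transcription of the fusion procedure."""
    K = len(kernels)
    n = len(kernels[0])
    denom = 2.0 if legacy_denominator else K - 1.0

    initial = []
    for S in kernels:
        NS = np.zeros((n, n))
        for j in range(n):
            col = sum(S[k, j] for k in range(n))
            for i in range(n):
                NS[i, j] = S[i, j] / col if col > 0 else 1.0 / n
        initial.append(NS)

    operators = []
    for S in kernels:
        hood = _neighbors_oracle(S, n_neighbors)
        F = np.zeros((n, n))
        for i in range(n):
            row = sum(S[i, j] for j in hood[i])
            for j in hood[i]:
                F[i, j] = S[i, j] / row if row > 0 else 1.0 / len(hood[i])
        operators.append(F)

    statuses = [m.copy() for m in initial]
    for _ in range(n_iterations):
        new = []
        for r in range(K):
            comp_t = sum(statuses[k] for k in range(K) if k != r) / denom
            comp_0 = sum(initial[k] for k in range(K) if k != r) / denom
            m = alpha * (operators[r] @ comp_t @ operators[r].T) + (1 - alpha) * comp_0
            new.append((m + m.T) / 2)
        delta = max(float(np.abs(new[r] - statuses[r]).max()) for r in range(K))
        statuses = new
        if delta < tol:
            break

    overall = sum(statuses) / K
    hood = _neighbors_oracle(overall, n_neighbors)
    member = [[j in hood[i] for j in range(n)] for i in range(n)]
    fused = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if member[i][j] and member[j][i]:
                w = 1.0
            elif not member[i][j] and not member[j][i]:
                w = 0.0
            else:
                w = 0.5
            fused[i, j] = w * overall[i, j]
    return fused


# ---------------------------------------------------------------- metrics


def confusion_oracle(y_true, y_pred) -> dict:
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    pre = tp / (tp + fp) if tp + fp else math.nan
    sen = tp / (tp + fn) if tp + fn else math.nan
    acc = (tp + tn) / (tp + tn + fp + fn)
    if not (math.isnan(pre) or math.isnan(sen)) and pre + sen > 0:
        f1 = 2 * sen * pre / (sen + pre)
    elif math.isnan(pre) or math.isnan(sen):
        f1 = math.nan
    else:
        f1 = math.nan
    den = math.sqrt((tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    mcc = (tp * tn - fp * fn) / den if den else math.nan
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "precision": pre, "sensitivity": sen, "accuracy": acc, "f1": f1, "mcc": mcc,
    }


def auc_concordance_oracle(y_true, scores) -> float:
    """P(score_pos > score_neg) with half credit for ties, by full enumeration."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_trapezoid_oracle(y_true, scores) -> float:
    """Trapezoidal area under the PR curve, thresholds at distinct scores."""
    y = list(y_true)
    n_pos = sum(y)
    points = []  # (recall, precision), recall increasing
    for thr in sorted(set(scores), reverse=True):
        pred = [1 if s >= thr else 0 for s in scores]
        tp = sum(1 for t, p in zip(y, pred) if t == 1 and p == 1)
        fp = sum(1 for t, p in zip(y, pred) if t == 0 and p == 1)
        points.append((tp / n_pos, tp / (tp + fp)))
    points = [(0.0, 1.0)] + points
    area = 0.0
    for (r0, p0), (r1, p1) in zip(points[:-1], points[1:]):
        area += (r1 - r0) * (p0 + p1) / 2
    return area
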