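"""Naive double-loop reference for the variability statistics.

Deliberately direct: windowed np.corrcoef matrices, explicit Python
loops over window pairs, scipy-free Pearson via np.corrcoef.  Used as
the independent oracle against the vectorised implementation.
"""

from __future__ import annotations

import numpy as np


def naive_segment(T: int, l: int, s: int) -> list[tuple[int, int]]:
    num = (T - s + 1) // l
    return [(s - 1 + i * l, s - 1 + (i + 1) * l) for i in range(num)]


def naive_fc_stack(data: np.ndarray, windows) -> list[np.ndarray]:
    return [np.corrcoef(data[a:b].T) for a, b in windows]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _mean_pairwise(vectors: list[np.ndarray]) -> float:
    vals = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            vals.append(_pearson(vectors[i], vectors[j]))
    return float(np.mean(vals))


def naive_regional(fcs: list[np.ndarray], k: int) -> float:
    R = fcs[0].shape[0]
    others = [c for c in range(R) if c != k]
    vectors = [fc[k, others] for fc in fcs]
    return 1.0 - _mean_pairwise(vectors)


def naive_intra(fcs: list[np.ndarray], members) -> float:
    members = list(members)
    if len(members) < 3:
        return float("nan")
    vectors = []
    for fc in fcs:
        vals = [
            fc[members[i], members[j]]
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
        vectors.append(np.array(vals))
    return 1.0 - _mean_pairwise(vectors)


def naive_inter(fcs: list[np.ndarray], members_m, members_n) -> float:
    vectors = []
    for fc in fcs:
        vals = [fc[a, b] for a in members_m for b in members_n]
        vectors.append(np.array(vals))
    return 1.0 - _mean_pairwise(vectors)


def naive_multiscale_regional(
    data: np.ndarray, lengths, min_windows: int = 2
) -> np.ndarray:
    """Unweighted mean of naive_regional over every retained (l, s)."""
    T, R = data.shape
    acc = []
    for l in lengths:
        for s in range(1, l):
            windows = naive_segment(T, l, s)
            if len(windows) < min_windows:
                continue
            fcs = naive_fc_stack(data, windows)
            acc.append([naive_regional(fcs, k) for k in range(R)])
    return np.mean(np.array(acc), axis=0)
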