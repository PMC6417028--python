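"""Independent brute-force oracles used only by the tests.

These deliberately use naive enumeration (voxel-by-voxel loops, BFS flood
fill, concordant-pair counting, closed-form least squares) so they share
no code path with the package implementations they check.
"""

import itertools

import numpy as np


def brute_glcm(levels, mask, offset, n_levels):
    """Pair enumeration: count (a, b) at +offset, both in mask; symmetrize."""
    mat = np.zeros((n_levels, n_levels))
    shape = levels.shape
    off = np.asarray(offset)
    for idx in itertools.product(*(range(n) for n in shape)):
        if not mask[idx]:
            continue
        nbr = tuple(np.asarray(idx) + off)
        if all(0 <= c < n for c, n in zip(nbr, shape)) and mask[nbr]:
            mat[levels[idx] - 1, levels[nbr] - 1] += 1
    return mat + mat.T


def brute_glrlm(levels, mask, offset, n_levels):
    """Run enumeration: walk every maximal run of equal level along offset."""
    shape = levels.shape
    off = np.asarray(offset)
    runs = []
    for idx in itertools.product(*(range(n) for n in shape)):
        if not mask[idx] or levels[idx] == 0:
            continue
        prev = tuple(np.asarray(idx) - off)
        inside = all(0 <= c < n for c, n in zip(prev, shape))
        if inside and mask[prev] and levels[prev] == levels[idx]:
            continue  # not a run start
        length = 1
        cur = np.asarray(idx)
        while True:
            nxt = cur + off
            t = tuple(nxt)
            if not all(0 <= c < n for c, n in zip(t, shape)):
                break
            if not mask[t] or levels[t] != levels[idx]:
                break
            length += 1
            cur = nxt
        runs.append((int(levels[idx]), length))
    if not runs:
        return np.zeros((n_levels, 1))
    max_len = max(l for _, l in runs)
    mat = np.zeros((n_levels, max_len))
    for g, l in runs:
        mat[g - 1, l - 1] += 1
    return mat


def brute_glszm(levels, mask, n_levels):
    """Flood-fill enumeration of 26-connected equal-level zones."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    neighbours = [d for d in itertools.product((-1, 0, 1), repeat=3)
                  if d != (0, 0, 0)]
    zones = []
    for idx in itertools.product(*(range(n) for n in shape)):
        if seen[idx] or not mask[idx] or levels[idx] == 0:
            continue
        level = levels[idx]
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in neighbours:
                nbr = tuple(c + o for c, o in zip(cur, d))
                if not all(0 <= c < n for c, n in zip(nbr, shape)):
                    continue
                if seen[nbr] or not mask[nbr] or levels[nbr] != level:
                    continue
                seen[nbr] = True
                stack.append(nbr)
        zones.append((int(level), size))
    if not zones:
        return np.zeros((n_levels, 1))
    max_size = max(s for _, s in zones)
    mat = np.zeros((n_levels, max_size))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


def brute_auc(scores, labels):
    """Concordant-pair counting with ties worth one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ols_coefficients(X, y):
    """Closed-form least squares with intercept (normal equations)."""
    A = np.column_stack([np.ones(len(X)), X])
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    return coef[1:]
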