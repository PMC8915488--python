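"""Independent brute-force reference implementations used as test oracles.

Deliberately naive: plain loops, stdlib statistics where possible, no reuse
of the package's own code paths.
"""

from __future__ import annotations

import statistics

import numpy as np


def robust_z_column(col):
    """Per-column robust z by direct hand computation (unscaled MAD)."""
    vals = [v for v in col if not np.isnan(v)]
    med = statistics.median(vals)
    mad = statistics.median([abs(v - med) for v in vals])
    return [(v - med) / mad if not np.isnan(v) else np.nan for v in col]


def genewise_z_row(row):
    """Per-row robust z (strain median / strain MAD)."""
    vals = [v for v in row if not np.isnan(v)]
    med = statistics.median(vals)
    mad = statistics.median([abs(v - med) for v in vals])
    return [(v - med) / mad if not np.isnan(v) else np.nan for v in row]


def pearson_pairwise(x, y):
    """Pairwise-complete Pearson by the textbook formula; None if undefined."""
    pairs = [(a, b) for a, b in zip(x, y) if not (np.isnan(a) or np.isnan(b))]
    if len(pairs) < 2:
        return None, 0
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
    sxx = sum((a - mx) ** 2 for a in xs)
    syy = sum((b - my) ** 2 for b in ys)
    if sxx == 0 or syy == 0:
        return None, len(pairs)
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    return sxy / (sxx * syy) ** 0.5, len(pairs)


def clearance_literal(profile: dict[str, float], positive_only: bool = True):
    """O(n^2) literal transcription of the clearance definition.

    For each strain, its gap is its FD minus the greatest FD ranked strictly
    after it (full descending order, ties broken by strain id).  clearance_max
    is the largest gap at a position with FD > 0 (every position when
    *positive_only* is False); fd_max is the FD of the highest-FD strain
    achieving it; every strain with FD >= fd_max receives clearance_max,
    everyone else their own gap.

    Returns (per-strain clearance dict, clearance_max, fd_max).
    """
    items = list(profile.items())

    def rank_key(item):
        return (-item[1], item[0])

    gaps: dict[str, float] = {}
    for sid, fd in items:
        below = [f for s2, f in items if rank_key((s2, f)) > rank_key((sid, fd))]
        if below:
            gaps[sid] = fd - max(below)

    eligible = [(sid, g) for sid, g in gaps.items()
                if (profile[sid] > 0 or not positive_only)]
    if not eligible:
        return {sid: 0.0 for sid in profile}, 0.0, float("nan")
    clearance_max = max(g for _, g in eligible)
    fd_max = max(profile[sid] for sid, g in eligible if g == clearance_max)
    out = {}
    for sid, fd in items:
        if fd >= fd_max:
            out[sid] = clearance_max
        else:
            out[sid] = gaps.get(sid, 0.0)
    return out, clearance_max, fd_max


def ward_d_naive(D: np.ndarray):
    """O(n^3) Lance-Williams Ward agglomeration on a given dissimilarity.

    Returns the list of merges as (frozenset_a, frozenset_b, height).
    Ties broken by the lexicographically smallest member pair.
    """
    n = D.shape[0]
    clusters: dict[frozenset, int] = {frozenset([i]): 1 for i in range(n)}
    dist: dict[frozenset, dict[frozenset, float]] = {}
    keys = list(clusters)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            d = D[min(a), min(b)]
            dist.setdefault(a, {})[b] = d
            dist.setdefault(b, {})[a] = d
    merges = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in dist[a]:
                key = (dist[a][b], tuple(sorted(a | b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_, _), a, b = best[0], best[1], best[2]
        h = dist[a][b]
        merged = a | b
        na, nb = clusters[a], clusters[b]
        merges.append((a, b, h))
        new_d = {}
        for c in clusters:
            if c in (a, b):
                continue
            nc = clusters[c]
            t = na + nb + nc
            new_d[c] = ((na + nc) * dist[a][c] + (nb + nc) * dist[b][c]
                        - nc * h) / t
        del clusters[a], clusters[b]
        for c in list(dist):
            dist[c].pop(a, None)
            dist[c].pop(b, None)
        del dist[a], dist[b]
        clusters[merged] = na + nb
        dist[merged] = {}
        for c, d in new_d.items():
            dist[merged][c] = d
            dist[c][merged] = d
    return merges


def cophenetic_from_merges(merges, n: int) -> np.ndarray:
    """Leaf-pair cophenetic heights implied by a merge list."""
    C = np.zeros((n, n))
    for a, b, h in merges:
        for i in a:
            for j in b:
                C[i, j] = C[j, i] = h
    return C


def median_polish_batch_effects(log2_matrix: np.ndarray, batch_of_col,
                                n_iter: int = 200):
    """Direct two-way (array + batch) median polish run to convergence.

    Returns (overall, array_effects, batch_effects) estimated by alternating
    median sweeps on the additive model
    ``x = overall + array + batch + residual``.
    """
    x = np.asarray(log2_matrix, dtype=float)
    n_rows, n_cols = x.shape
    batches = sorted(set(batch_of_col))
    overall = float(np.nanmedian(x))
    a = np.zeros(n_cols)
    b = {g: 0.0 for g in batches}
    for _ in range(n_iter):
        resid = x - overall - a - np.array([b[batch_of_col[j]] for j in range(n_cols)])
        delta = np.nanmedian(resid, axis=0)
        a = a + np.where(np.isnan(delta), 0.0, delta)
        for g in batches:
            cols = [j for j in range(n_cols) if batch_of_col[j] == g]
            shift = float(np.median(a[cols]))
            b[g] += shift
            a[cols] -= shift
        shift = float(np.median(list(b.values())))
        overall += shift
        for g in batches:
            b[g] -= shift
    return overall, a, b
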