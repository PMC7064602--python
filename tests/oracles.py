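"""Naive reference implementations used to cross-check the vectorized code.

Everything here is written as plain loops over cells and PSMs, independent
of the package's numpy/scipy pipeline, so agreement is meaningful.
"""

import numpy as np


def oracle_box_mean(array, window):
    """Border-clipped box mean by explicit slicing per cell."""
    array = np.asarray(array, dtype=float)
    half = window // 2
    out = np.empty_like(array)
    for idx in np.ndindex(array.shape):
        slices = tuple(
            slice(max(i - half, 0), min(i + half + 1, n))
            for i, n in zip(idx, array.shape)
        )
        out[idx] = array[slices].mean()
    return out


def _bin_of(value, edges):
    """Interval [e_i, e_{i+1}) containing value; top edge joins the last bin."""
    for i in range(len(edges) - 2):
        if value < edges[i + 1]:
            return i
    return len(edges) - 2


def oracle_grid_gamma(scores, is_decoy, bins, smooth, window, eps0, eps1):
    """Per-PSM gamma by naive counting, smoothing and normalisation."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    ndim = scores.shape[1]
    edges = [np.linspace(scores[:, d].min(), scores[:, d].max(), bins + 1) for d in range(ndim)]
    shape = (bins,) * ndim
    n0 = np.zeros(shape)
    t = np.zeros(shape)
    cells = []
    for row, decoy in zip(scores, is_decoy):
        cell = tuple(_bin_of(row[d], edges[d]) for d in range(ndim))
        cells.append(cell)
        if decoy:
            n0[cell] += 1
        else:
            t[cell] += 1
    diff = t - n0
    if smooth:
        n0 = oracle_box_mean(n0, window)
        n1 = np.maximum(oracle_box_mean(diff, window), 0.0)
        eps0 = eps0 / window**ndim
        eps1 = eps1 / window**ndim
    else:
        n1 = np.maximum(diff, 0.0)
    total0 = max(n0.sum(), 1.0)
    total1 = max(n1.sum(), 1.0)
    gamma = ((n1 + eps1) / total1) / ((n0 + eps0) / total0)
    return np.array([gamma[c] for c in cells])


def oracle_threshold(lfdr_values, alpha):
    """Largest lFDR value whose <=-prefix has mean <= alpha, by enumeration."""
    values = sorted(lfdr_values)
    best = None
    for v in sorted(set(values)):
        prefix = [u for u in values if u <= v]
        if np.mean(prefix) <= alpha:
            best = v
    return best


def oracle_pipeline_lfdr(psms, grouping, score_dims, alpha, bins, smooth, window, eps0, eps1):
    """Per-PSM lFDR and acceptance of the full pipeline, recomputed naively."""
    lfdr = np.full(len(psms), np.nan)
    strata = {}
    for i, r in enumerate(psms):
        key = "Z1" if r.charge == 1 else ("Z2" if r.charge == 2 else "Z3plus")
        strata.setdefault(key, []).append(i)
    gamma = np.full(len(psms), np.nan)
    for idxs in strata.values():
        if score_dims == 3:
            scores = [[psms[i].xcorr, psms[i].delta_cn, psms[i].sp_score] for i in idxs]
        else:
            scores = [[psms[i].xcorr] for i in idxs]
        decoys = [psms[i].is_decoy for i in idxs]
        g = oracle_grid_gamma(scores, decoys, bins, smooth, window, eps0, eps1)
        for i, value in zip(idxs, g):
            gamma[i] = value

    if grouping == "two_group":
        group_of = lambda r: r.group.value
    else:
        group_of = lambda r: "all"
    accepted = np.zeros(len(psms), dtype=bool)
    for name in sorted({group_of(r) for r in psms}):
        members = [i for i, r in enumerate(psms) if group_of(r) == name]
        T = sum(1 for i in members if not psms[i].is_decoy)
        D = len(members) - T
        pi = max(T - D, 0) / max(D, 1)
        for i in members:
            lfdr[i] = 1.0 / (1.0 + pi * gamma[i])
        target_vals = [lfdr[i] for i in members if not psms[i].is_decoy]
        thr = oracle_threshold(target_vals, alpha)
        if thr is not None:
            for i in members:
                if not psms[i].is_decoy and lfdr[i] <= thr:
                    accepted[i] = True
    return lfdr, accepted
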