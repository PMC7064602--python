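"""Group-specific local-FDR estimation over the 3D search-engine score space.

For each charge stratum (Z=1, Z=2, Z>=3) the score vectors
``x = (XCorr, deltaCn, spScore)`` of all PSMs are binned into a histogram
with 40 intervals per dimension.  In each cell the decoy count gives the
number of wrong hits ``n0`` and the target excess over decoys the number of
true hits ``n1``; both are smoothed by averaging over the cell's nearest
neighbourhood and normalised into probability estimates
``p(x|Z, H=0)`` and ``p(x|Z, H=1)``.  The local FDR of a cell is

    lFDR(x, Z) = (1 + (pi1/pi0) * gamma(x, Z))^-1,
    gamma(x, Z) = p(x|Z, H=1) / p(x|Z, H=0),

where ``pi1/pi0`` is the prior odds that a PSM is correct.  The density
ratio ``gamma`` is shared by all PSMs, but the prior odds are estimated
separately for proteome-derived and non-canonical PSM groups — the
non-canonical search space is large and mostly wrong, so its far lower
pi1/pi0 raises every non-canonical lFDR and protects the group from the
leniency earned by the clean proteome group.  Finally the lFDR acceptance
threshold is adjusted so that the estimated global FDR (the running mean
of accepted lFDR values) meets the requested level, 3% by default.

A 1D fallback using only XCorr (``score_dims=1``) is provided for
comparison; it runs the identical machinery on a one-dimensional grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from newance.io_formats import Group, PsmRecord, PsmTable

__all__ = [
    "ScoreGrid",
    "GroupPriors",
    "LfdrResult",
    "SmallStratumWarning",
    "DegenerateScoreError",
    "stratify_by_charge",
    "build_score_grid",
    "lfdr",
    "estimate_group_priors",
    "select_threshold",
    "run_newance_fdr",
    "STRATA",
]

STRATA = ("Z1", "Z2", "Z3plus")

#: pseudocounts (raw-count scale) guarding the density ratio in decoy-free
#: cells; kept well below one count so they regularize only genuinely empty
#: neighbourhoods instead of capping the ratio in clean high-score cells
DEFAULT_EPS0 = 0.05
DEFAULT_EPS1 = 0.05
#: pi1/pi0 guard: at least one decoy in the denominator, ratio capped
PI_RATIO_CAP = 1e6
#: below this stratum size the 3D histogram becomes unreliable
DEFAULT_MIN_PSM_WARNING = 100_000


class SmallStratumWarning(UserWarning):
    """A charge stratum holds too few PSMs for a stable 3D histogram."""


class DegenerateScoreError(ValueError):
    """All scores identical in one dimension; the grid cannot be built."""


def _stratum_of(charge: int) -> str:
    if charge <= 1:
        return "Z1"
    if charge == 2:
        return "Z2"
    return "Z3plus"


def stratify_by_charge(psms: PsmTable | list[PsmRecord]) -> dict[str, list[PsmRecord]]:
    """Partition PSMs into charge strata Z=1, Z=2, Z>=3 (exhaustive, disjoint)."""
    rows = psms.rows if isinstance(psms, PsmTable) else list(psms)
    out: dict[str, list[PsmRecord]] = {s: [] for s in STRATA}
    for r in rows:
        out[_stratum_of(r.charge)].append(r)
    return out


def _score_matrix(psms: list[PsmRecord], score_dims: int) -> np.ndarray:
    if score_dims == 3:
        return np.column_stack(
            [
                np.fromiter((r.xcorr for r in psms), float, len(psms)),
                np.fromiter((r.delta_cn for r in psms), float, len(psms)),
                np.fromiter((r.sp_score for r in psms), float, len(psms)),
            ]
        )
    if score_dims == 1:
        return np.fromiter((r.xcorr for r in psms), float, len(psms)).reshape(-1, 1)
    raise ValueError(f"score_dims must be 1 or 3, got {score_dims}")


def _box_mean(array: np.ndarray, window: int) -> np.ndarray:
    """Mean over a centred window box, clipped at the grid borders.

    Border cells average over their existing neighbours only (no zero
    padding mass), so a constant array is left unchanged.
    """
    num = ndimage.uniform_filter(array, size=window, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(np.ones_like(array), size=window, mode="constant", cval=0.0)
    return num / den


@dataclass(slots=True)
class ScoreGrid:
    """Per-charge-stratum histogram over the score space with density ratios."""

    charge_stratum: str
    bins_per_dim: int
    edges: list[np.ndarray]
    n0: np.ndarray  # smoothed wrong-hit counts
    n1: np.ndarray  # smoothed true-hit counts, floored at 0
    p0: np.ndarray  # n0 normalised to sum 1
    p1: np.ndarray  # n1 normalised to sum 1
    gamma: np.ndarray
    n_psms: int = 0

    @property
    def score_dims(self) -> int:
        return len(self.edges)

    def cell_index(self, scores: np.ndarray) -> tuple[np.ndarray, ...]:
        """Cell index per row of ``scores``; upper-edge values go to the last bin."""
        scores = np.atleast_2d(scores)
        idx = []
        for d, edges in enumerate(self.edges):
            i = np.searchsorted(edges, scores[:, d], side="right") - 1
            idx.append(np.clip(i, 0, self.bins_per_dim - 1))
        return tuple(idx)

    def gamma_at(self, scores: np.ndarray) -> np.ndarray:
        return self.gamma[self.cell_index(scores)]


def build_score_grid(
    psms: list[PsmRecord],
    bins: int = 40,
    smooth: bool = True,
    window: int = 3,
    score_dims: int = 3,
    eps0: float = DEFAULT_EPS0,
    eps1: float = DEFAULT_EPS1,
    charge_stratum: str = "",
) -> ScoreGrid:
    """Build the target/decoy histogram and density ratio for one stratum.

    Per cell, ``n0`` is the decoy count and ``n1`` the target count minus
    ``n0``; with ``smooth`` both are averaged over the ``window``-wide
    neighbourhood box (border-clipped) before ``n1`` is floored at zero.
    The arrays are normalised to probability estimates and the ratio

        gamma = ((n1 + eps1) / sum(n1)) / ((n0 + eps0) / sum(n0))

    is guarded by pseudocounts so that decoy-free cells stay finite.
    """
    if not psms:
        raise ValueError("cannot build a score grid from zero PSMs")
    X = _score_matrix(psms, score_dims)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite scores in PSM list")
    is_decoy = np.fromiter((r.is_decoy for r in psms), bool, len(psms))
    return build_score_grid_arrays(
        X, is_decoy, bins=bins, smooth=smooth, window=window,
        eps0=eps0, eps1=eps1, charge_stratum=charge_stratum,
    )


def build_score_grid_arrays(
    scores: np.ndarray,
    is_decoy: np.ndarray,
    bins: int = 40,
    smooth: bool = True,
    window: int = 3,
    eps0: float = DEFAULT_EPS0,
    eps1: float = DEFAULT_EPS1,
    charge_stratum: str = "",
) -> ScoreGrid:
    """Array-level grid construction (see :func:`build_score_grid`)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    is_decoy = np.asarray(is_decoy, dtype=bool)
    ndim = scores.shape[1]
    edges: list[np.ndarray] = []
    for d in range(ndim):
        lo, hi = scores[:, d].min(), scores[:, d].max()
        if lo == hi:
            raise DegenerateScoreError(
                f"all values identical in score dimension {d} "
                f"({'xcorr/delta_cn/sp_score'.split('/')[d] if ndim == 3 else 'xcorr'}); "
                "consider 1D mode (score_dims=1)"
            )
        edges.append(np.linspace(lo, hi, bins + 1))
    shape = (bins,) * ndim
    idx = tuple(
        np.clip(np.searchsorted(edges[d], scores[:, d], side="right") - 1, 0, bins - 1)
        for d in range(ndim)
    )
    flat = np.ravel_multi_index(idx, shape)
    n0_raw = np.bincount(flat[is_decoy], minlength=bins**ndim).astype(float).reshape(shape)
    t_raw = np.bincount(flat[~is_decoy], minlength=bins**ndim).astype(float).reshape(shape)
    diff = t_raw - n0_raw
    if smooth:
        n0_s = _box_mean(n0_raw, window)
        n1_s = np.maximum(_box_mean(diff, window), 0.0)
        # box-mean output is on a counts/window^d scale; express the
        # half-count pseudo-observations on the same scale
        eps0 = eps0 / window**ndim
        eps1 = eps1 / window**ndim
    else:
        n0_s = n0_raw
        n1_s = np.maximum(diff, 0.0)
    total0 = n0_s.sum()
    total1 = n1_s.sum()
    p0 = n0_s / total0 if total0 > 0 else np.zeros_like(n0_s)
    p1 = n1_s / total1 if total1 > 0 else np.zeros_like(n1_s)
    gamma = ((n1_s + eps1) / max(total1, 1.0)) / ((n0_s + eps0) / max(total0, 1.0))
    return ScoreGrid(
        charge_stratum=charge_stratum,
        bins_per_dim=bins,
        edges=edges,
        n0=n0_s,
        n1=n1_s,
        p0=p0,
        p1=p1,
        gamma=gamma,
        n_psms=len(scores),
    )


def lfdr(gamma_value, pi_ratio):
    """Local FDR of a score cell: ``(1 + pi_ratio * gamma) ** -1``.

    Accepts scalars or arrays; the result lies in (0, 1].  ``gamma`` is the
    true/wrong density ratio of the cell and ``pi_ratio`` the prior odds
    pi1/pi0 of the PSM's group.
    """
    gamma_value = np.asarray(gamma_value, dtype=float)
    if np.any(gamma_value < 0):
        raise ValueError("gamma must be >= 0")
    if np.any(np.asarray(pi_ratio) < 0):
        raise ValueError("pi_ratio must be >= 0")
    out = 1.0 / (1.0 + pi_ratio * gamma_value)
    return float(out) if out.ndim == 0 else out


@dataclass(slots=True)
class GroupPriors:
    """Target/decoy counts and prior odds pi1/pi0 for one PSM group."""

    group: Group
    n_targets: int
    n_decoys: int
    pi_ratio: float


def estimate_group_priors(
    psms: list[PsmRecord],
    group: Group | str | None = None,
    cap: float = PI_RATIO_CAP,
) -> GroupPriors:
    """Estimate pi1/pi0 for one group from target and decoy counts.

    ``pi_ratio = max(T - D, 0) / max(D, 1)`` where T and D are the group's
    target and decoy PSM counts: decoys estimate the number of wrong target
    matches, so the excess of targets over decoys estimates the true
    matches.  A decoy-free group yields a capped ratio with a warning.
    """
    if group is not None:
        group = Group(group)
        members = [r for r in psms if r.group == group]
    else:
        members = list(psms)
    if not members:
        raise ValueError(
            f"no PSMs in group {group}; use one_group mode for sparse datasets"
        )
    n_decoys = sum(r.is_decoy for r in members)
    n_targets = len(members) - n_decoys
    ratio = max(n_targets - n_decoys, 0) / max(n_decoys, 1)
    if n_decoys == 0:
        warnings.warn(
            f"group {group}: no decoy PSMs, pi1/pi0 is unreliable", SmallStratumWarning
        )
    ratio = min(ratio, cap)
    return GroupPriors(
        group=group if group is not None else Group.unassigned,
        n_targets=n_targets,
        n_decoys=n_decoys,
        pi_ratio=ratio,
    )


def _select(lfdr_values: np.ndarray, alpha: float) -> tuple[float, float]:
    """Largest lFDR threshold whose running mean stays within ``alpha``.

    Returns (threshold, achieved estimate); a NaN threshold means nothing
    passes.  Ties are resolved on whole cells: the running mean is
    evaluated at the last occurrence of each distinct lFDR value, so the
    accepted set {lfdr <= threshold} is exactly the evaluated prefix.
    """
    if len(lfdr_values) == 0:
        return float("nan"), float("nan")
    order = np.sort(lfdr_values)
    cummean = np.cumsum(order) / np.arange(1, len(order) + 1)
    # last index of each distinct value
    last = np.nonzero(np.diff(order, append=np.inf) != 0)[0]
    ok = last[cummean[last] <= alpha]
    if len(ok) == 0:
        return float("nan"), float("nan")
    k = ok[-1]
    return float(order[k]), float(cummean[k])


@dataclass(slots=True)
class LfdrResult:
    """Per-PSM lFDR values and the acceptance decision.

    ``lfdr`` and ``accepted`` align with ``psms`` (original order); decoy
    PSMs carry diagnostic lFDR values but are never accepted.  Thresholds
    and achieved-FDR estimates are per group in two-group mode, under the
    key ``"all"`` otherwise.  ``decoy_fdr_estimate`` is the classical
    decoy-counting cross-check (#decoys passing / #targets passing).
    """

    psms: list[PsmRecord]
    lfdr: np.ndarray
    accepted: np.ndarray
    thresholds: dict[str, float]
    nominal_fdr: float
    achieved_fdr_estimate: dict[str, float]
    decoy_fdr_estimate: dict[str, float] = field(default_factory=dict)
    mode: str = "two_group_d3"
    priors: dict[str, GroupPriors] = field(default_factory=dict)

    @property
    def accepted_psms(self) -> list[PsmRecord]:
        return [r for r, a in zip(self.psms, self.accepted) if a]

    def accepted_in_group(self, group: Group | str) -> list[PsmRecord]:
        group = Group(group)
        return [r for r in self.accepted_psms if r.group == group]


def select_threshold(
    psms: list[PsmRecord], lfdr_values: np.ndarray, alpha: float = 0.03
) -> LfdrResult:
    """Threshold a single pooled PSM population at global FDR ``alpha``.

    Target PSMs are sorted by lFDR; the threshold is the largest lFDR whose
    running mean (the global-FDR estimate of the accepted list) stays at or
    below ``alpha``.  Decoys never enter the accepted set.  An alpha no PSM
    satisfies yields an empty acceptance with a warning, not an error.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    lfdr_values = np.asarray(lfdr_values, dtype=float)
    is_decoy = np.fromiter((r.is_decoy for r in psms), bool, len(psms))
    threshold, achieved = _select(lfdr_values[~is_decoy], alpha)
    if np.isnan(threshold):
        warnings.warn("no PSM satisfies the requested global FDR", UserWarning)
        accepted = np.zeros(len(psms), dtype=bool)
    else:
        accepted = (lfdr_values <= threshold) & ~is_decoy
    n_acc = int(accepted.sum())
    n_dec = int(((lfdr_values <= threshold) & is_decoy).sum()) if not np.isnan(threshold) else 0
    return LfdrResult(
        psms=list(psms),
        lfdr=lfdr_values,
        accepted=accepted,
        thresholds={"all": threshold},
        nominal_fdr=alpha,
        achieved_fdr_estimate={"all": achieved},
        decoy_fdr_estimate={"all": n_dec / n_acc if n_acc else float("nan")},
        mode="one_group",
    )


def run_newance_fdr(
    psms: PsmTable | list[PsmRecord],
    grouping: str = "two_group",
    score_dims: int = 3,
    alpha: float = 0.03,
    bins: int = 40,
    smooth: bool = True,
    window: int = 3,
    eps0: float = DEFAULT_EPS0,
    eps1: float = DEFAULT_EPS1,
    min_psm_warning: int = DEFAULT_MIN_PSM_WARNING,
) -> LfdrResult:
    """Composite lFDR pipeline over all charge strata.

    Per stratum a :class:`ScoreGrid` is built from *all* PSMs (targets and
    decoys of both groups — the density ratio gamma is assumed shared), and
    each PSM receives the gamma of its cell.  In ``two_group`` mode the
    prior odds pi1/pi0 and the acceptance threshold are computed separately
    for proteome and non-canonical PSMs (pooled across strata); in
    ``one_group`` mode a single prior and threshold apply to everything.

    ``score_dims=3`` uses (XCorr, deltaCn, spScore); ``score_dims=1`` is
    the XCorr-only comparison mode on the same machinery.
    """
    rows = psms.rows if isinstance(psms, PsmTable) else list(psms)
    if grouping not in {"one_group", "two_group"}:
        raise ValueError(f"unknown grouping {grouping!r}")
    if not rows:
        raise ValueError("no PSMs")
    if grouping == "two_group" and any(r.group == Group.unassigned for r in rows):
        raise ValueError("two_group mode requires every PSM to carry a group label")

    strata = stratify_by_charge(rows)
    index_of = {id(r): i for i, r in enumerate(rows)}
    gamma_all = np.full(len(rows), np.nan)
    grids: dict[str, ScoreGrid] = {}
    for stratum, members in strata.items():
        if not members:
            continue
        if len(members) < min_psm_warning:
            warnings.warn(
                f"stratum {stratum}: only {len(members)} PSMs; the histogram "
                "density estimates may be unstable",
                SmallStratumWarning,
            )
        grid = build_score_grid(
            members, bins=bins, smooth=smooth, window=window,
            score_dims=score_dims, eps0=eps0, eps1=eps1, charge_stratum=stratum,
        )
        grids[stratum] = grid
        g = grid.gamma_at(_score_matrix(members, score_dims))
        for r, value in zip(members, g):
            gamma_all[index_of[id(r)]] = value

    is_decoy = np.fromiter((r.is_decoy for r in rows), bool, len(rows))
    lfdr_all = np.full(len(rows), np.nan)
    accepted = np.zeros(len(rows), dtype=bool)
    thresholds: dict[str, float] = {}
    achieved: dict[str, float] = {}
    decoy_est: dict[str, float] = {}
    priors: dict[str, GroupPriors] = {}

    if grouping == "two_group":
        group_masks = {
            g.value: np.fromiter((r.group == g for r in rows), bool, len(rows))
            for g in (Group.proteome, Group.noncanonical)
        }
    else:
        group_masks = {"all": np.ones(len(rows), dtype=bool)}

    for name, mask in group_masks.items():
        if not mask.any():
            raise ValueError(f"no PSMs in group {name!r}; use one_group mode")
        pri = estimate_group_priors([r for r, m in zip(rows, mask) if m])
        priors[name] = pri
        lfdr_all[mask] = lfdr(gamma_all[mask], pri.pi_ratio)
        thr, ach = _select(lfdr_all[mask & ~is_decoy], alpha)
        thresholds[name] = thr
        achieved[name] = ach
        if np.isnan(thr):
            warnings.warn(f"group {name!r}: no PSM satisfies alpha={alpha}", UserWarning)
            continue
        acc = mask & ~is_decoy & (lfdr_all <= thr)
        accepted |= acc
        n_acc = int(acc.sum())
        n_dec = int((mask & is_decoy & (lfdr_all <= thr)).sum())
        decoy_est[name] = n_dec / n_acc if n_acc else float("nan")

    return LfdrResult(
        psms=rows,
        lfdr=lfdr_all,
        accepted=accepted,
        thresholds=thresholds,
        nominal_fdr=alpha,
        achieved_fdr_estimate=achieved,
        decoy_fdr_estimate=decoy_est,
        mode=f"{grouping}_d{score_dims}",
        priors=priors,
    )
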