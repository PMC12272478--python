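"""Voxel-wise two-group inference on dose-surface maps.

The statistical contract: for each of the 8190 map voxels, compare surface
dose between event and non-event patients with Welch's unequal-variance
t-statistic

    t = (X1 - X2) / sqrt(S1^2/N1 + S2^2/N2)

(positive t means events received higher dose), then control the family-wise
error rate with a permutation Tmax procedure: outcome labels are reshuffled
(preserving the observed event count), the statistic map recomputed, and the
95th nearest-rank percentile of the per-permutation maxima is the
significance threshold.  A rank-based alternative (standardized Mann-Whitney
U) plugs into the same machinery.  Overlap between significance masks is
quantified by the Dice similarity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .conventions import DegenerateGroupsError
from .geometry import DoseSurfaceMap

__all__ = [
    "TMap",
    "PermutationResult",
    "DSCResult",
    "ShapiroScreen",
    "stack_maps",
    "welch_tmap",
    "mannwhitney_map",
    "shapiro_screen",
    "permutation_tmax",
    "dsc",
    "count_significant",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TMap:
    """Voxel-wise statistic map (NaN outside the valid mask)."""

    t: np.ndarray
    n_event: int
    n_nonevent: int
    valid: np.ndarray
    statistic: str = "welch"
    u_raw: np.ndarray | None = None   # event-group Mann-Whitney U, if rank-based

    def __post_init__(self) -> None:
        if self.n_event < 2 or self.n_nonevent < 2:
            raise DegenerateGroupsError("both groups need >= 2 patients")
        if not np.all(np.isfinite(self.t[self.valid])):
            raise ValueError("statistic must be finite on valid voxels")


@dataclass(frozen=True)
class PermutationResult:
    observed: TMap
    tmax_samples: np.ndarray          # per-permutation map maxima
    tmin_samples: np.ndarray          # per-permutation map minima
    threshold_upper: float
    threshold_lower: float | None
    sig_mask_high: np.ndarray
    sig_mask_low: np.ndarray
    n_iterations: int
    percentile: float
    seed: int
    tails: str

    @property
    def sig_mask(self) -> np.ndarray:
        """Union of the enabled tails' significance masks."""
        return self.sig_mask_high | self.sig_mask_low


@dataclass(frozen=True)
class DSCResult:
    dsc: float
    n_a: int
    n_b: int
    n_intersection: int


@dataclass(frozen=True)
class ShapiroScreen:
    p_values: np.ndarray        # NaN where non-analysable
    non_normal: np.ndarray      # bool, p < alpha
    analysable: np.ndarray      # bool
    failing_fraction: float
    alpha: float


# --------------------------------------------------------------------------
# map stacking
# --------------------------------------------------------------------------

def stack_maps(maps: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Stack DSMs (or plain 2D arrays) into (n_patients, rows, cols) plus the
    common validity mask (AND over patients)."""
    if len(maps) == 0:
        raise ValueError("empty map collection")
    arrs, valids = [], []
    for m in maps:
        if isinstance(m, DoseSurfaceMap):
            arrs.append(m.doses)
            valids.append(m.valid)
        else:
            a = np.asarray(m, dtype=float)
            arrs.append(a)
            valids.append(np.isfinite(a))
    X = np.stack(arrs)
    valid = np.logical_and.reduce(np.stack(valids))
    return X, valid


def _as_matrix(event, nonevent):
    Xe, ve = stack_maps(event)
    Xn, vn = stack_maps(nonevent)
    if Xe.shape[1:] != Xn.shape[1:]:
        raise ValueError("event / non-event map shapes differ")
    if Xe.shape[0] < 2 or Xn.shape[0] < 2:
        raise DegenerateGroupsError("both groups need >= 2 patients")
    valid = ve & vn
    if not valid.any():
        raise DegenerateGroupsError("no voxel is valid in both groups")
    return Xe, Xn, valid


# --------------------------------------------------------------------------
# Welch t
# --------------------------------------------------------------------------

def _welch_from_groups(xe: np.ndarray, xn: np.ndarray) -> np.ndarray:
    """Welch t per column of two (n_i, V) matrices; NaN where the pooled
    denominator vanishes."""
    n1, n2 = xe.shape[0], xn.shape[0]
    m1, m2 = xe.mean(0), xn.mean(0)
    v1 = xe.var(0, ddof=1)
    v2 = xn.var(0, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom > 0, t, np.nan)


def welch_tmap(event, nonevent) -> TMap:
    """Voxel-wise Welch t-map; positive t means events got higher dose.

    Voxels whose pooled denominator is zero (dose constant across all
    patients) are removed from the valid mask rather than epsilon-padded.
    """
    Xe, Xn, valid = _as_matrix(event, nonevent)
    shape = Xe.shape[1:]
    t = _welch_from_groups(Xe.reshape(Xe.shape[0], -1),
                           Xn.reshape(Xn.shape[0], -1)).reshape(shape)
    valid = valid & np.isfinite(t)
    t = np.where(valid, t, np.nan)
    return TMap(t=t, n_event=Xe.shape[0], n_nonevent=Xn.shape[0],
                valid=valid, statistic="welch")


def _batch_welch(X: np.ndarray, X2: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Welch t for a batch of label vectors.

    X, X2: (n, V) data and element-wise squares; labels: (B, n) in {0,1} with
    a constant row sum.  Returns (B, V).
    """
    n = X.shape[0]
    n1 = int(labels[0].sum())
    n2 = n - n1
    L = labels.astype(float)
    s1 = L @ X
    q1 = L @ X2
    s2 = X.sum(0) - s1
    q2 = X2.sum(0) - q1
    m1 = s1 / n1
    m2 = s2 / n2
    v1 = (q1 - n1 * m1 ** 2) / (n1 - 1)
    v2 = (q2 - n2 * m2 ** 2) / (n2 - 1)
    denom = np.sqrt(np.maximum(v1, 0) / n1 + np.maximum(v2, 0) / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom > 0, t, np.nan)


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------

def _rank_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks per column plus the tie-corrected null variance factor."""
    n = X.shape[0]
    R = stats.rankdata(X, axis=0)
    # tie correction: sum of (t^3 - t) over tie groups, per column
    tie_term = np.zeros(X.shape[1])
    Xs = np.sort(X, axis=0)
    for j in range(X.shape[1]):
        _, counts = np.unique(Xs[:, j], return_counts=True)
        tie_term[j] = np.sum(counts.astype(float) ** 3 - counts)
    return R, tie_term


def _u_stats(R: np.ndarray, tie_term: np.ndarray, labels: np.ndarray):
    """Raw event-group U and its standardized form for label batch (B, n)."""
    n = R.shape[0]
    n1 = int(labels[0].sum())
    n2 = n - n1
    rank_sum = labels.astype(float) @ R          # (B, V)
    u1 = rank_sum - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mean) / np.sqrt(var)
    z = np.where(var > 0, z, np.nan)
    return u1, z


def mannwhitney_map(event, nonevent) -> TMap:
    """Voxel-wise rank-sum map: raw event-group U plus standardized U (z),
    so the same Tmax machinery applies as for Welch t."""
    Xe, Xn, valid = _as_matrix(event, nonevent)
    shape = Xe.shape[1:]
    X = np.vstack([Xe, Xn]).reshape(Xe.shape[0] + Xn.shape[0], -1)
    labels = np.zeros((1, X.shape[0]))
    labels[0, :Xe.shape[0]] = 1
    R, tie = _rank_matrix(X)
    u1, z = _u_stats(R, tie, labels)
    u1 = u1.reshape(shape)
    z = z.reshape(shape)
    valid = valid & np.isfinite(z)
    return TMap(t=np.where(valid, z, np.nan), n_event=Xe.shape[0],
                n_nonevent=Xn.shape[0], valid=valid, statistic="mannwhitney",
                u_raw=np.where(valid, u1, np.nan))


# --------------------------------------------------------------------------
# normality screen
# --------------------------------------------------------------------------

def shapiro_screen(group, alpha: float = 0.05) -> ShapiroScreen:
    """Per-voxel Shapiro-Wilk normality screen for one group.

    Constant voxels are flagged non-analysable (the test is undefined at zero
    variance).  The summary is the fraction of analysable voxels failing at
    ``alpha``; the screen is reported, never used to gate the t-map.
    """
    X, valid = stack_maps(group)
    if X.shape[0] < 3:
        raise DegenerateGroupsError("Shapiro-Wilk screen needs >= 3 patients")
    shape = X.shape[1:]
    flat = X.reshape(X.shape[0], -1)
    vflat = valid.ravel()
    p = np.full(flat.shape[1], np.nan)
    analysable = vflat & (flat.std(0) > 0)
    for j in np.flatnonzero(analysable):
        p[j] = stats.shapiro(flat[:, j]).pvalue
    non_normal = (p < alpha) & analysable
    frac = float(non_normal.sum() / analysable.sum()) if analysable.any() else float("nan")
    return ShapiroScreen(p_values=p.reshape(shape),
                         non_normal=non_normal.reshape(shape),
                         analysable=analysable.reshape(shape),
                         failing_fraction=frac, alpha=alpha)


# --------------------------------------------------------------------------
# permutation Tmax
# --------------------------------------------------------------------------

def _nearest_rank(sorted_asc: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile of an ascending sample (950th of 1000 at 95)."""
    n = len(sorted_asc)
    k = int(np.ceil(percentile / 100.0 * n))
    k = min(max(k, 1), n)
    return float(sorted_asc[k - 1])


def permutation_tmax(maps, labels, statistic: str = "welch",
                     n_iterations: int = 1000, percentile: float = 95.0,
                     seed: int = 0, tails: str = "both",
                     chunk: int = 250) -> PermutationResult:
    """Permutation Tmax family-wise significance thresholds for a voxel map.

    ``maps`` is a sequence of DSMs (or 2D arrays) and ``labels`` the matching
    0/1 event labels (ints or :class:`~drmap.toxicity.OutcomeLabel`).  Each
    permutation reshuffles the labels without replacement (preserving the
    observed event count), recomputes the statistic map and records its
    maximum (Tmax) and minimum (Tmin) over valid voxels.  The upper threshold
    is the nearest-rank ``percentile`` of the Tmax sample; with
    ``tails="both"`` a lower threshold is taken symmetrically from the Tmin
    sample at ``100 - percentile``.  Fully reproducible under ``seed``.
    """
    if statistic not in ("welch", "mannwhitney"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if tails not in ("upper", "lower", "both"):
        raise ValueError(f"unknown tails {tails!r}")
    if n_iterations < 100:
        raise ValueError("need at least 100 permutations")

    lab = np.array([getattr(l, "event", l) for l in labels], dtype=int)
    if set(np.unique(lab)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    X_full, valid = stack_maps(maps)
    if len(lab) != X_full.shape[0]:
        raise ValueError("need one label per map")
    n1 = int(lab.sum())
    n2 = len(lab) - n1
    if n1 < 2 or n2 < 2:
        raise DegenerateGroupsError("both observed groups need >= 2 patients")

    shape = X_full.shape[1:]
    # observed map (also fixes the final valid mask: constant voxels drop out)
    ev = [x for x, l in zip(X_full, lab) if l == 1]
    nv = [x for x, l in zip(X_full, lab) if l == 0]
    observed = welch_tmap(ev, nv) if statistic == "welch" else mannwhitney_map(ev, nv)
    valid = observed.valid & valid

    cols = valid.ravel()
    X = X_full.reshape(X_full.shape[0], -1)[:, cols]
    if statistic == "welch":
        X2 = X ** 2
        stat_fn = lambda L: _batch_welch(X, X2, L)
    else:
        R, tie = _rank_matrix(X)
        stat_fn = lambda L: _u_stats(R, tie, L)[1]

    rng = np.random.default_rng(seed)
    tmax = np.empty(n_iterations)
    tmin = np.empty(n_iterations)
    done = 0
    while done < n_iterations:
        b = min(chunk, n_iterations - done)
        L = rng.permuted(np.broadcast_to(lab, (b, len(lab))).copy(), axis=1)
        T = stat_fn(L)
        tmax[done:done + b] = np.nanmax(T, axis=1)
        tmin[done:done + b] = np.nanmin(T, axis=1)
        done += b

    thr_up = _nearest_rank(np.sort(tmax), percentile)
    thr_lo = _nearest_rank(np.sort(tmin), 100.0 - percentile)

    obs = observed.t
    sig_high = np.zeros(shape, dtype=bool)
    sig_low = np.zeros(shape, dtype=bool)
    if tails in ("upper", "both"):
        sig_high = valid & (obs >= thr_up)
    if tails in ("lower", "both"):
        sig_low = valid & (obs <= thr_lo)
    return PermutationResult(
        observed=observed, tmax_samples=tmax, tmin_samples=tmin,
        threshold_upper=thr_up,
        threshold_lower=thr_lo if tails in ("lower", "both") else None,
        sig_mask_high=sig_high, sig_mask_low=sig_low,
        n_iterations=n_iterations, percentile=percentile, seed=seed,
        tails=tails)


# --------------------------------------------------------------------------
# mask comparison
# --------------------------------------------------------------------------

def dsc(mask_a: np.ndarray, mask_b: np.ndarray) -> DSCResult:
    """Dice similarity coefficient 2|A&B| / (|A| + |B|) of two binary masks.

    Defined as 0.0 when both masks are empty (matching the reporting
    convention DSC = 0 whenever one method finds no voxels).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    n_a, n_b = int(a.sum()), int(b.sum())
    n_i = int((a & b).sum())
    value = 2.0 * n_i / (n_a + n_b) if (n_a + n_b) > 0 else 0.0
    return DSCResult(dsc=value, n_a=n_a, n_b=n_b, n_intersection=n_i)


def count_significant(mask: np.ndarray) -> int:
    """Number of significant voxels in a binary mask."""
    return int(np.asarray(mask, dtype=bool).sum())
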