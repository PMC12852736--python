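"""Shared statistical primitives: t-tests, Bonferroni, Fisher-z group inference.

All group tests in this package are two-sided one-sample (or paired) t-tests;
multiple-comparison families use plain Bonferroni with the family size the
analysis defines (5 peak contrasts, 3 model-profile pairs, one per sphere for
along-vector profiles, 6 index-activation categories).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "bonferroni_threshold",
    "bonferroni_adjust",
    "fisher_z",
    "one_sample_t",
    "paired_t",
    "permutation_p",
    "GroupCorrelationStat",
    "group_profile_correlation",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold for a family of ``m`` tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return alpha / m


def bonferroni_adjust(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Bonferroni-adjusted p-values, clipped at 1."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform, with r clipped away from +/-1 for finiteness."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-12, 1 - 1e-12)
    return np.arctanh(r)


def one_sample_t(x: np.ndarray, axis: int = 0, popmean: float = 0.0):
    """Two-sided one-sample t-test along ``axis``.

    Returns ``(t, df, p)``; voxels/cells with zero variance yield NaN t and p
    rather than raising, so callers can flag them explicitly.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 2:
        raise ValueError("one-sample t-test needs at least 2 observations")
    mean = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, (mean - popmean) / (sd / np.sqrt(n)), np.nan)
    p = 2 * sps.t.sf(np.abs(t), df)
    return t, df, p


def paired_t(a: np.ndarray, b: np.ndarray, axis: int = 0):
    """Two-sided paired t-test (difference ``a - b``) along ``axis``."""
    return one_sample_t(np.asarray(a, float) - np.asarray(b, float), axis=axis)


def permutation_p(count_at_least_as_extreme: int, n_perm: int) -> float:
    """One-sided permutation p with the minimum resolvable value 1/n_perm."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    return max(int(count_at_least_as_extreme), 1) / n_perm


@dataclass(frozen=True)
class GroupCorrelationStat:
    """Group-level inference on per-subject correlation coefficients.

    The per-subject Pearson r values are Fisher-z transformed and tested
    against zero with a two-sided one-sample t-test; ``p_bonferroni`` applies
    the family size ``m`` the caller declared.
    """

    per_subject_r: np.ndarray
    mean_r: float
    t: float
    df: int
    p: float
    m: int
    p_bonferroni: float
    significant: bool


def group_profile_correlation(
    a: np.ndarray,
    b: np.ndarray,
    *,
    valid: np.ndarray | None = None,
    m: int = 1,
    alpha: float = 0.05,
) -> GroupCorrelationStat:
    """Correlate two per-subject profiles across positions, then test the group.

    ``a`` and ``b`` are (n_subjects, n_positions) arrays (e.g., two models'
    RSA fits along the vector-of-ROIs, or an index profile and an activation
    profile). Positions flagged invalid (``valid`` False, or NaN in either
    profile) are pairwise-deleted; fewer than 3 shared positions is an error.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("profiles must be matching (n_subjects, n_positions) arrays")
    if a.shape[0] < 2:
        raise ValueError("group profile correlation needs >= 2 subjects")
    keep = np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
    if valid is not None:
        keep &= np.asarray(valid, bool)
    if keep.sum() < 3:
        raise ValueError(
            f"only {int(keep.sum())} shared valid positions; need at least 3"
        )
    aa, bb = a[:, keep], b[:, keep]
    az = aa - aa.mean(axis=1, keepdims=True)
    bz = bb - bb.mean(axis=1, keepdims=True)
    denom = np.sqrt((az**2).sum(axis=1) * (bz**2).sum(axis=1))
    if np.any(denom == 0):
        raise ValueError("a subject profile has zero variance across positions")
    r = (az * bz).sum(axis=1) / denom
    t, df, p = one_sample_t(fisher_z(r))
    p_b = float(bonferroni_adjust(p, m))
    return GroupCorrelationStat(
        per_subject_r=r,
        mean_r=float(r.mean()),
        t=float(t),
        df=int(df),
        p=float(p),
        m=m,
        p_bonferroni=p_b,
        significant=bool(p_b < alpha),
    )
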