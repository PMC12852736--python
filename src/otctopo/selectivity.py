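"""Category-selectivity maps, cluster-level correction, and cluster overlap.

The category contrast at each voxel is (beta for the category) minus (mean
beta of the other five categories), tested with a one-sample t across runs
(single subject, df = n_runs - 1) or across subjects' run-averaged contrasts
(group, df = n_subjects - 1). Suprathreshold voxels are grouped into
connected components (18-neighbour by default); cluster-level correction is
nonparametric: a sign-flip permutation null of the maximum cluster size gives
each observed cluster a p-value, and Benjamini-Hochberg controls the FDR
across clusters. The pairwise overlap index between two categories' surviving
clusters is |A ∩ B| / min(|A|, |B|): 0 for disjoint clusters, 1 when the
smaller cluster is nested inside the larger.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stats import permutation_p
from .synthgen import CATEGORIES, SubjectBetas

__all__ = [
    "TMap",
    "ClusterSet",
    "EmptyClusterError",
    "compute_category_tmap",
    "compute_group_tmap",
    "threshold_and_cluster",
    "overlap_index",
    "overlap_table",
    "visual_mask",
]

logger = logging.getLogger(__name__)

_CONNECTIVITY_ORDER = {6: 1, 18: 2, 26: 3}


class EmptyClusterError(ValueError):
    """Overlap is undefined when a category has no surviving cluster.

    Kept distinct from an index of 0 so that "no significant activation"
    can be reported separately from "no overlap"."""


@dataclass(frozen=True)
class TMap:
    """Voxelwise t-statistics plus the observation-level contrast samples.

    ``samples`` ((n_obs, *grid): run-level contrasts for a single subject,
    subject-level run-averaged contrasts for a group map) are retained so
    cluster-level permutation inference can reuse the exact data the map was
    computed from. ``undefined`` flags zero-variance voxels (t is NaN there;
    they are excluded from thresholding, never silently dropped).
    """

    t: np.ndarray
    df: int
    contrast: str
    undefined: np.ndarray
    samples: np.ndarray
    level: str  # "run" | "subject"

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.t.shape


def _contrast_stack(subject: SubjectBetas, category: str) -> np.ndarray:
    """(n_runs, *grid) per-run contrast: category minus mean of the others."""
    j = subject.conditions.index(category)
    others = [k for k in range(len(subject.conditions)) if k != j]
    return subject.data[:, j] - subject.data[:, others].mean(axis=1)


def _t_from_samples(samples: np.ndarray):
    n = samples.shape[0]
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    undefined = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~undefined, mean / (sd / np.sqrt(n)), np.nan)
    return t, n - 1, undefined


def compute_category_tmap(subject: SubjectBetas, category: str) -> TMap:
    """One-sample t across runs of the category-vs-all contrast, per voxel."""
    if subject.n_runs < 2:
        raise ValueError("need at least 2 runs for a t-map")
    if category not in subject.conditions:
        raise ValueError(f"unknown category {category!r}")
    samples = _contrast_stack(subject, category)
    t, df, undefined = _t_from_samples(samples)
    if undefined.any():
        logger.info(
            "%s/%s: %d zero-variance voxels flagged undefined",
            subject.subject,
            category,
            int(undefined.sum()),
        )
    return TMap(
        t=t,
        df=df,
        contrast=f"{category} vs mean(others)",
        undefined=undefined,
        samples=samples,
        level="run",
    )


def compute_group_tmap(subjects: Sequence[SubjectBetas], category: str) -> TMap:
    """Group t-map: one-sample t across subjects' run-averaged contrasts.

    All subjects must share grid and affine (synthetic subjects do by
    construction)."""
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a group t-map")
    ref = subjects[0]
    for s in subjects[1:]:
        if s.grid_shape != ref.grid_shape or not np.allclose(s.affine, ref.affine):
            raise ValueError("subjects disagree on grid or affine")
    samples = np.stack(
        [_contrast_stack(s, category).mean(axis=0) for s in subjects]
    )
    t, df, undefined = _t_from_samples(samples)
    return TMap(
        t=t,
        df=df,
        contrast=f"{category} vs mean(others), group",
        undefined=undefined,
        samples=samples,
        level="subject",
    )


@dataclass(frozen=True)
class ClusterSet:
    """Surviving clusters of one category's thresholded t-map.

    ``labels`` is an integer grid with surviving clusters numbered 1..k in
    decreasing size order; membership, sizes, and the thresholds used are
    recorded. An empty set (no suprathreshold voxels, or none surviving the
    cluster criterion) is a valid value, not an error.
    """

    labels: np.ndarray
    sizes: tuple[int, ...]
    cluster_p: tuple[float, ...]
    category: str | None
    voxel_thresh_t: float
    cluster_alpha: float
    connectivity: int
    n_perm: int

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def voxel_indices(self) -> np.ndarray:
        """Flat (C-order) indices of all member voxels."""
        return np.flatnonzero(self.mask.ravel())


def _sign_patterns(n_obs: int, n_perm: int, rng: np.random.Generator):
    """All 2^n sign-flip patterns when feasible, else a random sample."""
    if 2**n_obs <= n_perm:
        k = 2**n_obs
        bits = ((np.arange(k)[:, None] >> np.arange(n_obs)) & 1) * 2 - 1
        return bits.astype(float), k, True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_obs))
    return signs, n_perm, False


def _max_cluster_sizes(
    suprathresh: np.ndarray, grid_shape, structure: np.ndarray
) -> np.ndarray:
    """Largest connected-component size per permutation (rows of a flat stack)."""
    out = np.empty(len(suprathresh), dtype=int)
    for i, flat in enumerate(suprathresh):
        if not flat.any():
            out[i] = 0
            continue
        lab, n = ndimage.label(flat.reshape(grid_shape), structure=structure)
        out[i] = np.bincount(lab.ravel())[1:].max() if n else 0
    return out


def threshold_and_cluster(
    tmap: TMap,
    voxel_p: float = 0.001,
    voxel_thresh_t: float | None = None,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    connectivity: int = 18,
    mask: np.ndarray | None = None,
    seed: int | np.random.Generator | None = 0,
) -> ClusterSet:
    """Voxel thresholding plus permutation cluster-size FDR correction.

    Voxels pass at ``t > voxel_thresh_t`` (or the one-sided t equivalent of
    ``voxel_p`` at the map's df). Connected components of passing voxels are
    assigned p-values against a sign-flip permutation null of the maximum
    cluster size (sign patterns fully enumerated when 2^n_obs <= n_perm), and
    Benjamini-Hochberg selects survivors at ``cluster_alpha``.
    """
    if connectivity not in _CONNECTIVITY_ORDER:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_ORDER)}")
    if n_perm < 1000:
        raise ValueError("cluster permutation null needs n_perm >= 1000")
    if voxel_thresh_t is None:
        if not 0 < voxel_p < 1:
            raise ValueError("voxel_p must be in (0, 1)")
        voxel_thresh_t = float(sps.t.isf(voxel_p, tmap.df))
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_ORDER[connectivity])
    analysis = np.ones(tmap.grid_shape, bool) if mask is None else np.asarray(mask, bool)
    analysis = analysis & ~tmap.undefined

    def _empty() -> ClusterSet:
        return ClusterSet(
            labels=np.zeros(tmap.grid_shape, int),
            sizes=(),
            cluster_p=(),
            category=tmap.contrast,
            voxel_thresh_t=voxel_thresh_t,
            cluster_alpha=cluster_alpha,
            connectivity=connectivity,
            n_perm=n_perm,
        )

    observed = (tmap.t > voxel_thresh_t) & analysis
    if not observed.any():
        return _empty()
    lab, n_clusters = ndimage.label(observed, structure=structure)
    sizes = np.bincount(lab.ravel())[1:]

    # permutation null of the maximum cluster size, via sign flips of the
    # observation-level contrast samples
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    flat_ok = analysis.ravel()
    S = tmap.samples.reshape(tmap.samples.shape[0], -1)[:, flat_ok]
    n_obs = S.shape[0]
    sumsq = (S**2).sum(axis=0)
    signs, n_total, _ = _sign_patterns(n_obs, n_perm, rng)
    max_sizes = np.empty(n_total, dtype=int)
    chunk = 256
    grid_flat_template = np.zeros(int(np.prod(tmap.grid_shape)), bool)
    for lo in range(0, n_total, chunk):
        sg = signs[lo : lo + chunk]
        mean = sg @ S / n_obs
        with np.errstate(divide="ignore", invalid="ignore"):
            var = np.maximum(sumsq - n_obs * mean**2, 0.0) / (n_obs - 1)
            t_perm = np.where(var > 0, mean / np.sqrt(var / n_obs), np.nan)
        supra = t_perm > voxel_thresh_t
        stack = np.repeat(grid_flat_template[None], len(sg), axis=0)
        stack[:, flat_ok] = supra
        max_sizes[lo : lo + chunk] = _max_cluster_sizes(
            stack, tmap.grid_shape, structure
        )
    pvals = np.array(
        [permutation_p(int((max_sizes >= s).sum()), n_total) for s in sizes]
    )
    reject, _, _, _ = multipletests(pvals, alpha=cluster_alpha, method="fdr_bh")
    if not reject.any():
        return _empty()
    keep = np.flatnonzero(reject)
    keep = keep[np.argsort(-sizes[keep], kind="stable")]
    labels = np.zeros(tmap.grid_shape, int)
    for new_id, old in enumerate(keep, start=1):
        labels[lab == old + 1] = new_id
    return ClusterSet(
        labels=labels,
        sizes=tuple(int(sizes[k]) for k in keep),
        cluster_p=tuple(float(pvals[k]) for k in keep),
        category=tmap.contrast,
        voxel_thresh_t=voxel_thresh_t,
        cluster_alpha=cluster_alpha,
        connectivity=connectivity,
        n_perm=n_total,
    )


def _as_mask(x) -> np.ndarray:
    if isinstance(x, ClusterSet):
        return x.mask
    return np.asarray(x, bool)


def overlap_index(a, b) -> float:
    """|A ∩ B| / min(|A|, |B|) between two categories' selective voxel sets.

    Symmetric; 1.0 iff the smaller set is contained in the larger. Raises
    :class:`EmptyClusterError` if either set is empty (the "no significant
    activation" case is reported separately, not as overlap 0).
    """
    ma, mb = _as_mask(a), _as_mask(b)
    if ma.shape != mb.shape:
        raise ValueError("cluster sets live on different grids")
    na, nb = int(ma.sum()), int(mb.sum())
    if na == 0 or nb == 0:
        raise EmptyClusterError("empty cluster: overlap index undefined")
    return int((ma & mb).sum()) / min(na, nb)


def overlap_table(cluster_sets: dict[str, ClusterSet]) -> pd.DataFrame:
    """Pairwise overlap indices for all category pairs with surviving clusters.

    Categories with empty cluster sets appear with NaN index (reported, not
    silently dropped)."""
    rows = []
    cats = list(cluster_sets)
    for i, ca in enumerate(cats):
        for cb in cats[i + 1 :]:
            a, b = cluster_sets[ca], cluster_sets[cb]
            na, nb = a.n_voxels, b.n_voxels
            common = int((a.mask & b.mask).sum())
            idx = common / min(na, nb) if na and nb else np.nan
            rows.append((ca, cb, idx, na, nb, common))
    return pd.DataFrame(
        rows,
        columns=[
            "category_a",
            "category_b",
            "overlap_index",
            "size_a",
            "size_b",
            "n_common",
        ],
    )


def visual_mask(
    subjects: SubjectBetas | Sequence[SubjectBetas],
    anatomical_mask: np.ndarray,
    baseline_p: float = 0.05,
) -> np.ndarray:
    """Visually responsive voxels: all-conditions-vs-baseline at a liberal p.

    Intersects the anatomical mask with voxels whose mean beta over all
    conditions is positive at one-sided p < ``baseline_p`` (one-sample t
    across runs for a single subject, across subjects for a group)."""
    if isinstance(subjects, SubjectBetas):
        samples = subjects.data.mean(axis=1)  # (runs, *grid)
    else:
        samples = np.stack([s.data.mean(axis=(0, 1)) for s in subjects])
    anatomical = np.asarray(anatomical_mask, bool)
    if anatomical.shape != samples.shape[1:]:
        raise ValueError("anatomical mask is not on the data grid")
    if not anatomical.any():
        return anatomical.copy()
    t, df, undefined = _t_from_samples(samples)
    thresh = sps.t.isf(baseline_p, df)
    out = anatomical & ~undefined & (t > thresh)
    if not out.any():
        warnings.warn("visual mask is empty at this baseline threshold")
    return out
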