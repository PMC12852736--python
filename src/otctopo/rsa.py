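"""Representational similarity analysis: RDMs, model fits, noise ceiling, MDS.

Neural RDMs are 6 x 6 Pearson correlation matrices of condition patterns
(voxels of one sphere, or units of one network layer). Three model RDMs
capture candidate organizing dimensions: *animacy* and *action* from
behavioural ratings (pairwise Euclidean distances of the 1-7 scores), and
*shape* from the stimulus images' aspect ratio P^2 / (4 pi A) (perimeter P,
area A of the binary object mask). Model-brain correspondence is the Pearson
correlation of the 15 lower-triangle entries, after converting neural
similarity to dissimilarity (1 - r). The noise-ceiling lower bound is the
mean leave-one-subject-out correlation between individual and group-average
RDMs. Classical (Torgerson) multidimensional scaling embeds a dissimilarity
RDM in the plane for inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import measure

from .stats import (
    GroupCorrelationStat,
    bonferroni_adjust,
    group_profile_correlation,
    one_sample_t,
)
from .synthgen import CATEGORIES

__all__ = [
    "RDM",
    "AspectRatioResult",
    "ModelFitProfile",
    "ZeroVariancePatternError",
    "neural_rdm",
    "sphere_rdms",
    "aspect_ratio",
    "aspect_ratio_result",
    "model_rdm_from_ratings",
    "model_rdm_from_shape",
    "rsa_correlate",
    "noise_ceiling_lower",
    "noise_ceiling_profile",
    "model_fit_profile",
    "model_profile_correlation",
    "model_rdm_correlations",
    "mds_embed",
]


class ZeroVariancePatternError(ValueError):
    """A condition's pattern has zero variance, so Pearson r is undefined."""


@dataclass(frozen=True)
class RDM:
    """A labelled square (dis)similarity matrix.

    ``kind`` is "similarity" (Pearson r, unit diagonal) or "dissimilarity"
    (non-negative, zero diagonal)."""

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self):
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if self.kind not in ("similarity", "dissimilarity"):
            raise ValueError(f"unknown RDM kind {self.kind!r}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if self.kind == "similarity":
            if not np.allclose(np.diag(v), 1.0, atol=1e-8):
                raise ValueError("similarity RDM must have unit diagonal")
        else:
            if not np.allclose(np.diag(v), 0.0, atol=1e-10):
                raise ValueError("dissimilarity RDM must have zero diagonal")
            if np.any(v < -1e-10):
                raise ValueError("dissimilarity RDM must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def lower_triangle(self) -> np.ndarray:
        """Off-diagonal lower-triangle entries (15 values for 6 labels)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def to_dissimilarity(self) -> "RDM":
        if self.kind == "dissimilarity":
            return self
        return RDM(
            labels=self.labels,
            values=1.0 - self.values + np.diag(np.diag(self.values) - 1.0),
            kind="dissimilarity",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def neural_rdm(patterns: np.ndarray, labels: Sequence[str] = CATEGORIES) -> RDM:
    """Pairwise Pearson correlation of condition patterns.

    ``patterns`` is (n_conditions, n_features) with at least 3 features;
    conditions with zero pattern variance are rejected by name.
    """
    x = np.asarray(patterns, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("patterns must be (n_conditions >= 2, n_features)")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 features per pattern")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ZeroVariancePatternError(
            f"zero-variance pattern for condition(s): {', '.join(map(str, bad))}"
        )
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    return RDM(labels=tuple(labels), values=r, kind="similarity")


def sphere_rdms(patterns, labels: Sequence[str] = CATEGORIES):
    """Neural RDMs for nested per-subject, per-sphere patterns.

    ``patterns[subject][sphere]`` is a (n_conditions, n_voxels) array or None
    (missing sphere, propagated as None).
    """
    return [
        [None if p is None else neural_rdm(p, labels) for p in subj]
        for subj in patterns
    ]


@dataclass(frozen=True)
class AspectRatioResult:
    perimeter_px: float
    area_px: float
    ratio: float


def aspect_ratio_result(
    mask: np.ndarray, multiple: str = "error", smooth_sigma: float = 1.0
) -> AspectRatioResult:
    """Aspect ratio P^2 / (4 pi A) of a binary object mask.

    Area is the foreground pixel count; perimeter is the marching-squares
    contour length of the mask after a light Gaussian pre-smoothing
    (``smooth_sigma`` px) that removes the rasterization staircase — a circle
    then scores ~1.0 as the isoperimetric identity requires. ``multiple``
    controls behaviour with several components: "error" rejects, "sum" totals
    perimeter and area over components before applying the formula.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be a 2-D image")
    area = float(m.sum())
    if area == 0:
        raise ValueError("empty mask")
    labels = measure.label(m, connectivity=2)
    n_comp = labels.max()
    if n_comp > 1 and multiple == "error":
        raise ValueError(f"mask has {n_comp} components, expected 1")
    img = m.astype(float)
    if smooth_sigma > 0:
        img = gaussian_filter(img, smooth_sigma)
    contours = measure.find_contours(img, 0.5)
    if not contours:
        raise ValueError("no 0.5-level contour found (mask too thin?)")
    if multiple == "sum" and n_comp > 1:
        perim = float(
            sum(np.sqrt((np.diff(c, axis=0) ** 2).sum(1)).sum() for c in contours)
        )
    else:
        perim = float(
            max(np.sqrt((np.diff(c, axis=0) ** 2).sum(1)).sum() for c in contours)
        )
    return AspectRatioResult(
        perimeter_px=perim, area_px=area, ratio=perim**2 / (4 * np.pi * area)
    )


def aspect_ratio(mask: np.ndarray, multiple: str = "error") -> float:
    """Scalar aspect ratio of a binary mask (see :func:`aspect_ratio_result`)."""
    return aspect_ratio_result(mask, multiple=multiple).ratio


def model_rdm_from_ratings(
    ratings: pd.DataFrame,
    dimension: str | None = None,
    level: str = "category",
    categories: Sequence[str] = CATEGORIES,
) -> RDM:
    """Dissimilarity RDM from 1-D ratings: pairwise absolute differences.

    At stimulus level, entry (i, j) is |v_i - v_j|. At category level, entry
    (A, B) is the mean over cross-category stimulus pairs (i in A, j in B) of
    |v_i - v_j| — which collapses to |mean_A - mean_B| when ratings are
    noiseless.
    """
    df = ratings
    dims = df["dimension"].unique()
    if dimension is None:
        if len(dims) != 1:
            raise ValueError(f"table has dimensions {list(dims)}; pass dimension=")
        dimension = dims[0]
    df = df[df["dimension"] == dimension]
    if df.empty:
        raise ValueError(f"no ratings for dimension {dimension!r}")
    if level == "stimulus":
        df = df.sort_values("stimulus_id")
        v = df["value"].to_numpy(float)
        labels = tuple(df["stimulus_id"])
        d = np.abs(v[:, None] - v[None, :])
        return RDM(labels=labels, values=d, kind="dissimilarity")
    if level != "category":
        raise ValueError("level must be 'stimulus' or 'category'")
    groups = {}
    for c in categories:
        vals = df.loc[df["category"] == c, "value"].to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"missing category {c!r} in ratings")
        groups[c] = vals
    n = len(categories)
    d = np.zeros((n, n))
    for i, a in enumerate(categories):
        for j, b in enumerate(categories):
            if i < j:
                d[i, j] = d[j, i] = np.abs(
                    groups[a][:, None] - groups[b][None, :]
                ).mean()
    return RDM(labels=tuple(categories), values=d, kind="dissimilarity")


def model_rdm_from_shape(
    masks: Mapping[str, np.ndarray],
    category_map: Mapping[str, str],
    categories: Sequence[str] | None = None,
) -> tuple[RDM, pd.DataFrame]:
    """Shape-model RDM: absolute differences of category-mean aspect ratios.

    Returns the RDM plus the per-stimulus table (perimeter, area, ratio).
    """
    rows = []
    for stim, mask in masks.items():
        res = aspect_ratio_result(mask)
        rows.append((stim, category_map[stim], res.perimeter_px, res.area_px, res.ratio))
    table = pd.DataFrame(
        rows, columns=["stimulus_id", "category", "perimeter_px", "area_px", "ratio"]
    )
    if categories is None:
        categories = tuple(dict.fromkeys(table["category"]))
    means = table.groupby("category")["ratio"].mean()
    missing = [c for c in categories if c not in means.index]
    if missing:
        raise ValueError(f"no masks for categories: {missing}")
    v = means.reindex(list(categories)).to_numpy()
    d = np.abs(v[:, None] - v[None, :])
    np.fill_diagonal(d, 0.0)
    return RDM(labels=tuple(categories), values=d, kind="dissimilarity"), table


def rsa_correlate(
    neural: RDM, model: RDM, neural_to_dissimilarity: bool = True
) -> float:
    """Pearson correlation between neural and model lower triangles.

    A similarity-kind neural RDM is first converted to dissimilarity (1 - r)
    so that its sign convention matches the model distances; set
    ``neural_to_dissimilarity=False`` to correlate the raw similarities
    (flips the sign of the result).
    """
    if neural.labels != model.labels:
        raise ValueError("neural and model RDMs must share labels")
    nv = neural
    if neural_to_dissimilarity and neural.kind == "similarity":
        nv = neural.to_dissimilarity()
    a = nv.lower_triangle()
    b = model.to_dissimilarity().lower_triangle() if model.kind == "similarity" else model.lower_triangle()
    if b.std() == 0:
        raise ValueError("model RDM has zero variance in its lower triangle")
    if a.std() == 0:
        raise ValueError("neural RDM has zero variance in its lower triangle")
    return float(np.corrcoef(a, b)[0, 1])


def noise_ceiling_lower(subject_rdms: Sequence[RDM]) -> float:
    """Lower-bound noise ceiling: mean leave-one-out subject-group correlation.

    Each subject's lower triangle is correlated with the average lower
    triangle of all remaining subjects; the mean over subjects bounds from
    below the fit any model can achieve given between-subject noise.
    """
    if len(subject_rdms) < 3:
        raise ValueError("noise ceiling needs >= 3 subjects")
    tri = np.stack([r.lower_triangle() for r in subject_rdms])
    n = tri.shape[0]
    total = tri.sum(axis=0)
    rs = []
    for i in range(n):
        loo = (total - tri[i]) / (n - 1)
        rs.append(np.corrcoef(tri[i], loo)[0, 1])
    return float(np.mean(rs))


def noise_ceiling_profile(rdms) -> np.ndarray:
    """Per-sphere noise-ceiling lower bounds from nested subject x sphere RDMs.

    ``rdms[subject][sphere]`` is an :class:`RDM` or None; spheres missing for
    any subject yield NaN.
    """
    n_sub = len(rdms)
    n_sph = len(rdms[0])
    out = np.full(n_sph, np.nan)
    for k in range(n_sph):
        col = [rdms[i][k] for i in range(n_sub)]
        if all(r is not None for r in col):
            out[k] = noise_ceiling_lower(col)
    return out


@dataclass(frozen=True)
class ModelFitProfile:
    """Per subject x sphere x model RSA fits with along-vector inference.

    Per-sphere significance is a two-sided one-sample t over subjects on the
    Fisher-z fits, Bonferroni-corrected for the number of spheres.
    """

    fits: np.ndarray  # (n_subjects, n_spheres, n_models)
    models: tuple[str, ...]
    subjects: tuple[str, ...]
    missing: np.ndarray  # (n_spheres,) bool
    group_mean: np.ndarray  # (n_spheres, n_models)
    group_sem: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_bonferroni: np.ndarray
    significant: np.ndarray

    def profile(self, model: str) -> np.ndarray:
        """(n_subjects, n_spheres) fits for one model."""
        return self.fits[:, :, self.models.index(model)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sub in enumerate(self.subjects):
            for k in range(self.fits.shape[1]):
                for j, mname in enumerate(self.models):
                    rows.append((sub, k, mname, self.fits[i, k, j]))
        return pd.DataFrame(rows, columns=["subject", "sphere", "model", "r"])


def model_fit_profile(
    rdms,
    models: Mapping[str, RDM],
    subjects: Sequence[str] | None = None,
    alpha: float = 0.05,
    neural_to_dissimilarity: bool = True,
) -> ModelFitProfile:
    """Correlate each subject's per-sphere neural RDM with each model RDM."""
    from .stats import fisher_z

    n_sub = len(rdms)
    n_sph = len(rdms[0])
    names = tuple(models)
    fits = np.full((n_sub, n_sph, len(names)), np.nan)
    for i in range(n_sub):
        for k in range(n_sph):
            r = rdms[i][k]
            if r is None:
                continue
            for j, mname in enumerate(names):
                fits[i, k, j] = rsa_correlate(
                    r, models[mname], neural_to_dissimilarity=neural_to_dissimilarity
                )
    missing = np.isnan(fits).any(axis=(0, 2))
    group_mean = np.nanmean(fits, axis=0)
    group_sem = np.nanstd(fits, axis=0, ddof=1) / np.sqrt(n_sub)
    t = np.full((n_sph, len(names)), np.nan)
    p = np.full_like(t, np.nan)
    ok = ~missing
    if ok.any():
        tt, _, pp = one_sample_t(fisher_z(fits[:, ok, :]))
        t[ok], p[ok] = tt, pp
    m = int((~missing).sum())
    p_b = bonferroni_adjust(p, max(m, 1))
    return ModelFitProfile(
        fits=fits,
        models=names,
        subjects=tuple(subjects) if subjects else tuple(f"sub-{i+1:02d}" for i in range(n_sub)),
        missing=missing,
        group_mean=group_mean,
        group_sem=group_sem,
        t=t,
        p=p,
        p_bonferroni=p_b,
        significant=np.where(np.isnan(p_b), False, p_b < alpha),
    )


def model_profile_correlation(
    fits: ModelFitProfile, model_a: str, model_b: str, m: int = 3, alpha: float = 0.05
) -> GroupCorrelationStat:
    """Do two models' RSA effects co-vary along the vector?

    Per subject, the Pearson correlation between the two models' fit profiles
    across spheres (missing spheres pairwise-deleted); group inference is a
    two-sided one-sample t on the Fisher-z values, Bonferroni m = 3 (the
    number of model pairs).
    """
    a = fits.profile(model_a)
    b = fits.profile(model_b)
    return group_profile_correlation(a, b, valid=~fits.missing, m=m, alpha=alpha)


def model_rdm_correlations(models: Mapping[str, RDM]) -> pd.DataFrame:
    """Pairwise lower-triangle Pearson correlations between model RDMs.

    The model-orthogonality report: near-zero entries mean the candidate
    dimensions make independent predictions."""
    names = list(models)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va = models[a].lower_triangle()
            vb = models[b].lower_triangle()
            rows.append((a, b, float(np.corrcoef(va, vb)[0, 1])))
    return pd.DataFrame(rows, columns=["model_a", "model_b", "r"])


def mds_embed(rdm: RDM, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a dissimilarity RDM.

    Double-centres the squared distances and projects on the top ``dims``
    eigenvectors scaled by the square roots of their eigenvalues. A warning
    is issued for strongly non-Euclidean input — when the negative eigenvalue
    mass exceeds half of the positive mass (the double-centred Gram matrix
    has non-negative trace, so negative mass can never exceed half of the
    *total* mass).
    """
    if rdm.kind != "dissimilarity":
        raise ValueError("MDS needs a dissimilarity RDM")
    d2 = rdm.values**2
    n = rdm.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    neg = -w[w < 0].sum()
    pos = w[w > 0].sum()
    if pos > 0 and neg / pos > 0.5:
        warnings.warn("large negative eigenvalue mass: strongly non-Euclidean input")
    coords = v[:, :dims] * np.sqrt(np.maximum(w[:dims], 0.0))
    return coords
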