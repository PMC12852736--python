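"""Synthetic subjects, ratings, stimulus masks, and unit sheets.

Everything downstream of first-level modelling is exercised on data generated
here with known planted structure: condition-wise beta volumes are additive
Gaussian blobs on a 3 mm isotropic grid plus i.i.d. run-level Gaussian noise
(no haemodynamic or temporal simulation — the pipeline consumes beta maps);
behavioural ratings are clipped Gaussians around per-category means on the
1-7 Likert scale; stimulus masks are rasterized ellipses/rectangles; unit
sheets place tuned units on a 2-D surface either at random (null) or spatially
clustered by category.

The default :class:`PlantedTopography` encodes the study conditions the rest
of the package is validated against: 18 subjects x 8 runs x 6 categories on a
36 x 10 x 10 grid, with a gradient axis along which the object categories are
ordered (non-manipulable -> manipulable -> tools) and hand/tool blobs placed
6 mm apart so their selective clusters overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import draw as skdraw
from scipy import ndimage

from .unitsheet import UnitSheet

__all__ = [
    "CATEGORIES",
    "BODY_PARTS",
    "OBJECT_CATEGORIES",
    "N_STIMULI_PER_CATEGORY",
    "DEFAULT_ACTION_MEANS",
    "DEFAULT_ANIMACY_MEANS",
    "PlantedTopography",
    "BetaVolume",
    "SubjectBetas",
    "ShapeSpec",
    "UnitSheetConfig",
    "generate_subject_betas",
    "generate_dataset",
    "generate_ratings",
    "generate_stimulus_masks",
    "generate_unit_sheet",
    "default_stimulus_ids",
]

#: The six analysis categories, in canonical order.
CATEGORIES = ("faces", "bodies", "hands", "tools", "manipulable", "nonmanipulable")
BODY_PARTS = ("faces", "bodies", "hands")
OBJECT_CATEGORIES = ("tools", "manipulable", "nonmanipulable")
N_STIMULI_PER_CATEGORY = 12

#: Behaviourally validated mean action ratings per category (1-7 scale).
DEFAULT_ACTION_MEANS = {
    "hands": 6.3,
    "tools": 5.7,
    "bodies": 4.5,
    "faces": 3.4,
    "manipulable": 3.3,
    "nonmanipulable": 2.9,
}

#: Synthetic animacy means: body parts high, objects low (no published values;
#: chosen to produce the canonical animate/inanimate block structure).
DEFAULT_ANIMACY_MEANS = {
    "faces": 6.8,
    "bodies": 6.5,
    "hands": 6.2,
    "tools": 1.8,
    "manipulable": 1.6,
    "nonmanipulable": 1.5,
}

_DEFAULT_CENTERS = {
    "nonmanipulable": 25.0,
    "faces": 33.0,
    "manipulable": 50.0,
    "tools": 75.0,
    "hands": 81.0,
    "bodies": 90.0,
}
_DEFAULT_SIGMAS = {
    "faces": 9.0,
    "bodies": 9.0,
    "hands": 9.0,
    "tools": 15.0,
    "manipulable": 15.0,
    "nonmanipulable": 15.0,
}


def default_stimulus_ids() -> list[str]:
    """Canonical 72 stimulus ids: 12 per category, category-prefixed."""
    return [f"{c}_{i:02d}" for c in CATEGORIES for i in range(N_STIMULI_PER_CATEGORY)]


@dataclass(frozen=True)
class PlantedTopography:
    """Ground-truth spatial layout for synthetic beta volumes.

    Each category's noiseless signal is an isotropic Gaussian blob of peak
    ``amplitudes[c]`` and spread ``blob_sigma_mm[c]``, centred at
    ``category_centers_mm[c]`` along the gradient axis (axis 0) and at the
    grid midpoint on the other two axes. Runs differ only by i.i.d. Gaussian
    noise of sd ``noise_sd`` added voxelwise.
    """

    grid_shape: tuple[int, int, int] = (36, 10, 10)
    voxel_size_mm: float = 3.0
    category_centers_mm: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CENTERS)
    )
    blob_sigma_mm: Mapping[str, float] | float = field(
        default_factory=lambda: dict(_DEFAULT_SIGMAS)
    )
    amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CATEGORIES}
    )
    noise_sd: float = 0.25
    n_runs: int = 8
    n_subjects: int = 18

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if set(self.category_centers_mm) != set(CATEGORIES):
            raise ValueError(
                "category_centers_mm must cover exactly the six analysis categories"
            )
        for c in CATEGORIES:
            if self.sigma_for(c) <= 0:
                raise ValueError(f"blob_sigma_mm for {c!r} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_runs < 1 or self.n_subjects < 1:
            raise ValueError("n_runs and n_subjects must be >= 1")

    def sigma_for(self, category: str) -> float:
        if isinstance(self.blob_sigma_mm, Mapping):
            return float(self.blob_sigma_mm[category])
        return float(self.blob_sigma_mm)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def voxel_centers_mm(self) -> np.ndarray:
        """(n_voxels, 3) world coordinates of voxel centres, C-order."""
        grids = np.meshgrid(
            *[np.arange(n) * self.voxel_size_mm for n in self.grid_shape],
            indexing="ij",
        )
        return np.stack([g.ravel() for g in grids], axis=1)

    def blob_center_mm(self, category: str) -> np.ndarray:
        mid = [(n - 1) * self.voxel_size_mm / 2.0 for n in self.grid_shape[1:]]
        return np.array([float(self.category_centers_mm[category]), *mid])

    def signal(self, category: str) -> np.ndarray:
        """Noiseless beta volume for one category."""
        centers = self.voxel_centers_mm()
        d2 = ((centers - self.blob_center_mm(category)) ** 2).sum(axis=1)
        amp = float(self.amplitudes.get(category, 0.0))
        sig = amp * np.exp(-d2 / (2.0 * self.sigma_for(category) ** 2))
        return sig.reshape(self.grid_shape)

    def signal_stack(self) -> np.ndarray:
        """(6, *grid) noiseless signal for all categories in canonical order."""
        return np.stack([self.signal(c) for c in CATEGORIES])


@dataclass(frozen=True)
class BetaVolume:
    """One condition's beta estimates on a 3-D voxel grid."""

    values: np.ndarray
    affine: np.ndarray
    condition: str
    run: int
    subject: str

    def __post_init__(self):
        if np.asarray(self.values).ndim != 3:
            raise ValueError("beta values must be a 3-D array")
        aff = np.asarray(self.affine, float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")


@dataclass(frozen=True)
class SubjectBetas:
    """All beta volumes of one subject: (n_runs, n_conditions, *grid)."""

    data: np.ndarray
    affine: np.ndarray
    conditions: tuple[str, ...]
    subject: str

    @property
    def n_runs(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[2:]

    def get(self, run: int, condition: str) -> BetaVolume:
        j = self.conditions.index(condition)
        return BetaVolume(
            values=self.data[run, j],
            affine=self.affine,
            condition=condition,
            run=run,
            subject=self.subject,
        )

    def volumes(self) -> Iterator[BetaVolume]:
        for run in range(self.n_runs):
            for cond in self.conditions:
                yield self.get(run, cond)

    def run_average(self, runs: Sequence[int] | None = None) -> np.ndarray:
        """(n_conditions, *grid) beta averaged over the given runs (all by default)."""
        sel = self.data if runs is None else self.data[np.asarray(runs, int)]
        return sel.mean(axis=0)

    def voxel_centers_mm(self) -> np.ndarray:
        ijk = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.grid_shape], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (homog @ self.affine.T)[:, :3]


def generate_subject_betas(
    topo: PlantedTopography, subject_seed: int, subject: str = "sub-01"
) -> SubjectBetas:
    """Per-run, per-condition beta volumes for one synthetic subject.

    The noiseless signal is identical across runs; the same
    (topography, seed) pair always produces bit-identical output.
    """
    rng = np.random.default_rng(subject_seed)
    signal = topo.signal_stack()
    shape = (topo.n_runs, len(CATEGORIES), *topo.grid_shape)
    noise = (
        rng.normal(0.0, topo.noise_sd, size=shape)
        if topo.noise_sd > 0
        else np.zeros(shape)
    )
    return SubjectBetas(
        data=signal[None] + noise,
        affine=topo.affine,
        conditions=CATEGORIES,
        subject=subject,
    )


def generate_dataset(topo: PlantedTopography, seed: int) -> list[SubjectBetas]:
    """All subjects of one synthetic study; per-subject seeds are spawned
    deterministically from ``seed``."""
    children = np.random.SeedSequence(seed).spawn(topo.n_subjects)
    return [
        generate_subject_betas(
            topo, ss, subject=f"sub-{i + 1:02d}"
        )
        for i, ss in enumerate(children)
    ]


def generate_ratings(
    means: Mapping[str, float] | None = None,
    sd: float = 0.5,
    n_per_category: int = N_STIMULI_PER_CATEGORY,
    seed: int | None = 0,
    dimension: str = "action",
    scale: tuple[float, float] = (1.0, 7.0),
) -> pd.DataFrame:
    """Per-stimulus ratings around per-category means, clipped to the scale.

    Returns a long table (stimulus_id, category, dimension, value). With
    sd = 0 every stimulus rating equals its category mean exactly.
    """
    if means is None:
        means = DEFAULT_ACTION_MEANS if dimension == "action" else DEFAULT_ANIMACY_MEANS
    if not means:
        raise ValueError("means must name at least one category")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for cat, mu in means.items():
        vals = np.full(n_per_category, float(mu))
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, size=n_per_category)
        vals = np.clip(vals, *scale)
        for i, v in enumerate(vals):
            rows.append((f"{cat}_{i:02d}", cat, dimension, float(v)))
    return pd.DataFrame(rows, columns=["stimulus_id", "category", "dimension", "value"])


@dataclass(frozen=True)
class ShapeSpec:
    """One binary stimulus mask: a filled ellipse or rectangle.

    ``size_px`` is (semi-axis a, semi-axis b) for ellipses and
    (height, width) for rectangles; ``orientation_deg`` rotates the shape
    counter-clockwise about its centre.
    """

    kind: str  # "ellipse" | "rectangle"
    size_px: tuple[float, float]
    orientation_deg: float = 0.0
    center_px: tuple[float, float] | None = None
    name: str | None = None

    def __post_init__(self):
        if self.kind not in ("ellipse", "rectangle"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        a, b = self.size_px
        if a <= 0 or b <= 0:
            raise ValueError(f"degenerate (zero-area) shape: size {self.size_px}")


def _rasterize(spec: ShapeSpec, canvas_px: int) -> np.ndarray:
    center = spec.center_px or (canvas_px / 2.0, canvas_px / 2.0)
    mask = np.zeros((canvas_px, canvas_px), dtype=bool)
    a, b = spec.size_px
    if spec.kind == "ellipse":
        extent = max(a, b)
        rr, cc = skdraw.ellipse(
            center[0],
            center[1],
            a,
            b,
            shape=mask.shape,
            rotation=np.deg2rad(spec.orientation_deg),
        )
        mask[rr, cc] = True
    else:
        # exact rasterization: a pixel belongs to the rectangle iff its
        # center falls in the half-open box, so an axis-aligned h x w
        # rectangle covers exactly h*w pixels
        th = np.deg2rad(spec.orientation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rr, cc = np.meshgrid(np.arange(canvas_px), np.arange(canvas_px), indexing="ij")
        rel = np.stack([rr - center[0], cc - center[1]], axis=-1) @ rot
        inside = (
            (rel[..., 0] >= -a / 2.0)
            & (rel[..., 0] < a / 2.0)
            & (rel[..., 1] >= -b / 2.0)
            & (rel[..., 1] < b / 2.0)
        )
        mask |= inside
        extent = np.hypot(a, b) / 2.0
    lo = np.array(center) - extent
    hi = np.array(center) + extent
    if (lo < -0.5).any() or (hi > canvas_px - 0.5).any():
        raise ValueError(f"shape {spec} does not fit the {canvas_px}px canvas")
    return mask


def generate_stimulus_masks(
    specs: Sequence[ShapeSpec], canvas_px: int = 400, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Rasterize shape descriptors into filled, single-component binary masks.

    ``seed`` is accepted for interface symmetry with the other generators;
    rasterization itself is deterministic in the specs.
    """
    del seed
    out: dict[str, np.ndarray] = {}
    for i, spec in enumerate(specs):
        mask = _rasterize(spec, canvas_px)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
        if n != 1:
            raise ValueError(f"shape {spec} rasterized to {n} components, expected 1")
        out[spec.name or f"shape_{i:02d}"] = mask
    return out


@dataclass(frozen=True)
class UnitSheetConfig:
    """Generator settings for a synthetic 2-D unit sheet.

    In ``null`` mode each unit is tuned to each category independently with
    probability ``tuning_prob``, regardless of position — category selectivity
    then carries no spatial information, which is the chance condition for the
    section-overlap score. In ``clustered`` mode a unit is tuned to a category
    iff it lies within ``spread_mm`` of that category's planted centre.
    Tuned responses are ``tuning_amplitude`` above baseline; i.i.d. Gaussian
    noise of sd ``response_sd`` is added everywhere. The defaults (sparse
    tuning at probability 0.05, amplitude 5x the noise sd) are chosen so the
    realized selectivity map essentially equals the planted tuning map: the
    amplitude keeps the category-vs-all t of tuned units above the 3.5
    threshold even when a unit happens to be tuned to a second category
    (co-tuning inflates the pooled variance of the contrast), and the sparse
    tuning makes triple co-tuning — where detection does fail — negligible.
    In null mode the selectivity indicators are then genuinely independent
    across categories, which is what makes 0.5 the chance value of the
    section-overlap score.
    """

    sheet_extent_mm: tuple[float, float] = (50.0, 50.0)
    n_units: int = 2500
    mode: str = "null"  # "null" | "clustered"
    cluster_assignments: Mapping[str, tuple[tuple[float, float], float]] | None = None
    response_sd: float = 1.0
    tuning_amplitude: float = 5.0
    tuning_prob: float = 0.05
    n_per_category: int = N_STIMULI_PER_CATEGORY

    def __post_init__(self):
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        if self.mode not in ("null", "clustered"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.response_sd < 0:
            raise ValueError("response_sd must be >= 0")
        if self.mode == "clustered":
            if not self.cluster_assignments:
                raise ValueError("clustered mode requires cluster_assignments")
            ext = np.asarray(self.sheet_extent_mm, float)
            for cat, (center, spread) in self.cluster_assignments.items():
                c = np.asarray(center, float)
                if (c < 0).any() or (c > ext).any():
                    raise ValueError(
                        f"cluster center for {cat!r} lies outside the sheet"
                    )
                if spread <= 0:
                    raise ValueError(f"cluster spread for {cat!r} must be positive")


def generate_unit_sheet(cfg: UnitSheetConfig, seed: int | None = 0) -> UnitSheet:
    """Draw unit positions and per-stimulus responses for one sheet."""
    rng = np.random.default_rng(seed)
    ext = np.asarray(cfg.sheet_extent_mm, float)
    positions = rng.uniform(0.0, ext, size=(cfg.n_units, 2))
    # planted tuning matrix: units x categories
    if cfg.mode == "null":
        tuned = rng.random((cfg.n_units, len(CATEGORIES))) < cfg.tuning_prob
    else:
        tuned = np.zeros((cfg.n_units, len(CATEGORIES)), dtype=bool)
        for j, cat in enumerate(CATEGORIES):
            if cfg.cluster_assignments and cat in cfg.cluster_assignments:
                center, spread = cfg.cluster_assignments[cat]
                d = np.linalg.norm(positions - np.asarray(center, float), axis=1)
                tuned[:, j] = d <= spread
            else:
                tuned[:, j] = rng.random(cfg.n_units) < cfg.tuning_prob
    labels = [c for c in CATEGORIES for _ in range(cfg.n_per_category)]
    ind = np.stack(
        [(np.asarray(labels) == c).astype(float) for c in CATEGORIES], axis=1
    )
    signal = cfg.tuning_amplitude * (tuned.astype(float) @ ind.T)
    noise = (
        rng.normal(0.0, cfg.response_sd, size=signal.shape)
        if cfg.response_sd > 0
        else 0.0
    )
    return UnitSheet(
        positions=positions,
        responses=signal + noise,
        stimulus_categories=tuple(labels),
        extent_mm=(float(ext[0]), float(ext[1])),
    )
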