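"""Action-effector and grasp indices from condition-similarity matrices.

Both indices contrast a body part's pattern similarity with two object
categories that differ in exactly one action property. The *effector* index,
r(body part, tools) - r(body part, manipulable), isolates the action-effector
property (tools act on other objects; manipulable objects are merely
graspable). The *grasp* index, r(body part, manipulable) -
r(body part, non-manipulable), isolates graspability. The two telescope:
effector + grasp = r(body part, tools) - r(body part, non-manipulable).
Indices are computed on raw Pearson similarities per the definition; group
inference along the vector-of-ROIs is a two-sided one-sample t per sphere
with Bonferroni correction for the number of spheres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .rsa import RDM, ModelFitProfile  # noqa: F401  (re-export convenience)
from .roivector import SphereProfile
from .stats import (
    GroupCorrelationStat,
    bonferroni_adjust,
    fisher_z,
    group_profile_correlation,
    one_sample_t,
)
from .synthgen import BODY_PARTS

__all__ = [
    "INDEX_KINDS",
    "effector_index",
    "grasp_index",
    "IndexProfile",
    "index_profile",
    "index_activation_correlation",
]

INDEX_KINDS = ("effector", "grasp")

_PAIR = {
    "effector": ("tools", "manipulable"),
    "grasp": ("manipulable", "nonmanipulable"),
}


def _similarity(rdm: RDM, a: str, b: str) -> float:
    if rdm.kind != "similarity":
        raise ValueError("indices are defined on similarity RDMs")
    for lbl in (a, b):
        if lbl not in rdm.labels:
            raise ValueError(f"RDM is missing label {lbl!r}")
    return float(rdm.values[rdm.labels.index(a), rdm.labels.index(b)])


def effector_index(rdm: RDM, body_part: str, fisher: bool = False) -> float:
    """r(body_part, tools) - r(body_part, manipulable).

    Positive values mean the body part's activity pattern resembles action
    effectors more than merely graspable objects. ``fisher=True`` computes
    the difference on Fisher-z scale instead of raw r.
    """
    r1 = _similarity(rdm, body_part, "tools")
    r2 = _similarity(rdm, body_part, "manipulable")
    if fisher:
        return float(fisher_z(r1) - fisher_z(r2))
    return r1 - r2


def grasp_index(rdm: RDM, body_part: str, fisher: bool = False) -> float:
    """r(body_part, manipulable) - r(body_part, nonmanipulable)."""
    r1 = _similarity(rdm, body_part, "manipulable")
    r2 = _similarity(rdm, body_part, "nonmanipulable")
    if fisher:
        return float(fisher_z(r1) - fisher_z(r2))
    return r1 - r2


@dataclass(frozen=True)
class IndexProfile:
    """Per subject x sphere x body part x index-kind values with inference.

    ``values`` is (n_subjects, n_spheres, n_body_parts, 2); per-sphere group
    t-tests are Bonferroni-corrected for the number of non-missing spheres.
    Values are differences of two correlations and therefore lie in [-2, 2].
    """

    values: np.ndarray
    body_parts: tuple[str, ...]
    kinds: tuple[str, ...]
    subjects: tuple[str, ...]
    missing: np.ndarray  # (n_spheres,)
    group_mean: np.ndarray  # (n_spheres, n_body_parts, 2)
    group_sem: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_bonferroni: np.ndarray
    significant: np.ndarray

    def profile(self, body_part: str, kind: str) -> np.ndarray:
        """(n_subjects, n_spheres) index values for one body part and kind."""
        return self.values[:, :, self.body_parts.index(body_part), self.kinds.index(kind)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n_sub, n_sph = self.values.shape[:2]
        for i in range(n_sub):
            for k in range(n_sph):
                for bi, bp in enumerate(self.body_parts):
                    for ki, kind in enumerate(self.kinds):
                        rows.append(
                            (self.subjects[i], k, bp, kind, self.values[i, k, bi, ki])
                        )
        return pd.DataFrame(
            rows, columns=["subject", "sphere", "body_part", "index_kind", "value"]
        )

    def group_frame(self) -> pd.DataFrame:
        rows = []
        n_sph = self.values.shape[1]
        for k in range(n_sph):
            for bi, bp in enumerate(self.body_parts):
                for ki, kind in enumerate(self.kinds):
                    rows.append(
                        (
                            k,
                            bp,
                            kind,
                            self.group_mean[k, bi, ki],
                            self.group_sem[k, bi, ki],
                            self.t[k, bi, ki],
                            self.p[k, bi, ki],
                            bool(self.significant[k, bi, ki]),
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["sphere", "body_part", "index_kind", "mean", "sem", "t", "p", "significant"],
        )


def index_profile(
    rdms,
    body_parts: Sequence[str] = BODY_PARTS,
    subjects: Sequence[str] | None = None,
    alpha: float = 0.05,
    fisher: bool = False,
) -> IndexProfile:
    """Effector and grasp indices along the vector-of-ROIs.

    ``rdms[subject][sphere]`` is a similarity :class:`RDM` or None (missing
    spheres propagate as NaN). Per sphere, body part, and kind, the group
    test is a two-sided one-sample t vs 0 with Bonferroni m = number of
    usable spheres.
    """
    n_sub = len(rdms)
    if n_sub < 2:
        raise ValueError("index profile needs >= 2 subjects")
    n_sph = len(rdms[0])
    vals = np.full((n_sub, n_sph, len(body_parts), 2), np.nan)
    for i in range(n_sub):
        for k in range(n_sph):
            r = rdms[i][k]
            if r is None:
                continue
            for bi, bp in enumerate(body_parts):
                vals[i, k, bi, 0] = effector_index(r, bp, fisher=fisher)
                vals[i, k, bi, 1] = grasp_index(r, bp, fisher=fisher)
    missing = np.isnan(vals).any(axis=(0, 2, 3))
    mean = np.nanmean(vals, axis=0)
    sem = np.nanstd(vals, axis=0, ddof=1) / np.sqrt(n_sub)
    t = np.full(mean.shape, np.nan)
    p = np.full(mean.shape, np.nan)
    ok = ~missing
    if ok.any():
        tt, _, pp = one_sample_t(vals[:, ok])
        t[ok], p[ok] = tt, pp
    m = max(int(ok.sum()), 1)
    p_b = bonferroni_adjust(p, m)
    return IndexProfile(
        values=vals,
        body_parts=tuple(body_parts),
        kinds=INDEX_KINDS,
        subjects=tuple(subjects) if subjects else tuple(f"sub-{i+1:02d}" for i in range(n_sub)),
        missing=missing,
        group_mean=mean,
        group_sem=sem,
        t=t,
        p=p,
        p_bonferroni=p_b,
        significant=np.where(np.isnan(p_b), False, p_b < alpha),
    )


def index_activation_correlation(
    index: IndexProfile,
    profiles: SphereProfile,
    category: str,
    body_part: str = "hands",
    kind: str = "effector",
    m: int = 6,
    alpha: float = 0.05,
) -> GroupCorrelationStat:
    """Does the index track a category's activation along the vector?

    Per subject, the Pearson correlation between the index profile and the
    category's normalized activation profile across spheres; group inference
    on Fisher-z values, Bonferroni m = 6 (one test per object category).
    """
    a = index.profile(body_part, kind)
    j = profiles.conditions.index(category)
    b = profiles.norm_beta[:, :, j]
    if a.shape != b.shape:
        raise ValueError("index and activation profiles disagree on shape")
    valid = ~(index.missing | profiles.missing)
    return group_profile_correlation(a, b, valid=valid, m=m, alpha=alpha)
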