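"""Analyses of 2-D unit sheets from topographic network layers.

A *unit sheet* is a set of model units with 2-D positions (mm) on a simulated
cortical surface and one response per stimulus. The analyses mirror the
standard treatment of topographic network layers: category selectivity by a
two-sample t contrast (category vs. all other stimuli, t > 3.5), response
profiles of the top-k most selective units, and a section-based co-occurrence
score — the sheet is tiled into 1 mm square sections, the fraction of
selective units per section is computed per category, and two categories'
fraction vectors are correlated. The score is mapped to [0, 1] via
(Pearson r + 1) / 2, so 0.5 means the presence of one category carries no
information about the other, 0 means perfect mutual exclusion and 1 perfect
co-occurrence. Inference uses label-shuffling permutation tests (one-sided,
minimum resolvable p = 1/n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import permutation_p

__all__ = [
    "UnitSheet",
    "SelectivityMap",
    "SectionGrid",
    "UninformativeMapError",
    "unit_selectivity",
    "top_k_profile",
    "build_section_grid",
    "section_overlap_score",
    "overlap_score_matrix",
    "PermutationResult",
    "permutation_test",
    "overlap_contrast",
]


class UninformativeMapError(ValueError):
    """A selective-fraction vector has zero variance, so no score is defined."""


@dataclass(frozen=True)
class UnitSheet:
    """Units on a 2-D sheet with per-stimulus responses.

    positions: (n_units, 2) mm coordinates within ``extent_mm``.
    responses: (n_units, n_stimuli) activations.
    stimulus_categories: length n_stimuli category label per stimulus.
    """

    positions: np.ndarray
    responses: np.ndarray
    stimulus_categories: tuple[str, ...]
    extent_mm: tuple[float, float]

    def __post_init__(self):
        pos = np.asarray(self.positions, float)
        resp = np.asarray(self.responses, float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "responses", resp)
        object.__setattr__(
            self, "stimulus_categories", tuple(self.stimulus_categories)
        )
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be (n_units, 2)")
        if resp.shape[0] != pos.shape[0]:
            raise ValueError("responses and positions disagree on n_units")
        if resp.shape[1] != len(self.stimulus_categories):
            raise ValueError("responses and stimulus_categories disagree on n_stimuli")
        ext = np.asarray(self.extent_mm, float)
        if np.any(pos < -1e-9) or np.any(pos > ext + 1e-9):
            raise ValueError("unit positions fall outside the declared extent")
        counts = pd.Series(self.stimulus_categories).value_counts()
        if (counts < 2).any():
            raise ValueError("every category needs at least 2 stimuli")

    @property
    def n_units(self) -> int:
        return self.positions.shape[0]

    @property
    def categories(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.stimulus_categories:
            seen.setdefault(c)
        return tuple(seen)

    def category_indicator(self) -> np.ndarray:
        """(n_stimuli, n_categories) 0/1 indicator in ``self.categories`` order."""
        cats = self.categories
        labels = np.asarray(self.stimulus_categories)
        return np.stack([(labels == c).astype(float) for c in cats], axis=1)


@dataclass(frozen=True)
class SelectivityMap:
    """Per unit x category t-values and the boolean selectivity call."""

    categories: tuple[str, ...]
    t: np.ndarray  # (n_units, n_categories), NaN where undefined
    selective: np.ndarray  # bool, False where undefined
    undefined: np.ndarray  # bool
    df: int
    t_thresh: float

    def to_frame(self) -> pd.DataFrame:
        n = self.t.shape[0]
        rows = []
        for j, c in enumerate(self.categories):
            rows.append(
                pd.DataFrame(
                    {
                        "unit_id": np.arange(n),
                        "category": c,
                        "t": self.t[:, j],
                        "selective": self.selective[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _category_t(R: np.ndarray, R2: np.ndarray, indicator: np.ndarray):
    """Vectorized two-sample pooled-variance t per unit x category.

    R is (n_units, n_stimuli) responses, R2 its elementwise square, and
    ``indicator`` an (n_stimuli, n_categories) 0/1 matrix. Returns (t, df)
    with NaN where the pooled variance is zero.
    """
    n_stim = R.shape[1]
    n_c = indicator.sum(axis=0)  # per category
    n_o = n_stim - n_c
    if np.any(n_c < 2) or np.any(n_o < 2):
        raise ValueError("need >= 2 stimuli on each side of the contrast")
    sum_c = R @ indicator
    sumsq_c = R2 @ indicator
    tot = R.sum(axis=1, keepdims=True)
    totsq = R2.sum(axis=1, keepdims=True)
    mean_c = sum_c / n_c
    mean_o = (tot - sum_c) / n_o
    ss_c = sumsq_c - n_c * mean_c**2
    ss_o = (totsq - sumsq_c) - n_o * mean_o**2
    df = n_stim - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = (ss_c + ss_o) / df
        se = np.sqrt(s2 * (1.0 / n_c + 1.0 / n_o))
        t = np.where(se > 0, (mean_c - mean_o) / se, np.nan)
    return t, df


def unit_selectivity(sheet: UnitSheet, t_thresh: float = 3.5) -> SelectivityMap:
    """Category-vs-all two-sample t per unit; selective iff t > ``t_thresh``.

    The contrast compares the unit's responses to the category's stimuli with
    its responses to all remaining stimuli, using the pooled variance
    (df = n_stimuli - 2). Units with zero pooled variance are flagged
    undefined and never selective.
    """
    R = sheet.responses
    t, df = _category_t(R, R**2, sheet.category_indicator())
    undefined = ~np.isfinite(t)
    selective = np.where(undefined, False, t > t_thresh)
    return SelectivityMap(
        categories=sheet.categories,
        t=t,
        selective=selective.astype(bool),
        undefined=undefined,
        df=df,
        t_thresh=t_thresh,
    )


def top_k_profile(
    selmap: SelectivityMap, sheet: UnitSheet, category: str, k: int = 50
) -> pd.Series:
    """Mean response per category over the k most ``category``-selective units.

    Units are ranked by t descending; ties and ranking are made deterministic
    by breaking ties with ascending unit id. Units with undefined t are not
    rankable.
    """
    j = selmap.categories.index(category)
    t = selmap.t[:, j]
    ok = np.isfinite(t)
    if ok.sum() < k:
        raise ValueError(f"only {int(ok.sum())} rankable units; need k={k}")
    ids = np.flatnonzero(ok)
    order = ids[np.lexsort((ids, -t[ok]))][:k]
    ind = sheet.category_indicator()
    means = (sheet.responses[order].mean(axis=0) @ ind) / ind.sum(axis=0)
    return pd.Series(means, index=list(sheet.categories), name=category)


@dataclass(frozen=True)
class SectionGrid:
    """Per-section selective fractions on a square tiling of the sheet.

    Sections that contain no units are excluded (they carry no information
    about co-occurrence, not evidence of absence).
    """

    categories: tuple[str, ...]
    fractions: np.ndarray  # (n_nonempty_sections, n_categories)
    counts: np.ndarray  # units per retained section
    section_mm: float
    section_ids: np.ndarray  # (n_nonempty_sections, 2) integer tile coords


def build_section_grid(
    sheet: UnitSheet, selmap: SelectivityMap, section_mm: float = 1.0
) -> SectionGrid:
    """Tile the sheet into ``section_mm``-wide squares and count selectivity.

    Each unit belongs to exactly one section (floor of position / width, with
    units on the far edge assigned to the last section).
    """
    if section_mm <= 0:
        raise ValueError("section_mm must be positive")
    ext = np.asarray(sheet.extent_mm, float)
    n_tiles = np.maximum(1, np.ceil(ext / section_mm - 1e-9).astype(int))
    idx = np.minimum((sheet.positions // section_mm).astype(int), n_tiles - 1)
    flat = idx[:, 0] * n_tiles[1] + idx[:, 1]
    order = np.argsort(flat, kind="stable")
    uniq, start_counts = np.unique(flat[order], return_counts=True)
    sel = selmap.selective.astype(float)
    sums = np.zeros((uniq.size, sel.shape[1]))
    np.add.at(sums, np.searchsorted(uniq, flat), sel)
    fractions = sums / start_counts[:, None]
    section_ids = np.stack([uniq // n_tiles[1], uniq % n_tiles[1]], axis=1)
    return SectionGrid(
        categories=selmap.categories,
        fractions=fractions,
        counts=start_counts,
        section_mm=float(section_mm),
        section_ids=section_ids,
    )


def section_overlap_score(grid: SectionGrid, cat_a: str, cat_b: str) -> float:
    """Co-occurrence score in [0, 1]: (Pearson r + 1) / 2 of section fractions.

    1 means the two categories' selective populations perfectly co-occur
    across sections, 0 means perfect mutual exclusion, and 0.5 means the
    presence of one category does not predict the other (chance baseline).
    """
    fa = grid.fractions[:, grid.categories.index(cat_a)]
    fb = grid.fractions[:, grid.categories.index(cat_b)]
    if fa.size < 2:
        raise ValueError("need at least 2 populated sections")
    sa, sb = fa.std(), fb.std()
    if sa == 0 or sb == 0:
        raise UninformativeMapError(
            f"uninformative map: zero variance in selective fractions for "
            f"{cat_a if sa == 0 else cat_b}"
        )
    r = float(np.corrcoef(fa, fb)[0, 1])
    return (r + 1.0) / 2.0


def overlap_score_matrix(grid: SectionGrid) -> pd.DataFrame:
    """All pairwise section-overlap scores as a symmetric DataFrame."""
    cats = grid.categories
    out = pd.DataFrame(np.eye(len(cats)), index=list(cats), columns=list(cats))
    for i, a in enumerate(cats):
        for j, b in enumerate(cats):
            if i < j:
                s = section_overlap_score(grid, a, b)
                out.iloc[i, j] = out.iloc[j, i] = s
    return out


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p: float
    n_perm: int
    n_undefined: int = 0
    alternative: str = "greater"


def permutation_test(
    statistic: Callable[[Sequence[str]], float],
    labels: Sequence[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "greater",
    max_undefined_frac: float = 0.10,
) -> PermutationResult:
    """Label-shuffling permutation test for ``statistic(labels)``.

    The observed statistic is compared with its distribution under random
    shuffles of the stimulus-to-category labels; the one-sided p-value is
    max(count at least as extreme, 1) / n_perm, so the minimum resolvable
    p equals 1/n_perm (0.0001 at the conventional 10,000 shuffles).
    Permutations on which the statistic is undefined (NaN) are counted and the
    test aborts if they exceed ``max_undefined_frac`` of the shuffles.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    labels = np.asarray(labels)
    observed = float(statistic(labels))
    if not np.isfinite(observed):
        raise ValueError("statistic undefined on the observed labels")
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = statistic(rng.permutation(labels))
    bad = int((~np.isfinite(null)).sum())
    if bad > max_undefined_frac * n_perm:
        raise ValueError(
            f"statistic undefined on {bad}/{n_perm} permutations "
            f"(> {max_undefined_frac:.0%}); null distribution unreliable"
        )
    ok = null[np.isfinite(null)]
    if alternative == "greater":
        count = int((ok >= observed).sum())
    else:
        count = int((ok <= observed).sum())
    return PermutationResult(
        observed=observed,
        p=permutation_p(count, n_perm),
        n_perm=n_perm,
        n_undefined=bad,
        alternative=alternative,
    )


def _pair_score_statistic(
    sheets: Sequence[UnitSheet],
    pair_1: tuple[str, str],
    pair_2: tuple[str, str] | None,
    t_thresh: float,
    section_mm: float,
):
    """Closure computing mean(score(pair_1)) - mean(score(pair_2)) efficiently.

    Selectivity, section fractions and scores are all recomputed from scratch
    for whatever label vector the permutation engine passes in; per-sheet
    response matrices and section memberships are precomputed once.
    """
    cats = sheets[0].categories
    pre = []
    for sh in sheets:
        if sh.categories != cats:
            raise ValueError("sheets disagree on category set")
        R = sh.responses
        ext = np.asarray(sh.extent_mm, float)
        n_tiles = np.maximum(1, np.ceil(ext / section_mm - 1e-9).astype(int))
        idx = np.minimum((sh.positions // section_mm).astype(int), n_tiles - 1)
        flat = idx[:, 0] * n_tiles[1] + idx[:, 1]
        uniq, counts = np.unique(flat, return_counts=True)
        pre.append((R, R**2, np.searchsorted(uniq, flat), uniq.size, counts))
    ia, ib = cats.index(pair_1[0]), cats.index(pair_1[1])
    pair2_idx = None
    if pair_2 is not None:
        pair2_idx = (cats.index(pair_2[0]), cats.index(pair_2[1]))

    def score_from_fracs(fr: np.ndarray, i: int, j: int) -> float:
        sa, sb = fr[:, i].std(), fr[:, j].std()
        if sa == 0 or sb == 0:
            return np.nan
        return (float(np.corrcoef(fr[:, i], fr[:, j])[0, 1]) + 1.0) / 2.0

    def statistic(labels) -> float:
        labels = np.asarray(labels)
        ind = np.stack([(labels == c).astype(float) for c in cats], axis=1)
        diffs = []
        for R, R2, sec_of_unit, n_sec, counts in pre:
            t, _ = _category_t(R, R2, ind)
            sel = np.where(np.isfinite(t), t > t_thresh, False).astype(float)
            sums = np.zeros((n_sec, len(cats)))
            np.add.at(sums, sec_of_unit, sel)
            fr = sums / counts[:, None]
            s1 = score_from_fracs(fr, ia, ib)
            s2 = 0.0 if pair2_idx is None else score_from_fracs(fr, *pair2_idx)
            diffs.append(s1 - s2)
        return float(np.mean(diffs))

    return statistic


def overlap_contrast(
    sheets: Sequence[UnitSheet],
    pair_1: tuple[str, str],
    pair_2: tuple[str, str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    t_thresh: float = 3.5,
    section_mm: float = 1.0,
    scheme: str = "positions",
) -> PermutationResult:
    """Permutation p for score(pair_1) > score(pair_2) across model instances.

    The statistic is the difference of the two pairs' mean section-overlap
    scores across instances (network initializations or subjects). Two null
    schemes are available:

    ``positions`` (default) shuffles each sheet's unit-to-position assignment
    per permutation — selectivity is preserved while its spatial arrangement
    is broken, the exchangeable null for a co-occurrence statistic.
    ``labels`` shuffles the stimulus-to-category labels and recomputes
    selectivity from scratch; on sheets with clear category tuning this
    leaves (almost) no suprathreshold units under the shuffle, the scores are
    undefined, and the test aborts with diagnostics.
    """
    if len(sheets) < 2:
        raise ValueError("need >= 2 instances (sheets)")
    if scheme == "labels":
        stat = _pair_score_statistic(sheets, pair_1, pair_2, t_thresh, section_mm)
        return permutation_test(
            stat, sheets[0].stimulus_categories, n_perm=n_perm, seed=seed
        )
    if scheme != "positions":
        raise ValueError("scheme must be 'positions' or 'labels'")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    cats = sheets[0].categories
    ia, ib = cats.index(pair_1[0]), cats.index(pair_1[1])
    ja, jb = cats.index(pair_2[0]), cats.index(pair_2[1])
    pre = []
    for sh in sheets:
        if sh.categories != cats:
            raise ValueError("sheets disagree on category set")
        sel = unit_selectivity(sh, t_thresh=t_thresh).selective.astype(float)
        ext = np.asarray(sh.extent_mm, float)
        n_tiles = np.maximum(1, np.ceil(ext / section_mm - 1e-9).astype(int))
        idx = np.minimum((sh.positions // section_mm).astype(int), n_tiles - 1)
        flat = idx[:, 0] * n_tiles[1] + idx[:, 1]
        uniq = np.unique(flat)
        pre.append((sel, np.searchsorted(uniq, flat), uniq.size))

    def _diff(section_of_unit_per_sheet) -> float:
        diffs = []
        for (sel, _, n_sec), sec in zip(pre, section_of_unit_per_sheet):
            sums = np.zeros((n_sec, len(cats)))
            np.add.at(sums, sec, sel)
            counts = np.bincount(sec, minlength=n_sec)[:, None].astype(float)
            fr = sums / counts
            vals = []
            for i, j in ((ia, ib), (ja, jb)):
                if fr[:, i].std() == 0 or fr[:, j].std() == 0:
                    return np.nan
                vals.append((float(np.corrcoef(fr[:, i], fr[:, j])[0, 1]) + 1) / 2)
            diffs.append(vals[0] - vals[1])
        return float(np.mean(diffs))

    observed = _diff([sec for _, sec, _ in pre])
    if not np.isfinite(observed):
        raise UninformativeMapError("observed overlap scores undefined")
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _diff([rng.permutation(sec) for _, sec, _ in pre])
    bad = int((~np.isfinite(null)).sum())
    if bad > 0.10 * n_perm:
        raise ValueError(
            f"statistic undefined on {bad}/{n_perm} permutations; "
            "null distribution unreliable"
        )
    ok = null[np.isfinite(null)]
    return PermutationResult(
        observed=observed,
        p=permutation_p(int((ok >= observed).sum()), n_perm),
        n_perm=n_perm,
        n_undefined=bad,
        alternative="greater",
    )
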