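"""End-to-end orchestration of the synthetic demonstration run.

Stages (dependency order): simulate -> selectivity -> vector -> rsa ->
indices -> unitsheet -> report. Each stage reads only files earlier stages
wrote (so stages can be re-run independently), writes TSV/NIfTI/PNG outputs
under the configured output directory, and appends an entry — config hash,
stage seed, sha256 per file — to an append-only ``provenance.json``. All
randomness derives from the single root seed via a documented SeedSequence
scheme (stage seed = SeedSequence([root_seed, stage_ordinal])), so any
subset of stages reproduces bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from .indices import index_activation_correlation, index_profile
from .roivector import (
    default_region_split,
    default_synthetic_anchors,
    extract_sphere_patterns,
    extract_sphere_profiles,
    fit_roi_spline,
    peak_analysis,
)
from .rsa import (
    mds_embed,
    model_fit_profile,
    model_profile_correlation,
    model_rdm_correlations,
    model_rdm_from_ratings,
    model_rdm_from_shape,
    neural_rdm,
    noise_ceiling_profile,
    sphere_rdms,
)
from .selectivity import (
    compute_group_tmap,
    overlap_table,
    threshold_and_cluster,
    visual_mask,
)
from .synthgen import (
    CATEGORIES,
    N_STIMULI_PER_CATEGORY,
    PlantedTopography,
    ShapeSpec,
    UnitSheetConfig,
    generate_dataset,
    generate_ratings,
    generate_stimulus_masks,
    generate_unit_sheet,
)
from .unitsheet import (
    build_section_grid,
    overlap_contrast,
    overlap_score_matrix,
    top_k_profile,
    unit_selectivity,
)

__all__ = ["RunConfig", "DependencyError", "IntegrityError", "STAGES", "run_pipeline", "report"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "selectivity", "vector", "rsa", "indices", "unitsheet", "report")

#: What each stage needs on disk before it can run (relative to out_dir).
_REQUIRES: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "selectivity": ("betas",),
    "vector": ("betas", "anchors.tsv"),
    "rsa": ("betas", "anchors.tsv", "ratings_action.tsv", "ratings_animacy.tsv", "masks"),
    "indices": ("betas", "anchors.tsv", "profiles.tsv"),
    "unitsheet": ("sheets",),
    "report": ("provenance.json",),
}


class DependencyError(RuntimeError):
    """A requested stage's inputs are missing; the message lists the gaps."""


class IntegrityError(RuntimeError):
    """A recorded output no longer matches its provenance checksum."""


@dataclass
class RunConfig:
    """All pipeline parameters; serialized into every output's sidecar."""

    out_dir: Path = Path("otctopo-run")
    seed: int = 0
    # synthetic study conditions
    n_subjects: int = 18
    n_runs: int = 8
    grid_shape: tuple[int, int, int] = (36, 10, 10)
    voxel_size_mm: float = 3.0
    noise_sd: float = 0.25
    rating_sd: float = 0.5
    n_sheets: int = 5
    sheet_units: int = 2500
    sheet_extent_mm: float = 50.0
    # analysis parameters
    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    n_perm_cluster: int = 1000
    connectivity: int = 18
    sphere_radius_mm: float = 6.0
    sphere_spacing_mm: float = 3.0
    t_thresh: float = 3.5
    top_k: int = 50
    n_perm: int = 10_000
    baseline_p: float = 0.05
    m_peak: int = 5
    m_model_pairs: int = 3
    m_index_activation: int = 6
    neural_to_dissimilarity: bool = True

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        checks = [
            (self.n_subjects >= 2, "n_subjects must be >= 2"),
            (self.n_runs >= 2, "n_runs must be >= 2"),
            (0 < self.voxel_p < 1, "voxel_p must be in (0, 1)"),
            (0 < self.cluster_alpha < 1, "cluster_alpha must be in (0, 1)"),
            (0 < self.baseline_p < 1, "baseline_p must be in (0, 1)"),
            (self.n_perm_cluster >= 1000, "n_perm_cluster must be >= 1000"),
            (self.n_perm >= 1, "n_perm must be >= 1"),
            (self.connectivity in (6, 18, 26), "connectivity must be 6, 18, or 26"),
            (self.sphere_radius_mm > 0, "sphere_radius_mm must be positive"),
            (self.sphere_spacing_mm > 0, "sphere_spacing_mm must be positive"),
            (self.noise_sd >= 0, "noise_sd must be >= 0"),
            (self.rating_sd >= 0, "rating_sd must be >= 0"),
            (self.top_k >= 1, "top_k must be >= 1"),
            (self.n_sheets >= 2, "n_sheets must be >= 2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def topography(self) -> PlantedTopography:
        return PlantedTopography(
            grid_shape=self.grid_shape,
            voxel_size_mm=self.voxel_size_mm,
            noise_sd=self.noise_sd,
            n_runs=self.n_runs,
            n_subjects=self.n_subjects,
        )

    def stage_seed(self, stage: str) -> int:
        ordinal = STAGES.index(stage)
        ss = np.random.SeedSequence([int(self.seed), ordinal])
        return int(ss.generate_state(1)[0] % (2**31))


def _meta(config: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seed": config.stage_seed(stage),
        "config": config.to_dict(),
    }


def _append_provenance(config: RunConfig, stage: str, files: Sequence[Path]) -> None:
    path = config.out_dir / "provenance.json"
    log = json.loads(path.read_text()) if path.exists() else []
    log.append(
        {
            "stage": stage,
            "config_hash": config.config_hash(),
            "stage_seed": config.stage_seed(stage),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "files": {
                str(Path(f).relative_to(config.out_dir)): oio.sha256_of(f)
                for f in files
            },
        }
    )
    path.write_text(json.dumps(log, indent=1))


def _check_requirements(config: RunConfig, stage: str) -> None:
    missing = [
        req
        for req in _REQUIRES[stage]
        if not (config.out_dir / req).exists()
    ]
    if missing:
        raise DependencyError(
            f"stage {stage!r} needs outputs that are not present: "
            f"{', '.join(missing)} — run the producing stage(s) first "
            f"(order: {' -> '.join(STAGES)})"
        )


def _load_subjects(config: RunConfig):
    betas_dir = config.out_dir / "betas"
    subs = sorted({p.name.split("_")[0] for p in betas_dir.glob("sub-*_run-*_cond-*.nii*")})
    return [oio.load_subject_betas(betas_dir, s, CATEGORIES) for s in subs]


def _vector_for(config: RunConfig):
    anchors = oio.load_anchors(config.out_dir / "anchors.tsv")
    return fit_roi_spline(
        anchors, radius_mm=config.sphere_radius_mm, spacing_mm=config.sphere_spacing_mm
    )


def _default_shape_specs() -> list[ShapeSpec]:
    """One mask per stimulus: per-category shape families with size jitter.

    Body parts are round-ish ellipses; tools are elongated rectangles;
    manipulable objects mildly elongated; non-manipulable large squares —
    enough structure for a non-degenerate shape model.
    """
    specs = []
    families = {
        "faces": ("ellipse", (60.0, 52.0)),
        "bodies": ("ellipse", (80.0, 40.0)),
        "hands": ("ellipse", (70.0, 45.0)),
        "tools": ("rectangle", (180.0, 36.0)),
        "manipulable": ("rectangle", (120.0, 60.0)),
        "nonmanipulable": ("rectangle", (130.0, 110.0)),
    }
    for cat, (kind, (a, b)) in families.items():
        for i in range(N_STIMULI_PER_CATEGORY):
            scale = 1.0 + 0.02 * (i - N_STIMULI_PER_CATEGORY / 2) / N_STIMULI_PER_CATEGORY
            specs.append(
                ShapeSpec(
                    kind=kind,
                    size_px=(a * scale, b * scale),
                    orientation_deg=15.0 * (i % 3),
                    name=f"{cat}_{i:02d}",
                )
            )
    return specs


def _stage_simulate(config: RunConfig) -> list[Path]:
    seed = config.stage_seed("simulate")
    topo = config.topography()
    files: list[Path] = []
    subjects = generate_dataset(topo, seed)
    for sub in subjects:
        files += oio.save_subject_betas(sub, config.out_dir / "betas")
    files.append(oio.save_anchors(default_synthetic_anchors(topo), config.out_dir / "anchors.tsv"))
    for dim in ("action", "animacy"):
        ratings = generate_ratings(sd=config.rating_sd, seed=seed + 1, dimension=dim)
        files.append(oio.save_ratings(ratings, config.out_dir / f"ratings_{dim}.tsv"))
    masks = generate_stimulus_masks(_default_shape_specs())
    files += oio.save_masks(masks, config.out_dir / "masks")
    # clustered sheets: animate and inanimate categories form two separate
    # territories (no hand-tool co-clustering) — the network-like condition
    ext = config.sheet_extent_mm
    assignments = {
        "faces": ((0.3 * ext, 0.28 * ext), 0.16 * ext),
        "bodies": ((0.22 * ext, 0.42 * ext), 0.16 * ext),
        "hands": ((0.38 * ext, 0.40 * ext), 0.16 * ext),
        "tools": ((0.68 * ext, 0.66 * ext), 0.18 * ext),
        "manipulable": ((0.76 * ext, 0.56 * ext), 0.18 * ext),
        "nonmanipulable": ((0.64 * ext, 0.76 * ext), 0.18 * ext),
    }
    cfg = UnitSheetConfig(
        sheet_extent_mm=(ext, ext),
        n_units=config.sheet_units,
        mode="clustered",
        cluster_assignments=assignments,
    )
    sheet_dir = config.out_dir / "sheets"
    sheet_dir.mkdir(parents=True, exist_ok=True)
    for i in range(config.n_sheets):
        sheet = generate_unit_sheet(cfg, seed=seed + 100 + i)
        files.append(oio.save_unit_sheet(sheet, sheet_dir / f"sheet-{i + 1:02d}.tsv"))
    return files


def _stage_selectivity(config: RunConfig) -> list[Path]:
    subjects = _load_subjects(config)
    anatomical = np.ones(subjects[0].grid_shape, bool)
    vmask = visual_mask(subjects, anatomical, baseline_p=config.baseline_p)
    files = [oio.save_nifti(vmask.astype(np.float32), subjects[0].affine, config.out_dir / "visual_mask.nii.gz")]
    clusters = {}
    seed = config.stage_seed("selectivity")
    for i, cat in enumerate(CATEGORIES):
        tmap = compute_group_tmap(subjects, cat)
        files.append(
            oio.save_nifti(
                np.nan_to_num(tmap.t), subjects[0].affine, config.out_dir / f"tmap_{cat}.nii.gz"
            )
        )
        cs = threshold_and_cluster(
            tmap,
            voxel_p=config.voxel_p,
            cluster_alpha=config.cluster_alpha,
            n_perm=config.n_perm_cluster,
            connectivity=config.connectivity,
            mask=vmask,
            seed=seed + i,
        )
        clusters[cat] = cs
        files.append(
            oio.save_nifti(cs.labels.astype(np.float32), subjects[0].affine, config.out_dir / f"clusters_{cat}.nii.gz")
        )
    files.append(
        oio.write_table(overlap_table(clusters), config.out_dir / "overlap.tsv", _meta(config, "selectivity"))
    )
    return files


def _stage_vector(config: RunConfig) -> list[Path]:
    subjects = _load_subjects(config)
    vector = _vector_for(config)
    files = [oio.write_table(vector.to_frame(), config.out_dir / "spheres.tsv", _meta(config, "vector"))]
    profiles = extract_sphere_profiles(subjects, vector)
    files.append(oio.write_table(profiles.to_frame(), config.out_dir / "profiles.tsv", _meta(config, "vector")))
    # split-half peak analysis: peaks selected on odd runs, tested on even
    runs = np.arange(subjects[0].n_runs)
    sel = extract_sphere_profiles(subjects, vector, runs=runs[1::2])
    test = extract_sphere_profiles(subjects, vector, runs=runs[0::2])
    peaks = peak_analysis(test, default_region_split(vector), selection_profiles=sel, m=config.m_peak)
    rows = []
    for (region, cat), pr in peaks.items():
        for _, row in pr.contrasts.iterrows():
            rows.append(
                (region, cat, pr.peak_sphere, pr.peak_arc_mm, row["other"], row["t"], row["p"], row["p_bonferroni"], row["significant"])
            )
    df = pd.DataFrame(
        rows,
        columns=["region", "category", "peak_sphere", "peak_arc_mm", "other", "t", "p", "p_bonferroni", "significant"],
    )
    files.append(oio.write_table(df, config.out_dir / "peaks.tsv", _meta(config, "vector")))
    return files


def _model_rdms(config: RunConfig):
    action = oio.load_ratings(config.out_dir / "ratings_action.tsv")
    animacy = oio.load_ratings(config.out_dir / "ratings_animacy.tsv")
    masks = oio.load_masks(config.out_dir / "masks")
    category_map = {stim: stim.rsplit("_", 1)[0] for stim in masks}
    shape_rdm, shape_table = model_rdm_from_shape(masks, category_map, categories=CATEGORIES)
    return {
        "animacy": model_rdm_from_ratings(animacy, level="category"),
        "action": model_rdm_from_ratings(action, level="category"),
        "shape": shape_rdm,
    }, shape_table


def _stage_rsa(config: RunConfig) -> list[Path]:
    subjects = _load_subjects(config)
    vector = _vector_for(config)
    patterns, _ = extract_sphere_patterns(subjects, vector)
    rdms = sphere_rdms(patterns)
    models, shape_table = _model_rdms(config)
    meta = _meta(config, "rsa")
    files = [oio.write_table(shape_table, config.out_dir / "aspect_ratios.tsv", meta)]
    for name, rdm in models.items():
        files.append(oio.save_rdm(rdm, config.out_dir / f"model_rdm_{name}.tsv", source=name))
    files.append(oio.write_table(model_rdm_correlations(models), config.out_dir / "model_correlations.tsv", meta))
    fits = model_fit_profile(
        rdms, models, subjects=[s.subject for s in subjects],
        neural_to_dissimilarity=config.neural_to_dissimilarity,
    )
    files.append(oio.write_table(fits.to_frame(), config.out_dir / "rsa_fits.tsv", meta))
    group = pd.DataFrame(
        {
            "sphere": np.arange(fits.fits.shape[1]),
            **{
                f"{m}_mean": fits.group_mean[:, j]
                for j, m in enumerate(fits.models)
            },
            **{
                f"{m}_significant": fits.significant[:, j]
                for j, m in enumerate(fits.models)
            },
            "noise_ceiling_lower": noise_ceiling_profile(rdms),
        }
    )
    files.append(oio.write_table(group, config.out_dir / "rsa_group.tsv", meta))
    pair_rows = []
    names = list(fits.models)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            st = model_profile_correlation(fits, a, b, m=config.m_model_pairs)
            pair_rows.append((a, b, st.mean_r, st.t, st.df, st.p, st.p_bonferroni, st.significant))
    files.append(
        oio.write_table(
            pd.DataFrame(pair_rows, columns=["model_a", "model_b", "mean_r", "t", "df", "p", "p_bonferroni", "significant"]),
            config.out_dir / "model_profile_correlations.tsv",
            meta,
        )
    )
    # MDS of the across-subject, across-sphere average neural RDM
    stacks = [r.values for subj in rdms for r in subj if r is not None]
    mean_sim = np.mean(stacks, axis=0)
    np.fill_diagonal(mean_sim, 1.0)
    from .rsa import RDM

    mean_rdm = RDM(labels=CATEGORIES, values=mean_sim, kind="similarity").to_dissimilarity()
    coords = mds_embed(mean_rdm, dims=2)
    files.append(
        oio.write_table(
            pd.DataFrame({"category": CATEGORIES, "dim1": coords[:, 0], "dim2": coords[:, 1]}),
            config.out_dir / "mds.tsv",
            meta,
        )
    )
    return files


def _stage_indices(config: RunConfig) -> list[Path]:
    subjects = _load_subjects(config)
    vector = _vector_for(config)
    patterns, _ = extract_sphere_patterns(subjects, vector)
    rdms = sphere_rdms(patterns)
    profiles = extract_sphere_profiles(subjects, vector)
    meta = _meta(config, "indices")
    prof = index_profile(rdms, subjects=[s.subject for s in subjects])
    files = [
        oio.write_table(prof.to_frame(), config.out_dir / "index_values.tsv", meta),
        oio.write_table(prof.group_frame(), config.out_dir / "index_group.tsv", meta),
    ]
    rows = []
    for cat in CATEGORIES:
        st = index_activation_correlation(
            prof, profiles, cat, body_part="hands", kind="effector", m=config.m_index_activation
        )
        rows.append(("hands", "effector", cat, st.mean_r, st.t, st.p, st.p_bonferroni, st.significant))
    files.append(
        oio.write_table(
            pd.DataFrame(rows, columns=["body_part", "index_kind", "category", "mean_r", "t", "p", "p_bonferroni", "significant"]),
            config.out_dir / "index_activation.tsv",
            meta,
        )
    )
    return files


def _stage_unitsheet(config: RunConfig) -> list[Path]:
    sheet_paths = sorted((config.out_dir / "sheets").glob("sheet-*.tsv"))
    sheets = [oio.load_unit_sheet(p) for p in sheet_paths]
    meta = _meta(config, "unitsheet")
    files = []
    sel_frames, score_frames, topk_rows = [], [], []
    for p, sheet in zip(sheet_paths, sheets):
        selmap = unit_selectivity(sheet, t_thresh=config.t_thresh)
        df = selmap.to_frame()
        df.insert(0, "sheet", p.stem)
        sel_frames.append(df)
        grid = build_section_grid(sheet, selmap)
        sc = overlap_score_matrix(grid).reset_index(names="category_a").melt(
            id_vars="category_a", var_name="category_b", value_name="score"
        )
        sc.insert(0, "sheet", p.stem)
        score_frames.append(sc)
        for cat in sheet.categories:
            prof = top_k_profile(selmap, sheet, cat, k=min(config.top_k, sheet.n_units))
            for resp_cat, v in prof.items():
                topk_rows.append((p.stem, cat, resp_cat, v))
    files.append(oio.write_table(pd.concat(sel_frames, ignore_index=True), config.out_dir / "unit_selectivity.tsv", meta))
    files.append(oio.write_table(pd.concat(score_frames, ignore_index=True), config.out_dir / "overlap_scores.tsv", meta))
    files.append(
        oio.write_table(
            pd.DataFrame(topk_rows, columns=["sheet", "selected_for", "category", "mean_response"]),
            config.out_dir / "topk_profiles.tsv",
            meta,
        )
    )
    res = overlap_contrast(
        sheets, ("hands", "tools"), ("hands", "manipulable"),
        n_perm=config.n_perm, seed=config.stage_seed("unitsheet"),
    )
    files.append(
        oio.write_table(
            pd.DataFrame(
                [("hands-tools vs hands-manipulable", res.observed, res.p, res.n_perm)],
                columns=["contrast", "score_difference", "p", "n_perm"],
            ),
            config.out_dir / "overlap_contrast.tsv",
            meta,
        )
    )
    return files


def verify_provenance(out_dir: Path) -> dict[str, str]:
    """Check every recorded output against its checksum; raise on mismatch.

    Returns the latest recorded checksum per file. Files recorded by multiple
    stage entries are checked against the most recent record."""
    path = Path(out_dir) / "provenance.json"
    if not path.exists():
        raise DependencyError("no provenance.json: nothing to report on")
    latest: dict[str, str] = {}
    for entry in json.loads(path.read_text()):
        latest.update(entry.get("files", {}))
    for rel, digest in latest.items():
        f = Path(out_dir) / rel
        if not f.exists():
            raise IntegrityError(f"recorded output missing: {rel}")
        if oio.sha256_of(f) != digest:
            raise IntegrityError(f"checksum mismatch for {rel}: file was modified after its stage ran")
    return latest


def report(config: RunConfig) -> list[Path]:
    """Human-readable summary (markdown + figures) of whatever stages ran.

    Verifies provenance checksums first and refuses to render from tampered
    outputs; panels whose inputs are absent are skipped with a notice.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = config.out_dir
    verify_provenance(out)
    files: list[Path] = []
    lines = ["# otctopo synthetic run report", ""]
    lines.append(f"Config hash: `{config.config_hash()}`; root seed: {config.seed}.")
    lines.append("")

    def _have(name: str) -> bool:
        return (out / name).exists()

    if _have("overlap.tsv"):
        df = pd.read_csv(out / "overlap.tsv", sep="\t")
        lines += ["## Category cluster overlap", "", df.to_markdown(index=False), ""]
    else:
        lines += ["## Category cluster overlap", "", "_skipped: selectivity stage has not run_", ""]

    if _have("profiles.tsv"):
        df = pd.read_csv(out / "profiles.tsv", sep="\t")
        g = df.groupby(["sphere", "condition"])["norm_beta"].mean().unstack()
        fig, ax = plt.subplots(figsize=(7, 4))
        for cat in g.columns:
            ax.plot(g.index, g[cat], label=cat)
        ax.set_xlabel("sphere along vector")
        ax.set_ylabel("normalized beta")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "fig_profiles.png", dpi=110)
        plt.close(fig)
        files.append(out / "fig_profiles.png")
        lines += ["## Vector-of-ROIs profiles", "", "![profiles](fig_profiles.png)", ""]
    else:
        lines += ["## Vector-of-ROIs profiles", "", "_skipped: vector stage has not run_", ""]

    if _have("rsa_group.tsv"):
        df = pd.read_csv(out / "rsa_group.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(7, 4))
        for m in ("animacy", "action", "shape"):
            ax.plot(df["sphere"], df[f"{m}_mean"], label=m)
        ax.plot(df["sphere"], df["noise_ceiling_lower"], "k--", label="noise ceiling (lower)")
        ax.set_xlabel("sphere along vector")
        ax.set_ylabel("model-brain r")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "fig_rsa.png", dpi=110)
        plt.close(fig)
        files.append(out / "fig_rsa.png")
        lines += ["## RSA model fits", "", "![rsa](fig_rsa.png)", ""]

    if _have("index_group.tsv"):
        df = pd.read_csv(out / "index_group.tsv", sep="\t")
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        for ax, kind in zip(axes, ("effector", "grasp")):
            sub = df[df["index_kind"] == kind]
            for bp in sub["body_part"].unique():
                s = sub[sub["body_part"] == bp]
                ax.plot(s["sphere"], s["mean"], label=bp)
            ax.axhline(0, color="k", lw=0.5)
            ax.set_title(f"{kind} index")
            ax.set_xlabel("sphere")
        axes[0].set_ylabel("index value")
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "fig_indices.png", dpi=110)
        plt.close(fig)
        files.append(out / "fig_indices.png")
        lines += ["## Effector and grasp indices", "", "![indices](fig_indices.png)", ""]

    if _have("overlap_scores.tsv"):
        df = pd.read_csv(out / "overlap_scores.tsv", sep="\t")
        mean_scores = df.groupby(["category_a", "category_b"])["score"].mean().unstack()
        lines += ["## Unit-sheet section overlap scores (mean across sheets)", "", mean_scores.round(3).to_markdown(), ""]
        if _have("overlap_contrast.tsv"):
            dc = pd.read_csv(out / "overlap_contrast.tsv", sep="\t")
            lines += [dc.to_markdown(index=False), ""]

    if len([s for s in ("overlap.tsv", "profiles.tsv", "rsa_group.tsv", "index_group.tsv", "overlap_scores.tsv") if _have(s)]) == 0:
        lines += ["_No analysis outputs present; report is empty._", ""]

    md = out / "report.md"
    md.write_text("\n".join(lines))
    files.append(md)
    return files


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "selectivity": _stage_selectivity,
    "vector": _stage_vector,
    "rsa": _stage_rsa,
    "indices": _stage_indices,
    "unitsheet": _stage_unitsheet,
}


def run_pipeline(config: RunConfig, stages: Sequence[str] = STAGES) -> dict[str, list[Path]]:
    """Execute the requested stages in dependency order.

    Raises :class:`DependencyError` (listing the gap) when a stage's inputs
    from earlier stages are absent. Stage outputs and checksums are appended
    to ``provenance.json``; re-running with the same config and seed
    reproduces deterministic outputs bit-identically.
    """
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    ordered = [s for s in STAGES if s in stages]
    config.out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, list[Path]] = {}
    for stage in ordered:
        _check_requirements(config, stage)
        t0 = time.time()
        logger.info("stage %s starting", stage)
        if stage == "report":
            files = report(config)
        else:
            files = _STAGE_FUNCS[stage](config)
            _append_provenance(config, stage, files)
        logger.info("stage %s done in %.1fs (%d files)", stage, time.time() - t0, len(files))
        print(f"[otctopo] {stage}: {len(files)} files in {time.time() - t0:.1f}s", file=sys.stderr)
        results[stage] = files
    return results
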