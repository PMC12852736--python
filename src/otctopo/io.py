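"""Standard-format I/O: NIfTI betas, TSV tables, PNG masks, JSON sidecars.

File layouts:
  betas       sub-XX_run-YY_cond-<label>.nii.gz (one volume per file)
  ratings     TSV: stimulus_id, category, dimension, value
  masks       PNG, foreground 255 / background 0
  unit sheet  TSV: unit_id, x_mm, y_mm, then one response column per
              stimulus; column names <category>_<nn> carry the category
  RDMs        TSV matrix with label header row/column + JSON sidecar
  anchors     TSV: name, x_mm, y_mm, z_mm, order
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .roivector import AnchorList
from .rsa import RDM
from .synthgen import SubjectBetas
from .unitsheet import UnitSheet

__all__ = [
    "save_subject_betas",
    "load_subject_betas",
    "save_nifti",
    "load_nifti",
    "save_ratings",
    "load_ratings",
    "save_masks",
    "load_masks",
    "save_unit_sheet",
    "load_unit_sheet",
    "load_unit_sheet_mtx",
    "save_rdm",
    "load_rdm",
    "save_anchors",
    "load_anchors",
    "write_table",
    "sha256_of",
]

_BETA_RE = re.compile(r"sub-(?P<sub>\w+?)_run-(?P<run>\d+)_cond-(?P<cond>[\w]+)\.nii(\.gz)?$")


def save_nifti(values: np.ndarray, affine: np.ndarray, path: Path | str) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(values, np.float32), np.asarray(affine)), path)
    return path


def load_nifti(path: Path | str):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_subject_betas(subject: SubjectBetas, outdir: Path | str) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in range(subject.n_runs):
        for j, cond in enumerate(subject.conditions):
            name = f"sub-{subject.subject.removeprefix('sub-')}_run-{run + 1:02d}_cond-{cond}.nii.gz"
            paths.append(save_nifti(subject.data[run, j], subject.affine, outdir / name))
    return paths


def load_subject_betas(
    directory: Path | str, subject: str, conditions: Sequence[str]
) -> SubjectBetas:
    directory = Path(directory)
    sub_id = subject.removeprefix("sub-")
    files: dict[tuple[int, str], Path] = {}
    for p in directory.glob(f"sub-{sub_id}_run-*_cond-*.nii*"):
        m = _BETA_RE.search(p.name)
        if m and m.group("sub") == sub_id:
            files[(int(m.group("run")), m.group("cond"))] = p
    if not files:
        raise FileNotFoundError(f"no beta volumes for {subject} in {directory}")
    runs = sorted({r for r, _ in files})
    vols = []
    affine = None
    for r in runs:
        per_cond = []
        for c in conditions:
            if (r, c) not in files:
                raise FileNotFoundError(f"missing sub-{sub_id} run {r} condition {c}")
            vals, aff = load_nifti(files[(r, c)])
            affine = aff if affine is None else affine
            per_cond.append(vals)
        vols.append(np.stack(per_cond))
    return SubjectBetas(
        data=np.stack(vols), affine=affine, conditions=tuple(conditions), subject=subject
    )


def save_ratings(ratings: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    ratings.to_csv(path, sep="\t", index=False)
    return path


def load_ratings(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_masks(masks: Mapping[str, np.ndarray], outdir: Path | str) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, mask in masks.items():
        p = outdir / f"{name}.png"
        iio.imwrite(p, (np.asarray(mask, bool) * np.uint8(255)))
        paths.append(p)
    return paths


def load_masks(directory: Path | str) -> dict[str, np.ndarray]:
    out = {}
    for p in sorted(Path(directory).glob("*.png")):
        out[p.stem] = np.asarray(iio.imread(p)) > 127
    return out


def save_unit_sheet(sheet: UnitSheet, path: Path | str) -> Path:
    path = Path(path)
    cols = {"unit_id": np.arange(sheet.n_units)}
    cols["x_mm"] = sheet.positions[:, 0]
    cols["y_mm"] = sheet.positions[:, 1]
    counts: dict[str, int] = {}
    for j, cat in enumerate(sheet.stimulus_categories):
        i = counts.get(cat, 0)
        counts[cat] = i + 1
        cols[f"{cat}_{i:02d}"] = sheet.responses[:, j]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# extent_mm\t{sheet.extent_mm[0]}\t{sheet.extent_mm[1]}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def load_unit_sheet(path: Path | str) -> UnitSheet:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# extent_mm"):
            parts = first.strip().split("\t")
            extent = (float(parts[1]), float(parts[2]))
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
            extent = None
    pos = df[["x_mm", "y_mm"]].to_numpy(float)
    stim_cols = [c for c in df.columns if c not in ("unit_id", "x_mm", "y_mm")]
    cats = tuple(c.rsplit("_", 1)[0] for c in stim_cols)
    if extent is None:
        extent = (float(pos[:, 0].max()), float(pos[:, 1].max()))
    return UnitSheet(
        positions=pos,
        responses=df[stim_cols].to_numpy(float),
        stimulus_categories=cats,
        extent_mm=extent,
    )


def load_unit_sheet_mtx(
    matrix_path: Path | str,
    positions_path: Path | str,
    stimulus_categories: Sequence[str],
    extent_mm: tuple[float, float] | None = None,
) -> UnitSheet:
    """Real network-layer activations: stimulus x unit MatrixMarket matrix
    plus a TSV positions sidecar (unit_id, x_mm, y_mm)."""
    from scipy.io import mmread

    mat = mmread(str(matrix_path))
    resp = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    pos_df = pd.read_csv(positions_path, sep="\t").sort_values("unit_id")
    pos = pos_df[["x_mm", "y_mm"]].to_numpy(float)
    if resp.shape[0] == len(stimulus_categories) and resp.shape[1] == len(pos):
        resp = resp.T  # stimulus x unit -> unit x stimulus
    if extent_mm is None:
        extent_mm = (float(pos[:, 0].max()), float(pos[:, 1].max()))
    return UnitSheet(
        positions=pos,
        responses=resp,
        stimulus_categories=tuple(stimulus_categories),
        extent_mm=extent_mm,
    )


def save_rdm(rdm: RDM, path: Path | str, source: str = "") -> Path:
    path = Path(path)
    rdm.to_frame().to_csv(path, sep="\t", index_label="label")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"kind": rdm.kind, "labels": list(rdm.labels), "source": source}, indent=1
        )
    )
    return path


def load_rdm(path: Path | str) -> RDM:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="label")
    sidecar = path.with_suffix(path.suffix + ".json")
    kind = "dissimilarity"
    if sidecar.exists():
        kind = json.loads(sidecar.read_text())["kind"]
    return RDM(labels=tuple(df.columns), values=df.to_numpy(float), kind=kind)


def save_anchors(anchors: AnchorList, path: Path | str) -> Path:
    path = Path(path)
    anchors.to_frame().to_csv(path, sep="\t", index=False)
    return path


def load_anchors(path: Path | str) -> AnchorList:
    return AnchorList.from_frame(pd.read_csv(path, sep="\t"))


def write_table(df: pd.DataFrame, path: Path | str, meta: Mapping | None = None) -> Path:
    """TSV plus a JSON sidecar carrying provenance metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    if meta is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(dict(meta), indent=1, default=str))
    return path


def sha256_of(path: Path | str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
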