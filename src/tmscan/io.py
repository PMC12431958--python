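"""File formats: CSV grids with JSON sidecars, spectra containers.

Grid-valued data (phantoms, reconstructed images, masks) are stored as plain
CSV matrices — rows are y (row 0 is the y = 0 chest-wall edge), columns are x —
with a JSON sidecar carrying the grid spec and scan metadata.  Per-scan spectra
go into a single .npz container with a JSON sidecar describing sweep and
geometry.  All round-trips are lossless to float repr precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grid import GridSpec
from .phantom import BreastPhantom, TumorSpec
from .recon import ReconImage
from .segment import SegmentationResult

_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_matrix(path: Path, arr: np.ndarray) -> None:
    np.savetxt(path, arr, delimiter=",", fmt=_FMT)


def _read_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def _grid_to_dict(grid: GridSpec) -> dict:
    return {"width_mm": grid.width_mm, "height_mm": grid.height_mm, "pixel_mm": grid.pixel_mm}


def _grid_from_dict(d: dict) -> GridSpec:
    return GridSpec(**d)


def write_phantom(path: str | Path, phantom: BreastPhantom) -> None:
    path = Path(path)
    _write_matrix(path, phantom.epsilon_map)
    meta = {
        "kind": "phantom",
        "grid": _grid_to_dict(phantom.grid),
        "view": phantom.view,
        "density_category": phantom.density_category,
        "separation_mm": phantom.separation_mm,
        "seed": phantom.seed,
        "tumor": None
        if phantom.tumor is None
        else {
            "center_mm": list(phantom.tumor.center_mm),
            "semi_axes_mm": list(phantom.tumor.semi_axes_mm),
            "permittivity": phantom.tumor.permittivity,
        },
        "breast_mask_rle": _mask_to_rle(phantom.breast_mask_true),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_phantom(path: str | Path) -> BreastPhantom:
    path = Path(path)
    if not _sidecar(path).exists():
        raise FileNotFoundError(f"missing sidecar {_sidecar(path)}")
    meta = json.loads(_sidecar(path).read_text())
    grid = _grid_from_dict(meta["grid"])
    eps = _read_matrix(path)
    if eps.shape != grid.shape:
        raise ValueError(f"matrix shape {eps.shape} does not match grid {grid.shape}")
    tumor = None
    if meta.get("tumor"):
        t = meta["tumor"]
        tumor = TumorSpec(tuple(t["center_mm"]), tuple(t["semi_axes_mm"]), t["permittivity"])
    return BreastPhantom(
        grid=grid,
        epsilon_map=eps,
        breast_mask_true=_rle_to_mask(meta["breast_mask_rle"], grid.shape),
        view=meta["view"],
        density_category=meta["density_category"],
        separation_mm=meta["separation_mm"],
        tumor=tumor,
        seed=meta.get("seed", 0),
    )


def _mask_to_rle(mask: np.ndarray) -> list[int]:
    """Run-length encode a boolean grid (flattened row-major, starts with a
    run of False)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    runs = []
    current, count = False, 0
    for v in flat:
        if v == current:
            count += 1
        else:
            runs.append(count)
            current, count = v, 1
    runs.append(count)
    return runs


def _rle_to_mask(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for run in runs:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    if pos != flat.size:
        raise ValueError("mask run-length does not match grid size")
    return flat.reshape(shape)


def write_image(path: str | Path, image: ReconImage) -> None:
    path = Path(path)
    _write_matrix(path, image.epsilon_map)
    meta = {
        "kind": "recon_image",
        "grid": _grid_to_dict(image.grid),
        "view": image.view,
        "subject_id": image.subject_id,
        "separation_mm": image.separation_mm,
        "metadata": image.metadata,
        "coverage_rle": _coverage_to_runs(image.coverage),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_image(path: str | Path) -> ReconImage:
    path = Path(path)
    if not _sidecar(path).exists():
        raise FileNotFoundError(f"missing sidecar {_sidecar(path)}")
    meta = json.loads(_sidecar(path).read_text())
    grid = _grid_from_dict(meta["grid"])
    eps = _read_matrix(path)
    if eps.shape != grid.shape:
        raise ValueError(f"matrix shape {eps.shape} does not match grid {grid.shape}")
    return ReconImage(
        grid=grid,
        epsilon_map=eps,
        coverage=_runs_to_coverage(meta["coverage_rle"], grid.shape),
        separation_mm=meta["separation_mm"],
        view=meta.get("view", ""),
        subject_id=meta.get("subject_id", ""),
        metadata=meta.get("metadata", {}),
    )


def _coverage_to_runs(cov: np.ndarray) -> list[list[int]]:
    """[value, run] pairs over the flattened coverage grid."""
    flat = np.asarray(cov, dtype=int).ravel()
    runs: list[list[int]] = []
    for v in flat:
        if runs and runs[-1][0] == int(v):
            runs[-1][1] += 1
        else:
            runs.append([int(v), 1])
    return runs


def _runs_to_coverage(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.concatenate([np.full(n, v, dtype=int) for v, n in runs]) if runs else np.zeros(0, int)
    if flat.size != int(np.prod(shape)):
        raise ValueError("coverage run-length does not match grid size")
    return flat.reshape(shape)


def write_segmentation(path: str | Path, result: SegmentationResult) -> None:
    """Segmentation summary as JSON plus the breast mask as CSV of 0/1."""
    path = Path(path)
    meta = {
        "kind": "segmentation",
        "cluster_means": list(result.cluster_means),
        "region_fractions": [float(f) for f in result.region_fractions],
        "breast_area_ratio": result.breast_area_ratio,
        "thresholds": list(result.config.thresholds),
    }
    path.write_text(json.dumps(meta, indent=1))
    np.savetxt(path.with_suffix(".mask.csv"), result.breast_mask.astype(int), delimiter=",", fmt="%d")


def write_spectra(path: str | Path, spectra: np.ndarray, references: np.ndarray, meta: dict) -> None:
    """Per-scan spectra container (.npz) with a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path, spectra=spectra, references=references)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_spectra(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        spectra, refs = data["spectra"], data["references"]
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return spectra, refs, meta
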