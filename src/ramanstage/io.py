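"""HDF5 persistence for hyperspectral cubes and PCA models.

Cube layout (one file per FOV): datasets ``/intensities`` (H x W x C) and
``/wavenumber_cm1`` (C); root attributes ``line``, ``organoid_id``,
``stage_weeks``, ``fov_id``, ``pitch_um``.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import h5py
import numpy as np

from .axes import WavenumberAxis
from .decompose import PCAModel
from .synth import HyperspectralCube


def save_cube(cube: HyperspectralCube, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("intensities", data=cube.intensities)
        f.create_dataset("wavenumber_cm1", data=cube.axis.values)
        f.attrs["line"] = cube.line
        f.attrs["organoid_id"] = cube.organoid_id
        f.attrs["stage_weeks"] = int(cube.stage_weeks)
        f.attrs["fov_id"] = cube.fov_id
        f.attrs["pitch_um"] = float(cube.pitch_um)


def load_cube(path: str | Path) -> HyperspectralCube:
    with h5py.File(path, "r") as f:
        return HyperspectralCube(
            intensities=np.asarray(f["intensities"]),
            axis=WavenumberAxis(np.asarray(f["wavenumber_cm1"])),
            line=str(f.attrs["line"]),
            organoid_id=str(f.attrs["organoid_id"]),
            stage_weeks=int(f.attrs["stage_weeks"]),
            fov_id=str(f.attrs["fov_id"]),
            pitch_um=float(f.attrs["pitch_um"]),
        )


def save_study(cubes: Iterable[HyperspectralCube], directory: str | Path) -> list[Path]:
    """One HDF5 file per cube, named cube_0000.h5, cube_0001.h5, ..."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, cube in enumerate(cubes):
        path = directory / f"cube_{i:04d}.h5"
        save_cube(cube, path)
        paths.append(path)
    return paths


def iter_study_files(directory: str | Path) -> Iterator[HyperspectralCube]:
    files = sorted(Path(directory).glob("cube_*.h5"))
    if not files:
        raise FileNotFoundError(f"no cube_*.h5 files in {directory}")
    for path in files:
        yield load_cube(path)


def save_pca(model: PCAModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mean_spectrum", data=model.mean_spectrum)
        f.create_dataset("loadings", data=model.loadings)
        f.create_dataset("scores", data=model.scores)
        f.create_dataset(
            "explained_variance_fraction", data=model.explained_variance_fraction
        )
        if model.axis is not None:
            f.create_dataset("wavenumber_cm1", data=model.axis.values)


def load_pca(path: str | Path) -> PCAModel:
    with h5py.File(path, "r") as f:
        axis = None
        if "wavenumber_cm1" in f:
            axis = WavenumberAxis(np.asarray(f["wavenumber_cm1"]))
        return PCAModel(
            mean_spectrum=np.asarray(f["mean_spectrum"]),
            loadings=np.asarray(f["loadings"]),
            scores=np.asarray(f["scores"]),
            explained_variance_fraction=np.asarray(
                f["explained_variance_fraction"]
            ),
            axis=axis,
        )
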