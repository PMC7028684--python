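"""File formats and spatial conventions used across the pipeline.

Conventions (fixed once, relied on everywhere):

* voxel indices are 0-based;
* world coordinates are millimetres, obtained via the 4x4 voxel-to-world
  affine;
* a world point belongs to the voxel ``floor(A^-1 p + 0.5)`` (nearest-voxel
  rule);
* streamlines are stored in world mm, matching common tractogram formats.

Volumes are NIfTI (via nibabel), tractograms TCK, meshes a plain ASCII OFF
dialect (with optional GIFTI export), tables TSV with an explicit header and
empty-string missing markers.
"""

from __future__ import annotations

import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mesh import SurfaceMesh

_EPS = 1e-6


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid shape, spacing and voxel-to-world affine (mm)."""

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size_mm",
                           tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "affine",
                           np.asarray(self.affine, dtype=float))
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        col_norms = np.linalg.norm(self.affine[:3, :3], axis=0)
        if not np.allclose(col_norms, self.voxel_size_mm, atol=_EPS):
            raise ValueError(
                f"voxel_size_mm {self.voxel_size_mm} inconsistent with "
                f"affine column norms {tuple(col_norms)}")

    @classmethod
    def from_spacing(cls, dims, voxel_size_mm, origin=(0.0, 0.0, 0.0)
                     ) -> "VolumeGeometry":
        """Axis-aligned geometry with the given spacing and world origin."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(voxel_size_mm)
        aff[:3, 3] = origin
        return cls(tuple(dims), tuple(voxel_size_mm), aff)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (ijk @ self.affine[:3, :3].T + self.affine[:3, 3]).squeeze()

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (xyz @ inv[:3, :3].T + inv[:3, 3]).squeeze()

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Owning voxel index under the nearest-voxel rule."""
        c = np.atleast_2d(self.world_to_voxel(xyz))
        return np.floor(c + 0.5).astype(np.int64).squeeze()

    def contains_index(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        ok = np.all((ijk >= 0) & (ijk < np.array(self.dims)), axis=1)
        return ok if ok.size > 1 else bool(ok[0])


# ---------------------------------------------------------------------------
# tractograms
# ---------------------------------------------------------------------------

@dataclass
class Tractogram:
    """Ordered 3-D point sequences in world mm with per-streamline attributes.

    ``length_mm`` is the sum of consecutive point distances;
    ``mean_anisotropy`` the arithmetic mean of FA interpolated along the
    streamline (filled by the tractography stage).
    """

    streamlines: list[np.ndarray]
    length_mm: np.ndarray = field(default=None)
    mean_anisotropy: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float)
                            for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
                raise ValueError("each streamline needs >= 2 3-D points")
        if self.length_mm is None:
            self.length_mm = np.array([streamline_length(s)
                                       for s in self.streamlines])
        else:
            self.length_mm = np.asarray(self.length_mm, dtype=float)
        if self.mean_anisotropy is not None:
            self.mean_anisotropy = np.asarray(self.mean_anisotropy,
                                              dtype=float)

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, idx) -> "Tractogram":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Tractogram(
            [self.streamlines[i] for i in idx],
            length_mm=self.length_mm[idx],
            mean_anisotropy=(None if self.mean_anisotropy is None
                             else self.mean_anisotropy[idx]))

    def endpoints(self) -> np.ndarray:
        """(n, 2, 3) array of first and last points."""
        if not self.streamlines:
            return np.zeros((0, 2, 3))
        return np.stack([[s[0], s[-1]] for s in self.streamlines])


def streamline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# volumes (NIfTI)
# ---------------------------------------------------------------------------

def write_volume(array: np.ndarray, geometry: VolumeGeometry,
                 path: str | Path) -> None:
    """Write a scalar or multi-component volume as float32 NIfTI."""
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32),
                          geometry.affine)
    img.header.set_zooms(geometry.voxel_size_mm
                         + (1.0,) * (array.ndim - 3))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeGeometry]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"cannot read volume {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float32)
    aff = img.affine
    geom = VolumeGeometry(data.shape[:3],
                          tuple(np.linalg.norm(aff[:3, :3], axis=0)), aff)
    return data, geom


# ---------------------------------------------------------------------------
# meshes (ASCII OFF, optional GIFTI)
# ---------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """ASCII OFF: header line, counts, vertex rows, face rows."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    with path.open() as fh:
        tokens = fh.read().split()
    if not tokens or tokens[0] != "OFF":
        raise IOError(f"{path}: not an OFF mesh (missing magic)")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    need = pos + 3 * nv
    if len(tokens) < need:
        raise IOError(f"{path}: truncated at token {len(tokens)} "
                      f"(expected {need} vertex tokens)")
    verts = np.array(tokens[pos:need], dtype=float).reshape(nv, 3)
    pos = need
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        if len(tokens) < pos + 4:
            raise IOError(f"{path}: truncated in face {i} at token {pos}")
        if tokens[pos] != "3":
            raise IOError(f"{path}: face {i} is not a triangle")
        faces[i] = [int(t) for t in tokens[pos + 1:pos + 4]]
        pos += 4
    return SurfaceMesh(verts, faces)


def write_mesh_gifti(mesh: SurfaceMesh, path: str | Path) -> None:
    """GIFTI surface export (pointset + triangle arrays)."""
    from nibabel import gifti

    g = gifti.GiftiImage()
    g.add_gifti_data_array(gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"))
    g.add_gifti_data_array(gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"))
    nib.save(g, str(path))


# ---------------------------------------------------------------------------
# tractogram files (TCK)
# ---------------------------------------------------------------------------

def write_tractogram(tractogram: Tractogram, path: str | Path) -> None:
    sl = nib.streamlines.Tractogram(tractogram.streamlines,
                                    affine_to_rasmm=np.eye(4))
    nib.streamlines.save(sl, str(path))


def read_tractogram(path: str | Path) -> Tractogram:
    try:
        tck = nib.streamlines.load(str(path))
    except Exception as exc:
        raise IOError(f"cannot read tractogram {path}: {exc}") from exc
    return Tractogram([np.asarray(s) for s in tck.streamlines])


# ---------------------------------------------------------------------------
# tables (TSV)
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[""],
                       keep_default_na=True)


# ---------------------------------------------------------------------------
# config + logging
# ---------------------------------------------------------------------------

def load_config(path: str | Path, overrides: dict | None = None) -> dict:
    """Read a TOML config; ``overrides`` (e.g. from flags) win over the file."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    if overrides:
        cfg = {**cfg, **{k: v for k, v in overrides.items() if v is not None}}
    return cfg


def get_logger(name: str = "ficd", level: int = logging.INFO
               ) -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger
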