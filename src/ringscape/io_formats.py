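"""External representations: NIfTI volumes, binary masks, label atlases, streamlines.

Every on-disk format the pipeline touches is read and written here; all other
modules operate on the in-memory types only.  Conventions:

* voxel indices are 0-based and voxel *centers* map to world mm via the affine;
* a world point lies inside a mask voxel when its nearest voxel center
  (rounding half up, per axis) is true;
* streamline coordinates are always world mm — TRK native offsets are
  converted on read and never escape this module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "ReferenceAtlas",
    "Streamline",
    "FormatError",
    "ValidationError",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "read_atlas",
    "write_atlas",
    "read_streamlines",
    "write_streamlines",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_report",
]


@dataclass(frozen=True)
class VolumeGrid:
    """A common voxel space: array shape plus a voxel-to-world affine (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4, got {aff.shape}")
        if any(s < 1 for s in shape) or len(shape) != 3:
            raise ValidationError(f"bad grid shape {shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(float(v) for v in np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest-voxel-center indices for world points (round half up per axis)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        cont = xyz @ inv[:3, :3].T + inv[:3, 3]
        return np.floor(cont + 0.5).astype(int)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash(self.shape)


@dataclass(frozen=True)
class BinaryMask:
    """Boolean footprint over a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=bool)
        if vals.shape != self.grid.shape:
            raise ValidationError(
                f"mask shape {vals.shape} != grid shape {self.grid.shape}"
            )
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def size(self) -> int:
        return int(self.values.sum())

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.values & other.values)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.values | other.values)

    def contains_points(self, xyz: np.ndarray) -> np.ndarray:
        """True per world point whose nearest voxel center is inside the mask."""
        ijk = self.grid.world_to_voxel(xyz)
        inside = np.all((ijk >= 0) & (ijk < np.array(self.grid.shape)), axis=1)
        out = np.zeros(len(ijk), dtype=bool)
        sel = ijk[inside]
        out[inside] = self.values[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out


def _check_same_grid(a: VolumeGrid, b: VolumeGrid) -> None:
    if a != b:
        raise ValidationError("grids differ between operands")


@dataclass
class ReferenceAtlas:
    """Named set of binary masks on one grid (units may overlap or partition)."""

    grid: VolumeGrid
    units: list[tuple[str, BinaryMask]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.units]
        if len(set(names)) != len(names):
            raise ValidationError("atlas unit names are not unique")
        for name, mask in self.units:
            if mask.grid != self.grid:
                raise ValidationError(f"unit {name!r} is on a different grid")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.units]

    def __getitem__(self, name: str) -> BinaryMask:
        for n, m in self.units:
            if n == name:
                return m
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.units)


@dataclass(frozen=True, eq=False)
class Streamline:
    """Tractography path as an ordered polyline in world mm."""

    points: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Streamline):
            return NotImplemented
        return np.array_equal(self.points, other.points)

    def __hash__(self) -> int:
        return hash(self.points.shape)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValidationError("streamline needs >= 2 points of dimension 3")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("streamline has non-finite coordinates")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValidationError("consecutive streamline points must be distinct")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return int(self.points.shape[0])


# ---------------------------------------------------------------------------
# volumes


def read_volume(path: str | Path) -> tuple[VolumeGrid, np.ndarray]:
    """Read a NIfTI volume; returns the grid and a 3D or 4D (x, y, z[, t]) array."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected 3D/4D data, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: volume contains non-finite voxels")
    grid = VolumeGrid(tuple(data.shape[:3]), np.asarray(img.affine))
    return grid, data


def write_volume(path: str | Path, grid: VolumeGrid, data: np.ndarray) -> None:
    data = np.asarray(data)
    if tuple(data.shape[:3]) != grid.shape:
        raise ValidationError("data shape does not match grid")
    nib.save(nib.Nifti1Image(data, np.asarray(grid.affine)), str(path))


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    write_volume(path, mask.grid, mask.values.astype(np.uint8))


def read_mask(path: str | Path) -> BinaryMask:
    grid, data = read_volume(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: mask must be 3D")
    return BinaryMask(grid, data > 0)


def write_atlas(path_prefix: str | Path, atlas: ReferenceAtlas) -> None:
    """Write an atlas as a label volume plus a JSON name map (label -> name)."""
    prefix = Path(path_prefix)
    labels = np.zeros(atlas.grid.shape, dtype=np.int16)
    name_map: dict[str, str] = {}
    for i, (name, mask) in enumerate(atlas.units, start=1):
        labels[mask.values] = i
        name_map[str(i)] = name
    write_volume(prefix.with_suffix(".nii.gz"), atlas.grid, labels)
    prefix.with_suffix(".json").write_text(json.dumps(name_map, indent=1))


def read_atlas(path_prefix: str | Path) -> ReferenceAtlas:
    prefix = Path(path_prefix)
    grid, labels = read_volume(prefix.with_suffix(".nii.gz"))
    try:
        name_map = json.loads(prefix.with_suffix(".json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read atlas name map for {prefix}: {exc}") from exc
    units = []
    for label_str, name in sorted(name_map.items(), key=lambda kv: int(kv[0])):
        units.append((name, BinaryMask(grid, labels == int(label_str))))
    return ReferenceAtlas(grid, units)


# ---------------------------------------------------------------------------
# streamlines


def read_streamlines(path: str | Path) -> list[Streamline]:
    """Read TRK or plain polyline text; coordinates come back in world mm."""
    path = Path(path)
    if path.suffix.lower() == ".trk":
        return _read_trk(path)
    return _read_polyline_text(path)


def write_streamlines(
    path: str | Path, lines: Sequence[Streamline], grid: VolumeGrid | None = None
) -> None:
    path = Path(path)
    if path.suffix.lower() == ".trk":
        if grid is None:
            raise ValidationError("writing TRK requires a reference grid")
        _write_trk(path, lines, grid)
    else:
        _write_polyline_text(path, lines)


def _read_trk(path: Path) -> list[Streamline]:
    try:
        trk = nib.streamlines.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read TRK file {path}: {exc}") from exc
    out: list[Streamline] = []
    # nibabel returns streamlines already in RAS+ world mm
    for pts in trk.tractogram.streamlines:
        sl = _make_streamline_or_warn(np.asarray(pts, dtype=float), path)
        if sl is not None:
            out.append(sl)
    return out


def _write_trk(path: Path, lines: Sequence[Streamline], grid: VolumeGrid) -> None:
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(l.points, dtype=np.float32) for l in lines],
        affine_to_rasmm=np.eye(4),
    )
    header = {
        "dimensions": np.asarray(grid.shape, dtype=np.int16),
        "voxel_sizes": np.asarray(grid.voxel_size, dtype=np.float32),
        "voxel_to_rasmm": np.asarray(grid.affine, dtype=np.float32),
        "voxel_order": "".join(nib.aff2axcodes(np.asarray(grid.affine))),
    }
    nib.streamlines.save(nib.streamlines.TrkFile(tractogram, header), str(path))


def _read_polyline_text(path: Path) -> list[Streamline]:
    """Whitespace-delimited dialect: one point per line, blank line between lines."""
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    out: list[Streamline] = []
    block: list[list[float]] = []
    for raw in text.splitlines() + [""]:
        stripped = raw.strip()
        if not stripped:
            if block:
                sl = _make_streamline_or_warn(np.asarray(block), path)
                if sl is not None:
                    out.append(sl)
                block = []
            continue
        parts = stripped.split()
        if len(parts) != 3:
            raise FormatError(f"{path}: expected 3 coordinates per line, got {raw!r}")
        try:
            block.append([float(p) for p in parts])
        except ValueError as exc:
            raise FormatError(f"{path}: bad coordinate in {raw!r}") from exc
    return out


def _write_polyline_text(path: Path, lines: Sequence[Streamline]) -> None:
    chunks = []
    for sl in lines:
        chunks.append(
            "\n".join(" ".join(f"{c:.6f}" for c in p) for p in sl.points)
        )
    path.write_text("\n\n".join(chunks) + ("\n" if chunks else ""))


def _make_streamline_or_warn(pts: np.ndarray, path: Path) -> Streamline | None:
    if pts.shape[0] < 2:
        logger.warning("dropping streamline with < 2 points in %s", path)
        return None
    # collapse exactly duplicated consecutive points (float32 storage artefact)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    pts = pts[keep]
    if pts.shape[0] < 2:
        logger.warning("dropping degenerate streamline in %s", path)
        return None
    return Streamline(pts)


# ---------------------------------------------------------------------------
# tabular / report plumbing


def write_matrix_tsv(
    path: str | Path,
    matrix: np.ndarray,
    row_labels: Iterable,
    col_labels: Iterable,
) -> None:
    pd.DataFrame(matrix, index=list(row_labels), columns=list(col_labels)).to_csv(
        path, sep="\t"
    )


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot read matrix TSV {path}: {exc}") from exc


def write_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
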