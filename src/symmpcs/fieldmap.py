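"""PCS field evaluation on a 3D grid and OpenDX export.

The summed multi-center PCS field visualizes the reach of the tags: for
tags of the strength fitted here the +-0.2 ppm isosurfaces extend beyond
100 angstrom, which is what makes remote-distance studies possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, ParseError
from .model import K_PCS, ChiTensor
from .structure import Structure

log = logging.getLogger(__name__)

__all__ = ["FieldMap", "evaluate_grid", "default_grid", "write_dx", "read_dx",
           "DEFAULT_LEVELS"]

#: Recommended contour levels (ppm): inner/outer surfaces of each sign.
DEFAULT_LEVELS = (-1.0, -0.2, 0.2, 1.0)

#: Magnitude at which near-metal cells are clamped (ppm).  Keeps files
#: loadable by graphics programs while flagging invalid cells.
SENTINEL = 1.0e6

#: Radius (angstrom) around a metal inside which cells carry the sentinel;
#: the point-dipole model has no meaning that close to the center.
GUARD_RADIUS = 1.0


@dataclass
class FieldMap:
    """A scalar PCS field on a regular grid."""

    origin: np.ndarray   # angstrom, position of grid node (0, 0, 0)
    spacing: float       # angstrom, isotropic
    dims: tuple[int, int, int]
    values: np.ndarray   # shape dims, ppm

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.dims = tuple(int(d) for d in self.dims)
        if any(d < 1 for d in self.dims):
            raise InvalidArgumentError(f"grid dims must be positive, got {self.dims}")
        if self.values.shape != self.dims:
            raise InvalidArgumentError(
                f"values shape {self.values.shape} != dims {self.dims}"
            )

    def cell_centers(self) -> np.ndarray:
        """(nx*ny*nz, 3) array of node coordinates, x slowest / z fastest."""
        nx, ny, nz = self.dims
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.origin + idx * self.spacing


def evaluate_grid(
    tensors: list[ChiTensor],
    origin: np.ndarray,
    spacing: float,
    dims: tuple[int, int, int],
    guard_radius: float = GUARD_RADIUS,
) -> FieldMap:
    """Summed PCS of all tensors at every grid node.

    Cells within ``guard_radius`` of any metal are set to the sentinel
    value +-1e6 ppm (sign of the local field).
    """
    tensors = list(tensors)
    if not tensors:
        raise InvalidArgumentError("evaluate_grid requires at least one tensor")
    fmap = FieldMap(origin=np.asarray(origin, dtype=float), spacing=float(spacing),
                    dims=dims, values=np.zeros(dims))
    pts = fmap.cell_centers()
    total = np.zeros(len(pts))
    near = np.zeros(len(pts), dtype=bool)
    for t in tensors:
        d = pts - t.position
        local = d @ t.rotation
        x2, y2, z2 = local[:, 0] ** 2, local[:, 1] ** 2, local[:, 2] ** 2
        r2 = x2 + y2 + z2
        near |= r2 < guard_radius**2
        r2 = np.maximum(r2, 1e-12)
        total += K_PCS * (
            t.dchi_ax * (2.0 * z2 - x2 - y2) + 1.5 * t.dchi_rh * (x2 - y2)
        ) / r2**2.5
    total = np.where(near, np.where(total < 0, -SENTINEL, SENTINEL), total)
    total = np.clip(total, -SENTINEL, SENTINEL)
    fmap.values = total.reshape(fmap.dims)
    lo = fmap.origin
    hi = fmap.origin + (np.array(fmap.dims) - 1) * fmap.spacing
    if not any(np.all((t.position >= lo) & (t.position <= hi)) for t in tensors):
        log.warning("grid does not enclose any paramagnetic center")
    return fmap


def default_grid(
    structure: Structure, pad: float = 30.0, spacing: float = 2.0
) -> tuple[np.ndarray, float, tuple[int, int, int]]:
    """Grid covering the structure bounding box padded by ``pad`` angstrom."""
    lo, hi = structure.bounding_box()
    origin = lo - pad
    dims = tuple(int(np.ceil((h - l + 2 * pad) / spacing)) + 1 for l, h in zip(lo, hi))
    return origin, float(spacing), dims


def write_dx(
    fmap: FieldMap, path: str, levels: tuple[float, ...] = DEFAULT_LEVELS
) -> None:
    """Write an OpenDX scalar field plus a companion contour-level file.

    Data values follow the OpenDX grid convention (last index fastest,
    i.e. z fastest); the file loads in PyMOL, VMD and Chimera.  The
    companion ``<path>.levels.txt`` lists the recommended isosurface
    levels in ppm.
    """
    nx, ny, nz = fmap.dims
    vals = fmap.values.reshape(-1)  # C order: z fastest
    with open(path, "w") as fh:
        fh.write("# PCS field (ppm); near-metal cells clamped to +-1e6\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*fmap.origin))
        fh.write(f"delta {fmap.spacing:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {fmap.spacing:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {fmap.spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {vals.size} data follows\n"
        )
        for i in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.9e}" for v in vals[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "pcs field" class field\n')
    with open(str(path) + ".levels.txt", "w") as fh:
        fh.write("# recommended isosurface levels, ppm\n")
        for lvl in levels:
            fh.write(f"{lvl:g}\n")


def read_dx(path: str) -> FieldMap:
    """Parse an OpenDX scalar field written by :func:`write_dx`."""
    dims = None
    origin = None
    deltas = []
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("attribute") or s.startswith('object "'):
                continue
            if s.startswith("object 1"):
                dims = tuple(int(v) for v in s.split()[-3:])
            elif s.startswith("origin"):
                origin = np.array([float(v) for v in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append([float(v) for v in s.split()[1:4]])
            elif s.startswith("object"):
                if "data follows" in s:
                    n_items = int(s.split("items")[1].split()[0])
            else:
                values.extend(float(v) for v in s.split())
    if dims is None or origin is None or len(deltas) != 3 or n_items is None:
        raise ParseError(f"{path}: not a recognizable OpenDX scalar field")
    if len(values) != n_items:
        raise ParseError(f"{path}: expected {n_items} values, found {len(values)}")
    spacing = deltas[0][0]
    return FieldMap(origin=origin, spacing=spacing, dims=dims,
                    values=np.array(values).reshape(dims))
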