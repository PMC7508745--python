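"""Forward model: pseudocontact shifts from anisotropic susceptibility tensors.

The pseudocontact shift (PCS) of a nucleus at position ``x, y, z`` in the
frame of a paramagnetic center (point-dipole approximation) is

    sigma = (1 / 12 pi) * [ dchi_ax * (2 z^2 - x^2 - y^2) / r^5
                            + 1.5 * dchi_rh * (x^2 - y^2) / r^5 ]

Unit convention, fixed project-wide: coordinates in angstrom, anisotropies
``dchi_ax``/``dchi_rh`` in 1e-32 m^3, PCS in ppm.  With these units the
prefactor becomes ``K_PCS = 1e4 / (12 pi)``: the 1e-32 m^3 of dchi against
the 1e-30 m^3 of an angstrom cubed leaves 1e-2, and the ppm scale
contributes 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from . import geometry
from .errors import InvalidArgumentError, ParseError, SingularityError

__all__ = [
    "K_PCS",
    "MIN_DISTANCE",
    "ChiTensor",
    "SpinSite",
    "PCSDataset",
    "pcs_single",
    "pcs_multi",
]

#: Prefactor of the PCS expression for angstrom / 1e-32 m^3 / ppm units.
K_PCS = 1.0e4 / (12.0 * np.pi)

#: Default minimum nucleus-metal distance (angstrom).  The point-dipole
#: model is invalid at the metal anyway; this only guards the r^-5 pole.
MIN_DISTANCE = 1e-6


@dataclass(frozen=True)
class ChiTensor:
    """One paramagnetic center: anisotropy, position and orientation.

    Parameters
    ----------
    dchi_ax, dchi_rh : float
        Axial and rhombic anisotropy of the magnetic susceptibility tensor,
        in 1e-32 m^3.
    position : array-like of 3 floats
        Metal position in the molecular frame, angstrom.  The tensor frame
        has its origin here.
    euler : tuple of 3 floats
        ZYZ Euler angles (degrees) orienting the tensor frame relative to
        the molecular frame (columns of the rotation matrix are the tensor
        principal axes in molecular coordinates).
    """

    dchi_ax: float
    dchi_rh: float
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise InvalidArgumentError("tensor position must be finite")
        if not (np.isfinite(self.dchi_ax) and np.isfinite(self.dchi_rh)):
            raise InvalidArgumentError("dchi values must be finite")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "euler", tuple(float(a) for a in self.euler))

    @property
    def rotation(self) -> np.ndarray:
        """Active rotation matrix of the tensor frame (ZYZ)."""
        return geometry.rotation_from_euler(*self.euler)

    def full_tensor(self) -> np.ndarray:
        """The traceless 3x3 anisotropy tensor in the molecular frame.

        Principal values are (-ax/3 + rh/2, -ax/3 - rh/2, 2 ax/3) so that
        dchi_ax = chi_zz - (chi_xx + chi_yy)/2 and dchi_rh = chi_xx - chi_yy.
        """
        d = np.diag(
            [
                -self.dchi_ax / 3.0 + self.dchi_rh / 2.0,
                -self.dchi_ax / 3.0 - self.dchi_rh / 2.0,
                2.0 * self.dchi_ax / 3.0,
            ]
        )
        R = self.rotation
        return R @ d @ R.T

    def canonicalized(self) -> "ChiTensor":
        """Unique representative among the equivalent parameterizations.

        Two degeneracies are resolved: (i) relabeling of principal axes
        (enforcing the standard rhombicity bound |dchi_rh| <= 2/3 |dchi_ax|
        with the z axis on the largest-magnitude principal value), and
        (ii) the four ZYZ triples describing the same frame up to 180-deg
        flips about principal axes (choose beta in [0, 90] when possible,
        then smallest alpha, then smallest gamma).  The PCS field is
        unchanged.
        """
        if abs(self.dchi_ax) < 1e-15 and abs(self.dchi_rh) < 1e-15:
            return replace(self, dchi_ax=0.0, dchi_rh=0.0, euler=(0.0, 0.0, 0.0))
        T = self.full_tensor()
        vals, vecs = np.linalg.eigh(T)
        order = np.argsort(np.abs(vals))  # |x| <= |y| <= |z|
        vals = vals[order]
        vecs = vecs[:, order]
        ax = 1.5 * vals[2]
        rh = vals[0] - vals[1]
        if np.linalg.det(vecs) < 0:
            vecs[:, 0] = -vecs[:, 0]
        # four sign choices preserving right-handedness
        flips = (
            np.diag([1.0, 1.0, 1.0]),
            np.diag([1.0, -1.0, -1.0]),
            np.diag([-1.0, 1.0, -1.0]),
            np.diag([-1.0, -1.0, 1.0]),
        )
        candidates = [geometry.euler_from_rotation(vecs @ D) for D in flips]
        ok = [e for e in candidates if e[1] <= 90.0 + 1e-9]
        pool = ok if ok else candidates
        euler = min(pool, key=lambda e: (round(e[0], 9), round(e[2], 9)))
        return replace(self, dchi_ax=float(ax), dchi_rh=float(rh), euler=euler)

    def to_dict(self) -> dict:
        return {
            "dchi_ax": float(self.dchi_ax),
            "dchi_rh": float(self.dchi_rh),
            "position": [float(v) for v in self.position],
            "euler": list(self.euler),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChiTensor":
        return cls(
            dchi_ax=float(d["dchi_ax"]),
            dchi_rh=float(d["dchi_rh"]),
            position=np.asarray(d["position"], dtype=float),
            euler=tuple(float(v) for v in d["euler"]),
        )


@dataclass(frozen=True)
class SpinSite:
    """A nucleus in the molecular frame."""

    chain: str
    residue: int
    atom: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coord, dtype=float).reshape(3)
        if not np.all(np.isfinite(c)):
            raise InvalidArgumentError(
                f"non-finite coordinates for {self.chain}/{self.residue}/{self.atom}"
            )
        object.__setattr__(self, "coord", c)

    @property
    def key(self) -> tuple[int, str]:
        """Chain-agnostic (residue, atom) key.

        Experimental PCS carry no chain label: in a symmetric multimer the
        equivalent amides of all protomers superimpose into one resonance.
        """
        return (self.residue, self.atom)


class PCSDataset:
    """PCS values keyed by chain-agnostic (residue, atom), with weights."""

    def __init__(self) -> None:
        self._data: dict[tuple[int, str], tuple[float, float]] = {}

    def add(self, residue: int, atom: str, value: float, weight: float = 1.0) -> None:
        key = (int(residue), str(atom))
        if key in self._data:
            raise ParseError(f"duplicate PCS entry for residue {key[0]} atom {key[1]}")
        if not np.isfinite(value):
            raise InvalidArgumentError(f"non-finite PCS for {key}")
        self._data[key] = (float(value), float(weight))

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, key: tuple[int, str]) -> bool:
        return tuple(key) in self._data

    def __iter__(self) -> Iterator[tuple[int, str]]:
        return iter(self._data)

    def keys(self) -> Iterable[tuple[int, str]]:
        return self._data.keys()

    def value(self, key: tuple[int, str]) -> float:
        return self._data[tuple(key)][0]

    def weight(self, key: tuple[int, str]) -> float:
        return self._data[tuple(key)][1]

    def items(self) -> Iterable[tuple[tuple[int, str], float]]:
        for k, (v, _) in self._data.items():
            yield k, v

    def subset(self, keys: Iterable[tuple[int, str]]) -> "PCSDataset":
        out = PCSDataset()
        for k in keys:
            v, w = self._data[tuple(k)]
            out.add(k[0], k[1], v, w)
        return out

    def filter_atoms(self, atoms: Iterable[str]) -> "PCSDataset":
        allowed = set(atoms)
        out = PCSDataset()
        for (res, atom), (v, w) in self._data.items():
            if atom in allowed:
                out.add(res, atom, v, w)
        return out


def _to_tensor_frame(tensor: ChiTensor, coords: np.ndarray) -> np.ndarray:
    """Express molecular-frame coordinates in the tensor frame."""
    d = np.atleast_2d(np.asarray(coords, dtype=float)) - tensor.position
    return d @ tensor.rotation  # row-vector form of R^T (x - p)


def pcs_values(tensor: ChiTensor, coords: np.ndarray, min_distance: float = MIN_DISTANCE) -> np.ndarray:
    """Vectorized single-center PCS for an (n, 3) coordinate array (ppm)."""
    local = _to_tensor_frame(tensor, coords)
    x2, y2, z2 = local[:, 0] ** 2, local[:, 1] ** 2, local[:, 2] ** 2
    r2 = x2 + y2 + z2
    if np.any(r2 < min_distance**2):
        raise SingularityError(
            f"nucleus within {min_distance} A of the paramagnetic center"
        )
    r5 = r2**2.5
    return K_PCS * (
        tensor.dchi_ax * (2.0 * z2 - x2 - y2) + 1.5 * tensor.dchi_rh * (x2 - y2)
    ) / r5


def pcs_single(tensor: ChiTensor, coord: np.ndarray, min_distance: float = MIN_DISTANCE) -> float:
    """PCS (ppm) at one nucleus from one paramagnetic center."""
    return float(pcs_values(tensor, np.asarray(coord, dtype=float).reshape(1, 3), min_distance)[0])


def pcs_multi(
    tensors: Iterable[ChiTensor], coord: np.ndarray, min_distance: float = MIN_DISTANCE
) -> float:
    """Summed PCS (ppm) at one nucleus from several paramagnetic centers."""
    tensors = list(tensors)
    if not tensors:
        raise InvalidArgumentError("pcs_multi requires at least one tensor")
    total = 0.0
    for i, t in enumerate(tensors):
        try:
            total += pcs_single(t, coord, min_distance)
        except SingularityError as exc:
            raise SingularityError(f"tensor {i}: {exc}") from exc
    return total
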