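"""Cn symmetry machinery.

The central identity of the whole approach: in a Cn-symmetric multimer
carrying one tag per protomer, the PCS observed at a spin (the sum over the
n symmetry-related tags, each with its own tensor frame) equals the sum of
the PCS generated by a *single* tag at the n symmetry-equivalent copies of
that spin.  This reduces a 8n-parameter problem to 8 parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import geometry
from .errors import (
    InvalidArgumentError,
    LookupMissingError,
    SymmetryDetectionError,
)
from .model import ChiTensor, SpinSite, pcs_values

__all__ = [
    "SymmetryGroup",
    "symmetry_operators",
    "expand_tensor",
    "equivalent_sites",
    "symmetric_pcs",
    "axis_from_chains",
]


@dataclass(frozen=True)
class SymmetryGroup:
    """A cyclic rotation group Cn about an axis in space."""

    order: int
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if int(self.order) < 1:
            raise InvalidArgumentError(f"group order must be >= 1, got {self.order}")
        object.__setattr__(self, "order", int(self.order))
        p = np.asarray(self.axis_point, dtype=float).reshape(3)
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n < 1e-12:
            raise InvalidArgumentError("axis direction must be a nonzero vector")
        object.__setattr__(self, "axis_point", p)
        object.__setattr__(self, "axis_direction", d / n)


def symmetry_operators(group: SymmetryGroup) -> list[tuple[np.ndarray, np.ndarray]]:
    """The n rigid transforms (R_k, t_k), rotations by k*360/n about the axis.

    Operator 0 is the identity; each transform fixes every point of the axis.
    """
    ops = []
    for k in range(group.order):
        R = geometry.axis_angle_rotation(group.axis_direction, 360.0 * k / group.order)
        t = group.axis_point - R @ group.axis_point
        ops.append((R, t))
    return ops


def expand_tensor(tensor: ChiTensor, group: SymmetryGroup) -> list[ChiTensor]:
    """The n symmetry-related copies of one tensor.

    Positions and orientations are transformed by each group operator;
    the anisotropy values are shared by all copies (identical tags).
    """
    out = []
    for R, t in symmetry_operators(group):
        pos = R @ tensor.position + t
        euler = geometry.euler_from_rotation(R @ tensor.rotation)
        out.append(replace(tensor, position=pos, euler=euler))
    return out


def equivalent_sites(
    structure, site_key: tuple[int, str], chain_map: Sequence[str]
) -> list[SpinSite]:
    """The same (residue, atom) site from each mapped chain, in order.

    Raises :class:`LookupMissingError` naming the first chain where the
    site is absent.
    """
    residue, atom = int(site_key[0]), str(site_key[1])
    sites = []
    for chain in chain_map:
        coord = structure.find_coord(chain, residue, atom)
        if coord is None:
            raise LookupMissingError(
                f"site residue {residue} atom {atom} missing in chain {chain}"
            )
        sites.append(SpinSite(chain=chain, residue=residue, atom=atom, coord=coord))
    return sites


def symmetric_pcs(
    tensor: ChiTensor, sites: Iterable[SpinSite], min_distance: float | None = None
) -> float:
    """Sum of single-tensor PCS over symmetry-equivalent sites (ppm).

    On an ideally symmetric structure this equals the multi-center sum
    ``pcs_multi(expand_tensor(tensor, group), site.coord)`` exactly; on a
    real (slightly asymmetric) structure the two differ and the difference
    is a useful diagnostic of residual asymmetry.
    """
    coords = np.array([s.coord for s in sites], dtype=float)
    if coords.size == 0:
        raise InvalidArgumentError("symmetric_pcs requires at least one site")
    kwargs = {} if min_distance is None else {"min_distance": min_distance}
    return float(np.sum(pcs_values(tensor, coords, **kwargs)))


def axis_from_chains(structure, chain_a: str, chain_b: str, tol_deg: float = 5.0) -> SymmetryGroup:
    """Detect the Cn axis relating two chains by least-squares superposition.

    Superposes the shared C-alpha atoms of ``chain_a`` onto ``chain_b``
    (paired by residue number), reads the rotation angle and axis off the
    transform, and returns a group of order round(360/angle) with the axis
    through the transform's fixed point.
    """
    pa, pb = [], []
    for residue in structure.shared_residues(chain_a, chain_b):
        ca_a = structure.find_coord(chain_a, residue, "CA")
        ca_b = structure.find_coord(chain_b, residue, "CA")
        if ca_a is not None and ca_b is not None:
            pa.append(ca_a)
            pb.append(ca_b)
    if len(pa) < 3:
        raise SymmetryDetectionError(
            f"chains {chain_a}/{chain_b} share fewer than 3 C-alpha pairs"
        )
    R, t, _ = geometry.kabsch_superpose(np.array(pa), np.array(pb))
    axis, angle = geometry.rotation_axis_angle(R)
    if angle < 1e-6:
        raise SymmetryDetectionError("chains are related by the identity, no axis")
    order = int(round(360.0 / angle))
    if order < 2 or abs(angle - 360.0 / order) > tol_deg:
        raise SymmetryDetectionError(
            f"rotation angle {angle:.2f} deg is not consistent with an integer order"
        )
    # fixed point: minimum-norm solution of (I - R) p = t, orthogonal to axis
    p = np.linalg.pinv(np.eye(3) - R) @ t
    return SymmetryGroup(order=order, axis_point=p, axis_direction=axis)
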