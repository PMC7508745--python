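"""Tabular text formats and tensor reporting.

PCS tables are whitespace/tab-separated with columns
``residue atom pcs_ppm [weight]``; peak lists carry
``id h_ppm n_ppm [assignment]``.  Lines starting with ``#`` are comments.

Tensor reports follow the standard convention for symmetric multimers:
the origin is placed at the center of gravity of the n metal positions,
all metals lie in the xy-plane, and each metal is given in polar
coordinates (r_metal, theta_metal) with the tensor orientation re-expressed
as ZYZ Euler angles in that frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ParseError
from .geometry import euler_from_rotation
from .model import ChiTensor, PCSDataset

__all__ = [
    "read_pcs_table",
    "write_pcs_table",
    "TensorReport",
    "report_tensor",
]


def read_pcs_table(path: str) -> PCSDataset:
    """Read a PCS table; duplicate (residue, atom) keys are an error."""
    dataset = PCSDataset()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ParseError(f"{path}:{lineno}: expected 3-4 columns, got {len(parts)}")
            try:
                residue = int(parts[0])
                value = float(parts[2])
                weight = float(parts[3]) if len(parts) == 4 else 1.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                dataset.add(residue, parts[1], value, weight)
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if len(dataset) == 0:
        raise ParseError(f"{path}: empty PCS table")
    return dataset


def write_pcs_table(dataset: PCSDataset, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# residue atom pcs_ppm weight\n")
        for key in sorted(dataset.keys()):
            fh.write(
                f"{key[0]}\t{key[1]}\t{dataset.value(key):.6f}\t{dataset.weight(key):g}\n"
            )


@dataclass(frozen=True)
class TensorReport:
    """Table-style tensor parameters in the metals-in-xy-plane frame."""

    chain: str
    dchi_ax: float
    dchi_rh: float
    r_metal: float      # angstrom, distance from the metal centroid in-plane
    theta_metal: float  # degrees in [0, 360)
    alpha: float        # ZYZ Euler angles, degrees, in the reporting frame
    beta: float
    gamma: float
    dist_tag_ca: float | None = None  # metal to tag-residue C-alpha, angstrom
    dist_tag_cb: float | None = None  # metal to tag-residue C-beta, angstrom

    def rows(self) -> list[tuple[str, str]]:
        rows = [
            ("dchi_ax_1e-32m3", f"{self.dchi_ax:.1f}"),
            ("dchi_rh_1e-32m3", f"{self.dchi_rh:.1f}"),
            ("r_metal_A", f"{self.r_metal:.1f}"),
            ("theta_metal_deg", f"{self.theta_metal:.1f}"),
            ("alpha_deg", f"{self.alpha:.1f}"),
            ("beta_deg", f"{self.beta:.1f}"),
            ("gamma_deg", f"{self.gamma:.1f}"),
        ]
        if self.dist_tag_ca is not None:
            rows.append(("dist_metal_tag_CA_A", f"{self.dist_tag_ca:.1f}"))
        if self.dist_tag_cb is not None:
            rows.append(("dist_metal_tag_CB_A", f"{self.dist_tag_cb:.1f}"))
        return rows


def metal_plane_frame(
    metals: np.ndarray,
    axis_direction: np.ndarray | None = None,
    reference_index: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Reporting frame for n metal positions.

    Origin at the metal centroid; z along the best-fit plane normal
    (aligned with ``axis_direction`` when given, otherwise with the
    metal-order circulation so that the frame is stable across runs);
    x such that the reference metal sits at theta = 0.

    Returns (origin, R) with the columns of R being the frame axes in
    molecular coordinates.
    """
    metals = np.asarray(metals, dtype=float)
    origin = metals.mean(axis=0)
    centered = metals - origin
    # plane normal: smallest principal direction of the centered metals
    _, s, vt = np.linalg.svd(centered)
    if len(s) < 2 or s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError("metal positions are collinear; no plane frame")
    z = vt[2]
    if axis_direction is not None:
        if np.dot(z, np.asarray(axis_direction, dtype=float)) < 0:
            z = -z
    else:
        circ = np.cross(centered[0], centered[1 % len(metals)])
        if np.dot(z, circ) < 0:
            z = -z
    xref = centered[reference_index] - np.dot(centered[reference_index], z) * z
    nx = np.linalg.norm(xref)
    if nx < 1e-8:
        raise DegenerateGeometryError("reference metal lies on the frame z-axis")
    x = xref / nx
    y = np.cross(z, x)
    return origin, np.column_stack([x, y, z])


def report_tensor(
    tensor: ChiTensor,
    all_metals: np.ndarray,
    metal_index: int = 0,
    axis_direction: np.ndarray | None = None,
    reference_index: int = 0,
    chain: str = "",
    tag_ca: np.ndarray | None = None,
    tag_cb: np.ndarray | None = None,
) -> TensorReport:
    """Express one fitted tensor in the metals-in-xy-plane reporting frame.

    ``all_metals`` are the n symmetry-related metal positions (molecular
    frame); ``metal_index`` selects which of them this tensor sits on.
    """
    origin, F = metal_plane_frame(all_metals, axis_direction, reference_index)
    m = (np.asarray(all_metals, dtype=float)[metal_index] - origin) @ F
    r_metal = float(np.hypot(m[0], m[1]))
    theta = float(np.degrees(np.arctan2(m[1], m[0])) % 360.0)
    if theta >= 360.0 - 1e-9:
        theta = 0.0
    R_rep = F.T @ tensor.rotation
    alpha, beta, gamma = euler_from_rotation(R_rep)
    pos = tensor.position
    return TensorReport(
        chain=chain,
        dchi_ax=float(tensor.dchi_ax),
        dchi_rh=float(tensor.dchi_rh),
        r_metal=r_metal,
        theta_metal=theta,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        dist_tag_ca=None if tag_ca is None else float(np.linalg.norm(pos - tag_ca)),
        dist_tag_cb=None if tag_cb is None else float(np.linalg.norm(pos - tag_cb)),
    )


def write_tensor_reports(reports: list[TensorReport], path: str) -> None:
    """TSV mirror of the report table: one column per chain."""
    with open(path, "w") as fh:
        fh.write("# quantity\t" + "\t".join(r.chain or f"fit{i}" for i, r in enumerate(reports)) + "\n")
        names = [name for name, _ in reports[0].rows()]
        per = [dict(r.rows()) for r in reports]
        for name in names:
            fh.write(name + "\t" + "\t".join(p.get(name, "") for p in per) + "\n")
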