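"""Deterministic Cn-symmetric synthetic fixtures.

Generates a homomultimer-like structure (one backbone-like protomer
replicated by the cyclic group), a ground-truth susceptibility tensor tied
to a designated tag residue, simulated PCS datasets and 2D peak lists.
Everything is derived from one explicitly seeded generator per call, so
identical specs give bitwise-identical outputs.

The geometry is deliberately simple -- a gentle helical curve with
idealized local peptide geometry -- because exercising the mathematics
does not require a realistic protein fold.  The default conditions mirror
the demonstration system: a C3 trimer, 60 amides per protomer, a strongly
shifting lanthanide-scale tensor (dchi_ax -43, dchi_rh -7.8 in 1e-32 m^3),
Gaussian PCS noise of 0.02 ppm, and PRE-like censoring of amides closer
than 13 angstrom to any metal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import axis_angle_rotation
from .model import ChiTensor, PCSDataset
from .structure import Atom, Chain, Residue, Structure, build_amide_protons
from .symmetry import SymmetryGroup, equivalent_sites, expand_tensor, symmetric_pcs
from .assignment import Peak

__all__ = [
    "FixtureSpec",
    "make_cn_structure",
    "default_truth_tensor",
    "simulate_pcs",
    "simulate_peaklists",
    "standard_fixture",
]

#: Default PRE censoring cutoff, angstrom: amides closer than this to any
#: metal are line-broadened beyond detection and dropped.
PRE_CUTOFF = 13.0


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for one synthetic study."""

    order: int = 3
    spins_per_chain: int = 60
    radius: float = 12.0        # protomer helix radius, angstrom
    rise: float = 1.5           # helix rise per residue, angstrom
    twist: float = 20.0         # helix turn per residue, degrees
    center_offset: float = 18.0  # protomer axis offset from the Cn axis, angstrom
    tag_residue: int = 30
    noise_sigma: float = 0.02   # ppm
    jitter_sigma: float = 0.0   # angstrom, symmetry breaking
    seed: int = 0
    truth_dchi_ax: float = -43.0   # 1e-32 m^3
    truth_dchi_rh: float = -7.8    # 1e-32 m^3
    truth_euler: tuple[float, float, float] = (96.0, 120.3, 71.7)

    @property
    def chain_ids(self) -> list[str]:
        return [chr(ord("A") + k) for k in range(self.order)]

    @property
    def group(self) -> SymmetryGroup:
        return SymmetryGroup(order=self.order)


def _protomer_backbone(spec: FixtureSpec) -> list[tuple[int, str, dict[str, np.ndarray]]]:
    """Backbone-like N/CA/C sites along a helical curve for one protomer."""
    out = []
    n = spec.spins_per_chain
    for i in range(n):
        t = np.deg2rad(spec.twist) * i
        ca = np.array(
            [
                spec.center_offset + spec.radius * np.cos(t),
                spec.radius * np.sin(t),
                spec.rise * i,
            ]
        )
        # local frame: curve tangent, outward radial (from the protomer axis)
        tang = np.array(
            [-spec.radius * np.sin(t) * np.deg2rad(spec.twist),
             spec.radius * np.cos(t) * np.deg2rad(spec.twist),
             spec.rise]
        )
        tang /= np.linalg.norm(tang)
        radial = np.array([np.cos(t), np.sin(t), 0.0])
        atoms = {
            "N": ca - 1.2 * tang - 0.6 * radial,
            "CA": ca,
            "C": ca + 1.2 * tang - 0.4 * radial,
        }
        residue = i + 1
        if residue == spec.tag_residue:
            outward = ca - np.array([0.0, 0.0, ca[2]])
            outward /= np.linalg.norm(outward)
            atoms["CB"] = ca + 1.53 * outward
        out.append((residue, "CYS" if residue == spec.tag_residue else "ALA", atoms))
    return out


def make_cn_structure(spec: FixtureSpec, protonate: bool = True) -> Structure:
    """Build the Cn-symmetric structure (with amide protons by default).

    Coordinate jitter (``jitter_sigma`` > 0) is added to every atom after
    replication, breaking the symmetry by a controlled, seeded amount.
    """
    rng = np.random.default_rng(spec.seed)
    protomer = _protomer_backbone(spec)
    structure = Structure()
    for k, cid in enumerate(spec.chain_ids):
        R = axis_angle_rotation([0.0, 0.0, 1.0], 360.0 * k / spec.order)
        chain = Chain(id=cid)
        for number, name, atoms in protomer:
            res = Residue(number=number, name=name)
            for aname, coord in atoms.items():
                res.add(Atom(name=aname, element=aname[0], coord=R @ coord))
            chain.add(res)
        structure.add_chain(chain)
    if spec.jitter_sigma > 0:
        for chain in structure.chains.values():
            for res in chain.residues.values():
                for at in res.atoms.values():
                    at.coord = at.coord + rng.normal(0.0, spec.jitter_sigma, 3)
    return build_amide_protons(structure) if protonate else structure


def default_truth_tensor(structure: Structure, spec: FixtureSpec) -> ChiTensor:
    """Ground truth: metal 6 angstrom outward from the chain-A tag CB."""
    ca = structure.find_coord(spec.chain_ids[0], spec.tag_residue, "CA")
    cb = structure.find_coord(spec.chain_ids[0], spec.tag_residue, "CB")
    d = cb - ca
    pos = cb + 6.0 * d / np.linalg.norm(d)
    return ChiTensor(
        dchi_ax=spec.truth_dchi_ax,
        dchi_rh=spec.truth_dchi_rh,
        position=pos,
        euler=spec.truth_euler,
    )


def _metal_positions(truth: ChiTensor, group: SymmetryGroup) -> np.ndarray:
    return np.array([t.position for t in expand_tensor(truth, group)])


def simulate_pcs(
    structure: Structure,
    truth: ChiTensor,
    group: SymmetryGroup,
    chain_map: list[str],
    noise_sigma: float = 0.02,
    seed: int = 0,
    censor_cutoff: float | None = PRE_CUTOFF,
    atoms: tuple[str, ...] = ("H", "N"),
) -> PCSDataset:
    """Forward-simulate the observable PCS dataset.

    Each surviving (residue, atom) key gets the symmetric multi-center
    value plus Gaussian noise.  ``censor_cutoff`` emulates PRE loss: sites
    whose minimum distance to any symmetry-expanded metal is below the
    cutoff are dropped (peak broadened beyond detection).
    """
    rng = np.random.default_rng(seed)
    metals = _metal_positions(truth, group)
    dataset = PCSDataset()
    first = structure.chains[chain_map[0]]
    for res in first.sorted_residues():
        for atom in atoms:
            if atom not in res.atoms:
                continue
            try:
                sites = equivalent_sites(structure, (res.number, atom), chain_map)
            except Exception:
                continue
            if censor_cutoff is not None:
                dmin = min(
                    float(np.linalg.norm(s.coord - m)) for s in sites for m in metals
                )
                if dmin < censor_cutoff:
                    continue
            value = symmetric_pcs(truth, sites)
            if noise_sigma > 0:
                value += rng.normal(0.0, noise_sigma)
            dataset.add(res.number, atom, value)
    return dataset


def simulate_peaklists(
    structure: Structure,
    truth: ChiTensor,
    group: SymmetryGroup,
    chain_map: list[str],
    noise_sigma: float = 0.02,
    seed: int = 0,
    censor_cutoff: float | None = PRE_CUTOFF,
    spurious_fraction: float = 0.0,
) -> tuple[list[Peak], list[Peak], dict[int, str]]:
    """Simulate diamagnetic and paramagnetic 2D peak lists.

    Diamagnetic shifts are drawn uniformly from typical amide ranges
    (1H 7-10 ppm, 15N 105-130 ppm).  Paramagnetic peaks are the diamagnetic
    positions plus the per-dimension PCS (evaluated at the H and N
    coordinates respectively) plus Gaussian noise; PRE-censored residues
    have no paramagnetic peak.  Optionally a fraction of spurious peaks is
    injected.  Returns (diamagnetic, paramagnetic, truth assignment map
    residue -> paramagnetic peak id).
    """
    rng = np.random.default_rng(seed)
    metals = _metal_positions(truth, group)
    dia: list[Peak] = []
    para: list[Peak] = []
    truth_map: dict[int, str] = {}
    first = structure.chains[chain_map[0]]
    for res in first.sorted_residues():
        if "H" not in res.atoms or "N" not in res.atoms:
            continue
        try:
            h_sites = equivalent_sites(structure, (res.number, "H"), chain_map)
            n_sites = equivalent_sites(structure, (res.number, "N"), chain_map)
        except Exception:
            continue
        h0 = rng.uniform(7.0, 10.0)
        n0 = rng.uniform(105.0, 130.0)
        dia.append(Peak(id=f"dia{res.number}", h_ppm=h0, n_ppm=n0, assignment=res.number))
        dmin = min(float(np.linalg.norm(s.coord - m)) for s in h_sites for m in metals)
        if censor_cutoff is not None and dmin < censor_cutoff:
            continue  # broadened beyond detection
        pid = f"para{res.number}"
        noise = rng.normal(0.0, noise_sigma, 2) if noise_sigma > 0 else np.zeros(2)
        para.append(
            Peak(
                id=pid,
                h_ppm=h0 + symmetric_pcs(truth, h_sites) + noise[0],
                n_ppm=n0 + symmetric_pcs(truth, n_sites) + noise[1],
            )
        )
        truth_map[res.number] = pid
    n_spurious = int(round(spurious_fraction * len(para)))
    for i in range(n_spurious):
        para.append(
            Peak(
                id=f"spur{i}",
                h_ppm=rng.uniform(4.0, 13.0),
                n_ppm=rng.uniform(100.0, 135.0),
            )
        )
    return dia, para, truth_map


def standard_fixture(
    spec: FixtureSpec | None = None,
) -> tuple[Structure, ChiTensor, SymmetryGroup, PCSDataset]:
    """The standard study: structure, truth tensor, group and PCS dataset."""
    spec = spec or FixtureSpec()
    structure = make_cn_structure(spec)
    truth = default_truth_tensor(structure, spec)
    group = spec.group
    dataset = simulate_pcs(
        structure,
        truth,
        group,
        spec.chain_ids,
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
    )
    return structure, truth, group, dataset
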