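"""Shared fixtures: the standard synthetic C3 study and its expensive fits."""

import numpy as np
import pytest

from symmpcs.assignment import iterative_assign
from symmpcs.fitting import FitProblem, multi_start_fit
from symmpcs.fixtures import (
    FixtureSpec,
    make_cn_structure,
    default_truth_tensor,
    simulate_pcs,
    simulate_peaklists,
)
from symmpcs.model import PCSDataset


@pytest.fixture(scope="session")
def std():
    """Standard study: C3 trimer, 60 spins/chain, sigma 0.02 ppm, seed 42."""
    spec = FixtureSpec(seed=42)
    structure = make_cn_structure(spec)
    truth = default_truth_tensor(structure, spec)
    dataset = simulate_pcs(
        structure, truth, spec.group, spec.chain_ids,
        noise_sigma=spec.noise_sigma, seed=spec.seed,
    )
    return {
        "spec": spec,
        "structure": structure,
        "truth": truth,
        "group": spec.group,
        "dataset": dataset,
        "chain_map": spec.chain_ids,
    }


@pytest.fixture(scope="session")
def std_problem(std):
    return FitProblem(std["structure"], std["dataset"], std["chain_map"])


@pytest.fixture(scope="session")
def std_multistart(std, std_problem):
    """The three symmetry-related minima of the standard study."""
    return multi_start_fit(std_problem, tag_residue=std["spec"].tag_residue)


@pytest.fixture(scope="session")
def peaklists(std):
    """Simulated diamagnetic/paramagnetic peak lists plus truth mapping."""
    spec = std["spec"]
    dia, para, truth_map = simulate_peaklists(
        std["structure"], std["truth"], std["group"], std["chain_map"],
        noise_sigma=spec.noise_sigma, seed=spec.seed,
    )
    return {"dia": dia, "para": para, "truth_map": truth_map}


@pytest.fixture(scope="session")
def seed_pcs(peaklists):
    """Ten seed PCS values: the largest observed-minus-diamagnetic 1H shifts."""
    dia_by = {p.assignment: p for p in peaklists["dia"]}
    para_by = {p.id: p for p in peaklists["para"]}
    pairs = sorted(
        ((r, para_by[pid].h_ppm - dia_by[r].h_ppm)
         for r, pid in peaklists["truth_map"].items()),
        key=lambda x: -abs(x[1]),
    )
    dataset = PCSDataset()
    for residue, value in pairs[:10]:
        dataset.add(residue, "H", value)
    return dataset


@pytest.fixture(scope="session")
def assignment_run(std, peaklists, seed_pcs):
    """Full iterative assignment on the standard study (shared; ~15 s)."""
    return iterative_assign(
        seed_pcs.subset(seed_pcs.keys()),
        peaklists["dia"],
        peaklists["para"],
        std["structure"],
        std["chain_map"],
        std["spec"].tag_residue,
    )


def random_tensor(rng):
    """A physically scaled random tensor for property tests."""
    from symmpcs.model import ChiTensor

    ax = rng.uniform(10.0, 60.0) * rng.choice([-1.0, 1.0])
    rh = rng.uniform(0.0, 2.0 / 3.0) * abs(ax) * rng.choice([-1.0, 1.0])
    return ChiTensor(
        dchi_ax=ax,
        dchi_rh=rh,
        position=rng.uniform(-30, 30, 3),
        euler=tuple(rng.uniform(0, 360, 3)),
    )
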