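"""Cost function oracle, parameter recovery, multi-start minima, diagnostics."""

import numpy as np
import pytest

from symmpcs.errors import UnderdeterminedError
from symmpcs.fitting import (
    FitOptions,
    FitProblem,
    classify_deviation,
    cost_f,
    fit_diagnostics,
    fit_tensor,
    multi_start_fit,
    staged_fit,
    start_position_for_chain,
)
from symmpcs.fixtures import (
    FixtureSpec,
    default_truth_tensor,
    make_cn_structure,
    simulate_pcs,
)
from symmpcs.geometry import apply_rigid
from symmpcs.model import PCSDataset
from symmpcs.symmetry import symmetry_operators


def brute_force_cost(params, problem):
    """Independent implementation of the cost: explicit python loops and an
    explicitly assembled rotation matrix; shares no code with cost_f."""
    ax, rh, px, py, pz, alpha, beta, gamma = [float(v) for v in params]
    a, b, g = np.deg2rad([alpha, beta, gamma])
    Rz1 = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    Ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    Rz2 = np.array([[np.cos(g), -np.sin(g), 0], [np.sin(g), np.cos(g), 0], [0, 0, 1]])
    R = Rz1 @ Ry @ Rz2
    k = 1e4 / (12.0 * np.pi)
    total = 0.0
    for i, key in enumerate(problem.keys):
        calc = 0.0
        for c in range(len(problem.chain_map)):
            v = problem.coords[i, c] - np.array([px, py, pz])
            x, y, z = R.T @ v
            r = np.sqrt(x * x + y * y + z * z)
            calc += k * (ax * (2 * z * z - x * x - y * y) + 1.5 * rh * (x * x - y * y)) / r**5
        total += problem.weights[i] * (problem.values[i] - calc) ** 2
    return total


class TestCostFunction:
    def test_oracle_agreement_on_50_random_problems(self, std):
        rng = np.random.default_rng(99)
        structure = std["structure"]
        worst = 0.0
        for _ in range(50):
            dataset = PCSDataset()
            residues = rng.choice(np.arange(2, 60), size=12, replace=False)
            for res in residues:
                dataset.add(int(res), "H", float(rng.normal(scale=2.0)))
            problem = FitProblem(structure, dataset, std["chain_map"])
            params = np.array([
                rng.uniform(-60, 60), rng.uniform(-20, 20),
                *rng.uniform(-30, 30, 3), *rng.uniform(0, 360, 3),
            ])
            mine = cost_f(params, problem)
            ref = brute_force_cost(params, problem)
            worst = max(worst, abs(mine - ref) / max(abs(ref), 1e-300))
        assert worst < 1e-12

    def test_zero_at_generating_parameters_of_noiseless_data(self, std):
        spec = std["spec"]
        truth = std["truth"]
        noiseless = simulate_pcs(std["structure"], truth, std["group"],
                                 std["chain_map"], noise_sigma=0.0, seed=0)
        problem = FitProblem(std["structure"], noiseless, std["chain_map"])
        params = np.array([truth.dchi_ax, truth.dchi_rh, *truth.position, *truth.euler])
        assert cost_f(params, problem) < 1e-16

    def test_empty_dataset_degenerate_zero(self, std):
        # an empty problem via a dataset whose only key resolves nowhere
        d = PCSDataset()
        d.add(9999, "H", 1.0)
        problem = FitProblem(std["structure"], d, std["chain_map"])
        assert problem.n_points == 0
        assert problem.excluded == [(9999, "H")]
        assert cost_f(np.zeros(8), problem) == 0.0

    def test_metal_on_nucleus_gives_large_finite_penalty(self, std):
        problem = FitProblem(std["structure"], std["dataset"], std["chain_map"])
        spot = problem.coords[0, 0]  # exactly on a nucleus
        params = np.array([-43.0, -7.8, *spot, 0.0, 0.0, 0.0])
        value = cost_f(params, problem)
        assert np.isfinite(value) and value > 1e10


class TestFitTensor:
    def test_exact_recovery_noiseless(self, std):
        spec, truth = std["spec"], std["truth"]
        noiseless = simulate_pcs(std["structure"], truth, std["group"],
                                 std["chain_map"], noise_sigma=0.0, seed=0)
        problem = FitProblem(std["structure"], noiseless, std["chain_map"])
        start = np.array([truth.dchi_ax * 1.3, truth.dchi_rh * 0.5,
                          *(truth.position + [2.0, -2.0, 1.0]), 50.0, 70.0, 10.0])
        result = fit_tensor(problem, start)
        canon = truth.canonicalized()
        assert result.tensor.dchi_ax == pytest.approx(canon.dchi_ax, rel=1e-6)
        assert result.tensor.dchi_rh == pytest.approx(canon.dchi_rh, rel=1e-6)
        assert np.linalg.norm(result.metal_position - truth.position) < 1e-4

    def test_noisy_recovery_within_tolerance(self, std, std_multistart):
        canon = std["truth"].canonicalized()
        r = std_multistart[0]
        assert r.tensor.dchi_ax == pytest.approx(canon.dchi_ax, rel=0.02)
        assert np.linalg.norm(r.metal_position - std["truth"].position) < 0.2

    def test_cost_equals_sum_squared_residuals(self, std_multistart):
        for r in std_multistart:
            ssr = sum(v * v for v in r.residuals.values())
            assert r.cost == pytest.approx(ssr, rel=1e-10)
            assert len(r.residuals) == r.n_points

    def test_underdetermined_rejected(self, std):
        d = PCSDataset()
        for res in range(2, 9):  # 7 points < 8 parameters
            d.add(res, "H", 0.1 * res)
        problem = FitProblem(std["structure"], d, std["chain_map"])
        with pytest.raises(UnderdeterminedError):
            fit_tensor(problem, np.array([-40, -8, 10, 10, 40, 0, 0, 0]))

    def test_proton_only_agrees_with_all_nuclei(self, std, std_multistart):
        options = FitOptions(proton_only=True)
        problem = FitProblem(std["structure"], std["dataset"], std["chain_map"],
                             options=options)
        assert all(k[1] == "H" for k in problem.keys)
        start = start_position_for_chain(std["structure"], "A", std["spec"].tag_residue)
        r = staged_fit(problem, start, label="A")
        full = std_multistart[0]
        # no nucleus bias in the generator: tensors agree within noise scale
        assert r.tensor.dchi_ax == pytest.approx(full.tensor.dchi_ax, rel=0.02)
        assert np.linalg.norm(r.metal_position - full.metal_position) < 0.3


class TestMultiStart:
    def test_three_minima_related_by_symmetry(self, std, std_multistart):
        ops = symmetry_operators(std["group"])
        positions = [r.metal_position for r in std_multistart]
        for k in (1, 2):
            R, t = ops[k]
            rotated = apply_rigid(R, t, positions[0])
            assert np.linalg.norm(rotated - positions[k]) < 1e-3

    def test_costs_equal_across_minima(self, std_multistart):
        costs = [r.cost for r in std_multistart]
        assert np.ptp(costs) / costs[0] < 1e-8

    def test_dchi_identical_across_minima(self, std_multistart):
        ax = [r.tensor.dchi_ax for r in std_multistart]
        rh = [r.tensor.dchi_rh for r in std_multistart]
        assert np.ptp(ax) < 1e-4 and np.ptp(rh) < 1e-4

    def test_labels_follow_chains(self, std_multistart):
        assert [r.start_label for r in std_multistart] == ["A", "B", "C"]
        assert all(r.duplicate_of is None for r in std_multistart)

    def test_jittered_trimer_minima_remain_similar(self):
        spec = FixtureSpec(seed=13, jitter_sigma=0.3, spins_per_chain=40)
        structure = make_cn_structure(spec)
        truth = default_truth_tensor(structure, spec)
        dataset = simulate_pcs(structure, truth, spec.group, spec.chain_ids,
                               noise_sigma=0.02, seed=13)
        problem = FitProblem(structure, dataset, spec.chain_ids)
        results = multi_start_fit(problem, tag_residue=spec.tag_residue)
        ax = [r.tensor.dchi_ax for r in results]
        # three slightly different parameter sets, similar on the jitter scale
        assert np.ptp(ax) / abs(np.mean(ax)) < 0.1


class TestParameterRecoveryReplicates:
    def test_median_errors_over_replicates(self, std):
        """Median recovery error over seeded replicates of the standard study."""
        ax_errors, pos_errors = [], []
        for seed in range(10):
            spec = FixtureSpec(seed=seed)
            structure = make_cn_structure(spec)
            truth = default_truth_tensor(structure, spec)
            dataset = simulate_pcs(structure, truth, spec.group, spec.chain_ids,
                                   noise_sigma=0.02, seed=seed)
            problem = FitProblem(structure, dataset, spec.chain_ids)
            start = start_position_for_chain(structure, "A", spec.tag_residue)
            r = staged_fit(problem, start, label="A")
            canon = truth.canonicalized()
            ax_errors.append(abs(r.tensor.dchi_ax - canon.dchi_ax) / abs(canon.dchi_ax))
            pos_errors.append(np.linalg.norm(r.metal_position - truth.position))
        assert np.median(ax_errors) < 0.02
        assert np.median(pos_errors) < 0.2


class TestConvergenceWithDataSize:
    def test_forty_points_match_full_fit_within_one_percent(self, std, std_multistart):
        rng = np.random.default_rng(17)
        keys = sorted(std["dataset"].keys())
        chosen = [keys[i] for i in rng.choice(len(keys), size=40, replace=False)]
        sub = std["dataset"].subset(chosen)
        problem = FitProblem(std["structure"], sub, std["chain_map"])
        start = start_position_for_chain(std["structure"], "A", std["spec"].tag_residue)
        r40 = staged_fit(problem, start, label="A")
        full = std_multistart[0]
        assert abs(r40.tensor.dchi_ax - full.tensor.dchi_ax) / abs(full.tensor.dchi_ax) < 0.01
        assert abs(r40.tensor.dchi_rh - full.tensor.dchi_rh) / abs(full.tensor.dchi_rh) < 0.05
        assert np.linalg.norm(r40.metal_position - full.metal_position) < 0.2


class TestDiagnostics:
    def test_threshold_classes(self):
        assert [classify_deviation(v) for v in (0.1, 0.3, 0.5)] == ["ok", "warn", "bad"]

    def test_boundaries_half_open_lower_inclusive(self):
        assert classify_deviation(0.2) == "warn"
        assert classify_deviation(0.4) == "bad"
        assert classify_deviation(0.19999) == "ok"

    def test_perfect_fit_statistics(self, std):
        truth = std["truth"]
        noiseless = simulate_pcs(std["structure"], truth, std["group"],
                                 std["chain_map"], noise_sigma=0.0, seed=0)
        problem = FitProblem(std["structure"], noiseless, std["chain_map"])
        start = np.array([truth.dchi_ax, truth.dchi_rh, *truth.position, *truth.euler])
        r = fit_tensor(problem, start)
        d = fit_diagnostics(r)
        assert d.correlation == pytest.approx(1.0, abs=1e-9)
        assert d.rmsd == pytest.approx(0.0, abs=1e-9)
        assert set(d.classes.values()) == {"ok"}
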