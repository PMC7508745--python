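"""Symmetry-reduced eight-parameter tensor fitting.

For one tag site per protomer of a Cn-symmetric multimer, the observed PCS
at spin j equals the PCS generated by a single tensor at the n
symmetry-equivalent copies of j.  The fit therefore has only eight free
parameters -- dchi_ax, dchi_rh, the metal position (x, y, z) and the three
ZYZ Euler angles -- and minimizes the quadratic cost

    f = sum_j w_j * [ PCS_j^exp - sum_chains PCS^calc(tensor, j_chain) ]^2

with a quasi-Newton method (L-BFGS-B, central finite differences).  In a
Cn-symmetric environment f has n equivalent local minima, one per chain the
tag can be thought to sit on; :func:`multi_start_fit` visits all of them by
starting each minimization near a different chain's tag site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import InvalidArgumentError, UnderdeterminedError
from .model import K_PCS, MIN_DISTANCE, ChiTensor, PCSDataset
from .geometry import rotation_from_euler
from .structure import Structure
from .symmetry import SymmetryGroup

log = logging.getLogger(__name__)

__all__ = [
    "FitOptions",
    "FitProblem",
    "FitResult",
    "cost_f",
    "fit_tensor",
    "multi_start_fit",
    "fit_diagnostics",
    "FitDiagnostics",
]

#: Deviation thresholds (ppm) separating the ok / warn / bad classes.
DEVIATION_OK = 0.2
DEVIATION_WARN = 0.4

_PENALTY = 1e12  # finite cost returned when the metal hits a nucleus

# internal parameter scaling: dchi and coordinates divided by 10, angles in
# radians, to condition the quasi-Newton Hessian approximation
_SCALE = np.array([10.0, 10.0, 10.0, 10.0, 10.0, 180.0 / np.pi, 180.0 / np.pi, 180.0 / np.pi])


@dataclass
class FitOptions:
    proton_only: bool = False       # restrict to 1H data (atom name "H")
    min_distance: float = MIN_DISTANCE  # singularity guard, angstrom
    gtol: float = 1e-8              # projected-gradient tolerance (scaled problem)
    max_iterations: int = 2000
    dchi_bound: float = 200.0       # |dchi| bound, 1e-32 m^3
    position_pad: float = 30.0      # metal box: structure bbox + pad, angstrom


class FitProblem:
    """A validated, vectorized fitting problem.

    Every dataset key is resolved to coordinates in all mapped chains;
    unresolvable keys are excluded and recorded in ``excluded``.
    """

    def __init__(
        self,
        structure: Structure,
        dataset: PCSDataset,
        chain_map: list[str],
        options: FitOptions | None = None,
        group: SymmetryGroup | None = None,
    ) -> None:
        self.structure = structure
        self.chain_map = list(chain_map)
        self.options = options or FitOptions()
        self.group = group
        if self.options.proton_only:
            dataset = dataset.filter_atoms(["H"])
        self.dataset = dataset
        keys, coords, values, weights, excluded = [], [], [], [], []
        for key in sorted(dataset.keys()):
            residue, atom = key
            site_coords = []
            for chain in self.chain_map:
                c = structure.find_coord(chain, residue, atom)
                if c is None:
                    break
                site_coords.append(c)
            if len(site_coords) != len(self.chain_map):
                excluded.append(key)
                continue
            keys.append(key)
            coords.append(site_coords)
            values.append(dataset.value(key))
            weights.append(dataset.weight(key))
        if excluded:
            log.warning("excluded %d PCS keys without coordinates in all chains: %s",
                        len(excluded), excluded[:10])
        self.keys: list[tuple[int, str]] = keys
        self.coords = np.array(coords, dtype=float).reshape(len(keys), len(self.chain_map), 3)
        self.values = np.array(values, dtype=float)
        self.weights = np.array(weights, dtype=float)
        self.excluded: list[tuple[int, str]] = excluded

    @property
    def n_points(self) -> int:
        return len(self.keys)

    def position_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.structure.bounding_box()
        return lo - self.options.position_pad, hi + self.options.position_pad


def _tensor_from_params(params: np.ndarray) -> ChiTensor:
    p = np.asarray(params, dtype=float)
    return ChiTensor(
        dchi_ax=p[0], dchi_rh=p[1], position=p[2:5], euler=(p[5], p[6], p[7])
    )


def _calc_sums(tensor: ChiTensor, problem: FitProblem) -> np.ndarray:
    """Per-key symmetric PCS sums, with a finite penalty near singularities."""
    m, nch, _ = problem.coords.shape
    flat = problem.coords.reshape(m * nch, 3) - tensor.position
    local = flat @ tensor.rotation
    x2, y2, z2 = local[:, 0] ** 2, local[:, 1] ** 2, local[:, 2] ** 2
    r2 = x2 + y2 + z2
    guard2 = problem.options.min_distance**2
    bad = r2 < guard2
    r2 = np.maximum(r2, guard2)
    vals = K_PCS * (
        tensor.dchi_ax * (2.0 * z2 - x2 - y2) + 1.5 * tensor.dchi_rh * (x2 - y2)
    ) / r2**2.5
    sums = vals.reshape(m, nch).sum(axis=1)
    if bad.any():
        return sums, True
    return sums, False


def cost_f(params: np.ndarray, problem: FitProblem) -> float:
    """The quadratic cost f (ppm^2) at an 8-parameter vector.

    ``params = (dchi_ax, dchi_rh, x, y, z, alpha, beta, gamma)`` with
    angles in degrees.  A metal position inside the singularity guard of a
    nucleus yields a large finite penalty rather than an exception, so an
    optimizer can retreat from it.
    """
    if problem.n_points == 0:
        log.warning("cost_f on an empty dataset: degenerate problem, f = 0")
        return 0.0
    tensor = _tensor_from_params(params)
    sums, hit = _calc_sums(tensor, problem)
    cost = float(np.sum(problem.weights * (problem.values - sums) ** 2))
    if hit:
        return _PENALTY + cost
    return cost


@dataclass
class FitResult:
    """Outcome of one local minimization."""

    tensor: ChiTensor               # canonicalized parameters
    cost: float                     # final f, ppm^2
    n_points: int
    residuals: dict[tuple[int, str], float]  # exp - calc, ppm
    correlation: float              # Pearson r between exp and calc
    rmsd: float                     # ppm
    start_label: str = ""           # which chain's start produced this minimum
    converged: bool = True
    n_iterations: int = 0
    duplicate_of: str | None = None  # set when another start found the same minimum
    fitted_params: np.ndarray = field(default_factory=lambda: np.zeros(8))

    @property
    def metal_position(self) -> np.ndarray:
        return self.tensor.position


def _result_from_params(
    params: np.ndarray, problem: FitProblem, label: str, converged: bool, nit: int
) -> FitResult:
    tensor = _tensor_from_params(params)
    sums, _ = _calc_sums(tensor, problem)
    res = problem.values - sums
    cost = float(np.sum(problem.weights * res**2))
    if problem.n_points >= 2 and np.std(sums) > 0 and np.std(problem.values) > 0:
        corr = float(np.corrcoef(problem.values, sums)[0, 1])
    else:
        corr = float("nan")
    return FitResult(
        tensor=tensor.canonicalized(),
        cost=cost,
        n_points=problem.n_points,
        residuals={k: float(r) for k, r in zip(problem.keys, res)},
        correlation=corr,
        rmsd=float(np.sqrt(np.mean(res**2))) if problem.n_points else float("nan"),
        start_label=label,
        converged=converged,
        n_iterations=nit,
        fitted_params=np.asarray(params, dtype=float).copy(),
    )


def fit_tensor(problem: FitProblem, start: np.ndarray, label: str = "") -> FitResult:
    """Minimize the cost from one 8-parameter start (degrees for angles)."""
    if problem.n_points < 8:
        raise UnderdeterminedError(
            f"{problem.n_points} PCS values cannot determine 8 parameters"
        )
    start = np.asarray(start, dtype=float)
    if start.shape != (8,):
        raise InvalidArgumentError(f"start must be an 8-vector, got shape {start.shape}")
    opts = problem.options
    x0 = start / _SCALE
    lo, hi = problem.position_bounds()
    bounds = [(-opts.dchi_bound / 10.0, opts.dchi_bound / 10.0)] * 2
    bounds += [(lo[i] / 10.0, hi[i] / 10.0) for i in range(3)]
    bounds += [(None, None)] * 3

    def fun(x: np.ndarray) -> float:
        return cost_f(x * _SCALE, problem)

    opt = minimize(
        fun,
        x0,
        method="L-BFGS-B",
        jac="3-point",
        bounds=bounds,
        options={
            "maxiter": opts.max_iterations,
            "gtol": opts.gtol,
            "ftol": 1e-15,
        },
    )
    if not opt.success:
        log.warning("fit from start %s did not fully converge: %s", label, opt.message)
    return _result_from_params(
        opt.x * _SCALE, problem, label, bool(opt.success), int(opt.nit)
    )


def estimate_dchi(problem: FitProblem, position: np.ndarray, euler: tuple) -> tuple[float, float]:
    """Linear least-squares estimate of (dchi_ax, dchi_rh) at fixed geometry.

    The PCS is linear in the two anisotropy values, so for a candidate
    metal position and orientation the optimal pair has a closed form;
    used to seed the nonlinear fit.
    """
    basis = []
    for ax, rh in ((1.0, 0.0), (0.0, 1.0)):
        t = ChiTensor(dchi_ax=ax, dchi_rh=rh, position=position, euler=euler)
        sums, _ = _calc_sums(t, problem)
        basis.append(sums)
    A = np.column_stack(basis) * np.sqrt(problem.weights)[:, None]
    b = problem.values * np.sqrt(problem.weights)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(sol[0]), float(sol[1])


def fit_axial_start(
    problem: FitProblem,
    position: np.ndarray,
    alphas: tuple = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0),
    betas: tuple = (30.0, 90.0, 150.0),
) -> np.ndarray:
    """Best axial-only (rhombicity-free) parameter vector near a position.

    Fits the 6-parameter axial model (dchi_ax, position, alpha, beta) from
    a coarse orientation grid and returns the winning 8-parameter vector
    (dchi_rh = 0, gamma = 0) for use as a full-fit start.  With few data
    points the full 8-parameter problem is barely determined and noise can
    carve spurious minima; the axial model is much better conditioned and
    lands in the right basin.
    """
    position = np.asarray(position, dtype=float)

    def fun(x: np.ndarray) -> float:
        return cost_f(
            np.array([x[0] * 10.0, 0.0, x[1] * 10.0, x[2] * 10.0, x[3] * 10.0,
                      np.rad2deg(x[4]), np.rad2deg(x[5]), 0.0]),
            problem,
        )

    best = None
    for alpha in alphas:
        for beta in betas:
            ax, _ = estimate_dchi(problem, position, (alpha, beta, 0.0))
            x0 = np.array([ax / 10.0, *(position / 10.0),
                           np.deg2rad(alpha), np.deg2rad(beta)])
            opt = minimize(fun, x0, method="L-BFGS-B", jac="3-point",
                           options={"maxiter": problem.options.max_iterations,
                                    "ftol": 1e-15, "gtol": problem.options.gtol})
            if best is None or opt.fun < best.fun:
                best = opt
    x = best.x
    return np.array([x[0] * 10.0, 0.0, x[1] * 10.0, x[2] * 10.0, x[3] * 10.0,
                     np.rad2deg(x[4]) % 360.0, np.rad2deg(x[5]) % 360.0, 0.0])


#: Below this many data points the cost surface is too shallow to trust a
#: comparison of competing full-model minima; the staged fit then relies
#: on the axial-stage basin alone.
FULL_FIT_THRESHOLD = 20


def staged_fit(
    problem: FitProblem,
    position: np.ndarray,
    label: str = "",
    prev_params: np.ndarray | None = None,
) -> FitResult:
    """Axial-stage-then-full fit from one start position.

    With fewer than :data:`FULL_FIT_THRESHOLD` points, the full model is
    refined only from the axial-stage solution.  With more data, the full
    fit is additionally started from a set of orientation seeds (linear
    dchi estimates) and optionally a warm start, and the lowest-cost
    minimum wins.
    """
    p_ax = fit_axial_start(problem, position)
    candidates = [fit_tensor(problem, p_ax, label=label)]
    if problem.n_points >= FULL_FIT_THRESHOLD:
        if prev_params is not None:
            candidates.append(fit_tensor(problem, prev_params, label=label))
        for euler in DEFAULT_EULER_STARTS:
            ax, rh = estimate_dchi(problem, position, euler)
            start = np.array([ax, rh, *position, *euler])
            candidates.append(fit_tensor(problem, start, label=label))
    return min(candidates, key=lambda r: r.cost)


#: Orientation seeds tried at each start position; the linear dchi estimate
#: is recomputed for each, and the best converged minimum is kept.
DEFAULT_EULER_STARTS = ((0.0, 0.0, 0.0), (0.0, 60.0, 0.0), (120.0, 60.0, 240.0), (240.0, 120.0, 60.0))

#: Distance from the tag-residue C-beta at which a start metal is placed,
#: along the C-alpha -> C-beta direction (typical tag-arm length).
TAG_START_OFFSET = 6.0


def start_position_for_chain(
    structure: Structure, chain: str, tag_residue: int, offset: float = TAG_START_OFFSET
) -> np.ndarray:
    """Start heuristic: tag-residue CB + ``offset`` angstrom outward along CA->CB."""
    ca = structure.find_coord(chain, tag_residue, "CA")
    cb = structure.find_coord(chain, tag_residue, "CB")
    if ca is None or cb is None:
        raise InvalidArgumentError(
            f"tag residue {tag_residue} needs CA and CB in chain {chain}"
        )
    d = cb - ca
    return cb + offset * d / np.linalg.norm(d)


def multi_start_fit(
    problem: FitProblem,
    tag_residue: int | None = None,
    start_positions: dict[str, np.ndarray] | None = None,
) -> list[FitResult]:
    """One staged fit per chain, each started near that chain's tag site.

    Returns results in chain-map order, labelled by chain.  Starts that
    converge to a minimum already found (metal positions within 1 angstrom)
    are flagged as duplicates with a warning.
    """
    if start_positions is None:
        if tag_residue is None:
            raise InvalidArgumentError("need tag_residue or explicit start_positions")
        start_positions = {
            chain: start_position_for_chain(problem.structure, chain, tag_residue)
            for chain in problem.chain_map
        }
    results: list[FitResult] = [
        staged_fit(problem, pos, label=chain)
        for chain, pos in start_positions.items()
    ]
    for i, a in enumerate(results):
        for b in results[:i]:
            if np.linalg.norm(a.metal_position - b.metal_position) < 1.0:
                a.duplicate_of = b.start_label
                log.warning(
                    "starts %s and %s converged to the same minimum "
                    "(metal positions within 1 A)", a.start_label, b.start_label,
                )
    return results


@dataclass
class FitDiagnostics:
    """Per-residue deviation classes plus global fit-quality numbers."""

    classes: dict[int, str]         # residue -> ok | warn | bad
    correlation: float
    rmsd: float

    def table(self) -> str:
        lines = ["# residue class"]
        lines += [f"{res}\t{cls}" for res, cls in sorted(self.classes.items())]
        return "\n".join(lines) + "\n"


def classify_deviation(dev: float) -> str:
    """Half-open deviation classes, lower bound inclusive (ppm)."""
    dev = abs(dev)
    if dev < DEVIATION_OK:
        return "ok"
    if dev < DEVIATION_WARN:
        return "warn"
    return "bad"


def fit_diagnostics(result: FitResult) -> FitDiagnostics:
    """Classify each residue by its total PCS deviation (summed over atoms)."""
    per_residue: dict[int, float] = {}
    for (residue, _atom), r in result.residuals.items():
        per_residue[residue] = per_residue.get(residue, 0.0) + abs(r)
    classes = {res: classify_deviation(d) for res, d in per_residue.items()}
    return FitDiagnostics(
        classes=classes, correlation=result.correlation, rmsd=result.rmsd
    )
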