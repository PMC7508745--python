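"""Iterative assignment of the paramagnetic spectrum.

The PCS of an amide is the difference between its peak position in the
paramagnetic spectrum and in the diamagnetic reference.  Starting from a
small set of unambiguous PCS values, the tensor is approximated, the
paramagnetic peak positions are back-predicted from the assigned
diamagnetic spectrum, predicted and observed peaks are matched, the new
matches yield further PCS values, and the cycle repeats until no further
assignments are possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidArgumentError, ParseError
from .fitting import (
    FitProblem,
    FitResult,
    staged_fit,
    start_position_for_chain,
)
from .model import ChiTensor, PCSDataset
from .structure import Structure
from .symmetry import equivalent_sites, symmetric_pcs

log = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "read_peak_list",
    "write_peak_list",
    "back_predict_peaks",
    "match_peaks",
    "iterative_assign",
    "AssignmentResult",
]

#: Default matching tolerances (ppm), on the order of TROSY linewidths.
TOL_H = 0.05
TOL_N = 0.5

#: Two match candidates whose scaled distances are within this factor of
#: each other are considered ambiguous and both left unassigned.
AMBIGUITY_FACTOR = 1.1


@dataclass(frozen=True)
class Peak:
    """One 2D amide correlation peak."""

    id: str
    h_ppm: float
    n_ppm: float
    assignment: int | None = None  # residue number, when known

    def __post_init__(self) -> None:
        if not (np.isfinite(self.h_ppm) and np.isfinite(self.n_ppm)):
            raise InvalidArgumentError(f"non-finite shifts for peak {self.id}")


def read_peak_list(path: str) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ParseError(f"{path}:{lineno}: expected 3-4 columns")
            try:
                assignment = int(parts[3]) if len(parts) == 4 else None
                peaks.append(
                    Peak(id=parts[0], h_ppm=float(parts[1]), n_ppm=float(parts[2]),
                         assignment=assignment)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peak_list(peaks: list[Peak], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# id h_ppm n_ppm assignment\n")
        for p in peaks:
            a = "" if p.assignment is None else f"\t{p.assignment}"
            fh.write(f"{p.id}\t{p.h_ppm:.4f}\t{p.n_ppm:.4f}{a}\n")


def back_predict_peaks(
    diamagnetic: list[Peak],
    tensor: ChiTensor,
    structure: Structure,
    chain_map: list[str],
) -> list[Peak]:
    """Predict paramagnetic peak positions from assigned diamagnetic peaks.

    Each prediction adds the symmetric PCS, evaluated at the amide H
    coordinate for the 1H dimension and at the N coordinate for the 15N
    dimension.  Residues lacking coordinates are skipped with a warning.
    """
    predicted = []
    for peak in diamagnetic:
        if peak.assignment is None:
            continue
        try:
            h_sites = equivalent_sites(structure, (peak.assignment, "H"), chain_map)
            n_sites = equivalent_sites(structure, (peak.assignment, "N"), chain_map)
        except Exception:
            log.warning("no coordinates for residue %s; peak %s skipped",
                        peak.assignment, peak.id)
            continue
        predicted.append(
            replace(
                peak,
                h_ppm=peak.h_ppm + symmetric_pcs(tensor, h_sites),
                n_ppm=peak.n_ppm + symmetric_pcs(tensor, n_sites),
            )
        )
    return predicted


def match_peaks(
    predicted: list[Peak],
    observed: list[Peak],
    tol_h: float = TOL_H,
    tol_n: float = TOL_N,
) -> list[tuple[Peak, Peak]]:
    """One-to-one matching of predicted to observed peaks.

    Distances are measured in tolerance-scaled ppm space,
    ``d^2 = (dh/tol_h)^2 + (dn/tol_n)^2``; a match requires ``d <= 1``,
    mutual nearest-neighborhood, and no ambiguity: if a second candidate
    lies within 10% of the best candidate's distance (on either side of
    the pairing) both peaks stay unassigned.  The rule is order-independent.
    """
    if tol_h <= 0 or tol_n <= 0:
        raise InvalidArgumentError("matching tolerances must be positive")
    if not predicted or not observed:
        return []
    P = np.array([[p.h_ppm, p.n_ppm] for p in predicted])
    O = np.array([[o.h_ppm, o.n_ppm] for o in observed])
    scale = np.array([tol_h, tol_n])
    D = np.sqrt(
        (((P[:, None, :] - O[None, :, :]) / scale) ** 2).sum(axis=2)
    )  # (n_pred, n_obs)

    def best_two(row: np.ndarray) -> tuple[int, float, float]:
        order = np.argsort(row)
        second = row[order[1]] if len(order) > 1 else np.inf
        return int(order[0]), float(row[order[0]]), float(second)

    matches = []
    for i in range(len(predicted)):
        j, d, d2_pred = best_two(D[i])
        if d > 1.0:
            continue
        jj, dd, d2_obs = best_two(D[:, j])
        if jj != i:
            continue  # not mutual
        if d2_pred <= AMBIGUITY_FACTOR * d or d2_obs <= AMBIGUITY_FACTOR * d:
            continue  # ambiguous on either side
        matches.append((predicted[i], observed[j]))
    return matches


@dataclass
class AssignmentResult:
    fit: FitResult
    assignments: dict[int, str]       # residue -> observed peak id
    dataset: PCSDataset               # final PCS set used for the fit
    rounds: int
    trace: list[dict]                 # per-round summary
    converged: bool


def iterative_assign(
    seed_pcs: PCSDataset,
    diamagnetic: list[Peak],
    observed: list[Peak],
    structure: Structure,
    chain_map: list[str],
    tag_residue: int,
    tol_h: float = TOL_H,
    tol_n: float = TOL_N,
    max_rounds: int = 20,
    include_nitrogen: bool = False,
    fit_options=None,
) -> AssignmentResult:
    """Assign the paramagnetic spectrum by iterated fit / predict / match.

    Assignments only accumulate (existing matches are never revoked), so
    the loop reaches a fixed point or stops after ``max_rounds``.  Each
    emitted PCS value is exactly the observed-minus-diamagnetic shift
    difference in the dimension it came from (1H by default; 15N values
    are added as separate entries when ``include_nitrogen`` is set).
    """
    if len(seed_pcs) < 8:
        raise InvalidArgumentError(
            f"seed PCS set of {len(seed_pcs)} entries cannot determine 8 parameters"
        )
    dataset = seed_pcs.subset(seed_pcs.keys())
    assignments: dict[int, str] = {}
    used_obs: set[str] = set()
    dia_by_res = {p.assignment: p for p in diamagnetic if p.assignment is not None}
    trace: list[dict] = []
    fit = None
    converged = False
    start = start_position_for_chain(structure, chain_map[0], tag_residue)
    prev_params = None
    for round_no in range(1, max_rounds + 1):
        problem = FitProblem(structure, dataset, chain_map, options=fit_options)
        fit = staged_fit(problem, start, label=chain_map[0], prev_params=prev_params)
        prev_params = fit.fitted_params
        unassigned_dia = [
            p for res, p in dia_by_res.items() if res not in assignments
        ]
        predicted = back_predict_peaks(unassigned_dia, fit.tensor, structure, chain_map)
        candidates = [o for o in observed if o.id not in used_obs]
        matches = match_peaks(predicted, candidates, tol_h=tol_h, tol_n=tol_n)
        new = 0
        for pred, obs in matches:
            residue = pred.assignment
            dia = dia_by_res[residue]
            if (residue, "H") not in dataset:
                dataset.add(residue, "H", obs.h_ppm - dia.h_ppm)
            if include_nitrogen and (residue, "N") not in dataset:
                dataset.add(residue, "N", obs.n_ppm - dia.n_ppm)
            assignments[residue] = obs.id
            used_obs.add(obs.id)
            new += 1
        trace.append(
            {"round": round_no, "n_pcs": len(dataset), "new_assignments": new,
             "cost": fit.cost}
        )
        log.info("assignment round %d: %d new matches, %d PCS values",
                 round_no, new, len(dataset))
        if new == 0:
            converged = True
            break
    if not converged:
        log.warning("assignment did not reach a fixed point in %d rounds", max_rounds)
    # final refit on the complete dataset
    problem = FitProblem(structure, dataset, chain_map, options=fit_options)
    fit = staged_fit(problem, start, label=chain_map[0], prev_params=prev_params)
    return AssignmentResult(
        fit=fit,
        assignments=assignments,
        dataset=dataset,
        rounds=len(trace),
        trace=trace,
        converged=converged,
    )


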