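"""Metabolite-constrained flux balance analysis.

The linear program maximizes flux through the designated ATP-demand
reaction subject to steady state (S·v = 0) and bounds; a secondary
parsimonious step minimizes total absolute flux at the fixed optimum so the
returned distribution is unique and solver-independent. Measured tissue
metabolite levels enter as proportional scalings of exchange upper bounds
against the control-group mean (NMR yields relative pool sizes, not
fluxes, so the mapping is explicit and configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicNetwork

logger = logging.getLogger(__name__)


class FBAError(ValueError):
    pass


@dataclass
class FluxProblem:
    S: np.ndarray  # metabolites x reactions
    bounds: list[tuple[float, float]]
    reaction_ids: list[str]
    metabolite_ids: list[str]
    objective_id: str

    def __post_init__(self) -> None:
        if self.S.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise FBAError("S shape inconsistent with id lists")
        if len(self.bounds) != len(self.reaction_ids):
            raise FBAError("one bound pair per reaction required")
        if self.objective_id not in self.reaction_ids:
            raise FBAError(f"objective {self.objective_id!r} not a reaction")

    @property
    def objective_index(self) -> int:
        return self.reaction_ids.index(self.objective_id)


@dataclass
class FluxDistribution:
    sample_id: str
    status: str  # optimal | infeasible | unbounded
    objective: float | None = None
    fluxes: dict[str, float] | None = None
    mass_balance_residual: float | None = None

    def flux(self, rxn_id: str) -> float:
        if self.fluxes is None:
            raise FBAError(f"no flux vector (status {self.status})")
        return self.fluxes[rxn_id]


def problem_from_network(network: MetabolicNetwork) -> FluxProblem:
    S, met_ids, rxn_ids = network.stoichiometric_matrix()
    bounds = [(r.lb, r.ub) for r in network.reactions]
    return FluxProblem(
        S=S, bounds=bounds, reaction_ids=rxn_ids, metabolite_ids=met_ids,
        objective_id=network.atp_demand.id,
    )


def constrain_from_concentrations(
    network: MetabolicNetwork,
    sample: dict[str, float],
    reference: dict[str, float],
    v_max: float,
) -> FluxProblem:
    """Scale exchange upper bounds by measured concentration ratios.

    For each measured metabolite mapped to an exchange reaction, the uptake
    upper bound becomes ``v_max * c_sample / c_reference`` (reference =
    control-group mean). Internal reactions keep their default wide bounds
    ("without constraining enzymatic activities"); unmeasured exchanges
    keep defaults. Measured metabolites with no mapped exchange are skipped
    with a log entry.
    """
    if v_max <= 0:
        raise FBAError("v_max must be positive")
    problem = problem_from_network(network)
    index = {rid: i for i, rid in enumerate(problem.reaction_ids)}
    for met, conc in sample.items():
        rxn = network.exchange_for(met)
        if rxn is None:
            logger.warning("measured metabolite %r has no mapped exchange; skipped", met)
            continue
        if met not in reference:
            raise FBAError(f"no reference concentration for {met!r}")
        if reference[met] <= 0:
            raise FBAError(f"non-positive reference concentration for {met!r}")
        i = index[rxn.id]
        lb = problem.bounds[i][0]
        ub = v_max * conc / reference[met]
        problem.bounds[i] = (min(lb, ub), ub)
    return problem


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


def solve_fba(problem: FluxProblem, sample_id: str = "sample") -> FluxDistribution:
    """Maximize the objective flux, then minimize total |v| at the optimum."""
    n = len(problem.reaction_ids)
    c = np.zeros(n)
    c[problem.objective_index] = -1.0
    primary = linprog(
        c, A_eq=problem.S, b_eq=np.zeros(problem.S.shape[0]),
        bounds=problem.bounds, method="highs",
    )
    status = _STATUS.get(primary.status, "failed")
    if status != "optimal":
        return FluxDistribution(sample_id=sample_id, status=status)
    v_opt = -primary.fun

    # parsimonious step: variables [v; u], minimize sum(u) with |v| <= u and
    # the objective flux pinned (tiny slack for solver tolerance).
    S = problem.S
    m = S.shape[0]
    A_eq = np.hstack([S, np.zeros((m, n))])
    eye = np.eye(n)
    A_ub = np.vstack([
        np.hstack([eye, -eye]),    # v - u <= 0
        np.hstack([-eye, -eye]),   # -v - u <= 0
    ])
    slack = 1e-9 * max(1.0, abs(v_opt))
    bounds = list(problem.bounds)
    lo, hi = bounds[problem.objective_index]
    bounds[problem.objective_index] = (max(lo, v_opt - slack), min(hi, v_opt + slack))
    bounds = bounds + [(0.0, None)] * n
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    secondary = linprog(
        c2, A_ub=A_ub, b_ub=np.zeros(2 * n), A_eq=A_eq,
        b_eq=np.zeros(m), bounds=bounds, method="highs",
    )
    if secondary.status != 0:  # fall back to the primary vertex
        v = primary.x
    else:
        v = secondary.x[:n]
    residual = float(np.max(np.abs(S @ v))) if n else 0.0
    fluxes = {rid: float(v[i]) for i, rid in enumerate(problem.reaction_ids)}
    return FluxDistribution(
        sample_id=sample_id, status="optimal", objective=float(v_opt),
        fluxes=fluxes, mass_balance_residual=residual,
    )


def solve_cohort(
    network: MetabolicNetwork,
    table,
    tissue: str,
    reference_group: str,
    v_max: float,
) -> list[FluxDistribution]:
    """One metabolite-constrained LP per sample of a tissue.

    The reference is the control-group mean concentration per metabolite,
    restricted to metabolites that map onto exchange reactions.
    """
    sub = table.subset(tissue)
    measured = [m for m in sub.metabolites if network.exchange_for(m) is not None]
    reference = {
        m: float(np.nanmean(sub.values(m, group=reference_group))) for m in measured
    }
    distributions = []
    for _, row in sub.data.iterrows():
        sample = {m: float(row[m]) for m in measured if np.isfinite(row[m])}
        problem = constrain_from_concentrations(network, sample, reference, v_max)
        distributions.append(solve_fba(problem, sample_id=str(row["sample_id"])))
    return distributions
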