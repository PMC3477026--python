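"""Expression-constrained flux fitting.

The predictor chooses, among all steady-state flux patterns, the one whose
fluxes track the expression-derived reaction weightings most closely:

    minimise  Z = sum_i (1/sigma_i) |v_i - d_i|

subject to N.v = 0 and L <= v <= U, where the sum runs over reactions with a
known flux direction and available expression data. The absolute deviations
are linearised as v_i = s_i d_i + d_i^+ - d_i^-, d_i^+/- >= 0 (s_i the sign of
the committed direction), so the whole fit is a linear program.

Because the direction of a reversible reaction is a priori arbitrary, scoring
proceeds iteratively: fit over the currently irreversible reactions, run flux
variability analysis (FVA) under the constraint Z <= Z*, commit every reaction
whose range has collapsed to one sign, and repeat. The irreversible set never
shrinks, so the loop terminates. Reactions still reversible at termination
never enter Z.

Alternate optima are resolved by geometric centring: within the optimal
polytope {N.v = 0, bounds, Z <= Z*}, flux ranges are computed, the fluxes are
pulled towards the per-reaction range midpoints (an L1 projection), and the
bounds are tightened around the projected point until the remaining range is
negligible. The result is a unique, reproducible representative of the
solution space.

Fluxes are fitted in expression units; physical units enter only through the
final rescaling to the measured glucose uptake.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .expression import ExpressionProfile, ReactionWeights, map_expression
from .lp import FluxLP, InfeasibleError
from .model_io import MetabolicModel

__all__ = [
    "FitProblem",
    "FitResult",
    "initial_problem",
    "solve_weighted_fit",
    "fva_under_objective",
    "iterative_fit",
    "center_solution",
    "scale_to_glucose",
    "find_glucose_exchange",
    "ExpressionFluxModel",
    "ExpressionFluxResults",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-9
CENTER_CONV_TOL = 1e-6
CENTER_MAX_ITER = 50


@dataclass
class FitProblem:
    """State of the direction-assignment iteration.

    ``direction_map`` holds the committed direction sign (+1 forward, -1
    backward) of every currently irreversible reaction; ``scored_set`` is the
    subset of those that carry expression data and hence enter Z. Bounds are
    working copies — committing a direction clamps the opposing bound to 0.
    """

    model: MetabolicModel
    weights: ReactionWeights
    scored_set: set[str] = field(default_factory=set)
    direction_map: dict[str, int] = field(default_factory=dict)
    lower_bounds: np.ndarray = None
    upper_bounds: np.ndarray = None

    def __post_init__(self) -> None:
        if self.lower_bounds is None:
            self.lower_bounds = self.model.lower_bounds.copy()
        if self.upper_bounds is None:
            self.upper_bounds = self.model.upper_bounds.copy()
        bad = self.scored_set - self.weights.has_data
        if bad:
            raise ValueError(f"scored reactions without data: {sorted(bad)}")
        undirected = self.scored_set - set(self.direction_map)
        if undirected:
            raise ValueError(f"scored reactions without direction: {sorted(undirected)}")


def initial_problem(model: MetabolicModel, weights: ReactionWeights) -> FitProblem:
    """Fit problem over the initial (bound-derived) irreversible set."""
    directions = model.initial_directions()
    scored = set(directions) & weights.has_data
    return FitProblem(model=model, weights=weights, scored_set=scored, direction_map=directions)


def _build_fit_lp(problem: FitProblem) -> tuple[FluxLP, dict[str, float]]:
    """LP with one |v_i - s_i d_i| deviation pair per scored reaction."""
    lp = FluxLP(problem.model)
    for i, rid in enumerate(problem.model.reaction_ids):
        lp.set_bounds(rid, problem.lower_bounds[i], problem.upper_bounds[i])
    conf = {}
    for rid in sorted(problem.scored_set):
        sign = problem.direction_map[rid]
        lp.add_deviation(rid, sign * problem.weights.d[rid])
        conf[rid] = 1.0 / problem.weights.sigma[rid]
    return lp, conf


def solve_weighted_fit(problem: FitProblem) -> tuple[float, np.ndarray]:
    """Minimise the confidence-weighted absolute deviation Z.

    Returns (Z*, v). With an empty scored set Z* is 0 and the zero vector is
    returned when feasible (it always satisfies N.v = 0), otherwise any
    feasible vector.
    """
    if not problem.scored_set:
        if np.all(problem.lower_bounds <= 0) and np.all(problem.upper_bounds >= 0):
            return 0.0, np.zeros(problem.model.n_reactions)
        lp = FluxLP(problem.model)
        for i, rid in enumerate(problem.model.reaction_ids):
            lp.set_bounds(rid, problem.lower_bounds[i], problem.upper_bounds[i])
        lp.set_objective(0.0 * lp.v(problem.model.reaction_ids[0]), "min")
        lp.optimize(context="feasibility with empty scored set")
        return 0.0, lp.fluxes()
    lp, conf = _build_fit_lp(problem)
    lp.set_objective(lp.deviation_expr(conf), "min")
    zstar = lp.optimize(context="weighted deviation fit")
    return max(zstar, 0.0), lp.fluxes()


def fva_under_objective(
    problem: FitProblem, zstar: float, tol: float = DEFAULT_TOL
) -> dict[str, tuple[float, float]]:
    """Flux ranges subject to the fit staying (near-)optimal, Z <= Z* + tol."""
    lp, conf = _build_fit_lp(problem)
    if problem.scored_set:
        lp.add_constraint(lp.deviation_expr(conf), ub=zstar + tol, name="z_cap")
    return lp.fva()


@dataclass
class FitResult:
    """Outcome of the iterative direction-assignment fit (pre-centring)."""

    flux: np.ndarray
    objective: float
    iterations: int
    irreversible_trace: list[int]
    scored_count: int
    problem: FitProblem


def iterative_fit(
    model: MetabolicModel,
    weights: ReactionWeights,
    tol: float = DEFAULT_TOL,
    max_iter: int = 100,
) -> FitResult:
    """Alternate the weighted fit with FVA until the irreversible set is stable.

    Each cycle: (1) minimise Z over the current scored set; (2) FVA under
    Z <= Z* classifies reversible reactions whose feasible range lies on one
    side of zero as newly unidirectional; (3) they join the irreversible set
    (and, when they carry data, the scored set with the sign found) and the
    fit is re-solved. The set never shrinks, so termination is guaranteed;
    ``max_iter`` is a safety net only.
    """
    problem = initial_problem(model, weights)
    trace: list[int] = []
    zstar, v = 0.0, np.zeros(model.n_reactions)
    for iteration in range(1, max_iter + 1):
        zstar, v = solve_weighted_fit(problem)
        ranges = fva_under_objective(problem, zstar, tol)
        grew = False
        for i, rid in enumerate(model.reaction_ids):
            if rid in problem.direction_map:
                continue
            lo, hi = ranges[rid]
            if lo >= -tol:
                problem.direction_map[rid] = +1
                problem.lower_bounds[i] = max(problem.lower_bounds[i], 0.0)
                grew = True
            elif hi <= tol:
                problem.direction_map[rid] = -1
                problem.upper_bounds[i] = min(problem.upper_bounds[i], 0.0)
                grew = True
            else:
                continue
            if rid in weights.has_data:
                problem.scored_set.add(rid)
        trace.append(len(problem.direction_map))
        if not grew:
            return FitResult(
                flux=v,
                objective=zstar,
                iterations=iteration,
                irreversible_trace=trace,
                scored_count=len(problem.scored_set),
                problem=problem,
            )
    raise RuntimeError(
        f"direction assignment did not stabilise in {max_iter} iterations; trace={trace}"
    )


def center_solution(
    problem: FitProblem,
    zstar: float,
    tol: float = DEFAULT_TOL,
    conv_tol: float = CENTER_CONV_TOL,
    max_iter: int = CENTER_MAX_ITER,
) -> np.ndarray:
    """Geometric centre of the alternate-optima polytope {Eq. 1, Z <= Z*}.

    Iteratively: compute per-reaction flux ranges, L1-project onto the range
    midpoints, then tighten each reaction's bounds to the interval spanned by
    the projection and the midpoint. Ranges at least halve each pass, so the
    iteration converges geometrically; it stops when every range is below
    ``conv_tol`` and returns the last projection (with a warning if the cap
    ``max_iter`` is hit first).
    """
    lp, conf = _build_fit_lp(problem)
    if problem.scored_set:
        lp.add_constraint(lp.deviation_expr(conf), ub=zstar + tol, name="z_cap")
    rids = problem.model.reaction_ids
    # midpoint-deviation machinery: v_r = m_r + p_r - q_r, updated each pass
    aux: dict[str, tuple] = {}
    for rid in rids:
        p = lp.add_variable(f"cp_{rid}", lb=0)
        q = lp.add_variable(f"cq_{rid}", lb=0)
        con = lp.add_constraint(lp.v(rid) - p + q, lb=0.0, ub=0.0, name=f"ctr_{rid}")
        aux[rid] = (p, q, con)
    center_obj = sum(p + q for p, q, _ in aux.values())

    margin = 1e-9  # keeps tightened bounds solver-feasible
    v = np.zeros(len(rids))
    for _ in range(max_iter):
        ranges = lp.fva(rids)
        spread = max(hi - lo for lo, hi in ranges.values())
        for rid in rids:
            lo, hi = ranges[rid]
            m = 0.5 * (lo + hi)
            _, _, con = aux[rid]
            con.lb = None
            con.ub = m
            con.lb = m
        lp.set_objective(center_obj, "min")
        lp.optimize(context="geometric centring projection")
        v = lp.fluxes()
        if spread < conv_tol:
            return v
        for i, rid in enumerate(rids):
            lo, hi = ranges[rid]
            m = 0.5 * (lo + hi)
            lp.set_bounds(rid, min(v[i], m) - margin, max(v[i], m) + margin)
    logger.warning(
        "geometric centring did not converge in %d iterations (spread %.3g)",
        max_iter,
        spread,
    )
    return v


def find_glucose_exchange(model: MetabolicModel, glucose_exchange_id: Optional[str] = None) -> str:
    """Locate the glucose exchange reaction, by explicit id or name heuristic."""
    if glucose_exchange_id is not None:
        if glucose_exchange_id not in model.reaction_ids:
            raise KeyError(f"no reaction {glucose_exchange_id!r} in model")
        return glucose_exchange_id
    hits = [
        rid
        for rid in model.exchange_ids
        if "glc" in rid.lower() or "glucose" in rid.lower()
    ]
    if len(hits) != 1:
        raise ValueError(
            f"could not identify a unique glucose exchange (candidates: {hits}); "
            "pass glucose_exchange_id explicitly"
        )
    return hits[0]


def scale_to_glucose(
    v: np.ndarray,
    model: MetabolicModel,
    measured_uptake: float,
    glucose_exchange_id: Optional[str] = None,
) -> np.ndarray:
    """Rescale a flux vector so glucose uptake equals the measured rate.

    The fit is carried out in expression units; multiplying every flux by
    measured_uptake / |predicted glucose uptake| converts the whole pattern to
    physical units (mmol/h/gDW) without disturbing flux ratios.
    """
    rid = find_glucose_exchange(model, glucose_exchange_id)
    predicted = v[model.reaction_index(rid)]
    if abs(predicted) < 1e-12:
        raise ValueError(
            f"predicted glucose uptake through {rid} is zero; cannot normalise"
        )
    return v * (measured_uptake / abs(predicted))


# ---------------------------------------------------------------------------
# Model / Results layer
# ---------------------------------------------------------------------------


class ExpressionFluxModel:
    """Expression-constrained flux prediction on a metabolic network.

    Parameters
    ----------
    model
        The metabolic network (see :func:`transflux.model_io.load_model`).
    profile
        Per-gene absolute expression (e.g. RPKM). Either this or ``weights``
        must be given; a profile is mapped through the GPR rules.
    weights
        Pre-computed reaction weightings, if GPR mapping was done separately.
    sigma_floor
        Lower bound on sigma_i, keeping 1/sigma_i finite (expression units).

    Examples
    --------
    >>> mdl = ExpressionFluxModel.from_files("yeast.xml", "expression.tsv")
    >>> res = mdl.fit()
    >>> res.scale_to_glucose(16.5).loc[res.exchange_ids]
    """

    def __init__(
        self,
        model: MetabolicModel,
        profile: Optional[ExpressionProfile] = None,
        weights: Optional[ReactionWeights] = None,
        sigma_floor: float = 1e-6,
    ):
        if weights is None:
            if profile is None:
                raise ValueError("provide an expression profile or reaction weights")
            weights = map_expression(model, profile, sigma_floor=sigma_floor)
        self.model = model
        self.profile = profile
        self.weights = weights

    @classmethod
    def from_files(
        cls, sbml_path: str, expression_path: str, sigma_floor: float = 1e-6
    ) -> "ExpressionFluxModel":
        from .expression import load_expression
        from .model_io import load_model

        model = load_model(sbml_path)
        profile = load_expression(expression_path)
        return cls(model, profile=profile, sigma_floor=sigma_floor)

    def fit(
        self, tol: float = DEFAULT_TOL, center: bool = True, max_iter: int = 100
    ) -> "ExpressionFluxResults":
        """Run the iterative fit; optionally centre the optimal polytope."""
        result = iterative_fit(self.model, self.weights, tol=tol, max_iter=max_iter)
        flux = result.flux
        if center:
            flux = center_solution(result.problem, result.objective, tol=tol)
        return ExpressionFluxResults(self, result, flux)


class ExpressionFluxResults:
    """Fitted flux distribution with its optimisation diagnostics."""

    def __init__(self, model: ExpressionFluxModel, fit_result: FitResult, flux: np.ndarray):
        self.model = model
        self.fit_result = fit_result
        self._flux = np.asarray(flux, dtype=float)

    @property
    def fluxes(self) -> pd.Series:
        """Centred flux distribution, in expression units."""
        return pd.Series(self._flux, index=self.model.model.reaction_ids, name="flux")

    @property
    def objective(self) -> float:
        """Optimal weighted absolute deviation Z*."""
        return self.fit_result.objective

    @property
    def iterations(self) -> int:
        return self.fit_result.iterations

    @property
    def irreversible_trace(self) -> list[int]:
        return self.fit_result.irreversible_trace

    @property
    def scored_count(self) -> int:
        return self.fit_result.scored_count

    @property
    def exchange_ids(self) -> list[str]:
        return self.model.model.exchange_ids

    def steady_state_residual(self) -> float:
        """Max-norm of N.v — should be ~0 for any valid solution."""
        N = self.model.model.stoichiometry
        return float(np.max(np.abs(N @ self._flux))) if N.shape[0] else 0.0

    def scale_to_glucose(
        self, measured_uptake: float, glucose_exchange_id: Optional[str] = None
    ) -> pd.Series:
        """Fluxes rescaled so glucose uptake equals the measured rate."""
        scaled = scale_to_glucose(
            self._flux, self.model.model, measured_uptake, glucose_exchange_id
        )
        return pd.Series(scaled, index=self.model.model.reaction_ids, name="flux_scaled")

    def summary(self) -> str:
        m = self.model.model
        lines = [
            "Expression-constrained flux fit",
            "=" * 47,
            f"Reactions:            {m.n_reactions}",
            f"Metabolites:          {m.n_metabolites}",
            f"Scored reactions:     {self.scored_count}",
            f"Objective Z*:         {self.objective:.6g}",
            f"Iterations:           {self.iterations}",
            f"Irreversible trace:   {self.irreversible_trace}",
            f"Steady-state |N.v|:   {self.steady_state_residual():.3g}",
            "",
            "Exchange fluxes (expression units):",
        ]
        fx = self.fluxes
        for rid in self.exchange_ids:
            lines.append(f"  {rid:<24s} {fx[rid]: .6g}")
        return "\n".join(lines)
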