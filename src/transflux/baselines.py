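"""Reference flux predictors: standard FBA, fitted FBA, GIMME and iMAT.

These are the comparison methods for the expression-constrained fit. GIMME
and iMAT follow their published formulations at the fidelity needed for a
like-for-like comparison — both consume the same GPR-mapped reaction
weightings as the main method, so the comparison isolates the algorithm, not
the expression mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .expression import ReactionWeights
from .fit import CENTER_CONV_TOL, CENTER_MAX_ITER, center_solution, find_glucose_exchange
from .lp import FluxLP, UnboundedError
from .model_io import MetabolicModel

__all__ = ["BaselineConfig", "standard_fba", "fitted_fba", "gimme", "imat"]

REL_TOL = 1e-9


@dataclass
class BaselineConfig:
    """Settings for the expression-aware baselines.

    GIMME penalises flux through reactions expressed below ``gimme_threshold``
    (default: 25th percentile of the available weightings) while requiring at
    least ``gimme_fraction`` of the maximal biomass rate. iMAT classifies
    reactions into high/low expression by the ``imat_high``/``imat_low``
    weight quantiles (default tertiles) and maximises the number of high
    reactions carrying at least ``imat_eps`` flux plus low reactions carrying
    none.
    """

    gimme_threshold: Optional[float] = None  # None -> 25th percentile of weights
    gimme_fraction: float = 0.9
    imat_high: float = 2 / 3
    imat_low: float = 1 / 3
    imat_eps: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gimme_fraction <= 1.0:
            raise ValueError("gimme_fraction must lie in [0, 1]")
        if not self.imat_low < self.imat_high:
            raise ValueError("imat_low quantile must be below imat_high")
        if self.imat_eps <= 0:
            raise ValueError("imat_eps must be positive")


def _require_biomass(model: MetabolicModel) -> str:
    if model.biomass_reaction_id is None:
        raise ValueError("model declares no biomass reaction")
    return model.biomass_reaction_id


def _biomass_lp(
    model: MetabolicModel,
    glucose_uptake: Optional[float],
    glucose_exchange_id: Optional[str],
) -> tuple[FluxLP, str]:
    """Polytope with the glucose uptake capped at the measured rate."""
    lp = FluxLP(model)
    if glucose_uptake is not None:
        glc = find_glucose_exchange(model, glucose_exchange_id)
        _, hi = lp.bounds(glc)
        lp.set_bounds(glc, -abs(glucose_uptake), hi)
    return lp, _require_biomass(model)


def _max_biomass(lp: FluxLP, biomass: str) -> float:
    lp.set_objective(1.0 * lp.v(biomass), "max")
    try:
        return lp.optimize(context="biomass maximisation")
    except UnboundedError as exc:
        raise UnboundedError(
            "biomass objective unbounded; bound the glucose uptake"
        ) from exc


def _center(lp_factory, model: MetabolicModel) -> np.ndarray:
    """Geometric centring of an arbitrary polytope given by an LP factory.

    The factory must return a fresh constrained :class:`FluxLP` each call; a
    single instance is reused across the centring iterations.
    """
    lp = lp_factory()
    rids = model.reaction_ids
    aux = {}
    for rid in rids:
        p = lp.add_variable(f"cp_{rid}", lb=0)
        q = lp.add_variable(f"cq_{rid}", lb=0)
        con = lp.add_constraint(lp.v(rid) - p + q, lb=0.0, ub=0.0, name=f"ctr_{rid}")
        aux[rid] = (p, q, con)
    obj = sum(p + q for p, q, _ in aux.values())
    margin = 1e-9
    v = np.zeros(len(rids))
    for _ in range(CENTER_MAX_ITER):
        ranges = lp.fva(rids)
        spread = max(hi - lo for lo, hi in ranges.values())
        for rid in rids:
            lo, hi = ranges[rid]
            m = 0.5 * (lo + hi)
            _, _, con = aux[rid]
            con.lb = None
            con.ub = m
            con.lb = m
        lp.set_objective(obj, "min")
        lp.optimize(context="geometric centring projection")
        v = lp.fluxes()
        if spread < CENTER_CONV_TOL:
            return v
        for i, rid in enumerate(rids):
            lo, hi = ranges[rid]
            m = 0.5 * (lo + hi)
            lp.set_bounds(rid, min(v[i], m) - margin, max(v[i], m) + margin)
    return v


def standard_fba(
    model: MetabolicModel,
    glucose_uptake: float,
    glucose_exchange_id: Optional[str] = None,
) -> np.ndarray:
    """Maximise biomass at the measured glucose uptake; centre the optima.

    The returned vector is the geometric centre of the biomass-optimal
    polytope, making the prediction unique and reproducible.
    """
    lp, biomass = _biomass_lp(model, glucose_uptake, glucose_exchange_id)
    mu = _max_biomass(lp, biomass)

    def factory() -> FluxLP:
        lp2, _ = _biomass_lp(model, glucose_uptake, glucose_exchange_id)
        lp2.add_constraint(1.0 * lp2.v(biomass), lb=mu - abs(mu) * REL_TOL - 1e-12)
        return lp2

    return _center(factory, model)


def fitted_fba(
    model: MetabolicModel,
    measured: dict[str, float],
    glucose_uptake: float,
    glucose_exchange_id: Optional[str] = None,
) -> np.ndarray:
    """Best fit to measured exchange fluxes among biomass-optimal solutions.

    Two-stage LP: maximise biomass, then minimise the L1 distance between the
    model's exchange fluxes and the measured values (keyed by exchange
    reaction id, same units as ``glucose_uptake``). Remaining degeneracy is
    resolved by geometric centring. An empty measurement table reduces to
    :func:`standard_fba`.
    """
    if not measured:
        return standard_fba(model, glucose_uptake, glucose_exchange_id)
    missing = [rid for rid in measured if rid not in model.reaction_ids]
    if missing:
        raise KeyError(f"measured exchanges not in model: {missing}")

    lp, biomass = _biomass_lp(model, glucose_uptake, glucose_exchange_id)
    mu = _max_biomass(lp, biomass)

    def stage2(lp2: FluxLP) -> None:
        lp2.add_constraint(1.0 * lp2.v(biomass), lb=mu - abs(mu) * REL_TOL - 1e-12)
        for rid, value in measured.items():
            lp2.add_deviation(rid, float(value))

    lp2, _ = _biomass_lp(model, glucose_uptake, glucose_exchange_id)
    stage2(lp2)
    dist_expr = lp2.deviation_expr({rid: 1.0 for rid in measured})
    lp2.set_objective(dist_expr, "min")
    dist = lp2.optimize(context="fit to measured exchanges")

    def factory() -> FluxLP:
        lp3, _ = _biomass_lp(model, glucose_uptake, glucose_exchange_id)
        stage2(lp3)
        lp3.add_constraint(
            lp3.deviation_expr({rid: 1.0 for rid in measured}),
            ub=dist + abs(dist) * REL_TOL + 1e-12,
        )
        return lp3

    return _center(factory, model)


def gimme(
    model: MetabolicModel,
    weights: ReactionWeights,
    config: BaselineConfig = BaselineConfig(),
    glucose_uptake: Optional[float] = None,
    glucose_exchange_id: Optional[str] = None,
) -> np.ndarray:
    """GIMME: minimise below-threshold flux while sustaining growth.

    Minimises sum_i max(0, threshold - d_i) |v_i| subject to biomass >=
    ``gimme_fraction`` x maximal biomass. Reactions without expression data
    carry no penalty.
    """
    lp, biomass = _biomass_lp(model, glucose_uptake, glucose_exchange_id)
    mu = _max_biomass(lp, biomass)
    if mu <= 0 and config.gimme_fraction > 0:
        raise ValueError("maximal biomass is nonpositive; lower gimme_fraction")

    threshold = config.gimme_threshold
    if threshold is None:
        vals = [weights.d[r] for r in sorted(weights.has_data)]
        if not vals:
            raise ValueError("no reaction weightings available to set a GIMME threshold")
        threshold = float(np.percentile(vals, 25))

    lp, biomass = _biomass_lp(model, glucose_uptake, glucose_exchange_id)
    lp.add_constraint(1.0 * lp.v(biomass), lb=config.gimme_fraction * mu - 1e-12)
    terms = []
    for rid in sorted(weights.has_data):
        penalty = threshold - weights.d[rid]
        if penalty <= 0:
            continue
        i = model.reaction_index(rid)
        lo, hi = model.lower_bounds[i], model.upper_bounds[i]
        vp = lp.add_variable(f"gp_{rid}", lb=0, ub=max(hi, 0.0))
        vn = lp.add_variable(f"gn_{rid}", lb=0, ub=max(-lo, 0.0))
        lp.add_constraint(lp.v(rid) - vp + vn, lb=0.0, ub=0.0, name=f"gabs_{rid}")
        terms.append(penalty * (vp + vn))
    if terms:
        lp.set_objective(sum(terms), "min")
    else:
        lp.set_objective(0.0 * lp.v(biomass), "min")
    try:
        lp.optimize(context="GIMME")
    except Exception as exc:
        raise type(exc)(
            f"{exc}; the biomass fraction {config.gimme_fraction} may be too high"
        ) from exc
    return lp.fluxes()


def imat(
    model: MetabolicModel,
    weights: ReactionWeights,
    config: BaselineConfig = BaselineConfig(),
    glucose_uptake: Optional[float] = None,
    glucose_exchange_id: Optional[str] = None,
) -> np.ndarray:
    """iMAT: maximise agreement between flux activity and expression category.

    High-expression reactions score when carrying at least ``imat_eps`` flux
    in either direction; low-expression reactions score when carrying none.
    Solved as a MILP; GLPK's deterministic branch-and-bound fixes tie-breaks.
    """
    lp = FluxLP(model)
    if glucose_uptake is not None:
        glc = find_glucose_exchange(model, glucose_exchange_id)
        lo, hi = lp.bounds(glc)
        lp.set_bounds(glc, -abs(glucose_uptake), hi)

    rids = sorted(weights.has_data)
    if rids:
        vals = np.array([weights.d[r] for r in rids])
        hi_cut = float(np.quantile(vals, config.imat_high))
        lo_cut = float(np.quantile(vals, config.imat_low))
        high = [r for r in rids if weights.d[r] >= hi_cut]
        low = [r for r in rids if weights.d[r] <= lo_cut]
    else:
        high, low = [], []

    eps = config.imat_eps
    score_terms = []
    for rid in high:
        i = model.reaction_index(rid)
        L, U = float(model.lower_bounds[i]), float(model.upper_bounds[i])
        yf = lp.add_variable(f"yf_{rid}", lb=0, ub=1, vtype="binary")
        # yf=1 forces v >= eps:  v + yf(L - eps) >= L
        lp.add_constraint(lp.v(rid) + (L - eps) * yf, lb=L, name=f"ihf_{rid}")
        term = yf
        if L < 0:
            yb = lp.add_variable(f"yb_{rid}", lb=0, ub=1, vtype="binary")
            # yb=1 forces v <= -eps:  v + yb(U + eps) <= U
            lp.add_constraint(lp.v(rid) + (U + eps) * yb, ub=U, name=f"ihb_{rid}")
            lp.add_constraint(yf + yb, ub=1, name=f"ihx_{rid}")
            term = yf + yb
        score_terms.append(term)
    for rid in low:
        i = model.reaction_index(rid)
        L, U = float(model.lower_bounds[i]), float(model.upper_bounds[i])
        y0 = lp.add_variable(f"y0_{rid}", lb=0, ub=1, vtype="binary")
        # y0=1 forces v = 0:  v + U.y0 <= U  and  v + L.y0 >= L
        lp.add_constraint(lp.v(rid) + U * y0, ub=U, name=f"ilu_{rid}")
        lp.add_constraint(lp.v(rid) + L * y0, lb=L, name=f"ill_{rid}")
        score_terms.append(y0)

    if score_terms:
        lp.set_objective(sum(score_terms), "max")
    else:
        lp.set_objective(0.0 * lp.v(model.reaction_ids[0]), "max")
    lp.optimize(context="iMAT consistency MILP")
    return lp.fluxes()
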