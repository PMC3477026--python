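"""Thin optlang/GLPK layer for steady-state flux programs.

Builds the polytope {v : N.v = 0, L <= v <= U} once and lets callers attach
L1-deviation terms, extra constraints and alternating objectives on top (the
weighted fit, FVA sweeps, geometric centring and the baseline programs all
share this machinery). GLPK's simplex is deterministic for a fixed problem,
which is what makes centred solutions reproducible run to run.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
from optlang.glpk_interface import Constraint, Model, Objective, Variable

from .model_io import MetabolicModel

__all__ = ["FluxLP", "InfeasibleError", "UnboundedError", "SolverError"]


class SolverError(RuntimeError):
    pass


class InfeasibleError(SolverError):
    """The steady-state polytope (plus any added constraints) is empty."""


class UnboundedError(SolverError):
    """The objective is unbounded over the feasible polytope."""


class FluxLP:
    """A mutable LP/MILP over the flux space of a metabolic model."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self._lp = Model(name="flux")
        self._v: dict[str, Variable] = {}
        for i, rid in enumerate(model.reaction_ids):
            self._v[rid] = Variable(
                f"v_{rid}", lb=float(model.lower_bounds[i]), ub=float(model.upper_bounds[i])
            )
        N = model.stoichiometry.tocsr()
        constraints = []
        for m in range(model.n_metabolites):
            row = N.getrow(m)
            if row.nnz == 0:
                continue
            expr = sum(
                float(coef) * self._v[model.reaction_ids[j]]
                for j, coef in zip(row.indices, row.data)
            )
            constraints.append(Constraint(expr, lb=0, ub=0, name=f"mass_{m}"))
        self._lp.add(list(self._v.values()))
        self._lp.add(constraints)
        # deviation bookkeeping: rid -> (dplus, dminus, equality constraint)
        self._dev: dict[str, tuple[Variable, Variable, Constraint]] = {}
        self._aux_count = 0

    # -- variables & bounds --------------------------------------------------

    def v(self, rid: str) -> Variable:
        return self._v[rid]

    def set_bounds(self, rid: str, lb: float, ub: float) -> None:
        var = self._v[rid]
        # clear then set to avoid transient lb > ub errors
        var.lb = None
        var.ub = float(ub)
        var.lb = float(lb)

    def bounds(self, rid: str) -> tuple[float, float]:
        var = self._v[rid]
        return var.lb, var.ub

    def add_variable(self, name: str, lb=0.0, ub=None, vtype: str = "continuous") -> Variable:
        var = Variable(name, lb=lb, ub=ub, type=vtype)
        self._lp.add([var])
        return var

    def add_constraint(self, expr, lb=None, ub=None, name: Optional[str] = None) -> Constraint:
        self._aux_count += 1
        con = Constraint(expr, lb=lb, ub=ub, name=name or f"aux_{self._aux_count}")
        self._lp.add([con])
        return con

    def remove_constraint(self, con: Constraint) -> None:
        self._lp.remove([con])

    # -- L1 deviations ---------------------------------------------------------

    def add_deviation(self, rid: str, target: float):
        """Attach v_rid = target + dplus - dminus with dplus, dminus >= 0.

        Returns (dplus, dminus); the term (dplus + dminus) equals
        |v_rid - target| at any optimum that minimises it.
        """
        if rid in self._dev:
            raise ValueError(f"deviation already attached to {rid}")
        dp = Variable(f"dplus_{rid}", lb=0)
        dm = Variable(f"dminus_{rid}", lb=0)
        con = Constraint(
            self._v[rid] - dp + dm, lb=float(target), ub=float(target), name=f"dev_{rid}"
        )
        self._lp.add([dp, dm, con])
        self._dev[rid] = (dp, dm, con)
        return dp, dm

    def set_deviation_target(self, rid: str, target: float) -> None:
        _, _, con = self._dev[rid]
        con.lb = None
        con.ub = float(target)
        con.lb = float(target)

    def deviation_expr(self, weights: dict[str, float]):
        """Sum of weight * (dplus + dminus) over attached deviations."""
        return sum(w * (self._dev[r][0] + self._dev[r][1]) for r, w in weights.items())

    # -- solving ----------------------------------------------------------------

    def set_objective(self, expr, direction: str = "min") -> None:
        self._lp.objective = Objective(expr, direction=direction)

    def optimize(self, context: str = "") -> float:
        status = self._lp.optimize()
        if status == "optimal":
            return float(self._lp.objective.value)
        where = f" ({context})" if context else ""
        if status == "infeasible":
            raise InfeasibleError(f"no steady-state flux pattern within bounds{where}")
        if status == "unbounded":
            raise UnboundedError(f"objective unbounded{where}")
        raise SolverError(f"solver returned status {status!r}{where}")

    def fluxes(self) -> np.ndarray:
        return np.array([self._v[r].primal for r in self.model.reaction_ids], dtype=float)

    def flux(self, rid: str) -> float:
        return float(self._v[rid].primal)

    def fva(self, rids: Optional[Iterable[str]] = None) -> dict[str, tuple[float, float]]:
        """Per-reaction flux range over the current feasible set."""
        out: dict[str, tuple[float, float]] = {}
        for rid in rids if rids is not None else self.model.reaction_ids:
            var = self._v[rid]
            try:
                self.set_objective(1.0 * var, "min")
                lo = self.optimize(context=f"FVA min {rid}")
                self.set_objective(1.0 * var, "max")
                hi = self.optimize(context=f"FVA max {rid}")
            except SolverError as exc:
                raise SolverError(f"FVA failed for reaction {rid}: {exc}") from exc
            out[rid] = (lo, hi)
        return out
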