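"""Comparison of predicted and measured exometabolome fluxes.

Predictions are judged on the organism's metabolic footprint: the exchange
fluxes of excreted metabolites, glucose-normalised so that methods and
conditions are comparable. Goodness of fit is the coefficient of
determination R^2 = 1 - SS_res/SS_tot: 1 is a perfect match, 0 is what
predicting the observed mean achieves, negative is worse than the mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fit import scale_to_glucose
from .model_io import MetabolicModel

__all__ = ["ExchangeObservation", "EvaluationReport", "r_squared", "build_report"]


@dataclass(frozen=True)
class ExchangeObservation:
    """A measured exometabolome flux tied to one model exchange reaction.

    ``flux`` is in mmol/h/gDW with excretion positive, matching the sign of
    the model's exchange fluxes.
    """

    metabolite: str
    reaction_id: str
    flux: float


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination of ``predicted`` against ``observed``.

    R^2 = 1 - SS_res/SS_tot with SS_tot about the observed mean; never
    exceeds 1 and is unbounded below.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are all identical (SS_tot = 0)")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class EvaluationReport:
    """Per-method glucose-normalised exchange predictions and their R^2."""

    table: pd.DataFrame  # rows metabolites, columns: measured + one per method
    r2: dict[str, float]

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"r_squared": self.r2}, fh, indent=2)

    def __str__(self) -> str:
        lines = [self.table.to_string(float_format=lambda x: f"{x:.4g}")]
        lines.append("")
        for method, r2 in self.r2.items():
            lines.append(f"R^2 {method}: {r2:.2f}")
        return "\n".join(lines)


def build_report(
    model: MetabolicModel,
    observations: Sequence[ExchangeObservation],
    method_fluxes: dict[str, np.ndarray],
    glucose_uptake: float,
    glucose_exchange_id: Optional[str] = None,
) -> EvaluationReport:
    """Tabulate glucose-normalised exchange predictions against measurements.

    ``method_fluxes`` maps method name to a raw flux vector on ``model``;
    each vector is rescaled to the measured glucose uptake before the
    observed exchanges are extracted.
    """
    seen: dict[str, str] = {}
    for obs in observations:
        if obs.reaction_id not in model.reaction_ids:
            raise KeyError(
                f"observation {obs.metabolite!r} maps to unknown exchange "
                f"{obs.reaction_id!r}"
            )
        if obs.metabolite in seen:
            raise ValueError(f"duplicate observation for metabolite {obs.metabolite!r}")
        seen[obs.metabolite] = obs.reaction_id

    mets = [o.metabolite for o in observations]
    measured = [o.flux for o in observations]
    data: dict[str, list[float]] = {"measured": measured}
    r2: dict[str, float] = {}
    for method, v in method_fluxes.items():
        scaled = scale_to_glucose(
            np.asarray(v, dtype=float), model, glucose_uptake, glucose_exchange_id
        )
        pred = [float(scaled[model.reaction_index(o.reaction_id)]) for o in observations]
        data[method] = pred
        r2[method] = r_squared(measured, pred)
    table = pd.DataFrame(data, index=pd.Index(mets, name="metabolite"))
    return EvaluationReport(table=table, r2=r2)
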