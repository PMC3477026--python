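"""Genome-scale metabolic model container and SBML input.

The in-memory representation is deliberately minimal: a sparse stoichiometric
matrix N, per-reaction flux bounds [L_i, U_i], exchange flags and parsed GPR
trees — the quantities entering the steady-state constraint N·v = 0,
L_i <= v_i <= U_i. SBML parsing (Level 2 legacy ``GENE_ASSOCIATION`` notes and
Level 3 fbc gene-product associations alike) is delegated to cobrapy, which
normalises both encodings to one rule string; the rule string is then parsed
by :func:`transflux.gpr.parse_gpr`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse

from .gpr import GPRNode, gpr_to_string, parse_gpr

__all__ = ["MetabolicModel", "load_model", "from_cobra", "reactions_frame"]

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0


@dataclass
class MetabolicModel:
    """Stoichiometry, bounds and gene associations of a metabolic network.

    Attributes
    ----------
    metabolite_ids, reaction_ids
        Row and column identities of ``stoichiometry``.
    stoichiometry
        Sparse matrix N, metabolites x reactions.
    lower_bounds, upper_bounds
        Flux bounds L, U (flux units), one entry per reaction.
    gpr
        Mapping reaction id -> parsed GPR tree, only for reactions that have
        a gene association.
    biomass_reaction_id
        The growth pseudo-reaction, when the model declares one.
    exchange_ids
        Boundary pseudo-reactions (single nonzero stoichiometric entry);
        positive flux is excretion, negative flux uptake.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    stoichiometry: sparse.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    gpr: dict[str, GPRNode] = field(default_factory=dict)
    biomass_reaction_id: Optional[str] = None
    exchange_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stoichiometry = sparse.csc_matrix(self.stoichiometry)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.validate()
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}

    # -- structure ---------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, reaction_id: str) -> int:
        return self._rxn_index[reaction_id]

    @property
    def reversible_flags(self) -> np.ndarray:
        """True where L_i < 0 < U_i (flux may run either way)."""
        return (self.lower_bounds < 0) & (self.upper_bounds > 0)

    def initial_directions(self) -> dict[str, int]:
        """Signs of the initially irreversible reactions.

        +1 for forward-only (L_i >= 0), -1 for backward-only (U_i <= 0);
        reversible reactions are absent from the map.
        """
        out: dict[str, int] = {}
        for i, rid in enumerate(self.reaction_ids):
            if self.lower_bounds[i] >= 0:
                out[rid] = +1
            elif self.upper_bounds[i] <= 0:
                out[rid] = -1
        return out

    def validate(self) -> None:
        n_met, n_rxn = self.stoichiometry.shape
        if n_met != len(self.metabolite_ids):
            raise ValueError("metabolite count does not match stoichiometry rows")
        if n_rxn != len(self.reaction_ids):
            raise ValueError("reaction count does not match stoichiometry columns")
        if len(self.lower_bounds) != n_rxn or len(self.upper_bounds) != n_rxn:
            raise ValueError("bound vectors must have one entry per reaction")
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = np.flatnonzero(self.lower_bounds > self.upper_bounds)
            raise ValueError(
                f"lower bound exceeds upper bound for {[self.reaction_ids[i] for i in bad]}"
            )
        csc = self.stoichiometry.tocsc()
        for rid in self.exchange_ids:
            j = self.reaction_ids.index(rid)
            nnz = csc[:, j].count_nonzero()
            if nnz != 1:
                raise ValueError(
                    f"exchange reaction {rid} has {nnz} nonzero stoichiometric entries"
                )


def from_cobra(cobra_model) -> MetabolicModel:
    """Convert a cobrapy model into a :class:`MetabolicModel`."""
    import cobra.util.array

    met_ids = [m.id for m in cobra_model.metabolites]
    rxn_ids = [r.id for r in cobra_model.reactions]
    N = cobra.util.array.create_stoichiometric_matrix(cobra_model, array_type="lil")
    N = sparse.csc_matrix(N)

    lb = np.array([r.lower_bound for r in cobra_model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cobra_model.reactions], dtype=float)

    gprs: dict[str, GPRNode] = {}
    for r in cobra_model.reactions:
        tree = parse_gpr(r.gene_reaction_rule)
        if tree is not None:
            gprs[r.id] = tree

    biomass = None
    for r in cobra_model.reactions:
        if r.objective_coefficient:
            biomass = r.id
            break
    if biomass is None:
        for r in cobra_model.reactions:
            if "biomass" in r.id.lower() or "biomass" in (r.name or "").lower():
                biomass = r.id
                break

    exchange_ids = [r.id for r in cobra_model.boundary]
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        stoichiometry=N,
        lower_bounds=lb,
        upper_bounds=ub,
        gpr=gprs,
        biomass_reaction_id=biomass,
        exchange_ids=exchange_ids,
    )


def load_model(path: str) -> MetabolicModel:
    """Read an SBML model (Level 2 or 3) from ``path``.

    Reactions lacking a gene association get no GPR entry. Reactions with
    missing bounds are defaulted by the reader to [-1000, 1000] if reversible
    and [0, 1000] otherwise, with a logged warning.
    """
    import cobra.io

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cobra_model = cobra.io.read_sbml_model(path)
    except OSError:
        raise
    except Exception as exc:  # libsbml reports parse errors many ways
        raise IOError(f"could not read SBML model from {path!r}: {exc}") from exc
    for w in caught:
        # cobrapy warns when it fills in missing bounds; funnel to logging
        if "bound" in str(w.message).lower():
            logger.warning("defaulted missing bounds: %s", w.message)
    return from_cobra(cobra_model)


def reactions_frame(model: MetabolicModel) -> pd.DataFrame:
    """Tabular dump of reactions: id, bounds, reversibility, GPR string."""
    rev = model.reversible_flags
    return pd.DataFrame(
        {
            "reaction_id": model.reaction_ids,
            "lower_bound": model.lower_bounds,
            "upper_bound": model.upper_bounds,
            "reversible": rev,
            "gpr": [gpr_to_string(model.gpr.get(r)) for r in model.reaction_ids],
        }
    )
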