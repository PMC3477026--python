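"""Synthetic models, expression profiles and planted flux patterns.

Everything the fitting pipeline consumes can be generated here without any
external model or data file: random connected toy networks with GPR trees,
feasible planted flux patterns with expression data derived from them, and a
hand-built overflow-metabolism network that mimics the qualitative physiology
of fermenting yeast (respiration vs. fermentation, plus minor glycerol,
acetate, lactate and trehalose branches). Generation is a pure function of
the seed. Fixtures target algorithmic correctness, not topological realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse

from .expression import ExpressionProfile
from .gpr import GPRNode, gpr_genes, gpr_to_string, parse_gpr
from .lp import FluxLP
from .model_io import MetabolicModel, from_cobra

__all__ = [
    "FixtureSpec",
    "make_toy_model",
    "plant_fluxes_and_expression",
    "to_sbml",
    "make_overflow_model",
    "make_overflow_dataset",
]

BOUND = 1000.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random toy network.

    The network is a linear backbone M0 -> M1 -> ... with one nutrient
    exchange and one product exchange, padded with random internal reactions
    up to ``n_reactions``. ``gpr_complexity`` caps the depth of the random
    GPR trees (1 = a single fresh gene per reaction, which makes the mapped
    weight of a noise-free planted flux exact). ``noise_sd`` is in expression
    units.
    """

    n_metabolites: int = 6
    n_reactions: int = 9
    fraction_reversible: float = 0.0
    gpr_complexity: int = 1
    noise_sd: float = 0.0
    seed: int = 0
    with_biomass: bool = False

    def __post_init__(self) -> None:
        if self.n_metabolites < 2 or self.n_reactions <= 0:
            raise ValueError("counts must be positive (>= 2 metabolites)")
        if self.n_reactions < self.n_metabolites + 1:
            raise ValueError("need at least n_metabolites + 1 reactions (chain + exchanges)")
        if not 0.0 <= self.fraction_reversible <= 1.0:
            raise ValueError("fraction_reversible must lie in [0, 1]")
        if self.gpr_complexity < 1:
            raise ValueError("gpr_complexity must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _random_gpr(
    rng: np.random.Generator, depth: int, pool: list[str], allow_reuse: bool = True
) -> GPRNode:
    def fresh_leaf() -> GPRNode:
        # occasional reuse of an existing gene exercises promiscuous enzymes
        if allow_reuse and pool and rng.random() < 0.15:
            gene = pool[int(rng.integers(len(pool)))]
        else:
            gene = f"g{len(pool):04d}"
            pool.append(gene)
        return GPRNode("gene", gene_id=gene)

    if depth <= 1 or rng.random() < 0.5:
        return fresh_leaf()
    kind = "and" if rng.random() < 0.5 else "or"
    n_children = int(rng.integers(2, 4))
    children = tuple(
        _random_gpr(rng, depth - 1, pool, allow_reuse) for _ in range(n_children)
    )
    return GPRNode(kind, children=children)


def make_toy_model(spec: FixtureSpec) -> MetabolicModel:
    """Generate a connected, feasible toy network from a fixture spec."""
    rng = np.random.default_rng(spec.seed)
    n_met = spec.n_metabolites
    met_ids = [f"M{i}" for i in range(n_met)]

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rxn_ids: list[str] = []
    lbs: list[float] = []
    ubs: list[float] = []

    def add_reaction(rid: str, stoich: dict[int, float], lb: float, ub: float) -> None:
        j = len(rxn_ids)
        rxn_ids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        for i, coef in stoich.items():
            rows.append(i)
            cols.append(j)
            vals.append(coef)

    def maybe_reversible(lb: float) -> float:
        return -BOUND if rng.random() < spec.fraction_reversible else lb

    # backbone chain keeps the network connected and feasible
    add_reaction("EX_nutrient", {0: -1.0}, -BOUND, 0.0)
    for i in range(n_met - 1):
        add_reaction(f"R_chain_{i}", {i: -1.0, i + 1: 1.0}, maybe_reversible(0.0), BOUND)
    add_reaction("EX_product", {n_met - 1: -1.0}, 0.0, BOUND)

    n_extra = spec.n_reactions - len(rxn_ids)
    for k in range(n_extra):
        i, j = rng.choice(n_met, size=2, replace=False)
        add_reaction(f"R_extra_{k}", {int(i): -1.0, int(j): 1.0}, maybe_reversible(0.0), BOUND)

    exchange_ids = ["EX_nutrient", "EX_product"]
    biomass_id = None
    if spec.with_biomass:
        met_ids.append("x_biomass")
        precursor = int(rng.integers(1, n_met))
        add_reaction("BIOMASS", {precursor: -1.0, n_met: 1.0}, 0.0, BOUND)
        add_reaction("EX_biomass", {n_met: -1.0}, 0.0, BOUND)
        exchange_ids.append("EX_biomass")
        biomass_id = "BIOMASS"

    pool: list[str] = []
    gprs: dict[str, GPRNode] = {}
    for rid in rxn_ids:
        if rid.startswith("EX_") or rid == "BIOMASS":
            continue
        # depth-1 trees get one exclusive gene per reaction, so a noise-free
        # planted flux maps back to d_i = |v*_i| exactly
        tree = _random_gpr(rng, spec.gpr_complexity, pool, allow_reuse=spec.gpr_complexity > 1)
        # canonicalise (flatten nested same-operator nodes) so SBML round-trips
        gprs[rid] = parse_gpr(gpr_to_string(tree))

    N = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        stoichiometry=N,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        gpr=gprs,
        biomass_reaction_id=biomass_id,
        exchange_ids=exchange_ids,
    )


def plant_fluxes_and_expression(
    model: MetabolicModel, spec: FixtureSpec, uptake: float = 10.0
) -> tuple[np.ndarray, ExpressionProfile]:
    """Sample a feasible flux pattern and derive expression data from it.

    The planted flux maximises a seed-dependent random linear objective with
    the nutrient uptake pinned, so N.v* = 0 holds to solver precision. Each
    gene's expression mean is the largest |v*| over the reactions it
    catalyses (a promiscuous gene must cover its busiest reaction) plus
    zero-truncated Gaussian noise of width ``noise_sd``; the reported sd is
    ``noise_sd`` itself.
    """
    rng = np.random.default_rng(spec.seed + 1)
    nutrient = model.exchange_ids[0]
    lp = FluxLP(model)
    lp.set_bounds(nutrient, -uptake, -uptake)
    v = None
    for _ in range(100):
        c = rng.standard_normal(model.n_reactions)
        lp.set_objective(
            sum(float(ci) * lp.v(rid) for ci, rid in zip(c, model.reaction_ids)), "max"
        )
        lp.optimize(context="planting a flux pattern")
        v = lp.fluxes()
        if np.max(np.abs(v)) > 1e-6:
            break
    else:
        raise RuntimeError("could not plant a nonzero feasible flux pattern")

    gene_rxns: dict[str, list[int]] = {}
    for rid, tree in model.gpr.items():
        j = model.reaction_index(rid)
        for gene in gpr_genes(tree):
            gene_rxns.setdefault(gene, []).append(j)

    entries: dict[str, tuple[float, float]] = {}
    for gene in sorted(gene_rxns):
        base = max(abs(v[j]) for j in gene_rxns[gene])
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        entries[gene] = (max(0.0, base + noise), spec.noise_sd)
    return v, ExpressionProfile(entries=entries)


def to_sbml(model: MetabolicModel, path: str) -> None:
    """Serialise a fixture model to SBML Level 3 (via cobrapy)."""
    import cobra
    import cobra.io

    cm = cobra.Model("fixture")
    mets = {mid: cobra.Metabolite(mid, compartment="c") for mid in model.metabolite_ids}
    cm.add_metabolites(list(mets.values()))
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(
            rid,
            lower_bound=float(model.lower_bounds[j]),
            upper_bound=float(model.upper_bounds[j]),
        )
        reactions.append(rxn)
    cm.add_reactions(reactions)
    N = model.stoichiometry.tocsc()
    for j, rid in enumerate(model.reaction_ids):
        col = N.getcol(j)
        cm.reactions.get_by_id(rid).add_metabolites(
            {
                mets[model.metabolite_ids[i]]: float(coef)
                for i, coef in zip(col.indices, col.data)
            }
        )
        tree = model.gpr.get(rid)
        if tree is not None:
            cm.reactions.get_by_id(rid).gene_reaction_rule = gpr_to_string(tree)
    if model.biomass_reaction_id is not None:
        cm.objective = cm.reactions.get_by_id(model.biomass_reaction_id)
    cobra.io.write_sbml_model(cm, path)


# ---------------------------------------------------------------------------
# Overflow-metabolism toy: a qualitative stand-in for fermenting yeast
# ---------------------------------------------------------------------------

#: reactions of the overflow network: (id, stoichiometry, lb, ub, gene)
_OVERFLOW_REACTIONS = [
    ("EX_glc", {"glc": -1.0}, -BOUND, 0.0, None),
    ("GLY", {"glc": -1.0, "pyr": 2.0, "atp": 2.0}, 0.0, BOUND, "gGLY"),
    ("RESP", {"pyr": -1.0, "co2": 3.0, "atp": 9.0}, 0.0, BOUND, "gRESP"),
    ("FERM", {"pyr": -1.0, "etoh": 1.0, "co2": 1.0}, 0.0, BOUND, "gFERM"),
    ("GPD", {"glc": -1.0, "glyc": 2.0}, 0.0, BOUND, "gGPD"),
    ("ACS", {"pyr": -1.0, "ac": 1.0, "co2": 1.0}, 0.0, BOUND, "gACS"),
    ("LDH", {"pyr": -1.0, "lac": 1.0}, 0.0, BOUND, "gLDH"),
    ("TPS", {"glc": -1.0, "tre": 0.5}, 0.0, BOUND, "gTPS"),
    ("BIOMASS", {"glc": -1.0, "atp": -100.0, "x_biomass": 1.0}, 0.0, BOUND, None),
    ("EX_biomass", {"x_biomass": -1.0}, 0.0, BOUND, None),
    ("ATPM", {"atp": -1.0}, 0.0, BOUND, None),
    ("EX_etoh", {"etoh": -1.0}, 0.0, BOUND, None),
    ("EX_co2", {"co2": -1.0}, 0.0, BOUND, None),
    ("EX_glyc", {"glyc": -1.0}, 0.0, BOUND, None),
    ("EX_ac", {"ac": -1.0}, 0.0, BOUND, None),
    ("EX_lac", {"lac": -1.0}, 0.0, BOUND, None),
    ("EX_tre", {"tre": -1.0}, 0.0, BOUND, None),
]

#: planted fermentative flux pattern (glucose uptake 10)
OVERFLOW_PLANTED = {
    "EX_glc": -10.0,
    "GLY": 9.3,
    "RESP": 1.0,
    "FERM": 17.0,
    "GPD": 0.3,
    "ACS": 0.3,
    "LDH": 0.3,
    "TPS": 0.2,
    "BIOMASS": 0.2,
    "EX_biomass": 0.2,
    "ATPM": 7.6,
    "EX_etoh": 17.0,
    "EX_co2": 20.3,
    "EX_glyc": 0.6,
    "EX_ac": 0.3,
    "EX_lac": 0.3,
    "EX_tre": 0.1,
}

OVERFLOW_UPTAKE = 10.0  # "measured" glucose uptake of the planted pattern

#: metabolite -> exchange id, the six footprint metabolites
OVERFLOW_FOOTPRINT = {
    "ethanol": "EX_etoh",
    "co2": "EX_co2",
    "glycerol": "EX_glyc",
    "acetate": "EX_ac",
    "lactate": "EX_lac",
    "trehalose": "EX_tre",
}


def make_overflow_model() -> MetabolicModel:
    """Carbon-balanced toy of glucose overflow metabolism.

    Glucose is split between glycolysis (to pyruvate + ATP), minor glycerol /
    trehalose branches and a biomass drain; pyruvate is split between
    respiration (CO2, high ATP yield) and fermentation / acetate / lactate
    branches. Biomass maximisation therefore routes all carbon to CO2, while
    the planted "measured" state is fermentative — the contrast the
    expression-constrained fit is designed to resolve.
    """
    met_ids = ["glc", "pyr", "atp", "co2", "etoh", "glyc", "ac", "lac", "tre", "x_biomass"]
    midx = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals, rids, lbs, ubs = [], [], [], [], [], []
    gprs: dict[str, GPRNode] = {}
    for j, (rid, stoich, lb, ub, gene) in enumerate(_OVERFLOW_REACTIONS):
        rids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        for met, coef in stoich.items():
            rows.append(midx[met])
            cols.append(j)
            vals.append(coef)
        if gene is not None:
            gprs[rid] = parse_gpr(gene)
    N = sparse.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rids)))
    exchange_ids = [r for r in rids if r.startswith("EX_")] + ["ATPM"]
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rids,
        stoichiometry=N,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        gpr=gprs,
        biomass_reaction_id="BIOMASS",
        exchange_ids=exchange_ids,
    )


def make_overflow_dataset(
    noise_sd: float = 0.0, seed: int = 0
) -> tuple[MetabolicModel, ExpressionProfile, dict[str, float], float, np.ndarray]:
    """Overflow model plus expression data planted from its fermentative state.

    Returns (model, profile, observations, measured glucose uptake, planted
    flux vector). ``observations`` maps the six footprint exchange ids to
    their planted ("measured") excretion fluxes. Expression means equal the
    planted flux magnitudes of the catalysed reactions, perturbed by
    zero-truncated Gaussian noise of width ``noise_sd`` (relative to flux
    units); reported sds are 5% of the mean, floored at 0.01, mimicking
    replicate scatter.
    """
    model = make_overflow_model()
    rng = np.random.default_rng(seed)
    entries: dict[str, tuple[float, float]] = {}
    for rid, tree in sorted(model.gpr.items()):
        (gene,) = gpr_genes(tree)
        base = abs(OVERFLOW_PLANTED[rid])
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        mean = max(0.0, base + noise)
        entries[gene] = (mean, max(0.05 * mean, 0.01))
    profile = ExpressionProfile(entries=entries)
    observations = {
        OVERFLOW_FOOTPRINT[met]: OVERFLOW_PLANTED[OVERFLOW_FOOTPRINT[met]]
        for met in OVERFLOW_FOOTPRINT
    }
    v_star = np.array([OVERFLOW_PLANTED[r] for r in model.reaction_ids])
    return model, profile, observations, OVERFLOW_UPTAKE, v_star
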