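"""Shared hand-built networks for the test suite.

All fixtures are generated in memory; nothing is read from disk except files
the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

from transflux.gpr import parse_gpr
from transflux.model_io import MetabolicModel

BOUND = 1000.0


def build_model(
    reactions: list[tuple],
    metabolite_ids: list[str],
    biomass: str | None = None,
) -> MetabolicModel:
    """Assemble a MetabolicModel from (id, {met: coef}, lb, ub, gpr_string).

    Reactions with exactly one nonzero stoichiometric entry are flagged as
    exchanges.
    """
    midx = {m: i for i, m in enumerate(metabolite_ids)}
    rows, cols, vals, rids, lbs, ubs = [], [], [], [], [], []
    gprs = {}
    for j, (rid, stoich, lb, ub, rule) in enumerate(reactions):
        rids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        for met, coef in stoich.items():
            rows.append(midx[met])
            cols.append(j)
            vals.append(float(coef))
        if rule:
            gprs[rid] = parse_gpr(rule)
    N = sparse.csc_matrix((vals, (rows, cols)), shape=(len(metabolite_ids), len(rids)))
    exchange = [rid for rid, st, *_ in reactions if len(st) == 1]
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=rids,
        stoichiometry=N,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        gpr=gprs,
        biomass_reaction_id=biomass,
        exchange_ids=exchange,
    )


def chain_model(cap_r1: float = BOUND) -> MetabolicModel:
    """A -> B -> C with free uptake of A and excretion of C."""
    return build_model(
        [
            ("EX_A", {"A": -1}, -BOUND, 0.0, None),
            ("R1", {"A": -1, "B": 1}, 0.0, cap_r1, "g1"),
            ("R2", {"B": -1, "C": 1}, 0.0, BOUND, "g2"),
            ("EX_C", {"C": -1}, 0.0, BOUND, None),
        ],
        ["A", "B", "C"],
    )


@pytest.fixture
def worked_profile():
    """The gene means/sds of the carbamoyl-phosphate-synthase worked example."""
    from transflux.expression import ExpressionProfile

    return ExpressionProfile(
        {
            "YJR109C": (0.156, 0.083),
            "YOR303W": (0.0976, 0.033),
            "YJL130C": (0.126, 0.013),
        }
    )


@pytest.fixture(scope="session")
def overflow():
    """Overflow-metabolism toy with planted fermentative data (noise-free)."""
    from transflux.fixtures import make_overflow_dataset

    model, profile, observations, uptake, v_star = make_overflow_dataset()
    return {
        "model": model,
        "profile": profile,
        "observations": observations,
        "uptake": uptake,
        "v_star": v_star,
    }
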