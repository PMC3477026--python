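"""Mapping absolute gene-expression data onto metabolic reactions.

Absolute expression measurements (e.g. RPKM from RNA-Seq, comparable across
genes) are converted into continuous per-reaction weightings d_i with
uncertainties sigma_i by evaluating each reaction's GPR tree:

* ``and`` (enzymatic complex): the complex concentration is bounded by its
  scarcest component, so the weighting is the child with the minimal mean,
  carrying that child's standard deviation.
* ``or`` (isoenzymes): alternative catalysts add capacity, so means are
  summed and variances are added under the assumption that the measurements
  are uncorrelated (sd = sqrt of the summed variances).

Missing genes propagate as missing data: an ``or`` simply drops missing
children (an unmeasured isoenzyme contributes nothing), while an ``and`` with
any missing child is itself missing, since a complex cannot be bounded by an
unknown component. A reaction whose whole tree evaluates to missing — or that
has no GPR at all — carries no weighting (``has_data`` false) and never enters
the fitting objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .gpr import GPRNode
from .model_io import MetabolicModel

__all__ = [
    "ExpressionProfile",
    "ReactionWeights",
    "load_expression",
    "evaluate_gpr",
    "map_expression",
]

DEFAULT_SIGMA_FLOOR = 1e-6


@dataclass
class ExpressionProfile:
    """Per-gene absolute expression: gene id -> (mean, sd), both >= 0."""

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: gene ids whose sd was absent in the source table and defaulted to 0
    missing_sd: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for gene, (mean, sd) in self.entries.items():
            if mean < 0:
                raise ValueError(f"negative expression mean for gene {gene}")
            if sd < 0:
                raise ValueError(f"negative expression sd for gene {gene}")

    def get(self, gene_id: str) -> Optional[tuple[float, float]]:
        return self.entries.get(gene_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries


@dataclass
class ReactionWeights:
    """Expression-derived reaction weightings d_i with uncertainties sigma_i.

    ``has_data`` holds the reaction ids for which a weighting exists; for
    those, ``d[rid]`` is the target flux magnitude (expression units) and
    ``sigma[rid] > 0`` the confidence weight denominator.
    """

    d: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)
    has_data: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.has_data != set(self.d) or self.has_data != set(self.sigma):
            raise ValueError("d, sigma and has_data must cover the same reactions")
        for rid, s in self.sigma.items():
            if s <= 0:
                raise ValueError(f"sigma must be positive after flooring ({rid}: {s})")

    def to_frame(self, reaction_ids: Optional[list[str]] = None) -> pd.DataFrame:
        rids = reaction_ids if reaction_ids is not None else sorted(self.has_data)
        return pd.DataFrame(
            {
                "reaction_id": rids,
                "d": [self.d.get(r, np.nan) for r in rids],
                "sigma": [self.sigma.get(r, np.nan) for r in rids],
                "has_data": [r in self.has_data for r in rids],
            }
        )


def load_expression(path: str) -> ExpressionProfile:
    """Read a delimited table of (gene id, mean, sd) into a profile.

    The sd column is optional; rows lacking it get sd = 0 and are flagged in
    ``missing_sd``. Duplicate gene ids or negative means are errors.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"expression table {path!r} needs at least gene id and mean")
    gene_col, mean_col = cols[0], cols[1]
    sd_col = cols[2] if len(cols) > 2 else None

    dup = df[gene_col][df[gene_col].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate gene ids in {path!r}: {sorted(set(map(str, dup)))}")

    entries: dict[str, tuple[float, float]] = {}
    missing_sd: set[str] = set()
    for _, row in df.iterrows():
        gene = str(row[gene_col])
        mean = float(row[mean_col])
        if mean < 0:
            raise ValueError(f"negative expression mean for gene {gene}")
        sd = float(row[sd_col]) if sd_col is not None else np.nan
        if np.isnan(sd):
            sd = 0.0
            missing_sd.add(gene)
        entries[gene] = (mean, sd)
    return ExpressionProfile(entries=entries, missing_sd=missing_sd)


def evaluate_gpr(
    node: GPRNode, profile: ExpressionProfile
) -> Optional[tuple[float, float]]:
    """Evaluate a GPR tree against an expression profile.

    Returns the reaction weighting (mean, sd) in expression units, or ``None``
    when the tree is entirely unmeasured. When two ``and`` children share the
    minimal mean the one with the smaller sd is taken (the more confident
    bound on the complex).
    """
    if node.kind == "gene":
        return profile.get(node.gene_id)
    vals = [evaluate_gpr(c, profile) for c in node.children]
    if node.kind == "and":
        if any(v is None for v in vals):
            return None
        return min(vals, key=lambda ms: (ms[0], ms[1]))
    # or: isoenzymes add; unmeasured children are dropped
    present = [v for v in vals if v is not None]
    if not present:
        return None
    mean = float(sum(v[0] for v in present))
    sd = float(np.sqrt(sum(v[1] ** 2 for v in present)))
    return (mean, sd)


def map_expression(
    model: MetabolicModel,
    profile: ExpressionProfile,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> ReactionWeights:
    """Evaluate every reaction's GPR, flooring sigma at ``sigma_floor``.

    The floor keeps the 1/sigma_i confidence weight finite for genes reported
    with zero variance (e.g. single observations).
    """
    if sigma_floor <= 0:
        raise ValueError("sigma_floor must be positive")
    d: dict[str, float] = {}
    sigma: dict[str, float] = {}
    has_data: set[str] = set()
    for rid in model.reaction_ids:
        tree = model.gpr.get(rid)
        if tree is None:
            continue
        val = evaluate_gpr(tree, profile)
        if val is None:
            continue
        mean, sd = val
        d[rid] = mean
        sigma[rid] = max(sd, sigma_floor)
        has_data.add(rid)
    return ReactionWeights(d=d, sigma=sigma, has_data=has_data)
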