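"""Small constraint-based models with planted, analytically known targets.

The branched toy emulates the situation the ranking method is built for: a
carbon source feeds a linear trunk to a hub metabolite that is split between
a product branch and a competing biomass branch.  Forcing production up must
pull the trunk and product branch fluxes up (overexpression targets) and
squeeze the competing branch down (downregulation, or knockout when no
biomass floor is kept).  A decoy pathway on an independent substrate carries
the same flux range in every state and must never be ranked.

All planted stoichiometry is 1:1 on the trunk so the ground truth stays
hand-computable: with uptake U and biomass floor fraction b, maximum growth
is U, the maximum theoretical yield of the product exchange is
branch_yield × (1 − b) × U, and at full enforcement the product branch span
collapses to a point while the competing branch is pinned at its floor.

Seeded jitter perturbs only the decoy bounds and the wide default capacities
of non-planted reactions — never stoichiometry — so the analytic ground
truth holds for every seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

import cobra.io

from .model_io import (
    MetabolicModel,
    MetaboliteRecord,
    ReactionRecord,
    to_cobra,
    validate,
)

__all__ = ["ToyModelSpec", "GroundTruth", "build_branched_toy", "write_fixture"]

_WIDE = 1000.0


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of the branched toy model.

    ``uptake_rate`` is the carbon uptake bound in mmol/gDW/h; ``n_chain`` the
    number of trunk reactions; ``branch_yield`` the product stoichiometry per
    hub metabolite; ``seed`` drives the bound jitter on non-planted reactions.
    """

    uptake_rate: float = 10.0
    n_chain: int = 1
    branch_yield: float = 1.0
    with_cofactor_drain: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.uptake_rate < 0:
            raise ValueError("uptake_rate must be nonnegative")
        if self.n_chain < 1:
            raise ValueError("n_chain must be at least 1")
        if self.branch_yield <= 0:
            raise ValueError("branch_yield must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted expectations for the branched toy."""

    product_id: str
    biomass_id: str
    carbon_id: str
    overexpress_ids: tuple[str, ...]  # trunk + product branch (+ coupled drain)
    competing_id: str  # biomass branch entry
    decoy_ids: tuple[str, ...]  # internal reactions that must never rank

    def expected_intervention(self, reaction_id: str, biomass_min_fraction: float) -> str:
        """The intervention the pipeline should recommend for a planted reaction."""
        if reaction_id in self.overexpress_ids:
            return "overexpress"
        if reaction_id == self.competing_id:
            return "knockout" if biomass_min_fraction == 0 else "downregulate"
        return "none"


def build_branched_toy(spec: ToyModelSpec = ToyModelSpec()) -> tuple[MetabolicModel, GroundTruth]:
    """Construct the branched toy model and its ground truth.

    Layout (n_chain = 1)::

        EX_A ⇒ A --R1--> B --R2--> P ⇒ EX_P        (product branch)
                          \\--R3--> C ⇒ BIOMASS     (competing branch)
        EX_X ⇒ X --R_X--> Y ⇒ EX_Y                  (decoy, carbon-independent)
    """
    rng = np.random.default_rng(spec.seed)
    mets = [MetaboliteRecord("A_c", "c")]
    rxns = [
        ReactionRecord("EX_A", "carbon source exchange", {"A_c": -1.0}, -spec.uptake_rate, _WIDE)
    ]
    overexpress = []
    prev = "A_c"
    for i in range(1, spec.n_chain + 1):
        nxt = "B_c" if i == spec.n_chain else f"M{i}_c"
        mets.append(MetaboliteRecord(nxt, "c"))
        rid = f"R{i}"
        rxns.append(
            ReactionRecord(rid, f"trunk step {i}", {prev: -1.0, nxt: 1.0}, 0.0, _WIDE, gpr=f"gT{i}")
        )
        overexpress.append(rid)
        prev = nxt

    prod_rid = f"R{spec.n_chain + 1}"
    comp_rid = f"R{spec.n_chain + 2}"
    mets += [MetaboliteRecord("P_c", "c"), MetaboliteRecord("C_c", "c")]
    prod_stoich = {"B_c": -1.0, "P_c": spec.branch_yield}
    if spec.with_cofactor_drain:
        mets.append(MetaboliteRecord("Q_c", "c"))
        prod_stoich["Q_c"] = 1.0
    rxns += [
        ReactionRecord(prod_rid, "product branch", prod_stoich, 0.0, _WIDE, gpr="gP1 and gP2"),
        ReactionRecord("EX_P", "product exchange", {"P_c": -1.0}, 0.0, _WIDE),
        ReactionRecord(comp_rid, "competing biomass branch", {"B_c": -1.0, "C_c": 1.0}, 0.0, _WIDE,
                       gpr="gB1 or gB2"),
        ReactionRecord("BIOMASS", "biomass sink", {"C_c": -1.0}, 0.0, _WIDE),
    ]
    overexpress.append(prod_rid)
    if spec.with_cofactor_drain:
        rxns.append(
            ReactionRecord("DRAIN_Q", "cofactor byproduct drain", {"Q_c": -1.0}, 0.0, _WIDE)
        )
        overexpress.append("DRAIN_Q")

    # decoy pathway on an independent substrate; jittered capacities keep it
    # active but uncorrelated with production
    # 6-decimal bounds survive every serialisation round-trip bit-faithfully
    cap_in = round(float(rng.uniform(3.0, 8.0)), 6)
    cap_rx = round(float(rng.uniform(cap_in, cap_in + 4.0)), 6)
    mets += [MetaboliteRecord("X_c", "c"), MetaboliteRecord("Y_c", "c")]
    rxns += [
        ReactionRecord("EX_X", "decoy substrate exchange", {"X_c": -1.0}, -cap_in, _WIDE),
        ReactionRecord("R_X", "decoy conversion", {"X_c": -1.0, "Y_c": 1.0}, 0.0, cap_rx, gpr="gX"),
        ReactionRecord("EX_Y", "decoy product exchange", {"Y_c": -1.0}, 0.0, _WIDE),
    ]

    model = MetabolicModel(
        model_id=f"branched_toy_seed{spec.seed}",
        metabolites=tuple(mets),
        reactions=tuple(rxns),
        genes=tuple(sorted({g for r in rxns for g in _genes_of(r.gpr)})),
        objective_reaction="BIOMASS",
    )
    validate(model)
    truth = GroundTruth(
        product_id="EX_P",
        biomass_id="BIOMASS",
        carbon_id="EX_A",
        overexpress_ids=tuple(overexpress),
        competing_id=comp_rid,
        decoy_ids=("R_X",),
    )
    return model, truth


def _genes_of(gpr: str) -> list[str]:
    return [tok for tok in gpr.replace("(", " ").replace(")", " ").split()
            if tok not in ("and", "or")]


def write_fixture(
    model: MetabolicModel, path: str | Path, format: Literal["sbml", "json"] = "json"
) -> Path:
    """Serialise a model to BiGG-style JSON (canonical key order, so
    re-serialisation is byte-identical) or SBML L3 FBC v2."""
    path = Path(path)
    if format == "json":
        path.write_text(_canonical_json(model))
    elif format == "sbml":
        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _canonical_json(model: MetabolicModel) -> str:
    doc = {
        "id": model.model_id,
        "version": "1",
        "metabolites": [
            {"id": m.id, "compartment": m.compartment}
            for m in sorted(model.metabolites)
        ],
        "genes": [{"id": g} for g in sorted(model.genes)],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "objective_coefficient": 1.0 if r.id == model.objective_reaction else 0.0,
            }
            for r in sorted(model.reactions, key=lambda r: r.id)
        ],
    }
    return json.dumps(doc, sort_keys=True, indent=1) + "\n"
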