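"""Reading, validating and minimally manipulating constraint-based models.

Supported dialects are SBML Level 3 with the FBC v2 extension and the
BiGG-distribution JSON schema (``reactions`` / ``metabolites`` / ``genes``
top-level keys, per-reaction ``lower_bound`` / ``upper_bound`` /
``metabolites`` / ``gene_reaction_rule``).  Parsing is delegated to cobrapy
(and libsbml underneath); the result is converted into the small immutable
:class:`MetabolicModel` container that the rest of the package operates on.

Flux sign convention throughout: negative exchange flux is uptake, positive
is secretion (the BiGG convention).  All fluxes are in mmol/gDW/h; no unit
conversion is performed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

import cobra
import cobra.io
import libsbml

from .exceptions import ModelFormatError, ModelValidationError, ReactionLookupError

__all__ = [
    "MetaboliteRecord",
    "ReactionRecord",
    "MetabolicModel",
    "load_model",
    "set_carbon_source",
    "resolve_reaction",
    "to_cobra",
    "from_cobra",
]

#: Reaction-id prefixes treated as boundary/exchange reactions (BiGG convention).
EXCHANGE_PREFIXES = ("EX_", "DM_", "SK_")


class MetaboliteRecord(NamedTuple):
    id: str
    compartment: str


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: stoichiometry, flux bounds and gene association.

    ``stoichiometry`` maps metabolite id to its signed coefficient
    (negative = consumed).  ``gpr`` is the raw boolean gene-association
    string over gene ids using ``and`` / ``or`` and parentheses; it may be
    empty for spontaneous or boundary reactions.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""

    @property
    def is_exchange(self) -> bool:
        """Heuristic boundary test: BiGG-style id prefix, or a single-metabolite
        reaction whose id starts with a recognised prefix."""
        return self.id.startswith(EXCHANGE_PREFIXES)


@dataclass(frozen=True)
class MetabolicModel:
    """An immutable stoichiometric model: the substrate of all LP operations."""

    model_id: str
    metabolites: tuple[MetaboliteRecord, ...]
    reactions: tuple[ReactionRecord, ...]
    genes: tuple[str, ...]
    objective_reaction: str | None = None

    def reaction(self, reaction_id: str) -> ReactionRecord:
        for rxn in self.reactions:
            if rxn.id == reaction_id:
                return rxn
        raise ReactionLookupError(reaction_id, _closest_ids(reaction_id, self.reaction_ids()))

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def canonical(self) -> "MetabolicModel":
        """Copy with metabolites, reactions and genes sorted by id, so models
        loaded from differently ordered serialisations compare equal."""
        return replace(
            self,
            metabolites=tuple(sorted(self.metabolites)),
            reactions=tuple(sorted(self.reactions, key=lambda r: r.id)),
            genes=tuple(sorted(self.genes)),
        )


# ---------------------------------------------------------------------------
# validation


def validate(model: MetabolicModel) -> None:
    """Check the structural invariants; raise :class:`ModelValidationError`."""
    rids = model.reaction_ids()
    dup = _duplicates(rids)
    if dup:
        raise ModelValidationError(f"duplicate reaction ids: {sorted(dup)}")
    mids = model.metabolite_ids()
    dup = _duplicates(mids)
    if dup:
        raise ModelValidationError(f"duplicate metabolite ids: {sorted(dup)}")
    declared = set(mids)
    for rxn in model.reactions:
        missing = set(rxn.stoichiometry) - declared
        if missing:
            raise ModelValidationError(
                f"reaction {rxn.id!r} references undeclared metabolites {sorted(missing)}"
            )
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r} has lower_bound {rxn.lower_bound} > "
                f"upper_bound {rxn.upper_bound}"
            )
        if math.isnan(rxn.lower_bound) or math.isnan(rxn.upper_bound):
            raise ModelValidationError(f"reaction {rxn.id!r} has NaN bounds")


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def _edit_distance(a: str, b: str) -> int:
    # classic Levenshtein, adequate for suggestion lists over reaction ids
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _closest_ids(query: str, ids: list[str], n: int = 5) -> list[str]:
    return sorted(ids, key=lambda i: (_edit_distance(query, i), i))[:n]


# ---------------------------------------------------------------------------
# loading


def load_model(path: str | Path, format: Literal["sbml", "json", "auto"] = "auto") -> MetabolicModel:
    """Load an SBML L3-FBC or BiGG-JSON model file into a :class:`MetabolicModel`.

    ``format="auto"`` dispatches on the file extension (``.xml``/``.sbml`` vs
    ``.json``) and falls back to content sniffing.  Bounds and stoichiometric
    coefficients are kept as the double-precision values in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    fmt = format
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in (".xml", ".sbml"):
            fmt = "sbml"
        elif suffix == ".json":
            fmt = "json"
        else:
            head = path.read_text(errors="replace").lstrip()[:1]
            fmt = "sbml" if head == "<" else "json"
    if fmt == "sbml":
        model = _load_sbml(path)
    elif fmt == "json":
        model = _load_json(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    model = model.canonical()
    validate(model)
    return model


def _load_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"malformed SBML in {path.name}: {err.getMessage().strip()}")
    if doc.getLevel() < 3:
        raise ModelFormatError(
            f"{path.name} is SBML Level {doc.getLevel()}; only Level 3 with the "
            "FBC extension is supported — re-export the model as SBML L3 FBC v2"
        )
    sbml_model = doc.getModel()
    if sbml_model is None or sbml_model.getPlugin("fbc") is None:
        raise ModelFormatError(
            f"{path.name} lacks the FBC package; only SBML L3 FBC v2 is supported"
        )
    try:
        cb = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra wraps libsbml failures loosely
        raise ModelFormatError(f"could not parse SBML file {path.name}: {exc}") from exc
    return from_cobra(cb)


def _load_json(path: Path) -> MetabolicModel:
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"malformed JSON in {path.name}: {exc}") from exc
    for key in ("reactions", "metabolites"):
        if key not in raw:
            raise ModelFormatError(f"{path.name} is missing the {key!r} list")
    # pre-scan the raw document: cobra's containers would mask duplicate ids
    for key in ("reactions", "metabolites", "genes"):
        ids = [entry.get("id") for entry in raw.get(key, [])]
        dup = _duplicates([i for i in ids if i is not None])
        if dup:
            raise ModelValidationError(f"duplicate {key[:-1]} ids in {path.name}: {sorted(dup)}")
    try:
        cb = cobra.io.load_json_model(str(path))
    except Exception as exc:
        raise ModelFormatError(f"could not parse JSON model {path.name}: {exc}") from exc
    return from_cobra(cb)


# ---------------------------------------------------------------------------
# cobra conversion


def from_cobra(cb: "cobra.Model") -> MetabolicModel:
    """Convert a cobrapy model into the immutable container."""
    objective = None
    coeffs = cobra.util.solver.linear_reaction_coefficients(cb)
    if coeffs:
        # by convention a single reaction carries the objective
        objective = max(coeffs, key=lambda r: abs(coeffs[r])).id
    reactions = tuple(
        ReactionRecord(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=r.gene_reaction_rule or "",
        )
        for r in cb.reactions
    )
    return MetabolicModel(
        model_id=cb.id or "model",
        metabolites=tuple(MetaboliteRecord(m.id, m.compartment or "") for m in cb.metabolites),
        reactions=reactions,
        genes=tuple(g.id for g in cb.genes),
        objective_reaction=objective,
    )


def to_cobra(model: MetabolicModel) -> "cobra.Model":
    """Materialise a cobrapy model (the LP substrate) from the container."""
    cb = cobra.Model(model.model_id)
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c") for m in model.metabolites}
    rxns = []
    for rec in model.reactions:
        r = cobra.Reaction(rec.id, name=rec.name)
        r.lower_bound = rec.lower_bound
        r.upper_bound = rec.upper_bound
        rxns.append(r)
    cb.add_reactions(rxns)
    for rec, r in zip(model.reactions, cb.reactions):
        r.add_metabolites({mets[mid]: c for mid, c in rec.stoichiometry.items()})
        if rec.gpr:
            r.gene_reaction_rule = rec.gpr
    if model.objective_reaction is not None:
        cb.objective = model.objective_reaction
    return cb


# ---------------------------------------------------------------------------
# manipulation


def set_carbon_source(model: MetabolicModel, exchange_id: str, uptake_rate: float) -> MetabolicModel:
    """Return a copy of *model* with the named exchange allowed to take up at
    most ``uptake_rate`` (lower bound set to ``-uptake_rate``; uptake is
    negative flux).  The input model is not mutated."""
    if uptake_rate < 0:
        raise ValueError(f"uptake_rate must be nonnegative, got {uptake_rate}")
    target = resolve_reaction(model, exchange_id)  # raises with suggestions
    new_reactions = tuple(
        replace(r, lower_bound=-float(uptake_rate)) if r.id == target.id else r
        for r in model.reactions
    )
    updated = replace(model, reactions=new_reactions)
    validate(updated)
    return updated


def resolve_reaction(model: MetabolicModel, query: str) -> ReactionRecord:
    """Return the reaction whose id equals *query* exactly (case-sensitive).

    This is the guard for user-supplied product/biomass/carbon ids; on a miss
    it raises :class:`ReactionLookupError` carrying the five closest ids by
    edit distance.
    """
    for rxn in model.reactions:
        if rxn.id == query:
            return rxn
    raise ReactionLookupError(query, _closest_ids(query, model.reaction_ids()))
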