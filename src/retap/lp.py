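"""Linear-programming layer: FBA, FVA, maximum theoretical yield and the
enforced-production fraction scan.

All solves go through cobrapy/optlang (GLPK).  Only LP optima are stored —
never the degenerate flux vectors — so repeated runs on the same model and
parameters are bit-identical.

The scan is the data-generating step of the ranking method: the product
reaction's lower bound is raised to successive fractions of the maximum
theoretical yield (MTY) while a biomass floor keeps the states
physiologically meaningful, and per-reaction feasible flux intervals are
recorded at every fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import cobra
from cobra.flux_analysis import flux_variability_analysis as _cobra_fva

from .exceptions import InfeasibleModelError, ScanError
from .model_io import MetabolicModel, resolve_reaction, to_cobra

__all__ = [
    "ObjectiveSolution",
    "FluxSpan",
    "ScanResult",
    "optimize_flux",
    "flux_variability",
    "max_theoretical_yield",
    "enforced_production_scan",
    "default_fraction_grid",
]

log = logging.getLogger(__name__)

#: feasibility tolerance used when comparing or clipping LP results
FEAS_TOL = 1e-9


@dataclass(frozen=True)
class ObjectiveSolution:
    """Outcome of a single FBA solve."""

    status: Literal["optimal", "infeasible", "unbounded"]
    objective_value: float
    fluxes: Mapping[str, float]


@dataclass(frozen=True)
class FluxSpan:
    """Feasible flux interval of one reaction at one enforcement fraction."""

    reaction_id: str
    fraction: float
    min_flux: float
    max_flux: float

    @property
    def width(self) -> float:
        return self.max_flux - self.min_flux


@dataclass(frozen=True)
class ScanResult:
    """Full output of an enforced-production scan.

    ``spans[rid]`` holds one :class:`FluxSpan` per fraction, in fraction
    order.  ``config_echo`` records every parameter of the run so downstream
    ranking (and a replay of the scan) needs no other context.
    """

    mty: float
    max_growth: float
    fractions: tuple[float, ...]
    spans: Mapping[str, tuple[FluxSpan, ...]]
    exchange_ids: frozenset[str] = field(default_factory=frozenset)
    config_echo: Mapping[str, object] = field(default_factory=dict)


def default_fraction_grid(n: int = 10) -> tuple[float, ...]:
    """``n`` equally spaced enforcement fractions ending at 1.0
    (n=10 gives 0.1, 0.2, ..., 1.0)."""
    if n < 4:
        raise ValueError("at least 4 fractions are needed (two low + two high states)")
    return tuple((i + 1) / n for i in range(n))


def _status(cobra_status: str) -> str:
    if cobra_status == "optimal":
        return "optimal"
    if "unbounded" in cobra_status:
        return "unbounded"
    return "infeasible"


def optimize_flux(
    model: MetabolicModel | cobra.Model,
    objective_id: str,
    sense: Literal["maximize", "minimize"] = "maximize",
) -> ObjectiveSolution:
    """FBA: optimize a single reaction flux subject to S·v = 0 and bounds.

    Infeasibility and unboundedness are reported through ``status``, not
    raised.
    """
    cb = to_cobra(model) if isinstance(model, MetabolicModel) else model
    if objective_id not in cb.reactions:
        if isinstance(model, MetabolicModel):
            resolve_reaction(model, objective_id)  # raises with suggestions
        raise KeyError(objective_id)
    with cb:
        cb.objective = objective_id
        cb.objective_direction = "max" if sense == "maximize" else "min"
        try:
            sol = cb.optimize(raise_error=False)
            status, value, fluxes = sol.status, sol.objective_value, dict(sol.fluxes)
        except Exception:  # cobra raises on e.g. unbounded despite raise_error=False
            status, value, fluxes = cb.solver.status, float("nan"), {}
        if _status(status) != "optimal":
            return ObjectiveSolution(_status(status), float("nan"), {})
        return ObjectiveSolution("optimal", float(value), fluxes)


def flux_variability(
    model: MetabolicModel | cobra.Model,
    reaction_ids: Sequence[str] | None = None,
    extra_bounds: Sequence[tuple[str, float, float]] = (),
    fraction: float = 0.0,
) -> list[FluxSpan]:
    """FVA: the exact feasible [min, max] flux interval of each requested
    reaction under the model bounds tightened by ``extra_bounds``.

    ``fraction`` is carried into the returned spans for the caller's
    bookkeeping; it does not influence the LP.
    """
    cb = to_cobra(model) if isinstance(model, MetabolicModel) else model
    for rid, lb, ub in extra_bounds:
        if lb > ub + FEAS_TOL:
            raise ValueError(f"inconsistent extra bound for {rid!r}: lb {lb} > ub {ub}")
    with cb:
        for rid, lb, ub in extra_bounds:
            rxn = cb.reactions.get_by_id(rid)
            rxn.lower_bound = max(rxn.lower_bound, lb)
            rxn.upper_bound = min(rxn.upper_bound, ub)
        targets = list(reaction_ids) if reaction_ids is not None else [r.id for r in cb.reactions]
        try:
            table = _cobra_fva(
                cb,
                reaction_list=targets,
                fraction_of_optimum=0.0,
                processes=1,
            )
        except Exception as exc:
            enforced = ", ".join(f"{rid}∈[{lb},{ub}]" for rid, lb, ub in extra_bounds) or "none"
            raise InfeasibleModelError(
                f"FVA infeasible under enforced bounds ({enforced}): {exc}"
            ) from exc
    spans = []
    for rid in targets:
        lo = float(table.at[rid, "minimum"])
        hi = float(table.at[rid, "maximum"])
        if lo > hi:  # solver round-off on a fixed flux
            lo = hi = 0.5 * (lo + hi)
        spans.append(FluxSpan(rid, fraction, lo, hi))
    return spans


def max_theoretical_yield(
    model: MetabolicModel,
    product_id: str,
    biomass_id: str,
    carbon_id: str,
    biomass_min_fraction: float = 0.1,
) -> tuple[float, float]:
    """Maximum growth, then maximum product flux with the biomass floor applied.

    Returns ``(mty, max_growth)``.  The floor (``biomass_min_fraction ×
    max_growth`` as the biomass lower bound) is applied *before* maximizing
    the product, so the full-enforcement state of a subsequent scan is
    feasible by construction.
    """
    if not 0 <= biomass_min_fraction < 1:
        raise ValueError("biomass_min_fraction must be in [0, 1)")
    for rid in (product_id, biomass_id, carbon_id):
        resolve_reaction(model, rid)
    cb = to_cobra(model)
    mty, max_growth = _mty_on_cobra(cb, product_id, biomass_id, biomass_min_fraction)
    return mty, max_growth


def _mty_on_cobra(
    cb: cobra.Model, product_id: str, biomass_id: str, biomass_min_fraction: float
) -> tuple[float, float]:
    growth_sol = optimize_flux(cb, biomass_id, "maximize")
    if growth_sol.status != "optimal":
        raise InfeasibleModelError(f"maximizing biomass {biomass_id!r}: {growth_sol.status}")
    max_growth = max(growth_sol.objective_value, 0.0)
    if max_growth <= FEAS_TOL and biomass_min_fraction > 0:
        raise InfeasibleModelError(
            "maximum growth is zero but a biomass floor was requested — check the "
            "medium (carbon-source uptake bound) before scanning"
        )
    with cb:
        rxn = cb.reactions.get_by_id(biomass_id)
        rxn.lower_bound = max(rxn.lower_bound, biomass_min_fraction * max_growth)
        prod_sol = optimize_flux(cb, product_id, "maximize")
    if prod_sol.status != "optimal":
        raise InfeasibleModelError(f"maximizing product {product_id!r}: {prod_sol.status}")
    mty = prod_sol.objective_value
    if -FEAS_TOL <= mty < 0:
        mty = 0.0
    return mty, max_growth


def enforced_production_scan(
    model: MetabolicModel,
    product_id: str,
    biomass_id: str,
    carbon_id: str,
    fractions: Sequence[float] | None = None,
    biomass_min_fraction: float = 0.1,
) -> ScanResult:
    """Record every reaction's feasible flux interval while production is
    stepped up to the maximum theoretical yield.

    For each fraction ``f`` the product reaction's lower bound is set to
    ``f × MTY`` (its upper bound is untouched) with the biomass lower bound
    held at ``biomass_min_fraction × max_growth``, and FVA spans are stored
    for all reactions.  The input model is never mutated.
    """
    fractions = tuple(fractions) if fractions is not None else default_fraction_grid()
    if len(fractions) < 4:
        raise ValueError("at least 4 fractions are required (two low + two high states)")
    if any(f2 <= f1 for f1, f2 in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be strictly increasing")
    if fractions[0] <= 0 or fractions[-1] > 1:
        raise ValueError("fractions must lie in (0, 1]")
    if abs(fractions[-1] - 1.0) > 1e-12:
        raise ValueError("the last fraction must be 1.0 (full enforcement of the MTY)")
    for rid in (product_id, biomass_id, carbon_id):
        resolve_reaction(model, rid)

    cb = to_cobra(model)
    mty, max_growth = _mty_on_cobra(cb, product_id, biomass_id, biomass_min_fraction)
    if mty <= FEAS_TOL:
        raise ScanError(
            f"product {product_id!r} is not producible under the current medium "
            "(maximum theoretical yield is zero)"
        )
    log.info("scan: mty=%g max_growth=%g fractions=%s", mty, max_growth, fractions)

    all_ids = [r.id for r in cb.reactions]
    spans: dict[str, list[FluxSpan]] = {rid: [] for rid in all_ids}
    biomass_floor = biomass_min_fraction * max_growth
    for f in fractions:
        extra = [(product_id, f * mty, float("inf")), (biomass_id, biomass_floor, float("inf"))]
        extra = [(rid, lb, _orig_ub(cb, rid)) for rid, lb, _ in extra]
        try:
            frame = flux_variability(cb, all_ids, extra_bounds=extra, fraction=f)
        except InfeasibleModelError as exc:
            raise InfeasibleModelError(f"fraction {f:g} of MTY is infeasible: {exc}") from exc
        for span in frame:
            spans[span.reaction_id].append(span)
        log.info("scan: fraction %.3g done", f)

    exchange_ids = frozenset(r.id for r in model.reactions if r.is_exchange)
    return ScanResult(
        mty=mty,
        max_growth=max_growth,
        fractions=fractions,
        spans={rid: tuple(lst) for rid, lst in spans.items()},
        exchange_ids=exchange_ids,
        config_echo={
            "product_id": product_id,
            "biomass_id": biomass_id,
            "carbon_id": carbon_id,
            "biomass_min_fraction": biomass_min_fraction,
            "fractions": fractions,
            "model_id": model.model_id,
        },
    )


def _orig_ub(cb: cobra.Model, rid: str) -> float:
    return float(cb.reactions.get_by_id(rid).upper_bound)
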