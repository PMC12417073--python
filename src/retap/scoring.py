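"""Reaction-target scoring: gaussian state summaries, overlap index,
intervention classification, filtering, ranking and gene mapping.

The idea: a reaction that *must* change flux between a low-production and a
high-production state is a promising engineering target.  Each state is
summarized as a normal distribution fitted to the reaction's feasible flux
intervals at the two lowest (or two highest) enforcement fractions of a
production scan:

* µ is the arithmetic mean of the four interval endpoints of the two
  fractions (equivalently, the mean of the two interval midpoints);
* σ is the overall spread — the largest maximum minus the smallest minimum
  across both fractions — floored at ``sigma_floor`` so a fixed flux still
  yields a proper density.

The *overlap index* of the two states is ∫ min(φ_low, φ_high) dx, which is
1 for identical densities and 0 for disjoint ones.  The reported score is
1/overlap (capped): a high score means the reaction has no choice but to
change when production is forced up, hence high confidence in the target.
The sign of the mean shift picks the intervention: flux rising with
production → overexpress; falling → downregulate; forced to exactly zero at
full production → knockout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

from scipy.integrate import quad
from scipy.stats import norm

from .lp import FluxSpan, ScanResult
from .model_io import MetabolicModel

__all__ = [
    "GaussianSummary",
    "TargetScore",
    "FilterConfig",
    "summarize_state",
    "overlap_index",
    "classify_intervention",
    "score_reaction",
    "rank_targets",
    "map_genes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaussianSummary:
    """(µ, σ) description of one production state for one reaction."""

    mu: float
    sigma: float


@dataclass(frozen=True)
class FilterConfig:
    """All selectivity and numerical knobs of the ranking step.

    Units: every flux-valued field (``flux_diff_cutoff``, ``knockout_eps``,
    ``sigma_floor``) is in mmol/gDW/h like the model bounds.
    """

    biomass_min_fraction: float = 0.1
    n_fractions: int = 10
    flux_diff_cutoff: float = 1e-4
    score_cutoff: float = 1.0
    knockout_eps: float = 1e-6
    sigma_floor: float = 1e-6
    score_cap: float = 1e6
    exclude_exchanges: bool = True
    exclude_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be positive")
        for name in ("flux_diff_cutoff", "score_cutoff", "knockout_eps", "score_cap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.biomass_min_fraction < 1:
            raise ValueError("biomass_min_fraction must be in [0, 1)")
        if self.n_fractions < 4:
            raise ValueError("n_fractions must be at least 4")


@dataclass(frozen=True)
class TargetScore:
    """One row of the final report: a scored, classified reaction target."""

    reaction_id: str
    low: GaussianSummary
    high: GaussianSummary
    overlap: float
    score: float
    delta_mu: float
    intervention: str  # overexpress | downregulate | knockout | none
    genes: tuple[str, ...] = ()
    gpr: str = ""
    reaction_name: str = ""


def summarize_state(
    span_a: FluxSpan, span_b: FluxSpan, sigma_floor: float = 1e-6
) -> GaussianSummary:
    """Fit the (µ, σ) state summary to two flux spans of the same reaction.

    µ = mean of the four endpoints; σ = overall max − overall min, floored.
    """
    if span_a.reaction_id != span_b.reaction_id:
        raise ValueError(
            f"spans belong to different reactions: {span_a.reaction_id!r} vs "
            f"{span_b.reaction_id!r}"
        )
    if not span_a.fraction < span_b.fraction:
        raise ValueError("span_a must come from the smaller fraction")
    mu = (span_a.min_flux + span_a.max_flux + span_b.min_flux + span_b.max_flux) / 4.0
    sigma = max(span_a.max_flux, span_b.max_flux) - min(span_a.min_flux, span_b.min_flux)
    return GaussianSummary(mu=mu, sigma=max(sigma, sigma_floor))


# ---------------------------------------------------------------------------
# overlap index

#: relative σ difference below which the equal-σ closed form is used
_EQUAL_SIGMA_RTOL = 1e-9


def overlap_index(g1: GaussianSummary, g2: GaussianSummary) -> float:
    """∫ min(φ(x; g1), φ(x; g2)) dx for two normal densities, in [0, 1].

    Evaluated analytically through the crossing points of the two densities:
    one crossing for equal σ, two otherwise, with each piece a difference of
    normal CDFs.  Symmetric in its arguments; 1 iff the densities coincide.
    """
    if g1.sigma <= 0 or g2.sigma <= 0:
        raise ValueError("overlap_index requires strictly positive sigmas")
    if g1.mu == g2.mu and g1.sigma == g2.sigma:
        return 1.0
    if abs(g1.sigma - g2.sigma) <= _EQUAL_SIGMA_RTOL * max(g1.sigma, g2.sigma):
        # equal spreads: single crossing at the midpoint
        sigma = 0.5 * (g1.sigma + g2.sigma)
        return float(min(1.0, 2.0 * norm.cdf(-abs(g1.mu - g2.mu) / (2.0 * sigma))))
    # narrow density n, wide density w: min() equals w between the two
    # crossings and n outside them
    n, w = (g1, g2) if g1.sigma < g2.sigma else (g2, g1)
    roots = _density_crossings(n, w)
    if roots is None:  # numerically degenerate; fall back to quadrature
        return _overlap_quadrature(g1, g2)
    x1, x2 = roots
    inner = norm.cdf(x2, w.mu, w.sigma) - norm.cdf(x1, w.mu, w.sigma)
    outer = norm.cdf(x1, n.mu, n.sigma) + norm.sf(x2, n.mu, n.sigma)
    return float(min(1.0, max(0.0, inner + outer)))


def _density_crossings(n: GaussianSummary, w: GaussianSummary) -> tuple[float, float] | None:
    """Solve φ_n(x) = φ_w(x) for σ_n < σ_w: a quadratic with two real roots."""
    a = 1.0 / (2.0 * w.sigma**2) - 1.0 / (2.0 * n.sigma**2)  # a < 0
    b = n.mu / n.sigma**2 - w.mu / w.sigma**2
    c = (
        w.mu**2 / (2.0 * w.sigma**2)
        - n.mu**2 / (2.0 * n.sigma**2)
        + math.log(w.sigma / n.sigma)
    )
    disc = b * b - 4.0 * a * c
    if disc <= 0 or a == 0:
        return None
    sq = math.sqrt(disc)
    x1 = (-b + sq) / (2.0 * a)  # a < 0 flips the usual ordering
    x2 = (-b - sq) / (2.0 * a)
    return (x1, x2) if x1 <= x2 else (x2, x1)


def _overlap_quadrature(g1: GaussianSummary, g2: GaussianSummary) -> float:
    lo = min(g1.mu - 8 * g1.sigma, g2.mu - 8 * g2.sigma)
    hi = max(g1.mu + 8 * g1.sigma, g2.mu + 8 * g2.sigma)
    val, _ = quad(
        lambda x: min(norm.pdf(x, g1.mu, g1.sigma), norm.pdf(x, g2.mu, g2.sigma)),
        lo,
        hi,
        limit=200,
    )
    return float(min(1.0, max(0.0, val)))


# ---------------------------------------------------------------------------
# classification and scoring


def classify_intervention(
    low: GaussianSummary,
    high: GaussianSummary,
    cfg: FilterConfig,
    final_span: FluxSpan | None = None,
) -> str:
    """Recommend a genetic intervention from the direction of the mean shift.

    Mean flux rising with enforced production → overexpress; falling →
    downregulate; falling *and* pinned at zero in the full-production state →
    knockout.  "Pinned at zero" is judged on ``final_span`` (the feasible
    interval at the highest enforcement fraction) when available, otherwise
    on |high.µ| alone.  Shifts smaller than ``flux_diff_cutoff`` are noise →
    none.  All comparisons use signed means.
    """
    delta = high.mu - low.mu
    if abs(delta) < cfg.flux_diff_cutoff:
        return "none"
    if delta > 0:
        return "overexpress"
    if final_span is not None:
        forced_zero = (
            abs(final_span.min_flux) <= cfg.knockout_eps
            and abs(final_span.max_flux) <= cfg.knockout_eps
        )
    else:
        forced_zero = abs(high.mu) <= cfg.knockout_eps
    return "knockout" if forced_zero else "downregulate"


def score_reaction(
    reaction_id: str,
    low: GaussianSummary,
    high: GaussianSummary,
    cfg: FilterConfig,
    final_span: FluxSpan | None = None,
) -> TargetScore:
    """Score one reaction: overlap of its two state gaussians, 1/overlap
    (capped at ``score_cap``), mean shift, and intervention class."""
    overlap = overlap_index(low, high)
    if overlap <= 1.0 / cfg.score_cap:
        score = cfg.score_cap
    else:
        score = 1.0 / overlap
    return TargetScore(
        reaction_id=reaction_id,
        low=low,
        high=high,
        overlap=overlap,
        score=score,
        delta_mu=high.mu - low.mu,
        intervention=classify_intervention(low, high, cfg, final_span),
    )


def rank_targets(scan: ScanResult, cfg: FilterConfig | None = None) -> list[TargetScore]:
    """Score every reaction of a scan and return the filtered, ranked targets.

    Low state: the two smallest fractions; high state: the two largest.
    Dropped: intervention "none"; score below ``score_cutoff``; |Δµ| below
    ``flux_diff_cutoff``; the product, biomass and carbon reactions (always);
    exchanges when ``exclude_exchanges``; explicit ``exclude_ids``.  Ordering:
    descending score, then descending |Δµ|, then ascending reaction id.
    """
    cfg = cfg or FilterConfig()
    if len(scan.fractions) < 4:
        raise ValueError("scan must contain at least 4 fractions")
    always_excluded = {
        scan.config_echo.get("product_id"),
        scan.config_echo.get("biomass_id"),
        scan.config_echo.get("carbon_id"),
    } | set(cfg.exclude_ids)

    n_scored = n_kept = 0
    targets: list[TargetScore] = []
    for rid, spans in scan.spans.items():
        if rid in always_excluded:
            continue
        if cfg.exclude_exchanges and rid in scan.exchange_ids:
            continue
        low = summarize_state(spans[0], spans[1], cfg.sigma_floor)
        high = summarize_state(spans[-2], spans[-1], cfg.sigma_floor)
        ts = score_reaction(rid, low, high, cfg, final_span=spans[-1])
        n_scored += 1
        if ts.intervention == "none":
            continue
        if ts.score < cfg.score_cutoff:
            continue
        if abs(ts.delta_mu) < cfg.flux_diff_cutoff:
            continue
        targets.append(ts)
        n_kept += 1
    log.info("rank_targets: %d reactions scored, %d kept after filters", n_scored, n_kept)
    targets.sort(key=lambda t: (-t.score, -abs(t.delta_mu), t.reaction_id))
    return targets


# ---------------------------------------------------------------------------
# gene mapping


def map_genes(model: MetabolicModel, targets: list[TargetScore]) -> list[TargetScore]:
    """Attach each target's gene association: the verbatim rule string plus
    the flattened, deduplicated, sorted gene list.  Reactions without a rule
    keep an empty gene list but remain valid reaction targets."""
    from cobra.core.gene import GPR

    by_id = {r.id: r for r in model.reactions}
    out = []
    for t in targets:
        rec = by_id.get(t.reaction_id)
        gpr_str = rec.gpr if rec is not None else ""
        name = rec.name if rec is not None else ""
        genes: tuple[str, ...] = ()
        if gpr_str:
            try:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", SyntaxWarning)
                    genes = tuple(sorted(GPR.from_string(gpr_str).genes))
            except Exception:
                genes = ()
            if not genes:
                log.warning("could not parse gene rule for %s: %r", t.reaction_id, gpr_str)
        out.append(replace(t, gpr=gpr_str, genes=genes, reaction_name=name))
    return out
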