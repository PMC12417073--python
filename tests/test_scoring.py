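"""Gaussian state summaries, overlap index, scoring, classification,
ranking and gene mapping."""

import logging
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from retap import (
    FilterConfig,
    GaussianSummary,
    ToyModelSpec,
    build_branched_toy,
    classify_intervention,
    map_genes,
    overlap_index,
    rank_targets,
    score_reaction,
    set_carbon_source,
    summarize_state,
)
from retap.lp import FluxSpan, ScanResult

from .oracles import equal_sigma_overlap, overlap_by_quadrature

CFG = FilterConfig()

mus = st.floats(-50, 50)
sigmas = st.floats(0.05, 20)


def span(rid, fraction, lo, hi):
    return FluxSpan(rid, fraction, lo, hi)


class TestSummarizeState:
    @pytest.mark.parametrize(
        "a, b, mu, sigma",
        [
            ((2.0, 4.0), (3.0, 5.0), 3.5, 3.0),
            ((0.0, 9.0), (0.9, 9.0), 4.725, 9.0),  # product branch, low state
            ((-4.0, -2.0), (-5.0, -3.0), -3.5, 3.0),  # signed fluxes
        ],
    )
    def test_endpoint_mean_and_overall_spread(self, a, b, mu, sigma):
        g = summarize_state(span("R", 0.1, *a), span("R", 0.2, *b))
        assert g.mu == pytest.approx(mu)
        assert g.sigma == pytest.approx(sigma)

    def test_fixed_flux_floored_to_proper_density(self):
        g = summarize_state(span("R", 0.1, 3.0, 3.0), span("R", 0.2, 3.0, 3.0),
                            sigma_floor=1e-6)
        assert g.mu == 3.0
        assert g.sigma == 1e-6

    def test_mixed_reactions_rejected(self):
        with pytest.raises(ValueError, match="different reactions"):
            summarize_state(span("R1", 0.1, 0, 1), span("R2", 0.2, 0, 1))

    def test_fraction_order_enforced(self):
        with pytest.raises(ValueError, match="smaller fraction"):
            summarize_state(span("R", 0.2, 0, 1), span("R", 0.1, 0, 1))


class TestOverlapIndex:
    def test_identical_densities_overlap_completely(self):
        assert overlap_index(GaussianSummary(2.5, 0.7), GaussianSummary(2.5, 0.7)) == 1.0

    @pytest.mark.parametrize(
        "g1, g2, expected",
        [
            ((0, 1), (1, 1), 0.6171),  # 2Φ(−1/2)
            ((0, 1), (10, 1), 2 * 0.5 * math.erfc(5 / math.sqrt(2))),  # 2Φ(−5)
        ],
    )
    def test_equal_sigma_closed_form(self, g1, g2, expected):
        got = overlap_index(GaussianSummary(*g1), GaussianSummary(*g2))
        assert got == pytest.approx(expected, abs=1e-4 if expected > 1e-3 else 1e-9)

    def test_unequal_sigma_matches_grid_quadrature(self):
        # two crossing points; oracle is dense trapezoidal integration
        got = overlap_index(GaussianSummary(0, 1), GaussianSummary(0, 3))
        assert got == pytest.approx(overlap_by_quadrature(0, 1, 0, 3), abs=1e-6)

    @given(mu1=mus, mu2=mus, s1=sigmas, s2=sigmas)
    def test_symmetric_bounded_and_matches_quadrature(self, mu1, mu2, s1, s2):
        g1, g2 = GaussianSummary(mu1, s1), GaussianSummary(mu2, s2)
        fwd, rev = overlap_index(g1, g2), overlap_index(g2, g1)
        assert fwd == pytest.approx(rev, abs=1e-9)
        assert 0.0 <= fwd <= 1.0
        assert fwd == pytest.approx(overlap_by_quadrature(mu1, s1, mu2, s2), abs=1e-6)

    @given(mu=st.floats(0.1, 30), sigma=sigmas)
    def test_equal_sigma_agrees_with_closed_form(self, mu, sigma):
        got = overlap_index(GaussianSummary(0, sigma), GaussianSummary(mu, sigma))
        assert got == pytest.approx(equal_sigma_overlap(0, mu, sigma), abs=1e-6)

    def test_monotone_decrease_with_mean_separation(self):
        vals = [overlap_index(GaussianSummary(0, 1.0), GaussianSummary(d, 2.0))
                for d in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            overlap_index(GaussianSummary(0, 0.0), GaussianSummary(0, 1.0))


class TestClassifyIntervention:
    @pytest.mark.parametrize(
        "low_mu, high_mu, expected",
        [
            (2.0, 8.0, "overexpress"),
            (5.0, 0.0, "knockout"),
            (5.0, 2.0, "downregulate"),
            (3.0, 3.0, "none"),
        ],
    )
    def test_mean_shift_direction(self, low_mu, high_mu, expected):
        got = classify_intervention(GaussianSummary(low_mu, 1.0),
                                    GaussianSummary(high_mu, 1.0), CFG)
        assert got == expected

    def test_final_span_pinned_at_zero_means_knockout(self):
        # mean of the last two fractions can sit above zero even when the
        # reaction is forced off at full enforcement
        got = classify_intervention(
            GaussianSummary(4.25, 9.0), GaussianSummary(0.25, 1.0), CFG,
            final_span=span("R", 1.0, 0.0, 0.0),
        )
        assert got == "knockout"

    def test_final_span_above_zero_overrides_small_mean(self):
        got = classify_intervention(
            GaussianSummary(5.0, 1.0), GaussianSummary(0.0, 1.0), CFG,
            final_span=span("R", 1.0, 1.0, 1.0),
        )
        assert got == "downregulate"

    def test_signed_means_compare_signed(self):
        got = classify_intervention(GaussianSummary(-8.0, 1.0),
                                    GaussianSummary(-2.0, 1.0), CFG)
        assert got == "overexpress"


class TestScoreReaction:
    def test_score_is_reciprocal_overlap(self):
        ts = score_reaction("R", GaussianSummary(0, 1), GaussianSummary(1, 1), CFG)
        assert ts.score == pytest.approx(1.0 / ts.overlap)
        assert ts.delta_mu == pytest.approx(1.0)

    def test_complete_overlap_is_lowest_score_and_no_action(self):
        g = GaussianSummary(4.0, 2.0)
        ts = score_reaction("R", g, g, CFG)
        assert (ts.overlap, ts.score, ts.intervention) == (1.0, 1.0, "none")

    def test_disjoint_states_cap_the_score(self):
        low, high = GaussianSummary(5, 0.5), GaussianSummary(0, 0.5)
        cfg = FilterConfig(knockout_eps=0.01)
        ts = score_reaction("R", low, high, cfg)
        assert ts.overlap == pytest.approx(2 * 0.5 * math.erfc(5 / math.sqrt(2)), rel=1e-6)
        assert ts.score == cfg.score_cap  # 1/overlap ≈ 1.745e6 exceeds the cap
        assert ts.intervention == "knockout"
        roomy = FilterConfig(knockout_eps=0.01, score_cap=1e7)
        assert score_reaction("R", low, high, roomy).score == pytest.approx(1.7446e6, rel=1e-3)

    @pytest.mark.parametrize("gap", [(0.0, 1.0), (1.0, 2.0), (2.0, 4.0), (4.0, 8.0)])
    def test_score_never_decreases_with_mean_gap(self, gap):
        small, big = gap
        s_small = score_reaction("R", GaussianSummary(0, 1), GaussianSummary(small, 1), CFG).score
        s_big = score_reaction("R", GaussianSummary(0, 1), GaussianSummary(big, 1), CFG).score
        assert s_big >= s_small


def synthetic_scan(spans_by_rid, exchange_ids=frozenset()):
    fractions = (0.1, 0.2, 0.9, 1.0)
    return ScanResult(
        mty=1.0,
        max_growth=1.0,
        fractions=fractions,
        spans={
            rid: tuple(FluxSpan(rid, f, lo, hi) for f, (lo, hi) in zip(fractions, intervals))
            for rid, intervals in spans_by_rid.items()
        },
        exchange_ids=exchange_ids,
        config_echo={"product_id": "EX_P", "biomass_id": "BIOMASS", "carbon_id": "EX_A"},
    )


class TestRankTargets:
    def test_planted_targets_recovered(self, toy_scan):
        targets = rank_targets(toy_scan)
        by_id = {t.reaction_id: t for t in targets}
        assert by_id["R2"].intervention == "overexpress"
        assert by_id["R3"].intervention == "downregulate"  # biomass floor prevents knockout
        assert "R_X" not in by_id  # decoy: complete overlap, no action

    def test_prohibitive_cutoff_empties_report(self, toy_scan):
        cfg = FilterConfig(score_cutoff=CFG.score_cap + 1)
        assert rank_targets(toy_scan, cfg) == []

    def test_ties_break_lexicographically(self):
        intervals = [(0.0, 4.0), (0.5, 4.0), (3.5, 4.0), (4.0, 4.0)]
        scan = synthetic_scan({"RB": intervals, "RA": intervals})
        assert [t.reaction_id for t in rank_targets(scan)] == ["RA", "RB"]

    def test_enforced_and_exchange_reactions_never_reported(self, toy_scan):
        reported = {t.reaction_id for t in rank_targets(toy_scan)}
        assert reported.isdisjoint({"EX_P", "BIOMASS", "EX_A", "EX_X", "EX_Y"})

    def test_exchanges_kept_on_request(self, toy_scan):
        cfg = FilterConfig(exclude_exchanges=False)
        reported = {t.reaction_id for t in rank_targets(toy_scan, cfg)}
        assert "EX_Y" not in reported  # decoy exchange still has no mean shift
        assert {"R1", "R2", "R3"} <= reported

    def test_explicit_exclusions_respected(self, toy_scan):
        cfg = FilterConfig(exclude_ids=("R1",))
        assert "R1" not in {t.reaction_id for t in rank_targets(toy_scan, cfg)}

    @pytest.mark.parametrize("knob", ["score_cutoff", "flux_diff_cutoff"])
    def test_filters_are_monotone_in_stringency(self, toy_scan, knob):
        grid = [0.0, 1.0, 2.0, 5.0, 1e3, 1e7]
        counts = [len(rank_targets(toy_scan, FilterConfig(**{knob: v}))) for v in grid]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_short_scan_rejected(self, toy_scan):
        import dataclasses

        short = dataclasses.replace(toy_scan, fractions=toy_scan.fractions[:3])
        with pytest.raises(ValueError, match="4 fractions"):
            rank_targets(short)


class TestMapGenes:
    @pytest.fixture()
    def toy_targets(self, toy, toy_scan):
        model, _ = toy
        return {t.reaction_id: t for t in map_genes(model, rank_targets(toy_scan))}

    def test_isozyme_and_complex_rules_flattened(self, toy_targets):
        assert toy_targets["R2"].genes == ("gP1", "gP2")
        assert toy_targets["R2"].gpr == "gP1 and gP2"
        assert toy_targets["R3"].genes == ("gB1", "gB2")

    def test_reaction_names_attached(self, toy_targets):
        assert toy_targets["R2"].reaction_name == "product branch"

    def test_flatten_dedup_sort(self):
        model, _ = build_branched_toy(ToyModelSpec())
        import dataclasses

        rxns = tuple(
            dataclasses.replace(r, gpr="(g2 and g1) or g2") if r.id == "R2" else r
            for r in model.reactions
        )
        model = dataclasses.replace(model, reactions=rxns)
        ts = score_reaction("R2", GaussianSummary(0, 1), GaussianSummary(5, 1), CFG)
        (mapped,) = map_genes(model, [ts])
        assert mapped.genes == ("g1", "g2")

    def test_empty_rule_keeps_reaction_as_target(self, toy, toy_scan):
        model, _ = toy
        cfg = FilterConfig(exclude_exchanges=False)
        mapped = {t.reaction_id: t for t in map_genes(model, rank_targets(toy_scan, cfg))}
        assert mapped["R1"].genes == ("gT1",)
        # the carbon-free trunk has a rule; exchanges do not, yet stay listed
        exchange_like = [t for t in mapped.values() if not t.gpr]
        assert all(t.genes == () for t in exchange_like)

    def test_unparseable_rule_warns_and_keeps_raw_string(self, toy, caplog):
        model, _ = toy
        import dataclasses

        rxns = tuple(
            dataclasses.replace(r, gpr="g1 and and") if r.id == "R2" else r
            for r in model.reactions
        )
        broken = dataclasses.replace(model, reactions=rxns)
        ts = score_reaction("R2", GaussianSummary(0, 1), GaussianSummary(5, 1), CFG)
        with caplog.at_level(logging.WARNING):
            (mapped,) = map_genes(broken, [ts])
        assert mapped.genes == ()
        assert mapped.gpr == "g1 and and"
        assert any("could not parse" in r.message for r in caplog.records)
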