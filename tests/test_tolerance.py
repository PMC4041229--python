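"""Tolerance analytics: solubility percentages, free-phase classification,
normalized scores, regressions, rankings, curated fixture integrity."""

import numpy as np
import pytest

import solvtol as st
from solvtol.doseresp import EC50Estimate


def point(v, method="interpolated"):
    return EC50Estimate(v, "point", None, method)


def left(b):
    return EC50Estimate(None, "left", b, "assigned")


def right(b):
    return EC50Estimate(None, "right", b, "assigned")


def make_panel(mu0, ec50s, solvents):
    return st.SpeciesPanel(mu0, ec50s, solvents)


@pytest.fixture
def two_solvents():
    mk = lambda name, lp, sol: st.SolventSpec(name, 100.0, 1.2, lp, sol, ((30.0, 0.5),))
    return {"A": mk("A", 2.9, 0.9), "B": mk("B", 1.5, 80.0)}


class TestPercentOfSolubility:
    def test_one_fifth_of_solubility_is_20_percent(self, ct):
        res = st.percent_of_solubility(1.0, ct)
        assert res.percent == pytest.approx(20.0)
        assert res.rounded == 20

    def test_identity_and_direct_ratio(self, solvents):
        pce = solvents["PCE"]
        assert st.percent_of_solubility(0.9, pce).percent == pytest.approx(100.0)
        assert st.percent_of_solubility(0.45, pce).percent == pytest.approx(50.0)

    def test_censored_estimates_become_inequalities(self, ct):
        assert st.percent_of_solubility(left(0.5), ct).relation == "<"
        assert st.percent_of_solubility(right(2.5), ct).relation == ">"
        assert st.percent_of_solubility(point(1.0), ct).relation == "="


class TestFreePhaseClassification:
    def test_nominal_ec50_above_solubility(self, solvents):
        assert st.classify_free_phase_tolerance(point(4.95, "extrapolated"), solvents["PCE"])

    def test_left_censored_below_solubility(self, solvents):
        assert not st.classify_free_phase_tolerance(left(0.2), solvents["PCE"])

    def test_exactly_at_solubility_is_not_tolerant(self, solvents):
        assert not st.classify_free_phase_tolerance(point(0.9), solvents["PCE"])

    def test_agrees_with_percent_of_solubility(self, solvents):
        pce = solvents["PCE"]
        for est in (point(0.3), point(0.9), point(1.2), right(4.0)):
            tolerant = st.classify_free_phase_tolerance(est, pce)
            pct = st.percent_of_solubility(est, pce)
            assert tolerant == (pct.percent > 100.0)


class TestNormalizedScores:
    def test_reference_scores_100_and_ratios_hold(self, two_solvents):
        panel = make_panel(
            {"ref": 1.0, "half": 0.5},
            {"ref": {"A": point(2.0), "B": point(10.0)},
             "half": {"A": point(1.0), "B": point(5.0)}},
            two_solvents,
        )
        scores = {s.species: s for s in st.normalized_tolerance_scores(panel, reference="ref")}
        assert scores["ref"].average == pytest.approx(100.0)
        assert all(v == pytest.approx(100.0) for v in scores["ref"].per_solvent.values())
        assert scores["half"].average == pytest.approx(50.0)

    def test_max_reference_matches_named_maximum(self, two_solvents):
        panel = make_panel(
            {"big": 1.0, "small": 0.5},
            {"big": {"A": point(2.0), "B": point(10.0)},
             "small": {"A": point(0.5), "B": point(2.5)}},
            two_solvents,
        )
        by_max = {s.species: s.average for s in st.normalized_tolerance_scores(panel, "max")}
        by_name = {s.species: s.average for s in st.normalized_tolerance_scores(panel, "big")}
        assert by_max == pytest.approx(by_name)

    def test_invariant_to_per_solvent_rescaling(self, two_solvents):
        ec = {"x": {"A": point(2.0), "B": point(10.0)},
              "y": {"A": point(1.0), "B": point(2.0)}}
        k = 7.3
        ec_scaled = {sp: {"A": point(e["A"].value * k), "B": e["B"]}
                     for sp, e in ec.items()}
        p1 = make_panel({"x": 1.0, "y": 0.5}, ec, two_solvents)
        p2 = make_panel({"x": 1.0, "y": 0.5}, ec_scaled, two_solvents)
        s1 = {s.species: s.average for s in st.normalized_tolerance_scores(p1)}
        s2 = {s.species: s.average for s in st.normalized_tolerance_scores(p2)}
        assert s1 == pytest.approx(s2)

    def test_raising_one_ec50_never_lowers_the_score(self, two_solvents):
        base = {"refsp": {"A": point(4.0), "B": point(20.0)},
                "other": {"A": point(1.0), "B": point(5.0)}}
        p = make_panel({"refsp": 1.0, "other": 0.5}, base, two_solvents)
        s0 = {s.species: s.average
              for s in st.normalized_tolerance_scores(p, reference="refsp")}["other"]
        bumped = {"refsp": base["refsp"],
                  "other": {"A": point(1.5), "B": base["other"]["B"]}}
        p2 = make_panel({"refsp": 1.0, "other": 0.5}, bumped, two_solvents)
        s1 = {s.species: s.average
              for s in st.normalized_tolerance_scores(p2, reference="refsp")}["other"]
        assert s1 >= s0

    def test_censored_estimates_use_bounds_and_are_flagged(self, two_solvents):
        panel = make_panel(
            {"ref": 1.0, "cens": 0.5},
            {"ref": {"A": point(2.0), "B": point(10.0)},
             "cens": {"A": left(0.5), "B": right(10.0)}},
            two_solvents,
        )
        sc = {s.species: s for s in st.normalized_tolerance_scores(panel, "ref")}
        assert set(sc["cens"].censored_solvents) == {"A", "B"}
        assert sc["cens"].per_solvent["A"] == pytest.approx(25.0)
        # exclude mode drops them instead
        sc2 = {s.species: s
               for s in st.normalized_tolerance_scores(panel, "ref", censored="exclude")}
        assert sc2["cens"].per_solvent == {}

    def test_incomplete_species_flagged(self, two_solvents):
        panel = make_panel(
            {"ref": 1.0, "partial": 0.5},
            {"ref": {"A": point(2.0), "B": point(10.0)},
             "partial": {"A": point(1.0)}},
            two_solvents,
        )
        sc = {s.species: s for s in st.normalized_tolerance_scores(panel, "ref")}
        assert sc["partial"].incomplete and not sc["ref"].incomplete


class TestRegression:
    def test_collinear_points_give_r2_of_1(self, two_solvents):
        mu0 = {f"s{i}": 0.2 * (i + 1) for i in range(4)}
        ec = {sp: {"A": point(3.0 * m + 0.1), "B": point(5.0 * m + 1.0)}
              for sp, m in mu0.items()}
        res = st.regress_ec50_vs_mu0(make_panel(mu0, ec, two_solvents))
        assert res["A"].r2 == pytest.approx(1.0)
        assert res["A"].slope == pytest.approx(3.0)
        assert res["B"].intercept == pytest.approx(1.0)

    def test_two_species_is_an_error(self, two_solvents):
        mu0 = {"a": 0.2, "b": 0.4}
        ec = {sp: {"A": point(1.0), "B": point(2.0)} for sp in mu0}
        with pytest.raises(ValueError, match=">= 3"):
            st.regress_ec50_vs_mu0(make_panel(mu0, ec, two_solvents))

    def test_degenerate_mu0_variance_is_an_error(self, two_solvents):
        mu0 = {"a": 0.2, "b": 0.2, "c": 0.2}
        ec = {sp: {"A": point(1.0), "B": point(2.0)} for sp in mu0}
        with pytest.raises(ValueError, match="variance"):
            st.regress_ec50_vs_mu0(make_panel(mu0, ec, two_solvents))

    def test_score_regression_recovers_positive_trend(self, two_solvents):
        rng = np.random.default_rng(1)
        mu0 = {f"s{i}": m for i, m in enumerate((0.1, 0.3, 0.5, 0.8, 1.0))}
        ec = {sp: {"A": point(2.0 * m + rng.normal(0, 0.01)),
                   "B": point(10.0 * m + rng.normal(0, 0.05))}
              for sp, m in mu0.items()}
        res = st.regress_ec50_vs_mu0(make_panel(mu0, ec, two_solvents), use="score")
        assert res.slope > 0 and res.r2 > 0.9


class TestToxicityRanking:
    def test_consistent_with_hydrophobicity(self, solvents):
        # EC50 rises as log_pow falls: zero violations expected
        ec = {"sp": {"PCE": point(0.3), "CT": point(0.5), "CF": point(3.5),
                     "1,2-DCA": point(7.0)}}
        ranks = st.toxicity_ranking(make_panel({"sp": 0.5}, ec, solvents))
        assert ranks[0].consistent_with_log_pow
        assert ranks[0].order[0][0] == "PCE" and ranks[0].order[-1][0] == "1,2-DCA"

    def test_ct_more_toxic_than_pce_is_flagged(self, solvents):
        ec = {"sp": {"PCE": point(1.5), "CT": point(0.5), "CF": point(3.5),
                     "1,2-DCA": point(7.0)}}
        ranks = st.toxicity_ranking(make_panel({"sp": 0.5}, ec, solvents))
        assert ("CT", "PCE") in ranks[0].violations


class TestCuratedFixture:
    def test_full_eight_by_four_panel(self):
        recs = st.load_curated_results()
        assert len(recs) == 32
        species = {r.species for r in recs}
        solvents = {r.solvent for r in recs}
        assert len(species) == 8 and solvents == {"PCE", "CT", "CF", "1,2-DCA"}

    def test_printed_point_values(self):
        by = st.curated_effective_values()
        assert by["Klebsiella sp."]["PCE"].value == pytest.approx(4.95)
        assert by["Klebsiella sp."]["PCE"].method == "extrapolated"
        assert by["Paenibacillus sp."]["CT"].value == pytest.approx(2.4)
        assert by["G. sulfurreducens"]["CF"].value == pytest.approx(0.2)
        assert by["G. sulfurreducens"]["1,2-DCA"].value == pytest.approx(6.5)

    def test_censored_entries(self):
        by = st.curated_effective_values()
        assert by["D. vulgaris"]["1,2-DCA"].kind == "right"
        assert by["D. vulgaris"]["1,2-DCA"].bound == pytest.approx(6.5)
        assert by["D. vulgaris"]["CF"].kind == "left"
        assert by["D. vulgaris"]["CF"].bound == pytest.approx(0.2)
        ct_bounds = {sp: by[sp]["CT"].bound
                     for sp in ("S. oneidensis", "D. vulgaris", "G. sulfurreducens")}
        assert ct_bounds == pytest.approx(
            {"S. oneidensis": 0.08, "D. vulgaris": 0.08, "G. sulfurreducens": 0.03}
        )

    def test_flags_and_ranges(self):
        recs = st.load_curated_results()
        pce_tolerant = [r for r in recs if "above_pce_solubility" in r.flags]
        assert len(pce_tolerant) == 5
        no_growth = [r for r in recs if "no_growth_at_lowest" in r.flags]
        assert {(r.species, r.solvent) for r in no_growth} == {
            ("S. oneidensis", "CT"), ("D. vulgaris", "CT"),
            ("G. sulfurreducens", "CT"), ("D. vulgaris", "CF"),
        }
        # every species' 1,2-DCA entry sits at or above 6.5 mM
        assert all(r.effective_value >= 6.5 for r in recs if r.solvent == "1,2-DCA")
        # non-censored CT values within the printed range
        for r in recs:
            if r.solvent == "CT" and r.kind in ("point", "range"):
                assert 0.5 <= r.effective_value <= 2.4

    def test_provenance_pointers_present_and_no_figure_values(self):
        for r in st.load_curated_results():
            assert r.source.strip(), f"{r.species}/{r.solvent} lacks a source locator"
            assert "fig" not in r.source.lower()
            if r.kind == "point":
                assert r.value is not None and r.value > 0
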