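"""Inverse-variance combination, FDR, replication calling, worked example."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ewaskit as ek
from ewaskit.meta import StudySummary, stage_result_from_effect_p
from ewaskit.worked_example import N_REPLICATION_TESTS, replicated_dmps

from conftest import qvalues_oracle, stepup_oracle


def _s(study, effect, se, probe="cg1"):
    return StudySummary(study_id=study, probe_id=probe, effect=effect, se=se)


class TestIvwMeta:
    def test_equal_weights_give_mean(self):
        r = ek.ivw_meta([_s("a", 1.0, 1.0), _s("b", 3.0, 1.0)])
        assert r.effect == pytest.approx(2.0)
        assert r.se == pytest.approx(1 / np.sqrt(2))
        assert r.q_cochran == pytest.approx(2.0)
        assert r.i_squared == pytest.approx(50.0)
        assert r.direction == "++"

    def test_order_invariance(self):
        studies = [_s("a", 1.2, 0.5), _s("b", -0.3, 1.5), _s("c", 2.0, 0.8)]
        fwd = ek.ivw_meta(studies)
        rev = ek.ivw_meta(studies[::-1])
        assert fwd.effect == pytest.approx(rev.effect, abs=1e-12)
        assert fwd.se == pytest.approx(rev.se, abs=1e-12)
        assert fwd.direction == rev.direction

    def test_precision_dominance(self):
        studies = [_s("a", 1.0, 0.7), _s("b", 2.0, 1.1), _s("c", 0.5, 2.0)]
        r = ek.ivw_meta(studies)
        assert r.se <= min(s.se for s in studies)

    def test_minimum_two_studies(self):
        with pytest.raises(ValueError, match="< required"):
            ek.ivw_meta([_s("a", 1.0, 1.0)])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_association_of_partitions(self, seed):
        # meta of sub-metas equals meta of all studies (fixed-effect algebra)
        rng = np.random.default_rng(seed)
        k = rng.integers(4, 9)
        studies = [_s(f"s{i}", rng.normal(0, 2), rng.uniform(0.3, 2.0)) for i in range(k)]
        cut = rng.integers(2, k - 1)
        left = ek.ivw_meta(studies[:cut]) if cut >= 2 else None
        right = ek.ivw_meta(studies[cut:]) if k - cut >= 2 else None
        if left is None or right is None:
            return
        combined = ek.ivw_meta(
            [
                _s("left", left.effect, left.se),
                _s("right", right.effect, right.se),
            ]
        )
        full = ek.ivw_meta(studies)
        assert combined.effect == pytest.approx(full.effect, abs=1e-12)
        assert combined.se == pytest.approx(full.se, abs=1e-12)


class TestSeFromEffectP:
    def test_z_score_anchor(self):
        assert ek.se_from_effect_p(1.96, 0.05) == pytest.approx(1.0, abs=2e-3)

    def test_table_value(self):
        # oracle: |b| / Phi^-1(1 - p/2) evaluated directly
        expected = 32.71 / stats.norm.isf(1.41e-9 / 2)
        se = ek.se_from_effect_p(-32.71, 1.41e-9)
        assert se == pytest.approx(expected, rel=1e-12)
        assert se == pytest.approx(5.40, abs=0.01)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-50, 50).filter(lambda b: abs(b) > 1e-3), st.floats(1e-12, 0.999))
    def test_round_trip(self, effect, p):
        se = ek.se_from_effect_p(effect, p)
        p_back = 2 * stats.norm.sf(abs(effect) / se)
        assert p_back == pytest.approx(p, rel=1e-9)

    def test_invalid(self):
        with pytest.raises(ValueError):
            ek.se_from_effect_p(0.0, 0.05)
        with pytest.raises(ValueError):
            ek.se_from_effect_p(1.0, 1.0)


class TestFdrAndThresholds:
    def test_single_p(self):
        q, rej = ek.bh_fdr([0.03])
        assert rej[0] and q[0] == pytest.approx(0.03)

    def test_all_rejected_example(self):
        _, rej = ek.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert rej.all()

    def test_none_rejected_example(self):
        _, rej = ek.bh_fdr([0.04, 0.9, 0.9, 0.9])
        assert not rej.any()

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40), st.floats(0.01, 0.2))
    def test_bh_matches_stepup_enumeration(self, ps, alpha):
        q, rej = ek.bh_fdr(ps, alpha=alpha)
        np.testing.assert_array_equal(rej, stepup_oracle(ps, alpha))
        np.testing.assert_allclose(q, qvalues_oracle(ps), atol=1e-12)

    def test_bonferroni(self):
        assert ek.bonferroni_threshold(0.05, 78) == pytest.approx(6.4e-4, abs=5e-6)
        assert ek.bonferroni_threshold(0.05, 1) == 0.05
        assert ek.bonferroni_threshold(0.01, 4) == 0.0025
        with pytest.raises(ValueError):
            ek.bonferroni_threshold(0.05, 0)


class TestReplication:
    def _meta(self, probe, effect, p):
        return stage_result_from_effect_p(probe, effect, p)

    def test_discordant_direction_fails(self):
        disc = [self._meta("cg1", -30.0, 1e-8)]
        repl = [self._meta("cg1", 5.0, 1e-6)]
        (call,) = ek.call_replication(disc, repl)
        assert not call.replicated and not call.concordant

    def test_replicated_example(self):
        disc = [self._meta(f"cg{i}", -30.0, 1e-7) for i in range(N_REPLICATION_TESTS)]
        repl = [self._meta("cg0", -16.34, 5.67e-7)]
        calls = ek.call_replication(disc, repl)
        assert calls[0].replicated
        assert calls[0].threshold == pytest.approx(0.05 / 78)
        assert all(c.reason == "untested" and not c.replicated for c in calls[1:])

    def test_boundary_p_equal_threshold_passes(self):
        disc = [self._meta("cg1", 10.0, 1e-8)]
        repl = [self._meta("cg1", 8.0, 0.05)]  # threshold = 0.05/1
        (call,) = ek.call_replication(disc, repl)
        assert call.replicated

    def test_min_studies_filter(self):
        mapping = {"a": [_s("s1", 1, 1, "a")], "b": [_s("s1", 1, 1, "b"), _s("s2", 1, 1, "b")]}
        assert set(ek.min_studies_filter(mapping)) == {"b"}
        assert set(ek.min_studies_filter(mapping, k=1)) == {"a", "b"}

    def test_identical_stages_halve_variance(self):
        d = ek.MetaResult("cg1", -10.0, 2.0, -5.0, 1e-6, 0, 0, 0, 2, 100, "--")
        r = ek.MetaResult("cg1", -10.0, 2.0, -5.0, 1e-6, 0, 0, 0, 2, 100, "--")
        c = ek.combine_discovery_replication(d, r)
        assert c.effect == pytest.approx(-10.0)
        assert c.se == pytest.approx(2.0 / np.sqrt(2))


class TestWorkedExample:
    """Round-trip of the published two-stage estimates for 13 replicated DMPs."""

    def test_combined_effects_reproduced(self):
        # printed combined effects, in the table's row order
        expected = {
            "cg13235761": -29.81,
            "cg26099045": 12.81,
            "cg04428662": -32.82,
            "cg23174201": -35.27,
            "cg17170437": -24.24,
            "cg14871770": -33.36,
            "cg02157636": -33.33,
            "cg26039141": -36.06,
            "cg22593432": -22.64,
            "cg11789371": -27.80,
            "cg05796561": -29.24,
            "cg17944885": -20.72,
            "cg15787712": -33.30,
        }
        for row in replicated_dmps().itertuples(index=False):
            d = stage_result_from_effect_p(row.probe_id, row.discovery_effect, row.discovery_p)
            r = stage_result_from_effect_p(row.probe_id, row.replication_effect, row.replication_p)
            c = ek.combine_discovery_replication(d, r)
            assert c.effect == pytest.approx(expected[row.probe_id], abs=0.05), row.probe_id

    def test_all_rows_replicate_under_bonferroni(self):
        t = replicated_dmps()
        threshold = ek.bonferroni_threshold(0.05, N_REPLICATION_TESTS)
        assert (t["replication_p"] <= threshold).all()
        assert (np.sign(t["replication_effect"]) == np.sign(t["discovery_effect"])).all()


class TestRoutingAndPlotData:
    def test_ethnic_replication_routing(self):
        mk = stage_result_from_effect_p
        discovery = {
            "EA": [mk("cgE", -20.0, 1e-7)],
            "HL": [mk("cgH", -25.0, 1e-7)],
            "AA": [mk("cgA", -30.0, 1e-7)],
        }
        replication = {
            "EA": [mk("cgE", -15.0, 1e-5), mk("cgH", -18.0, 1e-5)],
            "AA": [mk("cgA", 12.0, 1e-5)],  # discordant
        }
        calls = ek.meta.route_replication(discovery, replication)
        assert calls["EA"][0].replicated and calls["HL"][0].replicated
        assert not calls["AA"][0].replicated  # direction flips
        with pytest.raises(KeyError):
            ek.meta.route_replication({"XX": []}, replication)

    def test_qq_and_manhattan_tables(self):
        import pandas as pd

        results = pd.DataFrame({"probe_id": ["a", "b"], "p": [0.01, 0.5]})
        manifest = pd.DataFrame({"probe_id": ["a", "b"], "chrom": ["chr1", "chr2"], "pos": [10, 20]})
        mt = ek.meta.manhattan_table(results, manifest)
        assert list(mt["chrom"]) == ["chr1", "chr2"]
        assert mt["neglog10_p"].iloc[0] == pytest.approx(2.0)
        qq = ek.meta.qq_table(results["p"])
        assert (qq["observed_neglog10"].diff().dropna() <= 0).all()
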