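"""Substrate-driven kinase activity inference and acceptance filters."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliomics.core import OmicsMatrix, RelationMap
from gliomics.kinase import (ActivityEstimate, filter_activities,
                             infer_activities, substrate_readout,
                             superfamily_summary)
from gliomics.network import pattern_of

from conftest import make_matrix


def ks_map(rows):
    return RelationMap("kinase_substrate", pd.DataFrame(
        rows, columns=["regulator", "target", "site"]))


def phospho_matrix(design, sites, values):
    return make_matrix(values, design, layer="phosphoproteome",
                       features=sites)


class TestInference:
    def test_noiseless_single_kinase_exact(self, design):
        v = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2.0])
        m = phospho_matrix(design, [f"SUB{i}_S1" for i in range(1, 4)],
                           np.tile(v, (3, 1)))
        rel = ks_map([("KA", f"SUB{i}", "S1") for i in range(1, 4)])
        (est,) = infer_activities(m, rel, seed=0)
        assert est.n_substrates == 3
        assert np.abs(est.activity.to_numpy() - v).max() <= 1e-6
        assert est.restart_sd <= 1e-6

    def test_disjoint_kinases_match_normal_equations(self, design):
        rng = np.random.default_rng(6)
        vA = rng.normal(0, 1, 10)
        vB = rng.normal(0, 1, 10)
        YA = np.tile(vA, (3, 1)) + rng.normal(0, 0.1, (3, 10))
        YB = np.tile(vB, (4, 1)) + rng.normal(0, 0.1, (4, 10))
        sites = [f"A{i}_S1" for i in range(3)] + [f"B{i}_S1" for i in range(4)]
        m = phospho_matrix(design, sites, np.vstack([YA, YB]))
        rel = ks_map([("KA", f"A{i}", "S1") for i in range(3)]
                     + [("KB", f"B{i}", "S1") for i in range(4)])
        ests = {e.regulator_id: e for e in infer_activities(m, rel, seed=1)}
        # independent per-kinase least squares = substrate mean (ridge ~ 0)
        assert np.allclose(ests["KA"].activity, YA.mean(axis=0), atol=1e-5)
        assert np.allclose(ests["KB"].activity, YB.mean(axis=0), atol=1e-5)

    def test_shared_substrate_joint_fit(self, design):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        rows = [("KA", "U1", "S1"), ("KA", "U2", "S1"), ("KA", "U3", "S1"),
                ("KB", "V1", "S1"), ("KB", "V2", "S1"), ("KB", "V3", "S1"),
                ("KA", "W1", "S1"), ("KB", "W1", "S1")]
        sites = ["U1_S1", "U2_S1", "U3_S1", "V1_S1", "V2_S1", "V3_S1", "W1_S1"]
        Y = np.vstack([a, a, a, b, b, b, a + b])
        m = phospho_matrix(design, sites, Y)
        ests = {e.regulator_id: e
                for e in infer_activities(m, ks_map(rows), seed=2)}
        assert np.abs(ests["KA"].activity.to_numpy() - a).max() < 1e-4
        assert np.abs(ests["KB"].activity.to_numpy() - b).max() < 1e-4

    def test_kinase_without_observed_sites_excluded(self, design):
        m = phospho_matrix(design, ["X1_S1"], np.zeros((1, 10)))
        rel = ks_map([("KA", "X1", "S1"), ("KB", "ABSENT", "S9")])
        ests = infer_activities(m, rel, seed=0)
        assert [e.regulator_id for e in ests] == ["KA"]

    def test_restart_determinism(self, design):
        rng = np.random.default_rng(8)
        Y = rng.normal(0, 1, (4, 10))
        m = phospho_matrix(design, [f"S{i}_S1" for i in range(4)], Y)
        rel = ks_map([("KA", f"S{i}", "S1") for i in range(4)])
        e1 = infer_activities(m, rel, seed=42)[0]
        e2 = infer_activities(m, rel, seed=42)[0]
        assert np.array_equal(e1.activity.to_numpy(), e2.activity.to_numpy())


def _estimate(design, kid, v, sd=0.0, n_sub=3, p=0.001):
    act = pd.Series(v, index=list(design.sample_ids))
    return ActivityEstimate(kid, act, sd, n_sub, p_value=p, q_value=p)


class TestFilters:
    def _pattern_vec(self, design):
        return np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2.0]) \
            + np.tile([0, 0.02, -0.02], 4)[:10]

    def test_small_substrate_set_rejected_without_upstream(self, design):
        v = self._pattern_vec(design)
        ests = [_estimate(design, "K2", v, n_sub=2)]
        accepted = filter_activities(ests, ks_map([]), design)
        assert accepted == []

    def test_small_substrate_set_rescued_by_coactivated_upstream(self, design):
        v = self._pattern_vec(design)
        ests = [_estimate(design, "KUP", v, n_sub=5),
                _estimate(design, "K2", v + 0.1, n_sub=2)]
        rel = ks_map([("KUP", "K2", "S99")])
        accepted = filter_activities(ests, rel, design)
        assert {e.regulator_id for e in accepted} == {"KUP", "K2"}
        assert ests[1].rescued_by_upstream

    def test_rescue_requires_matching_pattern(self, design):
        v = self._pattern_vec(design)
        ests = [_estimate(design, "KUP", -v, n_sub=5),
                _estimate(design, "K2", v, n_sub=2)]
        accepted = filter_activities(ests, ks_map([("KUP", "K2", "S99")]),
                                     design)
        assert {e.regulator_id for e in accepted} == {"KUP"}

    def test_nonconverged_rejected_regardless_of_p(self, design):
        v = self._pattern_vec(design)
        ests = [_estimate(design, "K1", v, sd=0.25, n_sub=8, p=1e-9)]
        assert filter_activities(ests, ks_map([]), design) == []

    def test_sd_at_cutoff_kept(self, design):
        v = self._pattern_vec(design)
        ests = [_estimate(design, "K1", v, sd=0.2, n_sub=8)]
        assert len(filter_activities(ests, ks_map([]), design)) == 1


class TestSuperfamily:
    def test_fisher_matches_hypergeometric_oracle(self, design):
        # family AGC: 8 activated, 2 not; rest: 10 activated, 40 not
        ests = []
        fam = {}
        for i in range(10):
            e = _estimate(design, f"A{i}", np.zeros(10))
            e.accepted = i < 8
            fam[e.regulator_id] = "AGC"
            ests.append(e)
        for i in range(50):
            e = _estimate(design, f"R{i}", np.zeros(10))
            e.accepted = i < 10
            fam[e.regulator_id] = "other"
            ests.append(e)
        (agc,) = [s for s in superfamily_summary(ests, fam) if s.family == "AGC"]
        # one-sided Fisher upper tail = hypergeometric P(X >= 8)
        p_oracle = sum(comb(18, x) * comb(42, 10 - x) for x in range(8, 11)) \
            / comb(60, 10)
        assert agc.fisher_p == pytest.approx(p_oracle, rel=1e-10)

    def test_all_activated_p_one(self, design):
        ests = []
        fam = {}
        for i in range(12):
            e = _estimate(design, f"K{i}", np.zeros(10))
            e.accepted = True
            fam[e.regulator_id] = "AGC" if i < 6 else "CMGC"
            ests.append(e)
        for s in superfamily_summary(ests, fam):
            assert s.fisher_p == pytest.approx(1.0)
            assert not s.significant


class TestSubstrateReadout:
    def test_pattern_agreement_selects_substrates(self, design):
        v = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2.0])
        est = _estimate(design, "KA", v, n_sub=3)
        est.accepted = True
        sites = ["M1_S1", "M2_S1", "M3_S1"]
        Y = np.vstack([v + 0.1, np.zeros(10), -v])  # match, flat, inverted
        m = phospho_matrix(design, sites, Y)
        rel = ks_map([("KA", "M1", "S1"), ("KA", "M2", "S1"),
                      ("KA", "M3", "S1")])
        assert substrate_readout(est, m, rel) == ["M1_S1"]
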