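"""TF regulon enrichment, layer intersection, validation, repressor calls."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from gliomics.core import RelationMap
from gliomics.pipeline import run_coexpression, run_de, run_tf_stage
from gliomics.tf import (TFActivityCall, intersect_layers, repressor_mode,
                         tf_target_enrichment, validate_tf)


def tf_map(rows):
    return RelationMap("tf_target", pd.DataFrame(
        rows, columns=["regulator", "target"]))


def exhaustive_fisher_tail(universe_n, n_targets, n_de, overlap):
    """P(overlap >= k) by enumeration over DE-set placements."""
    total = comb(universe_n, n_de)
    hits = sum(comb(n_targets, x) * comb(universe_n - n_targets, n_de - x)
               for x in range(overlap, min(n_targets, n_de) + 1))
    return hits / total


class TestEnrichment:
    def test_fisher_equals_hypergeometric_tail(self):
        # 2x2 table (6,4;4,86): 10 targets, 10 DE, overlap 6, universe 100
        universe = [f"g{i}" for i in range(100)]
        targets = universe[:10]
        de = universe[:6] + universe[50:54]
        rel = tf_map([("TF1", t) for t in targets])
        res = tf_target_enrichment(de, rel, universe)
        oracle = exhaustive_fisher_tail(100, 10, 10, 6)
        assert res.loc["TF1", "p"] == pytest.approx(oracle, rel=1e-10)

    def test_small_universe_enumeration(self):
        universe = [f"g{i}" for i in range(12)]
        targets = universe[:5]
        de = universe[2:8]
        rel = tf_map([("TF1", t) for t in targets])
        res = tf_target_enrichment(de, rel, universe)
        oracle = exhaustive_fisher_tail(12, 5, 6, 3)
        assert res.loc["TF1", "p"] == pytest.approx(oracle, rel=1e-10)

    def test_zero_de_targets_p_near_one(self):
        universe = [f"g{i}" for i in range(50)]
        rel = tf_map([("TF1", t) for t in universe[:10]])
        res = tf_target_enrichment(universe[40:45], rel, universe)
        assert res.loc["TF1", "p"] > 0.5

    def test_tf_without_targets_in_universe_skipped(self):
        rel = tf_map([("TF1", "absent_gene")])
        res = tf_target_enrichment(["g1"], rel, ["g1", "g2"])
        assert len(res) == 0


def _enr(tfs, sig):
    df = pd.DataFrame({"n_targets": 10, "overlap": 5,
                       "p": [0.001 if s else 0.9 for s in sig],
                       "q": [0.004 if s else 0.9 for s in sig],
                       "significant": sig}, index=tfs)
    return df


class TestIntersectLayers:
    def test_transcriptome_only_rejected(self):
        calls = intersect_layers(_enr(["TF1"], [True]),
                                 {1: _enr(["TF1"], [False])}, ["TF1"])
        assert not calls[0].accepted_by_targets
        assert "proteome" in calls[0].reject_reason

    def test_both_layers_and_ms_detection_accepted(self):
        calls = intersect_layers(_enr(["TF1"], [True]),
                                 {1: _enr(["TF1"], [True])}, ["TF1", "X"])
        assert calls[0].accepted_by_targets

    def test_undetected_by_ms_rejected_with_reason(self):
        calls = intersect_layers(_enr(["TF1"], [True]),
                                 {1: _enr(["TF1"], [True])}, ["OTHER"])
        assert not calls[0].accepted_by_targets
        assert calls[0].reject_reason == "not identified by MS"


def _de_table(features, is_de, means=None):
    df = pd.DataFrame({"is_de": is_de}, index=features)
    if means:
        for col, vals in means.items():
            df[col] = vals
    return df


class TestValidation:
    def test_phospho_activation_site(self):
        call = TFActivityCall("MYC", accepted_by_targets=True)
        prot = _de_table(["MYC"], [False])
        ph = _de_table(["MYC_S62"], [True],
                       {"mean_cortex": [0.0], "mean_PDGFRA": [1.0],
                        "mean_NTRK": [2.0]})
        validate_tf(call, prot, ph)
        assert call.validated == "phospho_activation_site"
        assert call.activation_sites == ["MYC_S62"]

    def test_protein_level_only(self):
        call = TFActivityCall("JUN", accepted_by_targets=True)
        prot = _de_table(["JUN"], [True])
        ph = _de_table([], [])
        validate_tf(call, prot, ph)
        assert call.validated == "protein_level"

    def test_neither_is_none(self):
        call = TFActivityCall("EP300", accepted_by_targets=True)
        validate_tf(call, _de_table(["EP300"], [False]), _de_table([], []))
        assert call.validated == "none"

    def test_downregulated_activation_site_not_validating(self):
        call = TFActivityCall("JUND", accepted_by_targets=True)
        ph = _de_table(["JUND_S100"], [True],
                       {"mean_cortex": [2.0], "mean_PDGFRA": [1.0],
                        "mean_NTRK": [0.0]})
        validate_tf(call, _de_table(["JUND"], [False]), ph)
        assert call.validated == "none"


class TestRepressorMode:
    def _call(self):
        return TFActivityCall("REST", accepted_by_targets=True)

    def test_all_targets_down_is_repressor(self):
        fc = pd.Series(-np.ones(10))
        assert repressor_mode(self._call(), fc) == "repressor"

    def test_all_targets_up_is_activator(self):
        fc = pd.Series(np.ones(10))
        assert repressor_mode(self._call(), fc) == "activator"

    def test_balanced_targets_undetermined(self):
        fc = pd.Series([1.0] * 5 + [-1.0] * 5)
        assert repressor_mode(self._call(), fc) == "undetermined"

    def test_too_few_targets_undetermined(self):
        fc = pd.Series([-1.0, -1.0, -1.0])
        assert repressor_mode(self._call(), fc) == "undetermined"

    def test_sign_test_matches_binomial_oracle(self):
        # 9 down of 10: one-sided binomial P(X>=9 | n=10, 0.5) = 11/1024
        fc = pd.Series([-1.0] * 9 + [1.0])
        assert repressor_mode(self._call(), fc, p_cut=11 / 1024) == "repressor"
        assert repressor_mode(self._call(), fc,
                              p_cut=10 / 1024) == "undetermined"


class TestSyntheticOperatingCharacteristics:
    def test_planted_tfs_recovered_inactive_rejected(self, study):
        s = study
        tx_de = run_de(s.transcriptome, n_perm=300, seed=1)
        pr_de = run_de(s.proteome, n_perm=300, seed=2)
        ph_de = run_de(s.phosphoproteome, n_perm=300, seed=3)
        clusters = run_coexpression(s.proteome, pr_de)
        calls = run_tf_stage(s, tx_de, pr_de, ph_de, clusters)
        accepted = {c.tf_id for c in calls if c.accepted_by_targets}
        active = set(s.truth.active_tfs)
        assert len(accepted & active) / len(active) >= 0.9
        inactive_accepted = accepted - active
        n_inactive = len(set(s.truth.tf_targets) - active)
        assert len(inactive_accepted) / n_inactive <= 0.05
        # phospho-validated TFs carry their planted activation site
        for c in calls:
            if c.tf_id in s.truth.phospho_validated_tfs and \
                    c.accepted_by_targets:
                assert c.validated in ("phospho_activation_site", "both")
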