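"""Dual-gRNA dropout normalization, construct tests, gene-level hit calls."""

import numpy as np
import pandas as pd
import pytest

from gliomics.core import DataError
from gliomics.crispr import (GRNACountTable, NONTARGETING, call_gene_hits,
                             construct_dropout_test, construct_ratios,
                             hit_summary, normalize_counts)
from gliomics.simulate import generate_grna_screen


def table(rows):
    return GRNACountTable(pd.DataFrame(rows))


def row(cid, gene, start, final):
    d = {"construct_id": cid, "gene": gene}
    d.update({f"start_{i+1}": v for i, v in enumerate(start)})
    d.update({f"final_{i+1}": v for i, v in enumerate(final)})
    return d


BASE = [row("nt_1", NONTARGETING, [100, 110, 90], [100, 105, 95]),
        row("nt_2", NONTARGETING, [95, 100, 100], [90, 100, 110]),
        row("nt_3", NONTARGETING, [105, 95, 100], [110, 95, 100])]


class TestNormalize:
    def test_depth_invariance(self):
        rows = [row("a", "G1", [100, 200], [100, 200]),
                row("b", NONTARGETING, [300, 600], [300, 600])]
        norm = normalize_counts(table(rows))
        assert norm.loc["a", "start_1"] == pytest.approx(
            norm.loc["a", "start_2"])
        assert norm.loc["b", "final_1"] == pytest.approx(
            norm.loc["b", "final_2"])

    def test_zero_count_pseudocount(self):
        rows = [row("a", "G1", [0, 10], [0, 10]),
                row("b", NONTARGETING, [100, 100], [100, 100])]
        norm = normalize_counts(table(rows))
        assert norm.loc["a", "start_1"] == pytest.approx(0.0)  # log2(0+1)

    def test_hand_cpm_toy(self):
        rows = [row("a", "G1", [250], [100]),
                row("b", "G1", [250], [100]),
                row("c", NONTARGETING, [500], [800])]
        norm = normalize_counts(table(rows))
        # library sizes 1000; CPM(a,start) = 250e3; log2(250e3 + 1)
        assert norm.loc["a", "start_1"] == pytest.approx(np.log2(250_000 + 1))
        assert norm.loc["c", "final_1"] == pytest.approx(np.log2(800_000 + 1))

    def test_zero_library_rejected(self):
        rows = [row("a", "G1", [0], [10]),
                row("b", NONTARGETING, [0], [10])]
        with pytest.raises(DataError):
            normalize_counts(table(rows))


class TestConstructTest:
    def test_null_construct_not_significant(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(0, 0.1, 18)
        ratios = rng.normal(0, 0.1, 3)
        _, p, down = construct_dropout_test(ratios, ctrl)
        assert not down

    def test_planted_dropout_significant(self):
        ctrl = np.array([0.05, -0.03, 0.02, -0.05, 0.01, 0.0])
        ratios = np.array([-3.0, -2.9, -3.1])
        t, p, down = construct_dropout_test(ratios, ctrl)
        assert down and p < 1e-4 and t < 0

    def test_enriched_construct_never_down(self):
        ctrl = np.array([0.05, -0.03, 0.02, -0.05, 0.01, 0.0])
        ratios = np.array([3.0, 2.9, 3.1])
        _, p, down = construct_dropout_test(ratios, ctrl)
        assert not down

    def test_degenerate_variance_ties_p_one(self):
        _, p, down = construct_dropout_test([0.0, 0.0, 0.0],
                                            [0.0, 0.0, 0.0])
        assert p == 1.0 and not down


def screen_rows(gene_ratios):
    """Build a screen; gene_ratios maps gene -> list of 3 construct log2fc."""
    rows = [r.copy() for r in BASE]
    for gene, fcs in gene_ratios.items():
        for i, fc in enumerate(fcs, start=1):
            start = [1000, 1000, 1000]
            final = [int(1000 * 2 ** (fc + d)) for d in (-0.01, 0.0, 0.01)]
            rows.append(row(f"{gene}_c{i}", gene, start, final))
    return rows


class TestGeneHits:
    def test_two_of_three_down_is_hit(self):
        calls = call_gene_hits(table(screen_rows(
            {"G1": [-3.0, -3.0, 0.0]})))
        (g1,) = [c for c in calls if c.gene == "G1"]
        assert g1.n_significant_down == 2 and g1.is_hit

    def test_one_of_three_not_hit(self):
        calls = call_gene_hits(table(screen_rows({"G1": [-3.0, 0.0, 0.0]})))
        (g1,) = [c for c in calls if c.gene == "G1"]
        assert g1.n_significant_down == 1 and not g1.is_hit

    def test_nontargeting_never_hit(self):
        calls = call_gene_hits(table(screen_rows({"G1": [-3, -3, -3]})))
        (nt,) = [c for c in calls if c.gene == NONTARGETING]
        assert not nt.is_hit

    def test_nonstandard_construct_count_flagged(self):
        rows = screen_rows({"G1": [-3.0, -3.0, 0.0]})
        rows.append(row("G1_c4", "G1", [1000] * 3, [1000] * 3))
        calls = call_gene_hits(table(rows))
        (g1,) = [c for c in calls if c.gene == "G1"]
        assert g1.flagged
        assert not g1.is_hit  # needs ceil(8/3) = 3 of 4

    def test_invariance_to_order_and_depth(self):
        rows = screen_rows({"G1": [-3.0, -3.0, 0.0], "G2": [0, 0, 0]})
        t1 = table(rows)
        shuffled = pd.DataFrame(rows).iloc[::-1].reset_index(drop=True)
        scaled = shuffled.copy()
        for c in [c for c in scaled.columns if c.startswith(("start_",
                                                             "final_"))]:
            scaled[c] = scaled[c] * 7
        hits1 = {c.gene: c.is_hit for c in call_gene_hits(t1)}
        hits2 = {c.gene: c.is_hit
                 for c in call_gene_hits(GRNACountTable(scaled))}
        assert hits1 == hits2


class TestSyntheticScreen:
    def test_planted_essentials_recovered(self):
        genes = [f"GENE{i}" for i in range(1, 10)]
        tab = generate_grna_screen(genes, genes[:5], dropout_fold=8.0, seed=3)
        assert len(tab.table) == 9 * 3 + 6
        summary = hit_summary(call_gene_hits(tab))
        assert summary["hits"] == sorted(genes[:5])
        assert summary["hit_fraction"] == pytest.approx(5 / 9)

    def test_null_dropout_controls_and_essentials_alike(self):
        genes = [f"GENE{i}" for i in range(1, 10)]
        tab = generate_grna_screen(genes, genes[:5], dropout_fold=1.0, seed=4)
        norm = normalize_counts(tab)
        ratios = construct_ratios(norm, tab.n_replicates)
        rep = [c for c in ratios.columns if c.startswith("ratio_")]
        ess = ratios.loc[ratios.index.str.startswith("GENE1_"), rep]
        ctrl = ratios.loc[ratios["gene"] == NONTARGETING, rep]
        from scipy import stats
        _, p = stats.ttest_ind(ess.to_numpy().ravel(),
                               ctrl.to_numpy().ravel())
        assert p > 0.01

    def test_strong_dropout_all_essential_constructs_decrease(self):
        genes = [f"GENE{i}" for i in range(1, 10)]
        tab = generate_grna_screen(genes, genes[:5], dropout_fold=8.0,
                                   dispersion=0.01, seed=5)
        norm = normalize_counts(tab)
        ratios = construct_ratios(norm, tab.n_replicates)
        rep = [c for c in ratios.columns if c.startswith("ratio_")]
        ess_mask = ratios["gene"].isin(genes[:5])
        assert (ratios.loc[ess_mask, rep].mean(axis=1) < -1).all()
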