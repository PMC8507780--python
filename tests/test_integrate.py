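"""Cross-layer correlations, altered-protein selection, gene-set
enrichment and activation z-scores."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hlaquant.integrate import (activation_zscore, add_activation_zscores,
                                enrich_gene_sets,
                                peptide_protein_correlation,
                                proteome_interactome_correlation,
                                select_altered)


def pep_quant(proteins, log2s):
    return pd.DataFrame({
        "peptide": [f"pep{i}" for i in range(len(proteins))],
        "proteins": proteins,
        "log2_ratio": log2s,
        "capped": ["none"] * len(proteins),
    })


def prot_quant(proteins, log2s, genes=None):
    return pd.DataFrame({
        "protein": proteins,
        "gene": genes or proteins,
        "log2_ratio": log2s,
        "capped": ["none"] * len(proteins),
    })


class TestPeptideProteinCorrelation:
    def test_identical_layers_perfect_fit(self):
        prots = [f"P{i}" for i in range(10)]
        log2s = list(np.linspace(-1, 1, 10))
        res = peptide_protein_correlation(pep_quant(prots, log2s),
                                          prot_quant(prots, log2s))
        assert np.isclose(res["r"], 1.0)
        assert np.isclose(res["slope"], 1.0)

    def test_median_aggregation_of_sibling_peptides(self):
        peps = pep_quant(["P1", "P1", "P1", "P2", "P3"],
                         [0.2, 0.8, 0.4, 0.0, 0.3])
        res = peptide_protein_correlation(
            peps, prot_quant(["P1", "P2", "P3"], [1.0, 0.0, 0.5]))
        paired = res["paired"].set_index("protein")
        assert paired.loc["P1", "peptide_log2"] == 0.4

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            peptide_protein_correlation(pep_quant(["P1"], [0.1]),
                                        prot_quant(["P1"], [0.1]))

    def test_independent_layers_uncorrelated(self):
        """Null recovery: independently planted peptide and protein ratios
        should not correlate (at most 1 of 3 datasets significant)."""
        n_sig = 0
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            prots = [f"P{i}" for i in range(200)]
            res = peptide_protein_correlation(
                pep_quant(prots, rng.normal(-0.5, 1.0, 200)),
                prot_quant(prots, rng.normal(0.0, 0.5, 200)))
            assert abs(res["r"]) < 0.25
            n_sig += res["p"] < 0.05
        assert n_sig <= 1

    def test_pipeline_layers_independent(self, pipeline_run):
        _, summary = pipeline_run
        assert abs(summary["integration"]["peptide_protein"]["r"]) < 0.25


class TestSelectAltered:
    def test_cutoff_boundaries(self):
        q = prot_quant(["P1", "P2", "P3", "P4"], [0.61, 0.59, -0.7, 0.0])
        assert select_altered(q) == ["P1", "P3"]

    def test_all_zero_empty(self):
        assert select_altered(prot_quant(["P1"], [0.0])) == []


class TestEnrichGeneSets:
    def test_query_equals_set_equals_universe(self):
        res = enrich_gene_sets({"a", "b"}, {"S": {"genes": ["a", "b"]}},
                               {"a", "b"})
        assert np.isclose(res.iloc[0]["p"], 1.0)

    def test_matches_exhaustive_enumeration_oracle(self):
        # universe 10, set 4, query 3, overlap 3: enumerate all C(10,3) draws
        universe = [f"g{i}" for i in range(10)]
        members = universe[:4]
        res = enrich_gene_sets(set(members[:3]), {"S": {"genes": members}},
                               set(universe))
        n_hits = sum(1 for draw in itertools.combinations(universe, 3)
                     if len(set(draw) & set(members)) >= 3)
        expected = n_hits / math.comb(10, 3)
        assert np.isclose(res.iloc[0]["p"], expected, atol=1e-12)
        assert np.isclose(res.iloc[0]["p"], 4 / 120)

    @pytest.mark.parametrize("n_universe,set_size,query_size,seed",
                             [(8, 3, 4, 0), (12, 5, 6, 1), (10, 4, 5, 2)])
    def test_hypergeometric_equals_enumeration_small_universes(
            self, n_universe, set_size, query_size, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(n_universe)]
        members = list(rng.choice(universe, set_size, replace=False))
        query = set(rng.choice(universe, query_size, replace=False))
        res = enrich_gene_sets(query, {"S": {"genes": members}}, set(universe))
        k = len(query & set(members))
        n_hits = sum(1 for draw in itertools.combinations(universe, query_size)
                     if len(set(draw) & set(members)) >= k)
        expected = n_hits / math.comb(n_universe, query_size)
        assert np.isclose(res.iloc[0]["p"], expected, atol=1e-12)

    def test_zero_overlap_with_tiny_set(self):
        universe = [f"g{i}" for i in range(100)]
        res = enrich_gene_sets({"g0"}, {"S": {"genes": ["g99"]}},
                               set(universe))
        assert res.iloc[0]["p"] > 0.9

    def test_bh_adjustment_properties(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(50)]
        sets = {f"S{j}": {"genes": list(rng.choice(universe, 10,
                                                   replace=False))}
                for j in range(12)}
        res = enrich_gene_sets(set(universe[:8]), sets, set(universe))
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert (res["p_adj"] <= 1.0).all()
        assert res["p"].is_monotonic_increasing
        assert res["p_adj"].is_monotonic_increasing

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_gene_sets(set(), {}, set())

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_gene_sets({"x"}, {}, {"a"})


class TestActivationZscore:
    def test_all_concordant(self):
        genes = [f"g{i}" for i in range(9)]
        log2s = {g: 1.0 for g in genes}
        dirs = {g: 1 for g in genes}
        assert activation_zscore(genes, log2s, dirs) == pytest.approx(3.0)

    def test_balanced_signs_zero(self):
        genes = ["a", "b", "c", "d"]
        log2s = {"a": 1.0, "b": 1.0, "c": -1.0, "d": -1.0}
        dirs = {g: 1 for g in genes}
        assert activation_zscore(genes, log2s, dirs) == pytest.approx(0.0)

    def test_five_concordant_one_discordant(self):
        genes = [f"g{i}" for i in range(6)]
        log2s = {g: 1.0 for g in genes}
        dirs = {g: 1 for g in genes}
        dirs["g5"] = -1
        assert activation_zscore(genes, log2s, dirs) == \
            pytest.approx(4 / math.sqrt(6))

    def test_sub_cutoff_genes_excluded(self):
        log2s = {"a": 0.5, "b": 1.0}
        assert activation_zscore(["a", "b"], log2s, {"a": 1, "b": 1}) == \
            pytest.approx(1.0)

    def test_no_contributing_genes_absent(self):
        assert activation_zscore(["a"], {}, {"a": 1}) is None

    def test_bounded_by_sqrt_m(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(17)]
        log2s = {g: float(rng.normal(0, 1.5)) for g in genes}
        dirs = {g: int(rng.choice([-1, 1])) for g in genes}
        z = activation_zscore(genes, log2s, dirs)
        m = sum(1 for g in genes if abs(log2s[g]) > 0.6)
        assert z is None or abs(z) <= math.sqrt(m) + 1e-12

    def test_planted_pathway_directions_recovered(self, experiment):
        """Planted activated sets score positive z, inhibited negative."""
        truth = experiment.truth.proteome
        log2s = dict(zip(truth["gene"], truth["true_log2"]))
        enr = pd.DataFrame({"set": list(experiment.gene_sets)})
        enr = add_activation_zscores(enr, experiment.gene_sets, log2s,
                                     experiment.directions)
        z = enr.set_index("set")["z"]
        for name in z.index:
            if name.startswith("SET_ACT"):
                assert z[name] > 0
            elif name.startswith("SET_INH"):
                assert z[name] < 0


class TestProteomeInteractomeCorrelation:
    def test_identical_vectors(self):
        q = prot_quant([f"P{i}" for i in range(5)], [0.1, 0.5, -0.3, 0.9, 0.0])
        res = proteome_interactome_correlation(q, q)
        assert np.isclose(res["r"], 1.0)

    def test_planted_shared_signal_detected(self):
        # shared true fold change plus independent noise at n=300
        rng = np.random.default_rng(0)
        shared = rng.normal(0, 0.8, 300)
        prots = [f"P{i}" for i in range(300)]
        a = prot_quant(prots, shared + rng.normal(0, 0.3, 300))
        b = prot_quant(prots, shared + rng.normal(0, 0.3, 300))
        res = proteome_interactome_correlation(a, b)
        assert res["p"] < 1e-4
        assert res["r"] > 0

    def test_independent_vectors_not_significant(self):
        n_sig = 0
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            prots = [f"P{i}" for i in range(300)]
            a = prot_quant(prots, rng.normal(0, 0.5, 300))
            b = prot_quant(prots, rng.normal(0, 0.5, 300))
            n_sig += proteome_interactome_correlation(a, b)["p"] < 0.05
        assert n_sig <= 1

    def test_too_few_shared_rejected(self):
        a = prot_quant(["P1", "P2"], [0.1, 0.2])
        with pytest.raises(ValueError):
            proteome_interactome_correlation(a, a)

    def test_pipeline_reports_positive_correlation(self, pipeline_run):
        _, summary = pipeline_run
        pi = summary["integration"]["proteome_interactome"]
        assert pi["r"] > 0
        assert pi["p"] < 1e-4
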