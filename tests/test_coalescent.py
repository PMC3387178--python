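"""MSC gene-tree simulator: rates, unit conversion, closed-form checks."""

import numpy as np
import pytest
from scipy import stats

from lineagesort import (
    NeConfig,
    SimRequest,
    parse_newick,
    simulate_baseline_sample,
    simulate_msc_gene_tree,
    time_to_generations,
    write_newick,
)
from lineagesort.coalescent import simulate_single_population_genealogy
from lineagesort.trees import TreeSample, tip_labels


class TestNeConfig:
    def test_plastid_defaults_to_half(self):
        ne = NeConfig("x", 190000.0)
        assert ne.plastid_ne == 95000.0
        assert ne.ne_for("plastid") == 95000.0
        assert ne.ne_for("nuclear") == 190000.0

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_ne_rejected(self, bad):
        with pytest.raises(ValueError):
            NeConfig("x", bad)

    def test_unknown_locus_kind(self):
        with pytest.raises(ValueError, match="locus"):
            NeConfig("x", 1000.0).ne_for("mitochondrial")


@pytest.mark.parametrize(
    "ma,gt,expected",
    [(1.0, 1.0, 1_000_000.0), (0.5, 2.0, 250_000.0), (0.0, 5.0, 0.0)],
)
def test_time_to_generations(ma, gt, expected):
    assert time_to_generations(ma, gt) == expected


def test_time_to_generations_bad_generation_time():
    with pytest.raises(ValueError):
        time_to_generations(1.0, 0.0)


class TestSingleSimulation:
    def test_tip_set_matches_chronogram(self, chronogram8):
        g = simulate_msc_gene_tree(chronogram8, NeConfig("m", 320000.0), seed=5)
        assert tip_labels(g) == tip_labels(chronogram8)

    def test_binary_and_positive_lengths(self, chronogram8):
        g = simulate_msc_gene_tree(chronogram8, NeConfig("m", 320000.0), seed=5)
        for node in g.preorder_internal_node_iter():
            assert len(node.child_nodes()) == 2
        for node in g.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length >= 0

    def test_node_times_respect_species_tree(self, chronogram8):
        """Coalescence cannot predate the species divergence (in generations)."""
        ne = NeConfig("m", 320000.0)
        g = simulate_msc_gene_tree(chronogram8, ne, seed=9)
        # pairwise TMRCA in the gene tree >= species divergence time
        pdm_sp = chronogram8.phylogenetic_distance_matrix()
        pdm_g = g.phylogenetic_distance_matrix()
        sp_tax = {t.label: t for t in chronogram8.taxon_namespace}
        g_tax = {t.label: t for t in g.taxon_namespace}
        labels = sorted(sp_tax)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                div_gen = time_to_generations(
                    pdm_sp.distance(sp_tax[a], sp_tax[b]) / 2.0, ne.generation_time
                )
                tmrca_gen = pdm_g.distance(g_tax[a], g_tax[b]) / 2.0
                assert tmrca_gen >= div_gen - 1e-6

    def test_non_ultrametric_input_rejected(self):
        bad = parse_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            simulate_msc_gene_tree(bad, NeConfig("m", 1000.0), seed=0)

    def test_multiple_samples_per_species(self, chronogram8):
        g = simulate_msc_gene_tree(
            chronogram8, NeConfig("m", 1e5), seed=0, samples_per_species=2
        )
        assert len(g.leaf_nodes()) == 16

    def test_deterministic_from_seed(self, chronogram8):
        a = simulate_msc_gene_tree(chronogram8, NeConfig("m", 3e5), seed=77)
        b = simulate_msc_gene_tree(chronogram8, NeConfig("m", 3e5), seed=77)
        assert write_newick(a) == write_newick(b)


class TestCoalescentMath:
    def test_pairwise_tmrca_mean_is_2ne(self):
        """E[T2] = 2Ne under the 1/(2Ne) pair rate."""
        ne = 1000.0
        rng = np.random.default_rng(11)
        times = [
            simulate_single_population_genealogy(2, ne, seed=rng)
            .seed_node.child_nodes()[0]
            .edge.length
            for _ in range(5000)
        ]
        assert np.mean(times) == pytest.approx(2 * ne, rel=0.06)

    def test_first_coalescence_waiting_time_exponential(self):
        """T_k ~ Exp(k(k-1)/2 / (2Ne)) for the k-lineage stage."""
        ne, k = 500.0, 6
        rng = np.random.default_rng(21)
        waits = []
        for _ in range(5000):
            g = simulate_single_population_genealogy(k, ne, seed=rng)
            # first coalescence time = min internal node age
            ages = []
            depth = {g.seed_node: 0.0}
            for node in g.preorder_node_iter():
                if node.parent_node is not None:
                    depth[node] = depth[node.parent_node] + node.edge.length
            h = max(d for n, d in depth.items() if n.is_leaf())
            for node in g.preorder_internal_node_iter():
                ages.append(h - depth[node])
            waits.append(min(ages))
        rate = k * (k - 1) / 2.0 / (2.0 * ne)
        stat, p = stats.kstest(waits, "expon", args=(0, 1.0 / rate))
        assert p > 0.01

    def test_three_taxon_concordance(self):
        """P(concordant) = 1 - (2/3) exp(-t/(2Ne)) for internal branch t."""
        ne = NeConfig("m", 320000.0)  # 2Ne = 640k generations
        t_2ne = 1.0  # internal branch equal to 2Ne generations
        internal_ma = t_2ne * 2 * ne.nuclear_ne / 1e6
        nwk = f"((A:1.0,B:1.0):{internal_ma},C:{1.0 + internal_ma});"
        sp = parse_newick(nwk)
        rng = np.random.default_rng(31)
        hits = 0
        n = 4000
        for _ in range(n):
            g = simulate_msc_gene_tree(sp, ne, seed=rng)
            for node in g.postorder_internal_node_iter():
                kids = node.child_nodes()
                if len(kids) == 2 and all(k.is_leaf() for k in kids):
                    hits += {k.taxon.label for k in kids} == {"A", "B"}
        p_exp = 1 - (2 / 3) * np.exp(-t_2ne)
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(hits / n - p_exp) < 3 * se

    def test_long_internal_branch_always_concordant(self):
        ne = NeConfig("tiny", 100.0)
        sp = parse_newick("((A:1.0,B:1.0):1.0,C:2.0);")  # 1 Ma >> 2Ne gens
        rng = np.random.default_rng(41)
        for _ in range(200):
            g = simulate_msc_gene_tree(sp, ne, seed=rng)
            cherries = [
                {k.taxon.label for k in nd.child_nodes()}
                for nd in g.postorder_internal_node_iter()
                if all(k.is_leaf() for k in nd.child_nodes())
            ]
            assert {"A", "B"} in cherries

    def test_msprime_cross_check_pairwise_tmrca(self):
        """Independent oracle: msprime single-population pairwise TMRCA."""
        msprime = pytest.importorskip("msprime")
        ne = 1000.0
        ts_means = []
        for seed in range(1, 6):
            reps = msprime.sim_ancestry(
                samples=1,  # one diploid -> 2 lineages
                population_size=ne,
                ploidy=2,
                num_replicates=1000,
                random_seed=seed,
            )
            ts_means.extend(t.max_root_time for t in reps)
        rng = np.random.default_rng(51)
        ours = [
            simulate_single_population_genealogy(2, ne, seed=rng)
            .seed_node.child_nodes()[0]
            .edge.length
            for _ in range(5000)
        ]
        assert np.mean(ours) == pytest.approx(np.mean(ts_means), rel=0.08)


class TestBaselineSample:
    def test_default_counts_20x5(self, null_scenario):
        post = null_scenario.posteriors["ITS"]
        sim = simulate_baseline_sample(
            SimRequest(chronograms=post, replicates=5, seed=1), NeConfig("m", 3e5)
        )
        assert len(sim) == 100
        assert sim.metadata[0]["chronogram_index"] == 0
        assert sim.metadata[-1]["chronogram_index"] == 19

    def test_determinism(self, null_scenario):
        post = null_scenario.posteriors["ITS"]
        req = SimRequest(chronograms=post, replicates=2, seed=9)
        a = simulate_baseline_sample(req, NeConfig("m", 3e5))
        b = simulate_baseline_sample(req, NeConfig("m", 3e5))
        assert [write_newick(t) for t in a] == [write_newick(t) for t in b]

    def test_plastid_coalesces_faster_than_nuclear(self, chronogram8):
        """Ne scaling 0.5 means strictly faster average coalescence."""
        ne = NeConfig("m", 320000.0)
        sample = TreeSample([chronogram8] * 5)

        def mean_height(locus, seed):
            sim = simulate_baseline_sample(
                SimRequest(chronograms=sample, locus=locus, replicates=20, seed=seed),
                ne,
            )
            return np.mean(
                [max(l.distance_from_root() for l in t.leaf_node_iter()) for t in sim]
            )

        assert mean_height("plastid", 3) < mean_height("nuclear", 3)

    def test_invalid_request(self, chronogram8):
        sample = TreeSample([chronogram8])
        with pytest.raises(ValueError):
            SimRequest(chronograms=sample, replicates=0)
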