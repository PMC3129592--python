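import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import hypergeom

import tissueatlas as ta
from tissueatlas.crossspecies import OrthoFamily


class TestCollapseProbes:
    def test_single_probe_identity(self):
        mat = pd.DataFrame([[3.0, 9.0]], index=["p0"], columns=["head", "gut"])
        out = ta.collapse_probes(mat, pd.Series({"p0": "gA"}))
        np.testing.assert_allclose(out.loc["gA"], [3.0, 9.0])

    def test_per_tissue_max(self):
        mat = pd.DataFrame(
            [[3.0, 9.0], [5.0, 4.0]], index=["p0", "p1"], columns=["head", "gut"]
        )
        out = ta.collapse_probes(mat, pd.Series({"p0": "gA", "p1": "gA"}))
        np.testing.assert_allclose(out.loc["gA"], [5.0, 9.0])

    def test_unannotated_probe_dropped_with_tally(self):
        mat = pd.DataFrame(
            [[3.0, 9.0], [5.0, 4.0]], index=["p0", "px"], columns=["head", "gut"]
        )
        out = ta.collapse_probes(mat, pd.Series({"p0": "gA"}))
        assert list(out.index) == ["gA"]
        assert out.attrs["dropped_probes"] == 1


class TestCombineSexes:
    def _values(self, male, female, tissue="head"):
        cols = pd.MultiIndex.from_tuples(
            [(tissue, "male", 1), (tissue, "male", 2), (tissue, "female", 1)],
            names=["tissue", "sex", "replicate"],
        )
        return pd.DataFrame([[male, male, female]], index=["g0"], columns=cols)

    def test_equal_weight_of_sexes(self):
        # male mean 4 (2 reps), female mean 8 (1 rep) -> 6, not the pooled mean
        out = ta.combine_sexes(self._values(4.0, 8.0))
        assert out.loc["g0", "head"] == pytest.approx(6.0)

    def test_single_sex_tissue_keeps_that_sex(self):
        cols = pd.MultiIndex.from_tuples(
            [("testis", "male", 1), ("testis", "male", 2)],
            names=["tissue", "sex", "replicate"],
        )
        df = pd.DataFrame([[4.0, 6.0]], index=["g0"], columns=cols)
        assert ta.combine_sexes(df).loc["g0", "testis"] == pytest.approx(5.0)


class TestRelativeAbundance:
    def test_uniform_profile(self):
        mat = pd.DataFrame([[2.0] * 6], index=["g0"])
        np.testing.assert_allclose(ta.relative_abundance(mat).loc["g0"], [1 / 6] * 6)

    def test_single_tissue_profile(self):
        mat = pd.DataFrame([[0.0, 10.0, 0.0]], index=["g0"])
        np.testing.assert_allclose(ta.relative_abundance(mat).loc["g0"], [0, 1, 0])

    def test_rows_sum_to_one_and_zero_rows_listed(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.uniform(0, 5, (20, 6)))
        mat.iloc[3] = 0.0
        ra = ta.relative_abundance(mat)
        np.testing.assert_allclose(ra.sum(axis=1), 1.0)
        assert ra.attrs["excluded"] == [3]

    def test_log2_scale_unlogs_first(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["g0"])  # linear 2, 4
        np.testing.assert_allclose(ta.relative_abundance(mat, scale="log2").loc["g0"], [1 / 3, 2 / 3])

    def test_negative_linear_is_error(self):
        with pytest.raises(ValueError):
            ta.relative_abundance(pd.DataFrame([[-1.0, 2.0]]))


class TestCoexpressionClusters:
    def test_planted_blocks_recovered(self):
        ocfg = ta.OrthologSimConfig(
            n_pairs=240, n_clusters=3, cluster_size=60, within_r=0.9,
            diverged_fraction=1.0, seed=11,
        )
        ag, _, _, truth = ta.simulate_orthologs(ocfg)
        ra = ta.relative_abundance(ag.loc[truth.gene_ag])
        cs = ta.gene_coexpression_clusters(ra, 0.8, 50)
        assert len(cs.clusters) == 3
        assert all(c.mean_correlation > 0.8 and c.size > 50 for c in cs.clusters)
        assignment = {g: i for i, c in enumerate(cs.clusters) for g in c.genes}
        tr = truth.set_index("gene_ag")
        correct = total = 0
        for block in range(3):
            members = tr.index[tr.cluster_id == block]
            labels = [assignment.get(g, -1) for g in members]
            best = max(set(labels), key=labels.count)
            correct += sum(1 for l in labels if l == best and l != -1)
            total += len(members)
        assert correct / total >= 0.95

    def test_huge_min_size_gives_no_clusters(self):
        rng = np.random.default_rng(1)
        ra = ta.relative_abundance(pd.DataFrame(rng.uniform(0.1, 1, (60, 5))))
        cs = ta.gene_coexpression_clusters(ra, 0.8, min_size=10**6)
        assert cs.clusters == []

    def test_exactly_min_size_cluster_excluded(self):
        # a perfect 50-gene block fails the strict "> 50" rule
        rng = np.random.default_rng(2)
        base = np.array([10.0, 1, 1, 1, 1, 1])
        block = base + rng.normal(0, 0.05, (50, 6))
        noise = rng.uniform(0.1, 1, (10, 6))
        ra = ta.relative_abundance(pd.DataFrame(np.vstack([block, noise])))
        cs = ta.gene_coexpression_clusters(ra, 0.8, min_size=50)
        assert all(set(c.genes) != set(range(50)) for c in cs.clusters)
        cs49 = ta.gene_coexpression_clusters(ra, 0.8, min_size=49)
        assert any(set(c.genes) >= set(range(50)) for c in cs49.clusters)

    def test_constant_profiles_excluded_with_tally(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.uniform(0.1, 1, (30, 5)))
        mat.iloc[5] = 0.2  # constant RA row after normalization
        ra = ta.relative_abundance(mat)
        cs = ta.gene_coexpression_clusters(ra, 0.8, 5)
        assert 5 in cs.excluded_constant

    def test_clusters_are_disjoint(self):
        ag, _, _, truth = ta.simulate_orthologs(ta.OrthologSimConfig(seed=4))
        ra = ta.relative_abundance(ag.loc[truth.gene_ag])
        cs = ta.gene_coexpression_clusters(ra, 0.8, 20)
        all_genes = list(itertools.chain.from_iterable(c.genes for c in cs.clusters))
        assert len(all_genes) == len(set(all_genes))


def oracle_hypergeom_tail(k, N, m, n):
    """Full enumeration of the upper tail for small N."""
    return sum(
        comb(m, i, exact=True) * comb(N - m, n - i, exact=True)
        for i in range(k, min(m, n) + 1)
    ) / comb(N, n, exact=True)


class TestClusterOverlap:
    def _sets(self, clusters_a, clusters_b, universe_a, universe_b):
        def mk(clusters, universe):
            cl = [
                ta.GeneCluster(list(genes), pd.Series(dtype=float), 1.0)
                for genes in clusters
            ]
            used = {g for c in cl for g in c.genes}
            return ta.GeneClusterSet(cl, list(universe), [g for g in universe if g not in used])

        return mk(clusters_a, universe_a), mk(clusters_b, universe_b)

    def test_extreme_tail_closed_form(self):
        ua = [f"a{i}" for i in range(100)]
        ub = [f"b{i}" for i in range(100)]
        pairs = list(zip(ua, ub))
        sa, sb = self._sets([ua[:10]], [ub[:10]], ua, ub)
        res = ta.cluster_overlap(sa, sb, pairs)
        assert res.loc[0, "overlap"] == 10
        assert res.loc[0, "p_value"] == pytest.approx(1 / comb(100, 10, exact=True))

    def test_zero_overlap_gives_p_one(self):
        ua = [f"a{i}" for i in range(40)]
        ub = [f"b{i}" for i in range(40)]
        pairs = list(zip(ua, ub))
        sa, sb = self._sets([ua[:10]], [ub[20:30]], ua, ub)
        res = ta.cluster_overlap(sa, sb, pairs)
        assert res.loc[0, "p_value"] == 1.0

    def test_matches_enumeration_for_small_universe(self):
        for N, m, n, k in [(20, 6, 8, 3), (30, 10, 10, 5), (12, 4, 6, 2)]:
            ua = [f"a{i}" for i in range(N)]
            ub = [f"b{i}" for i in range(N)]
            pairs = list(zip(ua, ub))
            # overlap k: cluster B takes k genes from A's cluster and n-k outside
            cb = ub[:k] + ub[m : m + (n - k)]
            sa, sb = self._sets([ua[:m]], [cb], ua, ub)
            res = ta.cluster_overlap(sa, sb, pairs)
            assert res.loc[0, "p_value"] == pytest.approx(
                oracle_hypergeom_tail(k, N, m, n), rel=1e-12
            )

    def test_matches_permutation_oracle(self):
        N, m, n, k = 100, 10, 10, 5
        rng = np.random.default_rng(5)
        p_exact = float(hypergeom.sf(k - 1, N, m, n))
        hits = 0
        shuffles = 10000
        b_set = set(range(n))
        for _ in range(shuffles):
            perm = rng.permutation(N)[:m]
            if sum(1 for x in perm if x in b_set) >= k:
                hits += 1
        p_mc = hits / shuffles
        se = np.sqrt(p_exact * (1 - p_exact) / shuffles)
        assert abs(p_mc - p_exact) <= 3 * se

    def test_planted_clusters_all_significant_when_fully_conserved(self):
        ocfg = ta.OrthologSimConfig(
            n_pairs=240, n_clusters=3, cluster_size=60, diverged_fraction=0.0, seed=6
        )
        ag, dm, fams, truth = ta.simulate_orthologs(ocfg)
        pairs = list(zip(truth.gene_ag, truth.gene_dm))
        ra_a = ta.relative_abundance(ag.loc[truth.gene_ag])
        ra_b = ta.relative_abundance(dm)
        sa = ta.gene_coexpression_clusters(ra_a, 0.8, 50)
        sb = ta.gene_coexpression_clusters(ra_b, 0.8, 50)
        res = ta.cluster_overlap(sa, sb, pairs)
        strong = res[res.band == "p<0.01"]
        # every planted block matches exactly one partner cluster, nothing else
        assert len(strong) == 3
        assert (res.loc[~res.index.isin(strong.index), "band"] == "ns").all()

    def test_empty_universe_is_error(self):
        sa, sb = self._sets([["a0"]], [["b0"]], ["a0"], ["b0"])
        with pytest.raises(ValueError):
            ta.cluster_overlap(sa, sb, [])


class TestTissueDendrogram:
    def test_near_points_merge_first(self):
        mat = pd.DataFrame(
            [[0.0, 0.0], [0.0, 1.0], [10.0, 10.0]], index=["a", "b", "c"]
        )
        tree = ta.tissue_dendrogram(mat)
        first_clade = next(iter(tree.clades()))[0]
        assert first_clade == frozenset({"a", "b"})

    def test_identical_items_merge_at_zero(self):
        mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=["a", "b", "c"])
        tree = ta.tissue_dendrogram(mat)
        clade, height = next(iter(tree.clades()))
        assert height == 0.0

    def test_ultrametric_distances_reproduced(self):
        # three points with pairwise distances 2, 2, 4 (ultrametric)
        mat = pd.DataFrame(
            [[0.0, 0.0], [2.0, 0.0], [1.0, np.sqrt(15)]], index=["a", "b", "c"]
        )
        tree = ta.tissue_dendrogram(mat)
        heights = sorted(h for _, h in tree.clades())
        assert heights[0] == pytest.approx(2.0)
        assert heights[1] == pytest.approx(4.0)

    def test_duplicate_labels_are_error(self):
        mat = pd.DataFrame([[0.0], [1.0]], index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            ta.tissue_dendrogram(mat)


class TestBootstrapSupport:
    def _two_groups(self, seed=7, n_features=100, sep=10.0, jitter=0.5):
        rng = np.random.default_rng(seed)
        base = np.array([[0.0] * n_features, [0.0] * n_features, [sep] * n_features, [sep] * n_features])
        x = base + rng.normal(0, jitter, base.shape)
        return pd.DataFrame(x, index=["a1", "a2", "b1", "b2"])

    def test_well_separated_groups_fully_supported(self):
        tree = ta.bootstrap_support(self._two_groups(), B=200, seed=8)
        assert all(s >= 0.99 for s in tree.supports.values())

    def test_supports_in_unit_interval(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(rng.normal(0, 1, (6, 30)), index=list("abcdef"))
        tree = ta.bootstrap_support(mat, B=100, seed=10)
        assert all(0.0 <= s <= 1.0 for s in tree.supports.values())

    def test_seed_determinism(self):
        mat = self._two_groups(seed=11, jitter=2.0)
        t1 = ta.bootstrap_support(mat, B=100, seed=12)
        t2 = ta.bootstrap_support(mat, B=100, seed=12)
        assert t1.supports == t2.supports

    def test_small_b_is_error(self):
        with pytest.raises(ValueError):
            ta.bootstrap_support(self._two_groups(), B=50, seed=0)

    def test_homologous_tissues_group_across_species(self):
        # high planted conservation: the tree pairs the same tissue of the two
        # species before unrelated tissues
        ocfg = ta.OrthologSimConfig(
            n_pairs=200, n_clusters=0, cluster_size=2, diverged_fraction=0.0, seed=13
        )
        ag, dm, _, truth = ta.simulate_orthologs(ocfg)
        ra_a = ta.relative_abundance(ag.loc[truth.gene_ag]).T
        ra_b = ta.relative_abundance(dm).T
        ra_b.columns = ra_a.columns  # orthologue pairing aligns the gene axes
        both = pd.concat(
            [ra_a.rename(index=lambda t: f"Ag:{t}"), ra_b.rename(index=lambda t: f"Dm:{t}")]
        )
        tree = ta.tissue_dendrogram(both)
        clades = [c for c, _ in tree.clades()]
        for tissue in ra_a.index:
            assert frozenset({f"Ag:{tissue}", f"Dm:{tissue}"}) in clades


class TestFamilies:
    def _fam(self, species_genes):
        members = frozenset(
            (sp, f"{sp.lower()}{i}") for sp, n in species_genes.items() for i in range(n)
        )
        return OrthoFamily("famX", members)

    @pytest.mark.parametrize(
        "species, expected",
        [
            ({"Ag": 1, "Dm": 1}, "Diptera"),
            ({"Ag": 1, "Dm": 1, "Tc": 1}, "Coleoptera"),
            ({"Ag": 1, "Dm": 1, "Tc": 1, "Am": 1}, "Hymenoptera"),
            ({"Ag": 1, "Dm": 1, "Tc": 1, "Am": 1, "Ce": 1}, "Metazoa"),
            ({"Ag": 1, "Ce": 1}, "Metazoa"),
        ],
    )
    def test_origin_precedence(self, species, expected):
        assert ta.family_origin(self._fam(species)) == expected

    def test_origin_requires_dipteran_member(self):
        with pytest.raises(ValueError):
            ta.family_origin(self._fam({"Tc": 1, "Ce": 1}))

    @pytest.mark.parametrize("n_ag, expected", [(1, "single_copy"), (3, "expanded")])
    def test_copy_classification(self, n_ag, expected):
        assert ta.classify_family_copies(self._fam({"Ag": n_ag, "Dm": 1})) == expected

    def test_copy_classification_needs_ag(self):
        with pytest.raises(ValueError):
            ta.classify_family_copies(self._fam({"Dm": 2}))

    def test_relation_labels(self):
        assert self._fam({"Ag": 1, "Dm": 1}).relation == "one-to-one"
        assert self._fam({"Ag": 2, "Dm": 1}).relation == "one-to-many"
        assert self._fam({"Ag": 2, "Dm": 3}).relation == "many-to-many"


class TestNarrowFamilyReport:
    def _tau(self, rows):
        return pd.DataFrame(rows, columns=["gene", "tau", "peak_tissue"])

    def test_rules(self):
        fams = [
            OrthoFamily("f1", frozenset({("Ag", "a1"), ("Ag", "a2"), ("Dm", "d1")})),
            OrthoFamily("f2", frozenset({("Ag", "a3"), ("Dm", "d2")})),
            OrthoFamily("f3", frozenset({("Ag", "a4"), ("Dm", "d3")})),
        ]
        tau_ag = self._tau(
            [("a1", 1.0, "gonad"), ("a2", 0.5, "head"), ("a3", 0.9, "head"), ("a4", 0.9, "head")]
        )
        tau_dm = self._tau([("d1", 1.0, "gonad"), ("d2", 0.9, "head"), ("d3", 0.9, "gut")])
        table_a, table_b = ta.narrow_family_report(fams, tau_ag, tau_dm)
        # expanded family: only the tau=1 member is counted, under its peak tissue
        assert list(table_a.gene) == ["a1"]
        assert list(table_a.peak_tissue) == ["gonad"]
        # single-copy: both narrow and same peak -> f2 in; different peaks -> f3 out
        assert list(table_b.family_id) == ["f2"]

    def test_mismatched_peaks_excluded(self):
        fams = [OrthoFamily("f1", frozenset({("Ag", "a1"), ("Dm", "d1")}))]
        table_a, table_b = ta.narrow_family_report(
            fams,
            self._tau([("a1", 0.95, "head")]),
            self._tau([("d1", 0.95, "gonad")]),
        )
        assert table_b.empty
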