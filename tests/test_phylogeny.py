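import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_min_changes
from ychron.formats import FormatError, HaplotypeMatrix, Site
from ychron.phylogeny import (build_tree, identical_groups,
                              mutations_to_root, place_recurrent, polarize)
from ychron.synthetic import SimConfig, sim_genealogy, sim_snps, \
    simulate_dataset


def matrix_from_patterns(samples, patterns):
    """Helper: one site per derived-carrier pattern (list of sample names)."""
    sites = [Site("Y", j + 1, "A", "G") for j in range(len(patterns))]
    calls = np.zeros((len(samples), len(patterns)), dtype=np.int8)
    for j, pat in enumerate(patterns):
        for s in pat:
            calls[samples.index(s), j] = 1
    return HaplotypeMatrix(samples, sites, calls,
                           np.ones(len(patterns), dtype=bool))


class TestPolarize:
    def test_flip_when_outgroup_carries_alt(self):
        m = matrix_from_patterns(["S1", "S2", "OG"], [["S1", "OG"]])
        out = polarize(m, "outgroup:OG")
        # outgroup carries alt => alt is ancestral => S2 becomes derived
        assert out.sample_ids == ["S1", "S2"]
        assert out.calls[:, 0].tolist() == [0, 1]
        assert out.ancestral_known.all()

    def test_identity_when_ref_is_ancestral(self):
        m = matrix_from_patterns(["S1", "S2"], [["S1"]])
        out = polarize(m, "ref-is-ancestral")
        assert np.array_equal(out.calls, m.calls)

    def test_outgroup_missing_call_flags_site(self):
        m = matrix_from_patterns(["S1", "S2", "OG"], [["S1"], ["S2"]])
        m.calls[2, 1] = -1
        out = polarize(m, "outgroup:OG")
        assert out.ancestral_known.tolist() == [True, False]

    def test_ancestral_table_recovers_simulated_truth(self, small_dataset):
        # simulator emits derived-coded calls with ref ancestral; scramble
        # half the sites to alt-ancestral coding and polarize back
        m = small_dataset.matrix
        rng = np.random.default_rng(0)
        flip = rng.random(m.n_sites) < 0.5
        calls = m.calls.copy()
        calls[:, flip] = 1 - calls[:, flip]
        sites = [Site(s.chrom, s.pos, s.alt, s.ref) if f else s
                 for s, f in zip(m.sites, flip)]
        scrambled = HaplotypeMatrix(m.sample_ids, sites, calls)
        anc = {s2.site_id: s1.ref
               for s1, s2 in zip(m.sites, sites)}
        out = polarize(scrambled, anc)
        assert out.ancestral_known.all()
        assert np.array_equal(out.calls, m.calls)


class TestBuildTree:
    def test_worked_laminar_family(self, worked_matrix):
        tree, report = build_tree(worked_matrix)
        assert report.table["compatible"].all()
        assert report.total_events == 4
        by_clade = {
            frozenset(tree.clade_samples(n.id)): n.n_mut
            for n in tree.preorder() if n.parent is not None}
        assert by_clade[frozenset({"S1", "S2"})] == 1
        assert by_clade[frozenset({"S3", "S4"})] == 2
        assert by_clade[frozenset({"S1"})] == 1

    def test_incompatible_site_placed_by_parsimony(self, worked_matrix):
        m = worked_matrix
        extra = Site("Y", 5, "A", "G")
        calls = np.c_[m.calls, np.array([0, 1, 1, 0], dtype=np.int8)]
        m5 = HaplotypeMatrix(m.sample_ids, list(m.sites) + [extra], calls,
                             np.ones(5, dtype=bool))
        tree, report = build_tree(m5)
        row = report.table.loc[extra.site_id]
        assert not row["compatible"] and row["n_events"] == 2
        assert report.total_events == 6
        assert tree.total_events() == 6

    def test_singleton_only_matrix_gives_star(self):
        samples = [f"S{i}" for i in range(6)]
        m = matrix_from_patterns(samples, [[s] for s in samples])
        tree, report = build_tree(m)
        assert all(n.parent == tree.root for n in tree.tips())
        assert mutations_to_root(tree).tolist() == [1] * 6

    def test_identical_haplotypes_share_node_via_zero_branches(self):
        m = matrix_from_patterns(["A", "B", "C"], [["A", "B"]])
        tree, _ = build_tree(m)
        ta, tb = tree.tip_by_sample("A"), tree.tip_by_sample("B")
        assert ta.parent == tb.parent and ta.n_mut == tb.n_mut == 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(FormatError):
            build_tree(HaplotypeMatrix(
                [], [], np.zeros((0, 0), dtype=np.int8)))

    def test_missing_calls_rejected(self):
        m = matrix_from_patterns(["A", "B"], [["A"]])
        m.calls[1, 0] = -1
        with pytest.raises(FormatError, match="missing"):
            build_tree(m)

    def test_perfect_phylogeny_roundtrip_on_simulations(self):
        # rebuilding haplotypes from branch mutations reproduces the input
        for seed in range(12):
            ds = sim_snps(*_small_tree_and_config(seed))
            matrix = ds[0]
            tree, report = build_tree(matrix)
            assert report.table["compatible"].all()
            rebuilt = _haplotypes_from_tree(tree, matrix)
            assert np.array_equal(rebuilt, matrix.calls)

    def test_branch_sum_equals_tip_path_mean(self):
        from ychron.dating_snp import rho_sigma
        for seed in range(10):
            ds = simulate_dataset(SimConfig(seed=seed + 100, n=12))
            tree, _ = build_tree(ds.matrix)
            rho, _ = rho_sigma(tree)
            assert rho == pytest.approx(
                mutations_to_root(tree).mean(), abs=1e-9)


def _small_tree_and_config(seed):
    cfg = SimConfig(seed=seed, n=8, genealogy="star",
                    star_depth_years=20_000.0)
    return sim_genealogy(cfg), cfg


def _haplotypes_from_tree(tree, matrix):
    col = {s: j for j, s in enumerate(matrix.site_ids)}
    out = np.zeros_like(matrix.calls)
    for node in tree.preorder():
        if node.parent is None:
            continue
        rows = [matrix.sample_index(s)
                for s in tree.clade_samples(node.id)]
        for m in node.mutations:
            out[rows, col[m.site_id]] ^= 1
    return out


class TestPlaceRecurrent:
    def test_existing_clade_needs_one_event(self, worked_tree):
        count, placement, back = place_recurrent(worked_tree, {"S3", "S4"})
        assert count == 1 and not back

    def test_disjoint_tips_need_two_events(self, worked_tree):
        count, placement, back = place_recurrent(worked_tree, {"S2", "S3"})
        assert count == 2
        assert {p for p, _ in placement} == {"S2", "S3"}

    def test_clade_complement_flags_back_mutation(self, worked_tree):
        count, placement, back = place_recurrent(
            worked_tree, {"S2", "S3", "S4"}, root_state=None)
        assert count == 1 and back
        assert placement == [("S1", True)]

    def test_unknown_tip_rejected(self, worked_tree):
        with pytest.raises(KeyError):
            place_recurrent(worked_tree, {"S1", "nope"})

    @pytest.mark.parametrize("root_state", [0, None])
    def test_matches_exhaustive_parsimony_small_trees(self, root_state):
        rng = np.random.default_rng(42)
        for rep in range(30):
            n = int(rng.integers(4, 9))
            cfg = SimConfig(seed=1000 + rep, n=n)
            tree = sim_genealogy(cfg)
            tips = [t.sample_id for t in tree.tips()]
            k = int(rng.integers(1, n + 1))
            carriers = set(rng.choice(tips, size=k, replace=False))
            count, placement, _ = place_recurrent(tree, carriers,
                                                  root_state=root_state)
            assert count == brute_force_min_changes(tree, carriers,
                                                    root_state)
            assert len(placement) == count


class TestMutationsToRoot:
    def test_worked_tree_path_sums(self, worked_tree):
        assert dict(mutations_to_root(worked_tree)) == {
            "S1": 2, "S2": 1, "S3": 2, "S4": 2}

    def test_simulated_counts_match_truth_log(self):
        ds = simulate_dataset(SimConfig(seed=5, n=50))
        tree, _ = build_tree(ds.matrix)
        counts = mutations_to_root(tree)
        truth = ds.event_log.groupby("branch").size()
        # true per-tip tally: events on the tip's root path in the true tree
        for tip in ds.tree.tips():
            path = [n.id for n in ds.tree.path_to_root(tip.id)]
            expected = int(truth.reindex(path).fillna(0).sum())
            assert counts[tip.sample_id] == expected


class TestIdenticalGroups:
    def test_duplicated_rows_form_one_pair(self):
        m = matrix_from_patterns(["A", "B", "C", "D"],
                                 [["A", "B"], ["C"]])
        rep = identical_groups(m)
        assert rep.groups == [["A", "B"]]
        assert rep.n_pairs == 1 and rep.n_classes == 3

    def test_str_subset_changes_resolution(self):
        prof = pd.DataFrame(
            {"DYS19": [14, 14], "DYS576": [17, 18], "DYS390": [22, 22]},
            index=["X", "Y"])
        from ychron.formats import STRProfileTable
        table = STRProfileTable(prof, subsets={
            "set21": ["DYS19", "DYS576", "DYS390"],
            "set17": ["DYS19", "DYS390"]})
        assert identical_groups(table, "set21").groups == []
        assert identical_groups(table, "set17").groups == [["X", "Y"]]

    def test_simulated_forced_duplicate_recovered(self, small_dataset):
        m = small_dataset.matrix
        calls = m.calls.copy()
        calls[1] = calls[0]  # force the first two rows identical
        dup = HaplotypeMatrix(m.sample_ids, m.sites, calls,
                              m.ancestral_known)
        rep = identical_groups(dup)
        forced = sorted(m.sample_ids[:2])
        assert sorted(map(sorted, rep.groups)) == [forced]

    def test_snp_differences_reported_for_str_groups(self, small_dataset):
        rep = identical_groups(small_dataset.strs, "set13",
                               matrix=small_dataset.matrix)
        for (a, b), d in (rep.snp_differences or {}).items():
            ra = small_dataset.matrix.calls[
                small_dataset.matrix.sample_index(a)]
            rb = small_dataset.matrix.calls[
                small_dataset.matrix.sample_index(b)]
            assert d == int((ra != rb).sum())
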