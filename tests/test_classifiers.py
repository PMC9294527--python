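import numpy as np
import pytest

from musselid.classifiers import (
    AMBIGUOUS,
    NO_MATCH,
    PUTATIVE_HYBRID,
    AbgdParams,
    BcmThreshold,
    ab_classify,
    abgd_partition,
    annotate_support,
    bcm_classify,
    bcm_threshold,
    bootstrap_support,
    dsc_classify,
    evaluate_method,
    fins_classify,
    nj_tree,
    tree_bipartitions,
)
from musselid.classifiers.evaluate import calls_ab, calls_bcm, summarize_calls
from musselid.distances import DistanceMatrix, SitePolicy, distance_matrix
from musselid.seqio import AlignedSet, BarcodeRecord
from musselid.synthetic import SimConfig, simulate_dataset


def _mutate(seq, positions, subs="G"):
    out = list(seq)
    for pos in positions:
        out[pos] = subs if out[pos] != subs else "C"
    return "".join(out)


def _two_species_toy(n_sites=100, divergence=10, rng_seed=0):
    """Two clean species: refs identical within species, fixed differences between."""
    rng = np.random.default_rng(rng_seed)
    base = "".join(rng.choice(list("ACGT"), size=n_sites))
    other = _mutate(base, rng.choice(n_sites, size=divergence, replace=False))
    recs = [BarcodeRecord(f"a{i}", base, label="spA") for i in range(3)]
    recs += [BarcodeRecord(f"b{i}", other, label="spB") for i in range(3)]
    return AlignedSet(recs), base, other


class TestDsc:
    def test_clear_case_assigns_species(self):
        aln, base, other = _two_species_toy()
        query = BarcodeRecord("q", base)
        res = dsc_classify(query, aln, threshold_pct=98.0)
        assert res.call == "spA"

    def test_two_qualifying_species_is_ambiguous(self):
        # query equally similar (>99 %) to both species' references
        aln, base, other = _two_species_toy(n_sites=400, divergence=2)
        query = BarcodeRecord("q", base)
        res = dsc_classify(query, aln, threshold_pct=99.0)
        assert res.call == AMBIGUOUS

    def test_no_species_above_threshold_is_no_match(self):
        aln, base, _ = _two_species_toy(n_sites=100, divergence=10)
        query = BarcodeRecord("q", _mutate(base, range(0, 30)))
        assert dsc_classify(query, aln).call == NO_MATCH

    def test_hybrid_flag_passes_through(self):
        aln, base, _ = _two_species_toy()
        query = BarcodeRecord("q", base)
        res = dsc_classify(query, aln, hybrid_flagged=True)
        assert res.call == PUTATIVE_HYBRID

    def test_reference_panel_required(self):
        unlabelled = AlignedSet([BarcodeRecord("r", "ACGT")])
        with pytest.raises(ValueError):
            dsc_classify(BarcodeRecord("q", "ACGT"), unlabelled)

    def test_dataset2_like_set_fully_correct_at_99(self):
        cfg = SimConfig(n_A=8, n_B=8, n_hybrids=0,
                        intraspecific_theta=0.001, seed=2020)
        aln, _ = simulate_dataset(cfg)
        for rec in aln:
            res = dsc_classify(rec, aln, threshold_pct=99.0)
            assert res.call == rec.label


class TestBcmThreshold:
    def test_identical_conspecific_references_give_zero(self):
        recs = [BarcodeRecord(f"r{i}", "ACGT" * 25, label="sp") for i in range(3)]
        thr = bcm_threshold(AlignedSet(recs))
        assert thr.value == 0.0
        assert thr.n_intraspecific_pairs == 3

    def test_matches_direct_percentile_oracle(self, paperlike):
        aln, _, _ = paperlike
        dm = distance_matrix(aln, model="K2P")
        thr = bcm_threshold(aln, dm=dm)
        intra = [
            dm.pair(a.id, b.id)
            for i, a in enumerate(aln.records)
            for b in aln.records[i + 1:]
            if a.label == b.label
        ]
        assert thr.value == pytest.approx(
            100 * np.percentile(intra, 95, method="linear")
        )
        assert thr.n_intraspecific_pairs == len(intra)

    def test_percentile_interpolation_on_ladder(self):
        # distances 0.1..2.0 % -> 95th percentile 1.905 % (linear rule)
        ladder = np.arange(0.1, 2.01, 0.1)
        assert np.percentile(ladder, 95, method="linear") == pytest.approx(1.905)

    def test_no_intraspecific_pair_is_an_error(self):
        recs = [BarcodeRecord("a", "ACGT", label="sp1"),
                BarcodeRecord("b", "ACGT", label="sp2")]
        with pytest.raises(ValueError, match="intraspecific"):
            bcm_threshold(AlignedSet(recs))


def _query_matrix(aln, query):
    return distance_matrix(AlignedSet(aln.records + [query]), model="K2P")


class TestBcmClassify:
    def test_close_conspecific_within_threshold(self):
        aln, base, _ = _two_species_toy()
        query = BarcodeRecord("q", _mutate(base, [0]))
        dm = _query_matrix(aln, query)
        thr = BcmThreshold(value=1.28, percentile=95, n_intraspecific_pairs=6, model="K2P")
        assert bcm_classify("q", aln, thr, dm).call == "spA"

    def test_equidistant_tie_across_species_is_ambiguous(self):
        # query exactly one transition from a spA and from a spB reference:
        # identical K2P distances, so the minimum is shared across species
        recs = [
            BarcodeRecord("a0", "A" * 99 + "G", label="spA"),
            BarcodeRecord("b0", "A" * 98 + "GA", label="spB"),
        ]
        aln = AlignedSet(recs)
        query = BarcodeRecord("q", "A" * 100)
        dm = _query_matrix(aln, query)
        thr = BcmThreshold(value=5.0, percentile=95, n_intraspecific_pairs=1, model="K2P")
        assert bcm_classify("q", aln, thr, dm).call == AMBIGUOUS

    def test_beyond_threshold_is_no_match(self):
        aln, base, _ = _two_species_toy()
        query = BarcodeRecord("q", _mutate(base, range(0, 20)))
        dm = _query_matrix(aln, query)
        thr = BcmThreshold(value=1.28, percentile=95, n_intraspecific_pairs=6, model="K2P")
        assert bcm_classify("q", aln, thr, dm).call == NO_MATCH


class TestAbClassify:
    def _threshold(self, pct=5.0):
        return BcmThreshold(value=pct, percentile=95, n_intraspecific_pairs=6, model="K2P")

    def test_pure_conspecific_block_tops_the_list(self):
        aln, base, _ = _two_species_toy()
        query = BarcodeRecord("q", _mutate(base, [0]))
        dm = _query_matrix(aln, query)
        assert ab_classify("q", aln, self._threshold(), dm).call == "spA"

    def test_interleaved_heterospecific_is_ambiguous(self):
        # one spB reference sits between the query's spA references
        base = "A" * 100
        recs = [
            BarcodeRecord("a0", _mutate(base, [0]), label="spA"),
            BarcodeRecord("a1", _mutate(base, [0, 1, 2, 3, 4, 5]), label="spA"),
            BarcodeRecord("b0", _mutate(base, [10, 11]), label="spB"),
            BarcodeRecord("b1", _mutate(base, list(range(20, 40))), label="spB"),
        ]
        aln = AlignedSet(recs)
        query = BarcodeRecord("q", base)
        dm = _query_matrix(aln, query)
        assert ab_classify("q", aln, self._threshold(), dm).call == AMBIGUOUS

    def test_fewer_than_two_conspecific_references_is_no_match(self):
        base = "A" * 100
        recs = [
            BarcodeRecord("a0", _mutate(base, [0]), label="spA"),
            BarcodeRecord("b0", _mutate(base, list(range(10, 20))), label="spB"),
            BarcodeRecord("b1", _mutate(base, list(range(10, 21))), label="spB"),
        ]
        aln = AlignedSet(recs)
        query = BarcodeRecord("q", base)
        dm = _query_matrix(aln, query)
        assert ab_classify("q", aln, self._threshold(), dm).call == NO_MATCH

    def test_min_distance_beyond_threshold_is_no_match(self):
        aln, base, _ = _two_species_toy()
        query = BarcodeRecord("q", _mutate(base, range(0, 20)))
        dm = _query_matrix(aln, query)
        assert ab_classify("q", aln, self._threshold(1.0), dm).call == NO_MATCH

    def test_ab_correct_implies_bcm_correct(self, paperlike):
        aln, _, _ = paperlike
        policy = SitePolicy(ambiguity_match="mismatch")
        ab = calls_ab(aln, policy=policy)
        bcm = calls_bcm(aln, policy=policy)
        truth = {r.id: r.label for r in aln}
        for rid, call in ab.items():
            if call == truth[rid]:
                assert bcm[rid] == truth[rid]


class TestAbgd:
    def test_single_sequence_is_one_group(self):
        dm = DistanceMatrix(ids=["x"], values=np.zeros((1, 1)), model="K2P")
        part = abgd_partition(dm)
        assert part.groups == [["x"]] and not part.gap_found

    def test_clear_gap_recovers_species(self, clean_sim):
        aln, truth = clean_sim
        part = abgd_partition(distance_matrix(aln, model="K2P"))
        assert part.gap_found and part.n_groups == 2
        groups = [set(g) for g in part.groups]
        assert set(truth.ids_of("speciesA")) in groups
        assert set(truth.ids_of("speciesB")) in groups

    def test_trivial_partition_when_all_distances_below_prior(self):
        cfg = SimConfig(n_A=6, n_B=0, n_hybrids=0, intraspecific_theta=0.002,
                        interspecific_divergence=0.02, seed=3)
        aln, _ = simulate_dataset(cfg)
        dm = distance_matrix(aln, model="K2P")
        params = AbgdParams(prior_P=float(dm.condensed().max()) + 0.001)
        part = abgd_partition(dm, params)
        assert part.n_groups == 1 and not part.gap_found

    def test_hybrids_chain_the_species_into_one_group(self):
        cfg = SimConfig(intraspecific_theta=0.002, seed=2020)  # 7/42/12 shape
        aln, truth = simulate_dataset(cfg)
        part = abgd_partition(distance_matrix(aln, model="K2P"))
        assert part.n_groups == 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AbgdParams(prior_P=0.0)
        with pytest.raises(ValueError):
            AbgdParams(relative_gap_width_X=-1.0)


def _matrix_from_tree(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.distance(taxa[i], taxa[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values, model="p")


def _random_tree(n_taxa, seed):
    import random

    import dendropy

    rng = random.Random(seed)
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
        num_extant_tips=n_taxa, rng=rng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = rng.uniform(0.05, 1.0)
    # NJ reconstructs the unrooted tree; collapse the degree-2 root so the
    # reference branch lengths are comparable
    tree.deroot()
    tree.is_rooted = False
    return tree


def _edge_lengths_by_bipartition(tree):
    """Canonical (leafset side without the smallest label) -> branch length."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = min(labels)
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(labels - side)
        out[side] = round(node.edge.length or 0.0, 9)
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        values = np.array([[0.0, 0.3, 0.5],
                           [0.3, 0.0, 0.6],
                           [0.5, 0.6, 0.0]])
        dm = DistanceMatrix(ids=["a", "b", "c"], values=values, model="p")
        tree = nj_tree(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    @pytest.mark.parametrize("seed", range(5))
    def test_additive_matrices_recover_generating_tree(self, n_taxa, seed):
        tree = _random_tree(n_taxa, seed)
        dm = _matrix_from_tree(tree)
        rebuilt = nj_tree(dm)
        assert tree_bipartitions(rebuilt) == tree_bipartitions(tree)
        # leaf branch lengths are also recovered on additive input
        want = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        got = {lf.taxon.label: lf.edge.length for lf in rebuilt.leaf_node_iter()}
        for label in want:
            assert got[label] == pytest.approx(want[label], abs=1e-9)

    def test_topology_matches_scikit_bio(self):
        import skbio

        rng = np.random.default_rng(8)
        n = 7
        noise = rng.uniform(0, 0.02, size=(n, n))
        values = _matrix_from_tree(_random_tree(n, 123)).values + noise + noise.T
        values = (values + values.T) / 2.0  # exact symmetry for both consumers
        np.fill_diagonal(values, 0.0)
        ids = [f"t{i}" for i in range(n)]
        mine = nj_tree(DistanceMatrix(ids=ids, values=values, model="p"))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(values, ids))
        from musselid.seqio import read_newick

        skbio_tree = read_newick(str(theirs))
        assert tree_bipartitions(mine) == tree_bipartitions(skbio_tree)

    def test_record_order_invariance(self):
        tree = _random_tree(6, 42)
        dm = _matrix_from_tree(tree)
        perm = [3, 0, 5, 1, 4, 2]
        ids = [dm.ids[i] for i in perm]
        dm_perm = DistanceMatrix(
            ids=ids, values=dm.values[np.ix_(perm, perm)], model="p"
        )
        assert _edge_lengths_by_bipartition(nj_tree(dm)) == _edge_lengths_by_bipartition(
            nj_tree(dm_perm)
        )

    def test_non_finite_distance_rejected(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            nj_tree(DistanceMatrix(ids=list("abc"), values=values, model="p"))


class TestBootstrap:
    def _clade_alignment(self):
        rng = np.random.default_rng(21)
        base = "".join(rng.choice(list("ACGT"), size=300))
        other = _mutate(base, rng.choice(300, size=30, replace=False))
        recs = []
        for i in range(4):
            recs.append(BarcodeRecord(f"a{i}", _mutate(base, [i]), label="spA"))
        for i in range(4):
            recs.append(BarcodeRecord(f"b{i}", _mutate(other, [100 + i]), label="spB"))
        return AlignedSet(recs)

    def test_clear_split_gets_high_support(self):
        aln = self._clade_alignment()
        tree, supports = bootstrap_support(aln, model="K2P", replicates=100, seed=5)
        central = frozenset(f"b{i}" for i in range(4))
        assert supports[central] >= 95.0

    def test_same_seed_same_supports(self):
        aln = self._clade_alignment()
        _, s1 = bootstrap_support(aln, replicates=30, seed=9)
        _, s2 = bootstrap_support(aln, replicates=30, seed=9)
        assert s1 == s2

    def test_identical_sequences_yield_unsupported_resolution(self):
        recs = [BarcodeRecord(f"r{i}", "ACGT" * 30) for i in range(5)]
        tree, supports = bootstrap_support(AlignedSet(recs), replicates=20, seed=1)
        assert all(0.0 <= v <= 100.0 for v in supports.values())

    def test_annotate_support_writes_node_labels(self):
        aln = self._clade_alignment()
        tree, supports = bootstrap_support(aln, replicates=20, seed=2)
        annotate_support(tree, supports)
        labels = [
            node.label
            for node in tree.preorder_node_iter()
            if not node.is_leaf() and node.parent_node is not None and node.label
        ]
        assert labels  # at least the central split carries a support label


class TestFins:
    def _setup(self):
        aln = TestBootstrap()._clade_alignment()
        tree, supports = bootstrap_support(aln, model="K2P", replicates=50, seed=3)
        labels = {rec.id: rec.label for rec in aln}
        return tree, supports, labels

    def test_query_in_supported_pure_clade_gets_species(self):
        tree, supports, labels = self._setup()
        refs = {k: v for k, v in labels.items() if k != "b0"}
        res = fins_classify(tree, supports, "b0", refs, min_support=70.0)
        assert res.call == "spB"

    def test_unsupported_or_mixed_clade_is_ambiguous(self):
        tree, supports, labels = self._setup()
        refs = {k: v for k, v in labels.items() if k != "b0"}
        res = fins_classify(tree, supports, "b0", refs, min_support=100.1)
        assert res.call == AMBIGUOUS

    def test_mixed_species_clade_is_ambiguous(self):
        tree, supports, labels = self._setup()
        mislabelled = dict(labels)
        for k in mislabelled:
            mislabelled[k] = "spA" if k in ("b1", "a0") else "spB"
        res = fins_classify(tree, supports, "b0",
                            {k: v for k, v in mislabelled.items() if k != "b0"})
        assert res.call == AMBIGUOUS

    def test_missing_query_is_an_error(self):
        tree, supports, labels = self._setup()
        with pytest.raises(ValueError, match="not in tree"):
            fins_classify(tree, supports, "zz", labels)


class TestEvaluateMethod:
    def test_perfect_classifiers_on_clean_data(self, clean_sim):
        aln, _ = clean_sim
        for method in ("DSC", "BCM", "AB"):
            summary = evaluate_method(method, aln)
            assert summary.pct_correct == 100.0
            assert summary.n == len(aln)

    def test_counts_back_sum_to_n(self, paperlike):
        aln, _, _ = paperlike
        summary = evaluate_method("BCM", aln,
                                  policy=SitePolicy(ambiguity_match="mismatch"))
        assert summary.n_correct + summary.n_ambiguous + summary.n_incorrect == summary.n
        total = summary.pct_correct + summary.pct_ambiguous + summary.pct_incorrect
        assert total == pytest.approx(100.0, abs=0.15)  # three 1-decimal roundings

    def test_unknown_method_rejected(self, clean_sim):
        aln, _ = clean_sim
        with pytest.raises(ValueError, match="unknown method"):
            evaluate_method("HRM", aln)
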