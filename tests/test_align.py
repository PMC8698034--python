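"""Module-architecture alignment, ortholog calls and inventory matching."""

from itertools import product

import pytest

from clusterline import (
    GeneratorConfig,
    align_clusters,
    compare_inventories,
    generate_cluster,
    generate_inventory,
    module_similarity,
    mutate_cluster,
    parse_orf_architecture,
    render_alignment,
    screen_for_ortholog,
)
from clusterline.config import DEFAULT_ALIGNMENT


def module_of(text):
    return parse_orf_architecture(text, "m").modules[0]


def brute_force_best_score(ref_mods, qry_mods, gap):
    """Enumerate every global alignment recursively (oracle for small n)."""

    def best(i, j):
        if i == len(ref_mods) and j == len(qry_mods):
            return 0.0
        options = []
        if i < len(ref_mods) and j < len(qry_mods):
            options.append(
                module_similarity(
                    ref_mods[i], qry_mods[j],
                    DEFAULT_ALIGNMENT.specificity_weight,
                )
                + best(i + 1, j + 1)
            )
        if i < len(ref_mods):
            options.append(-gap + best(i + 1, j))
        if j < len(qry_mods):
            options.append(-gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


class TestModuleSimilarity:
    def test_identity(self):
        a = module_of("KS/AT_m_/KR/ACP")
        assert module_similarity(a, a) == 1.0

    def test_one_domain_difference_is_jaccard(self):
        a = module_of("KS/AT_m_/DH/KR/ACP")
        b = module_of("KS/AT_m_/KR/ACP")
        assert module_similarity(a, b) == pytest.approx(4 / 5)

    def test_disjoint_chemistries(self):
        assert (
            module_similarity(module_of("KS/AT_m_/KR/ACP"), module_of("C/A_ser_/T"))
            == 0.0
        )

    def test_symmetry(self):
        a = module_of("KS/AT_m_/DH/ER/KR/ACP")
        b = module_of("KS/AT_mm_/KR/ACP")
        assert module_similarity(a, b) == module_similarity(b, a)

    def test_specificity_disagreement_penalized(self):
        a = module_of("KS/AT_m_/KR/ACP")
        b = module_of("KS/AT_mm_/KR/ACP")
        assert module_similarity(a, b) < 1.0
        # an unannotated AT matches either extender without penalty
        c = module_of("KS/AT/KR/ACP")
        assert module_similarity(a, c) == 1.0

    def test_loading_never_matches_extension(self):
        loading = module_of("CoL/ACP")
        ext = module_of("KS/AT_m_/ACP")
        assert module_similarity(loading, ext) == 0.0


class TestAlignClusters:
    def test_self_alignment_is_perfect(self, tp_a0316):
        cluster = tp_a0316.get("t1pks-2")
        aln = align_clusters(cluster, cluster)
        assert aln.ref_gaps == [] and aln.query_gaps == []
        assert aln.mean_similarity == 1.0
        assert aln.coverage == 1.0 and aln.query_coverage == 1.0
        assert aln.ortholog

    @pytest.mark.parametrize("strain", ["tp_a0316", "tp_a0468"])
    def test_qnm_reference_gap_at_module_4(self, qnm, strain, request):
        query = request.getfixturevalue(strain).get("t1pks-2")
        aln = align_clusters(qnm, query)
        assert aln.ref_gaps == ["4"]
        assert aln.query_gaps == []
        assert aln.ortholog

    def test_rendered_table_marks_absent_module(self, qnm, tp_a0316):
        aln = align_clusters(qnm, tp_a0316.get("t1pks-2"))
        table = render_alignment(qnm, tp_a0316.get("t1pks-2"), aln)
        gap_row = [l for l in table.splitlines() if l.startswith("4 ")]
        assert gap_row and gap_row[0].rstrip().endswith("-")

    def test_zero_module_cluster_is_usage_error(self, tp_a0316):
        t2 = tp_a0316.get("t2pks-1")
        with pytest.raises(ValueError):
            align_clusters(t2, tp_a0316.get("t1pks-2"))

    def test_score_symmetry(self):
        a = generate_cluster(GeneratorConfig(seed=5, n_modules=9), "t1pks", "a")
        b = generate_cluster(GeneratorConfig(seed=6, n_modules=7), "t1pks", "b")
        fwd = align_clusters(a, b)
        rev = align_clusters(b, a)
        assert fwd.score == pytest.approx(rev.score)
        assert len(fwd.ref_gaps) == len(rev.query_gaps)
        assert len(fwd.query_gaps) == len(rev.ref_gaps)

    def test_module_count_difference_bounds_gaps(self):
        for sa, sb in [(1, 2), (3, 4), (7, 8)]:
            a = generate_cluster(
                GeneratorConfig(seed=sa, n_modules=(4, 14)), "t1pks", "a"
            )
            b = generate_cluster(
                GeneratorConfig(seed=sb, n_modules=(4, 14)), "t1pks", "b"
            )
            aln = align_clusters(a, b)
            na = len(a.counted_modules())
            nb = len(b.counted_modules())
            assert len(aln.ref_gaps) + len(aln.query_gaps) >= abs(na - nb)

    @pytest.mark.parametrize("seed", range(20))
    def test_dp_matches_brute_force_enumeration(self, seed):
        kind = ("t1pks", "nrps", "pks_nrps")[seed % 3]
        a = generate_cluster(
            GeneratorConfig(seed=seed, n_modules=(2, 6)), kind, "a"
        )
        b = generate_cluster(
            GeneratorConfig(seed=seed + 100, n_modules=(2, 6)), kind, "b"
        )
        aln = align_clusters(a, b)
        oracle = brute_force_best_score(
            a.counted_modules(), b.counted_modules(),
            DEFAULT_ALIGNMENT.gap_penalty,
        )
        assert aln.score == pytest.approx(oracle)


class TestMutationRecovery:
    def test_single_deletion_recovers_at_position(self):
        parent = generate_cluster(
            GeneratorConfig(seed=42, n_modules=20), "t1pks", "parent"
        )
        config = GeneratorConfig(seed=9, mutation_rates=(0.15, 0.0, 0.0, 0.0))
        mutant, log = mutate_cluster(parent, config, max_indels=3)
        deleted = sorted(e[1] for e in log if e[0] == "delete_module")
        assert deleted
        aln = align_clusters(parent, mutant)
        assert len(aln.ref_gaps) == len(deleted)

    def test_deletion_localization_rate(self):
        """>= 95% of seeded deletion trials recover the exact indel set.

        'Exact' means removing the gapped reference positions from the
        parent reproduces the mutant's module sequence (tandem identical
        modules make the literal position degenerate).
        """
        hits = 0
        trials = 200
        for t in range(trials):
            parent = generate_cluster(
                GeneratorConfig(seed=10_000 + t, n_modules=(15, 25)),
                "t1pks",
                "parent",
            )
            config = GeneratorConfig(
                seed=t, mutation_rates=(0.12, 0.0, 0.0, 0.0)
            )
            mutant, log = mutate_cluster(parent, config, max_indels=3)
            deleted = {e[1] for e in log if e[0] == "delete_module"}
            if not deleted:
                hits += 1  # nothing to localize
                continue
            aln = align_clusters(parent, mutant)
            if len(aln.ref_gaps) != len(deleted):
                continue
            parent_mods = parent.counted_modules()
            labels = {m.index_label: i for i, m in enumerate(parent_mods)}
            gapped = {labels[g] for g in aln.ref_gaps}
            survivors = [
                m.notation()
                for i, m in enumerate(parent_mods)
                if i not in gapped
            ]
            if survivors == [m.notation() for m in mutant.counted_modules()]:
                hits += 1
        assert hits / trials >= 0.95


class TestInventoryComparison:
    def test_four_conserved_pairs_between_strains(self, tp_a0316, tp_a0468):
        comp = compare_inventories(tp_a0316, tp_a0468)
        pairs = {(a, b) for a, b, _ in comp.matched_pairs}
        assert pairs == {
            ("t1pks-2", "t1pks-2"),
            ("t3pks-1", "t3pks-1"),
            ("pks/nrps-2", "pks/nrps-2"),
            ("pks/nrps-3", "pks/nrps-3"),
        }

    def test_matching_is_one_to_one(self, tp_a0316, tp_a0468):
        comp = compare_inventories(tp_a0316, tp_a0468)
        a_side = [a for a, _, _ in comp.matched_pairs]
        b_side = [b for _, b, _ in comp.matched_pairs]
        assert len(set(a_side)) == len(a_side)
        assert len(set(b_side)) == len(b_side)
        assert set(comp.unmatched_a) | set(a_side) == {
            c.cluster_id for c in tp_a0316
        }

    def test_inventory_vs_itself_matches_everything_matchable(self, tp_a0316):
        comp = compare_inventories(tp_a0316, tp_a0316)
        matched = {(a, b) for a, b, _ in comp.matched_pairs}
        for ca, cb in matched:
            assert ca == cb
        # every cluster with alignable architecture matches itself
        assert ("t1pks-2", "t1pks-2") in matched
        assert ("nrps-5", "nrps-5") in matched
        assert ("t3pks-1", "t3pks-1") in matched

    def test_disjoint_random_inventories_share_nothing(self):
        inv_a = generate_inventory(
            GeneratorConfig(seed=101, n_modules=(3, 10)), 6, "SYN-A"
        )
        inv_b = generate_inventory(
            GeneratorConfig(seed=202, n_modules=(3, 10)), 6, "SYN-B"
        )
        comp = compare_inventories(inv_a, inv_b)
        for _, _, aln in comp.matched_pairs:
            # random same-chemistry clusters may collide only at
            # near-identity; none should pass the ortholog bar here
            assert aln.mean_similarity >= DEFAULT_ALIGNMENT.s_min
        assert len(comp.matched_pairs) == 0


class TestScreening:
    def test_both_strains_harbor_the_reference_ortholog(
        self, qnm, tp_a0316, tp_a0468
    ):
        results = screen_for_ortholog(qnm, [tp_a0316, tp_a0468])
        assert [r.present for r in results] == [True, True]
        assert [r.best_cluster_id for r in results] == ["t1pks-2", "t1pks-2"]

    def test_strain_without_matching_type_is_absent(self, qnm):
        inv = generate_inventory(
            GeneratorConfig(seed=77, n_modules=(2, 6)), 4, "SYN",
            kinds=("nrps",),
        )
        (result,) = screen_for_ortholog(qnm, [inv])
        assert not result.present
        assert result.best_cluster_id is None

    def test_seeded_panel_recall(self, qnm):
        """Presence calls exactly recover strains seeded with a mutated
        copy of the reference (<= 3 module indels) among decoys."""
        inventories = []
        truth = []
        for k in range(50):
            seeded = k % 2 == 0
            decoys = generate_inventory(
                GeneratorConfig(seed=500 + k, n_modules=(3, 10)),
                3,
                f"SYN-{k}",
            )
            if seeded:
                config = GeneratorConfig(
                    seed=k, mutation_rates=(0.06, 0.03, 0.05, 0.05)
                )
                mutant, _ = mutate_cluster(qnm, config, max_indels=3)
                mutant.cluster_id = f"qnm-copy-{k}"
                mutant.strain_id = decoys.strain_id
                decoys.clusters.append(mutant)
            inventories.append(decoys)
            truth.append(seeded)
        results = screen_for_ortholog(qnm, inventories)
        assert [r.present for r in results] == truth
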