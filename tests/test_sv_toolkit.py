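import numpy as np
import pytest

from strainvar.sv_toolkit import (
    SVCluster,
    StructuralVariant,
    cds_overlap,
    cross_strain_private_svs,
    filter_svs,
    merge_deletions,
    merge_insertions,
    read_sv_table,
    reciprocal_overlap,
    sensitivity_from_counts,
    validation_sensitivity,
    write_sv_table,
)
from strainvar.variant_model import GeneModel


def _del(start, end, chrom="chr1", strain="S1", caller="breakdancer"):
    return StructuralVariant(chrom=chrom, start=start, end=end, svtype="DEL",
                             strain=strain, caller=caller)


def _ins(pos, chrom="chr1", strain="S1", caller="breakdancer"):
    return StructuralVariant(chrom=chrom, start=pos, end=pos, svtype="INS",
                             strain=strain, caller=caller, ins_length=500)


def brute_force_ro(a, b):
    """Per-base set intersection oracle for reciprocal overlap."""
    if a[0] != b[0]:
        return 0.0
    sa = set(range(a[1], a[2] + 1))
    sb = set(range(b[1], b[2] + 1))
    ov = len(sa & sb)
    return min(ov / len(sa), ov / len(sb))


def brute_force_clusters(svs, related):
    """O(n^2) transitive closure over the merge relation."""
    n = len(svs)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if related(svs[i], svs[j]):
                adj[i].append(j)
                adj[j].append(i)
    seen, components = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x])
        seen |= comp
        components.append(frozenset(comp))
    return set(components)


def cluster_partition(svs, clusters):
    index = {id(sv): i for i, sv in enumerate(svs)}
    return {frozenset(index[id(m)] for m in cl.members) for cl in clusters}


class TestReciprocalOverlap:
    def test_identity(self):
        assert reciprocal_overlap(("chr1", 100, 199), ("chr1", 100, 199)) == 1.0

    def test_half_overlap(self):
        assert reciprocal_overlap(("chr1", 100, 199), ("chr1", 150, 249)) == 0.5

    def test_disjoint_and_cross_chromosome(self):
        assert reciprocal_overlap(("chr1", 100, 199), ("chr1", 300, 400)) == 0.0
        assert reciprocal_overlap(("chr1", 100, 199), ("chr2", 100, 199)) == 0.0

    def test_symmetry_random(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s1, s2 = rng.integers(1, 1000, size=2)
            a = ("chr1", int(s1), int(s1 + rng.integers(1, 500)))
            b = ("chr1", int(s2), int(s2 + rng.integers(1, 500)))
            assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)
            assert reciprocal_overlap(a, b) == pytest.approx(brute_force_ro(a, b))


class TestFilterSvs:
    GAPS = [("chr1", 10_000, 11_000)]
    TELO = [("chr1", 1, 5_000)]

    def test_near_gap_removed(self):
        # deletion ends 400 bp before the gap start
        sv = _del(9_000, 9_600)
        retained, rejected = filter_svs([sv], self.GAPS, [])
        assert retained == [] and "gap" in rejected[0].reason

    def test_far_from_telomere_retained(self):
        sv = _del(30_000, 31_000)  # 25 kb past the telomere end
        retained, rejected = filter_svs([sv], [], self.TELO)
        assert retained == [sv]

    def test_near_telomere_removed(self):
        sv = _del(20_000, 21_000)  # 15 kb from telomere end
        retained, rejected = filter_svs([sv], [], self.TELO)
        assert retained == [] and "telomere" in rejected[0].reason

    def test_oversized_removed(self):
        sv = _del(2_000_000, 3_500_000)
        retained, rejected = filter_svs([sv])
        assert retained == [] and "length" in rejected[0].reason

    def test_distance_arithmetic_against_brute_force(self):
        rng = np.random.default_rng(1)
        gaps = [("chr1", 50_000, 51_000)]
        for _ in range(100):
            s = int(rng.integers(40_000, 60_000))
            sv = _del(s, s + int(rng.integers(200, 2_000)))
            retained, _ = filter_svs([sv], gaps, [])
            bases = set(range(sv.start - 500, sv.end + 501))
            overlaps = bool(bases & set(range(50_000, 51_001)))
            assert (retained == []) == overlaps


class TestMergeDeletions:
    def test_identical_calls_three_callers(self):
        svs = [_del(1000, 2000, caller=c) for c in ("breakdancer", "cnd", "lumpy")]
        (cluster,) = merge_deletions(svs)
        assert (cluster.secondary_start, cluster.secondary_end) == (1000, 2000)
        assert (cluster.primary_start, cluster.primary_end) == (1000, 2000)
        assert len(cluster.members) == 3

    def test_exact_90_percent_not_merged(self):
        # two 1000-bp calls overlapping exactly 900 bp: RO = 0.9, strict rule
        a, b = _del(1, 1000), _del(101, 1100)
        assert reciprocal_overlap(a.interval, b.interval) == pytest.approx(0.9)
        assert len(merge_deletions([a, b])) == 2

    def test_just_over_90_percent_merged(self):
        a, b = _del(1, 1000), _del(100, 1099)
        assert reciprocal_overlap(a.interval, b.interval) > 0.9
        assert len(merge_deletions([a, b])) == 1

    def test_primary_breakpoints_follow_caller_priority(self):
        svs = [_del(1002, 2001, caller="cnd"), _del(1000, 2000, caller="lumpy"),
               _del(1001, 2002, caller="breakdancer")]
        (cluster,) = merge_deletions(svs)
        assert (cluster.primary_start, cluster.primary_end) == (1001, 2002)
        assert cluster.secondary_start == 1000 and cluster.secondary_end == 2002

    def test_mixed_svtype_rejected(self):
        with pytest.raises(ValueError):
            merge_deletions([_del(1, 200), _ins(100)])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_transitive_closure(self, seed):
        rng = np.random.default_rng(seed)
        svs = []
        for _ in range(200):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            start = int(rng.integers(1, 50_000))
            svs.append(_del(start, start + int(rng.integers(150, 3_000)), chrom=chrom))
        clusters = merge_deletions(svs)

        def related(a, b):
            return reciprocal_overlap(a.interval, b.interval) > 0.9

        assert cluster_partition(svs, clusters) == brute_force_clusters(svs, related)

    def test_order_invariant_and_idempotent(self):
        rng = np.random.default_rng(42)
        svs = []
        for _ in range(100):
            start = int(rng.integers(1, 30_000))
            svs.append(_del(start, start + int(rng.integers(150, 2_000))))
        ref_partition = cluster_partition(svs, merge_deletions(svs))
        for perm_seed in range(3):
            perm = np.random.default_rng(perm_seed).permutation(len(svs))
            shuffled = [svs[i] for i in perm]
            assert cluster_partition(svs, merge_deletions(shuffled)) == ref_partition
        # idempotence: re-merging the merged representatives changes nothing
        clusters = merge_deletions(svs)
        reps = [_del(c.secondary_start, c.secondary_end, chrom=c.chrom) for c in clusters]
        assert len(merge_deletions(reps)) == len(clusters)

    def test_secondary_bounds_contain_primary_and_members(self):
        rng = np.random.default_rng(9)
        svs = []
        for _ in range(150):
            start = int(rng.integers(1, 20_000))
            svs.append(_del(start, start + int(rng.integers(150, 2_500)),
                            caller=["breakdancer", "cnd", "lumpy"][int(rng.integers(3))]))
        for cl in merge_deletions(svs):
            assert cl.secondary_start <= cl.primary_start
            assert cl.primary_end <= cl.secondary_end
            for m in cl.members:
                assert cl.secondary_start <= m.start and m.end <= cl.secondary_end
            assert any((m.start, m.end) == (cl.primary_start, cl.primary_end)
                       for m in cl.members)


class TestMergeInsertions:
    def test_identical_positions_one_cluster(self):
        assert len(merge_insertions([_ins(500), _ins(500)])) == 1

    def test_beyond_window_two_clusters(self):
        assert len(merge_insertions([_ins(500), _ins(700)], window=100)) == 2

    def test_within_window_one_cluster(self):
        assert len(merge_insertions([_ins(500), _ins(580)], window=100)) == 1

    def test_jittered_clusters_recovered(self):
        from strainvar.synthetic_data import simulate_sv_callsets

        calls, truth = simulate_sv_callsets(n_true_deletions=1, n_strains=3,
                                            n_true_insertions=12, seed=5)
        ins = [c for c in calls if c.svtype == "INS"]
        clusters = merge_insertions(ins, window=100)
        # one cluster per (true insertion, carrier strain) after per-strain split
        per_strain = {}
        for s in truth.data["strains"]:
            per_strain[s] = merge_insertions([c for c in ins if c.strain == s], window=100)
        expected = sum(len(t["strains"]) for t in truth.data["insertions"])
        assert sum(len(v) for v in per_strain.values()) == expected
        assert len(clusters) == len(truth.data["insertions"])


class TestCrossStrainPrivate:
    def test_single_strain_deletion_private(self):
        per_strain = {"A": merge_deletions([_del(1000, 2000, strain="A")]),
                      "B": []}
        priv = cross_strain_private_svs(per_strain)
        assert len(priv["A"]) == 1

    def test_shared_deletion_private_to_neither(self):
        per_strain = {
            "A": merge_deletions([_del(1000, 2000, strain="A")]),
            "B": merge_deletions([_del(1001, 2001, strain="B")]),
        }
        priv = cross_strain_private_svs(per_strain)
        assert priv["A"] == [] and priv["B"] == []

    def test_planted_truth_recovery(self):
        from strainvar.synthetic_data import simulate_sv_callsets

        calls, truth = simulate_sv_callsets(n_true_deletions=25, n_strains=5,
                                            shared_across_strains=0.4, seed=8)
        per_strain = {
            s: merge_deletions([c for c in calls if c.strain == s and c.svtype == "DEL"])
            for s in truth.data["strains"]
        }
        priv = cross_strain_private_svs(per_strain)
        expected = {s: sum(1 for t in truth.data["deletions"]
                           if t["private"] and t["strains"] == [s])
                    for s in truth.data["strains"]}
        assert {s: len(v) for s, v in priv.items()} == expected


class TestCdsOverlap:
    MODELS = [
        GeneModel(gene_id="G1", chrom="chr1", cds_intervals=[(1000, 1200), (1500, 1700)]),
        GeneModel(gene_id="G2", chrom="chr1", cds_intervals=[(5000, 5200)]),
    ]

    def _cluster(self, start, end, chrom="chr1"):
        return SVCluster(members=[_del(start, end, chrom=chrom)])

    def test_deletion_spanning_gene_reported_once(self):
        res = cds_overlap([self._cluster(900, 2000)], self.MODELS)
        assert res.per_cluster[0][1] == {"G1"}
        assert res.n_clusters_hit == 1 and res.n_genes_hit == 1

    def test_intronic_deletion_no_hit(self):
        res = cds_overlap([self._cluster(1250, 1450)], self.MODELS)
        assert res.per_cluster[0][1] == frozenset()
        assert res.n_clusters_hit == 0

    def test_against_brute_force_intersection(self):
        rng = np.random.default_rng(3)
        models = []
        for i in range(30):
            s = int(rng.integers(1, 100_000))
            models.append(GeneModel(gene_id=f"G{i}", chrom="chr1",
                                    cds_intervals=[(s, s + int(rng.integers(50, 800)))]))
        clusters = []
        for _ in range(50):
            s = int(rng.integers(1, 100_000))
            clusters.append(self._cluster(s, s + int(rng.integers(100, 5_000))))
        res = cds_overlap(clusters, models)
        for ci, hits in res.per_cluster:
            cl = clusters[ci]
            expected = {
                gm.gene_id
                for gm in models
                for s, e in gm.cds_intervals
                if s <= cl.secondary_end and e >= cl.secondary_start
            }
            assert hits == expected


class TestValidationSensitivity:
    def test_paper_deletion_arithmetic(self):
        rep = sensitivity_from_counts(n_validated=151, n_found=131, n_excluded=8)
        assert rep.n_comparable == 143
        assert round(rep.sensitivity, 2) == 91.61

    def test_paper_insertion_arithmetic(self):
        rep = sensitivity_from_counts(n_validated=84, n_found=76, n_excluded=0)
        assert round(rep.sensitivity, 2) == 90.48

    def test_zero_found(self):
        assert sensitivity_from_counts(10, 0, 0).sensitivity == 0.0

    def test_zero_comparable_flagged(self):
        rep = sensitivity_from_counts(5, 0, 5)
        assert not rep.defined and rep.sensitivity is None

    def test_interval_based_any_overlap(self):
        called = merge_deletions([_del(1000, 2000), _del(9000, 9500)])
        validated = [("chr1", 1900, 2500), ("chr1", 5000, 5100), ("chr1", 9400, 9600)]
        rep = validation_sensitivity(called, validated, excluded=[("chr1", 5000, 5100)])
        assert (rep.n_found, rep.n_comparable) == (2, 2)
        assert rep.sensitivity == 100.0


class TestSvTableIO:
    def test_round_trip(self, tmp_path):
        svs = [_del(1000, 2000), _ins(5000, strain="S2", caller="lumpy")]
        path = tmp_path / "svs.tsv"
        write_sv_table(path, svs)
        back = read_sv_table(path)
        assert back == svs
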