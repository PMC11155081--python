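import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ldstack as L
from ldstack.cluster import ClusterConfig, chain_regions, group_mae, predicted_neglogp
from ldstack.ld import R2_MISSING

from conftest import DictLd, make_assoc


def naive_mae(s_values, r2_values):
    """Independently coded reference: mean |s_k - s_max * r²_k|."""
    s_max = max(s_values)
    total = 0.0
    for s, r2 in zip(s_values, r2_values):
        total += abs(s - s_max * r2)
    return total / len(s_values)


def oracle_regions(positions, max_gap, min_significant):
    """Transitive-closure reference for chaining: same region iff connected
    through pairs <= max_gap apart (union-find over all pairs)."""
    pos = sorted(positions)
    parent = list(range(len(pos)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if abs(pos[i] - pos[j]) <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(pos):
        groups.setdefault(find(i), []).append(p)
    return sorted((min(g), max(g)) for g in groups.values()
                  if len(g) >= min_significant)


class TestChainRegions:
    def test_gaps_at_or_below_threshold_join(self):
        cfg = ClusterConfig(min_significant=3)
        assocs = [make_assoc(bp, 0.01) for bp in (100, 3000, 7900)]
        regions = chain_regions(assocs, cfg)
        assert [(r.start_bp, r.end_bp) for r in regions] == [(100, 7900)]

    def test_gap_above_threshold_splits(self):
        cfg = ClusterConfig(min_significant=2)
        assocs = [make_assoc(bp, 0.01) for bp in (100, 3000, 9001)]
        regions = chain_regions(assocs, cfg)
        assert [(r.start_bp, r.end_bp) for r in regions] == [(100, 3000)]

    def test_below_minimum_count_discarded(self):
        cfg = ClusterConfig(min_significant=10)
        assocs = [make_assoc(100 + 10 * i, 0.01) for i in range(9)]
        assert chain_regions(assocs, cfg) == []

    def test_nonsignificant_snps_neither_bridge_nor_break(self):
        cfg = ClusterConfig(min_significant=2)
        assocs = [make_assoc(100, 0.01), make_assoc(4000, 0.5),
                  make_assoc(9000, 0.01), make_assoc(9100, 0.01)]
        regions = chain_regions(assocs, cfg)
        # the p=0.5 SNP at 4000 does not bridge 100 -> 9000
        assert [(r.start_bp, r.end_bp) for r in regions] == [(9000, 9100)]

    def test_all_snps_populated_inside_boundaries(self):
        cfg = ClusterConfig(min_significant=2)
        assocs = [make_assoc(100, 0.01), make_assoc(150, 0.9),
                  make_assoc(200, 0.01), make_assoc(99, 0.9)]
        assocs.sort(key=lambda a: a.sort_key)
        r = chain_regions(assocs, cfg)[0]
        assert [a.bp for a in r.all_snps] == [100, 150, 200]

    def test_unsorted_input_rejected(self):
        assocs = [make_assoc(200, 0.01), make_assoc(100, 0.01)]
        with pytest.raises(ValueError, match="sorted"):
            chain_regions(assocs, ClusterConfig())

    def test_chromosomes_never_merge(self):
        cfg = ClusterConfig(min_significant=2)
        assocs = sorted([make_assoc(100, 0.01, chrom="1"),
                         make_assoc(200, 0.01, chrom="1"),
                         make_assoc(100, 0.01, chrom="2"),
                         make_assoc(300, 0.01, chrom="2")],
                        key=lambda a: a.sort_key)
        regions = chain_regions(assocs, cfg)
        assert [(r.chrom, r.start_bp) for r in regions] == [("1", 100), ("2", 100)]

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(1, 60_000), min_size=1, max_size=60, unique=True),
           st.integers(1, 4))
    def test_matches_transitive_closure_oracle(self, positions, min_significant):
        cfg = ClusterConfig(min_significant=min_significant)
        assocs = [make_assoc(bp, 0.01) for bp in sorted(positions)]
        regions = chain_regions(assocs, cfg)
        assert [(r.start_bp, r.end_bp) for r in regions] == \
            oracle_regions(positions, cfg.max_gap_bp, min_significant)


class TestConsistencyScore:
    @pytest.mark.parametrize("s_max,r2,expected", [
        (8.0, 1.0, 8.0), (8.0, 0.0, 0.0), (6.0, 0.5, 3.0)])
    def test_predicted_neglogp(self, s_max, r2, expected):
        assert predicted_neglogp(s_max, r2) == expected

    def test_sentinel_propagates(self):
        assert math.isnan(predicted_neglogp(8.0, R2_MISSING))

    def test_exact_fit_gives_zero(self):
        assert group_mae([8, 4, 2], [1.0, 0.5, 0.25]) == 0.0

    def test_direct_arithmetic(self):
        assert group_mae([8, 1], [1.0, 0.5]) == pytest.approx(1.5, abs=1e-12)

    def test_matches_naive_loop_oracle(self, rng):
        for _ in range(50):
            k = rng.integers(1, 20)
            s = rng.uniform(0, 30, k)
            r2 = rng.uniform(0, 1, k)
            assert group_mae(s, r2) == pytest.approx(naive_mae(s, r2), abs=1e-12)

    def test_reorder_invariance(self, rng):
        s = rng.uniform(0, 20, 10)
        r2 = rng.uniform(0, 1, 10)
        perm = rng.permutation(10)
        assert group_mae(s, r2) == pytest.approx(group_mae(s[perm], r2[perm]),
                                                 abs=1e-12)

    def test_perturbing_one_member_increases_mae(self):
        s = [10.0, 5.0, 3.0]
        r2 = [1.0, 0.6, 0.4]
        base = group_mae(s, r2)
        worse = list(s)
        worse[2] = 1.0  # move further below s_max * r² = 4
        assert group_mae(worse, r2) > base

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_mae([], [])

    def test_sentinel_member_makes_group_unscoreable(self):
        assert math.isnan(group_mae([8, 4], [1.0, R2_MISSING]))


def build_region(snps):
    snps = sorted(snps, key=lambda a: a.sort_key)
    sig = [s for s in snps if s.p_value < 0.05]
    return L.Region(chrom="1", start_bp=sig[0].bp, end_bp=sig[-1].bp,
                    significant_snps=sig, all_snps=snps)


class TestSignalGroups:
    def test_perfect_ld_single_group_zero_mae(self):
        snps = [make_assoc(100 + i, 0.001) for i in range(5)]
        region = build_region(snps)
        ld = DictLd({(a.snp_id, b.snp_id): 1.0 for a in snps for b in snps})
        L.form_signal_groups(region, ld, ClusterConfig(min_significant=5))
        assert len(region.signal_groups) == 1
        g = region.signal_groups[0]
        assert g.direction is L.Direction.UP and g.mae == 0.0
        assert g.residuals[0] == 0.0  # top SNP always sits on the line

    def test_direction_partition(self):
        up = [make_assoc(100 + i, 0.001, odds_ratio=2.0) for i in range(5)]
        down = [make_assoc(200 + i, 0.001, odds_ratio=0.5) for i in range(5)]
        region = build_region(up + down)
        pairs = {}
        for grp in (up, down):
            for a in grp:
                for b in grp:
                    pairs[(a.snp_id, b.snp_id)] = 1.0
        L.form_signal_groups(region, DictLd(pairs), ClusterConfig())
        dirs = sorted(g.direction.value for g in region.signal_groups)
        assert dirs == ["DOWN", "UP"]
        assert all(g.size == 5 for g in region.signal_groups)

    def test_iterative_reanchoring_two_islands(self):
        # two LD islands among 6 same-direction SNPs: the strongest SNP anchors
        # island A; the strongest remaining SNP re-anchors island B
        island_a = [make_assoc(100, 1e-8, snp_id="a1"),
                    make_assoc(110, 1e-6, snp_id="a2"),
                    make_assoc(120, 1e-5, snp_id="a3")]
        island_b = [make_assoc(130, 1e-4, snp_id="b1"),
                    make_assoc(140, 1e-3, snp_id="b2"),
                    make_assoc(150, 1e-2, snp_id="b3")]
        pairs = {}
        for island in (island_a, island_b):
            for a in island:
                for b in island:
                    pairs[(a.snp_id, b.snp_id)] = 0.9
        region = build_region(island_a + island_b)
        L.form_signal_groups(region, DictLd(pairs), ClusterConfig())
        groups = {g.top_snp.snp_id: sorted(m.snp_id for m in g.members)
                  for g in region.signal_groups}
        assert groups == {"a1": ["a1", "a2", "a3"], "b1": ["b1", "b2", "b3"]}

    def test_every_significant_snp_in_exactly_one_group(self, rng):
        snps = [make_assoc(100 + i, float(rng.uniform(1e-6, 0.04)),
                           odds_ratio=float(rng.choice([0.5, 2.0])))
                for i in range(20)]
        ids = [s.snp_id for s in snps]
        pairs = {(a, b): float(rng.uniform(0, 1))
                 for i, a in enumerate(ids) for b in ids[i + 1:]}
        region = build_region(snps)
        L.form_signal_groups(region, DictLd(pairs), ClusterConfig())
        assigned = [m.snp_id for g in region.signal_groups for m in g.members]
        assert sorted(assigned) == sorted(ids)

    def test_neutral_or_excluded_from_groups(self):
        snps = [make_assoc(100 + i, 0.001) for i in range(4)]
        snps.append(make_assoc(200, 0.001, odds_ratio=1.0, snp_id="neutral"))
        region = build_region(snps)
        ld = DictLd({(a.snp_id, b.snp_id): 1.0 for a in snps for b in snps})
        L.form_signal_groups(region, ld, ClusterConfig())
        assigned = {m.snp_id for g in region.signal_groups for m in g.members}
        assert "neutral" not in assigned
        assert "neutral" in {s.snp_id for s in region.significant_snps}

    def test_anchor_without_ld_information_yields_sentinel_mae(self):
        snps = [make_assoc(100 + i, 0.001) for i in range(3)]
        region = build_region(snps)
        ld = DictLd(missing_ids=[s.snp_id for s in snps])
        L.form_signal_groups(region, ld, ClusterConfig())
        assert all(math.isnan(g.mae) for g in region.signal_groups)

    def test_tie_break_smaller_bp_anchors(self):
        snps = [make_assoc(200, 0.001, snp_id="later"),
                make_assoc(100, 0.001, snp_id="earlier")]
        region = build_region(snps)
        ld = DictLd({("later", "earlier"): 0.9})
        L.form_signal_groups(region, ld, ClusterConfig())
        assert region.signal_groups[0].top_snp.snp_id == "earlier"


def region_with_maes(maes, sizes=None):
    sizes = sizes or [3] * len(maes)
    snps = [make_assoc(100, 0.001)]
    region = L.Region(chrom="1", start_bp=100, end_bp=100,
                      significant_snps=snps, all_snps=snps)
    for mae, size in zip(maes, sizes):
        members = [make_assoc(100 + i, 0.001) for i in range(size)]
        region.signal_groups.append(L.SignalGroup(
            direction=L.Direction.UP, top_snp=members[0], members=members,
            r2_values=[1.0] * size, predicted=[0.0] * size,
            residuals=[0.0] * size, mae=mae))
    return region


class TestPrioritize:
    def test_one_group_below_threshold_prioritizes(self):
        region = region_with_maes([4.2, 2.9])
        L.prioritize([region], ClusterConfig())
        assert region.prioritized

    def test_boundary_mae_not_prioritized(self):
        region = region_with_maes([3.0])
        L.prioritize([region], ClusterConfig())
        assert not region.prioritized

    def test_sentinel_only_not_prioritized(self):
        region = region_with_maes([R2_MISSING])
        L.prioritize([region], ClusterConfig())
        assert not region.prioritized

    def test_singleton_group_carries_no_evidence(self):
        region = region_with_maes([0.0], sizes=[1])
        L.prioritize([region], ClusterConfig())
        assert not region.prioritized

    def test_monotone_in_mae_threshold(self):
        regions = [region_with_maes([m]) for m in (0.5, 2.0, 3.5, 6.0)]
        L.prioritize(regions, ClusterConfig(mae_threshold=2.5))
        low = [r.prioritized for r in regions]
        L.prioritize(regions, ClusterConfig(mae_threshold=5.0))
        high = [r.prioritized for r in regions]
        assert all(h or not l for l, h in zip(low, high))


class TestRunClusterAnalysis:
    def test_empty_input_empty_output(self):
        regions, pri = L.run_cluster_analysis([], DictLd())
        assert regions == [] and pri == []

    def test_prioritized_snps_subset_of_region_members(self, rng):
        snps = sorted([make_assoc(100 + 10 * i, float(rng.uniform(1e-6, 0.2)))
                       for i in range(40)], key=lambda a: a.sort_key)
        ids = [s.snp_id for s in snps]
        pairs = {(a, b): 0.9 for i, a in enumerate(ids) for b in ids[i + 1:]}
        regions, pri = L.run_cluster_analysis(snps, DictLd(pairs),
                                              ClusterConfig(min_significant=5))
        member_ids = {a.snp_id for r in regions if r.prioritized for a in r.all_snps}
        assert {a.snp_id for a in pri} == member_ids

    def test_shuffled_pvalues_not_prioritized(self):
        """A dense high-LD stack whose p-values are permuted loses its
        LD-consistency and must not be prioritized.

        The stack must be cohesive (all members above the r² threshold to any
        anchor): in a loosely linked cluster, permutation followed by
        re-anchoring produces small splinter groups that can be consistent by
        chance — a documented weakness of the MAE score for tiny groups.
        """
        rejected = 0
        for seed in range(10):
            cfg = L.SimulationConfig(n_cases=136, n_controls=1864,
                                     causal_or=1.0, n_spike_snps=12,
                                     spike_clustered=True, seed=seed)
            ds = L.simulate_dataset(cfg)
            assocs = L.logistic_assoc_additive(ds.table, ds.phenotype)
            bps = ds.table.variants.set_index("snp_id") \
                .loc[ds.truth.spike_ids, "bp"]
            rng = np.random.default_rng(seed)
            shuffled = L.permute_pvalues_in_window(
                assocs, "1", int(bps.min()), int(bps.max()), rng)
            regions, _ = L.run_cluster_analysis(
                shuffled, L.GenotypeLdSource(ds.table))
            stack = [r for r in regions
                     if any(r.start_bp <= bp <= r.end_bp for bp in bps)]
            if stack and not stack[0].prioritized:
                rejected += 1
        assert rejected >= 8
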