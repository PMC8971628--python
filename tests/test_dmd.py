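import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_dmd
from famvar.core.cnv import CNVCall
from famvar.core.pedigree import AnalysisGroups
from famvar.core.variants import VariantRecord
from famvar.dmd import (
    DMDLandscape,
    WindowTally,
    call_hotspots,
    compute_landscape,
    consensus_cnv,
    differential_cnv,
    dmd_score,
    score_granularity,
    window_tally,
)


def _variant(chrom, pos, carriers, all_ids):
    return VariantRecord(
        chrom=chrom, pos=pos, ref="A", alt="G",
        genotypes={m: (1 if m in carriers else 0) for m in all_ids},
    )


AFFECTED_IDS = {f"a{i}" for i in range(5)}
HEALTHY_IDS = {f"h{i}" for i in range(12)}
ALL_IDS = AFFECTED_IDS | HEALTHY_IDS
GROUPS = AnalysisGroups(
    affected_ids=AFFECTED_IDS,
    healthy_comparator_ids=HEALTHY_IDS,
    healthy_all_ids=HEALTHY_IDS,
)


class TestWindowTally:
    def test_window_arithmetic(self):
        v = _variant("chr1", 1_500_000, AFFECTED_IDS, ALL_IDS)
        (tally,) = window_tally([v], GROUPS)
        assert tally.window_start == 1_000_001
        assert tally.window_end == 2_000_000

    def test_boundary_belongs_downstream(self):
        at_boundary = _variant("chr1", 1_000_001, AFFECTED_IDS, ALL_IDS)
        before = _variant("chr1", 1_000_000, AFFECTED_IDS, ALL_IDS)
        tallies = window_tally([before, at_boundary], GROUPS)
        assert [t.window_start for t in tallies] == [1, 1_000_001]

    def test_empty_variants(self):
        assert window_tally([], GROUPS) == []

    def test_bucket_counts_sum(self):
        # oracle: independent bucket count over 10 fixed positions
        positions = [1, 2, 999_999, 1_000_000, 1_000_001, 1_500_000,
                     2_000_000, 2_000_001, 2_500_000, 3_000_000]
        variants = [
            _variant("chr2", p, set(), ALL_IDS) for p in positions
        ]
        tallies = window_tally(variants, GROUPS)
        expected_buckets = {(p - 1) // 1_000_000 for p in positions}
        assert len(tallies) == len(expected_buckets)
        assert sum(t.n for t in tallies) == 10

    def test_bad_window_size(self):
        with pytest.raises(ValueError, match="positive"):
            window_tally([], GROUPS, window_size=0)

    def test_occurrence_counts_carriers_not_alleles(self):
        hom = VariantRecord(
            chrom="chr1", pos=5, ref="A", alt="G",
            genotypes={**{m: 0 for m in ALL_IDS}, "a0": 2},
        )
        (tally,) = window_tally([hom], GROUPS)
        assert tally.occurrences[0][1] == 1


class TestDmdScore:
    def test_all_affected_no_healthy(self):
        tally = WindowTally("chr1", 1, 10**6, [(("k",), 5, 0)])
        assert dmd_score(tally, 5, 12) == 1.0

    def test_no_affected_all_healthy(self):
        tally = WindowTally("chr1", 1, 10**6, [(("k",), 0, 12)])
        assert dmd_score(tally, 5, 12) == -1.0

    def test_forty_perfect_variants(self):
        tally = WindowTally(
            "chr1", 1, 10**6, [((f"k{i}",), 5, 0) for i in range(40)]
        )
        assert dmd_score(tally, 5, 12) == 40.0

    def test_matches_brute_force_oracle(self):
        occurrences = [
            ((f"k{i}",), i % 6, (i * 7) % 13) for i in range(50)
        ]
        tally = WindowTally("chr3", 1, 10**6, occurrences)
        expected = brute_force_dmd(occurrences, 5, 12)
        assert dmd_score(tally, 5, 12) == pytest.approx(expected, abs=1e-12)

    def test_occurrence_exceeding_group_size(self):
        tally = WindowTally("chr1", 1, 10**6, [(("k",), 6, 0)])
        with pytest.raises(ValueError, match="exceeds"):
            dmd_score(tally, 5, 12)

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 12)),
            min_size=0,
            max_size=60,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_granularity_and_additivity(self, counts):
        occ = [((f"k{i}",), d, h) for i, (d, h) in enumerate(counts)]
        tally = WindowTally("chr1", 1, 10**6, occ)
        score = dmd_score(tally, 5, 12)
        # every score is an integer multiple of 1/lcm(5, 12) = 1/60
        assert abs(round(score * 60) - score * 60) < 1e-9
        # additive over disjoint subsets
        left = WindowTally("chr1", 1, 10**6, occ[: len(occ) // 2])
        right = WindowTally("chr1", 1, 10**6, occ[len(occ) // 2:])
        assert dmd_score(left, 5, 12) + dmd_score(right, 5, 12) == pytest.approx(
            score, abs=1e-9
        )

    def test_label_swap_negates_when_groups_equal(self):
        occ = [((f"k{i}",), i % 4, (i * 3) % 4) for i in range(20)]
        fwd = dmd_score(WindowTally("chr1", 1, 10**6, occ), 4, 4)
        swapped = [(k, h, d) for k, d, h in occ]
        rev = dmd_score(WindowTally("chr1", 1, 10**6, swapped), 4, 4)
        assert fwd == pytest.approx(-rev, abs=1e-12)


class TestLandscape:
    def test_granularity_on_simulated_set(
        self, default_variant_set, template_pedigree, template_groups
    ):
        records, _ = default_variant_set
        landscape = compute_landscape(records, template_groups)
        denom = score_granularity(landscape)
        assert denom == 60
        for _, _, score in landscape.scores:
            assert abs(round(score * denom) - score * denom) < 1e-6


class TestHotspots:
    def _landscape(self, scores):
        return DMDLandscape(scores=scores, n_affected=5, n_healthy=12)

    def test_all_below_threshold(self):
        ls = self._landscape([("chr1", 1, 19.9), ("chr2", 1, 20.0)])
        assert call_hotspots(ls, 20.0) == []

    def test_single_window_hotspot(self):
        # 1979/60 mirrors the granularity of a realistic high-load window
        ls = self._landscape([("chr12", 1, 1979 / 60), ("chr12", 1_000_001, 3.0)])
        hotspots = call_hotspots(ls, 20.0)
        assert len(hotspots) == 1
        assert hotspots[0].dmd == pytest.approx(32.9833, abs=1e-3)
        assert hotspots[0].label == "chr12:1"

    def test_adjacent_windows_merge(self):
        ls = self._landscape(
            [("chr1", 1, 25.0), ("chr1", 1_000_001, 21.0), ("chr1", 5_000_001, 30.0)]
        )
        hotspots = call_hotspots(ls, 20.0)
        assert len(hotspots) == 2
        assert hotspots[0].start == 1 and hotspots[0].end == 2_000_000
        assert hotspots[0].dmd == 25.0

    def test_strict_inequality(self):
        ls = self._landscape([("chr1", 1, 20.0)])
        assert call_hotspots(ls, 20.0) == []

    def test_gene_annotation(self):
        occ = [(("chr1", 10, "A", "G"), 5, 0)]
        tally = WindowTally("chr1", 1, 10**6, occ)
        ls = self._landscape([("chr1", 1, 21.0)])
        (hs,) = call_hotspots(
            ls, 20.0, tallies=[tally], gene_map={("chr1", 10, "A", "G"): "GENE1"}
        )
        assert hs.genes == {"GENE1"}
        assert hs.variant_count == 1


def _cnv(member, chrom, start, end, state="deletion", caller="a"):
    return CNVCall(chrom, start, end, state, caller, member)


class TestConsensusCnv:
    def test_identical_call_retained(self):
        a = _cnv("m1", "chr1", 100, 199)
        out = consensus_cnv([a], [_cnv("m1", "chr1", 100, 199, caller="b")])
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 199)
        assert out[0].caller == "consensus"

    def test_disjoint_empty(self):
        out = consensus_cnv(
            [_cnv("m1", "chr1", 100, 199)], [_cnv("m1", "chr1", 300, 399)]
        )
        assert out == []

    def test_sixty_percent_overlap_intersected(self):
        # oracle: manual interval arithmetic — [100,199] vs [140,239],
        # intersection 60 bp, reciprocal overlap 0.6 on both sides
        a = _cnv("m1", "chr1", 100, 199)
        b = _cnv("m1", "chr1", 140, 239, caller="b")
        (out,) = consensus_cnv([a], [b], min_reciprocal_overlap=0.5)
        assert (out.start, out.end) == (140, 199)

    def test_member_and_state_must_match(self):
        a = _cnv("m1", "chr1", 100, 199)
        assert consensus_cnv([a], [_cnv("m2", "chr1", 100, 199)]) == []
        assert (
            consensus_cnv([a], [_cnv("m1", "chr1", 100, 199, state="duplication")])
            == []
        )

    def test_bad_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            consensus_cnv([], [], min_reciprocal_overlap=0.0)


class TestDifferentialCnv:
    def test_shared_by_everyone_not_differential(self, template_groups):
        calls = [
            _cnv(m, "chr1", 100, 199)
            for m in template_groups.affected_ids
            | template_groups.healthy_comparator_ids
        ]
        assert differential_cnv(calls, template_groups) == []

    def test_affected_only_is_differential(self, template_groups):
        affected = sorted(template_groups.affected_ids)[:3]
        calls = [_cnv(m, "chr1", 100, 199) for m in affected]
        out = differential_cnv(calls, template_groups)
        assert {c.member_id for c in out} == set(affected)

    def test_null_simulated_fixture_empty(self, template_pedigree, template_groups):
        from famvar.synth import SimulationConfig, simulate_cnv_calls

        calls_a, calls_b = simulate_cnv_calls(
            template_pedigree, SimulationConfig(seed=13)
        )
        consensus = consensus_cnv(calls_a, calls_b)
        assert consensus  # the shared regions do reach consensus
        assert differential_cnv(consensus, template_groups) == []
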