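import numpy as np
import pytest

from enhscape.config import AnalysisConfig
from enhscape.de import DEResult
from enhscape.enhancers import (
    MODALITIES,
    build_report,
    call_enhancers,
    classify_modality,
    attach_de_status,
    tss_accessibility_table,
)
from enhscape.intervals import GenomicInterval, IntervalSet, TSSRecord
from enhscape.pipeline import run_study_landscape
from enhscape.report import report_percent
from enhscape.simulate import SimulationParams, simulate_study

from helpers import brute_call_and_classify, brute_tss_changes


def _iv(start, end, name=None, chrom="chr1"):
    return GenomicInterval(chrom, start, end, name=name)


def _de(gene, status):
    return DEResult(gene, 1, 1, 1.0, 0.0, 0.5, 0.5, status)


EMPTY = IntervalSet([])
TSS_FAR = [TSSRecord("far", "chr1", 10_000_000, "+")]


class TestCallEnhancers:
    def _call(self, *, atac_a=EMPTY, k4_a=EMPTY, k27_a=EMPTY,
              atac_b=None, k4_b=None, k27_b=None, tss=TSS_FAR, config=None):
        return call_enhancers(atac_a, k4_a, k27_a, atac_b, k4_b, k27_b, tss, config)

    def test_full_b_pattern_without_prior_k27ac_is_called(self):
        peak = _iv(10_000, 10_500, "e1")
        calls = self._call(
            atac_b=IntervalSet([peak]), k4_b=IntervalSet([peak]),
            k27_b=IntervalSet([peak]),
        )
        assert [c.region.name for c in calls] == ["e1"]
        assert calls[0].condB_status == (True, True, True)

    def test_prior_k27ac_excludes_the_region(self):
        peak = _iv(10_000, 10_500)
        calls = self._call(
            k27_a=IntervalSet([_iv(10_200, 10_300)]),
            atac_b=IntervalSet([peak]), k4_b=IntervalSet([peak]),
            k27_b=IntervalSet([peak]),
        )
        assert calls == []

    def test_missing_b_k4me1_fails_the_conjunction(self):
        peak = _iv(10_000, 10_500)
        calls = self._call(
            atac_b=IntervalSet([peak]), k4_b=EMPTY, k27_b=IntervalSet([peak]),
        )
        assert calls == []

    def test_distal_filter_drops_tss_proximal_regions(self):
        peak = _iv(10_000, 10_500)
        tss = [TSSRecord("near", "chr1", 11_000, "+")]
        tracks = dict(atac_b=IntervalSet([peak]), k4_b=IntervalSet([peak]),
                      k27_b=IntervalSet([peak]))
        assert self._call(tss=tss, **tracks) == []
        keep = AnalysisConfig(distal_filter=False)
        calls = self._call(tss=tss, config=keep, **tracks)
        assert len(calls) == 1 and calls[0].nearest_gene == "near"

    def test_region_coordinates_come_from_the_b_k27ac_peak(self):
        k27 = _iv(10_000, 10_800, "k27span")
        other = _iv(10_300, 10_400)
        calls = self._call(
            atac_b=IntervalSet([other]), k4_b=IntervalSet([other]),
            k27_b=IntervalSet([k27]),
        )
        assert (calls[0].region.start, calls[0].region.end) == (10_000, 10_800)


class TestClassifyModality:
    @pytest.mark.parametrize(
        "atac, k4, expected",
        [
            (True, False, "accessible"),
            (True, True, "poised"),
            (False, False, "unmarked"),
            (False, True, "de_novo"),
        ],
    )
    def test_two_by_two_map(self, atac, k4, expected):
        peak = _iv(10_000, 10_500)
        call = call_enhancers(
            EMPTY, EMPTY, EMPTY,
            IntervalSet([peak]), IntervalSet([peak]), IntervalSet([peak]),
            TSS_FAR,
        )[0]
        atac_a = IntervalSet([peak]) if atac else EMPTY
        k4_a = IntervalSet([peak]) if k4 else EMPTY
        got = classify_modality(call, atac_a, k4_a)
        assert got.modality == expected
        assert got.condA_status == (atac, k4, False)

    def test_exhaustive_four_region_toy_set(self):
        regions = [_iv(i * 10_000, i * 10_000 + 500, f"r{i}") for i in range(1, 5)]
        tracks = IntervalSet(regions)
        calls = call_enhancers(EMPTY, EMPTY, EMPTY, tracks, tracks, tracks, TSS_FAR)
        atac_a = IntervalSet(regions[:2])          # r1, r2 open in A
        k4_a = IntervalSet([regions[1], regions[3]])  # r2, r4 primed in A
        got = sorted(
            (classify_modality(c, atac_a, k4_a) for c in calls),
            key=lambda c: c.region.start,
        )
        assert [c.modality for c in got] == ["accessible", "poised", "unmarked", "de_novo"]


class TestTSSAccessibility:
    TSS = [TSSRecord("g_up", "chr1", 50_000, "+"),
           TSSRecord("g_down", "chr1", 150_000, "+"),
           TSSRecord("g_ns", "chr1", 250_000, "+")]

    def test_gained_lost_and_stable(self):
        de = [_de("g_up", "up"), _de("g_down", "down"), _de("g_ns", "ns")]
        atac_a = IntervalSet([_iv(149_500, 150_500), _iv(249_500, 250_500)])
        atac_b = IntervalSet([_iv(49_500, 50_500), _iv(249_500, 250_500)])
        rows = {c.gene_id: c for c in
                tss_accessibility_table(de, atac_a, atac_b, self.TSS)}
        assert rows["g_up"].change == "gained"
        assert rows["g_down"].change == "lost"
        assert rows["g_ns"].change == "stable_open"

    def test_peak_must_fall_in_the_two_kb_window(self):
        de = [_de("g_up", "up")]
        # peak ends exactly at the window edge (48,000): no overlap
        atac_b = IntervalSet([_iv(47_000, 48_000)])
        (row,) = tss_accessibility_table(de, EMPTY, atac_b, self.TSS)
        assert row.change == "stable_closed"

    def test_genes_absent_from_tss_table_are_skipped(self):
        de = [_de("g_up", "up"), _de("unknown", "up")]
        rows = tss_accessibility_table(de, EMPTY, EMPTY, self.TSS)
        assert [r.gene_id for r in rows] == ["g_up"]


class TestReport:
    def _calls(self, counts, de_status=None):
        calls = []
        i = 0
        for modality, n in zip(MODALITIES, counts):
            for _ in range(n):
                peak = _iv(100_000 + i * 1000, 100_000 + i * 1000 + 500, f"e{i}")
                call = call_enhancers(
                    EMPTY, EMPTY, EMPTY,
                    IntervalSet([peak]), IntervalSet([peak]), IntervalSet([peak]),
                    TSS_FAR,
                )[0]
                atac = IntervalSet([peak]) if modality in ("accessible", "poised") else EMPTY
                k4 = IntervalSet([peak]) if modality in ("poised", "de_novo") else EMPTY
                calls.append(classify_modality(call, atac, k4))
                i += 1
        return calls

    def test_observed_class_counts_round_to_printed_percentages(self):
        calls = self._calls((597, 386, 379, 120))
        rep = build_report(calls, [], [])
        assert rep.n_enhancers == 1482
        assert rep.modality_counts == dict(zip(MODALITIES, (597, 386, 379, 120)))
        assert [rep.modality_percent[m] for m in MODALITIES] == [40, 26, 26, 8]

    def test_tss_gain_percentage(self):
        changes = (
            [_de_change("u%d" % i, "up", False, True) for i in range(1385)]
            + [_de_change("u%d" % i, "up", True, True) for i in range(1385, 2022)]
        )
        rep = build_report([], changes, [])
        assert rep.pct_up_with_gain == 68
        assert (rep.n_up_gained, rep.n_up) == (1385, 2022)

    def test_zero_enhancers_gives_na_not_errors(self):
        rep = build_report([], [], [])
        assert rep.n_enhancers == 0
        assert all(v is None for v in rep.modality_percent.values())
        assert rep.pct_up_with_gain is None

    def test_invariant_under_row_permutation(self, rng):
        calls = self._calls((5, 3, 2, 1))
        shuffled = list(calls)
        rng.shuffle(shuffled)
        assert build_report(calls, [], []) == build_report(shuffled, [], [])

    def test_nearest_gene_association(self):
        calls = self._calls((2, 1, 1, 0))
        de = [_de("far", "up")]
        calls = attach_de_status(calls, de)
        rep = build_report(calls, [], de)
        assert rep.pct_enhancers_near_upregulated == 100
        # one distinct up gene, reachable from three modalities
        assert rep.upregulated_gene_counts_per_modality["accessible"] == 1
        assert rep.pct_upregulated_per_modality["de_novo"] == 0


def _de_change(gene, status, a, b):
    from enhscape.enhancers import TSSAccessibilityChange
    return TSSAccessibilityChange(gene, status, a, b)


@pytest.mark.parametrize(
    "n, d, decimals, expected",
    [
        (1385, 2022, 0, 68),
        (597, 1482, 0, 40),
        (379, 1482, 1, 25.6),
        (0, 10, 0, 0),
        (5, 0, 0, None),
        (1, 8, 0, 13),  # 12.5 rounds half-up, never banker's
    ],
)
def test_report_percent(n, d, decimals, expected):
    assert report_percent(n, d, decimals) == expected


class TestOracleEquivalence:
    """Calls, classes and TSS changes equal all-pairs re-derivations."""

    @pytest.mark.parametrize("seed", range(5))
    def test_random_synthetic_studies(self, seed, tmp_path):
        params = SimulationParams(
            seed=seed, n_genes=60, n_enhancers=30, n_loops=0,
            peak_fdr_noise=0.1, tags_per_peak=0,
        )
        study = simulate_study(params, tmp_path / str(seed))
        result = run_study_landscape(study)
        from enhscape.pipeline import _study_tracks
        tracks = {k: list(v) for k, v in _study_tracks(study).items()}
        tss = [t.tss for t in study.truth_de.values()]
        expected = brute_call_and_classify(
            tracks["atac_a"], tracks["k4_a"], tracks["k27_a"],
            tracks["atac_b"], tracks["k4_b"], tracks["k27_b"], tss,
        )
        got = {c.region.name: c.modality for c in result.calls}
        assert got == expected
        expected_changes = brute_tss_changes(
            result.de, tracks["atac_a"], tracks["atac_b"], tss
        )
        got_changes = {c.gene_id: (c.atac_a, c.atac_b) for c in result.changes}
        assert got_changes == expected_changes
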