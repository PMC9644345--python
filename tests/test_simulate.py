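import hashlib

import numpy as np
import pytest

from enhscape.errors import InfeasibleLayout
from enhscape.io import read_bed, read_bedpe, read_expression, read_tss_table
from enhscape.intervals import replicate_reproducible
from enhscape.pipeline import modality_recovery, run_study_landscape
from enhscape.simulate import (
    CLASS_NAMES,
    PAPER_CLASS_MIX,
    SimulationParams,
    largest_remainder,
    make_en7_fixture,
    simulate_study,
)

from helpers import brute_overlaps


class TestApportionment:
    def test_printed_percentage_vector(self):
        # quoted one-decimal class mix; the missing 0.5% seat goes to the
        # smallest class under the tie rule
        assert largest_remainder(200, (0.4, 0.26, 0.255, 0.08)) == [80, 52, 51, 17]

    def test_exact_mix_reproduces_observed_counts(self):
        assert largest_remainder(1482, PAPER_CLASS_MIX) == [597, 386, 379, 120]

    @pytest.mark.parametrize("n", [1, 7, 100, 1482])
    def test_counts_sum_exactly(self, n):
        counts = largest_remainder(n, PAPER_CLASS_MIX)
        assert sum(counts) == n and all(c >= 0 for c in counts)


def _file_digest(paths):
    h = hashlib.sha256()
    for p in sorted(paths, key=lambda p: p.name):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def test_same_seed_is_byte_identical(tmp_path):
    p = SimulationParams(seed=5, n_genes=60, n_enhancers=20, n_loops=5)
    s1 = simulate_study(p, tmp_path / "a")
    s2 = simulate_study(p, tmp_path / "b")
    assert _file_digest(s1.emitted.values()) == _file_digest(s2.emitted.values())


def test_different_seed_differs(tmp_path):
    s1 = simulate_study(SimulationParams(seed=1, n_genes=60, n_enhancers=20, n_loops=5),
                        tmp_path / "a")
    s2 = simulate_study(SimulationParams(seed=2, n_genes=60, n_enhancers=20, n_loops=5),
                        tmp_path / "b")
    assert _file_digest(s1.emitted.values()) != _file_digest(s2.emitted.values())


class TestTruthConsistency:
    """At zero noise every emitted file must re-derive to the truth record."""

    def test_enhancer_marks_match_planted_class(self, small_study):
        s = small_study
        p = s.params
        tracks = {}
        for track in ("atac", "h3k4me1", "h3k27ac"):
            for cond in (p.cond_a, p.cond_b):
                rep1 = read_bed(s.emitted[f"{track}_{cond}_rep1"])
                rep2 = read_bed(s.emitted[f"{track}_{cond}_rep2"])
                tracks[(track, cond)] = replicate_reproducible(rep1, rep2)
        prior = {"accessible": (True, False), "poised": (True, True),
                 "unmarked": (False, False), "de_novo": (False, True)}
        for te in s.truth_enhancers:
            status = {
                key: any(brute_overlaps(te.region, iv) for iv in tracks[key])
                for key in tracks
            }
            assert status[("h3k27ac", p.cond_b)] and status[("atac", p.cond_b)]
            assert status[("h3k4me1", p.cond_b)]
            assert not status[("h3k27ac", p.cond_a)]
            want_atac, want_k4 = prior[te.modality]
            assert status[("atac", p.cond_a)] == want_atac
            assert status[("h3k4me1", p.cond_a)] == want_k4

    def test_class_counts_follow_apportionment(self, small_study):
        counts = largest_remainder(
            small_study.params.n_enhancers, small_study.params.class_proportions
        )
        got = [sum(1 for t in small_study.truth_enhancers if t.modality == m)
               for m in CLASS_NAMES]
        assert got == counts

    def test_tss_accessibility_files_match_truth(self, small_study):
        s = small_study
        p = s.params
        atac = {}
        for cond in (p.cond_a, p.cond_b):
            atac[cond] = replicate_reproducible(
                read_bed(s.emitted[f"atac_{cond}_rep1"]),
                read_bed(s.emitted[f"atac_{cond}_rep2"]),
            )
        for rec in read_tss_table(s.emitted["tss"]):
            tg = s.truth_de[rec.gene_id]
            win_lo, win_hi = rec.tss - 2000, rec.tss + 2000
            present = {}
            for cond, track in atac.items():
                present[cond] = any(
                    iv.chrom == rec.chrom and iv.start < win_hi and win_lo < iv.end
                    and (iv.name or "").startswith("tss_")
                    for iv in track
                )
            expect = {
                "gained": (False, True), "lost": (True, False),
                "stable_open": (True, True), "stable_closed": (False, False),
            }[tg.accessibility]
            assert (present[p.cond_a], present[p.cond_b]) == expect

    def test_expression_equals_planted_means_at_zero_cv(self, tmp_path):
        s = simulate_study(
            SimulationParams(seed=3, n_genes=40, n_enhancers=10, n_loops=0,
                             replicate_cv=0.0),
            tmp_path,
        )
        table = read_expression(s.emitted["expression"])
        for i, gene in enumerate(table.gene_ids):
            tg = s.truth_de[gene]
            np.testing.assert_allclose(
                table.condition_matrix(s.params.cond_a)[i], tg.mean_a, rtol=1e-5
            )
            np.testing.assert_allclose(
                table.condition_matrix(s.params.cond_b)[i], tg.mean_b, rtol=1e-5
            )

    def test_loops_connect_planted_enhancer_and_promoter_bins(self, small_study):
        s = small_study
        loops = read_bedpe(s.emitted[f"loops_{s.params.cond_b}"],
                           s.params.hic_resolution, s.params.cond_b)
        assert len(loops) == len(s.truth_loops)
        emitted = {(i.anchor1.start, i.anchor2.start) for i in loops}
        for tl in s.truth_loops:
            pair = tuple(sorted((tl.anchor_enh.start, tl.anchor_prom.start)))
            assert pair in emitted


def test_noise_free_classification_recovers_all_planted_classes(small_study):
    assert modality_recovery(small_study) == 1.0


def test_recovery_monotone_in_noise(tmp_path):
    levels = (0.0, 0.05, 0.2)
    means = []
    for noise in levels:
        recs = []
        for seed in range(10):
            s = simulate_study(
                SimulationParams(seed=seed, n_genes=80, n_enhancers=60,
                                 n_loops=0, peak_fdr_noise=noise, tags_per_peak=0),
                tmp_path / f"n{noise}_{seed}",
            )
            recs.append(modality_recovery(s))
        means.append(float(np.mean(recs)))
    assert means[0] >= means[1] >= means[2]
    assert means[0] == 1.0


def test_infeasible_layout_raises(tmp_path):
    with pytest.raises(InfeasibleLayout):
        simulate_study(
            SimulationParams(n_genes=50, n_enhancers=10, n_loops=5,
                             chrom_sizes={"chr1": 20_000}),
            tmp_path,
        )


@pytest.mark.parametrize(
    "kwargs",
    [
        {"class_proportions": (0.5, 0.5, 0.5, 0.5)},
        {"frac_up": 0.8, "frac_down": 0.3},
        {"n_enhancers": 600},
        {"n_loops": 200},
        {"n_replicates": 1},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulationParams(**kwargs)


class TestEn7Fixture:
    def test_exactly_one_element_matches_the_discovery_pattern(self, en7_fixture):
        fx = en7_fixture
        conds = fx.meta["conditions"]
        atac = {c: list(read_bed(fx.emitted[f"atac_{c}"])) for c in conds}
        loops = {c: read_bedpe(fx.emitted[f"loops_{c}"], 10_000, c) for c in conds}
        tss = read_tss_table(fx.emitted["tss"])[0]
        prom_lo, prom_hi = tss.tss - 2000, tss.tss + 2000
        matching = []
        for el in read_bed(fx.emitted["elements"]):
            accessible = {c for c in conds
                          if any(brute_overlaps(el, p) for p in atac[c])}
            looped = set()
            for c, inters in loops.items():
                for it in inters:
                    for x, y in ((it.anchor1, it.anchor2), (it.anchor2, it.anchor1)):
                        if (brute_overlaps(x, el) and y.chrom == tss.chrom
                                and y.start < prom_hi and prom_lo < y.end):
                            looped.add(c)
            if (len(accessible) >= 4 and {"aPSM", "HIFLR"} <= looped
                    and "ESC" not in looped):
                matching.append(el.name)
        assert matching == ["En7"]

    def test_upstream_decoys_are_accessible_but_unlooped(self, en7_fixture):
        fx = en7_fixture
        loops = [it for c in fx.meta["conditions"]
                 for it in read_bedpe(fx.emitted[f"loops_{c}"], 10_000, c)]
        for name in ("minus25kb", "minus3.5kb"):
            el = next(e for e in read_bed(fx.emitted["elements"]) if e.name == name)
            open_in = [c for c in fx.meta["conditions"]
                       if any(brute_overlaps(el, p)
                              for p in read_bed(fx.emitted[f"atac_{c}"]))]
            assert len(open_in) >= 4
            # no loop anchored both at the decoy and at the promoter
            tss = read_tss_table(fx.emitted["tss"])[0]
            for it in loops:
                for x, y in ((it.anchor1, it.anchor2), (it.anchor2, it.anchor1)):
                    if brute_overlaps(x, el):
                        assert not (y.start < tss.tss + 2000 and tss.tss - 2000 < y.end
                                    and y.chrom == tss.chrom)
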