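"""Normalization, threshold calibration, run detection, persistence, colocalization."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midgap import gapcall, synthgen
from midgap.gapcall import GapCall
from midgap.linescan import IntensityTrace

from conftest import make_background


def brute_force_runs(mask, min_run):
    """Independent run enumeration via itertools.groupby."""
    runs, i = [], 0
    for val, grp in itertools.groupby(mask):
        n = len(list(grp))
        if val and n >= min_run:
            runs.append((i, i + n))
        i += n
    return runs


def make_trace(norm_a, norm_b, cyto_mean=100.0):
    """Trace whose bg_subtracted layer normalizes to the given arrays."""
    norm_a, norm_b = np.asarray(norm_a, float), np.asarray(norm_b, float)
    bgsub = np.column_stack([(norm_a + 1) * cyto_mean, (norm_b + 1) * cyto_mean])
    return IntensityTrace(
        positions_um=np.arange(len(norm_a), dtype=float),
        raw=bgsub.copy(),
        bg_subtracted=bgsub,
    )


class TestNormalize:
    def test_formula_arithmetic(self):
        bg = make_background({"chA": 0.2, "chB": 0.2}, cyto_mean=100.0)
        trace = IntensityTrace(
            positions_um=np.arange(3.0),
            raw=np.array([[120.0, 100.0], [100.0, 100.0], [80.0, 150.0]]),
        ).with_background_subtracted(0.0)
        norm = gapcall.normalize_trace(trace, bg)
        np.testing.assert_allclose(norm.normalized[:, 0], [0.2, 0.0, -0.2])
        np.testing.assert_allclose(norm.normalized[:, 1], [0.0, 0.0, 0.5])

    def test_scale_invariance_of_normalized_layer(self, gapped_embryo):
        emb = gapped_embryo
        trace = emb.corrected_trace()
        samples = emb.bg_subtracted_samples()
        bg1 = gapcall.calibrate_threshold(samples)
        n1 = gapcall.normalize_trace(trace, bg1)
        scaled = IntensityTrace(
            positions_um=trace.positions_um, raw=3 * trace.raw,
            bg_subtracted=3 * trace.bg_subtracted,
        )
        bg3 = gapcall.calibrate_threshold({c: 3 * v for c, v in samples.items()})
        n3 = gapcall.normalize_trace(scaled, bg3)
        np.testing.assert_allclose(n3.normalized, n1.normalized, rtol=1e-12)

    def test_requires_background_subtraction_and_positive_mean(self):
        trace = IntensityTrace(positions_um=np.arange(3.0), raw=np.zeros((3, 2)))
        bg = make_background({"chA": 0.2, "chB": 0.2})
        with pytest.raises(ValueError, match="slide background"):
            gapcall.normalize_trace(trace, bg)


class TestCalibrate:
    def test_gaussian_coverage_near_phi_of_two(self):
        rng = np.random.default_rng(12)
        samples = {"chA": rng.normal(100, 10, 10_000), "chB": rng.normal(100, 10, 10_000)}
        bg = gapcall.calibrate_threshold(samples)
        for ch in bg.channels:
            assert ch.coverage == pytest.approx(0.9772, abs=0.005)
            assert ch.threshold == pytest.approx(2 * 10 / 100, rel=0.05)

    def test_two_point_hand_arithmetic(self):
        # raw {0, 200} normalizes to {-1, +1}: sd sqrt(2), threshold 2*sqrt(2)
        bg = gapcall.calibrate_threshold(
            {"chA": np.array([0.0, 200.0])}, min_n=2
        )
        ch = bg["chA"]
        assert ch.norm_sd == pytest.approx(np.sqrt(2))
        assert ch.threshold == pytest.approx(2 * np.sqrt(2))
        assert ch.coverage == 1.0

    def test_constant_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gapcall.calibrate_threshold({"chA": np.full(50, 7.0)})

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="required"):
            gapcall.calibrate_threshold({"chA": np.arange(5.0) + 1})


class TestClassify:
    def test_two_channel_conjunction(self):
        bg = make_background({"chA": 0.2, "chB": 0.2})
        trace = gapcall.normalize_trace(
            make_trace([0.0, 5.0, 0.0], [0.0, 0.0, 5.0]), bg
        )
        mask = gapcall.classify_background_level(trace, bg)
        np.testing.assert_array_equal(mask, [True, False, False])

    def test_threshold_boundary_is_strict(self):
        bg = make_background({"chA": 0.2, "chB": 0.2})
        trace = gapcall.normalize_trace(make_trace([0.2], [0.0]), bg)
        assert trace.normalized[0, 0] == bg["chA"].threshold  # exact tie by construction
        assert not gapcall.classify_background_level(trace, bg)[0]

    def test_requires_two_channels(self):
        trace = IntensityTrace(
            positions_um=np.arange(3.0), raw=np.zeros((3, 1)) + 100,
            channel_names=("chA",), bg_subtracted=np.zeros((3, 1)) + 100,
            normalized=np.zeros((3, 1)),
        )
        with pytest.raises(ValueError, match="two-channel"):
            gapcall.classify_background_level(trace, make_background({"chA": 0.2}))


class TestCallGaps:
    def test_basic_run_detection(self):
        gaps = gapcall.call_gaps(np.array([0, 0, 1, 1, 1, 0], bool))
        assert [(g.start_idx, g.end_idx, g.length_points) for g in gaps] == [(2, 5, 3)]

    def test_short_runs_ignored(self):
        assert gapcall.call_gaps(np.array([1, 1, 0, 1, 1], bool)) == []

    def test_physical_length_counts_one_spacing_per_point(self):
        positions = np.arange(10) * 0.11
        (gap,) = gapcall.call_gaps(
            np.array([0, 1, 1, 1, 0, 0, 0, 0, 0, 0], bool), positions_um=positions
        )
        assert gap.length_um == pytest.approx(3 * 0.11)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        mask=st.lists(st.booleans(), min_size=3, max_size=120),
        min_run=st.integers(1, 5),
    )
    def test_matches_brute_force_enumeration(self, mask, min_run):
        mask = np.asarray(mask, bool)
        got = [(g.start_idx, g.end_idx) for g in gapcall.call_gaps(mask, min_run)]
        assert got == brute_force_runs(mask, min_run)

    def test_min_run_monotonicity(self):
        rng = np.random.default_rng(5)
        mask = rng.random(300) < 0.4
        counts = [len(gapcall.call_gaps(mask, r)) for r in (1, 2, 3, 5)]
        assert counts == sorted(counts, reverse=True)


class TestSummaries:
    def test_summary_counts_from_constructed_mask(self):
        trace = make_trace(np.zeros(200), np.zeros(200))
        mask = np.zeros(200, bool)
        mask[40:45] = True
        gaps = gapcall.call_gaps(mask, positions_um=trace.positions_um)
        s = gapcall.summarize_embryo("e1", "mut", trace, gaps, mask)
        assert s.n_gaps == 1 and s.has_gap
        assert s.n_background_level == 5
        assert s.frac_background_level == pytest.approx(5 / 200)
        # invariant: background-level points at least cover the gap lengths
        assert s.n_background_level >= sum(g.length_points for g in gaps)

    def test_pipeline_recovers_cohort_gap_percentage(self):
        plan = synthgen.GenotypePlan.with_single_gap("mut", 18, 10, gap_length=12)
        cohort = synthgen.generate_cohort([plan], seed=21)
        n_gapped = sum(
            gapcall.run_gap_analysis(
                e.corrected_trace(), e.bg_subtracted_samples()
            ).summary.has_gap
            for e in cohort
        )
        assert round(100 * n_gapped / 18, 1) == 55.6

    def test_gap_calls_invariant_under_global_rescaling(self, gapped_embryo):
        emb = gapped_embryo
        base = gapcall.run_gap_analysis(
            emb.corrected_trace(), emb.bg_subtracted_samples()
        )
        for k in (0.25, 3.0, 17.0):
            trace = emb.corrected_trace()
            scaled = IntensityTrace(
                positions_um=trace.positions_um, raw=k * trace.raw,
                bg_subtracted=k * trace.bg_subtracted,
            )
            res = gapcall.run_gap_analysis(
                scaled, {c: k * v for c, v in emb.bg_subtracted_samples().items()}
            )
            assert [(g.start_idx, g.end_idx) for g in res.gaps] == [
                (g.start_idx, g.end_idx) for g in base.gaps
            ]


class TestTimepoints:
    def test_verdicts(self):
        def s(n, eid="e1"):
            return gapcall.EmbryoGapSummary(eid, "g", 0, False, n, n / 200, 22.0)

        assert not gapcall.compare_timepoints(s(0), s(0)).increased
        assert gapcall.compare_timepoints(s(2), s(7)).increased
        with pytest.raises(ValueError, match="mismatched"):
            gapcall.compare_timepoints(s(0, "e1"), s(0, "e2"))

    def test_static_control_cohort_never_increases(self):
        # the same trace measured at two timepoints cannot gain background points
        plan = synthgen.GenotypePlan.no_gaps("control", 7)
        increased = 0
        for emb in synthgen.generate_cohort([plan], seed=8):
            res = gapcall.run_gap_analysis(
                emb.corrected_trace(), emb.bg_subtracted_samples(), embryo_id=emb.embryo_id
            )
            verdict = gapcall.compare_timepoints(res.summary, res.summary)
            increased += verdict.increased
        assert increased == 0  # 0/7 embryos


class TestPersistence:
    def g(self, a, b):
        return GapCall(a, b, b - a, float("nan"), ("chA", "chB"))

    def test_gap_reaching_final_frame_after_24_min_is_persistent(self):
        frames = [[] if f < 2 else [self.g(100, 112)] for f in range(9)]
        (locus,) = gapcall.track_persistence(frames, frame_interval_min=4.0)
        assert locus.duration_min == 24.0
        assert locus.present_at_end
        assert locus.verdict == "persistent"

    def test_short_midmovie_gap_is_transient(self):
        frames = [[self.g(50, 60)] if f in (2, 3) else [] for f in range(9)]
        (locus,) = gapcall.track_persistence(frames, frame_interval_min=4.0)
        assert locus.duration_min == 4.0  # present 2 frames = lasted 8 min or less
        assert locus.verdict == "transient"

    def test_gap_only_in_final_frame_is_transient(self):
        frames = [[] for _ in range(8)] + [[self.g(10, 20)]]
        (locus,) = gapcall.track_persistence(frames, frame_interval_min=4.0)
        assert locus.duration_min == 0.0
        assert locus.present_at_end and locus.verdict == "transient"

    def test_reappearing_gap_forms_two_loci(self):
        frames = [[self.g(10, 20)], [], [self.g(10, 20)], [self.g(10, 20)]]
        loci = gapcall.track_persistence(frames, frame_interval_min=4.0)
        assert len(loci) == 2

    def test_nonoverlapping_gaps_tracked_separately(self):
        frames = [[self.g(10, 20), self.g(50, 60)], [self.g(10, 20), self.g(50, 60)]]
        loci = gapcall.track_persistence(frames, frame_interval_min=4.0)
        assert len(loci) == 2

    def test_full_pipeline_on_synthetic_timelapse(self):
        tl = synthgen.generate_timelapse(
            synthgen.TraceParams(seed=13), events=[((2, 9), (100, 112))], n_frames=9
        )
        _, loci = gapcall.analyze_timelapse(
            tl.corrected_series(), tl.bg_subtracted_samples()
        )
        assert any(l.persistent for l in loci)


class TestColocalization:
    def test_apical_marker_in_gap_is_localized(self):
        gap = GapCall(5, 10, 5, 0.5, ("chA", "chB"))
        bg = make_background({"chC": 0.2})["chC"]
        assert gapcall.gap_colocalization(gap, np.full(20, 4.0), bg)

    def test_background_marker_is_not_localized(self):
        gap = GapCall(5, 10, 5, 0.5, ("chA", "chB"))
        bg = make_background({"chC": 0.2})["chC"]
        assert not gapcall.gap_colocalization(gap, np.zeros(20), bg)

    def test_mean_rule_on_half_apical_gap(self):
        gap = GapCall(0, 4, 4, 0.4, ("chA", "chB"))
        other = np.array([4.0, 4.0, 0.0, 0.0])  # mean 2.0 >> threshold
        bg = make_background({"chC": 0.2})["chC"]
        assert gapcall.gap_colocalization(gap, other, bg)


class TestLengthNormalize:
    def test_constant_profile_stays_constant(self):
        _, out = gapcall.length_normalize(np.full(37, 2.5))
        np.testing.assert_allclose(out, 2.5)

    def test_identity_when_lengths_match(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        _, out = gapcall.length_normalize(v, n_out=4)
        np.testing.assert_allclose(out, v)

    def test_linear_ramp_stays_linear(self):
        v = np.linspace(0, 9, 37)
        frac, out = gapcall.length_normalize(v, n_out=100)
        np.testing.assert_allclose(out, 9 * frac, atol=1e-9)

    def test_rejects_tiny_outputs(self):
        with pytest.raises(ValueError):
            gapcall.length_normalize(np.arange(5.0), n_out=1)
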