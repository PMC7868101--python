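import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sosperf import (
    DefectFinding,
    DynamicVolume,
    LVModel,
    aha_segment_curves,
    classify_hypointensity,
    discard_edge_slices,
    grade_severity,
    recovery_metrics,
    true_defect_segments,
)
from sosperf.analysis import AHA_SEGMENT_NAMES, SegmentTimeCurves


class TestDiscardEdgeSlices:
    def test_16_slice_stack_keeps_12(self):
        vol = DynamicVolume(np.ones((2, 16, 4, 4), dtype=complex))
        out = discard_edge_slices(vol, 4)
        assert out.n_slices == 12

    def test_zero_is_identity(self):
        vol = DynamicVolume(np.ones((2, 6, 4, 4), dtype=complex))
        assert discard_edge_slices(vol, 0) is vol

    def test_discarding_all_slices_rejected(self):
        vol = DynamicVolume(np.ones((2, 6, 4, 4), dtype=complex))
        with pytest.raises(ValueError):
            discard_edge_slices(vol, 6)

    def test_odd_count_rejected(self):
        vol = DynamicVolume(np.ones((2, 6, 4, 4), dtype=complex))
        with pytest.raises(ValueError):
            discard_edge_slices(vol, 3)

    def test_symmetric_trim(self):
        data = np.arange(8)[None, :, None, None] * np.ones((1, 8, 2, 2))
        out = discard_edge_slices(DynamicVolume(data.astype(complex)), 4)
        assert list(out.data[0, :, 0, 0].real) == [2, 3, 4, 5]


@pytest.fixture(scope="module")
def phantom_curves(tiny_phantom):
    spec, vol, gt = tiny_phantom
    lv_model = LVModel.from_ground_truth(gt)
    return gt, aha_segment_curves(vol, lv_model)


class TestAhaSegmentCurves:
    def test_sixteen_segments(self, phantom_curves):
        _, curves = phantom_curves
        assert curves.curves.shape[0] == 16
        assert len(AHA_SEGMENT_NAMES) == 16

    def test_uniform_volume_gives_identical_curves(self, tiny_phantom):
        spec, vol, gt = tiny_phantom
        uniform = vol.copy_with(np.ones_like(vol.data))
        curves = aha_segment_curves(uniform, LVModel.from_ground_truth(gt))
        covered = curves.coverage > 0
        vals = curves.curves[covered]
        assert np.allclose(vals, 1.0)

    def test_defect_appears_in_inferior_septal_territory(self, phantom_curves):
        """The phantom's wedge at 150-230 deg must depress the curves of the
        inferior/inferoseptal segments relative to remote myocardium."""
        gt, curves = phantom_curves
        truth = true_defect_segments(gt)
        assert truth, "ground-truth defect should overlap at least one segment"
        peak = int(np.argmax(gt.signals["myocardium"]))
        affected = list(truth)
        unaffected = [
            s for s in range(16)
            if s not in truth and curves.coverage[s, peak] > 0
        ]
        assert all("inferior" in AHA_SEGMENT_NAMES[s] or "infero" in AHA_SEGMENT_NAMES[s]
                   or "septal" in AHA_SEGMENT_NAMES[s] for s in affected)
        worst_affected = min(curves.curves[s, peak] for s in affected)
        mean_remote = np.mean([curves.curves[s, peak] for s in unaffected])
        assert worst_affected < mean_remote

    def test_empty_myocardium_rejected(self, tiny_phantom):
        spec, vol, gt = tiny_phantom
        lv = LVModel.from_ground_truth(gt)
        # push the LV centre far outside the FOV
        lv.centers_mm = lv.centers_mm + 1e6
        with pytest.raises(ValueError):
            aha_segment_curves(vol, lv)


def _synthetic_curves(
    n_frames=24, dip_segments=(), dip_start=0, dip_len=0, dip_frac=0.4,
    endo_only=False,
):
    """Hand-built segment curves: gamma-like bloodpool, flat myocardium
    enhancement, optional rectangular dips in chosen segments."""
    t = np.arange(n_frames, dtype=float)
    blood = np.exp(-((t - 8.0) ** 2) / 8.0)  # peak at frame 8
    myo = 0.2 + 0.6 / (1 + np.exp(-(t - 10.0)))
    curves = np.tile(myo, (16, 1))
    endo = curves.copy()
    epi = curves.copy()
    for s in dip_segments:
        sl = slice(dip_start, dip_start + dip_len)
        curves[s, sl] *= 1 - dip_frac
        endo[s, sl] *= 1 - (dip_frac if not endo_only else 2 * dip_frac)
        epi[s, sl] *= 1 - (dip_frac if not endo_only else 0.0)
    return SegmentTimeCurves(
        curves=curves, endo_curves=endo, epi_curves=epi,
        bloodpool=blood, frame_times_s=t,
        coverage=np.ones((16, n_frames), dtype=int),
    )


class TestClassifyHypointensity:
    def test_no_defect_gives_empty_list(self):
        curves = _synthetic_curves()
        assert classify_hypointensity(curves) == []

    def test_short_dip_at_bloodpool_peak_is_artifact(self):
        """A 2-frame dip coinciding with the contrast peak is the dark-rim
        artefact signature, not a perfusion defect."""
        curves = _synthetic_curves(dip_segments=[3], dip_start=8, dip_len=2)
        findings = classify_hypointensity(curves)
        assert len(findings) == 1
        assert findings[0].classification == "transient-artifact"

    def test_persistent_post_peak_deficit_is_defect(self):
        curves = _synthetic_curves(dip_segments=[3], dip_start=12, dip_len=10)
        findings = classify_hypointensity(curves)
        flagged = [f for f in findings if f.classification == "persistent-defect"]
        assert len(flagged) == 1
        assert flagged[0].segment_id == 3
        assert flagged[0].depth == pytest.approx(0.4, abs=0.05)

    def test_subendocardial_dip_has_partial_transmurality(self):
        curves = _synthetic_curves(
            dip_segments=[5], dip_start=12, dip_len=10, dip_frac=0.25, endo_only=True
        )
        findings = classify_hypointensity(curves)
        flagged = [f for f in findings if f.classification == "persistent-defect"]
        assert flagged and flagged[0].transmurality == pytest.approx(0.5, abs=0.1)

    def test_threshold_monotonicity(self):
        """Looser thresholds flag a superset of segments."""
        curves = _synthetic_curves(dip_segments=[2, 7], dip_start=12, dip_len=10,
                                   dip_frac=0.3)
        segs = {}
        for frac in (0.25, 0.15, 0.05):
            found = classify_hypointensity(
                _synthetic_curves(dip_segments=[2, 7], dip_start=12, dip_len=10,
                                  dip_frac=0.3),
                threshold_frac=frac,
            )
            segs[frac] = {f.segment_id for f in found
                          if f.classification == "persistent-defect"}
        assert segs[0.25] <= segs[0.15] <= segs[0.05]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_hypointensity(_synthetic_curves(), threshold_frac=1.5)


class TestGradeSeverity:
    def _finding(self, depth, trans, persist):
        return DefectFinding(
            segment_id=0, segment_name="basal anterior", onset_frame=5,
            persistence=persist, depth=depth, transmurality=trans,
            classification="persistent-defect",
        )

    def test_maximal_defect_is_severe(self):
        assert grade_severity(self._finding(1.0, 1.0, 30), 20) == "severe"

    def test_below_mild_floor_is_none(self):
        assert grade_severity(self._finding(0.05, 0.5, 2), 20) == "none"

    def test_worked_composite_score(self):
        # 0.5 * 0.6 * 1.0 = 0.30 -> moderate under the default thresholds
        assert grade_severity(self._finding(0.5, 0.6, 20), 20) == "moderate"

    def test_transient_input_rejected(self):
        f = self._finding(0.5, 0.5, 5)
        f.classification = "transient-artifact"
        with pytest.raises(ValueError):
            grade_severity(f, 20)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        d1=st.floats(0.1, 1.0), d2=st.floats(0.1, 1.0),
        t1=st.floats(0.1, 1.0), t2=st.floats(0.1, 1.0),
        p1=st.integers(1, 30), p2=st.integers(1, 30),
    )
    def test_monotone_in_every_component(self, d1, d2, t1, t2, p1, p2):
        order = ["none", "mild", "moderate", "severe"]
        lo = self._finding(min(d1, d2), min(t1, t2), min(p1, p2))
        hi = self._finding(max(d1, d2), max(t1, t2), max(p1, p2))
        assert order.index(grade_severity(hi, 20)) >= order.index(
            grade_severity(lo, 20)
        )


class TestRecoveryMetrics:
    def _finding(self, seg):
        return DefectFinding(
            segment_id=seg, segment_name=AHA_SEGMENT_NAMES[seg], onset_frame=0,
            persistence=8, depth=0.5, transmurality=1.0,
            classification="persistent-defect", severity="moderate",
        )

    def test_perfect_recovery(self):
        truth = {3: "severe", 9: "moderate"}
        m = recovery_metrics([self._finding(3), self._finding(9)], truth)
        assert m["sensitivity"] == {"moderate": 1.0, "severe": 1.0}
        assert m["dice"] == 1.0 and m["specificity"] == 1.0

    def test_empty_findings_zero_sensitivity(self):
        m = recovery_metrics([], {3: "severe"})
        assert m["sensitivity"]["severe"] == 0.0

    def test_dice_two_thirds(self):
        # one of two true segments flagged, no false positives
        m = recovery_metrics([self._finding(3)], {3: "mild", 4: "mild"})
        assert m["dice"] == pytest.approx(2 / 3)
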