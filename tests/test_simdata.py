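"""Simulator, augmentation and dataset-protocol tests."""

import numpy as np
import pytest

from zfheart.cardiometrics import AxisPair, mask_area
from zfheart.simdata import (LabeledFrame, SynthHeartSpec, augment,
                             contraction_waveform, expand_training_set,
                             rasterize_ellipse, simulate_heart_video,
                             split_dataset)


class TestSimulateHeartVideo:
    def test_cycle_count_by_construction(self, clean_spec, clean_video):
        """120 bpm over a 2-s video spans exactly 4 full cycles."""
        _, _, gt = clean_video
        assert gt.HR == 120.0
        assert gt.n_cycles == 4
        assert clean_spec.n_frames / clean_spec.fps == 2.0

    def test_no_contraction_gives_flat_trace(self):
        spec = SynthHeartSpec(contraction_frac=(0.0, 0.0), noise_sd=0.0,
                              blur_sigma=0.0, jitter_px=0.0)
        _, masks, gt = simulate_heart_video(spec)
        areas = masks.sum(axis=(1, 2))
        assert gt.FAC == 0.0 and gt.FS == 0.0
        assert np.all(areas == areas[0])  # constant up to rasterization

    def test_ed_mask_area_matches_analytic_ellipse(self, clean_video):
        """Rasterized end-diastolic ellipse area is pi*a0*b0 within 3%."""
        _, masks, _ = clean_video
        # first end-diastole falls a quarter period in (frame 6 at 120 bpm)
        areas = masks.sum(axis=(1, 2))
        ed_area = areas.max()
        assert ed_area == pytest.approx(np.pi * 20 * 10, rel=0.03)

    def test_area_trace_periodic_at_simulated_rate(self, clean_spec,
                                                   clean_video):
        """Autocorrelation of the mask-area trace peaks at the true period."""
        _, masks, _ = clean_video
        from scipy.signal import find_peaks
        x = masks.sum(axis=(1, 2)).astype(float)
        x = x - x.mean()
        n = len(x)
        ac = np.correlate(x, x, mode="full")[n - 1:]
        ac = ac / (n - np.arange(n))  # unbiased normalization
        peaks, _ = find_peaks(ac, prominence=0.1 * ac[0])
        expected = clean_spec.fps * 60.0 / clean_spec.hr_bpm
        assert peaks[0] == int(round(expected)) == 25

    def test_deterministic_for_fixed_seed(self):
        spec = SynthHeartSpec(noise_sd=0.05, jitter_px=1.0, seed=7,
                              n_frames=10)
        v1, m1, _ = simulate_heart_video(spec)
        v2, m2, _ = simulate_heart_video(spec)
        assert np.array_equal(v1.frames, v2.frames)
        assert np.array_equal(m1, m2)

    @pytest.mark.parametrize("bad", [
        dict(ed_semi_axes=(10.0, 20.0)),       # a0 < b0
        dict(ed_semi_axes=(10.0, 0.0)),
        dict(contraction_frac=(1.0, 0.2)),
        dict(contraction_frac=(-0.1, 0.2)),
        dict(hr_bpm=0.0),
        dict(hr_bpm=float("nan")),
        dict(fps=-1.0),
        dict(n_frames=0),
        dict(noise_sd=-0.1),
        dict(edema=2),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            SynthHeartSpec(**bad)

    def test_waveform_bounds_and_asymmetry(self):
        t = np.linspace(0, 2, 400)
        for kind in ("raised-cosine", "asymmetric"):
            s = contraction_waveform(t, 120.0, kind)
            assert s.min() >= 0.0 and s.max() <= 1.0 + 1e-12

    def test_rasterization_centre_inside_convention(self):
        # a 1-pixel-wide ellipse centred on a pixel centre hits that pixel
        m = rasterize_ellipse(9, 9, (4.5, 4.5), 0.4, 0.4, 0.0)
        assert mask_area(m) == 1 and m[4, 4]


class TestAugment:
    def _frame(self, value=0.5):
        img = np.zeros((32, 32), dtype=np.float32)
        mask = np.zeros((32, 32), dtype=bool)
        img[10:20, 8:18] = value
        mask[10:20, 8:18] = True
        return LabeledFrame(image=img, mask=mask, true_area_px=100,
                            true_axes=AxisPair(10.0, 10.0, 0.0))

    def test_identity_when_disabled(self):
        f = self._frame()
        g = augment(f, angle_deg=0.0, flip_h=False, flip_v=False, gain=1.0)
        assert np.array_equal(f.image, g.image)
        assert np.array_equal(f.mask, g.mask)

    def test_flip_is_involution(self):
        f = self._frame()
        kw = dict(angle_deg=0.0, flip_v=False, gain=1.0)
        g = augment(augment(f, flip_h=True, **kw), flip_h=True, **kw)
        assert np.array_equal(f.image, g.image)
        assert np.array_equal(f.mask, g.mask)

    def test_contrast_gain_applied_and_clipped(self):
        f = self._frame(value=100.0)
        g = augment(f, angle_deg=0.0, flip_h=False, flip_v=False, gain=1.1,
                    clip_range=(0.0, 255.0))
        assert g.image[15, 12] == pytest.approx(110.0)
        h = augment(self._frame(value=0.95), angle_deg=0.0, flip_h=False,
                    flip_v=False, gain=1.1)
        assert h.image.max() == pytest.approx(1.0)  # clipped to [0, 1]

    def test_mask_stays_binary_and_aligned_under_rotation(self):
        f = self._frame()
        g = augment(f, angle_deg=33.0, flip_h=False, flip_v=False, gain=1.0)
        assert set(np.unique(g.mask)) <= {False, True}
        assert g.image.shape == f.image.shape
        # image foreground and mask still coincide (noiseless rectangle)
        overlap = (g.image > 0.25) & g.mask
        assert overlap.sum() / g.mask.sum() > 0.9
        assert g.true_area_px == mask_area(g.mask)


class TestSplitAndExpand:
    def test_split_protocol_sizes(self):
        train, val = split_dataset(range(2125), ratio=(4, 1), seed=0)
        assert (len(train), len(val)) == (1700, 425)

    def test_split_small(self):
        train, val = split_dataset(range(5), ratio=(4, 1), seed=1)
        assert (len(train), len(val)) == (4, 1)

    def test_split_disjoint_exhaustive_and_deterministic(self):
        items = list(range(103))
        t1, v1 = split_dataset(items, (4, 1), seed=9)
        t2, v2 = split_dataset(items, (4, 1), seed=9)
        assert t1 == t2 and v1 == v2
        assert sorted(t1 + v1) == items

    def test_split_rejects_empty_part(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], ratio=(4, 1), seed=0)

    def test_expand_reaches_protocol_size(self):
        f = TestAugment()._frame()
        out = expand_training_set([f] * 1700, factor=3, seed=0)
        assert len(out) == 5100

    def test_expand_factor_one_is_identity(self):
        f = TestAugment()._frame()
        out = expand_training_set([f] * 10, factor=1, seed=0)
        assert len(out) == 10 and all(o is i for o, i in zip(out, [f] * 10))

    def test_expand_keeps_originals_verbatim(self):
        frames = [TestAugment()._frame(v) for v in np.linspace(0.2, 0.8, 10)]
        out = expand_training_set(frames, factor=2, seed=3)
        assert len(out) == 20
        for orig, kept in zip(frames, out[:10]):
            assert np.array_equal(orig.image, kept.image)
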