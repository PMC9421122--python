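"""Augmentation methods: printed-formula arithmetic, identities, involutions,
determinism, and one-to-one doubling."""

import numpy as np
import pytest

from pcgbench.augment import (
    MaskParams,
    PitchTimeParams,
    SvPerturbParams,
    TrainingItem,
    augment_training_set,
    compose_method,
    compute_rms,
    hflip,
    inject_awgn,
    pca_color_augment,
    pitch_shift,
    pitch_time_augment,
    random_color_filter,
    rgb_to_hsv,
    sample_mask_params,
    sample_pitch_time_params,
    sv_perturb,
    time_frequency_mask,
    time_stretch,
    vflip,
)
from pcgbench.colorspaces import REGISTRY_SIZE, registry
from pcgbench.spectral import MelSpectrogram, SpectrogramImage
from pcgbench.synthetic import AudioRecording, generate_recording

from conftest import spectral_peak_hz


# ---------------------------------------------------------------- audio level


def test_pitch_shift_octave_up(tone):
    out = pitch_shift(tone, 12)
    assert out.samples.size == tone.samples.size
    peak = spectral_peak_hz(out.samples, tone.sample_rate)
    assert abs(peak - 440.0) <= tone.sample_rate / 512  # within one analysis bin


def test_pitch_shift_identity(tone):
    out = pitch_shift(tone, 0)
    err = np.sqrt(np.mean((out.samples - tone.samples) ** 2)) / np.sqrt(
        np.mean(tone.samples**2)
    )
    assert err < 1e-3


def test_pitch_shift_ratio_within_2_percent(tone):
    for p in (-5, 3):
        out = pitch_shift(tone, p)
        peak = spectral_peak_hz(out.samples, tone.sample_rate)
        assert peak / 220.0 == pytest.approx(2 ** (p / 12), rel=0.02)


def test_time_stretch_durations(tone):
    assert time_stretch(tone, 2.0).duration == pytest.approx(2 * tone.duration, abs=0.2)
    assert time_stretch(tone, 0.5).duration == pytest.approx(0.5 * tone.duration, abs=0.2)
    same = time_stretch(tone, 1.0)
    assert same.duration == tone.duration
    assert abs(spectral_peak_hz(same.samples, tone.sample_rate) - 220.0) <= 4.0
    with pytest.raises(ValueError):
        time_stretch(tone, 0.0)


def test_time_stretch_preserves_pitch(tone):
    out = time_stretch(tone, 1.7)
    peak = spectral_peak_hz(out.samples, tone.sample_rate)
    assert peak == pytest.approx(220.0, rel=0.02)
    assert out.duration == pytest.approx(1.7 * tone.duration, rel=0.02)


def test_sampled_pitch_time_params_distribution():
    rng = np.random.default_rng(0)
    draws = [sample_pitch_time_params(rng) for _ in range(1000)]
    ps = [d.p for d in draws]
    assert all(isinstance(p, int) and 1 <= abs(p) <= 10 for p in ps)
    assert any(p > 0 for p in ps) and any(p < 0 for p in ps)
    assert all(0.5 <= d.t <= 2.0 for d in draws)
    with pytest.raises(ValueError):
        PitchTimeParams(p=11, t=1.0).validate()
    with pytest.raises(ValueError):
        PitchTimeParams(p=3, t=3.0).validate()


def test_compute_rms_examples():
    assert compute_rms([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
    assert compute_rms([1, 1, 1, 1]) == 1.0
    assert compute_rms(np.zeros(5)) == 0.0
    with pytest.raises(ValueError):
        compute_rms([])


def test_awgn_snr_and_determinism(normal_rec):
    raw = inject_awgn(normal_rec, rng=np.random.default_rng(5), renormalize=False)
    noise = raw.samples - normal_rec.samples
    snr = 20 * np.log10(compute_rms(normal_rec.samples) / compute_rms(noise))
    assert abs(snr) < 0.3
    a = inject_awgn(normal_rec, rng=np.random.default_rng(7))
    b = inject_awgn(normal_rec, rng=np.random.default_rng(7))
    np.testing.assert_array_equal(a.samples, b.samples)
    assert np.max(np.abs(a.samples)) <= 1.0
    with pytest.raises(ValueError):
        inject_awgn(AudioRecording(np.zeros(100), 2000, 0, "z"), rng=1)


def test_awgn_variance_doubles():
    # zero-mean unit-RMS signal: var(signal + noise) ~ 1 + 1 = 2
    sr = 2000
    t = np.arange(0, 40, 1 / sr)  # 80000 samples
    sig = AudioRecording(np.sqrt(2) * 0.5 * np.sin(2 * np.pi * 97 * t) * 2, sr, 0, "s")
    sig.samples = sig.samples / compute_rms(sig.samples)  # exactly unit RMS
    out = inject_awgn(sig, rng=np.random.default_rng(3), renormalize=False)
    assert np.var(out.samples) == pytest.approx(2.0, abs=0.1)


# ---------------------------------------------------------------- image level


def test_hflip_coordinates(random_image):
    out = hflip(random_image)
    # pixel at x=0 lands at x = width-1
    np.testing.assert_array_equal(out.pixels[:, 179, :], random_image.pixels[:, 0, :])
    np.testing.assert_array_equal(hflip(out).pixels, random_image.pixels)


def test_vflip_coordinates(random_image):
    out = vflip(random_image)
    np.testing.assert_array_equal(out.pixels[99, :, :], random_image.pixels[0, :, :])
    np.testing.assert_array_equal(vflip(out).pixels, random_image.pixels)


def test_flip_toy_rows():
    row = np.zeros((100, 180, 3), np.uint8)
    row[0, :3, 0] = [1, 2, 3]
    img = SpectrogramImage(row)
    assert list(hflip(img).pixels[0, -3:, 0]) == [3, 2, 1]
    col = np.zeros((100, 180, 3), np.uint8)
    col[:3, 0, 0] = [1, 2, 3]
    assert list(vflip(SpectrogramImage(col)).pixels[-3:, 0, 0]) == [3, 2, 1]


def test_rgb_to_hsv_printed_cases():
    np.testing.assert_allclose(rgb_to_hsv([255, 0, 0]), [0.0, 1.0, 1.0])
    np.testing.assert_allclose(rgb_to_hsv([0, 255, 0]), [120.0, 1.0, 1.0])
    h, s, v = rgb_to_hsv([128, 128, 128])
    assert (h, s) == (0.0, 0.0)
    assert v == pytest.approx(128 / 255)
    # blue primary exercises the Cmax = B' branch
    np.testing.assert_allclose(rgb_to_hsv([0, 0, 255]), [240.0, 1.0, 1.0])


def test_sv_identity_and_halving(random_image):
    out, _ = sv_perturb(random_image, SvPerturbParams(1.0, 1.0))
    np.testing.assert_array_equal(out.pixels, random_image.pixels)
    halved, _ = sv_perturb(random_image, SvPerturbParams(0.5, 1.0))
    np.testing.assert_array_equal(halved.pixels, np.round(random_image.pixels * 0.5))


def test_sv_saturation_pass_fixes_grayscale(rng):
    gray = np.repeat(rng.integers(0, 256, (100, 180, 1)), 3, axis=2).astype(np.uint8)
    img = SpectrogramImage(gray)
    out, _ = sv_perturb(img, SvPerturbParams(1.0, 0.3))
    np.testing.assert_array_equal(out.pixels, img.pixels)


def test_sv_sampled_bounds(random_image):
    rng = np.random.default_rng(2)
    for _ in range(50):
        _, p = sv_perturb(random_image, rng=rng)
        assert 0.5 <= p.alpha_brightness <= 2.0
        assert 0.1 <= p.alpha_saturation <= 2.0


def test_pca_identities(random_image):
    out, _ = pca_color_augment(random_image, alpha=0.0)
    np.testing.assert_array_equal(out.pixels, random_image.pixels)
    const = SpectrogramImage(np.full((100, 180, 3), 55, np.uint8))
    out, _ = pca_color_augment(const, alpha=812.0)
    np.testing.assert_array_equal(out.pixels, const.pixels)


def _eig3_oracle(cov):
    """Characteristic-polynomial eigensolver, independent of LAPACK eigh."""
    c2 = -np.trace(cov)
    c1 = 0.5 * (np.trace(cov) ** 2 - np.trace(cov @ cov))
    c0 = -np.linalg.det(cov)
    lams = np.sort(np.roots([1.0, c2, c1, c0]).real)
    vecs = []
    for lam in lams:
        a = cov - lam * np.eye(3)
        # eigenvector from the cross product of two independent rows
        candidates = [np.cross(a[i], a[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        v = max(candidates, key=lambda c: np.linalg.norm(c))
        v = v / np.linalg.norm(v)
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
        vecs.append(v)
    return lams, np.stack(vecs, axis=1)


def test_pca_matches_characteristic_polynomial_oracle():
    rng = np.random.default_rng(8)
    tile = rng.integers(0, 256, (2, 2, 3)).astype(np.uint8)
    pixels = np.tile(tile, (50, 90, 1))  # 4 distinct pixels, full-size image
    img = SpectrogramImage(pixels)
    alpha = 0.37  # small alpha keeps the perturbation inside [0, 255]
    out, _ = pca_color_augment(img, alpha=alpha)
    flat = pixels.reshape(-1, 3).astype(float)
    cov = np.cov(flat.T)
    lams, vecs = _eig3_oracle(cov)
    delta = vecs @ (alpha * lams)
    expected = np.clip(np.round(flat + delta), 0, 255).reshape(pixels.shape)
    np.testing.assert_array_equal(out.pixels, expected.astype(np.uint8))


def test_color_filter_registry(random_image):
    reg = registry()
    assert len(reg) == REGISTRY_SIZE == 150
    assert len({name for name, _ in reg}) == 150
    np.testing.assert_array_equal(reg[0][1](random_image.pixels), random_image.pixels)
    a, name_a = random_color_filter(random_image, rng=np.random.default_rng(4))
    b, name_b = random_color_filter(random_image, rng=np.random.default_rng(4))
    assert name_a == name_b
    np.testing.assert_array_equal(a.pixels, b.pixels)
    assert a.pixels.shape == (100, 180, 3)


def test_mask_zero_widths_identity(random_mel):
    params = MaskParams(freq_masks=((5, 0), (9, 0), (2, 0)), time_masks=((0, 0), (7, 0), (1, 0)))
    out, _ = time_frequency_mask(random_mel, params=params)
    np.testing.assert_array_equal(out.values, random_mel.values)


def test_mask_bounds_and_fill(random_mel):
    rng = np.random.default_rng(6)
    for _ in range(20):
        params = sample_mask_params(random_mel, rng)
        out, _ = time_frequency_mask(random_mel, params=params)
        masked_rows = np.unique(
            np.concatenate([np.arange(f0, f0 + f) for f0, f in params.freq_masks])
        )
        masked_cols = np.unique(
            np.concatenate([np.arange(t0, t0 + t) for t0, t in params.time_masks])
        )
        assert masked_rows.size <= 60 and masked_cols.size <= 60
        for f0, f in params.freq_masks:
            assert 0 < f0 and f0 + f <= random_mel.n_channels and f <= 20
            assert np.all(out.values[f0 : f0 + f, :] == 0.0)
        for t0, t in params.time_masks:
            assert 0 <= t0 and t0 + t <= random_mel.n_steps and t <= 20
            assert np.all(out.values[:, t0 : t0 + t] == 0.0)
        # untouched cells unchanged
        keep = np.ones(random_mel.values.shape, bool)
        keep[masked_rows, :] = False
        keep[:, masked_cols] = False
        np.testing.assert_array_equal(out.values[keep], random_mel.values[keep])


def test_mask_determinism_and_small_input(random_mel):
    a, pa = time_frequency_mask(random_mel, rng=np.random.default_rng(9))
    b, pb = time_frequency_mask(random_mel, rng=np.random.default_rng(9))
    assert pa == pb
    np.testing.assert_array_equal(a.values, b.values)
    tiny = MelSpectrogram(np.zeros((10, 10)), np.arange(10.0), np.arange(10.0))
    with pytest.raises(ValueError):
        time_frequency_mask(tiny, rng=np.random.default_rng(0))


def test_composition_contracts(random_image):
    # PCA alpha=0 then hflip == hflip alone
    ident, _ = pca_color_augment(random_image, alpha=0.0)
    np.testing.assert_array_equal(hflip(ident).pixels, hflip(random_image).pixels)
    # SV alpha=1 then hflip == hflip alone
    ident, _ = sv_perturb(random_image, SvPerturbParams(1.0, 1.0))
    np.testing.assert_array_equal(hflip(ident).pixels, hflip(random_image).pixels)
    # composed operator equals running the two operators in sequence
    composed, params = compose_method(random_image, "pca", "hflip", rng=np.random.default_rng(3))
    manual, alpha = pca_color_augment(random_image, rng=np.random.default_rng(3))
    np.testing.assert_array_equal(composed.pixels, hflip(manual).pixels)
    assert params["first"]["alpha"] == alpha
    with pytest.raises(ValueError):
        compose_method(random_image, "pca", "mask", rng=np.random.default_rng(0))


def test_hflip_commutes_with_per_pixel_ops(random_image):
    sv_then_flip, _ = sv_perturb(hflip(random_image).copy(), SvPerturbParams(1.3, 0.7))
    flip_then_sv = hflip(sv_perturb(random_image, SvPerturbParams(1.3, 0.7))[0])
    np.testing.assert_array_equal(sv_then_flip.pixels, flip_then_sv.pixels)
    f_a, _ = random_color_filter(hflip(random_image), index=37)
    f_b = hflip(random_color_filter(random_image, index=37)[0])
    np.testing.assert_array_equal(f_a.pixels, f_b.pixels)
    # PCA statistics are permutation-invariant over pixels, so it commutes too
    p_a, _ = pca_color_augment(hflip(random_image), alpha=0.4)
    p_b = hflip(pca_color_augment(random_image, alpha=0.4)[0])
    np.testing.assert_array_equal(p_a.pixels, p_b.pixels)


# ------------------------------------------------------------------- doubling


def _items_for(method, rng):
    if method in ("pitch_time", "noise"):
        recs = [generate_recording(i % 2, seed=40 + i, duration=8.0) for i in range(4)]
        return [TrainingItem(f"r{i}", r.label, r) for i, r in enumerate(recs)]
    if method == "mask":
        mels = [
            MelSpectrogram(rng.uniform(-80, 0, (128, 60)), np.arange(60.0), np.arange(128.0))
            for _ in range(4)
        ]
        return [TrainingItem(f"r{i}", i % 2, m) for i, m in enumerate(mels)]
    imgs = [
        SpectrogramImage(rng.integers(0, 256, (100, 180, 3)).astype(np.uint8)) for _ in range(4)
    ]
    return [TrainingItem(f"r{i}", i % 2, im) for i, im in enumerate(imgs)]


@pytest.mark.parametrize(
    "method",
    ["pitch_time", "noise", "hflip", "vflip", "sv", "pca", "color_filter", "mask",
     "hflip_pca", "hflip_sv"],
)
def test_one_to_one_doubling_preserves_labels(method, rng):
    items = _items_for(method, rng)
    out = augment_training_set(items, method, master_seed=5)
    assert len(out) == 2 * len(items)
    originals, augmented = out[: len(items)], out[len(items) :]
    for orig, twin in zip(originals, augmented):
        assert twin.label == orig.label
        assert twin.source_id == orig.record_id
        assert twin.spec is not None and twin.spec.method == method
        if method not in ("pitch_time", "noise", "mask"):
            assert twin.payload.pixels.shape == (100, 180, 3)
            assert twin.payload.pixels.dtype == np.uint8


def test_doubling_class_counts():
    rng = np.random.default_rng(0)
    imgs = [
        SpectrogramImage(rng.integers(0, 256, (100, 180, 3)).astype(np.uint8))
        for _ in range(10)
    ]
    labels = [0] * 8 + [1] * 2
    items = [TrainingItem(f"r{i}", lab, im) for i, (lab, im) in enumerate(zip(labels, imgs))]
    out = augment_training_set(items, "hflip", master_seed=1)
    assert len(out) == 20
    assert sum(1 for i in out if i.label == 0) == 16
    assert sum(1 for i in out if i.label == 1) == 4
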