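"""Synchrosqueezed features: localization, shape chain, reduction oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cardiomech import (
    RunConfig,
    SynthSpec,
    class_atoms,
    extract_features,
    feature_matrix,
    flatten,
    generate_subject,
    preprocess_recording,
    reduce_to_image,
    split_and_truncate,
    sst_transform,
)
from cardiomech.sst import cwt_morlet, frequency_grid
from cardiomech.errors import ShapeError, ValidationError

FS = 250.0
T = np.arange(2500) / FS


def band_fraction(plane, lo, hi):
    total = plane.values.sum()
    mask = (plane.freq_axis >= lo) & (plane.freq_axis <= hi)
    return plane.values[mask].sum() / total


def test_zero_series_gives_zero_plane():
    plane = sst_transform(np.zeros(2500), FS)
    assert plane.values.shape == (178, 2500)
    assert plane.values.sum() == 0.0


def test_pure_tone_energy_concentrates_within_2hz():
    plane = sst_transform(np.sin(2 * np.pi * 10.0 * T), FS)
    assert band_fraction(plane, 8.0, 12.0) >= 0.70


def test_two_tones_produce_two_disjoint_bands():
    x = np.sin(2 * np.pi * 5.0 * T) + np.sin(2 * np.pi * 20.0 * T)
    plane = sst_transform(x, FS)
    assert band_fraction(plane, 4.0, 6.0) >= 0.30
    assert band_fraction(plane, 18.0, 22.0) >= 0.30
    assert band_fraction(plane, 8.0, 16.0) <= 0.10


def test_synchrosqueezing_sharpens_the_scalogram():
    x = np.sin(2 * np.pi * 10.0 * T)
    freqs = frequency_grid(FS)
    plane = sst_transform(x, FS, freqs)
    W, _ = cwt_morlet(x, FS, freqs)
    scalogram = np.abs(W)

    def in_band(mag):
        p = mag.sum(axis=1)
        return p[(freqs >= 8.0) & (freqs <= 12.0)].sum() / p.sum()

    # reallocation concentrates strictly more tone energy within +/-2 Hz
    assert in_band(plane.values) > in_band(scalogram) + 0.2


def test_nonfinite_input_rejected():
    x = np.zeros(2500)
    x[7] = np.nan
    with pytest.raises(ValidationError):
        sst_transform(x, FS)


def test_split_yields_ten_150_by_250_planes():
    plane = sst_transform(np.random.default_rng(0).standard_normal(2500), FS)
    parts = split_and_truncate(plane)
    assert len(parts) == 10
    assert all(p.shape == (150, 250) for p in parts)


def test_tone_above_cutoff_removed_by_truncation():
    plane = sst_transform(np.sin(2 * np.pi * 45.0 * T), FS)
    parts = split_and_truncate(plane)
    kept = sum(p.sum() for p in parts)
    assert kept < 0.05 * plane.values.sum()


def test_impulse_energy_stays_in_its_cycle():
    x = np.zeros(2500)
    x[700] = 1.0
    parts = split_and_truncate(sst_transform(x, FS))
    shares = np.array([p.sum() for p in parts])
    shares = shares / shares.sum()
    assert int(np.argmax(shares)) == 2
    assert shares[2] > 0.5


def test_wrong_column_count_rejected():
    plane = sst_transform(np.zeros(2500), FS)
    plane.values = plane.values[:, :2000]
    with pytest.raises(ShapeError):
        split_and_truncate(plane)


def test_regridding_standardises_row_count():
    # a transform run on a non-standard grid still yields 150 band rows
    freqs = frequency_grid(FS, n_rows=120, band_rows=100)
    plane = sst_transform(np.sin(2 * np.pi * 10.0 * T), FS, freqs)
    parts = split_and_truncate(plane)
    assert all(p.shape == (150, 250) for p in parts)


def test_reduce_constant_plane_maps_to_zero():
    out = reduce_to_image(np.ones((150, 250)))
    assert out.shape == (30, 25)
    assert np.all(out == 0.0)


def test_reduce_matches_brute_force_block_means():
    rng = np.random.default_rng(5)
    m = rng.random((150, 250))
    out = reduce_to_image(m)
    brute = np.empty((30, 25))
    for i in range(30):
        for j in range(25):
            brute[i, j] = m[5 * i : 5 * (i + 1), 10 * j : 10 * (j + 1)].mean()
    brute = (brute - brute.min()) / (brute.max() - brute.min())
    np.testing.assert_allclose(out, brute, atol=1e-12)
    assert out.min() == 0.0 and out.max() == 1.0


@given(st.floats(0.1, 100.0))
def test_reduction_is_invariant_to_positive_scaling(c):
    m = np.random.default_rng(11).random((150, 250))
    np.testing.assert_allclose(reduce_to_image(c * m), reduce_to_image(m), atol=1e-9)


def test_flatten_is_row_major_and_invertible():
    img = np.zeros((30, 25))
    img[2, 3] = 1.0
    vec = flatten(img)
    assert vec.size == 750
    assert vec[2 * 25 + 3] == 1.0 and vec.sum() == 1.0
    np.testing.assert_array_equal(vec.reshape(30, 25), img)
    with pytest.raises(ShapeError):
        flatten(np.zeros((25, 30)))


class TestExtractFeatures:
    def test_sixty_seconds_at_60bpm_yields_50_vectors_per_channel(self):
        spec = SynthSpec(duration_s=60.0, hr_sd_bpm=0.0, seed=1)
        rec = generate_subject(spec, "nonCAD", 31, "s")
        feats = extract_features(preprocess_recording(rec))
        assert set(feats) == {"scg_x", "scg_y", "scg_z", "gcg_x", "gcg_y", "gcg_z"}
        for vectors in feats.values():
            assert len(vectors) == 50  # 59 cycles -> 5 series -> 50 cycles
            for v in vectors:
                assert v.values.shape == (750,)
                assert v.values.min() >= 0.0 and v.values.max() <= 1.0 + 1e-12

    def test_class_difference_appears_at_the_shifted_atom_frequency(self):
        spec = SynthSpec(duration_s=60.0, separation=1.0, noise_sd=0.02, seed=6)
        cad = generate_subject(spec, "CAD", 51, "a")
        non = generate_subject(spec, "nonCAD", 52, "b")
        img_cad = feature_matrix(
            extract_features(preprocess_recording(cad))["scg_z"]
        ).mean(axis=0).reshape(30, 25)
        img_non = feature_matrix(
            extract_features(preprocess_recording(non))["scg_z"]
        ).mean(axis=0).reshape(30, 25)
        diff = np.abs(img_cad - img_non).sum(axis=1)
        freqs = frequency_grid(FS)[:150][2::5]  # centre of each 5-row block
        f_hot = freqs[int(np.argmax(diff))]
        f_base = class_atoms(spec, "nonCAD")[1][1]
        f_cad = class_atoms(spec, "CAD")[1][1]
        assert min(f_base, f_cad) * 0.7 <= f_hot <= f_cad * 1.4
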