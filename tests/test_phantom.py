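"""Phantom generator, artifact injectors and manifests."""

import numpy as np
import pytest

from dwiqc import phantom
from dwiqc.directional import accumulate, build_bins, entropy
from dwiqc.intensity import interlace_check, slice_wise_check
from dwiqc.io import Protocol


def noise_free(scheme6, seed=4, dims=(16, 16, 16)):
    return phantom.make_phantom(dims=dims, scheme=scheme6, snr=None,
                                seed=seed)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def test_same_seed_bit_identical(scheme6):
    a, _ = phantom.make_phantom(dims=(16, 16, 16), scheme=scheme6, seed=5)
    b, _ = phantom.make_phantom(dims=(16, 16, 16), scheme=scheme6, seed=5)
    np.testing.assert_array_equal(a.signal, b.signal)
    c, _ = phantom.make_phantom(dims=(16, 16, 16), scheme=scheme6, seed=6)
    assert not np.array_equal(a.signal, c.signal)


def test_noise_free_signal_matches_model(scheme6):
    scan, manifest = noise_free(scheme6)
    tensors, mask, _ = phantom.true_tensor_field(manifest.dims,
                                                 manifest.tensor_layout)
    dirs, bvals = scheme6.full_table()
    quad = np.einsum("ni,xyzij,nj->xyzn", dirs, tensors, dirs)
    expected = 1000.0 * np.exp(-bvals * quad)
    expected[~mask] = 0.0
    np.testing.assert_allclose(scan.signal, expected, rtol=1e-12)
    assert (scan.signal[~mask] == 0).all()


def test_manifest_json_round_trip(tmp_path, clean_phantom):
    _, manifest = clean_phantom
    path = tmp_path / "m.json"
    manifest.to_json(path)
    back = phantom.PhantomManifest.from_json(path)
    assert back == manifest


def test_sample_layout_reproducible():
    a = phantom.sample_layout(np.random.default_rng(3))
    b = phantom.sample_layout(np.random.default_rng(3))
    assert a == b
    assert sum(a["proportions"]) == pytest.approx(1.0)
    R = np.asarray(a["axis_rotation"])
    np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
    assert 0.42 <= a["ellipsoid_factor"] <= 0.48


def test_layout_validation():
    with pytest.raises(ValueError, match="16"):
        phantom.true_tensor_field((8, 16, 16))
    cramped = dict(phantom.CANONICAL_LAYOUT)
    cramped["ellipsoid_factor"] = 0.30
    with pytest.raises(ValueError, match="cuboid"):
        phantom.true_tensor_field((24, 24, 24), cramped)


def test_equal_blocks_level0_entropy_near_ln3():
    layout = dict(phantom.CANONICAL_LAYOUT)
    layout["dispersion"] = 0.0
    _, _, lay = phantom.true_tensor_field((24, 24, 24), layout)
    pds = []
    for blk in lay["blocks"]:
        (a, b), (y0, y1), (z0, z1) = (blk["x_range"], blk["y_range"],
                                      blk["z_range"])
        n = (b - a) * (y1 - y0) * (z1 - z0)
        pds.append(np.tile(blk["pd_axis"], (n, 1)))
    hist = accumulate(build_bins(0), np.vstack(pds))
    assert int((hist.counts > 0).sum()) == 3
    H = entropy(hist)
    assert abs(H - np.log(3.0)) / np.log(3.0) < 0.05


# ---------------------------------------------------------------------------
# injectors (noise-free: effects are exact)
# ---------------------------------------------------------------------------

def test_slice_dropout_scales_the_clean_slice(scheme6):
    scan, manifest = noise_free(scheme6)
    ref = scan.signal.copy()
    phantom.inject_slice_dropout(scan, manifest, volume=3, slice_index=8,
                                 factor=0.3)
    np.testing.assert_allclose(scan.signal[:, :, 8, 3], 0.3 * ref[:, :, 8, 3],
                               rtol=1e-12)
    other = np.ones(16, dtype=bool)
    other[8] = False
    np.testing.assert_allclose(scan.signal[:, :, other, 3],
                               ref[:, :, other, 3], rtol=1e-12)
    untouched = [v for v in range(scan.n_volumes) if v != 3]
    np.testing.assert_array_equal(scan.signal[..., untouched],
                                  ref[..., untouched])
    assert manifest.artifacts == [{"type": "slice_dropout", "volume": 3,
                                   "slices": [8], "magnitude": 0.3}]


def test_repeated_dropout_composes_multiplicatively(scheme6):
    scan, manifest = noise_free(scheme6)
    ref = scan.signal.copy()
    phantom.inject_slice_dropout(scan, manifest, 3, 8, 0.5)
    phantom.inject_slice_dropout(scan, manifest, 3, 8, 0.4)
    assert len(manifest.artifacts) == 2
    np.testing.assert_allclose(scan.signal[:, :, 8, 3],
                               0.2 * ref[:, :, 8, 3], rtol=1e-12)


def test_venetian_blind_scales_even_slices(scheme6):
    scan, manifest = noise_free(scheme6)
    ref = scan.signal.copy()
    phantom.inject_venetian_blind(scan, manifest, volume=2, factor=0.6)
    np.testing.assert_allclose(scan.signal[:, :, 0::2, 2],
                               0.6 * ref[:, :, 0::2, 2], rtol=1e-12)
    np.testing.assert_allclose(scan.signal[:, :, 1::2, 2],
                               ref[:, :, 1::2, 2], rtol=1e-12)


def test_directional_bias_affected_set_exact(scheme42):
    scan, manifest = phantom.make_phantom(scheme=scheme42, snr=None, seed=4)
    axis = np.array([1.0, 0.0, 0.0])
    threshold = 0.8
    expected = np.flatnonzero(
        (np.abs(scan.gradients.directions @ axis) > threshold)
        & ~scan.baseline_mask).tolist()
    assert expected                      # the scheme covers the x pole
    ref = scan.signal.copy()
    phantom.inject_directional_bias(scan, manifest, axis, threshold, 0.5)
    rec = manifest.artifacts[0]
    assert rec["volume"] == expected
    assert rec["slices"] is None
    for v in expected:
        np.testing.assert_allclose(scan.signal[..., v], 0.5 * ref[..., v],
                                   rtol=1e-12)
    clean = [v for v in range(scan.n_volumes) if v not in expected]
    np.testing.assert_array_equal(scan.signal[..., clean], ref[..., clean])


def test_directional_bias_no_match_records_empty(scheme6):
    scan, manifest = noise_free(scheme6)
    ref = scan.signal.copy()
    phantom.inject_directional_bias(scan, manifest, (1.0, 0.0, 0.0),
                                    0.9999, 0.5)
    assert manifest.artifacts[0]["volume"] == []
    np.testing.assert_array_equal(scan.signal, ref)


def test_injector_argument_validation(scheme6):
    scan, manifest = noise_free(scheme6)
    with pytest.raises(ValueError):
        phantom.inject_slice_dropout(scan, manifest, 1, 2, 1.0)
    with pytest.raises(IndexError):
        phantom.inject_slice_dropout(scan, manifest, 99, 2, 0.5)
    with pytest.raises(IndexError):
        phantom.inject_slice_dropout(scan, manifest, 1, 99, 0.5)
    with pytest.raises(ValueError):
        phantom.inject_venetian_blind(scan, manifest, 1, 0.0)
    with pytest.raises(ValueError):
        phantom.inject_directional_bias(scan, manifest, (1, 0, 0), 1.5, 0.5)


def test_injection_is_deterministic_on_noisy_phantoms(scheme42):
    pair = []
    for _ in range(2):
        scan, manifest = phantom.make_phantom(scheme=scheme42, seed=11)
        phantom.inject_slice_dropout(scan, manifest, 5, 12, 0.35)
        pair.append(scan.signal)
    np.testing.assert_array_equal(pair[0], pair[1])


# ---------------------------------------------------------------------------
# cross-module: injected artifacts are recoverable by the QC stages
# ---------------------------------------------------------------------------

def test_severe_dropout_detected_by_slice_wise(scheme42, protocol):
    scan, manifest = phantom.make_phantom(scheme=scheme42, seed=21)
    vol = int(np.flatnonzero(~scan.baseline_mask)[4])
    phantom.inject_slice_dropout(scan, manifest, vol, 12,
                                 phantom.ARTIFACT_PRESETS["severe"])
    _, verdicts = slice_wise_check(scan, protocol)
    assert verdicts[vol] is not None
    assert "12" in verdicts[vol]


def test_severe_venetian_detected_by_interlace(scheme42, protocol):
    scan, manifest = phantom.make_phantom(scheme=scheme42, seed=22)
    vol = int(np.flatnonzero(~scan.baseline_mask)[7])
    phantom.inject_venetian_blind(scan, manifest, vol,
                                  phantom.ARTIFACT_PRESETS["severe"])
    res = interlace_check(scan, protocol)
    assert res.flagged[vol]


def test_severe_bias_drops_entropy_by_sigmas(scheme42, protocol,
                                             trained_stats):
    from dwiqc.directional import scan_entropy
    scan, manifest = phantom.make_phantom(scheme=scheme42, seed=23)
    clean_H = scan_entropy(scan, protocol)
    phantom.inject_directional_bias(scan, manifest, (1.0, 0.0, 0.0), 0.8,
                                    phantom.ARTIFACT_PRESETS["severe"])
    biased_H = scan_entropy(scan, protocol)
    assert clean_H - biased_H > 3.0 * trained_stats.sd_entropy


def test_make_cohort_shapes_and_manifests(scheme6):
    clean, art = phantom.make_cohort(2, 3, seed=9, dims=(16, 16, 16),
                                     scheme=scheme6,
                                     artifact="slice_dropout")
    assert len(clean) == 2 and len(art) == 3
    assert all(not m.artifacts for _, m in clean)
    for scan, m in art:
        assert len(m.artifacts) == 1
        rec = m.artifacts[0]
        assert rec["type"] == "slice_dropout"
        assert not scan.baseline_mask[rec["volume"]]
        assert 4 <= rec["slices"][0] < 12     # central band of 16 slices
    seeds = [m.seed for _, m in clean + art]
    assert len(set(seeds)) == len(seeds)
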