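"""Stimulus protocol, dipole waveforms, phantom and sensitivity generators."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import erf

from megdot import megfeat, synthgen as sg


# ---------------------------------------------------------------------------
# Stimulus trains and run schedules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("frequency,n_expected", [(0.5, 2), (1.0, 3), (2.0, 5), (4.0, 9)])
def test_stimulus_train_protocol(frequency, n_expected):
    tr = sg.make_stimulus_train(frequency)
    assert tr.n_stimuli == n_expected
    assert tr.duration == pytest.approx(2.0002, abs=1e-12)
    assert tr.onsets[0] == 0.0
    assert np.all(np.diff(tr.onsets) > 0)
    np.testing.assert_allclose(tr.onsets, np.arange(n_expected) / frequency)


def test_stimulus_train_rejects_nonpositive_frequency():
    with pytest.raises(ValueError):
        sg.make_stimulus_train(0.0)
    with pytest.raises(ValueError):
        sg.make_stimulus_train(-1.0)


def test_stimulus_train_warns_off_protocol():
    with pytest.warns(UserWarning):
        tr = sg.make_stimulus_train(3.0)
    assert tr.n_stimuli == 7


def test_run_schedule_counts_and_rests():
    sched = sg.make_run_schedule(seed=42, n_repetitions=15)
    assert sched.n_blocks == 60
    freqs = sched.frequencies
    for f in sg.PROTOCOL_FREQUENCIES:
        assert np.sum(freqs == f) == 15
    assert np.all(sched.rest_durations >= 14.0)
    assert np.all(sched.rest_durations <= 65.0)
    # no frequency more than 3 times in a row
    run = 1
    for a, b in zip(freqs[:-1], freqs[1:]):
        run = run + 1 if a == b else 1
        assert run <= 3
    # blocks do not overlap
    starts = sched.onset_times
    assert np.all(np.diff(starts) > 2.0)


def test_run_schedule_deterministic_and_minimal():
    a = sg.make_run_schedule(seed=7)
    b = sg.make_run_schedule(seed=7)
    assert np.array_equal(a.frequencies, b.frequencies)
    np.testing.assert_allclose(a.rest_durations, b.rest_durations)
    small = sg.make_run_schedule(seed=0, n_repetitions=1)
    assert small.n_blocks == 4
    assert sorted(small.frequencies) == sorted(sg.PROTOCOL_FREQUENCIES)
    with pytest.raises(ValueError):
        sg.make_run_schedule(seed=0, n_repetitions=0)
    with pytest.raises(ValueError):
        sg.make_run_schedule(seed=0, rest_range=(30.0, 20.0))


# ---------------------------------------------------------------------------
# Dipole waveforms and habituation
# ---------------------------------------------------------------------------

def test_habituation_factor_formula():
    # ISI = 2 s, tau = 0.5 s -> 1 - e^-4
    assert sg.habituation_factor(2.0, 0.5) == pytest.approx(1.0 - np.exp(-4.0), abs=1e-12)
    assert sg.habituation_factor(0.25, 0.0) == 1.0
    with pytest.raises(ValueError):
        sg.habituation_factor(1.0, -1.0)


def test_no_habituation_in_tau_zero_limit():
    params = sg.DipoleSimParams(taus={k: 0.0 for k in ("N20m", "P35m", "P60m", "SII")})
    tf = sg.true_feature_amplitudes(params)
    for (f, feat), grp in tf.groupby(["frequency", "feature_id"]):
        vals = grp.sort_values("stimulus_index")["value"].to_numpy()
        np.testing.assert_allclose(vals, vals[0], rtol=1e-12)


def test_habituation_monotonic_in_frequency():
    """For stimuli k >= 2 the feature amplitude never grows with rate."""
    tf = sg.true_feature_amplitudes(sg.DipoleSimParams())
    for feat in ("N20m", "P35m", "P60m", "SII60-200ms"):
        sub = tf[(tf.feature_id == feat) & (tf.stimulus_index == 1)]
        vals = sub.set_index("frequency")["value"].abs()
        ordered = vals.loc[list(sg.PROTOCOL_FREQUENCIES)].to_numpy()
        assert np.all(np.diff(ordered) <= 1e-12)


def test_dipole_epoch_window_and_errors():
    tr = sg.make_stimulus_train(4.0)
    rec = sg.simulate_dipole_waveforms(sg.DipoleSimParams(), tr, noise_sd=0.0)
    assert rec.t[0] == pytest.approx(-0.2)
    assert rec.t[-1] == pytest.approx(tr.onsets[-1] + 0.25, abs=2e-3)
    assert rec.fs == 1000.0
    with pytest.raises(ValueError):
        sg.simulate_dipole_waveforms(sg.DipoleSimParams(), tr, fs=500.0)
    with pytest.raises(ValueError):
        sg.simulate_dipole_waveforms(sg.DipoleSimParams(), tr, post=0.1)


def _model_window_integral(params, train, k_stim, lo_ms, hi_ms, dipole="SI"):
    """Closed-form (erf) integral of the noiseless waveform over a window.

    The window is expressed in ms relative to stimulus ``k_stim``; all
    lobes of all stimuli contribute, so this is an independent oracle
    for the trapezoidal AUC of the generated signal.
    """
    lobes = ("N20m", "P35m", "P60m") if dipole == "SI" else ("SII",)
    amps = sg._stimulus_amplitudes(params, train)
    onset = train.onsets[k_stim] * 1000.0
    total = 0.0
    for kk, ons in enumerate(train.onsets):
        for name in lobes:
            mu, sigma, sign = params.lobes[name]
            c = ons * 1000.0 + mu
            a = sign * amps[name][kk]
            z1 = (onset + lo_ms - c) / (np.sqrt(2) * sigma)
            z2 = (onset + hi_ms - c) / (np.sqrt(2) * sigma)
            total += a * sigma * np.sqrt(np.pi / 2) * (erf(z2) - erf(z1))
    return total / 1000.0        # nAm ms -> nAm s


@pytest.mark.parametrize("frequency", [0.5, 4.0])
def test_extracted_auc_matches_closed_form(frequency):
    """Feature AUCs agree with the analytic lobe integrals within 2%."""
    params = sg.DipoleSimParams()
    tr = sg.make_stimulus_train(frequency)
    rec = sg.simulate_dipole_waveforms(params, tr, noise_sd=0.0)
    rec = megfeat.remove_baseline_drift(rec)
    table = megfeat.extract_features(rec)
    for _, row in table[table.feature_id.isin(["N20m", "P35m", "P60m"])].iterrows():
        expected = _model_window_integral(
            params, tr, int(row.stimulus_index), row.window_begin_ms, row.window_end_ms)
        assert row.value == pytest.approx(expected, rel=0.02), row.feature_id


def test_noise_free_rms_matches_model():
    params = sg.DipoleSimParams()
    tr = sg.make_stimulus_train(0.5)
    rec = sg.simulate_dipole_waveforms(params, tr, noise_sd=0.0)
    table = megfeat.extract_features(rec)
    model = sg.true_feature_amplitudes(params, {0.5: tr})
    for feat in ("SI_RMS", "SII_RMS"):
        got = table[(table.feature_id == feat) & (table.stimulus_index == 0)].value.iloc[0]
        want = model[(model.feature_id == feat) & (model.frequency == 0.5)
                     & (model.stimulus_index == 0)].value.iloc[0]
        assert got == pytest.approx(want, rel=0.02)


# ---------------------------------------------------------------------------
# Head phantom and probe
# ---------------------------------------------------------------------------

def test_head_phantom_partition_and_masks(small_head):
    labels = small_head.labels
    assert labels.shape == small_head.shape
    assert set(np.unique(labels)) <= set(range(len(small_head.tissue_names)))
    gm = small_head.gm_mask
    assert gm.sum() > 0
    assert not np.any(gm & small_head.mask("scalp"))


def test_head_phantom_tissue_parameters(small_head):
    mua, mus, g, n = small_head.optical_parameters("gray_matter")
    assert mua == 0.032
    assert mus == 69.5
    assert small_head.optical_parameters("scalp")[0] == 0.0164


def test_head_phantom_errors():
    with pytest.raises(ValueError):
        sg.build_head_phantom((10, 10, 10))
    with pytest.raises(ValueError):
        sg.build_head_phantom((24, 24, 16), 2.0, layers=(
            ("scalp", 20.0), ("skull", 20.0), ("gray_matter", None)))


def test_head_phantom_nifti_roundtrip(small_head, tmp_path):
    img = small_head.to_nifti()
    path = tmp_path / "labels.nii.gz"
    import nibabel as nib

    nib.save(img, path)
    back = nib.load(path)
    assert np.array_equal(np.asarray(back.dataobj), small_head.labels)


def test_probe_geometry_counts_and_gates(small_layout):
    assert len(small_layout.positions) == 32
    sep = small_layout.separations
    assert np.all(sep >= 10.0) and np.all(sep <= 40.0)


def test_probe_geometry_pitch_scaling():
    a = sg.build_probe_geometry(pitch_mm=10.0, min_separation=0.0, max_separation=None)
    b = sg.build_probe_geometry(pitch_mm=20.0, min_separation=0.0, max_separation=None)
    np.testing.assert_allclose(b.separations, 2.0 * a.separations)


def test_probe_geometry_no_pairs_error():
    with pytest.raises(ValueError):
        sg.build_probe_geometry(pitch_mm=1.0, min_separation=50.0, max_separation=60.0)


# ---------------------------------------------------------------------------
# Sensitivity kernels
# ---------------------------------------------------------------------------

def test_sensitivity_nonpositive_and_finite(small_sens):
    for J in small_sens.J.values():
        assert np.all(J <= 0)
        assert np.all(np.isfinite(J))


def test_sensitivity_decays_with_depth(small_head, small_layout, small_sens):
    """|J| decreases monotonically down the column under a pair midpoint."""
    J = small_sens.J[758]
    pair = int(np.argmax(small_layout.separations))
    si, di = small_layout.pairs[pair]
    mid = 0.5 * (small_layout.sources[si] + small_layout.detectors[di])
    centers = small_head.voxel_centers()
    nx, ny, nz = small_head.shape
    lateral = centers[:, :2] - mid[:2]
    col = np.argmin(np.linalg.norm(lateral, axis=1))
    i, j, _ = np.unravel_index(col, small_head.shape)
    col_idx = [np.ravel_multi_index((i, j, k), small_head.shape) for k in range(nz)]
    profile = np.abs(J[pair, col_idx])
    assert np.all(np.diff(profile) < 0)


def test_sensitivity_banana_shape(small_head, small_layout, small_sens):
    """The most-sensed GM voxel lies laterally between source and detector."""
    J = small_sens.J[758]
    gm_flat = small_head.gm_mask.ravel()
    centers = small_head.voxel_centers()
    pair = int(np.argmax(small_layout.separations))
    si, di = small_layout.pairs[pair]
    s, d = small_layout.sources[si], small_layout.detectors[di]
    row = np.where(gm_flat, np.abs(J[pair]), 0.0)
    v = centers[np.argmax(row)]
    lo = np.minimum(s[:2], d[:2]) - 1e-6
    hi = np.maximum(s[:2], d[:2]) + 1e-6
    assert np.all(v[:2] >= lo) and np.all(v[:2] <= hi)


# ---------------------------------------------------------------------------
# Optical run simulation
# ---------------------------------------------------------------------------

def _tiny_run(head, sens, layout, truth, seed=0, noise=None):
    sched = sg.make_run_schedule(seed=3, n_repetitions=1)
    feats = sg.true_feature_amplitudes(sg.DipoleSimParams())
    return sg.simulate_optical_run(
        sched, truth, feats, sens, head,
        noise_cfg=noise or sg.NoiseConfig.off(), seed=seed, layout=layout)


def test_optical_run_reproducible(small_head, small_sens, small_layout):
    truth = sg.GroundTruth.null()
    noise = sg.NoiseConfig()
    a = _tiny_run(small_head, small_sens, small_layout, truth, seed=5, noise=noise)
    b = _tiny_run(small_head, small_sens, small_layout, truth, seed=5, noise=noise)
    assert np.array_equal(a.A, b.A)
    assert a.A.shape[0] == small_sens.n_pairs
    assert np.all(a.A > 0)


def test_optical_run_null_is_flat(small_head, small_sens, small_layout):
    rec = _tiny_run(small_head, small_sens, small_layout, sg.GroundTruth.null())
    assert np.ptp(rec.A, axis=-1).max() == pytest.approx(0.0, abs=1e-12)


def test_optical_run_linearity_in_beta(small_head, small_sens, small_layout):
    region = sg.make_ball_region(small_head, radius_mm=6.0)
    t1 = sg.GroundTruth(active_regions={"SI-like": region},
                        coupling={("SI-like", "P35m"): 5.0})
    t2 = sg.GroundTruth(active_regions={"SI-like": region},
                        coupling={("SI-like", "P35m"): 10.0})
    a = _tiny_run(small_head, small_sens, small_layout, t1)
    b = _tiny_run(small_head, small_sens, small_layout, t2)
    la, lb = np.log(a.A), np.log(b.A)
    la -= la[..., :1]
    lb -= lb[..., :1]
    np.testing.assert_allclose(lb, 2.0 * la, atol=5e-6)


def test_ground_truth_region_must_be_gray_matter(small_head, small_sens, small_layout):
    scalp_vox = np.nonzero(small_head.mask("scalp").ravel())[0][:5]
    truth = sg.GroundTruth(active_regions={"bad": scalp_vox},
                           coupling={("bad", "P35m"): 1.0})
    with pytest.raises(ValueError):
        _tiny_run(small_head, small_sens, small_layout, truth)


def test_optical_recording_hdf5_roundtrip(small_head, small_sens, small_layout,
                                          tmp_path):
    import h5py

    rec = _tiny_run(small_head, small_sens, small_layout, sg.GroundTruth.null(),
                    noise=sg.NoiseConfig())
    path = tmp_path / "run.h5"
    rec.save_hdf5(path)
    with h5py.File(path) as f:
        np.testing.assert_array_equal(f["A"][...], rec.A)
        assert f.attrs["fs"] == rec.fs
        assert list(f.attrs["wavelengths"]) == [758, 824]


def test_hbo2_hbr_split_sums_to_hbt():
    truth = sg.GroundTruth(hbo2_fraction=1.25)
    f = truth.hbo2_fraction
    assert f + (1.0 - f) == pytest.approx(1.0)
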