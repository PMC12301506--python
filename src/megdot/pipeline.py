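"""End-to-end orchestration: simulate -> features -> predict -> reconstruct
-> correlate -> cluster -> report.

The pipeline ties the stage modules together for a whole synthetic
experiment: a shared head phantom, probe and sensitivity model (the
"context"), per-subject MEG and optical simulations, the Method-1 /
Method-2 / frequency correlation maps over the field of view, and the
cluster report.  Everything is reproducible from a single seed; stage
artifacts and a manifest with file hashes are written when an output
directory is given.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import couplestats, dotrecon, megfeat, synthgen
from .hemopredict import (
    FEATURES,
    METHOD2_SAMPLE_TIMES,
    canonical_hrf,
    predict_from_features,
)

__all__ = [
    "PipelineConfig",
    "PipelineContext",
    "SubjectResult",
    "DatasetResult",
    "build_context",
    "run_subject",
    "run_dataset",
    "run_pipeline",
    "make_report",
]

FREQ_ORDER = (0.5, 1.0, 2.0, 4.0)


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run, with study defaults."""

    seed: int = 0
    n_subjects: int = 18
    n_repetitions: int = 15                 # stimulus blocks per frequency per run
    rest_range: tuple = (14.0, 65.0)
    grid_shape: tuple = (40, 40, 20)
    voxel_size_mm: float = 2.0
    pitch_mm: float = 10.0
    min_separation: float = 10.0
    max_separation: float = 40.0
    fs_optical: float = 10.0                # native optical sampling (Hz)
    artifact_sd: float = 7.0                # optical artifact threshold (SDs)
    dipole_noise_sd: float = 2.0            # nAm per epoch
    noise: dict = field(default_factory=lambda: {
        "white_sd": 0.002, "drift_step": 5e-5,
        "sinusoids": [[1.0, 0.008], [0.3, 0.003], [0.1, 0.003]],
    })
    coupling: dict = field(default_factory=lambda: {
        "region": "SI-like", "center_xy": [0.0, 0.0], "radius_mm": 8.0,
        "features": {"P35m": 10.0},         # peak DHbT in uM per feature
    })
    subject_variability: float = 0.2        # lognormal sd of amplitude jitter
    alpha: float | None = None              # None -> scale-matched default
    alpha_rel: float = 10.0
    fov_threshold: float = 0.01
    min_volume: float = couplestats.MIN_CLUSTER_VOLUME
    n_mc: int = couplestats.N_MC
    connectivity: int = 6
    methods: tuple = ("method1", "method2", "frequency")
    levels: dict = field(default_factory=lambda: dict(couplestats.LEVELS))
    output_dir: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for k in ("rest_range", "grid_shape", "methods"):
            if k in raw and raw[k] is not None:
                raw[k] = tuple(raw[k])
        return cls(**raw)


@dataclass
class PipelineContext:
    """Shared geometry and inverse operator, reusable across datasets."""

    head: synthgen.HeadModel
    layout: synthgen.OptodeLayout
    sensitivity: synthgen.Sensitivity
    laplacian: object
    reconstructor: dotrecon.TikhonovReconstructor
    fov_mask: np.ndarray
    fov_indices: np.ndarray          # flat grid indices of FOV voxels
    hrf: object
    trains: dict


def build_context(cfg: PipelineConfig) -> PipelineContext:
    """Build the phantom, probe, sensitivity, FOV and inverse operator."""
    head = synthgen.build_head_phantom(cfg.grid_shape, cfg.voxel_size_mm)
    layout = synthgen.build_probe_geometry(
        pitch_mm=cfg.pitch_mm, min_separation=cfg.min_separation,
        max_separation=cfg.max_separation,
    )
    sens = synthgen.simulate_sensitivity(head, layout)
    L = dotrecon.build_laplacian(head.shape)
    J = sens.J[sens.wavelengths[0]]
    recon = dotrecon.TikhonovReconstructor(J, L, alpha=cfg.alpha,
                                           alpha_rel=cfg.alpha_rel,
                                           grid_shape=head.shape)
    fov = dotrecon.compute_fov([J], head.gm_mask, threshold=cfg.fov_threshold)
    return PipelineContext(
        head=head, layout=layout, sensitivity=sens, laplacian=L,
        reconstructor=recon, fov_mask=fov, fov_indices=np.nonzero(fov.ravel())[0],
        hrf=canonical_hrf(), trains={f: synthgen.make_stimulus_train(f) for f in FREQ_ORDER},
    )


def make_ground_truth(cfg: PipelineConfig, ctx: PipelineContext) -> synthgen.GroundTruth:
    """Ground truth from the coupling config (empty features -> null)."""
    feats = cfg.coupling.get("features") or {}
    if not feats or all(v == 0 for v in feats.values()):
        return synthgen.GroundTruth.null()
    region = cfg.coupling.get("region", "SI-like")
    vox = synthgen.make_ball_region(
        ctx.head, tuple(cfg.coupling.get("center_xy", (0.0, 0.0))),
        cfg.coupling.get("radius_mm", 6.0),
    )
    coupling = {(region, feat): float(beta) for feat, beta in feats.items()}
    return synthgen.GroundTruth(active_regions={region: vox}, coupling=coupling)


@dataclass
class SubjectResult:
    subject_id: str
    feature_table: pd.DataFrame         # extracted per-stimulus features
    predictions: pd.DataFrame           # predicted AUC + Method-2 samples
    hbt_auc: np.ndarray                 # (4 frequencies, n_fov)
    hbt_samples: np.ndarray             # (20, n_fov) frequency-major


def _subject_params(rng: np.random.Generator, subject_id: str,
                    variability: float) -> synthgen.DipoleSimParams:
    base = synthgen.DipoleSimParams(subject_id=subject_id)
    amps = {k: v * rng.lognormal(0.0, variability)
            for k, v in base.amplitudes.items()}
    taus = {k: v * rng.lognormal(0.0, variability / 2)
            for k, v in base.taus.items()}
    return synthgen.DipoleSimParams(subject_id=subject_id, amplitudes=amps, taus=taus)


def run_subject(
    cfg: PipelineConfig,
    ctx: PipelineContext,
    truth: synthgen.GroundTruth,
    subject_id: str,
    seed,
) -> SubjectResult:
    """Simulate and analyze one subject end to end."""
    rng = np.random.default_rng(seed)
    params = _subject_params(rng, subject_id, cfg.subject_variability)
    schedule = synthgen.make_run_schedule(rng, n_repetitions=cfg.n_repetitions,
                                          rest_range=cfg.rest_range)
    # --- MEG side -----------------------------------------------------
    epochs = [
        synthgen.simulate_dipole_waveforms(params, train, cfg.dipole_noise_sd, seed=rng)
        for train, _ in schedule.blocks
    ]
    averaged = megfeat.preprocess_and_average(epochs)
    feats = []
    for freq in sorted(averaged):
        rec = megfeat.remove_baseline_drift(averaged[freq])
        feats.append(megfeat.extract_features(rec))
    feature_table = pd.concat(feats, ignore_index=True)
    predictions = predict_from_features(feature_table, ctx.trains, ctx.hrf)

    # --- optical side -------------------------------------------------
    true_feats = synthgen.true_feature_amplitudes(params, ctx.trains)
    noise_cfg = synthgen.NoiseConfig(
        white_sd=cfg.noise["white_sd"], drift_step=cfg.noise["drift_step"],
        sinusoids=tuple(tuple(s) for s in cfg.noise["sinusoids"]),
    )
    rec = synthgen.simulate_optical_run(
        schedule, truth, true_feats, ctx.sensitivity, ctx.head,
        noise_cfg=noise_cfg, seed=rng, fs=cfg.fs_optical, hrf=ctx.hrf,
        layout=ctx.layout,
    )
    pre = dotrecon.preprocess_amplitudes(rec.A, rec.fs, artifact_sd=cfg.artifact_sd)
    resp = dotrecon.average_block_responses(
        pre.y, schedule.onset_times, schedule.frequencies,
        fs=pre.fs, artifact=pre.artifact, freq_order=FREQ_ORDER,
    )   # (n_pairs, n_wav, 4, n_taps)

    # lag grid of the FIR window
    lag_t = np.arange(resp.shape[-1]) / pre.fs - 1.0
    auc_sel = (lag_t >= 1.0 - 1e-9) & (lag_t <= 9.0 + 1e-9)
    sample_idx = [int(round((t + 1.0) * pre.fs)) for t in METHOD2_SAMPLE_TIMES]

    wavelengths = ctx.sensitivity.wavelengths
    n_fov = ctx.fov_indices.size
    # measured dlogA summaries -> batched reconstruction over FOV voxels
    dlogA_auc = np.trapezoid(resp[..., auc_sel], lag_t[auc_sel], axis=-1)  # (np, nw, 4)
    dlogA_samp = resp[..., sample_idx]                                     # (np, nw, 4, 5)
    hbt_auc = np.empty((len(FREQ_ORDER), n_fov))
    hbt_samples = np.empty((len(FREQ_ORDER) * 5, n_fov))
    dmua_auc = np.empty((len(wavelengths), len(FREQ_ORDER), n_fov))
    dmua_samp = np.empty((len(wavelengths), len(FREQ_ORDER) * 5, n_fov))
    for wi, w in enumerate(wavelengths):
        # identical J across wavelengths shares one factorized operator
        b = np.concatenate(
            [dlogA_auc[:, wi, :], dlogA_samp[:, wi].reshape(dlogA_samp.shape[0], -1)],
            axis=1,
        )
        x = ctx.reconstructor.solve_subset(b, ctx.fov_indices)   # (n_fov, 4+20)
        dmua_auc[wi] = x[:, : len(FREQ_ORDER)].T
        dmua_samp[wi] = x[:, len(FREQ_ORDER):].T
    hbt_auc = dotrecon.absorption_to_hemoglobin(dmua_auc, wavelengths)["HbT"]
    hbt_samples = dotrecon.absorption_to_hemoglobin(dmua_samp, wavelengths)["HbT"]
    return SubjectResult(
        subject_id=subject_id, feature_table=feature_table,
        predictions=predictions, hbt_auc=hbt_auc, hbt_samples=hbt_samples,
    )


@dataclass
class DatasetResult:
    subjects: list
    Y_auc: np.ndarray                   # (n_subjects*4, n_fov)
    rows: pd.DataFrame                  # subject, frequency per row
    X: np.ndarray                       # (n_rows, 6) predicted AUCs
    measured_m2: np.ndarray             # (n_subjects, 20, n_fov)
    predicted_m2: dict                  # feature -> (n_subjects, 20)
    stat_maps: dict                     # (method, feature|None) -> VoxelStatMap
    clusters: list
    fov_indices: np.ndarray
    grid_shape: tuple
    voxel_size: float


def _cluster_fn_corr(Y, x, pos_of_flat):
    def fn(vox_flat):
        cols = pos_of_flat[vox_flat]
        sig = Y[:, cols].mean(axis=1)
        return couplestats.pearson_rp(x, sig)
    return fn


def _cluster_fn_method2(measured, predicted, pos_of_flat):
    from scipy import stats

    def fn(vox_flat):
        cols = pos_of_flat[vox_flat]
        sig = measured[:, :, cols].mean(axis=2)     # (n_subj, 20)
        rs = np.array([
            couplestats.pearson_rp(predicted[s], sig[s])[0]
            for s in range(sig.shape[0])
        ])
        zs = couplestats.fisher_z(rs)
        tt = stats.ttest_1samp(zs, 0.0)
        return float(np.tanh(zs.mean())), float(tt.pvalue)
    return fn


def run_dataset(
    cfg: PipelineConfig,
    ctx: PipelineContext,
    truth: synthgen.GroundTruth | None = None,
    seed: int | None = None,
) -> DatasetResult:
    """Simulate a whole cohort and run the correlation-cluster analysis."""
    if truth is None:
        truth = make_ground_truth(cfg, ctx)
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    children = root.spawn(cfg.n_subjects)
    subjects = [
        run_subject(cfg, ctx, truth, f"s{i + 1:02d}", children[i])
        for i in range(cfg.n_subjects)
    ]
    n_fov = ctx.fov_indices.size
    rows, Y, X = [], [], []
    for s in subjects:
        pred = s.predictions.set_index(["frequency", "feature_id"])["auc"]
        for fi, f in enumerate(FREQ_ORDER):
            rows.append({"subject": s.subject_id, "frequency": f})
            Y.append(s.hbt_auc[fi])
            X.append([float(pred.loc[(f, feat)]) for feat in FEATURES])
    Y = np.asarray(Y)
    X = np.asarray(X)
    rows = pd.DataFrame(rows)
    measured_m2 = np.stack([s.hbt_samples for s in subjects])
    predicted_m2 = {}
    for feat in FEATURES:
        mats = []
        for s in subjects:
            pr = s.predictions.set_index(["frequency", "feature_id"])
            samp = np.concatenate([
                pr.loc[(f, feat), [f"sample_{int(t)}" for t in METHOD2_SAMPLE_TIMES]]
                .to_numpy(dtype=float)
                for f in FREQ_ORDER
            ])
            mats.append(samp)
        predicted_m2[feat] = np.asarray(mats)

    pos_of_flat = np.full(int(np.prod(ctx.head.shape)), -1)
    pos_of_flat[ctx.fov_indices] = np.arange(n_fov)
    common = dict(voxel_indices=ctx.fov_indices, grid_shape=ctx.head.shape,
                  voxel_size=ctx.head.voxel_size)
    stat_maps, clusters = {}, []
    if "method1" in cfg.methods:
        for j, feat in enumerate(FEATURES):
            sm = couplestats.correlate_method1(Y, X[:, j], feature_id=feat, **common)
            stat_maps[("method1", feat)] = sm
            clusters += couplestats.form_clusters(
                sm, _cluster_fn_corr(Y, X[:, j], pos_of_flat),
                min_volume=cfg.min_volume, levels=cfg.levels,
                connectivity=cfg.connectivity,
            )
    if "method2" in cfg.methods and cfg.n_subjects >= 3:
        for feat in FEATURES:
            sm = couplestats.correlate_method2(
                measured_m2, predicted_m2[feat], feature_id=feat, **common)
            stat_maps[("method2", feat)] = sm
            clusters += couplestats.form_clusters(
                sm, _cluster_fn_method2(measured_m2, predicted_m2[feat], pos_of_flat),
                min_volume=cfg.min_volume, levels=cfg.levels,
                connectivity=cfg.connectivity,
            )
    if "frequency" in cfg.methods:
        freqs = rows["frequency"].to_numpy(dtype=float)
        sm = couplestats.correlate_frequency(Y, freqs, **common)
        stat_maps[("frequency", None)] = sm
        clusters += couplestats.form_clusters(
            sm, _cluster_fn_corr(Y, freqs, pos_of_flat),
            min_volume=cfg.min_volume, levels=cfg.levels,
            connectivity=cfg.connectivity,
        )
    clusters = couplestats.correct_clusters(clusters, n_mc=cfg.n_mc)
    return DatasetResult(
        subjects=subjects, Y_auc=Y, rows=rows, X=X, measured_m2=measured_m2,
        predicted_m2=predicted_m2, stat_maps=stat_maps, clusters=clusters,
        fov_indices=ctx.fov_indices, grid_shape=ctx.head.shape,
        voxel_size=ctx.head.voxel_size,
    )


# ---------------------------------------------------------------------------
# Null calibration of the minimum-volume rule
# ---------------------------------------------------------------------------

def null_config(cfg: PipelineConfig | None = None, **overrides) -> PipelineConfig:
    """A copy of ``cfg`` with coupling disabled (null hypothesis)."""
    import copy

    out = copy.deepcopy(cfg) if cfg is not None else PipelineConfig()
    out.coupling = {"features": {}}
    for k, v in overrides.items():
        setattr(out, k, v)
    return out


def max_null_component_volume(
    cfg: PipelineConfig,
    ctx: PipelineContext,
    seed,
    level: str = "L3",
) -> float:
    """Largest suprathreshold component (mm^3) in one null dataset.

    Runs the full pipeline on a dataset with coupling disabled and
    returns the maximum connected-component volume at the voxel
    threshold of ``level`` across all Method-1 feature maps (the family
    over which the false-positive rate is controlled); 0.0 when no
    voxel is suprathreshold.
    """
    ds = run_dataset(cfg, ctx, truth=synthgen.GroundTruth.null(), seed=seed)
    thr = cfg.levels[level]
    vmax = 0.0
    for (method, _feat), sm in ds.stat_maps.items():
        if method != "method1":
            continue
        vols = couplestats.component_volumes(sm, thr, cfg.connectivity)
        if vols.size:
            vmax = max(vmax, float(vols.max()))
    return vmax


def calibrate_and_measure_fpr(
    cfg: PipelineConfig,
    ctx: PipelineContext,
    seed: int,
    n_calibration: int = 150,
    n_evaluation: int = 200,
    level: str = "L3",
    target_fpr: float = 0.05,
) -> dict:
    """Calibrate the minimum cluster volume on null data and verify it.

    Two independent batches of null datasets are simulated: the first
    calibrates the minimum-volume rule to the target family-wise
    false-positive rate (fraction of null datasets with at least one
    surviving component at the ``level`` threshold); the second,
    held-out batch measures the achieved rate.  Returns a dict with the
    calibrated volume and the measured FPR.
    """
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(n_calibration + n_evaluation)
    calib = np.array([
        max_null_component_volume(cfg, ctx, seeds[i], level)
        for i in range(n_calibration)
    ])
    min_volume = couplestats.calibrate_min_volume(
        [np.array([v]) if v > 0 else np.array([]) for v in calib],
        voxel_volume=ctx.head.voxel_volume, target_fpr=target_fpr,
    )
    evald = np.array([
        max_null_component_volume(cfg, ctx, seeds[n_calibration + i], level)
        for i in range(n_evaluation)
    ])
    fpr = float(np.mean(evald >= min_volume))
    return {
        "min_volume_mm3": float(min_volume),
        "fpr": fpr,
        "n_calibration": n_calibration,
        "n_evaluation": n_evaluation,
        "level": level,
        "calibration_max_volumes": calib,
        "evaluation_max_volumes": evald,
    }


# ---------------------------------------------------------------------------
# Reporting and provenance
# ---------------------------------------------------------------------------

def make_report(clusters: list, report_p: float = couplestats.REPORT_P,
                signif_p: float = couplestats.SIGNIF_P) -> pd.DataFrame:
    """Cluster summary table (one row per cluster, NS/asterisk rendering).

    ``p_display`` shows the Bonferroni-corrected p, rendered "NS" at or
    above ``report_p`` and suffixed with an asterisk below ``signif_p``.
    """
    rows = []
    for i, c in enumerate(sorted(clusters, key=lambda c: (c.p_corrected is None, c.p_corrected))):
        pc = c.p_corrected
        if pc is None:
            disp = ""
        elif pc >= report_p:
            disp = "NS"
        elif pc < signif_p:
            disp = f"{pc:.3g}*"
        else:
            disp = f"{pc:.3g}"
        rows.append({
            "cluster": f"C{i + 1}",
            "method": c.method,
            "leading_feature": c.feature_id or "frequency",
            "leading_variable": c.leading_variable,
            "volume_mm3": c.volume_mm3,
            "level": c.level,
            "n_voxels": c.n_voxels,
            "r": c.r,
            "p": c.p,
            "p_corrected": pc,
            "p_display": disp,
        })
    cols = ["cluster", "method", "leading_feature", "leading_variable",
            "volume_mm3", "level", "n_voxels", "r", "p", "p_corrected", "p_display"]
    return pd.DataFrame(rows, columns=cols)


def _cluster_json(clusters: list) -> list:
    return [
        {
            "voxels": c.voxel_indices.tolist(),
            "volume_mm3": c.volume_mm3,
            "level": c.level,
            "method": c.method,
            "leading_feature": c.feature_id,
            "leading_variable": c.leading_variable,
            "r": c.r,
            "p": c.p,
            "p_corrected": c.p_corrected,
            "significant": c.significant,
        }
        for c in clusters
    ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline and (optionally) write artifacts + manifest.

    Returns a manifest dict; when ``cfg.output_dir`` is set the cluster
    report (JSON + CSV + text), feature and design tables, stat maps
    (NIfTI) and the manifest (with SHA-256 hashes of every artifact)
    are written there.  Byte-identical outputs for a fixed seed.
    """
    import nibabel as nib

    ctx = build_context(cfg)
    truth = make_ground_truth(cfg, ctx)
    ds = run_dataset(cfg, ctx, truth)
    report = make_report(ds.clusters)
    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "n_fov_voxels": int(ds.fov_indices.size),
        "n_clusters": len(ds.clusters),
        "clusters": _cluster_json(ds.clusters),
        "artifacts": {},
    }
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")
        feats = pd.concat([s.feature_table.assign(subject=s.subject_id)
                           for s in ds.subjects], ignore_index=True)
        feats.to_csv(out / "meg_features.csv", index=False)
        design = ds.rows.copy()
        for j, feat in enumerate(FEATURES):
            design[f"X_{feat}"] = ds.X[:, j]
        design.to_csv(out / "design.csv", index=False)
        with open(out / "clusters.json", "w") as f:
            json.dump(_cluster_json(ds.clusters), f, indent=1)
        report.to_csv(out / "cluster_report.csv", index=False)
        (out / "cluster_report.txt").write_text(
            report.to_string(index=False) + "\n" if len(report) else "no clusters\n")
        affine = np.diag([ds.voxel_size] * 3 + [1.0])
        for (method, feat), sm in ds.stat_maps.items():
            vol = sm.p_volume().astype(np.float32)
            name = f"pmap_{method}" + (f"_{feat}" if feat else "") + ".nii.gz"
            nib.save(nib.Nifti1Image(vol, affine), out / name)
        nib.save(nib.Nifti1Image(
            ctx.fov_mask.astype(np.uint8), affine), out / "fov_mask.nii.gz")
        for p in sorted(out.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest["artifacts"][p.name] = _sha256(p)
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=1, sort_keys=True)
    return manifest
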