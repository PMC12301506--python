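"""Synthetic data generation for the MEG-DOT coupling pipeline.

The experiment emulated here: electrical median-nerve stimulation is
delivered in ~2 s trains at 0.5, 1, 2 or 4 Hz (2, 3, 5 or 9 pulses),
each train followed by a 14-65 s rest.  MEG equivalent-current-dipole
(ECD) waveforms from primary (SI) and secondary (SII) somatosensory
cortex show characteristic deflections (N20m, P35m, P60m; a broad SII
response at 60-200 ms) whose amplitudes habituate at short
inter-stimulus intervals.  A high-density optical probe over the
contralateral parietal cortex records two-wavelength amplitude time
series whose evoked component is a Jacobian-projected hemoglobin
response coupled linearly to the MEG features, on top of physiological
noise.

This module generates every input the analysis pipeline consumes:
stimulus schedules, dipole waveforms with habituation, a layered head
phantom with literature tissue optics, analytic diffusion-kernel
sensitivity matrices, and noisy optical recordings with a configurable
neurovascular-coupling ground truth.  All generators are reproducible
from a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PROTOCOL_FREQUENCIES",
    "TISSUE_OPTICS",
    "StimulusTrain",
    "RunSchedule",
    "DipoleRecord",
    "DipoleSimParams",
    "HeadModel",
    "OptodeLayout",
    "Sensitivity",
    "GroundTruth",
    "NoiseConfig",
    "OpticalRecording",
    "make_stimulus_train",
    "make_run_schedule",
    "simulate_dipole_waveforms",
    "true_feature_amplitudes",
    "build_head_phantom",
    "build_probe_geometry",
    "simulate_sensitivity",
    "simulate_optical_run",
    "make_ball_region",
    "make_ellipsoid_head",
]

#: The four stimulation frequencies of the protocol (Hz).
PROTOCOL_FREQUENCIES = (0.5, 1.0, 2.0, 4.0)

#: Duration of one stimulus current pulse (s).
PULSE_DURATION = 0.0002

#: Tissue optical parameters: absorption mua (1/mm), scattering mus
#: (1/mm), anisotropy g, refractive index n.  Literature values for
#: adult head tissue at 780-800 nm.
TISSUE_OPTICS = {
    "scalp": (0.0164, 7.1, 0.9, 1.35),
    "skull": (0.0115, 9.1, 0.9, 1.35),
    "trabecular": (0.016, 16.0, 0.95, 1.35),
    "csf": (0.0041, 2.5, 0.9, 1.35),          # subarachnoid CSF
    "csf_sulci": (0.002, 0.01, 0.9, 1.35),
    "sss": (0.3, 20.0, 0.95, 1.35),           # superior sagittal sinus
    "gray_matter": (0.032, 69.5, 0.97, 1.35),
    "white_matter": (0.005, 55.0, 0.85, 1.35),
}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Stimulation protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusTrain:
    """One ~2 s train of electrical stimuli at a fixed rate."""

    frequency: float              # Hz
    onsets: np.ndarray            # seconds from train start, first = 0
    pulse_duration: float = PULSE_DURATION

    @property
    def n_stimuli(self) -> int:
        return int(len(self.onsets))

    @property
    def isi(self) -> float:
        """Inter-stimulus-onset interval (s)."""
        return 1.0 / self.frequency

    @property
    def duration(self) -> float:
        """Onset of first pulse to offset of last pulse (s)."""
        return float(self.onsets[-1] - self.onsets[0] + self.pulse_duration)


def make_stimulus_train(frequency: float) -> StimulusTrain:
    """Build the stimulus train for one stimulation frequency.

    Protocol frequencies (0.5, 1, 2, 4 Hz) give 2, 3, 5 and 9 stimuli
    with onsets k/frequency, so the onset-to-offset duration is 2.0002 s
    for all four.  Other positive frequencies are allowed with a warning
    and use n = floor(2 f) + 1 stimuli.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    if frequency not in PROTOCOL_FREQUENCIES:
        warnings.warn(
            f"{frequency} Hz is not a protocol frequency; using n = floor(2f)+1 stimuli"
        )
    n = int(np.floor(2.0 * frequency)) + 1
    onsets = np.arange(n) / frequency
    return StimulusTrain(frequency=float(frequency), onsets=onsets)


@dataclass(frozen=True)
class RunSchedule:
    """Pseudorandom ordering of stimulus trains within one run.

    ``blocks`` holds (train, start_time) with start times in seconds
    from run start; every block is preceded by one rest drawn from
    ``rest_range`` and the run ends with a fixed tail long enough for
    the final hemodynamic response to be estimated.
    """

    blocks: tuple                      # ((StimulusTrain, start_time), ...)
    rest_durations: np.ndarray         # one pre-block rest per block (s)
    n_repetitions: int
    rest_range: tuple
    tail: float = 12.0

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def duration(self) -> float:
        train, start = self.blocks[-1]
        return float(start + train.duration + self.tail)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([b[0].frequency for b in self.blocks])

    @property
    def onset_times(self) -> np.ndarray:
        return np.array([b[1] for b in self.blocks])

    def blocks_of(self, frequency: float):
        return [b for b in self.blocks if b[0].frequency == frequency]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": np.arange(self.n_blocks),
                "frequency": self.frequencies,
                "start_time": self.onset_times,
                "n_stimuli": [b[0].n_stimuli for b in self.blocks],
                "pre_rest": self.rest_durations,
            }
        )


def _order_without_long_runs(
    rng: np.random.Generator, labels: np.ndarray, max_consecutive: int
) -> np.ndarray:
    """Shuffle until no label appears more than max_consecutive times in a row."""
    for _ in range(10_000):
        perm = rng.permutation(labels)
        run, worst = 1, 1
        for a, b in zip(perm[:-1], perm[1:]):
            run = run + 1 if a == b else 1
            worst = max(worst, run)
        if worst <= max_consecutive:
            return perm
    raise RuntimeError("could not satisfy the consecutive-frequency constraint")


def make_run_schedule(
    seed,
    n_repetitions: int = 15,
    rest_range: tuple[float, float] = (14.0, 65.0),
    frequencies: tuple[float, ...] = PROTOCOL_FREQUENCIES,
    max_consecutive: int = 3,
    tail: float = 12.0,
) -> RunSchedule:
    """Build one measurement run: pseudorandom block order with rests.

    Each frequency appears exactly ``n_repetitions`` times (60 blocks
    per run at the default 15), in a seeded shuffled order constrained
    so that no frequency repeats more than ``max_consecutive`` times
    consecutively.  Rest durations are drawn uniformly from
    ``rest_range`` (default 14-65 s); each block is preceded by its
    rest.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    lo, hi = rest_range
    if not (lo <= hi) or lo < 0:
        raise ValueError(f"invalid rest_range {rest_range}")
    rng = _rng(seed)
    labels = np.repeat(np.asarray(frequencies, dtype=float), n_repetitions)
    order = _order_without_long_runs(rng, labels, max_consecutive)
    rests = rng.uniform(lo, hi, size=order.size)
    trains = {f: make_stimulus_train(f) for f in frequencies}
    blocks, t = [], 0.0
    for f, rest in zip(order, rests):
        t += rest
        train = trains[float(f)]
        blocks.append((train, t))
        t += train.duration
    return RunSchedule(
        blocks=tuple(blocks),
        rest_durations=rests,
        n_repetitions=n_repetitions,
        rest_range=tuple(rest_range),
        tail=tail,
    )


# ---------------------------------------------------------------------------
# MEG dipole waveforms
# ---------------------------------------------------------------------------

#: (center ms, width ms, sign) of the Gaussian lobes of the SI response
#: and the broad SII response.  Signs alternate across the SI
#: deflections as in somatosensory ECD waveforms.
LOBE_SHAPE = {
    "N20m": (21.0, 1.5, -1.0),
    "P35m": (34.0, 2.5, +1.0),
    "P60m": (60.0, 8.0, -1.0),
    "SII": (110.0, 30.0, +1.0),
}


@dataclass(frozen=True)
class DipoleSimParams:
    """Per-subject generative parameters for the ECD waveforms.

    ``amplitudes`` are peak dipole moments in nAm for the first
    stimulus of a train; subsequent stimuli are attenuated by the
    habituation factor rho_i(ISI) = 1 - exp(-ISI / tau_i), so short
    inter-stimulus intervals suppress the response more for features
    with long recovery time constants ``taus`` (seconds).
    """

    subject_id: str = "s01"
    amplitudes: dict = field(
        default_factory=lambda: {"N20m": 15.0, "P35m": 25.0, "P60m": 10.0, "SII": 8.0}
    )
    taus: dict = field(
        default_factory=lambda: {"N20m": 0.1, "P35m": 0.5, "P60m": 1.0, "SII": 2.0}
    )
    lobes: dict = field(default_factory=lambda: dict(LOBE_SHAPE))

    def with_subject(self, subject_id: str) -> "DipoleSimParams":
        return replace(self, subject_id=subject_id)


@dataclass
class DipoleRecord:
    """ECD waveforms for one subject and one stimulation frequency.

    ``t`` runs from 200 ms before the first stimulus to 250 ms after
    the last; ``waveforms`` maps dipole name ("SI", "SII") to nAm time
    series sampled at ``fs`` (>= 600 Hz).
    """

    subject_id: str
    frequency: float
    fs: float
    t: np.ndarray
    waveforms: dict
    train: StimulusTrain | None = None

    @property
    def epoch_window(self) -> tuple[float, float]:
        return (float(self.t[0]), float(self.t[-1]))


def habituation_factor(isi: float, tau: float) -> float:
    """Recovery fraction rho(ISI) = 1 - exp(-ISI/tau); rho -> 1 as tau -> 0."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if tau == 0:
        return 1.0
    return float(1.0 - np.exp(-isi / tau))


def _stimulus_amplitudes(params: DipoleSimParams, train: StimulusTrain) -> dict:
    """Peak amplitude of each lobe for each stimulus in the train."""
    out = {}
    for name, base in params.amplitudes.items():
        rho = habituation_factor(train.isi, params.taus[name])
        amps = np.full(train.n_stimuli, base * rho)
        amps[0] = base
        out[name] = amps
    return out


def simulate_dipole_waveforms(
    params: DipoleSimParams,
    train: StimulusTrain,
    noise_sd: float = 2.0,
    fs: float = 1000.0,
    seed=None,
    pre: float = 0.2,
    post: float = 0.25,
) -> DipoleRecord:
    """Simulate SI and SII dipole waveforms for one stimulus train.

    The SI waveform is a sum over stimuli of three Gaussian lobes
    (N20m, P35m, P60m) with alternating polarity; the SII waveform is a
    single broad positive lobe in the 60-200 ms range.  Stimulus k >= 2
    is attenuated by the habituation factor for its feature.  White
    noise of standard deviation ``noise_sd`` (nAm) is added; the epoch
    covers -200 ms to last stimulus + 250 ms at ``fs`` >= 600 Hz.
    """
    if fs < 600:
        raise ValueError(f"sampling rate must be >= 600 Hz, got {fs}")
    if post < 0.25:
        raise ValueError("epoch must extend at least 250 ms past the last stimulus")
    rng = _rng(seed)
    t = np.arange(-pre, train.onsets[-1] + post + 0.5 / fs, 1.0 / fs)
    amps = _stimulus_amplitudes(params, train)
    si = np.zeros_like(t)
    sii = np.zeros_like(t)
    for k, onset in enumerate(train.onsets):
        tau_ms = (t - onset) * 1000.0
        for name in ("N20m", "P35m", "P60m"):
            mu, sigma, sign = params.lobes[name]
            si += sign * amps[name][k] * np.exp(-((tau_ms - mu) ** 2) / (2 * sigma**2))
        mu, sigma, sign = params.lobes["SII"]
        sii += sign * amps["SII"][k] * np.exp(-((tau_ms - mu) ** 2) / (2 * sigma**2))
    if noise_sd > 0:
        si = si + rng.normal(0, noise_sd, t.size)
        sii = sii + rng.normal(0, noise_sd, t.size)
    return DipoleRecord(
        subject_id=params.subject_id,
        frequency=train.frequency,
        fs=fs,
        t=t,
        waveforms={"SI": si, "SII": sii},
        train=train,
    )


def true_feature_amplitudes(
    params: DipoleSimParams,
    trains: dict[float, StimulusTrain] | None = None,
) -> pd.DataFrame:
    """Closed-form per-stimulus feature values implied by the generator.

    AUC features are the analytic Gaussian-lobe integrals
    sign * a * sigma * sqrt(2 pi) (nAm s, with habituation applied);
    RMS features are the model RMS of the noiseless waveform over the
    10-200 ms window after each stimulus.  Used as the neurovascular
    coupling drive of the optical simulation, independent of the MEG
    feature-extraction stage.
    """
    if trains is None:
        trains = {f: make_stimulus_train(f) for f in PROTOCOL_FREQUENCIES}
    feature_of_lobe = {"N20m": "N20m", "P35m": "P35m", "P60m": "P60m", "SII": "SII60-200ms"}
    rows = []
    for f, train in trains.items():
        amps = _stimulus_amplitudes(params, train)
        for k in range(train.n_stimuli):
            for lobe, feat in feature_of_lobe.items():
                mu, sigma, sign = params.lobes[lobe]
                auc = sign * amps[lobe][k] * (sigma / 1000.0) * np.sqrt(2 * np.pi)
                rows.append(
                    {"subject": params.subject_id, "frequency": f,
                     "stimulus_index": k, "feature_id": feat, "value": auc}
                )
            # model RMS over 10-200 ms post stimulus, noiseless
            tt = np.linspace(10.0, 200.0, 1901)
            si = np.zeros_like(tt)
            for lobe in ("N20m", "P35m", "P60m"):
                mu, sigma, sign = params.lobes[lobe]
                si += sign * amps[lobe][k] * np.exp(-((tt - mu) ** 2) / (2 * sigma**2))
            mu, sigma, sign = params.lobes["SII"]
            sii = sign * amps["SII"][k] * np.exp(-((tt - mu) ** 2) / (2 * sigma**2))
            rows.append({"subject": params.subject_id, "frequency": f,
                         "stimulus_index": k, "feature_id": "SI_RMS",
                         "value": float(np.sqrt(np.mean(si**2)))})
            rows.append({"subject": params.subject_id, "frequency": f,
                         "stimulus_index": k, "feature_id": "SII_RMS",
                         "value": float(np.sqrt(np.mean(sii**2)))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Head phantom and probe geometry
# ---------------------------------------------------------------------------

@dataclass
class HeadModel:
    """Layered half-space head phantom on a regular voxel grid.

    Axis 2 is depth: slab boundaries are measured from the surface at
    z = 0 where the optodes sit.  ``labels`` holds integer tissue codes
    indexing ``tissue_names``; optical parameters per tissue come from
    :data:`TISSUE_OPTICS`.
    """

    shape: tuple
    voxel_size: float              # mm, isotropic
    labels: np.ndarray             # int array, shape == shape
    tissue_names: tuple            # index -> tissue name

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(self.voxel_size**3)

    def mask(self, tissue: str) -> np.ndarray:
        idx = self.tissue_names.index(tissue)
        return self.labels == idx

    @property
    def gm_mask(self) -> np.ndarray:
        return self.mask("gray_matter")

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) centers in mm; x/y centered on 0, z = depth."""
        nx, ny, nz = self.shape
        v = self.voxel_size
        x = (np.arange(nx) + 0.5) * v - nx * v / 2.0
        y = (np.arange(ny) + 0.5) * v - ny * v / 2.0
        z = (np.arange(nz) + 0.5) * v
        g = np.stack(np.meshgrid(x, y, z, indexing="ij"), axis=-1)
        return g.reshape(-1, 3)

    def optical_parameters(self, tissue: str) -> tuple:
        """(mua, mus, g, n) for a tissue label."""
        return TISSUE_OPTICS[tissue]

    def homogeneous_parameters(self) -> tuple[float, float]:
        """Volume-averaged (mua, reduced scattering mus') of the head.

        The average runs over the superficial layers down to the bottom
        of the deepest finite layer (scalp through gray matter by
        default): near-infrared photon paths rarely sample the
        semi-infinite deep fill, and including it would let the white
        matter's very high reduced scattering dominate the effective
        attenuation.
        """
        mua = np.zeros(len(self.tissue_names))
        musp = np.zeros(len(self.tissue_names))
        for i, name in enumerate(self.tissue_names):
            ma, ms, g, _ = TISSUE_OPTICS[name]
            mua[i], musp[i] = ma, ms * (1.0 - g)
        counts = np.bincount(self.labels.ravel(), minlength=len(self.tissue_names))
        deep = self.labels.ravel()[-1]          # label of the deepest voxel
        if counts[:deep].sum() > 0:
            counts = counts.copy()
            counts[deep] = 0
        w = counts / counts.sum()
        return float(w @ mua), float(w @ musp)

    def to_nifti(self):
        import nibabel as nib

        affine = np.diag([self.voxel_size] * 3 + [1.0])
        return nib.Nifti1Image(self.labels.astype(np.int16), affine)


DEFAULT_LAYERS = (
    ("scalp", 5.0),
    ("skull", 6.0),
    ("csf", 2.0),
    ("gray_matter", 4.0),
    ("white_matter", None),    # fills the remaining depth
)


def build_head_phantom(
    shape: tuple[int, int, int] = (40, 40, 20),
    voxel_size_mm: float = 2.0,
    layers=DEFAULT_LAYERS,
) -> HeadModel:
    """Build a layered slab phantom (scalp/skull/CSF/GM/WM by default).

    ``layers`` lists (tissue, thickness_mm) from the surface inward;
    the last thickness may be None to fill the remaining depth.  Every
    voxel receives exactly one label (assignment by voxel-center depth).
    """
    shape = tuple(int(s) for s in shape)
    if shape[0] < 20 or shape[1] < 20 or shape[2] < 15:
        raise ValueError(f"grid too small: {shape}, need >= 20x20x15")
    depth_total = shape[2] * voxel_size_mm
    names = tuple(name for name, _ in layers)
    bounds, z = [], 0.0
    for name, thick in layers:
        if thick is None:
            z = depth_total
        else:
            z += float(thick)
        bounds.append(z)
    if bounds[-1] < depth_total:
        raise ValueError("layers do not cover the grid depth; make the last layer None")
    if len(bounds) > 1 and bounds[-2] >= depth_total:
        raise ValueError(
            f"layer thicknesses ({bounds[-2]} mm) meet or exceed grid depth {depth_total} mm"
        )
    depth = (np.arange(shape[2]) + 0.5) * voxel_size_mm
    label_of_slice = np.searchsorted(np.asarray(bounds), depth, side="left")
    labels = np.broadcast_to(
        label_of_slice[None, None, :], shape
    ).astype(np.int32).copy()
    return HeadModel(shape=shape, voxel_size=float(voxel_size_mm),
                     labels=labels, tissue_names=names)


@dataclass
class OptodeLayout:
    """Interleaved source/detector grid on the phantom surface (z = 0)."""

    sources: np.ndarray            # (n_sources, 3) mm
    detectors: np.ndarray          # (n_detectors, 3) mm
    pairs: np.ndarray              # (n_pairs, 2) int indices (source, detector)
    pitch: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def positions(self) -> np.ndarray:
        return np.vstack([self.sources, self.detectors])

    @property
    def separations(self) -> np.ndarray:
        return np.linalg.norm(
            self.sources[self.pairs[:, 0]] - self.detectors[self.pairs[:, 1]], axis=1
        )

    def to_frame(self) -> pd.DataFrame:
        sep = self.separations
        return pd.DataFrame(
            {"source": self.pairs[:, 0], "detector": self.pairs[:, 1],
             "separation_mm": sep}
        )


def build_probe_geometry(
    n_sources: int = 16,
    n_detectors: int = 16,
    pitch_mm: float = 10.0,
    min_separation: float = 10.0,
    max_separation: float | None = 40.0,
) -> OptodeLayout:
    """Checkerboard source/detector grid with distance-gated pairs.

    Sources and detectors alternate on a square grid of spacing
    ``pitch_mm`` centered on the origin.  Active source-detector pairs
    are those with separation within [min_separation, max_separation]
    (default 10-40 mm, the usable range for cortical sensitivity).
    """
    total = n_sources + n_detectors
    side = int(np.ceil(np.sqrt(total)))
    xs, ys, kinds = [], [], []
    ns = nd = 0
    for r in range(side):
        for c in range(side):
            want_source = (r + c) % 2 == 0
            if want_source and ns < n_sources:
                kinds.append("S"); ns += 1
            elif not want_source and nd < n_detectors:
                kinds.append("D"); nd += 1
            elif ns < n_sources:
                kinds.append("S"); ns += 1
            elif nd < n_detectors:
                kinds.append("D"); nd += 1
            else:
                continue
            xs.append(c); ys.append(r)
    xs = np.asarray(xs, dtype=float); ys = np.asarray(ys, dtype=float)
    xs = (xs - xs.mean()) * pitch_mm
    ys = (ys - ys.mean()) * pitch_mm
    pts = np.column_stack([xs, ys, np.zeros_like(xs)])
    kinds = np.asarray(kinds)
    sources = pts[kinds == "S"]
    detectors = pts[kinds == "D"]
    d = np.linalg.norm(sources[:, None, :] - detectors[None, :, :], axis=2)
    keep = d >= min_separation
    if max_separation is not None:
        keep &= d <= max_separation
    si, di = np.nonzero(keep)
    if si.size == 0:
        raise ValueError("no active source-detector pairs; check pitch and separation gates")
    pairs = np.column_stack([si, di])
    return OptodeLayout(sources=sources, detectors=detectors, pairs=pairs,
                        pitch=float(pitch_mm))


# ---------------------------------------------------------------------------
# Analytic sensitivity (Jacobian) matrices
# ---------------------------------------------------------------------------

@dataclass
class Sensitivity:
    """Absorption Jacobians J = d logA / d mua per wavelength.

    ``J[wavelength]`` has shape (n_pairs, n_voxels) in mm (voxel volume
    times photon-measurement-density, negative everywhere: increasing
    absorption anywhere can only decrease the detected amplitude).
    """

    J: dict                        # wavelength nm -> (n_pairs, n_voxels)
    wavelengths: tuple
    grid_shape: tuple
    voxel_size: float
    mu_eff: dict                   # wavelength -> effective attenuation (1/mm)

    @property
    def n_pairs(self) -> int:
        return next(iter(self.J.values())).shape[0]

    def stack(self) -> np.ndarray:
        """(n_wavelengths, n_pairs, n_voxels) array in wavelength order."""
        return np.stack([self.J[w] for w in self.wavelengths])


def _green(dist: np.ndarray, mu_eff: float) -> np.ndarray:
    return np.exp(-mu_eff * dist) / dist


def simulate_sensitivity(
    head: HeadModel,
    layout: OptodeLayout,
    wavelengths: tuple[int, ...] = (758, 824),
) -> Sensitivity:
    """Analytic diffusion-kernel sensitivity for every active pair.

    A homogeneous medium with the phantom's volume-averaged absorption
    and reduced scattering is assumed; the sensitivity of pair (s, d)
    to absorption in voxel v is the normalized product of isotropic
    diffusion Green functions (the photon-measurement density function)

        J[(s,d), v] = -(1/D) G(r_s, r_v) G(r_v, r_d) / G(r_s, r_d) * V_voxel

    with G(r) = exp(-mu_eff r)/r, mu_eff = sqrt(3 mua mus') and the
    diffusion coefficient D = 1/(3 mus'), which reproduces the
    banana-shaped weighting of continuous-wave measurements and yields
    total sensitivities on the scale of physical photon pathlengths.
    Distances are floored at one voxel size to avoid the
    Green-function singularity at the optodes.
    """
    mua, musp = head.homogeneous_parameters()
    mu_eff = float(np.sqrt(3.0 * mua * musp))
    inv_D = 3.0 * musp
    centers = head.voxel_centers()
    floor = head.voxel_size
    d_src = np.maximum(
        np.linalg.norm(layout.sources[:, None, :] - centers[None, :, :], axis=2), floor
    )
    d_det = np.maximum(
        np.linalg.norm(layout.detectors[:, None, :] - centers[None, :, :], axis=2), floor
    )
    si, di = layout.pairs[:, 0], layout.pairs[:, 1]
    sep = np.maximum(layout.separations, floor)
    g_sd = _green(sep, mu_eff)
    J = -inv_D * (
        _green(d_src[si], mu_eff) * _green(d_det[di], mu_eff) / g_sd[:, None]
    ) * head.voxel_volume / (4.0 * np.pi)
    # Baseline optics are taken as wavelength-independent, so the same
    # kernel serves both wavelengths; chromophore specificity enters
    # through the extinction coefficients, not the Jacobian.
    Jd = {int(w): J for w in wavelengths}
    return Sensitivity(
        J=Jd,
        wavelengths=tuple(int(w) for w in wavelengths),
        grid_shape=head.shape,
        voxel_size=head.voxel_size,
        mu_eff={int(w): mu_eff for w in wavelengths},
    )


# ---------------------------------------------------------------------------
# Neurovascular coupling ground truth and optical recordings
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Configured coupling between MEG features and voxel hemodynamics.

    ``active_regions`` maps a region label (e.g. "SI-like") to flat
    voxel indices; ``coupling`` maps (region, feature_id) to the peak
    total-hemoglobin change in uM produced by a unit-normalized
    regressor of that feature.  DHbT splits into DHbO2 = f DHbT and
    DHbR = (1 - f) DHbT with f = ``hbo2_fraction`` (default 1.25, the
    typical activation polarity: HbO2 up, HbR down).
    """

    active_regions: dict = field(default_factory=dict)
    coupling: dict = field(default_factory=dict)
    hbo2_fraction: float = 1.25

    @classmethod
    def null(cls) -> "GroundTruth":
        """No coupled activity anywhere (beta = 0)."""
        return cls()

    def validate(self, gm_flat: np.ndarray) -> None:
        for name, vox in self.active_regions.items():
            if not np.all(gm_flat[np.asarray(vox)]):
                raise ValueError(f"active region {name!r} is not inside gray matter")
        for key, beta in self.coupling.items():
            if not np.isfinite(beta):
                raise ValueError(f"non-finite coupling weight for {key}")


def make_ball_region(
    head: HeadModel,
    center_xy: tuple[float, float] = (0.0, 0.0),
    radius_mm: float = 6.0,
) -> np.ndarray:
    """Flat indices of GM voxels within a lateral ball (an SI-like patch)."""
    centers = head.voxel_centers()
    gm = head.gm_mask.ravel()
    gm_depth = centers[gm, 2].mean()
    target = np.array([center_xy[0], center_xy[1], gm_depth])
    dist = np.linalg.norm(centers - target, axis=1)
    idx = np.nonzero(gm & (dist <= radius_mm))[0]
    if idx.size == 0:
        raise ValueError("no GM voxels inside the requested ball")
    return idx


@dataclass(frozen=True)
class NoiseConfig:
    """Physiological and instrument noise in log-amplitude units.

    Sinusoids model cardiac (~1 Hz), respiratory (~0.3 Hz) and Mayer
    wave (~0.1 Hz) oscillations with per-channel random phase; white
    noise is per-sample instrument noise and ``drift_step`` drives a
    slow random-walk drift.
    """

    white_sd: float = 0.002
    drift_step: float = 5e-5
    sinusoids: tuple = ((1.0, 0.008), (0.3, 0.003), (0.1, 0.003))

    @classmethod
    def off(cls) -> "NoiseConfig":
        return cls(white_sd=0.0, drift_step=0.0, sinusoids=())


@dataclass
class OpticalRecording:
    """Raw two-wavelength amplitude recording for one run.

    ``A`` has shape (n_pairs, n_wavelengths, n_samples); amplitudes are
    strictly positive so the log-transform of the preprocessing stage
    is defined.
    """

    A: np.ndarray
    fs: float
    wavelengths: tuple
    layout: OptodeLayout
    schedule: RunSchedule

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.A.shape[-1]) / self.fs

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("A", data=self.A, compression="gzip")
            f.attrs["fs"] = self.fs
            f.attrs["wavelengths"] = list(self.wavelengths)
            f.create_dataset("pairs", data=self.layout.pairs)


def _normalized_feature_regressors(
    feature_table: pd.DataFrame,
    trains: dict[float, StimulusTrain],
    hrf,
    fs: float,
    block_len: float,
) -> dict:
    """Unit-peak HRF regressors per (frequency, feature) at rate fs.

    Normalization is global over the four frequencies per feature, so
    the relative response size across frequencies (habituation, number
    of stimuli) is preserved and beta sets the peak DHbT in uM.
    """
    from .hemopredict import build_impulse_series, predict_response

    raw = {}
    for (freq, feat), grp in feature_table.groupby(["frequency", "feature_id"]):
        train = trains[float(freq)]
        vals = grp.sort_values("stimulus_index")["value"].to_numpy()
        _, n = build_impulse_series(vals, train, dt=hrf.dt, hrf_duration=hrf.duration)
        m_full = np.convolve(n, hrf.h)[: len(n)]
        t20 = np.arange(m_full.size) * hrf.dt
        t_run = np.arange(0.0, block_len, 1.0 / fs)
        raw[(float(freq), feat)] = np.interp(t_run, t20, m_full)
    peaks = {}
    for (freq, feat), m in raw.items():
        peaks[feat] = max(peaks.get(feat, 0.0), float(np.max(np.abs(m))))
    return {
        k: (m / peaks[k[1]] if peaks[k[1]] > 0 else m) for k, m in raw.items()
    }


def simulate_optical_run(
    schedule: RunSchedule,
    truth: GroundTruth,
    feature_table: pd.DataFrame,
    sensitivity: Sensitivity,
    head: HeadModel,
    noise_cfg: NoiseConfig | None = None,
    seed=None,
    fs: float = 10.0,
    hrf=None,
    baseline_amplitude: float = 1.0,
    layout: OptodeLayout | None = None,
) -> OpticalRecording:
    """Simulate one run of two-wavelength optical amplitudes.

    Inside each active region, DHbT(t) is the sum over coupled features
    of beta times the unit-peak regressor built from the per-stimulus
    feature values (the forward direction of the linear convolution
    model); it is split into DHbO2/DHbR, converted to absorption
    changes per wavelength through the hemoglobin extinction
    coefficients, and projected to log-amplitude through the
    sensitivity matrix.  Physiological noise is added in log-amplitude
    and the recording returned as A = A0 exp(DlogA + noise) at the
    native rate ``fs`` (10 Hz by default).
    """
    from .dotrecon import extinction_matrix
    from .hemopredict import canonical_hrf

    if noise_cfg is None:
        noise_cfg = NoiseConfig()
    if hrf is None:
        hrf = canonical_hrf()
    rng = _rng(seed)
    truth.validate(head.gm_mask.ravel())

    n_samples = int(np.ceil(schedule.duration * fs))
    t = np.arange(n_samples) / fs
    wavelengths = sensitivity.wavelengths
    n_pairs = sensitivity.n_pairs
    dlogA = np.zeros((n_pairs, len(wavelengths), n_samples), dtype=np.float32)

    if truth.active_regions and truth.coupling:
        trains = {f: make_stimulus_train(f) for f in PROTOCOL_FREQUENCIES}
        block_len = 2.0 + hrf.duration
        regs = _normalized_feature_regressors(feature_table, trains, hrf, fs, block_len)
        if not regs:
            raise ValueError("feature table has no regressors covering the schedule")
        E = extinction_matrix(wavelengths)      # (n_wav, 2): columns HbO2, HbR
        f_split = np.array([truth.hbo2_fraction, 1.0 - truth.hbo2_fraction])
        block_n = next(iter(regs.values())).size
        for region, vox in truth.active_regions.items():
            vox = np.asarray(vox)
            dhbt = np.zeros(n_samples)
            for (reg_name, feat), beta in truth.coupling.items():
                if reg_name != region or beta == 0.0:
                    continue
                for train, start in schedule.blocks:
                    i0 = int(round(start * fs))
                    i1 = min(i0 + block_n, n_samples)
                    dhbt[i0:i1] += beta * regs[(train.frequency, feat)][: i1 - i0]
            # uM -> absorption change per wavelength (1/mm)
            dmua = np.outer(E @ f_split, dhbt)              # (n_wav, n_samples)
            for wi, w in enumerate(wavelengths):
                col = sensitivity.J[w][:, vox].sum(axis=1)  # (n_pairs,)
                dlogA[:, wi, :] += np.outer(col, dmua[wi]).astype(np.float32)

    # noise synthesized in single precision (well below the physical
    # noise floor) to keep long multi-channel runs cheap
    noise = np.zeros(dlogA.shape, dtype=np.float32)
    if noise_cfg.white_sd > 0:
        noise += noise_cfg.white_sd * rng.standard_normal(dlogA.shape, dtype=np.float32)
    if noise_cfg.drift_step > 0:
        steps = noise_cfg.drift_step * rng.standard_normal(dlogA.shape, dtype=np.float32)
        noise += np.cumsum(steps, axis=-1)
    t32 = t.astype(np.float32)
    for f_hz, amp in noise_cfg.sinusoids:
        # amp sin(w t + phi) = amp cos(phi) sin(w t) + amp sin(phi) cos(w t):
        # one small matrix product per oscillation instead of per-channel sines
        phase = rng.uniform(0, 2 * np.pi, dlogA.shape[:2])
        w = np.float32(2 * np.pi * f_hz)
        basis = np.stack([np.sin(w * t32), np.cos(w * t32)])            # (2, n)
        coef = (amp * np.stack([np.cos(phase), np.sin(phase)], axis=-1)
                ).astype(np.float32)                                    # (np, nw, 2)
        noise += (coef.reshape(-1, 2) @ basis).reshape(noise.shape)

    if layout is not None:
        # realistic baseline decay with source-detector separation
        sep = np.maximum(layout.separations, 1.0)
        mu = sensitivity.mu_eff[wavelengths[0]]
        A0 = baseline_amplitude * np.exp(-mu * sep)[:, None, None] / sep[:, None, None] ** 2
        A0 = A0.astype(np.float32)
    else:
        A0 = np.float32(baseline_amplitude)
    noise += dlogA
    A = A0 * np.exp(noise, out=noise)
    return OpticalRecording(A=A, fs=fs, wavelengths=wavelengths,
                            layout=layout, schedule=schedule)


# ---------------------------------------------------------------------------
# Ellipsoid head fixture for registration
# ---------------------------------------------------------------------------

def make_ellipsoid_head(
    radii: tuple[float, float, float] = (80.0, 95.0, 70.0),
    subdivisions: int = 3,
    n_surface_points: int = 200,
    seed=0,
):
    """Synthetic ellipsoid "head" for registration exercises.

    Returns ``(mesh, landmarks, head_points, facial)``: a triangulated
    ellipsoid scalp (trimesh), a landmark table (nasion on the anterior
    pole, left/right helix-tragus junctions on the lateral poles), a
    cloud of surface points, and a boolean facial flag for points on
    the anterior-inferior surface (below the nasion), which receive
    lower weight in the surface registration error.
    """
    import trimesh

    rng = _rng(seed)
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
    mesh.apply_scale(radii)
    rx, ry, rz = radii
    landmarks = pd.DataFrame(
        [
            {"label": "nasion", "x": 0.0, "y": ry, "z": 0.0},
            {"label": "lpa", "x": -rx, "y": 0.0, "z": 0.0},
            {"label": "rpa", "x": rx, "y": 0.0, "z": 0.0},
        ]
    )
    # random points on the triangulated surface (barycentric sampling), so
    # that a perfectly registered mesh has zero surface error
    faces = np.asarray(mesh.faces)
    verts = np.asarray(mesh.vertices)
    fi = rng.integers(0, len(faces), size=n_surface_points)
    u, v = rng.random(n_surface_points), rng.random(n_surface_points)
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    a, b, c = (verts[faces[fi, k]] for k in range(3))
    head_points = a + u[:, None] * (b - a) + v[:, None] * (c - a)
    facial = (head_points[:, 1] > 0.5 * ry) & (head_points[:, 2] < 0.0)
    return mesh, landmarks, head_points, facial
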