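"""Hemodynamic response prediction from MEG evoked-field features.

Per-stimulus MEG feature amplitudes (signed AUCs of the SI deflections,
the SII 60-200 ms AUC, and the SI/SII RMS values) are placed as impulses
at the stimulus onsets and convolved with a canonical double-gamma
hemodynamic response function (HRF).  The resulting regressor is the
*predicted* total-hemoglobin response for one ~2 s stimulus train.  Two
summaries are derived from it:

* the AUC over 1-9 s after train onset (used by the across-subject
  correlation, "Method 1"), and
* five samples at 1, 3, 5, 7 and 9 s after train onset (0.5 Hz spacing,
  used by the within-subject time-course correlation, "Method 2").

Regressors are constructed on a 20 Hz grid and resampled to 2 Hz to
match the optical sampling chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import gamma as gamma_dist

from .synthgen import StimulusTrain

__all__ = [
    "FEATURES",
    "CanonicalHRF",
    "PredictedResponse",
    "DesignMatrices",
    "canonical_hrf",
    "build_impulse_series",
    "predict_response",
    "assemble_design",
    "METHOD2_SAMPLE_TIMES",
]

#: Protocol order of the six MEG features used as regressor amplitudes.
FEATURES = ("N20m", "P35m", "P60m", "SII60-200ms", "SI_RMS", "SII_RMS")

#: Method-2 sampling grid: seconds after stimulus-train onset (0.5 Hz).
METHOD2_SAMPLE_TIMES = (1.0, 3.0, 5.0, 7.0, 9.0)

#: Method-1 AUC integration window (seconds after train onset).
AUC_WINDOW = (1.0, 9.0)


@dataclass(frozen=True)
class CanonicalHRF:
    """Sampled canonical HRF kernel.

    The kernel is the standard difference of two gamma densities
    (response minus a scaled undershoot) with the response delay reduced
    by ``peak_shift`` to model the slightly faster total-hemoglobin
    response compared to BOLD.
    """

    t: np.ndarray
    h: np.ndarray
    dt: float
    response_delay: float
    undershoot_delay: float
    response_dispersion: float
    undershoot_dispersion: float
    undershoot_ratio: float
    duration: float
    peak_shift: float

    @property
    def time_to_peak(self) -> float:
        return float(self.t[int(np.argmax(self.h))])


@dataclass
class PredictedResponse:
    """Predicted hemodynamic regressor for one train and one feature."""

    t: np.ndarray          # 2 Hz time grid, seconds from train onset
    m: np.ndarray          # regressor values at 2 Hz
    auc: float             # trapezoidal integral over the 1-9 s window
    samples: np.ndarray    # values at 1, 3, 5, 7, 9 s
    frequency: float | None = None
    feature_id: str | None = None


@dataclass
class DesignMatrices:
    """Across-subject design for Method 1.

    ``y`` stacks the measured HbT AUCs, one row per (subject, frequency)
    in subject-major order; ``X`` holds the predicted AUCs for the six
    MEG features in protocol order, with identical row ordering.
    """

    y: np.ndarray
    X: np.ndarray
    rows: pd.DataFrame = field(repr=False)  # columns: subject, frequency
    features: tuple = FEATURES


def canonical_hrf(
    dt: float = 0.05,
    response_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    response_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
    duration: float = 32.0,
    peak_shift: float = -0.5,
) -> CanonicalHRF:
    """Build the canonical double-gamma HRF kernel.

    With the default parameters the unshifted kernel peaks at 5.0 s; the
    ``peak_shift`` of -0.5 s is applied to the response-delay parameter
    (6 -> 5.5 s) rather than as a post-hoc time shift, so that h(0) = 0
    is preserved and the kernel remains a valid density difference.

    Parameters
    ----------
    dt
        Sampling interval in seconds (default 0.05 s, i.e. 20 Hz).
    response_delay, undershoot_delay
        Gamma-density delay parameters in seconds (shape = delay/dispersion).
    undershoot_ratio
        Amplitude of the undershoot relative to the main response.
    duration
        Kernel support in seconds (truncated at this length).
    peak_shift
        Added to ``response_delay`` (negative values shorten time-to-peak).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    delay = response_delay + peak_shift
    if delay <= response_dispersion:
        raise ValueError("shifted response delay must exceed the dispersion")
    t = np.arange(0.0, duration + dt / 2, dt)
    h = gamma_dist.pdf(t, delay / response_dispersion, scale=response_dispersion)
    h = h - undershoot_ratio * gamma_dist.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    return CanonicalHRF(
        t=t, h=h, dt=dt,
        response_delay=response_delay,
        undershoot_delay=undershoot_delay,
        response_dispersion=response_dispersion,
        undershoot_dispersion=undershoot_dispersion,
        undershoot_ratio=undershoot_ratio,
        duration=duration,
        peak_shift=peak_shift,
    )


def build_impulse_series(
    values: np.ndarray,
    train: StimulusTrain,
    dt: float = 0.05,
    duration: float | None = None,
    hrf_duration: float = 32.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Place per-stimulus feature values as impulses on a 20 Hz grid.

    Each stimulus in the train contributes a single nonzero sample at
    its onset (rounded to the nearest grid bin) whose value is the
    feature amplitude (AUC or RMS) for that stimulus.

    Returns ``(t, n)``: the time grid and the impulse series.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (train.n_stimuli,):
        raise ValueError(
            f"need one value per stimulus ({train.n_stimuli}), got shape {values.shape}"
        )
    if duration is None:
        duration = train.onsets[-1] + hrf_duration
    t = np.arange(0.0, duration + dt / 2, dt)
    n = np.zeros_like(t)
    idx = np.rint(train.onsets / dt).astype(int)
    if np.any(idx < 0) or np.any(idx >= t.size):
        raise ValueError("stimulus onsets fall outside the impulse grid")
    np.add.at(n, idx, values)
    return t, n


def predict_response(
    n: np.ndarray,
    hrf: CanonicalHRF,
    fs_out: float = 2.0,
    frequency: float | None = None,
    feature_id: str | None = None,
) -> PredictedResponse:
    """Convolve an impulse series with the HRF and summarize.

    The full-rate (20 Hz) linear convolution is decimated to ``fs_out``
    (2 Hz) with an anti-aliasing FIR filter; the AUC is the trapezoidal
    integral of the 2 Hz regressor over 1-9 s, and the Method-2 samples
    are read off the 2 Hz grid at 1, 3, 5, 7 and 9 s.
    """
    fs_in = 1.0 / hrf.dt
    q = fs_in / fs_out
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"input rate {fs_in} Hz is not an integer multiple of {fs_out} Hz")
    q = int(round(q))
    m_full = np.convolve(np.asarray(n, dtype=float), hrf.h)[: len(n)]
    if q > 1:
        m = signal.decimate(m_full, q, ftype="fir", zero_phase=True)
    else:
        m = m_full
    t = np.arange(m.size) / fs_out
    lo, hi = AUC_WINDOW
    in_win = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if in_win.sum() < 2:
        raise ValueError("regressor too short to cover the 1-9 s AUC window")
    auc = float(np.trapezoid(m[in_win], t[in_win]))
    sample_idx = np.rint(np.asarray(METHOD2_SAMPLE_TIMES) * fs_out).astype(int)
    if sample_idx.max() >= m.size:
        raise ValueError("regressor too short to cover the Method-2 sample grid")
    return PredictedResponse(
        t=t, m=m, auc=auc, samples=m[sample_idx].copy(),
        frequency=frequency, feature_id=feature_id,
    )


def predict_from_features(
    feature_table: pd.DataFrame,
    trains: dict[float, StimulusTrain],
    hrf: CanonicalHRF | None = None,
) -> pd.DataFrame:
    """Predict regressor summaries for every (subject, frequency, feature).

    ``feature_table`` is the tidy output of the MEG feature extraction
    with columns ``subject, frequency, stimulus_index, feature_id,
    value``.  Returns a tidy frame with one row per (subject, frequency,
    feature) holding ``auc`` and ``sample_1 .. sample_9``.
    """
    if hrf is None:
        hrf = canonical_hrf()
    out = []
    for (subj, freq, feat), grp in feature_table.groupby(
        ["subject", "frequency", "feature_id"], sort=True
    ):
        train = trains[float(freq)]
        vals = (
            grp.sort_values("stimulus_index")["value"].to_numpy()
        )
        _, n = build_impulse_series(vals, train, dt=hrf.dt, hrf_duration=hrf.duration)
        pred = predict_response(n, hrf, frequency=freq, feature_id=feat)
        row = {"subject": subj, "frequency": freq, "feature_id": feat, "auc": pred.auc}
        for t_s, v in zip(METHOD2_SAMPLE_TIMES, pred.samples):
            row[f"sample_{int(t_s)}"] = v
        out.append(row)
    return pd.DataFrame(out)


def assemble_design(
    measured_auc: pd.DataFrame,
    predictions: pd.DataFrame,
    frequencies: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    features: tuple[str, ...] = FEATURES,
) -> DesignMatrices:
    """Assemble the Method-1 regression vectors.

    Parameters
    ----------
    measured_auc
        Columns ``subject, frequency, value`` -- the measured HbT AUC
        per (subject, frequency) cell (one voxel or cluster average).
    predictions
        Output of :func:`predict_from_features` (needs ``auc``).

    Rows follow subject-major, frequency-minor order.  Cells missing
    from either table are dropped from both ``y`` and ``X`` with a
    warning naming the cell.
    """
    meas = measured_auc.set_index(["subject", "frequency"])["value"]
    pred = predictions.set_index(["subject", "frequency", "feature_id"])["auc"]
    subjects = sorted(measured_auc["subject"].unique())
    rows, y, X = [], [], []
    for s in subjects:
        for f in frequencies:
            key = (s, f)
            try:
                yv = float(meas.loc[key])
                xv = [float(pred.loc[(s, f, feat)]) for feat in features]
            except KeyError:
                warnings.warn(f"dropping incomplete cell subject={s} frequency={f}")
                continue
            rows.append({"subject": s, "frequency": f})
            y.append(yv)
            X.append(xv)
    if not rows:
        raise ValueError("no complete (subject, frequency) cells")
    return DesignMatrices(
        y=np.asarray(y), X=np.asarray(X), rows=pd.DataFrame(rows), features=features
    )
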