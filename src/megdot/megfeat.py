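"""MEG dipole-waveform averaging, baseline correction and feature extraction.

The equivalent-current-dipole (ECD) time series from SI and SII are
averaged per stimulation frequency, the inter-stimulus baseline drift
is removed with a smoothed piecewise-linear fit to the -10..0 ms
pre-stimulus windows, and six per-stimulus feature values are
extracted: signed AUCs of the SI N20m/P35m/P60m deflections (lobe
bounds from zero crossings between peaks), the SII AUC over a fixed
60-200 ms window, and SI/SII RMS over 10-200 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .synthgen import DipoleRecord

__all__ = [
    "TABLE_WINDOWS",
    "preprocess_and_average",
    "remove_baseline_drift",
    "extract_features",
]

#: Empirical feature windows: (begin mean, begin SD, end mean, end SD),
#: milliseconds after stimulus onset.  SI peaks are searched within
#: mean +/- 3 SD of these bounds; SII and RMS windows are fixed.
TABLE_WINDOWS = {
    "N20m": (18.0, 2.0, 27.0, 2.0),
    "P35m": (28.0, 2.0, 40.0, 7.0),
    "P60m": (42.0, 8.0, 135.0, 26.0),
}
SII_WINDOW = (60.0, 200.0)
RMS_WINDOW = (10.0, 200.0)
#: Hard bounds for any AUC window (ms post stimulus).
AUC_BOUNDS = (10.0, 200.0)


def _zero_phase_lowpass(x: np.ndarray, cutoff_hz: float, fs: float, order: int = 4):
    """Zero-phase Butterworth low-pass with a true -3 dB point at ``cutoff_hz``.

    filtfilt squares the magnitude response, so the design cutoff is
    raised by (sqrt(2)-1)^(-1/(2 order)) to keep the two-pass -3 dB
    point at the requested frequency.
    """
    adj = cutoff_hz / (np.sqrt(2.0) - 1.0) ** (1.0 / (2.0 * order))
    adj = min(adj, 0.99 * fs / 2.0)
    sos = signal.butter(order, adj, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


@lru_cache(maxsize=32)
def _epoch_filters(fs: float, lowpass: float, notch: float):
    designs = []
    if notch and notch < fs / 2:
        designs.append(signal.iirnotch(notch, Q=30.0, fs=fs))
    sos = None
    if lowpass and lowpass < fs / 2:
        sos = signal.butter(4, lowpass, btype="low", fs=fs, output="sos")
    return designs, sos


def _filter_epoch(x: np.ndarray, fs: float, lowpass: float = 250.0,
                  notch: float = 50.0) -> np.ndarray:
    """Zero-phase notch + low-pass along the last axis (1D or stacked 2D)."""
    notches, sos = _epoch_filters(fs, lowpass, notch)
    for b, a in notches:
        x = signal.filtfilt(b, a, x, axis=-1)
    if sos is not None:
        x = signal.sosfiltfilt(sos, x, axis=-1)
    return x


def preprocess_and_average(
    epochs: list[DipoleRecord],
    blank_artifact: bool = True,
    lowpass: float = 250.0,
    notch: float = 50.0,
) -> dict[float, DipoleRecord]:
    """Filter and average dipole epochs per stimulation frequency.

    Each accepted epoch is notch-filtered at the power-line frequency,
    low-pass filtered at 250 Hz (zero-phase, Butterworth order 4) and,
    optionally, median-filter blanked over the first 10 ms after each
    stimulus where the electrical-stimulator artifact lives.  Epochs of
    the same frequency are then averaged sample-by-sample.

    Returns a dict mapping frequency to the averaged record.  A
    frequency with zero accepted epochs is absent from the result and
    reported with a warning.
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    by_freq: dict[float, list[DipoleRecord]] = {}
    for ep in epochs:
        by_freq.setdefault(float(ep.frequency), []).append(ep)
    out = {}
    for freq, eps in sorted(by_freq.items()):
        ref = eps[0]
        n = min(ep.t.size for ep in eps)
        onsets = ref.train.onsets if ref.train is not None else np.array([0.0])
        avg = {}
        for name in ref.waveforms:
            # epochs of one frequency share a time grid: filter them as
            # one 2D batch (zero-phase filtering is per-row)
            X = np.stack([ep.waveforms[name][:n] for ep in eps])
            X = _filter_epoch(X, ref.fs, lowpass=lowpass, notch=notch)
            if blank_artifact:
                k = max(3, int(round(2 * 10.0 * ref.fs / 1000.0)) | 1)
                t = ref.t[:n]
                for onset in onsets:
                    idx = np.nonzero((t >= onset) & (t < onset + 0.010))[0]
                    if idx.size == 0:
                        continue
                    lo = max(0, idx[0] - k)
                    hi = min(n, idx[-1] + k + 1)
                    med = ndimage.median_filter(X[:, lo:hi], size=(1, k),
                                                mode="nearest")
                    X[:, idx] = med[:, idx - lo]
            avg[name] = X.mean(axis=0)
        out[freq] = DipoleRecord(
            subject_id=ref.subject_id, frequency=freq, fs=ref.fs,
            t=ref.t[:n].copy(), waveforms=avg, train=ref.train,
        )
    missing = set()
    for ep in epochs:
        if float(ep.frequency) not in out:
            missing.add(float(ep.frequency))
    if missing:
        warnings.warn(f"no accepted epochs for frequencies {sorted(missing)}")
    return out


def remove_baseline_drift(avg: DipoleRecord, cutoff_hz: float = 8.0) -> DipoleRecord:
    """Subtract the smoothed piecewise-linear pre-stimulus baseline.

    For each stimulus, the mean over the -10..0 ms pre-stimulus window
    anchors a piecewise-linear function (constant before the first and
    after the last anchor), which is low-pass filtered with a -3 dB
    cutoff at 8 Hz and subtracted from the averaged waveform.  This
    removes the offset left by incompletely recovered responses at the
    highest stimulation frequency without distorting the evoked peaks.
    """
    if avg.train is None:
        raise ValueError("averaged record needs its stimulus train for baseline anchors")
    onsets = avg.train.onsets
    t = avg.t
    out_wf = {}
    for name, x in avg.waveforms.items():
        anchors_t, anchors_v = [], []
        for onset in onsets:
            m = (t >= onset - 0.010) & (t < onset)
            if not np.any(m):
                raise ValueError(f"no -10..0 ms window inside the epoch for onset {onset}")
            anchors_t.append(onset - 0.005)
            anchors_v.append(float(x[m].mean()))
        base = np.interp(t, anchors_t, anchors_v)
        if len(anchors_t) > 1:
            base = _zero_phase_lowpass(base, cutoff_hz, avg.fs)
        out_wf[name] = x - base
    return replace(avg, waveforms=out_wf)


def _search_peak(t_ms, x, lo, hi):
    """Index of the largest local extremum of |x| within [lo, hi] ms.

    A local maximum of |x| is required so that the rising flank of a
    larger neighboring deflection at the window edge cannot win; when
    the window contains no interior extremum the plain argmax is the
    fallback.  Earliest extremum wins ties (argmax picks the first).
    """
    m = (t_ms >= lo) & (t_ms <= hi)
    idx = np.nonzero(m)[0]
    if idx.size == 0:
        return None
    seg = np.abs(x[idx])
    pk, _ = signal.find_peaks(seg)
    if pk.size:
        return int(idx[pk[np.argmax(seg[pk])]])
    return int(idx[np.argmax(seg)])


def _lobe_bounds(x, i_peak, i_lo, i_hi):
    """Window bounds around a peak: nearest zero crossings, else |x| minima."""
    s = np.sign(x[i_peak])
    i0 = i_lo
    for i in range(i_peak, i_lo - 1, -1):
        if x[i] == 0:
            i0 = i
            break
        if np.sign(x[i]) != s:
            # last sample of the lobe's own polarity, so neighboring
            # lobes' windows stay disjoint
            i0 = min(i + 1, i_peak)
            break
    else:
        seg = np.abs(x[i_lo:i_peak + 1])
        i0 = i_lo + int(np.argmin(seg)) if seg.size else i_lo
    i1 = i_hi
    for i in range(i_peak, i_hi + 1):
        if x[i] == 0:
            i1 = i
            break
        if np.sign(x[i]) != s:
            i1 = max(i - 1, i_peak)
            break
    else:
        seg = np.abs(x[i_peak:i_hi + 1])
        i1 = i_peak + int(np.argmin(seg)) if seg.size else i_hi
    return i0, i1


def extract_features(
    avg: DipoleRecord,
    rectify: bool = False,
) -> pd.DataFrame:
    """Extract the six per-stimulus feature values from averaged waveforms.

    SI N20m/P35m/P60m: the peak is the largest-|x| extremum inside the
    empirical window (mean +/- 3 SD of the begin/end points, and after
    the previous peak); the lobe is bounded by the nearest zero
    crossings (falling back to minima of |x| when no crossing exists)
    and integrated with the trapezoidal rule to a signed AUC in nAm s.
    SII AUC uses the fixed 60-200 ms window; SI/SII RMS use 10-200 ms.

    Returns a tidy frame with columns ``subject, frequency,
    stimulus_index, feature_id, value, window_begin_ms, window_end_ms``.
    """
    if avg.train is None:
        raise ValueError("record needs its stimulus train")
    t = avg.t
    fs = avg.fs
    si = avg.waveforms["SI"]
    sii = avg.waveforms["SII"]
    rows = []
    for k, onset in enumerate(avg.train.onsets):
        t_ms = (t - onset) * 1000.0
        prev_peak_ms = AUC_BOUNDS[0]
        for feat, (b_mu, b_sd, e_mu, e_sd) in TABLE_WINDOWS.items():
            lo = max(b_mu - 3 * b_sd, prev_peak_ms, AUC_BOUNDS[0])
            hi = min(e_mu + 3 * e_sd, AUC_BOUNDS[1])
            i_peak = _search_peak(t_ms, si, lo, hi)
            if i_peak is None:
                warnings.warn(f"no samples in search window for {feat}, stimulus {k}")
                continue
            i_lo = int(np.searchsorted(t_ms, lo))
            i_hi = int(np.searchsorted(t_ms, hi, side="right")) - 1
            i0, i1 = _lobe_bounds(si, i_peak, i_lo, i_hi)
            if i1 <= i0:
                i0, i1 = i_lo, i_hi
            auc = float(np.trapezoid(si[i0:i1 + 1], t[i0:i1 + 1]))
            if rectify:
                auc = abs(auc)
            rows.append({
                "subject": avg.subject_id, "frequency": avg.frequency,
                "stimulus_index": k, "feature_id": feat, "value": auc,
                "window_begin_ms": float(t_ms[i0]), "window_end_ms": float(t_ms[i1]),
            })
            prev_peak_ms = t_ms[i_peak] + 2.0 / fs * 1000.0
        m_sii = (t_ms >= SII_WINDOW[0]) & (t_ms <= SII_WINDOW[1])
        auc = float(np.trapezoid(sii[m_sii], t[m_sii]))
        if rectify:
            auc = abs(auc)
        rows.append({
            "subject": avg.subject_id, "frequency": avg.frequency,
            "stimulus_index": k, "feature_id": "SII60-200ms", "value": auc,
            "window_begin_ms": SII_WINDOW[0], "window_end_ms": SII_WINDOW[1],
        })
        m_rms = (t_ms >= RMS_WINDOW[0]) & (t_ms <= RMS_WINDOW[1])
        for feat, wf in (("SI_RMS", si), ("SII_RMS", sii)):
            rows.append({
                "subject": avg.subject_id, "frequency": avg.frequency,
                "stimulus_index": k, "feature_id": feat,
                "value": float(np.sqrt(np.mean(wf[m_rms] ** 2))),
                "window_begin_ms": RMS_WINDOW[0], "window_end_ms": RMS_WINDOW[1],
            })
    return pd.DataFrame(rows)
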