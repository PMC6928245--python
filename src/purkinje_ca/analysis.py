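"""Derived metrics: AP morphology, Ca²⁺ transients, afterdepolarizations, sparks.

All functions operate on uniformly sampled traces (numpy arrays plus a time
vector in ms) and are deterministic.  Detection thresholds are keyword
parameters with the package defaults; every event-detection routine reports
them back in its output records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "APMetrics",
    "CaTransientMetrics",
    "SparkEvent",
    "EventRecord",
    "ap_metrics",
    "ap_metrics_all",
    "ca_metrics",
    "detect_events",
    "detect_sparks_simple",
    "detect_sparks_iterative",
    "spark_frequency",
    "biphasic_transient",
]

AP_DVDT_THRESHOLD = 10.0  # mV/ms, upstroke detection
DAD_THRESHOLD = 2.0  # mV above diastolic baseline
AP_REFRACTORY = 25.0  # ms, minimum separation between detected upstrokes


@dataclass(frozen=True)
class APMetrics:
    """Morphology of one action potential."""

    t_upstroke: float  # ms, instant of dV/dt max
    dvdt_max: float  # mV/ms
    peak: float  # mV
    diastolic: float  # mV
    amplitude: float  # mV
    apd50: float  # ms
    apd70: float
    apd90: float


@dataclass(frozen=True)
class CaTransientMetrics:
    peak_amplitude: float  # µM above baseline
    time_to_peak: float  # ms from stimulus onset
    decay_time: float  # ms, peak → 90% return to baseline
    decay_tau: float  # ms, monoexponential fit of the decay limb
    baseline: float  # µM


@dataclass(frozen=True)
class SparkEvent:
    disc: int
    t_start: float  # ms
    duration: float  # ms
    peak_flux: float  # µM·µm³/ms


@dataclass
class EventRecord:
    """DADs and triggered APs detected in an observation window."""

    dads: list = field(default_factory=list)  # (time ms, amplitude mV)
    triggered_aps: list = field(default_factory=list)  # times ms
    window: tuple = (0.0, 0.0)
    dad_threshold: float = DAD_THRESHOLD
    ap_dvdt_threshold: float = AP_DVDT_THRESHOLD

    @property
    def n_dads(self) -> int:
        return len(self.dads)

    @property
    def n_triggered(self) -> int:
        return len(self.triggered_aps)


def _find_upstrokes(v: np.ndarray, t: np.ndarray, dvdt_threshold: float) -> np.ndarray:
    """Indices of upstroke onsets (dV/dt crossing the threshold upward)."""
    dt = t[1] - t[0]
    dvdt = np.diff(v) / dt
    above = dvdt > dvdt_threshold
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if onsets.size == 0:
        return onsets
    keep = [int(onsets[0])]
    for i in onsets[1:]:
        if t[i] - t[keep[-1]] >= AP_REFRACTORY:
            keep.append(int(i))
    return np.asarray(keep)


def _interp_crossing(t0, t1, v0, v1, level) -> float:
    if v1 == v0:
        return t1
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_metrics_all(
    v: np.ndarray, t: np.ndarray, dvdt_threshold: float = AP_DVDT_THRESHOLD
) -> list[APMetrics]:
    """Metrics for every action potential found in the trace.

    dV/dt_max is the maximum forward-difference slope during the upstroke;
    APDx runs from the instant of dV/dt_max to x% repolarization of the
    amplitude (peak − diastolic), with linear interpolation at crossings.
    """
    v = np.asarray(v, float)
    t = np.asarray(t, float)
    dt = t[1] - t[0]
    onsets = _find_upstrokes(v, t, dvdt_threshold)
    out: list[APMetrics] = []
    for n, i0 in enumerate(onsets):
        i_end = onsets[n + 1] if n + 1 < len(onsets) else len(v) - 1
        # diastolic reference: median of the 5 ms preceding the onset
        j0 = max(0, i0 - int(round(5.0 / dt)))
        diastolic = float(np.median(v[j0 : i0 + 1])) if i0 > j0 else float(v[i0])
        # upstroke region: from onset until v peaks
        seg = slice(i0, i_end + 1)
        i_peak = i0 + int(np.argmax(v[seg]))
        if i_peak <= i0:
            continue
        dvdt_seg = np.diff(v[i0 : i_peak + 1]) / dt
        k = int(np.argmax(dvdt_seg))
        dvdt_max = float(dvdt_seg[k])
        i_up = i0 + k
        peak = float(v[i_peak])
        amplitude = peak - diastolic
        if amplitude <= 0:
            continue
        apds = {}
        for frac, name in ((0.5, "apd50"), (0.7, "apd70"), (0.9, "apd90")):
            level = peak - frac * amplitude
            apds[name] = np.nan
            for i in range(i_peak, i_end):
                if v[i] > level >= v[i + 1]:
                    tc = _interp_crossing(t[i], t[i + 1], v[i], v[i + 1], level)
                    apds[name] = tc - t[i_up]
                    break
        out.append(
            APMetrics(
                t_upstroke=float(t[i_up]),
                dvdt_max=dvdt_max,
                peak=peak,
                diastolic=diastolic,
                amplitude=amplitude,
                **apds,
            )
        )
    return out


def ap_metrics(
    v: np.ndarray, t: np.ndarray, dvdt_threshold: float = AP_DVDT_THRESHOLD
) -> APMetrics:
    """Metrics of the first action potential in the trace."""
    all_ = ap_metrics_all(v, t, dvdt_threshold)
    if not all_:
        raise ValueError("no action potential detected in trace")
    return all_[0]


def ca_metrics(
    ca: np.ndarray, t: np.ndarray, stim_time: float, t_end: float | None = None
) -> CaTransientMetrics:
    """Morphology of a single Ca²⁺ transient following a stimulus.

    Baseline is the trace value at the stimulus onset; ``decay_time`` is the
    time from the peak to 90% return toward baseline; ``decay_tau`` comes
    from a log-linear fit of the decay limb between the peak and the 90%
    point.
    """
    ca = np.asarray(ca, float)
    t = np.asarray(t, float)
    i0 = int(np.searchsorted(t, stim_time))
    i1 = int(np.searchsorted(t, t_end)) if t_end is not None else len(t)
    if i1 - i0 < 3:
        raise ValueError("transient window too short")
    seg = ca[i0:i1]
    ts = t[i0:i1]
    baseline = float(seg[0])
    i_peak = int(np.argmax(seg))
    amp = float(seg[i_peak] - baseline)
    ttp = float(ts[i_peak] - stim_time)
    if amp <= 0:
        return CaTransientMetrics(0.0, 0.0, 0.0, 0.0, baseline)
    level = baseline + 0.1 * amp
    decay_time = np.nan
    i90 = None
    for i in range(i_peak, len(seg) - 1):
        if seg[i] > level >= seg[i + 1]:
            tc = _interp_crossing(ts[i], ts[i + 1], seg[i], seg[i + 1], level)
            decay_time = tc - ts[i_peak]
            i90 = i + 1
            break
    decay_tau = np.nan
    j_end = i90 if i90 is not None else len(seg)
    decay = seg[i_peak:j_end] - baseline
    tt = ts[i_peak:j_end] - ts[i_peak]
    pos = decay > 0
    if pos.sum() >= 3:
        coef = np.polyfit(tt[pos], np.log(decay[pos]), 1)
        if coef[0] < 0:
            decay_tau = -1.0 / coef[0]
    return CaTransientMetrics(amp, ttp, float(decay_time), float(decay_tau), baseline)


def detect_events(
    v: np.ndarray,
    t: np.ndarray,
    window: tuple[float, float],
    stim_times: np.ndarray | None = None,
    dad_threshold: float = DAD_THRESHOLD,
    ap_dvdt_threshold: float = AP_DVDT_THRESHOLD,
) -> EventRecord:
    """Classify post-pacing depolarizations into DADs and triggered APs.

    A triggered AP is a non-paced upstroke whose maximum dV/dt exceeds
    ``ap_dvdt_threshold`` (upstrokes within 5 ms of a stimulus onset are
    paced and excluded).  A DAD is a subthreshold local depolarization at
    least ``dad_threshold`` mV above the running diastolic baseline that
    does not elicit an AP; classification is exclusive.
    """
    v = np.asarray(v, float)
    t = np.asarray(t, float)
    stim_times = np.asarray(stim_times if stim_times is not None else [], float)
    rec = EventRecord(
        window=window, dad_threshold=dad_threshold, ap_dvdt_threshold=ap_dvdt_threshold
    )
    sel = (t >= window[0]) & (t <= window[1])
    if sel.sum() < 3:
        return rec
    tv = t[sel]
    vv = v[sel]
    dt = tv[1] - tv[0]
    onsets = _find_upstrokes(vv, tv, ap_dvdt_threshold)
    ap_mask = np.zeros(len(vv), dtype=bool)
    for i0 in onsets:
        paced = stim_times.size and np.any(np.abs(tv[i0] - stim_times) <= 5.0)
        if not paced:
            rec.triggered_aps.append(float(tv[i0]))
        # mask out the AP body until v returns below the pre-upstroke level + 5 mV
        vref = vv[max(0, i0 - int(round(2.0 / dt)))]
        j = i0
        while j < len(vv) - 1 and not (j > i0 + int(5 / dt) and vv[j] < vref + 5.0):
            ap_mask[j] = True
            j += 1
    # diastolic segments: find subthreshold humps by peak prominence
    dia = ~ap_mask
    vd = np.where(dia, vv, np.nan)
    finite = np.isfinite(vd)
    if finite.sum() > 10:
        filled = vd.copy()
        # split into contiguous diastolic runs and find peaks per run
        run_start = None
        for i in range(len(filled) + 1):
            inside = i < len(filled) and finite[i]
            if inside and run_start is None:
                run_start = i
            elif not inside and run_start is not None:
                seg = vv[run_start:i]
                if len(seg) > int(2.0 / dt):
                    peaks, props = signal.find_peaks(seg, prominence=dad_threshold)
                    for p, prom in zip(peaks, props["prominences"]):
                        rec.dads.append((float(tv[run_start + p]), float(prom)))
                run_start = None
    return rec


def detect_sparks_simple(
    ryr_flux: np.ndarray,
    t: np.ndarray,
    min_duration: float = 1.0,
    min_amplitude: float = 0.5,
) -> list[SparkEvent]:
    """Sparks as supra-baseline RyR-flux excursions sustained ≥ ``min_duration`` ms.

    Intended for the low-variability (no-isoproterenol) regime where single
    release events are directly visible.  ``ryr_flux`` is (n_samples,
    n_discs); the per-disc baseline is the median (quiescent) flux level.
    """
    flux = np.atleast_2d(np.asarray(ryr_flux, float))
    if flux.shape[0] == len(t):
        flux = flux.T  # (discs, samples)
    dt = t[1] - t[0]
    events: list[SparkEvent] = []
    for disc in range(flux.shape[0]):
        f = flux[disc]
        thr = float(np.median(f)) + min_amplitude
        above = f > thr
        i = 0
        n = len(f)
        while i < n:
            if above[i]:
                j = i
                while j < n and above[j]:
                    j += 1
                duration = (j - i) * dt
                if duration >= min_duration:
                    events.append(
                        SparkEvent(
                            disc=disc,
                            t_start=float(t[i]),
                            duration=float(duration),
                            peak_flux=float(f[i:j].max()),
                        )
                    )
                i = j
            else:
                i += 1
    return sorted(events, key=lambda e: (e.t_start, e.disc))


def detect_sparks_iterative(
    ryr_flux: np.ndarray,
    t: np.ndarray,
    min_duration: float = 1.0,
) -> list[SparkEvent]:
    """Two-pass 2-SD spark detector for the high-variability regime.

    Works on the per-disc first differences of the flux ("changes in flux").
    Pass 1 flags samples whose absolute change exceeds mean + 2·SD; pass 2
    removes those, recomputes mean and SD on the remainder, and flags again
    at the new mean + 2·SD.  The two flag sets are combined; a spark runs
    from a flagged upward change to the next flagged downward change.
    Events shorter than ``min_duration`` ms are discarded, as are intervals
    whose flux does not remain elevated above the pre-event level by the
    detection threshold for the whole interval (the "sustained" rule).
    Deterministic.
    """
    flux = np.atleast_2d(np.asarray(ryr_flux, float))
    if flux.shape[0] == len(t):
        flux = flux.T
    dt = t[1] - t[0]
    if (len(t) - 1) * dt < min_duration:
        raise ValueError("trace shorter than the minimum spark duration")
    events: list[SparkEvent] = []
    for disc in range(flux.shape[0]):
        f = flux[disc]
        d = np.diff(f)
        a = np.abs(d)
        thr1 = a.mean() + 2.0 * a.std()
        flag1 = a > thr1
        rest = a[~flag1]
        if rest.size:
            thr = rest.mean() + 2.0 * rest.std()
            flags = flag1 | (a > thr)
        else:
            thr = thr1
            flags = flag1

        def sustained(start: int, end: int) -> bool:
            return bool(np.min(f[start + 1 : end + 1]) >= f[start] + thr)

        idx = np.flatnonzero(flags)
        open_start = None
        for i in idx:
            if d[i] > 0:
                if open_start is None:
                    open_start = i
                elif f[i] <= f[open_start] + thr:
                    # the earlier opening never produced a sustained
                    # elevation; re-anchor the event at this upward change
                    open_start = i
            else:
                if open_start is not None:
                    # a flagged downward change only ends the event when the
                    # flux has actually returned toward the pre-event level;
                    # otherwise it is an intra-event fluctuation
                    if f[i + 1] >= f[open_start] + thr:
                        continue
                    duration = (i - open_start) * dt
                    if duration >= min_duration and sustained(open_start, i):
                        events.append(
                            SparkEvent(
                                disc=disc,
                                t_start=float(t[open_start]),
                                duration=float(duration),
                                peak_flux=float(f[open_start : i + 1].max()),
                            )
                        )
                    open_start = None
        if open_start is not None:
            duration = (len(f) - 1 - open_start) * dt
            if duration >= min_duration and sustained(open_start, len(f) - 1):
                events.append(
                    SparkEvent(
                        disc=disc,
                        t_start=float(t[open_start]),
                        duration=float(duration),
                        peak_flux=float(f[open_start:].max()),
                    )
                )
    return sorted(events, key=lambda e: (e.t_start, e.disc))


def spark_frequency(events: list, cell_length: float, window: float) -> float:
    """Spark frequency in events per 100 µm per second.

    ``cell_length`` in µm, ``window`` in s.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    return len(events) / ((cell_length / 100.0) * window)


def biphasic_transient(
    ca_subsl: np.ndarray,
    ca_subsr: np.ndarray,
    t: np.ndarray,
    t_start: float,
    t_end: float,
    min_prominence_frac: float = 0.03,
) -> dict:
    """Test the biphasic shape of the sub-SL transient during one beat.

    Returns the times of the sub-SL maxima (sarcolemmal influx peak and the
    later SR-release peak) and of the sub-SR peak, plus a flag for whether
    the sub-SR peak precedes the second sub-SL peak.
    """
    sel = (t >= t_start) & (t <= t_end)
    ts = t[sel]
    sl = np.asarray(ca_subsl, float)[sel]
    sr = np.asarray(ca_subsr, float)[sel]
    prom = min_prominence_frac * (sl.max() - sl.min())
    peaks, _ = signal.find_peaks(sl, prominence=prom)
    sr_peak_t = float(ts[np.argmax(sr)])
    out = {
        "sl_peak_times": [float(ts[p]) for p in peaks],
        "sr_peak_time": sr_peak_t,
        "biphasic": False,
        "sr_before_second_sl_peak": False,
    }
    if len(peaks) >= 2:
        out["biphasic"] = True
        out["sr_before_second_sl_peak"] = sr_peak_t < float(ts[peaks[1]])
    return out
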