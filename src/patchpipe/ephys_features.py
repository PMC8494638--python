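"""Sweep QC and intrinsic electrophysiology feature extraction.

Spike detection finds upward crossings of a threshold (default 20 mV/ms) on
the smoothed voltage derivative inside the stimulus window, then refines
candidates by threshold-to-peak height, threshold-to-peak interval and
absolute peak height.  Spike threshold is the point where dV/dt first
reaches a fraction (default 5%) of that spike's maximal upstroke.

Per-cell features (18): rmp, r_input, tau, sag, rheobase, fi_slope, latency,
initial_rate, mean_rate, adaptation, and eight AP-shape features taken from
the first spike of the rheobase sweep.  Voltages are reported uncorrected
for the liquid junction potential; the -14 mV offset is carried as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .sweeps import Sweep

__all__ = [
    "SpikeIndices",
    "SpikeRecord",
    "EphysFeatureSet",
    "FEATURE_NAMES",
    "smoothed_dvdt",
    "detect_spikes",
    "extract_spike_features",
    "sweep_qc",
    "subthreshold_features",
    "suprathreshold_features",
    "cell_features",
]

JUNCTION_POTENTIAL_OFFSET_MV = -14.0

FEATURE_NAMES = [
    "rmp",
    "r_input",
    "tau",
    "sag",
    "rheobase",
    "fi_slope",
    "latency",
    "initial_rate",
    "mean_rate",
    "adaptation",
    "ap_threshold",
    "ap_height",
    "ap_width",
    "ap_fast_ahp",
    "ap_trough",
    "ap_upstroke",
    "ap_downstroke",
    "ap_updown_ratio",
]


@dataclass(frozen=True)
class SpikeIndices:
    threshold: int
    peak: int
    trough: int


@dataclass
class SpikeRecord:
    threshold_v: float  # mV
    threshold_t: float  # s
    peak_v: float  # mV
    height: float  # mV
    width_half_height: float  # ms
    fast_ahp: float  # mV, relative to threshold
    trough: float  # mV, relative to threshold
    upstroke: float  # mV/ms
    downstroke: float  # mV/ms
    updown_ratio: float


@dataclass
class EphysFeatureSet:
    """The 18 per-cell intrinsic features; missing values are None."""

    rmp: float | None = None
    r_input: float | None = None
    tau: float | None = None
    sag: float | None = None
    rheobase: float | None = None
    fi_slope: float | None = None
    latency: float | None = None
    initial_rate: float | None = None
    mean_rate: float | None = None
    adaptation: float | None = None
    ap_threshold: float | None = None
    ap_height: float | None = None
    ap_width: float | None = None
    ap_fast_ahp: float | None = None
    ap_trough: float | None = None
    ap_upstroke: float | None = None
    ap_downstroke: float | None = None
    ap_updown_ratio: float | None = None
    missing_reasons: dict = field(default_factory=dict)
    junction_offset_mv: float = JUNCTION_POTENTIAL_OFFSET_MV

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in FEATURE_NAMES}

    @property
    def n_present(self) -> int:
        return sum(getattr(self, f) is not None for f in FEATURE_NAMES)


def smoothed_dvdt(sweep: Sweep, window_ms: float = 0.5) -> np.ndarray:
    """Smoothed voltage derivative in mV/ms (local-polynomial smoother)."""
    n_win = int(round(window_ms * 1e-3 * sweep.sampling_rate))
    if n_win < 2:
        raise ValueError("smoothing window shorter than 2 samples")
    if n_win % 2 == 0:
        n_win += 1
    n_win = max(n_win, 5)
    dt_ms = 1e3 / sweep.sampling_rate
    return savgol_filter(sweep.voltage, n_win, polyorder=3, deriv=1, delta=dt_ms)


def _refine_threshold_index(
    dvdt: np.ndarray, onset: int, peak: int, search_start: int, frac: float
) -> int:
    """Index where dV/dt first reaches ``frac`` of the spike's max upstroke."""
    seg = dvdt[search_start : peak + 1]
    max_up = seg.max()
    target = frac * max_up
    above = np.flatnonzero(seg >= target)
    if len(above) == 0:
        return onset
    # walk back from the upstroke max to the start of this excursion
    i_max = int(np.argmax(seg))
    i = i_max
    while i > 0 and seg[i - 1] >= target:
        i -= 1
    return search_start + i


def detect_spikes(
    sweep: Sweep,
    dvdt_threshold: float = 20.0,
    smoothing_window_ms: float = 0.5,
    min_height: float = 2.0,
    max_interval_ms: float = 5.0,
    min_peak: float = -30.0,
    threshold_fraction: float = 0.05,
) -> list[SpikeIndices]:
    """Detect spikes in the stimulus window; returns ordered index triples."""
    if dvdt_threshold <= 0:
        raise ValueError("dvdt_threshold must be positive")
    dvdt = smoothed_dvdt(sweep, smoothing_window_ms)
    v = sweep.voltage
    fs = sweep.sampling_rate
    sl = sweep.stim_slice
    i0, i1 = sl.start, sl.stop

    above = dvdt >= dvdt_threshold
    crossings = [
        i for i in range(max(i0, 1), i1) if above[i] and not above[i - 1]
    ]
    max_int = int(round(max_interval_ms * 1e-3 * fs))

    peaks: list[tuple[int, int]] = []  # (onset, peak)
    for c in crossings:
        stop = min(c + max_int + 1, i1)
        if stop <= c + 1:
            continue
        peak = c + int(np.argmax(v[c:stop]))
        if v[peak] < min_peak:
            continue
        if v[peak] - v[c] < min_height:
            continue
        if peaks and peak == peaks[-1][1]:
            continue
        peaks.append((c, peak))

    spikes: list[SpikeIndices] = []
    prev_peak = i0
    for k, (onset, peak) in enumerate(peaks):
        search_start = max(prev_peak, onset - max_int)
        thr = _refine_threshold_index(dvdt, onset, peak, search_start, threshold_fraction)
        end = peaks[k + 1][1] if k + 1 < len(peaks) else i1
        if end <= peak + 1:
            trough = peak
        else:
            trough = peak + 1 + int(np.argmin(v[peak + 1 : end]))
        spikes.append(SpikeIndices(threshold=thr, peak=peak, trough=trough))
        prev_peak = peak
    return spikes


def _interp_crossing_time(t0, t1, v0, v1, level) -> float:
    if v1 == v0:
        return t0
    return t0 + (t1 - t0) * (level - v0) / (v1 - v0)


def extract_spike_features(
    sweep: Sweep,
    spikes: list[SpikeIndices],
    smoothing_window_ms: float = 0.5,
    fast_ahp_window_ms: float = 5.0,
) -> list[SpikeRecord]:
    """Per-spike waveform features; widths by linear interpolation."""
    n = sweep.n_samples
    last = -1
    for s in spikes:
        if not (0 <= s.threshold <= s.peak <= s.trough < n) or s.threshold < last:
            raise ValueError("spike indices out of order or out of range")
        last = s.threshold
    dvdt = smoothed_dvdt(sweep, smoothing_window_ms)
    v = sweep.voltage
    t = sweep.t
    dt_ms = 1e3 / sweep.sampling_rate
    records = []
    for s in spikes:
        thr_v = v[s.threshold]
        peak_v = v[s.peak]
        height = peak_v - thr_v
        half = thr_v + height / 2.0

        rise = np.flatnonzero(v[s.threshold : s.peak + 1] >= half)
        if len(rise):
            i = s.threshold + rise[0]
            t_rise = _interp_crossing_time(
                t[max(i - 1, 0)], t[i], v[max(i - 1, 0)], v[i], half
            )
        else:
            t_rise = t[s.peak]
        fall = np.flatnonzero(v[s.peak : s.trough + 1] <= half)
        if len(fall):
            j = s.peak + fall[0]
            t_fall = _interp_crossing_time(
                t[max(j - 1, 0)], t[j], v[max(j - 1, 0)], v[j], half
            )
        else:
            t_fall = t[s.trough]
        width_ms = (t_fall - t_rise) * 1e3

        upstroke = float(dvdt[s.threshold : s.peak + 1].max())
        down_seg = dvdt[s.peak : s.trough + 1]
        downstroke = float(down_seg.min()) if len(down_seg) else np.nan

        below = np.flatnonzero(v[s.peak : s.trough + 1] <= thr_v)
        de = s.peak + below[0] if len(below) else s.trough
        ahp_stop = min(de + int(round(fast_ahp_window_ms * 1e-3 / (dt_ms * 1e-3))), n)
        ahp_stop = max(ahp_stop, de + 1)
        fast_ahp = float(v[de:ahp_stop].min() - thr_v)
        trough_rel = float(v[s.trough] - thr_v)

        records.append(
            SpikeRecord(
                threshold_v=float(thr_v),
                threshold_t=float(t[s.threshold]),
                peak_v=float(peak_v),
                height=float(height),
                width_half_height=float(width_ms),
                fast_ahp=fast_ahp,
                trough=trough_rel,
                upstroke=upstroke,
                downstroke=downstroke,
                updown_ratio=float(upstroke / abs(downstroke)),
            )
        )
    return records


def sweep_qc(
    sweep: Sweep,
    r_input: float,
    bridge_abs_max: float = 20.0,
    bridge_rel_max: float = 0.15,
    bias_abs_max: float = 100.0,
    rms_short_max: float = 0.07,
    rms_long_max: float = 0.5,
    baseline_window_s: float = 0.5,
    short_window_ms: float = 1.5,
) -> tuple[bool, list[str]]:
    """Per-sweep QC; returns (passed, reason codes for every failure)."""
    if r_input <= 0:
        raise ValueError("r_input must be positive")
    reasons: list[str] = []
    if sweep.bridge_balance is None or sweep.bias_current is None:
        return False, ["missing_metadata"]
    if sweep.bridge_balance >= bridge_abs_max:
        reasons.append("bridge_abs")
    if sweep.bridge_balance >= bridge_rel_max * r_input:
        reasons.append("bridge_rel")
    if abs(sweep.bias_current) > bias_abs_max:
        reasons.append("bias")

    i_stim = int(round(sweep.stim_start * sweep.sampling_rate))
    n_base = int(round(baseline_window_s * sweep.sampling_rate))
    base = sweep.voltage[max(0, i_stim - n_base) : i_stim]
    if len(base) >= 4:
        x = np.arange(len(base))
        slope, icpt = np.polyfit(x, base, 1)
        resid = base - (slope * x + icpt)
        rms_long = float(np.sqrt(np.mean(resid**2)))
        if rms_long >= rms_long_max:
            reasons.append("rms_long")
        n_short = max(2, int(round(short_window_ms * 1e-3 * sweep.sampling_rate)))
        sq = uniform_filter1d(resid**2, size=n_short, mode="nearest")
        rms_short = float(np.sqrt(sq.max()))
        if rms_short >= rms_short_max:
            reasons.append("rms_short")
    return (len(reasons) == 0), reasons


def _steady_state_and_baseline(sweep: Sweep, ss_fraction: float = 0.1):
    v = sweep.voltage
    sl = sweep.stim_slice
    baseline = float(v[: sl.start].mean()) if sl.start else float(v[0])
    n_ss = max(1, int(round((sl.stop - sl.start) * ss_fraction)))
    v_ss = float(v[sl.stop - n_ss : sl.stop].mean())
    return v_ss, baseline


def _fit_tau_ms(sweep: Sweep, v_ss: float, baseline: float) -> float | None:
    """Single-exponential fit to the 10-90% onset transient, tau in ms."""
    v = sweep.voltage
    fs = sweep.sampling_rate
    sl = sweep.stim_slice
    defl = v_ss - baseline
    if abs(defl) < 1e-9:
        return None
    frac = (v[sl.start : sl.stop] - baseline) / defl
    # light smoothing for robust crossing detection under noise
    frac_s = uniform_filter1d(frac, size=max(1, int(round(0.5e-3 * fs))))
    i10 = np.flatnonzero(frac_s >= 0.1)
    i90 = np.flatnonzero(frac_s >= 0.9)
    if not len(i10) or not len(i90) or i90[0] <= i10[0] + 3:
        return None
    a, b = i10[0], i90[0]
    tt = np.arange(b - a) / fs * 1e3  # ms
    seg = v[sl.start + a : sl.start + b]
    tau0 = (tt[-1] - tt[0]) / np.log(9.0) if len(tt) > 1 else 1.0

    def model(x, v_inf, amp, tau):
        return v_inf + amp * np.exp(-x / tau)

    try:
        popt, _ = curve_fit(
            model,
            tt,
            seg,
            p0=[v_ss, seg[0] - v_ss, tau0],
            maxfev=10000,
        )
    except RuntimeError:
        return None
    tau = float(popt[2])
    return tau if 0 < tau < 1e4 else None


def subthreshold_features(
    sweeps: list[Sweep],
    sag_target_pa: float = -100.0,
    sag_tolerance_pa: float = 20.0,
    smooth_ms: float = 5.0,
) -> dict:
    """rmp, r_input, tau and sag from hyperpolarizing long steps."""
    hyper = [s for s in sweeps if s.stim_amplitude < 0]
    amps = sorted({s.stim_amplitude for s in hyper})
    if len(amps) < 2:
        raise ValueError("need >=2 distinct hyperpolarizing amplitudes")

    baselines, deflections, taus, amplitudes = [], [], [], []
    for s in hyper:
        v_ss, base = _steady_state_and_baseline(s)
        baselines.append(base)
        deflections.append(v_ss - base)
        amplitudes.append(s.stim_amplitude)
        tau = _fit_tau_ms(s, v_ss, base)
        if tau is not None:
            taus.append(tau)

    rmp = float(np.mean(baselines))
    slope, _ = np.polyfit(amplitudes, deflections, 1)  # mV/pA = GOhm
    r_input = float(slope * 1e3)  # MOhm
    tau = float(np.mean(taus)) if taus else None

    sag = None
    near = [s for s in hyper if abs(s.stim_amplitude - sag_target_pa) <= sag_tolerance_pa]
    if near:
        s = min(near, key=lambda sw: abs(sw.stim_amplitude - sag_target_pa))
        v_ss, base = _steady_state_and_baseline(s)
        n_sm = max(1, int(round(smooth_ms * 1e-3 * s.sampling_rate)))
        v_smooth = uniform_filter1d(s.voltage, size=n_sm)
        v_min = float(v_smooth[s.stim_slice].min())
        if v_min < base:
            sag = float((v_min - v_ss) / (v_min - base))
    return {"rmp": rmp, "r_input": r_input, "tau": tau, "sag": sag}


def suprathreshold_features(
    sweeps: list[Sweep],
    rate_step_above_rheobase_pa: float = 50.0,
    **detect_kwargs,
) -> dict:
    """rheobase, f-I slope, latency, initial/mean rates and adaptation."""
    depol = sorted(
        (s for s in sweeps if s.stim_amplitude > 0), key=lambda s: s.stim_amplitude
    )
    spike_trains = {
        s.stim_amplitude: (s, detect_spikes(s, **detect_kwargs)) for s in depol
    }
    spiking = {a: (s, sp) for a, (s, sp) in spike_trains.items() if len(sp) >= 1}
    out = dict.fromkeys(
        ["rheobase", "fi_slope", "latency", "initial_rate", "mean_rate", "adaptation"]
    )
    if not spiking:
        return out

    rheo = min(spiking)
    out["rheobase"] = float(rheo)
    s_rheo, sp_rheo = spiking[rheo]
    thr_times = np.array([s_rheo.t[sp.threshold] for sp in sp_rheo])
    out["latency"] = float(thr_times[0] - s_rheo.stim_start)
    if len(thr_times) >= 2:
        out["initial_rate"] = float(1.0 / (thr_times[1] - thr_times[0]))

    if len(spiking) >= 2:
        amps = np.array(sorted(spiking))
        rates = np.array(
            [
                len(spiking[a][1]) / (spiking[a][0].stim_end - spiking[a][0].stim_start)
                for a in amps
            ]
        )
        out["fi_slope"] = float(np.polyfit(amps, rates, 1)[0])

    target = rheo + rate_step_above_rheobase_pa
    a_near = min(spiking, key=lambda a: abs(a - target))
    s_near, sp_near = spiking[a_near]
    out["mean_rate"] = float(
        len(sp_near) / (s_near.stim_end - s_near.stim_start)
    )
    tts = np.array([s_near.t[sp.threshold] for sp in sp_near])
    isis = np.diff(tts)
    if len(isis) >= 2:
        pair_idx = (isis[1:] - isis[:-1]) / (isis[1:] + isis[:-1])
        out["adaptation"] = float(np.mean(pair_idx))
    return out


def cell_features(
    sweeps: list[Sweep],
    apply_qc: bool = True,
    **detect_kwargs,
) -> EphysFeatureSet:
    """Aggregate the 18-feature set from a cell's sweep collection.

    AP-shape features come from the first spike of the rheobase sweep.  When
    ``apply_qc`` is set, sweeps failing QC (using a provisional input
    resistance from all hyperpolarizing sweeps) are excluded first.
    """
    if not sweeps:
        raise ValueError("empty sweep set")
    fs = EphysFeatureSet()
    use = list(sweeps)
    if apply_qc:
        try:
            provisional = subthreshold_features(sweeps)["r_input"]
        except ValueError:
            provisional = None
        if provisional and provisional > 0:
            use = [s for s in sweeps if sweep_qc(s, provisional)[0]]
        if not use:
            raise ValueError("no QC-passing sweeps")

    try:
        sub = subthreshold_features(use)
    except ValueError as exc:
        sub = {"rmp": None, "r_input": None, "tau": None, "sag": None}
        fs.missing_reasons["subthreshold"] = str(exc)
    for k, v in sub.items():
        setattr(fs, k, v)
    if sub.get("sag") is None and "subthreshold" not in fs.missing_reasons:
        fs.missing_reasons["sag"] = "no sweep near -100 pA"

    supra = suprathreshold_features(use, **detect_kwargs)
    for k, v in supra.items():
        setattr(fs, k, v)
    if supra["rheobase"] is None:
        fs.missing_reasons["suprathreshold"] = "no spiking sweep"
        return fs

    rheo_sweep = next(
        s
        for s in sorted(use, key=lambda s: s.stim_amplitude)
        if s.stim_amplitude == supra["rheobase"]
    )
    spikes = detect_spikes(rheo_sweep, **detect_kwargs)
    rec = extract_spike_features(rheo_sweep, spikes)[0]
    fs.ap_threshold = rec.threshold_v
    fs.ap_height = rec.height
    fs.ap_width = rec.width_half_height
    fs.ap_fast_ahp = rec.fast_ahp
    fs.ap_trough = rec.trough
    fs.ap_upstroke = rec.upstroke
    fs.ap_downstroke = rec.downstroke
    fs.ap_updown_ratio = rec.updown_ratio
    for name in FEATURE_NAMES:
        if getattr(fs, name) is None and name not in fs.missing_reasons:
            fs.missing_reasons.setdefault(name, "not measurable from protocol")
    return fs
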