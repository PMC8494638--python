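"""Independent brute-force oracles and trace builders used by the tests.

These deliberately re-derive everything from first principles (explicit
polynomial least squares for the derivative filter, pure-Python scans for
crossings and refinement) so they share no code path with the package
implementation they check.
"""

import numpy as np

from patchpipe.sweeps import Sweep


def savgol_deriv_coeffs(n_win: int, poly: int, dt_ms: float) -> np.ndarray:
    """First-derivative smoothing filter coefficients from explicit LSQ.

    Fitting a degree-``poly`` polynomial over a centred window and taking its
    derivative at the centre is a linear operation; solve for its weights.
    """
    half = n_win // 2
    x = np.arange(-half, half + 1, dtype=float) * dt_ms
    A = np.vander(x, poly + 1, increasing=True)  # columns 1, x, x^2, ...
    # pinv row 1 gives the coefficient of x -> derivative at window centre
    return np.linalg.pinv(A)[1]


def oracle_detect_spikes(
    sweep: Sweep,
    dvdt_threshold: float = 20.0,
    smoothing_window_ms: float = 0.5,
    min_height: float = 2.0,
    max_interval_ms: float = 5.0,
    min_peak: float = -30.0,
    threshold_fraction: float = 0.05,
):
    """Exhaustive crossing scan + refinement re-check (pure Python)."""
    fs = sweep.sampling_rate
    dt_ms = 1e3 / fs
    n_win = int(round(smoothing_window_ms * 1e-3 * fs))
    if n_win % 2 == 0:
        n_win += 1
    n_win = max(n_win, 5)
    w = savgol_deriv_coeffs(n_win, 3, dt_ms)
    v = sweep.voltage
    half = n_win // 2
    dvdt = np.full(v.size, np.nan)
    for i in range(half, v.size - half):
        dvdt[i] = float(np.dot(w, v[i - half : i + half + 1]))

    sl = sweep.stim_slice
    i0, i1 = sl.start, sl.stop
    max_int = int(round(max_interval_ms * 1e-3 * fs))

    crossings = []
    for i in range(max(i0, 1), i1):
        if dvdt[i] >= dvdt_threshold and not (dvdt[i - 1] >= dvdt_threshold):
            crossings.append(i)

    peaks = []
    for c in crossings:
        stop = min(c + max_int + 1, i1)
        if stop <= c + 1:
            continue
        peak = c
        for j in range(c, stop):
            if v[j] > v[peak]:
                peak = j
        if v[peak] < min_peak:
            continue
        if v[peak] - v[c] < min_height:
            continue
        if peaks and peak == peaks[-1][1]:
            continue
        peaks.append((c, peak))

    spikes = []
    prev_peak = i0
    for k, (onset, peak) in enumerate(peaks):
        start = max(prev_peak, onset - max_int)
        seg = dvdt[start : peak + 1]
        target = threshold_fraction * np.nanmax(seg)
        i_max = start + int(np.nanargmax(seg))
        thr = i_max
        while thr > start and dvdt[thr - 1] >= target:
            thr -= 1
        end = peaks[k + 1][1] if k + 1 < len(peaks) else i1
        if end <= peak + 1:
            trough = peak
        else:
            trough = peak + 1
            for j in range(peak + 1, end):
                if v[j] < v[trough]:
                    trough = j
        spikes.append((thr, peak, trough))
        prev_peak = peak
    return spikes


def make_spike_train_sweep(
    spike_times_s,
    fs: float = 25_000.0,
    duration: float = 1.5,
    stim_start: float = 0.2,
    stim_end: float = 1.2,
    stim_amplitude: float = 100.0,
    baseline: float = -70.0,
    threshold_level: float = -50.0,
    peak: float = 30.0,
    rise_ms: float = 1.0,
    fall_ms: float = 1.5,
) -> Sweep:
    """Flat baseline with stereotyped triangular APs spliced at given times."""
    n = int(round(duration * fs))
    v = np.full(n, baseline)
    cur = np.zeros(n)
    cur[int(round(stim_start * fs)) : int(round(stim_end * fs))] = stim_amplitude
    n_rise = int(round(rise_ms * 1e-3 * fs))
    n_fall = int(round(fall_ms * 1e-3 * fs))
    for t in spike_times_s:
        i = int(round(t * fs))
        up = np.linspace(baseline, peak, n_rise + 1)
        down = np.linspace(peak, threshold_level - 5.0, n_fall + 1)[1:]
        wave = np.concatenate([up, down])
        stop = min(i + wave.size, n)
        v[i:stop] = wave[: stop - i]
        # relax quickly back to baseline after the AHP
        tail = min(stop + n_fall, n)
        v[stop:tail] = np.linspace(v[stop - 1], baseline, tail - stop + 1)[1:]
    return Sweep(
        sampling_rate=fs,
        voltage=v,
        current=cur,
        stim_start=stim_start,
        stim_end=stim_end,
        stim_amplitude=stim_amplitude,
        bridge_balance=5.0,
        bias_current=0.0,
    )


def brute_force_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = p[i] * m / rank_from_end
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def brute_force_mannwhitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for sample a by direct pair counting (ties count half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u
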