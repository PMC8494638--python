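"""Leaky integrate-and-fire current-clamp simulator with known ground truth.

The membrane is a single RC compartment (time constant ``tau``, resistance
``r_input``).  Hyperpolarizing steps additionally engage a slow two-stage
depolarizing pathway whose step response is ``h(t) = 1 - (1 + t/ts) e^{-t/ts}``
(zero initial slope, so the early charging transient stays single-exponential).
Its amplitude is calibrated so that the closed-form voltage trajectory for a
long step satisfies ``(V_min - V_ss) / (V_min - rmp) = sag_fraction`` exactly.

When the voltage crosses ``v_threshold`` a stereotyped action potential is
spliced in: a 1 ms linear rise to +30 mV, then a 1.5 ms fall to 5 mV below
threshold, from which integration resumes.  Depolarizing dynamics are pure
LIF, so the analytic rheobase ``(v_threshold - rmp) / r_input`` is exact.

All trajectories are built segment-by-segment from the closed-form solution
of the RC equation, so noise-free traces match the closed forms to machine
precision at sample times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from ..sweeps import Sweep

__all__ = ["EphysGroundTruth", "default_protocol", "simulate_sweep_set"]

# stereotyped AP shape constants (ms / mV)
AP_PEAK_MV = 30.0
AP_RISE_MS = 1.0
AP_FALL_MS = 1.5
AP_AHP_DROP_MV = 5.0


@dataclass(frozen=True)
class EphysGroundTruth:
    """Ground-truth membrane parameters of one simulated cell.

    Units: mV, MOhm, ms, pA.  ``1 pA * 1 MOhm = 1e-3 mV``.
    """

    rmp: float = -70.0
    r_input: float = 100.0
    tau: float = 20.0
    sag_fraction: float = 0.0
    v_threshold: float = -50.0
    tau_slow: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_input <= 0:
            raise ValueError("r_input must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0 <= self.sag_fraction < 1):
            raise ValueError("sag_fraction must be in [0, 1)")
        if self.v_threshold <= self.rmp:
            raise ValueError("v_threshold must exceed rmp")
        if self.tau_slow <= self.tau:
            raise ValueError("tau_slow must exceed tau")

    @property
    def rheobase_true(self) -> float:
        """Analytic LIF rheobase in pA."""
        return 1000.0 * (self.v_threshold - self.rmp) / self.r_input

    def deflection_mv(self, amplitude_pa: float) -> float:
        """Steady-state voltage deflection for a current step (Ohm's law)."""
        return amplitude_pa * self.r_input * 1e-3


def _slow_step_response(t: np.ndarray | float, tau_slow: float):
    """Step response of the two-stage slow cascade; 0 slope at t=0."""
    x = np.asarray(t, dtype=float) / tau_slow
    return 1.0 - (1.0 + x) * np.exp(-x)


def _hyperpolarizing_shape(t, b: float, tau: float, tau_slow: float):
    """Unit-step deflection shape: steady state 1, transient max 1/(1-sag)."""
    t = np.asarray(t, dtype=float)
    fast = (1.0 + b) * (1.0 - np.exp(-t / tau))
    return fast - b * _slow_step_response(t, tau_slow)


def _shape_max(b: float, tau: float, tau_slow: float) -> float:
    res = minimize_scalar(
        lambda t: -_hyperpolarizing_shape(t, b, tau, tau_slow),
        bounds=(1e-6 * tau, 30.0 * tau_slow),
        method="bounded",
        options={"xatol": 1e-10 * tau_slow},
    )
    return -res.fun


def sag_pathway_amplitude(sag_fraction: float, tau: float, tau_slow: float) -> float:
    """Slow-pathway amplitude ``b`` such that the closed-form trajectory of an
    infinitely long step has fractional rebound exactly ``sag_fraction``."""
    if sag_fraction <= 0:
        return 0.0
    target = 1.0 / (1.0 - sag_fraction)  # required transient max / steady state
    hi = 1.0
    while _shape_max(hi, tau, tau_slow) < target:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("sag_fraction too large for this tau/tau_slow pair")
    return brentq(
        lambda b: _shape_max(b, tau, tau_slow) - target, 0.0, hi, xtol=1e-12
    )


def default_protocol(
    truth: EphysGroundTruth,
    grid_pa: float = 10.0,
    n_above: int = 6,
    duration_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Standard square-pulse protocol: three hyperpolarizing steps (one at
    -100 pA for sag) plus a depolarizing series straddling rheobase."""
    rheo = truth.rheobase_true
    lo = grid_pa * np.floor((rheo - 3 * grid_pa) / grid_pa)
    depol = [lo + k * grid_pa for k in range(int(3 + n_above))]
    steps = [-100.0, -70.0, -30.0] + [a for a in depol if a > 0]
    return [(float(a), duration_s) for a in steps]


def _fill_decay(v0: float, v_inf: float, n: int, dt: float, tau: float) -> np.ndarray:
    """Closed-form RC relaxation sampled at n points starting at t=0."""
    t = np.arange(n) * dt
    return v_inf + (v0 - v_inf) * np.exp(-t / tau)


def _simulate_one(
    truth: EphysGroundTruth,
    amplitude: float,
    duration: float,
    fs: float,
    pre_s: float,
    post_s: float,
    b: float,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Noise-free voltage and current traces for one square step."""
    dt = 1.0 / fs
    n_pre = int(round(pre_s * fs))
    n_stim = int(round(duration * fs))
    n_post = int(round(post_s * fs))
    n = n_pre + n_stim + n_post
    rmp, tau, taus = truth.rmp, truth.tau, truth.tau_slow
    tau_ms = tau  # parameters are in ms; work in ms internally
    dt_ms = dt * 1e3

    v = np.full(n, rmp, dtype=float)
    i_tr = np.zeros(n, dtype=float)
    i_tr[n_pre : n_pre + n_stim] = amplitude

    defl = truth.deflection_mv(amplitude)  # steady-state deflection, mV
    t_stim_ms = np.arange(n_stim) * dt_ms

    if amplitude < 0 and b > 0:
        # hyperpolarizing with sag: closed-form two-pathway trajectory
        v[n_pre : n_pre + n_stim] = rmp + defl * _hyperpolarizing_shape(
            t_stim_ms, b, tau_ms, taus
        )
        # state at stimulus end, then free relaxation of all three states
        T = n_stim * dt_ms
        u_fast = (1.0 + b) * defl * (1.0 - np.exp(-T / tau_ms))
        x_T = -b * defl * (1.0 - np.exp(-T / taus))
        y_T = -b * defl * _slow_step_response(T, taus)
        t_post = np.arange(n_post) * dt_ms
        v[n_pre + n_stim :] = (
            rmp
            + u_fast * np.exp(-t_post / tau_ms)
            + (y_T + x_T * t_post / taus) * np.exp(-t_post / taus)
        )
        return v, i_tr, defl, rmp + defl

    v_inf = rmp + defl
    if v_inf <= truth.v_threshold:
        # subthreshold (or exactly at threshold): single-exponential charge
        v[n_pre : n_pre + n_stim] = v_inf + (rmp - v_inf) * np.exp(-t_stim_ms / tau_ms)
        v_end = v[n_pre + n_stim - 1] if n_stim else rmp
        v_end = v_inf + (rmp - v_inf) * np.exp(-n_stim * dt_ms / tau_ms)
        v[n_pre + n_stim :] = _fill_decay(
            v_end, rmp, n_post, dt_ms, tau_ms
        )
        return v, i_tr, defl, v_inf

    # suprathreshold: iterate charge-to-threshold / AP-splice segments
    n_rise = max(1, int(round(AP_RISE_MS * 1e-3 * fs)))
    n_fall = max(1, int(round(AP_FALL_MS * 1e-3 * fs)))
    v_ahp = truth.v_threshold - AP_AHP_DROP_MV
    i_end = n_pre + n_stim
    cursor = n_pre
    v0 = rmp
    while cursor < i_end:
        # analytic time (ms) to threshold crossing from the cursor
        t_cross_ms = tau_ms * np.log((v_inf - v0) / (v_inf - truth.v_threshold))
        k_cross = cursor + max(1, int(np.ceil(t_cross_ms / dt_ms)))
        k_fill = min(k_cross, i_end)
        seg = np.arange(k_fill - cursor) * dt_ms
        v[cursor:k_fill] = v_inf + (v0 - v_inf) * np.exp(-seg / tau_ms)
        if k_cross >= i_end:
            v0 = v_inf + (v0 - v_inf) * np.exp(-(i_end - cursor) * dt_ms / tau_ms)
            cursor = i_end
            break
        # splice stereotyped AP starting at the crossing sample
        rise = truth.v_threshold + (AP_PEAK_MV - truth.v_threshold) * (
            np.arange(n_rise + 1) / n_rise
        )
        fall = AP_PEAK_MV + (v_ahp - AP_PEAK_MV) * (np.arange(1, n_fall + 1) / n_fall)
        wave = np.concatenate([rise, fall])
        stop = min(k_cross + wave.size, n)
        v[k_cross:stop] = wave[: stop - k_cross]
        cursor = k_cross + wave.size
        v0 = v_ahp
    if cursor < n:
        v[cursor:] = _fill_decay(v0, rmp, n - cursor, dt_ms, tau_ms)
    return v, i_tr, defl, v_inf


def simulate_sweep_set(
    truth: EphysGroundTruth,
    protocol: list[tuple[float, float]],
    sampling_rate: float = 50_000.0,
    noise_sd: float = 0.0,
    pre_s: float = 0.6,
    post_s: float = 0.3,
    bridge_mohm: float = 10.0,
    bias_pa: float = 0.0,
) -> list[Sweep]:
    """Simulate one :class:`Sweep` per protocol step.

    ``protocol`` is a list of ``(amplitude_pa, duration_s)`` square pulses.
    Gaussian noise of ``noise_sd`` mV is added to the voltage only; the
    current trace records the commanded stimulus exactly.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if not protocol:
        raise ValueError("protocol must contain at least one step")
    rng = np.random.default_rng(truth.seed)
    b = sag_pathway_amplitude(truth.sag_fraction, truth.tau, truth.tau_slow)
    sweeps = []
    for amplitude, duration in protocol:
        v, i_tr, _, _ = _simulate_one(
            truth, amplitude, duration, sampling_rate, pre_s, post_s, b
        )
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=v.size)
        sweeps.append(
            Sweep(
                sampling_rate=sampling_rate,
                voltage=v,
                current=i_tr,
                stim_start=pre_s,
                stim_end=pre_s + duration,
                stim_amplitude=amplitude,
                bridge_balance=bridge_mohm,
                bias_current=bias_pa,
                meta={"junction_potential_offset_mv": -14.0},
            )
        )
    return sweeps
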