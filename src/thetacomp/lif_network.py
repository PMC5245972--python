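"""Leaky integrate-and-fire CA1 circuit with conductance synapses and a theta pacemaker.

Pyramidal (place) cells and interneurons follow

    dVm/dt = -(Vm - E0)/tau_m - g(t) (Vm - E_rev)/Cm + I_ext/Cm + noise

with exponentially decaying synaptic conductances.  Interneurons receive a
tonic depolarizing current plus an 8 Hz pacemaker drive
``I0I - Itheta cos(omega_theta t)`` (the septal theta input); pyramidal cells
receive a Gaussian place-field current along a linear trajectory
``x(t) = x0 + v t``.  Each pyramidal cell connects to exactly one interneuron
and each interneuron reciprocally inhibits exactly the cells it receives
from; there are no same-type connections.

Integration is forward Euler at ``dt = 0.1 ms`` with the threshold test after
the update and no refractory period.  The membrane noise term adds
``sigma_n * eta * sqrt(dt / tau_m)`` per step with ``eta ~ N(0, 1)`` drawn
each step -- a Langevin term whose stationary membrane fluctuation is
``sigma_n / sqrt(2)``, the scale at which the published noise amplitudes
measurably broaden place fields.  A step-bound variant
(``sigma_n * eta * dt / tau_m``) is available as a flag for sensitivity
checks.  Conductances decay by exactly ``exp(-dt/tau)`` between
spikes and spikes increment them by the synaptic weight on the next step.
Identical configuration and seed give bit-identical results.

All internal quantities are SI; the speed laws, parameter-set helpers and
:meth:`DriveSet.from_speed` accept the conventional units (pA, mV, ms, cm, nS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "LIFParams",
    "NetworkConfig",
    "DriveSet",
    "SpeedLaw",
    "PerturbationProtocol",
    "SimResult",
    "SimulationError",
    "interneuron_params",
    "pyramidal_params",
    "build_connectivity",
    "make_pacemaker_current",
    "make_place_current",
    "speed_params",
    "dorsoventral_params",
    "lif_isi_closed_form",
    "simulate",
    "DEFAULT_DT",
    "DEFAULT_SPEED_LAW",
]

DEFAULT_DT = 1e-4  # s

# unit helpers (paper-convention units -> SI)
PA = 1e-12
MV = 1e-3
MS = 1e-3
CM = 1e-2
NS = 1e-9


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LIFParams:
    """Single-population LIF parameters (SI units)."""

    tau_m: float  # s
    c_m: float  # F
    e_rest: float  # V
    v_thresh: float  # V
    v_reset: float  # V
    noise_sigma: float = 0.0  # V (per-step noise amplitude, see module docstring)
    e_exc: float = 0.0  # V
    e_inh: float = -70e-3  # V
    tau_syn_exc: float = 2e-3  # s
    tau_syn_inh: float = 10e-3  # s

    def __post_init__(self) -> None:
        if self.v_reset >= self.v_thresh:
            raise ValueError("reset potential must lie below threshold")
        if min(self.tau_m, self.c_m, self.tau_syn_exc, self.tau_syn_inh) <= 0:
            raise ValueError("time constants and capacitance must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise amplitude must be >= 0")


def interneuron_params(noise_sigma_mV: float = 0.0) -> LIFParams:
    """Fixed interneuron parameters: tau_m 40 ms, Cm 200 pF, rest -65 mV,
    threshold -50 mV, reset -70 mV.  Interneuron noise defaults to zero."""
    return LIFParams(
        tau_m=40 * MS,
        c_m=200e-12,
        e_rest=-65 * MV,
        v_thresh=-50 * MV,
        v_reset=-70 * MV,
        noise_sigma=noise_sigma_mV * MV,
    )


def pyramidal_params(noise_sigma_mV: float = 0.0) -> LIFParams:
    """Fixed pyramidal-cell parameters: tau_m 20 ms, Cm 155 pF, rest -65 mV,
    threshold -50 mV, reset -70 mV."""
    return LIFParams(
        tau_m=20 * MS,
        c_m=155e-12,
        e_rest=-65 * MV,
        v_thresh=-50 * MV,
        v_reset=-70 * MV,
        noise_sigma=noise_sigma_mV * MV,
    )


@dataclass(frozen=True)
class NetworkConfig:
    """Population sizes, pyramidal-to-interneuron partnership, synaptic weights.

    ``partner[i]`` is the unique interneuron that pyramidal cell ``i``
    excites (weight ``w_exc``, S) and is reciprocally inhibited by (weight
    ``w_inh``, S): the inhibitory incidence is the transpose of the
    excitatory one.
    """

    n_pyramidal: int
    n_interneuron: int
    partner: np.ndarray
    w_exc: np.ndarray  # per-pyramidal-cell excitatory weight (S)
    w_inh: np.ndarray  # per-pyramidal-cell inhibitory weight (S)

    def __post_init__(self) -> None:
        p = np.asarray(self.partner)
        if p.shape != (self.n_pyramidal,):
            raise ValueError("partner must have one entry per pyramidal cell")
        if self.n_pyramidal % self.n_interneuron:
            raise ValueError("the number of interneurons must divide the number of pyramidal cells")
        counts = np.bincount(p, minlength=self.n_interneuron)
        if not np.all(counts == self.n_pyramidal // self.n_interneuron):
            raise ValueError("each interneuron must receive the same number of pyramidal cells")

    @property
    def incidence(self) -> np.ndarray:
        """Binary Np x NI excitatory incidence matrix (rows sum to 1)."""
        c = np.zeros((self.n_pyramidal, self.n_interneuron), dtype=int)
        c[np.arange(self.n_pyramidal), self.partner] = 1
        return c


def build_connectivity(
    n_pyramidal: int,
    n_interneuron: int,
    seed: int | None = None,
    w_exc: float = 0.5 * NS,
    w_inh: float = 25 * NS,
) -> NetworkConfig:
    """Block partnership: cell ``i`` couples to interneuron ``i // (Np/NI)``.

    With a seed, the cell-to-interneuron assignment is randomly permuted
    while keeping the per-interneuron load exactly ``Np / NI``.
    """
    if n_pyramidal % n_interneuron:
        raise ValueError("n_interneuron must divide n_pyramidal")
    per = n_pyramidal // n_interneuron
    partner = np.repeat(np.arange(n_interneuron), per)
    if seed is not None:
        partner = np.random.default_rng(seed).permutation(partner)
    return NetworkConfig(
        n_pyramidal=n_pyramidal,
        n_interneuron=n_interneuron,
        partner=partner,
        w_exc=np.full(n_pyramidal, w_exc),
        w_inh=np.full(n_pyramidal, w_inh),
    )


@dataclass(frozen=True)
class SpeedLaw:
    """Linear running-speed dependence of the drive parameters.

    Evaluated with ``v`` in cm/s; currents in pA, noise in mV (the
    conventional units), converted to SI by :class:`DriveSet` constructors.
    """

    i0_intercept_pA: float = 79.5
    i0_slope: float = 0.027
    itheta_intercept_pA: float = 0.0
    itheta_slope: float = 0.065
    ie_intercept_pA: float = 110.0
    ie_slope: float = 0.5
    noise_intercept_mV: float = 1.75
    noise_slope: float = -0.025

    def max_speed(self) -> float:
        """Largest speed (cm/s) keeping the place-cell noise non-negative."""
        if self.noise_slope >= 0:
            return math.inf
        return self.noise_intercept_mV / -self.noise_slope


DEFAULT_SPEED_LAW = SpeedLaw()


def speed_params(v_cm_s: float, law: SpeedLaw = DEFAULT_SPEED_LAW) -> tuple[float, float, float, float]:
    """Evaluate the four speed laws: (I0I pA, Itheta pA, IE pA, sigma_nE mV)."""
    if not 0 <= v_cm_s <= law.max_speed():
        raise ValueError(
            f"speed {v_cm_s} cm/s outside the supported range [0, {law.max_speed():g}]"
        )
    return (
        law.i0_intercept_pA + law.i0_slope * v_cm_s,
        law.itheta_intercept_pA + law.itheta_slope * v_cm_s,
        law.ie_intercept_pA + law.ie_slope * v_cm_s,
        law.noise_intercept_mV + law.noise_slope * v_cm_s,
    )


def dorsoventral_params(pole: str) -> dict:
    """Printed parameter sets for the dorsal and ventral poles (both at v = 30 cm/s)."""
    sets = {
        "dorsal": dict(sigma_cm=45.0, noise_mV=0.7, i0_pA=80.455, itheta_pA=1.95, w_exc_nS=0.53, v_cm_s=30.0),
        "ventral": dict(sigma_cm=600.0, noise_mV=3.0, i0_pA=79.525, itheta_pA=0.12, w_exc_nS=0.081, v_cm_s=30.0),
    }
    try:
        return dict(sets[pole])
    except KeyError:
        raise ValueError(f"unknown pole {pole!r}; expected 'dorsal' or 'ventral'") from None


@dataclass(frozen=True)
class DriveSet:
    """External drives: pacemaker input to interneurons, place-field input to
    pyramidal cells, and the trajectory (SI units)."""

    i0_int: np.ndarray  # tonic interneuron current per interneuron (A)
    itheta_int: np.ndarray  # pacemaker amplitude per interneuron (A)
    f_theta: float  # pacemaker frequency (Hz)
    ie_amp: np.ndarray  # place-field current amplitude per pyramidal cell (A)
    centers: np.ndarray  # field center per pyramidal cell (m)
    sigma_field: np.ndarray  # Gaussian field width per pyramidal cell (m)
    x0: float = 0.0  # trajectory start (m)
    speed: float = 0.0  # running speed (m/s)
    lateral_offset: np.ndarray | float = 0.0  # perpendicular offset of the pass (m)

    def __post_init__(self) -> None:
        if self.f_theta <= 0:
            raise ValueError("pacemaker frequency must be > 0")
        if np.any(np.asarray(self.sigma_field) <= 0):
            raise ValueError("field width must be > 0")

    @property
    def omega_theta(self) -> float:
        return 2.0 * math.pi * self.f_theta

    @classmethod
    def from_speed(
        cls,
        v_cm_s: float,
        centers_m: Sequence[float],
        *,
        law: SpeedLaw = DEFAULT_SPEED_LAW,
        n_interneuron: int = 1,
        sigma_cm: float = 40.0,
        f_theta: float = 8.0,
        x0_m: float = 0.0,
        lateral_offset_m: float = 0.0,
        place_drive: bool = True,
        ie_scale: float = 1.0,
    ) -> "DriveSet":
        """Build drives from the running-speed laws at ``v`` (cm/s).

        ``ie_scale`` multiplies the speed-law place-field amplitude (used by
        the drive-envelope sweep); ``place_drive=False`` zeroes it.
        """
        i0, ith, ie, _sig_n = speed_params(v_cm_s, law)
        centers = np.asarray(centers_m, dtype=float)
        amp = ie * PA * ie_scale if place_drive else 0.0
        return cls(
            i0_int=np.full(n_interneuron, i0 * PA),
            itheta_int=np.full(n_interneuron, ith * PA),
            f_theta=f_theta,
            ie_amp=np.full(centers.size, amp),
            centers=centers,
            sigma_field=np.full(centers.size, sigma_cm * CM),
            x0=x0_m,
            speed=v_cm_s * CM,
            lateral_offset=lateral_offset_m,
        )


def make_pacemaker_current(i0: float, itheta: float, f_theta: float):
    """Interneuron drive ``I0I - Itheta cos(2 pi f t)``; minimal at t = 0."""
    w = 2.0 * math.pi * f_theta

    def current(t):
        return i0 - itheta * np.cos(w * np.asarray(t, dtype=float))

    return current


def make_place_current(ie: float, xc: float, sigma: float, x0: float, v: float, lateral_offset: float = 0.0):
    """Gaussian place-field drive along the pass ``x(t) = x0 + v t``.

    The peak equals ``ie`` at closest approach for an on-center pass and
    ``ie * exp(-offset^2 / (2 sigma^2))`` for a laterally offset pass.
    """

    def current(t):
        x = x0 + v * np.asarray(t, dtype=float)
        d2 = (x - xc) ** 2 + lateral_offset**2
        return ie * np.exp(-d2 / (2.0 * sigma**2))

    return current


@dataclass(frozen=True)
class PerturbationProtocol:
    """Current injection window, optionally with a pacemaker phase reset.

    ``amp_pyr`` / ``amp_int`` are added (negative for silencing) to every
    pyramidal cell / interneuron during ``[onset, onset + duration)``.  With
    ``pacemaker_reset`` the theta phase returns to its t = 0 value at onset.
    """

    amp_pyr: float = 0.0  # A
    amp_int: float = 0.0  # A
    onset: float = 0.0  # s
    duration: float = 0.0  # s
    pacemaker_reset: bool = False

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    @staticmethod
    def transient_reset(onset: float) -> "PerturbationProtocol":
        """Transient intrahippocampal perturbation: -50 pA to the pyramidal
        cell and -20 pA to the interneuron for 200 ms, with a theta reset."""
        return PerturbationProtocol(
            amp_pyr=-50 * PA, amp_int=-20 * PA, onset=onset, duration=0.2, pacemaker_reset=True
        )

    @staticmethod
    def interneuron_silencing(onset: float) -> "PerturbationProtocol":
        """Optogenetic-style interneuron silencing: -10 pA for 1 s, no reset."""
        return PerturbationProtocol(amp_pyr=0.0, amp_int=-10 * PA, onset=onset, duration=1.0)


@dataclass
class SimResult:
    """Spike trains, recorded membrane traces and pacemaker phase of one run."""

    dt: float
    seed: int
    duration: float
    x0: float
    speed: float
    spikes_pyr: list  # list of np.ndarray spike times (s), one per pyramidal cell
    spikes_int: list  # list of np.ndarray spike times (s), one per interneuron
    trace_times: np.ndarray
    v_pyr: dict  # cell index -> membrane trace (V)
    v_int: dict
    theta_phase: np.ndarray  # pacemaker phase (rad, unwrapped within reset segments)
    reset_times: list  # pacemaker reset events (s)

    def position(self, t) -> np.ndarray:
        return self.x0 + self.speed * np.asarray(t, dtype=float)

    def to_spikes_frame(self) -> pd.DataFrame:
        rows = []
        for i, times in enumerate(self.spikes_pyr):
            rows.append(pd.DataFrame({"cell_id": i, "cell_type": "pyramidal", "spike_time_s": times}))
        for j, times in enumerate(self.spikes_int):
            rows.append(pd.DataFrame({"cell_id": j, "cell_type": "interneuron", "spike_time_s": times}))
        if not rows:
            return pd.DataFrame(columns=["cell_id", "cell_type", "spike_time_s"])
        return pd.concat(rows, ignore_index=True)

    def write_spikes_csv(self, path) -> None:
        self.to_spikes_frame().to_csv(path, index=False)

    def write_traces_csv(self, path) -> None:
        data = {"time_s": self.trace_times}
        for i, v in self.v_pyr.items():
            data[f"v_pyr_{i}"] = v
        for j, v in self.v_int.items():
            data[f"v_int_{j}"] = v
        pd.DataFrame(data).to_csv(path, index=False)


@njit(cache=True)
def _integrate_network(
    dt,
    n_steps,
    seed,
    # pyramidal population
    taum_e,
    cm_e,
    e0_e,
    vth_e,
    vr_e,
    noise_fac_e,  # per cell, volts per unit normal per step
    ie_amp,
    xc,
    sig_f,
    lat_off,
    x0,
    speed,
    e_inh_rev,
    tau_inh,
    # interneuron population
    taum_i,
    cm_i,
    e0_i,
    vth_i,
    vr_i,
    noise_fac_i,
    i0_int,
    itheta_int,
    omega_th,
    e_exc_rev,
    tau_exc,
    # coupling
    partner,
    w_exc,
    w_inh,
    tgt_indptr,
    tgt_idx,
    # perturbation
    p_on,
    p_off,
    p_amp_e,
    p_amp_i,
    p_reset,
    # recording
    rec_e,
    rec_i,
    max_spikes,
):
    n_e = ie_amp.shape[0]
    n_i = i0_int.shape[0]
    v_e = np.full(n_e, e0_e)
    v_i = np.full(n_i, e0_i)
    g_inh = np.zeros(n_e)
    g_exc = np.zeros(n_i)
    dec_inh = math.exp(-dt / tau_inh)
    dec_exc = math.exp(-dt / tau_exc)
    spike_cell = np.empty(max_spikes, dtype=np.int64)
    spike_step = np.empty(max_spikes, dtype=np.int64)
    n_spk = 0
    theta_t0 = 0.0
    v_rec_e = np.empty((n_steps, rec_e.shape[0]))
    v_rec_i = np.empty((n_steps, rec_i.shape[0]))
    theta_rec = np.empty(n_steps)
    np.random.seed(seed)
    overflow = False
    for k in range(n_steps):
        t = k * dt
        in_pert = (k >= p_on) and (k < p_off)
        if p_reset and k == p_on:
            theta_t0 = t
        theta = omega_th * (t - theta_t0)
        theta_rec[k] = theta
        for r in range(rec_e.shape[0]):
            v_rec_e[k, r] = v_e[rec_e[r]]
        for r in range(rec_i.shape[0]):
            v_rec_i[k, r] = v_i[rec_i[r]]
        x = x0 + speed * t
        # membrane updates (forward Euler on the state at time t)
        for i in range(n_e):
            dxi = x - xc[i]
            d2 = dxi * dxi + lat_off[i] * lat_off[i]
            iext = ie_amp[i] * math.exp(-d2 / (2.0 * sig_f[i] * sig_f[i]))
            if in_pert:
                iext += p_amp_e[i]
            dv = (
                -(v_e[i] - e0_e) / taum_e
                - g_inh[i] * (v_e[i] - e_inh_rev) / cm_e
                + iext / cm_e
            ) * dt
            if noise_fac_e[i] > 0.0:
                dv += noise_fac_e[i] * np.random.normal()
            v_e[i] += dv
        cos_theta = math.cos(theta)
        for j in range(n_i):
            iext = i0_int[j] - itheta_int[j] * cos_theta
            if in_pert:
                iext += p_amp_i[j]
            dv = (
                -(v_i[j] - e0_i) / taum_i
                - g_exc[j] * (v_i[j] - e_exc_rev) / cm_i
                + iext / cm_i
            ) * dt
            if noise_fac_i[j] > 0.0:
                dv += noise_fac_i[j] * np.random.normal()
            v_i[j] += dv
        # exact exponential conductance decay, then this step's spikes
        for i in range(n_e):
            g_inh[i] *= dec_inh
        for j in range(n_i):
            g_exc[j] *= dec_exc
        for i in range(n_e):
            if v_e[i] >= vth_e:
                v_e[i] = vr_e
                if n_spk >= max_spikes:
                    overflow = True
                    break
                spike_cell[n_spk] = i
                spike_step[n_spk] = k + 1
                n_spk += 1
                g_exc[partner[i]] += w_exc[i]
        if overflow:
            break
        for j in range(n_i):
            if v_i[j] >= vth_i:
                v_i[j] = vr_i
                if n_spk >= max_spikes:
                    overflow = True
                    break
                spike_cell[n_spk] = n_e + j
                spike_step[n_spk] = k + 1
                n_spk += 1
                for q in range(tgt_indptr[j], tgt_indptr[j + 1]):
                    i = tgt_idx[q]
                    g_inh[i] += w_inh[i]
        if overflow:
            break
    if overflow:
        n_spk = -1
    return spike_cell, spike_step, n_spk, v_rec_e, v_rec_i, theta_rec, theta_t0


def simulate(
    net: NetworkConfig,
    drives: DriveSet,
    T: float,
    *,
    lif_pyr: LIFParams | None = None,
    lif_int: LIFParams | None = None,
    perturb: PerturbationProtocol | None = None,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    record_pyr: Sequence[int] = (),
    record_int: Sequence[int] = (),
    noise_dt_bound: bool = False,
    max_rate_hz: float = 500.0,
) -> SimResult:
    """Run one seeded network simulation of duration ``T`` seconds.

    ``record_pyr`` / ``record_int`` select cells whose membrane traces are
    kept (sampled every step).  ``noise_dt_bound`` switches the per-step
    noise increment from the Langevin ``sigma sqrt(dt / tau_m)`` (default)
    to the step-bound ``sigma dt / tau_m``.
    """
    lif_pyr = lif_pyr or pyramidal_params()
    lif_int = lif_int or interneuron_params()
    n_e, n_i = net.n_pyramidal, net.n_interneuron
    n_steps = int(round(T / dt))
    if n_steps < 1:
        raise ValueError("simulation must span at least one step")

    if perturb is not None and perturb.duration > 0:
        if perturb.onset < 0 or perturb.onset + perturb.duration > T:
            raise ValueError("perturbation window must lie within [0, T]")
        p_on = int(round(perturb.onset / dt))
        p_off = int(round((perturb.onset + perturb.duration) / dt))
        p_amp_e = np.full(n_e, perturb.amp_pyr)
        p_amp_i = np.full(n_i, perturb.amp_int)
        p_reset = perturb.pacemaker_reset
    else:
        p_on, p_off = 0, 0
        p_amp_e = np.zeros(n_e)
        p_amp_i = np.zeros(n_i)
        p_reset = False

    if noise_dt_bound:
        noise_fac_e = np.full(n_e, lif_pyr.noise_sigma * dt / lif_pyr.tau_m)
        noise_fac_i = np.full(n_i, lif_int.noise_sigma * dt / lif_int.tau_m)
    else:
        noise_fac_e = np.full(n_e, lif_pyr.noise_sigma * math.sqrt(dt / lif_pyr.tau_m))
        noise_fac_i = np.full(n_i, lif_int.noise_sigma * math.sqrt(dt / lif_int.tau_m))

    order = np.argsort(net.partner, kind="stable")
    tgt_idx = order.astype(np.int64)
    tgt_indptr = np.zeros(n_i + 1, dtype=np.int64)
    np.cumsum(np.bincount(net.partner, minlength=n_i), out=tgt_indptr[1:])

    max_spikes = int((n_e + n_i) * T * max_rate_hz) + 1024

    lat = np.asarray(drives.lateral_offset, dtype=float)
    lat_off = np.full(n_e, float(lat)) if lat.ndim == 0 else lat.astype(float)

    (spike_cell, spike_step, n_spk, v_rec_e, v_rec_i, theta_rec, _t0) = _integrate_network(
        float(dt),
        n_steps,
        int(seed),
        lif_pyr.tau_m,
        lif_pyr.c_m,
        lif_pyr.e_rest,
        lif_pyr.v_thresh,
        lif_pyr.v_reset,
        noise_fac_e,
        np.asarray(drives.ie_amp, dtype=float),
        np.asarray(drives.centers, dtype=float),
        np.asarray(drives.sigma_field, dtype=float),
        lat_off,
        float(drives.x0),
        float(drives.speed),
        lif_pyr.e_inh,
        lif_pyr.tau_syn_inh,
        lif_int.tau_m,
        lif_int.c_m,
        lif_int.e_rest,
        lif_int.v_thresh,
        lif_int.v_reset,
        noise_fac_i,
        np.asarray(drives.i0_int, dtype=float),
        np.asarray(drives.itheta_int, dtype=float),
        drives.omega_theta,
        lif_int.e_exc,
        lif_int.tau_syn_exc,
        net.partner.astype(np.int64),
        np.asarray(net.w_exc, dtype=float),
        np.asarray(net.w_inh, dtype=float),
        tgt_indptr,
        tgt_idx,
        p_on,
        p_off,
        p_amp_e,
        p_amp_i,
        p_reset,
        np.asarray(record_pyr, dtype=np.int64),
        np.asarray(record_int, dtype=np.int64),
        max_spikes,
    )
    if n_spk < 0:
        raise SimulationError("spike buffer overflow: firing rates exceed max_rate_hz")
    if (v_rec_e.size and not np.all(np.isfinite(v_rec_e))) or (
        v_rec_i.size and not np.all(np.isfinite(v_rec_i))
    ):
        raise SimulationError("non-finite membrane trace: simulation unstable")

    cells = spike_cell[:n_spk]
    times = spike_step[:n_spk] * dt
    spikes_pyr = [times[cells == i] for i in range(n_e)]
    spikes_int = [times[cells == n_e + j] for j in range(n_i)]
    reset_times = [perturb.onset] if (perturb is not None and p_reset) else []

    return SimResult(
        dt=dt,
        seed=seed,
        duration=n_steps * dt,
        x0=drives.x0,
        speed=drives.speed,
        spikes_pyr=spikes_pyr,
        spikes_int=spikes_int,
        trace_times=np.arange(n_steps) * dt,
        v_pyr={int(i): v_rec_e[:, r] for r, i in enumerate(record_pyr)},
        v_int={int(j): v_rec_i[:, r] for r, j in enumerate(record_int)},
        theta_phase=theta_rec,
        reset_times=reset_times,
    )


def lif_isi_closed_form(lif: LIFParams, i_const: float) -> float:
    """Noise-free inter-spike interval of a LIF cell under constant current.

    ``ISI = tau_m * ln((Vinf - Vr) / (Vinf - Vth))`` with
    ``Vinf = E0 + I tau_m / Cm``; infinite below rheobase.
    """
    v_inf = lif.e_rest + i_const * lif.tau_m / lif.c_m
    if v_inf <= lif.v_thresh:
        return math.inf
    return lif.tau_m * math.log((v_inf - lif.v_reset) / (v_inf - lif.v_thresh))
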