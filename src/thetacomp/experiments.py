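"""Config-driven simulation experiments: pair and network protocols, wired
from the simulator through the analysis metrics to summary tables.

Every experiment is a pure function of its keyword arguments plus a base
seed: per-lap seeds are derived as ``seed + lap_index`` (fresh noise per
lap), so identical configuration and seed reproduce every table bit for bit.
Lap geometry places the field center ``margin`` meters into the run and
extends the trajectory ``margin`` meters beyond the ±3σ drive window, giving
the interneuron locked plateaus before and after the crossing from which the
winding number (cycles precessed) is measured.

Published-scale defaults (lap counts, trial counts, population sizes) are plain
keyword arguments, so scaled-down runs are a configuration choice, never a
code change.
"""

from __future__ import annotations

import hashlib
import inspect
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import capacity as cap
from . import lif_network as ln
from . import metrics as mx

__all__ = [
    "ExperimentResult",
    "pair_lap",
    "lap_winding",
    "network_lap",
    "network_lap_metrics",
    "run_minimal_pair",
    "run_speed_sweep",
    "run_dorsoventral",
    "run_envelope_sweep",
    "run_two_cells",
    "run_network_density",
    "run_noise_sweep",
    "run_perturbations",
    "run_pooled_distribution",
    "run_capacity_table",
]

F_THETA = 8.0
TWO_PI = 2.0 * math.pi


@dataclass
class ExperimentResult:
    """Tables plus summary statistics and provenance for one experiment run."""

    name: str
    config: dict
    tables: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, outdir: str | Path) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.resolved.yaml", "w") as fh:
            yaml.safe_dump(
                {"experiment": self.name, "config": _yaml_safe(self.config)}, fh, sort_keys=True
            )
        for tname, table in self.tables.items():
            table.to_csv(out / f"metrics_{tname}.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {
                    "experiment": self.name,
                    "config_hash": self.config_hash,
                    "package_version": __version__,
                    **_json_safe(self.summary),
                },
                fh,
                indent=2,
            )
        return out


def _yaml_safe(obj):
    return json.loads(json.dumps(obj, default=str))


def _json_safe(obj):
    def conv(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    return json.loads(json.dumps(obj, default=conv))


def _resolved(func: Callable, local_vars: dict) -> dict:
    """Snapshot the experiment's effective keyword configuration."""
    names = [p for p in inspect.signature(func).parameters]
    return {n: local_vars[n] for n in names if n in local_vars}


# ---------------------------------------------------------------------------
# lap primitives


def pair_lap(
    *,
    v_cm_s: float = 40.0,
    sigma_cm: float = 40.0,
    margin_m: float = 2.5,
    seed: int = 0,
    ie_scale: float = 1.0,
    lateral_offset_m: float = 0.0,
    place_drive: bool = True,
    perturb: ln.PerturbationProtocol | None = None,
    record: bool = False,
    law: ln.SpeedLaw = ln.DEFAULT_SPEED_LAW,
) -> tuple[ln.SimResult, float, float]:
    """One pass of a single place-cell/interneuron pair through its field.

    Returns ``(result, field_center_m, duration_s)``.  The trajectory runs
    from 0 to ``6 sigma + 2 margin`` meters with the field center in the
    middle, at constant speed.
    """
    sig = sigma_cm / 100.0
    xc = margin_m + 3.0 * sig
    T = (6.0 * sig + 2.0 * margin_m) / (v_cm_s / 100.0)
    net = ln.build_connectivity(1, 1)
    _i0, _ith, _ie, noise_mV = ln.speed_params(v_cm_s, law)
    drives = ln.DriveSet.from_speed(
        v_cm_s,
        centers_m=[xc],
        law=law,
        sigma_cm=sigma_cm,
        ie_scale=ie_scale,
        lateral_offset_m=lateral_offset_m,
        place_drive=place_drive,
    )
    res = ln.simulate(
        net,
        drives,
        T,
        seed=seed,
        perturb=perturb,
        lif_pyr=ln.pyramidal_params(noise_sigma_mV=noise_mV),
        record_pyr=(0,) if record else (),
        record_int=(0,) if record else (),
    )
    return res, xc, T


def lap_winding(
    res: ln.SimResult,
    T: float,
    *,
    f_theta: float = F_THETA,
    plateau_s: float = 1.5,
    gap_s: float = 0.3,
) -> tuple[int | None, int]:
    """Interneuron cycles precessed over the lap, by plateau-to-plateau winding.

    The mean unwrapped interneuron spike phase over a locked plateau just
    before the first pyramidal spike is compared with the plateau at the end
    of the lap; the winding number of the drop is the number of full
    pacemaker cycles precessed.  Returns ``(cycles or None, n_pyr_spikes)``;
    ``None`` when the lap has no usable crossing or plateaus.
    """
    pyr = res.spikes_pyr[0]
    inter = res.spikes_int[0]
    if pyr.size < 2 or inter.size < 4:
        return None, int(pyr.size)
    u = np.unwrap(mx.spike_phases(inter, f_theta, res.reset_times))
    pre = (inter > pyr[0] - plateau_s - gap_s) & (inter < pyr[0] - gap_s)
    post = inter > T - plateau_s
    if pre.sum() < 3 or post.sum() < 3:
        return None, int(pyr.size)
    return int(round((u[pre].mean() - u[post].mean()) / TWO_PI)), int(pyr.size)


def network_lap(
    *,
    n_pyr: int,
    n_int: int,
    map_type: str = "random",
    seed: int = 0,
    track_m: float = 5.0,
    v_cm_s: float = 40.0,
    sigma_cm: float = 40.0,
    noise_pyr_mV: float | None = None,
    noise_int_mV: float = 0.0,
    law: ln.SpeedLaw = ln.DEFAULT_SPEED_LAW,
) -> tuple[ln.SimResult, np.ndarray]:
    """One lap of a place-cell network on a linear track.

    ``map_type`` is ``random`` (uniform field centers) or ``optimal``
    (equally spaced per interneuron, uniform coverage).  Returns the
    simulation result and the field centers.
    """
    rng = np.random.default_rng(seed)
    if map_type == "random":
        centers = rng.uniform(0.0, track_m, n_pyr)
    elif map_type == "optimal":
        centers = cap.optimal_centers(n_pyr, n_int, track_m)
    else:
        raise ValueError(f"unknown map type {map_type!r}")
    _i0, _ith, _ie, law_noise = ln.speed_params(v_cm_s, law)
    if noise_pyr_mV is None:
        noise_pyr_mV = law_noise
    net = ln.build_connectivity(n_pyr, n_int)
    drives = ln.DriveSet.from_speed(
        v_cm_s, centers_m=centers, law=law, sigma_cm=sigma_cm, n_interneuron=n_int
    )
    res = ln.simulate(
        net,
        drives,
        track_m / (v_cm_s / 100.0),
        seed=seed,
        lif_pyr=ln.pyramidal_params(noise_sigma_mV=noise_pyr_mV),
        lif_int=ln.interneuron_params(noise_sigma_mV=noise_int_mV),
    )
    return res, centers


def _pool_spikes(res: ln.SimResult, centers: np.ndarray, f_theta: float = F_THETA):
    ts, dist, ph, cid, cen = [], [], [], [], []
    for i, s in enumerate(res.spikes_pyr):
        if s.size == 0:
            continue
        x = res.position(s)
        ts.append(s)
        cid.append(np.full(s.size, i))
        dist.append(x - centers[i])
        cen.append(np.full(s.size, centers[i]))
        ph.append(mx.spike_phases(s, f_theta, res.reset_times))
    if not ts:
        raise ValueError("no pyramidal spikes in lap")
    return (
        np.concatenate(ts),
        np.concatenate(dist),
        np.concatenate(ph),
        np.concatenate(cid),
        np.concatenate(cen),
    )


def network_lap_metrics(
    res: ln.SimResult,
    centers: np.ndarray,
    *,
    f_theta: float = F_THETA,
    min_spikes_cell: int = 5,
) -> dict:
    """Population precession, mean theta-sequence score, and mean per-lap
    single-cell precession for one network lap."""
    ts, dist, ph, cid, cen = _pool_spikes(res, centers, f_theta)
    pop = mx.population_precession(dist, ph)
    try:
        seq = mx.theta_sequence_score(
            ts, cen, cid, period=1.0 / f_theta, phase_offset=pop.offset
        )
        seq_mean = float(seq["rho"].mean())
        n_cycles = int(len(seq))
    except ValueError:
        seq_mean, n_cycles = math.nan, 0
    rhos = []
    for i, s in enumerate(res.spikes_pyr):
        if s.size < min_spikes_cell:
            continue
        x = res.position(s)
        if np.ptp(x) == 0.0:
            continue
        try:
            rhos.append(
                mx.single_cell_precession(x, mx.spike_phases(s, f_theta, res.reset_times)).rho
            )
        except ValueError:
            continue
    return {
        "pop_rho": pop.rho,
        "pop_offset": pop.offset,
        "seq_rho_mean": seq_mean,
        "n_cycles": n_cycles,
        "single_rho_mean": float(np.mean(rhos)) if rhos else math.nan,
        "n_cells_scored": len(rhos),
        "n_spikes": int(ts.size),
    }


# ---------------------------------------------------------------------------
# experiments


def run_minimal_pair(seed: int = 0, *, v_cm_s: float = 40.0, n_laps: int = 20) -> ExperimentResult:
    """Minimal circuit: entrainment outside the field, precession inside.

    Per lap: interneuron out-of-field rate and phase dispersion, pyramidal
    spike count, maximum pyramidal spikes in one theta cycle, single-cell
    precession correlation, and the interneuron winding number.
    """
    config = _resolved(run_minimal_pair, locals())
    rows = []
    for lap in range(n_laps):
        res, xc, T = pair_lap(v_cm_s=v_cm_s, seed=seed + lap)
        pyr, inter = res.spikes_pyr[0], res.spikes_int[0]
        cycles, n_pyr = lap_winding(res, T)
        # out-of-field epoch: settled, before the field
        t_enter = (pyr[0] if pyr.size else T / 2.0) - 0.3
        out = inter[(inter > 3.0) & (inter < t_enter)]
        out_rate = out.size / max(t_enter - 3.0, 1e-9)
        ph_out = mx.spike_phases(out, F_THETA)
        z = np.mean(np.exp(1j * ph_out)) if out.size else np.nan
        phase_sd_deg = math.degrees(math.sqrt(max(-2.0 * math.log(min(abs(z), 1.0)), 0.0))) if out.size else math.nan
        per_cycle = np.bincount((pyr * F_THETA).astype(int)) if pyr.size else np.array([0])
        row = {
            "lap": lap,
            "n_pyr_spikes": n_pyr,
            "cycles_precessed": cycles,
            "out_rate_hz": out_rate,
            "out_phase_sd_deg": phase_sd_deg,
            "max_spikes_per_cycle": int(per_cycle.max()),
            "field_width_m": float((pyr[-1] - pyr[0]) * res.speed) if pyr.size >= 2 else math.nan,
        }
        if pyr.size >= 3:
            fit = mx.single_cell_precession(res.position(pyr), mx.spike_phases(pyr, F_THETA))
            row["single_rho"] = fit.rho
        rows.append(row)
    laps = pd.DataFrame(rows)
    counted = laps["cycles_precessed"].dropna().astype(int)
    modal = int(counted.mode().iloc[0]) if len(counted) else 0
    summary = {
        "n_laps": n_laps,
        "modal_cycles": modal,
        "modal_advance_deg": 360.0 * modal,
        "fraction_modal": float((counted == modal).mean()) if len(counted) else math.nan,
        "out_rate_hz_mean": float(laps["out_rate_hz"].mean()),
        "out_rate_hz_sd": float(laps["out_rate_hz"].std(ddof=1)),
        "pyr_spikes_mean": float(laps["n_pyr_spikes"].mean()),
        "pyr_spikes_sd": float(laps["n_pyr_spikes"].std(ddof=1)),
        "max_spikes_per_cycle": int(laps["max_spikes_per_cycle"].max()),
    }
    return ExperimentResult("minimal_pair", config, {"laps": laps}, summary)


def run_speed_sweep(
    seed: int = 0,
    *,
    speeds_cm_s: tuple = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0),
    n_laps: int = 20,
    margin_m: float = 1.0,
    window_radius_m: float = 0.15,
) -> ExperimentResult:
    """Precession frequency versus running speed from place-cell membrane traces.

    Per lap the theta-band instantaneous frequency of the place-cell membrane
    is averaged within 15 cm of the field center; laps failing the
    1.75x-standard-deviation rule (per speed) are excluded.  Reports the mean
    precession frequency (in-field frequency minus the pacemaker's 8 Hz) per
    speed and the linear trend across speeds.
    """
    config = _resolved(run_speed_sweep, locals())
    rows = []
    for v in speeds_cm_s:
        traces, positions = [], []
        for lap in range(n_laps):
            res, xc, T = pair_lap(v_cm_s=v, margin_m=margin_m, seed=seed + lap, record=True)
            ft = mx.instantaneous_theta_frequency(
                res.v_pyr[0], fs=1.0 / res.dt, clip_at=ln.pyramidal_params().v_thresh
            )
            traces.append(ft)
            positions.append(res.position(ft.times))
        table = mx.lap_precession_frequency(
            traces, positions, xc, radius=window_radius_m
        )
        for _, r in table.iterrows():
            rows.append(
                {
                    "speed_cm_s": v,
                    "lap": int(r["lap"]),
                    "field_freq_hz": r["freq_hz"],
                    "precession_freq_hz": r["freq_hz"] - F_THETA,
                    "excluded": bool(r["excluded"]),
                }
            )
    laps = pd.DataFrame(rows)
    ok = laps[~laps["excluded"]]
    per_speed = (
        ok.groupby("speed_cm_s")["precession_freq_hz"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "precession_freq_hz", "std": "sd", "count": "n"})
    )
    slope, intercept = np.polyfit(ok["speed_cm_s"], ok["precession_freq_hz"], 1)
    summary = {
        "slope_hz_per_cm_s": float(slope),
        "intercept_hz": float(intercept),
        "n_excluded": int(laps["excluded"].sum()),
        "n_laps_total": int(len(laps)),
    }
    return ExperimentResult(
        "speed_sweep", config, {"laps": laps, "per_speed": per_speed}, summary
    )


def _locking_phase_deg(
    i0_pA: float,
    itheta_pA: float,
    *,
    seed: int = 0,
    T: float = 60.0,
    settle: float = 30.0,
    lock_sd_deg: float = 5.0,
    lock_drift_cps: float = 0.01,
) -> tuple[float, bool]:
    """Mean interneuron spike phase (deg) under tonic + pacemaker drive, and
    whether the cell is phase locked (low dispersion, negligible drift)."""
    net = ln.build_connectivity(1, 1)
    drives = ln.DriveSet(
        i0_int=np.array([i0_pA * 1e-12]),
        itheta_int=np.array([itheta_pA * 1e-12]),
        f_theta=F_THETA,
        ie_amp=np.array([0.0]),
        centers=np.array([0.0]),
        sigma_field=np.array([0.4]),
    )
    res = ln.simulate(net, drives, T, seed=seed)
    spk = res.spikes_int[0]
    spk = spk[spk >= settle]
    if spk.size < 10:
        return math.nan, False
    ph = mx.spike_phases(spk, F_THETA)
    z = np.mean(np.exp(1j * ph))
    mean_deg = math.degrees(np.angle(z)) % 360.0
    sd_deg = math.degrees(math.sqrt(max(-2.0 * math.log(min(abs(z), 1.0)), 1e-30)))
    u = np.unwrap(ph)
    drift = abs(u[-1] - u[0]) / TWO_PI / (spk[-1] - spk[0])
    return mean_deg, bool(sd_deg < lock_sd_deg and drift < lock_drift_cps)


def locking_sweep(
    seed: int = 0,
    *,
    itheta_pA: float = 1.95,
    i0_lo_pA: float = 78.2,
    i0_hi_pA: float = 81.0,
    n_points: int = 13,
    refine_iters: int = 20,
    edge_inset_pA: float = 0.002,
) -> pd.DataFrame:
    """Interneuron locking phase versus tonic current with edge refinement.

    A coarse sweep locates the locking region; bisection refines both
    locking/pulling boundaries, and the phase is evaluated just inside each
    edge so the measured phase range approaches the full extent.
    """
    grid = np.linspace(i0_lo_pA, i0_hi_pA, n_points)
    rows = [
        {"i0_pA": i0, **dict(zip(("phase_deg", "locked"), _locking_phase_deg(i0, itheta_pA, seed=seed)))}
        for i0 in grid
    ]
    df = pd.DataFrame(rows)
    locked_i0 = df.loc[df["locked"], "i0_pA"]
    if len(locked_i0) >= 2:
        lo_in, hi_in = float(locked_i0.min()), float(locked_i0.max())

        def bisect(inside: float, outside: float) -> float:
            a, b = inside, outside  # a locked, b not
            for _ in range(refine_iters):
                mid = 0.5 * (a + b)
                _, lk = _locking_phase_deg(mid, itheta_pA, seed=seed, T=80.0, settle=50.0)
                if lk:
                    a = mid
                else:
                    b = mid
            return a

        lo_edge = bisect(lo_in, i0_lo_pA)
        hi_edge = bisect(hi_in, i0_hi_pA)
        extra = []
        for i0 in (lo_edge + edge_inset_pA, hi_edge - edge_inset_pA):
            ph, lk = _locking_phase_deg(i0, itheta_pA, seed=seed, T=160.0, settle=120.0)
            extra.append({"i0_pA": i0, "phase_deg": ph, "locked": lk})
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True).sort_values("i0_pA")
    return df.reset_index(drop=True)


def pole_pair_lap(pole: str, *, seed: int = 0, margin_m: float | None = None):
    """One field crossing for a dorsal- or ventral-pole pair (printed parameter sets)."""
    p = ln.dorsoventral_params(pole)
    sig = p["sigma_cm"] / 100.0
    v = p["v_cm_s"] / 100.0
    if margin_m is None:
        margin_m = max(2.5, 1.5 * sig)
    xc = margin_m + 3.0 * sig
    T = (6.0 * sig + 2.0 * margin_m) / v
    net = ln.build_connectivity(1, 1, w_exc=p["w_exc_nS"] * 1e-9)
    ie_pA = ln.speed_params(p["v_cm_s"])[2]
    drives = ln.DriveSet(
        i0_int=np.array([p["i0_pA"] * 1e-12]),
        itheta_int=np.array([p["itheta_pA"] * 1e-12]),
        f_theta=F_THETA,
        ie_amp=np.array([ie_pA * 1e-12]),
        centers=np.array([xc]),
        sigma_field=np.array([sig]),
        x0=0.0,
        speed=v,
    )
    res = ln.simulate(
        net, drives, T, seed=seed, lif_pyr=ln.pyramidal_params(noise_sigma_mV=p["noise_mV"])
    )
    return res, xc, T


def run_dorsoventral(
    seed: int = 0, *, n_sweep_points: int = 13, n_pole_laps: int = 5, refine_iters: int = 20
) -> ExperimentResult:
    """Dorsoventral gradient: locking-phase sweep plus dorsal/ventral pole pairs.

    (a) locking phase versus tonic current at the v = 30 cm/s pacemaker
    amplitude, with the measured phase range across the locking region;
    (b) the printed dorsal and ventral parameter sets: out-of-field locking
    phases (circular separation) and in-field winding numbers.
    """
    config = _resolved(run_dorsoventral, locals())
    sweep = locking_sweep(seed=seed, n_points=n_sweep_points, refine_iters=refine_iters)
    locked = sweep[sweep["locked"]]
    phase_range = float(locked["phase_deg"].max() - locked["phase_deg"].min()) if len(locked) else math.nan

    pole_rows = []
    lock_deg = {}
    for pole in ("dorsal", "ventral"):
        p = ln.dorsoventral_params(pole)
        lock_deg[pole], _ = _locking_phase_deg(
            p["i0_pA"], p["itheta_pA"], seed=seed, T=60.0, settle=30.0
        )
        for lap in range(n_pole_laps):
            res, xc, T = pole_pair_lap(pole, seed=seed + lap)
            cycles, n_pyr = lap_winding(res, T, plateau_s=2.0)
            pyr = res.spikes_pyr[0]
            pole_rows.append(
                {
                    "pole": pole,
                    "lap": lap,
                    "n_pyr_spikes": n_pyr,
                    "cycles_precessed": cycles,
                    "field_width_m": float((pyr[-1] - pyr[0]) * res.speed)
                    if pyr.size >= 2
                    else math.nan,
                }
            )
    sep = abs(lock_deg["dorsal"] - lock_deg["ventral"])
    sep = min(sep, 360.0 - sep)
    poles = pd.DataFrame(pole_rows)
    summary = {
        "locking_range_deg": phase_range,
        "dorsal_lock_deg": lock_deg["dorsal"],
        "ventral_lock_deg": lock_deg["ventral"],
        "pole_separation_deg": sep,
        "dorsal_modal_cycles": int(
            poles.loc[poles.pole == "dorsal", "cycles_precessed"].dropna().mode().iloc[0]
        ),
        "ventral_modal_cycles": int(
            poles.loc[poles.pole == "ventral", "cycles_precessed"].dropna().mode().iloc[0]
        ),
    }
    return ExperimentResult(
        "dorsoventral", config, {"locking_sweep": sweep, "poles": poles}, summary
    )


def run_envelope_sweep(
    seed: int = 0,
    *,
    amplitudes_pA: tuple = tuple(np.linspace(110.0, 250.0, 15)),
    n_trials: int = 100,
    v_cm_s: float = 40.0,
    edge_pass: bool = False,
) -> ExperimentResult:
    """Robustness of precession to the place-field drive amplitude.

    For each envelope amplitude, ``n_trials`` seeded laps record the
    place-cell spike count and the interneuron winding number; the summary
    re-bins cycle probabilities against spike count and reports the largest
    mean spike count whose modal winding is one cycle.  ``edge_pass`` offsets
    the trajectory 14 cm from the field center.
    """
    config = _resolved(run_envelope_sweep, locals())
    ie_default = ln.speed_params(v_cm_s)[2]
    rows = []
    for amp in amplitudes_pA:
        for trial in range(n_trials):
            res, xc, T = pair_lap(
                v_cm_s=v_cm_s,
                seed=seed + trial,
                ie_scale=amp / ie_default,
                lateral_offset_m=0.14 if edge_pass else 0.0,
            )
            cycles, n_pyr = lap_winding(res, T)
            rows.append(
                {"ie_pA": amp, "trial": trial, "n_pyr_spikes": n_pyr, "cycles": cycles}
            )
    trials = pd.DataFrame(rows)
    per_amp = []
    for amp, grp in trials.groupby("ie_pA"):
        counted = grp["cycles"].dropna().astype(int)
        probs = counted.value_counts(normalize=True).to_dict()
        per_amp.append(
            {
                "ie_pA": amp,
                "spikes_mean": float(grp["n_pyr_spikes"].mean()),
                "spikes_sd": float(grp["n_pyr_spikes"].std(ddof=1)),
                "n": int(len(grp)),
                "modal_cycles": int(counted.mode().iloc[0]) if len(counted) else -1,
                **{f"p_cycles_{k}": float(probs.get(k, 0.0)) for k in (0, 1, 2, 3)},
            }
        )
    per_amp = pd.DataFrame(per_amp)
    one = per_amp[per_amp["modal_cycles"] == 1]
    summary = {
        "largest_one_cycle_spike_count": float(one["spikes_mean"].max()) if len(one) else math.nan,
        "smallest_one_cycle_spike_count": float(one["spikes_mean"].min()) if len(one) else math.nan,
        "n_amplitudes": len(amplitudes_pA),
        "n_trials": n_trials,
    }
    return ExperimentResult(
        "envelope_sweep", config, {"trials": trials, "per_amplitude": per_amp}, summary
    )


def run_two_cells(
    seed: int = 0,
    *,
    separation_m: float = 1.6,
    v_cm_s: float = 40.0,
    sigma_cm: float = 40.0,
    margin_m: float = 2.5,
    identical_centers: bool = False,
) -> ExperimentResult:
    """Two pyramidal cells sharing one interneuron.

    With temporally separated fields the interneuron precesses once per
    field, and the silent cell's membrane theta frequency rises during its
    partner's field (subthreshold precession).  With identical centers the
    cells synchronize and can drive multi-cycle precession.
    """
    config = _resolved(run_two_cells, locals())
    sig = sigma_cm / 100.0
    v = v_cm_s / 100.0
    xc1 = margin_m + 3.0 * sig
    xc2 = xc1 if identical_centers else xc1 + separation_m
    T = (xc2 + 3.0 * sig + margin_m) / v
    net = ln.build_connectivity(2, 1)
    _i0, _ith, ie_pA, noise_mV = ln.speed_params(v_cm_s)
    drives = ln.DriveSet.from_speed(
        v_cm_s, centers_m=[xc1, xc2], sigma_cm=sigma_cm, n_interneuron=1
    )
    res = ln.simulate(
        net,
        drives,
        T,
        seed=seed,
        lif_pyr=ln.pyramidal_params(noise_sigma_mV=noise_mV),
        record_pyr=(0, 1),
        record_int=(0,),
    )
    inter = res.spikes_int[0]
    u = np.unwrap(mx.spike_phases(inter, F_THETA))

    def winding(t0: float, t1: float, pad: float = 1.2) -> int | None:
        pre = (inter > t0 - 1.5 - 0.3) & (inter < t0 - 0.3)
        post = (inter > t1 + pad) & (inter < t1 + pad + 1.5)
        if pre.sum() < 3 or post.sum() < 3:
            return None
        return int(round((u[pre].mean() - u[post].mean()) / TWO_PI))

    rows = []
    fs = 1.0 / res.dt
    for i, xc in enumerate((xc1, xc2)):
        spk = res.spikes_pyr[i]
        other = 1 - i
        row = {"cell": i, "center_m": xc, "n_spikes": int(spk.size)}
        if spk.size >= 2:
            row["cycles_in_field"] = winding(spk[0], spk[-1])
        # partner's subthreshold frequency during this cell's field
        ft = mx.instantaneous_theta_frequency(
            res.v_pyr[other], fs=fs, clip_at=ln.pyramidal_params().v_thresh
        )
        x_ft = res.position(ft.times)
        in_field = np.abs(x_ft - xc) < sig
        out_field = (x_ft < xc1 - 3 * sig) | (x_ft > xc2 + 3 * sig)
        row["partner_subthreshold_freq_in"] = float(np.mean(ft.freq[in_field]))
        row["partner_subthreshold_freq_out"] = (
            float(np.mean(ft.freq[out_field])) if out_field.any() else math.nan
        )
        rows.append(row)
    cells = pd.DataFrame(rows)
    summary = {
        "cycles_field_1": rows[0].get("cycles_in_field"),
        "cycles_field_2": rows[1].get("cycles_in_field"),
        "identical_centers": identical_centers,
    }
    if identical_centers:
        both = np.sort(np.concatenate(res.spikes_pyr))
        full = winding(both[0], both[-1]) if both.size >= 2 else None
        summary["cycles_joint_field"] = full
    return ExperimentResult("two_cells", config, {"cells": cells}, summary)


def run_network_density(
    seed: int = 0,
    *,
    n_pyr: int = 1000,
    cells_per_interneuron: tuple = (1, 2, 5, 10, 20),
    map_types: tuple = ("random", "optimal"),
    n_repeats: int = 10,
    track_m: float = 5.0,
    v_cm_s: float = 40.0,
) -> ExperimentResult:
    """Sequence compression versus place-field density for random and optimal maps.

    One lap per map instance with a fresh map per repeat; reports the
    population precession, mean theta-sequence score, and mean per-lap
    single-cell precession per (density, map type).
    """
    config = _resolved(run_network_density, locals())
    rows = []
    for density in cells_per_interneuron:
        if n_pyr % density:
            raise ValueError(f"density {density} does not divide n_pyr={n_pyr}")
        n_int = n_pyr // density
        for map_type in map_types:
            for rep in range(n_repeats):
                res, centers = network_lap(
                    n_pyr=n_pyr,
                    n_int=n_int,
                    map_type=map_type,
                    seed=seed + 1000 * rep,
                    track_m=track_m,
                    v_cm_s=v_cm_s,
                )
                m = network_lap_metrics(res, centers)
                rows.append(
                    {"density": density, "map_type": map_type, "repeat": rep, **m}
                )
    laps = pd.DataFrame(rows)
    per_cond = (
        laps.groupby(["density", "map_type"])[["pop_rho", "seq_rho_mean", "single_rho_mean"]]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    per_cond.columns = ["_".join(c).rstrip("_") for c in per_cond.columns]
    summary = {
        "densities": list(cells_per_interneuron),
        "map_types": list(map_types),
        "n_repeats": n_repeats,
    }
    return ExperimentResult(
        "network_density", config, {"laps": laps, "per_condition": per_cond}, summary
    )


def run_noise_sweep(
    seed: int = 0,
    *,
    n_pyr: int = 200,
    n_int: int = 200,
    pyr_noise_mV: tuple = (0.75, 2.0, 4.0, 8.0),
    int_noise_mV: tuple = (0.0, 1.0, 2.0, 4.0),
    n_repeats: int = 3,
    track_m: float = 5.0,
) -> ExperimentResult:
    """Extraneous-noise robustness: vary one population's noise at a time.

    Place-cell noise degrades single-cell and population metrics in
    parallel; interneuron noise decoheres the population (sequences and
    pooled precession) while single-trial single-cell precession survives.
    """
    config = _resolved(run_noise_sweep, locals())
    rows = []
    for population, levels in (("pyramidal", pyr_noise_mV), ("interneuron", int_noise_mV)):
        for level in levels:
            for rep in range(n_repeats):
                res, centers = network_lap(
                    n_pyr=n_pyr,
                    n_int=n_int,
                    map_type="optimal",
                    seed=seed + 100 * rep,
                    track_m=track_m,
                    noise_pyr_mV=level if population == "pyramidal" else None,
                    noise_int_mV=level if population == "interneuron" else 0.0,
                )
                m = network_lap_metrics(res, centers)
                rows.append({"population": population, "noise_mV": level, "repeat": rep, **m})
    laps = pd.DataFrame(rows)
    per_cond = (
        laps.groupby(["population", "noise_mV"])[["pop_rho", "seq_rho_mean", "single_rho_mean"]]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    per_cond.columns = ["_".join(c).rstrip("_") for c in per_cond.columns]
    return ExperimentResult(
        "noise_sweep",
        config,
        {"laps": laps, "per_condition": per_cond},
        {"n_repeats": n_repeats},
    )


def run_perturbations(
    seed: int = 0,
    *,
    protocol: str = "theta_reset",
    n_laps: int = 1050,
    jitter_cm: float = 0.0,
    v_cm_s: float = 40.0,
    n_bins: int = 5,
) -> ExperimentResult:
    """Perturbation protocols: transient silencing with theta reset, or
    1 s interneuron silencing (optionally jittered within ±20 cm of the
    field center) compared against unperturbed control laps in 5 spatial bins.
    """
    config = _resolved(run_perturbations, locals())
    if protocol not in ("theta_reset", "interneuron_silencing"):
        raise ValueError(f"unknown protocol {protocol!r}")
    v = v_cm_s / 100.0
    rng = np.random.default_rng(seed)

    if protocol == "theta_reset":
        sig = 0.4
        xc = 2.5 + 3.0 * sig  # pair_lap geometry at the default margin
        pert = ln.PerturbationProtocol.transient_reset(onset=xc / v - 0.1)
        rows = []
        for lap in range(n_laps):
            res, _xc, T = pair_lap(v_cm_s=v_cm_s, seed=seed + lap, perturb=pert)
            pyr, inter = res.spikes_pyr[0], res.spikes_int[0]
            win = (pert.onset, pert.onset + pert.duration)
            silent = lambda s: int(np.sum((s >= win[0]) & (s < win[1])))  # noqa: E731
            # resumption: spikes and precession after the window
            post_pyr = pyr[pyr >= win[1]]
            resumed = False
            if post_pyr.size >= 3:
                fit = mx.single_cell_precession(
                    res.position(post_pyr), mx.spike_phases(post_pyr, F_THETA, res.reset_times)
                )
                resumed = fit.rho < -0.3
            rows.append(
                {
                    "lap": lap,
                    "pyr_spikes_in_window": silent(pyr),
                    "int_spikes_in_window": silent(inter),
                    "post_pyr_spikes": int(post_pyr.size),
                    "precession_resumes": resumed,
                }
            )
        laps = pd.DataFrame(rows)
        summary = {
            "fraction_windows_silent": float(
                ((laps["pyr_spikes_in_window"] == 0) & (laps["int_spikes_in_window"] == 0)).mean()
            ),
            "fraction_precession_resumes": float(laps["precession_resumes"].mean()),
        }
        return ExperimentResult("perturbation_theta_reset", config, {"laps": laps}, summary)

    # interneuron silencing: control vs perturbed spike phases in 5 field bins
    ctrl_x, ctrl_ph, pert_x, pert_ph = [], [], [], []
    xc = 2.5 + 3.0 * 0.4  # pair_lap geometry at the default margin
    for lap in range(n_laps):
        center_m = xc + (rng.uniform(-jitter_cm, jitter_cm) / 100.0 if jitter_cm else 0.0)
        pert = ln.PerturbationProtocol.interneuron_silencing(onset=center_m / v - 0.5)
        res_c, _, _ = pair_lap(v_cm_s=v_cm_s, seed=seed + 2 * lap)
        res_p, _, _ = pair_lap(v_cm_s=v_cm_s, seed=seed + 2 * lap + 1, perturb=pert)
        for res, xs, ps in ((res_c, ctrl_x, ctrl_ph), (res_p, pert_x, pert_ph)):
            s = res.spikes_pyr[0]
            xs.append(res.position(s))
            ps.append(mx.spike_phases(s, F_THETA))
    ctrl_x, ctrl_ph = np.concatenate(ctrl_x), np.concatenate(ctrl_ph)
    pert_x, pert_ph = np.concatenate(pert_x), np.concatenate(pert_ph)
    lo = min(ctrl_x.min(), pert_x.min())
    hi = max(ctrl_x.max(), pert_x.max())
    bins = mx.binned_phase_shift(
        ctrl_x, ctrl_ph, pert_x, pert_ph, n_bins=n_bins, extent=(lo, hi)
    )
    mean_shift = float(np.nanmean(bins["shift"]))
    summary = {
        "mean_shift_deg": math.degrees(mean_shift),
        "n_laps": n_laps,
        "jitter_cm": jitter_cm,
        "n_control_spikes": int(ctrl_x.size),
        "n_perturbed_spikes": int(pert_x.size),
    }
    return ExperimentResult(
        "perturbation_interneuron_silencing", config, {"bins": bins}, summary
    )


def run_pooled_distribution(
    seed: int = 0,
    *,
    n_pyr: int = 200,
    cells_per_interneuron: tuple = (1, 5, 20),
    n_laps: int = 30,
    track_m: float = 5.0,
    v_cm_s: float = 40.0,
) -> ExperimentResult:
    """Distribution of pooled (multi-lap) single-cell precession versus density.

    One fixed random map per density; each cell's spikes are pooled over
    ``n_laps`` laps before computing its phase-position correlation.
    """
    config = _resolved(run_pooled_distribution, locals())
    rows = []
    for density in cells_per_interneuron:
        n_int = n_pyr // density
        map_rng = np.random.default_rng(seed)
        centers = map_rng.uniform(0.0, track_m, n_pyr)
        pooled_x = [[] for _ in range(n_pyr)]
        pooled_ph = [[] for _ in range(n_pyr)]
        for lap in range(n_laps):
            net = ln.build_connectivity(n_pyr, n_int)
            drives = ln.DriveSet.from_speed(
                v_cm_s, centers_m=centers, sigma_cm=40.0, n_interneuron=n_int
            )
            noise_mV = ln.speed_params(v_cm_s)[3]
            res = ln.simulate(
                net,
                drives,
                track_m / (v_cm_s / 100.0),
                seed=seed + lap,
                lif_pyr=ln.pyramidal_params(noise_sigma_mV=noise_mV),
            )
            for i, s in enumerate(res.spikes_pyr):
                if s.size:
                    pooled_x[i].append(res.position(s))
                    pooled_ph[i].append(mx.spike_phases(s, F_THETA))
        for i in range(n_pyr):
            if not pooled_x[i]:
                continue
            x = np.concatenate(pooled_x[i])
            ph = np.concatenate(pooled_ph[i])
            if x.size < 10 or np.ptp(x) == 0.0:
                continue
            fit = mx.single_cell_precession(x, ph)
            rows.append(
                {"density": density, "cell": i, "pooled_rho": fit.rho, "n_spikes": int(x.size)}
            )
    cells = pd.DataFrame(rows)
    per_density = (
        cells.groupby("density")["pooled_rho"].agg(["mean", "std", "count"]).reset_index()
    )
    summary = {
        "mean_rho_by_density": {
            int(r["density"]): float(r["mean"]) for _, r in per_density.iterrows()
        }
    }
    return ExperimentResult(
        "pooled_distribution", config, {"cells": cells, "per_density": per_density}, summary
    )


def run_capacity_table(
    *,
    n_pyr: int = 10_000,
    n_int: int = 1000,
    fields_per_cell: float = 0.2,
    track_m: float = 5.0,
    zone_m: float = 1.0,
    resolution_m: float = 0.1,
    assembly_size: int = 100,
    sequence_length: int = 7,
) -> ExperimentResult:
    """Capacity combinatorics table: density bound and log10 counts of maps,
    assemblies, and phase sequences."""
    config = _resolved(run_capacity_table, locals())
    track = cap.TrackDiscretization(track_m, resolution_m)
    cons = cap.ExclusionConstraint(zone_m)
    params = cap.CapacityParams(
        n_pyr, n_int, fields_per_cell, assembly_size=assembly_size, sequence_length=sequence_length
    )
    rows = {
        "density_bound_F_max": cap.density_bound(n_int, n_pyr, track_m, zone_m),
        "log10_maps": cap.ln_to_log10(cap.log_map_count(params, track, cons)),
        "log10_maps_stirling": cap.ln_to_log10(cap.log_map_count_stirling(params, track, cons)),
        "log10_assemblies": cap.ln_to_log10(cap.log_assembly_count(params)),
        "log10_assemblies_stirling": cap.ln_to_log10(cap.log_assembly_count_stirling(params)),
        "log10_sequences": cap.ln_to_log10(cap.log_sequence_count(params)),
        "log10_sequences_stirling": cap.ln_to_log10(cap.log_sequence_count_stirling(params)),
    }
    table = pd.DataFrame([{"quantity": k, "value": v} for k, v in rows.items()])
    return ExperimentResult("capacity", config, {"capacity": table}, rows)
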