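"""Measurement pipeline for phase precession and theta-sequence compression.

Given spike trains and membrane traces from the circuit simulator this module
computes:

* the instantaneous theta-band frequency of a membrane trace (zero-phase
  band-pass 6.25-10 Hz, Hilbert phase, 250 ms moving average, derivative);
* per-lap precession frequency within 15 cm of the field center, with the
  1.75x-standard-deviation run-exclusion rule;
* spike phases against the pacemaker (honoring phase resets);
* the single-cell and population phase-precession metrics: the Pearson
  correlation between spike phase and position (or signed distance from the
  field center), minimized over a global rotation of the phases;
* the per-theta-cycle sequence metric: the within-cycle correlation between
  spike times and the field centers of the corresponding cells;
* the integer number of pacemaker cycles an interneuron precesses through
  during a field crossing;
* binned circular spike-phase statistics for perturbation experiments.

Spike phases are pacemaker phases ``2 pi f_theta (t - t_reset) mod 2 pi``, so
a precessing neuron's spike phase *decreases* across a traversal; phase
advance is counted positive in that direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.stats import circmean, circstd

__all__ = [
    "FrequencyTrace",
    "PrecessionFit",
    "instantaneous_theta_frequency",
    "lap_precession_frequency",
    "spike_phases",
    "single_cell_precession",
    "population_precession",
    "theta_sequence_score",
    "cycles_precessed",
    "binned_phase_shift",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class FrequencyTrace:
    """Instantaneous theta-band frequency (Hz) on a (transient-trimmed) time base."""

    times: np.ndarray
    freq: np.ndarray

    def mean_in_window(self, mask: np.ndarray) -> float:
        return float(np.mean(self.freq[mask]))


@dataclass(frozen=True)
class PrecessionFit:
    """Rotation-minimized phase-position correlation and its phase offset (rad)."""

    rho: float
    offset: float
    n_spikes: int


def instantaneous_theta_frequency(
    trace: np.ndarray,
    fs: float,
    *,
    band: tuple[float, float] = (6.25, 10.0),
    smooth_s: float = 0.25,
    clip_at: float | None = None,
    trim_s: float = 0.75,
) -> FrequencyTrace:
    """Theta-band instantaneous frequency of a membrane trace.

    Zero-phase (forward-backward) 2nd-order Butterworth band-pass, analytic
    signal phase, unwrap, ``smooth_s`` moving average, time derivative.
    ``trim_s`` seconds are dropped at each edge to discard the filter
    transient; ``clip_at`` caps the trace (e.g. at the spike threshold)
    before filtering.
    """
    v = np.asarray(trace, dtype=float)
    if fs < 1000.0:
        raise ValueError("sampling rate must be at least 1 kHz")
    n_trim = int(round(trim_s * fs))
    if v.size <= 2 * n_trim + 4:
        raise ValueError("trace shorter than twice the filter transient")
    if clip_at is not None:
        v = np.minimum(v, clip_at)
    sos = butter(2, band, btype="bandpass", fs=fs, output="sos")
    filt = sosfiltfilt(sos, v - v.mean())
    phase = np.unwrap(np.angle(hilbert(filt)))
    width = max(1, int(round(smooth_s * fs)))
    phase = uniform_filter1d(phase, size=width, mode="nearest")
    freq = np.gradient(phase, 1.0 / fs) / TWO_PI
    times = np.arange(v.size) / fs
    sl = slice(n_trim, v.size - n_trim)
    return FrequencyTrace(times=times[sl], freq=freq[sl])


def lap_precession_frequency(
    freq_traces: Sequence[FrequencyTrace],
    positions: Sequence[np.ndarray],
    field_center: float,
    *,
    radius: float = 0.15,
    exclusion_factor: float = 1.75,
) -> pd.DataFrame:
    """Per-lap mean in-field frequency with the variability-based exclusion rule.

    For each lap the frequency is averaged within ``radius`` meters of the
    field center; a lap is excluded when the in-window standard deviation
    exceeds ``exclusion_factor`` times the mean standard deviation over all
    laps of the set (runs at one speed are analyzed together).
    """
    means, sds = [], []
    for ft, pos in zip(freq_traces, positions):
        mask = np.abs(np.asarray(pos) - field_center) <= radius
        if not np.any(mask):
            raise ValueError("field-center window lies outside the recorded trace")
        means.append(float(np.mean(ft.freq[mask])))
        sds.append(float(np.std(ft.freq[mask])))
    sds_arr = np.asarray(sds)
    # the absolute floor keeps numerically identical laps from tripping the rule
    excluded = sds_arr > exclusion_factor * sds_arr.mean() + 1e-9
    return pd.DataFrame(
        {
            "lap": np.arange(len(means)),
            "freq_hz": means,
            "freq_sd_hz": sds,
            "excluded": excluded,
        }
    )


def spike_phases(
    spike_times: np.ndarray, f_theta: float, reset_times: Sequence[float] = ()
) -> np.ndarray:
    """Pacemaker phase of each spike in [0, 2 pi), honoring pacemaker resets."""
    t = np.asarray(spike_times, dtype=float)
    anchors = np.concatenate(([0.0], np.sort(np.asarray(reset_times, dtype=float))))
    idx = np.searchsorted(anchors, t, side="right") - 1
    return (TWO_PI * f_theta * (t - anchors[idx])) % TWO_PI


def _rotated_correlations(x: np.ndarray, phases: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Pearson correlation of x against (phases + offset) mod 2 pi for each offset."""
    xc = x - x.mean()
    sx = math.sqrt(float(np.sum(xc * xc)))
    shifted = (phases[None, :] + offsets[:, None]) % TWO_PI
    sc = shifted - shifted.mean(axis=1, keepdims=True)
    denom = sx * np.sqrt(np.sum(sc * sc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (sc @ xc) / denom
    return rho


def single_cell_precession(
    x: np.ndarray, phases: np.ndarray, *, grid_deg: float = 1.0
) -> PrecessionFit:
    """Phase-position correlation minimized over a global phase rotation.

    After adding the offset, phases are wrapped to [0, 2 pi) and correlated
    *linearly* with position; the returned ``rho`` is the most negative value
    over an exhaustive offset grid (default 1 degree), so a strongly
    precessing cell approaches -1.  Invariant (up to grid resolution) under
    any global rotation of the input phases.
    """
    x = np.asarray(x, dtype=float)
    phases = np.asarray(phases, dtype=float) % TWO_PI
    if x.size != phases.size:
        raise ValueError("position and phase vectors must have equal length")
    if x.size < 3:
        raise ValueError("at least 3 spikes required")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in position")
    offsets = np.deg2rad(np.arange(0.0, 360.0, grid_deg))
    rho = _rotated_correlations(x, phases, offsets)
    if np.all(np.isnan(rho)):
        raise ValueError("zero variance in rotated phases at every offset")
    best = int(np.nanargmin(rho))
    return PrecessionFit(rho=float(rho[best]), offset=float(offsets[best]), n_spikes=x.size)


def population_precession(
    distances: np.ndarray, phases: np.ndarray, *, grid_deg: float = 1.0
) -> PrecessionFit:
    """Population metric: pooled spikes, position replaced by the signed
    distance of the animal from each spike's own field center."""
    return single_cell_precession(distances, phases, grid_deg=grid_deg)


def theta_sequence_score(
    spike_times: np.ndarray,
    field_centers: np.ndarray,
    cell_ids: np.ndarray,
    *,
    period: float,
    phase_offset: float = 0.0,
    min_spikes: int = 3,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Per-theta-cycle correlation between spike times and field centers.

    Cycle windows have width ``period`` and are anchored by the lap's
    population phase offset ``phase_offset``: a window starts wherever the
    rotated spike phase ``(phase + phase_offset) mod 2 pi`` crosses zero, so
    each window brackets one full precession ramp and boundaries fall between
    sequences rather than through them.  Cycles with fewer than
    ``min_spikes`` spikes or ``min_cells`` distinct cells are skipped.
    A positive correlation means within-cycle firing order recapitulates the
    spatial order of the field centers.
    """
    t = np.asarray(spike_times, dtype=float)
    c = np.asarray(field_centers, dtype=float)
    ids = np.asarray(cell_ids)
    if not (t.size == c.size == ids.size):
        raise ValueError("spike_times, field_centers and cell_ids must align")
    shift = ((-phase_offset) % TWO_PI) / TWO_PI * period
    cycle = np.floor((t - shift) / period).astype(int)
    rows = []
    for k in np.unique(cycle):
        m = cycle == k
        if m.sum() < min_spikes or np.unique(ids[m]).size < min_cells:
            continue
        tc, cc = t[m], c[m]
        if np.ptp(tc) == 0.0 or np.ptp(cc) == 0.0:
            continue
        rho = float(np.corrcoef(tc, cc)[0, 1])
        rows.append({"cycle": int(k), "rho": rho, "n_spikes": int(m.sum())})
    if not rows:
        raise ValueError("no theta cycle satisfies the spike/cell preconditions")
    return pd.DataFrame(rows)


def cycles_precessed(phases: np.ndarray) -> int:
    """Integer number of pacemaker cycles precessed over a field crossing.

    ``phases`` are the spike phases (rad, in [0, 2 pi)) of the interneuron
    within the crossing window; they are unwrapped and the winding number of
    the total advance is returned.  Because pacemaker spike phase decreases
    while precessing, a drop of ``2 pi k`` yields ``+k``.
    """
    ph = np.asarray(phases, dtype=float)
    if ph.size < 2:
        raise ValueError("at least 2 spikes required")
    u = np.unwrap(ph)
    return int(round((u[0] - u[-1]) / TWO_PI))


def binned_phase_shift(
    x_control: np.ndarray,
    ph_control: np.ndarray,
    x_perturbed: np.ndarray,
    ph_perturbed: np.ndarray,
    *,
    n_bins: int = 5,
    extent: tuple[float, float],
) -> pd.DataFrame:
    """Binned circular spike-phase comparison between two conditions.

    The field ``extent`` is divided into ``n_bins`` equal bins; per bin and
    condition the circular mean and circular standard error are computed, and
    the per-bin circular phase shift (perturbed - control) is wrapped to
    ``(-pi, pi]``.  Bins empty in either condition are flagged missing.
    """
    edges = np.linspace(extent[0], extent[1], n_bins + 1)

    def _stats(x, ph):
        means = np.full(n_bins, np.nan)
        ses = np.full(n_bins, np.nan)
        counts = np.zeros(n_bins, dtype=int)
        which = np.digitize(x, edges) - 1
        for b in range(n_bins):
            sel = ph[which == b]
            counts[b] = sel.size
            if sel.size:
                means[b] = circmean(sel, high=TWO_PI, low=0.0)
                ses[b] = circstd(sel, high=TWO_PI, low=0.0) / math.sqrt(sel.size)
        return means, ses, counts

    mc, sec, nc = _stats(np.asarray(x_control, float), np.asarray(ph_control, float))
    mp, sep, np_ = _stats(np.asarray(x_perturbed, float), np.asarray(ph_perturbed, float))
    diff = mp - mc
    shift = np.where(np.isnan(diff), np.nan, (diff + math.pi) % TWO_PI - math.pi)
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "bin_center": 0.5 * (edges[:-1] + edges[1:]),
            "control_mean": mc,
            "control_se": sec,
            "control_n": nc,
            "perturbed_mean": mp,
            "perturbed_se": sep,
            "perturbed_n": np_,
            "shift": shift,
            "missing": np.isnan(diff),
        }
    )
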