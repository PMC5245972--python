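"""Reduced phase model of a pacemaker-driven interneuron.

An interneuron firing tonically at intrinsic angular frequency ``omega`` and
weakly forced by an oscillatory pacemaker (the septal theta drive) reduces,
after averaging over single theta cycles, to the Adler equation for the
phase difference ``dphi = phi - theta``::

    d(dphi)/dt = detuning - A * sin(dphi)

where ``detuning = omega - omega_theta`` and the synchronization factor
``A = Q0 * z1 / 2`` is set by the pacemaker amplitude ``Q0`` and the
sinusoidal component ``z1`` of the neuron's phase response curve
``z(phi) = z0 - z1 sin(phi)``.

Two regimes exist: *phase locking* for ``|detuning| < A`` (stable phase
``arcsin(detuning / A)``, so the full family of stable locking phases spans
exactly 180 degrees) and *frequency pulling* for ``|detuning| > A``, where the
phase drifts through full cycles at the precession frequency
``sqrt(detuning**2 - A**2) / (2*pi)``.  This module provides the closed-form
trajectory, fixed-step integrators for both the averaged and un-averaged
models (used as numeric oracles for each other), and the running-speed
constraint that ties the detuning to place-field size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "PhaseResponseCurve",
    "PacemakerPerturbation",
    "PhaseReductionParams",
    "PhaseTrajectory",
    "SpeedConstraintInputs",
    "InvalidRegimeError",
    "DegenerateParametersError",
    "synchronization_factor",
    "classify_regime",
    "locking_phase",
    "locking_phase_range_deg",
    "precession_frequency",
    "drift_direction",
    "adler_solution",
    "adler_constant",
    "adler_solution_from_initial",
    "integrate_adler",
    "integrate_prc_model",
    "speed_constraint_detuning",
]


class InvalidRegimeError(ValueError):
    """Requested quantity is undefined in the current locking/pulling regime."""


class DegenerateParametersError(ValueError):
    """Both the detuning and the synchronization factor vanish."""


@dataclass(frozen=True)
class PhaseResponseCurve:
    """Sinusoidal infinitesimal PRC, ``z(phi) = z0 - z1 * sin(phi)``.

    Parameters are in radians of phase shift per unit input.
    """

    z0: float
    z1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.z0) and math.isfinite(self.z1)):
            raise ValueError("PRC components must be finite")
        if self.z1 < 0:
            raise ValueError("sinusoidal PRC amplitude z1 must be >= 0")

    def __call__(self, phi):
        return self.z0 - self.z1 * np.sin(phi)


@dataclass(frozen=True)
class PacemakerPerturbation:
    """Oscillatory forcing ``Q(t) = Q0 * cos(theta(t))`` with ``theta = omega_theta * t``."""

    q0: float
    omega_theta: float

    def __post_init__(self) -> None:
        if self.q0 < 0:
            raise ValueError("perturbation amplitude Q0 must be >= 0")
        if self.omega_theta <= 0:
            raise ValueError("pacemaker angular frequency must be > 0")

    def phase(self, t):
        return self.omega_theta * np.asarray(t, dtype=float)

    def __call__(self, t):
        return self.q0 * np.cos(self.phase(t))


@dataclass(frozen=True)
class PhaseReductionParams:
    """Parameters of the averaged (Adler) phase model.

    ``detuning`` is the intrinsic-minus-pacemaker angular frequency (rad/s)
    and ``sync_factor`` the entrainment strength A (rad/s).
    """

    detuning: float
    sync_factor: float
    intrinsic_omega: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.detuning):
            raise ValueError("detuning must be finite")
        if self.sync_factor < 0:
            raise ValueError("sync_factor must be >= 0")

    @classmethod
    def from_drive(
        cls,
        omega: float,
        pert: PacemakerPerturbation,
        prc: PhaseResponseCurve,
    ) -> "PhaseReductionParams":
        return cls(
            detuning=omega - pert.omega_theta,
            sync_factor=synchronization_factor(pert, prc),
            intrinsic_omega=omega,
        )


@dataclass(frozen=True)
class PhaseTrajectory:
    """Unwrapped phase-difference trajectory sampled on a strictly increasing time grid."""

    times: np.ndarray
    phase_diff: np.ndarray
    integration_constant: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing 1-d array")
        if np.asarray(self.phase_diff).shape != t.shape:
            raise ValueError("phase_diff must match times in shape")


@dataclass(frozen=True)
class SpeedConstraintInputs:
    """Inputs to the running-speed constraint on the detuning."""

    running_speed: float  # m/s
    field_radius: float  # m
    sync_factor: float  # rad/s

    def __post_init__(self) -> None:
        if self.running_speed < 0:
            raise ValueError("running speed must be >= 0")
        if self.field_radius <= 0:
            raise ValueError("field radius must be > 0")
        if self.sync_factor < 0:
            raise ValueError("sync_factor must be >= 0")


def synchronization_factor(pert: PacemakerPerturbation, prc: PhaseResponseCurve) -> float:
    """Entrainment strength ``A = Q0 * z1 / 2`` of the averaged model (rad/s)."""
    return 0.5 * pert.q0 * prc.z1


Regime = Literal["locking", "pulling", "boundary"]

#: relative tolerance on |detuning| - A for the saddle-node boundary
BOUNDARY_RTOL = 1e-9


def classify_regime(p: PhaseReductionParams, rtol: float = BOUNDARY_RTOL) -> Regime:
    """Classify the Adler dynamics as phase locking, frequency pulling, or boundary."""
    gap = abs(p.detuning) - p.sync_factor
    scale = max(abs(p.detuning), p.sync_factor)
    if abs(gap) <= rtol * scale or (scale == 0.0):
        return "boundary"
    return "locking" if gap < 0 else "pulling"


def locking_phase(p: PhaseReductionParams) -> float:
    """Stable locking phase ``arcsin(detuning / A)`` in (-pi/2, pi/2) (rad)."""
    if classify_regime(p) != "locking":
        raise InvalidRegimeError(
            f"locking phase undefined: |detuning|={abs(p.detuning)} >= A={p.sync_factor}"
        )
    return math.asin(p.detuning / p.sync_factor)


def locking_phase_range_deg() -> float:
    """Angular extent of stable locking phases over all admissible detunings (degrees).

    The stable phase ``arcsin(detuning/A)`` sweeps (-pi/2, pi/2) as the
    detuning sweeps (-A, A), i.e. exactly 180 degrees.
    """
    return math.degrees(math.asin(1.0) - math.asin(-1.0))


def precession_frequency(p: PhaseReductionParams) -> float:
    """Precession frequency ``sqrt(detuning^2 - A^2) / (2 pi)`` in Hz (pulling regime)."""
    if classify_regime(p) != "pulling":
        raise InvalidRegimeError(
            f"precession frequency undefined: |detuning|={abs(p.detuning)} <= A={p.sync_factor}"
        )
    return math.sqrt(p.detuning**2 - p.sync_factor**2) / (2.0 * math.pi)


def drift_direction(p: PhaseReductionParams) -> int:
    """Sign of the phase drift in the pulling regime: +1 precession, -1 regression."""
    if classify_regime(p) != "pulling":
        raise InvalidRegimeError("drift direction defined only in the pulling regime")
    return 1 if p.detuning > 0 else -1


def adler_constant(p: PhaseReductionParams, phi0: float) -> float:
    """Integration constant ``c`` such that ``adler_solution(p, c, 0.0) == phi0``.

    Requires a nonzero detuning (the closed form divides by it); ``phi0`` must
    not sit exactly on a fixed point of the locking regime.
    """
    dw, a = p.detuning, p.sync_factor
    if dw == 0.0:
        raise DegenerateParametersError("adler_constant requires a nonzero detuning")
    disc = dw * dw - a * a
    tan_half = math.tan(0.5 * _principal(phi0))
    if disc > 0:
        k = math.sqrt(disc)
        return (2.0 / k) * math.atan((a - dw * tan_half) / k)
    if disc < 0:
        k = math.sqrt(-disc)
        arg = (dw * tan_half - a) / k
        if abs(arg) >= 1.0:
            raise ValueError("phi0 lies on or beyond a fixed point of the locking regime")
        return (2.0 / k) * math.atanh(arg)
    raise InvalidRegimeError("closed form is degenerate exactly at the saddle-node boundary")


def _principal(phi: float) -> float:
    """Map an angle to (-pi, pi]."""
    out = math.remainder(phi, 2.0 * math.pi)
    return out if out != -math.pi else math.pi


def adler_solution(p: PhaseReductionParams, c: float, t) -> np.ndarray:
    """Closed-form Adler trajectory ``dphi(t)``, continuous/unwrapped, vectorized in ``t``.

    In the pulling regime the raw two-argument-arctangent expression is
    evaluated per branch of the inner tangent and stitched into a continuous
    trajectory by adding one signed full cycle per completed tangent branch,
    so that ``dphi(t + 1/f) = dphi(t) + 2*pi*sign(detuning)``.
    """
    t = np.asarray(t, dtype=float)
    dw, a = p.detuning, p.sync_factor
    if dw == 0.0 and a == 0.0:
        raise DegenerateParametersError("detuning and sync_factor are both zero")
    if a == 0.0:
        return dw * (t - c)
    if dw == 0.0:
        # pure locking with symmetric fixed points; use adler_solution_from_initial
        raise DegenerateParametersError(
            "closed form with an integration constant requires detuning != 0; "
            "use adler_solution_from_initial for detuning == 0"
        )
    disc = dw * dw - a * a
    if disc > 0:  # frequency pulling
        k = math.sqrt(disc)
        u = 0.5 * k * (c - t)
        branch = np.floor(u / math.pi + 0.5)
        raw = 2.0 * np.arctan((a - k * np.tan(u - branch * math.pi)) / dw)
        return raw - 2.0 * math.pi * np.sign(dw) * branch
    if disc < 0:  # phase locking: tan of imaginary argument -> tanh
        k = math.sqrt(-disc)
        return 2.0 * np.arctan((a + k * np.tanh(0.5 * k * (c - t))) / dw)
    raise InvalidRegimeError("closed form is degenerate exactly at the saddle-node boundary")


def adler_solution_from_initial(p: PhaseReductionParams, phi0: float, t) -> np.ndarray:
    """Closed-form Adler trajectory through ``dphi(0) = phi0``.

    Valid for any initial phase in either regime (the ``c``-parameterized
    branch of :func:`adler_solution` covers only part of the locking basin);
    in the locking regime the half-angle substitution ``u = tan(dphi/2)``
    turns the equation into a constant-coefficient Riccati equation whose
    solution interpolates between the two fixed points
    ``u± = (A ± sqrt(A^2 - dw^2)) / dw``.
    """
    t = np.asarray(t, dtype=float)
    dw, a = p.detuning, p.sync_factor
    if dw == 0.0 and a == 0.0:
        raise DegenerateParametersError("detuning and sync_factor are both zero")
    if a == 0.0:
        return phi0 + dw * t
    phi0p = _principal(phi0)
    anchor = phi0 - phi0p
    if dw == 0.0:
        # d(dphi)/dt = -A sin(dphi): tan(dphi/2) decays exponentially at rate A
        if abs(abs(phi0p) - math.pi) < 1e-15:
            return np.full_like(t, phi0, dtype=float)  # unstable fixed point
        tan_half = math.tan(0.5 * phi0p)
        return anchor + 2.0 * np.arctan(tan_half * np.exp(-a * t))
    disc = dw * dw - a * a
    if disc > 0:  # pulling: the c-branch covers the whole circle
        c = adler_constant(p, phi0)
        sol = adler_solution(p, c, t)
        offset = phi0 - float(adler_solution(p, c, 0.0))
        return sol + 2.0 * math.pi * round(offset / (2.0 * math.pi))
    if disc == 0:
        raise InvalidRegimeError("closed form is degenerate exactly at the saddle-node boundary")
    k = math.sqrt(-disc)
    u_stable = (a - k) / dw  # tan(lock/2)
    u_unstable = (a + k) / dw
    if abs(abs(phi0p) - math.pi) < 1e-12:
        # at the wrap point the flow moves in the direction of the detuning;
        # start infinitesimally inside the branch it flows through
        phi0p = math.copysign(math.pi - 1e-9, -dw)
        anchor = phi0 - phi0p
    u0 = math.tan(0.5 * phi0p)
    if u0 == u_unstable:
        return np.full_like(t, phi0, dtype=float)
    r0 = (u0 - u_unstable) / (u0 - u_stable)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        r = r0 * np.exp(k * t)
        u = np.where(np.isinf(r), u_stable, (u_unstable - r * u_stable) / (1.0 - r))
    raw = 2.0 * np.arctan(u)
    crossed = (r > 1.0) != (r0 > 1.0)
    return anchor + raw + 2.0 * math.pi * math.copysign(1.0, dw) * crossed


class StepTooLargeError(ValueError):
    """Integration step too coarse for the requested rates."""


def _check_step(dt: float, rate: float) -> None:
    if dt <= 0:
        raise StepTooLargeError("dt must be > 0")
    if dt * rate > 0.1:
        raise StepTooLargeError(
            f"dt={dt} too large for phase rate {rate:.3g} rad/s (dt*rate must be <= 0.1)"
        )


def integrate_adler(
    p: PhaseReductionParams, phi0: float, T: float, dt: float = 1e-4
) -> PhaseTrajectory:
    """Classical fixed-step RK4 integration of the Adler equation (numeric oracle)."""
    dw, a = p.detuning, p.sync_factor
    _check_step(dt, abs(dw) + a)
    n = int(round(T / dt))
    out = np.empty(n + 1)
    out[0] = phi = float(phi0)
    for i in range(n):
        k1 = dw - a * math.sin(phi)
        k2 = dw - a * math.sin(phi + 0.5 * dt * k1)
        k3 = dw - a * math.sin(phi + 0.5 * dt * k2)
        k4 = dw - a * math.sin(phi + dt * k3)
        phi += (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = phi
    times = np.arange(n + 1) * dt
    return PhaseTrajectory(times=times, phase_diff=out)


def integrate_prc_model(
    omega: float,
    prc: PhaseResponseCurve,
    pert: PacemakerPerturbation,
    phi0: float,
    T: float,
    dt: float = 1e-4,
) -> PhaseTrajectory:
    """RK4 integration of the un-averaged phase model ``dphi/dt = omega + z(phi) Q(t)``.

    Returns the phase difference ``phi(t) - omega_theta * t``; comparing it
    against :func:`integrate_adler` with ``A = Q0 z1 / 2`` validates the
    cycle-averaging step of the reduction.
    """
    z0, z1, q0, wth = prc.z0, prc.z1, pert.q0, pert.omega_theta
    rate = abs(omega) + q0 * (abs(z0) + z1)
    _check_step(dt, max(rate, wth))

    def f(phi: float, t: float) -> float:
        return omega + (z0 - z1 * math.sin(phi)) * q0 * math.cos(wth * t)

    n = int(round(T / dt))
    out = np.empty(n + 1)
    out[0] = phi = float(phi0)
    for i in range(n):
        t = i * dt
        k1 = f(phi, t)
        k2 = f(phi + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = f(phi + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = f(phi + dt * k3, t + dt)
        phi += (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = phi
    times = np.arange(n + 1) * dt
    return PhaseTrajectory(times=times, phase_diff=out - wth * times)


def speed_constraint_detuning(s: SpeedConstraintInputs) -> float:
    """Detuning required for precession frequency ``v / (2 R)`` at speed ``v``.

    Solves ``detuning^2 = A^2 + (pi v / R)^2``; with this detuning the
    pulling-regime precession frequency equals exactly ``v / (2 R)``.
    """
    return math.hypot(s.sync_factor, math.pi * s.running_speed / s.field_radius)
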