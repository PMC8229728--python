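"""Deterministic kinetics of a reader/writer nonself-recognition system.

Each allele at the recognition locus encodes a bifunctional reader/writer
protein.  The writer activity post-translationally modifies its own cognate
target; the reader activity generates a death signal in proportion to the
amount of *unmodified* cognate target it encounters.  In a cell whose nuclei
express every reader present, targets are written down fast enough that the
signal stays below the cell-death threshold; when cytoplasms of genetically
distinct mycelia mix, a foreign reader meets a large standing pool of
unmodified target and the signal spikes above the threshold.

Per allele i (R_i reader/writer, U_i unmodified target, S shared signal):

    dR_i/dt = alpha * [nucleus i present] - delta_R * R_i
    dU_i/dt = beta - k_write * R_i * U_i - delta_T * U_i
    dS/dt   = sum_i k_read * R_i * U_i - delta_S * S

Target production is constitutive in every cell for every allele's target;
writing removes target from the unmodified pool; reading generates signal
without consuming target.  Cell death is triggered the first time S reaches
the threshold theta and is absorbing.  A bookkeeping pool W_i (cumulative
modified target, dW_i/dt = k_write*R_i*U_i - delta_T*W_i) is integrated
alongside for mass accounting; it feeds back into nothing.

The contrast that matters biologically: *fertilization* (a migrating
nucleus arrives with no cytoplasm; its reader/writer accumulates gradually
from zero, writing down its target as it comes up) stays below threshold,
while *fusion* (bulk cytoplasmic mixing between established mycelia) shoots
above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "RWParams",
    "CytoplasmState",
    "Trajectory",
    "DeathMargin",
    "IntegrationError",
    "DEFAULT_THETA",
    "steady_state",
    "mix",
    "integrate",
    "simulate_heterokaryon_fusion",
    "simulate_fertilization",
    "death_margin",
    "calibrate_theta",
]


class IntegrationError(RuntimeError):
    """Raised when the fixed-step integrator goes unstable (negative pools)."""


# Death threshold shipped with the default kinetics: the geometric mean of
# the fertilization (A <- B) and heterokaryon-fusion (AB x AC) signal peaks
# under those kinetics, recomputed by calibrate_theta().
DEFAULT_THETA = 57.69433802995629


@dataclass(frozen=True)
class RWParams:
    """Kinetic constants of the reader/writer system.

    Units are arbitrary but consistent: concentrations in conc, time in
    time units, first-order rates in 1/time, bimolecular rates in
    1/(conc*time).  The reader activity ``k_read`` is five-fold the writing
    activity ``k_write`` by default.
    """

    alpha: float = 1.0      # reader/writer expression per present nucleus
    delta_R: float = 0.1    # reader/writer decay
    beta: float = 1.0       # constitutive target production
    delta_T: float = 0.05   # target decay
    k_write: float = 0.2    # writing (modification) rate constant
    k_read: float = 1.0     # reading (signal-generation) rate constant
    delta_S: float = 0.5    # signal decay
    theta: float = DEFAULT_THETA  # death threshold on the signal

    def __post_init__(self) -> None:
        for name in ("alpha", "delta_R", "beta", "delta_T", "k_write", "k_read", "delta_S"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.theta > 0:
            raise ValueError("theta must be positive")

    def to_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha, "delta_R": self.delta_R, "beta": self.beta,
            "delta_T": self.delta_T, "k_write": self.k_write,
            "k_read": self.k_read, "delta_S": self.delta_S, "theta": self.theta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RWParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class CytoplasmState:
    """Concentrations in one cell over a fixed allele universe."""

    alleles: tuple[str, ...]
    R: np.ndarray           # reader/writer per allele
    U: np.ndarray           # unmodified target per allele
    W: np.ndarray           # modified target per allele (bookkeeping)
    S: float = 0.0          # death signal
    alive: bool = True
    t: float = 0.0

    def __post_init__(self) -> None:
        self.alleles = tuple(self.alleles)
        self.R = np.asarray(self.R, dtype=float).copy()
        self.U = np.asarray(self.U, dtype=float).copy()
        self.W = np.asarray(self.W, dtype=float).copy()
        n = len(self.alleles)
        if not (self.R.shape == self.U.shape == self.W.shape == (n,)):
            raise ValueError("R, U, W must each have one entry per allele")
        if (self.R < 0).any() or (self.U < 0).any() or (self.W < 0).any() or self.S < 0:
            raise ValueError("concentrations must be non-negative")

    def index(self, allele: str) -> int:
        return self.alleles.index(allele)


@dataclass
class Trajectory:
    """Time course of a cytoplasm, with death metadata."""

    alleles: tuple[str, ...]
    times: np.ndarray
    R: np.ndarray           # shape (T, n)
    U: np.ndarray
    W: np.ndarray
    S: np.ndarray           # shape (T,)
    theta: float
    death_time: Optional[float] = None
    peak_signal: float = 0.0
    peak_time: float = 0.0

    @property
    def alive(self) -> bool:
        return self.death_time is None

    def state_at(self, i: int) -> CytoplasmState:
        dead = self.death_time is not None and self.times[i] >= self.death_time
        return CytoplasmState(
            alleles=self.alleles,
            R=self.R[i], U=self.U[i], W=self.W[i], S=float(self.S[i]),
            alive=not dead, t=float(self.times[i]),
        )

    @property
    def final_state(self) -> CytoplasmState:
        return self.state_at(len(self.times) - 1)


@dataclass
class DeathMargin:
    """Signal peaks of the two canonical scenarios relative to the threshold."""

    fertilization_peak: float
    fusion_peak: float
    theta: float

    @property
    def ordering_ok(self) -> bool:
        return self.fertilization_peak < self.theta < self.fusion_peak


# ---------------------------------------------------------------------------
# Closed-form equilibrium
# ---------------------------------------------------------------------------


def steady_state(
    present_alleles: Iterable[str],
    all_alleles: Iterable[str],
    params: RWParams,
) -> CytoplasmState:
    """Resident equilibrium of a cell whose nuclei are ``present_alleles``.

    For a present allele, R* = alpha/delta_R and
    U* = beta/(k_write*R* + delta_T); for an absent allele R* = 0 and the
    unmodified foreign-cognate target accumulates to U* = beta/delta_T.
    S* = sum_present k_read*R*_i*U*_i / delta_S.
    """
    universe = tuple(sorted(set(all_alleles)))
    present = set(present_alleles)
    if not present:
        raise ValueError("present allele set must be nonempty")
    if not present <= set(universe):
        raise ValueError("present alleles must lie in the allele universe")
    n = len(universe)
    R = np.zeros(n)
    U = np.zeros(n)
    W = np.zeros(n)
    for i, a in enumerate(universe):
        if a in present:
            Rs = params.alpha / params.delta_R if params.delta_R > 0 else 0.0
            R[i] = Rs
            denom = params.k_write * Rs + params.delta_T
            U[i] = params.beta / denom if denom > 0 else 0.0
            if params.delta_T > 0:
                W[i] = params.k_write * Rs * U[i] / params.delta_T
        else:
            U[i] = params.beta / params.delta_T if params.delta_T > 0 else 0.0
    S = float(np.sum(params.k_read * R * U) / params.delta_S) if params.delta_S > 0 else 0.0
    return CytoplasmState(alleles=universe, R=R, U=U, W=W, S=S)


def mix(s1: CytoplasmState, s2: CytoplasmState, phi: float) -> CytoplasmState:
    """Volume-weighted blend of two cytoplasms: phi of s1 plus (1-phi) of s2."""
    if not (0.0 <= phi <= 1.0):
        raise ValueError("phi must lie in [0, 1]")
    if s1.alleles != s2.alleles:
        raise ValueError("states must share the allele universe")
    if not (s1.alive and s2.alive):
        raise ValueError("cannot mix a dead cytoplasm")
    return CytoplasmState(
        alleles=s1.alleles,
        R=phi * s1.R + (1 - phi) * s2.R,
        U=phi * s1.U + (1 - phi) * s2.U,
        W=phi * s1.W + (1 - phi) * s2.W,
        S=phi * s1.S + (1 - phi) * s2.S,
        alive=True,
        t=0.0,
    )


# ---------------------------------------------------------------------------
# Fixed-step integrator
# ---------------------------------------------------------------------------


def integrate(
    state: CytoplasmState,
    present_nuclei: Iterable[str],
    params: RWParams,
    t_max: float = 200.0,
    dt: float = 0.01,
) -> Trajectory:
    """Fixed-step 4th-order (classical Runge-Kutta) integration.

    Death is recorded at the first step where S >= theta; the crossing time
    is localized by linear interpolation within that step, after which the
    state is frozen.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_max < dt:
        raise ValueError("t_max must be at least dt")
    universe = state.alleles
    present = np.array([a in set(present_nuclei) for a in universe], dtype=float)
    n = len(universe)
    a, dR, b, dT = params.alpha, params.delta_R, params.beta, params.delta_T
    kw, kr, dS = params.k_write, params.k_read, params.delta_S
    theta = params.theta

    def deriv(y: np.ndarray) -> np.ndarray:
        R = y[:n]
        U = y[n:2 * n]
        W = y[2 * n:3 * n]
        S = y[3 * n]
        flux = kw * R * U
        read = kr * R * U
        out = np.empty_like(y)
        out[:n] = a * present - dR * R
        out[n:2 * n] = b - flux - dT * U
        out[2 * n:3 * n] = flux - dT * W
        out[3 * n] = read.sum() - dS * S
        return out

    n_steps = int(round(t_max / dt))
    times = np.arange(n_steps + 1) * dt
    Y = np.empty((n_steps + 1, 3 * n + 1))
    y = np.concatenate([state.R, state.U, state.W, [state.S]])
    Y[0] = y
    death_time: Optional[float] = None
    if y[3 * n] >= theta:
        death_time = 0.0
    i_dead = 0 if death_time is not None else None
    for i in range(n_steps):
        if death_time is not None:
            Y[i + 1] = Y[i]
            continue
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y_new = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if (y_new[:3 * n] < -1e-9).any():
            raise IntegrationError(
                "negative concentrations encountered; reduce dt"
            )
        np.clip(y_new[:3 * n], 0.0, None, out=y_new[:3 * n])
        Y[i + 1] = y_new
        if y_new[3 * n] >= theta:
            s0, s1 = y[3 * n], y_new[3 * n]
            frac = (theta - s0) / (s1 - s0) if s1 > s0 else 1.0
            death_time = times[i] + frac * dt
            i_dead = i + 1
        y = y_new
    if i_dead is not None:
        Y[i_dead + 1:] = Y[i_dead]
    S_traj = Y[:, 3 * n]
    ipk = int(np.argmax(S_traj))
    return Trajectory(
        alleles=universe,
        times=times,
        R=Y[:, :n],
        U=Y[:, n:2 * n],
        W=Y[:, 2 * n:3 * n],
        S=S_traj,
        theta=theta,
        death_time=death_time,
        peak_signal=float(S_traj[ipk]),
        peak_time=float(times[ipk]),
    )


# ---------------------------------------------------------------------------
# Canonical scenarios
# ---------------------------------------------------------------------------


def simulate_heterokaryon_fusion(
    karyotype1: Iterable[str],
    karyotype2: Iterable[str],
    params: RWParams = RWParams(),
    phi: float = 0.5,
    t_max: float = 200.0,
    dt: float = 0.01,
) -> Trajectory:
    """Anastomosis with cytoplasmic mixing between two established mycelia.

    Both partners start at their resident steady states, their cytoplasms
    blend with volume fraction ``phi``, and the fusion cell carries the
    union of the two nuclear sets.
    """
    k1, k2 = set(karyotype1), set(karyotype2)
    universe = tuple(sorted(k1 | k2))
    s1 = steady_state(k1, universe, params)
    s2 = steady_state(k2, universe, params)
    fused = mix(s1, s2, phi)
    return integrate(fused, k1 | k2, params, t_max=t_max, dt=dt)


def simulate_fertilization(
    resident_alleles: Iterable[str],
    incoming_allele: str,
    params: RWParams = RWParams(),
    t_max: float = 200.0,
    dt: float = 0.01,
) -> Trajectory:
    """A migrating nucleus arrives in a resident cell with no cytoplasm.

    The resident steady state is the initial condition (no mixing); the
    incoming nucleus switches on expression of its reader/writer from zero,
    gradually writing down its cognate target.
    """
    resident = set(resident_alleles)
    if incoming_allele in resident:
        raise ValueError("incoming allele must differ from the residents")
    universe = tuple(sorted(resident | {incoming_allele}))
    s0 = steady_state(resident, universe, params)
    return integrate(s0, resident | {incoming_allele}, params, t_max=t_max, dt=dt)


def death_margin(
    params: RWParams = RWParams(),
    t_max: float = 200.0,
    dt: float = 0.01,
) -> DeathMargin:
    """Uncensored signal peaks of the canonical fertilization and fusion runs.

    Fertilization is A <- B; fusion is AB x AC.  Peaks are measured with the
    threshold disabled so that a lethal trajectory is not truncated at the
    crossing; the returned margin compares them with ``params.theta``.
    """
    free = replace(params, theta=math.inf)
    fert = simulate_fertilization({"A"}, "B", free, t_max=t_max, dt=dt)
    fus = simulate_heterokaryon_fusion({"A", "B"}, {"A", "C"}, free, t_max=t_max, dt=dt)
    return DeathMargin(
        fertilization_peak=fert.peak_signal,
        fusion_peak=fus.peak_signal,
        theta=params.theta,
    )


def calibrate_theta(
    params: RWParams = RWParams(),
    t_max: float = 200.0,
    dt: float = 0.01,
) -> float:
    """Death threshold as the geometric mean of the two canonical peaks.

    Placing theta at the geometric mean of the fertilization and fusion
    signal peaks guarantees fertilization survives and fusion dies with a
    symmetric (log-scale) margin on each side.
    """
    m = death_margin(params, t_max=t_max, dt=dt)
    return math.sqrt(m.fertilization_peak * m.fusion_peak)
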