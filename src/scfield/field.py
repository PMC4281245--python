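"""The 1-D dynamic neural field: geometry, kernel, dynamics, gain.

The field is a row of ``n`` leaky integrators spanning a few millimetres of
collicular tissue along the chord through target and distractor.  Lateral
connectivity is Mexican-hat shaped (short-range excitation, longer-range
inhibition, plus a global inhibitory constant):

    w(d) = a exp(-d^2 / 2 sigma_a^2) - b exp(-d^2 / 2 sigma_b^2) - c

Node dynamics are leaky integration of recurrent plus external input,

    tau du_i/dt = -u_i + (g/n) sum_j w_ij q_j + I_i,

integrated with forward Euler, and discharge follows the logistic gain
q = 1 / (1 + exp(-beta u)), so q is bounded in (0, 1) and the saccade
initiation threshold "80% of the maximum discharge" is q = 0.8.

``g`` is a dimensionless recurrent coupling.  The published parameter set
fixes the kernel amplitudes and the input strengths but not the
discretization convention of the recurrent sum; ``g`` makes that convention
explicit.  The default (4.25) puts the model in the regime where saccade
initiation is driven by the endogenous target signal (threshold crossings
~140-170 ms after target onset) rather than by the visual transient alone,
and where a transient-only distractor bubble decays instead of
self-sustaining.  See docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _dc_field

import numpy as np

__all__ = [
    "FieldGeometry", "KernelParams", "DynamicsParams", "FieldState",
    "build_kernel", "gain", "step", "settle", "NumericalError",
]


class NumericalError(RuntimeError):
    """The field state became non-finite."""


@dataclass(frozen=True)
class FieldGeometry:
    """Uniform node grid over a finite patch of tissue."""

    n_nodes: int = 1000
    extent_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be > 0")

    @property
    def spacing_mm(self) -> float:
        return self.extent_mm / (self.n_nodes - 1)

    @property
    def positions_mm(self) -> np.ndarray:
        return np.linspace(0.0, self.extent_mm, self.n_nodes)


@dataclass(frozen=True)
class KernelParams:
    """Mexican-hat lateral interaction parameters (small excitation zone)."""

    a: float = 144.0
    b: float = 24.0
    c: float = 9.0
    sigma_a_mm: float = 0.25
    sigma_b_mm: float = 1.5

    def __post_init__(self) -> None:
        if not (self.a > self.b >= 0 and self.c >= 0):
            raise ValueError("require a > b >= 0 and c >= 0")
        if not (0 < self.sigma_a_mm < self.sigma_b_mm):
            raise ValueError("require 0 < sigma_a < sigma_b")


@dataclass(frozen=True)
class DynamicsParams:
    """Leaky-integrator time constant, gain slope, Euler step and coupling.

    ``resting_level`` and ``gain_offset`` default to zero; they are exposed
    because the underlying model family sometimes carries a resting potential
    in the integrator or a threshold offset in the gain.
    """

    tau_ms: float = 10.0
    beta: float = 0.08
    dt_ms: float = 0.5
    coupling: float = 4.25
    resting_level: float = 0.0
    gain_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_ms <= 0 or self.beta <= 0 or self.coupling <= 0:
            raise ValueError("tau_ms, beta and coupling must be > 0")
        if not (0 < self.dt_ms <= self.tau_ms / 5.0):
            raise ValueError("require 0 < dt_ms <= tau_ms / 5")


@dataclass
class FieldState:
    """Per-node internal state and discharge at one time step."""

    t_ms: float
    u: np.ndarray
    q: np.ndarray = _dc_field(default=None)  # type: ignore[assignment]

    def copy(self) -> "FieldState":
        return FieldState(self.t_ms, self.u.copy(), self.q.copy())


def build_kernel(geom: FieldGeometry, kp: KernelParams = KernelParams()) -> np.ndarray:
    """Dense n x n lateral weight matrix over the node grid.

    Symmetric and translation invariant by construction (it depends only on
    |x_i - x_j|).  The field is a finite excised patch: no wraparound, the
    surround is simply truncated at the boundaries.
    """
    x = geom.positions_mm
    d2 = (x[:, None] - x[None, :]) ** 2
    return (
        kp.a * np.exp(-d2 / (2.0 * kp.sigma_a_mm**2))
        - kp.b * np.exp(-d2 / (2.0 * kp.sigma_b_mm**2))
        - kp.c
    )


def gain(u: np.ndarray | float, dp: DynamicsParams = DynamicsParams()):
    """Logistic discharge q = 1 / (1 + exp(-beta (u - offset))) in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-dp.beta * (np.asarray(u, dtype=float) - dp.gain_offset)))


def step(
    state: FieldState,
    total_input: np.ndarray,
    kernel: np.ndarray,
    dp: DynamicsParams,
) -> FieldState:
    """One forward-Euler update of the field.

    ``total_input`` is the external input vector I at the current time (see
    :func:`scfield.inputs.total_input`).  The recurrent drive is the
    mean-field sum (coupling/n) * W q.  Deterministic.
    """
    n = state.u.shape[0]
    q = gain(state.u, dp)
    rec = (dp.coupling / n) * (kernel @ q)
    du = (dp.dt_ms / dp.tau_ms) * (-state.u + dp.resting_level + rec + total_input)
    u_new = state.u + du
    if not np.all(np.isfinite(u_new)):
        raise NumericalError("field state became non-finite")
    return FieldState(state.t_ms + dp.dt_ms, u_new, gain(u_new, dp))


def settle(
    geom: FieldGeometry,
    kernel: np.ndarray,
    dp: DynamicsParams,
    tonic_input: np.ndarray,
    tol: float = 1e-8,
    max_ms: float = 500.0,
) -> FieldState:
    """Equilibrate the field under tonic inputs only.

    Runs the Euler dynamics from u = 0 until the largest per-step change in u
    drops below ``tol`` or ``max_ms`` of simulated time have elapsed; in the
    latter case a warning is emitted and the current state is returned.  The
    result is the pre-stimulus initial condition of a trial (nigral and
    fixation-zone inhibition are active from the beginning of a trial).
    """
    u = np.zeros(geom.n_nodes)
    state = FieldState(0.0, u, gain(u, dp))
    n_steps = int(round(max_ms / dp.dt_ms))
    for _ in range(n_steps):
        new = step(state, tonic_input, kernel, dp)
        delta = np.max(np.abs(new.u - state.u))
        state = new
        if delta < tol:
            state.t_ms = 0.0
            return state
    warnings.warn(
        f"settle() did not reach |du| < {tol} within {max_ms} ms; "
        "returning the state at the time cap",
        RuntimeWarning,
        stacklevel=2,
    )
    state.t_ms = 0.0
    return state
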