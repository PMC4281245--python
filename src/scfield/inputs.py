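"""External inputs to the field: visual, top-down, nigral and fixation-zone.

All excitatory inputs share a Gaussian spatial profile of width sigma_e.
The *exogenous* (visual) input arrives delta_exo = 70 ms after stimulus
onset at both the target and the distractor site and decays exponentially
with tau_exo = 10 ms.  The *endogenous* (top-down selection) input arrives
50 ms later (delta_endo = 120 ms), only at the target, is sustained, and is
switched off when the saccade initiation threshold is crossed.  The
substantia nigra pars reticulata contributes a constant inhibition of -16 to
every node.  The fixation zone at the rostral pole contributes a sustained
Gaussian inhibition centred at the chord midpoint between target and
distractor, of width sigma_fix = 0.7 mm and strength f (weak -0.5, strong
-1.8), active from the beginning of the trial and removed either when the
threshold is crossed (``at_threshold``) or at a fixed time relative to
target onset (``fixed_offset``; gap = -150 ms, overlap = +150 ms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

__all__ = [
    "StimulusConfig", "FixationConfig", "SNrConfig",
    "exogenous_input", "endogenous_input", "fixation_input", "total_input",
]


@dataclass(frozen=True)
class StimulusConfig:
    """Excitatory input geometry, strengths and timing."""

    target_pos_mm: float
    distractor_pos_mm: Optional[float] = None
    sigma_e_mm: float = 0.53
    e_exo: float = 30.0
    e_endo: float = 15.0
    delta_exo_ms: float = 70.0
    delta_endo_ms: float = 120.0
    tau_exo_ms: float = 10.0
    t_on_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.e_exo < 0 or self.e_endo < 0:
            raise ValueError("input strengths must be >= 0")
        if self.delta_endo_ms <= self.delta_exo_ms:
            raise ValueError("endogenous delay must exceed exogenous delay")
        if self.sigma_e_mm <= 0 or self.tau_exo_ms <= 0:
            raise ValueError("sigma_e_mm and tau_exo_ms must be > 0")


@dataclass(frozen=True)
class FixationConfig:
    """Fixation-zone inhibition.

    ``offset_mode='at_threshold'`` keeps the input active until the saccade
    initiation threshold is crossed.  ``offset_mode='fixed_offset'`` removes
    it at ``t_on + offset_ms`` (negative offset = gap, positive = overlap);
    it is additionally removed at threshold crossing if that happens first,
    since fixation neurons pause during saccades.
    """

    f: float = -0.5
    sigma_fix_mm: float = 0.7
    center_mm: float = 2.5
    offset_mode: Literal["at_threshold", "fixed_offset"] = "at_threshold"
    offset_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.f > 0:
            raise ValueError("fixation strength f must be <= 0")
        if self.sigma_fix_mm <= 0:
            raise ValueError("sigma_fix_mm must be > 0")
        if self.offset_mode not in ("at_threshold", "fixed_offset"):
            raise ValueError("offset_mode must be 'at_threshold' or 'fixed_offset'")


@dataclass(frozen=True)
class SNrConfig:
    """Constant nigral inhibition applied to every node."""

    level: float = -16.0

    def __post_init__(self) -> None:
        if self.level > 0:
            raise ValueError("SNr level must be <= 0")


def _gaussian(x_mm: np.ndarray | float, center_mm: float, sigma_mm: float):
    x = np.asarray(x_mm, dtype=float)
    return np.exp(-((x - center_mm) ** 2) / (2.0 * sigma_mm**2))


def exogenous_input(
    t_ms: float,
    x_mm: np.ndarray | float,
    sc: StimulusConfig,
    which: Literal["target", "distractor"] = "target",
):
    """Transient visual input at the target or distractor site.

    Zero before ``t_on + delta_exo``; thereafter
    ``e_exo * exp(-(t - t_on - delta_exo)/tau_exo)`` with the Gaussian
    spatial profile.
    """
    if which == "target":
        center = sc.target_pos_mm
    elif which == "distractor":
        if sc.distractor_pos_mm is None:
            raise ValueError("no distractor in this stimulus configuration")
        center = sc.distractor_pos_mm
    else:
        raise ValueError("which must be 'target' or 'distractor'")
    t_arr = sc.t_on_ms + sc.delta_exo_ms
    if t_ms < t_arr:
        return np.zeros_like(np.asarray(x_mm, dtype=float))
    amp = sc.e_exo * np.exp(-(t_ms - t_arr) / sc.tau_exo_ms)
    return amp * _gaussian(x_mm, center, sc.sigma_e_mm)


def endogenous_input(
    t_ms: float,
    x_mm: np.ndarray | float,
    sc: StimulusConfig,
    t_off_ms: Optional[float] = None,
):
    """Sustained top-down selection input, applied at the target only.

    Zero before ``t_on + delta_endo`` and (when ``t_off_ms`` is given) from
    the threshold-crossing time onwards.
    """
    t_arr = sc.t_on_ms + sc.delta_endo_ms
    if t_ms < t_arr or (t_off_ms is not None and t_ms >= t_off_ms):
        return np.zeros_like(np.asarray(x_mm, dtype=float))
    return sc.e_endo * _gaussian(x_mm, sc.target_pos_mm, sc.sigma_e_mm)


def fixation_input(
    t_ms: float,
    x_mm: np.ndarray | float,
    fc: FixationConfig,
    t_on_ms: float = 0.0,
    t_off_ms: Optional[float] = None,
):
    """Fixation-zone inhibition at time ``t_ms``.

    ``t_off_ms`` is the threshold-crossing time when already known (the input
    is always zero from that moment on).  In ``fixed_offset`` mode the input
    is additionally zero from ``t_on + offset_ms``.
    """
    active = True
    if t_off_ms is not None and t_ms >= t_off_ms:
        active = False
    if fc.offset_mode == "fixed_offset" and t_ms >= t_on_ms + fc.offset_ms:
        active = False
    if not active:
        return np.zeros_like(np.asarray(x_mm, dtype=float))
    return fc.f * _gaussian(x_mm, fc.center_mm, fc.sigma_fix_mm)


def total_input(
    t_ms: float,
    x_mm: np.ndarray,
    sc: Optional[StimulusConfig],
    fc: Optional[FixationConfig],
    snr: SNrConfig = SNrConfig(),
    t_off_ms: Optional[float] = None,
) -> np.ndarray:
    """Sum of all external inputs at each node at time ``t_ms``.

    ``sc=None`` gives the tonic (pre-stimulus) input, ``fc=None`` omits the
    fixation component.  ``t_off_ms`` is the threshold-crossing time, once
    known; it silences the endogenous and fixation inputs.
    """
    x = np.asarray(x_mm, dtype=float)
    out = np.full(x.shape, snr.level, dtype=float)
    if fc is not None:
        t_on = sc.t_on_ms if sc is not None else 0.0
        out = out + fixation_input(t_ms, x, fc, t_on, t_off_ms)
    if sc is not None:
        out = out + exogenous_input(t_ms, x, sc, "target")
        if sc.distractor_pos_mm is not None:
            out = out + exogenous_input(t_ms, x, sc, "distractor")
        out = out + endogenous_input(t_ms, x, sc, t_off_ms)
    return out
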