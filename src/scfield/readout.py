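"""Saccade initiation, direction decoding and the simulated deviation measure.

A simulated trial runs: equilibrate the field under tonic inputs (nigral plus
fixation inhibition), present the stimuli, integrate until some node's
discharge reaches the saccade initiation threshold (80% of the maximum
discharge level, i.e. q = 0.8), then decode the saccade direction from the
spatial discharge profile at the crossing time.

Decoding.  The default read-out is the discharge-weighted centroid of the
activity bubble containing the most active node, over nodes with q >= 0.4
(half the initiation threshold).  Restricting the centroid to the winning
bubble respects the bubble-competition account: when target and distractor
activity have merged into a single bubble the centroid lies between the two
stimulus sites, and when two bubbles coexist the saccade is read from the
winning one rather than from a meaningless average of both.  The global
masked centroid and a parabolic peak interpolation are available as
alternative modes, and the decode can optionally be averaged over a short
post-crossing window.

Deviation.  The decoded field position is converted to a visual direction
through the inverse collicular mapping along the trial's chord, and the
deviation is that direction minus a baseline direction, signed positive
toward the distractor.  The default baseline is the nominal target direction
(``baseline='nominal'``): on the 2-D motor map the drift a distractor-absent
saccade suffers from fixation-zone inhibition is radial, so it carries no
direction component, and the direction read off a distractor-absent trial is
the target direction itself.  Referencing to the decoded position of a 1-D
absent chord trial (``baseline='decoded'``) is also supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field, replace
from typing import Literal, Optional

import numpy as np

from scfield.field import (
    DynamicsParams,
    FieldGeometry,
    FieldState,
    KernelParams,
    build_kernel,
    gain,
    settle,
    step,
)
from scfield.inputs import FixationConfig, SNrConfig, StimulusConfig, total_input
from scfield.mapping import ChordGeometry

__all__ = [
    "TrialResult", "TrialConfig", "detect_initiation", "decode_position",
    "deviation", "run_trial", "DecodeFailureError", "UndefinedDeviationError",
]

THRESHOLD = 0.8          # saccade initiation: 80% of the maximum discharge
DECODE_MASK = 0.4        # half of the initiation threshold


class DecodeFailureError(RuntimeError):
    """No node above the decode mask at the decode time."""


class UndefinedDeviationError(RuntimeError):
    """Deviation requested for a timed-out trial."""


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    srt_ms: Optional[float]
    t_off_ms: Optional[float]
    decoded_pos_mm: Optional[float]
    timed_out: bool
    deviation_deg: Optional[float] = None


@dataclass(frozen=True)
class TrialConfig:
    """Everything needed to simulate one trial."""

    stimulus: StimulusConfig
    fixation: Optional[FixationConfig] = None
    snr: SNrConfig = SNrConfig()
    geometry: FieldGeometry = FieldGeometry()
    kernel: KernelParams = KernelParams()
    dynamics: DynamicsParams = DynamicsParams()
    threshold: float = THRESHOLD
    decode_mask: float = DECODE_MASK
    decode_mode: Literal["bubble", "global", "peak"] = "bubble"
    decode_window_ms: float = 0.0
    max_trial_ms: float = 600.0
    settle_max_ms: float = 500.0

    def pre_roll_ms(self) -> float:
        """Simulated time before target onset.

        Zero unless the fixation offset is time-locked before target onset
        (gap), in which case the trial starts 50 ms before the fixation
        change so its dynamics are captured.
        """
        if (
            self.fixation is not None
            and self.fixation.offset_mode == "fixed_offset"
            and self.fixation.offset_ms < 0
        ):
            return -self.fixation.offset_ms + 50.0
        return 0.0


def detect_initiation(
    q_trace: np.ndarray,
    dt_ms: float,
    threshold: float = THRESHOLD,
    t0_ms: float = 0.0,
) -> Optional[float]:
    """First time any node's discharge reaches threshold, or None.

    ``q_trace`` has shape (n_times, n_nodes); row i is the discharge at
    ``t0_ms + i * dt_ms``.
    """
    hits = np.flatnonzero((q_trace >= threshold).any(axis=1))
    if hits.size == 0:
        return None
    return t0_ms + float(hits[0]) * dt_ms


def decode_position(
    q: np.ndarray,
    positions_mm: np.ndarray,
    mask: float = DECODE_MASK,
    mode: Literal["bubble", "global", "peak"] = "bubble",
) -> float:
    """Decode the saccade locus from a discharge profile.

    ``bubble``: discharge-weighted centroid of the contiguous above-mask
    region containing the most active node.  ``global``: centroid over all
    above-mask nodes.  ``peak``: parabolic interpolation of the maximum.
    """
    above = q >= mask
    if not above.any():
        raise DecodeFailureError(f"no node above the decode mask {mask}")
    if mode == "global":
        w = q[above]
        return float(np.sum(positions_mm[above] * w) / np.sum(w))
    i = int(np.argmax(q))
    if mode == "peak":
        if 0 < i < q.size - 1:
            denom = q[i - 1] - 2 * q[i] + q[i + 1]
            off = 0.5 * (q[i - 1] - q[i + 1]) / denom if denom != 0 else 0.0
            dx = positions_mm[1] - positions_mm[0]
            return float(positions_mm[i] + off * dx)
        return float(positions_mm[i])
    if mode != "bubble":
        raise ValueError("decode mode must be 'bubble', 'global' or 'peak'")
    lo = i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i
    while hi < q.size - 1 and above[hi + 1]:
        hi += 1
    w = q[lo : hi + 1]
    return float(np.sum(positions_mm[lo : hi + 1] * w) / np.sum(w))


def run_trial(
    config: TrialConfig, initial_state: Optional[FieldState] = None
) -> TrialResult:
    """Simulate one trial: settle, stimulate, detect, decode.

    ``initial_state`` may carry a pre-computed settled state (it depends only
    on the tonic inputs, so it can be shared across trials of a sweep);
    otherwise :func:`scfield.field.settle` is run first.  Deterministic.
    """
    geom, dyn = config.geometry, config.dynamics
    x = geom.positions_mm
    kernel = build_kernel(geom, config.kernel)

    if initial_state is None:
        # tonic inputs: stimulus absent, fixation active (whatever its
        # offset mode, it is on from the beginning of the trial)
        fc_tonic = (
            replace(config.fixation, offset_mode="at_threshold")
            if config.fixation is not None
            else None
        )
        tonic = total_input(0.0, x, None, fc_tonic, config.snr)
        initial_state = settle(
            geom, kernel, dyn, tonic, max_ms=config.settle_max_ms
        )
    state = initial_state.copy()
    state.t_ms = -config.pre_roll_ms()

    sc = config.stimulus
    t_off: Optional[float] = None
    decoded: Optional[float] = None
    window_sum, window_n = 0.0, 0
    t_end = sc.t_on_ms + config.max_trial_ms
    while state.t_ms < t_end:
        I = total_input(state.t_ms, x, sc, config.fixation, config.snr, t_off)
        state = step(state, I, kernel, dyn)
        if t_off is None and np.max(state.q) >= config.threshold:
            t_off = state.t_ms
            decoded = decode_position(
                state.q, x, config.decode_mask, config.decode_mode
            )
            if config.decode_window_ms <= 0:
                break
            window_sum, window_n = decoded, 1
        elif t_off is not None:
            window_sum += decode_position(
                state.q, x, config.decode_mask, config.decode_mode
            )
            window_n += 1
            if state.t_ms >= t_off + config.decode_window_ms:
                decoded = window_sum / window_n
                break
    if t_off is None:
        return TrialResult(None, None, None, timed_out=True)
    if window_n:
        decoded = window_sum / window_n
    return TrialResult(t_off - sc.t_on_ms, t_off, decoded, timed_out=False)


def deviation(
    present: TrialResult,
    absent: TrialResult,
    chord: ChordGeometry,
    baseline: Literal["nominal", "decoded"] = "nominal",
) -> float:
    """Signed directional deviation (deg), positive toward the distractor.

    Decoded field positions are converted to visual polar angles through the
    inverse mapping along the chord.  With ``baseline='nominal'`` the
    reference direction is the nominal target direction; with
    ``baseline='decoded'`` it is the decoded direction of the
    distractor-absent trial.  Either trial having timed out raises
    :class:`UndefinedDeviationError`.
    """
    if present.timed_out or absent.timed_out:
        raise UndefinedDeviationError("deviation undefined for timed-out trials")
    phi_p = chord.angle_at(present.decoded_pos_mm)
    if baseline == "decoded":
        ref = chord.angle_at(absent.decoded_pos_mm)
    elif baseline == "nominal":
        ref = chord.target_angle_deg
    else:
        raise ValueError("baseline must be 'nominal' or 'decoded'")
    return chord.toward_sign(phi_p - ref)
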