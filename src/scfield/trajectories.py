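"""Behavioural saccade-trajectory metrics, exclusion rules and fixtures.

Coordinates are screen degrees with the origin at the fixation cross and y
positive upward.  Directions are measured counter-clockwise from the
positive x axis, in degrees.  The ``distractor_side`` of a trial is the side
of the saccade's nominal direction the distractor lies on: ``"left"`` means
counter-clockwise of the target direction, ``"right"`` clockwise (as seen on
the screen), ``"none"`` for distractor-absent trials.  Deviation measures
are signed positive toward the distractor.

Two deviation measures are provided:

* *initial direction* -- the direction of the vector from the saccade start
  to an early sample, either a fixed time into the saccade (e.g. 10 ms) or a
  fixed fraction of its duration (e.g. 20%);
* *maximum curvature* -- the largest perpendicular distance of the
  intermediate samples to the straight start-to-end path, optionally divided
  by the saccade amplitude.

:func:`apply_filters` reproduces the trial-exclusion cascades of the two
behavioural experiments (response-time cutoffs, direction and start-point
tolerances, and a per-cell 2.35-standard-deviation outlier rule).

:func:`generate_fixture` builds synthetic 500-Hz saccades with a prescribed
initial-direction offset and maximum curvature, plus Gaussian sample noise;
it is the test bed for the metrics (the original raw eye-tracking data are
not public).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field
from typing import Dict, List, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "SaccadeTrajectory", "FilterCriteria", "initial_direction",
    "max_curvature", "reference_to_baseline", "apply_filters",
    "generate_fixture", "trajectories_to_frames", "frames_to_trajectories",
    "TooShortError", "ZeroAmplitudeError", "MissingBaselineError",
]

SAMPLE_INTERVAL_MS = 2.0  # 500 Hz


class TooShortError(ValueError):
    """Saccade shorter than the initial-direction rule's offset."""


class ZeroAmplitudeError(ValueError):
    """Degenerate saccade with coincident start and end points."""


class MissingBaselineError(ValueError):
    """No distractor-absent trials available in the matching cell."""


@dataclass
class SaccadeTrajectory:
    """Timestamped gaze samples of one trial with a marked saccade.

    ``t_ms, x_deg, y_deg`` are equal-length arrays sampled at a fixed rate;
    ``start_index``/``end_index`` delimit the saccade (inclusive);
    ``target_dir_deg`` is the nominal target direction and
    ``distractor_side`` the side the distractor was on.
    """

    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    start_index: int
    end_index: int
    target_dir_deg: float
    distractor_side: Literal["left", "right", "none"] = "none"
    trial_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        if not (len(self.t_ms) == len(self.x_deg) == len(self.y_deg)):
            raise ValueError("t, x, y must have equal length")
        if self.end_index - self.start_index < 2:
            raise ValueError("need at least 3 samples between start and end")
        dt = np.diff(self.t_ms)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.allclose(dt, dt[0]):
            raise ValueError("sampling interval must be constant")
        if self.distractor_side not in ("left", "right", "none"):
            raise ValueError("distractor_side must be left, right or none")

    @property
    def amplitude_deg(self) -> float:
        return float(
            math.hypot(
                self.x_deg[self.end_index] - self.x_deg[self.start_index],
                self.y_deg[self.end_index] - self.y_deg[self.start_index],
            )
        )

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[self.end_index] - self.t_ms[self.start_index])


@dataclass(frozen=True)
class FilterCriteria:
    """Cutoffs of the trial-exclusion cascade."""

    srt_min_ms: float = 80.0
    srt_max_ms: float = 500.0
    start_tolerance_deg: float = 1.5
    direction_tolerance_deg: float = 30.0
    outlier_sd: float = 2.35

    def __post_init__(self) -> None:
        if self.srt_min_ms >= self.srt_max_ms:
            raise ValueError("srt_min_ms must be < srt_max_ms")
        if min(self.start_tolerance_deg, self.direction_tolerance_deg,
               self.outlier_sd) <= 0:
            raise ValueError("tolerances must be > 0")


#: Cutoffs used by the two behavioural experiments.
EXPERIMENT_CRITERIA = {
    1: FilterCriteria(80.0, 500.0, 1.5, 30.0, 2.35),
    2: FilterCriteria(80.0, 550.0, 2.0, 30.0, 2.35),
}


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def _toward_sign(ccw_value: float, side: str) -> float:
    """Counter-clockwise-positive value -> toward-distractor-positive."""
    if side == "left":
        return ccw_value
    if side == "right":
        return -ccw_value
    return ccw_value


def initial_direction(
    tr: SaccadeTrajectory,
    rule: Union[Tuple[str, float], str] = ("at_time", 10.0),
) -> float:
    """Initial saccade direction (deg, CCW from +x) under a sampling rule.

    ``rule`` is ``("at_time", ms)`` -- the sample nearest ``ms`` after
    saccade onset -- or ``("at_fraction", p)`` -- the sample nearest a
    fraction ``p`` of the saccade duration.  The direction is the angle of
    the vector from the start sample to the rule's sample.
    """
    kind, value = rule
    t0 = tr.t_ms[tr.start_index]
    if kind == "at_time":
        t_probe = t0 + value
    elif kind == "at_fraction":
        if not (0.0 < value < 1.0):
            raise ValueError("fraction must be in (0, 1)")
        t_probe = t0 + value * tr.duration_ms
    else:
        raise ValueError("rule kind must be 'at_time' or 'at_fraction'")
    if t_probe > tr.t_ms[tr.end_index] + 1e-9:
        raise TooShortError(
            f"saccade of {tr.duration_ms:.1f} ms too short for the rule {rule}"
        )
    idx = tr.start_index + int(
        round((t_probe - t0) / (tr.t_ms[1] - tr.t_ms[0]))
    )
    idx = min(idx, tr.end_index)
    if idx <= tr.start_index:
        raise TooShortError("rule selects the start sample itself")
    dx = tr.x_deg[idx] - tr.x_deg[tr.start_index]
    dy = tr.y_deg[idx] - tr.y_deg[tr.start_index]
    return math.degrees(math.atan2(dy, dx))


def max_curvature(tr: SaccadeTrajectory, normalize: bool = False) -> float:
    """Signed maximum perpendicular deviation from the straight path.

    The maximum distance of the intermediate samples to the segment from the
    saccade start to its endpoint; positive when the extreme point lies on
    the distractor's side.  Ties are resolved to the earliest sample.  With
    ``normalize=True`` the distance is divided by the saccade amplitude
    (dimensionless).
    """
    i0, i1 = tr.start_index, tr.end_index
    p0 = np.array([tr.x_deg[i0], tr.y_deg[i0]])
    p1 = np.array([tr.x_deg[i1], tr.y_deg[i1]])
    seg = p1 - p0
    L = float(np.hypot(*seg))
    if L == 0.0:
        raise ZeroAmplitudeError("start and end points coincide")
    pts = np.stack(
        [tr.x_deg[i0 + 1 : i1], tr.y_deg[i0 + 1 : i1]], axis=1
    ) - p0
    # signed perpendicular distance, CCW (left of travel) positive
    cross = (seg[0] * pts[:, 1] - seg[1] * pts[:, 0]) / L
    k = int(np.argmax(np.abs(cross)))  # argmax takes the first maximum
    value = _toward_sign(float(cross[k]), tr.distractor_side)
    return value / L if normalize else value


def reference_to_baseline(
    values: Sequence[float], baseline_values: Sequence[float]
) -> np.ndarray:
    """Subtract the mean of the distractor-absent cell from each value.

    Both inputs are in the toward-distractor-positive convention; an empty
    baseline raises :class:`MissingBaselineError`.
    """
    baseline = np.asarray(baseline_values, dtype=float)
    if baseline.size == 0:
        raise MissingBaselineError("empty distractor-absent baseline cell")
    return np.asarray(values, dtype=float) - baseline.mean()


def _loo_outlier(values: np.ndarray, n_sd: float) -> np.ndarray:
    """Leave-one-out SD-outlier mask (True = outlier).

    Each value is compared against the mean and standard deviation of the
    *other* values in its cell; with fewer than 3 values nothing is flagged.
    """
    n = values.size
    out = np.zeros(n, dtype=bool)
    if n < 3:
        return out
    s, s2 = values.sum(), (values**2).sum()
    for i in range(n):
        m = (s - values[i]) / (n - 1)
        var = ((s2 - values[i] ** 2) - (n - 1) * m * m) / (n - 2)
        sd = math.sqrt(max(var, 0.0))
        out[i] = abs(values[i] - m) > n_sd * sd
    return out


def apply_filters(
    records: pd.DataFrame,
    fc: Optional[FilterCriteria] = None,
    experiment: int = 1,
    recursive: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply a trial-exclusion cascade; return kept records and counts.

    ``records`` needs columns ``srt_ms``, ``start_offset_deg`` (distance of
    the saccade start point from the fixation cross) and, for experiment 1,
    ``initial_dir_deg`` and ``target_dir_deg``; for experiment 2 a
    ``dir_dev_deg`` column (directional deviation from the target direction)
    and a ``cell`` column identifying the condition cell for the outlier
    rule.  Rules are applied in order; every record receives all the
    exclusion flags it triggers (in an ``exclusion_flags`` column), and the
    SD-outlier rule operates per cell on the records surviving the earlier
    rules, judging each record against the mean and standard deviation of
    the *other* survivors in its cell.  By default that rule is repeated
    until no further trial is excluded, making the surviving set a fixed
    point (the cascade is then idempotent); ``recursive=False`` applies it
    once.  Returns the surviving records plus per-rule counts.
    """
    if fc is None:
        fc = EXPERIMENT_CRITERIA[experiment]
    rec = records.copy()
    flags: List[List[str]] = [[] for _ in range(len(rec))]
    counts: Dict[str, int] = {}

    srt = rec["srt_ms"].to_numpy(dtype=float)
    bad_srt = (srt < fc.srt_min_ms) | (srt > fc.srt_max_ms)
    counts["srt"] = int(bad_srt.sum())
    for i in np.flatnonzero(bad_srt):
        flags[i].append("srt")

    if experiment == 1:
        diff = np.array(
            [
                abs(_wrap_deg(a - b))
                for a, b in zip(
                    rec["initial_dir_deg"].to_numpy(dtype=float),
                    rec["target_dir_deg"].to_numpy(dtype=float),
                )
            ]
        )
        bad_dir = diff > fc.direction_tolerance_deg
        counts["direction"] = int(bad_dir.sum())
        for i in np.flatnonzero(bad_dir):
            flags[i].append("direction")

    start = rec["start_offset_deg"].to_numpy(dtype=float)
    bad_start = start > fc.start_tolerance_deg
    counts["start"] = int(bad_start.sum())
    for i in np.flatnonzero(bad_start):
        flags[i].append("start")

    if experiment == 2:
        excluded = np.array([len(f) > 0 for f in flags])
        n_out = 0
        while True:
            new = 0
            for _, cell_idx in rec.groupby("cell").groups.items():
                pos = rec.index.get_indexer(cell_idx)
                alive = [i for i in pos if not excluded[i]]
                if len(alive) < 3:
                    continue
                vals = rec["dir_dev_deg"].to_numpy(dtype=float)[alive]
                mask = _loo_outlier(vals, fc.outlier_sd)
                for j, is_out in zip(alive, mask):
                    if is_out:
                        flags[j].append("outlier")
                        excluded[j] = True
                        new += 1
            n_out += new
            if not (recursive and new):
                break
        counts["outlier"] = n_out

    rec["exclusion_flags"] = [";".join(f) for f in flags]
    kept = rec[[len(f) == 0 for f in flags]].copy()
    counts["kept"] = len(kept)
    return kept, counts


def _perp_profile(
    s: np.ndarray, L: float, deviation_deg: float, curvature_deg: float,
    s_linear: float = 0.3, s_peak: float = 0.65,
) -> np.ndarray:
    """Perpendicular offset profile along the normalized path coordinate.

    Piecewise: a linear ramp of slope ``L * tan(deviation)`` up to
    ``s_linear`` (so the direction from the start to any early sample is
    offset by exactly ``deviation_deg``), a cubic Hermite rise to the
    curvature extremum at ``s_peak``, and a smooth fall back to zero.  The
    maximum |offset| equals |curvature_deg| whenever the curvature dominates
    the ramp end point (inconsistent parameter signs are allowed; then the
    measured maximum follows the larger excursion).
    """
    k = L * math.tan(math.radians(deviation_deg))
    p = np.empty_like(s)
    p0 = k * s_linear

    m1 = s <= s_linear
    p[m1] = k * s[m1]

    m2 = (s > s_linear) & (s <= s_peak)
    tt = (s[m2] - s_linear) / (s_peak - s_linear)
    h00 = 2 * tt**3 - 3 * tt**2 + 1
    h10 = tt**3 - 2 * tt**2 + tt
    h01 = -2 * tt**3 + 3 * tt**2
    p[m2] = h00 * p0 + h10 * k * (s_peak - s_linear) + h01 * curvature_deg

    m3 = s > s_peak
    tt = (s[m3] - s_peak) / (1.0 - s_peak)
    p[m3] = curvature_deg * (2 * tt**3 - 3 * tt**2 + 1)
    return p


def generate_fixture(
    n_trials: int,
    deviation_deg: float = 5.0,
    curvature_deg: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    target_dir_deg: float = 75.0,
    amplitude_deg: float = 10.0,
    duration_ms: float = 40.0,
    distractor_side: Literal["left", "right"] = "left",
    pre_samples: int = 5,
    post_samples: int = 5,
) -> List[SaccadeTrajectory]:
    """Synthetic 500-Hz saccades with known deviation and curvature.

    Saccades run from the fixation cross to a target ``amplitude_deg``
    eccentric in direction ``target_dir_deg``, as arcs whose initial
    direction is offset toward-positive by ``deviation_deg`` and whose
    maximum perpendicular excursion is ``curvature_deg`` (both in the
    toward-distractor-positive convention of ``distractor_side``).  The
    path is traversed at constant speed; independent Gaussian noise of
    ``noise_sd`` deg is added to every sample.  Reproducible per ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_sacc = int(round(duration_ms / SAMPLE_INTERVAL_MS)) + 1
    s = np.linspace(0.0, 1.0, n_sacc)
    sign = 1.0 if distractor_side == "left" else -1.0
    perp = _perp_profile(s, amplitude_deg, sign * deviation_deg,
                         sign * curvature_deg)

    th = math.radians(target_dir_deg)
    u_hat = np.array([math.cos(th), math.sin(th)])
    n_hat = np.array([-math.sin(th), math.cos(th)])  # CCW normal

    trajectories = []
    for trial in range(n_trials):
        along = s * amplitude_deg
        pts = along[:, None] * u_hat[None, :] + perp[:, None] * n_hat[None, :]
        xy = np.concatenate(
            [
                np.repeat(pts[:1], pre_samples, axis=0),
                pts,
                np.repeat(pts[-1:], post_samples, axis=0),
            ]
        )
        xy = xy + rng.normal(0.0, noise_sd, size=xy.shape)
        n_total = len(xy)
        t = np.arange(n_total) * SAMPLE_INTERVAL_MS
        trajectories.append(
            SaccadeTrajectory(
                t_ms=t,
                x_deg=xy[:, 0],
                y_deg=xy[:, 1],
                start_index=pre_samples,
                end_index=pre_samples + n_sacc - 1,
                target_dir_deg=target_dir_deg,
                distractor_side=distractor_side,
                trial_id=trial,
            )
        )
    return trajectories


def trajectories_to_frames(
    trajectories: Sequence[SaccadeTrajectory],
    condition: str = "fixture",
    separation_deg: float = float("nan"),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize trajectories to the tabular sample + metadata format.

    Samples: ``trial_id, t_ms, x_deg, y_deg``.  Metadata: ``trial_id,
    condition, separation_deg, distractor_side, target_dir_deg,
    saccade_start_ms, saccade_end_ms``.
    """
    sample_rows, meta_rows = [], []
    for i, tr in enumerate(trajectories):
        tid = tr.trial_id if tr.trial_id is not None else i
        sample_rows.append(
            pd.DataFrame(
                {"trial_id": tid, "t_ms": tr.t_ms,
                 "x_deg": tr.x_deg, "y_deg": tr.y_deg}
            )
        )
        meta_rows.append(
            {
                "trial_id": tid,
                "condition": condition,
                "separation_deg": separation_deg,
                "distractor_side": tr.distractor_side,
                "target_dir_deg": tr.target_dir_deg,
                "saccade_start_ms": tr.t_ms[tr.start_index],
                "saccade_end_ms": tr.t_ms[tr.end_index],
            }
        )
    return pd.concat(sample_rows, ignore_index=True), pd.DataFrame(meta_rows)


def frames_to_trajectories(
    samples: pd.DataFrame, meta: pd.DataFrame
) -> List[SaccadeTrajectory]:
    """Rebuild :class:`SaccadeTrajectory` objects from the tabular format."""
    out = []
    for _, m in meta.iterrows():
        sub = samples[samples["trial_id"] == m["trial_id"]].sort_values("t_ms")
        t = sub["t_ms"].to_numpy(dtype=float)
        start = int(np.argmin(np.abs(t - m["saccade_start_ms"])))
        end = int(np.argmin(np.abs(t - m["saccade_end_ms"])))
        out.append(
            SaccadeTrajectory(
                t_ms=t,
                x_deg=sub["x_deg"].to_numpy(dtype=float),
                y_deg=sub["y_deg"].to_numpy(dtype=float),
                start_index=start,
                end_index=end,
                target_dir_deg=float(m["target_dir_deg"]),
                distractor_side=str(m["distractor_side"]),
                trial_id=int(m["trial_id"]),
            )
        )
    return out
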