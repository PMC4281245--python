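"""Separation x fixation-strength sweeps and transition-point estimation.

:func:`run_sweep` reproduces the simulation experiment behind the deviation
curves: for every combination of target-distractor separation and fixation
condition it simulates a distractor-present and a matched distractor-absent
trial on the tissue chord through the two stimuli, and records the decoded
directional deviation together with both saccadic response times.

:func:`find_transition` estimates the separation at which the deviation curve
changes sign from toward (positive) to away (negative), by linear
interpolation between adjacent grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field, replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from scfield.field import (
    DynamicsParams,
    FieldGeometry,
    KernelParams,
    build_kernel,
    settle,
)
from scfield.inputs import FixationConfig, SNrConfig, StimulusConfig, total_input
from scfield.mapping import ChordGeometry, MappingParams, DEFAULT_MAPPING
from scfield.readout import TrialConfig, deviation, run_trial

__all__ = ["SweepSpec", "run_sweep", "find_transition",
           "DEFAULT_SEPARATIONS", "FIXATION_CONDITIONS"]

DEFAULT_SEPARATIONS = (15, 30, 45, 60, 75, 90, 105, 120, 135, 150)

#: Named fixation conditions: sustained weak/strong inhibition, and the
#: gap/overlap timing variants of the behavioural paradigm.
FIXATION_CONDITIONS: Dict[str, FixationConfig] = {
    "weak": FixationConfig(f=-0.5),
    "strong": FixationConfig(f=-1.8),
    "gap": FixationConfig(f=-1.8, offset_mode="fixed_offset", offset_ms=-150.0),
    "overlap": FixationConfig(f=-1.8, offset_mode="fixed_offset", offset_ms=150.0),
}

SWEEP_COLUMNS = [
    "separation_deg", "condition", "fixation_f", "deviation_deg",
    "srt_ms", "srt_absent_ms", "timed_out",
]


@dataclass(frozen=True)
class SweepSpec:
    """A sweep over separations and fixation conditions."""

    separations_deg: Sequence[float] = DEFAULT_SEPARATIONS
    conditions: Sequence[str] = ("weak", "strong")
    eccentricity_deg: float = 10.0
    baseline: str = "nominal"
    geometry: FieldGeometry = FieldGeometry()
    kernel: KernelParams = KernelParams()
    dynamics: DynamicsParams = DynamicsParams()
    snr: SNrConfig = SNrConfig()
    mapping: MappingParams = DEFAULT_MAPPING
    decode_mode: str = "bubble"
    fixation_overrides: Optional[Dict[str, FixationConfig]] = None

    def __post_init__(self) -> None:
        if len(self.separations_deg) == 0 or len(self.conditions) == 0:
            raise ValueError("separations and conditions must be non-empty")
        for s in self.separations_deg:
            if not (0.0 < s < 180.0):
                raise ValueError(f"separation {s} outside (0, 180) deg")

    def fixation_for(self, condition: str) -> FixationConfig:
        table = dict(FIXATION_CONDITIONS)
        if self.fixation_overrides:
            table.update(self.fixation_overrides)
        try:
            return table[condition]
        except KeyError:
            raise ValueError(f"unknown fixation condition {condition!r}") from None


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the sweep and return one row per separation x condition cell.

    Columns: ``separation_deg, condition, fixation_f, deviation_deg, srt_ms,
    srt_absent_ms, timed_out``.  Deviations are signed positive toward the
    distractor.  A timed-out cell keeps its row with NaN measures and
    ``timed_out=True``; the sweep continues.  Deterministic: the settled
    initial state depends only on the fixation condition and is computed once
    per condition.
    """
    rows = []
    x = spec.geometry.positions_mm
    kernel = build_kernel(spec.geometry, spec.kernel)
    center = spec.geometry.extent_mm / 2.0

    for condition in spec.conditions:
        fc0 = spec.fixation_for(condition)
        fc = replace(fc0, center_mm=center)
        tonic = total_input(
            0.0, x, None, replace(fc, offset_mode="at_threshold"), spec.snr
        )
        settled = settle(spec.geometry, kernel, spec.dynamics, tonic)

        for sep in spec.separations_deg:
            chord = ChordGeometry(
                spec.eccentricity_deg, sep, spec.geometry.extent_mm,
                params=spec.mapping,
            )
            stim_present = StimulusConfig(
                target_pos_mm=chord.target_pos_mm,
                distractor_pos_mm=chord.distractor_pos_mm,
            )
            stim_absent = replace(stim_present, distractor_pos_mm=None)
            common = dict(
                fixation=fc, snr=spec.snr, geometry=spec.geometry,
                kernel=spec.kernel, dynamics=spec.dynamics,
                decode_mode=spec.decode_mode,
            )
            present = run_trial(
                TrialConfig(stimulus=stim_present, **common), settled
            )
            absent = run_trial(
                TrialConfig(stimulus=stim_absent, **common), settled
            )
            timed_out = present.timed_out or absent.timed_out
            dev = (
                deviation(present, absent, chord, baseline=spec.baseline)
                if not timed_out
                else np.nan
            )
            rows.append(
                {
                    "separation_deg": sep,
                    "condition": condition,
                    "fixation_f": fc.f,
                    "deviation_deg": dev,
                    "srt_ms": present.srt_ms if not present.timed_out else np.nan,
                    "srt_absent_ms": absent.srt_ms if not absent.timed_out else np.nan,
                    "timed_out": timed_out,
                }
            )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def find_transition(curve: pd.DataFrame, condition: str) -> Optional[float]:
    """Separation (deg) of the first toward-to-away sign change, or None.

    Scans the condition's deviation-versus-separation curve in increasing
    separation order and linearly interpolates the zero crossing of the first
    positive-to-negative transition.  Returns None when the curve never
    changes sign that way.
    """
    sub = (
        curve[curve["condition"] == condition]
        .dropna(subset=["deviation_deg"])
        .sort_values("separation_deg")
    )
    seps = sub["separation_deg"].to_numpy(dtype=float)
    devs = sub["deviation_deg"].to_numpy(dtype=float)
    for (s1, d1), (s2, d2) in zip(zip(seps, devs), zip(seps[1:], devs[1:])):
        if d1 > 0 and d2 < 0:
            return float(s1 + d1 * (s2 - s1) / (d1 - d2))
    return None
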