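"""Parametric experiment designs: PRF comparison, amplitude-duration
threshold mapping, and strength-duration summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .models import LEUSSequenceSpec, ResponseModel

DEFAULT_PA_LEVELS = (2.5e6, 4.0e6, 5.2e6, 6.6e6, 7.1e6, 7.3e6)
DEFAULT_NCYCLES_LEVELS = (175, 350, 525, 800, 975, 1150)


class PulseTiming(NamedTuple):
    pulse_duration_s: float
    pulse_period_s: float
    burst_duration_s: float


def pulse_timing(spec: LEUSSequenceSpec) -> PulseTiming:
    """Derived timing of a pulsed sequence: duration = N_cycles/f,
    period = 1/PRF, burst = (N_pulses - 1) x period + duration."""
    return PulseTiming(
        pulse_duration_s=spec.pulse_duration_s,
        pulse_period_s=spec.pulse_period_s,
        burst_duration_s=spec.burst_duration_s,
    )


@dataclass(frozen=True)
class ParametricDesign:
    """Factor grid and administration plan for a parametric trial."""

    prf_levels_hz: tuple[float, ...] = (125.0, 25.0)
    pa_levels_pa: tuple[float, ...] = DEFAULT_PA_LEVELS
    n_cycles_levels: tuple[int, ...] = DEFAULT_NCYCLES_LEVELS
    instances_per_condition: int = 20
    min_null_attempts: int = 5
    seed: int = 0
    base_leus: LEUSSequenceSpec = field(default_factory=LEUSSequenceSpec)

    def __post_init__(self) -> None:
        for name, levels in (
            ("prf_levels_hz", self.prf_levels_hz),
            ("pa_levels_pa", self.pa_levels_pa),
            ("n_cycles_levels", self.n_cycles_levels),
        ):
            if any(not (math.isfinite(v) and v > 0) for v in levels):
                raise ValueError(f"all {name} must be positive and finite")
        if self.instances_per_condition < 1:
            raise ValueError("instances_per_condition must be >= 1")
        if self.min_null_attempts < 1:
            raise ValueError("min_null_attempts must be >= 1")


Responder = ResponseModel | Callable[[LEUSSequenceSpec, np.random.Generator], int]


def _administer(
    responder: Responder,
    leus: LEUSSequenceSpec,
    stim_index: int,
    rng: np.random.Generator,
) -> int:
    if isinstance(responder, ResponseModel):
        return responder.sample_response(leus, stim_index, rng)
    return int(responder(leus, rng))


@dataclass
class ConditionSummary:
    condition: float
    administered: int
    responded: int
    ap_counts: np.ndarray  # one entry per administered stimulus, zeros included

    @property
    def success_rate(self) -> float:
        return self.responded / self.administered


@dataclass
class PRFComparisonResult:
    per_prf: dict[float, ConditionSummary]
    order: list[float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "prf_hz": prf,
                "administered": s.administered,
                "responded": s.responded,
                "success_rate": s.success_rate,
                "ap_counts": " ".join(str(c) for c in s.ap_counts),
            }
            for prf, s in self.per_prf.items()
        ]
        return pd.DataFrame(rows)


def run_prf_comparison(
    design: ParametricDesign,
    responder: Responder,
    rng: np.random.Generator | None = None,
    level_specs: Sequence[LEUSSequenceSpec] | None = None,
) -> PRFComparisonResult:
    """Randomized comparison of success rate and AP count across PRF levels.

    All levels share the non-PRF parameters of ``design.base_leus``; the
    administration order is a seeded permutation of the declared instances.
    AP-count vectors keep non-responses as zeros, one entry per stimulus.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    if level_specs is not None:
        if len(level_specs) != len(design.prf_levels_hz):
            raise ValueError("one LEUS spec required per PRF level")
        for spec in level_specs:
            if replace(spec, prf_hz=design.base_leus.prf_hz) != design.base_leus:
                raise ValueError(
                    "PRF levels must share every non-PRF parameter with the base sequence"
                )
        specs = {s.prf_hz: s for s in level_specs}
    else:
        specs = {
            prf: replace(design.base_leus, prf_hz=prf) for prf in design.prf_levels_hz
        }

    schedule = np.repeat(design.prf_levels_hz, design.instances_per_condition)
    order = [float(p) for p in rng.permutation(schedule)]
    counts: dict[float, list[int]] = {float(p): [] for p in design.prf_levels_hz}
    for prf in order:
        counts[prf].append(_administer(responder, specs[prf], 0, rng))

    per_prf = {}
    for prf in design.prf_levels_hz:
        c = np.asarray(counts[float(prf)], dtype=int)
        per_prf[float(prf)] = ConditionSummary(
            condition=float(prf),
            administered=len(c),
            responded=int((c > 0).sum()),
            ap_counts=c,
        )
    return PRFComparisonResult(per_prf=per_prf, order=order)


ABOVE_MAX_TESTED = "above_max_tested"
BELOW_MIN_TESTED = "below_min_tested"


@dataclass
class ThresholdMap:
    """Per-duration response thresholds found by the descending search."""

    table: pd.DataFrame  # n_cycles, min_responding_pa, max_silent_pa, status
    administered: pd.DataFrame  # n_cycles, pressure_pa, ap_count

    def thresholds(self) -> dict[int, float]:
        out = {}
        for _, row in self.table.iterrows():
            if not np.isnan(row["min_responding_pa"]):
                out[int(row["n_cycles"])] = float(row["min_responding_pa"])
        return out


def threshold_search(
    durations: Sequence[int],
    amplitudes: Sequence[float],
    responder: Responder,
    min_null_attempts: int = 5,
    rng: np.random.Generator | None = None,
    base_leus: LEUSSequenceSpec | None = None,
    seed: int = 0,
) -> ThresholdMap:
    """Descending-amplitude search for the response threshold per duration.

    For each pulse duration (ascending), amplitudes are tested in
    descending order, administering ``min_null_attempts + 1`` stimuli per
    level, and the search stops at the first amplitude that evokes zero
    responses.  Every administered stimulus is recorded.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    base = base_leus or LEUSSequenceSpec()
    durations = sorted(int(d) for d in durations)
    amplitudes = sorted(float(a) for a in amplitudes)
    attempts_per_level = min_null_attempts + 1

    rows = []
    admin_rows = []
    for n_cycles in durations:
        min_responding = math.nan
        max_silent = math.nan
        status = "ok"
        reached_bottom = True
        for pa in reversed(amplitudes):
            leus = replace(base, n_cycles=n_cycles, pressure_amplitude_pa=pa)
            level_counts = []
            for _ in range(attempts_per_level):
                count = _administer(responder, leus, 0, rng)
                level_counts.append(count)
                admin_rows.append(
                    {"n_cycles": n_cycles, "pressure_pa": pa, "ap_count": count}
                )
            if any(c > 0 for c in level_counts):
                min_responding = pa
            else:
                max_silent = pa
                reached_bottom = False
                break
        if math.isnan(min_responding):
            status = ABOVE_MAX_TESTED
        elif reached_bottom:
            status = BELOW_MIN_TESTED
        rows.append(
            {
                "n_cycles": n_cycles,
                "min_responding_pa": min_responding,
                "max_silent_pa": max_silent,
                "status": status,
            }
        )
    return ThresholdMap(
        table=pd.DataFrame(rows, columns=["n_cycles", "min_responding_pa", "max_silent_pa", "status"]),
        administered=pd.DataFrame(admin_rows, columns=["n_cycles", "pressure_pa", "ap_count"]),
    )


@dataclass
class StrengthDurationSummary:
    table: pd.DataFrame
    non_increasing: dict[str, bool]
    plateau_level: dict[str, float | None]
    ordering: pd.DataFrame | None = None


def strength_duration_summary(
    thresholds: Mapping[float, float] | Mapping[str, Mapping[float, float]],
    plateau_tol: float = 0.05,
) -> StrengthDurationSummary:
    """Tabulate threshold versus duration and assess monotonicity/plateau.

    ``thresholds`` is either a single ``duration -> threshold`` mapping or
    one mapping per fiber class.  A plateau is declared when the last two
    thresholds differ by less than ``plateau_tol`` (relative).  With two
    classes, the per-duration ordering between them is also reported.
    """
    first_value = next(iter(thresholds.values()), None)
    if isinstance(first_value, Mapping):
        per_class = {str(k): dict(v) for k, v in thresholds.items()}
    else:
        per_class = {"all": dict(thresholds)}  # type: ignore[arg-type]

    frames = []
    non_increasing = {}
    plateau_level: dict[str, float | None] = {}
    for cls, series in per_class.items():
        durations = sorted(series)
        values = [series[d] for d in durations]
        frames.append(
            pd.DataFrame({"fiber": cls, "duration": durations, "threshold": values})
        )
        non_increasing[cls] = all(b <= a for a, b in zip(values, values[1:]))
        if len(values) >= 2 and abs(values[-1] - values[-2]) < plateau_tol * abs(values[-2]):
            plateau_level[cls] = values[-1]
        else:
            plateau_level[cls] = None

    ordering = None
    if len(per_class) == 2:
        (cls_a, ser_a), (cls_b, ser_b) = per_class.items()
        shared = sorted(set(ser_a) & set(ser_b))
        ordering = pd.DataFrame(
            {
                "duration": shared,
                f"{cls_a}_gt_{cls_b}": [ser_a[d] > ser_b[d] for d in shared],
            }
        )
    return StrengthDurationSummary(
        table=pd.concat(frames, ignore_index=True),
        non_increasing=non_increasing,
        plateau_level=plateau_level,
        ordering=ordering,
    )
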