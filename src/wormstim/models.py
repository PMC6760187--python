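"""Core domain models for giant-fiber stimulation experiments.

Everything is SI: seconds, metres, volts, hertz, pascals.  Two fiber
classes are modelled (MGF: fast/large, LGF: slow/smaller), stimulated by
one of three modalities (electrical, mechanical, pulsed ultrasound) and
recorded through two bipolar electrode pairs plus one artifact channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

MGF = "MGF"
LGF = "LGF"
UNKNOWN = "UNKNOWN"
FIBER_CLASSES = (MGF, LGF)

ESTIM = "EStim"
MSTIM = "MStim"
USTIM = "UStim"
MODALITIES = (ESTIM, MSTIM, USTIM)

ANTERIOR = "anterior"
POSTERIOR = "posterior"
MEDIAL = "medial"
REGIONS = (ANTERIOR, POSTERIOR, MEDIAL)

#: upper-quartile z-score of the standard normal; maps printed quartiles
#: onto the log-normal scale parameter.
_Z75 = 0.6744897501960817


def _require_finite(**named: float) -> None:
    for name, value in named.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


def _require_positive(**named: float) -> None:
    for name, value in named.items():
        if not (math.isfinite(value) and value > 0):
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def _require_nonnegative(**named: float) -> None:
    for name, value in named.items():
        if not (math.isfinite(value) and value >= 0):
            raise ValueError(f"{name} must be a non-negative finite number, got {value!r}")


@dataclass(frozen=True)
class FiberModel:
    """One giant-fiber class as seen by the recording electrodes.

    Parameters
    ----------
    fiber_class
        ``"MGF"`` or ``"LGF"``.
    conduction_velocity
        Mean conduction velocity in m/s.
    velocity_jitter_sd
        Per-AP Gaussian jitter of the instantaneous velocity, m/s.
    peak_amplitude
        Rendered lobe amplitude at the electrodes, volts.
    amplitude_jitter_cv
        Coefficient of variation of a mean-preserving log-normal amplitude
        jitter.
    refractory_period
        Minimum interval between two APs of the same fiber, seconds.
    """

    fiber_class: str
    conduction_velocity: float
    velocity_jitter_sd: float = 0.0
    peak_amplitude: float = 1.0e-3
    amplitude_jitter_cv: float = 0.0
    refractory_period: float = 4.0e-3

    def __post_init__(self) -> None:
        if self.fiber_class not in FIBER_CLASSES:
            raise ValueError(f"unknown fiber class {self.fiber_class!r}")
        _require_positive(
            conduction_velocity=self.conduction_velocity,
            peak_amplitude=self.peak_amplitude,
            refractory_period=self.refractory_period,
        )
        _require_nonnegative(
            velocity_jitter_sd=self.velocity_jitter_sd,
            amplitude_jitter_cv=self.amplitude_jitter_cv,
        )

    def sample_velocity(self, rng: np.random.Generator) -> float:
        if self.velocity_jitter_sd == 0.0:
            return self.conduction_velocity
        v = self.conduction_velocity + rng.normal(0.0, self.velocity_jitter_sd)
        # Gaussian tails cannot be allowed to produce a non-physical velocity.
        return max(v, 0.1 * self.conduction_velocity)

    def sample_amplitude(self, rng: np.random.Generator) -> float:
        if self.amplitude_jitter_cv == 0.0:
            return self.peak_amplitude
        sigma = math.sqrt(math.log1p(self.amplitude_jitter_cv**2))
        return self.peak_amplitude * math.exp(rng.normal(-0.5 * sigma**2, sigma))


@dataclass(frozen=True)
class TogDistribution:
    """Log-normal distribution over generation times (seconds).

    Parameterised by its median and log-scale spread so printed
    ``median [Q1-Q3]`` summaries translate directly into parameters.
    """

    median_s: float
    log_sigma: float = 0.0

    def __post_init__(self) -> None:
        _require_positive(median_s=self.median_s)
        _require_nonnegative(log_sigma=self.log_sigma)

    @classmethod
    def from_quartiles(cls, q1_s: float, median_s: float, q3_s: float) -> "TogDistribution":
        _require_positive(q1_s=q1_s, median_s=median_s, q3_s=q3_s)
        if not q1_s <= median_s <= q3_s:
            raise ValueError("quartiles must satisfy q1 <= median <= q3")
        log_sigma = math.log(q3_s / q1_s) / (2.0 * _Z75)
        return cls(median_s=median_s, log_sigma=log_sigma)

    @property
    def quartiles(self) -> tuple[float, float]:
        spread = math.exp(_Z75 * self.log_sigma)
        return self.median_s / spread, self.median_s * spread

    def sample(self, rng: np.random.Generator, size: int | None = None):
        draw = self.median_s * np.exp(rng.normal(0.0, self.log_sigma, size))
        return draw if size is not None else float(draw)


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class DoseResponse:
    """Success probability of pulsed-ultrasound stimulation.

    Product of a PRF-dependent plateau (logistic in log-PRF) and a steep
    amplitude gate whose threshold decreases with pulse duration, with a
    hard pressure floor below which no response is possible.
    All three partial dependencies are non-decreasing.
    """

    floor_pa: float = 4.0e6
    plateau_logit: float = 2.197
    prf_slope: float = 1.617
    prf_ref_hz: float = 125.0
    gate_steepness_per_mpa: float = 8.0
    gate_threshold_pa: float = 5.0e6
    gate_threshold_drop_pa: float = 1.5e6
    n_cycles_ref: tuple[float, float] = (175.0, 1150.0)

    def __post_init__(self) -> None:
        _require_positive(
            floor_pa=self.floor_pa,
            prf_ref_hz=self.prf_ref_hz,
            gate_threshold_pa=self.gate_threshold_pa,
        )
        _require_nonnegative(
            prf_slope=self.prf_slope,
            gate_steepness_per_mpa=self.gate_steepness_per_mpa,
            gate_threshold_drop_pa=self.gate_threshold_drop_pa,
        )
        lo, hi = self.n_cycles_ref
        if not 0 < lo < hi:
            raise ValueError("n_cycles_ref must be an increasing positive pair")

    def threshold_pa(self, n_cycles: float) -> float:
        """Amplitude-gate midpoint for a given pulse duration (in cycles)."""
        lo, hi = self.n_cycles_ref
        frac = math.log(n_cycles / lo) / math.log(hi / lo)
        return self.gate_threshold_pa - self.gate_threshold_drop_pa * frac

    def probability(self, prf_hz: float, pressure_pa: float, n_cycles: float) -> float:
        _require_positive(prf_hz=prf_hz, n_cycles=n_cycles)
        _require_nonnegative(pressure_pa=pressure_pa)
        if pressure_pa < self.floor_pa:
            return 0.0
        plateau = _expit(self.plateau_logit + self.prf_slope * math.log(prf_hz / self.prf_ref_hz))
        gate = _expit(
            self.gate_steepness_per_mpa * (pressure_pa - self.threshold_pa(n_cycles)) / 1.0e6
        )
        return plateau * gate


@dataclass(frozen=True)
class LEUSSequenceSpec:
    """Timing and amplitude of a pulsed low-energy ultrasound burst."""

    carrier_frequency_hz: float = 1.1e6
    n_cycles: int = 175
    prf_hz: float = 125.0
    n_pulses: int = 20
    pressure_amplitude_pa: float = 6.6e6
    burst_onsets_s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        _require_positive(
            carrier_frequency_hz=self.carrier_frequency_hz,
            n_cycles=float(self.n_cycles),
            prf_hz=self.prf_hz,
            n_pulses=float(self.n_pulses),
            pressure_amplitude_pa=self.pressure_amplitude_pa,
        )
        onsets = self.burst_onsets_s
        if onsets:
            gaps = np.diff(onsets)
            if len(gaps) and gaps.min() <= 0:
                raise ValueError("burst onsets must be strictly increasing")
            if len(gaps) and gaps.min() < self.n_pulses * self.pulse_period_s:
                raise ValueError("inter-burst interval shorter than the burst itself")

    @property
    def pulse_duration_s(self) -> float:
        return self.n_cycles / self.carrier_frequency_hz

    @property
    def pulse_period_s(self) -> float:
        return 1.0 / self.prf_hz

    @property
    def burst_duration_s(self) -> float:
        return (self.n_pulses - 1) * self.pulse_period_s + self.pulse_duration_s


@dataclass(frozen=True)
class StimulusEvent:
    """One administered stimulus."""

    stimulus_id: int
    modality: str
    onset_s: float
    region: str = ANTERIOR
    leus: LEUSSequenceSpec | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        _require_finite(onset_s=self.onset_s)
        if self.modality == USTIM and self.leus is None:
            raise ValueError("UStim events require a LEUSSequenceSpec")


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Longitudinal layout of the two bipolar recording pairs.

    Electrode order away from the stimulation site is
    anode1, cathode1, anode2, cathode2.  Defaults: 1 cm spacing between
    neighbouring electrodes, 2 cm between the anodes, 8.4 cm from the
    stimulation site to the first anode.
    """

    electrode_spacing: float = 0.01
    anode_separation: float = 0.02
    stim_to_first_anode: float = 0.084

    def __post_init__(self) -> None:
        _require_positive(
            electrode_spacing=self.electrode_spacing,
            anode_separation=self.anode_separation,
            stim_to_first_anode=self.stim_to_first_anode,
        )

    @property
    def anode_cathode_separation(self) -> float:
        return self.electrode_spacing

    @property
    def electrode_positions(self) -> tuple[float, float, float, float]:
        d0 = self.stim_to_first_anode
        return (
            d0,
            d0 + self.electrode_spacing,
            d0 + self.anode_separation,
            d0 + self.anode_separation + self.electrode_spacing,
        )


@dataclass(frozen=True)
class ResponseModel:
    """How a preparation responds to one stimulation modality.

    Encodes the success probability (constant, or a :class:`DoseResponse`
    for pulsed ultrasound), the generation-time distribution per fiber
    class, the region-to-fiber mapping, and within-trial adaptation of the
    AP count and inter-AP interval.
    """

    modality: str
    tog: Mapping[str, TogDistribution] = field(default_factory=dict)
    region: str = ANTERIOR
    base_success: float = 1.0
    medial_success: float = 0.1
    dose: DoseResponse | None = None
    mean_extra_aps: float = 0.0
    adaptation_ratio: float = 0.7
    interval_growth: float = 1.3
    base_interval_s: float = 0.012
    interval_jitter_cv: float = 0.15
    count_prf_exponent: float = 0.7
    tog_reference: str = "burst_onset"  # or "first_pulse"; identical when pulses start at onset

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not 0.0 <= self.base_success <= 1.0:
            raise ValueError("base_success must be in [0, 1]")
        if not 0.0 <= self.medial_success <= 1.0:
            raise ValueError("medial_success must be in [0, 1]")
        _require_nonnegative(mean_extra_aps=self.mean_extra_aps)
        _require_positive(
            adaptation_ratio=self.adaptation_ratio,
            interval_growth=self.interval_growth,
            base_interval_s=self.base_interval_s,
        )
        if self.adaptation_ratio > 1.0:
            raise ValueError("adaptation_ratio must be <= 1 (count never increases)")
        if self.tog_reference not in ("burst_onset", "first_pulse"):
            raise ValueError("tog_reference must be 'burst_onset' or 'first_pulse'")

    # -- success ---------------------------------------------------------

    def success_probability(self, leus: LEUSSequenceSpec | None = None) -> float:
        region_factor = 1.0
        if self.modality != ESTIM and self.region == MEDIAL:
            region_factor = self.medial_success
        if self.dose is not None and leus is not None:
            base = self.dose.probability(
                leus.prf_hz, leus.pressure_amplitude_pa, leus.n_cycles
            )
        else:
            base = self.base_success
        return region_factor * base

    def responding_fibers(self, rng: np.random.Generator) -> tuple[str, ...]:
        if self.modality == ESTIM:
            return FIBER_CLASSES
        if self.region == ANTERIOR:
            return (MGF,)
        if self.region == POSTERIOR:
            return (LGF,)
        return (MGF,) if rng.random() < 0.5 else (LGF,)

    # -- AP counts and timing -------------------------------------------

    def _count_gain(self, leus: LEUSSequenceSpec | None) -> float:
        if leus is None or self.modality != USTIM:
            return 1.0
        return (leus.prf_hz / 125.0) ** self.count_prf_exponent

    def _extra_ap_rate(self, stim_index: int, leus: LEUSSequenceSpec | None) -> float:
        return self.mean_extra_aps * self.adaptation_ratio**stim_index * self._count_gain(leus)

    def sample_togs(
        self,
        fiber_class: str,
        stim_index: int,
        rng: np.random.Generator,
        leus: LEUSSequenceSpec | None = None,
    ) -> np.ndarray:
        """Generation times of all APs in one response, seconds after onset."""
        if fiber_class not in self.tog:
            raise KeyError(f"no TOG distribution for fiber class {fiber_class!r}")
        togs = [self.tog[fiber_class].sample(rng)]
        lam = self._extra_ap_rate(stim_index, leus)
        extra = int(rng.poisson(lam)) if lam > 0 else 0
        sigma = (
            math.sqrt(math.log1p(self.interval_jitter_cv**2))
            if self.interval_jitter_cv
            else 0.0
        )
        for j in range(extra):
            interval = self.base_interval_s * self.interval_growth**j
            if sigma:
                interval *= math.exp(rng.normal(-0.5 * sigma**2, sigma))
            togs.append(togs[-1] + interval)
        return np.asarray(togs)

    def sample_response(
        self,
        leus: LEUSSequenceSpec | None,
        stim_index: int,
        rng: np.random.Generator,
    ) -> int:
        """AP count for one administered stimulus (0 = no response)."""
        if rng.random() >= self.success_probability(leus):
            return 0
        lam = self._extra_ap_rate(stim_index, leus)
        return 1 + (int(rng.poisson(lam)) if lam > 0 else 0)


@dataclass
class RecordingTrace:
    """Sampled multichannel voltage record plus acquisition metadata."""

    sampling_rate: float
    channels: dict[str, np.ndarray]
    geometry: ElectrodeGeometry | None = None
    protocol: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        _require_positive(sampling_rate=self.sampling_rate)
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy_with_channels(self, channels: dict[str, np.ndarray]) -> "RecordingTrace":
        return RecordingTrace(
            sampling_rate=self.sampling_rate,
            channels=channels,
            geometry=self.geometry,
            protocol=list(self.protocol),
        )


@dataclass(frozen=True)
class StudyModels:
    fibers: Mapping[str, FiberModel]
    responses: Mapping[str, ResponseModel]
    geometry: ElectrodeGeometry


def default_study_models() -> StudyModels:
    """Calibrated defaults for the two fiber classes and three modalities.

    Velocities 16.6 m/s (MGF) and 9.0 m/s (LGF); generation-time medians
    and quartiles per modality chosen to reproduce the reference summary
    values (electrical: 1.3/2.4 ms, mechanical: 33.0 ms, ultrasound:
    11.8 ms).
    """
    fibers = {
        MGF: FiberModel(
            MGF,
            conduction_velocity=16.6,
            velocity_jitter_sd=0.22,
            peak_amplitude=1.0e-3,
            amplitude_jitter_cv=0.05,
        ),
        LGF: FiberModel(
            LGF,
            conduction_velocity=9.0,
            velocity_jitter_sd=0.074,
            peak_amplitude=0.6e-3,
            amplitude_jitter_cv=0.05,
        ),
    }
    mstim_tog = TogDistribution.from_quartiles(26.1e-3, 33.0e-3, 36.6e-3)
    ustim_tog = TogDistribution.from_quartiles(11.2e-3, 11.8e-3, 13.1e-3)
    responses = {
        ESTIM: ResponseModel(
            ESTIM,
            tog={
                MGF: TogDistribution(1.3e-3, 0.01),
                LGF: TogDistribution.from_quartiles(2.3e-3, 2.4e-3, 2.4e-3),
            },
            region=ANTERIOR,
            base_success=1.0,
            mean_extra_aps=0.0,
        ),
        MSTIM: ResponseModel(
            MSTIM,
            tog={MGF: mstim_tog, LGF: mstim_tog},
            region=POSTERIOR,
            base_success=0.85,
            mean_extra_aps=1.5,
        ),
        USTIM: ResponseModel(
            USTIM,
            tog={MGF: ustim_tog, LGF: ustim_tog},
            region=POSTERIOR,
            dose=DoseResponse(),
            mean_extra_aps=2.5,
        ),
    }
    return StudyModels(fibers=fibers, responses=responses, geometry=ElectrodeGeometry())


def periodic_protocol(
    modalities: Sequence[str],
    n_stimuli: int,
    start_s: float = 0.5,
    interval_s: float = 0.5,
    region: str = POSTERIOR,
    leus: LEUSSequenceSpec | None = None,
) -> list[StimulusEvent]:
    """Evenly spaced protocol cycling through ``modalities``."""
    if not modalities:
        raise ValueError("at least one modality required")
    leus = leus or LEUSSequenceSpec()
    events = []
    for i in range(n_stimuli):
        modality = modalities[i % len(modalities)]
        events.append(
            StimulusEvent(
                stimulus_id=i,
                modality=modality,
                onset_s=start_s + i * interval_s,
                region=region,
                leus=leus if modality == USTIM else None,
            )
        )
    return events
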