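"""Synthetic laser-vibrometry signals and specimen cohorts.

Stands in for the laser hardware and the physical specimens so the whole
analysis chain is testable at a desk. Two generators:

* ``simulate_record`` — an impulse-excited screw vibration record: a
  superposition of exponentially damped sinusoids restarted at each laser
  trigger, an early broadband ablation transient after each pulse, and
  additive white noise. Default acquisition matches the measurement protocol
  (10 Hz pulse train, 16 pulses, 1.6 s record).
* ``generate_cohort`` — cohorts of specimens whose resonance frequency
  follows a logarithmic law in fixation force and whose ISQ is affine in RF,
  with tunable noise; six density groups of polyurethane-foam surrogates by
  default.

The damped-sinusoid modal model and the transient/noise magnitudes are
modeling choices of this package, not measured hardware characteristics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .pipeline import VibrationRecord
from .stability import IsqMap, rf_to_isq
from .validation import SpecimenMeasurements

__all__ = [
    "ModalMode",
    "ExcitationSchedule",
    "NoiseModel",
    "FixationLaw",
    "GroupSpec",
    "CohortSpec",
    "DEFAULT_SAMPLING_RATE",
    "DEFAULT_GROUPS",
    "simulate_record",
    "fixation_to_rf",
    "generate_cohort",
]

#: Default sampling rate (Hz): 10x the top of the 1000–5000 Hz search band.
DEFAULT_SAMPLING_RATE: float = 50_000.0


@dataclass(frozen=True)
class ModalMode:
    """One vibration mode: natural frequency, damping ratio, amplitude.

    The impulse response contributed by a mode after a trigger at ``t_k`` is
    ``A * exp(-zeta * w_n * tau) * sin(w_d * tau)`` with ``tau = t - t_k``,
    ``w_n = 2*pi*f_n`` and damped frequency ``f_d = f_n * sqrt(1 - zeta^2)``.
    """

    natural_frequency: float  # Hz
    damping_ratio: float = 0.01  # dimensionless, 0 < zeta < 1
    amplitude: float = 1.0  # velocity units, >= 0

    def __post_init__(self) -> None:
        if self.natural_frequency <= 0:
            raise ValueError("natural_frequency must be positive")
        if not 0 < self.damping_ratio < 1:
            raise ValueError("damping_ratio must lie in (0, 1)")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def damped_frequency(self) -> float:
        """f_n * sqrt(1 - zeta^2), the frequency actually seen in the spectrum."""
        return self.natural_frequency * math.sqrt(1.0 - self.damping_ratio**2)


@dataclass(frozen=True)
class ExcitationSchedule:
    """Pulse-train layout: 10 Hz repetition, 16 pulses, 1.6 s record by default."""

    repetition_rate: float = 10.0  # Hz
    n_pulses: int = 16
    record_duration: float = 1.6  # s
    first_pulse_time: float = 0.0  # s

    def __post_init__(self) -> None:
        if self.repetition_rate <= 0 or self.n_pulses < 1:
            raise ValueError("repetition_rate must be > 0 and n_pulses >= 1")
        if self.first_pulse_time < 0:
            raise ValueError("first_pulse_time must be >= 0")
        last = self.first_pulse_time + (self.n_pulses - 1) / self.repetition_rate
        if not last < self.record_duration:
            raise ValueError(
                f"last pulse at {last:g} s does not fit inside the "
                f"{self.record_duration:g} s record"
            )

    @property
    def trigger_times(self) -> np.ndarray:
        return self.first_pulse_time + np.arange(self.n_pulses) / self.repetition_rate


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise: stationary white noise plus a post-pulse ablation burst.

    ``broadband_sd`` is the standard deviation of white Gaussian noise over
    the whole record. After each trigger, white noise of standard deviation
    ``ablation_transient_gain * (sum of mode amplitudes, or 1 if that sum is
    0)`` is added for ``ablation_transient_duration`` seconds — a stand-in
    for the plume/plasma disturbance, scaled relative to the signal so the
    gain is dimensionless.
    """

    broadband_sd: float = 0.0
    ablation_transient_duration: float = 0.0045  # s, <= default purge time
    ablation_transient_gain: float = 0.0

    def __post_init__(self) -> None:
        if (
            self.broadband_sd < 0
            or self.ablation_transient_duration < 0
            or self.ablation_transient_gain < 0
        ):
            raise ValueError("noise parameters must be non-negative")


def simulate_record(
    modes: list[ModalMode],
    schedule: ExcitationSchedule | None = None,
    noise: NoiseModel | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    seed: int | None = 0,
) -> VibrationRecord:
    """Simulate a trigger-synchronized vibrometer record.

    Every laser pulse re-excites all modes; contributions from earlier pulses
    keep ringing down (they are negligible after one 100 ms period at the
    default damping). The noiseless signal is linear in the mode amplitudes.

    Raises
    ------
    ValueError
        If ``modes`` is empty or the sampling rate is below the Nyquist rate
        of any mode.
    """
    schedule = schedule or ExcitationSchedule()
    noise = noise or NoiseModel()
    if not modes:
        raise ValueError("at least one vibration mode is required")
    f_max = max(m.natural_frequency for m in modes)
    if sampling_rate <= 2 * f_max:
        raise ValueError(
            f"sampling_rate {sampling_rate:g} Hz is below the Nyquist rate "
            f"for the {f_max:g} Hz mode (need > {2 * f_max:g} Hz)"
        )

    n = round(schedule.record_duration * sampling_rate)
    t = np.arange(n) / sampling_rate
    signal = np.zeros(n)
    triggers = schedule.trigger_times
    for t_k in triggers:
        start = int(np.ceil(t_k * sampling_rate - 1e-9))
        tau = t[start:] - t_k
        for m in modes:
            if m.amplitude == 0:
                continue
            w_n = 2 * math.pi * m.natural_frequency
            w_d = 2 * math.pi * m.damped_frequency
            signal[start:] += (
                m.amplitude * np.exp(-m.damping_ratio * w_n * tau) * np.sin(w_d * tau)
            )

    rng = np.random.default_rng(seed)
    if noise.broadband_sd > 0:
        signal = signal + rng.normal(0.0, noise.broadband_sd, size=n)
    if noise.ablation_transient_gain > 0 and noise.ablation_transient_duration > 0:
        amp_scale = sum(m.amplitude for m in modes) or 1.0
        burst_sd = noise.ablation_transient_gain * amp_scale
        n_burst = round(noise.ablation_transient_duration * sampling_rate)
        for t_k in triggers:
            start = int(np.ceil(t_k * sampling_rate - 1e-9))
            stop = min(start + n_burst, n)
            signal[start:stop] += rng.normal(0.0, burst_sd, size=stop - start)

    return VibrationRecord(
        samples=signal,
        sampling_rate=sampling_rate,
        trigger_times=triggers,
        units="a.u.",
    )


@dataclass(frozen=True)
class FixationLaw:
    """Logarithmic fixation-force -> resonance-frequency law.

    ``RF(F) = c0 + c1 * ln(F)``, clamped to ``rf_clamp``. A logarithmic law
    captures the two-regime behavior of screw fixation: RF rises rapidly
    where fixation force is low (friction-dominated) and slowly where it is
    high (axial-force-dominated). With ``c1 > 0`` the law is monotone
    increasing. Defaults put typical foam-block torques (0.3–3 Nm) at
    3500–4450 Hz, inside both the search band and the ISQ map range.
    """

    intercept: float = 4000.0  # Hz (RF at 1 unit of force)
    slope: float = 400.0  # Hz per ln(force unit)
    valid_force_range: tuple[float, float] = (0.01, 50.0)
    rf_clamp: tuple[float, float] = (1000.0, 5000.0)

    def __post_init__(self) -> None:
        lo, hi = self.valid_force_range
        if not 0 < lo < hi:
            raise ValueError("valid_force_range must satisfy 0 < min < max")
        lo_rf, hi_rf = self.rf_clamp
        if not lo_rf < hi_rf:
            raise ValueError("rf_clamp must satisfy min < max")


def fixation_to_rf(force: float, law: FixationLaw | None = None) -> float:
    """Resonance frequency (Hz) for a fixation force (torque in Nm or POF in N).

    Raises
    ------
    ValueError
        For ``force <= 0`` (the log law is undefined) or a force outside the
        law's valid range.
    """
    law = law or FixationLaw()
    if force <= 0:
        raise ValueError(f"force must be positive for the log law, got {force}")
    lo, hi = law.valid_force_range
    if not lo <= force <= hi:
        raise ValueError(
            f"force {force:g} outside the law's valid range [{lo:g}, {hi:g}]"
        )
    rf = law.intercept + law.slope * math.log(force)
    return min(max(rf, law.rf_clamp[0]), law.rf_clamp[1])


@dataclass(frozen=True)
class GroupSpec:
    """One specimen group: label plus the torque distribution (mean, sd) in Nm."""

    label: str
    force_mean: float
    force_sd: float

    def __post_init__(self) -> None:
        if self.force_mean <= 0 or self.force_sd < 0:
            raise ValueError("force_mean must be > 0 and force_sd >= 0")


def _default_groups() -> tuple[GroupSpec, ...]:
    # Six polyurethane-foam surrogate groups (five solid densities plus one
    # cellular foam), densities in g/cm^3; insertion torque scales with foam
    # density, the cellular foam grips less than solid foam of equal density.
    solid = [0.08, 0.16, 0.192, 0.32, 0.48]
    groups = [
        GroupSpec(
            label=f"solid-{d:g}", force_mean=6.0 * d, force_sd=0.1 * 6.0 * d
        )
        for d in solid
    ]
    groups.append(
        GroupSpec(label="cellular-0.16", force_mean=0.6 * 6.0 * 0.16,
                  force_sd=0.1 * 0.6 * 6.0 * 0.16)
    )
    return tuple(groups)


DEFAULT_GROUPS: tuple[GroupSpec, ...] = _default_groups()


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic specimen cohort.

    Per specimen the generator draws a peak torque from its group's normal
    distribution (truncated positive), sets the true RF through the fixation
    law, adds Gaussian RF noise, derives ISQ from the (noisy) RF through the
    inverse ISQ map plus ISQ noise, and derives POF from torque through a
    proportional law (``pof_slope`` N per Nm) plus noise. Specimens are
    assigned to groups in contiguous blocks, as evenly as possible.

    Each specimen consumes its own deterministic random substream derived
    from ``seed``, so enlarging the cohort never reshuffles earlier
    specimens.
    """

    n_specimens: int = 30
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    fixation_law: FixationLaw = field(default_factory=FixationLaw)
    isq_map: IsqMap = field(default_factory=IsqMap)
    rf_noise_sd: float = 80.0  # Hz
    isq_noise_sd: float = 1.5  # ISQ units
    pof_slope: float = 600.0  # N per Nm
    pof_intercept: float = 0.0  # N
    pof_noise_sd: float = 30.0  # N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be >= 2")
        if not self.groups:
            raise ValueError("at least one group is required")
        for sd in (self.rf_noise_sd, self.isq_noise_sd, self.pof_noise_sd):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")
        if self.pof_slope <= 0:
            raise ValueError("pof_slope must be positive (POF grows with torque)")

    def noiseless(self) -> "CohortSpec":
        """Copy of the spec with every noise source set to zero."""
        return replace(self, rf_noise_sd=0.0, isq_noise_sd=0.0, pof_noise_sd=0.0)

    def group_sizes(self) -> list[int]:
        g = len(self.groups)
        base, extra = divmod(self.n_specimens, g)
        return [base + (1 if i < extra else 0) for i in range(g)]


def _specimen_rng(seed: int, index: int) -> np.random.Generator:
    # Stable per-specimen substream: independent of cohort size.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_cohort(spec: CohortSpec) -> list[SpecimenMeasurements]:
    """Generate a cohort of specimen measurement rows (see :class:`CohortSpec`)."""
    sizes = spec.group_sizes()
    group_of: list[GroupSpec] = []
    for g, size in zip(spec.groups, sizes):
        group_of.extend([g] * size)

    lo, hi = spec.fixation_law.valid_force_range
    cohort: list[SpecimenMeasurements] = []
    for i in range(spec.n_specimens):
        rng = _specimen_rng(spec.seed, i)
        g = group_of[i]
        torque = float(
            np.clip(rng.normal(g.force_mean, g.force_sd), max(lo, 1e-6), hi)
        )
        rf = fixation_to_rf(torque, spec.fixation_law)
        rf += float(rng.normal(0.0, spec.rf_noise_sd)) if spec.rf_noise_sd else 0.0
        isq = rf_to_isq(rf, spec.isq_map)
        if spec.isq_noise_sd:
            isq = float(
                np.clip(isq + rng.normal(0.0, spec.isq_noise_sd), 0.0, 100.0)
            )
        pof = spec.pof_intercept + spec.pof_slope * torque
        if spec.pof_noise_sd:
            pof = float(max(pof + rng.normal(0.0, spec.pof_noise_sd), 1e-6))
        cohort.append(
            SpecimenMeasurements(
                specimen_id=f"S{i + 1:03d}",
                group=g.label,
                peak_torque=torque,
                pullout=pof,
                isq=isq,
                rf=rf,
            )
        )
    return cohort
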