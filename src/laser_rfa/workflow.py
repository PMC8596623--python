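"""End-to-end reproducible runs: simulate -> analyze -> validate.

``RunConfig`` captures every knob of a run in one JSON-serializable object;
``run_end_to_end`` simulates a cohort's vibrometer records, extracts each
specimen's resonance frequency through the measurement chain, derives ISQ
from the detected RF, assembles the measurement table and the pairwise
correlation matrix, and writes the report plus figures. A run is fully
reproducible from (config, seed); the config is copied verbatim into the
output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_cohort
from .pipeline import AnalysisWindow, analyze_record
from .signal_model import (
    CohortSpec,
    ExcitationSchedule,
    FixationLaw,
    GroupSpec,
    ModalMode,
    NoiseModel,
    generate_cohort,
    simulate_record,
    DEFAULT_SAMPLING_RATE,
)
from .stability import IsqMap, rf_to_isq
from .validation import CorrelationMatrix, SpecimenMeasurements, correlation_table

__all__ = ["RecordingConfig", "RunConfig", "RunReport", "run_end_to_end"]

logger = logging.getLogger("laser_rfa")


@dataclass(frozen=True)
class RecordingConfig:
    """Per-specimen vibrometer-record simulation settings."""

    sampling_rate: float = DEFAULT_SAMPLING_RATE  # Hz
    damping_ratio: float = 0.01
    amplitude: float = 1.0
    broadband_sd: float = 0.02
    ablation_transient_gain: float = 5.0
    ablation_transient_duration: float = 0.004  # s, inside the 4.5 ms purge
    schedule: ExcitationSchedule = field(default_factory=ExcitationSchedule)

    def noise_model(self) -> NoiseModel:
        return NoiseModel(
            broadband_sd=self.broadband_sd,
            ablation_transient_duration=self.ablation_transient_duration,
            ablation_transient_gain=self.ablation_transient_gain,
        )


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    recording: RecordingConfig = field(default_factory=RecordingConfig)
    window: AnalysisWindow = field(default_factory=AnalysisWindow)
    band: tuple[float, float] = (1000.0, 5000.0)
    isq_map: IsqMap = field(default_factory=IsqMap)

    def noiseless(self) -> "RunConfig":
        """Copy with all cohort and record noise removed."""
        return dataclasses.replace(
            self,
            cohort=self.cohort.noiseless(),
            recording=dataclasses.replace(
                self.recording, broadband_sd=0.0, ablation_transient_gain=0.0
            ),
        )

    def to_dict(self) -> dict:
        c, r, w = self.cohort, self.recording, self.window
        return {
            "seed": self.seed,
            "band_hz": list(self.band),
            "isq_map": {
                "rf_at_isq0": self.isq_map.rf_at_isq0,
                "rf_at_isq100": self.isq_map.rf_at_isq100,
            },
            "window": {
                "purge_time_s": w.purge_time,
                "segment_length_s": w.segment_length,
            },
            "cohort": {
                "n_specimens": c.n_specimens,
                "groups": [
                    {
                        "label": g.label,
                        "force_mean_Nm": g.force_mean,
                        "force_sd_Nm": g.force_sd,
                    }
                    for g in c.groups
                ],
                "fixation_law": {
                    "intercept_hz": c.fixation_law.intercept,
                    "slope_hz_per_ln": c.fixation_law.slope,
                    "valid_force_range": list(c.fixation_law.valid_force_range),
                    "rf_clamp_hz": list(c.fixation_law.rf_clamp),
                },
                "rf_noise_sd_hz": c.rf_noise_sd,
                "isq_noise_sd": c.isq_noise_sd,
                "pof_slope_n_per_nm": c.pof_slope,
                "pof_intercept_n": c.pof_intercept,
                "pof_noise_sd_n": c.pof_noise_sd,
            },
            "recording": {
                "sampling_rate_hz": r.sampling_rate,
                "damping_ratio": r.damping_ratio,
                "amplitude": r.amplitude,
                "broadband_sd": r.broadband_sd,
                "ablation_transient_gain": r.ablation_transient_gain,
                "ablation_transient_duration_s": r.ablation_transient_duration,
                "schedule": {
                    "repetition_rate_hz": r.schedule.repetition_rate,
                    "n_pulses": r.schedule.n_pulses,
                    "record_duration_s": r.schedule.record_duration,
                    "first_pulse_time_s": r.schedule.first_pulse_time,
                },
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        isq_map = IsqMap(**d.get("isq_map", {})) if "isq_map" in d else IsqMap()
        w = d.get("window", {})
        window = AnalysisWindow(
            purge_time=w.get("purge_time_s", 0.0045),
            segment_length=w.get("segment_length_s", 0.1),
        )
        c = d.get("cohort", {})
        law_d = c.get("fixation_law", {})
        law = FixationLaw(
            intercept=law_d.get("intercept_hz", 4000.0),
            slope=law_d.get("slope_hz_per_ln", 400.0),
            valid_force_range=tuple(law_d.get("valid_force_range", (0.01, 50.0))),
            rf_clamp=tuple(law_d.get("rf_clamp_hz", (1000.0, 5000.0))),
        )
        groups = tuple(
            GroupSpec(
                label=g["label"],
                force_mean=g["force_mean_Nm"],
                force_sd=g["force_sd_Nm"],
            )
            for g in c["groups"]
        ) if "groups" in c else CohortSpec().groups
        seed = int(d.get("seed", 0))
        cohort = CohortSpec(
            n_specimens=c.get("n_specimens", 30),
            groups=groups,
            fixation_law=law,
            isq_map=isq_map,
            rf_noise_sd=c.get("rf_noise_sd_hz", 80.0),
            isq_noise_sd=c.get("isq_noise_sd", 1.5),
            pof_slope=c.get("pof_slope_n_per_nm", 600.0),
            pof_intercept=c.get("pof_intercept_n", 0.0),
            pof_noise_sd=c.get("pof_noise_sd_n", 30.0),
            seed=seed,
        )
        r = d.get("recording", {})
        s = r.get("schedule", {})
        recording = RecordingConfig(
            sampling_rate=r.get("sampling_rate_hz", DEFAULT_SAMPLING_RATE),
            damping_ratio=r.get("damping_ratio", 0.01),
            amplitude=r.get("amplitude", 1.0),
            broadband_sd=r.get("broadband_sd", 0.02),
            ablation_transient_gain=r.get("ablation_transient_gain", 5.0),
            ablation_transient_duration=r.get(
                "ablation_transient_duration_s", 0.004
            ),
            schedule=ExcitationSchedule(
                repetition_rate=s.get("repetition_rate_hz", 10.0),
                n_pulses=s.get("n_pulses", 16),
                record_duration=s.get("record_duration_s", 1.6),
                first_pulse_time=s.get("first_pulse_time_s", 0.0),
            ),
        )
        return cls(
            seed=seed,
            cohort=cohort,
            recording=recording,
            window=window,
            band=tuple(d.get("band_hz", (1000.0, 5000.0))),
            isq_map=isq_map,
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunReport:
    """Outcome of one end-to-end run."""

    cohort: list[SpecimenMeasurements]
    matrix: CorrelationMatrix
    n_analyzed: int
    failures: dict[str, str]
    out_dir: Path | None = None

    def to_dict(self) -> dict:
        return {
            "n_analyzed": self.n_analyzed,
            "failures": self.failures,
            "correlations": self.matrix.to_dict(),
        }


def _record_seed(root_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(root_seed, spawn_key=(10_000 + index,))


def run_end_to_end(
    config: RunConfig, out_dir: str | Path | None = None
) -> RunReport:
    """Simulate, measure and validate one cohort.

    Per specimen: a ground-truth torque/POF/RF row is drawn from the cohort
    spec; a vibrometer record is simulated with a single vibration mode at
    that specimen's (noisy) RF; the record runs through the measurement
    chain; ISQ is derived from the *detected* RF through the inverse ISQ map
    (plus configured ISQ noise). Specimens whose analysis fails are logged
    and skipped; the run errors only if every specimen fails.

    When ``out_dir`` is given, writes: ``config.json`` (the verbatim run
    config), ``cohort.csv``, ``correlation_matrix.csv``/``.json``,
    ``figures/pairs.png`` and ``report.json``.
    """
    truth = generate_cohort(config.cohort)
    rec = config.recording
    window = config.window
    measured: list[SpecimenMeasurements] = []
    failures: dict[str, str] = {}
    for i, spec in enumerate(truth):
        try:
            mode = ModalMode(
                natural_frequency=spec.rf,
                damping_ratio=rec.damping_ratio,
                amplitude=rec.amplitude,
            )
            record = simulate_record(
                [mode],
                rec.schedule,
                rec.noise_model(),
                sampling_rate=rec.sampling_rate,
                seed=_record_seed(config.seed, i),
            )
            result = analyze_record(record, window, config.band)
            isq = rf_to_isq(result.rf, config.isq_map)
            if config.cohort.isq_noise_sd:
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(20_000 + i,))
                )
                isq = float(
                    np.clip(
                        isq + rng.normal(0.0, config.cohort.isq_noise_sd),
                        0.0,
                        100.0,
                    )
                )
            measured.append(
                dataclasses.replace(spec, rf=result.rf, isq=isq)
            )
            logger.info(
                "specimen %s: detected RF %.1f Hz (%d segments)",
                spec.specimen_id,
                result.rf,
                result.n_segments,
            )
        except ValueError as exc:
            failures[spec.specimen_id] = str(exc)
            logger.warning("specimen %s failed: %s", spec.specimen_id, exc)
    if not measured:
        raise RuntimeError(f"all {len(truth)} specimens failed analysis: {failures}")

    matrix = correlation_table(measured)
    report = RunReport(
        cohort=measured,
        matrix=matrix,
        n_analyzed=len(measured),
        failures=failures,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "config.json")
        write_cohort(measured, out / "cohort.csv")
        matrix.to_frame().to_csv(out / "correlation_matrix.csv", index=False)
        (out / "correlation_matrix.json").write_text(
            json.dumps(matrix.to_dict(), indent=1)
        )
        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        from .plotting import plot_pair_grid

        fig = plot_pair_grid(measured, path=figdir / "pairs.png")
        import matplotlib.pyplot as plt

        plt.close(fig)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        report.out_dir = out
    return report
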