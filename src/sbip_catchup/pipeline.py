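"""End-to-end study orchestration: simulate/read → cohorts → coverage →
differences → volume → deficits, with a deterministic run manifest.

A :class:`StudyConfig` names either the three registry CSVs (``inputs``) or a
synthetic-study block (``simulate`` in full, or the ``simulate_default``
shorthand for the bundled study conditions); exactly one source must be
present. Reruns with an identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from . import study
from .administration_volume import PeriodVolume, period_volumes
from .cohort_builder import (
    Cohort,
    CohortMemberRow,
    CohortSpec,
    ExclusionRow,
    build_cohorts,
    default_specs,
)
from .coverage_engine import (
    CoveragePoint,
    CoverageDifferencePoint,
    coverage_difference,
    cumulative_coverage,
    doses_frame,
)
from .dates import entry_month, month_label, parse_month, reference_month
from .deficit_projection import deficit_table
from .errors import ConfigError, PipelineError
from .registry_model import SeriesSpec, read_registry, write_table
from .synthetic_registry import (
    GroundTruthDeficit,
    GroundTruthPoint,
    SimulationConfig,
    default_simulation_config,
    simulate as run_simulation,
)

log = logging.getLogger(__name__)

__version__ = "1.0.0"

STAGE_TARGETS = ("registry", "cohorts", "coverage", "diff", "volume", "deficits")


class InputPaths(BaseModel):
    persons: str
    enrollments: str
    doses: str


class SimulateDefault(BaseModel):
    """Shorthand for the bundled synthetic study conditions."""

    seed: int = Field(ge=0)
    cohort_size: int = Field(default=5000, ge=0)


class StudyConfig(BaseModel):
    seed: Optional[int] = None  # overrides the simulation block's seed
    observation_end: str = study.OBSERVATION_END
    ci_level: float = Field(default=0.95, gt=0.0, lt=1.0)
    inputs: Optional[InputPaths] = None
    simulate: Optional[SimulationConfig] = None
    simulate_default: Optional[SimulateDefault] = None
    volume_count_mode: str = "all_doses"

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "StudyConfig":
        sources = [
            s for s in (self.inputs, self.simulate, self.simulate_default) if s is not None
        ]
        if len(sources) != 1:
            raise ValueError(
                "exactly one of 'inputs', 'simulate', 'simulate_default' must be set"
            )
        if self.volume_count_mode not in ("all_doses", "first_dose_only"):
            raise ValueError(f"unknown volume_count_mode {self.volume_count_mode!r}")
        return self

    def resolved_simulation(self, seed_override: Optional[int] = None) -> Optional[SimulationConfig]:
        """The effective simulation config, if this is a synthetic study."""
        sim = self.simulate
        if self.simulate_default is not None:
            sim = default_simulation_config(
                seed=self.simulate_default.seed,
                cohort_size=self.simulate_default.cohort_size,
            )
        if sim is None:
            return None
        seed = seed_override if seed_override is not None else self.seed
        if seed is not None:
            sim = sim.model_copy(update={"seed": seed})
        return sim


def _specs_from_simulation(sim: SimulationConfig, observation_end: str) -> list[CohortSpec]:
    specs = []
    for c in sim.cohorts:
        ref = month_label(reference_month(c.school_year))
        start = month_label(entry_month(c.school_year)) if c.program == 1 else ref
        specs.append(
            CohortSpec(
                grade=c.grade,
                school_year=c.school_year,
                role=c.role,
                age_window=study.AGE_WINDOWS[c.grade],
                reference_month=ref,
                coverage_start_month=start,
                observation_end=observation_end,
                program_grade=c.program,
            )
        )
    return specs


def _registry_from_simulation(sim: SimulationConfig) -> dict[int, list[SeriesSpec]]:
    registry: dict[int, list[SeriesSpec]] = {}
    for s in sim.series:
        registry.setdefault(s.grade, []).append(
            SeriesSpec(
                antigen_group=s.antigen_group,
                grade=s.grade,
                required_doses_by_cohort_year=dict(s.required_doses),
                label=s.antigen_group,
            )
        )
    return registry


def _config_hash(config: StudyConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()


def run_pipeline(
    config: StudyConfig,
    out_dir: str | Path,
    seed: Optional[int] = None,
    targets: Sequence[str] = ("all",),
) -> dict:
    """Execute the study and write result tables plus ``manifest.json``.

    ``targets`` selects which outputs to write ("all" or a subset of
    ``registry, cohorts, coverage, diff, volume, deficits``); prerequisite
    stages always run in memory. On any stage failure, files written by this
    run are removed and a :class:`PipelineError` naming the stage is raised.
    """
    wanted = set(STAGE_TARGETS) if "all" in targets else set(targets)
    unknown = wanted - set(STAGE_TARGETS)
    if unknown:
        raise ConfigError(f"unknown pipeline target(s): {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "tool": "sbip-catchup",
        "version": __version__,
        "config_sha256": _config_hash(config),
        "seed": seed if seed is not None else config.seed,
        "stages": {},
    }

    def _write(rows, name: str, record_type=None) -> None:
        path = out_dir / name
        write_table(rows, path, record_type=record_type)
        written.append(path)
        manifest["stages"][name] = len(rows)

    stage = "configure"
    try:
        sim = config.resolved_simulation(seed_override=seed)
        if sim is not None:
            stage = "simulate"
            log.info("simulating registry (seed=%d, %d cohorts)", sim.seed, len(sim.cohorts))
            persons, enrollments, doses, truth = run_simulation(sim)
            manifest["seed"] = sim.seed
            if "registry" in wanted:
                from .registry_model import DoseRecord, EnrollmentRecord, PersonRecord

                _write(persons, "persons.csv", PersonRecord)
                _write(enrollments, "enrollments.csv", EnrollmentRecord)
                _write(doses, "doses.csv", DoseRecord)
                _write(list(truth.points), "ground_truth_coverage.csv", GroundTruthPoint)
                _write(list(truth.deficits), "ground_truth_deficits.csv", GroundTruthDeficit)
            specs = _specs_from_simulation(sim, config.observation_end)
            registry = _registry_from_simulation(sim)
        else:
            stage = "read"
            assert config.inputs is not None
            specs = default_specs(observation_end=config.observation_end)
            registry = study.default_series_registry()
            known = {s.antigen_group for group in registry.values() for s in group}
            persons, enrollments, doses = read_registry(
                config.inputs.persons,
                config.inputs.enrollments,
                config.inputs.doses,
                known_antigens=known,
            )
        log.info(
            "registry: %d persons, %d enrollments, %d doses",
            len(persons), len(enrollments), len(doses),
        )

        stage = "build-cohorts"
        cohorts = build_cohorts(persons, enrollments, specs)
        for c in cohorts:
            log.info(
                "cohort %s (%s): %d members, excluded %s",
                c.cohort_id, c.spec.role, c.size, dict(c.exclusion_tally) or "none",
            )
        if "cohorts" in wanted:
            member_rows = [
                CohortMemberRow(c.cohort_id, pid) for c in cohorts for pid in c.members
            ]
            _write(member_rows, "cohorts.csv", CohortMemberRow)
            excl_rows = [
                ExclusionRow(c.cohort_id, reason, count)
                for c in cohorts
                for reason, count in c.exclusion_tally.items()
            ]
            _write(excl_rows, "exclusions.csv", ExclusionRow)
        if not wanted - {"registry", "cohorts"}:
            _finish(manifest, out_dir, written)
            return manifest

        stage = "coverage"
        frame = doses_frame(doses)
        coverage: list[CoveragePoint] = []
        for cohort in cohorts:
            for series in registry.get(cohort.spec.program_grade, []):
                complete_k = series.required_doses(cohort.spec.school_year)
                coverage.extend(
                    cumulative_coverage(cohort, frame, series, level=config.ci_level)
                )
                if complete_k > 1:  # 1+ dose view alongside the complete series
                    coverage.extend(
                        cumulative_coverage(
                            cohort, frame, series, level=config.ci_level, dose_threshold=1
                        )
                    )
        if "coverage" in wanted:
            _write(coverage, "coverage.csv", CoveragePoint)

        stage = "diff"
        diffs: list[CoverageDifferencePoint] = []
        by_cohort = {c.cohort_id: c for c in cohorts}
        pre_by_grade = {
            c.spec.program_grade: c for c in cohorts if c.spec.role == "prepandemic"
        }

        def _points(cohort: Cohort, antigen: str, threshold: int) -> list[CoveragePoint]:
            return [
                p
                for p in coverage
                if p.cohort_id == cohort.cohort_id
                and p.antigen_group == antigen
                and p.dose_threshold == threshold
            ]

        for cohort in cohorts:
            if cohort.spec.role != "pandemic":
                continue
            pre = pre_by_grade.get(cohort.spec.program_grade)
            if pre is None:
                raise ConfigError(
                    f"no prepandemic cohort for grade {cohort.spec.program_grade}"
                )
            for series in registry.get(cohort.spec.program_grade, []):
                pan_k = series.required_doses(cohort.spec.school_year)
                pre_k = series.required_doses(pre.spec.school_year)
                diffs.extend(
                    coverage_difference(
                        _points(cohort, series.antigen_group, pan_k),
                        _points(pre, series.antigen_group, pre_k),
                        level=config.ci_level,
                    )
                )
        if "diff" in wanted:
            _write(diffs, "coverage_diff.csv", CoverageDifferencePoint)

        stage = "volume"
        study_range = (
            month_label(min(parse_month(c.spec.coverage_start_month) for c in cohorts)),
            config.observation_end,
        )
        volumes: list[PeriodVolume] = []
        for cohort in cohorts:
            for series in registry.get(cohort.spec.program_grade, []):
                volumes.extend(
                    period_volumes(
                        cohort, doses, series, study_range, config.volume_count_mode
                    )
                )
        if "volume" in wanted:
            _write(volumes, "volume.csv", PeriodVolume)

        stage = "deficits"
        if "deficits" in wanted:
            reports = deficit_table(coverage, volumes, cohorts, registry, study_range)
            for r in reports:
                log.info(
                    "grade %d %s: deficit %+d (min %.2f / avg %.2f years to clear)",
                    r.grade, r.antigen_group, r.cumulative_deficit,
                    r.min_years_to_clear, r.avg_years_to_clear,
                )
            _write(reports, "deficits.csv")

        _finish(manifest, out_dir, written)
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _finish(manifest: dict, out_dir: Path, written: list[Path]) -> None:
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(path)
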