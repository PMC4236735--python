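"""End-to-end draft-model pipeline: FBA -> reduction -> rate laws ->
concentrations -> reference fluxes -> validation.

Each stage writes its intermediate SBML model to the output directory, so
a run is fully inspectable and the stages can equally be driven one at a
time through the library (or the CLI subcommands) with identical results.
A plain-text log and a machine-readable JSON manifest record the
configuration and the validation outcome.
"""
from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .assembly import (
    DEFAULT_CONCENTRATION,
    add_metabolites,
    set_fluxes,
    validate_reference_state,
)
from .errors import KindraftError
from .fba import FBAProblem, reference_flux_workflow
from .network import normalize_directionality, read_sbml, write_sbml
from .rate_laws import LAW_TYPES, translate_kinetics
from .reduction import reduce_network, write_reduction_archive
from .tables import read_removal_list, read_value_table, write_value_table


@dataclass
class PipelineConfig:
    model_path: str
    concentration_table_path: str | None = None
    flux_table_path: str | None = None  # else run FBA with the fields below
    fba_objective: str | None = None
    fba_fixed_fluxes: dict[str, float] = field(default_factory=dict)
    fba_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    removal_list_path: str | None = None
    default_concentration: float = DEFAULT_CONCENTRATION
    law_type: str = "linlog"
    output_directory: str = "kindraft_out"
    tolerance: float = 1e-9

    def validate(self) -> None:
        if self.law_type not in LAW_TYPES:
            raise KindraftError(
                f"law_type must be one of {', '.join(LAW_TYPES)}, "
                f"got {self.law_type!r}"
            )
        if self.default_concentration < 0:
            raise KindraftError("default_concentration must be >= 0")
        if self.flux_table_path is None and self.fba_objective is None:
            raise KindraftError(
                "either flux_table_path or fba_objective must be given"
            )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        """Load a config file; relative paths resolve against its folder."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        base = os.path.dirname(os.path.abspath(os.fspath(path)))
        config = cls(**raw)
        for attr in ("model_path", "concentration_table_path",
                     "flux_table_path", "removal_list_path",
                     "output_directory"):
            value = getattr(config, attr)
            if value is not None and not os.path.isabs(value):
                setattr(config, attr, os.path.join(base, value))
        config.fba_bounds = {
            k: tuple(v) for k, v in (config.fba_bounds or {}).items()
        }
        return config


@dataclass
class PipelineResult:
    draft_model_path: str
    validation_passed: bool
    max_residual: float
    artifacts: dict[str, str]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the workflow stages in order and write all intermediates.

    Raises :class:`KindraftError` (naming the stage) on the first failing
    stage; artifacts written up to that point are kept.
    """
    config.validate()
    out = config.output_directory
    os.makedirs(out, exist_ok=True)
    artifacts: dict[str, str] = {}
    log_lines: list[str] = []

    def log(message: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"[{stamp}] {message}")

    def emit(name: str, writer) -> str:
        path = os.path.join(out, name)
        writer(path)
        artifacts[name] = path
        return path

    stage = "load model"
    try:
        network = read_sbml(config.model_path)
        log(f"loaded model with {len(network.species)} species, "
            f"{len(network.reactions)} reactions")

        if config.flux_table_path is not None:
            stage = "load fluxes"
            fluxes = read_value_table(config.flux_table_path, kind="flux")
            stage = "normalize directionality"
            network, fluxes = normalize_directionality(network, fluxes)
        else:
            stage = "fba"
            problem = FBAProblem(
                objective_reaction=config.fba_objective,
                fixed_fluxes=dict(config.fba_fixed_fluxes),
                bounds=dict(config.fba_bounds),
            )
            network, fluxes = reference_flux_workflow(network, problem)
            log(f"FBA optimum through {config.fba_objective}: "
                f"{fluxes[network.resolve_reaction(config.fba_objective)]:g}")
        emit("01_normalized_model.xml", lambda p: write_sbml(network, p))
        emit("01_reference_fluxes.tsv", lambda p: write_value_table(fluxes, p))

        if config.removal_list_path is not None:
            stage = "reduction"
            removal = read_removal_list(config.removal_list_path)
            result = reduce_network(network, fluxes, removal)
            network, fluxes = result.reduced_network, result.reduced_fluxes
            log(f"removed {len(removal)} species; "
                f"{len(network.reactions)} reactions remain "
                f"({len(result.lump_map)} lumped)")
            emit("02_reduction.zip", lambda p: write_reduction_archive(result, p))

        stage = "translate kinetics"
        network = translate_kinetics(network, config.law_type)
        emit("03_kinetic_model.xml", lambda p: write_sbml(network, p))

        stage = "add metabolites"
        if config.concentration_table_path is not None:
            known = read_value_table(
                config.concentration_table_path, kind="concentration"
            )
        else:
            from .tables import ConcentrationSet

            known = ConcentrationSet({})
        network, report = add_metabolites(
            network, known, config.default_concentration
        )
        log(f"concentrations: {len(report.assigned)} from table, "
            f"{len(report.defaulted)} defaulted to "
            f"{config.default_concentration} mM, "
            f"{len(report.unmatched)} table entries unmatched")
        emit("04_with_concentrations.xml", lambda p: write_sbml(network, p))

        if config.law_type == "linlog":
            stage = "set fluxes"
            network = set_fluxes(network, fluxes)

        stage = "validate"
        draft_path = emit("05_draft_model.xml", lambda p: write_sbml(network, p))
        validation = validate_reference_state(
            network, config.tolerance,
            reference_fluxes=fluxes if config.law_type == "linlog" else None,
        )
        log(validation.summary())
    except KindraftError as err:
        log(f"stage '{stage}' failed: {err}")
        _write_log(out, log_lines)
        raise KindraftError(f"pipeline stage '{stage}' failed: {err}") from err

    manifest = {
        "kindraft_version": __version__,
        "config": {k: v for k, v in vars(config).items()},
        "artifacts": sorted(artifacts),
        "validation": {
            "passed": validation.passed,
            "max_residual": validation.max_residual,
            "tolerance": validation.tolerance,
        },
    }
    with open(os.path.join(out, "run_manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    _write_log(out, log_lines)
    return PipelineResult(
        draft_model_path=draft_path,
        validation_passed=validation.passed,
        max_residual=validation.max_residual,
        artifacts=artifacts,
    )


def _write_log(out: str, lines: list[str]) -> None:
    with open(os.path.join(out, "run.log"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
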