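"""Run configuration: YAML/JSON configs, validation, test fixtures.

A config file describes one full experiment: the ensemble search, an
optional single scenario, an optional sweep grid, seeds and output
locations.  Unknown keys are rejected so typos fail loudly, and every
validation error names the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from cctradeoff.analysis import SweepGrid
from cctradeoff.ensemble import EnsembleSpec, search_ensemble
from cctradeoff.model import Metacommunity
from cctradeoff.scenarios import PulseSchedule, ScenarioConfig

__all__ = ["RunConfig", "load_config", "dump_config", "make_fixture_ensemble"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _take(d: Mapping[str, Any], allowed: dict[str, Any], section: str) -> dict:
    """Copy ``d`` filling defaults from ``allowed``; reject unknown keys."""
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section}: {', '.join(sorted(unknown))}"
        )
    out = dict(allowed)
    out.update(d)
    return out


@dataclass
class RunConfig:
    """Validated experiment description."""

    ensemble: EnsembleSpec = field(default_factory=EnsembleSpec)
    scenario: ScenarioConfig | None = None
    sweep: SweepGrid | None = None
    seed: int = 0
    outdir: str = "."
    rtol: float = 1e-10
    atol: float = 1e-14
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.scenario is not None:
            if not 1 <= self.scenario.invader_rank <= self.ensemble.N:
                raise ConfigError(
                    f"scenario.invader_rank {self.scenario.invader_rank} "
                    f"out of range 1..{self.ensemble.N}"
                )
        if self.sweep is not None:
            bad = [a for a in self.sweep.invader_ranks
                   if not 1 <= a <= self.ensemble.N]
            if bad:
                raise ConfigError(
                    f"sweep.invader_ranks out of range 1..{self.ensemble.N}: {bad}"
                )
        if self.verbosity not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"verbosity: unknown level {self.verbosity!r}")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "ensemble": self.ensemble.to_dict(),
            "seed": self.seed,
            "outdir": self.outdir,
            "rtol": self.rtol,
            "atol": self.atol,
            "verbosity": self.verbosity,
        }
        if self.scenario is not None:
            s: dict[str, Any] = {
                "invader_rank": self.scenario.invader_rank,
                "h_level": self.scenario.h_level,
                "invader_mortality_delta": self.scenario.invader_mortality_delta,
                "disturbance_mortality": self.scenario.disturbance_mortality,
                "horizon": self.scenario.horizon,
                "n_output": self.scenario.n_output,
                "extinction_threshold": self.scenario.extinction_threshold,
            }
            if self.scenario.h_pulse is not None:
                s["h_pulse"] = {
                    "onset": self.scenario.h_pulse.onset,
                    "duration": self.scenario.h_pulse.duration,
                    "level": self.scenario.h_pulse.level,
                }
            d["scenario"] = s
        if self.sweep is not None:
            d["sweep"] = {
                "invader_ranks": list(self.sweep.invader_ranks),
                "h_values": list(self.sweep.h_values),
                "mortality_deltas": list(self.sweep.mortality_deltas),
                "disturbance_levels": list(self.sweep.disturbance_levels),
            }
        return d


def _build_ensemble(d: Mapping[str, Any]) -> EnsembleSpec:
    defaults = EnsembleSpec().to_dict()
    vals = _take(d, defaults, "ensemble")
    try:
        return EnsembleSpec(**vals)
    except ValueError as exc:
        raise ConfigError(f"ensemble: {exc}") from exc


def _build_scenario(d: Mapping[str, Any]) -> ScenarioConfig:
    defaults = {
        "invader_rank": None, "h_level": 0.0, "h_pulse": None,
        "invader_mortality_delta": 0.0, "disturbance_mortality": None,
        "horizon": 5000.0, "n_output": 64, "extinction_threshold": 1e-4,
    }
    vals = _take(d, defaults, "scenario")
    if vals["invader_rank"] is None:
        raise ConfigError("scenario.invader_rank is required")
    if vals["h_pulse"] is not None:
        pulse = _take(vals["h_pulse"],
                      {"onset": None, "duration": None, "level": None},
                      "scenario.h_pulse")
        for k, v in pulse.items():
            if v is None:
                raise ConfigError(f"scenario.h_pulse.{k} is required")
        vals["h_pulse"] = PulseSchedule(**pulse)
    try:
        return ScenarioConfig(**vals)
    except ValueError as exc:
        raise ConfigError(f"scenario: {exc}") from exc


def _build_sweep(d: Mapping[str, Any]) -> SweepGrid:
    base = SweepGrid()
    defaults = {
        "invader_ranks": list(base.invader_ranks),
        "h_values": list(base.h_values),
        "mortality_deltas": list(base.mortality_deltas),
        "disturbance_levels": list(base.disturbance_levels),
    }
    vals = _take(d, defaults, "sweep")
    try:
        return SweepGrid(**{k: tuple(v) for k, v in vals.items()})
    except ValueError as exc:
        raise ConfigError(f"sweep: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML or JSON config file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    top_defaults: dict[str, Any] = {
        "ensemble": {}, "scenario": None, "sweep": None,
        "seed": 0, "outdir": ".", "rtol": 1e-10, "atol": 1e-14,
        "verbosity": "INFO",
    }
    vals = _take(doc, top_defaults, "config")
    ensemble = _build_ensemble(vals["ensemble"] or {})
    scenario = (_build_scenario(vals["scenario"])
                if vals["scenario"] is not None else None)
    sweep = _build_sweep(vals["sweep"]) if vals["sweep"] is not None else None
    return RunConfig(
        ensemble=ensemble, scenario=scenario, sweep=sweep,
        seed=int(vals["seed"]), outdir=str(vals["outdir"]),
        rtol=float(vals["rtol"]), atol=float(vals["atol"]),
        verbosity=str(vals["verbosity"]),
    )


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def make_fixture_ensemble(
    n_species: int, count: int, seed: int
) -> list[Metacommunity]:
    """Small feasible communities for test suites.

    At 2-6 species feasible draws are common, so a seeded search returns
    ``count`` coexisting communities in well under a second with no I/O.
    """
    if not 2 <= n_species <= 6:
        raise ValueError("fixture ensembles support 2..6 species")
    spec = EnsembleSpec(
        N=n_species, c_low=0.0, c_high=5.0, m0=0.05,
        target_count=count, max_draws=5_000_000, seed=seed,
    )
    communities, report = search_ensemble(spec, batch_size=20_000)
    if report.exhausted:  # pragma: no cover - budget is generous
        raise RuntimeError("fixture search exhausted its draw budget")
    return communities
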