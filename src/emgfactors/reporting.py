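"""Experiment driver: one config in, a reproducible report bundle out.

Runs synthesize -> preprocess -> features -> scenarios + feature-space
metrics and emits CSV summary tables (mean +- SD per scenario per level)
plus a JSON bundle with a provenance block (config hash, seeds, package
version).  All randomness flows from the config seeds; outputs carry no
wall-clock state, so identical configs give byte-identical bundles.

The tables mirror the layout of a typical condition-robustness study
(per-level motion accuracies, per-type factor accuracies, per-motion
trial-control accuracies), but every number in them is a property of the
synthetic generator's conditions — magnitudes are not measurements of
any real cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .feature_space import baseline_ri, between_factor_ri, msi_protocol
from .pipeline import compute_features
from .preprocess import WindowSpec
from .scenarios import (run_bfc, run_factor_classification,
                        run_trial_classification, run_wfc)
from .selection import baseline_level, factor_view, kind_levels
from .simulate import GeneratorConfig

log = logging.getLogger("emgfactors")

KNOWN_SCENARIOS = ("wfc", "bfc", "type1", "type2", "type3", "type4", "type5",
                   "trial", "feature_space")
_BANNER = ("Synthetic-data report: directions and orderings are the "
           "reproducible content; magnitudes are generator properties, "
           "not measurements of a real cohort.")


@dataclass(frozen=True)
class RunConfig:
    """Everything one experiment run depends on, seeds included."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_subjects: int = 4
    window_ms: float = 200.0
    overlap_ms: float = 50.0
    eps_scale: float = 0.01
    scenarios: tuple = ("wfc", "bfc", "type1", "type2", "type3", "type4",
                        "type5", "trial", "feature_space")
    metrics_seed: int = 0
    ri_draws: int = 10
    outdir: str | None = None

    def validate(self) -> None:
        unknown = [s for s in self.scenarios if s not in KNOWN_SCENARIOS]
        if unknown:
            raise ValueError(f"unknown scenario(s) {unknown}; "
                             f"known: {KNOWN_SCENARIOS}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        self.generator.validate()

    def subject_ids(self) -> list:
        return [f"sub{i + 1:02d}" for i in range(self.n_subjects)]

    def window(self) -> WindowSpec:
        return WindowSpec(fs=self.generator.fs, window_ms=self.window_ms,
                          overlap_ms=self.overlap_ms)


def config_dict(config: RunConfig) -> dict:
    """Config as plain data, minus the output location (which is where
    the report lands, not what it contains)."""
    d = dataclasses.asdict(config)
    d.pop("outdir", None)
    return d


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config_dict(config), sort_keys=True,
                      default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _summ(result) -> dict:
    return {"mean": result.mean, "sd": result.sd, "n_test": result.n_test}


def _run_scenarios(config: RunConfig, features: pd.DataFrame) -> dict:
    gen = config.generator
    out: dict = {}
    for name in config.scenarios:
        log.info("scenario %s on %d feature rows", name, len(features))
        try:
            if name == "wfc":
                out[name] = {}
                for kind in ("position", "shift"):
                    levels = kind_levels(factor_view(features, kind), kind)
                    out[name][kind] = {
                        lvl: _summ(run_wfc(features, kind, lvl))
                        for lvl in levels}
            elif name == "bfc":
                out[name] = {
                    kind: {lvl: _summ(res) for lvl, res in
                           run_bfc(features, kind).items()}
                    for kind in ("position", "shift")}
            elif name in ("type1", "type2"):
                ftype = int(name[-1])
                out[name] = {
                    motion: _summ(run_factor_classification(
                        features, ftype, motion=motion))
                    for motion in gen.motions}
            elif name in ("type3", "type4", "type5"):
                out[name] = _summ(run_factor_classification(
                    features, int(name[-1])))
            elif name == "trial":
                out[name] = {}
                for kind in ("position", "shift"):
                    view = factor_view(features, kind)
                    for lvl in kind_levels(view, kind):
                        if kind == "shift" and lvl == baseline_level("shift"):
                            continue  # S0 is the P1 data, reported once
                        out[name][lvl] = _summ(run_trial_classification(
                            features, kind, lvl))
            elif name == "feature_space":
                out[name] = {}
                for kind in ("position", "shift"):
                    out[name][kind] = {
                        "baseline_ri": baseline_ri(features, kind).to_dict(),
                        "between_ri": between_factor_ri(
                            features, kind, seed=config.metrics_seed,
                            n_draws=config.ri_draws).to_dict(),
                        "msi": msi_protocol(features, kind),
                    }
        except Exception as err:
            raise RuntimeError(f"scenario {name!r} failed: {err}") from err
    return out


def _tables(results: dict) -> dict:
    """Flatten the result dict into per-scenario summary DataFrames."""
    tables = {}
    for name, res in results.items():
        rows = []
        if name in ("wfc", "bfc"):
            for kind, levels in res.items():
                for lvl, s in levels.items():
                    rows.append({"factor_kind": kind, "level": lvl, **s})
        elif name in ("type1", "type2"):
            rows = [{"motion": m, **s} for m, s in res.items()]
        elif name in ("type3", "type4", "type5"):
            rows = [res]
        elif name == "trial":
            rows = [{"level": lvl, **s} for lvl, s in res.items()]
        elif name == "feature_space":
            for kind, metrics in res.items():
                for motion in metrics["baseline_ri"]:
                    rows.append({
                        "factor_kind": kind, "motion": motion,
                        "baseline_ri": metrics["baseline_ri"][motion],
                        "between_ri": metrics["between_ri"][motion],
                        "msi_baseline": metrics["msi"]["baseline"],
                        "msi_between": metrics["msi"]["between"],
                    })
        tables[name] = pd.DataFrame(rows)
    return tables


def run_experiment(config: RunConfig) -> dict:
    """Execute the full pipeline for one config.

    Returns the report bundle (results + provenance); when
    ``config.outdir`` is set, also writes ``report.json`` and one CSV
    table per scenario under ``tables/``.
    """
    config.validate()  # fail on unknown scenarios before any compute
    subjects = config.subject_ids()
    log.info("synthesizing %d subject(s)", len(subjects))
    features = compute_features(config.generator, subjects,
                                window=config.window(),
                                eps_scale=config.eps_scale)
    log.info("feature table: %d windows x %d columns", *features.shape)
    results = _run_scenarios(config, features)
    bundle = {
        "banner": _BANNER,
        "provenance": {
            "config": config_dict(config),
            "config_hash": config_hash(config),
            "package_version": __version__,
            "n_feature_rows": int(len(features)),
        },
        "results": results,
    }
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True, default=float)
            + "\n")
        tdir = outdir / "tables"
        tdir.mkdir(exist_ok=True)
        for name, table in _tables(results).items():
            table.to_csv(tdir / f"{name}.csv", index=False,
                         float_format="%.6g")
    return bundle
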