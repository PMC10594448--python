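"""End-to-end pipeline: fixtures -> ingest -> rank -> ORA -> SPR.

One reproducible invocation from a single config: generates (or loads)
the input tables, builds the vault, ranks candidates, runs
overrepresentation analysis on the top-ranked genes, and fits the SPR
sensorgrams.  Identical config + inputs produce bitwise-identical CSV
and JSON artifacts; per-stage timings go to the log, never into the
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import __version__, ora as ora_mod, ranking, spr as spr_mod, synth
from .store import Vault
from .types import ValidationError

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    ``top_n`` is the number of highest-ranked target genes submitted to
    ORA (default 100); ``fdr_threshold`` the significance cut (default
    0.1).  The fixture and sensorgram sub-configs drive the synthetic
    generators when no input paths are given.
    """

    out_dir: str = "vault_run"
    seed: int = 0
    cancer_type: str = "ovarian cancer"
    min_patient_fraction: float = 0.5
    apply_tm_filter: bool = True
    tm_min_agree: int = 5
    tm_required_segments: int = 1
    tissue_collapse: str = "max"
    top_n: int = 100
    ora_min_size: int = 5
    ora_max_size: int = 2000
    fdr_threshold: float = 0.1
    fixture: synth.FixtureConfig = field(default_factory=synth.FixtureConfig)
    sensorgram: synth.SimSensorgramConfig = field(
        default_factory=synth.SimSensorgramConfig)

    def __post_init__(self):
        if self.top_n < 1:
            raise ValidationError("top_n: must be >= 1")
        if not (0.0 <= self.min_patient_fraction < 1.0):
            raise ValidationError("min_patient_fraction: must be in [0, 1)")
        if not (0.0 < self.fdr_threshold <= 1.0):
            raise ValidationError("fdr_threshold: must be in (0, 1]")
        # Propagate the run seed into sub-configs left at their defaults.
        if self.fixture.seed != self.seed:
            object.__setattr__(
                self, "fixture", dataclasses.replace(self.fixture, seed=self.seed))
        if self.sensorgram.seed != self.seed:
            object.__setattr__(
                self, "sensorgram",
                dataclasses.replace(self.sensorgram, seed=self.seed))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        fixture = synth.FixtureConfig(**{
            **raw.pop("fixture", {}),
        }) if "fixture" in raw else None
        sensorgram = synth.SimSensorgramConfig(**{
            **raw.pop("sensorgram", {}),
        }) if "sensorgram" in raw else None
        kwargs = dict(raw)
        if fixture is not None:
            kwargs["fixture"] = fixture
        if sensorgram is not None:
            kwargs["sensorgram"] = sensorgram
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fixture"]["predictor_names"] = list(d["fixture"]["predictor_names"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Paths, summary counts and per-stage status of one run."""

    config_hash: str
    version: str
    stages: Dict[str, str] = field(default_factory=dict)
    paths: Dict[str, str] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _stage(report: RunReport, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                report.stages[name] = "ok"
                logger.info("stage %s: ok (%.2f s)", name, dt)
            else:
                report.stages[name] = f"failed: {exc}"
                logger.error("stage %s: FAILED after %.2f s: %s", name, dt, exc)
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run all stages; any stage failure aborts with the stage named."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=cfg.config_hash(), version=__version__)

    with _stage(report, "simulate"):
        fixture_paths = synth.write_fixture_set(
            cfg.fixture, out / "fixtures", cfg.cancer_type)
        spr_path = out / "fixtures" / "sensorgrams.csv"
        cycles = synth.simulate_sensorgram(cfg.sensorgram)
        synth.write_sensorgrams_csv(cycles, spr_path)
        report.paths.update({k: str(v) for k, v in fixture_paths.items()})
        report.paths["sensorgrams"] = str(spr_path)

    with _stage(report, "ingest"):
        db_path = out / "vault.db"
        if db_path.exists():
            db_path.unlink()
        vault = Vault.create(db_path)
        vault.ingest(fixture_paths["proteome"], fixture_paths["tm"],
                     fixture_paths["healthy"], fixture_paths["cancer"])
        report.paths["db"] = str(db_path)
        report.counts.update(vault.counts())

    with _stage(report, "rank"):
        targets = ranking.rank_targets(
            vault, cfg.cancer_type,
            min_patient_fraction=cfg.min_patient_fraction,
            apply_tm_filter=cfg.apply_tm_filter,
            min_agree=cfg.tm_min_agree,
            required_segments=cfg.tm_required_segments,
            tissue_collapse=cfg.tissue_collapse,
        )
        rank_path = out / "ranking.csv"
        ranking.export_ranking(targets, rank_path)
        report.paths["ranking"] = str(rank_path)
        report.counts["candidates"] = len(targets)

    with _stage(report, "ora"):
        if len(targets) < cfg.top_n:
            logger.warning("ora: only %d candidates for top_n=%d; using all",
                           len(targets), cfg.top_n)
        query = [t.gene_symbol for t in targets[: cfg.top_n]]
        universe = [p.gene_symbol for p in vault.proteins()]
        sets = ora_mod.read_gmt(fixture_paths["gene_sets"])
        results = ora_mod.ora(query, universe, sets,
                              min_size=cfg.ora_min_size, max_size=cfg.ora_max_size)
        ora_path = out / "ora.csv"
        ora_mod.export_ora(results, ora_path)
        report.paths["ora"] = str(ora_path)
        report.counts["gene_sets_tested"] = len(results)
        report.counts["gene_sets_significant"] = len(
            ora_mod.significant(results, cfg.fdr_threshold))

    with _stage(report, "spr"):
        cycles = synth.read_sensorgrams_csv(spr_path)
        corrected = spr_mod.double_reference_series(cycles)
        full = spr_mod.fit_full_kinetics(corrected)
        offrate = spr_mod.fit_dissociation(corrected, rmax_for_chi2=full.Rmax)
        spr_report = {
            "full_kinetics": _fit_to_dict(full),
            "offrate_screen": _fit_to_dict(offrate),
        }
        spr_report_path = out / "spr_report.json"
        spr_report_path.write_text(
            json.dumps(spr_report, indent=2, sort_keys=True), encoding="utf-8")
        report.paths["spr_report"] = str(spr_report_path)

    report_path = out / "run_report.json"
    report_path.write_text(report.to_json(), encoding="utf-8")
    report.paths["run_report"] = str(report_path)
    return report


def _fit_to_dict(fit) -> dict:
    import math

    d = dataclasses.asdict(fit)
    d["r0"] = {k: v for k, v in sorted(d["r0"].items())}
    # Dissociation-only fits have no ka/KD; keep the JSON strict.
    for key in ("ka", "kd", "KD"):
        if isinstance(d[key], float) and math.isnan(d[key]):
            d[key] = None
    return d
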