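"""End-to-end pipeline driver.

``run_pipeline`` chains simulate -> normalize -> screen (and optionally the
combination-index and xenograft/TGI stages) on one configuration, writing
every stage artifact plus a JSON manifest recording the package version, the
seed, all parameter values and a sha256 checksum per output file.  Re-running
the same configuration reproduces identical checksums, so a hit list is
always auditable back to its parameters and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PipelineError, SynscreenError
from .io import (FA_SCHEMA, TRAJECTORY_SCHEMA, WELLS_SCHEMA,
                 read_table, write_table)
from .median_effect import (ci_table, combination_index,
                            fit_median_effect, fit_table)
from .normalize import normalize_plate
from .screen import score_screen, volcano_table
from .simulate import (MedianEffectParams, ScreenSimConfig, XenoSimConfig,
                       simulate_combo_matrix, simulate_screen,
                       simulate_xenograft)
from .tgi import tgi_from_trajectories

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "normalize", "screen", "ci", "tgi")


@dataclass
class RunConfig:
    """Pipeline run configuration (usually loaded from a YAML file)."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "normalize", "screen")
    simulate: dict[str, Any] = field(default_factory=dict)
    screen: dict[str, Any] = field(default_factory=dict)
    ci: dict[str, Any] = field(default_factory=dict)
    tgi: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {', '.join(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(bad))}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the manifest.

    A stage failure aborts with a :class:`PipelineError` naming the stage;
    outputs of earlier stages are preserved on disk.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def run_stage(name, fn):
        try:
            fn()
        except PipelineError:
            raise
        except SynscreenError as exc:
            raise PipelineError(name, str(exc)) from exc

    def stage_simulate():
        cfg = ScreenSimConfig(seed=config.seed, **config.simulate)
        wells, truth = simulate_screen(cfg)
        artifacts["wells"] = write_table(wells, out / "wells.tsv")
        truth_df = truth.compounds.copy()
        for lab, fa in truth.fa_inducer.items():
            truth_df[f"fa_inducer_{lab}"] = fa
        artifacts["screen_truth"] = write_table(truth_df, out / "screen_truth.tsv")

    def stage_normalize():
        wells = read_table(out / "wells.tsv", WELLS_SCHEMA)
        fa = normalize_plate(wells)
        artifacts["fa"] = write_table(fa, out / "fa.tsv")

    def stage_screen():
        fa = read_table(out / "fa.tsv", FA_SCHEMA)
        results = score_screen(fa, **config.screen)
        artifacts["screen_results"] = write_table(results, out / "screen_results.tsv")
        hits = results[results["is_hit"]]
        artifacts["hits"] = write_table(hits, out / "hits.tsv")
        artifacts["volcano"] = write_table(volcano_table(results), out / "volcano.tsv")

    def stage_ci():
        p = dict(config.ci)
        params_a = MedianEffectParams(p.pop("dm_a", 2.0), p.pop("m_a", 1.5))
        params_b = MedianEffectParams(p.pop("dm_b", 8.0), p.pop("m_b", 1.5))
        ratio = tuple(p.pop("ratio", (0.5, 0.5)))
        fa_levels = tuple(p.pop("fa_levels", (0.5, 0.75, 0.9)))
        design = simulate_combo_matrix(
            params_a, params_b, ratio=ratio, seed=config.seed, **p
        )
        series = (design.drug_a, design.drug_b, design.combo)
        frames = [s.to_frame() for s in series]
        artifacts["series"] = write_table(pd.concat(frames), out / "series.tsv")
        fits = [fit_median_effect(s) for s in series]
        artifacts["fits"] = write_table(fit_table(fits), out / "fits.tsv")
        ci = combination_index(fits[0], fits[1], fits[2], ratio=ratio,
                               fa_levels=fa_levels)
        artifacts["ci"] = write_table(ci_table(ci), out / "ci.tsv")

    def stage_tgi():
        p = dict(config.tgi)
        control = p.pop("control", None)
        endpoint_day = p.pop("endpoint_day", None)
        if "groups" in p:
            p["groups"] = [tuple(g) for g in p["groups"]]
        cfg = XenoSimConfig(seed=config.seed, control=control, **p)
        traj, truth = simulate_xenograft(cfg)
        artifacts["trajectories"] = write_table(traj, out / "trajectories.tsv")
        artifacts["xeno_truth"] = write_table(truth, out / "xeno_truth.tsv")
        table = tgi_from_trajectories(
            read_table(out / "trajectories.tsv", TRAJECTORY_SCHEMA),
            control_group=cfg.control,
            endpoint_day=endpoint_day,
        )
        artifacts["tgi"] = write_table(table, out / "tgi.tsv")

    stage_fns = {
        "simulate": stage_simulate,
        "normalize": stage_normalize,
        "screen": stage_screen,
        "ci": stage_ci,
        "tgi": stage_tgi,
    }
    for name in config.stages:
        logger.info("running stage %s", name)
        run_stage(name, stage_fns[name])

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "simulate": config.simulate,
            "screen": config.screen,
            "ci": config.ci,
            "tgi": config.tgi,
        },
        "artifacts": {
            key: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for key, p in artifacts.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
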