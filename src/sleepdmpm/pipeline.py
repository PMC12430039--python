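"""Reproducible simulate -> fit -> contrast -> report pipeline.

A :class:`RunConfig` describes a run (mode, sizes, MCMC settings, seed,
output directory) and round-trips losslessly to YAML.  Every artifact a
stage writes is listed, with a SHA-256 hash, in the run manifest; the seed
is recorded in every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .do_contrast import ContrastResult, contrast_analysis
from .fit_bayes import MCMCConfig, PosteriorDraws, fit
from .panel_data import SUBSAMPLES, load_panel, write_panel
from .report import forest_plot, render_summary
from .synthetic_data import GeneratorConfig, generate_panel, write_true_params

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("sleepdmpm")

MODES = ("simulate", "fit", "contrast", "report", "full")


@dataclass
class RunConfig:
    mode: str = "full"
    out_dir: str = "sleepdmpm_run"
    seed: int = 1
    subsamples: tuple[str, ...] = SUBSAMPLES
    # generator
    n_subjects: int = 100
    n_days: int = 6
    # mcmc
    n_chains: int = 4
    n_warmup: int = 500
    n_iter: int = 500
    # contrast
    n_rep: int = 50
    thin_to: int = 100
    make_plot: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        self.subsamples = tuple(self.subsamples)
        unknown = set(self.subsamples) - set(SUBSAMPLES)
        if unknown:
            raise ValueError(f"unknown subsamples {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["subsamples"] = tuple(d.get("subsamples", SUBSAMPLES))
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(out: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s",
                            datefmt="%Y-%m-%dT%H:%M:%S")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "run.log")):
        h.setFormatter(fmt)
        logger.addHandler(h)


def _paths(out: Path, sub: str) -> dict[str, Path]:
    return {
        "panel": out / f"panel_{sub}.csv",
        "true_params": out / f"true_params_{sub}.json",
        "draws": out / f"draws_{sub}.csv",
        "diagnostics": out / f"diagnostics_{sub}.json",
        "contrast_csv": out / f"contrast_{sub}.csv",
        "contrast_json": out / f"contrast_{sub}.json",
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages per subsample and write a manifest.

    Returns the manifest dict; on a stage failure the manifest records the
    stage and error and the exception is re-raised after the manifest is
    written (the CLI converts it to a nonzero exit).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {},
        "stages": [],
    }
    do = {
        "simulate": config.mode in ("simulate", "full"),
        "fit": config.mode in ("fit", "full"),
        "contrast": config.mode in ("contrast", "full"),
        "report": config.mode in ("report", "full"),
    }
    results: dict[str, ContrastResult] = {}
    try:
        for k, sub in enumerate(config.subsamples):
            p = _paths(out, sub)
            if do["simulate"]:
                logger.info("simulate %s", sub)
                gcfg = GeneratorConfig(
                    n_subjects=config.n_subjects, n_days=config.n_days,
                    seed=(config.seed * 7919 + k) % (2**31 - 1), subsample=sub,
                )
                panel, true_params = generate_panel(gcfg)
                write_panel(panel, p["panel"])
                write_true_params(true_params, p["true_params"])
                manifest["stages"].append(f"simulate:{sub}")
            if do["fit"]:
                if not p["panel"].exists():
                    raise FileNotFoundError(
                        f"fit stage needs {p['panel']}; run simulate first or place "
                        "a panel CSV there"
                    )
                logger.info("fit %s", sub)
                panel = load_panel(p["panel"]).restrict(sub)
                draws = fit(panel, mcmc=MCMCConfig(
                    n_chains=config.n_chains, n_warmup=config.n_warmup,
                    n_iter=config.n_iter, seed=config.seed + k,
                ))
                draws.save(p["draws"])
                diag = draws.diagnostics.to_dict(orient="records")
                p["diagnostics"].write_text(json.dumps(
                    {"seed": config.seed, "warnings": draws.warnings,
                     "accept_rate": draws.accept_rate, "parameters": diag}, indent=1))
                manifest["stages"].append(f"fit:{sub}")
            if do["contrast"]:
                for need in ("panel", "draws"):
                    if not p[need].exists():
                        raise FileNotFoundError(
                            f"contrast stage needs {p[need]}; run earlier stages first"
                        )
                logger.info("contrast %s", sub)
                panel = load_panel(p["panel"]).restrict(sub)
                draws = PosteriorDraws.load(p["draws"], seed=config.seed)
                res = contrast_analysis(
                    draws, panel, n_rep=config.n_rep, seed=config.seed,
                    thin_to=config.thin_to,
                )
                res.to_csv(p["contrast_csv"])
                p["contrast_json"].write_text(json.dumps(res.to_json_dict(), indent=1))
                results[sub] = res
                manifest["stages"].append(f"contrast:{sub}")
        if do["report"]:
            logger.info("report")
            to_render: dict = dict(results)
            if not to_render:
                import pandas as pd
                for sub in config.subsamples:
                    p = _paths(out, sub)
                    if not p["contrast_csv"].exists():
                        raise FileNotFoundError(
                            f"report stage needs {p['contrast_csv']}"
                        )
                    to_render[sub] = pd.read_csv(p["contrast_csv"])
            (out / "report.txt").write_text(render_summary(to_render))
            if config.make_plot and results:
                forest_plot(results, out / "forest.svg")
            manifest["stages"].append("report")
    except Exception as exc:  # record, then propagate
        manifest["error"] = {"stage": manifest["stages"][-1] if manifest["stages"]
                             else "start", "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    for f in sorted(out.iterdir()):
        if f.name not in ("manifest.json", "run.log"):
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
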