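"""End-to-end orchestration: spectra -> PCA -> cosinor LMM -> summaries.

Each HSV channel is analysed as an independent model.  All artifacts are
written under the configured output directory and listed in a manifest
carrying the config hash and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .cosinor import MCMCSettings, PriorSpec, build_design, fit_cosinor_lmm
from .pca import fit_pca, score_pc1, spectra_to_matrix
from .spectra import (DEFAULT_BINS, build_spectrum, remove_specular, rgb_to_hsv)
from .summaries import summarize_posterior

__all__ = ["RunConfig", "run_pipeline", "compute_spectra", "flatten_summary"]

log = logging.getLogger("sicolor")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML/JSON."""

    metadata_path: str
    pixel_table_path: str
    output_dir: str
    channels: tuple = ("H", "S", "V")
    n_bins: dict = field(default_factory=lambda: dict(DEFAULT_BINS))
    specular_v_min: float = 0.95
    specular_s_max: float = 0.10
    tau: float = 365.0
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        priors = PriorSpec(**raw.pop("priors", {}))
        mcmc = MCMCSettings(**raw.pop("mcmc", {}))
        if "channels" in raw:
            raw["channels"] = tuple(raw["channels"])
        return cls(priors=priors, mcmc=mcmc, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        return d


def compute_spectra(pixel_sets, channel: str, n_bins: int | None = None,
                    v_min: float = 0.95, s_max: float = 0.10):
    """RGB pixel sets -> filtered, binned spectra for one channel."""
    out = []
    for ps in pixel_sets:
        hsv = remove_specular(rgb_to_hsv(ps), v_min=v_min, s_max=s_max)
        out.append(build_spectrum(hsv, channel, n_bins))
    return out


def flatten_summary(summary: dict) -> pd.DataFrame:
    """Flat CSV mirror of the nested summary JSON."""
    rows = []

    def walk(prefix, node):
        if isinstance(node, dict):
            for k, v in node.items():
                walk(f"{prefix}.{k}" if prefix else str(k), v)
        elif isinstance(node, (list, tuple)):
            for i, v in enumerate(node):
                walk(f"{prefix}[{i}]", v)
        else:
            rows.append({"key": prefix, "value": node})

    walk("", summary)
    return pd.DataFrame(rows)


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run spectra -> PCA -> fit -> summaries for each configured channel.

    Returns the manifest (also written to disk); stage failures are
    re-raised with the stage name attached.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = sio.config_hash(cfg.to_dict())
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _write_json(name, payload):
        path = outdir / name
        payload = dict(payload)
        payload["_config_hash"] = chash
        payload["_seed"] = cfg.seed
        path.write_text(json.dumps(payload, indent=2, default=float))
        artifacts[name] = str(path)

    try:
        stage = "read_inputs"
        t0 = _stage(stage)
        records = sio.read_metadata(cfg.metadata_path)
        pixel_sets = sio.read_pixel_table(cfg.pixel_table_path)
        by_id = {ps.individual_id: ps for ps in pixel_sets}
        records = [r for r in records if r.id in by_id]
        if not records:
            raise ValueError("no individuals shared between metadata and pixel table")
        timings[stage] = time.perf_counter() - t0

        summaries = {}
        rhat_warnings = {}
        for channel in cfg.channels:
            stage = f"spectra[{channel}]"
            t0 = _stage(stage)
            spectra = compute_spectra(
                [by_id[r.id] for r in records], channel,
                cfg.n_bins.get(channel), cfg.specular_v_min, cfg.specular_s_max,
            )
            spath = outdir / f"spectra_{channel}.csv"
            sio.write_spectra_csv(spectra, spath)
            artifacts[spath.name] = str(spath)
            timings[stage] = time.perf_counter() - t0

            stage = f"pca[{channel}]"
            t0 = _stage(stage)
            sm = spectra_to_matrix(spectra)
            pca = fit_pca(sm)
            scores = score_pc1(pca, sm)
            lpath = outdir / f"loadings_{channel}.csv"
            sio.write_loadings_csv(pca, lpath)
            artifacts[lpath.name] = str(lpath)
            scpath = outdir / f"scores_{channel}.csv"
            sio.write_scores_csv(sm.individual_ids, channel, scores, scpath)
            artifacts[scpath.name] = str(scpath)
            timings[stage] = time.perf_counter() - t0

            stage = f"fit[{channel}]"
            t0 = _stage(stage)
            for r, sc in zip(records, scores):
                r.score = float(sc)
            design = build_design(records, tau=cfg.tau)
            mcmc = MCMCSettings(chains=cfg.mcmc.chains, iterations=cfg.mcmc.iterations,
                                burnin=cfg.mcmc.burnin, thinning=cfg.mcmc.thinning,
                                seed=cfg.seed)
            draws = fit_cosinor_lmm(design, cfg.priors, mcmc)
            dpath = outdir / f"draws_{channel}.csv"
            sio.write_draws_csv(draws, dpath)
            artifacts[dpath.name] = str(dpath)
            rhat_warnings[channel] = {
                "rhat": draws.rhat, "converged": draws.converged,
            }
            timings[stage] = time.perf_counter() - t0

            stage = f"summarize[{channel}]"
            t0 = _stage(stage)
            summary = summarize_posterior(draws, channel=channel)
            summaries[channel] = summary
            _write_json(f"summary_{channel}.json", summary)
            cpath = outdir / f"summary_{channel}.csv"
            flatten_summary(summary).to_csv(cpath, index=False)
            artifacts[cpath.name] = str(cpath)
            timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_json("run_metadata.json", {
        "settings": cfg.to_dict(),
        "convergence": rhat_warnings,
        "timings_s": timings,
    })
    manifest = {
        "config_hash": chash,
        "seed": cfg.seed,
        "artifacts": sorted(artifacts),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
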