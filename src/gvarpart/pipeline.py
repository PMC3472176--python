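"""End-to-end driver: QC -> relationship matrices -> model fits -> summaries.

A single :class:`RunConfig` (loadable from YAML) names the input files, the
trait, the models to fit and the optional chromosome scan / beta-curve
stages. Every output directory gets a ``manifest.json`` recording the config
hash, the seed, the QC accounting and the stages completed, so a run is
reproducible and auditable from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .accuracy import beta_curve
from .errors import ConfigError
from .grm import build_G, qc_markers
from .io import read_genotypes, read_pedigree, read_phenotypes, read_raw
from .partition import chromosome_scan, fit_model
from .pedigree import build_A, restrict_to_ancestors
from .simulate import SimConfig, simulate_dataset

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "gvarpart_run"
    # either file inputs ...
    pedigree: Optional[str] = None
    genotypes: Optional[str] = None
    marker_map: Optional[str] = None
    phenotypes: Optional[str] = None
    genotype_format: str = "tsv"          # 'tsv' or 'raw'
    trait: Optional[str] = None
    # ... or simulate in memory
    simulate: Optional[dict] = None       # SimConfig field overrides

    models: tuple = (1, 2, 3)
    run_chromosome_scan: bool = False
    run_beta_curve: bool = False
    beta_n_values: tuple = (250, 500, 1000)
    beta_replicates: int = 10
    maf_threshold: float = 0.01
    reml_tol: float = 1e-8
    reml_maxiter: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            for key in ("pedigree", "genotypes", "marker_map", "phenotypes"):
                p = getattr(self, key)
                if p is None:
                    raise ConfigError(f"config needs either 'simulate' or the {key!r} path")
                if not Path(p).exists():
                    raise ConfigError(f"{key} path does not exist: {p}")
        if self.genotype_format not in ("tsv", "raw"):
            raise ConfigError("genotype_format must be 'tsv' or 'raw'")
        bad = [m for m in self.models if m not in (1, 2, 3, 4)]
        if bad:
            raise ConfigError(f"unknown model ids {bad}; model 4 runs via the chromosome scan")
        if not (0 <= self.maf_threshold < 0.5):
            raise ConfigError("maf_threshold must be in [0, 0.5)")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Artifacts written to ``cfg.outdir``: ``fits.tsv`` (trait, model,
    component, estimate, se, vr), optional ``partition.tsv`` and
    ``beta_curve.tsv`` / ``beta_summary.tsv``, and ``manifest.json``. On a
    stage failure, the manifest (with the stages completed so far) is still
    written before the error propagates.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.digest(), "seed": cfg.seed,
                "config": dataclasses.asdict(cfg), "stages": [], "files": [],
                "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def done(stage, **info):
        manifest["stages"].append({"stage": stage, **info})

    try:
        # ---- inputs
        if cfg.simulate is not None:
            sim = simulate_dataset(SimConfig(seed=cfg.seed, **cfg.simulate))
            ped, geno, phen = sim.pedigree, sim.genotypes, sim.phenotypes
            done("simulate", n_individuals=ped.n, n_markers=geno.m)
        else:
            ped = read_pedigree(cfg.pedigree)
            reader = read_raw if cfg.genotype_format == "raw" else read_genotypes
            geno = reader(cfg.genotypes, cfg.marker_map)
            phen = read_phenotypes(cfg.phenotypes, trait=cfg.trait)
            done("load", n_pedigree=ped.n, n_markers=geno.m, n_records=len(phen))

        # ---- QC
        geno, report = qc_markers(geno, maf_threshold=cfg.maf_threshold)
        done("qc", **{k: getattr(report, k) for k in
                      ("n_input", "n_removed_maf", "n_removed_dependence", "n_retained")})

        # ---- relationship matrices aligned to the phenotyped set
        ids = list(phen["id"])
        sub = restrict_to_ancestors(ped, ids)
        A = build_A(sub).subset(ids)
        G = build_G(geno.select_individuals(ids))
        done("matrices", n_phenotyped=len(ids), m_markers=G.meta["m_markers"])

        # ---- model fits
        fit_kw = dict(tol=cfg.reml_tol, maxiter=cfg.reml_maxiter)
        frames = []
        fits = {}
        for m in cfg.models:
            mr = fit_model(phen, m, A=A, G=G, trait=cfg.trait or "sim", **fit_kw)
            fits[m] = mr
            frames.append(mr.to_frame())
        if frames:
            import pandas as pd

            fits_path = out / "fits.tsv"
            pd.concat(frames).to_csv(fits_path, sep="\t", index=False)
            manifest["files"].append(str(fits_path))
            done("fits", models=list(cfg.models),
                 converged={m: bool(fits[m].results.converged) for m in fits})

        # ---- chromosome scan
        if cfg.run_chromosome_scan:
            part = chromosome_scan(phen, geno.select_individuals(ids), A,
                                   trait=cfg.trait or "sim",
                                   model3=fits.get(3), **fit_kw)
            part_path = out / "partition.tsv"
            part.table.to_csv(part_path, sep="\t", index=False)
            manifest["files"].append(str(part_path))
            done("chromosome_scan", sum_ratio=part.sum_ratio)

        # ---- beta curve
        if cfg.run_beta_curve:
            curve = beta_curve(geno, cfg.beta_n_values,
                               n_replicates=cfg.beta_replicates, seed=cfg.seed)
            for name, df in (("beta_curve.tsv", curve.replicates),
                             ("beta_summary.tsv", curve.summary)):
                p = out / name
                df.to_csv(p, sep="\t", index=False)
                manifest["files"].append(str(p))
            done("beta_curve", n_values=list(cfg.beta_n_values))

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
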