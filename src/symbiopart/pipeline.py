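"""End-to-end orchestration: classify -> normalize -> de -> biomarkers ->
network -> enrich, driven by a single validated config with a run manifest.

The manifest records input file hashes, all stage parameters, and
per-stage row counts, so a run is reproducible from the manifest plus the
input files alone.  All stage randomness is funnelled through explicit
seeds in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import biomarkers as bm
from . import coexpression as coex
from . import diffabund as da
from . import enrichment as enr
from . import expression as expr
from . import source_classifier as sc
from .taxonomy import load_taxonomy

logger = logging.getLogger("symbiopart")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated, defaulted parameters for a full pipeline run."""

    counts: str = "counts.tsv"
    castes: str = "castes.tsv"
    hits: str = "hits.tsv"
    taxonomy: str = "taxonomy.tsv"
    annotations: str = "go.tsv"
    outdir: str = "results"
    # classifier
    host_clade: int = sc.BLATTODEA_TAXID
    symbiont_clade: int = sc.METAMONADA_TAXID
    evalue: float = 1e-5
    tolerance_bp: int = 30
    # expression filter / normalization
    min_cpm: float = 1.0
    min_samples: int = 10
    # DE
    fc: float = 2.0
    alpha: float = 0.05
    # biomarkers
    lasso_seed: int = 1
    cv_folds: int = 10
    # network
    beta: float = 12.0
    edge_threshold: float = 0.5
    # enrichment
    enrich_alpha: float = 0.05
    # stage toggles
    run_biomarkers: bool = True
    run_network: bool = True
    run_enrichment: bool = True

    def __post_init__(self):
        if self.min_cpm < 0:
            raise ConfigError("min_cpm must be >= 0")
        if self.beta <= 0:
            raise ConfigError("beta must be > 0")
        if not 0 < self.alpha < 1 or not 0 < self.enrich_alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.edge_threshold < 0 or self.edge_threshold > 1:
            raise ConfigError("edge_threshold must be in [0, 1]")
        if self.evalue < 0 or self.tolerance_bp < 0:
            raise ConfigError("evalue and tolerance_bp must be >= 0")


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys and bad ranges."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest.

    Any stage failure aborts with the stage name and cause.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {name: Path(getattr(config, name)) for name in
              ("counts", "castes", "hits", "taxonomy", "annotations")}
    missing = [str(p) for p in inputs.values() if not p.exists()]
    if missing:
        raise ConfigError(f"missing input files: {missing}")

    manifest: dict = {
        "parameters": asdict(config),
        "inputs": {k: _sha256(p) for k, p in inputs.items()},
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                counts = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "rows": counts, "seconds": round(time.time() - t0, 3)}
            logger.info("stage %s: done (%s rows)", name, counts)
        return deco

    state: dict = {}

    @stage("classify")
    def _classify():
        tax = load_taxonomy(inputs["taxonomy"])
        params = sc.ClassifierParams(
            host_clade=config.host_clade,
            symbiont_clade=config.symbiont_clade,
            evalue_cutoff=config.evalue, tolerance_bp=config.tolerance_bp)
        hits = sc.parse_hits(inputs["hits"], config.evalue)
        cm = expr.CountMatrix.from_tsv(inputs["counts"], inputs["castes"])
        calls = sc.classify_all(hits, tax, params,
                                all_transcripts=list(cm.counts.index))
        sc.write_calls(calls, outdir / "calls.tsv", tax)
        state.update(tax=tax, calls=calls, cm=cm)
        return len(calls)

    @stage("normalize")
    def _normalize():
        filtered = expr.filter_low_expression(
            state["cm"], config.min_cpm, config.min_samples)
        factors, tmm = expr.tmm_normalize(filtered)
        tmm.to_csv(outdir / "tmm.tsv", sep="\t")
        factors.factors.to_csv(outdir / "factors.tsv", sep="\t",
                               header=["tmm_factor"])
        state.update(filtered=filtered, factors=factors, tmm=tmm)
        return tmm.shape[0]

    @stage("de")
    def _de():
        results = da.run_de(state["filtered"], state["factors"],
                            calls=state["calls"], fc=config.fc,
                            alpha=config.alpha)
        da.de_table(results).to_csv(outdir / "de.tsv", sep="\t")
        state["de"] = results
        return len(results)

    if config.run_biomarkers:
        @stage("biomarkers")
        def _biomarkers():
            fit = bm.fit_biomarkers(state["tmm"], state["filtered"].castes,
                                    seed=config.lasso_seed,
                                    k=config.cv_folds)
            report = bm.report_biomarkers(fit, state["calls"], state["de"],
                                          state["tmm"],
                                          state["filtered"].castes)
            report.to_csv(outdir / "biomarkers.tsv", sep="\t", index=False)
            state["biomarkers"] = report
            return len(report)

    if config.run_network:
        @stage("network")
        def _network():
            net = coex.build_caste_networks(
                state["tmm"], state["filtered"].castes, state["calls"],
                beta=config.beta, threshold=config.edge_threshold)
            for caste in ("worker", "soldier"):
                coex.pairs_table(net[f"pairs_{caste}"], state["calls"]) \
                    .to_csv(outdir / f"edges_{caste}.tsv", sep="\t",
                            index=False)
            coex.pairs_table(net["pairs_shared"], state["calls"]).to_csv(
                outdir / "shared_pairs.tsv", sep="\t", index=False)
            net["modules"].to_csv(outdir / "modules.tsv", sep="\t")
            state["network"] = net
            return len(net["pairs_worker"])

    if config.run_enrichment:
        @stage("enrich")
        def _enrich():
            annot = enr.load_annotations(inputs["annotations"])
            host_ids = {t for t, c in state["calls"].items()
                        if c.source == sc.TERMITE}
            background = host_ids & set(state["tmm"].index)
            n_rows = 0
            for status, tag in ((da.WORKER_BIASED, "worker"),
                                (da.SOLDIER_BIASED, "soldier")):
                fg = {r.transcript for r in state["de"]
                      if r.status == status} & background
                rows = enr.hypergeom_enrich(fg, background, annot)
                table = enr.enrichment_report(rows, config.enrich_alpha)
                table.to_csv(outdir / f"enrich_{tag}.tsv", sep="\t",
                             index=False)
                n_rows += len(table)
            return n_rows

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
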