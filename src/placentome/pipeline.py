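"""End-to-end pipeline driver.

Stages, in order: simulate (or load inputs) -> maternal/fetal origin
deconvolution -> differential expression (combined, male, female) -> DEG
summaries -> co-expression modules with SDM/hub calling -> panel enrichment.
Every stage's summary lands in one JSON report; all randomness flows from
the single global seed through named substreams, and the report is
byte-reproducible for a given seed apart from its single timestamp field.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import TRAITS, stage_rng
from .coexpr import (
    detect_modules,
    effective_trait_number,
    flag_sdm_and_key,
    hub_genes,
    module_trait_association,
    pick_soft_power,
    vst_like_transform,
)
from .de import (
    classify_layer_sharing,
    deg_sets_from_results,
    direction_discordance,
    run_de,
)
from .deconv import estimate_origins
from .enrich import permutation_enrichment
from .simulate import Cohort, SimConfig, simulate_cohort, write_cohort

logger = logging.getLogger("placentome")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_STAGES = ("simulate", "deconv", "de", "modules", "enrich")


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    write_inputs: bool = False
    # differential expression
    alpha: float = 0.05
    min_mean: float = 1.0
    # origin deconvolution
    min_snps: int = 5
    n_reps: int = 5
    min_depth: int = 10
    deconv_method: str = "2rf"
    # co-expression
    min_module_size: int = 30
    cut_height: float = 0.99
    trait_threshold: str = "meff"
    wgcna_n_genes: int = 2000
    wgcna_layers: list | None = None  # default: all layers
    wgcna_strata: tuple = ("male", "female")
    # enrichment
    n_perm: int = 10_000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wgcna_strata"] = list(self.wgcna_strata)
        return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default) + "\n")


def _deconv_stage(cohort: Cohort, config: PipelineConfig, outdir: Path) -> dict:
    seed = int(stage_rng(config.seed, "deconv").integers(2**31 - 1))
    estimates, failures = estimate_origins(
        cohort.allelic_counts,
        cohort.mother_gt,
        cohort.fetus_gt,
        cohort.metadata,
        seed=seed,
        min_snps=config.min_snps,
        n_reps=config.n_reps,
        min_depth=config.min_depth,
        method=config.deconv_method,
    )
    estimates.to_csv(outdir / "origin_estimates.tsv", sep="\t", index=False)
    per_layer = estimates.groupby("layer")["fetal_fraction"].mean().round(4).to_dict()
    summary = {
        "n_samples": int(len(estimates)),
        "n_failed": len(failures),
        "failed": [list(f) for f in failures[:20]],
        "mean_fetal_fraction_by_layer": per_layer,
        "output": "origin_estimates.tsv",
    }
    truth_f = pd.Series(cohort.truth.fetal_fraction)
    err = (estimates.set_index("sample_id")["fetal_fraction"] - truth_f).abs()
    summary["mean_abs_error_vs_truth"] = round(float(err.dropna().mean()), 4)
    return summary


def _de_stage(cohort: Cohort, config: PipelineConfig, outdir: Path) -> tuple[dict, dict]:
    pops = tuple(cohort.config.population_names)
    results = {}
    for stratum in ("combined", "male", "female"):
        results[stratum] = run_de(
            cohort.counts,
            cohort.metadata,
            stratum=stratum,
            alpha=config.alpha,
            min_mean=config.min_mean,
            population_levels=pops,
        )
        for layer, res in results[stratum].items():
            out = outdir / f"de_{layer}_{stratum}.tsv"
            header = (
                f"# log2FC > 0 means higher expression in {pops[0]} "
                f"(reference {pops[1]}); stratum={stratum}; layer={layer}\n"
            )
            with open(out, "w") as fh:
                fh.write(header)
                res.to_csv(fh, sep="\t")

    summary: dict = {"deg_counts": {}, "sharing": {}, "discordance": {}}
    universe = int((~results["combined"][cohort.config.layers[0]]["p"].isna()).sum())
    summary["universe_tested_genes"] = universe
    collections = {}
    for stratum in ("combined", "male", "female"):
        coll = deg_sets_from_results(results[stratum], stratum, universe_size=universe)
        collections[stratum] = coll
        _, sharing = classify_layer_sharing(coll)
        summary["deg_counts"][stratum] = sharing["per_layer"]
        summary["sharing"][stratum] = sharing
        summary["sharing"][stratum]["universe_share_pct"] = coll.universe_share_pct()
    for layer in cohort.config.layers:
        summary["discordance"][layer] = direction_discordance(
            results["male"][layer], results["female"][layer]
        )
    summary["male_total_degs"] = collections["male"].n_distinct
    summary["female_total_degs"] = collections["female"].n_distinct
    return summary, {"results": results, "collections": collections}


def _modules_stage(cohort: Cohort, config: PipelineConfig, outdir: Path, de_state: dict) -> dict:
    layers = config.wgcna_layers or list(cohort.config.layers)
    meta = cohort.metadata
    summary: dict = {}
    for stratum in config.wgcna_strata:
        sub_meta = meta[meta["infant_sex"] == stratum]
        pair_traits = sub_meta.drop_duplicates("pair_id").set_index("pair_id")
        trait_corr = pair_traits[list(TRAITS)].corr()
        meff, trait_alpha = effective_trait_number(trait_corr)
        for layer in layers:
            counts = cohort.counts[layer]
            cols = [c for c in counts.columns if c in set(sub_meta["sample_id"])]
            expr = vst_like_transform(counts[cols])
            top = expr.var(axis=0).nlargest(min(config.wgcna_n_genes, expr.shape[1])).index
            expr = expr[top]
            power = pick_soft_power(expr)
            mset = detect_modules(
                expr,
                power,
                min_size=config.min_module_size,
                cut_height=config.cut_height,
                layer=layer,
                stratum=stratum,
            )
            key_entry = {
                "soft_power": power,
                "n_genes": int(expr.shape[1]),
                "n_modules": len(mset.module_ids),
                "meff": round(meff, 4),
                "trait_alpha": trait_alpha if config.trait_threshold == "meff" else 0.05,
            }
            if mset.module_ids:
                sample_meta = sub_meta.set_index("sample_id").loc[expr.index]
                traits = sample_meta[list(TRAITS)]
                stats_tab = module_trait_association(
                    mset.eigengenes, traits, sample_meta["population"]
                )
                deg_map = de_state["collections"][stratum].sets.get(layer, {})
                flagged = flag_sdm_and_key(
                    stats_tab,
                    mset,
                    set(deg_map),
                    universe_size=de_state["collections"][stratum].universe_size,
                    meff=meff,
                    trait_threshold=config.trait_threshold,
                )
                hubs = hub_genes(mset, expr, traits)
                tag = f"{layer}_{stratum}"
                mset.assignments.rename("module").to_csv(
                    outdir / f"modules_{tag}.tsv", sep="\t", index_label="gene_id"
                )
                mset.eigengenes.to_csv(
                    outdir / f"eigengenes_{tag}.tsv", sep="\t", index_label="sample_id"
                )
                flagged.to_csv(outdir / f"module_trait_{tag}.tsv", sep="\t")
                hubs.to_csv(outdir / f"hubs_{tag}.tsv", sep="\t", index=False)
                sdms = flagged[flagged["is_sdm"]]
                key = flagged[flagged["is_key"]]
                key_entry.update(
                    {
                        "n_sdm": int(len(sdms)),
                        "n_sdm_05": int(flagged["is_sdm_05"].sum()),
                        "key_module": int(key.index[0]) if len(key) else None,
                        "n_hub_genes": int(len(hubs)),
                    }
                )
            summary[f"{layer}_{stratum}"] = key_entry
    return summary


def _enrich_stage(cohort: Cohort, config: PipelineConfig, outdir: Path, de_state: dict) -> dict:
    combined_res = de_state["results"]["combined"]
    first = next(iter(combined_res.values()))
    universe = sorted(first.index[~first["p"].isna()])
    uni_set = set(universe)
    panel = [g for g in cohort.truth.panel if g in uni_set]
    seed = int(stage_rng(config.seed, "enrich").integers(2**31 - 1))
    out = {}
    for stratum in ("combined", "male", "female"):
        coll = de_state["collections"][stratum]
        deg_union = {g for s in coll.sets.values() for g in s} & uni_set
        res = permutation_enrichment(
            universe,
            deg_union,
            panel=panel,
            n_perm=config.n_perm,
            seed=seed,
            name=stratum,
        )
        out[stratum] = res.to_dict()
    _write_json(outdir / "enrichment.json", out)
    return out


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Execute the configured stages and write ``report.json``.

    A pre-built cohort can be injected (used by tests); otherwise the
    simulate stage generates one from ``config.sim`` with the global seed.
    Stage failure raises :class:`PipelineError` after persisting the partial
    report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    report: dict = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    de_state: dict | None = None

    def run_stage(name, fn):
        nonlocal de_state
        if not config.stages.get(name, True):
            report["stages"][name] = "skipped"
            logger.info("stage %s skipped", name)
            return None
        logger.info("stage %s running", name)
        try:
            return fn()
        except Exception as err:
            report["stages"][name] = {"error": str(err)}
            report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
            _write_json(outdir / "report.json", report)
            raise PipelineError(name, err) from err

    if cohort is None and config.stages.get("simulate", True):
        def _simulate():
            sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
            c = simulate_cohort(sim_cfg)
            entry = {
                "n_pairs": c.config.n_pairs,
                "n_samples": int(len(c.metadata)),
                "n_layers": len(c.config.layers),
                "n_genes": c.config.n_genes,
                "n_snps": c.config.n_snps,
            }
            if config.write_inputs:
                write_cohort(c, outdir / "cohort")
                entry["written_to"] = "cohort/"
            report["stages"]["simulate"] = entry
            return c
        cohort = run_stage("simulate", _simulate)
    elif cohort is not None:
        report["stages"]["simulate"] = {
            "provided": True,
            "n_samples": int(len(cohort.metadata)),
        }
    if cohort is None:
        raise PipelineError("simulate", ValueError("no cohort: simulate disabled and none provided"))

    res = run_stage("deconv", lambda: _deconv_stage(cohort, config, outdir))
    if res is not None:
        report["stages"]["deconv"] = res

    def _de():
        summary, state = _de_stage(cohort, config, outdir)
        return summary, state

    out = run_stage("de", _de)
    if out is not None:
        report["stages"]["de"], de_state = out

    if de_state is not None:
        res = run_stage("modules", lambda: _modules_stage(cohort, config, outdir, de_state))
        if res is not None:
            report["stages"]["modules"] = res
        res = run_stage("enrich", lambda: _enrich_stage(cohort, config, outdir, de_state))
        if res is not None:
            report["stages"]["enrich"] = res
    else:
        for name in ("modules", "enrich"):
            if config.stages.get(name, True):
                report["stages"][name] = "skipped"

    report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_json(outdir / "report.json", report)
    return report
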