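"""End-to-end orchestration with a single JSON config and seed provenance.

Stages, in order: ``synth`` (optional; skipped when counts are supplied) ->
``count`` (optional; skipped when counts are supplied directly) ->
``fitness`` -> ``regress`` -> ``complete`` -> ``evolve`` -> ``compare``.
Each stage writes its outputs under ``outdir`` and registers them, with an
md5 checksum and the seed used, in ``manifest.json``.  Re-running with the
same config skips stages whose outputs already exist and whose config hash is
unchanged, unless forced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .completion import complete_landscape
from .counts import count_fastq
from .data import load_packaged_catalog
from .fitness import FitnessLandscape, landscape_from_counts
from .genotypes import MutationCatalog, to_string
from .regression import aic_stepwise, build_design, fit_ols, fit_terms, variance_partition
from .simulate import (
    SimulationConfig,
    compare_treatments,
    run_treatments,
    summarize_treatments,
    treatment_schedule,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

STAGES = ("synth", "count", "fitness", "regress", "complete", "evolve", "compare")


class PipelineConfig:
    """Validated pipeline configuration (see :func:`default_config`)."""

    def __init__(self, raw: dict):
        self.raw = dict(raw)
        for key in ("outdir", "seed"):
            if key not in raw:
                raise ValueError(f"pipeline config missing required key {key!r}")
        self.outdir = Path(raw["outdir"])
        self.seed = int(raw["seed"])
        self.catalog_path = raw.get("catalog")
        self.counts = raw.get("counts")  # optional {host: csv path}
        self.synth = raw.get("synth", {})
        self.fitness = raw.get("fitness", {})
        self.regress = raw.get("regress", {})
        self.evolve = raw.get("evolve", {})
        bad = set(raw) - {
            "outdir", "seed", "catalog", "counts", "synth", "fitness", "regress",
            "evolve", "emit_reads",
        }
        if bad:
            raise ValueError(f"unknown pipeline config keys: {sorted(bad)}")
        self.emit_reads = bool(raw.get("emit_reads", False))

    def catalog(self) -> MutationCatalog:
        if self.catalog_path:
            return MutationCatalog.from_json(self.catalog_path)
        return load_packaged_catalog()

    def stage_hash(self, stage: str) -> str:
        payload = {
            "seed": self.seed,
            "catalog": self.catalog_path,
            "stage_cfg": self.raw.get(stage if stage != "count" else "synth", {}),
        }
        return hashlib.md5(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def default_config(outdir: str, seed: int = 0) -> dict:
    """A small synthetic end-to-end configuration."""
    return {
        "outdir": outdir,
        "seed": seed,
        "synth": {
            "landscape": {"seed": seed},
            "library": {"missing_fraction": 0.345, "lognormal_sigma": 1.5},
            "sequencing": {"reads_per_sample": 50_000, "per_base_error": 1e-3},
        },
        "fitness": {"T": 4.0, "min_count": 1.0},
        "regress": {"q": 0.05},
        "evolve": {
            "N": 100_000,
            "generations": 100,
            "trials": 20,
            "batch_size": 10,
            "detection_threshold": 500,
            "switch_fractions": [0.5],
            "mutate_all_offspring": True,
            "mu_base": 1e-4,
        },
    }


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig(json.loads(Path(path).read_text()))


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig | dict, force: bool = False) -> dict:
    """Execute the pipeline; returns (and writes) the artifact manifest."""
    if isinstance(config, dict):
        config = PipelineConfig(config)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"stages": {}}
    )
    catalog = config.catalog()

    def satisfied(stage: str, outputs: list[Path]) -> bool:
        entry = manifest["stages"].get(stage)
        return (
            not force
            and entry is not None
            and entry.get("config_hash") == config.stage_hash(stage)
            and all(Path(p).exists() for p in entry.get("outputs", []))
            and all(p.exists() for p in outputs)
        )

    def register(stage: str, outputs: list[Path], executed: bool) -> None:
        manifest["stages"][stage] = {
            "outputs": [str(p) for p in outputs],
            "checksums": {p.name: _md5(p) for p in outputs if p.exists()},
            "seed": config.seed,
            "config_hash": config.stage_hash(stage),
            "executed": executed,
        }

    counts_paths = {
        host: outdir / f"counts_{host}.csv" for host in synth.HOSTS
    }
    # --- synth + count -----------------------------------------------------
    if config.counts:
        for host, p in config.counts.items():
            counts_paths[host] = Path(p)
        register("synth", [], executed=False)
        register("count", list(counts_paths.values()), executed=False)
    else:
        outs = list(counts_paths.values())
        if satisfied("synth", outs):
            register("synth", outs, executed=False)
            register("count", outs, executed=False)
        else:
            ls_spec = synth.TrueLandscapeSpec(**config.synth.get("landscape", {}))
            lib_spec = synth.LibraryCompositionSpec(**config.synth.get("library", {}))
            seq_spec = synth.SequencingSpec(**config.synth.get("sequencing", {}))
            counts_by_host, truth, coeffs, _ = synth.simulate_experiment(
                ls_spec, lib_spec, seq_spec, catalog, config.seed
            )
            truth_frame = pd.DataFrame(
                {
                    "genotype": [to_string(g, catalog.L) for g in range(2**catalog.L)],
                    **{h: truth[h] for h in synth.HOSTS},
                }
            )
            truth_frame.to_csv(outdir / "true_landscapes.csv", index=False,
                               float_format="%.10g")
            coeffs.to_csv(outdir / "true_coefficients.csv", float_format="%.10g")
            if config.emit_reads:
                for host in synth.HOSTS:
                    sheet = synth.emit_reads(
                        counts_by_host[host], catalog, seq_spec, config.seed,
                        outdir / "reads", prefix=host,
                    )
                    called, _ = count_fastq(sheet, catalog)
                    counts_by_host[host] = called
            for host in synth.HOSTS:
                df = counts_by_host[host].copy()
                df["genotype"] = [to_string(g, catalog.L) for g in df["genotype"]]
                df.to_csv(counts_paths[host], index=False)
            register("synth", outs + [outdir / "true_landscapes.csv"], executed=True)
            register("count", outs, executed=True)

    # --- fitness -----------------------------------------------------------
    from .genotypes import from_string

    land_paths = {h: outdir / f"landscape_{h}.csv" for h in synth.HOSTS}
    if satisfied("fitness", list(land_paths.values())):
        register("fitness", list(land_paths.values()), executed=False)
        landscapes = {
            h: FitnessLandscape.from_csv(p, T=config.fitness.get("T", 4.0))
            for h, p in land_paths.items()
        }
    else:
        landscapes = {}
        for host in synth.HOSTS:
            df = pd.read_csv(counts_paths[host], dtype={"genotype": str, "variant": str})
            df["variant"] = df["variant"].fillna("")
            df["genotype"] = df["genotype"].map(from_string)
            landscapes[host] = landscape_from_counts(
                df,
                host=host,
                L=catalog.L,
                T=config.fitness.get("T", 4.0),
                min_count=config.fitness.get("min_count", 1.0),
            )
            landscapes[host].to_csv(land_paths[host])
        register("fitness", list(land_paths.values()), executed=True)

    # --- regress -----------------------------------------------------------
    regress_out = outdir / "regression_combined.csv"
    summary_out = outdir / "regression_summary.json"
    if satisfied("regress", [regress_out, summary_out]):
        register("regress", [regress_out, summary_out], executed=False)
    else:
        design = build_design(
            landscapes["ancestral"], landscapes["malT_minus"], mode="combined"
        )
        fit = fit_ols(design, q=config.regress.get("q", 0.05))
        selected, _ = aic_stepwise(design)
        reduced = fit_terms(design, selected)
        table = fit.summary_frame()
        table["in_aic_model"] = [
            t in {s.name for s in selected} for t in table.index
        ]
        table.to_csv(regress_out, float_format="%.10g")
        partition = variance_partition(design)
        summary = {
            "r2": fit.rsquared,
            "r2_adj": fit.rsquared_adj,
            "F": fit.fvalue,
            "df_model": fit.df_model,
            "df_resid": fit.df_resid,
            "r2_adj_reduced": reduced.rsquared_adj,
            "n_terms_full": design.n_terms,
            "n_terms_reduced": len(selected),
            "variance_partition": partition.to_dict(orient="records"),
        }
        summary_out.write_text(json.dumps(summary, indent=1))
        register("regress", [regress_out, summary_out], executed=True)

    # --- complete (one example per host, master-seed substream) -------------
    comp_paths = {h: outdir / f"complete_{h}.csv" for h in synth.HOSTS}
    if satisfied("complete", list(comp_paths.values())):
        register("complete", list(comp_paths.values()), executed=False)
    else:
        for i, host in enumerate(synth.HOSTS):
            comp = complete_landscape(
                landscapes[host], np.random.default_rng([config.seed, 1000 + i])
            )
            comp.to_csv(comp_paths[host])
        register("complete", list(comp_paths.values()), executed=True)

    # --- evolve + compare --------------------------------------------------
    evolve_out = outdir / "treatments.csv"
    trials_out = outdir / "trials.jsonl"
    compare_out = outdir / "comparisons.csv"
    if satisfied("evolve", [evolve_out, trials_out]) and satisfied(
        "compare", [compare_out]
    ):
        register("evolve", [evolve_out, trials_out], executed=False)
        register("compare", [compare_out], executed=False)
    else:
        sim_cfg = SimulationConfig(L=catalog.L, seed=config.seed, **config.evolve)
        results = run_treatments(
            landscapes["ancestral"], landscapes["malT_minus"], sim_cfg, catalog
        )
        summarize_treatments(results).to_csv(evolve_out, index=False,
                                             float_format="%.10g")
        with open(trials_out, "w") as fh:
            for r in results:
                for t, (flag, gen) in enumerate(
                    zip(r.flags, r.detection_generations)
                ):
                    fh.write(
                        json.dumps(
                            {
                                "treatment": r.label,
                                "trial": t,
                                "seed": config.seed,
                                "ompf": bool(flag),
                                "detection_generation": gen,
                            }
                        )
                        + "\n"
                    )
        anova, tukey = compare_treatments(results)
        tukey.insert(0, "anova_F", anova["F"])
        tukey.insert(1, "anova_p", anova["p"])
        tukey.to_csv(compare_out, index=False, float_format="%.10g")
        register("evolve", [evolve_out, trials_out], executed=True)
        register("compare", [compare_out], executed=True)

    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
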