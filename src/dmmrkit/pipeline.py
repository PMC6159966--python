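"""Umbrella pipeline: simulate → MSI score → signatures → filter → immune → ROC.

The pipeline is configured by a nested dict (YAML-friendly) validated against
:data:`DEFAULT_CONFIG` — unknown keys are rejected.  Every run writes the
resolved configuration and a log (seed, config hash, per-stage record counts)
next to its outputs; with a fixed master seed a run is byte-identical across
repeats.
"""

from __future__ import annotations

import copy
import hashlib
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .immune import associate_genes, checkpoint_panel, load_panel
from .metrics import km_median_and_logrank, youden_cutoff
from .msi import MsingsBaseline
from .refsigs import make_reference_signatures, write_reference_signatures
from .signatures import build_context_matrix, fit_signatures, mmr_dominant
from .simulate import DMMR_SIGNATURE_NAMES, SimConfig, simulate_cohort, stage_seed
from .variants import apply_filters, dichotomize_load, mutation_load

__all__ = ["DEFAULT_CONFIG", "load_config", "resolve_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "stages": {
        "simulate": True,
        "msings": True,
        "mutsig": True,
        "variants": True,
        "immune": True,
        "metrics": True,
    },
    "simulate": {},  # overrides for SimConfig fields
    "msings": {
        "peak_fraction": 0.05,
        "sd_multiplier": 2.0,
        "min_reads": 30,
        "min_evaluated": 20,
        "exome_factor": 0.209,
    },
    "mutsig": {
        "rank": 4,
        "n_runs": 20,
        "max_iter": 10000,
        "tol": 1e-9,
    },
    "variants": {
        "panel_size_mb": 0.6,
        "load_threshold": 5.5,
        "indels": "exclude",
    },
    "immune": {
        "fdr": 0.1,
        "site_p": 0.05,
        "min_n": 10,
        "outlier_policy": "none",
        "panel": None,  # path to a panel file; default: bundled 32-gene panel
        "activity_file": None,  # per-sample activity TSV when mutsig is off
    },
}


def _check_keys(user: dict, defaults: dict, path: str = "") -> None:
    for key, value in user.items():
        if key not in defaults and path != "simulate.":
            raise KeyError(f"unknown config key: {path}{key}")
        if key in defaults and isinstance(defaults[key], dict) and isinstance(value, dict):
            _check_keys(value, defaults[key], f"{path}{key}.")


def resolve_config(overrides: dict | None = None) -> dict:
    """Defaults deep-merged with user overrides; unknown keys rejected
    (simulate.* keys are validated by SimConfig itself)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if overrides:
        _check_keys(overrides, DEFAULT_CONFIG)
        SimConfig(**{**overrides.get("simulate", {}),
                     "seed": 0})  # field validation
        for section, value in overrides.items():
            if isinstance(value, dict):
                cfg[section].update(value)
            else:
                cfg[section] = value
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return resolve_config(user)


def run_pipeline(config: dict | None = None, outdir="pipeline_out") -> Path:
    """Execute the configured stages in dependency order and write all
    artifacts under ``outdir``.  Returns the output directory."""
    cfg = resolve_config(config)  # idempotent on an already-resolved dict
    out = dio.ensure_dir(outdir)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    log: list[str] = [f"seed\t{seed}"]

    resolved = yaml.safe_dump(cfg, sort_keys=True)
    (out / "config.yaml").write_text(resolved)
    log.append(f"config_sha256\t{hashlib.sha256(resolved.encode()).hexdigest()}")

    if not stages.get("simulate", True):
        raise NotImplementedError(
            "only the synthetic entry point is wired into run_pipeline; run "
            "the per-stage commands on external inputs instead"
        )
    sim_cfg = SimConfig(**{**cfg["simulate"], "seed": seed})
    cohort = simulate_cohort(sim_cfg)
    truth = cohort.truth
    dio.write_fasta(cohort.reference, out / "reference.fa")
    dio.write_bed(truth.loci, out / "loci.bed")
    dio.write_histograms(cohort.histograms, out / "histograms.tsv")
    dio.write_maf(cohort.records, out / "mutations.tsv")
    dio.write_tsv_matrix(cohort.expression, out / "expression.tsv")
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    truth_dir = dio.ensure_dir(out / "ground_truth")
    truth.dmmr.to_frame().to_csv(truth_dir / "dmmr.tsv", sep="\t", index_label="sample_id")
    truth.exposures.to_csv(truth_dir / "exposures.tsv", sep="\t", index_label="sample_id")
    write_reference_signatures(truth.signatures, truth_dir / "signatures.tsv")
    truth.variant_class.to_frame("variant_class").to_csv(
        truth_dir / "variant_class.tsv", sep="\t", index_label="record")
    log.append(f"simulate\tsamples={sim_cfg.n_samples}\tloci={sim_cfg.n_loci}"
               f"\trecords={len(cohort.records)}")

    if stages.get("msings", True):
        m = cfg["msings"]
        normals = truth.dmmr.index[~truth.dmmr]
        baseline = MsingsBaseline(
            peak_fraction=m["peak_fraction"], sd_multiplier=m["sd_multiplier"],
            min_reads=m["min_reads"], min_evaluated=m["min_evaluated"],
        ).fit(cohort.histograms[cohort.histograms["sample_id"].isin(normals)])
        baseline.baseline_.to_csv(out / "msings_baseline.tsv", sep="\t",
                                  index_label="locus_id")
        calls = baseline.call_loci(cohort.histograms)
        calls.to_csv(out / "msings_locus_calls.tsv", sep="\t", index=False)
        msings = baseline.score_samples(cohort.histograms)
        msings.to_csv(out / "msings_scores.tsv", sep="\t", index=False)
        log.append(f"msings\tbaseline_loci={len(baseline.baseline_)}"
                   f"\tscored={len(msings)}")
    else:
        msings = None

    final = None
    if stages.get("variants", True):
        v = cfg["variants"]
        final, report = apply_filters(cohort.records, indels=v["indels"])
        dio.write_maf(final, out / "mutations_filtered.tsv")
        report.dispositions.to_frame("disposition").to_csv(
            out / "filter_dispositions.tsv", sep="\t", index_label="record")
        load = mutation_load(final, panel_size_mb=v["panel_size_mb"])
        load["load_class"] = load["count"].map(
            lambda c: dichotomize_load(c, v["load_threshold"]))
        load.to_csv(out / "mutation_load.tsv", sep="\t", index=False)
        log.append(f"variants\tinput={report.n_input}\tfinal={report.n_final}"
                   f"\trescued={report.n_rescued_cosmic}")

    model = None
    if stages.get("mutsig", True):
        s = cfg["mutsig"]
        source = final if final is not None else cohort.records
        V = build_context_matrix(source, cohort.reference)
        dio.write_tsv_matrix(V, out / "context_matrix.tsv", index_label="sample_id")
        model = fit_signatures(
            V, rank=s["rank"], n_runs=s["n_runs"],
            seed=stage_seed(seed, "nmf"), max_iter=s["max_iter"], tol=s["tol"],
            reference=make_reference_signatures(),
        )
        write_reference_signatures(model.W, out / "signatures_discovered.tsv")
        model.H.to_csv(out / "exposures.tsv", sep="\t", index_label="sample_id")
        model.proportions.to_csv(out / "exposure_proportions.tsv", sep="\t",
                                 index_label="sample_id")
        pd.DataFrame(model.assignments,
                     columns=["signature", "reference", "cosine", "matched"]
                     ).to_csv(out / "signature_assignments.tsv", sep="\t", index=False)
        log.append(f"mutsig\trank={s['rank']}\truns={s['n_runs']}"
                   f"\tresidual={model.residual:.6g}")

    if stages.get("immune", True):
        im = cfg["immune"]
        if model is not None:
            dmmr_cols = [sig for sig, ref, _, _ in model.assignments
                         if ref in DMMR_SIGNATURE_NAMES]
            activity = model.proportions[dmmr_cols].sum(axis=1)
            dominant = mmr_dominant(model.proportions, dmmr_cols)
            pd.DataFrame({"dmmr_activity": activity, "mmr_dominant": dominant}
                         ).to_csv(out / "dmmr_activity.tsv", sep="\t",
                                  index_label="sample_id")
        elif im["activity_file"]:
            activity = pd.read_csv(im["activity_file"], sep="\t", index_col=0
                                   ).iloc[:, 0]
        else:
            raise ValueError(
                "immune stage needs dMMR activity: enable the mutsig stage or "
                "provide immune.activity_file"
            )
        panel = load_panel(im["panel"]) if im["panel"] else checkpoint_panel()
        sites = cohort.clinical.set_index("sample_id")["site"]
        assoc = associate_genes(
            cohort.expression, activity.reindex(cohort.expression.columns).fillna(0.0),
            sites, genes=panel, fdr=im["fdr"], site_p=im["site_p"],
            min_n=im["min_n"], outlier_policy=im["outlier_policy"],
        )
        assoc.table.to_csv(out / "immune_associations.tsv", sep="\t",
                           index_label="gene")
        log.append(f"immune\tgenes={len(assoc.table)}"
                   f"\tpasses_overall={int(assoc.table['passes_overall'].sum())}"
                   f"\tsites={','.join(assoc.sites_tested)}")

    if stages.get("metrics", True) and msings is not None:
        scores = msings.set_index("sample_id")["score"]
        truth_flags = truth.dmmr.reindex(scores.index)
        roc = youden_cutoff(scores.to_numpy(), truth_flags.to_numpy())
        pd.DataFrame([{
            "auc": roc.auc, "optimal_cutoff": roc.optimal_cutoff,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
            "youden_j": roc.j,
        }]).to_csv(out / "roc.tsv", sep="\t", index=False)
        clin = cohort.clinical
        medians, stat, p = km_median_and_logrank(
            clin["time_years"], clin["event"], clin["dmmr"])
        pd.DataFrame([{
            "median_dmmr": medians.get(True), "median_pmmr": medians.get(False),
            "logrank_statistic": stat, "logrank_p": p,
        }]).to_csv(out / "survival.tsv", sep="\t", index=False)
        log.append(f"metrics\tauc={roc.auc:.4f}\tlogrank_p={p:.4g}")

    (out / "log.txt").write_text("\n".join(log) + "\n")
    return out
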