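"""End-to-end driver: discovery on cohort A, classification and prognostic
evaluation on cohort B.

Stage order mirrors the analysis the package implements: preprocess ->
consensus discovery -> signature derivation on the discovery cohort, then
single-sample enrichment classification -> survival models -> prognostic
benchmarking on the validation cohort. Every stage's artifacts and the
resolved config (including seeds) are persisted, and a rerun with the same
config reproduces all files bit-identically (floats written with 10
significant digits).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import benchmark as bench
from . import consensus, enrichment, io, preprocess, signatures, simulate
from . import survival as surv
from .config import resolve_config

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _load_cohort(spec: dict, default_seed: int):
    if "synthetic" in spec:
        params = dict(spec["synthetic"])
        params.setdefault("seed", default_seed)
        if "subtype_proportions" in params and params["subtype_proportions"]:
            params["subtype_proportions"] = tuple(params["subtype_proportions"])
        if "hazards_per_month" in params and params["hazards_per_month"]:
            params["hazards_per_month"] = tuple(params["hazards_per_month"])
        cohort = simulate.gen_cohort(simulate.CohortConfig(**params))
        return cohort.counts, cohort.clinical, cohort
    counts = io.read_counts_tsv(spec["counts"])
    clinical = io.read_clinical_csv(spec["clinical"]) if spec.get("clinical") else None
    if clinical is not None:
        io.check_sample_join(counts.sample_ids, clinical.index)
    return counts, clinical, None


def _preprocess(counts, cfg, quantile: bool):
    filtered = preprocess.expression_filter(
        counts, min_cpm=cfg["min_cpm"], min_fraction=cfg["min_fraction"]
    )
    logger.info(
        "expression filter: %d/%d genes retained", filtered.n_genes, counts.n_genes
    )
    return filtered, preprocess.normalize(filtered, quantile=quantile)


def run_pipeline(config: dict = None, outdir=None) -> dict:
    """Run the full pipeline; returns the in-memory artifacts by stage name."""
    config = resolve_config(config or {})
    outdir = Path(outdir or config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_json({"seed": config["seed"]}, outdir / "seed.json")
    from .config import dump_config

    dump_config(config, outdir / "config_resolved.yaml")
    artifacts = {}
    stage = "load"
    try:
        counts_a, clin_a, cohort_a = _load_cohort(
            config["cohorts"]["discovery"], config["seed"]
        )
        counts_b, clin_b, cohort_b = _load_cohort(
            config["cohorts"]["validation"], config["seed"] + 1
        )

        stage = "preprocess"
        pcfg = config["preprocess"]
        filt_a, norm_a = _preprocess(counts_a, pcfg, quantile=False)
        norm_a_mad = preprocess.mad_filter(norm_a, pcfg["keep_fraction"])
        logger.info("MAD filter: %d genes retained", len(norm_a_mad.kept_genes))
        io.write_normalized(
            norm_a_mad, outdir / "discovery_logexpr.tsv", outdir / "discovery_weights.tsv"
        )
        artifacts["norm_discovery"] = norm_a_mad

        stage = "discover"
        dcfg = config["discover"]
        result = consensus.discover_subtypes(
            norm_a_mad,
            k_range=range(dcfg["kmin"], dcfg["kmax"] + 1),
            n_resamples=dcfg["n_resamples"],
            item_fraction=dcfg["item_fraction"],
            seed=config["seed"],
            metric=dcfg["metric"],
            method=dcfg["method"],
            selector=dcfg["selector"],
        )
        logger.info("selected k* = %d", result.k_star)
        pd.DataFrame(
            {"k": list(result.A), "A": list(result.A.values())}
        ).to_csv(outdir / "cdf_area.csv", index=False, float_format=io.FLOAT_FORMAT)
        result.labels.to_frame().to_csv(outdir / "discovery_labels.csv")
        for k in result.k_range:
            io.write_matrix_tsv(result.M[k], outdir / f"consensus_k{k}.tsv")
        artifacts["consensus"] = result

        stage = "signatures"
        scfg = config["signatures"]
        de = signatures.all_pairwise_de(norm_a, result.labels)
        for (a, b), res in de.items():
            res.table.to_csv(
                outdir / f"de_C{a}_vs_C{b}.csv", float_format=io.FLOAT_FORMAT
            )
        sig = signatures.derive_signatures(
            de, q_threshold=scfg["q_threshold"], lfc_threshold=scfg["lfc_threshold"]
        )
        io.write_gmt(sig.sets, outdir / "signatures.gmt")
        logger.info(
            "signatures: %s", {n: len(s) for n, s in sorted(sig.sets.items())}
        )
        artifacts["signatures"] = sig

        stage = "classify"
        ccfg = config["classify"]
        filt_b, norm_b = _preprocess(counts_b, pcfg, quantile=True)
        sets = {n: s for n, s in sig.sets.items() if s}
        if ccfg.get("context_gmt"):
            sets.update(io.read_gmt(ccfg["context_gmt"]))
        enrich = enrichment.score_cohort(
            norm_b.logexpr,
            sets,
            alpha=ccfg["alpha"],
            n_perm=ccfg["n_perm"],
            seed=config["seed"],
        )
        enrich.to_csv(
            outdir / "enrichment.csv", index=False, float_format=io.FLOAT_FORMAT
        )
        calls = enrichment.classify_samples(
            enrich,
            [n for n in sets if n in sig.sets],
            threshold=ccfg["threshold"],
            require_sign_concordance=ccfg["require_sign_concordance"],
        )
        calls.to_csv(outdir / "calls.csv", float_format=io.FLOAT_FORMAT)
        artifacts["calls"] = calls
        artifacts["enrichment"] = enrich

        stage = "survival"
        if clin_b is None:
            raise PipelineError("validation cohort has no clinical table")
        vcfg = config["survival"]
        merged = clin_b.join(calls[["assigned_cluster"]], how="left")
        assigned = merged[merged["assigned_cluster"] != enrichment.UNASSIGNED].copy()
        assigned["cluster"] = "C" + assigned["assigned_cluster"].astype(str)
        fit = surv.cox_fit(
            assigned,
            time_col=vcfg["time_col"],
            event_col=vcfg["event_col"],
            covariates=["cluster"] + list(vcfg["extra_covariates"]),
        )
        fit.summary().to_csv(outdir / "cox_os.csv", float_format=io.FLOAT_FORMAT)
        ph = surv.schoenfeld_ph_test(fit)
        ph.to_csv(outdir / "schoenfeld.csv", float_format=io.FLOAT_FORMAT)
        if assigned["cluster"].nunique() >= 2:
            chi2, dfree, p = surv.logrank_test(
                assigned[vcfg["time_col"]],
                assigned[vcfg["event_col"]],
                assigned["cluster"],
            )
            io.write_json(
                {"chi2": chi2, "df": dfree, "p": p}, outdir / "logrank_clusters.json"
            )
        artifacts["cox"] = fit

        stage = "benchmark"
        bcfg = config["benchmark"]
        specs = [
            bench.ModelSpec("TC", ["cluster"]),
            bench.ModelSpec("AGE", ["age_years"]),
            bench.ModelSpec("TC+AGE", ["cluster", "age_years"]),
        ]
        if bcfg["risk_col"] in assigned.columns:
            specs += [
                bench.ModelSpec("RISK", [bcfg["risk_col"]]),
                bench.ModelSpec("TC+RISK", ["cluster", bcfg["risk_col"]]),
            ]
        ctab = bench.compare_models(
            assigned, specs, time_col=vcfg["time_col"], event_col=vcfg["event_col"]
        )
        ctab.to_csv(outdir / "cindex.csv", float_format=io.FLOAT_FORMAT)
        artifacts["cindex"] = ctab
        if bcfg["risk_col"] in assigned.columns:
            strata = bench.substratify_by_risk(
                assigned.assign(cluster_num=assigned["assigned_cluster"]),
                risk_col=bcfg["risk_col"],
                cluster_col="cluster_num",
                time_col=vcfg["time_col"],
                event_col=vcfg["event_col"],
                threshold=bcfg["risk_threshold"],
                grouping=bcfg["grouping"],
            )
            io.write_json(
                {
                    name: {
                        k: v
                        for k, v in entry.items()
                        if k in ("n", "group_sizes", "chi2", "df", "p")
                    }
                    for name, entry in strata.items()
                },
                outdir / "substrata.json",
            )
            artifacts["strata"] = strata
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return artifacts
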