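"""End-to-end orchestration of the cross-cohort signature pipeline.

Stages run in the order the method requires: restrict to common probes ->
joint quantile normalization -> reference-probe selection -> difference from
reference -> DEG-to-probe mapping -> per-probe enrichment test -> gene-level
signature call, with optional gene-set overlap, subtype and survival stages.
Every stage's artifact is persisted as TSV, and a run manifest (version,
parameters, input hashes, stage list, seed) is written alongside so any run
can be audited and reproduced; results are byte-identical for identical
inputs and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from datetime import datetime, timezone

import pandas as pd
import yaml

from . import __version__
from .errors import AmlsigError, PipelineError
from .io_formats import (
    ExpressionMatrix,
    read_expression_matrix,
    read_gmt,
    read_tabular_metadata,
    write_expression_matrix,
    write_results,
)
from .harmonize import (
    compute_difference_matrix,
    quantile_normalize_joint,
    restrict_to_common_probes,
    select_reference_probes,
)
from .signature_enrichment import (
    call_signature,
    enrichment_test,
    map_degs_to_probes,
)
from .geneset_overlap import enrich_genesets
from .cohort_stats import km_estimate, logrank_test, quartile_stratify
from .synthetic_data import (
    SimulationConfig,
    simulate_deg_list,
    simulate_survival_cohort,
    simulate_two_cohort_expression,
)

logger = logging.getLogger("amlsig")

_STAGES = [
    "restrict",
    "quantile_normalize",
    "select_reference",
    "difference",
    "map_degs",
    "enrichment_test",
    "call_signature",
]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {path!r} must be a mapping")
    return cfg


def write_manifest(out_dir: str, params: dict, input_paths: dict, seed) -> str:
    manifest = {
        "tool": "amlsig",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "parameters": params,
        "input_hashes": {k: _sha256(v) for k, v in input_paths.items()},
        "stages": _STAGES,
    }
    path = os.path.join(out_dir, "run_manifest.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _mark_failed(out_dir: str, stage: str, exc: Exception) -> None:
    try:
        with open(os.path.join(out_dir, "FAILED"), "w", encoding="utf-8") as fh:
            fh.write(f"stage: {stage}\nerror: {exc}\n")
    except OSError:
        pass


def simulate_inputs(config: dict, out_dir: str, seed: int | None = None):
    """Run the generator and persist all artifacts as pipeline input TSVs."""
    sim_params = dict(config.get("simulation", {}))
    if seed is not None:
        sim_params["seed"] = seed
    if "baseline_mean_range" in sim_params:
        sim_params["baseline_mean_range"] = tuple(sim_params["baseline_mean_range"])
    n_decoys = int(sim_params.pop("n_decoys", 20))
    sim = SimulationConfig(**sim_params)
    mat_a, mat_b, annot, orth, truth = simulate_two_cohort_expression(sim)
    degs = simulate_deg_list(truth, n_decoys=n_decoys, seed=sim.seed)

    os.makedirs(out_dir, exist_ok=True)
    write_expression_matrix(mat_a, os.path.join(out_dir, "matrix_a.tsv"))
    write_expression_matrix(mat_b, os.path.join(out_dir, "matrix_b.tsv"))
    annot_df = pd.DataFrame(
        sorted(annot.mapping.items()), columns=["probe_id", "gene_symbol"]
    )
    orth_rows = [
        (m, h) for m, hs in sorted(orth.mapping.items()) for h in sorted(hs)
    ]
    orth_df = pd.DataFrame(orth_rows, columns=["mouse_symbol", "human_symbol"])
    meta = pd.concat([mat_a.sample_meta, mat_b.sample_meta]).reset_index()
    write_results(
        {
            "probe_annotation": annot_df,
            "ortholog_map": orth_df,
            "deg_list": degs.entries,
            "sample_annotation": meta,
        },
        out_dir,
    )
    truth_json = {
        "signature_genes": sorted(truth.signature_genes),
        "signature_probes": sorted(truth.signature_probes),
        "reference_probe_pool": sorted(truth.reference_probe_pool),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(truth.config).items()
        },
    }
    with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(truth_json, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return mat_a, mat_b, annot, orth, degs, truth


def run_signature_pipeline(config: dict, out_dir: str, seed: int | None = None) -> dict:
    """Execute the full pipeline described by ``config`` into ``out_dir``.

    ``config`` keys (all stage parameters optional, defaults shown):
    ``simulate`` (bool) with a ``simulation`` sub-mapping, or the input paths
    ``matrix_a``, ``matrix_b``, ``probe_annotation`` (or ``annot_a``/
    ``annot_b``), ``orthologs``, ``degs``; ``q_var``/``q_mean`` (0.25),
    ``min_reference`` (10), ``alpha`` (0.05), ``fdr`` (false), ``pooled``
    (false); optional ``gmt`` for gene-set overlap and ``survival`` /
    ``simulate_survival`` for the survival stage. Returns a dict of result
    objects plus the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    stage = "load_inputs"
    try:
        input_paths: dict[str, str] = {}
        if config.get("simulate"):
            mat_a, mat_b, annot_a, orth, degs, truth = simulate_inputs(
                config, out_dir, seed
            )
            annot_b = annot_a
        else:
            required = ["matrix_a", "matrix_b", "orthologs", "degs"]
            missing = [k for k in required if k not in config]
            if "probe_annotation" not in config and not (
                "annot_a" in config and "annot_b" in config
            ):
                missing.append("probe_annotation")
            if missing:
                raise PipelineError(f"missing required input(s): {missing}")
            mat_a = read_expression_matrix(config["matrix_a"])
            mat_b = read_expression_matrix(config["matrix_b"])
            if "probe_annotation" in config:
                annot_a = annot_b = read_tabular_metadata(
                    config["probe_annotation"], "probe_annotation"
                )
                input_paths["probe_annotation"] = config["probe_annotation"]
            else:
                annot_a = read_tabular_metadata(config["annot_a"], "probe_annotation")
                annot_b = read_tabular_metadata(config["annot_b"], "probe_annotation")
                input_paths["annot_a"] = config["annot_a"]
                input_paths["annot_b"] = config["annot_b"]
            orth = read_tabular_metadata(config["orthologs"], "ortholog_map")
            degs = read_tabular_metadata(config["degs"], "deg_list")
            truth = None
            for k in required:
                input_paths[k] = config[k]

        results: dict = {}
        stage = "restrict"
        logger.info("restricting to common probes")
        a, b = restrict_to_common_probes(mat_a, mat_b)

        stage = "quantile_normalize"
        logger.info("joint quantile normalization of %d + %d samples",
                    len(a.sample_ids), len(b.sample_ids))
        aq, bq = quantile_normalize_joint(a, b)
        write_expression_matrix(aq, os.path.join(out_dir, "matrix_a_qnorm.tsv"))
        write_expression_matrix(bq, os.path.join(out_dir, "matrix_b_qnorm.tsv"))

        stage = "select_reference"
        ref = select_reference_probes(
            aq,
            bq,
            q_var=float(config.get("q_var", 0.25)),
            q_mean=float(config.get("q_mean", 0.25)),
            min_reference=int(config.get("min_reference", 10)),
            mode=config.get("reference_mode", "low"),
        )
        logger.info("selected %d reference probes", len(ref.probe_ids))
        results["reference"] = ref

        stage = "difference"
        d_a = compute_difference_matrix(aq, ref)
        d_b = compute_difference_matrix(bq, ref)

        stage = "map_degs"
        mapped = map_degs_to_probes(degs, orth, annot_a, annot_b)
        logger.info("mapped %d probe rows, %d genes unmapped",
                    len(mapped.mapped), len(mapped.unmapped_report))
        results["mapped"] = mapped

        stage = "enrichment_test"
        alpha = float(config.get("alpha", 0.05))
        use_fdr = bool(config.get("fdr", False))
        table = enrichment_test(
            d_a, d_b, mapped,
            alpha=alpha, use_fdr=use_fdr, pooled=bool(config.get("pooled", False)),
        )
        results["enrichment"] = table

        stage = "call_signature"
        signature = call_signature(table, alpha=alpha, use_fdr=use_fdr)
        results["signature"] = signature
        logger.info("signature: %d gene(s)", len(signature.genes))

        tables = {
            "reference_probes": pd.DataFrame(
                {"probe_id": sorted(ref.probe_ids)}
            ),
            "per_sample_reference": ref.per_sample_reference.rename("reference_value")
            .rename_axis("sample_id")
            .reset_index(),
            "enrichment_table": table,
            "signature_genes": signature.summary,
            "unmapped_report": mapped.unmapped_report,
        }

        if "gmt" in config:
            stage = "geneset_overlap"
            collection = read_gmt(config["gmt"])
            input_paths["gmt"] = config["gmt"]
            universe = sorted(annot_a.genes() & annot_b.genes())
            if signature.genes:
                overlaps = enrich_genesets(
                    set(signature.genes),
                    collection,
                    universe,
                    q_threshold=float(config.get("q_threshold", 0.05)),
                )
            else:
                from .geneset_overlap import OVERLAP_COLUMNS

                overlaps = pd.DataFrame(columns=OVERLAP_COLUMNS + ["significant"])
            results["geneset_overlap"] = overlaps
            tables["geneset_overlap"] = overlaps

        surv_table = None
        if "survival" in config:
            stage = "survival"
            surv_table = read_tabular_metadata(config["survival"], "survival")
            input_paths["survival"] = config["survival"]
        elif config.get("simulate_survival"):
            stage = "survival"
            sp = dict(config.get("survival_params", {}))
            surv_table = simulate_survival_cohort(
                n=int(sp.get("n", 150)),
                hazard_ratio=float(sp.get("hazard_ratio", 2.0)),
                baseline_median_days=float(sp.get("baseline_median_days", 365.0)),
                censor_rate=float(sp.get("censor_rate", 0.3)),
                seed=seed if seed is not None else int(sp.get("seed", 0)),
            )
        if surv_table is not None:
            surv_results = survival_analysis(surv_table)
            results["survival"] = surv_results
            tables["survival_strata"] = surv_results["strata_table"]
            tables["km_curves"] = surv_results["km_table"]
            tables["logrank"] = surv_results["logrank_table"]

        write_results(tables, out_dir)
        params = {
            k: v for k, v in config.items() if not isinstance(v, (dict, list))
        }
        write_manifest(out_dir, params | {"alpha": alpha, "fdr": use_fdr},
                       input_paths, seed)
        results["out_dir"] = out_dir
        results["truth"] = truth
        return results
    except AmlsigError as exc:
        _mark_failed(out_dir, stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def survival_analysis(table) -> dict:
    """Quartile-stratify, estimate KM per stratum, log-rank high vs low."""
    from .io_formats import SurvivalTable

    data = table.data.copy()
    data["stratum"] = quartile_stratify(data["expression"].to_numpy())
    high = SurvivalTable(data[data["stratum"] == "high"].reset_index(drop=True))
    low = SurvivalTable(data[data["stratum"] == "low"].reset_index(drop=True))
    km_rows = []
    curves = {}
    for name, stratum in (("high", high), ("low", low)):
        curve = km_estimate(stratum)
        curves[name] = curve
        for t, s, r, d in zip(
            curve.event_times, curve.survival, curve.at_risk, curve.n_events
        ):
            km_rows.append(
                {"stratum": name, "time_days": t, "survival": s,
                 "at_risk": r, "n_events": d}
            )
    lr = logrank_test(high, low)
    logrank_table = pd.DataFrame(
        [
            {
                "chi_square": lr.chi_square,
                "df": lr.df,
                "p_value": lr.p_value,
                "observed_high": lr.observed["high"],
                "expected_high": lr.expected["high"],
                "observed_low": lr.observed["low"],
                "expected_low": lr.expected["low"],
                "flag": lr.flag,
            }
        ]
    )
    return {
        "strata_table": data,
        "km_table": pd.DataFrame(
            km_rows, columns=["stratum", "time_days", "survival", "at_risk", "n_events"]
        ),
        "km_curves": curves,
        "logrank": lr,
        "logrank_table": logrank_table,
        "n_high": len(high),
        "n_low": len(low),
    }
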