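"""Config-driven end-to-end runs with a machine-readable report.

A run config (YAML or a plain dict) selects pipeline stages and their
parameters; :func:`run_pipeline` executes the stages in dependency order,
writes each stage's outputs under the configured output directory and
returns a report echoing every parameter, the checksums of consumed
inputs and the headline numbers of each stage. Two runs of the same
config over the same inputs produce identical reports except for the
timestamp. The screening thresholds (2-fold change, FDR < 0.1, support
in at least 4 cell lines, 1000 permutations, enrichment FDR < 0.05) are
the defaults of the corresponding keys.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

import foxnet
from foxnet.de_signature import codirectional_intersection, filter_de, read_de_table
from foxnet.gsea import (
    RankedList,
    gsea_preranked,
    read_gmt,
    read_ranked_list,
    results_to_frame,
)
from foxnet.network_screen import (
    build_screen_features,
    load_foxm1_target_panel,
    compare_candidates,
    rank_candidates,
    read_network,
    NetworkNeighborhood,
)
from foxnet.signature_core import read_signatures, write_signatures
from foxnet.simulate import (
    DeSimConfig,
    ScreenSimConfig,
    simulate_de_tables,
    simulate_screen,
)

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "StageError", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised when the run config violates the schema."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails."""


#: section -> {key: default}; None marks "required when section active"
_SCHEMA: dict[str, dict[str, Any]] = {
    "": {"output_dir": None, "seed": 0, "stages": None},
    "simulate_screen": {
        "n_genes": 978,
        "n_decoy_compounds": 49,
        "n_partner_genes": 3,
        "mixing_weight": 0.7,
        "n_replicates": 1,
    },
    "simulate_de": {
        "n_genes": 16275,
        "n_up_shared": 577,
        "n_down_shared": 687,
        "n_discordant": 77,
        "n_model_specific": 200,
        "effect_size": 2.0,
    },
    "screen": {
        "signatures": "",
        "metadata": "",
        "network": "",
        "proxy_target": "NPM1",
        "support_threshold": 0.3,
        "min_support": 4,
        "lambda_indirect": 0.5,
        "similarity": "spearman",
    },
    "de_signature": {
        "table_a": "",
        "table_b": "",
        "fold_threshold": 2.0,
        "fdr_threshold": 0.1,
        "biotype_filter": "protein_coding",
    },
    "gsea": {
        "ranked": "",
        "gmt": "",
        "n_permutations": 1000,
        "min_size": 15,
        "max_size": 500,
        "weight_exponent": 1.0,
        "fdr_threshold": 0.05,
        "ranking_metric": "log2_fc",
    },
    "panel": {
        "candidates": ["STL427944", "benzamil"],
        "suppression_threshold": -1.0,
    },
}

_STAGE_ORDER = [
    "simulate_screen",
    "simulate_de",
    "screen",
    "panel",
    "de_signature",
    "gsea",
]


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return config


def _validate(config: Mapping[str, Any]) -> dict:
    errors: list[str] = []
    top = _SCHEMA[""]
    merged: dict[str, Any] = {}
    for key in ("output_dir", "stages"):
        if key not in config:
            errors.append(f"missing required key: {key}")
    unknown = [
        k for k in config
        if k not in top and k not in _SCHEMA
    ]
    errors.extend(f"unknown key: {k}" for k in unknown)
    stages = config.get("stages", [])
    if not isinstance(stages, list) or not stages:
        errors.append("stages must be a non-empty list")
    else:
        for stage in stages:
            if stage not in _STAGE_ORDER:
                errors.append(f"unknown stage: {stage}")
    for section, defaults in _SCHEMA.items():
        if section == "":
            continue
        given = config.get(section, {})
        if not isinstance(given, Mapping):
            errors.append(f"section {section} must be a mapping")
            continue
        bad = [k for k in given if k not in defaults]
        errors.extend(f"unknown key: {section}.{k}" for k in bad)
        merged[section] = {**defaults, **dict(given)}
    if errors:
        raise ConfigError("; ".join(errors))
    merged[""] = {
        "output_dir": config["output_dir"],
        "seed": int(config.get("seed", 0)),
        "stages": [s for s in _STAGE_ORDER if s in stages],
    }
    return merged


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: Mapping[str, Any] | str | Path) -> dict:
    """Execute the configured stages and return the run report.

    Raises :class:`ConfigError` on schema violations and
    :class:`StageError` when a stage fails (the partial report is attached
    to the exception as ``.report``).
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    merged = _validate(config)
    top = merged[""]
    out_dir = Path(top["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = top["seed"]
    report: dict[str, Any] = {
        "software": {"name": "foxnet", "version": foxnet.__version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "stages": {},
        "input_checksums": {},
    }

    state: dict[str, Any] = {}
    try:
        for stage in top["stages"]:
            params = merged[stage]
            logger.info("stage %s: %s", stage, params)
            handler = _HANDLERS[stage]
            outputs = handler(params, seed, out_dir, state, report)
            report["stages"][stage] = {"parameters": params, "outputs": outputs}
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # stage failure: attach partial report
        error = StageError(f"stage {stage} failed: {exc}")
        error.report = report  # type: ignore[attr-defined]
        raise error from exc
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report


# ---------------------------------------------------------------------------
# Stage handlers


def _stage_simulate_screen(params, seed, out_dir, state, report):
    config = ScreenSimConfig(
        n_genes=params["n_genes"],
        n_decoy_compounds=params["n_decoy_compounds"],
        n_partner_genes=params["n_partner_genes"],
        mixing_weight=params["mixing_weight"],
        n_replicates=params["n_replicates"],
        seed=seed,
    )
    collection, truth = simulate_screen(config)
    sig_path = out_dir / "signatures.tsv"
    write_signatures(collection, sig_path)
    net_path = out_dir / "network.tsv"
    with open(net_path, "w") as fh:
        for partner in truth["partners"]:
            fh.write(f"{truth['proxy_target']}\t{partner}\n")
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    state["screen_collection"] = collection
    state["screen_truth"] = truth
    return {
        "signatures": str(sig_path),
        "network": str(net_path),
        "planted_compound": truth["planted_compound"],
        "n_signatures": len(collection),
    }


def _stage_simulate_de(params, seed, out_dir, state, report):
    config = DeSimConfig(
        n_genes=params["n_genes"],
        n_up_shared=params["n_up_shared"],
        n_down_shared=params["n_down_shared"],
        n_discordant=params["n_discordant"],
        n_model_specific=params["n_model_specific"],
        effect_size=params["effect_size"],
        seed=seed,
    )
    table_a, table_b, truth = simulate_de_tables(config)
    path_a = out_dir / "de_model_a.tsv"
    path_b = out_dir / "de_model_b.tsv"
    table_a.to_csv(path_a, sep="\t", index=False)
    table_b.to_csv(path_b, sep="\t", index=False)
    state["de_tables"] = (table_a, table_b)
    state["de_truth"] = truth
    return {"table_a": str(path_a), "table_b": str(path_b)}


def _stage_screen(params, seed, out_dir, state, report):
    if "screen_collection" in state:
        collection = state["screen_collection"]
        truth = state.get("screen_truth", {})
        network = NetworkNeighborhood(
            truth.get("proxy_target", params["proxy_target"]),
            tuple(truth.get("partners", ())),
        )
    else:
        for key in ("signatures", "network"):
            if not params[key]:
                raise ConfigError(f"screen.{key} is required")
            if not Path(params[key]).exists():
                raise ConfigError(
                    f"screen.{key}: path {params[key]} does not exist"
                )
            report["input_checksums"][f"screen.{key}"] = _checksum(
                Path(params[key])
            )
        collection = read_signatures(
            params["signatures"],
            metadata_path=params["metadata"] or None,
        )
        network = read_network(params["network"], params["proxy_target"])
    kd = collection.subset(perturbation_type="knockdown")
    compounds = collection.subset(perturbation_type="compound")
    features = build_screen_features(
        compounds,
        kd,
        network,
        support_threshold=params["support_threshold"],
        method=params["similarity"],
    )
    ranking = rank_candidates(
        features,
        seed=seed,
        lambda_indirect=params["lambda_indirect"],
        min_support=params["min_support"],
    )
    frame = ranking.to_frame()
    support = {f.compound_id: f.support_count for f in features}
    frame["support_count"] = frame["compound_id"].map(support)
    out_path = out_dir / "ranking.tsv"
    frame.to_csv(out_path, sep="\t", index=False)
    state["ranking"] = ranking
    head = frame.head(5).to_dict(orient="records")
    return {"ranking": str(out_path), "top_candidates": head}


def _stage_panel(params, seed, out_dir, state, report):
    table = load_foxm1_target_panel()
    comparison = compare_candidates(
        table, params["candidates"], params["suppression_threshold"]
    )
    out_path = out_dir / "panel_comparison.tsv"
    pd.DataFrame(
        comparison, columns=["candidate", "n_suppressed", "mean_z"]
    ).to_csv(out_path, sep="\t", index=False)
    return {
        "comparison": [
            {"candidate": c, "n_suppressed": n, "mean_z": z}
            for c, n, z in comparison
        ],
        "table": str(out_path),
    }


def _stage_de_signature(params, seed, out_dir, state, report):
    if "de_tables" in state:
        table_a, table_b = state["de_tables"]
    else:
        for key in ("table_a", "table_b"):
            if not params[key]:
                raise ConfigError(f"de_signature.{key} is required")
            if not Path(params[key]).exists():
                raise ConfigError(
                    f"de_signature.{key}: path {params[key]} does not exist"
                )
            report["input_checksums"][f"de_signature.{key}"] = _checksum(
                Path(params[key])
            )
        table_a = read_de_table(params["table_a"])
        table_b = read_de_table(params["table_b"])
    biotype = params["biotype_filter"] or None
    if biotype and "biotype" not in table_a.columns:
        biotype = None
    sets_a = filter_de(table_a, params["fold_threshold"],
                       params["fdr_threshold"], biotype)
    sets_b = filter_de(table_b, params["fold_threshold"],
                       params["fdr_threshold"], biotype)
    signature = codirectional_intersection(sets_a, sets_b)
    signature.to_json(out_dir / "de_signature.json")
    for name, genes in (
        ("up_both", signature.up_both),
        ("down_both", signature.down_both),
        ("combined", signature.combined),
    ):
        (out_dir / f"genes_{name}.txt").write_text(
            "\n".join(sorted(genes)) + "\n"
        )
    state["de_signature"] = signature
    state["de_table_a"] = table_a
    return {"counts": signature.counts(), "json": str(out_dir / "de_signature.json")}


def _stage_gsea(params, seed, out_dir, state, report):
    if params["ranked"]:
        if not Path(params["ranked"]).exists():
            raise ConfigError(f"gsea.ranked: path {params['ranked']} does not exist")
        ranked = read_ranked_list(params["ranked"])
    elif "de_table_a" in state:
        ranked = RankedList.from_de_table(
            state["de_table_a"], metric=params["ranking_metric"]
        )
    else:
        raise ConfigError("gsea.ranked is required (no DE stage output available)")
    if not params["gmt"]:
        raise ConfigError("gsea.gmt is required")
    if not Path(params["gmt"]).exists():
        raise ConfigError(f"gsea.gmt: path {params['gmt']} does not exist")
    report["input_checksums"]["gsea.gmt"] = _checksum(Path(params["gmt"]))
    collection = read_gmt(params["gmt"])
    results = gsea_preranked(
        ranked,
        collection,
        n_permutations=params["n_permutations"],
        min_size=params["min_size"],
        max_size=params["max_size"],
        seed=seed,
        weight_exponent=params["weight_exponent"],
    )
    frame = results_to_frame(results)
    out_path = out_dir / "gsea_results.tsv"
    frame.to_csv(out_path, sep="\t", index=False)
    significant = frame[frame["fdr_q"] < params["fdr_threshold"]]
    return {
        "results": str(out_path),
        "n_sets_tested": len(frame),
        "significant_sets": significant["set_name"].tolist(),
    }


_HANDLERS = {
    "simulate_screen": _stage_simulate_screen,
    "simulate_de": _stage_simulate_de,
    "screen": _stage_screen,
    "panel": _stage_panel,
    "de_signature": _stage_de_signature,
    "gsea": _stage_gsea,
}
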