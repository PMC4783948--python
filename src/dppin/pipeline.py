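"""End-to-end orchestration of the differential-network biomarker analysis.

For each time point: screen the differential protein group, augment it with
highly connected PPI neighbors, induce the candidate network, fit the case
network from that time point's case arrays and the control network from the
(by default pooled) control arrays, form the difference matrix, compute
TRVs and permutation p-values, screen significant proteins and export the
network.  Core biomarkers are the intersections of the per-time-point
significant sets (over all time points and over adjacent pairs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .differential import (
    classify_edges,
    compute_trv,
    core_biomarkers,
    difference_matrix,
    export_network,
    screen_significant,
    trv_pvalues,
)
from .errors import DataError, EmptyNetworkError
from .expression import (
    ExpressionMatrix,
    group_means,
    log2_fold_change,
    quantile_normalize,
    read_design,
    read_expression_table,
)
from .inference import InferenceSettings, fit_condition_network
from .ppi import (
    augment_with_neighbors,
    build_candidate_network,
    read_ppi_edges,
    select_differential_proteins,
    write_protein_set,
)

log = logging.getLogger("dppin")

RECORD_SCHEMA = ["protein", "trv", "p_value", "case_mean", "control_mean", "log2_fc"]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _settings(config: RunConfig) -> InferenceSettings:
    return InferenceSettings(
        alpha=config.alpha,
        screen_alpha=config.screen_alpha,
        order_cap=config.order_cap,
        allow_degenerate=config.allow_degenerate,
        pooled_control=config.pooled_control,
        intercept=config.intercept,
    )


def build_records(
    expr: ExpressionMatrix,
    time_point: str,
    trv: pd.Series,
    pvals: pd.Series,
) -> pd.DataFrame:
    """Assemble the per-protein report table for one time point."""
    means = group_means(expr, time_point).loc[trv.index]
    lfc = log2_fold_change(
        means["case_mean"].to_numpy(), means["control_mean"].to_numpy()
    )
    return pd.DataFrame(
        {
            "protein": trv.index,
            "trv": trv.to_numpy(),
            "p_value": pvals.reindex(trv.index).to_numpy(),
            "case_mean": means["case_mean"].to_numpy(),
            "control_mean": means["control_mean"].to_numpy(),
            "log2_fc": np.asarray(lfc),
        }
    ).reset_index(drop=True)


def analyze_time_point(
    expr: ExpressionMatrix,
    ppi,
    time_point: str,
    config: RunConfig,
    seed: int,
):
    """Run the full per-time-point analysis; returns a result dict."""
    settings = _settings(config)
    diff = select_differential_proteins(
        expr, time_point, config.screening_method, config.screening_threshold
    )
    group = augment_with_neighbors(diff, ppi, config.min_links)
    if not group:
        raise EmptyNetworkError("differential protein group is empty")
    net = build_candidate_network(group, ppi)
    log.info(
        "[%s] differential group %d -> augmented %d -> network %d nodes / %d edges",
        time_point, len(diff), len(group), len(net.nodes), net.n_edges,
    )
    case_ids = expr.sample_ids("case", time_point)
    control_ids = expr.sample_ids(
        "control", None if config.pooled_control else time_point
    )
    values = expr.values.loc[net.nodes]
    a_case = fit_condition_network(
        values[case_ids], net, settings, condition="case", time_point=time_point
    )
    a_control = fit_condition_network(
        values[control_ids], net, settings, condition="control", time_point=time_point
    )
    d = difference_matrix(a_case, a_control)
    trv = compute_trv(d)
    pvals = trv_pvalues(
        expr, net, time_point,
        b=config.permutations, seed=seed, settings=settings, observed_trv=trv,
    )
    records = build_records(expr, time_point, trv, pvals)
    significant = screen_significant(
        records, config.p_threshold, config.fc_threshold, config.require_fc
    )
    return {
        "time_point": time_point,
        "network": net,
        "a_case": a_case,
        "a_control": a_control,
        "difference": d,
        "trv": trv,
        "records": records,
        "significant": significant,
    }


def run_pipeline(config: RunConfig, expr: ExpressionMatrix | None = None, ppi=None) -> dict:
    """Run the whole analysis and write the result directory.

    ``expr``/``ppi`` may be passed directly (e.g. from the simulator);
    otherwise they are read from the configured paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}
    if expr is None:
        design = read_design(config.design, sep="\t")
        expr = read_expression_table(config.expression, design, sep=config.sep)
        checksums = {
            "expression": _sha256(config.expression),
            "design": _sha256(config.design),
        }
    if ppi is None:
        ppi = read_ppi_edges(config.ppi, config.ppi_dialect, config.organism_filter)
        checksums["ppi"] = _sha256(config.ppi)

    if config.normalization_scope != "none":
        expr = quantile_normalize(expr, scope=config.normalization_scope)
        expr.to_tsv(out / "normalized_expression.tsv")

    time_points = expr.time_points
    results, failures = {}, {}
    for t_idx, tp in enumerate(time_points):
        tp_seed = (config.seed + 1009 * (t_idx + 1)) % (2**31)
        try:
            res = analyze_time_point(expr, ppi, tp, config, tp_seed)
        except (DataError, EmptyNetworkError) as exc:
            log.warning("[%s] skipped: %s", tp, exc)
            failures[tp] = str(exc)
            continue
        results[tp] = res
        tag = str(tp).replace("/", "_")
        tp_dir = out / f"tp_{tag}"
        tp_dir.mkdir(exist_ok=True)
        res["a_case"].to_tsv(tp_dir / "a_case.tsv", tp_dir / "a_case.diagnostics.json")
        res["a_control"].to_tsv(
            tp_dir / "a_control.tsv", tp_dir / "a_control.diagnostics.json"
        )
        records = res["records"].copy()
        records["log2_fc"] = records["log2_fc"].round(2)
        records.sort_values(
            ["trv", "protein"], ascending=[False, True]
        ).to_csv(tp_dir / "trv_table.tsv", sep="\t", index=False, float_format="%.6g")
        write_protein_set(res["significant"], tp_dir / "significant_proteins.txt")
        labels = classify_edges(res["difference"])
        export_network(
            res["difference"],
            res["trv"],
            tp_dir / "network",
            labels=labels,
            p_values=res["records"].set_index("protein")["p_value"],
            log2_fc=res["records"].set_index("protein")["log2_fc"],
        )

    sig_sets = [results[tp]["significant"] for tp in time_points if tp in results]
    core: dict = {"all": set(), "adjacent": []}
    if len(sig_sets) >= 2:
        core["all"] = core_biomarkers(sig_sets, "all")
        core["adjacent"] = core_biomarkers(sig_sets, "adjacent")
        write_protein_set(core["all"], out / "core_biomarkers.txt")
        rows = []
        analyzed = [tp for tp in time_points if tp in results]
        for protein in sorted(core["all"]):
            for tp in analyzed:
                rec = results[tp]["records"]
                row = rec[rec["protein"] == protein].iloc[0]
                rows.append(
                    (protein, tp, row["trv"], row["p_value"], row["case_mean"],
                     row["control_mean"], round(row["log2_fc"], 2))
                )
        pd.DataFrame(
            rows,
            columns=["protein", "time_point", "trv", "p_value", "case_mean",
                     "control_mean", "log2_fc"],
        ).to_csv(out / "core_table.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "input_checksums": checksums,
        "time_points": list(map(str, time_points)),
        "analyzed": [str(tp) for tp in results],
        "failures": failures,
        "n_significant": {str(tp): len(results[tp]["significant"]) for tp in results},
        "core_all": sorted(core["all"]),
        "core_adjacent": [sorted(s) for s in core["adjacent"]],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {"results": results, "core": core, "manifest": manifest, "out_dir": str(out)}


def report(result_dir, top_n: int = 20) -> str:
    """Human-readable summary: top-N TRV table per time point + core table."""
    out = Path(result_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"missing {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lines = []
    for tp in manifest["analyzed"]:
        table_path = out / f"tp_{str(tp).replace('/', '_')}" / "trv_table.tsv"
        if not table_path.exists():
            raise DataError(f"missing {table_path}")
        table = pd.read_csv(table_path, sep="\t")
        table = table.sort_values(["trv", "protein"], ascending=[False, True])
        lines.append(f"== Top {min(top_n, len(table))} proteins by TRV at {tp} ==")
        lines.append(table.head(top_n).to_string(index=False))
        lines.append("")
    core_path = out / "core_table.tsv"
    if core_path.exists():
        lines.append("== Core network biomarkers (all time points) ==")
        lines.append(pd.read_csv(core_path, sep="\t").to_string(index=False))
    text = "\n".join(lines)
    with open(out / "report.txt", "w") as fh:
        fh.write(text + "\n")
    return text
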