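"""Difference matrices, the TRV node statistic, and significance screening.

The differential network for time point k is the entrywise difference of
the case and control interaction matrices, D^k = A_case(k) - A_control,
aligned on the union of their node sets (an edge retained in only one
condition contributes its full coefficient).  Each protein's relevance is
summarized by the TRV — the row sum of absolute coefficient differences,

    TRV_i = sum_j |d_ij|,

a nonnegative score that is zero exactly when protein i's outgoing
associations are identical in the two conditions.  Statistical significance
is assessed by permuting the case/control labels of the pooled arrays,
refitting both networks and recomputing the TRV for each permutation; the
empirical p-value carries the standard +1 correction so it is never zero.

Edges of D are classified by where their value falls relative to the
mean +/- one (population) standard deviation of the nonzero entries —
``red`` for strongly increased association in the case network, ``blue``
for strongly decreased, ``neutral`` otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .errors import ValidationError
from .expression import ExpressionMatrix
from .inference import InferenceSettings, InteractionMatrix, fit_condition_network
from .ppi import CandidateNetwork


@dataclass
class DifferenceMatrix:
    """Entrywise case-minus-control coefficient differences on the union index."""

    nodes: list
    d: np.ndarray
    time_point: str | None = None

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if not np.isfinite(self.d).all():
            raise ValidationError("difference matrix contains non-finite entries")


def difference_matrix(
    a_case: InteractionMatrix, a_control: InteractionMatrix
) -> DifferenceMatrix:
    """D = A_case - A_control aligned on the union of node sets.

    Entries absent from one matrix are treated as zero, so an edge retained
    in only one condition contributes its full coefficient.  Disjoint node
    sets produce a signed block union with a warning.
    """
    nodes = sorted(set(a_case.nodes) | set(a_control.nodes))
    if not set(a_case.nodes) & set(a_control.nodes):
        warnings.warn("case and control networks share no nodes")
    m = len(nodes)
    idx = {p: i for i, p in enumerate(nodes)}
    d = np.zeros((m, m))

    def _scatter(mat: InteractionMatrix, sign: float) -> None:
        rows = [idx[p] for p in mat.nodes]
        sel = np.ix_(rows, rows)
        d[sel] += sign * mat.coefficients

    _scatter(a_case, +1.0)
    _scatter(a_control, -1.0)
    return DifferenceMatrix(nodes=nodes, d=d, time_point=a_case.time_point)


def compute_trv(d: DifferenceMatrix) -> pd.Series:
    """TRV_i = sum_j |d_ij| (row sums of absolute differences)."""
    trv = np.abs(d.d).sum(axis=1)
    return pd.Series(trv, index=d.nodes, name="trv")


# -- permutation p-values ---------------------------------------------------


def _fit_trv(
    values: pd.DataFrame,
    net: CandidateNetwork,
    case_ids: list,
    control_ids: list,
    settings: InferenceSettings,
    time_point: str | None,
) -> pd.Series:
    a_case = fit_condition_network(
        values[case_ids], net, settings, condition="case", time_point=time_point
    )
    a_control = fit_condition_network(
        values[control_ids], net, settings, condition="control", time_point=time_point
    )
    return compute_trv(difference_matrix(a_case, a_control))


def trv_pvalues(
    expr: ExpressionMatrix,
    net: CandidateNetwork,
    time_point: str,
    b: int = 200,
    seed: int = 0,
    settings: InferenceSettings | None = None,
    observed_trv: pd.Series | None = None,
) -> pd.Series:
    """Permutation p-values for the TRV of every network node.

    The null pools the case samples at ``time_point`` with the control
    samples (all control arrays when ``settings.pooled_control``, else the
    time point's controls), randomly reassigns case/control labels b times
    respecting group sizes, refits both networks and recomputes the TRV.
    p_i = (1 + #{TRV*_i >= TRV_i}) / (1 + b).  Identical seed and settings
    give identical p-values.
    """
    if b < 1:
        raise ValidationError("number of permutations b must be >= 1")
    settings = settings or InferenceSettings()
    case_ids = expr.sample_ids("case", time_point)
    control_ids = expr.sample_ids(
        "control", None if settings.pooled_control else time_point
    )
    pooled = case_ids + control_ids
    if len(pooled) < 4:
        raise ValidationError("permutation test needs >= 4 pooled samples")
    values = expr.values.loc[[p for p in net.nodes]]
    if observed_trv is None:
        observed_trv = _fit_trv(values, net, case_ids, control_ids, settings, time_point)
    observed_trv = observed_trv.reindex(net.nodes)
    n_case = len(case_ids)
    n_distinct = math.comb(len(pooled), n_case)
    if n_distinct < b:
        warnings.warn(
            f"only {n_distinct} distinct label assignments; sampling "
            "permutations with replacement"
        )
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(net.nodes))
    pooled_arr = np.array(pooled)
    for _ in range(b):
        perm = rng.permutation(len(pooled_arr))
        perm_case = list(pooled_arr[perm[:n_case]])
        perm_control = list(pooled_arr[perm[n_case:]])
        trv_star = _fit_trv(values, net, perm_case, perm_control, settings, time_point)
        exceed += (
            trv_star.reindex(net.nodes).to_numpy()
            >= observed_trv.to_numpy() - 1e-12
        )
    pvals = (1.0 + exceed) / (1.0 + b)
    return pd.Series(pvals, index=net.nodes, name="p_value")


# -- screening and reporting ------------------------------------------------

RECORD_COLUMNS = ["protein", "trv", "p_value", "case_mean", "control_mean", "log2_fc"]


def screen_significant(
    records: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    require_fc: bool = True,
) -> set:
    """Select proteins with p_value < p_threshold, optionally intersected
    with |log2_fc| > log2(fc_threshold).

    ``records`` needs columns ``protein``, ``p_value`` and (when
    ``require_fc``) ``log2_fc``.
    """
    if not 0 < p_threshold < 1:
        raise ValidationError("p_threshold must be in (0, 1)")
    if fc_threshold <= 1:
        raise ValidationError("fc_threshold must be > 1")
    if records.empty:
        return set()
    keep = records["p_value"] < p_threshold
    if require_fc:
        keep &= records["log2_fc"].abs() > np.log2(fc_threshold)
    return set(records.loc[keep, "protein"])


def core_biomarkers(sets, mode: str = "all"):
    """Intersections of per-time-point significant sets.

    ``mode='all'`` returns the single intersection over every set;
    ``mode='adjacent'`` returns the list of pairwise intersections of
    consecutive sets (4-8, 8-24, 24-72 h in the four-time-point design).
    """
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValidationError("need at least two significance sets")
    if mode == "all":
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out
    if mode == "adjacent":
        return [sets[i] & sets[i + 1] for i in range(len(sets) - 1)]
    raise ValidationError(f"unknown core-biomarker mode {mode!r}")


def classify_edges(d: DifferenceMatrix) -> pd.DataFrame:
    """Label nonzero entries of D relative to their spread.

    mean and STD (population, ddof=0) are computed over the nonzero entries;
    entries >= mean + STD are ``red``, <= mean - STD ``blue``, the rest
    ``neutral``.  Fewer than two nonzero entries, or zero spread, labels
    everything neutral.
    """
    rows, cols = np.nonzero(d.d)
    vals = d.d[rows, cols]
    out = pd.DataFrame(
        {
            "source": [d.nodes[i] for i in rows],
            "target": [d.nodes[j] for j in cols],
            "d": vals,
        }
    )
    if len(vals) < 2:
        out["label"] = "neutral"
        return out
    mean, std = vals.mean(), vals.std(ddof=0)
    if std == 0:
        out["label"] = "neutral"
        return out
    label = np.where(
        vals >= mean + std, "red", np.where(vals <= mean - std, "blue", "neutral")
    )
    out["label"] = label
    return out


# -- export -----------------------------------------------------------------


def export_network(
    d: DifferenceMatrix,
    trv: pd.Series,
    out_prefix,
    labels: pd.DataFrame | None = None,
    p_values: pd.Series | None = None,
    log2_fc: pd.Series | None = None,
) -> dict:
    """Write Cytoscape-compatible files for a differential network.

    Produces ``<prefix>.sif`` (edges), ``<prefix>.edges.tsv`` (d value and
    red/blue/neutral label), ``<prefix>.nodes.tsv`` (TRV, p-value, log2 FC,
    node size scaled to TRV) and ``<prefix>.graphml`` with the same
    attributes.  Returns the path mapping.
    """
    out_prefix = str(out_prefix)
    if labels is None:
        labels = classify_edges(d)
    paths = {
        "sif": out_prefix + ".sif",
        "edges": out_prefix + ".edges.tsv",
        "nodes": out_prefix + ".nodes.tsv",
        "graphml": out_prefix + ".graphml",
    }
    with open(paths["sif"], "w") as fh:
        for _, row in labels.iterrows():
            fh.write(f"{row['source']}\tpp\t{row['target']}\n")
    labels.to_csv(paths["edges"], sep="\t", index=False, float_format="%.12g")

    trv = trv.reindex(d.nodes).fillna(0.0)
    max_trv = float(trv.max()) if len(trv) and trv.max() > 0 else 1.0
    node_table = pd.DataFrame({"protein": d.nodes, "trv": trv.to_numpy()})
    node_table["size"] = 20.0 + 40.0 * node_table["trv"] / max_trv
    if p_values is not None:
        node_table["p_value"] = p_values.reindex(d.nodes).to_numpy()
    if log2_fc is not None:
        node_table["log2_fc"] = log2_fc.reindex(d.nodes).to_numpy()
    node_table.to_csv(paths["nodes"], sep="\t", index=False, float_format="%.12g")

    g = nx.DiGraph()
    for _, row in node_table.iterrows():
        attrs = {k: row[k] for k in node_table.columns if k != "protein" and pd.notna(row[k])}
        g.add_node(row["protein"], **attrs)
    for _, row in labels.iterrows():
        g.add_edge(row["source"], row["target"], d=float(row["d"]), label=row["label"])
    nx.write_graphml(g, paths["graphml"])
    return paths
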