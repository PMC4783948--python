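"""Per-protein linear association fits and interaction-matrix assembly.

Each target protein i in a candidate network is modelled as a linear
combination of its interactors' expression, with no intercept:

    x_i(n) = sum_j alpha_ij * x_j(n) + w_i(n)

alpha_ij is the (dimensionless) association ability between target i and
interactor j, estimated by ordinary least squares over the arrays of one
condition.  Which interactors enter the model is decided in two stages:

1. *Order selection.*  Candidates are ranked by |Pearson correlation| with
   the target and nested models over the ranked prefix are scored with the
   Gaussian AIC, n*ln(RSS/n) + 2k.  A prefix is only extended while the
   newly added coefficient is individually significant (Student's t, with a
   Bonferroni correction for the number of candidates the ranking chose
   from — ranking picks the best of M_i correlations, so an uncorrected
   test would admit a spurious interactor far too often).  The chosen order
   is the AIC argmin over the admissible prefix, smallest order on ties.
2. *Pruning.*  At the chosen order, coefficients whose two-sided t-test
   p-value exceeds ``alpha`` are removed and the model is refit once on the
   survivors.

The retained coefficients of all rows assemble into the condition's
interaction matrix A (rows = targets); A is generally asymmetric because
row i's regression and row j's regression are independent fits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, EmptyNetworkError, ValidationError
from .ppi import CandidateNetwork

_RSS_FLOOR = 1e-12  # guards ln(0) on exact fits


# -- elementary operations -------------------------------------------------


def fit_least_squares(y: np.ndarray, x_cols: np.ndarray) -> tuple[np.ndarray, float]:
    """No-intercept least squares: coefficients minimizing ||y - X b||^2.

    Returns ``(coefficients, rss)``.  ``x_cols`` is n x k; k = 0 returns an
    empty coefficient vector with rss = sum(y^2).  Rank-deficient systems
    return the minimum-norm minimizer (SVD-based).
    """
    y = np.asarray(y, dtype=float).ravel()
    x_cols = np.asarray(x_cols, dtype=float)
    if x_cols.ndim == 1:
        x_cols = x_cols[:, None]
    if not np.isfinite(y).all() or not np.isfinite(x_cols).all():
        raise ValidationError("non-finite values in regression inputs")
    if y.size == 0:
        raise ValidationError("empty response vector")
    if x_cols.shape[1] == 0:
        return np.empty(0), float(y @ y)
    if x_cols.shape[0] != y.size:
        raise ValidationError("response/design length mismatch")
    beta, _, _, _ = np.linalg.lstsq(x_cols, y, rcond=None)
    resid = y - x_cols @ beta
    return beta, float(resid @ resid)


def aic_score(rss: float, n: int, k: int) -> float:
    """Gaussian AIC for a k-parameter no-intercept regression on n samples:
    n*ln(max(rss, eps)/n) + 2k."""
    if n <= 0:
        raise ValidationError("n must be positive")
    return n * np.log(max(rss, _RSS_FLOOR) / n) + 2 * k


def rank_candidates(y: np.ndarray, x: np.ndarray, names=None) -> list[int]:
    """Order candidate columns by descending |Pearson r| with the target.

    Zero-variance candidates get r = 0 and sort last.  Ties break
    lexicographically on ``names`` (column index if names are omitted).
    Returns the ordered list of column indices.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] == 0:
        return []
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    sy = np.sqrt(yc @ yc)
    sx = np.sqrt((xc * xc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r = np.nan_to_num(r, nan=0.0)
    keys = [str(j) for j in range(x.shape[1])] if names is None else [str(n) for n in names]
    return sorted(range(x.shape[1]), key=lambda j: (-abs(r[j]), keys[j]))


def _coef_inference(x_cols: np.ndarray, beta: np.ndarray, rss: float):
    """Classical OLS t statistics and two-sided p-values.

    Uses sigma2 = rss / (n - k) and cov = sigma2 * (X'X)^-1 (pseudo-inverse
    when X'X is singular).  Returns (t, p, df, sigma2).
    """
    n, k = x_cols.shape
    df = n - k
    if df <= 0:
        raise DegenerateDesignError("no residual degrees of freedom for t-test")
    sigma2 = rss / df
    xtx = x_cols.T @ x_cols
    try:
        cov = sigma2 * np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(xtx)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    t = np.nan_to_num(t, nan=0.0)
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p, df, sigma2


def select_model_order(
    y: np.ndarray,
    x_ranked: np.ndarray,
    order_cap: int | None = None,
    screen_alpha: float = 0.05,
    n_candidates_total: int | None = None,
) -> tuple[int, list[float], list[int]]:
    """Choose the model order by gated forward selection over the ranking.

    Candidates are visited in ranked order; one is accepted when (a) its
    incremental coefficient passes a Student's t-test at ``screen_alpha``
    Bonferroni-corrected by the candidate-pool size (the ranking picks the
    best of M_i correlations, so an uncorrected test would admit a spurious
    interactor with probability far above the nominal level) and (b) it
    lowers the AIC of the accepted model.  A failing candidate is skipped,
    not a stopping point — a weak early-ranked candidate must not block
    later true interactors.  The accepted count is capped at
    min(M_i, n - 2, order_cap), keeping residual degrees of freedom
    positive for the t-test.

    Returns ``(k_star, aic_trace, accepted_positions)``: the chosen order,
    the AIC of the accepted nested models for k = 0..k_star (strictly
    decreasing, so k_star is its argmin), and the positions (into the
    ranked matrix) of the accepted candidates in acceptance order.
    """
    y = np.asarray(y, dtype=float).ravel()
    x_ranked = np.asarray(x_ranked, dtype=float)
    if x_ranked.ndim == 1:
        x_ranked = x_ranked[:, None]
    n = y.size
    k_max = min(x_ranked.shape[1], max(n - 2, 0))
    if order_cap is not None:
        k_max = min(k_max, max(order_cap, 0))
    m_total = n_candidates_total if n_candidates_total else x_ranked.shape[1]
    gate = screen_alpha / max(m_total, 1)

    _, rss0 = fit_least_squares(y, np.empty((n, 0)))
    trace = [aic_score(rss0, n, 0)]
    accepted: list[int] = []
    for pos in range(x_ranked.shape[1]):
        if len(accepted) >= k_max:
            break
        trial = accepted + [pos]
        xk = x_ranked[:, trial]
        beta, rss = fit_least_squares(y, xk)
        try:
            _, p, _, _ = _coef_inference(xk, beta, rss)
        except DegenerateDesignError:
            break
        if p[-1] > gate:
            continue
        score = aic_score(rss, n, len(trial))
        if score >= trace[-1]:
            continue
        accepted.append(pos)
        trace.append(score)
    return len(accepted), trace, accepted


@dataclass
class ProteinFit:
    """One target protein's fitted association model."""

    target: str
    candidates: list  # ranked interactor ids (full candidate pool)
    alpha_hat: dict  # retained interactor -> coefficient
    sigma2_hat: float
    aic_trace: list
    chosen_order: int
    t_stats: dict
    p_values: dict
    retained: list
    pruning_skipped: bool = False

    @property
    def order_retained(self) -> int:
        """M_i' — interactors surviving order selection and pruning."""
        return len(self.retained)


def prune_by_ttest(
    y: np.ndarray,
    x_cols: np.ndarray,
    names,
    alpha: float = 0.05,
) -> tuple[dict, dict, dict, float, bool]:
    """Drop coefficients with two-sided OLS t-test p > alpha; refit once.

    Returns ``(alpha_hat, t_stats, p_values, sigma2, skipped)`` where the
    dicts are keyed by the surviving (t/p: all tested) interactor names.
    With zero residual degrees of freedom pruning is skipped with a warning
    and all coefficients are retained (flagged via ``skipped``).
    """
    names = list(names)
    x_cols = np.asarray(x_cols, dtype=float)
    if x_cols.ndim == 1:
        x_cols = x_cols[:, None]
    yv = np.asarray(y, dtype=float).ravel()
    if len(names) == 0:
        return {}, {}, {}, float(yv @ yv) / yv.size, False
    beta, rss = fit_least_squares(y, x_cols)
    try:
        t, p, df, sigma2 = _coef_inference(x_cols, beta, rss)
    except DegenerateDesignError:
        warnings.warn(
            "zero residual degrees of freedom: t-test pruning skipped, all "
            "coefficients retained"
        )
        return (
            dict(zip(names, beta)),
            {nm: float("nan") for nm in names},
            {nm: float("nan") for nm in names},
            float("nan"),
            True,
        )
    keep = p <= alpha
    t_stats = dict(zip(names, t))
    p_values = dict(zip(names, p))
    if keep.all():
        return dict(zip(names, beta)), t_stats, p_values, sigma2, False
    survivors = [nm for nm, k in zip(names, keep) if k]
    if not survivors:
        return {}, t_stats, p_values, float(yv @ yv) / x_cols.shape[0], False
    xs = x_cols[:, keep]
    beta2, rss2 = fit_least_squares(yv, xs)
    sigma2 = rss2 / max(x_cols.shape[0] - xs.shape[1], 1)
    return dict(zip(survivors, beta2)), t_stats, p_values, sigma2, False


@dataclass
class InferenceSettings:
    """Knobs for per-protein model fitting.

    ``alpha``: pruning t-test level.  ``screen_alpha``: order-selection gate
    (Bonferroni-corrected internally by the candidate count).  ``order_cap``:
    optional hard cap on model order.  ``allow_degenerate``: accept condition
    slices with < 3 samples, capping the order at n - 2.  ``pooled_control``:
    fit one control network from all control samples across time points.
    """

    alpha: float = 0.05
    screen_alpha: float = 0.05
    order_cap: int | None = None
    allow_degenerate: bool = False
    pooled_control: bool = True
    intercept: bool = False


@dataclass
class InteractionMatrix:
    """Assembled M x M association-coefficient matrix for one condition.

    Entry (i, j) is alpha_hat_ij from target i's regression; nonzero only on
    candidate-network edges, zero diagonal.
    """

    nodes: list
    coefficients: np.ndarray
    condition: str
    time_point: str | None = None
    diagnostics: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Long-form (source, target, alpha_hat) rows for nonzero entries."""
        rows = []
        for i, src in enumerate(self.nodes):
            for j in np.nonzero(self.coefficients[i])[0]:
                rows.append((src, self.nodes[j], self.coefficients[i, j]))
        return pd.DataFrame(rows, columns=["source", "target", "alpha_hat"])

    def to_tsv(self, path, diagnostics_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")
        if diagnostics_path is not None:
            with open(diagnostics_path, "w") as fh:
                json.dump(self.diagnostics, fh, indent=1, default=float)


def fit_protein(
    y: np.ndarray,
    candidate_matrix: np.ndarray,
    candidate_names,
    target: str,
    settings: InferenceSettings,
) -> ProteinFit:
    """Full per-protein pipeline: rank -> order selection -> prune.

    With ``settings.intercept`` the target and candidates are mean-centered
    before fitting, which yields the with-intercept slope estimates (the
    intercept itself is never an edge; its one degree of freedom is not
    charged to the t-test df, a deliberate simplification).
    """
    candidate_names = list(candidate_names)
    y = np.asarray(y, dtype=float).ravel()
    candidate_matrix = np.asarray(candidate_matrix, dtype=float)
    if settings.intercept:
        y = y - y.mean()
        if candidate_matrix.size:
            candidate_matrix = candidate_matrix - candidate_matrix.mean(axis=0)
    n = y.size
    order = rank_candidates(y, candidate_matrix, names=candidate_names)
    ranked_names = [candidate_names[j] for j in order]
    x_ranked = candidate_matrix[:, order] if candidate_matrix.size else candidate_matrix
    k_star, trace, accepted = select_model_order(
        y,
        x_ranked,
        order_cap=settings.order_cap,
        screen_alpha=settings.screen_alpha,
        n_candidates_total=len(candidate_names),
    )
    chosen_names = [ranked_names[p] for p in accepted]
    if k_star == 0:
        return ProteinFit(
            target=target,
            candidates=ranked_names,
            alpha_hat={},
            sigma2_hat=float(np.asarray(y, dtype=float) @ np.asarray(y, dtype=float)) / n,
            aic_trace=trace,
            chosen_order=0,
            t_stats={},
            p_values={},
            retained=[],
        )
    alpha_hat, t_stats, p_values, sigma2, skipped = prune_by_ttest(
        y, x_ranked[:, accepted], chosen_names, alpha=settings.alpha
    )
    return ProteinFit(
        target=target,
        candidates=ranked_names,
        alpha_hat=alpha_hat,
        sigma2_hat=sigma2,
        aic_trace=trace,
        chosen_order=k_star,
        t_stats=t_stats,
        p_values=p_values,
        retained=list(alpha_hat),
        pruning_skipped=skipped,
    )


def fit_condition_network(
    values: np.ndarray | pd.DataFrame,
    net: CandidateNetwork,
    settings: InferenceSettings | None = None,
    condition: str = "case",
    time_point: str | None = None,
) -> InteractionMatrix:
    """Fit the association model for every node of a candidate network.

    ``values``: expression of the network's nodes over one condition slice —
    either an array with rows in ``net.nodes`` order or a DataFrame indexed
    by gene id (reindexed to the node order).  Needs >= 3 samples unless
    ``allow_degenerate`` is set (then the order is capped at n - 2 >= 1).
    """
    settings = settings or InferenceSettings()
    if not net.nodes:
        raise EmptyNetworkError("candidate network has no nodes")
    if isinstance(values, pd.DataFrame):
        missing = [p for p in net.nodes if p not in values.index]
        if missing:
            raise ValidationError(f"expression lacks network nodes: {missing[:5]}")
        values = values.loc[net.nodes].to_numpy(dtype=float)
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    if m != len(net.nodes):
        raise ValidationError("value rows do not match network nodes")
    if n < 3 and not settings.allow_degenerate:
        raise DegenerateDesignError(
            f"{n} samples in condition slice; need >= 3 (or allow_degenerate)"
        )
    if n < 2:
        raise DegenerateDesignError("cannot fit with fewer than 2 samples")
    index = net.node_index()
    coef = np.zeros((m, m))
    diagnostics: dict = {"nodes": {}, "n_samples": n, "condition": condition}
    for i, target in enumerate(net.nodes):
        nbr_ids = net.neighbors[target]
        nbr_idx = [index[p] for p in nbr_ids]
        fit = fit_protein(
            values[i], values[nbr_idx].T, nbr_ids, target, settings
        )
        for nm, a in fit.alpha_hat.items():
            coef[i, index[nm]] = a
        diagnostics["nodes"][target] = {
            "chosen_order": fit.chosen_order,
            "retained": fit.order_retained,
            "sigma2": fit.sigma2_hat,
            "df": n - fit.chosen_order,
            "pruning_skipped": fit.pruning_skipped,
        }
    return InteractionMatrix(
        nodes=list(net.nodes),
        coefficients=coef,
        condition=condition,
        time_point=time_point,
        diagnostics=diagnostics,
    )
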