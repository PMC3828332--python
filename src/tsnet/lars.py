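"""Least-angle regression (LARS) model selection for co-expression groups.

Each group of co-expressed isoforms contributes one linear model: the
response is a per-isoform expression summary and the predictors are the
TF- and SF-interaction strength columns. LARS grows an active set one
predictor at a time, moving the fit along the direction equiangular to the
active predictors until an inactive predictor reaches the same absolute
correlation with the residual. The path is plain LARS (the active set only
grows; no LASSO drop step).

Model size is chosen with an extended-BIC criterion by default (Mallows'
Cp and a fixed-k option mirroring the classic "until k variables have
entered" stopping rule are also available), and fits are scored with
adjusted R-squared; groups whose best model explains too little
variance are flagged as not kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

log = logging.getLogger(__name__)

#: breakpoint correlations are considered equal / zero below this scale
_CORR_TOL = 1e-10


@dataclass
class DesignMatrix:
    """Standardized design for one group: unit-norm centered predictor
    columns, centered response, and the affine factors needed to report
    coefficients back on the original scale."""

    X: np.ndarray              # N x P, columns mean 0, unit Euclidean norm
    y: np.ndarray              # N, mean 0
    columns: list[str]
    col_means: np.ndarray
    col_norms: np.ndarray
    y_mean: float
    dropped: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]


@dataclass
class LarsBreakpoint:
    active: list[int]          # indices into DesignMatrix.columns, entry order
    coef: np.ndarray           # P, on the standardized scale
    max_abs_corr: float        # common |correlation| of the active set


@dataclass
class LarsPath:
    breakpoints: list[LarsBreakpoint]   # breakpoints[m] has m active predictors
    aborted: bool = False               # rank-deficient step encountered

    @property
    def n_steps(self) -> int:
        return len(self.breakpoints) - 1


@dataclass
class FitResult:
    group_id: int | str
    selected: list[str]
    factor_types: dict[str, str]        # factor -> {"TF","SF"}
    coefficients: dict[str, float]      # original scale
    intercept: float
    adjusted_r2: float
    kept: bool
    n_obs: int
    step: int
    criterion: str
    criterion_trace: list[float] = field(default_factory=list)


def standardize(X: pd.DataFrame, y: pd.Series | np.ndarray) -> DesignMatrix:
    """Center/scale predictors to unit Euclidean norm and center the response.

    Constant columns carry no information for an equiangular step and are
    dropped (logged); scaling factors are retained so that selected
    coefficients and the intercept can be reported on the original scale.
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n = Xv.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if yv.shape[0] != n:
        raise ValueError("response length does not match design rows")
    means = Xv.mean(axis=0)
    centered = Xv - means
    norms = np.sqrt((centered ** 2).sum(axis=0))
    scale = max(1.0, float(np.abs(Xv).max()))
    keep = norms > 1e-12 * scale
    if not keep.any():
        raise ValueError("all predictor columns are constant")
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    if dropped:
        log.info("standardize: dropped %d constant column(s): %s", len(dropped), dropped)
    Xs = centered[:, keep] / norms[keep]
    y_mean = float(yv.mean())
    return DesignMatrix(
        X=Xs,
        y=yv - y_mean,
        columns=[c for c, k in zip(X.columns, keep) if k],
        col_means=means[keep],
        col_norms=norms[keep],
        y_mean=y_mean,
        dropped=dropped,
    )


def lars_path(design: DesignMatrix, max_steps: int | None = None) -> LarsPath:
    """Compute the LARS breakpoint path.

    Step 1 activates the predictor most correlated with the response; each
    subsequent step advances the coefficients along the equiangular
    direction of the active set until an inactive predictor attains equal
    absolute correlation with the residual, which then joins. Ties are
    broken by column order. An entrant collinear with the active set spans
    no new direction and is set aside (logged); if no entrant admits a
    well-posed equiangular step the path is truncated with ``aborted`` set.
    """
    X, y = design.X, design.y
    n, p = X.shape
    limit = min(n - 1, p)
    if max_steps is None:
        max_steps = limit
    if max_steps > limit:
        raise ValueError(f"max_steps {max_steps} exceeds min(N-1, P) = {limit}")

    beta = np.zeros(p)
    mu = np.zeros(n)
    active: list[int] = []
    inactive = list(range(p))
    scale = max(float(np.abs(X.T @ y).max()), 1.0)
    tol = _CORR_TOL * scale

    c0 = X.T @ y
    path = LarsPath([LarsBreakpoint([], beta.copy(), float(np.abs(c0).max()))])

    while len(active) < max_steps and inactive:
        c = X.T @ (y - mu)
        C = float(np.abs(c).max())
        if C < tol:
            break

        # next entrant: inactive predictor with maximal |correlation|;
        # collinear candidates are set aside and the next-best tried
        step = None
        for j in sorted(inactive, key=lambda k: (-abs(c[k]), k)):
            trial = active + [j]
            s = np.sign(c[trial])
            Xa = X[:, trial] * s
            G = Xa.T @ Xa
            try:
                chol = scipy.linalg.cho_factor(G)
            except scipy.linalg.LinAlgError:
                log.debug("lars_path: %s collinear with active set; skipped",
                          design.columns[j])
                inactive.remove(j)
                continue
            ginv1 = scipy.linalg.cho_solve(chol, np.ones(len(trial)))
            denom = float(np.ones(len(trial)) @ ginv1)
            if denom <= 0 or not np.isfinite(denom):
                inactive.remove(j)
                continue
            step = (j, s, Xa, ginv1, denom)
            break
        if step is None:
            log.warning("lars_path: no well-posed entrant at step %d; "
                        "path truncated", len(active) + 1)
            path.aborted = True
            return path

        j, s, Xa, ginv1, denom = step
        active.append(j)
        inactive.remove(j)
        AA = 1.0 / math.sqrt(denom)
        w = AA * ginv1
        u = Xa @ w                       # equiangular unit vector
        a = X.T @ u

        gamma = C / AA                   # full step reaches the active-set OLS fit
        with np.errstate(divide="ignore", invalid="ignore"):
            for k in inactive:
                for cand in ((C - c[k]) / (AA - a[k]), (C + c[k]) / (AA + a[k])):
                    if np.isfinite(cand) and 1e-12 < cand < gamma:
                        gamma = float(cand)

        mu = mu + gamma * u
        beta[active] += gamma * s * w
        path.breakpoints.append(
            LarsBreakpoint(list(active), beta.copy(), max(C - gamma * AA, 0.0))
        )
        if C - gamma * AA < tol:         # residual fully explained
            break
    return path


def adjusted_r_squared(response, fitted, n_predictors: int) -> float:
    """1 - (1 - R^2)(N - 1)/(N - p - 1) with R^2 = 1 - RSS/TSS."""
    y = np.asarray(response, dtype=float).ravel()
    f = np.asarray(fitted, dtype=float).ravel()
    n = y.size
    if n <= n_predictors + 1:
        raise ValueError(f"need N > p + 1 (N={n}, p={n_predictors})")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        raise ValueError("zero total sum of squares: response is constant")
    rss = float(((y - f) ** 2).sum())
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


def _rss_per_step(path: LarsPath, design: DesignMatrix) -> np.ndarray:
    return np.array(
        [float(((design.y - design.X @ bp.coef) ** 2).sum()) for bp in path.breakpoints]
    )


def _ols_rss_per_step(path: LarsPath, design: DesignMatrix) -> np.ndarray:
    """RSS of the least-squares refit on each breakpoint's active set."""
    out = np.empty(len(path.breakpoints))
    y = design.y
    for m, bp in enumerate(path.breakpoints):
        if not bp.active:
            out[m] = float((y ** 2).sum())
            continue
        Xa = design.X[:, bp.active]
        coef, *_ = np.linalg.lstsq(Xa, y, rcond=None)
        out[m] = float(((y - Xa @ coef) ** 2).sum())
    return out


#: extra model-size penalty weight of the extended BIC (gamma = 1)
EBIC_GAMMA = 1.0


def select_step(
    path: LarsPath,
    design: DesignMatrix,
    criterion: str = "ebic",
    k: int | None = None,
    group_id: int | str = 0,
    factor_types: dict[str, str] | None = None,
    r2_min: float = 0.5,
) -> FitResult:
    """Choose a breakpoint on the path and report the fit on the original scale.

    criterion="ebic" (default): minimize the extended BIC
    N*ln(RSS_m/N) + m*ln N + 2*gamma*m*ln P over the least-squares refits of
    the active sets; the extra 2*gamma*m*ln P term keeps the null model small
    when predictors outnumber observations, where ordinary Cp/BIC penalties
    are swamped by adaptive selection.

    criterion="cp": minimize Mallows' Cp = RSS/sigma^2 - N + 2m on the path
    estimates, with sigma^2 from the largest path model that retains at
    least 4 residual degrees of freedom (the saturated model has none when
    P >= N). Prone to over-selection in the P >= N regime; kept for
    low-dimensional designs.

    criterion="max_steps_k": take step k as given. In every mode an exact
    fit (RSS ~ 0 relative to TSS) short-circuits to the smallest perfectly
    fitting step.
    """
    n = design.n_obs
    p = design.n_predictors
    rss = _rss_per_step(path, design)
    tss = float((design.y ** 2).sum())
    n_bp = len(path.breakpoints)
    trace: list[float] = []

    # adjusted R-squared needs at least one residual degree of freedom
    report_cap = min(n_bp - 1, n - 2)
    if criterion == "max_steps_k":
        if k is None or not (0 <= k <= report_cap):
            raise ValueError(
                f"step k={k} outside selectable path (0..{report_cap})"
            )
        chosen = k
    elif criterion in ("ebic", "cp"):
        if criterion == "ebic":
            rss_sel = _ols_rss_per_step(path, design)
            # consistency of the extended BIC needs model size << N; near-
            # saturated refits interpolate and would always win on RSS alone
            sel_cap = min(report_cap, max(1, (n - 1) // 2))
        else:
            rss_sel = rss
            sel_cap = report_cap
        candidates = np.arange(sel_cap + 1)
        # an exact fit anywhere on the reportable path wins outright
        exact = rss_sel[: report_cap + 1] <= max(1e-10 * tss, 1e-24)
        if exact.any():
            chosen = int(np.argmax(exact))               # smallest perfect fit
        elif criterion == "ebic":
            score = (
                n * np.log(np.maximum(rss_sel[candidates], 1e-300) / n)
                + candidates * math.log(n)
                + 2.0 * EBIC_GAMMA * candidates * math.log(max(p, 2))
            )
            trace = [float(v) for v in score]
            chosen = int(candidates[np.argmin(score)])
        else:
            df_ok = [m for m in candidates if n - m - 1 >= 4]
            m_sigma = max(df_ok) if df_ok else int(candidates[-1])
            sigma2 = rss_sel[m_sigma] / max(n - m_sigma - 1, 1)
            cp = rss_sel[candidates] / sigma2 - n + 2 * candidates
            trace = [float(v) for v in cp]
            chosen = int(candidates[np.argmin(cp)])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    bp = path.breakpoints[chosen]
    selected = [design.columns[j] for j in bp.active]
    coef_std = bp.coef
    coef_orig = coef_std / design.col_norms
    intercept = design.y_mean - float(coef_orig @ design.col_means)
    fitted = design.X @ coef_std
    adj_r2 = adjusted_r_squared(design.y, fitted, len(bp.active))
    ftypes = factor_types or {}
    return FitResult(
        group_id=group_id,
        selected=selected,
        factor_types={f: ftypes.get(f, "TF") for f in selected},
        coefficients={f: float(coef_orig[j]) for f, j in zip(selected, bp.active)},
        intercept=intercept,
        adjusted_r2=adj_r2,
        kept=adj_r2 >= r2_min,
        n_obs=n,
        step=chosen,
        criterion=criterion,
        criterion_trace=trace,
    )


@dataclass
class FitOptions:
    """Knobs for fitting one co-expression group.

    response: which expression summary is regressed per isoform —
    "condition_mean" (mean FPKM over the samples of the isoform's
    up-regulated condition; the default), "all_mean", or "log2_condition_mean"
    (log2(FPKM + 1) before averaging).
    """

    response: str = "condition_mean"
    criterion: str = "ebic"
    k: int | None = None
    max_steps: int | None = None
    r2_min: float = 0.5


def group_response(
    expr: pd.DataFrame,
    sample_conditions: dict[str, str],
    up_conditions: dict[str, str],
    mode: str = "condition_mean",
) -> pd.Series:
    """Per-isoform expression summary used as the regression response."""
    samples = list(expr.columns)
    vals = expr.to_numpy(float)
    if mode == "all_mean":
        return pd.Series(vals.mean(axis=1), index=expr.index)
    if mode not in ("condition_mean", "log2_condition_mean"):
        raise ValueError(f"unknown response mode {mode!r}")
    if mode == "log2_condition_mean":
        vals = np.log2(vals + 1.0)
    out = np.empty(len(expr))
    for i, iso in enumerate(expr.index):
        cond = up_conditions[iso]
        cols = [j for j, s in enumerate(samples) if sample_conditions[s] == cond]
        if not cols:
            raise ValueError(f"isoform {iso}: no samples for condition {cond!r}")
        out[i] = vals[i, cols].mean()
    return pd.Series(out, index=expr.index)


def fit_group(
    group,
    tf_strengths: pd.DataFrame,
    sf_strengths: pd.DataFrame,
    sample_conditions: dict[str, str],
    up_conditions: dict[str, str],
    options: FitOptions | None = None,
) -> FitResult:
    """Assemble the group design (TF columns then SF columns), standardize,
    run the LARS path and select a model.

    Group members absent from a strength matrix contribute all-zero rows
    (no detected sites), which is logged.
    """
    opts = options or FitOptions()
    members = list(group.members)
    if len(members) < 3:
        raise ValueError(f"group {group.group_id}: need >= 3 members, got {len(members)}")

    blocks = []
    types: dict[str, str] = {}
    for mat, flavor in ((tf_strengths, "TF"), (sf_strengths, "SF")):
        missing = [m for m in members if m not in mat.index]
        if missing:
            log.info(
                "fit_group %s: %d member(s) missing from %s strengths, using zeros",
                group.group_id, len(missing), flavor,
            )
        block = mat.reindex(index=members).fillna(0.0)
        blocks.append(block)
        types.update({c: flavor for c in mat.columns})
    X = pd.concat(blocks, axis=1)

    y = group_response(
        group.expression, sample_conditions, up_conditions, opts.response
    ).loc[members]

    design = standardize(X, y)
    limit = min(design.n_obs - 2, design.n_predictors)
    max_steps = limit if opts.max_steps is None else min(opts.max_steps, limit)
    path = lars_path(design, max_steps=max_steps)
    return select_step(
        path,
        design,
        criterion=opts.criterion,
        k=opts.k,
        group_id=group.group_id,
        factor_types=types,
        r2_min=opts.r2_min,
    )
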