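"""Within-subject inference layer.

Two model families mirror the study design:

* continuous dependent measures (response time, fixation counts, head
  path, grouping shares, fixation ratio) are analyzed with
  repeated-measures ANOVA on per-subject cell means: for a k-level
  within-subject factor and m subjects the F statistic carries
  df = (k - 1, (k - 1)(m - 1));
* answer correctness sits near ceiling, so it is analyzed with a
  binomial (logit link) mixed model with a subject-level random
  intercept, fitted by maximum likelihood with Gauss-Hermite quadrature;
  factors are tested with joint Wald chi-square statistics.

A learning-effect factor is built by blocking the 18 trials of a session
into 6 consecutive blocks of 3.

Per-subject cell means are taken before ANOVA (classical repeated
measures aggregation) because the random factor assignment allocates an
unequal number of trials to the cells.  No sphericity correction is
applied by default; Greenhouse-Geisser is available via a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import logsumexp
from statsmodels.stats.anova import AnovaRM
from statsmodels.tools.numdiff import approx_hess

from .errors import DegenerateDesignError, InvalidInputError, MissingDesignError

__all__ = [
    "EffectResult",
    "AnalysisConfig",
    "learning_blocks",
    "rm_anova",
    "rm_anova_nway",
    "fit_accuracy_model",
]

log = logging.getLogger(__name__)


@dataclass
class EffectResult:
    """One tested effect: statistic, degrees of freedom, p-value."""

    effect: str
    statistic: float
    stat_name: str  # "F" or "chi2"
    df_num: int
    df_den: int | None
    p_value: float
    significant: bool
    warning: str | None = None

    def __str__(self) -> str:  # compact report form
        if self.stat_name == "F":
            core = f"F({self.df_num},{self.df_den}) = {self.statistic:.3f}"
        else:
            core = f"chi2({self.df_num}) = {self.statistic:.3f}"
        return f"{self.effect}: {core}, p = {self.p_value:.4g}"


@dataclass
class AnalysisConfig:
    """alpha: significance level; n_blocks: learning-effect blocking of the
    n_trials trials into consecutive equal blocks."""

    alpha: float = 0.05
    n_blocks: int = 6
    n_trials: int = 18
    gg_correction: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must be in (0, 1)")
        if self.n_trials % self.n_blocks != 0:
            raise InvalidInputError("n_blocks must divide n_trials")


def learning_blocks(trial_indices, n_trials: int = 18, n_blocks: int = 6) -> np.ndarray:
    """Map 1-based trial indices to consecutive learning blocks (1-based).

    With the defaults, trials 1-3 form block 1, ..., trials 16-18 block 6.
    """
    if n_trials % n_blocks != 0:
        raise InvalidInputError("n_blocks must divide n_trials")
    size = n_trials // n_blocks
    idx = np.asarray(trial_indices, dtype=int)
    if np.any((idx < 1) | (idx > n_trials)):
        raise InvalidInputError(f"trial indices must lie in 1..{n_trials}")
    out = (idx - 1) // size + 1
    return out if out.shape else int(out)


def _cell_means(
    df: pd.DataFrame, dv: str, factors: list[str], subject: str
) -> pd.DataFrame:
    """Per-subject cell means over the full factor grid; error on empties."""
    piv = df.pivot_table(index=subject, columns=factors, values=dv, aggfunc="mean")
    # complete the grid so missing combinations show up as NaN columns
    if len(factors) == 1:
        levels = [sorted(df[factors[0]].unique())]
        piv = piv.reindex(columns=levels[0])
    else:
        full = pd.MultiIndex.from_product(
            [sorted(df[f].unique()) for f in factors], names=factors
        )
        piv = piv.reindex(columns=full)
    if piv.isna().any().any():
        n_missing = int(piv.isna().sum().sum())
        raise MissingDesignError(
            f"{n_missing} empty subject x cell combination(s) for dv={dv!r}, "
            f"factors={factors}; repeated-measures ANOVA needs a complete design"
        )
    return piv


def rm_anova(
    df: pd.DataFrame,
    dv: str,
    within: str,
    subject: str = "subject_id",
    alpha: float = 0.05,
    gg_correction: bool = False,
) -> EffectResult:
    """One-way repeated-measures ANOVA on per-subject cell means.

    df carries one row per trial; trials are first averaged per
    subject x level.  Returns F with df = (k - 1, (k - 1)(m - 1)).
    """
    piv = _cell_means(df, dv, [within], subject)
    y = piv.to_numpy(float)
    m, k = y.shape
    if m < 2 or k < 2:
        raise InvalidInputError("need >= 2 subjects and >= 2 factor levels")
    grand = y.mean()
    subj_mean = y.mean(axis=1, keepdims=True)
    lvl_mean = y.mean(axis=0, keepdims=True)
    ss_factor = m * float(np.sum((lvl_mean - grand) ** 2))
    resid = y - subj_mean - lvl_mean + grand
    ss_error = float(np.sum(resid**2))
    df_num, df_den = k - 1, (k - 1) * (m - 1)
    if ss_error <= 0.0:
        raise DegenerateDesignError("zero residual variance in repeated-measures design")
    f_stat = (ss_factor / df_num) / (ss_error / df_den)
    if gg_correction:
        eps = _greenhouse_geisser_epsilon(y)
        p = float(sps.f.sf(f_stat, df_num * eps, df_den * eps))
    else:
        p = float(sps.f.sf(f_stat, df_num, df_den))
    return EffectResult(
        effect=within,
        statistic=float(f_stat),
        stat_name="F",
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        significant=p < alpha,
    )


def _greenhouse_geisser_epsilon(y: np.ndarray) -> float:
    k = y.shape[1]
    s = np.cov(y.T, bias=False)
    mean_diag = np.trace(s) / k
    num = (k * mean_diag - s.mean()) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(s.mean(axis=1) ** 2) + k**2 * s.mean() ** 2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova_nway(
    df: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject_id",
    alpha: float = 0.05,
) -> list[EffectResult]:
    """n-way repeated-measures ANOVA (main effects + interactions).

    Per-subject cell means over the full factor grid are handed to a
    standard fully-within ANOVA.  Every subject must populate every cell,
    otherwise a :class:`MissingDesignError` is raised (no imputation).
    """
    piv = _cell_means(df, dv, list(within), subject)
    long = piv.stack(list(range(len(within))), future_stack=True).rename(dv).reset_index()
    res = AnovaRM(long, depvar=dv, subject=subject, within=list(within)).fit()
    out = []
    for effect, row in res.anova_table.iterrows():
        p = float(row["Pr > F"])
        out.append(
            EffectResult(
                effect=str(effect).replace(":", " x "),
                statistic=float(row["F Value"]),
                stat_name="F",
                df_num=int(row["Num DF"]),
                df_den=int(row["Den DF"]),
                p_value=p,
                significant=p < alpha,
            )
        )
    return out


# ---------------------------------------------------------------------------
# binomial random-intercept mixed model (accuracy)
# ---------------------------------------------------------------------------

class _RandomInterceptLogit:
    """Binomial GLMM with a subject random intercept, ML via Gauss-Hermite.

    The marginal likelihood integrates the subject intercept b ~ N(0, s^2)
    with adaptive-free Gauss-Hermite quadrature (the subject cluster sizes
    here are small and s is moderate, so fixed-node quadrature with 25
    nodes is accurate).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, group_starts: np.ndarray, n_quad: int = 25):
        self.X = X
        self.y = y.astype(float)
        self.starts = group_starts
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        self.nodes = nodes * np.sqrt(2.0)
        self.logw = np.log(weights / np.sqrt(np.pi))

    def nll(self, theta: np.ndarray) -> float:
        beta, sigma = theta[:-1], abs(theta[-1])
        eta0 = self.X @ beta
        b = sigma * self.nodes
        eta = eta0[:, None] + b[None, :]
        ll_obs = self.y[:, None] * eta - np.logaddexp(0.0, eta)
        ll_grp = np.add.reduceat(ll_obs, self.starts, axis=0)
        return -float(np.sum(logsumexp(ll_grp + self.logw[None, :], axis=1)))

    def fit(self, x0: np.ndarray):
        res = optimize.minimize(
            self.nll, x0, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-11},
        )
        return res


def fit_accuracy_model(
    df: pd.DataFrame,
    factors: list[str] | None = None,
    subject: str = "subject_id",
    response: str = "correct",
    alpha: float = 0.05,
    n_quad: int = 25,
) -> list[EffectResult]:
    """Binomial logit mixed model for answer correctness.

    Fixed effects: treatment-coded factors (default complexity, start
    position, orientation difference, sameness and learning block);
    random effect: per-subject intercept.  Each factor is tested with a
    joint Wald chi-square over its dummy coefficients.  Complete or
    quasi-complete separation is flagged with a warning instead of
    raising.
    """
    if factors is None:
        factors = ["complexity", "start_position", "orientation_diff", "same", "block"]
    work = df.copy()
    if "block" in factors and "block" not in work.columns:
        work["block"] = learning_blocks(work["trial_index"].to_numpy())
    y = work[response].astype(float).to_numpy()
    if np.all(y == y[0]):
        warnings.warn("constant response: complete separation, model not identifiable")
        return [
            EffectResult(f, float("nan"), "chi2", 1, None, float("nan"), False,
                         warning="complete separation (constant response)")
            for f in factors
        ]
    work = work.sort_values(subject, kind="stable").reset_index(drop=True)
    y = work[response].astype(float).to_numpy()
    cols: list[np.ndarray] = [np.ones(len(work))]
    names: list[str] = ["Intercept"]
    groups_of: dict[str, list[int]] = {}
    for f in factors:
        levels = sorted(pd.unique(work[f]))
        idxs = []
        for lev in levels[1:]:
            cols.append((work[f] == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
            idxs.append(len(cols) - 1)
        if not idxs:
            raise InvalidInputError(f"factor {f!r} has a single level")
        groups_of[f] = idxs
    X = np.column_stack(cols)
    subj = work[subject].to_numpy()
    starts = np.concatenate([[0], np.nonzero(subj[1:] != subj[:-1])[0] + 1])
    model = _RandomInterceptLogit(X, y, starts, n_quad=n_quad)
    p0 = np.zeros(X.shape[1] + 1)
    mean_y = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    p0[0] = np.log(mean_y / (1 - mean_y))
    p0[-1] = 0.5
    res = model.fit(p0)
    theta = res.x
    warning = None
    if not res.success:
        warning = f"optimizer did not converge: {res.message}"
    if np.max(np.abs(theta[:-1])) > 15:
        warning = "possible (quasi-)separation: extreme coefficient"
    hess = approx_hess(theta, model.nll)
    nb = X.shape[1]
    try:
        cov = np.linalg.inv(hess)[:nb, :nb]
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        try:
            cov = np.linalg.inv(hess[:nb, :nb])
        except np.linalg.LinAlgError:
            cov = np.full((nb, nb), np.nan)
            warning = warning or "singular Hessian: standard errors unavailable"
    beta = theta[:nb]
    out = []
    for f in factors:
        idx = groups_of[f]
        bsub = beta[idx]
        csub = cov[np.ix_(idx, idx)]
        try:
            w = float(bsub @ np.linalg.solve(csub, bsub))
            p = float(sps.chi2.sf(w, len(idx)))
        except np.linalg.LinAlgError:
            w, p = float("nan"), float("nan")
        out.append(
            EffectResult(
                effect=f,
                statistic=w,
                stat_name="chi2",
                df_num=len(idx),
                df_den=None,
                p_value=p,
                significant=bool(p < alpha) if np.isfinite(p) else False,
                warning=warning,
            )
        )
    # expose the fitted coefficients for parameter-recovery checks
    out_meta = {"coef": dict(zip(names, beta)), "sigma_subject": float(abs(theta[-1]))}
    for r in out:
        r.meta = out_meta  # type: ignore[attr-defined]
    return out
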