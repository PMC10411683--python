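"""Condition-level and single-trial inference.

Three pieces of machinery:

* a one-sided paired t-test on the participant-level theta summaries
  (AV-AV > AP-AP);
* a cluster-based permutation test on the theta time course: pointwise
  paired t-values are thresholded (two-sided, alpha = .05 by default),
  contiguous supra-threshold runs are scored by their summed t, and the
  family-wise-corrected p-value of each cluster comes from the distribution
  of the maximum |cluster sum| under random per-participant sign flips of
  the condition difference — the canonical paired variant of the
  cluster-permutation approach, with an exhaustive-enumeration mode for
  small cohorts;
* a random-intercept linear mixed model relating single-trial theta power
  to reaction time, estimated by restricted maximum likelihood with the
  variance ratio profiled out (1-D optimization; closed-form GLS fixed
  effects via the Woodbury identity). Conflict type is coded +/-0.5
  (AV-AV = +0.5) and theta/RT are grand-mean centered, so the theta main
  effect is the average within-condition slope. Fixed-effect p-values use a
  t distribution with n_obs - n_fixed degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats as st

from thetaconflict.exceptions import InvalidInputError
from thetaconflict.task_design import PairedTestResult, paired_t_test


# --------------------------------------------------------------------------
# condition-level theta test
# --------------------------------------------------------------------------

def theta_condition_test(summary_table: pd.DataFrame,
                         value_col: str = "theta_sum_db") -> PairedTestResult:
    """One-sided paired t-test that theta power is higher in AV-AV.

    ``summary_table`` needs columns participant_id, condition and the value
    column, one row per participant x condition.
    """
    wide = summary_table.pivot(index="participant_id", columns="condition",
                               values=value_col)
    for cond in ("AV-AV", "AP-AP"):
        if cond not in wide.columns or wide[cond].isna().any():
            raise InvalidInputError(f"condition {cond} missing for some participant")
    return paired_t_test(wide["AV-AV"].to_numpy(), wide["AP-AP"].to_numpy(),
                         tail="one_sided")


# --------------------------------------------------------------------------
# cluster-based permutation test
# --------------------------------------------------------------------------

@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    sum_statistic: float
    p_corrected: float


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    null_distribution: np.ndarray
    n_permutations: int
    cluster_forming_alpha: float
    seed: int | None
    t_values: np.ndarray
    times_ms: np.ndarray

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < 0.05]

    def to_dict(self) -> dict:
        return {
            "clusters": [{"start_ms": c.start_ms, "end_ms": c.end_ms,
                          "sum_statistic": c.sum_statistic,
                          "p_corrected": c.p_corrected} for c in self.clusters],
            "n_permutations": self.n_permutations,
            "cluster_forming_alpha": self.cluster_forming_alpha,
            "seed": self.seed,
        }


def _runs(mask: np.ndarray):
    """Maximal runs of True as (start, stop) half-open index pairs."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def _cluster_sums(t_values: np.ndarray, threshold: float):
    """Supra-threshold clusters of |t| with their summed t."""
    return [(a, b, float(t_values[a:b].sum()))
            for a, b in _runs(np.abs(t_values) > threshold)]


def _max_cluster_stats(signs: np.ndarray, diff: np.ndarray,
                       threshold: float) -> np.ndarray:
    """Max |cluster sum| per sign-flip pattern (rows of ``signs``)."""
    n = diff.shape[0]
    ss = (diff ** 2).sum(axis=0)  # invariant under sign flips
    means = signs @ diff / n
    var = (ss[None, :] - n * means ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = means / np.sqrt(var / n)
    tvals = np.nan_to_num(tvals)
    out = np.empty(signs.shape[0])
    for r in range(signs.shape[0]):
        sums = _cluster_sums(tvals[r], threshold)
        out[r] = max((abs(s) for _, _, s in sums), default=0.0)
    return out


def cluster_permutation_paired(tc_a: np.ndarray, tc_b: np.ndarray,
                               times_ms: np.ndarray,
                               n_permutations: int = 1000,
                               cluster_forming_alpha: float = 0.05,
                               seed: int | None = None,
                               exact: bool = False) -> ClusterTestResult:
    """Paired cluster permutation test of condition A vs B time courses.

    ``tc_a``/``tc_b`` are participants x timepoints matrices. ``exact=True``
    enumerates all 2^n sign-flip patterns (n <= 16) and reports exact
    permutation p-values; otherwise ``n_permutations`` random flips are drawn
    and p-values use the (1 + count)/(n_perm + 1) estimator.
    """
    tc_a = np.asarray(tc_a, float)
    tc_b = np.asarray(tc_b, float)
    if tc_a.shape != tc_b.shape or tc_a.ndim != 2:
        raise InvalidInputError("condition matrices must share shape (participants x time)")
    n, n_t = tc_a.shape
    if n < 2:
        raise InvalidInputError("need at least 2 participants")
    if len(times_ms) != n_t:
        raise InvalidInputError("time axis length mismatch")
    if not exact and n_permutations < 1:
        raise InvalidInputError("n_permutations must be >= 1")
    if not exact and n_permutations < 100:
        import warnings
        warnings.warn("fewer than 100 permutations gives a coarse null",
                      stacklevel=2)

    diff = tc_a - tc_b
    sd = diff.std(axis=0, ddof=1)
    if np.all(sd == 0):
        return ClusterTestResult([], np.zeros(0), 0, cluster_forming_alpha,
                                 seed, np.zeros(n_t), np.asarray(times_ms, float))
    threshold = float(st.t.ppf(1 - cluster_forming_alpha / 2, n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = diff.mean(axis=0) / (sd / np.sqrt(n))
    t_obs = np.nan_to_num(t_obs)
    observed = _cluster_sums(t_obs, threshold)

    if exact:
        if n > 16:
            raise InvalidInputError("exact enumeration limited to n <= 16")
        signs = np.array(list(product((-1.0, 1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1.0, 1.0), size=(n_permutations, n))
    null = _max_cluster_stats(signs, diff, threshold)

    clusters = []
    times = np.asarray(times_ms, float)
    step = float(times[1] - times[0]) if n_t > 1 else 0.0
    for a, b, s in observed:
        if exact:
            p = float((null >= abs(s) - 1e-12).mean())
        else:
            p = float((1 + (null >= abs(s) - 1e-12).sum()) / (len(null) + 1))
        clusters.append(Cluster(float(times[a]), float(times[b - 1] + step), s, p))
    clusters.sort(key=lambda c: abs(c.sum_statistic), reverse=True)
    return ClusterTestResult(clusters, null, len(signs), cluster_forming_alpha,
                             seed, t_obs, times)


# --------------------------------------------------------------------------
# random-intercept linear mixed model
# --------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    """REML fit of a Gaussian random-intercept model.

    ``params`` has one row per fixed effect: estimate, se, t, p (t
    distribution, df = n_obs - n_fixed), and 95% CI bounds.
    """

    params: pd.DataFrame
    random_intercept_variance: float
    residual_variance: float
    random_intercept_variance_ci: tuple[float, float]
    n_obs: int
    n_groups: int
    reml_criterion: float
    ols_fallback: bool = False

    def coef(self, term: str) -> pd.Series:
        return self.params.set_index("term").loc[term]

    def summary(self) -> str:
        lines = ["Random-intercept linear mixed model (REML)",
                 f"  observations: {self.n_obs}   groups: {self.n_groups}",
                 f"  random-intercept variance: {self.random_intercept_variance:.4g}"
                 + ("  [OLS fallback: variance at zero]" if self.ols_fallback else ""),
                 f"  residual variance:         {self.residual_variance:.4g}",
                 ""]
        lines.append(self.params.to_string(index=False,
                                           float_format=lambda v: f"{v: .4g}"))
        return "\n".join(lines)


def _group_sums(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group column sums needed for the Woodbury-form GLS."""
    labels, inv = np.unique(groups, return_inverse=True)
    g = len(labels)
    n_i = np.bincount(inv, minlength=g).astype(float)
    sx = np.zeros((g, X.shape[1]))
    for j in range(X.shape[1]):
        sx[:, j] = np.bincount(inv, weights=X[:, j], minlength=g)
    sy = np.bincount(inv, weights=y, minlength=g)
    return labels, n_i, sx, sy


def _gls_pieces(lam: float, XtX, Xty, yty, n_i, sx, sy):
    """A = X'WX, c = X'Wy, q = y'Wy for W = (I + lam*J)^{-1} blockwise."""
    w = lam / (1.0 + lam * n_i)
    A = XtX - (sx * w[:, None]).T @ sx
    c = Xty - (sx * w[:, None]).T @ sy
    q = yty - float(w @ (sy ** 2))
    return A, c, q


def _reml_criterion(lam: float, XtX, Xty, yty, n_i, sx, sy, n: int, p: int):
    """-2 * restricted log-likelihood, profiled over beta and sigma_e^2."""
    A, c, q = _gls_pieces(lam, XtX, Xty, yty, n_i, sx, sy)
    beta = np.linalg.solve(A, c)
    rss = q - float(beta @ c)
    rss = max(rss, 1e-300)
    sigma_e2 = rss / (n - p)
    _, logdet_A = np.linalg.slogdet(A)
    return ((n - p) * np.log(sigma_e2) + float(np.sum(np.log1p(lam * n_i)))
            + logdet_A + (n - p)), beta, rss, sigma_e2, A


def fit_random_intercept_reml(y, X, groups, term_names=None) -> MixedModelFit:
    """REML random-intercept fit with the variance ratio profiled out.

    Optimizes lambda = sigma_b^2 / sigma_e^2 on a log grid refined by golden
    search; lambda = 0 (ordinary least squares) is checked explicitly and
    reported via ``ols_fallback``. The CI for the random-intercept variance
    is Wald on the log scale from a finite-difference Hessian of the REML
    criterion in (log sigma_b^2, log sigma_e^2).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise InvalidInputError("singular fixed-effects design")
    labels, n_i, sx, sy = _group_sums(X, y, groups)
    if n < len(labels) + p:
        raise InvalidInputError("too few observations for the design")
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def crit(log_lam):
        return _reml_criterion(np.exp(log_lam), XtX, Xty, yty, n_i, sx, sy, n, p)[0]

    grid = np.linspace(-12.0, 8.0, 41)
    vals = [crit(g) for g in grid]
    k = int(np.argmin(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = scipy.optimize.minimize_scalar(crit, bounds=(lo, hi), method="bounded")
    lam = float(np.exp(res.x))
    crit_val, beta, rss, sigma_e2, A = _reml_criterion(
        lam, XtX, Xty, yty, n_i, sx, sy, n, p)
    # boundary check: does lambda -> 0 (plain OLS) do at least as well?
    crit0, beta0, rss0, sig0, A0 = _reml_criterion(
        0.0, XtX, Xty, yty, n_i, sx, sy, n, p)
    ols_fallback = crit0 <= crit_val + 1e-9
    if ols_fallback:
        lam, crit_val, beta, rss, sigma_e2, A = 0.0, crit0, beta0, rss0, sig0, A0
    sigma_b2 = lam * sigma_e2

    cov = sigma_e2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    df = n - p
    tvals = beta / se
    pvals = 2 * st.t.sf(np.abs(tvals), df)
    tcrit = st.t.ppf(0.975, df)
    params = pd.DataFrame({
        "term": term_names, "estimate": beta, "se": se, "t": tvals,
        "p": pvals, "ci_low": beta - tcrit * se, "ci_high": beta + tcrit * se,
    })

    vb_ci = (0.0, 0.0)
    if sigma_b2 > 0:
        vb_ci = _variance_ci(sigma_b2, sigma_e2, XtX, Xty, yty, n_i, sx, sy, n, p)

    return MixedModelFit(params, float(sigma_b2), float(sigma_e2), vb_ci,
                         n, len(labels), float(crit_val), ols_fallback)


def _neg2_reml_full(vb: float, ve: float, XtX, Xty, yty, n_i, sx, sy,
                    n: int, p: int) -> float:
    """-2 restricted log-likelihood at explicit (sigma_b^2, sigma_e^2)."""
    lam = vb / ve
    A, c, q = _gls_pieces(lam, XtX, Xty, yty, n_i, sx, sy)
    beta = np.linalg.solve(A, c)
    rss = max(q - float(beta @ c), 1e-300)
    _, logdet_A = np.linalg.slogdet(A)
    return ((n - p) * np.log(ve) + float(np.sum(np.log1p(lam * n_i)))
            + logdet_A + rss / ve)


def _variance_ci(vb, ve, XtX, Xty, yty, n_i, sx, sy, n, p,
                 level: float = 0.95) -> tuple[float, float]:
    """Wald CI for sigma_b^2 on the log scale (finite-difference Hessian)."""
    theta0 = np.log([vb, ve])
    h = 1e-4

    def f(th):
        return _neg2_reml_full(np.exp(th[0]), np.exp(th[1]), XtX, Xty, yty,
                               n_i, sx, sy, n, p)

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            e_i = np.eye(2)[i] * h
            e_j = np.eye(2)[j] * h
            H[i, j] = (f(theta0 + e_i + e_j) - f(theta0 + e_i - e_j)
                       - f(theta0 - e_i + e_j) + f(theta0 - e_i - e_j)) / (4 * h * h)
    H *= 0.5  # Hessian of the log-likelihood is half that of -2*loglik
    try:
        cov = np.linalg.inv(H)
        se_log = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        return (0.0, np.inf)
    z = st.norm.ppf(0.5 + level / 2)
    return (float(vb * np.exp(-z * se_log)), float(vb * np.exp(z * se_log)))


def prepare_single_trial_frame(table: pd.DataFrame,
                               theta_col: str = "theta_db",
                               rt_col: str = "rt_ms") -> pd.DataFrame:
    """Grand-mean center theta and RT and code conflict type +/-0.5."""
    for col in ("participant_id", "condition", theta_col, rt_col):
        if col not in table.columns:
            raise InvalidInputError(f"single-trial table missing column {col!r}")
    out = table.copy()
    out["theta_c"] = out[theta_col] - out[theta_col].mean()
    out["rt_c"] = out[rt_col] - out[rt_col].mean()
    out["conflict_c"] = np.where(out["condition"] == "AV-AV", 0.5, -0.5)
    return out


def fit_random_intercept_lmm(table: pd.DataFrame,
                             theta_col: str = "theta_db",
                             rt_col: str = "rt_ms") -> MixedModelFit:
    """RT ~ theta * conflict_type with random intercepts for participants.

    Predictors and outcome are centered as in
    :func:`prepare_single_trial_frame`; the theta main effect is therefore
    the average within-condition theta -> RT slope, and the interaction is
    the AV-AV minus AP-AP slope difference (with the +/-0.5 coding).
    """
    d = prepare_single_trial_frame(table, theta_col, rt_col)
    X = np.column_stack([
        np.ones(len(d)), d["theta_c"], d["conflict_c"],
        d["theta_c"] * d["conflict_c"],
    ])
    return fit_random_intercept_reml(
        d["rt_c"].to_numpy(), X, d["participant_id"].to_numpy(),
        ["intercept", "theta", "conflict_type", "theta:conflict_type"])


def per_condition_slopes(table: pd.DataFrame,
                         theta_col: str = "theta_db",
                         rt_col: str = "rt_ms") -> dict[str, MixedModelFit]:
    """Separate random-intercept fits per conflict type, theta as sole
    fixed predictor."""
    fits = {}
    for cond in ("AP-AP", "AV-AV"):
        sub = table[table["condition"] == cond]
        if sub.empty:
            raise InvalidInputError(f"no rows for condition {cond}")
        d = prepare_single_trial_frame(sub, theta_col, rt_col)
        X = np.column_stack([np.ones(len(d)), d["theta_c"]])
        fits[cond] = fit_random_intercept_reml(
            d["rt_c"].to_numpy(), X, d["participant_id"].to_numpy(),
            ["intercept", "theta"])
    return fits
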