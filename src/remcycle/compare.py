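"""Bootstrap comparison of conditional-mixture parameters between conditions,
and a thin ordinary-least-squares utility for the correlation analyses.

To compare two conditions (typically light vs dark phase), cycles of each
condition are resampled with replacement, the full conditional model is
refit on every replicate, and each parameter curve (k_long with its
min(.,1) clamp applied) is averaged over a common REM_pre grid spanning
the model domain.  The two resulting bootstrap distributions per parameter
are summarised by percentile intervals and compared with Welch's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from remcycle.conditional_gmm import ConditionalGMM, fit_bin_mixtures, fit_parameter_curves

COMPARED_PARAMS = ("k_long", "mu_long", "sigma_long")


@dataclass(frozen=True)
class BootstrapComparison:
    """Bootstrap distributions of one parameter's domain-average, per condition."""

    parameter: str
    values_a: np.ndarray
    values_b: np.ndarray
    n_boot: int
    n_dropped: int
    mean_diff: float
    ci_a: tuple
    ci_b: tuple
    ci_diff: tuple
    t_stat: float
    p_value: float


def _curve_average(model: ConditionalGMM, param: str, grid: np.ndarray) -> float:
    vals = np.asarray(model.curves[param](grid), dtype=float)
    if param == "k_long":
        vals = np.clip(vals, 0.0, 1.0)
    return float(vals.mean())


def _fit_model(cycles, k_fit_bins, min_count, n_restarts, rng, phase):
    bins = fit_bin_mixtures(cycles, min_count=min_count, n_restarts=n_restarts, rng=rng)
    return fit_parameter_curves(bins, k_fit_bins=k_fit_bins, phase=phase)


def bootstrap_phase_comparison(
    cycles_a,
    cycles_b,
    params=COMPARED_PARAMS,
    n_boot: int = 10000,
    rng: np.random.Generator | None = None,
    k_fit_bins_a: int = 6,
    k_fit_bins_b: int = 6,
    min_count: int = 10,
    n_restarts: int = 5,
    step: float = 2.5,
    max_drop_frac: float = 0.05,
) -> dict:
    """Bootstrap the domain-averaged parameter curves of two conditions.

    Returns a dict mapping parameter name to :class:`BootstrapComparison`.
    Iterations whose refit fails (e.g. a resampled bin falls below the
    minimum count) are dropped; more than ``max_drop_frac`` dropped
    iterations raise an error.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    cycles_a, cycles_b = list(cycles_a), list(cycles_b)

    # common REM_pre grid from the two point-estimate models
    m_a = _fit_model(cycles_a, k_fit_bins_a, min_count, max(n_restarts, 10), rng, "a")
    m_b = _fit_model(cycles_b, k_fit_bins_b, min_count, max(n_restarts, 10), rng, "b")
    lo = max(m_a.domain_min, m_b.domain_min)
    hi = min(m_a.rem_pre_max_fit, m_b.rem_pre_max_fit)
    grid = np.arange(lo, hi, step)

    acc = {p: ([], []) for p in params}
    dropped = 0
    for _ in range(n_boot):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ra = [cycles_a[i] for i in rng.integers(0, len(cycles_a), len(cycles_a))]
                rb = [cycles_b[i] for i in rng.integers(0, len(cycles_b), len(cycles_b))]
                ma = _fit_model(ra, k_fit_bins_a, min_count, n_restarts, rng, "a")
                mb = _fit_model(rb, k_fit_bins_b, min_count, n_restarts, rng, "b")
        except Exception:
            dropped += 1
            continue
        for p in params:
            acc[p][0].append(_curve_average(ma, p, grid))
            acc[p][1].append(_curve_average(mb, p, grid))
    if dropped > max_drop_frac * n_boot:
        raise RuntimeError(f"{dropped}/{n_boot} bootstrap iterations failed to refit")

    out = {}
    for p in params:
        va = np.asarray(acc[p][0])
        vb = np.asarray(acc[p][1])
        diff = va - vb  # iteration-paired difference of independent resamples
        if va.size > 1:
            t = stats.ttest_ind(va, vb, equal_var=False)
            t_stat, p_val = float(t.statistic), float(t.pvalue)
            ci = lambda v: (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))
        else:
            t_stat, p_val = float("nan"), float("nan")
            ci = lambda v: (float(v[0]), float(v[0]))
        out[p] = BootstrapComparison(
            parameter=p,
            values_a=va,
            values_b=vb,
            n_boot=n_boot,
            n_dropped=dropped,
            mean_diff=float(va.mean() - vb.mean()),
            ci_a=ci(va),
            ci_b=ci(vb),
            ci_diff=ci(diff),
            t_stat=t_stat,
            p_value=p_val,
        )
    return out


def ols_fit(x, y):
    """Ordinary least squares of y on x.

    Returns (slope, intercept, r_squared, p_value) where the p-value is the
    standard two-sided t-test of the slope.  With only two points the fit is
    exact and the p-value is NaN (no residual degrees of freedom).
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need paired vectors with at least 2 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.var(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        p = float(res.pvalues[1]) if res.df_resid > 0 else float("nan")
        return float(res.params[1]), float(res.params[0]), float(res.rsquared), p
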