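"""Goodness-of-fit tests for the mixture model.

Two checks are provided.  First, a Lilliefors-corrected Kolmogorov-Smirnov
test per REM_pre bin: because the mixture parameters are estimated from the
same data the test is applied to, the null distribution of the KS statistic
is obtained by Monte-Carlo — samples of the original size are drawn from
the fitted mixture, the mixture is re-estimated on each, and the KS
statistic of each simulated sample against its own re-fitted distribution
forms the reference distribution KS_sim.  The fit is rejected when the
observed statistic exceeds the 95th percentile of KS_sim.

Second, a whole-model simulation: for every observed REM_pre in the model's
domain, ln(|N|) values are repeatedly drawn from the conditional mixture
and the pooled simulated distribution is compared with the observed one by
a two-sample KS test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from remcycle.conditional_gmm import BinMixtureFit, ConditionalGMM
from remcycle.mixture import em_fit_batch


@dataclass(frozen=True)
class GofResult:
    """Lilliefors-corrected KS result for one REM_pre bin."""

    bin_lo: float
    bin_hi: float
    n: int
    ks_obs: float
    ks_sim_95: float
    p_value: float
    reject: bool
    n_sim: int


def _fit_cdf(fit: BinMixtureFit):
    """CDF (on the ln scale) of a bin's fitted mixture."""

    def cdf(x):
        x = np.asarray(x, dtype=float)
        out = fit.k_long * stats.norm.cdf(x, fit.mu_long, fit.sigma_long)
        if not fit.unimodal:
            out = out + (1 - fit.k_long) * stats.norm.cdf(x, fit.mu_short, fit.sigma_short)
        return out

    return cdf


def _sample_fit(fit: BinMixtureFit, size, rng):
    """Draw ln(|N|) values from a bin's fitted mixture; ``size`` may be a tuple."""
    if fit.unimodal:
        return rng.normal(fit.mu_long, fit.sigma_long, size=size)
    long = rng.random(size) < fit.k_long
    return np.where(
        long,
        rng.normal(fit.mu_long, fit.sigma_long, size=size),
        rng.normal(fit.mu_short, fit.sigma_short, size=size),
    )


def _ks_rows(X, cdf_vals):
    """Two-sided KS statistic per row given the model CDF at the sorted sample."""
    n = X.shape[1]
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    return np.maximum(
        (grid_hi - cdf_vals).max(axis=1),
        (cdf_vals - grid_lo).max(axis=1),
    )


def lilliefors_ks(
    ln_n,
    fit: BinMixtureFit,
    n_sim: int = 10000,
    rng: np.random.Generator | None = None,
    refit: bool = True,
    n_restarts: int = 10,
) -> GofResult:
    """Monte-Carlo (Lilliefors-corrected) KS test of a bin's mixture fit.

    Parameters
    ----------
    ln_n : array
        The ln(|N|) sample the fit was estimated from.
    fit : BinMixtureFit
        The mixture fit under test.
    n_sim : int
        Number of Monte-Carlo replicates.
    refit : bool
        Re-estimate the mixture on every simulated sample (the correction
        for estimated parameters).  With ``refit=False`` each simulated
        sample is compared against the original fitted distribution,
        which yields the classical (conservative, parameters-known) null.
    n_restarts : int
        EM restarts per simulated-sample refit.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    x = np.sort(np.asarray(ln_n, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if rng is None:
        rng = np.random.default_rng(0)

    cdf = _fit_cdf(fit)
    ks_obs = float(_ks_rows(x[None, :], cdf(x)[None, :])[0])

    sims = np.sort(_sample_fit(fit, (n_sim, n), rng), axis=1)
    if not refit:
        cdf_vals = cdf(sims)
    elif fit.unimodal:
        mu = sims.mean(axis=1, keepdims=True)
        sd = sims.std(axis=1, keepdims=True)
        cdf_vals = stats.norm.cdf(sims, mu, sd)
    else:
        r = em_fit_batch(sims, n_restarts=n_restarts, rng=rng)
        cdf_vals = r["w_long"][:, None] * stats.norm.cdf(
            sims, r["mu_long"][:, None], r["sigma_long"][:, None]
        ) + (1 - r["w_long"][:, None]) * stats.norm.cdf(
            sims, r["mu_short"][:, None], r["sigma_short"][:, None]
        )
    ks_sim = _ks_rows(sims, cdf_vals)

    q95 = float(np.quantile(ks_sim, 0.95))
    p = float(np.mean(ks_sim >= ks_obs))
    return GofResult(
        bin_lo=fit.bin_lo,
        bin_hi=fit.bin_hi,
        n=n,
        ks_obs=ks_obs,
        ks_sim_95=q95,
        p_value=p,
        reject=bool(ks_obs > q95),
        n_sim=n_sim,
    )


@dataclass(frozen=True)
class SimulationComparison:
    """Whole-model simulation output and its two-sample KS comparison."""

    sample: np.ndarray  # pooled simulated ln(|N|)
    n_skipped: int
    ks_stat: float | None = None
    ks_p_value: float | None = None


def simulate_model_distribution(
    m: ConditionalGMM,
    rem_pre_values,
    reps: int = 10000,
    rng: np.random.Generator | None = None,
    empirical_ln_n=None,
) -> SimulationComparison:
    """Simulate the pooled ln(|N|) distribution implied by the model.

    For each repetition, one ln(|N|) is drawn from the conditional mixture
    for every in-domain REM_pre value (values outside
    [domain_min, rem_pre_max_fit) are skipped with a warning).  If an
    empirical sample is given, the pooled simulation is compared to it with
    a two-sample KS test.
    """
    rem_pre_values = np.asarray(rem_pre_values, dtype=float)
    if rem_pre_values.size == 0:
        raise ValueError("rem_pre_values must be non-empty")
    if rng is None:
        rng = np.random.default_rng(0)

    ok = (rem_pre_values >= m.domain_min) & (rem_pre_values < m.rem_pre_max_fit)
    n_skipped = int((~ok).sum())
    if n_skipped:
        warnings.warn(
            f"skipping {n_skipped} REM_pre values outside "
            f"[{m.domain_min}, {m.rem_pre_max_fit}) s"
        )
    xs = rem_pre_values[ok]
    if xs.size == 0:
        raise ValueError("no REM_pre values inside the model domain")

    params = [m.parameters(x) for x in xs]
    k = np.array([p.k_long for p in params])
    mu_l = np.array([p.mu_long for p in params])
    mu_s = np.array([p.mu_short for p in params])
    s_l = np.array([p.sigma_long for p in params])
    s_s = np.array([p.sigma_short for p in params])

    long = rng.random((reps, xs.size)) < k
    draws = np.where(
        long,
        rng.normal(mu_l, s_l, size=(reps, xs.size)),
        rng.normal(mu_s, s_s, size=(reps, xs.size)),
    )
    sample = draws.ravel()

    if empirical_ln_n is None:
        return SimulationComparison(sample=sample, n_skipped=n_skipped)
    ks = stats.ks_2samp(sample, np.asarray(empirical_ln_n, dtype=float))
    return SimulationComparison(
        sample=sample,
        n_skipped=n_skipped,
        ks_stat=float(ks.statistic),
        ks_p_value=float(ks.pvalue),
    )
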