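"""Maximum-likelihood fitting of one-dimensional two-component Gaussian mixtures.

The fitting problem here is small (a few hundred ln(|N|) values per
REM_pre bin) but is solved very many times: once per bin, and again for
every Monte-Carlo replicate of the Lilliefors-corrected KS test and every
bootstrap iteration.  The expectation-maximization loop is therefore
implemented batched: a whole stack of independent samples (and all random
restarts for each) is advanced through the E and M steps simultaneously
as one ndarray computation.

Component identity is normalised after fitting so that component "long"
is the one with the larger mean.
"""

from __future__ import annotations

import numpy as np

_LOG_2PI = float(np.log(2.0 * np.pi))

#: floor on component variances (ln-seconds squared); prevents collapse of a
#: component onto a single data point during EM
VAR_FLOOR = 1e-6


class DegenerateSampleError(ValueError):
    """Raised when a sample has (near-)zero variance and no mixture can be fit."""


def gaussian_mixture_logpdf(x, w_long, mu_short, mu_long, sigma_short, sigma_long):
    """Log-density of the two-component mixture at points ``x`` (broadcasting)."""
    x = np.asarray(x, dtype=float)
    z_s = (x - mu_short) / sigma_short
    z_l = (x - mu_long) / sigma_long
    log_s = -0.5 * (z_s**2 + _LOG_2PI) - np.log(sigma_short)
    log_l = -0.5 * (z_l**2 + _LOG_2PI) - np.log(sigma_long)
    # numerically stable logsumexp of the two weighted terms
    t_s = np.where(w_long < 1.0, np.log(np.maximum(1.0 - w_long, 1e-300)) + log_s, -np.inf)
    t_l = np.where(w_long > 0.0, np.log(np.maximum(w_long, 1e-300)) + log_l, -np.inf)
    m = np.maximum(t_s, t_l)
    return m + np.log(np.exp(t_s - m) + np.exp(t_l - m))


def mixture_loglik(x, w_long, mu_short, mu_long, sigma_short, sigma_long) -> float:
    """Total log-likelihood of a sample under the mixture."""
    return float(np.sum(gaussian_mixture_logpdf(x, w_long, mu_short, mu_long, sigma_short, sigma_long)))


def fit_single_gaussian(x):
    """Closed-form MLE of a single Gaussian: sample mean and (biased) sd."""
    x = np.asarray(x, dtype=float)
    mu = float(x.mean())
    var = float(x.var())
    if var < VAR_FLOOR:
        raise DegenerateSampleError("sample variance below floor; all values (nearly) identical")
    sd = float(np.sqrt(var))
    ll = float(np.sum(-0.5 * (((x - mu) / sd) ** 2 + _LOG_2PI) - np.log(sd)))
    return mu, sd, ll


def _split_init(xs_sorted, cs, css, t):
    """Moment initialisation from a hard split of the sorted sample at index t.

    ``cs``/``css`` are cumulative sums of the sorted values and their squares
    with a leading zero; shapes (..., n+1).  ``t`` broadcasts against the
    leading axes.  Returns (w, mu1, mu2, var1, var2).
    """
    n = xs_sorted.shape[-1]
    t = np.asarray(t)
    idx = t[..., None]
    s1 = np.take_along_axis(cs, idx, axis=-1)[..., 0]
    q1 = np.take_along_axis(css, idx, axis=-1)[..., 0]
    s2 = cs[..., -1] - s1
    q2 = css[..., -1] - q1
    n1 = t.astype(float)
    n2 = n - n1
    mu1 = s1 / n1
    mu2 = s2 / n2
    var1 = np.maximum(q1 / n1 - mu1**2, VAR_FLOOR)
    var2 = np.maximum(q2 / n2 - mu2**2, VAR_FLOOR)
    w = n2 / n
    return w, mu1, mu2, var1, var2


def em_fit_batch(
    X,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    rng: np.random.Generator | None = None,
):
    """Fit a two-component 1-D Gaussian mixture to each row of ``X`` by EM.

    Parameters
    ----------
    X : ndarray, shape (B, n)
        Stack of independent samples; each row is fit separately.
    n_restarts : int
        Number of initialisations per row.  The first is a split at the
        sample median; the rest split at random quantiles.
    tol : float
        Convergence tolerance on the per-chain log-likelihood increment.
    max_iter : int
        Iteration cap; chains still improving at the cap keep their last state.
    rng : numpy Generator, optional
        Source of the random split points.  Defaults to a fixed-seed
        generator so that fits are reproducible.

    Returns
    -------
    dict of ndarrays, each of shape (B,), with keys
    ``w_long, mu_short, mu_long, sigma_short, sigma_long, loglik``.

    Raises
    ------
    DegenerateSampleError
        If any row has variance below the floor.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B, n = X.shape
    if n < 4:
        raise ValueError(f"need at least 4 observations per sample, got {n}")
    if np.any(X.var(axis=1) < VAR_FLOOR):
        raise DegenerateSampleError("at least one sample has variance below floor")
    if rng is None:
        rng = np.random.default_rng(0)

    Xs = np.sort(X, axis=1)
    cs = np.concatenate([np.zeros((B, 1)), np.cumsum(Xs, axis=1)], axis=1)
    css = np.concatenate([np.zeros((B, 1)), np.cumsum(Xs**2, axis=1)], axis=1)

    # split indices: median first, then random interior quantiles
    t0 = np.full((B, 1), n // 2, dtype=int)
    if n_restarts > 1:
        tr = rng.integers(max(2, int(0.1 * n)), min(n - 2, int(0.9 * n)) + 1, size=(B, n_restarts - 1))
        t = np.concatenate([t0, tr], axis=1)
    else:
        t = t0
    t = np.clip(t, 2, n - 2)

    # expand to (B, R) chains, then flatten to C = B*R
    cs_e = np.broadcast_to(cs[:, None, :], (B, t.shape[1], n + 1))
    css_e = np.broadcast_to(css[:, None, :], (B, t.shape[1], n + 1))
    xs_e = np.broadcast_to(Xs[:, None, :], (B, t.shape[1], n))
    w, mu1, mu2, var1, var2 = _split_init(xs_e, cs_e, css_e, t)

    R = t.shape[1]
    C = B * R
    data = np.broadcast_to(X[:, None, :], (B, R, n)).reshape(C, n)
    w = w.reshape(C)
    mu1, mu2 = mu1.reshape(C), mu2.reshape(C)
    var1, var2 = var1.reshape(C), var2.reshape(C)

    ll = np.full(C, -np.inf)
    active = np.ones(C, dtype=bool)
    for _ in range(max_iter):
        d = data[active]
        m1, m2 = mu1[active, None], mu2[active, None]
        v1, v2 = var1[active, None], var2[active, None]
        wl = w[active, None]
        log1 = -0.5 * ((d - m1) ** 2 / v1 + np.log(v1) + _LOG_2PI) + np.log(np.maximum(1 - wl, 1e-300))
        log2 = -0.5 * ((d - m2) ** 2 / v2 + np.log(v2) + _LOG_2PI) + np.log(np.maximum(wl, 1e-300))
        mx = np.maximum(log1, log2)
        lse = mx + np.log(np.exp(log1 - mx) + np.exp(log2 - mx))
        new_ll = lse.sum(axis=1)
        r2 = np.exp(log2 - lse)  # responsibility of component 2

        n2 = r2.sum(axis=1)
        n1 = n - n2
        n1c = np.maximum(n1, 1e-12)
        n2c = np.maximum(n2, 1e-12)
        mu1_new = ((1 - r2) * d).sum(axis=1) / n1c
        mu2_new = (r2 * d).sum(axis=1) / n2c
        var1_new = np.maximum(((1 - r2) * (d - mu1_new[:, None]) ** 2).sum(axis=1) / n1c, VAR_FLOOR)
        var2_new = np.maximum((r2 * (d - mu2_new[:, None]) ** 2).sum(axis=1) / n2c, VAR_FLOOR)
        w_new = n2 / n

        idx = np.flatnonzero(active)
        converged = new_ll - ll[idx] < tol
        mu1[idx], mu2[idx] = mu1_new, mu2_new
        var1[idx], var2[idx] = var1_new, var2_new
        w[idx] = w_new
        ll[idx] = new_ll
        active[idx[converged]] = False
        if not active.any():
            break

    # pick best restart per sample
    ll = ll.reshape(B, R)
    best = ll.argmax(axis=1)
    rows = np.arange(B)

    def _pick(a):
        return a.reshape(B, R)[rows, best]

    w, mu1, mu2 = _pick(w), _pick(mu1), _pick(mu2)
    var1, var2 = _pick(var1), _pick(var2)
    loglik = ll[rows, best]

    # enforce "long" = larger mean
    swap = mu1 > mu2
    mu_s = np.where(swap, mu2, mu1)
    mu_l = np.where(swap, mu1, mu2)
    v_s = np.where(swap, var2, var1)
    v_l = np.where(swap, var1, var2)
    w_long = np.where(swap, 1 - w, w)

    return {
        "w_long": w_long,
        "mu_short": mu_s,
        "mu_long": mu_l,
        "sigma_short": np.sqrt(v_s),
        "sigma_long": np.sqrt(v_l),
        "loglik": loglik,
    }


def em_fit(x, n_restarts: int = 20, tol: float = 1e-8, max_iter: int = 500, rng=None):
    """Fit a single sample; returns a dict of scalars (see :func:`em_fit_batch`)."""
    out = em_fit_batch(np.asarray(x, dtype=float)[None, :], n_restarts=n_restarts, tol=tol, max_iter=max_iter, rng=rng)
    return {k: float(v[0]) for k, v in out.items()}
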