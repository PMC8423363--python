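"""The conditional Gaussian mixture model of inter-REM NREM amounts.

For each 30 s bin of preceding REM duration (REM_pre), the distribution of
ln(|N|) — the natural log of the total NREM time in the following inter-REM
interval — is fit as a two-component Gaussian mixture by maximum likelihood
(EM).  The five resulting parameters

    k_long, mu_long, mu_short, sigma_long, sigma_short

are then modelled as smooth functions of REM_pre, each by whichever of a
linear (y = a*x + b) or logarithmic (y = a*ln(x + b) + c, b >= 0) curve
achieves the lower residual sum of squares.  The weight of the long
component is clamped, k_long(x) = min(a*ln(x+b)+c, 1), since it is a
probability; bins at or above the unimodality threshold (150 s by default)
are fit with a single Gaussian (k_long = 1).

The assembled :class:`ConditionalGMM` is a full conditional probability
model P(ln|N| given REM_pre = x): it exposes the mixture pdf and cdf,
sampling, and its domain minimum — the smallest REM_pre for which the two
weighted component densities intersect strictly between their means.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from remcycle.mixture import DegenerateSampleError, em_fit, fit_single_gaussian

SIGMA_FLOOR = 1e-3


class DomainError(ValueError):
    """REM_pre below the model's domain minimum."""


class ModelInvalidError(ValueError):
    """No REM_pre value yields a valid between-means component intersection."""


@dataclass(frozen=True)
class BinMixtureFit:
    """Mixture fit for one REM_pre bin.

    For unimodal bins (REM_pre >= the unimodality threshold) ``k_long`` is 1
    and the short-component fields are ``None``.
    """

    bin_lo: float
    bin_hi: float
    n: int
    k_long: float
    mu_long: float
    sigma_long: float
    mu_short: float | None = None
    sigma_short: float | None = None
    unimodal: bool = False

    def __post_init__(self):
        if not 0.0 <= self.k_long <= 1.0:
            raise ValueError(f"k_long must lie in [0, 1], got {self.k_long}")
        if self.sigma_long <= 0:
            raise ValueError("sigma_long must be positive")
        if self.unimodal and self.k_long != 1.0:
            raise ValueError("unimodal fits must have k_long = 1")
        if not self.unimodal and (self.mu_short is None or self.sigma_short is None):
            raise ValueError("bimodal fits require short-component parameters")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.bin_lo + self.bin_hi)


def _log_model(x, a, b, c):
    return a * np.log(np.maximum(x + b, 1e-12)) + c


@dataclass(frozen=True)
class ParamCurve:
    """One fitted parameter curve: linear or logarithmic in REM_pre."""

    kind: str  # "linear" or "logarithmic"
    a: float
    b: float
    c: float = 0.0
    rss: float = float("nan")

    def __post_init__(self):
        if self.kind not in ("linear", "logarithmic"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.kind == "logarithmic" and self.b < 0:
            raise ValueError("logarithmic curves require b >= 0")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return self.a * x + self.b
        return _log_model(x, self.a, self.b, self.c)


def _fit_linear(x, y) -> ParamCurve:
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((A @ coef - y) ** 2))
    return ParamCurve("linear", float(coef[0]), float(coef[1]), 0.0, rss)


def _fit_logarithmic(x, y) -> ParamCurve | None:
    """Bounded (b >= 0) nonlinear least squares with multi-start over b."""
    best = None
    for b0 in (0.0, 1.0, 10.0, 100.0):
        # profile start: optimal a, c for this b by linear regression on ln(x+b)
        t = np.log(x + b0 + 1e-12)
        A = np.vstack([t, np.ones_like(t)]).T
        (a0, c0), *_ = np.linalg.lstsq(A, y, rcond=None)
        try:
            res = optimize.least_squares(
                lambda p: _log_model(x, *p) - y,
                x0=[a0, b0, c0],
                bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                method="trf",
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        rss = float(2 * res.cost)
        if best is None or rss < best.rss:
            best = ParamCurve("logarithmic", float(res.x[0]), float(res.x[1]), float(res.x[2]), rss)
    return best


def fit_param_curve(x, y) -> ParamCurve:
    """Fit both curve kinds and keep the one with lower RSS.

    Falls back to the linear fit (with a warning) if the logarithmic
    solver fails to produce a finite solution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 bins to fit a parameter curve")
    lin = _fit_linear(x, y)
    log = _fit_logarithmic(x, y)
    if log is None:
        warnings.warn("logarithmic curve fit failed to converge; using linear fit")
        return lin
    return log if log.rss < lin.rss else lin


class GMMParams(NamedTuple):
    k_long: float
    k_short: float
    mu_long: float
    mu_short: float
    sigma_long: float
    sigma_short: float


def gaussian_intersection(k_short, mu_short, sigma_short, k_long, mu_long, sigma_long):
    """Intersection of two weighted Gaussian densities between their means.

    Solves k_short * f_short(x) = k_long * f_long(x), which reduces to a
    quadratic in x, and returns the root lying strictly inside
    (mu_short, mu_long).  Returns ``None`` when no such root exists.
    """
    if k_long <= 0 or k_short <= 0 or not mu_short < mu_long:
        return None
    vs, vl = sigma_short**2, sigma_long**2
    # ln(ks/ss) - (x-ms)^2/(2 vs) = ln(kl/sl) - (x-ml)^2/(2 vl)
    A = 0.5 * (1.0 / vl - 1.0 / vs)
    B = mu_short / vs - mu_long / vl
    C = 0.5 * (mu_long**2 / vl - mu_short**2 / vs) + np.log((k_short * sigma_long) / (k_long * sigma_short))
    if abs(A) < 1e-14:
        if abs(B) < 1e-14:
            return None
        roots = [-C / B]
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            return None
        sq = np.sqrt(disc)
        roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    inside = [r for r in roots if mu_short < r < mu_long]
    return float(inside[0]) if inside else None


@dataclass(frozen=True)
class ConditionalGMM:
    """Conditional mixture model of ln(|N|) given REM_pre.

    ``curves`` maps each of the five parameter names to its
    :class:`ParamCurve`; ``domain_min`` is the smallest REM_pre (on the
    epoch grid) at which the weighted component densities intersect
    strictly between their means, below which the model is undefined.
    """

    curves: dict
    domain_min: float
    rem_pre_max_fit: float = 240.0
    phase: str = "unknown"
    bin_fits: tuple = ()

    _PARAMS = ("k_long", "mu_long", "mu_short", "sigma_long", "sigma_short")

    def __post_init__(self):
        missing = set(self._PARAMS) - set(self.curves)
        if missing:
            raise ValueError(f"missing parameter curves: {sorted(missing)}")

    # -- parameter evaluation -------------------------------------------------

    def _check_domain(self, rem_pre) -> None:
        rem_pre = np.asarray(rem_pre, dtype=float)
        if np.any(rem_pre < self.domain_min):
            raise DomainError(
                f"REM_pre below the model domain minimum ({self.domain_min} s); "
                "the conditional mixture is undefined there"
            )
        if np.any(rem_pre > self.rem_pre_max_fit):
            warnings.warn(
                f"evaluating parameter curves beyond the fitted REM_pre range "
                f"(> {self.rem_pre_max_fit} s); this is an extrapolation"
            )

    def parameters(self, rem_pre: float) -> GMMParams:
        """Evaluate the five parameter curves at one REM_pre value.

        k_long is clamped to [0, 1]; standard deviations are floored at a
        small positive epsilon.
        """
        self._check_domain(rem_pre)
        x = float(rem_pre)
        k = float(np.clip(self.curves["k_long"](x), 0.0, 1.0))
        return GMMParams(
            k_long=k,
            k_short=1.0 - k,
            mu_long=float(self.curves["mu_long"](x)),
            mu_short=float(self.curves["mu_short"](x)),
            sigma_long=max(float(self.curves["sigma_long"](x)), SIGMA_FLOOR),
            sigma_short=max(float(self.curves["sigma_short"](x)), SIGMA_FLOOR),
        )

    # -- distribution ----------------------------------------------------------

    def pdf(self, rem_pre: float, ln_n) -> np.ndarray:
        """Mixture density of ln(|N|) at ``ln_n`` given REM_pre."""
        p = self.parameters(rem_pre)
        ln_n = np.asarray(ln_n, dtype=float)
        out = p.k_long * stats.norm.pdf(ln_n, p.mu_long, p.sigma_long)
        if p.k_short > 0:
            out = out + p.k_short * stats.norm.pdf(ln_n, p.mu_short, p.sigma_short)
        return out

    def cdf(self, rem_pre: float, n_seconds) -> np.ndarray:
        """P(|N| <= n_seconds given REM_pre): the REM-propensity function.

        Defined for n_seconds >= 0, with cdf(., 0) = 0.
        """
        n_arr = np.asarray(n_seconds, dtype=float)
        if np.any(n_arr < 0):
            raise ValueError("|N| must be non-negative")
        p = self.parameters(rem_pre)
        with np.errstate(divide="ignore"):
            ln_n = np.log(n_arr)
        out = p.k_long * stats.norm.cdf(ln_n, p.mu_long, p.sigma_long)
        if p.k_short > 0:
            out = out + p.k_short * stats.norm.cdf(ln_n, p.mu_short, p.sigma_short)
        out = np.where(n_arr == 0, 0.0, out)
        return out if out.shape else float(out)

    def sample_n(self, rem_pre: float, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw |N| values (seconds) from the conditional mixture."""
        if n < 1:
            raise ValueError("n must be >= 1")
        p = self.parameters(rem_pre)
        long = rng.random(n) < p.k_long
        ln_n = np.where(
            long,
            rng.normal(p.mu_long, p.sigma_long, size=n),
            rng.normal(p.mu_short, p.sigma_short, size=n),
        )
        return np.exp(ln_n)

    # -- serialization ----------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "phase": self.phase,
            "domain_min": self.domain_min,
            "rem_pre_max_fit": self.rem_pre_max_fit,
            "curves": {
                name: {"kind": c.kind, "a": c.a, "b": c.b, "c": c.c, "rss": c.rss}
                for name, c in self.curves.items()
            },
            "bin_fits": [vars(b).copy() for b in self.bin_fits],
        }
        s = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "ConditionalGMM":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        curves = {
            name: ParamCurve(d["kind"], d["a"], d["b"], d.get("c", 0.0), d.get("rss", float("nan")))
            for name, d in doc["curves"].items()
        }
        bins = tuple(BinMixtureFit(**b) for b in doc.get("bin_fits", []))
        return cls(
            curves=curves,
            domain_min=doc["domain_min"],
            rem_pre_max_fit=doc.get("rem_pre_max_fit", 240.0),
            phase=doc.get("phase", "unknown"),
            bin_fits=bins,
        )


def fit_bin_mixtures(
    cycles: Sequence,
    bin_width: float = 30.0,
    unimodal_from: float = 150.0,
    rem_pre_max: float = 240.0,
    min_count: int = 10,
    n_restarts: int = 20,
    rng: np.random.Generator | None = None,
) -> list:
    """EM mixture fits of ln(|N|) per REM_pre bin.

    Cycles are grouped into non-overlapping ``bin_width`` s bins of REM_pre
    below ``rem_pre_max``.  Bins starting at or above ``unimodal_from`` are
    fit with a single Gaussian (k_long = 1).  Bins with fewer than
    ``min_count`` cycles are skipped with a warning.
    """
    cycles = list(cycles)
    if any(c.n_total <= 0 for c in cycles):
        raise ValueError("cycle with |N| = 0 encountered; ln(|N|) is undefined")
    rem_pre = np.array([c.rem_pre for c in cycles])
    ln_n = np.log(np.array([c.n_total for c in cycles]))

    fits = []
    edges = np.arange(0.0, rem_pre_max + bin_width / 2, bin_width)
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (rem_pre >= lo) & (rem_pre < hi)
        x = ln_n[mask]
        if x.size < min_count:
            warnings.warn(f"REM_pre bin [{lo}, {hi}) has only {x.size} cycles; skipped")
            continue
        if lo >= unimodal_from:
            mu, sd, _ = fit_single_gaussian(x)
            fits.append(
                BinMixtureFit(bin_lo=lo, bin_hi=hi, n=x.size, k_long=1.0, mu_long=mu, sigma_long=sd, unimodal=True)
            )
        else:
            r = em_fit(x, n_restarts=n_restarts, rng=rng)
            fits.append(
                BinMixtureFit(
                    bin_lo=lo,
                    bin_hi=hi,
                    n=x.size,
                    k_long=min(max(r["w_long"], 0.0), 1.0),
                    mu_long=r["mu_long"],
                    sigma_long=r["sigma_long"],
                    mu_short=r["mu_short"],
                    sigma_short=r["sigma_short"],
                )
            )
    return fits


def compute_domain_min(
    curves: dict,
    step: float = 2.5,
    rem_pre_max: float = 240.0,
) -> float:
    """Smallest grid REM_pre with a valid between-means component intersection.

    Scans the ``step`` grid upward and returns the first x for which the
    weighted short and long densities intersect strictly between mu_short
    and mu_long.  Raises :class:`ModelInvalidError` if no grid point below
    ``rem_pre_max`` qualifies.
    """
    for x in np.arange(step, rem_pre_max, step):
        k = float(np.clip(curves["k_long"](x), 0.0, 1.0))
        if not 0.0 < k < 1.0:
            continue
        mu_s = float(curves["mu_short"](x))
        mu_l = float(curves["mu_long"](x))
        s_s = max(float(curves["sigma_short"](x)), SIGMA_FLOOR)
        s_l = max(float(curves["sigma_long"](x)), SIGMA_FLOOR)
        if gaussian_intersection(1 - k, mu_s, s_s, k, mu_l, s_l) is not None:
            return float(x)
    raise ModelInvalidError(
        "no REM_pre below the fitted range yields a component intersection between the means"
    )


def fit_parameter_curves(
    bins: Sequence[BinMixtureFit],
    k_fit_bins: int = 6,
    phase: str = "unknown",
    step: float = 2.5,
    rem_pre_max_fit: float = 240.0,
) -> ConditionalGMM:
    """Fit the five parameter curves over REM_pre and assemble the model.

    Each parameter is fit with both curve kinds at the bin midpoints and the
    lower-RSS kind is kept.  k_long uses only the first ``k_fit_bins`` bin
    values (beyond the unimodality threshold it is identically 1 and would
    otherwise dominate the fit).  The short-component curves use bimodal
    bins only.
    """
    bins = sorted(bins, key=lambda b: b.bin_lo)
    if len(bins) < 3:
        raise ValueError("need at least 3 bins to fit parameter curves")
    mid = np.array([b.midpoint for b in bins])
    bimodal = np.array([not b.unimodal for b in bins])

    curves = {}
    curves["mu_long"] = fit_param_curve(mid, np.array([b.mu_long for b in bins]))
    curves["sigma_long"] = fit_param_curve(mid, np.array([b.sigma_long for b in bins]))

    if bimodal.sum() < 3:
        raise ValueError("need at least 3 bimodal bins for the short-component curves")
    mid_b = mid[bimodal]
    curves["mu_short"] = fit_param_curve(mid_b, np.array([b.mu_short for b in bins if not b.unimodal]))
    curves["sigma_short"] = fit_param_curve(mid_b, np.array([b.sigma_short for b in bins if not b.unimodal]))

    k_idx = slice(0, min(k_fit_bins, len(bins)))
    curves["k_long"] = fit_param_curve(mid[k_idx], np.array([b.k_long for b in bins])[k_idx])

    domain_min = compute_domain_min(curves, step=step, rem_pre_max=rem_pre_max_fit)
    return ConditionalGMM(
        curves=curves,
        domain_min=domain_min,
        rem_pre_max_fit=rem_pre_max_fit,
        phase=phase,
        bin_fits=tuple(bins),
    )
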