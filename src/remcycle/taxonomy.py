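"""Cycle taxonomy: sequential vs single cycles, refractory/permissive split,
and REM propensity at REM onset.

A cycle is *sequential* when its ln(|N|) falls below the intersection point
of the weighted short and long component densities of the conditional
mixture at its REM_pre — equivalently, when the weighted short density
exceeds the weighted long density there.  Otherwise it is *single*.  Cycles
with REM_pre below the model's domain minimum are *undefined*.

For single cycles, the NREM of the inter-REM interval splits into a
refractory period (NREM time up to the 1st percentile of the long
component's lognormal distribution) and the remaining permissive period.
The model CDF evaluated at |N| — the accumulated NREM at REM onset — serves
as the REM-propensity measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from remcycle.conditional_gmm import ConditionalGMM, DomainError, gaussian_intersection
from remcycle.hypnogram import MA, NREM, REM, WAKE, Hypnogram, SleepCycle

SEQUENTIAL = "sequential"
SINGLE = "single"
UNDEFINED = "undefined"


class NoIntersectionError(ValueError):
    """The weighted component densities do not intersect between their means."""


def intersection_threshold(m: ConditionalGMM, rem_pre: float) -> float:
    """ln(|N|) value separating sequential from single cycles at this REM_pre.

    Closed-form root of k_short*f_short(x) = k_long*f_long(x) inside
    (mu_short, mu_long).  Requires both components present (k_long < 1).
    """
    p = m.parameters(rem_pre)
    if p.k_long >= 1.0:
        raise ValueError("distribution is unimodal at this REM_pre (k_long = 1); no intersection")
    x = gaussian_intersection(p.k_short, p.mu_short, p.sigma_short, p.k_long, p.mu_long, p.sigma_long)
    if x is None:
        raise NoIntersectionError(
            f"no intersection between the component means at REM_pre = {rem_pre}"
        )
    return x


def classify_cycle(m: ConditionalGMM, cycle: SleepCycle) -> str:
    """Label one cycle as sequential, single, or undefined.

    Undefined below the domain minimum; single wherever k_long = 1.  If the
    densities fail to intersect between the means (possible under
    extrapolated curves), the label falls back to comparing the weighted
    component densities at ln(|N|) directly — the rule the intersection
    threshold is equivalent to.
    """
    if cycle.n_total <= 0:
        raise ValueError("cycle with |N| = 0; ln(|N|) is undefined")
    if cycle.rem_pre < m.domain_min:
        return UNDEFINED
    p = m.parameters(cycle.rem_pre)
    ln_n = float(np.log(cycle.n_total))
    if p.k_long >= 1.0:
        return SINGLE
    try:
        x_int = intersection_threshold(m, cycle.rem_pre)
    except NoIntersectionError:
        d_short = p.k_short * stats.norm.pdf(ln_n, p.mu_short, p.sigma_short)
        d_long = p.k_long * stats.norm.pdf(ln_n, p.mu_long, p.sigma_long)
        return SEQUENTIAL if d_short > d_long else SINGLE
    return SEQUENTIAL if ln_n < x_int else SINGLE


def refractory_threshold(m: ConditionalGMM, rem_pre: float, q: float = 0.01) -> float:
    """NREM amount (seconds) ending the refractory period at this REM_pre.

    The threshold is the |N| for which the long component's CDF equals
    ``q`` (1% by default): exp(mu_long + sigma_long * z_q).
    """
    p = m.parameters(rem_pre)
    z = stats.norm.ppf(q)
    return float(np.exp(p.mu_long + p.sigma_long * z))


def segment_cycle(cycle: SleepCycle, h: Hypnogram, threshold: float):
    """Split a single cycle's inter-REM NREM epochs at the refractory threshold.

    Walks the hypnogram from the end of the leading REM episode to the start
    of the next one, accumulating NREM (incl. MA) time.  Epochs up to the
    point where the accumulated NREM first reaches ``threshold`` seconds are
    refractory, the rest permissive.  Wake epochs count into neither period
    but do not reset the accumulator.

    Returns
    -------
    (refractory, permissive) : two lists of epoch indices into ``h``.
    If |N| < threshold the whole interval is refractory and the permissive
    list is empty.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    epochs = h.epochs
    # locate the inter-REM interval following the cycle's leading REM episode
    i = cycle.start_index
    if epochs[i] != REM:
        raise ValueError("cycle start_index does not point at a REM episode")
    while i < len(epochs) and epochs[i] == REM:
        i += 1
    refractory, permissive = [], []
    acc = 0.0
    j = i
    while j < len(epochs) and epochs[j] != REM:
        if epochs[j] in (NREM, MA):
            if acc < threshold:
                refractory.append(j)
            else:
                permissive.append(j)
            acc += h.epoch_len
        j += 1
    return refractory, permissive


def propensity_at_rem_onset(m: ConditionalGMM, cycle: SleepCycle, long_only: bool = False) -> float:
    """Model CDF at the accumulated NREM amount when the next REM episode starts.

    With ``long_only`` the CDF of the long component alone is used instead of
    the full mixture (relevant when restricting to single cycles).
    """
    if long_only:
        p = m.parameters(cycle.rem_pre)
        if cycle.n_total == 0:
            return 0.0
        return float(stats.norm.cdf(np.log(cycle.n_total), p.mu_long, p.sigma_long))
    return float(m.cdf(cycle.rem_pre, cycle.n_total))


@dataclass(frozen=True)
class CycleAnnotation:
    """Per-cycle taxonomy results (one row of the `classify` output)."""

    label: str
    x_intersect: float | None
    refractory_threshold_n: float | None
    propensity: float | None


def annotate_cycle(m: ConditionalGMM, cycle: SleepCycle) -> CycleAnnotation:
    """Classify one cycle and attach threshold and propensity values."""
    label = classify_cycle(m, cycle)
    if label == UNDEFINED:
        return CycleAnnotation(label, None, None, None)
    p = m.parameters(cycle.rem_pre)
    x_int = None
    if p.k_long < 1.0:
        x_int = gaussian_intersection(
            p.k_short, p.mu_short, p.sigma_short, p.k_long, p.mu_long, p.sigma_long
        )
    thr = refractory_threshold(m, cycle.rem_pre) if label == SINGLE else None
    return CycleAnnotation(
        label=label,
        x_intersect=x_int,
        refractory_threshold_n=thr,
        propensity=propensity_at_rem_onset(m, cycle),
    )


def sequence_lengths(labels) -> list:
    """Run lengths of consecutive sequential cycles (REM-sequence sizes)."""
    out = []
    run = 0
    for lab in labels:
        if lab == SEQUENTIAL:
            run += 1
        elif run:
            out.append(run)
            run = 0
    if run:
        out.append(run)
    return out
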