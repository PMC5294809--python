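"""Posterior-trace post-processing: credible model sets, HPD intervals, coverage.

The 95% credible set of models is the smallest set of models whose posterior
probabilities sum to at least 0.95 (models sorted by decreasing probability,
ties broken by model string).  The HPD interval of a scalar parameter is the
shortest contiguous window of ceil(level * n) consecutive order statistics.
Coverage of a validation study is the fraction of replicates in which the
generating value lies inside its 95% HPD interval (parameters) or inside the
95% credible set (models); a calibrated sampler achieves about 95% of
either, with binomial spread — e.g. with 100 replicates there is only a
~1.1% chance of seeing 89 or fewer successes.

Gamma-shape and p_inv summaries are conditioned on the part of the posterior
sample where the relevant indicator is 1 (and, for coverage, on sampling the
true site-model variant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CredibleModelSet",
    "HpdInterval",
    "apply_burnin",
    "credible_model_set",
    "hpd_interval",
    "indicator_posterior",
    "conditional_summary",
    "site_model_variant_credible_set",
    "coverage_report",
    "effective_sample_size",
]

SITE_VARIANTS = ("plain", "+G", "+I", "+G+I")


@dataclass(frozen=True)
class CredibleModelSet:
    """Smallest model set reaching the target posterior mass."""

    models: Tuple[str, ...]
    probabilities: Tuple[float, ...]
    level: float

    @property
    def mass(self) -> float:
        return float(sum(self.probabilities))

    def __contains__(self, model: str) -> bool:
        return model in self.models

    def __len__(self) -> int:
        return len(self.models)


@dataclass(frozen=True)
class HpdInterval:
    lower: float
    upper: float
    level: float

    def __contains__(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def apply_burnin(trace: pd.DataFrame, burnin_frac: float = 0.1) -> pd.DataFrame:
    """Drop the leading burn-in fraction of a trace."""
    if not 0.0 <= burnin_frac < 1.0:
        raise ValueError("burnin_frac must lie in [0,1)")
    start = int(math.ceil(burnin_frac * len(trace)))
    return trace.iloc[start:]


def _credible_from_probs(probs: Dict[str, float], level: float) -> CredibleModelSet:
    items = sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))
    models: List[str] = []
    mass: List[float] = []
    total = 0.0
    for name, p in items:
        models.append(name)
        mass.append(p)
        total += p
        if total >= level:
            break
    return CredibleModelSet(tuple(models), tuple(mass), level)


def credible_model_set(trace: pd.DataFrame, level: float = 0.95) -> CredibleModelSet:
    """Smallest set of substitution models with posterior mass >= level."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    counts = trace["model"].value_counts()
    probs = {str(k): float(v) / len(trace) for k, v in counts.items()}
    return _credible_from_probs(probs, level)


def site_model_variant_credible_set(trace: pd.DataFrame, level: float = 0.95) -> CredibleModelSet:
    """Credible set over the four rate-heterogeneity variants (plain/+G/+I/+G+I)."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    g = trace["hasGammaRates"].to_numpy(dtype=int)
    i = trace["hasInvariableSites"].to_numpy(dtype=int)
    labels = np.array(SITE_VARIANTS)[g + 2 * i]
    names, counts = np.unique(labels, return_counts=True)
    probs = {str(n): float(c) / len(trace) for n, c in zip(names, counts)}
    return _credible_from_probs(probs, level)


def variant_label(has_gamma: int, has_inv: int) -> str:
    return SITE_VARIANTS[int(has_gamma) + 2 * int(has_inv)]


def hpd_interval(samples: Sequence[float], level: float = 0.95) -> HpdInterval:
    """Shortest window of ceil(level*n) consecutive order statistics."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least two samples")
    w = max(1, int(math.ceil(level * n)))
    if w >= n:
        return HpdInterval(float(x[0]), float(x[-1]), level)
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))
    return HpdInterval(float(x[i]), float(x[i + w - 1]), level)


def indicator_posterior(trace: pd.DataFrame, which: str) -> float:
    """Posterior probability that a binary indicator column equals 1."""
    if which not in trace.columns:
        raise KeyError(f"no column {which!r} in trace")
    return float(trace[which].mean())


@dataclass(frozen=True)
class ConditionalSummary:
    """Mean and HPD of a parameter over the sub-trace where an indicator is 1."""

    mean: Optional[float]
    hpd: Optional[HpdInterval]
    n: int

    @property
    def missing(self) -> bool:
        return self.n < 2


def conditional_summary(
    trace: pd.DataFrame, parameter: str, indicator: str, level: float = 0.95
) -> ConditionalSummary:
    sub = trace.loc[trace[indicator] == 1, parameter]
    if len(sub) < 2:
        return ConditionalSummary(mean=None, hpd=None, n=len(sub))
    return ConditionalSummary(
        mean=float(sub.mean()), hpd=hpd_interval(sub.to_numpy(), level), n=len(sub)
    )


_RATE_COLS = ("rateAC", "rateAG", "rateAT", "rateCG", "rateCT", "rateGT")
_FREQ_COLS = ("freqA", "freqC", "freqG", "freqT")


def coverage_report(
    truths: Sequence[Dict[str, float]],
    traces: Sequence[pd.DataFrame],
    level: float = 0.95,
    burnin_frac: float = 0.1,
) -> pd.DataFrame:
    """Per-parameter and per-model coverage over paired truth/trace replicates.

    ``truths`` are records as produced by
    :meth:`modeljump.simulate.Replicate.truth_record`.  Returns a table with
    one row per quantity: hits, the number of replicates in which the
    quantity was assessable (n), and coverage in percent.  Frequency
    coverage is assessed only on replicates generated with unequal
    frequencies; for equal-frequency truths the equal-frequency indicator
    itself is scored instead.  Alpha and p_inv coverage conditions on the
    sub-trace sampling the true site-model variant.
    """
    if len(truths) != len(traces):
        raise ValueError("truths and traces must pair up")
    hits: Dict[str, int] = {}
    totals: Dict[str, int] = {}

    def tally(key: str, hit: Optional[bool]) -> None:
        if hit is None:
            return
        totals[key] = totals.get(key, 0) + 1
        hits[key] = hits.get(key, 0) + int(hit)

    for truth, raw in zip(truths, traces):
        trace = apply_burnin(raw, burnin_frac)
        for col in _RATE_COLS:
            tally(col, float(truth[col]) in hpd_interval(trace[col].to_numpy(), level))
        cset = credible_model_set(trace, level)
        tally("substModel", str(truth["model"]) in cset)
        vset = site_model_variant_credible_set(trace, level)
        true_variant = variant_label(truth["hasGammaRates"], truth["hasInvariableSites"])
        tally("siteModel", true_variant in vset)
        if truth["hasEqualFreqs"]:
            tally("equalFreqIndicator", indicator_posterior(trace, "hasEqualFreqs") >= 1 - level)
        else:
            for col in _FREQ_COLS:
                tally(col, float(truth[col]) in hpd_interval(trace[col].to_numpy(), level))
        # alpha / p_inv conditioned on sampling the true site-model variant
        sub = trace.loc[
            (trace["hasGammaRates"] == truth["hasGammaRates"])
            & (trace["hasInvariableSites"] == truth["hasInvariableSites"])
        ]
        if truth["hasGammaRates"]:
            hit = (
                float(truth["gammaShape"]) in hpd_interval(sub["gammaShape"].to_numpy(), level)
                if len(sub) >= 2
                else None
            )
            tally("gammaShape", hit)
        if truth["hasInvariableSites"]:
            hit = (
                float(truth["proportionInvariable"])
                in hpd_interval(sub["proportionInvariable"].to_numpy(), level)
                if len(sub) >= 2
                else None
            )
            tally("proportionInvariable", hit)

    rows = []
    for key in totals:
        rows.append(
            {
                "quantity": key,
                "hits": hits[key],
                "n": totals[key],
                "coverage_pct": 100.0 * hits[key] / totals[key],
            }
        )
    return pd.DataFrame(rows).set_index("quantity")


def effective_sample_size(samples: Sequence[float]) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimate."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return float(n)
    # FFT autocorrelation
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acf = np.fft.irfft(f * np.conjugate(f), m)[:n].real / (var * n)
    tau = 1.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        tau += 2.0 * acf[lag]
    return float(n / tau)
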