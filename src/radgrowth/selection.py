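"""Information-criterion model selection: AICc, BIC, criterion differences,
Akaike weights, tie-averaged rankings, cohort summaries, and residual
normality checks (Shapiro–Wilk plus a Monte-Carlo Lilliefors test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError, ValidationError

__all__ = [
    "aicc",
    "bic",
    "deltas",
    "akaike_weights",
    "rank_models",
    "ComparisonTable",
    "build_comparison",
    "cohort_summary",
    "lilliefors_statistic",
    "LillieforsNull",
    "residual_normality",
    "DEFAULT_TIE_TOL",
]

#: Default tie tolerance on criterion differences (2-decimal printing scale).
DEFAULT_TIE_TOL = 5e-3


def _check_ssr_n_k(ssr_value: float, n: int, k: int, need_aicc_guard: bool) -> None:
    if ssr_value < 0:
        raise DomainError(f"SSR must be >= 0, got {ssr_value}")
    if ssr_value == 0:
        raise DomainError(
            "SSR is exactly 0: the log-likelihood term diverges to -inf; "
            "information criteria are undefined for a perfect fit"
        )
    if n <= 0:
        raise DomainError(f"n must be positive, got {n}")
    if need_aicc_guard and n <= k + 1:
        raise DomainError(
            f"AICc undefined for n={n}, k={k}: requires n >= k + 2 "
            "(small-sample correction denominator)"
        )


def aicc(ssr_value: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion from an SSR fit:
    n ln(SSR/n) + 2k + 2k(k+1)/(n-k-1)."""
    _check_ssr_n_k(ssr_value, n, k, need_aicc_guard=True)
    return n * math.log(ssr_value / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def bic(ssr_value: float, n: int, k: int) -> float:
    """Bayesian information criterion: n ln(SSR/n) + k ln(n)."""
    _check_ssr_n_k(ssr_value, n, k, need_aicc_guard=False)
    return n * math.log(ssr_value / n) + k * math.log(n)


def deltas(scores: Sequence[float]) -> np.ndarray:
    """Criterion differences Delta_i = score_i - min(score)."""
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise DomainError("need at least 2 model scores to form differences")
    return arr - arr.min()


def akaike_weights(delta_values: Sequence[float]) -> np.ndarray:
    """Evidence weights w_i = exp(-Delta_i/2) / sum_r exp(-Delta_r/2)."""
    arr = np.asarray(delta_values, dtype=float)
    if np.any(arr < 0):
        raise DomainError("delta values must be >= 0")
    lik = np.exp(-0.5 * arr)
    return lik / lik.sum()


def rank_models(delta_values: Sequence[float], tie_tol: float = DEFAULT_TIE_TOL) -> np.ndarray:
    """Ascending ranks of the criterion differences, ties replaced by the
    average of their positions.

    Values closer than ``tie_tol`` are treated as tied (criterion tables
    are conventionally printed to 2 decimals, so exact float ties are
    rare but printed ties are not).
    """
    arr = np.asarray(delta_values, dtype=float)
    if arr.size == 0:
        return np.array([])
    order = np.argsort(arr, kind="stable")
    # cluster consecutive sorted values whose gap is <= tie_tol
    cluster = np.zeros(arr.size, dtype=int)
    cid = 0
    for pos in range(1, arr.size):
        if arr[order[pos]] - arr[order[pos - 1]] > tie_tol:
            cid += 1
        cluster[order[pos]] = cid
    cluster[order[0]] = 0
    return stats.rankdata(cluster, method="average")


@dataclass
class ComparisonTable:
    """Per-patient model comparison: criterion scores, differences, weights
    and ranks for a fixed set of model names."""

    patient_id: str
    model_names: tuple[str, ...]
    n: int
    aicc_scores: np.ndarray
    bic_scores: np.ndarray
    aicc_deltas: np.ndarray = field(init=False)
    bic_deltas: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)
    aicc_ranks: np.ndarray = field(init=False)
    bic_ranks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.aicc_scores = np.asarray(self.aicc_scores, dtype=float)
        self.bic_scores = np.asarray(self.bic_scores, dtype=float)
        if len(self.model_names) != self.aicc_scores.size:
            raise ValidationError("model_names and scores length mismatch")
        self.aicc_deltas = deltas(self.aicc_scores)
        self.bic_deltas = deltas(self.bic_scores)
        self.weights = akaike_weights(self.aicc_deltas)
        self.aicc_ranks = rank_models(self.aicc_deltas)
        self.bic_ranks = rank_models(self.bic_deltas)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient": self.patient_id,
                "model": list(self.model_names),
                "n": self.n,
                "aicc": self.aicc_scores,
                "bic": self.bic_scores,
                "aicc_delta": self.aicc_deltas,
                "bic_delta": self.bic_deltas,
                "weight": self.weights,
                "aicc_rank": self.aicc_ranks,
                "bic_rank": self.bic_ranks,
            }
        )


def build_comparison(patient_id: str, fits: Sequence, model_names: Sequence[str] | None = None) -> ComparisonTable:
    """Build a :class:`ComparisonTable` from FitResult-like objects exposing
    ``ssr``, ``n``, ``n_params`` and (for default naming) ``law`` /
    ``fractional`` attributes."""
    names = tuple(
        model_names
        if model_names is not None
        else [("fractional_" if f.fractional else "") + f.law for f in fits]
    )
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValidationError(f"fits disagree on the number of data points: {sorted(ns)}")
    n = ns.pop()
    return ComparisonTable(
        patient_id=patient_id,
        model_names=names,
        n=n,
        aicc_scores=np.array([aicc(f.ssr, f.n, f.n_params) for f in fits]),
        bic_scores=np.array([bic(f.ssr, f.n, f.n_params) for f in fits]),
    )


def cohort_summary(tables: Sequence[ComparisonTable]) -> pd.DataFrame:
    """Cohort roll-up: per-model mean criterion differences, tie-averaged
    rank tallies (sum of per-patient ranks) and mean Akaike weight."""
    if not tables:
        raise ValidationError("no comparison tables supplied")
    names = tables[0].model_names
    for tbl in tables:
        if tbl.model_names != names:
            raise ValidationError("inconsistent model sets across patients")
    return pd.DataFrame(
        {
            "model": list(names),
            "mean_aicc_delta": np.mean([t.aicc_deltas for t in tables], axis=0),
            "aicc_rank_tally": np.sum([t.aicc_ranks for t in tables], axis=0),
            "mean_weight": np.mean([t.weights for t in tables], axis=0),
            "mean_bic_delta": np.mean([t.bic_deltas for t in tables], axis=0),
            "bic_rank_tally": np.sum([t.bic_ranks for t in tables], axis=0),
        }
    )


# ---------------------------------------------------------------------------
# Residual normality
# ---------------------------------------------------------------------------

def lilliefors_statistic(x: np.ndarray) -> float:
    """Kolmogorov–Smirnov distance between the empirical CDF and a normal
    CDF with mean and standard deviation estimated from the sample."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return 1.0
    cdf = stats.norm.cdf((x - mean) / sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


class LillieforsNull:
    """Seeded Monte-Carlo null distribution of the Lilliefors statistic for
    a fixed sample size; reusable across many tests of the same n."""

    def __init__(self, n: int, size: int = 10_000, seed: int = 0, chunk: int = 1000):
        if n < 4:
            raise InsufficientDataError("Lilliefors test requires n >= 4")
        self.n = n
        self.size = size
        self.seed = seed
        rng = np.random.default_rng(seed)
        stats_out = np.empty(size)
        pos = 0
        idx = np.arange(1, n + 1)
        while pos < size:
            m = min(chunk, size - pos)
            sample = rng.standard_normal((m, n))
            sample.sort(axis=1)
            mean = sample.mean(axis=1, keepdims=True)
            sd = sample.std(axis=1, ddof=1, keepdims=True)
            cdf = stats.norm.cdf((sample - mean) / sd)
            d_plus = np.max(idx / n - cdf, axis=1)
            d_minus = np.max(cdf - (idx - 1) / n, axis=1)
            stats_out[pos : pos + m] = np.maximum(d_plus, d_minus)
            pos += m
        self.null_stats = np.sort(stats_out)

    def pvalue(self, statistic: float) -> float:
        """Monte-Carlo p-value with the +1 continuity adjustment."""
        exceed = self.null_stats.size - np.searchsorted(self.null_stats, statistic, side="left")
        return float((exceed + 1) / (self.null_stats.size + 1))


def residual_normality(
    residuals: Sequence[float],
    significance: float = 0.05,
    mc_size: int = 10_000,
    seed: int = 0,
    null: LillieforsNull | None = None,
) -> dict:
    """Shapiro–Wilk and Monte-Carlo Lilliefors normality tests.

    Returns both p-values plus a ``normal`` flag that is True only when
    neither test rejects at the given significance level.
    """
    resid = np.asarray(residuals, dtype=float)
    if resid.size < 4:
        raise InsufficientDataError(
            f"normality testing requires >= 4 residuals, got {resid.size}"
        )
    lf_stat = lilliefors_statistic(resid)
    if null is None:
        null = LillieforsNull(resid.size, size=mc_size, seed=seed)
    elif null.n != resid.size:
        raise ValidationError(
            f"null distribution was built for n={null.n}, data have n={resid.size}"
        )
    lf_p = null.pvalue(lf_stat)
    sw_stat, sw_p = stats.shapiro(resid)
    return {
        "lilliefors_statistic": lf_stat,
        "lilliefors_pvalue": lf_p,
        "shapiro_statistic": float(sw_stat),
        "shapiro_pvalue": float(sw_p),
        "significance": significance,
        "normal": bool(lf_p > significance and sw_p > significance),
    }
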