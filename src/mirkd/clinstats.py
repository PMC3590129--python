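"""Clinical validation statistics.

Covers the study's non-sequencing statistics: reference-normalized qRT-PCR
abundance (2^-dCt against the RNU48 small nucleolar RNA), exact paired and
unpaired rank tests (tie-adjusted, by convolution of the null distribution),
Spearman correlation, the Monte-Carlo power of the paired Wilcoxon design,
and the RNase-protection fraction quantifying how much of a circulating miR
is shielded inside membrane vesicles.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_LIMIT_WILCOXON = 25   # pairs; beyond this, normal approximation
EXACT_LIMIT_MANNWHITNEY = 25  # total sample size

VESICLE_CONDITIONS = (
    "untreated", "rnase", "prot_k_rnase", "triton_rnase", "prot_k_triton_rnase",
)


# --------------------------------------------------------------------------
# qRT-PCR relative abundance

def relative_abundance(panel: pd.DataFrame,
                       ct_col: str = "ct",
                       ref_col: str = "ct_rnu48") -> pd.DataFrame:
    """Per-record relative level ``2 ** -(Ct_target - Ct_reference)``.

    Records with a missing reference Ct are skipped with a warning.
    Assumes doubling amplification efficiency per cycle.
    """
    if ct_col not in panel.columns or ref_col not in panel.columns:
        raise ValueError(f"panel needs columns {ct_col!r} and {ref_col!r}")
    ok = panel[ref_col].notna() & panel[ct_col].notna()
    if (~ok).any():
        warnings.warn(f"skipping {(~ok).sum()} records with missing Ct")
    out = panel.loc[ok].copy()
    out["level"] = 2.0 ** -(out[ct_col] - out[ref_col])
    return out


# --------------------------------------------------------------------------
# exact rank tests

class TestResult(NamedTuple):
    statistic: float
    pvalue: float


def _signed_rank_null(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts over doubled-W values for the 2^n sign-flip null (tie-adjusted)."""
    total = sum(doubled_ranks)
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(dp)
        shifted[r:] = dp[:total + 1 - r]
        dp = dp + shifted
    return dp / dp.sum()


_signed_rank_null_cached = lru_cache(maxsize=64)(_signed_rank_null)


def _two_sided_from_dist(dist: np.ndarray, stat2: int) -> float:
    lower = dist[:stat2 + 1].sum()
    upper = dist[stat2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test.

    ``x`` is either the paired differences or the first member of each pair
    (with ``y`` the second).  Zero differences are dropped; tied absolute
    differences get average ranks.  Exact p by convolution of the sign-flip
    distribution up to 25 informative pairs, then a tie-corrected normal
    approximation with continuity correction.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(0.0, 1.0)
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT_WILCOXON:
        r2 = tuple(int(round(2 * r)) for r in sorted(ranks))
        dist = _signed_rank_null_cached(r2)
        return TestResult(w, _two_sided_from_dist(dist, int(round(2 * w))))
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 \
        - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w - mu - 0.5 * np.sign(w - mu)) / math.sqrt(var)
    return TestResult(w, float(min(1.0, 2.0 * stats.norm.sf(abs(z)))))


def _rank_sum_null(doubled_ranks: tuple[int, ...], n_a: int) -> np.ndarray:
    """Distribution of group-A doubled rank sum over all C(n, n_a) assignments."""
    total = sum(doubled_ranks)
    dp = np.zeros((n_a + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        for j in range(n_a, 0, -1):
            dp[j, r:] += dp[j - 1, :total + 1 - r]
    dist = dp[n_a]
    return dist / dist.sum()


_rank_sum_null_cached = lru_cache(maxsize=64)(_rank_sum_null)


def mann_whitney(a, b) -> TestResult:
    """Exact two-sided Mann–Whitney U test (tie-adjusted).

    Exact p by enumeration (dynamic program over rank assignments) for
    combined sample sizes up to 25; two-sided by doubling the smaller tail,
    capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = float(ranks[:n_a].sum())
    u = r_a - n_a * (n_a + 1) / 2.0
    if n_a + n_b <= EXACT_LIMIT_MANNWHITNEY:
        r2 = tuple(int(round(2 * r)) for r in sorted(ranks))
        dist = _rank_sum_null_cached(r2, n_a)
        return TestResult(u, _two_sided_from_dist(dist, int(round(2 * r_a))))
    mu = n_a * (n_a + n_b + 1) / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    z = (r_a - mu - 0.5 * np.sign(r_a - mu)) / math.sqrt(var)
    return TestResult(u, float(min(1.0, 2.0 * stats.norm.sf(abs(z)))))


def spearman(x, y) -> float:
    """Spearman rho (average ranks for ties); NaN for a constant vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def spearman_permutation(x, y, reps: int = 10_000,
                         seed: int = 0) -> TestResult:
    """Spearman rho with a seeded Monte-Carlo permutation p-value."""
    rho = spearman(x, y)
    if math.isnan(rho):
        return TestResult(rho, float("nan"))
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    hits = 1
    for _ in range(reps):
        r = spearman(x, rng.permutation(y))
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return TestResult(rho, hits / (reps + 1))


# --------------------------------------------------------------------------
# power of the paired design

@dataclass(frozen=True)
class PowerConfig:
    """Monte-Carlo design for the paired Wilcoxon power estimate."""

    n_pairs: int = 12
    effect_size: float = 1.0   # standardized mean of paired differences
    alpha: float = 0.05
    reps: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1_000:
            raise ValueError("need at least 1,000 replicates")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


class PowerResult(NamedTuple):
    power: float
    se: float
    reps: int


def power_paired_wilcoxon(config: PowerConfig | None = None,
                          **kwargs) -> PowerResult:
    """Monte-Carlo power of the exact two-sided paired Wilcoxon test.

    Each replicate draws ``n_pairs`` paired differences from
    ``Normal(effect_size, 1)`` and applies the exact signed-rank test at
    ``alpha``; power is the rejection fraction, reported with its binomial
    Monte-Carlo standard error.
    """
    cfg = config if config is not None else PowerConfig(**kwargs)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    # continuous draws: ties/zeros have probability 0, so the null
    # distribution of W is the untied one for ranks 1..n
    dist = _signed_rank_null_cached(tuple(range(2, 2 * n + 1, 2)))
    max2 = len(dist) - 1
    cdf = np.cumsum(dist)
    sf = np.cumsum(dist[::-1])[::-1]
    p_lookup = np.minimum(1.0, 2.0 * np.minimum(cdf, sf))
    reject_lookup = p_lookup <= cfg.alpha

    rejections = 0
    block = 10_000
    done = 0
    while done < cfg.reps:
        m = min(block, cfg.reps - done)
        d = rng.normal(cfg.effect_size, 1.0, size=(m, n))
        ranks = stats.rankdata(np.abs(d), axis=1)
        w2 = np.rint(2 * (ranks * (d > 0)).sum(axis=1)).astype(int)
        rejections += int(reject_lookup[np.clip(w2, 0, max2)].sum())
        done += m
    power = rejections / cfg.reps
    se = math.sqrt(power * (1 - power) / cfg.reps)
    return PowerResult(power, se, cfg.reps)


# --------------------------------------------------------------------------
# vesicle RNase protection

class VesicleFraction(NamedTuple):
    fraction: float   # clamped to [0, 1]
    raw: float        # 1 - level(triton_rnase) / level(rnase)


def vesicle_protected_fraction(levels: dict[str, float]) -> VesicleFraction:
    """Fraction of transcripts degraded once the membrane is disrupted.

    ``1 - level(triton_rnase) / level(rnase)``: RNase alone spares
    vesicle-protected RNA, Triton + RNase does not, so the drop measures the
    membrane-protected share.  Reported clamped to [0, 1] with the raw value
    retained (and logged when clamping occurs).
    """
    for cond in ("rnase", "triton_rnase"):
        if cond not in levels:
            raise ValueError(f"missing vesicle assay condition {cond!r}")
        if not levels[cond] > 0:
            raise ValueError(f"condition {cond!r} must have a positive level")
    raw = 1.0 - levels["triton_rnase"] / levels["rnase"]
    clamped = min(max(raw, 0.0), 1.0)
    if clamped != raw:
        logger.warning("vesicle fraction %.4f outside [0, 1]; clamped", raw)
    return VesicleFraction(clamped, raw)
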