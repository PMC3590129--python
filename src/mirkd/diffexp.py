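"""Negative-binomial differential expression for miR count matrices.

The model follows the classic two-condition NB count workflow: per-library
size factors by the median-of-ratios method, per-row method-of-moments
dispersion with a ``a0/q + a1`` trend and a conservative maximum rule, a
conditional exact test on the split of each row's total count between the
two conditions, Benjamini–Hochberg adjustment, and fold changes on both the
plain normalized-mean scale and a variance-stabilized log2 scale.

Usage is statsmodels-like::

    model = NegativeBinomialDE(counts, conditions)
    res = model.fit()
    res.summary()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_VST_ALPHA_FLOOR = 1e-8


def estimate_size_factors(counts: pd.DataFrame,
                          use_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    ``s_j`` is the median over all-positive rows of ``k_ij`` divided by the
    row's geometric mean.  With ``use_pseudo_reference`` the geometric mean
    and median are taken over the positive entries of every non-zero row —
    the fallback for sparse matrices without any all-positive row.
    """
    k = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    if use_pseudo_reference:
        row_ok = (k > 0).any(axis=1)
        if not row_ok.any():
            raise ValueError("count matrix is all zero")
        loggeo = np.array([
            logk[i][k[i] > 0].mean() for i in np.flatnonzero(row_ok)
        ])
        sf = []
        for j in range(k.shape[1]):
            ratios = logk[row_ok, j] - loggeo
            ratios = ratios[np.isfinite(ratios)]
            if ratios.size == 0:
                raise ValueError(f"library {counts.columns[j]} has no usable counts")
            sf.append(np.exp(np.median(ratios)))
        return pd.Series(sf, index=counts.columns, name="size_factor")
    all_pos = (k > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no row with all-positive counts; re-run with "
            "use_pseudo_reference=True")
    loggeo = logk[all_pos].mean(axis=1)
    sf = np.exp(np.median(logk[all_pos] - loggeo[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


@dataclass
class DispersionEstimates:
    """Raw, trend and final per-row NB dispersions."""

    alpha_mom: pd.Series      # method-of-moments estimate, floored at 0
    trend_coefs: tuple[float, float]   # (a0, a1) in alpha_fit(q) = a0/q + a1
    alpha_final: pd.Series    # max(alpha_mom, alpha_fit(base_mean))
    base_mean: pd.Series

    def trend(self, q) -> np.ndarray:
        a0, a1 = self.trend_coefs
        return np.maximum(a0 / np.maximum(np.asarray(q, dtype=float), 1e-12) + a1,
                          0.0)


def estimate_dispersions(counts: pd.DataFrame, size_factors: pd.Series,
                         conditions: pd.Series | list) -> DispersionEstimates:
    """Method-of-moments dispersion with an ``a0/q + a1`` trend floor.

    For each row, with normalized counts ``q_ij = k_ij / s_j``:
    ``alpha_hat_i = max(0, (v_i - qbar_i * mean(1/s_j)) / qbar_i**2)`` where
    ``v_i`` is the sample variance of the normalized counts.  The trend is a
    least-squares fit of ``alpha_hat`` on ``1/qbar`` over rows with positive
    ``alpha_hat``; the final dispersion takes the row-wise maximum of raw
    estimate and evaluated trend (the conservative sharing rule).
    """
    conditions = pd.Series(list(conditions), index=counts.columns)
    if (conditions.value_counts() < 2).any():
        raise ValueError("each condition needs at least 2 libraries")
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    q = counts.to_numpy(dtype=float) / s
    qbar = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    xi = (1.0 / s).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(qbar > 0, (v - qbar * xi) / qbar**2, 0.0)
    alpha_mom = np.maximum(np.nan_to_num(alpha_mom), 0.0)

    fit_rows = alpha_mom > 0
    if fit_rows.sum() >= 2:
        x = 1.0 / qbar[fit_rows]
        design = np.column_stack([x, np.ones_like(x)])
        coefs, *_ = np.linalg.lstsq(design, alpha_mom[fit_rows], rcond=None)
        a0, a1 = float(coefs[0]), float(coefs[1])
    else:
        a0 = a1 = 0.0
    est = DispersionEstimates(
        alpha_mom=pd.Series(alpha_mom, index=counts.index, name="alpha_mom"),
        trend_coefs=(a0, a1),
        alpha_final=pd.Series(0.0, index=counts.index, name="alpha"),
        base_mean=pd.Series(qbar, index=counts.index, name="base_mean"),
    )
    est.alpha_final = pd.Series(
        np.maximum(alpha_mom, est.trend(qbar)), index=counts.index, name="alpha",
    )
    return est


def _nb_pmf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    """NB (or Poisson-limit) pmf parametrized by mean and variance."""
    if mean <= 0:
        return np.where(x == 0, 1.0, 0.0)
    if var <= mean * (1 + 1e-12):
        return stats.poisson.pmf(x, mean)
    r = mean**2 / (var - mean)
    return stats.nbinom.pmf(x, r, r / (r + mean))


def nb_exact_test(row_counts, conditions, size_factors, dispersion: float) -> float:
    """Conditional NB exact test for one row.

    Conditions on the row total ``K``: enumerates every split ``(a, K - a)``
    between the two conditions, scores each with the product of NB
    probabilities whose means and variances are the condition-summed library
    means/variances at the pooled rate ``q0 = K / sum(s_j)``, and returns
    the total probability of splits no more likely than the observed one
    (two-sided, the summed-tails convention).
    """
    k = np.asarray(row_counts, dtype=float)
    conds = np.asarray(conditions)
    s = np.asarray(size_factors, dtype=float)
    labels = pd.unique(conds)
    if len(labels) != 2:
        raise ValueError("exactly two conditions required")
    in_a = conds == labels[0]
    K_a, K_b = int(k[in_a].sum()), int(k[~in_a].sum())
    K = K_a + K_b
    if K == 0:
        return 1.0
    q0 = K / s.sum()
    mu_a = q0 * s[in_a].sum()
    var_a = mu_a + dispersion * q0**2 * (s[in_a]**2).sum()
    mu_b = q0 * s[~in_a].sum()
    var_b = mu_b + dispersion * q0**2 * (s[~in_a]**2).sum()
    a = np.arange(K + 1)
    probs = _nb_pmf(a, mu_a, var_a) * _nb_pmf(K - a, mu_b, var_b)
    total = probs.sum()
    if total <= 0:
        return 1.0
    p_obs = probs[K_a]
    return float(min(probs[probs <= p_obs * (1 + 1e-12)].sum() / total, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def vst_log2(k_norm, alpha: float) -> np.ndarray:
    """Variance-stabilizing transform on the log2 scale.

    ``u(k) = 2 * log2(sqrt(alpha*k) + sqrt(alpha*k + 1))``, the antiderivative
    of ``1/sqrt(k + alpha*k^2)`` rescaled so that differences approach plain
    log2 ratios when ``alpha * k >> 1``.
    """
    a = max(alpha, _VST_ALPHA_FLOOR)
    ak = a * np.asarray(k_norm, dtype=float)
    return 2.0 * np.log2(np.sqrt(ak) + np.sqrt(ak + 1.0))


def fold_changes(counts: pd.DataFrame, size_factors: pd.Series,
                 conditions, contrast: tuple[str, str],
                 dispersions: pd.Series | float = 0.1) -> pd.DataFrame:
    """Per-row fold change (ratio of mean normalized counts) and VST log2 FC.

    ``contrast = (numerator, denominator)``.  A zero denominator mean leaves
    ``fold_change`` missing (NaN) while ``vst_log2fc`` stays defined.
    """
    conds = pd.Series(list(conditions), index=counts.columns)
    s = size_factors.loc[counts.columns]
    q = counts / s
    num, den = contrast
    q_num = q.loc[:, (conds == num).to_numpy()].mean(axis=1)
    q_den = q.loc[:, (conds == den).to_numpy()].mean(axis=1)
    if np.isscalar(dispersions):
        disp = pd.Series(float(dispersions), index=counts.index)
    else:
        disp = dispersions.loc[counts.index]
    vst_fc = np.empty(len(counts))
    for i, rid in enumerate(counts.index):
        u = vst_log2(q.loc[rid].to_numpy(), float(disp.loc[rid]))
        vst_fc[i] = (u[(conds == num).to_numpy()].mean()
                     - u[(conds == den).to_numpy()].mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(q_den > 0, q_num / q_den, np.nan)
    return pd.DataFrame({
        f"mean_{num}": q_num, f"mean_{den}": q_den,
        "fold_change": fc, "vst_log2fc": vst_fc,
    }, index=counts.index)


class NegativeBinomialDE:
    """Two-condition NB differential-expression model for a count matrix.

    Parameters
    ----------
    counts : DataFrame
        miR × library matrix of nonnegative integer counts.
    conditions : sequence of str
        Condition label per library (two distinct labels).
    contrast : (numerator, denominator), optional
        Defaults to ``("acute", <other>)`` when an "acute" label is present,
        otherwise to first-appearance order.
    """

    def __init__(self, counts: pd.DataFrame, conditions,
                 contrast: tuple[str, str] | None = None,
                 size_factors: pd.Series | None = None):
        self.counts = counts
        self.conditions = pd.Series(list(conditions), index=counts.columns,
                                    name="condition")
        labels = list(pd.unique(self.conditions))
        if len(labels) != 2:
            raise ValueError("exactly two condition labels required")
        if contrast is None:
            if "acute" in labels:
                other = labels[0] if labels[1] == "acute" else labels[1]
                contrast = ("acute", other)
            else:
                contrast = (labels[0], labels[1])
        if set(contrast) != set(labels):
            raise ValueError("contrast labels do not match conditions")
        self.contrast = contrast
        self._size_factors = size_factors

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, samples: pd.DataFrame,
                       library_col: str = "library",
                       condition_col: str = "condition",
                       **kwargs) -> "NegativeBinomialDE":
        """Build from a count matrix plus a sample sheet."""
        samples = samples.set_index(library_col)
        conditions = samples.loc[counts.columns, condition_col]
        return cls(counts, conditions, **kwargs)

    def fit(self, use_pseudo_reference: bool = False) -> "DEResults":
        """Estimate size factors and dispersions, test every non-zero row."""
        counts = self.counts
        nonzero = counts.sum(axis=1) > 0
        tested = counts.loc[nonzero]
        sf = (self._size_factors if self._size_factors is not None
              else estimate_size_factors(counts, use_pseudo_reference))
        disp = estimate_dispersions(tested, sf, self.conditions)
        conds = self.conditions.to_numpy()
        s = sf.loc[counts.columns].to_numpy(dtype=float)
        # orient the test so condition A is the contrast numerator
        order = np.argsort(conds != self.contrast[0], kind="stable")
        pvals = np.array([
            nb_exact_test(tested.iloc[i].to_numpy()[order], conds[order],
                          s[order], float(disp.alpha_final.iloc[i]))
            for i in range(len(tested))
        ])
        padj = bh_adjust(pvals)
        fc = fold_changes(tested, sf, self.conditions, self.contrast,
                          disp.alpha_final)
        frame = fc.copy()
        frame.insert(0, "base_mean", disp.base_mean)
        frame["dispersion"] = disp.alpha_final
        frame["pval"] = pvals
        frame["padj"] = padj
        return DEResults(frame=frame, size_factors=sf, dispersions=disp,
                         contrast=self.contrast, n_dropped=int((~nonzero).sum()))


@dataclass
class DEResults:
    """Fitted differential-expression results.

    ``frame`` has one row per tested miR with columns ``base_mean``,
    ``mean_<A>``, ``mean_<B>``, ``fold_change``, ``vst_log2fc``,
    ``dispersion``, ``pval`` and ``padj``.  Rows with zero total count were
    dropped before testing and are excluded from the BH family.
    """

    frame: pd.DataFrame
    size_factors: pd.Series
    dispersions: DispersionEstimates
    contrast: tuple[str, str]
    n_dropped: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return (self.frame[self.frame["padj"] < alpha]
                .sort_values("padj"))

    def sorted(self) -> pd.DataFrame:
        return self.frame.sort_values(["padj", "pval"])

    def summary(self, top: int = 10) -> str:
        num, den = self.contrast
        sig = self.significant()
        lines = [
            "Negative-binomial differential expression",
            f"  contrast:        {num} vs {den}",
            f"  miRs tested:     {len(self.frame)} "
            f"({self.n_dropped} all-zero rows dropped)",
            f"  significant at BH<0.05: {len(sig)}",
            "",
            self.sorted().head(top).to_string(
                float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def plot_ma(self, ax=None, alpha: float = 0.05):
        """MA plot: VST log2 fold change against mean normalized count."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sig = self.frame["padj"] < alpha
        ax.scatter(self.frame.loc[~sig, "base_mean"],
                   self.frame.loc[~sig, "vst_log2fc"], s=8, c="grey",
                   label="not significant")
        ax.scatter(self.frame.loc[sig, "base_mean"],
                   self.frame.loc[sig, "vst_log2fc"], s=10, c="crimson",
                   label=f"BH < {alpha:g}")
        ax.set_xscale("log")
        ax.set_xlabel("mean normalized count")
        ax.set_ylabel("VST log2 fold change")
        ax.legend(frameon=False)
        return ax

    def to_tsv(self, path) -> None:
        self.sorted().to_csv(path, sep="\t")


def run_diffexp(counts: pd.DataFrame, samples: pd.DataFrame,
                **kwargs) -> DEResults:
    """One-call convenience wrapper used by the CLI."""
    model = NegativeBinomialDE.from_dataframe(counts, samples, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return model.fit()
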