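"""Distributional summaries and within-subject inferential statistics.

Per-subject metric values are summarized with a Gaussian kernel density
estimate (fixed bandwidth, 0.2 m/s for speed distributions) and
Tukey-style boxplot statistics, and compared across conditions with
classical repeated-measures ANOVA:

* one-way within-subject: ``F = MS_condition / MS_(condition × subject)``
  with df ``(a − 1, (a − 1)(s − 1))``;
* two-way within-subject: each main effect and the interaction is tested
  against its own interaction-with-subject error term.

No sphericity correction is applied by default (a Greenhouse–Geisser
mode is available), matching the uncorrected df convention. Post-hoc
comparisons are two-sided paired t-tests, Bonferroni-corrected over the
number of pairs and halved to yield a one-sided result whose direction
is read off the sign of the t statistic — an unconventional but
deliberate convention, with a standard two-sided mode available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .io_model import ValidationError

__all__ = [
    "KdeEstimate",
    "BoxplotSummary",
    "AnovaResult",
    "kde",
    "boxplot_summary",
    "rm_anova",
    "posthoc_paired_t",
]


@dataclass
class KdeEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


@dataclass
class BoxplotSummary:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


@dataclass
class PairwiseComparison:
    pair: tuple
    t: float
    p_raw: float
    p_corrected: float
    direction: str
    significant: bool


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: tuple
    p: float
    posthoc: list = field(default_factory=list)


def kde(values: np.ndarray, h: float = 0.2, grid: np.ndarray | None = None) -> KdeEstimate:
    """Gaussian kernel density estimate with fixed bandwidth.

    ``f̂_h(x) = 1/(n h) Σ_i K((x − x_i)/h)`` with the standard normal
    kernel ``K``. When no grid is given, one spanning data ± 6h at 512
    points is used.
    """
    values = np.asarray(values, dtype=float).ravel()
    if len(values) < 1:
        raise ValidationError("need at least one sample")
    if h <= 0:
        raise ValidationError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(values.min() - 6 * h, values.max() + 6 * h, 512)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - values[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (len(values) * h * np.sqrt(2.0 * np.pi))
    return KdeEstimate(grid, density, h)


def boxplot_summary(values: np.ndarray) -> BoxplotSummary:
    """Tukey boxplot statistics: quartiles, 1.5 IQR whiskers, outliers.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme samples within 1.5 IQR of the box.
    """
    values = np.asarray(values, dtype=float).ravel()
    if len(values) < 2:
        raise ValidationError("need at least two samples for a boxplot summary")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    in_low = values[values >= q1 - 1.5 * iqr]
    in_high = values[values <= q3 + 1.5 * iqr]
    lo = float(in_low.min())
    hi = float(in_high.max())
    outliers = values[(values < lo) | (values > hi)]
    return BoxplotSummary(float(q1), float(med), float(q3), lo, hi, outliers)


def _f_test(ss_eff, df_eff, ss_err, df_err):
    if ss_eff <= 0:
        return 0.0, 1.0
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return float("inf"), 0.0
    f = ms_eff / ms_err
    return float(f), float(sps.f.sf(f, df_eff, df_err))


def rm_anova(values: np.ndarray, design: str = "one-way",
             correction: str = "none") -> dict:
    """Repeated-measures ANOVA by the classical within-subject decomposition.

    Parameters
    ----------
    values
        ``one-way``: array of shape (subjects, conditions).
        ``two-way``: array of shape (subjects, levels_A, levels_B), one
        observation per cell; each effect is tested against its
        subject-interaction error term.

    Returns
    -------
    dict mapping effect name ("condition", or "A"/"B"/"A:B") to
    :class:`AnovaResult`. The design must be complete and balanced; cells
    may not be missing (no imputation is performed).
    """
    y = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValidationError("unbalanced design: missing or non-finite cells")

    if design == "one-way":
        if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
            raise ValidationError("one-way design needs a (subjects >= 2, conditions >= 2) table")
        s, a = y.shape
        gm = y.mean()
        ss_a = s * np.sum((y.mean(axis=0) - gm) ** 2)
        ss_s = a * np.sum((y.mean(axis=1) - gm) ** 2)
        ss_tot = np.sum((y - gm) ** 2)
        ss_err = ss_tot - ss_a - ss_s
        df_a, df_err = a - 1, (a - 1) * (s - 1)
        f, p = _f_test(ss_a, df_a, ss_err, df_err)
        if correction == "gg" and f > 0 and np.isfinite(f):
            # Greenhouse-Geisser sphericity correction of the p-value
            cov = np.cov(y, rowvar=False)
            centered = cov - cov.mean(axis=0) - cov.mean(axis=1)[:, None] + cov.mean()
            lam = np.linalg.eigvalsh(centered)
            eps = lam.sum() ** 2 / ((a - 1) * np.sum(lam ** 2))
            p = float(sps.f.sf(f, eps * df_a, eps * df_err))
        elif correction not in ("none", "gg"):
            raise ValueError(f"unknown correction {correction!r}")
        return {"condition": AnovaResult("condition", f, (df_a, df_err), p)}

    if design == "two-way":
        if y.ndim != 3 or y.shape[0] < 2 or y.shape[1] < 2 or y.shape[2] < 2:
            raise ValidationError("two-way design needs a (subjects, A, B) table, all >= 2")
        s, a, b = y.shape
        gm = y.mean()
        m_s = y.mean(axis=(1, 2))
        m_a = y.mean(axis=(0, 2))
        m_b = y.mean(axis=(0, 1))
        m_sa = y.mean(axis=2)
        m_sb = y.mean(axis=1)
        m_ab = y.mean(axis=0)
        ss_a = s * b * np.sum((m_a - gm) ** 2)
        ss_b = s * a * np.sum((m_b - gm) ** 2)
        ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
        ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
        ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
        ss_s = a * b * np.sum((m_s - gm) ** 2)
        ss_tot = np.sum((y - gm) ** 2)
        ss_sab = ss_tot - ss_a - ss_b - ss_ab - ss_sa - ss_sb - ss_s
        out = {}
        for name, ss_eff, df_eff, ss_err, df_err in [
            ("A", ss_a, a - 1, ss_sa, (a - 1) * (s - 1)),
            ("B", ss_b, b - 1, ss_sb, (b - 1) * (s - 1)),
            ("A:B", ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (s - 1)),
        ]:
            f, p = _f_test(ss_eff, df_eff, max(ss_err, 0.0), df_err)
            out[name] = AnovaResult(name, f, (df_eff, df_err), p)
        return out

    raise ValueError(f"unknown design {design!r}")


def posthoc_paired_t(values: np.ndarray, labels=None, alpha: float = 0.05,
                     halve: bool = True) -> list:
    """Bonferroni-corrected paired t-tests between all condition pairs.

    For each pair a two-sided paired t-test is run; the corrected p-value
    is ``min(1, p·m)`` over the m pairs, halved by default to give a
    one-sided result whose direction follows the sign of t ("greater"
    means the first condition of the pair is larger).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValidationError("need a (subjects >= 2, conditions) table")
    s, a = y.shape
    if labels is None:
        labels = list(range(a))
    pairs = list(combinations(range(a), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        diff = y[:, i] - y[:, j]
        if np.allclose(diff, diff[0]) and np.allclose(diff[0], 0.0):
            t_stat, p_raw = 0.0, 1.0
        else:
            t_stat, p_raw = sps.ttest_rel(y[:, i], y[:, j])
            t_stat, p_raw = float(t_stat), float(p_raw)
            if not np.isfinite(p_raw):
                p_raw = 0.0
        p_corr = min(1.0, p_raw * m)
        if halve:
            p_corr /= 2.0
        out.append(
            PairwiseComparison(
                (labels[i], labels[j]), t_stat, p_raw, p_corr,
                "greater" if t_stat > 0 else ("less" if t_stat < 0 else "equal"),
                p_corr < alpha,
            )
        )
    return out
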