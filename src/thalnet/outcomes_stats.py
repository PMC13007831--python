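"""Seizure outcomes, responder categories, and the cohort's two tests.

Patients are categorized by seizure-frequency reduction at last follow-up:
responders (> 50%), partial responders (25–50%, both bounds included), and
nonresponders (< 25%); partial and nonresponders are pooled for the group
comparison.  Two nonparametric tests are used:

* Spearman rank correlation (two-sided) between the per-patient activated
  streamline proportion and seizure reduction, with a t-approximation p-value
  by default and an exact permutation p for small samples (n <= 8); and
* a Mann–Whitney U test comparing the peak connectivity probability inside
  the VTA between responders and pooled partial/nonresponders, exact by full
  enumeration of group assignments for combined n <= 20 (e.g. all
  C(12, 7) = 792 assignments for a 7-vs-5 split), otherwise a normal
  approximation with tie correction.

The exact paths are enumerated here by hand so they can be cross-checked
against scipy.stats in the test suite without circularity.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations, permutations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OutcomeRecord",
    "StatResults",
    "seizure_reduction",
    "classify_response",
    "spearman",
    "mann_whitney",
    "run_group_comparison",
    "run_correlation",
]

RESPONDER = "responder"
PARTIAL = "partial"
NONRESPONDER = "nonresponder"


@dataclasses.dataclass
class OutcomeRecord:
    patient_id: str
    pre_per_month: float
    post_per_month: float
    engel: str = ""

    @property
    def reduction_percent(self) -> float:
        return seizure_reduction(self.pre_per_month, self.post_per_month)

    @property
    def category(self) -> str:
        return classify_response(self.reduction_percent)


def seizure_reduction(pre: float, post: float) -> float:
    """Percent seizure reduction, clamped at 0 when frequency worsened."""
    if pre <= 0:
        raise ValueError("preoperative seizure frequency must be positive")
    if post < 0:
        raise ValueError("postoperative seizure frequency must be >= 0")
    return max(0.0, 100.0 * (pre - post) / pre)


def classify_response(reduction: float) -> str:
    """>50 -> responder; 25..50 inclusive -> partial; <25 -> nonresponder."""
    if not 0 <= reduction <= 100:
        raise ValueError("reduction must be in [0, 100]")
    if reduction > 50:
        return RESPONDER
    if reduction >= 25:
        return PARTIAL
    return NONRESPONDER


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(
    x, y, method: str = "auto", n_exact_max: int = 8
) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided p-value.

    ``method``: 'auto' uses exact permutation when n <= ``n_exact_max``, the
    t-approximation with n-2 df otherwise; 'exact' and 't' force a flavor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho is undefined for a constant vector")
    rx, ry = _average_ranks(x), _average_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if method == "exact" or (method == "auto" and n <= n_exact_max):
        # permutation distribution of rho under independence
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        obs = abs(rho)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = float((rx_c[list(perm)] * ry_c).sum()) / denom
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a from rank sums with average ranks."""
    n_a = len(a)
    ranks = _average_ranks(np.concatenate([a, b]))
    r_a = ranks[:n_a].sum()
    return float(r_a - n_a * (n_a + 1) / 2)


def mann_whitney(
    a, b, method: str = "auto", n_exact_max: int = 20
) -> tuple[float, float]:
    """Mann–Whitney U (for the first group) with a two-sided p-value.

    Exact p enumerates all C(n_a + n_b, n_a) assignments of the pooled values
    to groups (ties handled naturally through average ranks); the asymptotic
    flavor is a normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    u_obs = _u_statistic(a, b)
    mu = n_a * n_b / 2
    if method == "exact" or (method == "auto" and n <= n_exact_max):
        pooled = np.concatenate([a, b])
        ranks = _average_ranks(pooled)
        offset = n_a * (n_a + 1) / 2
        dev_obs = abs(u_obs - mu)
        count = 0
        total = comb(n, n_a)
        # vectorized enumeration over all group assignments
        idx = np.fromiter(
            (i for c in combinations(range(n), n_a) for i in c), dtype=int
        ).reshape(total, n_a)
        us = ranks[idx].sum(axis=1) - offset
        count = int(np.sum(np.abs(us - mu) >= dev_obs - 1e-12))
        return u_obs, count / total
    ties = pd.Series(np.concatenate([a, b])).value_counts().to_numpy()
    tie_term = (ties**3 - ties).sum() / (n * (n - 1))
    var = n_a * n_b / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (u_obs - mu) / np.sqrt(var)
    return u_obs, float(min(1.0, 2 * sps.norm.sf(abs(z))))


def _iqr(x: np.ndarray) -> tuple[float, float]:
    """Inclusive 25th/75th percentiles with linear interpolation."""
    return (float(np.percentile(x, 25)), float(np.percentile(x, 75)))


@dataclasses.dataclass
class StatResults:
    """Results of the cohort analyses, with a printable summary."""

    spearman_rho: float | None = None
    spearman_p: float | None = None
    mannwhitney_u: float | None = None
    mannwhitney_p: float | None = None
    median_responders: float | None = None
    iqr_responders: tuple[float, float] | None = None
    median_others: float | None = None
    iqr_others: tuple[float, float] | None = None
    n_responders: int | None = None
    n_others: int | None = None

    def summary(self) -> str:
        lines = ["Cohort outcome analysis", "=" * 34]
        if self.spearman_rho is not None:
            lines.append(
                f"Spearman (activation vs reduction): rho = {self.spearman_rho:.3f}, "
                f"p = {self.spearman_p:.4f}"
            )
        if self.mannwhitney_u is not None:
            lines.append(
                f"Mann-Whitney U (peak probability, responders vs others): "
                f"U = {self.mannwhitney_u:.1f}, p = {self.mannwhitney_p:.4f}"
            )
            lines.append(
                f"  responders (n={self.n_responders}): median = "
                f"{self.median_responders:.3f}, IQR = {self.iqr_responders[0]:.3f}-"
                f"{self.iqr_responders[1]:.3f}"
            )
            lines.append(
                f"  partial/nonresponders (n={self.n_others}): median = "
                f"{self.median_others:.3f}, IQR = {self.iqr_others[0]:.3f}-"
                f"{self.iqr_others[1]:.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["iqr_responders"] = list(d["iqr_responders"]) if d["iqr_responders"] else None
        d["iqr_others"] = list(d["iqr_others"]) if d["iqr_others"] else None
        return d


def run_correlation(cohort: pd.DataFrame, method: str = "auto") -> StatResults:
    """Spearman correlation between activation proportion and reduction %.

    ``cohort`` needs columns ``n_activated``, ``n_total`` (or ``proportion``)
    and ``reduction_percent``.
    """
    if "proportion" in cohort:
        x = cohort["proportion"].to_numpy(float)
    else:
        x = cohort["n_activated"].to_numpy(float) / cohort["n_total"].to_numpy(float)
    y = cohort["reduction_percent"].to_numpy(float)
    rho, p = spearman(x, y, method=method)
    return StatResults(spearman_rho=rho, spearman_p=p)


def run_group_comparison(cohort: pd.DataFrame, method: str = "auto") -> StatResults:
    """Responders vs pooled partial/nonresponders on peak probability.

    ``cohort`` needs ``peak_probability`` and ``reduction_percent`` columns.
    """
    cats = cohort["reduction_percent"].map(classify_response)
    resp = cohort.loc[cats == RESPONDER, "peak_probability"].to_numpy(float)
    other = cohort.loc[cats != RESPONDER, "peak_probability"].to_numpy(float)
    if len(resp) == 0 or len(other) == 0:
        raise ValueError("both response groups must be nonempty")
    u, p = mann_whitney(resp, other, method=method)
    return StatResults(
        mannwhitney_u=u,
        mannwhitney_p=p,
        median_responders=float(np.median(resp)),
        iqr_responders=_iqr(resp),
        median_others=float(np.median(other)),
        iqr_others=_iqr(other),
        n_responders=len(resp),
        n_others=len(other),
    )


def analyze_cohort(cohort: pd.DataFrame, method: str = "auto") -> StatResults:
    """Both analyses on one cohort table.  An analysis that is undefined for
    the given cohort (too few patients, an empty response group, a constant
    metric) leaves its fields unset rather than failing the other one."""
    out = StatResults()
    try:
        corr = run_correlation(cohort, method=method)
        out.spearman_rho = corr.spearman_rho
        out.spearman_p = corr.spearman_p
    except ValueError:
        pass
    if "peak_probability" in cohort:
        try:
            grp = run_group_comparison(cohort, method=method)
            for field in (
                "mannwhitney_u",
                "mannwhitney_p",
                "median_responders",
                "iqr_responders",
                "median_others",
                "iqr_others",
                "n_responders",
                "n_others",
            ):
                setattr(out, field, getattr(grp, field))
        except ValueError:
            pass
    return out
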