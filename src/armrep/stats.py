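"""Bilateral descriptive summaries and paired Wilcoxon signed-rank tests.

The test is two-sided throughout.  Zero differences are dropped (classical
Wilcoxon); tied absolute differences receive mid-ranks.  For up to
``EXACT_N_MAX`` effective pairs the two-sided p-value is exact, equivalent
to full enumeration of all sign assignments (computed by dynamic
programming over the tie-aware rank-sum distribution); above that a normal
approximation with tie correction and a continuity correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DataError

EXACT_N_MAX = 25

#: Fixed reporting order for the bilateral comparison table.
METRIC_ORDER = [
    "n_resting_bouts",
    "total_resting_s",
    "resting_duration_mean_s",
    "n_active_bouts",
    "total_active_s",
    "all_bouts.active_duration_mean_s",
    "all_bouts.cycles_per_bout_mean",
    "all_bouts.median_elevation_deg_mean",
    "all_bouts.peak_elevation_deg_mean",
    "bouts_gt_long.n_bouts",
    "bouts_gt_long.total_active_s",
    "bouts_gt_long.active_duration_mean_s",
    "bouts_gt_long.cycles_per_bout_mean",
    "bouts_gt_long.median_elevation_deg_mean",
    "bouts_gt_long.peak_elevation_deg_mean",
]


@dataclass
class PairedMetricSample:
    """One participant's (dominant, non-dominant) value pair for one metric."""

    participant_id: str
    metric_name: str
    dominant_value: float
    nondominant_value: float

    @property
    def difference(self) -> float:
        return self.dominant_value - self.nondominant_value

    @property
    def is_finite(self) -> bool:
        return bool(
            np.isfinite(self.dominant_value) and np.isfinite(self.nondominant_value)
        )


@dataclass
class SideSummary:
    mean: float
    sd: float | None
    median: float
    q1: float
    q3: float

    @classmethod
    def of(cls, values: np.ndarray) -> "SideSummary":
        x = np.asarray(values, dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return cls(
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)) if x.size >= 2 else None,
            median=float(med),
            q1=float(q1),
            q3=float(q3),
        )


@dataclass
class BilateralResult:
    metric_name: str
    n_pairs: int
    n_effective: int
    dominant: SideSummary | None
    nondominant: SideSummary | None
    w_statistic: float | None
    p_two_sided: float | None
    method: str  # "exact" | "normal" | "degenerate" | "insufficient"

    def __post_init__(self) -> None:
        if self.p_two_sided is not None and not (0.0 <= self.p_two_sided <= 1.0):
            raise DataError(f"p-value out of range: {self.p_two_sided}")
        if self.n_effective > self.n_pairs:
            raise DataError("n_effective cannot exceed n_pairs")


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks of |d| for nonzero differences, plus the sign vector."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    return ranks, np.sign(d)


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ by DP over all 2^n equally likely sign vectors.

    Ranks may be mid-ranks (multiples of 0.5); doubling makes them integers
    so the distribution of 2*W+ is supported on integers.
    """
    r2 = np.rint(2 * ranks).astype(int)
    if not np.allclose(2 * ranks, r2):
        raise DataError("ranks are not multiples of 0.5")
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(round(2 * w_plus))
    n_total = 1 << len(r2)
    cdf = int(np.sum(counts[: w2 + 1]))
    sf = int(np.sum(counts[w2:]))  # includes P(W == w)
    return min(1.0, 2.0 * min(cdf, sf) / n_total)


def _normal_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Large-sample normal approximation with tie and continuity corrections."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return 1.0
    d = w_plus - mu
    # continuity correction shrinks |d| by 0.5
    d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    z = d / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def wilcoxon_signed_rank(
    pairs: list[PairedMetricSample] | np.ndarray,
) -> BilateralResult:
    """Paired two-sided Wilcoxon signed-rank test for one metric.

    Accepts either PairedMetricSample objects or a raw array of paired
    differences.  All differences zero (or no pairs) gives a degenerate
    result with p = 1.
    """
    if isinstance(pairs, (list, tuple)) and pairs and isinstance(pairs[0], PairedMetricSample):
        metric = pairs[0].metric_name
        usable = [p for p in pairs if p.is_finite]
        diffs = np.array([p.difference for p in usable])
        dom = np.array([p.dominant_value for p in usable])
        nond = np.array([p.nondominant_value for p in usable])
    else:
        metric = ""
        diffs = np.asarray(pairs, dtype=float)
        diffs = diffs[np.isfinite(diffs)]
        dom = nond = None

    n_pairs = len(diffs)
    ranks, signs = _signed_ranks(diffs)
    n_eff = len(ranks)
    dom_summary = SideSummary.of(dom) if dom is not None and n_pairs else None
    nond_summary = SideSummary.of(nond) if nond is not None and n_pairs else None
    if n_eff == 0:
        return BilateralResult(
            metric_name=metric,
            n_pairs=n_pairs,
            n_effective=0,
            dominant=dom_summary,
            nondominant=nond_summary,
            w_statistic=None,
            p_two_sided=1.0,
            method="degenerate",
        )
    w_plus = float(np.sum(ranks[signs > 0]))
    if n_eff <= EXACT_N_MAX:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "exact"
    else:
        p = _normal_two_sided_p(ranks, w_plus)
        method = "normal"
    return BilateralResult(
        metric_name=metric,
        n_pairs=n_pairs,
        n_effective=n_eff,
        dominant=dom_summary,
        nondominant=nond_summary,
        w_statistic=w_plus,
        p_two_sided=p,
        method=method,
    )


def bilateral_summary(samples: list[PairedMetricSample]) -> list[BilateralResult]:
    """One BilateralResult per metric, in the documented fixed order.

    Each participant must contribute at most one pair per metric (average
    multi-day values per participant first).  Metrics with fewer than two
    finite pairs are summarized without a test and flagged "insufficient".
    """
    by_metric: dict[str, list[PairedMetricSample]] = {}
    for s in samples:
        seen = by_metric.setdefault(s.metric_name, [])
        if any(p.participant_id == s.participant_id for p in seen):
            raise DataError(
                f"participant {s.participant_id!r} contributes more than one pair "
                f"for metric {s.metric_name!r}; average per participant first"
            )
        seen.append(s)

    ordered = [m for m in METRIC_ORDER if m in by_metric]
    ordered += sorted(m for m in by_metric if m not in METRIC_ORDER)

    results = []
    for metric in ordered:
        pairs = [p for p in by_metric[metric] if p.is_finite]
        if len(pairs) < 2:
            dom = np.array([p.dominant_value for p in pairs])
            nond = np.array([p.nondominant_value for p in pairs])
            results.append(
                BilateralResult(
                    metric_name=metric,
                    n_pairs=len(pairs),
                    n_effective=0,
                    dominant=SideSummary.of(dom) if len(pairs) else None,
                    nondominant=SideSummary.of(nond) if len(pairs) else None,
                    w_statistic=None,
                    p_two_sided=None,
                    method="insufficient",
                )
            )
        else:
            results.append(wilcoxon_signed_rank(pairs))
    return results
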