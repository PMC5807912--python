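"""Group comparison: means with SEM, one-way ANOVA, Duncan's multiple range test.

Per-sample metric values are compared between experimental groups with a
classical fixed-effects one-way ANOVA at alpha = 0.05, followed by Duncan's
multiple range post hoc test.  Significance of post hoc pairs is reported as
star levels (1/2/3 for p <= 0.05 / 0.01 / 0.001), mirroring the usual figure
annotation; all uncertainty estimates are SEM.

Duncan's test ranks the group means and compares each pair against a
critical range that depends on how many ranks the pair spans: for a span of
r means the range is

    R_r = q(1 - alpha_r; r, df_within) * sqrt(MS_within / n_h)

where q is the studentized range quantile, alpha_r = 1 - (1 - alpha)^(r-1)
is Duncan's protection level, and n_h is the harmonic mean of the two
compared groups' sizes (the test assumes equal n; harmonic averaging is the
standard unequal-n adaptation).  A pair is declared non-significant outright
when any enclosing span has already tested non-significant (the step-down
containment rule), which keeps the decision pattern transitive.

Quantiles come from the studentized range distribution itself rather than
printed tables, so arbitrary df are supported; they agree with published
Duncan tables to interpolation accuracy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

from .errors import DegenerateVarianceError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
STAR_ALPHAS = (0.05, 0.01, 0.001)


@dataclass
class GroupData:
    """One experimental group's per-sample values for a single metric."""

    group_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p,
        }


@dataclass
class PairComparison:
    group_a: str
    group_b: str
    mean_diff: float
    significant: bool
    star_level: int
    p_value: float | None = None

    def to_dict(self) -> dict:
        d = {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "mean_diff": self.mean_diff,
            "significant": self.significant,
            "star_level": self.star_level,
        }
        if self.p_value is not None:
            d["p_value"] = self.p_value
        return d


@dataclass
class PosthocResult:
    pairs: list[PairComparison]
    alpha: float = DEFAULT_ALPHA

    def pair(self, a: str, b: str) -> PairComparison:
        for p in self.pairs:
            if {p.group_a, p.group_b} == {a, b}:
                return p
        raise KeyError(f"no comparison for pair ({a}, {b})")

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "pairs": [p.to_dict() for p in self.pairs]}


def group_summary(data: GroupData | np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and SEM (sample sd with n-1 denominator over sqrt n).

    A single-value group gets SEM 0 by convention (sd undefined), with a
    warning; an empty group is an error.
    """
    values = data.values if isinstance(data, GroupData) else np.asarray(data, float)
    n = len(values)
    if n == 0:
        raise ValueError("cannot summarize an empty group")
    mean = float(values.mean())
    if n == 1:
        logger.warning("group of size 1: SEM reported as 0 (sd undefined)")
        return mean, 0.0
    sem = float(values.std(ddof=1) / math.sqrt(n))
    return mean, sem


def one_way_anova(groups: list[GroupData]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom; p from
    the F distribution's upper tail.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.group_name!r} has n={g.n} < 2")
    k = len(groups)
    ns = np.array([g.n for g in groups])
    n_total = int(ns.sum())
    grand_mean = float(np.concatenate([g.values for g in groups]).mean())
    ss_between = float(sum(g.n * (g.mean - grand_mean) ** 2 for g in groups))
    ss_within = float(sum(((g.values - g.mean) ** 2).sum() for g in groups))
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0:
        raise DegenerateVarianceError(
            "zero within-group variance in every group; F is undefined"
        )
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    F = ms_between / ms_within
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(
        F=F, df_between=df_between, df_within=df_within, p=p, ms_within=ms_within
    )


@lru_cache(maxsize=8192)
def _q_critical(one_minus_alpha_r: float, span: int, df: int) -> float:
    """Cached studentized range quantile q(1 - alpha_r; span, df)."""
    return float(stats.studentized_range.ppf(one_minus_alpha_r, span, df))


def _duncan_decisions(
    means: np.ndarray, ns: np.ndarray, ms_within: float, df_within: int, alpha: float
) -> dict[tuple[int, int], bool]:
    """Duncan decisions over rank-sorted means; keys are rank-index pairs.

    Spans are processed widest first so the containment rule can block
    sub-ranges of a non-significant range.
    """
    k = len(means)
    decisions: dict[tuple[int, int], bool] = {}
    nonsig_spans: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        alpha_r = 1.0 - (1.0 - alpha) ** (span - 1)
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(a <= i and j <= b for a, b in nonsig_spans):
                decisions[(i, j)] = False
                continue
            n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
            q = _q_critical(round(1.0 - alpha_r, 12), span, df_within)
            critical_range = q * math.sqrt(ms_within / n_h)
            significant = bool(means[j] - means[i] > critical_range)
            decisions[(i, j)] = significant
            if not significant:
                nonsig_spans.append((i, j))
    return decisions


def duncan_posthoc(
    groups: list[GroupData],
    alpha: float = DEFAULT_ALPHA,
    exact_p: bool = False,
) -> PosthocResult:
    """Duncan's multiple range test over all group pairs.

    ``significant`` reflects the decision at ``alpha``; ``star_level`` is
    the number of stars earned by re-running the procedure at 0.05, 0.01
    and 0.001.  With ``exact_p`` a per-pair p-value is found by bisection
    over alpha (the smallest alpha at which the pair turns significant) —
    Duncan's procedure natively yields decisions, not p-values.
    """
    if len(groups) < 2:
        raise ValueError("post hoc comparison requires at least two groups")
    anova = one_way_anova(groups)
    order = np.argsort([g.mean for g in groups], kind="stable")
    sorted_groups = [groups[i] for i in order]
    means = np.array([g.mean for g in sorted_groups])
    ns = np.array([g.n for g in sorted_groups], dtype=float)
    if len(set(g.n for g in groups)) > 1:
        logger.info(
            "unequal group sizes %s: harmonic-mean n used per pair",
            [g.n for g in groups],
        )

    per_alpha = {
        a: _duncan_decisions(means, ns, anova.ms_within, anova.df_within, a)
        for a in sorted(set(STAR_ALPHAS) | {alpha}, reverse=True)
    }

    pairs = []
    for i in range(len(sorted_groups)):
        for j in range(i + 1, len(sorted_groups)):
            star = 0
            for level, a in enumerate(STAR_ALPHAS, start=1):
                if per_alpha[a][(i, j)]:
                    star = level
                else:
                    break
            p_value = None
            if exact_p:
                p_value = _duncan_pair_p(
                    means, ns, anova.ms_within, anova.df_within, (i, j)
                )
            pairs.append(
                PairComparison(
                    group_a=sorted_groups[i].group_name,
                    group_b=sorted_groups[j].group_name,
                    mean_diff=float(means[j] - means[i]),
                    significant=per_alpha[alpha][(i, j)],
                    star_level=star,
                    p_value=p_value,
                )
            )
    return PosthocResult(pairs=pairs, alpha=alpha)


def _duncan_pair_p(
    means: np.ndarray,
    ns: np.ndarray,
    ms_within: float,
    df_within: int,
    key: tuple[int, int],
    tol: float = 1e-4,
) -> float:
    """Smallest alpha at which the pair is significant, by bisection.

    The decision is monotone in alpha (critical ranges shrink and blocking
    spans unblock as alpha grows), so bisection is valid.
    """

    def significant_at(a: float) -> bool:
        return _duncan_decisions(means, ns, ms_within, df_within, a)[key]

    lo, hi = 1e-9, 1.0 - 1e-9
    if significant_at(lo):
        return lo
    if not significant_at(hi):
        return hi
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if significant_at(mid):
            hi = mid
        else:
            lo = mid
    return hi
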