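"""Condition summaries (mean ± SEM), two-sample t-tests and significance tiers.

Mirrors the study's reporting conventions: per-condition mean ± standard
error of the mean with the image as the sampling unit, unpaired two-sided
Student's t-tests (pooled variance by default, Welch available), and
per-figure significance-star maps (the published figures use different
cutoff-to-star conventions, so the maps are named, not global).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist


class StatsError(ValueError):
    """Invalid statistical input."""


@dataclass(frozen=True)
class ConditionSummary:
    """Mean ± SEM for one condition; SEM is NaN for n = 1."""

    condition: str
    n: int
    mean: float
    sem: float

    def __str__(self) -> str:
        return f"{self.condition}: {self.mean:.2f} ± {self.sem:.2f} (n={self.n})"


@dataclass(frozen=True)
class TestResult:
    """Two-sample t-test outcome with its significance tier."""

    condition_a: str
    condition_b: str
    t: float
    df: float
    p: float
    tier_label: str = ""


#: Ordered (cutoff, symbol) maps as printed in the study's figure captions.
TIER_MAPS = {
    "fig3": ((0.05, "*"), (0.01, "**"), (0.001, "***"), (0.0001, "****")),
    "fig3d": ((0.05, "*"), (0.01, "**"), (0.001, "***")),
    "fig4": ((0.0001, "*"), (0.00001, "**")),
    "fig5": ((0.05, "*"),),
    "fig5d": ((0.01, "**"), (0.001, "***")),
}


def summarize(values, condition: str = "") -> ConditionSummary:
    """Mean and SEM (sample standard deviation / sqrt(n))."""
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise StatsError("need at least one finite value")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 \
        else float("nan")
    return ConditionSummary(condition=condition, n=int(vals.size),
                            mean=mean, sem=sem)


def t_test(a, b, variant: str = "pooled",
           label_a: str = "a", label_b: str = "b") -> TestResult:
    """Unpaired two-sided t-test between two samples.

    ``variant="pooled"`` is the classical Student's test with pooled
    variance; ``variant="welch"`` uses the Welch–Satterthwaite correction.
    Two zero-variance groups with equal means give t = 0, p = 1.
    """
    if variant not in ("pooled", "welch"):
        raise StatsError(f"unknown t-test variant {variant!r}")
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs n >= 2")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if variant == "pooled":
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        denom = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        denom = math.sqrt(va / na + vb / nb)
        if denom > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            df = float(na + nb - 2)

    if denom == 0.0:
        tstat = 0.0 if ma == mb else math.copysign(math.inf, ma - mb)
        p = 1.0 if ma == mb else 0.0
    else:
        tstat = (ma - mb) / denom
        p = float(2.0 * t_dist.sf(abs(tstat), df))
    return TestResult(condition_a=label_a, condition_b=label_b,
                      t=float(tstat), df=float(df), p=p)


def tier(p: float, tier_map) -> str:
    """Significance symbol for p under an ordered cutoff map.

    ``tier_map`` is a sequence of (cutoff, symbol) pairs with strictly
    decreasing cutoffs, or the name of a built-in figure map. Returns the
    symbol of the most stringent cutoff satisfied, or "n.s." if none is.
    """
    if isinstance(tier_map, str):
        try:
            tier_map = TIER_MAPS[tier_map]
        except KeyError:
            raise StatsError(f"unknown tier map {tier_map!r}") from None
    cutoffs = [c for c, _ in tier_map]
    if any(c2 >= c1 for c1, c2 in zip(cutoffs, cutoffs[1:])):
        raise StatsError("tier map cutoffs must be strictly decreasing")
    if not 0.0 <= p <= 1.0:
        raise StatsError(f"p must be a probability, got {p}")
    label = "n.s."
    for cutoff, symbol in tier_map:
        if p < cutoff:
            label = symbol
    return label


def compare_conditions(frame: pd.DataFrame, metric: str, pairs,
                       tier_map="fig3", variant: str = "pooled") -> pd.DataFrame:
    """Summaries and pairwise t-tests from a tidy QuantRecord frame.

    ``frame`` must have columns condition/metric/value; ``pairs`` is an
    iterable of (condition_a, condition_b) tuples. Returns one row per pair
    with group means ± SEM, t, df, p and the tier symbol.
    """
    sub = frame[frame["metric"] == metric]
    groups = {c: g["value"].to_numpy() for c, g in sub.groupby("condition")}
    rows = []
    for ca, cb in pairs:
        for c in (ca, cb):
            if c not in groups:
                raise StatsError(f"condition {c!r} absent for metric {metric!r}")
        res = t_test(groups[ca], groups[cb], variant=variant,
                     label_a=ca, label_b=cb)
        sa, sb = summarize(groups[ca], ca), summarize(groups[cb], cb)
        rows.append({"metric": metric, "condition_a": ca, "condition_b": cb,
                     "n_a": sa.n, "mean_a": sa.mean, "sem_a": sa.sem,
                     "n_b": sb.n, "mean_b": sb.mean, "sem_b": sb.sem,
                     "t": res.t, "df": res.df, "p": res.p,
                     "tier": tier(res.p, tier_map)})
    return pd.DataFrame(rows)
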