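"""Group-level per-tract inference against a binomial false-positive null.

If single-subject calls were pure chance, the number of patients flagged
on a given tract and metric would follow X ~ Binomial(m, p0), where m is
the number of patients in whom the tract was evaluable and p0 the
per-subject significance threshold (.025).  The group p-value for an
observed count k is the upper tail P(X >= k), either in closed form or
as a Monte-Carlo estimate over a dense simulated null (default 100,000
draws).  Tracts whose group p falls below alpha_group (default .01) are
reported as preferentially affected across the group.

Two conventions are configurable for fidelity to alternative readings:
``exceedance`` (">=" default; ">" strict) and ``null_trials``
("patients" default, the count the observed statistic actually has
support over; "tracts" sets the number of binomial trials to the number
of evaluable tracts instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import SubjectReport
from .normative import NotEvaluable
from .registry import TractRegistry

__all__ = [
    "DEFAULT_ALPHA_GROUP",
    "DEFAULT_P0",
    "DEFAULT_ITERATIONS",
    "NullDistribution",
    "GroupResult",
    "exact_binomial_tail",
    "mc_null",
    "group_tract_test",
    "group_summary",
    "render_group_table",
]

DEFAULT_ALPHA_GROUP = 0.01
DEFAULT_P0 = 0.025
DEFAULT_ITERATIONS = 100_000


def exact_binomial_tail(k: int, m: int, p0: float = DEFAULT_P0) -> float:
    """Upper tail P(X >= k) for X ~ Binomial(m, p0)."""
    if not 0 <= k <= m:
        raise ValueError(f"need 0 <= k <= m, got k={k}, m={m}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, m, p0))


@dataclass
class NullDistribution:
    """Simulated false-positive-count null: iid Binomial(m, p0) draws."""

    draws: np.ndarray
    trials: int
    p0: float
    iterations: int
    seed: int

    def tail_p(self, k: int, exceedance: Literal[">=", ">"] = ">=") -> float:
        """Monte-Carlo tail probability, floored at 1/iterations."""
        if exceedance == ">=":
            count = int(np.count_nonzero(self.draws >= k))
        elif exceedance == ">":
            count = int(np.count_nonzero(self.draws > k))
        else:
            raise ValueError(f"exceedance must be '>=' or '>', got {exceedance!r}")
        return max(count, 1) / self.iterations


def mc_null(m: int, p0: float = DEFAULT_P0,
            iterations: int = DEFAULT_ITERATIONS, *, seed: int) -> NullDistribution:
    """Draw the Monte-Carlo binomial null; reproducible given ``seed``."""
    if m < 0:
        raise ValueError("m must be >= 0")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(m, p0, size=iterations)
    return NullDistribution(draws=draws, trials=m, p0=p0,
                            iterations=iterations, seed=seed)


@dataclass(frozen=True)
class GroupResult:
    tract: str
    metric: str
    m: int            # patients with the tract evaluable
    k_observed: int   # of those, patients individually significant
    p_group: float
    significant: bool


def _observed_counts(reports: Sequence[SubjectReport], tract: str,
                     metric: str) -> tuple[int, int]:
    m = 0
    k = 0
    for report in reports:
        flag = report.is_significant(tract, metric)
        if flag is None:
            continue
        m += 1
        if flag:
            k += 1
    return m, k


def _n_distinct_tracts(reports: Sequence[SubjectReport]) -> int:
    tracts: set[str] = set()
    for r in reports:
        tracts.update(r.evaluable_tracts)
    return len(tracts)


def group_tract_test(reports: Sequence[SubjectReport], tract: str, metric: str,
                     alpha_group: float = DEFAULT_ALPHA_GROUP,
                     mode: Literal["exact", "monte_carlo"] = "exact",
                     iterations: int = DEFAULT_ITERATIONS,
                     seed: int | None = None,
                     p0: float = DEFAULT_P0,
                     exceedance: Literal[">=", ">"] = ">=",
                     null_trials: Literal["patients", "tracts"] = "patients",
                     ) -> GroupResult:
    """Test one (tract, metric) count of significant patients against the null.

    ``mode="exact"`` uses the closed-form binomial tail; ``monte_carlo``
    compares the observed count to ``iterations`` simulated
    false-positive counts (seed required) and floors p at 1/iterations.
    """
    m, k = _observed_counts(reports, tract, metric)
    if m == 0:
        raise NotEvaluable(f"{tract} / {metric.upper()}: evaluable in no report")

    trials = m if null_trials == "patients" else _n_distinct_tracts(reports)
    if null_trials not in ("patients", "tracts"):
        raise ValueError(f"unknown null_trials {null_trials!r}")

    if mode == "exact":
        if exceedance == ">=":
            p_group = exact_binomial_tail(k, trials, p0) if k <= trials else 0.0
        else:
            p_group = (exact_binomial_tail(k + 1, trials, p0)
                       if k + 1 <= trials else 0.0)
    elif mode == "monte_carlo":
        if seed is None:
            raise ValueError("monte_carlo mode requires a seed")
        null = mc_null(trials, p0, iterations, seed=seed)
        p_group = null.tail_p(k, exceedance)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return GroupResult(tract=tract, metric=metric, m=m, k_observed=k,
                       p_group=p_group, significant=p_group < alpha_group)


def group_summary(reports: Sequence[SubjectReport], registry: TractRegistry,
                  metric: str, alpha_group: float = DEFAULT_ALPHA_GROUP,
                  **kwargs) -> pd.DataFrame:
    """One :class:`GroupResult` per evaluable tract, ascending ``p_group``.

    Extra keyword arguments are forwarded to :func:`group_tract_test`
    (mode, iterations, seed, p0, exceedance, null_trials).  Monte-Carlo
    seeds are derived per tract from the supplied seed so tract tests
    are independent yet reproducible.
    """
    if not reports:
        raise ValueError("no subject reports supplied")
    base_seed = kwargs.pop("seed", None)
    rows = []
    for i, tract in enumerate(registry.names):
        kw = dict(kwargs)
        if base_seed is not None:
            kw["seed"] = int(np.random.SeedSequence([base_seed, i]).generate_state(1)[0] % (2**31))
        try:
            res = group_tract_test(reports, tract, metric,
                                   alpha_group=alpha_group, **kw)
        except NotEvaluable:
            continue
        rows.append(res)
    df = pd.DataFrame(
        [(r.tract, r.metric, r.m, r.k_observed, r.p_group, r.significant)
         for r in rows],
        columns=["tract", "metric", "m", "k_observed", "p_group", "significant"],
    )
    return df.sort_values(["p_group", "tract"], kind="mergesort",
                          ignore_index=True)


def render_group_table(df: pd.DataFrame, title: str = "Affected tracts",
                       alpha_group: float = DEFAULT_ALPHA_GROUP) -> str:
    """Text rendering of the significant subset: tract name and group p."""
    lines = [title, f"(group-level alpha = {alpha_group}, p_FWER column)"]
    sig = df[df["significant"]]
    if sig.empty:
        lines.append("  none")
    for _, row in sig.iterrows():
        p = row["p_group"]
        p_txt = "<.0001" if p < 1e-4 else f"{p:.4f}".lstrip("0")
        lines.append(f"  {row['tract']} [{row['metric'].upper()}]  {p_txt}")
    return "\n".join(lines) + "\n"
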