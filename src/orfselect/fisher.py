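"""Fisher's exact test on the substitution contingency table.

A selection estimate is turned into a 2x2 table of substituted versus
non-substituted positions,

    nonsynonymous |  n_NS  |  N_NS - n_NS
    synonymous    |  n_S   |  N_S  - n_S

with every entry rounded to the nearest integer (half away from zero) so
the table is integral.  Under the null hypothesis that the ORF does not
encode a real protein, the synonymous/nonsynonymous site labels are
arbitrary and the two rows should show the same substitution fraction; the
two-sided Fisher exact p-value quantifies the departure.  A small p-value
confirms the ORF pair (the two position types genuinely behave
differently); a large one marks the prediction dubious.

The test is computed from scratch: with all margins fixed, the point
probability of each admissible table is hypergeometric, evaluated in
log-space, and the two-sided p-value sums the probabilities of all tables
whose point probability does not exceed the observed one (ties resolved
with a 1e-7 relative tolerance, since exact floating-point equality of
point probabilities is ill-defined).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .selection import SelectionEstimate

__all__ = [
    "ContingencyTable",
    "TestResult",
    "round_half_away",
    "build_table",
    "fisher_exact",
    "adjust_alpha",
    "classify_batch",
    "ALPHA_POLICIES",
]

logger = logging.getLogger(__name__)

#: relative tolerance for "as or more extreme" point-probability ties
TIE_RTOL = 1e-7

ALPHA_POLICIES = ("one-fp", "bonferroni", "none")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1, 10.5 -> 11)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ContingencyTable:
    """Integer 2x2 table of substituted / non-substituted positions.

    Row 1 is nonsynonymous, row 2 synonymous; column 1 substituted.
    """

    ns_sub: int
    ns_unsub: int
    s_sub: int
    s_unsub: int

    def __post_init__(self) -> None:
        for cell in (self.ns_sub, self.ns_unsub, self.s_sub, self.s_unsub):
            if cell < 0:
                raise ValueError(f"negative cell in contingency table: {self}")

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.ns_sub + self.ns_unsub, self.s_sub + self.s_unsub)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.ns_sub + self.s_sub, self.ns_unsub + self.s_unsub)

    @property
    def total_substitutions(self) -> int:
        return self.ns_sub + self.s_sub

    def as_array(self) -> np.ndarray:
        return np.array([[self.ns_sub, self.ns_unsub], [self.s_sub, self.s_unsub]])


def build_table(est: SelectionEstimate) -> ContingencyTable:
    """Round a selection estimate into the 2x2 substitution table.

    Substituted cells are the products ``d_N * N_NS`` and ``d_S * N_S``
    rounded to the nearest integers; margins are the rounded site counts
    and the unsubstituted cells the differences.  Because cells and margins
    round independently, a substituted cell can exceed its margin by one in
    pathological cases; it is then clamped with a warning.
    """
    if est.sites.n_ns <= 0 or est.sites.n_s <= 0:
        raise ValueError("site counts must be positive to build a table")
    n_ns_total = round_half_away(est.sites.n_ns)
    n_s_total = round_half_away(est.sites.n_s)
    ns_sub = round_half_away(est.d_n * est.sites.n_ns)
    s_sub = round_half_away(est.d_s * est.sites.n_s)
    if ns_sub > n_ns_total:
        logger.warning(
            "rounded nonsynonymous substitutions (%d) exceed rounded sites (%d); clamping",
            ns_sub,
            n_ns_total,
        )
        ns_sub = n_ns_total
    if s_sub > n_s_total:
        logger.warning(
            "rounded synonymous substitutions (%d) exceed rounded sites (%d); clamping",
            s_sub,
            n_s_total,
        )
        s_sub = n_s_total
    return ContingencyTable(
        ns_sub=ns_sub,
        ns_unsub=n_ns_total - ns_sub,
        s_sub=s_sub,
        s_unsub=n_s_total - s_sub,
    )


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table.

    Sums, over all tables with the observed margins, the hypergeometric
    point probabilities that are <= the observed table's (within
    ``TIE_RTOL`` relative).  A zero row or column margin carries no
    information and gives p = 1 by convention.
    """
    r1, r2 = table.row_margins
    c1, c2 = table.col_margins
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    x = np.arange(lo, hi + 1)
    # log P(X = x) for X ~ Hypergeom(n, r1, c1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(x + 1)
        - gammaln(r1 - x + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - x + 1)
        - gammaln(r2 - (c1 - x) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    log_obs = logpmf[table.ns_sub - lo]
    # p_x <= p_obs * (1 + rtol), in log space
    mask = logpmf <= log_obs + math.log1p(TIE_RTOL)
    p = float(np.exp(logpmf[mask]).sum())
    return min(p, 1.0)


def adjust_alpha(m_tests: int, alpha_nominal: float, policy: str = "one-fp") -> float:
    """Multiple-testing adjustment of the significance threshold.

    ``"one-fp"`` (default) sets the threshold at which the expected number
    of false positives over the batch is at most one under the global
    null: ``min(alpha, 1/m)``.  ``"bonferroni"`` gives ``alpha/m``;
    ``"none"`` leaves ``alpha`` unchanged.
    """
    if m_tests < 1:
        raise ValueError(f"m_tests must be >= 1, got {m_tests}")
    if not 0 < alpha_nominal <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha_nominal}")
    if policy == "one-fp":
        return min(alpha_nominal, 1.0 / m_tests)
    if policy == "bonferroni":
        return alpha_nominal / m_tests
    if policy == "none":
        return alpha_nominal
    raise ValueError(f"unknown alpha policy {policy!r}; choose from {ALPHA_POLICIES}")


@dataclass(frozen=True)
class TestResult:
    """Outcome of the exact test for one ORF pair."""

    p_value: float
    alpha_nominal: float
    alpha_adjusted: float
    m_tests: int
    verdict: str  # "confirmed" | "dubious" | "insufficient"
    omega: float | None
    table: ContingencyTable | None = None
    error: str | None = None


def _test_one(
    est: SelectionEstimate, alpha_nominal: float, alpha_adjusted: float, m: int
) -> TestResult:
    table = build_table(est)
    p = fisher_exact(table)
    if table.total_substitutions == 0:
        verdict = "insufficient"
    elif p <= alpha_adjusted:
        verdict = "confirmed"
    else:
        verdict = "dubious"
    return TestResult(
        p_value=p,
        alpha_nominal=alpha_nominal,
        alpha_adjusted=alpha_adjusted,
        m_tests=m,
        verdict=verdict,
        omega=est.omega,
        table=table,
    )


def classify_batch(
    estimates: Sequence[SelectionEstimate],
    alpha_nominal: float = 0.05,
    policy: str = "one-fp",
) -> list[TestResult]:
    """Test a batch of estimates against a threshold adjusted for its size.

    ``m_tests`` is the batch length.  Pairs without any substitution are
    verdict ``"insufficient"`` — the exact test automatically filters out
    alignments too similar or too short to be informative.  A failure on
    one item is recorded in its result, not raised.
    """
    if not estimates:
        raise ValueError("empty batch")
    m = len(estimates)
    alpha_adj = adjust_alpha(m, alpha_nominal, policy)
    results = []
    for est in estimates:
        try:
            results.append(_test_one(est, alpha_nominal, alpha_adj, m))
        except Exception as exc:  # per-item failure must not kill the batch
            logger.warning("test failed for one pair: %s", exc)
            results.append(
                TestResult(
                    p_value=float("nan"),
                    alpha_nominal=alpha_nominal,
                    alpha_adjusted=alpha_adj,
                    m_tests=m,
                    verdict="insufficient",
                    omega=est.omega,
                    error=str(exc),
                )
            )
    return results
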