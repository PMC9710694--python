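"""Model/results interface for one pair of homologous coding sequences.

:class:`PairwiseSelection` bundles the whole per-pair procedure — protein
alignment, codon back-translation, site and substitution counting, rate
estimation, contingency table and exact test — behind a familiar
model-object surface::

    model = PairwiseSelection(orf_a, orf_b)
    res = model.fit(alpha=0.05)
    print(res.summary())

``fit`` returns a :class:`PairwiseSelectionResults` carrying the
estimates, the table, the p-value and the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

from . import fisher as _fisher
from .codon_alignment import (
    CodonAlignment,
    OrfRecord,
    ProteinAlignment,
    align_pair,
    back_translate,
    orf_from_nt,
    passes_quality,
)
from .genetic_code import GeneticCode, universal_code
from .selection import SelectionEstimate, estimate

__all__ = ["PairwiseSelection", "PairwiseSelectionResults"]


class PairwiseSelection:
    """Selection-pressure test for a pair of homologous CDSs."""

    def __init__(
        self, orf_a: OrfRecord, orf_b: OrfRecord, code: GeneticCode | None = None
    ):
        self.orf_a = orf_a
        self.orf_b = orf_b
        self.code = code or universal_code()

    @classmethod
    def from_sequences(
        cls, nt_a: str, nt_b: str, code: GeneticCode | None = None
    ) -> "PairwiseSelection":
        code = code or universal_code()
        return cls(orf_from_nt("a", nt_a, code), orf_from_nt("b", nt_b, code), code)

    @cached_property
    def protein_alignment(self) -> ProteinAlignment:
        return align_pair(self.orf_a, self.orf_b)

    @cached_property
    def codon_alignment(self) -> CodonAlignment:
        return back_translate(self.protein_alignment, self.orf_a, self.orf_b)

    def fit(
        self,
        alpha: float = 0.05,
        m_tests: int = 1,
        alpha_policy: str = "one-fp",
    ) -> "PairwiseSelectionResults":
        """Estimate d_N, d_S, omega and run the exact test.

        ``m_tests`` is the size of the batch this pair belongs to, used to
        adjust the significance threshold.
        """
        est = estimate(self.codon_alignment, self.code)
        alpha_adj = _fisher.adjust_alpha(m_tests, alpha, alpha_policy)
        table = _fisher.build_table(est)
        p = _fisher.fisher_exact(table)
        if table.total_substitutions == 0:
            verdict = "insufficient"
        elif p <= alpha_adj:
            verdict = "confirmed"
        else:
            verdict = "dubious"
        return PairwiseSelectionResults(
            model=self,
            estimate=est,
            table=table,
            p_value=p,
            alpha_nominal=alpha,
            alpha_adjusted=alpha_adj,
            m_tests=m_tests,
            verdict=verdict,
        )


@dataclass(frozen=True)
class PairwiseSelectionResults:
    """Fitted per-pair results: rates, table, p-value and verdict."""

    model: PairwiseSelection
    estimate: SelectionEstimate
    table: _fisher.ContingencyTable
    p_value: float
    alpha_nominal: float
    alpha_adjusted: float
    m_tests: int
    verdict: str

    @property
    def d_n(self) -> float:
        return self.estimate.d_n

    @property
    def d_s(self) -> float:
        return self.estimate.d_s

    @property
    def omega(self) -> float | None:
        return self.estimate.omega

    @property
    def identity(self) -> float:
        return self.model.protein_alignment.identity

    def quality(self, min_identity: float = 0.70, max_ds: float = 1.0):
        return passes_quality(self.identity, self.d_s, min_identity, max_ds)

    def summary(self) -> str:
        """Human-readable summary table of the fitted pair."""
        t = self.table
        omega = "undefined" if self.omega is None else f"{self.omega:.4f}"
        lines = [
            "Pairwise selection-pressure test",
            "=" * 48,
            f"pair:            {self.model.orf_a.id}  vs  {self.model.orf_b.id}",
            f"codons compared: {self.model.codon_alignment.n_codons}",
            f"identity:        {self.identity:.3f}",
            f"sites      N_S = {self.estimate.sites.n_s:10.2f}   N_NS = {self.estimate.sites.n_ns:10.2f}",
            f"subst.     n_S = {self.estimate.subs.n_s:10.2f}   n_NS = {self.estimate.subs.n_ns:10.2f}",
            f"rates      d_S = {self.d_s:10.4f}   d_N  = {self.d_n:10.4f}",
            f"omega (dN/dS):   {omega}",
            "-" * 48,
            "contingency table (substituted / non-substituted)",
            f"  nonsynonymous  {t.ns_sub:6d}  {t.ns_unsub:6d}",
            f"  synonymous     {t.s_sub:6d}  {t.s_unsub:6d}",
            f"Fisher exact p:  {self.p_value:.4g}",
            f"alpha (adjusted for m={self.m_tests}): {self.alpha_adjusted:.4g}",
            f"verdict:         {self.verdict}",
        ]
        return "\n".join(lines)
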