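"""Estimation of the selection pressure omega = d_N/d_S from a codon alignment.

Sites are counted per sequence with :mod:`orfselect.genetic_code` and
averaged over the two sequences (``N_S``, ``N_NS``).  Observed differences
between paired codons are resolved into single-nucleotide steps: for a
codon pair differing at ``k`` positions all ``k!`` orderings of the steps
are enumerated, orderings passing through a stop codon are discarded, and
the synonymous/nonsynonymous tallies are averaged over the surviving
orderings — the classical pathway-averaging rule.  This yields fractional
substitution counts ``n_S`` and ``n_NS``, from which

    d_N = n_NS / N_NS        d_S = n_S / N_S        omega = d_N / d_S

as uncorrected proportions.  No multiple-hit correction is applied: the
method is meant for high-identity pairs (identity > 70 %, d_S < 1) where
multiple substitutions at one site are improbable, and the downstream
contingency-table test needs raw counts, not corrected distances.

Estimates can also be imported from CODEML pairwise-mode output
(``runmode = -2``); those carry ``source="codeml"`` and use CODEML's own
ML site counts and rates.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable

from .codon_alignment import CodonAlignment
from .genetic_code import (
    GeneticCode,
    SiteCounts,
    count_sites,
    universal_code,
)

__all__ = [
    "SubstitutionCounts",
    "SelectionEstimate",
    "classify_codon_pair",
    "count_substitutions",
    "estimate",
    "parse_codeml_pairwise",
    "CodemlParseError",
    "SiteCounts",
]


@dataclass(frozen=True)
class SubstitutionCounts:
    """Fractional counts of synonymous (``n_S``) and nonsynonymous (``n_NS``)
    substitutions observed over a codon alignment."""

    n_s: float = 0.0
    n_ns: float = 0.0

    def __add__(self, other: "SubstitutionCounts") -> "SubstitutionCounts":
        return SubstitutionCounts(self.n_s + other.n_s, self.n_ns + other.n_ns)

    @property
    def total(self) -> float:
        return self.n_s + self.n_ns


@dataclass(frozen=True)
class SelectionEstimate:
    """d_N, d_S and omega for one pair, with counting provenance.

    ``omega`` is ``None`` (explicitly undefined) when ``d_S = 0``.
    ``source`` is ``"internal"`` for pathway counting on a codon alignment,
    ``"codeml"`` for values parsed from CODEML pairwise output.
    """

    d_n: float
    d_s: float
    sites: SiteCounts
    subs: SubstitutionCounts
    source: str = "internal"

    @property
    def omega(self) -> float | None:
        if self.d_s == 0.0:
            return None
        return self.d_n / self.d_s


_pair_cache: dict[tuple[str, str, str], tuple[float, float]] = {}


def classify_codon_pair(
    codon_a: str, codon_b: str, code: GeneticCode | None = None
) -> tuple[float, float]:
    """Resolve the differences between two sense codons into (n_S, n_NS).

    All orderings of the single-nucleotide steps from ``codon_a`` to
    ``codon_b`` are enumerated; orderings whose intermediate codons are
    stops are discarded and the per-ordering tallies averaged.  If every
    ordering is blocked by stops, each differing position is classified
    independently against its direct single-position mutant (stop mutants
    count as nonsynonymous), so the pair still contributes.
    """
    code = code or universal_code()
    key = (code.id, codon_a, codon_b)
    cached = _pair_cache.get(key)
    if cached is not None:
        return cached

    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        result = (0.0, 0.0)
        _pair_cache[key] = result
        return result

    tallies: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        current = codon_a
        n_s = n_ns = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.aa(nxt) == code.aa(current):
                n_s += 1
            else:
                n_ns += 1
            current = nxt
        if ok:
            tallies.append((n_s, n_ns))

    if tallies:
        result = (
            sum(t[0] for t in tallies) / len(tallies),
            sum(t[1] for t in tallies) / len(tallies),
        )
    else:
        # all pathways stop-blocked: classify each difference directly
        n_s = n_ns = 0
        for pos in diffs:
            mutant = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1 :]
            if not code.is_stop(mutant) and code.aa(mutant) == code.aa(codon_a):
                n_s += 1
            else:
                n_ns += 1
        result = (float(n_s), float(n_ns))
    _pair_cache[key] = result
    return result


def count_substitutions(
    ca: CodonAlignment, code: GeneticCode | None = None
) -> tuple[SiteCounts, SubstitutionCounts]:
    """Count sites and substitutions over a codon alignment.

    Site counts are the average of the two sequences' own counts;
    substitutions come from pathway-averaged classification of every
    differing codon pair.
    """
    code = code or universal_code()
    if ca.n_codons == 0:
        raise ValueError("no codons to count")
    codons_a = [a for a, _ in ca.columns]
    codons_b = [b for _, b in ca.columns]
    sa = count_sites(codons_a, code)
    sb = count_sites(codons_b, code)
    sites = SiteCounts((sa.n_s + sb.n_s) / 2.0, (sa.n_ns + sb.n_ns) / 2.0)
    n_s = n_ns = 0.0
    for a, b in ca.columns:
        if a != b:
            s, ns = classify_codon_pair(a, b, code)
            n_s += s
            n_ns += ns
    return sites, SubstitutionCounts(n_s=n_s, n_ns=n_ns)


def estimate(ca: CodonAlignment, code: GeneticCode | None = None) -> SelectionEstimate:
    """Estimate d_N, d_S and omega from a codon alignment by internal counting."""
    sites, subs = count_substitutions(ca, code)
    if sites.n_s <= 0.0 or sites.n_ns <= 0.0:
        raise ValueError(
            f"degenerate site counts (N_S={sites.n_s:g}, N_NS={sites.n_ns:g})"
        )
    return SelectionEstimate(
        d_n=subs.n_ns / sites.n_ns,
        d_s=subs.n_s / sites.n_s,
        sites=sites,
        subs=subs,
        source="internal",
    )


class CodemlParseError(ValueError):
    """The text is not parseable CODEML pairwise output."""


_PAIR_HEADER = re.compile(
    r"^\s*\d+\s+\((?P<b>\S+)\)\s+\.\.\.\s+\d+\s+\((?P<a>\S+)\)", re.MULTILINE
)
_STATS_LINE = re.compile(
    r"t\s*=\s*(?P<t>\S+)\s+S\s*=\s*(?P<S>\S+)\s+N\s*=\s*(?P<N>\S+)"
    r"\s+dN/dS\s*=\s*(?P<w>\S+)\s+dN\s*=\s*(?P<dN>\S+)\s+dS\s*=\s*(?P<dS>\S+)"
)


def parse_codeml_pairwise(
    out_text: str,
) -> list[tuple[tuple[str, str], SelectionEstimate]]:
    """Parse CODEML pairwise-mode (runmode = -2) main output.

    For each pair block, the summary line ``t= … S= … N= … dN/dS= … dN = …
    dS = …`` is read; ``S`` and ``N`` map to ``N_S`` and ``N_NS``, and the
    substitution counts are reconstructed as ``n_S = d_S·N_S`` and
    ``n_NS = d_N·N_NS``.  Returns ``[((id_a, id_b), estimate), …]`` in file
    order with ``source="codeml"``.
    """
    headers = [(m.start(), m.group("a"), m.group("b")) for m in _PAIR_HEADER.finditer(out_text)]
    if not headers:
        raise CodemlParseError("not a pairwise CODEML output (no pair blocks found)")
    results: list[tuple[tuple[str, str], SelectionEstimate]] = []
    for idx, (start, id_a, id_b) in enumerate(headers):
        end = headers[idx + 1][0] if idx + 1 < len(headers) else len(out_text)
        block = out_text[start:end]
        m = _STATS_LINE.search(block)
        if m is None:
            raise CodemlParseError(
                f"pair block {id_a} ... {id_b}: no 't= ... dS = ...' summary line"
            )
        try:
            n_sites_s = float(m.group("S"))
            n_sites_n = float(m.group("N"))
            d_n = float(m.group("dN"))
            d_s = float(m.group("dS"))
        except ValueError as exc:
            raise CodemlParseError(
                f"pair block {id_a} ... {id_b}: malformed numeric field in "
                f"{m.group(0)!r}"
            ) from exc
        est = SelectionEstimate(
            d_n=d_n,
            d_s=d_s,
            sites=SiteCounts(n_s=n_sites_s, n_ns=n_sites_n),
            subs=SubstitutionCounts(n_s=d_s * n_sites_s, n_ns=d_n * n_sites_n),
            source="codeml",
        )
        results.append(((id_a, id_b), est))
    return results
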