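"""Per-ORF discriminators: codon adaptation index, G+C content, and
two-sample Kolmogorov–Smirnov comparisons between verdict groups.

CAI follows the conventional definition: each codon's relative
adaptiveness ``w`` is its usage frequency divided by the maximum frequency
among its synonyms, and an ORF's CAI is the geometric mean of ``w`` over
its codons, excluding the single-codon families (Met ATG, Trp TGG) whose
``w`` is 1 by construction.  Stop codons never enter usage or CAI.  The
reference usage defaults to the pooled codon counts of the input CDS set
itself; an external two-column codon/count table may be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .codon_alignment import OrfRecord
from .genetic_code import BASES, GeneticCode, universal_code

__all__ = [
    "CodonUsageTable",
    "build_usage",
    "read_usage_table",
    "cai",
    "gc_fraction",
    "PopulationComparison",
    "ks_compare",
]

#: pseudo-count assigned to sense codons never observed in the reference
#: set, so log w stays finite
PSEUDO_COUNT = 0.5


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon counts and relative adaptiveness ``w`` per sense codon."""

    counts: Mapping[str, float]
    w: Mapping[str, float]
    single_codon_families: frozenset[str]

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, float], code: GeneticCode | None = None
    ) -> "CodonUsageTable":
        code = code or universal_code()
        full = {c: float(counts.get(c, 0.0)) for c in code.sense_codons}
        full = {c: (n if n > 0 else PSEUDO_COUNT) for c, n in full.items()}
        families: dict[str, list[str]] = {}
        for codon in code.sense_codons:
            families.setdefault(code.aa(codon), []).append(codon)
        w = {}
        for aa, codons in families.items():
            peak = max(full[c] for c in codons)
            for c in codons:
                w[c] = full[c] / peak
        singles = frozenset(
            codons[0] for codons in families.values() if len(codons) == 1
        )
        return cls(counts=full, w=w, single_codon_families=singles)


def build_usage(
    orfs: Sequence[OrfRecord], code: GeneticCode | None = None
) -> CodonUsageTable:
    """Pool codon counts over a set of ORFs into a usage/adaptiveness table."""
    if not orfs:
        raise ValueError("cannot build codon usage from an empty ORF set")
    code = code or universal_code()
    counts: dict[str, float] = {}
    for orf in orfs:
        for codon in orf.codons():
            if all(b in BASES for b in codon) and code.is_sense(codon):
                counts[codon] = counts.get(codon, 0.0) + 1.0
    return CodonUsageTable.from_counts(counts, code)


def read_usage_table(
    path: str | Path, code: GeneticCode | None = None
) -> CodonUsageTable:
    """Read a plain-text usage table: one ``codon count`` pair per line,
    ``#`` comments allowed."""
    counts: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"usage table line must be 'codon count': {line!r}")
        counts[fields[0].upper().replace("U", "T")] = float(fields[1])
    if not counts:
        raise ValueError(f"no codon counts in {path}")
    return CodonUsageTable.from_counts(counts, code)


def cai(orf: OrfRecord, usage: CodonUsageTable) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Single-codon families and ambiguous codons are excluded from the mean.
    """
    log_sum = 0.0
    n = 0
    for codon in orf.codons():
        if codon in usage.single_codon_families or codon not in usage.w:
            continue
        log_sum += math.log(usage.w[codon])
        n += 1
    if n == 0:
        raise ValueError(f"{orf.id}: no codons usable for CAI")
    return math.exp(log_sum / n)


def gc_fraction(orf: OrfRecord) -> float:
    """G+C fraction of the coding sequence."""
    if not orf.nt:
        raise ValueError("empty sequence")
    return orf.gc


@dataclass(frozen=True)
class PopulationComparison:
    """Two-sample Kolmogorov–Smirnov comparison of one variable between groups."""

    variable: str
    n_x: int
    n_y: int
    statistic: float
    p_value: float


def ks_compare(
    x: Sequence[float], y: Sequence[float], variable: str = ""
) -> PopulationComparison:
    """Two-sided two-sample K–S test (exact for small samples, else asymptotic)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="auto")
    return PopulationComparison(
        variable=variable,
        n_x=len(x),
        n_y=len(y),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
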