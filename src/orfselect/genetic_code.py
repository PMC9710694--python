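"""Genetic code and synonymous/nonsynonymous site classification.

Every nucleotide position of a codon is split into a synonymous and a
nonsynonymous fraction according to the degeneracy of the genetic code:
the synonymous fraction of position *i* is the number of the three
single-nucleotide mutants at *i* that encode the same amino acid, divided
by the number of mutants that do not create a stop codon — the
Nei–Gojobori counting convention, under which nonsense changes are not
counted as mutational opportunity.  Summed over a coding sequence these
fractions give the synonymous (``N_S``) and nonsynonymous (``N_NS``) site
totals, with ``N_S + N_NS = 3 L`` for an ``L``-codon sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

from Bio.Data import CodonTable

__all__ = [
    "BASES",
    "GeneticCode",
    "CodonSiteProfile",
    "SiteCounts",
    "StopCodonError",
    "AmbiguousCodonError",
    "universal_code",
    "site_profile",
    "count_sites",
]

BASES = "ACGT"
STOP = "*"


class StopCodonError(ValueError):
    """A stop codon appeared where a sense codon is required."""


class AmbiguousCodonError(ValueError):
    """A codon contains a base outside A, C, G, T."""


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table.

    Parameters
    ----------
    table : mapping
        Uppercase DNA triplet -> single-letter amino acid, with ``"*"``
        marking stop codons.  Must contain exactly 64 entries.
    id : str
        Identifier for provenance (default ``"universal"``).
    """

    table: Mapping[str, str]
    id: str = "universal"

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must define 64 codons, got {len(self.table)}")
        object.__setattr__(self, "table", dict(self.table))

    def __hash__(self) -> int:  # frozen but holds a dict
        return hash((self.id, tuple(sorted(self.table.items()))))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GeneticCode)
            and self.id == other.id
            and self.table == other.table
        )

    # -- queries ---------------------------------------------------------

    def aa(self, codon: str) -> str:
        """Translate one codon; ambiguous codons give ``'X'``."""
        codon = codon.upper()
        try:
            return self.table[codon]
        except KeyError:
            if len(codon) != 3:
                raise ValueError(f"not a codon: {codon!r}") from None
            return "X"

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon.upper()) == STOP

    def is_sense(self, codon: str) -> bool:
        return self.table.get(codon.upper(), STOP) != STOP

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, a in self.table.items() if a == STOP))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, a in self.table.items() if a != STOP))

    def translate(self, nt: str) -> str:
        """Translate an in-frame nucleotide sequence (no stop handling)."""
        nt = nt.upper()
        if len(nt) % 3:
            raise ValueError(f"sequence length {len(nt)} not a multiple of 3")
        return "".join(self.aa(nt[i : i + 3]) for i in range(0, len(nt), 3))


@lru_cache(maxsize=None)
def universal_code() -> GeneticCode:
    """The universal (standard) genetic code, NCBI table 1."""
    ncbi = CodonTable.unambiguous_dna_by_id[1]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = STOP
    return GeneticCode(table=table, id="universal")


@dataclass(frozen=True)
class CodonSiteProfile:
    """Per-position synonymous site fractions of one sense codon."""

    codon: str
    syn_fraction_by_pos: tuple[float, float, float]

    @property
    def syn_sites(self) -> float:
        """Synonymous sites contributed by this codon (0 to 3)."""
        return sum(self.syn_fraction_by_pos)

    @property
    def nonsyn_sites(self) -> float:
        return 3.0 - self.syn_sites


@dataclass(frozen=True)
class SiteCounts:
    """Totals of synonymous (``N_S``) and nonsynonymous (``N_NS``) sites."""

    n_s: float = 0.0
    n_ns: float = 0.0

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.n_s + other.n_s, self.n_ns + other.n_ns)


def _validate_sense_codon(codon: str, code: GeneticCode) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise AmbiguousCodonError(f"ambiguous codon: {codon!r}")
    if code.is_stop(codon):
        raise StopCodonError(f"stop codon has no site profile: {codon}")
    return codon


@lru_cache(maxsize=8192)
def _site_profile_cached(codon: str, code: GeneticCode) -> CodonSiteProfile:
    aa = code.aa(codon)
    fractions = []
    for pos in range(3):
        syn = 0
        non_stop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if code.is_stop(mutant):
                # nonsense changes are not mutational opportunity
                continue
            non_stop += 1
            if code.aa(mutant) == aa:
                syn += 1
        # every sense codon has >= 1 non-stop mutant at each position
        fractions.append(syn / non_stop)
    return CodonSiteProfile(codon=codon, syn_fraction_by_pos=tuple(fractions))


def site_profile(codon: str, code: GeneticCode | None = None) -> CodonSiteProfile:
    """Classify each position of ``codon`` into synonymous/nonsynonymous fractions.

    The synonymous fraction at a position is the number of single-nucleotide
    mutants there that preserve the amino acid, divided by the number of
    mutants that do not create a stop codon.  Stop codons are rejected.
    """
    code = code or universal_code()
    return _site_profile_cached(_validate_sense_codon(codon, code), code)


def count_sites(codons: Iterable[str], code: GeneticCode | None = None) -> SiteCounts:
    """Sum synonymous/nonsynonymous sites over a list of sense codons.

    ``N_S + N_NS = 3 * len(codons)`` always holds.  An empty list gives
    ``SiteCounts(0, 0)``; a stop codon raises :class:`StopCodonError`.
    """
    code = code or universal_code()
    codons = list(codons)
    n_s = sum(site_profile(c, code).syn_sites for c in codons)
    return SiteCounts(n_s=n_s, n_ns=3.0 * len(codons) - n_s)


def codons_of(nt: str) -> list[str]:
    """Split an in-frame nucleotide sequence into codons."""
    if len(nt) % 3:
        raise ValueError(f"sequence length {len(nt)} not a multiple of 3")
    return [nt[i : i + 3] for i in range(0, len(nt), 3)]
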