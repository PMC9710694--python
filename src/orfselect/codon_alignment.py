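"""Pairwise codon-aware alignment of predicted coding sequences.

Two homologous CDSs are compared by globally aligning their translations
(BLOSUM62, affine gaps) and back-translating the protein alignment
codon-wise onto the nucleotide sequences.  Columns where either side is a
gap, or where a codon contains an ambiguous base, are dropped, leaving a
strict list of paired sense codons on which substitution counting operates.

Alignment scoring is fixed so results are reproducible: BLOSUM62, gap of
length ``k`` costs ``10 + 0.5*(k-1)``, end gaps penalised (true global
alignment).  Identity is computed over residue-pair columns only (gaps
excluded from the denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .genetic_code import BASES, GeneticCode, codons_of, universal_code

__all__ = [
    "OrfRecord",
    "ProteinAlignment",
    "CodonAlignment",
    "OrfError",
    "orf_from_nt",
    "load_orfs",
    "read_pairs_tsv",
    "make_aligner",
    "align_pair",
    "alignment_score",
    "back_translate",
    "QualityVerdict",
    "passes_quality",
    "reciprocal_best_pairs",
]

logger = logging.getLogger(__name__)

GAP_OPEN = 10.0
GAP_EXTEND = 0.5
MATRIX = "BLOSUM62"


class OrfError(ValueError):
    """A sequence cannot be interpreted as a clean ORF/CDS."""


@dataclass(frozen=True)
class OrfRecord:
    """One predicted coding sequence.

    ``nt`` is the coding nucleotide sequence with any terminal stop codon
    already stripped; it contains no internal stop.  ``aa`` is its
    translation.
    """

    id: str
    nt: str
    aa: str

    @property
    def length_aa(self) -> int:
        return len(self.aa)

    @property
    def gc(self) -> float:
        """G+C fraction of the coding sequence."""
        if not self.nt:
            return 0.0
        return sum(1 for b in self.nt if b in "GC") / len(self.nt)

    def codons(self) -> list[str]:
        return codons_of(self.nt)


def orf_from_nt(seq_id: str, nt: str, code: GeneticCode | None = None) -> OrfRecord:
    """Build an :class:`OrfRecord`, stripping a terminal stop codon.

    Raises :class:`OrfError` if the length is not a multiple of 3, the
    sequence contains an internal stop codon, or is empty after stripping.
    """
    code = code or universal_code()
    nt = nt.upper().replace("U", "T")
    if len(nt) % 3:
        raise OrfError(f"{seq_id}: length {len(nt)} not a multiple of 3")
    if len(nt) >= 3 and code.is_stop(nt[-3:]):
        nt = nt[:-3]
    if not nt:
        raise OrfError(f"{seq_id}: empty coding sequence")
    for i in range(0, len(nt), 3):
        if code.is_stop(nt[i : i + 3]):
            raise OrfError(f"{seq_id}: internal stop codon at codon {i // 3 + 1}")
    return OrfRecord(id=seq_id, nt=nt, aa=code.translate(nt))


def load_orfs(fasta_path: str | Path, code: GeneticCode | None = None) -> list[OrfRecord]:
    """Read nucleotide CDSs from a FASTA file.

    Records that are not clean ORFs (internal stop, length not divisible
    by 3) are skipped with a logged warning rather than raising, so one bad
    gene model does not abort a proteome-scale run.
    """
    code = code or universal_code()
    records: list[OrfRecord] = []
    n_seen = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_seen += 1
        try:
            records.append(orf_from_nt(rec.id, str(rec.seq), code))
        except OrfError as exc:
            logger.warning("skipping %s: %s", rec.id, exc)
    if n_seen == 0:
        raise OrfError(f"no sequences in {fasta_path}")
    return records


def read_pairs_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read an ortholog pairing file: two tab-separated ids per line, '#' comments."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"pairs file line needs two tab-separated ids: {line!r}")
        pairs.append((fields[0], fields[1]))
    return pairs


@dataclass(frozen=True)
class ProteinAlignment:
    """A global pairwise protein alignment with its score and identity."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def identity(self) -> float:
        """Fraction of identical residue pairs over non-gap columns."""
        pairs = [
            (x, y)
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        ]
        if not pairs:
            return 0.0
        return sum(x == y for x, y in pairs) / len(pairs)


def make_aligner() -> PairwiseAligner:
    """The module's fixed global protein aligner (BLOSUM62, affine gaps)."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(MATRIX)
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = None


def _aligner() -> PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = make_aligner()
    return _ALIGNER


def alignment_score(aa_a: str, aa_b: str) -> float:
    """Global alignment score of two protein sequences under the fixed scheme."""
    return float(_aligner().score(aa_a, aa_b))


def align_pair(a: OrfRecord, b: OrfRecord) -> ProteinAlignment:
    """Optimal global alignment of the two translations.

    Deterministic for fixed inputs: among co-optimal alignments the
    aligner's first traceback is taken, which is stable across runs.
    """
    if not a.aa or not b.aa:
        raise ValueError("cannot align an empty translation")
    alignments = _aligner().align(a.aa, b.aa)
    best = alignments[0]
    return ProteinAlignment(
        aligned_a=str(best[0]), aligned_b=str(best[1]), score=float(best.score)
    )


@dataclass(frozen=True)
class CodonAlignment:
    """Paired sense codons from a back-translated protein alignment."""

    columns: tuple[tuple[str, str], ...]

    @property
    def n_codons(self) -> int:
        return len(self.columns)

    def swapped(self) -> "CodonAlignment":
        return CodonAlignment(tuple((y, x) for x, y in self.columns))


def back_translate(pa: ProteinAlignment, a: OrfRecord, b: OrfRecord) -> CodonAlignment:
    """Map each aligned residue column back to its source codons.

    Columns with a gap on either side, or where either codon contains an
    ambiguous base, are excluded.
    """
    if pa.aligned_a.replace("-", "") != a.aa or pa.aligned_b.replace("-", "") != b.aa:
        raise ValueError("alignment does not match the supplied records")
    codons_a = a.codons()
    codons_b = b.codons()
    i = j = 0
    columns: list[tuple[str, str]] = []
    for x, y in zip(pa.aligned_a, pa.aligned_b):
        if x != "-" and y != "-":
            ca, cb = codons_a[i], codons_b[j]
            if all(base in BASES for base in ca + cb):
                columns.append((ca, cb))
        if x != "-":
            i += 1
        if y != "-":
            j += 1
    return CodonAlignment(tuple(columns))


@dataclass(frozen=True)
class QualityVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()


def passes_quality(
    pa: "ProteinAlignment | float",
    est: object | float | None,
    min_identity: float = 0.70,
    max_ds: float = 1.0,
) -> QualityVerdict:
    """Alignment-quality filter: identity must exceed ``min_identity`` and
    the synonymous divergence must stay below ``max_ds``.

    High identity and ``d_S < 1`` keep the probability of multiple
    substitutions per site negligible, the validity condition of the
    uncorrected rate estimates.

    ``pa`` may be a :class:`ProteinAlignment` or a bare identity fraction;
    ``est`` may be a selection estimate (its ``d_s`` is used), a bare
    ``d_S`` value, or ``None`` when no synonymous rate is available.
    """
    identity = pa.identity if isinstance(pa, ProteinAlignment) else float(pa)
    d_s = getattr(est, "d_s", est)
    reasons = []
    if identity <= min_identity:
        reasons.append(f"identity <= {min_identity:g}")
    if d_s is not None and d_s >= max_ds:
        reasons.append(f"d_S >= {max_ds:g}")
    return QualityVerdict(passed=not reasons, reasons=tuple(reasons))


def reciprocal_best_pairs(
    proteome_a: Sequence[OrfRecord], proteome_b: Sequence[OrfRecord]
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairing under the module's alignment score.

    Each record's best partner in the other set is found by exhaustive
    all-vs-all global alignment (score, ties broken by lexicographic id);
    a pair is kept only if the choice is mutual.  Output is sorted by id_a.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    scores: dict[tuple[str, str], float] = {}
    for ra in proteome_a:
        for rb in proteome_b:
            scores[(ra.id, rb.id)] = alignment_score(ra.aa, rb.aa)

    def best_partner(rec_id: str, partners: Sequence[OrfRecord], flip: bool) -> str:
        key = lambda p: (
            -(scores[(p.id, rec_id)] if flip else scores[(rec_id, p.id)]),
            p.id,
        )
        return min(partners, key=key).id

    best_a = {ra.id: best_partner(ra.id, proteome_b, flip=False) for ra in proteome_a}
    best_b = {rb.id: best_partner(rb.id, proteome_a, flip=True) for rb in proteome_b}
    pairs = [
        (id_a, id_b) for id_a, id_b in best_a.items() if best_b.get(id_b) == id_a
    ]
    return sorted(pairs)
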