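"""Simulation of homologous ORF pairs with known true selection pressure.

The generator provides the ground truth the field data cannot: pairs of
coding sequences whose true omega is set by construction, so the type-I
error and power of the contingency-table test are directly measurable.

Model
-----
An ancestral sense-codon sequence (first codon ATG, G+C near a target) is
evolved independently down two branches (star topology, matching the
pairwise comparison design).  Evolution is acceptance–rejection over
single-nucleotide proposals, uniform over positions and target bases
(equal transition/transversion rates, kappa = 1): a proposal is accepted
with probability 1 if synonymous, ``omega_true`` if nonsynonymous, and 0
if it would create a stop codon.  This is deliberately not a full codon
rate-matrix simulator — it is the minimal process for which "omega_true"
is exactly the relative fixation probability of nonsynonymous changes.

The number of proposals per branch is calibrated so the expected pairwise
synonymous divergence matches ``expected_ds``: a uniform proposal is
synonymous with probability ``N_S / (3L)`` (ancestor site counts), so
``3 L * expected_ds / 2`` proposals per branch yield about
``expected_ds * N_S`` synonymous substitutions across the pair.
Composition drift during the walk leaves a small residual bias in the
realised d_S, which is measured by the calibration tests rather than
corrected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import fisher
from .codon_alignment import OrfRecord, align_pair, back_translate, orf_from_nt
from .genetic_code import BASES, GeneticCode, count_sites, universal_code
from .selection import SelectionEstimate, estimate

__all__ = [
    "SimulationSpec",
    "simulate_ancestor",
    "evolve_pair",
    "generate_pairs",
    "write_pair_files",
    "operating_characteristics",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulation condition.

    Defaults are the neutral-null reference condition used for test
    calibration: 300-codon ORFs at the G+C level of a high-GC viral
    coding region (0.61), pairwise synonymous divergence 0.3, true
    omega 1, 500 replicate pairs.
    """

    n_codons: int = 300
    gc_target: float = 0.61
    omega_true: float = 1.0
    expected_ds: float = 0.3
    n_pairs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")
        if self.expected_ds <= 0:
            raise ValueError("expected_ds must be > 0")
        if self.omega_true < 0:
            raise ValueError("omega_true must be >= 0")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")


GC_TOLERANCE = 0.05
_MAX_ANCESTOR_TRIES = 500


def _sample_codon(rng: np.random.Generator, p: np.ndarray, code: GeneticCode) -> str:
    while True:
        idx = rng.choice(4, size=3, p=p)
        codon = "".join(BASES[i] for i in idx)
        if code.is_sense(codon):
            return codon


def simulate_ancestor(
    spec: SimulationSpec,
    rng: np.random.Generator,
    code: GeneticCode | None = None,
    orf_id: str = "anc",
) -> OrfRecord:
    """Draw a random stop-free ancestor: ATG followed by sense codons whose
    bases follow the target G+C level; resampled until the realised G+C is
    within +/-0.05 of ``gc_target`` (error if the target is infeasible)."""
    code = code or universal_code()
    gc = spec.gc_target
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A, C, G, T
    for _ in range(_MAX_ANCESTOR_TRIES):
        codons = ["ATG"] + [
            _sample_codon(rng, p, code) for _ in range(spec.n_codons - 1)
        ]
        nt = "".join(codons)
        realised = sum(1 for b in nt if b in "GC") / len(nt)
        if abs(realised - gc) <= GC_TOLERANCE:
            return OrfRecord(id=orf_id, nt=nt, aa=code.translate(nt))
    raise ValueError(
        f"gc_target={gc} infeasible within +/-{GC_TOLERANCE} for "
        f"n_codons={spec.n_codons}"
    )


def _evolve_branch(
    codons: list[str],
    n_proposals: int,
    omega_true: float,
    rng: np.random.Generator,
    code: GeneticCode,
) -> list[str]:
    codons = list(codons)
    n_nt = 3 * len(codons)
    for _ in range(n_proposals):
        pos = int(rng.integers(n_nt))
        ci, off = divmod(pos, 3)
        current = codons[ci]
        # uniform over the three non-current bases
        others = [b for b in BASES if b != current[off]]
        base = others[int(rng.integers(3))]
        mutant = current[:off] + base + current[off + 1 :]
        if code.is_stop(mutant):
            continue
        if code.aa(mutant) != code.aa(current) and rng.random() >= omega_true:
            continue
        codons[ci] = mutant
    return codons


def evolve_pair(
    ancestor: OrfRecord,
    spec: SimulationSpec,
    rng: np.random.Generator,
    code: GeneticCode | None = None,
) -> tuple[OrfRecord, OrfRecord]:
    """Evolve two independent descendants of ``ancestor``.

    Each branch receives ``round(3 L * expected_ds / 2)`` uniform
    single-nucleotide proposals filtered by the acceptance rule, targeting
    a pairwise synonymous divergence of ``expected_ds``.
    """
    code = code or universal_code()
    codons = ancestor.codons()
    n_prop = int(round(3 * len(codons) * spec.expected_ds / 2.0))
    out = []
    for tag in ("a", "b"):
        desc = _evolve_branch(codons, n_prop, spec.omega_true, rng, code)
        nt = "".join(desc)
        out.append(OrfRecord(id=f"{ancestor.id}_{tag}", nt=nt, aa=code.translate(nt)))
    return out[0], out[1]


def generate_pairs(
    spec: SimulationSpec,
    code: GeneticCode | None = None,
    id_prefix: str = "sim",
) -> list[tuple[OrfRecord, OrfRecord]]:
    """Generate ``spec.n_pairs`` independent homologous pairs (fresh ancestor
    each).  Fully reproducible from ``spec.seed``; ``id_prefix`` keeps ids
    distinct when several batches are pooled."""
    code = code or universal_code()
    rng = np.random.default_rng(spec.seed)
    pairs = []
    for k in range(spec.n_pairs):
        anc = simulate_ancestor(spec, rng, code, orf_id=f"{id_prefix}{k:04d}")
        pairs.append(evolve_pair(anc, spec, rng, code))
    return pairs


def write_pair_files(
    pairs: Sequence[tuple[OrfRecord, OrfRecord]],
    fasta_a: str | Path,
    fasta_b: str | Path,
    pairs_tsv: str | Path,
) -> None:
    """Write simulated pairs as two FASTA files plus a pairing TSV, in the
    exact formats the pipeline consumes."""
    with open(fasta_a, "w") as fa, open(fasta_b, "w") as fb, open(pairs_tsv, "w") as fp:
        fp.write("# id_a\tid_b\n")
        for a, b in pairs:
            fa.write(f">{a.id}\n{a.nt}\n")
            fb.write(f">{b.id}\n{b.nt}\n")
            fp.write(f"{a.id}\t{b.id}\n")


def estimate_pair(
    a: OrfRecord, b: OrfRecord, code: GeneticCode | None = None
) -> SelectionEstimate:
    """Align a pair end-to-end and estimate selection (internal counting)."""
    pa = align_pair(a, b)
    ca = back_translate(pa, a, b)
    return estimate(ca, code)


def operating_characteristics(
    spec_grid: Sequence[SimulationSpec],
    alpha: float = 0.05,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Measure rejection rate and estimator behaviour over a grid of conditions.

    For each condition the full pipeline — simulate, align, back-translate,
    estimate, table, exact test — runs on every replicate pair; the
    rejection rate uses the unadjusted ``alpha``.  Returns one row per
    condition with columns ``n_codons, gc_target, omega_true, expected_ds,
    n_pairs, seed, rejection_rate, mean_omega_hat, mean_dn_hat,
    mean_ds_hat, n_omega_defined``.
    """
    if not spec_grid:
        raise ValueError("empty simulation grid")
    code = code or universal_code()
    rows = []
    for spec in spec_grid:
        rejections = 0
        omegas: list[float] = []
        dns: list[float] = []
        dss: list[float] = []
        for a, b in generate_pairs(spec, code):
            est = estimate_pair(a, b, code)
            p = fisher.fisher_exact(fisher.build_table(est))
            if p <= alpha:
                rejections += 1
            dns.append(est.d_n)
            dss.append(est.d_s)
            if est.omega is not None:
                omegas.append(est.omega)
        rows.append(
            {
                "n_codons": spec.n_codons,
                "gc_target": spec.gc_target,
                "omega_true": spec.omega_true,
                "expected_ds": spec.expected_ds,
                "n_pairs": spec.n_pairs,
                "seed": spec.seed,
                "rejection_rate": rejections / spec.n_pairs,
                "mean_omega_hat": float(np.mean(omegas)) if omegas else float("nan"),
                "mean_dn_hat": float(np.mean(dns)),
                "mean_ds_hat": float(np.mean(dss)),
                "n_omega_defined": len(omegas),
            }
        )
    return pd.DataFrame(rows)
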