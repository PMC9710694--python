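"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from orfselect.genetic_code import BASES, universal_code


@pytest.fixture(scope="session")
def code():
    return universal_code()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sense_codons(rng: np.random.Generator, n: int, code) -> list[str]:
    """Uniform random sense codons."""
    sense = code.sense_codons
    return [sense[i] for i in rng.integers(len(sense), size=n)]


def write_fasta(path, records):
    """records: iterable of (id, nt)"""
    with open(path, "w") as fh:
        for rid, nt in records:
            fh.write(f">{rid}\n{nt}\n")
    return path


def codeml_pairwise_text(pairs):
    """Render a CODEML pairwise-mode output fixture.

    ``pairs``: iterable of dicts with keys id_a, id_b, t, S, N, w, dN, dS.
    Mimics the main-output dialect: a pair header line ``2 (B) ... 1 (A)``
    followed by the one-line summary of t, S, N, dN/dS, dN and dS.
    """
    lines = [
        "CODONML (in paml version 4.9j, February 2020)",
        "Model: One dN/dS ratio for branches,",
        "",
    ]
    for k, p in enumerate(pairs):
        lines += [
            f"{2 * k + 2} ({p['id_b']}) ... {2 * k + 1} ({p['id_a']})",
            "lnL = -1234.567890",
            " 0.12345 0.54321",
            "",
            f"t={p['t']:8.4f}  S={p['S']:9.1f}  N={p['N']:9.1f}  "
            f"dN/dS={p['w']:8.4f}  dN = {p['dN']:.4f}  dS = {p['dS']:.4f}",
            "",
        ]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# independent oracles


def site_profile_oracle(codon: str, code) -> list[float]:
    """Enumerate all 9 single-nucleotide mutants and classify translations;
    stop-creating mutants are excluded from the per-position denominator."""
    aa = code.aa(codon)
    fractions = []
    for pos in range(3):
        syn = considered = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue
            considered += 1
            if code.aa(mutant) == aa:
                syn += 1
        fractions.append(syn / considered)
    return fractions


def pathway_oracle(codon_a: str, codon_b: str, code) -> tuple[float, float]:
    """Recursively enumerate all orderings of the single-nucleotide steps from
    ``codon_a`` to ``codon_b``, pruning at stop intermediates; average the
    (synonymous, nonsynonymous) tallies over surviving complete pathways."""

    def walk(cur: str):
        diffs = [i for i in range(3) if cur[i] != codon_b[i]]
        if not diffs:
            return [(0, 0)]
        paths = []
        for i in diffs:
            nxt = cur[:i] + codon_b[i] + cur[i + 1 :]
            if code.is_stop(nxt):
                continue
            step = (1, 0) if code.aa(nxt) == code.aa(cur) else (0, 1)
            for s, ns in walk(nxt):
                paths.append((step[0] + s, step[1] + ns))
        return paths

    paths = walk(codon_a)
    if paths:
        return (
            sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths),
        )
    # every ordering stop-blocked: classify each difference directly
    s = ns = 0
    for i in range(3):
        if codon_a[i] == codon_b[i]:
            continue
        mutant = codon_a[:i] + codon_b[i] + codon_a[i + 1 :]
        if not code.is_stop(mutant) and code.aa(mutant) == code.aa(codon_a):
            s += 1
        else:
            ns += 1
    return float(s), float(ns)


def gotoh_score_oracle(a: str, b: str, matrix, gap_open=10.0, gap_ext=0.5) -> float:
    """Brute-force affine-gap global alignment score (Gotoh), where a gap of
    length k costs ``gap_open + gap_ext*(k-1)``, end gaps included."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_ext * (i - 1))
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_ext * (j - 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - gap_open, X[i - 1][j] - gap_ext, Y[i - 1][j] - gap_open
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open, X[i][j - 1] - gap_open, Y[i][j - 1] - gap_ext
            )
    return max(M[n][m], X[n][m], Y[n][m])
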