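"""End-to-end orchestration: load, pair, align, filter, estimate, test,
annotate, compare, report.

Two input modes exist.  In FASTA mode two CDS files are loaded, pairs come
from a TSV pairing file or from reciprocal-best-hit matching, and rates
are estimated internally.  In CODEML mode a CODEML pairwise-output file is
post-processed; an optional FASTA supplies the per-ORF metric annotations.

Pairs failing the alignment-quality rule (identity <= 70 % or d_S >= 1 by
default) receive verdict ``"filtered"`` and are excluded from the count of
tests ``m`` used to adjust the significance threshold — the adjustment
reflects tests actually performed.  The TSV report is byte-stable: fixed
column set, fixed float formatting, rows in input order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import fisher as _fisher
from .codon_alignment import (
    OrfRecord,
    align_pair,
    back_translate,
    load_orfs,
    passes_quality,
    read_pairs_tsv,
    reciprocal_best_pairs,
)
from .genetic_code import GeneticCode, universal_code
from .metrics import (
    CodonUsageTable,
    PopulationComparison,
    build_usage,
    cai,
    ks_compare,
    read_usage_table,
)
from .selection import SelectionEstimate, estimate, parse_codeml_pairwise

__all__ = [
    "PipelineConfig",
    "TestedPair",
    "RunResult",
    "run",
    "summarize_populations",
    "REPORT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: fixed, versioned column set of the TSV report
REPORT_COLUMNS = [
    "id_a",
    "id_b",
    "source",
    "identity",
    "n_codons",
    "N_S",
    "N_NS",
    "n_S",
    "n_NS",
    "d_N",
    "d_S",
    "omega",
    "ns_sub",
    "ns_unsub",
    "s_sub",
    "s_unsub",
    "p_value",
    "alpha_adjusted",
    "verdict",
    "quality_reasons",
    "cai_a",
    "cai_b",
    "gc_a",
    "gc_b",
    "length_a",
    "length_b",
]


@dataclass(frozen=True)
class TestedPair:
    """One report row: everything measured for one ORF pair."""

    id_a: str
    id_b: str
    source: str
    identity: float | None
    n_codons: int | None
    estimate: SelectionEstimate | None
    table: _fisher.ContingencyTable | None
    p_value: float | None
    alpha_adjusted: float | None
    verdict: str  # confirmed | dubious | insufficient | filtered
    quality_reasons: tuple[str, ...] = ()
    cai_a: float | None = None
    cai_b: float | None = None
    gc_a: float | None = None
    gc_b: float | None = None
    length_a: int | None = None
    length_b: int | None = None

    @property
    def omega(self) -> float | None:
        return None if self.estimate is None else self.estimate.omega


@dataclass
class PipelineConfig:
    """Inputs and policies of one pipeline run."""

    fasta_a: str | Path | None = None
    fasta_b: str | Path | None = None
    pairs_tsv: str | Path | None = None
    codeml_out: str | Path | None = None
    metrics_fasta: tuple[str | Path, ...] = ()
    alpha: float = 0.05
    alpha_policy: str = "one-fp"
    min_identity: float = 0.70
    max_ds: float = 1.0
    usage_table: str | Path | None = None


@dataclass
class RunResult:
    """Rows, population comparisons and the run summary of one pipeline run."""

    rows: list[TestedPair]
    comparisons: list[PopulationComparison]
    notices: list[str]
    summary: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([_row_dict(r) for r in self.rows], columns=REPORT_COLUMNS)

    def write(self, out_prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.tsv`` and ``<prefix>.summary.json``; byte-stable."""
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        tsv = out_prefix.with_suffix(".tsv")
        lines = ["\t".join(REPORT_COLUMNS)]
        for r in self.rows:
            d = _row_dict(r)
            lines.append("\t".join(_fmt(d[c]) for c in REPORT_COLUMNS))
        tsv.write_text("\n".join(lines) + "\n")
        js = out_prefix.with_suffix(".summary.json")
        js.write_text(json.dumps(self.summary, indent=2, sort_keys=True) + "\n")
        return tsv, js


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _row_dict(r: TestedPair) -> dict:
    est, t = r.estimate, r.table
    return {
        "id_a": r.id_a,
        "id_b": r.id_b,
        "source": r.source,
        "identity": r.identity,
        "n_codons": r.n_codons,
        "N_S": None if est is None else est.sites.n_s,
        "N_NS": None if est is None else est.sites.n_ns,
        "n_S": None if est is None else est.subs.n_s,
        "n_NS": None if est is None else est.subs.n_ns,
        "d_N": None if est is None else est.d_n,
        "d_S": None if est is None else est.d_s,
        "omega": r.omega,
        "ns_sub": None if t is None else t.ns_sub,
        "ns_unsub": None if t is None else t.ns_unsub,
        "s_sub": None if t is None else t.s_sub,
        "s_unsub": None if t is None else t.s_unsub,
        "p_value": r.p_value,
        "alpha_adjusted": r.alpha_adjusted,
        "verdict": r.verdict,
        "quality_reasons": ";".join(r.quality_reasons) if r.quality_reasons else "",
        "cai_a": r.cai_a,
        "cai_b": r.cai_b,
        "gc_a": r.gc_a,
        "gc_b": r.gc_b,
        "length_a": r.length_a,
        "length_b": r.length_b,
    }


def _safe_cai(orf: OrfRecord | None, usage: CodonUsageTable | None) -> float | None:
    if orf is None or usage is None:
        return None
    try:
        return cai(orf, usage)
    except ValueError:
        return None


def run(config: PipelineConfig, code: GeneticCode | None = None) -> RunResult:
    """Execute the full validation pipeline under ``config``."""
    code = code or universal_code()
    fasta_mode = config.fasta_a is not None or config.fasta_b is not None
    codeml_mode = config.codeml_out is not None
    if fasta_mode and codeml_mode:
        raise ValueError("conflicting input modes: give FASTA files or CODEML output, not both")
    if not fasta_mode and not codeml_mode:
        raise ValueError("no input: give two FASTA files or a CODEML output file")

    if fasta_mode:
        if config.fasta_a is None or config.fasta_b is None:
            raise ValueError("FASTA mode needs both fasta_a and fasta_b")
        rows = _run_fasta(config, code)
    else:
        rows = _run_codeml(config, code)

    if not rows:
        raise ValueError("zero testable pairs: check inputs and pairing")

    # quality-filtered pairs are excluded from m; the rest are tested
    tested_idx = [i for i, r in enumerate(rows) if r.verdict == "pending"]
    if not tested_idx:
        raise ValueError("zero pairs pass the quality filter; nothing to test")
    m = len(tested_idx)
    results = _fisher.classify_batch(
        [rows[i].estimate for i in tested_idx], config.alpha, config.alpha_policy
    )
    for i, res in zip(tested_idx, results):
        r = rows[i]
        rows[i] = TestedPair(
            **{
                **r.__dict__,
                "p_value": res.p_value,
                "alpha_adjusted": res.alpha_adjusted,
                "verdict": res.verdict,
                "table": res.table,
            }
        )

    comparisons, notices = summarize_populations(rows)
    counts: dict[str, int] = {}
    for r in rows:
        counts[r.verdict] = counts.get(r.verdict, 0) + 1
    summary = {
        "n_pairs": len(rows),
        "m_tests": m,
        "alpha_nominal": config.alpha,
        "alpha_policy": config.alpha_policy,
        "alpha_adjusted": _fisher.adjust_alpha(m, config.alpha, config.alpha_policy),
        "verdict_counts": dict(sorted(counts.items())),
        "comparisons": [
            {
                "variable": c.variable,
                "n_confirmed": c.n_x,
                "n_dubious": c.n_y,
                "D": c.statistic,
                "p_value": c.p_value,
            }
            for c in comparisons
        ],
        "notices": notices,
    }
    logger.info(
        "tested %d pairs (m=%d): %s",
        len(rows),
        m,
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
    )
    return RunResult(rows=rows, comparisons=comparisons, notices=notices, summary=summary)


def _run_fasta(config: PipelineConfig, code: GeneticCode) -> list[TestedPair]:
    orfs_a = {o.id: o for o in load_orfs(config.fasta_a, code)}
    orfs_b = {o.id: o for o in load_orfs(config.fasta_b, code)}
    if config.pairs_tsv is not None:
        pairs = read_pairs_tsv(config.pairs_tsv)
    else:
        pairs = reciprocal_best_pairs(list(orfs_a.values()), list(orfs_b.values()))
    if config.usage_table is not None:
        usage = read_usage_table(config.usage_table, code)
    else:
        usage = build_usage(list(orfs_a.values()) + list(orfs_b.values()), code)

    rows: list[TestedPair] = []
    for id_a, id_b in pairs:
        if id_a not in orfs_a or id_b not in orfs_b:
            logger.warning("pair (%s, %s): id not found in inputs; skipped", id_a, id_b)
            continue
        a, b = orfs_a[id_a], orfs_b[id_b]
        base = dict(
            id_a=id_a,
            id_b=id_b,
            source="internal",
            cai_a=_safe_cai(a, usage),
            cai_b=_safe_cai(b, usage),
            gc_a=a.gc,
            gc_b=b.gc,
            length_a=a.length_aa,
            length_b=b.length_aa,
        )
        try:
            pa = align_pair(a, b)
            ca = back_translate(pa, a, b)
            est = estimate(ca, code)
        except ValueError as exc:
            logger.warning("pair (%s, %s): %s", id_a, id_b, exc)
            rows.append(
                TestedPair(
                    **base,
                    identity=None,
                    n_codons=None,
                    estimate=None,
                    table=None,
                    p_value=None,
                    alpha_adjusted=None,
                    verdict="filtered",
                    quality_reasons=(str(exc),),
                )
            )
            continue
        quality = passes_quality(pa, est, config.min_identity, config.max_ds)
        rows.append(
            TestedPair(
                **base,
                identity=pa.identity,
                n_codons=ca.n_codons,
                estimate=est,
                table=None,
                p_value=None,
                alpha_adjusted=None,
                verdict="pending" if quality.passed else "filtered",
                quality_reasons=quality.reasons,
            )
        )
    return rows


def _run_codeml(config: PipelineConfig, code: GeneticCode) -> list[TestedPair]:
    text = Path(config.codeml_out).read_text()
    parsed = parse_codeml_pairwise(text)
    orfs: dict[str, OrfRecord] = {}
    for fasta in config.metrics_fasta:
        for o in load_orfs(fasta, code):
            orfs[o.id] = o
    usage = build_usage(list(orfs.values()), code) if orfs else None
    rows: list[TestedPair] = []
    for (id_a, id_b), est in parsed:
        a = orfs.get(id_a)
        b = orfs.get(id_b)
        # identity is unknown in CODEML mode; only the d_S rule applies
        quality = passes_quality(1.0, est, min_identity=-1.0, max_ds=config.max_ds)
        rows.append(
            TestedPair(
                id_a=id_a,
                id_b=id_b,
                source="codeml",
                identity=None,
                n_codons=None,
                estimate=est,
                table=None,
                p_value=None,
                alpha_adjusted=None,
                verdict="pending" if quality.passed else "filtered",
                quality_reasons=quality.reasons,
                cai_a=_safe_cai(a, usage),
                cai_b=_safe_cai(b, usage),
                gc_a=None if a is None else a.gc,
                gc_b=None if b is None else b.gc,
                length_a=None if a is None else a.length_aa,
                length_b=None if b is None else b.length_aa,
            )
        )
    return rows


def _group_values(rows: Sequence[TestedPair], verdict: str, variable: str) -> list[float]:
    vals: list[float] = []
    for r in rows:
        if r.verdict != verdict:
            continue
        if variable == "omega":
            v = r.omega
        elif variable == "length":
            parts = [x for x in (r.length_a, r.length_b) if x is not None]
            v = sum(parts) / len(parts) if parts else None
        elif variable == "cai":
            parts = [x for x in (r.cai_a, r.cai_b) if x is not None]
            v = sum(parts) / len(parts) if parts else None
        elif variable == "gc":
            parts = [x for x in (r.gc_a, r.gc_b) if x is not None]
            v = sum(parts) / len(parts) if parts else None
        else:
            raise ValueError(f"unknown variable {variable!r}")
        if v is not None:
            vals.append(float(v))
    return vals


def summarize_populations(
    rows: Sequence[TestedPair],
) -> tuple[list[PopulationComparison], list[str]]:
    """K–S comparisons of omega, length, CAI and G+C between the confirmed
    and dubious groups.  Variables with fewer than two values in either
    group are skipped with a notice."""
    comparisons: list[PopulationComparison] = []
    notices: list[str] = []
    for variable in ("omega", "length", "cai", "gc"):
        x = _group_values(rows, "confirmed", variable)
        y = _group_values(rows, "dubious", variable)
        if len(x) < 2 or len(y) < 2:
            notices.append(
                f"{variable}: comparison skipped (confirmed n={len(x)}, dubious n={len(y)})"
            )
            continue
        comparisons.append(ks_compare(x, y, variable))
    return comparisons, notices
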