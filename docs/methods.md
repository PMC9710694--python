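# Methods

## The model and its assumptions

`orfselect` decides whether a predicted ORF pair evolves like a protein.
Real proteins keep their amino-acid sequence under purifying selection:
nonsynonymous codon positions accumulate substitutions more slowly than
synonymous ones, so ω = d_N/d_S < 1. If the ORF encodes nothing, the
synonymous/nonsynonymous classification of positions is biologically
meaningless and both classes substitute at the same per-site rate, ω ≈ 1.
The procedure therefore tests homogeneity of the two substitution
proportions rather than thresholding the ω point estimate, which is a
ratio of two small counts and fluctuates wildly at realistic divergences.

The whole approach presumes an alignment of impeccable quality and a
divergence small enough that multiple substitutions at one site are rare.
Both assumptions are enforced, not hoped for: pairs with protein identity
≤ 70 % or d_S ≥ 1 are excluded before testing.

## Site counting

Per-codon site fractions follow the Nei–Gojobori convention. At each of
the three positions of a sense codon, the synonymous fraction is the
number of single-nucleotide changes preserving the amino acid divided by
the number of changes that do not create a stop codon; nonsense changes
are not counted as mutational opportunity. Fractions at a position always
have a denominator ≥ 1 (no sense codon has three stop neighbours at one
position), and syn + nonsyn sites sum to exactly 3 per codon, hence
N_S + N_NS = 3L per sequence. Site totals for a pair are the average of
the two sequences' own totals.

The alternative convention — counting stop-creating changes as
nonsynonymous opportunity with a fixed denominator of 3 — was measured
and rejected: under the package's own neutral simulator (which never
fixes nonsense changes) it depresses E[ω̂] to ≈ 0.95, turning the
calibrated null into a systematically rejectable hypothesis at large L
(null rejection 0.12 instead of 0.05 at 1000 codons). With the convention
used here the neutral simulator yields mean ω̂ = 0.99 and a null
rejection rate of 0.03–0.05.

## Substitution counting

Codon pairs differing at k ∈ {1,2,3} positions are resolved by
enumerating all k! orderings of the single-nucleotide steps, discarding
orderings that pass through a stop codon, and averaging the
synonymous/nonsynonymous step tallies over the surviving orderings. In
the rare case where every ordering is stop-blocked, each differing
position is classified against its direct single-position mutant so the
pair still contributes. Counts stay fractional here; rounding happens
only when the contingency table is built.

No multiple-hit correction is applied (no Jukes–Cantor-style transform):
d_N and d_S are the raw proportions the contingency table needs, and the
quality filter restricts use to the regime where the correction would be
negligible anyway. Consequently realised d_S underestimates the true
number of accepted synonymous changes by the saturation factor — about
17 % at d_S = 0.3 — which is immaterial to the test because the same
process acts on both rows of the table.

## The exact test

The 2×2 table is [n_NS, N_NS − n_NS; n_S, N_S − n_S] with every entry
rounded half-away-from-zero to the nearest integer. Margins round
independently of cells; if a rounded substituted cell exceeds its rounded
margin (possible by one count), it is clamped with a warning. The
two-sided p-value is computed from scratch in log-space: with margins
fixed, each admissible table has a hypergeometric point probability, and
the p-value sums those ≤ the observed table's. Point-probability ties are
resolved with a relative tolerance of 1e−7, since exact floating-point
equality is ill-defined; the tolerance only matters for exactly
symmetric tables, where the tied probability is included as it should be.
A zero row or column margin means the table carries no information and
gives p = 1; in particular p = 1 whenever no substitution was observed,
and such pairs are reported as "insufficient" rather than "dubious".

Across a batch of m tested pairs the significance threshold defaults to
α_adj = min(α, 1/m): under the global null the expected number of false
positives is then at most one. This "one false positive" policy, not
Bonferroni, is the default because the quantity being controlled is an
expected count, not a family-wise rate; `bonferroni` and `none` policies
are selectable. Quality-filtered pairs do not count toward m — the
adjustment reflects tests actually performed — and m is recorded in the
run summary.

## Alignment

Translations are aligned globally (end gaps penalised) with BLOSUM62,
gap open 10, gap extension 0.5 per additional gapped residue, via
Biopython's PairwiseAligner; among co-optimal alignments the aligner's
first traceback is taken, which is deterministic for fixed inputs.
Identity is the fraction of identical residues over residue-pair columns
(gap columns excluded from the denominator). Reciprocal-best-hit pairing
ranks partners by alignment score — not identity, which is
length-confounded — with lexicographic id as the tie-break.

## CODEML import

`parse_codeml_pairwise` consumes the pairwise-mode (runmode = −2) main
output and maps S → N_S, N → N_NS, dN → d_N, dS → d_S, reconstructing
the substituted cells as the products d_S·N_S and d_N·N_NS. CODEML's ML
site counts (CodonFreq-weighted) differ numerically from Nei–Gojobori
counts for the same pair; the two routes are treated as interchangeable
inputs to the test and distinguished by the `source` field
("internal"/"codeml"), never asserted equal. CODEML itself is never
executed.

## Codon metrics

CAI uses the conventional definition: relative adaptiveness w = codon
frequency / max frequency within its synonym family; an ORF's CAI is the
geometric mean of w over its codons, excluding the single-codon families
ATG and TGG. Unseen sense codons receive a pseudo-count of 0.5 so log w
is finite. The default reference usage is pooled from the input CDS set
itself, mirroring self-referential proteome-scale practice; an external
two-column codon/count table can be supplied, and results should be read
as reference-dependent. Group contrasts (ω, length, CAI, G+C between
confirmed and dubious pairs) use the two-sample two-sided
Kolmogorov–Smirnov test (scipy; exact method for small samples,
asymptotic otherwise).

## The simulator: what it emulates and what it does not

The generator draws an ancestral sequence (first codon ATG, bases i.i.d.
at a target G+C, stop codons rejected; the realised G+C must land within
±0.05 of the target or the target is declared infeasible) and evolves two
independent descendants — a star topology matching the pairwise design.
Evolution is acceptance–rejection over single-nucleotide proposals,
uniform over positions and target bases (kappa = 1, no
transition/transversion bias): synonymous proposals are always accepted,
nonsynonymous ones with probability ω_true, stop-creating ones never. The
proposal count per branch is 3L·d_S_target/2, which makes the expected
accepted synonymous changes per synonymous site equal the target pairwise
d_S; composition drift leaves a residual calibration bias that the tests
measure (realised mean d_S within ±30 % of target) rather than correct.

Defaults state the reference condition used throughout calibration:
300 codons, G+C 0.61 (the coding regime of high-GC giant viruses),
pairwise d_S 0.3, ω_true 1, 500 replicate pairs.

This is deliberately **not** a GY94/codon-rate-matrix simulator: no
transition/transversion bias, no site-heterogeneous ω, no indels, no
codon-frequency stationary distribution. A green calibration therefore
establishes that the test is exact for the stated null — label
exchangeability of site classes — and powerful against uniform purifying
selection; it does not establish robustness to rate heterogeneity,
alignment error, or indel-rich histories. Note also that at neutral
divergence d_S ≈ 0.3 a simulated pair has ≈ 63 % protein identity and is
(correctly) rejected by the quality filter; pipeline-level demonstrations
therefore use either lower divergence or purifying regimes, which is
exactly the filter's intent.

## Numerical and degenerate-input choices

- Rounding is half-away-from-zero; all rounded quantities are ≥ 0.
- ω is carried as an explicit undefined state (`None`) when d_S = 0,
  never as ∞/NaN; undefined ω does not block testing (the table still
  exists).
- Degenerate site counts (N_S = 0 or N_NS = 0) are an error at
  estimation; inside a batch the error is recorded per-item and the
  batch continues.
- Terminal stop codons are stripped on input; internal stops and lengths
  not divisible by 3 reject the record (logged, not fatal, at FASTA
  loading; a hard error when constructing a record directly).
- Columns containing ambiguous bases are dropped at back-translation;
  ambiguous codons translate to `X` for alignment purposes only.
- Reports are byte-stable: fixed column set, `%.6g` float formatting,
  rows in input order (RBH pairs sorted lexicographically).

## Known limitations

- The uncorrected-proportion estimator saturates at high divergence;
  beyond the d_S < 1 filter it is biased toward 1 and should not be
  interpreted, only filtered.
- The 1/m adjustment controls an expected count, not the probability of
  any false positive; batches assembled differently (e.g. ORFans and
  non-ORFans pooled vs separate) give different thresholds, so the batch
  definition is caller-controlled and logged.
- CODEML-mode rows lack identity (CODEML does not report it), so only
  the d_S component of the quality rule applies there.
- The simulator's feasibility check for extreme G+C targets is empirical
  (resampling bound), not analytic.
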