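# Methods

## The FT model

A protein is a string over the 20 canonical amino-acid letters (tolerated
extra letters X, B, Z, U, O and `*` may appear in input but never form part
of an FT occurrence). For word length k (default 3) every window of k
canonical letters is an occurrence of its k-mer; occurrences are counted at
every start position, so overlapping matches all count — a run of seven A's
contains five occurrences of AAA. A k-mer with at least n occurrences
(default n = 5) is a Frequent Triplet (FT). The *restrictive* variant
additionally requires some n occurrences to fall within a window of M
consecutive residues (first start to last end ≤ M; default M = 2000 when
enabled), implemented as a sliding criterion over the sorted position list.
A kept k-mer always retains its full occurrence list, including occurrences
outside the qualifying window — trimming to the window would make the
downstream interval statistics depend on which window qualified first,
which is not well defined.

Null model: treating the W = L − k + 1 ≈ L − 2 windows as independent
Bernoulli trials with per-window probability p (uniform model: p = 1/8000;
unigram model: p_t = product of the letter probabilities of triplet t,
estimated from a user-supplied reference set), the number of occurrences of
a fixed triplet is Binomial(W, p) and the expected number of triplets
reaching the threshold is E(L, n) = Σ_t P(X_t ≥ n); E/8000 is the
per-triplet misidentification P-value. The tail is computed with the scipy
binomial survival function (numerically stable to L = 35,000 and beyond).
Window overlap induces weak positive dependence for self-overlapping words
(periods 1 and 2, i.e. 400 of the 8000 triplets); Monte-Carlo scanning of
simulated proteins shows the independence approximation holds within ~2
standard errors of a 200-replicate mean up to L = 20,000, which is the
basis of the agreement test.

W = L − 2 (the window count) is used rather than L itself; the difference
is negligible at protein scale but the window count is the exact trial
number.

## Order measures

- **RC** = |union of [pos, pos+k−1] over all FT occurrences| / L ∈ [0, 1].
  For a CO protein RC ≥ 7/L, since five overlapping occurrences of one
  triplet cover at least 7 loci. (A figure caption in the source literature
  quotes 3/L for this bound; 7/L is what the arithmetic implies, and the
  package asserts 7/L.)
- **Interval distribution**: for each FT with occurrence starts p₁ < p₂ <
  …, the gaps p_{i+1} − p_i; pooled over all FTs of the protein.
- **MFI**: the modal pooled interval; ties resolve to the smallest tied
  interval (the lower harmonic). Undefined only when no FT recurs, which
  cannot happen at n ≥ 2.
- **RP** = (# pooled intervals equal to MFI) / (total FT occurrences).
  Two readings of "occurrences within the MFI" are arithmetically possible
  (count MFI-sized gaps, or count occurrences participating in at least one
  MFI-sized gap). The package evaluated both against the six published
  example proteins; only the gap-count convention reproduces all six
  printed RP values (0.4, 0.13, 0.69, 0.14, 0.35, 0.84), so it is frozen.
  Note RP's numerator has at most total−1 entries, so RP < 1 always; it
  tends to 0 as the MFI loses support.
- **Periodic flag**: MFI support (recurrences at MFI) ≥ 4 by default —
  the setting at which roughly half of CO proteins in a typical vertebrate
  proteome qualify.
- **Purity**: DFT = MFI → `pure` (the FTs tile one motif of unit length
  MFI), DFT < MFI → `degraded`, DFT > MFI → `complex`.
- **Entropy**: S_k = −Σ (n_i/W) log₂(n_i/W) over the W = L − k + 1
  overlapping windows (overlapping, for consistency with FT counting).
  Normalization base: log₂(20^k) when 20^k ≤ L, else log₂(L). The
  literature states the log₂(L) base "for k > 2"; the 20^k ≤ L switch is
  the same rule for k = 1 and k = 3 and behaves continuously at k = 2.
  All window k-mers are counted (tolerated letters included): entropy is a
  composition statistic, not an FT statistic.

Measure values written to TSV carry 4 decimals; comparisons against
printed reference values use decimal half-up rounding at the printed
precision (`round_half_up`).

## Vocabulary and universality fits

The proteome vocabulary is the union of per-protein FT sets; carrier
counts (number of CO proteins containing an FT) drive the predominant-FT
ranking (ties lexicographic, for deterministic output) with homo-run
flagging (all k letters equal). Vocabulary size is invariant under protein
duplication and proteome ordering.

Power-law fits are ordinary least squares on (log₁₀ x, log₁₀ y), restricted
to an optional log₁₀-x range, with non-positive points excluded (log
undefined at 0); slope, Pearson r and the regression P-value come from
`scipy.stats.linregress`. The measure–length regressions bin CO proteins
into 50 equally spaced intervals along the raw measure axis (empty bins
dropped, not interpolated), average L within each bin, and fit
log₁₀(bin center) on log₁₀(mean L); the unbinned Pearson correlation of the
log variables is reported alongside. Binning on the raw measure scale
before taking logs is a choice — log-spaced binning is the plausible
alternative for unbounded measures like DFT — and is configurable only via
the bin count.

Hierarchical clustering of the C_IJ matrix (average linkage on Euclidean
distances between matrix rows, Newick export) is standard plumbing via
scipy/scikit-bio and is not an accuracy surface of this package.

## Enrichment sweeps

Annotation matching is case-insensitive literal substring search in
user-supplied free text; no ontology graph is consulted. Thresholds sweep
strictly `>` (a boundary protein with measure exactly equal to a threshold
drops out at that threshold). The default grid is the deciles of the
measure's empirical distribution, preceded by a minimal threshold just
below the observed minimum so the first point covers the whole CO set.
The P-value is the one-sided upper hypergeometric tail at the
ratio-maximizing *admissible* threshold (n_fun > 15 and n_fun ≥ 10% of its
value at the minimal threshold), with population and successes taken at the
minimal threshold; when no threshold is admissible the curve is returned
with the P-value undefined and a reason code. The run-length measure is
the number of pooled intervals equal to 1 (the effective coverage of runs).

## Synthetic data

`plant_motif` lays r copies of a motif head-to-tail, applies i.i.d.
substitutions at a given impurity rate (substitute-to-different letter),
pads with i.i.d. random flanks, and returns exact ground-truth coordinates.
`generate_proteome` draws lengths from a log-normal (defaults
μ = ln 375, σ = 0.65 — median ~375 residues, resembling eukaryotic protein
length distributions), plants motifs from a pool into a configurable
fraction of proteins (default 0.3, of the order of the CO fraction seen in
vertebrate proteomes), and, when requested, assigns an annotation term with
log-odds proportional to the planted repeat-array coverage fraction, giving
a known enrichment effect size. All generators take a single seed and are
byte-reproducible.

What the generators do *not* emulate: slippage/duplication mutation
processes, homology between proteins, realistic amino-acid composition
(uniform letters by default), or annotation vocabularies. Passing recovery
tests therefore shows the measures respond correctly to planted
statistical structure, not that they summarize any real proteome
faithfully.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
null-model agreement uses a length grid up to 20,000 with 200 replicates
per point; planted-motif recovery uses 25 seeds per pure motif and 100
seeds at impurity 0.2; synthetic proteomes use 150–600 proteins. These
sizes give the statistical power the assertions need while keeping a full
run in seconds to minutes.

## Known limitations and documented discrepancies

- The bundled LORI example sequence carries a one-letter transcription
  defect (length preserved at 312): its computed FT coverage is 223 loci,
  one short of the 224 that would round to the reference value 0.72, so
  the package reports RC = 0.71 for it. All its other measures (DFT 12,
  MFI 1, RP 0.13) match the reference exactly. The sequence is kept
  verbatim rather than edited toward the expected value.
- The bundled A4 example sequence is 769 residues; its source table states
  770 (one residue lost in transcription). All of its published measures
  reproduce exactly on the 769-residue sequence.
- The analytic misidentification P-value at L = 7999, n = 5 is
  3.65 × 10⁻³ (a Poisson(1) upper tail at the fifth count), not below
  10⁻³ as sometimes quoted; the 10⁻³ level is crossed near L ≈ 6100. The
  package reports the exact Eq.-style binomial value, verified against an
  exact rational-arithmetic summation.
- Overlapping-word autocorrelation corrections (Guibas–Odlyzko style) are
  deliberately out of scope: the null model is the independent-trial
  binomial, and the simulation quantifies its (small) error.
- Species-scale results (per-proteome DFT counts across taxa, kingdom
  separations, ortholog comparisons, GO-based enrichment P-values) require
  external proteome and annotation downloads; the operations to compute
  them from user-supplied FASTA/TSV inputs exist, but no published
  species-level number is asserted by the tests.
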