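# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic-data generators do and do not emulate, and
the design decisions that were genuinely open.

## Motif model

The C2H2 zinc-finger motif is treated as a hard residue-class pattern with
bounded gap repeats, `Ø-X-C-X{2,4,5}-C-X3-Ø-X5-Ø-X2-H-X{3,4}-H`: two
cysteines and two histidines at fixed relative spacing (the zinc-coordinating
residues), three hydrophobic anchor positions, and any-residue gaps whose
repeat counts are restricted to the listed sets.  There is no position
weighting or HMM scoring — a span either satisfies every element or it does
not.  Consequences of the element counts: every match is 23–27 aa.

Conventions, chosen for determinism and oracle-checkability:

* **Hydrophobic set.** The literature's Ø class is not a single canonical
  set; the default here is {A, C, F, I, L, M, V, W, Y} and every entry point
  accepts an alternative.  All scanning properties (strand symmetry, length
  bounds, oracle equivalence) hold for any configured set.
* **Stops and ambiguity.** `*` (stop) and `X` (codon containing N) satisfy
  no residue class, including the any-residue class: a motif interrupted by
  a stop cannot be a coding motif.
* **Counting.** One match is counted per distinct (frame, aa_start) that
  admits any gap expansion; within a start, the leftmost-shortest expansion
  (smallest total length, ties to smaller counts in earlier elements) fixes
  the reported length.  Whether overlapping starts are collapsed matters in
  principle, but for 90-bp seeds multi-match events are vanishingly rare
  (the per-seed match probability is ~5×10⁻⁶ at uniform composition), so
  campaign statistics are insensitive to the convention.
* **Coordinates.** DNA coordinates are 0-based half-open on the forward
  strand in every frame; `dna_end − dna_start = 3·aa_length` always.

Two scanning paths exist: a readable per-sequence scanner and a vectorised
batch counter used by the campaign (uint8 base codes, codon-index lookup,
a vectorised fixed-prefix prefilter followed by per-candidate verification).
They are tested to agree exactly, and the scalar path is additionally tested
against a brute-force matcher that enumerates every (start, gap-combination)
pair.

## Origination campaign

One simulation draws `T = ⌊genome_size / seed_length⌋` i.i.d. seed sequences
(seed_length 90 bp) from the supplied base frequencies and records the total
motif-match count over all six frames of all seeds; the origination
probability is the fraction of `n_sims` simulations (default 100,000)
whose count reaches the expected number of ancestral starter genes
(default 5).  The comparison is `≥`, so `expected_count = 0` gives
probability 1 identically.

* **Stream vs two-stage.** Stream mode regenerates and scans every seed
  (exact; memory bounded by chunked generation).  Two-stage mode first
  estimates the per-seed match probability `p̂` as the fraction of
  `n_rate_est` fresh seeds carrying ≥ 1 match, then draws each simulation's
  count from `Binomial(T, p̂)`.  Because seeds are i.i.d. by construction,
  the binomial form is exact for the number of motif-bearing seeds; it
  differs from the stream total only through multi-match seeds, which are
  negligible at 90 bp.  Two-stage is the only desk-feasible route at
  genome-scale `T` (~4×10⁶ for rice).
* **Analytic reference.** `poisson_reference(p̂, T, E) = P(X ≥ E)` for
  `X ~ Poisson(T·p̂)` (scipy's survival function) validates either mode in
  the binomial→Poisson limit; tests require agreement within combined Monte
  Carlo standard errors, where "combined" includes the delta-method error
  contributed by `p̂` itself — at rates of a few per million, the rate
  estimate's own Poisson noise dominates and ignoring it would miscalibrate
  the check.
* **RNG discipline.** One integer seed; each simulation and the rate
  estimator use substreams spawned from `(seed, stream tag, index)`
  (NumPy `SeedSequence` semantics), so results are independent of execution
  order and chunk size never leaks into the statistics.
* **Genome-scale defaults.** `RICE_GENOME_SIZE = 373,245,519` bp and
  `RICE_BASE_FREQS = (0.282, 0.218, 0.218, 0.282)` encode a rice-sized
  nuclear genome at 43.6% GC for users without a genome FASTA at hand;
  `base_composition()` derives exact frequencies from any FASTA.  The
  headline probability depends on the assembly actually used, so runs with
  these defaults characterise the mechanism, not any particular published
  figure.
* **KDE export.** The count distribution can be smoothed with a Gaussian
  kernel for plotting.  The bandwidth is absolute (or Silverman's rule);
  the evaluation is the explicit Gaussian-mixture sum rather than a wrapper
  around a relative-bandwidth KDE object, so a fixed bandwidth means what it
  says; degenerate single-valued data fall back to bandwidth 1 with a
  warning.

## Neutrality statistics

Site handling is complete deletion only: any column containing a gap or N in
any sample sequence — or in the selected outgroup when polarisation is
requested — is dropped before counting.  This mirrors the most common
population-genetics default and makes results reproducible across tools at
the cost of discarding columns a pairwise policy would keep.

From retained columns: `π` is the mean number of pairwise differences, `S`
the count of segregating sites, `η = Σ(alleles − 1)` the total mutation
count (a triallelic column contributes 2 to η and 1 to S), and `η_e` the
number of outgroup-polarised derived singletons — a site counts toward
`η_e` only if it is biallelic in the sample, the outgroup allele is present
in the sample, and the other allele occurs exactly once.  Sites where the
outgroup carries a third allele stay in S/η/π but are excluded from `η_e`.

Coefficients are functions of n only: the Tajima (1989) chain
`a1, a2, b1, b2, c1 = b1 − 1/a1, c2, e1 = c1/a1, e2 = c2/(a1² + a2)`, and
the Fu & Li (1993) outgroup `u_D, v_D, u_F, v_F` with the
Simonsen–Churchill–Aquadro (1995) corrected F variance (the form using the
harmonic sum to n, `a_{n+1}`).  The implementation is validated against an
independent exact-fractions transcription at several n.  `n ≥ 4` is
enforced: at n = 3 the Tajima numerator is identically zero.

Statistics whose denominator vanishes (S = 0 or η = 0) are returned as NaN
and flagged undefined rather than raised, since monomorphic windows are a
normal outcome.

**p-values.** Significance comes from simulation, not tables: `n_reps`
neutral coalescent samples of size n conditioned on the observed S
(mutations placed on branches with probability proportional to branch
length — the standard fixed-S device), the statistic recomputed on each, and
`p = (r + 1)/(n_reps + 1)` with r the number of replicates at least as
extreme in absolute value.  This two-sided definition is rank-based, hence
exactly uniform under the null regardless of the statistic's skewness, and
its floor `1/(n_reps + 1)` is the honest resolution limit.  `n_reps ≥ 1000`
is enforced.  The conditional-on-S null ignores recombination (conservative
for positive D) and treats θ as nuisance by conditioning.

## Coalescent and spectrum generators

`coalescent_sample` implements the standard neutral Kingman coalescent:
exponential waiting times with rate C(k,2), uniformly chosen pairs,
infinite-sites mutations as a Poisson process with rate θ/2 per unit branch
length (or exactly S mutations placed branch-length-proportionally when
conditioning).  Columns are materialised as real sequences — ancestral base
A, derived base drawn from {C, G, T} — so downstream code exercises its real
input path, and the outgroup carries the ancestral allele everywhere plus an
optional number of private derived columns.  `skewed_sample` plants S
biallelic columns whose derived-allele counts follow a user weight table,
with carriers chosen uniformly — the device used to verify the sign response
of Tajima's D to spectrum distortion.

What these generators do **not** emulate: recombination, gene conversion,
demography, migration, back-mutation/multiple hits, base-compositional
heterogeneity along the locus, alignment error and sequencing error.
Passing tests therefore demonstrate correctness of the statistics and the
null machinery under the ideal neutral model, not robustness of inference on
real resequencing data.

## CDS degeneration classification

`align_pair` performs global affine-gap alignment (match +5, mismatch −4,
gap open −10, extend −0.5; a length-L gap costs 10 + 0.5(L−1)) via
Biopython's PairwiseAligner, then canonicalises the optimal alignment by
shifting every gap run as far left as the flanking context allows without
changing the score — the same normalisation as VCF indel left-alignment.
Canonical gap placement, rather than a bespoke tie-breaking DP, is what
makes event coordinates deterministic; scores are verified against an
independent full-matrix Gotoh recurrence on small pairs.

`classify_events` makes the curator's rules mechanical: contiguous gap runs
are single indel events (in-frame iff length ≡ 0 mod 3); a running frame
offset is maintained, and substitutions are typed by codon translation only
while the offset is ≡ 0 mod 3 — downstream of an uncompensated frameshift
they are reported `unclassified` because the codon correspondence is lost.
A substituted codon translating to a stop is `stop_gain`.  The verdict is
`frameshifted` if the offset was ever nonzero mod 3 (even if later
compensated — the intervening peptide is garbled), else `premature_stop` if
any stop was gained, else `intact_with_inframe_indels` / `intact`.
Multi-base substitutions within one codon yield one event per differing base
but are typed on the whole codon replacement.  Event coordinates are 1-based
on the ungapped reference; insertions take the coordinate of the reference
base following the insertion point.

The mutagenesis generator (`mutate_cds`) plants non-overlapping,
well-separated events whose indel edges differ from their flanking bases, so
the planted coordinate is the left-aligned canonical one and recovery can be
asserted exactly.  Real ortholog divergence includes homopolymer-ambiguous
indels where any coordinate is a convention, plus alignment uncertainty the
event list inherits silently — the recovery tests do not speak to those.

## Problem sizes in the test suite

The statistical checks run at sizes chosen to give the assertions real
power while keeping the default `pytest` run to a few minutes: 10,000 seeds
for scanner/oracle equivalence, a stream campaign of 2,000 simulations ×
2,000 seeds against a 10⁶-seed independent rate estimate, 2,000 neutral
replicates for Watterson/Tajima recovery, 200 replicates per
spectrum-distortion regime, 500 draws × 1,000 replicates for p-value
calibration, and 100 mutated CDS fixtures.  The acceptance script uses the
full 100,000-simulation campaign in two-stage mode at rice-scale T.

## Known limitations

* The motif model is binary; degenerate or diverged zinc fingers that a
  profile HMM would accept score as non-matches.
* Two-stage campaigns inherit the error of `p̂`; at per-seed rates of a few
  per million, `n_rate_est = 10⁶` yields ~40–50% relative uncertainty in the
  rate (and hence in `λ = T·p̂`), which dominates all downstream comparisons
  and is propagated explicitly where the package checks itself.
* Fu & Li's within-sample starred variants (no outgroup) are not
  implemented; requesting the outgroup tests without an outgroup is an
  error.
* The null model for p-values has no recombination; for strongly positive
  observed D this is conservative.
* `summarize` is a per-column Python loop — fine for population loci
  (10²–10⁴ columns), not intended for chromosome-scale alignments.
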