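# Methods

## Model

A microhaplotype locus is an ordered set of known biallelic substitution
SNPs on one chromosome whose span fits in a single read-length window
(default 60 bp, inclusive of both end SNPs: `last.pos − first.pos ≤ 59`).
Loci are defined by anchoring a window at every SNP and emitting the
contained SNP set unless it is a subset of the previously emitted locus,
so the window effectively advances until at least one new SNP enters.
Indels and multiallelic sites are out of scope; bases matching neither
known allele of a site are discarded at extraction.

Both estimators share one observation model. A base call at a SNP is
wrong — i.e. reports the other allele — if exactly one of two
independent stages flipped it: pre-sequencing (rate `e1`, default 0.01;
library prep and PCR) or sequencing (rate `e2 = 10^(−Q/10)` from the
per-base Phred score). Hence

    e = e1 + e2 − 2·e1·e2 .

Because observations are restricted to the two known alleles, a mismatch
has probability `e` rather than `e/3`. The likelihood of a read given a
haplotype is the product over covered SNPs of `1 − e` or `e`; reads are
conditionally independent given their source haplotype(s).

**Individual method.** For individual *i* with read set `R_i`, the
likelihood is a mixture over the K(K+1)/2 genotypes of the K candidate
haplotypes, each read an equal (½/½) mixture over the genotype's two
haplotypes. Genotype weights follow from the allele frequencies under
Hardy–Weinberg equilibrium, so the free parameters are the K allele
frequencies. The EM E-step computes per-individual genotype
responsibilities; the M-step sets each allele frequency to its expected
share of the 2N gene copies.

**Pool method.** Reads are modelled as drawn i.i.d. from the population
pool of alleles; the mixture weights are the allele frequencies
themselves and no HWE assumption is made. The E-step computes per-read
haplotype responsibilities; the M-step averages them.

Per-read likelihoods are computed in probability space (a read covers at
most ~10 SNPs, far from underflow) and accumulated across reads in log
space; per-individual genotype mixtures use a log-sum-exp shift. The
total log-likelihood is non-decreasing across EM iterations, which the
test suite asserts on every recorded fit.

## Pruning

With `y` SNPs there are `2^y` possible haplotypes, and quadratically
many genotypes on top for the individual method; linkage makes most
non-existent. The fit therefore proceeds over SNP prefixes: iteration
*t* considers the first `min(t·x, y)` SNPs, with candidates formed by
extending the previous iteration's survivors by every allele combination
of the newly added SNPs. After each fit except the last, candidates with
estimated frequency below `c` are removed and the surviving frequencies
renormalized; the final iteration never drops (dropping there would buy
no efficiency). Defaults are `x = 1`, `c = 0.001`.

Each iteration's EM is initialized uniformly over its candidates; the
survivor frequencies only determine the candidate set. This makes a run
with `c = 0` bit-identical to a single-pass EM over the full haplotype
enumeration, a property the tests rely on. If every candidate falls
below `c` (possible only with pathological settings), the single highest
frequency candidate is retained rather than emptying the model. Ties at
the threshold survive (`< c` removal). Individuals (or reads) with no
calls inside the current prefix are excluded from that iteration's
likelihood, where their contribution would be constant.

Loci are skipped, with the reason recorded in the output, when any SNP
has zero read depth or when the candidate count at the start of any
iteration exceeds 128 (individual) or 256 (pool).

## Numerical choices

* Convergence: maximum absolute frequency change < 1e-6, or 1000
  iterations (both configurable).
* Output frequencies are renormalized to sum to one exactly;
  `He = 1 − Σ p²`.
* Genotype enumeration and haplotype ordering are lexicographic, so all
  results are deterministic; no RNG is used during estimation.
* A non-finite log-likelihood (e.g. an individual whose reads are
  impossible under every candidate genotype at zero error) raises an
  error naming the locus.

## Extraction

Alignments are read per locus from coordinate-sorted, indexed BAMs.
Records that are unmapped, secondary, supplementary, duplicates, or
below mapping quality 20 are excluded; base calls below quality 5 are
discarded (both configurable). Extraction is CIGAR-aware: positions
deleted in the read yield no call. The two mates of a fragment are
merged into one observation — they derive from one DNA molecule, and
counting them twice at overlapping SNPs would pseudo-replicate —
with conflicts at a shared site resolved in favour of the higher base
quality (equal qualities drop the site). In individual mode the source
of a read is its read group's SM sample, falling back to the BAM file
name; in pool mode read groups are ignored.

## Synthetic data

The generator emulates the data regime the estimators target. Per locus:
SNP positions are drawn within one 60-bp window (2–6 SNPs by default);
the true haplotype set is a random subset of 2–8 of the `2^y`
possibilities (emulating linkage-induced sparsity) with frequencies from
a symmetric Dirichlet(1); diploid individuals draw two haplotypes
independently from those frequencies (HWE). Reads of fixed length
(default 60 bp) are placed uniformly over the start positions covering
at least one SNP; per-individual read counts are Poisson such that the
expected depth at every SNP equals `mean_depth` (the levels of interest
being 0.1–2×), or an exact per-locus read total can be requested. Each
covered allele is flipped with probability `e1`, then with the
Phred-implied probability of its drawn quality score (uniform Q20–Q40 by
default) — exactly the estimator's error model, so simulation studies
probe estimation error, not model misspecification. Datasets can be
materialized as an indexed single-end BAM with one read group per
individual, a SNP table and a truth TSV, or kept in memory.

The generator does not emulate mapping error, reference bias, indels,
duplicates, RAD-seq read stacking, or base-quality miscalibration.
Passing tests therefore demonstrate correctness of the estimators under
their own assumptions, not robustness to upstream artefacts in real
data.

## Evaluation protocol

Estimates are compared against the *realized sample* allele frequencies
(the frequencies among the 2N simulated gene copies), the quantity a
full-depth genotyping of the same individuals would report. Loci are
binned by the number of reads informing the estimate; only loci with at
least 2 SNPs and observed He > 0.1 enter (the methods target variable
microhaplotypes); one allele with observed frequency > 0.01 is chosen at
random per locus per bin; and when a locus contributes several estimates
to one bin (e.g. from different depths) one is chosen at random, both
under a caller-supplied seed. The signed error is observed − estimated;
an allele absent from an estimate counts as frequency zero.

## Behaviour and limitations

Simulation results (see `scripts/acceptance.py`) reproduce the expected
qualitative behaviour: mean allele-frequency error near zero from ~20–25
reads per locus, mean squared error falling roughly an order of
magnitude between the 1–5 read bin and the ≥ 20 read bin, the individual
method slightly but consistently ahead of the pool method, and expected
heterozygosity biased low when data are scarce (the estimator spreads a
few percent of probability mass onto error-generated haplotypes that the
final, non-dropping iteration retains; common alleles are correspondingly
slightly under-estimated). This small-sample bias largely disappears by
~30 reads and entirely by a few hundred. Estimates informed by fewer
than ~20 reads should not be relied upon.

Problem sizes in the test suite and the acceptance script (200 loci, 25
individuals, three depth levels) were chosen to give stable Monte-Carlo
estimates of these properties while keeping a full run under a minute.

Confidence intervals on the frequencies, multi-population joint
estimation, CRAM input, and SNP discovery are out of scope; the package
assumes a known set of substitution SNPs.
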