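# Methods

`panstruct` reimplements, at desk scale, the computational pipeline behind a
multi-reference pan-genome panel of Asian rice: aggregation of replicate
admixture analyses into a stable subpopulation grouping, membership
classification, representative-accession selection, assembly gene-space and
size statistics, and pairwise structural-variant (SV) quantification. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic data do and do not establish.

## Admixture model and EM estimator

The genotype model is the standard admixture likelihood: sample *i* carries
ancestry proportions **q**<sub>i</sub> over *K* populations with allele
frequencies *f<sub>kj</sub>* at SNP *j*, and the dosage *g<sub>ij</sub>* ∈
{0, 1, 2} is Binomial(2, *p<sub>ij</sub>*) with *p<sub>ij</sub>* = Σ<sub>k</sub>
*q<sub>ik</sub> f<sub>kj</sub>*. `admixture_em.em_fit` maximizes this by plain
EM (allele-origin responsibilities in the E step; row-normalized expected
ancestry counts and frequency ratios in the M step) rather than the
block-relaxation quasi-Newton scheme of the genome-scale tools — the model and
optimum family are identical and speed is irrelevant at fixture sizes.
Choices:

- frequencies clamped to [1e-6, 1−1e-6] so the log-likelihood stays finite;
- initialization seeded: Q rows from Dirichlet(1,…,1), F from the per-SNP
  sample frequency jittered by ±0.05;
- missing dosages contribute nothing (complete case per cell);
- convergence when the log-likelihood gain drops below `tol` (default 1e-4)
  or `max_iter` (default 2000); non-convergence returns a flagged fit with a
  warning, never an exception. The likelihood trace is non-decreasing by
  construction and asserted in tests.

The test suites run the estimator on a panel of n = 200 samples × m = 5,000
SNPs (K = 3, F<sub>ST</sub> 0.15, 20 within-group 50/50 admixed samples) with
the iteration cap at 600: the EM tail converges slowly on the admixed block,
but ancestry recovery is already RMSE ≈ 0.025 (bound asserted: < 0.05) and
further iterations only polish the third decimal.

## Q-matrix aggregation

Independent runs at the same K suffer label switching and can converge to
genuinely different solutions ("modes", typically differing in which subgroup
is split). The aggregation procedure:

1. **Alignment** — the K×K matrix of squared column distances is solved by
   exact optimal assignment (`scipy.optimize.linear_sum_assignment`), a
   least-squares analogue of the CLUMPP objective. Exhaustive K! search
   confirms optimality for K ≤ 6 in tests.
2. **Run distance** — per-cell RMS difference after alignment, normalized by
   √(2n) so that the value lies in [0, 1] (two disjoint hard assignments
   differ by 2 per row).
3. **Clustering** — average-linkage hierarchical clustering on the run
   distance matrix, cut at `cut_threshold` (default 0.1, i.e. a tenth of the
   maximal per-cell scale). The original description fixes neither metric,
   linkage nor cut rule; these are this package's choices, made once.
4. **Mode summaries** — singleton clusters are discarded as outlier runs;
   each surviving cluster is aligned to its medoid (order-independent) and
   averaged cell-wise, rows renormalized to the simplex. Modes are labelled
   "K", "K.1", … in decreasing cluster-size order, so the secondary mode at a
   given K carries the ".1" suffix.
5. **Ladder matching** — columns at K+1 are linked to their best-correlated
   (Pearson, across samples) column at K; a parent with ≥ 2 children is a
   split, and child names extend the parent's name ("XI-1B" → "XI-1B1",
   "XI-1B2") ordered by mean proportion. How the original analysis combined
   levels into its final grouping is under-specified; correlation matching is
   one faithful reading and is the one implemented.

## Membership rules and representative selection

With threshold *t* = 0.65 on a Q row: the largest component ≥ *t* names the
subpopulation directly (for *t* > 0.5 at most one component can qualify — a
simplex argument asserted at run time); otherwise the summed components
within each major variety group (cA, XI, GJ, evaluated in that fixed order,
maximal sum winning ties) yield "cA-adm"/"XI-adm"/"GJ-adm" when ≥ *t*; all
remaining samples are fully admixed. Both "exceeding 0.65" and "≥ 0.65"
readings appear in the source material; ≥ is used uniformly (boundary cases
are measure-zero on real data) and the comparison is float-tolerant (1e-9).

Identity-by-state distance is d<sub>ij</sub> = half the mean absolute dosage
difference over pairwise-complete SNPs. "PCA of a distance matrix" is
implemented as classical multidimensional scaling (PCoA): double-center
−D²/2, take the top eigenvectors scaled by √eigenvalue, fix each axis's sign
so its largest-magnitude loading is positive. The representative of a group
is the member closest (Euclidean, over the first 5 axes) to the group
centroid among entries whose seed is available — availability is an input
flag, not inferred — with lexicographic tie-breaking.

## Assembly statistics and the adjusted BUSCO score

N50 is the largest contig length whose descending cumulative sum reaches half
the assembly; gaps are maximal runs of N. The adjusted gene-space score
rescales a raw completeness percentage from the full 1,440-gene benchmark to
the universe excluding the 13 genes absent from the whole cereal lineage:
adjusted = raw × 1440/1427, rounded **half-up** to 2 decimals to reproduce
the published table bit-for-bit (the formula is not printed anywhere; it is
validated in tests against all 12 printed raw/adjusted pairs).
`universal_missing` reproduces the supporting set logic: the intersection of
per-assembly missing sets, and its subset absent from every outgroup genome.

## k-mer genome-size estimation

Canonical k-mers (k = 17 by default, supported 13–31) are counted over the
reads; the depth histogram is split at its first local minimum to exclude the
sequencing-error peak, and the genome size is the number of k-mer
observations above the cutoff divided by the peak depth. The peak depth is
measured as the **mean** depth of the post-cutoff spectrum rather than the
raw histogram mode: read placement makes neighbouring depths strongly
correlated over a read length, so at desk scale the integer mode wobbles by
±1–2 around the true peak (a 5–10% error at 20×), while the post-cutoff mean
estimates the same homozygous-peak position to a fraction of a percent. The
heterozygosity/repeat modelling of the full GCE program is out of scope; the
estimator is the basic homozygous one. Error-free 20× reads from a 100-kb
genome recover the size within 2%, and the estimate is invariant to read
order and (within 2%) to doubling coverage.

## Pairwise SV quantification

`fragment` emulates the 10× redundant 50-kb pseudo-read set as `redundancy`
phase-shifted non-overlapping tilings (offsets of read_len/redundancy) — a
plain splitter is non-overlapping, and phase-shifting is a deterministic way
to realize the stated redundancy; every interior base is covered
redundancy−1 or redundancy times. Filtering keeps insertions, deletions and
tandem duplications with length ≤ 25,000 bp ("up to" read as inclusive).
`affected_bp` merges DEL/DUP reference footprints (counted once) and adds
inserted lengths; whether the original analysis merged overlaps is unstated —
merging is adopted here. Comparisons are directional (query fragmented onto
reference) and never symmetrized. The TE-related fraction intersects DEL/DUP
footprints with the reference TE track; an insertion counts as TE only when
externally flagged (unflagged insertions count as non-TE and the limitation
is logged), since matching inserted sequence against a TE library is out of
scope.

The toy-scale detector `naive_pair_sv` (mapping/calling on real genomes stays
external) chains k-mers unique in both sequences (k = 21) into the longest
collinear chain and classifies inter-anchor gaps: reference-only extent →
DEL, query-only extent → INS, query-only extent whose sequence matches
(edlib, ≤ 10% divergence) the reference window abutting the breakpoint on
either side → tandem duplication. On planted events ≥ 200 bp spaced ≥ 2 kb it
recovers ≥ 90% with correct type, position within ±k and length within a few
bp; events below ~50 bp are deliberately ignored (`min_len`).

## Synthetic data: what it emulates and what it does not

- **Genotypes** follow the Balding–Nichols model: per-population frequencies
  Beta-distributed around ancestral frequencies with Var = F<sub>ST</sub>
  p(1−p); dosages Binomial(2, q·f). Defaults: F<sub>ST</sub> 0.15 (a fixture
  choice — the source states no differentiation level), ancestral
  frequencies Uniform(0.1, 0.9). No linkage disequilibrium, no coalescent
  history, no genotyping-error model: passing tests show the estimators
  recover the generating model, not that they are robust to real LD or
  ascertainment structure.
- **Run ensembles** perturb rows by Dirichlet resampling with concentration
  1/noise_sd² (rows stay on the simplex by construction) and permute columns;
  the optional second mode merges the two closest groups and re-splits the
  largest with a structured per-sample weight, mimicking the split ambiguity
  seen between analysis runs.
- **Toy genome pairs** plant non-overlapping INS/DEL/tandem-DUP events on a
  uniform-composition (GC 0.44) random genome and emit a TE track covering a
  configured fraction (default 0.7) of the planted events. Real TE landscapes
  are nested and repeat-rich; unique-anchor density in real repeats would be
  far lower than in these fixtures.
- **Reads** are uniformly placed, optionally with uniform substitution
  errors; no indel errors, no quality model. Start positions are encoded in
  read ids.

All generators are pure functions of (parameters, seed) and refuse to run
unseeded.

## Problem sizes

The default test-and-acceptance sizes are: genotype panel 200 × 5,000
(K = 3), run ensembles of 10–16 replicates at K = 4, toy genomes of 40–230 kb
with 4–20 planted events, 20–40× read sets over 60–100 kb. The end-to-end
pipeline smoke configuration is smaller still (51 samples × 1,000 SNPs,
K 3–4, 4 runs per K). These sizes were chosen so the entire suite runs in
about a minute while every statistical check retains comfortable margin.

## Known limitations

- The EM estimator offers no K-selection statistic (the analysis protocol
  fixes K = 5..15 by design) and no standard errors.
- `ladder_match` assumes a single dominant mode per K when building names
  across levels.
- The SV detector requires unique anchors; diverged or highly repetitive
  inputs raise "sequences unrelated at k" rather than degrade silently.
- The k-mer estimator assumes an effectively homozygous genome and errors
  rare enough that the error peak is separable.
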