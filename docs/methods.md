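# Methods

`causalpie` constructs gene clusters that behave like Rothman's
sufficient-cause ("causal pie") model from case-control SNP data: each
cluster is anchored by a shared (major) gene, its member SNP pairs carry
*risky combinatory genotypes* (component causes), and a subject carrying a
sufficient fraction of a cluster's risky genotypes is classified as a case.
This note records the model, the choices made where the procedure was
genuinely open, the synthetic-data design, and the limits of what the test
suite demonstrates.

## Risky genotype sets and thresholds

For a case population of size S_HT and a control population of size S_NC,
the percentage criteria C_HT (default 2.0) and C_NC (default 0.1) are
converted to integer carrier thresholds by the ceiling rule

    t_HT = ⌈S_HT · C_HT%⌉,   t_NC = ⌈S_NC · C_NC%⌉,

computed exactly with rational arithmetic (no float round-off at integer
boundaries such as 200 · 2% = 4).  A *risky genotype set* of a single SNP
is a set of genotypes carried by ≥ t_HT cases and ≤ t_NC controls; a
*risky combinatory genotype set* of a SNP pair applies the same criterion
to the 9 joint genotype cells.  A pair is a *disease gene pair* only if
neither member qualifies alone (single disease genes are excluded from the
pair scan).  Qualification must hold in **every** training dataset, with
thresholds computed per dataset; this multi-dataset requirement — in
particular the presence of one control-rich dataset — is what gives the
stringent criteria their specificity.

The genotype subset attached to a qualifying SNP (pair) is found by exact
enumeration of all nonempty cell subsets (≤ 511), maximizing total case
carriers under the control budget; ties prefer fewer genotypes, then the
lexicographically smallest dose-coded cell tuple.  Two modes exist:

- **dose-monotone (default):** candidate subsets are restricted to upper
  sets of the minor-allele-dose lattice, the natural reading of a "disease
  allele" whose dose increases risk.  A subset is an upper set *relative to
  the observed cells* — cells absent from the data do not constrain it.
- **unrestricted:** any subset.  At desk scale this mode lets scattered
  near-empty cells be unioned into "risky" sets and admits on the order of
  10³ chance pairs out of ~2·10⁶ on pure-noise data, so it is available
  but not the default.

Genotypes are unordered allele pairs; internally each SNP is recoded as
minor-allele dose {0,1,2} with the minor allele determined from pooled
training data (the allele-pair form remains authoritative).  Missing
genotypes never count as carriage on either side.  SNPs whose observed
allele sets conflict across datasets are excluded from multi-dataset
qualification with a warning; no strand flipping is attempted.

The pairwise scan is vectorized: one-hot dose indicators and BLAS products
produce all 9 joint cell counts for every pair at once; a per-cell
feasibility bound prunes pairs before the exact subset step, and the exact
step runs as a (pairs × 511) integer product whose arg-max encodes the
enumeration tie-break.  The vectorized scan is required to be set-identical
to a naive per-pair reference; the test suite enforces this on random
instances in both subset modes.

## The three-stage cluster construction

**Stage 1 — selection.** Stringent thresholds (t_HT0, t_NC0).  Genes shared
by ≥ 2 qualifying pairs anchor clusters; a pair sharing no gene forms a
singleton that is later grown twice, once per gene as hub.

**Stage 2 — growth.** Thresholds are relaxed one step per round
(t_HT −1, t_NC +1) and pairs involving the hub gene are rescanned.  The
cluster's *frequently identified subjects* (FIS) are maintained from the
per-subject identification counts: MFIS = subjects identified by the
maximal number of member pairs; FIS = subjects identified at least
⌈max/4⌉ times, topped up to the t_HT most frequently identified if fewer.
FIS is pooled over the training datasets' cases (per-dataset FIS is
derivable from the per-dataset carrier records).  A new pair is
*FIS-aligned* when ≥ 50% of its identified cases lie in the current FIS;
when the aligned fraction of a round's new pairs falls below
`stop_overlap` (default 0.5) growth stops and the round is discarded.
The any-overlap variant of this rule cannot terminate once FIS grows and
lets clusters absorb unbounded chance pairs at deep relaxation, which is
why alignment is fractional.  Growth also stops when t_HT would reach 0 or
after `max_nc_steps` (default 10) rounds.  The single-disease-gene
exclusion set is fixed at the stringent stage: recomputing it at relaxed
thresholds would progressively disqualify genuine hub SNPs as t_NC grows.

**Stage 3 — pruning.** Clusters keep ≥ t_HT0 FIS or are dropped; a member
pair is removed when fewer than `keep_fraction` (default 0.5) of its
identified cases lie in the FIS (`--prune-strict` applies the literal
all-in-FIS rule).  Counts and FIS are not recomputed after pruning.
Clusters are ranked by member-pair count.

**False-positive bound.** The probability that a *given* set of k non-LD
member pairs forms a cluster identifying a *fixed* set of m subjects out
of n is at most (m/n)^k.  The Monte-Carlo check mirrors exactly this
event: on label-permuted null data, a surviving cluster's first three
SNP-disjoint members must all identify cases inside a 12-subject target
set fixed before the permutation draw.  The bound does **not** cover
adaptive events — e.g. the frequency with which *some* coincident trio
exists anywhere in the scan output — and such coincidences (driven by
genotypically similar subjects) are in fact common at desk scale; the
package treats them as what they are, dependent evidence that LD/identity
reduction and the ranking step must handle.

## Carriage classification

A subject's carriage percentage for a cluster is carried/measurable × 100,
where measurable counts the member pairs whose two SNPs are assayed on the
subject's platform ("identified" requires carrying ≥ 1).  Cut-offs are
fitted per (cluster, stratum) — scenario S1 stratifies by ethnic group, S2
by platform — choosing among the observed case percentages the value
minimizing misclassification among identified subjects, ties toward the
higher cut-off.  Because candidates are case percentages only, a stratum
where the distributions coincide is forced to predict-all (there is no
predict-none cut-off); this follows the procedure's definition rather than
symmetric-error intuition.  Classification: predicted case iff the
percentage reaches the cut-off in ≥ 1 cluster; evaluation is restricted to
identified subjects, and a subject appearing on several platforms counts
once.  The allelic association test used for major-gene checks is the
standard 1-df chi-square on the 2×2 allele-count table without continuity
correction, Bonferroni being the only multiple-testing adjustment offered.

## Redundancy reduction

Two-locus haplotype frequencies are estimated from unphased genotypes by
EM (double heterozygotes split between coupling/repulsion in proportion to
current haplotype-frequency products; tolerance 1e-9, ≤ 1000 iterations),
giving D′ = |D|/D_max.  LD is computed on pooled controls by default
(controls approximate population LD).  `ld_reduce` keeps, among member
pairs whose partner SNPs have D′ ≥ 0.9, the member with the larger case
carrier count; reduction is reported both in pairs and in distinct SNPs,
with the training error recomputed.  `minimal_gene_set` searches binary
partner-gene masks for the smallest set preserving the training error
(≤ baseline; strict equality mode available): exhaustive smallest-first up
to 20 partner genes, otherwise a seeded genetic algorithm (population 100,
200 generations, uniform crossover 0.8, bit-flip mutation 1/L, tournament
size 3).  The hub gene is structurally necessary and always included.

## Expression-based gene selection

Replicate QC follows the array-processing recipe: drop subjects with any
pairwise replicate Pearson correlation < 0.9 (computed on raw
intensities); per gene, set the value missing when the replicate minimum is
below 60% of the maximum; median-merge; log2; global Z-score over
non-missing entries; values > 6 set missing (0 encodes missing
throughout — a deliberate sentinel inherited from the array pipeline, at
the cost of conflating exact zeros with missingness).  Influential genes
are chosen greedily from the hub: each step scores every remaining cluster
gene by the worst of three Welch-test p-values contrasting case carriers
against case non-carriers, control carriers and control non-carriers on
the mean normalized expression of the augmented gene set, Bonferroni
adjusted by the number of candidates at that step (per-step adjustment is
our documented choice; the alternative — a single global factor — is less
conservative early).  Selection stops when no candidate improves the worst
adjusted p; ties break by gene id, making the procedure deterministic.

## Synthetic data

The generator emulates the structure the pipeline is designed to find.

- **Background:** independent SNPs under Hardy-Weinberg equilibrium,
  MAF ~ U(0.05, 0.5), grouped into genes of 4 SNPs (background genotypes
  are `binomial(2, q)` draws, which *is* the HWE distribution).
- **Pies:** each pie has a hub gene with one hub-side SNP per pair and one
  partner gene/SNP per pair.  The risky combinatory genotype is the
  dose-lattice upper region dose ≥ (1,1) with planted MAF ~ U(0.25,
  0.35): each planted genotype is *common marginally* (heterozygote
  frequency ≈ 42%, so no planted SNP can qualify alone or anchor
  control-splitting chance pairs) while the *joint* region is carried only
  by the pie's target cases — any other subject falling into the region is
  moved out of it (one dose knocked below threshold, side at random),
  leaving control carriage to the leak rate (default 0.0005/pair).  This
  depletion is the case-control sampling signature of a high-penetrance
  component cause: population members carrying a sufficient cause are
  cases, so they are (almost) absent from the control sample.
- **Default study conditions** (`default_simulation`): a shared 2000-SNP
  panel, two training datasets with disjoint subjects — one control-rich
  (300 cases / 2400 controls) and one balanced desk-scale (200 cases /
  400 controls) — and three pies of 10/8/12 pairs, 12 target cases per
  dataset each, penetrance 1.  The control-rich dataset mirrors the
  original training design and is essential: with two balanced 200/400
  datasets the stringent criteria admit hundreds of chance pairs, and
  "hot" SNPs (chance case-enriched rare genotypes) anchor runaway
  clusters.  At the committed design the measured null rate is 0
  qualifying pairs out of ~2·10⁶.
- **LD duplicates:** a pie can append partner SNPs copying an existing
  partner column (per-subject resampling probability ε), exercising the
  D′ ≥ 0.9 reduction.
- **Two platforms:** planted pairs are shared between panels with a given
  probability; platform-specific pairs get fresh SNPs in the same genes
  planted into a *different* case subset, reproducing the observation that
  the same gene pair assayed through different SNPs identifies different
  patients.
- **Expression:** log2-scale baselines N(8, 1) per gene, subject noise
  N(0, 1), +`effect_size` on the first pie's genes for its carriers, three
  replicates with N(0, 0.1) replicate noise, and a configurable fraction
  of subjects with one scrambled replicate to exercise the 0.9-correlation
  filter.

Everything is reproducible from the seed (identical byte-level outputs).

What the generator does *not* emulate: coalescent LD structure along the
chromosome, population stratification, genotyping-error models beyond the
leak rate, related individuals, and any marginal main effects of the
planted SNPs.  Passing tests therefore demonstrate the algorithm's
correctness and its behavior under the idealized sufficient-cause signal,
not performance on real GWAS panels, where LD, stratification and partial
penetrance all blur the criteria.

## Problem sizes and numerical choices

The reference analyses run at the default simulation scale (two datasets,
2000 SNPs, ≤ 2700 subjects; full pipeline in seconds), 1000 label
permutations for the null check, 10 replicates per subsampling fraction
for the robustness experiment, and 20 random instances for scan/oracle
equivalence — sizes chosen so the whole suite reruns quickly on a single
CPU while keeping Monte-Carlo error well below the asserted margins.
Robustness declines steeply below ~50% subsampling at desk scale (the
ceiling thresholds t_HT0 drop to 2-3 and chance pairs reappear); the
qualitative non-increasing trend, not the crash point, is the property the
suite asserts.  Threshold arithmetic uses exact rationals; EM convergence
is 1e-9; all RNG flows through `numpy.random.default_rng` seeds.
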