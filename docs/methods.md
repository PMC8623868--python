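# Methods

This note documents the models implemented in `scstrmix`, the parameters
that matter, the numerical choices, and the limits of what the synthetic
data can show.

## Population and pedigree model

Contributor genotypes are drawn per locus from the panel allele frequencies
with the Balding–Nichols (Pólya urn) substructure correction: the next
allele is allele *A* with probability

    (x·θ + (1−θ)·p_A) / (1 + (n−1)·θ)

where *x* is the number of copies of *A* among the *n* alleles already
drawn at that locus, θ the substructure coefficient (F<sub>ST</sub>), and
*p_A* the panel frequency.  With θ = 0 this is Hardy–Weinberg sampling; for
one individual's two draws it yields the familiar genotype probabilities
P(AA) = p(θ + (1−θ)p) and P(AB) = 2pq(1−θ).  Each individual's draws are
conditioned only on that individual's own previous draws at the locus; loci
are independent.  The default θ is 0.01.

Relatives are built by Mendelian transmission (each parent passes one of
its two alleles with probability ½).  Transmissions mutate under a
two-phase microsatellite model: with probability `rate_per_locus`
(default 1.5 × 10⁻³ per transmission, a typical autosomal STR average) the
transmitted allele changes by ±1 repeat with probability `p_single_step`
(default 0.9) or by a geometric multi-step size (parameter 0.5) otherwise,
directions equiprobable.  The defaults are configuration: published
per-locus rates vary by an order of magnitude across loci and sexes, and
any per-locus table can be supplied by constructing `MutationModel`s per
locus.  Mutated designations outside the panel are clamped to the nearest
panel allele so every simulated allele keeps a defined frequency (needed by
drop-in draws and LR denominators).  For a parent–child pair the child's
non-transmitted allele continues the θ recursion over the child's own
transmitted allele only — the simplest reading of the sampling scheme; an
alternative (conditioning on all previously drawn alleles of the case)
would couple all contributors through a shared subpopulation and is not
implemented.

## Cell observation model

A diploid cell observes its contributor's genotype through two noise
processes, applied in this order:

* **Drop-out.** At a heterozygous locus each allele independently drops
  with probability *D* (default 0.2).  A homozygous locus drops as a whole
  with probability *D₂*, default ½·D² (both copies of the same allele must
  fail).  A called homozygote fills both attribute slots.
* **Drop-in / miscall.** Every surviving call is independently replaced
  with probability *e* (default 0.01) by a uniformly chosen *different*
  allele of that locus.  Because miscalls apply to survivors only, a
  heterozygous drop-in always coincides with the loss of the true allele —
  a heterozygote never shows three alleles — while the ADO and ADI draws
  themselves stay independent.

Haploid cells (sperm) carry one uniformly inherited allele per locus, which
drops with probability *D* and miscalls with probability *e*; no separate
haploid drop-out rate is defined.

Observed calls are stored sorted ascending and **left-packed**: when the
smaller allele of a heterozygote drops, the survivor moves into slot 1.
This is deliberate — it reproduces the attribute-vector representation
(2L numeric ARFF attributes for L loci, `?` for missing) that the
clustering operates on, and it is the main source of within-contributor
feature variation beyond missingness itself.

The miscall target is uniform over the other panel alleles, not
frequency-weighted.  At a homozygous locus both slots can miscall in one
cell (probability e² per called locus); the model does not forbid it.

## NOC estimation

Cells are clustered in the packed numeric attribute space.

**EM** fits a k-component Gaussian mixture with diagonal covariances.
Missing slots are handled by marginal likelihood: a cell's component
density is the product over its *observed* slots only, and the M-step
re-estimates each slot's mean and variance from the responsibility-weighted
cells observing that slot.  This is exact EM for the observed-data
likelihood under missing-at-random, so the log-likelihood is non-decreasing
(asserted per iteration in the tests).  Per-slot variances are floored at
10⁻⁴ — noiseless clusters are point masses and need a floor; the floor is
also what makes duplicated profiles clusterable at all.  Convergence is an
absolute log-likelihood improvement below 10⁻³ or 100 iterations.  EM is
initialized from a K-Means partition; `estimate_noc` runs 5 restarts per k
(differently seeded K-Means initializations) and keeps the highest final
log-likelihood, the analog of WEKA-style repeated k-means initialization.

**K-Means** (Lloyd, k-means++ seeding) and the **silhouette coefficient**
use a missing-rescaled Euclidean distance: squared differences are summed
over the slots observed in both profiles and rescaled by
(total slots / compared slots), computed on per-slot min–max normalized
values — the normalization convention of WEKA's distance functions, which
the original workflow was built on.  Normalization keeps high-repeat-number
loci from dominating the distance; a `normalize=False` switch restores raw
repeat-number coordinates, and mean imputation is available by filling the
matrix before encoding.  Centroid slots are updated as weighted means over
observing cells (weights = each cell's rescale factor), which keeps the
objective non-increasing.  Empty clusters are repaired deterministically by
re-seeding at the cell farthest from its centroid.

The NOC is the k in [2, 6] with the highest average silhouette, ties broken
toward smaller k (conservative).  Silhouette is undefined at k = 1, so
clustering never reports a single source; the IBS estimator covers that
case: link two cells when their pairwise IBS exceeds a threshold (default
24 of a maximum 42 for 21 loci) and report the number of connected
components.  The IBS estimator assumes unrelated contributors and is
unreliable for haploid cells, where the consensus of a single cell is
homozygous everywhere and the same-source and unrelated IBS distributions
overlap; it warns on haploid input.

Cells in singleton clusters contribute silhouette 0, as do cells with
a(i) = b(i) = 0 (coincident clusters).  Two cells with no shared observed
slot get distance 0 — they carry no comparative information; with the
default call rates this never occurs in practice.

## Consensus and scoring

The consensus of a cluster is the per-slot modal observed allele; missing
calls cast no vote; ties break toward the smaller allele (determinism).
Haploid clusters are expanded to a diploid consensus per locus: the two
most frequent distinct alleles fill the slots ascending, a single observed
allele is duplicated (hence a one-cell haploid consensus is homozygous at
every called locus).  This expansion reconciles per-slot voting with the
42-slot accuracy denominator and is an interpretation choice, not the only
possible one; genotype-level consensus is out of scope.

Consensus accuracy against truth is the fraction of the 2L truth slots
(truth stored ascending) matched exactly; missing consensus slots count as
wrong.  Clusters are matched one-to-one to true contributors by maximizing
total IBS (Hungarian assignment); matching, and therefore consensus
scoring, is only defined when the estimated NOC equals the true NOC —
replicates with a wrong NOC contribute to NOC accuracy only, and the
silhouette-winning partition is used directly (no re-clustering at the
true k).

## Likelihood ratios

Observation (transition) probabilities Pr(observed call set | true
genotype, D, e) are computed by exhaustively enumerating every drop/miscall
outcome of the cell model at a locus, so the LR machinery inverts the
simulator exactly (the test suite cross-validates the enumeration against
Monte-Carlo outcome frequencies).  For a consensus profile A and a
reference genotype B:

* **Same source**: per locus, numerator Pr(B)·Pr(A | B) and denominator
  Pr(A as genotype)·Pr(B); with D = e = 0 and A = B this is exactly the
  inverse random match probability of A.  The D and e supplied here should
  be *consensus-level* effective rates — far lower than single-cell rates —
  which `estimate_consensus_error_rates` measures empirically by simulating
  clusters of a stated size.
* **Kinship** (parent–child (0,1,0), full siblings (¼,½,¼)): both
  hypotheses marginalize A's latent true genotype over the IBD-state
  mixture, with θ-corrected conditional allele draws continuing the
  Balding–Nichols recursion past B's two alleles; the unrelated hypothesis
  (1,0,0) therefore gives LR ≡ 1.  Mutation is not modeled in the kinship
  transition.

Loci where A is fully missing contribute a factor 1; a half-missing locus
is not representable as a genotype and is skipped with a warning.

## Synthetic frequency panels

No published population table is bundled.  `synthesize_frequency_table`
draws per-locus frequencies from a symmetric Dirichlet; the defaults
(21 loci, 8 consecutive integer alleles from 8, concentration 1.0) give a
mean expected heterozygosity of ≈ 0.78, matching the autosomal loci of
common forensic multiplexes in locus count, attribute geometry (42 slots,
maximum IBS 42) and discriminating power.  What the synthetic panel does
*not* emulate: microvariant alleles (the loader accepts designations such
as 12.3, the generator does not produce them), locus-specific allele-count
differences, and the exact shape of any published frequency distribution —
absolute IBS histogram shapes for unrelated pairs therefore differ slightly
from those computed on a real population table, while rates, separations
and accuracies at the thresholds used here are insensitive to this choice.
Real panels load from a 3-column TSV (`locus allele frequency`), with
per-locus renormalization when raw sums are within 2% of 1 (published
tables are rounded) and rejection beyond that.

## Evaluation harness and problem sizes

`run_scenario` repeats: simulate genotypes → simulate and pool cells →
estimate NOC → (if correct) consensus, matching, accuracy; all randomness
derives from one scenario seed via spawned generator streams, so results
are exactly reproducible.  NOC accuracy gets a 95% Wilson interval;
consensus accuracy a normal-approximation interval over replicate means.

The packaged acceptance run uses 200 replicates for the (80, 80) scenario
and 500 for (20, 20) — at measured accuracies near 100% these already bound
the accuracy above 99% at 95% confidence, and a replicate costs ~0.1 s, so
the harness stays desk-scale; `--replicates` scales any scenario up.
Simulation studies over the full scenario grid, stutter/degradation
modeling, >2-allele calls, lineage markers, and alternative model-selection
indices are out of scope.
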