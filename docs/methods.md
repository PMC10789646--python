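# Methods

`xlquant` implements the quantitative tail of a photo-cross-linking
interactome experiment: given MaxQuant-style protein-group tables from
paired UV-irradiated (+UV) and control (−UV) samples, it identifies
candidate covalently-trapped binding partners; given ITC injection heats,
it fits the one-site binding model used to validate individual partners;
given called ChIP-seq peaks, it summarizes genomic colocalization.  Each
stage has a matched synthetic-data generator with ground-truth labels, so
the whole chain is benchmarkable without external data.

## Proteomics enrichment

**Entry filtering.** Rows flagged as potential contaminants or reversed
decoys are removed; rows flagged only-identified-by-site are retained.  An
entry carrying both flags is removed once and logged as a decoy.

**Shared-peptide grouping.** Two entries are linked when they share more
than 30% of their peptides; groups are the connected components of the
sharing graph (single linkage, so merging is transitive).  The denominator
of "their peptides" is ambiguous for sets of unequal size; the default
`min_set` rule (intersection over the smaller set) merges fragment/subset
entries, which is the usual intent of parsimony-style grouping, and a
`jaccard` rule is available.  The threshold comparison is strict (a pair at
exactly 0.30 does not merge).  Member intensities are pooled by per-sample
summation (keeping the representative's values is available as an option);
the representative is the member with the largest summed iBAQ, ties broken
lexicographically.  The implementation is checked against a brute-force
all-pairs merge-to-fixpoint oracle on random instances.

**riBAQ.** A group is *present* in a condition only if its iBAQ is positive
in every replicate of that condition (the both-replicates rule).  Groups
present in neither condition are dropped.  Each sample column is normalized
over the groups retained for that sample's condition, so riBAQ is
compositional: every column sums to 1.  Normalization is per run, not per
condition pool, matching the conventional definition of relative iBAQ.  No
pseudocounts are used anywhere; the presence rule guarantees positivity
wherever logarithms are taken.

**Classification.** Groups present in +UV with zero intensity in *every*
−UV replicate are `exclusive_plus` (and symmetrically `exclusive_minus`);
these are the strongest cross-linking candidates and carry no finite fold
or p-value.  Groups present in both conditions are tested: fold enrichment
is mean riBAQ(+UV) / mean riBAQ(−UV) on the linear scale, and a two-sided
two-sample t-test runs on log2 riBAQ (log transformation stabilizes the
multiplicative replicate noise).  A group is `common_enriched` at
p ≤ 0.05 and fold ≥ 2, `common_depleted` at p ≤ 0.05 and fold ≤ 0.5, else
`common_ns`.  The "fold change ∼2" criterion is implemented as a hard,
configurable cutoff at 2.0.  A group present in one condition whose
opposite-condition replicates are only partially detected (one zero, one
positive) is neither exclusive nor testable; it is reported as `common_ns`
with undefined fold/p so the five categories still partition every analyzed
group.

**Choice of t-test.** The default is Student's pooled-variance t-test.
With two replicates per condition — the design this package targets — the
Welch test's Satterthwaite degrees-of-freedom estimate makes it markedly
conservative: on Gaussian null data its empirical size is ≈0.02 at nominal
0.05, which costs roughly 15 percentage points of sensitivity in the
spike-in benchmark.  Student's t has empirical size ≈0.047 under the same
null and is the test used by the mainstream MaxQuant/Perseus workflow.
Welch remains available via `EnrichmentConfig(test="welch")` for designs
with more replicates and genuinely unequal variances.  No multiple-testing
correction is applied by default, matching the raw p ≤ 0.05 rule this kind
of screen reports; a Benjamini–Hochberg option exists.

## One-site ITC model

The forward model is the standard one-set-of-sites isotherm for a perfusion
cell.  With cumulative injected volume `dV` into a cell of volume `V0`, the
displaced-volume correction gives active concentrations

    Mt = M0 (1 − dV/2V0) / (1 + dV/2V0)
    Xt = X0 (dV/V0)      / (1 + dV/2V0)

The bound-site fraction Θ is the physical root of the mass-action
quadratic in Θ with association constant Ka = 1/Kd and stoichiometry N;
cumulative heat is Q = N·Θ·Mt·ΔH·V0 and the per-injection heat corrects
for liquid expelled during the injection,
ΔQᵢ = Qᵢ − Qᵢ₋₁ + (vᵢ/V0)(Qᵢ + Qᵢ₋₁)/2, plus a constant molar dilution-heat
offset per mole of injectant (a blank-titration subtraction is deliberately
not the default; the offset absorbs the same effect with one parameter).
The quadratic root is verified against bisection on the binding polynomial.

Units are μM, μl, μcal and kcal/mol throughout (kcal, not kJ, is the
convention in the bromodomain ITC literature).  The default protocol is one
0.4 μl priming injection followed by 18 × 2 μl injections into a 200 μl
cell at 288.15 K, syringe 1600 μM and cell 90 μM — mid-range of the
1.5–1.8 mM / 80–100 μM setup typical for acetylpeptide-bromodomain
titrations.  The priming injection is flagged and excluded from all fits,
as instrument practice dictates.

**Fitting.** Nonlinear least squares on the molar heats of the
non-discarded injections over (N, Kd, ΔH, offset), via a bounded
trust-region method.  Internally the optimizer works on log10 Kd (bounds
N ∈ [0.1, 10], log10 Kd ∈ [−3, 5]); the logarithmic scale conditions the
shallow low-c regime (c = N·M0/Kd ≈ 0.3 for a 250 μM binder at 90 μM cell
concentration), where the transition is broad and Kd and ΔH are strongly
correlated.  When no initial guess is supplied, plateau heuristics set ΔH
and the offset, the half-amplitude molar ratio sets N, and the fit is
multi-started over tight/moderate/shallow Kd regimes, keeping the lowest
SSE.  Convergence tolerances are 1e-15 (relative SSE and step), and
noise-free round trips recover parameters to ~1e-10 relative.  Isotherms
whose amplitude is below three times a trend-insensitive point-noise
estimate (from median absolute second differences) are refused as flat —
a fit to such data would return arbitrary parameters.  Standard errors come
from the local quadratic approximation (J'J inverse scaled by residual
variance, delta method for the log-Kd variable); ±2 SE intervals cover the
truth in ≥80% of noisy simulations at 0.5 μcal noise.

Derived quantities: ΔG = RT·ln(Kd·10⁻⁶) with R = 1.9872×10⁻³ kcal/mol/K,
and −TΔS = ΔG − ΔH.

## Peak colocalization

Coordinates are 0-based half-open (BED) everywhere; GFF-style 1-based input
must be converted at the boundary.  The overlap predicate is ≥1 bp
intersection, with no reciprocal-fraction requirement.  `overlap_fraction`
reports the fraction of *anchor* peaks intersecting the merged other set
and is asymmetric by design — both directions are meaningful and the caller
picks the anchor.  Peak-level three-set Venn counts are inherently
anchor-dependent (peaks of different sets need not correspond one-to-one),
so `venn3` reports all three anchor perspectives instead of pretending a
unique 7-region diagram exists.

`tss_matrix` averages binned signal over [TSS − flank, TSS + flank)
(default ±5 kb, 50 bp bins; a ±3 kb variant is the same operation with
`flank=3000`), reverses minus-strand rows so column 0 is always 5′-most,
zero-pads and flags windows that cross chromosome ends, and sorts rows by
descending mean signal with a stable sort (input order breaks ties) —
the input of a tornado plot plus its mean-profile line graph.
`signal_correlation` concatenates genome-wide bin vectors and reports
Pearson or Spearman matrices; zero-variance tracks yield missing values
with a warning rather than an arbitrary number.  Interval queries use
binary search over merged per-chromosome interval arrays and are verified
against quadratic per-peak scans.

## Synthetic data

The proteomics generator emulates the ±UV design: baseline abundances are
log-normal (natural-log mean 14, sd 1.5 — a plausible iBAQ dynamic range of
~4 orders of magnitude), replicate noise is log-normal with CV 25%, and
true interactors receive an 8-fold +UV multiplier.  Default cohort sizes
(800 background, 50 true interactors, 40 +UV-exclusive, 20 contaminants,
10 decoys, 2 replicates per condition) mirror a single-bait cross-linking
screen in which a few percent of detected proteins are genuine partners.
Dropout is logistic in log abundance (midpoint 10.5, slope 1.5 — ~1% of
baseline-abundance proteins lose a measurement, rising steeply for the
low-abundance tail), applied after enrichment so exclusivity can arise both
by construction and stochastically.  Designated peptide-sharing pairs are
built to exceed the 30% grouping threshold.  The generator does not emulate
ratio compression, peptide-level missingness structure, or batch effects,
so passing benchmarks demonstrate correctness of the statistical chain, not
performance on any specific instrument's data.

The ITC generator adds Gaussian noise (default 0.5 μcal) to the forward
model's raw heats.  The peak generator draws latent sites uniformly on a
toy genome (default 1 Mb) and includes each in a set with a per-set
probability, giving direct control of pairwise co-occurrence; tracks are
rectangular bumps plus Gaussian bin noise.  On a crowded genome incidental
collisions add to the observed overlap, so co-occurrence calibration checks
run on a sparse 10 Mb genome where that term is negligible.

All generators are pure functions of (config, seed) and their outputs
round-trip through the package's readers byte-exactly.

## Benchmark scales

The shipped checks use desk-scale problems chosen to exercise every code
path: ≤ 1000 proteins per cohort, 20 seeds for spike-in recovery, 50 seeds
for noisy ITC recovery, 50 random peak-set triples and 100 random grouping
instances against brute-force oracles.  At these scales the full suite and
the acceptance script each complete in well under five minutes on one core.

## Known limitations

- Protein inference is single-linkage sharing-graph grouping, not Occam
  set-cover parsimony; highly ambiguous peptide evidence can chain distinct
  proteins into one group.
- The enrichment test assumes approximately log-normal riBAQ within
  condition; with n = 2 its power rests on that assumption.
- The ITC module fits integrated injection heats; it does not integrate raw
  power thermograms, and offers no competitive or multi-site models.
- Colocalization operates on called peaks and binned tracks; peak calling,
  IDR and blacklist filtering are upstream of this package.
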