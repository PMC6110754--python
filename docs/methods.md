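# Methods

This note documents the models and procedures `nrf2atlas` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohorts do and do not emulate.

## Consensus mutation cataloguing

Somatic calls are keyed by (case barcode, gene, chromosome, position, ref,
alt); case identity is the first 12 characters of the TCGA-style barcode.
`merge_caller_calls` unions the reporting callers per key and keeps keys
reported by at least `min_callers` (default 2) of {MuSE, MuTect2,
SomaticSniper, VarScan2}. Duplicate keys within one caller's table are
deduplicated with a warning; the output is monotone in `min_callers`.

Variant classes map the MAF `Variant_Classification` vocabulary
(Missense/Nonsense/Frame_Shift_*/In_Frame_*/Splice_Site/Silent → missense/
nonsense/frameshift/inframe_indel/splice/silent, anything else → other).
"Non-synonymous" means every protein-altering class, i.e. all but silent
and other. Transitions are substitutions within {A,G} or {C,T}; everything
else is a transversion; the classification is invariant under joint
complementation (strand flips).

Burden counts mutation *events* per case, not unique positions; indels are
counted in the total but left unclassified on the transition/transversion
axis. The active-vs-inactive burden comparison uses a two-sided
Mann–Whitney U per tumor type (the original analysis reports significance
of medians without naming a test; Mann–Whitney is this package's choice):
the exact U distribution when both groups have ≤ 8 cases and no ties, the
normal approximation with tie correction otherwise, BH-adjusted across
types. Constant burdens give p = 1.

Set overlap offers an exact mode (hypergeometric upper tail P(X ≥ k)) and a
Monte-Carlo mode that samples the overlap of random same-size subsets and
applies (b+1)/(m+1); both report the chance expectation |A||B|/N. Sampling
is unconditional on tumor-type composition (stratified sampling is out of
scope). Correlation p-values use the Fisher transform: z = atanh(r),
p = 2·Φ(−|z|·√(n−3)), requiring n ≥ 4 pairs; zero-variance inputs return an
absent correlation with a warning.

## Monte-Carlo positional enrichment

The permutation estimator is p̂ = (b+1)/(m+1), where b counts permutations
whose statistic reaches the observed value; its floor 1/(m+1) reflects that
the observed arrangement is itself one of m+1 exchangeable ones. The
original analysis used m = 5×10⁶; the package default is m = 10⁵, which
resolves q-values comfortably below 0.05 for desk-scale scans (the floor is
10⁻⁵), with m configurable wherever the estimator appears.

The positional null redistributes the gene's n pooled events independently
and uniformly over its L codons (what exactly was permuted in the original
analysis is unstated; pooled events over a uniform codon null is the
simplest null consistent with counting "enrichment frequency greater than
or equal to that observed"). Only positions with ≥ 1 observed event are
tested and enter the BH family — zero-count positions can never be enriched
and would only dilute the correction; the family is per-gene. For speed the
joint null counts at the T tested positions are drawn per permutation as a
single multinomial over T+1 cells (each tested position has probability
1/L, plus a rest cell); results depend only on (seed, m, counts), not on
internal batching, which is asserted by test.

Tumor-type enrichment at a position draws k cases without replacement from
the gene's mutant pool (a multivariate hypergeometric over types) m times;
the hotspot transversion-bias test is a one-sided Fisher exact test on the
2×2 table (hotspot vs elsewhere) × (transversion vs transition).

## Signature derivation

**VST.** Size factors are median-of-ratios against the per-gene geometric
mean reference, computed on genes nonzero in every sample, with the
conventional geometric-mean-1 normalization; transformed values are
log2(count/size_factor + 1). If no gene covers all samples the transform
falls back to total-count scaling with a warning. The global count scale is
unidentifiable: scaling all samples jointly shifts the transform, scaling
samples relative to each other does not change it.

**DE filter.** The differential-expression stage is pluggable: the built-in
test is per-gene Welch t on the transformed values with BH across genes,
keeping q < 0.05 and |mean difference| ≥ 2.5 log2 units; a table from an
external DE engine (e.g. a count-model fit) can be passed through the
`de_table` adapter and is subjected to the same thresholds. The package
deliberately does not reimplement shrinkage-based count models — the
downstream ranking and selection are the contribution, and they consume
only a gene list.

**|d_r| ranking.** d_r is the difference in mean transformed expression
between the two tumor types, computed over the training *tumors* only
(whether the original computation used tumors, normals, or both is
unstated; tumors-only is chosen because the ranking's purpose is to keep
tumor-type structure out of the tumor signature, and normals carry their
own type structure). Genes sort ascending by |d_r|, ties by name, so the
least type-confounded genes lead.

**MLS and sequential selection.** For k = 2…k_max the top-k ranked genes
define the feature space; training samples are Ward-clustered and cut at
two clusters; MLS = L_Inter/L_Intra is recorded; the selected signature is
the prefix maximizing MLS, smallest k on ties (parsimony). L_Intra is the
mean over clusters of the mean within-cluster pairwise Euclidean distance,
singletons excluded; L_Intra = 0 yields an infinite score, reported as a
sentinel. For L_Inter two readings of "the intergroup distance between
normal and tumor cases" were candidates: the distance between group
centroids, and the minimum normal–tumor pair distance (the separation
margin). The margin is the default. The reason is structural: with the
centroid reading, both numerator and denominator grow as √k when genes are
added, so the expected score is flat in gene-set size and the argmax
degenerates toward k = 2 even on designs where a larger complementary gene
set is plainly required to separate the groups; the margin rises only while
added genes separate tumors that previous genes left among the normals, so
the trace has an interior maximum at a complementary informative set and
declines once type-biased or noise genes enter — the behavior the
sequential procedure presupposes. The centroid reading remains available
via `mls_score(..., inter="centroid")`.

A consequence worth stating: when every informative gene separates the
groups on its own (homogeneous planted effects), no reading of MLS prefers
the full gene set over a small subset — the trace is flat and the
smallest-k tie rule selects a minimal separating subset. Full-set recovery
is only expected when the genes are complementary (each capturing different
samples), which is also the regime the method was designed for.

## Stratification

Ward k=3 clustering on the signature genes (Euclidean, cut at three
clusters, deterministic and order-invariant up to label renaming). G1 is
the cluster with the highest normal-tissue fraction; of the remaining two,
G2 has the higher mean signature expression (up-regulated signature genes
when effect signs are available, all signature genes otherwise) and G3 the
lower; ties break deterministically (larger cluster → G3) with a warning.
Mutant enrichment in G2 versus G3 is a one-sided Fisher exact test (the
original analysis does not name its test; Fisher is chosen for determinism,
and the Monte-Carlo machinery is available as an alternative), run for any
mutant case set — per gene, or position-restricted carriers.

## Codon spectra

Every codon has nine single-nucleotide neighbors, enumerated against the
standard genetic code (translation table 1; human nuclear genes) and
classified synonymous/missense/nonsense. The spectrum-bias null assigns
each of the nine substitutions equal probability 1/9 (a
transition/transversion-weighted null with weight κ on transitions is
available, since hotspots are transversion-enriched; the unweighted null is
the default for interpretability), aggregates substitutions to amino-acid
outcomes, and distributes the n observed events multinomially. Per outcome,
enrichment uses the upper tail and depletion the lower tail of the
Monte-Carlo estimator, BH across non-stop outcomes; stop gains are reported
but excluded from testing. Multi-nucleotide codon changes are outside the
null and rejected.

## Half-life kinetics

Chase series (≥ 3 timepoints, positive intensities) are fit by ordinary
least squares of ln(intensity) on time: λ = −slope, N₀ = exp(intercept),
t½ = ln 2/λ. The log-linear fit is closed-form, deterministic, and exact on
noiseless data; a nonlinear raw-scale fit seeded by the log-linear estimate
sits behind a flag. Non-decaying series (slope ≥ 0) are flagged rather than
given a negative rate. Each replicate is fit separately and constructs are
compared on replicate half-lives with a two-tailed Welch t-test (the
equal-variance test is available via `pooled=True`); per-replicate fitting
matches reporting a mean ± SD over biological replicates. The default
simulated timepoint grid is 0/30/60/90/120 minutes, matching half-hourly
harvests.

## Synthetic cohorts: what they emulate, and what they do not

`SimulationConfig` drives all stages from one seed; per-stage substreams
(mutations, expression, chase) are derived deterministically, so
regenerating one stage never perturbs another.

Mutations: true events per tumor case are Poisson(background_mutation_rate,
default 10 — a mid-range exome burden); each event picks a gene uniformly
among the configured proteins, a codon uniformly (or the planted hotspot
with the configured fraction), and a nucleotide change with
transition:transversion odds `tstv_odds` (default 2:1, the genome-wide
norm). Each caller reports each true event independently with probability
`caller_concordance` (default 0.9); spurious calls are Poisson per case,
always carry exactly one caller flag, and occupy sites distinct from all
other calls, so the ≥2-caller filter removes exactly the spurious set when
concordance is 1 — which is what makes the filter checkable against planted
truth. A fraction of non-hotspot events (default 5%) is emitted silent so
non-synonymous filters have something to filter. Protein changes are
emitted as `p.<ref><pos><alt>` single-letter HGVSp-short strings over a
deterministic pseudo protein sequence per gene.

Expression: counts are negative binomial parameterized by mean and
dispersion α with variance μ + αμ² (default α = 0.1, between technical
replication and the heavier inter-patient dispersion of real cohorts);
baselines are log-normal around 500 counts. Activated tumors gain the
activation log2 effect on the signature-true genes; batch genes gain a
per-tumor-type log2 offset in every sample of that type; the two gene sets
must be disjoint. The `activated` flag can be assigned preferentially to
hotspot-gene mutant cases (`activate_mutants_first`), coupling genotype to
expression the way gain-of-function mutations do. `balanced_types` assigns
exact per-type sample counts (largest remainder) instead of i.i.d. draws,
matching balanced training designs such as 12 tumors and 12 normals split
6/6 across two types.

Chase: intensities are N₀·2^(−t/t½) with multiplicative lognormal noise per
timepoint.

Not emulated: real genomic coordinates, trinucleotide mutational
signatures, copy number, isoform structure, gene–gene correlation in
expression, per-case activation-strength heterogeneity, and library-size
variation beyond what the NB draws induce. Consequently, passing tests on
these cohorts demonstrate the correctness and calibration of the
statistical machinery and the recoverability of planted structure — not
robustness to the full heterogeneity of patient data.

## Numerical choices and problem sizes

Monte-Carlo defaults are m = 10⁵ per estimate; simulation-based checks use
cohorts of 12–200 cases, 80–300 genes, 20 seeds for recovery rates, and 500
cohorts for type-I calibration at m = 999 — sizes chosen so the full suite
and the acceptance script each run in seconds to a few minutes on one core
while leaving the binomial error bars meaningfully narrow. BH uses the
standard step-up with q capped at 1, returned in input order. Degenerate
inputs are handled explicitly: empty 2×2 margins give p = 1 with a warning,
zero-variance correlations are absent with a warning, all-tied burden
comparisons give p = 1, non-decaying chase series are flagged, and the
Monte-Carlo estimator never returns 0.
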