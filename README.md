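# nrf2atlas

Somatic gain-of-function mutations in *NFE2L2* (encoding the NRF2
transcription factor) and loss-of-function mutations in its negative
regulator *KEAP1* drive a constitutive antioxidant transcriptional program
in many carcinogen-exposed tumor types. `nrf2atlas` implements, as a tested
and reusable Python library, the computational pipeline used to
characterize such mutations in a TCGA-style cohort:

- **Consensus mutation cataloguing** — merge calls from the four TCGA
  somatic callers (MuSE, MuTect2, SomaticSniper, VarScan2) and keep sites
  reported by at least two; classify substitutions as transitions or
  transversions; per-case burden; hypergeometric/Monte-Carlo overlap of
  mutant case sets; Mann–Whitney burden comparisons; Pearson correlations
  with Fisher-transform p-values.
- **Positional hotspot enrichment** — for a gene of length *L* codons with
  *n* observed events, the null redistributes the *n* events uniformly over
  codons; per-position permutation p-values use the Monte-Carlo estimator
  *P(b) = (b+1)/(m+1)*, with Benjamini–Hochberg adjustment across tested
  positions. Tumor-type-restricted enrichment and hotspot transversion-bias
  tests use the same machinery.
- **Activation-signature derivation** — variance-stabilizing transform
  (median-of-ratios size factors, log2), a pluggable differential-expression
  filter (built-in: Welch t with BH, q < 0.05 and |log2 FC| ≥ 2.5), ranking
  by the tumor-type bias |d_r| (ascending), and sequential Ward clustering
  that adds one gene per iteration and scores each gene set with
  *MLS = L_Inter / L_Intra*; the signature is the gene set maximizing MLS.
- **Cohort stratification** — Ward's minimum-variance clustering on the
  signature genes, cut into three groups: G1 (normal tissue), G2
  (NRF2-active tumors, higher mean signature expression), G3 (inactive);
  one-sided Fisher tests for mutant enrichment in G2 versus G3.
- **Codon substitution spectra** — enumeration of the nine single-nucleotide
  neighbors of a codon against the standard genetic code (e.g. arginine's
  CGA reaches exactly the missense set {G, Q, P, L}), with Monte-Carlo
  enrichment/depletion tests of observed variant spectra.
- **Half-life kinetics** — log-linear fits of cycloheximide-chase
  densitometry to *N(t) = N₀ e^(−λt)*, *t½ = ln 2 / λ*, and Welch t-tests
  between constructs.
- **Synthetic cohorts** — a first-class, seeded generator for all of the
  above: per-caller call tables with controllable concordance, planted
  hotspots, negative-binomial counts with planted activation and batch
  structure, and noisy exponential chase series.

## Worked example

Fit half-lives from a simulated chase experiment (three constructs, three
replicates, 10% multiplicative noise; `examples/07_halflife.py`):

```text
           mean  std
construct
E82G       53.6  4.7
R34L       21.3  0.4
WT         15.0  0.2
R34L vs WT: 21.3±0.4 vs 15.0±0.2 min, p = 0.000223
E82G vs WT: 53.6±4.7 vs 15.0±0.2 min, p = 0.00478
```

The constructs were simulated with true half-lives 15, 22, and 58 minutes;
the per-replicate log-linear fits recover them within noise, and both
mutants are significantly more stable than wild type.

Scan a gene for hotspots (`examples/03_hotspot_scan.py`, planted hotspot at
codon 34 receiving 40% of events):

```text
top positions (position, observed, p_hat, q):
    34  261 1.00e-05 2.90e-03
   575    4 2.42e-02 6.67e-01
```

The planted codon attains the Monte-Carlo floor p̂ = 1/(m+1) at m = 10⁵ and
is the only position significant after BH adjustment.

The other capabilities each have a short narrative script under
`examples/`: cohort simulation, consensus filtering and burden, signature
derivation, stratification, and codon spectra. A thin CLI mirrors the
pipeline stages:

```bash
nrf2atlas simulate --config config.yaml --outdir out/
nrf2atlas catalogue --mafs out/mutations.maf.tsv --min-callers 2 --out consensus.tsv
nrf2atlas hotspots --consensus consensus.tsv --gene NFE2L2 --length 605 \
    --m 100000 --seed 7 --out hotspots.tsv
```

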