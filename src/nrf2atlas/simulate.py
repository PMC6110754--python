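"""Synthetic TCGA-like cohort generator.

Produces the four inputs the analysis stages consume — per-caller somatic
mutation tables, a sample sheet, a gene-by-sample count matrix, and
cycloheximide-chase densitometry series — with the statistical structure the
downstream methods assume:

* true mutation events per tumor case are Poisson distributed, each event is
  reported independently by each of four callers with a common concordance
  probability, and spurious artifact calls carry exactly one caller flag;
* one gene may carry a planted per-residue hotspot receiving a fixed fraction
  of that gene's events;
* RNA-seq counts are negative binomial with a planted log2 activation effect
  on a signature gene set in "activated" tumors plus a per-tumor-type batch
  offset on a disjoint gene set;
* chase intensities decay exponentially with multiplicative lognormal noise.

One global seed drives everything; each stage draws from a deterministic
substream so that, e.g., regenerating expression does not perturb mutations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CALLERS = ("MuSE", "MuTect2", "SomaticSniper", "VarScan2")

_BASES = np.array(["A", "C", "G", "T"])
# transition partner of each base, and the two transversion alternatives
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# substream ids — fixed so that stages are individually reproducible
_STREAM_MUTATIONS = 1
_STREAM_EXPRESSION = 2
_STREAM_CHASE = 3


@dataclass(frozen=True)
class HotspotSpec:
    """A planted per-residue hotspot.

    ``fraction`` of the ``gene``'s events land on codon ``position``; the
    rest are uniform over the protein. ``spectrum`` optionally fixes the
    relative frequencies of alternate amino acids at the hotspot (e.g.
    ``{"G": 2, "P": 1, "Q": 1}``).
    """

    gene: str
    position: int
    fraction: float
    spectrum: Mapping[str, float] | None = None


@dataclass(frozen=True)
class ActivationSpec:
    """Planted activation program: ``genes`` gain ``log2_effect`` in the
    ``fraction`` of tumors flagged as activated."""

    genes: tuple[str, ...]
    log2_effect: float
    fraction: float


@dataclass(frozen=True)
class BatchSpec:
    """Per-tumor-type batch structure: ``genes`` are offset by
    ``offset_by_type[t]`` log2 units in every sample of tumor type ``t``."""

    genes: tuple[str, ...]
    offset_by_type: Mapping[str, float]


@dataclass(frozen=True)
class ChaseSpec:
    """Chase-series design: true half-lives (minutes) per construct, the
    shared timepoint grid, multiplicative lognormal noise sd, replicates."""

    half_lives: Mapping[str, float]
    timepoints: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0)
    noise_sd: float = 0.1
    replicates: int = 3


@dataclass
class SimulationConfig:
    """Single seeded configuration for all synthetic stages.

    Parameters
    ----------
    seed
        Global seed; per-stage substreams are derived deterministically.
    n_cases, n_normals
        Tumor cases and normal-tissue samples in the cohort.
    tumor_types
        Mapping of tumor-type code to cohort proportion (sums to 1).
    n_genes
        Genes in the expression matrix (activation and batch genes included).
    protein_length_by_gene
        Protein length in codons for each gene that receives mutation calls.
    hotspot_spec, activation_spec, batch_spec, chase_spec
        Planted structure; each may be ``None`` to disable that feature.
    caller_concordance
        Probability each of the 4 callers reports a true event, independently.
    spurious_rate
        Mean spurious singleton calls per case (always exactly 1 caller flag).
    background_mutation_rate
        Mean true events per tumor case (Poisson).
    tstv_odds
        Transition:transversion odds for substitution draws.
    silent_fraction
        Fraction of non-hotspot events emitted as synonymous (Silent) calls.
    nb_dispersion
        Negative-binomial dispersion alpha, variance = mu + alpha * mu**2.
    activate_mutants_first
        Assign the activated flag preferentially to hotspot-gene mutant cases
        so that mutation status and expression activation are coupled.
    """

    seed: int
    n_cases: int = 200
    tumor_types: Mapping[str, float] = field(
        default_factory=lambda: {"LUAD": 0.5, "LUSC": 0.5}
    )
    n_genes: int = 300
    protein_length_by_gene: Mapping[str, int] = field(
        default_factory=lambda: {"NFE2L2": 605, "KEAP1": 624, "TP53": 393}
    )
    hotspot_spec: HotspotSpec | None = None
    caller_concordance: float = 0.9
    spurious_rate: float = 0.5
    background_mutation_rate: float = 10.0
    tstv_odds: float = 2.0
    silent_fraction: float = 0.05
    n_normals: int = 0
    activation_spec: ActivationSpec | None = None
    batch_spec: BatchSpec | None = None
    nb_dispersion: float = 0.1
    chase_spec: ChaseSpec | None = None
    activate_mutants_first: bool = True
    balanced_types: bool = False  # exact per-type counts (training designs)

    def __post_init__(self) -> None:
        props = np.asarray(list(self.tumor_types.values()), dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("tumor type proportions must sum to 1 within 1e-9")
        if self.n_cases <= 0 or self.n_genes <= 0:
            raise ValueError("n_cases and n_genes must be strictly positive")
        if self.n_normals < 0:
            raise ValueError("n_normals must be non-negative")
        if self.background_mutation_rate <= 0:
            raise ValueError("background_mutation_rate must be strictly positive")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be non-negative")
        if not 0.0 <= self.caller_concordance <= 1.0:
            raise ValueError("caller_concordance must lie in [0, 1]")
        if not 0.0 <= self.silent_fraction <= 1.0:
            raise ValueError("silent_fraction must lie in [0, 1]")
        if self.tstv_odds <= 0:
            raise ValueError("tstv_odds must be strictly positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be strictly positive")
        for gene, length in self.protein_length_by_gene.items():
            if length <= 0:
                raise ValueError(f"protein length for {gene} must be positive")
        hs = self.hotspot_spec
        if hs is not None:
            if hs.gene not in self.protein_length_by_gene:
                raise ValueError(f"hotspot gene {hs.gene!r} has no protein length")
            if not 1 <= hs.position <= self.protein_length_by_gene[hs.gene]:
                raise ValueError(
                    "hotspot position exceeds protein length "
                    f"({hs.position} > {self.protein_length_by_gene[hs.gene]})"
                )
            if not 0.0 <= hs.fraction <= 1.0:
                raise ValueError("hotspot fraction must lie in [0, 1]")
        act = self.activation_spec
        if act is not None and not 0.0 <= act.fraction <= 1.0:
            raise ValueError("activation fraction must lie in [0, 1]")
        if act is not None and self.batch_spec is not None:
            shared = set(act.genes) & set(self.batch_spec.genes)
            if shared:
                raise ValueError(
                    f"activation and batch gene sets must be disjoint; shared: {sorted(shared)}"
                )
        cs = self.chase_spec
        if cs is not None:
            if len(cs.timepoints) < 3:
                raise ValueError("chase needs >= 3 timepoints (fit underdetermined)")
            if any(t <= 0 for t in cs.half_lives.values()):
                raise ValueError("true half-lives must be strictly positive")
            if cs.replicates < 1:
                raise ValueError("chase needs >= 1 replicate")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic substream generator for one stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )

    def expression_genes(self) -> list[str]:
        """Gene universe of the count matrix: planted sets first, filler after."""
        planted: list[str] = []
        if self.activation_spec is not None:
            planted.extend(self.activation_spec.genes)
        if self.batch_spec is not None:
            planted.extend(self.batch_spec.genes)
        if len(planted) > self.n_genes:
            raise ValueError("n_genes smaller than the planted gene sets")
        filler = [f"GENE{i:05d}" for i in range(self.n_genes - len(planted))]
        return planted + filler


def _exact_type_counts(types, props, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n samples over the type codes."""
    raw = np.asarray(props) * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for i in range(n - counts.sum()):
        counts[order[i % len(types)]] += 1
    return np.repeat(types, counts)


def _protein_sequence(gene: str, length: int) -> np.ndarray:
    """Deterministic pseudo amino-acid sequence for a gene (stable across
    runs and configs: keyed on the gene name only)."""
    rng = np.random.default_rng(zlib.crc32(gene.encode()) & 0x7FFFFFFF)
    return rng.choice(_AA20, size=length)


def _draw_substitution(rng: np.random.Generator, tstv_odds: float) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    if rng.random() < tstv_odds / (tstv_odds + 1.0):
        return ref, _TRANSITION[ref]
    return ref, _TRANSVERSIONS[ref][int(rng.integers(2))]


@dataclass
class SimulatedMutations:
    """Mutation-stage output: aggregated MAF-like table with a semicolon
    ``callers`` column, the sample sheet, and the planted truth keys."""

    maf: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame  # true events, one row each, regardless of caller reporting


_MAF_KEY = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome",
            "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2"]


def simulate_mutations(config: SimulationConfig) -> SimulatedMutations:
    """Generate the somatic mutation calls and the cohort sample sheet.

    Each tumor case receives Poisson(background_mutation_rate) true events.
    An event in the hotspot gene lands on the planted codon with the planted
    fraction, otherwise uniformly over codons. Each true event is reported by
    each of the four callers independently with probability
    ``caller_concordance`` (events no caller reports stay in the truth table
    but are absent from the call table). Spurious singleton calls — exactly
    one caller flag each, at sites distinct from all other calls — are added
    at Poisson(spurious_rate) per case, so the >=2-caller consensus filter
    removes exactly the spurious set when concordance is 1.
    """
    rng = config.rng(_STREAM_MUTATIONS)
    genes = list(config.protein_length_by_gene)
    seqs = {g: _protein_sequence(g, L) for g, L in config.protein_length_by_gene.items()}
    # pseudo genomic layout: one chromosome slot and base offset per gene
    chrom = {g: f"chr{1 + i % 22}" for i, g in enumerate(genes)}
    gstart = {g: 1_000_000 * (i + 1) for i, g in enumerate(genes)}
    hs = config.hotspot_spec

    # --- sample sheet (tumors) ---
    types = list(config.tumor_types)
    props = np.asarray([config.tumor_types[t] for t in types], dtype=float)
    case_ids = [f"TCGA-SY-{i:04d}" for i in range(config.n_cases)]
    if config.balanced_types:
        case_types = rng.permutation(_exact_type_counts(types, props, config.n_cases))
    else:
        case_types = rng.choice(types, size=config.n_cases, p=props)

    rows: list[dict] = []
    truth_rows: list[dict] = []
    seen_keys: set[tuple] = set()

    n_events = rng.poisson(config.background_mutation_rate, size=config.n_cases)
    for case, ttype, k in zip(case_ids, case_types, n_events):
        for _ in range(int(k)):
            gene = genes[int(rng.integers(len(genes)))]
            L = config.protein_length_by_gene[gene]
            if hs is not None and gene == hs.gene and rng.random() < hs.fraction:
                pos = hs.position
                at_hotspot = True
            else:
                pos = int(rng.integers(1, L + 1))
                at_hotspot = False
            # avoid key collisions (same case/site/ref/alt) by redrawing the
            # nucleotide change; keeps positions (and the hotspot fraction) intact
            for _attempt in range(20):
                ref_nt, alt_nt = _draw_substitution(rng, config.tstv_odds)
                site_key = (case, gene, pos, ref_nt, alt_nt)
                if site_key not in seen_keys:
                    break
            seen_keys.add(site_key)
            ref_aa = str(seqs[gene][pos - 1])
            if at_hotspot and hs.spectrum is not None:
                alts = list(hs.spectrum)
                w = np.asarray([hs.spectrum[a] for a in alts], dtype=float)
                alt_aa = str(rng.choice(alts, p=w / w.sum()))
                silent = False
            elif not at_hotspot and rng.random() < config.silent_fraction:
                alt_aa = ref_aa
                silent = True
            else:
                alt_aa = str(rng.choice(_AA20[_AA20 != ref_aa]))
                silent = False
            flags = rng.random(4) < config.caller_concordance
            rec = {
                "Tumor_Sample_Barcode": case,
                "tumor_type": ttype,
                "Hugo_Symbol": gene,
                "Chromosome": chrom[gene],
                "Start_Position": gstart[gene] + 3 * pos,
                "Reference_Allele": ref_nt,
                "Tumor_Seq_Allele2": alt_nt,
                "Variant_Classification": "Silent" if silent else "Missense_Mutation",
                "HGVSp_Short": f"p.{ref_aa}{pos}{alt_aa}",
            }
            truth_rows.append(rec)
            if flags.any():
                rows.append(rec | {"callers": ";".join(c for c, f in zip(CALLERS, flags) if f)})

    # --- spurious singleton calls at sites distinct from every other call ---
    n_spur = rng.poisson(config.spurious_rate, size=config.n_cases)
    for case, ttype, k in zip(case_ids, case_types, n_spur):
        for _ in range(int(k)):
            for _attempt in range(100):
                gene = genes[int(rng.integers(len(genes)))]
                L = config.protein_length_by_gene[gene]
                pos = int(rng.integers(1, L + 1))
                ref_nt, alt_nt = _draw_substitution(rng, config.tstv_odds)
                site_key = (case, gene, pos, ref_nt, alt_nt)
                if site_key not in seen_keys:
                    break
            seen_keys.add(site_key)
            rec = {
                "Tumor_Sample_Barcode": case,
                "tumor_type": ttype,
                "Hugo_Symbol": gene,
                "Chromosome": chrom[gene],
                "Start_Position": gstart[gene] + 3 * pos,
                "Reference_Allele": ref_nt,
                "Tumor_Seq_Allele2": alt_nt,
            }
            ref_aa = str(seqs[gene][pos - 1])
            alt_aa = str(rng.choice(_AA20[_AA20 != ref_aa]))
            rows.append(rec | {
                "Variant_Classification": "Missense_Mutation",
                "HGVSp_Short": f"p.{ref_aa}{pos}{alt_aa}",
                "callers": str(rng.choice(CALLERS)),
            })

    columns = _MAF_KEY[:1] + ["tumor_type"] + _MAF_KEY[1:] + [
        "Variant_Classification", "HGVSp_Short", "callers"]
    # fixed column order; explicit empty frames so zero-event configs still work
    maf = pd.DataFrame(rows, columns=columns)
    truth = pd.DataFrame(truth_rows, columns=[c for c in columns if c != "callers"])

    sheet = pd.DataFrame({
        "case_id": case_ids,
        "tumor_type": case_types,
        "tissue": "tumor",
    })
    if config.n_normals:
        if config.balanced_types:
            norm_types = _exact_type_counts(types, props, config.n_normals)
        else:
            norm_types = np.repeat(types, rng.multinomial(config.n_normals, props))
        sheet = pd.concat([sheet, pd.DataFrame({
            "case_id": [f"TCGA-SN-{i:04d}" for i in range(config.n_normals)],
            "tumor_type": norm_types,
            "tissue": "normal",
        })], ignore_index=True)

    sheet["activated"] = False
    act = config.activation_spec
    if act is not None:
        tumor_idx = sheet.index[sheet["tissue"] == "tumor"]
        n_act = int(round(act.fraction * len(tumor_idx)))
        order = np.array(tumor_idx)
        if config.activate_mutants_first and hs is not None:
            nonsyn = truth[(truth["Hugo_Symbol"] == hs.gene)
                           & (truth["Variant_Classification"] != "Silent")]
            mutants = set(nonsyn["Tumor_Sample_Barcode"])
            is_mut = sheet.loc[tumor_idx, "case_id"].isin(mutants).to_numpy()
            mut_part = rng.permutation(order[is_mut])
            rest = rng.permutation(order[~is_mut])
            order = np.concatenate([mut_part, rest])
        else:
            order = rng.permutation(order)
        sheet.loc[order[:n_act], "activated"] = True

    return SimulatedMutations(maf=maf, sample_sheet=sheet, truth=truth)


def simulate_expression(
    sample_sheet: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Negative-binomial count matrix (genes x samples) for the sample sheet.

    Per-gene baseline means are log-normal. Signature-true genes gain the
    activation log2 effect in activated tumors; batch genes gain the
    per-tumor-type log2 offset in every sample of that type. Counts are
    NB(mean mu, variance mu + alpha*mu^2).
    """
    required = {"case_id", "tumor_type", "tissue", "activated"}
    missing = required - set(sample_sheet.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    rng = config.rng(_STREAM_EXPRESSION)
    genes = config.expression_genes()
    base = np.exp(rng.normal(np.log(500.0), 1.0, size=len(genes)))
    if not np.any(base > 0):
        raise ValueError("all-zero baseline means are forbidden")
    log2mu = np.log2(base)[:, None] * np.ones((1, len(sample_sheet)))

    act = config.activation_spec
    if act is not None:
        gi = np.asarray([g in set(act.genes) for g in genes])
        si = (sample_sheet["activated"] & (sample_sheet["tissue"] == "tumor")).to_numpy()
        log2mu[np.ix_(gi, si)] += act.log2_effect
    bat = config.batch_spec
    if bat is not None:
        gi = np.asarray([g in set(bat.genes) for g in genes])
        for ttype, off in bat.offset_by_type.items():
            si = (sample_sheet["tumor_type"] == ttype).to_numpy()
            log2mu[np.ix_(gi, si)] += off

    mu = np.exp2(log2mu)
    alpha = config.nb_dispersion
    n_param = 1.0 / alpha  # NB successes; variance = mu + alpha mu^2
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)
    return pd.DataFrame(counts, index=genes, columns=sample_sheet["case_id"].to_numpy())


def simulate_chase(config: SimulationConfig) -> pd.DataFrame:
    """Chase series: N0 * exp(-ln2 * t / t_half) with multiplicative
    lognormal noise, one row per (construct, replicate, timepoint)."""
    cs = config.chase_spec
    if cs is None:
        raise ValueError("config.chase_spec is not set")
    rng = config.rng(_STREAM_CHASE)
    t = np.asarray(cs.timepoints, dtype=float)
    rows = []
    n0 = 100.0
    for construct, thalf in cs.half_lives.items():
        for rep in range(1, cs.replicates + 1):
            clean = n0 * np.exp(-np.log(2.0) * t / thalf)
            noise = (np.exp(rng.normal(0.0, cs.noise_sd, size=t.size))
                     if cs.noise_sd > 0 else np.ones_like(t))
            for ti, yi in zip(t, clean * noise):
                rows.append({"construct": construct, "replicate": rep,
                             "time_min": ti, "intensity": yi})
    return pd.DataFrame(rows, columns=["construct", "replicate", "time_min", "intensity"])


def expected_multicaller_fraction(concordance: float, n_callers: int = 4) -> float:
    """Closed-form probability a reported true event carries >=2 caller flags.

    Conditioned on at least one caller reporting (unreported events never
    enter the call table): P(X>=2 | X>=1) for X ~ Binomial(n, c).
    """
    from scipy import stats

    p0 = stats.binom.pmf(0, n_callers, concordance)
    p1 = stats.binom.pmf(1, n_callers, concordance)
    return (1.0 - p0 - p1) / (1.0 - p0)
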