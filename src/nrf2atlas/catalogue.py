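"""Consensus mutation cataloguing and cohort-level mutation statistics.

Merges per-caller somatic call tables into a consensus catalogue (calls
reported by at least ``min_callers`` of the four TCGA callers), classifies
nucleotide substitutions, parses protein-change strings, and computes the
case-level summaries the cohort analyses rest on: mutant case sets,
set-overlap tests, per-case mutation burden, active-vs-inactive burden
comparisons, and activation/mutation-type correlations.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hotspots import bh_adjust

CALLERS = ("MuSE", "MuTect2", "SomaticSniper", "VarScan2")

_KEY = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome",
        "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2"]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

# MAF Variant_Classification -> internal class vocabulary
VARIANT_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Splice_Site": "splice",
    "Silent": "silent",
}

# "non-synonymous" = every protein-altering class; silent and other excluded
NONSYNONYMOUS_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice"}
)


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of two case sets drawn from a universe of ``n_universe``."""

    n_universe: int
    size_a: int
    size_b: int
    observed: int
    expected: float
    p_value: float
    mode: str


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with Fisher-transform two-sided p-value."""

    r: float
    n: int
    z: float
    p_value: float


def case_id(barcode: str) -> str:
    """Participant identity: first 12 characters of a TCGA-style barcode."""
    return str(barcode)[:12]


def per_caller_tables(maf: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split an aggregated table (semicolon ``callers`` column) into the
    per-caller call tables `merge_caller_calls` consumes."""
    out: dict[str, pd.DataFrame] = {}
    for caller in CALLERS:
        mask = maf["callers"].str.split(";").apply(lambda cs: caller in cs)
        out[caller] = maf.loc[mask].drop(columns=["callers"]).reset_index(drop=True)
    return out


def merge_caller_calls(
    tables: dict[str, pd.DataFrame], min_callers: int = 2
) -> pd.DataFrame:
    """Build the consensus catalogue from per-caller call tables.

    Records are keyed by (case, gene, chromosome, position, ref, alt); the
    consensus keeps one record per key with ``callers`` the union of
    reporting callers, dropping keys seen by fewer than ``min_callers``.
    Duplicate keys within a single caller's table are deduplicated with a
    warning; an unknown caller name is an error.
    """
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    unknown = set(tables) - set(CALLERS)
    if unknown:
        raise ValueError(f"unknown caller name(s): {sorted(unknown)}")
    pieces = []
    for caller, df in tables.items():
        if df.empty:
            continue
        dup = df.duplicated(subset=_KEY)
        if dup.any():
            warnings.warn(
                f"{int(dup.sum())} duplicate record(s) in {caller} table; deduplicated",
                stacklevel=2,
            )
            df = df.loc[~dup]
        pieces.append(df.assign(_caller=caller))
    if not pieces:
        return pd.DataFrame(columns=_KEY + ["callers", "n_callers"])
    stacked = pd.concat(pieces, ignore_index=True)
    extra = [c for c in stacked.columns if c not in _KEY + ["_caller"]]
    grouped = stacked.groupby(_KEY, sort=True)
    callers = grouped["_caller"].agg(
        lambda cs: ";".join(c for c in CALLERS if c in set(cs))
    )
    consensus = grouped[extra].first() if extra else grouped.size().to_frame("_n").drop(columns="_n")
    consensus["callers"] = callers
    consensus["n_callers"] = callers.str.count(";") + 1
    consensus = consensus.reset_index()
    return consensus.loc[consensus["n_callers"] >= min_callers].reset_index(drop=True)


def classify_substitution(ref_nt: str, alt_nt: str) -> str:
    """Classify a single-base substitution as transition or transversion.

    Transitions swap within a chemical class ({A,G} or {C,T}); everything
    else is a transversion. Symmetric in (ref, alt) and invariant under
    simultaneous complementation of both bases.
    """
    for b in (ref_nt, alt_nt):
        if b not in "ACGT" or len(b) != 1:
            raise ValueError(f"invalid base {b!r}")
    if ref_nt == alt_nt:
        raise ValueError("ref and alt bases must differ")
    pair = {ref_nt, alt_nt}
    return "transition" if pair in (_PURINES, _PYRIMIDINES) else "transversion"


_HGVSP_SUB = re.compile(r"^p\.([A-Z\*])(\d+)([A-Z\*])$")
_HGVSP_FS = re.compile(r"^p\.([A-Z\*])(\d+)fs.*$")


def parse_protein_change(hgvsp: str):
    """Parse an HGVSp-short string like ``p.R34G`` / ``p.R34*`` / ``p.E82fs``.

    Returns ``(ref_aa, protein_pos, alt_aa, variant_class)``; all-``None``
    fields with class ``None`` for an empty string. Raises ``ValueError`` on
    a malformed string (table-level callers flag and exclude such records).
    """
    if hgvsp is None or (isinstance(hgvsp, float) and np.isnan(hgvsp)) or hgvsp == "":
        return (None, None, None, None)
    m = _HGVSP_SUB.match(hgvsp)
    if m:
        ref_aa, pos, alt_aa = m.group(1), int(m.group(2)), m.group(3)
        if pos < 1:
            raise ValueError(f"protein position must be >= 1 in {hgvsp!r}")
        if alt_aa == ref_aa:
            vclass = "silent"
        elif alt_aa == "*":
            vclass = "nonsense"
        else:
            vclass = "missense"
        return (ref_aa, pos, alt_aa, vclass)
    m = _HGVSP_FS.match(hgvsp)
    if m:
        pos = int(m.group(2))
        if pos < 1:
            raise ValueError(f"protein position must be >= 1 in {hgvsp!r}")
        return (m.group(1), pos, None, "frameshift")
    raise ValueError(f"malformed protein change {hgvsp!r}")


def annotate_protein_changes(table: pd.DataFrame) -> pd.DataFrame:
    """Add parsed protein-change columns (ref_aa, protein_pos, alt_aa,
    protein_class) to a consensus table; malformed strings are counted,
    warned about, and left with null protein fields so positional analyses
    skip them."""
    out = table.copy()
    parsed = []
    n_bad = 0
    for s in out.get("HGVSp_Short", pd.Series([""] * len(out))):
        try:
            parsed.append(parse_protein_change(s))
        except ValueError:
            n_bad += 1
            parsed.append((None, None, None, None))
    if n_bad:
        warnings.warn(
            f"{n_bad} malformed protein-change string(s) excluded from positional analyses",
            stacklevel=2,
        )
    cols = list(zip(*parsed)) if parsed else [[], [], [], []]
    out["ref_aa"], out["protein_pos"], out["alt_aa"], out["protein_class"] = (
        pd.Series(c, index=out.index, dtype=object) for c in cols
    )
    return out


def variant_classes(table: pd.DataFrame) -> pd.Series:
    """Map MAF Variant_Classification to the internal class vocabulary."""
    return table["Variant_Classification"].map(lambda v: VARIANT_CLASS_MAP.get(v, "other"))


def mutant_case_sets(
    table: pd.DataFrame, gene: str, nonsynonymous_only: bool = True
) -> set[str]:
    """Unique case ids carrying at least one qualifying record in ``gene``."""
    if table.empty:
        return set()
    sub = table.loc[table["Hugo_Symbol"] == gene]
    if sub.empty:
        warnings.warn(f"no records for gene {gene!r}", stacklevel=2)
        return set()
    if nonsynonymous_only:
        sub = sub.loc[variant_classes(sub).isin(NONSYNONYMOUS_CLASSES)]
    return {case_id(b) for b in sub["Tumor_Sample_Barcode"]}


def overlap_test(
    set_a: set[str],
    set_b: set[str],
    universe_size: int,
    mode: str = "exact",
    m: int = 100_000,
    seed: int | None = None,
) -> OverlapResult:
    """Is the overlap of two case sets larger than chance?

    ``exact`` gives the hypergeometric upper tail P(X >= k); ``montecarlo``
    draws ``m`` independent pairs of random subsets of the stated sizes from
    the universe and estimates p as (b+1)/(m+1), b the number of draws with
    overlap >= observed. Both report the chance expectation |A||B|/N.
    """
    K, n = len(set_a), len(set_b)
    if universe_size < max(K, n):
        raise ValueError("universe smaller than one of the sets")
    k = len(set_a & set_b)
    expected = K * n / universe_size
    if mode == "exact":
        p = float(stats.hypergeom.sf(k - 1, universe_size, K, n))
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        # overlap of a random size-n subset with a fixed size-K subset is
        # hypergeometric; sampling it directly is equivalent to drawing both
        # subsets at random
        draws = rng.hypergeometric(K, universe_size - K, n, size=m)
        b = int(np.count_nonzero(draws >= k))
        p = (b + 1) / (m + 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return OverlapResult(universe_size, K, n, k, expected, min(p, 1.0), mode)


def case_burden(
    table: pd.DataFrame, sample_sheet: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-case mutation burden: total events and transition/transversion
    counts (indels left unclassified). Cases present in the sample sheet but
    absent from the table get zero rows."""
    if table.empty:
        burdens = pd.DataFrame(columns=["case_id", "n_total", "n_transition", "n_transversion"])
    else:
        cases = table["Tumor_Sample_Barcode"].map(case_id)
        ref = table["Reference_Allele"].astype(str)
        alt = table["Tumor_Seq_Allele2"].astype(str)
        is_sub = (ref.str.len() == 1) & (alt.str.len() == 1) & \
            ref.isin(list("ACGT")) & alt.isin(list("ACGT")) & (ref != alt)
        cls = pd.Series("none", index=table.index)
        cls.loc[is_sub] = [
            classify_substitution(r, a) for r, a in zip(ref[is_sub], alt[is_sub])
        ]
        burdens = pd.DataFrame({
            "case_id": cases,
            "ts": (cls == "transition").astype(int),
            "tv": (cls == "transversion").astype(int),
        }).groupby("case_id", sort=True).agg(
            n_total=("ts", "size"), n_transition=("ts", "sum"), n_transversion=("tv", "sum")
        ).reset_index()
    if sample_sheet is not None:
        tumor_cases = sample_sheet.loc[
            sample_sheet.get("tissue", "tumor") == "tumor", "case_id"
        ].map(case_id).unique()
        burdens = burdens.set_index("case_id").reindex(tumor_cases, fill_value=0)
        burdens.index.name = "case_id"
        burdens = burdens.reset_index()
    return burdens.astype({"n_total": int, "n_transition": int, "n_transversion": int})


def burden_comparison(
    burden: pd.DataFrame,
    activated: pd.Series,
    tumor_type: pd.Series,
) -> pd.DataFrame:
    """Per-tumor-type active-vs-inactive burden comparison.

    Two-sided Mann-Whitney U per tumor type on ``n_total`` (exact U
    distribution when both groups have <= 8 cases and no ties, normal
    approximation with tie correction otherwise), plus group medians and a
    BH-adjusted q across types. Types lacking a case in either group are
    skipped with a warning.
    """
    df = burden.assign(
        activated=activated.reindex(burden.index).to_numpy(),
        tumor_type=tumor_type.reindex(burden.index).to_numpy(),
    )
    rows = []
    for ttype, sub in df.groupby("tumor_type", sort=True):
        act = sub.loc[sub["activated"].astype(bool), "n_total"].to_numpy()
        inact = sub.loc[~sub["activated"].astype(bool), "n_total"].to_numpy()
        if len(act) == 0 or len(inact) == 0:
            warnings.warn(f"tumor type {ttype} lacks one group; skipped", stacklevel=2)
            continue
        if np.ptp(np.concatenate([act, inact])) == 0:
            p = 1.0
        else:
            method = "exact" if max(len(act), len(inact)) <= 8 else "asymptotic"
            try:
                p = float(stats.mannwhitneyu(act, inact, alternative="two-sided",
                                             method=method).pvalue)
            except ValueError:  # ties with exact method
                p = float(stats.mannwhitneyu(act, inact, alternative="two-sided",
                                             method="asymptotic").pvalue)
        rows.append({
            "tumor_type": ttype,
            "median_active": float(np.median(act)),
            "median_inactive": float(np.median(inact)),
            "n_active": len(act),
            "n_inactive": len(inact),
            "p_value": min(p, 1.0),
        })
    out = pd.DataFrame(rows, columns=["tumor_type", "median_active", "median_inactive",
                                      "n_active", "n_inactive", "p_value"])
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


def pearson_fisher(x, y) -> CorrelationResult:
    """Pearson r with the Fisher-transform two-sided p: z = atanh(r),
    p = 2 * Phi(-|z| * sqrt(n - 3))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 paired observations for the Fisher transform")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return CorrelationResult(float("nan"), n, float("nan"), float("nan"))
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(r, n, float(np.sign(r)) * np.inf, 0.0)
    z = float(np.arctanh(r))
    p = float(2.0 * stats.norm.sf(abs(z) * np.sqrt(n - 3)))
    return CorrelationResult(r, n, z, min(p, 1.0))


def activation_mutation_correlation(
    per_type: pd.DataFrame,
) -> dict[str, CorrelationResult]:
    """Correlate the per-tumor-type activation fraction with the per-type
    median transversion and transition burdens.

    ``per_type`` needs columns ``activation_fraction``, ``median_tv``,
    ``median_ts`` (one row per tumor type, >= 4 types). Returns the two
    Pearson/Fisher results keyed ``"transversion"`` and ``"transition"``.
    """
    if len(per_type) < 4:
        raise ValueError("need >= 4 tumor types")
    act = per_type["activation_fraction"].to_numpy(dtype=float)
    return {
        "transversion": pearson_fisher(act, per_type["median_tv"].to_numpy(dtype=float)),
        "transition": pearson_fisher(act, per_type["median_ts"].to_numpy(dtype=float)),
    }
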