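"""Codon substitution-spectrum analysis.

A codon has exactly nine single-nucleotide neighbors (three positions x
three alternative bases). Enumerating them against the standard genetic
code partitions the neighborhood into synonymous, missense, and nonsense
outcomes — e.g. arginine's CGA codon reaches exactly the missense set
{G, Q, P, L}, one stop (TGA), and four synonymous codons. Observed variant
spectra at a residue are tested against a null that spreads the observed
events over the nine substitutions (uniformly, or transition/transversion-
weighted), using the Monte-Carlo (b+1)/(m+1) estimator for per-variant
enrichment and depletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .hotspots import bh_adjust

_BASES = ("A", "C", "G", "T")
_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _translate(codon: str) -> str:
    """One-letter amino acid, '*' for stop (standard code)."""
    return "*" if codon in _TABLE.stop_codons else _TABLE.forward_table[codon]


@dataclass(frozen=True)
class CodonNeighbor:
    """One single-nucleotide neighbor of a source codon."""

    source_codon: str
    offset: int  # changed position within the codon, 1-based
    alt_base: str
    alt_codon: str
    source_aa: str
    alt_aa: str
    variant_class: str  # synonymous | missense | nonsense


def single_substitution_variants(codon: str) -> list[CodonNeighbor]:
    """Enumerate all 9 single-nucleotide neighbors of a codon.

    Classes: synonymous (amino acid unchanged), nonsense (stop gained),
    missense (any other change). Neighbors of a stop codon that restore a
    residue are classed missense.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    src_aa = _translate(codon)
    out = []
    for i in range(3):
        for alt in _BASES:
            if alt == codon[i]:
                continue
            alt_codon = codon[:i] + alt + codon[i + 1:]
            alt_aa = _translate(alt_codon)
            if alt_aa == src_aa:
                vclass = "synonymous"
            elif alt_aa == "*":
                vclass = "nonsense"
            else:
                vclass = "missense"
            out.append(CodonNeighbor(codon, i + 1, alt, alt_codon, src_aa, alt_aa, vclass))
    return out


def substitution_null(codon: str, tstv_kappa: float = 1.0) -> pd.Series:
    """Null probability of each amino-acid outcome reachable from ``codon``.

    Each of the 9 substitutions carries weight ``tstv_kappa`` if it is a
    transition and 1 if a transversion (kappa=1: the uniform 1/9 null);
    weights are normalized and aggregated to amino-acid outcomes.
    """
    if tstv_kappa <= 0:
        raise ValueError("tstv_kappa must be positive")
    nb = single_substitution_variants(codon)
    w = np.array([
        tstv_kappa if _TRANSITION[n.source_codon[n.offset - 1]] == n.alt_base else 1.0
        for n in nb
    ])
    w = w / w.sum()
    probs: dict[str, float] = {}
    for n, wi in zip(nb, w):
        probs[n.alt_aa] = probs.get(n.alt_aa, 0.0) + wi
    return pd.Series(probs).sort_index()


def variant_spectrum_bias(
    observed: dict[str, int],
    codon: str,
    m: int = 100_000,
    seed: int | None = None,
    tstv_kappa: float = 1.0,
) -> pd.DataFrame:
    """Per-variant enrichment/depletion of an observed amino-acid spectrum.

    ``observed`` maps alternate amino acid to event count at the position.
    The null distributes the n = sum(observed) events over the 9 single-
    nucleotide substitutions (weights per ``substitution_null``), aggregated
    to amino-acid outcomes. For each non-stop outcome the enrichment p_hat
    counts permutations whose outcome count >= observed (upper tail) and the
    depletion p_hat counts <= observed (lower tail), both via (b+1)/(m+1),
    BH-adjusted across tested variants. Stop outcomes are reported but
    excluded from testing. An observed variant unreachable from the codon is
    an error naming the variant.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    null = substitution_null(codon, tstv_kappa)
    reachable = set(null.index)
    for aa in observed:
        if aa not in reachable:
            raise ValueError(f"variant {aa!r} is not reachable from {codon} by single substitution")
    n = int(sum(observed.values()))
    if n < 1:
        raise ValueError("need at least one observed event")
    outcomes = list(null.index)
    obs = np.array([int(observed.get(aa, 0)) for aa in outcomes])
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, null.to_numpy(), size=m)
    b_up = (draws >= obs[None, :]).sum(axis=0)
    b_dn = (draws <= obs[None, :]).sum(axis=0)
    res = pd.DataFrame({
        "variant": outcomes,
        "observed": obs,
        "null_prob": null.to_numpy(),
        "p_enriched": (b_up + 1) / (m + 1),
        "p_depleted": (b_dn + 1) / (m + 1),
        "is_stop": [aa == "*" for aa in outcomes],
    })
    testable = ~res["is_stop"]
    res["q_enriched"] = np.nan
    res["q_depleted"] = np.nan
    res.loc[testable, "q_enriched"] = bh_adjust(res.loc[testable, "p_enriched"].to_numpy())
    res.loc[testable, "q_depleted"] = bh_adjust(res.loc[testable, "p_depleted"].to_numpy())
    return res


def tabulate_position_variants(
    table: pd.DataFrame, gene: str, position: int
) -> pd.DataFrame:
    """Contingency counts of alternate amino acid x tumor type at one
    residue of one gene (rows: alt_aa; columns: tumor_type). Totals match
    the positional event count used by the hotspot scan."""
    if "protein_pos" not in table.columns:
        raise ValueError("table lacks parsed protein positions; annotate first")
    sub = table.loc[
        (table["Hugo_Symbol"] == gene)
        & (pd.to_numeric(table["protein_pos"], errors="coerce") == position)
        & table["alt_aa"].notna()
    ]
    if sub.empty:
        return pd.DataFrame()
    return pd.crosstab(sub["alt_aa"], sub["tumor_type"])
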