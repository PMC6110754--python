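"""Monte-Carlo positional hotspot enrichment.

A hotspot is a protein residue carrying more mutation events than a uniform
positional null predicts. The null redistributes the gene's n observed
events independently and uniformly over its L codons; for each tested
position the permutation p-value is estimated as

    p_hat = (b + 1) / (m + 1)

where b is the number of permutations whose count at that position reaches
the observed count and m the number of permutations. Estimates are adjusted
across tested positions with Benjamini-Hochberg. The same estimator drives
tumor-type-restricted enrichment (drawing position carriers from the gene's
mutant case pool without replacement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PositionEnrichment:
    """Per-residue Monte-Carlo enrichment result."""

    protein_pos: int
    observed: int
    b: int
    m: int
    p_hat: float
    q: float


def montecarlo_pvalue(b: int, m: int) -> float:
    """Permutation p-value estimator (b+1)/(m+1).

    Never returns 0: with b = 0 the smallest attainable estimate is
    1/(m+1), reflecting that the observed configuration itself is one of
    the m+1 exchangeable arrangements.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= b <= m:
        raise ValueError("b must satisfy 0 <= b <= m")
    return (b + 1) / (m + 1)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def position_counts(
    table: pd.DataFrame, gene: str, protein_length: int
) -> np.ndarray:
    """Per-codon nonsynonymous event counts for one gene, codons 1..L.

    Records need parsed ``protein_pos`` (see
    ``catalogue.annotate_protein_changes``); silent and unparsed records are
    excluded, out-of-range positions are logged and dropped.
    """
    from . import catalogue as _cat  # deferred: catalogue imports bh_adjust from here

    if protein_length <= 0:
        raise ValueError("protein length must be positive")
    counts = np.zeros(protein_length, dtype=int)
    if table.empty:
        return counts
    sub = table.loc[table["Hugo_Symbol"] == gene]
    if "protein_pos" not in sub.columns:
        raise ValueError("table lacks parsed protein positions; annotate first")
    cls = _cat.variant_classes(sub)
    sub = sub.loc[cls.isin(_cat.NONSYNONYMOUS_CLASSES)]
    pos = pd.to_numeric(sub["protein_pos"], errors="coerce").dropna().astype(int)
    in_range = (pos >= 1) & (pos <= protein_length)
    if (~in_range).any():
        warnings.warn(
            f"{int((~in_range).sum())} event(s) with out-of-range positions excluded",
            stacklevel=2,
        )
    np.add.at(counts, pos[in_range].to_numpy() - 1, 1)
    return counts


def positional_enrichment(
    counts: np.ndarray,
    m: int = 100_000,
    seed: int | None = None,
    batch: int = 20_000,
) -> list[PositionEnrichment]:
    """Monte-Carlo positional enrichment over a per-codon count vector.

    Each permutation redistributes the n = sum(counts) events independently
    and uniformly over the L codons. Only positions with at least one
    observed event are tested (zero-count positions can never be enriched)
    and only those enter the BH family. Results depend only on
    (seed, m, counts), not on internal batching: the joint null counts at
    the T tested positions are drawn as a single multinomial over T+1 cells
    (one per tested position, probability 1/L each, plus a rest cell).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    counts = np.asarray(counts, dtype=int)
    L = counts.size
    n = int(counts.sum())
    if n < 1:
        raise ValueError("need at least one observed event")
    tested = np.flatnonzero(counts > 0)
    observed = counts[tested]
    pvec = np.full(tested.size + 1, 1.0 / L)
    pvec[-1] = 1.0 - tested.size / L
    rng = np.random.default_rng(seed)
    b = np.zeros(tested.size, dtype=np.int64)
    done = 0
    while done < m:
        size = min(batch, m - done)
        draws = rng.multinomial(n, pvec, size=size)[:, :-1]
        b += (draws >= observed[None, :]).sum(axis=0)
        done += size
    p_hat = (b + 1) / (m + 1)
    q = bh_adjust(p_hat)
    return [
        PositionEnrichment(int(pos + 1), int(obs), int(bi), m, float(pi), float(qi))
        for pos, obs, bi, pi, qi in zip(tested, observed, b, p_hat, q)
    ]


def enrichment_table(results: list[PositionEnrichment]) -> pd.DataFrame:
    """Tabular view of positional results (position, observed, b, m, p_hat, q)."""
    return pd.DataFrame(
        [(r.protein_pos, r.observed, r.b, r.m, r.p_hat, r.q) for r in results],
        columns=["position", "observed", "b", "m", "p_hat", "q"],
    )


def tumor_type_enrichment(
    position_case_types: pd.Series,
    pool_case_types: pd.Series,
    m: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Is a position's mutant-case tumor-type mix biased relative to the
    gene's full mutant pool?

    The null draws k = len(position_case_types) cases without replacement
    from the gene-mutant case pool m times (a multivariate hypergeometric
    over tumor types); per type, b counts permutations whose draw for that
    type reaches the observed count. p_hat = (b+1)/(m+1), BH across types.
    """
    k = len(position_case_types)
    if k < 1:
        raise ValueError("need at least one case at the position")
    if k > len(pool_case_types):
        raise ValueError("position case count exceeds the mutant pool size")
    pool_counts = pool_case_types.value_counts().sort_index()
    types = list(pool_counts.index)
    observed = position_case_types.value_counts().reindex(types, fill_value=0)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(pool_counts.to_numpy(), k, size=m)
    b = (draws >= observed.to_numpy()[None, :]).sum(axis=0)
    p_hat = (b + 1) / (m + 1)
    return pd.DataFrame({
        "tumor_type": types,
        "observed": observed.to_numpy(),
        "pool": pool_counts.to_numpy(),
        "b": b,
        "m": m,
        "p_hat": p_hat,
        "q": bh_adjust(p_hat),
    })


def hotspot_transversion_bias(
    table: pd.DataFrame, hotspot_positions: set[int], gene: str
) -> float:
    """One-sided Fisher test for transversion excess at hotspot residues.

    Builds the 2x2 table (hotspot vs elsewhere) x (transversion vs
    transition) over the gene's substitution events and returns the
    one-sided p for transversions being over-represented at hotspots.
    """
    from . import catalogue as _cat

    sub = table.loc[table["Hugo_Symbol"] == gene]
    if "protein_pos" not in sub.columns:
        raise ValueError("table lacks parsed protein positions; annotate first")
    ref = sub["Reference_Allele"].astype(str)
    alt = sub["Tumor_Seq_Allele2"].astype(str)
    is_sub = (ref.str.len() == 1) & (alt.str.len() == 1) & \
        ref.isin(list("ACGT")) & alt.isin(list("ACGT")) & (ref != alt)
    sub = sub.loc[is_sub & sub["protein_pos"].notna()]
    if sub.empty:
        warnings.warn("no classifiable substitutions; p = 1", stacklevel=2)
        return 1.0
    tv = np.array([
        _cat.classify_substitution(r, a) == "transversion"
        for r, a in zip(sub["Reference_Allele"], sub["Tumor_Seq_Allele2"])
    ])
    at_hs = sub["protein_pos"].astype(int).isin(hotspot_positions).to_numpy()
    tab = np.array([
        [int((at_hs & tv).sum()), int((at_hs & ~tv).sum())],
        [int((~at_hs & tv).sum()), int((~at_hs & ~tv).sum())],
    ])
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        warnings.warn("empty margin in the 2x2 table; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(tab, alternative="greater")[1])
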