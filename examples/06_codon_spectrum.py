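"""Single-nucleotide neighborhood of the arginine codon CGA and spectrum bias.

CGA reaches exactly four missense outcomes (G, Q, P, L), one stop (TGA) and
four synonymous codons. An observed spectrum with no L among many events is
tested for depletion under the uniform 1/9-per-substitution null.
"""

import nrf2atlas as na

neighbors = na.single_substitution_variants("CGA")
for n in neighbors:
    print(f"  CGA -> {n.alt_codon}: {n.source_aa} -> {n.alt_aa} ({n.variant_class})")

observed = {"G": 20, "Q": 8, "P": 6}  # 34 events, no L
res = na.variant_spectrum_bias(observed, "CGA", m=100_000, seed=7)
print(res[["variant", "observed", "null_prob", "p_enriched", "p_depleted",
           "q_enriched", "q_depleted"]].to_string(index=False))
# With 34 events and null probability 1/9, seeing zero L has probability
# (8/9)^34 ~ 0.018: the missing variant is depleted before correction,
# while the over-represented G is flagged enriched.
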