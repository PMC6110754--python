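"""Generate a small synthetic TCGA-like cohort and look at its pieces.

Builds a 100-case cohort over two lung tumor types with a planted mutation
hotspot at NFE2L2 codon 34, then prints the shapes of the call table,
sample sheet, and count matrix.
"""

import nrf2atlas as na

cfg = na.SimulationConfig(
    seed=42,
    n_cases=100,
    n_normals=20,
    tumor_types={"LUAD": 0.6, "LUSC": 0.4},
    hotspot_spec=na.HotspotSpec("NFE2L2", 34, 0.4, spectrum={"G": 2, "P": 1, "Q": 1}),
    activation_spec=na.ActivationSpec(("GPX2", "TXNRD1", "AKR1B10", "GCLM"), 4.0, 0.4),
    n_genes=120,
)
sim = na.simulate_mutations(cfg)
counts = na.simulate_expression(sim.sample_sheet, cfg)

print(f"mutation calls: {len(sim.maf)} records "
      f"({len(sim.truth)} planted true events; the rest are spurious singletons)")
print(f"sample sheet: {len(sim.sample_sheet)} samples, "
      f"{(sim.sample_sheet['tissue'] == 'normal').sum()} normal")
print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print(sim.maf.head(3).to_string())
# Each record mimics a MAF row: barcode, gene, genomic change, protein
# change, and the semicolon-joined list of callers that reported it.
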