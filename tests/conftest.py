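import numpy as np
import pandas as pd
import pytest

import nrf2atlas as na


@pytest.fixture(scope="session")
def hotspot_cohort():
    """Cohort with a planted NFE2L2 R34-like hotspot and full caller
    concordance; shared by catalogue and hotspot tests."""
    cfg = na.SimulationConfig(
        seed=11,
        n_cases=200,
        caller_concordance=1.0,
        spurious_rate=0.5,
        hotspot_spec=na.HotspotSpec(
            "NFE2L2", 34, 0.4, spectrum={"G": 2, "P": 1, "Q": 1}
        ),
    )
    sim = na.simulate_mutations(cfg)
    consensus = na.merge_caller_calls(na.per_caller_tables(sim.maf), min_callers=2)
    return cfg, sim, na.annotate_protein_changes(consensus)


@pytest.fixture(scope="session")
def training_cohort():
    """12 activated tumors vs 12 normals over two tumor types with planted
    activation and batch gene sets; shared by signature/stratification tests."""
    sig_genes = tuple(f"SIG{i}" for i in range(8))
    bat_genes = tuple(f"BAT{i}" for i in range(5))
    cfg = na.SimulationConfig(
        seed=5,
        n_cases=12,
        n_normals=12,
        tumor_types={"LUAD": 0.5, "LUSC": 0.5},
        balanced_types=True,
        n_genes=200,
        nb_dispersion=0.05,
        activation_spec=na.ActivationSpec(sig_genes, 4.0, 1.0),
        batch_spec=na.BatchSpec(bat_genes, {"LUAD": 3.0}),
    )
    sim = na.simulate_mutations(cfg)
    counts = na.simulate_expression(sim.sample_sheet, cfg)
    return cfg, sim.sample_sheet, counts, sig_genes, bat_genes
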