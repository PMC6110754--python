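"""Tab-separated readers/writers for the pipeline's file formats.

All tables travel as plain TSV: MAF-like mutation tables (with a semicolon-
joined ``callers`` column), sample sheets, genes-by-samples count matrices,
and chase densitometry series. YAML carries simulation configurations.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .simulate import (
    ActivationSpec,
    BatchSpec,
    ChaseSpec,
    HotspotSpec,
    SimulationConfig,
)


def read_maf(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"Reference_Allele": str,
                                              "Tumor_Seq_Allele2": str})


def write_maf(maf: pd.DataFrame, path) -> None:
    maf.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    """Count matrix TSV, genes as rows (first column), samples as columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_chase(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_chase(chase: pd.DataFrame, path) -> None:
    chase.to_csv(path, sep="\t", index=False)


def load_config(path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file.

    Nested specs use the field names of the corresponding dataclasses, e.g.::

        seed: 7
        n_cases: 300
        hotspot_spec: {gene: NFE2L2, position: 34, fraction: 0.4}
        activation_spec: {genes: [GPX2, TXNRD1], log2_effect: 4.0, fraction: 0.4}
    """
    raw = yaml.safe_load(Path(path).read_text())
    if "hotspot_spec" in raw and raw["hotspot_spec"] is not None:
        raw["hotspot_spec"] = HotspotSpec(**raw["hotspot_spec"])
    if "activation_spec" in raw and raw["activation_spec"] is not None:
        spec = dict(raw["activation_spec"])
        spec["genes"] = tuple(spec["genes"])
        raw["activation_spec"] = ActivationSpec(**spec)
    if "batch_spec" in raw and raw["batch_spec"] is not None:
        spec = dict(raw["batch_spec"])
        spec["genes"] = tuple(spec["genes"])
        raw["batch_spec"] = BatchSpec(**spec)
    if "chase_spec" in raw and raw["chase_spec"] is not None:
        spec = dict(raw["chase_spec"])
        if "timepoints" in spec:
            spec["timepoints"] = tuple(spec["timepoints"])
        raw["chase_spec"] = ChaseSpec(**spec)
    return SimulationConfig(**raw)
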