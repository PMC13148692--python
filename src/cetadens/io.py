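"""Readers, writers and configuration for the pipeline's exchange formats.

ASV tables travel as TSV (samples x ASVs with metadata columns, or the
transposed orientation, auto-detected) or as BIOM 1.0 JSON; sightings and
effort as CSV with fixed headers; configuration as YAML.  All readers
validate types and units on the way in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PipelineConfig",
    "read_asv_table",
    "write_asv_table",
    "read_sightings",
    "read_effort",
    "write_sightings",
    "write_effort",
    "read_biom",
    "write_biom",
    "load_config",
]

METADATA_COLUMNS = ("cruise", "transect", "station", "depth")
SIGHTING_COLUMNS = ("cruise", "transect", "species", "distance_m",
                    "group_size", "beaufort", "swell_m", "platform")
EFFORT_COLUMNS = ("cruise", "transect", "length_km", "truncation_w")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings with the analysis defaults."""

    outdir: str = "cetadens_output"
    species: tuple = ("whale",)
    markers: tuple = ("16S",)
    truncation_w: float = 2400.0
    prevalence_lo: float = 0.01
    prevalence_hi: float = 0.99
    gbm_prior_strength: float = 1.0
    lambda_grid: tuple = tuple(np.linspace(0.5, 0.95, 21).round(6))
    pi_max: float = 0.9
    pfer_level: float = 0.5
    k_grid: tuple = tuple(range(4, 13))
    jaccard_alpha: float = 0.5
    zero_offset_fraction: float = 0.5
    bootstrap_n: int = 200
    bootstrap_level: float = 0.90
    seed: int = 0
    # input files (optional; simulation is used when absent)
    sightings_path: str | None = None
    effort_path: str | None = None
    asv_table_paths: dict = field(default_factory=dict)  # marker -> path
    cruise_quarters: dict = field(default_factory=dict)  # cruise id -> quarter label
    # validation switches
    run_outer_validation: bool = True
    run_bootstrap: bool = True
    simulate: dict = field(default_factory=dict)  # SimConfig overrides


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**raw)
    if not 0 <= cfg.prevalence_lo < cfg.prevalence_hi <= 1:
        raise ValueError("prevalence thresholds out of range")
    if not 0.5 < cfg.pi_max <= 1:
        raise ValueError("pi_max must lie in (0.5, 1]")
    return cfg


# --- sightings / effort CSV ------------------------------------------------

def write_sightings(sightings: pd.DataFrame, path) -> None:
    sightings.to_csv(path, index=False, columns=list(SIGHTING_COLUMNS))


def read_sightings(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(SIGHTING_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"sightings file missing columns: {sorted(missing)}")
    if (table["distance_m"] < 0).any():
        raise ValueError("negative perpendicular distance")
    if (table["group_size"] < 1).any():
        raise ValueError("group sizes must be >= 1")
    table["platform"] = table["platform"].astype(str)
    return table


def write_effort(effort: pd.DataFrame, path) -> None:
    effort.to_csv(path, index=False, columns=list(EFFORT_COLUMNS))


def read_effort(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(EFFORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"effort file missing columns: {sorted(missing)}")
    if (table["length_km"] <= 0).any():
        raise ValueError("transect lengths must be positive")
    if (table["truncation_w"] <= 0).any():
        raise ValueError("truncation distance must be positive")
    return table


# --- ASV tables ------------------------------------------------------------

def write_asv_table(counts: pd.DataFrame, metadata: pd.DataFrame, path,
                    marker: str = "16S", transposed: bool = False) -> None:
    """TSV with per-sample metadata columns then ASV count columns."""
    joined = metadata.join(counts)
    joined.insert(len(METADATA_COLUMNS), "marker", marker)
    joined.index.name = "sample_id"
    out = joined.reset_index()
    if transposed:
        out = out.set_index("sample_id").T.reset_index(names="field")
    out.to_csv(path, sep="\t", index=False)


def _parse_samples_by_rows(table: pd.DataFrame):
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ASV table missing metadata column: {missing[0]!r}")
    if table["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    table = table.set_index("sample_id")
    marker = None
    if "marker" in table.columns:
        marker = str(table["marker"].iloc[0])
        table = table.drop(columns="marker")
    metadata = table[list(METADATA_COLUMNS)].copy()
    counts = table.drop(columns=list(METADATA_COLUMNS)).astype(float)
    counts.columns.name = None
    metadata.columns.name = None
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if not np.allclose(counts.to_numpy() % 1, 0):
        raise ValueError("counts must be integers")
    return counts.astype(int), metadata, marker


def read_asv_table(path, fmt: str = "tsv"):
    """Read a sample x ASV table; orientation auto-detected.

    Returns (counts, metadata, marker).  ``fmt`` is "tsv" (default) or
    "biom" (BIOM 1.0 JSON).
    """
    if fmt == "biom":
        return read_biom(path)
    table = pd.read_csv(path, sep="\t")
    first = table.columns[0]
    if first == "sample_id":
        return _parse_samples_by_rows(table)
    if first == "field":
        # transposed orientation: columns are samples
        pivot = table.set_index("field").T
        pivot.index.name = "sample_id"
        pivot = pivot.reset_index()
        return _parse_samples_by_rows(pivot)
    raise ValueError(
        "cannot detect ASV table orientation: first column must be "
        "'sample_id' (samples in rows) or 'field' (samples in columns)"
    )


# --- minimal BIOM 1.0 (JSON) support ---------------------------------------

def write_biom(counts: pd.DataFrame, metadata: pd.DataFrame, path,
               marker: str = "16S") -> None:
    """BIOM 1.0 JSON, dense, observations x samples as the format expects."""
    data = counts.T  # observations (ASVs) x samples
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "cetadens",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": list(data.shape),
        "rows": [{"id": str(asv), "metadata": None} for asv in data.index],
        "columns": [
            {"id": str(s),
             "metadata": {**metadata.loc[s].to_dict(), "marker": marker}}
            for s in data.columns
        ],
        "data": data.to_numpy().astype(int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_biom(path):
    with open(path) as fh:
        doc = json.load(fh)
    n_obs, n_samp = doc["shape"]
    if doc["matrix_type"] == "dense":
        matrix = np.asarray(doc["data"], dtype=float)
    else:  # sparse: [row, col, value] triplets
        matrix = np.zeros((n_obs, n_samp))
        for r, c, v in doc["data"]:
            matrix[int(r), int(c)] = v
    asv_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    counts = pd.DataFrame(matrix.T, index=sample_ids, columns=asv_ids)
    counts.index.name = "sample_id"
    meta_rows, marker = [], None
    for col in doc["columns"]:
        md = col.get("metadata") or {}
        marker = md.get("marker", marker)
        meta_rows.append({k: md.get(k) for k in METADATA_COLUMNS})
    metadata = pd.DataFrame(meta_rows, index=sample_ids)
    metadata.index.name = "sample_id"
    missing = [c for c in METADATA_COLUMNS if metadata[c].isna().any()]
    if missing:
        raise ValueError(f"ASV table missing metadata column: {missing[0]!r}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return counts.astype(int), metadata, marker
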