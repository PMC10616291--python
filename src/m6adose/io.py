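"""Table schemas, validated delimited-text I/O, and pipeline configuration.

All pipeline tables are plain tab-separated text with documented headers.
Doses are in Gy, microarray time in days; cell-experiment time carries an
explicit unit column and is never inferred.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["SCHEMAS", "read_table", "write_table", "PipelineConfig"]


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: dict  # column -> dtype kind: "str" | "float" | "int" | "bool"
    nullable: tuple = ()


SCHEMAS: dict[str, TableSchema] = {
    "array": TableSchema(
        "array",
        {
            "probe_id": "str",
            "gene_id": "str",
            "is_spikein": "bool",
            "sample_id": "str",
            "ip_intensity": "float",
            "sup_intensity": "float",
        },
    ),
    "samples": TableSchema(
        "samples",
        {"sample_id": "str", "dose_gy": "float", "tpi_days": "float", "replicate": "int"},
    ),
    "ct": TableSchema(
        "ct",
        {
            "target_id": "str",
            "primer_id": "str",
            "fraction": "str",
            "ct": "float",
            "rna_mass_ng": "float",
            "group_id": "str",
            "replicate": "int",
            "dose_gy": "float",
            "tpi": "float",
            "tpi_unit": "str",
        },
        nullable=("dose_gy", "tpi"),
    ),
    "dose_response": TableSchema(
        "dose_response",
        {
            "subject_id": "str",
            "m6a_value": "float",
            "m6a_scale": "str",
            "tpi_days": "float",
            "dose_gy": "float",
        },
        nullable=("tpi_days",),
    ),
    "diff": TableSchema(
        "diff",
        {
            "gene_id": "str",
            "log2_fc": "float",
            "p_value": "float",
            "bh_fdr": "float",
            "status": "str",
        },
    ),
    "truth": TableSchema(
        "truth",
        {"gene_id": "str", "pattern": "str", "effect": "float", "baseline_fraction": "float"},
    ),
}


def read_table(path, schema_id: str) -> pd.DataFrame:
    """Read and validate a delimited table against a named schema.

    Missing required columns raise (naming the column); unknown columns
    warn; non-numeric entries in numeric columns raise with 1-based file
    line numbers (header = line 1).
    """
    schema = SCHEMAS[schema_id]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing} for schema '{schema_id}'")
    unknown = [c for c in df.columns if c not in schema.required]
    if unknown:
        warnings.warn(f"{path.name}: ignoring unknown column(s) {unknown}", UserWarning)
    out = {}
    for col, kind in schema.required.items():
        raw = df[col]
        if kind == "str":
            out[col] = raw.astype(str)
        elif kind == "bool":
            low = raw.astype(str).str.lower()
            bad = ~low.isin(["true", "false", "1", "0"])
            if bad.any():
                lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
                raise ValueError(f"{path.name}: non-boolean '{col}' at line(s) {lines[:10]}")
            out[col] = low.isin(["true", "1"])
        else:
            num = pd.to_numeric(raw, errors="coerce")
            bad = num.isna() & raw.notna()
            if col not in schema.nullable and num.isna().any():
                bad = num.isna()
            if bad.any():
                lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
                raise ValueError(
                    f"{path.name}: non-numeric or missing '{col}' at line(s) {lines[:10]}"
                )
            out[col] = num.astype(float) if kind == "float" else num.astype(int)
    return pd.DataFrame(out)


def write_table(df: pd.DataFrame, path, schema_id: str | None = None) -> Path:
    """Write a table as TSV (deterministic float formatting, %.12g)."""
    path = Path(path)
    if schema_id is not None:
        schema = SCHEMAS[schema_id]
        missing = [c for c in schema.required if c not in df.columns]
        if missing:
            raise ValueError(f"cannot write schema '{schema_id}': missing {missing}")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


@dataclass
class PipelineConfig:
    """Every threshold, size and seed the end-to-end pipeline uses.

    Defaults are the study's values where one exists: fold-change thresholds
    2 / 0.5 with alpha 0.01, two sub-clusters per category with fuzzifier 2,
    MeRIP masses 2000/500 ng at efficiency 2.0, five-fold cross-validation
    repeated 100 times, cutoffs at the administered doses.
    """

    seed: int = 0
    # synthetic study
    n_genes: int = 2000
    n_planted_consistent: int = 20
    n_planted_transient: int = 10
    n_planted_hypo: int = 10
    effect: float = 4.0
    noise_sd_log2: float = 0.15
    noise_cv: float = 0.1
    # differential thresholds
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    alpha: float = 0.01
    welch: bool = False
    # clustering
    n_clusters: int = 2
    fuzzifier: float = 2.0
    # qPCR
    efficiency: float = 2.0
    mass_ip_ng: float = 2000.0
    mass_input_ng: float = 500.0
    select_normalization: str = "literal"
    min_signal_ratio: float = 4.0
    dunnett_n_mc: int = 100_000
    # dosimetry
    model_basis: str = "total"
    cv_k: int = 5
    cv_reps: int = 100
    cutoffs: tuple = (0.2, 0.5, 1.0, 2.0, 4.0, 6.5)
    stratify_by: str = "group"
    clamp_negative: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoffs"] = list(d["cutoffs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "cutoffs" in d:
            d = {**d, "cutoffs": tuple(d["cutoffs"])}
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
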