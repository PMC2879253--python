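"""Readers and writers for the pipeline's plain-text formats.

Expression matrices are tab-delimited gene x sample tables (first column
gene id, header sample ids); clinical tables are CSV; gene sets are GMT
(one set per line: name, description, member genes, tab-separated);
probe annotations are TSV with columns probe_id, gene_symbol[, chip].
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .gsea import GeneSet
from .simulate import Cohort, SimulationConfig

CLINICAL_COLUMNS = ["sample", "label", "time_years", "event", "age", "wbc", "sex"]


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False, columns=CLINICAL_COLUMNS)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df


def write_cohort(cohort: Cohort, directory, stem: str = "cohort") -> dict:
    """Write expression TSV + clinical CSV; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / f"{stem}_expression.tsv",
        "clinical": directory / f"{stem}_clinical.csv",
    }
    write_expression_tsv(cohort.expression, paths["expression"])
    write_clinical_csv(cohort.clinical, paths["clinical"])
    return paths


def read_cohort(expression_path, clinical_path, platform: str = "file") -> Cohort:
    return Cohort(
        read_expression_tsv(expression_path),
        read_clinical_csv(clinical_path),
        platform=platform,
    )


def config_to_yaml(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def config_to_json(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(_config_dict(config), fh, indent=2)


def config_from_json(path) -> SimulationConfig:
    with open(path) as fh:
        return _config_from_dict(json.load(fh))


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["planted_genes"] = [list(p) for p in config.planted_genes]
    d["relapse_time_range"] = list(config.relapse_time_range)
    d["followup_range"] = list(config.followup_range)
    return d


def _config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["planted_genes"] = tuple((g, float(f)) for g, f in d["planted_genes"])
    d["relapse_time_range"] = tuple(d["relapse_time_range"])
    d["followup_range"] = tuple(d["followup_range"])
    return SimulationConfig(**d)


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets.append(GeneSet(name=fields[0], members=set(g for g in fields[2:] if g)))
    return sets


def write_gmt(gene_sets: list[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, description] + sorted(gs.members)) + "\n")


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "gene_symbol"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    return df
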