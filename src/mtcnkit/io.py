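"""File I/O and pipeline configuration.

TSV with explicit headers is the interchange format throughout; VCF support
is deliberately minimal (plain-text, GT/DS fields only).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "PipelineConfig",
    "read_genotypes",
    "write_assoc_stats",
    "read_assoc_stats",
]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run.

    Unknown keys in a YAML file are rejected.  A copy of the resolved
    configuration is written next to the outputs of every run.
    """

    seed: int = 0
    outdir: str = "mtcn_run"
    schema_version: int = SCHEMA_VERSION
    # stage toggles
    stages: dict = field(default_factory=lambda: {
        "synthdata": True, "mtcn": True, "assoc": True, "finemap": True,
        "pheclust": True, "genesets": True, "mito": True,
    })
    # synthetic cohort scale
    n_individuals: int = 2000
    n_snps: int = 500
    n_mtsnps: int = 120
    n_traits: int = 41
    # permutation budgets (desk scale)
    n_perm_enrichment: int = 2000
    n_outer_threshold: int = 60
    n_perm_cutoff: int = 200
    n_geneset_iter: int = 50
    n_dummy_traits: int = 60
    dummy_rank: int = 3
    wes_overlap_fraction: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def read_genotypes(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Dosage matrix (individuals × variants) from TSV or minimal VCF.

    The TSV layout is samples in rows (first column the sample id) and
    variants in columns.  The VCF reader handles uncompressed files with GT
    (``0/0``-style, any ploidy) or DS fields and reports the offending line
    number on malformed input.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = df.columns[df.isna().any()]
        if len(bad):
            raise ValueError(f"missing dosage values in columns {list(bad)[:5]}")
        return df
    if format != "vcf":
        raise ValueError(f"unknown genotype format {format!r}")

    samples: list[str] = []
    variant_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line.strip():
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                samples = fields[9:]
                continue
            fields = line.split("\t")
            if len(fields) != 9 + len(samples) or not samples:
                raise ValueError(f"{path}:{lineno}: malformed VCF record")
            fmt = fields[8].split(":")
            try:
                if "DS" in fmt:
                    k = fmt.index("DS")
                    dosages = [float(f.split(":")[k]) for f in fields[9:]]
                elif "GT" in fmt:
                    k = fmt.index("GT")
                    dosages = []
                    for f in fields[9:]:
                        gt = f.split(":")[k].replace("|", "/")
                        alleles = [a for a in gt.split("/") if a != "."]
                        dosages.append(float(sum(int(a) > 0 for a in alleles)))
                else:
                    raise ValueError("record lacks GT and DS")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            variant_ids.append(fields[2] if fields[2] != "." else
                               f"{fields[0]}:{fields[1]}")
            rows.append(dosages)
    if not samples:
        raise ValueError(f"{path}: no #CHROM header line found")
    return pd.DataFrame(rows, index=variant_ids, columns=samples).T


def write_assoc_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """Summary-stat TSV with the fixed column schema."""
    from .assoc import ASSOC_COLUMNS
    stats[ASSOC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_assoc_stats(path: str | Path) -> pd.DataFrame:
    from .assoc import ASSOC_COLUMNS
    df = pd.read_csv(path, sep="\t")
    missing = set(ASSOC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-stat file missing columns: {sorted(missing)}")
    return df
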