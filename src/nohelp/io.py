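"""Readers and writers for the on-disk formats.

Count matrices and metadata are plain TSV; gene sets are standard GMT
(name, description, then member genes per line); cross-species gene
mappings are two-column TSV. Every filtering step logs how many records
it kept and dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .matrix import CountMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneMapping",
    "normalize_gene_id",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_mapping",
    "write_mapping",
    "write_manifest",
]


def normalize_gene_id(gene_id: str) -> str:
    """Canonical form used when matching gene ids across datasets.

    Exact string match after uppercasing and stripping whitespace, so that
    mouse-style symbols ("Tcf7") and human-style symbols ("TCF7") meet.
    """
    return gene_id.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set '{self.name}' is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneMapping:
    """One source->target gene id pair (e.g. mouse symbol -> human symbol)."""

    source_id: str
    target_id: str


# ---------------------------------------------------------------------------
# count matrix TSV


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV (first column gene id, header = samples)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene id: {dup[:5]}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df[col][vals.isna()].iloc[0]
            raise ValueError(f"non-numeric count {bad!r} in sample {col}")
        df[col] = vals
    return CountMatrix(df)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# sample metadata TSV


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file; duplicate genes within a line collapse with a warning."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set '{name}' has no genes")
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "gene set %s: %d duplicate gene entries collapsed",
                    name,
                    len(genes) - len(unique),
                )
            sets.append(GeneSet(name=name, description=description, genes=unique))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description}\t{genes}\n")


# ---------------------------------------------------------------------------
# gene-id mapping TSV


def read_mapping(path: str | Path) -> list[GeneMapping]:
    """Read a two-column source->target TSV, keeping only one-to-one pairs.

    Any source appearing with several targets, or target with several
    sources, is ambiguous and all its pairs are dropped (count logged).
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: expected two tab-separated ids")
            pairs.append((fields[0].strip(), fields[1].strip()))
    return filter_one_to_one(pairs)


def filter_one_to_one(pairs: list[tuple[str, str]]) -> list[GeneMapping]:
    pairs = list(dict.fromkeys(pairs))  # drop exact duplicates, keep order
    src_count: dict[str, int] = {}
    tgt_count: dict[str, int] = {}
    for s, t in pairs:
        src_count[s] = src_count.get(s, 0) + 1
        tgt_count[t] = tgt_count.get(t, 0) + 1
    kept = [
        GeneMapping(s, t)
        for s, t in pairs
        if src_count[s] == 1 and tgt_count[t] == 1
    ]
    dropped = len(pairs) - len(kept)
    if dropped:
        logger.info(
            "gene mapping: kept %d one-to-one pairs, dropped %d ambiguous",
            len(kept),
            dropped,
        )
    return kept


def write_mapping(mapping: list[GeneMapping], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mapping:
            fh.write(f"{m.source_id}\t{m.target_id}\n")


# ---------------------------------------------------------------------------
# provenance


def write_manifest(path: str | Path, *, command: str, inputs: dict, params: dict,
                   seed: int | None = None) -> None:
    """Write the JSON run-manifest recording inputs, parameters and seed."""
    from . import __version__

    manifest = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "params": params,
        "seed": seed,
        "version": __version__,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
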