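"""Capsule construction: CpG -> context groupings.

Capsules can be built from Illumina-450k-style annotation columns
(``UCSC_RefGene_Name``, ``Relation_to_UCSC_CpG_Island``, ...), from GMT gene
sets layered on gene capsules, from fixed-width genomic bins, or from a custom
two-column mapping. All coordinates follow the BED convention: 0-based,
half-open intervals.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import CapsuleMap, ValidationError

__all__ = [
    "build_from_annotation",
    "build_genomic_bins",
    "build_from_gene_sets",
    "filter_min_cpgs",
    "load_gene_sets",
    "load_chrom_sizes",
]

logger = logging.getLogger(__name__)

#: composite annotation fields list several contexts separated by ';'
CONTEXT_DELIMITER = ";"


def build_from_annotation(
    annotation: pd.DataFrame,
    universe: Sequence[str],
    context_column: str,
) -> CapsuleMap:
    """Group CpGs by the distinct values of an annotation column.

    ``annotation`` is indexed by CpG id. Composite ';'-delimited values
    contribute the CpG to every named context (deduplicated); CpGs with a
    blank context, or outside ``universe``, are assigned to no capsule.
    """
    if context_column not in annotation.columns:
        raise KeyError(
            f"unknown column {context_column!r}; available: {list(annotation.columns)}"
        )
    universe_set = set(universe)
    capsules: dict[str, list[str]] = {}
    for cpg, value in annotation[context_column].items():
        if cpg not in universe_set:
            continue
        if pd.isna(value):
            continue
        seen: set[str] = set()
        for ctx in str(value).split(CONTEXT_DELIMITER):
            ctx = ctx.strip()
            if not ctx or ctx in seen:
                continue
            seen.add(ctx)
            capsules.setdefault(ctx, []).append(str(cpg))
    return CapsuleMap(capsules)


def build_genomic_bins(
    coords: Mapping[str, tuple[str, int]],
    chrom_sizes: Mapping[str, int],
    width: int,
    step: int | None = None,
) -> CapsuleMap:
    """Tile each chromosome with half-open windows and assign CpGs by overlap.

    Bins are ``[start, start + width)`` placed every ``step`` bases from 0
    (``step`` defaults to ``width``, i.e. non-overlapping tiles). A CpG joins
    every bin whose interval contains its position; empty bins are omitted.
    Capsule names are ``"chrom:start-end"``.
    """
    if width <= 0:
        raise ValidationError("bin width must be positive")
    step = width if step is None else step
    if not (0 < step <= width):
        raise ValidationError("step must satisfy 0 < step <= width")

    capsules: dict[str, list[str]] = {}
    for cpg, (chrom, pos) in coords.items():
        if chrom not in chrom_sizes:
            raise ValidationError(f"CpG {cpg!r} on unknown chromosome {chrom!r}")
        length = chrom_sizes[chrom]
        if not (0 <= pos < length):
            raise ValidationError(
                f"CpG {cpg!r} position {pos} outside chromosome {chrom!r} length {length}"
            )
        # bins with start in (pos - width, pos] overlap a point at pos
        first = max(0, (pos - width) // step + 1)
        start = first * step
        while start <= pos:
            end = start + width
            capsules.setdefault(f"{chrom}:{start}-{end}", []).append(cpg)
            start += step
    # deterministic bin order: by chromosome then start
    def _key(name: str) -> tuple[str, int]:
        chrom, span = name.rsplit(":", 1)
        return chrom, int(span.split("-")[0])

    return CapsuleMap({k: capsules[k] for k in sorted(capsules, key=_key)})


def build_from_gene_sets(
    gene_sets: Mapping[str, Sequence[str]],
    gene_capsules: CapsuleMap,
) -> CapsuleMap:
    """Form one capsule per gene set as the union of member genes' CpGs.

    Gene symbols are matched case-insensitively (uppercase-normalized); genes
    absent from ``gene_capsules`` are skipped (counted in the log) and sets
    with zero mapped CpGs are omitted.
    """
    by_gene = {name.upper(): cpgs for name, cpgs in gene_capsules.capsules.items()}
    capsules: dict[str, list[str]] = {}
    n_missing = 0
    for set_name, genes in gene_sets.items():
        seen: dict[str, None] = {}
        for gene in genes:
            cpgs = by_gene.get(str(gene).upper())
            if cpgs is None:
                n_missing += 1
                continue
            for c in cpgs:
                seen.setdefault(c, None)
        if seen:
            capsules[set_name] = list(seen)
    if n_missing:
        logger.info("build_from_gene_sets: %d gene memberships had no CpGs", n_missing)
    return CapsuleMap(capsules)


def filter_min_cpgs(cmap: CapsuleMap, min_cpgs: int = 5) -> CapsuleMap:
    """Retain capsules with *more than* ``min_cpgs`` CpGs (strict inequality).

    The default of 5 keeps gene capsules with more than five associated CpGs.
    Idempotent, and monotone in ``min_cpgs``.
    """
    if min_cpgs < 0:
        raise ValidationError("min_cpgs must be >= 0")
    return CapsuleMap(
        {name: list(cpgs) for name, cpgs in cmap.capsules.items() if len(cpgs) > min_cpgs}
    )


def prefix_names(cmap: CapsuleMap, prefix: str) -> CapsuleMap:
    """Prefix capsule names (e.g. ``bin:``, ``gmt:``) to keep merged maps unambiguous."""
    return CapsuleMap({f"{prefix}{name}": list(c) for name, c in cmap.capsules.items()})


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def load_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: set name, description, then member gene symbols."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name = fields[0]
            genes = [g.upper() for g in fields[2:] if g]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r}")
            sets[name] = genes
    return sets


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes
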