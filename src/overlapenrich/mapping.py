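"""Map genome-wide significant GWAS loci to nearby protein-coding features.

A trait's *element set* is built by assigning every independent significant
variant to the closest allowed (whitelisted-biotype) gene within a distance
window (default 5 kb up- or downstream), deduplicating by feature id, and
applying a minimum-set-size power filter.  LD clumping — deciding which loci
are independent — is the caller's responsibility and happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import (
    BedParseError,
    GenomeDefinition,
    IntervalSet,
    natural_key,
)

__all__ = [
    "DEFAULT_BIOTYPES",
    "DEFAULT_DIST_BP",
    "DEFAULT_MIN_SET_SIZE",
    "VariantHit",
    "GeneFeature",
    "BiotypeWhitelist",
    "ElementSet",
    "SizeRejection",
    "GeneIndex",
    "read_hits_tsv",
    "read_gene_table",
    "map_hit_to_feature",
    "build_element_set",
    "filter_min_size",
    "write_element_set_bed",
]

DEFAULT_DIST_BP = 5000
DEFAULT_MIN_SET_SIZE = 50
#: Alternative power threshold used when reporting overlap results for small
#: gene sets (kept as a preset; the default filter is 50).
REPORTING_MIN_SET_SIZE = 40

#: Ensembl/VEP biotypes counted as protein-coding features.
DEFAULT_BIOTYPES = frozenset(
    {
        "protein_coding",
        "IG_C_gene",
        "IG_D_gene",
        "IG_J_gene",
        "IG_LV_gene",
        "IG_M_gene",
        "IG_V_gene",
        "IG_Z_gene",
        "nonsense_mediated_decay",
        "nontranslating_CDS",
        "non_stop_decay",
        "polymorphic_pseudogene",
        "TR_C_gene",
        "TR_D_gene",
        "TR_J_gene",
    }
)


@dataclass(frozen=True)
class VariantHit:
    """One independent genome-wide significant locus (1-based position)."""

    chrom: str
    pos: int
    id: str
    pvalue: float

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant position must be 1-based positive, got {self.pos}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"p-value must be in (0, 1], got {self.pvalue}")


@dataclass(frozen=True)
class GeneFeature:
    """A gene-body span (0-based half-open) with an Ensembl-style biotype."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "protein_coding"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span {self.chrom}:{self.start}-{self.end}")
        if not self.biotype:
            raise ValueError("biotype must be nonempty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BiotypeWhitelist:
    allowed: frozenset = DEFAULT_BIOTYPES

    def __post_init__(self):
        allowed = frozenset(self.allowed)
        if not allowed:
            raise ValueError("biotype whitelist must be nonempty")
        object.__setattr__(self, "allowed", allowed)

    def __contains__(self, biotype: str) -> bool:
        return biotype in self.allowed


@dataclass
class ElementSet:
    """Deduplicated whitelisted gene features mapped from a trait's loci."""

    trait_id: str
    elements: IntervalSet  # names carry feature ids
    n_input_hits: int
    dist_threshold_bp: int = DEFAULT_DIST_BP

    @property
    def size(self) -> int:
        return len(self.elements)

    @property
    def feature_ids(self) -> list[str]:
        return [str(n) for n in self.elements.names] if self.elements.names is not None else []


@dataclass(frozen=True)
class SizeRejection:
    """Typed rejection of an underpowered element set (not an exception)."""

    trait_id: str
    size: int
    min_set_size: int

    def __bool__(self) -> bool:
        return False


class GeneIndex:
    """Genes grouped by chromosome with arrays for fast nearest-feature search."""

    def __init__(self, genes: Sequence[GeneFeature], whitelist: BiotypeWhitelist | None = None):
        whitelist = whitelist or BiotypeWhitelist()
        by_chrom: dict[str, list[GeneFeature]] = {}
        for g in genes:
            if g.biotype in whitelist:
                by_chrom.setdefault(g.chrom, []).append(g)
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GeneFeature]]] = {}
        for chrom, glist in by_chrom.items():
            # deterministic tie-break order: start, then feature_id
            glist.sort(key=lambda g: (g.start, g.feature_id))
            starts = np.array([g.start for g in glist], dtype=np.int64)
            ends = np.array([g.end for g in glist], dtype=np.int64)
            self._chrom[chrom] = (starts, ends, glist)

    def nearest(self, chrom: str, pos0: int, dist_bp: int) -> Optional[GeneFeature]:
        """Closest whitelisted gene within dist_bp of 0-based position pos0.

        Distance is 0 inside the gene body, otherwise the 1-based separation
        between the variant and the nearest included gene base.  Ties break by
        smaller start, then lexicographic feature id (the index sort order).
        """
        entry = self._chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, glist = entry
        inside = (starts <= pos0) & (pos0 < ends)
        dist = np.where(
            inside, 0, np.where(pos0 < starts, starts - pos0, pos0 - ends + 1)
        )
        best = int(np.argmin(dist))  # first minimum = smallest start, then id
        if dist[best] > dist_bp:
            return None
        return glist[best]


def map_hit_to_feature(
    hit: VariantHit,
    genes: Union[GeneIndex, Sequence[GeneFeature]],
    whitelist: BiotypeWhitelist | None = None,
    dist_bp: int = DEFAULT_DIST_BP,
) -> Optional[GeneFeature]:
    """Closest whitelisted gene within ``dist_bp`` of the variant, or None."""
    if dist_bp < 0:
        raise ValueError("dist_bp must be nonnegative")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, whitelist)
    return index.nearest(hit.chrom, hit.pos - 1, dist_bp)


def build_element_set(
    hits: Sequence[VariantHit],
    genes: Union[GeneIndex, Sequence[GeneFeature]],
    whitelist: BiotypeWhitelist | None = None,
    dist_bp: int = DEFAULT_DIST_BP,
    trait_id: str = "trait",
    build_label: str = "custom",
) -> ElementSet:
    """Map every hit, drop unmapped ones, deduplicate by feature id."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, whitelist)
    seen: dict[str, GeneFeature] = {}
    for hit in hits:
        feature = index.nearest(hit.chrom, hit.pos - 1, dist_bp)
        if feature is not None and feature.feature_id not in seen:
            seen[feature.feature_id] = feature
    elements = IntervalSet.from_intervals(
        [(g.chrom, g.start, g.end, g.feature_id) for g in seen.values()],
        build_label=build_label,
    )
    return ElementSet(
        trait_id=trait_id,
        elements=elements,
        n_input_hits=len(hits),
        dist_threshold_bp=dist_bp,
    )


def filter_min_size(
    es: ElementSet, min_set_size: int = DEFAULT_MIN_SET_SIZE
) -> Union[ElementSet, SizeRejection]:
    """Pass sets with >= min_set_size elements; otherwise a typed rejection."""
    if es.size >= min_set_size:
        return es
    return SizeRejection(trait_id=es.trait_id, size=es.size, min_set_size=min_set_size)


def read_hits_tsv(path, genome: GenomeDefinition | None = None) -> list[VariantHit]:
    """Read a GWAS-hits TSV with header columns chrom, pos, id, pvalue."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str}, comment="#")
    required = {"chrom", "pos", "id", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise BedParseError(f"hits file missing columns: {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        if genome is not None:
            if row.chrom not in genome.chromosomes:
                raise BedParseError(f"unknown chromosome {row.chrom!r} in hits file")
            if not (1 <= row.pos <= genome.length_of(row.chrom)):
                raise BedParseError(
                    f"position {row.chrom}:{row.pos} outside chromosome bounds"
                )
        hits.append(VariantHit(str(row.chrom), int(row.pos), str(row.id), float(row.pvalue)))
    return hits


_GFF_BIOTYPE_KEYS = ("biotype", "gene_biotype", "gene_type")


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            out[key.strip()] = value.strip()
    return out


def read_gene_table(path, fmt: str | None = None) -> list[GeneFeature]:
    """Read gene features from a TSV or GFF3 file.

    TSV: header columns feature_id, chrom, start, end, strand, biotype with
    1-based inclusive coordinates (converted to 0-based half-open on read).
    GFF3: gene-level records whose attribute column carries an ID and a
    biotype/gene_biotype/gene_type key (GFF3 is 1-based inclusive).
    """
    path = str(path)
    if fmt is None:
        fmt = "gff3" if path.endswith((".gff", ".gff3")) else "tsv"
    genes: list[GeneFeature] = []
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
        required = {"feature_id", "chrom", "start", "end", "strand", "biotype"}
        missing = required - set(df.columns)
        if missing:
            raise BedParseError(f"gene table missing columns: {sorted(missing)}")
        for row in df.itertuples(index=False):
            genes.append(
                GeneFeature(
                    feature_id=str(row.feature_id),
                    chrom=str(row.chrom),
                    start=int(row.start) - 1,  # 1-based inclusive -> 0-based half-open
                    end=int(row.end),
                    strand=str(row.strand),
                    biotype=str(row.biotype),
                )
            )
    elif fmt == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise BedParseError("expected 9 tab-separated GFF3 columns", lineno)
                if fields[2] != "gene":
                    continue
                attrs = _parse_gff_attributes(fields[8])
                biotype = next(
                    (attrs[k] for k in _GFF_BIOTYPE_KEYS if k in attrs), None
                )
                feature_id = attrs.get("ID") or attrs.get("gene_id")
                if feature_id is None:
                    raise BedParseError("gene record lacks ID attribute", lineno)
                if biotype is None:
                    raise BedParseError(
                        f"gene {feature_id!r} lacks a biotype attribute", lineno
                    )
                genes.append(
                    GeneFeature(
                        feature_id=str(feature_id),
                        chrom=fields[0],
                        start=int(fields[3]) - 1,
                        end=int(fields[4]),
                        strand=fields[6],
                        biotype=biotype,
                    )
                )
    else:
        raise ValueError(f"unknown gene table format {fmt!r}")
    return genes


def write_element_set_bed(es: ElementSet, path) -> None:
    """Write an element set as BED with the feature id in the name column."""
    from .intervals import write_bed

    write_bed(es.elements, path)
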