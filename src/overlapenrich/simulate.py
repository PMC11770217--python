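"""Desk-scale synthetic genomes, gene models, annotations, and GWAS hits.

The generator is the test substrate for the whole pipeline.  It emulates the
shape of the real inputs — a genome with heavy-tailed (log-normal) gene
lengths, a clustered annotation covering a configurable genome fraction, and
per-trait sets of significant loci — with a *planted* enrichment level rho:
each hit's gene is, with probability rho, forced to be one that overlaps the
annotation, and otherwise drawn uniformly from all whitelisted genes.
rho = 0 yields a null trait whose element set overlaps the annotation no
more than random genes do.  The planted truth is defined at the gene level
because the pipeline's statistic counts overlapping elements.

It deliberately omits LD structure, allele frequencies, and realistic effect
sizes: those shape which loci are significant, a decision upstream of this
pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomeDefinition,
    IntervalSet,
    merge,
    overlap_flags,
    write_bed,
)
from .mapping import DEFAULT_BIOTYPES, GeneFeature, VariantHit

__all__ = [
    "SimConfig",
    "simulate_genome_and_genes",
    "simulate_annotation",
    "simulate_trait_hits",
    "simulate_results_table",
    "write_fixture_dir",
]

#: biotypes used for the non-protein-coding remainder of simulated genes
NONCODING_BIOTYPES = ("lincRNA", "antisense", "processed_pseudogene", "miRNA", "snoRNA")

GENOME_WIDE_ALPHA = 5e-8


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixture.

    Defaults are desk-scale: a 2 x 10 Mb genome, 2,000 genes with log-normal
    lengths (median 2 kb), an annotation covering 5% of the genome in ~1.5 kb
    regions, and 60 hits per trait.
    """

    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 2000
    gene_length_median: int = 2000
    gene_length_sigma: float = 0.5
    pc_fraction: float = 0.7
    annot_coverage: float = 0.05
    annot_region_median: int = 1500
    annot_region_sigma: float = 0.5
    n_hits: int = 60
    planted_enrichment: float = 0.0
    dist_bp: int = 5000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.annot_coverage < 1):
            raise ValueError("annot_coverage must be in (0, 1)")
        if not (0 <= self.planted_enrichment <= 1):
            raise ValueError("planted_enrichment must be in [0, 1]")
        if not (0 < self.pc_fraction <= 1):
            raise ValueError("pc_fraction must be in (0, 1]")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_hits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.gene_length_median >= self.chrom_length:
            raise ValueError("gene lengths cannot exceed chromosome length")

    @property
    def build_label(self) -> str:
        return f"sim{self.n_chroms}x{self.chrom_length}"


def _rng(cfg_seed, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg_seed), salt]))


def _lognormal_lengths(
    rng: np.random.Generator, median: int, sigma: float, size: int, upper: int
) -> np.ndarray:
    lengths = rng.lognormal(mean=math.log(median), sigma=sigma, size=size)
    return np.clip(np.round(lengths).astype(np.int64), 50, upper)


def simulate_genome_and_genes(cfg: SimConfig):
    """Uniformly placed genes with log-normal lengths and assigned biotypes.

    Returns (GenomeDefinition, list[GeneFeature]).  Genes may overlap each
    other (as real gene bodies do); exactly floor(pc_fraction * n) genes,
    chosen at random, are protein_coding, the rest cycle through non-coding
    biotypes.  The whole table is deterministic under cfg.seed.
    """
    genome = GenomeDefinition(
        cfg.build_label,
        {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)},
    )
    rng = _rng(cfg.seed, 1)
    upper = max(cfg.chrom_length // 10, 100)
    lengths = _lognormal_lengths(
        rng, cfg.gene_length_median, cfg.gene_length_sigma, cfg.n_genes, upper
    )
    chrom_names = list(genome.chromosomes)
    chrom_idx = rng.integers(0, cfg.n_chroms, size=cfg.n_genes)
    starts = rng.integers(0, cfg.chrom_length - lengths + 1)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    n_pc = int(math.floor(cfg.pc_fraction * cfg.n_genes))
    is_pc = np.zeros(cfg.n_genes, dtype=bool)
    pc_choice = rng.permutation(cfg.n_genes)[:n_pc]
    is_pc[pc_choice] = True
    genes = []
    for i in range(cfg.n_genes):
        biotype = (
            "protein_coding" if is_pc[i] else NONCODING_BIOTYPES[i % len(NONCODING_BIOTYPES)]
        )
        genes.append(
            GeneFeature(
                feature_id=f"G{i:05d}",
                chrom=chrom_names[chrom_idx[i]],
                start=int(starts[i]),
                end=int(starts[i] + lengths[i]),
                strand=str(strands[i]),
                biotype=biotype,
            )
        )
    return genome, genes


def simulate_annotation(cfg: SimConfig, genome: GenomeDefinition) -> IntervalSet:
    """Random regions accumulated until the merged set covers the target
    genome fraction; realized coverage lands within 2% of target (the last
    regions are trimmed on overshoot).  Output is merged."""
    rng = _rng(cfg.seed, 2)
    target = cfg.annot_coverage * genome.total_bp
    chrom_names = list(genome.chromosomes)
    chrom_lengths = np.array([genome.chromosomes[c] for c in chrom_names])
    probs = chrom_lengths / chrom_lengths.sum()
    rows: list[tuple] = []
    covered = 0
    batch = max(16, int(target / cfg.annot_region_median / 8))
    while covered < target:
        lengths = _lognormal_lengths(
            rng, cfg.annot_region_median, cfg.annot_region_sigma, batch,
            int(chrom_lengths.min()),
        )
        cidx = rng.choice(len(chrom_names), size=batch, p=probs)
        starts = rng.integers(0, chrom_lengths[cidx] - lengths + 1)
        for ci, st, ln in zip(cidx, starts, lengths):
            if covered >= target:
                break
            st, en = int(st), int(st + ln)
            # trim the final region so coverage lands on target
            overshoot = covered + (en - st) - target
            if overshoot > 0:
                en = max(st + 1, en - int(math.ceil(overshoot)))
            rows.append((chrom_names[ci], st, en))
            merged = merge(IntervalSet.from_intervals(rows, genome.build_label))
            covered = merged.total_bp
    return merge(IntervalSet.from_intervals(rows, genome.build_label))


def simulate_trait_hits(
    cfg: SimConfig,
    genome: GenomeDefinition,
    genes: Sequence[GeneFeature],
    annot: IntervalSet,
    rng_seed=None,
    trait_salt: int = 3,
) -> list[VariantHit]:
    """Significant loci for one trait with planted enrichment rho.

    Each hit picks a whitelisted gene — with probability rho one that
    overlaps the annotation, otherwise uniformly from all whitelisted genes.
    Non-planted variants are placed uniformly within the gene body extended
    by dist_bp/2 on each side (so mapping recovers the gene up to occasional
    nearest-gene swaps).  Planted variants are placed inside the gene's
    overlap with the annotation: the mapped element then contains an
    annotated base even if a distance-0 tie swaps genes, so at rho = 1 every
    mapped element overlaps the annotation.
    """
    rng = (
        np.random.default_rng(rng_seed)
        if rng_seed is not None
        else _rng(cfg.seed, trait_salt)
    )
    rho = cfg.planted_enrichment
    wl = [g for g in genes if g.biotype in DEFAULT_BIOTYPES]
    if not wl:
        raise ValueError("no whitelisted genes in the simulated gene table")
    wl_set = IntervalSet.from_intervals(
        [(g.chrom, g.start, g.end, g.feature_id) for g in wl],
        build_label=genome.build_label,
    )
    annot_m = annot if annot.merged else merge(annot)
    flags = overlap_flags(wl_set, annot_m)
    by_id = {g.feature_id: g for g in wl}
    names = [str(n) for n in wl_set.names]
    overlapping = [by_id[n] for n, f in zip(names, flags) if f]
    if rho > 0 and not overlapping:
        raise ValueError(
            "planted enrichment requested but no whitelisted gene overlaps the annotation"
        )
    # annotated segments per overlapping gene, for planted-hit placement
    overlap_segments: dict[str, list[tuple[int, int]]] = {}
    if overlapping:
        from .intervals import intersect

        for g in overlapping:
            gi = IntervalSet.from_intervals(
                [(g.chrom, g.start, g.end)], build_label=genome.build_label
            )
            segs = intersect(gi, annot_m)
            overlap_segments[g.feature_id] = [
                (int(s), int(e)) for _, s, e in zip(segs.chroms, segs.starts, segs.ends)
            ]
    pad = cfg.dist_bp // 2
    hits = []
    for i in range(cfg.n_hits):
        planted = rho > 0 and rng.random() < rho
        if planted:
            gene = overlapping[rng.integers(0, len(overlapping))]
            segs = overlap_segments[gene.feature_id]
            seg_lens = np.array([e - s for s, e in segs])
            j = rng.choice(len(segs), p=seg_lens / seg_lens.sum())
            pos0 = int(rng.integers(segs[j][0], segs[j][1]))
        else:
            gene = wl[rng.integers(0, len(wl))]
            lo = max(0, gene.start - pad)
            hi = min(genome.length_of(gene.chrom), gene.end + pad)
            pos0 = int(rng.integers(lo, hi))
        # log-uniform p-value below the genome-wide threshold
        logp = rng.uniform(math.log10(GENOME_WIDE_ALPHA) - 4, math.log10(GENOME_WIDE_ALPHA))
        hits.append(
            VariantHit(
                chrom=gene.chrom,
                pos=pos0 + 1,
                id=f"rs{i:06d}",
                pvalue=10 ** logp,
            )
        )
    return hits


def simulate_results_table(
    n_traits: int,
    noise: float = 0.5,
    latent_sign: float = 1.0,
    seed: int = 0,
    annot_id: str = "annot1",
):
    """Paired method-results tables with controllable rank agreement.

    Both tables share a latent per-trait effect; independent Gaussian noise
    of the given SD is added to each.  noise=0 gives identical rankings;
    latent_sign=-1 makes the second table anti-correlated (reversed ranking
    at noise 0).  Returns (table_a, table_b) with columns trait_id, annot_id,
    enrichment, se, p.
    """
    rng = np.random.default_rng(seed)
    latent = rng.normal(0.0, 1.0, size=n_traits)
    trait_ids = [f"trait{i:03d}" for i in range(n_traits)]

    def build(values: np.ndarray) -> pd.DataFrame:
        se = np.full(n_traits, 0.25)
        z = values / se
        from scipy import stats as sps

        return pd.DataFrame(
            {
                "trait_id": trait_ids,
                "annot_id": annot_id,
                "enrichment": values,
                "se": se,
                "p": 2 * sps.norm.sf(np.abs(z)),
            }
        )

    a = build(latent + noise * rng.normal(size=n_traits))
    b = build(latent_sign * latent + noise * rng.normal(size=n_traits))
    return a, b


def write_fixture_dir(
    cfg: SimConfig,
    outdir,
    n_traits: int = 1,
    rho_values: Optional[Sequence[float]] = None,
) -> Path:
    """Emit a complete fixture directory in the pipeline's input formats.

    chrom.sizes, genes.tsv (1-based inclusive), annotation.bed, one
    hits_<trait>.tsv per trait, and sim_config.json recording the exact
    conditions.  Deterministic under cfg.seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate_genome_and_genes(cfg)
    annot = simulate_annotation(cfg, genome)

    with open(outdir / "chrom.sizes", "w") as fh:
        for name, length in genome.chromosomes.items():
            fh.write(f"{name}\t{length}\n")
    gene_rows = pd.DataFrame(
        {
            "feature_id": [g.feature_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start + 1 for g in genes],  # back to 1-based inclusive
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "biotype": [g.biotype for g in genes],
        }
    )
    gene_rows.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    write_bed(annot, outdir / "annotation.bed")

    rhos = list(rho_values) if rho_values is not None else [cfg.planted_enrichment] * n_traits
    trait_ids = []
    for t, rho in enumerate(rhos):
        tcfg = SimConfig(**{**asdict(cfg), "planted_enrichment": rho})
        seed = np.random.SeedSequence([cfg.seed, 1000 + t]).generate_state(1)[0]
        hits = simulate_trait_hits(tcfg, genome, genes, annot, rng_seed=int(seed))
        trait_id = f"trait{t:03d}"
        trait_ids.append(trait_id)
        pd.DataFrame(
            {
                "chrom": [h.chrom for h in hits],
                "pos": [h.pos for h in hits],
                "id": [h.id for h in hits],
                "pvalue": [h.pvalue for h in hits],
            }
        ).to_csv(outdir / f"hits_{trait_id}.tsv", sep="\t", index=False)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(
            {**asdict(cfg), "traits": trait_ids, "rho_values": [float(r) for r in rhos]},
            fh,
            indent=2,
        )
        fh.write("\n")
    return outdir
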