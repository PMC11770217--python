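# overlapenrich

Gene-overlap enrichment of GWAS loci in genomic annotations, with a
length-matched resampling null.

## The problem

Given a trait's genome-wide significant loci and a set of genomic regions of
interest — human-gained enhancers and promoters, accelerated regions,
selective-sweep intervals, introgression maps, or any other BED annotation —
does the trait's gene set overlap those regions more than random chance
allows?  Heritability-partitioning methods such as stratified LD score
regression answer a related question at the SNP level, but they are biased
for small annotations that cover too few common variants.  `overlapenrich`
implements the complementary gene-level test: map each significant variant
to its closest protein-coding gene, measure how many of those genes touch
the annotation, and calibrate that overlap against random expectation.

It is a library plus a CLI, aimed at statistical geneticists who have
LD-clumped GWAS hits and annotations in standard formats (chrom.sizes,
GFF3/TSV gene tables, BED) and want a tested, reproducible enrichment
pipeline with a built-in synthetic-data generator for validation.

## The method

For a trait with significant variants mapped to a deduplicated *element
set* of genes E (variants map to the closest whitelisted-biotype feature
within 5 kb; sets smaller than 50 elements are dropped as underpowered),
the test statistic against annotation A is intersections per base pair:

    T(E, A) = #{ g in E : g overlaps A } / total_bp(E)

The null distribution is built by resampling: element lengths are split
into deciles, and each of 1,000 replicates places, for every decile, n_k
random intervals of the decile's mean length l_k uniformly on the genome
(chromosome chosen proportional to the number of valid start positions).
A two-parameter Weibull fitted to the replicate statistics by maximum
likelihood gives the upper-tail p-value

    p = P(T >= t_obs) = exp( -(t_obs / lambda)^k ).

Overlap enrichment is the percent difference against the background mean:

    I = (t_obs - mean(T_null)) / mean(T_null) * 100%,

with I > 0 meaning enrichment.  Benjamini–Hochberg FDR is applied across
each results batch.  Companion stages:

- **perturb** — robustness harness: drop 10% of annotation regions (3
  replicates) or shrink/extend every region's ends by 5% of its length,
  rerun with identical background seeds, and report Pearson correlations
  with the original results;
- **concord** — two-sided Wilcoxon signed-rank test on independently ranked
  results from two methods (e.g. this pipeline vs a heritability-enrichment
  table);
- **meta** — random-effects meta-analysis of per-trait estimates by trait
  category under a genetic-correlation-aware error structure
  (Cov(eps) = diag(s)·R·diag(s), tau² by REML, summary estimate by GLS).

## Worked example

Everything runs on synthetic data out of the box.  Generate a two-trait
fixture with a strong planted signal (each hit's gene overlaps the
annotation with probability 0.6) and run the pipeline:

```bash
overlapenrich simulate --out demo/fixture --n-traits 2 --rho 0.6 --seed 42
overlapenrich run \
    --genome demo/fixture/chrom.sizes \
    --genes  demo/fixture/genes.tsv \
    --annot  demo/fixture/annotation.bed \
    --hits   demo/fixture/hits_trait000.tsv \
    --hits   demo/fixture/hits_trait001.tsv \
    --out    demo/results --seed 7
```

`demo/results/results.tsv` (provenance header omitted):

```
trait_id  annot_id    set_size  observed  bg_mean   I_percent   I_percent_count  p         q
trait000  annotation  52        0.000311  0.000049  533.373213  533.356791       0.000000  0.000000
trait001  annotation  57        0.000225  0.000049  363.586063  363.586063       0.000000  0.000000
```

Reading trait000's row: its 60 hits mapped to 52 unique genes; 0.000311
intersections per bp were observed against 0.000049 expected from 1,000
length-matched random sets, a +533% overlap enrichment whose Weibull tail
p-value (and BH q) round to zero at the table's fixed six decimals.  A null
trait (`--rho 0`) instead gives I near 0% and a p-value uniform on (0, 1].
Traits whose element sets fall below 50 genes are listed in
`rejected_traits.tsv` instead of the results.

The other subcommands (`perturb`, `meta`, `concord`, `intersect`) consume
the same fixture formats; `overlapenrich <cmd> --help` shows their options.

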