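# founderrate

Population-genetic analysis of the last woolly mammoth population: how fast
did its mitogenome evolve after the founding bottleneck?

When rising Holocene seas isolated Wrangel Island, the mammoths marooned
there descended from a single maternal lineage — their Holocene mitogenomes
form a star-like cluster of seven haplotypes within one or two mutational
steps of a modal sequence. Because every one of those haplotypes arose *in
situ* after a known founding time, the number of distinct haplotypes among
radiocarbon-dated samples is itself a clock. This package implements that
idea as a reusable, tested library for anyone working with serially sampled
(ancient-DNA) data from founder populations:

* a **heterochronous coalescent simulator** for a single isolated
  constant-size population with forced founder coalescence at the isolation
  time `T_iso`, with Poisson mutation dropping (infinite- or finite-sites,
  with transition bias) and haplotype counting;
* **grid inference**: score a log-spaced grid over the female effective
  population size and the mutation rate with the Monte-Carlo probability
  `P(K = k_obs)` of reproducing the observed haplotype count, marginalize
  over `N_ef`, and report the mode and 95% HPD of the rate curve;
* a **haplotype pipeline**: alignment masking, haplotype collapsing with an
  explicit missing-data policy, group counts, detection of group-exclusive
  fixed mutations, coding-effect classification under the vertebrate
  mitochondrial code (table 2), and median-joining networks with
  star-pattern diagnostics;
* **synthetic data generators** reproducing the study conditions (the
  14-sample Holocene sampling schedule, star-like alignments, planted
  synapomorphies) plus the packaged 42-sample metadata table.

## The model in brief

Backwards in time, sampled lineages enter the genealogy at their calibrated
ages; `k` active lineages coalesce at rate `k(k-1)/2 · 1/N` per generation
(`N` maternal lineages, generation time 15 y), and all survivors merge into
the founder at `T_iso` (default 12,000 calBP). Mutations fall on branches
at `μ·L` per year (`L` = 16,506 bp). The observed statistic is the
haplotype count `K` among `n = 14` serial samples; the data give
`k_obs = 7`. The grid's `N_ef` axis counts individuals of both sexes;
maternal lineages are `N_ef/2` under the 1:1 sex ratio (see
`docs/methods.md`).

## Worked example

```bash
python analysis/01_table1_haplotype_counts.py
python analysis/02_narrow_rate_inference.py
```

The first recomputes the haplotype bookkeeping from the packaged metadata:

```
34 haplotypes among 42 samples; the 14 Holocene island samples carry 7.
```

The second runs the narrow-prior inference (N_ef 100–450 individuals,
μ 0.17–66.7 × 10⁻⁸ site⁻¹ yr⁻¹, 40×40 log grid, 400 replicates per cell)
and prints:

```
Best-supported rate 3.12e-08 site^-1 year^-1 (95% HPD 1.07e-08 - 7.82e-08)
```

i.e. the probability of seeing exactly seven haplotypes among the fourteen
dated island samples is maximized at ≈3 × 10⁻⁸ substitutions per site per
year — two- to threefold above phylogenetic mitogenome rates, consistent
with relaxed purifying selection in the small island population.
`analysis/03_wide_grid_plateau.py` maps how the estimate depends on the
assumed population size (it stabilizes near 0.6 × 10⁻⁸ for very large
`N_ef`, where the genealogy is a pure star), and
`analysis/04_synthetic_pipeline.py` exercises the haplotype pipeline end to
end on a synthetic star alignment with planted tRNA/synonymous/
nonsynonymous mutations, recovering all three with their effect classes
(e.g. a `T19A`-style amino-acid replacement).

The same operations are scriptable via the CLI, e.g.:

```bash
founderrate simulate --ages ages.tsv --n-ef 164 --mu 3e-8 --reps 1000 \
    --seed 42 --out kdist.tsv
founderrate infer-rate --ages ages.tsv --k-obs 7 --grid 40x40 --reps 400 \
    --seed 42 --out surface.tsv --summary estimate.json
founderrate haplotypes --fasta aln.fa --meta meta.tsv --mask vntr.tsv \
    --out haplotypes.tsv
founderrate network --fasta aln.fa --meta meta.tsv --out net.graphml
```

## Layout

```
src/founderrate/     library (simulator, grid inference, pipeline, synth)
analysis/            numbered narrative drivers writing to results/
scripts/acceptance.py  headline-number reproduction
tests/               pytest suite (unit, property and end-to-end checks)
docs/methods.md      model, conventions, parameter defaults, limitations
```
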