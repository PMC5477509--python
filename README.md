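# feralgen

Population-genomic analysis of de-domesticated (feral) populations versus
their cultivated source, with a bundled forward Wright-Fisher simulator for
end-to-end validation. The pipeline covers:

- **Windowed statistics** — nucleotide diversity (π), Tajima's *D*,
  Weir & Cockerham (1984) weighted FST and observed heterozygosity (H_O) in
  sliding windows (default 100 kb / 10 kb step), tolerant of missing calls.
- **Genome scans** — divergent-region calling from genome-wide Z(FST) ≥ 3
  with gene mapping and overlap rates, and a balancing-selection detector
  (top-5% Tajima's *D* runs > 0.5 Mb, filtered on the cultivated background).
- **AFD analysis** — classification of feral-population SNPs into standing
  variation vs new mutations relative to the cultivated panel, and
  allele-frequency-differentiation (AFD) distributions genome-wide and inside
  selected regions.
- **Demographic inference** — simulation-based composite-likelihood
  comparison of four split models (bottleneck/no-bottleneck ×
  migration/no-migration) on projected, folded, singleton-masked joint site
  frequency spectra, plus `Ne = theta / (4 mu L)` arithmetic.
- **Simulator** — discrete-generation Wright-Fisher engine with recurrent
  biallelic mutation, viability selection (directional and overdominant),
  a founder bottleneck, post-bottleneck symmetric migration and free
  recombination, emitting VCF + population map + a truth table.

All interval arithmetic is 0-based half-open; VCF positions are converted on
read/write. Missing genotypes are handled per statistic (sites are never
dropped globally).

## CLI

Everything is exposed through one executable with global options
`--seed`, `--window-size`, `--window-step`, `--out-prefix`, `--log-level`
(exit codes: 0 ok, 1 input error, 2 degenerate computation):

```sh
# simulate a de-domestication scenario (VCF, popmap, truth table, params)
feralgen --seed 1 --out-prefix run simulate --n-weedy 40 --n-cult 40

# windowed pi / Tajima's D / H_O per group and weedy-vs-cultivated FST
feralgen --out-prefix run stats --vcf run.vcf --popmap run.popmap.tsv \
    --chrom-lengths run.chrom_lengths.tsv \
    --weedy-group weedy --cult-group cultivated

# Z(FST) divergent regions (optionally annotate genes from a BED file)
feralgen --out-prefix run scan-divergence \
    --fst-windows run.weedy_vs_cultivated.fst.tsv

# balancing-selection regions
feralgen --out-prefix run scan-balancing \
    --weedy-d run.weedy.tajimas_d.tsv --cult-d run.cultivated.tajimas_d.tsv \
    --fst-windows run.weedy_vs_cultivated.fst.tsv

# standing/new classification and AFD distributions
feralgen --out-prefix run afd --vcf run.vcf --popmap run.popmap.tsv \
    --weedy-group weedy --cult-group cultivated

# joint SFS (projected, folded, singletons masked) and model comparison
feralgen --out-prefix run sfs --vcf run.vcf --popmap run.popmap.tsv \
    --cult-group cultivated --weedy-group weedy --project 40 40
feralgen --seed 1 --out-prefix run fit-demography \
    --sfs-tsv run.sfs.tsv --sfs-json run.sfs.json
```

Inputs: VCF v4.x (GT field; biallelic SNPs, other records skipped), a
`sample<TAB>group<TAB>role` population map (roles: weedy, cultivated, wild),
BED annotations (optional 4th column name, 5th column `TE`/`non-TE`), and a
`chrom<TAB>length` TSV. All result tables are TSV; coordinates in outputs
other than VCF are 0-based half-open.

## Library use

```python
from feralgen import sim, scans, stats, demog

spec, demo_params, loci = sim.dedomestication_preset()
matrix, popmap, truth = sim.simulate_dedomestication(
    spec, demo_params, loci, n_sample_weedy=40, n_sample_cult=40, seed=1)
windows = scans.make_windows(spec.chrom_lengths)
fst = stats.wc_fst_window(
    matrix, popmap.samples_in_group("weedy"),
    popmap.samples_in_group("cultivated"), windows)
regions = scans.divergent_regions(fst, z_threshold=3.0)
```

Notes on conventions: π uses the full window span as denominator (invariant
bases included); windowed FST is the weighted ratio of summed W&C variance
components with negative estimates retained; Tajima's *D* uses the constants
at the per-window median called-allele count and requires ≥ 3 segregating
sites per window; spectra are built on alternative-allele counts and folded
to minor-allele orientation (no ancestral-state inference).
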