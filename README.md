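# aegiscan

Analysis toolkit for SNP genotyping arrays applied to wheat wild relatives.
Bread wheat (*Triticum aestivum*, AABBDD) has a narrow gene pool; the
goatgrass genus *Aegilops* — 23 species spanning diploid to hexaploid
genomes built from the D, S, U, C, N, M (and T) subgenomes — is a major
reservoir of disease-resistance and adaptation alleles that breeders move
into wheat through interspecific crosses.  `aegiscan` implements the
computational side of working with a ~36,711-probe wheat-relative
genotyping array:

* **Polyploid cluster calling** — biallelic probes report a B-allele
  hybridization fraction; in mixed-ploidy cohorts the cluster a sample
  lands in depends on who else was screened.  The package models
  *co-dominant* (single-subgenome) and *dominant* (cross-genome) probes
  and calls genotypes cohort-relatively: for a dominant D/M/U probe, a
  DDMMUU accession `ABAAAA` (fraction 1/6), a DDMMUU `BBAAAA` (2/6) and a
  diploid DD `AB` (1/2) are called 0, 1, 2.  Loci with more than three
  clusters are flagged as off-target variants.
* **Diversity statistics** — polymorphism counts within species and
  versus wheat, accession subset resampling, Nei's standard genetic
  distance *D* = −ln(J_xy / √(J_x·J_y)) and Hudson-estimator F_st
  (Nei G_st optional) between species.
* **Ordination and phylogeny prep** — 1−IBS distances (pairwise-complete
  over jointly called loci), classical PCoA with variance proportions,
  SNP filtering (drop monomorphic, MAF < 0.1, ≥10% missing), hapmap
  export and a deterministic neighbor-joining tree rooted on an outgroup.
* **Introgression scanning** — the detector used to track alien chromatin:
  percentage match between a hexaploid line and a donor accession over
  10-SNP windows; a window matching ≥40% flags putative donor material,
  and runs of flagged windows become BED segments.
* **Ground-truthed simulation** — generators for mixed-ploidy species
  panels and for wheat lines carrying donor blocks at known coordinates,
  with per-marker truth tracks, used throughout the test suite.

## Worked example

Simulate ten wheat lines that each carry one 100 Mbp *Ae. sharonensis*
block, then scan them against the donor parent:

```python
import numpy as np
from aegiscan import (IntrogressionBlock, ScanParams, SimulationConfig,
                      simulate_introgression_lines, scan_population)

blocks = tuple(
    IntrogressionBlock(f"L{i:02d}", "Aegilops sharonensis",
                       ("1A", "1B", "1D")[i % 3],
                       start := i * 40_000_000, start + 100_000_000)
    for i in range(10))
cfg = SimulationConfig(seed=2024, n_markers=2100,
                       chromosomes=("1A", "1B", "1D"),
                       nocall_rate=0.0, call_error_rate=0.0, blocks=blocks)
matrix, truth = simulate_introgression_lines(cfg)

donor = matrix.subset_samples(["Aegilops_sharonensis_01"])
lines = matrix.subset_samples([b.line_id for b in blocks])
result = scan_population(lines, donor, ScanParams(window_size=10,
                                                  match_threshold=40.0))
seg = result.segments[("L01", "Aegilops_sharonensis_01")][0]
print(seg.chromosome, seg.start_bp, seg.end_bp, round(seg.mean_match_percent))
```

This prints `1B 39460451 144670228 94`: the scan recovers the block
declared on chromosome 1B at 40–140 Mbp.  Segment bounds extend to the
outermost markers of the flanking flagged windows, so they bracket the
true block with sub-window slack, and the mean match of 94% reflects the
partially overlapping edge windows around an otherwise perfect interior.
Under the same configuration all ten declared blocks are recovered, while
lines without blocks flag fewer than 5% of windows.

The same analyses are available from the shell:

```sh
aegiscan simulate --seed 7 --mode panel --out-dir out/panel
aegiscan diversity --matrix out/panel/panel.tsv --out-dir out/div
aegiscan scan --lines lines.tsv --donors donors.tsv --window 10 \
    --threshold 40 --out-dir out/scan
```

`aegiscan diversity` also reports the packaged per-species summary of the
array (23 *Aegilops* species): e.g. 9,190/36,711 probes (25.0%)
polymorphic within *Ae. uniaristata*, a mean of 88.8% polymorphic versus
wheat, and R² = 0.56 between accession count and within-species
polymorphism.

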