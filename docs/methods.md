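# Methods

## Probe-response model and cohort-relative calling

Array probes are biallelic (alleles A/B) and differ in genome
specificity.  A *co-dominant* probe hybridizes a single subgenome, so a
diploid-like 0/1/2 dosage is read directly.  A *dominant* (cross-genome)
probe hybridizes several homoeologous subgenomes at once; the signal it
reports is the B-allele fraction over all hybridizing copies,

    f = (# B alleles among hybridizing subgenome copies) / (2 g),

where g is the number of hybridizing subgenome copies in that accession.
Fractions therefore live on the lattice {0, 1/(2g), …, 1}, and the same
probe reads different lattices in accessions of different ploidy.

Intensity-clustering callers assign genotype codes per cluster, not per
dosage, and the clusters present depend on the whole cohort.  We model
this with `cluster_call_cohort`: distinct fraction values (snapped to a
resolution, default 1/24 — fine enough to separate all lattices up to
dodecaploid) are ranked ascending and mapped to calls 0, 1, 2.  The
canonical mixed cohort — DDMMUU accessions ABAAAA (1/6) and BBAAAA (2/6)
with a diploid DD accession AB (1/2) under a dominant D/M/U probe —
yields calls 0, 1, 2.  Ascending-fraction labelling is a fixed convention
of this package; commercial callers label clusters arbitrarily, and the
co-dominant two-cluster case (where 0 = BB, 1 = AB is equally defensible)
is inherently label-ambiguous.  Loci with more than three distinct
clusters are treated as off-target variants (OTV): all calls are set to
NOCALL and the locus is flagged.

## Synthetic panels

`simulate_species_panel` emulates a mixed-ploidy relative-species screen.
Per species and subgenome, each marker receives a B-allele frequency:
with probability `prob_polymorphic` (default 0.4) it segregates with a
frequency drawn from Beta(0.8, 0.8); otherwise it is fixed for A or B
with equal probability, which is what creates fixed differences between
species.  Accession genotypes are drawn under Hardy–Weinberg within each
subgenome.  Probes are co-dominant with probability 0.7 (the array was
enriched for co-dominant behaviour); dominant probes draw ≥2 target
letters from the panel's subgenome universe.  Because probes derive from
wheat genic sequence with homoeoloci in every relative genome, an
accession lacking all of a probe's target subgenomes still hybridizes
through its homoeologous copies: a co-dominant probe then reads the
accession's first subgenome, a dominant probe all of them.  Noise is
injected after calling: call errors (replace with one of the other two
codes, default rate 0.01) then no-calls (default rate 0.05).  With the
default five-species panel this produces a mean call rate near 0.8 and an
OTV fraction near 0.15, in the range observed on real relative panels.
All draws come from a single seeded generator consumed in a fixed order
(marker placement → probe classes → frequencies → genotypes → noise), so
one seed fixes the whole dataset bit-for-bit.

Default sizes (2,000 markers; accession counts 12/14/22/15/5 across five
species spanning diploid to hexaploid) keep every statistic estimable at
desk scale while preserving the structure the real array shows:
subgenome-structured alleles, probe-class mixtures, missing data, and a
~36k-probe total is not required for any inference the package makes.

What the generator does **not** model: continuous hybridization
intensities and cluster-boundary miscalls, batch/plate effects, linkage
disequilibrium within species (frequencies are drawn independently per
marker), and ascertainment of probes toward wheat-vs-relative
polymorphism in the species panel.  Passing tests therefore demonstrate
correctness of the estimators and the detector's logic under the stated
statistical structure, not performance on any particular real dataset.

`simulate_introgression_lines` builds hexaploid wheat lines (AABBDD) plus
wheat background cultivars and donor accessions.  Wheat is fixed (AA or
BB, equal odds) at the interrogated subgenome of each marker; the donor
parent differs from wheat at a `donor_divergence` fraction of markers
(default 0.9, reflecting probes selected to maximize relative-vs-wheat
polymorphism) with a small residual heterozygosity (0.05; these are
largely selfing species).  Inside a declared block the line's
interrogated allele pair is replaced by the donor parent's pair before
calling; calls here are plain dosages (the straightforward co-dominant
case for discrete populations), and noise is applied after substitution.
The truth track records per-marker origin (background/donor) per line.

## Diversity statistics

Calls are B-dosages; NOCALL is excluded from every denominator and
nothing is imputed.  A locus enters a between-population statistic only
if every population involved has ≥1 called allele (≥2 for the Hudson
correction terms).

* Within-species polymorphism: number of markers with ≥2 distinct called
  genotypes among the species' accessions (monotone non-decreasing in the
  accession set).
* Versus-reference polymorphism: markers where any called genotype in the
  species differs from any called genotype in the reference group.  The
  any-difference rule (rather than fixed-differences-only) is what makes
  counts versus wheat approach the array total, as observed.
* Nei's standard distance: D = −ln(J_xy/√(J_x·J_y)) with identities
  averaged over usable loci; opposite fixation at all loci gives J_xy = 0,
  reported as +∞.
* F_st: Hudson ratio-of-averages by default — per-locus numerator
  (x−y)² − x(1−x)/(n_x−1) − y(1−y)/(n_y−1), denominator
  x(1−y) + y(1−x), summed before dividing — chosen for its small
  sample-size bias; Nei G_st is available as an option.  Negative
  multi-locus estimates are clamped to 0, and values are capped at 1.

## Ordination

The between-accession distance is 1 − IBS with sharing scores 1 / 0.5 / 0
for identical / het-vs-hom / opposite-homozygote call pairs, computed
pairwise-complete over jointly called loci; a pair with no shared called
locus is an error rather than a guess.  PCoA is classical metric scaling
(double-center −½D², `scipy.linalg.eigh`); negative eigenvalues from
non-Euclidean distances are dropped from both the axes and the variance
denominator, so reported variance proportions sum to 100% over retained
axes.  Axis signs and rotations are arbitrary — tests assert recovered
geometry, never coordinates.  A genotype-covariance PCA is provided as an
alternative view.

## Marker filtering and trees

Filtering follows SNP-phylogeny pipeline defaults: drop monomorphic
markers, markers with pooled-sample MAF < 0.1 (exactly 0.1 is kept), and
markers missing in ≥10% of samples (exactly 10% is removed; the missing
fraction is computed as an integer ratio so the boundary compares
exactly).  Each removed marker is charged to one rule in the priority
order monomorphic → MAF → missingness, so tallies sum to the number
removed, and the filter is idempotent.

The in-package tree is neighbor joining on any distance matrix (IBS by
default), with Q-criterion ties broken lexicographically on the joined
pair's labels for a deterministic topology, tiny negative branch lengths
clamped to zero, and rooting on a named outgroup.  It exists to make
species-level structure testable offline; likelihood trees and bootstrap
support are delegated to external pipelines via the hapmap export.

## Introgression scanning

Windows of 10 consecutive mapped markers (non-overlapping by default;
sliding available) are scored per chromosome as
100 × matches / usable, where usable means both samples called and a
match is call identity.  Windows with fewer usable markers than
`min_usable_fraction × window_size` (default 5) are UNDEFINED.  The flag
threshold is ≥40%, inclusive — deliberately permissive, absorbing
heterozygous and cohort-cluster ambiguity, in line with calibration on
known introgressions such as 1B/1RS.  Trailing partial windows are scored
over their actual size when they meet the usable minimum, avoiding blind
spots at chromosome ends.  Maximal runs of flagged windows become
segments spanning the first to last flagged marker (0-based half-open
BED); a single UNDEFINED window flanked by flagged windows is bridged by
default (two consecutive UNDEFINED windows break the run).  The scan may
be restricted to a diagnostic panel from `select_tracking_markers`
(markers where donor and background are called and differ), which is the
higher-contrast variant appropriate to a characterized cross.

Under the simulator's null (background-only lines versus a 90%-diverged
donor), the per-window flagging probability is the binomial tail
P(Bin(10, ~0.1) ≥ 4) ≈ 1–2%, which the false-positive tests bound at 5%.

## Numerical conventions

Coordinates are 0-based half-open internally and in BED; hapmap positions
are 1-based at the file boundary, and unmapped markers serialize as
chromosome "0", position 0.  Call tokens accept both letter (AA/AB/BB/
NoCall) and integer (0/1/2/−1) forms; integers are written.  Percentages
are reported to one decimal place.  Heterozygote hapmap codes use IUPAC
ambiguity letters, with "H" as the fallback for non-nucleotide allele
symbols.  All stochastic behaviour flows from explicit integer seeds
through `numpy.random.default_rng`.

## Known limitations

Cohort-relative cluster ranks are not dosages: the same true genotype can
receive different codes in different cohorts, which is faithful to the
platform but means diversity statistics operate on call codes, as the
original analyses did.  Fst/Nei D between species of different ploidy
inherit this code-level (rather than allele-level) interpretation.  The
NJ tree is a guide tree, not a substitute for likelihood inference.  The
packaged per-species summary table ships observed counts for one
278-accession screen; pairwise distance values between real species are
not reproducible without that raw dataset and are out of scope.
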