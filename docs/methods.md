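# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `tumourprint`. It is the package's own account of its
science; every number quoted here is computed by the test suite or the
acceptance script, not asserted from memory.

## 1. Observable model and simulator

### Admixture model

A tumour sample is a mixture of a fraction *p* (purity) of tumour cells and
1 − *p* normal diploid cells. A genomic segment of the tumour genome carries
an integer pair of allele copy numbers (*n_A*, *n_B*); we summarise it as
total copy number *cn* = *n_A* + *n_B* and (*major*, *minor*) =
(max, min). A SNP probe inside the segment with germline B-allele count
*g_B* ∈ {0, 1, 2} observes

- BAF: ((1 − p)·g_B + p·t_B) / ((1 − p)·2 + p·cn), where *t_B* is the
  tumour B count at the probe (0 for AA, *cn* for BB, *n_B* for AB);
- raw LRR: log2(((1 − p)·2 + p·cn) / 2).

Emitted LRR is recentred so the genome-wide median is 0, mimicking array
normalisation, which cannot observe absolute ploidy — this is exactly why
ploidy must be inferred rather than read off. Gaussian noise is added to
both observables (defaults: BAF SD 0.02, LRR SD 0.15, chosen so the state
bands stay separable at purity ≥ 0.4); BAF is clipped to [0, 1].

### Events

Events are applied sequentially to per-allele interval maps: whole-genome
duplication (WGD) first, doubling both alleles everywhere, then segmental
losses/gains (± integer copies of one named allele) and copy-neutral LOH
(all copies of the hit allele transferred to the other). Application can
never produce a negative per-allele count; violations raise. Ground truth
(*cn*, *major*, *minor* per interval) is recorded exactly.

### Probe design

Probes are evenly spaced (default 100 kb, a desk-scale stand-in for a
clinical SNP array); each probe is germline-heterozygous with probability
1/3 (typical array SNP minor-allele-frequency profile), otherwise AA/BB
with equal probability. Coordinates are 0-based half-open internally and
1-based inclusive in SEG files on disk.

### The bundled 23-tumour preset (`paper_cohort`)

The preset emulates a breast-tumour series from *ATM*-variant carriers:

- 23 tumours: 16 near-tetraploid (WGD) and 7 near-diploid; 21 from
  heterozygous carriers and 2 from biallelic (A-T) patients.
- *ATM*-locus LOH planted in 14 of the 21 carrier tumours (67%), as a
  one-copy loss (near-diploid), two-copy loss of one homologue
  (near-tetraploid), or copy-neutral LOH; the event interval alternates
  between the focal 11q22.3 band and a broad 11q14.1–qter region.
- Four hallmark loss loci, each planted in 18/23 tumours (78%):
  13q14.11-q14.3 (9.6 Mb), 17p13.2-p12 (12.7 Mb), 21p11.2-p11.1 (1.2 Mb),
  22q11.23 (2.0 Mb). Loss depth is ploidy-appropriate (−1 copy on a diploid
  background, −2 on a tetraploid one) so the planted events fall inside the
  ploidy-conditional calling bands.
- Background aneuploidy. Every near-tetraploid tumour carries, besides arm
  events (16q −1, 8q +1/+2, 1q +1), two whole-chromosome losses and one
  gain (rotating over chr4/9/14/18 and chr7/20). This reflects the
  chromosomal instability that follows genome doubling in real tumours and
  is also what makes absolute ploidy identifiable: a genome with only
  even copy numbers is mathematically indistinguishable from its halved
  alias at a rescaled purity (see §3).
- Purities drawn uniform(0.4, 0.9) per tumour — the source series does not
  publish per-tumour purities, so this range is an explicit assumption.
- Probe spacing 20 kb for this preset (denser than the generic default):
  the breakpoint filter discards segments under 50 SNPs, so the smallest
  hallmark locus (1.2 Mb) needs ≥ 50 probes within it to survive. This is
  the package's own scale choice balancing fidelity and desk-scale runtime
  (≈ 152k probes per tumour, 23 tumours ≈ 3.5M probe rows, full pipeline
  ≈ 20 s on one CPU).

Preset composition (who is tetraploid, who carries which event) is fixed;
the seed drives only purity draws, genotype draws and noise, so identical
(preset, seed) pairs produce byte-identical bundles.

The cohort bundle also includes a clinical table (23 records echoing the
series' IHC distribution: almost all ER+, predominantly luminal B),
microsatellite peak-height tables for four markers at the *ATM* locus, and
somatic-variant lists for a 4-tumour WGS-like subset. The variant lists are
a deliberately scaled-down emulation of the observed sharing structure
(≈ 500 distinct variants; 10 shared by exactly two tumours, 1 by three,
none by all four; six coding genes altered in exactly two tumours) — the
sharing *pattern*, not the absolute variant counts, is what the analysis
consumes.

### What the simulator does not emulate

No FFPE artefacts (wave/GC bias, DNA degradation), no subclonality, no
probe-specific response, no raw intensity (CEL-level) simulation, uniform
rather than SNP-panel probe spacing, and a simplified female karyotype
(22 autosomes + X, single-point centromeres, approximate band
coordinates). Tests passing on this generator therefore demonstrate
correctness of the inference machinery under the stated observable model,
not robustness to real-array artefacts.

## 2. Segmentation

Joint change-point detection on two standardized tracks per chromosome: LRR
of all probes and mirrored BAF (max(b, 1 − b)) of heterozygous probes.
Binary segmentation minimises the within-segment sum of squares with a
BIC-style per-changepoint penalty (multiplier 6 × log n × 2 tracks on the
standardized scale; min 10 probes per segment).

A plain single-split scan cannot detect a short event embedded in a long
segment — carving a 60-probe event out of a 2400-probe chromosome moves the
two half-means by almost nothing. The segmenter therefore also scans, at
each recursion step, a ladder of carve-out windows (widths from min_probes
upward in √2 steps): the best interior window scored as window-vs-rest,
paying the changepoint penalty twice since it inserts two boundaries. The
better of {best single split − penalty, best carve − 2·penalty} is applied,
recursively, until no move clears its penalty. The procedure is exact
arithmetic on cumulative sums, deterministic, and needs no tuning beyond
the penalty multiplier.

Segment boundaries sit at midpoints between flanking probes (chromosome
ends at the telomeres), giving a contiguous cover.

## 3. Purity and allele-specific copy-number fit

Segments concentrate on the lattice LRR(cn), mBAF(cn, major) given in the
README. The fit is a grid search:

- purity grid 0.10–1.00, step 0.01;
- centring candidates: the 5 most probe-heavy modes of the segment LRR
  distribution, each aligned with assumed copy number 1–4 (deduplicated);
- per candidate, each segment is scored against its nearest lattice state
  (cn 0–8, major ≥ minor), distances scaled by 0.25 log2-units (LRR) and
  0.05 (mBAF) — roughly the per-segment noise scales; segments without
  heterozygous probes are scored on LRR alone;
- total score = probe-weighted mean of squared nearest-lattice distances
  plus a ploidy-parsimony penalty λ·|probe-weighted mean cn − 2| with
  λ = 0.015.

**The diploid/tetraploid alias.** A profile whose copy numbers are all even
is exactly reproduced by halving every copy number and moving purity from
*p* to 2p/(1+p); no BAF/LRR method can distinguish the two. The penalty
breaks this exact tie toward the diploid reading. λ is deliberately small:
any segment with odd total copies (one aneuploid chromosome suffices)
contradicts the halved reading — its halved copy number is fractional and
off-lattice — and that data term must dominate the ≈ 2λ penalty the
tetraploid reading pays. At λ = 0.015 a single odd-copy chromosome at
purity 0.4 is decisive; at λ ≈ 0.04 it no longer is, which is why the
constant is documented and kept in one place.

Copy numbers beyond 8 are ascribed eight-copy status (the lattice simply
ends at 8). Exact distance ties resolve to the lower (cn, major) state via
the lattice scan order. A fit whose near-optimal purity set spans more than
0.3 of the grid is flagged `purity_unidentifiable` (e.g. a pure-normal
profile, where every purity explains (2,1) segments equally well); an
all-homozygous profile raises instead of returning a meaningless fit.

Measured performance (test suite, 50 simulated tumours, purities 0.4–0.9,
default noise): purity within ±0.05 in ≥ 90% of tumours (observed: all 50
within ±0.022 at the tested seed) and probe-weighted state accuracy ≥ 95%.

## 4. Ploidy classification and alteration calling

- Chromosome number = Σ over chromosomes of the probe-weighted modal copy
  number in a pericentric window (centromere midpoint ± 1 Mb; the window
  size is this package's choice — the source method does not define one).
  X counts once in the female karyotype. Near-tetraploid iff the sum
  reaches 3 × n_chromosomes (midpoint of 2n and 4n; 69 for 23
  chromosomes), else near-diploid.
- Calling rules, conditional on ploidy class: near-diploid loss cn ≤ 1,
  gain cn ≥ 4; near-tetraploid loss cn ≤ 2, gain cn ≥ 6. LOH iff
  minor = 0 and cn ≥ 1 (monoallelic content regardless of copy number);
  cn = 0 is labelled loss only. Combined labels: Loss, Gain, LOH,
  Loss/LOH, Gain/LOH, none.
- Breakpoint filter: segments with fewer than 50 SNPs merge into the
  neighbour with the nearer (cn, major) state (Euclidean; ties left); a
  chromosome consisting solely of sub-threshold segments collapses to its
  probe-weighted modal state. Total covered length is preserved and the
  breakpoint count never increases.

## 5. Large-scale state transitions and HRD

Segments are first split at the centromere and smoothed per arm: pieces
shorter than 3 Mb merge into an identical-state neighbour when one exists,
else the nearer state, and identical-state runs coalesce. An LST is then a
breakpoint (change in cn or major) whose two flanking segments each span
≥ 10 Mb within one arm; centromere-spanning breaks are not counted. HRD
positivity cutoffs: 15 (near-diploid) and 20 (near-tetraploid), boundary
inclusive. These parameters come from the established LST methodology and
live in `LstConfig`, not call sites. On the bundled preset no tumour
approaches the cutoff (observed counts 0–1), mirroring the absence of the
HRD signature in the emulated series.

## 6. Cohort recurrence and clustering

All tumours' calls are projected onto the atomic grid formed by the union
of their breakpoints (projection is lossless by construction; the
invariant is tested). The binary tumours × (atom, kind) matrix — kinds
loss, gain, LOH, loss∧LOH — supports:

- recurrent regions: maximal runs of consecutive atoms with frequency
  ≥ 70% (denominator: all tumours in the matrix, matching the fixed-
  denominator reading of "≥ 70% of the 23");
- hierarchical clustering: Jaccard distance on altered-column sets (all-
  zero vs non-empty row → 1; two all-zero rows → 0), Ward linkage via
  scipy, rows pre-sorted by tumour id for deterministic leaf order;
  exported as Newick;
- locus frequency: fraction of tumours whose calls of a kind cover ≥ 50%
  of a named locus;
- profile concordance: two profiles agree at a locus iff both assign the
  same combined label to ≥ 50% of its length; loci uncovered in either
  are flagged rather than counted.

## 7. Microsatellite LOH

For one marker with normal peaks (N_a, N_b) and tumour peaks (T_a, T_b):
informative iff the normal shows two peaks with height ratio in [0.5, 2];
LOH index = min(r, 1/r) with r = (T_a/T_b)/(N_a/N_b) — folding makes the
"ratio below 50%" rule two-sided and orientation-free; LOH iff index
< 0.5. An informative marker with zero tumour signal raises an assay
failure (a failed PCR is not LOH). Locus status over the four markers:
LOH iff ≥ 1 informative marker calls LOH and none asserts retention
(index > 0.8); both kinds of evidence → discordant flag, unadjudicated;
no informative markers → uninformative.

**Sensitivity limitation.** For a near-diploid tumour with a single-copy
loss, the expected tumour allele ratio is (1 − p)/((1 − p) + p), which is
≥ 0.5 whenever purity p ≤ 0.5: the assay *cannot* see such LOH below 50%
purity, whatever the noise. With preset purities drawn from uniform(0.4,
0.9) an occasional array-vs-microsatellite discordance is therefore
expected and genuine — the pipeline reports both calls and flags the
conflict rather than adjudicating. The concordance test asserts agreement
only where the expected index is decisively below threshold.

## 8. Clinical statistics

- St. Gallen subtypes from IHC: triple-negative (ER−, PR−, HER2−),
  HER2-overexpressing (ER−, PR−, HER2+), luminal A (ER+, HER2−,
  Ki-67 < 20%), luminal B (ER+, HER2−, Ki-67 ≥ 20%), luminal B/HER2+
  (ER+, HER2+, Ki-67 ≥ 20%). PR does not discriminate luminal A from B.
  HER2 resolves from IHC 3+, or 2+ with FISH amplification; unresolved or
  missing required fields → unknown. The classifier is total over the
  categorical grid (tested exhaustively).
- Descriptive tables: counts per category, unknowns separate, percentages
  among known values rounded half-up to integers.
- Fisher's exact test (2×k): two-sided by point-probability summation over
  all tables with the observed margins; zero-margin tables return p = 1
  with a warning. Tested against scipy's 2×2 implementation and a full
  enumeration oracle for 2×3.
- Logistic association: statsmodels ML fit of outcome ~ group (+ sex +
  age), Wald two-tailed p for the group coefficient; complete separation
  is flagged and no p reported. No multiple-testing correction is applied
  (per-test 5% level, matching the emulated analysis).
- Variant sharing: variants keyed by (chrom, pos, ref, alt), per-tumour
  duplicates dropped with a warning; counts of variants shared by exactly
  m tumours, and of genes (coding variants only) shared by exactly m.

The packaged series table (`data/atm_series_table2.tsv`, 36 tumours)
reproduces the published marginal counts of the emulated series
(histology, ER/PR/HER2, Ki-67, subtype); the row-level joint assignment is
synthetic, constructed to satisfy all marginals simultaneously, because
only the margins are published. Derived checks: ductal 86%, ER+ 97%,
luminal B 46%, luminal A 36% among known values.

## 9. Numerical choices and degenerate inputs

- Purity grid step 0.01; centring candidates rounded to 10⁻³ and
  deduplicated; scoring scales 0.25 (LRR) / 0.05 (mBAF); λ = 0.015.
- Segmentation penalty multiplier 6; min segment 10 probes; carve-out
  width ladder in √2 steps.
- Exact-tie resolution everywhere is "first in (cn, major) order" /
  "leftmost", making every stage deterministic.
- Degenerate inputs: empty cohort → empty but schema-valid bundle;
  pure-normal profile → flagged fit; all-homozygous profile → error;
  uncovered pericentric window → error naming the chromosome; zero-margin
  contingency table → p = 1 with warning; assay with no tumour signal →
  assay-failure error.
- Problem sizes: the bundled preset uses 20 kb probe spacing (≈ 3.5M probe
  rows across 23 tumours); the recovery experiments use the generic 100 kb
  spacing (≈ 30k probes per tumour, 50 tumours). Both were chosen as
  desk-scale renderings of the analysis.

## 10. Known limitations

- No subclonal fractions; states are clonal integers.
- No GC/replication-wave correction; the simulator generates none.
- The centring-mode search assumes the genome's dominant copy-number
  states populate the LRR histogram modes; a genome with no dominant
  state would need more candidates.
- The all-even-state tetraploid genome is unidentifiable in principle
  (§3); such a profile will be read as diploid, by design.
- Microsatellite LOH is insensitive below 50% purity for single-copy
  losses (§7).
- Approximate band coordinates for named loci; single-point centromeres.
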