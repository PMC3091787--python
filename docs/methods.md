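# Methods

## The estimation problem

SNP arrays report, per marker and individual, one of four phenotype
classes: A-like homozygote, heterozygote-like, B-like homozygote, or
no-call. Copy-number variants distort the class proportions in
characteristic ways. cnvfreq estimates the *population frequency* of two
simplified CNV allele types at each marker and combines that evidence with
an independent signal-intensity (SI) call stream.

### Trinomial HWE estimators

Let p, q be the visible SNP allele frequencies and r a third, silent
allele. Under random mating the genotype classes follow the trinomial
expansion (p + q + r)² = 1. For a **null (deletion) allele**, pr and p p
genotypes are both called as A-homozygotes, qr and qq as B-homozygotes, pq
as heterozygotes and rr as no-calls, so the expected class fractions (of
all n sampled individuals) are

    p_o = p² + 2pr,  q_o = q² + 2qr,  pq_o = 2pq,  no-call = r².

Solving for r in terms of the observables gives

    r_l = sqrt(0.25 − 0.25·pq_o + p_o·q_o/pq_o) − 0.5.

For a **gain allele** g — a duplicated haplotype carrying both SNP alleles,
so every carrier presents heterozygote-like — the fractions are p_o = p²,
q_o = q², pq_o = 1 − p² − q², and

    r_g = sqrt(p_o + q_o + pq_o) − sqrt(p_o) − sqrt(q_o).

Both inversions are exact on model-expected fractions (the test suite
checks ±1e-10 over a 0.05-step simplex grid) and return 0 under plain
biallelic HWE. The radicand of r_l is provably non-negative for any valid
fractions with pq_o > 0 (property-tested over random genotype counts).

Estimates are deliberately **not clamped**: a locus carrying a deletion
drives r_g negative and vice versa, and that anti-symmetry (a strong
negative correlation between the two estimators across markers) is itself
evidence that the estimators respond to real copy-number signal rather
than noise. Only `expected_nocalls` (n·max(r_l, 0)²; the minimum no-call
count a null allele of that frequency implies) clamps at zero.

### Choice of denominator

`phenotype_frequencies` divides by the number of successfully *called*
individuals by default, which is what a genotyping platform naturally
reports. Under a segregating null allele the no-call class contains the rr
homozygotes, so the called-only denominator slightly inflates r_l (a unit
test asserts the direction of the effect); the `denominator="total"`
option divides by all sampled individuals, under which the null-model
inversion is exact. The statistical-recovery checks in the acceptance
script use the total denominator for that reason; the user-facing default
stays "called" because real no-calls mix technical failure with rr
homozygotes and the called count is the only denominator that is always
observable.

### Per-marker screens

* **Polymorphism filter**: a marker is polymorphic iff at least two of the
  three called classes are observed; monomorphic markers get NaN
  estimators and never enter threshold calibration.
* **HWE χ² (1 df)**: standard biallelic goodness-of-fit on called
  genotypes, no continuity correction, raw p-values (no multiple-testing
  correction — the screen is descriptive, reporting the *fraction* of
  markers at p < 0.05, not per-marker significance claims).
* **Non-autosomal flag**: r_l > 100% is impossible for a true autosomal
  marker but is the expected signature of an all-male hemizygous (X-like)
  marker, where heterozygotes cannot occur. Markers with r_l > 1
  (including the pq_o = 0 case, which returns a +inf sentinel rather than
  raising) are flagged, excluded from calibration and selection, and
  reported as position-sorted contiguous runs so that a misassembled
  sex-chromosome block shows up as a single multi-marker interval.

## SI frequencies from rawcnv call lists

The PennCNV HMM is out of scope; cnvfreq consumes its per-sample `rawcnv`
output (one interval per line with SNP span and copy number in
{0, 1, 3, 4, 5}; single-marker calls allowed). Per marker, every sample
without a covering call is assumed diploid; copies lost
L = Σ max(0, 2 − cn) and gained G = Σ max(0, cn − 2) give

    l_si = 100·L/(2n),   g_si = 100·G/(2n)   (percent).

Keeping loss and gain tallies separate, rather than one absolute-value
statistic on the total copy count N_t, preserves information at mixed
loci; in pure-loss or pure-gain configurations the split reproduces
100·|1 − N_t/2n| exactly (asserted to 1e-12). Marker membership in a call
is endpoint-inclusive, matching the startsnp/endsnp semantics. cn = 0
contributes two lost copies — an extension beyond the (1, 3, 4, 5)
enumeration that the arithmetic handles naturally.

## Combining methods and building CNVRs

Per metric (r_l, l_si, r_g, g_si), the selection threshold is
mean + k·SD over eligible (polymorphic, unflagged, finite) markers, with
k = 1 by default and population SD (at tens of thousands of markers the
ddof distinction is far below any other source of uncertainty). Selection
is a strict AND across the two methods per CNV type (an OR mode exists but
is non-default); loss and gain pipelines run independently, so a locus can
legitimately appear in both lists.

Selected markers of one type are chained into regions by single-linkage:
consecutive position-sorted markers at most `cluster_distance` apart join
the same CNVR. The default is 500 bp. That is small relative to a ~50 kb
chip spacing — with the default, multi-marker regions essentially only
arise where markers genuinely cluster — but it is the documented published
convention and is exposed as a parameter (`--cluster-distance`) rather
than silently changed; pass e.g. 500000 to merge at chip scale. Singleton
regions are kept: one-marker evidence may correspond to an indel shorter
than 1 kb. Region frequency is the mean of member-marker frequencies;
both method averages are reported (`freq_hwe_pct`, `freq_si_pct`) and the
headline `frequency_pct` is the HWE-based one, since the HWE estimator has
the wider dynamic range and is the quantity validated against homozygote
counts.

Catalog confirmation is symmetric padded overlap: a region is confirmed if
a documented interval on the same chromosome lies within `proximity`
(default 500 bp, edge-to-edge); the catalog-side rate (fraction of
documented entries recovered) is reported alongside. A Monte-Carlo test
checks the implementation against the closed-form random-overlap
probability (l_r + l_c + 2·proximity + 1)/L per entry.

## Validation statistics

From k deletion-homozygotes among n individuals, the HWE point estimate of
the deletion-allele frequency is sqrt(k/n). The count is modelled as
Poisson; the exact (Garwood) interval is lower = χ²(α/2, 2k)/2 (0 for
k = 0), upper = χ²(1 − α/2, 2k + 2)/2, verified against direct CDF
root-finding to 1e-8 for k ≤ 50, and mapped to the allele scale by the
monotone transform f = sqrt(λ/n) (coverage-preserving; a 10,000-draw
simulation confirms ≥ 95% coverage — exact Poisson intervals are
conservative). For k = 2, n = 132 this gives 12.3% (4.3%, 23.4%).

## The synthetic-data generator

`cnvfreq.simulate` emulates the statistical structure the estimators
assume, at the scale of the motivating study: 912 samples, chip-like 50 kb
marker spacing across 29 autosomes, background allele frequencies uniform
on [0.05, 0.95], planted five-marker loss and gain clusters (default
allele frequency 0.15, 300 bp internal spacing), a 1.6% independent
technical no-call rate (≈15 missing calls per marker in 912 samples), and
a 30% per-carrier SI detection rate reflecting a conservative HMM. Two
gametes are drawn i.i.d. per individual (one for hemizygous markers);
markers in one cluster share their CNV-gamete draws, so planted events are
contiguous haplotypes and their rawcnv calls span the full cluster. By
default carriers are detected with the given probability and non-carriers
never produce calls; an optional false-positive rate emits spurious cn=1
calls.

Deliberately **not** modelled: linkage disequilibrium between markers (the
estimators are single-marker statistics, so LD affects neither their bias
nor their variance at a single locus), raw intensity values
(log R ratio / B-allele frequency), pedigree structure, selection,
mixed loss+gain loci, and multi-copy (cn > 3) gain genotypes — the gain
model treats every carrier as heterozygote-like. Passing tests therefore
demonstrate correctness of the estimators and pipeline under the stated
inheritance models, not robustness to HMM artefacts, batch effects or
assembly errors in real array data.

## Numerical and interface choices

* The r_l radicand is floored at 0 against floating-point rounding; the
  analytic non-negativity makes the floor inert on valid input.
* pq_o = 0 with both homozygote classes present returns +inf (flag
  semantics), not an exception; monomorphic markers return NaN.
* Genotype half-calls (one missing allele) count as no-calls;
  heterozygosity is decided on the unordered allele pair; no strand
  normalisation is attempted (inputs are assumed strand-consistent, and
  the statistics only need the three phenotype classes).
* Homozygote class labels (A vs B) follow the lexicographically smaller
  observed allele; every downstream statistic is symmetric in the labels.
* Markers present in genotype data but absent from the marker map are
  counted and reported, then excluded from position-dependent steps.
* All user-facing frequencies are percent; library-level HWE estimates are
  fractions.
* Problem sizes in the test and acceptance runs — 500 replicate markers
  for estimator recovery, 10,000 markers for χ² calibration, a
  5,100-marker panel for end-to-end recovery — were chosen to make the
  statistical assertions sharp (3–4 SE bands) while keeping a full run in
  the order of seconds.

## Known limitations

* Only single-copy loss and single-copy gain models; loci combining both,
  or higher copy numbers, are approximated at best (though the sign
  structure of r_l/r_g still carries signal there).
* The HWE route needs polymorphic markers; it is blind to duplications
  whose extra copy is identical to the source locus.
* The hemizygous model covers the all-male X case; X-chromosome
  inheritance in mixed-sex panels is not modelled, only flagged.
* The Poisson lower bound is the exact Garwood limit; other published
  lower-bound conventions for small counts differ noticeably at k = 2,
  and no attempt is made to match them.
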