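# Methods

This note records the models behind each module, the conventions and
defaults that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Coordinates, formats and SNP consumption

All internal coordinates are 1-based inclusive, the GFF3 convention;
conversion to 0-based half-open happens only at format boundaries. Gene
models keep chromosomal (unflipped) coordinates with the strand recorded;
exons are taken from the CDS features of the primary (first-by-ID)
transcript. Only biallelic single-nucleotide variants with A/C/G/T ref and
alt are consumed: indels, multi-allelic sites and malformed alleles are
skipped with logged counts. Heterozygous genotypes, if present in a VCF,
take the alt allele (natural accessions are treated as inbred haploid
lines) and are counted. The TSV dialect
(`accession chrom pos ref alt qual`) is the canonical exchange format; VCF
reading is a shim over it. At most one record per (accession, chrom, pos)
is permitted; duplicates raise at load.

## Allele assembly

For each accession and region, SNP alleles with Phred quality ≥ 25
(default `qual_min`) are substituted into the reference region sequence,
producing the variant allele; substituting the *reference* alleles at the
same coordinates produces a reference reconstruction that must be 100%
identical to the reference — any mismatch (a SNP whose stated ref allele
disagrees with the reference base) flags a coordinate or assembly-version
error for that accession. Substitution happens in chromosomal space;
minus-strand regions are reverse-complemented afterwards. Accessions with
no record at a site carry the reference allele, because variant-only SNP
matrices report non-reference calls; `missing_as_n=True` masks non-called
sites instead for users whose matrices distinguish "no call" from
"reference".

Outgroup CDSs are projected into reference coordinates through a global
protein alignment (Needleman–Wunsch, match 1 / mismatch −1 / gap −2, ties
broken diagonal > gap-in-first > gap-in-second so the optimum is unique):
columns gapping the reference are removed, outgroup deletions become `---`
placeholders, and the projected sequence always has the reference CDS
length. Placeholder and stop codons are dropped pairwise before
divergence estimation.

## Diversity statistics

- π_locus = Σ_{i<j} d_ij / C(n,2), where d_ij counts differences over
  sites at which both sequences are called (pairwise deletion of N);
  computed column-wise as discordant-pair counts for speed. π_site = π/L
  with L the full region length.
- θ_W = S/a₁, S the number of columns showing ≥ 2 distinct non-N alleles.
  Both per-locus and per-site values are emitted (the per-site convention
  is the one used for region comparisons).
- Tajima's D uses the standard constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂
  from n. D is undefined at S = 0. At n = 3 the variance constants vanish
  identically (c₁ = c₂ = 0); D is then reported as 0 when π = S/a₁ and as
  undefined otherwise.
- Significance of D uses the beta-distribution approximation to the
  neutral null: D is rescaled to [Dmin, Dmax] with
  Dmin = (2/n − 1/a₁)/√e₂ and Dmax = ((n+1)/2n − 1/a₁)/√e₂ (the odd-n
  maximum of mean pairwise diversity per segregating site), and shape
  parameters chosen so the rescaled variable has mean 0 and variance 1. A
  two-sided test at α = 0.05 flags D outside the central 95% of this
  distribution. The approximation is computed from n at run time rather
  than from a fixed table; tests cross-check its quantiles by independent
  numerical integration of the density.
- Minor-allele counting (not derived-allele) defines the MAF spectrum:
  minor count = min(alt carriers, roster − alt carriers); a singleton has
  minor count 1. Sites that come out monomorphic over the roster are
  excluded and counted. Coding SNPs are classed synonymous or
  nonsynonymous by substituting the alt allele into the reference codon
  under the standard code; stop gains/losses are nonsynonymous with a
  nonsense flag.

## Sliding windows and group comparisons

Windows are anchored at the transcription start site: the base immediately
upstream is offset −1 and 200 bp windows tile from the distal end in 100
bp steps, so a 2.5 kb promoter yields 24 windows (−2500..−2301 through
−200..−1); window count is ⌊(L − w)/s⌋ + 1. Latitude groups default to
[40,45), [45,50), [50,60] °N; expression groups to low [50,137), medium
[137,170), high [170,480] RPKM — left-closed bins with a closed top on the
last bin.

The Wilcoxon rank-sum test is exact (full enumeration) when
min(n_x, n_y) ≤ 8 and there are no ties, and otherwise uses the normal
approximation with midranks, tie correction and continuity correction.
Two identical samples return p = 1.

Windowed diversity yields one number per group per window, so the
replication unit of the group comparison is genuinely open. Two modes are
provided: `bootstrap` (default) computes each group's windowed π on 100
half-group accession subsamples drawn without replacement and compares
resample distributions per window; `windows` treats the windows inside a
stated band as replication units and runs one test per group pair.
Bootstrap resamples are not independent observations, so its p-values
should be read as a planted-structure detector, not literal error rates.
No multiple-testing correction is applied across windows by default
(a Benjamini–Hochberg flag can be layered on by users who need it).
Directional questions use one-sided alternatives ("is the focal group more
diverse?"); group-mean expression comparisons are two-sided.

## Codon model and neutrality test

The divergence engine is a pairwise Goldman–Yang-style model on the 61
sense codons of the universal code. Instantaneous rates allow single-
nucleotide changes only: q_ij ∝ π_j, times κ for transitions and ω for
nonsynonymous changes; Q is scaled to one expected substitution per codon
per unit t. The pair likelihood is Σ ln(π_{c1} · [exp(Qt)]_{c1,c2}), which
is orientation-symmetric by reversibility. Codon frequencies default to
F3x4 estimated from both sequences (a small pseudo-frequency, 1e-6 per
nucleotide-position count, keeps all sense codons strictly positive);
equal frequencies are available.

Fitting maximizes the likelihood over log-parameters with bounded
L-BFGS-B from a fixed start grid (t ∈ {0.1, 0.5}, κ = 2, ω ∈ {0.3, 1.5}),
bounds t ∈ [1e-6, 20], κ ∈ [0.01, 50], ω ∈ [1e-4, 20]; the best converged
start wins, so fits are deterministic. The neutrality statistic is
LR = 2(lnML2 − lnML1) with lnML1 the ω = 1 fit and lnML2 the free fit; the
free model nests the fixed one, so LR ≥ 0 (tiny negative optimizer noise
is clamped; beyond tolerance it raises as an optimizer-failure signal).
The call is Neutral iff LR < 2.71. That cutoff is the χ²₁ upper 10% point
(equivalently the 5% point of the ½χ²₀ + ½χ²₁ mixture used in practice
for one-parameter tests); it is computed from the χ² distribution at run
time, not hard-coded, and the observed type-I error at ω = 1 in the
calibration runs is consistent with its nominal ~10% level.

dN and dS under the fitted model follow the codeml convention:
dN = t·ρ_N/(3f_N), dS = t·ρ_S/(3f_S), with ρ the nonsynonymous/synonymous
shares of the stationary substitution flux at the fitted ω and f the same
shares at ω = 1, so dN/dS = ω̂ identically.

The NG86 companion estimator counts synonymous/nonsynonymous sites per
codon (fraction of the three single-nucleotide changes per position that
are synonymous; changes to stops count as nonsynonymous), averages site
counts over both sequences, weights minimal mutational pathways equally
while excluding pathways through stop codons (falling back to all pathways
if none survive), and applies the Jukes–Cantor correction
d = −(3/4)ln(1 − 4p/3), undefined at p ≥ 3/4 (flagged as saturated).

## Annotation rules

Introns per gene = exons − 1. Two family genes are tandem duplicates iff
they are on the same chromosome, at most 5 annotated genes (of any family)
lie strictly between them, and they are within 10 kb — measured between
nearest gene boundaries by default (start of downstream minus end of
upstream, floored at 0 for overlaps); measuring between gene starts is
available via `distance_mode="start"` since the boundary convention is a
choice, not a given. Upstream/downstream flanks are defined relative to
the coding strand (mirrored and reverse-complemented for minus-strand
genes), the biologically coherent choice for promoter analysis, and are
truncated, not padded, at chromosome ends with a truncation flag.

## Clustering

Per-gene statistic profiles (e.g. Tajima's D for UP/CDS/DN) are clustered
with Manhattan distances and the classical Ward criterion applied directly
to the unsquared dissimilarities — R's `ward.D` — via the Lance–Williams
update; scipy's `ward` implements the ward.D2 variant, so the linkage is
implemented here and cross-checked in tests through the sqrt/square
equivalence between the two. Merge ties break on the smallest node-id
pair, making dendrograms deterministic and row-order invariant. Rows with
undefined cells (regions with S = 0 have no D) are dropped with a warning
rather than imputed. The default cut is k = 3 groups on raw values;
z-scaling is optional and off by default.

## Synthetic data: what it emulates, and what it does not

The coalescent generator draws a Kingman genealogy (exponential waiting
times, uniform pair merges) and places infinite-sites mutations on
branches at Poisson rate θL/2 per unit coalescent time, each at a distinct
uniform site (collisions redrawn), rendered onto a random reference; Phred
qualities are drawn so 95% of calls pass the ≥ 25 filter. This matches
the biallelic-SNP consumption of the pipeline and makes the analytic
neutral expectations (E[S] = θLa₁, E[π_site] = θ) usable as independent
oracles. It does **not** model recombination, selection, demography,
population structure or linkage — so passing calibration shows estimator
correctness under the neutral model, not robustness to real *A. thaliana*
demography. `simulate_structured_region` shares one genealogy across
segments with segment-specific θ, which is how elevated promoter-band
diversity is planted for the window pipeline.

Codon pairs evolve per-codon independently under the same GY94 process the
fitter estimates (stationary ancestor, transition-probability sampling at
time t); there is no rate variation across sites or codon linkage, so
parameter-recovery results quantify estimator behaviour, not model
misspecification. Expression values are log-normal around group medians
(noise_sd = 0 returns the medians exactly); real expression data have
heavier tails, batch structure and zero inflation that this does not
emulate. Gene tables honor a stated spacing specification exactly and
exist to exercise the tandem-duplication rule.

All generators are bit-for-bit reproducible from (parameters, seed).

## Calibration experiments and problem sizes

`askpoly.calibration` bundles the experiments the acceptance script and
tests run; the defaults are the study conditions:

- Neutral calibration: n = 20 accessions, L = 1000 bp, θ = 0.01/site
  (θL = 10), 2,000 replicates. Checks: mean π̂_site and θ̂_site within 3
  Monte-Carlo SE of θ; mean Tajima's D within ±0.15 of 0 (the small
  negative bias of D at these sizes, about −0.1, is expected and inside
  the band).
- ω recovery and power: 500 codons, t = 0.3, κ = 2; 50 replicates at
  ω = 0.1 (median ω̂ expected in [0.05, 0.2], LRT rejection ≥ 90%) and 200
  replicates at ω = 1 for the type-I error (≤ ~10%, the cutoff's nominal
  level).
- Assembly round trip: 100 accessions over an 800 bp region at θ = 0.02;
  diff(variant, reference) must recover exactly the quality-passing SNP
  set and every reference reconstruction must equal the reference.
- Window-band detection: 3 groups of 24 accessions over 2.5 kb, background
  θ = 0.004 with θ = 0.04 planted in −1600..−500 for the focal group; 20
  seeds, detection = ≥ 80% of in-band comparisons significant at α = 0.05.
- Clustering: three Gaussian blobs in 3 features separated by ~10 with
  spread 0.3; the k = 3 cut must recover the planted partition exactly.

## Known limitations

- The pairwise codon likelihood conditions on the stationary distribution
  at one end; it is not a tree likelihood and does not handle more than
  two sequences.
- Tajima significance is an approximation; for small n (< ~10) its tails
  are U-shaped and critical values hug the bounds, as in the original
  derivation.
- The beta-approximation test, the bootstrap window comparison and the
  NG86 estimator are all per-region/per-pair tools; no genome-wide error
  control is attempted.
- VCF support covers GT-only genotypes; genotype likelihoods, phasing and
  structural variants are out of scope.
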