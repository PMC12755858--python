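# Methods

This note documents the models, conventions and numerical choices behind
`xstrlink`, and what the synthetic validation does and does not demonstrate.

## Transmission model

The X chromosome outside the pseudoautosomal regions is hemizygous in
males. A son therefore carries exactly his mother's transmitted haplotype,
and a daughter carries one maternal and one paternal X. At a biallelic SNP
this gives deterministic tracing rules for the transmitted **maternal**
allele:

| child | genotype | father | maternal allele |
|---|---|---|---|
| son | `a` | not needed | `a` |
| daughter | `a/a` | `a` | `a` |
| daughter | `a/a` | `b` | Mendelian error |
| daughter | `a/b` | `a` | `b` (subtraction) |
| daughter | `a/b` | missing | undetermined |

A SNP is *informative* when the mother is heterozygous **and phased** and
the maternal allele is determined; the vote is haplotype 1 if the allele
equals the mother's first phased allele. Mendelian-error sites are removed
from voting and tallied; a trio whose error share across all voted sites
exceeds `mendel_error_max` (default 0.10 — indicative of a sample swap
rather than isolated genotyping error or mutation) is excluded wholesale.

## Region origin calling and its conservatism

Each target locus has an upstream and a downstream flanking window of
`window_bp` (default 10 000 bp per side, i.e. a ~20 kb searched span).
Calling proceeds per segment, then per region:

* **segment**: unanimous votes → that haplotype; zero votes →
  uninformative (mother homozygous across the window); split votes →
  discordant. Unanimity is deliberate: a single conflicting SNP within
  10 kb more plausibly reflects genotyping error or gene conversion than
  two crossovers, and the cost of a wrong haplotype assignment (a phantom
  recombinant) outweighs the loss of one trio. A majority-vote mode exists
  behind `call_segment_origin`'s caller but is not used by default.
* **region**: both segments agreeing → assigned; segments naming different
  haplotypes (a crossover *inside* the span, leaving the STR's own phase
  ambiguous) or any discordant segment → excluded; otherwise uninformative.

Every pair estimate satisfies informative + uninformative + excluded =
total trios.

The default SNP filter is cohort MAF ≥ 0.2, recomputed from the supplied
samples rather than taken from VCF `INFO` so that simulated and real input
behave identically. At that threshold maternal heterozygosity per retained
site is ≥ 0.32, which with ~10 common SNPs per 10 kb window keeps the
uninformative fraction per segment below a few percent.

### Marker coordinates

Marker tables use 1-based inclusive coordinates (VCF convention); windows
are `[start − w, start − 1]` and `[end + 1, end + w]`, clamped at 1. The
bundled 25-locus, 7-group panel stores each locus as the midpoint of its
published ~20 kb searched range with `w` = 10 kb; that reproduces the
printed spans to within the repeat length, which is the best that can be
done because the printed ranges are narrower than the repeat-plus-two-
windows arithmetic would give. Overlapping searched spans of near-adjacent
loci are allowed; each locus is called independently.

### Male X encodings

Public releases mix haploid (`1`) and homozygous-diploid (`1|1`) male X
calls; both are accepted and collapsed to a single allele. A heterozygous
diploid male call is flagged as Mendelian-inconsistent and never used.
Missing genotypes exclude the site for that trio only.

## Junction pairs and recombination fractions

Between adjacent linkage groups the junction pair is (last locus of the
left group, first locus of the right group); within-group adjacent pairs
are available behind `intra_group`. The fraction for a pair is k/n over
trios informative at both loci, with an exact Clopper–Pearson CI. Exact
intervals (rather than Wald/Wilson) are used throughout because recombinant
counts within linkage groups are near zero, where approximate intervals
misbehave; the conservatism of the exact interval is acceptable for
forensic use.

## Phase-marginalized two-point likelihood

Family X-STR data give maternal meioses via the same subtraction rules,
with string-valued repeat alleles. The mother's two-locus phase is latent
and shared by all her children, so the family likelihood sums over her two
phase configurations with prior weights. Under linkage equilibrium the two
configurations of a double-heterozygous mother have *identical*
haplotype-frequency products, so the LE prior is exactly uniform (½, ½) —
supplying marker allele frequencies changes nothing unless genuine
haplotype-frequency information is available, which the API accepts as
explicit per-family weights.

Consequences worth knowing:

* one informative meiosis carries no linkage information (L ≡ ¼);
* n phase-unknown, recombinant-free meioses give MLOD = (n−1)·log₁₀2;
* meioses with alleles absent from the mother (candidate mutations) are
  excluded from θ estimation and counted — no mutation model is fitted,
  since separating mutation from recombination needs deeper pedigrees.

**Optimization.** θ̂ maximizes the log marginal likelihood on [0, 0.5] by
bounded scalar minimization (tolerance 1e-8), with the exact boundary
values evaluated as additional candidates; a tie (within 1e-12 log-units)
with θ = 0.5 resolves to 0.5, making MLOD exactly 0 for flat likelihoods.
MLOD is clipped at 0 by construction. The reported CI for the family-based
fraction anchors the exact binomial interval at (round(θ̂·n), n); it is an
approximation in the phase-unknown case, where no exact counting interval
exists.

**Kosambi map.** d = ¼ ln((1+2θ)/(1−2θ)) Morgans, reported in cM; the
inverse is θ = ½ tanh(2d). θ = 0.5 maps to +∞ and prints as NA.

## LD statistics

For phased binary haplotypes, D = p_AB − p_A p_B, D′ = |D|/D_max with the
sign-dependent normalizer, and r² = D²/(p_A q_A p_B q_B), which equals the
squared Pearson correlation of the allele indicators (the implementation
uses the correlation form; a direct-count oracle verifies the identity in
tests). Monomorphic sites are undefined and never enter curves. The decay
curve bins pairs into half-open bins ([k·w, (k+1)·w), default w = 500 bp,
max distance 300 kb) and reports the midpoint of the first non-empty bin
whose mean r² falls to the threshold (default 0.1). No interpolation is
attempted, so the crossing is resolved only to one bin width. Estimation
is haplotype-based only — inputs are phased, so no EM from unphased
genotypes is needed.

## Simulator

The generator emulates the analysed study designs:

* **trio cohorts** — default 602 trios over the bundled 25-locus panel;
  SNPs placed by a Poisson process at 1/kb inside flanking windows with
  uniform(0.05, 0.5) allele frequencies (the pipeline then applies its own
  0.2 cutoff, as it would on real data); mothers get two LE haplotypes,
  fathers one, and children a maternal gamete (sons) or gamete + paternal
  haplotype (daughters, maternal phased first). No father sample is
  emitted for sons.
* **meioses** — fair-coin starting haplotype, independent per-interval
  switch with probability θᵢ (default 0.5 between linkage groups, 0.01
  within). Interference is deliberately absent: every estimand is a
  between-locus switch indicator, for which only the marginal θᵢ matter.
  An optional gene-conversion mode overwrites ≤ 1 kb tracts inside a
  searched span to exercise the exclusion logic.
* **STR families** — the 66-family composition observed in the genotyped
  collection (22× mother+father+2 daughters, 21× mother+2 sons, 20×
  mother+father+son+daughter, plus three larger families); default
  7-allele frequency spectrum peaked at allele 13; optional single-step
  mutations.
* **founder-mosaic haplotype samples** — every haplotype copies from a
  shared panel of ancestors with a per-bp switch rate, giving genuine
  distance-dependent LD for decay tests. (Per-individual ancestor draws
  would give *no* sample-level LD; the shared panel is essential.)

One seed determines everything; identical configurations give
byte-identical output files.

**What the simulations do not capture:** coalescent demography and
realistic site-frequency spectra, phasing errors (phase is taken as given,
matching the phased-release premise), STR mutation-rate heterogeneity,
crossover interference and hotspots. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the stated
transmission model, not robustness to phasing artifacts or demographic
structure in real cohorts.

## Validation problem sizes

The test suite and acceptance script use 600-trio cohorts for pipeline
recovery across θ ∈ {0, 0.02, 0.1, 0.3, 0.5}, the 66-family design for
family-based recovery, 2 000 replicates for interval coverage at
(p = 0.5, n = 274), 300 replicates for the MLOD type-I check at θ = 0.5,
and 800 haplotypes × 300 sites for decay-crossing accuracy — sizes at
which the binomial/exact-CI checks have the intended operating
characteristics while the whole suite runs in seconds.

## Known limitations

* Crossover localization stops at "between locus A and B"; no attempt is
  made to place events within a window or detect gene conversion (the
  conservative exclusions absorb such events instead).
* The family-based CI construction is approximate under phase uncertainty
  (see above).
* Two-generation families only; no Elston–Stewart machinery for deeper
  pedigrees, and no multipoint linkage.
* The threshold crossing of the decay curve is bin-resolution limited and
  depends on the binning scheme, which published decay summaries rarely
  state.
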