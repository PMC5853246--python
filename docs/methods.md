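# Methods

## The incompatibility model

`cacaosi.si_model` formalizes the verbal genetic model of cacao's
late-acting self-incompatibility as two executable rule families over
S alleles.  An S allele has an activity (`active` / `amorphous`) and an
integer dominance rank (lower = more dominant; equal ranks = codominant).
`classical_alleles()` encodes the published series
S0 = S1 > S2 = S3 > Sf > S4 > S5 with ranks 0, 0, 1, 1, 2, 3, 4 and Sf
amorphous.

**Sporophytic expression.** A diploid plant expresses the most dominant
allele(s) of its pair, filtered to active ones.  This single definition
reproduces the three facts that constrain it: Sf/Sf expresses nothing
(self-compatible), an active allele dominant over Sf is expressed alone,
and S4 or S5 under Sf are silenced — the recessives are "recessive to the
self-compatible allele" precisely because the dominant amorphous allele
expresses nothing in their place.

**Gametic-fusion rule (CH4-type locus).** A female/male gamete pair fails
fusion iff both gametes carry the same specificity *s* and *s* is expressed
by the parents.  Whether *both* parents must express *s* or the mother
alone is not determined by the crosses the model is calibrated against;
the default is `both`, configurable per rule (`expression_scope`).  The
rule yields the canonical unfused-ovule classes after selfing: 0 %
(Sf/Sf), 25 % (Sf/S-active), 50 % (codominant heterozygote), 100 % (active
homozygote), and survivor ratios a : h = 1 : 2 with the active homozygote
class absent.

**Zygotic-elimination rule (CH1-type locus).** A set of
(activator, target) allele pairs: the target/target homozygous zygote is
eliminated whenever the activator is carried by a parent.  The default
scope for "carried by a parent" is `either` (mother, father, or both),
configurable, since the calibrating crosses are selfings and cannot
separate the alternatives.  Elimination is pre-fusion by contract: it
never adds ovule abortion, so a selfing and a compatible outcross of the
same clone show the same abortion rate (the baseline), while offspring
ratios skew to 0 : 2/3 : 1/3.

**Conditional law and simulation.** `expected_genotype_distribution`
enumerates the four equiprobable gamete pairs per locus, removes
fusion-failing pairs and eliminated zygotes, and renormalizes; loci are
unlinked so per-locus renormalization is exact.  A cross whose outcomes are
all eliminated raises `FullyIncompatibleCrossError` rather than dividing by
zero.  `simulate_progeny` is the Monte-Carlo twin: baseline abortion is
drawn first, fusion failures become unfused ovules, and zygotes hit by an
elimination rule are redrawn.  The redraw resamples the **full gamete
pair**, not the pollen gamete alone: pollen-only resampling would give
survivor odds h : b = 3 : 1 after selfing a heterozygote, whereas the
observed and analytic conditional law is 2 : 1.  Resampling the pair is the
rejection-sampling form of the renormalized law, and the ovule still counts
as fertilized, preserving the pre-fusion contract.  The redraw is bounded
(1000 rounds) and an upfront check rejects configurations with no
admissible pair.

**Mentor pollination.** `simulate_mixed_pollination` assigns each ovule to
mentor pollen with probability `mentor_fraction`.  Mentor-derived embryos
always fuse but are flat/nonviable; a fruit is retained iff its fused-ovule
proportion is ≥ `retention_threshold`.  The default threshold is 0 —
mentor pollination always rescues the fruit — because the biology this
emulates reports rescue without quantifying a threshold.  Viable offspring
are the self-derived embryos of retained fruits.

**Parentage classification.** `classify_offspring_parentage` labels a
seedling *outcross* on a foreign allele present in the candidate pollen
parent, *self* when all alleles derive from the seed parent and at least
one marker excludes the pollen parent (no seed × pollen assignment explains
the seedling), else *ambiguous*.

## Segregation scanning and region delimiting

Marker tables are sorted by (chromosome, position) with input order
breaking position ties (distinct markers may share a printed position), so
results are invariant to file order.  Per-marker goodness-of-fit uses χ²
with df = (classes with nonzero expectation) − 1 when all expected counts
are ≥ 5, otherwise an exact multinomial tail (sum of outcome probabilities
no larger than the observed one; the enumeration falls back to χ² above
2 × 10⁶ outcomes).  A nonzero count in a zero-expectation class returns
p = 0 outright.  Markers need ≥ 20 non-missing calls to be testable
(configurable); q-values are Benjamini–Hochberg.  The default expected
ratio is the selfed-F2 1:2:1; callers may test a model-conditional ratio
such as 0:2:1 to separate "distorted" from "fits the incompatibility
model".

Absent-class runs are maximal blocks of consecutive markers with zero
count of one class (markers with no calls can attest nothing and belong to
no run).  Regions are delimited by the nearest *informative* flanking
markers — markers outside the run with a nonzero count of the class, i.e.
observed recombinants — and the span is the plain difference of flank
positions in bp (no +1), reported in kb as bp/1000.  A run at a chromosome
end is measured from its outermost marker and flagged open.

## Diagnostic screening

The Fisher exact test and the logistic fits are implemented from first
principles because they are the computational core of the screen and must
be testable against independent oracles.

* **Fisher exact:** two-sided p sums hypergeometric point probabilities of
  all margin-fixed tables no more probable than the observed one, within
  relative tolerance 1e−7 (the convention of mainstream statistical
  packages).  Zero-margin tables carry no information: p = 1 with a
  warning.
* **FDR:** Benjamini–Hochberg step-up by default; a Storey π₀-scaled
  variant sits behind `method="storey"`.  BH is the default because π₀
  estimation is unstable at the small test counts typical of unit-scale
  problems; the q ≤ 0.05 rejection rule is kept.
* **Combination screen:** combinations of 1–3 distinct markers are built
  from *observed* genotypes only, with a carrier-support floor
  (`min_support`, default 3) to avoid degenerate 2×2 tables.  Carrying a
  combo means matching the exact genotype at every involved marker;
  individuals missing any involved marker are excluded from that combo's
  table (complete case), and the output reports carrier counts.
  P(SC | carrier) and P(SC | non-carrier) are the single-indicator logistic
  maximum-likelihood probabilities, which coincide with the empirical group
  proportions; a phenotype-pure group marks the fit as separated.
* **Allele dose:** logit P(SC) = β₀ + β₁·dose fitted by Newton scoring
  (IRLS), tolerance 1e−8, at most 100 iterations, with step-halving against
  overshoot.  Separation — a diverging MLE or any phenotype-pure dose
  group — triggers a bias-reduced Firth fit (Jeffreys-prior score
  adjustment), which always has a finite maximizer; the result carries a
  separation flag instead of boundary estimates crashing or silently
  passing.

## Allele frequencies and private alleles

Frequencies are allele-count proportions per (group, marker):
count / (2 × non-missing individuals), summing to 1 over observed alleles.
No inbreeding or null-allele correction is applied — the reference
varieties these analyses target are fully homozygous, which makes such
corrections moot.  An allele is *specific* to a group when its frequency is
≥ `f_min` (default 0.5) there and ≤ `epsilon` (default 0.05) in every other
group; `status` distinguishes strictly private alleles from
diagnostic-with-leakage ones, listing the leaking groups, because observed
low-frequency leakage typically reflects introgression from the target
variety rather than a failure of the marker.  With ε = 0 the report reduces
to the exact set difference of observed allele sets.
`haplotype_discriminators` searches both directions for second-marker
alleles that resolve the origin of an allele shared between two groups.

## qPCR quantification

ΔCt subtracts the arithmetic mean of the reference-gene Ct values (the
averaging rule is this package's choice; it equals the geometric mean on
the linear scale); ΔΔCt subtracts the calibrator's ΔCt; fold = 2^−ΔΔCt.
With per-primer efficiencies the corrected fold is
E_t^−ΔCt(t) / geomean over refs of E_r^−ΔCt(r), which reduces to 2^−ΔΔCt
exactly when every E = 2.  Folds use mean Ct per (condition, gene), so the
calibrator against itself is exactly 1, and adding a constant to every Ct
leaves the fold unchanged.  Differential expression between conditions
defaults to an exact permutation test on replicate log-fold means (all
assignments enumerated; at 3+3 replicates the smallest attainable p is
2/20 = 0.1, and a seeded 10 000-permutation sample takes over beyond
20 000 assignments).  A categorical mode (`mode="fisher"`) dichotomizes the
pooled replicates at their median and applies the Fisher exact test; it
exists because contingency-style testing of qPCR replicates requires *some*
categorization, and the choice of categorization is genuinely open — the
permutation default sidesteps it.

## Synthetic data: what it does and does not emulate

`gen_progeny_marker_table` simulates the S-locus genotype per individual
through the full selection model, then derives each marker by per-gamete
recombination against the locus at the marker's fraction (both parents
heterozygous at the markers, coupling phase).  There is no marker–marker
interference and no full meiosis model: each marker recombines
independently against the locus, which suffices to reproduce the
fine-mapping signature (a clean absent-class core, a few recombinant calls
at flanking markers) but not realistic double-recombinant patterns between
markers.  `gen_association_population` draws K subgroups with
group-specific SSR profiles and latent S genotypes; SC is assigned through
the same dominance engine as the forward simulator (one source of truth):
SC iff no active specificity is expressed.  LD between the designated SSR
allele and its S allele is planted by drawing, per haplotype, the coupled
state with probability r = √r² and an independent marginal draw otherwise —
the designated allele's frequency then equals the S allele's frequency and
the haplotype correlation is exactly r.  The panels have no kinship or
family structure and no genotyping error, so passing recovery tests shows
the screen's statistical behavior under clean LD, not robustness to
confounded population structure (the reason mixed-model GWAS exists).
Default panel size is 710 trees in three subgroups; the amorphous-allele
frequency 0.40 puts the SC fraction near one third, a realistic breeding-
population value.  `gen_ct_table` plants log2-fold effects with Gaussian
cycle noise and never shifts the references.  All generators are
bit-reproducible given their seed; nothing uses global random state.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `baseline_abortion` | 0.10 | ovule abortion from intrinsic clone fertility (observed 9–11 %), independent of the SI rules |
| `retention_threshold` | 0.0 | fused-ovule proportion needed to retain a fruit; 0 = mentor pollen always rescues |
| `min_calls` | 20 | non-missing calls for a marker to be testable |
| `alpha` | 0.05 | FDR cutoff on q-values |
| `min_support` | 3 | carriers needed for a genotype combination to be tested |
| `epsilon` | 0.05 | tolerated leakage frequency for a "specific" allele |
| `f_min` | 0.5 | minimum target-group frequency for a specific allele |
| IRLS | tol 1e−8, 100 iters | logistic maximum-likelihood convergence |

## Validation problem sizes

The test suite validates the analytic distributions exactly; the
Monte-Carlo/analytic agreement at n = 10 000 ovules over 100 seeds (3
binomial SD per class, ≥ 99/100 seeds); the exact test against brute-force
enumeration on 500 random tables with totals ≤ 30 (relative error ≤ 1e−7);
screening recovery of the planted allele in 100 panels of 700 trees at
r² = 0.9 (top q-rank in ≥ 95) with a uniform-p null check at r² = 0;
logistic recovery within ±0.15 at n = 2000; and locus recovery by the
scanner in 100 progenies of 800 at recombination 0.01.  The acceptance
script re-derives the headline numbers at these sizes from a single
command-line seed.

## Known limitations

* The model is phenomenological: no pollen-tube kinetics, protein
  interactions, or molecular mechanism, and no inference of S genotypes
  from sequence.
* The conditional law treats loci as unlinked; linked selected loci would
  need a joint gamete model.
* Pseudo-individual expansion of printed per-marker counts
  (`MarkerTable.from_counts`) is valid only for count-level analyses; it
  carries no linkage information across markers.
* The exact multinomial tail enumerates the 3-class simplex and falls back
  to χ² for very large n with tiny expected ratios.
* Storey's π₀ estimate uses the single λ = 0.5; it is offered as a variant,
  not a calibrated reimplementation of the full smoother.
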