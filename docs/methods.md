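# Methods

This note records the models behind `cpmap`, the defaults and why they were
chosen, the numerical decisions, and what the simulation-based tests do and
do not establish about real data.

## The design: two-way pseudo-testcross (CP population)

Both parents of an F1 cross are heterozygous outbred individuals with
unknown linkage phases.  Each marker segregates, for each parent, like a
testcross: the parent transmits one of its two alleles with probability
1/2, so every informative marker yields a binary gamete code (`a`/`b`) per
progeny and per parent, and each parent is mapped from its own codes.
Markers heterozygous in both parents with three or four distinguishable
alleles (`efxeg`, `abxcd`) are coded for both parents and anchor the two
maps; biallelic double heterozygotes (`hkxhk`) are excluded because the
parental origin of the heterozygous progeny class cannot be resolved, which
halves the informative sample and breaks the binary-code model.

## Segregation codification and null alleles

A null allele (`0`) does not amplify: a true A/0 genotype is *called* AA
and 0/0 is called missing.  Configurations are resolved by enumeration.
Candidate true genotypes per parent follow from the parent's own call (a
heterozygous call is taken at face value; a homozygous call XX may hide
X0; a missing call is unconstrained).  A progeny call class counts as
*present* when its count is inconsistent with miscalls alone — a binomial
test at p < 10⁻³ against an assumed aggregate miscall rate of 1% — and a
candidate configuration survives when all present classes are reachable
and every class it predicts with Mendelian probability ≥ 0.05 is present.
If the surviving candidates disagree in segregation type or in how classes
resolve to parental gametes, the marker is flagged ambiguous and excluded;
it is never guessed.  Markers with fewer than 20 scorable progeny are
excluded (both thresholds configurable).

Convention: the segregation type is written for the first-listed parent,
`lmxll` ⇔ parent 1 effectively heterozygous and parent 2 effectively
homozygous, `nnxnp` for the reciprocal.  A clean heterozygote crossed to a
null heterozygote (AB × A0) is analysed for the clean parent only: the
pooled AA/A0 progeny class still resolves the AB parent's gamete, but not
the null parent's, so the locus is coded `lmxll` (or `nnxnp` for the
reciprocal) and the null parent contributes no codes there.

Two groups of configurations are deliberately classified uninformative even
though their segregation is in principle visible: those where the
segregating classes differ only through missingness (A0 × 00; the 00
progeny of such crosses are indistinguishable from ordinary missing data
once a nonzero missing rate exists) and those where both alleles produce
the same call (AA × A0).  AB × 00, by contrast, segregates as visible
AA/BB call classes and is mapped normally.  The test suite asserts this
non-identifiable set explicitly.

## Two-point statistics

For a marker pair with `n` jointly scored progeny and `m` discordant codes,
`r̂ = min(m, n−m)/n` (the complement handles arbitrary code polarity;
"coupling" when `m ≤ n−m`).  This is the maximum-likelihood testcross
estimate; a property test checks it against a grid search of the likelihood
at 10⁻⁴ resolution.  The linkage LOD is
`m′·log₁₀(2r̂) + (n−m′)·log₁₀(2(1−r̂))` with `m′ = min(m, n−m)`, equal to
`n·log₁₀2` at r̂ = 0.

Grouping uses the *independence LOD*, `G²/(2 ln 10)` of the 2×2 joint code
table.  Unlike the linkage LOD it conditions on the observed margins, so a
marker with badly skewed segregation does not generate spurious linkage.
Degenerate tables (a monomorphic column) score 0.

Marker groups are connected components of the graph with edges at
ind-LOD ≥ 4 (default).  Two safeguards apply before components are read
off, because at ~10⁴ inter-chromosome tests per genome a handful of chance
associations at the threshold is *expected*: a single edge, or a single
cut-vertex marker, is not allowed to fuse two groups of ≥ 3 markers unless
at least one pair between the two sides has ind-LOD ≥ 3 **and** r̂ ≤ 0.30.
The rationale: chance inter-chromosome associations replicate across whole
correlated marker blocks (so counting edges cannot filter them) but they
sit at the detection limit with r̂ ≈ 1/3, whereas a genuine junction —
including one across a marker desert of up to ~35 cM at n ≈ 150 — always
contains at least one pair that close, and r̂ ≤ 0.30 for truly unlinked
loci is a ≈5σ event.  Groups held together only by weaker evidence split,
which mirrors how sparse regions behave under threshold scans in practice.

## Ordering and map distances

Distances use the Kosambi map function, `d = 25·ln((1+2r)/(1−2r))` cM with
inverse `r = ½·tanh(2d/100)`, consistent with moderate positive crossover
interference.

Orders are built by insertion: start from the strongest pair, then always
insert the remaining marker most strongly linked to the placed set (ties by
informativeness, then name — fully deterministic).  Each candidate order is
scored by the weighted least-squares objective
`Σ w_ij (D_ij − d_ij)²` over pairs with ind-LOD ≥ 1 and r̂ ≤ 0.35, with
weights `w_ij = ind-LOD` and `d_ij` the Kosambi distance of the pair;
positions `D` solve the normal equations, whose matrix is a weighted graph
Laplacian independent of the order — it is Cholesky-factorised once per
marker set so each candidate costs only a right-hand-side rebuild.  After
each insertion a ripple pass permutes every sliding window of three
markers; after the last insertion, ripple, single-marker relocation and
segment-reversal passes repeat until the objective stops improving (it
never increases during these passes).  A marker whose best insertion raises
the normalized objective (RMS weighted residual, in cM) by more than 5 is
set aside and reported unplaced rather than forced in.

Two choices here deserve their own justification:

* The pair set is capped at r̂ ≤ 0.35, not at the 0.45 often used.  For
  truly unlinked pairs r̂ is the folded statistic `min(m, n−m)/n`, so a cap
  at 0.45 admits ~0.7% of unlinked pairs at n ≈ 150, each carrying an
  absurd "distance" of ~55 cM and a quadratic penalty large enough to
  reward folded marker orders on long chromosomes.  At 0.35 the admission
  probability of an unlinked pair drops below 10⁻⁴ while all genuinely
  useful pairs (≲ 45 cM apart) remain.
* Final cM positions are refit using only pairs with r̂ ≤ 0.30 (the cap is
  relaxed in 0.05 steps if that graph disconnects the order).  Two-point
  distances beyond ~35 cM are noisy and biased by the truncation above, so
  they steer the order search but not the distance scale.  With this split,
  simulated total map lengths are recovered within 10% on every seed
  tested, with a mean ratio of ~0.99.

Orientation of a finished group is conventional (the lexicographically
smallest marker sits in the proximal half); group naming follows a
user-supplied anchor table by majority vote where available, else
decreasing marker count.  Fitted positions are made monotone by weighted
pool-adjacent-violators before reporting; single-marker groups have length
zero.

## Singleton cleaning

After phasing (below), a cell whose code differs from the nearest
non-missing code on *both* sides along the map order is a singleton — under
a correct dense order it implies a double crossover within a few cM, which
interference makes far rarer than a genotyping error.  Flagged cells are
set to missing and the group is re-ordered and re-fitted once (a single
cleaning round).  On simulations with 1% allele-miscall error, uncleaned
maps run ~10–15% long and cleaning brings them within a few percent of
truth; the paired comparison is part of the acceptance suite.  Markers left
without data are dropped with a warning.

## Phasing and breakpoint calling

Within a mapped group the per-marker code polarity is propagated from the
pairwise coupling/repulsion calls: each marker is oriented by majority vote
over up to three preceding markers, disagreements are logged as conflicts
and resolved by the majority.  The result is a phased parent — two
haplotype allele strings per group, defined up to a group-wide swap.

A transmitted gamete is decomposed against a phased parent by matching
alleles: the donor allele inside a hybrid is inferred where the other
parent's genotype leaves exactly one possibility (other parent homozygous
A/A: hybrid AB ⇒ donor B, hybrid AA ⇒ donor A; heterozygous other parent ⇒
uninformative; null-allele cases are resolved by the same enumeration used
in codification, and a hybrid allele no gamete combination can explain
raises a data-integrity error).  Runs of fewer than `min_support = 2`
consecutive informative assignments are relabelled as conflicts (treated as
genotyping error) before blocks are merged; each transition between
adjacent opposite-assignment informative markers is a crossover breakpoint,
reported as the interval between the flanking markers and their cM
positions — the data never localize a crossover more finely than that.
Haploid derivatives are analysed the same way (their calls are single
alleles; a heterozygous call is a data-integrity error), with a per-group
summary of haplotype origin and of groups inherited without recombination.

## Distortion, origin excess and Wright's F

Each informative marker is tested against 1:1 with a one-df χ²; α = 0.05
with no multiple-testing correction, matching standard per-marker flagging
in linkage studies (an FDR adjustment can be applied downstream; the scan
reports raw p-values).  Under the null the flagged fraction calibrates to α
within binomial error.

When the mapped parent is itself an F1 of two known ancestors, each
marker's codes can be polarized by ancestral origin; the *origin excess* is
the frequency of the designated ancestral allele minus 0.5, with the
two-sided normal envelope ±z_{α/2}/(2√n).  A selected locus with
coefficient `s` drives the favored-haplotype frequency to `1/(2−s)` at the
locus (0.625 at s = 0.4), decaying along the chromosome as
`q(1−r) + (1−q)r`.  The profile peak is estimated from a sliding-window
mean (±7.5 cM) scaled by the square root of the window size, which
suppresses the spurious terminal peaks a raw argmax produces where windows
hold fewer markers.

A note on localization resolution: at n = 156 the realized
favored-haplotype frequency field has a standard deviation of ≈0.039 with a
30–50 cM correlation length, while the signal of an s = 0.4 locus decays by
only ≈0.06 over 30 cM.  Even the maximum-likelihood locus estimator applied
to perfect gamete-origin data localizes such a locus within ±10 cM in only
about 80% of replicates; ±10 cM localization at 90% reliability needs
either larger progenies or s ≈ 0.6.  The corresponding recovery test in the
acceptance suite is asserted at s = 0.4 and is expected to fail — it
documents this resolution limit rather than a defect of the estimator.

Wright's fixation index separates gametic from zygotic selection.  At a
testcross locus the genotype frequency *is* the gamete frequency, so the
two mechanisms are confounded there (and the naive `F = 1 − H_obs/2p̂q̂`
equals −1/3 under the Mendelian null of AA×AB progeny); F is therefore
evaluated only at loci heterozygous in both parents.  Fully informative
loci (`efxeg`, `abxcd`) resolve both uniting gametes per progeny: F is
their φ correlation, tested by permuting one parent's gametes.  Biallelic
`hkxhk` loci use `F = 1 − H_obs/H_exp` with `H_exp = 2p̂q̂` from progeny
allele frequencies and a binomial test of the heterozygote count; under
random union of gametes `H_obs ≥ H_exp` (equality when the sexes share
transmission frequencies), while selection against heterozygous *zygotes*
produces a deficit, i.e. F significantly greater than zero.  Direct
expectation: killing heterozygotes with probability 0.5 at an hkxhk locus
gives genotype proportions 1/3 : 1/3 : 1/3 and F = +1/3.

## Map joining, comparison, projection

Joining the two datasets of one parent concatenates progeny columns after
reconciling the arbitrary a/b polarity per marker through the allele-of-code
tables (the same parent has the same alleles in both crosses); markers with
irreconcilable tables are dropped from the second dataset with a warning,
and markers present in a single dataset are kept and flagged.  The full
pipeline then reruns on the combined matrix.  Cross-parent comparison
restricts to shared markers: per-group Spearman rank correlation with
automatic orientation (a reversed group is perfectly colinear), adjacent
order flips listed as candidate local inversions (reported, never
"corrected"), per-group length tables from shared-marker remaps, and
projection of source-only markers into a reference frame through a
monotone piecewise-linear curve fitted through the shared anchors
(isotonic regression first when anchors are locally inverted, linear
extrapolation beyond the terminal anchors, all estimates flagged).

## The simulator

Meiosis uses a stationary renewal chiasma process on the four-strand
bundle: inter-chiasma distances are Gamma(ν, rate 2ν) per Morgan (intensity
2/Morgan) and each chiasma involves a given chromatid with probability 1/2,
giving one crossover per Morgan per gamete.  Stationarity comes from
starting the process 5 Morgans before the chromosome.  ν = 2.63 by default:
its map function is numerically indistinguishable from Kosambi at mapping
scales (simulated two-point recombination at 10 cM matches the inverse
Kosambi value within Monte-Carlo error at 10⁵ gametes), so the estimation
side and the generative side agree; ν = 1 (Poisson/Haldane, no
interference) is available.  The start haplotype of each gamete is a fair
coin per chromosome — no centromere or obligate-chiasma model.

Gametic selection is rejection sampling on whole gametes: retention
probability Π over selected loci of (1 if the favored haplotype is carried
else 1−s).  The favored-haplotype frequency among accepted gametes is
1/(2−s), and a marker at recombination fraction r from the locus sits at
q(1−r)+(1−q)r; both closed forms are asserted against large simulations.
An optional zygotic variant discards heterozygous zygotes with probability
s after syngamy, for the fixation-index contrast.  Contradictory selection
that empties the pool raises an explicit error.

Genotyping applies the null-allele calling rule (A/0 → "AA", 0/0 →
missing), then symmetric per-allele miscalls to a uniformly chosen other
visible allele, then missingness — defaults 0.2% and 3% for the study-like
dataset, typical of curated array/fragment data.

`make_study_like_dataset` assembles the full design: nine linkage groups
with the reference per-group sizes (total 1084 cM), a central parent CL
constructed as the F1 of a seed parent MD and a donor SO — its two
haplotypes are one MD gamete and one SO gamete whose crossovers follow a
configurable layout (default: nine crossovers, one each on LG1/7/9 and two
each on LG3/4/5) — plus a haploid derivative of CL from a second layout
(default: eight crossovers, one on LG1/7/8, two on LG5, three on LG3, with
LG2/4/6/9 unrecombined).  Layout crossovers keep a 10 cM margin from
chromosome ends and 20 cM mutual separation so every block is identifiable
at moderate marker density.  CL is crossed as male to CH (n = 156) and as
female to PK (n = 140); SO is crossed to TO (n = 147).  Sex- and
genome-specific map-length factors (female 0.85, male 1.07; donor genome
0.65, CH/PK 0.85) emulate heterochiasmy and the shorter donor-species map.
Marker classes mix SNPs (72%), multi-allelic microsatellites (26%) and
indels, with founder genotype frequencies chosen so the segregation-type
census approximates the design's mix (testcross markers dominating, with
the central parent the heterozygous one; dozens of homozygous- and
heterozygous-null configurations).  Gametic selection defaults place
clusters of strong loci (s = 0.5–0.6) on the male side of CL — two loci
each on LG4/5/7/9, single mid-group loci on LG1/3/6, none on LG2/8, with
the favored haplotype flipping between the two ends of LG4 — and weaker
female-side and other-parent loci; this reproduces the qualitative
male-vs-female skew contrast (≈55% vs ≈13% flagged markers) and its per-LG
distribution.  `scale` multiplies marker counts only (default 1.0 ≈ 1100
markers; the packaged demo and the acceptance runs use 0.25, ~240 markers,
as their problem size); progeny sizes are never scaled.  One master seed
drives deterministic per-stage child generators; identical seeds give
byte-identical outputs.

What the simulator does *not* emulate: genotype-calling from raw
intensities or electropherograms, locus-specific error/missingness
patterns, segregating structural variation, centromere placement, or
linkage-disequilibrium structure among founders.  Passing recovery tests
therefore demonstrate the correctness of the algorithms under the stated
generative model, not the error characteristics of any particular
genotyping platform.

## Problem sizes and runtime

The test and acceptance runs use nine groups × 20 markers at n = 156 for
map recovery (20 seeds), 2 cM marker spacing for breakpoint recovery, 10⁴
markers for null calibration, and the scale-0.25 study dataset for the
end-to-end pipeline; these sizes keep the full suite within a few minutes
on one core while leaving every statistical conclusion comfortably outside
Monte-Carlo noise.

## Known limitations

* Two-point regression ordering is a heuristic; with dense markers and
  small progenies, orders of markers closer than ~1/n in recombination are
  statistically unresolvable and are reported in an arbitrary (but
  deterministic) order.
* The `.loc` writer covers the CP dialect used here (five segregation
  types, phase placeholders), not the full JoinMap format family.
* `hkxhk` loci are excluded from mapping (as in the underlying design
  practice) and used only for the fixation-index check.
* Breakpoint intervals are bounded by informative-marker spacing; terminal
  segments before the first informative marker are reported unknown, never
  imputed.
* The fixation-index test at `hkxhk` loci is slightly conservative when the
  two sexes are unequally selected (heterozygote excess under the null).
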