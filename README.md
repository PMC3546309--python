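# cpmap — linkage mapping for outbred F1 (CP) populations

`cpmap` builds genetic maps from the progeny of two heterozygous, outbred
parents — the "CP population" / two-way pseudo-testcross design used for
fruit trees and other perennials where inbred lines do not exist.  It was
written around a citrus-style study design: two interspecific crosses that
share one central heterozygous parent (mapped as male in one cross and as
female in the other), a third cross mapping one of that parent's own
ancestors, heavy male-biased segregation distortion caused by gametic
selection, and the reconstruction of the crossovers carried by individual
transmitted gametes.

## What it does

* **Segregation codification** (`cpmap.segcoding`) — recovers the true
  parental configuration at each locus from raw diploid calls, including
  *null alleles* (a non-amplifying allele `0` makes A/0 look like AA and
  0/0 look like missing data); assigns JoinMap-style segregation types
  (`nnxnp`, `lmxll`, `hkxhk`, `efxeg`, `abxcd`) and extracts per-parent
  gamete codes.
* **Two-point linkage** (`cpmap.linkage`) — testcross recombination
  fraction `r̂ = min(m, n−m)/n`, linkage LOD, and the distortion-robust
  independence LOD `G²/(2 ln 10)` used for grouping at a LOD ≥ 4 threshold.
* **Ordering** (`cpmap.ordering`) — regression mapping: markers inserted by
  linkage strength, each order scored by a weighted least-squares fit of
  positions to pairwise Kosambi distances `d = 25 ln((1+2r)/(1−2r))`,
  refined by ripple/relocation/reversal passes; singletons (cells whose
  phase differs from both flanking markers — the signature of a genotyping
  error) are blanked and the map refitted once.
* **Distortion** (`cpmap.distortion`) — per-marker χ² tests against 1:1,
  allele-origin excess profiles (frequency of a designated ancestral allele
  minus 0.5, with significance envelope), and Wright's fixation index
  `F = 1 − H_obs/H_exp` to separate gametic from zygotic selection.
* **Haplotypes** (`cpmap.haplotypes`) — chromosome-scale phasing from
  pairwise coupling/repulsion, donor-allele inference in a hybrid, and
  crossover-breakpoint calling in transmitted gametes and haploid
  derivatives (blocks, with an error-smoothing minimum run length).
* **Map comparison** (`cpmap.mapcompare`) — joining the male- and
  female-derived datasets of one parent into a reference map, shared-marker
  remaps (length ratios, heterochiasmy), colinearity statistics, and
  projection of markers into a reference frame through monotone tendency
  curves.
* **Simulator** (`cpmap.simdata`) — meiosis with a gamma-renewal crossover
  process (`ν = 2.63`, Kosambi-consistent interference; Poisson/Haldane as
  an option), gametic selection by rejection sampling (favored-haplotype
  frequency converges to `1/(2−s)`), null-allele calling artifacts, and a
  three-progeny study-like dataset generator with ground truth, so that
  every stage is testable by parameter recovery.

## Worked example

`examples/07_full_study_pipeline.py` simulates the full three-progeny
design (n = 156/140/147, nine linkage groups, ~240 markers) and runs every
stage:

```
$ python examples/07_full_study_pipeline.py
  CH          9 LGs   34 markers    274.5 cM
  CL_male     9 LGs  179 markers   1000.0 cM
  CL_female   9 LGs  181 markers    838.0 cM
  PK         10 LGs   35 markers    304.6 cM
  SO          9 LGs  149 markers    508.2 cM
  CL_joined   9 LGs  195 markers    942.1 cM

skewed-marker fractions (alpha = 0.05):
  CL_male    0.58
  CL_female  0.13
  SO         0.19
  CH         0.18
  PK         0.06

Wright F at both-parent-informative loci: mean -0.021, significant fraction 0.00
(near zero despite heavy skew: selection acted on gametes, not zygotes)

donor-gamete breakpoints per LG: {'LG1': 1, 'LG2': 0, 'LG3': 2, 'LG4': 2, 'LG5': 2, 'LG6': 0, 'LG7': 1, 'LG8': 0, 'LG9': 1}
total: 9 (the simulated donor gamete carried 9 crossovers)
haploid-derivative breakpoints: 8 ; unrecombined LGs: ['LG2', 'LG4', 'LG6', 'LG9']
```

Reading the numbers: the central parent CL maps into nine linkage groups in
both crosses and their joined reference map; its *male* gametes show 58%
skewed markers against 13% in its female gametes (clustered gametic
selection is much stronger through pollen), yet Wright's F stays at zero
because gamete-level selection does not disturb the random union of
gametes.  The female-map and donor-species maps are shorter than the male
map (heterochiasmy and a reduced-recombination donor genome).  Finally, the
nine crossovers of the donor gamete that produced CL, and the eight
crossovers of the gamete behind CL's haploid derivative, are recovered
exactly, breakpoint for breakpoint.

The other examples each demonstrate one capability (simulation and
selection, null-allele codification, map building, distortion scanning,
breakpoint calling, map joining/comparison).  The same pipeline is
available from the shell:

```
cpmap all --config examples/demo_config.yaml --out out/
```

which writes genotype TSVs, JoinMap-style `.loc` files, map tables,
summaries, a JSON report and a deterministic run manifest (subcommands
`simulate | code | map | distort | haplotypes | compare` run the stages
separately).

## Layout

```
src/cpmap/        library (segcoding, linkage, ordering, distortion,
                  haplotypes, mapcompare, simdata, pipeline, io, cli)
examples/         one narrative script per capability + demo config
tests/            pytest suite (unit, property and end-to-end recovery)
scripts/          acceptance script
docs/methods.md   models, assumptions, parameter choices, limitations
```
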