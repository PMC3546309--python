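"""Run the whole study-like analysis on three simulated progenies.

One call simulates the full design — three crosses (n = 156 / 140 / 147)
sharing a central heterozygous parent that is itself the F1 of a seed parent
and a donor whose gamete carried nine crossovers — and runs every stage:
codification, per-parent maps, the joined reference map, distortion scans,
the fixation-index check, and donor/haploid breakpoint calling.

The same analysis is available from the shell:
    cpmap all --config examples/demo_config.yaml --out <dir>
"""

from cpmap import run_study_analysis

res = run_study_analysis(seed=1, scale=0.25)

print("linkage groups and map lengths:")
for label, m in res["maps"].items():
    print(f"  {label:10s} {len(m.genetic_map.linkage_groups):2d} LGs  "
          f"{m.genetic_map.total_markers:3d} markers  "
          f"{m.genetic_map.total_length:7.1f} cM")

print("\nskewed-marker fractions (alpha = 0.05):")
for label in ("CL_male", "CL_female", "SO", "CH", "PK"):
    print(f"  {label:10s} {res['skew'][label][1]:.2f}")

fx = res["fixation"]["CPxNC"]
if len(fx):
    print(f"\nWright F at both-parent-informative loci: mean {fx['F'].mean():+.3f}, "
          f"significant fraction {(fx['p'] < 0.05).mean():.2f}")
    print("(near zero despite heavy skew: selection acted on gametes, not zygotes)")

print("\ndonor-gamete breakpoints per LG:", res["donor_breakpoints"].counts())
print("total:", res["donor_breakpoints"].total_breakpoints,
      "(the simulated donor gamete carried",
      res["dataset"].donor_crossover_count, "crossovers)")
print("haploid-derivative breakpoints:", res["haploid_breakpoints"].total_breakpoints,
      "; unrecombined LGs:",
      sorted(res["haploid_summary"].index[res["haploid_summary"]["unrecombined"]]))
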