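"""Infer parental configurations, including hidden null alleles.

Three hand-built loci show the codification logic: a plain testcross, a
parent whose homozygous-looking call hides a null allele (revealed by an
otherwise impossible progeny class), and a fully heterozygous four-allele
microsatellite mapped for both parents.
"""

from cpmap import infer_parental_configuration

cases = [
    # (marker, parent1 call, parent2 call, progeny class counts)
    ("snp_testcross", "AB", "AA", {"AA": 74, "AB": 76}),
    ("snp_hidden_null", "AB", "BB", {"AA": 35, "AB": 70, "BB": 45}),
    ("ssr_four_allele", "AB", "CD", {"AC": 38, "AD": 36, "BC": 41, "BD": 35}),
]

for marker, p1, p2, counts in cases:
    cfg = infer_parental_configuration(marker, p1, p2, counts)
    print(f"{marker:18s} called ({p1} x {p2}) -> true {cfg.p1} x {cfg.p2}  "
          f"type <{cfg.seg_type}>  excluded={cfg.excluded}")

print()
print("The hidden-null case: AA progeny are impossible under AB x BB, so the")
print("second parent must carry a non-amplifying allele (true genotype B0);")
print("its apparent AA progeny are really A0 heterozygotes.")
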