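"""How a variant's MAF and functional annotation combine into one weight.

Builds the default weight scheme, evaluates the MAF parabola at a few
frequencies and shows how annotation increments stack for nonsynonymous
variants.
"""

from rareburden import VariantAnnotation, WeightScheme, combined_weight, maf_weight

scheme = WeightScheme()

print("MAF weight (parabola through (0, 10) and (0.01, 1), vertex at the cap):")
for maf in (0.0, 0.001, 0.005, 0.01):
    print(f"  maf={maf:<6} -> w={maf_weight(maf, scheme):.2f}")

print("\nAnnotation x MAF combined weights:")
examples = [
    ("LOF, maf 1e-4", 1e-4, VariantAnnotation("lof")),
    ("nonsynonymous, maf 0.005", 0.005, VariantAnnotation("protein_altering")),
    (
        "nonsynonymous + SIFT deleterious, maf 0.005",
        0.005,
        VariantAnnotation("protein_altering", sift="deleterious"),
    ),
    (
        "nonsyn + PolyPhen probably damaging + SIFT, maf 0.001",
        0.001,
        VariantAnnotation(
            "protein_altering", polyphen="probably_damaging", sift="deleterious"
        ),
    ),
    ("synonymous, maf 0.01", 0.01, VariantAnnotation("synonymous")),
]
for label, maf, ann in examples:
    print(f"  {label:<50} -> {combined_weight(maf, ann, scheme):8.2f}")

print(
    "\nA very rare LOF variant is worth ~1000 score units per allele; a common\n"
    "synonymous one is worth ~1 — the burden score is dominated by variants\n"
    "that are rare and predicted to be severe."
)
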