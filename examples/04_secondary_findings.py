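"""Screen annotated variants for actionable monogenic secondary findings.

Applies the four screening rules to a toy annotated-variant table: (1)
laboratory-known P/LP; (2) ClinVar P/LP with MAF < 0.1%; (3) HGMD
disease-causing with MAF < 0.03%; (4) loss-of-function with MAF < 0.1% in
a gene where that is a disease mechanism. Output is a candidate list for
expert review, not a classification.
"""

from clinprs import findings as sf

variants = [
    sf.AnnotatedVariant("17", 43_071_077, "T", "TA", "BRCA1", "frameshift",
                        maf=None, clinvar="LP"),
    sf.AnnotatedVariant("13", 32_338_200, "TT", "T", "BRCA2", "frameshift",
                        maf=0.0, clinvar="P"),
    sf.AnnotatedVariant("19", 11_113_300, "C", "T", "LDLR", "missense",
                        maf=0.0004, clinvar="none", hgmd_dm=True),
    sf.AnnotatedVariant("2", 47_478_521, "G", "A", "MSH2", "missense",
                        maf=0.002, clinvar="LP"),       # too common for gate 2
    sf.AnnotatedVariant("2", 179_400_000, "G", "A", "TTN", "nonsense",
                        maf=0.0, clinvar="P"),          # off panel
]

rules = sf.default_rules()  # 59-gene panel, published MAF gates
for f in sf.filter_variants(variants, rules):
    print(f"{f.gene:6s} {f.chrom}:{f.pos} {f.ref}>{f.alt}  "
          f"rules: {', '.join(f.rules_triggered)}")

print()
print("The two BRCA frameshifts qualify (ClinVar P/LP below the 0.1% gate;")
print("frameshift in LoF-mechanism genes). The LDLR HGMD variant fails the")
print("stricter 0.03% gate (0.04% >= 0.03%); the common MSH2 LP fails 0.1%;")
print("TTN is outside the screening panel. Candidates still require manual")
print("classification and orthogonal confirmation.")
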