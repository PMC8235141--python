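"""Fold short RNAs and verify the optimum against exhaustive enumeration.

The minimum-free-energy fold of a GC hairpin, an unpairable homopolymer, and
a constrained fold; each energy is checked against the brute-force optimum
over every nested structure.
"""

from rna2dbarcode import Constraints, enumerate_structures, fold_mfe, load_default_model

model = load_default_model()

for seq in ("GGGGAAAACCCC", "AAAAAAAA", "GGGCGCAAACAAGCGCCC"):
    st = fold_mfe(seq, model)
    best = min(enumerate_structures(seq, model=model), key=lambda s: s.energy)
    print(f"{seq:20s} {st.dotbracket:20s} {st.energy:7.2f} kcal/mol "
          f"(enumeration optimum {best.energy:.2f})")

constrained = fold_mfe("GGGGAAAACCCC", model, Constraints(unpaired=frozenset({0})))
print(f"{'with 5p end unpaired':20s} {constrained.dotbracket:20s} {constrained.energy:7.2f} kcal/mol")
print("\nLower (more negative) free energy = more stable structure; the")
print("constrained fold can never beat the unconstrained optimum.")
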