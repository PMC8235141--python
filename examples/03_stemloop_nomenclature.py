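"""Delimit a 16S 3'-half V domain and label its stem-loops L7-L13.

Folds the packaged reference sequence, finds the V domain between its
conserved flanking motifs, and tabulates each labelled hairpin: span (1-based
inclusive), stem length in base pairs, loop and bulge length in nucleotides.
"""

from rna2dbarcode import (
    delimit_v_domain,
    fold_mfe,
    load_default_model,
    load_reference_template,
    stemloop_table,
    template_anchors,
)

reference = load_reference_template()
st = fold_mfe(reference.source.record, load_default_model())
vd = delimit_v_domain(st, anchors=template_anchors(), reference=reference)

print(f"V domain region: {vd.region[0] + 1}-{vd.region[1]} (1-based)")
print(stemloop_table({"reference": vd}).to_string(index=False))
print("\nStem-loop length in nt = 2 x stem bp + loop nt + bulge nt;")
print("L7 is the 19-nt hairpin used as the 2D barcoding region.")
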