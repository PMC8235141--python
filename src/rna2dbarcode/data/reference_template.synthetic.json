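{
 "id": "V_domain_reference",
 "description": "Synthetic hand-designed 16S 3'-half V-domain template; hairpins labelled L7-L13 in 5'->3' order. Editorial stand-in for the literature nomenclature, not an empirical structure.",
 "sequence": "AAACAAACAAACAAAAACACAACAAAAACACACAACAAACAAACAAAACACACAACACACAGAAUAAGAGAGGGAAAAAAAACCCCUCAAAAAGCCCACAACGGGCACAAACUCGAAAAACCGAGAAAAGGGCAAAAGCCCAAACCAGCAAAAAAAGCUGAAACGGCAACAAGCCGAAACGCUCAAACAAAAGAGCGAUAAGAAUA",
 "structure": ".....................................................................(((((.........))))).....((((.....)))).....((((......))))....((((....))))....((((.......))))...((((.....))))...(((((........))))).........",
 "region": [
  69,
  197
 ],
 "anchor5": "AGAAUAAGA",
 "anchor3": "AUAAGAAUA",
 "labels": [
  "L7",
  "L8",
  "L9",
  "L10",
  "L11",
  "L12",
  "L13"
 ],
 "hairpin_spans": {
  "L7": [
   69,
   87
  ],
  "L8": [
   93,
   105
  ],
  "L9": [
   111,
   124
  ],
  "L10": [
   129,
   140
  ],
  "L11": [
   145,
   159
  ],
  "L12": [
   163,
   175
  ],
  "L13": [
   179,
   196
  ]
 }
}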