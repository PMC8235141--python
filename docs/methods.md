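# Methods

This note records the models, parameters and design choices behind
`rna2dbarcode`, and what the synthetic test conditions do and do not show
about real data.

## Secondary-structure model

Structures are *nested* pairings: no pseudoknots, every pair drawn from
{A·U, U·A, G·C, C·G, G·U, U·G}, hairpin loops of at least 3 nt (the standard
steric minimum), and IUPAC ambiguity codes never paired (conservative — an N
could pair, but we refuse to guess). Coordinates are 0-based half-open
internally and 1-based inclusive in every report.

The free energy of a structure is a sum over its loops:

* **stacks** — two directly adjacent pairs contribute a tabulated stacking
  energy (kcal/mol at 37 °C). The packaged table is seeded from published
  Turner-style nearest-neighbour values; the two slightly positive
  wobble-on-wobble stacks are clamped to 0.0 so that every tabulated stack is
  stabilising or neutral.
* **hairpin / bulge / internal loops** — size-indexed initiation penalties,
  tabulated to size 9 (hairpins) or 6 (bulges, internal) and extrapolated
  beyond with the Jacobson–Stockmayer form
  `ΔG(n) = ΔG(n_max) + 1.75·RT·ln(n/n_max)`, RT = 0.616 kcal/mol.
  No stacking bonus is granted across a bulge.
* **multibranch loops** — a flat initiation cost (3.4 kcal/mol) per
  multiloop, with unpaired multiloop positions free. Coaxial stacking and
  dangling ends are ignored.

Parameters live in `data/energy_params.json`; users may substitute full
Turner tables without touching code. This deliberately simplified model
*approximates* what a thermodynamic folding server would produce — it does
not reproduce any particular program's output, and analyses that depend on
fine energy differences should treat the packaged parameters as a default,
not ground truth. On the packaged template, an independent full-parameter
implementation (ViennaRNA) recovers essentially the same architecture (the
cross-check test requires ≥ 90 % pair agreement).

### Optimisation and determinism

`fold_mfe` is an exact O(n³) dynamic programme (interior loops capped at 30
unpaired nt, the usual practice) vectorised over diagonals; a 200-nt V domain
folds in about a second. Among co-optimal structures the traceback applies a
fixed preference order — pairing before skipping, stacked and 5′-most
decompositions first — so refolding is bit-identical across runs and
platforms. Constraints (positions held unpaired, pairs forced) are honoured
exactly and can only raise the optimum energy. Two independent oracles are
part of the package, not just the tests: `fold_maxpair` (Nussinov pair
maximisation) and `enumerate_structures` (every nested structure of a short
sequence, scored by an evaluator that is separate from the folding
recursions).

## Stem-loop decomposition and nomenclature

A stem-loop is grown outward from each hairpin-closing pair; helix segments
separated by at most **2 unpaired nt per side** merge into one stem (recorded
as bulges), larger interruptions start a new helix. This threshold is the
smallest rule consistent with drawing a bulged hairpin as one unit. Stem
length counts base pairs; stem-loop length counts `2·bp + loop + bulges`
(so a 5-bp stem with a 9-nt loop is a 19-nt stem-loop).

The V domain is delimited by two conserved flanking motifs (best ungapped
hit, ≤ 2 mismatches each; fallback: the 3′ half of the sequence, logged).
Hairpins inside it are labelled L7–L13 by order-preserving matching against a
packaged template: a dynamic programme that first maximises the number of
matched hairpins and then minimises the summed |midpoint offset| (offsets
taken relative to the region starts, matches refused beyond 40 nt); each
template label is used at most once and unmatched query hairpins are flagged
rather than forced. The packaged template
(`data/reference_template.synthetic.json`) is a *synthetic, hand-designed*
16S 3′-half whose seven hairpins carry the literature's L-numbers in 5′→3′
order — an editorial stand-in constructed so that its designed structure is
the unique optimum of the packaged energy model, not an empirical structure;
users with a curated template can supply their own.

## Cross-taxon comparison

* **Alignment.** Stems align by pairing rank (outermost to outermost; a
  shorter stem takes the inner ranks, leaving gaps at the outer ones), loops
  by global sequence alignment (match +1, mismatch 0, gap −1; ties resolved
  to the 5′-most gap), bulges as left-justified blocks keyed to the stem rank
  they interrupt; with more than two taxa the loops are joined by
  centre-star alignment around the longest loop. Columns are therefore
  structurally homologous by construction. Automatic bulge placement may
  differ from a manual alignment at the margins.
* **Divergence ranking.** A stem-loop's score is the mean per-column Shannon
  entropy (bits) over non-gap states, gap-containing columns down-weighted by
  their non-gap fraction; ties break toward the lower L-number. "Most
  divergent" is thereby operationalised as a single testable number.
* **Column classification.** Landmark = one state clade-wide; diagnostic =
  fixed within every group with ≥ 2 groups differing (strict fixation by
  default — a frequency-threshold mode, e.g. 0.9, is available behind a flag
  because some users prefer near-fixation); everything else polymorphic is
  variable. Columns with any gap or any non-ACGU code are set aside as
  `gapped` / `ambiguous` and excluded from biological verdicts: gaps here are
  alignment artefacts, not a fifth character state.
* **CBC bookkeeping.** For every taxon pair at every aligned stem rank with
  no gap: both sides changed with both state-pairs canonical → CBC; exactly
  one side changed, both canonical → semi-CBC; any non-canonical state-pair →
  pair broken. G·U wobble counts as a valid pair, per standard CBC practice.
* **Consensus.** A pair is kept when present in a strict majority (> 50 %);
  the consensus sequence takes the majority state per column with IUPAC
  degeneracy on ties. Non-nested majority pairs raise an error naming the
  conflict.
* **Structure distance.** The symmetric difference of pair sets on common
  coordinates — a proper metric, used as the package's proxy for "folding
  homology", which the qualitative literature does not define numerically.

A guide tree supplied as Newick is used as a taxon carrier: leaves are
grouped by name at the requested rank (genus = first word, species =
binomial). Explicit TSV assignments override this when the nomenclature does
not reflect the desired partition.

## The synthetic clade generator

`synthesize_clade` emulates the signal architecture of a V-domain study
clade on the packaged template: landmark loop positions held invariant;
diagnostic loop positions fixed to a different state in each genus;
species-variable loop positions fixed within species but cycled across the
species of a genus (so the column stays polymorphic within every genus and
can never masquerade as genus-diagnostic); optionally one stem pair of one
genus rewritten as a CBC (e.g. C–G → A–U) or semi-CBC (→ wobble); and an
optional per-site background mutation rate, with stem-touching background
mutations applied to both partners as a replacement canonical pair so the
template stays foldable.

Two constraints keep the generator honest about folding: planted loop states
are drawn from {A, C} (on this template no A/C combination can create a new
pair, so the planted signal provably cannot reshape the fold), and the
CBC/semi-CBC sites are stem ranks at which the replacement was verified not
to change the minimum-free-energy structure. Every random draw comes from a
stream named by (seed, genus, species, individual), so a taxon's sequence
does not depend on how many other taxa are generated.

Default study conditions: 2 genera × 3 species × 2 individuals, 4 landmark +
3 diagnostic + 2 species-variable positions in the 9-nt L7 loop of a 19-nt
L7 (5-bp stem), zero background — the clade architecture the analysis is
meant to resolve. What passing on these conditions shows: the pipeline
recovers a planted architecture of exactly this shape without false
positives, and folding is stable under the planted perturbations. What it
does not show: performance on real 16S data with indels inside loops,
heterogeneous stem lengths across taxa, sequencing ambiguities, or folding
models that disagree with the true structure — on real data the delimitation
report should be read alongside, not instead of, a phylogenetic analysis.

## Problem sizes used by the packaged analyses

The test suite and the acceptance script fold dozens (not thousands) of
~200-nt sequences, check the folding engine against exhaustive enumeration on
500 random sequences of length ≤ 15, and measure signal recovery on 100
seeded clades and CBC agreement on 60 — sizes chosen so the full analysis
re-runs from scratch in about a minute while every claim stays at full
strength (exact recovery, 100 % agreement).

## Known limitations

* No pseudoknots, no partition-function/ensemble view, no suboptimal
  sampling: a single MFE structure per sequence.
* The energy parameters are simplified; absolute energies are not comparable
  with full Turner-model outputs (architectures generally are).
* Centre-star loop alignment is exact for the pairwise case but heuristic for
  many taxa with heterogeneous indels.
* L-number labels are only as good as the template; for clades whose V
  domain departs strongly from the packaged architecture, supply a curated
  template.
* `fetch_accessions` requires network access and is deliberately untested;
  all analyses accept local FASTA.
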