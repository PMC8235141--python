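"""Synthetic clades with planted structural signal.

The generator emulates the signal architecture of a 16S V-domain study clade:
a shared template structure; *landmark* loop positions held invariant
clade-wide; *diagnostic* loop positions fixed to a different state in every
genus; *species-variable* loop positions fixed within each species but
distinct between the species of a genus; optional compensatory (CBC) or
semi-compensatory base changes planted into a stem of one genus; and an
optional per-site background mutation rate.  Stem-touching background
mutations are applied to both partners as a replacement canonical pair so the
template remains foldable.

Randomness is drawn from named streams keyed by (seed, genus, species,
individual), so each taxon's draws are independent of how many other taxa are
generated and every realisation is reproducible from the single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .energy import CANONICAL_PAIRS, load_default_model
from .fold import PairTable
from .io import SequenceRecord
from .stemloops import V_DOMAIN_LABELS, extract_stemloops, load_reference_template

__all__ = ["SyntheticCladeSpec", "synthesize_clade", "example_clade_spec"]

_BASES = "ACGU"


@dataclass(frozen=True)
class SyntheticCladeSpec:
    """Recipe for one synthetic clade. Positions are 0-based on the template."""

    seed: int
    template_sequence: str
    template_structure: str
    n_genera: int = 2
    n_species_per_genus: int = 3
    n_individuals_per_species: int = 2
    landmark_positions: frozenset[int] = frozenset()
    diagnostic_positions: dict[int, dict[str, str]] = field(default_factory=dict)
    species_variable_positions: frozenset[int] = frozenset()
    planted_cbc_pairs: tuple[tuple[int, str, str], ...] = ()  # (pair index, genus, replacement)
    background_mutation_rate: float = 0.0
    genus_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_genera, self.n_species_per_genus, self.n_individuals_per_species) < 1:
            raise ValueError("clade counts must all be >= 1")
        if not 0.0 <= self.background_mutation_rate < 1.0:
            raise ValueError("background_mutation_rate must be in [0, 1)")
        if len(self.template_sequence) != len(self.template_structure):
            raise ValueError("template sequence and structure lengths differ")
        n = len(self.template_sequence)
        pt = PairTable.from_dotbracket(self.template_structure)
        sets = {
            "landmark": set(self.landmark_positions),
            "diagnostic": set(self.diagnostic_positions),
            "species_variable": set(self.species_variable_positions),
        }
        seen: set[int] = set()
        for name, positions in sets.items():
            overlap = positions & seen
            if overlap:
                raise ValueError(f"position sets overlap at {sorted(overlap)} ({name})")
            seen |= positions
            bad = [p for p in positions if not 0 <= p < n]
            if bad:
                raise ValueError(f"{name} positions outside template: {sorted(bad)}")
            paired = [p for p in positions if pt.partner[p] != -1]
            if paired:
                raise ValueError(f"{name} positions must be unpaired (loop) sites: {sorted(paired)}")
        pairs = pt.pairs()
        for k, genus, repl in self.planted_cbc_pairs:
            if not 0 <= k < len(pairs):
                raise ValueError(f"stem pair index {k} outside the template's {len(pairs)} pairs")
            if repl not in CANONICAL_PAIRS:
                raise ValueError(f"replacement pair {repl!r} is not an allowed pair")
            i, j = pairs[k]
            if self.template_sequence[i] + self.template_sequence[j] == repl:
                raise ValueError(f"replacement pair {repl} equals the template pair at index {k}")
        for pos, states in self.diagnostic_positions.items():
            if len(set(states.values())) < 2:
                raise ValueError(f"diagnostic position {pos} needs >= 2 distinct genus states")

    @property
    def genera(self) -> tuple[str, ...]:
        if self.genus_names:
            if len(self.genus_names) != self.n_genera:
                raise ValueError("genus_names length must equal n_genera")
            return self.genus_names
        return tuple(f"Genus{g + 1}" for g in range(self.n_genera))


def _stream(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def synthesize_clade(spec: SyntheticCladeSpec) -> tuple[list[SequenceRecord], dict[str, Any]]:
    """Generate a clade of sequences plus an exact ground-truth record.

    Deterministic for a fixed spec (the seed names every random stream).  The
    ground truth lists the planted landmark/diagnostic/species states, CBC
    events with their expected classification, and every background mutation,
    exactly as applied.
    """
    seq0 = spec.template_sequence.upper().replace("T", "U")
    pt = PairTable.from_dotbracket(spec.template_structure)
    pairs = pt.pairs()
    genera = spec.genera

    # species-level states, drawn from the fold-safe {A, C} alphabet and cycled
    # across the species of a genus so every genus stays polymorphic (hence the
    # column can never read as genus-diagnostic) whenever it holds >= 2 species
    species_states: dict[tuple[str, int], dict[int, str]] = {}
    for g, genus in enumerate(genera):
        rng = _stream(spec.seed, g)
        for pos in sorted(spec.species_variable_positions):
            phase = int(rng.integers(2))
            for s in range(spec.n_species_per_genus):
                species_states.setdefault((genus, s), {})[pos] = "AC"[(s + phase) % 2]

    cbc_by_genus: dict[str, list[tuple[int, str]]] = {}
    cbc_events = []
    for k, genus, repl in spec.planted_cbc_pairs:
        i, j = pairs[k]
        old = seq0[i] + seq0[j]
        changed = (old[0] != repl[0]) + (old[1] != repl[1])
        cbc_by_genus.setdefault(genus, []).append((k, repl))
        cbc_events.append(
            {
                "pair_index": k,
                "positions": [i, j],
                "genus": genus,
                "template": old,
                "replacement": repl,
                "type": "CBC" if changed == 2 else "semiCBC",
            }
        )

    reserved = (
        set(spec.landmark_positions)
        | set(spec.diagnostic_positions)
        | set(spec.species_variable_positions)
        | {p for ev in cbc_events for p in ev["positions"]}
    )
    free_unpaired = [p for p in range(len(seq0)) if pt.partner[p] == -1 and p not in reserved]
    free_pairs = [(i, j) for i, j in pairs if i not in reserved and j not in reserved]

    records: list[SequenceRecord] = []
    taxa: dict[str, str] = {}
    background: dict[str, list[list[Any]]] = {}
    for g, genus in enumerate(genera):
        for s in range(spec.n_species_per_genus):
            binomial = f"{genus} sp{s + 1}"
            for ind in range(spec.n_individuals_per_species):
                seq = list(seq0)
                for pos, states in spec.diagnostic_positions.items():
                    if genus not in states:
                        raise ValueError(f"diagnostic position {pos} lacks a state for {genus}")
                    seq[pos] = states[genus]
                for pos, state in species_states.get((genus, s), {}).items():
                    seq[pos] = state
                for k, repl in cbc_by_genus.get(genus, []):
                    i, j = pairs[k]
                    seq[i], seq[j] = repl[0], repl[1]
                rec_id = f"{genus}_sp{s + 1}_i{ind + 1}"
                events: list[list[Any]] = []
                if spec.background_mutation_rate > 0:
                    rng = _stream(spec.seed, g, s, ind)
                    for p in free_unpaired:
                        if rng.random() < spec.background_mutation_rate:
                            new = rng.choice([b for b in _BASES if b != seq[p]])
                            events.append([p, seq[p], str(new)])
                            seq[p] = str(new)
                    for i, j in free_pairs:
                        if rng.random() < spec.background_mutation_rate:
                            old = seq[i] + seq[j]
                            choices = sorted(CANONICAL_PAIRS - {old})
                            new = str(rng.choice(choices))
                            events.append([i, old[0], new[0]])
                            events.append([j, old[1], new[1]])
                            seq[i], seq[j] = new[0], new[1]
                records.append(
                    SequenceRecord(id=rec_id, residues="".join(seq), taxon=binomial, marker="16S")
                )
                taxa[rec_id] = binomial
                background[rec_id] = events

    ground_truth: dict[str, Any] = {
        "template_length": len(seq0),
        "genera": list(genera),
        "taxa": taxa,
        "landmark_positions": sorted(spec.landmark_positions),
        "diagnostic_positions": {
            str(pos): dict(states) for pos, states in sorted(spec.diagnostic_positions.items())
        },
        "species_variable_positions": {
            str(pos): {
                f"{genus} sp{s + 1}": species_states[(genus, s)][pos]
                for genus in genera
                for s in range(spec.n_species_per_genus)
            }
            for pos in sorted(spec.species_variable_positions)
        },
        "cbc_events": cbc_events,
        "background_events": background,
    }
    return records, ground_truth


def example_clade_spec(
    seed: int,
    n_genera: int = 2,
    n_species_per_genus: int = 3,
    n_individuals_per_species: int = 2,
    background_mutation_rate: float = 0.0,
    planted_cbc: str | None = None,
    cbc_label: str = "L8",
    genus_names: tuple[str, ...] = (),
) -> SyntheticCladeSpec:
    """Study-condition clade on the packaged template.

    Plants, inside the 9-nt L7 loop: four landmark positions, three
    genus-diagnostic positions and two species-variable positions — the
    signal architecture of the *Dondice*-clade L7 ("six identical and three
    variable" loop nucleotides, three genus-separating substitutions, four
    clade-wide conserved positions).  ``planted_cbc`` = 'CBC' or 'semiCBC'
    additionally rewrites one stem pair of ``cbc_label`` in the last genus.
    """
    ref = load_reference_template()
    seq = ref.source.record.residues
    db = ref.source.dotbracket
    l7 = ref.by_label()["L7"]
    loop = list(range(l7.loop_span[0], l7.loop_span[1]))
    if len(loop) != 9:
        raise AssertionError("packaged template L7 loop is expected to span 9 nt")
    landmark = frozenset({loop[0], loop[2], loop[5], loop[8]})
    diag_sites = (loop[1], loop[4], loop[7])
    species_var = frozenset({loop[3], loop[6]})

    genera = genus_names or tuple(f"Genus{g + 1}" for g in range(n_genera))
    if n_genera != 2:
        raise ValueError(
            "the example spec plants fold-safe A/C diagnostic states and therefore "
            "supports exactly 2 genera; build a custom SyntheticCladeSpec for more"
        )
    diagnostic: dict[int, dict[str, str]] = {}
    for k, pos in enumerate(diag_sites):
        # alternate which genus carries A so the three sites are not identical
        diagnostic[pos] = {genera[0]: "AC"[k % 2], genera[1]: "AC"[(k + 1) % 2]}

    planted: tuple[tuple[int, str, str], ...] = ()
    if planted_cbc is not None:
        pt = PairTable.from_dotbracket(db)
        pairs = pt.pairs()
        # ranks at which the replacement is known not to reshape the MFE fold
        rank = 3 if planted_cbc.lower().startswith("semi") else 1
        target = ref.by_label()[cbc_label].stem_pairs[rank]
        k = pairs.index(target)
        i, j = target
        old = seq[i] + seq[j]
        repl = _cbc_replacement(old, semi=planted_cbc.lower().startswith("semi"))
        planted = ((k, genera[-1], repl),)

    return SyntheticCladeSpec(
        seed=seed,
        template_sequence=seq,
        template_structure=db,
        n_genera=n_genera,
        n_species_per_genus=n_species_per_genus,
        n_individuals_per_species=n_individuals_per_species,
        landmark_positions=landmark,
        diagnostic_positions=diagnostic,
        species_variable_positions=species_var,
        planted_cbc_pairs=planted,
        background_mutation_rate=background_mutation_rate,
        genus_names=genera,
    )


def _cbc_replacement(old: str, semi: bool) -> str:
    """A canonical replacement pair: both sides changed (CBC) or one (semi)."""
    for cand in sorted(CANONICAL_PAIRS):
        changed = (cand[0] != old[0]) + (cand[1] != old[1])
        if semi and changed == 1:
            return cand
        if not semi and changed == 2:
            return cand
    raise ValueError(f"no {'semi-' if semi else ''}compensatory replacement for {old}")
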