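"""Stem-loop decomposition and molluscan L-number nomenclature.

A *stem-loop* (hairpin) is an innermost helix closing an unpaired terminal
loop.  Helix segments separated by bulges or internal loops of at most two
unpaired positions per side are merged into a single stem; larger
interruptions start a new helix.  The variable 3' region of the mitochondrial
16S rRNA (the V domain) carries seven successive hairpins that the molluscan
literature labels L7 through L13; labels are assigned to a query structure by
order-preserving matching against a packaged labelled template.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .energy import load_default_model, structure_energy
from .fold import PairTable, SecondaryStructure, UNPAIRED, fold_mfe
from .io import SequenceRecord

__all__ = [
    "StemLoop",
    "VDomain",
    "extract_stemloops",
    "delimit_v_domain",
    "assign_loop_labels",
    "load_reference_template",
    "stemloop_table",
]

logger = logging.getLogger(__name__)

#: per-side unpaired-interruption size up to which helix segments merge
BULGE_MERGE_THRESHOLD = 2

V_DOMAIN_LABELS = tuple(f"L{k}" for k in range(7, 14))


@dataclass(frozen=True)
class StemLoop:
    """One hairpin: stem pairs (with bulges) closing an unpaired loop.

    Coordinates are 0-based on the source sequence; ``loop_span`` and bulge
    intervals are half-open.
    """

    closing_pair: tuple[int, int]
    stem_pairs: tuple[tuple[int, int], ...]  # outermost -> innermost
    loop_span: tuple[int, int]
    bulges: tuple[tuple[str, int, int], ...] = ()  # (side '5p'/'3p', start, end)
    label: str | None = None
    source: SecondaryStructure | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.stem_pairs[0] != self.closing_pair:
            raise ValueError("closing_pair must be the outermost stem pair")
        for (a, b), (c, d) in zip(self.stem_pairs, self.stem_pairs[1:]):
            if not (a < c < d < b):
                raise ValueError("stem pairs must be ordered outermost to innermost")

    # -- arithmetic used by the reports ---------------------------------

    @property
    def span(self) -> tuple[int, int]:
        """Closed interval [i, j] of the whole stem-loop."""
        return self.closing_pair

    @property
    def stem_bp(self) -> int:
        return len(self.stem_pairs)

    @property
    def loop_nt(self) -> int:
        return self.loop_span[1] - self.loop_span[0]

    @property
    def bulge_nt(self) -> int:
        return sum(e - s for _, s, e in self.bulges)

    @property
    def total_nt(self) -> int:
        """Stem (pairs x 2) + loop + bulge positions."""
        return 2 * self.stem_bp + self.loop_nt + self.bulge_nt

    @property
    def midpoint(self) -> float:
        i, j = self.closing_pair
        return (i + j) / 2.0

    def _seq(self) -> str:
        if self.source is None:
            raise ValueError("stem-loop has no source structure attached")
        return self.source.record.residues

    @property
    def sequence(self) -> str:
        i, j = self.closing_pair
        return self._seq()[i : j + 1]

    @property
    def loop_sequence(self) -> str:
        return self._seq()[self.loop_span[0] : self.loop_span[1]]

    @property
    def dotbracket(self) -> str:
        i, j = self.closing_pair
        return self.source.dotbracket[i : j + 1] if self.source else ""

    def positions(self) -> dict[str, object]:
        """Column-building description: stem ranks, bulges keyed by rank, loop."""
        bulge_map: dict[tuple[int, str], tuple[int, int]] = {}
        for side, s, e in self.bulges:
            # rank of the innermost stem pair outside this bulge
            if side == "5p":
                rank = max(r for r, (a, _) in enumerate(self.stem_pairs) if a < s)
            else:
                rank = max(r for r, (_, b) in enumerate(self.stem_pairs) if b > e - 1)
            bulge_map[(rank, side)] = (s, e)
        return {"stem": self.stem_pairs, "loop": self.loop_span, "bulges": bulge_map}


@dataclass(frozen=True)
class VDomain:
    """The delimited variable region of a folded 16S 3' half, with labels."""

    source: SecondaryStructure
    region: tuple[int, int]  # half-open on the source sequence
    stem_loops: tuple[StemLoop, ...]  # labelled, 5'->3'
    unassigned: tuple[StemLoop, ...] = ()

    def __post_init__(self) -> None:
        labels = [sl.label for sl in self.stem_loops]
        if any(lb is None for lb in labels):
            raise ValueError("V-domain stem_loops must all carry labels")
        order = [int(lb[1:]) for lb in labels]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError(f"labels must be unique and increasing 5'->3', got {labels}")

    def by_label(self) -> dict[str, StemLoop]:
        return {sl.label: sl for sl in self.stem_loops}


# ---------------------------------------------------------------------------


def extract_stemloops(structure: SecondaryStructure) -> list[StemLoop]:
    """Decompose a structure into its hairpins, 5' to 3'.

    Starting from each innermost (hairpin-closing) pair, the stem is grown
    outward through enclosing pairs as long as every interruption is at most
    ``BULGE_MERGE_THRESHOLD`` unpaired positions per side and the enclosing
    pair has no other branch.  A structure without hairpins gives ``[]``.
    """
    partner = structure.pairs.partner
    n = len(partner)

    # enclosing pair of each pair (None = exterior), and children count
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for i in range(n):
        j = partner[i]
        if j > i:
            parent = stack[-1] if stack else None
            children.setdefault(parent, []).append((i, j))
            children.setdefault((i, j), [])
            stack.append((i, j))
        elif j != UNPAIRED and j < i:
            stack.pop()

    parent_of: dict[tuple[int, int], tuple[int, int] | None] = {}
    for par, kids in children.items():
        for kid in kids:
            parent_of[kid] = par

    out: list[StemLoop] = []
    for pair, kids in children.items():
        if pair is None or kids:
            continue  # not a hairpin-closing pair
        inner = pair
        stem = [inner]
        bulges: list[tuple[str, int, int]] = []
        cur = inner
        while True:
            par = parent_of.get(cur)
            if par is None or len(children[par]) != 1:
                break
            gap5 = cur[0] - par[0] - 1
            gap3 = par[1] - cur[1] - 1
            if gap5 > BULGE_MERGE_THRESHOLD or gap3 > BULGE_MERGE_THRESHOLD:
                break
            if gap5:
                bulges.append(("5p", par[0] + 1, cur[0]))
            if gap3:
                bulges.append(("3p", cur[1] + 1, par[1]))
            stem.append(par)
            cur = par
        stem_pairs = tuple(reversed(stem))  # outermost first
        out.append(
            StemLoop(
                closing_pair=stem_pairs[0],
                stem_pairs=stem_pairs,
                loop_span=(inner[0] + 1, inner[1]),
                bulges=tuple(sorted(bulges, key=lambda b: b[1])),
                source=structure,
            )
        )
    out.sort(key=lambda sl: sl.closing_pair[0])
    return out


def _best_motif_hit(seq: str, motif: str, max_mismatch: int = 2) -> tuple[int, int] | None:
    """Best ungapped occurrence (start, mismatches) of ``motif`` in ``seq``."""
    best: tuple[int, int] | None = None
    m = len(motif)
    for s in range(0, len(seq) - m + 1):
        mm = sum(1 for a, b in zip(seq[s : s + m], motif) if a != b)
        if best is None or mm < best[1]:
            best = (s, mm)
    if best is not None and best[1] <= max_mismatch:
        return best
    return None


def delimit_v_domain(
    structure: SecondaryStructure,
    anchors: tuple[str, str] | None = None,
    reference: "VDomain | None" = None,
    max_offset: float = 40.0,
) -> VDomain:
    """Delimit the V domain and label its hairpins L7-L13.

    With ``anchors`` (5' and 3' flanking motifs), the region is the interval
    between the best ungapped hits with at most 2 mismatches each; otherwise,
    or when a motif does not match, the 3' half of the sequence is used.
    Hairpins inside the region are labelled against ``reference`` (default:
    the packaged template); hairpins with no acceptable match are flagged
    unassigned.
    """
    seq = structure.record.residues
    n = len(seq)
    region = (n // 2, n)
    if anchors is not None:
        a5, a3 = anchors
        h5 = _best_motif_hit(seq, a5.upper().replace("T", "U"))
        h3 = _best_motif_hit(seq, a3.upper().replace("T", "U"))
        if h5 is not None and h3 is not None and h5[0] + len(a5) <= h3[0]:
            region = (h5[0] + len(a5), h3[0])
        else:
            logger.warning("anchor motifs not found within 2 mismatches; using 3' half")
    if n < 2 * (3 + 2) and anchors is None:
        raise ValueError("sequence too short to delimit a V domain without anchors")

    loops = [
        sl for sl in extract_stemloops(structure)
        if region[0] <= sl.closing_pair[0] and sl.closing_pair[1] < region[1]
    ]
    if not loops:
        logger.warning("no hairpins found in the V-domain region %s", region)
        return VDomain(structure, region, (), ())
    if reference is None:
        reference = load_reference_template()
    labelled, unassigned = assign_loop_labels(
        loops, reference, query_origin=region[0], max_offset=max_offset
    )
    return VDomain(structure, region, tuple(labelled), tuple(unassigned))


def assign_loop_labels(
    stem_loops: list[StemLoop],
    reference: VDomain,
    query_origin: int | None = None,
    max_offset: float = 40.0,
) -> tuple[list[StemLoop], list[StemLoop]]:
    """Label query hairpins by order-preserving matching to a reference.

    Dynamic programme over the two ordered hairpin lists that first maximises
    the number of matches and then minimises the total |midpoint offset|
    (midpoints taken relative to the respective region starts); matches with
    offset above ``max_offset`` are disallowed, and each reference label is
    used at most once.  Returns (labelled, unassigned), both 5'->3'.
    """
    if not reference.stem_loops:
        raise ValueError("empty reference template")
    if not stem_loops:
        return [], []
    q_origin = query_origin if query_origin is not None else min(sl.closing_pair[0] for sl in stem_loops)
    r_origin = reference.region[0]
    q = sorted(stem_loops, key=lambda sl: sl.closing_pair[0])
    r = list(reference.stem_loops)
    qpos = [sl.midpoint - q_origin for sl in q]
    rpos = [sl.midpoint - r_origin for sl in r]

    NO = (0, 0.0)  # (-matches, offset) accumulates; we minimise lexicographically
    nq, nr = len(q), len(r)
    best: list[list[tuple[int, float]]] = [[(0, 0.0)] * (nr + 1) for _ in range(nq + 1)]
    back: list[list[str]] = [[""] * (nr + 1) for _ in range(nq + 1)]
    for qi in range(nq + 1):
        for ri in range(nr + 1):
            if qi == 0 and ri == 0:
                continue
            cands: list[tuple[tuple[int, float], str]] = []
            if qi > 0:
                m, o = best[qi - 1][ri]
                cands.append(((m, o), "q"))  # query hairpin unassigned
            if ri > 0:
                m, o = best[qi][ri - 1]
                cands.append(((m, o), "r"))  # reference label unused
            if qi > 0 and ri > 0:
                off = abs(qpos[qi - 1] - rpos[ri - 1])
                if off <= max_offset:
                    m, o = best[qi - 1][ri - 1]
                    cands.append(((m - 1, o + off), "m"))
            chosen = min(cands)
            best[qi][ri], back[qi][ri] = chosen

    labelled: list[StemLoop] = []
    unassigned: list[StemLoop] = []
    qi, ri = nq, nr
    while qi > 0 or ri > 0:
        move = back[qi][ri]
        if move == "m":
            labelled.append(replace(q[qi - 1], label=r[ri - 1].label))
            qi, ri = qi - 1, ri - 1
        elif move == "q":
            unassigned.append(q[qi - 1])
            qi -= 1
        else:
            ri -= 1
    labelled.reverse()
    unassigned.reverse()
    return labelled, unassigned


# ---------------------------------------------------------------------------
# packaged reference template


def load_reference_template(path: str | Path | None = None) -> VDomain:
    """Load the packaged labelled V-domain template (or a user-supplied one).

    The packaged template is a synthetic, hand-designed 16S 3'-half structure
    whose seven hairpins are tagged L7-L13 in 5'->3' order following the
    molluscan nomenclature; its exact spans are an editorial choice, not
    empirical data.  A user template uses the same JSON layout.
    """
    if path is None:
        path = resources.files("rna2dbarcode").joinpath("data/reference_template.synthetic.json")
    raw = json.loads(Path(path).read_text())
    rec = SequenceRecord(id=raw.get("id", "reference"), residues=raw["sequence"])
    model = load_default_model()
    pt = PairTable.from_dotbracket(raw["structure"], min_loop=model.min_loop)
    energy = structure_energy(rec.residues, list(pt.partner), model)
    structure = SecondaryStructure(rec, pt, energy)
    region = tuple(raw["region"])
    loops = [
        sl for sl in extract_stemloops(structure)
        if region[0] <= sl.closing_pair[0] and sl.closing_pair[1] < region[1]
    ]
    labels = raw.get("labels", list(V_DOMAIN_LABELS))
    if len(loops) != len(labels):
        raise ValueError(
            f"template declares {len(labels)} labels but its region folds into {len(loops)} hairpins"
        )
    labelled = tuple(replace(sl, label=lb) for sl, lb in zip(loops, labels))
    return VDomain(structure, region, labelled, ())


def template_anchors(path: str | Path | None = None) -> tuple[str, str]:
    """The template's conserved flanking motifs (5', 3')."""
    if path is None:
        path = resources.files("rna2dbarcode").joinpath("data/reference_template.synthetic.json")
    raw = json.loads(Path(path).read_text())
    return raw["anchor5"], raw["anchor3"]


def stemloop_table(structures: dict[str, VDomain]):
    """Per-hairpin report rows: id, label, 1-based span, composition, sequences."""
    import pandas as pd

    rows = []
    for sid, vd in structures.items():
        for sl in vd.stem_loops:
            i, j = sl.closing_pair
            rows.append(
                {
                    "structure_id": sid,
                    "label": sl.label,
                    "start": i + 1,
                    "end": j + 1,
                    "stem_bp": sl.stem_bp,
                    "loop_nt": sl.loop_nt,
                    "bulge_nt": sl.bulge_nt,
                    "total_nt": sl.total_nt,
                    "loop_seq": sl.loop_sequence,
                    "dotbracket": sl.dotbracket,
                }
            )
    return pd.DataFrame(rows)
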