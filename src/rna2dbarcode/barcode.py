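"""Cross-taxon comparison of homologous stem-loops.

The comparative layer of the package: structure-aware alignment of one
labelled stem-loop across taxa, per-loop divergence ranking, compensatory
base change (CBC / semi-CBC) detection, classification of alignment columns
into genus landmarks / diagnostic positions / variable sites, majority-rule
consensus structures, and the machine- and human-readable reports that a
taxonomist reads to delimit taxa.

Stems are aligned by pairing rank (outermost pair to outermost pair, shorter
stems occupying the inner ranks), loops by a global sequence alignment
(match +1, mismatch 0, gap -1, ties resolved to the 5'-most gap placement),
bulges by left-justified blocks keyed to the stem rank they interrupt.  A
column is therefore structurally homologous by construction, which is what
makes CBC bookkeeping at aligned stem ranks meaningful.
"""

from __future__ import annotations

import itertools
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .energy import CANONICAL_PAIRS, load_default_model, structure_energy
from .fold import PairTable, SecondaryStructure, UNPAIRED
from .io import SequenceRecord
from .stemloops import StemLoop, VDomain

__all__ = [
    "CladePartition",
    "StemLoopAlignment",
    "ColumnClassification",
    "CBCRecord",
    "CBCScan",
    "align_stemloops",
    "rank_variability",
    "detect_cbc",
    "classify_columns",
    "consensus_structure",
    "consensus_from_alignment",
    "basepair_distance",
    "barcode_report",
]

GAP = "-"
_BASES = set("ACGU")

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("U"): "U",
    frozenset("AG"): "R", frozenset("CU"): "Y", frozenset("CG"): "S", frozenset("AU"): "W",
    frozenset("GU"): "K", frozenset("AC"): "M", frozenset("CGU"): "B", frozenset("AGU"): "D",
    frozenset("ACU"): "H", frozenset("ACG"): "V", frozenset("ACGU"): "N",
}


# ---------------------------------------------------------------------------
# partitions


@dataclass(frozen=True)
class CladePartition:
    """Taxon -> group assignment at a chosen rank (genus or species)."""

    rank: str
    groups: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if self.rank not in ("genus", "species"):
            raise ValueError(f"rank must be 'genus' or 'species', got {self.rank!r}")
        if not self.groups:
            raise ValueError("partition has no groups")
        seen: set[str] = set()
        for label, members in self.groups.items():
            if not members:
                raise ValueError(f"group {label!r} is empty")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"taxa in more than one group: {sorted(overlap)}")
            seen |= set(members)

    def group_of(self, taxon: str) -> str:
        for label, members in self.groups.items():
            if taxon in members:
                return label
        raise KeyError(f"taxon {taxon!r} missing from the partition")

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(t for members in self.groups.values() for t in members)

    @classmethod
    def from_records(cls, records: list[SequenceRecord], rank: str = "genus") -> "CladePartition":
        """Group record ids by genus (first word) or species binomial."""
        groups: dict[str, set[str]] = {}
        for rec in records:
            key = rec.genus if rank == "genus" else " ".join(rec.taxon.split()[:2])
            if not key:
                raise ValueError(f"record {rec.id!r} lacks taxon metadata for rank {rank!r}")
            groups.setdefault(key, set()).add(rec.id)
        return cls(rank, {k: frozenset(v) for k, v in groups.items()})

    @classmethod
    def from_tsv(cls, path: str | Path, rank: str = "genus") -> "CladePartition":
        """Two-column TSV: taxon id <tab> group label (no header)."""
        groups: dict[str, set[str]] = {}
        for ln in Path(path).read_text().splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            taxon, group = ln.split("\t")[:2]
            groups.setdefault(group.strip(), set()).add(taxon.strip())
        return cls(rank, {k: frozenset(v) for k, v in groups.items()})

    @classmethod
    def from_newick(cls, path: str | Path, rank: str = "genus") -> "CladePartition":
        """Partition the leaves of a guide tree by name at the given rank."""
        import dendropy

        tree = dendropy.Tree.get(path=str(path), schema="newick")
        groups: dict[str, set[str]] = {}
        for leaf in tree.leaf_node_iter():
            name = (leaf.taxon.label if leaf.taxon else "").replace("_", " ")
            if not name:
                continue
            key = name.split()[0] if rank == "genus" else " ".join(name.split()[:2])
            groups.setdefault(key, set()).add(name.replace(" ", "_"))
        if not groups:
            raise ValueError(f"no labelled leaves in {path}")
        return cls(rank, {k: frozenset(v) for k, v in groups.items()})


# ---------------------------------------------------------------------------
# stem-loop alignment


@dataclass(frozen=True)
class StemLoopAlignment:
    """Column-matched homologous stem-loops across taxa."""

    label: str
    rows: dict[str, str]  # taxon id -> gapped sequence
    pairing_mask: tuple[str, ...]  # per column: stem/loop/bulge/mixed
    stem_rank_columns: tuple[tuple[int, int], ...]  # (5' col, 3' col) outer->inner
    source_loops: dict[str, StemLoop] = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        if lengths and lengths.pop() != len(self.pairing_mask):
            raise ValueError("pairing mask length differs from row length")

    @property
    def columns(self) -> int:
        return len(self.pairing_mask)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.rows)

    def column(self, c: int) -> dict[str, str]:
        return {t: self.rows[t][c] for t in self.rows}

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for taxon in self.taxa:
                fh.write(f">{taxon}\n{self.rows[taxon]}\n")


def _nw_loop(a: str, b: str) -> tuple[str, str]:
    """Global alignment, match +1 / mismatch 0 / gap -1, 5'-most gaps on ties."""
    n, m = len(a), len(b)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        S[i][0] = -i
    for j in range(1, m + 1):
        S[0][j] = -j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            S[i][j] = max(
                S[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else 0),
                S[i - 1][j] - 1,
                S[i][j - 1] - 1,
            )
    # traceback from the end, preferring diagonal, which defers gaps to the 5' end
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and S[i][j] == S[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else 0):
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and S[i][j] == S[i - 1][j] - 1:
            out_a.append(a[i - 1]); out_b.append(GAP); i -= 1
        else:
            out_a.append(GAP); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _star_align(seqs: dict[str, str]) -> dict[str, str]:
    """Centre-star multiple alignment around the longest sequence."""
    if not seqs:
        return {}
    lengths = {t: len(s) for t, s in seqs.items()}
    if len(set(lengths.values())) == 1:
        return dict(seqs)
    center = max(sorted(seqs), key=lambda t: lengths[t])
    cseq = seqs[center]
    pairwise: dict[str, tuple[str, str]] = {}
    ins_before: list[int] = [0] * (len(cseq) + 1)  # insertions before centre position k
    for t, s in seqs.items():
        if t == center:
            continue
        ac, at = _nw_loop(cseq, s)
        pairwise[t] = (ac, at)
        k = 0
        run = 0
        for ch in ac:
            if ch == GAP:
                run += 1
            else:
                ins_before[k] = max(ins_before[k], run)
                run = 0
                k += 1
        ins_before[len(cseq)] = max(ins_before[len(cseq)], run)

    def place(ac: str, at: str) -> str:
        out: list[str] = []
        k = 0
        buf: list[str] = []
        for cc, tc in zip(ac, at):
            if cc == GAP:
                buf.append(tc)
            else:
                out.append(GAP * (ins_before[k] - len(buf)) + "".join(buf))
                buf = []
                out.append(tc)
                k += 1
        out.append(GAP * (ins_before[len(cseq)] - len(buf)) + "".join(buf))
        return "".join(out)

    rows = {center: place(cseq, cseq)}
    for t in seqs:
        if t != center:
            rows[t] = place(*pairwise[t])
    return rows


def align_stemloops(stem_loops: dict[str, StemLoop]) -> StemLoopAlignment:
    """Structure-aware alignment of one labelled stem-loop across taxa.

    Stems are matched by pairing rank with shorter stems at the inner ranks,
    loops by sequence alignment, bulge runs by left-justified blocks keyed to
    the stem rank they interrupt.  Requires >= 2 taxa sharing one label.
    """
    if len(stem_loops) < 2:
        raise ValueError("alignment needs at least 2 taxa")
    labels = {sl.label for sl in stem_loops.values()}
    if len(labels) != 1:
        raise ValueError(f"stem-loops carry different labels: {sorted(map(str, labels))}")
    label = labels.pop() or ""

    taxa = sorted(stem_loops)
    max_stem = max(sl.stem_bp for sl in stem_loops.values())
    offsets = {t: max_stem - stem_loops[t].stem_bp for t in taxa}
    info = {t: stem_loops[t].positions() for t in taxa}
    seqs = {t: stem_loops[t]._seq() for t in taxa}

    # bulge blocks: (global rank, side) -> width
    bulge_width: dict[tuple[int, str], int] = {}
    for t in taxa:
        for (rank, side), (s, e) in info[t]["bulges"].items():
            key = (rank + offsets[t], side)
            bulge_width[key] = max(bulge_width.get(key, 0), e - s)

    loop_rows = _star_align({t: stem_loops[t].loop_sequence for t in taxa})
    loop_cols = len(next(iter(loop_rows.values()))) if loop_rows else 0

    cols: list[tuple[str, object]] = []  # (kind, key)
    for r in range(max_stem):
        cols.append(("stem5", r))
        for side in ("5p",):
            if (r, side) in bulge_width:
                cols.append(("bulge", (r, side)))
    for c in range(loop_cols):
        cols.append(("loop", c))
    for r in range(max_stem - 1, -1, -1):
        if (r, "3p") in bulge_width:
            cols.append(("bulge", (r, "3p")))
        cols.append(("stem3", r))

    rows: dict[str, list[str]] = {t: [] for t in taxa}
    rank_cols: dict[int, list[int]] = {}
    mask: list[str] = []
    offset = 0  # next column index in the final alignment
    for kind, key in cols:
        if kind in ("stem5", "stem3"):
            rank = int(key)  # global rank
            rank_cols.setdefault(rank, [None, None])
            rank_cols[rank][0 if kind == "stem5" else 1] = offset
            offset += 1
            for t in taxa:
                local = rank - offsets[t]
                pairs = info[t]["stem"]
                if 0 <= local < len(pairs):
                    i, j = pairs[local]
                    rows[t].append(seqs[t][i if kind == "stem5" else j])
                else:
                    rows[t].append(GAP)
            mask.append("stem")
        elif kind == "loop":
            offset += 1
            for t in taxa:
                rows[t].append(loop_rows[t][int(key)])
            mask.append("loop")
        else:  # bulge block, left-justified
            grank, side = key
            width = bulge_width[(grank, side)]
            offset += width
            for t in taxa:
                local = grank - offsets[t]
                span = info[t]["bulges"].get((local, side))
                chunk = seqs[t][span[0] : span[1]] if span else ""
                rows[t].append(chunk.ljust(width, GAP))
            mask.extend(["bulge"] * width)

    joined = {t: "".join(rows[t]) for t in taxa}
    # expand bulge blocks into per-column mask already done above; rebuild column count
    ncol = len(next(iter(joined.values())))
    if len(mask) != ncol:
        raise AssertionError("column bookkeeping out of step")
    stem_rank_columns = tuple(
        (rank_cols[r][0], rank_cols[r][1]) for r in range(max_stem)
    )
    return StemLoopAlignment(
        label=label,
        rows=joined,
        pairing_mask=tuple(mask),
        stem_rank_columns=stem_rank_columns,
        source_loops=dict(stem_loops),
    )


# ---------------------------------------------------------------------------
# variability ranking


def rank_variability(alignments: dict[str, StemLoopAlignment]) -> list[tuple[str, float]]:
    """Order stem-loop labels by mean per-column Shannon entropy, descending.

    Columns containing gaps contribute the entropy of their non-gap states
    weighted by the non-gap fraction.  Ties break toward the lower L-number.
    """
    if not alignments:
        raise ValueError("no alignments to rank")
    scored = []
    for label, aln in alignments.items():
        total = 0.0
        for c in range(aln.columns):
            states = [aln.rows[t][c] for t in aln.taxa]
            non_gap = [s for s in states if s != GAP]
            if not non_gap:
                continue
            counts = Counter(non_gap)
            h = -sum((k / len(non_gap)) * math.log2(k / len(non_gap)) for k in counts.values())
            total += (len(non_gap) / len(states)) * h
        scored.append((label, total / aln.columns if aln.columns else 0.0))

    def sort_key(item):
        label, score = item
        num = int(label[1:]) if label[1:].isdigit() else 0
        return (-score, num, label)

    return sorted(scored, key=sort_key)


# ---------------------------------------------------------------------------
# CBC detection


@dataclass(frozen=True)
class CBCRecord:
    """One taxon-pair comparison at one aligned stem rank."""

    taxon_pair: tuple[str, str]
    rank: int
    columns: tuple[int, int]
    states: tuple[str, str]  # e.g. ("GC", "AU")
    type: str  # CBC / semiCBC / pair_broken / none


@dataclass(frozen=True)
class CBCScan:
    records: tuple[CBCRecord, ...]
    skipped_gapped: int

    def of_type(self, kind: str) -> list[CBCRecord]:
        return [r for r in self.records if r.type == kind]

    @property
    def n_cbc(self) -> int:
        return len(self.of_type("CBC"))

    @property
    def n_semicbc(self) -> int:
        return len(self.of_type("semiCBC"))


def classify_pair_change(p1: str, p2: str) -> str:
    """CBC bookkeeping for two states of one aligned pair (wobble G.U allowed)."""
    if p1 == p2:
        return "none"
    changed = (p1[0] != p2[0]) + (p1[1] != p2[1])
    if p1 in CANONICAL_PAIRS and p2 in CANONICAL_PAIRS:
        return "CBC" if changed == 2 else "semiCBC"
    return "pair_broken"


def detect_cbc(
    alignment: StemLoopAlignment,
    structures: dict[str, SecondaryStructure] | None = None,
) -> CBCScan:
    """Scan every taxon pair at every aligned stem rank for CBC / semi-CBC.

    Rank columns with a gap in either taxon are skipped and counted.  With
    ``structures`` given, each row is checked against the stem-loop of its
    folded structure (length mismatch raises).
    """
    if structures is not None:
        for taxon, sl in alignment.source_loops.items():
            st = structures.get(taxon)
            if st is None:
                continue
            degapped = alignment.rows[taxon].replace(GAP, "")
            i, j = sl.closing_pair
            if st.record.residues[i : j + 1] != degapped:
                raise ValueError(f"alignment row for {taxon!r} does not match its structure")
    records: list[CBCRecord] = []
    skipped = 0
    for t1, t2 in itertools.combinations(alignment.taxa, 2):
        for rank, (c5, c3) in enumerate(alignment.stem_rank_columns):
            s1 = alignment.rows[t1][c5] + alignment.rows[t1][c3]
            s2 = alignment.rows[t2][c5] + alignment.rows[t2][c3]
            if GAP in s1 or GAP in s2:
                skipped += 1
                continue
            records.append(
                CBCRecord(
                    taxon_pair=(t1, t2),
                    rank=rank,
                    columns=(c5, c3),
                    states=(s1, s2),
                    type=classify_pair_change(s1, s2),
                )
            )
    return CBCScan(tuple(records), skipped)


# ---------------------------------------------------------------------------
# column classification


@dataclass(frozen=True)
class ColumnClassification:
    """Per-column verdicts over a stem-loop alignment under a partition."""

    verdicts: tuple[str, ...]  # landmark/diagnostic/variable/gapped/ambiguous
    group_states: tuple[dict[str, str], ...]  # per column: group -> modal state(s)
    counts: dict[str, int]

    def positions(self, verdict: str) -> list[int]:
        return [c for c, v in enumerate(self.verdicts) if v == verdict]


def classify_columns(
    alignment: StemLoopAlignment,
    partition: CladePartition,
    fixation_threshold: float = 1.0,
) -> ColumnClassification:
    """Classify every column as landmark / diagnostic / variable / gapped / ambiguous.

    A *landmark* column shows a single state clade-wide; a *diagnostic* column
    is fixed within every group with at least two groups differing; anything
    else polymorphic is *variable*.  Columns with any gap, or any non-ACGU
    code, are set aside as gapped / ambiguous and excluded from the biological
    verdicts.  ``fixation_threshold`` < 1 relaxes within-group fixation to a
    modal-state frequency (off by default: the strict reading).
    """
    if len(partition.groups) < 2:
        raise ValueError("diagnostic classification needs >= 2 groups")
    for taxon in alignment.taxa:
        partition.group_of(taxon)  # raises if missing

    verdicts: list[str] = []
    per_col_states: list[dict[str, str]] = []
    for c in range(alignment.columns):
        column = {t: alignment.rows[t][c] for t in alignment.taxa}
        states = list(column.values())
        if GAP in states:
            verdicts.append("gapped")
            per_col_states.append({})
            continue
        if any(s not in _BASES for s in states):
            verdicts.append("ambiguous")
            per_col_states.append({})
            continue
        group_modal: dict[str, str] = {}
        all_fixed = True
        for gname, members in partition.groups.items():
            got = [column[t] for t in alignment.taxa if t in members]
            if not got:
                continue
            counts = Counter(got)
            modal, n_modal = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            group_modal[gname] = modal
            if n_modal / len(got) < fixation_threshold:
                all_fixed = False
        per_col_states.append(group_modal)
        if len(set(states)) == 1:
            verdicts.append("landmark")
        elif all_fixed and len(set(group_modal.values())) >= 2:
            verdicts.append("diagnostic")
        else:
            verdicts.append("variable")
    counts = dict(Counter(verdicts))
    for k in ("landmark", "diagnostic", "variable", "gapped", "ambiguous"):
        counts.setdefault(k, 0)
    return ColumnClassification(tuple(verdicts), tuple(per_col_states), counts)


# ---------------------------------------------------------------------------
# consensus and structure distance


def consensus_structure(structures: list[SecondaryStructure]) -> SecondaryStructure:
    """Majority-rule consensus of structures on common coordinates.

    A pair is kept when present (same (i, j)) in a strict majority; the
    consensus sequence takes the majority state per position with IUPAC
    degeneracy on ties.  Non-nested majority pairs raise with the conflict.
    """
    if len(structures) < 2:
        raise ValueError("consensus needs >= 2 structures")
    n = structures[0].n
    if any(s.n != n for s in structures):
        raise ValueError("structures are not on common coordinates (length mismatch)")
    pair_counts = Counter(p for s in structures for p in s.pairs.pairs())
    kept = sorted(p for p, k in pair_counts.items() if k * 2 > len(structures))
    partner = [UNPAIRED] * n
    opened: list[tuple[int, int]] = []
    for i, j in kept:
        while opened and opened[-1][1] < i:
            opened.pop()
        if opened and not (opened[-1][0] < i and j < opened[-1][1]):
            raise ValueError(f"conflicting majority pairs {opened[-1]} and ({i},{j}) are not nested")
        if partner[i] != UNPAIRED or partner[j] != UNPAIRED:
            raise ValueError(f"conflicting majority pairs at position {i} or {j}")
        partner[i], partner[j] = j, i
        opened.append((i, j))
    seq_chars = []
    for c in range(n):
        counts = Counter(s.record.residues[c] for s in structures)
        top = max(counts.values())
        winners = frozenset(b for b, k in counts.items() if k == top)
        seq_chars.append(_IUPAC.get(winners, "N") if len(winners) > 1 else next(iter(winners)))
    seq = "".join(seq_chars)
    rec = SequenceRecord(id="consensus", residues=seq)
    pt = PairTable(tuple(partner))
    model = load_default_model()
    try:
        energy = structure_energy(seq, partner, model)
    except ValueError:  # degenerate states in a stem: energy undefined
        energy = float("nan")
    return SecondaryStructure(rec, pt, energy)


def consensus_from_alignment(alignment: StemLoopAlignment, taxa: list[str] | None = None):
    """Consensus stem-loop over (a subset of) an alignment's rows.

    Returns (consensus sequence with IUPAC degeneracy, consensus dot-bracket)
    in column space; pairs kept at ranks present in a strict majority.
    Columns gapped in a majority of rows are dropped.
    """
    taxa = sorted(taxa) if taxa is not None else alignment.taxa
    if len(taxa) < 2:
        raise ValueError("consensus needs >= 2 rows")
    nrow = len(taxa)
    keep_rank = {
        r
        for r, (c5, c3) in enumerate(alignment.stem_rank_columns)
        if sum(alignment.rows[t][c5] != GAP for t in taxa) * 2 > nrow
    }
    keep_col = [
        c
        for c in range(alignment.columns)
        if sum(alignment.rows[t][c] != GAP for t in taxa) * 2 > nrow
    ]
    colmap = {c: k for k, c in enumerate(keep_col)}
    db = ["."] * len(keep_col)
    for r in keep_rank:
        c5, c3 = alignment.stem_rank_columns[r]
        if c5 in colmap and c3 in colmap:
            db[colmap[c5]], db[colmap[c3]] = "(", ")"
    seq = []
    for c in keep_col:
        counts = Counter(alignment.rows[t][c] for t in taxa if alignment.rows[t][c] != GAP)
        top = max(counts.values())
        winners = frozenset(b for b, k in counts.items() if k == top)
        seq.append(_IUPAC.get(winners, "N") if len(winners) > 1 else next(iter(winners)))
    return "".join(seq), "".join(db)


def basepair_distance(s1: SecondaryStructure, s2: SecondaryStructure) -> int:
    """Size of the symmetric difference of the two pair sets (a metric)."""
    if s1.n != s2.n:
        raise ValueError("structures are not on common coordinates (length mismatch)")
    return len(set(s1.pairs.pairs()) ^ set(s2.pairs.pairs()))


# ---------------------------------------------------------------------------
# the barcode report


def barcode_report(
    v_domains: dict[str, VDomain],
    partition: CladePartition | None,
    chosen_label: str = "auto",
) -> dict:
    """Assemble the 2D-barcoding report for a clade.

    Folds are taken as given (``v_domains`` maps taxon id to its labelled V
    domain).  The report carries, per taxon, the chosen stem-loop's sequence,
    structure and composition; and per clade, the variability ranking over
    all shared labels, the column classification under ``partition``, the CBC
    table, pairwise base-pair distances in aligned-column space, per-group
    consensus stem-loops, and within-species structural variability.
    Returns a JSON-serialisable dict (see also :func:`report_markdown`).
    """
    if not v_domains:
        raise ValueError("no folded V domains supplied")

    by_label: dict[str, dict[str, StemLoop]] = {}
    for taxon, vd in v_domains.items():
        for sl in vd.stem_loops:
            by_label.setdefault(sl.label, {})[taxon] = sl
    alignments = {
        lb: align_stemloops(loops) for lb, loops in sorted(by_label.items()) if len(loops) >= 2
    }
    if not alignments:
        raise ValueError("no stem-loop label is shared by >= 2 taxa")
    ranking = rank_variability(alignments)
    label = ranking[0][0] if chosen_label == "auto" else chosen_label
    if label not in alignments:
        raise ValueError(f"chosen stem-loop {label!r} is not shared by >= 2 taxa")
    aln = alignments[label]

    missing = sorted(t for t in v_domains if t not in by_label.get(label, {}))
    per_taxon = {}
    for taxon in aln.taxa:
        sl = by_label[label][taxon]
        per_taxon[taxon] = {
            "sequence": sl.sequence,
            "dotbracket": sl.dotbracket,
            "stem_bp": sl.stem_bp,
            "loop_nt": sl.loop_nt,
            "bulge_nt": sl.bulge_nt,
            "total_nt": sl.total_nt,
            "span_1based": [sl.closing_pair[0] + 1, sl.closing_pair[1] + 1],
        }

    classification = None
    if partition is not None:
        cls = classify_columns(aln, partition)
        classification = {
            "rank": partition.rank,
            "verdicts": list(cls.verdicts),
            "counts": cls.counts,
            "loop_column_verdicts": {
                "landmark": [c for c in cls.positions("landmark") if aln.pairing_mask[c] == "loop"],
                "diagnostic": [c for c in cls.positions("diagnostic") if aln.pairing_mask[c] == "loop"],
                "variable": [c for c in cls.positions("variable") if aln.pairing_mask[c] == "loop"],
            },
        }

    scan = detect_cbc(aln)
    group_of = partition.group_of if partition is not None else (lambda t: "all")
    cbc_rows = [
        {
            "taxa": list(r.taxon_pair),
            "within_group": group_of(r.taxon_pair[0]) == group_of(r.taxon_pair[1]),
            "rank": r.rank,
            "columns": list(r.columns),
            "states": list(r.states),
            "type": r.type,
        }
        for r in scan.records
        if r.type != "none"
    ]

    # pairwise base-pair distance in aligned-column space
    pair_sets = {}
    for taxon in aln.taxa:
        present = set()
        off = len(aln.stem_rank_columns) - by_label[label][taxon].stem_bp
        for r, cols in enumerate(aln.stem_rank_columns):
            if r >= off:
                present.add(cols)
        pair_sets[taxon] = present
    distances = {
        f"{t1}|{t2}": len(pair_sets[t1] ^ pair_sets[t2])
        for t1, t2 in itertools.combinations(aln.taxa, 2)
    }

    consensus = {}
    if partition is not None:
        for gname, members in sorted(partition.groups.items()):
            rows = [t for t in aln.taxa if t in members]
            if len(rows) >= 2:
                cseq, cdb = consensus_from_alignment(aln, rows)
                consensus[gname] = {"sequence": cseq, "dotbracket": cdb}

    by_species: dict[str, set[str]] = {}
    for taxon, vd in v_domains.items():
        sp = vd.source.record.taxon or taxon
        sl = by_label.get(label, {}).get(taxon)
        if sl is not None:
            by_species.setdefault(sp, set()).add(sl.dotbracket)
    within_species = {
        sp: {"n_structures": len(dbs), "invariant": len(dbs) == 1}
        for sp, dbs in sorted(by_species.items())
    }

    return {
        "schema_version": "1.0",
        "chosen_label": label,
        "chosen_by": "variability_ranking" if chosen_label == "auto" else "user",
        "variability_ranking": [{"label": lb, "score": round(s, 6)} for lb, s in ranking],
        "alignment": {"columns": aln.columns, "pairing_mask": list(aln.pairing_mask),
                      "rows": {t: aln.rows[t] for t in aln.taxa}},
        "per_taxon": per_taxon,
        "missing_taxa": missing,
        "classification": classification,
        "cbc": {
            "records": cbc_rows,
            "n_cbc": scan.n_cbc,
            "n_semicbc": scan.n_semicbc,
            "skipped_gapped": scan.skipped_gapped,
        },
        "basepair_distances": distances,
        "group_consensus": consensus,
        "within_species_structures": within_species,
    }


def report_markdown(report: dict) -> str:
    """Human-readable summary of a :func:`barcode_report` result."""
    lines = [
        f"# 2D RNA barcode report (schema {report['schema_version']})",
        "",
        f"Chosen stem-loop: **{report['chosen_label']}** ({report['chosen_by']})",
        "",
        "## Variability ranking",
        "",
        "| label | mean column entropy (bits) |",
        "|---|---|",
    ]
    for item in report["variability_ranking"]:
        lines.append(f"| {item['label']} | {item['score']:.4f} |")
    lines += ["", "## Per-taxon stem-loop", "", "| taxon | sequence | structure | stem bp | loop nt | total nt |", "|---|---|---|---|---|---|"]
    for taxon, row in sorted(report["per_taxon"].items()):
        lines.append(
            f"| {taxon} | `{row['sequence']}` | `{row['dotbracket']}` | "
            f"{row['stem_bp']} | {row['loop_nt']} | {row['total_nt']} |"
        )
    if report["classification"] is not None:
        cts = report["classification"]["counts"]
        lines += [
            "",
            f"## Column classification (rank: {report['classification']['rank']})",
            "",
            f"- landmark (clade-wide conserved): {cts['landmark']}",
            f"- diagnostic (fixed within groups, differing between): {cts['diagnostic']}",
            f"- variable: {cts['variable']}",
            f"- gapped: {cts['gapped']}, ambiguous: {cts['ambiguous']}",
        ]
    cbc = report["cbc"]
    lines += ["", "## Compensatory base changes", "",
              f"- CBC: {cbc['n_cbc']}, semi-CBC: {cbc['n_semicbc']} "
              f"(gapped rank comparisons skipped: {cbc['skipped_gapped']})"]
    inv = report["within_species_structures"]
    if inv:
        bad = [sp for sp, row in inv.items() if not row["invariant"]]
        lines += ["", "## Within-species folding variability", ""]
        if bad:
            lines.append(f"- species with >1 structure: {', '.join(bad)}")
        else:
            lines.append("- no within-species structural variability detected")
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write the JSON report, Markdown summary, alignment FASTA and CBC TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out / "barcode_report.json",
        "markdown": out / "barcode_report.md",
        "alignment": out / f"{report['chosen_label']}_alignment.fasta",
        "cbc": out / "cbc_table.tsv",
    }
    paths["json"].write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    paths["markdown"].write_text(report_markdown(report))
    with open(paths["alignment"], "w") as fh:
        for taxon, row in sorted(report["alignment"]["rows"].items()):
            fh.write(f">{taxon}\n{row}\n")
    with open(paths["cbc"], "w") as fh:
        fh.write("taxon1\ttaxon2\twithin_group\trank\tcol5\tcol3\tstates\ttype\n")
        for r in report["cbc"]["records"]:
            fh.write(
                f"{r['taxa'][0]}\t{r['taxa'][1]}\t{r['within_group']}\t{r['rank']}\t"
                f"{r['columns'][0]}\t{r['columns'][1]}\t{r['states'][0]}>{r['states'][1]}\t{r['type']}\n"
            )
    return paths
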