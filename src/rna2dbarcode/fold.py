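"""Nested RNA secondary-structure prediction.

Three routes to a structure, in decreasing rigour and increasing reach:

* :func:`enumerate_structures` — every valid nested structure of a short
  sequence, scored explicitly.  Exponential; the ground-truth oracle.
* :func:`fold_maxpair` — Nussinov base-pair maximisation.  A second,
  model-free oracle whose optimum is easy to verify by enumeration.
* :func:`fold_mfe` — minimum free energy under the packaged nearest-neighbour
  model (stacking + loop penalties + flat multibranch cost), the production
  folding route.  O(n^3) dynamic programme with the interior-loop span capped,
  vectorised over the diagonal so that V-domain-sized inputs (~150-400 nt)
  fold in about a second.

Coordinates are 0-based half-open internally; reports are 1-based inclusive.
Ambiguity codes never pair.  Ties are broken by a fixed traceback preference
(pairing before skipping, 5'-most and most-stacked decompositions first), so
refolding is bit-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .energy import EnergyModel, load_default_model, structure_energy
from .io import SequenceRecord

__all__ = [
    "PairTable",
    "SecondaryStructure",
    "Constraints",
    "fold_mfe",
    "fold_maxpair",
    "enumerate_structures",
    "read_dotbracket",
    "write_dotbracket",
]

UNPAIRED = -1
_INF = 1e9
_BASES = "ACGU"


# ---------------------------------------------------------------------------
# pair table / structure containers


@dataclass(frozen=True)
class PairTable:
    """Nested pairing of a sequence: ``partner[i] == j`` iff (i, j) pair."""

    partner: tuple[int, ...]
    min_loop: int = 3

    def __post_init__(self) -> None:
        n = len(self.partner)
        stack: list[int] = []
        for i, j in enumerate(self.partner):
            if j == UNPAIRED:
                continue
            if j == i:
                raise ValueError(f"position {i} paired with itself")
            if not 0 <= j < n or self.partner[j] != i:
                raise ValueError(f"pair table not symmetric at position {i}")
            if j > i:
                if j - i - 1 < self.min_loop:
                    raise ValueError(f"pair ({i},{j}) closes a loop shorter than {self.min_loop}")
                stack.append(j)
            else:  # closing side: must match the innermost open pair
                if not stack or stack[-1] != i:
                    raise ValueError(f"pairs are not nested at position {i}")
                stack.pop()

    @property
    def n(self) -> int:
        return len(self.partner)

    def pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in enumerate(self.partner) if j > i]

    def to_dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self.partner):
            out.append("." if j == UNPAIRED else ("(" if j > i else ")"))
        return "".join(out)

    @classmethod
    def from_dotbracket(cls, db: str, min_loop: int = 3) -> "PairTable":
        partner = [UNPAIRED] * len(db)
        stack: list[int] = []
        for i, ch in enumerate(db):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {i}")
                j = stack.pop()
                partner[i], partner[j] = j, i
            elif ch != ".":
                raise ValueError(f"invalid dot-bracket character {ch!r} at position {i}")
        if stack:
            raise ValueError(f"unbalanced '(' at position {stack[-1]}")
        return cls(tuple(partner), min_loop=min_loop)


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence, its nested pairing and the energy of that pairing."""

    record: SequenceRecord
    pairs: PairTable
    energy: float

    def __post_init__(self) -> None:
        if self.pairs.n != len(self.record.residues):
            raise ValueError("pair table length does not match sequence length")

    @property
    def dotbracket(self) -> str:
        return self.pairs.to_dotbracket()

    @property
    def n(self) -> int:
        return self.pairs.n


@dataclass(frozen=True)
class Constraints:
    """Hard folding constraints: positions held unpaired, pairs forced present."""

    unpaired: frozenset[int] = frozenset()
    pairs: frozenset[tuple[int, int]] = frozenset()

    def validate(self, seq: str, model: EnergyModel) -> None:
        n = len(seq)
        for i in self.unpaired:
            if not 0 <= i < n:
                raise ValueError(f"constrained position {i} outside sequence")
        norm = {(min(i, j), max(i, j)) for i, j in self.pairs}
        ends: set[int] = set()
        for i, j in sorted(norm):
            if not (0 <= i < j < n):
                raise ValueError(f"forced pair ({i},{j}) outside sequence")
            if j - i - 1 < model.min_loop:
                raise ValueError(f"forced pair ({i},{j}) violates the minimum loop size")
            if not model.pair_allowed(seq[i], seq[j]):
                raise ValueError(f"forced pair ({i},{j}) = {seq[i]}{seq[j]} is not an allowed pair")
            if i in self.unpaired or j in self.unpaired:
                raise ValueError(f"forced pair ({i},{j}) conflicts with an unpaired constraint")
            if i in ends or j in ends:
                raise ValueError(f"position in more than one forced pair near ({i},{j})")
            ends.update((i, j))
        # nesting among forced pairs
        opened: list[tuple[int, int]] = []
        for i, j in sorted(norm):
            while opened and opened[-1][1] < i:
                opened.pop()
            if opened and not (opened[-1][0] < i and j < opened[-1][1]):
                raise ValueError(f"forced pairs {opened[-1]} and ({i},{j}) are not nested")
            opened.append((i, j))


# ---------------------------------------------------------------------------
# shared machinery


def _coerce(record: SequenceRecord | str) -> SequenceRecord:
    if isinstance(record, SequenceRecord):
        return record
    return SequenceRecord(id="seq", residues=record)


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASES.index(c) if c in _BASES else -1 for c in seq], dtype=np.int64)


def _pair_matrices(model: EnergyModel):
    """Integer pair-type matrix (6 canonical types, -1 otherwise) + stack table."""
    pair_list = ["AU", "UA", "GC", "CG", "GU", "UG"]
    ptype = -np.ones((5, 5), dtype=np.int64)  # index 4 = ambiguity bucket
    for t, p in enumerate(pair_list):
        if p in model.allowed_pairs:
            ptype[_BASES.index(p[0]), _BASES.index(p[1])] = t
    stack_tab = np.full((6, 6), _INF)
    for a, pa in enumerate(pair_list):
        for b, pb in enumerate(pair_list):
            if pa in model.allowed_pairs and pb in model.allowed_pairs:
                stack_tab[a, b] = model.stack_energy(pa, pb)
    return ptype, stack_tab


class _MfeTables:
    """Filled DP matrices for one sequence, ready for traceback."""

    def __init__(self, seq: str, model: EnergyModel, constraints: Constraints):
        self.seq = seq
        self.model = model
        self.constraints = constraints
        n = self.n = len(seq)
        enc = _encode(seq)
        ptype_tab, self.stack_tab = _pair_matrices(model)
        enc_safe = np.where(enc < 0, 4, enc)
        self.ptype = ptype_tab[enc_safe[:, None], enc_safe[None, :]]  # n x n

        forced_partner = np.full(n, -2, dtype=np.int64)  # -2 = unconstrained
        for i, j in constraints.pairs:
            i, j = min(i, j), max(i, j)
            forced_partner[i], forced_partner[j] = j, i
        can_pair = self.ptype >= 0
        iu = np.zeros(n, dtype=bool)
        for i in constraints.unpaired:
            iu[i] = True
        can_pair[iu, :] = False
        can_pair[:, iu] = False
        for i in range(n):
            fp = forced_partner[i]
            if fp >= 0:
                mask = np.zeros(n, dtype=bool)
                mask[fp] = True
                can_pair[i, :] &= mask
                can_pair[:, i] &= mask
        self.can_pair = can_pair
        # positions that may stay unpaired (forced-pair endpoints may not)
        self.skippable = forced_partner == -2
        # cumulative count of unskippable positions, for O(1) interval checks
        self.bad_cum = np.concatenate([[0], np.cumsum(~self.skippable)])

        ml = model.min_loop
        max_tab = 64  # precomputed penalty vectors; extrapolated beyond tables
        self.hp = np.array([model.hairpin_penalty(s) if s >= ml else _INF for s in range(n + 1)]) if n else np.array([])
        self.bp = np.array([_INF] + [model.bulge_penalty(s) for s in range(1, max_tab)])
        self.ip = np.array([_INF, _INF] + [model.internal_penalty(s) for s in range(2, max_tab)])

        self.V = np.full((n, n), _INF)
        self.WM = np.full((n, n), _INF)
        self._fill()
        self.W, self.Wok = self._fill_exterior()

    def _region_free(self, i: int, j: int) -> bool:
        """True iff every position in [i, j) may stay unpaired."""
        if i >= j:
            return True
        return self.bad_cum[j] - self.bad_cum[i] == 0

    def _fill(self) -> None:
        n, ml = self.n, self.model.min_loop
        V, WM = self.V, self.WM
        idx = np.arange(n)
        free = np.concatenate([[0], np.cumsum(~self.skippable)])  # alias of bad_cum
        for L in range(ml + 1, n):  # j = i + L
            i_all = idx[: n - L]
            j_all = i_all + L
            pairable = self.can_pair[i_all, j_all]
            if pairable.any():
                cand = np.full((0, len(i_all)), _INF)
                rows = []
                # hairpin: interior must be free of forced endpoints
                interior_free = (free[j_all] - free[i_all + 1]) == 0
                hp = np.where(interior_free, self.hp[L - 1], _INF)
                rows.append(hp)
                # stack / bulge / interior
                max_int = min(self.model.max_interior, L - ml - 2)
                for d5 in range(0, max_int + 1):
                    rem = max_int - d5
                    for d3 in range(0, rem + 1):
                        p, q = d5 + 1, L - d3 - 1  # inner pair offsets from i
                        if q - p - 1 < ml:
                            break
                        inner = V[i_all + p, i_all + q]
                        if d5 == 0 and d3 == 0:
                            cost = self.stack_tab[
                                np.where(pairable, self.ptype[i_all, j_all], 0),
                                np.where(self.ptype[i_all + p, i_all + q] >= 0, self.ptype[i_all + p, i_all + q], 0),
                            ]
                            cost = np.where(self.ptype[i_all + p, i_all + q] >= 0, cost, _INF)
                        else:
                            cost = self.bp[d5 + d3] if (d5 == 0 or d3 == 0) else self.ip[d5 + d3]
                        gap_ok = (free[i_all + p] - free[i_all + 1]) == 0
                        gap_ok &= (free[j_all] - free[i_all + q + 1]) == 0
                        rows.append(np.where(gap_ok, inner + cost, _INF))
                # multibranch: ml_init + min_k WM(i+1,k) + WM(k+1,j-1)
                if L >= 2 * (ml + 2):
                    best_split = np.full(len(i_all), _INF)
                    for m in range(1, L - 1):
                        left = WM[i_all + 1, i_all + m]
                        right = WM[i_all + m + 1, j_all - 1]
                        np.minimum(best_split, left + right, out=best_split)
                    rows.append(best_split + self.model.multiloop_init)
                vals = np.min(np.stack(rows), axis=0)
                V[i_all, j_all] = np.where(pairable, vals, _INF)
            # WM
            wm_rows = [V[i_all, j_all]]
            wm_rows.append(np.where(self.skippable[i_all], WM[i_all + 1, j_all], _INF))
            wm_rows.append(np.where(self.skippable[j_all], WM[i_all, j_all - 1], _INF))
            best_split = np.full(len(i_all), _INF)
            for m in range(0, L):
                left = WM[i_all, i_all + m]
                right = WM[i_all + m + 1, j_all]
                np.minimum(best_split, left + right, out=best_split)
            wm_rows.append(best_split)
            WM[i_all, j_all] = np.min(np.stack(wm_rows), axis=0)

    def _fill_exterior(self):
        """Suffix minima: W[i] = best energy of region i..n-1 in the exterior."""
        n = self.n
        W = np.full(n + 1, _INF)
        W[n] = 0.0
        for i in range(n - 1, -1, -1):
            best = W[i + 1] if self.skippable[i] else _INF
            js = np.nonzero(self.can_pair[i, :])[0]
            for j in js:
                if j > i:
                    cand = self.V[i, j] + W[j + 1]
                    if cand < best:
                        best = cand
            W[i] = best
        return W, W[0] < _INF / 2


# ---------------------------------------------------------------------------
# traceback (deterministic preference order)

_EPS = 1e-9


def _trace(tbl: _MfeTables) -> list[int]:
    partner = [UNPAIRED] * tbl.n
    stack: list[tuple[str, int, int]] = [("W", 0, tbl.n - 1)]
    while stack:
        kind, i, j = stack.pop()
        if i > j:
            continue
        if kind == "W":
            _trace_w(tbl, i, partner, stack)
        elif kind == "V":
            _trace_v(tbl, i, j, partner, stack)
        else:
            _trace_wm(tbl, i, j, partner, stack)
    return partner


def _trace_w(tbl, i, partner, stack) -> None:
    target = tbl.W[i]
    if target >= _INF / 2:
        raise ValueError("constraints admit no valid structure")
    # prefer pairing i (smallest partner first), then leaving it unpaired
    for j in np.nonzero(tbl.can_pair[i, :])[0]:
        j = int(j)
        if j > i and abs(tbl.V[i, j] + tbl.W[j + 1] - target) < _EPS:
            partner[i], partner[j] = j, i
            stack.append(("W", j + 1, tbl.n - 1))
            stack.append(("V", i, j))
            return
    if tbl.skippable[i] and abs(tbl.W[i + 1] - target) < _EPS:
        stack.append(("W", i + 1, tbl.n - 1))
        return
    raise AssertionError("exterior traceback failed")


def _trace_v(tbl, i, j, partner, stack) -> None:
    target = tbl.V[i, j]
    ml = tbl.model.min_loop
    L = j - i
    max_int = min(tbl.model.max_interior, L - ml - 2)
    for d5 in range(0, max_int + 1):
        for d3 in range(0, max_int - d5 + 1):
            p, q = i + d5 + 1, j - d3 - 1
            if q - p - 1 < ml:
                break
            if not (tbl._region_free(i + 1, p) and tbl._region_free(q + 1, j)):
                continue
            if tbl.ptype[p, q] < 0:
                continue
            if d5 == 0 and d3 == 0:
                cost = tbl.stack_tab[tbl.ptype[i, j], tbl.ptype[p, q]]
            elif d5 == 0 or d3 == 0:
                cost = tbl.bp[d5 + d3]
            else:
                cost = tbl.ip[d5 + d3]
            if abs(tbl.V[p, q] + cost - target) < _EPS:
                partner[p], partner[q] = q, p
                stack.append(("V", p, q))
                return
    if tbl._region_free(i + 1, j) and abs(tbl.hp[L - 1] - target) < _EPS:
        return  # hairpin
    # multibranch
    for m in range(1, L - 1):
        left, right = tbl.WM[i + 1, i + m], tbl.WM[i + m + 1, j - 1]
        if abs(left + right + tbl.model.multiloop_init - target) < _EPS:
            stack.append(("WM", i + m + 1, j - 1))
            stack.append(("WM", i + 1, i + m))
            return
    raise AssertionError(f"V traceback failed at ({i},{j})")


def _trace_wm(tbl, i, j, partner, stack) -> None:
    target = tbl.WM[i, j]
    # prefer a branch starting at i; remainder either all-unpaired or more branches
    for k in range(i + tbl.model.min_loop + 1, j + 1):
        if not tbl.can_pair[i, k]:
            continue
        if tbl._region_free(k + 1, j + 1) and abs(tbl.V[i, k] - target) < _EPS:
            partner[i], partner[k] = k, i
            stack.append(("V", i, k))
            return
        if k < j and abs(tbl.V[i, k] + tbl.WM[k + 1, j] - target) < _EPS:
            partner[i], partner[k] = k, i
            stack.append(("WM", k + 1, j))
            stack.append(("V", i, k))
            return
    if tbl.skippable[i] and abs(tbl.WM[i + 1, j] - target) < _EPS:
        stack.append(("WM", i + 1, j))
        return
    raise AssertionError(f"WM traceback failed at ({i},{j})")


# ---------------------------------------------------------------------------
# public folding API


def fold_mfe(
    record: SequenceRecord | str,
    model: EnergyModel | None = None,
    constraints: Constraints | None = None,
) -> SecondaryStructure:
    """Minimum-free-energy nested structure of ``record`` under ``model``.

    Deterministic: equal-energy optima are resolved by a fixed traceback
    preference order.  ``constraints`` may hold positions unpaired or force
    specific pairs; an infeasible or ill-formed constraint set raises
    ``ValueError``.  Sequences too short to form any pair come back fully
    unpaired with energy 0.
    """
    rec = _coerce(record)
    model = model or load_default_model()
    constraints = constraints or Constraints()
    seq = rec.residues
    constraints.validate(seq, model)
    n = len(seq)
    if n < model.min_loop + 2:
        if constraints.pairs:
            raise ValueError("sequence too short for the forced pairs")
        pt = PairTable(tuple([UNPAIRED] * n), min_loop=model.min_loop)
        return SecondaryStructure(rec, pt, 0.0)
    tbl = _MfeTables(seq, model, constraints)
    if not tbl.Wok:
        raise ValueError("constraints admit no valid structure")
    partner = _trace(tbl)
    pt = PairTable(tuple(partner), min_loop=model.min_loop)
    for i, j in constraints.pairs:
        if partner[min(i, j)] != max(i, j):
            raise AssertionError(f"forced pair ({i},{j}) missing from traceback")
    energy = structure_energy(seq, partner, model) if any(p != UNPAIRED for p in partner) else 0.0
    if abs(energy - tbl.W[0]) > 1e-6:
        raise AssertionError(f"traceback energy {energy} != DP optimum {tbl.W[0]}")
    return SecondaryStructure(rec, pt, float(energy))


def fold_maxpair(record: SequenceRecord | str, min_loop: int = 3,
                 allowed_pairs: frozenset[str] | None = None) -> SecondaryStructure:
    """Nussinov base-pair maximisation; energy is reported as -(pair count)."""
    rec = _coerce(record)
    model = load_default_model()
    allowed = allowed_pairs or model.allowed_pairs
    seq = rec.residues
    n = len(seq)
    N = np.zeros((n, n), dtype=np.int64)
    can = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            can[i, j] = seq[i] + seq[j] in allowed
    for L in range(min_loop + 1, n):
        for i in range(0, n - L):
            j = i + L
            best = N[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if can[i, k]:
                    cand = 1 + N[i + 1, k - 1] + (N[k + 1, j] if k < j else 0)
                    if cand > best:
                        best = cand
            N[i, j] = best
    partner = [UNPAIRED] * n
    work = [(0, n - 1)] if n else []
    while work:
        i, j = work.pop()
        if i >= j:
            continue
        target = N[i, j]
        if target == 0:
            continue
        placed = False
        for k in range(i + min_loop + 1, j + 1):
            if can[i, k] and 1 + N[i + 1, k - 1] + (N[k + 1, j] if k < j else 0) == target:
                partner[i], partner[k] = k, i
                work.append((i + 1, k - 1))
                if k < j:
                    work.append((k + 1, j))
                placed = True
                break
        if not placed:
            work.append((i + 1, j))
    pt = PairTable(tuple(partner), min_loop=min_loop)
    npairs = len(pt.pairs())
    assert npairs == N[0, n - 1] if n else npairs == 0
    return SecondaryStructure(rec, pt, float(-npairs))


def enumerate_structures(
    record: SequenceRecord | str,
    max_len: int = 18,
    model: EnergyModel | None = None,
    constraints: Constraints | None = None,
) -> list[SecondaryStructure]:
    """Every valid nested structure of a short sequence, scored under ``model``.

    The number of structures grows exponentially; sequences longer than
    ``max_len`` are refused.  With ``constraints``, only conforming structures
    are returned.  This is the package's ground-truth oracle.
    """
    rec = _coerce(record)
    model = model or load_default_model()
    seq = rec.residues
    n = len(seq)
    if n > max_len:
        raise ValueError(f"sequence of length {n} exceeds enumeration limit {max_len}")

    ml = model.min_loop

    def gen(i: int, j: int) -> Iterator[tuple[tuple[int, int], ...]]:
        """All nested pair sets on [i, j]."""
        if i > j:
            yield ()
            return
        # i unpaired
        for rest in gen(i + 1, j):
            yield rest
        # i paired with k
        for k in range(i + ml + 1, j + 1):
            if model.pair_allowed(seq[i], seq[k]):
                for inside in gen(i + 1, k - 1):
                    for outside in gen(k + 1, j):
                        yield ((i, k),) + inside + outside

    out = []
    for pairset in gen(0, n - 1):
        partner = [UNPAIRED] * n
        for i, j in pairset:
            partner[i], partner[j] = j, i
        if constraints is not None:
            if any(partner[p] != UNPAIRED for p in constraints.unpaired):
                continue
            if any(partner[min(a, b)] != max(a, b) for a, b in constraints.pairs):
                continue
        energy = structure_energy(seq, partner, model) if pairset else 0.0
        out.append(SecondaryStructure(rec, PairTable(tuple(partner), min_loop=ml), float(energy)))
    return out


# ---------------------------------------------------------------------------
# Vienna dot-bracket file format


def write_dotbracket(structure: SecondaryStructure, path: str | Path, with_energy: bool = True) -> None:
    """Single-record Vienna format: '>id', sequence, structure [ (energy)]."""
    lines = [f">{structure.record.id}", structure.record.residues]
    if with_energy:
        lines.append(f"{structure.dotbracket} ({structure.energy:.2f})")
    else:
        lines.append(structure.dotbracket)
    Path(path).write_text("\n".join(lines) + "\n")


def read_dotbracket(path: str | Path, min_loop: int = 3) -> SecondaryStructure:
    """Inverse of :func:`write_dotbracket`; bit-exact round trip."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3 or not lines[0].startswith(">"):
        raise ValueError(f"{path} is not a single-record dot-bracket file")
    rec_id = lines[0][1:].strip()
    seq = lines[1].strip()
    struct_line = lines[2].strip()
    energy = 0.0
    if " (" in struct_line and struct_line.endswith(")"):
        db, _, tail = struct_line.rpartition(" (")
        energy = float(tail[:-1])
    else:
        db = struct_line
    meta = _parse_vienna_id(rec_id)
    rec = SequenceRecord(id=meta, residues=seq)
    pt = PairTable.from_dotbracket(db, min_loop=min_loop)
    return SecondaryStructure(rec, pt, energy)


def _parse_vienna_id(raw: str) -> str:
    return raw.split()[0] if raw.split() else "seq"
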