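"""Simplified nearest-neighbour free-energy model for nested RNA structure.

The model scores a nested secondary structure as a sum over its loops:
stacking energies for directly adjacent base pairs, size-indexed initiation
penalties for hairpin, bulge and internal loops, and a flat initiation cost
per multibranch loop.  Exterior (unpaired, outside every pair) positions are
free.  Loop penalties beyond the tabulated sizes are extrapolated with the
Jacobson-Stockmayer form ``dG(n) = dG(n_max) + c * RT * ln(n / n_max)``.

Parameters live in ``data/energy_params.json`` (kcal/mol at 37 C) and can be
replaced wholesale by users who want a richer parameterisation; the folding
and evaluation code only sees the :class:`EnergyModel` surface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = ["EnergyModel", "load_default_model", "structure_energy"]

#: pairs the model will ever close (Watson-Crick plus G.U wobble)
CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})


@dataclass(frozen=True)
class EnergyModel:
    allowed_pairs: frozenset[str]
    stack: dict[str, dict[str, float]]
    hairpin: dict[int, float]
    bulge: dict[int, float]
    internal: dict[int, float]
    min_loop: int = 3
    max_interior: int = 30
    multiloop_init: float = 3.4
    extrapolation_coeff: float = 1.75
    extrapolation_rt: float = 0.616
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")
        for p1, row in self.stack.items():
            for p2, e in row.items():
                if p1 in CANONICAL_PAIRS and p2 in CANONICAL_PAIRS and e > 0:
                    raise ValueError(f"stack energy {p1}/{p2} = {e} must be <= 0")
        for name, table in (("hairpin", self.hairpin), ("bulge", self.bulge), ("internal", self.internal)):
            for size, e in table.items():
                if e < 0:
                    raise ValueError(f"{name} penalty for size {size} must be >= 0")

    # -- lookups ---------------------------------------------------------

    def pair_allowed(self, a: str, b: str) -> bool:
        return a + b in self.allowed_pairs

    def stack_energy(self, outer: str, inner: str) -> float:
        return self.stack[outer][inner]

    def _loop_penalty(self, table: dict[int, float], size: int) -> float:
        if size in table:
            return table[size]
        n_max = max(table)
        if size < n_max:
            raise ValueError(f"no penalty tabulated for loop size {size}")
        return table[n_max] + self.extrapolation_coeff * self.extrapolation_rt * math.log(size / n_max)

    def hairpin_penalty(self, size: int) -> float:
        if size < self.min_loop:
            raise ValueError(f"hairpin loop of {size} < min_loop {self.min_loop}")
        return self._loop_penalty(self.hairpin, size)

    def bulge_penalty(self, size: int) -> float:
        return self._loop_penalty(self.bulge, size)

    def internal_penalty(self, size: int) -> float:
        return self._loop_penalty(self.internal, size)

    def two_loop_energy(self, gap5: int, gap3: int, outer: str, inner: str) -> float:
        """Energy of the loop between pair ``outer`` and its only child ``inner``.

        ``gap5``/``gap3`` count unpaired positions on the 5' and 3' side.
        A (0,0) gap is a stack; one-sided gaps are bulges (no stacking bonus
        across the bulge); two-sided gaps are internal loops sized by total.
        """
        if gap5 == 0 and gap3 == 0:
            return self.stack_energy(outer, inner)
        if gap5 == 0 or gap3 == 0:
            return self.bulge_penalty(gap5 + gap3)
        return self.internal_penalty(gap5 + gap3)


def load_default_model(path: str | Path | None = None) -> EnergyModel:
    """Load the packaged parameter file (or a user-supplied one)."""
    if path is None:
        path = resources.files("rna2dbarcode").joinpath("data/energy_params.json")
    raw = json.loads(Path(path).read_text())
    return EnergyModel(
        allowed_pairs=frozenset(raw["allowed_pairs"]),
        stack={p1: dict(row) for p1, row in raw["stack"].items()},
        hairpin={int(k): v for k, v in raw["hairpin"].items()},
        bulge={int(k): v for k, v in raw["bulge"].items()},
        internal={int(k): v for k, v in raw["internal"].items()},
        min_loop=int(raw["min_loop"]),
        max_interior=int(raw.get("max_interior", 30)),
        multiloop_init=float(raw["multiloop_init"]),
        extrapolation_coeff=float(raw["extrapolation"]["coefficient"]),
        extrapolation_rt=float(raw["extrapolation"]["RT"]),
        source=str(path),
    )


def structure_energy(seq: str, partner: list[int], model: EnergyModel) -> float:
    """Free energy of an explicit nested structure under ``model``.

    Independent of the folding recursions: the structure is decomposed into
    loops by walking pairs outermost-first and summing loop terms.  Used both
    to score enumerated structures and as a cross-check on the optimiser.
    """
    n = len(seq)
    pairs = sorted((i, j) for i, j in enumerate(partner) if j > i)
    for i, j in pairs:
        duplex = seq[i] + seq[j]
        if duplex not in model.allowed_pairs:
            raise ValueError(f"pair ({i},{j}) = {duplex} not in the allowed pair set")
    energy = 0.0
    for i, j in pairs:
        # children: maximal pairs strictly inside (i, j)
        children = []
        k = i + 1
        while k < j:
            if partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not children:
            energy += model.hairpin_penalty(j - i - 1)
        elif len(children) == 1:
            (a, b) = children[0]
            energy += model.two_loop_energy(a - i - 1, j - b - 1, seq[i] + seq[j], seq[a] + seq[b])
        else:
            energy += model.multiloop_init
    return energy
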