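"""Ideal beta-sheet generator.

Builds synthetic multi-strand beta sheets with known pairing so the mining
stage can be exercised (and oracle-tested) without downloading structures.
Strands run along the x axis on a common grid of "slots" spaced by the rise
per residue; successive strands are stacked along z at the inter-strand
spacing, and each residue's amide and carbonyl groups face the neighbouring
strand on alternating sides, reproducing the canonical hydrogen-bond ladder
of parallel and antiparallel sheets.  Only relative geometry matters for
mining, so bond lengths and offsets are idealized constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .structures import AA20, Chain, Residue, Structure

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"

# In-plane offset of N and C from CA along the strand axis (Angstrom).
_NC_OFFSET = 1.16
# Out-of-plane displacement of the amide N toward the facing strand; this is
# what makes the reconstructed amide H point at the acceptor carbonyl.
_N_FACE_DISP = 0.30
# Carbonyl C=O bond length, pointing toward the facing strand.
_CO_LENGTH = 1.23


@dataclass(frozen=True)
class GeometryParams:
    """Idealized sheet geometry: canonical textbook values, configurable."""

    rise_per_residue: float = 3.47
    inter_strand_spacing: float = 4.85
    pleat_amplitude: float = 1.0


@dataclass(frozen=True)
class StrandSpec:
    """One strand: sequence, orientation relative to the first strand, and the
    slot offset of this strand's leftmost residue relative to the previous
    strand's leftmost slot (the register)."""

    sequence: str
    orientation_vs_first: str = ANTIPARALLEL
    register_offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("strand sequence must be non-empty")
        bad = set(self.sequence) - set(AA20)
        if bad:
            raise ValueError(f"strand sequence has invalid letters: {sorted(bad)}")
        if self.orientation_vs_first not in (PARALLEL, ANTIPARALLEL):
            raise ValueError(f"unknown orientation {self.orientation_vs_first!r}")


@dataclass(frozen=True)
class SheetSpec:
    strands: List[StrandSpec] = field(default_factory=list)
    geometry: GeometryParams = GeometryParams()
    sheet_id: str = "ideal_sheet"

    def __post_init__(self) -> None:
        if not self.strands:
            raise ValueError("sheet needs at least one strand")


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def build_ideal_sheet(spec: SheetSpec) -> Structure:
    """Deterministically build one chain per strand with the canonical
    alternating hydrogen-bond ladder between adjacent strands.

    Raises ValueError if a register offset leaves adjacent strands without
    any inter-strand contact.
    """
    geo = spec.geometry
    chains: List[Chain] = []
    base = 0  # leftmost slot of current strand
    phase = 0  # facing parity: residue at slot k faces +z iff (k + phase) even
    prev_direction = 1
    prev_slots: Tuple[int, int] | None = None

    for s_idx, strand in enumerate(spec.strands):
        # the first strand defines the reference frame; its orientation field is moot
        if s_idx == 0:
            direction = 1
        else:
            direction = 1 if strand.orientation_vs_first == PARALLEL else -1
        length = len(strand.sequence)
        if s_idx > 0:
            base = base + strand.register_offset
            # facing parity flips across antiparallel interfaces only
            if direction != prev_direction:
                phase = (phase + 1) % 2
            lo, hi = base, base + length - 1
            plo, phi = prev_slots  # type: ignore[misc]
            if min(hi, phi) < max(lo, plo):
                raise ValueError(
                    f"register_offset {strand.register_offset} leaves no "
                    f"inter-strand contact for strand {s_idx + 1}"
                )
        z0 = s_idx * geo.inter_strand_spacing
        residues: List[Residue] = []
        for i, aa in enumerate(strand.sequence):
            # slot occupied by residue i (chains with direction -1 run right to left)
            slot = base + (i if direction == 1 else length - 1 - i)
            x = slot * geo.rise_per_residue
            facing = 1.0 if (slot + phase) % 2 == 0 else -1.0
            pleat_y = 0.5 * geo.pleat_amplitude * (1.0 if slot % 2 == 0 else -1.0)
            ca = np.array([x, pleat_y, z0])
            n = np.array([x - _NC_OFFSET * direction, 0.0, z0 + _N_FACE_DISP * facing])
            c = np.array([x + _NC_OFFSET * direction, 0.0, z0])
            o = np.array([x + _NC_OFFSET * direction, 0.0, z0 + _CO_LENGTH * facing])
            residues.append(
                Residue(i + 1, aa, {"N": n, "CA": ca, "C": c, "O": o})
            )
        chains.append(Chain(_CHAIN_IDS[s_idx], residues))
        prev_direction = direction
        prev_slots = (base, base + length - 1)

    return Structure(spec.sheet_id, chains)
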