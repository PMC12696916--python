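"""Cascade assembly of complementary peptides (paratopes) and scoring.

Given a fragment library mined from beta-sheet pairings, a paratope for a
linear epitope is assembled by seeding with a library fragment that matches
an epitope prefix and extending with overlapping fragments that agree exactly
with the complementary residues already placed.  Candidates are ranked by a
complementarity score C (mean log-evidence over positions) and an intrinsic
solubility score.

Assembly works in "facing space": position i of the working string is the
complementary residue facing epitope position i.  For antiparallel designs
the emitted peptide sequence (N->C) is the reverse of the facing string, so
a design fully covered by a single library fragment reports exactly that
fragment's complementary subsequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .mining import FragmentLibrary
from .sheets import ANTIPARALLEL, PARALLEL
from .structures import AA20

NEGATIVE_CONTROL_PATTERN = "SGAAAGSGS"

# simplified intrinsic-solubility coefficients: hydropathy vs charge weight
_W_HYDROPATHY = 0.6
_W_CHARGE = 0.4
_CHARGED = frozenset("DEKR")
_KD_SCALE = max(abs(v) for v in KYTE_DOOLITTLE.values())  # 4.5


@dataclass(frozen=True)
class CascadeParams:
    min_frag_len: int = 3
    overlap_min: int = 2
    beam_width: int = 64
    max_candidates: int = 10

    def __post_init__(self) -> None:
        if self.overlap_min < 1:
            raise ValueError("overlap_min must be >= 1")
        if self.min_frag_len < 2:
            raise ValueError("min_frag_len must be >= 2")


@dataclass(frozen=True)
class ParatopeDesign:
    epitope_seq: str
    paratope_seq: str
    orientation: str
    support: Tuple[int, ...]
    c_score: float
    solubility: float
    fragments_used: Tuple[Tuple[str, str, int], ...]  # (target_subseq, comp_subseq, offset)
    epitope_window: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.paratope_seq) != len(self.epitope_seq):
            raise ValueError("paratope and epitope must have equal length")
        if len(self.support) != len(self.epitope_seq):
            raise ValueError("support must have one entry per epitope position")


def c_from_support(support: Sequence[int]) -> float:
    """C = (1/L) * sum_i log10(1 + n_i): zero at no support, monotone in counts."""
    if not support:
        return 0.0
    return sum(math.log10(1 + n) for n in support) / len(support)


def complementarity_score(design: ParatopeDesign) -> float:
    return c_from_support(design.support)


def solubility_score(seq: str, window: int = 7) -> float:
    """Simplified intrinsic solubility profile score; higher = more soluble.

    Per-residue value 0.6*(-H) + 0.4*q, with H the Kyte-Doolittle hydropathy
    rescaled to [-1, 1] and q = 1 for D/E/K/R else 0; the profile is smoothed
    with a centered moving average of width min(window, length) (forced odd)
    and averaged.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    bad = set(seq) - set(AA20)
    if bad:
        raise ValueError(f"non-standard letters in sequence: {sorted(bad)}")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    z = [
        _W_HYDROPATHY * (-KYTE_DOOLITTLE[a] / _KD_SCALE) + _W_CHARGE * (1.0 if a in _CHARGED else 0.0)
        for a in seq
    ]
    w = min(window, len(seq))
    if w % 2 == 0:
        w -= 1
    h = w // 2
    smoothed = []
    for i in range(len(z)):
        lo, hi = max(0, i - h), min(len(z), i + h + 1)
        smoothed.append(sum(z[lo:hi]) / (hi - lo))
    return sum(smoothed) / len(smoothed)


def make_negative_control(length: int) -> str:
    """Deterministic short-side-chain (S/G/A) sequence; length 9 gives SGAAAGSGS."""
    if length < 1:
        raise ValueError("length must be >= 1")
    reps = -(-length // len(NEGATIVE_CONTROL_PATTERN))
    return (NEGATIVE_CONTROL_PATTERN * reps)[:length]


def is_negative_control(seq: str) -> bool:
    return bool(seq) and set(seq) <= set("SGA")


@dataclass(frozen=True)
class _State:
    covered: int
    facing: str
    support: Tuple[int, ...]
    frags: Tuple[Tuple[str, str, int], ...]


def _epitope_fragments(
    lib: FragmentLibrary, epitope_seq: str, orientation: str, min_frag_len: int
):
    """All library fragments matching contiguous epitope subsequences.

    Returns a list of (start0, facing_subseq, comp_subseq, count) where
    facing_subseq is ordered along the epitope.
    """
    L = len(epitope_seq)
    lo = max(min_frag_len, lib.min_len)
    out = []
    for s0 in range(L):
        for ln in range(lo, min(lib.max_len, L - s0) + 1):
            sub = epitope_seq[s0 : s0 + ln]
            for obs in lib.query(sub, orientation):
                facing = obs.comp_subseq if orientation == PARALLEL else obs.comp_subseq[::-1]
                out.append((s0, facing, obs.comp_subseq, obs.count))
    return out


def cascade_assemble(
    lib: FragmentLibrary,
    epitope_seq: str,
    params: CascadeParams = CascadeParams(),
    orientations: Sequence[str] = (ANTIPARALLEL, PARALLEL),
    window: Optional[Tuple[int, int]] = None,
    _beam: bool = True,
) -> List[ParatopeDesign]:
    """Assemble complementary peptides covering the whole epitope.

    Breadth-limited search: seeds are fragments matching an epitope prefix;
    extensions must start inside the covered region, overlap by at least
    overlap_min positions and agree exactly on the overlap.  Candidates are
    de-duplicated by peptide sequence and ranked by C score, solubility, then
    lexicographically; at most max_candidates are returned.  An epitope no
    fragment chain can cover yields an empty list.
    """
    if "X" in epitope_seq:
        raise ValueError("epitope contains nonstandard residue 'X'")
    bad = set(epitope_seq) - set(AA20)
    if bad:
        raise ValueError(f"epitope has invalid letters: {sorted(bad)}")
    L = len(epitope_seq)
    if L < params.min_frag_len:
        raise ValueError("epitope shorter than the minimum fragment length")

    designs: List[ParatopeDesign] = []
    for orientation in orientations:
        frags = _epitope_fragments(lib, epitope_seq, orientation, params.min_frag_len)
        by_start: Dict[int, list] = {}
        for f in frags:
            by_start.setdefault(f[0], []).append(f)

        complete: Dict[str, _State] = {}
        frontier: List[_State] = [
            _State(len(f[1]), f[1], (f[3],) * len(f[1]), ((epitope_seq[: len(f[1])], f[2], 1),))
            for f in by_start.get(0, [])
        ]
        seen = set()
        while frontier:
            level: Dict[int, List[_State]] = {}
            for st in frontier:
                if st.covered == L:
                    key = st.facing
                    prev = complete.get(key)
                    if prev is None or _rank_key(st) < _rank_key(prev):
                        complete[key] = st
                    continue
                level.setdefault(st.covered, []).append(st)
            frontier = []
            for covered, states in sorted(level.items()):
                states.sort(key=_rank_key)
                if _beam:
                    states = states[: params.beam_width]
                for st in states:
                    for s0, facing, comp, count in frags:
                        if s0 > covered - params.overlap_min:
                            continue  # must overlap covered region by >= overlap_min
                        end = s0 + len(facing)
                        if end <= covered:
                            continue  # must extend
                        ov = covered - s0
                        if st.facing[s0:covered] != facing[:ov]:
                            continue  # exact agreement on the overlap
                        new_support = list(st.support) + [0] * (end - covered)
                        for k in range(s0, end):
                            new_support[k] += count
                        new = _State(
                            end,
                            st.facing + facing[ov:],
                            tuple(new_support),
                            st.frags + ((epitope_seq[s0:end], comp, s0 + 1),),
                        )
                        sig = (new.covered, new.facing, new.support, new.frags)
                        if sig not in seen:
                            seen.add(sig)
                            frontier.append(new)

        for st in complete.values():
            paratope = st.facing if orientation == PARALLEL else st.facing[::-1]
            designs.append(
                ParatopeDesign(
                    epitope_seq=epitope_seq,
                    paratope_seq=paratope,
                    orientation=orientation,
                    support=st.support,
                    c_score=c_from_support(st.support),
                    solubility=solubility_score(paratope),
                    fragments_used=st.frags,
                    epitope_window=window,
                )
            )

    # de-duplicate by peptide sequence keeping the best-supported design
    best: Dict[str, ParatopeDesign] = {}
    for d in designs:
        prev = best.get(d.paratope_seq)
        if prev is None or (-d.c_score, -d.solubility) < (-prev.c_score, -prev.solubility):
            best[d.paratope_seq] = d
    ranked = sorted(best.values(), key=lambda d: (-d.c_score, -d.solubility, d.paratope_seq))
    return ranked[: params.max_candidates]


def _rank_key(st: _State):
    return (-c_from_support(st.support), st.facing)
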