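"""Beta-strand pairing detection and the paired-fragment library.

Hydrogen bonds between backbone amide (N-H) and carbonyl (C=O) groups are
detected with the DSSP electrostatic criterion: the amide H is reconstructed
from N, CA and the preceding residue's C, and the interaction energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

marks a hydrogen bond when E < -0.5 kcal/mol.  Strand pairings are maximal
runs of residue pairs supported by the two DSSP bridge patterns (mutual
bonds for antiparallel ladders, the offset i-1/j+1 patterns for wide pairs
and parallel ladders); a run needs at least two inter-strand hydrogen bonds,
which excludes isolated contacts and turns.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sheets import ANTIPARALLEL, PARALLEL
from .structures import Structure

HBOND_CUTOFF = -0.5  # kcal/mol, DSSP threshold
_Q1Q2_F = 0.084 * 332.0  # DSSP electrostatic prefactor (partial charges * 332)
MIN_SEQ_SEPARATION = 3  # |i - j| >= 3 within a chain


@dataclass(frozen=True)
class ResidueRef:
    """Address of a residue: chain index, position within chain, chain id, seq index."""

    chain_idx: int
    pos: int
    chain_id: str
    seq_index: int


@dataclass(frozen=True)
class HBond:
    """Directed backbone hydrogen bond, donor (N-H) -> acceptor (C=O)."""

    donor: ResidueRef
    acceptor: ResidueRef
    energy: float


@dataclass(frozen=True)
class PairedFragment:
    source_id: str
    target_seq: str
    comp_seq: str
    orientation: str
    register_offset: int
    target_locus: Tuple[str, int, int]  # chain_id, start, end (1-based inclusive)
    comp_locus: Tuple[str, int, int]

    def __post_init__(self) -> None:
        if len(self.target_seq) != len(self.comp_seq):
            raise ValueError("target and complementary fragments must have equal length")

    def __len__(self) -> int:
        return len(self.target_seq)

    def facing(self) -> str:
        """Complementary residues ordered along the target (N->C of target)."""
        return self.comp_seq if self.orientation == PARALLEL else self.comp_seq[::-1]


def _amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Reconstruct the amide H 1 A from N, along the bisector pointing away
    from both CA and the preceding carbonyl carbon."""
    u1 = ca - n
    u1 /= np.linalg.norm(u1)
    u2 = c_prev - n
    u2 /= np.linalg.norm(u2)
    d = -(u1 + u2)
    norm = np.linalg.norm(d)
    if norm < 1e-9:  # collinear degenerate case
        return None
    return n + d / norm


def _flatten(structure: Structure):
    """Per-residue arrays used by hydrogen-bond detection."""
    refs: List[ResidueRef] = []
    atoms: List[dict] = []
    for ci, chain in enumerate(structure.chains):
        for pi, res in enumerate(chain.residues):
            refs.append(ResidueRef(ci, pi, chain.chain_id, res.seq_index))
            atoms.append(res.atoms if res.eligible else None)
    return refs, atoms


def detect_hbonds(structure: Structure, cutoff: float = HBOND_CUTOFF) -> List[HBond]:
    """All backbone N-H...O=C hydrogen bonds under the DSSP energy criterion.

    Donors need N, CA and a directly preceding residue (for the H position);
    acceptors need C and O.  Within a chain, |i - j| >= 3 is required.
    """
    refs, atoms = _flatten(structure)
    n = len(refs)
    chains = structure.chains

    h_pos: List[Optional[np.ndarray]] = [None] * n
    for k, ref in enumerate(refs):
        if atoms[k] is None or ref.pos == 0:
            continue
        prev = chains[ref.chain_idx].residues[ref.pos - 1]
        if prev.seq_index != ref.seq_index - 1 or not prev.eligible:
            continue  # gap in numbering: no peptide bond, no amide H
        h_pos[k] = _amide_h(atoms[k]["N"], atoms[k]["CA"], prev.atoms["C"])

    bonds: List[HBond] = []
    for d in range(n):
        if h_pos[d] is None:
            continue
        nd = atoms[d]["N"]
        hd = h_pos[d]
        for a in range(n):
            if a == d or atoms[a] is None:
                continue
            if refs[d].chain_idx == refs[a].chain_idx and abs(
                refs[d].seq_index - refs[a].seq_index
            ) < MIN_SEQ_SEPARATION:
                continue
            ca_, oa = atoms[a]["C"], atoms[a]["O"]
            r_on = np.linalg.norm(oa - nd)
            if r_on > 5.2:  # beyond any plausible bond; energy would be ~0
                continue
            r_ch = np.linalg.norm(ca_ - hd)
            r_oh = np.linalg.norm(oa - hd)
            r_cn = np.linalg.norm(ca_ - nd)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing/malformed input
            energy = _Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < cutoff:
                bonds.append(HBond(refs[d], refs[a], float(energy)))
    return bonds


def _neighbor(structure: Structure, ref: ResidueRef, step: int) -> Optional[ResidueRef]:
    """Residue at seq_index +- 1 in the same chain, if present and consecutive."""
    chain = structure.chains[ref.chain_idx]
    pos = ref.pos + step
    if 0 <= pos < len(chain.residues):
        res = chain.residues[pos]
        if res.seq_index == ref.seq_index + step:
            return ResidueRef(ref.chain_idx, pos, ref.chain_id, res.seq_index)
    return None


def _pair_key(a: ResidueRef, b: ResidueRef):
    """Canonical unordered residue pair (lower chain/pos first)."""
    if (a.chain_idx, a.pos) <= (b.chain_idx, b.pos):
        return a, b
    return b, a


def detect_strand_pairs(
    structure: Structure, min_len: int = 3, cutoff: float = HBOND_CUTOFF
) -> List[PairedFragment]:
    """Extract maximal beta-strand pairings as PairedFragments.

    Residue pairs are supported by hydrogen bonds through the DSSP bridge
    patterns: a bond CO(A)...HN(D) supports the antiparallel pairs {A, D} and
    {A+1, D-1} and the parallel pairs {A+1, D} and {D-1, A}.  Supported pairs
    lying on a common pairing diagonal form runs; runs shorter than min_len
    or backed by fewer than two hydrogen bonds are discarded.  Overlapping
    runs on the same chain pair are resolved greedily, longest first.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    bonds = detect_hbonds(structure, cutoff=cutoff)
    if not bonds:
        return []

    bond_set = {(b.donor, b.acceptor) for b in bonds}

    # votes[(chainpair, orientation, diagonal)] -> set of paired positions
    votes: Dict[tuple, set] = defaultdict(set)

    def vote(x: Optional[ResidueRef], y: Optional[ResidueRef], orientation: str) -> None:
        if x is None or y is None:
            return
        a, b = _pair_key(x, y)
        if a.chain_idx == b.chain_idx and abs(a.seq_index - b.seq_index) < MIN_SEQ_SEPARATION:
            return
        chainpair = (a.chain_idx, b.chain_idx)
        if orientation == ANTIPARALLEL:
            diag = a.pos + b.pos
        else:
            diag = a.pos - b.pos
        votes[(chainpair, orientation, diag)].add((a, b))

    for b in bonds:
        acc, don = b.acceptor, b.donor
        vote(acc, don, ANTIPARALLEL)
        vote(_neighbor(structure, acc, +1), _neighbor(structure, don, -1), ANTIPARALLEL)
        vote(_neighbor(structure, acc, +1), don, PARALLEL)
        vote(_neighbor(structure, don, -1), acc, PARALLEL)

    # assemble runs along each diagonal
    candidates = []  # (run: list of (a, b) pairs, orientation, n_bonds)
    for (chainpair, orientation, _diag), pairs in votes.items():
        ordered = sorted(pairs, key=lambda ab: ab[0].pos)
        run: List[tuple] = []
        runs: List[List[tuple]] = []
        for pair in ordered:
            if run and pair[0].pos == run[-1][0].pos + 1:
                run.append(pair)
            else:
                if run:
                    runs.append(run)
                run = [pair]
        if run:
            runs.append(run)
        for r in runs:
            members = {id_ for ab in r for id_ in ab}
            n_bonds = sum(1 for (d, a) in bond_set if d in members and a in members)
            if len(r) >= min_len and n_bonds >= 2:
                candidates.append((r, orientation, n_bonds, chainpair))

    # greedy conflict resolution per chain pair: longest, most-bonded first
    candidates.sort(key=lambda c: (-len(c[0]), -c[2], c[3], c[0][0][0].pos))
    claimed: Dict[tuple, set] = defaultdict(set)
    fragments: List[PairedFragment] = []
    for run, orientation, _n_bonds, chainpair in candidates:
        members = {id_ for ab in run for id_ in ab}
        if members & claimed[chainpair]:
            continue
        claimed[chainpair] |= members
        fragments.append(_run_to_fragment(structure, run, orientation))

    fragments.sort(key=lambda f: (f.target_locus, f.comp_locus))
    return fragments


def _run_to_fragment(structure: Structure, run: List[tuple], orientation: str) -> PairedFragment:
    a_refs = [ab[0] for ab in run]
    b_refs = [ab[1] for ab in run]
    # a side is contiguous ascending by construction; b side ascending (parallel)
    # or descending (antiparallel) along the run
    a_chain = structure.chains[a_refs[0].chain_idx]
    b_chain = structure.chains[b_refs[0].chain_idx]
    a_start, a_end = a_refs[0].seq_index, a_refs[-1].seq_index
    b_indices = [r.seq_index for r in b_refs]
    b_start, b_end = min(b_indices), max(b_indices)

    a_seq = "".join(a_chain.residues[r.pos].aa for r in a_refs)
    b_seq_by_pos = {r.seq_index: b_chain.residues[r.pos].aa for r in b_refs}
    b_seq = "".join(b_seq_by_pos[i] for i in range(b_start, b_end + 1))

    # orientation from the chains' own N->C direction vectors at paired residues:
    # sum of dot products of CA(i+1)-CA(i) steps, >= 0 parallel, < 0 antiparallel
    def _local_dir(chain, pos: int) -> Optional[np.ndarray]:
        if pos + 1 < len(chain.residues):
            return chain.residues[pos + 1].atoms["CA"] - chain.residues[pos].atoms["CA"]
        if pos > 0:
            return chain.residues[pos].atoms["CA"] - chain.residues[pos - 1].atoms["CA"]
        return None

    if len(run) >= 2:
        dot = 0.0
        for ra, rb in run:
            va = _local_dir(a_chain, ra.pos)
            vb = _local_dir(b_chain, rb.pos)
            if va is not None and vb is not None:
                dot += float(np.dot(va, vb))
        orientation = PARALLEL if dot >= 0 else ANTIPARALLEL

    if orientation == PARALLEL:
        register = b_start - a_start  # comp index = target index + register
    else:
        register = a_start + b_end  # comp index = register - target index

    return PairedFragment(
        source_id=structure.structure_id,
        target_seq=a_seq,
        comp_seq=b_seq,
        orientation=orientation,
        register_offset=register,
        target_locus=(a_chain.chain_id, a_start, a_end),
        comp_locus=(b_chain.chain_id, b_start, b_end),
    )


@dataclass(frozen=True)
class Observation:
    """A complementary fragment observed for a target-side subsequence."""

    comp_subseq: str
    count: int
    sources: Tuple[str, ...]


@dataclass
class FragmentLibrary:
    """Index from (target-side subsequence, orientation) to observed
    complementary fragments with observation counts."""

    min_len: int = 3
    max_len: int = 9
    # (target_subseq, orientation) -> comp_subseq -> [count, set of sources]
    _index: Dict[Tuple[str, str], Dict[str, list]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (2 <= self.min_len <= self.max_len):
            raise ValueError("need max_len >= min_len >= 2")

    @property
    def n_keys(self) -> int:
        return len(self._index)

    @property
    def total_count(self) -> int:
        return sum(rec[0] for obs in self._index.values() for rec in obs.values())

    def _add(self, target_subseq: str, orientation: str, comp_subseq: str,
             source_id: str, count: int = 1) -> None:
        obs = self._index.setdefault((target_subseq, orientation), {})
        rec = obs.setdefault(comp_subseq, [0, set()])
        rec[0] += count
        rec[1].add(source_id)

    def add_observation(
        self,
        target_subseq: str,
        orientation: str,
        comp_subseq: str,
        source_id: str = "manual",
        count: int = 1,
    ) -> None:
        """Directly record an observation (mainly for synthetic libraries)."""
        if not (self.min_len <= len(target_subseq) <= self.max_len):
            raise ValueError("target subsequence length outside library bounds")
        if len(comp_subseq) != len(target_subseq):
            raise ValueError("complementary subsequence must match target length")
        self._add(target_subseq, orientation, comp_subseq, source_id, count)

    def add_fragment(self, frag: PairedFragment) -> None:
        """Index every sub-window of a paired fragment (skipping 'X')."""
        facing = frag.facing()
        L = len(frag)
        for start in range(L):
            for ln in range(self.min_len, self.max_len + 1):
                if start + ln > L:
                    break
                t_sub = frag.target_seq[start : start + ln]
                f_sub = facing[start : start + ln]
                if "X" in t_sub or "X" in f_sub:
                    continue
                comp_sub = f_sub if frag.orientation == PARALLEL else f_sub[::-1]
                self._add(t_sub, frag.orientation, comp_sub, frag.source_id)

    def query(self, target_subseq: str, orientation: str) -> List[Observation]:
        """Observations for a target subsequence, ordered by descending count
        then lexicographic complementary sequence."""
        if not (self.min_len <= len(target_subseq) <= self.max_len):
            raise ValueError(
                f"query length {len(target_subseq)} outside "
                f"[{self.min_len}, {self.max_len}]"
            )
        obs = self._index.get((target_subseq, orientation), {})
        out = [
            Observation(comp, rec[0], tuple(sorted(rec[1])))
            for comp, rec in obs.items()
        ]
        out.sort(key=lambda o: (-o.count, o.comp_subseq))
        return out

    def merge(self, other: "FragmentLibrary") -> None:
        if (self.min_len, self.max_len) != (other.min_len, other.max_len):
            raise ValueError("cannot merge libraries with different length bounds")
        for (t_sub, orientation), obs in other._index.items():
            for comp, rec in obs.items():
                node = self._index.setdefault((t_sub, orientation), {})
                mine = node.setdefault(comp, [0, set()])
                mine[0] += rec[0]
                mine[1] |= rec[1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target_subseq": t,
                "orientation": o,
                "comp_subseq": comp,
                "count": rec[0],
                "sources": ",".join(sorted(rec[1])),
            }
            for (t, o), obs in sorted(self._index.items())
            for comp, rec in sorted(obs.items())
        ]
        return pd.DataFrame(
            rows, columns=["target_subseq", "orientation", "comp_subseq", "count", "sources"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, min_len: int = 3, max_len: int = 9) -> "FragmentLibrary":
        df = pd.read_csv(path, sep="\t", dtype={"target_subseq": str, "comp_subseq": str})
        lib = cls(min_len=min_len, max_len=max_len)
        for row in df.itertuples(index=False):
            obs = lib._index.setdefault((row.target_subseq, row.orientation), {})
            obs[row.comp_subseq] = [int(row.count), set(str(row.sources).split(","))]
        return lib


def build_library(
    structures: Iterable[Structure],
    min_len: int = 3,
    max_len: int = 9,
    cutoff: float = HBOND_CUTOFF,
) -> FragmentLibrary:
    """Mine every structure for strand pairings and index all sub-windows.

    Counts are additive over input structures; fragments containing 'X'
    never enter the library.
    """
    lib = FragmentLibrary(min_len=min_len, max_len=max_len)
    n = 0
    for structure in structures:
        n += 1
        for frag in detect_strand_pairs(structure, min_len=min_len, cutoff=cutoff):
            lib.add_fragment(frag)
    if n == 0:
        warnings.warn("empty structure list: returning empty library", stacklevel=2)
    return lib
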