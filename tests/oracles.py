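"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with plain exhaustive loops, separate
from the package implementation, so agreement is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Dict, List, Optional, Tuple

import numpy as np

Q = 0.084 * 332.0
CUTOFF = -0.5


def _residue_table(structure):
    """[(chain_idx, pos, chain_id, seq_index, atoms-or-None)]"""
    table = []
    for ci, chain in enumerate(structure.chains):
        for pi, res in enumerate(chain.residues):
            atoms = res.atoms if all(a in res.atoms for a in ("N", "CA", "C", "O")) else None
            table.append((ci, pi, chain.chain_id, res.seq_index, atoms))
    return table


def brute_force_hbonds(structure) -> set:
    """All (donor, acceptor) pairs as ((chain_id, seq_index), ...) tuples with
    DSSP energy below -0.5 kcal/mol, computed with plain nested loops."""
    table = _residue_table(structure)
    # amide H per residue (needs previous residue consecutive in seq index)
    h = {}
    for ci, pi, cid, six, atoms in table:
        if atoms is None or pi == 0:
            continue
        prev = structure.chains[ci].residues[pi - 1]
        if prev.seq_index != six - 1 or not all(a in prev.atoms for a in ("N", "CA", "C", "O")):
            continue
        n, ca, cp = atoms["N"], atoms["CA"], prev.atoms["C"]
        u1 = (ca - n) / np.linalg.norm(ca - n)
        u2 = (cp - n) / np.linalg.norm(cp - n)
        d = -(u1 + u2)
        if np.linalg.norm(d) < 1e-9:
            continue
        h[(ci, pi)] = n + d / np.linalg.norm(d)

    bonds = set()
    for ci, pi, cid, six, atoms in table:
        if (ci, pi) not in h:
            continue
        for cj, pj, cjd, sjx, atj in table:
            if atj is None or (ci, pi) == (cj, pj):
                continue
            if ci == cj and abs(six - sjx) < 3:
                continue
            n, hpos = atoms["N"], h[(ci, pi)]
            c, o = atj["C"], atj["O"]
            r_on = np.linalg.norm(o - n)
            r_ch = np.linalg.norm(c - hpos)
            r_oh = np.linalg.norm(o - hpos)
            r_cn = np.linalg.norm(c - n)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e = Q * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if e < CUTOFF:
                bonds.add(((cid, six), (cjd, sjx)))
    return bonds


def brute_force_ladders(structure, min_len: int) -> set:
    """Exhaustive search over all contiguous residue-pair runs satisfying the
    hydrogen-bond-ladder definition; returns frozensets of paired loci
    {((chain, idx), (chain, idx)), ...} per accepted ladder, after the same
    longest-first conflict resolution."""
    table = _residue_table(structure)
    addr = {}  # (chain_id, seq_index) -> (ci, pi)
    for ci, pi, cid, six, atoms in table:
        addr[(cid, six)] = (ci, pi, atoms)
    bonds = brute_force_hbonds(structure)

    def shift(key, step):
        cid, six = key
        nxt = (cid, six + step)
        return nxt if nxt in addr else None

    votes: Dict[tuple, set] = {}

    def vote(x, y, orientation):
        if x is None or y is None:
            return
        a, b = sorted((x, y), key=lambda k: (addr[k][0], addr[k][1]))
        ai, bi = addr[a], addr[b]
        if ai[0] == bi[0] and abs(a[1] - b[1]) < 3:
            return
        diag = ai[1] + bi[1] if orientation == "antiparallel" else ai[1] - bi[1]
        votes.setdefault(((ai[0], bi[0]), orientation, diag), set()).add((a, b))

    for don, acc in bonds:
        vote(acc, don, "antiparallel")
        vote(shift(acc, +1), shift(don, -1), "antiparallel")
        vote(shift(acc, +1), don, "parallel")
        vote(shift(don, -1), acc, "parallel")

    candidates = []
    for (chainpair, orientation, _diag), pairs in votes.items():
        ordered = sorted(pairs, key=lambda ab: addr[ab[0]][1])
        # every maximal run of consecutive first-member positions
        runs, run = [], [ordered[0]]
        for pair in ordered[1:]:
            if addr[pair[0]][1] == addr[run[-1][0]][1] + 1:
                run.append(pair)
            else:
                runs.append(run)
                run = [pair]
        runs.append(run)
        for r in runs:
            members = {m for ab in r for m in ab}
            n_bonds = sum(1 for (d, a) in bonds if d in members and a in members)
            if len(r) >= min_len and n_bonds >= 2:
                candidates.append((r, orientation, n_bonds, chainpair))

    candidates.sort(
        key=lambda c: (-len(c[0]), -c[2], c[3], addr[c[0][0][0]][1])
    )
    claimed: Dict[tuple, set] = {}
    ladders = set()
    for run, orientation, _n, chainpair in candidates:
        members = {m for ab in run for m in ab}
        taken = claimed.setdefault(chainpair, set())
        if members & taken:
            continue
        taken |= members
        ladders.add(frozenset(tuple(sorted(ab)) for ab in run))
    return ladders


def brute_force_assemble(fragments, epitope_seq, overlap_min=2, max_candidates=10):
    """Exhaustive cascade enumeration.

    fragments: list of (start0, facing, comp_subseq, count, orientation).
    Returns ranked (paratope_seq, orientation, support, C, solubility) tuples
    using the same scoring definitions, computed here from first principles.
    """
    from abscan.cascade import solubility_score

    L = len(epitope_seq)
    results = {}

    def c_of(support):
        return sum(math.log10(1 + n) for n in support) / len(support)

    def emit(facing, support, orientation):
        paratope = facing if orientation == "parallel" else facing[::-1]
        key = paratope
        c = c_of(support)
        sol = solubility_score(paratope)
        prev = results.get(key)
        cand = (paratope, orientation, tuple(support), c, sol)
        if prev is None or (-c, -sol) < (-prev[3], -prev[4]):
            results[key] = cand

    def extend(covered, facing, support, orientation):
        if covered == L:
            emit(facing, support, orientation)
            return
        for (s0, ffac, _comp, count, orient) in fragments:
            if orient != orientation:
                continue
            if s0 > covered - overlap_min:
                continue
            end = s0 + len(ffac)
            if end <= covered:
                continue
            if facing[s0:covered] != ffac[: covered - s0]:
                continue
            sup = list(support) + [0] * (end - covered)
            for k in range(s0, end):
                sup[k] += count
            extend(end, facing + ffac[covered - s0 :], sup, orientation)

    for (s0, ffac, _comp, count, orient) in fragments:
        if s0 == 0:
            extend(len(ffac), ffac, [count] * len(ffac), orient)

    ranked = sorted(results.values(), key=lambda r: (-r[3], -r[4], r[0]))
    return ranked[:max_candidates]
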