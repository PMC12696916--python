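"""Epitope-window enumeration, validation and whole-sequence scanning.

Windows are 1-based inclusive on the target sequence.  A mask (set of
residue indices) excludes regions such as a disulfide-bonded N-terminus;
no window may intersect it.  Scanning runs the cascade on each window's
subsequence independently and keeps the top-ranked design per window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .cascade import CascadeParams, ParatopeDesign, cascade_assemble
from .mining import FragmentLibrary


def normalize_label(label: str) -> str:
    """Accept en-dash window labels (as printed) and normalize to ASCII hyphen."""
    return label.replace("–", "-")


@dataclass(frozen=True)
class EpitopeWindow:
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid window ({self.start}, {self.end})")

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_label(cls, label: str) -> "EpitopeWindow":
        start, end = normalize_label(label).split("-")
        return cls(int(start), int(end))


@dataclass
class Panel:
    target_id: str
    target_seq: str
    designs: List[Tuple[EpitopeWindow, Optional[ParatopeDesign]]]
    mask: FrozenSet[int] = frozenset()

    @property
    def n_designed(self) -> int:
        return sum(1 for _, d in self.designs if d is not None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w, d in self.designs:
            rows.append(
                {
                    "window": w.label,
                    "epitope_seq": self.target_seq[w.start - 1 : w.end],
                    "paratope_seq": d.paratope_seq if d else "",
                    "orientation": d.orientation if d else "",
                    "c_score": round(d.c_score, 6) if d else float("nan"),
                    "solubility": round(d.solubility, 6) if d else float("nan"),
                    "support": ",".join(map(str, d.support)) if d else "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "window", "epitope_seq", "paratope_seq", "orientation",
                "c_score", "solubility", "support",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def enumerate_windows(
    target_len: int,
    mask: Iterable[int] = (),
    min_len: int = 7,
    max_len: int = 9,
    step: int = 3,
) -> List[EpitopeWindow]:
    """Tile the unmasked target with windows of min_len advancing by step; the
    final window stretches (up to max_len) to end exactly at the last residue."""
    if target_len < min_len:
        raise ValueError("target shorter than the minimum window length")
    mask = frozenset(mask)
    unmasked = [i for i in range(1, target_len + 1) if i not in mask]
    if not unmasked:
        warnings.warn("target fully masked: no windows", stacklevel=2)
        return []
    first = unmasked[0]
    windows: List[EpitopeWindow] = []
    for start in range(first, target_len + 1, step):
        end = start + min_len - 1
        if end > target_len:
            break
        windows.append(EpitopeWindow(start, end))
    if windows:
        last = windows[-1]
        if last.end < target_len and target_len - last.start + 1 <= max_len:
            windows[-1] = EpitopeWindow(last.start, target_len)
    windows = [w for w in windows if not (set(range(w.start, w.end + 1)) & mask)]
    if not windows:
        warnings.warn("unmasked region shorter than min_len: no windows", stacklevel=2)
    return windows


def validate_windows(
    windows: Sequence[EpitopeWindow],
    target_len: int,
    mask: Iterable[int] = (),
) -> List[EpitopeWindow]:
    """Reject windows out of target range or intersecting the mask."""
    mask = frozenset(mask)
    offending = []
    for w in windows:
        if w.end > target_len:
            offending.append(f"{w.label} (out of range for target length {target_len})")
        elif set(range(w.start, w.end + 1)) & mask:
            offending.append(f"{w.label} (intersects mask)")
    if offending:
        raise ValueError("invalid windows: " + "; ".join(offending))
    return list(windows)


def scan(
    target_seq: str,
    windows: Sequence[EpitopeWindow],
    lib: FragmentLibrary,
    params: CascadeParams = CascadeParams(),
    target_id: str = "target",
    mask: Iterable[int] = (),
) -> Panel:
    """Run the cascade per window and keep the top design; windows that fail
    or have no feasible design carry None without aborting the others."""
    designs: List[Tuple[EpitopeWindow, Optional[ParatopeDesign]]] = []
    for w in windows:
        epitope = target_seq[w.start - 1 : w.end]
        try:
            candidates = cascade_assemble(lib, epitope, params, window=(w.start, w.end))
        except ValueError as exc:
            warnings.warn(f"window {w.label}: {exc}", stacklevel=2)
            candidates = []
        designs.append((w, candidates[0] if candidates else None))
    return Panel(target_id, target_seq, designs, frozenset(mask))
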