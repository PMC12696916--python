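"""Packaged fixtures: the IAPP target, scaffold templates, and the planted
ideal-sheet generator that makes the full pipeline testable offline.

The fixture generator builds, for each epitope window, an ideal two-strand
sheet whose first strand carries the epitope subsequence and whose second
strand is a randomly drawn complementary peptide.  Mining those sheets must
recover exactly the planted (epitope fragment -> complementary fragment)
pairs, which the manifest records for test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .graft import ScaffoldTemplate
from .scan import EpitopeWindow
from .sheets import ANTIPARALLEL, PARALLEL, SheetSpec, StrandSpec, build_ideal_sheet
from .structures import AA20, Structure, write_pdb

# the nine epitope windows scanning IAPP (N-terminal disulfide region masked)
IAPP_WINDOWS: Tuple[Tuple[int, int], ...] = (
    (9, 17), (12, 18), (15, 22), (19, 26), (20, 28),
    (22, 29), (26, 32), (26, 34), (30, 37),
)
# Cys2-Cys7 disulfide region: residues 1-8 are never scanned
IAPP_MASK: FrozenSet[int] = frozenset(range(1, 9))


def load_iapp() -> Tuple[str, str]:
    """(record id, sequence) of the packaged 37-residue mature human IAPP."""
    with resources.files("abscan").joinpath("data/iapp.fasta").open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return record.id, str(record.seq)


def load_template(name_or_path) -> ScaffoldTemplate:
    """Load a scaffold template: 'sdab'/'monobody' for the packaged examples,
    or a path to a YAML template file."""
    packaged = {"sdab": "sdab_scaffold.yaml", "monobody": "monobody_scaffold.yaml"}
    key = str(name_or_path)
    if key in packaged:
        with resources.as_file(
            resources.files("abscan").joinpath(f"data/{packaged[key]}")
        ) as path:
            return ScaffoldTemplate.from_yaml(path)
    return ScaffoldTemplate.from_yaml(name_or_path)


@dataclass(frozen=True)
class PlantedPair:
    """Ground truth for one fixture sheet: the epitope-side fragment, the
    complementary strand (N->C), and the orientation."""

    sheet_id: str
    window: Tuple[int, int]
    target_subseq: str
    comp_seq: str
    orientation: str


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def plant_sheet(
    target_subseq: str,
    comp_seq: str,
    orientation: str = ANTIPARALLEL,
    sheet_id: str = "planted",
) -> SheetSpec:
    """Two-strand sheet spec pairing a target fragment with a chosen
    complementary peptide over the full fragment length."""
    if len(comp_seq) != len(target_subseq):
        raise ValueError("complementary strand must match the target length")
    return SheetSpec(
        strands=[
            StrandSpec(target_subseq),
            StrandSpec(comp_seq, orientation_vs_first=orientation, register_offset=0),
        ],
        sheet_id=sheet_id,
    )


def generate_planted_fixtures(
    target_seq: str,
    windows: Sequence[Tuple[int, int]] = IAPP_WINDOWS,
    seed: int = 0,
    orientation: str = ANTIPARALLEL,
) -> Tuple[List[Structure], List[PlantedPair]]:
    """One ideal sheet per epitope window with a random planted complement."""
    rng = np.random.default_rng(seed)
    structures: List[Structure] = []
    truth: List[PlantedPair] = []
    for start, end in windows:
        epitope = target_seq[start - 1 : end]
        comp = random_peptide(rng, len(epitope))
        sheet_id = f"fixture_{start}_{end}"
        spec = plant_sheet(epitope, comp, orientation, sheet_id=sheet_id)
        structures.append(build_ideal_sheet(spec))
        truth.append(PlantedPair(sheet_id, (start, end), epitope, comp, orientation))
    return structures, truth


def manifest_frame(truth: Sequence[PlantedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sheet_id": p.sheet_id,
                "window": f"{p.window[0]}-{p.window[1]}",
                "target_subseq": p.target_subseq,
                "comp_seq": p.comp_seq,
                "orientation": p.orientation,
            }
            for p in truth
        ]
    )


def write_fixtures(
    out_dir,
    target_seq: Optional[str] = None,
    windows: Sequence[Tuple[int, int]] = IAPP_WINDOWS,
    seed: int = 0,
    orientation: str = ANTIPARALLEL,
    force: bool = False,
) -> Tuple[List[Path], Path]:
    """Write planted-sheet PDB files plus a planted-truth manifest TSV."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out_dir} is not empty (use force to overwrite)"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    if target_seq is None:
        _, target_seq = load_iapp()
    structures, truth = generate_planted_fixtures(target_seq, windows, seed, orientation)
    paths = []
    for st in structures:
        path = out_dir / f"{st.structure_id}.pdb"
        write_pdb(st, path)
        paths.append(path)
    manifest_path = out_dir / "manifest.tsv"
    manifest_frame(truth).to_csv(manifest_path, sep="\t", index=False)
    return paths, manifest_path
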