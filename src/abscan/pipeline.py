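"""Run configuration and the end-to-end pipeline: mine -> library -> scan -> graft."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, List, Optional, Sequence, Tuple

import yaml

from . import fixtures as fx
from .cascade import CascadeParams
from .graft import (
    Construct,
    build_panel_constructs,
    constructs_to_fasta,
    constructs_to_frame,
    substitute_cysteines,
)
from .mining import HBOND_CUTOFF, FragmentLibrary, build_library
from .scan import EpitopeWindow, Panel, scan, validate_windows
from .structures import Structure, read_pdb


def parse_mask(spec: str) -> FrozenSet[int]:
    """Parse '1-8' or '1-8,12' into a set of residue indices."""
    out = set()
    spec = spec.strip()
    if not spec:
        return frozenset()
    for part in spec.split(","):
        if "-" in part:
            lo, hi = part.split("-")
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(part))
    return frozenset(out)


def read_windows_file(path) -> List[EpitopeWindow]:
    """Two-column text (start, end) window list; '#' comments allowed."""
    windows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        start, end = line.replace(",", " ").split()[:2]
        windows.append(EpitopeWindow(int(start), int(end)))
    return windows


@dataclass
class RunConfig:
    structure_paths: Tuple[str, ...] = ()
    fixture_seed: Optional[int] = None  # generate planted fixtures instead of reading
    min_len: int = 3
    max_len: int = 9
    hbond_cutoff: float = HBOND_CUTOFF
    overlap_min: int = 2
    beam_width: int = 64
    max_candidates: int = 10
    windows: Tuple[Tuple[int, int], ...] = fx.IAPP_WINDOWS
    mask: FrozenSet[int] = fx.IAPP_MASK
    target_fasta: Optional[str] = None  # default: packaged IAPP
    scaffold: str = "sdab"
    cys_scheme: str = "AA"
    graft_site: str = "CDR3"
    graft_mode: str = "core"
    out_dir: str = "abscan_out"
    strict: bool = False

    def __post_init__(self) -> None:
        if not (2 <= self.min_len <= self.max_len):
            raise ValueError("need max_len >= min_len >= 2")
        if self.hbond_cutoff >= 0:
            raise ValueError("hbond_cutoff must be negative (kcal/mol)")

    @property
    def cascade_params(self) -> CascadeParams:
        return CascadeParams(
            min_frag_len=self.min_len,
            overlap_min=self.overlap_min,
            beam_width=self.beam_width,
            max_candidates=self.max_candidates,
        )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        if "windows" in cfg:
            cfg["windows"] = tuple((int(s), int(e)) for s, e in cfg["windows"])
        if "mask" in cfg and isinstance(cfg["mask"], str):
            cfg["mask"] = parse_mask(cfg["mask"])
        if "structure_paths" in cfg:
            cfg["structure_paths"] = tuple(cfg["structure_paths"])
        return cls(**cfg)


@dataclass
class PipelineResult:
    library: FragmentLibrary
    panel: Panel
    constructs: List[Construct]
    out_dir: Path


def load_target(config: RunConfig) -> Tuple[str, str]:
    if config.target_fasta is None:
        return fx.load_iapp()
    from Bio import SeqIO

    record = next(SeqIO.parse(config.target_fasta, "fasta"))
    return record.id, str(record.seq)


def gather_structures(config: RunConfig, target_seq: str) -> List[Structure]:
    if config.fixture_seed is not None:
        structures, _truth = fx.generate_planted_fixtures(
            target_seq, config.windows, seed=config.fixture_seed
        )
        return structures
    if not config.structure_paths:
        raise ValueError("mining stage: no structures given (paths or fixture_seed)")
    return [read_pdb(p) for p in config.structure_paths]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Mine structures, build the library, scan the target and graft the panel,
    writing library/panel TSVs and the construct FASTA + manifest."""
    target_id, target_seq = load_target(config)
    structures = gather_structures(config, target_seq)
    library = build_library(
        structures, min_len=config.min_len, max_len=config.max_len,
        cutoff=config.hbond_cutoff,
    )
    windows = validate_windows(
        [EpitopeWindow(s, e) for s, e in config.windows], len(target_seq), config.mask
    )
    panel = scan(
        target_seq, windows, library, config.cascade_params,
        target_id=target_id, mask=config.mask,
    )
    template = fx.load_template(config.scaffold)
    if template.kind == "sdab":
        template = substitute_cysteines(template, config.cys_scheme)
    constructs = build_panel_constructs(
        panel, template, site=config.graft_site, mode=config.graft_mode
    )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    library.to_tsv(out_dir / "library.tsv")
    panel.to_tsv(out_dir / "panel.tsv")
    constructs_to_fasta(constructs, out_dir / "constructs.fasta")
    constructs_to_frame(constructs).to_csv(
        out_dir / "constructs.tsv", sep="\t", index=False
    )

    if config.strict and panel.n_designed < len(windows):
        missing = [w.label for w, d in panel.designs if d is None]
        raise RuntimeError(f"strict mode: windows without designs: {missing}")
    return PipelineResult(library, panel, constructs, out_dir)
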