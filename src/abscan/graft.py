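"""Scaffold engineering grammar: cysteine substitution, N-terminal truncation,
loop replacement and paratope grafting on configurable templates.

Two template kinds are supported: a single-domain antibody (sdAb) whose CDR3
loop receives designed paratopes and whose conserved Cys23/Cys97 disulfide
can be substituted away (C23A/C97A or C23A/C97V), and a fibronectin-III
monobody binding through its BC and FG loops.  Every construct carries an
ordered edit list; replaying the edits on the template reproduces the
construct sequence exactly, and construct names follow the printed
conventions ("N-8-FETLTLR(BC)-AAAAS(FG)", "DesAb_9-17", ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .cascade import make_negative_control
from .scan import Panel, normalize_label
from .structures import AA20

SDAB = "sdab"
MONOBODY = "monobody"

FULL_LOOP_PREFIX = "GS"
FULL_LOOP_SUFFIX = "EEE"


@dataclass(frozen=True)
class EditRecord:
    kind: str  # substitute | truncate_n | replace_loop | graft
    site: Optional[str]
    position: Optional[int]  # 1-based, in current template coordinates
    before: str
    after: str


@dataclass(frozen=True)
class ScaffoldTemplate:
    name: str
    kind: str  # sdab | monobody
    sequence: str
    sites: Dict[str, Tuple[int, int]]  # site -> (start, end), 1-based inclusive
    numbered_residues: Dict[str, int] = field(default_factory=dict)
    numbering_offset: int = 0
    n_terminal_region: Optional[Tuple[int, int]] = None
    edits: Tuple[EditRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (SDAB, MONOBODY):
            raise ValueError(f"unknown scaffold kind {self.kind!r}")
        bad = set(self.sequence) - set(AA20)
        if bad:
            raise ValueError(f"template sequence has invalid letters: {sorted(bad)}")
        spans = sorted(self.sites.values())
        for (s, e) in spans:
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(f"site ({s}, {e}) out of sequence bounds")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("sites must not overlap")
        if not self.edits:  # unedited template: numbered Cys labels must hold
            for label, idx in self.numbered_residues.items():
                if label.startswith("C") and self.sequence[idx - 1] != "C":
                    raise ValueError(
                        f"numbered residue {label} points at "
                        f"{self.sequence[idx - 1]!r}, expected 'C'"
                    )

    def resolve(self, label: str) -> int:
        """Raw 1-based index of a numbered residue label."""
        return self.numbered_residues[label]

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScaffoldTemplate":
        offset = int(cfg.get("numbering_offset", 0))
        numbered = {
            str(k): int(v) + offset for k, v in (cfg.get("numbered_residues") or {}).items()
        }
        ntr = cfg.get("n_terminal_region")
        return cls(
            name=cfg["name"],
            kind=cfg.get("kind", MONOBODY),
            sequence=cfg["sequence"],
            sites={str(k): (int(v[0]), int(v[1])) for k, v in cfg["sites"].items()},
            numbered_residues=numbered,
            numbering_offset=offset,
            n_terminal_region=tuple(ntr) if ntr else None,
        )

    @classmethod
    def from_yaml(cls, path) -> "ScaffoldTemplate":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class Construct:
    name: str
    sequence: str
    template_name: str
    edits: Tuple[EditRecord, ...]


def _apply_edit(sequence: str, sites: Dict[str, Tuple[int, int]],
                numbered: Dict[str, int], edit: EditRecord):
    """Apply one edit to (sequence, sites, numbered), returning updated copies."""
    sites = dict(sites)
    numbered = dict(numbered)
    if edit.kind == "substitute":
        pos = edit.position
        if sequence[pos - 1] != edit.before:
            raise ValueError(
                f"substitution expects {edit.before!r} at position {pos}, "
                f"found {sequence[pos - 1]!r}"
            )
        sequence = sequence[: pos - 1] + edit.after + sequence[pos:]
    elif edit.kind == "truncate_n":
        n = len(edit.before)
        if sequence[:n] != edit.before:
            raise ValueError("truncation prefix does not match sequence")
        sequence = sequence[n:]
        sites = {k: (s - n, e - n) for k, (s, e) in sites.items()}
        numbered = {k: v - n for k, v in numbered.items()}
    elif edit.kind in ("replace_loop", "graft"):
        s, e = sites[edit.site]
        if sequence[s - 1 : e] != edit.before:
            raise ValueError(f"site {edit.site} content does not match edit record")
        sequence = sequence[: s - 1] + edit.after + sequence[e:]
        delta = len(edit.after) - len(edit.before)
        sites[edit.site] = (s, e + delta)
        for k, (ks, ke) in sites.items():
            if ks > e:
                sites[k] = (ks + delta, ke + delta)
        for k, v in numbered.items():
            if v > e:
                numbered[k] = v + delta
    else:
        raise ValueError(f"unknown edit kind {edit.kind!r}")
    return sequence, sites, numbered


def replay_edits(template: ScaffoldTemplate, edits: Sequence[EditRecord]) -> str:
    """Reapply an edit list to the (unedited) template; returns the sequence."""
    seq, sites, numbered = template.sequence, template.sites, template.numbered_residues
    for edit in edits:
        seq, sites, numbered = _apply_edit(seq, sites, numbered, edit)
    return seq


def _edited(template: ScaffoldTemplate, edit: EditRecord) -> ScaffoldTemplate:
    seq, sites, numbered = _apply_edit(
        template.sequence, template.sites, template.numbered_residues, edit
    )
    ntr = template.n_terminal_region
    if edit.kind == "truncate_n" and ntr is not None:
        n = len(edit.before)
        ntr = (1, max(ntr[1] - n, 0)) if ntr[1] > n else None
    return replace(
        template,
        sequence=seq,
        sites=sites,
        numbered_residues=numbered,
        n_terminal_region=ntr,
        edits=template.edits + (edit,),
    )


CYS_SCHEMES = {"AA": ("A", "A"), "AV": ("A", "V")}


def substitute_cysteines(template: ScaffoldTemplate, scheme: str) -> ScaffoldTemplate:
    """Remove the conserved sdAb disulfide: C23/C97 -> A/A or A/V."""
    if scheme not in CYS_SCHEMES:
        raise ValueError(f"scheme must be one of {sorted(CYS_SCHEMES)}")
    aa23, aa97 = CYS_SCHEMES[scheme]
    out = template
    for label, new_aa in (("C23", aa23), ("C97", aa97)):
        pos = out.resolve(label)
        if out.sequence[pos - 1] != "C":
            raise ValueError(
                f"residue at {label} (index {pos}) is {out.sequence[pos - 1]!r}, "
                "not 'C' — template misconfigured or already substituted"
            )
        out = _edited(out, EditRecord("substitute", label, pos, "C", new_aa))
    return out


def truncate_n_terminus(template: ScaffoldTemplate, n: int) -> ScaffoldTemplate:
    """Remove the first n residues, shifting all site/numbered indices by -n."""
    earliest = min(s for s, _ in template.sites.values())
    if not (1 <= n < earliest):
        raise ValueError(
            f"truncation of {n} residues reaches the earliest site (start {earliest})"
        )
    return _edited(
        template, EditRecord("truncate_n", None, 1, template.sequence[:n], "")
    )


def replace_loop(template: ScaffoldTemplate, site: str, seq: str) -> ScaffoldTemplate:
    """Replace a loop site with a new sequence, updating downstream indices."""
    if site not in template.sites:
        raise ValueError(f"unknown site {site!r}")
    if not seq or set(seq) - set(AA20):
        raise ValueError("replacement sequence must be non-empty standard letters")
    s, e = template.sites[site]
    return _edited(
        template, EditRecord("replace_loop", site, s, template.sequence[s - 1 : e], seq)
    )


def graft(
    template: ScaffoldTemplate,
    site: str,
    insert: str,
    mode: str = "core",
    name: Optional[str] = None,
) -> Construct:
    """Graft a designed paratope into a loop site.

    mode="core" replaces the site by the insert itself; mode="full_loop"
    embeds it in the canonical designed-CDR3 flanks GS...EEE.
    """
    if site not in template.sites:
        raise ValueError(f"unknown site {site!r}")
    if not insert or set(insert) - set(AA20):
        raise ValueError("insert must be non-empty standard letters")
    if mode not in ("core", "full_loop"):
        raise ValueError("mode must be 'core' or 'full_loop'")
    effective = insert if mode == "core" else FULL_LOOP_PREFIX + insert + FULL_LOOP_SUFFIX
    s, e = template.sites[site]
    edit = EditRecord("graft", site, s, template.sequence[s - 1 : e], effective)
    edited = _edited(template, edit)
    return Construct(
        name=name or make_name(edited.edits, template.kind),
        sequence=edited.sequence,
        template_name=template.name,
        edits=edited.edits,
    )


def make_name(
    edits: Sequence[EditRecord],
    kind: str,
    window_label: Optional[str] = None,
) -> str:
    """Canonical construct name derived from the edit list.

    Monobody: "<N-k->?<BCtoken>(BC)-<FGtoken>(FG)" with "wt" for untouched
    loops; sdAb: "DesAb_<start>-<end>" for panel grafts (window label given)
    or "<insert>_<cys suffix>" for engineering variants.
    """
    cys = "".join(
        f"{e.site}{e.after}" for e in edits if e.kind == "substitute"
    )
    trunc = next((len(e.before) for e in edits if e.kind == "truncate_n"), None)
    loops: Dict[str, str] = {}
    for e in edits:
        if e.kind in ("replace_loop", "graft") and e.site is not None:
            loops[e.site] = e.after

    if kind == MONOBODY:
        prefix = f"N-{trunc}-" if trunc else ""
        bc = loops.get("BC", "wt")
        fg = loops.get("FG", "wt")
        return f"{prefix}{bc}(BC)-{fg}(FG)"

    if window_label is not None:
        return f"DesAb_{normalize_label(window_label)}"
    graft_edit = next((e for e in edits if e.kind == "graft"), None)
    if graft_edit is not None:
        insert = graft_edit.after
        if insert.startswith(FULL_LOOP_PREFIX) and insert.endswith(FULL_LOOP_SUFFIX):
            core = insert[len(FULL_LOOP_PREFIX) : -len(FULL_LOOP_SUFFIX)]
            insert = core or insert
        return f"{insert}_{cys}" if cys else insert
    return cys


_MONOBODY_NAME = re.compile(r"^(?:N-(\d+)-)?(.+)\(BC\)-(.+)\(FG\)$")
_DESAB_NAME = re.compile(r"^DesAb_(neg|\d+-\d+)$")
_SDAB_VARIANT = re.compile(r"^(?:(.+)_)?(C23[AV]C97[AV])$")


def parse_name(name: str) -> dict:
    """Parse a construct name back to its edit summary (en-dash accepted)."""
    name = normalize_label(name)
    m = _MONOBODY_NAME.match(name)
    if m:
        out = {"scaffold": MONOBODY, "bc": m.group(2), "fg": m.group(3)}
        if m.group(1):
            out["truncate_n"] = int(m.group(1))
        return out
    m = _DESAB_NAME.match(name)
    if m:
        if m.group(1) == "neg":
            return {"scaffold": SDAB, "window": "neg"}
        start, end = m.group(1).split("-")
        return {"scaffold": SDAB, "window": (int(start), int(end))}
    m = _SDAB_VARIANT.match(name)
    if m:
        out = {"scaffold": SDAB, "cys_scheme": "AA" if m.group(2).endswith("A") else "AV"}
        if m.group(1):
            out["insert"] = m.group(1)
        return out
    raise ValueError(f"unparseable construct name {name!r}")


def enumerate_variants(
    template: ScaffoldTemplate,
    inserts: Sequence[str],
    sites: Sequence[str],
    mode: str = "core",
) -> List[Construct]:
    """Cartesian product of sites x inserts, one graft per construct
    (site-major order); duplicate names are an error."""
    if not inserts or not sites:
        raise ValueError("inserts and sites must be non-empty")
    constructs = [
        graft(template, site, insert, mode=mode)
        for site in sites
        for insert in inserts
    ]
    names = [c.name for c in constructs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate construct names: {dupes}")
    return constructs


def build_panel_constructs(
    panel: Panel,
    template: ScaffoldTemplate,
    site: str = "CDR3",
    mode: str = "core",
    negative_length: int = 9,
) -> List[Construct]:
    """One construct per panel design plus the negative control (DesAb_neg).

    For an sdAb template the conserved cysteines must already be substituted
    (no 'C' at the numbered positions).
    """
    if not panel.designs:
        raise ValueError("panel is empty")
    if template.kind == SDAB:
        for label in ("C23", "C97"):
            if label in template.numbered_residues:
                pos = template.resolve(label)
                if template.sequence[pos - 1] == "C":
                    raise ValueError(
                        "sdAb template still has a cysteine at "
                        f"{label}; apply substitute_cysteines first"
                    )
    constructs = []
    for window, design in panel.designs:
        if design is None:
            continue
        constructs.append(
            graft(template, site, design.paratope_seq, mode=mode,
                  name=f"DesAb_{window.label}")
        )
    constructs.append(
        graft(template, site, make_negative_control(negative_length), mode=mode,
              name="DesAb_neg")
    )
    return constructs


def constructs_to_fasta(constructs: Sequence[Construct], path) -> None:
    """Write one FASTA record per construct, headers = names."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description="") for c in constructs
    ]
    seqio_write(records, str(path), "fasta")


def constructs_to_frame(constructs: Sequence[Construct]):
    import pandas as pd

    rows = [
        {
            "name": c.name,
            "length": len(c.sequence),
            "template": c.template_name,
            "edits": ";".join(
                f"{e.kind}:{e.site or e.position}:{e.before}>{e.after}" for e in c.edits
            ),
            "sequence": c.sequence,
        }
        for c in constructs
    ]
    return pd.DataFrame(rows, columns=["name", "length", "template", "edits", "sequence"])
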