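# abscan

Rational antibody scanning by complementary-peptide design.

`abscan` implements a fragment-based ("cascade") workflow for designing
antibody-like binders against linear epitopes of an amyloidogenic target —
here the 37-residue islet amyloid polypeptide (IAPP/amylin), whose
aggregation is implicated in type 2 diabetes.  It is aimed at protein
engineers and structural bioinformaticians who want sequence-ready construct
panels scanning a target sequence:

1. **Mine** protein structures (PDB format) for short peptide fragments that
   pair in β-strand geometry, using the DSSP electrostatic hydrogen-bond
   criterion (E < −0.5 kcal/mol on reconstructed backbone N–H···O=C
   interactions) and hydrogen-bond-ladder detection of strand pairings.
2. **Index** every paired sub-fragment in a queryable library:
   (target-side subsequence, orientation) → observed complementary fragments
   with counts.
3. **Assemble** a complementary peptide (paratope) for an epitope by linking
   overlapping library fragments that agree exactly on their overlaps, and
   rank candidates by a complementarity score
   C = (1/L) Σᵢ log₁₀(1 + nᵢ) — nᵢ the structural evidence supporting
   position i — and by an intrinsic solubility score (charge-weighted,
   smoothed Kyte–Doolittle profile; higher = more soluble).
4. **Scan** the target with epitope windows (the nine IAPP windows 9–17 …
   30–37 are built in; residues 1–8 are masked for the Cys2–Cys7 disulfide)
   and keep the best design per window.
5. **Graft** the designs into scaffold templates: a single-domain antibody
   (sdAb) whose conserved Cys23/Cys97 disulfide is substituted away
   (C23A/C97A or C23A/C97V) before the paratope is grafted onto the CDR3
   loop, or a fibronectin-III monobody engineered through its BC/FG loops,
   N-terminal truncation and loop shortening — with canonical construct
   names such as `N-8-FETLTLR(BC)-AAAAS(FG)` and `DesAb_9-17`, plus the
   non-binding control `DesAb_neg` (loop `SGAAAGSGS`).

No structure downloads are required: a deterministic ideal-β-sheet generator
produces synthetic sheets with known pairing (planted complements), so the
whole pipeline runs and is tested offline.  The shipped scaffold templates
are documented synthetic stand-ins; exact scaffold sequences can be supplied
through the same YAML schema.

## Worked example

```python
from abscan import build_library, cascade_assemble
from abscan.fixtures import generate_planted_fixtures, load_iapp

_, iapp = load_iapp()                       # KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY
structures, truth = generate_planted_fixtures(iapp, seed=1)
lib = build_library(structures)
print("library keys:", lib.n_keys, "total count:", lib.total_count)
for d in cascade_assemble(lib, iapp[8:17]):  # epitope window 9-17, TQRLANFLV
    print(d.paratope_seq, d.orientation, round(d.c_score, 4),
          round(d.solubility, 4), d.support)
```

prints

```
library keys: 128 total count: 198
LMSYADTWF antiparallel 0.7124 0.0447 (7, 7, 7, 6, 5, 4, 3, 2, 1)
```

The designed 9-mer `LMSYADTWF` is exactly the complementary strand planted
opposite epitope 9–17 in the seed-1 fixtures (`truth[0].comp_seq`).  Its
support vector counts the library fragments backing each epitope position
(position 1 is covered by seven overlapping sub-fragments, the final
position only by the full-length fragment), giving C = 0.7124; the
solubility score 0.0447 is the mean of the smoothed hydropathy/charge
profile.

The same run from the shell:

```sh
abscan pipeline --fixture-seed 1 --out-dir out/
```

writes `library.tsv`, `panel.tsv` (nine windows, one design each) and
`constructs.fasta` / `constructs.tsv` (ten records: `DesAb_9-17` …
`DesAb_30-37` plus `DesAb_neg`), grafted onto the C23A/C97A-substituted sdAb
template.  `abscan fixtures`, `mine`, `design`, `scan` and `graft` expose the
individual stages.

## Layout

- `abscan.structures` — backbone structure model, PDB reader/writer (gemmi)
- `abscan.sheets` — ideal β-sheet generator (the synthetic-data source)
- `abscan.mining` — H-bond detection, strand pairing, fragment library
- `abscan.cascade` — paratope assembly, C score, solubility, negative control
- `abscan.scan` — epitope windows, validation, panel scanning
- `abscan.graft` — scaffold templates, edits, naming, FASTA emission
- `abscan.pipeline` / `abscan.cli` — run configuration and the `abscan` CLI

See `docs/methods.md` for the model, parameter defaults and limitations.
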