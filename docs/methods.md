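# Methods

## Scope and model

`abscan` designs complementary peptides (paratopes) for linear epitopes of a
target sequence by re-using β-strand pairing evidence observed in protein
structures, then grafts them into antibody-like scaffolds.  The underlying
assumption is the one behind β-strand-mediated binder design: a peptide that
has been observed facing a given sequence motif in a β-sheet is a plausible
complement for that motif in a designed binder, and complements for
overlapping motifs can be chained into a full-length paratope.  Everything
downstream of the input structures is deterministic; the only randomness in
the package is in the synthetic fixture generator.

## Hydrogen bonds and strand pairing

Backbone hydrogen bonds use the DSSP electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

with a bond assigned when E < −0.5 kcal/mol (`hbond_cutoff`, configurable).
Amide hydrogens are not read from input; the H is rebuilt 1 Å from N along
the bisector pointing away from CA and the preceding residue's carbonyl
carbon, so the first residue of a chain can never donate.  Within a chain a
separation |i−j| ≥ 3 is required, which excludes helical and tight-turn
contacts.

Strand pairings are derived from the two DSSP bridge patterns.  Each bond
CO(A)···HN(D) supports the antiparallel residue pairs {A, D} and
{A+1, D−1} and the parallel pairs {A+1, D} and {D−1, A}.  Supported pairs
sharing a pairing diagonal are merged into maximal consecutive runs; a run is
kept when it spans at least `min_len` (default 3) residues and contains at
least two inter-strand hydrogen bonds — a single isolated bond never seeds a
fragment.  Deriving pairs from both bridge patterns (rather than from DSSP
bridges directly) lets chain-terminal residue pairs, which DSSP cannot label
because the patterns reference i±1, join the ladder their neighbours support;
on ideal sheets the detected pairing then covers the full strand overlap.
Overlapping runs on the same chain pair (e.g. the short spurious
parallel-pattern echoes of a strong antiparallel ladder) are resolved
greedily, longest run first.  Orientation is assigned from the chains' own
N→C direction vectors: the sum over paired residues of the dot products of
CA(i+1)−CA(i) steps, ≥ 0 parallel, < 0 antiparallel.  β-bulges and
bifurcated bonds are out of scope.

## Fragment library

Every contiguous sub-window (lengths `min_len`..`max_len`, default 3..9 —
spanning the 7–9-residue epitope windows used for scanning) of every paired
fragment is indexed under its target-side subsequence and orientation.
Complementary subsequences are stored N→C of their own chain; "facing" order
(aligned along the target) is the reverse for antiparallel pairs.  Counts
accumulate over identical (target, complement, orientation) observations, so
the library of a union of structure sets is the sum of the libraries.
Fragments containing the nonstandard-residue placeholder 'X' are never
indexed.  Both pairing orientations are mined; antiparallel is the common
case in practice and is searched first.

## Cascade assembly

For an epitope of length L, candidate paratopes are assembled per
orientation in facing space.  Seeds are library fragments matching an
epitope prefix; an extension fragment must start inside the covered region,
overlap it by at least `overlap_min` (default 2) positions, agree exactly
with the residues already placed, and extend coverage.  A candidate is
complete when all L positions are covered.  The search is breadth-limited to
`beam_width` (default 64) partial states per coverage level, ranked by the
running C score; on the small libraries used in tests this is exhaustive
(verified against brute-force enumeration), and the beam only matters for
very dense libraries.  Exact-agreement linking and the minimum overlap are
the smallest rules that make assembly well-posed; mixed-orientation
candidates are disallowed.

Position support nᵢ is the sum of the counts of the used fragments covering
position i; the complementarity score is C = (1/L) Σ log₁₀(1 + nᵢ), chosen
to be 0 with no support and strictly monotone in evidence.  Candidates are
de-duplicated by peptide sequence (keeping the best-supported assembly) and
ranked by C, then solubility, then lexicographically; at most
`max_candidates` (default 10) are returned.  The emitted `paratope_seq` is
N→C of the designed peptide, so a single-fragment design reproduces the
library fragment verbatim in both orientations.

The solubility score is an intentionally simplified intrinsic profile, not a
reimplementation of any published predictor: per residue
z = 0.6·(−H/4.5) + 0.4·q with H the Kyte–Doolittle hydropathy (from
Biopython) and q = 1 for D/E/K/R else 0, smoothed by a centered moving
average of width min(7, length) (forced odd) and averaged.  It is used only
for ranking; its absolute values carry no calibrated meaning.

## Epitope windows and scanning

Windows are 1-based inclusive.  The nine IAPP windows (9–17, 12–18, 15–22,
19–26, 20–28, 22–29, 26–32, 26–34, 30–37) are irregular in length and step
and are therefore first-class input; auto-enumeration (length 7, step 3,
final window stretched to at most 9 to end at the target C-terminus) is a
convenience that reproduces a comparable tiling.  The mask is a set of
residue indices no window may touch; for IAPP it is 1–8, covering the
Cys2–Cys7 disulfide region.  The shipped target is the canonical 37-residue
mature human IAPP (UniProt P10997 residues 34–70).  Scanning runs the
cascade per window independently (failures are per-window, not global) and
keeps the top design; window order permutes the panel and nothing else.

## Scaffold grammar

Templates are YAML documents: sequence, named loop sites (1-based inclusive,
non-overlapping), numbered residues resolved through `numbering_offset`
(covering scaffolds whose literature numbering differs from the raw index),
and an N-terminal region.  Edits are applied in the canonical order
truncate → substitute → replace_loop → graft, and every construct stores its
edit list; replaying the list on the unedited template must reproduce the
construct byte-for-byte (tested).  Cysteine substitution (schemes AA and AV
at C23/C97) refuses templates whose numbered positions do not hold cysteine,
which also catches double application.  Grafting is `core` (the designed
peptide replaces the site) or `full_loop` (embedded in the GS…EEE designed
CDR3 flanks).  Monobody names follow
`<N-k->?<BCtoken>(BC)-<FGtoken>(FG)` with `wt` for untouched loops; sdAb
panel constructs are `DesAb_<start>-<end>` plus `DesAb_neg`.  En-dash labels
are accepted on input and normalized to ASCII hyphens in machine output.
Panel grafts default to `core` mode so the emitted loop is exactly the
designed peptide (the negative control's loop is then the literal
`SGAAAGSGS`).

The shipped sdAb template is a synthetic VHH-like framework composed for
testing (cysteines at raw indices 23 and 97, a 12-residue CDR3 site); the
monobody template uses the public wild-type 10FN3 sequence with this
package's choice of BC (23–30) and FG (77–85) bounds.  Neither claims to be
a published engineered scaffold; exact sequences are supplied via the same
schema.

## Synthetic fixtures: what they do and do not show

The ideal-sheet generator places strands on a slot grid: rise 3.47 Å per
residue along the strand, 4.85 Å between strands, 1.0 Å pleat on CA, with
amide and carbonyl groups facing alternate sides (facing parity flips across
antiparallel interfaces and is preserved across parallel ones).  The small
in-plane and facing offsets of N, C and O are fixed so that the generated
geometry satisfies the DSSP energy criterion with the canonical alternating
ladder in both orientations; the spacing between H-bond partners, not
peptide-bond realism, is what matters for mining.  Fixtures are therefore
ideal-case inputs: they demonstrate correctness of detection, indexing,
assembly and ranking, but not robustness to the distorted strands, bulges,
missing atoms and conformational heterogeneity of experimental structures,
nor do planted random complements carry any binding plausibility.  Mining
real PDB files is supported through the same reader but its fragment
statistics are entirely those of the user's structure set.

## Numerical and design choices

- All coordinates and windows are 1-based inclusive; comparisons of written
  coordinates are exact to the PDB's three decimals.
- Determinism: identical inputs and parameters give identical outputs,
  including file bytes; fixture randomness is confined to NumPy generators
  seeded from the run seed.
- Ties in ranking are broken lexicographically by peptide sequence; query
  results order by descending count then lexicographic complement.
- Degenerate inputs fail loudly: empty PDB files, empty structures on write,
  epitopes containing 'X', windows intersecting the mask, truncations
  reaching a loop site, duplicate construct names.
- Problem sizes in the test and acceptance runs (sheets ≤ 30 residues for
  brute-force oracle comparisons, libraries ≤ 50 fragments, 20 planted
  recovery trials, 12 random oracle cases) were chosen as the smallest sets
  that exercise both orientations, non-zero registers and multi-fragment
  assemblies while keeping exhaustive enumeration cheap.

## Known limitations

- No selection thresholds for "high" C or solubility are imposed; the
  ranking is exposed and cut-offs are left to the user.
- Hydrogen-bond patterns beyond orientation and register (e.g. alternative
  weave patterns for the same epitope) are not enumerated separately.
- No structural verification of grafted loops (loop-conformation modelling
  is out of scope), no mmCIF input, no side chains, first conformer only.
- The complementarity and solubility scores are this package's documented
  definitions; they are not calibrated against any published score's
  numerical values.
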