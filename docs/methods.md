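# Methods

This note documents the models and procedures implemented in `rhizoglob`,
the defaults and why they were chosen, what the synthetic data does and does
not emulate, and the package's numerical conventions and limitations.

## Globin identification

**ORF model.** Maximal ORFs on both strands under genetic code 11; start
codons ATG/GTG/TTG (alternative starts translate to Met), stops
TAA/TAG/TGA.  Each stop-to-stop segment contributes at most one ORF,
beginning at its first start codon.  ORFs lacking a terminal stop (running
off a scaffold edge) are discarded.  Codons containing N translate to X.
There is no canonical ORF-calling rule for this analysis; stop-to-stop with
first-start is the simplest convention that makes planted genes exactly
recoverable.

**Alignment.** Global Needleman–Wunsch with Gotoh's affine-gap recursion:
BLOSUM62, gap open 10, gap extend 0.5 (a gap of length k costs
`10 + 0.5·(k−1)`), end gaps penalized.  These are the community-default
protein parameters and are fully specified, which matters more here than
matching any particular historical aligner.  The traceback breaks ties
diagonal > up > left (and prefers the match-state predecessor within gap
states), so alignments are unique and runs are reproducible.  A score-only
fast path delegates to Biopython's C `PairwiseAligner` configured with the
identical model; the test suite asserts exact score agreement between the
two paths and against brute-force enumeration over all alignments for short
sequences.

**Significance: permutation Z score.** The observed alignment score of a
query against a reference is standardized against the score distribution of
residue-shuffled copies of the query (uniform permutations, composition and
length preserved).  Defaults: 50 shuffles during classification (the
enforced floor; the null mean/σ are stable enough at n = 50 for a gate at
Z > 6, since true globins score Z ≈ 40–140 and random proteins Z ≈ 0 ± 1),
`sd = 0` nulls report +∞ with a warning.  The acceptance threshold Z > 6 is
the field's convention for high-specificity globin detection; it is
config-exposed because the original profile-based Z scale and a permutation
Z scale are not numerically identical, even though both separate true
globins from noise by an enormous margin.

**Acceptance criteria.** A call is accepted iff (1) length ≥ 100 aa — the
"~100 aa" convention is implemented as an exact ≥ 100, configurable; (2)
Z > 6; (3) His at F8, the proximal heme-iron-binding position, located by
mapping the reference's F8 column through the alignment.  Exception: GCS
proteins are sometimes aligned with Glu at F8, an assignment the literature
itself flags as a possible alignment artifact; by default such calls are
accepted when typed GCS but marked `f8_exception` (disable via
`allow_gcs_glu_f8=False`).

**Type refinement by architecture.** Family/type are inherited from the
best reference (argmax Z; ties broken by percent identity, then panel
order).  A long protein whose best match is a *single-domain* globin with
the matched region in its N-terminal half is promoted to the corresponding
chimeric type: SDgb-like (M family) and ≥ 300 aa → fHb; SSDgb-like
(S family) and ≥ 350 aa → GCS.  The two length thresholds sit between the
single-domain lengths (~140 aa) and the two-domain averages (fHb ~400 aa,
GCS ~510 aa).  Keying the promotion on the family of the matched
single-domain reference avoids the ambiguity that a 400-aa protein exceeds
both thresholds.  tHb class (1/2/3) is inherited from the best-matching tHb
reference; there is no bespoke class model.

**Mass.** Average (not monoisotopic) residue masses plus one water, in kDa.

## Reference panel

Classification requires an eight-type query panel (fHb, SDgb, GCS,
protoglobin, sensor single-domain globin, tHb classes 1–3).  The shipped
panel (`synthetic_references.py`) is **synthetic**: deterministic sequences
generated from a fixed seed, with realistic per-type lengths, His at F8,
Tyr/Phe at B10/CD1, type-appropriate distal E7 residues, and — importantly
for phenetics — a shared 3/3-fold ancestor behind the M/S-family globin
domains and a separate 2/2-fold ancestor behind the tHbs, so the two
bacterial globin lineages segregate in trees the way real sequences do.
The panel is *not* a set of database sequences; analyses of real genomes
should supply the canonical accession panel via `load_references()` (FASTA
plus a JSON sidecar of types and fold positions).  All closed-loop results
in this package are statements about recovery of planted truth, not about
any particular natural sequence.

## Promoter scanning

Window: 130 nt immediately 5′ of the start codon, on the coding strand
(reverse-complemented for minus-strand genes), truncated with a flag at
scaffold edges.  Offset convention: −1 is the nucleotide adjacent to the
start codon; hits print "near to far" (e.g. `-36 to -41`).

Matching is deliberately simple and transparent rather than statistical:

* **Hamming mode** (−10, −35, Fnr): every full-length placement of the
  consensus with at most `max_mismatches` mismatches.  Defaults: 1 for the
  6-nt boxes; 5 for the 14-nt Fnr box, i.e. ≥ 9/14 identities, bracketing
  the degeneracy seen in published Fnr-like hits.  All hits are retained;
  the primary hit has fewest mismatches, then smallest |near|.
* **Partial mode** (Shine-Dalgarno): maximal exact substring matches of
  `AGGAGG` of length ≥ 3, nearest first — published SD hits are often
  shorter than the full consensus.

Case coding: position i is uppercase iff it equals the consensus.  The
number of lowercase characters therefore equals the Hamming distance (a
property test).

False positives are a designed-in property of short motifs: a 6-nt box with
≤ 1 mismatch matches random sequence frequently, while the expected number
of exact 14-mer hits per 130-nt window is ≈ 117/4¹⁴ ≈ 4×10⁻⁷ (0 observed in
10⁴ seeded windows).  Published tables also contain −35 hits spanning 4–9 nt
whose matching rule was never stated; this scanner makes no attempt to
reproduce those widths and reports full-consensus placements only.  Whether
published positions count from the start codon or a transcription start is
likewise unstated; the start-codon convention used here is explicit.

## Neighborhood mapping

Neighbors are annotated genes whose nearest-edge gap to the focal gene is
≤ 5000 nt ("~5 kb" implemented as exactly 5000, configurable); distance is
edge-to-edge, 0 for overlaps, signed negative upstream.  Up/downstream are
defined relative to the focal gene's strand, matching how flanking genes
are discussed in terms of transcription direction.  Queries run on an
interval tree; the unit tests compare against a brute-force filter.
Tandem arrays: same-type calls, adjacent, gap ≤ span, with no annotated
gene strictly between.  Product categories are case-insensitive substring
matches against a keyword map (nitrate/nitrite, chemotaxis, transport,
nif/fix/nos, transcriptional regulator, hypothetical; unmatched → other);
substring matching is crude but mirrors how such labels are actually
screened.

## Phenetics

Distance: `d = 100 − percent identity`, no multiple-hit correction — the
output is a phenogram (similarity tree), not a phylogeny, and is presented
as such.  Percent identity: identical aligned pairs over columns where both
sequences carry a residue.  This denominator is stable for sets mixing
~140-aa single-domain globins with ~400–510-aa chimeras; the
shorter-sequence denominator is available as an option since identity
conventions differ between programs.

UPGMA: iteratively merge the closest pair; merge height d/2; distances to
the merged cluster are size-weighted means; ties broken by the
lexicographically smallest (min-leaf-label) pair.  Output is ultrametric by
construction (asserted to 1e-9), reproduces ultrametric inputs exactly
(cophenetic round-trip), and matches scipy's average-linkage cophenetic
matrix on random inputs (independent oracle).  Newick is emitted with
branch lengths; round-trips are checked through dendropy.

Progressive MSA: profile–profile global alignment along the UPGMA guide
tree; the column score is the mean substitution score over non-gap residue
pairs, with the same affine gap penalties, so aligning two single sequences
reduces exactly to the pairwise aligner.  This is a ClustalW-style
approximation, adequate for the conservation summaries it feeds, not a
modern MSA engine.

Lineage segregation: for each group, the smallest clade containing all its
leaves is located; the group is monophyletic (in the phenogram sense) iff
it equals that clade, and the clade's purity is reported.  Domain-split
conservation for fHb/GCS pairs: the boundary in each protein is the last
residue aligned to its best single-domain globin reference (rejected if
that alignment's Z < 6), and identities are computed separately for the two
segments.

## Heme-pocket geometry

Distances are Euclidean (Å); dihedrals use the IUPAC sign convention in
(−180°, 180°], with degenerate (collinear) geometry returning an explicit
None; χ1 is N–CA–CB–(first γ atom).  Probe atoms measured against Fe
default to the side-chain functional tip (His NE2, Gln NE2, Asn ND2,
Tyr OH, Phe CZ) and otherwise fall back, with a warning, to the side-chain
heavy atom nearest Fe — which atom the original measurements probed is not
recorded, so the choice is documented rather than asserted.  Coordination:
hexa if the distal probe is within 3.0 Å of Fe, penta if only the proximal
probe is, indeterminate otherwise; the cutoff is config-exposed because
published coordination inferences are qualitative, drawn from distance
ranges (e.g. proximal 1.44–2.47 Å vs distal 6.71–15.35 Å in fHbs implying
pentacoordination).

PDB I/O is a strict fixed-column parser/writer (line-numbered errors;
cross-checked against gemmi in tests); exactly one heme Fe (HEM/HEC/HEB) is
required per analyzed model.  Kabsch superposition is the closed-form SVD
solution with the determinant correction to a proper rotation; it rejects
< 3 pairs or collinear sets, and is checked against scipy's
`Rotation.align_vectors`, against random rigid motions, and against the
analytic RMSD expectation for noisy copies.

## Synthetic data: what it emulates, and what it does not

The generator plants, with exact machine-readable truth: globin ORFs
(mutated reference copies back-translated with a fixed one-codon-per-residue
table, invertible by translation), promoter/SD motifs at exact upstream
offsets with exact mismatch counts, neighbor ORFs at exact edge distances
with product labels, and toy heme pockets whose planted distances are exact
to 1e-3 Å and dihedrals to well under 0.1° despite PDB coordinate rounding
(probe atoms sit on coordinate axes; residue frames use 2-Å schematic
bonds so rounding-induced angular error stays ≈ 0.02°).

Mutation is i.i.d. per-site substitution at a given rate, with the F8
position protected by default so that truth labels remain valid under the
classifier's His gate (protection can be disabled, which is how the
F8-mutant rejection experiments are built).  Background sequence is i.i.d.
nucleotides at a chosen GC content (default 0.62, typical of rhizobial
genomes).  An in-frame stop codon is written immediately 5′ of each planted
start (unless a planted motif occupies those positions) so the planted ATG
is the first start of its ORF segment and coordinates round-trip exactly.

Not emulated: realistic codon usage, operon structure, phylogenetically
correlated divergence, indels, sequencing error, or stereochemically
realistic residue geometry.  Consequently, passing closed-loop tests
demonstrates that the *algorithms* recover planted truth under controlled
divergence — it does not certify recall on real genomes, where gene
fragmentation, unusual starts and annotation noise dominate.

## Pipeline conventions

Genomes are grouped by FASTA file stem (overridable via a genome map).
Copy-number tables count genomes per (type, copy-count) cell; the Venn
summary reports all 15 non-empty regions of the {fhb, sdgb, gcs, thb}
four-set diagram, with regions defined by each genome's exact type
composition.  Labels of the published form
`<3+3 binomial letters><strain><type><copy>` (e.g. `brajapUSDA38sdgb2`) are
parsed by `parse_glb_label` for re-counting deposited gene tables.

Determinism is a hard contract: identical config + seed ⇒ byte-identical
outputs.  For that reason no wall-clock timestamps appear in any report
file; provenance records the package version, seed and a config hash.
`resume=True` leaves existing outputs untouched.

## Problem sizes used in validation

The shipped experiments are sized for a single CPU: 50 enumeration-checked
alignment pairs (length ≤ 8); 200 planted windows plus 10⁴ null windows for
the scanner; 400 classified proteins (8 types × 50 replicates at 10%
substitution) for recovery; 100 random matrices for UPGMA properties; an
18-leaf cohort (6 rhizobial types × 3 copies) for lineage segregation; and
a two-gene genome for the determinism check.  These sizes give binomial
standard errors comfortably inside the asserted margins (e.g. recovery is
asserted at ≥ 95% where the observed rate is 100% over 400 trials).

## Known limitations

* The permutation Z is a score-significance gate, not a structural
  threading score; its numeric scale differs from profile-based detectors
  even though the acceptance decision is robust over a wide threshold range.
* The shipped reference panel is synthetic; real-genome analyses should
  provide the canonical panel.
* The promoter scanner is consensus-based (no PWM/energy model) and will
  not reproduce published hits whose matching rule was never specified.
* The MSA is a guide-tree progressive heuristic without iterative
  refinement.
* Structure models are inputs; the package performs no structure
  prediction, helix assignment or fold-type classification.
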