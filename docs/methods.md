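# Methods

This note documents the models, conventions and numerical choices behind
`gpxprx`, and what the synthetic benchmarks do and do not establish.

## The classification model

The package classifies Gpx-like protein sequences by three sequence-level
criteria, evaluated in a shared reference numbering (catalytic tetrad
61/95/150/151, resolving Cys 107): (i) a peroxidatic Cys rather than
selenocysteine, (ii) a resolving Cys at position 107 or anywhere in the
Cys-block window 103–113, and (iii) absence of both oligomerization
interfaces — the `PGGG` dimer loop and the C-terminal oligomerization
loop. All three together define a TRX-dependent, Gpx-like peroxiredoxin.
Selenocysteine at the peroxidatic site, or a peroxidatic Cys with neither
a resolving Cys nor absent loops, defines a canonical GSH-dependent Gpx.
Every remaining combination — including a peroxidatic residue that is
neither `C` nor `U`, which the criteria do not cover — is reported as
`AMBIGUOUS` rather than forced into a class.

Loop detection is deliberately conservative about alignment artifacts: the
dimer-loop motif (`PGGG`, up to one mismatch by default) only counts when
the row actually covers the region (< 50 % gaps there), and the
oligomerization loop requires an *ungapped* insertion of at least 8
residues at columns where the reference row is gapped. A row that is gap
at every diagnostic column is flagged unalignable and refused
classification rather than guessed.

The dimer/oligomerization intervals default to 126–146 and 155–175 in
reference coordinates. These are placeholders aligned with the synthetic
generator's planted coordinates; for real data the user should supply
region definitions (`regions` in the pipeline config or `ColumnMap`),
because interface-domain boundaries are a property of the reference
structure, not of this algorithm. The GSH-binding triplet (57/185/147)
follows bovine numbering carried over as reference-map positions; the
cross-species offset makes those letters descriptive evidence, not a
classification criterion.

## Synthetic families

The generator exists so every downstream stage can be tested with known
truth. A scaffold of length 190 is drawn uniformly over the 20 canonical
amino acids — a conservative null for consensus statistics, not a
realistic composition — with neutral alanines at all diagnostic positions.
`plant_class` then writes one class onto it:

- **TRX-like**: `C` at 61 and 107, Q/W/N at 95/150/151, P/F/Y at
  97/106/111, both loop regions deleted (41 positions; final length 148);
- **canonical**: `U` at 61, `S` at 107, R/R/M at 57/185/147, `PGGG`
  planted mid-dimer-loop, and a 10-residue insertion after position 165
  (final length 200);
- **ambiguous**: `C` at 61, no resolving Cys, both loops deleted
  (1-Cys-like).

The whole Cys-block window counts as diagnostic: a stray background `C`
anywhere in 103–113 would read as a resolving Cys downstream, so the
generator controls the window rather than leaving it to chance. For the
same reason the ambiguous class deletes the loop regions: a random
21-residue window matches `PGGG` within one mismatch roughly once per
hundred sequences, which would contaminate a "no loops" truth label.

Divergence is modeled as independent per-site substitution to a uniformly
chosen *different* canonical residue, applied only outside a protected set
(the diagnostic positions mapped through the planted deletions/insertion,
plus the planted `PGGG`). The substitution count over L unprotected sites
is exactly Binomial(L, rate), which the tests verify by moment checks.
There are no indels beyond the planted loop events, no substitution-matrix
bias, no rate heterogeneity, and no simulated structures. Consequently,
passing benchmarks demonstrate correctness of the algorithms under a
clean, well-specified null — not robustness to real evolutionary
processes, compositional bias, or alignment-breaking indel patterns.

## Alignment

Pairwise alignment is global Needleman–Wunsch with affine gaps via the
Gotoh three-state recurrences; a gap run of length k costs
`gap_open + (k−1)·gap_extend` (defaults BLOSUM62, 10, 1). Traceback is
deterministic with preference diagonal > up > left, so ties never
introduce run-to-run variation. `U` is scored as `C` — BLOSUM62 has no
selenocysteine column and in Gpx families `U` occupies the Cys column —
but is preserved verbatim in output; `X` scores 0 against everything.
Scores are validated against exhaustive enumeration of all alignments for
short sequences (tests and the acceptance script).

The multiple aligner is progressive: guide tree by neighbor joining on
`1 − fractional identity` distances from all-pairs global alignments,
then profile–profile merging leaves-inward ("once a gap, always a gap")
with column scores `f_A · S · f_B` over residue frequencies (gaps
contribute zero) and the same affine penalties. There is no iterative
refinement; externally curated alignments can be imported instead
(`import_alignment`), and heavily gapped termini can be trimmed with an
explicit column rule (`trim_terminal_gap_columns`, default threshold 80 %
gaps) rather than a hidden heuristic. The inner DP kernel is numba-compiled;
all arithmetic is float64 and deterministic.

## Non-redundant sets

`greedy_cluster` reproduces the cd-hit scheme at desk scale: sort by
descending length (ties lexicographic by id), each record joins the first
representative with identity strictly above the threshold, else founds a
cluster. Identity is fractional identity over the optimal global
alignment; a "similarity" mode (positively scoring substitution pairs) is
exposed because survey literature often says "similarity" where the tool
computes identity. Determinism holds for a fixed input order; invariance
under permutation is *not* promised — greedy clustering is order
dependent by construction. No k-mer prefilter is used; inputs here are
hundreds of sequences, not millions.

## Conservation

Per column, the profile reports the modal letter and the consensus
*group*: starting from the modal letter, other letters from the same cell
of a fixed physicochemical partition ({ILVMF} {WY} {ST} {DE} {KRH} {NQ}
{AG} {C} {P}; everything else singleton) are added greedily while each
contributes ≥ 5 % of non-gap rows. Proportions are over non-gap rows;
all-gap columns report proportion 0 with gap fraction 1. Conserved
domains are maximal runs of columns at proportion ≥ 0.7 (default),
bridging at most 2 consecutive below-threshold columns, starting and
ending on above-threshold columns; columns more than 50 % gapped break
runs unconditionally. Segments shorter than 5 columns are dropped, and
coverage is segment residues over the reference length. The domain count
is emergent from the data, never a parameter. This is consensus counting,
not evolutionary-rate estimation: no tree-aware conservation scoring is
attempted.

## Phylogeny

Distances are p-distance (mismatches over shared non-gap columns) or the
Poisson correction `−ln(1−p)` (default); saturated pairs (p ≥ 1) are an
error naming the pair rather than a silent cap. Neighbor joining follows
Saitou–Nei with the standard Q criterion; ties take the lowest index
pair, and negative branch-length estimates are clamped to zero and
flagged, matching common tree-software behavior. On additive matrices the
implementation recovers the generating topology and all path lengths to
1e-9 — this is the module's central oracle, checked on random trees.

Bootstrap resamples alignment columns with replacement; each replicate's
NJ tree contributes its bipartitions, and internal-edge support is the
percentage of successful replicates containing the edge's bipartition.
Replicates whose resampled rows are all identical (possible at very low
divergence) are skipped with a warning and excluded from the denominator;
the skip count is kept on the tree. Star-likeness is the fraction of
internal edges below a support threshold (default 70) — near 1 means the
phylogeny is an unresolved radiation. Phylum mixing counts, per phylum,
the maximal monophyletic same-phylum clades with the tree read as rooted
at its trifurcation; the mixing index is the mean of clades/leaves per
phylum (1/n = perfectly clustered, 1 = fully scattered). Before tree
building the pipeline masks columns more than 50 % gapped, so a
minority-carried oligomerization-loop insertion cannot distort distances.

## Structure metrics

Superposition is the Kabsch least-squares rotation with reflection
correction; rank-deficient (collinear) point sets are flagged degenerate.
The disulfide readout defaults to the Cys SG–SG distance with a CA
fallback, and reports which atoms were used. SASA is Shrake–Rupley with
golden-spiral sphere sampling; at the default 960 points the isolated
sphere is within 1 % of `4π(r+probe)²`, and the implementation matches a
naive all-pairs point-count oracle exactly point-for-point. Relative
accessibility normalizes summed SASA by per-residue-type maxima; the
shipped table is the theoretical Gly-X-Gly extended-context maxima of
Tien et al. (2013), and any user table can be passed instead. Van der
Waals radii default to C 1.70, N 1.55, O 1.52, S 1.80, Se 1.90 Å.
Homology modeling, electrostatics and docking are out of scope; the
metrics operate on user-supplied coordinates only.

## Pipeline and problem sizes

`run_pipeline` executes ingest → length filter → dedup → align → anchor →
classify → conserve → tree → report, logging the record funnel at each
stage and writing a JSON report with output checksums; a failing stage
aborts with its name and keeps partial outputs. The reference row anchors
the column map but is exempt from filtering/dedup and excluded from the
cohort statistics and the tree. All randomness derives from one seed and
runs are byte-for-byte reproducible (reports carry no timestamps).

Length-filter bounds default to 0.5×/2× the median input length.
Dedup defaults to identity 0.8 and a second, looser convention of 0.7 is
common for representative-set construction; both are plain config values.
Bootstrap defaults to 1000 replicates in the config; the demo uses 50.

The `demo` cohort is 83 TRX-like + 17 canonical sequences (so the
oligomerization-loop fraction is 0.17 by construction) at divergence
0.10 with protected diagnostics, deduplicated at identity 0.95: at this
divergence within-class identities sit near 0.84, so the survey default
of 0.8 would collapse each class to a single representative and erase the
cohort fractions the demo exists to show. The acceptance benchmarks use
3 × 50-sequence cohorts for classification, 500 short pairs for aligner
optimality, 50 × 20-record inputs for clustering, 100 random additive
trees (6–10 taxa) for NJ, and 200 bootstrap replicates for the support
checks; these sizes keep a full verification run in the low minutes on a
single CPU while leaving the pass/fail thresholds statistically
unambiguous.

## Known limitations

- The uniform-background, substitution-only generator cannot probe
  alignment quality under indels, compositional bias or repeat content.
- Region definitions for real data must come from the user; the package
  refuses to silently guess interface-domain boundaries.
- Greedy clustering is input-order dependent beyond the documented
  longest-first rule, as in the tool it emulates.
- Consensus-proportion conservation ignores phylogenetic correlation
  between rows; closely related sequences inflate proportions.
- The progressive aligner has no refinement pass and will not match a
  dedicated MSA tool column-for-column on hard cases.
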