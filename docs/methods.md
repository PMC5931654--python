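# Methods

## Model and procedure

The method treats a hypervariable, unalignable locus — the P8 stem-loop of
the plastid trnL(UAA) group-I intron — as a source of *restriction-site
characters* rather than aligned positions. For each taxon the P8 region is
excised, every recognition site of a chosen enzyme panel is located, and
the taxon is represented by its exact set of (enzyme, position) sites plus
its region length. Two taxa are indistinguishable under a criterion iff
their representations under that criterion are exactly equal; no
similarity threshold or alignment is involved. UPGMA dendrograms on the
binary site characters are a visualisation of profile similarity only —
because P8 evolves by repeat expansion, tree topology is *not* a
phylogenetic estimate, and the package makes no such claim.

Assumptions worth stating explicitly:

- Site positions are global 1-based coordinates within each taxon's own
  P8 region. Taxa of different lengths can still share identical position
  lists (and then score as identical); positions are deliberately not
  normalised or aligned, since exact coordinate identity is what defines
  the character.
- A recognition site is an IUPAC-degenerate motif of ≥ 5 nt; only the
  footprint start matters. Cut offsets, overhangs, methylation and star
  activity are out of scope.
- Identity of the taxon is its name string in the input; the bundled
  survey uses names as printed in its source, including two footnoted
  naming corrections.

## Matching semantics (two polarities)

Degenerate bases are resolved through IUPAC base sets, with *different
polarity* for the two matching problems:

- **Primer/anchor matching** (delimitation) is permissive: subject base
  matches pattern base when their base sets intersect, with an optional
  Hamming mismatch budget. This mirrors the tolerance of primer binding.
- **Site scanning** is conservative: a subject base matches a motif
  position only when the subject's base set is a *subset* of the motif's.
  An `N` in a downloaded sequence therefore never creates a restriction
  site that might not exist in the true sequence.

Scanning reports all overlapping occurrences. Forward-strand scanning is
the default; `strand_mode="both"` additionally scans the
reverse-complement motif and reports hits at their forward-strand
footprint start. Three of the four core enzymes (AgsI `TTSAA`, ApoI
`RAATTY`, VspI `ATTAAT`) are degenerate palindromes, for which the two
modes coincide; only TspDTI (`ATGAA`) is orientation-sensitive.

## Region delimitation

The c/d primers are stored 5′→3′ (`CGAAATCGGTAGACGCTACG` /
`GGGGATAGAGGGACTTGAAC`); the d primer is matched as a reverse complement
on the forward strand, and a record found in the opposite orientation is
handled by mirroring. The P8 borders themselves have no printed,
universally agreed motifs — in practice they are derived from published
secondary-structure models for the group under study. They are therefore
*configuration*: an `AnchorConfig` (left motif, right motif, mismatch
budget) read from a small TSV. The bundled default anchors are the pair
used by the synthetic generator and are documented as placeholders; real
surveys should supply literature-derived anchors. The region is taken
strictly between the innermost left-anchor match (largest end coordinate)
and the nearest right-anchor match beyond it; records missing either
anchor are excluded with a logged reason, mirroring the exclusion of
incomplete records in survey practice.

## Similarity and clustering

The qualitative coefficient defaults to **simple matching**
((both-present + both-absent) / features), with Jaccard and Dice
selectable. Simple matching is the conventional default for qualitative
restriction data and, on sparse binary matrices, yields the high
(≈ 0.9–1.0) similarity ranges typical of these datasets; the historic
analysis software does not pin the coefficient, so it is a parameter.
Degenerate denominators (no features, or no presences in a pair) resolve
to 1.0 exactly when both rows are all-zero, else 0.0.

UPGMA runs on distance 1 − similarity with size-weighted average linkage
(equivalently: unweighted mean over original leaf-pair distances — the
package cross-checks its implementation against both a naive O(n³)
re-derivation and SciPy average linkage in tests). Determinism under ties
matters for golden outputs, so the minimal pair is chosen by the
lexicographically smallest pair of original input indices; distances
within 1e-9 count as tied so that last-ulp float noise cannot flip the
choice. The dendrogram is ultrametric; Newick branch lengths use the
midpoint-split convention (a node joined at distance *h* sits at height
*h*/2), so leaf-to-leaf path lengths reconstruct merge distances exactly.
Labels containing spaces are single-quoted.

## The bundled survey dataset

`fixtures.load_table1()` returns 98 orchid taxa (tribe Vandeae; GenBank
accessions retained) with P8 lengths of 200–669 nt and core-four site
positions, checksummed on load. Curation is confined to two malformed
cells of the printed source (duplicated position runs, one with a
typographic join), each documented in the bundled curation log with
printed and curated values. Positions that cannot fit their stated region
length — most prominently the Phalaenopsis inscriptiosinensis row, whose
lists run to position 981 against a stated length of 498 — are kept as
printed and flagged with a `UserWarning` (flag-and-keep), never silently
repaired. Headline quantities recomputed from this dataset: length
extrema 200/669; 42 taxa with unique lengths; a modal group of 8 taxa at
521 nt; single-enzyme discrimination AgsI 80, ApoI 77, TspDTI 78, VspI
66; AgsI+ApoI 86; AgsI+ApoI+TspDTI 92 (VspI adds nothing); sites plus
length 94 of 98 (95.9 %).

The extended 31-enzyme table carries recognition motifs from standard
REBASE definitions. The historic site lists for those enzymes cannot be
regenerated exactly (the defunct web mapper's enzyme definitions are not
recoverable), so the extended panel supports exploratory scans only; all
quantitative claims rest on the core four.

## Synthetic generator

`generate_synthetic(n, seed, ...)` emulates the survey's input regime:
records carrying the c/d primer sites, anchor-flanked P8 regions of
200–700 nt (uniform), A-rich background composition (A 0.40 / T 0.28 /
C 0.16 / G 0.16), 1–3 tandem-repeat arrays per region (short A-rich
motifs, geometric copy counts with p = 0.5 — a stand-in for slipped-strand
mispairing, whose mechanism but not parameters is established), and 1–4
non-overlapping concrete motif instances per enzyme planted at recorded
positions. Planted positions are re-verified against the scanner before a
record is emitted, making the truth a sound oracle for the
delimit → map pipeline. The generator does **not** model secondary
structure, shared ancestry between records, sequencing error or ambiguous
base calls — so passing end-to-end tests demonstrate pipeline
correctness on clean, well-formed inputs, not robustness to noisy
GenBank records.

## Numerical and interface choices

- Coordinates are 1-based inclusive everywhere.
- Positions within a profile are deduplicated and sorted on construction.
- Binary-matrix features are sorted by (enzyme name, position); taxa keep
  input order; all-zero rows are retained (a taxon without sites for a
  panel is still a taxon), while all-zero columns cannot occur by
  construction.
- Discrimination reports order groups by first member and members
  alphabetically, making serialized reports stable for golden tests.
- Problem sizes in the test and acceptance runs (1000 random
  scanner/oracle pairs, 150–200 small UPGMA matrices, 100 synthetic
  end-to-end records) keep the full suite in the low seconds while
  exercising every code path; the bundled-survey computations are exact
  and instantaneous.

## Known limitations

- Default anchors are placeholders; delimitation accuracy on real
  GenBank material depends entirely on user-supplied, group-appropriate
  border motifs.
- The similarity ranges shown in dendrogram summaries depend on the
  coefficient choice; only profile *identity* (similarity 1.0), which is
  coefficient-invariant, feeds the discrimination counts.
- Indistinguishable taxa may be genuinely identical at the locus
  (identical P8 sequences occur); deciding whether such pairs are
  hybrids, ecotypes or synonyms requires other markers and is out of
  scope.
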