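# Methods

## The screen

A flavinylation-substrate candidate is called from three independent pieces
of evidence, all computable from a genome annotation:

1. **Domain evidence.** Proteins are annotated with the Pfam accession of
   their best hmmsearch match. The package consumes per-domain tabular
   output ("domtblout") rather than running hmmsearch: the cutoff
   (default E ≤ 10⁻³) is applied to the per-domain *independent* E-value
   (column 13), the best hit is the minimal E-value with ties broken by
   maximal bitscore and then lexicographic accession, and Pfam version
   suffixes are stripped so accession sets match across database releases.
   The full-sequence E-value column is deliberately not used: the
   independent E-value is the per-region statistic and is robust for
   multi-domain proteins.
2. **Motif evidence.** The flavinylated residue sits at the final position
   of a degenerate [S/T]GA[S/T] motif. The scanner is exact (regex with a
   lookahead so overlapping matches are all reported) and configurable via
   bracket notation, but the default pattern is exactly [ST]GA[ST] — the
   motif is described in the literature as "-like", yet loosening the
   default would silently inflate false positives, so any relaxation is an
   explicit caller decision. An optional residue-interval mask lets callers
   restrict the scan (e.g. to a region predicted to be extracytosolic); no
   topology predictor is bundled.
3. **Colocalization.** The neighborhood of an anchor gene is the window of
   genes with rank index within ±k (default k = 5) on the same contig,
   truncated at contig ends. Rank is defined by start coordinate regardless
   of strand — neighborhoods are genomic, not transcriptional, because gene
   order is the only signal the screen uses. Coordinates are 1-based
   inclusive throughout (the GFF3 convention).

A window's verdict depends only on its members: `has_apbE`,
`has_known_ET_system` and `has_flavin_transporter` are set from the
members' best accessions; substrate candidates are anchor-family members
with ≥1 motif in apbE-positive windows; cytochrome candidates are
DUF4405-family members of apbE-positive windows lacking a known
electron-transfer system. Two anchor modes exist: `anchor-first` (default;
windows around candidate-family genes) and `apbe-first` (windows around
*apbE* itself, the natural frame when mining for unknown cytochromes).
Overlapping windows of nearby anchors are reported separately, never
merged.

**Accession sets.** The original screen's accession sets are not published
in full, so the defaults are explicit and overridable (config file or
`ScreenConfig`): apbE = PF02424; anchors = PF03358 (FMN_red), PF12682
(Flavodoxin_4), PF14358 (DUF4405); cytochromes = PF14358; known
electron-transfer systems = PF03116 (NqrB/RnfD-like), PF04205 (FMN_bind),
PF03413 (PepSY), PF01794 (ferric-reductase/MsrQ-like). The transporter set
ships empty — no specific accession is defensible from the source material,
so the flag stays `False` until a caller supplies a set.

**Domain copies.** Multi-copy flavinylated domains (FMN-bind_2-like) pair
into pseudo-symmetric two-site units, so the copy count's parity is
informative. Copies are counted as the maximal set of non-overlapping
passing hits selected greedily by ascending E-value; the greedy rule is a
design choice (no counting procedure is prescribed anywhere) and is
deterministic under the full tie-break chain.

## Structural context

**Superposition** is the closed-form Kabsch solution (SVD of the
cross-covariance of centered point sets, determinant-corrected so the
rotation is always proper). Correspondence is caller-supplied; no
sequence-based pairing is attempted, keeping the geometry core honest. The
test suite checks it against an independent multi-start Nelder–Mead
minimizer over rotation vectors.

**Membrane model.** A membrane is an implicit slab: center, unit normal,
half-thickness (default 15 Å, a typical hydrophobic half-width; no
lipid-based estimation). With transmembrane segments supplied, the normal
is the sign-aligned mean of per-segment Cα displacement vectors; without
them it is the principal axis of the Cα trace after smoothing each chain
with an 18-residue moving average (18 residues × 100°/residue is exactly
five helical turns, so the off-axis circular component of an ideal helix
cancels and the axis is recovered exactly). The normal's sign is fixed
deterministically (largest-magnitude component positive).

**TM segments** are runs of consecutive residues whose Cα depth traverses
from ≤ −(h−5) Å to ≥ +(h−5) Å or vice versa (h = half-thickness), extended
over contiguous residues still inside the slab and filtered to 15–45
residues (longer runs are trimmed symmetrically; the 5 Å margin tolerates
helix ends that stop short of the slab face).

**Bis-His sites.** Candidate heme sites are His pairs with NE2–NE2
distance ≤ 8 Å whose midpoint lies within the central half of the slab
(±7.5 Å at defaults). The 8 Å window is twice the ~4.4 Å spacing of a holo
axial bis-His iron site (two ~2.2 Å Fe–NE2 bonds): predicted apo models
relax, so the window is doubled. "Central" is quantified as a fraction of
the half-thickness because no numeric definition exists in the source
material; both thresholds are parameters. ND1 can be accepted as the
coordinating atom via a flag (tautomer placement in predicted models is
unreliable); the default is NE2 only. Every qualifying pair is reported —
a His may appear in several pairs — sorted by distance.

**Pocket proximity.** The distance from a motif Ser/Thr side-chain oxygen
(OG/OG1) to the centroid of a caller-selected pocket (e.g. the flavin
isoalloxazine atoms) quantifies whether a flavinylated residue is
positioned to engage a flavin-binding site. It is a plain Euclidean
measurement; no conformational sampling is performed.

## Conservation

Column statistics follow the sequence-logo convention: frequencies over
non-gap symbols, information content IC = log₂20 − H against a uniform
background. Gaps are excluded rather than treated as a 21st symbol;
columns with >50% gaps are flagged excluded but still profiled. The
small-sample correction e_n = 19/(2·ln2·n) is available behind a flag and
off by default (logo software differs here, and the default keeps IC a
pure function of the frequency vector). Conserved positions are columns
whose consensus is in a requested residue set at ≥ a frequency threshold
(default 0.9); `map_column_to_residue` links a column to the 1-based
ungapped position of any member sequence, which is how a logo column is
tied to a residue in a structure.

## Synthetic data: what it emulates and what it does not

The generators stand in for database-scale inputs (tens of thousands of
genomes; predicted structure models) and are deliberately *noise-free in
the labels*: planted domain hits get E ≤ 10⁻⁵ and background hits
E ≥ 10⁻², so the 10⁻³ cutoff separates them with two orders of magnitude
of margin, and background proteins are scrubbed of accidental motifs by
rejection. Each contig is its own single-contig genome, mirroring the
many-small-genomes shape of a database screen and giving the taxonomy
summary realistic marginals.

Planted neighborhoods occupy disjoint 2k+1 blocks so windows never
collide; substrate anchors carry 1–2 motifs in their C-terminal half
(mirroring the candidates' C-terminal extensions and internal insertions);
decoys violate exactly one calling condition each (`motif_no_apbE`,
`apbE_no_motif`, `wrong_domain`, cycled). Helix bundles use textbook ideal
parameters (1.5 Å rise, 100° turn, Cα 2.3 Å off-axis), alternate up/down
on a circle, and place planted NE2 pairs on helix-axis chords so distinct
pairs are geometrically separated; the generator verifies at build time
that no non-planted His pair could satisfy the detector's thresholds (with
slack) and raises rather than emit an ambiguous bundle.

Consequently, passing recovery tests demonstrates the *logic* of the
screen — windowing, flag derivation, candidate conditions, geometry — under
clean labels. They do not demonstrate robustness to annotation noise,
fragmented assemblies, borderline E-values, non-ideal helices or wrong
tautomers; on real data those failure modes return and the thresholds
become genuinely consequential.

## Problem sizes and numerics

The reference recovery runs use 50 contigs × 40 genes with 20 substrate and
20 decoy neighborhoods; 1,000 random 500-residue sequences for the scanner
oracle; 200 random 3–50-point instances for the superposition oracle; 50
six-helix bundles (0/1/2 pairs, 3 decoy His); and 10⁴ columns for the IC
bounds. These sizes exercise every code path while keeping the whole suite
fast on a single CPU. All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawn keys (one substream per generator), so
every artifact is byte-reproducible and adding a generator does not perturb
the others.

Numerical conventions: E-value ties break by bitscore, then accession, then
alignment position; consensus ties break alphabetically; the slab normal's
sign is canonicalized; report rows are ordered by (genome, contig, anchor
index). Degenerate inputs fail loudly — empty sequences, ragged alignments,
non-finite coordinates, duplicate atoms after alt-location resolution, and
infeasible cluster packings are all errors, not warnings.

## Known limitations

- No topology prediction: motif sites are not filtered for extracytosolic
  exposure unless the caller supplies a region mask.
- The membrane slab is planar and of fixed thickness; curved or deformed
  bilayers are out of scope.
- Superposition requires caller-supplied correspondence.
- The screen reports raw counts; it implements no colocalization-frequency
  threshold, operon model, or phylogenetic correction.
- Structure models are taken as given — no quality filtering (e.g. by
  predicted confidence) is applied.
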