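# Methods

## The problem

CACTA elements are Class 2 (cut-and-paste) DNA transposons bounded by
short terminal inverted repeats (TIRs) that begin with the conserved
5'-CACTA motif, with subterminal repeat regions (subTIRs) built from
10–20-bp units repeated in direct orientation at the 5' end and inverted
orientation at the 3' end. Insertion creates a 3-bp target-site
duplication (TSD). The transposase (TPase) ORF — carrying the TAD,
Transposase_21 (tnp2), DUF4218 and DUF4216 conserved domains — is the
element's most alignable region; a second ORF is structurally labile and
may gain Transposase_24 and/or Peptidase_C48 domains. Elements may also
carry captured host-gene fragments in the 5' region upstream of TAD, and
multi-kilobase tandem satellite-DNA arrays near the 3' end.

cactascan re-implements this annotation problem as a pipeline: position
full-length tnp2 domains from a protein-domain hit table, delimit the
element around each anchor by its terminal structure, classify the
conserved-domain architecture (CDA), and annotate captures and satellite
arrays. A synthetic element generator with exact ground truth supplies
test data at every stage.

## Coordinate convention

Intervals are 1-based with `length = end − start` (the interval covers
positions `start..end−1` inclusive). This convention reproduces the
published satellite-array arithmetic (15648 − 10098 = 5550 bp) and the
754-bp gap between the second Neprosin fragment end (3457) and the TAD
start (4211). GFF3 output converts to 1-based inclusive coordinates and
BED to 0-based half-open.

## Terminal-structure detection

**TIR pairs** (`find_tir`). An element sequence must begin with CACTA
and end with its reverse complement. The 5' prefix is compared against
the reverse complement of the 3' suffix at every length in [25, 40] bp,
and the length maximizing the ungapped pair identity (longest among
ties) is reported when that identity reaches 0.70. Identity rather than
length is maximized because in a well-mirrored element the inverted
terminal match continues through the subTIR arrays, so "longest
qualifying" would always saturate at the cap; `call_element`
additionally bounds the reported TIR at the first subTIR copy.

**subTIR arrays** (`detect_subtir`). The unit period is estimated in the
5' terminal window (600 bp, generously covering all published layouts of
≤ 23 copies × 12 bp) by a seed-and-chain search: for each period p in
[10, 20] and each seed, consecutive unit-length windows are chained
while adjacent windows agree at ≥ 0.80 identity. Because adjacent
shifted windows share p−m bases, chains can seed slightly off the true
phase; maximal-count chains are therefore re-ranked by mean identity to
their own consensus (quantized to 2 decimals so substitution noise
cannot override the leftmost-seed preference). The motif is the
majority-rule consensus of the phased copies, reported in 5' direct
orientation. Copies are then counted on the best phase lattice per end —
direct at 5', reverse-complement at 3' — taking the contiguous run with
the most qualifying tiles and bridging at most two consecutive decayed
copies. A second pass rebuilds the consensus from every detected copy
and canonicalizes its rotation by total copy count (a rotated target
fits one fewer full window per array), with summed copy identity as the
tie-break. Fixed-stride tiling avoids the re-synchronization artifacts a
sliding scan exhibits on noisy arrays.

The copy-identity threshold 0.80 admits all published per-copy
similarities (which bottom out at 83.3 % = 10/12) without admitting 9/12
copies. The unit-period estimator (`estimate_unit_length`) is the plain
shifted-self-identity argmax over [10, 20], ties to the smaller period.
A cluster of at least 3 chained copies is required before any subTIR
annotation is made; windows without one report zero copies. (A
whole-window mean-identity criterion would be diluted by the
non-periodic remainder of the 600-bp window — about 0.39 at the true
period for a realistic layout — and would reject every real element.)

**Element calling** (`call_element`). Searching up to 15 kb on each side
of a tnp2 anchor: candidate CACTA starts upstream and TAGTG ends
downstream are paired and screened with `find_tir`; the pair with the
highest identity (widest span among ties) delimits the element.
Completeness is `complete` when the CACTA-intact pair is corroborated by
subTIR units on both ends. Two safeguards apply. First, unit junctions
of CAC-terminal motifs regenerate a CACTA, so a "TIR" whose subTIR
copies overlap the terminal anchor itself is rejected as mirrored
subterminal sequence — this is what distinguishes a genuinely
TIR-ablated element from a complete one. Second, when no intact anchor
pair exists, unit clusters are sought on both flanks (extended across at
most two consecutive decayed copies), and a decayed anchor pair
(≥ 3/5 identity to CACTA, validated by inverted-pair identity ≥ 0.70
over the implied TIR) is admitted to recover the element boundaries;
such elements are classified `subtir_only`, matching the published
"almost complete ends (subTIRs are detectable)" category. Anchors are
screened permissively because at 5 % substitution both 5-bp CACTA
motifs are intact in only ~60 % of elements, while the 28-bp pair
identity remains a reliable gate. Elements with neither structure are
`incomplete`, spanning the searched window.

**TSD** (`check_tsd`): the 3-mer immediately 5' of the span is reported
when it equals the 3-mer immediately 3' of it.

## Domain architecture

Hit tables follow the DANTE dialect (GFF3 attributes Name, Identity,
Similarity, Relat_Length, Interruptions, optional Length_Proportion, or
a flat TSV with the same fields). Filtering keeps hits with identity
≥ 0.35, similarity ≥ 0.45, aligned-length proportion ≥ 0.8, zero
interruptions (frameshifts + stop codons) and length proportion ≤ 1.2 —
the standard TPase retrieval setting. Full-length tnp2 anchors are
Transposase_21 hits within ±10 % of 630 bp (closed interval; "about
630 bp" requires a concrete tolerance and ±10 % is documented as that
choice). Hits are assigned ORF1 if contained in the coding interval
holding the tnp2 anchor (midpoint rule, flagged, for straddlers), else
ORF2. For classification, the highest-identity hit per canonical domain
name is kept and ordered by start position:

| type  | ordered domains |
|-------|-----------------|
| type1 | TAD, Transposase_21, DUF4218, DUF4216 |
| type2 | basic + Peptidase_C48 |
| type3 | basic + Transposase_24 |
| type4 | basic + Transposase_24 + Peptidase_C48 |

Exactly these four ordered lists map to types; any other multiset or
order — including rearranged canonical sets, which warn — is `other`.
Domain completeness is reported but not used for typing.

## Captures and satellite arrays

Captured fragments are located relative to the TAD start:
`dist_to_tad = TAD.start − fragment.end` (the intervening gap, matching
"754 bp upstream" phrasing; start-to-start measurement was considered
and rejected as inconsistent with the published coordinates). Region
labels are five_prime / internal / three_prime against the coding
intervals.

Tandem arrays are found by rolling shifted self-identity (lag p, window
p) over monomer lengths 30–400 bp; runs ≥ 0.70 identity spanning at
least 3 monomers are candidates, longest first (smallest period among
ties). Each region is phased to maximize full-copy count then mean copy
identity (quantized, leftmost among ties); harmonic periods are folded
to the fundamental (a consensus periodic at an admissible shorter lag);
consensus monomers that are themselves periodic below 30 bp are
rejected, which keeps subTIR unit arrays (10–20 bp) out of satellite
calls even at harmonic periods. Boundaries are refined by whole-copy
extension and score-based partial-copy extension (+1 match / −1
mismatch, best prefix/suffix kept) so a clean trailing partial copy is
captured without random bases riding along. Copy number is
`interval_length / monomer_len` rounded half-up to one decimal — the
granularity of the published 32.5 figure, which this arithmetic
reproduces from the printed interval bounds.

## TPase comparative analysis

Distances on caller-aligned sequences: protein p-distance (gap columns
excluded pairwise) and the Tamura (1992) three-parameter nucleotide
distance, d = −h·ln(1 − P/h − Q) − ½(1 − h)·ln(1 − 2Q) with h =
2θ(1 − θ) for GC fraction θ (averaged over the pair, non-ACGT sites
excluded). The continuous-gamma variant replaces −ln x with
a(x^(−1/a) − 1); the discrete-category approximation used by common GUI
software converges to this form and the difference is a documented
stand-in choice. Saturated pairs (non-positive log arguments) return
`inf` — flagged, never silently dropped; neighbor joining excludes such
taxa with a warning. NJ itself is scikit-bio's implementation behind
this package's `DistanceMatrix`; maximum-likelihood inference and
bootstrap support are out of scope, since the claim supported here is
clade separation (two well-separated TPase lineages within single
genomes), not deep-branch resolution. Clade assignment is the
nearest-reference rule with a distance cutoff; equidistant queries
beyond the cutoff are `unassigned`.

## Synthetic data

The generator assembles elements on the published structural grammar
(TIR · direct units · 5' region with captures · ORF1 · optional ORF2 ·
3' region with optional satellite array · inverted units · reverse-
complement TIR), embeds them in i.i.d. background of chosen GC content
with duplicated TSD flanks, and applies i.i.d. substitution noise.
Design points:

- **Noise is substitution-only** by default: the published per-copy
  similarity figures (83.3 % = 10/12) are consistent with substitutions
  over fixed-length units, and substitutions preserve coordinates, so
  ground truth needs no lift-over. Indel noise is out of scope.
- **Domain placeholders** are distinct fixed stop/ATG-free codon
  sequences per domain name, so truth hit tables can be emitted by
  construction and the ORF finder sees clean reading frames. Placeholder
  lengths (TAD 393, Transposase_21 630, DUF4218 525, DUF4216 456,
  Transposase_24 501, Peptidase_C48 123 bp) put ORF1 near its published
  ~3.3-kb scale; they are nominal, not measured values.
- **Background sanitization**: random spacer bases that would form
  chance ≥ 0.80 matches to any rotation of the unit motif inside the
  terminal scan windows are resampled, so ground-truth copy counts are
  exact by construction. Designated copies and fixed features are never
  touched.
- **Named families** (`published_family_spec`) rebuild each published
  element from its printed parameters: TIR, unit motif, per-end copy
  counts, CDA domain set and total length (padding goes into the 3'
  spacer). The vulvaria family pins its 5' geometry so the published
  Neprosin fragment coordinates (2894–3007 and 3254–3457, 754 bp
  upstream of TAD) hold by construction. The quinoa scaffold-3500
  family's per-end counts are not published; a nominal 10/10 layout and
  the iljinii unit motif are used. Seeds are mandatory; there is no
  hidden global randomness.

What the generator does **not** emulate: nested elements, indels and
rearrangements, sequencing error profiles, assembly artifacts, genome-
scale repeat landscapes, and real host-gene sequence for captures
(fragments are labelled placeholders). Passing round trips therefore
demonstrate detector correctness on the published structural model with
substitution noise — not performance on raw genome assemblies.

## Numerical and degenerate-input choices

- N and IUPAC ambiguity codes count as mismatches in identity metrics
  (conservative, deterministic).
- Global alignment identity uses total alignment columns (gaps
  included) as denominator, with the high-road traceback (diagonal >
  up > left) fixed for determinism.
- Consensus ties break by the base order A < C < G < T.
- Element sequences shorter than twice the TIR search cap raise rather
  than silently truncating.
- Same configuration and inputs give byte-identical GFF3/TSV outputs;
  run reports echo the full effective configuration and version.

## Problem sizes

Tests and drivers run at desk scale: single elements of 8–10 kb in
22–40-kb contigs, satellite arrays up to ~6 kb, alignments of ~630 bp
(the tnp2 scale), and replicate counts of 40–200 for statistical
properties. These sizes keep every check deterministic and fast while
exercising the published geometries at full scale — the reconstructed
elements are full-length, not scaled down.

## Known limitations

- Unit-array phase is only defined modulo the unit length; reported
  motifs may be a rotation of the published string (counts are
  rotation-invariant). When a TIR's terminal base coincides with the
  motif's, two rotations are genuinely indistinguishable and noisy
  boundary windows can be judged on a shifted lattice (±1 copy).
- TIR length cannot be delimited from a single element when the subTIR
  mirror continues the terminal match; cross-species conservation
  (sequence logos) would be required, and is out of scope.
- The satellite detector reports maximal non-overlapping arrays; nested
  or interleaved repeat families resolve to the longest-run candidate.
- `global_align_identity` is quadratic and intended for element-scale
  pairwise comparisons, not genome alignments.
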