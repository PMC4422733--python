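# Methods

This note documents the models, parameter defaults and numerical choices
behind `gstmine`, and what the synthetic validation does and does not show.

## Translated homology search

Queries are aligned with Smith–Waterman (BLOSUM62; affine gaps, a gap of
length *k* costing 11 + (*k* − 1); implemented on Biopython's
`PairwiseAligner`) against each of the six frame translations of every
contig; the best frame per (query, contig) is kept. Significance uses the
Karlin–Altschul formula `E = K·m·n·e^(−λS)` with the ungapped BLOSUM62
parameters λ = 0.3176, K = 0.134, *m* the query length and *n* the summed
residue count of all six frame translations of the searched assembly. These
parameters are not strictly correct for gapped alignments, so E-values are
treated as a ranking/thresholding statistic, not as calibrated probabilities.
The default cutoff of 1e−5 is deliberately permissive: on desk-scale data
true family members score far below it, and final retention is decided by
the reciprocal-annotation floor (below), not by the search cutoff. There is
no heuristic seeding: every query×contig pair is aligned exhaustively, which
is exact and fast enough at the scales this package targets (hundreds of
contigs), but not a substitute for BLAST-style indexing on full assemblies.

## ORF extraction and completeness

Within each frame translation, every maximal stop-free stretch of at least
`min_orf_len` residues is reported, both as the full stretch and (when it
contains a methionine) as its Met-initiated resolution. `min_orf_len`
defaults to 40 aa — small enough to keep genuine partial fragments, large
enough that random UTR sequence (bounded at 120 nt in the generator) cannot
produce a qualifying ORF. Completeness is a pure function of three booleans:
in-frame stop upstream, start Met, in-frame stop downstream (see the table in
`orf.py`). The *putative full-length* category covers Met-initiated ORFs with
a downstream stop but no upstream stop observed — complete by content but not
certified by context.

When several ORFs from one contig are candidates, the one with the highest
local-alignment score against the query that retrieved the contig is chosen.
Exact ties are resolved by (1) preferring a Met-initiated form whose Met
aligns to the query's initial Met — this matters because a Met form and the
full stretch containing it have identical local scores, and the Met form is
the protein a curator would deduce; then (2) the longer ORF; then (3) frame
order +1, +2, +3, −1, −2, −3. A putative-full-length pick whose start Met
matches the query's initial Met is promoted to full length, mirroring how
full-length status is argued from a query anchor when no upstream stop is
visible.

## Identity and similarity

Percent identity = identical aligned residue pairs ÷ ungapped length of the
longer sequence × 100; percent similarity additionally counts pairs sharing
a Clustal strong or weak conservation group (the `:` and `.` symbols of the
emitted conservation line). `X` and gap columns never count. For partial
proteins, counting and the denominator are restricted to the region of
overlap: the closed column interval between the first and last column where
both rows have residues. Metrics are computed on global alignments made in a
canonical argument order, so they are exactly symmetric even when co-optimal
alignment paths exist. Full precision is kept internally; report tables
round to integers.

## Reciprocal annotation and vetting

A deduced protein takes the class/subclass label of its best local hit in
the reference panel (ties → higher identity, then lexicographic id). Hits
scoring below a floor of 120 raw BLOSUM62 units leave the protein
unassigned; the floor was calibrated once against an empirical null — the
best panel score of shuffled family proteins (null maximum ≈ 90 across
thousands of draws) — against true members, whose weakest observed score was
≈ 178. Pipeline retention is gated on this annotation floor alone; domain
and motif evidence are reported as vetting columns rather than used as a
second veto, because a truncated protein can legitimately lack a domain
while the score floor already rejects non-family sequence decisively.

Domain presence (GSTN, GSTC, thioredoxin-like/THX, MAPEG) is scored by
sliding a log-odds PSSM (pseudocount 0.5, uniform background, bits) built
from the shipped seed alignments; windows may overhang down to 50 columns of
overlap so truncated domains still score. The statistic is the best mean
per-column score; per-domain thresholds (0.08, 0.10, 0.055, 0.15 bits) were
frozen after calibration on shuffled-protein and random-protein nulls (99th
percentile plus margin, giving a measured false-positive rate below 1%)
while keeping every intact planted domain above threshold. The shipped seed
alignments are synthetic (see below) — substituting real curated seed
alignments for real data only requires dropping aligned FASTA files and a
`thresholds.yaml` into a profile directory.

Motif scanning is exact sliding-window matching of fixed/wildcard patterns
(wildcard `x`); every window within the mismatch budget is reported with its
substitution list, each substitution classified conservative when the
expected and observed residues share a strong or weak group (so L→Q at
position 9 of `VERVRRxHLNDxENIx` is non-conservative: leucine's hydrophobic
groups share no member with glutamine's polar ones).

## Cross-population correspondence

Within each assigned subclass, proteins from the two assemblies are paired
by bidirectional best hit on overlap identity. Verdict thresholds encode the
empirical structure of the problem: orthologs from isolated populations of
one species sit near or above 90% identity, while within-subclass paralogs
sit around 30–50%; hence `t_same` = 90 (same gene) and `t_distinct` = 50
(distinct gene), both configurable, with the interval between reported as
*divergent ortholog* — deliberately without asserting gene identity, since
that range is genuinely ambiguous. An unmatched protein qualifies as an
additional-gene candidate only if it is below `t_distinct` to every
same-assembly subclass mate; candidates trigger a targeted re-search of the
other assembly (cutoff relaxed to 1e−3) and are upgraded to a same-gene pair
when a ≥ `t_same` partner — typically a short partial transcript missed by
primary mining — appears. Merging counts one gene per reciprocal pair above
`t_distinct`, two per distinct-gene pair, and one per remaining unmatched
protein, with completeness upgraded to the best evidence across assemblies.

## Expression

RPKM = counts ÷ (transcript length in kb × mapped reads in millions), with
the library's total mapped reads (whole reference, not just the family
catalog) as the denominator. Stage summaries are means and sample standard
deviations over replicates of log2(RPKM + pseudocount); the pseudocount
defaults to 1 so zero counts plot at 0, and raw RPKM is always carried
alongside. SD is defined as 0 for single-replicate stages. Read mapping and
quality filtering are out of scope: the count table is the interface.

## Synthetic data generator

The generator is first-class, tested code that defines the validation
conditions; it emulates the divergence structure of a duplicated enzyme
superfamily observed across two mostly isolated populations:

* **Architecture.** Each subclass ancestor is built from shared domain
  consensus segments (cytosolic: Met + lead + GSTN + linker + GSTC + tail,
  ~230 aa; mitochondrial: THX + extension, ~255 aa; microsomal: MAPEG,
  ~151 aa) with subclass-specific random linkers, then diverged to 50%
  identity to the consensus. Realized cross-subclass protein identity is
  ~10–22%, far below the within-subclass band.
* **Divergence model.** Iterated point substitution with accept/reject on
  measured identity; replacements are drawn from the current residue's
  strong conservation group 70% of the time, so similarity stays well above
  identity, as in real families. Targets are met within one substitution
  (±0.5% at these lengths).
* **Families.** Paralogs descend from the ancestor at per-gene identities
  chosen so pairwise within-subclass identity lands in the requested band
  (default 30–60%). Population-B orthologs descend from the population-A
  protein at a per-gene target sampled from 88–100% (per-gene overrides
  allow outliers such as a 48% population-specific form). Private genes are
  accepted only when below 44% to every subclass mate, safely under the
  distinct-gene threshold.
* **Contigs.** Proteins are back-translated with uniform codon choice.
  Full-length genes get random UTRs (30–90 nt) with an in-frame stop
  directly upstream of the start codon; a `fraction_partial` subset
  (default 0.15) is truncated into C-terminal/N-terminal partials or
  internal fragments, with per-class cut ranges that keep at least one
  scorable domain window and never start the fragment on a Met. Decoys
  (default 100 per assembly) are half random nucleotide contigs, half
  back-translations of shuffled planted proteins (composition-matched
  nulls). In the mGST-1 subclass the 16-mer motif is held fixed apart from a
  planted Q at position 9, emulating a species-specific non-conservative
  substitution against the canonical L.
* **Counts.** Per library, multinomial sampling at depth 2×10⁶ over planted
  transcripts plus a constant background mass 25× the stage-averaged catalog
  weight (so the family is a small, realistic slice of each library and
  RPKM is comparable across stages); weights are planted stage level ×
  length × log-normal replicate noise (σ = 0.25). The default stage profile
  gives Delta and Sigma genes an embryo-low → late-copepodite/adult-high
  ramp and other genes flat moderate expression.

The default scenario plants 39 genes in population A (Delta 11, Theta 1,
Mu 5, Omega 3, Sigma 10, Zeta 2, Kappa 1, mGST-1 2, mGST-3 4) plus one
private Delta and one private Omega in population B, so the merged catalog
holds 41 genes. Everything is deterministic given the seed (byte-identical
FASTA output).

**What passing tests show — and don't.** Exact recovery on this generator
demonstrates that the classification logic, thresholds and bookkeeping are
correct under controlled divergence with substitutions only. Real
assemblies add indels, chimeric and fragmented contigs, alternative
isoforms, codon bias, sequencing error and assembly artifacts, none of which
are simulated; on real data the search/annotation margins will be narrower
and the identity thresholds should be read as biological conventions, not as
guaranteed separators.

## Synthetic profile seeds

The shipped seed alignments under `data/profiles/` are synthetic: a fixed
random consensus per domain plus seven variants at 75–45% identity generated
with the same group-biased substitution process (filenames and headers are
marked accordingly). They define a self-consistent universe for the
generator and the vetting profiles. They are not curated GST domain models,
and presence/absence calls on real proteins require real seed alignments.

## Numerical choices and edge cases

* Alignment conventions: end gaps penalised in global mode; empty local
  alignments (no positive-scoring pair) return score 0.
* Degenerate inputs: `N` codons translate to `X`, which never counts as
  identical or similar; empty FASTA files, duplicate ids, zero-length
  overlap in partial-mode metrics, zero mapped reads, and negative
  pseudocounts all raise explicit errors.
* Determinism: no global random state; every stochastic routine takes a
  seed or `numpy` Generator, and pipeline reports hash-compare equal across
  runs.
* Scale: the default scenario (≈ 280 contigs × 18 queries × 6 frames per
  assembly pair) runs in ~25 s on one CPU; the ten-seed recovery check runs
  in a few minutes. These problem sizes were chosen to exercise every code
  path at full fidelity while staying desk-scale.

## Known limitations

* No frameshift stitching across frames: a contig with an indel that splits
  the ORF across frames yields two partials, not one repaired protein.
* E-values are ordering statistics (ungapped parameters, no length
  corrections or compositional adjustment).
* Domain boundaries from PSSM windows are approximate; only
  presence/absence and rough spans are meaningful.
* The correspondence verdicts depend on alignment parameters near the
  thresholds; identities within ±2 points of 50% or 90% can plausibly change
  verdicts with different gap settings, which is why validation avoids
  those bands.
* Multiple sequence alignment, phylogenetics, read mapping and differential
  expression are out of scope.
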