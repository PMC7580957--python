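# Methods

## Coordinate and end conventions

All internal coordinates are 0-based half-open `[start, end)` on a named
contig with strand `+`, `-`, or `.`; GFF3 (1-based inclusive) and SAM
(1-based in text form) are converted at the I/O boundary.  For a `+`
alignment spanning `[s, e)` the 5′ end is `s` and the 3′ end is `e − 1`
— the last aligned base, since a nuclease cut abuts the final nucleotide
and the half-open `e` is a bookkeeping convention, not a position on the
molecule.  For a `-` alignment the roles swap.  End profiles are indexed
5′→3′ along the *feature's* strand so plots read the same way regardless
of genomic orientation; end types always follow the read's own chemistry,
so an antisense read contributes its 5′ count at the feature-frame
position of its genomic 5′ base.  Gapped alignments are collapsed to
their reference span (bacterial Ribo-Seq is effectively ungapped);
duplicate alignments are kept; reads on strand `.` are accepted for
coverage/RPKM but rejected by end profiling, which needs an orientation.

## Expression calls

RPKM = count / (length/10³) / (total_mapped/10⁶), with `total_mapped`
defaulting to all primary mapped alignments in the library.  Counting is
any-overlap (≥ 1 nt, half-open, so abutting intervals do not overlap) and
strand-agnostic by default, matching `bedtools multicov` without flags; a
`stranded` switch restricts to same-strand reads.  A feature is
"expressed" when RPKM strictly exceeds the threshold (default 10).  The
threshold comparison being strict matters only at the exact boundary and
is covered by a dedicated test.

## ORF enumeration and overlap classes

ORFs are every span from a bacterial start codon (ATG, GTG, TTG) to the
nearest in-frame stop (TAA, TAG, TGA), stop included in the length, on
both strands and all three frames, down to 15 nt (4 aa + stop).  Nested
starts sharing a stop are distinct candidates.  ORFs containing N are
skipped with a log entry.  Ribosome-binding sites are called by scanning
for AGGAGG with ≤ 1 mismatch at a spacer of 5–13 nt upstream of the start
codon, strand-aware; motif, mismatch budget, and spacer window are
configurable, since no single bacterial RBS definition is canonical.
Start-site and coding-potential support comes from a Prodigal `-s`-style
score table joined to ORFs by exact coordinates (we consume the gene
caller's output rather than re-deriving its model; a score row matching
no enumerated ORF is an error).  An ncRNA is then classified by the ORFs
overlapping it on either strand: `no_possible_orf`, `possible_orf_only`,
or `orf_with_support` when any overlapping ORF has start score > 0,
coding score > 0, an RBS, or is small (< 50 aa — the class gene callers
handle worst, so smallness alone keeps an ORF "possible").

## The fragment-length filter

A read whose aligned length reaches the sequencer read length cannot
certify that its fragment ended where the read ends: the 3′ end is where
the machine stopped, not where the nuclease cut.  `filter_fragment_truncated`
removes reads with `query_length ≥ max_read_len` (boundary inclusive for
exactly that reason).  `max_read_len` is deliberately a required
parameter with no default — it is a property of the sequencing run, and
libraries differ.  One consequence worth keeping in mind: with 36-nt
reads the *effective* upper size limit of profiled fragments is 35 nt,
regardless of the 45-nt wet-lab size selection.

## Permutation tests

Two association statistics share one null construction:

* junction test — statistic = fraction of called peaks within ± `tolerance`
  nt (circular distance) of any paired↔unpaired junction;
* CRISPR partition — statistic = fraction of total depth inside repeats
  (on uniform depth this equals the repeat-length fraction exactly).

The null rotates the observed configuration (peak set, or depth vector)
by a single uniform random offset per permutation.  Rotation preserves
the internal spacing of the data, which makes the test stricter than
independent resampling: a periodic peak pattern re-aligns with periodic
windows under rotation, and only genuinely position-locked association
survives.  P-values use the add-one estimator
`(1 + #{null ≥ observed}) / (n_perm + 1)`, floor `1/(n_perm+1)`.

Peak calling is a local-maximum rule: position *i* is a peak iff
`count[i] ≥ min_count` (default 5) and `count[i]` is maximal within
± `window` (default 2); among equal-height candidates within a window the
leftmost is reported, so output is deterministic.

### Resolution of the rotation null

Because the null only shifts, offsets of ± `tolerance` keep every
exact-junction peak inside its window and tie the observed statistic, so
the attainable p-value is bounded below by roughly
`(2·tolerance + 1) / L` plus the floor.  For a 300-nt feature at the
default tolerance 2 that bound is ≈ 0.017: no peak set, however perfect,
can reach p ≤ 0.01.  Sharper testing at short-feature scale therefore
uses tolerance 0 on the 5′-end profile, whose peaks land exactly on
junctions — the cut bond at a junction is the bond between the last
unpaired and first paired base, and the 5′ end of the resulting fragment
*is* the junction position.  (3′ ends sit one base inside the stem by the
last-aligned-base convention, so they are the wrong end type for an
exact-position test.)  The pipeline default stays at tolerance 2, which
is the right setting for diffuse real-data peaks; the acceptance checks
use tolerance 0 where sub-0.01 significance is asserted.

### Calibration and its discreteness

The add-one estimator with ties counted against significance is
conservative: the statistic takes ~`n_peaks` distinct values, the null
matches the observed value with probability ~0.1, and the resulting
p-values are discretely super-uniform.  Measured on no-protection
digests (equal cut probabilities), type-I error at nominal 0.05 is
0.02–0.07 and a two-sided KS against the continuous uniform rejects an
appreciable fraction of honest runs on discreteness alone.  The
calibration check is therefore one-sided — it rejects only if small
p-values are *over*-produced, the failure mode that would manufacture
false structure calls — and the type-I rate is measured on a larger
instantiation (3000-nt transcript, 40 stems, 200–400 uniform random
peaks) where the statistic is fine-grained enough for the rate to sit
near nominal (measured ≈ 0.043 ± 0.010 across seed streams).

## The digestion simulator

The generator emulates structure-protected nuclease digestion with size
selection.  Cut events live on the bonds *between* nucleotides: each
bond is cut independently per molecule with probability `p_cut_unpaired`
(default 0.2) unless **both** flanking bases are paired, in which case
`p_cut_paired` (default 0.005) applies.  Junction bonds have one unpaired
flank and therefore cut at the high rate — exactly the mechanism that
concentrates fragment ends at junctions.  Molecule ends count as cuts;
fragments are the runs between cuts; a hard [15, 45] nt window models
gel size selection (no length-dependent efficiency curve).  Each
surviving fragment becomes one error-free, ungapped alignment; fragments
longer than `read_len` (default 36) are truncated from the 5′ end and
flagged in ground truth — these are exactly the reads the fragment
filter must remove.  All randomness flows from one seeded
`numpy.random.Generator` per invocation; identical seeds give
byte-identical outputs.

Default transcript geometry emulates a heavily base-paired regulatory
RNA of the 6S-RNA kind: hairpins with arms up to 25 nt (jittered
downward a few nt per hairpin), 4-nt loops, and short unpaired linkers
(3–7 nt, leftover length spread across them).  Three constraints shaped
these defaults, and they are design choices, not biological
calibration:

1. an arm plus its short unpaired flanks must fit under the 36-nt read
   length, or stem fragments are lost to the fragment filter and
   junction classes lose their anchored 5′ peaks;
2. the architecture must be aperiodic (jittered arms and linkers) —
   identical evenly spaced hairpins are self-similar under rotation,
   which fattens the null tail of the rotation test and no natural RNA
   is periodic anyway;
3. residual cutting inside stems scales with
   `p_cut_paired × n_molecules`, so the default depth (400 molecules,
   ≈ 2,300 surviving fragments for the 300-nt/4-stem condition) keeps
   that noise floor below the peak threshold `min_count = 5`.

Simulated CRISPR arrays alternate identical hairpin repeats (default
30 nt: 13-bp arms, 4-nt loop) with unstructured spacers (default 35 nt),
matching the premise that direct repeats are the only structured regions
of a CRISPR transcript; the emitted GFF uses minCED/Prokka-style
`repeat_region` rows and round-trips through the parser.  Ribosome
footprints are placed uniformly inside coding ORFs with lengths uniform
in 15–40 nt — a deliberately featureless background (no periodicity, no
ramp), sufficient for expression arithmetic but not for codon-level
analyses, which are out of scope.

What the simulator does *not* model: MNase A/T sequence preference,
ligation bias, partial digestion kinetics, transcript-abundance
heterogeneity, or mapping error.  Passing the recovery tests therefore
shows the analysis correctly inverts the protection geometry it assumes,
not that real libraries are free of these confounders; on real data the
enrichment statistics remain valid as tests, but effect sizes will be
attenuated by everything the generator idealizes away.

## Scenario scale

The shipped study conditions are desk-scale by construction: a 300-nt
transcript with 4 stems digested as 400 molecules, a 65-ncRNA expression
panel (61 expressed, planted counts of 100 reads each over 200-nt
features against a 5,000-footprint coding background; silent ncRNAs get
zero reads, because at a ~25k-read library even one read on 200 nt
exceeds RPKM 10), and an 18-repeat CRISPR array.  The full test suite
runs in well under a minute; `scripts/acceptance.py` in a few seconds.

## Degenerate inputs and tie-breaks

Balanced-bracket and length validation happens at `StructureAnnotation`
construction; unbalanced or mixed-length records never enter the
pipeline.  Zero peaks or zero junctions make the enrichment test raise
("nothing to test" is distinct from a negative result), as does an
all-zero depth vector over a CRISPR array.  Single-repeat arrays warn
and carry no spacers.  Overlapping repeat rows are an error.  Peak ties
break leftmost; GFF duplicate IDs are an error listing the offenders;
BED records without a strand column are rejected (RPKM tolerates strand
`.`, end profiling does not).
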