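# Methods

## Scope and model

`mirquest` re-implements a small-RNA analysis protocol with two branches
sharing one read ledger: (1) quantification of known mature miRNAs and
fold-change comparison between libraries, and (2) discovery of novel
miRNA-like loci from reads that match no known miRNA. All genomic
coordinates are 0-based half-open in memory; GFF3 (1-based inclusive) is
converted at the file boundary. Sequence files use the DNA alphabet; the
RNA view (T→U) exists only inside the structure module.

## Quantification

Identical read sequences are collapsed per library before matching and
copy counts carried, never recomputed. Contaminant filtering is a
substring match against labelled rRNA/tRNA/repeat/adapter records
(mismatch budget configurable, default exact). Mature matching is
5′-anchored Hamming comparison: the mature start may sit within
`max_shift` (default 2) nt of the read start, substitutions are counted
over the overlap (N always mismatches), terminal bases outside the
overlap are not penalised, and the overlap must reach 15 nt. This is a
deliberate base-space translation of the original protocol's color-space
budgets (3 seed + 6 total color mismatches), which have no exact
base-space equivalent; ≤ 2 substitutions with ≤ 2 nt shift is
conservative and testable, and both knobs are configurable. No indels:
the matcher is not an aligner, and isomiR cataloguing is out of scope.

The multi-hit rule follows the published worked example: 1 hit → the
mature name; 2–5 hits all in one family → the family key; more hits or
several families → discarded as ambiguous. Whether the 5-hit cap applies
to distinct precursor hits or to families after collapsing is not
specified by the protocol; the default caps distinct hits, and
`cap_on="families"` switches. Family keys come from an explicit family
map when given, else from stripping a trailing `-<digit>` copy suffix.

## Expression comparison

Counts are normalized by the highest value in the library (per-library
max; a `global_max` mode normalizes all libraries by one shared maximum —
the published description is ambiguous between the two, and per-library
max is the default because it makes profiles comparable as relative
abundances). Differential calls are a pure fold-change rule at ≥ 2, with
no variance model, applied only to labels expressed in both libraries:
the expression floor defaults to the smallest nonzero normalized value,
so zero-versus-nonzero labels never produce infinite folds and are
reported by `unique_expressed` (≥ 10 copies in one library, zero in the
other) instead. Percentages of shared miRNAs are rounded half-up to two
decimals, matching the precision of the published comparison table. The
published raw→normalized factors for clinical samples are internally
inconsistent in one sample and are not used as oracles anywhere.

## Discovery

Reads kept for discovery are `< 35` nt with `>= 10` copies (the protocol
states both "more than 10 copies" and "at least ten reads" in different
places; inclusive is the default, a flag switches to strict). Mapping is
exact on both strands — the original mapper was color-space-specific, and
exact matching keeps the branch self-contained and deterministic — with
reads placed at more than 5 loci dropped and logged (the 5 mirrors the
multi-hit cap; the protocol does not state a genomic cap). Clusters chain
placements with gaps ≤ 10 nt (protocol silent; configurable) and are
extended 100 nt both ways, clamped at chromosome ends; the extension size
derives from the observation that 98% of annotated human precursors are
shorter than 135 nt (the inclusive lower quantile is exposed as
`length_quantile`). The extension starts from the cluster span, not the
single read, when clusters hold several reads.

Adjacent candidates on one chrom/strand within 50 nt (or overlapping) are
merged when, after folding their joint interval, reads of the two
candidates sit on opposite arms of a single helix (≥ 50% of the read on
the arm) — the mature/star signature. Merging iterates to a fixpoint and
is idempotent.

## Folding and the read-in-stem call

The built-in folder is a pair-scored Nussinov dynamic program (GC 3,
AU 2, GU 1; minimum hairpin loop 3) maximising the summed pair score; the
reported `energy_score` is minus that sum — a stability proxy, never
kcal/mol. Traceback ties are fixed: the 5′-most base of each subinterval
pairs with its smallest admissible partner whenever pairing attains the
optimum. The DP fill is JIT-compiled (numba); the traceback is plain
Python. External Vienna-style structures with real free energies can be
parsed in and flow through classification unchanged; published candidate
energies are reproducible only with the original folder and sequences, so
they are never asserted.

Helices are maximal runs of stacked pairs tolerating per-arm gaps ≤ 2 nt
(bulges); arm intervals include tolerated bulge positions, so a read over
a small interior bulge still classifies TOTAL. The overlap call is set
arithmetic on the union of arm intervals: TOTAL if every read position is
inside, NONE if none, PARTIAL otherwise (no lower bound on PARTIAL — the
protocol's "partially" is unquantified).

## Ab-initio score

The stand-in for HMM-based precursor classification is a logistic over
fold features with frozen weights (`ABINITIO_WEIGHTS`), calibrated once
on synthetic draws (planted precursors vs shuffled sequence) and not
revisited. The dominant feature is the longest *strictly stacked* helix
overlapping the read: maximum-pairing folds of random 222 nt windows pair
~73% of bases and produce long *bulged* helices, so global pairing
statistics (paired fraction, energy per nt, loop length) barely separate
the classes — but an uninterrupted ≥ 14-pair duplex under the read occurs
essentially only when a real inverted repeat was planted (shuffled
controls topped out at 9 stacked pairs in calibration). Those weaker
global features are retained with small weights. The 0.71 cutoff
mirrors the published operating point of the original classifier; scores
below it are recorded, not discarded, since the published candidate
table itself lists sub-threshold scores as predictions, and verdicts are
decided by the tier rules.

## Evidence integration

Similarity search seeds on exact 6-mers and runs full Smith–Waterman
(+1/−1/−2, linear gaps) on seeded subjects; retention requires identity
≥ 80% and coverage ≥ 80% of query *or* subject (a 22 nt mature inside a
222 nt precursor passes on the subject side with ~10% query coverage, as
in the published hits). The E-value is a Karlin–Altschul-shaped proxy
(`evalue_proxy`) used as a permissive pre-filter only: reproducing a real
aligner's statistics is out of scope, and a legitimate 80%-identity hit
over a short subject carries a large nominal E-value, so identity and
coverage are decisive. False-positive exclusion removes candidates on
annotated exons (strand-aware; feature priority exon > intron >
intergenic), candidates matching non-miRNA ncRNA types above the
similarity cutoffs ("miRNA" and "unclassified RNA" types never exclude),
and candidates named by an external tRNA caller; each exclusion carries
exactly one primary reason in that priority order. Adapters parse
covariance-model tabular output (bit-score cutoff 25, coordinates
normalized to candidate-local 0-based half-open) and two-column ab-initio
score files.

Verdict tiers operationalise what was originally a manual curation step:
**excluded** (failed a false-positive rule), **strong** (reads on both
arms of one stem — the merged mature/star case — or a structural family
hit covering the read with the read at least partially in a stem),
**supported** (≥ 1 positive channel with the read in a stem, or ≥ 2
positive channels), **weak** (everything else). Tiers are deterministic
and monotone: adding a positive channel never lowers a tier. Mature
proposals for promoted candidates are the read itself plus its star — the
positions paired to the read shifted 3′ by the canonical 2 nt duplex
overhang.

## Synthetic data

The generator emulates the experimental design at desk scale: one
chromosome (default 60 kb) with 21 non-overlapping planted loci — 12
known miRNA hairpins (the first two are genomic copies of one family with
identical mature sequences, exercising family collapsing; one locus is
ten-fold dominant and anchors the library maximum; two are 4-fold up in
each library; one is expressed only in L1), 3 novel two-arm hairpins
absent from the mature reference (mature arm at the full per-locus mean,
star arm at half, the last one inside an annotated intron), 2 decoys
(shuffled hairpin inserts; the last sits in an annotated exon), and 4
contaminant loci. Per-locus counts are Poisson with mean 100 (fixed-count
mode for exact tests); read ends are trimmed 0–2 nt with weights 0.8 /
0.15 / 0.05 favouring canonical ends, as in real libraries; substitution
errors default to 0.5% per base; FASTQ qualities are constant because the
protocol uses none.

Two screening steps keep planted classes true to their definitions, both
deterministic per seed. Hairpin stems receive G·U wobbles (rate 0.1, at
least one forced): real precursor stems are wobble-rich, and a perfect
inverted repeat would map its reads to both genome strands. Because a
wobble occasionally lets the folder trade a weakened stem pair for a
spurious loop-local pair, hairpin draws are redone until the mature (and
for novel loci the star) arm classifies TOTAL in the ±100 nt window the
pipeline will fold; symmetrically, decoy shuffles — whose base
composition remains self-complementary and can re-form a long duplex by
chance — are redone until the read region carries no hairpin signal.

What the generator does not emulate: color-space chemistry, adapter
ligation artefacts, quality-score structure, expression heterogeneity
beyond per-locus Poisson, isomiR 3′ tailing, and cross-mapping between
near-identical paralogs other than the planted family pair. Passing tests
therefore demonstrate the correctness of the pipeline's logic and its
recovery behaviour under idealised noise, not performance on real SOLiD
libraries — whose raw reads were never deposited and whose dataset-level
headline numbers (counts of detected/differential miRNAs, 448 candidates)
are consequently not reproducible and not asserted.

## Problem sizes and determinism

Defaults are chosen so a full end-to-end run (two libraries, ~7 400 read
copies, 5 candidates) completes in seconds: folding is O(n³) in the
222 nt precursor length and is the dominant cost. Every random draw flows
from a single integer seed through `numpy.random.default_rng`; reruns
with one seed produce byte-identical fixture bundles and report files
(asserted by checksum in the tests). Degenerate inputs are defined
errors: empty profiles, empty clusters, out-of-range read intervals and
malformed external files raise with context rather than propagating
nonsense.
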