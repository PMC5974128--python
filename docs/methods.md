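# Methods

## Reference mapping and the conservation profile

Homologs are mapped to the reference repeat unit one at a time, read-mapping
style, rather than through a progressive multiple alignment: rDNA records
pulled from public databases are heterogeneous in length, orientation and
quality, and independent semi-global alignment keeps every decision local to
one sequence. The aligner (Biopython's `PairwiseAligner`) runs globally with
free end gaps on both sequences, so a homolog may cover any interval of the
reference and may overhang its ends; scores are match +1, mismatch −2,
gap open −5, gap extend −2 — conventional DNA mapping weights, configurable
via `AlignmentScoring`. Both orientations are tried and the one with more
identically aligned nucleotides wins, ties resolving to forward.

A homolog is **accepted** when at least `min_match = 50` nucleotides align
identically. Acceptance is monotone in the threshold by construction
(the alignment is computed once; only the cutoff moves).

The profile lives strictly in reference coordinates (1-based inclusive
throughout the package): each accepted homolog increments the count of its
aligned base at every aligned reference column. Insertions relative to the
reference have no column and are ignored; deletions leave columns
un-incremented, so per-column depth = A+C+G+T count ≤ number of accepted
homologs. Non-ACGT letters in input homologs (database `N`s) are skipped.

## Degenerate consensus

At each column with depth ≥ `min_depth` (default 2) the consensus letter is
the IUPAC code covering exactly the set of bases whose frequency among
counted bases reaches `freq_threshold` (default 0.2); the most frequent
base — all of them on a tie — is always included so the set is never empty.
Columns below `min_depth` are trimmed from the flanks and written as `N`
internally. `freq_threshold` is restricted to (0, 0.5]: above 0.5 the
"always include the majority" rule would be the only active clause.
Consensus degeneracy is monotone non-increasing in the threshold.

## Melting temperature

The Tm engine is the empirical GC/length closed form with salt and
formamide corrections:

    Tm = b + s·log10([Na+]) + g·(%GC) − n/L − f·F

with defaults b = 81.5 °C, s = 16.6 °C per log10 M, g = 0.41 °C per %GC,
n = 675 °C·nt, f = 0.65 °C per % formamide — the standard FISH-oligo
formula family. It is applied only for L ≥ 14 nt, below which the
oligonucleotide regime takes over and the formula is not meaningful.
`[Na+] = 0.195 × SSC fold` counts the three sodiums of trisodium citrate on
top of 0.15 M NaCl; set `na_per_ssc_fold = 0.165` for the NaCl-only
convention. Default conditions are 2×SSC with 50% formamide.

For a degenerate pool, Tm varies across expansions only through the GC
count, in which the closed form is monotone, so the pool's Tm interval is
attained at the minimum- and maximum-GC expansions; `tm_range` uses the GC
bounds directly and agrees with brute-force enumeration (tested).

Printed probe tables rarely disclose their Tm engine, and the degenerate-row
range widths in the packaged table are wider than the GC-only form can
produce (suggesting a nearest-neighbor engine). The printed Tm column is
therefore treated as **calibration data, not ground truth**:
`calibrate_model` grid-searches n ∈ [400, 800] (step 5) and
f ∈ [0.5, 0.8] (step 0.01), profiling the intercept b out in closed form
(clipped to [75, 90]), and minimizes RMSE against the fixed-sequence rows.
At a single hybridization condition b and f are exactly collinear — only
b − f·F is identified — so the fit's predictions, not its individual
coefficients, are meaningful; against the packaged table the best fit
leaves an RMSE the test suite only requires to be finite and reported.
A zero-variance Tm column is flagged (`degenerate_fit`) rather than fitted
silently. A nearest-neighbor model is deliberately out of scope; the
`TmModel` seam permits adding one.

## Probe scanning

Candidates are all consensus windows of `len_min..len_max` (24–31 nt)
containing no `N`, with pool size ≤ 256, whose **entire** Tm interval lies
inside [39, 53] °C — conservative on purpose, because every member of a
pooled degenerate probe must hybridize — and whose mean depth is at least
half the profile maximum. Candidates are ranked by mean depth fraction,
then Tm floor (a higher floor hybridizes more robustly at room
temperature), then leftmost start, and selected greedily with ≥ 20 nt
between chosen probes. Greedy selection (not an ILP) matches how such
panels are picked in practice and is deterministic. Probes are reported on
the consensus (sense) strand; hybridization targets denatured chromosomal
DNA, so strandedness is a labeling convention and `--revcomp` emits the
antisense sequences.

Note that when a fully conserved window ties with its neighbors at maximal
depth, the Tm tie-break may select a probe extending a nucleotide or two
past the window edge; the scan guarantees a probe *targeting* a conserved
window, not one confined to it.

## Tandem-repeat probes

A tandem-target probe is the length-`target_len` prefix of the infinite
monomer repetition started at offset `phase`. Monomers must be primitive
(not themselves a repetition). `pick_tandem_length` scans 24–31 nt at phase
0 and returns the smallest length whose Tm lands in the window, or an
infeasibility report listing the per-length Tm (an AT-rich monomer such as
a telomere repeat can undershoot the window at every legal length under
the default model).

## Panel assembly

Probe names encode target class (`18SrDNA_`/`5.8SrDNA_` → 45S, `5SrDNA_` →
5S, `Tel_` → telomere, `Pgms` → minisatellite), lineage (`ang`, `gym`,
`cranial`, or `UniOP` = universal) and a trailing design-position index that
groups lineage variants of one position. Cocktails pool one target class
under one fluorophore — the experiment's label choice overrides the table's
column — and no two cocktails in an experiment may share an emission
channel (FAM and Alexa Fluor 488 are both green-class). Tandem rDNA arrays
carry thousands of binding sites; flagging such a target as bright truncates
its cocktail to the `cap` lowest-numbered probes (default 4) so its signal
does not bleed into neighboring filters. Spectral unmixing is out of scope.

The packaged table transcribes a published 26-probe panel; sequence-derived
length is authoritative and machine-checked against the printed length
column on load. All rows are 5′-labeled.

## Minisatellite read screen

A read matches when some window of ≥ `min_span` nt (default 30 ≈ three
11-mer copies) aligns to the infinite monomer concatemer at some rotation,
on either strand, with mismatch fraction ≤ `max_mismatch_frac` (default
0.1). Matching is ungapped — copies are short and trying all phases absorbs
register shifts; gapped matching is out of scope. The search is exact: with
prefix sums of (mismatch − tolerance), a qualifying window of any length
≥ `min_span` exists iff the minimum over window sums is ≤ 0, evaluated for
all phases at once in vectorized form. Outcomes are invariant to monomer
rotation and read reverse-complementation, and monotone in the tolerance
(all tested, including against an exhaustive all-phase/all-window oracle).

A sample's mapped fraction is mapped/evaluable (evaluable: read ≥ one
monomer long). The presence call compares that fraction to 10× the
empirical random-match rate measured on base-shuffled copies of the same
reads (seeded, hence deterministic), floored at one read so an all-negative
sample is never called present; an explicit threshold can be supplied
instead. Presence calls are threshold-relative, not absolute abundance
estimates.

## Synthetic data

`simulate_family` draws a random ancestor and mutates each homolog
independently (star phylogeny — no tree structure, deliberately):
substitutions at the per-lineage rate, uniform over the three alternative
bases (no transition bias; sufficient for consensus/degeneracy testing),
and single-base indels at `indel_rate` with equal insertion/deletion odds —
enough to exercise reference-coordinate bookkeeping without complicating
the ground truth, which records every mutation and is replayable (tested).
Planted conserved windows are never mutated, and their ancestor bases are
drawn GC-rich (60% vs 50% background) to emulate the GC-rich conserved
cores of rDNA genes — the property that puts real conserved-region probes
inside the 39–53 °C window. Defaults: 600-nt ancestor, 3 lineages × 20
homologs, 5% substitution rate, 1% indel rate, one 30-nt window at columns
286–315, seed 42.

`simulate_reads` plants a fraction of concatemer reads (random phase,
random strand, per-base error rate 1%) among uniform random background;
read ids carry the ground truth. What these generators do **not** emulate:
real rDNA covariation structure, database contamination and partial
records, sequencing quality profiles, and genome-scale background
complexity — so passing tests demonstrate correctness of the algorithms
under controlled conditions, not field performance on arbitrary databases.

## Problem sizes and numerical notes

Tests run the full pipeline at a 600-nt ancestor with 60 homologs and
10,000-read screens; the brute-force screen oracle is checked on 300 noisy
reads. Floating-point window tests use a 1e-9 slack so a window exactly at
the mismatch tolerance counts as matching. All randomness flows through
`numpy.random.default_rng` seeds carried in the spec objects; identical
specs give byte-identical output.

## Known limitations

- No cross-hybridization screen against a background genome, no secondary
  structure or self-dimer checks.
- The Tm default is a GC/length approximation; absolute printed-table
  agreement requires calibration and even then only the identified
  coefficient combinations are recovered.
- Consensus quality depends on the homolog set supplied; the package does
  not fetch or curate database sequences.
- The read screen is ungapped and presence calls are relative to an
  empirical background threshold.
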