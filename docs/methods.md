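# Methods

## The pipeline

orthohunt automates a common phylogenomics task: given a set of query
profile HMMs (one per gene family of interest) and a set of proteomes, find
each gene in each proteome, decide whether it is single-copy, and collect
the single-copy sequences into per-marker FASTA files.  The run loops over
proteomes (outer) and profiles (inner); for each pair it

1. scores every protein with the forward algorithm (below) and keeps hits
   with E ≤ `evalue_max` (default 1e-3, per-database);
2. applies the best-hit rule: keep hits with bit score ≥ `bitscore_fraction`
   × the best hit's score (default 0.85, the criterion BUSCO uses to define
   top hits).  Kept hits are the putative homolog set for the pair;
3. classifies the pair by the size of that set: 0 → absent, 1 →
   single-copy, ≥ 2 → multi-copy.

Gene-specific score and length cutoffs of the kind BUSCO layers on top of
this rule are deliberately not implemented; the fraction filter is the
whole criterion.  Isoform collapsing is likewise out of scope: a proteome
containing multiple isoforms of one gene will legitimately be called
multi-copy, and isoforms should be collapsed before (or interpreted after)
a run.

## Scoring model

Bit scores are uni-hit local forward log-odds:

    score = log2 [ P(seq | profile, local) / P(seq | null) ]

with the following fully specified generative model.

**Alignment region.**  A local alignment begins and ends on a match state.
The (entry k, exit l ≥ k) pair is drawn uniformly over the M(M+1)/2
possibilities; between entry and exit the path follows the profile's own
match/insert/delete transition probabilities as stored in the HMMER3 file.
Delete states emit nothing; paths through the last node's insert state
cannot reach an exit and carry no probability into the score.

**Flanks and null.**  Unaligned N- and C-terminal residues are emitted from
the profile's background distribution by flank states with loop probability
p = L/(L+2) (L = sequence length).  The null model emits all L residues
i.i.d. from the background with geometric length parameter L/(L+1).
Because flank and null emissions share the background, they cancel in the
odds ratio, leaving the aligned region's emission odds plus length-model
corrections.  The resulting model is a (sub)probability distribution over
sequences, which gives the diagnostic property — verified by a Monte-Carlo
test — that sequences drawn from the background have non-positive expected
log-odds.

The forward recursion is computed entirely in log space (log-sum-exp per
cell), so sequences of at least 10,000 residues score without underflow.
Scoring is deterministic: identical inputs give bit-identical results.

Residues outside the canonical 20-letter alphabet (X, B, Z, U, `*`, ...)
are scored with their background frequency mass, i.e. emission odds of 1.
This is simple and monotone: ambiguity neither rewards nor penalises.

**Fidelity.**  This engine deliberately trades HMMER3 bit-for-bit parity
(which would require reproducing its multihit configuration, entry/exit
occupancy weighting and filter pipeline) for a transparent model that an
exhaustive path enumeration can verify.  The test suite checks agreement
with brute-force path summation to 1e-9 bits over every profile of M ≤ 3
crossed with every sequence of length ≤ 4 on a reduced 3-letter alphabet
harness, and cross-checks search behaviour qualitatively against HMMER
(via pyhmmer) on planted fixtures.  Users who need HMMER-exact scores can
run `hmmsearch --tblout` themselves and feed the table to
`orthohunt.read_tblout`; downstream filtering and classification are
identical from that point on.

**E-values.**  With forward-tail calibration (tau in bits, lambda per bit),
P(S ≥ s) = exp(−lambda · (s − tau)) capped at 1, and E = Z · P where Z is
the number of sequences in the proteome being searched (one search per
FASTA file, per-database E-values).  The E ≤ threshold comparison is
inclusive.  A profile without calibration statistics raises an error by
default; callers may opt into the conservative fallback P = 1 (E = Z),
which effectively disables E-value screening rather than fabricating
significance.

## Filter semantics and edge cases

- The threshold is fraction × best computed algebraically.  At fraction 0
  it is defined as −∞ so that negative-scoring (but E-value-passing) hits
  are also kept — the relaxed regime recommended for gene-family censuses
  (e.g. fraction 0.25).
- A hit exactly at the threshold is kept (≥, matching the inclusive rule).
- All hits tied with the best score are always kept; a multi-way tie at the
  top therefore yields a multi-copy call.  No secondary criterion breaks
  score ties beyond deterministic id-ascending ordering in outputs.
- With a negative best score the algebraic threshold lies above the best
  score; only hits tied with the best survive.  This is documented rather
  than special-cased: E-value screening makes negative-score hits rare.

## Outputs

File naming, column layouts and sort orders are fixed so runs are
byte-reproducible and golden-file testable: hit tables are named
`<proteome>__<hmm>.tsv`; per-marker FASTAs use `>{proteome}|{target_id}`
headers with proteome blocks in input order; `short_summary.txt`
percentages are over the proteome count with 2 decimals, half-up rounding;
`long_summary.txt` rows sort by (proteome, hmm) with `-` placeholders for
absent pairs.  Numeric cells use shortest-round-trip float formatting so
re-parsing a table reproduces the in-memory values exactly.  A marker
absent from every proteome still gets (empty) `all_sequences/` and `scog/`
files.  `scog` drops only the multi-copy or absent proteomes from a
marker's file, never the whole marker.  Outputs are written to a temporary
directory and promoted atomically on success.

## Evaluation arithmetic

precision = TP/(TP+FP) and recall = TP/(TP+FN) over single-copy calls.  The
false-positive rate is reported as FP/(TP+FP) = 1 − precision: with no
finite universe of true negatives in an ortholog-calling benchmark, the
classical FP/(FP+TN) is uncomputable, and the share-of-wrong-calls reading
is the one consistent with a rate of 0.02 at 231 TP / 4 FP.  Undefined
metrics (zero denominator) are reported as not-available, never as 0/0.
Call-set disagreement counts cells of a (gene × proteome) grid on which two
call sets differ under a pluggable cell-equality predicate (default:
status equality) and reports the percentage over all cells.

## Synthetic data

The fixture generator emulates the structure of a real benchmark at desk
scale, from a single seed:

- **profiles**: length 60 by default (a typical short domain), match
  emissions peaked at 0.9 on a random consensus with the remainder spread
  uniformly, inserts emitting the background, generic high-self-transition
  node parameters.  Calibration is empirical rather than theoretical: the
  profile is scored against 200 background-random sequences and an
  exponential tail is fitted above the 90th percentile (lambda from the
  mean tail excess, tau where the fitted exceedance reaches 1), keeping
  E-values self-consistent with whatever the engine computes.
- **homologs**: the consensus with i.i.d. per-site substitutions at the
  requested divergence (default 0.10), always to a different residue drawn
  from the background, so divergence is the expected Hamming fraction.
- **multi-copy cells**: a recent duplication — the planted homolog plus a
  copy re-substituted at rate 0.01.  Recent paralogs are near-identical in
  practice, and this is precisely the regime the 85% rule must keep
  together; independently diverged copies at higher divergence are also
  exercised in the tests.
- **decoys**: 20 background-i.i.d. sequences per proteome with lengths
  0.5–1.5× the profile length; an optional "hard decoy" mode adds a
  homolog truncated to ~40% of the profile, which passes the E-value
  filter but falls between the relaxed (0.25) and strict (0.85) fraction
  thresholds.
- **truth**: a `truth.tsv` recording the planted status of every cell.

Not emulated: indels, rate heterogeneity across sites, phylogenetic
correlation among proteomes, compositional bias, isoforms.  Passing the
recovery tests therefore demonstrates that the search–filter–classify
chain is correct under clean signal/noise separation, not that the default
thresholds are optimal for any particular real clade.

## Problem sizes

The shipped checks run at desk scale by design: the enumeration harness
sweeps all 9 profile sizes × 120 reduced-alphabet sequences; end-to-end
recovery uses ten seeded 3-profile × 4-proteome scenarios (120 planted
cells, 100% recovery expected); the worked benchmark arithmetic operates on
the published confusion counts and a 255 × 6 grid.  Full-scale replication
against real proteomes and curated pHMM sets is possible by pointing the
same two list files at downloaded data, with runtimes dominated by the
forward recursion (O(L·M) per sequence-profile pair).

## Known limitations

- Uni-hit scoring only: a protein containing two copies of a domain scores
  as one alignment, and domain-level coordinates are not reported.
- The engine's absolute bit scores differ from HMMER3's by modest,
  model-configuration-dependent offsets; the fraction filter depends only
  on score ratios within one search, which is why the pipeline contract is
  preserved, but externally calibrated score cutoffs should not be mixed
  between engines.
- Empirical tail calibration extrapolates an exponential beyond the
  simulated null scores; for the near-normal null score distributions of
  i.i.d. sequences this overestimates tail mass, i.e. it errs conservative.
- `scog` files guarantee at-most-one sequence per proteome per marker, not
  orthology; phylogenetic verification of the retrieved markers remains
  the user's responsibility.
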