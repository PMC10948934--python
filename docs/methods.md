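# Methods

## Motif model

FFAT-class motifs are modelled as 19 contiguous residues — upstream
flank U1–U6, core C1–C7, downstream flank D1–D6 — scored additively
against a penalty matrix: `score(w) = Σ_j penalty(position_j, w_j)`.
Penalties are non-negative and every position has at least one
zero-penalty residue, so an ideal motif scores exactly 0 and scores are
comparable across proteins. Lower is better; the significance band is
closed, `0 ≤ score ≤ 2.5`. The band is closed at both ends because 0 is
the ideal score and must count, and a score equal to the threshold is
conventionally reported as significant.

Only fully contained windows are scored — no padding at the termini.
Consequence: a motif whose 19-mer would extend within six residues of
either terminus is undetectable. This is a deliberate, documented
limitation; padding variants were excluded to keep per-protein output
tables unambiguous.

The conventional matrix is a single-point derivative of the phospho
matrix: core position C4 (the acid / phospho-acceptor position — the
only position whose preference distinguishes the two classes) is edited
to penalise S/T with 4 and accept D/E at 0. "Position 4" is read as the
fourth *core* position (window position 10), the only reading
consistent with the S/T-vs-D/E swap.

### Matrix provenance

The numeric weights of the published Phospho-FFAT matrix are not
reproduced in any source available to this package, so the bundled
files (`phospho_ffat_synthetic.tsv`, `conventional_ffat_synthetic.tsv`)
are a **synthetic reconstruction** around the FFAT consensus: acidic
flanks (D/E free, S/T cheap, basics most expensive), core preferences
E–F–F–[S/T]–A–x–E with C6 as a free wildcard, all values on a 0.5 grid.
They satisfy every structural invariant (19×20, non-negative, a zero
per position, C4 S/T = 0 in the phospho matrix) and the exact C4
transform. All code treats the matrix as data; swapping in a published
weight set is a file replacement, not a code change. Penalties on the
0.5 grid are exactly representable in binary floating point, so score
equalities in tests are exact, not approximate.

### Degenerate inputs and edge rules

* Sequences are upper-cased on read; `*` stop characters stripped with
  a warning; other non-letters are errors.
* Residues outside the 20 canonical letters (X, B, Z, U, O): the
  default `max_penalty` policy charges the position's column maximum —
  conservative, since an ambiguous residue can then never create a
  false ideal hit. `skip_window` (drop any window containing one) is
  available as an alternative.
* Sequences shorter than 19 yield an empty hit list with a logged
  warning, not an exception, so bulk scans survive peptide records.
* Best-2 reporting requires core-disjoint hits (C1..C7 intervals must
  not overlap), otherwise the shifted windows of one motif would always
  occupy both report slots. Ties in score break toward the smaller
  start (N-terminal first). Coordinates are 1-based inclusive.

## Enrichment model

Per bait (VAP-A, VAP-B) and protein, the ratio score is
`(psm_wt + c)/(psm_mut + c)` with Laplace pseudocount `c = 1`: finite
at zero mutant counts, rank-preserving, and converging to the plain
ratio as `c → 0`. Selection defaults — ratio ≥ 2 and WT peptides ≥ 2 —
are package choices exposed in `PipelineConfig`; the ranking criteria
are inherent to the design but no canonical numeric cutoffs exist, so
these are deliberately conservative, adjustable values. The
search-engine MS score column is carried as opaque data and not
filtered on by default, because its scale is instrument- and
search-engine-specific. Absence of a protein from a sample is a zero
count, not missing data.

## Screen tabulation

Suppression is graded per RNAi line (`++` definite, `+` partial). A
gene is a *confirmed* suppressor with ≥ 2 positive independent lines; a
gene whose only available line is positive is tabulated as a
*single-line* suppressor with explicit unconfirmed status — this
reconciles the two-line confirmation rule with screens that tabulate
single-line entries when no second line exists. Inviable crosses are
a separately reported set and never counted as tested lines; the
accounting from mapped genes to suppressors is therefore reported
stage-by-stage rather than forced to a single arithmetic identity.
Effector vs trigger-specific classification is the boolean *norpA*
suppression flag; ERG flagging requires the same abnormality (lower or
higher amplitude) in every tested line of a gene, and rough-eye
developmental phenotypes are segregated into their own list rather
than flagged.

The packaged `table1_screen.tsv` transcribes the 52-gene suppressor
table (genes, line IDs, grades, the three single-line entries). The
five *norpA*-positive genes named in the source text are flagged
directly; the remaining eight flags required to reach the printed class
total of 13 are synthetic placeholders drawn from the RNA/DNA-binding
functional classes reported to dominate that category — the file
header marks them as such. Per-line ERG outcomes are reconstructed
from the named genes (five consistently lower, one consistently
higher, two rough-eye in both lines, four rough-eye then lower).

## Synthetic data

The generators define the verification conditions; their defaults are
the study-scale conditions, not tuning knobs.

**Proteome** (`gen_proteome`): 100 proteins of 150–400 residues,
uniform background composition (a custom composition table may be
supplied; uniform suffices for the margin guarantee and keeps tests
self-contained). 18 conventional + 18 phospho motifs are planted, one
per protein. Each plant starts from the matrix's ideal 19-mer and is
degraded by randomised-greedy substitutions whose penalties sum
*exactly* to the budget (default 2.5), so the truth record's expected
score is exact with no tolerance. Every non-planted window of every
protein is rejection-resampled until it scores strictly above
`budget + margin` (margin 2.0) under *both* matrices, making each
planted start the unique minimum — downstream recovery is guaranteed
by construction. An unreachable budget (e.g. any positive budget under
an all-zero matrix) is an error.

**IP-MS** (`gen_psm_experiment`): 50 true interactors with WT counts
~ Poisson(20) and mutant counts ~ Poisson(1); 200 background proteins
~ Poisson(50) in both conditions, modelling abundant nonspecific
binders that stick to WT and binding-dead bait alike — their WT/mutant
ratio then concentrates near 1 and essentially never crosses the
selection cutoff (analytic false-positive probability ≈ 4 × 10⁻⁴ per
protein per bait). Poisson is the minimal standard model for spectral
counts; the generator only needs rank-separable structure. Counts are
drawn independently per bait; every true interactor is enriched in
both baits, with union/intersection variation arising from sampling.
Peptides are `ceil(psm/3)` and the MS score column `10·psm` — opaque
plumbing, not modelling claims. Recovery bounds used in tests
(≥ 48/50 true, ≤ 2 background per bait) were frozen from a one-time
oracle run of generator + selector across twelve seeds.

**Screen** (`gen_screen_tables`): 388 genes, 52 suppressors (3
single-line), 13 effectors, 6 ERG-abnormal (the last planted is
`higher`, the rest `lower`), 15 inviable single-line crosses — the
same funnel shape the real tabulation produces.

**Seeding.** Each generator takes its own integer seed and is
bit-for-bit reproducible. A pipeline-level seed fans out through
`numpy.random.SeedSequence(seed, spawn_key=(index,))` with index 0 =
proteome, 1 = IP-MS, 2 = screen (indices ≥ 10 are used by the
acceptance script for auxiliary streams), so adding a generator never
perturbs another's draws.

### What the synthetic data does not emulate

Real spectral counts are overdispersed and correlated with protein
length and abundance; real proteomes have biased composition, repeats
and disordered regions where FFAT-like strings arise by chance; real
screens have incomplete penetrance and scorer disagreement. Passing
tests therefore demonstrate the *correctness of the computations*
under known ground truth — exact scoring, exact tabulation, faithful
set algebra — not the sensitivity/specificity of the thresholds on
real data. The printed-scale counts that depend on unpublished
selection cutoffs and full supplementary tables (401 pulled-down
proteins, 194 shared, 136 motif-significant) are correspondingly
exercised through the synthetic truth equivalents and the packaged
screen transcription.

## Numerical and design choices

* Scores are float64 sums of at most 19 matrix cells — exact for the
  shipped 0.5-grid values; no rounding is applied anywhere.
* `ideal_sequence` tie-breaks alphabetically for determinism.
* All tables are TSV with `#` comments; row and column order of every
  output is deterministic given the inputs, and the run manifest
  (SHA-256 of inputs and outputs, echoed config, package version,
  per-stage counts) makes reruns verifiable.
* Problem sizes in tests and the acceptance script (1,000 random
  matrices; 200×10 and 40×5 scanner-oracle sweeps; 100-protein
  proteomes; 250-protein PSM tables) were chosen as the smallest sizes
  at which every property is exercised at study scale and failures
  remain attributable.

## Known limitations

* Motifs within six residues of a terminus are invisible (no window
  padding).
* The bundled matrices are consensus reconstructions, adequate for
  method verification and relative ranking but not a substitute for
  empirically fitted weights when scoring real proteomes.
* The two best hits per class are core-disjoint by construction;
  biologically overlapping tandem motifs closer than seven residues
  will report as one.
* Ortholog mapping is consumed as a table (one best fly gene per human
  protein, coverage > 90%); no ortholog prediction is performed.
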