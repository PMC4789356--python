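# Methods

## Problem and model

The package classifies bacterial protein sequences into hemoglobin-like
(HbL) and background (non-HbL) classes and resolves HbL sequences into
subfamilies and domain-architecture subgroups. Every classifier is a
binary soft-margin SVM with RBF kernel `K(x, y) = exp(−γ‖x−y‖²)` acting
on a fixed-dimension composition encoding of the sequence. The decision
function is the kernel expansion `f(x) = Σᵢ αᵢyᵢK(xᵢ, x) + b`; a
sequence is called positive iff `f(x) ≥ τ` with threshold τ = 0.0. The
≥ convention at the threshold is deliberate and fixed: a score exactly
at 0.0 classifies positive.

Multi-class decisions (subfamily, domain subgroup) combine one-vs-rest
binary models by the argmax of decision scores. When every one-vs-rest
score is negative the sequence is reported as an unclassified HbL rather
than forced into a class. Argmax ties break by fixed task order
(sHb < flavoHb < trHb; domain tasks in registry order) so predictions
are deterministic. The single-domain and truncated-domain stage-3 tasks
have exactly the same positive sets as the sHb and trHb subfamily tasks,
so those models are shared, not retrained — retraining them separately
could only introduce silent divergence between stages.

## Encodings

All composition features are fractions in [0, 1], not percentages; the
tabulated default γ values assume this scale. AC and MM sum to 1; DC
sums to 1 for any sequence of length ≥ 2 (denominator L − 1, the number
of dipeptide windows actually present — not the 400 possible pairs). DC
indexing is row-major, first residue alphabetical then second residue
alphabetical; models are therefore portable across implementations that
document the same order. The MM profile is a pure fixed permutation of
AC (order `ALEKIVGDPNFQRTMYSHWC`); since the RBF kernel is invariant
under coordinate permutations, MM and AC models trained with identical
hyperparameters are mathematically identical — MM exists as a
first-class scheme because its per-task default hyperparameters differ.

The PSSM composition groups the row-normalized L×20 matrix by the query
sequence residue at each position (rows of the 20×20 accumulator)
against all 20 substitution columns, then divides by L. The wording of
"composition of occurrences of each type of amino acid corresponding to
each type of amino acid" admits the transpose; the query-residue-grouped
construction used here is the standard PSSM-400 and is stated
prominently because the two variants are not interchangeable.

Row normalization maps the row minimum to 0 and maximum to 1; a
constant row (division by zero) maps to all zeros rather than 0.5,
preserving sparsity and determinism. Full float precision is kept
internally everywhere; `truncate4` (floor to 4 decimals) exists only as
a compatibility formatter for printed reference values, which truncate
rather than round (236/1433 = 0.16468… prints 0.1646).

The ASCII PSSM dialect is the PSI-BLAST text layout: header with the
20-letter column order, then one row per position carrying 40 numeric
score fields (20 log-odds + 20 percentages). Only the log-odds block is
consumed — its magnitudes match the reference worked example, whereas
the percentage block does not. The parser honours the header's column
order, so classic PSI-BLAST ordering (`ARNDCQEGHILKMFPSTWYV`) and
alphabetical files both load correctly.

## Dataset curation

Curation mirrors how a training set is assembled from a raw keyword
search: (1) drop entries whose description contains any of
{fragment, isoform, potential, similarity, probable} — case-insensitive
substring match on the description only, singular forms so plurals also
match; (2) greedy redundancy reduction at a 90% identity cutoff:
records sorted longest-first (ties by id), each retained iff its
identity to every already-retained record is ≤ cutoff. Identity is the
number of identical aligned positions in a global Needleman–Wunsch
alignment (match 1, mismatch 0, linear gap −1) divided by the *shorter*
sequence's length. The shorter-length denominator is a documented
package choice among the common conventions; the greedy longest-first
scheme is the deterministic desk-scale equivalent of CD-HIT clustering.
Sequence validation defaults to *reject* (error on any non-standard
residue, listing positions) so silent data corruption requires an
explicit `strip` or `remap` (B→D, Z→E, U→C) request.

## Training and evaluation protocol

The dual QP is solved by libsvm (via scikit-learn) at tolerance 1e−3;
the fitted expansion is extracted into a plain model object so scoring
and JSON serialization are exact, backend-independent, and bit-stable
across save/load. Determinism is guaranteed by fixed seeds and fixed
data order; permuting the training set changes the solution only within
solver tolerance (~1e−4 in decision-score units on toy problems).

Evaluation reports ACC, SN, SP, FPR as percentages and MCC in [−1, 1].
A metric with a zero denominator is reported as undefined (None) with a
warning, never as 0. k-fold splitting is a seeded shuffle followed by
round-robin assignment; stratified splitting is the default because the
smallest real class (sHb, 29 sequences) would otherwise produce
class-empty folds at k = 5. Stratification carries the round-robin
pointer across classes so fold sizes still differ by at most one
globally. Cross-validation reports both the pooled-count metrics and the
per-fold accuracy mean ± SD (sample SD, n − 1); both are given because
either convention is common and they differ on unbalanced folds. ROC
curves sweep all distinct score thresholds on the continuous decision
scores (not hard labels); AUC is trapezoidal and equals the
tie-corrected normalized Mann–Whitney statistic, which the test suite
checks against an independent implementation.

## Synthetic data generator

The generator emulates the compositional structure of the real classes
as deviations from a uniform 5% baseline, drawn i.i.d. per residue:

| class | bias (percentage points at separation 1) | length (aa) |
|---|---|---|
| non-HbL | S, T +0.5 | 100–500 |
| all HbL | A, E, H +0.5 | — |
| sHb | K +4 (≥ 8% after renormalization), I, N +1 | 110–160 |
| flavoHb | G, Q, S, T, V −0.4 | 300–500 |
| trHb | R +2; D, F, P, W −0.4 | 100–140 |

The flavoHb length range reflects the longest real domain architecture;
the sHb and trHb ranges are plausible globin lengths chosen by the
package. The three flavoHb domain subgroups carry *synthetic* disjoint
marker-residue biases (C/M/W +2 pp) — real data provides no
compositional signature for them, and these markers exist only to make
the stage-3 task learnable in tests. Per-class counts may be given as a
mapping to mirror the real collections' proportions (337 non-HbL vs
333 HbL split 217 flavoHb / 87 trHb / 29 sHb).

A single `separation` parameter rescales every profile's deviation from
the baseline: 0 collapses all classes (downstream CV accuracy falls to
chance), 1 is the realistic regime, and 6.0 is used as the cleanly
separable regime in end-to-end checks. The 6.0 value comes from
composition-noise arithmetic: between-class AC offsets must dominate
the per-sequence sampling SD ≈ √(p(1−p)/L) ≈ 0.012–0.02 for the
length ranges above.

Because sampling is i.i.d., the generator reproduces only bulk
composition, never positional motifs, secondary-structure signal, or
phylogenetic correlation between sequences. Passing tests therefore
demonstrate that the pipeline machinery is correct and that
composition-separable classes are recovered — not that real HbL
discrimination reaches any particular accuracy. Synthetic PSSMs place a
high signal-scaled score (≈ 300 + 600·signal with integer noise scaled
by 1 − signal) in each position's own-residue column over a uniform
low background; they are format-valid and exercise the full parse →
normalize → compose path but do not resemble real evolutionary
profiles.

## Numerical and interface choices

- Default (γ, C) per task and scheme are tabulated from tuning on the
  original curated collections; they are starting points, not claims of
  optimality on other data.
- Problem sizes in tests and end-to-end checks (tens to a few hundred
  sequences per class) are chosen so the full suite runs in seconds;
  the SVMs involved are small and the conclusions are insensitive to
  scale in the separable regime.
- Model files are versioned JSON; floats round-trip via JSON's repr
  semantics, so reloaded models score bit-identically.
- CLI exit codes: 0 success, 2 usage errors (the click convention),
  1 data/model errors. Logs and warnings go to stderr; machine output
  is never mixed with logs.
- Datasets without domain-level labels train a 7-model registry (no
  flavoHb-subgroup models); stage 3 is then reported as unavailable
  rather than guessed from the subfamily models alone.

## Known limitations

- The redundancy filter is O(n²) pairwise alignment — intended for
  curated desk-scale sets, not genome-scale scans.
- PSSMs are inputs: the package parses and simulates them but does not
  run PSI-BLAST or manage a sequence database.
- The permutation-equivalence of AC and MM means reported differences
  between those schemes on real data must come from hyperparameters or
  data handling, not the encoding itself.
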