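# Methods

## Problem setting

Given a target CBM sequence *t* and a set *P* of structure templates with
known ligand-binding aromatic residues, the front end produces, per target:
HAR calls, a preliminary alignment set *A* (one feature-incorporated
alignment per template), a filtered candidate set *CA*, a ranked set of
single/double-template model candidates with structure-quality z scores, the
selected candidate *s\** (minimum z), and a PIR export for an external
coordinate-building engine. Coordinate generation and statistical-potential
evaluation are deliberately outside the package: they are delegated through
the PIR files and the scorer plug-in contract.

## HAR scoring

Aromatic residues (W, Y, F) drive carbohydrate stacking interactions; their
immediate sequence context in binding sites is enriched in small and polar
residues. Each aromatic at position *i* receives the sum of the weight-table
entries of residues *i−2, i−1, i+1, i+2*. Design choices:

- **Aromatic set = {W, Y, F}.** Histidine is excluded; it occurs in the
  weight table only as a flank.
- **Boundary handling.** Flank positions outside the sequence contribute 0,
  as do `X`/unknown residues. This is conservative: terminal aromatics can
  only lose score, never gain, so calls near termini are strict.
- **Threshold 97** by default, exposed everywhere (CLI flag, function
  argument) so ROC sweeps can vary it. The call rule is `score ≥ threshold`.
- An optional **strict mode** additionally requires both immediate
  neighbours to be polar (the older flanking definition); off by default.

The score range under the default table is 0–196 (four flanks × max weight
49).

## Feature-incorporated alignment

Global alignment (Gotoh three-state recurrence) with affine gaps: a gap run
of length L costs `open + (L−1)·extend`, defaults 11/1 — the standard
BLOSUM62 pairing. The position score is

    S(i, j) = BLOSUM62(t_i, p_j) + b_har·[both HAR] + b_ss·[same state ∈ {H, E}]

with defaults `b_har = 5`, `b_ss = 2`. The bonus magnitudes are this
package's defaults (roughly half a strong match / a weak match on the
BLOSUM62 scale, enough to break register ties without overriding clear
substitution signal); both are configuration parameters, and setting them to
0 reduces the aligner to plain Gotoh — which is how it is validated against
an exhaustive-enumeration oracle. Loop–loop matches earn no bonus: loops are
the least conserved, least informative state.

Numerical/determinism choices:

- End gaps are penalized by default; `free_end_gaps=True` switches to
  semi-global alignment for domain-in-protein use.
- Traceback tie-break: diagonal, then gap-in-template-row, then
  gap-in-target-row — output is byte-deterministic.
- The matrix fill is JIT-compiled (numba) so corpus-scale batches
  (~76k alignments of ~60-residue sequences) complete in seconds; a
  pure-Python fallback with identical semantics exists.
- Scores are float64 sums of integer matrix entries and integer-valued
  penalties; traceback equality tests use a 1e-6 tolerance so fractional
  user-supplied penalties remain safe.
- Residues outside the 20-letter alphabet score through the matrix's `X`
  row.
- "Similar" pairs are aligned pairs with a positive BLOSUM62 entry (the
  standard "positives" convention); identical pairs are a subset.
- `gap_openings` counts maximal gap runs over both rows.

## Template filter

For each alignment, with γ ≥ 0 (default 1):

    identity_level   = 100·(ident − γ·gap_openings) / n_columns
    similarity_level = 100·(sim   − γ·gap_openings) / n_columns

Both may be negative for gappy, low-identity alignments — that is the point
of the charge. The denominator is configurable (`columns` default, or
`min_length`). *CA* is the union of the top-k by each statistic (k default
5, matching the top-five unit used in candidate evaluation); ties break by
higher raw alignment score, then lexicographic template id. With a pool of
at least 2k alignments, `k ≤ |CA| ≤ 2k` by construction.

## Candidate enumeration and selection

From *CA* with n members: n single-template candidates plus all
C(n, 2) unordered double-template candidates, singles first, pairs in rank
order. Triples and beyond are excluded — their cost grows combinatorially
while double templates already capture the useful "main skeleton plus
compatible/complementary partner" pattern.

The scorer contract takes `(target, candidate)` and returns a finite,
deterministic z score, lower = better. A scorer exception excludes that
candidate and the run continues — one bad template must not abort a batch.
Selection is the argmin of z; ties prefer fewer templates, then candidate
id. Because the overview phrasing of the selection could also be read as an
average over repeated assessments, `rank_candidates` accepts `n_runs` to
average multiple scorer calls; with deterministic scorers (the default) the
value is unchanged.

The **mock scorer** is a deterministic stand-in for a statistical-potential
assessment: per alignment, `1 − 2·(ident/n_columns) − 0.5·(HAR coverage)`,
averaged over the candidate's alignments, where HAR coverage is the fraction
of the target's HARs aligned onto template positions annotated as binding
residues. Range −1.5 … 1.0. It orders candidates the way a real assessor
plausibly would (better-templated, binding-site-consistent models score
lower), but it is a rank proxy, not an energy; absolute mock z values carry
no physical meaning. Real engine scores are injected with
`table_scorer`/`--z-table`.

## Evaluation

Sites are `(protein id, 1-based position)` pairs; prediction rule
`score ≥ threshold` (consistent with HAR calling). The ROC curve has one
point per distinct score plus a sentinel above the maximum, so the
endpoints are (1,1) and (0,0) in (FPR, TPR) space; AUC is trapezoidal, and
is cross-checked against scikit-learn in the test suite. The negative set
for binding-residue evaluation — aromatics without experimental annotation —
inevitably contains undiscovered binders, so measured FP rates are upper
bounds and TP rates lower bounds; no correction is applied.

## Synthetic benchmark

The generator emulates the study conditions of a CBM modeling corpus:

- **Templates** (default length 100, matching the >85-residue domains the
  corpus restricts to; 3 planted binding motifs): uniform-random background
  sequences; each motif is a 5-residue window — two flanks from
  {G, N, S, T, D} (the five heaviest weights), a W/Y/F centre, two more
  heavy flanks — so every planted centre scores ≥ 132 ≥ 97 by construction.
  Centres become `known_binding_positions`. Tracks are run-structured and
  strand-rich (E/L/H run probabilities 0.5/0.4/0.1, run length 4–12),
  mimicking β-sandwich folds.
- **Targets**: per-template mutants. Substitution levels default to
  0.3/0.5/0.7, reproducing the <30% identity regime (a demo run reports
  ~26% mean identity). Indels are geometric (p = 0.5) capped at 5, rate
  0.02. Planted motif windows are exempt from all edits, so HAR recovery is
  exact by design — that invariant is what lets recovery tests isolate the
  alignment and filter stages. Target tracks inherit the template's states
  through the indel map, then each state flips with probability 0.3,
  emulating ~70% three-state secondary-structure prediction accuracy.
- All generators are deterministic per seed.

What passing synthetic tests do **not** show: performance on real CBM
families (real homology is not uniform substitution noise; real binding
motifs are not guaranteed high-scoring windows; background residue
frequencies are uniform by default, with a BLOSUM-frequency option), nor
anything about 3D model quality, which requires real coordinate building
and potential-energy scoring.

## Problem sizes in tests

The test suite runs entirely on generated data: the corpus-bookkeeping
check uses 817 targets × 93 templates at sequence length 60 with 2 motifs
per template; DP-vs-enumeration uses 500 random pairs of length ≤ 6 (the
enumeration oracle is exponential); recovery uses 10 templates × 5 targets
at substitution rate 0.7, k = 5, seed 20110922, with the bound fixed from a
pilot run at that seed.

## Known limitations

- The FIA bonus weighting is a two-parameter surrogate; no claim is made
  that it reproduces any particular published weighting scheme.
- The filter statistics' exact functional form (percentage of columns,
  linear gap charge) is one concrete realization of "charge opening gaps";
  γ and the denominator are exposed rather than asserted.
- HAR scoring is purely sequence-based; solvent accessibility is not
  consulted, so buried aromatics in high-scoring contexts are still called.
- The mock scorer cannot rank genuinely novel folds; with it, double
  candidates are favoured only insofar as both alignments are good.
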