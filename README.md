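# cbmfia

A homology-modeling **front end for carbohydrate-binding modules (CBMs)** —
the non-catalytic domains that target polysaccharide-active enzymes to their
substrates. Fewer than 5% of CBMs have solved structures and cross-family
sequence identities are usually below 30%, which is where conventional
target–template alignment breaks down. `cbmfia` addresses that regime by
exploiting two features CBM families conserve even at low identity: their
secondary-structure topology (mostly β-sandwich folds) and their
solvent-exposed **hydrophilic aromatic residues (HARs)** — the W/Y/F residues
that stack against sugar rings in the binding site.

The package provides:

- **HAR identification** — every aromatic residue is scored by summing
  occurrence-derived weights of its two upstream and two downstream
  neighbours, `score(i) = Σ w(r_{i±1}) + Σ w(r_{i±2})`; aromatics with
  `score ≥ 97` are called HARs and treated as candidate binding residues.
  The default weight table (G=49, N=43, S=34, … W=3) reflects how often each
  residue flanks experimentally annotated binding aromatics.
- **Feature-incorporated alignment (FIA)** — global Gotoh alignment with
  affine gaps (open 11, extend 1) over BLOSUM62, with position bonuses for
  HAR–HAR columns (+5) and matched helix/strand states (+2), steering the
  alignment toward the structurally meaningful register.
- **Template filter** — alignments are ranked by gap-charged statistics
  `identity_level = 100·(ident − γ·gap)/columns` (similarly for
  `similarity_level`); the candidate set *CA* is the union of the top-*k*
  under each, so `k ≤ |CA| ≤ 2k`.
- **Model-candidate selection** — all single templates and unordered double
  templates from *CA* (`n + n(n−1)/2` candidates) are scored by a pluggable
  structure scorer (surface-potential z score, lower = better); the
  minimum-z candidate is exported as a PIR alignment for an external
  modeling engine. A deterministic mock scorer keeps the pipeline testable
  offline; real engine scores can be injected from a table.
- **Evaluation** — confusion counts and ROC curves for HAR-based
  binding-residue prediction, plus corpus summaries (mean identity /
  similarity, single- vs double-template usage).
- **Synthetic benchmark generator** — CBM-like templates with planted
  binding motifs and mutated low-identity targets, so every stage runs
  without downloads.

## Worked example

Score the two canonical 5-residue windows:

```python
>>> from cbmfia import har_score, identify_hars
>>> har_score("GSWNP", 3)     # G+S+N+P = 49+34+43+8
134
>>> har_score("PTYKA", 3)     # P+T+K+A = 8+34+20+30
92
>>> identify_hars("AAGSWNPAA")[0].is_har   # 134 >= 97
True
>>> identify_hars("AAPTYKAAA")[0].is_har   # 92 < 97
False
```

The central tryptophan of `GSWNP` is a HAR (134 ≥ 97) and a candidate
ligand-binding residue; the tyrosine of `PTYKA` (92) is not.

Run the whole pipeline on a simulated benchmark:

```bash
$ cbmfia simulate --n-templates 5 --targets-per-template 2 --length 80 --seed 7 -o bench
wrote 10 targets / 5 templates to bench
$ cbmfia pipeline --benchmark-dir bench -o run
pipeline complete: 10/10 targets modeled -> run
```

`run/manifest.json` then records, per target, the selected model candidate,
e.g. for target `tmpl000_t0` (a mutant of template `tmpl000`):

```json
{"candidate_id": "tmpl000", "origin": "single", "z_score": -0.788, "pir": "tmpl000_t0.pir"}
```

— the pipeline recovered the true source template, and the mock scorer's z
score (range −1.5 … 1.0) is strongly negative because identity is high and
the target's HARs land on the template's annotated binding residues. The
manifest's alignment summary for this run reports a mean identity of 25.8%
and mean similarity of 37.3% over the 50 target–template alignments — the
low-homology regime the tool is built for. `run/candidates.tsv` lists every
scored single/double candidate, `run/candidate_sets.tsv` the filtered *CA*
per target, and `run/pir/*.pir` the alignments ready for a modeling engine.

Other subcommands: `har-scan` (TSV of HAR calls), `align`, `filter`,
`select`, `roc` — run `cbmfia --help`.

## File formats

- **Sequences**: FASTA (uppercased; `*` stripped).
- **Secondary-structure tracks**: a bespoke two-line text file — line 1 the
  per-residue states over `H/E/L` (`C` accepted as loop), optional line 2
  comma-separated confidences in [0,1]. Helix/strand states with confidence
  < 0.5 are relabeled to loop on read.
- **Template profiles**: CSV/TSV with columns `template_id, family,
  sequence, known_binding_positions` (semicolon-separated 1-based positions
  of experimentally annotated binding aromatics) and optional `sec_struct`.
- **PIR** (Modeller dialect): template entries typed `structureX`, target
  typed `sequence`, equal column counts, `*`-terminated.

All residue coordinates are 1-based inclusive.

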