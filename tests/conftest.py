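import math
import random

import pytest

from cbmfia.core import AnnotatedSequence, FeatureTrack, ProteinSequence

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_ann(residues, states=None, har_flags=None, seq_id="seq"):
    """Build an AnnotatedSequence with explicit features for alignment tests."""
    seq = ProteinSequence(id=seq_id, residues=residues)
    track = FeatureTrack(
        states=states if states is not None else "L" * len(residues),
        har_flags=list(har_flags) if har_flags is not None else [],
    )
    return AnnotatedSequence(seq=seq, track=track)


def brute_force_affine(t, p, score_fn, gap_open, gap_extend):
    """Exhaustive enumeration of every global alignment under affine gaps.

    Independent oracle for the Gotoh DP: recursion over all column
    sequences (no gap-in-both columns), a gap run of length L costing
    gap_open + (L-1)*gap_extend.  Exponential — only for tiny sequences.
    """
    m, n = len(t), len(p)
    best = [-math.inf]

    def rec(i, j, acc, last):
        if i == m and j == n:
            if acc > best[0]:
                best[0] = acc
            return
        if i < m and j < n:
            rec(i + 1, j + 1, acc + score_fn(t[i], p[j]), "D")
        if i < m:
            cost = gap_extend if last == "V" else gap_open
            rec(i + 1, j, acc - cost, "V")
        if j < n:
            cost = gap_extend if last == "H" else gap_open
            rec(i, j + 1, acc - cost, "H")

    rec(0, 0, 0.0, None)
    return best[0]


def random_protein(rng: random.Random, min_len=1, max_len=10):
    return "".join(
        rng.choice(AA20) for _ in range(rng.randint(min_len, max_len))
    )


@pytest.fixture(scope="session")
def tiny_benchmark():
    from cbmfia.fixtures import generate_benchmark

    return generate_benchmark(
        n_templates=4, n_targets_per_template=2,
        divergence_levels=(0.0, 0.4), seed=11, length=60, n_binding=2,
    )
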