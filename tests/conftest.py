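"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (pure-Python all-positions scans,
exhaustive pair enumeration, full permutation enumeration) and stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pirna_immunity import simulate as sim
from pirna_immunity.mapping import CanonicalTE

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_te_hits(seq, te_panel, max_mm):
    """All best-stratum placements by naive all-positions Hamming scan."""
    best, out = max_mm + 1, []
    for te in te_panel:
        for strand, q in (("+", seq), ("-", rc(seq))):
            if len(q) > te.length:
                continue
            for p in range(te.length - len(q) + 1):
                mm = sum(a != b for a, b in zip(q, te.sequence[p : p + len(q)]))
                if mm < best:
                    best, out = mm, []
                if mm == best and mm <= max_mm:
                    out.append((te.id, p, strand, mm))
    return sorted(out)


def brute_force_genome_hits(seq, genome):
    """All exact placements by substring scan over every chromosome."""
    out = []
    for chrom in sorted(genome):
        text = genome[chrom]
        for strand, q in (("+", seq), ("-", rc(seq))):
            for p in range(len(text) - len(q) + 1):
                if text[p : p + len(q)] == q:
                    out.append((chrom, p, strand))
    return sorted(out)


def brute_force_overlap_counts(alignments, length_range=(24, 29), max_offset=30):
    """Exhaustive double loop over all sense/antisense read pairs."""
    counts = np.zeros(max_offset + 1)
    inrange = [
        a for a in alignments if length_range[0] <= a.read_length <= length_range[1]
    ]
    sense = [a for a in inrange if a.strand == "+"]
    anti = [a for a in inrange if a.strand == "-"]
    for s in sense:
        for a in anti:
            o = a.five_prime - s.five_prime + 1
            if 1 <= o <= max_offset:
                counts[o] += s.weight * a.weight
    return counts


def enumerate_spearman_p(x, y):
    """Two-sided exact permutation p for Spearman rho via scipy per permutation."""
    from scipy import stats as sps

    rho_obs = sps.spearmanr(x, y).statistic
    n = len(x)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        r = sps.spearmanr(x, [y[i] for i in perm]).statistic
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / total


def enumerate_wilcoxon_p(x, y):
    """Two-sided exact rank-sum p via explicit C(n+m, n) subset enumeration."""
    from scipy import stats as sps

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, N = len(x), len(pooled)
    w_obs = ranks[:n].sum()
    mu = n * (N + 1) / 2.0
    hits = total = 0
    for combo in itertools.combinations(range(N), n):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


@pytest.fixture(scope="session")
def toy_panel():
    rng = np.random.default_rng(42)
    return [
        CanonicalTE("alpha", random_seq(rng, 300), "germline", active=True),
        CanonicalTE("beta", random_seq(rng, 250), "germline", active=False),
        CanonicalTE("soma", random_seq(rng, 200), "somatic", active=False),
    ]


@pytest.fixture(scope="session")
def small_dataset():
    return sim.simulate_genome(
        sim.PanelSpec(n_te=4, te_length=600), sim.ClusterSpec(genic_length=400), seed=31
    )
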