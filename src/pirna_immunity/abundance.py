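"""Per-transposon genomic abundance from DNA-seq and occupancy comparison.

DNA reads are mapped with the same canonical-sequence contract as small RNAs
(up to 3 mismatches, fractional multi-family weights).  Genomic abundance is
the RPM-normalized mapped-read weight plus a per-position coverage vector;
strain occupancy is compared with a two-sided Wilcoxon rank-sum test on
depth-normalized per-position coverage (exact null enumeration for small
samples, tie- and continuity-corrected normal approximation otherwise).

Per-position coverage values are autocorrelated, so i.i.d.-null p-values
are anti-conservative; a window-averaging option is provided to mitigate.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, erfc, sqrt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mapping import CanonicalTE, TEAlignment


@dataclass
class TEGenomicAbundance:
    te_id: str
    weight: float
    dna_rpm: float
    coverage: np.ndarray  # per-position read depth over the canonical sequence


@dataclass(slots=True)
class OccupancyComparison:
    te_id: str
    strain_a: str
    strain_b: str
    statistic: float  # rank sum of sample A
    p_value: float
    method: str  # "exact" | "normal-approx"


def te_genomic_abundance(
    alignments: Iterable[TEAlignment],
    te_panel: Sequence[CanonicalTE],
    depth: float,
) -> dict[str, TEGenomicAbundance]:
    """Accumulate mapped-read weight and coverage per canonical transposon."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    out = {
        te.id: TEGenomicAbundance(te.id, 0.0, 0.0, np.zeros(te.length))
        for te in te_panel
    }
    for a in alignments:
        rec = out[a.te_id]
        rec.weight += a.weight
        rec.coverage[a.start : a.end] += a.weight
    for rec in out.values():
        rec.dna_rpm = rec.weight / depth * 1e6
    return out


def abundance_table(abundances: dict[str, TEGenomicAbundance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"te_id": te_id, "weight": rec.weight, "dna_rpm": rec.dna_rpm}
            for te_id, rec in sorted(abundances.items())
        ]
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _exact_two_sided(ranks2: np.ndarray, n: int, w2_obs: int) -> float:
    """Exact P(|W - mu| >= |W_obs - mu|) by DP over doubled midranks."""
    N = len(ranks2)
    total2 = int(ranks2.sum())
    # dp[k][s] = number of k-subsets with doubled rank-sum s
    dp = np.zeros((n + 1, total2 + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(min(n, N), 0, -1):
            dp[k, r:] += dp[k - 1, : total2 + 1 - r]
    dist = dp[n]
    n_subsets = comb(N, n)
    mu2 = n * total2 / N
    dev = abs(w2_obs - mu2)
    sums = np.arange(total2 + 1)
    extreme = dist[np.abs(sums - mu2) >= dev - 1e-9].sum()
    return min(1.0, float(extreme / n_subsets))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    exact_limit: int = 20,
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (rank sum of ``x``, two-sided p, method).  ``method='auto'``
    enumerates the exact null when n+m <= ``exact_limit``, otherwise uses
    the normal approximation with tie correction and continuity correction.
    All-tied inputs give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    N = n + m
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n].sum())

    if np.all(pooled == pooled[0]):
        return w, 1.0, "exact" if N <= exact_limit else "normal-approx"

    if method == "auto":
        method = "exact" if N <= exact_limit else "normal-approx"
    if method == "exact":
        ranks2 = np.rint(ranks * 2).astype(int)
        p = _exact_two_sided(ranks2, n, int(round(w * 2)))
        return w, p, "exact"

    mu = n * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((N) * (N - 1))
    var = n * m / 12.0 * (N + 1 - tie_term)
    dev = abs(w - mu) - 0.5  # continuity correction
    dev = max(dev, 0.0)
    z = dev / sqrt(var)
    p = min(1.0, erfc(z / sqrt(2)))
    return w, p, "normal-approx"


def compare_occupancy(
    coverage_a: np.ndarray,
    coverage_b: np.ndarray,
    depth_a: float = 1.0,
    depth_b: float = 1.0,
    te_id: str = "",
    strain_a: str = "A",
    strain_b: str = "B",
    window: int | None = None,
) -> OccupancyComparison:
    """Compare per-position occupancy of one canonical sequence between strains.

    Coverage is depth-normalized to RPM before testing.  ``window`` averages
    coverage in non-overlapping bins first (reduces autocorrelation).
    """
    coverage_a = np.asarray(coverage_a, dtype=float)
    coverage_b = np.asarray(coverage_b, dtype=float)
    if coverage_a.shape != coverage_b.shape:
        raise ValueError("coverage vectors must share the canonical sequence length")
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("depths must be positive")
    a = coverage_a / depth_a * 1e6
    b = coverage_b / depth_b * 1e6
    if window:
        n_bins = len(a) // window
        a = a[: n_bins * window].reshape(n_bins, window).mean(axis=1)
        b = b[: n_bins * window].reshape(n_bins, window).mean(axis=1)
    w, p, method = wilcoxon_rank_sum(a, b)
    if window:
        method += f"|binned:{window}"
    return OccupancyComparison(te_id, strain_a, strain_b, w, p, method)
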