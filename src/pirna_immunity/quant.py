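"""Expression summaries: size profiles, 1U bias, RPM/RPKM/TPM, copy-number
normalization, and the genic-cluster ratio matrix."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import SmallRNARead
from .mapping import TEAlignment


def te_read_counts(
    alignments: Iterable[TEAlignment],
    length_range: tuple[int, int] | None = None,
) -> pd.Series:
    """Weighted read count per transposon (each read counts its weight once per family)."""
    totals: dict[str, float] = {}
    for a in alignments:
        if length_range and not length_range[0] <= a.read_length <= length_range[1]:
            continue
        totals[a.te_id] = totals.get(a.te_id, 0.0) + a.weight
    return pd.Series(totals, dtype=float).sort_index()


def size_distribution(
    alignments: Iterable[TEAlignment],
    length_range: tuple[int, int] = (18, 30),
) -> pd.DataFrame:
    """Per-length, per-strand read counts and within-strand fractions.

    Lengths outside ``length_range`` are excluded before fractions are taken.
    """
    lo, hi = length_range
    lengths = range(lo, hi + 1)
    counts = {s: {n: 0.0 for n in lengths} for s in "+-"}
    for a in alignments:
        if lo <= a.read_length <= hi:
            counts[a.strand][a.read_length] += a.weight
    rows = []
    for strand in "+-":
        total = sum(counts[strand].values())
        for n in lengths:
            c = counts[strand][n]
            rows.append(
                {
                    "length": n,
                    "strand": strand,
                    "count": c,
                    "fraction": c / total if total > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def u1_bias(
    alignments: Iterable[TEAlignment],
    reads: Mapping[str, str] | Iterable[SmallRNARead],
    min_len: int = 24,
    max_len: int = 29,
) -> dict[str, float | None]:
    """Per-strand fraction of in-range reads whose first sequenced base is U.

    The bias is evaluated on the read's own 5' base in read orientation for
    both strands.  Strands with no in-range reads report ``None``.
    """
    if not isinstance(reads, Mapping):
        reads = {r.id: r.sequence for r in reads}
    hit = {"+": 0.0, "-": 0.0}
    tot = {"+": 0.0, "-": 0.0}
    for a in alignments:
        if not min_len <= a.read_length <= max_len:
            continue
        seq = reads.get(a.read_id)
        if not seq:
            continue
        tot[a.strand] += a.weight
        if seq[0] == "T":
            hit[a.strand] += a.weight
    return {s: (hit[s] / tot[s] if tot[s] > 0 else None) for s in "+-"}


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class ExpressionRecord:
    feature_id: str
    count: float
    length: int
    rpm: float
    rpkm: float
    tpm: float


def normalize(
    counts: Mapping[str, float],
    depth: float,
    lengths: Mapping[str, int],
) -> pd.DataFrame:
    """RPM/RPKM/TPM table from weighted counts.

    rpm  = count / depth * 1e6
    rpkm = rpm / (length / 1000)
    tpm  = (count / length_kb) / sum(count / length_kb) * 1e6
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    feats = sorted(counts)
    count = np.array([counts[f] for f in feats], dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be non-negative")
    length = np.array([lengths[f] for f in feats], dtype=float)
    rpm = count / depth * 1e6
    rpkm = rpm / (length / 1000.0)
    rate = count / (length / 1000.0)
    denom = rate.sum()
    tpm = rate / denom * 1e6 if denom > 0 else np.zeros_like(rate)
    return pd.DataFrame(
        {
            "feature": feats,
            "count": count,
            "length": length.astype(int),
            "rpm": rpm,
            "rpkm": rpkm,
            "tpm": tpm,
        }
    ).set_index("feature")


CN_DIALECTS = ("log-ratio", "divide-by-log2")


def copy_number_normalize(
    pirna_rpm: Mapping[str, float] | pd.Series,
    dna_rpm: Mapping[str, float] | pd.Series,
    pseudocount: float = 1.0,
    dialect: str = "log-ratio",
) -> pd.DataFrame:
    """Normalize piRNA expression to genomic abundance.

    Default ``log-ratio`` dialect:  log2(pirna + pc) - log2(dna + pc).
    Literal ``divide-by-log2``:     log2(pirna + pc) / log2(dna + pc).
    Features with zero genomic abundance are flagged, never dropped.
    """
    if dialect not in CN_DIALECTS:
        raise ValueError(f"dialect must be one of {CN_DIALECTS}")
    pirna = pd.Series(pirna_rpm, dtype=float)
    dna = pd.Series(dna_rpm, dtype=float)
    if (pirna < 0).any() or (dna < 0).any():
        raise ValueError("RPM values must be non-negative")
    feats = pirna.index.intersection(dna.index).sort_values()
    p = pirna.loc[feats]
    d = dna.loc[feats]
    log_p = np.log2(p + pseudocount)
    log_d = np.log2(d + pseudocount)
    if dialect == "log-ratio":
        value = log_p - log_d
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            value = log_p / log_d
    out = pd.DataFrame(
        {
            "log2_pirna_rpm": log_p,
            "log2_dna_rpm": log_d,
            "value": value,
            "dna_rpm_zero": d == 0,
        },
        index=feats,
    )
    out.attrs["dialect"] = dialect
    out.attrs["pseudocount"] = pseudocount
    return out


# ---------------------------------------------------------------------------
# genic-cluster ratio matrix
# ---------------------------------------------------------------------------

def genic_cluster_matrix(
    rpkm: pd.DataFrame,
    reference_strain: str,
    sort_strain: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """log2(RPKM_strain / RPKM_reference) per genic cluster.

    ``rpkm`` is clusters x strains.  Rows are sorted by decreasing ratio in
    ``sort_strain`` (default: first non-reference strain).  Returns the ratio
    matrix and the strain dendrogram leaf order from average-linkage
    hierarchical clustering on Euclidean distances (deterministic
    tie-breaking: columns are pre-sorted by label).
    """
    if reference_strain not in rpkm.columns:
        raise ValueError(f"reference strain {reference_strain!r} absent from matrix")
    strains = sorted(c for c in rpkm.columns if c != reference_strain)
    if sort_strain is None:
        sort_strain = strains[0] if strains else reference_strain
    ref = rpkm[reference_strain]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(rpkm[strains].div(ref, axis=0))
    ratios[ref == 0] = np.nan  # reference RPKM 0 -> flagged missing
    ratios = ratios.replace([np.inf, -np.inf], np.nan)
    if sort_strain in ratios.columns:
        ratios = ratios.sort_values(sort_strain, ascending=False, kind="mergesort")

    leaf_order = list(ratios.columns)
    if len(ratios.columns) >= 2 and len(ratios.dropna()) >= 1:
        filled = ratios.dropna()
        dist = pdist(filled.T.to_numpy(), metric="euclidean")
        link = hierarchy.linkage(dist, method="average")
        leaf_order = [ratios.columns[i] for i in hierarchy.leaves_list(link)]
        ratios.attrs["linkage"] = link
    return ratios, leaf_order


def strain_dendrogram_newick(ratios: pd.DataFrame) -> str:
    """Newick text for the strain dendrogram attached by genic_cluster_matrix."""
    link = ratios.attrs.get("linkage")
    if link is None:
        return "(" + ",".join(ratios.columns) + ");"
    labels = list(ratios.columns)
    tree = hierarchy.to_tree(link)

    def _render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({_render(node.left)},{_render(node.right)}):{node.dist:.6g}"

    return _render(tree) + ";"
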