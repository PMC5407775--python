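"""5'-overlap profiles and the offset-10 ping-pong signature.

For one transposon, let S(p) be the summed weight of sense reads with their
5' end at reference position p, and A(q) the summed weight of antisense
reads whose biological 5' base sits at reference position q (the rightmost
base of the antisense span).  The overlap profile is

    counts[o] = sum_p S(p) * A(p + o - 1)        for o = 1..30,

so an exact ping-pong pair registers at offset 10.  Profiles are
z-normalized over offsets (sample SD) and the signature is z[10].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mapping import TEAlignment

MAX_OFFSET = 30


@dataclass
class OverlapProfile:
    te_id: str
    counts: np.ndarray  # index 0 unused; counts[o] for o = 1..MAX_OFFSET
    z: np.ndarray | None = None

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(1, len(self.counts))

    @property
    def z10(self) -> float | None:
        if self.z is None:
            return None
        return float(self.z[10])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "count": self.counts[1:],
                "z": self.z[1:] if self.z is not None else np.nan,
            }
        )


@dataclass(slots=True)
class ProfileCorrelation:
    te_id: str
    strain_a: str
    strain_b: str
    rho: float | None
    n_offsets: int


def overlap_profile(
    alignments: Iterable[TEAlignment],
    length_range: tuple[int, int] = (24, 29),
    max_offset: int = MAX_OFFSET,
    species_mode: bool = False,
) -> OverlapProfile:
    """Compute the 5'-overlap profile for one transposon's alignments.

    Pair weight is the product of the summed read weights at the two 5'
    positions; ``species_mode`` collapses duplicate read species (same 5'
    position, strand and length count once with unit weight).
    """
    alignments = [
        a for a in alignments if length_range[0] <= a.read_length <= length_range[1]
    ]
    te_ids = {a.te_id for a in alignments}
    if len(te_ids) > 1:
        raise ValueError(f"alignments span multiple transposons: {sorted(te_ids)}")
    te_id = te_ids.pop() if te_ids else ""

    if species_mode:
        seen = set()
        unique = []
        for a in alignments:
            key = (a.strand, a.five_prime, a.read_length)
            if key not in seen:
                seen.add(key)
                unique.append(a)
        weights = {id(a): 1.0 for a in unique}
        alignments = unique
    else:
        weights = {id(a): a.weight for a in alignments}

    size = max((a.end for a in alignments), default=0) + max_offset + 1
    sense = np.zeros(size)
    anti = np.zeros(size)
    for a in alignments:
        if a.strand == "+":
            sense[a.five_prime] += weights[id(a)]
        else:
            anti[a.five_prime] += weights[id(a)]

    counts = np.zeros(max_offset + 1)
    for o in range(1, max_offset + 1):
        d = o - 1
        counts[o] = float(np.dot(sense[: size - d], anti[d:]))
    profile = OverlapProfile(te_id=te_id, counts=counts)
    return znormalize(profile)


def znormalize(profile: OverlapProfile) -> OverlapProfile:
    """Populate z over offsets: mean 0, sample SD 1.  Constant profiles get no z."""
    counts = profile.counts[1:]
    if counts.size < 2:
        profile.z = None
        return profile
    sd = counts.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        profile.z = None
        return profile
    z = np.empty_like(profile.counts)
    z[0] = np.nan
    z[1:] = (counts - counts.mean()) / sd
    profile.z = z
    return profile


def profile_correlation(
    profile_a: OverlapProfile,
    profile_b: OverlapProfile,
    strain_a: str = "A",
    strain_b: str = "B",
) -> ProfileCorrelation:
    """Spearman correlation of two z-normalized profiles (average ranks for ties)."""
    te_id = profile_a.te_id or profile_b.te_id
    if profile_a.z is None or profile_b.z is None:
        return ProfileCorrelation(te_id, strain_a, strain_b, None, 0)
    za, zb = profile_a.z[1:], profile_b.z[1:]
    n = min(za.size, zb.size)
    if n < 3:
        return ProfileCorrelation(te_id, strain_a, strain_b, None, n)
    rho = sps.spearmanr(za[:n], zb[:n]).statistic
    return ProfileCorrelation(te_id, strain_a, strain_b, float(rho), n)


def pingpong_table(
    alignments: Iterable[TEAlignment],
    length_range: tuple[int, int] = (24, 29),
    species_mode: bool = False,
) -> pd.DataFrame:
    """Per-transposon ping-pong summary: offset-10 count and z10."""
    groups: dict[str, list[TEAlignment]] = {}
    for a in alignments:
        groups.setdefault(a.te_id, []).append(a)
    rows = []
    for te_id in sorted(groups):
        prof = overlap_profile(groups[te_id], length_range, species_mode=species_mode)
        rows.append(
            {
                "te_id": te_id,
                "count10": prof.counts[10],
                "z10": prof.z10 if prof.z10 is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["te_id", "count10", "z10"])
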