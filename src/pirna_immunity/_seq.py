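"""Low-level sequence helpers shared by the mapper and the simulator."""

from __future__ import annotations

import hashlib

import numpy as np

ALPHABET = "ACGT"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte value -> 0..3 code; everything else maps to 255 (disallowed)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement (uppercase-preserving, N-safe)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array of codes 0..3."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def decode_rows(mat: np.ndarray, lengths: np.ndarray) -> list[str]:
    """Decode each row of a padded code matrix to its stated length."""
    raw = _DEC[mat].tobytes()
    width = mat.shape[1]
    return [raw[i * width : i * width + int(n)].decode("ascii") for i, n in enumerate(lengths)]


def segment_bounds(length: int, n_segments: int) -> list[tuple[int, int]]:
    """Split [0, length) into ``n_segments`` near-equal contiguous pieces."""
    base, extra = divmod(length, n_segments)
    bounds = []
    pos = 0
    for i in range(n_segments):
        step = base + (1 if i < extra else 0)
        bounds.append((pos, pos + step))
        pos += step
    return bounds


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) occurrence starts of ``needle``."""
    hits: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def substream(seed: int, *tags) -> np.random.Generator:
    """Derive a reproducible RNG substream from a top-level seed and tags.

    Tags are hashed with SHA-256 so the stream depends only on their values,
    not on Python's per-process hash randomization.
    """
    digest = hashlib.sha256(("|".join(str(t) for t in tags)).encode()).digest()
    key = tuple(int.from_bytes(digest[k : k + 8], "little") for k in range(0, 32, 8))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))
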