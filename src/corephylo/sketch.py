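"""MinHash genome sketches and Mash distances for reference selection.

A genome is reduced to the ``s`` smallest 64-bit hashes of its canonical
k-mers (bottom-s sketch).  The Jaccard index of two genomes is estimated
from the shared fraction of the bottom-s sketch of the union, and converted
to an evolutionary distance with the Mash formula
``d = -(1/k) * ln(2j / (1+j))``.  The reference genome for the pipeline is
the complete genome with the smallest total distance to all other samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._seq import N_CODE, encode
from .io import SequenceRecord

_CHUNK = 1 << 20


@dataclass
class MinHashSketch:
    """Bottom-s MinHash sketch of one genome's canonical k-mers."""

    k: int
    sketch_size: int
    hashes: np.ndarray  # sorted, strictly increasing uint64
    genome_length: int


@dataclass
class DistanceEstimate:
    jaccard: float
    distance: float


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer: a fixed, documented 64-bit mixing function."""
    x = x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x += np.uint64(0x9E3779B97F4A7C15)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        x = x ^ (x >> np.uint64(31))
    return x


def _canonical_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit canonical k-mers of one contig, N-containing ones skipped."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    fwd_pow = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    rev_pow = fwd_pow[::-1].copy()
    out = []
    step = _CHUNK
    for start in range(0, n - k + 1, step):
        stop = min(start + step + k - 1, n)
        chunk = codes[start:stop].astype(np.uint64)
        win = np.lib.stride_tricks.sliding_window_view(chunk, k)
        valid = (win < N_CODE).all(axis=1)
        if not valid.any():
            continue
        win = win[valid]
        fwd = win @ fwd_pow
        rev = (np.uint64(3) - win) @ rev_pow
        out.append(np.minimum(fwd, rev))
    if not out:
        return np.empty(0, dtype=np.uint64)
    return np.concatenate(out)


def build_sketch(genome: Iterable[SequenceRecord], k: int = 21, s: int = 1000) -> MinHashSketch:
    """Sketch a (possibly multi-contig) genome.

    Keeps the ``s`` smallest distinct hashes over all canonical k-mers; k-mers
    containing non-ACGT bases are skipped.
    """
    if k < 3 or k > 31:
        raise ValueError("k must be in [3, 31]")
    records = list(genome)
    total = sum(len(r.residues) for r in records)
    if total < k:
        raise ValueError(f"genome length {total} shorter than k={k}")
    kmers = [
        _canonical_kmers(encode(rec.residues), k) for rec in records
    ]
    packed = np.concatenate(kmers) if kmers else np.empty(0, dtype=np.uint64)
    hashes = np.unique(_mix64(packed))
    return MinHashSketch(k=k, sketch_size=s, hashes=hashes[:s], genome_length=total)


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> DistanceEstimate:
    """Mash distance between two sketches built with identical parameters."""
    if a.k != b.k or a.sketch_size != b.sketch_size:
        raise ValueError("sketches built with different k or sketch size")
    union = np.union1d(a.hashes, b.hashes)
    s = min(a.sketch_size, len(union))
    if s == 0:
        return DistanceEstimate(jaccard=0.0, distance=1.0)
    bottom = union[:s]
    in_both = np.isin(bottom, a.hashes, assume_unique=True) & np.isin(
        bottom, b.hashes, assume_unique=True
    )
    j = int(in_both.sum()) / s
    if j <= 0.0:
        return DistanceEstimate(jaccard=0.0, distance=1.0)
    if j >= 1.0:
        return DistanceEstimate(jaccard=1.0, distance=0.0)
    d = -np.log(2.0 * j / (1.0 + j)) / a.k
    return DistanceEstimate(jaccard=j, distance=float(max(d, 0.0)))


def select_reference(
    sketches: Mapping[str, MinHashSketch],
    mode: str = "minhash",
    user_id: Optional[str] = None,
    complete_ids: Optional[Sequence[str]] = None,
    seed: int = 42,
) -> str:
    """Pick the reference sample id.

    ``minhash`` mode returns the complete genome minimizing the summed Mash
    distance to every other sample (ties: lexicographically smallest id);
    ``random`` draws uniformly among complete genomes with the run seed.
    """
    samples = sorted(sketches)
    eligible = sorted(complete_ids) if complete_ids is not None else samples
    unknown = [e for e in eligible if e not in sketches]
    if unknown:
        raise ValueError(f"eligible samples missing sketches: {unknown}")
    if mode == "user_specified":
        if user_id is None or user_id not in sketches:
            raise ValueError(f"reference {user_id!r} is not among the samples")
        return user_id
    if not eligible:
        raise ValueError("no complete genome is eligible as reference")
    if mode == "random":
        rng = np.random.default_rng(seed)
        return eligible[int(rng.integers(len(eligible)))]
    if mode != "minhash":
        raise ValueError(f"unknown reference mode {mode!r}")
    if len(eligible) < 1 or len(samples) < 2:
        raise ValueError("minhash mode needs at least two samples")
    best_id, best_total = None, np.inf
    for cand in eligible:
        total = sum(
            mash_distance(sketches[cand], sketches[other]).distance
            for other in samples
            if other != cand
        )
        if total < best_total - 1e-15 or (
            abs(total - best_total) <= 1e-15 and (best_id is None or cand < best_id)
        ):
            best_id, best_total = cand, total
    assert best_id is not None
    return best_id


# ---------------------------------------------------------------------------
# TSV persistence


def write_sketches(sketches: Mapping[str, MinHashSketch], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tk\ts\tgenome_length\thashes\n")
        for name in sorted(sketches):
            sk = sketches[name]
            hexes = ",".join(format(int(h), "x") for h in sk.hashes)
            fh.write(f"{name}\t{sk.k}\t{sk.sketch_size}\t{sk.genome_length}\t{hexes}\n")


def read_sketches(path) -> dict[str, MinHashSketch]:
    out: dict[str, MinHashSketch] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("sample\t"):
            raise ValueError("not a sketch TSV")
        for line in fh:
            name, k, s, glen, hexes = line.rstrip("\n").split("\t")
            hashes = np.array([int(h, 16) for h in hexes.split(",") if h], dtype=np.uint64)
            out[name] = MinHashSketch(
                k=int(k), sketch_size=int(s), hashes=hashes, genome_length=int(glen)
            )
    return out
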