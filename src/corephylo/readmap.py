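"""Seed-and-extend read mapping and pileup consensus calling.

Reads are placed by exact seed k-mer votes on both strands, scored with the
same affine scheme as the genome aligner, and kept only when a single locus
wins outright (ties or identity below ``min_identity`` leave the read
unmapped — multi-mapping reads must never manufacture SNPs).  Consensus
calls require ``min_depth`` coverage and a winning allele fraction of at
least ``min_allele_fraction`` (default 0.6: at least 60% of mapped reads
must agree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import AMBIG_CODE, GAP_CODE, N_CODE, encode, revcomp
from .align import DEFAULT_SCORING, EditScript, Scoring, banded_global_align
from .io import ReadRecord, SequenceRecord

SEED_K = 15
MAX_SEED_HITS = 64
MIN_IDENTITY = 0.85
BAND_PAD = 16


@dataclass
class ReadAlignment:
    read_id: str
    ref_contig: str
    ref_start: int  # 0-based
    strand: str
    ops: EditScript
    score: int
    unique: bool = True


@dataclass
class ReferenceIndex:
    """Exact seed k-mer lookup over a concatenated reference."""

    seed_k: int
    max_seed_hits: int
    names: list[str]
    offsets: np.ndarray  # contig start in concatenated coordinates
    lengths: np.ndarray
    codes: np.ndarray  # concatenated codes, contigs padded with N_CODE
    sorted_kmers: np.ndarray
    starts: np.ndarray  # group starts into `positions`
    positions: np.ndarray
    repetitive: np.ndarray  # per group: more than max_seed_hits occurrences

    def locate(self, gpos: int) -> tuple[int, int]:
        idx = int(np.searchsorted(self.offsets, gpos, side="right") - 1)
        return idx, gpos - int(self.offsets[idx])


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(values, valid) for every window; windows containing N are invalid."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    valid = (win < N_CODE).all(axis=1)
    values = win @ powers
    return values, valid


def build_index(
    ref: Sequence[SequenceRecord],
    seed_k: int = SEED_K,
    max_seed_hits: int = MAX_SEED_HITS,
) -> ReferenceIndex:
    """Index every seed k-mer position of the reference; seeds occurring more
    than ``max_seed_hits`` times are flagged repetitive and never vote."""
    names, offsets, lengths, parts = [], [], [], []
    pos = 0
    pad = np.full(seed_k, N_CODE, dtype=np.uint8)
    for rec in ref:
        names.append(rec.id)
        offsets.append(pos)
        codes = encode(rec.residues)
        lengths.append(len(codes))
        parts.append(codes)
        parts.append(pad)
        pos += len(codes) + seed_k
    codes = np.concatenate(parts)
    values, valid = _kmer_values(codes, seed_k)
    idx = np.nonzero(valid)[0]
    vals = values[idx]
    order = np.argsort(vals, kind="stable")
    vals_sorted = vals[order]
    positions = idx[order]
    uniq, starts = np.unique(vals_sorted, return_index=True)
    counts = np.diff(np.concatenate([starts, [len(vals_sorted)]]))
    return ReferenceIndex(
        seed_k=seed_k,
        max_seed_hits=max_seed_hits,
        names=names,
        offsets=np.array(offsets, dtype=np.int64),
        lengths=np.array(lengths, dtype=np.int64),
        codes=codes,
        sorted_kmers=uniq,
        starts=np.concatenate([starts, [len(vals_sorted)]]),
        positions=positions,
        repetitive=counts > max_seed_hits,
    )


def _candidate_diagonals(index: ReferenceIndex, read_codes: np.ndarray) -> np.ndarray:
    """Diagonals (ref_gpos - read_offset) receiving seed votes, vote-sorted."""
    k = index.seed_k
    values, valid = _kmer_values(read_codes, k)
    offs = np.nonzero(valid)[0]
    if offs.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    vals = values[offs]
    gi = np.searchsorted(index.sorted_kmers, vals)
    gi = np.clip(gi, 0, len(index.sorted_kmers) - 1)
    hit = index.sorted_kmers[gi] == vals
    hit &= ~index.repetitive[gi]
    if not hit.any():
        return np.empty((0, 2), dtype=np.int64)
    diags = []
    for o, g in zip(offs[hit], gi[hit]):
        s, e = index.starts[g], index.starts[g + 1]
        diags.append(index.positions[s:e] - o)
    alld = np.concatenate(diags)
    uniq, votes = np.unique(alld, return_counts=True)
    # merge diagonals within the band into one candidate locus
    order = np.argsort(uniq)
    uniq, votes = uniq[order], votes[order]
    merged: list[list[int]] = []
    for d, v in zip(uniq, votes):
        if merged and d - merged[-1][0] <= BAND_PAD:
            merged[-1][1] += v
            continue
        merged.append([int(d), int(v)])
    out = np.array(merged, dtype=np.int64)
    return out[np.argsort(-out[:, 1], kind="stable")]


def map_read(
    read: ReadRecord,
    index: ReferenceIndex,
    scoring: Scoring = DEFAULT_SCORING,
    min_identity: float = MIN_IDENTITY,
    band_pad: int = BAND_PAD,
    max_candidates: int = 8,
) -> Optional[ReadAlignment]:
    """Best unique placement of one read, or None if unmapped."""
    fwd = encode(read.residues)
    if len(fwd) < index.seed_k:
        return None
    best: Optional[tuple[int, int, str, EditScript]] = None  # score, gpos, strand, ops
    tie = False
    for strand, codes in (("+", fwd), ("-", revcomp(fwd))):
        cands = _candidate_diagonals(index, codes)
        for d, _votes in cands[:max_candidates]:
            score, gpos, ops = _extend(index, codes, int(d), scoring, band_pad)
            if score is None:
                continue
            if best is None or score > best[0]:
                best = (score, gpos, strand, ops)
                tie = False
            elif score == best[0] and (gpos != best[1] or strand != best[2]):
                tie = True
    if best is None or tie:
        return None
    score, gpos, strand, ops = best
    matches = sum(n for op, n in ops if op == "M")
    span = sum(n for op, n in ops if op in "MXI")
    if span == 0 or matches / span < min_identity:
        return None
    ci, cpos = index.locate(gpos)
    return ReadAlignment(
        read_id=read.id,
        ref_contig=index.names[ci],
        ref_start=cpos,
        strand=strand,
        ops=ops,
        score=score,
    )


def _extend(
    index: ReferenceIndex,
    read_codes: np.ndarray,
    diag: int,
    scoring: Scoring,
    band_pad: int,
) -> tuple[Optional[int], int, EditScript]:
    """Score the read against the reference window on one diagonal."""
    L = len(read_codes)
    gstart = diag
    if gstart < 0 or gstart + L > len(index.codes):
        lo = max(gstart, 0)
        hi = min(gstart + L, len(index.codes))
        if hi - lo < L:  # read would hang off the reference: reject candidate
            return None, 0, []
    window = index.codes[gstart : gstart + L]
    eq = (window == read_codes) & (read_codes < N_CODE) & (window < N_CODE)
    mism = int(L - eq.sum())
    gapless = scoring.match * (L - mism) + scoring.mismatch * mism
    # substitutions-only reads need no DP; an indel shifts half the read and
    # pushes the mismatch count far above this threshold
    if mism <= max(2, int(0.06 * L)):
        return gapless, gstart, _eq_to_ops(eq)
    # gapped fallback over a padded window
    wlo = max(0, gstart - band_pad)
    whi = min(len(index.codes), gstart + L + band_pad)
    ref_win = index.codes[wlo:whi]
    try:
        score, ops = banded_global_align(ref_win, read_codes, scoring, band_pad)
    except ValueError:
        return (gapless, gstart, _eq_to_ops(eq))
    # flanking reference overhang is free: strip leading/trailing D ops
    lead = ops[0][1] if ops and ops[0][0] == "D" else 0
    if lead:
        score -= scoring.gap_open + scoring.gap_extend * lead
        ops = ops[1:]
    trail = ops[-1][1] if ops and ops[-1][0] == "D" else 0
    if trail:
        score -= scoring.gap_open + scoring.gap_extend * trail
        ops = ops[:-1]
    if score <= gapless:
        return gapless, gstart, _eq_to_ops(eq)
    return score, wlo + lead, ops


def _eq_to_ops(eq: np.ndarray) -> EditScript:
    ops: EditScript = []
    if eq.all():
        return [("M", len(eq))]
    changes = np.nonzero(np.diff(eq.astype(np.int8)))[0] + 1
    bounds = [0, *changes.tolist(), len(eq)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        ops.append(("M" if eq[s] else "X", e - s))
    return ops


def map_reads(
    reads: Iterable[ReadRecord],
    index: ReferenceIndex,
    scoring: Scoring = DEFAULT_SCORING,
    min_identity: float = MIN_IDENTITY,
) -> list[ReadAlignment]:
    out = []
    for read in reads:
        aln = map_read(read, index, scoring, min_identity)
        if aln is not None:
            out.append(aln)
    return out


# ---------------------------------------------------------------------------
# pileup and consensus


@dataclass
class Pileup:
    """Per-position base tallies over the concatenated reference layout."""

    names: list[str]
    lengths: np.ndarray
    counts: dict[str, np.ndarray]  # contig -> (4, L) tallies

    def depth(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=0)


@dataclass
class SampleCallTrack:
    """Per-reference-position consensus calls for one sample."""

    sample: str
    calls: dict[str, np.ndarray]  # contig -> uint8 codes (base/GAP/AMBIG)
    depth: dict[str, np.ndarray] = field(default_factory=dict)
    fraction: dict[str, np.ndarray] = field(default_factory=dict)


def build_pileup(alignments: Iterable[ReadAlignment], ref: Sequence[SequenceRecord]) -> Pileup:
    """Tally read bases per reference position; read-gap ops contribute nothing."""
    names = [r.id for r in ref]
    lengths = np.array([len(r.residues) for r in ref], dtype=np.int64)
    counts = {r.id: np.zeros((4, len(r.residues)), dtype=np.int32) for r in ref}
    for aln in alignments:
        cnt = counts[aln.ref_contig]
        L = cnt.shape[1]
        rpos = aln.ref_start
        qpos = 0
        read_codes = getattr(aln, "_codes", None)
        if read_codes is None:
            raise ValueError("alignment lacks attached read codes")
        for op, n in aln.ops:
            if op in ("M", "X"):
                if rpos + n > L:
                    raise ValueError(f"alignment extends past contig end ({aln.read_id})")
                seg = read_codes[qpos : qpos + n]
                ok = seg < 4
                np.add.at(cnt, (seg[ok], np.arange(rpos, rpos + n)[ok]), 1)
                rpos += n
                qpos += n
            elif op == "D":
                rpos += n
            elif op == "I":
                qpos += n
    return Pileup(names=names, lengths=lengths, counts=counts)


def attach_read_codes(aln: ReadAlignment, read: ReadRecord) -> ReadAlignment:
    """Attach oriented read codes so the pileup can tally bases."""
    codes = encode(read.residues)
    aln._codes = codes if aln.strand == "+" else revcomp(codes)  # type: ignore[attr-defined]
    return aln


def map_sample(
    reads: Iterable[ReadRecord],
    index: ReferenceIndex,
    ref: Sequence[SequenceRecord],
    scoring: Scoring = DEFAULT_SCORING,
    min_identity: float = MIN_IDENTITY,
) -> tuple[Pileup, int, int]:
    """Map reads and build the pileup in one pass.

    Returns (pileup, n_mapped, n_total).
    """
    alns = []
    total = 0
    for read in reads:
        total += 1
        aln = map_read(read, index, scoring, min_identity)
        if aln is not None:
            alns.append(attach_read_codes(aln, read))
    return build_pileup(alns, ref), len(alns), total


def call_consensus(
    pileup: Pileup,
    min_depth: int = 5,
    min_allele_fraction: float = 0.6,
    sample: str = "sample",
) -> SampleCallTrack:
    """Base call where depth >= min_depth and the winning base reaches the
    allele fraction; AMBIG when covered but no base qualifies; GAP otherwise."""
    if not 0.5 < min_allele_fraction <= 1.0:
        raise ValueError("min_allele_fraction must be in (0.5, 1]")
    calls: dict[str, np.ndarray] = {}
    depths: dict[str, np.ndarray] = {}
    fracs: dict[str, np.ndarray] = {}
    for name in pileup.names:
        cnt = pileup.counts[name]
        depth = cnt.sum(axis=0)
        winner = cnt.argmax(axis=0).astype(np.uint8)
        wcount = cnt.max(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, wcount / np.maximum(depth, 1), 0.0)
        call = np.full(cnt.shape[1], GAP_CODE, dtype=np.uint8)
        covered = depth >= min_depth
        call[covered] = AMBIG_CODE
        good = covered & (frac >= min_allele_fraction)
        call[good] = winner[good]
        calls[name] = call
        depths[name] = depth
        fracs[name] = frac
    return SampleCallTrack(sample=sample, calls=calls, depth=depths, fraction=fracs)


def write_call_track(track: SampleCallTrack, path) -> None:
    from ._seq import decode

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ref_contig\tpos\tcall\tdepth\tfraction\n")
        for name, call in track.calls.items():
            depth = track.depth.get(name)
            frac = track.fraction.get(name)
            sym = decode(call)
            for i, ch in enumerate(sym):
                d = int(depth[i]) if depth is not None else 0
                f = float(frac[i]) if frac is not None else 0.0
                fh.write(f"{name}\t{i + 1}\t{ch}\t{d}\t{f:.3f}\n")
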