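"""Repeat masking and anchor-based pairwise whole-genome alignment.

The aligner follows the classic seed-chain-extend design: maximal unique
matches (MUMs) between reference and query are found with a generalized
suffix array, the heaviest strictly colinear chain of anchors is kept per
(reference contig, query contig, strand) pair, and the short segments
between consecutive anchors are closed with banded affine-gap alignment.
Indels and unaligned reference segments become core-excluding gaps;
substitution columns with plain ACGT bases on both sides become SNPs.

Coordinates are 0-based half-open internally; emitted reports are 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import align as _align
from ._seq import N_CODE, encode, lcp_array, revcomp, suffix_array
from .align import DEFAULT_SCORING, EditScript, Scoring, merge_ops
from .io import SequenceRecord

MIN_ANCHOR_LEN = 20
MIN_REPEAT_LEN = 50
MAX_FILL = 10_000
BAND_PAD = 50
# inter-anchor fills / end extensions longer than this must reach the
# identity floor, else they stay unaligned (random DNA aligns at ~0.45
# identity under this scoring; homologous segments at <=10% divergence
# align at >=0.9)
MIN_FILL_IDENTITY = 0.7
FILL_IDENTITY_MIN_COLS = 30


def _fill_acceptable(ops: EditScript) -> bool:
    cols = sum(n for _, n in ops)
    if cols < FILL_IDENTITY_MIN_COLS:
        return True
    matches = sum(n for op, n in ops if op == "M")
    return matches / cols >= MIN_FILL_IDENTITY


@dataclass
class RepeatMask:
    """Merged, non-overlapping masked intervals per reference contig (0-based half-open)."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def masked_fraction(self, lengths: dict[str, int]) -> float:
        total = sum(lengths.values())
        masked = sum(e - s for ivs in self.intervals.values() for s, e in ivs)
        return masked / total if total else 0.0

    def bool_track(self, contig: str, length: int) -> np.ndarray:
        track = np.zeros(length, dtype=bool)
        for s, e in self.intervals.get(contig, []):
            track[s:e] = True
        return track


@dataclass
class Anchor:
    """A maximal match unique in both genomes (coordinates in aligned orientation).

    ``qry_start`` is a position in the query contig as aligned: for strand
    '-' it indexes the reverse complement of the query contig.
    """

    ref_contig: str
    ref_start: int
    qry_contig: str
    qry_start: int
    length: int
    strand: str


@dataclass
class Chain:
    ref_contig: str
    qry_contig: str
    strand: str
    anchors: list[Anchor]
    weight: int


@dataclass
class AlignmentBlock:
    ref_contig: str
    ref_start: int
    ref_end: int
    qry_contig: str
    qry_start: int
    qry_end: int
    strand: str
    ops: EditScript


@dataclass
class PairwiseResult:
    """One query genome aligned against the reference."""

    sample: str
    blocks: list[AlignmentBlock]
    snps: list[tuple[str, int, str, str]]  # (ref_contig, ref_pos0, ref_base, qry_base)
    ambig: list[tuple[str, int]]  # aligned columns where either side is N
    gaps: dict[str, list[tuple[int, int]]]  # per contig, 0-based half-open
    aligned_fraction: float


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return [iv for iv in out if iv[1] > iv[0]]


class _Concat:
    """Concatenation of contigs with unique separators and per-position N codes.

    Separator and N positions receive unique large codes so exact matches can
    never span contig boundaries or include ambiguous bases.
    """

    def __init__(self, records: Sequence[SequenceRecord], code_base: int):
        parts = []
        self.offsets: list[int] = []
        self.names: list[str] = []
        pos = 0
        uniq = code_base
        for rec in records:
            codes = encode(rec.residues).astype(np.int64)
            amb = np.nonzero(codes >= N_CODE)[0]
            codes[amb] = uniq + np.arange(len(amb))
            uniq += len(amb)
            self.offsets.append(pos)
            self.names.append(rec.id)
            parts.append(codes)
            parts.append(np.array([uniq], dtype=np.int64))
            uniq += 1
            pos += len(codes) + 1
        self.codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        self.length = pos
        self.next_code = uniq
        self._bounds = np.array(self.offsets + [self.length], dtype=np.int64)
        self._lengths = [len(r.residues) for r in records]

    def locate(self, pos: int) -> tuple[int, int]:
        """(contig index, offset within contig) for a global position."""
        idx = int(np.searchsorted(self._bounds, pos, side="right") - 1)
        return idx, pos - self.offsets[idx]


def _self_matches_mask(records: Sequence[SequenceRecord], min_len: int) -> RepeatMask:
    """Mask every position covered by an off-diagonal exact self-match >= min_len."""
    fwd = _Concat(records, code_base=10)
    rc_records = [
        SequenceRecord(id=r.id, residues=_rc_str(r.residues)) for r in records
    ]
    rc = _Concat(rc_records, code_base=fwd.next_code)
    combined = np.concatenate([fwd.codes, rc.codes])
    n_fwd = len(fwd.codes)
    sa = suffix_array(combined)
    lcp = lcp_array(combined, sa)

    per_contig: dict[str, list[tuple[int, int]]] = {r.id: [] for r in records}
    lengths = {r.id: len(r.residues) for r in records}

    def genome_interval(gpos: int, length: int) -> Optional[tuple[str, int, int]]:
        """Map a combined-string interval back to forward genome coordinates."""
        if gpos < n_fwd:
            ci, off = fwd.locate(gpos)
            name = fwd.names[ci]
            return name, off, off + length
        ci, off = rc.locate(gpos - n_fwd)
        name = rc.names[ci]
        L = lengths[name]
        return name, L - (off + length), L - off

    hits = np.nonzero(lcp >= min_len)[0]
    for i in hits:
        length = int(lcp[i])
        pa, pb = int(sa[i - 1]), int(sa[i])
        iv_a = genome_interval(pa, length)
        iv_b = genome_interval(pb, length)
        if iv_a is None or iv_b is None:
            continue
        if iv_a == iv_b:
            continue  # same genomic interval seen forward+reverse (self-palindrome)
        for name, s, e in (iv_a, iv_b):
            per_contig[name].append((s, e))
    return RepeatMask({k: _merge_intervals(v) for k, v in per_contig.items() if v})


def _rc_str(seq: str) -> str:
    from ._seq import revcomp_str

    return revcomp_str(seq)


def mask_repeats(
    genome: Sequence[SequenceRecord], min_repeat_len: int = MIN_REPEAT_LEN
) -> RepeatMask:
    """Self-comparison repeat mask: both copies of every exact repeat
    (forward or inverted, within or across contigs) of length >= min_repeat_len
    are masked."""
    if not genome:
        raise ValueError("empty genome")
    return _self_matches_mask(genome, min_repeat_len)


def find_mums(
    ref: Sequence[SequenceRecord],
    qry: Sequence[SequenceRecord],
    min_anchor_len: int = MIN_ANCHOR_LEN,
) -> list[Anchor]:
    """Maximal matches of length >= min_anchor_len occurring exactly once in
    the reference and once in the query, on either strand."""
    anchors: list[Anchor] = []
    for strand in "+-":
        if strand == "+":
            qrecs = list(qry)
        else:
            qrecs = [SequenceRecord(id=r.id, residues=_rc_str(r.residues)) for r in qry]
        rcat = _Concat(ref, code_base=10)
        qcat = _Concat(qrecs, code_base=rcat.next_code)
        combined = np.concatenate([rcat.codes, qcat.codes])
        n_ref = len(rcat.codes)
        sa = suffix_array(combined)
        lcp = lcp_array(combined, sa)
        n = len(combined)
        lcp_ext = np.concatenate([lcp, [0, 0]])
        pa = sa[:-1]
        pb = sa[1:]
        ell_v = lcp_ext[1:n]
        # unique: the matched string occurs only at these two suffixes
        unique = (lcp_ext[0 : n - 1] < ell_v) & (lcp_ext[2 : n + 1] < ell_v)
        cross = (pa < n_ref) != (pb < n_ref)
        cand = np.nonzero((ell_v >= min_anchor_len) & unique & cross)[0]
        # left-maximality: characters preceding the two occurrences differ
        prev_a = np.where(pa[cand] > 0, combined[pa[cand] - 1], -1)
        prev_b = np.where(pb[cand] > 0, combined[pb[cand] - 1], -2)
        cand = cand[prev_a != prev_b]
        for i in cand:
            ell = int(ell_v[i])
            a_pos, b_pos = int(pa[i]), int(pb[i])
            rpos, qpos = (a_pos, b_pos) if a_pos < n_ref else (b_pos, a_pos)
            rci, roff = rcat.locate(rpos)
            qci, qoff = qcat.locate(qpos - n_ref)
            anchors.append(
                Anchor(
                    ref_contig=rcat.names[rci],
                    ref_start=roff,
                    qry_contig=qcat.names[qci],
                    qry_start=qoff,
                    length=ell,
                    strand=strand,
                )
            )
    anchors.sort(key=lambda a: (a.ref_contig, a.ref_start, a.qry_contig, a.strand))
    return anchors


def chain_anchors(anchors: Sequence[Anchor]) -> list[Chain]:
    """Maximum-weight strictly colinear chain per (ref contig, qry contig, strand).

    Weight is the summed anchor length; overlapping or order-crossing anchors
    are dropped.  Ties resolve toward the chain whose anchors start earliest
    on the reference.
    """
    groups: dict[tuple[str, str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.ref_contig, a.qry_contig, a.strand), []).append(a)
    chains: list[Chain] = []
    for (rc_name, qc_name, strand), group in sorted(groups.items()):
        group.sort(key=lambda a: (a.ref_start, a.qry_start))
        n = len(group)
        ref_start = np.array([a.ref_start for a in group])
        ref_end = ref_start + np.array([a.length for a in group])
        qry_start = np.array([a.qry_start for a in group])
        qry_end = qry_start + np.array([a.length for a in group])
        weight = np.array([a.length for a in group], dtype=np.int64)
        dp = weight.copy()
        parent = np.full(n, -1, dtype=np.int64)
        for i in range(n):
            # strict order in both genomes; bounded overlap is tolerated and
            # penalized by its size (MUMs can over-extend past a true breakpoint)
            ok = (
                (ref_start[:i] < ref_start[i])
                & (qry_start[:i] < qry_start[i])
                & (ref_end[:i] < ref_end[i])
                & (qry_end[:i] < qry_end[i])
            )
            if ok.any():
                pen = np.maximum(
                    np.maximum(ref_end[:i] - ref_start[i], qry_end[:i] - qry_start[i]), 0
                )
                scores = np.where(ok, dp[:i] - pen, np.int64(-(10**15)))
                best = int(np.argmax(scores))
                if scores[best] > -(10**14):
                    dp[i] = scores[best] + weight[i]
                    parent[i] = best
        end = int(np.argmax(dp))
        kept_idx = []
        while end >= 0:
            kept_idx.append(end)
            end = int(parent[end])
        kept = [group[i] for i in reversed(kept_idx)]
        chains.append(
            Chain(
                ref_contig=rc_name,
                qry_contig=qc_name,
                strand=strand,
                anchors=kept,
                weight=int(dp.max()),
            )
        )
    chains.sort(key=lambda c: (-c.weight, c.ref_contig, c.anchors[0].ref_start))
    return chains


def fill_gaps(
    chain: Chain,
    ref_codes: np.ndarray,
    qry_codes: np.ndarray,
    max_fill: int = MAX_FILL,
    scoring: Scoring = DEFAULT_SCORING,
    band_pad: int = BAND_PAD,
) -> list[AlignmentBlock]:
    """Close inter-anchor segments with banded affine alignment, merging
    anchors into blocks; segment pairs with either side > max_fill stay
    unaligned and split the chain into separate blocks.

    ``qry_codes`` must be in the aligned orientation (reverse-complemented
    for '-' chains); block query coordinates are in that same orientation.
    """
    blocks: list[AlignmentBlock] = []
    cur_ops: EditScript = []
    cur_ref0 = cur_qry0 = None
    prev_ref_end = prev_qry_end = None

    # extend the chain to the sequence ends so variants within
    # min_anchor_len of an edge still align (bounded indel slack)
    lead_ops: EditScript = []
    first = chain.anchors[0]
    lq = first.qry_start
    lr = min(first.ref_start, lq)
    if 0 < lq <= max_fill and lr > 0:
        _, lead_ops = _align.banded_global_align(
            ref_codes[first.ref_start - lr : first.ref_start],
            qry_codes[first.qry_start - lq : first.qry_start],
            scoring,
            band_pad,
        )
        if not _fill_acceptable(lead_ops):
            lead_ops = []
            lr = lq = 0
    else:
        lr = lq = 0
    tail_ops: EditScript = []
    last = chain.anchors[-1]
    last_ref_end = last.ref_start + last.length
    last_qry_end = last.qry_start + last.length
    tq = len(qry_codes) - last_qry_end
    tr = min(len(ref_codes) - last_ref_end, tq)
    if 0 < tq <= max_fill and tr > 0:
        _, tail_ops = _align.banded_global_align(
            ref_codes[last_ref_end : last_ref_end + tr],
            qry_codes[last_qry_end : last_qry_end + tq],
            scoring,
            band_pad,
        )
        if not _fill_acceptable(tail_ops):
            tail_ops = []
            tr = tq = 0

    def flush(ref_end: int, qry_end: int) -> None:
        nonlocal cur_ops, cur_ref0, cur_qry0
        if cur_ops:
            blocks.append(
                AlignmentBlock(
                    ref_contig=chain.ref_contig,
                    ref_start=cur_ref0,
                    ref_end=ref_end,
                    qry_contig=chain.qry_contig,
                    qry_start=cur_qry0,
                    qry_end=qry_end,
                    strand=chain.strand,
                    ops=merge_ops(cur_ops),
                )
            )
        cur_ops, cur_ref0, cur_qry0 = [], None, None

    for a in chain.anchors:
        a_ref, a_qry, a_len = a.ref_start, a.qry_start, a.length
        if not cur_ops and a is first and lead_ops:
            cur_ref0, cur_qry0 = a_ref - lr, a_qry - lq
            cur_ops.extend(lead_ops)
            cur_ops.append(("M", a_len))
            prev_ref_end = a_ref + a_len
            prev_qry_end = a_qry + a_len
            continue
        if cur_ops:
            # trim any residual overlap with the previous anchor
            trim = max(prev_ref_end - a_ref, prev_qry_end - a_qry, 0)
            a_ref += trim
            a_qry += trim
            a_len -= trim
            if a_len <= 0:
                continue
            rseg = ref_codes[prev_ref_end:a_ref]
            qseg = qry_codes[prev_qry_end:a_qry]
            ops = None
            if len(rseg) <= max_fill and len(qseg) <= max_fill:
                _, ops = _align.banded_global_align(rseg, qseg, scoring, band_pad)
                if not _fill_acceptable(ops):
                    ops = None
            if ops is not None:
                cur_ops.extend(ops)
            else:
                flush(prev_ref_end, prev_qry_end)
        if not cur_ops:
            cur_ref0, cur_qry0 = a_ref, a_qry
        cur_ops.append(("M", a_len))
        prev_ref_end = a_ref + a_len
        prev_qry_end = a_qry + a_len
    if tail_ops and cur_ops:
        cur_ops.extend(tail_ops)
        prev_ref_end += tr
        prev_qry_end += tq
    flush(prev_ref_end, prev_qry_end)
    return blocks


def align_pair(
    ref: Sequence[SequenceRecord],
    qry: Sequence[SequenceRecord],
    sample: str,
    mask: Optional[RepeatMask] = None,
    min_anchor_len: int = MIN_ANCHOR_LEN,
    max_fill: int = MAX_FILL,
    scoring: Scoring = DEFAULT_SCORING,
    band_pad: int = BAND_PAD,
) -> PairwiseResult:
    """Align one query genome (complete or contigs) against the reference.

    Conflicting claims on a reference locus resolve to the heavier chain;
    substitutions become SNPs only when both bases are plain ACGT and the
    position is unmasked; indel columns and unaligned reference positions
    become gaps.
    """
    anchors = find_mums(ref, qry, min_anchor_len)
    chains = [c for c in chain_anchors(anchors) if c.anchors]

    ref_codes = {r.id: encode(r.residues) for r in ref}
    ref_lengths = {r.id: len(r.residues) for r in ref}
    qry_fwd = {r.id: encode(r.residues) for r in qry}
    qry_rc = {r.id: revcomp(c) for r, c in zip(qry, (qry_fwd[r.id] for r in qry))}

    claimed = {name: np.zeros(n, dtype=bool) for name, n in ref_lengths.items()}
    covered = {name: np.zeros(n, dtype=bool) for name, n in ref_lengths.items()}
    mask_tracks = {
        name: (mask.bool_track(name, n) if mask else np.zeros(n, dtype=bool))
        for name, n in ref_lengths.items()
    }

    blocks: list[AlignmentBlock] = []
    snps: list[tuple[str, int, str, str]] = []
    ambig: list[tuple[str, int]] = []
    indel_gap: dict[str, list[tuple[int, int]]] = {name: [] for name in ref_lengths}

    for chain in chains:
        qcodes = qry_fwd[chain.qry_contig] if chain.strand == "+" else qry_rc[chain.qry_contig]
        for block in fill_gaps(
            chain, ref_codes[chain.ref_contig], qcodes, max_fill, scoring, band_pad
        ):
            blocks.append(block)
            _emit_block(
                block,
                ref_codes[block.ref_contig],
                qcodes,
                mask_tracks[block.ref_contig],
                covered[block.ref_contig],
                claimed[block.ref_contig],
                snps,
                ambig,
                indel_gap[block.ref_contig],
            )

    gaps: dict[str, list[tuple[int, int]]] = {}
    total = aligned = 0
    for name, n in ref_lengths.items():
        unaligned = ~covered[name]
        ivs = _bool_to_intervals(unaligned)
        gaps[name] = _merge_intervals(ivs + indel_gap[name])
        total += n
        aligned += int(covered[name].sum())
    # map '-' block query coords back to forward orientation for reporting
    for b in blocks:
        if b.strand == "-":
            L = len(qry_fwd[b.qry_contig])
            b.qry_start, b.qry_end = L - b.qry_end, L - b.qry_start
    snps.sort()
    return PairwiseResult(
        sample=sample,
        blocks=blocks,
        snps=snps,
        ambig=sorted(ambig),
        gaps=gaps,
        aligned_fraction=aligned / total if total else 0.0,
    )


def _emit_block(
    block: AlignmentBlock,
    ref_codes: np.ndarray,
    qry_codes: np.ndarray,
    masked: np.ndarray,
    covered: np.ndarray,
    claimed: np.ndarray,
    snps: list,
    ambig: list,
    indel_gap: list,
) -> None:
    """Emit per-position calls; positions already claimed by a heavier chain
    are skipped (first-claim-wins conflict resolution)."""
    from ._seq import BASES

    rpos, qpos = block.ref_start, block.qry_start
    contig = block.ref_contig
    for op, n in block.ops:
        if op == "M":
            fresh = ~claimed[rpos : rpos + n]
            covered[rpos : rpos + n] |= fresh
            claimed[rpos : rpos + n] = True
            rpos += n
            qpos += n
        elif op == "X":
            for i in range(n):
                if claimed[rpos + i]:
                    continue
                rb, qb = int(ref_codes[rpos + i]), int(qry_codes[qpos + i])
                covered[rpos + i] = True
                claimed[rpos + i] = True
                if rb < 4 and qb < 4:
                    if not masked[rpos + i]:
                        snps.append((contig, rpos + i, BASES[rb], BASES[qb]))
                else:
                    ambig.append((contig, rpos + i))
            rpos += n
            qpos += n
        elif op == "D":  # deletion in query: reference positions are gap columns
            fresh = ~claimed[rpos : rpos + n]
            for s, e in _bool_to_intervals(fresh):
                indel_gap.append((rpos + s, rpos + e))
            claimed[rpos : rpos + n] = True
            rpos += n
        elif op == "I":  # insertion in query: no reference column is consumed
            qpos += n


def _bool_to_intervals(arr: np.ndarray) -> list[tuple[int, int]]:
    if not arr.any():
        return []
    diff = np.diff(arr.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if arr[0]:
        starts.insert(0, 0)
    if arr[-1]:
        ends.append(len(arr))
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# report writers (1-based inclusive, GFF convention)


def write_snp_report(result: PairwiseResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ref_contig\tref_pos\tref_base\tqry_base\n")
        for contig, pos0, rb, qb in result.snps:
            fh.write(f"{contig}\t{pos0 + 1}\t{rb}\t{qb}\n")


def write_gap_report(result: PairwiseResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ref_contig\tstart\tend\n")
        for contig in sorted(result.gaps):
            for s, e in result.gaps[contig]:
                fh.write(f"{contig}\t{s + 1}\t{e}\n")
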