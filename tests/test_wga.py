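"""Repeat masking, MUM finding, chaining and pairwise alignment.

Oracles are brute-force: an all-pairs substring scan for repeats, direct
enumeration of maximal unique matches, and simulator ground truth for
planted variation.
"""

from collections import defaultdict

import numpy as np
import pytest

from corephylo._seq import revcomp_str
from corephylo.io import SequenceRecord
from corephylo.wga import (
    Anchor,
    align_pair,
    chain_anchors,
    find_mums,
    mask_repeats,
)

from conftest import random_dna


def brute_force_repeat_cover(seq: str, min_len: int) -> np.ndarray:
    """Positions covered by an off-diagonal exact self-match (either strand)."""
    n = len(seq)
    rc = revcomp_str(seq)
    cov = np.zeros(n, dtype=bool)
    occ = defaultdict(list)
    for i in range(n - min_len + 1):
        occ[seq[i : i + min_len]].append(("f", i))
    for i in range(n - min_len + 1):
        occ[rc[i : i + min_len]].append(("r", i))
    for _, hits in occ.items():
        if len(hits) < 2:
            continue
        for st, i in hits:
            gi = i if st == "f" else n - i - min_len
            others = [
                (s2, j)
                for s2, j in hits
                if not (s2 == st and j == i)
                and not ((s2 != st) and (n - j - min_len) == gi)
            ]
            if others:
                cov[gi : gi + min_len] = True
    return cov


def brute_force_mums(ref: str, qry: str, min_len: int) -> set[tuple[int, int, int]]:
    """(ref_start, qry_start, length) of forward-strand MUMs by enumeration."""
    out = set()
    for i in range(len(ref)):
        for j in range(len(qry)):
            # maximal match starting at i,j
            if i > 0 and j > 0 and ref[i - 1] == qry[j - 1]:
                continue  # not left-maximal
            l = 0
            while i + l < len(ref) and j + l < len(qry) and ref[i + l] == qry[j + l]:
                l += 1
            if l < min_len:
                continue
            sub = ref[i : i + l]
            if ref.count(sub) == 1 and qry.count(sub) == 1:
                out.add((i, j, l))
    return out


class TestMaskRepeats:
    def test_planted_repeat_matches_brute_force(self):
        rng = np.random.default_rng(0)
        base = random_dna(1000, rng)
        g = base[:500] + base[100:160] + base[560:]  # 60 bp copy at pos 500
        mask = mask_repeats([SequenceRecord("c", g)], 50)
        got = mask.bool_track("c", len(g))
        assert np.array_equal(got, brute_force_repeat_cover(g, 50))
        assert got.sum() >= 120  # both copies masked

    def test_repeat_free_genome_unmasked(self):
        rng = np.random.default_rng(1)
        g = random_dna(1000, rng)
        mask = mask_repeats([SequenceRecord("c", g)], 50)
        assert not brute_force_repeat_cover(g, 50).any()
        assert mask.intervals == {}

    def test_inverted_repeat_masks_both_halves(self):
        rng = np.random.default_rng(2)
        half = random_dna(200, rng)
        g = half + revcomp_str(half)
        mask = mask_repeats([SequenceRecord("c", g)], 50)
        assert mask.bool_track("c", len(g)).all()

    def test_cross_contig_repeat(self):
        rng = np.random.default_rng(3)
        a = random_dna(300, rng)
        b = random_dna(100, rng) + a[50:120] + random_dna(100, rng)
        mask = mask_repeats(
            [SequenceRecord("c1", a), SequenceRecord("c2", b)], 50
        )
        assert mask.bool_track("c1", 300)[50:120].all()
        assert mask.bool_track("c2", len(b))[100:170].all()


class TestFindMums:
    def test_identical_sequences(self):
        rng = np.random.default_rng(4)
        s = random_dna(100, rng)
        mums = [m for m in find_mums([SequenceRecord("r", s)], [SequenceRecord("q", s)], 20)
                if m.strand == "+"]
        assert len(mums) == 1
        assert (mums[0].ref_start, mums[0].qry_start, mums[0].length) == (0, 0, 100)

    def test_substitution_splits_into_flanking_anchors(self):
        rng = np.random.default_rng(5)
        s = random_dna(101, rng)
        q = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
        got = {
            (m.ref_start, m.qry_start, m.length)
            for m in find_mums([SequenceRecord("r", s)], [SequenceRecord("q", q)], 20)
            if m.strand == "+"
        }
        assert got == brute_force_mums(s, q, 20)
        assert (0, 0, 50) in got and (51, 51, 50) in got

    def test_reverse_complement_query(self):
        rng = np.random.default_rng(6)
        s = random_dna(120, rng)
        mums = find_mums(
            [SequenceRecord("r", s)], [SequenceRecord("q", revcomp_str(s))], 20
        )
        assert len(mums) == 1
        assert mums[0].strand == "-" and mums[0].length == 120

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_dna(150, rng)
        # mutate a few positions so several MUMs exist
        arr = list(ref)
        for p in rng.choice(150, 4, replace=False):
            arr[p] = "ACGT"[("ACGT".index(arr[p]) + 1) % 4]
        qry = "".join(arr)
        got = {
            (m.ref_start, m.qry_start, m.length)
            for m in find_mums([SequenceRecord("r", ref)], [SequenceRecord("q", qry)], 10)
            if m.strand == "+"
        }
        assert got == brute_force_mums(ref, qry, 10)

    def test_n_breaks_anchors(self):
        rng = np.random.default_rng(7)
        s = random_dna(100, rng)
        q = s[:40] + "N" + s[41:]
        mums = [m for m in find_mums([SequenceRecord("r", s)], [SequenceRecord("q", q)], 10)
                if m.strand == "+"]
        for m in mums:
            assert not ("N" in q[m.qry_start : m.qry_start + m.length])


def _anchor(r, q, l):
    return Anchor("c", r, "q", q, l, "+")


class TestChainAnchors:
    def test_colinear_anchors_all_kept(self):
        anchors = [_anchor(0, 0, 30), _anchor(40, 40, 30), _anchor(80, 80, 30)]
        chains = chain_anchors(anchors)
        assert len(chains) == 1
        assert len(chains[0].anchors) == 3
        assert chains[0].weight == 90

    def test_crossing_anchor_dropped(self):
        # B crosses A's order: exhaustive chains are {A}, {B}; A wins on weight
        a = _anchor(0, 50, 30)
        b = _anchor(40, 0, 10)
        chains = chain_anchors([a, b])
        assert chains[0].anchors == [a]
        assert chains[0].weight == 30

    def test_empty_input(self):
        assert chain_anchors([]) == []

    def test_exhaustive_best_chain_on_random_anchors(self):
        """DP result equals brute-force enumeration over all anchor subsets."""
        import itertools

        rng = np.random.default_rng(8)
        for _ in range(20):
            anchors = [
                _anchor(int(rng.integers(0, 200)), int(rng.integers(0, 200)),
                        int(rng.integers(5, 30)))
                for _ in range(6)
            ]
            best = 0
            for r in range(1, 7):
                for combo in itertools.combinations(anchors, r):
                    combo = sorted(combo, key=lambda a: a.ref_start)
                    ok = all(
                        c1.ref_start < c2.ref_start
                        and c1.qry_start < c2.qry_start
                        and c1.ref_start + c1.length < c2.ref_start + c2.length
                        and c1.qry_start + c1.length < c2.qry_start + c2.length
                        for c1, c2 in zip(combo, combo[1:])
                    )
                    if not ok:
                        continue
                    w = sum(a.length for a in combo) - sum(
                        max(
                            c1.ref_start + c1.length - c2.ref_start,
                            c1.qry_start + c1.length - c2.qry_start,
                            0,
                        )
                        for c1, c2 in zip(combo, combo[1:])
                    )
                    best = max(best, w)
            chains = chain_anchors(anchors)
            assert chains[0].weight == best


class TestAlignPair:
    def test_planted_substitutions_recovered_exactly(self):
        rng = np.random.default_rng(9)
        s = random_dna(20_000, rng)
        arr = list(s)
        planted = []
        for p in sorted(rng.choice(len(s), 25, replace=False)):
            alt = "ACGT"[("ACGT".index(arr[p]) + int(rng.integers(1, 4))) % 4]
            planted.append((int(p), arr[p], alt))
            arr[p] = alt
        res = align_pair([SequenceRecord("r", s)], [SequenceRecord("q", "".join(arr))], "q")
        assert [(p, rb, qb) for _, p, rb, qb in res.snps] == planted
        assert res.aligned_fraction == 1.0

    def test_deletion_becomes_gap(self):
        rng = np.random.default_rng(10)
        s = random_dna(10_000, rng)
        q = s[:4000] + s[4300:]
        res = align_pair([SequenceRecord("r", s)], [SequenceRecord("q", q)], "q")
        assert len(res.snps) == 0
        gaps = res.gaps["r"]
        assert len(gaps) == 1
        start, end = gaps[0]
        # homology at the breakpoint can shift the interval by a few bases
        assert abs(start - 4000) <= 5 and abs(end - 4300) <= 5
        assert end - start == 300

    def test_unrelated_sequence_aligns_nowhere(self):
        rng = np.random.default_rng(11)
        res = align_pair(
            [SequenceRecord("r", random_dna(5000, rng))],
            [SequenceRecord("q", random_dna(5000, np.random.default_rng(99)))],
            "q",
        )
        assert res.aligned_fraction < 0.01

    def test_self_alignment_identity(self):
        rng = np.random.default_rng(12)
        s = random_dna(10_000, rng)
        res = align_pair([SequenceRecord("r", s)], [SequenceRecord("q", s)], "q")
        assert res.snps == [] and res.aligned_fraction == 1.0

    def test_masked_positions_never_emit_snps(self):
        rng = np.random.default_rng(13)
        base = random_dna(5000, rng)
        g = base[:2000] + base[500:600] + base[2100:]  # 100bp repeat
        from corephylo.wga import mask_repeats

        mask = mask_repeats([SequenceRecord("r", g)])
        arr = list(g)
        masked_positions = np.nonzero(mask.bool_track("r", len(g)))[0]
        p = int(masked_positions[10])
        arr[p] = "ACGT"[("ACGT".index(arr[p]) + 1) % 4]
        res = align_pair([SequenceRecord("r", g)], [SequenceRecord("q", "".join(arr))], "q", mask)
        assert all(pos != p for _, pos, _, _ in res.snps)

    def test_symmetric_snp_count(self):
        rng = np.random.default_rng(14)
        s = random_dna(10_000, rng)
        arr = list(s)
        for p in rng.choice(len(s), 30, replace=False):
            arr[p] = "ACGT"[("ACGT".index(arr[p]) + 2) % 4]
        q = "".join(arr)
        ab = align_pair([SequenceRecord("r", s)], [SequenceRecord("q", q)], "q")
        ba = align_pair([SequenceRecord("r", q)], [SequenceRecord("q", s)], "q")
        assert len(ab.snps) == len(ba.snps) == 30

    def test_position_state_partition(self):
        """Every reference position is exactly one of: covered or gap."""
        rng = np.random.default_rng(15)
        s = random_dna(3000, rng)
        q = s[:1000] + s[1050:2000] + random_dna(500, np.random.default_rng(1))
        res = align_pair([SequenceRecord("r", s)], [SequenceRecord("q", q)], "q")
        state = np.zeros(len(s), dtype=int)
        for iv_s, iv_e in res.gaps["r"]:
            state[iv_s:iv_e] += 1
        covered = int(res.aligned_fraction * len(s) + 0.5)
        assert (state <= 1).all()
        # SNP positions lie outside gaps
        for _, p, _, _ in res.snps:
            assert state[p] == 0
        assert covered + state.sum() == len(s)

    def test_multi_contig_query_both_strands(self):
        rng = np.random.default_rng(16)
        s = random_dna(6000, rng)
        contigs = [
            SequenceRecord("c1", s[:3000]),
            SequenceRecord("c2", revcomp_str(s[3000:])),
        ]
        res = align_pair([SequenceRecord("r", s)], contigs, "q")
        assert res.aligned_fraction == 1.0
        assert res.snps == []
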