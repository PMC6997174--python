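"""SNP annotation, codon effects, and the NG86 selection screen.

Oracles: translate-and-compare for codon effects; a clean-room NG86
implementation (and Biopython's, where defined) for dN/dS.
"""

import itertools
import math
import warnings

import numpy as np
import pytest
from Bio.Data import CodonTable
from Bio.Seq import Seq

from corephylo.core import build_allele_table
from corephylo.io import FeatureRecord, SequenceRecord
from corephylo.molevol import (
    GeneModel,
    GeneRejection,
    GeneSequences,
    bh_adjust,
    classify_snps,
    genes_from_gff,
    ng86_pair,
    reconstruct_gene_sequences,
    screen_genes,
    translate_codon,
)
from corephylo.wga import align_pair

from conftest import random_dna

BASES = "ACGT"


def reference_ng86(seq1: str, seq2: str, table_id: int = 11):
    """Clean-room NG86 oracle: counts via Biopython translation, all
    minimal pathways enumerated explicitly.  Returns (S, N, Sd, Nd)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]

    def tr(codon):
        return "*" if codon in table.stop_codons else str(Seq(codon).translate(table=table_id))

    S = N = Sd = Nd = 0.0
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k : k + 3], seq2[k : k + 3]
        if c1 in table.stop_codons or c2 in table.stop_codons:
            continue
        for c in (c1, c2):
            syn = 0.0
            for i, b in itertools.product(range(3), BASES):
                if b != c[i]:
                    syn += (tr(c[:i] + b + c[i + 1 :]) == tr(c)) / 3.0
            S += syn / 2.0
            N += (3.0 - syn) / 2.0
        diffs = [i for i in range(3) if c1[i] != c2[i]]
        if diffs:
            paths = list(itertools.permutations(diffs))
            sd = nd = 0.0
            for order in paths:
                cur = c1
                for i in order:
                    nxt = cur[:i] + c2[i] + cur[i + 1 :]
                    if tr(nxt) == tr(cur):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
            Sd += sd / len(paths)
            Nd += nd / len(paths)
    return S, N, Sd, Nd


ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]


class TestCodonArithmetic:
    @pytest.mark.parametrize("table_id", [1, 11])
    def test_site_counts_conserve_three_per_codon(self, table_id):
        from corephylo.molevol import _codon_sites

        table = CodonTable.unambiguous_dna_by_id[table_id]
        for codon in ALL_CODONS:
            if codon in table.stop_codons:
                continue
            s, n = _codon_sites(codon, table_id)
            assert s + n == pytest.approx(3.0, abs=1e-12)
            assert s >= 0 and n >= 0

    def test_effect_oracle_1000_random_mutations(self):
        """Effect classification equals translate-and-compare."""
        rng = np.random.default_rng(300)
        for _ in range(1000):
            codon = ALL_CODONS[int(rng.integers(64))]
            i = int(rng.integers(3))
            alt = BASES[(BASES.index(codon[i]) + int(rng.integers(1, 4))) % 4]
            mutant = codon[:i] + alt + codon[i + 1 :]
            expected = (
                "synonymous"
                if str(Seq(codon).translate(table=11)) == str(Seq(mutant).translate(table=11))
                else "nonsynonymous"
            )
            got = (
                "synonymous"
                if translate_codon(codon) == translate_codon(mutant)
                else "nonsynonymous"
            )
            assert got == expected


class TestClassifySnps:
    GENOME = "TTAA" + "ATGGCTCGACGATTT" + "CCGGC"  # CDS at 5..19 (1-based)
    FEATS = [FeatureRecord("chr", "CDS", 5, 19, "+", 0, {"ID": "g1"})]

    def test_intergenic_snp(self):
        genes = genes_from_gff(self.FEATS)
        anns = classify_snps([("chr", 1, "T", "C", "s")], genes, {"chr": self.GENOME})
        assert anns[0].region == "intergenic"

    def test_plus_strand_codon_context(self):
        genes = genes_from_gff(self.FEATS)
        # position 7 (1-based) = third base of codon 0 ('ATG')
        anns = classify_snps([("chr", 6, "G", "A", "s")], genes, {"chr": self.GENOME})
        a = anns[0]
        assert a.region == "CDS" and a.gene_id == "g1"
        assert a.codon_index == 0 and a.codon_pos == 3
        assert a.ref_codon == "ATG" and a.alt_codon == "ATA"
        assert a.effect == "nonsynonymous"  # M -> I

    def test_minus_strand_effect_via_revcomp_oracle(self):
        rng = np.random.default_rng(301)
        coding = "ATG" + "".join(
            ALL_CODONS[int(rng.integers(64))] for _ in range(8)
        )
        genome = "AA" + str(Seq(coding).reverse_complement()) + "TT"
        L = len(coding)
        feats = [FeatureRecord("chr", "CDS", 3, 2 + L, "-", 0, {"ID": "g"})]
        genes = genes_from_gff(feats)
        # mutate each genomic position inside the gene, compare with oracle
        for gpos in range(2, 2 + L):
            ref_b = genome[gpos]
            alt_b = BASES[(BASES.index(ref_b) + 1) % 4]
            anns = classify_snps([("chr", gpos, ref_b, alt_b, "s")], genes, {"chr": genome})
            a = anns[0]
            # oracle: mutate the genome, extract & translate the coding strand
            mutated = genome[:gpos] + alt_b + genome[gpos + 1 :]
            prot_ref = str(Seq(genome[2 : 2 + L]).reverse_complement().translate(table=11))
            prot_alt = str(Seq(mutated[2 : 2 + L]).reverse_complement().translate(table=11))
            expected = "synonymous" if prot_ref == prot_alt else "nonsynonymous"
            assert a.effect == expected, gpos

    def test_strand_symmetry(self):
        """A + strand gene and its reverse-complement twin on - give the
        same effects for corresponding SNPs."""
        rng = np.random.default_rng(302)
        coding = "ATG" + "".join(ALL_CODONS[int(rng.integers(64))] for _ in range(5))
        fwd_genome = "CC" + coding + "GG"
        rev_genome = "CC" + str(Seq(coding).reverse_complement()) + "GG"
        L = len(coding)
        fwd_genes = genes_from_gff([FeatureRecord("chr", "CDS", 3, 2 + L, "+", 0, {"ID": "g"})])
        rev_genes = genes_from_gff([FeatureRecord("chr", "CDS", 3, 2 + L, "-", 0, {"ID": "g"})])
        for i in range(L):
            fwd_pos = 2 + i
            rev_pos = 2 + (L - 1 - i)
            rb = fwd_genome[fwd_pos]
            alt = BASES[(BASES.index(rb) + 2) % 4]
            fa = classify_snps([("chr", fwd_pos, rb, alt, "s")], fwd_genes, {"chr": fwd_genome})[0]
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            ra = classify_snps(
                [("chr", rev_pos, comp[rb], comp[alt], "s")], rev_genes, {"chr": rev_genome}
            )[0]
            assert fa.effect == ra.effect
            assert fa.ref_codon == ra.ref_codon and fa.alt_codon == ra.alt_codon

    def test_overlapping_genes_annotated_independently(self):
        genome = "ATGGCTCGACGATTTGCC"
        feats = [
            FeatureRecord("chr", "CDS", 1, 15, "+", 0, {"ID": "a"}),
            FeatureRecord("chr", "CDS", 2, 16, "+", 0, {"ID": "b"}),
        ]
        anns = classify_snps([("chr", 5, genome[5], "A", "s")], genes_from_gff(feats),
                             {"chr": genome})
        assert {a.gene_id for a in anns} == {"a", "b"}


class TestNg86Pair:
    def test_identical_sequences(self):
        r = ng86_pair("TTTATGGCT", "TTTATGGCT")
        assert r.dn == 0.0 and r.ds == 0.0

    def test_synonymous_only_pair(self):
        # one Phe codon swapped TTT -> TTC inside an identical context
        ctx = "ATGGCTCGACGACAT"
        r = ng86_pair(ctx + "TTT", ctx + "TTC")
        assert r.syn_diffs == 1.0 and r.nonsyn_diffs == 0.0
        assert r.dn == 0.0 and r.ds > 0.0

    def test_matches_cleanroom_oracle_on_toy_pairs(self):
        rng = np.random.default_rng(303)
        for _ in range(25):
            codons1, codons2 = [], []
            stops = CodonTable.unambiguous_dna_by_id[11].stop_codons
            for _ in range(6):
                c = stops[0]
                while c in stops:
                    c = ALL_CODONS[int(rng.integers(64))]
                codons1.append(c)
                # mutate 0-2 positions
                c2 = list(c)
                for i in rng.choice(3, int(rng.integers(0, 3)), replace=False):
                    c2[i] = BASES[(BASES.index(c2[i]) + int(rng.integers(1, 4))) % 4]
                codons2.append("".join(c2) if "".join(c2) not in stops else c)
            s1, s2 = "".join(codons1), "".join(codons2)
            S, N, Sd, Nd = reference_ng86(s1, s2)
            r = ng86_pair(s1, s2, on_stop="skip")
            assert r.syn_sites == pytest.approx(S, abs=1e-9)
            assert r.nonsyn_sites == pytest.approx(N, abs=1e-9)
            assert r.syn_diffs == pytest.approx(Sd, abs=1e-9)
            assert r.nonsyn_diffs == pytest.approx(Nd, abs=1e-9)
            # Jukes-Cantor correction applied to the proportions
            if r.ps < 0.75:
                assert r.ds == pytest.approx(-0.75 * math.log(1 - 4 * r.ps / 3), abs=1e-12)

    def test_cross_checks_biopython_where_defined(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        s1 = "TTTATGGCTCGACGACAT"
        s2 = "TTCATGGCTCGCCGACAC"
        dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
        r = ng86_pair(s1, s2, table_id=1)
        assert r.dn == pytest.approx(dn, abs=5e-4)
        assert r.ds == pytest.approx(ds, abs=5e-4)

    def test_symmetry(self):
        s1 = "ATGGCTCGACGATTTAAACATGGTTGTCCA"
        s2 = "ATGGCACGCCGATTCAAACATGGGTGTCCA"
        a, b = ng86_pair(s1, s2), ng86_pair(s2, s1)
        assert (a.dn, a.ds) == (b.dn, b.ds)
        assert a.ds > 0 or a.dn > 0  # the pair is informative

    def test_internal_stop_rejected_by_default(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_pair("TAAGCT", "TAAGCA")

    def test_length_contract(self):
        with pytest.raises(ValueError):
            ng86_pair("ATG", "ATGGCT")
        with pytest.raises(ValueError):
            ng86_pair("ATGC", "ATGC")


def _gene_table(ref_seq: str, sample_seqs: dict[str, str]):
    ref = [SequenceRecord("chr", ref_seq)]
    results = [
        align_pair(ref, [SequenceRecord("chr", s)], name)
        for name, s in sample_seqs.items()
    ]
    return build_allele_table(ref, None, results, reference_name="ref")


class TestGeneReconstruction:
    def _setup(self, rng, n_codons=120):
        stops = CodonTable.unambiguous_dna_by_id[11].stop_codons
        codons = []
        while len(codons) < n_codons:
            c = ALL_CODONS[int(rng.integers(64))]
            if c not in stops:
                codons.append(c)
        coding = "".join(codons)
        genome = random_dna(300, rng) + coding + random_dna(300, rng)
        gene = GeneModel("g1", "chr", "+", [(301, 300 + len(coding))], 0)
        return genome, gene

    def test_planted_snps_reappear_in_sequences(self):
        rng = np.random.default_rng(305)
        genome, gene = self._setup(rng)
        arr = list(genome)
        p1, p2 = 400, 520  # inside the gene
        for p in (p1, p2):
            arr[p] = BASES[(BASES.index(arr[p]) + 1) % 4]
        table = _gene_table(genome, {"mut": "".join(arr)})
        rec = reconstruct_gene_sequences(table, gene)
        assert isinstance(rec, GeneSequences)
        diffs = [
            i
            for i, (x, y) in enumerate(zip(rec.sequences["ref"], rec.sequences["mut"]))
            if x != y
        ]
        assert diffs == [p1 - 300, p2 - 300]

    def test_gap_inside_gene_rejects(self):
        rng = np.random.default_rng(306)
        genome, gene = self._setup(rng)
        # deletion inside the gene
        mutant = genome[:400] + genome[450:]
        table = _gene_table(genome, {"del": mutant})
        rec = reconstruct_gene_sequences(table, gene)
        assert isinstance(rec, GeneRejection) and rec.reason == "gapped"

    def test_invariant_gene_rejects(self):
        rng = np.random.default_rng(307)
        genome, gene = self._setup(rng)
        table = _gene_table(genome, {"twin": genome})
        rec = reconstruct_gene_sequences(table, gene)
        assert isinstance(rec, GeneRejection) and rec.reason == "invariant"


class TestScreenGenes:
    def test_synonymous_only_evolution_never_positive(self):
        """Genes evolved with only synonymous changes are not flagged."""
        rng = np.random.default_rng(308)
        stops = CodonTable.unambiguous_dna_by_id[11].stop_codons
        fwd = CodonTable.unambiguous_dna_by_id[11].forward_table
        by_aa: dict[str, list[str]] = {}
        for c, aa in fwd.items():
            by_aa.setdefault(aa, []).append(c)
        codons = []
        while len(codons) < 200:
            c = ALL_CODONS[int(rng.integers(64))]
            if c not in stops and len(by_aa[fwd[c]]) > 1:
                codons.append(c)
        genome = random_dna(100, rng) + "".join(codons) + random_dna(100, rng)
        gene = GeneModel("g", "chr", "+", [(101, 100 + 600)], 0)
        # two samples with single-position synonymous substitutions only
        seqs = {}
        for name in ("a", "b"):
            mut = list(codons)
            planted = 0
            for i in rng.permutation(len(mut)):
                if planted >= 12:
                    break
                c = mut[int(i)]
                syns = [
                    s
                    for s in by_aa[fwd[c]]
                    if sum(x != y for x, y in zip(s, c)) == 1
                ]
                if syns:
                    mut[int(i)] = syns[int(rng.integers(len(syns)))]
                    planted += 1
            seqs[name] = genome[:100] + "".join(mut) + genome[-100:]
        table = _gene_table(genome, seqs)
        results, _ = screen_genes(table, [gene])
        assert len(results) == 1
        assert results[0].classification != "positive"
        assert results[0].dn == pytest.approx(0.0, abs=1e-9)

    def test_excess_nonsynonymous_flags_omega_above_one(self):
        """A gene with many planted nonsynonymous changes shows omega > 1."""
        rng = np.random.default_rng(309)
        stops = CodonTable.unambiguous_dna_by_id[11].stop_codons
        codons = []
        while len(codons) < 200:
            c = ALL_CODONS[int(rng.integers(64))]
            if c not in stops:
                codons.append(c)
        genome = random_dna(90, rng) + "".join(codons) + random_dna(90, rng)
        gene = GeneModel("g", "chr", "+", [(91, 90 + 600)], 0)
        # a 10:1 excess of nonsynonymous over synonymous planted changes
        fwd = CodonTable.unambiguous_dna_by_id[11].forward_table
        by_aa: dict[str, list[str]] = {}
        for c, aa in fwd.items():
            by_aa.setdefault(aa, []).append(c)
        seqs = {}
        for name, n_mut in (("a", 30), ("b", 25)):
            mut = list(codons)
            planted = n_syn = 0
            for i in rng.permutation(len(mut)):
                if planted >= n_mut:
                    break
                c = mut[int(i)]
                if n_syn < 3:  # a few synonymous changes so dS is defined
                    syns = [
                        s for s in by_aa[fwd[c]]
                        if sum(x != y for x, y in zip(s, c)) == 1
                    ]
                    if syns:
                        mut[int(i)] = syns[0]
                        n_syn += 1
                        continue
                alt = BASES[(BASES.index(c[0]) + 1) % 4] + c[1:]
                if alt in stops:
                    continue
                if translate_codon(alt) != translate_codon(c):
                    mut[int(i)] = alt
                    planted += 1
            seqs[name] = genome[:90] + "".join(mut) + genome[-90:]
        table = _gene_table(genome, seqs)
        results, _ = screen_genes(table, [gene])
        assert len(results) == 1
        assert results[0].omega > 1.0
        assert results[0].classification == "positive"

    def test_no_eligible_genes_empty_result(self):
        rng = np.random.default_rng(310)
        genome = random_dna(600, rng)
        table = _gene_table(genome, {"twin": genome})
        gene = GeneModel("g", "chr", "+", [(1, 300)], 0)
        results, rejections = screen_genes(table, [gene])
        assert results == []
        assert rejections and rejections[0].reason == "invariant"


class TestBhAdjust:
    def test_monotone_and_bounded(self):
        ps = [0.001, 0.02, 0.04, 0.5, 0.9]
        qs = bh_adjust(ps)
        assert all(0 <= q <= 1 for q in qs)
        order = np.argsort(ps)
        assert all(qs[order[i]] <= qs[order[i + 1]] + 1e-12 for i in range(len(ps) - 1))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(311)
        ps = rng.uniform(0, 1, 40).tolist()
        _, q_sm, _, _ = multipletests(ps, method="fdr_bh")
        assert np.allclose(bh_adjust(ps), q_sm)
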