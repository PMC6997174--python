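"""SNP annotation by gene context and a counting-method selection screen.

SNPs are partitioned into CDS and intergenic classes using the reference
annotation; CDS SNPs get codon context (codon index, in-codon position,
reference and alternate codons) computed on the coding strand, and a
synonymous/nonsynonymous effect from the chosen genetic code.

The per-gene selection screen is the Nei-Gojobori (1986) counting method:
synonymous and nonsynonymous *sites* are counted per codon by fractional
weighting of the nine possible single-base mutations, observed differences
are apportioned over all minimal mutational pathways with equal weight,
proportions are Jukes-Cantor corrected (d = -(3/4)ln(1 - 4p/3)), and a
normal-approximation z-test on pN - pS classifies each gene as under
positive, purifying, or neutral evolution, with Benjamini-Hochberg control
across genes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from ._seq import BASES, N_CODE
from .core import AlleleTable
from .io import FeatureRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def translate_codon(codon: str, table_id: int = 11) -> str:
    """Amino acid for a codon ('*' for stop) under an NCBI code table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


@dataclass
class GeneModel:
    """One protein-coding gene on the reference (1-based inclusive segments)."""

    gene_id: str
    contig: str
    strand: str
    segments: list[tuple[int, int]]  # ordered 5'->3' on the coding strand
    phase: int = 0

    def genomic_positions(self) -> list[int]:
        """0-based genomic positions in coding order (5'->3' of the mRNA)."""
        pos: list[int] = []
        for s, e in self.segments:
            block = list(range(s - 1, e))
            if self.strand == "-":
                block.reverse()
            pos.extend(block)
        return pos[self.phase :]


def genes_from_gff(features: Iterable[FeatureRecord]) -> list[GeneModel]:
    """Collect CDS features into gene models, grouped by ID/Parent/locus_tag."""
    groups: dict[str, list[FeatureRecord]] = {}
    for f in features:
        if f.type != "CDS":
            continue
        key = (
            f.attributes.get("ID")
            or f.attributes.get("Parent")
            or f.attributes.get("locus_tag")
            or f"cds_{f.seqid}_{f.start}"
        )
        groups.setdefault(key, []).append(f)
    genes = []
    for gid, feats in groups.items():
        strand = feats[0].strand
        contig = feats[0].seqid
        segs = sorted((f.start, f.end) for f in feats)
        if strand == "-":
            segs.reverse()
            phase = feats[[f.start for f in feats].index(max(f.start for f in feats))].phase
        else:
            phase = min(feats, key=lambda f: f.start).phase
        genes.append(
            GeneModel(
                gene_id=gid, contig=contig, strand=strand, segments=segs, phase=phase or 0
            )
        )
    genes.sort(key=lambda g: (g.contig, g.segments[0][0]))
    return genes


@dataclass
class SnpAnnotation:
    contig: str
    pos: int  # 0-based reference position
    ref_base: str
    alt_base: str
    sample: str
    region: str  # CDS | intergenic
    gene_id: Optional[str] = None
    codon_index: Optional[int] = None
    codon_pos: Optional[int] = None  # 1..3 on the coding strand
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    effect: Optional[str] = None  # synonymous | nonsynonymous


def classify_snps(
    snps: Sequence[tuple[str, int, str, str, str]],
    genes: Sequence[GeneModel],
    ref_seqs: dict[str, str],
    table_id: int = 11,
) -> list[SnpAnnotation]:
    """Annotate SNPs (contig, pos0, ref, alt, sample) with gene/codon context.

    A SNP inside several overlapping genes yields one annotation per gene,
    each computed in that gene's own frame and strand.
    """
    # genomic position -> coding index, per gene
    gene_maps: list[tuple[GeneModel, list[int], dict[int, int]]] = []
    for g in genes:
        coding = g.genomic_positions()
        gene_maps.append((g, coding, {p: i for i, p in enumerate(coding)}))

    out: list[SnpAnnotation] = []
    for contig, pos, rb, ab, sample in snps:
        if contig not in ref_seqs:
            raise ValueError(f"SNP on unknown contig {contig!r}")
        if pos >= len(ref_seqs[contig]):
            raise ValueError(f"SNP position {pos} outside contig {contig!r}")
        hit = False
        for g, coding_positions, mapping in gene_maps:
            if g.contig != contig or pos not in mapping:
                continue
            ci = mapping[pos]
            codon_index = ci // 3
            codon_pos = ci % 3
            codon_genomic = coding_positions[codon_index * 3 : codon_index * 3 + 3]
            if len(codon_genomic) < 3:
                continue  # trailing partial codon
            seq = ref_seqs[contig]
            bases = [seq[p] for p in codon_genomic]
            if g.strand == "-":
                bases = [_COMP[b] if b in _COMP else "N" for b in bases]
            ref_codon = "".join(bases)
            alt = ab if g.strand == "+" else _COMP.get(ab, "N")
            alt_codon = ref_codon[:codon_pos] + alt + ref_codon[codon_pos + 1 :]
            if any(c not in "ACGT" for c in ref_codon + alt_codon):
                effect = None
            else:
                effect = (
                    "synonymous"
                    if translate_codon(ref_codon, table_id)
                    == translate_codon(alt_codon, table_id)
                    else "nonsynonymous"
                )
            out.append(
                SnpAnnotation(
                    contig=contig,
                    pos=pos,
                    ref_base=rb,
                    alt_base=ab,
                    sample=sample,
                    region="CDS",
                    gene_id=g.gene_id,
                    codon_index=codon_index,
                    codon_pos=codon_pos + 1,
                    ref_codon=ref_codon,
                    alt_codon=alt_codon,
                    effect=effect,
                )
            )
            hit = True
        if not hit:
            out.append(
                SnpAnnotation(
                    contig=contig, pos=pos, ref_base=rb, alt_base=ab, sample=sample,
                    region="intergenic",
                )
            )
    return out


# ---------------------------------------------------------------------------
# gene sequence reconstruction


@dataclass
class GeneSequences:
    gene: GeneModel
    sequences: dict[str, str]  # sample -> coding-strand sequence
    n_codons: int


@dataclass
class GeneRejection:
    gene: GeneModel
    reason: str  # gapped | invariant | frame


def reconstruct_gene_sequences(
    table: AlleleTable,
    gene: GeneModel,
    samples: Optional[Sequence[str]] = None,
) -> GeneSequences | GeneRejection:
    """Positionally extract in-frame coding sequences for every sample.

    Eligible genes have a plain base call in every sample over all CDS
    positions (otherwise ``gapped``) and at least one polymorphic position
    (otherwise ``invariant``).
    """
    samples = list(samples) if samples is not None else list(table.samples)
    layout = table.layout
    if gene.contig not in layout.names:
        raise ValueError(f"gene contig {gene.contig!r} not in reference")
    off = layout.offsets[layout.names.index(gene.contig)]
    clen = layout.lengths[layout.names.index(gene.contig)]
    coding = gene.genomic_positions()
    if any(p < 0 or p >= clen for p in coding):
        raise ValueError(f"gene {gene.gene_id!r} outside contig bounds")
    n_codons = len(coding) // 3
    coding = coding[: n_codons * 3]
    if n_codons == 0:
        return GeneRejection(gene, "frame")
    gpos = np.array(coding, dtype=np.int64) + off
    sub = np.stack([table.tracks[s][gpos] for s in samples])
    if (sub >= N_CODE).any():
        return GeneRejection(gene, "gapped")
    if (sub.min(axis=0) == sub.max(axis=0)).all():
        return GeneRejection(gene, "invariant")
    seqs = {}
    for row, s in enumerate(samples):
        bases = "".join(BASES[b] for b in sub[row])
        if gene.strand == "-":
            bases = "".join(_COMP[b] for b in bases)  # positions already 5'->3'
        seqs[s] = bases
    return GeneSequences(gene=gene, sequences=seqs, n_codons=n_codons)


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986


def _codon_sites(codon: str, table_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon; sums to 3."""
    aa = translate_codon(codon, table_id)
    syn = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if translate_codon(mutant, table_id) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _codon_differences(c1: str, c2: str, table_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over minimal pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    nd = len(diff_pos)
    if nd == 0:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0.0
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if translate_codon(cur, table_id) == translate_codon(nxt, table_id):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        syn_total += syn
        nonsyn_total += nonsyn
        n_paths += 1
    return syn_total / n_paths, nonsyn_total / n_paths


def _jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction; NaN when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return float("nan")
    return max(0.0, -0.75 * math.log(1.0 - 4.0 * p / 3.0))


@dataclass
class PairwiseDnDs:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float
    pn: float
    ds: float
    dn: float
    z: float
    p_value: float


def ng86_pair(
    seq_a: str,
    seq_b: str,
    table_id: int = 11,
    on_stop: str = "error",
) -> PairwiseDnDs:
    """Nei-Gojobori dN/dS between two equal-length in-frame sequences.

    ``on_stop='error'`` rejects internal stop codons; ``'skip'`` drops codon
    pairs where either side is a stop (they carry no defined sites), which
    the gene screen uses for evolved-in stops.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("sequence length not a multiple of 3")
    n_codons = len(seq_a) // 3
    S = Nsites = Sd = Nd = 0.0
    table = CodonTable.unambiguous_dna_by_id[table_id]
    for k in range(n_codons):
        c1 = seq_a[3 * k : 3 * k + 3]
        c2 = seq_b[3 * k : 3 * k + 3]
        stop = c1 in table.stop_codons or c2 in table.stop_codons
        if stop:
            if k < n_codons - 1 and on_stop == "error":
                raise ValueError(f"internal stop codon at codon {k}")
            continue  # terminal stops and skipped codons carry no sites
        s1, n1 = _codon_sites(c1, table_id)
        s2, n2 = _codon_sites(c2, table_id)
        S += (s1 + s2) / 2.0
        Nsites += (n1 + n2) / 2.0
        sd, nd = _codon_differences(c1, c2, table_id)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / Nsites if Nsites > 0 else 0.0
    ds = _jc_correct(ps)
    dn = _jc_correct(pn)
    var = 0.0
    if S > 0:
        var += ps * (1 - ps) / S
    if Nsites > 0:
        var += pn * (1 - pn) / Nsites
    z = (pn - ps) / math.sqrt(var) if var > 0 else 0.0
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return PairwiseDnDs(
        syn_sites=S, nonsyn_sites=Nsites, syn_diffs=Sd, nonsyn_diffs=Nd,
        ps=ps, pn=pn, ds=ds, dn=dn, z=z, p_value=p_value,
    )


# ---------------------------------------------------------------------------
# gene screen


@dataclass
class GeneSelectionResult:
    gene_id: str
    n_codons: int
    dn: float
    ds: float
    omega: float  # NaN when dS undefined
    z: float
    p_value: float
    q_value: float = float("nan")
    classification: str = "undetermined"


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    m = len(pvalues)
    if m == 0:
        return []
    order = np.argsort(pvalues)
    adj = np.empty(m, dtype=float)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, pvalues[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj.tolist()


def screen_genes(
    table: AlleleTable,
    genes: Sequence[GeneModel],
    table_id: int = 11,
    alpha: float = 0.05,
    samples: Optional[Sequence[str]] = None,
) -> tuple[list[GeneSelectionResult], list[GeneRejection]]:
    """NG86 selection screen over all eligible genes.

    Per gene, dN and dS are means over all sample pairs and omega is the
    ratio of those means; the z-test runs on the mean proportions.  BH-FDR
    is applied across genes; 'positive' needs omega > 1 at q <= alpha,
    'purifying' omega < 1 at q <= alpha.
    """
    results: list[GeneSelectionResult] = []
    rejections: list[GeneRejection] = []
    for gene in genes:
        rec = reconstruct_gene_sequences(table, gene, samples)
        if isinstance(rec, GeneRejection):
            rejections.append(rec)
            continue
        names = list(rec.sequences)
        pairs = [
            ng86_pair(rec.sequences[a], rec.sequences[b], table_id, on_stop="skip")
            for a, b in itertools.combinations(names, 2)
        ]
        pairs = [p for p in pairs if p.syn_sites + p.nonsyn_sites > 0]
        if not pairs:
            rejections.append(GeneRejection(gene, "no_sites"))
            continue
        dn_vals = [p.dn for p in pairs]
        ds_vals = [p.ds for p in pairs]
        dn_mean = float(np.nanmean(dn_vals)) if not all(math.isnan(v) for v in dn_vals) else float("nan")
        ds_mean = float(np.nanmean(ds_vals)) if not all(math.isnan(v) for v in ds_vals) else float("nan")
        pn_mean = float(np.mean([p.pn for p in pairs]))
        ps_mean = float(np.mean([p.ps for p in pairs]))
        s_mean = float(np.mean([p.syn_sites for p in pairs]))
        n_mean = float(np.mean([p.nonsyn_sites for p in pairs]))
        var = 0.0
        if s_mean > 0:
            var += ps_mean * (1 - ps_mean) / s_mean
        if n_mean > 0:
            var += pn_mean * (1 - pn_mean) / n_mean
        z = (pn_mean - ps_mean) / math.sqrt(var) if var > 0 else 0.0
        p_value = float(2.0 * stats.norm.sf(abs(z)))
        omega = (
            dn_mean / ds_mean
            if ds_mean and not math.isnan(ds_mean) and ds_mean > 0 and not math.isnan(dn_mean)
            else float("nan")
        )
        results.append(
            GeneSelectionResult(
                gene_id=gene.gene_id,
                n_codons=rec.n_codons,
                dn=dn_mean,
                ds=ds_mean,
                omega=omega,
                z=z,
                p_value=p_value,
            )
        )
    qvals = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qvals):
        r.q_value = q
        if math.isnan(r.omega):
            r.classification = "undetermined"
        elif q <= alpha and r.omega > 1.0:
            r.classification = "positive"
        elif q <= alpha and r.omega < 1.0:
            r.classification = "purifying"
        else:
            r.classification = "neutral"
    return results, rejections


# ---------------------------------------------------------------------------
# report writers


def write_snp_annotation(annotations: Sequence[SnpAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "contig\tpos\tref\talt\tsample\tregion\tgene\tcodon_index\t"
            "codon_pos\tref_codon\talt_codon\teffect\n"
        )
        for a in annotations:
            fh.write(
                f"{a.contig}\t{a.pos + 1}\t{a.ref_base}\t{a.alt_base}\t{a.sample}\t"
                f"{a.region}\t{a.gene_id or '.'}\t"
                f"{a.codon_index if a.codon_index is not None else '.'}\t"
                f"{a.codon_pos if a.codon_pos is not None else '.'}\t"
                f"{a.ref_codon or '.'}\t{a.alt_codon or '.'}\t{a.effect or '.'}\n"
            )


def write_gene_selection(results: Sequence[GeneSelectionResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tn_codons\tdN\tdS\tomega\tz\tp\tq\tclass\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.n_codons}\t{r.dn:.6f}\t{r.ds:.6f}\t{r.omega:.6f}\t"
                f"{r.z:.4f}\t{r.p_value:.6g}\t{r.q_value:.6g}\t{r.classification}\n"
            )
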