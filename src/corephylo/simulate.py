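"""Ground-truth simulator: clades, contigs, reads, and metagenome mixtures.

The generator produces the known-answer inputs every pipeline stage is
validated against: a random (or user-supplied) tree, a root genome, leaf
genomes evolved by Jukes-Cantor substitutions (Poisson number per branch,
uniform positions, uniform alternative base), optional planted deletions
and repeats, a synthetic GFF3 of non-overlapping stop-free CDS genes, and
read sets with uniform coverage and uniform per-base substitution error.

All randomness flows from one integer seed through named per-operation
generators, so each output is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._seq import BASES, decode, encode, revcomp
from .io import FeatureRecord, ReadRecord, SequenceRecord
from .phylo import Tree, TreeNode, write_newick

# operation tags for derived generators
_OP_TREE, _OP_ROOT, _OP_EVOLVE, _OP_READS, _OP_CONTIG, _OP_MIX, _OP_GENES = range(7)


def _rng(seed: int, op: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, op, extra])


@dataclass
class ReadSpec:
    length: int = 100
    coverage: float = 20.0
    error_rate: float = 0.01
    paired: bool = False
    insert_mean: float = 300.0
    insert_sd: float = 30.0


@dataclass
class SimulationConfig:
    n_taxa: int = 5
    genome_length: int = 200_000
    gc_content: float = 0.5
    branch_length: float = 0.005  # expected substitutions/site per branch
    tree_newick: Optional[str] = None
    indel_rate: float = 0.0  # deletions per site per branch
    indel_mean_len: float = 50.0
    repeat_count: int = 0
    repeat_length: int = 0
    repeat_copies: int = 2
    cds_fraction: float = 0.85
    seed: int = 42

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least two taxa")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if self.branch_length < 0 or self.indel_rate < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class GroundTruth:
    tree: Tree
    newick: str
    root_genome: np.ndarray
    leaf_genomes: dict[str, np.ndarray]  # pre-indel, root coordinates
    deletions: dict[str, list[tuple[int, int]]]
    repeat_intervals: list[tuple[int, int]]

    def substitutions(self, sample: str) -> list[tuple[int, str, str]]:
        """Per-sample (root position, root base, leaf base) differences."""
        leaf = self.leaf_genomes[sample]
        diff = np.nonzero(leaf != self.root_genome)[0]
        return [
            (int(p), BASES[self.root_genome[p]], BASES[leaf[p]]) for p in diff
        ]

    def polymorphic_positions(self, samples: Optional[Sequence[str]] = None) -> np.ndarray:
        """Root positions where at least two of the given leaves differ."""
        names = list(samples) if samples is not None else sorted(self.leaf_genomes)
        mat = np.stack([self.leaf_genomes[s] for s in names])
        return np.nonzero(mat.min(axis=0) != mat.max(axis=0))[0]

    def expected_snps_vs(self, reference: str, sample: str) -> list[tuple[int, str, str]]:
        """(position, ref base, sample base) where sample differs from reference."""
        ref = self.leaf_genomes[reference]
        qry = self.leaf_genomes[sample]
        diff = np.nonzero(ref != qry)[0]
        return [(int(p), BASES[ref[p]], BASES[qry[p]]) for p in diff]


@dataclass
class SimulatedClade:
    config: SimulationConfig
    samples: dict[str, list[SequenceRecord]]  # leaf name -> genome FASTA records
    features: list[FeatureRecord]  # synthetic annotation, root coordinates
    truth: GroundTruth

    def features_for(self, sample: str) -> list[FeatureRecord]:
        """The annotation retargeted to one leaf's contig name.

        Valid whenever that leaf carries no planted deletions (coordinates
        are shared with the root in substitution-only simulations).
        """
        if self.truth.deletions.get(sample):
            raise ValueError(f"{sample!r} has deletions; root coordinates do not apply")
        return [
            FeatureRecord(
                seqid=sample,
                type=f.type,
                start=f.start,
                end=f.end,
                strand=f.strand,
                phase=f.phase,
                attributes=dict(f.attributes),
            )
            for f in self.features
        ]


def _random_topology(names: list[str], branch_length: float, rng: np.random.Generator) -> Tree:
    nodes = [TreeNode(name=n, length=branch_length) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        p = TreeNode(length=branch_length, children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [p]
    if len(nodes) == 2:  # n_taxa == 2
        return Tree(root=TreeNode(children=nodes))
    return Tree(root=TreeNode(children=nodes))


def _stop_free_codons(table_stops: set[str], rng: np.random.Generator, n: int) -> np.ndarray:
    """n random sense codons as a flat code array."""
    sense = [
        c1 + c2 + c3
        for c1 in BASES
        for c2 in BASES
        for c3 in BASES
        if c1 + c2 + c3 not in table_stops
    ]
    picks = rng.integers(0, len(sense), n)
    return np.concatenate([encode(sense[i]) for i in picks])


def synthetic_annotation(
    length: int,
    cds_fraction: float,
    rng: np.random.Generator,
    contig: str = "chr1",
) -> tuple[list[FeatureRecord], np.ndarray]:
    """Non-overlapping frame-0 CDS genes tiling ~cds_fraction of the genome.

    Returns the features and a boolean mask of gene body positions whose
    sequence the caller should overwrite with stop-free codons (alternating
    strands, phase 0).
    """
    features: list[FeatureRecord] = []
    mask = np.zeros(length, dtype=bool)
    pos = int(rng.integers(20, 200))
    gi = 0
    while pos < length - 400:
        n_codons = int(rng.integers(100, 500))
        glen = 3 * n_codons
        if pos + glen > length - 20:
            break
        strand = "+" if gi % 2 == 0 else "-"
        features.append(
            FeatureRecord(
                seqid=contig,
                type="CDS",
                start=pos + 1,
                end=pos + glen,
                strand=strand,
                phase=0,
                attributes={"ID": f"gene{gi:04d}", "locus_tag": f"gene{gi:04d}"},
            )
        )
        mask[pos : pos + glen] = True
        gi += 1
        # intergenic spacer sized to hit the target coding fraction
        spacer = max(10, int(glen * (1 - cds_fraction) / max(cds_fraction, 1e-9)))
        pos += glen + int(rng.integers(10, max(11, spacer * 2)))
    return features, mask


def simulate_clade(config: SimulationConfig) -> SimulatedClade:
    """Evolve a clade of genomes with full ground truth."""
    config.validate()
    L = config.genome_length
    names = [f"s{i:02d}" for i in range(config.n_taxa)]

    if config.tree_newick is not None:
        from .phylo import read_newick

        tree = read_newick(config.tree_newick)
        if sorted(tree.leaf_names()) != sorted(names) and config.n_taxa != len(
            tree.leaf_names()
        ):
            raise ValueError("tree leaf count does not match n_taxa")
        names = tree.leaf_names()
    else:
        tree = _random_topology(names, config.branch_length, _rng(config.seed, _OP_TREE))

    # root genome
    rng_root = _rng(config.seed, _OP_ROOT)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    root = rng_root.choice(4, size=L, p=probs).astype(np.uint8)

    # synthetic genes: overwrite gene bodies with stop-free codons so the
    # selection screen sees translatable frames (reverse strand genes carry
    # the sense codons on their own strand)
    from Bio.Data import CodonTable

    stops = set(CodonTable.unambiguous_dna_by_id[11].stop_codons)
    rng_genes = _rng(config.seed, _OP_GENES)
    features, gene_mask = synthetic_annotation(L, config.cds_fraction, rng_genes)
    for f in features:
        glen = f.end - f.start + 1
        codons = _stop_free_codons(stops, rng_genes, glen // 3)
        if f.strand == "-":
            codons = revcomp(codons)
        root[f.start - 1 : f.end] = codons

    # planted repeats (copy a segment to new loci)
    repeat_intervals: list[tuple[int, int]] = []
    if config.repeat_count and config.repeat_length:
        rng_rep = _rng(config.seed, _OP_ROOT, 1)
        for _ in range(config.repeat_count):
            src = int(rng_rep.integers(0, L - config.repeat_length))
            seg = root[src : src + config.repeat_length].copy()
            repeat_intervals.append((src, src + config.repeat_length))
            for _c in range(config.repeat_copies - 1):
                dst = int(rng_rep.integers(0, L - config.repeat_length))
                root[dst : dst + config.repeat_length] = seg
                repeat_intervals.append((dst, dst + config.repeat_length))

    # evolve along the tree
    leaf_genomes: dict[str, np.ndarray] = {}
    deletions: dict[str, list[tuple[int, int]]] = {}
    rng_evo = _rng(config.seed, _OP_EVOLVE)

    def evolve(node: TreeNode, genome: np.ndarray, dels: list[tuple[int, int]]) -> None:
        genome = genome.copy()
        n_sub = rng_evo.poisson(node.length * L)
        if n_sub:
            pos = rng_evo.choice(L, size=min(n_sub, L), replace=False)
            shift = rng_evo.integers(1, 4, size=len(pos)).astype(np.uint8)
            genome[pos] = (genome[pos] + shift) % 4
        dels = list(dels)
        n_del = rng_evo.poisson(config.indel_rate * L) if config.indel_rate else 0
        for _ in range(int(n_del)):
            dlen = max(1, int(rng_evo.geometric(1.0 / config.indel_mean_len)))
            start = int(rng_evo.integers(0, max(1, L - dlen)))
            dels.append((start, start + dlen))
        if node.is_leaf:
            leaf_genomes[node.name] = genome
            deletions[node.name] = _merge(dels)
        else:
            for c in node.children:
                evolve(c, genome, dels)

    for child in tree.root.children:
        evolve(child, root, [])

    samples = {}
    for name in names:
        genome = leaf_genomes[name]
        keep = np.ones(L, dtype=bool)
        for s, e in deletions[name]:
            keep[s:e] = False
        samples[name] = [SequenceRecord(id=name, residues=decode(genome[keep]))]

    truth = GroundTruth(
        tree=tree,
        newick=write_newick(tree),
        root_genome=root,
        leaf_genomes=leaf_genomes,
        deletions=deletions,
        repeat_intervals=sorted(repeat_intervals),
    )
    return SimulatedClade(config=config, samples=samples, features=features, truth=truth)


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def fragment_contigs(
    genome: Sequence[SequenceRecord],
    n_breaks: int,
    drop_fraction: float = 0.0,
    seed: int = 42,
) -> list[SequenceRecord]:
    """Cut a genome at uniform positions into shuffled, renamed contigs.

    ``drop_fraction`` of the fragments (by count, rounded down) is removed.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    rng = _rng(seed, _OP_CONTIG)
    residues = "".join(r.residues for r in genome)
    L = len(residues)
    if n_breaks >= L:
        raise ValueError("more breaks than bases")
    if n_breaks == 0:
        frags = [residues]
    else:
        cuts = np.sort(rng.choice(np.arange(1, L), size=n_breaks, replace=False))
        bounds = [0, *cuts.tolist(), L]
        frags = [residues[s:e] for s, e in zip(bounds[:-1], bounds[1:])]
    n_drop = int(len(frags) * drop_fraction)
    order = rng.permutation(len(frags))
    kept = sorted(order[: len(frags) - n_drop])
    shuffled = rng.permutation(len(kept))
    base = genome[0].id
    return [
        SequenceRecord(id=f"{base}_ctg{i:03d}", residues=frags[kept[j]])
        for i, j in enumerate(shuffled)
    ]


def simulate_reads(
    genome: Sequence[SequenceRecord],
    spec: ReadSpec = ReadSpec(),
    seed: int = 42,
    name_prefix: str = "read",
) -> tuple[list[ReadRecord], list[tuple[str, int, str]]]:
    """Uniform-coverage reads with uniform substitution errors.

    Returns (reads, origin) where origin records (contig, 0-based start,
    strand) per read (per fragment for paired mode).  Qualities are a
    constant Q30 placeholder.
    """
    rng = _rng(seed, _OP_READS)
    residues = "".join(r.residues for r in genome)
    codes = encode(residues)
    L = len(codes)
    rl = spec.length
    if rl > L:
        raise ValueError("read length exceeds genome length")
    n_reads = int(np.ceil(spec.coverage * L / rl))
    reads: list[ReadRecord] = []
    origin: list[tuple[str, int, str]] = []
    contig = genome[0].id
    quals = [30] * rl

    def finish(seq_codes: np.ndarray, rid: str, mate: int) -> ReadRecord:
        seq = seq_codes.copy()
        n_err = rng.binomial(rl, spec.error_rate)
        if n_err:
            pos = rng.choice(rl, size=n_err, replace=False)
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            ok = seq[pos] < 4
            seq[pos[ok]] = (seq[pos[ok]] + shift[ok]) % 4
        return ReadRecord(id=rid, residues=decode(seq), qualities=list(quals), mate=mate)

    if not spec.paired:
        for i in range(n_reads):
            start = int(rng.integers(0, L - rl + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seg = codes[start : start + rl]
            if strand == "-":
                seg = revcomp(seg)
            reads.append(finish(seg, f"{name_prefix}{i}", 0))
            origin.append((contig, start, strand))
    else:
        n_pairs = (n_reads + 1) // 2
        for i in range(n_pairs):
            insert = max(rl, int(rng.normal(spec.insert_mean, spec.insert_sd)))
            insert = min(insert, L)
            start = int(rng.integers(0, L - insert + 1))
            frag = codes[start : start + insert]
            fwd = frag[:rl]
            rev = revcomp(frag[-rl:])
            reads.append(finish(fwd, f"{name_prefix}{i}/1", 0))
            reads.append(finish(rev, f"{name_prefix}{i}/2", 1))
            origin.append((contig, start, "+"))
    return reads, origin


def mix_metagenome(
    target_reads: Sequence[ReadRecord],
    background_genomes: Sequence[Sequence[SequenceRecord]],
    proportions: Sequence[float],
    total_reads: int,
    seed: int = 42,
    read_length: int = 100,
    error_rate: float = 0.01,
) -> tuple[list[ReadRecord], list[str]]:
    """Multinomial mixture of target reads and background-genome reads.

    ``proportions[0]`` is the target fraction; the rest map to the
    background genomes in order.  Returns shuffled reads and per-read
    source labels ('target' or 'background<i>').
    """
    props = np.asarray(proportions, dtype=float)
    if len(props) != 1 + len(background_genomes):
        raise ValueError("need one proportion per source")
    if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
        raise ValueError("proportions must be nonnegative and sum to 1")
    rng = _rng(seed, _OP_MIX)
    counts = rng.multinomial(total_reads, props)
    reads: list[ReadRecord] = []
    labels: list[str] = []
    n_t = int(counts[0])
    if n_t:
        if not target_reads:
            raise ValueError("target proportion > 0 but no target reads given")
        idx = rng.choice(len(target_reads), size=n_t, replace=n_t > len(target_reads))
        for k, i in enumerate(idx):
            src = target_reads[int(i)]
            reads.append(
                ReadRecord(
                    id=f"mix_t{k}", residues=src.residues, qualities=list(src.qualities)
                )
            )
            labels.append("target")
    for b, genome in enumerate(background_genomes):
        n_b = int(counts[b + 1])
        if n_b == 0:
            continue
        spec = ReadSpec(length=read_length, coverage=0.0, error_rate=error_rate)
        codes = encode("".join(r.residues for r in genome))
        L = len(codes)
        for k in range(n_b):
            start = int(rng.integers(0, L - read_length + 1))
            seg = codes[start : start + read_length].copy()
            if rng.random() < 0.5:
                seg = revcomp(seg)
            n_err = rng.binomial(read_length, error_rate)
            if n_err:
                pos = rng.choice(read_length, size=n_err, replace=False)
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                seg[pos] = (seg[pos] + shift) % 4
            reads.append(
                ReadRecord(
                    id=f"mix_b{b}_{k}", residues=decode(seg), qualities=[30] * read_length
                )
            )
            labels.append(f"background{b}")
    order = rng.permutation(len(reads))
    return [reads[i] for i in order], [labels[i] for i in order]


# ---------------------------------------------------------------------------
# file emission (CLI surface)


def write_clade(clade: SimulatedClade, out_dir) -> None:
    from .io import write_fasta

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for name, records in clade.samples.items():
        write_fasta(records, d / f"{name}.fasta")
    with open(d / "annotation.gff3", "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for f in clade.features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write(
                f"{f.seqid}\t corephylo_sim\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t"
                f"{f.phase}\t{attrs}\n".replace("\t ", "\t")
            )
    (d / "truth_tree.nwk").write_text(clade.truth.newick + "\n", encoding="utf-8")
    with open(d / "truth_snps.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample\tpos\troot_base\tleaf_base\n")
        for name in sorted(clade.truth.leaf_genomes):
            for pos, rb, lb in clade.truth.substitutions(name):
                fh.write(f"{name}\t{pos + 1}\t{rb}\t{lb}\n")
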