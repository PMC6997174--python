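"""The allele table and core-genome extraction.

The :class:`AlleleTable` is the pipeline's central orthology store: one
dense call track per sample over every reference position, with calls in
``{A, C, G, T, GAP, AMBIG}``.  Everything downstream — the core alignment,
SNP matrices, subset re-analysis and incremental sample placement — is a
pure function of this table, so subsets and additions never trigger
realignment.

The core genome is the set of positions where every retained sample has a
plain base; core SNP columns are core positions where at least two samples
disagree.  Ambiguous calls (N columns, sub-threshold read evidence) exclude
a position from the core exactly like gaps do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._seq import AMBIG_CODE, BASES, GAP_CODE, N_CODE, decode, encode
from .io import FeatureRecord, SequenceRecord
from .readmap import SampleCallTrack
from .wga import PairwiseResult, RepeatMask

_TRACK_SYMBOLS = "ACGTN-?"


@dataclass
class ReferenceLayout:
    names: list[str]
    lengths: list[int]

    @property
    def offsets(self) -> list[int]:
        out, pos = [], 0
        for n in self.lengths:
            out.append(pos)
            pos += n
        return out

    @property
    def total(self) -> int:
        return sum(self.lengths)

    def global_to_local(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        bounds = np.array(self.offsets + [self.total])
        idx = np.searchsorted(bounds, gpos, side="right") - 1
        return idx, gpos - bounds[idx]


@dataclass
class AlleleTable:
    layout: ReferenceLayout
    reference: str
    samples: list[str]  # ordered, reference first
    data_types: dict[str, str]
    tracks: dict[str, np.ndarray]  # sample -> uint8 codes over layout.total
    genome_lengths: dict[str, int] = field(default_factory=dict)  # input genome sizes
    mask_fraction: float = 0.0

    def aligned_fraction(self, sample: str) -> float:
        track = self.tracks[sample]
        return float((track != GAP_CODE).sum() / len(track))


@dataclass
class CoreAlignment:
    samples: list[str]
    positions: np.ndarray  # global reference positions of core columns
    matrix: np.ndarray  # (n_samples, n_core) uint8 base codes
    snp_index: np.ndarray  # indices into columns with >=2 distinct bases
    cds_label: Optional[np.ndarray] = None  # per core column, True = CDS

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_snps(self) -> int:
        return len(self.snp_index)

    def snp_positions(self) -> np.ndarray:
        return self.positions[self.snp_index]

    def snp_matrix(self) -> np.ndarray:
        return self.matrix[:, self.snp_index]


@dataclass
class SnpMatrixSet:
    samples: list[str]
    core: np.ndarray
    cds: Optional[np.ndarray]
    intergenic: Optional[np.ndarray]
    core_length: int


def _track_from_pairwise(
    result: PairwiseResult, layout: ReferenceLayout, ref_track: np.ndarray
) -> np.ndarray:
    track = ref_track.copy()
    track[track >= N_CODE] = AMBIG_CODE
    offsets = dict(zip(layout.names, layout.offsets))
    for contig, ivs in result.gaps.items():
        off = offsets[contig]
        for s, e in ivs:
            track[off + s : off + e] = GAP_CODE
    for contig, pos in result.ambig:
        track[offsets[contig] + pos] = AMBIG_CODE
    for contig, pos, _rb, qb in result.snps:
        track[offsets[contig] + pos] = BASES.index(qb)
    return track


def _track_from_calls(calls: SampleCallTrack, layout: ReferenceLayout) -> np.ndarray:
    parts = []
    for name in layout.names:
        arr = calls.calls[name]
        arr = arr.copy()
        arr[arr == N_CODE] = AMBIG_CODE
        parts.append(arr)
    return np.concatenate(parts)


def build_allele_table(
    ref: Sequence[SequenceRecord],
    mask: Optional[RepeatMask],
    pairwise_results: Iterable[PairwiseResult] = (),
    read_tracks: Iterable[SampleCallTrack] = (),
    reference_name: str = "reference",
    data_types: Optional[Mapping[str, str]] = None,
    genome_lengths: Optional[Mapping[str, int]] = None,
) -> AlleleTable:
    """Fuse the reference, pairwise alignments and read call tracks into one table.

    Masked reference positions are forced to GAP for every sample, the
    reference included, so repeats can never contribute core columns.
    """
    layout = ReferenceLayout(
        names=[r.id for r in ref], lengths=[len(r.residues) for r in ref]
    )
    ref_codes = np.concatenate([encode(r.residues) for r in ref])
    ref_track = ref_codes.copy()
    ref_track[ref_track >= N_CODE] = AMBIG_CODE

    masked = np.zeros(layout.total, dtype=bool)
    if mask is not None:
        for name, off, length in zip(layout.names, layout.offsets, layout.lengths):
            masked[off : off + length] = mask.bool_track(name, length)

    data_types = dict(data_types or {})
    data_types.setdefault(reference_name, "complete")
    tracks: dict[str, np.ndarray] = {}
    order: list[str] = [reference_name]
    tracks[reference_name] = ref_track.copy()

    for res in pairwise_results:
        if res.sample in tracks:
            raise ValueError(f"duplicate sample id {res.sample!r}")
        tracks[res.sample] = _track_from_pairwise(res, layout, ref_codes)
        order.append(res.sample)
        data_types.setdefault(res.sample, "complete")
    for calls in read_tracks:
        if calls.sample in tracks:
            raise ValueError(f"duplicate sample id {calls.sample!r}")
        track = _track_from_calls(calls, layout)
        if len(track) != layout.total:
            raise ValueError(f"track length mismatch for {calls.sample!r}")
        tracks[calls.sample] = track
        order.append(calls.sample)
        data_types.setdefault(calls.sample, "reads")

    for track in tracks.values():
        track[masked] = GAP_CODE

    glens = dict(genome_lengths or {})
    glens.setdefault(reference_name, layout.total)
    return AlleleTable(
        layout=layout,
        reference=reference_name,
        samples=order,
        data_types={s: data_types[s] for s in order},
        tracks=tracks,
        genome_lengths=glens,
        mask_fraction=float(masked.mean()) if layout.total else 0.0,
    )


def filter_samples(table: AlleleTable, cutoff: float) -> tuple[AlleleTable, dict[str, float]]:
    """Drop samples whose non-GAP fraction of the reference is below ``cutoff``.

    The reference itself is never dropped.  Returns the filtered table and
    the dropped samples with their aligned fractions.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    dropped: dict[str, float] = {}
    kept = [table.reference]
    for s in table.samples:
        if s == table.reference:
            continue
        frac = table.aligned_fraction(s)
        if frac < cutoff:
            dropped[s] = frac
        else:
            kept.append(s)
    if len(kept) < 2:
        raise ValueError("aligned-fraction cutoff removed every non-reference sample")
    return (
        AlleleTable(
            layout=table.layout,
            reference=table.reference,
            samples=kept,
            data_types={s: table.data_types[s] for s in kept},
            tracks={s: table.tracks[s] for s in kept},
            genome_lengths={
                s: table.genome_lengths[s] for s in kept if s in table.genome_lengths
            },
            mask_fraction=table.mask_fraction,
        ),
        dropped,
    )


def cds_track(layout: ReferenceLayout, features: Iterable[FeatureRecord]) -> np.ndarray:
    """Boolean CDS/intergenic label per reference position from the annotation."""
    track = np.zeros(layout.total, dtype=bool)
    offsets = dict(zip(layout.names, layout.offsets))
    lengths = dict(zip(layout.names, layout.lengths))
    for f in features:
        if f.type != "CDS" or f.seqid not in offsets:
            continue
        off = offsets[f.seqid]
        end = min(f.end, lengths[f.seqid])
        track[off + f.start - 1 : off + end] = True
    return track


def compute_core(
    table: AlleleTable,
    sample_subset: Optional[Sequence[str]] = None,
    cds_positions: Optional[np.ndarray] = None,
) -> CoreAlignment:
    """Core columns = positions where every subset sample calls a plain base."""
    subset = list(sample_subset) if sample_subset is not None else list(table.samples)
    if table.reference not in subset:
        subset = [table.reference] + subset
    unknown = [s for s in subset if s not in table.tracks]
    if unknown:
        raise ValueError(f"unknown samples {unknown}")
    # keep the table's deterministic sample order
    subset = [s for s in table.samples if s in set(subset)]
    if len(subset) < 2:
        raise ValueError("need at least two samples for a core alignment")
    mat = np.stack([table.tracks[s] for s in subset])
    core_mask = (mat < N_CODE).all(axis=0)
    positions = np.nonzero(core_mask)[0]
    matrix = mat[:, core_mask]
    if matrix.shape[1]:
        snp_cols = matrix.min(axis=0) != matrix.max(axis=0)
    else:
        snp_cols = np.zeros(0, dtype=bool)
    labels = cds_positions[positions] if cds_positions is not None else None
    return CoreAlignment(
        samples=subset,
        positions=positions,
        matrix=matrix,
        snp_index=np.nonzero(snp_cols)[0],
        cds_label=labels,
    )


def pairwise_matrices(core: CoreAlignment) -> SnpMatrixSet:
    """Pairwise SNP counts over core columns, with CDS/intergenic partitions."""
    k = len(core.samples)
    snp_mat = core.snp_matrix()
    counts = np.zeros((k, k), dtype=np.int64)
    cds = intergenic = None
    if core.cds_label is not None:
        cds = np.zeros((k, k), dtype=np.int64)
        intergenic = np.zeros((k, k), dtype=np.int64)
        snp_cds = core.cds_label[core.snp_index]
    for i in range(k):
        for j in range(i + 1, k):
            diff = snp_mat[i] != snp_mat[j]
            counts[i, j] = counts[j, i] = int(diff.sum())
            if cds is not None:
                c = int((diff & snp_cds).sum())
                cds[i, j] = cds[j, i] = c
                intergenic[i, j] = intergenic[j, i] = counts[i, j] - c
    return SnpMatrixSet(
        samples=list(core.samples),
        core=counts,
        cds=cds,
        intergenic=intergenic,
        core_length=core.length,
    )


def subset_recompute(
    table: AlleleTable,
    subset: Sequence[str],
    cds_positions: Optional[np.ndarray] = None,
) -> tuple[CoreAlignment, SnpMatrixSet]:
    """Recompute core + matrices for a sample subset without realignment."""
    core = compute_core(table, subset, cds_positions)
    return core, pairwise_matrices(core)


def add_sample(
    table: AlleleTable,
    new_result: PairwiseResult | SampleCallTrack,
    data_type: Optional[str] = None,
    genome_length: Optional[int] = None,
) -> AlleleTable:
    """Extend the table by one sample track; existing tracks are untouched."""
    ref_codes = table.tracks[table.reference]
    if isinstance(new_result, PairwiseResult):
        name = new_result.sample
        # rebuild against the raw reference codes (reference track may hold
        # masked GAPs; recover base codes from a stored clean copy)
        clean = ref_codes.copy()
        track = _track_from_pairwise(new_result, table.layout, clean)
        dtype = data_type or "complete"
    else:
        name = new_result.sample
        track = _track_from_calls(new_result, table.layout)
        dtype = data_type or "reads"
    if name in table.tracks:
        raise ValueError(f"sample id collision: {name!r}")
    masked = ref_codes == GAP_CODE  # reference GAP == masked position
    track = track.copy()
    track[masked] = GAP_CODE
    tracks = dict(table.tracks)
    tracks[name] = track
    glens = dict(table.genome_lengths)
    if genome_length is not None:
        glens[name] = genome_length
    return AlleleTable(
        layout=table.layout,
        reference=table.reference,
        samples=table.samples + [name],
        data_types={**table.data_types, name: dtype},
        tracks=tracks,
        genome_lengths=glens,
        mask_fraction=table.mask_fraction,
    )


# ---------------------------------------------------------------------------
# persistence (text-only: header JSON + per-sample run-length-encoded tracks)


def save_table(table: AlleleTable, directory) -> None:
    d = Path(directory)
    (d / "tracks").mkdir(parents=True, exist_ok=True)
    header = {
        "contigs": [
            {"name": n, "length": ln}
            for n, ln in zip(table.layout.names, table.layout.lengths)
        ],
        "reference": table.reference,
        "samples": table.samples,
        "data_types": table.data_types,
        "genome_lengths": table.genome_lengths,
        "mask_fraction": table.mask_fraction,
    }
    (d / "allele_table.json").write_text(json.dumps(header, indent=1), encoding="utf-8")
    for s in table.samples:
        track = table.tracks[s]
        runs = _rle_encode(track)
        with open(d / "tracks" / f"{s}.rle.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(runs) + "\n")


def load_table(directory) -> AlleleTable:
    d = Path(directory)
    header = json.loads((d / "allele_table.json").read_text(encoding="utf-8"))
    layout = ReferenceLayout(
        names=[c["name"] for c in header["contigs"]],
        lengths=[c["length"] for c in header["contigs"]],
    )
    tracks = {}
    for s in header["samples"]:
        text = (d / "tracks" / f"{s}.rle.txt").read_text(encoding="utf-8")
        tracks[s] = _rle_decode(text.split(), layout.total)
    return AlleleTable(
        layout=layout,
        reference=header["reference"],
        samples=header["samples"],
        data_types=header["data_types"],
        tracks=tracks,
        genome_lengths={k: int(v) for k, v in header["genome_lengths"].items()},
        mask_fraction=header.get("mask_fraction", 0.0),
    )


def _rle_encode(track: np.ndarray) -> list[str]:
    changes = np.nonzero(np.diff(track))[0] + 1
    bounds = [0, *changes.tolist(), len(track)]
    return [
        f"{_TRACK_SYMBOLS[track[s]]}{e - s}" for s, e in zip(bounds[:-1], bounds[1:])
    ]


def _rle_decode(runs: list[str], total: int) -> np.ndarray:
    out = np.empty(total, dtype=np.uint8)
    pos = 0
    for run in runs:
        sym, n = run[0], int(run[1:])
        code = _TRACK_SYMBOLS.index(sym)
        out[pos : pos + n] = code
        pos += n
    if pos != total:
        raise ValueError("track length mismatch in RLE file")
    return out


# ---------------------------------------------------------------------------
# exports


def write_core_fasta(core: CoreAlignment, path, snps_only: bool = False) -> None:
    mat = core.snp_matrix() if snps_only else core.matrix
    with open(path, "w", encoding="utf-8") as fh:
        for i, s in enumerate(core.samples):
            fh.write(f">{s}\n")
            seq = decode(mat[i])
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")


def write_matrix(samples: list[str], matrix: np.ndarray, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\t" + "\t".join(samples) + "\n")
        for i, s in enumerate(samples):
            fh.write(s + "\t" + "\t".join(str(int(x)) for x in matrix[i]) + "\n")


def write_snp_positions(core: CoreAlignment, layout: ReferenceLayout, path) -> None:
    snp_pos = core.snp_positions()
    cidx, local = layout.global_to_local(snp_pos)
    mat = core.snp_matrix()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("contig\tpos\t" + "\t".join(core.samples) + "\n")
        for col, (ci, lp) in enumerate(zip(cidx, local)):
            bases = "\t".join(decode(mat[:, col]))
            fh.write(f"{layout.names[int(ci)]}\t{int(lp) + 1}\t{bases}\n")


def write_vcf(core: CoreAlignment, layout: ReferenceLayout, path) -> None:
    """Minimal multi-sample VCF text of the core SNP columns."""
    snp_pos = core.snp_positions()
    cidx, local = layout.global_to_local(snp_pos)
    mat = core.snp_matrix()
    ref_row = 0  # reference is always the first sample
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, ln in zip(layout.names, layout.lengths):
            fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(core.samples[1:])
            + "\n"
        )
        for col, (ci, lp) in enumerate(zip(cidx, local)):
            column = mat[:, col]
            ref_base = BASES[column[ref_row]]
            alts = sorted({BASES[b] for b in column if b != column[ref_row]})
            alt_index = {b: i + 1 for i, b in enumerate(alts)}
            gts = []
            for b in column[1:]:
                base = BASES[b]
                gts.append("0" if base == ref_base else str(alt_index[base]))
            fh.write(
                f"{layout.names[int(ci)]}\t{int(lp) + 1}\t.\t{ref_base}\t"
                f"{','.join(alts) or '.'}\t.\tPASS\tNS={len(column)}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
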