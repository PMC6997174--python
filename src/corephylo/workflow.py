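"""End-to-end orchestration: reference selection through tree and report.

``run_workflow`` drives the full pipeline from a :class:`~corephylo.io.RunConfig`:
sketch + reference selection, repeat masking, genome/contig alignment, read
mapping and consensus calling, allele-table fusion, aligned-fraction
filtering, core extraction, SNP matrices, annotation partitioning, the NJ
tree with bootstraps, and the optional gene selection screen.  Every stage's
outputs land under ``output_dir`` with a JSON manifest; a completed run is
skipped on rerun (same configuration) unless forced, and the persisted
allele table lets ``place_sample`` add one dataset without realignment.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import core as _core
from . import molevol as _mol
from . import phylo as _phylo
from . import readmap as _rm
from . import sketch as _sk
from . import wga as _wga
from .io import (
    ReadRecord,
    RunConfig,
    SequenceRecord,
    parse_fasta,
    parse_fastq,
    parse_gff3,
    write_fasta,
)


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class RunReport:
    """Run summary mirroring the pipeline's headline statistics table."""

    reference: str
    n_complete: int
    n_assembly: int
    n_reads: int
    average_genome_length: Optional[float]
    core_length: int
    percent_core: Optional[float]
    n_core_snps: int
    percent_core_snps: Optional[float]
    n_cds_snps: Optional[int]
    percent_cds_snps: Optional[float]
    dropped: dict[str, float] = field(default_factory=dict)
    wall_seconds: float = 0.0

    def to_tsv(self) -> str:
        def fmt(v) -> str:
            if v is None:
                return "NA"
            return str(v)

        rows = [
            ("reference", self.reference),
            ("genomes(complete/assembly/reads)",
             f"{self.n_complete}/{self.n_assembly}/{self.n_reads}"),
            ("average_genome_length", fmt(self.average_genome_length)),
            ("core_genome_length", self.core_length),
            ("percent_core", fmt(self.percent_core)),
            ("core_snps", self.n_core_snps),
            ("percent_core_snps", fmt(self.percent_core_snps)),
            ("cds_snps", fmt(self.n_cds_snps)),
            ("percent_cds_snps", fmt(self.percent_cds_snps)),
            ("dropped_samples", ",".join(sorted(self.dropped)) or "none"),
            ("wall_seconds", f"{self.wall_seconds:.1f}"),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def summarize(
    core_length: int,
    n_core_snps: int,
    n_cds_snps: Optional[int],
    genome_lengths: Sequence[int],
    counts: tuple[int, int, int] = (0, 0, 0),
    reference: str = "reference",
    dropped: Optional[dict[str, float]] = None,
) -> RunReport:
    """Build the summary report; percentages round half-up to one decimal.

    ``genome_lengths`` are the input sizes of complete and assembled samples
    only (read datasets have no meaningful genome length and are excluded
    from the average).  Zero denominators yield NA.
    """
    avg = float(np.mean(genome_lengths)) if len(genome_lengths) else None
    pct_core = _round1(100.0 * core_length / avg) if avg else None
    pct_snps = _round1(100.0 * n_core_snps / core_length) if core_length else None
    pct_cds = (
        _round1(100.0 * n_cds_snps / n_core_snps)
        if (n_cds_snps is not None and n_core_snps)
        else None
    )
    return RunReport(
        reference=reference,
        n_complete=counts[0],
        n_assembly=counts[1],
        n_reads=counts[2],
        average_genome_length=round(avg, 1) if avg is not None else None,
        core_length=core_length,
        percent_core=pct_core,
        n_core_snps=n_core_snps,
        percent_core_snps=pct_snps,
        n_cds_snps=n_cds_snps,
        percent_cds_snps=pct_cds,
        dropped=dropped or {},
    )


@dataclass
class SampleInput:
    name: str
    data_type: str  # complete | contig | reads
    genome: Optional[list[SequenceRecord]] = None
    reads: Optional[list[ReadRecord]] = None


class WorkflowError(RuntimeError):
    def __init__(self, message: str, exit_code: int = 2):
        super().__init__(message)
        self.exit_code = exit_code


class _Log:
    def __init__(self, path: Optional[Path]):
        self.path = path
        self.events: list[dict] = []

    def event(self, stage: str, **fields) -> None:
        entry = {"t": round(time.time(), 3), "stage": stage, **fields}
        self.events.append(entry)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry) + "\n")


def load_inputs(cfg: RunConfig, base_dir: Optional[Path] = None) -> list[SampleInput]:
    base = Path(base_dir) if base_dir else Path(".")
    inputs = []
    for name, dtype in cfg.data_types.items():
        paths = [base / p for p in cfg.sample_paths[name]]
        if dtype == "reads":
            reads = parse_fastq(paths[0], paths[1] if len(paths) > 1 else None)
            inputs.append(SampleInput(name=name, data_type=dtype, reads=reads))
        else:
            inputs.append(
                SampleInput(name=name, data_type=dtype, genome=parse_fasta(paths[0]))
            )
    return inputs


def _config_key(cfg: RunConfig) -> str:
    d = {k: v for k, v in vars(cfg).items() if k not in ("output_dir",)}
    return json.dumps(d, sort_keys=True, default=str)


def run_workflow(
    cfg: RunConfig,
    inputs: Optional[list[SampleInput]] = None,
    annotation=None,
    force: bool = False,
    base_dir: Optional[Path] = None,
) -> RunReport:
    """Execute the full pipeline and write all artifacts under output_dir."""
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        if manifest.get("config_key") == _config_key(cfg) and manifest.get("completed"):
            report = _report_from_json(manifest["report"])
            return report

    log = _Log(out / "run_log.jsonl")
    if (out / "run_log.jsonl").exists():
        (out / "run_log.jsonl").unlink()

    if inputs is None:
        inputs = load_inputs(cfg, base_dir)
    if len(inputs) < 2:
        raise WorkflowError("need at least two samples", 2)
    by_name = {s.name: s for s in inputs}
    if annotation is None and cfg.annotation:
        annotation = parse_gff3(
            (Path(base_dir) if base_dir else Path(".")) / cfg.annotation
        )

    # --- reference selection -------------------------------------------------
    complete = [s.name for s in inputs if s.data_type == "complete"]
    if cfg.reference_mode == "user_specified":
        if cfg.reference_id not in by_name:
            raise WorkflowError(f"reference {cfg.reference_id!r} not among samples", 2)
        reference = cfg.reference_id
    else:
        if not complete:
            raise WorkflowError("no complete genome eligible as reference", 2)
        sketches = {}
        for s in inputs:
            records = s.genome
            if records is None:
                records = [
                    SequenceRecord(id=r.id, residues=r.residues) for r in s.reads or []
                ]
            sketches[s.name] = _sk.build_sketch(records)
        reference = _sk.select_reference(
            sketches, mode=cfg.reference_mode, complete_ids=complete, seed=cfg.seed
        )
        _sk.write_sketches(sketches, out / "sketches.tsv")
    log.event("reference", reference=reference)
    ref_input = by_name[reference]
    if ref_input.genome is None:
        raise WorkflowError("reference sample must be a genome, not reads", 2)
    ref = ref_input.genome
    write_fasta(ref, out / "reference.fasta")

    # --- repeat masking ------------------------------------------------------
    mask = _wga.mask_repeats(ref)
    ref_lengths = {r.id: len(r.residues) for r in ref}
    log.event("mask", masked_fraction=round(mask.masked_fraction(ref_lengths), 6))

    # --- alignment / mapping -------------------------------------------------
    pairwise = []
    tracks = []
    index = None
    for s in inputs:
        if s.name == reference:
            continue
        if s.data_type in ("complete", "contig"):
            res = _wga.align_pair(ref, s.genome, s.name, mask)
            pairwise.append(res)
            _wga.write_snp_report(res, out / f"{s.name}.snps.tsv")
            _wga.write_gap_report(res, out / f"{s.name}.gaps.tsv")
            log.event(
                "align", sample=s.name, snps=len(res.snps),
                aligned_fraction=round(res.aligned_fraction, 6),
            )
        else:
            if index is None:
                index = _rm.build_index(ref)
            pile, n_mapped, n_total = _rm.map_sample(s.reads, index, ref)
            track = _rm.call_consensus(
                pile, cfg.min_depth, cfg.min_allele_fraction, s.name
            )
            tracks.append(track)
            log.event("map", sample=s.name, mapped=n_mapped, total=n_total)

    # --- allele table + filtering -------------------------------------------
    glens = {
        s.name: sum(len(r.residues) for r in s.genome)
        for s in inputs
        if s.genome is not None
    }
    table = _core.build_allele_table(
        ref,
        mask,
        pairwise,
        tracks,
        reference_name=reference,
        data_types={s.name: s.data_type for s in inputs},
        genome_lengths=glens,
    )
    table, dropped = _core.filter_samples(table, cfg.aligned_fraction_cutoff)
    for name, frac in dropped.items():
        log.event("drop", sample=name, aligned_fraction=round(frac, 6))
    _core.save_table(table, out / "allele_table")

    # --- core + matrices -----------------------------------------------------
    cds = _core.cds_track(table.layout, annotation) if annotation else None
    core = _core.compute_core(table, cds_positions=cds)
    if core.length == 0:
        log.event("core", warning="empty core alignment")
    matrices = _core.pairwise_matrices(core)
    _core.write_core_fasta(core, out / "core.fasta")
    _core.write_core_fasta(core, out / "coreSNP.fasta", snps_only=True)
    _core.write_matrix(matrices.samples, matrices.core, out / "coreMatrix.txt")
    if matrices.cds is not None:
        _core.write_matrix(matrices.samples, matrices.cds, out / "CDSMatrix.txt")
        _core.write_matrix(
            matrices.samples, matrices.intergenic, out / "intergenicMatrix.txt"
        )
    _core.write_snp_positions(core, table.layout, out / "snp_positions.tsv")
    _core.write_vcf(core, table.layout, out / "core_snps.vcf")
    _phylo.write_phylip(core, out / "core.phy")
    log.event("core", length=core.length, snps=core.n_snps)

    # --- annotation of SNPs --------------------------------------------------
    n_cds_snps = None
    genes = None
    if annotation:
        genes = _mol.genes_from_gff(annotation)
        snp_records = _snps_vs_reference(core, table)
        ref_seqs = {r.id: r.residues for r in ref}
        annotations = _mol.classify_snps(
            snp_records, genes, ref_seqs, cfg.genetic_code_table
        )
        _mol.write_snp_annotation(annotations, out / "snp_annotation.tsv")
        if cds is not None:
            n_cds_snps = int(cds[core.snp_positions()].sum()) if core.n_snps else 0

    # --- tree ----------------------------------------------------------------
    tree = None
    if core.length == 0 or len(core.samples) < 2:
        log.event("tree", skipped="empty core")
    elif cfg.tree_method == "nj":
        if cfg.bootstrap_reps > 0 and len(core.samples) >= 4:
            tree = _phylo.bootstrap_support(core, cfg.bootstrap_reps, cfg.seed)
        else:
            tree = _phylo.nj_tree(_phylo.distance_matrix(core, "jc"))
        if tree.clamped_branches:
            log.event("tree", clamped_branches=tree.clamped_branches)
        (out / "tree.nwk").write_text(
            _phylo.write_newick(tree) + "\n", encoding="utf-8"
        )
    else:
        log.event("tree", external="core.fasta/core.phy exported for external ML")

    # --- selection screen ----------------------------------------------------
    if cfg.selection_screen and genes:
        results, rejections = _mol.screen_genes(
            table, genes, cfg.genetic_code_table, samples=core.samples
        )
        _mol.write_gene_selection(results, out / "gene_selection.tsv")
        log.event(
            "selection", tested=len(results), rejected=len(rejections),
            positive=sum(1 for r in results if r.classification == "positive"),
        )

    # --- report --------------------------------------------------------------
    counts = (
        sum(1 for s in table.samples if table.data_types[s] == "complete"),
        sum(1 for s in table.samples if table.data_types[s] == "contig"),
        sum(1 for s in table.samples if table.data_types[s] == "reads"),
    )
    genome_lengths = [
        table.genome_lengths[s]
        for s in table.samples
        if table.data_types[s] in ("complete", "contig") and s in table.genome_lengths
    ]
    report = summarize(
        core.length,
        core.n_snps,
        n_cds_snps,
        genome_lengths,
        counts,
        reference=reference,
        dropped=dropped,
    )
    report.wall_seconds = time.time() - t0
    (out / "report.tsv").write_text(report.to_tsv(), encoding="utf-8")
    manifest = {
        "config_key": _config_key(cfg),
        "completed": True,
        "reference": reference,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        "report": _report_to_json(report),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return report


def _snps_vs_reference(core: _core.CoreAlignment, table: _core.AlleleTable):
    """Per-sample SNP records (contig, pos0, ref, alt, sample) at core SNP columns."""
    from ._seq import BASES

    layout = table.layout
    snp_pos = core.snp_positions()
    if not len(snp_pos):
        return []
    cidx, local = layout.global_to_local(snp_pos)
    mat = core.snp_matrix()
    ref_row = core.samples.index(table.reference)
    out = []
    for col in range(mat.shape[1]):
        contig = layout.names[int(cidx[col])]
        pos = int(local[col])
        rb = BASES[mat[ref_row, col]]
        for row, sample in enumerate(core.samples):
            if row == ref_row or mat[row, col] == mat[ref_row, col]:
                continue
            out.append((contig, pos, rb, BASES[mat[row, col]], sample))
    return out


def _report_to_json(r: RunReport) -> dict:
    return {k: v for k, v in vars(r).items()}


def _report_from_json(d: dict) -> RunReport:
    return RunReport(**d)


# ---------------------------------------------------------------------------
# incremental placement


def place_sample(
    run_dir,
    new_input: SampleInput,
    cfg: Optional[RunConfig] = None,
) -> RunReport:
    """Add one dataset to a completed run without realigning existing samples.

    The stored allele table and reference are reused; the result equals a
    from-scratch run over the enlarged sample set.
    """
    run = Path(run_dir)
    if not (run / "allele_table").exists():
        raise WorkflowError("run directory lacks a persisted allele table", 2)
    cfg = cfg or RunConfig()
    table = _core.load_table(run / "allele_table")
    ref = parse_fasta(run / "reference.fasta")
    if [r.id for r in ref] != table.layout.names or [
        len(r.residues) for r in ref
    ] != table.layout.lengths:
        raise WorkflowError("stored reference does not match allele table layout", 2)
    mask = _wga.mask_repeats(ref)
    if new_input.data_type in ("complete", "contig"):
        res = _wga.align_pair(ref, new_input.genome, new_input.name, mask)
        glen = sum(len(r.residues) for r in new_input.genome)
        table2 = _core.add_sample(table, res, new_input.data_type, glen)
        frac = res.aligned_fraction
    else:
        index = _rm.build_index(ref)
        pile, _, _ = _rm.map_sample(new_input.reads, index, ref)
        track = _rm.call_consensus(
            pile, cfg.min_depth, cfg.min_allele_fraction, new_input.name
        )
        table2 = _core.add_sample(table, track, "reads")
        frac = table2.aligned_fraction(new_input.name)
    if frac < cfg.aligned_fraction_cutoff:
        raise WorkflowError(
            f"{new_input.name!r} aligned fraction {frac:.3f} below cutoff "
            f"{cfg.aligned_fraction_cutoff}",
            3,
        )
    out = run
    _core.save_table(table2, out / "allele_table")
    core = _core.compute_core(table2)
    matrices = _core.pairwise_matrices(core)
    _core.write_core_fasta(core, out / "core.fasta")
    _core.write_core_fasta(core, out / "coreSNP.fasta", snps_only=True)
    _core.write_matrix(matrices.samples, matrices.core, out / "coreMatrix.txt")
    if core.length and len(core.samples) >= 3:
        if cfg.bootstrap_reps > 0 and len(core.samples) >= 4:
            tree = _phylo.bootstrap_support(core, cfg.bootstrap_reps, cfg.seed)
        else:
            tree = _phylo.nj_tree(_phylo.distance_matrix(core, "jc"))
        (out / "tree.nwk").write_text(_phylo.write_newick(tree) + "\n", encoding="utf-8")
    counts = (
        sum(1 for s in table2.samples if table2.data_types[s] == "complete"),
        sum(1 for s in table2.samples if table2.data_types[s] == "contig"),
        sum(1 for s in table2.samples if table2.data_types[s] == "reads"),
    )
    genome_lengths = [
        table2.genome_lengths[s]
        for s in table2.samples
        if table2.data_types[s] in ("complete", "contig") and s in table2.genome_lengths
    ]
    report = summarize(
        core.length, core.n_snps, None, genome_lengths, counts,
        reference=table2.reference,
    )
    (out / "report.tsv").write_text(report.to_tsv(), encoding="utf-8")
    return report
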