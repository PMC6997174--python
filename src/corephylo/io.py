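"""Readers and writers for FASTA/FASTQ/GFF3 and the run control file.

FASTA and FASTQ records pass through Biopython's parsers and are then
validated against the pipeline's stricter contracts (IUPAC-only residues,
quality/residue length agreement).  GFF3 is read by a direct line parser
because only coordinate-bearing feature lines are consumed.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Union

from Bio import SeqIO

from ._seq import IUPAC

Stream = Union[str, Path, IO[str]]


@dataclass
class SequenceRecord:
    """One FASTA sequence: a chromosome, replicon, or contig."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred quality scores."""

    id: str
    residues: str
    qualities: list[int]
    mate: int = 0  # 0 = unpaired/first file, 1 = second file


@dataclass
class FeatureRecord:
    """One coordinate-bearing GFF3 line (1-based inclusive coordinates)."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str
    phase: Optional[int]
    attributes: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# run configuration


VALID_REFERENCE_MODES = ("user_specified", "random", "minhash")
VALID_TREE_METHODS = ("nj", "external")
VALID_SCOPES = ("all", "cds_only")


@dataclass
class RunConfig:
    """Parameters of one workflow run, as read from the control file.

    Defaults: keep all samples (``aligned_fraction_cutoff=0``), call a base
    from reads only at >=5x depth with >=60% agreement, 100 bootstrap
    replicates, bacterial genetic code (NCBI table 11).
    """

    reference_mode: str = "minhash"
    reference_id: Optional[str] = None
    data_types: dict[str, str] = field(default_factory=dict)  # sample -> complete|contig|reads
    sample_paths: dict[str, tuple[str, ...]] = field(default_factory=dict)
    annotation: Optional[str] = None
    aligned_fraction_cutoff: float = 0.0
    min_depth: int = 5
    min_allele_fraction: float = 0.6
    tree_method: str = "nj"
    bootstrap_reps: int = 100
    seed: int = 42
    genetic_code_table: int = 11
    analysis_scope: str = "all"
    selection_screen: bool = False
    output_dir: str = "corephylo_out"

    def validate(self) -> None:
        if self.reference_mode not in VALID_REFERENCE_MODES:
            raise ValueError(f"unknown reference mode {self.reference_mode!r}")
        if self.reference_mode == "user_specified" and not self.reference_id:
            raise ValueError("reference_id required when reference mode is user_specified")
        if not 0.0 <= self.aligned_fraction_cutoff <= 1.0:
            raise ValueError("aligned_fraction_cutoff must be in [0, 1]")
        if not 0.5 < self.min_allele_fraction <= 1.0:
            raise ValueError(
                "min_allele_fraction must be in (0.5, 1] so at most one allele can qualify"
            )
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")
        if self.tree_method not in VALID_TREE_METHODS:
            raise ValueError(f"unknown tree method {self.tree_method!r}")
        if self.analysis_scope not in VALID_SCOPES:
            raise ValueError(f"unknown analysis scope {self.analysis_scope!r}")


# ---------------------------------------------------------------------------
# parsing helpers


def _as_handle(stream: Stream) -> IO[str]:
    """Plain ``str`` is literal text; use ``Path`` (or a handle) for files."""
    if isinstance(stream, Path):
        return open(stream, "r", encoding="utf-8")
    if isinstance(stream, str):
        return _io.StringIO(stream)
    return stream


def _validate_residues(seq: str, record_id: str) -> str:
    seq = seq.upper()
    for offset, ch in enumerate(seq):
        if ch not in IUPAC:
            raise ValueError(
                f"record {record_id!r}: non-IUPAC character {ch!r} at offset {offset}"
            )
    return seq


def parse_fasta(stream: Stream) -> list[SequenceRecord]:
    """Parse FASTA text into validated, uppercase SequenceRecords."""
    handle = _as_handle(stream)
    records = []
    for rec in SeqIO.parse(handle, "fasta"):
        seq = _validate_residues(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=seq, description=desc))
    if not records:
        raise ValueError("no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], stream: Stream, width: int = 70) -> None:
    own = isinstance(stream, (str, Path))
    handle = open(stream, "w", encoding="utf-8") if own else stream
    try:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")
    finally:
        if own:
            handle.close()


def parse_fastq(stream: Stream, mate_stream: Optional[Stream] = None) -> list[ReadRecord]:
    """Parse single or paired FASTQ (Phred+33) into a flat list of reads.

    Paired inputs are flattened with ``mate`` recording the file of origin.
    """
    reads: list[ReadRecord] = []
    for mate, src in enumerate(s for s in (stream, mate_stream) if s is not None):
        handle = _as_handle(src)
        for rec in SeqIO.parse(handle, "fastq"):
            seq = str(rec.seq).upper()
            quals = rec.letter_annotations["phred_quality"]
            if len(seq) != len(quals):  # pragma: no cover - biopython pre-checks
                raise ValueError(f"read {rec.id!r}: residue/quality length mismatch")
            for offset, ch in enumerate(seq):
                if ch not in "ACGTN":
                    raise ValueError(
                        f"read {rec.id!r}: invalid character {ch!r} at offset {offset}"
                    )
            reads.append(ReadRecord(id=rec.id, residues=seq, qualities=list(quals), mate=mate))
    return reads


def write_fastq(reads: Iterable[ReadRecord], stream: Stream) -> None:
    own = isinstance(stream, (str, Path))
    handle = open(stream, "w", encoding="utf-8") if own else stream
    try:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            handle.write(f"@{r.id}\n{r.residues}\n+\n{qual}\n")
    finally:
        if own:
            handle.close()


def parse_gff3(stream: Stream) -> list[FeatureRecord]:
    """Parse GFF3 feature lines; comments and the FASTA trailer are skipped."""
    handle = _as_handle(stream)
    features: list[FeatureRecord] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            if line.startswith("##FASTA"):
                break
            continue
        if line.startswith(">"):
            break  # FASTA trailer without ##FASTA directive
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"line {lineno}: expected 9 tab-separated fields")
        seqid, _source, ftype, start_s, end_s, _score, strand, phase_s, attr_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer coordinates") from exc
        if start < 1 or start > end:
            raise ValueError(f"line {lineno}: invalid interval {start}..{end}")
        phase: Optional[int] = int(phase_s) if phase_s in ("0", "1", "2") else None
        if ftype == "CDS" and phase is None:
            raise ValueError(f"line {lineno}: CDS feature without phase")
        attributes: dict[str, str] = {}
        for item in attr_s.split(";"):
            item = item.strip()
            if item and "=" in item:
                key, _, value = item.partition("=")
                attributes[key] = value
        features.append(
            FeatureRecord(
                seqid=seqid,
                type=ftype,
                start=start,
                end=end,
                strand=strand if strand in "+-" else "+",
                phase=phase,
                attributes=attributes,
            )
        )
    return features


# ---------------------------------------------------------------------------
# control file

_SCALAR_KEYS = {
    "reference",
    "cutoff",
    "min_depth",
    "min_allele_fraction",
    "tree",
    "bootstrap",
    "seed",
    "code_table",
    "scope",
    "selection",
    "outdir",
    "annotation",
}
_SAMPLE_KEYS = {"genome": "complete", "contigs": "contig", "reads": "reads"}


def _parse_sample_value(value: str) -> tuple[str, tuple[str, ...]]:
    """``NAME=path[,path2]`` or a bare path (name = file stem)."""
    if "=" in value:
        name, _, paths = value.partition("=")
        name = name.strip()
    else:
        paths = value
        name = Path(value.split(",")[0].strip()).stem
    path_tuple = tuple(p.strip() for p in paths.split(",") if p.strip())
    if not name or not path_tuple:
        raise ValueError(f"malformed sample declaration {value!r}")
    return name, path_tuple


def parse_control_file(stream: Stream) -> RunConfig:
    """Parse ``key = value`` control-file text into a validated RunConfig.

    Unknown keys warn rather than fail so control files stay forward
    compatible; out-of-range values are rejected.
    """
    handle = _as_handle(stream)
    cfg = RunConfig()
    for lineno, raw in enumerate(handle, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if key in _SAMPLE_KEYS:
            name, paths = _parse_sample_value(value)
            if name in cfg.data_types:
                raise ValueError(f"line {lineno}: duplicate sample {name!r}")
            cfg.data_types[name] = _SAMPLE_KEYS[key]
            cfg.sample_paths[name] = paths
            continue
        if key not in _SCALAR_KEYS:
            warnings.warn(f"control file line {lineno}: unknown key {key!r} ignored")
            continue
        try:
            if key == "reference":
                if value in ("minhash", "random"):
                    cfg.reference_mode = value
                else:
                    cfg.reference_mode = "user_specified"
                    cfg.reference_id = value
            elif key == "cutoff":
                cfg.aligned_fraction_cutoff = float(value)
            elif key == "min_depth":
                cfg.min_depth = int(value)
            elif key == "min_allele_fraction":
                cfg.min_allele_fraction = float(value)
            elif key == "tree":
                cfg.tree_method = value
            elif key == "bootstrap":
                cfg.bootstrap_reps = int(value)
            elif key == "seed":
                cfg.seed = int(value)
            elif key == "code_table":
                cfg.genetic_code_table = int(value)
            elif key == "scope":
                cfg.analysis_scope = value
            elif key == "selection":
                cfg.selection_screen = value.lower() in ("on", "true", "yes", "1")
            elif key == "outdir":
                cfg.output_dir = value
            elif key == "annotation":
                cfg.annotation = value
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad value for {key!r}: {exc}") from exc
    cfg.validate()
    return cfg
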