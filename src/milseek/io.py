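"""File formats, run configuration and stage logging.

All sequence coordinates are 0-based half-open internally; conversion to the
1-based inclusive convention of GFF3 happens only at file boundaries.  Small-RNA
and transcript sequences are held as RNA (``T`` mapped to ``U`` on input),
genome scaffolds as DNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import yaml
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .context import GeneModel
    from .discover import ConservedHit, MilRnaCandidate


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ParameterError(ValueError):
    """A parameter value violates its contract."""


# ---------------------------------------------------------------------------
# sequence alphabet helpers

_RNA_ALPHABET = frozenset("ACGUN")
_DNA_ALPHABET = frozenset("ACGTN")
_RC_DNA = str.maketrans("ACGTN", "TGCAN")
_RC_RNA = str.maketrans("ACGUN", "UGCAN")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RC_RNA)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_RC_DNA)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional Phred quality scores."""

    id: str
    sequence: str
    quality: list[int] | None = None
    moltype: str = "RNA"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        alphabet = _RNA_ALPHABET if self.moltype == "RNA" else _DNA_ALPHABET
        bad = set(self.sequence) - alphabet
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters {sorted(bad)} not in "
                f"{self.moltype} alphabet"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, serializable to YAML.

    ``fc_down`` defaults to ``1 / fc_up`` when not set explicitly.
    """

    # read preprocessing
    min_read_len: int = 18
    max_read_len: int = 35
    min_mean_q: float = 20.0
    adapter_seed_len: int = 7
    adapter_seed_mm: int = 1
    drop_untrimmed: bool = False
    # folding
    min_loop: int = 3
    stem_gap_max: int = 3
    fold_max_len: int = 2000
    fold_window: int = 700
    fold_step: int = 350
    # discovery
    mismatch_max: int = 3          # "fewer than 4" mismatches
    stem_overlap_frac: float = 0.6
    duplex_overlap_frac: float = 0.5
    duplex_slack_nt: int = 3
    locus_cluster_nt: int = 2
    accession_prefix: str = "aci-milR"
    conserved_mm_max: int = 2
    conserved_min_overlap: int = 18
    conserved_stem_frac: float = 0.5
    # differential expression
    fdr_threshold: float = 0.05
    fc_up: float = 2.0
    fc_down: float | None = None
    min_specific: int = 5
    exact_test_below: int = 30
    # target prediction
    expectation_max: float = 4.0
    gap_max: int = 2
    core_start: int = 2
    core_end: int = 13
    translation_start: int = 9
    translation_end: int = 11
    # genome context / k-mer estimator
    kmer_k: int = 17
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ParameterError("fdr_threshold must lie in (0, 1)")
        if self.mismatch_max < 0:
            raise ParameterError("mismatch_max must be >= 0")
        if self.min_read_len < 1 or self.max_read_len < self.min_read_len:
            raise ParameterError("read length bounds inconsistent")
        if self.fc_up <= 1.0:
            raise ParameterError("fc_up must exceed 1")
        if self.fc_down is None:
            self.fc_down = 1.0 / self.fc_up
        if self.min_loop < 1:
            raise ParameterError("min_loop must be >= 1")
        if self.expectation_max < 0:
            raise ParameterError("expectation_max must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def replace(self, **overrides) -> "RunConfig":
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update(overrides)
        return RunConfig(**data)


# ---------------------------------------------------------------------------
# logging

def get_logger(name: str = "milseek") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def log_stage(stage: str, n_in: int, n_out: int) -> None:
    """One structured line per pipeline stage: inputs in, outputs out."""
    get_logger(f"milseek.{stage}").info("stage=%s n_in=%d n_out=%d", stage, n_in, n_out)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path, moltype: str = "RNA") -> list[SequenceRecord]:
    """Read a FASTA file, normalizing T/U to the requested moltype.

    Raises :class:`FormatError` on text before the first header, an empty
    sequence, or a duplicated id.
    """
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path.name}:{lineno}: expected FASTA header")
        break
    convert = to_rna if moltype == "RNA" else to_dna
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path.name}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path.name}: record {rec.id!r} has empty sequence")
        records.append(SequenceRecord(rec.id, convert(seq), moltype=moltype))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_fastq(path: str | Path, moltype: str = "RNA") -> list[SequenceRecord]:
    """Read Phred+33 FASTQ; quality decoded to integer scores."""
    path = Path(path)
    convert = to_rna if moltype == "RNA" else to_dna
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            if rec.id in seen:
                raise FormatError(f"{path.name}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(
                SequenceRecord(
                    rec.id,
                    convert(str(rec.seq)),
                    quality=list(rec.letter_annotations["phred_quality"]),
                    moltype=moltype,
                )
            )
    except ValueError as exc:  # biopython signals malformed records this way
        raise FormatError(f"{path.name}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else [40] * len(rec)
            qline = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qline}\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> "list[GeneModel]":
    """Parse gene/mRNA/exon features into :class:`~milseek.context.GeneModel`.

    Coordinates are converted from GFF3 1-based inclusive to internal 0-based
    half-open.  An exon whose Parent chain does not reach a gene is an error.
    """
    import gffutils

    from .context import GeneModel

    path = Path(path)
    lines = path.read_text().splitlines()
    content = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not content:
        return []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise FormatError(f"{path.name}:{lineno}: expected 9 columns")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: non-integer coordinates") from exc
        if end < start:
            raise FormatError(f"{path.name}:{lineno}: end < start")

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene_exons: dict[str, list[tuple[int, int]]] = {}
    gene_meta: dict[str, tuple[str, str]] = {}
    gene_order: list[str] = []
    for gene in db.features_of_type("gene"):
        gene_meta[gene.id] = (gene.seqid, gene.strand)
        gene_exons[gene.id] = []
        gene_order.append(gene.id)
    for exon in db.features_of_type("exon"):
        parents = [p for p in db.parents(exon.id) if p.featuretype == "gene"]
        if not parents:
            raise FormatError(
                f"{path.name}: exon {exon.id!r} has no resolvable gene parent"
            )
        for parent in parents:
            gene_exons[parent.id].append((exon.start - 1, exon.end))
    models = []
    for gid in gene_order:
        scaffold, strand = gene_meta[gid]
        exons = sorted(gene_exons[gid])
        models.append(GeneModel(gene_id=gid, scaffold=scaffold, strand=strand, exons=exons))
    return models


def write_gff3(genes: "Sequence[GeneModel]", path: str | Path) -> None:
    """Write gene models as gene/mRNA/exon features, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            g0 = gene.exons[0][0]
            g1 = gene.exons[-1][1]
            base = (gene.scaffold, "milseek", g0 + 1, g1)
            fh.write(
                f"{gene.scaffold}\tmilseek\tgene\t{g0 + 1}\t{g1}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            fh.write(
                f"{gene.scaffold}\tmilseek\tmRNA\t{g0 + 1}\t{g1}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}.t1;Parent={gene.gene_id}\n"
            )
            for i, (s, e) in enumerate(gene.exons, start=1):
                fh.write(
                    f"{gene.scaffold}\tmilseek\texon\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id}.e{i};"
                    f"Parent={gene.gene_id}.t1\n"
                )


# ---------------------------------------------------------------------------
# curated reference tables (shipped with the package)

_DATA_DIR = Path(__file__).parent / "data"
REFERENCE_CANDIDATES_TSV = _DATA_DIR / "aci_milrna_candidates.tsv"
REFERENCE_CONSERVED_TSV = _DATA_DIR / "aci_conserved_mirna.tsv"


def load_reference_candidates(path: str | Path | None = None) -> "list[MilRnaCandidate]":
    """Load the curated A. cinnamomea milRNA candidate table.

    Rows carry a per-library flag (M/F/B) and a total read count; totals for
    B rows are split across libraries so the class invariant holds.
    """
    import pandas as pd

    from .discover import MilRnaCandidate

    path = Path(path) if path is not None else REFERENCE_CANDIDATES_TSV
    df = pd.read_csv(path, sep="\t", dtype={"reads": int})
    expected = ["lib", "accession", "contig_id", "sequence", "reads"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    out: list[MilRnaCandidate] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.lib not in {"M", "F", "B"}:
            raise FormatError(f"{path}: bad lib flag {row.lib!r}")
        if row.accession in seen:
            raise FormatError(f"{path}: duplicate accession {row.accession!r}")
        seen.add(row.accession)
        seq = to_rna(row.sequence)
        if set(seq) - _RNA_ALPHABET:
            raise FormatError(f"{path}: bad sequence for {row.accession!r}")
        reads = int(row.reads)
        if reads < 1:
            raise FormatError(f"{path}: non-positive read count for {row.accession!r}")
        if row.lib == "M":
            c_my, c_fb = reads, 0
        elif row.lib == "F":
            c_my, c_fb = 0, reads
        else:
            c_my, c_fb = reads - reads // 2, reads // 2
        out.append(
            MilRnaCandidate(
                accession=row.accession,
                precursor_id=row.contig_id,
                contig_id=row.contig_id,
                arm=None,
                role="milR",
                sequence=seq,
                start=None,
                mismatches=None,
                count_MY=c_my,
                count_FB=c_fb,
            )
        )
    return out


def load_reference_conserved(path: str | Path | None = None) -> "list[ConservedHit]":
    """Load and validate the curated conserved-miRNA table."""
    import pandas as pd

    from .discover import ConservedHit

    path = Path(path) if path is not None else REFERENCE_CONSERVED_TSV
    df = pd.read_csv(path, sep="\t", dtype={"reads": int})
    expected = ["lib", "name", "sequence", "reads"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    out: list[ConservedHit] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.lib not in {"M", "F", "B"}:
            raise FormatError(f"{path}: bad lib flag {row.lib!r}")
        if row.name in seen:
            raise FormatError(f"{path}: duplicate miRNA name {row.name!r}")
        seen.add(row.name)
        seq = to_rna(row.sequence)
        if set(seq) - _RNA_ALPHABET:
            raise FormatError(f"{path}: bad sequence for {row.name!r}")
        if int(row.reads) < 1:
            raise FormatError(f"{path}: non-positive read count for {row.name!r}")
        out.append(
            ConservedHit(
                sequence=seq, ref_name=row.name, mismatches=0, stem_located=True
            )
        )
    return out
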