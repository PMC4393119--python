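"""Genomic placement of precursors, context classification and the k-mer
genome-size estimator."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import ParameterError, SequenceRecord, revcomp_dna, to_dna


class EstimationError(ValueError):
    """The k-mer histogram has no usable coverage peak."""


@dataclass
class GeneModel:
    """A gene as an ordered set of exon intervals (0-based half-open)."""

    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ParameterError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if not self.exons:
            raise ParameterError(f"gene {self.gene_id!r}: no exons")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ParameterError(f"gene {self.gene_id!r}: empty exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ParameterError(f"gene {self.gene_id!r}: overlapping exons")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class GenomicPlacement:
    precursor_id: str
    scaffold: str
    start: int
    strand: str
    length: int
    context: str | None = None
    multi_hit: bool = False

    @property
    def end(self) -> int:
        return self.start + self.length


def place_on_genome(
    precursor: SequenceRecord, scaffolds: Sequence[SequenceRecord]
) -> GenomicPlacement | None:
    """Exact-match search for a precursor (forward and reverse complement).

    Multiple exact hits resolve to the first by (scaffold id, position) with a
    ``multi_hit`` flag set.
    """
    query = to_dna(precursor.sequence)
    rc = revcomp_dna(query)
    hits: list[tuple[str, int, str]] = []
    for scaf in sorted(scaffolds, key=lambda s: s.id):
        genome = to_dna(scaf.sequence)
        for strand, needle in (("+", query), ("-", rc)):
            pos = genome.find(needle)
            while pos != -1:
                hits.append((scaf.id, pos, strand))
                pos = genome.find(needle, pos + 1)
    if not hits:
        return None
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    scaffold, start, strand = hits[0]
    return GenomicPlacement(
        precursor_id=precursor.id,
        scaffold=scaffold,
        start=start,
        strand=strand,
        length=len(query),
        multi_hit=len(hits) > 1,
    )


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def classify_context(placement: GenomicPlacement, genes: Iterable[GeneModel]) -> str:
    """Classify a placement as exon_antisense / exon_sense / intron / intergenic.

    Overlap means at least one shared base; exon overlap takes precedence over
    intron, and strand is judged relative to the placement.
    """
    exon_sense = exon_anti = intron = False
    for gene in genes:
        if gene.scaffold != placement.scaffold:
            continue
        for s, e in gene.exons:
            if _overlaps(placement.start, placement.end, s, e):
                if gene.strand == placement.strand:
                    exon_sense = True
                else:
                    exon_anti = True
        for s, e in gene.introns:
            if _overlaps(placement.start, placement.end, s, e):
                intron = True
    if exon_anti:
        return "exon_antisense"
    if exon_sense:
        return "exon_sense"
    if intron:
        return "intron"
    return "intergenic"


def nearest_gene(
    placement: GenomicPlacement, genes: Iterable[GeneModel]
) -> tuple[str | None, int | None]:
    """Nearest gene on the placement's scaffold and its distance (0 if
    overlapping)."""
    best: tuple[int, str] | None = None
    for gene in genes:
        if gene.scaffold != placement.scaffold:
            continue
        g0, g1 = gene.span
        if _overlaps(placement.start, placement.end, g0, g1):
            dist = 0
        elif g1 <= placement.start:
            dist = placement.start - g1
        else:
            dist = g0 - placement.end
        if best is None or (dist, gene.gene_id) < best:
            best = (dist, gene.gene_id)
    if best is None:
        return None, None
    return best[1], best[0]


def kmer_genome_size(
    reads: Sequence[SequenceRecord], k: int = 17, error_shoulder: int = 2
) -> float:
    """Estimate genome size from the k-mer multiplicity histogram.

    The estimate is ``total k-mers / d`` where ``d`` is the modal k-mer
    multiplicity above the low-multiplicity error shoulder.  K-mers are
    counted canonically (lexicographic minimum of a k-mer and its reverse
    complement).
    """
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ParameterError("k must be odd and within [11, 31]")
    if not reads:
        raise EstimationError("no reads supplied")
    counts: Counter[str] = Counter()
    total = 0
    for read in reads:
        seq = to_dna(read.sequence)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            canon = min(kmer, revcomp_dna(kmer))
            counts[canon] += 1
            total += 1
    hist: Counter[int] = Counter(counts.values())
    peak_candidates = {m: c for m, c in hist.items() if m > error_shoulder}
    if not peak_candidates:
        raise EstimationError("no multiplicity peak above the error shoulder")
    depth = max(peak_candidates, key=lambda m: (peak_candidates[m], -m))
    return total / depth
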