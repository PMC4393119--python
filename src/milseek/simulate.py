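"""Synthetic toy study generator.

Produces a genome with gene models, transcript contigs carrying planted
hairpin precursors, two small-RNA libraries (MY and FB) with 3' adapters and
optional substitution noise, a mature-miRNA reference, a unigene count table
and a truth table — so every downstream stage has a known answer.

Planted milR lengths peak at 23 nt (range 20-26) and their 5' nucleotide is
biased to U, mirroring the length and 5'-end profiles the pipeline is meant
to report.  Background reads are drawn uniformly at random so that truth
evaluation stays unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import fold as fold_mod
from .discover import MilRnaCandidate, ReadPlacement, same_stem_check
from .io import (
    ParameterError,
    RunConfig,
    SequenceRecord,
    revcomp_dna,
    revcomp_rna,
    to_dna,
    write_fasta,
    write_fastq,
    write_gff3,
)
from .preprocess import GroupedSRna


class GenerationError(ValueError):
    """The requested synthetic study cannot be generated."""


_BASES = "ACGU"
_PAIRS_OF = {"A": {"U"}, "C": {"G"}, "G": {"C", "U"}, "U": {"A", "G"}}

#: modal milR length 23 within range 20-26
_LEN_CHOICES = np.array([20, 21, 22, 23, 24, 25, 26])
_LEN_WEIGHTS = np.array([1, 1, 3, 6, 3, 1, 1], dtype=float)

DEFAULT_ADAPTER = "UCGUAUGCCGUCUUCUGCU"  # fixed 19-nt 3' adapter
READ_LEN = 35


@dataclass
class PlantedLocus:
    precursor_id: str
    contig_id: str
    context: str
    milR_seq: str
    milRstar_seq: str
    precursor_seq: str
    milR_count_MY: int
    milR_count_FB: int
    milRstar_count_MY: int
    milRstar_count_FB: int
    genome_scaffold: str | None = None
    genome_pos: int | None = None
    strand: str = "+"
    recoverable: bool = True

    @property
    def milR_total(self) -> int:
        return self.milR_count_MY + self.milR_count_FB

    @property
    def milRstar_total(self) -> int:
        return self.milRstar_count_MY + self.milRstar_count_FB

    def lib_class_of(self, which: str) -> str:
        my, fb = (
            (self.milR_count_MY, self.milR_count_FB)
            if which == "milR"
            else (self.milRstar_count_MY, self.milRstar_count_FB)
        )
        if fb == 0:
            return "M"
        if my == 0:
            return "F"
        return "B"


@dataclass
class SyntheticTruth:
    loci: list[PlantedLocus]
    deg_genes: dict[str, float]
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.0
    background_fraction: float = 0.0
    seed: int = 0
    genes_enabled: bool = True


def _mutate_star_arm(milR: str, bulges: int) -> str:
    """Reverse complement of milR with exactly ``bulges`` substitutions,
    chosen deterministically so the substituted bases cannot pair (even by
    wobble) with the milR base they face."""
    arm = list(revcomp_rna(milR))
    n = len(arm)
    if bulges > max(n - 4, 0):
        raise ParameterError("too many bulges for the milR length")
    # spread positions over the interior of the arm
    positions = [2 + (i * (n - 4)) // bulges for i in range(bulges)] if bulges else []
    for p in positions:
        facing = milR[n - 1 - p]
        forbidden = _PAIRS_OF[facing] | {arm[p]}
        arm[p] = next(b for b in _BASES if b not in forbidden)
    return "".join(arm)


def make_hairpin(milR: str, loop_len: int, bulges: int = 0, min_loop: int = 3) -> str:
    """Build a hairpin precursor: milR on the 5' arm, its near-reverse
    complement (``bulges`` substitutions) on the 3' arm, a loop between."""
    milR = milR.upper().replace("T", "U")
    if not (18 <= len(milR) <= 30):
        raise ParameterError("milR length must be within [18, 30]")
    if loop_len < min_loop:
        raise ParameterError(f"loop_len must be >= min_loop ({min_loop})")
    loop = ("AAC" * loop_len)[:loop_len]
    return milR + loop + _mutate_star_arm(milR, bulges)


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _random_milR(rng: np.random.Generator) -> str:
    n = int(rng.choice(_LEN_CHOICES, p=_LEN_WEIGHTS / _LEN_WEIGHTS.sum()))
    first = "U" if rng.random() < 0.5 else _BASES[rng.integers(0, 4)]
    return first + _random_rna(rng, n - 1)


def default_truth(
    seed: int = 0,
    n_loci: int = 20,
    error_rate: float = 0.0,
    background_fraction: float = 0.0,
    n_deg_genes: int = 6,
) -> SyntheticTruth:
    """A fully specified toy study with ``n_loci`` planted hairpin loci.

    Library patterns cycle M, F, B; contexts cycle intergenic, intron,
    exon-antisense.  The recoverable flag is set from the designed duplex and
    the count criterion, checked with the same folding contract the pipeline
    uses.
    """
    rng = np.random.default_rng(seed)
    contexts = ["intergenic", "intron", "exon_antisense"]
    loci: list[PlantedLocus] = []
    seen_seqs: set[str] = set()
    for i in range(n_loci):
        while True:
            milR = _random_milR(rng)
            loop_len = int(rng.integers(6, 11))
            bulges = int(rng.integers(0, 3))
            precursor = make_hairpin(milR, loop_len, bulges)
            star = precursor[len(milR) + loop_len :]
            if milR not in seen_seqs and star not in seen_seqs and milR != star:
                break
        seen_seqs.update({milR, star})
        c = int(rng.integers(30, 81))
        c_star = max(2, c // 10)
        pattern = i % 3
        if pattern == 0:  # M
            counts = (c, 0, c_star, 0)
        elif pattern == 1:  # F
            counts = (0, c, 0, c_star)
        else:  # B
            c2 = int(rng.integers(20, 61))
            counts = (c, c2, c_star, max(1, c2 // 10))
        locus = PlantedLocus(
            precursor_id=f"prec_{i + 1:03d}",
            contig_id=f"contig_{i + 1:03d}",
            context=contexts[i % 3],
            milR_seq=milR,
            milRstar_seq=star,
            precursor_seq=precursor,
            milR_count_MY=counts[0],
            milR_count_FB=counts[1],
            milRstar_count_MY=counts[2],
            milRstar_count_FB=counts[3],
        )
        loci.append(locus)
    deg_genes = {}
    for j in range(min(n_deg_genes, n_loci)):
        deg_genes[f"contig_{j + 1:03d}"] = 2.0 if j % 2 == 0 else -2.0
    return SyntheticTruth(
        loci=loci,
        deg_genes=deg_genes,
        error_rate=error_rate,
        background_fraction=background_fraction,
        seed=seed,
    )


def _check_recoverable(locus: PlantedLocus, contig_seq: str, config: RunConfig) -> bool:
    """Duplex + count criterion on the designed locus, using the pipeline's
    own folding contract."""
    if not (locus.milR_total > locus.milRstar_total and locus.milRstar_total >= 1):
        return False
    folded = fold_mod.fold(contig_seq, min_loop=config.min_loop, contig_id=locus.contig_id)
    start_r = contig_seq.find(locus.milR_seq)
    start_s = contig_seq.find(locus.milRstar_seq)
    if start_r < 0 or start_s < 0:
        return False
    p1 = ReadPlacement(GroupedSRna(locus.milR_seq, 1, 0), locus.contig_id, start_r, 0)
    p2 = ReadPlacement(GroupedSRna(locus.milRstar_seq, 1, 0), locus.contig_id, start_s, 0)
    chk = same_stem_check(
        p1,
        p2,
        folded,
        overlap_frac=config.stem_overlap_frac,
        duplex_frac=config.duplex_overlap_frac,
        duplex_slack=config.duplex_slack_nt,
        stem_gap_max=config.stem_gap_max,
    )
    return chk.ok and chk.arm_of_p1 == "5p"


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
    for i in hits:
        alternatives = [b for b in _BASES if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def _make_read(insert: str, adapter: str) -> str:
    return (insert + adapter)[:READ_LEN]


def simulate_study(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Generate all study files under ``out_dir``; reproducible from the seed.

    Returns a mapping of logical names (genome, genes, contigs, srna_MY,
    srna_FB, mature_ref, counts, truth) to file paths.
    """
    from .context import GeneModel  # deferred: context imports io only

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed + 1)
    config = RunConfig(seed=truth.seed)

    ids = [l.contig_id for l in truth.loci] + [l.precursor_id for l in truth.loci]
    if len(set(ids)) != len(ids):
        raise GenerationError("colliding locus ids in truth")
    needs_genes = [l for l in truth.loci if l.context in {"intron", "exon_antisense"}]
    if needs_genes and not truth.genes_enabled:
        raise GenerationError(
            f"context {needs_genes[0].context!r} requested but gene models disabled"
        )

    # --- contigs with embedded precursors -------------------------------
    contigs: list[SequenceRecord] = []
    for locus in truth.loci:
        flank5 = _random_rna(rng, int(rng.integers(60, 101)))
        flank3 = _random_rna(rng, int(rng.integers(60, 101)))
        contig_seq = flank5 + locus.precursor_seq + flank3
        contigs.append(SequenceRecord(locus.contig_id, contig_seq, moltype="RNA"))
        locus.recoverable = _check_recoverable(locus, contig_seq, config)
    n_bg_contigs = max(3, len(truth.loci) // 4)
    for b in range(n_bg_contigs):
        contigs.append(
            SequenceRecord(f"bgcontig_{b + 1:03d}", _random_rna(rng, 220), moltype="RNA")
        )

    # --- genome scaffolds and gene models -------------------------------
    n_int = sum(1 for l in truth.loci if l.context == "intergenic")
    n_intron = sum(1 for l in truth.loci if l.context == "intron")
    n_anti = sum(1 for l in truth.loci if l.context == "exon_antisense")
    scaf1_len = 600 + 300 * max(n_int, 1)
    scaf2_len = 1000 * (n_intron + n_anti) + 1200
    scaf1 = list(_random_dna(rng, scaf1_len))
    scaf2 = list(_random_dna(rng, scaf2_len))
    genes: list[GeneModel] = []

    int_slot = iter(range(max(n_int, 1)))
    intron_slot = iter(range(n_intron))
    anti_slot = iter(range(n_anti))
    gene_no = 0
    intron_gene_start: dict[int, int] = {}
    anti_gene_start: dict[int, int] = {}
    for k in range(n_intron):
        s = 1000 * k + 200
        gene_no += 1
        genes.append(
            GeneModel(
                gene_id=f"gene_{gene_no:03d}",
                scaffold="scaffold_2",
                strand="+",
                exons=[(s, s + 300), (s + 500, s + 800)],
            )
        )
        intron_gene_start[k] = s
    for k in range(n_anti):
        s = 1000 * (n_intron + k) + 200
        gene_no += 1
        genes.append(
            GeneModel(
                gene_id=f"gene_{gene_no:03d}",
                scaffold="scaffold_2",
                strand="+",
                exons=[(s, s + 300), (s + 500, s + 800)],
            )
        )
        anti_gene_start[k] = s

    for locus in truth.loci:
        prec_dna = to_dna(locus.precursor_seq)
        if locus.context == "intergenic":
            slot = next(int_slot)
            pos = 300 * slot + 150
            scaf1[pos : pos + len(prec_dna)] = prec_dna
            locus.genome_scaffold, locus.genome_pos, locus.strand = "scaffold_1", pos, "+"
        elif locus.context == "intron":
            slot = next(intron_slot)
            pos = intron_gene_start[slot] + 350  # inside the (s+300, s+500) intron
            scaf2[pos : pos + len(prec_dna)] = prec_dna
            locus.genome_scaffold, locus.genome_pos, locus.strand = "scaffold_2", pos, "+"
        else:  # exon_antisense: reverse complement inside a + strand exon
            slot = next(anti_slot)
            pos = anti_gene_start[slot] + 100
            rc = revcomp_dna(prec_dna)
            scaf2[pos : pos + len(rc)] = rc
            locus.genome_scaffold, locus.genome_pos, locus.strand = "scaffold_2", pos, "-"
    scaffolds = [
        SequenceRecord("scaffold_1", "".join(scaf1), moltype="DNA"),
        SequenceRecord("scaffold_2", "".join(scaf2), moltype="DNA"),
    ]

    # --- small RNA libraries --------------------------------------------
    reads: dict[str, list[str]] = {"MY": [], "FB": []}
    for locus in truth.loci:
        for seq, my, fb in (
            (locus.milR_seq, locus.milR_count_MY, locus.milR_count_FB),
            (locus.milRstar_seq, locus.milRstar_count_MY, locus.milRstar_count_FB),
        ):
            reads["MY"].extend([_make_read(seq, truth.adapter)] * my)
            reads["FB"].extend([_make_read(seq, truth.adapter)] * fb)
    for lib in ("MY", "FB"):
        n_planted = len(reads[lib])
        if truth.background_fraction > 0:
            n_bg = round(
                truth.background_fraction * n_planted / (1.0 - truth.background_fraction)
            )
            for _ in range(n_bg):
                insert = _random_rna(rng, int(rng.integers(18, 36)))
                reads[lib].append(_make_read(insert, truth.adapter))
        noisy = [_apply_errors(rng, r, truth.error_rate) for r in reads[lib]]
        order = rng.permutation(len(noisy))
        reads[lib] = [noisy[i] for i in order]

    # --- mature miRNA reference -----------------------------------------
    mature: list[SequenceRecord] = []
    for j, locus in enumerate(truth.loci[:2], start=1):
        mature.append(SequenceRecord(f"ref-miR-{j}", locus.milR_seq, moltype="RNA"))
    for j in range(2):
        mature.append(
            SequenceRecord(f"ref-miR-decoy-{j + 1}", _random_rna(rng, 22), moltype="RNA")
        )

    # --- unigene count table --------------------------------------------
    rows = []
    for contig in contigs:
        lfc = truth.deg_genes.get(contig.id, 0.0)
        lam = rng.uniform(30, 120)
        lam_my = lam * 2.0 ** (-lfc / 2.0)
        lam_fb = lam * 2.0 ** (lfc / 2.0)
        rows.append(
            {
                "unigene_id": contig.id,
                "length_bp": len(contig),
                "count_MY": int(rng.poisson(lam_my)),
                "count_FB": int(rng.poisson(lam_fb)),
            }
        )
    counts_df = pd.DataFrame(rows)

    # --- write everything ------------------------------------------------
    paths = {
        "genome": out_dir / "genome.fa",
        "genes": out_dir / "genes.gff3",
        "contigs": out_dir / "contigs.fa",
        "srna_MY": out_dir / "srna_MY.fastq",
        "srna_FB": out_dir / "srna_FB.fastq",
        "mature_ref": out_dir / "mature_ref.fa",
        "counts": out_dir / "unigene_counts.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(scaffolds, paths["genome"])
    write_gff3(genes, paths["genes"])
    write_fasta(contigs, paths["contigs"])
    for lib in ("MY", "FB"):
        recs = [
            SequenceRecord(f"{lib}_{i + 1:06d}", seq, quality=[40] * len(seq))
            for i, seq in enumerate(reads[lib])
        ]
        write_fastq(recs, paths[f"srna_{lib}"])
    write_fasta(mature, paths["mature_ref"])
    counts_df.to_csv(paths["counts"], sep="\t", index=False)
    truth_df = pd.DataFrame(
        {
            "precursor_id": [l.precursor_id for l in truth.loci],
            "contig_id": [l.contig_id for l in truth.loci],
            "scaffold": [l.genome_scaffold for l in truth.loci],
            "pos": [l.genome_pos for l in truth.loci],
            "strand": [l.strand for l in truth.loci],
            "context": [l.context for l in truth.loci],
            "milR_seq": [l.milR_seq for l in truth.loci],
            "milRstar_seq": [l.milRstar_seq for l in truth.loci],
            "milR_count_MY": [l.milR_count_MY for l in truth.loci],
            "milR_count_FB": [l.milR_count_FB for l in truth.loci],
            "milRstar_count_MY": [l.milRstar_count_MY for l in truth.loci],
            "milRstar_count_FB": [l.milRstar_count_FB for l in truth.loci],
            "recoverable": [l.recoverable for l in truth.loci],
        }
    )
    with open(paths["truth"], "w") as fh:
        fh.write(
            f"# adapter={truth.adapter} error_rate={truth.error_rate} "
            f"background_fraction={truth.background_fraction} seed={truth.seed}\n"
        )
        truth_df.to_csv(fh, sep="\t", index=False)
    return paths


def evaluate_recovery(
    candidates: Sequence[MilRnaCandidate], truth: SyntheticTruth
) -> tuple[int, int, list[str]]:
    """Fraction of recoverable planted loci recovered with exact roles and
    library classes.  Returns (recovered, recoverable, missed precursor ids).
    """
    by_seq: dict[tuple[str, str], list[MilRnaCandidate]] = {}
    for c in candidates:
        by_seq.setdefault((c.sequence, c.role), []).append(c)

    def found(seq: str, role: str, lib_class: str, arm: str) -> bool:
        return any(
            c.lib_class == lib_class and c.arm == arm
            for c in by_seq.get((seq, role), [])
        )

    recovered = 0
    recoverable = 0
    missed: list[str] = []
    for locus in truth.loci:
        if not locus.recoverable:
            continue
        recoverable += 1
        ok = found(
            locus.milR_seq, "milR", locus.lib_class_of("milR"), "5p"
        ) and found(
            locus.milRstar_seq, "milRstar", locus.lib_class_of("milRstar"), "3p"
        )
        if ok:
            recovered += 1
        else:
            missed.append(locus.precursor_id)
    return recovered, recoverable, missed
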