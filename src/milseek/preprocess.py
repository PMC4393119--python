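"""Small-RNA read preprocessing: adapter trimming, quality filtering and
collapsing to unique sequences with per-library counts."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import ParameterError, RunConfig, SequenceRecord


@dataclass
class GroupedSRna:
    """A unique small-RNA sequence with its read multiplicity per library."""

    sequence: str
    count_MY: int = 0
    count_FB: int = 0

    def __post_init__(self) -> None:
        if self.count_MY + self.count_FB < 1:
            raise ParameterError("grouped sRNA must carry at least one read")

    @property
    def total(self) -> int:
        return self.count_MY + self.count_FB

    @property
    def lib_class(self) -> str:
        if self.count_FB == 0:
            return "M"
        if self.count_MY == 0:
            return "F"
        return "B"

    def __len__(self) -> int:
        return len(self.sequence)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(
    read: SequenceRecord,
    adapter: str,
    min_read_len: int = 18,
    seed_len: int = 7,
    seed_mm: int = 1,
) -> SequenceRecord | None:
    """Trim the 3' adapter off a read; ``None`` means the read is discarded.

    The leftmost position where a prefix of the adapter (at least ``seed_len``
    nt, at most ``seed_mm`` mismatches) occurs truncates the read there.
    Reads with no detectable adapter are kept whole; trimmed inserts shorter
    than ``min_read_len`` are discarded.
    """
    if len(adapter) < 7:
        raise ParameterError("adapter must be at least 7 nt")
    adapter = adapter.upper().replace("T", "U")
    seq = read.sequence
    cut = None
    for p in range(0, len(seq) - seed_len + 1):
        span = min(len(adapter), len(seq) - p)
        if span < seed_len:
            break
        if _hamming(seq[p : p + span], adapter[:span]) <= seed_mm:
            cut = p
            break
    if cut is None:
        return read
    if cut < min_read_len:
        return None
    return SequenceRecord(
        read.id,
        seq[:cut],
        quality=read.quality[:cut] if read.quality is not None else None,
        moltype=read.moltype,
    )


def quality_filter(read: SequenceRecord, min_mean_q: float = 20.0) -> bool:
    """Keep verdict: drop reads containing N or with mean quality below
    ``min_mean_q``; reads without quality default to keep."""
    if "N" in read.sequence:
        return False
    if read.quality is None:
        return True
    return sum(read.quality) / len(read.quality) >= min_mean_q


def preprocess_library(
    reads: Iterable[SequenceRecord],
    adapter: str | None,
    config: RunConfig | None = None,
) -> list[str]:
    """Trim + filter one library; returns surviving insert sequences."""
    config = config or RunConfig()
    out: list[str] = []
    for read in reads:
        if not quality_filter(read, config.min_mean_q):
            continue
        if adapter is not None:
            trimmed = trim_adapter(
                read,
                adapter,
                min_read_len=config.min_read_len,
                seed_len=config.adapter_seed_len,
                seed_mm=config.adapter_seed_mm,
            )
            if trimmed is None:
                continue
            if config.drop_untrimmed and trimmed is read:
                continue
            read = trimmed
        if config.min_read_len <= len(read) <= config.max_read_len:
            out.append(read.sequence)
    return out


def group_reads(
    reads_MY: Sequence[str | SequenceRecord],
    reads_FB: Sequence[str | SequenceRecord],
) -> list[GroupedSRna]:
    """Collapse reads to unique sequences with exact per-library counts.

    Output is sorted by total count descending, ties broken lexicographically.
    """

    def seqs(reads):
        return [r.sequence if isinstance(r, SequenceRecord) else r for r in reads]

    my = Counter(seqs(reads_MY))
    fb = Counter(seqs(reads_FB))
    grouped = [
        GroupedSRna(seq, count_MY=my.get(seq, 0), count_FB=fb.get(seq, 0))
        for seq in set(my) | set(fb)
    ]
    grouped.sort(key=lambda g: (-g.total, g.sequence))
    return grouped


def length_histogram(items: Iterable[str | GroupedSRna]) -> dict[int, int]:
    """Histogram of sequence lengths; sums to the item count."""
    hist: Counter[int] = Counter()
    for item in items:
        hist[len(item)] += 1
    return dict(sorted(hist.items()))


def five_prime_freq(items: Iterable[str | GroupedSRna]) -> dict[str, int]:
    """Frequency of the 5'-end nucleotide over {A, C, G, U}."""
    freq: Counter[str] = Counter()
    for item in items:
        seq = item.sequence if isinstance(item, GroupedSRna) else item
        freq[seq[0]] += 1
    return {b: freq.get(b, 0) for b in "ACGU"} if freq else {}


def modal_length(items: Iterable[str | GroupedSRna]) -> int | None:
    hist = length_histogram(items)
    if not hist:
        return None
    return max(hist, key=lambda L: (hist[L], -L))
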