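"""Raw-read preprocessing: adapter trimming, quality/length filtering,
collapsing to unique tags, and read-length profiling.

Clean tags are the 16-30 nt trimmed sequences surviving the junk filters; they
are collapsed to one row per distinct sequence with a raw count per library,
the atom the downstream annotation cascade and expression statistics consume.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .simlib import GROUPS

MIN_LEN, MAX_LEN = 16, 30


def trim_adapter(read: str, adapter: str, max_mismatch: int = 1,
                 min_overlap: int = 6) -> tuple[str, bool]:
    """Locate the leftmost 3' adapter occurrence and return the insert.

    Scans every alignment of an adapter prefix of length >= ``min_overlap``
    against the read, allowing up to ``max_mismatch`` substitutions (no
    indels; small-RNA adapters dominate the 3' end, so an ungapped scan
    suffices). Returns ``(insert, True)`` on a hit, or the whole read with
    ``False`` when no adapter is found.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    n, la = len(read), len(adapter)
    for i in range(0, n - min_overlap + 1):
        span = min(la, n - i)
        mism = 0
        for a, b in zip(read[i:i + span], adapter[:span]):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return read[:i], True
    return read, False


@dataclass
class FilterStats:
    """Read accounting through one library's preprocessing.

    Partitions the input exactly: total == kept + sum of drop reasons.
    """

    total: int = 0
    kept: int = 0
    no_adapter: int = 0  # informational; such reads are kept whole, then length-filtered
    drop_length: int = 0
    drop_ambiguous: int = 0
    drop_quality: int = 0

    def check(self) -> None:
        assert self.total == self.kept + self.drop_length + self.drop_ambiguous + self.drop_quality

    def as_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in
                ("total", "kept", "no_adapter", "drop_length", "drop_ambiguous", "drop_quality")}


def _mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


def filter_reads(
    records,
    adapter: str,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    max_N: int = 0,
    min_mean_qual: float = 20.0,
    max_mismatch: int = 1,
    min_overlap: int = 6,
) -> tuple[Counter, FilterStats]:
    """Trim and filter one library of (id, seq, qual) records.

    Keeps reads whose trimmed length lies in ``[min_len, max_len]`` inclusive,
    with at most ``max_N`` ambiguous bases and mean Phred >= ``min_mean_qual``
    (the junk-read rule; the thresholds are conventions of this package).
    Returns a Counter of clean tag sequences and the exact read accounting.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    stats = FilterStats()
    tags: Counter = Counter()
    trim_cache: dict[str, tuple[str, bool]] = {}
    for idx, rec in enumerate(records):
        try:
            _rid, seq, qual = rec
        except (TypeError, ValueError) as exc:
            raise IOError(f"malformed FASTQ record at index {idx}") from exc
        stats.total += 1
        if len(seq) != len(qual):
            raise IOError(f"malformed FASTQ record at index {idx}: "
                          "sequence/quality length mismatch")
        if _mean_phred(qual) < min_mean_qual:
            stats.drop_quality += 1
            continue
        hit = trim_cache.get(seq)
        if hit is None:
            hit = trim_adapter(seq, adapter, max_mismatch, min_overlap)
            trim_cache[seq] = hit
        trimmed, found = hit
        if not found:
            stats.no_adapter += 1
        if not (min_len <= len(trimmed) <= max_len):
            stats.drop_length += 1
            continue
        if trimmed.count("N") > max_N:
            stats.drop_ambiguous += 1
            continue
        stats.kept += 1
        tags[trimmed] += 1
    stats.check()
    return tags, stats


def collapse(library_tags: dict[str, Counter],
             groups: tuple[str, ...] = GROUPS) -> pd.DataFrame:
    """Collapse per-library clean-tag counters into a unique-tag table.

    One row per distinct sequence, one count column per library; column sums
    equal each library's clean-read total exactly. Rows are sorted by sequence
    so the table is identical under any input permutation.
    """
    seqs = sorted(set().union(*[set(c) for c in library_tags.values()])) \
        if library_tags else []
    data = {f"count_{g}": [library_tags.get(g, Counter()).get(s, 0) for s in seqs]
            for g in groups}
    df = pd.DataFrame(data, index=pd.Index(seqs, name="sequence"))
    return df


@dataclass
class LengthProfile:
    """Read-length histogram over the clean-tag range plus detected peaks."""

    bins: dict[int, int]
    peaks: list[tuple[int, int]] = field(default_factory=list)  # inclusive windows

    @property
    def total(self) -> int:
        return sum(self.bins.values())


def length_profile(tags: pd.DataFrame | Counter, by: str = "distinct",
                   peak_factor: float = 1.5,
                   group: str | None = None) -> LengthProfile:
    """Histogram tag lengths and report peak windows.

    ``by='distinct'`` counts each unique sequence once (the convention used
    for library quality assessment); ``by='total'`` weights by read counts.
    Peaks are maximal runs of lengths whose bin count exceeds
    ``peak_factor`` x the median bin count.
    """
    if by not in ("distinct", "total"):
        raise ValueError("by must be 'distinct' or 'total'")
    if isinstance(tags, pd.DataFrame):
        if len(tags) == 0:
            raise ValueError("empty tag table")
        lengths = tags.index.str.len()
        if by == "distinct":
            weights = pd.Series(1, index=tags.index)
        else:
            cols = [f"count_{group}"] if group else [c for c in tags.columns
                                                    if c.startswith("count_")]
            weights = tags[cols].sum(axis=1)
        hist = pd.Series(weights.values).groupby(pd.Series(lengths)).sum().to_dict()
    else:
        if not tags:
            raise ValueError("empty tag input")
        hist = {}
        for seq, n in tags.items():
            w = 1 if by == "distinct" else n
            hist[len(seq)] = hist.get(len(seq), 0) + w
    bins = {ln: int(hist.get(ln, 0)) for ln in range(MIN_LEN, MAX_LEN + 1)}
    counts = sorted(bins.values())
    mid = len(counts) // 2
    median = (counts[mid] if len(counts) % 2 else
              (counts[mid - 1] + counts[mid]) / 2)
    thresh = peak_factor * median
    peaks, run = [], None
    for ln in range(MIN_LEN, MAX_LEN + 1):
        if bins[ln] > thresh and bins[ln] > 0:
            run = (run[0], ln) if run else (ln, ln)
        else:
            if run:
                peaks.append(run)
            run = None
    if run:
        peaks.append(run)
    return LengthProfile(bins=bins, peaks=peaks)


def read_fastq(path: str | Path):
    """Iterate (id, seq, qual) from a Phred+33 FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def preprocess_libraries(records_by_group: dict[str, list], adapter: str,
                         **filter_kw) -> tuple[pd.DataFrame, dict[str, FilterStats]]:
    """Run trim+filter+collapse over the three-library design."""
    counters, stats = {}, {}
    for g, recs in records_by_group.items():
        counters[g], stats[g] = filter_reads(recs, adapter, **filter_kw)
    return collapse(counters, tuple(records_by_group)), stats
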