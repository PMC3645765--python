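"""Raw FASTQ -> high-quality unique tags.

The stages, in order: 3' adapter trimming, collapsing identical inserts into
unique tags with per-library counts, a filter cascade (length 14–27 nt;
composition: no single nucleotide at >=80% of the read and at most two N;
copy number: more than 3 reads across both libraries), and removal of tags
matching known contaminant RNA classes (rRNA/tRNA/snRNA/snoRNA/repeats).
Tags surviving all stages are the "high-quality" tag set. Every stage is
accounted in a :class:`FilterReport` whose input = retained + discarded
identity holds exactly.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import revcomp, scan_tags

__all__ = [
    "UniqueTag",
    "FilterParams",
    "StageCount",
    "FilterReport",
    "read_fastq_sequences",
    "trim_adapter",
    "collapse_reads",
    "apply_filter_cascade",
    "remove_known_rna_classes",
    "length_distribution",
    "process_pair",
    "write_tags_fasta",
    "write_tags_tsv",
]

CONTAMINANT_CLASS_ORDER = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")


class UniqueTag(NamedTuple):
    sequence: str
    count_a: int
    count_b: int

    @property
    def total(self) -> int:
        return self.count_a + self.count_b


Tags = dict[str, UniqueTag]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the high-quality filter cascade.

    ``min_copies`` is the smallest retained combined count, i.e. the default 4
    implements the "strictly more than 3 reads" rule. ``copy_filter_scope``
    is ``combined`` (count_a + count_b thresholded together, the default) or
    ``per-library`` (retained when either single library reaches the
    threshold on its own).
    """

    len_min: int = 14
    len_max: int = 27
    max_single_base_frac: float = 0.80
    max_n: int = 2
    min_copies: int = 4
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_adapter_overlap: int = 6
    copy_filter_scope: str = "combined"
    contaminant_max_mismatches: int = 1

    def __post_init__(self) -> None:
        if self.len_min > self.len_max:
            raise ValueError("len_min must be <= len_max")
        if not 0 < self.max_single_base_frac <= 1:
            raise ValueError("max_single_base_frac must be in (0, 1]")
        if self.copy_filter_scope not in ("combined", "per-library"):
            raise ValueError("copy_filter_scope must be 'combined' or 'per-library'")


class StageCount(NamedTuple):
    stage: str
    tags_in: int
    tags_out: int
    reads_in: int
    reads_out: int

    @property
    def tags_discarded(self) -> int:
        return self.tags_in - self.tags_out

    @property
    def reads_discarded(self) -> int:
        return self.reads_in - self.reads_out


@dataclass
class FilterReport:
    """Per-stage accounting of the cascade; conservation holds at each stage."""

    stages: list[StageCount] = field(default_factory=list)
    raw_reads: int = 0

    def add(self, stage: str, tags_in: int, tags_out: int, reads_in: int, reads_out: int) -> None:
        self.stages.append(StageCount(stage, tags_in, tags_out, reads_in, reads_out))

    @property
    def high_quality_reads(self) -> int:
        return self.stages[-1].reads_out if self.stages else 0

    @property
    def high_quality_pct(self) -> float:
        return 100.0 * self.high_quality_reads / self.raw_reads if self.raw_reads else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def __str__(self) -> str:
        buf = io.StringIO()
        for s in self.stages:
            buf.write(
                f"{s.stage}: tags {s.tags_in} -> {s.tags_out} "
                f"(-{s.tags_discarded}), reads {s.reads_in} -> {s.reads_out} (-{s.reads_discarded})\n"
            )
        if self.raw_reads:
            buf.write(f"high-quality: {self.high_quality_reads}/{self.raw_reads} ({self.high_quality_pct:.2f}%)\n")
        return buf.getvalue()


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Read sequences of a FASTQ file (Sanger 4-line records)."""
    with open(path) as fh:
        return [seq for _title, seq, _q in FastqGeneralIterator(fh)]


# ---------------------------------------------------------------------------
# adapter trimming
# ---------------------------------------------------------------------------

def trim_adapter(read_sequence: str, params: FilterParams) -> str | None:
    """Insert preceding the left-most 3' adapter match, or ``None``.

    A match at position ``i`` requires the read from ``i`` onward to equal a
    prefix of the adapter of length ``min(len(adapter), len(read) - i)`` with
    at least ``min_adapter_overlap`` bases. Reads with no match cannot be
    sized (their insert exceeds the read length) and are discarded; a match
    at position 0 yields an empty insert, also reported as ``None``.
    """
    if not read_sequence:
        raise ValueError("empty read")
    adapter = params.adapter
    n, la = len(read_sequence), len(adapter)
    # interior positions need the full adapter; scan those with str.find
    best = read_sequence.find(adapter)
    limit = best if best != -1 else n
    # near the 3' end only a prefix of the adapter fits
    tail_start = max(0, n - la + 1)
    for i in range(tail_start, limit):
        k = n - i
        if k >= params.min_adapter_overlap and read_sequence[i : i + k] == adapter[:k]:
            limit = i
            break
    if limit == n:
        return None
    return read_sequence[:limit] if limit > 0 else None


# ---------------------------------------------------------------------------
# collapsing and the filter cascade
# ---------------------------------------------------------------------------

def collapse_reads(inserts_a: Sequence[str], inserts_b: Sequence[str]) -> Tags:
    """Collapse inserts into unique tags with per-library occurrence counts."""
    ca = Counter(inserts_a)
    cb = Counter(inserts_b)
    return {
        seq: UniqueTag(seq, ca.get(seq, 0), cb.get(seq, 0))
        for seq in sorted(set(ca) | set(cb))
    }


def _passes_length(tag: UniqueTag, p: FilterParams) -> bool:
    return p.len_min <= len(tag.sequence) <= p.len_max


def _passes_composition(tag: UniqueTag, p: FilterParams) -> bool:
    seq = tag.sequence
    n = len(seq)
    if seq.count("N") > p.max_n:
        return False
    # N bases are governed solely by max_n and never by the single-base rule
    return all(seq.count(b) / n < p.max_single_base_frac for b in "ACGT")


def _passes_copies(tag: UniqueTag, p: FilterParams) -> bool:
    if p.copy_filter_scope == "per-library":
        return tag.count_a >= p.min_copies or tag.count_b >= p.min_copies
    return tag.total >= p.min_copies


def _reads(tags: Tags) -> int:
    return sum(t.total for t in tags.values())


def apply_filter_cascade(tags: Tags, params: FilterParams) -> tuple[Tags, FilterReport]:
    """Apply length -> composition -> copy-number filters with accounting.

    The three predicates are independent per tag, so their order does not
    change the final set; the cascade order only shapes the per-stage report.
    """
    report = FilterReport()
    current = tags
    for stage, pred in (
        ("length", _passes_length),
        ("composition", _passes_composition),
        ("copy_number", _passes_copies),
    ):
        kept = {s: t for s, t in current.items() if pred(t, params)}
        report.add(stage, len(current), len(kept), _reads(current), _reads(kept))
        current = kept
    return current, report


# ---------------------------------------------------------------------------
# contaminant removal
# ---------------------------------------------------------------------------

def _concat(seqs: Iterable[str]) -> str:
    # 'X' separators can never take part in an ungapped full-tag match
    return "X".join(seqs)


def remove_known_rna_classes(
    tags: Tags,
    contaminants: Sequence,
    params: FilterParams,
) -> tuple[Tags, dict[str, tuple[int, int]]]:
    """Drop tags matching contaminant RNA records; tally removals per class.

    Matching policy: ungapped placement of the full tag within a contaminant
    sequence with at most ``contaminant_max_mismatches`` mismatches — both
    strands for the ``repeat`` class, forward strand only for structural
    RNAs. A tag matching several classes is tallied under the first class in
    rRNA < tRNA < snRNA < snoRNA < repeat order. The tally maps class name to
    (tags removed, reads removed).
    """
    by_class: dict[str, list[str]] = {}
    for rec in contaminants:
        by_class.setdefault(rec.rna_class, []).append(rec.sequence)
    removed_class: dict[str, str] = {}
    remaining = set(tags)
    order = [c for c in CONTAMINANT_CLASS_ORDER if c in by_class] + [
        c for c in by_class if c not in CONTAMINANT_CLASS_ORDER
    ]
    for cls in order:
        if not remaining:
            break
        seqs = by_class[cls]
        ref = _concat(seqs)
        if cls == "repeat":
            ref = _concat([ref] + [revcomp(s) for s in seqs])
        hit = scan_tags(sorted(remaining), ref, params.contaminant_max_mismatches)
        for seq in hit:
            removed_class[seq] = cls
        remaining -= set(hit)
    kept = {s: t for s, t in tags.items() if s in remaining}
    tally: dict[str, tuple[int, int]] = {}
    for seq, cls in removed_class.items():
        t_tags, t_reads = tally.get(cls, (0, 0))
        tally[cls] = (t_tags + 1, t_reads + tags[seq].total)
    return kept, tally


# ---------------------------------------------------------------------------
# summaries and orchestration
# ---------------------------------------------------------------------------

def length_distribution(tags: Tags) -> dict[int, float]:
    """Read-count-weighted fraction of tags at each insert length."""
    weights: dict[int, int] = {}
    for t in tags.values():
        weights[len(t.sequence)] = weights.get(len(t.sequence), 0) + t.total
    total = sum(weights.values())
    if total == 0:
        return {}
    return {ln: weights[ln] / total for ln in sorted(weights)}


def process_pair(
    reads_a: Sequence[str],
    reads_b: Sequence[str],
    params: FilterParams,
    contaminants: Sequence = (),
) -> tuple[Tags, FilterReport]:
    """Full read-processing pipeline for a two-library pair of read sets."""
    report = FilterReport(raw_reads=len(reads_a) + len(reads_b))
    trimmed_a = [t for t in (trim_adapter(r, params) for r in reads_a) if t is not None]
    trimmed_b = [t for t in (trim_adapter(r, params) for r in reads_b) if t is not None]
    report.add(
        "adapter_trim", 0, 0,
        len(reads_a) + len(reads_b), len(trimmed_a) + len(trimmed_b),
    )
    tags = collapse_reads(trimmed_a, trimmed_b)
    filtered, cascade_report = apply_filter_cascade(tags, params)
    report.stages.extend(cascade_report.stages)
    if contaminants:
        kept, _tally = remove_known_rna_classes(filtered, contaminants, params)
    else:
        kept = filtered
    report.add("contaminants", len(filtered), len(kept), _reads(filtered), _reads(kept))
    return kept, report


def write_tags_fasta(tags: Tags, path: str | Path) -> None:
    """FASTA with ``>tag<i>_x<count_a>_y<count_b>`` headers."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags.values()):
            fh.write(f">tag{i}_x{t.count_a}_y{t.count_b}\n{t.sequence}\n")


def write_tags_tsv(tags: Tags, path: str | Path) -> None:
    pd.DataFrame(list(tags.values())).to_csv(path, sep="\t", index=False)
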