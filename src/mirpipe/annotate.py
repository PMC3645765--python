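"""Hierarchical miRNA classification of high-quality tags.

Tags are assigned by the first matching branch:

1. ungapped full-tag hit on a *known* precursor (species tier) -> ``known``;
2. hit on an *other-mammal conserved* precursor that itself occurs in the
   genome -> ``conserved``, named after the conserved miRNA;
3. otherwise, tags longer than 18 nt that map to the genome are clustered
   into candidate loci (single linkage, small gap); each locus is extended by
   60 nt of genomic flank on both sides and folded; loci whose fold is an
   acceptable hairpin with the mature cluster on one arm become ``PPN``
   (putative novel) miRNAs.

Folding is weighted base-pair maximisation (Nussinov dynamic programming,
GC=3, AU=2, GU=1 with a minimum loop of 3), a deterministic, exhaustively
testable stand-in for thermodynamic folding; ``fold_rna`` exposes the full
pairing map so alternative folders can be plugged in for comparison via the
``folder`` hook of :func:`classify_tags`.

Tags from one precursor arm form an isomiR group whose most abundant member
(ties: longer sequence, then lexicographically smaller) is the class
reference sequence; group counts are summed over members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from ._util import as_dna, find_matches, revcomp, scan_tags
from .readproc import Tags, UniqueTag

__all__ = [
    "TagAlignment",
    "Locus",
    "HairpinFold",
    "HairpinParams",
    "IsomiRGroup",
    "MiRNARecord",
    "AnnotateParams",
    "ClassificationResult",
    "align_tag",
    "cluster_genomic_hits",
    "extract_hairpin_candidate",
    "fold_rna",
    "evaluate_hairpin",
    "build_isomir_groups",
    "isomir_reference_correlation",
    "classify_tags",
    "write_loci_gff3",
]

MIN_LOOP = 3
PAIR_WEIGHTS = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2, ("G", "T"): 1, ("T", "G"): 1}


class TagAlignment(NamedTuple):
    tag: str
    ref_name: str
    tier: str  # known-precursor | conserved-precursor | genome | contaminant
    start: int  # 0-based, half-open end, forward-strand reference coordinates
    end: int
    strand: str
    mismatches: int


@dataclass
class Locus:
    contig: str
    start: int
    end: int
    strand: str
    members: dict[str, UniqueTag]

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HairpinParams:
    """Acceptance rules for a candidate precursor fold.

    Defaults are calibrated so constructed stem-loop precursors pass while
    random ~140-nt candidates essentially never do: the mature cluster must
    sit entirely on one arm of the dominant stem, at least 60% of its bases
    must pair into the opposite arm, at least ``min_helix_run`` of those
    pairs must be consecutively stacked (a mature with at most 2 mismatched
    positions always retains a stack of 7), the terminal loop must span
    3–25 nt and the total fold score must reach ``score_min`` (40 for
    ~140-nt candidates).
    """

    score_min: int = 40
    min_mature_paired_frac: float = 0.6
    min_helix_run: int = 6
    loop_min: int = 3
    loop_max: int = 25


@dataclass
class HairpinFold:
    """A nested pairing of a sequence: ``pairs[i]`` is the partner of ``i`` or -1."""

    sequence: str
    pairs: np.ndarray
    score: int
    min_loop: int = MIN_LOOP

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        p = self.pairs
        n = len(self.sequence)
        if len(p) != n:
            raise ValueError("pairing map length mismatch")
        opened: list[int] = []
        for i in range(n):
            j = int(p[i])
            if j == -1:
                continue
            if not 0 <= j < n or int(p[j]) != i or j == i:
                raise ValueError("pairing map is not an involution")
            if j > i:
                if abs(j - i) - 1 < self.min_loop:
                    raise ValueError("minimum loop violated")
                opened.append(j)
            else:
                if not opened or opened[-1] != i:
                    raise ValueError("crossing pairs")  # pseudoknot
                opened.pop()

    @property
    def n_pairs(self) -> int:
        return int((self.pairs >= 0).sum()) // 2

    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairs):
            out.append("." if j == -1 else ("(" if j > i else ")"))
        return "".join(out)

    def hairpin_loops(self) -> list[tuple[int, int]]:
        """Innermost pairs (i, j) with no paired base strictly between them."""
        loops = []
        p = self.pairs
        for i in range(len(p)):
            j = int(p[i])
            if j > i and all(p[k] == -1 for k in range(i + 1, j)):
                loops.append((i, j))
        return loops

    def dominant_stem(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None:
        """(loop pair, 5' arm interval, 3' arm interval) of the best-supported stem.

        The dominant stem is the hairpin loop enclosed by the most pairs
        (ties -> leftmost); arm intervals are half-open and span from the
        outermost enclosing pair to the loop-closing pair.
        """
        loops = self.hairpin_loops()
        if not loops:
            return None
        p = self.pairs
        all_pairs = [(i, int(p[i])) for i in range(len(p)) if int(p[i]) > i]
        best = None
        for (li, lj) in loops:
            enc = [(a, b) for a, b in all_pairs if a <= li and b >= lj]
            key = (len(enc), -li)
            if best is None or key > best[0]:
                pmin = min(a for a, _ in enc)
                qmax = max(b for _, b in enc)
                best = (key, (li, lj), (pmin, li + 1), (lj, qmax + 1))
        return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

def _weight_table(seq: str) -> np.ndarray:
    idx = np.full(256, 4, dtype=np.int64)
    for k, b in enumerate("ACGT"):
        idx[ord(b)] = k
    codes = idx[np.frombuffer(seq.encode(), dtype=np.uint8)]
    wtab = np.zeros((5, 5), dtype=np.int32)
    for (a, b), w in PAIR_WEIGHTS.items():
        wtab["ACGT".index(a), "ACGT".index(b)] = w
    return wtab[codes[:, None], codes[None, :]]


def fold_rna(sequence: str, min_loop: int = MIN_LOOP) -> HairpinFold:
    """Maximum weighted nested pairing by dynamic programming.

    Accepts DNA or RNA; U is treated as T. The recurrence is solved per
    anti-diagonal with vectorised candidate evaluation; the traceback is
    deterministic, preferring the admissible partner with the smallest left
    index for the rightmost base of each subproblem (which naturally extends
    helices inward).
    """
    seq = as_dna(sequence)
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    W = _weight_table(seq)
    M = np.zeros((n, n), dtype=np.int32)
    for d in range(min_loop + 1, n):
        i = np.arange(0, n - d)
        j = i + d
        best = M[i, j - 1].copy()  # j unpaired
        for t in range(0, d - min_loop):
            k = i + t
            w = W[k, j]
            left = M[i, k - 1] if t > 0 else 0
            cand = left + M[k + 1, j - 1] + w
            np.maximum(best, np.where(w > 0, cand, -1), out=best)
        M[i, j] = best
    pairs = np.full(n, -1, dtype=np.int64)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1 or M[i, j] == 0:
            continue
        target = M[i, j]
        chosen = -1
        for k in range(i, j - min_loop):
            if W[k, j] == 0:
                continue
            left = M[i, k - 1] if k > i else 0
            if left + M[k + 1, j - 1] + W[k, j] == target:
                chosen = k
                break
        if chosen == -1:
            stack.append((i, j - 1))
        else:
            pairs[chosen] = j
            pairs[j] = chosen
            if chosen - 1 > i:
                stack.append((i, chosen - 1))
            stack.append((chosen + 1, j - 1))
    return HairpinFold(sequence=seq, pairs=pairs, score=int(M[0, n - 1]), min_loop=min_loop)


def evaluate_hairpin(
    fold: HairpinFold,
    mature: tuple[int, int],
    params: HairpinParams | None = None,
) -> tuple[bool, dict]:
    """Decide whether a fold is an acceptable miRNA precursor hairpin.

    ``mature`` is the half-open interval of the mature (tag cluster) within
    the folded sequence. Returns (pass, diagnostics); diagnostics include the
    per-rule outcomes, the dominant stem geometry and the mature arm label.
    """
    params = params or HairpinParams()
    s, e = mature
    if not 0 <= s < e <= len(fold.sequence):
        raise ValueError("mature interval outside sequence")
    diag: dict = {"score": fold.score}
    stem = fold.dominant_stem()
    if stem is None:
        diag.update(has_stem=False)
        return False, diag
    (li, lj), arm5, arm3 = stem
    loop_len = lj - li - 1
    on5 = arm5[0] <= s and e <= arm5[1]
    on3 = arm3[0] <= s and e <= arm3[1]
    opposite = arm3 if on5 else arm5

    def is_cross(m: int) -> bool:
        return fold.pairs[m] != -1 and opposite[0] <= fold.pairs[m] < opposite[1]

    paired_cross = sum(1 for m in range(s, e) if is_cross(m))
    frac = paired_cross / (e - s)

    def is_wc(m: int) -> bool:
        return (fold.sequence[m], fold.sequence[int(fold.pairs[m])]) in (
            ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")
        )

    # longest run of consecutively stacked Watson-Crick cross-arm pairs in
    # the mature: the solid helix core a true precursor always retains, and
    # one a G.U-riddled chance pairing rarely reaches
    best_run = run = 0
    for m in range(s, e):
        if is_cross(m) and is_wc(m):
            run += 1
            best_run = max(best_run, run)
            if m + 1 < e and fold.pairs[m + 1] != fold.pairs[m] - 1:
                run = 0
        else:
            run = 0
    checks = {
        "mature_on_arm": on5 or on3,
        "mature_paired": frac >= params.min_mature_paired_frac,
        "helix_run": best_run >= params.min_helix_run,
        "score": fold.score >= params.score_min,
        "loop": params.loop_min <= loop_len <= params.loop_max,
    }
    diag.update(
        has_stem=True, loop=(li, lj), loop_len=loop_len, arm5=arm5, arm3=arm3,
        mature_arm="5p" if on5 else ("3p" if on3 else "loop"),
        mature_paired_frac=frac, helix_run=best_run, checks=checks,
    )
    return all(checks.values()), diag


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_tag(
    tag: str,
    references: Mapping[str, str],
    tier: str,
    max_mismatches: int = 1,
    strands: str = "+",
) -> list[TagAlignment]:
    """All ungapped full-tag placements on a set of references.

    ``strands`` is ``"+"`` (forward only; precursor tiers) or ``"+-"``
    (both; genome). Results are ordered by (reference name, start, strand).
    An N in the tag mismatches every reference base.
    """
    out: list[TagAlignment] = []
    for name in sorted(references):
        ref = references[name]
        for strand in strands:
            query = tag if strand == "+" else revcomp(tag)
            for start, mm in find_matches(query, ref, max_mismatches):
                out.append(TagAlignment(tag, name, tier, start, start + len(tag), strand, mm))
    out.sort(key=lambda a: (a.ref_name, a.start, a.strand))
    return out


class _RefIndex:
    """Concatenated reference set supporting batched tag scans."""

    def __init__(self, seqmap: Mapping[str, str]):
        self.names = sorted(seqmap)
        self.seqs = [seqmap[n] for n in self.names]
        self.offsets = []
        pos = 0
        parts = []
        for s in self.seqs:
            self.offsets.append(pos)
            parts.append(s)
            pos += len(s) + 1
        self.concat = "X".join(parts)
        self._starts = np.array(self.offsets, dtype=np.int64)

    def locate(self, pos: int, length: int) -> tuple[str, int] | None:
        i = int(np.searchsorted(self._starts, pos, side="right")) - 1
        local = pos - self.offsets[i]
        if local + length <= len(self.seqs[i]):
            return self.names[i], local
        return None  # placement crosses a record boundary

    def scan(self, tags: Sequence[str], max_mm: int) -> dict[str, list[tuple[str, int, int]]]:
        raw = scan_tags(tags, self.concat, max_mm)
        out: dict[str, list[tuple[str, int, int]]] = {}
        for tag, hits in raw.items():
            placed = []
            for pos, mm in hits:
                loc = self.locate(pos, len(tag))
                if loc is not None:
                    placed.append((loc[0], loc[1], mm))
            if placed:
                placed.sort()
                out[tag] = placed
        return out


# ---------------------------------------------------------------------------
# genomic clustering and candidate extraction
# ---------------------------------------------------------------------------

def cluster_genomic_hits(
    alignments: Sequence[TagAlignment],
    tags: Mapping[str, UniqueTag],
    max_gap: int = 10,
) -> list[Locus]:
    """Single-linkage clustering of genome alignments on (contig, strand).

    Two alignments join the same locus when the gap between them is at most
    ``max_gap`` nt (overlaps always join). Each tag should contribute one
    alignment; loci are returned sorted by (contig, start, strand).
    """
    loci: list[Locus] = []
    by_key: dict[tuple[str, str], list[TagAlignment]] = {}
    for a in alignments:
        by_key.setdefault((a.ref_name, a.strand), []).append(a)
    for (contig, strand), group in sorted(by_key.items()):
        group.sort(key=lambda a: (a.start, a.end))
        current: Locus | None = None
        for a in group:
            member = tags[a.tag] if a.tag in tags else UniqueTag(a.tag, 0, 0)
            if current is not None and a.start - current.end <= max_gap:
                current.end = max(current.end, a.end)
                current.members.setdefault(a.tag, member)
            else:
                current = Locus(contig, a.start, a.end, strand, {a.tag: member})
                loci.append(current)
    loci.sort(key=lambda l: (l.contig, l.start, l.strand))
    return loci


def extract_hairpin_candidate(
    genome: Mapping[str, str],
    locus: Locus,
    flank: int = 60,
) -> tuple[str, int]:
    """Locus sequence with up to ``flank`` nt of genomic context on each side.

    For minus-strand loci the candidate is reverse-complemented so the mature
    cluster reads 5'->3'. Returns (candidate, mature offset in candidate
    coordinates); flanks are truncated at contig edges.
    """
    contig = genome[locus.contig]
    if not 0 <= locus.start < locus.end <= len(contig):
        raise ValueError("locus outside contig bounds")
    left = max(0, locus.start - flank)
    right = min(len(contig), locus.end + flank)
    candidate = contig[left:right]
    if locus.strand == "-":
        candidate = revcomp(candidate)
        offset = right - locus.end
    else:
        offset = locus.start - left
    return candidate, offset


# ---------------------------------------------------------------------------
# isomiR consolidation
# ---------------------------------------------------------------------------

@dataclass
class IsomiRGroup:
    precursor: str
    arm: str
    members: dict[str, UniqueTag]
    reference: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty isomiR group")
        if not self.reference:
            self.reference = max(
                self.members,
                key=lambda s: (self.members[s].total, len(s), _lex_desc(s)),
            )

    @property
    def count_a(self) -> int:
        return sum(t.count_a for t in self.members.values())

    @property
    def count_b(self) -> int:
        return sum(t.count_b for t in self.members.values())

    @property
    def reference_tag(self) -> UniqueTag:
        return self.members[self.reference]


def _lex_desc(s: str):
    # sort key making lexicographically *smaller* strings win under max()
    return tuple(-ord(c) for c in s)


def build_isomir_groups(
    grouped: Mapping[tuple[str, str], Mapping[str, UniqueTag]]
) -> list[IsomiRGroup]:
    """One :class:`IsomiRGroup` per (precursor, arm) with its reference tag."""
    return [
        IsomiRGroup(precursor=prec, arm=arm, members=dict(members))
        for (prec, arm), members in sorted(grouped.items())
    ]


def isomir_reference_correlation(
    groups: Sequence[IsomiRGroup], library: str = "a"
) -> tuple[float, float]:
    """Spearman correlation of reference-tag counts vs group totals.

    The diagnostic behind using the most abundant isomiR as the class
    reference: across classes, the reference count should track the total.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 isomiR groups for a rank correlation")
    if library == "a":
        ref = [g.reference_tag.count_a for g in groups]
        tot = [g.count_a for g in groups]
    elif library == "b":
        ref = [g.reference_tag.count_b for g in groups]
        tot = [g.count_b for g in groups]
    else:
        raise ValueError("library must be 'a' or 'b'")
    res = stats.spearmanr(ref, tot)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotateParams:
    max_mismatches: int = 1
    cluster_gap: int = 10
    flank: int = 60
    min_novel_len: int = 19  # "longer than 18 nt"
    max_cluster_span: int = 30
    hairpin: HairpinParams = field(default_factory=HairpinParams)
    count_mode: str = "group"  # group sums vs reference-tag-only counts

    def __post_init__(self) -> None:
        if self.count_mode not in ("group", "reference"):
            raise ValueError("count_mode must be 'group' or 'reference'")


@dataclass
class MiRNARecord:
    name: str
    group: str  # known | conserved | PPN
    precursor: str
    reference_sequence: str
    count_a: int
    count_b: int
    star: bool = False


@dataclass
class ClassificationResult:
    records: list[MiRNARecord]
    unique_records: list[MiRNARecord]
    groups: list[IsomiRGroup]
    loci: list[Locus]
    assignments: dict[str, tuple[str, str, str]]  # seq -> (group, precursor, arm)
    unclassified: dict[str, tuple[int, int]]  # reason -> (tags, reads)
    folds: dict[str, tuple[HairpinFold, dict]]


def _seqmap(m: Mapping[str, object]) -> dict[str, str]:
    out = {}
    for name, v in m.items():
        out[name] = v if isinstance(v, str) else v.sequence  # type: ignore[union-attr]
    return out


def _arm_of(hit_start: int, tag_len: int, precursor_len: int) -> str:
    mid = hit_start + tag_len / 2
    return "5p" if mid < precursor_len / 2 else "3p"


def classify_tags(
    tags: Tags,
    bundle,
    params: AnnotateParams | None = None,
    folder: Callable[[str], HairpinFold] = fold_rna,
) -> ClassificationResult:
    """Run the full hierarchical classification on a high-quality tag set.

    ``bundle`` needs ``known_precursors`` and ``conserved_precursors``
    (mappings of name to sequence or to records with a ``sequence``
    attribute) and ``genome`` (mapping of contig name to sequence).
    """
    params = params or AnnotateParams()
    known = _seqmap(bundle.known_precursors)
    conserved = _seqmap(bundle.conserved_precursors)
    genome: Mapping[str, str] = bundle.genome
    seqs = sorted(tags)

    assignments: dict[str, tuple[str, str, str]] = {}
    unclassified_tags: dict[str, str] = {}
    grouped: dict[tuple[str, str], dict[str, UniqueTag]] = {}
    group_tier: dict[str, str] = {}

    def assign(seq: str, group: str, precursor: str, arm: str) -> None:
        assignments[seq] = (group, precursor, arm)
        grouped.setdefault((precursor, arm), {})[seq] = tags[seq]
        group_tier[precursor] = group

    # branch 1: known precursor tier (forward strand)
    remaining = list(seqs)
    if known:
        idx = _RefIndex(known)
        hits = idx.scan(remaining, params.max_mismatches)
        for seq in remaining:
            if seq in hits:
                name, start, _mm = min(hits[seq], key=lambda h: (h[2], h[0], h[1]))
                assign(seq, "known", name, _arm_of(start, len(seq), len(known[name])))
        remaining = [s for s in remaining if s not in assignments]

    # branch 2: conserved tier, precursor must also occur in the genome
    if conserved and remaining:
        genomic_cache: dict[str, bool] = {}

        def in_genome(name: str) -> bool:
            if name not in genomic_cache:
                seq = conserved[name]
                found = False
                for contig in genome.values():
                    if (
                        contig.find(seq) != -1
                        or contig.find(revcomp(seq)) != -1
                        or find_matches(seq, contig, params.max_mismatches)
                        or find_matches(revcomp(seq), contig, params.max_mismatches)
                    ):
                        found = True
                        break
                genomic_cache[name] = found
            return genomic_cache[name]

        idx = _RefIndex(conserved)
        hits = idx.scan(remaining, params.max_mismatches)
        for seq in remaining:
            if seq in hits:
                genomic = [h for h in hits[seq] if in_genome(h[0])]
                if genomic:
                    name, start, _mm = min(genomic, key=lambda h: (h[2], h[0], h[1]))
                    assign(seq, "conserved", name, _arm_of(start, len(seq), len(conserved[name])))
        remaining = [s for s in remaining if s not in assignments]

    # branches 3-4: genome-only tags, clustered and folded
    loci: list[Locus] = []
    folds: dict[str, tuple[HairpinFold, dict]] = {}
    if remaining:
        gidx = _RefIndex(dict(genome))
        rc_genome = {c: revcomp(s) for c, s in genome.items()}
        gidx_rc = _RefIndex(rc_genome)
        fwd = gidx.scan(remaining, params.max_mismatches)
        rev = gidx_rc.scan(remaining, params.max_mismatches)
        chosen: list[TagAlignment] = []
        for seq in remaining:
            cands: list[TagAlignment] = []
            for contig, start, mm in fwd.get(seq, []):
                cands.append(TagAlignment(seq, contig, "genome", start, start + len(seq), "+", mm))
            for contig, start, mm in rev.get(seq, []):
                fstart = len(genome[contig]) - start - len(seq)
                cands.append(TagAlignment(seq, contig, "genome", fstart, fstart + len(seq), "-", mm))
            if not cands:
                unclassified_tags[seq] = "unmapped"
                continue
            if len(seq) < params.min_novel_len:
                unclassified_tags[seq] = "too_short"
                continue
            cands.sort(key=lambda a: (a.mismatches, a.ref_name, a.start, a.strand))
            chosen.append(cands[0])
        loci = cluster_genomic_hits(chosen, tags, params.cluster_gap)
        for locus in loci:
            if locus.span > params.max_cluster_span:
                for seq in locus.members:
                    unclassified_tags[seq] = "wide_cluster"
                continue
            candidate, offset = extract_hairpin_candidate(genome, locus, params.flank)
            fold = folder(candidate)
            ok, diag = evaluate_hairpin(fold, (offset, offset + locus.span), params.hairpin)
            name = f"PPN-{locus.contig}-{locus.start + 1}"
            folds[name] = (fold, diag)
            if ok:
                arm = diag["mature_arm"]
                for seq in locus.members:
                    assign(seq, "PPN", name, arm)
            else:
                for seq in locus.members:
                    unclassified_tags[seq] = "no_hairpin"

    groups = build_isomir_groups(grouped)

    # star call: within a multi-arm precursor, the minor arm is the star
    arms_per_prec: dict[str, list[IsomiRGroup]] = {}
    for g in groups:
        arms_per_prec.setdefault(g.precursor, []).append(g)
    star_keys: set[tuple[str, str]] = set()
    for prec, gs in arms_per_prec.items():
        if len(gs) > 1:
            major = max(gs, key=lambda g: (g.count_a + g.count_b, g.arm == "5p"))
            star_keys.update((g.precursor, g.arm) for g in gs if g is not major)

    records: list[MiRNARecord] = []
    for g in groups:
        tier = group_tier[g.precursor]
        name = g.precursor if tier == "PPN" else f"{g.precursor}-{g.arm}"
        if tier == "PPN" and len(arms_per_prec[g.precursor]) > 1:
            name = f"{g.precursor}-{g.arm}"
        if params.count_mode == "reference":
            ca, cb = g.reference_tag.count_a, g.reference_tag.count_b
        else:
            ca, cb = g.count_a, g.count_b
        records.append(
            MiRNARecord(
                name=name, group=tier, precursor=g.precursor,
                reference_sequence=g.reference, count_a=ca, count_b=cb,
                star=(g.precursor, g.arm) in star_keys,
            )
        )
    order = {"known": 0, "conserved": 1, "PPN": 2}
    records.sort(key=lambda r: (order[r.group], r.name))

    # distinct precursors encoding the same mature collapse to one unique-sequence record
    unique: dict[str, MiRNARecord] = {}
    for r in records:
        u = unique.get(r.reference_sequence)
        if u is None:
            unique[r.reference_sequence] = MiRNARecord(
                name=r.name, group=r.group, precursor=r.precursor,
                reference_sequence=r.reference_sequence,
                count_a=r.count_a, count_b=r.count_b, star=r.star,
            )
        else:
            u.count_a += r.count_a
            u.count_b += r.count_b

    tally: dict[str, tuple[int, int]] = {}
    for seq, reason in unclassified_tags.items():
        t, rd = tally.get(reason, (0, 0))
        tally[reason] = (t + 1, rd + tags[seq].total)

    return ClassificationResult(
        records=records,
        unique_records=list(unique.values()),
        groups=groups,
        loci=loci,
        assignments=assignments,
        unclassified=tally,
        folds=folds,
    )


def write_loci_gff3(loci: Sequence[Locus], path: str | Path) -> None:
    """Export candidate loci as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, l in enumerate(loci):
            attrs = f"ID=locus{i};n_tags={len(l.members)}"
            fh.write(
                f"{l.contig}\tmirpipe\tmiRNA_locus\t{l.start + 1}\t{l.end}\t.\t{l.strand}\t.\t{attrs}\n"
            )
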