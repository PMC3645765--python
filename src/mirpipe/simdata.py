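"""Synthetic small RNA-seq data with known classification and expression truth.

Generates (1) a reference bundle — a genome with embedded hairpin precursors in
three tiers (species-known, other-mammal-conserved, novel-in-genome-only) plus
contaminant RNA records — and (2) paired two-condition FASTQ libraries whose
reads are isomiR mixtures around the mature sequences, with configurable
differential abundance, contaminant and junk read admixture. Every read gets a
truth row, so each downstream stage (filtering, classification, differential
calling) can be scored against ground truth.

Precursors are built as ``arm + loop + revcomp(arm)`` with 0–2 mismatches
injected into the 3' arm, so each locus is a true hairpin by construction and
classification truth is analytic. Reads carry uniform maximal base quality:
the filter cascade modelled here is sequence-based only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import random_dna, revcomp

__all__ = [
    "SimConfig",
    "Precursor",
    "Contaminant",
    "LocusTruth",
    "ReferenceBundle",
    "TruthTable",
    "SimRead",
    "CapacityError",
    "generate_references",
    "simulate_libraries",
    "write_fastq",
    "write_bundle",
    "isomir_variants",
    "variant_lookup",
    "classification_confusion",
    "de_performance",
]

CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")

#: Illumina small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class CapacityError(ValueError):
    """Genome too short to embed the requested loci without overlap."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults emulate a two-library small RNA-seq comparison: ~22-nt matures,
    isomiR offsets concentrated at 0, an 8-fold effect in a third of loci, and
    modest contaminant/junk admixture.
    """

    seed: int = 0
    genome_length: int = 60_000
    n_known_precursors: int = 20
    n_conserved_precursors: int = 10
    n_novel_loci: int = 20
    mature_length_mean: float = 22.0
    mature_length_sd: float = 0.8
    isomir_template_shifts: dict[int, float] = field(
        default_factory=lambda: {-2: 0.02, -1: 0.07, 0: 0.80, 1: 0.07, 2: 0.04}
    )
    library_depth: int = 100_000
    de_fraction: float = 0.3
    de_fold: float = 8.0
    contaminant_fraction: float = 0.10
    junk_fraction: float = 0.05
    adapter_sequence: str = DEFAULT_ADAPTER
    read_length: int = 40
    abundance_sigma: float = 1.0  # log-normal spread of per-locus abundance
    substitution_rate: float = 0.0
    n_contaminants_per_class: int = 3
    contaminant_length: int = 400
    n_fragments_per_contaminant: int = 8  # distinct expressed degradation fragments
    arm_pad: int = 4  # bases flanking the mature within each stem arm
    loop_length_range: tuple[int, int] = (8, 15)
    max_injected_mismatches: int = 2
    min_locus_separation: int = 150

    def __post_init__(self) -> None:
        for name in ("de_fraction", "contaminant_fraction", "junk_fraction", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.contaminant_fraction + self.junk_fraction > 1.0:
            raise ValueError("read-source fractions sum to more than 1")
        if self.de_fold <= 1.0:
            raise ValueError("de_fold must be > 1")
        probs = np.array(list(self.isomir_template_shifts.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("isomir_template_shifts probabilities must be >= 0 and sum to 1")
        if any(not -2 <= k <= 2 for k in self.isomir_template_shifts):
            raise ValueError("isomiR offsets must lie in [-2, 2]")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["loop_length_range"] = list(self.loop_length_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "loop_length_range" in d:
            d["loop_length_range"] = tuple(d["loop_length_range"])
        if "isomir_template_shifts" in d:
            d["isomir_template_shifts"] = {int(k): float(v) for k, v in d["isomir_template_shifts"].items()}
        return cls(**d)


@dataclass(frozen=True)
class Precursor:
    name: str
    sequence: str
    mature_start: int  # interval of the mature within the precursor, 0-based half-open
    mature_end: int
    arm: str = "5p"

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_start : self.mature_end]


@dataclass(frozen=True)
class Contaminant:
    name: str
    rna_class: str
    sequence: str


@dataclass(frozen=True)
class LocusTruth:
    """Ground-truth placement of one miRNA locus in the genome."""

    name: str
    tier: str  # known | conserved | novel
    contig: str
    start: int
    end: int
    strand: str
    precursor: Precursor


@dataclass
class ReferenceBundle:
    """Genome + two precursor tiers + contaminants, with ground-truth loci."""

    genome: dict[str, str]
    known_precursors: dict[str, Precursor]
    conserved_precursors: dict[str, Precursor]
    contaminants: list[Contaminant]
    loci: list[LocusTruth]  # ground truth, including novel loci; not a classification input

    def contig(self, name: str = "chr1") -> str:
        return self.genome[name]


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    quality: str


@dataclass
class TruthTable:
    """Per-read origins and per-miRNA expected abundance / DE status."""

    reads: pd.DataFrame  # read_id, library, source, locus, off5, off3
    mirnas: pd.DataFrame  # name, tier, mature, expected_a, expected_b, is_de, direction

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        self.reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        self.mirnas.to_csv(out / "truth_mirnas.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _assemble_genome(
    rng: np.random.Generator,
    length: int,
    placements: Sequence[tuple[int, str]],
    k: int = 6,
    window: int = 160,
) -> str:
    """Background DNA with embedded loci, constrained against chance hairpins.

    Background bases are resampled so that a Watson-Crick ``k``-stack cannot
    form within any ``window`` nt span of background, nor between background
    and a nearby embedded precursor: a helix of ``k`` stacked Watson-Crick
    pairs requires a ``k``-mer to co-occur with its reverse complement, and
    such co-occurrences are rejected during generation (both against the
    recent background and against the next placement's ``k``-mer set).
    Together with the fold-acceptance ``min_helix_run`` rule this makes "no
    hairpin locus outside the embedded precursors" hold by construction.
    Only ~4% of background bases are resampled, so composition and
    mappability stay essentially uniform. ``placements`` are (start,
    sequence), sorted and non-overlapping.
    """
    last_seen: dict[str, int] = {}
    out: list[str] = []

    def record(kmer: str) -> None:
        last_seen[kmer] = len(out) - 1

    def background_until(target: int, ahead: frozenset[str], ahead_from: int) -> None:
        while len(out) < target:
            i = len(out)
            base = "ACGT"[rng.integers(0, 4)]
            if i + 1 >= k:
                prefix = "".join(out[i - k + 1 :])
                for _attempt in range(12):
                    rc = revcomp(prefix + base)
                    prev = last_seen.get(rc)
                    clash = prev is not None and i - prev <= window
                    if not clash and i >= ahead_from:
                        clash = rc in ahead
                    if not clash:
                        break
                    base = "ACGT"[rng.integers(0, 4)]
                out.append(base)
                record(prefix + base)
            else:
                out.append(base)

    for start, seq in placements:
        kmers = frozenset(seq[j : j + k] for j in range(len(seq) - k + 1))
        background_until(start, kmers, max(0, start - window))
        for ch in seq:
            out.append(ch)
            if len(out) >= k:
                record("".join(out[-k:]))
    background_until(length, frozenset(), length)
    return "".join(out)


def _make_precursor(rng: np.random.Generator, name: str, cfg: SimConfig) -> Precursor:
    length = int(np.clip(round(rng.normal(cfg.mature_length_mean, cfg.mature_length_sd)), 20, 24))
    mature = random_dna(rng, length)
    pad = cfg.arm_pad
    arm5 = random_dna(rng, pad) + mature + random_dna(rng, pad)
    loop = random_dna(rng, int(rng.integers(cfg.loop_length_range[0], cfg.loop_length_range[1] + 1)))
    arm3 = list(revcomp(arm5))
    n_mm = int(rng.integers(0, cfg.max_injected_mismatches + 1))
    for pos in rng.choice(len(arm3), size=min(n_mm, len(arm3)), replace=False):
        current = arm3[pos]
        arm3[pos] = rng.choice([b for b in "ACGT" if b != current])
    seq = arm5 + loop + "".join(arm3)
    return Precursor(name=name, sequence=seq, mature_start=pad, mature_end=pad + length)


def generate_references(config: SimConfig) -> ReferenceBundle:
    """Build a deterministic reference bundle for ``config``.

    Known and conserved precursors are embedded verbatim on the + strand;
    novel loci are embedded on a random strand and appear only in the genome.
    Raises :class:`CapacityError` when the loci cannot be placed with the
    configured separation.
    """
    rng = np.random.default_rng([config.seed, 0])
    tiers = (
        [("known", f"ssc-mir-K{i:03d}") for i in range(config.n_known_precursors)]
        + [("conserved", f"cons-mir-C{i:03d}") for i in range(config.n_conserved_precursors)]
        + [("novel", f"novel-N{i:03d}") for i in range(config.n_novel_loci)]
    )
    precursors = [(tier, _make_precursor(rng, name, config)) for tier, name in tiers]

    sep = config.min_locus_separation
    total = sum(len(p.sequence) for _, p in precursors) + sep * (len(precursors) + 1)
    if total > config.genome_length:
        raise CapacityError(
            f"genome_length={config.genome_length} cannot hold {len(precursors)} loci "
            f"with separation {sep} (needs >= {total})"
        )

    # place loci left-to-right with random slack distributed between them
    order = rng.permutation(len(precursors))
    slack = config.genome_length - total
    cuts = np.sort(rng.integers(0, slack + 1, size=len(precursors))) if slack > 0 else np.zeros(len(precursors), int)
    loci: list[LocusTruth] = []
    placements: list[tuple[int, str]] = []
    cursor = sep
    prev_cut = 0
    for idx, cut in zip(order, cuts):
        cursor += int(cut) - prev_cut
        prev_cut = int(cut)
        tier, prec = precursors[idx]
        strand = "+" if tier != "novel" else ("+" if rng.random() < 0.5 else "-")
        embedded = prec.sequence if strand == "+" else revcomp(prec.sequence)
        start = cursor
        placements.append((start, embedded))
        loci.append(
            LocusTruth(
                name=prec.name, tier=tier, contig="chr1",
                start=start, end=start + len(embedded), strand=strand, precursor=prec,
            )
        )
        cursor += len(embedded) + sep
    genome = _assemble_genome(rng, config.genome_length, placements)

    contaminants = [
        Contaminant(
            name=f"{cls}-{i}", rna_class=cls,
            sequence=random_dna(rng, config.contaminant_length),
        )
        for cls in CONTAMINANT_CLASSES
        for i in range(config.n_contaminants_per_class)
    ]
    loci.sort(key=lambda l: l.start)
    return ReferenceBundle(
        genome={"chr1": "".join(genome)},
        known_precursors={p.name: p for t, p in precursors if t == "known"},
        conserved_precursors={p.name: p for t, p in precursors if t == "conserved"},
        contaminants=contaminants,
        loci=loci,
    )


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _mature_insert(prec: Precursor, off5: int, off3: int) -> str:
    s = prec.mature_start + off5
    e = prec.mature_end + off3
    s = max(s, 0)
    e = min(e, len(prec.sequence))
    return prec.sequence[s:e]


def isomir_variants(prec: Precursor, shifts: Mapping[int, float]) -> set[str]:
    """All insert sequences a locus can emit under a shift distribution."""
    offs = [k for k, p in shifts.items() if p > 0]
    return {_mature_insert(prec, o5, o3) for o5 in offs for o3 in offs}


def simulate_libraries(
    bundle: ReferenceBundle, config: SimConfig
) -> tuple[list[SimRead], list[SimRead], TruthTable]:
    """Draw two libraries of ``library_depth`` reads each, with truth rows.

    Per-locus baseline abundance is log-normal; loci flagged differentially
    expressed get their library-A weight multiplied and library-B weight
    divided by sqrt(de_fold) (or the reverse), so the expected A:B count
    ratio is ``de_fold``. Reads are insert + 3' adapter, padded with random
    bases and truncated to the machine read length.
    """
    rng = np.random.default_rng([config.seed, 1])
    loci = bundle.loci
    n = len(loci)
    if n == 0 and config.contaminant_fraction + config.junk_fraction < 1.0:
        raise ValueError("bundle has no miRNA loci but miRNA read fraction > 0")

    base_w = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    is_de = rng.random(n) < config.de_fraction
    # Directions are assigned by greedy mass balancing (heaviest DE locus
    # first, to the lighter side) so the two libraries' totals stay nearly
    # equal: the count tests compare proportions, and an imbalanced total
    # would shift every non-DE proportion by a common detectable factor.
    up_in_a = np.zeros(n, dtype=bool)
    mass_up = mass_down = 0.0
    for i in sorted(np.nonzero(is_de)[0], key=lambda k: -base_w[k]):
        if mass_up <= mass_down:
            up_in_a[i] = True
            mass_up += base_w[i]
        else:
            mass_down += base_w[i]
    f = np.sqrt(config.de_fold)
    w_a = base_w * np.where(is_de, np.where(up_in_a, f, 1.0 / f), 1.0)
    w_b = base_w * np.where(is_de, np.where(up_in_a, 1.0 / f, f), 1.0)

    p_mir = 1.0 - config.contaminant_fraction - config.junk_fraction
    frags = [
        rec.sequence[s : s + ln]
        for rec in bundle.contaminants
        for s, ln in zip(
            rng.integers(0, config.contaminant_length - 26, size=config.n_fragments_per_contaminant),
            rng.integers(18, 27, size=config.n_fragments_per_contaminant),
        )
    ]
    frag_origin = [rec.name for rec in bundle.contaminants for _ in range(config.n_fragments_per_contaminant)]
    offsets = np.array(sorted(config.isomir_template_shifts))
    offset_p = np.array([config.isomir_template_shifts[k] for k in offsets], dtype=float)

    def one_library(lib: str, weights: np.ndarray) -> tuple[list[SimRead], pd.DataFrame]:
        depth = config.library_depth
        reads: list[SimRead] = []
        rows: list[tuple] = []
        if depth == 0:
            return reads, pd.DataFrame(rows, columns=["read_id", "library", "source", "locus", "off5", "off3"])
        sources = rng.choice(3, size=depth, p=[p_mir, config.contaminant_fraction, config.junk_fraction])
        p_lib = weights / weights.sum() if n else None
        n_mir = int((sources == 0).sum())
        loci_idx = rng.choice(n, size=n_mir, p=p_lib) if n_mir else np.empty(0, int)
        o5 = rng.choice(offsets, size=n_mir, p=offset_p)
        o3 = rng.choice(offsets, size=n_mir, p=offset_p)
        n_cont = int((sources == 1).sum())
        frag_idx = rng.integers(0, len(frags), size=n_cont) if n_cont else np.empty(0, int)
        n_junk = int((sources == 2).sum())
        junk_len = rng.integers(10, 35, size=n_junk)
        junk_pool = random_dna(rng, int(junk_len.sum()) if n_junk else 0)
        pad_pool = random_dna(rng, config.read_length * 2)
        qual = "I" * config.read_length
        im = ic = ij = 0
        jcur = 0
        for i, src in enumerate(sources):
            rid = f"{lib}_{i:07d}"
            if src == 0:
                locus = loci[loci_idx[im]]
                insert = _mature_insert(locus.precursor, int(o5[im]), int(o3[im]))
                rows.append((rid, lib, locus.tier, locus.name, int(o5[im]), int(o3[im])))
                im += 1
            elif src == 1:
                insert = frags[frag_idx[ic]]
                rows.append((rid, lib, "contaminant", frag_origin[frag_idx[ic]], 0, 0))
                ic += 1
            else:
                ln = int(junk_len[ij])
                insert = junk_pool[jcur : jcur + ln]
                jcur += ln
                rows.append((rid, lib, "junk", "", 0, 0))
                ij += 1
            if config.substitution_rate > 0 and insert:
                chars = list(insert)
                hits = np.nonzero(rng.random(len(chars)) < config.substitution_rate)[0]
                for h in hits:
                    chars[h] = rng.choice([b for b in "ACGT" if b != chars[h]])
                insert = "".join(chars)
            seq = (insert + config.adapter_sequence + pad_pool)[: config.read_length]
            reads.append(SimRead(rid, seq, qual))
        return reads, pd.DataFrame(rows, columns=["read_id", "library", "source", "locus", "off5", "off3"])

    reads_a, rows_a = one_library("A", w_a)
    reads_b, rows_b = one_library("B", w_b)
    exp_a = config.library_depth * p_mir * (w_a / w_a.sum()) if n else np.empty(0)
    exp_b = config.library_depth * p_mir * (w_b / w_b.sum()) if n else np.empty(0)
    mirnas = pd.DataFrame(
        {
            "name": [l.name for l in loci],
            "tier": [l.tier for l in loci],
            "mature": [l.precursor.mature for l in loci],
            "expected_a": exp_a,
            "expected_b": exp_b,
            "is_de": is_de,
            "direction": np.where(is_de, np.where(up_in_a, "A-enriched", "B-enriched"), ""),
        }
    )
    truth = TruthTable(reads=pd.concat([rows_a, rows_b], ignore_index=True), mirnas=mirnas)
    return reads_a, reads_b, truth


# ---------------------------------------------------------------------------
# on-disk interchange
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[SimRead], path: str | Path) -> None:
    """Write 4-line FASTQ records with Sanger (offset-33) qualities."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_bundle(bundle: ReferenceBundle, out_dir: str | Path) -> None:
    """Write the bundle as FASTA files (genome, two precursor tiers, contaminants)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def recs(items: Sequence[tuple[str, str, str]]):
        return [SeqRecord(Seq(s), id=name, description=desc) for name, s, desc in items]

    seqio_write(recs([(c, s, "") for c, s in bundle.genome.items()]), out / "genome.fa", "fasta")
    seqio_write(
        recs([(p.name, p.sequence, f"mature={p.mature_start}-{p.mature_end}") for p in bundle.known_precursors.values()]),
        out / "known_precursors.fa", "fasta",
    )
    seqio_write(
        recs([(p.name, p.sequence, f"mature={p.mature_start}-{p.mature_end}") for p in bundle.conserved_precursors.values()]),
        out / "conserved_precursors.fa", "fasta",
    )
    seqio_write(
        recs([(c.name, c.sequence, f"class={c.rna_class}") for c in bundle.contaminants]),
        out / "contaminants.fa", "fasta",
    )


# ---------------------------------------------------------------------------
# truth-based scoring of pipeline output
# ---------------------------------------------------------------------------

def variant_lookup(bundle: ReferenceBundle, config: SimConfig) -> dict[str, str]:
    """Map every possible isomiR insert sequence to its locus name."""
    lut: dict[str, str] = {}
    for locus in bundle.loci:
        for v in isomir_variants(locus.precursor, config.isomir_template_shifts):
            lut.setdefault(v, locus.name)
    return lut


def classification_confusion(
    assignments: Mapping[str, tuple[str, str]],
    bundle: ReferenceBundle,
    config: SimConfig,
    tag_counts: Mapping[str, tuple[int, int]],
) -> pd.DataFrame:
    """Read-weighted confusion matrix of predicted vs true tier for miRNA tags.

    ``assignments`` maps tag sequence -> (group, precursor/locus); tags absent
    from it are counted as predicted 'unclassified'. Only tags whose sequence
    is a possible isomiR insert of a truth locus are scored.
    """
    lut = variant_lookup(bundle, config)
    tier_of = {l.name: l.tier for l in bundle.loci}
    counts: dict[tuple[str, str], int] = {}
    for seq, (ca, cb) in tag_counts.items():
        locus = lut.get(seq)
        if locus is None:
            continue
        true_tier = tier_of[locus]
        pred = assignments.get(seq, ("unclassified", ""))[0]
        pred = {"PPN": "novel"}.get(pred, pred)
        counts[(true_tier, pred)] = counts.get((true_tier, pred), 0) + ca + cb
    rows = sorted({k[0] for k in counts})
    cols = sorted({k[1] for k in counts})
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (t, p), c in counts.items():
        mat.loc[t, p] = c
    return mat


def offdiagonal_rate(confusion: pd.DataFrame) -> float:
    total = confusion.to_numpy().sum()
    if total == 0:
        return 0.0
    diag = sum(
        confusion.loc[t, t] for t in confusion.index if t in confusion.columns
    )
    return float((total - diag) / total)


def de_performance(
    de_names_by_direction: Mapping[str, str],
    bundle: ReferenceBundle,
    config: SimConfig,
    truth: TruthTable,
    record_sequences: Mapping[str, str],
) -> tuple[float, float]:
    """(sensitivity, false positive rate) of a DE call set against truth.

    ``de_names_by_direction`` maps called-DE record name -> direction;
    ``record_sequences`` maps every tested record name -> its reference
    sequence, used to link records to truth loci via the isomiR lookup.
    """
    lut = variant_lookup(bundle, config)
    truth_de = dict(zip(truth.mirnas["name"], truth.mirnas["is_de"]))
    called: set[str] = set()
    tested: set[str] = set()
    for name, seq in record_sequences.items():
        locus = lut.get(seq)
        if locus is None:
            continue
        tested.add(locus)
        if name in de_names_by_direction:
            called.add(locus)
    pos = [l for l in tested if truth_de.get(l, False)]
    neg = [l for l in tested if not truth_de.get(l, False)]
    sens = sum(1 for l in pos if l in called) / len(pos) if pos else float("nan")
    fpr = sum(1 for l in neg if l in called) / len(neg) if neg else 0.0
    return sens, fpr
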