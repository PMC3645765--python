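"""Downstream interpretation: target-list consensus, functional-category
tallies, qPCR normalization/validation and report generation.

Target prediction itself is external: three predictor output lists per miRNA
are consumed and the consensus keeps genes supported by at least two of the
three (the union of pairwise intersections). qPCR normalization follows the
qBase model: per gene, relative quantity Q = E^(Ct_min - Ct) with the gene's
minimum Ct as calibrator; each sample's normalization factor is the
geometric mean of its reference-gene Q values. The classic delta-delta-Ct
fold change (E = 2, reference-gene mean Ct) is provided alongside and agrees
with the qBase route in the single-reference, E = 2 case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult, de_table, percent

__all__ = [
    "TargetLists",
    "CategoryAnnotation",
    "QPCRPlate",
    "consensus_target_sets",
    "tag_functional_categories",
    "qbase_normalize",
    "deltadeltact_fold_change",
    "crossplatform_correlation",
    "write_report",
    "load_category_annotation",
    "load_qpcr_table",
]


# ---------------------------------------------------------------------------
# target-list consensus
# ---------------------------------------------------------------------------

@dataclass
class TargetLists:
    """Per-miRNA gene sets from three external predictors."""

    predictor_a: set[str]
    predictor_b: set[str]
    predictor_c: set[str]

    def __post_init__(self) -> None:
        self.predictor_a = {g.upper() for g in self.predictor_a}
        self.predictor_b = {g.upper() for g in self.predictor_b}
        self.predictor_c = {g.upper() for g in self.predictor_c}


def consensus_target_sets(lists: TargetLists, mode: str = "two-of-three") -> set[str]:
    """Genes supported by at least two predictors: (A∩B) ∪ (A∩C) ∪ (B∩C).

    ``mode='all-three'`` returns the stricter triple intersection instead.
    """
    a, b, c = lists.predictor_a, lists.predictor_b, lists.predictor_c
    if mode == "two-of-three":
        return (a & b) | (a & c) | (b & c)
    if mode == "all-three":
        return a & b & c
    raise ValueError("mode must be 'two-of-three' or 'all-three'")


# ---------------------------------------------------------------------------
# functional categories
# ---------------------------------------------------------------------------

@dataclass
class CategoryAnnotation:
    """miRNA -> category labels from a closed vocabulary."""

    vocabulary: tuple[str, ...]
    labels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vocab = set(self.vocabulary)
        for mirna, cats in self.labels.items():
            bad = [c for c in cats if c not in vocab]
            if bad:
                raise ValueError(f"labels {bad} for {mirna} not in declared vocabulary {sorted(vocab)}")


def load_category_annotation(path: str | Path) -> CategoryAnnotation:
    """Load a category TSV whose first line declares the vocabulary.

    Format::

        #categories: inflammation,diabetes
        miR-21\tinflammation
        miR-30a\tdiabetes
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#categories:"):
        raise ValueError("annotation file must start with a '#categories:' header")
    vocab = tuple(c.strip() for c in lines[0].split(":", 1)[1].split(",") if c.strip())
    labels: dict[str, list[str]] = {}
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        mirna, cat = line.split("\t")[:2]
        labels.setdefault(mirna, []).append(cat.strip())
    return CategoryAnnotation(vocabulary=vocab, labels={k: tuple(v) for k, v in labels.items()})


def tag_functional_categories(
    de: Sequence[DEResult], ann: CategoryAnnotation
) -> pd.DataFrame:
    """Per-category tallies of DE miRNAs split by enrichment direction.

    Rows are the declared categories plus an ``unannotated`` row; columns are
    total DE members, A-enriched and B-enriched members.
    """
    rows = {c: [0, 0, 0] for c in ann.vocabulary}
    rows["unannotated"] = [0, 0, 0]
    for r in de:
        if not r.de_flag:
            continue
        cats = ann.labels.get(r.name, ())
        targets = cats if cats else ("unannotated",)
        for c in targets:
            rows[c][0] += 1
            rows[c][1 if r.direction == "A-enriched" else 2] += 1
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["de_total", "a_enriched", "b_enriched"]
    ).rename_axis("category")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

@dataclass
class QPCRPlate:
    """Samples x genes Ct matrix with reference genes and efficiencies.

    ``ct`` has samples as the index and genes as columns; replicate Ct values
    are averaged before construction (see :func:`load_qpcr_table`).
    Efficiency E is per gene (default 2.0, perfect doubling per cycle).
    """

    ct: pd.DataFrame
    reference_genes: tuple[str, ...]
    efficiencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reference_genes:
            raise ValueError("at least one reference gene is required")
        missing = [g for g in self.reference_genes if g not in self.ct.columns]
        if missing:
            raise ValueError(f"reference genes {missing} absent from the Ct matrix")
        if self.ct.isna().any().any():
            raise ValueError("missing Ct values; fill or drop samples before analysis")
        if (self.ct <= 0).any().any():
            raise ValueError("Ct values must be positive")
        for g, e in self.efficiencies.items():
            if not 1.0 < e <= 2.0:
                raise ValueError(f"amplification efficiency for {g} must be in (1, 2], got {e}")

    def efficiency(self, gene: str) -> float:
        return self.efficiencies.get(gene, 2.0)

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.ct.columns if g not in self.reference_genes]


def load_qpcr_table(path: str | Path, reference_genes: Sequence[str],
                    efficiencies: Mapping[str, float] | None = None) -> QPCRPlate:
    """Read a long-format TSV (sample, gene, replicate, ct) into a plate.

    Replicate Ct values are averaged per (sample, gene).
    """
    df = pd.read_csv(path, sep="\t")
    ct = df.pivot_table(index="sample", columns="gene", values="ct", aggfunc="mean")
    return QPCRPlate(ct=ct, reference_genes=tuple(reference_genes),
                     efficiencies=dict(efficiencies or {}))


def qbase_normalize(plate: QPCRPlate) -> tuple[pd.DataFrame, pd.Series]:
    """qBase relative quantities and per-sample normalization factors.

    Per gene g and sample s: Q[s, g] = E_g^(min_s' Ct[s', g] - Ct[s, g]); the
    per-gene minimum Ct (highest expression) is the calibrator. NF(s) is the
    geometric mean of the reference-gene Q values; normalized quantity is
    Q / NF. Returns (normalized target quantities, NF series).
    """
    q = pd.DataFrame(index=plate.ct.index, columns=plate.ct.columns, dtype=float)
    for g in plate.ct.columns:
        e = plate.efficiency(g)
        q[g] = np.power(e, plate.ct[g].min() - plate.ct[g])
    nf = pd.Series(
        stats.gmean(q[list(plate.reference_genes)], axis=1), index=q.index, name="NF"
    )
    normalized = q[plate.target_genes].div(nf, axis=0)
    return normalized, nf


def deltadeltact_fold_change(
    plate: QPCRPlate,
    conditions: Mapping[str, str],
    condition_pair: tuple[str, str],
    targets: Sequence[str] | None = None,
) -> pd.Series:
    """Classic delta-delta-Ct fold changes between two conditions.

    ΔCt = Ct_target - mean(Ct of reference genes) per sample; ΔΔCt is the
    difference of condition-mean ΔCt values (condition 1 minus condition 2);
    fold change = 2^(-ΔΔCt), so a target amplifying 2 cycles earlier in
    condition 1 gives fold change 4. Assumes E = 2 throughout.
    """
    c1, c2 = condition_pair
    samples_1 = [s for s, c in conditions.items() if c == c1]
    samples_2 = [s for s, c in conditions.items() if c == c2]
    if not samples_1 or not samples_2:
        raise ValueError("both conditions need at least one sample")
    targets = list(targets) if targets is not None else plate.target_genes
    ref_ct = plate.ct[list(plate.reference_genes)].mean(axis=1)
    out = {}
    for t in targets:
        dct = plate.ct[t] - ref_ct
        ddct = dct.loc[samples_1].mean() - dct.loc[samples_2].mean()
        out[t] = 2.0 ** (-ddct)
    return pd.Series(out, name="fold_change")


def crossplatform_correlation(
    seq_fold_changes: Sequence[float], qpcr_fold_changes: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of log2 fold changes between sequencing and qPCR.

    Two-sided p via the t transform with n-2 degrees of freedom. Raises on
    fewer than 3 pairs or zero variance in either vector.
    """
    a = np.log2(np.asarray(seq_fold_changes, dtype=float))
    b = np.log2(np.asarray(qpcr_fold_changes, dtype=float))
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _abundance_strata(counts: Sequence[int]) -> dict[str, int]:
    c = np.asarray(counts)
    return {
        "low (<=100)": int((c <= 100).sum()),
        "mid (100, 1e5]": int(((c > 100) & (c <= 100_000)).sum()),
        "high (>1e5)": int((c > 100_000).sum()),
    }


def _top10_share(counts: Sequence[int]) -> float:
    c = np.sort(np.asarray(counts))[::-1]
    total = c.sum()
    return float(c[:10].sum() / total) if total else 0.0


def write_report(
    out_dir: str | Path,
    length_dist: Mapping[int, float],
    records: Sequence,
    partition: Mapping[str, Mapping[str, float | int]],
    de_results: Sequence[DEResult],
    category_table: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Emit the standard TSV report bundle plus a plain-text summary.

    Deterministic: rerunning on identical inputs produces byte-identical
    files. Returns the tables that were written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    tables["length_distribution"] = pd.DataFrame(
        {"length_nt": list(length_dist), "fraction": [length_dist[k] for k in length_dist]}
    ).sort_values("length_nt").reset_index(drop=True)

    groups = sorted({r.group for r in records})
    rows = []
    for g in groups:
        grp = [r for r in records if r.group == g]
        rows.append({"group": g, "n_mirnas": len(grp),
                     "reads_a": sum(r.count_a for r in grp),
                     "reads_b": sum(r.count_b for r in grp)})
    tables["group_breakdown"] = pd.DataFrame(rows)

    strata_rows = []
    for lib, attr in (("A", "count_a"), ("B", "count_b")):
        counts = [getattr(r, attr) for r in records if getattr(r, attr) > 0]
        strata = _abundance_strata(counts)
        strata_rows.append({"library": lib, **strata,
                            "top10_share_pct": percent(round(_top10_share(counts) * 1_000_000), 1_000_000)})
    tables["abundance_strata"] = pd.DataFrame(strata_rows)

    tables["partition"] = pd.DataFrame(
        [{"set": k, "count": v["count"], "pct": v["pct"]} for k, v in partition.items()]
    )

    tables["de"] = de_table(list(de_results))
    if category_table is not None:
        tables["categories"] = category_table.reset_index()

    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)

    n_de = sum(1 for r in de_results if r.de_flag)
    summary = [
        f"unique miRNAs: {len(records)}",
        f"shared between libraries: {partition['shared']['count']} ({partition['shared']['pct']}%)",
        f"A-specific: {partition['a_only']['count']} ({partition['a_only']['pct']}%)",
        f"B-specific: {partition['b_only']['count']} ({partition['b_only']['pct']}%)",
        f"abundance-filtered miRNAs tested: {len(de_results)}",
        f"differentially expressed (three-test consensus): {n_de}"
        + (f" ({percent(n_de, len(de_results))}%)" if de_results else ""),
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return tables
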