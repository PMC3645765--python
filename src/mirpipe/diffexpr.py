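"""Two-library differential expression by three-test consensus.

Each miRNA contributes a 2x2 table (count in library A vs B against the
library totals). Three tests are computed per miRNA — the Audic–Claverie
exact count test, Fisher's exact test, and the chi-squared 2x2 test — each
Bonferroni-corrected across the abundance-filtered miRNAs, and a miRNA is
called differentially expressed only when all three adjusted p-values fall
below alpha (0.001 by default). Low-abundance miRNAs (at most 1000 reads in
both libraries) are excluded before testing.

The Audic–Claverie conditional distribution

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

is the negative binomial with x+1 successes and success probability
N1/(N1+N2), which is how it is evaluated here (log-space, stable for counts
up to 1e7). The two-sided p-value doubles the smaller tail and caps at 1;
one-sided tails are available via ``sided``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, NamedTuple, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "CountPair",
    "DEParams",
    "DEResult",
    "audic_claverie_p",
    "fisher_exact_p",
    "chi_square_p",
    "bonferroni_adjust",
    "call_differential",
    "partition_by_library",
    "percent",
    "de_table",
]


class CountPair(NamedTuple):
    name: str
    x: int  # count in library A
    y: int  # count in library B
    n1: int  # total miRNA-mapped counts, library A
    n2: int  # total miRNA-mapped counts, library B

    def validate(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("library totals must be >= 1")
        if not (0 <= self.x <= self.n1 and 0 <= self.y <= self.n2):
            raise ValueError("counts must satisfy 0 <= x <= N1 and 0 <= y <= N2")


@dataclass(frozen=True)
class DEParams:
    abundance_min: int = 1000  # strict: tested iff x > abundance_min or y > abundance_min
    alpha: float = 0.001
    sided: str = "two"
    yates: bool = False
    adjust: bool = True  # Bonferroni across the tested miRNAs; False reproduces raw-p calling

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.abundance_min < 0:
            raise ValueError("abundance_min must be >= 0")
        if self.sided not in ("two", "less", "greater"):
            raise ValueError("sided must be 'two', 'less' or 'greater'")


@dataclass
class DEResult:
    pair: CountPair
    p_ac: float
    p_fisher: float
    p_chisq: float
    adj_ac: float
    adj_fisher: float
    adj_chisq: float
    de_flag: bool
    direction: str  # A-enriched | B-enriched

    @property
    def name(self) -> str:
        return self.pair.name


# ---------------------------------------------------------------------------
# the three tests
# ---------------------------------------------------------------------------

def audic_claverie_p(pair: CountPair, sided: str = "two") -> float:
    """Audic–Claverie exact p-value for a two-library count difference.

    Conditions on x: Y | x ~ NegBinom(x+1, N1/(N1+N2)). ``sided='two'``
    doubles the smaller of P(Y<=y) and P(Y>=y) and caps at 1; ``'less'`` and
    ``'greater'`` return the respective single tails.
    """
    pair.validate()
    x, y = pair.x, pair.y
    p_success = pair.n1 / (pair.n1 + pair.n2)
    lower = float(stats.nbinom.cdf(y, x + 1, p_success))  # P(Y <= y)
    upper = float(stats.nbinom.sf(y - 1, x + 1, p_success))  # P(Y >= y)
    if sided == "less":
        return min(1.0, lower)
    if sided == "greater":
        return min(1.0, upper)
    return min(1.0, 2.0 * min(lower, upper))


def fisher_exact_p(pair: CountPair) -> float:
    """Two-sided Fisher exact p for the table (x, N1-x; y, N2-y).

    Sums hypergeometric probabilities of all tables with fixed margins whose
    point probability is at most the observed one (within a small relative
    tolerance); degenerate margins give p = 1.
    """
    pair.validate()
    table = [[pair.x, pair.n1 - pair.x], [pair.y, pair.n2 - pair.y]]
    return float(min(1.0, stats.fisher_exact(table, alternative="two-sided")[1]))


def chi_square_p(pair: CountPair, yates: bool = False) -> float:
    """Chi-squared 2x2 test on (x, N1-x; y, N2-y), 1 degree of freedom.

    Without the Yates continuity correction by default: tested counts here
    are large (>1000 after the abundance filter), where the correction is
    negligible. A zero margin makes only one table possible; p = 1 with a
    warning.
    """
    pair.validate()
    a, b = pair.x, pair.n1 - pair.x
    c, d = pair.y, pair.n2 - pair.y
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        warnings.warn("zero margin in 2x2 table; chi-square undefined, returning p=1")
        return 1.0
    delta = abs(a * d - b * c)
    if yates:
        delta = max(0.0, delta - n / 2.0)
    statistic = n * delta * delta / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(stats.chi2.sf(statistic, df=1))


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

def call_differential(pairs: Sequence[CountPair], params: DEParams | None = None) -> list[DEResult]:
    """Abundance-filter, test, adjust and consensus-call a set of miRNAs.

    Retains pairs with x > abundance_min or y > abundance_min; m = number
    retained is the Bonferroni correction factor for all three tests. The DE
    flag requires all three adjusted p-values < alpha; direction compares the
    normalised proportions x/N1 vs y/N2.
    """
    params = params or DEParams()
    retained = [p for p in pairs if p.x > params.abundance_min or p.y > params.abundance_min]
    if not retained:
        warnings.warn("no miRNA passes the abundance filter; empty DE result")
        return []
    m = len(retained)
    results = []
    for pair in retained:
        p_ac = audic_claverie_p(pair, sided=params.sided)
        p_f = fisher_exact_p(pair)
        p_c = chi_square_p(pair, yates=params.yates)
        if params.adjust:
            adj = tuple(bonferroni_adjust(p, m) for p in (p_ac, p_f, p_c))
        else:
            adj = (p_ac, p_f, p_c)
        de = all(a < params.alpha for a in adj)
        direction = "A-enriched" if pair.x / pair.n1 >= pair.y / pair.n2 else "B-enriched"
        results.append(
            DEResult(
                pair=pair, p_ac=p_ac, p_fisher=p_f, p_chisq=p_c,
                adj_ac=adj[0], adj_fisher=adj[1], adj_chisq=adj[2],
                de_flag=de, direction=direction,
            )
        )
    return results


def de_table(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in results],
            "count_a": [r.pair.x for r in results],
            "count_b": [r.pair.y for r in results],
            "p_ac": [r.p_ac for r in results],
            "p_fisher": [r.p_fisher for r in results],
            "p_chisq": [r.p_chisq for r in results],
            "adj_ac": [r.adj_ac for r in results],
            "adj_fisher": [r.adj_fisher for r in results],
            "adj_chisq": [r.adj_chisq for r in results],
            "de_flag": [r.de_flag for r in results],
            "direction": [r.direction for r in results],
        }
    )


# ---------------------------------------------------------------------------
# library-specificity partition
# ---------------------------------------------------------------------------

def percent(part: int, whole: int) -> float:
    """Percentage rounded half-up to 2 decimals (printed-table convention)."""
    if whole == 0:
        return 0.0
    return float(
        (Decimal(part) * 100 / Decimal(whole)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def partition_by_library(records: Sequence) -> dict[str, dict[str, float | int]]:
    """Shared / A-only / B-only split of unique-sequence miRNA records.

    ``records`` may be objects with ``count_a``/``count_b`` attributes or
    (count_a, count_b) tuples. Percentages are of the total record count,
    rounded half-up to 2 decimals.
    """
    shared = a_only = b_only = 0
    for r in records:
        ca, cb = (r.count_a, r.count_b) if hasattr(r, "count_a") else (r[0], r[1])
        if ca > 0 and cb > 0:
            shared += 1
        elif ca > 0:
            a_only += 1
        elif cb > 0:
            b_only += 1
    total = shared + a_only + b_only
    return {
        "shared": {"count": shared, "pct": percent(shared, total)},
        "a_only": {"count": a_only, "pct": percent(a_only, total)},
        "b_only": {"count": b_only, "pct": percent(b_only, total)},
        "total": {"count": total, "pct": percent(total, total) if total else 0.0},
    }


def count_pairs_from_records(
    records: Sequence, totals: tuple[int, int] | None = None
) -> list[CountPair]:
    """Build :class:`CountPair` inputs from unique-sequence miRNA records.

    N1/N2 default to the totals of classified miRNA counts per library — the
    tests compare relative miRNA abundance — but explicit (raw-read) totals
    can be supplied instead.
    """
    counts: list[tuple[str, int, int]] = []
    for r in records:
        if hasattr(r, "count_a"):
            counts.append((r.name, r.count_a, r.count_b))
        else:
            name, ca, cb = r
            counts.append((name, ca, cb))
    if totals is None:
        n1 = sum(c[1] for c in counts)
        n2 = sum(c[2] for c in counts)
    else:
        n1, n2 = totals
    return [CountPair(name, ca, cb, n1, n2) for name, ca, cb in counts]
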