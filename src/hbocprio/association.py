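"""Case-control allele-count statistics.

A comparison between a cancer-patient group and a cancer-free group is a
2x2 table of alternate vs reference allele counts::

               alt        ref
    cases       a          b        (b = total alleles - alt alleles)
    controls    c          d

The two-sided Fisher exact p-value is the sum of hypergeometric point
probabilities, over all tables with the observed margins, that do not
exceed the observed table's point probability (relative tie tolerance
1e-7, the usual exact-test convention). The association odds ratio is the
sample cross-product ad/(bc); confidence intervals are available from the
Woolf log-OR normal approximation or by inverting the noncentral
hypergeometric likelihood (exact conditional).

Gene-level burden collapsing sums qualifying rare LoF alleles per gene in
each group before testing, comparing cumulative allele frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import classify_lof, is_last_exon

logger = logging.getLogger(__name__)

#: Relative tolerance for point-probability ties in the two-sided sum.
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class TwoByTwoTable:
    """Allele-count contingency table with fixed margins."""

    a: int  # case alt
    b: int  # case ref
    c: int  # control alt
    d: int  # control ref

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")

    @classmethod
    def from_counts(cls, case_alt: int, case_total: int, control_alt: int, control_total: int) -> "TwoByTwoTable":
        """Build from alt/total allele counts (ref = total - alt)."""
        if case_alt > case_total or control_alt > control_total:
            raise ValueError("alt alleles exceed total alleles")
        return cls(case_alt, case_total - case_alt, control_alt, control_total - control_alt)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AssociationResult:
    table: TwoByTwoTable
    p_two_sided: float
    odds_ratio: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    method: str
    degenerate_ci: bool = False
    n_qualifying_variants: Optional[int] = None


def fisher_two_sided(table: TwoByTwoTable) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums hypergeometric point probabilities (margins fixed) of all tables
    at most as probable as the observed one, with relative tie tolerance
    ``TIE_RTOL``. A zero margin makes every table certain; p is defined as
    1 with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1 = a + b  # case alleles
    c1 = a + c  # alt alleles
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        logger.warning("degenerate 2x2 table (zero margin): p defined as 1")
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + TIE_RTOL)].sum())
    return min(p, 1.0)


def _woolf_ci(table: TwoByTwoTable, alpha: float) -> tuple[float, float]:
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    a, b, c, d = table.a, table.b, table.c, table.d
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def odds_ratio_ci(
    table: TwoByTwoTable, method: str = "exact_conditional", alpha: float = 0.05
) -> AssociationResult:
    """Point odds ratio ad/(bc) with a (1 - alpha) confidence interval.

    ``method`` is ``"woolf"`` (normal approximation on log OR) or
    ``"exact_conditional"`` (inverts the noncentral hypergeometric
    likelihood). With any zero cell the point OR is degenerate (0 or inf)
    and the CI is omitted, flagged via ``degenerate_ci``; no continuity
    correction is applied.
    """
    if method not in ("woolf", "exact_conditional"):
        raise ValueError(f"unknown CI method {method!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    p = fisher_two_sided(table)
    if min(a, b, c, d) == 0:
        if a * d == 0 and b * c == 0:
            point = float("nan")
        elif b * c == 0:
            point = float("inf")
        else:
            point = 0.0
        return AssociationResult(table, p, point, None, None, method, degenerate_ci=True)
    point = (a * d) / (b * c)
    if method == "woolf":
        lo, hi = _woolf_ci(table, alpha)
    else:
        res = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
        ci = res.confidence_interval(confidence_level=1.0 - alpha)
        lo, hi = float(ci.low), float(ci.high)
    return AssociationResult(table, p, point, lo, hi, method)


@dataclass
class EmptyBurdenResult:
    """Explicit marker for a gene with no qualifying variants."""

    gene: str
    reason: str = "no qualifying variants"


def variant_qualifies_for_burden(
    annotation, maf_a: Optional[float], maf_b: Optional[float], maf_max: float = 0.001
) -> bool:
    """Burden qualification: LoF, not last-exon, rare in both panels.

    Panel-absent frequencies count as 0; an unknown exon position is
    treated conservatively as last-exon (excluded).
    """
    if not classify_lof(annotation):
        return False
    last = is_last_exon(annotation)
    if last is None or last:
        return False
    return (maf_a or 0.0) <= maf_max and (maf_b or 0.0) <= maf_max


def burden_collapse(
    gene: str,
    case_counts: Sequence[tuple[int, int]],
    control_counts: Sequence[tuple[int, int]],
    method: str = "exact_conditional",
):
    """Collapse per-variant (alt, total) allele counts for one gene.

    ``case_counts`` and ``control_counts`` are parallel sequences over the
    gene's qualifying variants. Cumulative alt alleles are compared against
    cumulative reference alleles across groups with the Fisher test.
    Returns :class:`EmptyBurdenResult` when there are no qualifying
    variants, never a silent p = 1.
    """
    if len(case_counts) != len(control_counts):
        raise ValueError("case and control variant lists differ in length")
    if not case_counts:
        return EmptyBurdenResult(gene)
    a = sum(alt for alt, _ in case_counts)
    b = sum(total - alt for alt, total in case_counts)
    c = sum(alt for alt, _ in control_counts)
    d = sum(total - alt for alt, total in control_counts)
    result = odds_ratio_ci(TwoByTwoTable(a, b, c, d), method=method)
    result.n_qualifying_variants = len(case_counts)
    return result


def bh_adjust(pvalues: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(list(pvalues), dtype=float)
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj.tolist()
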