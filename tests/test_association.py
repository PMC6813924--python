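"""Fisher exact test, odds ratios and burden collapsing.

The two-sided p implementation is checked against two independent routes:
an exact-arithmetic enumeration of the hypergeometric support (helpers)
and scipy's own fisher_exact.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from helpers import fisher_exact_bruteforce
from hbocprio.association import (
    AssociationResult,
    EmptyBurdenResult,
    TwoByTwoTable,
    burden_collapse,
    bh_adjust,
    fisher_two_sided,
    odds_ratio_ci,
    variant_qualifies_for_burden,
)
from hbocprio.annotation import ConsequenceAnnotation

# Printed study comparisons: (case alt, case total, control alt, control total,
# expected OR at 2 dp). The first and fourth rows also reproduce the printed
# p-values at 4 dp.
PUBLISHED_TABLES = [
    (169, 12388, 593, 54328, 1.25, 0.0114),
    (1792, 107410, 8652, 513585, 0.99, None),
    (374, 19799, 4517, 270628, 1.13, None),
    (44, 12392, 132, 54344, 1.46, 0.0325),
    (389, 108789, 1633, 520670, 1.14, None),
    (63, 20110, 850, 274273, 1.01, None),
]


@pytest.mark.parametrize("case_alt,case_total,ctrl_alt,ctrl_total,or2dp,p4dp", PUBLISHED_TABLES)
def test_published_allele_count_tables_reproduce(case_alt, case_total, ctrl_alt, ctrl_total, or2dp, p4dp):
    table = TwoByTwoTable.from_counts(case_alt, case_total, ctrl_alt, ctrl_total)
    res = odds_ratio_ci(table, method="exact_conditional")
    assert round(res.odds_ratio, 2) == or2dp
    if p4dp is not None:
        assert round(res.p_two_sided, 4) == p4dp


def test_published_confidence_intervals_consistent():
    # 169/12,388 vs 593/54,328 -> 1.25 (1.05-1.49); sparse table -> 1.46 (1.02-2.07)
    res = odds_ratio_ci(TwoByTwoTable.from_counts(169, 12388, 593, 54328))
    assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (1.05, 1.49)
    res = odds_ratio_ci(TwoByTwoTable.from_counts(44, 12392, 132, 54344))
    assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (1.02, 2.07)


def test_symmetric_table_gives_p_one():
    assert fisher_two_sided(TwoByTwoTable(5, 95, 5, 95)) == pytest.approx(1.0)


def test_zero_margin_defined_as_one():
    assert fisher_two_sided(TwoByTwoTable(0, 10, 0, 20)) == 1.0


@pytest.mark.parametrize(
    "table",
    [(1, 9, 11, 3), (0, 5, 8, 2), (3, 3, 3, 3), (7, 0, 2, 6), (2, 14, 9, 1), (1, 1, 1, 13)],
)
def test_fisher_matches_bruteforce_and_scipy(table):
    a, b, c, d = table
    p = fisher_two_sided(TwoByTwoTable(a, b, c, d))
    assert p == pytest.approx(fisher_exact_bruteforce(a, b, c, d), rel=1e-9)
    assert p == pytest.approx(stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-7)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 25)] * 4))
def test_fisher_invariances(cells):
    a, b, c, d = cells
    p = fisher_two_sided(TwoByTwoTable(a, b, c, d))
    assert 0.0 <= p <= 1.0
    # simultaneous row swap and simultaneous column swap leave p unchanged
    assert p == pytest.approx(fisher_two_sided(TwoByTwoTable(c, d, a, b)), rel=1e-12)
    assert p == pytest.approx(fisher_two_sided(TwoByTwoTable(b, a, d, c)), rel=1e-12)


def test_or_inverts_under_group_swap():
    res = odds_ratio_ci(TwoByTwoTable(12, 88, 5, 95), method="woolf")
    swapped = odds_ratio_ci(TwoByTwoTable(5, 95, 12, 88), method="woolf")
    assert res.odds_ratio == pytest.approx(1.0 / swapped.odds_ratio)


def test_woolf_ci_contains_point_estimate_and_formula():
    t = TwoByTwoTable(12, 88, 5, 95)
    res = odds_ratio_ci(t, method="woolf")
    assert res.ci_low < res.odds_ratio < res.ci_high
    se = math.sqrt(1 / 12 + 1 / 88 + 1 / 5 + 1 / 95)
    z = stats.norm.ppf(0.975)
    assert res.ci_low == pytest.approx(res.odds_ratio * math.exp(-z * se))
    assert res.ci_high == pytest.approx(res.odds_ratio * math.exp(z * se))


def test_woolf_ci_narrows_with_scaled_counts():
    widths = []
    for scale in (1, 4, 16):
        res = odds_ratio_ci(
            TwoByTwoTable(6 * scale, 94 * scale, 3 * scale, 97 * scale), method="woolf"
        )
        widths.append(math.log(res.ci_high) - math.log(res.ci_low))
    assert widths[0] > widths[1] > widths[2]


def test_zero_cell_degenerate_or():
    res = odds_ratio_ci(TwoByTwoTable(0, 10, 5, 5))
    assert res.odds_ratio == 0.0 and res.degenerate_ci and res.ci_low is None
    res = odds_ratio_ci(TwoByTwoTable(5, 5, 0, 10))
    assert res.odds_ratio == math.inf and res.degenerate_ci


def test_invalid_cells_rejected():
    with pytest.raises(ValueError):
        TwoByTwoTable(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        TwoByTwoTable.from_counts(10, 5, 0, 10)  # alt > total


# --- burden collapsing -----------------------------------------------------


def test_singleton_collapse_equals_per_variant_result():
    single = burden_collapse("G", [(4, 2000)], [(1, 20000)])
    direct = odds_ratio_ci(TwoByTwoTable.from_counts(4, 2000, 1, 20000))
    assert single.p_two_sided == direct.p_two_sided
    assert single.odds_ratio == direct.odds_ratio
    assert single.n_qualifying_variants == 1


def test_burden_sums_alt_and_ref_alleles():
    # 3 qualifying variants: (1,2,1)/2000 case alleles vs (0,1,0)/20000 controls
    res = burden_collapse(
        "G",
        [(1, 2000), (2, 2000), (1, 2000)],
        [(0, 20000), (1, 20000), (0, 20000)],
    )
    assert (res.table.a, res.table.b) == (4, 5996)
    assert (res.table.c, res.table.d) == (1, 59999)
    assert res.p_two_sided == pytest.approx(fisher_exact_bruteforce(4, 5996, 1, 59999), rel=1e-9)


def test_empty_burden_is_explicit():
    res = burden_collapse("G", [], [])
    assert isinstance(res, EmptyBurdenResult)
    assert res.gene == "G"


@pytest.mark.parametrize(
    "term,exon,maf_b,expected",
    [
        ("stop_gained", (2, 10), 0.0005, True),
        ("stop_gained", (10, 10), 0.0005, False),  # last exon contributes nothing
        ("stop_gained", (None, None), 0.0005, False),  # unknown position: conservative
        ("missense_variant", (2, 10), 0.0005, False),
        ("stop_gained", (2, 10), 0.002, False),  # too common in one panel
    ],
)
def test_burden_qualification_rule(term, exon, maf_b, expected):
    ann = ConsequenceAnnotation(
        gene="G", transcript_id="T", consequence_term=term,
        exon_rank=exon[0], exon_total=exon[1],
    )
    assert variant_qualifies_for_burden(ann, None, maf_b) is expected


def test_bh_adjustment_monotone_and_bounded():
    p = [0.001, 0.02, 0.02, 0.5, 0.9]
    adj = bh_adjust(p)
    assert all(a >= raw for a, raw in zip(adj, p))
    assert all(0 <= a <= 1 for a in adj)
    assert adj[0] == pytest.approx(0.005)
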