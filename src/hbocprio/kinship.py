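"""Pairwise kinship estimation and pedigree concordance checks.

The kinship coefficient phi of a pair is estimated from biallelic
genotype dosages with the KING-robust within-pair estimator,

    phi = (N_het,het - 2 * N_AA,aa) / (N_het(i) + N_het(j)),

where N_het,het counts sites at which both samples are heterozygous,
N_AA,aa counts opposite homozygotes, and the denominator sums each
sample's heterozygous-site counts over the sites used for the pair.
The estimator is robust to population structure and needs no external
allele frequencies. Identical samples give phi = 0.5 exactly; expected
values are 0.25 for first-degree relatives and ~0 for unrelated pairs.

Declared relationships are read off the pedigree by computing the
expected (pedigree) kinship coefficient recursively; observed estimates
falling below the unrelated cutoff for a declared close relationship are
flagged, and a sample discordant with every declared relative is
recommended for exclusion — the programmatic form of dropping a
misattributed family member before any segregation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import PedigreeCollection, VariantRecord

logger = logging.getLogger(__name__)

# Standard KING relationship-band cutoffs (powers of two around 2^-(d+3/2)).
DUPLICATE_CUTOFF = 0.354
FIRST_DEGREE_CUTOFF = 0.177
SECOND_DEGREE_CUTOFF = 0.0884
UNRELATED_CUTOFF = 0.0442  # below this: third-degree or less, treated unrelated


class UndefinedKinshipError(ValueError):
    """No heterozygous sites usable for the pair; phi is undefined."""


@dataclass(frozen=True)
class KinshipEstimate:
    sample_i: str
    sample_j: str
    phi: float
    n_both_het: int
    n_opposite_hom: int
    n_het_i: int
    n_het_j: int
    n_sites_used: int


def genotype_matrix(
    records: Sequence[VariantRecord], samples: Sequence[str], maf_floor: float = 0.0
) -> np.ndarray:
    """Samples x sites dosage matrix (np.nan = missing).

    Sites monomorphic in the cohort (cohort MAF 0, counting non-missing
    calls) are uninformative for kinship and are dropped; ``maf_floor``
    optionally drops additional near-monomorphic sites.
    """
    n, m = len(samples), len(records)
    G = np.full((n, m), np.nan)
    for j, rec in enumerate(records):
        for i, s in enumerate(samples):
            g = rec.genotypes.get(s)
            if g is not None and g.allele_count is not None:
                G[i, j] = g.allele_count
    with np.errstate(invalid="ignore"):
        called = np.sum(~np.isnan(G), axis=0)
        alt = np.nansum(G, axis=0)
    freq = np.divide(alt, 2.0 * called, out=np.zeros(G.shape[1]), where=called > 0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (called > 0) & (freq > 0) & (freq < 1) & (maf >= maf_floor)
    return G[:, keep]


def estimate_kinship(G: np.ndarray, i: int, j: int, sample_ids: Optional[Sequence[str]] = None) -> KinshipEstimate:
    """KING-robust kinship for the pair (i, j) of rows of ``G``.

    Missing genotypes are dropped pairwise. Raises
    :class:`UndefinedKinshipError` when neither sample is heterozygous at
    any shared site (denominator zero) — never a silent 0.
    """
    gi, gj = G[i], G[j]
    valid = ~np.isnan(gi) & ~np.isnan(gj)
    gi, gj = gi[valid], gj[valid]
    n_both_het = int(np.sum((gi == 1) & (gj == 1)))
    n_opp_hom = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    n_het_i = int(np.sum(gi == 1))
    n_het_j = int(np.sum(gj == 1))
    denom = n_het_i + n_het_j
    name_i = sample_ids[i] if sample_ids is not None else str(i)
    name_j = sample_ids[j] if sample_ids is not None else str(j)
    if denom == 0:
        raise UndefinedKinshipError(
            f"no heterozygous sites for pair ({name_i}, {name_j}); phi undefined"
        )
    phi = (n_both_het - 2 * n_opp_hom) / denom
    return KinshipEstimate(
        name_i, name_j, phi, n_both_het, n_opp_hom, n_het_i, n_het_j, int(valid.sum())
    )


def kinship_table(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    maf_floor: float = 0.0,
) -> pd.DataFrame:
    """Kinship estimates for the given sample pairs (default: all pairs)."""
    G = genotype_matrix(records, samples, maf_floor=maf_floor)
    idx = {s: k for k, s in enumerate(samples)}
    if pairs is None:
        pairs = [(samples[i], samples[j]) for i in range(len(samples)) for j in range(i + 1, len(samples))]
    rows = []
    for si, sj in pairs:
        try:
            est = estimate_kinship(G, idx[si], idx[sj], sample_ids=list(samples))
            rows.append(
                {
                    "sample_i": si,
                    "sample_j": sj,
                    "phi": est.phi,
                    "n_both_het": est.n_both_het,
                    "n_opposite_hom": est.n_opposite_hom,
                    "n_het_i": est.n_het_i,
                    "n_het_j": est.n_het_j,
                    "n_sites_used": est.n_sites_used,
                }
            )
        except UndefinedKinshipError:
            logger.warning("kinship undefined for pair (%s, %s); omitted", si, sj)
    return pd.DataFrame(rows)


def expected_kinship(pedigrees: PedigreeCollection) -> Dict[Tuple[str, str], float]:
    """Pedigree-expected kinship coefficients for all within-family pairs.

    Uses the standard recursion: phi(x, x) = (1 + phi(f, m)) / 2 and, with
    x not an ancestor of y, phi(x, y) = (phi(f_x, y) + phi(m_x, y)) / 2,
    founders unrelated.
    """
    out: Dict[Tuple[str, str], float] = {}
    for ped in pedigrees.families.values():
        members = ped.members

        depth_memo: Dict[str, int] = {}

        def depth(s: Optional[str]) -> int:
            if s is None or s not in members:
                return 0
            if s not in depth_memo:
                ind = members[s]
                depth_memo[s] = 1 + max(depth(ind.father_id), depth(ind.mother_id))
            return depth_memo[s]

        @lru_cache(maxsize=None)
        def phi(x: Optional[str], y: Optional[str]) -> float:
            if x is None or y is None:
                return 0.0
            if x == y:
                ind = members[x]
                return 0.5 * (1.0 + phi_ordered(ind.father_id, ind.mother_id))
            return phi_ordered(x, y)

        def phi_ordered(x: Optional[str], y: Optional[str]) -> float:
            if x is None or y is None:
                return 0.0
            if x == y:
                return phi(x, x)
            # recurse through the deeper individual's parents
            if depth(x) < depth(y):
                x, y = y, x
            ind = members[x]
            if ind.is_founder:
                return 0.0
            return 0.5 * (phi(ind.father_id, y) + phi(ind.mother_id, y))

        ids = sorted(members)
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                out[(ids[a], ids[b])] = phi(ids[a], ids[b])
        phi.cache_clear()
    return out


@dataclass
class DiscordantPair:
    sample_i: str
    sample_j: str
    family_id: str
    expected_phi: float
    observed_phi: float


@dataclass
class DiscordanceReport:
    discordant_pairs: List[DiscordantPair]
    exclusions: List[str]  # samples discordant with ALL declared relatives


def flag_pedigree_discordance(
    kin: pd.DataFrame,
    pedigrees: PedigreeCollection,
    unrelated_cutoff: float = UNRELATED_CUTOFF,
    min_informative_hets: int = 100,
) -> DiscordanceReport:
    """Compare observed kinship with pedigree expectation.

    A declared close pair (expected phi at or above the second-degree band)
    whose observed phi falls below ``unrelated_cutoff`` is flagged; a
    sample flagged against every one of its declared relatives is
    recommended for exclusion from all downstream analyses.

    Pairs whose phi denominator (summed heterozygous-site counts) falls
    below ``min_informative_hets`` are too noisy to call unrelated and are
    skipped rather than flagged.
    """
    expected = expected_kinship(pedigrees)
    observed: Dict[Tuple[str, str], float] = {}
    informative: Dict[Tuple[str, str], int] = {}
    for row in kin.itertuples(index=False):
        for pair in ((row.sample_i, row.sample_j), (row.sample_j, row.sample_i)):
            observed[pair] = row.phi
            informative[pair] = int(row.n_het_i + row.n_het_j)

    pairs: List[DiscordantPair] = []
    n_declared: Dict[str, int] = {}
    n_discordant: Dict[str, int] = {}
    for (si, sj), exp_phi in sorted(expected.items()):
        if exp_phi < SECOND_DEGREE_CUTOFF:
            continue  # distant declared relationships are not testable against the unrelated cutoff
        if (si, sj) not in observed:
            continue
        if informative[(si, sj)] < min_informative_hets:
            logger.warning(
                "pair (%s, %s): only %d informative het sites; discordance not assessed",
                si,
                sj,
                informative[(si, sj)],
            )
            continue
        obs = observed[(si, sj)]
        fam = pedigrees.family_of(si)
        n_declared[si] = n_declared.get(si, 0) + 1
        n_declared[sj] = n_declared.get(sj, 0) + 1
        if obs < unrelated_cutoff:
            pairs.append(DiscordantPair(si, sj, fam, exp_phi, obs))
            n_discordant[si] = n_discordant.get(si, 0) + 1
            n_discordant[sj] = n_discordant.get(sj, 0) + 1
    exclusions = sorted(
        s for s, nd in n_discordant.items() if nd == n_declared.get(s, 0) and nd > 0
    )
    return DiscordanceReport(pairs, exclusions)


def relationship_class(phi: float) -> str:
    """KING band for an observed phi (duplicate / first / second degree / unrelated)."""
    if phi >= DUPLICATE_CUTOFF:
        return "duplicate"
    if phi >= FIRST_DEGREE_CUTOFF:
        return "first_degree"
    if phi >= SECOND_DEGREE_CUTOFF:
        return "second_degree"
    if phi >= UNRELATED_CUTOFF:
        return "third_degree"
    return "unrelated"
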