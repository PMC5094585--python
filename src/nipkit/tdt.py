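"""Transmission disequilibrium testing for SNPs and short haplotypes.

The transmission disequilibrium test (TDT) compares, over heterozygous
parents of affected children, how often an allele (or haplotype) is
transmitted (T) versus not transmitted (U). Under the null of no linked
association T ~ Binomial(T+U, 1/2) and the McNemar statistic

    chi2 = (T - U)^2 / (T + U)

is asymptotically chi-square with 1 df.

Haplotype windows of 1-3 SNPs within a gene are phased per trio by
exhaustive Mendelian-constraint enumeration; trios whose consistent
assignments disagree on the transmitted/untransmitted haplotype pairs
are ambiguous and dropped. X-linked genes contribute maternal
transmissions only; pseudoautosomal panels are analysed as autosomal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .pedigree import (
    Cohort,
    Family,
    Marker,
    affected_in_subgroup,
    mendel_check,
    subset_cohort,
    transmission_assignments,
)

logger = logging.getLogger(__name__)

#: Sentinel returned when a trio's phase cannot be resolved uniquely.
AMBIGUOUS = "AMBIGUOUS"

#: Default "major haplotype" frequency filter.
MAJOR_HAPLOTYPE_FREQ = 0.05


@dataclass(frozen=True)
class Haplotype:
    window: tuple[str, ...]
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.window) != len(self.alleles):
            raise ValueError("haplotype alleles must match window length")

    def __str__(self) -> str:
        return "|".join(self.alleles)


@dataclass
class TransmissionCount:
    unit: str | Haplotype
    T: int = 0
    U: int = 0


@dataclass(frozen=True)
class TdtStat:
    chi_square: float
    p_value: float


@dataclass
class TdtResult:
    gene: str
    window: tuple[str, ...]
    unit: str | Haplotype
    subgroup: str
    haplotype_frequency: float
    count: TransmissionCount
    stat: TdtStat
    p_corrected: float = float("nan")
    n_tests: int = 1


def tdt_statistic(T: int, U: int) -> TdtStat | None:
    """McNemar chi-square of transmitted vs untransmitted counts.

    Returns None for a zero-information unit (T + U = 0): no test is
    defined, and callers report such units as no-test rows rather than
    p = 1.
    """
    if T < 0 or U < 0:
        raise ValueError("counts must be non-negative")
    n = T + U
    if n == 0:
        return None
    chi2 = (T - U) ** 2 / n
    return TdtStat(float(chi2), float(stats.chi2.sf(chi2, df=1)))


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p-value, min(1, p * n_tests)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    if n_tests < 1:
        raise ValueError("n_tests must be a positive integer")
    return min(1.0, p * n_tests)


# ---------------------------------------------------------------------------
# single-SNP counting


def count_snp_transmissions(
    family: Family,
    marker: Marker,
    affected_filter: str = "IBD",
) -> dict[str, TransmissionCount]:
    """Allele-level T/U counts contributed by one family at one marker.

    Every (heterozygous parent, affected child) pair in a fully genotyped
    trio contributes one transmitted and one untransmitted allele;
    homozygous parents contribute nothing. A Mendelian violation at the
    marker skips the whole family with a logged reason. X-linked markers
    count maternal transmissions only; pseudoautosomal markers are
    autosomal.
    """
    chrom = "autosome" if marker.chromosome == "pseudoautosomal" else marker.chromosome
    counts = {a: TransmissionCount(a) for a in marker.alleles}
    if mendel_check(family, marker):
        logger.info(
            "family %s skipped at %s: Mendelian inconsistency", family.id, marker.id
        )
        return counts
    for father, mother, child in family.trios():
        if not affected_in_subgroup(child, affected_filter):
            continue
        fgt, mgt, cgt = (
            p.genotype(marker.id) for p in (father, mother, child)
        )
        if fgt.is_missing or mgt.is_missing or cgt.is_missing:
            continue
        assignments = transmission_assignments(
            fgt.alleles, mgt.alleles, cgt.alleles, chrom, child.sex
        )
        if not assignments:
            continue  # unreachable after the family-level check; defensive
        deltas = set()
        for tf, tm in assignments:
            delta: list[tuple[str, str, str]] = []
            if chrom != "X" and fgt.allele_1 != fgt.allele_2:
                other = fgt.allele_1 if tf == fgt.allele_2 else fgt.allele_2
                delta.append(("F", tf, other))  # type: ignore[arg-type]
            if mgt.allele_1 != mgt.allele_2:
                other = mgt.allele_1 if tm == mgt.allele_2 else mgt.allele_2
                delta.append(("M", tm, other))
            deltas.add(tuple(sorted(delta)))
        # biallelic markers: consistent assignments agree on allele counts
        delta = sorted(deltas)[0]
        for _parent, transmitted, untransmitted in delta:
            counts[transmitted].T += 1
            counts[untransmitted].U += 1
    return counts


# ---------------------------------------------------------------------------
# haplotype windows and trio phasing


def enumerate_marker_windows(
    gene_panel: Sequence[Marker], sizes: Iterable[int] = (1, 2, 3)
) -> list[tuple[Marker, ...]]:
    """All order-preserving marker subsets of the requested sizes.

    Sizes exceeding the panel length are skipped. Deterministic ordering:
    ascending size, then position order.
    """
    if not gene_panel:
        raise ValueError("empty gene panel")
    windows: list[tuple[Marker, ...]] = []
    for size in sorted(set(sizes)):
        if size < 1 or size > len(gene_panel):
            continue
        windows.extend(combinations(gene_panel, size))
    return windows


def _splits(genotype: tuple[tuple[str, str], ...]) -> set[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Unordered haplotype-pair decompositions of a multilocus genotype."""
    per_marker = [((a, b),) if a == b else ((a, b), (b, a)) for a, b in genotype]
    pairs = set()
    for choice in product(*per_marker):
        h1 = tuple(c[0] for c in choice)
        h2 = tuple(c[1] for c in choice)
        pairs.add(tuple(sorted((h1, h2))))  # type: ignore[arg-type]
    return pairs  # type: ignore[return-value]


@lru_cache(maxsize=200_000)
def _phase_cached(
    father: tuple[tuple[str, str], ...],
    mother: tuple[tuple[str, str], ...],
    child: tuple[tuple[str, str], ...],
    chromosome: str,
    child_sex: int,
) -> tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] | str | None:
    w = len(child)

    def fits(hf: tuple[str, ...], hm: tuple[str, ...]) -> bool:
        return all(tuple(sorted((hf[i], hm[i]))) == child[i] for i in range(w))

    contributions = set()
    if chromosome == "X":
        msplits = _splits(mother)
        if child_sex == 1:
            if any(a != b for a, b in child):
                return None
            chap = tuple(a for a, _ in child)
            for m1, m2 in msplits:
                for mt, mu in ((m1, m2), (m2, m1)):
                    if mt == chap:
                        contributions.add(((mt, mu),))
        else:
            if any(a != b for a, b in father):
                return None
            fhap = tuple(a for a, _ in father)
            for m1, m2 in msplits:
                for mt, mu in ((m1, m2), (m2, m1)):
                    if fits(fhap, mt):
                        contributions.add(((mt, mu),))
    else:
        for f1, f2 in _splits(father):
            for m1, m2 in _splits(mother):
                for ft, fu in ((f1, f2), (f2, f1)):
                    for mt, mu in ((m1, m2), (m2, m1)):
                        if fits(ft, mt):
                            contributions.add(tuple(sorted(((ft, fu), (mt, mu)))))
    if not contributions:
        return None
    if len(contributions) > 1:
        return AMBIGUOUS
    return next(iter(contributions))


def phase_trio_haplotypes(
    father: Sequence[tuple[str, str]],
    mother: Sequence[tuple[str, str]],
    child: Sequence[tuple[str, str]],
    chromosome: str = "autosome",
    child_sex: int = 2,
) -> list[tuple[tuple[str, ...], tuple[str, ...]]] | str | None:
    """Resolve per-parent (transmitted, untransmitted) haplotypes for a trio.

    Genotypes are per-marker unordered allele pairs over the window. All
    parental haplotype assignments consistent with Mendelian transmission
    are enumerated; when every consistent assignment implies the same
    unordered set of per-parent (transmitted, untransmitted) haplotype
    pairs, that set is returned (one pair per contributing parent — both
    parents for autosomal windows, the mother only for X-linked windows).
    Otherwise :data:`AMBIGUOUS`. ``None`` marks a trio excluded outright:
    Mendelian-inconsistent, or malformed hemizygous coding.

    Missing genotypes must be screened by the caller (trios with missing
    window genotypes are excluded before phasing).
    """
    if chromosome == "pseudoautosomal":
        chromosome = "autosome"
    fkey = tuple(tuple(sorted(g)) for g in father)
    mkey = tuple(tuple(sorted(g)) for g in mother)
    ckey = tuple(tuple(sorted(g)) for g in child)
    result = _phase_cached(fkey, mkey, ckey, chromosome, child_sex)
    if result is None or result == AMBIGUOUS:
        return result
    return list(result)


# ---------------------------------------------------------------------------
# haplotype TDT


def _window_genotypes(individual, window: Sequence[Marker]):
    gts = [individual.genotype(m.id) for m in window]
    if any(g.is_missing for g in gts):
        return None
    return tuple(g.alleles for g in gts)


def haplotype_tdt(
    cohort: Cohort,
    window: Sequence[Marker],
    subgroup: str = "IBD",
    min_freq: float = MAJOR_HAPLOTYPE_FREQ,
) -> list[TdtResult]:
    """Pooled haplotype T/U counts and TDT statistics over one window.

    The cohort is assumed to be the already-selected subgroup; ``subgroup``
    sets the affected rule for transmission counting and labels the output.
    Haplotype frequencies are estimated from the phased parental
    haplotypes of unambiguous trios, and results are filtered to major
    haplotypes (frequency > ``min_freq``). Zero-information haplotypes
    yield no row.
    """
    chrom = window[0].chromosome
    if any(m.chromosome != chrom for m in window):
        raise ValueError("window mixes chromosome classes")
    if chrom == "pseudoautosomal":
        chrom = "autosome"
    gene = window[0].gene
    window_ids = tuple(m.id for m in window)

    T: dict[tuple[str, ...], int] = {}
    U: dict[tuple[str, ...], int] = {}
    pool: dict[tuple[str, ...], int] = {}
    n_pool = 0
    for family in cohort.families:
        for father, mother, child in family.trios():
            if not affected_in_subgroup(child, subgroup):
                continue
            fgt = _window_genotypes(father, window)
            mgt = _window_genotypes(mother, window)
            cgt = _window_genotypes(child, window)
            if fgt is None or mgt is None or cgt is None:
                continue
            phased = phase_trio_haplotypes(fgt, mgt, cgt, chrom, child.sex)
            if phased is None or phased == AMBIGUOUS:
                continue
            for transmitted, untransmitted in phased:
                for hap in (transmitted, untransmitted):
                    pool[hap] = pool.get(hap, 0) + 1
                    n_pool += 1
                if transmitted != untransmitted:
                    T[transmitted] = T.get(transmitted, 0) + 1
                    U[untransmitted] = U.get(untransmitted, 0) + 1

    results: list[TdtResult] = []
    for hap in sorted(pool):
        freq = pool[hap] / n_pool
        if freq <= min_freq:
            continue
        t, u = T.get(hap, 0), U.get(hap, 0)
        stat = tdt_statistic(t, u)
        if stat is None:
            continue
        results.append(
            TdtResult(
                gene=gene,
                window=window_ids,
                unit=Haplotype(window_ids, hap),
                subgroup=subgroup,
                haplotype_frequency=freq,
                count=TransmissionCount(Haplotype(window_ids, hap), t, u),
                stat=stat,
            )
        )
    return results


def run_gene_scan(
    cohort: Cohort,
    gene_panels: Mapping[str, Sequence[Marker]],
    subgroups: Iterable[str] = ("IBD", "CD", "UC", "CD_nod2_mutated", "CD_nod2_wildtype"),
    sizes: Iterable[int] = (1, 2, 3),
    min_freq: float = MAJOR_HAPLOTYPE_FREQ,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full genes x windows x subgroups haplotype-TDT scan.

    Bonferroni correction is per gene within each subgroup: ``n_tests`` is
    the number of haplotype tests actually performed for that gene (after
    the frequency filter). Rows are flagged significant at corrected
    p < ``alpha``.
    """
    sizes = tuple(sizes)
    records: list[TdtResult] = []
    for subgroup in subgroups:
        sub = subset_cohort(cohort, subgroup)
        if not sub.families:
            continue
        for gene, panel in gene_panels.items():
            gene_results: list[TdtResult] = []
            for window in enumerate_marker_windows(panel, sizes):
                gene_results.extend(haplotype_tdt(sub, window, subgroup, min_freq))
            n_tests = len(gene_results)
            for res in gene_results:
                res.n_tests = n_tests
                res.p_corrected = bonferroni(res.stat.p_value, n_tests)
            records.extend(gene_results)

    rows = [
        {
            "gene": r.gene,
            "window": ";".join(r.window),
            "haplotype": str(r.unit),
            "subgroup": r.subgroup,
            "freq": r.haplotype_frequency,
            "T": r.count.T,
            "U": r.count.U,
            "chi2": r.stat.chi_square,
            "p": r.stat.p_value,
            "p_corrected": r.p_corrected,
            "n_tests": r.n_tests,
            "flag": r.p_corrected < alpha,
        }
        for r in records
    ]
    columns = [
        "gene", "window", "haplotype", "subgroup", "freq", "T", "U",
        "chi2", "p", "p_corrected", "n_tests", "flag",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# replication


class ComparisonError(ValueError):
    """Replication results cannot be compared to the primary finding."""


REPLICATED = "replicated"
NOT_REPLICATED = "not_replicated"
DIFFERENT_HAPLOTYPE = "different_haplotype"


def replication_check(
    primary: TdtResult,
    replication: Sequence[TdtResult],
    alpha: float = 0.05,
) -> str:
    """Two-cohort replication verdict for a significant primary haplotype.

    Replicated only when the same haplotype (same window, same alleles) is
    over-transmitted (T > U) with raw p < ``alpha`` in the replication
    cohort. A significant over-transmission of a different haplotype of
    the same gene is a non-replication reported as
    :data:`DIFFERENT_HAPLOTYPE`.
    """
    if not replication:
        return NOT_REPLICATED
    if any(r.gene != primary.gene for r in replication):
        raise ComparisonError("replication results must come from the same gene")
    same = [
        r
        for r in replication
        if r.window == primary.window and str(r.unit) == str(primary.unit)
    ]
    for r in same:
        if r.count.T > r.count.U and r.stat.p_value < alpha:
            return REPLICATED
    for r in replication:
        if r in same:
            continue
        if r.count.T > r.count.U and r.stat.p_value < alpha:
            return DIFFERENT_HAPLOTYPE
    return NOT_REPLICATED
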