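"""Shared fixtures: tiny hand-built families and cohorts."""

from __future__ import annotations

import pytest

from nipkit.pedigree import Cohort, Family, GenotypeCall, Individual, Marker


def make_trio(
    father_gt,
    mother_gt,
    child_gt,
    markers,
    child_diagnosis="CD",
    child_sex=2,
    family_id="F1",
    nod2=frozenset(),
):
    """One nuclear family: two healthy parents and one affected child.

    Genotypes are per-marker allele pairs (or None for missing).
    """

    def geno(pairs):
        return {
            m.id: GenotypeCall(*pair)
            for m, pair in zip(markers, pairs)
            if pair is not None
        }

    father = Individual(
        f"{family_id}_P1", family_id, sex=1, genotypes=geno(father_gt), nod2_mutations=nod2
    )
    mother = Individual(f"{family_id}_P2", family_id, sex=2, genotypes=geno(mother_gt))
    child = Individual(
        f"{family_id}_C1",
        family_id,
        father_id=father.id,
        mother_id=mother.id,
        sex=child_sex,
        diagnosis=child_diagnosis,
        genotypes=geno(child_gt),
    )
    return Family(family_id, [father, mother, child])


@pytest.fixture
def biallelic_marker():
    return Marker("rs1", "GENE1", "autosome", 0, ("A", "a"))


@pytest.fixture
def two_snp_markers():
    return [
        Marker("rs1", "GENE1", "autosome", 0, ("1", "2")),
        Marker("rs2", "GENE1", "autosome", 1, ("1", "2")),
    ]


@pytest.fixture
def trio_cohort(two_snp_markers):
    fam = make_trio(
        [("1", "2"), ("1", "1")],
        [("1", "1"), ("1", "2")],
        [("1", "1"), ("1", "2")],
        two_snp_markers,
    )
    return Cohort([fam], two_snp_markers)
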