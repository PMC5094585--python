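"""Nuclear-family genotype data: parsing, classification and QC.

The cohort model mirrors family-based IBD association studies: nuclear
families with CD / UC / IC / healthy diagnoses, NOD2 mutation carrier
flags (R702W, G908R, 1007fs), and genotypes at a panel of candidate-gene
SNPs. Input is PED/MAP-style tab-separated text plus a phenotype sidecar
table; see :func:`read_pedigree`.

Subgroup conventions follow the usual family-based analysis splits:
``IBD`` (all families, any IBD diagnosis affected), ``CD`` / ``UC``
(single-diagnosis families only), and the NOD2-mutated / wild-type split
of the CD-only families.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Mapping, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: PED missing-genotype sentinel.
MISSING = "0"

ALLELE_ALPHABET = frozenset("ACGT12")

DIAGNOSES = ("CD", "UC", "IC", "healthy")
NOD2_MUTATIONS = ("R702W", "G908R", "1007fs")
SUBGROUPS = ("IBD", "CD", "UC", "CD_nod2_mutated", "CD_nod2_wildtype")
FAMILY_CLASSES = ("CD_only", "UC_only", "mixed")
CHROMOSOME_CLASSES = ("autosome", "X", "pseudoautosomal")


class PedigreeFormatError(ValueError):
    """Malformed pedigree/marker text (inconsistent columns, bad codes)."""


class PedigreeStructureError(ValueError):
    """Pedigree references (parent ids, marker ids) that do not resolve."""


class ClassificationError(ValueError):
    """A family cannot be assigned a diagnosis class (no affected members)."""


@dataclass(frozen=True)
class Marker:
    id: str
    gene: str
    chromosome: str = "autosome"
    position_index: int = 0
    alleles: tuple[str, str] = ("1", "2")

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOME_CLASSES:
            raise ValueError(f"unknown chromosome class {self.chromosome!r}")
        if len(set(self.alleles)) != 2:
            raise ValueError(f"marker {self.id}: alleles must be two distinct codes")


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid call; both alleles present or both missing."""

    allele_1: str = MISSING
    allele_2: str = MISSING

    def __post_init__(self) -> None:
        if (self.allele_1 == MISSING) != (self.allele_2 == MISSING):
            raise ValueError("half-missing genotype call")

    @property
    def is_missing(self) -> bool:
        return self.allele_1 == MISSING

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_1, self.allele_2)

    def sorted(self) -> tuple[str, str]:
        return tuple(sorted(self.alleles))  # type: ignore[return-value]


MISSING_CALL = GenotypeCall()


@dataclass
class Individual:
    id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = 0  # 1 male, 2 female, 0 unknown
    diagnosis: str = "healthy"
    nod2_mutations: frozenset[str] = frozenset()
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        unknown = set(self.nod2_mutations) - set(NOD2_MUTATIONS)
        if unknown:
            raise ValueError(f"unknown NOD2 mutation flags {sorted(unknown)}")

    @property
    def is_affected(self) -> bool:
        return self.diagnosis != "healthy"

    def genotype(self, marker_id: str) -> GenotypeCall:
        return self.genotypes.get(marker_id, MISSING_CALL)


@dataclass
class Family:
    id: str
    members: list[Individual] = field(default_factory=list)

    def member(self, individual_id: str) -> Individual | None:
        for m in self.members:
            if m.id == individual_id:
                return m
        return None

    @property
    def affected(self) -> list[Individual]:
        return [m for m in self.members if m.is_affected]

    @property
    def family_class(self) -> str:
        return classify_family(self)[0]

    @property
    def nod2_class(self) -> str:
        return classify_family(self)[1]

    def trios(self) -> Iterator[tuple[Individual, Individual, Individual]]:
        """Yield (father, mother, child) for children with both parents present."""
        for child in self.members:
            if child.father_id is None or child.mother_id is None:
                continue
            father = self.member(child.father_id)
            mother = self.member(child.mother_id)
            if father is None or mother is None:
                continue
            yield father, mother, child


@dataclass
class Cohort:
    families: list[Family] = field(default_factory=list)
    markers: list[Marker] = field(default_factory=list)
    label: str = ""

    @property
    def marker_by_id(self) -> dict[str, Marker]:
        return {m.id: m for m in self.markers}

    @property
    def individuals(self) -> list[Individual]:
        return [m for f in self.families for m in f.members]

    @property
    def founders(self) -> list[Individual]:
        return [
            m
            for f in self.families
            for m in f.members
            if m.father_id is None and m.mother_id is None
        ]


# ---------------------------------------------------------------------------
# parsing


def _as_text_lines(stream: IO[str] | str | Iterable[str]) -> list[str]:
    if isinstance(stream, str):
        with open(stream) as fh:
            return fh.read().splitlines()
    if isinstance(stream, io.IOBase) or hasattr(stream, "read"):
        return stream.read().splitlines()  # type: ignore[union-attr]
    return [line.rstrip("\n") for line in stream]


def read_markers(map_stream: IO[str] | str | Iterable[str]) -> list[Marker]:
    """Read the marker-definition table.

    Tab-separated columns: gene, marker id, chromosome class, ordinal, and
    optionally the two allele codes (defaulting to 1/2).
    """
    markers: list[Marker] = []
    for lineno, line in enumerate(_as_text_lines(map_stream), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) not in (4, 6):
            raise PedigreeFormatError(
                f"marker line {lineno}: expected 4 or 6 tab-separated columns, got {len(cols)}"
            )
        gene, marker_id, chrom, ordinal = (c.strip() for c in cols[:4])
        alleles = ("1", "2") if len(cols) == 4 else (cols[4].strip(), cols[5].strip())
        for a in alleles:
            if a not in ALLELE_ALPHABET:
                raise PedigreeFormatError(
                    f"marker line {lineno}: allele code {a!r} outside alphabet"
                )
        try:
            pos = int(ordinal)
        except ValueError as exc:
            raise PedigreeFormatError(f"marker line {lineno}: bad ordinal {ordinal!r}") from exc
        markers.append(Marker(marker_id, gene, chrom, pos, alleles))  # type: ignore[arg-type]
    seen: dict[tuple[str, int], str] = {}
    for m in markers:
        key = (m.gene, m.position_index)
        if key in seen:
            raise PedigreeFormatError(
                f"duplicate ordinal {m.position_index} within gene {m.gene}"
            )
        seen[key] = m.id
    return markers


def read_phenotypes(phenotype_stream: IO[str] | str | Iterable[str]) -> pd.DataFrame:
    """Read the diagnosis sidecar.

    Tab-separated with header: individual_id, diagnosis, nod2_mutations
    (semicolon-separated subset of R702W;G908R;1007fs, may be empty).
    """
    lines = _as_text_lines(phenotype_stream)
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", dtype=str).fillna("")
    required = {"individual_id", "diagnosis"}
    if not required.issubset(df.columns):
        raise PedigreeFormatError(
            f"phenotype table must have columns {sorted(required)}"
        )
    if "nod2_mutations" not in df.columns:
        df["nod2_mutations"] = ""
    return df


def read_pedigree(
    ped_stream: IO[str] | str | Iterable[str],
    map_stream: IO[str] | str | Iterable[str],
    phenotype_stream: IO[str] | str | Iterable[str],
    label: str = "",
) -> Cohort:
    """Parse PED-style genotypes plus marker and phenotype tables into a Cohort.

    PED columns: family, individual, father, mother, sex, phenotype, then two
    allele columns per marker (marker order from the marker table). ``0``
    denotes missing (parent, sex, or allele). Half-missing genotype calls are
    promoted to fully missing with a logged warning.
    """
    markers = read_markers(map_stream)
    phen = read_phenotypes(phenotype_stream)
    phen_by_id = {
        str(r.individual_id): r for r in phen.itertuples(index=False)
    }

    expected_cols = 6 + 2 * len(markers)
    families: dict[str, Family] = {}
    for lineno, line in enumerate(_as_text_lines(ped_stream), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip().split("\t")
        if len(cols) != expected_cols:
            raise PedigreeFormatError(
                f"ped line {lineno}: expected {expected_cols} columns, got {len(cols)}"
            )
        fam_id, ind_id, father, mother, sex_code = (c.strip() for c in cols[:5])
        genotypes: dict[str, GenotypeCall] = {}
        for i, marker in enumerate(markers):
            a1, a2 = cols[6 + 2 * i].strip(), cols[7 + 2 * i].strip()
            for a in (a1, a2):
                if a != MISSING and a not in ALLELE_ALPHABET:
                    raise PedigreeFormatError(
                        f"ped line {lineno}: allele code {a!r} outside alphabet"
                    )
                if a != MISSING and a not in marker.alleles:
                    raise PedigreeFormatError(
                        f"ped line {lineno}: allele {a!r} not declared for marker {marker.id}"
                    )
            if (a1 == MISSING) != (a2 == MISSING):
                logger.warning(
                    "ped line %d, marker %s: half-missing call promoted to missing",
                    lineno,
                    marker.id,
                )
                a1 = a2 = MISSING
            if a1 != MISSING:
                genotypes[marker.id] = GenotypeCall(a1, a2)

        prow = phen_by_id.get(ind_id)
        if prow is None:
            raise PedigreeStructureError(
                f"individual {ind_id!r} missing from the phenotype table"
            )
        flags = frozenset(
            tok for tok in str(prow.nod2_mutations).split(";") if tok.strip()
        )
        individual = Individual(
            id=ind_id,
            family_id=fam_id,
            father_id=None if father == MISSING else father,
            mother_id=None if mother == MISSING else mother,
            sex=int(sex_code) if sex_code in ("1", "2") else 0,
            diagnosis=str(prow.diagnosis),
            nod2_mutations=flags,
            genotypes=genotypes,
        )
        families.setdefault(fam_id, Family(fam_id)).members.append(individual)

    for fam in families.values():
        ids = {m.id for m in fam.members}
        for m in fam.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in ids:
                    raise PedigreeStructureError(
                        f"family {fam.id}: parent {parent!r} of {m.id!r} not in family"
                    )
    return Cohort(list(families.values()), markers, label=label)


def write_pedigree(
    cohort: Cohort,
    ped_stream: IO[str] | str,
    map_stream: IO[str] | str,
    phenotype_stream: IO[str] | str,
) -> None:
    """Write a cohort back to PED/MAP/phenotype text (round-trips read_pedigree)."""

    def _open(target: IO[str] | str):
        return open(target, "w") if isinstance(target, str) else target

    def _maybe_close(handle, target) -> None:
        if isinstance(target, str):
            handle.close()

    fh = _open(map_stream)
    for m in cohort.markers:
        fh.write(
            f"{m.gene}\t{m.id}\t{m.chromosome}\t{m.position_index}"
            f"\t{m.alleles[0]}\t{m.alleles[1]}\n"
        )
    _maybe_close(fh, map_stream)

    fh = _open(phenotype_stream)
    fh.write("individual_id\tdiagnosis\tnod2_mutations\n")
    for ind in cohort.individuals:
        flags = ";".join(sorted(ind.nod2_mutations))
        fh.write(f"{ind.id}\t{ind.diagnosis}\t{flags}\n")
    _maybe_close(fh, phenotype_stream)

    fh = _open(ped_stream)
    for fam in cohort.families:
        for ind in fam.members:
            cols = [
                fam.id,
                ind.id,
                ind.father_id or MISSING,
                ind.mother_id or MISSING,
                str(ind.sex),
                "2" if ind.is_affected else "1",
            ]
            for marker in cohort.markers:
                gt = ind.genotype(marker.id)
                cols.extend(gt.alleles)
            fh.write("\t".join(cols) + "\n")
    _maybe_close(fh, ped_stream)


# ---------------------------------------------------------------------------
# classification and subgroups


def classify_family(family: Family) -> tuple[str, str]:
    """Derive (family_class, nod2_class).

    CD_only / UC_only require every affected member to carry that single
    diagnosis; any IC case or CD+UC combination makes the family mixed.
    A family is NOD2-mutated when any member carries at least one of the
    three main NOD2 mutations.
    """
    affected = family.affected
    if not affected:
        raise ClassificationError(f"family {family.id} has no affected members")
    diagnoses = {m.diagnosis for m in affected}
    if diagnoses == {"CD"}:
        family_class = "CD_only"
    elif diagnoses == {"UC"}:
        family_class = "UC_only"
    else:
        family_class = "mixed"
    nod2_class = (
        "mutated" if any(m.nod2_mutations for m in family.members) else "wildtype"
    )
    return family_class, nod2_class


def affected_in_subgroup(individual: Individual, subgroup: str) -> bool:
    """Affected status used for transmission counting within a subgroup."""
    if subgroup == "IBD":
        return individual.diagnosis in ("CD", "UC", "IC")
    if subgroup in ("CD", "CD_nod2_mutated", "CD_nod2_wildtype"):
        return individual.diagnosis == "CD"
    if subgroup == "UC":
        return individual.diagnosis == "UC"
    raise ValueError(f"unknown subgroup {subgroup!r}")


def subset_cohort(cohort: Cohort, subgroup: str) -> Cohort:
    """Select the families analysed in a subgroup.

    IBD keeps every family; CD/UC keep the single-diagnosis families; the
    NOD2 splits further filter the CD-only families by carrier status.
    """
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}")
    selected: list[Family] = []
    for fam in cohort.families:
        family_class, nod2_class = classify_family(fam)
        if subgroup == "IBD":
            keep = True
        elif subgroup == "CD":
            keep = family_class == "CD_only"
        elif subgroup == "UC":
            keep = family_class == "UC_only"
        elif subgroup == "CD_nod2_mutated":
            keep = family_class == "CD_only" and nod2_class == "mutated"
        else:  # CD_nod2_wildtype
            keep = family_class == "CD_only" and nod2_class == "wildtype"
        if keep:
            selected.append(fam)
    return Cohort(selected, cohort.markers, label=subgroup)


# ---------------------------------------------------------------------------
# Mendelian consistency


def transmission_assignments(
    father: tuple[str, str],
    mother: tuple[str, str],
    child: tuple[str, str],
    chromosome: str = "autosome",
    child_sex: int = 2,
) -> set[tuple[str | None, str]]:
    """All (paternal, maternal) transmitted-allele pairs consistent with a trio.

    An empty set means the trio is Mendelian-inconsistent. X-linked markers:
    sons receive no paternal allele (paternal slot is None) and must be
    hemizygous, coded as a homozygous call; fathers must likewise be coded
    homozygous. Pseudoautosomal markers are handled as autosomal by callers.
    """
    if chromosome == "X":
        if child_sex == 1:
            if child[0] != child[1]:
                return set()  # heterozygous male X call is itself an error
            return {(None, child[0])} if child[0] in mother else set()
        if father[0] != father[1]:
            return set()
        out: set[tuple[str | None, str]] = set()
        for tm in set(mother):
            if tuple(sorted((father[0], tm))) == tuple(sorted(child)):
                out.add((father[0], tm))
        return out
    out = set()
    for tf in set(father):
        for tm in set(mother):
            if tuple(sorted((tf, tm))) == tuple(sorted(child)):
                out.add((tf, tm))
    return out


@dataclass(frozen=True)
class MendelViolation:
    family_id: str
    child_id: str
    marker_id: str


def mendel_check(family: Family, marker: Marker) -> list[MendelViolation]:
    """Children whose genotype is incompatible with their parents' at a marker.

    Children with an absent parent or with any missing genotype in the trio
    are not checkable and produce no record.
    """
    chrom = "autosome" if marker.chromosome == "pseudoautosomal" else marker.chromosome
    violations = []
    for father, mother, child in family.trios():
        gts = [p.genotype(marker.id) for p in (father, mother, child)]
        if any(g.is_missing for g in gts):
            continue
        ok = transmission_assignments(
            gts[0].alleles, gts[1].alleles, gts[2].alleles, chrom, child.sex
        )
        if not ok:
            violations.append(MendelViolation(family.id, child.id, marker.id))
    return violations


# ---------------------------------------------------------------------------
# QC


def hwe_test(genotype_counts: Sequence[int]) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions.

    ``genotype_counts`` is (hom-ref, het, hom-alt); allele frequencies are
    estimated from the sample. Returns (chi_square, p_value). Monomorphic
    samples fit exactly (chi-square 0).
    """
    if len(genotype_counts) != 3 or any(c < 0 for c in genotype_counts):
        raise ValueError("genotype_counts must be three non-negative integers")
    n_rr, n_ra, n_aa = genotype_counts
    n = n_rr + n_ra + n_aa
    if n == 0:
        raise ValueError("zero total genotype count")
    p_hat = (2 * n_rr + n_ra) / (2 * n)
    q_hat = 1.0 - p_hat
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0
    expected = (n * p_hat**2, 2 * n * p_hat * q_hat, n * q_hat**2)
    chi2 = sum(
        (obs - exp) ** 2 / exp for obs, exp in zip((n_rr, n_ra, n_aa), expected)
    )
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def founder_genotype_counts(cohort: Cohort, marker: Marker) -> tuple[int, int, int]:
    """Genotype counts (hom-ref, het, hom-alt) over founders only.

    Restricting to founders avoids relatedness-driven inflation of the HWE
    statistic.
    """
    ref, alt = marker.alleles
    n_rr = n_ra = n_aa = 0
    for ind in cohort.founders:
        gt = ind.genotype(marker.id)
        if gt.is_missing:
            continue
        het = gt.allele_1 != gt.allele_2
        if het:
            n_ra += 1
        elif gt.allele_1 == ref:
            n_rr += 1
        else:
            n_aa += 1
    return n_rr, n_ra, n_aa


def hwe_table(cohort: Cohort) -> pd.DataFrame:
    """Founder-level HWE chi-square and p per marker."""
    rows = []
    for marker in cohort.markers:
        counts = founder_genotype_counts(cohort, marker)
        if sum(counts) == 0:
            chi2 = p = float("nan")
        else:
            chi2, p = hwe_test(counts)
        rows.append(
            {
                "marker": marker.id,
                "gene": marker.gene,
                "n_hom_ref": counts[0],
                "n_het": counts[1],
                "n_hom_alt": counts[2],
                "chi2": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def genotyping_qc(cohort: Cohort, threshold: float = 0.99) -> pd.DataFrame:
    """Per-marker call rate, flagging markers below ``threshold``.

    The default reflects the >99% genotyping success expected of the
    Illumina/Taqman panels this models.
    """
    individuals = cohort.individuals
    n_total = len(individuals)
    rows = []
    for marker in cohort.markers:
        n_called = sum(
            1 for ind in individuals if not ind.genotype(marker.id).is_missing
        )
        rate = n_called / n_total if n_total else 0.0
        rows.append(
            {
                "marker": marker.id,
                "gene": marker.gene,
                "n_called": n_called,
                "n_total": n_total,
                "call_rate": rate,
                "flagged": rate < threshold,
            }
        )
    return pd.DataFrame(rows)
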