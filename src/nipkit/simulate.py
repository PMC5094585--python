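"""Seeded generators for cohort, BRET, qPCR and evidence inputs.

The study this models deposited no raw data, so every pipeline stage is
exercised on synthetic inputs with the statistical structure the stage
assumes:

* :func:`simulate_cohort` builds nuclear IBD families whose class sizes
  default to the modelled cohort (104 + 78 NOD2-mutated/wildtype CD-only,
  59 UC-only, 102 mixed = 343 families). Founder haplotypes are drawn
  from block-level haplotype frequencies under Hardy-Weinberg, and
  transmissions from risk-heterozygous parents to affected children are
  biased to probability τ (τ = 0.5 is the null).
* :func:`simulate_titration` produces plate wells whose derived points
  follow a one-site saturation hyperbola with Gaussian mBRET noise, with
  optional MDP multipliers on the two parameters.
* :func:`simulate_ct` produces Ct tables with stable housekeeping genes
  and condition effects expressed as expression ratios.
* :func:`simulate_evidence` returns deterministic evidence profiles for
  the scoring rubric.

All generators are reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Cohort, Family, GenotypeCall, Individual, Marker
from .scoring import EvidenceProfile


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# cohort simulation


def _default_panel_markers() -> tuple[Marker, ...]:
    return (
        Marker("snp1", "GENE1", "autosome", 0, ("1", "2")),
        Marker("snp2", "GENE1", "autosome", 1, ("1", "2")),
        Marker("snp3", "GENE1", "autosome", 2, ("1", "2")),
    )


@dataclass(frozen=True)
class PanelSimConfig:
    """One gene panel: markers, block haplotypes and their frequencies."""

    markers: tuple[Marker, ...] = field(default_factory=_default_panel_markers)
    #: default block: a cascade of tag-SNP haplotypes with one dominant
    #: major haplotype, the structure typical of the candidate-gene blocks
    #: this emulates (the best-characterized block there has a ~0.56 major
    #: haplotype and a handful of common haplotype groups).
    haplotypes: tuple[tuple[str, ...], ...] = (
        ("1", "1", "1"),
        ("2", "1", "1"),
        ("2", "2", "1"),
        ("2", "2", "2"),
    )
    frequencies: tuple[float, ...] = (0.55, 0.25, 0.12, 0.08)
    risk_haplotype: int | None = None

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.frequencies):
            raise ConfigError("one frequency per haplotype required")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ConfigError("haplotype frequencies must sum to 1")
        if any(len(h) != len(self.markers) for h in self.haplotypes):
            raise ConfigError("haplotype length must match the marker panel")
        if self.risk_haplotype is not None and not (
            0 <= self.risk_haplotype < len(self.haplotypes)
        ):
            raise ConfigError("risk_haplotype index out of range")

    @property
    def gene(self) -> str:
        return self.markers[0].gene

    @property
    def chromosome(self) -> str:
        return self.markers[0].chromosome


@dataclass(frozen=True)
class CohortSimConfig:
    """Family structure, disease-model and noise parameters for a cohort."""

    seed: int = 0
    n_cd_nod2_mutated: int = 104
    n_cd_nod2_wildtype: int = 78
    n_uc: int = 59
    n_mixed: int = 102
    #: affected children per family (all families share this count).
    n_affected_children: int = 1
    #: probability a risk-heterozygous parent transmits the risk haplotype
    #: to an affected child. 0.5 is the null of no transmission distortion.
    transmission_probability: float = 0.5
    missing_rate: float = 0.0
    mendel_error_rate: float = 0.0
    panels: tuple[PanelSimConfig, ...] = (PanelSimConfig(),)
    label: str = "simulated"

    def __post_init__(self) -> None:
        if not 0.0 < self.transmission_probability < 1.0:
            raise ConfigError("transmission probability must lie in (0, 1)")
        for rate in (self.missing_rate, self.mendel_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if self.n_affected_children < 1:
            raise ConfigError("families need at least one affected child")


def simulate_transmissions(
    n_informative: int, tau: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Transmitted/untransmitted counts over informative meioses.

    Each informative meiosis (a risk-heterozygous parent transmitting to
    an affected child) passes the risk unit with probability ``tau``.
    """
    if not 0.0 < tau < 1.0:
        raise ConfigError("tau must lie in (0, 1)")
    T = int(rng.binomial(n_informative, tau))
    return T, n_informative - T


def _draw_haplotype(panel: PanelSimConfig, rng: np.random.Generator) -> int:
    return int(rng.choice(len(panel.haplotypes), p=panel.frequencies))


def _transmit(
    parent_haps: tuple[int, int],
    panel: PanelSimConfig,
    tau: float,
    rng: np.random.Generator,
) -> int:
    h1, h2 = parent_haps
    risk = panel.risk_haplotype
    if risk is not None and (h1 == risk) != (h2 == risk):
        take_risk = rng.random() < tau
        return risk if take_risk else (h2 if h1 == risk else h1)
    return h1 if rng.random() < 0.5 else h2


def _incompatible_genotype(
    father: GenotypeCall, mother: GenotypeCall, alleles: tuple[str, str]
) -> GenotypeCall | None:
    from .pedigree import transmission_assignments

    a, b = alleles
    for gt in ((a, a), (a, b), (b, b)):
        if not transmission_assignments(father.alleles, mother.alleles, gt):
            return GenotypeCall(*gt)
    return None


def simulate_cohort(
    config: CohortSimConfig, return_info: bool = False
) -> Cohort | tuple[Cohort, dict]:
    """Generate a cohort of nuclear families under the configured model.

    Founders carry two haplotypes drawn independently from the panel
    frequencies (Hardy-Weinberg at the block level); each affected child
    receives one haplotype per parent, biased to the risk haplotype with
    probability τ when the parent is risk-heterozygous. Missing calls and
    Mendelian errors are injected at the configured rates (errors only
    where an incompatible genotype exists, so they are detectable).

    With ``return_info`` the byproduct dict reports the number of
    injected Mendelian errors and risk-informative transmissions.
    """
    rng = np.random.default_rng(config.seed)
    markers = [m for panel in config.panels for m in panel.markers]
    families: list[Family] = []
    info = {"n_mendel_errors": 0, "n_informative": 0, "n_risk_transmitted": 0}

    specs = (
        [("CD_only", "mutated")] * config.n_cd_nod2_mutated
        + [("CD_only", "wildtype")] * config.n_cd_nod2_wildtype
        + [("UC_only", "wildtype")] * config.n_uc
        + [("mixed", "wildtype")] * config.n_mixed
    )
    for fam_idx, (family_class, nod2_class) in enumerate(specs):
        fam_id = f"F{fam_idx:04d}"
        father = Individual(f"{fam_id}_P1", fam_id, sex=1)
        mother = Individual(f"{fam_id}_P2", fam_id, sex=2)
        if nod2_class == "mutated":
            carrier = father if rng.random() < 0.5 else mother
            mutation = ("R702W", "G908R", "1007fs")[int(rng.integers(3))]
            carrier.nod2_mutations = frozenset({mutation})

        n_children = config.n_affected_children
        if family_class == "CD_only":
            diagnoses = ["CD"] * n_children
        elif family_class == "UC_only":
            diagnoses = ["UC"] * n_children
        elif n_children == 1:
            diagnoses = ["IC"]
        else:
            diagnoses = ["CD", "UC"] + [
                ("CD", "UC", "IC")[int(rng.integers(3))] for _ in range(n_children - 2)
            ]
        children = [
            Individual(
                f"{fam_id}_C{i + 1}",
                fam_id,
                father_id=father.id,
                mother_id=mother.id,
                sex=1 + int(rng.integers(2)),
                diagnosis=diagnoses[i],
            )
            for i in range(n_children)
        ]

        for panel in config.panels:
            x_linked = panel.chromosome == "X"
            if x_linked:
                h = _draw_haplotype(panel, rng)
                f_haps = (h, h)  # hemizygous father, coded homozygous
            else:
                f_haps = (_draw_haplotype(panel, rng), _draw_haplotype(panel, rng))
            m_haps = (_draw_haplotype(panel, rng), _draw_haplotype(panel, rng))

            def set_genotypes(ind: Individual, haps: tuple[int, int]) -> None:
                ha, hb = panel.haplotypes[haps[0]], panel.haplotypes[haps[1]]
                for i, marker in enumerate(panel.markers):
                    ind.genotypes[marker.id] = GenotypeCall(ha[i], hb[i])

            set_genotypes(father, f_haps)
            set_genotypes(mother, m_haps)

            risk = panel.risk_haplotype
            tau = config.transmission_probability
            for child in children:
                pat = None if (x_linked and child.sex == 1) else (
                    f_haps[0] if x_linked else _transmit(f_haps, panel, tau, rng)
                )
                mat = _transmit(m_haps, panel, tau, rng)
                if risk is not None:
                    parent_transmissions = []
                    if pat is not None and not x_linked:
                        parent_transmissions.append((f_haps, pat))
                    parent_transmissions.append((m_haps, mat))
                    for (h1, h2), transmitted in parent_transmissions:
                        if (h1 == risk) != (h2 == risk):
                            info["n_informative"] += 1
                            if transmitted == risk:
                                info["n_risk_transmitted"] += 1
                if x_linked and child.sex == 1:
                    mat_h = panel.haplotypes[mat]
                    for i, marker in enumerate(panel.markers):
                        child.genotypes[marker.id] = GenotypeCall(mat_h[i], mat_h[i])
                else:
                    pat_h = panel.haplotypes[pat]  # type: ignore[index]
                    mat_h = panel.haplotypes[mat]
                    for i, marker in enumerate(panel.markers):
                        child.genotypes[marker.id] = GenotypeCall(pat_h[i], mat_h[i])

            if config.mendel_error_rate > 0:
                for child in children:
                    if x_linked:
                        continue  # error injection kept to autosomal panels
                    for marker in panel.markers:
                        if rng.random() >= config.mendel_error_rate:
                            continue
                        bad = _incompatible_genotype(
                            father.genotype(marker.id),
                            mother.genotype(marker.id),
                            marker.alleles,
                        )
                        if bad is not None:
                            child.genotypes[marker.id] = bad
                            info["n_mendel_errors"] += 1

        members = [father, mother, *children]
        if config.missing_rate > 0:
            for ind in members:
                for marker in markers:
                    if rng.random() < config.missing_rate:
                        ind.genotypes.pop(marker.id, None)
        families.append(Family(fam_id, members))

    cohort = Cohort(families, markers, label=config.label)
    return (cohort, info) if return_info else cohort


# ---------------------------------------------------------------------------
# BRET titration simulation


@dataclass(frozen=True)
class TitrationSimConfig:
    """One-site saturation ground truth plus plate/noise parameters."""

    seed: int = 0
    bret_max: float = 200.0
    bret_50: float = 0.5
    doses_ng: tuple[float, ...] = (0.0, 50.0, 100.0, 200.0, 400.0, 800.0)
    noise_sd_mbret: float = 5.0
    conditions: tuple[str, ...] = ("control",)
    mdp_bret_max_multiplier: float = 1.0
    mdp_bret_50_multiplier: float = 1.0
    luminescence: float = 1e5
    background_ratio: float = 0.8
    fluo_per_ng: float = 250.0
    plate: str = "plate1"

    def __post_init__(self) -> None:
        if len(self.doses_ng) < 3:
            raise ConfigError("at least 3 acceptor doses required")
        if any(d < 0 for d in self.doses_ng):
            raise ConfigError("doses must be non-negative")
        if self.noise_sd_mbret < 0:
            raise ConfigError("noise sd must be non-negative")


def simulate_titration(config: TitrationSimConfig) -> pd.DataFrame:
    """Simulated plate wells for one titration (per condition, triplicate).

    Each dose yields a triplicate of sample wells whose derived (x, y)
    point follows y = BRETmax * x / (BRET50 + x) + N(0, sd); donor-only
    background wells are included per condition. The MDP condition
    applies the configured multipliers to the two parameters.
    """
    rng = np.random.default_rng(config.seed)
    L = config.luminescence
    bg = config.background_ratio
    rows = []
    for condition in config.conditions:
        bmax = config.bret_max
        b50 = config.bret_50
        if condition == "MDP":
            bmax *= config.mdp_bret_max_multiplier
            b50 *= config.mdp_bret_50_multiplier
        for rep in range(3):
            rows.append(
                {
                    "plate": config.plate,
                    "well": f"{condition}_donor_{rep}",
                    "role": "donor_only",
                    "condition": condition,
                    "group": "donor",
                    "lum480": L,
                    "em530": bg * L,
                    "fluo": 0.0,
                }
            )
        for dose in config.doses_ng:
            fluo = dose * config.fluo_per_ng
            x = fluo / L
            y_true = bmax * x / (b50 + x)
            for rep in range(3):
                y = y_true + (
                    rng.normal(0.0, config.noise_sd_mbret)
                    if config.noise_sd_mbret > 0
                    else 0.0
                )
                rows.append(
                    {
                        "plate": config.plate,
                        "well": f"{condition}_d{dose:g}_{rep}",
                        "role": "sample",
                        "condition": condition,
                        "group": f"d{dose:g}",
                        "lum480": L,
                        "em530": (bg + y / 1000.0) * L,
                        "fluo": fluo,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ct and evidence simulation


def simulate_ct(
    genes: Sequence[str],
    conditions: Sequence[str],
    effects: Mapping[tuple[str, str], float],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 2,
    reference_condition: str = "untreated",
    housekeeping: Mapping[str, float] = {"GAPDH": 18.0, "TBP": 22.0},
) -> pd.DataFrame:
    """Long-format Ct table with condition effects on target genes.

    ``effects`` maps (gene, condition) to an expression ratio relative to
    the reference condition; the target Ct shifts by -log2(ratio).
    Housekeeping Cts are constant across conditions (plus replicate
    noise). Conditions not listed keep ratio 1.
    """
    if noise_sd < 0:
        raise ConfigError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    all_conditions = [reference_condition] + [
        c for c in conditions if c != reference_condition
    ]
    rows = []
    for g_idx, gene in enumerate(genes):
        base_ct = 24.0 + g_idx
        for condition in all_conditions:
            ratio = effects.get((gene, condition), 1.0)
            if ratio <= 0:
                raise ConfigError("effects must be positive expression ratios")
            ct = base_ct - np.log2(ratio)
            for rep in range(n_replicates):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {"gene": gene, "condition": condition, "replicate": rep, "ct": ct + noise}
                )
    for hk_gene, hk_ct in housekeeping.items():
        for condition in all_conditions:
            for rep in range(n_replicates):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {"gene": hk_gene, "condition": condition, "replicate": rep, "ct": hk_ct + noise}
                )
    return pd.DataFrame(rows)


def simulate_evidence(
    specs: Mapping[str, Mapping[str, object]]
) -> dict[str, EvidenceProfile]:
    """Deterministic evidence profiles for the scoring rubric.

    ``specs`` maps protein name to keyword arguments of
    :class:`~nipkit.scoring.EvidenceProfile`; invalid categories raise at
    scoring time via the rubric's own validation, invalid structure here.
    """
    from .scoring import BRET_POINTS, COIP_POINTS

    profiles = {}
    for protein, kwargs in specs.items():
        profile = EvidenceProfile(**kwargs)  # type: ignore[arg-type]
        if profile.coip_category not in COIP_POINTS:
            raise ValueError(f"{protein}: unknown co-IP category {profile.coip_category!r}")
        if profile.bret_category not in BRET_POINTS:
            raise ValueError(f"{protein}: unknown BRET category {profile.bret_category!r}")
        profiles[protein] = profile
    return profiles
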