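"""Multi-evidence interaction scoring for candidate NOD2 partners.

Each candidate interactor accumulates points from three independent
lines of evidence:

* yeast two-hybrid (Y2H) hit counts across up to four screens
  (5 points for a single hit, 10 for 2-3 hits, 15 for more than 3,
  +5 when hits come from at least two independent screens; capped at
  20). A "+" flag marks reconfirmation by Y2H with the full-length cDNA.
* co-immunoprecipitation: none 0, weak 5, clear in one orientation 10,
  both orientations 20.
* BRET: none 0, specific hyperbolic saturation 10, saturation modified
  by MDP stimulation 20.

The total (5-60 points, arbitrary units) ranks the candidates. Component
points may also be supplied directly (the "verbatim" path) when raw
per-screen evidence is not available; out-of-rubric component values are
accepted there but logged as rubric violations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

COIP_POINTS = {"none": 0, "weak": 5, "one_orientation": 10, "both_orientations": 20}
BRET_POINTS = {"none": 0, "hyperbolic": 10, "hyperbolic_mdp_modulated": 20}
Y2H_ALLOWED = frozenset({5, 10, 15, 20})
Y2H_CAP = 20

_SCORES_RESOURCE = "interaction_scores.tsv"


@dataclass(frozen=True)
class EvidenceProfile:
    y2h_hits_per_screen: Mapping[str, int]
    full_length_reconfirmed: bool = False
    coip_category: str = "none"
    bret_category: str = "none"

    def __post_init__(self) -> None:
        if not self.y2h_hits_per_screen:
            raise ValueError("at least one Y2H screen must be present")
        if any(h < 0 for h in self.y2h_hits_per_screen.values()):
            raise ValueError("Y2H hit counts must be non-negative")


@dataclass(frozen=True)
class InteractionScore:
    y2h_points: int
    coip_points: int
    bret_points: int
    plus_flag: bool = False

    @property
    def total(self) -> int:
        return self.y2h_points + self.coip_points + self.bret_points


def y2h_points(
    hits_per_screen: Mapping[str, int], full_length_reconfirmed: bool = False
) -> tuple[int, bool]:
    """Y2H component points and the full-length reconfirmation flag.

    Base points follow the total hit count pooled over screens (1 hit: 5;
    2-3: 10; >3: 15) with a 5-point bonus for isolation in at least two
    independent screens, capped at 20.
    """
    total_hits = sum(hits_per_screen.values())
    if total_hits < 1:
        raise ValueError("a candidate needs at least one Y2H hit")
    if total_hits == 1:
        points = 5
    elif total_hits <= 3:
        points = 10
    else:
        points = 15
    if sum(1 for h in hits_per_screen.values() if h > 0) >= 2:
        points += 5
    return min(points, Y2H_CAP), bool(full_length_reconfirmed)


def coip_points(category: str) -> int:
    """Co-immunoprecipitation component points."""
    try:
        return COIP_POINTS[category]
    except KeyError:
        raise ValueError(
            f"unknown co-IP category {category!r}; expected {sorted(COIP_POINTS)}"
        ) from None


def bret_points(category: str) -> int:
    """BRET component points."""
    try:
        return BRET_POINTS[category]
    except KeyError:
        raise ValueError(
            f"unknown BRET category {category!r}; expected {sorted(BRET_POINTS)}"
        ) from None


def interaction_score(profile: EvidenceProfile) -> InteractionScore:
    """Score a full evidence profile under the rubric."""
    y2h, plus = y2h_points(
        profile.y2h_hits_per_screen, profile.full_length_reconfirmed
    )
    return InteractionScore(
        y2h_points=y2h,
        coip_points=coip_points(profile.coip_category),
        bret_points=bret_points(profile.bret_category),
        plus_flag=plus,
    )


def score_from_components(
    y2h: int, coip: int, bret: int, protein: str = ""
) -> tuple[int, list[str]]:
    """Total score from pre-assigned component points (verbatim path).

    Values outside the rubric's component sets are accepted but returned
    (and logged) as rubric violations rather than silently scored.
    """
    violations = []
    if y2h not in Y2H_ALLOWED:
        violations.append(f"y2h={y2h} outside {sorted(Y2H_ALLOWED)}")
    if coip not in COIP_POINTS.values():
        violations.append(f"coip={coip} outside {sorted(set(COIP_POINTS.values()))}")
    if bret not in BRET_POINTS.values():
        violations.append(f"bret={bret} outside {sorted(set(BRET_POINTS.values()))}")
    for v in violations:
        logger.warning("rubric violation%s: %s", f" for {protein}" if protein else "", v)
    return y2h + coip + bret, violations


def score_component_table(components: pd.DataFrame) -> pd.DataFrame:
    """Score a component table (protein, y2h, coip, bret[, y2h_plus]).

    Returns the table with recomputed totals, sorted by total descending,
    plus a ``rubric_violations`` column listing any out-of-rubric
    component values.
    """
    rows = []
    for row in components.itertuples(index=False):
        total, violations = score_from_components(
            int(row.y2h), int(row.coip), int(row.bret), str(row.protein)
        )
        rows.append(
            {
                "protein": row.protein,
                "y2h": int(row.y2h),
                "y2h_plus": str(getattr(row, "y2h_plus", "") or "").strip() == "+",
                "coip": int(row.coip),
                "bret": int(row.bret),
                "total": total,
                "rubric_violations": "; ".join(violations),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("total", ascending=False, kind="stable").reset_index(drop=True)


def load_reference_scores() -> pd.DataFrame:
    """The packaged NOD2-partner component/score table."""
    with resources.files("nipkit.data").joinpath(_SCORES_RESOURCE).open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)
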