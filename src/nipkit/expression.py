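"""qPCR fold regulation (ΔΔCt) and dual-luciferase reporter summaries.

Relative expression uses the ΔΔCt method with two housekeeping genes
(GAPDH and TBP): the normalizer is the arithmetic mean of the two
housekeeping mean Cts (equivalent to normalizing expression by their
geometric mean), amplification efficiency is fixed at 2, and

    ratio = 2^-((Ct_target - Ct_norm)_condition - (Ct_target - Ct_norm)_reference)

Folds are reported in the signed convention common in qPCR array
reports: ratios below 1 become negative reciprocals (ratio 0.5 -> -2.0),
and a |fold| >= 2 is called a significant change.

Reporter assays are summarized as RLU = firefly / renilla with the
standard error of the mean over replicates, and siRNA experiments are
accepted when at least 70% of the target mRNA is knocked down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FOLD_THRESHOLD = 2.0
KNOCKDOWN_THRESHOLD = 0.70
HOUSEKEEPING_GENES = ("GAPDH", "TBP")


@dataclass
class CtMeasurement:
    gene: str
    condition: str
    ct_replicates: Sequence[float]
    housekeeping: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        values = list(self.ct_replicates) + [
            ct for reps in self.housekeeping.values() for ct in reps
        ]
        if not self.ct_replicates:
            raise ValueError("at least one Ct replicate required")
        if any(not math.isfinite(ct) or ct <= 0 for ct in values):
            raise ValueError("Ct values must be positive and finite")


@dataclass(frozen=True)
class FoldRegulation:
    gene: str
    condition: str
    ratio: float
    signed_fold: float
    significant: bool


def _normalizer_ct(housekeeping: Mapping[str, Sequence[float]]) -> float:
    if not housekeeping:
        raise ValueError("housekeeping Cts missing")
    return float(np.mean([np.mean(list(reps)) for reps in housekeeping.values()]))


def delta_delta_ct(target: CtMeasurement, reference_condition: CtMeasurement) -> float:
    """Expression ratio 2^-ΔΔCt of a condition against the reference.

    Both measurements must be for the same gene and carry housekeeping
    Cts; replicates are averaged before differencing.
    """
    if target.gene != reference_condition.gene:
        raise ValueError("ΔΔCt compares conditions of the same gene")
    d_ct_cond = float(np.mean(list(target.ct_replicates))) - _normalizer_ct(
        target.housekeeping
    )
    d_ct_ref = float(np.mean(list(reference_condition.ct_replicates))) - _normalizer_ct(
        reference_condition.housekeeping
    )
    return float(2.0 ** -(d_ct_cond - d_ct_ref))


def fold_regulation(
    ratio: float,
    gene: str = "",
    condition: str = "",
    threshold: float = FOLD_THRESHOLD,
) -> FoldRegulation:
    """Signed fold and significance call for an expression ratio.

    Ratios >= 1 are reported as-is; ratios < 1 as negative reciprocals,
    so |signed_fold| >= 1 always and a 2-fold change in either direction
    is significant.
    """
    if not ratio > 0:
        raise ValueError("expression ratio must be positive")
    signed = ratio if ratio >= 1.0 else -1.0 / ratio
    return FoldRegulation(gene, condition, float(ratio), float(signed), abs(signed) >= threshold)


def fold_table(
    ct_table: pd.DataFrame,
    reference_condition: str = "untreated",
    housekeeping_genes: Sequence[str] = HOUSEKEEPING_GENES,
    threshold: float = FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Fold-regulation table from a long-format Ct table.

    ``ct_table`` columns: gene, condition, replicate, ct. Housekeeping
    genes are identified by name and used to normalize every other gene
    within each condition.
    """
    required = {"gene", "condition", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    hk = [g for g in housekeeping_genes if g in set(ct_table["gene"])]
    if len(hk) < len(housekeeping_genes):
        missing = set(housekeeping_genes) - set(hk)
        raise ValueError(f"housekeeping gene(s) {sorted(missing)} absent from Ct table")

    def measurement(gene: str, condition: str) -> CtMeasurement:
        sub = ct_table[(ct_table["gene"] == gene) & (ct_table["condition"] == condition)]
        if sub.empty:
            raise ValueError(f"no Ct rows for gene {gene!r} condition {condition!r}")
        housekeeping = {
            g: list(
                ct_table[
                    (ct_table["gene"] == g) & (ct_table["condition"] == condition)
                ]["ct"]
            )
            for g in hk
        }
        return CtMeasurement(gene, condition, list(sub["ct"]), housekeeping)

    genes = [g for g in ct_table["gene"].unique() if g not in hk]
    conditions = [c for c in ct_table["condition"].unique() if c != reference_condition]
    rows = []
    for gene in genes:
        ref = measurement(gene, reference_condition)
        for condition in conditions:
            ratio = delta_delta_ct(measurement(gene, condition), ref)
            fold = fold_regulation(ratio, gene, condition, threshold)
            rows.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "ratio": fold.ratio,
                    "fold": fold.signed_fold,
                    "significant": fold.significant,
                }
            )
    return pd.DataFrame(rows)


def rlu(firefly: float, renilla: float) -> float:
    """Relative luciferase units: firefly signal / renilla control."""
    if renilla <= 0:
        raise ValueError("renilla reading must be positive")
    if firefly < 0:
        raise ValueError("firefly reading must be non-negative")
    return firefly / renilla


def summarize_reporter(
    reporter: pd.DataFrame, condition_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean RLU and SEM per condition from replicate firefly/renilla wells.

    ``reporter`` columns: condition, firefly, renilla (one row per
    replicate). Single-replicate conditions keep their mean but get an
    NA SEM.
    """
    required = {"condition", "firefly", "renilla"}
    if not required.issubset(reporter.columns):
        raise ValueError(f"reporter table must have columns {sorted(required)}")
    values = reporter.assign(
        rlu=[rlu(f, r) for f, r in zip(reporter["firefly"], reporter["renilla"])]
    )
    rows = []
    for condition, block in values.groupby("condition", sort=False):
        n = len(block)
        mean = float(block["rlu"].mean())
        sem = float(block["rlu"].std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        rows.append({"condition": condition, "n": n, "mean_rlu": mean, "sem": sem})
    out = pd.DataFrame(rows)
    if condition_order is not None:
        order = {c: i for i, c in enumerate(condition_order)}
        out = out.sort_values(
            "condition", key=lambda s: s.map(lambda c: order.get(c, len(order))),
            kind="stable",
        ).reset_index(drop=True)
    return out


def knockdown_ok(
    fraction_remaining: float, threshold: float = KNOCKDOWN_THRESHOLD
) -> bool:
    """Whether an siRNA experiment achieved sufficient knockdown.

    True iff the inhibition (1 - fraction of target mRNA remaining)
    reaches the threshold (default 70%).
    """
    if not 0.0 <= fraction_remaining <= 1.0:
        raise ValueError("fraction_remaining must lie in [0, 1]")
    return (1.0 - fraction_remaining) >= threshold
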