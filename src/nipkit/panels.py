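"""Candidate-gene SNP panels for the NOD2-partner association scan.

The packaged panel table lists, per gene, its cytogenetic localization,
haplotype-block summary and the genotyped tag SNPs (semicolon-separated).
The chromosome class of each panel is derived from the localization: an
X-only band is X-linked (maternal transmissions only in the TDT), a band
on both X and Y is pseudoautosomal (analysed as autosomal), anything else
is an autosome.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .pedigree import Marker

_PANEL_RESOURCE = "nod2_partner_panels.tsv"


def chromosome_class(localization: str) -> str:
    bands = [b.strip() for b in localization.split(";")]
    has_x = any(b.startswith("X") for b in bands)
    has_y = any(b.startswith("Y") for b in bands)
    if has_x and has_y:
        return "pseudoautosomal"
    if has_x:
        return "X"
    return "autosome"


def load_panel_table(path: str | None = None) -> pd.DataFrame:
    """Load the panel table (the packaged NOD2-partner panel by default)."""
    if path is None:
        with resources.files("nipkit.data").joinpath(_PANEL_RESOURCE).open() as fh:
            return pd.read_csv(fh, sep="\t")
    return pd.read_csv(path, sep="\t")


def parse_snp_ids(snp_field: str) -> list[tuple[str, bool]]:
    """Split a semicolon-separated SNP list into (id, provisional) pairs.

    A parenthesized id, e.g. ``(rs10870446)``, is kept but flagged
    provisional — its genotyping status in the source panel is uncertain.
    """
    out = []
    for tok in snp_field.split(";"):
        tok = tok.strip()
        if not tok:
            continue
        provisional = tok.startswith("(") and tok.endswith(")")
        out.append((tok.strip("()"), provisional))
    return out


def load_gene_panels(path: str | None = None) -> dict[str, list[Marker]]:
    """Gene panels as ordered marker lists, keyed by gene symbol."""
    table = load_panel_table(path)
    panels: dict[str, list[Marker]] = {}
    for row in table.itertuples(index=False):
        chrom = chromosome_class(str(row.localization))
        markers = [
            Marker(snp_id, str(row.gene), chrom, idx)
            for idx, (snp_id, _prov) in enumerate(parse_snp_ids(str(row.snps)))
        ]
        panels[str(row.gene)] = markers
    return panels


def panel_snp_count(path: str | None = None) -> tuple[int, int]:
    """(number of SNP identifiers, number of genes) in a panel table."""
    panels = load_gene_panels(path)
    return sum(len(m) for m in panels.values()), len(panels)
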