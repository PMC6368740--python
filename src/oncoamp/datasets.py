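"""Bundled reference tables: panel gene list and observed actionable calls.

Two small fixtures ship with the package: the 79-gene content of the
amplicon panel (with a flag for genes whose amplicon count was too low
for copy-number reporting) and the published table of actionable
alterations observed in the validation cohorts, usable as a regression
fixture for the actionability tiering machinery.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .cnv_caller import CopyNumberCall

__all__ = [
    "ObservedVariant",
    "ObservedCalls",
    "panel_gene_table",
    "observed_actionable_calls",
]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("oncoamp").joinpath(f"data/{name}")))


def panel_gene_table() -> pd.DataFrame:
    """The panel's gene content: columns ``gene`` and ``cnv_reported``.

    ``cnv_reported`` is 0 for genes with too few amplicons for
    copy-number calling.
    """
    return pd.read_csv(_data_path("panel_genes.tsv"), sep="\t")


@dataclass(frozen=True)
class ObservedVariant:
    """A minimal SNV record for actionability matching."""

    sample_id: str
    gene: str
    protein_change: str
    allele_fraction: float


@dataclass
class ObservedCalls:
    """Observed actionable alterations, split into SNVs and amplifications."""

    variants: list[ObservedVariant]
    cnv_calls: list[CopyNumberCall]


def observed_actionable_calls(cohort: str | None = None) -> ObservedCalls:
    """Load the bundled table of observed actionable alterations.

    ``cohort`` filters to "solid" or "ctdna" (None = all). Amplification
    rows become amplified :class:`CopyNumberCall` records with no stored
    magnitude (the source table reports the event, not the ratio).
    """
    variants: list[ObservedVariant] = []
    cnv_calls: list[CopyNumberCall] = []
    with open(_data_path("observed_actionable_calls.tsv"), newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if cohort is not None and row["cohort"] != cohort:
                continue
            if row["alteration"] == "Amplification":
                cnv_calls.append(
                    CopyNumberCall(
                        sample_id=row["sample_id"],
                        gene=row["gene"],
                        log2_ratio=math.nan,
                        absolute_cn=math.nan,
                        status="amplified",
                    )
                )
            else:
                variants.append(
                    ObservedVariant(
                        sample_id=row["sample_id"],
                        gene=row["gene"],
                        protein_change=row["alteration"],
                        allele_fraction=float(row["allele_fraction"]),
                    )
                )
    return ObservedCalls(variants=variants, cnv_calls=cnv_calls)
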