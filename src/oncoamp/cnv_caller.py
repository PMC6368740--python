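"""Gene-level copy-number calling from amplicon read depths.

Amplicon panels have no off-target reads, so copy number is estimated by
comparing a tumor sample's per-amplicon depth profile against a pooled
normal reference built from germline samples. Each sample is normalized
to its library size; the reference is the per-amplicon median of the
normalized normal profiles (robust to a single aberrant normal). A tumor
amplicon's log2 ratio is log2(normalized depth / reference), a gene's
log2 ratio is the median over its amplicons, and absolute copy number is
2 * 2**log2. Only genes with enough amplicons (default >= 4) are called.

Reporting thresholds are strict: amplified iff absolute CN > 6
(log2 > 1.58), deleted iff absolute CN < 1 (log2 < -1); boundary values
are neutral. No GC or amplification-efficiency bias correction is
applied beyond the pooled reference itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import CNV_MIN_AMPLICONS, PanelDesign

__all__ = [
    "PooledReference",
    "CopyNumberCall",
    "build_pooled_reference",
    "sample_log2_ratios",
    "gene_level_cn",
    "call_cnv",
    "call_matrix",
    "cn_to_log2",
    "log2_to_cn",
    "coamplification_count",
]

AMP_THRESHOLD_CN = 6.0  # absolute CN above which a gene is amplified
DEL_THRESHOLD_CN = 1.0  # absolute CN below which a gene is deleted


def cn_to_log2(cn: float) -> float:
    """log2 ratio of an absolute copy number relative to diploid: log2(cn/2)."""
    if cn <= 0:
        raise ValueError(f"copy number must be positive, got {cn}")
    return math.log2(cn / 2.0)


def log2_to_cn(log2_ratio: float) -> float:
    """Absolute copy number from a log2 ratio: 2 * 2**log2."""
    return 2.0 * 2.0**log2_ratio


@dataclass
class PooledReference:
    """Per-amplicon expected depth fraction from pooled normal samples.

    ``values`` holds each amplicon's median library-size-normalized depth;
    amplicons with zero median are flagged unusable and excluded from
    ratio computation.
    """

    values: pd.Series
    usable: pd.Series  # boolean mask, same index

    @property
    def usable_amplicons(self) -> pd.Index:
        return self.values.index[self.usable]


def build_pooled_reference(normal_matrix: pd.DataFrame) -> PooledReference:
    """Build the pooled normal reference (amplicons x samples count matrix).

    Each normal column is normalized to its total read count; the
    reference is the per-amplicon median across normals.
    """
    if normal_matrix.shape[1] < 2:
        raise ValueError("pooled reference requires at least 2 normal samples")
    if (normal_matrix < 0).any().any():
        raise ValueError("read counts must be non-negative")
    totals = normal_matrix.sum(axis=0)
    if (totals == 0).any():
        empty = list(normal_matrix.columns[totals == 0])
        raise ValueError(f"normal samples with zero total reads: {empty}")
    fractions = normal_matrix / totals
    median = fractions.median(axis=1)
    return PooledReference(values=median, usable=median > 0)


def sample_log2_ratios(sample_counts: pd.Series, reference: PooledReference) -> pd.Series:
    """Per-amplicon log2(observed/expected) for one sample.

    The sample is normalized to its own library size; unusable reference
    amplicons are omitted. Zero-count amplicons in the sample yield -inf.
    """
    total = sample_counts.sum()
    if total == 0:
        raise ValueError("sample has zero total reads")
    fractions = sample_counts / total
    usable = reference.usable_amplicons.intersection(sample_counts.index)
    with np.errstate(divide="ignore"):
        ratios = np.log2(fractions.loc[usable] / reference.values.loc[usable])
    return pd.Series(ratios, index=usable, name=sample_counts.name)


@dataclass
class CopyNumberCall:
    """Gene-level copy-number estimate for one sample."""

    sample_id: str
    gene: str
    log2_ratio: float
    absolute_cn: float
    status: str = "neutral"  # amplified | deleted | neutral
    n_amplicons: int = 0


def gene_level_cn(
    amplicon_ratios: pd.Series,
    panel: PanelDesign | Mapping[str, str],
    sample_id: str = "",
    min_amplicons: int = CNV_MIN_AMPLICONS,
) -> list[CopyNumberCall]:
    """Aggregate amplicon log2 ratios to gene calls (median per gene).

    ``panel`` is either a :class:`PanelDesign` (amplicon ids must match the
    ratio index) or a plain amplicon_id -> gene mapping. Genes with fewer
    than ``min_amplicons`` amplicons in the ratio index are not called.
    """
    if isinstance(panel, PanelDesign):
        amp_to_gene = {a.amplicon_id: a.gene for a in panel.amplicons}
    else:
        amp_to_gene = dict(panel)
    by_gene: dict[str, list[float]] = {}
    for amp_id, ratio in amplicon_ratios.items():
        gene = amp_to_gene.get(amp_id)
        if gene is not None:
            by_gene.setdefault(gene, []).append(float(ratio))
    calls: list[CopyNumberCall] = []
    for gene in sorted(by_gene):
        ratios = by_gene[gene]
        if len(ratios) < min_amplicons:
            continue
        log2 = float(np.median(ratios))
        calls.append(
            CopyNumberCall(
                sample_id=sample_id,
                gene=gene,
                log2_ratio=log2,
                absolute_cn=log2_to_cn(log2),
                n_amplicons=len(ratios),
            )
        )
    return call_cnv(calls)


def call_cnv(
    cn_calls: Sequence[CopyNumberCall],
    amp_threshold: float = AMP_THRESHOLD_CN,
    del_threshold: float = DEL_THRESHOLD_CN,
) -> list[CopyNumberCall]:
    """Assign amplified/deleted/neutral status (strict thresholds)."""
    if amp_threshold <= del_threshold:
        raise ValueError("amp_threshold must exceed del_threshold")
    for call in cn_calls:
        if call.absolute_cn > amp_threshold:
            call.status = "amplified"
        elif call.absolute_cn < del_threshold:
            call.status = "deleted"
        else:
            call.status = "neutral"
    return list(cn_calls)


def call_matrix(
    tumor_matrix: pd.DataFrame,
    reference: PooledReference,
    panel: PanelDesign | Mapping[str, str],
    min_amplicons: int = CNV_MIN_AMPLICONS,
) -> list[CopyNumberCall]:
    """Gene-level calls for every sample column of a tumor count matrix."""
    calls: list[CopyNumberCall] = []
    for sample_id in tumor_matrix.columns:
        ratios = sample_log2_ratios(tumor_matrix[sample_id], reference)
        calls.extend(
            gene_level_cn(ratios, panel, sample_id=str(sample_id), min_amplicons=min_amplicons)
        )
    return calls


def coamplification_count(
    cohort_calls: Iterable[CopyNumberCall], gene_a: str, gene_b: str
) -> int:
    """Number of samples in which both genes are amplified."""
    cohort_calls = list(cohort_calls)
    known_genes = {c.gene for c in cohort_calls}
    for gene in (gene_a, gene_b):
        if gene not in known_genes:
            raise ValueError(f"gene {gene!r} has no copy-number calls in this cohort")
    amplified: dict[str, set[str]] = {}
    for c in cohort_calls:
        if c.status == "amplified":
            amplified.setdefault(c.gene, set()).add(c.sample_id)
    return len(amplified.get(gene_a, set()) & amplified.get(gene_b, set()))
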