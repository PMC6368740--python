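"""Cohort-level summaries: mutation burden, correlations, oncoprint export.

Covers per-sample burden tables with outlier flagging (burden greater
than median + 1.5*IQR), the Pearson correlation between mutational and
copy-number burden, serial liquid-biopsy allele-fraction vs tumor-marker
trends, a gene x sample oncoprint matrix, and cross-platform allele
fraction concordance (R^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cnv_caller import CopyNumberCall
from .variant_io import VariantCall, VariantKey

__all__ = [
    "BurdenRecord",
    "SerialDraw",
    "SerialDrawSeries",
    "CorrelationResult",
    "TrendResult",
    "ConcordanceResult",
    "burden_table",
    "flag_outliers",
    "burden_cnv_correlation",
    "af_marker_trend",
    "oncoprint_matrix",
    "platform_concordance",
]

#: Allele fractions below this are treated as undetected in serial-draw
#: trend analysis (ddPCR-style lower limit of detection, 0.1%).
LLOD_AF = 0.001


@dataclass
class BurdenRecord:
    sample_id: str
    n_mutations: int
    n_cnv: int
    outlier: bool = False

    def __post_init__(self) -> None:
        if self.n_mutations < 0 or self.n_cnv < 0:
            raise ValueError("burden counts must be non-negative")


@dataclass
class SerialDraw:
    """One blood draw: date, per-variant allele fractions, marker value."""

    date: "object"  # anything orderable (datetime.date, int day index, ...)
    afs: dict[VariantKey, float] = field(default_factory=dict)
    marker_value: Optional[float] = None  # CA 27.29-like tumor marker units


@dataclass
class SerialDrawSeries:
    """Ordered serial draws for one patient (dates strictly increasing)."""

    patient_id: str
    draws: list[SerialDraw] = field(default_factory=list)

    def __post_init__(self) -> None:
        dates = [d.date for d in self.draws]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("draw dates must be strictly increasing")
        for d in self.draws:
            for key, af in d.afs.items():
                if not 0 <= af <= 1:
                    raise ValueError(f"AF out of [0,1] for {key}: {af}")


def burden_table(
    filtered_calls: Sequence[VariantCall],
    cnv_calls: Sequence[CopyNumberCall] = (),
    samples: Iterable[str] | None = None,
) -> list[BurdenRecord]:
    """Per-sample mutation and copy-number burden with outlier flags.

    Copy-number burden counts amplified plus deleted gene calls.
    ``samples`` optionally fixes the sample universe so samples with zero
    surviving calls still appear (with zero counts).
    """
    sample_ids = set(samples) if samples is not None else set()
    sample_ids |= {c.sample_id for c in filtered_calls}
    sample_ids |= {c.sample_id for c in cnv_calls}
    n_mut = {s: 0 for s in sample_ids}
    n_cnv = {s: 0 for s in sample_ids}
    for c in filtered_calls:
        n_mut[c.sample_id] += 1
    for c in cnv_calls:
        if c.status in ("amplified", "deleted"):
            n_cnv[c.sample_id] += 1
    records = [
        BurdenRecord(sample_id=s, n_mutations=n_mut[s], n_cnv=n_cnv[s])
        for s in sorted(sample_ids)
    ]
    flags = flag_outliers([r.n_mutations for r in records])
    for record, flag in zip(records, flags):
        record.outlier = bool(flag)
    return records


def flag_outliers(burdens: Sequence[float]) -> np.ndarray:
    """Flag burdens above median + 1.5*IQR.

    The IQR uses linear-interpolation quantiles (numpy default, type 7) —
    the flagging rule depends on the quantile definition, so it is fixed
    here. With fewer than 4 samples the quartiles are too unstable; all
    flags are False and a warning is issued.
    """
    burdens = np.asarray(burdens, dtype=float)
    if burdens.size < 4:
        warnings.warn("fewer than 4 samples: outlier flags not computed", stacklevel=2)
        return np.zeros(burdens.shape, dtype=bool)
    q1, median, q3 = np.quantile(burdens, [0.25, 0.5, 0.75])
    threshold = median + 1.5 * (q3 - q1)
    return burdens > threshold


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    defined: bool = True


def burden_cnv_correlation(burdens: Sequence[BurdenRecord]) -> CorrelationResult:
    """Pearson correlation between mutation and copy-number burden.

    Returns the standard two-sided t-test p-value. If either burden
    vector has zero variance the correlation is undefined and reported
    as such (NaN r, ``defined=False``).
    """
    if len(burdens) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    x = np.array([b.n_mutations for b in burdens], dtype=float)
    y = np.array([b.n_cnv for b in burdens], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=float("nan"), p_value=float("nan"), n=len(x), defined=False)
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


@dataclass
class TrendResult:
    r: float
    n_draws: int
    n_censored: int  # draws where the AF fell below the detection limit
    defined: bool = True


def af_marker_trend(
    series: SerialDrawSeries, llod: float = LLOD_AF
) -> dict[VariantKey, TrendResult]:
    """Per-variant Pearson r between AF trajectory and tumor-marker trajectory.

    Only draws carrying both a marker value and an AF entry for the
    variant are used (no interpolation). AFs below the detection limit
    are treated as 0 and counted as censored. Variants with fewer than 3
    usable draws are not computed; a constant trajectory gives an
    undefined correlation, reported as such.
    """
    keys = {k for d in series.draws for k in d.afs}
    out: dict[VariantKey, TrendResult] = {}
    for key in keys:
        afs, markers, n_censored = [], [], 0
        for d in series.draws:
            if d.marker_value is None or key not in d.afs:
                continue
            af = d.afs[key]
            if af < llod:
                af = 0.0
                n_censored += 1
            afs.append(af)
            markers.append(d.marker_value)
        if len(afs) < 3:
            continue
        if np.ptp(afs) == 0 or np.ptp(markers) == 0:
            out[key] = TrendResult(
                r=float("nan"), n_draws=len(afs), n_censored=n_censored, defined=False
            )
            continue
        res = stats.pearsonr(afs, markers)
        out[key] = TrendResult(r=float(res.statistic), n_draws=len(afs), n_censored=n_censored)
    return out


def oncoprint_matrix(
    calls: Sequence[VariantCall],
    cnv_calls: Sequence[CopyNumberCall] = (),
    samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Gene x sample alteration matrix for oncoprint-style display.

    Cell values: "mutation", "amplification", "deletion", "multiple"
    (several alteration types in one gene/sample), or "none". Genes are
    ordered by the number of altered samples, descending (ties
    alphabetical); columns are sorted sample ids.
    """
    events: dict[tuple[str, str], set[str]] = {}
    for c in calls:
        gene = c.gene or f"{c.chrom}:{c.pos}"
        events.setdefault((gene, c.sample_id), set()).add("mutation")
    for c in cnv_calls:
        if c.status == "amplified":
            events.setdefault((c.gene, c.sample_id), set()).add("amplification")
        elif c.status == "deleted":
            events.setdefault((c.gene, c.sample_id), set()).add("deletion")

    sample_ids = set(samples) if samples is not None else set()
    sample_ids |= {s for _, s in events}
    genes = {g for g, _ in events}
    altered_counts = {
        g: sum(1 for (gene, _s) in events if gene == g) for g in genes
    }
    gene_order = sorted(genes, key=lambda g: (-altered_counts[g], g))
    matrix = pd.DataFrame("none", index=gene_order, columns=sorted(sample_ids))
    for (gene, sample), kinds in events.items():
        matrix.loc[gene, sample] = kinds.pop() if len(kinds) == 1 else "multiple"
    matrix.index.name = "gene"
    return matrix


@dataclass
class ConcordanceResult:
    r_squared: float
    deltas: dict[VariantKey, float]
    detection_concordance: float  # fraction of keys detected by both or neither
    n: int
    defined: bool = True


def platform_concordance(
    af_pairs: Mapping[VariantKey, tuple[float, float]]
) -> ConcordanceResult:
    """Cross-platform allele-fraction concordance for shared variant keys.

    ``af_pairs`` maps each variant key to its (platform A, platform B)
    allele fractions (0 = not detected). Reports the R^2 of an ordinary
    least-squares fit of B on A, per-variant deltas (B - A), and the
    fraction of keys with concordant detection status.
    """
    if len(af_pairs) < 2:
        raise ValueError("need at least 2 variant pairs")
    keys = list(af_pairs)
    a = np.array([af_pairs[k][0] for k in keys], dtype=float)
    b = np.array([af_pairs[k][1] for k in keys], dtype=float)
    deltas = {k: float(bv - av) for k, av, bv in zip(keys, a, b)}
    detection = float(np.mean((a > 0) == (b > 0)))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return ConcordanceResult(
            r_squared=float("nan"),
            deltas=deltas,
            detection_concordance=detection,
            n=len(keys),
            defined=False,
        )
    res = stats.linregress(a, b)
    return ConcordanceResult(
        r_squared=float(res.rvalue**2),
        deltas=deltas,
        detection_concordance=detection,
        n=len(keys),
    )
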