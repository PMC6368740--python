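"""Multi-stage somatic variant filtering for tumor-only and ctDNA cohorts.

Tumor-only amplicon sequencing calls a mixture of true somatic mutations,
inherited (germline) variants, and platform-specific artifacts. The
cascade implemented here separates them with rule-based stages:

1. patient-matched germline subtraction (ctDNA cohorts only),
2. recurrence filter — a variant key seen in more than ``max_recurrence_samples``
   distinct samples is treated as a platform artifact or common SNP and
   removed from every sample,
3. non-coding removal, then synonymous removal, then removal of calls that
   could not be annotated (counted as its own stage),
4. population filter — known in ExAC or 1000 Genomes above ``pop_af_max``,
5. germline-AF filter — allele fraction above ``germline_af_min`` is
   presumed inherited,
6. strand-bias filter — calls outside the accepted forward-strand
   fraction window are presumed artifacts.

All comparative thresholds are strict inequalities ("more than 10",
"more than 1%", "above 90%"); the strand-bias window is closed on both
ends. Every stage reports input/surviving counts and the removed keys.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd

from .variant_io import VariantCall, VariantKey

__all__ = [
    "FilterConfig",
    "FilterStage",
    "FilterReport",
    "recurrence_artifact_filter",
    "coding_filter",
    "population_af_filter",
    "germline_af_filter",
    "strand_bias_filter",
    "subtract_germline",
    "run_cascade",
]


@dataclass
class FilterConfig:
    """Thresholds for the filter cascade.

    Defaults follow the published solid-tumor settings; use
    :meth:`ctdna_default` for liquid-biopsy cohorts (smaller cohort, hence
    a lower recurrence threshold, and a 1% research-grade AF floor that is
    not clinically validated).
    """

    max_recurrence_samples: int = 10
    pop_af_max: float = 0.01
    germline_af_min: float = 0.90
    strand_bias_range: tuple[float, float] = (0.5, 0.6)
    af_floor: float = 0.04
    drop_unannotated: bool = True

    def __post_init__(self) -> None:
        if self.max_recurrence_samples < 1:
            raise ValueError("max_recurrence_samples must be >= 1")
        if not 0 < self.af_floor < self.germline_af_min <= 1:
            raise ValueError("require 0 < af_floor < germline_af_min <= 1")
        low, high = self.strand_bias_range
        if low > high:
            raise ValueError("strand_bias_range low must be <= high")

    @classmethod
    def solid_default(cls) -> "FilterConfig":
        return cls()

    @classmethod
    def ctdna_default(cls) -> "FilterConfig":
        return cls(max_recurrence_samples=4, af_floor=0.01)


@dataclass
class FilterStage:
    """Accounting for one cascade stage."""

    name: str
    n_in: int
    n_out: int
    removed_keys: set[VariantKey] = field(default_factory=set)


@dataclass
class FilterReport:
    """Ordered per-stage accounting; stage inputs chain exactly."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, stage: FilterStage) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_out:
            raise ValueError(
                f"stage {stage.name!r} input count {stage.n_in} does not chain "
                f"from previous surviving count {self.stages[-1].n_out}"
            )
        if stage.n_in < 0 or stage.n_out < 0 or stage.n_out > stage.n_in:
            raise ValueError(f"stage {stage.name!r} has inconsistent counts")
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "input": s.n_in,
                    "surviving": s.n_out,
                    "removed": s.n_in - s.n_out,
                }
                for s in self.stages
            ]
        )


def _apply(
    calls: Sequence[VariantCall], keep: Callable[[VariantCall], bool]
) -> tuple[list[VariantCall], set[VariantKey]]:
    kept = [c for c in calls if keep(c)]
    removed = {c.key for c in calls if not keep(c)}
    return kept, removed


def recurrence_artifact_filter(
    calls: Sequence[VariantCall], max_samples: int
) -> list[VariantCall]:
    """Remove variant keys observed in more than ``max_samples`` samples.

    Recurrence across many unrelated tumors marks a platform artifact or a
    common SNP; the key is removed from all samples, not only the excess
    ones. The threshold is strict: a key in exactly ``max_samples``
    samples survives.
    """
    if max_samples < 1:
        raise ValueError("max_samples must be >= 1")
    n_samples_per_key = Counter()
    for key, samples in _samples_by_key(calls).items():
        n_samples_per_key[key] = len(samples)
    return [c for c in calls if n_samples_per_key[c.key] <= max_samples]


def _samples_by_key(calls: Sequence[VariantCall]) -> dict[VariantKey, set[str]]:
    by_key: dict[VariantKey, set[str]] = {}
    for c in calls:
        by_key.setdefault(c.key, set()).add(c.sample_id)
    return by_key


def coding_filter(
    calls: Sequence[VariantCall], drop_unannotated: bool = True
) -> list[VariantCall]:
    """Keep protein-altering calls: coding and non-synonymous.

    Unannotated calls (no consequence available) are removed by default;
    :func:`run_cascade` counts them as their own stage.
    """
    kept = [c for c in calls if c.is_coding]
    kept = [c for c in kept if not c.is_synonymous]
    if not drop_unannotated:
        kept += [c for c in calls if c.is_coding is None]
    return kept


def population_af_filter(
    calls: Sequence[VariantCall], pop_af_max: float = 0.01
) -> list[VariantCall]:
    """Remove variants common in population databases (strict >).

    A missing population AF means the variant is unknown to the databases
    and therefore cannot be removed by this stage.
    """
    return _apply(
        calls,
        lambda c: not (
            (c.pop_af_exac or 0.0) > pop_af_max or (c.pop_af_1kg or 0.0) > pop_af_max
        ),
    )[0]


def germline_af_filter(
    calls: Sequence[VariantCall], germline_af_min: float = 0.90
) -> list[VariantCall]:
    """Remove calls with allele fraction above the germline cutoff (strict)."""
    return [c for c in calls if c.allele_fraction <= germline_af_min]


def strand_bias_filter(
    calls: Sequence[VariantCall],
    sb_range: tuple[float, float] = (0.5, 0.6),
) -> list[VariantCall]:
    """Keep calls whose strand bias lies inside the closed window.

    Calls with no strand-bias value are retained (nothing to judge).
    """
    low, high = sb_range
    return [
        c for c in calls if c.strand_bias is None or low <= c.strand_bias <= high
    ]


def subtract_germline(
    ctdna_calls: Sequence[VariantCall],
    gdna_calls: Sequence[VariantCall],
    patient_map: Mapping[str, str],
) -> list[VariantCall]:
    """Remove patient-matched germline variants from ctDNA calls.

    ``patient_map`` maps each ctDNA sample id to the germline (buffy-coat)
    sample id from the same patient; several serial draws may share one
    germline sample. A ctDNA call is removed iff its variant key appears
    in the matched patient's germline calls — never another patient's.
    """
    ctdna_samples = {c.sample_id for c in ctdna_calls}
    unmatched = ctdna_samples - set(patient_map)
    if unmatched:
        raise ValueError(f"ctDNA samples with no matched germline sample: {sorted(unmatched)}")
    gdna_keys: dict[str, set[VariantKey]] = {}
    for c in gdna_calls:
        gdna_keys.setdefault(c.sample_id, set()).add(c.key)
    return [
        c
        for c in ctdna_calls
        if c.key not in gdna_keys.get(patient_map[c.sample_id], set())
    ]


def run_cascade(
    calls: Sequence[VariantCall],
    config: Optional[FilterConfig] = None,
    cohort: str = "solid",
    gdna_calls: Sequence[VariantCall] | None = None,
    patient_map: Mapping[str, str] | None = None,
) -> tuple[list[VariantCall], FilterReport]:
    """Run the full cascade in its frozen stage order with accounting.

    Order: [germline subtraction (ctDNA only)] -> recurrence -> non-coding
    -> synonymous -> unannotated -> population AF -> germline AF ->
    strand bias.
    """
    if cohort not in ("solid", "ctdna"):
        raise ValueError(f"cohort must be 'solid' or 'ctdna', got {cohort!r}")
    if config is None:
        config = FilterConfig.solid_default() if cohort == "solid" else FilterConfig.ctdna_default()

    report = FilterReport()
    current = list(calls)

    def _record(name: str, survivors: list[VariantCall]) -> list[VariantCall]:
        removed = {c.key for c in current} - {c.key for c in survivors}
        # only keys fully absent from survivors count as removed keys;
        # per-call removals within a surviving key are still reflected in counts
        report.add(FilterStage(name, n_in=len(current), n_out=len(survivors), removed_keys=removed))
        return survivors

    if cohort == "ctdna":
        if gdna_calls is None or patient_map is None:
            raise ValueError("ctDNA cascade requires gdna_calls and patient_map")
        current = _record(
            "germline_subtraction", subtract_germline(current, gdna_calls, patient_map)
        )

    current = _record(
        "recurrence", recurrence_artifact_filter(current, config.max_recurrence_samples)
    )
    current = _record("non_coding", [c for c in current if c.is_coding is not False])
    current = _record(
        "synonymous", [c for c in current if not (c.is_coding and c.is_synonymous)]
    )
    if config.drop_unannotated:
        current = _record("unannotated", [c for c in current if c.is_coding is not None])
    current = _record("population_af", population_af_filter(current, config.pop_af_max))
    current = _record("germline_af", germline_af_filter(current, config.germline_af_min))
    current = _record("strand_bias", strand_bias_filter(current, config.strand_bias_range))
    return current, report
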