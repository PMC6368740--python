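"""Clinical actionability tiering against a local knowledge base.

Filtered variants and copy-number calls are matched against a
knowledge-base table of (gene, alteration, evidence level, drugs), in the
style of the OncoKB precision-oncology database: level 1 is an
FDA-recognized biomarker, level 2 standard care, level 3 clinical-trial
evidence, level 4 compelling biological evidence. SNVs match on exact
(gene, protein change) after HGVS-style normalization (strip a leading
"p.", uppercase); amplified genes match the (gene, "Amplification")
entry. Each sample is then classified by its most actionable alteration
(numerically smallest level present).

The knowledge base is a versioned local TSV, not a live service query,
so results are deterministic and offline. A breast-cancer evidence scope
is assumed; a tumor-type column is reserved but unused.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .cnv_caller import CopyNumberCall

__all__ = [
    "KnowledgeBaseEntry",
    "ActionabilityCall",
    "ActionabilitySummary",
    "KnowledgeBaseError",
    "load_knowledge_base",
    "bundled_knowledge_base_path",
    "normalize_protein_change",
    "match_alterations",
    "classify_sample",
    "cohort_actionability_summary",
]

AMPLIFICATION = "Amplification"
VALID_LEVELS = {1, 2, 3, 4}


class KnowledgeBaseError(ValueError):
    """Raised on malformed or internally inconsistent knowledge bases."""


def normalize_protein_change(change: str) -> str:
    """Normalize an HGVS-like protein change for exact-string matching."""
    change = change.strip()
    if change.lower().startswith("p."):
        change = change[2:]
    return change.upper()


@dataclass(frozen=True)
class KnowledgeBaseEntry:
    gene: str
    alteration: str  # normalized protein change, or "Amplification"
    level: int
    drugs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.level not in VALID_LEVELS:
            raise KnowledgeBaseError(f"invalid evidence level: {self.level!r}")
        if not self.alteration:
            raise KnowledgeBaseError("alteration must be non-empty")


@dataclass(frozen=True)
class ActionabilityCall:
    """One actionable alteration observed in one sample."""

    sample_id: str
    gene: str
    alteration: str
    level: int
    drugs: tuple[str, ...] = ()
    allele_fraction: Optional[float] = None  # None for copy-number events

    def __post_init__(self) -> None:
        if self.allele_fraction is not None and not 0 <= self.allele_fraction <= 1:
            raise ValueError(f"allele fraction out of [0,1]: {self.allele_fraction}")


def bundled_knowledge_base_path() -> Path:
    """Path of the knowledge-base TSV shipped with the package."""
    return Path(str(resources.files("oncoamp").joinpath("data/oncokb_kb.tsv")))


def load_knowledge_base(path: str | Path | None = None) -> list[KnowledgeBaseEntry]:
    """Load and validate a knowledge base TSV (gene, alteration, level, drugs).

    The drugs cell is split on ";" — drug names may themselves contain
    "+" for combination regimens. Duplicate (gene, alteration) rows with
    conflicting levels raise :class:`KnowledgeBaseError`.
    """
    if path is None:
        path = bundled_knowledge_base_path()
    entries: dict[tuple[str, str], KnowledgeBaseEntry] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene", "alteration", "level", "drugs"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise KnowledgeBaseError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            try:
                level = int(row["level"])
            except ValueError as exc:
                raise KnowledgeBaseError(f"{path}: bad level {row['level']!r}") from exc
            alteration = row["alteration"].strip()
            if alteration != AMPLIFICATION:
                alteration = normalize_protein_change(alteration)
            drugs = tuple(d.strip() for d in row["drugs"].split(";") if d.strip())
            entry = KnowledgeBaseEntry(
                gene=row["gene"].strip(), alteration=alteration, level=level, drugs=drugs
            )
            key = (entry.gene, entry.alteration)
            if key in entries and entries[key].level != entry.level:
                raise KnowledgeBaseError(
                    f"{path}: conflicting levels for {key}: "
                    f"{entries[key].level} vs {entry.level}"
                )
            entries[key] = entry
    return list(entries.values())


def match_alterations(
    variants: Sequence,
    cnv_calls: Sequence[CopyNumberCall],
    kb: Sequence[KnowledgeBaseEntry],
) -> list[ActionabilityCall]:
    """Match variants and CNV calls against the knowledge base.

    ``variants`` need only expose sample_id, gene, protein_change and
    allele_fraction (duck-typed; :class:`~oncoamp.variant_io.VariantCall`
    qualifies). Unmatched alterations produce no call; every emitted call
    mirrors its knowledge-base entry exactly.
    """
    index = {(e.gene, e.alteration): e for e in kb}
    calls: list[ActionabilityCall] = []
    for v in variants:
        if not getattr(v, "protein_change", ""):
            continue
        key = (v.gene, normalize_protein_change(v.protein_change))
        entry = index.get(key)
        if entry is not None:
            calls.append(
                ActionabilityCall(
                    sample_id=v.sample_id,
                    gene=entry.gene,
                    alteration=entry.alteration,
                    level=entry.level,
                    drugs=entry.drugs,
                    allele_fraction=v.allele_fraction,
                )
            )
    for c in cnv_calls:
        if c.status != "amplified":
            continue
        entry = index.get((c.gene, AMPLIFICATION))
        if entry is not None:
            calls.append(
                ActionabilityCall(
                    sample_id=c.sample_id,
                    gene=entry.gene,
                    alteration=entry.alteration,
                    level=entry.level,
                    drugs=entry.drugs,
                )
            )
    return calls


def classify_sample(calls_for_sample: Iterable[ActionabilityCall]) -> Optional[int]:
    """Most actionable level among a sample's calls (1 best), None if no calls."""
    levels = [c.level for c in calls_for_sample]
    return min(levels) if levels else None


@dataclass
class ActionabilitySummary:
    """Cohort-level actionability accounting (distinct samples per level)."""

    n_samples: int
    samples_by_level: dict[int, set[str]] = field(default_factory=dict)
    n_alterations_by_level: dict[int, int] = field(default_factory=dict)

    @property
    def samples_level_1_3(self) -> set[str]:
        out: set[str] = set()
        for level in (1, 2, 3):
            out |= self.samples_by_level.get(level, set())
        return out

    @property
    def fraction_level_1_3(self) -> float:
        return len(self.samples_level_1_3) / self.n_samples


def cohort_actionability_summary(
    cohort_calls: Sequence[ActionabilityCall], n_samples: int
) -> ActionabilitySummary:
    """Count distinct samples and alterations per evidence level.

    ``n_samples`` is the cohort size (the fraction denominator), supplied
    by the caller because samples with no actionable alteration produce
    no calls.
    """
    distinct_samples = {c.sample_id for c in cohort_calls}
    if n_samples < len(distinct_samples):
        raise ValueError(
            f"n_samples ({n_samples}) is smaller than the number of distinct "
            f"samples with calls ({len(distinct_samples)})"
        )
    summary = ActionabilitySummary(n_samples=n_samples)
    for c in cohort_calls:
        summary.samples_by_level.setdefault(c.level, set()).add(c.sample_id)
        summary.n_alterations_by_level[c.level] = (
            summary.n_alterations_by_level.get(c.level, 0) + 1
        )
    return summary
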