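"""Amplicon panel representation, footprint arithmetic, and candidate scoring.

A targeted amplicon panel is a set of PCR-amplified genomic intervals
(amplicons) designed to cover recurrent hotspot mutations in a gene set.
This module loads panel designs from BED-like files, computes footprint and
cross-panel overlap statistics, scores candidate hotspot mutations for
inclusion against five prioritization criteria, and applies probe-design
failures to produce the final target list.

Coordinate conventions: amplicon intervals are 0-based half-open (BED);
hotspot positions are 1-based (VCF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Amplicon",
    "HotspotTarget",
    "PanelDesign",
    "CandidateMutation",
    "PanelOverlap",
    "DesignReport",
    "PanelFormatError",
    "load_panel",
    "footprint_bp",
    "merge_intervals",
    "intersect_intervals",
    "panel_overlap",
    "score_candidate",
    "finalize_panel",
    "gene_coverage_fraction",
    "tmb_suitability",
]

#: Minimum footprint (bp) below which panel-based mutational-burden
#: estimates are considered unreliable (0.5 Mb rule).
TMB_MIN_FOOTPRINT_BP = 500_000

#: Default minimum amplicon count for a gene to be eligible for
#: copy-number reporting ("more than 3 amplicons").
CNV_MIN_AMPLICONS = 4


class PanelFormatError(ValueError):
    """Raised when a panel input file is malformed; carries line numbers."""


@dataclass(frozen=True)
class Amplicon:
    """One targeted PCR interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    gene: str
    amplicon_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"amplicon {self.amplicon_id or self.gene}: end ({self.end}) "
                f"must exceed start ({self.start})"
            )
        if not self.gene:
            raise ValueError("amplicon gene symbol must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HotspotTarget:
    """One hotspot mutation the panel is designed to capture (1-based pos)."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    protein_change: str = ""
    design_ok: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"hotspot position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"hotspot ref and alt are identical: {self.ref}")


@dataclass
class CandidateMutation:
    """Evidence record for one candidate hotspot, scored for panel inclusion."""

    gene: str
    protein_change: str = ""
    is_smg: bool = False
    is_actionable: bool = False
    is_kinase_or_functional: bool = False
    n_primary: int = 0
    n_metastatic: int = 0
    in_both_settings: bool = False

    def __post_init__(self) -> None:
        if self.n_primary < 0 or self.n_metastatic < 0:
            raise ValueError("tumor counts must be non-negative")
        if self.in_both_settings and (self.n_primary < 1 or self.n_metastatic < 1):
            raise ValueError(
                "in_both_settings requires at least one primary and one "
                "metastatic observation"
            )


@dataclass
class PanelDesign:
    """An amplicon panel: intervals plus the hotspot mutations they target.

    ``genes`` derives from the amplicon gene symbols; for a target-only
    design (no amplicons yet, e.g. the output of :func:`finalize_panel`)
    it falls back to the target genes.
    """

    name: str
    amplicons: list[Amplicon] = field(default_factory=list)
    targets: list[HotspotTarget] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        if self.amplicons:
            return {a.gene for a in self.amplicons}
        return {t.gene for t in self.targets}

    def amplicon_counts(self) -> dict[str, int]:
        """Number of amplicons per gene."""
        counts: dict[str, int] = {}
        for a in self.amplicons:
            counts[a.gene] = counts.get(a.gene, 0) + 1
        return counts

    def cnv_eligible_genes(self, min_amplicons: int = CNV_MIN_AMPLICONS) -> set[str]:
        """Genes with enough amplicons for copy-number reporting."""
        return {g for g, n in self.amplicon_counts().items() if n >= min_amplicons}

    def intervals_by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for a in self.amplicons:
            by_chrom.setdefault(a.chrom, []).append((a.start, a.end))
        return by_chrom


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals on one sequence, sorted and merged."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def intersect_intervals(
    a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two half-open interval sets on one sequence."""
    a_merged, b_merged = merge_intervals(a), merge_intervals(b)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a_merged) and j < len(b_merged):
        lo = max(a_merged[i][0], b_merged[j][0])
        hi = min(a_merged[i][1], b_merged[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a_merged[i][1] < b_merged[j][1]:
            i += 1
        else:
            j += 1
    return out


def _interval_size(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(end - start for start, end in intervals)


def load_panel(
    bed_path: str | Path,
    targets_path: str | Path | None = None,
    name: str | None = None,
) -> PanelDesign:
    """Load a panel design from a BED file and an optional hotspot TSV.

    The BED file must have at least four columns (chrom, start, end, gene);
    a fifth column, if present, is the amplicon id. The hotspot TSV must
    have a header with columns gene, chrom, pos, ref, alt and may carry
    protein_change and design_ok.

    Malformed rows are reported together with their 1-based line numbers.
    """
    bed_path = Path(bed_path)
    amplicons: list[Amplicon] = []
    bad_lines: list[str] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                bad_lines.append(f"line {lineno}: expected >=4 columns, got {len(fields)}")
                continue
            try:
                amplicons.append(
                    Amplicon(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        gene=fields[3],
                        amplicon_id=fields[4] if len(fields) > 4 else f"amp_{lineno}",
                    )
                )
            except ValueError as exc:
                bad_lines.append(f"line {lineno}: {exc}")
    if bad_lines:
        raise PanelFormatError(f"{bed_path}: " + "; ".join(bad_lines))
    if not amplicons:
        raise PanelFormatError(f"{bed_path}: no amplicon intervals found")

    targets: list[HotspotTarget] = []
    if targets_path is not None:
        targets = _load_targets(Path(targets_path))

    return PanelDesign(name=name or bed_path.stem, amplicons=amplicons, targets=targets)


def _load_targets(path: Path) -> list[HotspotTarget]:
    required = {"gene", "chrom", "pos", "ref", "alt"}
    targets: list[HotspotTarget] = []
    bad_lines: list[str] = []
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise PanelFormatError(f"{path}: empty targets file")
        header = header_line.split("\t")
        missing = required - set(header)
        if missing:
            raise PanelFormatError(f"{path}: missing columns {sorted(missing)}")
        idx = {col: header.index(col) for col in header}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                targets.append(
                    HotspotTarget(
                        gene=fields[idx["gene"]],
                        chrom=fields[idx["chrom"]],
                        pos=int(fields[idx["pos"]]),
                        ref=fields[idx["ref"]],
                        alt=fields[idx["alt"]],
                        protein_change=(
                            fields[idx["protein_change"]] if "protein_change" in idx else ""
                        ),
                        design_ok=(
                            fields[idx["design_ok"]].strip().lower()
                            in ("1", "true", "yes")
                            if "design_ok" in idx
                            else True
                        ),
                    )
                )
            except (ValueError, IndexError) as exc:
                bad_lines.append(f"line {lineno}: {exc}")
    if bad_lines:
        raise PanelFormatError(f"{path}: " + "; ".join(bad_lines))
    return targets


def footprint_bp(panel: PanelDesign) -> int:
    """Total bases covered by the panel: union of amplicon intervals."""
    return sum(
        _interval_size(merge_intervals(ivs))
        for ivs in panel.intervals_by_chrom().values()
    )


@dataclass
class PanelOverlap:
    """Gene-set and base-pair overlap between two panel designs."""

    shared_genes: set[str]
    genes_only_a: set[str]
    genes_only_b: set[str]
    shared_bp: int


def panel_overlap(panel_a: PanelDesign, panel_b: PanelDesign) -> PanelOverlap:
    """Compare two panels by gene content and interval intersection size."""
    genes_a, genes_b = panel_a.genes, panel_b.genes
    by_chrom_a = panel_a.intervals_by_chrom()
    by_chrom_b = panel_b.intervals_by_chrom()
    shared_bp = sum(
        _interval_size(intersect_intervals(by_chrom_a[c], by_chrom_b[c]))
        for c in set(by_chrom_a) & set(by_chrom_b)
    )
    return PanelOverlap(
        shared_genes=genes_a & genes_b,
        genes_only_a=genes_a - genes_b,
        genes_only_b=genes_b - genes_a,
        shared_bp=shared_bp,
    )


def score_candidate(candidate: CandidateMutation) -> int:
    """Score a candidate hotspot against the five prioritization criteria.

    One point each for: (1) the gene is a significantly mutated gene,
    (2) the gene is clinically actionable (FDA-approved drug exists),
    (3) the gene is a kinase or otherwise of functional importance,
    (4) the mutation was observed in more than 5 primary OR more than 2
    metastatic tumors, (5) the mutation occurs in both primary and
    metastatic settings. Returns an integer in [0, 5].
    """
    score = 0
    score += candidate.is_smg
    score += candidate.is_actionable
    score += candidate.is_kinase_or_functional
    score += candidate.n_primary > 5 or candidate.n_metastatic > 2
    score += candidate.in_both_settings
    return int(score)


@dataclass
class DesignReport:
    """Outcome of applying probe-design results to a candidate target list."""

    n_input: int
    n_retained: int
    n_dropped: int
    dropped_genes: set[str]  # genes whose every target failed design


def finalize_panel(
    targets: Sequence[HotspotTarget], name: str = "final"
) -> tuple[PanelDesign, DesignReport]:
    """Drop targets whose probe design failed; report dropped counts/genes.

    A gene is reported as dropped when all of its targets failed design
    (it disappears from the panel entirely).
    """
    retained = [t for t in targets if t.design_ok]
    dropped = [t for t in targets if not t.design_ok]
    retained_genes = {t.gene for t in retained}
    dropped_genes = {t.gene for t in dropped} - retained_genes
    report = DesignReport(
        n_input=len(targets),
        n_retained=len(retained),
        n_dropped=len(dropped),
        dropped_genes=dropped_genes,
    )
    return PanelDesign(name=name, targets=retained), report


def gene_coverage_fraction(
    panel: PanelDesign,
    gene_models: Mapping[str, Sequence[tuple[str, int, int]]],
) -> tuple[dict[str, float], set[str]]:
    """Fraction of each gene's coding bases covered by panel amplicons.

    ``gene_models`` maps gene symbol to coding intervals as
    (chrom, start, end) tuples, 0-based half-open. Returns per-gene
    fractions in [0, 1] plus the set of panel genes absent from the
    models (reported, never silently scored 0).
    """
    by_gene: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for a in panel.amplicons:
        by_gene.setdefault(a.gene, {}).setdefault(a.chrom, []).append((a.start, a.end))

    fractions: dict[str, float] = {}
    missing: set[str] = set()
    for gene in panel.genes:
        if gene not in gene_models:
            missing.add(gene)
            continue
        coding_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in gene_models[gene]:
            coding_by_chrom.setdefault(chrom, []).append((start, end))
        coding_total = sum(
            _interval_size(merge_intervals(ivs)) for ivs in coding_by_chrom.values()
        )
        if coding_total == 0:
            fractions[gene] = 0.0
            continue
        amp_by_chrom = by_gene.get(gene, {})
        covered = sum(
            _interval_size(intersect_intervals(amp_by_chrom.get(c, []), ivs))
            for c, ivs in coding_by_chrom.items()
        )
        fractions[gene] = covered / coding_total
    return fractions, missing


@dataclass
class TmbSuitability:
    footprint_bp: int
    suitable: bool


def tmb_suitability(panel: PanelDesign) -> TmbSuitability:
    """Whether the panel footprint supports mutational-burden estimation.

    Panels below ~0.5 Mb yield highly variable burden estimates; the
    boundary (exactly 500,000 bp) is treated as suitable.
    """
    fp = footprint_bp(panel)
    return TmbSuitability(footprint_bp=fp, suitable=fp >= TMB_MIN_FOOTPRINT_BP)
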