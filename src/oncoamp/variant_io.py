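"""Reading and writing per-sample variant calls.

Variant observations come in as multi-sample VCF (one record per locus,
per-sample FORMAT fields for depth/alt observations/strand bias) and are
flattened into one :class:`VariantCall` per sample x locus x alt allele.
Annotations (gene, protein change, coding consequence, population allele
frequencies) arrive as a side table keyed by (chrom, pos, ref, alt) and
are attached after reading. Filtered call sets round-trip losslessly
through a sorted TSV.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "VariantCall",
    "AnnotationError",
    "read_vcf",
    "attach_annotations",
    "write_calls",
    "read_calls",
]

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "protein_change",
    "is_coding",
    "is_synonymous",
    "pop_af_exac",
    "pop_af_1kg",
]


class VariantKey(NamedTuple):
    """Sample-independent identity of a variant allele (1-based pos)."""

    chrom: str
    pos: int
    ref: str
    alt: str


class AnnotationError(ValueError):
    """Raised on conflicting duplicate annotations for one variant key."""


@dataclass(frozen=True)
class VariantCall:
    """One observed variant allele in one sample.

    ``is_coding`` is None until annotations are attached (unannotated);
    population allele frequencies are None when the variant is absent from
    the population databases.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    allele_fraction: float
    depth: int
    strand_bias: Optional[float] = None  # forward-strand fraction of alt reads
    gene: str = ""
    protein_change: str = ""
    is_coding: Optional[bool] = None
    is_synonymous: Optional[bool] = None
    pop_af_exac: Optional[float] = None
    pop_af_1kg: Optional[float] = None
    cohort: str = "solid"  # solid | ctdna | gdna

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele fraction out of [0,1]: {self.allele_fraction}")
        if self.depth < 0:
            raise ValueError(f"negative depth: {self.depth}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.strand_bias is not None and not 0.0 <= self.strand_bias <= 1.0:
            raise ValueError(f"strand bias out of [0,1]: {self.strand_bias}")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def annotated(self) -> bool:
        return self.is_coding is not None


def _format_value(sample, tag: str, index: int | None = None):
    """Fetch a FORMAT value, returning None when absent or missing."""
    if tag not in sample:
        return None
    val = sample[tag]
    if isinstance(val, tuple):
        if index is not None:
            val = val[index] if index < len(val) else None
        else:
            val = val[0] if val else None
    return val


def read_vcf(
    path: str | Path,
    sample_map: Mapping[str, str] | None = None,
    af_floor: float = 0.0,
    cohort: str = "solid",
    strand_bias_tag: str = "STB",
) -> list[VariantCall]:
    """Read a (multi-sample) VCF into flat per-sample variant calls.

    Multi-allelic records are split into one call per alt allele. The
    allele fraction comes from the per-sample AF field when present and is
    otherwise recomputed as alt observations / depth (AO/DP). Calls with
    allele fraction below ``af_floor`` are dropped (the floor itself is
    retained); samples with neither AF nor AO/DP at a record are skipped
    and counted in a warning. ``sample_map`` optionally renames VCF sample
    columns to cohort sample ids.
    """
    calls: list[VariantCall] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts):
                for vcf_sample, sample in rec.samples.items():
                    sample_id = (
                        sample_map.get(vcf_sample, vcf_sample) if sample_map else vcf_sample
                    )
                    depth = _format_value(sample, "DP")
                    ao = _format_value(sample, "AO", index=alt_index)
                    af = _format_value(sample, "AF", index=alt_index)
                    if af is None:
                        if ao is None or not depth:
                            n_skipped += 1
                            continue
                        af = ao / depth
                    else:
                        # FORMAT floats are stored as float32; round away the
                        # representation error so boundary AFs compare exactly
                        af = round(float(af), 6)
                    if af is None or af <= 0:
                        continue  # sample does not carry this alt
                    if af < af_floor:
                        continue
                    sb = _format_value(sample, strand_bias_tag, index=alt_index)
                    calls.append(
                        VariantCall(
                            sample_id=sample_id,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            allele_fraction=float(af),
                            depth=int(depth or 0),
                            strand_bias=None if sb is None else round(float(sb), 6),
                            cohort=cohort,
                        )
                    )
    if n_skipped:
        logger.warning("%s: skipped %d sample records lacking AF and AO/DP", path, n_skipped)
    return calls


def attach_annotations(
    calls: Sequence[VariantCall], annotation_table: pd.DataFrame
) -> list[VariantCall]:
    """Attach gene/consequence/population-AF annotations to calls.

    The table is keyed by (chrom, pos, ref, alt); duplicate keys with
    conflicting content raise :class:`AnnotationError`. Calls whose key is
    absent stay unannotated (``is_coding`` None, population AFs None) so
    downstream filters can count them explicitly.
    """
    table = annotation_table.copy()
    missing_cols = {"chrom", "pos", "ref", "alt"} - set(table.columns)
    if missing_cols:
        raise AnnotationError(f"annotation table missing columns {sorted(missing_cols)}")

    lookup: dict[VariantKey, dict] = {}
    for row in table.to_dict("records"):
        key = VariantKey(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        if key in lookup and lookup[key] != row:
            raise AnnotationError(f"conflicting duplicate annotations for {key}")
        lookup[key] = row

    def _opt_float(row: dict, col: str) -> Optional[float]:
        val = row.get(col)
        if val is None or (isinstance(val, float) and pd.isna(val)):
            return None
        return float(val)

    annotated: list[VariantCall] = []
    for call in calls:
        row = lookup.get(call.key)
        if row is None:
            annotated.append(call)
            continue
        annotated.append(
            replace(
                call,
                gene=str(row.get("gene", "") or ""),
                protein_change=str(row.get("protein_change", "") or ""),
                is_coding=bool(row["is_coding"]) if "is_coding" in row else None,
                is_synonymous=bool(row.get("is_synonymous", False)),
                pop_af_exac=_opt_float(row, "pop_af_exac"),
                pop_af_1kg=_opt_float(row, "pop_af_1kg"),
            )
        )
    return annotated


_TSV_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "allele_fraction",
    "depth",
    "strand_bias",
    "gene",
    "protein_change",
    "is_coding",
    "is_synonymous",
    "pop_af_exac",
    "pop_af_1kg",
    "cohort",
]


def _encode(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    return str(value)


def write_calls(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls to TSV, sorted by (chrom, pos, ref, alt, sample)."""
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt, c.sample_id))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for c in ordered:
            writer.writerow([_encode(getattr(c, col)) for col in _TSV_COLUMNS])


def read_calls(path: str | Path) -> list[VariantCall]:
    """Read back a call TSV written by :func:`write_calls`."""

    def _opt_bool(s: str) -> Optional[bool]:
        return None if s == "" else s == "1"

    def _opt_float(s: str) -> Optional[float]:
        return None if s == "" else float(s)

    calls: list[VariantCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            calls.append(
                VariantCall(
                    sample_id=row["sample_id"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    allele_fraction=float(row["allele_fraction"]),
                    depth=int(row["depth"]),
                    strand_bias=_opt_float(row["strand_bias"]),
                    gene=row["gene"],
                    protein_change=row["protein_change"],
                    is_coding=_opt_bool(row["is_coding"]),
                    is_synonymous=_opt_bool(row["is_synonymous"]),
                    pop_af_exac=_opt_float(row["pop_af_exac"]),
                    pop_af_1kg=_opt_float(row["pop_af_1kg"]),
                    cohort=row["cohort"],
                )
            )
    return calls
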