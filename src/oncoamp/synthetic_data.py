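"""Truth-labelled synthetic cohorts for end-to-end pipeline verification.

Real tumor-only amplicon data mixes somatic mutations with shared
germline variants, common SNPs, recurrent platform artifacts, and
non-coding or synonymous calls. This generator plants each of those
classes with attributes that violate exactly one filter stage
(separability), so the cascade's behaviour can be verified against a
known truth table: after filtering, the survivors must be exactly the
planted somatic calls.

Also generated: matched ctDNA/germline sample pairs, per-amplicon
coverage matrices with known integer copy number per gene, and serial
liquid-biopsy draws whose allele-fraction trajectory has a configured
correlation with a tumor-marker trajectory.

All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import pysam

from .cohort_report import SerialDraw, SerialDrawSeries
from .panel import Amplicon, PanelDesign
from .variant_io import ANNOTATION_COLUMNS, VariantCall, VariantKey

__all__ = [
    "CohortSpec",
    "TruthTable",
    "SyntheticCohort",
    "CoverageSet",
    "toy_panel",
    "generate_cohort",
    "generate_coverage",
    "generate_serial_draws",
]

# Breast-cancer driver genes used for the bundled toy panel.
_TOY_GENES = [
    "PIK3CA", "TP53", "ESR1", "ERBB2", "ATM", "CCND1", "FGF19", "FGFR1",
    "MYC", "AKT1", "GATA3", "MAP3K1", "CDH1", "PTEN", "KRAS", "BRAF",
    "FOXA1", "RB1", "NF1", "ARID1A", "KMT2C", "NCOR1", "CDK4", "CDK6",
    "MTOR", "BRCA1", "BRCA2", "EGFR", "IGF1R", "MDM2",
]


def toy_panel(
    n_genes: int = 30, amplicons_per_gene: int = 5, amplicon_length: int = 120
) -> PanelDesign:
    """A small deterministic amplicon panel over breast-cancer driver genes.

    The last two genes get only 2 amplicons each so the copy-number
    eligibility rule (>= 4 amplicons) has something to exclude.
    """
    genes = (_TOY_GENES * (n_genes // len(_TOY_GENES) + 1))[:n_genes]
    amplicons: list[Amplicon] = []
    for gi, gene in enumerate(genes):
        chrom = f"chr{gi % 5 + 1}"
        n_amps = 2 if gi >= n_genes - 2 else amplicons_per_gene
        gene_start = 1_000_000 + gi * 100_000
        for ai in range(n_amps):
            start = gene_start + ai * (amplicon_length + 30)
            amplicons.append(
                Amplicon(
                    chrom=chrom,
                    start=start,
                    end=start + amplicon_length,
                    gene=gene,
                    amplicon_id=f"{gene}_amp{ai + 1}",
                )
            )
    return PanelDesign(name="toy_panel", amplicons=amplicons)


@dataclass
class CohortSpec:
    """Parameters of a synthetic variant-call cohort.

    Defaults emulate the published solid-tumor study conditions: 46
    samples, around 3 somatic mutations per typical sample with a small
    hypermutated subset carrying most of the cohort's mutations, somatic
    allele fractions spanning the detectable range (floor 4%) up to the
    germline cutoff (90%), germline variants shared across more samples
    than the recurrence threshold (10), and recurrent artifacts with
    extreme strand bias.
    """

    n_samples: int = 46
    n_germline_shared: int = 8
    n_germline_private: int = 5
    n_artifacts: int = 5
    n_common_snp: int = 6
    n_synonymous: int = 6
    n_noncoding: int = 8
    mean_somatic_per_sample: float = 3.0
    n_hypermutated: int = 4
    hypermutated_burden: float = 60.0
    somatic_af_range: tuple[float, float] = (0.04, 0.90)
    strand_bias_window: tuple[float, float] = (0.5, 0.6)
    recurrence_threshold: int = 10
    snp_pop_af_range: tuple[float, float] = (0.02, 0.40)
    depth: int = 2311
    cohort: str = "solid"  # solid | ctdna
    draws_per_patient: int = 2  # ctDNA only: serial draws sharing one gDNA sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_hypermutated > self.n_samples:
            raise ValueError("more hypermutated samples than samples")
        lo, hi = self.somatic_af_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("invalid somatic_af_range")
        if self.n_germline_shared > 0 and self.n_samples <= self.recurrence_threshold:
            raise ValueError(
                "shared germline keys must recur in more samples than the "
                "recurrence threshold; lower recurrence_threshold or raise n_samples"
            )


@dataclass
class TruthTable:
    """Ground truth for a synthetic cohort.

    ``classes`` maps every planted variant key to its class; ``removal_stage``
    names the cascade stage expected to remove it (None for somatic
    survivors). ``cn_by_sample`` holds planted absolute copy number per
    gene where coverage was generated.
    """

    classes: dict[VariantKey, str] = field(default_factory=dict)
    removal_stage: dict[VariantKey, Optional[str]] = field(default_factory=dict)
    cn_by_sample: dict[str, dict[str, float]] = field(default_factory=dict)

    def keys_of_class(self, cls: str) -> set[VariantKey]:
        return {k for k, c in self.classes.items() if c == cls}

    @property
    def somatic_keys(self) -> set[VariantKey]:
        return self.keys_of_class("somatic")


@dataclass
class SyntheticCohort:
    """Generated cohort: annotated calls, annotation table, and truth."""

    spec: CohortSpec
    sample_ids: list[str]
    calls: list[VariantCall]
    annotations: pd.DataFrame
    truth: TruthTable
    gdna_calls: list[VariantCall] = field(default_factory=list)
    patient_map: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit VCF + annotation TSV + truth TSV; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out_dir / "cohort.vcf",
            "annotations": out_dir / "annotations.tsv",
            "truth": out_dir / "truth.tsv",
        }
        _write_vcf(self.calls, self.sample_ids, paths["vcf"])
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        truth_rows = [
            {
                "chrom": k.chrom,
                "pos": k.pos,
                "ref": k.ref,
                "alt": k.alt,
                "class": cls,
                "removal_stage": self.truth.removal_stage.get(k) or "",
            }
            for k, cls in sorted(self.truth.classes.items())
        ]
        pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
        if self.gdna_calls:
            paths["gdna_vcf"] = out_dir / "gdna.vcf"
            gdna_samples = sorted({c.sample_id for c in self.gdna_calls})
            _write_vcf(self.gdna_calls, gdna_samples, paths["gdna_vcf"])
        return paths


_BASES = ["A", "C", "G", "T"]


class _KeyFactory:
    """Draws unique variant positions from a panel's amplicon intervals."""

    def __init__(self, panel: PanelDesign, rng: np.random.Generator):
        self._rng = rng
        self._positions: list[tuple[str, int, str]] = []  # (chrom, 1-based pos, gene)
        for a in panel.amplicons:
            for pos in range(a.start + 1, a.end + 1):
                self._positions.append((a.chrom, pos, a.gene))
        self._order = rng.permutation(len(self._positions))
        self._cursor = 0

    def next_key(self) -> tuple[VariantKey, str]:
        if self._cursor >= len(self._order):
            raise ValueError("panel exhausted: more planted keys than panel positions")
        chrom, pos, gene = self._positions[self._order[self._cursor]]
        self._cursor += 1
        ref, alt = self._rng.choice(_BASES, size=2, replace=False)
        return VariantKey(chrom, pos, str(ref), str(alt)), gene


def _outside_window(rng: np.random.Generator, window: tuple[float, float]) -> float:
    """A strand-bias value strictly outside the accepted window."""
    low, high = window
    left = rng.uniform(0.0, max(low - 0.05, 0.01))
    right = rng.uniform(min(high + 0.05, 0.99), 1.0)
    return float(left if rng.random() < 0.5 else right)


def generate_cohort(spec: CohortSpec, panel: PanelDesign | None = None) -> SyntheticCohort:
    """Generate a truth-labelled cohort of annotated variant calls.

    Every planted class is separable: it fails exactly one cascade stage
    (germline subtraction for ctDNA patient germline, recurrence for
    shared germline, consequence stages for non-coding/synonymous,
    population AF for common SNPs, germline AF for private high-AF
    germline, strand bias for artifacts) while passing all others.
    Somatic calls pass every stage.
    """
    rng = np.random.default_rng(spec.seed)
    if panel is None:
        panel = toy_panel()
    keys = _KeyFactory(panel, rng)
    truth = TruthTable()
    sb_lo, sb_hi = spec.strand_bias_window

    if spec.cohort == "ctdna":
        n_patients = max(1, spec.n_samples // spec.draws_per_patient)
        sample_ids = []
        patient_map: dict[str, str] = {}
        for p in range(n_patients):
            for d in range(spec.draws_per_patient):
                if len(sample_ids) >= spec.n_samples:
                    break
                sid = f"CF_{p + 1:02d}_Draw_{d + 1}"
                sample_ids.append(sid)
                patient_map[sid] = f"gDNA_{p + 1:02d}"
        # pad with singleton patients if needed
        while len(sample_ids) < spec.n_samples:
            p = len(patient_map) + 1
            sid = f"CF_{p:02d}_Draw_1"
            sample_ids.append(sid)
            patient_map[sid] = f"gDNA_{p:02d}"
    else:
        sample_ids = [f"MET_{i + 1:02d}" for i in range(spec.n_samples)]
        patient_map = {}

    calls: list[VariantCall] = []
    gdna_calls: list[VariantCall] = []
    annotation_rows: list[dict] = []

    def good_sb() -> float:
        return float(rng.uniform(sb_lo, sb_hi))

    def somatic_af() -> float:
        return float(rng.uniform(*spec.somatic_af_range))

    def depth() -> int:
        return int(rng.poisson(spec.depth))

    def annotate(
        key: VariantKey,
        gene: str,
        coding: bool,
        synonymous: bool = False,
        pop_af: float = 0.0,
        protein_change: str = "",
    ) -> None:
        annotation_rows.append(
            {
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "gene": gene,
                "protein_change": protein_change,
                "is_coding": coding,
                "is_synonymous": synonymous,
                "pop_af_exac": pop_af if pop_af > 0 else None,
                "pop_af_1kg": None,
            }
        )

    def emit(key: VariantKey, gene: str, sample: str, af: float, sb: float) -> None:
        calls.append(
            VariantCall(
                sample_id=sample,
                chrom=key.chrom,
                pos=key.pos,
                ref=key.ref,
                alt=key.alt,
                allele_fraction=round(af, 6),
                depth=depth(),
                strand_bias=round(sb, 4),
                cohort=spec.cohort,
            )
        )

    def plant(
        cls: str,
        stage: Optional[str],
        carriers: list[str],
        af_fn,
        sb_fn,
        coding: bool = True,
        synonymous: bool = False,
        pop_af: float = 0.0,
    ) -> VariantKey:
        key, gene = keys.next_key()
        truth.classes[key] = cls
        truth.removal_stage[key] = stage
        annotate(key, gene, coding=coding, synonymous=synonymous, pop_af=pop_af,
                 protein_change="" if not coding else f"A{key.pos % 997 + 1}V")
        for sample in carriers:
            emit(key, gene, sample, af_fn(), sb_fn())
        return key

    def pick_samples(n: int) -> list[str]:
        n = min(n, len(sample_ids))
        return [sample_ids[i] for i in rng.choice(len(sample_ids), size=n, replace=False)]

    # -- patient-matched germline (ctDNA only): in every draw of a patient
    #    and in the matched gDNA sample; removed by germline subtraction.
    if spec.cohort == "ctdna":
        patients: dict[str, list[str]] = {}
        for sid, gid in patient_map.items():
            patients.setdefault(gid, []).append(sid)
        for gid, draws in patients.items():
            for _ in range(2):  # two germline hets per patient
                key, gene = keys.next_key()
                truth.classes[key] = "germline"
                truth.removal_stage[key] = "germline_subtraction"
                annotate(key, gene, coding=True,
                         protein_change=f"G{key.pos % 997 + 1}S")
                for sid in draws:
                    emit(key, gene, sid, float(np.clip(rng.normal(0.5, 0.03), 0.35, 0.65)),
                         good_sb())
                gdna_calls.append(
                    VariantCall(
                        sample_id=gid,
                        chrom=key.chrom,
                        pos=key.pos,
                        ref=key.ref,
                        alt=key.alt,
                        allele_fraction=0.5,
                        depth=depth(),
                        strand_bias=good_sb(),
                        cohort="gdna",
                    )
                )

    # -- shared germline / platform-recurrent keys: in more samples than the
    #    recurrence threshold, otherwise clean; removed by recurrence.
    for _ in range(spec.n_germline_shared):
        n_carriers = int(
            rng.integers(spec.recurrence_threshold + 1, spec.n_samples + 1)
        )
        plant(
            "germline",
            "recurrence",
            pick_samples(n_carriers),
            af_fn=lambda: float(np.clip(rng.normal(0.5, 0.03), 0.35, 0.65)),
            sb_fn=good_sb,
        )

    # -- private germline at near-homozygous AF; removed by the germline-AF
    #    cutoff (AF above 90%).
    for _ in range(spec.n_germline_private):
        plant(
            "germline",
            "germline_af",
            pick_samples(1),
            af_fn=lambda: float(rng.uniform(0.92, 0.99)),
            sb_fn=good_sb,
        )

    # -- recurrent artifacts with extreme strand bias; carried by exactly the
    #    recurrence-threshold number of samples (so they survive the
    #    recurrence stage) and removed by the strand-bias window.
    for _ in range(spec.n_artifacts):
        plant(
            "artifact",
            "strand_bias",
            pick_samples(min(spec.recurrence_threshold, spec.n_samples)),
            af_fn=somatic_af,
            sb_fn=lambda: _outside_window(rng, spec.strand_bias_window),
        )

    # -- common SNPs: annotated in the population databases above 1%.
    for _ in range(spec.n_common_snp):
        plant(
            "common_snp",
            "population_af",
            pick_samples(int(rng.integers(1, 4))),
            af_fn=lambda: float(np.clip(rng.normal(0.5, 0.03), 0.35, 0.65)),
            sb_fn=good_sb,
            pop_af=float(rng.uniform(*spec.snp_pop_af_range)),
        )

    # -- synonymous and non-coding calls.
    for _ in range(spec.n_synonymous):
        plant("synonymous", "synonymous", pick_samples(int(rng.integers(1, 4))),
              af_fn=somatic_af, sb_fn=good_sb, synonymous=True)
    for _ in range(spec.n_noncoding):
        plant("noncoding", "non_coding", pick_samples(int(rng.integers(1, 4))),
              af_fn=somatic_af, sb_fn=good_sb, coding=False)

    # -- somatic truth: private protein-altering calls that pass every stage.
    hyper = set(rng.choice(len(sample_ids), size=spec.n_hypermutated, replace=False))
    for i, sample in enumerate(sample_ids):
        mean = spec.hypermutated_burden if i in hyper else spec.mean_somatic_per_sample
        n_somatic = max(1, int(rng.poisson(mean)))
        for _ in range(n_somatic):
            plant("somatic", None, [sample], af_fn=somatic_af, sb_fn=good_sb)

    annotations = pd.DataFrame(annotation_rows, columns=ANNOTATION_COLUMNS)
    return SyntheticCohort(
        spec=spec,
        sample_ids=sample_ids,
        calls=calls,
        annotations=annotations,
        truth=truth,
        gdna_calls=gdna_calls,
        patient_map=patient_map,
    )


def _write_vcf(calls: list[VariantCall], sample_ids: list[str], path: Path) -> None:
    """Write calls as an uncompressed multi-sample VCF (one record per key)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alt observations">')
    header.add_line('##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">')
    header.add_line(
        '##FORMAT=<ID=STB,Number=A,Type=Float,Description="Forward-strand fraction of alt reads">'
    )
    contigs = sorted({c.chrom for c in calls})
    max_pos = max((c.pos for c in calls), default=1)
    for contig in contigs:
        header.add_line(f"##contig=<ID={contig},length={max_pos + 10_000}>")
    for sid in sample_ids:
        header.add_sample(sid)

    by_key: dict[VariantKey, dict[str, VariantCall]] = {}
    for c in calls:
        by_key.setdefault(c.key, {})[c.sample_id] = c

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for key in sorted(by_key, key=lambda k: (k.chrom, k.pos, k.ref, k.alt)):
            rec = vcf.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            for sid in sample_ids:
                call = by_key[key].get(sid)
                sample = rec.samples[sid]
                if call is None:
                    sample["GT"] = (0, 0)
                    sample["DP"] = 0
                    sample["AO"] = 0
                    sample["AF"] = 0.0
                else:
                    sample["GT"] = (0, 1)
                    sample["DP"] = call.depth
                    sample["AO"] = int(round(call.allele_fraction * call.depth))
                    sample["AF"] = call.allele_fraction
                    if call.strand_bias is not None:
                        sample["STB"] = call.strand_bias
            vcf.write(rec)


@dataclass
class CoverageSet:
    """Synthetic per-amplicon count matrices (amplicons x samples)."""

    normals: pd.DataFrame
    tumors: pd.DataFrame
    cn_truth: dict[str, dict[str, float]]  # sample -> gene -> absolute CN


def generate_coverage(
    panel: PanelDesign,
    cn_truth: Mapping[str, Mapping[str, float]],
    n_normals: int = 14,
    depth: int = 2311,
    seed: int = 0,
    weight_sigma: float = 0.3,
) -> CoverageSet:
    """Simulate amplicon read counts for normals and copy-altered tumors.

    A fixed per-amplicon efficiency profile (log-normal, ``weight_sigma``)
    emulates unequal amplification; each sample's counts are a multinomial
    draw of ``depth * n_amplicons`` total reads over that profile, with a
    tumor gene's amplicons up-/down-weighted by CN/2. ``cn_truth`` maps
    tumor sample -> gene -> planted absolute copy number (unlisted genes
    are diploid).
    """
    if n_normals < 2:
        raise ValueError("need at least 2 normal samples")
    rng = np.random.default_rng(seed)
    amp_ids = [a.amplicon_id for a in panel.amplicons]
    genes = [a.gene for a in panel.amplicons]
    weights = rng.lognormal(mean=0.0, sigma=weight_sigma, size=len(amp_ids))
    total_reads = depth * len(amp_ids)

    def draw(sample_weights: np.ndarray) -> np.ndarray:
        probs = sample_weights / sample_weights.sum()
        return rng.multinomial(total_reads, probs)

    normals = pd.DataFrame(
        {f"N_{i + 1:02d}": draw(weights) for i in range(n_normals)}, index=amp_ids
    )
    tumors = {}
    for sample, gene_cn in cn_truth.items():
        scale = np.array([gene_cn.get(g, 2.0) / 2.0 for g in genes])
        tumors[sample] = draw(weights * scale)
    tumor_df = pd.DataFrame(tumors, index=amp_ids)
    return CoverageSet(
        normals=normals,
        tumors=tumor_df,
        cn_truth={s: dict(g) for s, g in cn_truth.items()},
    )


def generate_serial_draws(
    patient_id: str = "CF_01",
    n_draws: int = 5,
    target_r: float = 0.9,
    n_variants: int = 2,
    seed: int = 0,
    llod: float = 0.001,
    interval_days: int = 90,
) -> tuple[SerialDrawSeries, dict[VariantKey, float]]:
    """Serial blood draws with a configured AF / tumor-marker correlation.

    The marker trajectory (CA 27.29-like units) is drawn first; each
    variant's allele-fraction trajectory is built as
    ``r * marker_z + sqrt(1-r^2) * noise`` in standardized space, so the
    population correlation equals ``target_r`` (exact at the sample level
    when ``|target_r| = 1``). AFs below ``llod`` are censored to 0,
    emulating a ddPCR lower limit of detection of 0.1%.
    """
    if n_draws < 3:
        raise ValueError("need at least 3 draws")
    if not -1 <= target_r <= 1:
        raise ValueError("target_r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    marker_z = rng.normal(size=n_draws)
    while np.ptp(marker_z) == 0:  # degenerate draw; cannot standardize
        marker_z = rng.normal(size=n_draws)
    marker_z = (marker_z - marker_z.mean()) / marker_z.std()
    marker = 35.0 + 18.0 * marker_z

    draws = [
        SerialDraw(date=i * interval_days, afs={}, marker_value=float(marker[i]))
        for i in range(n_draws)
    ]
    truth: dict[VariantKey, float] = {}
    for vi in range(n_variants):
        key = VariantKey("chr6", 152_098_700 + vi * 1000, "A", "G")
        noise = rng.normal(size=n_draws)
        noise = noise - noise.mean()
        if noise.std() > 0:
            noise = noise / noise.std()
        af_z = target_r * marker_z + np.sqrt(max(0.0, 1 - target_r**2)) * noise
        afs = np.clip(0.08 + 0.04 * af_z, 0.0, 1.0)
        for i, d in enumerate(draws):
            af = float(afs[i])
            d.afs[key] = 0.0 if af < llod else af
        truth[key] = target_r
    return SerialDrawSeries(patient_id=patient_id, draws=draws), truth
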