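"""Panel loading, footprint arithmetic, candidate scoring, design finalization."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncoamp.panel import (
    Amplicon,
    CandidateMutation,
    HotspotTarget,
    PanelDesign,
    PanelFormatError,
    finalize_panel,
    footprint_bp,
    gene_coverage_fraction,
    intersect_intervals,
    load_panel,
    merge_intervals,
    panel_overlap,
    score_candidate,
    tmb_suitability,
)


def _panel(intervals, gene="G", chrom="chr1"):
    return PanelDesign(
        name="t",
        amplicons=[
            Amplicon(chrom=chrom, start=s, end=e, gene=gene, amplicon_id=f"a{i}")
            for i, (s, e) in enumerate(intervals)
        ],
    )


class TestTypes:
    def test_amplicon_rejects_empty_interval_and_gene(self):
        with pytest.raises(ValueError):
            Amplicon("chr1", 100, 100, "G")
        with pytest.raises(ValueError):
            Amplicon("chr1", 100, 200, "")

    def test_hotspot_requires_vcf_convention(self):
        with pytest.raises(ValueError):
            HotspotTarget("G", "chr1", 0, "A", "C")
        with pytest.raises(ValueError):
            HotspotTarget("G", "chr1", 5, "A", "A")

    def test_candidate_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            CandidateMutation(gene="G", n_primary=-1)

    def test_in_both_settings_implies_counts(self):
        with pytest.raises(ValueError):
            CandidateMutation(gene="G", in_both_settings=True, n_primary=0, n_metastatic=1)


class TestLoadPanel:
    def test_load_and_cnv_eligibility(self, tmp_path):
        # 4 amplicons in gene A, 2 in gene B: only A is CNV-eligible
        bed = tmp_path / "p.bed"
        rows = [("chr1", 100 * i, 100 * i + 50, "A") for i in range(4)]
        rows += [("chr2", 100 * i, 100 * i + 50, "B") for i in range(2)]
        bed.write_text("".join(f"{c}\t{s}\t{e}\t{g}\n" for c, s, e, g in rows))
        design = load_panel(bed)
        assert design.genes == {"A", "B"}
        assert design.cnv_eligible_genes() == {"A"}

    def test_overlapping_amplicons_same_gene_accepted(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t0\t100\tG\nchr1\t50\t150\tG\n")
        design = load_panel(bed)
        assert design.genes == {"G"}
        assert len(design.amplicons) == 2

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t0\t100\tG\nchr1\tnot_an_int\t5\tG\nchr1\t10\n")
        with pytest.raises(PanelFormatError, match="line 2"):
            load_panel(bed)
        bed.write_text("chr1\t0\t100\tG\nchr1\t10\n")
        with pytest.raises(PanelFormatError, match="line 2"):
            load_panel(bed)

    def test_empty_bed_is_an_error(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("")
        with pytest.raises(PanelFormatError, match="no amplicon"):
            load_panel(bed)

    def test_targets_missing_columns(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t0\t100\tG\n")
        targets = tmp_path / "t.tsv"
        targets.write_text("gene\tchrom\tpos\n")
        with pytest.raises(PanelFormatError, match="missing columns"):
            load_panel(bed, targets)


class TestFootprint:
    @pytest.mark.parametrize(
        "intervals,expected",
        [
            ([(0, 100), (50, 150)], 150),  # overlapping: union, not sum
            ([(0, 10), (20, 30)], 20),  # disjoint
            ([(0, 10), (10, 20)], 20),  # adjacent half-open intervals touch
        ],
    )
    def test_union_arithmetic(self, intervals, expected):
        assert footprint_bp(_panel(intervals)) == expected

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 100)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=1,
            max_size=20,
        ),
        st.randoms(use_true_random=False),
    )
    def test_invariant_to_order_and_splitting(self, intervals, rnd):
        base = footprint_bp(_panel(intervals))
        shuffled = list(intervals)
        rnd.shuffle(shuffled)
        assert footprint_bp(_panel(shuffled)) == base
        # split the first amplicon into two adjacent pieces
        s, e = intervals[0]
        if e - s >= 2:
            mid = (s + e) // 2
            split = [(s, mid), (mid, e)] + intervals[1:]
            assert footprint_bp(_panel(split)) == base

    def test_merge_agrees_with_pyranges(self):
        pyranges = pytest.importorskip("pyranges")
        import pandas as pd

        rng = random.Random(7)
        starts = [rng.randrange(0, 10_000) for _ in range(200)]
        intervals = [(s, s + rng.randrange(1, 300)) for s in starts]
        ours = sum(e - s for s, e in merge_intervals(intervals))
        df = pd.DataFrame(
            {
                "Chromosome": "chr1",
                "Start": [s for s, _ in intervals],
                "End": [e for _, e in intervals],
            }
        )
        merged = pyranges.PyRanges(df).merge()
        theirs = int((merged.End - merged.Start).sum())
        assert ours == theirs


class TestOverlap:
    def test_identical_panels(self):
        p = _panel([(0, 100), (200, 300)])
        ov = panel_overlap(p, p)
        assert ov.shared_genes == p.genes
        assert not ov.genes_only_a and not ov.genes_only_b
        assert ov.shared_bp == footprint_bp(p)

    def test_disjoint_gene_sets(self):
        a = _panel([(0, 100)], gene="A")
        b = _panel([(0, 100)], gene="B", chrom="chr9")
        assert panel_overlap(a, b).shared_genes == set()

    def test_gene_sets_by_enumeration(self):
        # 5-gene vs 3-gene toy with 2 common genes, checked by brute force
        genes_a = ["G1", "G2", "G3", "G4", "G5"]
        genes_b = ["G4", "G5", "G6"]
        a = PanelDesign(
            "a", [Amplicon("chr1", i * 100, i * 100 + 50, g) for i, g in enumerate(genes_a)]
        )
        b = PanelDesign(
            "b", [Amplicon("chr2", i * 100, i * 100 + 50, g) for i, g in enumerate(genes_b)]
        )
        expected_shared = {g for g in genes_a if g in genes_b}
        ov = panel_overlap(a, b)
        assert ov.shared_genes == expected_shared
        assert len(ov.shared_genes) == 2
        # symmetry
        rev = panel_overlap(b, a)
        assert rev.shared_genes == ov.shared_genes
        assert rev.shared_bp == ov.shared_bp

    def test_shared_bp_bounded_by_min_footprint(self):
        a = _panel([(0, 100), (150, 400)])
        b = _panel([(50, 200)])
        ov = panel_overlap(a, b)
        assert ov.shared_bp <= min(footprint_bp(a), footprint_bp(b))
        assert ov.shared_bp == (100 - 50) + (200 - 150)

    def test_intersect_intervals_closed_form(self):
        assert intersect_intervals([(0, 100)], [(50, 150)]) == [(50, 100)]
        assert intersect_intervals([(0, 10)], [(10, 20)]) == []


class TestScoreCandidate:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (
                dict(is_smg=True, is_actionable=True, is_kinase_or_functional=True,
                     n_primary=10, n_metastatic=3, in_both_settings=True),
                5,
            ),
            (dict(), 0),
            (dict(is_actionable=True, n_primary=6), 2),  # criteria 2 and 4
            (dict(n_primary=5, n_metastatic=2), 0),  # strict: "more than 5 / 2"
            (dict(n_metastatic=3), 1),
        ],
    )
    def test_examples(self, kwargs, expected):
        assert score_candidate(CandidateMutation(gene="G", **kwargs)) == expected

    @settings(max_examples=60, derandomize=True)
    @given(
        st.booleans(), st.booleans(), st.booleans(),
        st.integers(1, 20), st.integers(1, 20), st.booleans(),
    )
    def test_monotone_in_every_criterion(self, smg, act, kin, n_p, n_m, both):
        base = CandidateMutation(
            gene="G", is_smg=smg, is_actionable=act, is_kinase_or_functional=kin,
            n_primary=n_p, n_metastatic=n_m, in_both_settings=both,
        )
        score = score_candidate(base)
        for flag in ("is_smg", "is_actionable", "is_kinase_or_functional", "in_both_settings"):
            kwargs = dict(
                is_smg=smg, is_actionable=act, is_kinase_or_functional=kin,
                n_primary=n_p, n_metastatic=n_m, in_both_settings=both,
            )
            kwargs[flag] = True
            assert score_candidate(CandidateMutation(gene="G", **kwargs)) >= score


def _candidate_targets(n_total=1398, n_failed=29):
    """Candidate list with a known number of design failures, including one
    gene whose every target failed (so it drops out of the panel)."""
    targets = []
    fully_failed_gene = "GENE_F"
    for i in range(3):  # all 3 targets of GENE_F fail design
        targets.append(
            HotspotTarget(fully_failed_gene, "chr9", 1000 + i, "A", "C", design_ok=False)
        )
    for i in range(n_failed - 3):
        targets.append(HotspotTarget(f"GENE_{i % 40}", "chr1", 5000 + i, "A", "G", design_ok=False))
    for i in range(n_total - n_failed):
        targets.append(HotspotTarget(f"GENE_{i % 77}", "chr2", 10_000 + i, "C", "T"))
    return targets


class TestFinalizePanel:
    def test_design_failures_are_dropped(self):
        targets = _candidate_targets()
        design, report = finalize_panel(targets)
        assert report.n_input == 1398
        assert report.n_dropped == 29
        assert report.n_retained == 1369
        assert len(design.targets) == 1369

    def test_gene_with_all_targets_failed_is_absent(self):
        design, report = finalize_panel(_candidate_targets())
        assert "GENE_F" not in design.genes
        assert "GENE_F" in report.dropped_genes

    def test_no_failures_is_identity(self):
        targets = [HotspotTarget("G", "chr1", i + 1, "A", "T") for i in range(10)]
        design, report = finalize_panel(targets)
        assert design.targets == targets
        assert report.n_dropped == 0 and not report.dropped_genes

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.booleans(), min_size=0, max_size=50))
    def test_retained_plus_dropped_conserved(self, flags):
        targets = [
            HotspotTarget(f"G{i % 5}", "chr1", i + 1, "A", "C", design_ok=ok)
            for i, ok in enumerate(flags)
        ]
        _, report = finalize_panel(targets)
        assert report.n_retained + report.n_dropped == report.n_input == len(targets)


class TestGeneCoverage:
    def test_exact_tiling_and_no_overlap(self):
        p = PanelDesign("p", [Amplicon("chr1", 0, 1000, "A"), Amplicon("chr2", 0, 10, "B")])
        models = {"A": [("chr1", 0, 1000)], "B": [("chr3", 0, 500)]}
        fractions, missing = gene_coverage_fraction(p, models)
        assert fractions["A"] == 1.0
        assert fractions["B"] == 0.0
        assert not missing

    def test_partial_coverage_interval_arithmetic(self):
        # coding region of 1000 bp, amplicons cover 250 bp of it
        p = PanelDesign("p", [Amplicon("chr1", 100, 250, "A"), Amplicon("chr1", 400, 500, "A")])
        fractions, _ = gene_coverage_fraction(p, {"A": [("chr1", 0, 1000)]})
        assert fractions["A"] == pytest.approx(0.25)

    def test_missing_gene_reported_not_zero(self):
        p = _panel([(0, 100)], gene="A")
        fractions, missing = gene_coverage_fraction(p, {})
        assert missing == {"A"}
        assert "A" not in fractions


class TestTmbSuitability:
    @pytest.mark.parametrize(
        "total_bp,suitable",
        [(82_035, False), (500_000, True), (1_000_000, True)],
    )
    def test_footprint_rule(self, total_bp, suitable):
        p = _panel([(0, total_bp)])
        res = tmb_suitability(p)
        assert res.footprint_bp == total_bp
        assert res.suitable is suitable
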