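"""Quality metrics and the back-ligation estimator."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hicqc import LINKER19, annotate_pairs, read_fastq_pairs
from hicqc.qc import (
    BackLigationModel,
    EmptyInputError,
    EstimatorError,
    LibraryQCReport,
    OrientationCounts,
    corrected_dangling_ends,
    count_orientations,
    dangling_ends,
    estimate_back_ligation,
    estimate_incidental_rate,
    summarize_library,
)


def pairs_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2",
                 "strand2", "status", "orientation", "separation"],
    )


class TestOrientationCounts:
    def test_one_per_class(self):
        df = pairs_frame([
            ("a", "chr1", 1, "+", "chr1", 500, "-", "valid", "FR", 499),
            ("b", "chr1", 1, "-", "chr1", 500, "+", "valid", "RF", 499),
            ("c", "chr1", 1, "+", "chr1", 500, "+", "valid", "FF", 499),
            ("d", "chr1", 1, "-", "chr1", 500, "-", "valid", "RR", 499),
            ("e", "chr1", 1, "+", "chr2", 500, "-", "valid", "trans", -1),
            ("f", "chr1", 1, "+", "chr1", 500, "-", "duplicate", "FR", 499),
        ])
        c = count_orientations(df)
        assert (c.fr, c.rf, c.ff, c.rr) == (1, 1, 1, 1)
        assert c.n_same == 2 and c.total == 4  # trans and duplicates excluded

    def test_subset_rule_applied(self):
        df = pairs_frame([
            ("a", "chr1", 1, "+", "chr1", 100, "-", "valid", "FR", 99),
            ("b", "chr1", 1, "+", "chr1", 5000, "-", "valid", "FR", 4999),
        ])
        c = count_orientations(df, subset_rule=lambda d: d["separation"] < 1000)
        assert c.fr == 1


class TestDanglingEnds:
    @pytest.mark.parametrize(
        "counts, expected, anomalous",
        [
            ((100, 100, 100, 100), 0, False),
            ((350, 150, 100, 100), 300, False),
            ((50, 50, 100, 100), -100, True),
        ],
    )
    def test_signed_excess(self, counts, expected, anomalous):
        de = dangling_ends(OrientationCounts(*counts))
        assert de.value == expected and de.anomalous == anomalous


class TestEstimatorClosedForm:
    def test_worked_example_with_incidental_rate(self):
        est = estimate_back_ligation(p1=250, p2=300, n=1000, de=400, c=0.05)
        assert est.y == pytest.approx(0.2)
        assert est.b == pytest.approx(150.0)
        assert est.g == pytest.approx(250.0)

    def test_worked_example_without_incidental_rate(self):
        est = estimate_back_ligation(p1=200, p2=260, n=1000, de=400, c=0.0)
        assert est.y == pytest.approx(0.2) and est.b == pytest.approx(300.0)

    def test_domain_boundary_raises(self):
        with pytest.raises(EstimatorError, match="no evidence"):
            estimate_back_ligation(p1=40, p2=100, n=1000, de=400, c=0.05)
        with pytest.raises(EmptyInputError):
            estimate_back_ligation(p1=0, p2=0, n=0, de=0, c=0.0)

    @given(
        n=st.integers(100, 10_000),
        y=st.floats(0.01, 0.95),
        c=st.floats(0.0, 0.2),
        b=st.integers(0, 5000),
        g=st.integers(0, 5000),
    )
    @settings(deadline=None, max_examples=200)
    def test_inverts_forward_equations_exactly(self, n, y, c, b, g):
        """Self-consistency: P1/P2 built by the forward model are inverted
        back to (y, B) at machine precision."""
        de = b + g
        p1 = n * (y + c)
        p2 = p1 + de * c + b * y
        est = estimate_back_ligation(p1, p2, n, de, c)
        assert est.y == pytest.approx(y, rel=1e-9, abs=1e-12)
        assert est.b == pytest.approx(b, rel=1e-9, abs=1e-6)

    def test_b_strictly_increasing_in_p2(self):
        bs = [
            estimate_back_ligation(250, p2, 1000, 400, 0.05).b
            for p2 in range(250, 400, 10)
        ]
        assert all(b2 > b1 for b1, b2 in zip(bs, bs[1:]))

    def test_clamping_reported_not_silent(self):
        est = estimate_back_ligation(p1=250, p2=900, n=1000, de=400, c=0.05)
        assert est.b > 400 and est.clamped and est.b_clamped == 400


class TestCorrectedDanglingEnds:
    def test_arithmetic(self):
        out = corrected_dangling_ends(400, 150)
        assert out.corrected == 250 and out.share == pytest.approx(0.375)

    def test_three_quarters_share(self):
        assert corrected_dangling_ends(400, 300).share == pytest.approx(0.75)

    def test_zero_b_identity(self):
        assert corrected_dangling_ends(400, 0).corrected == 400

    def test_non_positive_de_undefined_share(self):
        out = corrected_dangling_ends(0, 10)
        assert not out.share_defined and np.isnan(out.share)


def annotated_frame(n_same, p1, n_opp, p2, insert=200):
    rows = []
    for i in range(n_same):
        rows.append((f"s{i}", "chr1", 1, "+", "chr1", 300, "+", "valid", "FF",
                     299, insert, i < p1))
    for i in range(n_opp):
        rows.append((f"o{i}", "chr1", 1, "+", "chr1", 300, "-", "valid", "FR",
                     299, insert, i < p2))
    return pd.DataFrame(
        rows,
        columns=["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2",
                 "strand2", "status", "orientation", "separation", "insert",
                 "has_adapter"],
    )


class TestBackLigationModel:
    def test_from_annotated_pairs_counts(self):
        df = annotated_frame(100, 25, 140, 30)
        m = BackLigationModel.from_annotated_pairs(df, c=0.05)
        assert (m.n_same, m.p1, m.n_opposite, m.p2) == (100, 25, 140, 30)
        assert m.de == 40

    def test_long_inserts_excluded_from_subset(self):
        df = annotated_frame(100, 25, 140, 30, insert=400)
        m = BackLigationModel.from_annotated_pairs(df, c=0.05)
        assert m.n_same == 0

    def test_fit_results_and_summary(self):
        m = BackLigationModel(n_same=1000, p1=250, n_opposite=1400, p2=300, c=0.05)
        res = m.fit(n_boot=100, seed=3)
        assert res.params["y"] == pytest.approx(0.2)
        assert res.params["b"] == pytest.approx(150.0)
        assert res.bse["b"] > 0
        ci = res.conf_int()
        assert ci.loc["b", "lower"] < 150 < ci.loc["b", "upper"]
        text = res.summary()
        assert "back-ligation" in text.lower() and "0.2" in text

    def test_bootstrap_se_shrinks_with_sample_size(self):
        small = BackLigationModel(500, 125, 700, 150, c=0.05).fit(200, seed=1)
        large = BackLigationModel(50_000, 12_500, 70_000, 15_000, c=0.05).fit(200, seed=1)
        assert large.bse["y"] < small.bse["y"]

    def test_share_clamped_into_unit_interval(self):
        m = BackLigationModel(n_same=1000, p1=250, n_opposite=1400, p2=900, c=0.05)
        res = m.fit(n_boot=0)
        assert 0.0 <= res.back_ligation_share <= 1.0
        assert res.back_ligation_share_raw > 1.0


class TestIncidentalRate:
    def test_exact_fraction(self):
        df = annotated_frame(200, 10, 0, 0)
        assert estimate_incidental_rate(df) == pytest.approx(0.05)

    def test_empty_input_raises(self):
        df = annotated_frame(0, 0, 10, 0)
        with pytest.raises(EmptyInputError):
            estimate_incidental_rate(df)

    def test_adapter_free_library_has_near_zero_19bp_rate(self, sim_library):
        # the shared library carries a 19-bp adapter; an adapter-free library
        # must show only chance matches, essentially absent for a 19-mer
        from hicqc import GenomeSpec, SimulationConfig, SimulatedLibrary, generate_genome
        from hicqc.pipeline import annotate_pairs
        import tempfile

        genome = generate_genome(GenomeSpec(2, 200_000, seed=33))
        cfg = SimulationConfig(n_pairs=4000, seed=33, adapter_sequences=())
        lib = SimulatedLibrary(cfg, genome)
        with tempfile.TemporaryDirectory() as d:
            paths = lib.write_all(d, gzip_fastq=False)
            from hicqc import extract_pairs

            pairs = extract_pairs(paths["sam"])
            reads = read_fastq_pairs(paths["r1"], paths["r2"])
        ann = annotate_pairs(pairs, reads, LINKER19)
        c = estimate_incidental_rate(ann)
        assert c < 0.001

    def test_presets_expose_paper_scale_rates(self):
        from hicqc import BRIDGE7, LINKER19

        assert BRIDGE7.incidental_rate == pytest.approx(0.05)
        assert LINKER19.incidental_rate == pytest.approx(0.0)


class TestLibraryReport:
    def test_reported_and_cis_fractions(self):
        df = pairs_frame(
            [(f"v{i}", "chr1", 1, "+", "chr1", 500, "-", "valid", "FR", 499)
             for i in range(80)]
            + [(f"t{i}", "chr1", 1, "+", "chr2", 500, "-", "valid", "trans", -1)
               for i in range(10)]
            + [(f"u{i}", None, -1, ".", None, -1, ".", "unmapped", ".", -1)
               for i in range(10)]
        )
        rep = summarize_library(df, raw_read_count=100)
        assert rep.reported_pairs_fraction == pytest.approx(0.90)
        assert rep.cis_fraction == pytest.approx(80 / 90)
        assert rep.de == 80

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            summarize_library(pairs_frame([]), raw_read_count=0)

    def test_json_round_trip_and_schema_guard(self, tmp_path):
        df = annotated_frame(100, 25, 140, 30)
        res = BackLigationModel.from_annotated_pairs(df, c=0.05).fit(50, seed=2)
        rep = summarize_library(df, raw_read_count=500, results=res)
        path = tmp_path / "report.json"
        rep.to_json(str(path))
        loaded = LibraryQCReport.from_dict(json.loads(path.read_text()))
        assert loaded.subset["b"] == pytest.approx(rep.subset["b"])
        with pytest.raises(ValueError, match="schema"):
            LibraryQCReport.from_dict({"schema_version": 99})

    def test_cis_fraction_recovered_from_simulation(self, sim_library, sim_pairs):
        lib, _ = sim_library
        rep = summarize_library(sim_pairs, raw_read_count=len(lib.pairs))
        truth = lib.truth
        cis_true = (truth["chrom1"] == truth["chrom2"]).mean()
        n = rep.n_valid
        se = np.sqrt(cis_true * (1 - cis_true) / n)
        assert abs(rep.cis_fraction - cis_true) < 3 * se + 1e-3
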