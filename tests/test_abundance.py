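import numpy as np
import pytest

from rbprofiler import (
    CONTIG_MODE,
    GENOME_MODE,
    AlignmentRecord,
    FilterParams,
    ReferenceSet,
    covered_fraction,
    filter_records,
    read_sam,
    relative_abundance,
    rpkm,
)
from rbprofiler.abundance import InvalidRecordError

from _oracles import per_base_covered_pct


def mapped(read_id="r", ref="g1", start=1, aligned=150, read_len=150, identity=100.0):
    return AlignmentRecord(
        read_id=read_id,
        ref_id=ref,
        ref_start=start,
        aligned_length=aligned,
        read_length=read_len,
        percent_identity=identity,
        ref_aligned_length=aligned,
    )


@pytest.fixture()
def refset():
    return ReferenceSet(
        lengths={"g1": 1000, "g2": 2000, "g3": 1500},
        categories={"g1": "Skunavirus", "g2": "Skunavirus", "g3": "P335"},
    )


class TestFilterRecords:
    def test_identity_just_below_threshold_excluded(self):
        rec = mapped(identity=85.9)
        kept, n_filtered, _ = filter_records([rec], CONTIG_MODE)
        assert kept == []
        assert n_filtered == 1

    def test_thresholds_are_inclusive(self):
        rec = mapped(aligned=142, read_len=149, identity=86.0)  # aligned 95.30%
        exactly = mapped(aligned=95, read_len=100, identity=86.0)  # aligned 95.0%
        kept, _, _ = filter_records([rec, exactly], CONTIG_MODE)
        assert len(kept) == 2

    def test_unmapped_counted_separately(self):
        records = [AlignmentRecord(read_id="u", ref_id=None), mapped()]
        kept, n_filtered, n_unmapped = filter_records(records, GENOME_MODE)
        assert len(kept) == 1
        assert n_filtered == 0
        assert n_unmapped == 1

    def test_aligned_longer_than_read_rejected(self):
        with pytest.raises(InvalidRecordError):
            mapped(aligned=200, read_len=150)

    def test_counts_match_predicate_recount(self):
        rng = np.random.default_rng(10)
        records = []
        for i in range(2000):
            if rng.random() < 0.1:
                records.append(AlignmentRecord(read_id=f"u{i}", ref_id=None))
            else:
                read_len = 150
                aligned = int(rng.integers(50, 151))
                records.append(
                    mapped(
                        read_id=f"r{i}",
                        aligned=aligned,
                        read_len=read_len,
                        identity=float(rng.uniform(60, 100)),
                    )
                )
        for p in (GENOME_MODE, CONTIG_MODE):
            kept, n_filtered, n_unmapped = filter_records(records, p)
            expect = [
                r
                for r in records
                if r.mapped
                and r.percent_identity >= p.min_identity
                and 100.0 * r.aligned_length / r.read_length >= p.min_aligned_pct
            ]
            assert len(kept) == len(expect)
            assert n_unmapped == sum(1 for r in records if not r.mapped)
            assert n_filtered == len(records) - len(kept) - n_unmapped

    def test_tightening_thresholds_never_keeps_more(self):
        rng = np.random.default_rng(11)
        records = [
            mapped(
                read_id=f"r{i}",
                aligned=int(rng.integers(50, 151)),
                identity=float(rng.uniform(60, 100)),
            )
            for i in range(500)
        ]
        kept_sizes = []
        for min_ident in (70, 80, 86, 95):
            kept, _, _ = filter_records(records, FilterParams(min_ident, 50.0))
            kept_sizes.append(len(kept))
        assert kept_sizes == sorted(kept_sizes, reverse=True)


class TestCoveredFraction:
    def test_single_read_half_coverage(self, refset):
        records = [mapped(start=1, aligned=150, read_len=150)]
        records[0] = AlignmentRecord(
            read_id="r", ref_id="g1", ref_start=1, aligned_length=150,
            read_length=150, percent_identity=100.0, ref_aligned_length=500,
        )
        assert covered_fraction(records, "g1", refset) == pytest.approx(50.0)

    def test_duplicate_reads_union_semantics(self, refset):
        rec = AlignmentRecord(
            read_id="r", ref_id="g1", ref_start=1, aligned_length=150,
            read_length=150, percent_identity=100.0, ref_aligned_length=500,
        )
        assert covered_fraction([rec, rec], "g1", refset) == pytest.approx(50.0)

    def test_unknown_reference_rejected(self, refset):
        with pytest.raises(ValueError):
            covered_fraction([], "nope", refset)

    def test_matches_per_base_oracle(self, refset):
        rng = np.random.default_rng(12)
        for _ in range(20):
            records = []
            intervals = []
            for i in range(int(rng.integers(1, 40))):
                start = int(rng.integers(1, 900))
                span = int(rng.integers(1, 150))
                records.append(
                    AlignmentRecord(
                        read_id=f"r{i}", ref_id="g1", ref_start=start,
                        aligned_length=min(span, 150), read_length=150,
                        percent_identity=100.0, ref_aligned_length=span,
                    )
                )
                intervals.append((start, min(start + span - 1, 1000)))
            assert covered_fraction(records, "g1", refset) == pytest.approx(
                per_base_covered_pct(intervals, 1000)
            )


class TestRelativeAbundance:
    def test_single_category_no_filtering(self, refset):
        records = [mapped(read_id=f"r{i}", ref="g1") for i in range(100)]
        table = relative_abundance(records, refset, GENOME_MODE)
        assert table.categories.loc["Skunavirus", "relative_abundance_pct"] == pytest.approx(100.0)
        assert table.categories.loc["unmapped", "relative_abundance_pct"] == pytest.approx(0.0)

    def test_no_mapped_reads(self, refset):
        records = [AlignmentRecord(read_id=f"u{i}", ref_id=None) for i in range(10)]
        table = relative_abundance(records, refset, GENOME_MODE)
        assert table.categories.loc["unmapped", "relative_abundance_pct"] == pytest.approx(100.0)
        assert (
            table.categories.drop("unmapped").relative_abundance_pct == 0
        ).all()

    def test_empty_record_set(self, refset):
        table = relative_abundance([], refset, GENOME_MODE)
        assert table.categories.loc["unmapped", "relative_abundance_pct"] == 100.0

    def test_sums_to_100(self, refset):
        rng = np.random.default_rng(13)
        records = []
        for i in range(1000):
            if rng.random() < 0.2:
                records.append(AlignmentRecord(read_id=f"u{i}", ref_id=None))
            else:
                ref = str(rng.choice(["g1", "g2", "g3"]))
                records.append(
                    mapped(
                        read_id=f"r{i}", ref=ref,
                        aligned=int(rng.integers(75, 151)),
                        identity=float(rng.uniform(70, 100)),
                    )
                )
        table = relative_abundance(records, refset, GENOME_MODE)
        assert table.categories.relative_abundance_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_length_normalisation(self, refset):
        # same read count on g1 (1 kb) and g2 (2 kb): g1 carries twice the weight
        records = [mapped(read_id=f"a{i}", ref="g1") for i in range(50)]
        records += [mapped(read_id=f"b{i}", ref="g2") for i in range(50)]
        weights = {"g1": 50 / 1000, "g2": 50 / 2000}
        table = relative_abundance(records, refset, GENOME_MODE)
        expect = 100.0 * (weights["g1"] + weights["g2"]) / (weights["g1"] + weights["g2"])
        assert table.categories.loc["Skunavirus", "relative_abundance_pct"] == pytest.approx(expect)
        records += [mapped(read_id=f"c{i}", ref="g3") for i in range(30)]
        table = relative_abundance(records, refset, GENOME_MODE)
        w_sku = 50 / 1000 + 50 / 2000
        w_p335 = 30 / 1500
        assert table.categories.loc["P335", "relative_abundance_pct"] == pytest.approx(
            100.0 * w_p335 / (w_sku + w_p335)
        )


class TestRpkm:
    def test_closed_form(self):
        refset = ReferenceSet(lengths={"x": 1000}, categories={"x": "c"})
        records = [
            AlignmentRecord(
                read_id=f"r{i}", ref_id="x", ref_start=(i % 900) + 1,
                aligned_length=150, read_length=150, percent_identity=100.0,
                ref_aligned_length=150,
            )
            for i in range(1000)
        ]
        table = rpkm(records, refset, FilterParams(86.0, 95.0, min_covered_fraction=55.0))
        # 1000 kept reads on a 1 kb reference, 1000 total kept
        assert table.loc["x", "rpkm"] == pytest.approx(1000 / (1.0 * (1000 / 1e6)))

    def test_zero_kept_reads_is_zero_with_warning(self, refset):
        records = [mapped(identity=50.0)]
        with pytest.warns(UserWarning, match="no reads passed"):
            table = rpkm(records, refset, CONTIG_MODE)
        assert (table.rpkm == 0).all()

    def test_below_covered_fraction_flagged_zero(self, refset):
        # dense pile-up on 40% of g1 only
        records = [
            AlignmentRecord(
                read_id=f"r{i}", ref_id="g1", ref_start=1, aligned_length=150,
                read_length=150, percent_identity=100.0, ref_aligned_length=400,
            )
            for i in range(50)
        ]
        table = rpkm(records, refset, CONTIG_MODE)
        assert table.loc["g1", "covered_fraction_pct"] == pytest.approx(40.0)
        assert table.loc["g1", "rpkm"] == 0.0
        assert bool(table.loc["g1", "below_covered_threshold"])

    def test_matches_arithmetic_oracle(self, refset):
        rng = np.random.default_rng(14)
        records = []
        for i in range(3000):
            ref = str(rng.choice(["g1", "g2", "g3"]))
            start = int(rng.integers(1, refset.lengths[ref] - 150))
            records.append(
                mapped(
                    read_id=f"r{i}", ref=ref, start=start,
                    aligned=int(rng.integers(140, 151)),
                    identity=float(rng.uniform(80, 100)),
                )
            )
        p = CONTIG_MODE
        table = rpkm(records, refset, p)
        kept, _, _ = filter_records(records, p)
        total = len(kept)
        for ref in refset.lengths:
            n = sum(1 for r in kept if r.ref_id == ref)
            expect = n / ((refset.lengths[ref] / 1000) * (total / 1e6))
            if not table.loc[ref, "below_covered_threshold"]:
                assert table.loc[ref, "rpkm"] == pytest.approx(expect)


class TestSamIO:
    def test_round_trip_preserves_filter_quantities(self, tmp_path):
        from rbprofiler import ReadSimSpec, simulate_alignments, write_sam

        spec = ReadSimSpec(
            refs={"g1": (5000, "A"), "g2": (5000, "B")},
            true_weights={"A": 0.5, "B": 0.5},
            n_reads=300,
            seed=3,
        )
        records, _ = simulate_alignments(spec)
        path = tmp_path / "reads.sam"
        write_sam(records, spec.refs, path)
        back = read_sam(path)
        assert len(back) == len(records)
        for orig, rec in zip(records, back):
            assert rec.read_id == orig.read_id
            assert rec.ref_id == orig.ref_id
            if orig.mapped:
                assert rec.ref_start == orig.ref_start
                assert rec.aligned_length == orig.aligned_length
                assert rec.read_length == orig.read_length
                assert rec.percent_identity == pytest.approx(orig.percent_identity)

    def test_missing_nm_tag_rejected(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:g1\tLN:1000\n"
            "r1\t0\tg1\t1\t60\t150M\t*\t0\t0\t*\t*\n"
        )
        with pytest.raises(InvalidRecordError):
            read_sam(path)
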