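import numpy as np
import pytest
from hypothesis import given, strategies as st

from lactnet import core_io
from lactnet.core_io import (
    GenomicInterval,
    GtfParseError,
    SampleDesign,
    SnpRecord,
    TranscriptModel,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGenomicInterval:
    def test_length_inclusive(self):
        assert len(GenomicInterval("chr1", 100, 200, "+")) == 101

    def test_invalid(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 9)

    def test_distance(self):
        a = GenomicInterval("chr1", 100, 200)
        b = GenomicInterval("chr1", 300, 400)
        assert a.distance(b) == 99
        assert b.distance(a) == 99
        assert a.distance(GenomicInterval("chr1", 150, 250)) == 0
        assert a.distance(GenomicInterval("chr2", 100, 200)) is None

    @given(
        s1=st.integers(1, 1000), l1=st.integers(1, 100),
        s2=st.integers(1, 1000), l2=st.integers(1, 100),
    )
    def test_distance_symmetric(self, s1, l1, s2, l2):
        a = GenomicInterval("c", s1, s1 + l1)
        b = GenomicInterval("c", s2, s2 + l2)
        assert a.distance(b) == b.distance(a)


class TestTranscriptModel:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            TranscriptModel(
                "t1", "g1", GenomicInterval("chr1", 1, 300),
                exons=[GenomicInterval("chr1", 1, 100),
                       GenomicInterval("chr1", 50, 300)],
            )

    def test_sequence_length_checked(self):
        with pytest.raises(ValueError, match="sequence length"):
            TranscriptModel(
                "t1", "g1", GenomicInterval("chr1", 1, 100),
                exons=[GenomicInterval("chr1", 1, 100)], sequence="ACGT",
            )


class TestGtf:
    def test_two_exon_aggregation(self, tmp_path):
        gtf = write(tmp_path, "a.gtf", "\n".join([
            'chr1\tx\texon\t100\t199\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; class_code "u";',
            'chr1\tx\texon\t300\t399\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; class_code "u";',
        ]) + "\n")
        (t,) = core_io.read_gtf(gtf)
        assert t.n_exons == 2
        assert t.length == 200
        assert t.interval.start == 100 and t.interval.end == 399
        assert t.class_code == "u"

    def test_wrong_column_count(self, tmp_path):
        gtf = write(tmp_path, "bad.gtf",
                    "chr1\tx\texon\t1\t10\t.\t+\n")
        with pytest.raises(GtfParseError, match=":1"):
            core_io.read_gtf(gtf)

    def test_end_before_start(self, tmp_path):
        gtf = write(tmp_path, "bad2.gtf",
                    'chr1\tx\texon\t50\t10\t.\t+\t.\ttranscript_id "t";\n')
        with pytest.raises(ValueError):
            core_io.read_gtf(gtf)

    def test_missing_class_code_defaults(self, tmp_path, caplog):
        gtf = write(tmp_path, "c.gtf",
                    'chr1\tx\texon\t1\t10\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
        with caplog.at_level("WARNING"):
            (t,) = core_io.read_gtf(gtf)
        assert t.class_code == "="
        assert "class_code" in caplog.text

    def test_round_trip_50_transcripts(self, tmp_path):
        rng = np.random.default_rng(0)
        originals = []
        for i in range(50):
            start = int(rng.integers(1, 10_000))
            exons, pos = [], start
            for _ in range(int(rng.integers(1, 5))):
                ln = int(rng.integers(50, 400))
                exons.append(GenomicInterval("chr2", pos, pos + ln - 1, "-"))
                pos += ln + int(rng.integers(50, 500))
            originals.append(TranscriptModel(
                f"t{i}", f"g{i}",
                GenomicInterval("chr2", exons[0].start, exons[-1].end, "-"),
                exons=exons, class_code=str(rng.choice(["u", "i", "="])),
                assembler_support=int(rng.integers(0, 3)),
                sample_occurrence=int(rng.integers(0, 16)),
            ))
        path = tmp_path / "rt.gtf"
        core_io.write_gtf(originals, path)
        back = core_io.read_gtf(path)
        assert back == originals


class TestExpressionMatrix:
    def _write_trio(self, tmp_path, n_feat=10, shuffle_fpkm=False):
        rng = np.random.default_rng(1)
        sample_ids = [f"I{i}_S{s}" for i in (1, 2, 3) for s in core_io.STAGES]
        counts = rng.integers(0, 100, size=(n_feat, 15))
        header = "feature_id\t" + "\t".join(sample_ids)
        lines = [header] + [
            f"f{i}\t" + "\t".join(map(str, counts[i])) for i in range(n_feat)
        ]
        cpath = write(tmp_path, "counts.tsv", "\n".join(lines) + "\n")
        cols = list(range(15))
        if shuffle_fpkm:
            cols = list(rng.permutation(15))
        fheader = "feature_id\t" + "\t".join(sample_ids[c] for c in cols)
        flines = [fheader] + [
            f"f{i}\t" + "\t".join(str(counts[i, c] * 1.5) for c in cols)
            for i in range(n_feat)
        ]
        fpath = write(tmp_path, "fpkm.tsv", "\n".join(flines) + "\n")
        dlines = ["sample_id\tindividual\tstage"] + [
            f"I{i}_S{s}\tI{i}\t{s}" for i in (1, 2, 3) for s in core_io.STAGES
        ]
        dpath = write(tmp_path, "design.tsv", "\n".join(dlines) + "\n")
        return cpath, fpath, dpath, counts

    def test_shape(self, tmp_path):
        c, f, d, _ = self._write_trio(tmp_path)
        expr = core_io.read_expression_matrix(c, f, d)
        assert expr.shape == (10, 15)

    def test_missing_sample_named(self, tmp_path):
        c, f, d, _ = self._write_trio(tmp_path)
        content = c.read_text().splitlines()
        header = content[0].split("\t")
        drop = header.index("I3_S+1")
        trimmed = "\n".join(
            "\t".join(v for j, v in enumerate(l.split("\t")) if j != drop)
            for l in content
        )
        c.write_text(trimmed + "\n")
        with pytest.raises(ValueError, match="I3_S\\+1"):
            core_io.read_expression_matrix(c, f, d)

    def test_shuffled_fpkm_realigned(self, tmp_path):
        c, f, d, counts = self._write_trio(tmp_path, shuffle_fpkm=True)
        expr = core_io.read_expression_matrix(c, f, d)
        np.testing.assert_allclose(expr.fpkm, expr.counts * 1.5)

    def test_negative_count_rejected(self, tmp_path):
        c, f, d, _ = self._write_trio(tmp_path)
        c.write_text(c.read_text().replace("\t3\t", "\t-3\t", 1))
        with pytest.raises(ValueError):
            core_io.read_expression_matrix(c, f, d)

    def test_duplicate_design_pair_rejected(self):
        s = [SampleDesign("a", "I1", "-14"), SampleDesign("b", "I1", "-14")]
        with pytest.raises(ValueError, match="duplicate"):
            core_io.ExpressionMatrix(["f"], s, np.zeros((1, 2)), np.zeros((1, 2)))


class TestSnpEffects:
    def test_three_rows_sorted(self, tmp_path):
        p = write(tmp_path, "s.tsv",
                  "id\tchrom\tpos\tbeta\nr3\tchr2\t5\t0.1\nr1\tchr1\t9\t0.2\nr2\tchr1\t3\t-0.5\n")
        snps = core_io.read_snp_effects(p)
        assert [s.id for s in snps] == ["r2", "r1", "r3"]

    def test_na_beta_rejected(self, tmp_path):
        p = write(tmp_path, "s.tsv", "id\tchrom\tpos\tbeta\nr1\tchr1\t9\tNA\n")
        with pytest.raises(ValueError, match="beta"):
            core_io.read_snp_effects(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = write(tmp_path, "s.tsv",
                  "id\tchrom\tpos\tbeta\nr1\tchr1\t9\t0.1\nr1\tchr1\t10\t0.2\n")
        with pytest.raises(ValueError, match="duplicate"):
            core_io.read_snp_effects(p)

    def test_round_trip_1000(self, tmp_path):
        rng = np.random.default_rng(3)
        snps = sorted(
            (
                SnpRecord(
                    f"s{i}", f"chr{rng.integers(1, 4)}", int(rng.integers(1, 10**6)),
                    float(np.round(rng.normal(), 6)),
                    tuple(int(x) for x in rng.multinomial(100, [0.25, 0.5, 0.25])),
                )
                for i in range(1000)
            ),
            key=lambda s: (s.chrom, s.pos, s.id),
        )
        p = tmp_path / "snps.tsv"
        core_io.write_snp_effects(snps, p)
        assert core_io.read_snp_effects(p) == snps


class TestBed:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.bed"
        core_io.write_bed([("name", GenomicInterval("chr1", 100, 200, "+"))], p)
        assert p.read_text() == "chr1\t99\t200\tname\t0\t+\n"

    def test_empty(self, tmp_path):
        p = tmp_path / "e.bed"
        core_io.write_bed([], p)
        assert p.read_text() == ""

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        feats = []
        for i in range(100):
            start = int(rng.integers(1, 10**6))
            feats.append((
                f"f{i:03d}",
                GenomicInterval(f"chr{rng.integers(1, 3)}", start,
                                start + int(rng.integers(0, 5000)),
                                str(rng.choice(["+", "-"]))),
            ))
        p = tmp_path / "rt.bed"
        core_io.write_bed(feats, p)
        back = core_io.read_bed(p)
        assert sorted(back) == sorted(feats)
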