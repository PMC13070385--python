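"""Data pipeline: encoding, binning, cropping, formats and example assembly."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from seq2track.data import (Dataset, DatasetManifest, GenomicWindow, bin_signal,
                            crop_center, decode_one_hot, make_examples,
                            one_hot_encode, read_coverage, read_fasta,
                            write_bedgraph, write_fasta)


class TestOneHot:
    def test_encoding_table(self):
        np.testing.assert_array_equal(
            one_hot_encode("ACGT"),
            [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])

    def test_n_is_all_zero_and_case_folds(self):
        np.testing.assert_array_equal(one_hot_encode("N"), [[0, 0, 0, 0]])
        np.testing.assert_array_equal(one_hot_encode("acgtn"),
                                      one_hot_encode("ACGTN"))

    def test_empty_sequence(self):
        assert one_hot_encode("").shape == (0, 4)

    def test_invalid_character_reports_offset(self):
        with pytest.raises(ValueError, match="offset 2"):
            one_hot_encode("ACXGT")

    @given(st.text(alphabet="ACGTNacgtn", max_size=200))
    def test_decode_inverts_encode(self, seq):
        assert decode_one_hot(one_hot_encode(seq)) == seq.upper()


class TestBinning:
    def test_examples(self):
        np.testing.assert_array_equal(bin_signal(np.zeros(256), 128), [0.0, 0.0])
        np.testing.assert_array_equal(bin_signal(np.ones(128), 128), [128.0])
        np.testing.assert_array_equal(bin_signal([1, 2, 3, 4], 2), [3.0, 7.0])

    def test_length_not_multiple_suggests_padding(self):
        with pytest.raises(ValueError, match="pad"):
            bin_signal(np.ones(100), 64)

    @given(st.integers(0, 6), st.integers(1, 5))
    def test_binning_conserves_mass(self, nbins_pow, bin_pow):
        rng = np.random.default_rng(nbins_pow * 7 + bin_pow)
        n_bins, bin_size = 2 ** nbins_pow, 2 ** bin_pow
        values = rng.random(n_bins * bin_size) * (rng.random(n_bins * bin_size) < 0.2)
        assert bin_signal(values, bin_size).sum() == pytest.approx(
            values.sum(), rel=1e-9)


class TestCrop:
    def test_centered_offset(self):
        v = np.arange(196608)
        out = crop_center(v, 114688)
        assert out[0] == (196608 - 114688) // 2 == 40960
        assert out.size == 114688 and 114688 // 128 == 896

    def test_identity_and_errors(self):
        v = np.arange(10)
        np.testing.assert_array_equal(crop_center(v, 10), v)
        with pytest.raises(ValueError):
            crop_center(v, 12)
        with pytest.raises(ValueError):
            crop_center(v, 5)


class TestFormats:
    def test_fasta_roundtrip(self, tmp_path):
        seqs = {"chrA": "ACGTN" * 10, "chrB": "GGCC" * 5}
        write_fasta(seqs, tmp_path / "g.fa")
        assert read_fasta(tmp_path / "g.fa") == seqs

    def test_bedgraph_interval_expansion(self, tmp_path):
        (tmp_path / "c.bedGraph").write_text("chr1\t0\t128\t3.0\n")
        cov = read_coverage(tmp_path / "c.bedGraph", {"chr1": 200})
        assert (cov["chr1"][:128] == 3.0).all() and (cov["chr1"][128:] == 0).all()

    def test_bedgraph_roundtrip(self, tmp_path, rng):
        vec = np.round(rng.random(300) * (rng.random(300) < 0.3), 3)
        write_bedgraph({"chr1": vec}, tmp_path / "t.bedGraph")
        back = read_coverage(tmp_path / "t.bedGraph", {"chr1": 300})
        np.testing.assert_allclose(back["chr1"], vec, atol=1e-12)

    def test_malformed_line_reports_number(self, tmp_path):
        (tmp_path / "bad.bedGraph").write_text("chr1\t0\t10\t1.0\nchr1\t5\n")
        with pytest.raises(ValueError, match=":2"):
            read_coverage(tmp_path / "bad.bedGraph", {"chr1": 100})

    def test_manifest_roundtrip(self, tmp_path, micro_ref_dataset):
        m = micro_ref_dataset.manifest
        m.write(tmp_path / "m.json")
        back = DatasetManifest.read(tmp_path / "m.json")
        assert back.records == m.records and back.track_names == m.track_names

    def test_manifest_rejects_bad_split_labels(self):
        with pytest.raises(ValueError, match="split"):
            DatasetManifest(records=[{"id": "w", "split": "extra"}],
                            track_names=[], input_length=4, crop_length=4,
                            bin_size=2)


class TestMakeExamples:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.genome = {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10240)])}
        self.tracks = {
            "t1": {"chr1": rng.random(10240)},
            "t2": {"chr1": np.zeros(10240)},
        }
        self.windows = [GenomicWindow("chr1", s, s + 4096)
                        for s in range(0, 6145, 1024)]

    def make(self, **kw):
        return make_examples(self.genome, self.tracks, self.windows,
                             4096, 2048, 128, **kw)

    def test_geometry(self):
        ds = self.make()
        assert ds.X.shape == (len(self.windows), 4096, 4)
        assert ds.Y.shape == (len(self.windows), 16, 2)

    def test_all_zero_track_yields_zero_column(self):
        assert (self.make().Y[:, :, 1] == 0).all()

    def test_labels_match_binned_crop(self):
        ds = self.make()
        w = self.windows[2]
        segment = self.tracks["t1"]["chr1"][w.start + 1024:w.start + 1024 + 2048]
        np.testing.assert_allclose(ds.Y[2, :, 0], bin_signal(segment, 128),
                                   rtol=1e-12)

    def test_subsample_is_seed_deterministic(self):
        a = self.make(subsample=5, seed=1)
        b = self.make(subsample=5, seed=1)
        c = self.make(subsample=5, seed=2)
        assert a.manifest.records == b.manifest.records
        assert len(a.manifest.records) == 5
        assert a.manifest.records != c.manifest.records

    def test_off_chromosome_windows_are_skipped(self, caplog):
        windows = self.windows + [GenomicWindow("chr1", 9000, 13096)]
        with caplog.at_level("WARNING"):
            ds = make_examples(self.genome, self.tracks, windows, 4096, 2048, 128)
        assert len(ds.manifest.records) == len(self.windows)
        assert ds.manifest.provenance["skipped_windows"] == 1


class TestDataset:
    def test_split_partition(self, micro_ref_dataset):
        ds = micro_ref_dataset
        all_idx = np.concatenate([ds.indices(s) for s in
                                  ("train", "validation", "test")])
        assert sorted(all_idx.tolist()) == list(range(len(ds.manifest.records)))

    def test_save_load_roundtrip(self, tmp_path, micro_ref_dataset):
        micro_ref_dataset.save(tmp_path / "d")
        back = Dataset.load(tmp_path / "d")
        np.testing.assert_array_equal(back.X, micro_ref_dataset.X)
        np.testing.assert_array_equal(back.Y, micro_ref_dataset.Y)

    def test_select_tracks_by_name_and_index(self, micro_ref_dataset):
        ds = micro_ref_dataset
        sub = ds.select_tracks([ds.track_names[1]])
        np.testing.assert_array_equal(sub.Y[:, :, 0], ds.Y[:, :, 1])

    def test_subsample_windows_keeps_heldout(self, micro_ref_dataset):
        ds = micro_ref_dataset
        sub = ds.subsample_windows(10, seed=0)
        assert len(sub.indices("train")) == 10
        assert len(sub.indices("test")) == len(ds.indices("test"))
        again = ds.subsample_windows(10, seed=0)
        assert sub.manifest.records == again.manifest.records
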