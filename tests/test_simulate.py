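"""Synthetic genome and count generation with known truth."""

import json

import numpy as np
import pytest

import fourc


class TestSimulateGenome:
    def test_determinism(self):
        a = fourc.simulate_genome(1_000, seed=1)
        b = fourc.simulate_genome(1_000, seed=1)
        assert a == b
        assert a != fourc.simulate_genome(1_000, seed=2)

    def test_gc_zero_restricts_alphabet(self):
        seq = fourc.simulate_genome(2_000, seed=3, gc=0.0)
        assert set(seq) <= {"A", "T"}

    def test_motif_density_matches_closed_form(self):
        # for i.i.d. bases, E[#GATC] = (L-3) * p(G) p(A) p(T) p(C)
        L, gc = 1_000_000, 0.41
        seq = fourc.simulate_genome(L, seed=4, gc=gc)
        p = (gc / 2) ** 2 * ((1 - gc) / 2) ** 2
        expected = (L - 3) * p
        sd = np.sqrt(expected)  # binomial-ish
        observed = len(fourc.find_cut_sites(seq, fourc.DPNII))
        assert abs(observed - expected) < 3 * sd

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            fourc.simulate_genome(0, seed=1)
        with pytest.raises(ValueError):
            fourc.simulate_genome(10, seed=1, gc=1.5)


class TestSimulateCounts:
    def test_seed_determinism(self, map5m, vp5m):
        t1 = fourc.default_truth(vp5m, seed=9)
        t2 = fourc.default_truth(vp5m, seed=9)
        t3 = fourc.default_truth(vp5m, seed=10)
        c1 = fourc.simulate_counts(map5m, t1).counts
        c2 = fourc.simulate_counts(map5m, t2).counts
        c3 = fourc.simulate_counts(map5m, t3).counts
        assert (c1 == c2).all()
        assert (c1 != c3).any()

    def test_poisson_limit_mean_variance(self, map5m, vp5m):
        # huge dispersion, no peaks, B = 0: counts are Poisson, so the
        # mean squared Pearson residual against the exact per-fragment
        # expectation is ~1
        truth = fourc.SimulationTruth(
            background=fourc.BackgroundModel(B=0.0, I_v=20.0, lam=100_000.0),
            peaks=(),
            viewpoint=vp5m,
            depth=1_000_000,
            dispersion=1e9,
            seed=21,
        )
        rc = fourc.simulate_counts(map5m, truth)
        df = map5m.df
        mid = map5m.midpoints()
        d = np.abs(mid - vp5m.centre)
        eligible = (
            (df["frag_class"] == "valid").to_numpy()
            & ((df["end"] - df["start"]).to_numpy() >= truth.min_len)
            & (d > vp5m.exclusion_radius)
        )
        shape = truth.signal(mid)
        scale = truth.depth / shape[eligible & (d <= vp5m.norm_radius)].sum()
        sel = eligible & (d < 150_000)
        mu = scale * shape[sel]
        ratio = np.mean((rc.counts[sel] - mu) ** 2 / mu)
        assert ratio == pytest.approx(1.0, abs=0.06)

    def test_mean_total_matches_depth(self):
        # small map so 1,000 replicates stay fast; the window covers the
        # whole chromosome and blind fragments are silenced, so the
        # expected total count equals the requested depth exactly
        genome = fourc.simulate_genome(60_000, seed=6)
        fmap = fourc.digest({"chrS": genome})
        vp = fourc.Viewpoint("chrS", 29_950, 30_050, exclusion_radius=2_000, norm_radius=70_000)
        totals = []
        for seed in range(1_000):
            truth = fourc.SimulationTruth(
                background=fourc.BackgroundModel(B=1.0, I_v=5.0, lam=10_000.0),
                peaks=(),
                viewpoint=vp,
                depth=10.0,
                dispersion=5.0,
                seed=seed,
                blind_signal=0.0,
            )
            totals.append(fourc.simulate_counts(fmap, truth).counts.sum())
        se = np.std(totals) / np.sqrt(len(totals))
        assert np.mean(totals) == pytest.approx(10.0, abs=3 * se + 1e-9)

    def test_peaks_must_respect_exclusion_window(self, vp5m):
        with pytest.raises(ValueError, match="exclusion"):
            fourc.SimulationTruth(
                background=fourc.BackgroundModel(B=1.0, I_v=1.0, lam=1e4),
                peaks=(fourc.GaussianPeak(vp5m.centre + 5_000, 1.0, 1e4),),
                viewpoint=vp5m,
                depth=100.0,
                dispersion=5.0,
                seed=0,
            )

    def test_blind_fragments_receive_background_noise(self, map5m, vp5m):
        truth = fourc.default_truth(vp5m, seed=30)
        rc = fourc.simulate_counts(map5m, truth)
        blind = (map5m.df["frag_class"] != "valid").to_numpy()
        assert rc.counts[blind].sum() > 0  # filters have work to do


class TestMakeFixture:
    def test_files_round_trip(self, tmp_path):
        from fourc import io as fio

        paths = fourc.make_fixture(str(tmp_path / "fx"), length=300_000, seed=7, depth=20_000)
        genome = fio.read_fasta(paths["fasta"])
        assert len(genome["chrS"]) == 300_000
        fmap = fio.read_fragments_bed(paths["fragments"])
        fmap.validate()
        rc = fourc.load_counts(paths["counts"], fmap)
        assert rc.total_reads > 0
        truth = fourc.SimulationTruth.from_dict(json.load(open(paths["truth"])))
        assert truth.depth == 20_000

    def test_zero_peaks_recorded(self, tmp_path):
        paths = fourc.make_fixture(str(tmp_path / "fx"), length=200_000, seed=7, peaks=[])
        truth = json.load(open(paths["truth"]))
        assert truth["peaks"] == []

    def test_byte_identical_reruns(self, tmp_path):
        p1 = fourc.make_fixture(str(tmp_path / "a"), length=150_000, seed=11)
        p2 = fourc.make_fixture(str(tmp_path / "b"), length=150_000, seed=11)
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()
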