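import numpy as np
import pandas as pd
import pytest

from allelix import chromatin as ch
from allelix.types import GeneModel, SignalTrack


def _flat_track(value=3.0, span=200_000, chrom="chrX"):
    return SignalTrack(
        chrom=chrom, bin_width=50,
        values={b: value for b in range(0, span, 50)},
    )


class TestPeakFraction:
    def _counts(self):
        return pd.DataFrame(
            {
                "snp_id": ["a", "b", "c"],
                "maternal_count": [40, 30, 5],
                "paternal_count": [20, 10, 5],
            }
        )

    def _positions(self):
        return pd.Series({"a": 101, "b": 151, "c": 901})

    def test_pooled_fraction_over_peak_snps(self):
        # peak covers SNPs a and b: 30 paternal / 100 total
        frac = ch.allelic_peak_fraction(
            ("chrX", 100, 200), self._counts(), self._positions()
        )
        assert frac == pytest.approx(30.0)

    def test_peak_without_snps_is_undefined(self):
        frac = ch.allelic_peak_fraction(
            ("chrX", 5000, 6000), self._counts(), self._positions()
        )
        assert np.isnan(frac)

    def test_merged_peak_equals_read_weighted_combination(self):
        counts, pos = self._counts(), self._positions()
        f1 = ch.allelic_peak_fraction(("chrX", 100, 200), counts, pos)
        f2 = ch.allelic_peak_fraction(("chrX", 900, 1000), counts, pos)
        merged = ch.allelic_peak_fraction(("chrX", 100, 1000), counts, pos)
        w1, w2 = 100, 10  # total allelic reads in each peak
        assert merged == pytest.approx((f1 * w1 + f2 * w2) / (w1 + w2))


class TestTssMetaprofile:
    def test_constant_track_gives_flat_profile(self):
        track = _flat_track(value=7.0)
        genes = [
            GeneModel("gp", "chrX", "+", 50_000, 60_000),
            GeneModel("gm", "chrX", "-", 80_000, 95_000),
        ]
        prof = ch.tss_metaprofile(track, genes)
        assert prof.matrix.shape == (2, 40)
        assert np.allclose(prof.matrix.to_numpy(), 7.0)

    def test_signal_block_at_plus_strand_tss_localizes(self):
        tss = 50_000
        track = SignalTrack(
            chrom="chrX", bin_width=50,
            values={b: 4.0 for b in range(tss, tss + 500, 50)},
        )
        g = GeneModel("g", "chrX", "+", tss, tss + 5_000)
        prof = ch.tss_metaprofile(track, [g])
        row = prof.matrix.loc["g"]
        assert row.loc[0] == pytest.approx(4.0)      # first downstream section
        nonzero = row[row > 0]
        assert list(nonzero.index) == [0]

    def test_minus_strand_gene_on_mirrored_track_identical_profile(self):
        rng = np.random.default_rng(5)
        tss_plus = 50_017                      # deliberately off-grid
        vals = rng.uniform(0, 10, size=4000)
        track_plus = SignalTrack(
            chrom="chrX", bin_width=50,
            values={b * 50: float(v) for b, v in enumerate(vals)},
        )
        g_plus = GeneModel("gp", "chrX", "+", tss_plus, tss_plus + 1000)
        # mirror around C = tss_plus + tss_minus with C % 50 == 49 so that
        # native bins map onto native bins: bin [b, b+50) -> [C+1-b-50, C+1-b)
        tss_minus = 149_982
        C = tss_plus + tss_minus
        assert C % 50 == 49
        mirrored = {}
        for b, v in track_plus.values.items():
            mb = C + 1 - b - 50
            if mb >= 0:
                mirrored[mb] = v
        track_minus = SignalTrack(chrom="chrX", bin_width=50, values=mirrored)
        g_minus = GeneModel("gm", "chrX", "-", tss_minus - 999, tss_minus + 1)
        p_plus = ch.tss_metaprofile(track_plus, [g_plus]).matrix.loc["gp"]
        p_minus = ch.tss_metaprofile(track_minus, [g_minus]).matrix.loc["gm"]
        assert np.allclose(p_plus.to_numpy(), p_minus.to_numpy(), equal_nan=True)

    def test_tss_near_contig_start_yields_missing_not_zero(self):
        track = _flat_track(value=2.0)
        g = GeneModel("g", "chrX", "+", 1_000, 8_000)  # upstream window off-grid
        row = ch.tss_metaprofile(track, [g]).matrix.loc["g"]
        assert row.iloc[0:17].isna().all()   # fully off-grid sections missing
        assert row.loc[0] == pytest.approx(2.0)

    def test_rebinning_conserves_signal_over_covered_window(self):
        rng = np.random.default_rng(11)
        track = SignalTrack(
            chrom="chrX", bin_width=50,
            values={b * 50: float(v)
                    for b, v in enumerate(rng.uniform(0, 5, 2000))},
        )
        tss = 50_000  # grid-aligned: sections tile native bins exactly
        g = GeneModel("g", "chrX", "+", tss, tss + 2_000)
        row = ch.tss_metaprofile(track, [g]).matrix.loc["g"]
        total_sections = row.to_numpy() @ np.full(40, 500.0)
        native = sum(
            track.values[b] * 50 for b in range(tss - 10_000, tss + 10_000, 50)
        )
        assert total_sections == pytest.approx(native)

    def test_exactly_40_bins(self):
        track = _flat_track()
        g = GeneModel("g", "chrX", "+", 50_000, 51_000)
        assert ch.tss_metaprofile(track, [g]).matrix.shape[1] == 40


class TestGenebodyProfile:
    def test_constant_track_flat_40_bins(self):
        track = _flat_track(value=1.5)
        genes = [
            GeneModel("small", "chrX", "+", 10_000, 10_700),   # < 40x50 bp
            GeneModel("big", "chrX", "-", 20_000, 90_000),
        ]
        prof = ch.genebody_profile(track, genes)
        assert prof.matrix.shape == (2, 40)
        assert np.allclose(prof.matrix.to_numpy(), 1.5)

    def test_2000bp_gene_sections_are_single_native_bins(self):
        rng = np.random.default_rng(2)
        start = 10_000
        vals = rng.uniform(0, 9, 40)
        track = SignalTrack(
            chrom="chrX", bin_width=50,
            values={start + i * 50: float(v) for i, v in enumerate(vals)},
        )
        g = GeneModel("g", "chrX", "+", start, start + 2_000)
        row = ch.genebody_profile(track, [g]).matrix.loc["g"]
        assert np.allclose(row.to_numpy(), vals)

    def test_length_doubling_preserves_profile_shape(self):
        # signal proportional to gene-body fraction: doubling the gene and
        # stretching the pattern leaves the 40-bin profile unchanged
        start = 20_000
        n_bins = 40
        track1 = SignalTrack(
            chrom="chrX", bin_width=50,
            values={start + i * 50: float(i) for i in range(n_bins)},
        )
        track2 = SignalTrack(
            chrom="chrX", bin_width=50,
            values={start + i * 50: float(i // 2) for i in range(2 * n_bins)},
        )
        g1 = GeneModel("g", "chrX", "+", start, start + n_bins * 50)
        g2 = GeneModel("g", "chrX", "+", start, start + 2 * n_bins * 50)
        p1 = ch.genebody_profile(track1, [g1]).matrix.loc["g"].to_numpy()
        p2 = ch.genebody_profile(track2, [g2]).matrix.loc["g"].to_numpy()
        assert np.allclose(p1, p2)

    def test_minus_strand_reversed(self):
        start = 10_000
        track = SignalTrack(
            chrom="chrX", bin_width=50,
            values={start + i * 50: float(i) for i in range(40)},
        )
        gp = GeneModel("gp", "chrX", "+", start, start + 2_000)
        gm = GeneModel("gm", "chrX", "-", start, start + 2_000)
        pp = ch.genebody_profile(track, [gp]).matrix.loc["gp"].to_numpy()
        pm = ch.genebody_profile(track, [gm]).matrix.loc["gm"].to_numpy()
        assert np.allclose(pm, pp[::-1])

    def test_zero_length_gene_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chrX", "+", 100, 100)


class TestProfileByClass:
    def _profile(self):
        matrix = pd.DataFrame(
            np.arange(12, dtype=float).reshape(3, 4),
            index=["g1", "g2", "g3"],
            columns=[0, 1, 2, 3],
        )
        return ch.Metaprofile(mode="tss", bin_labels=[0, 1, 2, 3], matrix=matrix)

    def test_singleton_class_profile_equals_gene_row(self):
        prof = self._profile()
        status = pd.Series(
            {"g1": "derepressed_up", "g2": "silenced", "g3": "escapee"}
        )
        by_class, sizes = ch.profile_by_class(prof, status)
        assert np.allclose(
            by_class.loc["silenced"].to_numpy(),
            prof.matrix.loc["g2"].to_numpy(),
        )
        assert sizes["escapee"] == 1

    def test_class_means_recombine_to_pooled_mean(self):
        prof = self._profile()
        status = pd.Series({"g1": "a", "g2": "a", "g3": "b"})
        by_class, sizes = ch.profile_by_class(prof, status)
        recombined = (
            by_class.mul(sizes.reindex(by_class.index), axis=0).sum(axis=0)
            / sizes.sum()
        )
        assert np.allclose(recombined.to_numpy(), prof.mean_profile.to_numpy())

    def test_unclassified_gene_errors(self):
        prof = self._profile()
        with pytest.raises(ValueError, match="without classification"):
            ch.profile_by_class(prof, pd.Series({"g1": "a"}))

    def test_synthetic_tracks_show_class_contrast(self, default_dataset):
        from allelix.simulate import simulate_signal_tracks

        ds = default_dataset
        track = simulate_signal_tracks(ds, amplitudes={
            "silenced": 1.0, "derepressed": 2.0, "escapee": 0.5,
        })
        prof = ch.tss_metaprofile(track, ds.genes)
        by_class, _ = ch.profile_by_class(
            prof, ds.truth["true_class"].reindex(prof.matrix.index)
        )
        # TSS sections are the two flanking bin labels closest to zero
        tss_cols = [c for c in by_class.columns if abs(c) <= 500]
        assert (
            by_class.loc["derepressed", tss_cols].mean()
            > by_class.loc["silenced", tss_cols].mean()
            > by_class.loc["escapee", tss_cols].mean()
        )
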