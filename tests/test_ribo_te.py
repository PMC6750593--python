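import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ribostall import fixtures
from ribostall.ribo_te import (compare_te_groups, compute_te,
                               metagene_profile, psite_coverage,
                               te_upstream)


class TestPsiteCoverage:
    def test_read_assigned_to_thirteenth_nucleotide(self):
        aln = pd.DataFrame({"transcript": ["t", "t"], "pos": [101, 1],
                            "length": [28, 28]})
        tracks, dropped = psite_coverage(aln, {"t": 200})
        assert dropped == 0
        assert tracks["t"][112] == 1  # 1-based 113
        assert tracks["t"][12] == 1   # 1-based 13
        assert tracks["t"].sum() == 2

    def test_out_of_bounds_reads_dropped_and_counted(self):
        aln = pd.DataFrame({"transcript": ["t"], "pos": [195]})
        tracks, dropped = psite_coverage(aln, {"t": 200})
        assert dropped == 1 and tracks["t"].sum() == 0

    def test_column_sums_equal_reads_kept(self, rng):
        n = 10_000
        aln = pd.DataFrame({
            "transcript": rng.choice(["a", "b"], size=n),
            "pos": rng.integers(1, 400, size=n)})
        tracks, dropped = psite_coverage(aln, {"a": 300, "b": 400})
        assert sum(t.sum() for t in tracks.values()) == n - dropped


class TestMetagene:
    def test_uniform_coverage_normalizes_to_one(self):
        tracks = {"t": np.full(600, 7)}
        regions = pd.DataFrame({"transcript": ["t"], "start_nt": [300]})
        prof = metagene_profile(tracks, regions)
        assert np.allclose(prof.mean_density, 1.0)
        assert prof.offset.iloc[0] == -59 and prof.offset.iloc[-1] == 90

    def test_single_spike_scales_to_window_length_share(self):
        # one spike carries the window's whole signal: density there is
        # spike/mean = window_len, zero elsewhere
        track = np.zeros(600, dtype=int)
        start = 300
        track[start - 1 + 23] = 5  # offset +24
        tracks = {"t": track}
        regions = pd.DataFrame({"transcript": ["t"], "start_nt": [start]})
        prof = metagene_profile(tracks, regions)
        peak = prof.loc[prof.offset == 24, "mean_density"].iloc[0]
        assert peak == pytest.approx(150.0)
        assert prof.mean_density.sum() == pytest.approx(150.0)

    def test_gaussian_bump_peaks_at_plus_24(self):
        tracks, regions, truth = fixtures.synth_coverage_tracks(
            n_genes=200, base_depth=20, seed=8)
        prof = metagene_profile(tracks, regions)
        assert int(prof.loc[prof.mean_density.idxmax(), "offset"]) == \
            truth.bump_offset_nt

    def test_per_window_normalization_conserved(self):
        tracks, regions, _ = fixtures.synth_coverage_tracks(seed=9)
        prof = metagene_profile(tracks, regions)
        # each window averages to 1 before cross-window averaging, so
        # the mean profile averages to 1 over the normalization span
        assert prof.mean_density.mean() == pytest.approx(1.0)

    def test_zero_coverage_windows_excluded_and_empty_errors(self):
        tracks = {"t": np.zeros(600, dtype=int)}
        regions = pd.DataFrame({"transcript": ["t"], "start_nt": [300]})
        with pytest.raises(ValueError):
            metagene_profile(tracks, regions)


class TestComputeTe:
    def test_ratio_and_threshold(self):
        ribo = pd.DataFrame({"gene": ["a", "b"], "rpkm": [10.0, 100.0]})
        rna = pd.DataFrame({"gene": ["a", "b"], "rpkm": [5.0, 4.0]})
        te = compute_te(ribo, rna)
        assert list(te.gene) == ["a"]        # b fails rna >= 5
        assert te.te.iloc[0] == pytest.approx(2.0)

    def test_retained_set_matches_threshold_oracle(self, rng):
        genes = [f"g{i}" for i in range(200)]
        ribo = pd.DataFrame({"gene": genes,
                             "rpkm": rng.lognormal(1.5, 1.0, 200)})
        rna = pd.DataFrame({"gene": genes,
                            "rpkm": rng.lognormal(1.5, 1.0, 200)})
        te = compute_te(ribo, rna)
        keep = {g for g, r, m in zip(genes, ribo.rpkm, rna.rpkm)
                if r >= 5 and m >= 5}
        assert set(te.gene) == keep

    @given(scale=st.floats(0.1, 100.0))
    def test_te_scale_invariant(self, scale):
        ribo = pd.DataFrame({"gene": ["a", "b"], "rpkm": [40.0, 8.0]})
        rna = pd.DataFrame({"gene": ["a", "b"], "rpkm": [10.0, 16.0]})
        base = compute_te(ribo, rna, min_rpkm=0)
        scaled = compute_te(
            ribo.assign(rpkm=ribo.rpkm * scale),
            rna.assign(rpkm=rna.rpkm * scale), min_rpkm=0)
        assert np.allclose(base.te, scaled.te)


class TestUpstreamTe:
    def test_uniform_coverage_gives_unit_te(self):
        track = np.full(900, 3)
        te = te_upstream({"g": track}, {"g": track}, {"g": 101})
        assert te.te.iloc[0] == pytest.approx(1.0)
        assert te.boundary.iloc[0] == 101

    def test_low_count_genes_excluded(self):
        ribo = np.full(900, 1)
        rna = np.zeros(900, dtype=int)
        rna[:299] = 1  # 99 reads in the 300-nt region -> excluded
        rna[:99] = 2
        te = te_upstream({"g": ribo}, {"g": rna[:900]}, {"g": 101})
        # ribo has 300 >= 100 but rna region sum must also clear 100
        assert (te.empty
                or (te.rna >= 100).all())

    def test_post_stall_depletion_does_not_affect_upstream_te(self):
        rna = np.full(900, 4)
        ribo = np.full(900, 4)
        depleted = ribo.copy()
        depleted[300:] = 0  # ribosome loss 3' of the stall at codon 101
        a = te_upstream({"g": ribo}, {"g": rna}, {"g": 101})
        b = te_upstream({"g": depleted}, {"g": rna}, {"g": 101})
        assert a.te.iloc[0] == b.te.iloc[0]

    def test_controls_truncated_at_median_boundary(self):
        track = np.full(900, 2)
        te = te_upstream({"g": track}, {"g": track}, {}, control_boundary=215)
        assert not te.stall.iloc[0]
        assert te.boundary.iloc[0] == 215


class TestGroupComparison:
    def test_identical_groups_give_zero_delta_unit_p(self):
        te = pd.DataFrame({"log2_te": [0.5] * 10 + [0.5] * 10,
                           "stall": [True] * 10 + [False] * 10})
        delta, p = compare_te_groups(te)
        assert delta == 0.0
        assert p > 0.99

    def test_implanted_offset_recovered(self):
        ribo, rna, truth = fixtures.synth_te_tables(
            n_stall=1000, n_free=3500, te_offset=0.23, seed=5)
        te = compute_te(ribo[["gene", "rpkm"]], rna[["gene", "rpkm"]])
        te = te.merge(ribo[["gene", "stall"]], on="gene")
        delta, p = compare_te_groups(te)
        # 95% CI half-width ~ 1.96 * dispersion * sqrt(1/n1 + 1/n2)
        ci = 1.96 * 0.5 * np.sqrt(1 / 1000 + 1 / 3500)
        assert abs(delta - 0.23) < ci
        assert p < 1e-15

    def test_empty_group_is_an_error(self):
        te = pd.DataFrame({"log2_te": [0.1, 0.2],
                           "stall": [True, True]})
        with pytest.raises(ValueError):
            compare_te_groups(te)
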