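"""Mapping-variant selection, dAF windowing, WMA smoothing, region calls."""

import numpy as np
import pytest

from mapseq.densmap import WindowSpec, iter_windows
from mapseq.genomeio import Genome, Variant, VariantSet
from mapseq.qtlmap import (
    DafProfile,
    MappingVariant,
    call_qtl_regions,
    select_mapping_variants,
    window_daf,
    wma_smooth,
)


def vs(sample, triples):
    """VariantSet from (pos, ref_count, alt_count) triples on c1."""
    return VariantSet(
        sample,
        [Variant("c1", p, "G", "A", 50.0, rc, ac) for p, rc, ac in triples],
    )


class TestSelectMappingVariants:
    def test_requires_presence_in_both_pools(self):
        out = select_mapping_variants(vs("p1", [(100, 5, 5)]), vs("p2", []))
        assert out == []

    def test_fixed_in_both_excluded(self):
        # af = 1 in both pools: parental difference to the reference, not
        # a segregating marker
        out = select_mapping_variants(
            vs("p1", [(100, 0, 10)]), vs("p2", [(100, 0, 10)])
        )
        assert out == []

    def test_intermediate_af_included_with_daf(self):
        (m,) = select_mapping_variants(
            vs("p1", [(100, 5, 5)]), vs("p2", [(100, 5, 5)])
        )
        assert m.daf == pytest.approx(0.0)

    def test_min_depth_in_both(self):
        out = select_mapping_variants(
            vs("p1", [(100, 2, 1)]), vs("p2", [(100, 10, 10)]), min_dp=5
        )
        assert out == []

    def test_undefined_af_is_hard_error(self):
        p1 = VariantSet("p1", [Variant("c1", 100, "G", "A")])
        p2 = VariantSet("p2", [Variant("c1", 100, "G", "A")])
        with pytest.raises(ValueError):
            select_mapping_variants(p1, p2, min_dp=0)

    def test_snp_only_by_default(self):
        p1 = VariantSet("p1", [Variant("c1", 100, "G", "GA", 50.0, 5, 5)])
        p2 = VariantSet("p2", [Variant("c1", 100, "G", "GA", 50.0, 5, 5)])
        assert select_mapping_variants(p1, p2) == []
        assert len(select_mapping_variants(p1, p2, snp_only=False)) == 1


def mv(chrom, pos, daf):
    af2 = 0.5 - daf / 2
    return MappingVariant(chrom, pos, "G", "A", af2 + daf, af2)


class TestWindowDaf:
    def test_mean_of_window(self):
        genome = Genome({"c1": "A" * 1000})
        prof = window_daf(
            [mv("c1", 10, 0.8), mv("c1", 20, 0.6)], genome, WindowSpec(1000, 1000)
        )
        assert prof.daf_mean[0] == pytest.approx(0.7)
        assert prof.n_variants[0] == 2

    def test_empty_window_undefined(self):
        genome = Genome({"c1": "A" * 2000})
        prof = window_daf([mv("c1", 10, 0.4)], genome, WindowSpec(1000, 1000))
        assert prof.n_variants.tolist() == [1, 0]
        assert np.isnan(prof.daf_mean[1])

    def test_matches_bruteforce_mean(self, rng):
        genome = Genome({"c1": "A" * 3_000_000, "c2": "A" * 2_000_000})
        mvars = [
            mv(("c1", "c2")[int(rng.integers(2))],
               int(rng.integers(1, 2_000_000)),
               float(rng.uniform(-1, 1)))
            for _ in range(1000)
        ]
        spec = WindowSpec(500_000, 250_000)
        prof = window_daf(mvars, genome, spec)
        for i, (chrom, s, e) in enumerate(iter_windows(genome, spec)):
            inside = [m.daf for m in mvars if m.chrom == chrom and s <= m.pos <= e]
            if inside:
                assert prof.daf_mean[i] == pytest.approx(np.mean(inside))
                assert prof.n_variants[i] == len(inside)
            else:
                assert np.isnan(prof.daf_mean[i])


def profile(values_by_chrom, size=100):
    windows, means = [], []
    for chrom, vals in values_by_chrom.items():
        for i, x in enumerate(vals):
            windows.append((chrom, 1 + i * size, (i + 1) * size))
            means.append(x)
    means = np.asarray(means, dtype=float)
    n = np.where(np.isnan(means), 0, 1).astype(int)
    return DafProfile(windows, n, means, None, WindowSpec(size, size))


class TestWmaSmooth:
    def test_constant_profile_unchanged(self):
        prof = wma_smooth(profile({"c1": [0.4] * 10}))
        np.testing.assert_allclose(prof.daf_wma, 0.4)

    def test_single_interior_spike(self):
        prof = wma_smooth(profile({"c1": [0, 0, 0.9, 0, 0]}))
        # center of the (1,2,3,2,1)/9 kernel
        assert prof.daf_wma[2] == pytest.approx(0.9 * 3 / 9)

    def test_edge_truncation_renormalizes(self):
        prof = wma_smooth(profile({"c1": [0.9, 0.3, 0.6]}))
        assert prof.daf_wma[0] == pytest.approx((3 * 0.9 + 2 * 0.3 + 1 * 0.6) / 6)
        assert prof.daf_wma[2] == pytest.approx((1 * 0.9 + 2 * 0.3 + 3 * 0.6) / 6)
        assert prof.daf_wma[1] == pytest.approx(
            (2 * 0.9 + 3 * 0.3 + 2 * 0.6) / 7
        )

    def test_empty_windows_bridged(self):
        # the NaN window is excluded from the support: its neighbors see
        # each other as adjacent
        with_gap = wma_smooth(profile({"c1": [0.8, np.nan, 0.2]}))
        without_gap = wma_smooth(profile({"c1": [0.8, 0.2]}))
        assert np.isnan(with_gap.daf_wma[1])
        assert with_gap.daf_wma[0] == pytest.approx(without_gap.daf_wma[0])
        assert with_gap.daf_wma[2] == pytest.approx(without_gap.daf_wma[1])

    def test_chromosomes_smoothed_independently(self):
        prof = wma_smooth(profile({"c1": [0.9, 0.9], "c2": [0.0, 0.0]}))
        np.testing.assert_allclose(prof.daf_wma[:2], 0.9)
        np.testing.assert_allclose(prof.daf_wma[2:], 0.0)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            wma_smooth(profile({"c1": [0.1]}), weights=(1, 2))
        with pytest.raises(ValueError):
            wma_smooth(profile({"c1": [0.1]}), weights=(1, -2, 1))

    def test_range_preserved(self, rng):
        vals = rng.uniform(-1, 1, 50)
        vals[rng.random(50) < 0.2] = np.nan
        prof = wma_smooth(profile({"c1": vals.tolist()}))
        ok = ~np.isnan(prof.daf_wma)
        assert np.nanmin(vals) - 1e-12 <= prof.daf_wma[ok].min()
        assert prof.daf_wma[ok].max() <= np.nanmax(vals) + 1e-12


class TestCallQtlRegions:
    def smoothed(self, values_by_chrom):
        prof = profile(values_by_chrom)
        return DafProfile(prof.windows, prof.n_variants, prof.daf_mean,
                          prof.daf_mean.copy(), prof.spec)

    def test_all_below_threshold(self):
        assert call_qtl_regions(self.smoothed({"c1": [0.2, -0.1, 0.24]})) == []

    def test_single_positive_run(self):
        regions = call_qtl_regions(self.smoothed({"c1": [0.1, 0.6, 0.6, 0.6, 0.6, 0.6, 0.1]}))
        assert len(regions) == 1
        r = regions[0]
        assert r.sign == "+" and r.extremum == pytest.approx(0.6)
        assert (r.start, r.end) == (101, 600)

    def test_sign_flip_splits_run(self):
        vals = [0.6, 0.6, 0.6, -0.6, -0.6, -0.6]
        regions = call_qtl_regions(self.smoothed({"c1": vals}))
        assert [r.sign for r in regions] == ["+", "-"]

    def test_short_run_not_called(self):
        assert call_qtl_regions(self.smoothed({"c1": [0.6, 0.6, 0.1]})) == []

    def test_matches_bruteforce_run_enumeration(self, rng):
        vals = rng.uniform(-0.6, 0.6, 200)
        vals[rng.random(200) < 0.1] = np.nan
        prof = self.smoothed({"c1": vals.tolist()})
        regions = call_qtl_regions(prof, daf_min=0.25, min_run=3)
        # brute force over the defined-window sequence
        seq = [(i, v) for i, v in enumerate(prof.daf_wma) if not np.isnan(v)]
        runs, cur = [], []
        for i, v in seq:
            s = 1 if v > 0 else -1
            if abs(v) >= 0.25 and (not cur or s == cur[-1][1]):
                cur.append((i, s))
            else:
                if len(cur) >= 3:
                    runs.append(cur)
                cur = [(i, s)] if abs(v) >= 0.25 else []
        if len(cur) >= 3:
            runs.append(cur)
        assert len(regions) == len(runs)
        for r, run in zip(regions, runs):
            assert r.start == prof.windows[run[0][0]][1]
            assert r.end == prof.windows[run[-1][0]][2]

    def test_unsmoothed_profile_rejected(self):
        with pytest.raises(ValueError):
            call_qtl_regions(profile({"c1": [0.3, 0.3, 0.3]}))


class TestAntisymmetry:
    def test_pool_swap_negates_profile_and_flips_signs(self, sim_bundle):
        from mapseq.simpop import SimConfig, simulate_qtlseq

        _, genome, _ = sim_bundle
        cfg = SimConfig(seed=42, population_size=200, read_depth=50)
        res = simulate_qtlseq(cfg, genome)
        p1, p2 = res.samples["pool1"], res.samples["pool2"]
        spec = WindowSpec()
        fwd = wma_smooth(window_daf(select_mapping_variants(p1, p2), genome, spec))
        rev = wma_smooth(window_daf(select_mapping_variants(p2, p1), genome, spec))
        np.testing.assert_allclose(fwd.daf_mean, -rev.daf_mean, equal_nan=True)
        np.testing.assert_allclose(fwd.daf_wma, -rev.daf_wma, equal_nan=True)
        rf = call_qtl_regions(fwd)
        rr = call_qtl_regions(rev)
        assert [(r.chrom, r.start, r.end, r.extremum) for r in rf] == [
            (r.chrom, r.start, r.end, r.extremum) for r in rr
        ]
        assert [r.sign for r in rf] == ["-" if r.sign == "+" else "+" for r in rr]
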