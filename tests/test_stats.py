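"""f3 test, LD decay/Ne inversion, weighted-LD dating, fragment survival."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from admixpower import (
    GenotypeMatrix,
    MosaicSpec,
    default_marker_table,
    f3_statistic,
    fit_exponential_decay,
    fragment_length_cdf,
    generate_mosaic_haplotypes,
    ld_decay_bins,
    mosaic_to_diploid,
    ne_from_ld,
    weighted_ld_curve,
)
from admixpower.stats import LDDecayCurve


# ---------------------------------------------------------------------------
# f3
# ---------------------------------------------------------------------------

class TestF3:
    def test_identical_populations_zero(self):
        f = np.random.default_rng(0).uniform(0.2, 0.8, 40)
        res = f3_statistic(f, f, f, block_size_snps=10)
        assert res.f3 == 0.0

    def test_hand_arithmetic_toy(self):
        a = np.array([0.2, 0.6])
        b = np.array([0.4, 0.8])
        c = np.array([0.3, 0.7])
        res = f3_statistic(c, a, b, block_size_snps=1)
        assert res.f3 == pytest.approx(-0.01)

    def test_symmetric_in_sources(self):
        rng = np.random.default_rng(1)
        a, b, c = rng.uniform(0.1, 0.9, (3, 60))
        r1 = f3_statistic(c, a, b, block_size_snps=10)
        r2 = f3_statistic(c, b, a, block_size_snps=10)
        assert r1.f3 == r2.f3 and r1.se == r2.se

    def test_jackknife_matches_brute_force(self):
        rng = np.random.default_rng(2)
        a, b, c = rng.uniform(0.1, 0.9, (3, 100))
        block = 10
        res = f3_statistic(c, a, b, block_size_snps=block)
        terms = (c - a) * (c - b)
        louts = []
        for s in range(0, 100, block):
            mask = np.ones(100, bool)
            mask[s : s + block] = False
            louts.append(terms[mask].mean())
        louts = np.array(louts)
        B = louts.size
        se = np.sqrt((B - 1) / B * np.sum((louts - louts.mean()) ** 2))
        assert res.n_blocks == B
        assert res.se == pytest.approx(se, rel=1e-12)

    def test_finite_sample_correction_subtracted(self):
        c = np.array([0.5, 0.5])
        a = b = np.array([0.5, 0.5])
        res = f3_statistic(c, a, b, block_size_snps=1, target_counts=np.array([10, 10]))
        h = 10 / 9 * 0.25
        assert res.f3 == pytest.approx(-h / 10)
        assert res.corrected

    def test_admixed_target_negative(self, bn_panels):
        freqs, panels, _ = bn_panels
        mixed = 0.5 * freqs[0] + 0.5 * freqs[1]
        res = f3_statistic(mixed, freqs[0], freqs[1], block_size_snps=100)
        assert res.f3 < 0 and res.z < -3

    def test_too_few_blocks_raises(self):
        with pytest.raises(ValueError, match="blocks"):
            f3_statistic(np.array([0.5]), np.array([0.4]), np.array([0.6]), 5)

    def test_monomorphic_everywhere_raises(self):
        z = np.zeros(10)
        with pytest.raises(ValueError, match="monomorphic"):
            f3_statistic(z, z, z, 2)


# ---------------------------------------------------------------------------
# LD decay bins and Ne trajectory
# ---------------------------------------------------------------------------

class TestLDDecay:
    def test_duplicated_marker_r2_one(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 3, size=(30, 1))
        geno = np.hstack([col, col]).astype(np.int8)
        markers = default_marker_table(2)
        markers.loc[:, "genetic_pos"] = [0.0, 0.0]
        markers.loc[:, "chrom"] = 1
        G = GenotypeMatrix([f"i{k}" for k in range(30)], geno, markers)
        curve = ld_decay_bins(G, np.array([0.0, 1e-6]))
        assert curve.bins[0][3] == pytest.approx(1.0 - 1 / 30)

    def test_unlinked_panel_adjusted_r2_near_zero(self, bn_panels):
        _, panels, _ = bn_panels
        sub = panels[0].subset_individuals(panels[0].sample_ids)
        # first 150 markers of chromosome 1: all pairwise distances
        keep = sub.markers["chrom"] == 1
        G = GenotypeMatrix(
            sub.sample_ids,
            sub.genotypes[:, keep.to_numpy()][:, :150],
            sub.markers[keep].iloc[:150].reset_index(drop=True),
        )
        curve = ld_decay_bins(G, np.array([0.0, 10.0]))
        _, _, _, r2adj, npairs = curve.bins[0]
        assert npairs > 10_000
        assert abs(r2adj) <= 0.01

    def test_deterministic(self, bn_panels):
        _, panels, _ = bn_panels
        keep = (panels[0].markers["chrom"] == 2).to_numpy()
        G = GenotypeMatrix(
            panels[0].sample_ids,
            panels[0].genotypes[:, keep][:, :50],
            panels[0].markers[keep].iloc[:50].reset_index(drop=True),
        )
        c1 = ld_decay_bins(G, np.array([0.0, 0.5, 10.0]))
        c2 = ld_decay_bins(G, np.array([0.0, 0.5, 10.0]))
        assert c1.bins == c2.bins


class TestNeFromLD:
    def test_direct_formula_point(self):
        curve = LDDecayCurve(bins=[(0.001, 0.001, 0.001, 0.05, 100)], sample_size=50)
        traj = ne_from_ld(curve)
        t, ne = traj.points[0]
        assert ne == pytest.approx(4500.0)
        assert t == pytest.approx(500.0)

    def test_round_trip_on_synthetic_curve(self):
        cs = np.array([0.001, 0.002, 0.005, 0.01])
        true_ne = 1500.0
        r2 = 1.0 / (4 * true_ne * cs + 2)
        curve = LDDecayCurve(
            bins=[(c, c, c, float(v), 10) for c, v in zip(cs, r2)], sample_size=50
        )
        traj = ne_from_ld(curve)
        for (t, ne), c in zip(traj.points, cs):
            assert ne == pytest.approx(true_ne, rel=1e-9)
            assert t == pytest.approx(1 / (2 * c))

    def test_unusable_bins_reported_not_raised(self):
        curve = LDDecayCurve(
            bins=[(0.001, 0.001, 0.001, -0.01, 5), (0.002, 0.002, 0.002, 0.9, 5)],
            sample_size=50,
        )
        with pytest.warns(UserWarning, match="no usable"):
            traj = ne_from_ld(curve)
        assert traj.points == []
        assert len(traj.skipped) == 2


# ---------------------------------------------------------------------------
# Weighted LD and the exponential fit
# ---------------------------------------------------------------------------

def _mosaic_target(m, lam, seed, n_hap=200):
    rng = np.random.default_rng(seed)
    n_chrom, mpc = 10, 150
    L = n_chrom * mpc
    fS = rng.uniform(0.1, 0.9, L)
    fB = np.clip(fS + rng.normal(0, 0.25, L), 0.02, 0.98)
    spec = MosaicSpec(
        m=m, lambda_rate=lam, map_length=0.05, n_chromosomes=n_chrom,
        markers_per_chromosome=mpc, n_haplotypes=n_hap,
        freqs_source=fS, freqs_background=fB, seed=seed + 1,
    )
    haps, _, mm, _ = generate_mosaic_haplotypes(spec)
    return mosaic_to_diploid(haps, mm), fS, fB


class TestWeightedLD:
    bins = np.linspace(0.0, 0.02, 21)

    def test_null_target_flat_curve(self):
        G, fS, fB = _mosaic_target(m=0.0, lam=240.0, seed=21)
        curve = weighted_ld_curve(G, fS, fB, self.bins)
        assert np.all(np.abs(curve.values) < 0.05)

    def test_admixed_target_decays_with_distance(self):
        G, fS, fB = _mosaic_target(m=0.3, lam=240.0, seed=23)
        curve = weighted_ld_curve(G, fS, fB, self.bins)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(curve.midpoints, curve.values)
        assert rho < -0.5

    def test_permutation_invariant(self):
        G, fS, fB = _mosaic_target(m=0.3, lam=240.0, seed=25, n_hap=60)
        c1 = weighted_ld_curve(G, fS, fB, self.bins)
        perm = np.random.default_rng(0).permutation(G.n_individuals)
        G2 = GenotypeMatrix(
            [G.sample_ids[i] for i in perm], G.genotypes[perm], G.markers
        )
        c2 = weighted_ld_curve(G2, fS, fB, self.bins)
        assert np.allclose(c1.values, c2.values)


class TestExponentialFit:
    def test_noiseless_inversion(self):
        d = np.linspace(0.001, 0.02, 20)
        curve = LDDecayCurve(
            bins=[(x, x, x, 0.01 * np.exp(-240 * x), 10) for x in d], sample_size=100
        )
        fit = fit_exponential_decay(curve)
        assert fit.decay_rate == pytest.approx(240.0, abs=1.0)
        assert fit.converged

    def test_mosaic_date_recovery(self):
        G, fS, fB = _mosaic_target(m=0.3, lam=240.0, seed=27)
        curve = weighted_ld_curve(G, fS, fB, np.linspace(0.0, 0.02, 21))
        fit = fit_exponential_decay(curve)
        assert 190 <= fit.decay_rate <= 290

    def test_flat_curve_flagged(self):
        d = np.linspace(0.001, 0.02, 10)
        rng = np.random.default_rng(5)
        curve = LDDecayCurve(
            bins=[(x, x, x, 1e-6 * rng.normal(), 10) for x in d], sample_size=100
        )
        fit = fit_exponential_decay(curve)
        assert not fit.converged

    def test_too_few_bins_raises(self):
        curve = LDDecayCurve(bins=[(0.1, 0.1, 0.1, 0.5, 1)] * 2, sample_size=10)
        with pytest.raises(ValueError, match="3 bins"):
            fit_exponential_decay(curve)


# ---------------------------------------------------------------------------
# Fragment survival
# ---------------------------------------------------------------------------

class TestFragmentCDF:
    def test_zero_length(self):
        assert fragment_length_cdf(240.0, 0.0) == 0.0

    def test_fifty_kb_after_six_thousand_years(self):
        # 50 kb at 1 cM/Mb = 5e-4 Morgans; rate 6000 -> 1 - e^-3
        v = fragment_length_cdf(6000.0, 5e-4)
        assert v == pytest.approx(1 - np.exp(-3), abs=1e-12)
        assert v >= 0.90

    def test_median_at_log_two(self):
        assert fragment_length_cdf(240.0, np.log(2) / 240.0) == pytest.approx(0.5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fragment_length_cdf(-1.0, 0.1)
        with pytest.raises(ValueError):
            fragment_length_cdf(1.0, -0.1)

    @given(
        lam=st.floats(0.0, 1e4),
        x1=st.floats(0.0, 10.0),
        x2=st.floats(0.0, 10.0),
    )
    def test_valid_cdf_properties(self, lam, x1, x2):
        lo, hi = sorted((x1, x2))
        a, b = fragment_length_cdf(lam, lo), fragment_length_cdf(lam, hi)
        assert 0.0 <= a <= b <= 1.0
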