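"""Synthetic panels, artificial admixed genomes, and ancestry mosaics."""

import numpy as np
import pytest
from scipy import stats as sps

from admixpower import (
    MosaicSpec,
    PanelSpec,
    generate_mosaic_haplotypes,
    generate_reference_panels,
    make_artificial_admixed,
)


def hudson_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    """Ratio-of-means Hudson Fst estimator from two dosage matrices."""
    n1, n2 = 2 * g1.shape[0], 2 * g2.shape[0]
    p1 = g1.mean(0) / 2
    p2 = g2.mean(0) / 2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())


class TestReferencePanels:
    def test_zero_fst_degenerates_to_ancestral_frequency(self):
        freqs, _, _ = generate_reference_panels(PanelSpec(fst=0.0, n_markers=100, seed=1))
        assert np.array_equal(freqs[0], freqs[1])

    def test_fst_one_rejected(self):
        with pytest.raises(ValueError, match="fst"):
            generate_reference_panels(PanelSpec(fst=1.0))

    def test_nominal_fst_recovered(self, bn_panels):
        _, panels, _ = bn_panels
        est = hudson_fst(
            panels[0].genotypes.astype(float), panels[1].genotypes.astype(float)
        )
        assert est == pytest.approx(0.1, abs=0.02)

    def test_same_seed_reproduces(self):
        spec = PanelSpec(n_markers=200, n_individuals=10, seed=9)
        f1, p1, _ = generate_reference_panels(spec)
        f2, p2, _ = generate_reference_panels(PanelSpec(n_markers=200, n_individuals=10, seed=9))
        assert np.array_equal(f1, f2)
        assert all(a == b for a, b in zip(p1, p2))


class TestArtificialAdmixed:
    def test_alpha_one_matches_source_distribution(self, bn_panels):
        freqs, _, _ = bn_panels
        G, truth = make_artificial_admixed(freqs[0], freqs[1], 1.0, 200, seed=4)
        # mean dosage per marker ~ 2 * freqsA
        err = np.abs(G.genotypes.mean(0) - 2 * freqs[0])
        assert np.mean(err) < 0.05
        assert all(v == 1.0 for v in truth.alpha.values())

    def test_alpha_half_diagnostic_panels_binomial_mean(self):
        L = 2000
        fA, fB = np.ones(L), np.zeros(L)
        G, _ = make_artificial_admixed(fA, fB, 0.5, 20, seed=5)
        means = G.genotypes.mean(1) / 2  # per-individual source fraction
        sd = np.sqrt(0.25 / L)  # Bernoulli(0.5) marker choice, exact dosage
        assert np.all(np.abs(means - 0.5) <= 3 * sd + 1e-12)

    def test_alpha_symmetry_under_panel_swap(self, bn_panels):
        freqs, _, _ = bn_panels
        Ga, _ = make_artificial_admixed(freqs[0], freqs[1], 0.3, 300, seed=6)
        Gb, _ = make_artificial_admixed(freqs[1], freqs[0], 0.7, 300, seed=7)
        # identically distributed: per-marker mean dosages agree closely
        diff = Ga.genotypes.mean(0) - Gb.genotypes.mean(0)
        assert abs(diff.mean()) < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            make_artificial_admixed(np.ones(3), np.ones(4), 0.5)


class TestMosaic:
    def test_m_zero_all_background(self):
        spec = MosaicSpec(m=0.0, lambda_rate=50.0, n_haplotypes=10, seed=2)
        _, anc, _, truth = generate_mosaic_haplotypes(spec)
        assert anc.sum() == 0
        assert all(v == 0.0 for v in truth.alpha.values())

    def test_boundary_count_poisson_mean(self):
        n_hap = 60
        spec = MosaicSpec(m=0.3, lambda_rate=240.0, map_length=1.0,
                          n_haplotypes=n_hap, seed=3)
        _, _, _, truth = generate_mosaic_haplotypes(spec)
        counts = truth.tracts.groupby(["hap_id", "chrom"]).size() - 1
        assert abs(counts.mean() - 240) <= 3 * np.sqrt(240 / n_hap)

    def test_tract_lengths_exponential(self):
        spec = MosaicSpec(m=0.3, lambda_rate=240.0, map_length=1.0,
                          n_haplotypes=50, seed=4)
        _, _, _, truth = generate_mosaic_haplotypes(spec)
        tr = truth.tracts
        # interior tracts (both endpoints are process events) are Exp(lambda)
        interior = tr.groupby(["hap_id", "chrom"], group_keys=False).apply(
            lambda d: d.iloc[1:-1], include_groups=False
        )
        lengths = (interior["end"] - interior["start"]).to_numpy()
        assert lengths.size > 10_000
        ks = sps.kstest(lengths, "expon", args=(0, 1 / 240)).statistic
        assert ks < 0.05

    def test_tracts_tile_each_chromosome(self):
        spec = MosaicSpec(m=0.4, lambda_rate=30.0, map_length=0.8,
                          n_haplotypes=5, n_chromosomes=2, seed=5)
        _, _, _, truth = generate_mosaic_haplotypes(spec)
        for (_, _), d in truth.tracts.groupby(["hap_id", "chrom"]):
            assert d["start"].iloc[0] == 0.0
            assert d["end"].iloc[-1] == pytest.approx(0.8)
            assert np.allclose(d["end"].to_numpy()[:-1], d["start"].to_numpy()[1:])

    def test_source_fraction_law_of_large_numbers(self):
        spec = MosaicSpec(m=0.3, lambda_rate=240.0, map_length=1.0,
                          n_haplotypes=100, seed=6)
        _, _, _, truth = generate_mosaic_haplotypes(spec)
        alphas = np.array(list(truth.alpha.values()))
        # each haplotype averages ~240 nearly independent tracts
        se = alphas.std(ddof=1) / np.sqrt(alphas.size)
        assert abs(alphas.mean() - 0.3) <= 3 * se + 0.01

    def test_zero_rate_gives_single_tract(self):
        spec = MosaicSpec(m=0.5, lambda_rate=0.0, n_haplotypes=4, seed=7)
        _, _, _, truth = generate_mosaic_haplotypes(spec)
        assert (truth.tracts.groupby(["hap_id", "chrom"]).size() == 1).all()
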