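"""Synthetic genotype generators.

Three generators cover the data needed by the downstream analyses:

* Balding–Nichols reference panels — two (or more) diverged populations whose
  per-marker allele frequencies are Beta-distributed around a shared ancestral
  frequency with differentiation parameter F (an Fst analogue).
* Artificial admixed genomes — marker-level mixtures: each marker's genotype
  is drawn from the source panel with probability alpha, otherwise from the
  other panel. This is the recent-admixture design on unlinked markers.
* Ancestry-mosaic haplotypes — chromosomes tiled by ancestry tracts whose
  boundaries follow a Poisson process of intensity lambda per Morgan, each
  tract being source ancestry with probability m. Tract lengths are therefore
  Exponential(lambda); this is the data on which admixture-LD dating is
  exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, default_marker_table


@dataclass
class PanelSpec:
    """Configuration of a set of Balding–Nichols reference panels."""

    n_pops: int = 2
    fst: float = 0.1
    n_markers: int = 5000
    n_individuals: int = 50
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must lie strictly inside (0, 1)")


@dataclass
class AncestryTruth:
    """True ancestry bookkeeping attached to generated individuals.

    ``alpha`` maps sample id to true source-ancestry fraction. ``tracts``
    (mosaic output only) holds one row per ancestry tract with columns
    ``hap_id, chrom, start, end, ancestry`` (positions in Morgans; ancestry
    1 = source). Tracts tile each chromosome without gaps or overlaps.
    """

    alpha: dict[str, float]
    tracts: pd.DataFrame | None = None

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.alpha), "true_alpha": list(self.alpha.values())}
        )


@dataclass
class MosaicSpec:
    """Configuration of the ancestry-mosaic haplotype generator."""

    m: float = 0.3
    lambda_rate: float = 240.0  # tract-boundary intensity per Morgan
    map_length: float = 1.0  # Morgans per chromosome
    n_chromosomes: int = 1
    markers_per_chromosome: int = 100
    n_haplotypes: int = 200
    freqs_source: np.ndarray | None = None  # per-marker source-panel freqs
    freqs_background: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must be in [0, 1]")
        if self.lambda_rate < 0:
            raise ValueError("lambda_rate must be >= 0")
        if self.map_length <= 0:
            raise ValueError("map_length must be positive")


def balding_nichols_freqs(
    ancestral: np.ndarray, fst: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-population frequencies around ``ancestral`` at divergence F.

    F = 0 degenerates to the ancestral frequency itself.
    """
    p = np.asarray(ancestral, float)
    if fst == 0.0:
        return np.tile(p, (n_pops, 1))
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale, size=(n_pops, p.size))


def generate_reference_panels(
    spec: PanelSpec,
) -> tuple[np.ndarray, list[GenotypeMatrix], AncestryTruth]:
    """Generate ``spec.n_pops`` diverged panels.

    Returns the (n_pops, n_markers) true population allele frequencies, one
    GenotypeMatrix per population (genotypes Binomial(2, pop frequency)),
    and an AncestryTruth assigning source fraction 1 to population 0 and 0
    to every other population.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=spec.n_markers)
    freqs = balding_nichols_freqs(ancestral, spec.fst, spec.n_pops, rng)

    markers = default_marker_table(spec.n_markers)
    panels, alpha = [], {}
    for k in range(spec.n_pops):
        ids = [f"pop{k}_ind{i + 1}" for i in range(spec.n_individuals)]
        geno = rng.binomial(2, freqs[k], size=(spec.n_individuals, spec.n_markers))
        panels.append(
            GenotypeMatrix(sample_ids=ids, genotypes=geno.astype(np.int8), markers=markers)
        )
        for s in ids:
            alpha[s] = 1.0 if k == 0 else 0.0
    return freqs, panels, AncestryTruth(alpha=alpha)


def make_artificial_admixed(
    freqsA: np.ndarray,
    freqsB: np.ndarray,
    alpha: float,
    n_individuals: int = 16,
    seed: int = 0,
    markers: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, AncestryTruth]:
    """Marker-level artificial admixture.

    Independently per individual and per marker, the genotype is drawn from
    Binomial(2, freqsA) with probability ``alpha`` and from Binomial(2,
    freqsB) otherwise. ``freqsA`` is the source panel; ``alpha`` is the true
    source-ancestry fraction recorded for every individual.
    """
    fA = np.asarray(freqsA, float)
    fB = np.asarray(freqsB, float)
    if fA.shape != fB.shape:
        raise ValueError("freqsA and freqsB must have the same length")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    from_A = rng.random(size=(n_individuals, fA.size)) < alpha
    probs = np.where(from_A, fA, fB)
    geno = rng.binomial(2, probs).astype(np.int8)
    ids = [f"admix_ind{i + 1}" for i in range(n_individuals)]
    G = GenotypeMatrix(
        sample_ids=ids,
        genotypes=geno,
        markers=default_marker_table(fA.size) if markers is None else markers,
    )
    return G, AncestryTruth(alpha={s: float(alpha) for s in ids})


def generate_mosaic_haplotypes(
    spec: MosaicSpec,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, AncestryTruth]:
    """Paint haplotypes with exponential ancestry tracts and draw alleles.

    Tract boundaries on each chromosome follow a Poisson process of intensity
    ``lambda_rate`` per Morgan; each tract is independently source ancestry
    with probability ``m``. Markers sit at evenly spaced genetic positions.
    Alleles are Bernoulli draws from the tract-ancestry panel's frequency
    (diagnostic frequencies 1/0 when no panels are supplied, in which case
    the allele equals the ancestry label).

    Returns
    -------
    haplotypes : (n_haplotypes, n_markers) 0/1 allele array
    ancestry : (n_haplotypes, n_markers) 0/1 source-ancestry labels
    marker_map : DataFrame with chrom and genetic_pos per marker
    truth : AncestryTruth with per-haplotype source fraction and tract table
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_mark = spec.n_chromosomes * spec.markers_per_chromosome
    pos_within = (np.arange(spec.markers_per_chromosome) + 0.5) * (
        spec.map_length / spec.markers_per_chromosome
    )
    marker_map = pd.DataFrame(
        {
            "chrom": np.repeat(np.arange(1, spec.n_chromosomes + 1), spec.markers_per_chromosome),
            "marker_id": [f"snp{i + 1}" for i in range(n_mark)],
            "genetic_pos": np.tile(pos_within, spec.n_chromosomes),
            "physical_pos": np.tile(
                (pos_within * 1e8).astype(int) + 1, spec.n_chromosomes
            ),
        }
    )

    fS = np.ones(n_mark) if spec.freqs_source is None else np.asarray(spec.freqs_source, float)
    fB = np.zeros(n_mark) if spec.freqs_background is None else np.asarray(
        spec.freqs_background, float
    )
    if fS.size != n_mark or fB.size != n_mark:
        raise ValueError("panel frequency vectors must match the marker count")

    haps = np.zeros((spec.n_haplotypes, n_mark), dtype=np.int8)
    anc = np.zeros((spec.n_haplotypes, n_mark), dtype=np.int8)
    alpha: dict[str, float] = {}
    tract_rows = []
    for h in range(spec.n_haplotypes):
        hap_id = f"hap{h + 1}"
        source_len = 0.0
        for c in range(1, spec.n_chromosomes + 1):
            L = spec.map_length
            k = rng.poisson(spec.lambda_rate * L)
            bounds = np.sort(rng.uniform(0.0, L, size=k))
            edges = np.concatenate(([0.0], bounds, [L]))
            labels = (rng.random(size=k + 1) < spec.m).astype(np.int8)
            for t in range(k + 1):
                tract_rows.append(
                    {
                        "hap_id": hap_id,
                        "chrom": c,
                        "start": edges[t],
                        "end": edges[t + 1],
                        "ancestry": int(labels[t]),
                    }
                )
            source_len += float(np.sum((edges[1:] - edges[:-1]) * labels))
            sel = marker_map["chrom"].to_numpy() == c
            tract_idx = np.searchsorted(bounds, pos_within, side="right")
            anc[h, sel] = labels[tract_idx]
        probs = np.where(anc[h] == 1, fS, fB)
        haps[h] = rng.random(n_mark) < probs
        alpha[hap_id] = source_len / (spec.map_length * spec.n_chromosomes)

    truth = AncestryTruth(alpha=alpha, tracts=pd.DataFrame(tract_rows))
    return haps, anc, marker_map, truth


def mosaic_to_diploid(
    haps: np.ndarray, marker_map: pd.DataFrame, prefix: str = "mosaic"
) -> GenotypeMatrix:
    """Pair consecutive haplotypes into diploid genotypes."""
    if haps.shape[0] % 2:
        haps = haps[:-1]
    geno = (haps[0::2] + haps[1::2]).astype(np.int8)
    ids = [f"{prefix}_ind{i + 1}" for i in range(geno.shape[0])]
    return GenotypeMatrix(sample_ids=ids, genotypes=geno, markers=marker_map)
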