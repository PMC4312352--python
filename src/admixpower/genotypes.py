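"""Diploid genotype container shared by every module in the package.

Genotypes are stored as minor/source-allele dosages (0, 1, 2) with a
distinguished missing code. Marker metadata (chromosome, genetic position in
Morgans, physical position in base pairs) rides along in a pandas DataFrame so
that LD machinery can bin marker pairs by genetic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Missing-genotype code used throughout the package.
MISSING = -1

MARKER_COLUMNS = ["chrom", "marker_id", "genetic_pos", "physical_pos"]


def default_marker_table(
    n_markers: int,
    n_chromosomes: int = 22,
    spacing_morgans: float = 0.01,
    spacing_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Evenly spaced marker map: markers split across ``n_chromosomes``.

    Genetic positions restart at 0 on each chromosome and increase by
    ``spacing_morgans``; physical positions by ``spacing_bp``.
    """
    if n_markers < 0:
        raise ValueError("n_markers must be non-negative")
    n_chromosomes = min(n_chromosomes, max(n_markers, 1))
    chrom = np.repeat(
        np.arange(1, n_chromosomes + 1),
        np.diff(np.linspace(0, n_markers, n_chromosomes + 1).astype(int)),
    )
    idx_within = np.concatenate(
        [np.arange(np.sum(chrom == c)) for c in range(1, n_chromosomes + 1)]
    ) if n_markers else np.array([], dtype=int)
    return pd.DataFrame(
        {
            "chrom": chrom.astype(int),
            "marker_id": [f"snp{i + 1}" for i in range(n_markers)],
            "genetic_pos": idx_within * spacing_morgans,
            "physical_pos": (idx_within * spacing_bp + 1).astype(int),
        }
    )


@dataclass
class GenotypeMatrix:
    """n_individuals x n_markers diploid dosage matrix.

    Parameters
    ----------
    sample_ids
        Unique individual identifiers, one per row.
    genotypes
        Integer array with entries in {0, 1, 2, MISSING}. Row i holds the
        dosages of individual ``sample_ids[i]``.
    markers
        One row per marker with columns ``chrom`` (int), ``marker_id`` (str),
        ``genetic_pos`` (Morgans), ``physical_pos`` (bp).
    alleles
        Optional (n_markers, 2) array of allele labels, column 0 the counted
        allele, column 1 the other. ``"0"`` in column 0 marks a marker where
        the counted allele was never observed (monomorphic input).
    """

    sample_ids: list[str]
    genotypes: np.ndarray
    markers: pd.DataFrame
    alleles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x markers)")
        if self.genotypes.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match genotype rows")
        if self.genotypes.shape[1] != len(self.markers):
            raise ValueError("markers table does not match genotype columns")
        if self.alleles is None:
            self.alleles = np.stack(
                [np.repeat("A", self.n_markers), np.repeat("B", self.n_markers)],
                axis=1,
            ) if self.n_markers else np.empty((0, 2), dtype="<U1")
        self.validate()

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        codes = np.unique(self.genotypes)
        bad = set(codes.tolist()) - {0, 1, 2, MISSING}
        if bad:
            raise ValueError(f"invalid genotype codes present: {sorted(bad)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        mid = self.markers["marker_id"]
        if mid.duplicated().any():
            raise ValueError("duplicate marker_ids")
        for c, sub in self.markers.groupby("chrom"):
            gp = sub["genetic_pos"].to_numpy(float)
            if np.any(np.diff(gp) < 0):
                raise ValueError(f"genetic_pos decreases within chromosome {c}")
            if np.any(gp < 0):
                raise ValueError("negative genetic position")

    # -- derived quantities ------------------------------------------------
    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing genotype calls."""
        if self.n_markers == 0:
            return np.zeros(self.n_individuals)
        return np.mean(self.genotypes == MISSING, axis=1)

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the counted allele over non-missing calls.

        Markers with no non-missing call get NaN.
        """
        g = self.genotypes.astype(float)
        obs = g != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs, g, 0.0).sum(0) / (2.0 * obs.sum(0))

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(
            sample_ids=list(ids),
            genotypes=self.genotypes[rows].copy(),
            markers=self.markers.reset_index(drop=True),
            alleles=None if self.alleles is None else self.alleles.copy(),
        )

    def __eq__(self, other: object) -> bool:  # code-level identity
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.genotypes, other.genotypes)
            and self.markers[MARKER_COLUMNS].reset_index(drop=True).equals(
                other.markers[MARKER_COLUMNS].reset_index(drop=True)
            )
        )
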