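"""Reading and writing genotype data in PLINK text (.ped/.map) format.

The .map file has four whitespace-separated columns per marker: chromosome,
marker id, genetic distance, physical position. Genetic distance is taken to
be in Morgans (PLINK's documented unit); pass ``map_unit="cM"`` for maps in
centimorgans. The .ped file has six leading columns (family, individual,
father, mother, sex, phenotype) followed by two allele columns per marker;
``0`` denotes a missing allele.

On read, genotypes are coded as dosages of the marker's minor allele in the
file (ties broken by taking the lexicographically smaller allele as minor).
A pair containing a ``0`` allele becomes the missing code. Writing emits the
stored allele labels, so read -> write -> read round-trips exactly; matrices
whose counted allele is the major one in the data (possible for generator
output) are re-coded to minor-allele dosage when read back.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


class PlinkFormatError(ValueError):
    """Malformed .ped/.map content; the message carries the line number."""


def _as_lines(source) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    return Path(source).read_text().splitlines()


def _read_map(map_source, map_unit: str) -> pd.DataFrame:
    if map_unit not in ("M", "cM"):
        raise ValueError("map_unit must be 'M' or 'cM'")
    rows = []
    for lineno, line in enumerate(_as_lines(map_source), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise PlinkFormatError(
                f".map line {lineno}: expected 4 columns, found {len(parts)}"
            )
        try:
            chrom = int(parts[0])
            gpos = float(parts[2])
            ppos = int(float(parts[3]))
        except ValueError as exc:
            raise PlinkFormatError(f".map line {lineno}: {exc}") from None
        rows.append((chrom, parts[1], gpos, ppos))
    table = pd.DataFrame(
        rows, columns=["chrom", "marker_id", "genetic_pos", "physical_pos"]
    )
    if map_unit == "cM":
        table["genetic_pos"] = table["genetic_pos"] / 100.0
    return table


def read_plink_text(ped_source, map_source, map_unit: str = "M") -> GenotypeMatrix:
    """Parse a .ped/.map pair into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    ped_source, map_source
        Paths or open text handles.
    map_unit
        Unit of the .map genetic-distance column, ``"M"`` (default) or
        ``"cM"``.

    Raises
    ------
    PlinkFormatError
        On malformed lines (reported with line number), marker-count
        mismatches between the two files, or non-biallelic markers.
    """
    markers = _read_map(map_source, map_unit)
    n_markers = len(markers)

    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    for lineno, line in enumerate(_as_lines(ped_source), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 6 or (len(parts) - 6) % 2:
            raise PlinkFormatError(
                f".ped line {lineno}: expected 6 columns + 2 alleles per marker,"
                f" found {len(parts)} fields"
            )
        if (len(parts) - 6) // 2 != n_markers:
            raise PlinkFormatError(
                f".ped line {lineno}: {(len(parts) - 6) // 2} markers but .map"
                f" lists {n_markers}"
            )
        sample_ids.append(parts[1])
        allele_rows.append(np.array(parts[6:], dtype="<U8").reshape(n_markers, 2))

    n = len(sample_ids)
    if n == 0:
        return GenotypeMatrix(
            sample_ids=[],
            genotypes=np.empty((0, n_markers), dtype=np.int8),
            markers=markers,
        )

    alleles = np.stack(allele_rows)  # (n, n_markers, 2)
    genotypes = np.full((n, n_markers), MISSING, dtype=np.int8)
    marker_alleles = np.empty((n_markers, 2), dtype="<U8")
    for j in range(n_markers):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        distinct = sorted(set(observed.tolist()))
        if len(distinct) > 2:
            raise PlinkFormatError(
                f"marker {markers['marker_id'].iloc[j]!r} has"
                f" {len(distinct)} alleles: {distinct}"
            )
        missing_row = (col == "0").any(axis=1)
        if len(distinct) == 0:
            marker_alleles[j] = ("0", "0")
            continue
        if len(distinct) == 1:
            marker_alleles[j] = ("0", distinct[0])
            genotypes[~missing_row, j] = 0
            continue
        a, b = distinct  # lexicographic order
        count_a = int((observed == a).sum())
        count_b = int((observed == b).sum())
        minor = a if count_a <= count_b else b  # tie -> lexicographically smaller
        major = b if minor == a else a
        marker_alleles[j] = (minor, major)
        dosage = (col == minor).sum(axis=1).astype(np.int8)
        genotypes[~missing_row, j] = dosage[~missing_row]

    return GenotypeMatrix(
        sample_ids=sample_ids,
        genotypes=genotypes,
        markers=markers,
        alleles=marker_alleles,
    )


def write_plink_text(G: GenotypeMatrix, ped_sink, map_sink) -> None:
    """Write ``G`` as a .ped/.map pair re-readable by :func:`read_plink_text`."""
    own_ped = not hasattr(ped_sink, "write")
    own_map = not hasattr(map_sink, "write")
    ped = open(ped_sink, "w") if own_ped else ped_sink
    mp = open(map_sink, "w") if own_map else map_sink
    try:
        for _, row in G.markers.iterrows():
            mp.write(
                f"{int(row['chrom'])}\t{row['marker_id']}\t"
                f"{row['genetic_pos']:.8g}\t{int(row['physical_pos'])}\n"
            )
        counted = G.alleles[:, 0]
        other = G.alleles[:, 1]
        # counted allele "0" (never observed) can only pair with dosage 0/missing
        for i, sid in enumerate(G.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(G.n_markers):
                g = int(G.genotypes[i, j])
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [counted[j]] * g + [other[j]] * (2 - g)
            ped.write(" ".join(fields) + "\n")
    finally:
        if own_ped:
            ped.close()
        if own_map:
            mp.close()


def align_frequencies(
    G: GenotypeMatrix, freq_alleles: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Re-orient a frequency vector onto ``G``'s counted alleles.

    ``freqs[j]`` is the frequency of allele ``freq_alleles[j]``. Reading
    PLINK text re-codes genotypes as minor-allele dosage, which can flip the
    counted allele relative to the table that produced the data; this
    returns the frequency of each marker's *counted* allele in ``G`` so that
    dosage-based estimators see consistent references.
    """
    freq_alleles = np.asarray(freq_alleles)
    freqs = np.asarray(freqs, float)
    counted = G.alleles[:, 0]
    other = G.alleles[:, 1]
    out = np.where(counted == freq_alleles, freqs, np.nan)
    flip = (other == freq_alleles) & (counted != freq_alleles)
    out = np.where(flip, 1.0 - freqs, out)
    # monomorphic on read: the counted allele was never observed ("0");
    # a table allele that is not the observed one is taken to be it
    unseen = (counted == "0") & (other != freq_alleles)
    out = np.where(unseen, freqs, out)
    if np.isnan(out).any():
        bad = int(np.isnan(out).sum())
        raise ValueError(
            f"{bad} markers have frequency-table alleles matching neither"
            " matrix allele"
        )
    return out


def to_plink_strings(G: GenotypeMatrix) -> tuple[str, str]:
    """Render ``G`` as (.ped text, .map text) strings."""
    ped, mp = io.StringIO(), io.StringIO()
    write_plink_text(G, ped, mp)
    return ped.getvalue(), mp.getvalue()
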