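"""Sample-level quality control: genotyping-rate and relatedness filters.

Two rules, applied in this order:

1. drop individuals with a missing-call fraction strictly above
   ``max_missing`` (default 0.20, i.e. ">20% missing data");
2. estimate pairwise PI_HAT — the method-of-moments proportion of alleles
   shared identical by descent — among the survivors and, for every pair with
   PI_HAT strictly above ``max_pihat`` (default 0.5), drop the member with the
   higher missing fraction (ties broken by sample order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class QCReport:
    """Outcome of sample-level QC.

    ``exclusions`` maps each removed sample id to the rule it violated
    (``"missingness"`` or ``"relatedness"``).
    """

    missing_fraction: dict[str, float]
    pihat_pairs: list[tuple[str, str, float]]
    kept_ids: list[str]
    max_missing: float
    max_pihat: float | None
    exclusions: dict[str, str] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        rows = []
        kept = set(self.kept_ids)
        for sid, frac in self.missing_fraction.items():
            rows.append(
                {
                    "sample_id": sid,
                    "missing_fraction": frac,
                    "kept": sid in kept,
                    "reason": self.exclusions.get(sid, ""),
                }
            )
        return pd.DataFrame(rows)


def missingness_filter(G: GenotypeMatrix, max_missing: float = 0.20) -> QCReport:
    """Keep individuals whose missing fraction is <= ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    frac = G.missing_fraction()
    kept, excl = [], {}
    for sid, f in zip(G.sample_ids, frac):
        if f > max_missing:
            excl[sid] = "missingness"
        else:
            kept.append(sid)
    return QCReport(
        missing_fraction=dict(zip(G.sample_ids, frac.tolist())),
        pihat_pairs=[],
        kept_ids=kept,
        max_missing=max_missing,
        max_pihat=None,
        exclusions=excl,
    )


def _ibd_state_probs(p: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-marker P(IBS = s | IBD = z) for a biallelic marker with freq p."""
    q = 1.0 - p
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibd1 = 2 * p * q
    e2_ibd1 = 1.0 - 2 * p * q
    return e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1


def pi_hat(
    G: GenotypeMatrix,
    i: str,
    j: str,
    allele_freqs: np.ndarray | None = None,
    markers: np.ndarray | None = None,
) -> float:
    """Method-of-moments PI_HAT = P(IBD=1)/2 + P(IBD=2) for one pair.

    From the counts of identity-by-state sharing classes across jointly
    non-missing, polymorphic markers and the sample allele frequencies,
    the IBD-state probabilities are solved by moments; negative estimates
    are clipped to 0 and the triple renormalised.

    Parameters
    ----------
    allele_freqs
        Optional per-marker counted-allele frequencies; estimated from the
        full matrix when omitted.
    markers
        Optional boolean mask restricting the marker set used.
    """
    if i == j:
        raise ValueError("pi_hat requires two distinct individuals")
    idx = {s: k for k, s in enumerate(G.sample_ids)}
    gi = G.genotypes[idx[i]].astype(float)
    gj = G.genotypes[idx[j]].astype(float)
    p = G.allele_frequencies() if allele_freqs is None else np.asarray(allele_freqs, float)

    use = (gi != MISSING) & (gj != MISSING) & np.isfinite(p) & (p > 0) & (p < 1)
    if markers is not None:
        use &= np.asarray(markers, bool)
    if not use.any():
        raise ValueError(f"no jointly non-missing polymorphic marker for ({i}, {j})")
    gi, gj, p = gi[use], gj[use], p[use]

    ibs = 2.0 - np.abs(gi - gj)
    n0 = float(np.sum(ibs == 0))
    n1 = float(np.sum(ibs == 1))
    n2 = float(np.sum(ibs == 2))
    m = float(len(p))

    e0_0, e1_0, e2_0, e1_1, e2_1 = _ibd_state_probs(p)
    P0 = n0 / e0_0.sum()
    P1 = (n1 - P0 * e1_0.sum()) / e1_1.sum()
    P2 = (n2 - P0 * e2_0.sum() - P1 * e2_1.sum()) / m
    probs = np.clip([P0, P1, P2], 0.0, None)
    total = probs.sum()
    if total == 0:
        return 0.0
    probs = probs / total
    return float(np.clip(probs[1] / 2.0 + probs[2], 0.0, 1.0))


def pihat_matrix(G: GenotypeMatrix, ids: list[str] | None = None) -> list[tuple[str, str, float]]:
    """PI_HAT for every unordered pair among ``ids`` (default: all samples)."""
    ids = list(G.sample_ids) if ids is None else list(ids)
    freqs = G.allele_frequencies()
    out = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            out.append((ids[a], ids[b], pi_hat(G, ids[a], ids[b], allele_freqs=freqs)))
    return out


def quality_control(
    G: GenotypeMatrix,
    max_missing: float = 0.20,
    max_pihat: float | None = 0.5,
) -> QCReport:
    """Full sample QC: missingness filter, then relatedness pruning.

    Set ``max_pihat=None`` to skip the relatedness step (e.g. when the
    pairwise computation is not wanted).
    """
    report = missingness_filter(G, max_missing)
    report.max_pihat = max_pihat
    if max_pihat is None or len(report.kept_ids) < 2:
        return report

    pairs = pihat_matrix(G, report.kept_ids)
    report.pihat_pairs = pairs
    frac = report.missing_fraction
    order = {s: k for k, s in enumerate(G.sample_ids)}
    kept = set(report.kept_ids)
    # Greedy pruning: repeatedly drop the worse member of the worst flagged pair.
    while True:
        flagged = [(a, b, v) for a, b, v in pairs if v > max_pihat and a in kept and b in kept]
        if not flagged:
            break
        a, b, _ = max(flagged, key=lambda t: t[2])
        if (frac[a], order[a]) >= (frac[b], order[b]):
            victim = a
        else:
            victim = b
        kept.discard(victim)
        report.exclusions[victim] = "relatedness"
    report.kept_ids = [s for s in report.kept_ids if s in kept]
    return report
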