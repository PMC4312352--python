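"""Formal admixture tests and LD machinery.

Contents:

* the three-population statistic f3(C; A, B) = E[(c - a)(c - b)] with the
  target finite-sample correction and a block-jackknife standard error;
* pairwise genotype-r^2 decay binned by genetic distance, with the 1/n
  finite-sample adjustment, and its inversion into an effective-population-
  size trajectory N(t) at t = 1/(2c) generations;
* an admixture-LD (weighted-LD) curve — dosage covariances between marker
  pairs weighted by the reference-panel frequency contrasts at both markers
  — and an exponential fit whose decay rate, in per-Morgan units, reads as
  generations since admixture;
* the exponential fragment-survival law for ancestry-tract lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .genotypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# f3 three-population test
# ---------------------------------------------------------------------------

@dataclass
class F3Result:
    f3: float
    se: float
    z: float
    n_blocks: int
    n_snps_used: int
    corrected: bool


def _block_slices(n_snps: int, block_size: int):
    return [slice(s, min(s + block_size, n_snps)) for s in range(0, n_snps, block_size)]


def f3_statistic(
    target_freqs: np.ndarray,
    srcA_freqs: np.ndarray,
    srcB_freqs: np.ndarray,
    block_size_snps: int,
    target_counts: np.ndarray | None = None,
) -> F3Result:
    """f3(target; A, B) with leave-one-block-out jackknife SE.

    Per SNP the summand is (c - a)(c - b); when ``target_counts`` (target
    chromosome counts n_c) are supplied, the finite-sample correction
    h_c / n_c with h_c = n_c/(n_c - 1) * c(1 - c) is subtracted. A
    significantly negative z signals that the target is admixed between
    populations related to A and B.
    """
    c = np.asarray(target_freqs, float)
    a = np.asarray(srcA_freqs, float)
    b = np.asarray(srcB_freqs, float)
    if not (c.shape == a.shape == b.shape):
        raise ValueError("frequency vectors must have equal length")
    if block_size_snps < 1:
        raise ValueError("block_size_snps must be >= 1")
    if np.all((c == 0) | (c == 1)) and np.all((a == 0) | (a == 1)) and np.all(
        (b == 0) | (b == 1)
    ):
        raise ValueError("all markers are monomorphic in every population")

    terms = (c - a) * (c - b)
    corrected = target_counts is not None
    if corrected:
        n_c = np.asarray(target_counts, float)
        h = n_c / (n_c - 1.0) * c * (1.0 - c)
        terms = terms - h / n_c

    blocks = _block_slices(terms.size, block_size_snps)
    if len(blocks) < 2:
        raise ValueError("need at least 2 jackknife blocks; reduce block_size_snps")

    stat = float(terms.mean())
    total = terms.sum()
    n = terms.size
    leave_out = np.array(
        [(total - terms[sl].sum()) / (n - (sl.stop - sl.start)) for sl in blocks]
    )
    B = len(blocks)
    se = float(np.sqrt((B - 1) / B * np.sum((leave_out - leave_out.mean()) ** 2)))
    z = stat / se if se > 0 else float("nan")
    return F3Result(
        f3=stat, se=se, z=z, n_blocks=B, n_snps_used=n, corrected=corrected
    )


# ---------------------------------------------------------------------------
# LD decay and Ne trajectory (McEvoy-style procedure)
# ---------------------------------------------------------------------------

@dataclass
class LDDecayCurve:
    """Mean adjusted r^2 per genetic-distance bin.

    ``bins`` is a list of (low, high, midpoint, mean adjusted r^2, pair
    count); the adjustment subtracts 1/n where n is the number of
    individuals used.
    """

    bins: list[tuple[float, float, float, float, int]]
    sample_size: int

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([b[2] for b in self.bins])

    @property
    def values(self) -> np.ndarray:
        return np.array([b[3] for b in self.bins])


def _pairwise_r2(G: GenotypeMatrix, max_distance: float | None = None):
    """Yield (distance, r^2) for marker pairs on the same chromosome."""
    geno = G.genotypes.astype(float)
    geno[G.genotypes == MISSING] = np.nan
    chroms = G.markers["chrom"].to_numpy()
    pos = G.markers["genetic_pos"].to_numpy(float)
    dists, r2s = [], []
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        sub = geno[:, idx]
        p = pos[idx]
        has_nan = np.isnan(sub).any()
        if not has_nan:
            with np.errstate(invalid="ignore"):
                sd = sub.std(axis=0)
                ok = sd > 0
                z = (sub[:, ok] - sub[:, ok].mean(0)) / sd[ok]
                corr = (z.T @ z) / sub.shape[0]
            pok = p[ok]
            iu, ju = np.triu_indices(pok.size, k=1)
            d = np.abs(pok[ju] - pok[iu])
            r2 = corr[iu, ju] ** 2
            if max_distance is not None:
                sel = d <= max_distance
                d, r2 = d[sel], r2[sel]
            dists.append(d)
            r2s.append(r2)
        else:  # missing data: per-pair complete observations
            m = idx.size
            for i in range(m):
                for j in range(i + 1, m):
                    d = abs(p[j] - p[i])
                    if max_distance is not None and d > max_distance:
                        continue
                    x, y = sub[:, i], sub[:, j]
                    use = ~np.isnan(x) & ~np.isnan(y)
                    if use.sum() < 2:
                        continue
                    xs, ys = x[use], y[use]
                    if xs.std() == 0 or ys.std() == 0:
                        continue
                    r = np.corrcoef(xs, ys)[0, 1]
                    dists.append(np.array([d]))
                    r2s.append(np.array([r**2]))
    if not dists:
        return np.array([]), np.array([])
    return np.concatenate(dists), np.concatenate(r2s)


def ld_decay_bins(G: GenotypeMatrix, distance_bins: np.ndarray) -> LDDecayCurve:
    """Bin same-chromosome marker-pair r^2 by genetic distance.

    r^2 is the squared Pearson correlation of dosage vectors over jointly
    non-missing individuals (monomorphic pairs skipped); the reported value
    per bin is mean r^2 minus 1/n. Pairs are pooled across chromosomes.
    """
    edges = np.asarray(distance_bins, float)
    if edges.size < 2:
        raise ValueError("distance_bins must contain at least 2 edges")
    d, r2 = _pairwise_r2(G, max_distance=float(edges[-1]))
    n = G.n_individuals
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d >= lo) & (d < hi)
        if sel.sum() == 0:
            continue
        out.append((float(lo), float(hi), float((lo + hi) / 2),
                    float(r2[sel].mean() - 1.0 / n), int(sel.sum())))
    return LDDecayCurve(bins=out, sample_size=n)


@dataclass
class NeTrajectory:
    """(t, Ne) points from LD bins; ``skipped`` lists unusable bins."""

    points: list[tuple[float, float]]  # (generations before present, diploid Ne)
    skipped: list[tuple[float, str]]   # (bin midpoint, reason)


def ne_from_ld(curve: LDDecayCurve, drift_constant: float = 2.0) -> NeTrajectory:
    """Invert adjusted r^2 into an Ne trajectory.

    For a bin at recombination distance c (Morgans) with adjusted r^2 in
    (0, 1/drift_constant): Ne = (1/(4c)) * (1/r^2_adj - drift_constant),
    dated at t = 1/(2c) generations before present. Bins outside the usable
    range are reported with reasons rather than raising.
    """
    points, skipped = [], []
    for lo, hi, mid, r2adj, npairs in curve.bins:
        if mid <= 0:
            skipped.append((mid, "non-positive distance"))
            continue
        if r2adj <= 0:
            skipped.append((mid, "adjusted r^2 <= 0"))
            continue
        if r2adj >= 1.0 / drift_constant:
            skipped.append((mid, f"adjusted r^2 >= 1/{drift_constant:g}"))
            continue
        ne = (1.0 / (4.0 * mid)) * (1.0 / r2adj - drift_constant)
        points.append((1.0 / (2.0 * mid), ne))
    if not points:
        import warnings

        warnings.warn("no usable LD bin; empty Ne trajectory")
    return NeTrajectory(points=points, skipped=skipped)


# ---------------------------------------------------------------------------
# Weighted (admixture) LD and exponential dating fit
# ---------------------------------------------------------------------------

def weighted_ld_curve(
    target_G: GenotypeMatrix,
    ref1_freqs: np.ndarray,
    ref2_freqs: np.ndarray,
    distance_bins: np.ndarray,
) -> LDDecayCurve:
    """Admixture-LD curve of the target against two reference panels.

    Per same-chromosome marker pair (l1, l2) the statistic is
    cov(g_l1, g_l2) * w_l1 * w_l2 with w = ref1 - ref2 frequency contrast;
    bin values are these products averaged with weights w^2 w^2 (so a
    population admixed between the panels yields approximately
    2 m (1 - m) exp(-lambda d) at distance d). Deterministic; invariant to
    permuting individuals.
    """
    edges = np.asarray(distance_bins, float)
    w = np.asarray(ref1_freqs, float) - np.asarray(ref2_freqs, float)
    if w.size != target_G.n_markers:
        raise ValueError("reference frequencies must align with target markers")
    geno = target_G.genotypes.astype(float)
    geno[target_G.genotypes == MISSING] = np.nan
    chroms = target_G.markers["chrom"].to_numpy()
    pos = target_G.markers["genetic_pos"].to_numpy(float)
    n = target_G.n_individuals

    dists, nums, dens = [], [], []
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        sub = geno[:, idx]
        if np.isnan(sub).any():
            col_means = np.nanmean(sub, axis=0)
            sub = np.where(np.isnan(sub), col_means, sub)
        centred = sub - sub.mean(0)
        cov = (centred.T @ centred) / (n - 1)
        wc = w[idx]
        p = pos[idx]
        iu, ju = np.triu_indices(idx.size, k=1)
        d = np.abs(p[ju] - p[iu])
        sel = d <= edges[-1]
        iu, ju, d = iu[sel], ju[sel], d[sel]
        dists.append(d)
        nums.append(cov[iu, ju] * wc[iu] * wc[ju])
        dens.append((wc[iu] ** 2) * (wc[ju] ** 2))
    d = np.concatenate(dists) if dists else np.array([])
    num = np.concatenate(nums) if nums else np.array([])
    den = np.concatenate(dens) if dens else np.array([])

    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d >= lo) & (d < hi)
        if sel.sum() == 0 or den[sel].sum() == 0:
            continue
        out.append((float(lo), float(hi), float((lo + hi) / 2),
                    float(num[sel].sum() / den[sel].sum()), int(sel.sum())))
    return LDDecayCurve(bins=out, sample_size=n)


@dataclass
class WeightedLDFit:
    amplitude: float
    decay_rate: float  # per Morgan == generations since admixture
    offset: float
    rss: float
    window: tuple[float, float]
    converged: bool


def fit_exponential_decay(
    curve: LDDecayCurve, window: tuple[float, float] | None = None
) -> WeightedLDFit:
    """Least-squares fit of A exp(-lambda d) + c0 to the binned curve.

    ``window`` restricts the fitted distance range (Morgans). The decay rate
    is per Morgan, i.e. generations since the admixture pulse. A fit that
    fails to converge, or a flat curve with unidentifiable rate, is returned
    flagged (``converged=False``, ``rss=inf`` on failure) rather than raised.
    """
    d = curve.midpoints
    y = curve.values
    if window is not None:
        sel = (d >= window[0]) & (d <= window[1])
        d, y = d[sel], y[sel]
    else:
        window = (float(d.min()), float(d.max())) if d.size else (0.0, 0.0)
    if d.size < 3:
        raise ValueError("need at least 3 bins in the fit window")

    def model(x, A, lam, c0):
        return A * np.exp(-lam * x) + c0

    # log-linear initial guess on the positive part
    ypos = y - y.min() + 1e-12
    slope, intercept = np.polyfit(d, np.log(ypos), 1)
    p0 = [max(float(np.exp(intercept)), 1e-9), max(-float(slope), 1.0), float(y.min())]
    try:
        popt, _ = curve_fit(
            model, d, y, p0=p0, bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return WeightedLDFit(
            amplitude=float("nan"), decay_rate=float("nan"), offset=float("nan"),
            rss=float("inf"), window=window, converged=False,
        )
    rss = float(np.sum((model(d, *popt) - y) ** 2))
    A, lam, c0 = (float(v) for v in popt)
    # flat curve: amplitude indistinguishable from 0 -> rate unidentifiable
    identifiable = A > 10 * np.sqrt(rss / d.size) if d.size else False
    return WeightedLDFit(
        amplitude=A, decay_rate=lam, offset=c0, rss=rss, window=window,
        converged=bool(identifiable),
    )


# ---------------------------------------------------------------------------
# Fragment-survival law
# ---------------------------------------------------------------------------

def fragment_length_cdf(lambda_rate: float, x) -> float | np.ndarray:
    """P(ancestry-fragment length <= x) = 1 - exp(-lambda x).

    ``lambda_rate`` is the tract-erosion rate per Morgan and ``x`` a length
    in Morgans; the survival function exp(-lambda x) gives the probability
    that a fragment of length x persists. Valid CDF: 0 at x = 0, monotone
    non-decreasing in both arguments, -> 1 as x grows.
    """
    x = np.asarray(x, float)
    if lambda_rate < 0:
        raise ValueError("lambda_rate must be >= 0")
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    out = -np.expm1(-lambda_rate * x)
    return float(out) if out.ndim == 0 else out
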