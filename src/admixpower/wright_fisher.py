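"""Forward-time Wright–Fisher simulation of a three-population demographic
model with a single migration pulse.

The demography: one ancestral population of size ``N_anc1`` from ``t_start``
generations ago; at ``t_split1`` it splits into a Source branch (optionally
expanded to ``N_source``) and a second ancestral branch; at ``t_split2`` the
latter splits into Control (``N_control``) and Admixed (``N_admix``)
populations. At ``t_pulse`` each Admixed individual is independently replaced
by a Source migrant with probability ``pulse_rate``. Samples of
``sample_size`` individuals are taken from every population at three time
points: just before the pulse, one mating generation after it, and at the
present day.

Because loci are unlinked and mating is random, the population-level allele-
frequency process is simulated exactly as the Wright–Fisher binomial chain
(2N gametes per generation per locus), and sampled individuals' genotypes are
drawn as Binomial(2, p) under Hardy–Weinberg — marginally identical to an
individual-based engine. True source ancestry is tracked per individual in
the Admixed population as an exact scalar: a migrant starts at 1 and every
offspring carries the mean of its two parents' values. The realised migrant
count couples the ancestry bookkeeping to the frequency pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genotypes import GenotypeMatrix, default_marker_table

TIME_POINTS = ("pre_pulse", "post_pulse", "present")
POPULATIONS = ("Source", "Control", "Admixed")


@dataclass
class DemographicModel:
    """Epoch times (generations before present), sizes, and locus layout.

    Defaults encode 95/25/11/6 Kya at 25 years per generation. Population
    sizes are diploid effective sizes; the defaults are package choices made
    in the absence of published values and every one is configurable.
    """

    generation_time: float = 25.0
    t_start: int = 3800
    t_split1: int = 1000
    t_split2: int = 440
    t_pulse: int = 240
    N_anc1: int = 10_000
    N_source: int = 30_000
    N_control: int = 2_000
    N_admix: int = 2_000
    source_growth: bool = True  # instantaneous expansion at t_split1
    pulse_rate: float = 0.10
    n_loci: int = 2200
    n_chromosomes: int = 22
    sample_size: int = 50
    n_replicates: int = 100
    init_freq_range: tuple[float, float] = (0.05, 0.95)

    def validate(self) -> None:
        if not self.t_start > self.t_split1 > self.t_split2 > self.t_pulse >= 0:
            raise ValueError("need t_start > t_split1 > t_split2 > t_pulse >= 0")
        for name in ("N_anc1", "N_source", "N_control", "N_admix"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if not 0.0 <= self.pulse_rate <= 1.0:
            raise ValueError("pulse_rate must be in [0, 1]")
        for name, N in (("Control", self.N_control), ("Admixed", self.N_admix),
                        ("Source", self.N_source)):
            if self.sample_size > N:
                raise ValueError(
                    f"sample_size {self.sample_size} exceeds population"
                    f" {name} size {N}"
                )


@dataclass
class SimulationSample:
    """One replicate's samples: (time point, population) -> genotypes + truth.

    ``genotypes[(tp, pop)]`` is a GenotypeMatrix of ``sample_size``
    individuals; ``ancestry[(tp, pop)]`` the matching true source-ancestry
    fractions (bookkept, not inferred). ``population_mean_ancestry`` records
    the full-population Admixed means at each time point.
    """

    genotypes: dict[tuple[str, str], GenotypeMatrix]
    ancestry: dict[tuple[str, str], np.ndarray]
    population_mean_ancestry: dict[str, float]
    seed: int


def _drift(p: np.ndarray, N: int, gens: int, rng: np.random.Generator) -> np.ndarray:
    """Advance locus frequencies ``gens`` Wright–Fisher generations."""
    two_n = 2 * N
    for _ in range(gens):
        p = rng.binomial(two_n, p) / two_n
    return p


def _sample_pop(
    p: np.ndarray,
    size: int,
    prefix: str,
    markers,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    geno = rng.binomial(2, p, size=(size, p.size)).astype(np.int8)
    ids = [f"{prefix}_ind{i + 1}" for i in range(size)]
    return GenotypeMatrix(sample_ids=ids, genotypes=geno, markers=markers)


def _ancestry_generation(anc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One generation of random mating: each child averages two parents."""
    parents = rng.integers(0, anc.size, size=(anc.size, 2))
    return anc[parents].mean(axis=1)


def simulate_model(model: DemographicModel, seed: int = 0) -> SimulationSample:
    """Run one replicate of the demographic model.

    Returns genotype samples and true-ancestry vectors for every population
    at the three sampling time points. With ``pulse_rate = 0`` every Control
    and Admixed ancestry is exactly 0.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    markers = default_marker_table(model.n_loci, model.n_chromosomes)

    lo, hi = model.init_freq_range
    p_anc = rng.uniform(lo, hi, size=model.n_loci)
    p_anc = _drift(p_anc, model.N_anc1, model.t_start - model.t_split1, rng)

    p_source = p_anc.copy()
    p_anc2 = p_anc
    N_src = model.N_source if model.source_growth else model.N_anc1
    gens = model.t_split1 - model.t_split2
    p_source = _drift(p_source, N_src, gens, rng)
    p_anc2 = _drift(p_anc2, model.N_anc1, gens, rng)

    p_control = p_anc2.copy()
    p_admix = p_anc2
    gens = model.t_split2 - model.t_pulse
    p_source = _drift(p_source, N_src, gens, rng)
    p_control = _drift(p_control, model.N_control, gens, rng)
    p_admix = _drift(p_admix, model.N_admix, gens, rng)

    genotypes: dict[tuple[str, str], GenotypeMatrix] = {}
    ancestry: dict[tuple[str, str], np.ndarray] = {}
    pop_mean: dict[str, float] = {}
    anc_admix = np.zeros(model.N_admix)

    def take(tp: str, pops: dict[str, np.ndarray]) -> None:
        for pop, p in pops.items():
            genotypes[(tp, pop)] = _sample_pop(
                p, model.sample_size, f"{tp}_{pop}", markers, rng
            )
            if pop == "Source":
                anc = np.ones(model.sample_size)
            elif pop == "Admixed":
                anc = rng.choice(anc_admix, size=model.sample_size, replace=False)
            else:
                anc = np.zeros(model.sample_size)
            ancestry[(tp, pop)] = anc
        pop_mean[tp] = float(anc_admix.mean())

    take("pre_pulse", {"Source": p_source, "Control": p_control, "Admixed": p_admix})

    # migration pulse: independent per-individual replacement by Source migrants
    migrants = rng.random(model.N_admix) < model.pulse_rate
    anc_admix = migrants.astype(float)
    realised = migrants.mean()
    p_admix = realised * p_source + (1.0 - realised) * p_admix

    # one mating generation, then the post-pulse sample
    p_source = _drift(p_source, N_src, 1, rng)
    p_control = _drift(p_control, model.N_control, 1, rng)
    p_admix = _drift(p_admix, model.N_admix, 1, rng)
    anc_admix = _ancestry_generation(anc_admix, rng)
    take("post_pulse", {"Source": p_source, "Control": p_control, "Admixed": p_admix})

    gens = model.t_pulse - 1
    p_source = _drift(p_source, N_src, gens, rng)
    p_control = _drift(p_control, model.N_control, gens, rng)
    p_admix = _drift(p_admix, model.N_admix, gens, rng)
    for _ in range(gens):
        anc_admix = _ancestry_generation(anc_admix, rng)
    take("present", {"Source": p_source, "Control": p_control, "Admixed": p_admix})

    return SimulationSample(
        genotypes=genotypes,
        ancestry=ancestry,
        population_mean_ancestry=pop_mean,
        seed=seed,
    )


def replicate_seed(base_seed: int, r: int) -> int:
    """Deterministic per-replicate seed derived from (base_seed, r)."""
    return int(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(r,)).generate_state(1)[0]
        % (2**31)
    )


def run_replicates(
    model: DemographicModel, n_replicates: int | None = None, base_seed: int = 0
) -> list[SimulationSample]:
    """Independent replicates with seeds derived from ``base_seed``."""
    n = model.n_replicates if n_replicates is None else n_replicates
    if n < 1:
        raise ValueError("n_replicates must be >= 1")
    return [simulate_model(model, replicate_seed(base_seed, r)) for r in range(n)]


# ---------------------------------------------------------------------------
# Two-locus emulation for LD-based Ne validation
# ---------------------------------------------------------------------------

def simulate_linked_pairs(
    N: int,
    c: float,
    n_pairs: int,
    n_generations: int,
    init_freq_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
) -> np.ndarray:
    """Population gamete frequencies for independent linked locus pairs.

    Each pair of biallelic loci at recombination fraction ``c`` evolves in a
    Wright–Fisher population of ``N`` diploids (2N gametes, recombination
    applied deterministically to expected haplotype frequencies before the
    multinomial resampling). Starts at linkage equilibrium. Returns an
    (n_pairs, 4) array of final haplotype frequencies in order AB, Ab, aB,
    ab. Used to validate the LD -> Ne inversion against a known truth.
    """
    rng = np.random.default_rng(seed)
    lo, hi = init_freq_range
    pA = rng.uniform(lo, hi, size=n_pairs)
    pB = rng.uniform(lo, hi, size=n_pairs)
    x = np.stack([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)], axis=1)
    two_n = 2 * N
    for _ in range(n_generations):
        D = x[:, 0] * x[:, 3] - x[:, 1] * x[:, 2]
        shift = c * D
        x = x + np.stack([-shift, shift, shift, -shift], axis=1)
        x = np.clip(x, 0.0, 1.0)
        x /= x.sum(1, keepdims=True)
        # multinomial resampling via conditional binomials (vectorised)
        n0 = rng.binomial(two_n, x[:, 0])
        rest = two_n - n0
        with np.errstate(invalid="ignore", divide="ignore"):
            q1 = np.where(x[:, 0] < 1, x[:, 1] / (1 - x[:, 0]), 0.0)
        n1 = rng.binomial(rest, np.clip(q1, 0, 1))
        rest = rest - n1
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = 1 - x[:, 0] - x[:, 1]
            q2 = np.where(denom > 0, x[:, 2] / denom, 0.0)
        n2 = rng.binomial(rest, np.clip(q2, 0, 1))
        n3 = rest - n2
        x = np.stack([n0, n1, n2, n3], axis=1) / two_n
    return x


def sample_pair_r2(
    gamete_freqs: np.ndarray, n_individuals: int, seed: int = 0
) -> np.ndarray:
    """Genotype-based r^2 from ``n_individuals`` diploids per locus pair.

    Each individual is the sum of two gametes drawn from the pair's final
    gamete-frequency vector. Pairs monomorphic in the sample yield NaN.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(gamete_freqs, float)
    out = np.full(x.shape[0], np.nan)
    allele1 = np.array([1, 1, 0, 0])
    allele2 = np.array([1, 0, 1, 0])
    for k in range(x.shape[0]):
        gametes = rng.choice(4, size=2 * n_individuals, p=x[k] / x[k].sum())
        d1 = allele1[gametes].reshape(n_individuals, 2).sum(1)
        d2 = allele2[gametes].reshape(n_individuals, 2).sum(1)
        if d1.std() == 0 or d2.std() == 0:
            continue
        out[k] = np.corrcoef(d1, d2)[0, 1] ** 2
    return out
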