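"""Power analysis: replicated pulse-migration simulations and detection rates.

For each migration rate the study runs replicated forward simulations and
asks, per replicate, whether the present-day Admixed population's mean
source ancestry reaches a detection threshold; power is the fraction of
replicates where it does, and the same question posed to the Control
population gives the false-positive rate. Ancestry can be the bookkept truth
(default — detection power given a method able to measure mean admixture
down to the threshold) or the supervised EM estimate computed from the
simulated genotypes with reference frequencies taken from the sampled Source
and Control panels.

Retention fractions summarise individual-level ancestry: the fraction of
individuals, pooled over replicates, whose ancestry exceeds 1% or 5% at each
sampling time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ancestry import estimate_admixture_fraction
from .wright_fisher import (
    TIME_POINTS,
    DemographicModel,
    SimulationSample,
    replicate_seed,
    run_replicates,
)

DEFAULT_RATES = (0.0, 0.01, 0.05, 0.10)
DEFAULT_THRESHOLDS = (0.001, 0.005)


@dataclass
class PowerResult:
    """Study output.

    ``power_table`` has one row per (rate, threshold) with columns ``power``
    and ``control_power``; ``replicate_means`` one row per (rate, replicate)
    with the present-day sample-mean ancestry (true, and estimated when
    computed) in Admixed and Control.
    """

    power_table: pd.DataFrame
    replicate_means: pd.DataFrame
    retention: pd.DataFrame | None
    rates: tuple[float, ...]
    thresholds: tuple[float, ...]
    n_replicates: int
    base_seed: int
    use_estimates: bool


def _estimate_means(sample: SimulationSample) -> tuple[float, float]:
    """Supervised-EM mean ancestry of Admixed and Control present samples.

    Reference frequencies come from the simulated present-day Source sample
    (source component) and Control sample (native component) — panels a
    practitioner could actually genotype.
    """
    src = sample.genotypes[("present", "Source")].allele_frequencies()
    ctl = sample.genotypes[("present", "Control")].allele_frequencies()
    adm_est = estimate_admixture_fraction(
        sample.genotypes[("present", "Admixed")], src, ctl
    )
    ctl_est = estimate_admixture_fraction(
        sample.genotypes[("present", "Control")], src, ctl
    )
    return float(adm_est.mean()), float(ctl_est.mean())


def retention_fractions(
    samples: list[SimulationSample],
    thresholds: tuple[float, ...] = (0.01, 0.05),
    use_estimates: bool = False,
) -> pd.DataFrame:
    """Fraction of individuals above each ancestry threshold.

    Pooled over replicates, per (time point, population, threshold). With
    ``use_estimates`` the supervised EM estimates replace the bookkept truth
    (present time point only has reference panels defined; estimates at the
    other time points use the same-time Source/Control samples).
    """
    rows = []
    pops = ("Admixed", "Control")
    for tp in TIME_POINTS:
        for pop in pops:
            values = []
            for s in samples:
                if use_estimates:
                    src = s.genotypes[(tp, "Source")].allele_frequencies()
                    ctl = s.genotypes[(tp, "Control")].allele_frequencies()
                    values.append(
                        estimate_admixture_fraction(s.genotypes[(tp, pop)], src, ctl)
                    )
                else:
                    values.append(s.ancestry[(tp, pop)])
            pooled = np.concatenate(values)
            for thr in thresholds:
                rows.append(
                    {
                        "timepoint": tp,
                        "population": pop,
                        "threshold": thr,
                        "fraction": float(np.mean(pooled > thr)),
                        "n_individuals": pooled.size,
                    }
                )
    return pd.DataFrame(rows)


def run_power_study(
    model_base: DemographicModel,
    rates: tuple[float, ...] = DEFAULT_RATES,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    n_replicates: int = 100,
    use_estimates: bool = False,
    base_seed: int = 0,
    keep_samples_for_rate: float | None = None,
) -> tuple[PowerResult, list[SimulationSample] | None]:
    """Power surface over migration rates x detection thresholds.

    Per rate, ``n_replicates`` replicates are simulated with seeds derived
    deterministically from ``base_seed`` (replicate streams are shared
    across rates so rates differ only through the pulse). Detection:
    present-day sample-mean ancestry >= threshold.

    ``keep_samples_for_rate`` optionally returns the replicate samples for
    one rate (for retention analysis) without re-simulating.
    """
    for r in rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be fractions in [0, 1]")
    for t in thresholds:
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must be fractions in [0, 1]")

    mean_rows = []
    kept: list[SimulationSample] | None = None
    for rate in rates:
        model = replace(model_base, pulse_rate=rate)
        samples = run_replicates(model, n_replicates, base_seed)
        if keep_samples_for_rate is not None and rate == keep_samples_for_rate:
            kept = samples
        for rep, s in enumerate(samples):
            row = {
                "rate": rate,
                "replicate": rep,
                "admixed_true_mean": float(s.ancestry[("present", "Admixed")].mean()),
                "control_true_mean": float(s.ancestry[("present", "Control")].mean()),
            }
            if use_estimates:
                adm, ctl = _estimate_means(s)
                row["admixed_est_mean"] = adm
                row["control_est_mean"] = ctl
            mean_rows.append(row)
    means = pd.DataFrame(mean_rows)

    adm_col = "admixed_est_mean" if use_estimates else "admixed_true_mean"
    ctl_col = "control_est_mean" if use_estimates else "control_true_mean"
    rows = []
    for rate in rates:
        sub = means[means["rate"] == rate]
        for thr in thresholds:
            rows.append(
                {
                    "rate": rate,
                    "threshold": thr,
                    "power": float(np.mean(sub[adm_col] >= thr)),
                    "control_power": float(np.mean(sub[ctl_col] >= thr)),
                }
            )
    table = pd.DataFrame(rows)

    retention = retention_fractions(kept) if kept is not None else None
    result = PowerResult(
        power_table=table,
        replicate_means=means,
        retention=retention,
        rates=tuple(rates),
        thresholds=tuple(thresholds),
        n_replicates=n_replicates,
        base_seed=base_seed,
        use_estimates=use_estimates,
    )
    return result, kept
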