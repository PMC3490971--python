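"""Simulation studies of the scan's operating characteristics.

Three reusable experiments drive both the analysis reports and the
acceptance checks: false-enrichment calibration on null data (the cohort is
drawn from the panel's own frequencies, so every call is false), detection
power and empirical false-discovery proportion on spiked datasets with known
truth, and the convergence of the small-vs-large subsampling correlation as
the small sample grows.
"""

from __future__ import annotations

import numpy as np

from .genotype_io import all_allele_stats
from .representativeness import subsample_frequency_correlation, summarize_correlations
from .simulate import (
    PopulationSpec,
    SimulationConfig,
    SpikeSpec,
    SubgroupSpec,
    simulate_dataset,
)
from .stats import NOT_ENRICHED, scan_enrichment

# the default 3/2/2 cohort split, with every subgroup drawn from the single
# panel population at zero extra divergence: a pure null for the scan
_NULL_SUBGROUPS = (
    SubgroupSpec("Q1", 3, "POP", 0.0),
    SubgroupSpec("Q2", 2, "POP", 0.0),
    SubgroupSpec("Q3", 2, "POP", 0.0),
)


def _rep_seed(seed: int, rep: int) -> int:
    return int(np.random.SeedSequence((seed, rep)).generate_state(1)[0] % 2**31)


def null_false_enrichment_rate(
    n_sites: int = 10_000,
    reps: int = 20,
    seed: int = 0,
    panel_individuals: int = 379,
    fst_threshold: float = 0.25,
    q_threshold: float = 0.05,
) -> dict:
    """Fraction of tested sites falsely called enriched on null replicates.

    Every replicate simulates one reference panel and a 7-individual cohort
    drawn from that panel's own frequencies, then runs the combined
    binomial + Fst + q-value scan; any enriched call is a false enrichment.
    Returns the per-replicate rates with their mean and Monte-Carlo SE.
    """
    rates = []
    for rep in range(reps):
        cfg = SimulationConfig(
            n_sites=n_sites,
            panels=(PopulationSpec("POP", panel_individuals, 0.08),),
            subgroups=_NULL_SUBGROUPS,
            seed=_rep_seed(seed, rep),
        )
        ds = simulate_dataset(cfg)
        x, n = all_allele_stats(ds.cohort)
        table, _ = scan_enrichment(
            x, n, ds.panel_table, fst_threshold=fst_threshold, q_threshold=q_threshold
        )
        n_tested = table["site_index"].nunique()
        n_false = table.loc[table["call"] != NOT_ENRICHED, "site_index"].nunique()
        rates.append(n_false / n_tested if n_tested else 0.0)
    rates = np.asarray(rates)
    se = rates.std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0
    return {
        "rates": rates,
        "mean_rate": float(rates.mean()),
        "mc_se": float(se),
        "n_sites": n_sites,
        "reps": reps,
    }


def spiked_scan_performance(
    n_sites: int = 10_000,
    n_spiked: int = 100,
    displacement: float = 0.5,
    reps: int = 5,
    seed: int = 0,
    fst_threshold: float = 0.25,
    q_threshold: float = 0.05,
) -> dict:
    """Detection power and empirical false-discovery proportion on spikes.

    The cohort's three subgroups all descend from the European-scale panel
    with zero extra divergence, so against that source panel only spiked
    sites are truly differentiated. Power counts spiked sites called
    enriched against at least one continent; the empirical FDR is the share
    of unspiked sites among the calls made against the source panel.
    """
    null_subgroups = (
        SubgroupSpec("Q1", 3, "EUR", 0.0),
        SubgroupSpec("Q2", 2, "EUR", 0.0),
        SubgroupSpec("Q3", 2, "EUR", 0.0),
    )
    powers, fdrs = [], []
    for rep in range(reps):
        cfg = SimulationConfig(
            n_sites=n_sites,
            subgroups=null_subgroups,
            spike=SpikeSpec(n_spiked, displacement, "higher"),
            seed=_rep_seed(seed, rep),
        )
        ds = simulate_dataset(cfg)
        x, n = all_allele_stats(ds.cohort)
        table, _ = scan_enrichment(
            x, n, ds.panel_table, fst_threshold=fst_threshold, q_threshold=q_threshold
        )
        spiked = set(np.nonzero(ds.truth["spiked"].to_numpy())[0])
        called_any = set(table.loc[table["call"] != NOT_ENRICHED, "site_index"])
        powers.append(len(spiked & called_any) / len(spiked))
        source = table[(table["continent"] == "EUR") & (table["call"] != NOT_ENRICHED)]
        called_source = set(source["site_index"])
        if called_source:
            fdrs.append(len(called_source - spiked) / len(called_source))
        else:
            fdrs.append(0.0)
    powers = np.asarray(powers)
    fdrs = np.asarray(fdrs)
    return {
        "power": float(powers.mean()),
        "power_mc_se": float(powers.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
        "fdr": float(fdrs.mean()),
        "fdr_mc_se": float(fdrs.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
        "displacement": displacement,
        "n_spiked": n_spiked,
        "n_sites": n_sites,
        "reps": reps,
    }


def power_curve(
    displacements: tuple[float, ...] = (0.1, 0.25, 0.4),
    n_sites: int = 5_000,
    n_spiked: int = 200,
    reps: int = 2,
    seed: int = 0,
) -> list[dict]:
    """Detection power at a grid of spike displacements (shared seeds)."""
    return [
        spiked_scan_performance(
            n_sites=n_sites,
            n_spiked=n_spiked,
            displacement=d,
            reps=reps,
            seed=seed,
        )
        for d in displacements
    ]


def subsample_convergence(
    k_grid: tuple[int, ...] = (5, 15, 40, 80),
    n_individuals: int = 120,
    n_sites: int = 200,
    reps: int = 25,
    seed: int = 0,
) -> list[dict]:
    """Mean small-vs-large frequency correlation for a grid of small-sample
    sizes within one panmictic population.

    The large comparator is the whole population (overlap permitted), so the
    correlation must rise to exactly 1 as the small sample reaches everyone;
    the disjoint design used in validation studies is available separately
    through :func:`~afenrich.representativeness.subsample_frequency_correlation`.
    """
    cfg = SimulationConfig(
        n_sites=n_sites,
        panels=(PopulationSpec("POP", n_individuals, 0.08),),
        subgroups=(SubgroupSpec("Q1", 1, "POP", 0.0),),
        missing_rate=0.0,
        panel_genotypes=True,
        seed=_rep_seed(seed, 0),
    )
    ds = simulate_dataset(cfg)
    dosage = ds.panel_dosage["POP"]
    labels = np.array(["POP"] * n_individuals)
    out = []
    for k in k_grid:
        per_rep = subsample_frequency_correlation(
            dosage, labels, k=k, m=None, reps=reps, seed=_rep_seed(seed, k),
            allow_overlap=True,
        )
        out.append({"k": int(k), **summarize_correlations(per_rep)})
    return out
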