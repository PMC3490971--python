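"""How representative is a tiny cohort's allele frequency of its population?

Given per-site allele frequencies in a small sample (e.g. 7 individuals, 14
alleles) and in a much larger sample from the same population, the Pearson
product-moment correlation with a Fisher-z confidence interval and a t-test
quantifies agreement. A subsampling study repeats this on panel genotypes:
draw a small sample (optionally a mixture over populations, e.g. 3 European
+ 2 Asian + 2 African individuals), compute frequencies in the small sample
and in a large disjoint sample, and record the correlation per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with Fisher-z 95% CI, t-test p (df = n-2) and OLS fit."""

    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float
    slope: float
    intercept: float


def fisher_ci(r: float, n: int, z_quantile: float = 1.96) -> tuple[float, float]:
    """95% confidence interval for a correlation via the Fisher z-transform:
    tanh(atanh(r) ± 1.96/sqrt(n-3))."""
    if n < 4:
        raise ValueError("Fisher-z interval requires n >= 4")
    if abs(r) >= 1.0:  # degenerate: the transform diverges at |r| = 1
        return float(r), float(r)
    z = np.arctanh(r)
    half = z_quantile / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_with_inference(
    f_small: Sequence[float] | np.ndarray,
    f_large: Sequence[float] | np.ndarray,
) -> CorrelationResult:
    """Pearson correlation of paired frequencies with full inference.

    The p-value is the two-sided Student-t test with n-2 degrees of freedom;
    the least-squares line regresses the large-sample frequency on the
    small-sample frequency.
    """
    a = np.asarray(f_small, dtype=float)
    b = np.asarray(f_large, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("frequency columns must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 frequency pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a frequency column; r undefined")
    r, p = sps.pearsonr(a, b)
    fit = sps.linregress(a, b)
    ci_low, ci_high = fisher_ci(float(r), a.size)
    return CorrelationResult(
        r=float(r),
        n=int(a.size),
        ci_low=ci_low,
        ci_high=ci_high,
        p=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


@dataclass(frozen=True)
class MixtureSpec:
    """Composition of a small sample across source populations."""

    composition: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if any(count < 0 for _, count in self.composition):
            raise ValueError("mixture counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(count for _, count in self.composition)


def compose_mixture_sample(
    pop_labels: Sequence[str] | np.ndarray,
    spec: MixtureSpec,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw individual indices without replacement per population.

    ``pop_labels`` gives the population of each individual (by index). The
    draw is uniform within each population and deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(pop_labels)
    chosen: list[np.ndarray] = []
    for pop, count in spec.composition:
        pool = np.nonzero(labels == pop)[0]
        if count > pool.size:
            raise ValueError(
                f"requested {count} individuals from population {pop!r} of size {pool.size}"
            )
        chosen.append(rng.choice(pool, size=count, replace=False))
    return np.sort(np.concatenate(chosen)) if chosen else np.empty(0, dtype=int)


def _frequencies(dosage: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per site over the given individuals, NaN where
    every call is missing."""
    sub = dosage[rows]
    called = sub >= 0
    n = 2 * called.sum(axis=0)
    x = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, x / np.maximum(n, 1), np.nan)


def subsample_frequency_correlation(
    dosage: np.ndarray,
    pop_labels: Sequence[str] | np.ndarray,
    *,
    k: int | None = None,
    mixture: MixtureSpec | None = None,
    small_pop: str | None = None,
    m: int | None = None,
    large_pops: Sequence[str] | None = None,
    reps: int = 50,
    seed: int = 0,
    allow_overlap: bool = False,
) -> pd.DataFrame:
    """Replicated small-vs-large allele-frequency correlation.

    Parameters
    ----------
    dosage
        (n_individuals, n_sites) alt-dosage matrix (0/1/2, -1 missing).
    k / small_pop or mixture
        The small sample: either ``k`` individuals from ``small_pop`` (or
        from everyone when ``small_pop`` is None), or a ``MixtureSpec``.
    m / large_pops
        The large comparator: ``m`` individuals drawn from ``large_pops``
        (all populations when None), excluding the small sample's
        individuals unless ``allow_overlap``. ``m=None`` uses everyone
        eligible.
    reps, seed
        Number of replicates; replicate generators are spawned from the
        master seed via a counter so each replicate is reproducible.

    Returns a per-replicate table (replicate, k, m, n_sites, r). Sites that
    are monomorphic (zero variance) in a replicate's small or large sample
    are dropped from that replicate's correlation.
    """
    dosage = np.asarray(dosage)
    labels = np.asarray(pop_labels)
    n_ind = dosage.shape[0]
    if mixture is None and k is None:
        raise ValueError("provide k or a MixtureSpec for the small sample")
    rows = []
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        if mixture is not None:
            small = compose_mixture_sample(labels, mixture, rng)
        else:
            pool = np.arange(n_ind) if small_pop is None else np.nonzero(labels == small_pop)[0]
            if k > pool.size:
                raise ValueError(f"small sample size {k} exceeds population size {pool.size}")
            small = rng.choice(pool, size=k, replace=False)
        large_pool = (
            np.arange(n_ind)
            if large_pops is None
            else np.nonzero(np.isin(labels, list(large_pops)))[0]
        )
        if not allow_overlap:
            large_pool = np.setdiff1d(large_pool, small)
        if m is not None:
            if m > large_pool.size:
                raise ValueError(f"large sample size {m} exceeds pool size {large_pool.size}")
            large = rng.choice(large_pool, size=m, replace=False)
        else:
            large = large_pool
        f_small = _frequencies(dosage, np.sort(small))
        f_large = _frequencies(dosage, np.sort(large))
        keep = ~np.isnan(f_small) & ~np.isnan(f_large)
        fs, fl = f_small[keep], f_large[keep]
        informative = (np.ptp(fs) > 0) & (np.ptp(fl) > 0)
        if keep.sum() >= 3 and informative:
            r = float(sps.pearsonr(fs, fl)[0])
        else:
            r = np.nan
        rows.append(
            {
                "replicate": rep,
                "k": int(small.size),
                "m": int(large.size),
                "n_sites": int(keep.sum()),
                "r": r,
            }
        )
    return pd.DataFrame(rows)


def summarize_correlations(per_replicate: pd.DataFrame) -> dict:
    r = per_replicate["r"].dropna()
    return {
        "reps": int(len(per_replicate)),
        "mean_r": float(r.mean()) if len(r) else float("nan"),
        "sd_r": float(r.std(ddof=1)) if len(r) > 1 else float("nan"),
    }
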