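"""Allele-frequency differentiation scan statistics.

The scan asks, per site and per continental reference panel, whether a tiny
cohort's alternate-allele count is extreme under a binomial null whose
success probability is the panel frequency. Two one-tailed exact tests are
used (one for higher, one for lower frequency), multiple testing is handled
with Storey q-values per continent (and per direction, by default), and a
Weir–Cockerham Fst threshold guards against panel-frequency sampling noise.
A site is called enriched against a continent when Fst > 0.25 and the
relevant q-value < 0.05 (both strict), and "enriched" overall when that
holds for at least one continent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import PanelFrequencyTable

Direction = Literal["higher", "lower"]

NOT_ENRICHED = "not_enriched"
ENRICHED_HIGHER = "enriched_higher"
ENRICHED_LOWER = "enriched_lower"


# ---------------------------------------------------------------------------
# Exact one-tailed binomial test


def binomial_tail_p(x, n, p, direction: Direction, *, inclusive: bool = True):
    """Exact one-tailed binomial tail probability.

    ``direction="higher"`` gives P(X >= x) and ``"lower"`` gives P(X <= x)
    for X ~ Binomial(n, p); the observed count is included in the tail
    (set ``inclusive=False`` for the strict tails P(X > x) / P(X < x)).
    Arguments broadcast; scalars in give a float back. Degenerate nulls
    (p = 0 or 1) are handled exactly by the binomial pmf itself.
    """
    x = np.asarray(x)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    if np.any((x < 0) | (x > n)):
        raise ValueError("require 0 <= x <= n")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("require 0 <= p <= 1")
    if direction == "higher":
        out = sps.binom.sf(x - 1 if inclusive else x, n, p)
    elif direction == "lower":
        out = sps.binom.cdf(x if inclusive else x - 1, n, p)
    else:
        raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Fst estimators (two populations, allele-count parameterization)


def _wc_components(x1, n1, x2, n2):
    """Weir–Cockerham (1984) mean squares for two demes of sampled alleles.

    Returns (MSP, MSG, n_c): the among-population and within-population mean
    squares of the allele indicator, and the effective sample-size weight
    n_c = 2*n1*n2/(n1+n2).
    """
    x1 = np.asarray(x1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("each sample needs at least 2 alleles")
    p1, p2 = x1 / n1, x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # df = r - 1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - 2)
    nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
    return msp, msg, nc


def fst_two_populations(x1, n1, x2, n2):
    """Weir–Cockerham θ between two allele samples.

    Parameters are alternate-allele counts and total called alleles per
    sample. Returns ``(raw, clamped)``: the raw θ estimate, which can be
    negative (sampling noise around zero differentiation) or NaN when both
    samples are monomorphic for the same allele (0/0), and a thresholding
    value with negatives and NaN floored at 0. Scalars in, floats out.
    """
    msp, msg, nc = _wc_components(x1, n1, x2, n2)
    denom = msp + (nc - 1) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(denom == 0, np.nan, (msp - msg) / denom)
    clamped = np.where(np.isnan(raw), 0.0, np.maximum(raw, 0.0))
    if raw.ndim == 0:
        return float(raw), float(clamped)
    return raw, clamped


def fst_multilocus(x1, n1, x2, n2) -> float:
    """Multi-locus Weir–Cockerham θ: ratio of summed variance components.

    This is the standard genome-wide combination (sum numerators over loci,
    sum denominators) and is the estimator that recovers the generating
    divergence parameter of a Balding–Nichols model consistently; averaging
    per-locus θ values is biased downward.
    """
    msp, msg, nc = _wc_components(x1, n1, x2, n2)
    num = (msp - msg).sum()
    den = (msp + (nc - 1) * msg).sum()
    if den == 0:
        return 0.0
    return float(num / den)


def hudson_fst(x1, n1, x2, n2):
    """Hudson's Fst estimator (1 - Hw/Hb form) for cross-checks.

    Returns NaN where the between-population heterozygosity is zero.
    """
    x1 = np.asarray(x1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1, p2 = x1 / n1, x2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den == 0, np.nan, num / den)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Storey q-values


@dataclass
class QValueResult:
    qvalues: np.ndarray
    pi0: float
    method: str

    def __post_init__(self) -> None:
        self.qvalues = np.asarray(self.qvalues, dtype=float)


def _pi0_smoother(p: np.ndarray, lambdas: np.ndarray) -> float:
    """Storey's π0 estimate: fit a smooth (cubic) trend to π0(λ) and read it
    off at the largest λ, capped into (0, 1]."""
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if np.allclose(pi0_lambda, pi0_lambda[0]):
        fit_at_max = pi0_lambda[-1]
    else:
        coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
        fit_at_max = float(np.polyval(coeffs, lambdas[-1]))
    pi0 = min(1.0, fit_at_max)
    if pi0 <= 0.0:
        positive = pi0_lambda[pi0_lambda > 0]
        pi0 = float(positive.min()) if positive.size else 1.0
        pi0 = min(1.0, pi0)
    return pi0


def storey_qvalues(
    pvalues: Sequence[float] | np.ndarray,
    pi0_mode: Literal["fixed_1", "smoother"] = "smoother",
    lambdas: np.ndarray | None = None,
) -> QValueResult:
    """Storey q-values: q_(i) = min_{j >= i} π0 · m · p_(j) / j.

    With ``pi0_mode="fixed_1"`` the q-values coincide exactly with
    Benjamini–Hochberg adjusted p-values; ``"smoother"`` estimates the null
    proportion π0 on a λ grid (default 0.05..0.95 step 0.05) with a cubic
    trend evaluated at the largest λ.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0_mode == "fixed_1":
        pi0 = 1.0
    elif pi0_mode == "smoother":
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        pi0 = _pi0_smoother(p, np.asarray(lambdas, dtype=float))
    else:
        raise ValueError(f"unknown pi0_mode {pi0_mode!r}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return QValueResult(qvalues=q, pi0=pi0, method=f"storey_{pi0_mode}")


# ---------------------------------------------------------------------------
# Combined enrichment call


def classify_enrichment(
    fst,
    q_higher,
    q_lower,
    fst_threshold: float = 0.25,
    q_threshold: float = 0.05,
):
    """Combined call: enriched only when Fst and the directional q-value both
    pass their strict thresholds (Fst > 0.25, q < 0.05 by default)."""
    fst = np.asarray(fst, dtype=float)
    q_higher = np.asarray(q_higher, dtype=float)
    q_lower = np.asarray(q_lower, dtype=float)
    fst_ok = fst > fst_threshold
    hi = fst_ok & (q_higher < q_threshold)
    lo = fst_ok & (q_lower < q_threshold)
    if np.any(hi & lo):
        warnings.warn(
            "site passes both directions (degenerate null); calling enriched_higher",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.where(hi, ENRICHED_HIGHER, np.where(lo, ENRICHED_LOWER, NOT_ENRICHED))
    return str(out) if out.ndim == 0 else out


def scan_enrichment(
    x: np.ndarray,
    n: np.ndarray,
    panel: PanelFrequencyTable,
    *,
    fst_threshold: float = 0.25,
    q_threshold: float = 0.05,
    pi0_mode: Literal["fixed_1", "smoother"] = "fixed_1",
    inclusive_tails: bool = True,
    pool_directions: bool = False,
    estimator: Literal["weir_cockerham", "hudson"] = "weir_cockerham",
) -> tuple[pd.DataFrame, list[int]]:
    """Run the combined scan for every site against every continent.

    Parameters
    ----------
    x, n
        Cohort alternate-allele counts and called-allele counts, aligned to
        ``panel.sites``.
    pool_directions
        When True the higher- and lower-tail p-values of one continent form
        a single q-value family; the default keeps directions separate.

    Returns
    -------
    (table, novel)
        ``table`` has one row per site x continent with data, columns
        x, n, p_cont, n_cont, fst_raw, fst, p_higher, p_lower, q_higher,
        q_lower, call. ``novel`` lists indices of sites absent from every
        continent (excluded from testing, reported as a separate stratum).
    """
    x = np.asarray(x, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if x.shape != (panel.n_sites,) or n.shape != (panel.n_sites,):
        raise ValueError("x and n must align with the panel's sites")
    present = ~np.isnan(panel.freq)
    novel = [i for i in range(panel.n_sites) if not present[i].any()]
    testable = n > 0  # sites with every cohort call missing cannot be tested
    frames = []
    for c, cont in enumerate(panel.continents):
        mask = present[:, c] & testable
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        xc, nc = x[idx], n[idx]
        pc = panel.freq[idx, c]
        panel_n = panel.n_alleles[idx, c]
        panel_x = np.rint(pc * panel_n)
        if estimator == "weir_cockerham":
            fst_raw, fst_clamped = fst_two_populations(xc, nc, panel_x, panel_n)
        elif estimator == "hudson":
            fst_raw = hudson_fst(xc, nc, panel_x, panel_n)
            fst_clamped = np.where(np.isnan(fst_raw), 0.0, np.maximum(fst_raw, 0.0))
        else:
            raise ValueError(f"unknown Fst estimator {estimator!r}")
        p_hi = binomial_tail_p(xc, nc, pc, "higher", inclusive=inclusive_tails)
        p_lo = binomial_tail_p(xc, nc, pc, "lower", inclusive=inclusive_tails)
        if pool_directions:
            pooled = storey_qvalues(np.concatenate([p_hi, p_lo]), pi0_mode)
            q_hi = pooled.qvalues[: idx.size]
            q_lo = pooled.qvalues[idx.size :]
        else:
            q_hi = storey_qvalues(p_hi, pi0_mode).qvalues
            q_lo = storey_qvalues(p_lo, pi0_mode).qvalues
        call = classify_enrichment(fst_clamped, q_hi, q_lo, fst_threshold, q_threshold)
        frames.append(
            pd.DataFrame(
                {
                    "site_index": idx,
                    "chrom": [panel.sites[i].chrom for i in idx],
                    "pos": [panel.sites[i].pos for i in idx],
                    "ref": [panel.sites[i].ref for i in idx],
                    "alt": [panel.sites[i].alt for i in idx],
                    "rsid": [panel.sites[i].rsid or "" for i in idx],
                    "continent": cont,
                    "x": xc,
                    "n": nc,
                    "p_cont": pc,
                    "n_cont": panel_n,
                    "fst_raw": fst_raw,
                    "fst": fst_clamped,
                    "p_higher": p_hi,
                    "p_lower": p_lo,
                    "q_higher": q_hi,
                    "q_lower": q_lo,
                    "call": call,
                }
            )
        )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "site_index", "chrom", "pos", "ref", "alt", "rsid", "continent",
                "x", "n", "p_cont", "n_cont", "fst_raw", "fst",
                "p_higher", "p_lower", "q_higher", "q_lower", "call",
            ]
        )
    )
    return table, novel


# ---------------------------------------------------------------------------
# Summaries


def summarize_enrichment(
    table: pd.DataFrame,
    tiers: dict[int, int] | None = None,
    deleterious: dict[int, bool] | None = None,
) -> dict:
    """Aggregate a scan table into the headline counts.

    Returns per-continent enriched counts, the union count over continents,
    counts by how many continents a site is enriched against (1-4+),
    higher-vs-all / lower-vs-all counts, and (when ``tiers`` /
    ``deleterious`` maps from site index are given) a cross-tab of enriched
    sites by deleterious flag and health tier.
    """
    if table.empty:
        return {
            "per_continent": {},
            "union": 0,
            "by_n_continents": {},
            "higher_vs_all": 0,
            "lower_vs_all": 0,
            "crosstab": {},
        }
    enriched = table[table["call"] != NOT_ENRICHED]
    continents = sorted(table["continent"].unique())
    per_continent = {
        c: int((enriched["continent"] == c).sum()) for c in continents
    }
    by_site = enriched.groupby("site_index")["call"]
    n_conts = by_site.size()
    by_n = {int(k): int(v) for k, v in n_conts.value_counts().sort_index().items()}
    union = int(n_conts.size)
    n_tested_per_site = table.groupby("site_index").size()
    all_cont = len(continents)
    higher_vs_all = lower_vs_all = 0
    for site_idx, calls in by_site:
        if n_tested_per_site[site_idx] == all_cont and len(calls) == all_cont:
            if (calls == ENRICHED_HIGHER).all():
                higher_vs_all += 1
            elif (calls == ENRICHED_LOWER).all():
                lower_vs_all += 1
    crosstab: dict[str, int] = {}
    if tiers is not None or deleterious is not None:
        for site_idx in n_conts.index:
            d = bool(deleterious.get(int(site_idx), False)) if deleterious else False
            t = tiers.get(int(site_idx)) if tiers else None
            key = f"deleterious={d},tier={t}"
            crosstab[key] = crosstab.get(key, 0) + 1
    return {
        "per_continent": per_continent,
        "union": union,
        "by_n_continents": by_n,
        "higher_vs_all": higher_vs_all,
        "lower_vs_all": lower_vs_all,
        "crosstab": crosstab,
    }
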