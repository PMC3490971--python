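"""Balding–Nichols synthetic data with known truth.

The generator emulates the study design the scan is built for: four
continental reference panels of realistic sizes, and a tiny admixed cohort
(default 7 individuals in three subgroups of 3/2/2, each tracing most of its
ancestry to one continental source). Per site an ancestral frequency p0 is
drawn uniformly inside configurable bounds, each population's frequency
follows the Balding–Nichols model

    p_pop ~ Beta(p0 (1-F)/F, (1-p0) (1-F)/F),

whose expected Fst to the ancestral population is F, and diploid genotypes
are binomial draws from the population frequency. Cohort subgroups diverge
from their source panel by a second, smaller F. Spiked sites displace the
cohort-source frequency from the panel frequency by a known amount, giving
ground truth for power and false-discovery calibration; annotation and
health-database fixtures make the functional-triage stage testable end to
end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import HealthDatabase
from .genotype_io import (
    MISSING,
    CohortGenotypes,
    PanelFrequencyTable,
    VariantSite,
    write_cohort_vcf,
    write_panel_frequencies,
)

_BASES = np.array(list("ACGT"))
_RESIDUES = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()


@dataclass(frozen=True)
class PopulationSpec:
    """A reference panel: label, diploid sample size, divergence from the
    ancestral population."""

    label: str
    n_individuals: int
    F: float

    def __post_init__(self) -> None:
        if not 0 < self.F < 1:
            raise ValueError(f"F must be in (0,1), got {self.F}")
        if self.n_individuals < 1:
            raise ValueError("population needs at least one individual")


@dataclass(frozen=True)
class SubgroupSpec:
    """A cohort subgroup: size, source panel, extra divergence from it.

    ``F=0`` makes the subgroup's frequencies equal the source panel's true
    frequencies (the null-calibration configuration).
    """

    label: str
    n_individuals: int
    source: str
    F: float = 0.02

    def __post_init__(self) -> None:
        if not 0 <= self.F < 1:
            raise ValueError(f"subgroup F must be in [0,1), got {self.F}")
        if self.n_individuals < 1:
            raise ValueError("subgroup needs at least one individual")


@dataclass(frozen=True)
class SpikeSpec:
    """Known differentiated sites: how many, how far, which direction."""

    count: int
    displacement: float
    direction: str = "higher"  # higher | lower | both

    def __post_init__(self) -> None:
        if self.direction not in ("higher", "lower", "both"):
            raise ValueError(f"unknown spike direction {self.direction!r}")
        if self.count < 0:
            raise ValueError("spike count must be >= 0")


# Defaults mirror the study design: reference-project-scale continental panels of
# 379/296/185/242 individuals and a 7-individual cohort split 3/2/2 across
# three ancestry subgroups.
DEFAULT_PANELS = (
    PopulationSpec("EUR", 379, 0.08),
    PopulationSpec("ASN", 296, 0.10),
    PopulationSpec("AFR", 185, 0.12),
    PopulationSpec("AMR", 242, 0.08),
)
DEFAULT_SUBGROUPS = (
    SubgroupSpec("Q1", 3, "EUR", 0.02),
    SubgroupSpec("Q2", 2, "ASN", 0.02),
    SubgroupSpec("Q3", 2, "AFR", 0.02),
)


@dataclass(frozen=True)
class SimulationConfig:
    n_sites: int = 2000
    panels: tuple[PopulationSpec, ...] = DEFAULT_PANELS
    subgroups: tuple[SubgroupSpec, ...] = DEFAULT_SUBGROUPS
    ancestral_bounds: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.02
    category_proportions: tuple[tuple[str, float], ...] = (
        ("noncoding", 0.50),
        ("silent", 0.15),
        ("missense", 0.30),
        ("splice", 0.035),
        ("nonsense", 0.015),
    )
    deleterious_fraction: float = 0.52  # of missense sites
    tier_proportions: tuple[float, float, float] = (0.72, 0.24, 0.04)
    spike: SpikeSpec | None = None
    panel_genotypes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_bounds
        if not 0 < lo < hi < 1:
            raise ValueError("ancestral bounds must satisfy 0 < lo < hi < 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        if not 0 <= self.deleterious_fraction <= 1:
            raise ValueError("deleterious_fraction must be in [0,1]")
        if abs(sum(p for _, p in self.category_proportions) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if sum(self.tier_proportions) > 1.0 + 1e-9:
            raise ValueError("tier proportions must sum to <= 1")
        labels = {p.label for p in self.panels}
        for sg in self.subgroups:
            if sg.source not in labels:
                raise ValueError(f"subgroup {sg.label} sources unknown panel {sg.source!r}")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    sites: list[VariantSite]
    cohort: CohortGenotypes
    panel_table: PanelFrequencyTable
    truth: pd.DataFrame
    panel_dosage: dict[str, np.ndarray] | None = None  # per-individual panels

    def write(self, directory: str | Path) -> None:
        """Write cohort VCF, panel table and truth JSON under a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_cohort_vcf(self.cohort, directory / "cohort.vcf")
        write_panel_frequencies(self.panel_table, directory / "panel_frequencies.tsv")
        truth = self.truth.copy()
        (directory / "truth.json").write_text(
            json.dumps(
                {
                    "seed": self.config.seed,
                    "n_sites": self.config.n_sites,
                    "sites": truth.to_dict(orient="list"),
                },
                default=float,
            )
        )


def _bn_frequencies(rng: np.random.Generator, p0: np.ndarray, F: float) -> np.ndarray:
    """Balding–Nichols draw; F=0 returns p0 unchanged."""
    if F == 0:
        return p0.copy()
    scale = (1.0 - F) / F
    freq = rng.beta(p0 * scale, (1.0 - p0) * scale)
    # guard against numerical underflow to exactly 0/1 so downstream Beta
    # parameters stay valid
    return np.clip(freq, 1e-12, 1.0 - 1e-12)


def _make_sites(rng: np.random.Generator, n_sites: int) -> list[VariantSite]:
    chroms = (np.arange(n_sites) % 22) + 1
    pos = 1000 + 100 * (np.arange(n_sites) // 22)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    return [
        VariantSite(
            str(chroms[i]),
            int(pos[i]),
            str(_BASES[ref_idx[i]]),
            str(_BASES[alt_idx[i]]),
            rsid=f"rs{9000000 + i}",
        )
        for i in range(n_sites)
    ]


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Simulate panels, cohort and truth under the Balding–Nichols model.

    Everything is reproducible from ``cfg.seed``: separate child generators
    drive sites, panel frequencies, genotypes, missingness and spiking, so
    toggling one feature does not shift another's stream.
    """
    root = np.random.SeedSequence(cfg.seed)
    kids = root.spawn(6)
    rng_sites = np.random.default_rng(kids[0])
    rng_freq = np.random.default_rng(kids[1])
    rng_panel = np.random.default_rng(kids[2])
    rng_cohort = np.random.default_rng(kids[3])
    rng_missing = np.random.default_rng(kids[4])

    sites = _make_sites(rng_sites, cfg.n_sites)
    lo, hi = cfg.ancestral_bounds
    p0 = rng_freq.uniform(lo, hi, size=cfg.n_sites)

    pop_freq: dict[str, np.ndarray] = {}
    panel_freq = np.empty((cfg.n_sites, len(cfg.panels)))
    panel_n = np.empty((cfg.n_sites, len(cfg.panels)), dtype=np.int64)
    panel_dosage: dict[str, np.ndarray] | None = {} if cfg.panel_genotypes else None
    for c, pop in enumerate(cfg.panels):
        freq = _bn_frequencies(rng_freq, p0, pop.F)
        pop_freq[pop.label] = freq
        n_alleles = 2 * pop.n_individuals
        if cfg.panel_genotypes:
            dosage = rng_panel.binomial(2, freq, size=(pop.n_individuals, cfg.n_sites))
            panel_dosage[pop.label] = dosage.astype(np.int8)
            x = dosage.sum(axis=0)
        else:
            x = rng_panel.binomial(n_alleles, freq)
        panel_freq[:, c] = x / n_alleles
        panel_n[:, c] = n_alleles

    # cohort subgroup source frequencies (possibly further diverged)
    subgroup_freq = {
        sg.label: _bn_frequencies(rng_freq, pop_freq[sg.source], sg.F)
        for sg in cfg.subgroups
    }

    truth = pd.DataFrame(
        {
            "p0": p0,
            **{f"freq_{pop.label}": pop_freq[pop.label] for pop in cfg.panels},
            **{f"freq_{sg.label}": subgroup_freq[sg.label] for sg in cfg.subgroups},
            "spiked": np.zeros(cfg.n_sites, dtype=bool),
            "spike_target": np.full(cfg.n_sites, np.nan),
        }
    )

    samples, calls = _draw_cohort(cfg, subgroup_freq, rng_cohort, rng_missing)
    ds = SyntheticDataset(
        config=cfg,
        sites=sites,
        cohort=CohortGenotypes(samples=samples, sites=sites, calls=calls),
        panel_table=PanelFrequencyTable(
            continents=[p.label for p in cfg.panels],
            sites=sites,
            freq=panel_freq,
            n_alleles=panel_n,
        ),
        truth=truth,
        panel_dosage=panel_dosage,
    )
    if cfg.spike is not None and cfg.spike.count > 0:
        ds = spike_differentiated_sites(ds, cfg.spike, seed_sequence=kids[5])
    return ds


def _draw_cohort(
    cfg: SimulationConfig,
    subgroup_freq: dict[str, np.ndarray],
    rng: np.random.Generator,
    rng_missing: np.random.Generator,
) -> tuple[list[str], np.ndarray]:
    calls = []
    samples = []
    for sg in cfg.subgroups:
        f = subgroup_freq[sg.label]
        for i in range(sg.n_individuals):
            samples.append(f"{sg.label}_{i + 1}")
            calls.append(rng.binomial(2, f).astype(np.int8))
    mat = np.vstack(calls)
    if cfg.missing_rate > 0:
        mask = rng_missing.random(mat.shape) < cfg.missing_rate
        mat[mask] = MISSING
    return samples, mat


def spike_differentiated_sites(
    ds: SyntheticDataset,
    spec: SpikeSpec,
    seed: int | None = None,
    seed_sequence: np.random.SeedSequence | None = None,
) -> SyntheticDataset:
    """Displace the cohort-source frequency at chosen sites by a known amount.

    The target frequency is the site's mean panel frequency plus (or minus)
    ``spec.displacement``, clipped to [0.02, 0.98]; every subgroup is moved
    to the target and the cohort genotypes at those sites are redrawn (with
    the configured missingness). A displacement of 0 only labels the sites.
    Returns a new dataset; the input is not modified.
    """
    if spec.count > ds.config.n_sites:
        raise ValueError("cannot spike more sites than exist")
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(
            ds.config.seed if seed is None else seed, spawn_key=(97,)
        )
    rng = np.random.default_rng(seed_sequence)
    idx = rng.choice(ds.config.n_sites, size=spec.count, replace=False)
    truth = ds.truth.copy()
    calls = ds.cohort.calls.copy()
    panel_mean = np.nanmean(ds.panel_table.freq[idx], axis=1)
    if spec.direction == "higher":
        sign = np.ones(spec.count)
    elif spec.direction == "lower":
        sign = -np.ones(spec.count)
    else:
        sign = rng.choice([-1.0, 1.0], size=spec.count)
    target = np.clip(panel_mean + sign * spec.displacement, 0.02, 0.98)
    truth.loc[idx, "spiked"] = True
    truth.loc[idx, "spike_target"] = target
    if spec.displacement != 0:
        for sg in ds.config.subgroups:
            truth.loc[idx, f"freq_{sg.label}"] = target
        new_calls = rng.binomial(2, target, size=(ds.cohort.n_samples, spec.count))
        if ds.config.missing_rate > 0:
            miss = rng.random(new_calls.shape) < ds.config.missing_rate
            new_calls = np.where(miss, MISSING, new_calls)
        calls[:, idx] = new_calls.astype(np.int8)
    cohort = CohortGenotypes(samples=list(ds.cohort.samples), sites=ds.sites, calls=calls)
    return SyntheticDataset(
        config=ds.config,
        sites=ds.sites,
        cohort=cohort,
        panel_table=ds.panel_table,
        truth=truth,
        panel_dosage=ds.panel_dosage,
    )


# ---------------------------------------------------------------------------
# Annotation and health-database fixtures


def simulate_annotation_and_healthdb(
    ds: SyntheticDataset, seed: int | None = None
) -> tuple[pd.DataFrame, HealthDatabase, pd.DataFrame]:
    """Synthesize an annotation table and health database with known tiers.

    Categories follow the configured proportions; each missense site is
    deleterious with probability ``deleterious_fraction``, with predictor
    labels drawn so the union rule (SIFT deleterious OR PolyPhen2 damaging)
    holds by construction; deleterious missense sites get a tier from the
    configured proportions, realised through rsID records, gene+substitution
    records (alternating, so both tier-3 query paths are exercised) or
    gene-only records. Every site gets its own synthetic gene so gene-level
    records never leak across sites.

    Returns ``(annotation_table, health_db, truth)`` where truth adds
    category / deleterious / tier columns to the dataset's truth table.
    """
    cfg = ds.config
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed if seed is None else seed, spawn_key=(131,))
    )
    n = cfg.n_sites
    cats = [c for c, _ in cfg.category_proportions]
    probs = np.array([p for _, p in cfg.category_proportions])
    category = rng.choice(cats, size=n, p=probs / probs.sum())
    deleterious = np.zeros(n, dtype=bool)
    mis = category == "missense"
    deleterious[mis] = rng.random(mis.sum()) < cfg.deleterious_fraction
    tier = np.zeros(n, dtype=int)
    t1, t2, t3 = cfg.tier_proportions
    total = t1 + t2 + t3
    dele_idx = np.nonzero(deleterious)[0]
    tier[dele_idx] = rng.choice([1, 2, 3], size=dele_idx.size, p=[t1 / total, t2 / total, t3 / total])

    db = HealthDatabase()
    rows = []
    tier3_toggle = 0
    for i, site in enumerate(ds.sites):
        gene = f"GENE{i:05d}"
        cat = str(category[i])
        substitution = None
        if cat == "missense":
            a, b = rng.choice(len(_RESIDUES), size=2, replace=False)
            substitution = f"{_RESIDUES[a]}{int(rng.integers(2, 900))}{_RESIDUES[b]}"
        if deleterious[i]:
            mode = rng.integers(0, 3)  # which predictor(s) fire
            sift = "deleterious" if mode in (0, 2) else "tolerated"
            polyphen = (
                str(rng.choice(["probably_damaging", "possibly_damaging"]))
                if mode in (1, 2)
                else "benign"
            )
        elif cat == "missense":
            sift, polyphen = "tolerated", "benign"
        else:
            sift, polyphen = "absent", "absent"
        if tier[i] == 3:
            if tier3_toggle % 2 == 0:
                db.snp_records[site.rsid] = ("OMIM", "synthetic phenotype")
            else:
                db.substitution_records[(gene, substitution)] = ("HGMD", "synthetic phenotype")
            db.gene_records[gene] = ("OMIM", "synthetic phenotype")
            tier3_toggle += 1
        elif tier[i] == 2:
            db.gene_records[gene] = ("PharmGKB", "synthetic phenotype")
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "gene": gene,
                "category": cat,
                "substitution": substitution or "",
                "sift_label": sift,
                "polyphen_label": polyphen,
            }
        )
    annotation = pd.DataFrame(rows)
    truth = ds.truth.copy()
    truth["category"] = category
    truth["deleterious"] = deleterious
    truth["tier"] = np.where(tier > 0, tier, np.nan)
    return annotation, db, truth
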