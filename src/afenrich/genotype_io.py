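"""Cohort genotype and panel-frequency I/O plus basic allele accounting.

Genotypes are stored as alternate-allele dosages in an int8 matrix of shape
(n_samples, n_sites): 0 = ref/ref, 1 = ref/alt, 2 = alt/alt, -1 = missing.
Half-called diploid genotypes (e.g. "0/.") are treated as fully missing so
that allele denominators always count whole diploid genotypes (2 alleles per
successfully typed sample). Coordinates are 1-based as in VCF and a site is
keyed by (chrom, pos, ref, alt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
_BASES = frozenset("ACGT")

SiteKey = tuple[str, int, str, str]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted as a biallelic SNP."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP on the reference assembly (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CohortGenotypes:
    """Diploid genotype calls for a cohort at biallelic SNP sites."""

    samples: list[str]
    sites: list[VariantSite]
    calls: np.ndarray  # int8, (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.samples) < 1:
            raise ValueError("cohort must contain at least one sample")
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self) -> dict[SiteKey, int]:
        return {s.key: i for i, s in enumerate(self.sites)}


@dataclass(frozen=True)
class AlleleStats:
    """Alternate-allele count over successfully genotyped alleles at one site.

    ``freq`` is NaN when every call is missing (undefined, distinct from 0).
    Failed genotypes are excluded from the denominator, so ``n_called`` is
    twice the number of non-missing diploid calls.
    """

    x: int
    n_called: int

    def __post_init__(self) -> None:
        if not 0 <= self.x <= max(self.n_called, 0):
            raise ValueError(f"alt count {self.x} outside [0, {self.n_called}]")

    @property
    def freq(self) -> float:
        if self.n_called == 0:
            return math.nan
        return self.x / self.n_called

    @property
    def display_freq(self) -> str:
        """Frequency rounded half-up to two decimals, as printed in reports."""
        if self.n_called == 0:
            return "NA"
        return f"{round_half_up(self.freq, 2):.2f}"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), unlike banker's rounding."""
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def cohort_allele_stats(g: CohortGenotypes, site: int) -> AlleleStats:
    """Alternate-allele count and missing-aware denominator at one site."""
    if not 0 <= site < g.n_sites:
        raise IndexError(f"site index {site} out of range for {g.n_sites} sites")
    col = g.calls[:, site]
    called = col != MISSING
    return AlleleStats(x=int(col[called].sum()), n_called=2 * int(called.sum()))


def all_allele_stats(g: CohortGenotypes) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised alt counts and called-allele counts for every site."""
    missing = g.calls == MISSING
    x = np.where(missing, 0, g.calls).sum(axis=0)
    n = 2 * (~missing).sum(axis=0)
    return x.astype(np.int64), n.astype(np.int64)


# ---------------------------------------------------------------------------
# VCF input / output


def _dosages_from_record(rec) -> np.ndarray:
    """Alt dosage per sample; any half-missing diploid call becomes missing
    (cyvcf2's gt_types would silently keep the called allele)."""
    out = np.empty(len(rec.genotypes), dtype=np.int8)
    for i, call in enumerate(rec.genotypes):
        alleles = call[:-1]  # last element is the phased flag
        if len(alleles) != 2 or any(a < 0 for a in alleles):
            out[i] = MISSING
        else:
            out[i] = alleles[0] + alleles[1]
    return out


def read_cohort_vcf(path: str | Path, multiallelic: str = "reject") -> CohortGenotypes:
    """Read diploid biallelic autosomal SNP genotypes from a VCF.

    Parameters
    ----------
    path
        VCF 4.x file with GT fields (plain text or bgzipped).
    multiallelic
        ``"reject"`` drops multi-allelic records (counted), ``"strict"``
        raises on any non-biallelic-SNP record.

    Half-missing diploid calls are mapped to missing; X/Y records are
    excluded, matching an autosomal analysis.
    """
    if multiallelic not in ("reject", "strict"):
        raise ValueError(f"unknown multiallelic mode {multiallelic!r}")
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"{path}: VCF has no sample columns")
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    n_rejected = 0
    for rec in vcf:
        chrom = rec.CHROM.removeprefix("chr")
        if chrom in ("X", "Y", "MT", "M"):
            continue
        snp = (
            len(rec.ALT) == 1
            and len(rec.REF) == 1
            and len(rec.ALT[0]) == 1
            and rec.REF in _BASES
            and rec.ALT[0] in _BASES
        )
        if not snp:
            if multiallelic == "strict":
                raise VcfParseError(
                    f"{path}: non-biallelic-SNP record at {rec.CHROM}:{rec.POS}"
                )
            n_rejected += 1
            continue
        rsid = rec.ID if rec.ID not in (None, ".") else None
        sites.append(VariantSite(chrom, rec.POS, rec.REF, rec.ALT[0], rsid))
        rows.append(_dosages_from_record(rec))
    cohort = CohortGenotypes(
        samples=samples,
        sites=sites,
        calls=np.column_stack(rows) if rows else np.empty((len(samples), 0), np.int8),
    )
    cohort.n_rejected_records = n_rejected  # type: ignore[attr-defined]
    return cohort


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_cohort_vcf(g: CohortGenotypes, path: str | Path) -> None:
    """Write the cohort as a minimal VCF 4.2 file (GT only)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen: dict[str, None] = {}
        for site in g.sites:
            seen.setdefault(site.chrom, None)
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, site in enumerate(g.sites):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.rsid or '.'}\t{site.ref}\t"
                f"{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Genotype concordance


@dataclass(frozen=True)
class ConcordanceReport:
    """Discordance between two call sets over shared, both-called cells."""

    n_compared: int
    n_discordant: int

    @property
    def discordance(self) -> float:
        if self.n_compared == 0:
            return math.nan
        return self.n_discordant / self.n_compared


def genotype_concordance(a: CohortGenotypes, b: CohortGenotypes) -> ConcordanceReport:
    """Compare two genotype call sets over their shared samples and sites.

    Comparison is on unordered diploid genotypes (dosage), so allele order
    within a call never counts as a difference; cells missing in either set
    are excluded.
    """
    shared_samples = [s for s in a.samples if s in set(b.samples)]
    idx_a = a.site_index()
    idx_b = b.site_index()
    shared_keys = [k for k in idx_a if k in idx_b]
    if not shared_samples or not shared_keys:
        raise ValueError("call sets share no samples or no sites")
    ai = [a.samples.index(s) for s in shared_samples]
    bi = [b.samples.index(s) for s in shared_samples]
    aj = [idx_a[k] for k in shared_keys]
    bj = [idx_b[k] for k in shared_keys]
    sub_a = a.calls[np.ix_(ai, aj)]
    sub_b = b.calls[np.ix_(bi, bj)]
    both = (sub_a != MISSING) & (sub_b != MISSING)
    n_compared = int(both.sum())
    n_discordant = int(((sub_a != sub_b) & both).sum())
    return ConcordanceReport(n_compared=n_compared, n_discordant=n_discordant)


# ---------------------------------------------------------------------------
# Panel frequency table


@dataclass
class PanelFrequencyTable:
    """Per-continent alternate-allele frequency and allele count per site.

    ``freq`` holds NaN where a continent has no data for a site — absent is
    distinct from frequency 0. ``n_alleles`` holds 0 at absent entries.
    """

    continents: list[str]
    sites: list[VariantSite]
    freq: np.ndarray  # float, (n_sites, n_continents), NaN = absent
    n_alleles: np.ndarray  # int, (n_sites, n_continents)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_alleles = np.asarray(self.n_alleles, dtype=np.int64)
        shape = (len(self.sites), len(self.continents))
        if self.freq.shape != shape or self.n_alleles.shape != shape:
            raise ValueError("frequency/count arrays do not match sites x continents")
        present = ~np.isnan(self.freq)
        if ((self.freq[present] < 0) | (self.freq[present] > 1)).any():
            raise ValueError("panel frequencies must lie in [0, 1]")
        if (self.n_alleles[present] <= 0).any():
            raise ValueError("panel allele counts must be positive where data present")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self) -> dict[SiteKey, int]:
        return {s.key: i for i, s in enumerate(self.sites)}

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {
            "chrom": [s.chrom for s in self.sites],
            "pos": [s.pos for s in self.sites],
            "ref": [s.ref for s in self.sites],
            "alt": [s.alt for s in self.sites],
            "rsid": [s.rsid or "" for s in self.sites],
        }
        for c, cont in enumerate(self.continents):
            data[f"{cont}_freq"] = self.freq[:, c]
            data[f"{cont}_n"] = self.n_alleles[:, c]
        return pd.DataFrame(data)


def read_panel_frequencies(path: str | Path) -> PanelFrequencyTable:
    """Read a tab-separated panel frequency table.

    Expected columns: ``chrom pos ref alt [rsid]`` then ``<CONT>_freq`` and
    ``<CONT>_n`` per continent. Empty frequency cells mean the continent has
    no data for that site (absent, not zero).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    continents = [c[:-5] for c in df.columns if c.endswith("_freq")]
    if not continents:
        raise ValueError(f"{path}: no <CONT>_freq columns found")
    sites = [
        VariantSite(
            str(r.chrom),
            int(r.pos),
            str(r.ref),
            str(r.alt),
            (str(r.rsid) if "rsid" in df.columns and pd.notna(r.rsid) and str(r.rsid) else None),
        )
        for r in df.itertuples()
    ]
    freq = df[[f"{c}_freq" for c in continents]].to_numpy(dtype=float)
    n = df[[f"{c}_n" for c in continents]].fillna(0).to_numpy(dtype=np.int64)
    bad = np.asarray(~np.isnan(freq) & ((freq < 0) | (freq > 1))).nonzero()
    if bad[0].size:
        i = int(bad[0][0])
        raise ValueError(
            f"{path}: frequency outside [0,1] at site {sites[i].key} "
            f"continent {continents[int(bad[1][0])]}"
        )
    n = np.where(np.isnan(freq), 0, n)
    return PanelFrequencyTable(continents=continents, sites=sites, freq=freq, n_alleles=n)


def write_panel_frequencies(table: PanelFrequencyTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, na_rep="")
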