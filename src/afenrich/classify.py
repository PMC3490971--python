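"""Functional triage: categories, deleteriousness union rule, health tiers.

A variant gets one functional category (the most severe across overlapping
transcripts), a "potentially deleterious" flag for missense variants flagged
by either of two protein-impact predictors (SIFT "deleterious" or PolyPhen2
"probably/possibly damaging" — the liberal union), and, when deleterious, a
health-linkage tier against a database of previously reported variants:

    tier 3 — this SNP (by rsID, or by gene + amino-acid substitution) was
             previously linked to a health phenotype;
    tier 2 — the gene was linked, but through a different SNP;
    tier 1 — neither the SNP nor its gene has a prior health link.

Tier 3 takes precedence over tier 2: a previously reported SNP is never also
counted as "gene only".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import AlleleStats, VariantSite, round_half_up

CATEGORIES = ("noncoding", "silent", "missense", "splice", "nonsense")
_SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}

SIFT_LABELS = ("deleterious", "tolerated", "absent")
POLYPHEN_LABELS = ("probably_damaging", "possibly_damaging", "benign", "absent")
_POLYPHEN_DAMAGING = ("probably_damaging", "possibly_damaging")


@dataclass(frozen=True)
class FunctionalAnnotation:
    """One transcript-level annotation of a site."""

    gene: str
    category: str
    substitution: str | None = None  # e.g. "Pro12Ala", present iff missense

    def __post_init__(self) -> None:
        if self.category not in _SEVERITY:
            raise ValueError(f"unknown functional category {self.category!r}")
        if (self.category == "missense") != (self.substitution is not None):
            raise ValueError("substitution label present iff category is missense")


@dataclass(frozen=True)
class DeleteriousnessPrediction:
    sift_label: str = "absent"
    polyphen_label: str = "absent"

    def __post_init__(self) -> None:
        if self.sift_label not in SIFT_LABELS:
            raise ValueError(f"unknown SIFT label {self.sift_label!r}")
        if self.polyphen_label not in POLYPHEN_LABELS:
            raise ValueError(f"unknown PolyPhen label {self.polyphen_label!r}")


def assign_functional_category(annotations: Sequence[FunctionalAnnotation | str]) -> str:
    """Most severe category across transcripts (nonsense > splice > missense
    > silent > noncoding)."""
    if not annotations:
        raise ValueError("at least one annotation required")
    cats = [a.category if isinstance(a, FunctionalAnnotation) else a for a in annotations]
    for c in cats:
        if c not in _SEVERITY:
            raise ValueError(f"unknown functional category {c!r}")
    return max(cats, key=_SEVERITY.__getitem__)


def is_potentially_deleterious(
    category: str, pred: DeleteriousnessPrediction, *, missense_only: bool = True
) -> bool:
    """Union rule: flagged by SIFT or by PolyPhen2 (probably/possibly damaging).

    Only missense variants are eligible by default; ``missense_only=False``
    extends eligibility to splice and nonsense variants.
    """
    if missense_only:
        eligible = category == "missense"
    else:
        eligible = category in ("missense", "splice", "nonsense")
    return eligible and (
        pred.sift_label == "deleterious" or pred.polyphen_label in _POLYPHEN_DAMAGING
    )


# ---------------------------------------------------------------------------
# Health-linkage database


def _norm(s: str) -> str:
    return s.strip().lower()


@dataclass
class HealthDatabase:
    """rsID-, substitution- and gene-level records of prior health links.

    Each record value is a ``(source, phenotype)`` pair, with source one of
    OMIM / HGMD / PharmGKB / HUGE. Substitution keys use three-letter residue
    codes ("Arg117His"); matching is case-insensitive.
    """

    snp_records: dict[str, tuple[str, str]] = field(default_factory=dict)
    substitution_records: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    gene_records: dict[str, tuple[str, str]] = field(default_factory=dict)

    def has_snp(self, rsid: str | None) -> bool:
        return rsid is not None and rsid in self.snp_records

    def has_substitution(self, gene: str, substitution: str | None) -> bool:
        if substitution is None:
            return False
        return (_norm(gene), _norm(substitution)) in {
            (_norm(g), _norm(s)) for g, s in self.substitution_records
        }

    def has_gene(self, gene: str) -> bool:
        return _norm(gene) in {_norm(g) for g in self.gene_records}

    @classmethod
    def from_dir(cls, directory: str | Path) -> "HealthDatabase":
        """Load snp.tsv / substitution.tsv / gene.tsv from a directory."""
        directory = Path(directory)
        db = cls()
        snp = pd.read_csv(directory / "snp.tsv", sep="\t", dtype=str)
        for r in snp.itertuples():
            db.snp_records[str(r.rsid)] = (str(r.source), str(r.phenotype))
        sub = pd.read_csv(directory / "substitution.tsv", sep="\t", dtype=str)
        for r in sub.itertuples():
            db.substitution_records[(str(r.gene), str(r.substitution))] = (
                str(r.source),
                str(r.phenotype),
            )
        gene = pd.read_csv(directory / "gene.tsv", sep="\t", dtype=str)
        for r in gene.itertuples():
            db.gene_records[str(r.gene)] = (str(r.source), str(r.phenotype))
        return db

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [(k, v[0], v[1]) for k, v in self.snp_records.items()],
            columns=["rsid", "source", "phenotype"],
        ).to_csv(directory / "snp.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(g, s, v[0], v[1]) for (g, s), v in self.substitution_records.items()],
            columns=["gene", "substitution", "source", "phenotype"],
        ).to_csv(directory / "substitution.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(g, v[0], v[1]) for g, v in self.gene_records.items()],
            columns=["gene", "source", "phenotype"],
        ).to_csv(directory / "gene.tsv", sep="\t", index=False)


def assign_health_tier(
    rsid: str | None,
    gene: str,
    substitution: str | None,
    db: HealthDatabase,
) -> int:
    """Three-tier health linkage for a deleterious missense variant."""
    if db.has_snp(rsid) or db.has_substitution(gene, substitution):
        return 3
    if db.has_gene(gene):
        return 2
    return 1


# ---------------------------------------------------------------------------
# Whole-cohort classification


@dataclass(frozen=True)
class ClassifiedVariant:
    site: VariantSite
    category: str
    deleterious: bool
    stats: AlleleStats
    gene: str | None = None
    substitution: str | None = None
    tier: int | None = None  # defined only for deleterious missense variants

    def __post_init__(self) -> None:
        if self.tier is not None and not (self.deleterious and self.category == "missense"):
            raise ValueError("tier is defined only for deleterious missense variants")
        if self.tier is not None and self.tier not in (1, 2, 3):
            raise ValueError(f"tier must be 1, 2 or 3, got {self.tier}")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """One row per (site, transcript): site key, gene, category, substitution,
    sift_label, polyphen_label."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt", "gene", "category", "sift_label", "polyphen_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {sorted(missing)}")
    return df


def classify_variants(
    cohort,
    annotations: pd.DataFrame,
    db: HealthDatabase,
    *,
    missense_only: bool = True,
) -> list[ClassifiedVariant]:
    """Classify every cohort site that carries at least one annotation row."""
    from .genotype_io import cohort_allele_stats

    by_key: dict[tuple, list[pd.Series]] = {}
    for _, row in annotations.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        by_key.setdefault(key, []).append(row)
    out: list[ClassifiedVariant] = []
    for j, site in enumerate(cohort.sites):
        rows = by_key.get(site.key)
        if not rows:
            continue
        category = assign_functional_category([str(r["category"]) for r in rows])
        # union across transcripts: any transcript's predictor may fire
        pred = DeleteriousnessPrediction(
            sift_label=(
                "deleterious"
                if any(str(r["sift_label"]) == "deleterious" for r in rows)
                else "absent"
            ),
            polyphen_label=(
                "probably_damaging"
                if any(str(r["polyphen_label"]) in _POLYPHEN_DAMAGING for r in rows)
                else "absent"
            ),
        )
        deleterious = is_potentially_deleterious(category, pred, missense_only=missense_only)
        mis = next((r for r in rows if str(r["category"]) == "missense"), rows[0])
        gene = str(mis["gene"])
        substitution = str(mis["substitution"]) if str(mis.get("substitution", "")) else None
        tier = (
            assign_health_tier(site.rsid, gene, substitution, db)
            if deleterious and category == "missense"
            else None
        )
        out.append(
            ClassifiedVariant(
                site=site,
                category=category,
                deleterious=deleterious,
                stats=cohort_allele_stats(cohort, j),
                gene=gene,
                substitution=substitution,
                tier=tier,
            )
        )
    return out


@dataclass
class ClassificationSummary:
    """Deleterious-variant counts per allele-count cutoff, split by tier."""

    thresholds: list[int]
    totals: dict[int, int]
    tier_counts: dict[int, dict[int, int]]  # threshold -> tier -> count

    def tier_percent(self, threshold: int, tier: int) -> float:
        """Tier share of the threshold total, full precision (NaN if empty)."""
        total = self.totals[threshold]
        if total == 0:
            return float("nan")
        return 100.0 * self.tier_counts[threshold][tier] / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.thresholds:
            total = self.totals[t]
            row: dict[str, object] = {"min_alt_count": t, "total": total}
            for tier in (1, 2, 3):
                n = self.tier_counts[t][tier]
                row[f"tier{tier}_n"] = n
                row[f"tier{tier}_pct"] = (
                    int(round_half_up(100.0 * n / total)) if total else 0
                )
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_classification(
    variants: Iterable[ClassifiedVariant],
    count_thresholds: Sequence[int] = (1, 6),
) -> ClassificationSummary:
    """Count deleterious variants with alt-allele count >= each cutoff, by tier."""
    thresholds = [int(t) for t in count_thresholds]
    if any(t < 1 for t in thresholds):
        raise ValueError("allele-count cutoffs must be integers >= 1")
    dele = [v for v in variants if v.deleterious and v.tier is not None]
    totals: dict[int, int] = {}
    tier_counts: dict[int, dict[int, int]] = {}
    for t in thresholds:
        hit = [v for v in dele if v.stats.x >= t]
        totals[t] = len(hit)
        tier_counts[t] = {k: sum(1 for v in hit if v.tier == k) for k in (1, 2, 3)}
    return ClassificationSummary(thresholds=thresholds, totals=totals, tier_counts=tier_counts)
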