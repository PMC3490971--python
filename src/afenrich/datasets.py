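"""Packaged validation fixtures: small published-style tables of health-linked
missense variants with small-cohort and larger-sample allele frequencies."""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.files("afenrich.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_taqman_validation() -> pd.DataFrame:
    """Ten health-linked deleterious missense SNPs with 7-exome (14-allele)
    frequencies, TaqMan frequencies from 86 individuals (172 alleles), and
    four continental panel frequencies."""
    return _read_tsv("taqman_validation.tsv")


def load_affymetrix_validation() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Array-validated examples: (tier-3 table, tier-2 table) with small-cohort
    and 149-individual (298-allele) frequencies."""
    return _read_tsv("affymetrix_tier3.tsv"), _read_tsv("affymetrix_tier2.tsv")


def load_classification_counts() -> dict:
    """Genome-wide deleterious-missense classification counts by allele-count
    cutoff and health tier."""
    with resources.files("afenrich.data").joinpath("classification_counts.json").open() as fh:
        return json.load(fh)
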