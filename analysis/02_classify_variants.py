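#!/usr/bin/env python
"""Functional triage of the synthetic cohort: assign categories, the
SIFT/PolyPhen2 union deleteriousness flag and health-linkage tiers, then
summarize deleterious variants at the >=1/14 and >=6/14 allele-count
cutoffs. Writes results/classification_summary.tsv and prints the tier
shares next to the published genome-wide ones for orientation.
"""

from pathlib import Path

from afenrich.classify import HealthDatabase, classify_variants, read_annotation_table, summarize_classification
from afenrich.datasets import load_classification_counts
from afenrich.genotype_io import read_cohort_vcf, round_half_up

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    syn = ROOT / "synthetic"
    cohort = read_cohort_vcf(syn / "cohort.vcf")
    variants = classify_variants(
        cohort, read_annotation_table(syn / "annotation.tsv"), HealthDatabase.from_dir(syn / "healthdb")
    )
    summary = summarize_classification(variants, (1, 6))
    frame = summary.to_frame()
    frame.to_csv(ROOT / "classification_summary.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))

    published = load_classification_counts()
    ge1 = published["by_min_alt_count"]["1"]
    share = 100.0 * ge1["total"] / published["total_deleterious_missense"]
    print(
        f"\npublished reference: {ge1['total']} of "
        f"{published['total_deleterious_missense']} deleterious sites observed "
        f">=1/14 ({round_half_up(share):.0f}%), tier split "
        f"{ge1['tier1']}/{ge1['tier2']}/{ge1['tier3']}"
    )
    for t in (1, 6):
        total = summary.totals[t]
        shares = [summary.tier_counts[t][k] for k in (1, 2, 3)]
        print(f"synthetic >= {t}/14: total {total}, tiers {shares}")


if __name__ == "__main__":
    main()
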