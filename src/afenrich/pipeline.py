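"""End-to-end orchestration: load or simulate inputs, classify, scan, report.

Outputs are tab-separated tables with a one-line metadata header (tool
version + config hash) plus a JSON run manifest recording the config, the
seed and per-stage counts, so a run is fully reproducible and every summary
number can be reconstructed from the per-site table (an internal consistency
check does exactly that at the end of each run).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .classify import (
    HealthDatabase,
    classify_variants,
    read_annotation_table,
    summarize_classification,
)
from .genotype_io import (
    all_allele_stats,
    read_cohort_vcf,
    read_panel_frequencies,
)
from .representativeness import CorrelationResult, pearson_with_inference
from .simulate import (
    PopulationSpec,
    SimulationConfig,
    SpikeSpec,
    SubgroupSpec,
    simulate_annotation_and_healthdb,
    simulate_dataset,
)
from .stats import NOT_ENRICHED, scan_enrichment, summarize_enrichment


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Either real inputs (vcf/panel/annotation/healthdb paths) or a
    simulation config; thresholds default to the published scan settings."""

    outdir: Path
    vcf: Path | None = None
    panel: Path | None = None
    annotation: Path | None = None
    healthdb: Path | None = None
    simulate: SimulationConfig | None = None
    fst_threshold: float = 0.25
    fdr_threshold: float = 0.05
    count_thresholds: tuple[int, ...] = (1, 6)
    pi0_mode: str = "fixed_1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        real = all(p is not None for p in (self.vcf, self.panel, self.annotation, self.healthdb))
        some_real = any(p is not None for p in (self.vcf, self.panel, self.annotation, self.healthdb))
        if self.simulate is not None and some_real:
            raise ValueError("configure exactly one of real inputs or simulate mode")
        if self.simulate is None and not real:
            raise ValueError("real mode requires vcf, panel, annotation and healthdb paths")
        # thresholds are strict (>fst, <q); values below 0 / above 1 make the
        # respective filter vacuous, which is occasionally useful
        if not -1 <= self.fst_threshold <= 1:
            raise ValueError("fst threshold must lie in [-1,1]")
        if self.fdr_threshold <= 0:
            raise ValueError("fdr threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = None
        if "simulate" in raw:
            s = dict(raw.pop("simulate"))
            if "panels" in s:
                s["panels"] = tuple(PopulationSpec(**p) for p in s["panels"])
            if "subgroups" in s:
                s["subgroups"] = tuple(SubgroupSpec(**p) for p in s["subgroups"])
            if "spike" in s and s["spike"] is not None:
                s["spike"] = SpikeSpec(**s["spike"])
            for key in ("ancestral_bounds", "tier_proportions"):
                if key in s:
                    s[key] = tuple(s[key])
            if "category_proportions" in s:
                s["category_proportions"] = tuple(
                    (str(k), float(v)) for k, v in s["category_proportions"]
                )
            sim = SimulationConfig(**s)
        for key in ("vcf", "panel", "annotation", "healthdb", "outdir"):
            if key in raw and raw[key] is not None:
                raw[key] = Path(raw[key])
        if "count_thresholds" in raw:
            raw["count_thresholds"] = tuple(raw["count_thresholds"])
        return cls(simulate=sim, **raw)

    def config_hash(self) -> str:
        def default(o: Any):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            raise TypeError(type(o))

        fields = dataclasses.asdict(self)
        fields.pop("outdir")  # where results land is not part of the analysis
        payload = json.dumps(fields, default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, meta: str) -> None:
    with path.open("w") as fh:
        fh.write(f"# {meta}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_enrichment_pipeline(cfg: PipelineConfig) -> dict:
    """Run classify + scan and write the report files.

    Writes classification_summary.tsv, enrichment_per_site.tsv,
    enrichment_summary.json, enriched_by_tier.tsv and manifest.json under
    ``cfg.outdir``. Returns the manifest dict (whose ``empty`` flag is true
    when no site survived filtering). On error, partial outputs are removed.
    """
    from . import __version__

    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    meta = f"afenrich v{__version__} config={cfg.config_hash()}"
    written: list[Path] = []
    counts: dict[str, int] = {}
    try:
        # ---- stage: load ---------------------------------------------------
        try:
            if cfg.simulate is not None:
                ds = simulate_dataset(cfg.simulate)
                cohort = ds.cohort
                panel = ds.panel_table
                annotation, db, _truth = simulate_annotation_and_healthdb(ds)
            else:
                cohort = read_cohort_vcf(cfg.vcf)
                panel = read_panel_frequencies(cfg.panel)
                annotation = read_annotation_table(cfg.annotation)
                db = HealthDatabase.from_dir(cfg.healthdb)
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
        counts["sites_read"] = cohort.n_sites

        # ---- stage: classify ----------------------------------------------
        try:
            variants = classify_variants(cohort, annotation, db)
            summary = summarize_classification(variants, cfg.count_thresholds)
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc
        counts["variants_annotated"] = len(variants)
        counts["deleterious"] = sum(1 for v in variants if v.deleterious)
        path = outdir / "classification_summary.tsv"
        _write_tsv(summary.to_frame(), path, meta)
        written.append(path)

        # ---- stage: scan ---------------------------------------------------
        try:
            panel_index = panel.site_index()
            keep = [j for j, s in enumerate(cohort.sites) if s.key in panel_index]
            x_all, n_all = all_allele_stats(cohort)
            order = [panel_index[cohort.sites[j].key] for j in keep]
            x = np.zeros(panel.n_sites, dtype=np.int64)
            n = np.zeros(panel.n_sites, dtype=np.int64)
            x[order] = x_all[keep]
            n[order] = n_all[keep]
            table, novel = scan_enrichment(
                x,
                n,
                panel,
                fst_threshold=cfg.fst_threshold,
                q_threshold=cfg.fdr_threshold,
                pi0_mode=cfg.pi0_mode,
            )
        except Exception as exc:
            raise PipelineError("scan", str(exc)) from exc
        counts["sites_in_panel"] = len(keep)
        counts["sites_novel"] = len(novel)
        counts["site_by_continent_tests"] = len(table)
        path = outdir / "enrichment_per_site.tsv"
        _write_tsv(table, path, meta)
        written.append(path)

        site_tiers = {}
        site_dele = {}
        key_to_panel_idx = panel_index
        for v in variants:
            idx = key_to_panel_idx.get(v.site.key)
            if idx is not None:
                site_dele[idx] = v.deleterious
                if v.tier is not None:
                    site_tiers[idx] = v.tier
        enr_summary = summarize_enrichment(table, tiers=site_tiers, deleterious=site_dele)
        counts["sites_enriched_union"] = enr_summary["union"]
        path = outdir / "enrichment_summary.json"
        path.write_text(json.dumps({"meta": meta, **enr_summary}, indent=2))
        written.append(path)

        # cross-tab of enriched x deleterious x tier
        enriched_sites = set(table.loc[table["call"] != NOT_ENRICHED, "site_index"])
        rows = []
        for tier in (None, 1, 2, 3):
            for dele in (False, True):
                n_sites = sum(
                    1
                    for i in enriched_sites
                    if site_dele.get(int(i), False) == dele and site_tiers.get(int(i)) == tier
                )
                rows.append({"tier": tier if tier else "none", "deleterious": dele, "n": n_sites})
        path = outdir / "enriched_by_tier.tsv"
        _write_tsv(pd.DataFrame(rows), path, meta)
        written.append(path)

        # ---- consistency check: summary reconstructible from per-site table
        recomputed = summarize_enrichment(table)
        if recomputed["union"] != enr_summary["union"]:
            raise PipelineError("consistency", "summary does not match per-site table")

        manifest = {
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed if cfg.simulate is None else cfg.simulate.seed,
            "thresholds": {
                "fst": cfg.fst_threshold,
                "fdr": cfg.fdr_threshold,
                "count": list(cfg.count_thresholds),
            },
            "pi0_mode": cfg.pi0_mode,
            "counts": counts,
            "empty": counts["site_by_continent_tests"] == 0,
            "outputs": [p.name for p in written],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def run_validation_report(
    pairs: pd.DataFrame,
    small_col: str = "qe7_freq",
    large_col: str = "qt86_freq",
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Correlate small-cohort vs larger-sample allele frequencies.

    ``pairs`` must hold at least 3 rows with both frequency columns present;
    returns the inference result and the paired table actually used.
    """
    used = pairs.dropna(subset=[small_col, large_col])
    if len(used) < 3:
        raise ValueError(f"need at least 3 shared sites, got {len(used)}")
    result = pearson_with_inference(
        used[small_col].to_numpy(float), used[large_col].to_numpy(float)
    )
    return result, used
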