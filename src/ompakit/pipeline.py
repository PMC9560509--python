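"""End-to-end orchestration: typing -> properties -> assays/growth -> stats
-> enrichment, with a run manifest for reproducibility.

Each stage consumes and emits plain UTF-8 CSV; a JSON manifest records the
subcommand, input paths, configuration hash, seed, package version and output
paths, and is sufficient to re-execute the run. Output tables are
deterministic for fixed inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alleles import batch_type, load_scheme, map_to_power_alleles, AlleleCall
from .assays import summarize_replicates
from .growth import GrowthCurve, LogPhaseParams, NoGrowthError, fit_curve
from .physicochem import tabulate_allele_properties
from .reference import load_reference
from .stats import (
    CountTable,
    DEFAULT_ALPHA,
    ENRICHMENT_ALPHA,
    LUMP_THRESHOLD,
    enrichment_scan,
    one_way_anova,
    pairwise_letter_groups,
    slope_ci_association,
)


@dataclass
class PipelineConfig:
    """Thresholds and knobs; defaults are the study's conventions."""

    alpha: float = DEFAULT_ALPHA                # t-test / ANOVA cutoff
    enrichment_alpha: float = ENRICHMENT_ALPHA  # Fisher exact cutoff
    conf: float = 0.95                          # slope CI level
    lump_threshold: int = LUMP_THRESHOLD        # rare-allele pooling
    pH: float = 8.0
    growth: LogPhaseParams = field(default_factory=LogPhaseParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        growth = LogPhaseParams(**data.pop("growth", {}))
        return cls(growth=growth, **data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def write_manifest(
    outdir: Path,
    subcommand: str,
    inputs: dict,
    outputs: list[str],
    config: PipelineConfig,
    seed: int | None,
) -> Path:
    manifest = {
        "subcommand": subcommand,
        "inputs": {k: str(v) for k, v in inputs.items() if v is not None},
        "config_hash": config.digest(),
        "config": asdict(config),
        "seed": seed,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": outputs,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_typing(fasta: str | Path, outdir: Path) -> pd.DataFrame:
    calls = batch_type(fasta)
    calls["power_allele"] = [
        map_to_power_alleles(AlleleCall(source_id=r.id, nterm=r.nterm, cterm=r.cterm,
                                        nterm_mismatches=0, cterm_mismatches=0))
        if r.nterm != "error" else "unmapped"
        for r in calls.itertuples()
    ]
    calls.to_csv(outdir / "allele_calls.csv", index=False)
    return calls


def stage_properties(outdir: Path, config: PipelineConfig) -> pd.DataFrame:
    table = tabulate_allele_properties(pH=config.pH)
    table.to_csv(outdir / "segment_properties.csv")
    return table


def stage_phenotype_stats(phenotypes: pd.DataFrame, outdir: Path, config: PipelineConfig):
    """Fig-2-style per-phenotype ANOVA + letter groups, and Fig-3-style
    pairwise slope-CI associations between phenotype allele means."""
    anova_rows, letter_rows = [], []
    for phenotype, sub in phenotypes.groupby("phenotype"):
        groups = {a: g["value"].to_numpy() for a, g in sub.groupby("allele")}
        if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
            continue
        F, p = one_way_anova(groups)
        anova_rows.append({"phenotype": phenotype, "F": F, "p": p,
                           "significant": bool(p < config.alpha)})
        letters = pairwise_letter_groups(groups, alpha=config.alpha)
        for allele, ls in letters.letters.items():
            g = groups[allele]
            letter_rows.append({
                "phenotype": phenotype, "allele": allele, "mean": float(g.mean()),
                "sd": float(g.std(ddof=1)), "n": int(g.size), "letters": ls,
            })
    anova = pd.DataFrame(anova_rows, columns=["phenotype", "F", "p", "significant"])
    letters_df = pd.DataFrame(
        letter_rows, columns=["phenotype", "allele", "mean", "sd", "n", "letters"])
    means = letters_df.pivot(index="allele", columns="phenotype", values="mean")
    corr_rows = []
    names = list(means.columns)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            paired = means[[a, b]].dropna()
            if len(paired) < 3 or np.ptp(paired[a].to_numpy()) == 0:
                continue
            assoc = slope_ci_association(paired[a].to_numpy(), paired[b].to_numpy(),
                                         conf=config.conf)
            corr_rows.append({
                "x": a, "y": b, "slope": assoc.slope, "ci_low": assoc.ci[0],
                "ci_high": assoc.ci[1], "significant": assoc.significant, "n": assoc.n,
            })
    correlations = pd.DataFrame(
        corr_rows, columns=["x", "y", "slope", "ci_low", "ci_high", "significant", "n"])
    anova.to_csv(outdir / "phenotype_anova.csv", index=False)
    letters_df.to_csv(outdir / "phenotype_letter_groups.csv", index=False)
    correlations.to_csv(outdir / "phenotype_correlations.csv", index=False)
    return anova, letters_df, correlations


def stage_growth(curves_df: pd.DataFrame, outdir: Path, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for (strain, condition), sub in curves_df.groupby(["strain", "condition"], dropna=False):
        sub = sub.sort_values("time_h")
        curve = GrowthCurve(times=sub["time_h"].to_numpy(), od=sub["od550"].to_numpy(),
                            strain=str(strain), condition=str(condition))
        try:
            fit = fit_curve(curve, config.growth)
            rows.append({
                "strain": strain, "condition": condition, "mu": fit.mu, "mu_sd": fit.mu_sd,
                "window_start": fit.window[0], "window_end": fit.window[1],
                "n_points": fit.n_points, "status": "ok",
            })
        except NoGrowthError as exc:
            rows.append({"strain": strain, "condition": condition, "mu": np.nan,
                         "mu_sd": np.nan, "window_start": -1, "window_end": -1,
                         "n_points": 0, "status": str(exc)})
    fits = pd.DataFrame(rows)
    fits.to_csv(outdir / "growth_fits.csv", index=False)
    return fits


def stage_enrichment(counts_df: pd.DataFrame, outdir: Path, config: PipelineConfig) -> pd.DataFrame:
    """`counts_df`: one row per group, 'group' and 'group_size' columns plus
    one column per allele."""
    df = counts_df.set_index("group")
    sizes = df.pop("group_size")
    table = CountTable(counts=df, group_sizes=sizes, reconstructed=False)
    table = table.lump_rare(config.lump_threshold)
    results = enrichment_scan(table, alpha=config.enrichment_alpha)
    results.to_csv(outdir / "enrichment.csv", index=False)
    return results


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_full_analysis(
    outdir: str | Path,
    sequences: str | Path | None = None,
    phenotypes: str | Path | None = None,
    curves: str | Path | None = None,
    counts: str | Path | None = None,
    assays: str | Path | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Execute every stage for which an input is present.

    Any stage failure aborts the run with the stage name and offending
    detail. Returns a dict of stage name -> result table.
    """
    if config is None:
        config = PipelineConfig()
    inputs = {"sequences": sequences, "phenotypes": phenotypes, "curves": curves,
              "counts": counts, "assays": assays}
    if all(v is None for v in inputs.values()):
        raise ValueError("at least one input must be present")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    outputs: list[str] = []

    def _run(stage: str, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, str(exc)) from exc

    if sequences is not None:
        results["typing"] = _run("typing", stage_typing, sequences, outdir)
        outputs.append("allele_calls.csv")
    results["properties"] = _run("properties", stage_properties, outdir, config)
    outputs.append("segment_properties.csv")
    if assays is not None:
        readings = pd.read_csv(assays)

        def _assays():
            out = summarize_replicates(readings)
            out.to_csv(outdir / "assay_summary.csv", index=False)
            return out

        results["assays"] = _run("assays", _assays)
        outputs.append("assay_summary.csv")
    if phenotypes is not None:
        pheno = pd.read_csv(phenotypes)
        results["stats"] = _run("stats", stage_phenotype_stats, pheno, outdir, config)
        outputs += ["phenotype_anova.csv", "phenotype_letter_groups.csv",
                    "phenotype_correlations.csv"]
    if curves is not None:
        curves_df = pd.read_csv(curves)
        results["growth"] = _run("growth", stage_growth, curves_df, outdir, config)
        outputs.append("growth_fits.csv")
    if counts is not None:
        counts_df = pd.read_csv(counts)
        results["enrichment"] = _run("enrich", stage_enrichment, counts_df, outdir, config)
        outputs.append("enrichment.csv")
    write_manifest(outdir, "run-all", inputs, outputs, config, seed)
    results["manifest"] = outdir / "manifest.json"
    return results
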