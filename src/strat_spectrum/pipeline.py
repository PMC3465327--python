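"""End-to-end pipeline: simulate -> QC -> stratify -> PCA/ancestry -> assoc.

Every stage reads its inputs from, and writes its outputs to, a single
output directory as PLINK/TSV text files, so each stage can be re-run in
isolation and every intermediate is inspectable. A manifest (JSON) records
the config hash, the global seed and a checksum per output file;
re-running with the same config reproduces every artifact bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from strat_spectrum import ancestry as anc
from strat_spectrum import assoc, pca, plinkio, simulate, stratify

STAGES = ("simulate", "qc", "stratify", "pca", "ancestry", "assoc", "report")

#: distinct exit-code family per stage
STAGE_CODES = {name: 10 * (i + 1) for i, name in enumerate(STAGES)}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = STAGE_CODES.get(stage, 99)


@dataclass
class PipelineConfig:
    """Validated configuration for the full analysis."""

    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)
    scenario: simulate.ScenarioConfig | None = None
    call_rate_min: float = 0.99
    hwe_alpha: float = 1e-8
    copy_threshold: int = 2
    prune_window: int = 50
    prune_step: int = 5
    prune_r2_max: float = 0.2
    n_pcs: int = 10
    pca_weighting: str = "af"
    pc_counts: tuple[int, ...] = (2, 3, 4, 10)
    ancestry_threshold: float = 0.5
    ancestry_max_iter: int = 2000
    seed: int = 0

    _KNOWN = {
        "simulation", "scenario", "call_rate_min", "hwe_alpha",
        "copy_threshold", "prune_window", "prune_step", "prune_r2_max",
        "n_pcs", "pca_weighting", "pc_counts", "ancestry_threshold",
        "ancestry_max_iter", "seed",
    }

    def validate(self) -> None:
        if not 0 <= self.call_rate_min <= 1:
            raise simulate.ConfigError("call_rate_min outside [0, 1]")
        if not 0 < self.hwe_alpha <= 1:
            raise simulate.ConfigError("hwe_alpha outside (0, 1]")
        if self.copy_threshold < 0:
            raise simulate.ConfigError("copy_threshold must be >= 0")
        if self.prune_window < 2 or self.prune_step < 1:
            raise simulate.ConfigError("invalid pruning window/step")
        if not 0 < self.prune_r2_max <= 1:
            raise simulate.ConfigError("prune_r2_max outside (0, 1]")
        if self.n_pcs < 1:
            raise simulate.ConfigError("n_pcs must be >= 1")
        self.simulation.validate()
        if self.scenario is not None:
            self.scenario.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise simulate.ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "simulation" in kwargs:
            kwargs["simulation"] = simulate.SimulationConfig(**kwargs["simulation"])
        if kwargs.get("scenario") is not None:
            kwargs["scenario"] = simulate.ScenarioConfig(**kwargs["scenario"])
        if "pc_counts" in kwargs:
            kwargs["pc_counts"] = tuple(kwargs["pc_counts"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in sorted(self._KNOWN)}
        out["simulation"] = vars(self.simulation).copy()
        out["scenario"] = (None if self.scenario is None
                           else vars(self.scenario).copy())
        out["pc_counts"] = list(self.pc_counts)
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(stage: str, message: str, t0: float) -> None:
    import sys
    print(f"[{stage}] {message} ({time.perf_counter() - t0:.1f}s)",
          file=sys.stderr)


# ---------------------------------------------------------------------------
# Stages (each reads/writes only within outdir)
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    sim = config.simulation
    cohort = simulate.simulate_cohort(sim)
    if config.scenario is not None:
        pheno = simulate.assign_case_control(cohort, config.scenario)
        cohort.sample_metadata["phenotype"] = pheno
    plinkio.write_plink(cohort.genotypes, str(outdir / "cohort"),
                        dialect="binary",
                        phenotypes=cohort.sample_metadata["phenotype"].to_numpy())
    cohort.sample_metadata.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    pd.DataFrame({"variant_id": cohort.genotypes.variant_ids,
                  "stratum": cohort.variant_strata}).to_csv(
        outdir / "variant_strata.tsv", sep="\t", index=False)
    _log("simulate", f"{cohort.genotypes.n_samples} samples x "
         f"{cohort.genotypes.n_variants} variants", t0)


def _load_cohort(outdir: Path, prefix: str):
    gm, _ = plinkio.read_plink(str(outdir / prefix), dialect="binary")
    meta = pd.read_csv(outdir / "samples.tsv", sep="\t")
    return gm, meta


def stage_qc(config: PipelineConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    gm, meta = _load_cohort(outdir, "cohort")
    cohorts, index = [], []
    controls = []
    for i, label in enumerate(pd.unique(meta["cohort"])):
        rows = np.flatnonzero((meta["cohort"] == label).to_numpy())
        cohorts.append(gm.take_samples(rows))
        index.append(rows)
        controls.append(i)  # both synthetic cohorts are control panels
    filtered, report = plinkio.qc_filter(
        cohorts, call_rate_min=config.call_rate_min,
        hwe_alpha=config.hwe_alpha, control_cohorts=controls)
    keep_ids = set(filtered[0].variant_ids)
    keep = np.flatnonzero(np.isin(gm.variant_ids, list(keep_ids)))
    gm_qc = gm.take_variants(keep)
    plinkio.write_plink(gm_qc, str(outdir / "qc"), dialect="binary",
                        phenotypes=meta["phenotype"].to_numpy())
    report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    _log("qc", f"retained {report.n_retained}/{report.n_input_variants}", t0)


def stage_stratify(config: PipelineConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    gm, meta = _load_cohort(outdir, "qc")
    regions = meta["region"].to_numpy()
    table = stratify.build_variant_table(gm, regions, config.copy_threshold)
    table.to_csv(outdir / "variant_table.tsv", sep="\t", index=False)

    for cat in ("rare", "lowfreq"):
        if (table["category"] == cat).any():
            summary = stratify.region_sharing(gm, regions, table, cat,
                                              expected=(cat == "rare"))
            frame = summary.to_frame()
            frame.to_csv(outdir / f"sharing_{cat}.tsv", sep="\t", index=False)

    burden_rows = []
    for cat in ("rare", "lowfreq"):
        if (table["category"] == cat).any():
            burden, kw, kw_p = stratify.rare_allele_burden(gm, table, regions, cat)
            burden_rows.append(pd.DataFrame({
                "sample_id": gm.sample_ids, "category": cat, "burden": burden}))
    if burden_rows:
        pd.concat(burden_rows).to_csv(outdir / "burden.tsv", sep="\t", index=False)

    _, pvals = stratify.heterogeneity_scan(gm, regions)
    lam_rows = []
    for cat in ("common", "lowfreq", "rare"):
        mask = (table["category"] == cat).to_numpy()
        if mask.any():
            lam_rows.append({"category": cat,
                             "lambda_r": stratify.lambda_r(pvals[mask])})
    pd.DataFrame(lam_rows).to_csv(outdir / "lambda_r.tsv", sep="\t", index=False)
    _log("stratify", f"{len(table)} variants categorized", t0)


def _pruned_pca(config: PipelineConfig, gm, table, category: str):
    mask = (table["category"] == category).to_numpy()
    idx = np.flatnonzero(mask)
    sub = gm.take_variants(idx)
    maf = table.loc[mask, "maf"].to_numpy()
    kept = pca.ld_prune(sub, maf, config.prune_window, config.prune_step,
                        config.prune_r2_max)
    pruned = sub.take_variants(kept)
    k = min(config.n_pcs, pruned.n_samples - 1, pruned.n_variants)
    return pruned, pca.eigen_pca(pruned, k=k, weighting=config.pca_weighting)


def stage_pca(config: PipelineConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    gm, meta = _load_cohort(outdir, "qc")
    regions = meta["region"].to_numpy()
    table = pd.read_csv(outdir / "variant_table.tsv", sep="\t")
    results = {}
    for cat in ("common", "lowfreq", "rare"):
        if not (table["category"] == cat).any():
            continue
        pruned, res = _pruned_pca(config, gm, table, cat)
        results[cat] = res
        scores = pd.DataFrame(
            res.scores, columns=[f"PC{i + 1}" for i in range(res.k)])
        scores.insert(0, "sample_id", gm.sample_ids)
        scores.to_csv(outdir / f"scores_{cat}.tsv", sep="\t", index=False)
        pd.DataFrame({"eigenvalue": res.eigenvalues, "pve": res.pve}).to_csv(
            outdir / f"eigen_{cat}.tsv", sep="\t", index=False)

    anova_rows = []
    for cat, res in results.items():
        for i in range(min(3, res.k)):
            f, p = pca.pc_region_anova(res.scores[:, i], regions)
            anova_rows.append({"set": cat, "pc": i + 1, "F": f, "p": p})
    pd.DataFrame(anova_rows).to_csv(outdir / "pc_anova.tsv", sep="\t",
                                    index=False)

    r2 = make_pc_r2_table(results, top_k=config.n_pcs)
    r2.to_csv(outdir / "pc_r2.tsv", sep="\t")
    _log("pca", f"{len(results)} variant sets decomposed", t0)


def stage_ancestry(config: PipelineConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    gm, meta = _load_cohort(outdir, "qc")
    table = pd.read_csv(outdir / "variant_table.tsv", sep="\t")
    is_ref = (meta["cohort"] == meta["cohort"].iloc[0]).to_numpy()
    ref = gm.take_samples(np.flatnonzero(is_ref))
    tgt = gm.take_samples(np.flatnonzero(~is_ref))
    ref_regions = meta.loc[is_ref, "region"].to_numpy()
    tgt_regions = meta.loc[~is_ref, "region"].to_numpy()
    rows = []
    for cat in ("common", "lowfreq", "rare"):
        mask = (table["category"] == cat).to_numpy()
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        res = anc.supervised_ancestry(
            ref.take_variants(idx), ref_regions, tgt.take_variants(idx),
            max_iter=config.ancestry_max_iter,
            threshold=config.ancestry_threshold)
        res.Q.to_csv(outdir / f"qmatrix_{cat}.tsv", sep="\t",
                     index_label="sample_id")
        n_ok, frac = anc.summarize_assignment(res, tgt_regions,
                                              config.ancestry_threshold)
        rows.append({"set": cat, "n_correct_confident": n_ok,
                     "fraction": frac})
    pd.DataFrame(rows).to_csv(outdir / "assignment_summary.tsv", sep="\t",
                              index=False)
    _log("ancestry", f"{len(rows)} variant sets assigned", t0)


def stage_assoc(config: PipelineConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    gm, meta = _load_cohort(outdir, "qc")
    pheno = meta["phenotype"].to_numpy()
    if not np.isin(pheno, [1, 2]).all():
        warnings.warn("no case-control phenotype set; skipping association")
        return
    regions = meta["region"].to_numpy()
    table = pd.read_csv(outdir / "variant_table.tsv", sep="\t")
    pc_sets, kinship_sets = {}, {}
    for cat in ("common", "lowfreq", "rare"):
        if not (table["category"] == cat).any():
            continue
        scores_path = outdir / f"scores_{cat}.tsv"
        if scores_path.exists():
            sc = pd.read_csv(scores_path, sep="\t").drop(columns="sample_id")
            pc_sets[cat] = sc.to_numpy()
        pruned, _ = _pruned_pca(config, gm, table, cat)
        kinship_sets[cat] = assoc.grm(pruned)
    grid = assoc.scan_and_summarize(
        gm, pheno, regions, table, pc_sets=pc_sets,
        pc_counts=config.pc_counts, kinship_sets=kinship_sets)
    grid.to_csv(outdir / "lambda_grid.tsv", sep="\t", index_label="method")
    _log("assoc", f"{grid.shape[0]} methods x {grid.shape[1]} categories", t0)


def stage_report(config: PipelineConfig, outdir: Path) -> None:
    t0 = time.perf_counter()
    manifest = {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "files": {},
    }
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["files"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _log("report", f"{len(manifest['files'])} artifacts checksummed", t0)


def make_pc_r2_table(results: dict[str, pca.PCResult],
                     top_k: int = 10) -> pd.DataFrame:
    """R-squared matrix across the per-category PCAs.

    Rows PC1.<set>/PC2.<set>; columns PC1.<set>, PC2.<set> and
    Top<k>.<set> (cumulative R-squared against the top components of each
    set), following the standard cross-category comparison layout.
    """
    cats = list(results)
    rows: dict[str, dict[str, float]] = {}
    for ca in cats:
        for cb in cats:
            tab = pca.pc_cross_correlation(results[ca], results[cb],
                                           top_k=top_k)
            kk = min(top_k, results[cb].k)
            for i in range(min(2, results[ca].k)):
                row = rows.setdefault(f"PC{i + 1}.{ca}", {})
                for j in range(min(2, results[cb].k)):
                    row[f"PC{j + 1}.{cb}"] = tab.iloc[i][f"PC{j + 1}"]
                row[f"Top{top_k}.{cb}"] = tab.iloc[i][f"Top{kk}"]
    return pd.DataFrame(rows).T


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "stratify": stage_stratify,
    "pca": stage_pca,
    "ancestry": stage_ancestry,
    "assoc": stage_assoc,
    "report": stage_report,
}


def run_stage(name: str, config: PipelineConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        _STAGE_FUNCS[name](config, outdir)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution on purpose
        raise PipelineStageError(name, str(exc)) from exc


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order; returns the main report tables.

    Deterministic under a fixed config: the manifest written by the report
    stage has identical checksums across re-runs.
    """
    config.validate()
    outdir = Path(outdir)
    for name in STAGES:
        if name == "assoc" and config.scenario is None:
            continue
        run_stage(name, config, outdir)
    out = {
        "qc_report": pd.read_csv(outdir / "qc_report.tsv", sep="\t"),
        "variant_table": pd.read_csv(outdir / "variant_table.tsv", sep="\t"),
        "lambda_r": pd.read_csv(outdir / "lambda_r.tsv", sep="\t"),
        "pc_r2": pd.read_csv(outdir / "pc_r2.tsv", sep="\t", index_col=0),
        "assignment": pd.read_csv(outdir / "assignment_summary.tsv", sep="\t"),
        "manifest": json.loads((outdir / "manifest.json").read_text()),
    }
    grid_path = outdir / "lambda_grid.tsv"
    if grid_path.exists():
        out["lambda_grid"] = pd.read_csv(grid_path, sep="\t", index_col=0)
    return out
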