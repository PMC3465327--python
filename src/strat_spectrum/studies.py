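"""Canonical simulation studies: null calibration and the confounded
two-region stratification scenario.

These functions pin down the study conditions used to validate the
pipeline, so the same experiment can be re-run from tests, scripts or a
notebook with a single seed.

``null_calibration``
    An unstructured cohort (fst = 0, two interchangeable regions of 250
    samples, 50,000 common variants). Every association test and the
    region-heterogeneity overdispersion coefficient must calibrate to
    lambda ~ 1 here.

``stratification_scenario``
    The confounded case-control design: a 12-region panel (sizes 252 for
    R1..R10, 146 for R11, 273 for R12) at fst = 0.05 with half the rare
    variants private to one region; MAF categories are computed on the
    full pooled panel; the scan then uses only the R11/R12 individuals,
    with exactly 59 of 146 (40.4%) R11 and 150 of 273 (54.9%) R12
    individuals assigned case status. Uncorrected tests inflate, most
    strongly for rare variants; CMH on the true strata stays calibrated
    for common variants; PC adjustment recovers most of the inflation.
"""

from __future__ import annotations

import numpy as np

from strat_spectrum import (
    ScenarioConfig,
    SimulationConfig,
    assign_case_control,
    build_variant_table,
    eigen_pca,
    grm,
    heterogeneity_scan,
    lambda_r,
    ld_prune,
    scan_and_summarize,
    simulate_cohort,
)

from strat_spectrum.ancestry import supervised_ancestry, summarize_assignment

#: region sizes of the confounded-scenario panel; R11 and R12 carry the
#: case-control design (146 and 273 individuals)
SCENARIO_REGION_SIZES = [252] * 10 + [146, 273]
SCENARIO_CASE_FRACTIONS = {"R11": 59 / 146, "R12": 150 / 273}


def null_calibration(seed: int = 0, n_variants: int = 50_000,
                     samples_per_region: int = 250) -> dict:
    """Lambda grid + lambda_r of an unstructured two-region cohort.

    Returns a dict with the lambda_GC of the raw trend test, CMH on the
    two (non-informative) regions, PC-adjusted tests at k = 2 and 10, the
    mixed-model scan, and lambda_r over the region-heterogeneity p-values.
    """
    config = SimulationConfig(
        n_regions=2,
        samples_per_region=samples_per_region,
        n_variants_by_stratum={"common": n_variants},
        ancestral_maf_spectrum={"common": ("uniform", 0.05, 0.5)},
        fst=0.0,
        private_rare_fraction=0.0,
        seed=seed,
    )
    cohort = simulate_cohort(config)
    scenario = ScenarioConfig(
        case_fraction_by_region={"R1": 0.5, "R2": 0.5}, seed=seed)
    y = assign_case_control(cohort, scenario)
    gm = cohort.genotypes
    regions = cohort.regions
    table = build_variant_table(gm, regions)

    mask = (table["category"] == "common").to_numpy()
    sub = gm.take_variants(np.flatnonzero(mask))
    pruned_ix = ld_prune(sub, table.loc[mask, "maf"].to_numpy())
    pruned = sub.take_variants(pruned_ix[:20_000])
    pcs = eigen_pca(pruned, k=10).scores
    kin = grm(pruned)

    grid = scan_and_summarize(
        gm, y, regions, table,
        pc_sets={"common": pcs}, pc_counts=(2, 10),
        kinship_sets={"common": kin})
    _, het_p = heterogeneity_scan(gm, regions)
    return {
        "lambda_raw": grid.loc["Raw", "common"],
        "lambda_cmh": grid.loc["CMH", "common"],
        "lambda_pc2": grid.loc["common.2", "common"],
        "lambda_pc10": grid.loc["common.10", "common"],
        "lambda_emmax": grid.loc["EMMAX.common", "common"],
        "lambda_r": lambda_r(het_p[mask]),
        "grid": grid,
    }


def stratification_scenario(seed: int = 0,
                            n_variants_by_stratum: dict | None = None,
                            fst: float = 0.05,
                            private_rare_fraction: float = 0.5) -> dict:
    """Confounded R11/R12 case-control scan (see module docstring).

    Returns the lambda grid over methods x MAF categories plus the case
    counts actually assigned per region.
    """
    if n_variants_by_stratum is None:
        n_variants_by_stratum = {"common": 25_000, "lowfreq": 2_900,
                                 "rare": 1_900}
    config = SimulationConfig(
        n_regions=12,
        samples_per_region=SCENARIO_REGION_SIZES,
        n_variants_by_stratum=n_variants_by_stratum,
        fst=fst,
        private_rare_fraction=private_rare_fraction,
        seed=seed,
    )
    cohort = simulate_cohort(config)
    gm = cohort.genotypes
    # MAF categories on the FULL pooled control panel
    table = build_variant_table(gm, cohort.regions)

    sub_ix = np.flatnonzero(np.isin(cohort.regions, ["R11", "R12"]))
    gsub = gm.take_samples(sub_ix)
    regions = cohort.regions[sub_ix]
    scenario = ScenarioConfig(case_fraction_by_region=SCENARIO_CASE_FRACTIONS,
                              assignment_mode="deterministic", seed=seed)
    y = assign_case_control(regions, scenario)
    n_cases = {r: int(((y == 2) & (regions == r)).sum()) for r in ("R11", "R12")}

    pc_sets, kinship_sets = {}, {}
    for cat in ("common", "rare"):
        mask = (table["category"] == cat).to_numpy()
        if not mask.any():
            continue
        sub = gsub.take_variants(np.flatnonzero(mask))
        pruned_ix = ld_prune(sub, table.loc[mask, "maf"].to_numpy())
        pruned = sub.take_variants(pruned_ix)
        k = min(10, pruned.n_variants - 1)
        pc_sets[cat] = eigen_pca(pruned, k=k).scores
        if cat == "common":
            kinship_sets[cat] = grm(pruned)

    grid = scan_and_summarize(
        gsub, y, regions, table,
        pc_sets=pc_sets, pc_counts=(2, 10), kinship_sets=kinship_sets)
    return {"grid": grid, "n_cases": n_cases,
            "n_samples": len(sub_ix), "table": table}


def ancestry_panels(fst: float, n_regions: int = 3, n_variants: int = 2000,
                    n_ref: int = 100, n_tgt: int = 100, seed: int = 0):
    """Reference/target panels drawn from one set of regional frequencies.

    Returns (ref genotypes, ref regions, target genotypes, target regions);
    the first ``n_ref`` samples of each region form the labelled reference,
    the next ``n_tgt`` the targets.
    """
    config = SimulationConfig(
        n_regions=n_regions, samples_per_region=n_ref + n_tgt,
        n_variants_by_stratum={"common": n_variants},
        ancestral_maf_spectrum={"common": ("uniform", 0.1, 0.5)},
        fst=fst, private_rare_fraction=0.0,
        missing_rate=0.0, genotype_error_rate=0.0, seed=seed)
    cohort = simulate_cohort(config)
    regions = cohort.regions
    ref_rows, tgt_rows = [], []
    for r in np.unique(regions):
        members = np.flatnonzero(regions == r)
        ref_rows.extend(members[:n_ref])
        tgt_rows.extend(members[n_ref:])
    ref_rows, tgt_rows = np.array(ref_rows), np.array(tgt_rows)
    return (cohort.genotypes.take_samples(ref_rows), regions[ref_rows],
            cohort.genotypes.take_samples(tgt_rows), regions[tgt_rows])


def ancestry_recovery(seed: int = 0) -> dict:
    """Supervised-ancestry parameter recovery at fst = 0.2 (K = 3, 2,000
    variants, 100 targets per region) plus the unidentifiable-limit
    control: identical reference panels per region (the fst = 0 flat
    likelihood), where proportions stay at 1/K and nothing clears the 0.5
    confidence threshold."""
    ref, ref_regions, tgt, tgt_regions = ancestry_panels(fst=0.2, seed=seed)
    res = supervised_ancestry(ref, ref_regions, tgt)
    correct = float((res.assignment == tgt_regions).mean())
    n_conf, frac_conf = summarize_assignment(res, tgt_regions)

    rng = np.random.default_rng(seed)
    panel = rng.binomial(2, rng.uniform(0.1, 0.5, 2000),
                         size=(100, 2000)).astype(np.int8)
    flat_ref = np.vstack([panel] * 3)
    flat_regions = np.repeat(["R1", "R2", "R3"], 100)
    flat_tgt = rng.binomial(2, rng.uniform(0.1, 0.5, 2000),
                            size=(300, 2000)).astype(np.int8)
    flat = supervised_ancestry(flat_ref, flat_regions, flat_tgt)
    return {
        "correct_assignment_rate": correct,
        "correct_confident_fraction": frac_conf,
        "flat_confident_rate": float(flat.confident.mean()),
        "n_targets": len(tgt_regions),
    }
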