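"""Region-structured case-control cohort simulation.

Emulates a chip-genotyped cohort drawn from geographic regions with
region-specific allele frequencies. Ancestral minor-allele frequencies are
drawn per stratum (common / low-frequency / rare) from a configurable
spectrum; regional frequencies follow the Balding-Nichols model, a Beta
distribution with mean equal to the ancestral frequency and variance
Fst * p * (1 - p). Genotypes are Binomial(2, regional frequency), after
which missingness and genotype errors are applied. A configurable fraction
of rare variants is made private to a single region, so the regional
sharing spectrum spans 1..n_regions as on real chip data.

Case-control status is assigned by region (the stratification scenario):
each region gets a case fraction, applied either as an exact count
(deterministic mode, default) or per-individual Bernoulli draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from strat_spectrum.plinkio import MISSING, GenotypeMatrix

#: default ancestral MAF spectrum per stratum: uniform over the interval
#: that defines each frequency category on the chip
DEFAULT_SPECTRA = {
    "common": ("uniform", 0.05, 0.5),
    "lowfreq": ("uniform", 0.01, 0.05),
    "rare": ("uniform", 0.001, 0.01),
}

#: default per-stratum variant counts, about 1/10 of a 500K-chip category
#: breakdown after QC
DEFAULT_N_VARIANTS = {"common": 25000, "lowfreq": 2900, "rare": 1900}


class ConfigError(ValueError):
    """Invalid simulation or scenario configuration."""


@dataclass
class SimulationConfig:
    """Full parameterization of the structured synthetic cohort.

    Defaults emulate a UK-scale study: 12 regions, ~245 samples per region
    split over two interchangeable control cohorts, weak differentiation
    (fst = 0.005), a small private-rare fraction, and low missingness and
    genotype-error rates.
    """

    n_regions: int = 12
    samples_per_region: list[int] | int = 245
    n_variants_by_stratum: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_VARIANTS))
    ancestral_maf_spectrum: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRA))
    fst: float = 0.005
    private_rare_fraction: float = 0.05
    missing_rate: float = 0.002
    genotype_error_rate: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ConfigError("n_regions must be positive")
        sizes = self.region_sizes()
        if len(sizes) != self.n_regions or any(s < 1 for s in sizes):
            raise ConfigError("samples_per_region must give a positive size per region")
        for stratum, n in self.n_variants_by_stratum.items():
            if n < 0:
                raise ConfigError(f"negative variant count for stratum {stratum!r}")
            if stratum not in self.ancestral_maf_spectrum:
                raise ConfigError(f"no spectrum for stratum {stratum!r}")
        if not 0 <= self.fst < 1:
            raise ConfigError("fst must lie in [0, 1); 0 means no structure")
        for name, value in [("private_rare_fraction", self.private_rare_fraction),
                            ("missing_rate", self.missing_rate),
                            ("genotype_error_rate", self.genotype_error_rate)]:
            if not 0 <= value <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")

    def region_sizes(self) -> list[int]:
        if isinstance(self.samples_per_region, int):
            return [self.samples_per_region] * self.n_regions
        return list(self.samples_per_region)


@dataclass
class ScenarioConfig:
    """Region-differential case assignment scheme.

    ``case_fraction_by_region`` maps region label -> probability of case
    status. In ``deterministic`` mode exactly round(fraction * region size)
    individuals per region become cases (chosen at random within the
    region); ``bernoulli`` mode draws status independently per individual.
    """

    case_fraction_by_region: dict[str, float]
    assignment_mode: str = "deterministic"
    seed: int = 0

    def validate(self) -> None:
        for region, frac in self.case_fraction_by_region.items():
            if not 0 <= frac <= 1:
                raise ConfigError(f"case fraction for {region!r} outside [0, 1]")
        if self.assignment_mode not in ("deterministic", "bernoulli"):
            raise ConfigError(f"unknown assignment_mode {self.assignment_mode!r}")


@dataclass
class SyntheticCohort:
    """A simulated cohort: genotypes, sample metadata and the true
    variants x regions frequency matrix used to generate them."""

    genotypes: GenotypeMatrix
    sample_metadata: pd.DataFrame  # sample_id, cohort, region, phenotype
    true_regional_frequencies: np.ndarray  # (n_variants, n_regions)
    variant_strata: np.ndarray  # per-variant stratum label

    def __post_init__(self) -> None:
        if len(self.sample_metadata) != self.genotypes.n_samples:
            raise ValueError("sample metadata length mismatch")
        if self.true_regional_frequencies.shape[0] != self.genotypes.n_variants:
            raise ValueError("frequency matrix row mismatch")
        ph = self.sample_metadata["phenotype"]
        if not ph.isin([0, 1, 2, -9]).all():
            raise ValueError("phenotypes must use PLINK coding (1/2, 0 or -9 unset)")

    @property
    def regions(self) -> np.ndarray:
        return self.sample_metadata["region"].to_numpy()


def draw_ancestral_frequencies(spectrum: tuple, n: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` ancestral allele frequencies from a named spectrum.

    ``spectrum`` is ("uniform", low, high) or ("point", value); bounds must
    lie strictly inside (0, 1).
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    name = spectrum[0]
    if name == "uniform":
        _, low, high = spectrum
        if not (0 < low <= high < 1):
            raise ConfigError(f"uniform spectrum bounds ({low}, {high}) outside (0, 1)")
        return rng.uniform(low, high, size=n)
    if name == "point":
        _, value = spectrum
        if not 0 < value < 1:
            raise ConfigError(f"point spectrum value {value} outside (0, 1)")
        return np.full(n, float(value))
    raise ConfigError(f"unknown spectrum {name!r}")


def draw_regional_frequencies(p: float | np.ndarray, fst: float, n_regions: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols regional frequencies for ancestral frequency ``p``.

    Each region's frequency is Beta with mean p and variance fst*p*(1-p),
    i.e. shape parameters p*(1-fst)/fst and (1-p)*(1-fst)/fst. With fst = 0
    every region receives p exactly. Accepts a scalar or a vector of
    ancestral frequencies; returns shape (n_variants, n_regions) (the first
    axis dropped for scalar input).
    """
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("ancestral frequency must lie in (0, 1)")
    if not 0 <= fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    if fst == 0:
        out = np.repeat(p_arr[:, None], n_regions, axis=1)
    else:
        scale = (1 - fst) / fst
        a = p_arr * scale
        b = (1 - p_arr) * scale
        out = rng.beta(a[:, None], b[:, None], size=(p_arr.size, n_regions))
    return out if np.ndim(p) else out[0]


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a structured cohort from ``config``.

    Genotype of individual i at variant j is Binomial(2, f[region(i), j]).
    A ``private_rare_fraction`` of rare-stratum variants has its frequency
    zeroed outside one uniformly chosen region. Missingness and genotype
    errors (perturbation to an adjacent dosage) are applied after drawing.
    Identical configs (including seed) reproduce identical cohorts.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # independent substreams per stage so stages can be reasoned about in
    # isolation
    ss = dict(zip(
        ["freq", "private", "genotype", "missing", "error", "cohort"],
        root.spawn(6)))
    rng_freq = np.random.default_rng(ss["freq"])
    rng_priv = np.random.default_rng(ss["private"])
    rng_geno = np.random.default_rng(ss["genotype"])
    rng_miss = np.random.default_rng(ss["missing"])
    rng_err = np.random.default_rng(ss["error"])
    rng_coh = np.random.default_rng(ss["cohort"])

    sizes = config.region_sizes()
    n_samples = sum(sizes)
    region_labels = [f"R{i + 1}" for i in range(config.n_regions)]
    region_of_sample = np.repeat(np.arange(config.n_regions), sizes)

    strata, freqs = [], []
    for stratum in sorted(config.n_variants_by_stratum):
        n = config.n_variants_by_stratum[stratum]
        if n == 0:
            continue
        p = draw_ancestral_frequencies(
            config.ancestral_maf_spectrum[stratum], n, rng_freq)
        f = draw_regional_frequencies(p, config.fst, config.n_regions, rng_freq)
        if stratum == "rare" and config.private_rare_fraction > 0:
            n_private = int(round(config.private_rare_fraction * n))
            idx = rng_priv.choice(n, size=n_private, replace=False)
            home = rng_priv.integers(0, config.n_regions, size=n_private)
            mask = np.ones((n_private, config.n_regions), dtype=bool)
            mask[np.arange(n_private), home] = False
            f[idx] = np.where(mask, 0.0, f[idx])
            # a private variant must stay polymorphic in its home region
            f[idx, home] = np.maximum(f[idx, home], 1e-12)
        strata.append(np.full(n, stratum, dtype=object))
        freqs.append(f)
    if not freqs:
        raise ConfigError("no variants requested")
    strata = np.concatenate(strata)
    freqs = np.vstack(freqs)  # (n_variants, n_regions)
    n_variants = freqs.shape[0]

    dosages = np.empty((n_samples, n_variants), dtype=np.int8)
    start = 0
    for r, size in enumerate(sizes):
        block = rng_geno.binomial(
            2, freqs[:, r][None, :], size=(size, n_variants))
        dosages[start:start + size] = block.astype(np.int8)
        start += size

    if config.genotype_error_rate > 0:
        err = rng_err.random(dosages.shape) < config.genotype_error_rate
        flip = rng_err.random(dosages.shape) < 0.5
        d = dosages[err]
        up = flip[err]
        # adjacent-dosage perturbation: 0->1, 2->1, 1 -> 0 or 2 evenly
        d = np.where(d == 0, 1, np.where(d == 2, 1, np.where(up, 2, 0)))
        dosages[err] = d.astype(np.int8)
    if config.missing_rate > 0:
        miss = rng_miss.random(dosages.shape) < config.missing_rate
        dosages[miss] = MISSING

    variants = pd.DataFrame({
        "variant_id": [f"var{j:07d}" for j in range(n_variants)],
        "chromosome": "1",
        "position": np.arange(1, n_variants + 1) * 1000,
        "allele1": "A",
        "allele2": "C",
    })
    sample_ids = np.array([f"S{i:05d}" for i in range(n_samples)], dtype=object)
    gm = GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, variants=variants)

    # split each region's samples over two interchangeable control cohorts
    cohort = np.empty(n_samples, dtype=object)
    for r in range(config.n_regions):
        members = np.flatnonzero(region_of_sample == r)
        shuffled = rng_coh.permutation(members)
        half = len(members) // 2
        cohort[shuffled[:half]] = "CTRL_A"
        cohort[shuffled[half:]] = "CTRL_B"

    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "cohort": cohort,
        "region": [region_labels[r] for r in region_of_sample],
        "phenotype": 0,  # unset
    })
    return SyntheticCohort(
        genotypes=gm,
        sample_metadata=meta,
        true_regional_frequencies=freqs,
        variant_strata=strata,
    )


def assign_case_control(cohort: SyntheticCohort | np.ndarray,
                        scenario: ScenarioConfig) -> np.ndarray:
    """Assign phenotypes by region; returns a PLINK-coded vector.

    ``cohort`` may be a :class:`SyntheticCohort` or a plain region-label
    array (e.g. for a subset of a larger cohort). Returns 2 for cases and
    1 for controls. Regions absent from the scenario map become all
    controls (with a warning). Deterministic mode assigns exactly
    round(fraction * region size) cases per region.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    regions = (cohort.regions if isinstance(cohort, SyntheticCohort)
               else np.asarray(cohort))
    pheno = np.ones(len(regions), dtype=int)
    for region in pd.unique(regions):
        members = np.flatnonzero(regions == region)
        if region not in scenario.case_fraction_by_region:
            warnings.warn(f"region {region!r} absent from scenario; all controls")
            continue
        frac = scenario.case_fraction_by_region[region]
        if scenario.assignment_mode == "deterministic":
            n_cases = int(round(frac * len(members)))
            chosen = rng.choice(members, size=n_cases, replace=False)
            pheno[chosen] = 2
        else:
            pheno[members[rng.random(len(members)) < frac]] = 2
    return pheno
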