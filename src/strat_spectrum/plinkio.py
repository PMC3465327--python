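"""PLINK-format genotype I/O, quality control and allele-frequency computation.

Genotypes are held as a samples x variants dosage matrix of int8 counting
copies of allele2 (0, 1, 2), with -1 marking a missing call. Both the
text dialect (.ped/.map) and the binary dialect (.bed/.bim/.fam, SNP-major,
2-bit encoded) are supported and round-trip exactly, including missingness.

QC follows the usual chip-data protocol: a variant survives only if it is
present in every cohort, well called (call rate >= 0.99 by default) in every
cohort, and consistent with Hardy-Weinberg proportions in the pooled
controls (exact conditional test, alpha = 1e-8 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

MISSING = -1

#: .bed magic bytes followed by the SNP-major mode byte
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit genotype codes in the .bed format: 00=hom allele1, 01=missing,
# 10=het, 11=hom allele2.  Maps dosage -> code and code -> dosage.
_DOSAGE_TO_CODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)

_VARIANT_COLUMNS = ["variant_id", "chromosome", "position", "allele1", "allele2"]


class PlinkFormatError(ValueError):
    """Malformed PLINK file (bad magic bytes, ragged rows, unknown alleles)."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with identifiers and variant records.

    Parameters
    ----------
    dosages
        int8 array of shape (n_samples, n_variants); entries count copies of
        allele2 (0/1/2) with -1 for missing.
    sample_ids
        Ordered, unique sample identifiers.
    variants
        DataFrame with columns variant_id, chromosome, position (1-based),
        allele1, allele2; one row per dosage column, variant_id unique.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant records for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample ids")
        vids = self.variants["variant_id"]
        if vids.duplicated().any():
            raise ValueError("duplicated variant ids")
        if (self.variants["position"] < 1).any():
            raise ValueError("positions must be >= 1 (1-based)")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, -1}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the variant columns in ``index`` (positional)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            sample_ids=self.sample_ids,
            variants=self.variants.iloc[index].reset_index(drop=True),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            sample_ids=self.sample_ids[index],
            variants=self.variants,
        )


@dataclass
class QCReport:
    """Per-filter variant removal counts; counts partition the input set."""

    n_input_variants: int
    n_removed_not_shared: int
    n_removed_by_call_rate: int
    n_removed_by_hwe: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (self.n_removed_not_shared + self.n_removed_by_call_rate
                 + self.n_removed_by_hwe + self.n_retained)
        if total != self.n_input_variants:
            raise ValueError("QC counts do not partition the input variants")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": ["input", "not_shared", "call_rate", "hwe", "retained"],
                "n_variants": [
                    self.n_input_variants,
                    self.n_removed_not_shared,
                    self.n_removed_by_call_rate,
                    self.n_removed_by_hwe,
                    self.n_retained,
                ],
            }
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_plink(
    gm: GenotypeMatrix,
    prefix: str,
    dialect: str = "binary",
    phenotypes: np.ndarray | None = None,
) -> None:
    """Write a GenotypeMatrix as PLINK files under ``prefix``.

    ``dialect='text'`` writes .ped/.map; ``'binary'`` writes .bed/.bim/.fam
    (SNP-major). Phenotypes use PLINK coding (1=control, 2=case, 0 or
    -9=missing); if omitted, -9 is written.
    """
    if dialect not in ("text", "binary"):
        raise ValueError(f"unknown dialect {dialect!r}")
    pheno = np.full(gm.n_samples, -9, dtype=int) if phenotypes is None else (
        np.asarray(phenotypes, dtype=int))
    if len(pheno) != gm.n_samples:
        raise ValueError("phenotype length mismatch")
    v = gm.variants
    if dialect == "text":
        _write_map(v, f"{prefix}.map")
        _write_ped(gm, pheno, f"{prefix}.ped")
    else:
        _write_bim(v, f"{prefix}.bim")
        _write_fam(gm.sample_ids, pheno, f"{prefix}.fam")
        _write_bed(gm.dosages, f"{prefix}.bed")


def read_plink(prefix: str, dialect: str = "binary",
               alleles: list[tuple[str, str]] | None = None):
    """Read PLINK files into (GenotypeMatrix, sample metadata DataFrame).

    The metadata frame carries sample_id and phenotype (PLINK coding).
    Round-trips with :func:`write_plink` exactly, missing calls included.

    The text dialect does not record allele order, so dosage orientation is
    inferred per variant: a heterozygote line fixes (allele1, allele2) in
    written order; otherwise the first-seen symbol is taken as allele1. A
    variant observed only as hom-allele2 is therefore read with flipped
    labels; pass ``alleles`` (one (a1, a2) pair per variant) to pin the
    orientation explicitly.
    """
    if dialect not in ("text", "binary"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "text":
        variants = _read_map(f"{prefix}.map")
        dosages, sample_ids, pheno, seen = _read_ped(
            f"{prefix}.ped", len(variants), alleles)
        # allele symbols come from the data in the text dialect
        variants = variants.copy()
        variants["allele1"] = [a[0] for a in seen]
        variants["allele2"] = [a[1] for a in seen]
    else:
        variants = _read_bim(f"{prefix}.bim")
        sample_ids, pheno = _read_fam(f"{prefix}.fam")
        dosages = _read_bed(f"{prefix}.bed", len(sample_ids), len(variants))
    gm = GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, variants=variants)
    meta = pd.DataFrame({"sample_id": sample_ids, "phenotype": pheno})
    return gm, meta


def _write_map(variants: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for row in variants.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.variant_id}\t0\t{row.position}\n")


def _read_map(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise PlinkFormatError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            rows.append((parts[1], parts[0], int(parts[3])))
    df = pd.DataFrame(rows, columns=["variant_id", "chromosome", "position"])
    df["allele1"] = "A"
    df["allele2"] = "B"
    return df


def _write_ped(gm: GenotypeMatrix, pheno: np.ndarray, path: str) -> None:
    a1 = gm.variants["allele1"].to_numpy()
    a2 = gm.variants["allele2"].to_numpy()
    with open(path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = [str(sid), str(sid), "0", "0", "0", str(pheno[i])]
            row = gm.dosages[i]
            for j, d in enumerate(row):
                if d == MISSING:
                    fields.append("0 0")
                elif d == 0:
                    fields.append(f"{a1[j]} {a1[j]}")
                elif d == 1:
                    fields.append(f"{a1[j]} {a2[j]}")
                else:
                    fields.append(f"{a2[j]} {a2[j]}")
            fh.write("\t".join(fields) + "\n")


def _read_ped(path: str, n_variants: int,
              alleles: list[tuple[str, str]] | None = None):
    lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_variants:
                raise PlinkFormatError(
                    f"{path}:{lineno}: expected {6 + 2 * n_variants} fields, "
                    f"got {len(parts)}")
            lines.append(parts)
    sample_ids = np.array([p[1] for p in lines], dtype=object)
    phenos = np.array([int(p[5]) for p in lines])

    if alleles is not None:
        if len(alleles) != n_variants:
            raise ValueError("alleles must list one (a1, a2) pair per variant")
        seen = [list(a) for a in alleles]
    else:
        # orientation pass: a het fixes allele order; else first-seen is allele1
        seen = [[None, None] for _ in range(n_variants)]
        for j in range(n_variants):
            first = None
            for p in lines:
                b1, b2 = p[6 + 2 * j], p[7 + 2 * j]
                if b1 == "0" or b2 == "0":
                    continue
                if b1 != b2:
                    seen[j] = [b1, b2]
                    break
                if first is None:
                    first = b1
            else:
                seen[j][0] = first

    dosages = np.empty((len(lines), n_variants), dtype=np.int8)
    for i, p in enumerate(lines):
        lineno = i + 1
        for j in range(n_variants):
            b1, b2 = p[6 + 2 * j], p[7 + 2 * j]
            if b1 == "0" or b2 == "0":
                if b1 != b2:
                    raise PlinkFormatError(
                        f"{path}:{lineno}: half-missing genotype at variant {j + 1}")
                dosages[i, j] = MISSING
                continue
            dosages[i, j] = (_allele_code(path, lineno, j, seen[j], b1)
                             + _allele_code(path, lineno, j, seen[j], b2))

    out_alleles = []
    for x1, x2 in seen:
        x1 = x1 or "A"
        out_alleles.append((x1, x2 or ("B" if x1 != "B" else "C")))
    return dosages, sample_ids, phenos, out_alleles


def _allele_code(path, lineno, j, seen, symbol) -> int:
    """Return 0/1 for allele1/allele2, learning unseen symbols in order."""
    if symbol == seen[0]:
        return 0
    if symbol == seen[1]:
        return 1
    if seen[0] is None:
        seen[0] = symbol
        return 0
    if seen[1] is None:
        seen[1] = symbol
        return 1
    raise PlinkFormatError(
        f"{path}:{lineno}: variant {j + 1} has >2 allele symbols ({symbol!r})")


def _write_bim(variants: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for row in variants.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.variant_id}\t0\t{row.position}"
                     f"\t{row.allele1}\t{row.allele2}\n")


def _read_bim(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise PlinkFormatError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            rows.append((parts[1], parts[0], int(parts[3]), parts[4], parts[5]))
    return pd.DataFrame(rows, columns=_VARIANT_COLUMNS)


def _write_fam(sample_ids: np.ndarray, pheno: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        for sid, ph in zip(sample_ids, pheno):
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t{ph}\n")


def _read_fam(path: str):
    ids, phenos = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise PlinkFormatError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            ids.append(parts[1])
            phenos.append(int(parts[5]))
    return np.array(ids, dtype=object), np.array(phenos)


def _write_bed(dosages: np.ndarray, path: str) -> None:
    n, m = dosages.shape
    codes = np.empty((m, n), dtype=np.uint8)
    dt = dosages.T
    codes[dt == 0] = 0b00
    codes[dt == 1] = 0b10
    codes[dt == 2] = 0b11
    codes[dt == MISSING] = 0b01
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    c = codes.reshape(m, -1, 4)
    packed = c[:, :, 0] | (c[:, :, 1] << 2) | (c[:, :, 2] << 4) | (c[:, :, 3] << 6)
    with open(path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def _read_bed(path: str, n_samples: int, n_variants: int) -> np.ndarray:
    with open(path, "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise PlinkFormatError(
                f"{path}: byte 0-2: bad magic/mode bytes {magic.hex()} "
                f"(expected {_BED_MAGIC.hex()}, SNP-major)")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bpv = (n_samples + 3) // 4
    if raw.size != bpv * n_variants:
        raise PlinkFormatError(
            f"{path}: byte {3 + raw.size}: expected {bpv * n_variants} data bytes, "
            f"got {raw.size}")
    raw = raw.reshape(n_variants, bpv)
    codes = np.empty((n_variants, bpv * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    return _CODE_TO_DOSAGE[codes[:, :n_samples]].T.copy()


# ---------------------------------------------------------------------------
# QC primitives
# ---------------------------------------------------------------------------

def variant_call_rate(gm: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-variant fraction of non-missing genotype calls, in [0, 1]."""
    d = gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    if d.shape[0] < 1:
        raise ValueError("call rate needs at least one sample")
    return (d != MISSING).mean(axis=0)


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed minor-allele count and sums the probabilities
    of all heterozygote counts at most as probable as the observed one
    (two-sided, by probability ordering). Valid deep in the tail where the
    chi-square approximation breaks down for rare alleles. Monomorphic
    samples return 1.
    """
    if n_hom1 < 0 or n_het < 0 or n_hom2 < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotype required")
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if n_minor == 0:
        return 1.0
    # possible het counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = _hwe_log_prob(hets, n_minor, n)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _hwe_log_prob(n_het: np.ndarray, n_minor: int, n: int) -> np.ndarray:
    """Log P(het count | minor-allele count) up to a shared constant."""
    n_hom_minor = (n_minor - n_het) // 2
    n_hom_major = n - n_het - n_hom_minor
    return (n_het * np.log(2.0)
            - gammaln(n_het + 1) - gammaln(n_hom_minor + 1) - gammaln(n_hom_major + 1))


def hwe_chisq_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """1-df chi-square Hardy-Weinberg test (cross-check for the exact test)."""
    if n_hom1 < 0 or n_het < 0 or n_hom2 < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotype required")
    p = (2 * n_hom1 + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p)**2])
    obs = np.array([n_hom1, n_het, n_hom2])
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def _genotype_counts(dosages: np.ndarray) -> np.ndarray:
    """Counts of (hom allele1, het, hom allele2) per variant, shape (m, 3)."""
    return np.stack([(dosages == 0).sum(axis=0),
                     (dosages == 1).sum(axis=0),
                     (dosages == 2).sum(axis=0)], axis=1)


def qc_filter(
    cohorts: list[GenotypeMatrix],
    call_rate_min: float = 0.99,
    hwe_alpha: float = 1e-8,
    control_cohorts: list[int] | None = None,
    exact_hwe: bool = True,
):
    """Filter variants across cohorts; returns (filtered cohorts, QCReport).

    A variant is kept iff (in this order, each variant counted at its first
    failing filter): present in every cohort; call rate >= ``call_rate_min``
    in every cohort; Hardy-Weinberg exact p >= ``hwe_alpha`` in the pooled
    control cohorts (``control_cohorts`` gives their indices; default all).
    """
    if not cohorts:
        raise ValueError("at least one cohort required")
    if not 0 <= call_rate_min <= 1:
        raise ValueError("call_rate_min must be in [0, 1]")
    if not 0 < hwe_alpha <= 1:
        raise ValueError("hwe_alpha must be in (0, 1]")
    if control_cohorts is None:
        control_cohorts = list(range(len(cohorts)))

    all_ids = [c.variant_ids for c in cohorts]
    union: dict[str, None] = {}
    for ids in all_ids:
        for v in ids:
            union.setdefault(v, None)
    n_input = len(union)
    shared = set(all_ids[0])
    for ids in all_ids[1:]:
        shared &= set(ids)
    n_not_shared = n_input - len(shared)

    # align every cohort to the shared variants in cohort-0 order
    order = [v for v in all_ids[0] if v in shared]
    aligned = [c.take_variants(_positions(c.variant_ids, order)) for c in cohorts]

    cr_ok = np.ones(len(order), dtype=bool)
    for c in aligned:
        cr_ok &= variant_call_rate(c) >= call_rate_min
    n_call_rate = int((~cr_ok).sum())

    pooled = np.vstack([aligned[i].dosages for i in control_cohorts])
    counts = _genotype_counts(pooled)
    test = hwe_exact_test if exact_hwe else hwe_chisq_test
    hwe_ok = np.ones(len(order), dtype=bool)
    for j in np.flatnonzero(cr_ok):
        hwe_ok[j] = test(*counts[j]) >= hwe_alpha
    n_hwe = int((cr_ok & ~hwe_ok).sum())

    keep = np.flatnonzero(cr_ok & hwe_ok)
    if keep.size == 0:
        warnings.warn("no variants survive QC; returning empty matrices")
    report = QCReport(
        n_input_variants=n_input,
        n_removed_not_shared=n_not_shared,
        n_removed_by_call_rate=n_call_rate,
        n_removed_by_hwe=n_hwe,
        n_retained=int(keep.size),
    )
    return [c.take_variants(keep) for c in aligned], report


def _positions(ids: np.ndarray, order: list[str]) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(ids)}
    return np.array([lookup[v] for v in order], dtype=int)


def compute_maf(gm: GenotypeMatrix | np.ndarray) -> pd.DataFrame:
    """Per-variant minor allele frequency, copy count and minor-allele side.

    Frequencies are computed over non-missing alleles only. A MAF of exactly
    0.5 is attributed to allele2 as the minor allele (deterministic
    tie-break). Variants with every genotype missing get MAF = NaN and
    ``defined`` = False; they are excluded from downstream categorization.

    Returns a DataFrame with columns maf, mac, minor_is_allele2, defined.
    """
    d = gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    nonmiss = (d != MISSING)
    n_called = nonmiss.sum(axis=0)
    copies2 = np.where(nonmiss, d, 0).sum(axis=0)
    total = 2 * n_called
    with np.errstate(divide="ignore", invalid="ignore"):
        freq2 = np.where(total > 0, copies2 / np.maximum(total, 1), np.nan)
    minor_is_allele2 = freq2 <= 0.5
    maf = np.where(minor_is_allele2, freq2, 1.0 - freq2)
    mac = np.where(minor_is_allele2, copies2, total - copies2)
    defined = total > 0
    maf = np.where(defined, maf, np.nan)
    return pd.DataFrame({
        "maf": maf,
        "mac": mac.astype(int),
        "minor_is_allele2": minor_is_allele2,
        "defined": defined,
    })
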