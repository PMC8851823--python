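"""Genotype input/output and per-SNP summaries.

Genotypes are held as a samples x SNPs matrix of diploid dosages counting
copies of the **reference** allele (0, 1, 2), with :data:`MISSING` (-1) for
no-calls.  The opposing-homozygote statistic downstream is symmetric under
allele relabelling, so the choice of counted allele is inert, but it is fixed
here and used consistently by the VCF reader/writer and the simulator.

Positions are 1-based as in VCF; chromosome names are kept as strings.  The
default autosome set is the pig autosomes "1".."18" (the design this tool
was built around), overridable everywhere it is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call.
MISSING: int = -1

#: Pig autosomes; the default chromosome set for autosomal filtering.
PIG_AUTOSOMES: frozenset[str] = frozenset(str(c) for c in range(1, 19))

#: Sample roles in a crossbreeding design.
ROLES = ("SIRE", "DAM", "OFFSPRING")

#: Missing-data tokens recognised in text dosage tables.
DEFAULT_MISSING_TOKENS = ("NA", "-9")


class GenotypeFormatError(ValueError):
    """Raised for malformed or empty genotype input."""


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with its SNP map.

    Parameters
    ----------
    samples
        Ordered unique sample identifiers (rows of ``calls``).
    snps
        DataFrame with columns ``snp_id``, ``chrom``, ``pos`` (1-based bp),
        one row per SNP in column order of ``calls``.
    calls
        ``int8`` array of shape ``(n_samples, n_snps)`` with values in
        {0, 1, 2, MISSING}, counting reference-allele copies.
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.samples = list(self.samples)
        if self.calls.ndim != 2:
            raise GenotypeFormatError("calls must be 2-D (samples x SNPs)")
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise GenotypeFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeFormatError("sample identifiers must be unique")
        if self.snps["snp_id"].duplicated().any():
            raise GenotypeFormatError("snp identifiers must be unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeFormatError(
                f"{bad.sum()} calls outside {{0,1,2,{MISSING}}}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        """Return a matrix restricted to ``keep`` (in the given order)."""
        idx = [self.sample_index(s) for s in keep]
        return GenotypeMatrix(list(keep), self.snps.reset_index(drop=True),
                              self.calls[idx])

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a matrix restricted to SNPs where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.samples,
            self.snps.loc[mask].reset_index(drop=True),
            self.calls[:, mask],
        )


@dataclass
class SampleRoles:
    """Mapping of every sample to its role in the design.

    Roles partition pairs into the six relationship groups (dam-offspring,
    sire-offspring, offspring-offspring, dam-dam, sire-sire, sire-dam).
    """

    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, r in self.roles.items():
            if r not in ROLES:
                raise ValueError(f"unknown role {r!r} for sample {s!r}")

    def __getitem__(self, sample_id: str) -> str:
        return self.roles[sample_id]

    def validate_against(self, g: GenotypeMatrix) -> None:
        missing = [s for s in g.samples if s not in self.roles]
        if missing:
            raise ValueError(f"samples without a role: {missing[:5]}...")


def read_roles(path: str | Path) -> SampleRoles:
    """Read a two-column TSV (sample_id, role) with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "role"} <= set(df.columns):
        raise GenotypeFormatError("roles file needs columns sample_id, role")
    return SampleRoles(dict(zip(df["sample_id"], df["role"].str.upper())))


def write_roles(roles: SampleRoles, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(roles.roles), "role": list(roles.roles.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid biallelic genotypes from a VCF into a GenotypeMatrix.

    Multiallelic records are skipped (the exclusion statistic is defined for
    biallelic SNPs); the number skipped is logged.  Dosage counts REF copies:
    0/0 -> 2, 0/1 -> 1, 1/1 -> 0, ./. -> MISSING.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    snp_rows: list[tuple[str, str, int]] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(rec.gt_types)
        dosage = (2 - gt).astype(np.int8)
        dosage[gt == 3] = MISSING
        rows.append(dosage)
        snp_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        snp_rows.append((snp_id, str(rec.CHROM), int(rec.POS)))
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic records", n_skipped)
    if not snp_rows:
        raise GenotypeFormatError("no biallelic SNPs in VCF")
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"])
    calls = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, snps, calls)


_GT_BY_DOSAGE = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal VCF 4.2 file (GT only, A/C alleles)."""
    chroms = pd.unique(g.snps["chrom"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j, row in enumerate(g.snps.itertuples(index=False)):
            gts = "\t".join(_GT_BY_DOSAGE[int(d)] for d in g.calls[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\tA\tC\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Text dosage tables
# ---------------------------------------------------------------------------

def read_dosage_table(
    path: str | Path,
    map_path: str | Path,
    orientation: str = "snps-by-samples",
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> GenotypeMatrix:
    """Read a whitespace-delimited 0/1/2 dosage table plus a 3-column SNP map.

    The table has a header of column identifiers and a first column of row
    identifiers.  ``orientation`` is ``"snps-by-samples"`` (rows are SNPs; the
    PLINK transposed convention) or ``"samples-by-snps"``.  The map file is
    header-less whitespace-delimited ``snp_id chrom pos``.

    Entries equal to one of ``missing_tokens`` become :data:`MISSING`.
    """
    if orientation not in ("snps-by-samples", "samples-by-snps"):
        raise ValueError(f"unknown orientation {orientation!r}")
    snp_map = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["snp_id", "chrom", "pos"],
        dtype={"snp_id": str, "chrom": str, "pos": int},
    )
    df = pd.read_csv(path, sep=r"\s+", index_col=0, dtype=str,
                     keep_default_na=False)
    df = df.replace({tok: str(MISSING) for tok in missing_tokens})
    try:
        values = df.to_numpy(dtype=np.int8)
    except ValueError as exc:
        raise GenotypeFormatError(f"non-numeric dosage entry: {exc}") from exc
    if orientation == "snps-by-samples":
        snp_ids = [str(i) for i in df.index]
        samples = [str(c) for c in df.columns]
        values = values.T
    else:
        samples = [str(i) for i in df.index]
        snp_ids = [str(c) for c in df.columns]
    if len(snp_ids) != len(snp_map):
        raise GenotypeFormatError(
            f"table has {len(snp_ids)} SNPs but map has {len(snp_map)}"
        )
    if list(snp_map["snp_id"]) != snp_ids:
        raise GenotypeFormatError("SNP order in table and map differ")
    return GenotypeMatrix(samples, snp_map, values)


def write_dosage_table(
    g: GenotypeMatrix, path: str | Path, map_path: str | Path,
    missing_token: str = "NA",
) -> None:
    """Write the matrix as a SNPs-by-samples dosage table + SNP map."""
    df = pd.DataFrame(g.calls.T.astype(object), index=g.snps["snp_id"],
                      columns=g.samples)
    df = df.where(df != MISSING, missing_token)
    df.index.name = "snp_id"
    df.to_csv(path, sep="\t")
    g.snps.to_csv(map_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Summaries and filters
# ---------------------------------------------------------------------------

def snp_summaries(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate and minor-allele frequency.

    Returns a DataFrame with columns ``snp_id``, ``chrom``, ``pos``,
    ``call_rate``, ``maf``.  MAF is computed over non-missing calls only and
    is NaN for SNPs with no calls (``call_rate`` 0).
    """
    observed = g.calls != MISSING
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / g.n_samples if g.n_samples else np.zeros(g.n_snps)
    ref_copies = np.where(observed, g.calls, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ref = np.where(n_obs > 0, ref_copies / (2.0 * n_obs), np.nan)
    maf = np.minimum(p_ref, 1.0 - p_ref)
    out = g.snps.copy()
    out["call_rate"] = call_rate
    out["maf"] = maf
    return out


def filter_snps(
    g: GenotypeMatrix,
    min_call_rate: float = 0.0,
    chromosomes: Iterable[str] | None = None,
) -> GenotypeMatrix:
    """Keep SNPs with call rate >= threshold and chromosome in the given set.

    ``chromosomes=None`` keeps all chromosomes.  SNP order is preserved; an
    empty result is permitted (with a warning).
    """
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError("min_call_rate must be in [0, 1]")
    summ = snp_summaries(g)
    mask = summ["call_rate"].to_numpy() >= min_call_rate
    if chromosomes is not None:
        chrom_set = {str(c) for c in chromosomes}
        mask &= g.snps["chrom"].astype(str).isin(chrom_set).to_numpy()
    if not mask.any():
        logger.warning("filter_snps removed every SNP")
    return g.subset_snps(mask)
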