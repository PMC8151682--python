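"""Genotype and phenotype I/O, quality control, and minor-allele orientation.

Genotypes are held as a dense ``samples x SNPs`` matrix of allele-copy codes
0/1/2 with -1 for missing, alongside a per-SNP metadata table.  Before
orientation the code counts copies of the B/ALT allele as read from the
source file; :func:`orient_minor_allele` re-expresses every SNP as copies of
its minor ("effect") allele, the convention all downstream effect estimates
use.

QC mirrors standard array workflows: keep autosomes 1-28, drop SNPs with a
call rate below 99%, then drop animals with a call rate below 95%.  There is
deliberately no minor-allele-frequency filter; monomorphic SNPs survive QC
(flagged via ``ea_freq == 0``) and are skipped later by the selection and
effect stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b", "ea", "oa", "ea_freq"]

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeMatrix",
    "QcReport",
    "read_genotypes",
    "read_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "apply_qc",
    "orient_minor_allele",
    "naive_impute",
    "ea_freq_from_counts",
]


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one biallelic SNP.

    ``ea``/``oa`` (effect = minor, other = major allele) and ``ea_freq`` are
    filled by :func:`orient_minor_allele`; before orientation they are None.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    ea: str | None = None
    oa: str | None = None
    ea_freq: float | None = None


@dataclass
class GenotypeMatrix:
    """Dense genotype codes plus per-SNP metadata.

    Attributes
    ----------
    sample_ids : list of str
    snps : DataFrame with columns ``snp_id chrom pos allele_a allele_b ea oa ea_freq``
    codes : int8 array, shape (n_samples, n_snps); -1 encodes a missing call
    oriented : True once codes count copies of the minor (effect) allele
    """

    sample_ids: list
    snps: pd.DataFrame
    codes: np.ndarray
    oriented: bool = False

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if not set(SNP_COLUMNS) <= set(self.snps.columns):
            missing = set(SNP_COLUMNS) - set(self.snps.columns)
            raise ValueError(f"snps table lacks columns: {sorted(missing)}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids), self.snps.copy(), self.codes.copy(), self.oriented
        )

    def take_snps(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.sample_ids),
            self.snps.iloc[idx].reset_index(drop=True),
            self.codes[:, idx],
            self.oriented,
        )

    def take_samples(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], self.snps.copy(), self.codes[idx], self.oriented
        )


def _empty_snp_table(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=SNP_COLUMNS)
    return df


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or TSV, dispatching on extension."""
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF (GT field only).

    Multi-allelic and non-SNP records are skipped; the skipped count is
    logged and stored on the returned matrix as ``skipped_records``.
    Codes count ALT copies (``0/0`` -> 0, ``0/1`` -> 1, ``1/1`` -> 2,
    ``./.`` -> missing); the matrix is returned unoriented.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    records, cols = [], []
    skipped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        codes = var.gt_types.astype(np.int8)  # gts012: 0,1,2, 3=missing
        codes[codes == 3] = MISSING
        cols.append(codes)
        records.append(
            dict(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM),
                pos=int(var.POS),
                allele_a=var.REF,
                allele_b=alts[0],
                ea=None,
                oa=None,
                ea_freq=np.nan,
            )
        )
    vcf.close()
    if skipped:
        logger.warning("skipped %d multi-allelic or non-SNP VCF records", skipped)
    codes = np.column_stack(cols) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    g = GenotypeMatrix(samples, _empty_snp_table(records), codes, oriented=False)
    g.skipped_records = skipped
    return g


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read the package's TSV layout: metadata rows ``#chrom``/``#pos``/
    ``#alleles`` then one row per sample; columns are SNP ids, cells 0/1/2/NA."""
    meta = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.startswith("#"):
                break
            key, *vals = line.rstrip("\n").split("\t")
            meta[key] = vals
    snp_ids = header[1:]
    df = pd.read_csv(path, sep="\t", comment="#", dtype={header[0]: str}, na_values=["NA"])
    sample_ids = df.iloc[:, 0].tolist()
    codes = df.iloc[:, 1:].to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    chroms = meta.get("#chrom", ["0"] * len(snp_ids))
    poss = meta.get("#pos", ["0"] * len(snp_ids))
    alleles = meta.get("#alleles", ["A/B"] * len(snp_ids))
    records = []
    for i, sid in enumerate(snp_ids):
        a, b = alleles[i].split("/")
        records.append(
            dict(
                snp_id=sid, chrom=str(chroms[i]), pos=int(poss[i]),
                allele_a=a, allele_b=b, ea=None, oa=None, ea_freq=np.nan,
            )
        )
    return GenotypeMatrix(sample_ids, _empty_snp_table(records), codes, oriented=False)


def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(g.snps["snp_id"]) + "\n")
        fh.write("#chrom\t" + "\t".join(map(str, g.snps["chrom"])) + "\n")
        fh.write("#pos\t" + "\t".join(map(str, g.snps["pos"])) + "\n")
        fh.write(
            "#alleles\t"
            + "\t".join(a + "/" + b for a, b in zip(g.snps["allele_a"], g.snps["allele_b"]))
            + "\n"
        )
        for i, sid in enumerate(g.sample_ids):
            row = ["NA" if c == MISSING else str(int(c)) for c in g.codes[i]]
            fh.write(str(sid) + "\t" + "\t".join(row) + "\n")


PHENO_FACTORS = ["hen_id", "generation", "line", "sire_id"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype CSV (hen_id, generation, line, sire_id, traits...)."""
    df = pd.read_csv(path, dtype={"hen_id": str, "sire_id": str})
    missing = [c for c in PHENO_FACTORS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns: {missing}")
    if df["hen_id"].duplicated().any():
        raise ValueError("duplicate hen_id in phenotype file")
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QcReport:
    """Counts removed/retained at each QC step, in the order applied."""

    n_snps_in: int
    n_samples_in: int
    n_snps_nonautosomal: int
    n_snps_low_call_rate: int
    n_samples_low_call_rate: int
    n_snps_out: int
    n_samples_out: int
    snp_call_rate: float
    animal_call_rate: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("input SNPs", self.n_snps_in),
                ("input animals", self.n_samples_in),
                ("removed: non-autosomal SNPs", self.n_snps_nonautosomal),
                (f"removed: SNP call rate < {self.snp_call_rate}", self.n_snps_low_call_rate),
                (
                    f"removed: animal call rate < {self.animal_call_rate}",
                    self.n_samples_low_call_rate,
                ),
                ("retained SNPs", self.n_snps_out),
                ("retained animals", self.n_samples_out),
            ],
            columns=["step", "count"],
        )


def apply_qc(
    g: GenotypeMatrix,
    snp_call_rate: float = 0.99,
    animal_call_rate: float = 0.95,
    autosomes=tuple(str(c) for c in range(1, 29)),
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs and animals by chromosome and call rate.

    Order: non-autosomal SNPs out first, then SNPs below ``snp_call_rate``,
    then animals below ``animal_call_rate`` (animal rates computed on the
    surviving SNPs).  Raises if nothing survives.
    """
    autosomes = {str(a) for a in autosomes}
    n_snps_in, n_samples_in = g.n_snps, g.n_samples

    auto_mask = g.snps["chrom"].astype(str).isin(autosomes).to_numpy()
    g1 = g.take_snps(auto_mask)

    called = g1.codes != MISSING
    snp_rate = called.mean(axis=0) if g1.n_samples else np.zeros(g1.n_snps)
    snp_mask = snp_rate >= snp_call_rate
    g2 = g1.take_snps(snp_mask)

    called2 = g2.codes != MISSING
    animal_rate = called2.mean(axis=1) if g2.n_snps else np.zeros(g2.n_samples)
    sample_mask = animal_rate >= animal_call_rate
    g3 = g2.take_samples(sample_mask)

    if g3.n_snps == 0 or g3.n_samples == 0:
        raise ValueError("QC removed all SNPs or all animals")

    report = QcReport(
        n_snps_in=n_snps_in,
        n_samples_in=n_samples_in,
        n_snps_nonautosomal=int((~auto_mask).sum()),
        n_snps_low_call_rate=int((~snp_mask).sum()),
        n_samples_low_call_rate=int((~sample_mask).sum()),
        n_snps_out=g3.n_snps,
        n_samples_out=g3.n_samples,
        snp_call_rate=snp_call_rate,
        animal_call_rate=animal_call_rate,
    )
    logger.info("QC: %s", report)
    return g3, report


# ---------------------------------------------------------------------------
# orientation and imputation
# ---------------------------------------------------------------------------


def ea_freq_from_counts(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Effect-allele (B) frequency from genotype counts: (n_AB + 2 n_BB) / 2N."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return float("nan")
    return (n_ab + 2 * n_bb) / (2 * n)


def orient_minor_allele(g: GenotypeMatrix) -> GenotypeMatrix:
    """Re-express every SNP as copies of its minor (effect) allele.

    The allele with sample frequency <= 0.5 among non-missing calls becomes
    the effect allele; codes are flipped ``c -> 2 - c`` where the B allele is
    currently the major one.  Exact 0.5 ties resolve to the lexicographically
    smaller allele string so the choice is deterministic across formats.
    Monomorphic SNPs are retained with ``ea_freq`` 0 and a warning.
    Already-oriented matrices are returned unchanged (idempotent).
    """
    if g.oriented:
        return g.copy()
    out = g.copy()
    codes = out.codes
    missing = codes == MISSING
    valid = np.where(missing, 0, codes).astype(float)
    n_called = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        b_freq = np.where(n_called > 0, valid.sum(axis=0) / (2 * np.maximum(n_called, 1)), np.nan)

    snps = out.snps
    ea, oa, eaf = [], [], []
    n_mono = 0
    for j in range(out.n_snps):
        a, b = snps.at[j, "allele_a"], snps.at[j, "allele_b"]
        f = b_freq[j]
        if np.isnan(f):
            flip = False  # no calls at all; keep B as effect allele by convention
            f = 0.0
        elif f < 0.5:
            flip = False
        elif f > 0.5:
            flip = True
        else:  # exact tie: effect allele = lexicographically smaller string
            flip = min(a, b) == a
        if flip:
            col = codes[:, j]
            keep_missing = col == MISSING
            codes[:, j] = 2 - col
            codes[keep_missing, j] = MISSING
            ea.append(a), oa.append(b), eaf.append(1.0 - f)
        else:
            ea.append(b), oa.append(a), eaf.append(f)
        if eaf[-1] == 0.0:
            n_mono += 1
    if n_mono:
        logger.warning("%d monomorphic SNPs retained with ea_freq 0", n_mono)
    snps["ea"], snps["oa"], snps["ea_freq"] = ea, oa, eaf
    out.oriented = True
    return out


def naive_impute(g: GenotypeMatrix, lines=None, seed: int = 0) -> GenotypeMatrix:
    """Fill missing calls by sampling from within-line genotype frequencies.

    This is a deliberately simple, self-contained imputation: each missing
    call is drawn from the empirical distribution of the observed 0/1/2
    codes of that SNP within the animal's layer line (overall frequencies
    when ``lines`` is None or a line has no observed calls for the SNP).
    It preserves marginal genotype frequencies but, unlike haplotype-based
    imputation, uses no linkage information.
    """
    rng = np.random.default_rng(seed)
    out = g.copy()
    codes = out.codes
    if lines is None:
        line_arr = np.zeros(out.n_samples, dtype=int)
    else:
        _, line_arr = np.unique(np.asarray(lines), return_inverse=True)
        if len(line_arr) != out.n_samples:
            raise ValueError("lines length does not match sample count")
    n_fallback = 0
    for j in range(out.n_snps):
        col = codes[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs_all = col[~miss]
        overall = np.bincount(obs_all, minlength=3).astype(float) if obs_all.size else None
        for line_id in np.unique(line_arr[miss]):
            sel = miss & (line_arr == line_id)
            obs = col[(~miss) & (line_arr == line_id)]
            if obs.size:
                freq = np.bincount(obs, minlength=3).astype(float)
            elif overall is not None:
                freq = overall
                n_fallback += 1
            else:
                raise ValueError(f"SNP {out.snps.at[j, 'snp_id']} has no observed calls")
            freq = freq / freq.sum()
            codes[sel, j] = rng.choice(3, size=int(sel.sum()), p=freq)
    if n_fallback:
        logger.warning(
            "%d SNP/line cells had no observed calls; fell back to overall frequencies",
            n_fallback,
        )
    return out
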