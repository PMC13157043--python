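"""Readers and writers for PLINK1 binary genotypes and the pipeline's TSV formats.

Conventions used throughout the package:

* ``allele1`` in every variant table is the **counted / effect** allele:
  genotype values are the number of ``allele1`` copies an individual carries.
  Note that this differs from the common PLINK usage where A1 is the minor
  allele; here the orientation is fixed by the effect allele of the score.
* Positions are 1-based (PLINK/VCF convention).
* Missing genotype calls are stored as :data:`MISSING` (``-1``) in ``int8``
  count matrices and serialized with the PLINK ``01`` two-bit code.
* All TSV artifacts are tab-delimited UTF-8 with a header row.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "KinshipTable",
    "PlinkFormatError",
    "ValidationError",
    "read_plink",
    "write_plink",
    "read_summary_stats",
    "write_summary_stats",
    "read_phenotypes",
    "write_phenotypes",
    "read_kinship",
    "write_kinship",
]

#: Sentinel for a missing genotype call in ``counts`` matrices.
MISSING = -1

_PLINK_MAGIC = bytes((0x6C, 0x1B))
_SNP_MAJOR = 0x01

# PLINK 2-bit codes, least-significant bits first within each byte:
# 00 -> homozygous allele1 (count 2), 01 -> missing, 10 -> het, 11 -> hom allele2.
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = np.zeros(4, dtype=np.uint8)
_COUNT_TO_CODE[2] = 0
_COUNT_TO_CODE[1] = 2
_COUNT_TO_CODE[0] = 3
# index 3 doubles as the slot for MISSING (-1) via counts % 4 -> 3
_COUNT_TO_CODE[3] = 1

VARIANT_COLUMNS = ["variant_id", "chromosome", "position", "allele1", "allele2"]

_VALID_ALLELES = frozenset("ACGT")


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam triple is malformed."""


class ValidationError(ValueError):
    """Raised when file contents violate a domain invariant."""


def _check_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing_cols:
        raise ValidationError(f"variant table missing columns: {missing_cols}")
    variants = variants[VARIANT_COLUMNS].reset_index(drop=True)
    pos = variants["position"].to_numpy()
    if (pos < 1).any():
        raise ValidationError("variant positions must be >= 1 (1-based)")
    for col in ("allele1", "allele2"):
        bad = ~variants[col].isin(list(_VALID_ALLELES))
        if bad.any():
            offender = variants.loc[bad, "variant_id"].iloc[0]
            raise ValidationError(
                f"non-biallelic-SNV allele in column {col!r} at variant {offender!r}"
            )
    same = variants["allele1"] == variants["allele2"]
    if same.any():
        offender = variants.loc[same, "variant_id"].iloc[0]
        raise ValidationError(f"allele1 == allele2 at variant {offender!r}")
    return variants


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x variants allele1-count matrix with variant metadata.

    ``counts[i, j]`` is the number of copies of ``variants.allele1[j]``
    carried by ``samples[i]``; values are 0, 1, 2 or :data:`MISSING`.
    """

    samples: list[str]
    variants: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        self.variants = _check_variant_table(self.variants)
        n, m = self.counts.shape
        if n != len(self.samples):
            raise ValidationError(
                f"counts has {n} rows but {len(self.samples)} samples"
            )
        if m != len(self.variants):
            raise ValidationError(
                f"counts has {m} columns but {len(self.variants)} variants"
            )
        valid = np.isin(self.counts, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValidationError("genotype counts must be 0, 1, 2 or MISSING")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    def select_variants(self, index) -> "GenotypeMatrix":
        """Subset to the given variant positions (integer indices), preserving order."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            counts=self.counts[:, index],
        )

    def select_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            variants=self.variants.copy(),
            counts=self.counts[index, :],
        )


# ---------------------------------------------------------------------------
# PLINK1 binary
# ---------------------------------------------------------------------------

def _ext(prefix: Path, suffix: str) -> Path:
    return prefix.parent / (prefix.name + suffix)


def _bed_payload_bytes(n_samples: int, n_variants: int) -> int:
    return ((n_samples + 3) // 4) * n_variants


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK1 ``.bed``/``.bim``/``.fam`` triple (SNP-major mode only)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        _ext(prefix, ".bim"),
        sep="\t",
        header=None,
        names=["chromosome", "variant_id", "cm", "position", "allele1", "allele2"],
        dtype={"chromosome": str, "variant_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        _ext(prefix, ".fam"),
        sep="\t",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    samples = fam["iid"].tolist()
    variants = bim[["variant_id", "chromosome", "position", "allele1", "allele2"]]

    raw = _ext(prefix, ".bed").read_bytes()
    if raw[:2] != _PLINK_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if len(raw) < 3 or raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{prefix}.bed: unsupported mode byte (need SNP-major 0x01)")
    n, m = len(samples), len(variants)
    expected = _bed_payload_bytes(n, m)
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: payload is {payload.size} bytes, expected {expected} "
            f"for {n} samples x {m} variants"
        )
    if m == 0:
        counts = np.zeros((n, 0), dtype=np.int8)
    else:
        per_variant = payload.reshape(m, -1)
        # unpack 2-bit codes, low bits first
        codes = np.empty((m, per_variant.shape[1] * 4), dtype=np.uint8)
        for slot in range(4):
            codes[:, slot::4] = (per_variant >> (2 * slot)) & 0x03
        counts = _CODE_TO_COUNT[codes[:, :n]].T.copy()
    return GenotypeMatrix(samples=samples, variants=variants, counts=counts)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as PLINK1 ``.bed``/``.bim``/``.fam``.

    Round-trips exactly through :func:`read_plink`, including missing calls.
    The .bim genetic-distance column is written as 0.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    try:
        bim = pd.DataFrame(
            {
                "chromosome": g.variants["chromosome"],
                "variant_id": g.variants["variant_id"],
                "cm": 0,
                "position": g.variants["position"],
                "allele1": g.variants["allele1"],
                "allele2": g.variants["allele2"],
            }
        )
        bim.to_csv(_ext(prefix, ".bim"), sep="\t", header=False, index=False)
        fam = pd.DataFrame(
            {
                "fid": g.samples,
                "iid": g.samples,
                "pat": 0,
                "mat": 0,
                "sex": 0,
                "pheno": -9,
            }
        )
        fam.to_csv(_ext(prefix, ".fam"), sep="\t", header=False, index=False)

        n, m = g.counts.shape
        n_padded = ((n + 3) // 4) * 4
        codes = np.full((m, n_padded), 0, dtype=np.uint8)  # pad slots -> code 0
        codes[:, :n] = _COUNT_TO_CODE[g.counts.T % 4]
        # pad slots must be zero bits per the PLINK spec
        codes[:, n:] = 0
        packed = np.zeros((m, n_padded // 4), dtype=np.uint8)
        for slot in range(4):
            packed |= codes[:, slot::4] << (2 * slot)
        with open(_ext(prefix, ".bed"), "wb") as fh:
            fh.write(_PLINK_MAGIC)
            fh.write(bytes((_SNP_MAJOR,)))
            fh.write(packed.tobytes())
    except OSError as exc:
        raise OSError(f"writing PLINK files at prefix {prefix}: {exc}") from exc


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "P"]


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV (SNP, CHR, POS, A1, A2, BETA, SE, P).

    Returns a DataFrame in file order. Rejects missing columns, non-numeric
    BETA/SE/P (with the offending row number), duplicate SNP IDs, SE <= 0 and
    P outside (0, 1].
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {missing}")
    df = df[SUMMARY_COLUMNS].copy()
    for col in ("BETA", "SE", "P"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
            raise ValidationError(f"{path}: non-numeric {col} at file row {row}")
        df[col] = vals.astype(float)
    dup = df["SNP"].duplicated()
    if dup.any():
        ids = df.loc[dup, "SNP"].unique().tolist()
        raise ValidationError(f"{path}: duplicate SNP ID(s): {ids}")
    if ((df["P"] <= 0) | (df["P"] > 1)).any():
        offender = df.loc[(df["P"] <= 0) | (df["P"] > 1), "SNP"].iloc[0]
        raise ValidationError(f"{path}: P must be in (0, 1] (variant {offender!r})")
    if (df["SE"] <= 0).any():
        offender = df.loc[df["SE"] <= 0, "SNP"].iloc[0]
        raise ValidationError(f"{path}: SE must be > 0 (variant {offender!r})")
    return df


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """Write summary statistics losslessly (17 significant digits)."""
    stats[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype/covariate TSV keyed by IID; IIDs must be unique."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"IID": str})
    if "IID" not in df.columns:
        raise ValidationError(f"{path}: phenotype table needs an IID column")
    if df["IID"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample IDs in phenotype table")
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

class KinshipTable:
    """Sparse symmetric kinship coefficients; absent pairs have kinship 0."""

    def __init__(self, entries: dict[tuple[str, str], float] | None = None):
        self._entries: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), k in entries.items():
                self.add(a, b, k)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, kinship: float) -> None:
        if a == b:
            raise ValidationError(f"self-pair in kinship table: {a!r}")
        if not 0.0 <= kinship <= 0.5:
            raise ValidationError(
                f"kinship for pair ({a!r}, {b!r}) outside [0, 0.5]: {kinship}"
            )
        self._entries[self._key(a, b)] = float(kinship)

    def lookup(self, a: str, b: str) -> float:
        """Symmetric lookup; unknown pairs return 0. Self-lookup returns 0.5."""
        if a == b:
            return 0.5
        return self._entries.get(self._key(a, b), 0.0)

    def pairs(self):
        """Iterate (id_a, id_b, kinship) in deterministic sorted order."""
        for (a, b) in sorted(self._entries):
            yield a, b, self._entries[(a, b)]

    def __len__(self) -> int:
        return len(self._entries)


def read_kinship(path: str | Path) -> KinshipTable:
    """Read sparse kinship triplets (ID_A, ID_B, KINSHIP)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"ID_A": str, "ID_B": str})
    for col in ("ID_A", "ID_B", "KINSHIP"):
        if col not in df.columns:
            raise ValidationError(f"{path}: kinship table needs column {col}")
    table = KinshipTable()
    for a, b, k in zip(df["ID_A"], df["ID_B"], df["KINSHIP"].astype(float)):
        table.add(a, b, k)
    return table


def write_kinship(table: KinshipTable, path: str | Path) -> None:
    rows = list(table.pairs())
    df = pd.DataFrame(rows, columns=["ID_A", "ID_B", "KINSHIP"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
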