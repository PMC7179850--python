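"""PLINK 1.9 genotype I/O and the central in-memory genotype container.

Genotypes are held as a dense ``samples x SNPs`` matrix of minor-allele
dosages (0, 1, 2) with ``-1`` marking a missing call.  The missing sentinel
is deliberately out-of-band so that monomorphic-SNP detection is never
confused by missingness.  Both the binary (``.bed/.bim/.fam``, SNP-major)
and text (``.ped/.map``) dialects are supported; readers accept tab or
space delimiters.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

BED_MAGIC = bytes([0x6C, 0x1B])
BED_SNP_MAJOR = 0x01

# 2-bit genotype codes of the PLINK 1.9 .bed format, low-order bits first:
# 0b00 = homozygous allele1 (dosage 2), 0b01 = missing, 0b10 = het,
# 0b11 = homozygous allele2 (dosage 0).
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

SNP_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
SAMPLE_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


class PlinkFormatError(ValueError):
    """Raised when a PLINK file violates the format specification."""


@dataclass
class GenotypeData:
    """Sample-by-SNP dosage matrix plus SNP map and sample records.

    Attributes
    ----------
    dosages : (n_samples, n_snps) int8 array
        Minor-allele dosage in {0, 1, 2}; ``MISSING`` (-1) for no-calls.
    snps : DataFrame with columns chrom, snp, cm, pos, a1, a2
        ``a1`` is the allele counted by the dosage.
    samples : DataFrame with columns fid, iid, father, mother, sex, phenotype
        Phenotype codes: 1 = control, 2 = case, 0/-9 = missing.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        # int8 range check: valid codes are exactly MISSING (-1) and 0..2
        lo, hi = (int(self.dosages.min()), int(self.dosages.max())) \
            if self.dosages.size else (0, 0)
        if lo < MISSING or hi > 2:
            raise ValueError("dosage values must be in {0, 1, 2} or missing")
        if self.snps["snp"].duplicated().any():
            raise ValueError("SNP identifiers must be unique")
        if self.samples.duplicated(subset=["fid", "iid"]).any():
            raise ValueError("(family ID, individual ID) pairs must be unique")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["iid"])

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snps["snp"])

    def dosage_float(self, cols=None) -> np.ndarray:
        """Dosages as float64 with missing cells as NaN.

        ``cols`` restricts to the given SNP column positions before the
        conversion (cheaper than converting the whole matrix).
        """
        d = self.dosages if cols is None else self.dosages[:, cols]
        x = d.astype(np.float64)
        x[d == MISSING] = np.nan
        return x

    def allele1_frequency(self) -> np.ndarray:
        """Per-SNP frequency of allele1 among non-missing calls (NaN if none)."""
        x = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0

    def subset_samples(self, index) -> "GenotypeData":
        """Subset rows; ``index`` is positions or a boolean mask. Order kept."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeData(
            dosages=self.dosages[index],
            snps=self.snps.copy(),
            samples=self.samples.iloc[index].reset_index(drop=True),
        )

    def subset_snps(self, index) -> "GenotypeData":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeData(
            dosages=self.dosages[:, index],
            snps=self.snps.iloc[index].reset_index(drop=True),
            samples=self.samples.copy(),
        )

    def select_samples_by_iid(self, iids) -> "GenotypeData":
        pos = pd.Index(self.samples["iid"]).get_indexer(list(iids))
        if (pos < 0).any():
            missing = [i for i, p in zip(iids, pos) if p < 0]
            raise KeyError(f"unknown sample IDs: {missing[:5]}")
        return self.subset_samples(pos)

    def snp_positions(self, snp_ids) -> np.ndarray:
        pos = self.snp_ids.get_indexer(list(snp_ids))
        if (pos < 0).any():
            missing = [s for s, p in zip(snp_ids, pos) if p < 0]
            raise KeyError(f"unknown SNP IDs: {missing[:5]}")
        return pos

    def copy(self) -> "GenotypeData":
        return GenotypeData(self.dosages.copy(), self.snps.copy(), self.samples.copy())


@dataclass
class Pedigree:
    """Per-sample family/parent records; parent ID 0 marks a founder."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = ["fid", "iid", "father", "mother"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree table missing columns: {missing}")
        t = self.table
        ids = set(t["iid"].astype(str))
        for col in ("father", "mother"):
            refs = set(t[col].astype(str)) - {"0"}
            unresolved = refs - ids
            if unresolved:
                raise ValueError(
                    f"{col} references not present in pedigree: {sorted(unresolved)[:5]}"
                )

    @classmethod
    def from_samples(cls, samples: pd.DataFrame) -> "Pedigree":
        return cls(samples[["fid", "iid", "father", "mother"]].astype(str).copy())

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, sep=r"\s+", dtype=str))


def _canonical_minor_orientation(data: GenotypeData) -> GenotypeData:
    """Flip SNPs so allele1 is the minor allele (ties kept as written)."""
    freq = data.allele1_frequency()
    flip = np.nan_to_num(freq, nan=0.0) > 0.5
    if not flip.any():
        return data
    out = data.copy()
    cols = np.flatnonzero(flip)
    block = out.dosages[:, cols]
    miss = block == MISSING
    block = (2 - block).astype(np.int8)
    block[miss] = MISSING
    out.dosages[:, cols] = block
    a1 = out.snps.loc[cols, "a1"].copy()
    out.snps.loc[cols, "a1"] = out.snps.loc[cols, "a2"].values
    out.snps.loc[cols, "a2"] = a1.values
    return out


# ---------------------------------------------------------------------------
# binary dialect


def _pack_bed_body(dosages: np.ndarray) -> bytes:
    n, m = dosages.shape
    n_bytes = (n + 3) // 4
    codes = np.empty((n, m), dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[dosages == dosage] = code
    # pad samples up to a multiple of 4 with homozygous-a2 (code 0b11 per
    # PLINK convention the padding bits are zero; plink writes zeros)
    padded = np.zeros((n_bytes * 4, m), dtype=np.uint8)
    padded[:n] = codes
    padded = padded.T.reshape(m, n_bytes, 4)
    packed = (
        padded[:, :, 0]
        | (padded[:, :, 1] << 2)
        | (padded[:, :, 2] << 4)
        | (padded[:, :, 3] << 6)
    ).astype(np.uint8)
    return packed.tobytes()


def _unpack_bed_body(body: bytes, n_samples: int, n_snps: int) -> np.ndarray:
    n_bytes = (n_samples + 3) // 4
    expected = n_bytes * n_snps
    raw = np.frombuffer(body, dtype=np.uint8)
    if raw.size != expected:
        raise PlinkFormatError(
            f".bed body has {raw.size} bytes, expected {expected} "
            f"({n_snps} SNPs x {n_bytes} bytes)"
        )
    raw = raw.reshape(n_snps, n_bytes)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (raw[:, :, None] >> shifts) & 0b11  # (m, n_bytes, 4)
    codes = codes.reshape(n_snps, n_bytes * 4)[:, :n_samples]
    return _CODE_TO_DOSAGE[codes].T.copy()  # -> (n, m)


def _read_bim(path) -> pd.DataFrame:
    bim = pd.read_csv(
        path, sep=r"\s+", header=None, names=SNP_COLUMNS,
        dtype={"chrom": int, "snp": str, "cm": float, "pos": int, "a1": str, "a2": str},
    )
    return bim


def _read_fam(path) -> pd.DataFrame:
    fam = pd.read_csv(
        path, sep=r"\s+", header=None, names=SAMPLE_COLUMNS,
        dtype={"fid": str, "iid": str, "father": str, "mother": str,
               "sex": int, "phenotype": int},
    )
    return fam


def read_bed(prefix) -> GenotypeData:
    prefix = str(prefix)
    bed_path = prefix + ".bed"
    snps = _read_bim(prefix + ".bim")
    samples = _read_fam(prefix + ".fam")
    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        if len(header) < 3 or header[:2] != BED_MAGIC:
            raise PlinkFormatError(
                f"{bed_path}: bad magic bytes {header[:2]!r}, expected 6C 1B"
            )
        if header[2] != BED_SNP_MAJOR:
            raise PlinkFormatError(
                f"{bed_path}: mode byte 0x{header[2]:02X} is not SNP-major (0x01)"
            )
        body = fh.read()
    dosages = _unpack_bed_body(body, len(samples), len(snps))
    data = GenotypeData(dosages, snps, samples)
    return _canonical_minor_orientation(data)


def write_bed(data: GenotypeData, prefix) -> None:
    prefix = str(prefix)
    data = _canonical_minor_orientation(data)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(BED_MAGIC + bytes([BED_SNP_MAJOR]))
        fh.write(_pack_bed_body(data.dosages))
    data.snps.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    data.samples.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# text dialect


def read_ped(prefix) -> GenotypeData:
    prefix = str(prefix)
    snps = pd.read_csv(
        prefix + ".map", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": int, "snp": str, "cm": float, "pos": int},
    )
    m = len(snps)
    sample_rows = []
    allele_rows = []
    with open(prefix + ".ped") as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PlinkFormatError(
                    f".ped line {line_no}: {len(fields)} fields, "
                    f"expected {6 + 2 * m}"
                )
            sample_rows.append(fields[:6])
            allele_rows.append(fields[6:])
    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    samples["sex"] = samples["sex"].astype(int)
    samples["phenotype"] = samples["phenotype"].astype(int)
    n = len(samples)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else (
        np.empty((0, m, 2), dtype=object)
    )
    dosages = np.full((n, m), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(m):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        uniq = sorted(set(observed.tolist()))
        if len(uniq) > 2:
            raise PlinkFormatError(
                f"SNP {snps['snp'][j]}: more than two alleles {uniq} in .ped"
            )
        if not uniq:
            a1, a2 = "0", "0"
        elif len(uniq) == 1:
            # single observed allele: count it so the flip below can decide
            a1, a2 = uniq[0], "0"
        else:
            a1, a2 = uniq
        a1_list.append(a1)
        a2_list.append(a2)
        if uniq:
            called = (col[:, 0] != "0") & (col[:, 1] != "0")
            counts = (col[:, 0] == a1).astype(np.int8) + (col[:, 1] == a1).astype(np.int8)
            dosages[called, j] = counts[called]
    snps = snps.assign(a1=a1_list, a2=a2_list)[SNP_COLUMNS]
    data = GenotypeData(dosages, snps, samples)
    return _canonical_minor_orientation(data)


def write_ped(data: GenotypeData, prefix) -> None:
    prefix = str(prefix)
    data = _canonical_minor_orientation(data)
    snps = data.snps
    a1 = snps["a1"].to_numpy(dtype=object)
    a2 = snps["a2"].to_numpy(dtype=object)
    # placeholder letters for SNPs whose alleles are unknown in the map
    a1 = np.where(a1 == "0", "A", a1)
    a2 = np.where(a2 == "0", "B", a2)
    genotype_strings = np.empty((4,) + a1.shape, dtype=object)
    genotype_strings[0] = a2 + " " + a2
    genotype_strings[1] = a1 + " " + a2
    genotype_strings[2] = a1 + " " + a1
    genotype_strings[3] = "0 0"
    with open(prefix + ".ped", "w") as fh:
        for i in range(data.n_samples):
            rec = data.samples.iloc[i]
            lead = f"{rec.fid} {rec.iid} {rec.father} {rec.mother} {rec.sex} {rec.phenotype}"
            d = data.dosages[i].copy()
            d[d == MISSING] = 3
            cells = genotype_strings[d, np.arange(data.n_snps)]
            fh.write(lead + (" " + " ".join(cells) if data.n_snps else "") + "\n")
    snps[["chrom", "snp", "cm", "pos"]].to_csv(
        prefix + ".map", sep="\t", header=False, index=False
    )


def read_plink(prefix) -> GenotypeData:
    """Load a cohort from ``prefix``, auto-detecting binary vs text dialect."""
    prefix = str(prefix)
    if os.path.exists(prefix + ".bed"):
        return read_bed(prefix)
    if os.path.exists(prefix + ".ped"):
        return read_ped(prefix)
    raise FileNotFoundError(f"no {prefix}.bed or {prefix}.ped found")


def write_plink(data: GenotypeData, prefix, text_mode: bool = False) -> None:
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    if text_mode:
        write_ped(data, prefix)
    else:
        write_bed(data, prefix)
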