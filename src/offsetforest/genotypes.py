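"""Genotype container and VCF / metadata I/O.

Genotypes are stored as a samples x loci dosage matrix of alternate
allele counts (0/1/2) with ``-1`` as the missing sentinel.  Loci carry
chromosome, 1-based position and REF/ALT alleles; samples carry id,
population, group and lon/lat sampling coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

__all__ = ["GenotypeMatrix", "read_vcf", "write_vcf", "read_metadata",
           "write_metadata", "MISSING"]


@dataclass
class GenotypeMatrix:
    """Samples x loci dosage matrix with locus and sample metadata.

    ``dosages``: int8 array (n_samples, n_loci), values in {0,1,2,-1}.
    ``loci``: DataFrame with columns chrom, pos, ref, alt (pos 1-based,
    strictly increasing within a chromosome).
    ``samples``: DataFrame with columns sample_id, population, group,
    lon, lat (sample_id unique).
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x loci)")
        if len(self.loci) != self.dosages.shape[1]:
            raise ValueError("loci table does not match dosage columns")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample table does not match dosage rows")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        for chrom, sub in self.loci.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with missing as NaN."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        return d

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosages[:, idx],
                              self.loci.iloc[idx].reset_index(drop=True),
                              self.samples.copy())

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosages[idx],
                              self.loci.copy(),
                              self.samples.iloc[idx].reset_index(drop=True))

    def sample_index(self, by: str, label: str) -> np.ndarray:
        """Row indices of samples whose ``by`` column equals ``label``."""
        return np.flatnonzero(self.samples[by].to_numpy() == label)

    def group_freqs(self, by: str = "group") -> pd.DataFrame:
        """Alternate-allele frequency per label (rows) and locus (cols).

        Frequencies use non-missing calls only; labels with no calls at
        a locus get NaN.
        """
        d = self.dosages_float()
        rows = {}
        for label in pd.unique(self.samples[by]):
            sub = d[self.sample_index(by, label)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rows[label] = np.nanmean(sub, axis=0) / 2.0
        return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# VCF I/O


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write diallelic genotypes to a plain-text VCF v4.2 (GT only)."""
    path = Path(path)
    lut = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                "INFO", "FORMAT"] + list(G.samples["sample_id"])
        fh.write("\t".join(cols) + "\n")
        for j in range(G.n_loci):
            loc = G.loci.iloc[j]
            gts = "\t".join(lut[int(v)] for v in G.dosages[:, j])
            fh.write(f"{loc.chrom}\t{loc.pos}\t.\t{loc.ref}\t{loc.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path, meta: str | Path | pd.DataFrame | None = None,
             strict_diallelic: bool = True) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    meta
        Optional sample metadata (TSV path or DataFrame with columns
        sample_id, population, group, lon, lat).  Metadata sample ids
        must cover the VCF samples exactly; mismatches raise with the
        offending ids listed.
    strict_diallelic
        If True (default), a multi-allelic record raises a ValueError
        naming the record; otherwise such records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            if strict_diallelic:
                raise ValueError(
                    f"multi-allelic record at {var.CHROM}:{var.POS} "
                    f"(ALT={','.join(var.ALT)}); diallelic VCF required")
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2; 3=missing
        gt[gt == 3] = MISSING
        cols.append(gt)
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = (np.stack(cols, axis=1) if cols
               else np.empty((len(sample_ids), 0), dtype=np.int8))

    if meta is None:
        samples = pd.DataFrame({
            "sample_id": sample_ids,
            "population": "NA", "group": "NA",
            "lon": np.nan, "lat": np.nan})
    else:
        samples = meta if isinstance(meta, pd.DataFrame) else read_metadata(meta)
        missing = set(sample_ids) - set(samples["sample_id"])
        extra = set(samples["sample_id"]) - set(sample_ids)
        if missing or extra:
            raise ValueError(
                "sample metadata mismatch; "
                f"absent from TSV: {sorted(missing)}; "
                f"absent from VCF: {sorted(extra)}")
        samples = (samples.set_index("sample_id").loc[sample_ids]
                   .reset_index())
    return GenotypeMatrix(dosages, loci, samples)


# ---------------------------------------------------------------------------
# metadata TSV


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "population", "group", "lon", "lat"}
    lacking = required - set(df.columns)
    if lacking:
        raise ValueError(f"metadata TSV lacks columns: {sorted(lacking)}")
    return df


def write_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)
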