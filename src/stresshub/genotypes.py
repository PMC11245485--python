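"""Genotype panel container and VCF 4.2 input/output.

The panel stores diploid dosages (count of the ALT allele, 0/1/2, -1 for
missing) for biallelic variants on a variants x accessions matrix.
Coordinates are 1-based inclusive at the interface (VCF convention);
any half-open arithmetic is kept local to the functions that need it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "read_vcf", "write_vcf"]


@dataclass
class GenotypePanel:
    """Biallelic diploid genotypes for a set of accessions.

    Attributes
    ----------
    variant_ids : list of str
        Variant identifiers (``vg``-style ids for simulated panels).
    chrom, pos : arrays
        Chromosome name and 1-based position per variant; positions must be
        sorted within each chromosome.
    ref, alt : lists of str
        Reference / alternate alleles. A length difference marks an InDel.
    dosage : int8 ndarray, shape (n_variants, n_accessions)
        ALT-allele dosage in {0, 1, 2}; -1 encodes a missing genotype.
    accession_ids : list of str
    groups : optional ndarray of str
        Population group per accession (e.g. "O. ruf", "japonica", "indica").
    """

    variant_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    ref: list
    alt: list
    dosage: np.ndarray
    accession_ids: list
    groups: np.ndarray | None = None

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n_var, n_acc = self.dosage.shape
        if not (len(self.variant_ids) == len(self.pos) == len(self.chrom)
                == len(self.ref) == len(self.alt) == n_var):
            raise ValueError("variant annotation lengths do not match dosage matrix")
        if len(self.accession_ids) != n_acc:
            raise ValueError("accession_ids length does not match dosage matrix")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on {c}")
        bad = ~np.isin(self.dosage, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[1]

    @property
    def variant_type(self) -> np.ndarray:
        """'SNP' or 'InDel' per variant."""
        return np.array(["SNP" if len(r) == len(a) == 1 else "InDel"
                         for r, a in zip(self.ref, self.alt)], dtype=object)

    def dosage_float(self) -> np.ndarray:
        """Dosage matrix as float with NaN for missing genotypes."""
        d = self.dosage.astype(float)
        d[self.dosage < 0] = np.nan
        return d

    def alt_freq(self) -> np.ndarray:
        """Per-variant ALT allele frequency over non-missing genotypes."""
        d = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset_region(self, chrom: str, start: int, end: int) -> "GenotypePanel":
        """Variants with start <= pos <= end on `chrom` (1-based inclusive)."""
        m = (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)
        return self._take_variants(np.where(m)[0])

    def subset_accessions(self, ids) -> "GenotypePanel":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise KeyError(f"accessions not in panel: {missing[:5]}")
        cols = [index[a] for a in ids]
        return GenotypePanel(
            variant_ids=list(self.variant_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=list(self.ref),
            alt=list(self.alt),
            dosage=self.dosage[:, cols].copy(),
            accession_ids=list(ids),
            groups=None if self.groups is None else np.asarray(self.groups)[cols].copy(),
        )

    def subset_group(self, group: str) -> "GenotypePanel":
        if self.groups is None:
            raise ValueError("panel carries no group labels")
        ids = [a for a, g in zip(self.accession_ids, self.groups) if g == group]
        if not ids:
            raise ValueError(f"group {group!r} absent from panel")
        return self.subset_accessions(ids)

    def _take_variants(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx, dtype=int)
        return GenotypePanel(
            variant_ids=[self.variant_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            dosage=self.dosage[idx].copy(),
            accession_ids=list(self.accession_ids),
            groups=None if self.groups is None else np.asarray(self.groups).copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Dosages as a variants x accessions DataFrame (NaN = missing)."""
        return pd.DataFrame(self.dosage_float(), index=self.variant_ids,
                            columns=self.accession_ids)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as an uncompressed VCF 4.2 text file."""
    contigs = []
    for c in panel.chrom:
        if c not in contigs:
            contigs.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stresshub\n")
        for c in contigs:
            length = int(panel.pos[panel.chrom == c].max()) + 1000
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.accession_ids) + "\n")
        for i in range(panel.n_variants):
            gts = "\t".join(_GT[int(d)] for d in panel.dosage[i])
            fh.write(f"{panel.chrom[i]}\t{panel.pos[i]}\t{panel.variant_ids[i]}\t"
                     f"{panel.ref[i]}\t{panel.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, groups: dict | None = None) -> GenotypePanel:
    """Read a VCF into a GenotypePanel (biallelic records only).

    Parameters
    ----------
    path : str
        VCF file (plain or bgzipped).
    groups : dict, optional
        accession id -> population group label.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    vid, chrom, pos, ref, alt, rows = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}; split first")
        vid.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.genotype.array()[:, :2]
        row = np.where((gt < 0).any(axis=1), -1, (gt > 0).sum(axis=1))
        rows.append(row.astype(np.int8))
    vcf.close()
    garr = None
    if groups is not None:
        garr = np.array([groups.get(s) for s in samples], dtype=object)
    return GenotypePanel(
        variant_ids=vid,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=ref,
        alt=alt,
        dosage=np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8),
        accession_ids=samples,
        groups=garr,
    )
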