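"""Diploid genotype matrices with RAD locus metadata.

The central container is :class:`GenotypeDataset`: individuals x sites
integer genotypes counting copies of the alternate allele (0/1/2, -1 for
missing), together with per-site locus id and 1-based position within the
RAD locus, an optional read-depth matrix and optional sampling-site
coordinates.  Genotypes can be read from and written to a plain TSV
dialect (rows = sites, columns = samples) and to VCF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: default RAD locus length in bp (single-end 125 bp reads)
LOCUS_LEN = 125


@dataclass
class GenotypeDataset:
    """Diploid genotypes for a set of individuals at biallelic SNP sites.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``genotypes``.
    site_labels
        Sampling-site (population) label of each sample.
    genotypes
        ``(n_samples, n_sites)`` int8 matrix of alternate-allele copy
        numbers in {0, 1, 2}; missing genotypes are ``-1``.
    locus_id
        Locus identifier of each SNP site (RAD locus the SNP belongs to).
    pos_in_locus
        1-based position of the SNP within its locus (``1..locus_len``).
    depth
        Optional ``(n_samples, n_sites)`` matrix of read depths.
    site_coords
        Optional mapping of sampling-site label to ``(lon, lat)`` in
        decimal degrees, used by the isolation-by-distance test.
    locus_len
        Length of a RAD locus in bp.
    """

    samples: list[str]
    site_labels: list[str]
    genotypes: np.ndarray
    locus_id: np.ndarray
    pos_in_locus: np.ndarray
    depth: np.ndarray | None = None
    site_coords: dict[str, tuple[float, float]] | None = None
    locus_len: int = LOCUS_LEN

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.locus_id = np.asarray(self.locus_id)
        self.pos_in_locus = np.asarray(self.pos_in_locus, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2D individuals x sites matrix")
        n_ind, n_sites = self.genotypes.shape
        if len(self.samples) != n_ind:
            raise ValueError(f"{len(self.samples)} sample ids for {n_ind} genotype rows")
        if len(self.site_labels) != n_ind:
            raise ValueError("site_labels must have one entry per sample")
        if len(self.locus_id) != n_sites or len(self.pos_in_locus) != n_sites:
            raise ValueError("locus metadata length must equal the number of sites")
        valid = (self.genotypes >= MISSING) & (self.genotypes <= 2)
        if not valid.all():
            raise ValueError("genotype values must be 0, 1, 2 or -1 (missing)")
        if n_sites and (
            self.pos_in_locus.min() < 1 or self.pos_in_locus.max() > self.locus_len
        ):
            raise ValueError(f"pos_in_locus must lie in [1, {self.locus_len}]")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.genotypes.shape:
                raise ValueError("depth matrix must match genotype matrix shape")
            if self.depth.size and self.depth.min() < 0:
                raise ValueError("depths must be non-negative")

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def sample_indices(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def samples_at_site(self, label: str) -> list[str]:
        """Sample ids belonging to one sampling site."""
        return [s for s, lab in zip(self.samples, self.site_labels) if lab == label]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeDataset":
        return replace(
            self,
            genotypes=self.genotypes[:, mask],
            locus_id=self.locus_id[mask],
            pos_in_locus=self.pos_in_locus[mask],
            depth=None if self.depth is None else self.depth[:, mask],
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeDataset":
        idx = self.sample_indices(ids)
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            site_labels=[self.site_labels[i] for i in idx],
            genotypes=self.genotypes[idx],
            depth=None if self.depth is None else self.depth[idx],
        )

    # -- TSV dialect ---------------------------------------------------
    # rows = sites, columns: locus_id, pos_in_locus, then one column per
    # sample with values 0/1/2/"."

    def to_tsv(self, path: str) -> None:
        geno = self.genotypes.T.astype(object)
        geno[geno == MISSING] = "."
        df = pd.DataFrame(geno, columns=self.samples)
        df.insert(0, "pos_in_locus", self.pos_in_locus)
        df.insert(0, "locus_id", self.locus_id)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str,
        site_labels: list[str] | None = None,
        **kwargs,
    ) -> "GenotypeDataset":
        df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
        samples = [c for c in df.columns if c not in ("locus_id", "pos_in_locus")]
        geno = df[samples].replace(".", MISSING).to_numpy(dtype=np.int8).T
        if site_labels is None:
            site_labels = list(samples)
        return cls(
            samples=samples,
            site_labels=site_labels,
            genotypes=geno,
            locus_id=df["locus_id"].to_numpy(),
            pos_in_locus=df["pos_in_locus"].to_numpy(),
            **kwargs,
        )

    # -- VCF -----------------------------------------------------------

    def to_vcf(self, path: str) -> None:
        """Write a minimal VCF 4.2 with one contig per RAD locus.

        CHROM is the locus id, POS the position within the locus; read
        depths, when present, go to the per-sample DP field.
        """
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=raddemog\n")
            for lid in pd.unique(self.locus_id):
                fh.write(f"##contig=<ID={lid},length={self.locus_len}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            fmt = "GT" if self.depth is None else "GT:DP"
            for j in range(self.n_sites):
                fields = [
                    str(self.locus_id[j]),
                    str(self.pos_in_locus[j]),
                    ".",
                    "A",
                    "T",
                    ".",
                    "PASS",
                    ".",
                    fmt,
                ]
                for i in range(self.n_samples):
                    cell = gt_codes[int(self.genotypes[i, j])]
                    if self.depth is not None:
                        cell += f":{int(self.depth[i, j])}"
                    fields.append(cell)
                fh.write("\t".join(fields) + "\n")

    @classmethod
    def from_vcf(
        cls, path: str, site_labels: list[str] | None = None, **kwargs
    ) -> "GenotypeDataset":
        """Read diploid GT (and DP when present) from a VCF file."""
        import pysam

        with pysam.VariantFile(path) as vcf:
            samples = list(vcf.header.samples)
            locus_id, pos, rows, depths = [], [], [], []
            has_depth = False
            for rec in vcf:
                locus_id.append(rec.chrom)
                pos.append(rec.pos)
                row, drow = [], []
                for s in samples:
                    call = rec.samples[s]
                    alleles = call.get("GT")
                    if alleles is None or any(a is None for a in alleles):
                        row.append(MISSING)
                    else:
                        row.append(int(sum(alleles)))
                    dp = call.get("DP")
                    if dp is not None:
                        has_depth = True
                    drow.append(0 if dp is None else int(dp))
                rows.append(row)
                depths.append(drow)
        geno = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
        depth = np.array(depths).T if (rows and has_depth) else None
        if site_labels is None:
            site_labels = list(samples)
        return cls(
            samples=samples,
            site_labels=site_labels,
            genotypes=geno,
            locus_id=np.array(locus_id),
            pos_in_locus=np.array(pos, dtype=np.int64),
            depth=depth,
            **kwargs,
        )

    # -- misc ----------------------------------------------------------

    def to_truth_json(self, path: str, params: dict) -> None:
        """Persist a generating-parameter sidecar next to a dataset."""
        with open(path, "w") as fh:
            json.dump(params, fh, indent=2, default=str)
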