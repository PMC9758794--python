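"""Post-assembly RAD-seq site and locus filters.

Emulates, at the called-genotype level, the depth and SNP-quality
filters applied to RAD loci before any population-genetic analysis:

1. genotype cells with read depth below a minimum are set to missing;
2. SNPs in the last few bp of a locus are removed (restriction-site
   artefacts);
3. SNPs heterozygous in a large fraction of individuals are removed
   (paralog collapse signature);
4. loci carrying too many SNPs are removed entirely (paralogous
   alignments);
5. optionally, a minor-allele-frequency floor is applied last.

Each site is counted once, in the first filter that removes it, so the
attrition report adds up exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset


@dataclass
class FilterReport:
    n_input_sites: int
    n_dropped_depth: int  # sites lost entirely to the depth filter (all genotypes missing)
    n_dropped_last5bp: int
    n_dropped_het80: int
    n_dropped_locus_gt5snp: int
    n_dropped_maf: int
    n_output_sites: int
    snps_per_locus: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        drops = (
            self.n_dropped_depth
            + self.n_dropped_last5bp
            + self.n_dropped_het80
            + self.n_dropped_locus_gt5snp
            + self.n_dropped_maf
        )
        if self.n_output_sites != self.n_input_sites - drops:
            raise ValueError("filter report does not add up")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def apply_filters(
    data: GenotypeDataset,
    min_depth: int = 3,
    last_bp: int = 5,
    het_frac: float = 0.80,
    max_snps_per_locus: int = 5,
    min_maf: float = 0.0,
) -> tuple[GenotypeDataset, FilterReport]:
    """Apply the RAD site/locus filters in their fixed order.

    Order: depth -> last-``last_bp``-bp -> heterozygosity -> locus SNP
    count -> MAF.  The depth filter masks individual genotype cells; a
    site only counts as dropped by it when every genotype is masked.
    The heterozygosity fraction is taken over non-missing individuals.
    The MAF filter runs only when ``min_maf > 0`` (it is an
    analysis-specific extra, not part of the core pipeline).
    """
    if not 0 < het_frac <= 1:
        raise ValueError("het_frac must be in (0, 1]")
    n_input = data.n_sites
    geno = data.genotypes.copy()

    # (1) depth: mask low-coverage cells
    if data.depth is None:
        if min_depth > 0:
            warnings.warn("no depth matrix attached; depth filter skipped", stacklevel=2)
    else:
        geno[data.depth < min_depth] = MISSING
    alive = ~(geno == MISSING).all(axis=0)
    n_drop_depth = int(n_input - alive.sum())

    # (2) last bp of the locus
    tail = data.pos_in_locus > data.locus_len - last_bp
    n_drop_tail = int((alive & tail).sum())
    alive &= ~tail

    # (3) excess heterozygosity among non-missing individuals
    het = (geno == 1).sum(axis=0)
    called = (geno != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        hfrac = np.where(called > 0, het / np.maximum(called, 1), 0.0)
    hot = hfrac >= het_frac
    n_drop_het = int((alive & hot).sum())
    alive &= ~hot

    # (4) loci with too many surviving SNPs (paralog suspects)
    locus_counts = pd.Series(data.locus_id[alive]).value_counts()
    bad_loci = set(locus_counts.index[locus_counts > max_snps_per_locus])
    in_bad = np.isin(data.locus_id, list(bad_loci))
    n_drop_locus = int((alive & in_bad).sum())
    alive &= ~in_bad

    # (5) minor allele frequency, over non-missing alleles
    n_drop_maf = 0
    if min_maf > 0:
        alt = np.where(geno == MISSING, 0, geno).sum(axis=0)
        tot = 2 * called
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
        maf = np.minimum(p, 1 - p)
        rare = maf < min_maf
        n_drop_maf = int((alive & rare).sum())
        alive &= ~rare

    out = GenotypeDataset(
        samples=list(data.samples),
        site_labels=list(data.site_labels),
        genotypes=geno[:, alive],
        locus_id=data.locus_id[alive],
        pos_in_locus=data.pos_in_locus[alive],
        depth=None if data.depth is None else data.depth[:, alive],
        site_coords=data.site_coords,
        locus_len=data.locus_len,
    )
    surviving = pd.Series(out.locus_id).value_counts().to_dict()
    report = FilterReport(
        n_input_sites=n_input,
        n_dropped_depth=n_drop_depth,
        n_dropped_last5bp=n_drop_tail,
        n_dropped_het80=n_drop_het,
        n_dropped_locus_gt5snp=n_drop_locus,
        n_dropped_maf=n_drop_maf,
        n_output_sites=out.n_sites,
        snps_per_locus={str(k): int(v) for k, v in surviving.items()},
    )
    return out, report
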