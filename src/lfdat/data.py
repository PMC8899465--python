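"""In-memory containers for a genotyped region and a longitudinal trait."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenotypeRegion:
    """Additive genotypes for one gene region.

    ``G`` is n subjects x L SNPs with entries in {0, 1, 2} (copies of the
    minor-tagged allele); ``positions`` are SNP coordinates affinely mapped
    to [0, 1]; ``maf`` is the per-SNP sample minor allele frequency.
    ``maf_param`` optionally records the generating (population) MAF when
    the region was simulated.
    """

    subject_ids: np.ndarray
    positions: np.ndarray
    G: np.ndarray
    maf: np.ndarray = None
    maf_param: np.ndarray = None
    positions_bp: np.ndarray = None
    region_id: str = "region"

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.positions = np.asarray(self.positions, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValueError("G must be n x L")
        n, L = self.G.shape
        if self.subject_ids.shape[0] != n:
            raise ValueError("subject_ids length must match G rows")
        if self.positions.shape[0] != L:
            raise ValueError("positions length must match G columns")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.G.min() < 0 or self.G.max() > 2:
            raise ValueError("genotypes must lie in [0, 2]")
        if self.maf is None:
            p = self.G.mean(axis=0) / 2.0
            self.maf = np.minimum(p, 1.0 - p)
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def L(self) -> int:
        return self.G.shape[1]


@dataclass
class LongitudinalPhenotype:
    """A quantitative trait measured for every subject on a shared time grid.

    ``Y`` is n x (Q+1); ``time_grid`` holds the raw measurement times (e.g.
    1..9) and ``time_norm`` their affine image in [0, 1] used by the time
    basis.
    """

    subject_ids: np.ndarray
    time_grid: np.ndarray
    Y: np.ndarray
    time_norm: np.ndarray = field(default=None)

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be n x (Q+1)")
        if self.Y.shape != (self.subject_ids.shape[0], self.time_grid.shape[0]):
            raise ValueError("Y shape must be (n_subjects, n_times)")
        if np.any(np.isnan(self.Y)):
            raise ValueError("Y contains missing values; clean them at ingestion")
        if self.time_norm is None:
            span = self.time_grid.max() - self.time_grid.min()
            if span > 0:
                self.time_norm = (self.time_grid - self.time_grid.min()) / span
            else:
                self.time_norm = np.full_like(self.time_grid, 0.5)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def n_times(self) -> int:
        return self.Y.shape[1]


def check_aligned(geno: GenotypeRegion, pheno: LongitudinalPhenotype) -> None:
    if geno.n != pheno.n:
        raise ValueError("genotype and phenotype subject counts differ")
    if not np.array_equal(geno.subject_ids.astype(str), pheno.subject_ids.astype(str)):
        raise ValueError("subject order differs between genotypes and phenotypes")
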