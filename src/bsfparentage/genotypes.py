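"""Core in-memory containers shared across the pipeline.

Genotypes are stored as alternate-allele dosage: 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, -1 = missing. Loci are biallelic
SNPs; per-locus metadata (chromosome, position, RAD locus of origin, position
within the RAD locus) travels with the call matrix so that the QC cascade can
apply positional filters. Sample metadata (colony, generation, family, role,
parent links) travels the same way for trio- and colony-aware stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: columns required in the per-sample metadata table
SAMPLE_COLUMNS = ["id", "colony", "generation", "family", "role", "sire", "dam"]
#: columns required in the per-locus metadata table
LOCUS_COLUMNS = ["id", "chrom", "pos", "rad_locus", "pos_in_locus"]


@dataclass
class AlleleFrequencies:
    """Per-locus alternate-allele frequencies for a biallelic panel."""

    locus_ids: list[str]
    alt_freq: np.ndarray

    def __post_init__(self) -> None:
        self.alt_freq = np.asarray(self.alt_freq, dtype=float)
        if len(self.locus_ids) != self.alt_freq.shape[0]:
            raise ValueError("locus_ids and alt_freq length mismatch")
        if np.any((self.alt_freq < 0) | (self.alt_freq > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.alt_freq.shape[0]

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency, folded to [0, 0.5]."""
        return np.minimum(self.alt_freq, 1.0 - self.alt_freq)

    def subset(self, idx: np.ndarray) -> "AlleleFrequencies":
        ids = [self.locus_ids[i] for i in np.atleast_1d(idx)]
        return AlleleFrequencies(ids, self.alt_freq[idx])


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of biallelic genotype calls.

    Attributes
    ----------
    calls
        int8 array of shape (n_samples, n_loci); -1 encodes missing.
    samples
        DataFrame with at least ``SAMPLE_COLUMNS`` (one row per sample,
        aligned with ``calls`` rows).
    loci
        DataFrame with at least ``LOCUS_COLUMNS`` (one row per locus,
        aligned with ``calls`` columns).
    depth
        Optional per-call read depth, same shape as ``calls``.
    """

    calls: np.ndarray
    samples: pd.DataFrame
    loci: pd.DataFrame
    depth: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x loci)")
        if len(self.samples) != self.calls.shape[0]:
            raise ValueError("sample table does not match call matrix rows")
        if len(self.loci) != self.calls.shape[1]:
            raise ValueError("locus table does not match call matrix columns")
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("calls must be coded -1/0/1/2")
        if self.depth is not None and self.depth.shape != self.calls.shape:
            raise ValueError("depth shape must match calls")
        self.samples = self.samples.reset_index(drop=True)
        self.loci = self.loci.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["id"].tolist()

    @property
    def locus_ids(self) -> list[str]:
        return self.loci["id"].tolist()

    def sample_index(self, sample_id: str) -> int:
        idx = self.samples.index[self.samples["id"] == sample_id]
        if len(idx) != 1:
            raise KeyError(f"sample {sample_id!r} not found (or duplicated)")
        return int(idx[0])

    # -- subsetting ------------------------------------------------------
    def subset(
        self,
        sample_idx: np.ndarray | None = None,
        locus_idx: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample/locus indices."""
        s = np.arange(self.n_samples) if sample_idx is None else np.atleast_1d(sample_idx)
        l = np.arange(self.n_loci) if locus_idx is None else np.atleast_1d(locus_idx)
        depth = None if self.depth is None else self.depth[np.ix_(s, l)]
        return GenotypeMatrix(
            calls=self.calls[np.ix_(s, l)].copy(),
            samples=self.samples.iloc[s].reset_index(drop=True),
            loci=self.loci.iloc[l].reset_index(drop=True),
            depth=depth,
        )

    # -- summaries -------------------------------------------------------
    def missing_rate_per_locus(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def missing_rate_per_sample(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def allele_frequencies(self) -> AlleleFrequencies:
        """Alternate-allele frequency per locus from non-missing calls.

        Loci with no calls at all get frequency NaN.
        """
        valid = self.calls != MISSING
        dose = np.where(valid, self.calls, 0).astype(float)
        n_alleles = 2.0 * valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(n_alleles > 0, dose.sum(axis=0) / n_alleles, np.nan)
        return AlleleFrequencies(self.locus_ids, p_alt)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            calls=self.calls.copy(),
            samples=self.samples.copy(),
            loci=self.loci.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )


def hwe_genotype_probs(alt_freq: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities, shape (L, 3) for dosage 0/1/2."""
    q = np.asarray(alt_freq, dtype=float)
    p = 1.0 - q
    return np.stack([p * p, 2.0 * p * q, q * q], axis=-1)
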