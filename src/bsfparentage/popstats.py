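"""Marker-informativeness and population statistics for biallelic panels.

Per-locus observed/expected heterozygosity, nucleotide diversity, F_IS,
polymorphism information content (Botstein's PIC), Jamieson-Taylor style
non-exclusion probabilities, Weir-Cockerham F_ST, and panel-level summaries
matching the descriptors conventionally reported for parentage marker sets.

Non-exclusion closed forms (q = 1 - p, any biallelic locus):

* first parent (no known co-parent): ``1 - 2 p^2 q^2`` — exclusion happens
  only through opposing homozygotes;
* second parent (one parent known): ``p^4 - 2 p^3 + 2 p^2 - p + 1``;
* parent pair: ``6 p^6 - 18 p^5 + 23 p^4 - 16 p^3 + 7 p^2 - 2 p + 1``.

All three were derived by exhaustive enumeration over genotype
configurations under Hardy-Weinberg proportions with error-free genotypes
and are symmetric in p <-> q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencies, GenotypeMatrix

NONEXCLUSION_MODES = ("first_parent", "second_parent", "parent_pair")


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def locus_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus MAF, Ho, He, delta_het, pi, Fis and PIC.

    He is the Hardy-Weinberg expectation 2p(1-p); pi applies the
    sample-size correction n/(n-1) to He with n = non-missing allele
    copies; Fis = 1 - Ho/He, reported as 0 for monomorphic loci.
    """
    calls = matrix.calls
    valid = calls != MISSING
    n_called = valid.sum(axis=0)
    n_alleles = 2.0 * n_called
    dose = np.where(valid, calls, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, dose.sum(axis=0) / n_alleles, np.nan)
        ho = np.where(n_called > 0, (calls == 1).sum(axis=0) / n_called, np.nan)
    he = 2.0 * p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n_alleles > 1, n_alleles / (n_alleles - 1.0) * he, np.nan)
        fis = np.where(he > 0, 1.0 - ho / he, 0.0)
    return pd.DataFrame(
        {"id": matrix.locus_ids, "maf": np.minimum(p, 1.0 - p), "Ho": ho,
         "He": he, "delta_het": he - ho, "pi": pi, "Fis": fis,
         "PIC": pic(np.where(np.isnan(p), 0.0, p))}
    )


def pic(p: np.ndarray | float) -> np.ndarray | float:
    """Botstein's polymorphism information content for a biallelic locus.

    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    out = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return float(out) if out.ndim == 0 else out


def nonexclusion(p: np.ndarray | float, mode: str) -> np.ndarray | float:
    """Per-locus non-exclusion probability under HWE, error-free genotypes.

    ``mode`` is one of ``first_parent`` (candidate tested with no known
    co-parent), ``second_parent`` (one true parent known) or ``parent_pair``
    (a candidate couple tested jointly).
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    if mode == "first_parent":
        out = 1.0 - 2.0 * p**2 * q**2
    elif mode == "second_parent":
        out = p**4 - 2.0 * p**3 + 2.0 * p**2 - p + 1.0
    elif mode == "parent_pair":
        out = (6.0 * p**6 - 18.0 * p**5 + 23.0 * p**4
               - 16.0 * p**3 + 7.0 * p**2 - 2.0 * p + 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected {NONEXCLUSION_MODES}")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# panel summary
# ---------------------------------------------------------------------------

@dataclass
class PanelSummary:
    n_individuals: int
    n_loci: int
    mean_prop_typed: float
    mean_He: float
    mean_Ho: float
    mean_PIC: float
    NE_1P: float
    NE_2P: float
    NE_PP: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Individual genotyped": self.n_individuals,
                "Number of loci used": self.n_loci,
                "Mean proportion of typed loci": self.mean_prop_typed,
                "Mean expected heterozygosity": self.mean_He,
                "Mean observed heterozygosity": self.mean_Ho,
                "Mean polymorphic information content": self.mean_PIC,
                "Non-exclusion probability 1st parent": self.NE_1P,
                "Non-exclusion probability 2nd parent": self.NE_2P,
                "Non-exclusion probability parent pair": self.NE_PP,
            }
        )


def panel_summary(
    matrix: GenotypeMatrix, freqs: AlleleFrequencies | None = None
) -> PanelSummary:
    """Panel descriptors; multilocus NE values are per-locus products."""
    if matrix.n_loci == 0:
        raise ValueError("panel is empty")
    if freqs is None:
        freqs = matrix.allele_frequencies()
    stats = locus_stats(matrix)
    p = freqs.alt_freq
    return PanelSummary(
        n_individuals=matrix.n_samples,
        n_loci=matrix.n_loci,
        mean_prop_typed=float(1.0 - matrix.missing_rate_per_locus().mean()),
        mean_He=float(stats["He"].mean()),
        mean_Ho=float(stats["Ho"].mean()),
        mean_PIC=float(stats["PIC"].mean()),
        NE_1P=float(np.prod(nonexclusion(p, "first_parent"))),
        NE_2P=float(np.prod(nonexclusion(p, "second_parent"))),
        NE_PP=float(np.prod(nonexclusion(p, "parent_pair"))),
    )


def panel_summary_table(panels: dict[float, GenotypeMatrix]) -> pd.DataFrame:
    """One summary column per MAF-tier panel."""
    cols = {f"MAF >{tier:g}": panel_summary(m).to_series()
            for tier, m in panels.items()}
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# F_ST (Weir & Cockerham)
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    locus_ids: list[str]
    per_locus: np.ndarray
    mean: float


def fst(matrix: GenotypeMatrix, group_by: str = "colony") -> FstResult:
    """Weir-Cockerham per-locus theta between populations.

    ``group_by`` names a column of the sample table (two or more groups).
    Loci monomorphic across all groups, or evaluable in fewer than two
    groups, are skipped (NaN). The mean is unweighted across defined loci.
    """
    labels = matrix.samples[group_by].to_numpy()
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two populations")
    calls = matrix.calls
    valid = calls != MISSING
    r = len(groups)
    n_i = np.zeros((r, matrix.n_loci))
    p_i = np.zeros((r, matrix.n_loci))
    h_i = np.zeros((r, matrix.n_loci))
    for k, g in enumerate(groups):
        sub = calls[labels == g]
        v = sub != MISSING
        n = v.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, np.where(v, sub, 0).sum(axis=0) / (2 * n), np.nan)
            h_i[k] = np.where(n > 0, (sub == 1).sum(axis=0) / n, np.nan)
        n_i[k] = n
    ok = (n_i >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_i.mean(axis=0)
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        denom = a + b + c
        theta = np.where(ok & (denom != 0), a / denom, np.nan)
    mean = float(np.nanmean(theta)) if np.any(~np.isnan(theta)) else float("nan")
    return FstResult(matrix.locus_ids, theta, mean)
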