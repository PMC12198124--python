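"""Sample- and marker-level SNP quality-control cascade.

Reproduces the full filter chain used to distil a genotyping-by-sequencing
call set into a small panel of high-quality markers suitable for parentage
assignment: monomorphic and colony-private markers out first, then outlier
samples (missingness, median depth, heterozygosity), then marker filters
(MAF, MAC, observed heterozygosity, mean depth, missingness, position on the
RAD locus, one SNP per locus, Hardy-Weinberg exact test, Mendelian error
over known trios) and finally windowed LD pruning. Every step is recorded in
an auditable report; any step can be disabled by setting its threshold to
None.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# configuration and report
# ---------------------------------------------------------------------------


@dataclass
class FilterConfig:
    """Thresholds for the QC cascade; None disables the step.

    Defaults are the values used in the study pipeline (Radiator outlier
    bounds for the sample filters, Stacks/Plink-style marker thresholds).
    """

    sample_max_missing: float | None = 0.30
    sample_median_depth_range: tuple[float, float] | None = (1.0, 27.0)
    sample_het_range: tuple[float, float] | None = (0.14, 0.61)
    marker_min_maf: float | None = 0.30
    marker_min_mac: int | None = 4
    marker_max_obs_het: float | None = 0.5
    marker_mean_depth_range: tuple[float, float] | None = (15.0, 75.0)
    marker_max_missing: float | None = 0.05
    locus_position_window: tuple[int, int] | None = (40, 70)
    one_snp_per_locus: bool = True
    hwe_alpha: float | None = 0.05
    mendel_max_rate: float | None = 0.03
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float | None = 0.5
    require_shared_across_colonies: bool = True
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        for name in ("sample_max_missing", "marker_min_maf", "marker_max_obs_het",
                     "marker_max_missing", "hwe_alpha", "mendel_max_rate", "ld_r2_max"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        for name in ("sample_median_depth_range", "sample_het_range",
                     "marker_mean_depth_range", "locus_position_window"):
            v = getattr(self, name)
            if v is not None and v[0] > v[1]:
                raise ValueError(f"{name} must be an ordered range")

    @classmethod
    def disabled(cls) -> "FilterConfig":
        """A configuration in which every step is a pass-through."""
        return cls(
            sample_max_missing=None, sample_median_depth_range=None,
            sample_het_range=None, marker_min_maf=None, marker_min_mac=None,
            marker_max_obs_het=None, marker_mean_depth_range=None,
            marker_max_missing=None, locus_position_window=None,
            one_snp_per_locus=False, hwe_alpha=None, mendel_max_rate=None,
            ld_r2_max=None, require_shared_across_colonies=False,
            drop_monomorphic=False,
        )


@dataclass
class FilterStep:
    name: str
    axis: str  # "samples" or "markers"
    removed: int
    samples_remaining: int
    markers_remaining: int


@dataclass
class FilterReport:
    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, axis: str, removed: int, n_samples: int, n_markers: int):
        self.steps.append(FilterStep(name, axis, removed, n_samples, n_markers))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class TrioSet:
    """Known (offspring, sire, dam) id triples for the Mendelian-error filter."""

    trios: list[tuple[str, str, str]]

    @classmethod
    def from_samples(cls, samples: pd.DataFrame) -> "TrioSet":
        """Build trios for every sample whose parents are also in the table."""
        present = set(samples["id"])
        trios = [
            (row.id, row.sire, row.dam)
            for row in samples.itertuples()
            if row.sire in present and row.dam in present
        ]
        return cls(trios)

    def __len__(self) -> int:
        return len(self.trios)


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus MAF, MAC, call rate, observed heterozygosity, mean depth.

    All statistics use non-missing calls only; loci with zero calls get
    call_rate 0 and NaN elsewhere.
    """
    calls = matrix.calls
    valid = calls != MISSING
    n_called = valid.sum(axis=0)
    dose = np.where(valid, calls, 0).astype(float)
    alt_count = dose.sum(axis=0)
    n_alleles = 2.0 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, alt_count / n_alleles, np.nan)
        maf = np.minimum(p_alt, 1.0 - p_alt)
        mac = np.minimum(alt_count, n_alleles - alt_count)
        obs_het = np.where(n_called > 0, (calls == 1).sum(axis=0) / n_called, np.nan)
    call_rate = n_called / matrix.n_samples
    if matrix.depth is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_depth = np.where(
                n_called > 0,
                np.where(valid, matrix.depth, 0).sum(axis=0) / n_called, np.nan)
    else:
        mean_depth = np.full(matrix.n_loci, np.nan)
    return pd.DataFrame(
        {"id": matrix.locus_ids, "maf": maf, "mac": mac, "call_rate": call_rate,
         "obs_het": obs_het, "mean_depth": mean_depth}
    )


def sample_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample missingness, heterozygosity and median depth."""
    calls = matrix.calls
    valid = calls != MISSING
    n_called = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, (calls == 1).sum(axis=1) / n_called, np.nan)
    if matrix.depth is not None:
        med = np.array(
            [np.median(matrix.depth[i, valid[i]]) if n_called[i] else np.nan
             for i in range(matrix.n_samples)])
    else:
        med = np.full(matrix.n_samples, np.nan)
    return pd.DataFrame(
        {"id": matrix.sample_ids, "missing": 1.0 - n_called / matrix.n_loci,
         "het": het, "median_depth": med}
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test for one biallelic locus.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count no more probable than the observed one
    (two-sided by probability mass). Monomorphic loci return 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    n_minor = min(n_a, n_b)
    if n_minor == 0:
        return 1.0
    # P(nab | n, n_minor) proportional to n! / (naa! nab! nbb!) * 2^nab
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = n - hets - homs_minor
    logp = (hets * np.log(2.0) - gammaln(homs_minor + 1)
            - gammaln(hets + 1) - gammaln(homs_major + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_ab][0]
    return float(p[p <= obs * (1.0 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# Mendelian error
# ---------------------------------------------------------------------------

def _mendel_possible() -> np.ndarray:
    """Boolean table possible[g_sire, g_dam, g_off] under Mendelian rules."""
    tab = np.zeros((3, 3, 3), dtype=bool)
    for gs in range(3):
        for gd in range(3):
            for a in ({0: (0, 0), 1: (0, 1), 2: (1, 1)}[gs]):
                for b in ({0: (0, 0), 1: (0, 1), 2: (1, 1)}[gd]):
                    tab[gs, gd, a + b] = True
    return tab


_MENDEL_OK = _mendel_possible()


def mendel_error_rate(matrix: GenotypeMatrix, trios: TrioSet) -> np.ndarray:
    """Per-locus fraction of evaluable trios with a Mendelian impossibility.

    A trio is evaluable at a locus when offspring and both parents are
    called there. Loci with zero evaluable trios return NaN (and pass the
    filter by convention).
    """
    if len(trios) == 0:
        return np.full(matrix.n_loci, np.nan)
    idx = {sid: i for i, sid in enumerate(matrix.sample_ids)}
    errors = np.zeros(matrix.n_loci, dtype=int)
    evaluable = np.zeros(matrix.n_loci, dtype=int)
    for off, sire, dam in trios.trios:
        go = matrix.calls[idx[off]]
        gs = matrix.calls[idx[sire]]
        gd = matrix.calls[idx[dam]]
        ok = (go != MISSING) & (gs != MISSING) & (gd != MISSING)
        evaluable += ok
        bad = ok & ~_MENDEL_OK[gs.clip(0), gd.clip(0), go.clip(0)]
        errors += bad
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(evaluable > 0, errors / evaluable, np.nan)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples (missing coded -1 or NaN).
    Returns NaN when fewer than two complete pairs remain or either vector
    has zero variance; the pruner treats NaN as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y) & (x >= 0) & (y >= 0)
    if ok.sum() < 2:
        return float("nan")
    xv, yv = x[ok], y[ok]
    dx, dy = xv - xv.mean(), yv - yv.mean()
    sx, sy = (dx**2).sum(), (dy**2).sum()
    if sx == 0 or sy == 0:
        return float("nan")
    r = (dx * dy).sum() / np.sqrt(sx * sy)
    return float(r * r)


def prune_ld(
    matrix: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns indices of retained loci.

    Loci are processed per chromosome in position order. Within each window
    of ``window`` variants (sliding by ``step``), while any retained pair has
    r^2 > ``r2_max`` the later-positioned member of the worst pair is
    removed. Deterministic for a fixed input.
    """
    loci = matrix.loci
    removed: set[int] = set()
    dose = np.where(matrix.calls == MISSING, np.nan, matrix.calls).astype(float)
    for _, grp in loci.groupby("chrom", sort=True):
        order = grp.sort_values("pos", kind="stable").index.to_numpy()
        n = len(order)
        starts = range(0, max(n - 1, 1), step)
        for s in starts:
            win = [i for i in order[s:s + window] if i not in removed]
            while len(win) > 1:
                worst = None
                worst_r2 = r2_max
                for a in range(len(win)):
                    for b in range(a + 1, len(win)):
                        r2 = ld_r2(dose[:, win[a]], dose[:, win[b]])
                        if not np.isnan(r2) and r2 > worst_r2:
                            worst_r2 = r2
                            worst = b  # later-positioned member of the pair
                if worst is None:
                    break
                removed.add(win[worst])
                win.pop(worst)
            if s + window >= n:
                break
    keep = [i for i in range(matrix.n_loci) if i not in removed]
    return np.asarray(keep, dtype=int)


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def run_cascade(
    matrix: GenotypeMatrix,
    trios: TrioSet | None = None,
    config: FilterConfig | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full sample/marker filter cascade in its canonical order.

    Order: monomorphic -> shared across colonies -> sample missingness ->
    sample median depth -> sample heterozygosity -> MAF -> MAC -> observed
    heterozygosity -> marker mean depth -> marker missingness -> RAD-locus
    position window -> one SNP per RAD locus -> HWE exact test -> Mendelian
    error -> LD pruning.
    """
    config = config or FilterConfig()
    if trios is None:
        trios = TrioSet.from_samples(matrix.samples)
    report = FilterReport()
    m = matrix

    def log(name: str, axis: str, removed: int) -> None:
        report.add(name, axis, removed, m.n_samples, m.n_loci)

    def drop_loci(name: str, keep_mask: np.ndarray) -> None:
        nonlocal m
        removed = int((~keep_mask).sum())
        if removed:
            m = m.subset(locus_idx=np.flatnonzero(keep_mask))
        log(name, "markers", removed)

    # -- marker pre-filters ---------------------------------------------
    if config.drop_monomorphic:
        stats = marker_stats(m)
        keep = (stats["mac"].to_numpy() > 0) & (stats["call_rate"].to_numpy() > 0)
        drop_loci("monomorphic", keep)
    if config.require_shared_across_colonies:
        colonies = m.samples["colony"].to_numpy()
        keep = np.ones(m.n_loci, dtype=bool)
        for colony in np.unique(colonies):
            sub = m.calls[colonies == colony]
            keep &= (sub != MISSING).any(axis=0)
        drop_loci("shared_across_colonies", keep)

    # -- sample filters ---------------------------------------------------
    def drop_samples(name: str, keep_mask: np.ndarray) -> None:
        nonlocal m
        removed = int((~keep_mask).sum())
        if removed:
            m = m.subset(sample_idx=np.flatnonzero(keep_mask))
        log(name, "samples", removed)

    if config.sample_max_missing is not None:
        ss = sample_stats(m)
        drop_samples("sample_missingness",
                     ss["missing"].to_numpy() <= config.sample_max_missing)
    if config.sample_median_depth_range is not None and m.depth is not None:
        lo, hi = config.sample_median_depth_range
        ss = sample_stats(m)
        med = ss["median_depth"].to_numpy()
        drop_samples("sample_median_depth", (med >= lo) & (med <= hi))
    if config.sample_het_range is not None:
        lo, hi = config.sample_het_range
        ss = sample_stats(m)
        het = ss["het"].to_numpy()
        drop_samples("sample_heterozygosity", (het >= lo) & (het <= hi))

    # -- marker filters ---------------------------------------------------
    if config.marker_min_maf is not None:
        stats = marker_stats(m)
        drop_loci("maf", np.nan_to_num(stats["maf"].to_numpy(), nan=-1.0)
                  >= config.marker_min_maf)
    if config.marker_min_mac is not None:
        stats = marker_stats(m)
        drop_loci("mac", np.nan_to_num(stats["mac"].to_numpy(), nan=-1.0)
                  >= config.marker_min_mac)
    if config.marker_max_obs_het is not None:
        stats = marker_stats(m)
        drop_loci("obs_het", np.nan_to_num(stats["obs_het"].to_numpy(), nan=0.0)
                  <= config.marker_max_obs_het)
    if config.marker_mean_depth_range is not None and m.depth is not None:
        lo, hi = config.marker_mean_depth_range
        stats = marker_stats(m)
        md = stats["mean_depth"].to_numpy()
        drop_loci("marker_mean_depth", (md >= lo) & (md <= hi))
    if config.marker_max_missing is not None:
        drop_loci("marker_missingness",
                  m.missing_rate_per_locus() <= config.marker_max_missing)
    if config.locus_position_window is not None:
        lo, hi = config.locus_position_window
        pos = m.loci["pos_in_locus"].to_numpy()
        drop_loci("rad_position_window", (pos >= lo) & (pos <= hi))
    if config.one_snp_per_locus:
        # keep the first SNP by position within each RAD locus
        keep = np.zeros(m.n_loci, dtype=bool)
        first = (m.loci.reset_index()
                 .sort_values(["rad_locus", "pos"], kind="stable")
                 .groupby("rad_locus", sort=False)["index"].first())
        keep[first.to_numpy()] = True
        drop_loci("one_snp_per_rad_locus", keep)
    if config.hwe_alpha is not None:
        calls = m.calls
        pvals = np.empty(m.n_loci)
        for j in range(m.n_loci):
            c = calls[:, j]
            pvals[j] = hwe_exact_pvalue(int((c == 0).sum()), int((c == 1).sum()),
                                        int((c == 2).sum()))
        drop_loci("hwe", pvals >= config.hwe_alpha)
    if config.mendel_max_rate is not None and len(trios) > 0:
        # sample filters may have removed trio members
        present = set(m.sample_ids)
        usable = TrioSet([t for t in trios.trios if set(t) <= present])
        rate = (mendel_error_rate(m, usable) if len(usable)
                else np.full(m.n_loci, np.nan))
        drop_loci("mendel_error",
                  np.isnan(rate) | (rate <= config.mendel_max_rate))
    if config.ld_r2_max is not None:
        keep_idx = prune_ld(m, config.ld_window, config.ld_step, config.ld_r2_max)
        keep = np.zeros(m.n_loci, dtype=bool)
        keep[keep_idx] = True
        drop_loci("ld_prune", keep)

    return m, report


# ---------------------------------------------------------------------------
# MAF-tier panels
# ---------------------------------------------------------------------------

def build_subsets(
    matrix: GenotypeMatrix, tiers: tuple[float, ...] = (0.40, 0.45, 0.47, 0.48)
) -> dict[float, GenotypeMatrix]:
    """Nested MAF-tier panels; tier t keeps loci with MAF strictly above t."""
    if list(tiers) != sorted(tiers):
        raise ValueError("tiers must be ascending")
    maf = marker_stats(matrix)["maf"].to_numpy()
    panels = {}
    for t in tiers:
        keep = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) > t)
        panels[t] = matrix.subset(locus_idx=keep)
    return panels
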