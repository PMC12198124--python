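"""Synthetic multigeneration full-sib breeding population.

Emulates the experimental design used to build the study population: two
colonies, each split into 12 families; within every family and generation
four mating pairs are hand-picked, one pair is retained and sequenced
together with two of its larvae, and the retained pair's offspring found the
next generation. Because mates in generations >= 1 are full sibs, larval
inbreeding accumulates as F = 0, 0.25, 0.375 over the three larval
generations.

Genotypes are dropped down the pedigree by Mendelian gene transmission from
Hardy-Weinberg founders, then optionally corrupted with a mistyping /
missingness error model matching the assumptions of the likelihood engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencies, GenotypeMatrix

ROLES = ("sire", "dam", "larva")


@dataclass
class DesignConfig:
    """Breeding-design parameters (defaults reproduce the study design)."""

    n_colonies: int = 2
    n_families: int = 12
    n_generations: int = 3
    n_pairs_per_family: int = 4
    n_larvae_sequenced_per_pair: int = 2
    n_loci: int = 500
    maf_low: float = 0.05
    maf_high: float = 0.5
    colony_names: tuple[str, ...] = ("ES", "UL")

    def __post_init__(self) -> None:
        for name in ("n_colonies", "n_families", "n_generations",
                     "n_pairs_per_family", "n_larvae_sequenced_per_pair", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if len(self.colony_names) < self.n_colonies:
            self.colony_names = tuple(
                f"C{i + 1}" for i in range(self.n_colonies)
            )

    @property
    def n_sequenced(self) -> int:
        """Sequenced samples: one retained couple + larvae, per family x generation."""
        per_cell = 2 + self.n_larvae_sequenced_per_pair
        return self.n_colonies * self.n_families * self.n_generations * per_cell


@dataclass
class ErrorModel:
    """Genotyping error model: mistyping and missingness, optional depth."""

    mistype_rate: float = 0.05
    missing_rate: float = 0.05
    depth_mean: float | None = 20.0
    depth_sd: float | None = 8.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mistype_rate < 1.0):
            raise ValueError("mistype_rate must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class Individual:
    id: str
    colony: str
    generation: int
    family: str
    role: str
    sire: str | None = None
    dam: str | None = None
    sequenced: bool = False
    pair: int | None = None  # index of the mating pair this individual belongs to

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class Pedigree:
    """Collection of individuals with parent links and kinship queries."""

    def __init__(self, individuals: list[Individual]):
        self._by_id: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._by_id:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        for ind in individuals:
            if (ind.sire is None) != (ind.dam is None):
                raise ValueError(f"{ind.id}: must have both parents or neither")
            for pid in (ind.sire, ind.dam):
                if pid is not None and pid not in self._by_id:
                    raise ValueError(f"{ind.id}: unresolved parent {pid!r}")

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def __iter__(self):
        return iter(self._by_id.values())

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def founders(self) -> list[Individual]:
        return [i for i in self if i.is_founder]

    def sequenced_ids(self) -> list[str]:
        return [i.id for i in self if i.sequenced]

    def couples(self, sequenced_only: bool = True) -> pd.DataFrame:
        """Retained mating couples as (colony, family, generation, sire, dam)."""
        rows = []
        by_key: dict[tuple, dict[str, str]] = {}
        for ind in self:
            if ind.role not in ("sire", "dam") or ind.pair is None:
                continue
            if sequenced_only and not ind.sequenced:
                continue
            key = (ind.colony, ind.family, ind.generation, ind.pair)
            by_key.setdefault(key, {})[ind.role] = ind.id
        for (colony, family, gen, pair), members in sorted(by_key.items()):
            if set(members) == {"sire", "dam"}:
                rows.append(
                    {"colony": colony, "family": family, "generation": gen,
                     "pair": pair, "sire": members["sire"], "dam": members["dam"]}
                )
        return pd.DataFrame(rows)

    # -- kinship / inbreeding -------------------------------------------
    def kinship(self, a: str, b: str) -> float:
        """Coefficient of kinship (coancestry) between two individuals."""
        if a not in self._by_id or b not in self._by_id:
            raise KeyError("unknown individual id")
        return self._kinship(a, b)

    @lru_cache(maxsize=None)  # noqa: B019 - pedigree is immutable after init
    def _kinship(self, a: str, b: str) -> float:
        ia, ib = self._by_id[a], self._by_id[b]
        if a == b:
            return 0.5 * (1.0 + self.inbreeding(a))
        # recurse on the younger individual; parents are always older
        if ia.generation < ib.generation:
            ia, ib = ib, ia
        if ia.is_founder:
            return 0.0  # distinct founders are assumed unrelated
        return 0.5 * (self._kinship(ia.sire, ib.id) + self._kinship(ia.dam, ib.id))

    def inbreeding(self, ind_id: str) -> float:
        """Wright's inbreeding coefficient F from the pedigree."""
        ind = self._by_id[ind_id]
        if ind.is_founder:
            return 0.0
        return self._kinship(ind.sire, ind.dam)

    # -- tabular export --------------------------------------------------
    def to_dataframe(self, with_inbreeding: bool = True) -> pd.DataFrame:
        rows = []
        for ind in self:
            row = {
                "id": ind.id, "colony": ind.colony, "generation": ind.generation,
                "family": ind.family, "role": ind.role, "sire": ind.sire or "",
                "dam": ind.dam or "", "sequenced": ind.sequenced,
            }
            if with_inbreeding:
                row["F"] = self.inbreeding(ind.id)
            rows.append(row)
        return pd.DataFrame(rows)

    def sample_table(self, ids: list[str]) -> pd.DataFrame:
        """Per-sample metadata table (genotypes.SAMPLE_COLUMNS) for given ids."""
        rows = []
        for sid in ids:
            ind = self._by_id[sid]
            rows.append(
                {"id": sid, "colony": ind.colony, "generation": ind.generation,
                 "family": ind.family, "role": ind.role,
                 "sire": ind.sire or "", "dam": ind.dam or ""}
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# founder allele frequencies
# ---------------------------------------------------------------------------

def sample_founder_frequencies(
    n_loci: int, maf_low: float, maf_high: float, seed: int
) -> AlleleFrequencies:
    """Draw per-locus founder MAF uniformly in (maf_low, maf_high].

    The minor allele is assigned to reference or alternate with equal
    probability, so alt_freq may exceed 0.5; the folded MAF respects the
    requested bounds.
    """
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    # uniform on (low, high]: reflect the half-open side
    maf = maf_high - rng.random(n_loci) * (maf_high - maf_low)
    flip = rng.random(n_loci) < 0.5
    alt = np.where(flip, 1.0 - maf, maf)
    ids = [f"snp{i:06d}" for i in range(n_loci)]
    return AlleleFrequencies(ids, alt)


# ---------------------------------------------------------------------------
# pedigree construction
# ---------------------------------------------------------------------------

def build_design(config: DesignConfig, seed: int = 0) -> Pedigree:
    """Build the full-sib breeding pedigree for the configured design.

    Generation 0 holds the hand-picked founder pairs; generations g >= 1 hold
    candidate pairs formed from full sibs (offspring of the retained pair of
    generation g-1) plus the sequenced larvae. The retained pair of each
    family x generation is pair 0 (retention in the study was by biomass,
    which has no genotypic consequence).
    """
    individuals: list[Individual] = []
    n_gen = config.n_generations
    for c in range(config.n_colonies):
        colony = config.colony_names[c]
        for f in range(config.n_families):
            family = f"{colony}-F{f + 1:02d}"
            # founder candidate pairs at generation 0
            pair_members: dict[tuple[int, int], tuple[str, str]] = {}
            for p in range(config.n_pairs_per_family):
                sid = f"{family}-G0-P{p}-S"
                did = f"{family}-G0-P{p}-D"
                retained = p == 0
                individuals.append(Individual(sid, colony, 0, family, "sire",
                                              sequenced=retained, pair=p))
                individuals.append(Individual(did, colony, 0, family, "dam",
                                              sequenced=retained, pair=p))
                pair_members[(0, p)] = (sid, did)
            for g in range(1, n_gen + 1):
                sire, dam = pair_members[(g - 1, 0)]  # retained pair
                # sequenced larvae of this generation
                for j in range(config.n_larvae_sequenced_per_pair):
                    lid = f"{family}-G{g}-L{j + 1}"
                    individuals.append(Individual(lid, colony, g, family, "larva",
                                                  sire=sire, dam=dam, sequenced=True))
                # candidate pairs for the next mating round (full sibs)
                if g < n_gen:
                    for p in range(config.n_pairs_per_family):
                        sid = f"{family}-G{g}-P{p}-S"
                        did = f"{family}-G{g}-P{p}-D"
                        retained = p == 0
                        individuals.append(Individual(sid, colony, g, family, "sire",
                                                      sire=sire, dam=dam,
                                                      sequenced=retained, pair=p))
                        individuals.append(Individual(did, colony, g, family, "dam",
                                                      sire=sire, dam=dam,
                                                      sequenced=retained, pair=p))
                        pair_members[(g, p)] = (sid, did)
    return Pedigree(individuals)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _default_locus_table(n_loci: int, locus_ids: list[str],
                         rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic genomic coordinates: 7 chromosomes, one SNP per RAD locus.

    Position within the RAD locus is uniform on [1, 100] so the positional
    QC window (40-70 bp) behaves as it would on real reduced-representation
    data.
    """
    chrom = rng.integers(1, 8, n_loci)
    pos = rng.integers(1, 100_000_000, n_loci)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    # deduplicate positions deterministically
    pos = pos + np.arange(n_loci)
    return pd.DataFrame(
        {"id": locus_ids, "chrom": [f"chr{c}" for c in chrom], "pos": pos,
         "rad_locus": [f"rad{i:06d}" for i in range(n_loci)],
         "pos_in_locus": rng.integers(1, 101, n_loci)}
    )


def _mate(g_sire: np.ndarray, g_dam: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mendelian transmission: one uniformly drawn allele from each parent."""
    a = rng.random(g_sire.shape) < g_sire / 2.0
    b = rng.random(g_dam.shape) < g_dam / 2.0
    return (a.astype(np.int8) + b.astype(np.int8)).astype(np.int8)


def drop_genotypes(
    pedigree: Pedigree,
    freqs: AlleleFrequencies,
    seed: int = 0,
    locus_table: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Error-free genotypes for every pedigree member.

    Founders are drawn under Hardy-Weinberg proportions from ``freqs``;
    every non-founder receives one uniformly random allele from each parent
    at each locus.
    """
    rng = np.random.default_rng(seed)
    n_loci = freqs.n_loci
    inds = sorted(pedigree, key=lambda i: (i.generation, i.id))
    geno: dict[str, np.ndarray] = {}
    q = freqs.alt_freq
    for ind in inds:
        if ind.is_founder:
            g = ((rng.random(n_loci) < q).astype(np.int8)
                 + (rng.random(n_loci) < q).astype(np.int8))
        else:
            g = _mate(geno[ind.sire], geno[ind.dam], rng)
        geno[ind.id] = g
    ids = [i.id for i in inds]
    calls = np.stack([geno[i] for i in ids])
    if locus_table is None:
        locus_table = _default_locus_table(n_loci, freqs.locus_ids,
                                           np.random.default_rng(seed + 1))
    return GenotypeMatrix(calls=calls, samples=pedigree.sample_table(ids),
                          loci=locus_table)


def expected_inbreeding(pedigree: Pedigree, ind_id: str) -> float:
    """Wright's F for one individual (pedigree path counting)."""
    return pedigree.inbreeding(ind_id)


# ---------------------------------------------------------------------------
# genotyping error
# ---------------------------------------------------------------------------

def corrupt(
    truth: GenotypeMatrix,
    model: ErrorModel,
    freqs: AlleleFrequencies,
    seed: int = 0,
) -> GenotypeMatrix:
    """Apply mistyping and missingness to an error-free matrix.

    Each call is independently replaced, with probability ``mistype_rate``,
    by a fresh Hardy-Weinberg draw at that locus (the replacement may equal
    the original call), and independently set missing with probability
    ``missing_rate``. When the model carries a depth distribution, per-call
    read depths are drawn gamma-Poisson; missing calls get depth 0.
    """
    if truth.n_loci != freqs.n_loci:
        raise ValueError("frequency vector does not match matrix loci")
    rng = np.random.default_rng(seed)
    n, L = truth.calls.shape
    calls = truth.calls.copy()
    if model.mistype_rate > 0:
        hit = rng.random((n, L)) < model.mistype_rate
        q = freqs.alt_freq
        hwe_draw = ((rng.random((n, L)) < q).astype(np.int8)
                    + (rng.random((n, L)) < q).astype(np.int8))
        calls = np.where(hit, hwe_draw, calls).astype(np.int8)
    if model.missing_rate > 0:
        calls = np.where(rng.random((n, L)) < model.missing_rate,
                         MISSING, calls).astype(np.int8)
    depth = None
    if model.depth_mean is not None:
        sd = model.depth_sd if model.depth_sd else np.sqrt(model.depth_mean)
        shape = (model.depth_mean / sd) ** 2
        scale = sd**2 / model.depth_mean
        lam = rng.gamma(shape, scale, (n, L))
        depth = rng.poisson(lam).astype(np.int32)
        depth[calls == MISSING] = 0
    return GenotypeMatrix(calls=calls, samples=truth.samples.copy(),
                          loci=truth.loci.copy(), depth=depth)


# ---------------------------------------------------------------------------
# post-QC style subsampling
# ---------------------------------------------------------------------------

def subsample_qc(
    pedigree: Pedigree,
    matrix: GenotypeMatrix,
    n_couples_by_colony: dict[str, int] | None = None,
    n_larvae_by_colony: dict[str, int] | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Subsample sequenced couples and larvae to post-QC study sizes.

    Defaults mirror the study's surviving samples: 19 + 28 couples and
    23 + 52 larvae for the two colonies (47 couples, 75 larvae in total).
    Larvae are drawn only among offspring of retained couples so that every
    retained larva has both true parents in the candidate set.
    """
    names = sorted({i.colony for i in pedigree})
    if n_couples_by_colony is None:
        n_couples_by_colony = dict(zip(names, [19, 28]))
    if n_larvae_by_colony is None:
        n_larvae_by_colony = dict(zip(names, [23, 52]))
    rng = np.random.default_rng(seed)
    couples = pedigree.couples()
    keep_ids: list[str] = []
    kept_couples = []
    for colony in names:
        sub = couples[couples["colony"] == colony]
        k = n_couples_by_colony.get(colony, len(sub))
        if k > len(sub):
            raise ValueError(f"asked for {k} couples but colony {colony} has {len(sub)}")
        sel = sub.iloc[np.sort(rng.choice(len(sub), size=k, replace=False))]
        kept_couples.append(sel)
        keep_ids.extend(sel["sire"])
        keep_ids.extend(sel["dam"])
    kept = pd.concat(kept_couples)
    kept_pairs = set(zip(kept["sire"], kept["dam"]))
    for colony in names:
        larvae = [i.id for i in pedigree
                  if i.role == "larva" and i.sequenced and i.colony == colony
                  and (i.sire, i.dam) in kept_pairs]
        k = n_larvae_by_colony.get(colony, len(larvae))
        if k > len(larvae):
            raise ValueError(
                f"asked for {k} larvae but colony {colony} has {len(larvae)} eligible")
        larvae = sorted(larvae)
        sel = np.sort(rng.choice(len(larvae), size=k, replace=False))
        keep_ids.extend(larvae[i] for i in sel)
    keep_set = set(keep_ids)
    idx = [i for i, sid in enumerate(matrix.sample_ids) if sid in keep_set]
    return matrix.subset(sample_idx=np.asarray(idx))
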