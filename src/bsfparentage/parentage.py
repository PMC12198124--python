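"""Likelihood-based parentage assignment with simulated confidence thresholds.

The engine scores each candidate parent (or parent pair) against each
offspring with a summed per-locus log-likelihood ratio (A-LOD, natural log):

    A-LOD = sum_l ln P(obs | candidate is parent) / P(obs | unrelated)

Both hypotheses marginalize a mistyping model over the *true* genotypes:
an observed genotype equals the true one with probability 1 - e and is
otherwise an independent Hardy-Weinberg draw at that locus. Under the
single-parent hypothesis the unsampled co-parent contributes alleles at
population frequency; under the pair hypothesis both parents are the
candidates. With e = 0 the ratio reduces to Mendelian transmission over
Hardy-Weinberg priors and opposing homozygotes give -inf (exclusion).

Critical thresholds (C-LOD) at the relaxed (80%) and strict (95%)
confidence levels are calibrated by simulating a large offspring cohort
whose non-true candidates are full sibs of the true parents (relatedness
0.5) and whose parents are themselves full sibs for a configurable fraction
of offspring (the inbreeding rate). Confidence is the proportion of
most-likely candidates above a threshold that are true parents; when that
proportion already meets the confidence level with no thresholding the
sentinel -999.0 is reported (complete separation), and when no threshold
attains it, +999.0 (no power).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencies, GenotypeMatrix, hwe_genotype_probs

MODES = ("male", "female", "parent_pair")
CONFIDENCE_CLASSES = (
    "strict", "relaxed", "unassigned_most_likely", "unassigned_not_most_likely")
SENTINEL_HIGH_POWER = -999.0
SENTINEL_NO_POWER = 999.0
INBREEDING_RATES = (0.0, 0.05, 0.10, 0.25, 0.50, 1.0)


@dataclass
class SimulationParams:
    """Parameters of the confidence-calibration simulation."""

    n_offspring: int = 10_000
    n_candidate_parents: int = 47
    prop_sampled: float = 1.0
    prop_typed: float = 0.95
    mistype_rate: float = 0.05
    min_typed_frac: float = 0.5
    relatedness_r: float = 0.5
    inbreeding_rate: float = 0.0
    confidence_relaxed: float = 0.80
    confidence_strict: float = 0.95

    def __post_init__(self) -> None:
        for name in ("prop_sampled", "prop_typed", "mistype_rate",
                     "min_typed_frac", "inbreeding_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.confidence_relaxed <= self.confidence_strict < 1.0):
            raise ValueError("need 0 < relaxed <= strict < 1")

    def min_typed_loci(self, n_loci: int) -> int:
        return int(np.ceil(self.min_typed_frac * n_loci))


@dataclass
class CriticalThresholds:
    mode: str
    c_lod_relaxed: float
    c_lod_strict: float

    def __post_init__(self) -> None:
        for v in (self.c_lod_relaxed, self.c_lod_strict):
            if not (SENTINEL_HIGH_POWER <= v <= SENTINEL_NO_POWER):
                raise ValueError("C-LOD values must lie within [-999, 999]")


@dataclass
class CalibrationResult:
    thresholds: CriticalThresholds
    accuracy: float  # fraction of simulated offspring whose top candidate is true
    n_valid: int
    mean_alod_true: float
    alod_top: np.ndarray = field(repr=False)
    top_is_true: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def estimate_allele_freqs(matrix: GenotypeMatrix) -> AlleleFrequencies:
    """Per-locus alternate-allele frequencies from non-missing calls.

    Loci with no calls at all are excluded from the returned panel, so the
    result may be shorter than the input; callers should subset the matrix
    to ``freqs.locus_ids`` when that happens.
    """
    freqs = matrix.allele_frequencies()
    ok = ~np.isnan(freqs.alt_freq)
    if ok.all():
        return freqs
    return freqs.subset(np.flatnonzero(ok))


# ---------------------------------------------------------------------------
# per-locus LOD tables
# ---------------------------------------------------------------------------

def _error_kernel(h: np.ndarray, e: float) -> np.ndarray:
    """O[l, true, obs] = P(observed | true) under HWE-replacement mistyping."""
    L = h.shape[0]
    out = np.broadcast_to(e * h[:, None, :], (L, 3, 3)).copy()
    out[:, np.arange(3), np.arange(3)] += 1.0 - e
    return out


def _transmission_single(q: np.ndarray) -> np.ndarray:
    """T1[l, g_parent, g_off]: co-parent drawn from population frequencies."""
    L = q.shape[0]
    t = np.array([0.0, 0.5, 1.0])  # P(transmit alt | parent genotype)
    T = np.empty((L, 3, 3))
    for gp in range(3):
        T[:, gp, 0] = (1 - t[gp]) * (1 - q)
        T[:, gp, 1] = t[gp] * (1 - q) + (1 - t[gp]) * q
        T[:, gp, 2] = t[gp] * q
    return T


def _transmission_pair() -> np.ndarray:
    """T2[g_sire, g_dam, g_off] under Mendelian transmission."""
    t = np.array([0.0, 0.5, 1.0])
    T = np.empty((3, 3, 3))
    for gs in range(3):
        for gd in range(3):
            T[gs, gd, 0] = (1 - t[gs]) * (1 - t[gd])
            T[gs, gd, 2] = t[gs] * t[gd]
            T[gs, gd, 1] = 1.0 - T[gs, gd, 0] - T[gs, gd, 2]
    return T


_T2 = _transmission_pair()


def lod_table_single(freqs: AlleleFrequencies, e: float) -> np.ndarray:
    """S[l, obs_off, obs_cand]: per-locus single-parent LOD contributions."""
    q = freqs.alt_freq
    h = hwe_genotype_probs(q)
    O = _error_kernel(h, e)
    T1 = _transmission_single(q)
    # joint P(obs_o, obs_c | candidate is a parent)
    joint = np.einsum("lc,lcx,lco,loy->lyx", h, O, T1, O)
    marg = np.einsum("lg,lgx->lx", h, O)  # P(obs)
    with np.errstate(divide="ignore"):
        return (np.log(joint) - np.log(marg)[:, :, None]
                - np.log(marg)[:, None, :])


def lod_table_pair(freqs: AlleleFrequencies, e: float) -> np.ndarray:
    """P[l, obs_off, obs_sire, obs_dam]: per-locus parent-pair LOD."""
    q = freqs.alt_freq
    h = hwe_genotype_probs(q)
    O = _error_kernel(h, e)
    joint = np.einsum("ls,lsx,ld,ldy,sdo,loz->lzxy", h, O, h, O, _T2, O)
    marg = np.einsum("lg,lgx->lx", h, O)
    with np.errstate(divide="ignore"):
        return (np.log(joint)
                - np.log(marg)[:, :, None, None]
                - np.log(marg)[:, None, :, None]
                - np.log(marg)[:, None, None, :])


def lod_single(g_o: int, g_c: int, alt_freq: float, e: float) -> float:
    """Single-locus, single-parent LOD (natural log); -inf on exclusion at e=0."""
    fr = AlleleFrequencies(["x"], np.array([alt_freq]))
    return float(lod_table_single(fr, e)[0, g_o, g_c])


def lod_pair(g_o: int, g_s: int, g_d: int, alt_freq: float, e: float) -> float:
    """Single-locus parent-pair LOD (natural log)."""
    fr = AlleleFrequencies(["x"], np.array([alt_freq]))
    return float(lod_table_pair(fr, e)[0, g_o, g_s, g_d])


# ---------------------------------------------------------------------------
# vectorized scoring
# ---------------------------------------------------------------------------

def score_single(table: np.ndarray, obs_o: np.ndarray, obs_c: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Summed A-LOD of offspring vs candidates using a single-parent table.

    obs_o: (..., L); obs_c: (..., C, L) with a candidate axis before the
    locus axis. Loci missing on either side are skipped.
    Returns (alod, n_compared) with the candidate axis last.
    """
    L = table.shape[0]
    o = obs_o[..., None, :]
    valid = (o != MISSING) & (obs_c != MISSING)
    oi = np.where(o == MISSING, 0, o).astype(np.intp)
    ci = np.where(obs_c == MISSING, 0, obs_c).astype(np.intp)
    vals = table.reshape(L, 9)[np.arange(L), oi * 3 + ci]
    alod = np.where(valid, vals, 0.0).sum(axis=-1)
    return alod, valid.sum(axis=-1)


def score_pair(table: np.ndarray, obs_o: np.ndarray, obs_s: np.ndarray,
               obs_d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Summed A-LOD of offspring vs candidate pairs using a pair table.

    obs_o: (..., L); obs_s, obs_d: (..., C, L). Loci missing in the
    offspring or in *both* members of the pair are skipped; a locus typed in
    only one member contributes through the single-parent marginalization
    implied by the error kernel, so for simplicity it is skipped as well
    (a locus counts only when all three genotypes are observed).
    """
    L = table.shape[0]
    o = obs_o[..., None, :]
    valid = (o != MISSING) & (obs_s != MISSING) & (obs_d != MISSING)
    oi = np.where(o == MISSING, 0, o).astype(np.intp)
    si = np.where(obs_s == MISSING, 0, obs_s).astype(np.intp)
    di = np.where(obs_d == MISSING, 0, obs_d).astype(np.intp)
    vals = table.reshape(L, 27)[np.arange(L), (oi * 3 + si) * 3 + di]
    alod = np.where(valid, vals, 0.0).sum(axis=-1)
    return alod, valid.sum(axis=-1)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _hwe_draw(q: np.ndarray, shape: tuple[int, ...], rng: np.random.Generator
              ) -> np.ndarray:
    return ((rng.random(shape + (q.shape[0],)) < q).astype(np.int8)
            + (rng.random(shape + (q.shape[0],)) < q).astype(np.int8))


def _mate(g1: np.ndarray, g2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    a = rng.random(g1.shape) < g1 / 2.0
    b = rng.random(g2.shape) < g2 / 2.0
    return (a.astype(np.int8) + b.astype(np.int8)).astype(np.int8)


def _observe(g: np.ndarray, q: np.ndarray, e: float, prop_typed: float,
             rng: np.random.Generator) -> np.ndarray:
    obs = g
    if e > 0:
        hit = rng.random(g.shape) < e
        obs = np.where(hit, _hwe_draw(q, g.shape[:-1], rng), obs).astype(np.int8)
    if prop_typed < 1.0:
        obs = np.where(rng.random(g.shape) < prop_typed, obs, MISSING).astype(np.int8)
    return obs


def critical_lod(alod: np.ndarray, is_true: np.ndarray, confidence: float) -> float:
    """Smallest threshold whose exceeders are true parents at the given rate.

    Returns -999.0 when the criterion holds with no thresholding (complete
    separation) and +999.0 when no threshold attains it.
    """
    n = alod.shape[0]
    if n == 0:
        return SENTINEL_NO_POWER
    order = np.argsort(-alod, kind="stable")
    frac_true = np.cumsum(is_true[order]) / np.arange(1, n + 1)
    ok = frac_true >= confidence
    if ok[-1]:
        return SENTINEL_HIGH_POWER
    if not ok.any():
        return SENTINEL_NO_POWER
    k = int(np.flatnonzero(ok).max())  # largest prefix meeting the confidence
    return float(np.clip(alod[order][k], SENTINEL_HIGH_POWER, SENTINEL_NO_POWER))


def calibrate(
    freqs: AlleleFrequencies,
    params: SimulationParams,
    mode: str,
    seed: int,
    batch: int = 1000,
) -> CalibrationResult:
    """Monte-Carlo calibration of the critical LOD thresholds for one mode.

    For every simulated offspring, true parents are bred from Hardy-Weinberg
    grandparents (shared between sire and dam for the inbred fraction), the
    other ``n_candidate_parents - 1`` candidates are full sibs of the true
    parent of the relevant sex, typing and mistyping noise is applied, all
    candidates are scored, and the most likely candidate's A-LOD is recorded
    together with whether it is the true parent.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    rng = np.random.default_rng(seed)
    q = freqs.alt_freq
    L = q.shape[0]
    C = params.n_candidate_parents
    e = params.mistype_rate
    min_typed = params.min_typed_loci(L)
    table_s = lod_table_single(freqs, e) if mode in ("male", "female") else None
    table_p = lod_table_pair(freqs, e) if mode == "parent_pair" else None

    tops, trues = [], []
    n_done = 0
    while n_done < params.n_offspring:
        n = min(batch, params.n_offspring - n_done)
        n_done += n
        inbred = rng.random(n) < params.inbreeding_rate
        pg_m = _hwe_draw(q, (n,), rng)
        pg_f = _hwe_draw(q, (n,), rng)
        mg_m = np.where(inbred[:, None], pg_m, _hwe_draw(q, (n,), rng)).astype(np.int8)
        mg_f = np.where(inbred[:, None], pg_f, _hwe_draw(q, (n,), rng)).astype(np.int8)
        sire = _mate(pg_m, pg_f, rng)
        dam = _mate(mg_m, mg_f, rng)
        off = _mate(sire, dam, rng)
        obs_off = _observe(off, q, e, params.prop_typed, rng)
        typed = (obs_off != MISSING).sum(axis=1)
        valid = typed >= min_typed

        def sib_pool(gm, gf):
            # candidate k=0 is the true parent; others are its full sibs
            pool = np.empty((n, C, L), dtype=np.int8)
            gm_b = np.repeat(gm[:, None, :], C - 1, axis=1)
            gf_b = np.repeat(gf[:, None, :], C - 1, axis=1)
            pool[:, 1:, :] = _mate(gm_b, gf_b, rng)
            return pool

        if mode == "male":
            cand = sib_pool(pg_m, pg_f)
            cand[:, 0, :] = sire
            obs_c = _observe(cand, q, e, params.prop_typed, rng)
            alod, _ = score_single(table_s, obs_off, obs_c)
        elif mode == "female":
            cand = sib_pool(mg_m, mg_f)
            cand[:, 0, :] = dam
            obs_c = _observe(cand, q, e, params.prop_typed, rng)
            alod, _ = score_single(table_s, obs_off, obs_c)
        else:
            cand_m = sib_pool(pg_m, pg_f)
            cand_m[:, 0, :] = sire
            cand_f = sib_pool(mg_m, mg_f)
            cand_f[:, 0, :] = dam
            obs_m = _observe(cand_m, q, e, params.prop_typed, rng)
            obs_f = _observe(cand_f, q, e, params.prop_typed, rng)
            alod, _ = score_pair(table_p, obs_off, obs_m, obs_f)

        top = np.argmax(alod, axis=1)
        tops.append(alod[np.arange(n), top][valid])
        trues.append((top == 0)[valid])

    alod_top = np.concatenate(tops)
    top_is_true = np.concatenate(trues)
    thr = CriticalThresholds(
        mode=mode,
        c_lod_relaxed=critical_lod(alod_top, top_is_true, params.confidence_relaxed),
        c_lod_strict=critical_lod(alod_top, top_is_true, params.confidence_strict),
    )
    true_scores = alod_top[top_is_true]
    return CalibrationResult(
        thresholds=thr,
        accuracy=float(top_is_true.mean()) if alod_top.size else float("nan"),
        n_valid=int(alod_top.size),
        mean_alod_true=float(true_scores.mean()) if true_scores.size else float("nan"),
        alod_top=alod_top,
        top_is_true=top_is_true,
    )


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _classify(a_lod: float, thr: CriticalThresholds) -> str:
    if a_lod >= thr.c_lod_strict:
        return "strict"
    if a_lod >= thr.c_lod_relaxed:
        return "relaxed"
    return "unassigned_most_likely" if a_lod > 0 else "unassigned_not_most_likely"


def assign(
    obs_o: np.ndarray,
    candidate_ids: list,
    obs_c: np.ndarray,
    thresholds: CriticalThresholds,
    table: np.ndarray,
    min_typed: int,
    obs_c2: np.ndarray | None = None,
) -> dict:
    """Assign one offspring to its most likely candidate (or pair).

    ``obs_c`` has shape (C, L); for parent-pair mode pass the sire
    observations in ``obs_c`` and the dam observations in ``obs_c2`` (the
    candidate ids then identify couples). Ties on the A-LOD are broken by
    candidate order.
    """
    if len(candidate_ids) == 0:
        raise ValueError("empty candidate set")
    if obs_c2 is None:
        alod, n_cmp = score_single(table, obs_o, obs_c)
    else:
        alod, n_cmp = score_pair(table, obs_o, obs_c, obs_c2)
    best = int(np.argmax(alod))
    if int(n_cmp[best]) < min_typed:
        return {"candidate": None, "a_lod": float("nan"), "n_loci_compared":
                int(n_cmp[best]), "confidence_class": "unassigned_not_most_likely"}
    return {
        "candidate": candidate_ids[best],
        "a_lod": float(alod[best]),
        "n_loci_compared": int(n_cmp[best]),
        "confidence_class": _classify(float(alod[best]), thresholds),
    }


def batch_assign(
    matrix: GenotypeMatrix,
    mode: str,
    thresholds: CriticalThresholds,
    params: SimulationParams,
    freqs: AlleleFrequencies | None = None,
) -> pd.DataFrame:
    """Assign every larva in the matrix within its colony x generation.

    Candidates are the sequenced parents (or couples) of the same colony
    whose mating generation is the larva's generation minus one. Offspring
    with an empty candidate set are skipped. Returns one row per tested
    offspring with the true parent for accuracy bookkeeping.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if freqs is None:
        freqs = estimate_allele_freqs(matrix)
        if freqs.n_loci != matrix.n_loci:
            keep = [matrix.locus_ids.index(i) for i in freqs.locus_ids]
            matrix = matrix.subset(locus_idx=np.asarray(keep))
    e = params.mistype_rate
    min_typed = params.min_typed_loci(matrix.n_loci)
    table = (lod_table_pair(freqs, e) if mode == "parent_pair"
             else lod_table_single(freqs, e))
    samples = matrix.samples
    idx = {sid: i for i, sid in enumerate(matrix.sample_ids)}
    larvae = samples[samples["role"] == "larva"]
    present = set(samples["id"])
    # couples: (colony, generation) -> list of (sire, dam)
    parents = samples[samples["role"].isin(["sire", "dam"])]
    couples: dict[tuple, list[tuple[str, str]]] = {}
    sire_rows = parents[parents["role"] == "sire"]
    for row in sire_rows.itertuples():
        couples.setdefault((row.colony, row.generation), [])
    # pair sires with dams that share colony/generation/family
    dams = parents[parents["role"] == "dam"]
    dam_lookup = {(r.colony, r.generation, r.family): r.id for r in dams.itertuples()}
    for row in sire_rows.itertuples():
        mate = dam_lookup.get((row.colony, row.generation, row.family))
        if mate is not None:
            couples[(row.colony, row.generation)].append((row.id, mate))

    rows = []
    for larva in larvae.itertuples():
        key = (larva.colony, larva.generation - 1)
        cands = sorted(couples.get(key, []))
        if not cands:
            continue
        obs_o = matrix.calls[idx[larva.id]]
        if mode == "male":
            ids = [s for s, _ in cands]
            obs_c = matrix.calls[[idx[s] for s in ids]]
            res = assign(obs_o, ids, obs_c, thresholds, table, min_typed)
            true_id = larva.sire if larva.sire in present else None
        elif mode == "female":
            ids = [d for _, d in cands]
            obs_c = matrix.calls[[idx[d] for d in ids]]
            res = assign(obs_o, ids, obs_c, thresholds, table, min_typed)
            true_id = larva.dam if larva.dam in present else None
        else:
            ids = [f"{s}+{d}" for s, d in cands]
            obs_s = matrix.calls[[idx[s] for s, _ in cands]]
            obs_d = matrix.calls[[idx[d] for _, d in cands]]
            res = assign(obs_o, ids, obs_s, thresholds, table, min_typed,
                         obs_c2=obs_d)
            true_id = (f"{larva.sire}+{larva.dam}"
                       if larva.sire in present and larva.dam in present else None)
        rows.append(
            {"offspring": larva.id, "mode": mode, "candidate": res["candidate"],
             "true_parent": true_id, "a_lod": res["a_lod"],
             "n_loci_compared": res["n_loci_compared"],
             "confidence_class": res["confidence_class"],
             "correct": res["candidate"] == true_id if true_id else np.nan}
        )
    return pd.DataFrame(rows)


def summarize_confidence(assignments: pd.DataFrame) -> pd.Series:
    """Percentage of tested offspring in each of the four confidence classes."""
    if len(assignments) == 0:
        raise ValueError("no assignments to summarize")
    counts = assignments["confidence_class"].value_counts()
    pct = pd.Series(
        {c: 100.0 * counts.get(c, 0) / len(assignments) for c in CONFIDENCE_CLASSES})
    return pct
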