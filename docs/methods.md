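# Methods

This note documents the models, estimators, numerical choices and known
limitations of `bsfparentage`. It is written for users deciding whether the
package's assumptions fit their data, and for maintainers wondering why a
design choice was made.

## The breeding-design simulator (`simpop`)

The simulator reproduces the statistical structure of a multigeneration
full-sib breeding experiment on black soldier fly. Per colony and family,
generation 0 holds the hand-picked founder mating pairs (assumed unrelated,
drawn from the colony at large). The retained pair of each generation
produces the next generation's larvae; in generations ≥ 1 every candidate
mating pair is formed from two of those larvae, so mates are full sibs.
Retention of the study's "best" pair was by larval biomass, which carries no
genotypic information, so the simulator retains pair 0 deterministically.

Default design: 2 colonies × 12 families × 3 generations × 4 pairs per
family, one retained pair plus 2 sequenced larvae per family-generation,
giving 288 sequenced samples. Larval inbreeding follows the full-sib
recurrence F_t = ¼(1 + 2F_{t−1} + F_{t−2}): F = 0, 1/4, 3/8 for larvae of
generations 1–3. `Pedigree.inbreeding` computes Wright's F exactly via the
kinship recursion (tabular method) with distinct founders assumed unrelated,
so these values are recovered for any design.

**Founder allele frequencies** are drawn with MAF uniform on a configurable
interval (default (0.05, 0.5]); the source publication never states the
empirical MAF distribution beyond the absence of marked skew, so a flat
draw over the interval of interest is the neutral choice. The minor allele
is attached to the reference or alternate allele with equal probability.

**Gene dropping** is Mendelian: founders are Hardy–Weinberg draws, children
receive one uniformly chosen allele from each parent per locus,
independently across loci (no linkage; the LD-pruning stage exists to make
this assumption acceptable for real panels).

**Genotyping error** uses the replacement model assumed by the likelihood
engine: with probability *e* (default 0.05) a call is replaced by a fresh
Hardy–Weinberg draw at that locus (which may coincide with the truth), and
with probability *m* (default 0.05) a call is set missing. Depths, when
requested, are gamma-Poisson with mean 20 and sd 8 — chosen so that a clean
simulated dataset sits inside both depth-based QC windows (sample median
1–27×, marker mean 15–75×), which are outlier bounds inherited from the
real-data pipeline. Keeping the simulator's error model identical to the
engine's likelihood model is deliberate: it makes the calibration
simulation exactly matched to the data-generating process, which is the
assumption the reference methodology itself makes.

**Post-QC subsampling.** In the study, sample-level QC reduced the 288
sequenced samples to 47 couples and 75 larvae (19 + 28 couples and 23 + 52
larvae per colony). QC attrition depends on depth and library artifacts the
simulator does not model, so `subsample_qc` imposes those counts directly
by seeded subsampling, drawing larvae only among offspring of retained
couples (a larva whose parents were lost to QC cannot be scored for
accuracy). Tests and the acceptance script use this to reproduce the
study-sized assignment problem.

What the simulator does **not** emulate: read-level artifacts (allele
dropout correlated with depth, paralogous RAD loci), linkage, sex
chromosomes, selection or phenotypes, and colony divergence beyond
independent founder draws. Consequently, passing results demonstrate the
correctness and power of the method under its own assumptions — not the
quality of any particular empirical genotype set.

## The QC cascade (`qcfilter`)

Filters run in a fixed order (marker pre-filters → sample outlier screens →
marker filters → positional filters → HWE → Mendel → LD), each step logged
with counts. All thresholds are configuration; `None` disables a step.
Notable semantics:

* **Sample screens are one-shot.** Sample missingness/heterozygosity are
  defined against the marker set at screening time. Re-applying them to a
  small filtered panel would re-classify samples on noisy statistics, so
  idempotence of the cascade is a marker-side property (covered by tests);
  sample screens are intended to run once on the full call set.
* **HWE**: exact conditional test (not χ²), two-sided by probability mass,
  on pooled samples — robust at the small counts this pipeline sees.
  Implemented with log-factorials; monomorphic loci return p = 1.
* **Mendelian error**: per-marker error rate across known trios (threshold
  0.03); trios with a missing member at a locus are not evaluable there; a
  locus with no evaluable trios passes by convention. Per-trio removal is
  not implemented (the reference pipeline's setting removed no trios).
* **LD pruning** uses variant-count windows (50 variants, step 5), matching
  the semantics of the tool the thresholds come from, even though the
  source text says "bp". Within a window the worst pair above r² = 0.5
  loses its later-positioned member; ties and ordering are deterministic.
  r² is the squared Pearson correlation of 0/1/2 dosages over
  pairwise-complete samples; undefined r² (zero variance) counts as 0.
* **One SNP per RAD locus** keeps the first SNP by position; the goal
  (avoid intra-fragment LD) does not single out a pick rule, so the
  deterministic one is used.
* **MAF tiers**: panel subsets keep loci with MAF *strictly* above each
  tier (0.40, 0.45, 0.47, 0.48 by default), giving nested panels.
* MAF/MAC are computed on pooled colonies after the shared-across-colonies
  filter.

Monotonicity caveat: tightening one threshold never increases survivors for
the marginal filters, but LD pruning can interact (removing a hub locus can
spare its partners), so the monotonicity guarantee — and its test — applies
with LD pruning disabled.

## Panel statistics (`popstats`)

Per locus with alternate-allele frequency p and q = 1 − p:

* Hₑ = 2pq; H₀ = heterozygote fraction of non-missing calls;
  F_IS = 1 − H₀/Hₑ (0 by convention when Hₑ = 0).
* π applies the unbiased correction n/(n − 1) to Hₑ with n = non-missing
  allele copies, i.e. the estimator reduced-representation callers report.
* PIC (Botstein) = 1 − (p² + q²) − 2p²q².
* Non-exclusion probabilities, assuming error-free genotypes and HWE
  (classical definitions; error-aware power is the likelihood engine's
  job):
  * first parent: NE₁ = 1 − 2p²q² (exclusion only via opposing
    homozygotes);
  * second parent: NE₂ = p⁴ − 2p³ + 2p² − p + 1;
  * parent pair: NE_PP = 6p⁶ − 18p⁵ + 23p⁴ − 16p³ + 7p² − 2p + 1.

  The polynomials were derived by exhaustive enumeration over genotype
  configurations and are validated in the test suite against an
  independent enumeration to 1e−12. Multilocus values are per-locus
  products (independent loci — hence the LD pruning upstream).
* F_ST is the Weir–Cockerham θ per locus, unweighted mean across loci.
  Note that AMOVA-based estimators used by some pipelines differ by a
  roughly constant offset; cross-tool comparisons should expect that.

## The likelihood engine (`parentage`)

Scores are natural-log likelihood ratios. For offspring observation g_o and
candidate observation g_c at a locus with alternate frequency q and
mistyping rate e:

    LOD = ln P(g_o, g_c | c parent) − ln P(g_o) − ln P(g_c)

where true genotypes are marginalized under P(observed | true) =
(1 − e)·𝟙[obs = true] + e·HWE(obs), transmission is Mendelian, and the
unsampled co-parent contributes an allele at population frequency. The
parent-pair score conditions on both candidates. With e = 0 the single
score reduces to ln T(g_o|g_c)/P(g_o) and opposing homozygotes give −∞;
with e > 0 all scores are finite. Scores are additive over loci; loci with
a missing member are skipped, and an assignment needs at least
`min_typed_frac` (default 50%) of the panel compared to be valid. Log base
is natural throughout; printed LOD magnitudes (~10–30 for 50–100-locus
panels) are consistent with this choice.

**Calibration.** For each of 10,000 simulated offspring (defaults follow
the study: 47 candidates, 95% typed, 5% mistyped, all parents sampled),
true parents are bred from Hardy–Weinberg grandparents and the other
candidates of each sex are full sibs of the true parent (relatedness 0.5 —
the worst case for a full-sib breeding design, matching the study's
"relatives" setting). With probability equal to the inbreeding rate the
two parents share their grandparent pair, making the offspring inbred
(F = 0.25). Candidates are resampled per offspring. After scoring, the
most-likely candidate's A-LOD and its truth status feed the threshold
search: the critical LOD at confidence γ is the smallest threshold such
that, among most-likely candidates scoring at or above it, the fraction of
true parents is ≥ γ. If the criterion holds with no threshold the sentinel
−999.0 is reported (complete separation, a very-high-power panel); if no
threshold achieves it, +999.0 (no power). Both sentinels auto-satisfy /
auto-fail classification, and c_lod_strict ≥ c_lod_relaxed whenever both
are finite.

**Assignment classes.** strict (A-LOD ≥ strict C-LOD), relaxed (≥ relaxed
C-LOD), otherwise unassigned-most-likely when the best A-LOD is positive
and unassigned-not-most-likely when it is not (the reference tool's exact
trigger for the last split is undocumented; positivity of the likelihood
ratio is the natural rule). Ties on the A-LOD break by candidate order.
Offspring typed below the minimum are reported unassigned with no
candidate. In `batch_assign`, candidate couples are restricted to the
offspring's colony and the mating generation directly above it, exactly as
the study restricted comparisons.

Determinism: one root seed is spawned into per-stage streams
(`numpy.random.SeedSequence`); identical seeds give bit-identical matrices,
thresholds and CSVs. Across seeds, finite C-LODs at 10,000 offspring move
by well under half a LOD unit.

## Problem sizes and expected results

The test suite and acceptance script run everything at the study's own
scale — 192/118/72/51-SNP panels, 47 candidate couples, 75 larvae, 10,000
calibration offspring — which completes in seconds to a few tens of
seconds per calibration. Under those conditions the package reproduces the
published headline behaviour: mean Hₑ ≈ 0.5 and PIC ≈ 0.37 for the
high-MAF tiers; 51-locus non-exclusion probabilities ≈ 1.1e−3 / 2.5e−5 /
5e−8; 100% assignment accuracy in all three modes at every inbreeding rate
(candidate ranking does not involve the inbreeding dial, which only moves
the confidence thresholds); 100% strict-confidence assignments for the
192-SNP single-parent and 118-SNP parent-pair analyses; and the −999.0
complete-separation sentinel for the 192-SNP strict C-LOD. Smaller panels
show the expected degradation: finite, then positive C-LODs, shrinking
A-LODs, and growing unassigned classes.

## Known limitations

* Single-parent and pair likelihoods assume candidate genotype priors at
  HWE population frequencies; strong within-candidate-set structure beyond
  the simulated full-sib relatedness is not modeled.
* The error model treats mistyping as locus-independent HWE replacement;
  systematic errors (allele dropout proportional to depth) would require a
  genotype-likelihood input the engine does not take.
* No multigenerational reconstruction or sibship inference: each offspring
  is assigned independently against declared candidates.
* The LD pruner is quadratic within windows; it is meant for the
  hundreds-to-thousands of markers that survive the earlier filters, not
  for whole-genome variant sets.
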