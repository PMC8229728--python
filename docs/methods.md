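# Methods

## Compatibility genetics

A haploid nucleus carries one allele per incompatibility locus; a mycelium
carries 1–3 nuclei (homokaryon, heterokaryon, transient trikaryon as in a
Buller fusion cell). The somatic-compatibility predicate is unordered
allele-set equality per locus: two mycelia tolerate each other iff at every
locus they present the same set of alleles, so that every reader present in
the merged cytoplasm finds only written targets. Set equality makes
compatibility an equivalence relation, which is why "compatibility groups"
in a population survey are exact partitions rather than approximate
clusters.

Genotypes are enumerated as *ordered* pairs of nuclei (first × second),
matching the row structure of published compatibility tables in which
A1/A2 and A2/A1 appear as separate rows; the predicate itself ignores
order. Three routes compute the compatible fraction between two random
heterokaryons:

- **Enumeration** sums genotype-pair probabilities grouped by allele-set
  signature (Σ_g w_g², where w_g is the probability mass of signature g),
  which equals the naive double sum exactly. A configurable cap (default
  10⁶ ordered genotype pairs) refuses state spaces where enumeration is
  pointless; the Monte-Carlo route is the escape hatch.
- **Closed form**: per locus f = Σᵢ pᵢ⁴ + Σ_{i<j} 4 pᵢ² pⱼ² (both pairs
  homozygous for the same allele, or both carrying the same heterozygous
  pair in either order), multiplied across loci. For k uniform alleles
  f = (2k−1)/k³. Enumeration is the brute-force oracle for this formula in
  the tests (k ≤ 5, L ≤ 3, random frequency vectors, agreement to 1e-12).
- **Monte-Carlo** sampling of i.i.d. genotype pairs with binomial standard
  errors, vectorised over numpy; one `default_rng(seed)` per call.

Sibling cohorts model offspring of one fruiting body: each spore takes
either parental allele per locus with probability 1/2, independently
across loci (loci are unlinked throughout; linkage is out of scope).
Mating-type constraints on which siblings can actually mate are *not*
applied in the fraction calculations — the cohort arithmetic treats all
ordered sibling pairs as possible heterokaryons; mating-type compatibility
appears only as a boolean scenario input in the lifecycle layer.

Percentages are reported rounded half away from zero at the stated
precision, with the full-precision fraction always available alongside.
Note that 1 − 0.375² = 0.859375 rounds to 86 % and 1 − (15/81)² = 0.9657
rounds to 97 %, while the single-triallelic-locus incompatible fraction
1 − 15/81 = 81.48 % rounds to 81 %.

The population survey samples heterokaryon isolates (optionally with
planted clonal replicates assigned round-robin to a fixed number of
genotypes) and reports the number of compatibility groups and the
false-clonemate rate: the fraction of non-clonal pairs that are
nevertheless compatible. Its expectation is the analytic compatible
fraction; pairs sharing an isolate are weakly dependent, so the survey
tests use bands wider than the naive binomial SE.

## Reader/writer kinetics

The dynamics are the minimal mass-action system honouring the verbal
model: constitutive target production for every allele's target in every
cell, writing removes target from the unmodified pool, reading generates
signal *without consuming target* (a design choice — sequestering readers
would add a parameter without changing any qualitative outcome), signal
decays, death at a threshold. Per allele i:

    dRᵢ/dt = α·[i present] − δ_R Rᵢ
    dUᵢ/dt = β − k_write Rᵢ Uᵢ − δ_T Uᵢ
    dS/dt  = Σᵢ k_read Rᵢ Uᵢ − δ_S S

Readers act only on their own cognate target (per-allele pools; no
cross-target promiscuity). A bookkeeping pool Wᵢ (cumulative modified
target, dWᵢ/dt = k_write Rᵢ Uᵢ − δ_T Wᵢ) is carried so mass accounting is
testable (with decay off, β·t lands in U + W); it feeds back into nothing.

Default parameters (arbitrary consistent units): α = 1 conc/time,
δ_R = 0.1/time, β = 1 conc/time, δ_T = 0.05/time, k_write = 0.2,
k_read = 1.0 per conc·time (the five-fold reader activity), δ_S = 0.5/time.
The death threshold θ is not free: it is calibrated as the geometric mean
of the signal peaks of the two canonical scenarios — fertilization of a
homokaryon A by an incoming nucleus B (peak 46.80) and fusion of AB with
AC heterokaryons with equal-volume mixing (peak 71.13) — giving
θ = 57.694, a symmetric log-scale margin on each side. With these values
the resident heterokaryon baseline signal is positive but sub-threshold
(S* = 19.5), fertilization survives, identical-karyotype fusion survives,
heterokaryon fusion dies at t ≈ 0.59, and homokaryon–homokaryon fusion
dies later (t ≈ 0.96, uncensored peak 61.4), reproducing the observation
that fusion-cell death between homokaryons is slower than between
heterokaryons. Parameter regimes exist where that ordering reverses (e.g.
k_read × 100 at fixed θ); `death_margin` reports the broken ordering
rather than raising.

The integrator is a hand-rolled classical fixed-step 4th-order
Runge-Kutta (default dt = 0.01, t_max = 200), because the reproducibility
contract — identical trajectories for identical inputs, death-crossing
localized by linear interpolation *within* a step, state frozen
afterwards (death is absorbing) — is part of the model's specification;
an adaptive library solver would not provide the fixed-step grid the
trajectory CSV format promises. Halving dt changes the canonical peak by
< 1e-6 relative (Richardson-style check in the tests). Steady states have
closed forms (R* = α/δ_R, U* = β/(k_write R* + δ_T) when present,
U* = β/δ_T when absent) and are verified to be integrator fixed points.
Concentrations more negative than −1e-9 abort with advice to reduce dt;
smaller excursions are clipped to zero.

## Lifecycle scenarios and adjudication

Five candidate recognition mechanisms are encoded as fate rules over the
partners' karyotypes:

- *allelic / nonallelic interaction*: the merged cytoplasm dies whenever
  any locus carries ≥ 2 distinct alleles — including within a standalone
  heterokaryon, which is the decisive failure.
- *differential expression (heterokaryon-only)*: the recognition
  machinery is expressed as soon as at least one partner is heterokaryotic
  and kills any pairing whose allele sets differ; two homokaryons express
  nothing and always tolerate each other. This rule makes the Buller
  fusion cell die (the heterokaryotic partner recognises the homokaryon),
  so Buller success fails without needing a hard-coded verdict, and it
  predicts *no* fusion-cell death between homokaryons, contradicting the
  microscopy-based observation encoded as criterion C5.
- *reader/writer PTM* (with or without migration): dies exactly when the
  allele sets differ at some locus. Migration changes the mating outcome,
  never the fusion cell's fate.

The migration race: migration initiation is exponential with rate r per
fusion cell; death is deterministic at t_d (taken from the kinetics module
when kinetic parameters are supplied, else a configured constant, default
5 time units); over N independent anastomoses
P(escape) = 1 − (1 − (1 − e^{−r t_d}))^N. Only a single nucleus needs to
escape for the mating to succeed. Expected successful heterokaryotic
sectors ("tufts") are N·(1 − e^{−r t_d}) — small but positive in the
low-migration regime, matching species where homokaryon pairings yield
only a few tufts at the interaction zone. Migration occurs only into a
homokaryon partner (never into an established heterokaryon), only when
mating types are compatible, and only under the migration-capable model;
homokaryon×homokaryon migration is reciprocal, Buller migration is
unidirectional into the homokaryon with the fertilizing nucleus drawn
uniformly from the heterokaryon's two haplotypes (the choice is not
constrained by observation; the seed makes it reproducible).

Adjudication scores each mechanism against six observations (C1
heterokaryon viability, C2 heterokaryon–heterokaryon SI, C3 homokaryon
mating success, C4 Buller success, C5 fusion-cell death between
homokaryons, C6 common-nucleus SI) on canonical single-locus pairings with
nuclei A–D. The expected table — only PTM + migration consistent; allelic
and nonallelic fail C1; differential expression fails C4 and C5; PTM
without migration fails C3 and C4 — is asserted in the tests both with
configured and with kinetic death times.

## Synthetic data

The fixture generator emits the canonical uniform biallelic/triallelic
loci, seeded random loci (k ∈ 2..4, Dirichlet frequencies), isolate
populations with planted clones, the four canonical pairing scenarios and
the default kinetic parameters; fixed seed ⇒ byte-identical files. These
fixtures emulate idealised populations: allele frequencies are exactly at
their population values, isolates are unstructured and independent, and
loci are unlinked. Real SI surveys face relatedness structure, linkage,
unequal allele frequencies maintained by balancing selection, and scoring
noise in the macroscopic phenotype — none of which the generator models,
so passing tests validate the combinatorics and kinetics of the model, not
its fit to any particular field dataset.

## Problem sizes and numerical choices

Exact enumeration is used wherever the ordered-pair space is ≤ 10⁶
(configurable); the Monte-Carlo route runs at 10⁶ pairs for headline
estimates and 10⁵ per seed in the multi-seed tests. The migration-race
stochastic check uses 10⁵ replicates per (r, t_d, N) combination.
Kinetic runs use t_max = 200, dt = 0.01 (2 × 10⁴ RK4 steps); the
random-parameter non-negativity sweep shortens to t_max = 5 at dt = 0.005
over 100 draws with rates in [0.01, 10]. Frequency vectors must sum to 1
within 1e-12; analytic-vs-enumeration agreement is asserted at 1e-12;
ties at the death threshold (S exactly θ at a grid point) count as death
at that point.

## Limitations

No spatial structure (within-cell gradients, colony-interface geometry),
no stochastic chemical kinetics, no transcription/translation delays, no
prion-like conformational dynamics, no mating-type locus genetics
(tetrapolar/bipolar systems reduce to a boolean), and no evolutionary
dynamics of allele frequencies. The kinetic parameter set is a calibrated
illustration — the biology constrains only the five-fold reader activity
and the existence of a threshold — so quantitative outputs of the dynamics
layer (peak heights, death times) are meaningful relative to each other,
not in absolute units.
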