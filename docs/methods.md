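# Methods

## The trial model

All analyses assume a randomized-complete-block trait trial: G landraces
(genotypes), each grown in r replicate plots (blocks), with n repeated
measurements per plot at each of several growth stages. The synthetic
generator draws every observation from the additive model

    y_ijks = mu + tau_s + g_i + b_j + (gs)_is + e_ijks

with genotype effects g_i ~ N(0, σ²g) drawn once per landrace and shared
across blocks, stages and replicates; block effects b_j ~ N(0, σ²b) drawn
once per block; additive stage offsets tau_s; an optional
genotype-by-stage interaction (default variance 0 — the classical
variance-component formulas assume none, and the default conditions keep
that assumption); and i.i.d. residuals. An optional cross-trait genetic
correlation ρ makes the genotype effects of different traits share a
common landrace factor, which is how the generator emulates genetically
coupled trait families (e.g. all shoot dimensions responding to the same
vigor differences). Default ρ = 0: traits independent unless a study asks
otherwise.

The default configuration reproduces the reference trial design: 18
landraces (their field labels are kept), 3 blocks, 10 measurements per
plot, shoot traits (SL, SW, SFM, SDM) at 42/49/56/63 days after sowing,
peduncle/fruit dimensions (PL, PW, FL, FW) at 0–5 days after anthesis
(intact) and 7/14/21/28 (harvested), fruit mass (FM) at harvested stages
only. Per-trait grand means and variance components follow the reference
trial's published genetic-parameter table; where that table reports
intact- and harvested-stage rows separately for one dimension, the
intact-fruit values are used for the whole stage axis (a single residual
variance must hold at every stage, and the intact magnitudes remain
plausible throughout). Stage offsets reproduce the reported growth trends:
shoots elongate, peduncles shorten, fruits elongate and widen. Shoot
moisture content (SMC) is never simulated directly: it is derived per
sample as (fresh − dry)/fresh × 100 from the simulated SFM/SDM pairs,
exactly as it would be computed from field data. Samples where the dry
mass exceeds the fresh mass (possible under the Gaussian model, not in
nature) yield missing SMC values.

Missingness is whole-cell: one Bernoulli draw per (landrace, stage)
removes every block and replicate of that cell, mirroring non-harvestable
shoots and aborted fruits. The defaults blank BG-19's first shoot stage
and NSRC's entire shoot record deterministically (probability 1), and give
the three high-abortion landraces (NqSC, NRC, NSRC) a 0.35 per-cell
missingness at fruit stages — the trial report gives no abortion rate, so
0.35 was chosen once as a realistic severity that leaves every landrace
with some fruit data.

What the generator does **not** emulate: growth curves within a stage,
non-Gaussian or heteroscedastic residuals, spatial field trends within
blocks, season-by-genotype interaction (the reference data pool two
seasons), and measurement truncation at zero. Tests that pass on this
generator therefore validate the estimators under the design's own
assumptions; they do not certify behavior under real-data pathologies
beyond unbalancedness and whole-cell missingness.

## Mean separation

Letters in stagewise trait tables must be comparable both across landraces
within a stage and across stages within a landrace. The only reading that
permits this is a joint one-way ANOVA in which every landrace × stage cell
is one treatment level (observations = raw within-cell measurements);
`mean_separation` implements exactly that, drops empty cells, and applies
Tukey–Kramer for the unequal n that whole-cell missingness produces.

The studentized-range critical value is computed from first principles:
the CDF is the normal-range probability integrated over the distribution
of the chi scale factor √(χ²ν/ν) (Gauss–Legendre quadrature, 160 nodes per
axis, scale window ±12 SD around 1), inverted by Brent root-finding.
df = ∞ uses the limit form with the scale collapsed to 1. Agreement with
scipy's implementation and with the √2·t closed form at k = 2 is at the
10⁻³ level or better, which is also the accuracy of published tables.

Compact letter displays use insert-and-absorb: start with one column
holding all groups; for each significant pair still sharing a column,
split that column into two copies each missing one member; absorb columns
that become subsets of others. Columns are bitmasks, so absorption is a
single bitwise comparison and 150+ cells letter in ~2 s. The invariant —
two groups share a letter iff their pair is not significant — is verified
exhaustively over every significance matrix on up to 5 groups and on
random larger matrices. Letters run a–z then aa, ab, …; ordering follows
descending group means so 'a' always tags the top cell.

## Correlations

Stagewise matrices pool all landraces' per-replicate values at one stage
(the larger-n reading; correlating landrace cell means instead is a
switch). The combined matrix correlates per-landrace trait summaries in
which each stage's cell mean contributes equally (available-case at both
levels); pairs with |r| strictly above 0.6 are flagged. p-values come from
the exact t transform with n − 2 df; no multiple-testing correction is
applied, matching standard practice in these trait studies. Pairs are
dropped pairwise, never listwise, and a pair with fewer than 3 complete
observations or zero variance is reported as an NA cell rather than
failing the matrix.

## PCA and clustering

PCA operates on the correlation matrix of the landrace × 10-trait summary
(SL, SW, SFM, SDM, SMC, PL, PW, FL, FW, FM, each averaged over its
stages), so eigenvalues sum to 10 and per-component variability is
λ/10 × 100. Eigenvector signs are fixed by making each vector's
largest-magnitude element positive; loadings are eigenvectors scaled by
√λ, so all-component loadings reconstruct the correlation matrix exactly.
Kaiser retention keeps λ ≥ 1 (inclusive); if nothing qualifies the first
component is kept with a warning. A landrace missing a whole trait group
(e.g. no harvestable shoots) is mean-imputed per trait with a warning
before ordination — exclusion would silently drop the landrace from every
figure, and the reference analysis evidently kept such landraces.

Clustering is UPGMA on Euclidean distances between z-scored trait
summaries. The recurrence updates cluster distances as size-weighted means
(equivalently: the plain mean of all between-cluster leaf distances, which
is how the independent test oracle recomputes them); merge heights use the
d/2 ultrametric convention, ties break on the lexicographically smallest
label pair, and the merge history exports to Newick with branch lengths
that make every root-to-leaf path equal the final merge height.

## Genetic parameters

The replication unit is the block (r = 3), with genotype × block plot
means as ANOVA observations — "replications" in the moment formulas means
plots, not the 10 within-plot subsamples. Consequently MSE estimates the
plot-mean residual variance; with heavy subsampling this is far below the
per-measurement σ²e, and simulated heritabilities on the default
configuration are accordingly high. Recovery tests that target a known h²
therefore use one measurement per plot, making the configured σ²e the
plot-level residual directly (true h² = σ²g/(σ²g + σ²e) × 100).

A negative moment estimate (MSG − MSE)/r is truncated to zero and flagged;
truncation keeps h² in [0, 100] at the cost of a small positive bias near
σ²g = 0, which the test suite bounds (mean ĥ² < 15 under a null of 0).
Genetic advance is reported both in trait units and as a percentage of the
grand mean; the published table's GA column is on an unstated scale that
the stated formula cannot reproduce, so only the formula value is
computed. Likewise the published PCV/GCV/h² columns are internally
inconsistent with their own formulas and printed inputs; the package
implements the stated formulas, and only the additive identity
σ²p = σ²g + σ²e is used as a published numerical anchor.

## Numerical choices and problem sizes

- Quadrature/root-finding tolerances as above; q-values cached per
  (k, df, α).
- RCBD error SS computed by subtraction and clipped at 0 against
  catastrophic cancellation (≤ 1e-15 relative).
- Monte-Carlo checks run at 150–500 seeds in the unit suite and 500 seeds
  (recovery) / 2000 replicates (calibration) in the acceptance script —
  sizes at which the standard error of each checked mean is an order of
  magnitude below its tolerance, keeping the default suite under a minute.
- CSV values are parsed with numpy's correctly-rounded strtod so written
  tables re-read bit-identically.

## Known limitations

- No REML / mixed-model estimation: unbalanced designs are handled by
  available-case exclusion of incomplete genotypes, not by likelihood.
- No G×E partitioning across seasons; no narrow-sense heritability.
- The exact cluster memberships and printed coefficient columns of the
  reference study are not reproducible from published information (raw
  data unavailable; internal inconsistencies documented above), so they
  are not targets anywhere in the package.
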