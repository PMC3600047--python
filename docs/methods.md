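# Methods

This note records the models implemented in `claderates`, the conventions
and defaults chosen where more than one reasonable option exists, and
what the synthetic-data tests do and do not establish about real data.

## The comparative design

Two sister clades diverged from one ancestor, so both have had exactly
the same time to accumulate species and substitutions. Under that
design, per-lineage path length (from the pair's common ancestor to a
representative tip) is proportional to the lineage's average
substitution rate, and extant species richness is a proxy for net
diversification. Each pair yields one signed contrast — species-rich
value minus species-poor value — for each of four metrics: total branch
length, dN, dS, and ω = dN/dS. Under the null of no rate–richness
association the contrasts are symmetric about zero; a one-tailed
Wilcoxon signed-rank test asks whether the rich lineages' values are
systematically larger.

Pairs are curated inputs, validated against the fitted topology: each
side must be monophyletic, the union monophyletic, and pairs must not
share tips (phylogenetic independence). One representative tip per
lineage is the default, avoiding the node-density effect (denser taxon
sampling inflating branch lengths); where several closely related genera
represent one lineage their path lengths are averaged, not summed, so
lineages with different representative counts stay comparable.

## Substitution models

**Nucleotide models.** The six GTR exchangeability slots (AC, AG, AT,
CG, CT, GT) can be tied into equality classes in any of Bell(6) = 203
ways; a tying is encoded as a restricted-growth string (`012345` = GTR,
`000000` = one class). Off-diagonal rates are θ_class(a,b) · π_b; the
class containing the AG slot has θ fixed to 1 for identifiability, and
base frequencies are empirical. The generator is rescaled to unit
expected flux, so branch lengths are expected substitutions per site.
Discrete-gamma rate variation uses 4 equal-probability categories, each
category rate the exact mean of its quantile bin (so the category mean
is 1); with a proportion p_inv of invariant sites, a rate-0 class of
weight p_inv is added and the gamma categories keep mean 1 over the
non-invariant fraction.

**Codon model.** MG94 over the 61 sense codons (stop codons are outside
the state space), crossed with any of the 203 exchangeability tyings and
with 3×4 position-specific nucleotide frequencies (stop-codon mass
removed and renormalized). A single-nucleotide codon change at position
p from a to b has rate θ_class(a,b) · f[p][b], times ω when the change
is nonsynonymous; multi-nucleotide changes have rate 0. ω is per branch
(one free ω per branch) for inference, matching per-branch dN/dS
reporting; a shared-ω mode exists for simulation and for scoring the
203-variant scan. Each branch's generator is rescaled so the expected
number of substitutions per unit time is 3 — one per nucleotide site —
under that branch's own ω, keeping nucleotide and codon branch lengths
on the same per-site scale.

## Likelihood and optimization

Log-likelihoods come from Felsenstein pruning over compressed site
patterns, with per-pattern rescaling of partials, and transition
matrices from the eigendecomposition of the π-symmetrized generator
(real spectrum by reversibility). Missing data and IUPAC ambiguities are
handled as partial likelihoods over the compatible states; a fully
missing sequence marginalizes out exactly.

Branch lengths are optimized coordinate-wise (bounded Brent per branch,
in branch index order), interleaved with scalar parameter updates (θ per
free class, gamma shape, p_inv, ω shared or per branch), until the
relative log-likelihood change falls below 1e-8 (branch tolerance 1e-7,
at most 200 sweeps unless a caller lowers it). Every accepted update is
improvement-guarded, so the log-likelihood is non-decreasing. Branch
lengths are floored at 1e-9 — zero-length branches are stored at the
floor so downstream ratios stay finite. Under a reversible model only
the sum of the two root-adjacent branch lengths is identifiable; the
free-parameter count uses the unrooted 2n − 3.

Model selection: per-partition BIC (−2 logL + k ln n_sites) for
nucleotide families; AIC (−2 logL + 2k) over the 203 MG94 variants. The
203-variant scan scores each variant with a shared ω and refits the
winner with per-branch ω; this keeps the scan tractable, and a
per-branch scan mode remains available. Ties break by fewer parameters,
then lexicographic label.

**Constant vs free rates.** "Constant rates" is read as a strict clock:
tips at height 0, n − 1 free internal-node heights (parameterized as
non-negative increments above the deeper child, so ultrametricity is
structural), giving df = (2n − 3) − (n − 1) = n − 2 against the
free-rates model, with a χ²_{n−2} null. For the dN and dS trees, the
clock is imposed on the branch's nonsynonymous (synonymous) length
rather than raw time — per-branch conversion factors derived from the
fitted ω values — while the free alternative is the unconstrained fit;
this is the natural reading of testing each rate tree for clocklike
behaviour, and it is isolated behind the LRT operation.

## dN/dS decomposition

For a branch of length t with ratio ω_b, the expected flux of the
branch's (flux-3-scaled) generator is split into synonymous and
nonsynonymous parts, E_S and E_N, which are then divided by 3·f_S and
3·f_N, the flux fractions of the *neutral* generator (same spec, ω = 1).
This normalization makes the identities exact: ω_b = 1 ⟹ dN = dS = t,
and dN/dS = ω_b always — so the branch parameter and the reported ratio
coincide, as required for tables where the ω column equals the ratio of
the printed dN and dS columns. dS values at or below the 1e-9 floor
produce floor-inflated ω values (order 10^5–10^6) and are flagged as
such; a lineage with dN = dS = 0 reports ω = 0, also flagged.

## The signed-rank engine

Absolute contrasts are ranked ascending with mean ranks for ties; W is
the sum of ranks of positive contrasts. The one-tailed p-value
P(W* ≥ W) under the symmetric null is exact for n ≤ 25, by a dynamic
program over doubled ranks (equivalent to enumerating all 2^n sign
vectors); beyond that, a normal approximation with variance Σr²/4
(exact under ties) and a 0.5 continuity correction. Pairs with equal
species richness cannot be oriented and are excluded at test time, not
during contrast construction, keeping the contrast table complete.

Zero differences admit three policies. `drop` (default, and R's
behaviour) excludes them. `rank_zero_positive` retains a zero at its
natural (smallest) rank, counted positive: printed tables round to a
finite number of digits, and a pair whose underlying difference is a
tiny positive prints as an exact tie, so this policy is the faithful way
to reproduce rank sums computed from unrounded values — the packaged
fixture reproduction uses it for the total-length metric, where exactly
one pair ties at the printed precision. `pratt` keeps zeros in the
ranking but excludes their ranks from W. The ω metric recomputed from
the printed fixture values yields W = 147 under `drop` (and under every
policy tried); the originally reported W = 100 evidently derives from
unrounded estimates and possibly different handling of the
floor-inflated pairs, and is documented as unrecoverable from the
printed table rather than targeted.

## Synthetic data

`simulate_pair_tree` builds n independent cherries on a comb backbone
plus an outgroup; both tips of a cherry sit at the same time depth, and
each tip branch is depth × lineage multiplier, so rate differences map
directly onto contrast differences. Defaults emulate the study scale:
20 pairs, depth 0.01 substitutions/site (chloroplast-like), lognormal
multipliers with ~2-fold spread. Sequences evolve by drawing the root
from the stationary distribution and applying each branch's transition
matrix; the codon state space contains only sense codons, so stop codons
are unreachable and nothing is rejected.

Species richness per lineage is drawn from a constant-rate birth–death
process conditioned on survival (geometric clade-size law), with
log λ = log λ₀ + κ · log(multiplier) and extinction held fixed — the
simplest coupling acting through net diversification. Defaults λ₀ = 3,
μ = 0, crown age 1 give a mean of ~20 extant species per lineage,
matching the order of magnitude of the real richness table. κ = 0 makes
richness independent of rates (the type-I-error condition); κ > 0
creates the alternative.

What passing tests show — and don't. The simulator realizes exactly the
model the estimators assume: equal-depth sister lineages, a correct
fixed topology, reversible stationary sequence evolution, no alignment
error, no among-gene conflict, and richness from a homogeneous
birth–death law. Calibration and recovery results (type-I error within
[0.04, 0.06] at 5000 replicates; clock-LRT rejection near nominal;
median ω recovered within [0.2, 0.4] at 500 codons × 6 taxa) therefore
validate the implementation, not the robustness of the design to
misaligned sequences, topology error, non-stationarity, or
diversification heterogeneity in real datasets.

The 20-pair fixture table is transcribed, not recomputed; an SHA-256
checksum in `synthetic_data.py` guards the transcription, and the ω
column is verified against the ratio of the dN and dS columns to printed
precision.

## Problem sizes used in the test suite

Tests run simulations at sizes chosen to make each statistical check
informative while keeping the suite quick to iterate on: exhaustive
likelihood oracles on ≤ 5-taxon trees; parameter recovery at 6 taxa ×
500 codons × 20 replicates; BIC preference at 1000 sites × 20
replicates; the 203-variant scan exercised on a small alignment with a
reduced sweep budget; type-I calibration at 5000 table-level studies;
clock-LRT calibration at 50 replicates of 8 taxa × 300 sites.

## Known limitations

- The clock LRT relies on the asymptotic χ² null; no mixture correction
  for boundary effects is applied (rejection rates calibrate well at the
  sizes tested).
- Codon-frequency parameters are empirical (F3×4 with pseudocounts), not
  ML-optimized; this matches common practice but differs from a full ML
  treatment by a usually negligible likelihood margin.
- The shared-ω scoring of the 203-variant scan can in principle pick a
  different winner than a full per-branch-ω scan; the per-branch mode is
  available where that matters.
- Site-rate heterogeneity for the codon model reuses the nucleotide
  Γ + I machinery (rates scale branch lengths); no codon-specific rate
  laws, codon-usage bias, or selection-on-synonymous-sites models are
  implemented.
- Topology inference, alignment construction and bootstrap support are
  out of scope: the topology and alignments are inputs.
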