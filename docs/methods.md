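# Methods

## Scope and data model

The package operates entirely on tables: per-candidate, per-conformer
isotropic shieldings (ppm) with relative Gibbs free energies (kcal/mol), and
one experimental assignment table of ¹H/¹³C shifts with nucleus metadata.
Conformer generation, geometry optimization and shielding computation are
upstream of the package and out of scope; their outputs are consumed as
CSV/TSV. Nucleus labels are opaque strings: primes and Greek letters (′, ″,
‴, α, β) are preserved verbatim, with an ASCII transliteration available for
downstream tools. Equivalence groups (e.g. the three protons of a methyl)
are declared in the metadata, never inferred — the package has no 3-D
model — and grouped nuclei are averaged (experimental and computed values
alike) before any statistic. Exchangeable N–H/O–H protons carry a flag and
are excluded from all statistics by default, since solvent exchange makes
their computed shifts unreliable.

## Ensemble averaging

Boltzmann weights w_i ∝ exp(−ΔG_i/RT) are computed after shifting the
ensemble minimum to 0; the default temperature is 298.15 K (configurable).
Energies are accepted in kcal/mol only — no unit auto-detection — with
R = 1.98720425864083×10⁻³ kcal mol⁻¹ K⁻¹. Conformers above a configurable
energy window (default 20 kcal/mol; stereoisomers tens of kcal/mol above the
base are physically negligible) are discarded with a logged report; the
minimum-energy member is retained by construction. Shieldings are
Boltzmann-averaged *before* scaling and statistics, so each candidate
contributes one averaged shielding vector and one error vector. Averaging
within a pre-clustered conformer group versus using a single representative
per group are both supported: pass the group's members or a singleton
ensemble respectively.

## Scaling and descriptors

Per candidate and per element, computed shieldings are regressed on
experimental shifts (σ = a·δ + b, ordinary least squares via
`scipy.stats.linregress`) and inverted to scaled shifts δ_s = (σ − b)/a. A
fit requires ≥ 3 points and a non-constant shift vector; anything less is an
explicit error, never a silent NaN. Separate ¹H and ¹³C fits per candidate
follow the DP4+ convention. Unscaled shifts need a per-element reference
shielding σ_ref (δ_u = σ_ref − σ), which is a required configuration value —
it depends on the level of theory, so no default is sensible.

MAE, CMAE and RMSD are implemented as mean |e|, mean |scaling residual| and
√(mean e²) — the readings under which all three are non-negative. CMAE is
invariant under any affine map of the shieldings (the internal regression
absorbs it), which the tests assert numerically. The across-candidate
normalization N(D) defaults to the literal D/range(D) × 100 %; a
conventional min-max variant ((D − min)/range × 100 %) is available behind a
flag, since the literal formula does not map the minimum to zero.

## DP4+ likelihood

Each nucleus contributes 1 − T_ν(|e − μ|/σ) per channel, with T_ν the
central Student-t CDF. The absolute value follows the original DP4/DP4+
convention: without it, negative errors would be rewarded asymmetrically.
The scaled channel fixes μ = 0 (scaling removes the bias); the unscaled
channels carry hybridization-split (ν, μ, σ) triplets because unscaled
errors are biased and the bias differs between sp² and sp³ carbons. Protons
inherit the hybridization of their attached carbon. The scaled channel is
not hybridization-split. Candidate probabilities are likelihoods normalized
over the candidate set, computed as sums of logs with each term floored at
the smallest positive normal (with a warning) to guard underflow; a
dedicated test shows the log-space path agrees with a direct product of
independently quadrature-evaluated CDF terms to better than 1e-9.

Parameter triplets are deliberately not hard-coded: they ship as editable
YAML profiles tagged with the functional/basis they were calibrated for, to
be transcribed from the calibration literature for real use. For synthetic
runs, `dp4_parameters_for` derives the exact triplets implied by the
generator's own noise model (see below), which is the correct likelihood for
recovery experiments.

## Staged workflow

Configurations are flip-bitstrings relative to the base; R/S labels are
display metadata. The single-flip scan evaluates the base plus the n
candidates at Hamming distance 1, in declared center order. Principle-center
selection works on per-type CMAE deviations from the base, min-max
normalized across the scan and averaged over ¹H/¹³C; centers within one
sample standard deviation of the base deviation are kept, capped at m = 6
(all configurable; `threshold_sd=None` skips the threshold and takes the m
least-degrading centers, which is appropriate when every flip is strongly
resolved). The 1-SD rule is a concrete default for an inherently qualitative
"confidence interval" criterion; it reproduces a 6-of-22 narrowing on the
structured test fixture without pretending to a published cutoff. NOESY or
other experimental exclusions are user-declared inputs with reasons — the
package cannot derive them — and energy exclusions use per-candidate ΔG
values when supplied. Expansion enumerates all 2^m combinations
(binary-counter order, base first, refusing m > 20). Ranking uses the
all-data DP4+ channel by default; candidates within 5 percentage points of
the top are reported together as key configurations, acknowledging that
distinct configurations can be statistically indistinguishable. Missing
candidate tables are listed as "not evaluable", never silently skipped. Ties
(probabilities equal within 1e-12) are broken lexicographically and flagged.

## Synthetic-data generator

The generator emulates the statistical structure of DFT-quality shielding
tables. Defaults, chosen once as realistic study conditions:

| parameter | default | rationale |
|---|---|---|
| slope a | −1.02 (¹H), −0.97 (¹³C) | near −1, off exactly −1 so unscaled bias is exercised |
| intercept b | 31 ppm (¹H), 186 ppm (¹³C) | typical reference-compound shieldings |
| noise scale | 0.15 ppm (¹H), 1.5 ppm (¹³C) | inside observed per-structure CMAE scatter (≈0.1–0.3 / 1–3 ppm) |
| noise law | Student-t, ν = 10 | heavy-tailed, consistent with the DP4+ likelihood; Gaussian optional |
| perturbation | 3× noise scale on 20 % of nuclei | localized systematic error of a wrong configuration |
| conformers | 3, ΔG spread 2 kcal/mol, jitter 0.03/0.3 ppm | low-energy ensemble |
| blueprint | 15 C + 16 H + 2 exchangeable at 5 centers | class proportions of a quaternary-rich polycyclic alkaloid |

Experimental shifts are drawn uniformly from class-typical ranges (sp²
carbons 105–175 ppm, sp³ 10–75 ppm, aromatic protons 6–8.5 ppm, aliphatic
0.8–4.8 ppm). Wrong candidates add sign-random offsets to the nuclei nearest
the flipped center in declaration order — declaration order stands in for
through-space proximity, which the pipeline cannot compute; a user-supplied
locality map overrides it. Offsets are drawn once per center, so a
multi-flip candidate is the sum of its centers' offsets and the
Hamming-0 candidate equals the truth byte-for-byte. All randomness flows
from one seed through `numpy.random.SeedSequence`, making outputs
byte-identical under a fixed seed. The generator does **not** emulate
ring-current/anisotropy physics, conformation-dependent error correlation,
or assignment ambiguity — passing recovery tests therefore demonstrates the
statistical machinery, not the accuracy of any DFT protocol on real
molecules.

With σ_ref set to the generator's intercept, the synthetic unscaled error is
e_u = −(1+a)δ − ε, so the implied unscaled triplets are μ = −(1+a)·E[δ] and
σ² = (1+a)²·Var[δ] + Var[ε] per hybridization cell, computed analytically
from the blueprint's class ranges. This mirrors how real DP4+ unscaled
statistics are biased and hybridization-dependent.

## Numerical choices and problem sizes

Weights are invariant under a common energy offset by construction
(min-shifting before exponentiation). Reports round probabilities to 4
decimals and ppm values to 3, sort JSON keys, and embed a config hash and
seed, so repeated runs are byte-identical. The recovery experiment used in
validation runs 200 replicates of the default 5-center system (≈31 nuclei,
3 conformers, base + 5 single-flip candidates per replicate), a size at
which a replicate takes tens of milliseconds; the observed top-1 recovery
rate is ≈97–100 % and 3-SE slope coverage ≈97–99 % across seeds, computed
fresh by `scripts/acceptance.py`.

## Known limitations

* The selection rule's 1-SD threshold is a pragmatic default; with uniformly
  strong flips it correctly selects nothing and must be relaxed or disabled.
* The scaled channel can reward wrong structures whose systematic offsets
  are nearly affine in the shift (the regression absorbs them) — visible in
  the generator when many same-sign offsets hit one element; the unscaled
  channels and the combined probability are the mitigation, as in DP4+
  practice.
* No coupling-constant (DP4-J) or neural-network extensions; no parsing of
  quantum-chemistry output files.
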