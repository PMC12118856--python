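# Methods

## Sequence model and digestion

Proteins are modelled as strings over the 20 standard residues with
1-based, inclusive peptide coordinates. Trypsin cleaves C-terminal to
Lys/Arg; cleavage before Pro is suppressed when `proline_rule` is on,
which is the default (the common "Trypsin, not Trypsin/P" search
convention — search engines differ, so the rule is a switch everywhere it
matters). `digest` returns every fully tryptic peptide with up to
`max_missed` retained internal sites; the brute-force equivalence used in
the tests enumerates all substrings with cleavage-compatible boundaries,
so the generator and the counting convention are checked against an
independent enumeration.

The iBAQ divisor (`count_theoretical_peptides`) counts **distinct,
zero-missed-cleavage** tryptic peptides of length 7–30 by default. The
bounds are configurable; 7–30 is the usual detectable-peptide window in
bottom-up proteomics and no stronger convention exists for the divisor.

Terminus classification: a peptide terminus conforms to tryptic cleavage
when it abuts a K/R bond (with the Pro suppression), sits at the chain
terminus, or — N-side only — starts at residue 2 behind an initiator Met
(Met-excised mature proteins are ubiquitous, so treating them as
conforming avoids systematically misclassifying protein N-terminal
peptides). Tryptic = both sides conform, semi-tryptic = exactly one,
non-tryptic = neither.

## GRAVY and isoelectric point

GRAVY is the arithmetic mean of Kyte–Doolittle hydropathy values, shipped
as a versioned TSV. It is linear under concatenation and order-invariant,
both of which are property-tested.

pI is computed by bisection on the Henderson–Hasselbalch net charge

    Q(pH) = Σ_basic n_g / (1 + 10^(pH − pKa_g)) − Σ_acidic n_g / (1 + 10^(pKa_g − pH))

over the two termini and the D/E/C/Y/H/K/R side chains. Q is strictly
decreasing in pH, so the root is unique; bisection on [0, 14] runs to a
tolerance of 1e-4 pH by default and agrees with a 0.001-step grid scan to
within 0.01 pH on random peptides. Two pKa sets ship with the package:
`IPC_peptide` (default; a peptide-optimised published set) and `EMBOSS`.
A deliberately simple pKa-set solver was chosen over a machine-learned pI
predictor: it is deterministic, fully specified by a small data file, and
oracle-verifiable.

## The synthetic diagenesis generator

The generator emulates the statistical structure of an ancient-tissue
extraction benchmark; it is the package's substitute for raw data when
validating estimators, and its defaults define the study conditions used
by the tests and the acceptance script.

* **Abundance.** Protein abundances are log-normal with `log_sd = 2`
  natural-log units (a typical proteome dynamic range, ~3.5 orders of
  magnitude between the 2.5th and 97.5th percentile). One abundance draw
  is shared across protocols so between-protocol correlation structure is
  real.
* **Hydrolysis.** Per protein, a Poisson number of backbone cleavage
  events with mean `hydrolysis_intensity × length / 100`; default
  intensity 1.5 events per 100 residues — a placeholder magnitude (no
  quantitative damage-versus-depth relationship is established for soft
  tissue) chosen to give a clearly visible semi-/non-tryptic fraction.
  Event positions are drawn without replacement, weighted by the residue
  N-terminal to the bond; Leu and Phe carry weight 5 against a baseline
  of 1, reflecting the aliphatic/aromatic cleavage contexts most often
  observed in degraded tissue. The 5× magnitude is a free choice.
* **Deamidation.** Independent Bernoulli per candidate site with
  per-class rates. Defaults are calibrated so the *observed* site-type
  mix is 51.4% Asn : 30.2% Gln : 18.3% Arg — the profile reported for
  archaeological soft tissue. Because the three residues occur at
  different background frequencies (N 4.06%, Q 3.93%, R 5.53%), the rates
  are the target mix divided by residue frequency, scaled so the Asn rate
  is 0.30: `{N: 0.300, Q: 0.1821, R: 0.0784}`.
* **Deamidation blocks cleavage.** Trypsin does not cleave after a
  deamidated Arg (the side-chain charge it recognises is gone), so
  modified K/R sites are forced missed cleavages in the stochastic
  digest. Besides being chemically right, this keeps deamidated-Arg
  events from being concentrated in short (sub-length-filter) peptides,
  which would otherwise bias the observed site mix.
* **Recovery.** Each candidate peptide is detected with probability
  proportional to `exp(log A + bias_gravy·GRAVY + bias_pi·pI)`, clipped at
  1 with the clipped mass redistributed (water-filling) so the expected
  number of detections equals `depth × faims_gain`. `faims_gain` is a pure
  depth multiplier standing in for ion-mobility filtering; no mobility
  physics is modelled.
* **Scores and nuisance structure.** q-values follow a 95:5 mixture of
  Uniform(0, 0.01) ("confident") and Uniform(0.01, 0.2) ("dubious"); PEP
  is a noisy multiple of q; ~1% of rows are reversed-sequence decoys;
  contaminants are drawn from a synthetic contaminant proteome (one
  protein per entry of the shipped target list) at `contaminant_load`,
  with no backbone hydrolysis and half-rate deamidation (their damage is
  prep-induced only). Intensities below the run's 15th percentile are
  left-censored to missing.
* **Determinism.** One seed sequence per run spawns one sub-stream per
  protein plus dedicated detection/noise/contaminant streams, so two
  profiles differing only in recovery bias see identical damaged
  candidate pools under the same seed, and reruns are byte-identical.

What the generator does **not** emulate: spectra and m/z space, retention
time, protein-inference ambiguity (peptides map 1:1 to their source
protein group), FDR estimation (q-values are drawn, not computed), and
any damage–depth interaction. Tests passing on simulated data therefore
validate the estimators' arithmetic and statistical behaviour under the
stated generative assumptions — not search-engine behaviour on real
spectra.

## Filters

The identification policy applies, in pinned order: flag removal
(decoys, contaminants) → confidence thresholds (precursor q, protein-group
q, PEP, all ≤ 0.01 by default) → support (≥ 2 unique peptides per protein
group, where "unique peptide" means a distinct stripped sequence assigned
to the group leader, collapsing modified forms and charge states). Order
changes the per-criterion removal counts, so the counts are reported with
the order fixed. The support rule applies per protocol by default
(switchable to pooled). Modified-peptide lists use the looser 0.05
thresholds and additionally require each modification type to be
supported by ≥ 2 unique peptides; unannotated tokens are dropped.
Missing intensities are retained as left-censored observations, never
coerced to zero.

## Quantification

iBAQ = summed precursor intensity / theoretical peptide count, per
(protein-group leader, protocol); absent observations are missing, not
zero. After log2, QRILC imputes per column: the column's underlying
normal is estimated by an ordinary least-squares fit of the sorted
observed values against normal quantiles whose plotting positions start
at the censored fraction (the upper half of the Q–Q pairs is used, where
censoring distortion is smallest), then imputations are drawn from that
normal truncated above at its 0.01 quantile. Columns with < 3
observations fall back to a pooled global estimate with a warning.
z-scores use the sample SD (n−1) and require a complete matrix; matrix
stages only move forward (raw → log2 → imputed → z).

Clustering uses SciPy agglomerative linkage (Manhattan/Euclidean;
complete/average/single) with items entered in sorted-label order so leaf
order is deterministic under ties. MDS is classical (Torgerson) scaling
with the axis sign fixed so the first point's coordinate is non-negative;
Kruskal stress-1 is reported. Exclusive intersections are tabulated for
every nonempty protocol combination and must partition the union (asserted
at run time).

## Protocol statistics

Peptide-level GRAVY or pI is modelled as

    y_ij = protocol_i + u_j + e_ij,   u_j ~ N(0, tau²),  e_ij ~ N(0, sigma²)

with a random intercept per protein, fit by REML (statsmodels MixedLM).
The common proteome — proteins identified by every protocol — enters the
fixed factor as its own protein-level reference group. A random intercept
(rather than random slopes) is the minimal structure that respects the
repeated measurement of the same proteins across protocols on shared
material; the response is per-peptide scores rather than per-protein
means, so protocols contribute with their actual peptide support.

Pairwise contrasts use Satterthwaite degrees of freedom via the
delta-method recipe: df = 2f²/(gᵀAg) with f = cᵀ(XᵀV⁻¹X)⁻¹c, g its
gradient in the variance components (finite differences on the log
scale), and A the inverse negative Hessian of the REML log-likelihood.
For a single random intercept, V⁻¹ per group has a closed (Woodbury)
form, so this is exact up to finite-difference error; the test suite
cross-checks estimates, SEs, df and Bonferroni p-values against
lme4/lmerTest/emmeans. Bonferroni family size is all pairwise comparisons
among the protocol levels including the common-proteome reference (55 for
10 protocols + reference). When tau² collapses to the boundary the model
degenerates to OLS with residual df, flagged `singular` with a warning.

Fisher exact over/under-representation reports fold enrichment
FE = (k/n)/(K/N) with two-sided p and Bonferroni over the tested
categories. Contamination risk grades each contaminant's share of a
protocol's total signal into levels 1–5 at relative-abundance cut points
{1e-4, 1e-3, 1e-2, 5e-2}; the cuts are package defaults (not taken from
any reference dataset) and configurable; the per-protocol global level is
the worst contaminant's level.

## Numerical and reporting conventions

* Percentages in artifacts always carry numerator and denominator columns
  and are rounded half-to-even at one decimal via a single helper, so any
  reported ratio is re-derivable arithmetic on the artifact.
* pI bisection tolerance 1e-4 pH; z-score invariants hold to 1e-9;
  Pearson matrices are checked positive semidefinite to −1e-8.
* Degenerate inputs fail loudly: empty FASTA, duplicate accessions,
  zero-variance columns under z-scoring, zero MS2 signal, deamidation
  annotated on a non-N/Q/R residue, unknown config keys.

## Problem sizes

The bundled tests and the acceptance script run entirely on simulated
data at desk scale: proteomes of 50–1,600 proteins of 120–400 residues,
protocol depths of 150–800 precursors (the deamidation-recovery run
detects all candidates), 10 protocols for ordering recovery, and 100
replicates for the familywise error calibration at 5 protocols × 12
proteins × 6 peptides. These sizes were chosen so each property is
measured with comfortable statistical margin while the whole suite stays
quick to run.

## Known limitations

* The mixed model assumes Gaussian residuals; GRAVY and pI distributions
  are multimodal in real proteomes, which the pre-checks (Shapiro–Wilk,
  Levene) will flag but the model does not remedy.
* QRILC's Q–Q estimate assumes each column is a censored normal; heavy
  tails bias the imputation low.
* MaxQuant evidence tables carry no precursor q-value; the q-threshold is
  vacuous there and PEP alone governs confidence (logged at read time).
* The risk thresholds and the hydrolysis-intensity default are
  order-of-magnitude choices, documented as such, not estimates.
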