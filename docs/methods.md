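# Methods

`taurna` reimplements, as a tested pipeline, the quantitative analyses behind
a tau–RNA complex-coacervation study: sequence-based charge balance, Hill
analysis of gel-shift titrations, one-set-of-sites ITC fitting, bright-field
droplet coverage, and post-alignment iCLIP analytics. Every stage is
exercised end-to-end on seeded synthetic data with machine-readable ground
truth. This note records the models, the defaults and why, the numerical
choices, and what the synthetic data does and does not establish.

## Charge balance (`chargecalc`)

Complex coacervation of a polycation (tau) and polyanion (RNA) is maximal
near overall charge neutrality, so the predictive quantity is the
protein(+):RNA(−) charge-concentration ratio of a mixture.

Protein net charge at pH *p* is the Henderson–Hasselbalch sum over ionizable
groups: +1/(1+10^(p−pKa)) per basic group, −1/(1+10^(pKa−p)) per acidic
group, including both termini. The default pKa table (R 12.5, K 10.8, H 6.5,
D 3.9, E 4.1, C 8.5, Y 10.1; N-term 8.6, C-term 3.6 — the EMBOSS-style set)
is a frozen, configurable choice made for determinism, not an inference of
any particular laboratory's convention. Spin-labelled cysteines carry no
free thiol and can be masked by position.

RNA charge concentration is mass concentration / mean nucleotide mass ×
charges per nucleotide, with 330 Da and one backbone phosphate charge per
nucleotide as defaults (overridable per species; tRNA can additionally carry
a 25 kDa chain mass for molar-ratio conversions).

**Expression-tag treatment.** `ProteinSpec` carries the biological sequence
and an optional expression tag (His6, `MHHHHHH`, on the Δtau187 fixture) as
separate fields. The tag always counts toward the construct's molar mass —
it is part of the molecule that is weighed and quantified — but is excluded
from the net-charge sum by default (`include_tag_charge=True` restores it).
Rationale: the tag is purification plumbing, not part of the tau
polyelectrolyte; its six histidines are ~76% neutral at pH 7 under the
default table yet would systematically inflate the modelled polycation
charge. With this convention the Δtau187 fixture gives Z ≈ +10.85 at pH 7
and a 7:1 protein:RNA mass ratio maps to a ≈1.21:1 charge ratio.

`charge_balance_map` scores a composition grid by |log(charge ratio)| and
returns the grid point closest to 1:1 (ties broken toward lower total mass
concentration, so the optimum is unique and order-independent).

Out of scope by design: no Poisson–Boltzmann or salt-screening model — NaCl
and temperature ride along as metadata only — and no prediction of droplet
yield beyond locating the 1:1 optimum.

## Hill binding analysis (`binding`)

Direct titrations (trace RNA, protein in excess) are fit to
y = 1/[1 + (K_d/x)^n] by bounded trust-region least squares
(`scipy.optimize.curve_fit`), with K_d ∈ (1, 10⁵) nM, n ∈ (0.2, 8),
initialized at the concentration nearest half-saturation with n = 1. The
optimizer is a package choice; only the equation is prescribed by the
analysis being reproduced. Standard errors come from the Jacobian at the
optimum; a seeded residual-resampling bootstrap is available. Fits pinned at
a box boundary, flat (non-identifiable) curves, and optimizer failures are
flagged `converged=False`; all-zero/all-one curves are rejected outright.

The "theoretical saturation" family for stoichiometric titrations is the
tight-binding limit min(1, m/r) for m protein sites per RNA, m = 1..6; a
finite-affinity variant (per-site mass-balance quadratic) is available via
`kd_nM=`/`rna_nM=`. Tight binding is the default because these curves are
meant to bracket data, not fit it.

## ITC (`itc`)

Perfusion-cell dilution uses the standard displacement model
(M_i = M0·Π(1 − dV_j/V0); titrant accumulated with the same factors). The
one-set-of-sites bound fraction Θ solves
Θ² − Θ(1 + X/(nM) + K_d/(nM)) + X/(nM) = 0 (root in [0,1]); cumulative heat
Q_i = n·Θ_i·M_i·ΔH·V0 (µM·ml·kcal/mol = µcal) and the per-injection heat
carries a trapezoidal displaced-heat correction
δQ_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i+Q_{i−1})/2. n is titrant (RNA) per
macromolecule (tau), so a protein-dimer:RNA stoichiometry appears as
n ≈ 0.5 on the titrant:macromolecule axis.

Fitting is bounded least squares over (K_d, ΔH, n) with ΔH initialized from
the first-injection heat and n from the molar ratio at half the cumulative
heat. Standard errors from (JᵀJ)⁻¹·s². An optional `drop_first` flag
implements the usual anomalous-first-injection practice. Thermograms whose
largest |heat| sits below a 0.05 µcal noise floor trigger a low-enthalpy
warning and `converged=False` — with such shallow heats no binding model is
identifiable, which is also why cooperative and two-site models are
deliberately not offered as fit options.

The default protocol is 300 µM titrant in 25 × 5 µl injections into 1 ml of
30 µM macromolecule; 25 injections drive the molar ratio to roughly twice
the fitted stoichiometry, which frames the isotherm's inflection. The
injection count and the synthetic truth ΔH = −2 kcal/mol are package
choices (the enthalpy is small, consistent with a weakly enthalpic,
entropy-dominated association; its exact value is not a target of any
check).

## Droplet coverage (`dropletquant`)

Pipeline: threshold from the mean of a buffer-only blank; droplet mask =
pixels strictly below threshold (droplets settle and are darker than
background); connected components (8-connectivity default — diagonal pixel
bridges on anti-aliased rims merge, configurable to 4); per-region area,
eccentricity of the same-second-moments ellipse, and equivalent diameter
2√(area/π) in µm (via `skimage.measure.regionprops`); regions with
eccentricity > 0.9 or equivalent diameter < 1 µm removed; percent coverage
= 100 × kept pixels / total pixels, aggregated as mean ± sd over replicates.

Numerical notes: the plain buffer-mean threshold is exact on noise-free
backgrounds but by construction classifies half of a *noisy* background as
sub-threshold, so `buffer_threshold(..., k_sigma=k)` provides a mean − k·σ
variant; with k ≈ 6 and background noise at 2% of droplet contrast, pipeline
coverage tracks the rasterized ground truth to within 0.2 percentage points
(tiny spurious specks are additionally removed by the 1 µm filter).
Border-touching regions are kept but flagged; holes are not filled by
default (`fill_holes` flag); no watershed splitting of merged droplets and
no illumination flattening.

## CLIP analytics (`clip`)

Coordinates are 0-based half-open (BED-compatible) throughout. Rules:

* **Deduplication** — identical (chromosome, start, strand, random barcode)
  collapses to one read; reads without a random barcode go to an
  `unbarcoded` bin rather than being dropped. Reads < 18 nt or with
  alignment score < 10 are removed. The operation is idempotent and
  order-independent.
* **Cross-link site** — the reverse-transcription truncation position: the
  nucleotide immediately 5′ of the read start in transcript orientation
  (start − 1 on +, end on −); a site falling before the chromosome start is
  clamped to 0 and marked. The "read start itself" convention differs by
  one nucleotide and can be recovered by shifting.
* **Category assignment** — each read is assigned through its cross-link
  site under the fixed precedence tRNA > rRNA > miRNA > snRNA > lincRNA >
  exon > intron > intergenic (small-RNA classes first so tRNA reads inside
  host genes are not swallowed). Genome category lengths are computed under
  the same precedence so percentages partition the genome; read percentages
  always sum to 100. Fold enrichment = read% / genome%.
* **Clusters** — single-linkage merge of same-strand reads overlapping by
  ≥ 1 nt; clusters with < 5 reads are discarded.
* **tRNA profile** — cross-link sites inside tRNA genes are re-indexed so
  the anticodon occupies positions 1–3 (5′ neighbours 0, −1, −2, …; 3′
  continues 4, 5, …), with per-structural-element totals.
* **Abundance comparison** — per-gene pool fractions and log2(CLIP /
  background); genes absent from one pool receive a 0.5-read pseudocount
  and are flagged pseudocount-dependent.

Multi-mapping reads are assumed resolved upstream; no peak-calling model
beyond the ≥5-read retention rule.

## Synthetic data (`synthdata`)

Generators are pure functions of their arguments and seed and attach a
truth record sufficient to score any downstream estimate.

* **Titrations** — Hill curve + additive Gaussian noise (σ = 0.03 default),
  clipped to [0,1], on 12 log-spaced points from 20 nM to 2 µM — the
  direct-titration design at trace (26 nM) RNA.
* **Thermograms** — model heats + (2% proportional + 0.1 µcal additive)
  Gaussian noise under the default protocol; optional constant dilution
  blank whose subtraction restores the binding signal.
* **Images** — Gaussian background (12-bit scale) minus a fixed contrast
  depth inside rasterized ellipses; truth carries exact per-object masks,
  eccentricities, diameters, and coverage. Default calibration 0.25 µm per
  pixel, a typical CCD/objective combination for micron-scale droplets.
* **Reads** — a 100 kb single-chromosome toy genome with the 8 categories
  laid out contiguously (tRNA block = 13 canonical 76-nt genes), read
  categories multinomial with probability ∝ genomic extent × planted fold
  (`fold_vector` builds vectors whose planted folds are exact), cross-link
  positions inside tRNA genes drawn by structural element with weights
  anticodon loop 0.70, T-loop 0.15, D-loop 0.10, elsewhere 0.05 — a
  qualitative ordering (anticodon loop ≫ T-loop > D-loop), not a measured
  histogram — plus configurable rates of injected PCR duplicates and
  sub-threshold reads with truth identities.

What passing on synthetic data shows — and does not. The ensembles
establish that the fitters are unbiased at realistic noise and that the
pipeline arithmetic is exact against independent oracles (brute-force
equilibrium solver for ITC, pixel-count rasterization for images, planted
multinomial truth for CLIP). They do not establish robustness to what real
data adds: uneven illumination and out-of-focus droplets, correlated
densitometry errors, baseline drift in calorimetry, multi-mapping tRNA
reads, or annotation ambiguity in a real genome.

## Problem sizes

Default ensemble sizes — 200 titration refits per binding condition, 100
thermogram refits per construct, 10⁵-read CLIP simulations, 500×500-pixel
images — are chosen so the medians and folds they estimate are stable to
well within the tolerances asserted in the test suite (stochastic medians
move by ≪ 1% between seeds at these sizes).

## Known limitations

* The charge model is ideal-solution: no counterion condensation, salt
  screening, or activity corrections; pH enters only through pKa sums.
* The Hill fit treats total protein as free protein (trace-RNA
  approximation) and weights all points equally.
* The ITC dilution convention (displacement + trapezoidal correction) is
  one standard choice among several instrument conventions.
* Droplet segmentation does not split touching droplets; coverage is a
  per-image statistic, blind to droplet number/size trade-offs.
* CLIP category assignment is single-nucleotide (cross-link site) based,
  consistent with truncation logic; majority-overlap assignment of whole
  read intervals is not implemented.
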