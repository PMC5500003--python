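# taurna

Analytics for tau–RNA complex coacervation: the liquid–liquid phase
separation of the neuronal protein tau (a polycation at neutral pH) with RNA
(a polyanion) into micrometre-sized droplets. The package is written for
biophysicists quantifying such systems and reimplements each quantitative
stage of that analysis as a tested, reusable library:

* **`chargecalc`** — Henderson–Hasselbalch net protein charge vs pH,
  RNA charge concentrations (1 charge / 330 Da per nucleotide), and
  protein(+):RNA(−) charge ratios of mixtures. Coacervation is maximal near
  1:1 charge balance, so `charge_balance_map` locates the composition whose
  ratio is closest to unity.
* **`binding`** — Hill fits, y = 1/[1 + (K_d/x)^n], of gel-shift
  titrations, plus the 1:1–6:1 tight-binding saturation curve family for
  stoichiometric titrations.
* **`itc`** — the independent (one-set-of-sites) binding isotherm for
  incremental-titration calorimetry, with perfusion-cell dilution
  bookkeeping, and least-squares recovery of (K_d, ΔH, n).
* **`dropletquant`** — bright-field droplet segmentation against a
  buffer-blank threshold, shape filters (eccentricity ≤ 0.9, equivalent
  diameter ≥ 1 µm), and percent droplet coverage per image and condition.
* **`clip`** — post-alignment iCLIP analytics: PCR-barcode deduplication,
  length/score filters, cross-link (truncation) site calling, ≥5-read
  cluster retention, 8-category genomic fold enrichment, and
  anticodon-anchored tRNA cross-link profiles.
* **`synthdata`** — seeded generators for all of the above with
  machine-readable ground truth.

The numbered scripts under `analysis/` run each stage end-to-end on
synthetic data and write tables under `results/`. `docs/methods.md` gives
the models, defaults and numerical choices in detail.

## Worked example

Charge balance of the bundled Δtau187 construct (tau residues 255–441 with
an N-terminal His6 tag) mixed with RNA at pH 7:

```python
from taurna import chargecalc, constructs

dtau = constructs.delta_tau187()
rna = chargecalc.RNASpec(name="RNA")

z = chargecalc.net_protein_charge(dtau, pH=7.0)
mixture = chargecalc.mixture_at_mass_ratio(80.0, 7.0, dtau)   # 7:1 by mass
report = chargecalc.charge_ratio(mixture, dtau, rna)
print(f"net charge {z:+.2f} e, charge ratio {report.charge_ratio:.2f}:1")
```

```
net charge +10.85 e, charge ratio 1.21:1
```

A 7:1 protein:RNA mass ratio therefore sits at ≈1.2:1 positive-to-negative
charge — close to the 1:1 balance at which droplet formation peaks.
Simulating a gel-shift titration and recovering its binding parameters:

```python
from taurna import binding, synthdata

curve, truth = synthdata.gen_binding_curve(kd_nM=460, n=2.8,
                                           noise_sd=0.03, seed=1)
fit = binding.fit_hill(curve)
print(f"K_d = {fit.kd_nM:.0f} ± {fit.kd_se:.0f} nM, n = {fit.n:.2f}")
```

```
K_d = 452 ± 7 nM, n = 2.83
```

i.e. the fitter recovers the planted dissociation constant (460 nM) and
Hill coefficient (2.8, cooperative binding of several tau per RNA) from a
single noisy 12-point titration. Running `python analysis/01_charge_balance.py`
through `05_clip_enrichment.py` prints the corresponding summaries for all
five stages, e.g.:

```
Delta-tau187 net charge at pH 7.0: +10.85 e (molar mass 20706 Da)
7:1 protein:RNA mass ratio -> charge ratio 1.21:1
molar-ratio grid {2,4,8,16,32}:1 -> optimum at 8:1 (closest to 1:1 charge balance)
...
tRNA: 39.6% of reads on 0.99% of the genome -> fold 40.1 (planted 40.0)
cross-link profile over 19818 sites: ... dominant element 'anticodon_loop'
```

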