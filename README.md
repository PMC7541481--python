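# cyrpipe

Cyanobacteria are photoautotrophs, yet a growing number of their genomes
carry microbial rhodopsin genes — retinal-binding seven-transmembrane
photoreceptors that heterotrophic bacteria use as an auxiliary light-energy
device. `cyrpipe` is a reusable pipeline for the computational side of
characterizing such rhodopsins, built around the cyanorhodopsin (CyR) clade
of light-driven outward proton pumps and its representative N2098R from
*Calothrix* sp. NIES-2098. It is aimed at microbiologists and biophysicists
who want to (a) screen proteomes for rhodopsin homologs and predict their
transport function from sequence, (b) place hits among reference clades on a
bootstrapped tree and tabulate habitat-stratified gene distributions, and
(c) simulate and fit flash-photolysis photocycle kinetics and pH-titration
pKa measurements.

## What it computes

**Sequence screen and function call.** Homologs are detected by pairwise
BLOSUM62 alignment (affine gaps, free end gaps) against a labeled reference
panel, with thresholds on percent identity and reference coverage. The
helix-C motif — proton acceptor, hydrogen-bond partner, proton donor
(Asp85/Thr89/Asp96 in bacteriorhodopsin numbering, hence "DTD") — plus the
Schiff-base lysine, the counterion aspartate, and the glutamate release pair
are read off the alignment, and an ordered rule table maps them to a
function label: DTD/DTE with the lysine → outward H⁺ pump, NDQ → Na⁺ pump,
NTQ/TSD → inward Cl⁻ pump, acceptor without a carboxylic donor → inward H⁺
pump, no lysine → nonfunctional opsin.

**Clade assignment and habitat table.** Neighbor joining on (optionally
Poisson-corrected) p-distances from a reference-anchored stacked alignment,
with classical column-bootstrap supports (default 100 replicates). A query
joins the clade of its nearest reference only if it also falls inside that
clade's monophyletic group with edge support ≥ 50% and passes a distance
gate. Genome records are summarized into a table of gene counts per clade
and rhodopsin-possessing genome counts per habitat, by genomic subclade.

**Photocycle kinetics.** After flash excitation the pigment traverses the
irreversible chain

    K (620 nm) --k1--> M (405 nm) --k2--> O (645 nm) --k3--> ground (550 nm)

whose populations follow the closed-form (Bateman) solution. Difference
spectra ΔA(λ, t) are intermediate Gaussian bands weighted by populations
minus the ground-state bleach. Inference includes the single-exponential
M-decay fit at 405 nm (the published N2098R value at pH 7.0 is ≈ 0.016
ms⁻¹), a variable-projection global fit yielding decay-associated spectra
with K/M/O assignment, and the pyranine proton-flux trace (−[M](t): one
proton released on M formation, taken up on M decay).

**pKa titration.** Absorbance-vs-pH curves at the most responsive wavelength
are fitted to the Henderson–Hasselbalch occupancy (single pKa, Hill slope
1). Midpoints within 0.5 pH units of the sampled range's edge are reported
as censored bounds — the convention behind statements like "pKa < 2.0" for
the proton acceptor Asp74, versus ≈ 10.7 for the Schiff-base Lys204.

A synthetic-data module generates every input with known ground truth —
proteomes with planted clade-labeled homologs and decoys, flash matrices on
the instrument grids (370–700 nm at 5 nm; 0.01–977 ms), titration series
over pH 1.00–11.52 — so all of the above is covered by recovery tests.

## Worked example

```python
import numpy as np
from cyrpipe import (PhotocycleModel, fit_m_decay, global_fit, fit_pka,
                     gen_flash_dataset, gen_titration_dataset, find_peak,
                     ground_state_spectrum)
from cyrpipe.photocycle import DEFAULT_WAVELENGTHS

model = PhotocycleModel()  # N2098R defaults
print("ground-state lambda_max:",
      find_peak(DEFAULT_WAVELENGTHS, ground_state_spectrum(model, DEFAULT_WAVELENGTHS)), "nm")

flash = gen_flash_dataset(model, noise_sigma=0.003, seed=1)
rate, stderr = fit_m_decay(flash)
print(f"M-decay rate: {rate:.4f} +/- {stderr:.4f} ms^-1")

fit = global_fit(flash, seed=1)
for label, tau in zip(fit.assignments, fit.taus):
    print(f"  {label}: tau = {tau:.3g} ms")

titr = gen_titration_dataset(10.7, acid_side=False,
                             ph_grid=np.arange(7.0, 12.01, 0.25),
                             noise_sigma=0.002, seed=1)
pka = fit_pka(titr)
print(f"Schiff-base lysine pKa: {pka.pka_estimate:.3f} +/- {pka.stderr:.3f}")
```

prints

```
ground-state lambda_max: 550.0 nm
M-decay rate: 0.0162 +/- 0.0002 ms^-1
  K: tau = 0.5 ms
  O: tau = 19.9 ms
  M: tau = 62.4 ms
Schiff-base lysine pKa: 10.700 +/- 0.003
```

The ground state absorbs maximally at 550 nm (green light that chlorophyll
cannot use directly); the fitted M-decay rate 0.0162 ms⁻¹ matches the 0.016
ms⁻¹ simulation truth within noise (τ_M ≈ 62.5 ms — an unusually long-lived
M state); and the alkaline titration recovers the Schiff-base midpoint 10.7.

The command-line interface exposes the same stages
(`cyrpipe generate|screen|motif|tree|assign|tabulate|photocycle|titrate`)
plus `cyrpipe pipeline --seed 3 --outdir run`, which runs the whole
synthetic survey end to end and writes hits, motif calls, a newick tree,
clade assignments, the habitat table, fit reports, and a manifest.

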