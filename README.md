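# bindkit

Quantitative analysis of ligand–protein binding experiments and
ensemble-docking post-processing, built around the comparative study of a
polyphenol ligand (punicalagin) binding the protein disulfide isomerases
PDIA1 and PDIA3. The package is aimed at biophysics and computational
chemistry practitioners who need the full chain from raw titration / docking
outputs to binding constants, thermodynamic decompositions, and proposed
binding modes — with seeded synthetic generators standing in for the
instruments and engines so every analysis is testable against known ground
truth.

## What it computes

**Fluorescence quenching** — Stern–Volmer analysis of tryptophan quenching,
F₀/F = 1 + K_SV·[L], with K_q = K_SV/τ to separate static from diffusional
quenching, and a dissociation constant from the iterative double-log
regression log₁₀((F₀−F)/F) = log₁₀K_a + n·log₁₀[L]_free, where [L]_free is
refined as [L]_tot − n·((F₀−F)/F₀)·[P]_tot.

**Isothermal titration calorimetry** — the one-set-of-sites (Wiseman)
isotherm for a displacement cell: after injection *i* the bound fraction Θᵢ
is the physical root of

Θ² − Θ·[1 + X/(nM) + 1/(n·K_a·M)] + X/(nM) = 0,

cumulative heat Qᵢ = n·Θᵢ·Mᵢ·ΔH·V₀, and injection heats corrected for the
displaced volume. Nonlinear least squares over (n, K_a, ΔH) with blank
subtraction or a co-fitted dilution offset; ΔG = RT·ln K_d and TΔS = ΔH − ΔG.

**Differential scanning calorimetry** — deconvolution of thermograms into
independent two-state transitions with separate calorimetric and van 't Hoff
enthalpies (non-two-state), Cp_ex = Σᵢ ΔH_cal,i·(ΔH_vH,i/RT²)·K/(1+K)².

**Dose–response** — 4-parameter logistic IC₅₀ fits on log-concentration with
residual-bootstrap confidence intervals.

**Ensemble docking post-processing** — common-frame projection of poses from
many receptor snapshots (Kabsch), PCA embedding of heavy-atom coordinates,
dual pose selection (best docking score and 2-D KDE density modes), the
MDCOM convergence metric (mean pairwise distance of selected poses' centres
of mass), receptor–ligand complex assembly, and rescoring-table ranking.

**Trajectory statistics** — Kabsch superposition, RMSD series and density
profiles, per-residue RMSF, Shrake–Rupley SASA with a deterministic spiral
point set, closest interdomain distance series, and snapshot sampling for
cross-docking.

Every input the pipeline consumes can be produced by the `synthetic_data`
generators (titrations, ITC heats, thermograms, dose–response curves,
planted pose clusters, a two-domain hinge-closing toy trajectory), each
seeded and carrying its ground truth.

## Worked example

```python
import numpy as np
from bindkit import ITCGeometry, ITCParams, gen_itc_experiment
from bindkit.binding_thermo import fit_itc_one_site

exp = gen_itc_experiment(ITCParams(n=1.0, K_d=1.0e-6, dH=-2.7),
                         ITCGeometry(), noise_sd=0.05,
                         dilution_heat=0.3, seed=7)
exp.dilution_heats = np.full(20, 0.3)   # the measured blank
fit = fit_itc_one_site(exp)
print(fit.K_d, fit.dG, fit.TdS)
```

Running `python examples/itc_fit.py` (this exact analysis) prints:

```
n    = 0.993
K_d  = 1.21 uM   95% CI [0.89, 1.64]
dH   = -2.78 kcal/mol
dG   = -8.07 kcal/mol
TdS  = 5.29 kcal/mol
c    = 20.5
```

i.e. a micromolar dissociation constant recovered from a 20-injection
schedule at realistic noise, with TΔS ≫ |ΔH| identifying an entropy-driven
interaction. The other scripts in `examples/` cover quenching analysis, DSC
deconvolution, IC₅₀ fitting, pose selection, and hinge-trajectory
statistics, one capability each.

A thin CLI mirrors the library (`bindkit simulate-*`, `bindkit fit-*`,
`bindkit poses-*`, `bindkit traj-*`, `bindkit run --config cfg.yaml`).

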