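# rosewater

Simulation and unsupervised phase-diagram construction for a simple
two-dimensional water model with explicit hydrogen bonding.

## The model and the problem

Each water molecule is a Lennard-Jones disc carrying three
hydrogen-bonding arms 120° apart. A pair at distance *r* with
orientations φᵢ, φⱼ interacts through

    u(r, φᵢ, φⱼ) = u_LJ(r) + (ε_HB/2)·U(θᵢⱼ)·s(r) + (ε_HB/2)·U(θⱼᵢ)·s(r)

where θᵢⱼ is the angle of the center-connecting line in molecule *i*'s
body frame, `U` is a 3-petal rose function (a combination of
cos 3θ and cos 6θ with coefficients a₁, a₂) normalized so its global
minimum — an arm pointing straight at the partner — is exactly −1, and
`s` is a double-sided cubic switching window around the hydrogen-bond
length r_HB with full width at half maximum r_fwhm. Each molecule
contributes its half of the bond independently, so "half bonds" of
energy −ε_HB/2 exist and a fully aligned pair reaches −ε_HB. Two
parametrizations ship as presets: **mb** (ε_LJ=0.1, σ_LJ=0.7 —
distinct LJ-contact and HB distances, rich phase behaviour) and
**real** (ε_LJ=0.2, σ_LJ=0.890899, wider HB window — the LJ minimum
coincides with the HB length).

The package answers: *where are this model's phases in the
pressure-temperature plane, using no human inspection of the data?*
It provides

* **NPT molecular dynamics** (velocity Verlet for translation and
  rotation, velocity-rescale / stochastic-velocity-rescale
  thermostats, Berendsen / stochastic-cell-rescale barostats);
* **constant-pressure nested sampling**, which turns one run into the
  partition function at every temperature — hence ⟨H⟩(T), C_p(T),
  κ_T(T), α_P(T) and the extrema that flag candidate transitions;
* **observables** per (T*, p*) phase point: angular distribution
  functions (ADFs) of the angle between an HB arm and the
  center-connecting line at the five structural distances 0.7, 1.0,
  1.73, 2.0, 3.0; Einstein-relation diffusion; hydrogen-bond counts;
  ψ₃/ψ₆ bond-orientational order; NPT fluctuation response functions;
* **unsupervised phase diagrams**: a 125-dimensional ADF descriptor or
  a standardized 15-quantity property vector per phase point, reduced
  to 3D (MDS, Isomap, spectral embedding or t-SNE) and clustered
  (k-means, Ward, DBSCAN); an "intelligent" two-stage pipeline that
  first peels gas/liquid/solid off the diffusion coefficient with
  sequential DBSCAN and then sub-clusters the solids; and a
  fraction-of-agreement score against a reference label grid with
  optimal (Hungarian) cluster matching.

All quantities are in reduced units: energies in ε_HB, lengths in
r_HB, T* = k_BT/ε_HB, p* = p·r_HB²/ε_HB.

## Worked example

```python
import numpy as np
from rosewater import preset
from rosewater.lattices import make_honeycomb
from rosewater.observables import compute_adf, count_adf_peaks, hb_statistics

mb = preset("mb")
ice = make_honeycomb(4, bond_length=1.0)   # 64-molecule hexagonal HB crystal

first = compute_adf(ice, 1.0)              # first-neighbor shell
second = compute_adf(ice, 1.73)            # second-neighbor shell
print(count_adf_peaks(first), first.angles[np.argmax(first.density)])
print(count_adf_peaks(second))
print(hb_statistics(ice, mb)["mean_hb_per_molecule"])
```

prints

```
1 0.0
2
3.0
```

— the honeycomb crystal shows a single ADF peak at 0° at the bond
distance (a direct hydrogen bond), two peaks at ±30° at distance 1.73
(two molecules bonded to a shared neighbor), and every molecule holds
exactly 3 hydrogen bonds.

A phase diagram over a (T*, p*) grid:

```python
from rosewater.md import MDProtocol
from rosewater.workbench import GridSpec, run_grid
from rosewater.phase_ml import adf_phase_pipeline

proto = MDProtocol(n_equil=8000, n_series=5, series_len=2000, n_molecules=64)
spec = GridSpec(temperatures=[0.05, 0.1, 0.15, 0.2, 0.25, 0.3],
                pressures=[0.01, 0.2, 1.0, 4.0, 8.0, 20.0],
                protocol=proto, initial="lattice")
res = run_grid(spec, "both", cache_dir="cache")
labels = adf_phase_pipeline(res["adf_table"], "isomap", "ward",
                            n_clusters=7, seed=1)
```

The same pipelines are scriptable from a shell:

```sh
phases run --features adf_table.csv --reduce isomap --cluster ward --k 7 --seed 1
phases intelligent --features properties.csv --reduce tsne --cluster dbscan
phases score --pred labels.csv --ref reference.csv --merge merge.json
```

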