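# spovmclust

Statistical-mechanical modelling of SpoVM membrane clustering and
curvature/tension-dependent adsorption.

SpoVM is a 26-residue amphipathic-helix protein of *Bacillus subtilis* that
marks the outer forespore membrane — apparently by sensing its micron-scale
convex curvature — and whose adsorption to spherical vesicles depends
strongly on vesicle radius. A single 4 nm protein lying on a 1 μm-diameter
sphere clears the surface by less than 0.2 Å, so direct single-molecule
curvature sensing is geometrically implausible; clustering must amplify the
signal. This package implements the equilibrium theory of that idea for
researchers in membrane biophysics: short-range attraction balanced against
longer-range repulsion gives finite clusters, and the repulsion strength is
the one parameter plausibly sensitive to membrane geometry.

## The model

With all energies in k_B·T (binding ϵ_b, nearest-neighbour attraction ϵ_nn,
pairwise intra-cluster repulsion e_r) and normalised concentrations
C_s = c_s/c_0, c_0 = e^{−(ϵ_nn+ϵ_b)}·α, the dilute-limit adsorption isotherm
is the cluster-partition sum

```
C_v(C_s, e_r) = Σ_{k≥1} k · exp(−k(k−1)·e_r/2) · C_s^k ,
```

linear and e_r-independent at small C_s (monomers), cooperative at large
C_s with dominant cluster size k* ≈ ln(C_s)/e_r and
ln C_v ≈ (ln C_s)²/(2 e_r). Radius dependence enters through e_r:
a curvature expansion e_r = c1 − c2/r, or a tension expansion
e_r = c1 + c2·r (vesicle tension grows with radius, σ = P·r/2). The
curvature law self-destructs: it crosses zero at r_div = c2/c1 ≈ 0.44 μm
for the published wild-type coefficients, i.e. adsorption would diverge just
below the measured radius range — the diagnostic favouring tension sensing
*in vitro*. A finite-range (step) repulsion variant yields a giant-cluster
condensation that localises protein almost completely onto a membrane
region whose binding energy is a mere 1% larger — the proposed *in vivo*
curvature-sensing mechanism.

Modules: `model` (partition sums, laws, geometry), `oracle` (direct
free-energy minimisation cross-check), `localization` (step repulsion and
two-region curves), `fitting` (law fits and discrimination), `synthetic`
(study-condition data generator), `io`/`plotting`/`cli` (interface).

## Worked example

```python
import numpy as np
import spovmclust as s

# adsorption and cluster statistics at one state point
print(s.adsorption(1.0, 2.0))         # 1.2781314101589674
print(s.mean_cluster_size(1.0, 2.0))  # 1.123315819784519

# the curvature law's divergence diagnostic
law = s.RepulsionLaw(kind="curvature", c1=2.67, c2=1.1649)
print(s.divergence_radius(law))       # 0.436292... (μm)

# close the loop: generate tension-law data, fit it back
spec = s.GeneratorSpec(law=s.RepulsionLaw(kind="tension", c1=0.7, c2=0.61),
                       radii=(0.75, 3.0),
                       concentrations=tuple(np.geomspace(0.5, 20, 20)),
                       noise_cv=0.0, seed=1)
fit = s.fit_concentration_profiles(s.generate_dataset(spec), "tension")
print(fit.c1, fit.c2)                 # 0.7000000000000051 0.6099999999999988
```

The same operations are available from the shell:

```
$ spovmclust isotherm --er 2 --cs 1
1.278131
$ spovmclust simulate-data --seed 1 --out data.csv
wrote data.csv (120 rows)
$ spovmclust fit --law tension --data data.csv --out fit.json
```

`1.278131` is the normalised adsorption C_v at C_s = 1, e_r = 2 — about
28% above the monomer-only value 1.0, the excess being dimers and larger
clusters; the fitted `c1`, `c2` recover the tension-law coefficients that
generated the data.

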