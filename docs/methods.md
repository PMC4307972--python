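# Methods

## The model

A vesicle of radius r sits in a dilute bath of SpoVM monomers.  Membrane and
solution are idealised as lattices: the solution has L_s sites holding n_s
proteins, the vesicle surface has L_v ≈ 4r²/a² sites (a ≈ 4 nm, the length of
the amphipathic helix; the convention is taken literally, without a factor of
π, since only the scaling with r matters).  Bound proteins gain a binding
energy ϵ_b, attract nearest neighbours within a cluster with energy ϵ_nn per
bond, and repel every other member of their cluster with strength ϵ_r —
short-range attraction against longer-range repulsion, the balance that
stabilises finite clusters.  For a cluster of k proteins the repulsive energy
is ϵ_r·k(k−1)/2 (every pair interacts while the interaction range exceeds the
cluster size).  All energies are expressed in k_B·T (room temperature);
e_r = ϵ_r/k_B·T.

Minimising F = E − TS over the cluster counts m_k in the dilute limit
(n_v ≪ L_v, n_s; n_s/L_s ≪ 1) gives the equilibrium distribution, and with
the normalisations C_s = c_s/c_0, c_0 = e^{−(ϵ_nn+ϵ_b)}·α and
C_v = n_v/(L_v e^{−ϵ_nn}), the adsorption isotherm becomes a pure
two-parameter family:

    C_v(C_s, e_r) = Σ_{k≥1} k · e^{−k(k−1)e_r/2} · C_s^k .

The series converges for every C_s ≥ 0 iff e_r > 0 (at e_r = 0 it is
geometric, C_v = C_s/(1−C_s)², convergent only below C_s = 1).  At low
concentration the monomer term dominates and adsorption is linear in C_s and
independent of e_r; at high concentration the dominant term sits near
k* ≈ ln(C_s)/e_r and ln C_v ≈ (ln C_s)²/(2 e_r).

Radius dependence enters only through e_r:

* curvature law, e_r = c1 − c2/r — leading order of an expansion in a/r;
* tension law,   e_r = c1 + c2·r — leading order of an expansion in membrane
  tension, which for vesicles at common osmotic pressure difference P grows
  as σ = P·r/2 (P and σ are absorbed into c2).

The curvature law carries its own refutation: with c1, c2 > 0 it crosses
zero at r_div = c2/c1, below which adsorption diverges.  With the wild-type
coefficients (c1 = 2.67 k_B·T, c2 = 1.1649 k_B·T·μm) r_div = 0.436 μm —
just below the smallest measured vesicles, which is unphysical.  The tension
law stays positive at every radius and reproduces the observed exp(−b·r)
decay of adsorption with radius (visible in the model as the cooperative
part C_v − C_s falling off as e^{−c2·r}).

## Numerics

Series are evaluated in log space (summand logs plus `logsumexp`), so
concentrations up to e^100 and adsorptions far beyond float range are
handled; `log_adsorption` exposes ln C_v directly.  Truncation is adaptive:
terms are extended (doubling) until past the mode and until the geometric
tail bound — next term divided by (1 − ratio) — is below `tol` (default
1e−12) times the partial sum, with a hard cap of 10⁶ terms.  Divergent
parameter combinations raise a dedicated error naming the offending
(C_s, e_r); the curvature law is deliberately allowed to return e_r ≤ 0 so
that the divergence surfaces downstream as the diagnostic it is.

"Average cluster size" is number-weighted by default (bound proteins per
cluster, Σk·m_k/Σm_k); the mass-weighted variant (average over proteins) is
available via a flag and always exceeds it.  Both conventions agree in the
monomer limit; the choice matters only deep in the cooperative regime.

## Free-energy verification

The closed-form distribution is cross-checked by minimising the finite-system
free energy directly.  The mixing entropy of cluster placements is written
with clusters as single placed objects, S_ves = ln[L_v!/(Π m_k!(L_v−N_cl)!)],
N_cl = Σm_k; the common dense notation with (L_v−n_v)! in place of
(L_v−N_cl)! is *not* the exact potential of the equilibrium distribution —
its literal derivative carries a factor k on ln(L_v−n_v) and its stationary
point is not extensive — but the two coincide in the dilute limit, and the
reported exact (log-gamma) entropy keeps the unoccupied-site convention for
comparability.  The objective is minimised by multi-start L-BFGS-B in
log-count space, seeded from the dilute closed form, and polished with an
exact reduction: at stationarity every m_k is an explicit function of n_v, so
the stationary point is a one-dimensional root (solved in the unbound count
x = n_s − n_v, which keeps full relative precision both in the dilute and
the strong-binding regime).  Convergence is declared at gradient ∞-norm
< 1e−8; the first-order conditions are additionally reported in the
unoccupied-site form.  At bath occupancy 1e−6 (with the bath lattice grown
at fixed n_s = 10⁴, L_v = 10⁴, K = 20) minimiser and closed form agree to
better than 0.1% per cluster size across a 3×3 grid of (ϵ_b, e_r); the
residual deviation is the genuine finite-size effect, of order
k·(n_v/n_s + n_s/L_s).

## Finite-range repulsion and two-region localization

If the repulsion has finite range — a step function in cluster units — the
cluster energy grows quadratically only up to k_max proteins and linearly,
[k_max(k_max−1) + (k−k_max)(k_max−1)]·e_r0/2, beyond.  The linear tail is
exactly E(k) = s·k with s = (k_max−1)e_r0/2, so once C_s exceeds e^s the
series terms grow with k and the sum must be truncated physically at the
region's site budget K_cap: above that threshold most bound protein
condenses into one giant cluster of the largest admissible size (the k =
K_cap term dominates).  Because the transition condition depends on C_s
only through ln C_s − s, the condensation flag flips exactly once along an
increasing concentration grid.

Two membrane regions of equal area sharing one bath differ only in binding
energy: the higher-curvature region (easier helix insertion) by δ_b,
defaulting to the 1%-of-ϵ_b scale (a relative difference requires an
absolute ϵ_b alongside it, since a percentage alone fixes no energy).  The
advantage enters as an effective concentration C_s·e^{δ_b} — every size-k
term in region 1 is favoured by e^{k·δ_b}, which proves the localization
fraction exceeds ½ for any δ_b > 0 and drives it towards 1 once giant
clusters (k ≈ K_cap = 1000, δ_b = 0.02 → e^{20} amplification) form.  In
the monomer limit the fraction is e^{δ_b}/(1+e^{δ_b}); with e_r0 = 0.2,
k_max = 10, K_cap = 1000 it exceeds 0.9 within the window where region 1
has condensed but region 2 has not.  A caveat on "site saturation": in the
step model the condensation point inherently sits at bound densities
comparable to the site budget (at the threshold the terms k > k_max are all
≈ k), so the per-site dilute bookkeeping is stretched there; the curves are
therefore read qualitatively — a sharp localization transition co-occurring
with giant-cluster formation — rather than as calibrated coverages, and the
pre-condensation window (region 1 giant, region 2 not) is used as the
operational "before saturation" criterion.  Bath depletion is ignored (both
regions see the same C_s), matching the dilute framework.  The
fixed-stoichiometry alternative (monomers ⇌ q-mers, C_v = C_s + q·K_q·C_s^q)
is provided for contrast; it produces a smooth cooperative upturn but no
condensation transition.

## Fitting and model discrimination

Observed adsorption is A·C_v(c/c_0, e_r(r)) with A (signal amplitude) and
c_0 (concentration scale) free nuisance parameters — both experimental axes
are in arbitrary units.  The objective is weighted least squares in linear
adsorption space, weights 1/σ² (unit weights when σ is absent), with a
log-space objective available by flag.  Positive parameters are optimised in
log; divergent proposals (curvature law past its divergence radius) receive
a large finite penalty instead of an exception, keeping the optimiser alive
near the boundary.  Fits are multi-start (default 16 seeded log-uniform
starts over c1 ∈ [0.05, 5], c2 ∈ [0.02, 5], A within a decade of the data
scale) refined by trust-region least squares; deterministic given data and
seed.  Radius-profile fits hold the effective C_s fixed (A and c_0 are not
separately identifiable from a single concentration slice) unless freed by
flag; concentration-profile fits share (c1, c2, A, c_0) across radii.
Identifiability diagnostics flag constant-adsorption designs, single-radius
comparisons (reported as a tie) and data confined to the linear regime,
where only A/c_0 is identified.

Synthetic datasets emulate the (non-deposited) vesicle measurements:
radius grids spanning 0.75–30 μm including 0.75/1.75/3.25 μm, a
concentration grid, amplitude-scaled model surface, and mean-one
multiplicative lognormal noise, ε ~ N(−cv²/2, cv) — adsorption signals are
positive intensities, making multiplicative error the natural default.  The
generator is fully reproducible from its seed and refuses grids containing
divergent state points.  What passing these tests shows is that the
pipeline recovers the truth under its own noise model; real measurements
add instrument effects (background, bleaching, radius uncertainty) the
generator deliberately does not imitate.

Two study designs are fixed by a-priori power analysis (computed from
noiseless information only, before any seed-level runs):

* noisy recovery — n = 40 (radii 0.75 and 3 μm × 20 concentrations),
  5% noise, 50 seeds.  With A and c_0 free, the tension offset c1 is nearly
  degenerate with them when data stay below C_s ≈ 5 (Cramér–Rao sd ≥ 15% of
  c1); concentrations spanning the deep cooperative regime C_s ∈ [0.5, 20]
  (mean cluster sizes 2–4) reduce the bound to ≈ 6.8% for c1 and ≈ 2.2% for
  c2, so the grid geomspace(0.5, 20, 20) is used.
* law discrimination — 16 radii over 0.75–30 μm, dense below 3 μm where the
  two laws differ most, fixed C_s = 4, 2% noise; chosen by the rule that
  the minimal cross-family lack-of-fit exceed the expected noise SSR by at
  least 5× in the weaker direction (measured ≈ 35× for tension-generated
  and ≈ 7× for curvature-generated data).

## Problem sizes and defaults

| quantity | default | why |
|---|---|---|
| series tolerance `tol` | 1e−12 relative tail | far below any reported precision |
| series hard cap | 10⁶ terms | covers ln C_s = 100 at e_r ≥ ~1e-4 |
| oracle system | L_v = n_s = 10⁴, K = 20, ns* ≤ 1e−3 | finite-size error ~k·n_v/n_s below test tolerances |
| minimiser | 4 starts, gradient tol 1e−8 | objective is near-convex around the dilute start |
| noise CV | 0.05 | intensity-type measurement scatter |
| localization | e_r0 = 0.2, k_max = 10, K_cap = 10³, δ_b = 0.02 | small repulsion is what makes localization sharp; K_cap = region site budget |
| fit starts | 16 (8 in heavy sweeps) | multimodality is mild; the global basin is wide |

## Limitations

* Everything is equilibrium; no kinetics of cluster growth or exchange.
* Dilute-limit bookkeeping: no Langmuir saturation correction beyond a
  coverage warning at n_v/L_v > 0.1.
* e_r is phenomenological — the elastic-membrane origin of the repulsion is
  not derived here.
* The step-repulsion region model has no spatial geometry; regions are
  abstract areas, and its quantitative coverages near condensation should
  not be over-read (see above).
* Printed tension-law coefficients appear in two variants (c2 = 0.61 and
  0.6 k_B·T·μm⁻¹) in the source material; both are accepted as
  configuration, 0.61 being the synthetic-data default.
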