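# Model and methods

## The physical picture

`cytodel` models the journey of an engineered protein (or peptide) from
the bloodstream into the cytosol of tumor cells, in a Krogh-cylinder
tissue element: a capillary of radius 8 µm feeding a concentric annulus
of tissue out to 108 µm (100 µm of tissue depth), with radial symmetry.
Along the way the agent (1) extravasates across the capillary wall,
(2) moves through the interstitium by diffusion and, when lymphatics
are functional, convection, (3) binds a cell-surface receptor,
(4) is internalized with the receptor, (5) which is replenished by
recycling and synthesis, (6) escapes the endosome with some small
efficiency, and (7) engages a cytosolic target protein — either
blocking it stoichiometrically (a *binder*) or destroying it
enzymatically with turnover `k_cat` (a *catalytic* inactivator).

Six concentration fields per radial shell describe the state: free
interstitial agent `A_int`, free receptor `R_free`, surface complex
`RC_surf` (all per liter of whole tissue), and free cytosolic agent
`A_cyt`, free target `T_free`, inhibitory complex `TC_cyt` (per liter
of cytosol).  An optional cargo-free "cold" competitor adds `A_int_cold`
and `RC_surf_cold`.  The cytosolic species use the cytosol-volume basis
because the quantities with physical anchors (copies per cell, the
~2–10 nM concentration of a few-thousand-copy protein) live there; the
cytosol volume fraction `phi = cell_density × cytosol_volume` converts
between bases wherever fluxes cross compartments.

## Transport

The wall flux density into the innermost shell is

    J_w = P (C_plasma − A_int/ε) + (1 − σ) v_wall C_plasma

a diffusive permeability term plus, when transmural filtration drives
interstitial convection, solvent drag of plasma solute with the
filtrate (Patlak flux; σ is the agent's osmotic reflection coefficient
at the vessel wall).  Inside the tissue the agent diffuses with an
effective interstitial diffusivity `D` and, when `v_wall > 0`, advects
with the radial filtration flow `v(r) = v_wall · r_cap/r`.  At the
outer (Krogh) boundary diffusion sees a closed wall; the convective
flux leaves the domain, representing lymphatic drainage (a reflective
variant is flag-switchable, `outer_boundary_sink=False`).

Transport coefficients are stored for a 70 kDa reference and rescaled
to an agent's size by power laws: `D ∝ MW^(−1/3)` (Stokes–Einstein on a
compact globule) and `P ∝ MW^(−0.65)` (hindered pore transport across
the endothelium falls off faster with size than free diffusion).  A
3.5 kDa peptide therefore extravasates ~7× faster and diffuses ~2.7×
faster than the 70 kDa protein.

## Reactions

Per shell (rates in 1/s; `ε` void fraction, `f` endosomal escape
fraction):

    A_int + R_free ⇌ RC_surf          kon·(A_int/ε)·R_free − koff·RC,  koff = kon·Kd
    RC_surf → internalized            ke·RC; fraction f appears in A_cyt (÷ phi),
                                      the rest is degraded in the endolysosome
    receptor replenishment            +ke·RC to R_free (synthesis/recycling matches
                                      internalization: the receptor pool is at
                                      steady state, as for delivery of a non-toxic agent)
    A_cyt decay                       ln2 / cytosolic_half_life
    T_free synthesis / decay          k_syn = T0·ln2/t_half_T;  decay ln2/t_half_T
    A_cyt + T_free ⇌ TC_cyt           kon_t, koff_t = kon_t·Kd_t
    TC_cyt decay                      ln2 / cytosolic_half_life (see below)
    catalytic turnover                TC_cyt → A_cyt at k_cat; the inactivated
                                      target is removed from the system

Two modelling choices deserve emphasis:

* **The inhibitory complex is degraded at the agent's cytosolic decay
  rate.**  A delivered protein remains accessible to the ubiquitin–
  proteasome system while bound, and the complexed target is destroyed
  with it.  The consequence is that *holding* a target down requires a
  sustained delivery rate, not merely an accumulated stock of agent —
  which is what makes cytosolic stability (a longer cytosolic
  half-life) extend the duration of the effect, with diminishing
  returns once target synthesis becomes limiting.
* **Catalysis recycles the enzyme.**  A catalytic agent is released
  intact on each turnover, so trace cytosolic amounts process an
  abundant target; this is why catalytic cargoes dominate binders at
  low doses and high target levels.

Pre-dose the system is at equilibrium: empty interstitium and cytosol,
full receptor pool, target at its synthesis/turnover steady state.
Plasma concentration is a forcing function — mono-exponential decay per
bolus with superposition of repeated doses — with no feedback from
tissue uptake (the tissue element drains a negligible fraction of a
systemic dose).

## Numerics

Finite volumes on a uniform radial grid (default 100 shells), central
differences for diffusion and first-order upwinding for convection
(positivity-preserving at the modest Péclet numbers of interstitial
flow).  The stacked system (6–8 species × shells, plus three cumulative
audit states) is integrated with BDF (`scipy.integrate.solve_ivp`) at
`rtol 1e-8`, `atol 1e-12` M, with a structural Jacobian-sparsity
pattern for the finite-difference Jacobian.  Dose times are integrator
restart points because the forcing is discontinuous there.  Outputs are
sampled every 0.25 h.

Three extra states integrate cumulative wall influx, degradation and
convective outflow of the warm agent, so every trajectory carries a
global mass audit; the residual is below 0.1% of the total influx in
the test suite (typically ~1e-12 relative).  Receptor conservation
(`R_free + RC_surf (+ cold)` constant per shell) holds to integrator
tolerance.  Slightly negative concentrations beyond `~1e3·atol` abort
the run with a diagnostic rather than being clipped.

At 100 shells a 72 h single-dose simulation takes well under a second
on one CPU core; affinity sweeps cache simulations by a hash of the
full parameter set and a full optimum search costs ~20–30 simulations.

## Outcome metrics

Inhibition at a point is `1 − T_free/T0`, the fractional reduction of
free, functional target below its pre-dose steady state; catalytically
inactivated target is gone from the free pool and therefore counts as
inhibited — blockade and degradation are scored by the same functional
outcome.  Tissue summaries weight shells by annular volume (the
capillary lumen is excluded):

* **maximum inhibition** — the largest volume-averaged inhibition at
  any single time;
* **inhibitory effect** — the volume-averaged inhibition integrated
  over time (fraction·hours; trapezoidal rule on the output grid);
* **time of maximum delivery** — the argmin over time of the
  volume-averaged free target (NaN if the target never drops, e.g.
  zero dose);
* **penetration depth** — the smallest depth from the capillary wall
  enclosing a given fraction (default 50%) of all tissue-associated
  agent (interstitial + surface + cytosolic, common tissue basis), with
  linear interpolation of the cumulative mass profile.

## Parameters: anchors and calibration

Literature-anchored values (used as preset defaults): agent 70 kDa with
receptor Kd 68 pM (a designed ankyrin-repeat EpCAM binder) and plasma
half-life 2.55 h (laronidase); peptide 3.5 kDa (calcitonin) with 0.28 h
half-life; cold competitor 10 kDa; tumor cellularity 2.9e8 cells/mL and
5.4e5 EpCAM receptors/cell (5.3e5 is also reported for MCF-7 cells);
internalization rates 0.002 (EpCAM), 0.01 (HER2), 0.08 (EGFR) min⁻¹;
catalytic rate 2.35 min⁻¹ (a RAS-cleaving enzyme); target levels 1e4
(typical) or 1e5 (abundant) copies/cell; single doses to 1 µM plasma,
or 200 nM for the sparse catalytic regimen.

The remaining constants are the package's calibration, fixed once so
that the default scenarios reproduce the canonical delivery phenotype
of this tissue type — maximum delivery near one day after dosing, the
majority of a tight binder confined to the first ~20 µm of tissue, an
affinity optimum in the sub-10 nM range without convection and a
~16 nM optimum with convection — and then frozen:

| parameter | default | rationale |
|---|---|---|
| vascular permeability P (70 kDa) | 3e-7 cm/s | leaky tumor microvessels, dextran-scale |
| interstitial diffusivity D (70 kDa) | 1e-8 cm²/s | strongly hindered diffusion in dense tumor ECM |
| void (interstitial) fraction ε | 0.2 | accessible volume fraction for a 70 kDa solute |
| filtration velocity v_wall (convection preset) | 0.1 µm/s | reported interstitial fluid velocities |
| reflection coefficient σ | 0.9 | a 70 kDa solute is mostly sieved at the wall |
| receptor kon | 1e5 M⁻¹s⁻¹ | typical protein–protein association; affinity varied via koff |
| endosomal escape fraction f | 0.02 | few-percent escape efficiencies of current delivery moieties |
| cytosolic half-life (agent & complex) | 6 h | intracellular protein degradation timescale |
| target engagement | Kd 0.1 nM, kon 1e6 M⁻¹s⁻¹ | engineered intracellular binder; capture fast vs decay |
| target half-life | 24 h | a stable cytosolic protein; sets the resynthesis rate |
| cytosol volume per cell | 1 pL | makes ~6000 copies ≈ 10 nM |
| muscle preset | P 3e-8 cm/s, σ 0.95, 5.4e4 receptors/cell | continuous endothelium; 10× lower off-target receptor level |

Because these effective constants are calibrated rather than measured,
the quantitative outputs should be read as order-of-magnitude
statements about this class of tissue, while the *comparative* results
(affinity optima shifting with convection, receptor density and
internalization rate; catalytic vs binder; cold dosing; stability
engineering) are the robust content of the model.

## Experiment drivers

`experiments` wraps the simulations the analyses need: 1-D parameter
sweeps (`run_sweep`, deterministic and memoized), affinity optimization
(`optimal_affinity`: a 13-point log-spaced Kd scan over 1 pM–10 µM
followed by golden-section refinement on log10 Kd to 0.02 decades; the
objective defaults to maximal delivery, i.e. the minimum over time of
the volume-averaged free target, with `max_inhibition` and
`inhibitory_effect` as alternatives — note the delivery and
max-inhibition optima coincide identically, since the volume-averaged
inhibition is an affine function of the volume-averaged free target),
receptor-density × affinity heatmaps with the per-density optimal-Kd
trace, and a side-by-side strategy comparison (baseline, optimal Kd,
cold dose, 100× cytosolic stability, catalytic cargo) with plasma
exposure (AUC) accounting.

Open modelling questions were resolved as follows: endosomal transit is
an instantaneous split (escape fraction to the cytosol, remainder
degraded) rather than an explicit seventh compartment; plasma is not
depleted by tissue uptake; the warm:cold dose ratio is 1:1 at the peak
(the cold dose shares the warm plasma profile, including its half-life,
while its tissue transport follows its own 10 kDa size); convective
outflow at the Krogh boundary is the default, with a reflective option.

## Limitations

Surface-charge effects on permeability and diffusivity are not
modelled; neither are passive (EPR) accumulation of large carriers,
transcytosis, explicit vascular networks, receptor down-regulation by
toxic cargo, or saturable plasma protein binding.  The Krogh element
assumes a uniformly spaced, uniformly perfused capillary bed — tumor
heterogeneity in perfusion, ECM density and receptor expression is
outside its scope.  Passing tests demonstrate internal consistency
(conservation, oracle agreement, grid convergence) and reproduction of
the comparative phenotypes above under the calibrated defaults; they do
not validate the absolute magnitudes against in vivo measurements.
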