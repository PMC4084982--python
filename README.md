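# ribofit

Free-energy machinery for cryo-EM-guided conformational transitions, built
around the workflow used to map large ribosomal motions (the intersubunit
"ratchet", the head swivel, and tRNA translocation) onto a free-energy
landscape:

- **density fitting** — synthetic density maps from atomic coordinates
  (mass-weighted Gaussian kernels), the real-space correlation coefficient
  (CC) as fitting objective `U_EM = -CC`, and the analytic per-atom fitting
  force `F_i = k_EM * dCC/dr_i`, with the force-balance weight `w_EM` that
  scales the mean density force against the mean structural force;
- **map alignment** — thresholding a map to the molecular volume,
  moment-of-inertia rigid fitting, deterministic CC-ascent refinement, and
  cloud-in-cell (CIC) regridding of the map into the model frame;
- **windowed sampling protocol** — per window: an EM-fitting phase
  (density force on, optional steering), umbrella centers pinned at the
  current group centers of mass, equilibration, then sampling of the
  umbrella coordinates, with `w_EM` auto-adjusted so no umbrella
  coordinate moves more than 0.60 Å per window;
- **adaptive path search** — moving harmonic targets
  `r*_n = <r>_{n-1} + δ û` for steered groups, with the force constant
  raised or lowered by 25 pN/Å depending on whether the realized progress
  projection beat the threshold Δ = δ/2 (initial k = 100 pN/Å,
  δ ∈ [0.3, 0.6] Å, 1 pN = 1.439×10⁻² kcal/mol/Å);
- **multidimensional WHAM** — the self-consistent estimate of per-window
  free-energy shifts `F_j` and unbiased per-sample weights (binless
  sample-reweighting form, tolerance 10⁻⁴ kcal/mol), with projected
  observables: the ratchet-progress coordinate
  `R₁ = vec(R - Rⁱ)·û_f` (after rigid superposition on the initial
  reference), the signed travel coordinate `R₂` along the tRNA P→E axis,
  1-D/2-D free-energy profiles `F(X) = -k_B T ln P(X)`, and weighted
  averages with spreads;
- **geometry descriptors** — ratchet angle (rotation vector projected on
  the intersubunit axis), signed head-swivel angle (third principal axis
  projected into the travel plane), the P/E-gate width
  `|COM(A790) - COM(G1338+A1339)|`, Chasles screw-axis decomposition of a
  rigid displacement, and the internal/external split of a conformational
  change;
- **synthetic fixtures** — a two-body ratchet bead assembly with head,
  tRNA and gate analogues, state density maps at a stated resolution, and
  analytic landscapes with exact Monte-Carlo umbrella samplers, so every
  stage is testable against a closed form.

It is aimed at method developers who want a desk-scale, fully testable
implementation of this pipeline: every stage runs in seconds to minutes on
one CPU against synthetic systems whose answers are known exactly.

## Worked example

Drive the toy assembly from its POST-like state into the PRE-state density
map through 72 fitting + umbrella windows, solve WHAM, and project the free
energy onto the progress coordinate:

```python
from ribofit.demo import run_transition_demo, endpoint_basins_are_minima

result = run_transition_demo(seed=42)
print(f"final CC vs target map: {result.cc_trace[-1]:.3f}")
centers, F, _ = result.profile
print(f"R1 span sampled: {result.r1_values.min():.1f} .. "
      f"{result.r1_values.max():.1f} A (endpoint at "
      f"{result.r1_endpoint:.1f} A)")
print("endpoint basins are local minima:",
      endpoint_basins_are_minima(centers, F))
```

Output from this exact call:

```
final CC vs target map: 0.996
R1 span sampled: 0.8 .. 18.5 A (endpoint at 18.4 A)
endpoint basins are local minima: True
```

The fitted model ends essentially inside the target map (CC 0.996), the
sampled progress coordinate covers the whole POST→PRE transition, and the
WHAM profile shows both endpoint states as free-energy basins separated by
an interior barrier — the qualitative structure the method is designed to
recover.

Measuring the toy assembly's descriptors:

```python
from ribofit import synthetic
from ribofit.geometry import ratchet_angle, gate_width
from ribofit.structure import SelectionSpec as S

toy = synthetic.make_toy_ribosome()
angle = ratchet_angle(toy.endpoints["PRE"], toy.endpoints["POST"],
                      S.group("large_body"), S.group("small_body"))
w = gate_width(toy.endpoints["PRE"], S.group("gate_A790"),
               S.group("gate_G1338") | S.group("gate_A1339"))
print(f"ratchet angle {angle:.2f} deg, open gate width {w:.1f} A")
# ratchet angle 7.00 deg, open gate width 21.2 A
```

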