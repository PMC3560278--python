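# colonyscatter

Label-free scoring of human embryonic stem-cell (hESC) colony quality from
laser forward-scattering patterns.

## The problem

hESC colonies are routinely graded by eye under a microscope: *good*
colonies grow as uniform, flat sheets with clear edges, while *bad*
(differentiating) colonies pile up into irregular-edged, lumpy mounds.
Manual grading is slow and subjective. An alternative is purely optical: a
low-power laser (λ = 633 nm) shone perpendicularly through a colony
produces a forward-scattering pattern on a CMOS sensor behind the dish, and
the pattern's shape encodes the colony's morphology — flat circular
colonies diffract into near-circular rings, lumpy irregular ones into
asymmetric speckle.

`colonyscatter` implements that measurement chain end to end on synthetic
colonies, so the whole pipeline is testable without wet-lab data:

1. **Phantoms** — 3-D colony thickness maps h(x, y) whose class statistics
   match confocal morphometry of real colonies (good: 53 ± 4.2 μm tall;
   bad: 44 ± 13.9 μm with lumps and edge ripple).
2. **Scattering** — the colony as a thin phase object,
   t(x, y) = exp(i·2πΔn·h(x, y)/λ), propagated to the detector with the
   band-limited angular-spectrum method (exact scalar diffraction).
3. **Features** — pseudo-Zernike moment magnitudes |A(n, m)| of the
   disk-mapped pattern,

       A(n, m) = (n+1)/π · Σ f(ρ, θ) R(n, m, ρ) e^(−imθ) ΔA,

   rotation-invariant shape descriptors; n ≤ 17 gives 171 of them, of which
   the 161 most class-separating are kept by Fisher's criterion
   F(j) = (μ₁ − μ₂)² / (s₁² + s₂²).
4. **Classification** — a linear SVM on the standardized selected features,
   reported as a 2×2 table of per-class "distinguish rates".
5. **Morphometry** — the validation measurements: colony height from
   confocal-like z-stacks (with a two-sample t-test between classes) and
   the Oct-4/DAPI integrated-intensity ratio, a proxy for the pluripotent
   cell fraction.

## Worked example

```python
import colonyscatter as cs

# one good and one bad colony, simulated to the detector
good = cs.generate_phantom(cs.GOOD_PARAMS, 0)
bad = cs.generate_phantom(cs.BAD_PARAMS, 1)
for ph in (good, bad):
    pattern = cs.simulate_pattern(ph, seed=0)
    print(ph.label, round(ph.peak_height, 1), "um,",
          "asymmetry", round(cs.asymmetry_index(pattern.intensity), 3))

# the full benchmark: 100 colonies per class, 70/30 split
from colonyscatter.pipeline import run_benchmark
bench = run_benchmark(n_good=100, n_bad=100, seed=42)
print(bench["report"].to_text())
```

prints

```
good 50.4 um, asymmetry 0.081
bad 90.7 um, asymmetry 0.717
True class              good         bad
good                  100.0%        0.0%
bad                     0.0%      100.0%
n_test = 60
```

The good colony's pattern is nearly rotation-symmetric (asymmetry index
0.08, mostly shot noise) while the bad colony's lumps break the symmetry
(0.72; this particular bad colony also carries a tall lump, hence its
90.7 μm peak against a 44 μm class mean). On the held-out 30% of the synthetic benchmark the linear SVM
separates the classes completely — comfortably above the 87.3% / 83.6%
per-class rates measured on real colonies, as expected for phantoms that
idealize the two morphology classes.

A command-line interface covers the same workflow file-to-file
(`colonyscatter simulate | extract | train | classify | evaluate | morpho`);
every run writes its effective config and seed so artifacts regenerate
bit-identically.

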