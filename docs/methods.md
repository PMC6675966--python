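# Methods

## Transport model

The medium is a laterally infinite stack of horizontal layers, each with
constant absorption `μa` (mm⁻¹), scattering `μs` (mm⁻¹),
Henyey–Greenstein anisotropy `g` and refractive index `n`; the last layer
is semi-infinite and the half-space above the surface has index
`n_ambient` (default 1.0, air). The source is a pencil beam at the
origin, normally incident. Packets move in exponential free paths
`s = −ln(u)/(μa+μs)`, and at every collision the packet weight is
multiplied by the single-scattering albedo `μs/(μa+μs)` (discrete
absorption weighting) before scattering through a Henyey–Greenstein polar
angle and uniform azimuth. The direction vector is renormalized after
every scatter and refraction so unit length holds to 1e−9 over
arbitrarily long trajectories.

Boundary physics: when a free path would cross a layer interface or the
top surface, the packet is moved exactly onto the boundary and the
unpolarized Fresnel reflectance decides stochastically between specular
reflection and Snell refraction (total internal reflection beyond the
critical angle). The unused fraction of the sampled optical path is
discarded and a fresh path drawn after the crossing — statistically exact
for the memoryless exponential. A packet that refracts out through the
top surface is detected regardless of exit angle; detection optics
(finite NA, polarizers) are not modeled.

Phase function choice: the Henyey–Greenstein function is the standard
single-parameter model in tissue optics and is fully determined by the
tabulated `g` values used here; no measured phase functions are
available for these media.

Specular handling: by default packets start just inside the surface with
weight 1, so the specular reflection at normal incidence is excluded from
the reported diffuse reflectance — the convention matching
crossed-polarizer SFDI instruments, which reject specular light. The
alternative (`specular="include"`, launch weight reduced by
`((n−n_amb)/(n+n_amb))²`) is available for matched-illumination studies.

Russian roulette: packets with weight below 1e−4 survive with probability
0.1 and are reweighted by 1/0.1, keeping deep-tail tallies unbiased. Both
parameters are configurable; threshold 0 disables roulette. A hard cap of
1e8 interactions per packet guards against unbounded walks; it only
matters in the exactly-conservative case `μa = 0` with roulette off,
where the depth random walk is recurrent with a heavy-tailed return time
and ~1e−4 of packets are truncated (the conservation test accounts for
this).

## SFD tally and depth distributions

Each detected packet contributes `ξ = W·exp(−2πi·fx·Δx)` with
`Δx = x_exit − x_entry`, the direct Monte Carlo estimator of spatially
modulated reflectance (modulation along x only; the y displacement
carries no phase). `ξ` is scored once at the bin of the packet's maximum
visited depth on a uniform grid (default `Δz = 0.01 mm` to 40 mm plus one
overflow bin); the reverse cumulative sum of `P_zmax` gives `P_V∩D(z)`.
This is mathematically identical to scoring every midway surface the
trajectory crossed — a packet crosses the plane at depth `z` iff its
maximum depth reaches `z` — but O(1) per packet; a stored-trajectory
brute-force implementation of the per-surface tally backs this
equivalence in the test suite.

Estimates are normalized by *launched* packets, making `P_V∩D(0)` the
diffuse reflectance per incident packet. Reported distributions are the
real parts of the complex estimates: the pencil-beam geometry is
symmetric in x, so the expectation is real; taking magnitudes would bias
small values upward by the noise floor. Imaginary parts are retained and
verified to be statistically zero. Per-bin second moments of the real and
imaginary parts provide 1-σ uncertainties.

Percentile depths invert the cumulative detected fraction `X(d)` with
linear interpolation inside the crossing bin, fixing sub-bin behaviour
deterministically. Mass in the overflow bin counts toward `Rd` but makes
large `X` unattainable; the error in that case says to raise `z_cap`
rather than extrapolating silently.

## Reproducibility

A run is fully determined by (seed, N, stack, fx list, grid, roulette,
specular mode). Packets are simulated in fixed chunks of 2¹⁶, each chunk
drawing from an independent `SeedSequence`-spawned PCG64 substream, so
results are bit-identical across repeats and partitionable at chunk
granularity. The propagation kernel is written once and instantiated
both numba-jitted (production) and as pure Python (reference and
trajectory recording). The two consume identical random streams and make
identical decisions; positions can drift by ~1 ulp per operation between
the variants because of compiler instruction fusion, which the
cross-check test bounds at 1e−8 while statuses and weights are
bit-identical.

## Two-layer validation geometry

The depth-restricted reflectance `Pzmax(z ≤ d)` is validated against an
explicit two-layer simulation whose base layer, starting at depth `d`,
has `μa = 100 mm⁻¹`, `μs = 0` — effectively perfect extinction within
0.01 mm (configurable). Physically this mirrors a liquid phantom over an
absorbing gel base; every packet that dives below `d` is lost, so the
two-layer total reflectance must equal the homogeneous restricted
reflectance within Monte Carlo noise. The refractive index of the
phantom-twin medium is taken as the package default n = 1.4; the liquid
phantom this emulates is water-based, so its true index is slightly
lower, which is one contribution to the residual experiment–simulation
band (±0.03) used as the acceptance tolerance.

## Lookup table

At fixed `(g, n)`, scaling `(μa, μs)` by `k` and `fx` by `k` contracts
every length by `1/k` exactly (congruent trajectories), so percentile
depths obey `dX = l* · F_X(μs′/μa, fx·l*)`. The shipped table stores
`dX/l*` for `X ∈ {0.1, 0.25, 0.5, 0.75, 0.9}` on the 18-value ratio grid
spanning 1–1000 (`l* = 1 mm`, `g = 0.8`, `n = 1.4`) and
`fx·l* ∈ {0, 0.05, 0.1, 0.2, 0.3, 0.5}`, built with 2×10⁵ packets per
node (seed and N recorded in the table metadata; per-node 1-σ stored
alongside). Queries interpolate bilinearly on `(ln(μs′/μa), fx·l*)` —
log spacing matches the roughly geometric ratio grid — and rescale by the
queried medium's `l*`. No extrapolation is performed outside the grid.

Tissues whose `g` and `n` differ from the table's fixed values rely on
the same similarity reduction; validation against direct simulations at
the true `(g, n)` for the eight embedded tissue presets bounds the
combined interpolation + similarity error below 7% on the median depth.

## Problem sizes and statistical tolerances

Published reference values for this method were generated at N = 10⁸
packets; this package's tests and acceptance script run at desk scale,
N = 10⁵–2×10⁶ per medium, chosen so every check resolves its target well
inside the available Monte Carlo error (standard error scales as
N^−1/2). Stochastic assertions use the printed precision of the
reference value plus 3-σ of the actual run (the σ computed by the tally
itself), never a hand-tuned band. Deterministic claims — scale
invariance, tally/oracle equivalence, reproducibility — are asserted at
machine precision or exactly.

Embedded tissue property tables are stored at full printed precision;
derived columns (μs′, l*, μs′/μa) are always recomputed, so
printed-versus-derived consistency is a test, not an assumption. The
published derived columns carry last-digit rounding inconsistencies
(ratios recomputed from the printed μa, μs, g differ by up to 0.04), and
the tests tolerate exactly that much.

## Known limitations

- Layered media only; no voxelized heterogeneity, fluorescence,
  polarization, or time-resolved transport.
- The source is an idealized normal-incidence pencil beam; oblique
  projection and finite beams are not modeled.
- Detection integrates over all exit angles; a finite collection NA
  would slightly reweight shallow trajectories.
- The synthetic two-layer geometry idealizes the absorbing base as a
  perfect extinguisher with a flat interface; real phantoms add index
  steps and finite absorber contrast, so passing the in-silico
  equivalence does not by itself bound instrument-level effects
  (calibration, demodulation), which are out of scope.
- Lookup-table queries are only as good as the similarity reduction for
  media whose `g`, `n` differ from 0.8/1.4; the 7% bound is empirical
  over the embedded tissue presets at the measurement frequencies
  (fx ≤ 0.3 mm⁻¹), not a theorem. Beyond `fx·l* ≈ 0.4`, transport turns
  subdiffusive and the reduction degrades for strongly forward-scattering
  media (g ≈ 0.97 breast shows ~9% there).
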