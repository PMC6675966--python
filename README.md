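# sfdepth

Monte Carlo optical sampling depth in the spatial frequency domain (SFD).

Spatial frequency domain imaging (SFDI) measures diffuse reflectance under
sinusoidally patterned illumination and inverts it for tissue optical
properties. Interpreting such measurements in layered tissue — skin burns,
breast tumors, subcutaneous targets — requires knowing *which depths* the
detected photons actually visited, and how that changes with the spatial
frequency `fx` of the illumination. `sfdepth` answers that question with a
transport-rigorous Monte Carlo method, for users of SFDI who need to know
what tissue thickness their signal represents.

## Method

Photon packets are launched as a pencil beam into a layered half-space and
propagated with conventional weighted Monte Carlo transport
(Henyey–Greenstein scattering with anisotropy `g`, discrete absorption
weighting by the single-scattering albedo, unpolarized Fresnel boundaries,
Russian roulette). Each packet that escapes through the top surface is
tallied directly in the SFD with the complex weight

```
ξ = W · exp[−2πi·fx·(x_f − x_0)]
```

where `W` is the detected packet weight and `x_f − x_0` its lateral
displacement. Scoring `ξ` once per packet at the bin of its **maximum
visited depth** `z_max` gives the distribution `P_zmax(z)`; its reverse
cumulative sum is the visitation-and-detection probability `P_V∩D(z)` —
the expected detected weight among packets that reached depth `z`.
`P_V∩D(0)` is the total diffuse reflectance `Rd(fx)`, and

```
X(d) = Pzmax(z ≤ d) / Rd
```

is the fraction of the detected signal whose trajectories never exceeded
depth `d`. Inverting `X(d)` yields percentile sampling depths `dX`
(`d10 … d90`): if `d90 = 5 mm`, then 90% of the measured reflectance is
certain to come from tissue no deeper than 5 mm.

Because diffuse transport at fixed `(g, n)` is similarity-invariant,
`dX/l*` depends only on `μs′/μa` and `fx·l*`, where `l* = 1/(μa+μs′)` is
the transport mean free path. The package ships a precomputed lookup table
on that dimensionless grid (`μs′/μa` from 1 to 1000), so sampling depths
for *any* medium follow from `(μa, μs′)` alone — no simulation required.

## Worked example

```python
from sfdepth import LayerStack, depth_summary, from_ratio, run_simulation

props = from_ratio(ratio=100.0, lstar=1.0, g=0.8, n=1.4)
result = run_simulation(LayerStack.homogeneous(props),
                        fx_list=[0.0, 0.1, 0.3, 0.5],
                        n_packets=200_000, seed=1)
print(depth_summary(result).table.round(3))
```

prints (one row per spatial frequency, depths in mm):

```
 fx    Rd   d10   d25   d50   d75   d90
0.0 0.621 0.439 0.885 1.800 3.493 5.944
0.1 0.233 0.227 0.448 0.825 1.378 2.104
0.3 0.060 0.087 0.184 0.346 0.567 0.813
0.5 0.032 0.054 0.119 0.227 0.370 0.518
```

Planar illumination (`fx=0`) of this reference medium (`μs′/μa = 100`,
`l* = 1 mm`) returns 62% of the injected light, half of it confined to the
top 1.8 mm; at `fx = 0.5 mm⁻¹` only 3% returns and the median sampling
depth shrinks to 0.23 mm — patterned light interrogates superficial
tissue. The `examples/` directory has narrative scripts for the two-layer
validation geometry (`phantom_layers.py`), literature tissue types
(`tissue_depths.py`) and table queries (`lookup_query.py`).

A thin CLI wraps the same library:

```
sfdepth simulate --preset "human skin@731" --fx 0 --fx 0.1 --photons 100000 --seed 1 --out run1
sfdepth lut query --mua 0.0044 --musp 1.1253 --fx 0 --fx 0.1
```

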