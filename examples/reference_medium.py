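"""Depth distributions for a highly scattering reference medium.

Simulates a semi-infinite medium with mus'/mua = 100, l* = 1 mm, g = 0.8,
n = 1.4 and prints the visitation-and-detection probability P_V&D at the
surface and at depth, plus percentile sampling depths per spatial
frequency.  P_V&D(z=0) is the total diffuse reflectance Rd(fx); its decay
with depth shows how little of the detected signal ever visited deep
tissue.
"""

from sfdepth import LayerStack, depth_summary, from_ratio, run_simulation

props = from_ratio(ratio=100.0, lstar=1.0, g=0.8, n=1.4)
print(f"medium: mua={props.mua:.6f} mm^-1, mus={props.mus:.6f} mm^-1, "
      f"g={props.g}, n={props.n}")

result = run_simulation(LayerStack.homogeneous(props),
                        fx_list=[0.0, 0.1, 0.3, 0.5],
                        n_packets=200_000, seed=1)

print(f"\nlaunched N={result.N}, detected {result.n_detected}")
for fx in result.fx:
    print(f"  fx={fx:4.2f} mm^-1:  Rd = P_V&D(0) = {result.rd(fx):.4f}")
print(f"\nP_V&D(z=20 mm, fx=0) = {result.pvd_at(0.0, 20.0):.2e}  "
      "(3 orders below the surface value: deep tissue barely contributes)")

stats = depth_summary(result)
print("\npercentile sampling depths (mm): fraction X of the detected signal")
print("never travelled deeper than dX")
print(stats.table.round(3).to_string(index=False))
print("\nd50 falls as fx rises: modulated illumination samples more "
      "superficially.")
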