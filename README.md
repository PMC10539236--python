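# vesselprox

Vascular-proximity morphometry for 3D contrast-enhanced micro-CT angiography.

## The problem

In chronic kidney disease (and other microvascular pathologies) capillaries
are lost — *capillary rarefaction* — and the open question is whether the
remaining vessels still reach all of the tissue. Oxygen diffusing from a
capillary supplies tissue only out to roughly 100 µm (the oxygen diffusion
limit; the Krogh cylinder is the classical model of this supply geometry).
The decisive quantity is therefore not vessel density but **the fraction of
organ tissue lying within a distance d of the nearest blood vessel**.

`vesselprox` computes that quantity from micro-CT scans of contrast-perfused
organs, where the vasculature appears bright on a dark background:

1. **Segmentation** — 3D Gaussian smoothing (σ = 1 voxel), a global intensity
   threshold (manual per sample, or Otsu's method on request), and extraction
   of the largest connected component to discard stray contrast agent.
2. **Organ mask** — morphological closing of the vessel network with a
   Euclidean ball (default 50 voxels; at the reference 4.444 µm scan voxel
   size this is a 222.2 µm ball), giving the organ outer shape.
3. **Distance transform** — the exact signed Euclidean distance transform of
   the vessel segment, in µm (positive in tissue, negative inside vessels).
4. **Proximity CDF** — the empirical distribution F(d) = P(distance ≤ d)
   over organ voxels, evaluated at query distances (default 20 µm and
   100 µm). F(100) close to 1 means essentially all tissue is within the
   oxygen diffusion limit.
5. **Group statistics** — per-distance comparison of two groups of samples
   with an unpaired, two-tailed Student's (pooled) t-test.

Because suitable raw scans are rarely shareable, the package ships a
synthetic-phantom generator (parallel Krogh lattices with exact closed-form
coverage fractions, random cylinder networks, branching trees) and a seeded
rarefaction operator that deletes a fraction of vessels, so the entire
pipeline is verifiable against analytic ground truth.

## Worked example

A noiseless Krogh-lattice phantom — parallel 10 µm-radius capillaries on a
100 µm square lattice, enclosed by a thin feeding shell — analysed by the
full pipeline at 2 µm voxels:

```python
from vesselprox import (PhantomSpec, generate_phantom, analyze_volume,
                        SegmentationParams, MorphometryParams)

spec = PhantomSpec(
    "krogh_array", domain_shape_um=(200.0, 448.0, 448.0), voxel_size_um=2.0,
    vessel_radius_um=10.0, spacing_um=100.0, enclosed=True, seed=0,
)
volume, truth = generate_phantom(spec)
profile, vessel, organ, dmap = analyze_volume(
    volume, 110.0, SegmentationParams(sigma_px=1.0), MorphometryParams(),
)
print("vessel volume fraction:", round(truth.vessel_volume_fraction, 4))
for d, f in sorted(profile.evaluations.items()):
    print(f"fraction of tissue within {d:g} um of a vessel: {f:.4f}")
for d, f in sorted(truth.analytic_fraction_within.items()):
    print(f"exact coverage at {d:g} um: {f:.4f}")
```

prints

```
vessel volume fraction: 0.1016
fraction of tissue within 20 um of a vessel: 0.5618
fraction of tissue within 100 um of a vessel: 1.0000
exact coverage at 20 um: 0.5654
exact coverage at 100 um: 1.0000
```

The measured fractions are the pipeline's output; the exact values come from
the phantom's closed-form coverage geometry. At 20 µm the pipeline is within
0.004 of the exact fraction; at 100 µm the whole tissue is covered — for this
lattice no tissue point is farther than 50·√2 − 10 ≈ 60.7 µm from a vessel
surface, so everything lies within the diffusion limit.

Real scans are analysed the same way from the shell, driven by a JSON/YAML
config listing TIFF stacks, voxel sizes, thresholds and group labels:

```sh
vesselprox analyze config.yaml            # segment → mask → CDF → t-tests
vesselprox distances stack_dir/ --voxel-size-um 4.444 --threshold otsu -o p.json
vesselprox phantom spec.yaml -o stack/    # generate synthetic fixtures
vesselprox compare p1.json p2.json ... --group s1=CTL --group s2=POD
```

Outputs are per-sample profile JSONs, a tidy `samples.csv`, a
`comparisons.json` with t, df and p per query distance, and a `manifest.json`
recording every parameter, seed and per-stage voxel count of the run.

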