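# armsim

Simulation pipeline for surface-electrode electrical stimulation (tDCS/tACS)
of a layered limb, built end to end from serial grayscale sections:

1. **`armsim.phantom`** — parametric five-tissue limb phantom (skin, fat,
   muscle, cortical bone, marrow; tapered, eccentric bone) voxelized to a
   ground-truth label volume and rendered into a noisy 16-bit grayscale slice
   stack.
2. **`armsim.segmentation`** — gray-threshold segmentation by the splitting
   method: threshold the whole stack, then Boolean-strip tissues layer by
   layer from skin to marrow (largest-component + hole-fill cleaning), and
   extract per-tissue boundary point clouds.
3. **`armsim.reconstruction`** — statistical point-cloud cleaning, watertight
   occupancy-isosurface reconstruction with volume-preserving smoothing,
   solidification back to a conforming label volume (innermost surface wins),
   and minimum-thickness compensation for thin layers (skin ≥ 1 mm).
4. **`armsim.meshing`** — Kuhn (6-tet, diagonal-consistent) decomposition of
   the label volume into a tagged conforming tetrahedral mesh with quality
   reporting and legacy-VTK export.
5. **`armsim.solver`** — quasi-static complex-conductivity P1 FEM:
   ∇·(−σ̃∇φ) ≈ 0 with σ̃ = σ + iωε₀εᵣ, impressed-current patch electrodes
   (20 × 20 mm default, I ≤ 20 mA), insulating exterior, phasor and transient
   (BDF2 backward-difference) modes, and a four-point σ/εᵣ dispersion table
   per tissue (1 kHz – 1 MHz, log-log interpolated).
6. **`armsim.postprocess`** — contact-potential traces, |J| line profiles
   along the inter-electrode center line, effective stimulation depth at a
   current-density threshold (default 10 A/m²), percent-excess comparison
   metrics, and planar section sampling.
7. **`armsim.oracles`** — closed-form references used to verify the solver:
   1-D layered slab, two-layer disk with arc electrodes (Fourier series), and
   a homogeneous box with patch electrodes (double cosine series).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equivalence,
conservation/symmetry, transient–phasor consistency, pipeline recovery,
DC/AC qualitative ordering). The full suite performs several large sparse
factorizations and takes ~10–15 minutes on one CPU; the non-acceptance tests
alone finish in about two minutes.

## CLI

Each stage is a subcommand; `run` chains them with one YAML config and writes
a JSON manifest (config hash, seed, versions, per-stage outputs, key metrics):

```sh
armsim phantom --spec spec.yaml --out out/phantom --seed 1
armsim segment --stack out/phantom/stack --thresholds t.yaml --out out/seg
armsim reconstruct --labels out/seg/segmented.npz --skin-min-thickness 1.0 --out out/recon
armsim mesh --labels out/recon/solid.npz --out out/mesh.vtk
armsim run --config run.yaml --out out/run            # full pipeline
armsim run --config run.yaml --stages phantom --out out/run
```

With no config, `armsim run --out DIR` uses the built-in default phantom
(48 × 48 × 96 voxels at 1 mm) and a 10 mA DC + 10 mA/1 kHz AC protocol pair
sharing 20 × 20 mm electrodes on opposite sides of the limb; the manifest
reports the DC contact potential, AC steady amplitude, effective depths and
percent-excess metrics.
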