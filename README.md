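# aznano

Multi-level density clustering and spatial statistics for two-channel
single-molecule localization microscopy (SMLM/*d*STORM) of presynaptic
active zones.

## The problem

At the *Drosophila* neuromuscular junction, the scaffold protein Bruchpilot
(Brp) marks individual presynaptic active zones (AZs), and proteins such as
RIM organize beneath it into nanometre-scale subclusters. Two-channel
*d*STORM resolves this organisation as two localization point clouds: a
scaffold channel whose density clusters delimit AZs, and a target channel
whose sub-structure carries the biology — how many nanoclusters per AZ,
how large, how dense, at what radial distance from the AZ centre, and how
they group into higher-order assemblies.

`aznano` implements that analysis as a reusable, tested pipeline for
people who work with localization tables (rapidSTORM-style CSV/TSV
exports) and need per-cluster and per-AZ statistics rather than images:

1. **Scaffold (AZ) extraction** — HDBSCAN over the Brp channel
   (minimum cluster size 100, minimum samples 25); per cluster the centre
   of mass, 2-D alpha-shape area (α = 800 nm², squared-circumradius
   convention), and circularity 4πA/P²; clusters with area ≤ 0.03 µm² or
   ≥ 0.3 µm² are excluded, and a circularity ≥ 0.6 gate selects
   planar-view AZs.
2. **Target-channel denoising** — either the two-channel rule (discard
   every target localization farther than 20 nm from retained scaffold
   signal) or a single-channel first-pass HDBSCAN (20/5; unclustered
   points are noise), which additionally exposes extrasynaptic signal.
3. **Subcluster (SC) extraction** — HDBSCAN (2/2) over the denoised
   target channel; per SC the c.o.m., alpha-shape area (α = 300 nm²),
   localization density, and equivalent radius √(A/π). Each SC is
   assigned to the scaffold cluster with the nearest localization; its
   *radial distance* is the SC-c.o.m.–to–AZ-c.o.m. distance. SCs are
   classified intrasynaptic (≤ 50 nm to scaffold signal), in AZ vicinity
   (> 50 and ≤ 400 nm at circular AZs) or extrasynaptic.
4. **Superclusters (SpCs)** — HDBSCAN (2/2, leaf selection) over the SC
   centres of mass of each circular AZ.
5. **Ripley statistics** — the uncorrected estimator
   K̂(r) = A/(n(n−1)) · Σ_{i≠j} 1(d_ij ≤ r) and its transform
   H(r) = √(K̂(r)/π) − r, evaluated from 0 to 120 nm in 1-nm steps and
   averaged (mean ± SD) over per-AZ localization groups; H ≡ 0 under
   complete spatial randomness and the maximum of the averaged curve
   reads out the dominant cluster-radius scale.
6. **Molecule estimates** — localization counts × 0.134, the
   molecules-per-localization conversion factor for these imaging
   conditions.

Because such datasets are rarely public, the package ships a **synthetic
scene generator** (`aznano.synthgen`) that emulates the assumed structure
— annular scaffold clusters of ring radius 186.3 nm, ~10 SCs per AZ of
1–2 molecules at ~120 nm radial distance, geometric blinking with
p = 0.134 (mean 1/p ≈ 7.5 localizations per molecule), extrasynaptic SC
sites, and uniform background — with a full ground-truth record, so every
stage is testable by parameter recovery.

## Worked example

```python
from aznano import (SceneConfig, PipelineConfig, generate_scene,
                    run_two_channel, recover_parameters)

scene = SceneConfig(seed=1)                  # 20 AZs, default conditions
brp, rim, truth = generate_scene(scene)
bundle = run_two_channel(PipelineConfig(seed=1), brp, rim)

s = bundle.summary_table
print(s[s.metric.isin(["az_n_sc", "az_mean_radial_nm", "az_circularity",
                       "az_area_um2", "sc_n_locs", "sc_area_nm2"])]
      .to_string(index=False))
report = recover_parameters(bundle, truth)
print(report.table.to_string(index=False))
print(f"AZ detection rate: {report.az_detection_rate:.2f}")
```

prints (medians with 25th–75th percentiles):

```
           metric                scope   n     median        q25        q75
        sc_n_locs     intrasynaptic SC 514   3.000000   2.000000   4.000000
      sc_area_nm2     intrasynaptic SC 264   9.589668   3.271641  31.840400
          az_n_sc                   AZ  20  25.500000  16.500000  30.000000
az_mean_radial_nm                   AZ  20 124.833452 120.965756 129.180722
   az_circularity                   AZ  20   0.842419   0.809166   0.866422
      az_area_um2                   AZ  20   0.207945   0.207320   0.209519
...
              parameter  generative  recovered  relative_error
               az_count   20.000000  20.000000        0.000000
        sc_count_per_az    9.000000  25.500000        1.833333
     radial_distance_nm  120.006049 124.833452        0.040226
sc_equivalent_radius_nm         NaN   1.747133             NaN
AZ detection rate: 1.00
```

Reading this: all 20 generated AZs are detected, with alpha-shape areas
(~0.21 µm²) inside the retention gate and circularity ~0.84 (planar
view); the median per-AZ radial distance recovers the generative 120 nm
to 4%. The SC count per AZ (25.5 recovered vs 10 generated) illustrates a
documented property of excess-of-mass HDBSCAN at minimum cluster size 2:
iid localization blobs are carved into ~3-localization fragments, so the
recovered "SC" is a blink-packet-scale unit rather than the generative
molecule cluster — see `docs/methods.md` for the analysis.

The same workflow is available from the shell:

```sh
aznano simulate --seed 1 --out scene/
aznano run-two-channel --brp scene/brp.csv --rim scene/rim.csv \
       --x-column x --y-column y --out results/
```

writing `sc_table.csv`, `az_table.csv`, `spc_table.csv`, `hcurve.csv`,
`nnd.csv`, `summary.csv` and `run_meta.toml`.

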