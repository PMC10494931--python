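# Methods

This note documents the models, parameters and numerical choices behind
`aznano`, and what the synthetic-data tests do and do not establish.

## Analysis pipeline

### Clustering backend

All three clustering levels use HDBSCAN (scikit-learn's implementation)
with the stage-specific parameter sets given below. The backend is
injectable everywhere (`backend=` argument): any callable mapping a point
array and a `ClusterParams` to integer labels (−1 = noise) can stand in,
which the test suite uses to drive the pure bookkeeping logic with
constructed labelings. Cluster labels are renumbered by order of first
appearance, so ids are deterministic in the input row order.

| stage | min cluster size | min samples | selection |
|---|---|---|---|
| scaffold (AZ) extraction | 100 | 25 | excess-of-mass |
| single-channel denoising (first pass) | 20 | 5 | excess-of-mass |
| subcluster (SC) extraction | 2 | 2 | excess-of-mass |
| supercluster (SpC) extraction | 2 | 2 | leaf |

Two properties of HDBSCAN shape what the pipeline can measure:

* **No lone cluster.** With the default (and here deliberately unchanged)
  `allow_single_cluster=False` behaviour, a field containing a single
  density blob yields no cluster at all: the root of the hierarchy is
  never selected. Consequently an analysis of one isolated AZ needs at
  least one other cluster in the field.
* **Over-segmentation at minimum cluster size 2.** With
  `min_cluster_size = 2`, excess-of-mass selection carves an iid point
  blob of n ≳ 6 into fragments of median size ~3, independent of the
  blob's spatial scale (pairs of mutually close points are always valid,
  often more stable children). The "SC" this stage recovers is therefore
  a blink-packet-scale unit: on synthetic molecule clusters carrying ~11
  localizations each, the pipeline reports ~2.5× as many SCs, each with
  ~3 localizations and correspondingly small alpha-shape areas. Radial
  distances are unaffected (fragments inherit their parent's position),
  and both denoising routes fragment identically, so route agreement and
  all distance-based statistics remain meaningful. Users comparing SC
  counts or areas between experimental groups are comparing
  fragmentation-scale quantities — consistent within a fixed parameter
  set, but not counts of underlying molecule clusters.

### Geometry

Cluster areas use the 2-D alpha complex: the sub-complex of the Delaunay
triangulation whose triangles have squared circumradius ≤ α, with α in
nm² (800 nm² for scaffold clusters, 300 nm² for SCs). Area is the total
area of kept triangles (holes excluded); perimeter is the length of the
complex boundary, hole rings included. Inputs with fewer than three
non-collinear points, or where no triangle survives, are flagged
degenerate with area 0 (never raised); degenerate SCs are excluded from
area and density statistics but keep their localization counts.

**Circularity** is the isoperimetric ratio 4πA/P², clamped to [0, 1]. The
default (`mode="outline"`) evaluates it on the exterior outline of the
alpha complex with holes filled. This choice is deliberate: a planar-view
scaffold ring is annular, and including its hole boundary in P would give
every ring t/2R ≈ 0.2 ≪ 0.6 and defeat the purpose of the gate, which is
to separate round (planar-view) from elongated (side-view) clusters by
their outline. `mode="boundary"` (total area over total alpha-boundary
perimeter) is available for convex or simply connected shapes, where the
two coincide.

Equivalent radius is √(A/π) — the radius of the circle of equal area.

### Distances, assignment, classification

SC-to-scaffold assignment minimises the distance from the SC c.o.m. to
the nearest member localization of each scaffold cluster (ties resolve to
the lowest AZ id). Radial distance is the Euclidean SC-c.o.m.–to–AZ-c.o.m.
distance; the per-AZ value is the mean over assigned intrasynaptic SCs.
Classification thresholds are inclusive exactly as follows: intrasynaptic
d ≤ 50 nm; vicinity 50 < d ≤ 400 nm *and* parent-AZ circularity ≥ 0.6;
extrasynaptic-far otherwise. The scaffold area gate excludes clusters
with A ≤ 0.03 µm² or A ≥ 0.3 µm² (both bounds inclusive); SCs assigned to
excluded scaffolds are excluded from all statistics.

### Ripley K and H

The estimator is the plain pair count without edge correction,
K̂(r) = A/(n(n−1)) · Σ_{i≠j} 1(d_ij ≤ r), evaluated on the inclusive grid
0…120 nm in 1-nm steps, and H(r) = √(K̂/π) − r, whose reference under
complete spatial randomness (CSR) is the zero line. Choices worth noting:

* **Normalisation** n(n−1) (unbiased pair count); alternatives using n²
  differ by (n−1)/n, negligible at the n of interest.
* **Study area.** Per-cluster window area defaults to the axis-aligned
  bounding box of the cluster's points (`"hull"` selects the convex hull
  instead). The H amplitude is sensitive to this; the argmax position is
  much less so.
* **Edge effects.** Without correction, CSR expectation on an L × L
  square is exactly E[K̂](r) = πr² − 8r³/(3L) + r⁴/(2L²); the deficit is
  a real property of the estimator (pinned by a unit test against this
  closed form). For null-calibration simulations, `ripley_k` accepts a
  `period=` argument that computes toroidal distances, removing the
  deficit without touching the estimator; the analysis pipeline itself
  never uses it.
* **Averaging.** `aggregate_h` averages per-cluster H curves (mean ± SD,
  sample SD), mirroring how such curves are reported. For CSR
  calibration, averaging square roots of small counts is biased
  (Jensen); the calibration test therefore transforms the pooled mean K̂
  once and propagates the SE by the delta method.
* **Radius readout.** `estimate_radius` returns the radius at the
  maximum of the mean curve (ties → smallest radius; all-nonpositive
  curves → NaN; a boundary maximum at r = 0 is flagged). The argmax of
  uncorrected H is *not* an unbiased cluster-radius estimator: for
  uniform-disk clusters of radius R embedded in AZ-scale windows it sits
  near the pair-distance saturation scale ≈ 1.7–1.9 R, and for Gaussian
  clusters near ~3σ. Synthetic disks of radius 6 nm read out at ~11 nm.
  The readout is a *scale*, comparable across conditions measured the
  same way, not a calibrated radius.

### Pipeline conventions

The H function is aggregated over denoised target localizations grouped
per retained circular AZ (nearest-scaffold membership, capped at the
400-nm vicinity radius so the single-channel route's extrasynaptic signal
does not distort windows). Summary tables report median
(25th–75th percentile) with linear interpolation of percentiles;
histograms normalise counts to a total of 1. Molecule estimates multiply
localization counts by 0.134 (so a 6-localization cluster reports ~0.8,
i.e. ~1 molecule). Per-AZ totals (SC count, localizations, summed SC
area) are recomputed from member SCs and asserted equal on every run.
Outputs are deterministic: identical inputs and configuration produce
byte-identical CSV tables.

## Synthetic scenes

`generate_scene` builds a two-channel scene with a full generative record:

* **AZ layout** — centres on a jittered grid guaranteeing pairwise
  separation > 2·(ring radius + max radial distance), so assignment is
  unambiguous.
* **Scaffold channel** — per AZ, a Poisson(1200, min 300) number of
  localizations uniform by area on an annulus of ring radius 186.3 nm and
  thickness 180 nm, plus Gaussian localization jitter. The thickness is
  chosen for coherence of the whole workflow: target SCs at ~120 nm
  radial distance must lie within 20 nm of scaffold signal or the
  two-channel denoising rule would delete them — as in real preparations,
  where the scaffold's labelled epitope cloud extends well inside the
  nominal ring. The resulting alpha-shape area (~0.21 µm²) falls inside
  the 0.03–0.3 µm² retention gate, and the annular outline passes the
  circularity gate.
* **Target channel** — per SC, 1–2 molecules placed with 4 nm Gaussian
  spread about the SC centre; SC centres at truncated-normal radial
  distance (mean 120 nm, SD 30 nm, bounds 30–180 nm) in uniform
  directions, Poisson(10, min 1) SCs per AZ. Blinking is
  geometric-with-minimum-1: each molecule emits k ~ Geom(p = 0.134)
  localizations (mean 1/p ≈ 7.5), the simplest memoryless model whose
  molecules-per-localization ratio equals the 0.134 conversion factor.
  Each localization adds isotropic Gaussian error of SD 8 nm, a typical
  far-red dSTORM lateral precision (the precision is a config field, not
  a measured value).
* **Extrasynaptic SCs** — same molecule counts at 2× spread, laid out in
  sites of three nearby SCs placed uniformly outside all AZ disks; a site
  (~30 localizations) can survive a min-cluster-size-20 first pass, which
  an isolated ~7-localization SC by construction cannot.
* **Background** — uniform, 20 µm⁻² per channel.

Every localization is attributable to exactly one source (scaffold ring,
SC molecule, background) through bookkeeping columns, and conservation
against the truth record is tested.

**What the synthetic tests show** — estimator correctness against
independent oracles, boundary-exact gate behaviour, determinism, blink
calibration, 100% AZ detection and ~4% radial-distance recovery under
realistic noise, and agreement of the two denoising routes within a few
percent. **What they do not show** — that recovered SC counts and areas
equal generative molecule-cluster counts and footprints (they measure
fragmentation-scale units, see above), nor anything about features real
data have and the generator lacks: drift and registration error,
correlated multi-emitter localizations, anisotropic precision,
heterogeneous labelling efficiency, and tissue-scale background
structure.

## Known limitations

* 2-D only; any z column in inputs is ignored.
* The SC stage's minimum cluster size of 2 makes SC counts and areas
  fragmentation-scale quantities (documented above) — meaningful for
  within-pipeline comparisons, not as absolute molecule-cluster counts.
* The H-curve peak is a relative scale, biased high as a radius estimate.
* The uncorrected K estimator underestimates K near window boundaries;
  with 120-nm radii on micrometre windows the effect on per-AZ curves is
  a few percent, identical across conditions.
* Supercluster extraction inherits HDBSCAN's inability to report a
  single cluster spanning all inputs; AZs whose SC c.o.m.s form one
  uniform group report zero SpCs and are counted as "no SpC detected".
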