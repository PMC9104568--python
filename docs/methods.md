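# Methods

## Monitoring model

A campaign is a weekly cycle of probe readings on a fixed grid over up to
six static-pile reactors. Each pile is described by a `PileSpec` (length,
width, height, three probing heights H1 < H2 < H3, sidewall flag, number of
cycles and cross-sections). The packaged default configuration encodes the
six-pile design this package was built around: four cross-sections at 2.5,
17.5, 32.5 and 47.5 m from the aeration fan, seven points per cross-section
(H1/H2/H3 on both flanks plus one deep centerline point), weekly cycles —
280 campaign points for pile A1 and 1288 over all six piles.

### Coordinates and probe tips

`x` runs along the pile axis from the fan, `y` across the pile with the
centerline at 0 (left flank negative, facing away from the fan), `z` above
ground. Field protocols record probe *entry* heights and a minimum insertion
depth (1.25 m), not tip positions, so tip placement is a convention:

* horizontal insertion: tip = entry point moved `insertion_depth_m` inward
  along a horizontal axis, i.e. `|y| = half_width(z) − depth`;
* H1 on sidewall piles is inserted at 45° over the wall to avoid it: the tip
  keeps `z = H1` and sits `depth/√2 ≈ 0.88 m` inboard of the wall plane
  (entry at `z = H1 + depth/√2` on the wall plane);
* deep probes sit on the centerline at mid height (H2).

Every generated tip is verified strictly inside the cross-section outline;
an infeasible insertion is a hard error naming the offending location.

### Outlines and zones

Membrane piles are isosceles trapezoids (apex width 0.25 × base width by
default — the true membrane shape is not documented; nothing downstream is
sensitive to it). Sidewall piles rise vertically to a wall at 0.6 × height
(configurable) then slope to the same apex. Three aeration channels sit
evenly spaced on the base by default.

Zone labels form the controlled vocabulary `{center, bottom, top, left,
right, near-sidewall}`: deep probes → center, H1 → bottom, H3 → top, flank →
left/right. On sidewall piles a tip within `near_wall_margin_m` of the wall
plane adds `near-sidewall`; the default margin is **1.0 m** because the 45°
H1 insertion geometrically pins those tips 0.88 m off the wall — they are
the probes that wall-adjacent cold zones are reported against, so the margin
must cover that standoff.

## Field reconstruction

Cross-sections use **natural-neighbor (Sibson) interpolation**: the value at
a query point is `Σ wᵢ vᵢ` where `wᵢ` is the fraction of the query's
prospective Voronoi cell stolen from site i's cell. Weights are computed
geometrically by half-plane clipping (each cell is an intersection of
bisector half-planes); the clip box is grown adaptively because a query
barely inside the site hull owns a bounded but very elongated cell. The
interpolant is exact at sites, its weights are nonnegative and sum to one,
so reconstructed fields never leave the data range — the right behavior for
bounded gas concentrations. Exact duplicate sites are collapsed when their
values agree (and are an error otherwise). Queries outside the site hull
have no Sibson coordinates; the ambient boundary ring normally guarantees
hull coverage of the outline, and any residual exterior query falls back to
the nearest site with a logged warning rather than extrapolating.

Longitudinal sections use **RBF interpolation** (multiquadric
`√(r² + c²)` by default; thin-plate and Gaussian available) augmented with a
linear polynomial under the side conditions `Pᵀw = 0`, so constant and
affine fields are reproduced exactly. The shape parameter defaults to the
mean nearest-neighbor site spacing; the source tool's settings are not
published, so both kernel and shape are exposed as configuration. Fewer than
three (or collinear) sites drop the polynomial to a constant term. Duplicate
sites are a hard error; a system conditioned worse than 1e12 gets a small
diagonal ridge with a logged warning. RBF can overshoot, so reconstructed
gas fields are clamped to physical bounds post hoc (clamp events logged).

Boundary conditions: 24 points (default) evenly spaced along the outline
carry the composition of atmospheric air (O₂ 20.9 %, CO₂ 0.04 %, CO 0 ppm —
ambient CO/CO₂ read as zero on the analyzer scale) and the outside
temperature of the day; the three channel positions carry channel
measurements when available, else the forced-air (ambient) values.
Longitudinal sections put ambient points along the top and both ends and
channel values along the base. Grids default to 0.1 m cells (cross-sections
≈ 80 × 25 nodes, longitudinal ≈ 500 × 25); grids are written as ESRI ASCII
rasters with the outline mask as NODATA. Cycles are reconstructed
independently — no temporal interpolation between weekly measurements.

## Spot classification and inventory

Thresholds are strict inequalities (`>60`, `<15`, `>5` read literally;
non-strict mode is available): equality at a threshold does not trigger.
Detection groups one pile-day's records by cross-section distance; any
triggering probe yields exactly one `SpotRecord` of its type per distance,
with zones the union of the triggering probes' labels. The counting unit is
the (pile, day, distance) occurrence because the campaign totals the package
reproduces equal the number of distance entries in the source inventory, not
row or probe counts. Records missing any criterion variable are rejected
before detection; a record missing only CO is kept, since CO is not a
criterion variable.

Cold-spot **exclusion windows** are data, not hard-code: the default
configuration ships (A1, cold, days 1–16) and (A2, cold, days 1–16), because
those two lightly loaded, heavily aerated piles sat near ambient for their
first three weeks and the cold criterion would fire everywhere.

`field_spot_regions` generalizes the point criteria to reconstructed grids:
per-node classification, 8-connected component labeling (scikit-image), and
a minimum-area filter (default 0.05 m²) to suppress single-node slivers.
This continuous-field localization is a convenience for visualization; the
inventory itself is defined at probe granularity.

The packaged campaign spot tables are shipped as a checksum-guarded CSV
fixture; enumerating them reproduces per-pile totals hot = 6/3/18/8/1/3 and
cold = 5/11/2/5/8/12 for A1/A2/B1/B2/C1/C2. The B1 hot total enumerates to
18 although the accompanying narrative states 16; the discrepancy is in the
source material and the fixture follows the table enumeration.

## Synthetic campaigns

The generator emulates the qualitative dynamics the analysis assumes; it is
deliberately phenomenological, not a heat/mass-transfer PDE model.

* **Temperature**: ambient through an optional lag; then a logistic rise
  (rate 0.35–0.6 d⁻¹, midpoint ~4–7 d after lag end) to a plateau; after
  `cooling_start_day`, exponential relaxation toward ambient. A basal
  cooling deficit `activity · strength_C · exp(−z/depth_scale)` (defaults
  0.6 m scale, 4–10 °C strength) represents forced-air chilling above the
  channels; scaling by momentary activity keeps a dormant pile exactly at
  ambient.
* **Gases**: O₂ = clamp(20.9 − k·max(0, T − T_amb)) with k = 0.25 %/°C;
  CO₂ = 0.7 × (O₂ depleted), so `o2 + co2/0.7 = 20.9` identically — the
  inverse O₂/CO₂ coupling of aerobic decomposition. CO grows exponentially
  with temperature (0.06 °C⁻¹), scaled to 1800 ppm at 75 °C and zero at
  ambient. The true coupling strengths are not quantified anywhere usable,
  so these are free parameters documented as such, with the CO anchor the
  one fixed calibration point.
* **Anomalies**: `SpotInjection` adds per-variable deltas with a Gaussian
  kernel `exp(−½ d²/r²)` (3-D distance from the center) over an inclusive
  day range. Injection centers must lie inside the pile volume.
* **Noise and quantization**: independent Gaussian noise per variable,
  truncated to physical bounds (instrument precision is stated, an error
  model is not — independent Gaussians are the minimal choice), then
  quantization to instrument resolution (1 °C, 0.1 % gas, 1 ppm CO).
* **Ground truth** is the inventory obtained by applying the spot criteria
  to the noise-free, quantized signal at probe locations — independent of
  noise realization and of all interpolation settings by construction.

Presets: `A-type` (two-week lag, 62 °C plateau, strong basal cooling —
lightly loaded, heavily aerated), `B-type` (no lag, 65 °C plateau), `quiet`
(45 °C plateau, slow cooling at 0.02 d⁻¹ so a full 10-cycle campaign stays
clear of the 30 °C cold threshold — a spot-free background for injection
studies). Presets are illustrative, not fits.

What passing synthetic tests does **not** show: real piles have
heterogeneous waste, drifting ambient conditions, spatially correlated
errors and anomalies that do not sit on probe tips. Recovery being exact in
noise-free simulation validates the pipeline's bookkeeping, not field
sensitivity.

## Numerical choices and problem sizes

* Sibson weights: clip box grown ×8 per step (max 40 steps) until the query
  cell closes; coincident query/site (< 1e-9) short-circuits to unit weight.
* RBF: condition threshold 1e12, ridge 1e-10 × max kernel entry.
* Tests and the acceptance script run randomized interpolation batteries on
  5–12-site configurations (100 configs in tests, 50 in the script), the
  noise-recovery sweep at temperature SDs {0, 2, 5, 10} °C with 50 seeds
  each on a single 10-cycle pile, and CLI field reconstruction at 0.5 m
  cells — sizes chosen so the whole suite completes in well under a minute
  while still exercising every code path; production use at 0.1 m cells is
  the default in the library API.

## Known limitations

* Natural-neighbor weight computation is O(n²) per query in pure Python —
  fine for monitoring grids (≤ ~60 sites), not for thousands of sites.
* The ESRI ASCII format carries no variable/plane metadata; round-trips
  preserve values and mask only.
* Longitudinal sections use the full-height rectangle as domain rather than
  a tapered end profile; end tapering is below the resolution of a 4-probe
  axis anyway.
* Channel boundary records are matched to channel positions by order, not
  by an explicit channel id.
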