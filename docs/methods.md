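# Methods

## Scope and model

`nervestereo` quantifies myelinated fibers in a transverse nerve section
the way design-based stereology prescribes: unbiased counts come from the
sampling *design* (systematic fields with a random offset, an
edge-effect-free counting rule), not from assumptions about fiber shape or
size.  The package works on an idealized but explicit geometric model:

- a nerve cross-section is a disk of radius `R` (default 160 µm);
- a myelinated fiber is two concentric disks: the axon (diameter `d`)
  inside its myelin sheath (outer fiber diameter `D = d/g`, with g-ratio
  `g = d/D ∈ (0,1)`);
- fibers lie wholly inside the nerve and never overlap.

All lengths are micrometres; coordinates are Cartesian with the origin at
the nerve center and y increasing upward.  Geometry is continuous;
rasterization exists only for visualization.

## Synthetic populations

Two phenotypes with configurable distributions (defaults in parentheses):

| parameter | control | regenerated (25 d post-crush) |
|---|---|---|
| axon diameter d | lognormal, median 3.5 µm, σ_log 0.35 | lognormal, median 2.2 µm, σ_log 0.35 |
| g-ratio | Normal(0.65, 0.05) truncated to (0.4, 0.85) | Normal(0.75, 0.05) truncated to (0.4, 0.95) |
| fiber count | 1200 | 1200 (regeneration restores the count) |
| sub-resolution tail | 15% of fibers, d lognormal median 0.35 µm, σ_log 0.2 | same |

The regenerated phenotype therefore has smaller axons, smaller fibers and
thinner myelin (its higher g means proportionally less myelin), while both
total count and the sub-resolution share match the control.  The equal
sub-resolution share is deliberate: both phenotypes show the same totals
under EM *and* under LM (only the LM-vs-EM gap within each nerve is
systematic), so the share of fibers below the LM limit must be comparable
across groups.  Unequal shares would turn the LM group comparison into a
significant difference, which is not what regenerated nerves at this
time point show.  All fractions remain configurable for studying that
regime.

Sections are packed by random sequential adsorption: diameters are drawn
first, sorted descending, and placed largest-first at uniform random
centers inside the region where the whole fiber fits, rejecting overlaps
(at most 10,000 candidate draws per fiber).  A population whose summed
disk area exceeds 0.55 of the nerve area is refused up front
(`PackingError`); the defaults pack at ≈ 0.40, where RSA converges
quickly and the resulting point pattern has the strong hard-core
regularity (variance well below Poisson) that real fiber mosaics show.
The default radius of 160 µm puts the default populations at a fiber
density of ~1.5×10⁴/mm², in the range of rodent nerve.

Cohorts pair a control and a regenerated section per animal through a
shared lognormal size multiplier (σ = 0.05) applied to all diameter
scales *and* to the nerve radius — a larger animal has a uniformly larger
nerve, and scaling both keeps the packing fraction constant.  The shared
multiplier gives the within-animal correlation that justifies paired
testing.

What the generator does *not* emulate: non-circular profiles,
unmyelinated axons, Schwann-cell nuclei and other structures that risk
misidentification, staining artifacts, or spatial trends in fiber size
across the fascicle.  Passing tests therefore validate the sampling and
estimation machinery on clean geometry; they do not certify segmentation
or identification performance on real micrographs.

## Sampling design

Fields are placed by systematic uniform random sampling.  Three details
matter for unbiasedness and were chosen with care:

1. **The grid spacing is a deterministic function of the design and the
   nerve geometry** — the largest spacing (never below the field size, so
   fields stay disjoint) at which *every* grid phase yields at least
   `n_fields` candidates intersecting the nerve (verified over a 33×33
   and a 64×64 phase grid).  The random offset is then drawn
   unconditionally.  Selecting a spacing conditional on the drawn offset
   (e.g. "shrink and redraw until enough fields intersect") skews the
   accepted grid phases and was measured to distort the local inclusion
   probability by up to a factor of ~3; fixing the spacing first removes
   the effect.  In the rare case where the realized offset still falls one
   candidate short (the phase grid is finite), the spacing shrinks by 3%
   and the *same* uniform fraction is reused — no redraw, no selection.
2. **Serpentine enumeration starts at a seed-randomized corner.**  The
   first `n_fields` intersecting candidates are used; surplus candidates
   are dropped at the end of the scan.  With a fixed scan origin the
   dropped fields always sit on the same side of the nerve, which
   produced a measurable (+1%) bias in pilot runs; randomizing the scan
   orientation restores the symmetry.
3. **Frames are never clipped, but the density denominator uses each
   frame's *reference area* — the part of the frame inside the nerve**
   (equal to the full frame area for interior frames, the common case).
   With counts `c_i` and reference areas `a_i`, `E[Σc] = N·p` and
   `E[Σa] = A_nerve·p` for the same coverage probability `p`, so the
   ratio estimate `N̂ = A_nerve·Σc/Σa` is unbiased up to a ratio-estimator
   term of order 1/n_fields.  Using raw frame areas instead would count
   empty space outside the nerve in the denominator and bias the total
   downward by the mean overhang fraction (tens of percent for a small
   nerve).  Circle/disk overlap areas are closed-form (lens formula);
   rectangle/disk overlaps of boundary-straddling EM screens use polygon
   clipping.

Default designs: LM — 15 fields of 60 × 60 µm (a typical 100× camera
field), two circular frames of radius 15 µm per field (the largest pair of
disjoint circles that fits); EM — 150 screens of 12.2 × 16.2 µm.  The
efforts were set from pilot variance runs to put the coefficient of error
of the total estimate near 3–4% for LM and below that for EM (EM is the
reference modality), the precision band stereological practice targets by
counting a few hundred events per subject.  All design parameters are
configurable; LM field counts outside 10–15 are unusual in practice.

## Counting rule

The top of a fiber is the topmost point of its outer disk at LM (what a
toluidine-blue profile shows) and of its axon at EM; both are unique
points of concentric disks, so the two conventions sample fibers with
identical probability under uniform placement.  Inclusion is
strict-interior for circular frames and half-open
`[x_min, x_max) × [y_min, y_max)` for rectangles: boundaries carry zero
probability under continuous placement, and half-openness makes a
rectangular tiling an exact partition — tiling the bounding box counts
every fiber exactly once, which the tests assert verbatim.  Ties are
impossible for disks (a unique maximum).  Fibers sampled by frames of
more than one field (possible only if fields overlap, which default
designs exclude) are flagged in the result.

## Estimation

Density pools counts over frames as a ratio of sums, `Σc/Σa` (in
fibers/mm²; 1 mm² = 10⁶ µm²) — the natural pooled estimator for a
systematic design, identical to the mean of per-frame ratios when frames
are congruent.  The total is `density × nerve cross-sectional area`,
real-valued, with rounding left to report time.  The EM total reuses the
section's (LM-measured) nerve area, as the modality never images the
whole nerve.  No coefficient-of-error machinery is included beyond the
retained per-frame counts.

## Detection model

LM resolvability is a hard threshold on the axon diameter, default
0.5 µm — the diffraction scale of oil-immersion light optics, and the
criterion consistent with how the sub-resolution tail is defined
(myelinated profiles are identified by their axon lumen).  A threshold on
the outer fiber diameter, or a logistic soft model (midpoint + slope,
seeded Bernoulli thinning), can be configured instead; EM defaults to
threshold 0 (resolves everything).  The filter is applied *before*
sampling: the observer never sees undetectable fibers, so LM estimates
are unbiased for the LM-visible population and systematically below EM
estimates of the same nerve — the mechanism behind the LM-vs-EM gap.

## Statistics

Two-tailed paired Student t-test: `t = mean(Δ)/(sd(Δ)/√n)` with the
sample SD (n−1), df = n−1, p from the Student t distribution.  Tiers use
inclusive cutoffs (\* ≤ 0.05, \*\* ≤ 0.01, \*\*\* ≤ 0.001).  Degenerate
cases are explicit: all differences zero → t = 0, p = 1; all differences
equal and nonzero → p = 0 with a degenerate-variance flag.  No
multiple-comparison correction is applied.  Group summaries report
mean ± sample SD; a singleton group reports SD 0 with a flag.  The
g-ratio is computed as d/D (the convention under which g ∈ (0,1); the
inverse D/d convention sometimes seen in print is available as a switch).

## Numerical and reproducibility choices

- One master seed derives all stage seeds via SHA-256 of
  `"{seed}:{stage-name}"`, truncated below 2³¹; identical configs produce
  byte-identical outputs.
- Fiber tables round-trip losslessly (shortest-roundtrip float printing,
  `float_precision="round_trip"` parsing).
- Disk disjointness and boundary containment are validated with 10⁻⁹ µm
  slack; morphometry round-trips d and D to 10⁻⁹ relative.
- Distribution draws are rejection-resampled into their supports (d > 0,
  g strictly inside (0,1) and any configured truncation bounds), with a
  bounded number of rounds.
- The worst-case spacing search is cached per (radius, field, n_fields);
  the radius is quantized downward in units of field-size/16, which
  preserves the worst-case guarantee (a smaller disk never gains
  candidates) and keeps the design equivariant under global rescaling.

## Problem sizes used in validation

The test and acceptance runs use: 1000 systematic placements on a fixed
1200-fiber section for estimator bias (acceptance bound: within 2% of
truth); 50 sections × 20 random frames for oracle equivalence (exact);
100 sections for tiling exactness (exact); 100 paired LM/EM runs for the
undercount direction (≥ 95% LM < EM); 50 five-animal cohorts for the
significance rates (≥ 80%); 10,000 null simulations for the t-test's
type-I error (0.05 ± 0.01).

## Known limitations

- Estimates refer to the detectable population of the chosen modality;
  no correction is attempted for fibers below the detection limit.
- The ratio estimator carries a small O(1/n_fields) bias from the random
  denominator; measured ≤ ~0.5% at default designs, well inside the 2%
  validation band.
- The nerve boundary is a perfect circle; fascicle irregularity, which
  changes reference-area bookkeeping at the margin, is not modeled.
- The packing algorithm cannot reach densely jammed states (> ~0.55 area
  fraction); truly crowded neonatal or regenerating nerves with higher
  packing would need a different packer.
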