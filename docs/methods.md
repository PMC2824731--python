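# Methods

## The model

Hydrodynamic shearing fragments DNA by accelerating a solution through a
narrow constriction; drag stretches each molecule until it snaps, and the
break lands near the molecule's midpoint. `shearscape` models one shearing
pass on a fragment of length *L* as a break position drawn from

    X ~ Normal(L / 2, sd_frac * L),    rounded to the nearest integer,

with `sd_frac = 0.125` by default, the measured spread for hydrodynamic
shearing. Draws outside the interior `[1, L − 1]` are redrawn (rejection),
not clamped: clamping would pile probability onto the first and last
positions and fabricate terminal breaks, which is exactly the artefact the
package exists to study. Shearing iterates: every fragment at least
`critical_length_bp` long breaks again, and fragments below the threshold
are final. The hard threshold stands in for drag forces falling below the
tensile strength of the strand; it is the simplest stopping rule consistent
with the sharp lower size cutoff seen in sheared-DNA size distributions
(fragments below ~0.8 kb are essentially absent). Whether real breakage is
probabilistic near the threshold is unknown; the hard rule is this package's
choice.

Two consequences follow directly from midpoint breakage and are the
phenomena the analysis layer quantifies:

* **Shear-resistant termini.** The final terminal fragment of a linear
  molecule is the "end half" of the last parent that broke, so its length is
  centred on roughly half that parent's length — far from zero. Breaks
  within ~1 kb of a terminus require an extreme tail draw, so the terminal
  zone is nearly break-free.
* **Subterminal peak with Gibbs-like oscillation.** Break density measured
  from a terminus peaks at approximately the mean fragment size, overshooting
  the interior plateau, then dips below it before levelling — the
  renewal-like oscillation expected when regularly sized fragments tile
  outward from a fixed end.

Coordinates are integer, 0-based, half-open everywhere, so fragment tiling of
the parent is exact and testable as an identity, not a tolerance.

**Circular molecules** have no midpoint, so the first break is uniform on
`[0, L)`; the molecule is then re-coordinatized to start at that break and
sheared as a linear molecule. By rotational symmetry the pooled circular
break distribution is uniform — the flat control track. Break coordinates
are mapped back to the original frame (so pooled profiles are comparable
across replicates), while fragments are emitted on the rotated frame;
`shear_circular_with_offset` exposes the rotation for read generation.

## Calibration

Laboratory shear speed maps onto mean fragment size (speed 12 ≈ 3.8 kb,
speed 6 ≈ 1.9 kb in the motivating experiment). `calibrate_critical_length`
inverts the model: mean final fragment length is nondecreasing in the
critical length, so an integer bisection over Monte-Carlo mean estimates
(default 128 shears per evaluation, verification at 256) finds the threshold
reproducing a target mean within 2%, or raises `CalibrationError`. On a
36 kb molecule, a 3.8 kb target calibrates to a critical length near 5.7 kb.

## Library construction

* **Size selection** is a hard window (default 3.8–4.2 kb, or 1.8–2.2 kb for
  the small-insert arm), a pure filter. Real gel excision has soft edges and
  recovery-efficiency structure; modelling that would only blur the window
  boundaries and is out of scope.
* **End reads**: each selected fragment yields a left mate covering
  `[start, start + r1)` forward and a right mate covering `[end − r2, end)`
  reverse-complemented, with read lengths Normal(400, 30) bp clipped to
  `[50, fragment length]` — spanning typical Sanger-era high-quality read
  lengths (~394–434 bp). Every read is prefixed with a fixed 10 bp
  polylinker tag, the remnant of the cloning site that a mapper must strip.
* **Chimeras** (optional, default rate 0) rewrite a fraction of clones:
  *orientation* chimeras flip the right mate onto the left mate's strand;
  *size* chimeras replace the right mate with that of a distant clone
  (> 3× the mean span, so the implied insert exceeds the 2× filter threshold
  even after chimeras inflate the estimated mean). Ground truth is recorded
  on the reads so filter recall is measurable exactly.

## Breakpoint mapping

Each read start marks a shearing breakpoint. The mapper strips the
polylinker by exact prefix match, takes the next 24 bases (`anchor_k`) and
exact-searches both strands of the reference; exactly one hit maps the read,
multiple hits mark it ambiguous (excluded from break calling — the
conservative treatment of repeats), zero hits unmapped. Reverse-strand hits
report the k-mer's right boundary in the forward frame, so the two mates of
a clone reproduce the fragment's `(start, end)` exactly; this convention is
stated because half-open coordinates make it easy to be off by `k`. Circular
references are searched on the doubled sequence so anchors spanning the
origin map correctly.

Mate pairs are validated in two passes: the mean insert size is first
estimated from all provisionally valid pairs (both mapped, opposite strands,
inward-facing), then pairs are classified — same strand or outward-facing →
orientation chimera; implied size > 2× the estimated mean → size chimera;
an unplaced mate → incomplete. On chimera-free data the two-pass procedure
is a fixed point. Mapping is exact-match only because simulated reads are
error-free; a mismatch-tolerant aligner would add nothing testable here.

## Analysis

* **Window profiles**: `spanning` mode slides a window (default 1 kb, step
  100 bp) across a region centred on an anchor; `terminal` mode starts with
  the trailing edge at a terminus and slides inward until the leading edge
  reaches the extent (default 10 kb). Each row carries both x-axis
  conventions — window midpoint and nearest-edge distance to the anchor.
  Counts are half-open (`start ≤ b < start + window`) and are verified
  against brute-force recounts in the tests.
* **Peak detection**: the maximal-count row (ties → smallest window start);
  the interior plateau is the mean count over rows whose nearest edge lies
  beyond twice the peak distance. The oscillation summary checks
  peak > plateau (overshoot) and that some window between one and two peak
  distances falls below the plateau (undershoot).
* **Terminus report**: nearest break, breaks within 1 kb and 2 kb, and the
  mean count over non-overlapping interior 2 kb windows. "Interior" is not
  sharply defined in the field, so the exclusion zone (default 4 kb per end)
  is an explicit parameter.
* **Overrepresentation**: observed reads in a region vs the uniform
  expectation `N · region / reference`.
* **Size distributions**: gel densitometry measures fluorescence ∝ mass;
  dividing by length converts to molecule counts (number weighting).
  `fraction_below` integrates sampled curves by trapezoid (with
  interpolation at the cutoff) and sums discrete fragment tables exactly.
* **Linkage feasibility**: a terminal read of length *r* is extended by an
  outward-reading subterminal read only if a break lies within
  `r − min_overlap` of the end (1 kb reads at 150 bp overlap → 850 bp). The
  minimum overlap a given assembler needs is not fixed by the model, so it
  is a parameter, not a constant.

## Randomness and determinism

Every simulation takes an explicit `numpy.random.Generator`. Replicates and
pipeline stages derive independent streams as
`default_rng((base_seed, *indices))` — SeedSequence tuple seeding, which is
collision-free and reproducible. `run_experiment` is byte-identical across
runs with the same config and seed; the report embeds the config digest,
seed and package version.

## Study conditions and problem sizes

The default experiment mirrors the three-arm design the model was built to
reproduce: one ~36 kb molecule (a round stand-in for a mid-30s kb cosmid)
sheared (a) circular at a 3.8 kb mean, (b) linear at 3.8 kb with a
3.8–4.2 kb gel window, (c) linear at 1.9 kb with 1.8–2.2 kb. The test suite
pools 12,000 linear shears (~10⁵ breaks) for density profiles, 250 circular
shears for the uniformity control, and an 800-replicate mapped library
(~1,000 clones) for round-trip, insert-size and overrepresentation checks;
`scripts/acceptance.py` uses 6,000 linear shears and the same library scale.
These sizes give Monte-Carlo standard errors comfortably inside the asserted
margins (e.g. the terminal break fraction is estimated from ~5 × 10⁴ breaks
against a 10⁻³ bound).

One statistical note: pooled circular window counts are slightly
*under*dispersed relative to Poisson, because breaks within one molecule are
regularly spaced about one fragment length apart (measured dispersion index
0.5–0.85). A two-sided Poisson dispersion test would therefore reject the
control for being too flat. Flatness is asserted as KS uniformity of pooled
break positions plus a one-sided test against *over*dispersion, which is the
direction clumping or a peak would push.

## What the generator does and does not emulate

Emulated: iterative near-midpoint breakage with SD 12.5% of fragment length,
hard size selection, polylinker-prefixed paired end reads with ground truth,
orientation and oversized-insert chimeras, and exact break recovery from
read starts. Not emulated: sequencing error and quality (mapping is
exact-match), GC-dependent breakage susceptibility, cloning bias against
AT-rich or methylated fragments, smooth gel-recovery curves, and assembly
itself (break coordinates are recovered directly; contig/gap structure is
downstream of scope). Passing tests therefore demonstrate the geometry and
statistics of shearing bias under the model, not platform-specific artefacts
of any particular sequencing pipeline; in particular the simulated
insert-size SD (~120 bp for a hard 3.8–4.2 kb window) is narrower than
gel-measured values (~490–560 bp), which include excision and migration
smearing.

## Known limitations

* The hard critical-length threshold makes the final size distribution
  narrower than experiment; a soft (probabilistic) threshold would widen it
  at the cost of a second free parameter.
* Exact-anchor mapping requires a unique-sequence reference; repetitive
  references produce `ambiguous` reads, which are excluded rather than
  rescued by mate information.
* Break densities near a terminus are hierarchy-correlated (children of one
  parent), so pooled counts are not an independent point process; tests that
  assume approximate independence (KS, dispersion) rely on pooling many
  replicates.
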