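# shearscape

Simulation and analysis of **terminal bias in hydrodynamically sheared DNA
shotgun libraries**.

When genomic DNA is sheared by forcing it through a narrow constriction,
strands break near their midpoints (SD ≈ 12.5 % of the molecule's length)
and fragmentation iterates until pieces are too short to experience enough
drag. For a *linear* molecule this has a striking consequence: the last
~1–2 kb at each end is a shear-resistant zone with almost no breaks, break
density peaks at roughly the mean fragment size from each terminus (with a
Gibbs-like undershoot beyond the peak), and after gel size selection the
terminal fragments become massively overrepresented among clones — yet no
clone can bridge a terminus to the interior. This is why telomeres of
organisms with short telomere tracts are simultaneously superabundant in raw
shotgun reads and missing from genome assemblies.

`shearscape` is for sequencing methods developers and genome-assembly
researchers who want to reproduce, quantify or explore this bias *in
silico*. It provides:

* **`shearing`** — a Monte-Carlo simulator of iterative near-midpoint
  breakage (`X ~ N(L/2, 0.125·L)`, rejection outside the interior) for
  linear and circular molecules, with calibration of the stopping threshold
  to a target mean fragment size;
* **`library_prep`** — hard gel size selection, polylinker-prefixed paired
  end reads with ground truth, and chimera injection;
* **`break_mapping`** — recovery of breakpoints from read starts: strip the
  polylinker, anchor the next 24 bases on both strands, validate mate pairs
  (opposite orientation, insert ≤ 2× the mean), emit break coordinates;
* **`terminus_analysis`** — sliding-window break-density profiles,
  nearest-break / breaks-within-d statistics, observed-vs-expected terminal
  read counts, peak and oscillation detection, and mass↔number weighting of
  fragment-size distributions;
* **`workflow_io`** + a `shearscape` CLI — FASTA/BED/TSV/JSON/YAML I/O and a
  one-command, fully deterministic multi-arm experiment runner.

## Worked example

Shear a 36 kb linear molecule to a 3.8 kb mean, select 3.8–4.2 kb fragments,
sequence both ends of every clone, map the read starts back, and measure the
terminal bias:

```python
import numpy as np
import shearscape as ss

rng = np.random.default_rng(0)
molecule = ss.random_molecule("cosmid", 36_000, "linear", rng)

params = ss.ShearParams(sd_frac=0.125, critical_length_bp=2)
crit = ss.calibrate_critical_length(3800, 36_000, params, rng)
print(f"critical length for a 3.8 kb mean: {crit} bp")

shear = ss.ShearParams(sd_frac=0.125, critical_length_bp=crit)
lib = ss.LibraryParams(select_min_bp=3800, select_max_bp=4200)
mapper = ss.MapperParams()

inserts, breaks = [], []
for rep in range(500):
    r = ss.replicate_rng(0, rep)
    bs, frags = ss.shear_linear(molecule, shear, r)
    breaks.append(bs.coordinates)
    sel = ss.size_select(frags, lib)
    reads = ss.generate_end_reads(sel, molecule, lib, r, id_prefix=f"r{rep}c")
    mapped = [ss.locate_insert_start(rd, molecule, mapper) for rd in reads]
    inserts.extend(ss.validate_clones(mapped, mapper))

valid = [i for i in inserts if i.status == "valid"]
mean, sd, n = ss.insert_size_stats(valid)
print(f"{n} valid inserts, size {mean:.0f} +/- {sd:.0f} bp")

pool = np.sort(np.concatenate(breaks))
report = ss.make_terminus_report(pool, 0, 36_000)
print(f"breaks within 2 kb of the left terminus: {report.breaks_within_2kb}")
print(f"mean breaks per interior 2 kb window:   {report.mean_breaks_per_2kb_window_interior:.0f}")

spec = ss.WindowSpec(window_bp=1000, step_bp=100, mode="terminal")
prof = ss.sliding_window_profile(pool, 0, spec, extent_bp=10_000)
peak = ss.density_peak(prof)
print(f"density peak at window midpoint {peak.peak_mid:.0f} bp "
      f"({peak.peak_count} breaks vs plateau {peak.plateau_mean:.0f})")

starts = np.array([i.start for i in valid])
over = ss.overrepresentation_report(starts, (0, 1), len(valid), 36_000)
print(f"clones starting at the terminus: {over.observed} observed vs "
      f"{over.expected:.3f} expected (ratio {over.ratio:.0f})")
```

Output:

```
critical length for a 3.8 kb mean: 5747 bp
640 valid inserts, size 3995 +/- 113 bp
breaks within 2 kb of the left terminus: 19
mean breaks per interior 2 kb window:   266
density peak at window midpoint 4200 bp (175 breaks vs plateau 129)
clones starting at the terminus: 69 observed vs 0.018 expected (ratio 3881)
```

Reading the numbers: the terminal 2 kb carries **14× fewer** breaks than an
interior 2 kb window (19 vs 266) — the shear-resistant zone; break density
peaks where the window midpoint sits about one mean fragment size from the
end and overshoots the interior plateau; and clones whose insert starts at
the very terminus are ~3900× the uniform expectation — every one of them
reading inward, so none can bridge the end to the interior assembly.

The same pipeline is available from the shell and composes through files:

```bash
shearscape simulate --length 36000 --mean-size 3800 --replicates 500 --seed 0 \
    --fasta ref.fasta --out-breaks breaks.bed --out-fragments frags.tsv
shearscape library  --fragments frags.tsv --fasta ref.fasta --select 3800:4200 \
    --seed 0 --out-reads reads.fasta --out-truth truth.tsv
shearscape map      --reference ref.fasta --reads reads.fasta \
    --out-mapped mapped.tsv --out-inserts inserts.tsv --out-breaks recovered.bed
shearscape profile  --breaks recovered.bed --anchor 0 --mode terminal --out profile.tsv
shearscape report   --breaks recovered.bed --length 36000 --out-json terminus.json
shearscape run      --out results/   # full three-arm experiment, report.json + tracks
```

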