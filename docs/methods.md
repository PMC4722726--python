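# Methods

## Assays modeled

The package analyses the promoter chromatin of recombinant CHO clones
through five measurement channels, each with its own module:

1. **Endogenous CpG methylation** by targeted bisulfite sequencing of
   cloned amplicons (one clone = one molecule).
2. **Chromatin accessibility** by single-molecule M.SssI footprinting:
   nuclei are exposed briefly to the CpG-specific methyltransferase, so
   methylation after the assay marks *accessible* DNA and its absence
   marks protein-protected DNA.  A naked-DNA control calibrates the
   enzymatic efficiency.
3. **Histone composition** by native ChIP-qPCR (canonical H2A, variants
   H2A.Z/H3.3, modifications H3K4me3/H3K27me3/H3K9ac/H3K9me3), reported
   as percent input and normalized to H2A.
4. **Open chromatin** by FAIRE-qPCR (aqueous-phase DNA).
5. **Expression and stability**: HC/LC transcript ratio by
   standard-curve qRT-PCR, transgene copy number by a calibrated
   ratio-of-ratios, and titer trajectories over serial passaging.

All coordinates are 1-based inclusive internally; BED I/O converts to
0-based half-open at the file boundary.

## Bisulfite model and methylation calling

Chemistry is top-strand only (targeted bisulfite PCR interrogates one
strand): unmethylated C → T with probability `1 − failure_rate`,
methylated C retained, `inappropriate_rate` of spurious conversion.
Calls at CpG sites are METH (read C), UNMETH (read T), MISSING
(anything else or uncovered).  MISSING cells never enter a denominator.

Reads are positioned by ungapped anchoring at the amplicon start,
scored bisulfite-aware (read T at a reference C is a match).  If the
mismatch fraction exceeds 0.2, a global alignment (match +1, mismatch
−1, gap open −2, gap extend −0.5, C/T equivalence at reference Cs) is
used; identity is matches over all alignment columns *including gaps*,
so stitched chance matches of an unrelated sequence cannot pass the
0.6 rejection threshold.

Per-molecule conversion efficiency is the converted fraction of aligned
non-CpG reference cytosines; molecules below 0.95 are excluded from
methylation summaries (incomplete conversion inflates apparent
methylation).  The threshold is exposed as a parameter.

## Footprint calling and occupancy

Protection maps invert M.SssI-mode matrices (methylated → accessible).
Footprints are maximal runs of protected CpGs; MISSING calls bridge a
run (conservative toward protection continuity) but contribute no
evidence.  Run intervals extend from the first to the last protected
CpG out to the midpoint toward the nearest flanking accessible CpG, or
to the amplicon edge.  A run is classified a nucleosome when its span
is ≥ 127 bp (147 bp of nucleosomal DNA minus one CpG-spacing tolerance,
since CpG density limits resolution) and it contains ≥ 3 protected
CpGs; both thresholds are parameters.

Occupancy is reported with two definitions.  The CpG-call-level
statistic `100 · protected / (protected + accessible)` over the
window's CpGs is primary: it is defined for partially covered windows
and produces non-round values (e.g. 60.67 %) that molecule-count
fractions at realistic depth cannot.  The molecule-level alternative
(fraction of molecules with a nucleosome-classified footprint over the
window midpoint) is computed alongside but is only fully observable for
windows whose CpG span inside the amplicon exceeds the span threshold —
in the default geometry that is the TSS-proximal window; the distal
window is clipped by the amplicon edge exactly as in the real assay.

With M.SssI efficiency `e`, a window planted at occupancy `p` has
expected CpG-level protection `p + (1 − p)(1 − e)`: inaccessible CpGs
are never methylated, accessible ones escape methylation with
probability `1 − e`.  Parameter-recovery tests check this mixture.

## qPCR algebra

`Ct = slope · log₁₀Q + intercept` is fitted by OLS over ≥ 3 dilution
points; `E = 10^(−1/slope)` (perfect doubling: slope −3.3219, 100 %
efficiency).  Replicates aggregate by the arithmetic mean of Ct — the
geometric mean of quantities — with SD carried as dispersion only.
Copy number uses the efficiency-corrected ratio-of-ratios against a
calibrator of known copy number; percent input first shifts the input
Ct by `log_E(1/input_fraction)` (default 1 % input, 6.64 cycles at
E = 2).  IgG wells are reported as a background track, never
subtracted.  FAIRE supports two normalizations — percent input
(default) and aqueous/organic — and records the mode in the output
metadata, since the field reports both.  Missing Cts are censored:
excluded from means and counted.

## Productivity

`IVCC = (c_XV1 + c_XV0)/2 · (t1 − t0)` in 10⁹ cell·h/L and
`q_p = (c_P1 − c_P0)/IVCC · 24` in pg/cell/day, computed between
successive sampled passages.  Units are enforced as measured
(10⁹ cells/L, hours, µg/mL); conversions happen at I/O only.  A series
mean of q_p is reported as an explicit aggregate in addition to the
per-interval values.  Relative titer normalizes to the first sampled
passage.  Note that on a declining harvest-titer series the per-interval
q_p is negative — it then measures the rate of productivity loss, and
the endpoint retention is the headline stability statistic.

## Signature table

One row per clone; columns are HC/LC mRNA %, H2A (raw % input), six
marks (relative to H2A, %), FAIRE, per-window occupancy (%), and
methylation (%).  Pearson correlations against mRNA are computed on the
values as reported — the deliberate unit mix is preserved and flagged
in the report.  Per-column maxima are flagged; ties flag all tied
clones.  With four clones the correlations are descriptive; no p-values
are printed by design.  Correlation needs ≥ 3 complete rows per column
(pairwise-complete where cells are missing) and both vectors
non-constant.

## Synthetic-data generator

The generator emulates the study conditions of four clonal lines:

* **Promoter** (default 1261 bp): an upstream CpG island (220-bp
  CpG-rich repeat), two adjacent 147-bp nucleosome windows ending
  107 bp before the 3′ end (853–999 and 1008–1154 at the default
  length), and a 231-bp amplicon with exactly 18 evenly spaced CpGs
  (12–56 supported; fewer would no longer satisfy the island criteria
  the amplicon must sit inside).  The amplicon fully covers the
  TSS-proximal window and the 3′ portion of the distal one.  The
  background is AT-rich and CpG-free by construction; a final pass
  removes stray boundary CpGs, and the constructed sequence is
  validated against the package's own island scanner
  (Gardiner-Garden/Frommer criteria: length ≥ 200 bp, GC ≥ 0.50,
  obs/exp CpG ≥ 0.6).
* **Molecules**: per molecule, each annotated window receives a
  nucleosome with the clone's occupancy probability; intervals sit
  exactly on the windows (no sliding — matching the two-window
  analysis; free positioning is out of scope).  M.SssI methylates
  accessible CpGs with probability 0.98 (the naked-DNA control level);
  bisulfite errors default to 0.5 % each way and 2 % unreadable calls.
  Default 15 molecules per clone, consistent with occupancy values such
  as 86.67 % = 13/15 at realistic cloning depth.
* **Ct tables**: `Ct = 35 − log_E(Q) + N(0, 0.15)` cycles with E = 2; a
  0.15-cycle replicate SD is typical instrument noise.  Each table
  embeds a 5-point 10-fold dilution series; ChIP tables carry paired
  input and IgG rows (0.1 % background recovery) per primer.
* **Clone profiles**: occupancies, H2A percent input, relative
  enrichments, FAIRE, HC/LC %, and methylation rates are the published
  per-clone values of the four PT1 lines, so the planted truth is the
  study's observed signature.  Copy numbers are 1/1/2/3 and endpoint
  titer retentions 0.2/0.8/0.4/0.6 (the printed extremes for PT1-1 and
  PT1-7; intermediates chosen once as plausible).
* **Determinism**: every dataset is a pure function of (config, seed);
  per-molecule substreams derive from `SeedSequence([seed, …, index])`
  so growing a dataset never changes earlier molecules, and stability
  noise streams are keyed per passage so same-seed clones differ only
  through their configured rates.  Truth sidecars (JSON) round-trip
  losslessly.

What the generator does **not** emulate: indels or substitutions
outside cytosines, chimeric or strand-flipped reads, sequencing-depth
or length effects, PCR bias among molecules, plate effects or melt
curves in qPCR, and interaction between endogenous methylation and
M.SssI accessibility (modes are simulated independently).  Passing
tests therefore demonstrate correctness of the estimators under the
stated noise model, not robustness to every artefact of real data.

## Problem sizes in tests

The acceptance-style checks use 600 molecules (10 800 CpG calls) for
the naked-DNA control, 1000 molecules per planted occupancy for
parameter recovery, and 60 molecules per clone for the end-to-end
study — sizes at which the binomial standard errors make the checks
sharp while the whole suite runs in well under a minute.

## Known limitations

* Direct (non-cloned) bisulfite trace quantitation by peak height is
  not implemented; clone-level sequencing is the modeled assay.
* Molecule-level occupancy under-reports windows clipped by the
  amplicon (see above); the CpG-level statistic is unaffected.
* No inferential statistics (ANOVA, t-tests) by design: the pipeline
  reports descriptive statistics and correlations only.
* Nucleosome-position prediction and TFBS scanning are consumed as
  input coordinates, never computed.
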