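# Methods

## The measurement model

The pipeline reproduces the analysis chain of a single-molecule
IF-FISH/SINAPS experiment. Each fluorescence channel is a 3D widefield
stack (voxel size 107.5 nm XY, 200 nm Z). Spots are detected per channel:
large-σ Gaussian background subtraction, Laplacian-of-Gaussian filtering at
the PSF scale (σ_xy 130 nm, σ_z 300 nm by default), strict 26-neighborhood
local maxima thresholded at `mean + 5·sd` of the response, then a
least-squares fit of `A·exp(−((Δx²+Δy²)/2σ_xy² + Δz²/2σ_z²)) + b` in a
5×9×9-voxel window. Positions use the voxel-center convention (center of
voxel *i* at `(i+0.5)·voxel_size`) and are reported in nm. Downstream
intensities are the analytic Gaussian volume in voxel-sum units
(`A·(2π)^{3/2}σ_xy²σ_z / v_xy²v_z`), not the amplitude, which is
PSF-width-confounded. Fits are rejected when σ pins at its physical bounds,
when the RMS misfit exceeds half the amplitude, or when the amplitude falls
below 3.5× a robust (MAD-based) noise floor; duplicate fits within one
voxel keep the brighter spot.

Nucleus and cell outlines are 2D: Otsu-thresholded, Gaussian-smoothed
maximum projections of the DAPI channel (distance-transform watershed
splits touching nuclei) and of the diffuse probe-background haze (seeded
watershed grows cells from their nuclei). Spots are assigned
nuclear/cytoplasmic by lateral position only; spots outside every cell are
excluded, and cells touching the field border are excluded from per-cell
metrics.

Colocalization is decided in 3D after drift correction. The inter-channel
drift is the mean displacement of mutual-nearest-neighbor pairs within
500 nm, plus one refinement pass at half that radius once the bulk offset
is removed (the tighter radius sheds chance pairs; residual error is
~10–20 nm under a ~2000-free-spot distractor load, dominated by surviving
chance pairs). Matching is greedy one-to-one in ascending distance order
with deterministic tie-breaks; gates are 500 nm (mRNA–SunTag) and 250 nm
(mRNA–AGO). Greedy was chosen over optimal assignment because it is
deterministic, oracle-checkable by brute force, and near-optimal at these
densities; the one-to-one rule means a partner can occasionally be
"stolen" by a closer mRNA when two mRNAs sit within one gate of the same
spot.

## Metrics and statistics

Per-cell metrics are ratios of counts and summed intensities (see README);
a ratio with a zero denominator is NaN and the cell is excluded from that
metric's summaries, never an exception. Bulk metrics pool included cells
as a ratio of sums. Ribosome numbers divide each on-mRNA SunTag intensity
by the median free-SunTag intensity — per cell when the cell has ≥10
cytoplasmic free spots, else the pooled median. The per-cell scope
respects cell-to-cell staining variation; the fallback keeps sparse cells
usable. R is a lower bound: bright spots include nascent partial epitope
arrays. Stability is normalized to the negative control's *bulk* (pooled)
value per time point; the pooled value was preferred over the control
median because it matches the ratio-of-sums convention of the bulk
metrics.

The statistical battery is implemented from first principles and
cross-checked against independent implementations in the tests:
Mann–Whitney U with exact enumeration of the rank-sum distribution for
tie-free samples of total size ≤ 20 and a tie- and continuity-corrected
normal approximation otherwise; Dunn's multiple-comparison z on pooled
ranks with the tie term `Σ(t³−t)/(12(N−1))` and Bonferroni adjustment over
the comparisons actually performed; Pearson r with a least-squares line.
One-tailed directions are explicit arguments; the pipeline presets encode
the biological hypotheses (miR-21 reduces S, T_eff, T_fra; increases
A_eff, A_fra). Significance bands are ***/*/n.s. at 0.001/0.05. In
time-course runs Dunn's test spans the six (condition × time) groups but
performs only the three within-time comparisons, so m = 3.

## The generative model

The synthetic generator is the test bed; its defaults are the study
conditions it emulates.

- **Geometry.** Cells are axis-aligned ellipses (semi-axes 12 × 10 µm,
  nucleus 5.5 × 4.5 µm) on a centered grid in a virtual field 25 z-planes
  (5 µm) deep. Geometry is analytic in spots-only mode and rasterized only
  for rendering. The cell volume was chosen so that ~2000 uniformly
  scattered free AGO spots produce a chance RISC-positive rate near 10%
  under the 250 nm gate, matching the observed mutant baseline.
- **Copy numbers.** Each cell draws an induction level from a Gamma
  distribution (shape 4, mean 45); reporter and Fluc counts are Poisson
  around that shared level, truncated at 100. Marginally this is a
  negative binomial with median ~40 and max 100 — the two published
  summaries — while the shared level models the bidirectional promoter:
  per-cell Sun/Fluc *ratios* are much tighter than the marginal spread,
  which is what makes the internal-control design informative.
- **Kinetics.** P(cytoplasmic) = 1 − exp(−k_export·(t + 30 min)) with
  k_export = 0.012/min; the 30-min offset is the transcription-pulse
  duration (transcripts are older than the chase clock), so the
  cytoplasmic pool is ~30% at 0 min and grows with time, while k_export=0
  still keeps every mRNA nuclear. RISC binds each cytoplasmic reporter
  with p = 0.5 (+miR-21) from t = 0; the mutant's linked-binding
  probability is 0 — its RISC-positive baseline arises from chance
  colocalization alone. Translation is a step model: before 30 min every
  cytoplasmic mRNA translates with p = 0.65 regardless of RISC; after
  onset, RISC-bound mRNAs drop to p = 0.15. Translated mRNAs carry
  1 + Poisson(mean−1) ribosomes (mean 8 active, 1 repressed). Decay is a
  single survival fraction (0.5) applied to cytoplasmic reporters of the
  decay-design +miR-21 condition at t ≥ 60 min. Step models were chosen
  because the experiment resolves only three time points.
- **Spots.** On-mRNA SunTag/AGO spots sit at the mRNA position plus
  isotropic Gaussian jitter (σ 60 nm, truncated at 3σ so designed partners
  always fall inside the gates). SunTag intensity is ribosome count ×
  a lognormal one-peptide unit (σ_log 0.3); free spots (225 SunTag, 2000
  AGO per cell) draw the same unit. The spots-only path adds 20 nm
  per-axis localization noise, per-channel drift, and 5% multiplicative
  intensity error. The render path draws each spot as an anisotropic 3D
  Gaussian whose voxel sum equals intensity × 2000 counts, adds a
  cytoplasmic haze, Poisson shot noise, and Gaussian read noise (σ 2).
- **Randomness.** One seed sequence is split per cell, so any prefix of
  the population regenerates identically; identical (config, seed) pairs
  are bit-identical.

What the generator does **not** emulate: aberrations or channel
bleed-through, transcription-site aggregates, non-elliptical or motile
cells, nuclear AGO pools, partial nascent-chain intensities, and spot
density heterogeneity (P-bodies). Passing tests therefore demonstrate the
*analysis* is correct and calibrated under the stated noise model, not
that detection would meet the same F1 on arbitrary real data.

## Numerical choices and edge cases

Fit windows shrink at stack boundaries. The detection threshold
(`threshold_sigmas = 5`) and the gates are explicit configuration, not
constants. Distances are always anisotropic-aware (computed in nm).
Matching ties break by (distance, mRNA id, partner id). Degenerate inputs:
blank images yield zero nuclei/candidates rather than errors; empty spot
tables propagate as empty outputs; drift estimation refuses to run on
fewer than 10 mutual pairs (callers fall back to zero drift with a
warning, since a colocalization-free field cannot constrain drift).

## Problem sizes

Default experiment runs use 50 cells per condition per time point (the
study's per-experiment cell count) in spots-only mode; rendering tests use
1–2 cells in 256×256×15 fields, which is where Gaussian fitting cost is
concentrated. Parameter-recovery checks pool ≥2000 cytoplasmic mRNAs so
binomial error (±3 s.d. ≈ 0.03) is the limiting tolerance; the recovery
configurations disable free spots to isolate the parameter from chance
colocalization. The per-cell median of S_norm carries a small upward
Jensen-type bias (~+0.04 at ~20 cytoplasmic mRNAs per cell) because it is
a median of count ratios; the pooled ratio-of-sums estimator is nearly
unbiased and both are checked.

## Known limitations

Single-Gaussian fits bias each other when two spots overlap within a
fitting window (dense-spot deconvolution is out of scope). Detection F1
degrades below ~0.95 when all spots sit exactly at the SNR 5 floor; the
quality checks use a realistic lognormal brightness distribution floored
at SNR 5. One-to-one greedy matching undercounts when mRNA density
approaches the gate scale. The site scanner handles canonical
8mer/7mer/6mer seed sites only — no 3′-only, bulged, or
thermodynamically scored sites.
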