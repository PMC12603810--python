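# Methods

This note documents the models, numerical choices and known limitations of
the `ticsupp` pipeline, in the order data flow through it.

## Synthetic cohort model

The generator is the canonical input source: it produces cohorts whose
*statistical structure* matches what the analysis assumes, so that every
downstream stage can be validated against known ground truth.  It does not
attempt to be a biophysical EEG simulator.

**Subjects.**  Two groups (default 37 TDC, 39 CTD).  Age is drawn from
group-specific normals (TDC 9.6 ± 1.5 y clipped to 8–12, CTD 9.7 ± 1.6 y
clipped to 8–14), sex from the group male fractions (19/37, 27/39), a
psychotropic-drug flag from the group frequencies (0, 9/39), and a
premonitory-urge score for CTD only (4.7 ± 2.3, clipped at 0).  Each
subject carries a unit-variance latent *suppression ability* that drives
both behaviour and, when coupled, the injected EEG modulation.

**Event trains.**  Tic/blink onsets follow a refractory Poisson process:
inter-event gaps are `refractory + Exp(λ)` with a fixed 1 s refractory
period and λ renormalised so the mean gap equals the reciprocal of the
target rate.  Per-subject rates are the group-condition means (defaults:
TDC 17.9/11.0/8.6, CTD 3.6/2.3/1.9 events/min — emulation targets, not
reproduction claims) times a subject-level log-normal multiplier (σ = 0.5
for TDC, 0.8 for CTD, matching the groups' observed coefficients of
variation) times a small condition-level log-normal (σ = 0.15).  Under
suppression the rate is additionally multiplied by
`exp(−softplus(ability)·κ)` (κ = 0.3), renormalised by its expectation over
a standard-normal ability so group means are preserved; this makes "better
ability → fewer events" monotone while keeping rates positive.  Rates are
capped just below the refractory ceiling (60/min at 1 s).  Block durations
are drawn uniformly from 5–7 min per subject.  Subjects with fewer than
`min_events = 15` events in any condition are *flagged* excluded but stay
in the table; with the default CTD rates this flags a large fraction of
CTD subjects, mirroring the attrition such inclusion rules produce in
practice.  Behavioural analyses operate on whichever subject set the
caller passes; the validation studies use the full cohort.

**IC epochs.**  Each subject contributes 2–5 ICs; each IC has a dipole
position drawn isotropically (σ = 8 mm) around one of 13 centroids spread
over a ±70 mm Talairach-like RAS volume.  Epochs span −5..0 s before each
event at 250 Hz (125 Hz in the reduced validation settings); events within
5 s of block start are dropped, since their pre-event window would leave
the recording — the same rule is applied regardless of overlap with a
previous event, which real epoch extraction would also permit.  The signal
is pink (1/f-power) noise, spectrally shaped per epoch, plus one carrier
sinusoid per configured effect at the geometric centre of its band.  The
carrier is present throughout the epoch; inside the effect window its
amplitude is multiplied by `10^(dB/20)` with raised-cosine 0.25 s ramps, so
the ERSP perturbation at the carrier frequency approaches the configured dB
value.  For suppression conditions the dB is scaled by
`1 + coupling_beta·ability`, linking EEG modulation and behaviour through
the same latent.  What the generator does **not** model: volume conduction
and scalp mixing, artefacts (EMG, blinks as waveforms), non-stationary
background spectra, inter-subject spectral variability, or broadband
(multi-carrier) effects; passing tests therefore demonstrate correctness of
the *analysis machinery*, not robustness to real-data pathologies.

## ERSP

Power is estimated with complex Morlet wavelets defined in the frequency
domain (Gaussian transfer functions, unit passband gain, zero at DC and
negative frequencies), which avoids time-domain truncation artefacts.
Wavelet length grows linearly from 3 cycles at 1 Hz to 15 cycles at 50 Hz —
the common "increasing cycles" convention; this affects smoothing only.
The default grid is 50 log-spaced frequencies in 1–50 Hz × 1251 latencies
in −5000..0 ms.

Epochs are reflection-padded by four standard deviations of the longest
wavelet so the full time grid is populated.  Power is averaged across
epochs *before* conversion to dB (stabler for low-trial ICs), then
referenced to the −5..−4 s baseline as `10·log10(P/P_b)` where `P_b` is the
**geometric mean** of the epoch-averaged power over the baseline columns
(i.e. the mean log power).  This choice makes every frequency row average
to exactly 0 dB inside the baseline window — a useful construction
invariant — and differs from an arithmetic-mean baseline by a fraction of a
dB for realistic data.  Known artefact: within ~2 wavelet standard
deviations of the epoch edges the analytic amplitude is attenuated (half
the local energy is reflected into negative frequencies), which biases
measured dB by up to ~0.3 dB at band centres and more in the lowest
frequency rows at the very edges; the amplitude-recovery tests bound this
at ±0.5 dB.  The collapse of the two suppression conditions averages their
per-condition ERSPs (rather than pooling epochs), and ΔERSP is
`(Supp_Vrb + Supp_Rwd)/2 − NoSupp` element-wise.

## Dipole clustering and density

k-means (k-means++ initialisation, 20 restarts, fixed seed) on dipole
coordinates in mm; the number of clusters is the argmax of the mean
silhouette over a configurable range (default 2–30; ties break toward
smaller k).  Silhouette uses the same Euclidean metric as the clustering.
A mean silhouette below 0.5 triggers a low-separation warning (Rousseeuw's
rule of thumb for weak structure).  Dipole density sums normalised
isotropic Gaussians with FWHM 20 mm (σ ≈ 8.49 mm) on a voxel grid that must
enclose all dipoles with a 2·FWHM margin.  Anatomical labels come from a
packaged *synthetic* lookup table of ~70 macro-regions with hand-placed
representative coordinates — decoration for reports, with no statistical
role; ties are broken lexicographically.

## Cluster-mass permutation statistics

Observation unit is the IC (matching the ERSP tensor's third dimension);
subject identity is retained for the permutation schemes.  Because both
factors have two levels, the split-plot ANOVA reduces to closed forms in
the per-IC condition means `M` and differences `D`:

* Group: one-way F on `M` with the subject(group) mean square as error,
  df (1, N−2);
* Suppression: `N·D̄²/2` against the within-cell residual of `D`;
* Interaction: the group contrast of `D̄_g` against the same residual.

These match a general mixed-ANOVA implementation to ~1e-12 (tested against
`pingouin.mixed_anova`, balanced and unbalanced).  Zero-variance pixels
yield F = 0 (no evidence) rather than NaN.

Pixels with parametric p < 0.05 form clusters under 4-connectivity
(8-connectivity available); each cluster's mass is `Σ|F|`.  The label
shuffles are: sign flips of `D` within ICs for Suppression; permutation of
group labels across *subjects* (ICs move with their subject) for Group and
Interaction — a conservative choice that respects the IC-within-subject
dependence, since exchangeability holds at the subject level.  Each
permutation recomputes the F map via the same closed forms (a few matrix
products for the whole batch), extracts clusters at the same threshold, and
records the largest mass.  The significance threshold is the 95th empirical
percentile (linear interpolation) of that null; true clusters with strictly
larger mass form the significance mask.  Default 1000 permutations
(200 in the reduced validation settings); fewer than 100 permutations or 5
exchangeable units is refused.  The full printed grid is tested, including
the baseline columns.

## Behavioural analysis

Counts are normalised to events/min.  All three condition pairs are
compared by paired t-tests within each group, with Benjamini–Hochberg FDR
applied within each group's family of three tests (the family composition
is a package choice; both raw and adjusted p are reported).  The reported
df is n−1, the paired-test df.  Zero-variance difference vectors are
flagged degenerate (p = 1 when the mean difference is 0, p = 0 otherwise)
instead of raising, so simulated edge cases do not abort a run.  The
suppression ratio is `NoSupp/((Supp_Vrb+Supp_Rwd)/2)`, undefined (an error)
at zero denominator.  Covariate adjustment uses fixed-effects OLS
(`rate ~ age + drug + condition*group`, treatment coding with TDC and
NoSupp as references, uncorrected per-term p, adjusted R²); a
random-intercept mixed model can be compared via a 1-df likelihood-ratio
test on ML fits.

## Brain–behaviour coupling

Within a cluster's significance mask, each member IC's ΔERSP is averaged
over mask pixels, then averaged across a subject's ICs, keeping the subject
as the unit of analysis.  Correlations with the suppression ratio are
computed per cluster × group cell (≥5 subjects required), the percentile
bootstrap (default 2000 resamples) resamples *subjects*, and FDR is applied
jointly across all cells.  In the pipeline each cluster is bound to its own
mask for a chosen effect (default the Interaction mask); binding to a
different effect's mask is a parameter.

## Validation studies and problem sizes

`ticsupp.experiments` packages the calibration/recovery studies; the
default sizes are desk-scale choices that keep a full sweep within minutes
on one CPU while leaving enough replicates for binomial error bars:

* weak-FWER calibration: 200 null cohorts × (6 subjects × 2 ICs per group,
  10 epochs/condition, 125 Hz, 25 × 200 grid), 200 permutations each;
* effect recovery: 50 cohorts with a +3 dB theta (4–8 Hz, −3..0 s)
  suppression effect; success = mask-vs-injected-region Jaccard ≥ 0.25 with
  the injected sign;
* correlation recovery: 100 cohorts of 39 subjects at population ρ = 0.5
  via the calibrated summary-level generator (both quantities load on the
  latent ability with noise variance set to `1/ρ − 1`); the estimate is
  checked against the 95% Fisher-z band;
* null correlation scan: 13 clusters × 2 groups of independent cells,
  any-FDR-significant rate vs α;
* behavioural power: 100 cohorts at the default rates/dispersions and
  group sizes;
* silhouette recovery: 13 blobs of 12 dipoles at 4 mm scatter
  (well-separated by construction against the ≥26 mm centroid spacing).

## Limitations

* The generator's effects are narrowband carriers; genuinely broadband
  effects are emulated by multiple entries.
* Wavelet edge attenuation near −5 s and 0 s is not corrected, only
  bounded; inferences at the extreme edges of the grid are conservative.
* The synthetic atlas is not a real stereotaxic atlas; labels are
  illustrative.
* Cluster-level inference provides pass/fail at the 95th-percentile
  threshold (weak FWER control) — no cluster p-values, strong control, or
  TFCE.
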