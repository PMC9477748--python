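# Methods

`dimertrack` quantifies homo- and heterodimerization and diffusion of
plasma-membrane receptors from dual-colour single-molecule TIRF movies, and
ships a synthetic-experiment generator that validates every analysis stage
by parameter recovery. This note documents the models, the defaults and the
reasoning behind the open design choices.

## Analysis model

### Channel registration

A dual-view image splitter leaves a chromatic offset between the two
spectral channels. The map from channel-B to channel-A coordinates is
modelled as a full 6-parameter 2D affine transform (translation, scale,
shear) estimated by linear least squares from paired fiducial-marker
localizations (≥ 3 non-collinear pairs required; residual RMS reported).
An affine family is assumed rather than a polynomial/spline field
distortion: dual-view optics are well approximated by an affine map over a
20 µm field, and the affine fit is identifiable from tens of fiducials.
The transform is always applied to channel B (B→A convention) before any
co-localization.

### Localization

Spot candidates are local maxima of the Laplacian-of-Gaussian-filtered
frame above a per-frame robust threshold (median + `snr_threshold` ·
1.4826·MAD of the filter response; default `snr_threshold = 4`), with
non-maximum suppression within 2·`psf_sigma`. The per-frame adaptive
threshold keeps sensitivity constant under bleaching-driven intensity
drift. Candidates are refined by least-squares fitting of a
pixel-integrated symmetric 2D Gaussian (free centre, integrated photon
count, width, offset). Fits are discarded when the window is clipped by the
frame edge, the solver fails, the window is flat, or the fitted width
leaves [0.5, 3]·`psf_sigma`. This is a single-emitter fitter: fields above
~1 emitter/µm² (overlapping PSFs) are outside the validated range, which is
sufficient for single-molecule receptor densities (~0.1–0.5/µm²).

### Trajectory linking

Per consecutive frame pair, localizations are linked by a one-to-one
assignment minimizing total squared displacement, with links beyond
`max_disp` (default 500 nm) forbidden. The assignment is solved exactly by
the Hungarian algorithm on a birth/death-padded cost matrix in which
leaving a point unlinked costs `max_disp²`; ties resolve deterministically.
Track ends are then joined to later track starts when the gap is ≤
`max_gap` frames (default 1) and the displacement ≤ `max_disp`·√(gap+1).
This deliberately simplifies full multi-hypothesis trackers (motion models,
merge/split handling): at the densities analysed here the assignment is
rarely ambiguous, and the simplification is validated against brute-force
enumeration (1,000 random instances, 100% agreement). Identity switches
between crossing particles remain possible and are the dominant residual
linking error (~3–6% of tracks at 0.4 particles/µm², less at lower
density).

### Immobile filtering

Receptors stuck to the substrate or trapped in endocytic structures are
removed before co-localization by thresholding the trajectory radius of
gyration: tracks with lifetime ≥ `min_lifetime` (10 frames) and Rg <
`rg_threshold` (75 nm) are classified immobile and excluded from
co-tracking and diffusion analysis. For a truly immobile emitter observed
with ~18 nm effective position noise, Rg ≈ 25 nm ≪ 75 nm; a Brownian track
at D = 0.1 µm²/s reaches Rg ≫ 75 nm within a few frames, so the two
classes separate cleanly (≥ 95% accuracy against ground truth at default
density).

### Co-tracking and dimer calling

Mobile-track localizations of the two channels are matched frame by frame
by optimal one-to-one assignment within a 100 nm cutoff; match midpoints
are linked over time with the same trajectory linker. A co-trajectory with
at least 10 matched frames (gap-closed frames do not count) is called a
dimer — the persistence criterion that distinguishes complexes from chance
encounters: at 0.1 particles/µm² per channel, chance co-localizations
essentially never persist 10 frames (measured dimer-called fraction 0).

**Dimer counting.** One physical A–B pair can fragment into several
dimer-called co-trajectories (blinking, borderline separations at tight
cutoffs). Counting fragments overstates — and at tight cutoffs even
inverts — the dimerization level, so dimer-called co-trajectories sharing a
member trajectory in either channel are grouped (connected components of
the member-track graph) and each group counts as one dimer pair. Raw
co-trajectory counts are retained in the audit trail so alternative
conventions can be recomputed.

**Normalization.** The per-cell relative dimerization level is
n_dimer_pairs / min(N_A, N_B), where N_A and N_B count mobile tracks with
lifetime > 10 frames. The min-denominator makes a fully paired population
read 1.0 under both the heterodimer labelling scheme (each receptor one
colour) and the homodimer scheme (one receptor, each protomer randomly
labelled either colour, so only ~half of true homodimers are two-colour
detectable). Because detectability factors (labelling degree, co-emission
probability) scale the numerator uniformly, the measure is a *relative*
level: proportional to the true dimerized fraction (validated: R² > 0.99
through the origin over ground-truth proportions 0–0.6), not equal to it.
Comparisons across conditions are therefore meaningful; absolute values are
not interpreted.

### Diffusion analysis

For every mobile trajectory with lifetime > 10 frames the time-averaged MSD
is computed per integer frame lag (pairs separated by exactly τ frames;
gaps contribute no pairs). Curves are pooled with pair-count weights and
fitted by weighted linear regression over lags 1–5:
MSD(τ) = 4·D·τ·Δt + 4·σ_loc². Short-lag fitting minimizes confinement and
statistical bias; the intercept absorbs the static localization error. A
negative slope truncates to D = 0 with a flag; a negative intercept floors
σ at 0. Per-trajectory D (for the immobile-fraction metric) uses the
two-point slope over lags 1–2, which cancels the localization-error offset;
the immobile fraction is the share of trajectories with D < 0.01 µm²/s.

### Intensity-based oligomer classification

Per cell and channel, the monomer intensity reference is the median of the
per-track mean intensities over mobile tracks that never co-localized —
robust to cell-to-cell illumination differences. Each dimer-called
co-trajectory gets a per-channel multiplicity:
round(mean background-subtracted intensity / reference); multiplicity ≥ 2
in either channel classifies it as a higher-order cluster, and the oligomer
fraction is the higher-order share of dimer calls.

Known limit: the estimator sees *emitting labels*. With sub-stoichiometric
labelling a 2:2 complex carrying one label per channel is indistinguishable
from a 1:1 dimer, and with blinking/bleaching one of a spot's two labels
can be dark for part of the co-trajectory, pulling the mean multiplicity
below the 1.5 rounding threshold. Under complete labelling with stable
emission and 20% per-frame intensity noise the classifier recovers the
true higher-order share to within ~0.1 percentage points; under the full
default photophysics it undershoots by roughly 3–6 points. This is a
property of any mean-intensity-ratio estimator, not of the implementation.

### Statistics

The statistical unit is the cell. Conditions are compared with two-sample
Kolmogorov–Smirnov tests on per-cell values; the statistic is the exact
supremum ECDF distance, and the p-value uses the asymptotic Kolmogorov
distribution with the standard finite-sample effective-n correction
λ = (√en + 0.12 + 0.11/√en)·D, en = n₁n₂/(n₁+n₂). At the cell counts
typical here (12–51 per condition) this approximation is adequate and
slightly conservative: measured type-I error 3.8% at nominal α = 5%
(n = 20 vs 20, 500 replicates). Box summaries are five-number summaries
(min, Q1, median, Q3, max) with linear-interpolation quartiles. Significance
tiers follow the star convention at 0.05/0.01/0.001/0.0001. No
multiple-testing correction is applied (raw tiers are reported).

## Synthetic experiment generator

The generator emulates the acquisition regime of live-cell receptor
dimerization measurements: 150-frame movies at 32 ms/frame of a 20 × 20 µm
membrane patch. Complexes (monomer-A/B, homodimer-AA/BB, heterodimer-AB,
ternary 2:2, and a hexameric array of six B protomers) are placed at a
configurable mixture and density; each complex centre performs 2D Brownian
motion with per-axis step variance 2·D·Δt between reflecting boundaries
(immobile complexes have D = 0), and each member protomer adds independent
per-frame Gaussian bond jitter (10 nm; none for single-protomer complexes,
which are their own centre). Complex composition is static within a movie:
the 4.8 s span probes equilibrium dimerization, not binding kinetics.

The observation model labels each protomer with channel probability
`label_prob` (0.8), runs a two-state blinking chain (off 0.05/frame,
recovery 0.5/frame) with irreversible bleaching (0.003/frame), merges
co-complex emitters of a channel into one spot (they sit within the bond
jitter, far below the diffraction limit; intensities sum), perturbs
positions with isotropic Gaussian localization error (15 nm), maps
channel-B coordinates through the chromatic transform (translation
(120, −80) nm + 0.1% scale, representative of dual-view splitters), and
adds uniform false positives (0.5/frame/channel). Per-label per-frame
intensity is `photons_mean`·(1 + 0.2·N(0,1)), truncated at 0. Movie
rendering integrates a symmetric Gaussian PSF (σ 150 nm) over 100 nm
pixels, draws Poisson photons over a 10 photon/px Poisson background,
applies gain 2 and Gaussian read noise, and clamps to 16 bit.

Default motion/density parameters — 0.2 complexes/µm² (≈0.1–0.15
particles/µm²/channel), D_free 0.10, D_dimer 0.07, D_oligomer 0.05 µm²/s,
immobile fraction 0.1 — are stated assumptions chosen once from the typical
single-molecule imaging regime; surface densities and photon budgets are
not constrained by published values. All randomness derives from a single
seed through `numpy.random.SeedSequence` substreams (truth, photophysics,
rendering; per-cell spawn keys in pipeline runs), so identical
configuration + seed reproduces outputs byte-identically.

What the generator does **not** emulate — and what passing recovery tests
therefore do not certify for real data: anomalous/confined diffusion,
binding/unbinding kinetics within a movie, spectral crosstalk and
channel-dependent detection efficiency, structured (vesicular,
autofluorescent) background, non-affine field distortion, motion blur
within the 32 ms exposure, and EMCCD excess noise.

## Validation experiments and problem sizes

The validation suite (`dimertrack.validation`, also run by
`scripts/acceptance.py`) regenerates all inputs from scratch per seed:

- **Diffusion recovery** — 200 trajectories × 150 frames at D = 0.10
  µm²/s, σ_loc 15 nm; pooled-MSD regression recovers D within 5% and σ
  within ±30%.
- **Dimerization linearity** — ground-truth heterodimer proportions
  {0, 0.1, 0.3, 0.6}, 10 cells each, at fixed per-channel particle density
  (0.12/µm²; a heterodimer consumes one particle of each colour, so the
  complex density is (2−p)·0.12). Estimates are strictly increasing and
  linear through the origin (R² > 0.95); the proportionality constant
  (~0.5–0.8) absorbs labelling degree and co-emission losses.
- **Chance-co-localization control** — independent monomeric channels at
  0.1/µm²; dimer-called fraction < 1%.
- **Comparison power and calibration** — 20 cells at proportion 0.3 vs 20
  at 0.05 give KS p < 0.001. Type-I calibration uses 500 replicate pairs of
  n = 20 per-cell values drawn from a Beta(4, 12) distribution matched to
  the per-cell spread (the KS null depends only on sample sizes, so the
  movie simulator adds nothing here); rejection at α = 0.05 must lie in
  5% ± 2%.
- **Registration** — default chromatic transform, 50 fiducials, 3 nm
  marker noise: residual RMS < 5 nm, and the dimer-called fraction of a
  heterodimer-rich cell strictly increases after registration (the 144 nm
  offset exceeds the 100 nm cutoff, so unregistered co-tracking collapses).
- **Linker oracle** — 1,000 random frame pairs with ≤ 5 points/frame;
  Hungarian objective equals exhaustive enumeration in 100% of instances.
- **Oligomer recovery** — 10% ternary 2:2 complexes among A–B complexes,
  20% intensity noise, complete labelling, stable emission (see the
  classifier-limit discussion above); estimate within ±5 points of the
  realized ground-truth share (measured ≤ 0.1 points).
- **KS oracle** — statistic equals double-loop ECDF enumeration on random
  instances with n ≤ 50.
- **Detection** — rendered movies at 0.5 emitters/µm², 2000 photons over
  10/px background (peak SNR ≈ 40): recall ≥ 95% and localization RMSE ≤
  25 nm over evaluable emitters (inside the fit-window margin and with no
  same-frame neighbour within 600 nm = 4·psf_sigma — edge windows are
  discarded by design and closer pairs are unresolvable by a
  single-emitter fitter), FDR ≤ 5% over all detections.

## Numerical choices and degenerate inputs

- Linking/matching tie-breaks are fixed by the deterministic Hungarian scan
  order; trajectory ids are assigned by (first frame, first x, first y).
- Unlink cost in the padded assignment is exactly `max_disp²` (or
  `cutoff²`); gap-closing costs are squared displacements normalized by
  (gap+1).
- A cell with zero qualifying tracks in a channel reports its dimerization
  level as missing, never 0; missing values are excluded from summaries and
  KS samples rather than imputed.
- Localization CSVs persist coordinates at 0.01 nm; all writers are
  byte-deterministic; readers reject malformed input (missing columns,
  non-numeric rows, truncated TIFFs) instead of coercing.
- `estimate_affine` refuses collinear or < 3 marker configurations;
  `AffineTransform2D` refuses singular linear parts (|det| ≤ 1e−6).

## Known limitations

- The linker has no motion model; identity switches at crossings leak a few
  percent of tracks at high density and are the main residual error in
  mobility classification.
- The relative dimerization level is proportional to, not equal to, the
  true dimerized fraction; only comparisons across conditions sharing a
  labelling scheme are meaningful.
- The oligomer classifier undershoots under incomplete labelling or strong
  blinking (see above).
- Single-emitter fitting saturates above ~1 emitter/µm².
- The asymptotic KS p-value is slightly conservative below ~15 cells per
  condition; the D statistic itself is exact.
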