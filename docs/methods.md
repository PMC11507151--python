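# Methods

`ceplane` quantifies the dynamics of intracranial EEG (iEEG) channels with
two ordinal-pattern information measures — normalized permutation Shannon
entropy and MPR statistical complexity — alongside Welch power spectral
density, and compares the distributions of these quantifiers between
female and male patient groups region by region. This note records the
model, the parameter choices, the numerical conventions, and what the
synthetic validation does and does not establish.

## Ordinal symbolization

A voltage series `x_1 … x_M` is embedded into overlapping vectors
`(x_t, x_{t+τ}, …, x_{t+(D−1)τ})`, giving `n = M − (D−1)τ` vectors. Each
vector is reduced to the permutation that sorts it ascending; the
permutation's lexicographic rank in `[0, D!−1]` is the pattern id.
The relative frequencies of the `D!` patterns form the Bandt–Pompe
probability distribution `P`. Because only rank order enters, `P` is
invariant under `x → a·x + b` for `a > 0` — the measures are insensitive
to amplifier gain and offset.

**Ties.** Recorded voltages are quantized, so exactly equal samples occur.
Ties are broken by temporal order (stable sort: the earlier sample ranks
lower). This is the convention of the common reference implementations
and makes the map from vector to pattern total, so every vector counts
exactly once.

**Sampling requirement.** The histogram is meaningful only when `n ≫ D!`.
The package enforces `n ≥ D!` as a hard error and warns below
`5·D!` (configurable via `EmbeddingConfig.min_oversampling`). The default
configuration — `D = 6`, `τ = 1`, 15 s windows at 200 Hz, so
`n = 2995 < 5·720` — sits in the warning zone; this is why every analysis
is repeated at `D = 5`, where `n/D! ≈ 25`, and conclusions are read from
the pair.

## Entropy and complexity

With `N = D!` states and `S[P] = −Σ p_j log2 p_j`:

* normalized entropy `H[P] = S[P]/log2(N) ∈ [0, 1]`;
* Jensen–Shannon divergence, written with normalized entropies,
  `J[P, Pe] = H[(P+Pe)/2] − H[P]/2 − H[Pe]/2`, with `Pe` uniform;
* disequilibrium `Q_J = Q_0·J`, where `Q_0 = 1/J[δ, Pe]` (δ any point
  mass), so `Q_J ∈ [0, 1]` with equality at a point mass;
* MPR complexity `C = Q_J · H ∈ [0, 1]`.

`Q_0` is evaluated numerically from the same `J` routine used everywhere
rather than from a transcribed closed form; this makes `C` internally
consistent by construction, and identical to the classical
unnormalized-entropy convention (the `1/log2 N` factors cancel between
`J` and `Q_0`). All logarithms are base 2; `0·log 0 ≡ 0`; probabilities
below 1e−15 are treated as exact zeros.

`C` vanishes at both extremes — perfect order (`H = 0`) and full
randomness (`J = 0` at `H = 1`) — and is large for structured broadband
dynamics: the fully chaotic logistic map (`r = 4`) lands at
`H ≈ 0.63, C ≈ 0.48` for `D = 6`, while white noise gives
`H > 0.99, C ≈ 0`. At `D = 3` the logistic map also exhibits its
forbidden pattern (three strictly decreasing samples never occur, because
a decrease requires `x > 3/4` and maps into `(0, 3/4)`), which the
ordinal histogram detects as an exactly zero count.

## Windowing

Channels are cut into non-overlapping 15 s windows (3000 samples at
200 Hz) from the start of the record; a trailing partial window is
discarded, so a 68 s record yields 4 windows with 1600 samples unused.
Records are zero-padded by the upstream source to a uniform 68 s length;
a window containing a run of at least `fs/2` identical consecutive values
is flagged as padding and excluded from quantifier accumulation by
default (a constant run would concentrate mass on one pattern and
masquerade as order). The flag can be overridden.

## Spectral estimation

Welch PSD per channel: blocks of 2 s advanced by 1 s, mean-detrended,
Hamming-weighted, averaged; the first 60 s of each record are used, which
yields exactly 59 blocks and 0.5 Hz resolution (using the full padded
68 s would give 67 blocks and let the zero tail bias the estimate).
The averaged spectrum is restricted to [0.5, 100) Hz — dropping the DC
bin, which is meaningless after padding and detrending — and normalized
to unit total power, removing the arbitrary voltage scale. Group curves
are pointwise medians with interquartile bands across channels.

Band fractions use conventional clinical edges, which the source
metadata never fixes: δ [0.5, 4), θ [4, 8), α [8, 13), β [13, 30),
γ [30, 100) Hz. `peak_frequency` locates the dominant oscillatory peak as
the power maximum inside a search range (default 2–20 Hz) so that the
1/f upturn at the lowest frequencies does not mask it.

## Cohorts and statistics

Channels are grouped by (region, hemisphere) with region labels matched
verbatim. A group enters the analysis only when each sex contributes at
least five **distinct patients**; channels never count twice for one
patient. Ineligible groups are retained but flagged.

Age-matched subsampling selects `k = 5` patients per sex minimizing
`|mean_F − mean_M| + 0.1·(sd_F + sd_M)` — the mean difference dominates,
the sd term prefers tighter age spreads among near-ties — by exhaustive
enumeration of subset pairs (seeded random search with 10,000 draws per
sex above 25 patients, where `C(n,5)` growth makes enumeration
impractical). Ties break toward lexicographically smallest patient ids,
so the selection is deterministic.

Per region and quantifier, window-level values are pooled across channels
and patients of each sex and compared with the two-sided Mann–Whitney U
test: exact null distribution when the smaller sample has ≤ 8
observations and the pooled values are tie-free, otherwise the normal
approximation with tie and continuity corrections (at `n = 8 + 8` the two
routes agree within 0.011, the exhaustively enumerated worst case).
`h = 1` iff `p < α = 0.05`, strict. Each (quantifier, D) family of region
tests is corrected with Benjamini–Hochberg FDR at `q = 0.05`.
Boxplot summaries follow Tukey (linear-interpolation quartiles, whiskers
at the most extreme points within 1.5·IQR, notch `median ±
1.57·IQR/√n`).

**Pseudo-replication caveat.** Pooling window-level values treats windows
as exchangeable observations. Windows from the same channel share that
channel's idiosyncrasies, and channels from the same patient share the
patient's; when channel- or patient-level heterogeneity is present the
effective sample size is smaller than the window count and the test is
anti-conservative. The synthetic experiments quantify this directly: with
homogeneous 1/f channels the null rejection rate is nominal (0.044 for H,
0.046 for C over 1000 cohort pairs), but adding a narrow-band peak whose
realized variance fraction fluctuates channel-to-channel (few spectral
degrees of freedom in a ~1 Hz band over 60 s) inflates it to roughly
0.2. Region-level conclusions from pooled windows should therefore lean
on the FDR-corrected values and on effect sizes, not on marginal
p-values.

## Synthetic cohorts

The generator emulates the *structure* of a wake iEEG atlas cohort — not
its physiology: per-channel series at 200 Hz with a `1/f^β` background,
an optional narrow-band oscillatory peak, a trailing zero-pad to 68 s,
and a metadata table (patient id, sex, age, region, hemisphere). Group
differences are injected as controlled shifts of β and of the peak
frequency between sexes.

Colored noise is synthesized spectrally: complex-Gaussian rFFT
coefficients with standard deviation `∝ f^(−β/2)`, inverse-transformed
and standardized to zero mean, unit variance. Drawing the coefficient
*amplitudes* at random (not only the phases) matters: with deterministic
amplitudes every channel would carry the exact same periodogram, windows
would not behave as independent realizations, and the null calibration of
the rank tests collapses (measured rejection rate ~0.003 instead of
0.05). The oscillatory component is band-limited noise with a Gaussian
spectral envelope (default 1 Hz bandwidth) mixed to carry a specified
fraction of total variance. Each channel has its own RNG stream derived
from (seed, patient index, channel index), so cohorts are reproducible
and insertion-order independent.

Defaults model one analyzed region: 5 patients per sex, 2 channels each,
68 s records with an 8 s zero tail (60 s of signal), `β = 1.5` for both
sexes (a typical wake broadband slope), a θ–α peak at 7.5 Hz (F) vs
9.0 Hz (M) carrying 30% of variance, and ages from normal laws
(F: 30 ± 10, M: 36 ± 10 years) truncated to [18, 65] and rounded to whole
years. None of these effect sizes is an estimate of real iEEG contrast;
they are chosen so that injected differences are comfortably detectable
at atlas-like group sizes.

**What passing tests show — and don't.** The synthetic suite validates
the machinery: exact ordinal bookkeeping, analytic quantifier limits,
nominal type-I error under an exchangeable null, near-certain detection
of a large injected contrast (β 0 vs 2), and recovery of injected
spectral peaks to within one 0.5 Hz bin. It does not validate biological
claims: real channels are heterogeneous, spatially correlated within
patients, and non-stationary, none of which the generator reproduces
(no artifacts, line noise, epileptiform transients, or neural-mass
dynamics).

## Problem sizes in the distributed checks

The validation suite and the reproduction script run on synthetic data
scaled for a single CPU: 1000 cohort pairs for the null calibration, 100
for the power estimate, `10^5`-sample series for uniformity and
forbidden-pattern checks, `10^6` for the logistic-map complexity bound.

## Known limitations

* The U test's pooling unit (windows) is a design choice; patient-level
  aggregation would be conservative but robust to pseudo-replication.
  The choice is exposed, and the caveat above quantifies the stakes.
* Band edges, the PSD span (60 s), and the age-matching objective weight
  (λ = 0.1) are conventions where the domain fixes none; all are
  configurable.
* EDF export quantizes to 16-bit integers over each channel's physical
  range (correlation with the source signal > 0.999999 in round-trip
  tests); the NPZ bundle is lossless.
* Real-data mode reads EDF via MNE and matches metadata verbatim; it has
  been exercised only on files produced by the built-in writer.
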