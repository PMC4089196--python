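# Methods

## Scope and data model

All analyses operate on daily series over a fixed study window (default
2009-05-01 … 2009-07-31, 92 days): pollen counts per station and taxon
(grass, birch; grains/m³ per 24 h), a regional search-volume index
(0–100 after normalization), and per-patient diaries (six symptom
grades 0–3 plus four medication-class flags per day). Days without an
observation are *gaps*, not zeros — a missing diary day drops out of
cohort means, and gap days propagate through alignment rather than
being imputed. Tables are plain CSV; a daily series in memory is a
date-indexed pandas Series.

## Scoring

RTSS is the sum of the six symptom grades (0–18). TRMS assigns points
per medication *class* per day — chromone eyedrops 1, oral
antihistamine 2, nasal corticosteroid 3, leukotriene antagonist 5 —
so repeated intakes of one class on one day count once; the achievable
TRMS values are the subset sums of {1, 2, 3, 5}, i.e. every integer
0–11. CSMS = RTSS + TRMS exactly, per patient-day. A day with a symptom
record but no medication record scores TRMS 0 (absence means no use).
Cohort series are the unweighted mean CSMS over patients with an entry
that day, with the per-day contributor count reported alongside.
Weekly averages (ISO weeks, stamped on the Monday) exist for plotting
only; every statistic runs on daily series.

## Birch adjustment of search indices

Raw search series are first normalized to max = 100 (the scale on which
public search-volume services report). The adjustment factor on day *t*
is grass_t / (grass_t + birch_t), computed on raw counts from one
explicitly chosen station — no smoothing, no automatic nearest-station
logic, since centre–station pairing is an analysis decision. On a
degenerate day with neither grass nor birch pollen the factor defaults
to 0 (no grass pollen ⇒ no grass-attributable search signal); a config
flag (`degenerate="gap"`) drops such days instead. Adjusted values stay
on the 0–100 input scale without re-normalization: cross-correlation is
invariant to positive scaling, so re-normalizing would change nothing
downstream while obscuring the size of the correction.

## Cross-correlation estimator

For aligned, gap-free sequences of common length n:

* ccf(k) = Σ (x_{t+k} − x̄)(y_t − ȳ) / (n · s_x · s_y), summed over the
  n − |k| valid offsets, with full-series means and population SDs
  (1/n). This is the convention of mainstream statistics packages. A
  consequence worth knowing: even a perfectly shifted copy scores
  slightly below 1 at its matching nonzero lag, because the truncated
  sum is divided by full-series moments.
* Sign convention: negative lag ⇔ predictor leads outcome. ccf(x, y, k)
  = ccf(y, x, −k).
* SE(k) = 1/√(n − |k|), the standard error under independence; it grows
  with |lag| for fixed n. Two-sided p = 2(1 − Φ(|ccf|/se)). These are
  screening statistics: no multiple-testing correction is applied
  across the 15 lags or across series pairs, so p-values are honest
  only per comparison.
* Alignment is listwise (date intersection before the scan), keeping a
  single n per series pair; at least 15 common dates are required —
  below that the SE approximation is meaningless.
* Best lag maximizes the *signed* CCF by default (the screening targets
  positive exposure–symptom coupling); `rule="absolute"` is available.
  Ties break toward smaller |lag|, then toward the negative lag.
* Strength bands: ≤ 0 nonpositive; (0, 0.5) weak; [0.5, 0.8) moderate;
  [0.8, 1] strong.
* Lag window default ±7 days, configurable.

## Subgroups

* IgE classes from kU/L: 0 < 0.35 ≤ I < 0.70 ≤ II < 3.50 ≤ III < 17.5 ≤
  IV < 50 ≤ V ≤ 100 < VI. Boundary values belong to the class whose
  range starts there. "IgE high" = class ≥ III. Patients without IgE
  information are excluded from that split with a logged warning, never
  guessed.
* CSMS split: each patient's mean daily CSMS over the period; the
  cohort mean is the *unweighted mean of per-patient means* (robust to
  unequal diary completeness, unlike a grand mean over patient-days);
  "low" is strictly below half of it, ties go to "high".
* Severe/mild pooling conjoins IgE-high, CSMS-high and asthma for
  "severe" (their complements for "mild"); which criteria are active is
  configurable because a strict three-way conjunction is infeasible in
  cohorts with few or no asthmatics. The default (`asthma_mode="auto"`)
  requires the asthma criterion only when the cohort contains at least
  one asthmatic. Patients meeting a mix of criteria belong to neither
  pooled group.
* The pipeline analyses low-n groups (even n = 1) but flags any group
  under 5 patients in the audit log; empty groups are skipped with a
  warning.

## Synthetic studies

The generator emulates one centre's season with known ground truth:

| parameter | default | why |
|---|---|---|
| window | 2009-05-01 – 2009-07-31 | the 92-day diary window of the emulated setting |
| grass season | Gaussian pulse, peak Jun 15, sd 16 d, amplitude 80 grains/m³ | unimodal mid-June grass peak; sd 16 makes the ±3 sd support cover the whole window, so grass pollen is positive on every diary day |
| birch season | peak Apr 25, sd 9 d, amplitude 120 grains/m³ | birch precedes grass; its tail reaches into mid-May, producing early-window search contamination |
| season noise | multiplicative log-normal, σ = 0.35 | day-to-day count variability; the shared daily roughness between exposure and outcome is what makes the lag identifiable at all |
| search signal | baseline 25 + 0.8·grass_{t+1} + 0.8·birch_{t+1} + N(0, 4), clipped at 0 | a positive off-season baseline (the index does not start at 0), equal grass/birch interest, and a 1-day lead: queries anticipate exposure |
| cohort | 20 patients, 50 % severe / 50 % mild | a typical single-centre cohort size |
| coupling | severe 3.0, mild 0.5 (latent-burden gain at peak pollen) | severe patients cross all three grade cut-points (0.5/1.5/2.5) at peak; mild patients stay below one grade step, so their scores are largely noise — this is what yields populated CSMS-low/mild groups and a visible severity contrast in the CCF |
| symptom noise | N(0, 0.4) per patient-day-symptom | ordinal grading variability |
| medication | class fires with probability 0.35/0.55/0.45/0.15 once same-day RTSS ≥ 3/4/6/10 | threshold-probabilistic rescue use, increasing with symptom load; not pharmacodynamic |
| missingness | 5 % of patient-days dropped | incomplete diaries |
| IgE | severe: log-uniform 3.5–100 kU/L (class ≥ III); mild: 0.05–3.4 (class < III) | ties the observable profile to the latent severity |
| asthma | 25 % of severe patients | a small asthmatic subgroup, as such cohorts show |
| RRTSS | uniform 8–18 | the retrospective-score eligibility screen (≥ 8) |

Pollen is simulated a few days past the window so the search signal
(which looks `lead_days` ahead) covers every diary day. All generators
are deterministic under a fixed seed; `truth.json` records lead, mixture
weights, couplings and the severe/mild patient lists for
parameter-recovery tests.

**What passing tests do and do not show.** The generator reproduces the
*structure* the analysis relies on — unimodal seasons, birch/grass
phasing, a search lead, severity-dependent coupling, ordinal scores,
diary gaps — but not the messiness of real data: no weather-driven
multi-peak seasons, no media events decoupled from pollen, no reporting
bias or weekend effects in diaries, no regional heterogeneity of search
behaviour, and its lead is a hard 1-day shift rather than a distributed
anticipation. Recovery of the ground truth here validates the
machinery, not the epidemiological claim on real cohorts.

## Validation problem sizes

The test suite and the acceptance script use 200 random pairs (length
15–50) for oracle agreement against a brute-force double-loop
implementation of the estimator (tolerance 1e-10), 100 independent
synthetic studies (20 patients × 92 days each) for the lag-recovery,
adjustment-benefit and severity-ordering rates, and the exhaustive
4⁶ × 2⁴ grid for scoring exactness. One full study simulates in about
30 ms, so these sizes keep whole-suite runtimes in tens of seconds.

## Other numerical choices and limitations

* Results tables round ccf/se to 3 decimals (round-half-even) and band
  p-values as "<0.001", "<0.01", or the exact 3-decimal value; the
  un-rounded p is always emitted in a machine column.
* End-to-end runs are deterministic: identical inputs, config and seed
  give byte-identical output files.
* The CCF/SE/p conventions reconstruct what general-purpose statistics
  software computes; other estimator conventions (pairwise-per-lag
  alignment, 1/(n−|k|) scaling, Bartlett SEs) would shift values
  slightly and are deliberately out of scope, as are prewhitening,
  spectral methods, and any causal reading beyond the lag sign.
* Keyword discovery against live search services is out of scope; the
  package starts from an already-extracted search-volume series.
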