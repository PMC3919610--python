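# Methods

## Model overview

One replication fork on an effectively infinite concatemer of a circular
template. Three coupled processes:

1. **Leading strand / fork.** Advances deterministically at `v_lead`
   (default 420 nt/s, the measured leading rate on the minicircle),
   exposing lagging-strand template. Its product *is* the lagging-strand
   template, so its dCMP label count equals the template C count over the
   extent traversed.
2. **Priming.** Either a Poisson process in time at the fork with rate
   `v_lead / target_spacing` (DnaG mode; default spacing 1500 nt, the
   physiological 1–2 kb range), or, in exogenous mode, a Bernoulli trial
   with probability `p_anneal` (default 0.23) at each passage of the fork
   over the template's unique site, which makes inter-primer spacings exact
   multiples of the circle length with geometric multiplicity
   (mean 409/0.23 ≈ 1778 nt, matching the ~1800 nt observed). DnaG primers
   are 12-mer RNA whose G+U content is read off the template (C and A
   positions under the primer); exogenous primers are 15-mer DNA with no
   G+U.
3. **Lagging polymerase.** Exactly one per fork (dimeric replisome with
   substoichiometric polymerase). Per-base dwell is deterministic,
   `1/rate`: the saturated rate `alpha_lag·v_sat` at A/G/T templates and
   the pool-dependent Michaelis–Menten rate `alpha_lag·r_C` opposite C. At
   each C it incorporates ddGMP with probability
   `p = s/(1+s)`, `s = f_sel·[ddGTP]/[dGTP]`, and stalls. Release is
   model-dependent:
   * *signaling* — a new primer deposition releases the polymerase
     (after `signaling_latency`, default 0) wherever it is — elongating,
     stalled, or waiting on a completed fragment — and it re-initiates
     (after `reinit_latency`, default 0) on the most recently deposited
     unused primer; older unused primers are abandoned and scored
     unutilized. A polymerase that finishes before any new primer exists
     waits idle.
   * *collision* — release only via the slow intrinsic pathways, both
     exponential: half-life `t_half_nick` (default 120 s) after completing
     a fragment to a nick, `t_half_stall` (default 480 s, the midpoint of
     the 6–11 min range) from a terminated chain in a gap.
   * *hybrid* — both triggers armed; first one wins.

Simulation is event-driven (primer depositions, nick/stall arrivals,
releases); elongation times over template intervals are computed in closed
form from per-circle C-count prefix sums, and terminator positions by
sampling the geometric count of C's to the first ddGMP. Cost scales with
event count, not with nucleotides, so long runs are cheap. Everything is
driven by one `numpy` generator per run: identical `(config, seed)` gives
identical results.

## Coordinates

Internally positions are fork coordinates (template in order of exposure).
Results are exported with positions along the *lagging-strand product*:
a fragment's interval `[start, end)` begins at its primer's 5′ end, and the
gap-fill assay extends `end` to the next downstream fragment's primer.
The two conventions are mirror images; every length, gap and spacing is
identical. One consequence worth knowing: ascending `start` order is
*reverse* chronological, so trend statistics over successive fragments sort
by `init_time`.

Bookkeeping is exact: fragments + gaps + slack tile the leading extent
(`SimResult.check_conservation`), where slack is the censored span of the
fragment still being synthesized at quench plus the unreplicated region
between the last primer and the fork.

## Calibrated parameters

* `v_chem_dGDPNP` (≈ 13.8 nt/s), the chemistry-limited maximal insertion
  rate opposite C with dGDPNP, is inverted in closed form from the anchor:
  composite velocity 23 nt/s on a 25%-C template at 30 µM analog, with
  `v = 1/(f_C/r_C + (1−f_C)/v_sat)` and `r_C = v_chem·c/(K_m+c)`. The same
  calibration then *predicts* a ≈ 12–13-fold (rather than the reported
  10-fold) slowdown at 240 µM and ≈ 13 nt/s on the 45%-C template; one
  clean anchor was preferred over force-fitting two loose ones.
* `f_sel` (≈ 0.054), the ddGTP-vs-dGTP selection factor, is set so that at
  4 µM ddGTP / 100 µM dGTP the expected fragment length
  `E[min(run, 1500)]` is 750 nt on the default (48.9% C) template, where
  the run to the terminating nucleotide is geometric with per-nt hazard
  `f_C·p`. The test suite re-derives this by brute-force summation. This
  anchor lives in the deterministic-spacing, full-length-fragment regime;
  in the default `alpha_lag = 1` DnaG world, signaling aborts already
  shorten unperturbed fragments, so the simulated 4 µM / 0 µM mean-length
  ratio is ≈ 0.63 rather than 0.50. With a fast lagging polymerase
  (`alpha_lag` ≫ 1) the simulated ratio approaches the anchor.
* `alpha_lag` is the fork-coupled lagging acceleration. The experiments
  imply it is well above 1 with natural nucleotides (lagging synthesis must
  outrun the fork for gaps to be rare) but give no number, so it ships as
  a free parameter with default 1.
* `frac_dC = 0.45` is kept as the quantification constant for the
  leading-strand dC fraction even though the default generated template has
  48.9% C: the integer base counts cannot make 50:1 C:G and 45% C hold
  simultaneously on 409 nt, and 50:1 is the template-design statement while
  0.45 is the constant used in the published analysis arithmetic.

## What the synthetic data does and does not emulate

The gel stage weights each fragment by its labeled-nucleotide count
(dGMP for the lagging label — ≈ 0.489 × length on the default template),
spreads bands log-normally (σ = 0.02 in log10 length) and adds seeded
truncated-Gaussian noise. It reproduces exactly the features the
quantification needs — label-per-length bias, finite band width, an
above-8-kb leading smear for the cutoff — and nothing else: no image
formation, background, lane warping or mobility nonlinearity. A green
lane-statistic test therefore establishes the *arithmetic* of the molar
mean (L = Σd/Σ(d/L), scale-invariant, cutoff-stable, within 2% of the
direct number-weighted mean for narrow bands), not gel physics.

Similarly, the simulator starts from an initialized fork (no helicase
loading, no pre-elongation labeling window), ignores leading-strand ddGMP
events (proofreading removes the rare incorporations on the C-poor leading
template), treats a signaling abort at base resolution, and counts — but
never degrades — unused primers.

## Numerical and design choices

* **Zero-gap regime.** With Poisson (CV = 1) priming and mid-fragment
  signaling release, the expected gap fraction is
  `v_lead/(v_lead+v_lag) > 0` for any finite lagging rate: some inter-primer
  intervals are always too short for the previous span to be finished.
  "Balanced synthesis has no gaps" is exact only for regular priming
  intervals, which the exogenous mode provides at `p_anneal = 1`; that
  deterministic limit is what the no-gap acceptance property tests. With
  DnaG priming, gaps shrink as `alpha_lag` grows but never reach zero.
* **Linearity statistic.** The bulk assay measures incorporation summed
  over very many forks, so linearity (R² of cumulative lagging synthesis)
  is assessed on the replicate-averaged curve; single-fork curves are
  staircases with R² ≈ 0.95.
* **Ties and degeneracies.** Simultaneous events are ordered
  nick/stall < release < signal < primer < bind. A primer annealing within
  a primer-length of already-replicated DNA is skipped (stays unused),
  which caps spacings at the primer length under saturating priming. A
  zero elongation rate never raises: the open fragment is closed with a
  `timeout` flag at the end of the run and its unfinished span is scored as
  slack, not gap.
* **Gap fill** extends to the downstream primer's 5′ end (the 3′-end
  alternative differs by 12–15 nt and is not resolvable from the assay),
  is idempotent, and refuses ddGTP-containing runs because no polymerase
  removes the terminator without strand displacement.
* **Rounding.** Utilization percentages are averaged after integer
  rounding and priming ratios before 4-dp rounding — the only pair of
  conventions that reproduces the published averages (66%, 0.0051). Both
  are switchable. Halves round away from zero. Known irreproducible cells:
  the 30 µM utilization average (prints 50, computes 51) and two per-row
  ratios (0.0081 vs computed 0.0082; 0.0098 vs 0.0097).

## Limitations

Single fork only (no shared protein pools), no SSB dynamics, no
single-nucleotide kinetic substeps or proofreading kinetics, no τ-complex
acceleration of release, and no fitting of `alpha_lag` to gel data (none is
deposited); figure-level claims are therefore covered by property tests
(monotonicity, linearity, tiling, banding), while the machine-checked
numbers are the table arithmetic, the rate calibration and the template
composition.
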