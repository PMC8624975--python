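# Methods

## Scope and assumptions

The model describes spatially averaged ("single-compartment") Ca²⁺ dynamics
in a mouse skeletal muscle fiber during electrically evoked twitches and
100 Hz tetani, at 22 °C. Three well-mixed pools exchange Ca²⁺ — sarcoplasm,
SR and mitochondrial matrix — plus a fixed extracellular bath tracked only
through a cumulative ledger. Release is a *prescribed* flux: there is no
voltage, action-potential or RyR gating model, so the SR cannot refuse to
release when depleted. Intra-compartment gradients, force generation, pH,
phosphate and thermal effects are out of scope. Fiber types differ only
through their parameter presets (volume fractions, buffer totals, transport
capacities); the reaction rate constants are shared.

## State, units, bookkeeping

Internal units are µM, ms and mV. Each concentration is referenced to its
home compartment's volume (SR free Ca²⁺ and CaCSQ to the SR, matrix free
Ca²⁺ and CaB to the mitochondria, everything else to the sarcoplasm). A
flux J stated per sarcoplasmic volume changes the SR state by
`J · v_sarc/v_SR` and the matrix state by `J · v_sarc/v_mito`; the audit
quantity

    Ca_total = free+bound (sarcoplasm)
             + (free+CaCSQ)/(v_sarc/v_SR)
             + (free+CaB)/(v_sarc/v_mito)
             + NCX ledger − SOCE ledger − sarcolemmal leak · t

is analytically constant, and its numerical drift (~10⁻¹² µM at default
tolerances, threshold 10⁻⁶ µM) is attached to every run. A magnesium audit
(free + MgPV + MgTNS + MgATP) is tracked the same way.

The MCU and NCE maximum rates are matrix-referenced: they were estimated
from matrix Ca²⁺ kinetics, and applying them sarcoplasm-referenced would
overfill the matrix by roughly the volume ratio (~5–10×). The sarcoplasm
correspondingly sees `(J_MCU − J_NCE)/(v_sarc/v_mito)`. SERCA, NCX and
SOCE capacities act on sarcoplasmic Ca²⁺ and are sarcoplasm-referenced.
The published NCX capacity for type I is read as 93.2 µM s⁻¹ (not ms⁻¹):
the ms⁻¹ reading would make a single twitch export more Ca²⁺ through the
sarcolemma than SERCA returns to the SR, contradicting the observed
NCX/SERCA capacity ratio of a few percent.

## Resting state and compensatory leaks

At 106 nM resting Ca²⁺ neither SERCA nor NCX is silent (resting SERCA flux
is 0.03–0.12 µM ms⁻¹ depending on fiber type), so the raw equations drift.
Two constant leaks, sized once at initialization, make rest exactly
stationary: an SR→sarcoplasm leak equal to resting SERCA, and a sarcolemmal
inward leak equal to resting NCX minus resting SOCE. Resting matrix Ca²⁺ is
not a free parameter: it is solved from `J_NCE(c) = J_MCU(rest)` (bisection
to 10⁻¹⁴ relative), giving ~2.8 nM–3 µM depending on the preset's NCE/MCU
balance. Leak sizes and the solved matrix rest are exposed via
`ModelSystem.leak_report()`. Bound species start at their exact algebraic
equilibrium (closed forms exist for every scheme, including the 2:1 dye via
a numerically stable quadratic), so the physical right-hand side vanishes
at t = 0 to float precision; the ledger components integrate their resting
fluxes by design, and the summary statistics subtract those baselines.

## Release waveform

`J_Rel(t) = Σ_j f_rel,j Σ_i R_i exp(−((t−(j−1)T₂−T1_i)/τ_i)²)`. A single
Gaussian is symmetric and cannot meet the asymmetric rise/decay targets, so
the default is N = 3 (dominant peak + leading and trailing satellites).
The shape (relative amplitudes, center offsets, widths) is fitted by
bounded least squares on four residuals — rise, half-width, decay, and
integral-to-peak ratio — from a fixed list of three deterministic starts
(≤250 evaluations each); amplitudes are then rescaled so the measured peak
is exact, and the waveform is translated so `J(0) ≤ 10⁻⁷ × peak`
(causality). Metrics and the integral are measured translation-invariantly
(full-support grid; closed-form `√π Σ R_i τ_i`), which matters: measuring
them on `t ≥ 0` before the causality shift lets the optimizer hide Gaussian
mass at negative times. The single-AP integral target (the released amount
over one twitch) is enabled by default; it pins the waveform scale that the
four shape metrics alone leave free. Per-AP factors scale amplitudes only,
so the train integral is exactly `Σ f_rel` times the single-AP integral.

## Reaction network

All buffers follow mass action. Fast-fiber troponin is a sequential
two-site scheme on 120 µM of molecules (240 µM of sites) with statistical
factors 2k₊ on the empty molecule and 2k₋₂ off the doubly occupied one;
positive cooperativity is a 40-fold off-rate reduction at the second site.
With the first-site Kd at 2.0 µM this puts resting occupancy near 5 % and
peak occupancy near 99 %, which is what the observed twitch ΔCaTn
(~198 µM of a 210 µM rescaled pool) requires. Slow-fiber troponin is a
single 1.0 µM-Kd site — note a single site physically caps ΔCaTn at
~97 µM for a 119 µM pool when free Ca²⁺ peaks at ~10 µM, since occupancy
cannot exceed its equilibrium at the peak. Parvalbumin and the troponin
Ca/Mg sites compete for Ca²⁺ and Mg²⁺; PV's Mg off-rate sits at the fast
end of reported values (Kd preserved at ~91 µM), which controls how fast
PV converts from its Mg-loaded resting form into the dominant slow Ca²⁺
sink of IIX/IIB decay. ATP binds Ca²⁺ fast and weakly (Kd 220 µM) and Mg²⁺
at Kd 100 µM. The dye is one elementary step `Ca + 2D ⇌ CaD₂` whose
equilibrium constant (1.652×10⁵ µM²) equals the in-situ calibration
constant and whose on-rate makes the dye track free Ca²⁺ with sub-ms lag.
CSQ (Kd 1 mM) and the matrix buffer B (Kd 50 µM) are single reversible
sites. Troponin totals are stated per myofibrillar-space water volume and
rescaled once by `v_MS/v_sarc`.

Rates are data, not code (`casim/data/rates.yaml`), each entry tagged with
its source and reference temperature; entries at 16 °C are brought to 22 °C
with Q₁₀ = 2 applied equally to k₊ and k₋ (Kd invariant). Where the cited
literature leaves latitude — the troponin cooperativity factor and
first-site Kd, PV Mg-exchange speed, CSQ/B affinities, the dye on-rate —
the values here were chosen once so that the full simulation reproduces the
published per-fiber-type summary statistics, and are not solver knobs.

A note on magnesium totals: the stated total Mg (3.3 mM) is inconsistent
with 5–8 mM ATP at any literature MgATP Kd (resting MgATP alone is
~5–7 mM). The model therefore anchors on resting *free* Mg²⁺ (0.78 mM),
derives all Mg-bound pools at equilibrium, and conserves that implied
total; the stated total is kept as metadata.

## Numerics

The stiff system (19 states; fastest eigenvalues ~30 µs from the dye and
ATP steps) is integrated with BDF at rtol 10⁻⁸, atol 10⁻¹⁰ µM, max step
1 ms, dense output every 0.01 ms. These defaults hold the conservation
audit near 10⁻¹² µM; tightening tolerances 10× moves reported peaks by
<0.1 %. Peaks and minima are refined parabolically around the discrete
extremum. Trace metrics interpolate level crossings linearly between
bracketing samples; the baseline defaults to the median of pre-onset
samples (median, not mean, so sub-threshold rising-limb samples cannot
inflate it). Degenerate inputs fail loudly: saturated fluorescence names
the offending sample, non-finite derivatives name the offending flux,
negative bound states raise before integration proceeds.

The calibration inverse and the dye equilibrium both use conjugate-form
quadratic roots; the naive forms lose 5–6 digits exactly in the working
regime (F near F_min, Ca ≪ K_d/D_T).

## Synthetic recordings

The fixture generator emulates a Mag-Fluo-4 recording: a free-Ca²⁺ pulse
(Gaussian activation × biexponential decay — smooth at its maximum, which
matters for unbiased peak estimation under smoothing) is shaped by a
deterministic fit to requested rise/half-width/decay, scaled to a requested
peak, summed over APs with per-AP factors, mapped through the inverse
calibration and overlaid with additive white Gaussian noise (seeded). It
emulates kinetics and noise amplitude only: no photobleaching, motion
artifacts, photon-counting statistics or baseline drift, so tests passing
on fixtures demonstrate the correctness of the calibration and metric
pipeline, not robustness to every experimental artifact. For noisy traces
the recommended pipeline smooths in the *fluorescence* domain before
calibrating (Savitzky-Golay, ~1.5 ms window) and clips sub-F_min samples:
the low-affinity 2:1 calibration amplifies baseline noise ~50-fold and its
convexity rectifies it upward, so calibrate-then-smooth is biased while
smooth-then-calibrate keeps the 100-replicate peak bias at ~+0.3 %.

The calibration formula follows the stated grouping
`(K_d/D_T)(F−F_min)(F_max−F_min)/(F_max−F)²`; a first-principles derivation
of the 2:1 scheme yields the same expression times ½. Both are monotone
bijections differing by a constant factor, and the package uses the
calibration and its inverse consistently, so no observable quantity in the
simulation pipeline depends on the choice.

## Known limitations

* Prescribed release ignores store feedback: with sufficiently slow CSQ
  kinetics the SR free Ca²⁺ could be driven negative; with the default CSQ
  rates it stays well positive in all presets and protocols.
* Under strict mass conservation the type I SR pool must supply ~4 mM
  (SR-referenced) for its stated twitch release; with a 23 mM single-site
  CSQ this drives SR free Ca²⁺ to ~54 % of rest, and correspondingly large
  CaCSQ depletion. Fast-fiber SR depletion (61–63 %) and store minima are
  reproduced; the type I SR minimum is not reproducible under conservation
  with a single-site luminal buffer.
* Mitochondrial uptake in type I integrates to ~2.5 µM (matrix-referenced)
  over a twitch given the stated MCU capacity and the simulated transient's
  duration; orderings across fiber types (I ≫ IIA ≫ IIX ≥ IIB) are robust,
  absolute matrix peaks are the least constrained numbers in the model.
* TNS kinetics consistent with the cited sources buffer more Ca²⁺ than the
  published TNS peaks suggest; reducing TNS participation inflates the
  free-Ca²⁺ tail and the NCX ledger by ~30–50 %, so the literature-style
  TNS values are kept.
* The tetanic envelope of slow fibers summates less than observed; the
  model is constrained to its single-twitch removal fluxes, which decay the
  inter-AP Ca²⁺ faster than the recordings suggest.
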