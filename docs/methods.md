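# Methods

## The model

`rewiremap` simulates the experience-dependent development and
reorganization of orientation maps in primary visual cortex as stochastic
rewiring of thalamo-cortical (geniculo-cortical) afferent synapses.

**LGN front end.** The model LGN is a periodic lattice (24×24 at full
scale) of four cell types: ON/OFF center (μ₁ = ±1) crossed with
non-lagged/lagged timing (μ₂ = ±1). Each cell has a separable
spatiotemporal receptive field: a difference-of-Gaussians (DOG) spatial
kernel

    S(d) = μ₁ [ N(d; λ_c) − κ_s/c N(d; λ_s) ],   N = normalized Gaussian,

with center extent λ_c = 0.225°, surround extent λ_s = 0.9°, and balanced
surround κ_s/c = 1, and a windowed damped sinusoid in time (decay 100 ms,
frequency 5 Hz, window 200 ms; the lagged kernel is sign-inverted,
envelope-reversed, and delayed by 57 ms). The response to a drifting
sinusoidal grating (0.4 cyc/deg, 4 Hz by default — the frequencies the
DOG and temporal kernels band-pass) is the half-rectified space–time
convolution of kernel and stimulus.

Because the periodic steady-state drive is a pure sinusoid in time, the
response table evaluates it in closed form: the DOG Fourier transform at
the grating's spatial frequency (radial, hence exactly independent of
drift direction), times the discrete transfer of the 5-ms-sampled temporal
kernel at the grating's temporal frequency, times a spatial phase set by
the cell's receptive-field center. A pixel-grid quadrature route
(0.125°/pixel, window of 4 surround extents) implements the same
convolution numerically and agrees with the closed form to ~2·10⁻⁵
relative; it serves as a cross-check, not the production path. Time
averages of rectified responses use the exact rectified-sinusoid mean
|A|/π, so the orientation-invariance of LGN means holds to machine
precision.

**Response units.** A discrete convolution has an arbitrary overall scale
(it depends on the sampling step). Responses are expressed in units of
the modulation evoked through the non-lagged kernel by a unit-contrast
stimulus at the receptive field's own characteristic frequency (unit
temporal gain at f_RFfreq). This puts LGN rate modulations at O(1) and,
importantly, fixes the absolute scale of the synapse growth rates: with
this convention the rewiring phase transition at reduced scale falls at
an inverse temperature of a few tens, so that the operating point β = 250
is well inside the ordered (map-forming) phase and β = 5 well outside.
Other conventions merely rescale β; this one keeps the quoted β values
meaningful.

**Cortex.** Neurons form a periodic lattice (48×48 at full scale,
spacing 50 length units), each with a disk-shaped dendritic field of 254
synaptic sites (square-packed at 15 units; the exact `n_sites` lattice
points closest to the soma). Each site hosts exactly one afferent synapse;
per-neuron synapse counts are conserved by construction. The dendrite is
electrotonically compact: the afferent membrane potential is
ς_aff = v Σ n·η_LGN with coupling v = 0.045, independent of site position.
The firing threshold ϑ is homeostatic — the long-time mean of the
potential over the active stimulus ensemble — and the afferent rate is the
half-rectified deviation η_aff = (ς_aff − ϑ)Θ(ς_aff − ϑ).

**Lateral interactions.** Short-range excitation / long-range inhibition,
a DOG with extents λ_ex = 82 and λ_inh = 328 length units, strength q = 4,
balanced (κ_inh/ex = 1). The DOG is a continuum density; the coupling
matrix over lattice neurons uses the density integrated per lattice cell
(density × a_cell²). This preserves the two properties that matter: the
balanced kernel sums to ≈0 over the lattice (no net drive from uniform
activity), and its transfer function keeps an O(1) peak gain ≈ q(e₁−e₂)
≈ 3 at the map wavelength Λ = 2π √[(λ_inh²−λ_ex²) / (2 ln(λ_inh²/λ_ex²))]
≈ 17 lattice spacings — the coupling that organizes neighbors into smooth
orientation domains. Without the per-cell normalization the lattice
coupling is smaller by a_cell² ≈ 2500 and no collective organization is
possible at any β. The matrix is truncated at 3λ_inh (minimum-image
periodic distance) and its diagonal is zero. Reported cortical rates add
the first-order lateral correction, gated by the neuron's own
suprathreshold indicator, and are clipped at zero where strong inhibition
would drive the linearized rate negative; the growth rate keeps the
linear lateral terms.

**Synapse growth rate.** Competition among transient synaptic contacts is
winner-take-all (the competitive Lotka–Volterra system retains only the
contact with the largest growth rate; `lv_steady_state` demonstrates
this, with an ODE-integration cross-check). The activity-dependent growth
rate of a candidate afferent c at neuron i combines a potentiating term
gated by suprathreshold episodes (coincident backpropagating spikes,
i.e. mBDNF-dominated release) and a depressing term for subthreshold
coincidence (proBDNF-dominated), with depression/potentiation efficiency
c_D/P = 2:

    ⟨b⟩ = (1+c)[⟨η_aff η_c⟩ + ϑ⟨Θ η_c⟩] − c⟨ς η_c⟩
          + (1+c)⟨Θ L η_c⟩ − c⟨L η_c⟩ ,

with L the summed lateral drive and ⟨·⟩ the mean over stimuli and time
samples. `cortex.growth_rate` implements this general five-term form. The
engine evaluates it on the *deviation* of the potential from its
homeostatic set point (ς → ς − ϑ, ϑ → 0), where it collapses to

    ⟨b⟩ = ⟨ w η_c ⟩,   w = [Θ(Δς) − c(1−Θ(Δς))] (Δς + L).

This centering is a deliberate design choice. The afferent potential is a
sum of rectified responses and carries a large DC (≈ v·n_sites·mean rate);
evaluated on the raw potential, the DC-amplified term (1+c)ϑ⟨Θη_c⟩
dominates every growth-rate difference by ~60× over the lateral terms — a
ratio invariant under every free normalization — and no orientation map
can then form at any β (verified empirically: neighbor alignment stays at
noise after several MC steps at full scale). On the centered potential,
afferent and lateral contributions are commensurate, maps form at β = 250
within ~1.5–2 MC steps at full scale, and a critical β of order tens
separates map-forming from non-forming regimes — the documented
phenomenology of this model class. Physically, centering says the
BDNF-release terms respond to deviations from the neuron's adapted
operating point, the same quantity whose positive part is its firing rate.

One consequence worth knowing: with c_D/P = 2 the depression weighting
makes a candidate firing during *sub*threshold episodes of the centered
potential outscore the exactly in-phase candidate. This inverts absolute
receptive-field *phase* preference (ON↔OFF labeling) but not orientation,
which is phase-blind; in practice it scrambles the spatial-phase map while
orientation maps remain smooth — the behavior reported for this model
class (random phase maps, band-pass orientation maps).

**Monte-Carlo rewiring.** One MC step = one trial per synaptic site on
average (585 216 trials at full scale); the trial counter is the
developmental clock t (in MC steps). Each trial:

1. pick a uniform random synaptic site;
2. pick a uniform random candidate from the site's retinotopic pool —
   a 9×9 window of LGN positions × 4 types (324 slots) centered on the
   LGN position corresponding to the site (neuron retinotopy + site
   offset × cortex→LGN magnification);
3. pass the candidate through the age-dependent spine-contact gate
   P = 1/(1+e^{−βg(t)}), g(t) = −ξ_max (t/(T_p+t))⁴ with ξ_max = 0.8,
   T_p = 15.75 MCs — the p75^NTR-mediated closure of the sensitive
   period (P = 1/2 at t = 0, ≈ 3.7·10⁻⁶ at t = T_p);
4. compute ⟨b⟩ for the current and the candidate synapse (the candidate's
   with the post-swap potential) and replace with probability
   1/(1+e^{−β(⟨b_new⟩−⟨b_old⟩)}), β = 250.

Thresholds and the lateral drive adapt once per MC sweep, on a canonical
schedule tied to the global trial counter, so splitting a run into
segments cannot change its trajectory. The initial wiring draws every
site uniformly from its candidate pool (a rough retinotopic projection).
Proposing the currently-wired cell counts as a null trial.

Each trial consumes exactly six pre-drawn uniforms (site, pool offsets,
type layer, gate, acceptance) from a single seeded PCG64 stream. The
compiled (numba) sweep kernel and the pure-Python reference trial walk
the same stream, which the suite uses to verify their equivalence
trajectory-for-trajectory; checkpoints store the bit-generator state so
resumed runs are bit-identical to uninterrupted ones.

## Stimulus ensembles and protocols

Normal vision is modeled as the balanced presentation of gratings
drifting in 24 directions (12 orientations × 2 directions); goggle
rearing as a single orientation (vertical by default) drifting in its two
directions. ⟨·⟩ averages run over the ensemble and over one full temporal
period (50 samples at 5 ms for 4 Hz); because a drifting grating's onset
phase is equivalent to a time shift, averaging over a full period already
averages over drift phase and no separate phase loop is needed.

The developmental clock maps to kitten age affinely: map formation starts
at t = 0 ≙ P24 and 2.25 MCs ≙ 10 days, so a 2-week exposure is 3.15 MCs
and the sensitive period closes near t ≈ 10 MCs ≙ P68. Exposure onsets
before t = 0 are truncated to their post-t=0 part (plasticity has not
begun), which produces the rising phase of the sensitive-period profile.

Probing freezes the wiring and measures time-averaged, direction-averaged
first-order cortical rates for the 12-orientation battery. From the
tuning curves: vector-sum preferred orientation and magnitude
(pref = ½ arg Σ_θ r e^{2iθ}, mag = |Σ_θ r e^{2iθ}|); 6- and 12-bin
relative-area histograms with bins centered on the stimulus orientations;
the over-representation index ORI = (area@90% − 100/6)/(100 − 100/6)
(the exact 100/6 is used so the uniform histogram gives exactly 0); and
the orientation selectivity index OSI = (1 − r_min/r_max)(1 − w/180),
where the full width at half height w is measured on the 180°-periodic
piecewise-linear curve at half height r_min + (r_max−r_min)/2 (floor-to-
peak convention; the alternative zero-to-peak convention changes OSI
magnitudes but not its qualitative behavior), with linear interpolation
between the 15°-spaced probes, and OSI forced to 0 when the curve crosses
the half-height line more than three times (no unique preference).
Orientation-nonselective neurons are those with OSI = 0 and vector-sum
magnitude below half the cortex-wide mean.

Map structure is quantified by the radially averaged power spectrum of
the complex field mag·e^{2i·pref} and the fraction of non-DC power in an
annulus around the lateral kernel's characteristic wavenumber
(0.5–2.5 × k_peak). Two readouts are recorded: the full first-order rates
(which inherit a band-pass imprint from the lateral kernel even for random
wiring, baseline ≈ 0.46) and afferent-only rates (baseline ≈ 0.2), the
latter isolating the wiring's own organization and serving as the
map-formation classifier (threshold 0.5, midway between the unstructured
baseline and mature maps ≳ 0.75).

## Problem sizes and runtimes

The full 48×48/24×24/254 geometry runs at ≈ 2–6 s per MC step on one
core and is exposed behind `CortexGeometry.full()` (CLI `--full-scale`).
The test suite and the bundled experiments use the reduced geometry —
16×16 cortex, 8×8 LGN, 64 sites (16 384 trials per MC step) — where the
qualitative properties (map emergence above a critical β, the
sensitive-period profile, recovery asymmetry) are scale-robust and each
MC step takes ~0.1 s. At reduced scale the map wavelength is comparable
to the domain, so band-pass structure concentrates in the lowest nonzero
wavenumbers, and the 9×9 pool wraps on the 8×8 LGN (some cells occupy two
proposal slots — harmless, the pool is a proposal distribution). The
critical-β bracketing sweep at reduced scale (6 MC steps) localizes the
transition between β = 30 and β = 250; the precise full-scale critical
value is a long-run property not asserted at desk scale.

## What the generator does and does not emulate

All inputs are synthetic by design: the stimulus ensembles are the
experimental rearing conditions (normal vision ≈ balanced orientations;
goggle rearing ≈ one orientation), not naturalistic movies. Single
spatial/temporal frequencies are presented (the LGN front end band-passes
around them); contrast is fixed; there is no binocularity, no
direction-selective machinery beyond the lagged/non-lagged dichotomy, no
retinal/LGN spontaneous correlations, and no intrinsic-signal imaging
noise. Passing tests therefore show that the rewiring mechanism produces
and reorganizes orientation structure under controlled exposure
statistics — not that it quantitatively matches optical-imaging data from
real kittens.

## Numerical choices and degenerate inputs

- Temporal step 5 ms (must divide the stimulus period; coarser steps are
  rejected); steady-state responses via circular convolution over one
  period with the kernel folded modulo the period.
- Logistic probabilities through `scipy.special.expit` (saturates cleanly;
  β → ∞ reduces to greedy acceptance, verified against an enumeration
  oracle).
- Ties: a tied Lotka–Volterra maximum is a degenerate-input error; equal
  growth rates give acceptance probability ½; an all-zero tuning curve has
  magnitude 0 and undefined (NaN) preference, excluded from histograms.
- Tuning-curve points exactly at half height count as above it when
  counting crossings.
- Histogram binning assigns each preference to the nearest bin center
  modulo 180°.
- Checkpoint restores recompute potentials from counts (no accumulated
  drift); incremental potential updates stay within 10⁻¹⁰ relative of
  batch recomputation over 10⁴ swaps.

## Known limitations

- The centered-potential evaluation of the growth rate is a modeling
  commitment (see above); the raw-potential alternative is available
  through `cortex.growth_rate`'s explicit threshold argument but does not
  self-organize maps.
- Binocular phenomena (ocular dominance, discordant goggles) and the
  late-onset *under*-representation of the exposed orientation seen
  experimentally after ~P60 are outside the model's scope; the model's
  sensitive-period profile declines to zero but does not go negative.
- The minimum-image lateral kernel slightly distorts the balanced-sum
  property when the domain is small relative to λ_inh (reduced scale);
  at full scale the distortion is negligible.
- OSI magnitudes depend on the half-height convention (floor-to-peak
  here) and on the 15° probe spacing through the interpolated FWHH.
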