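# Methods

## The measurement

A ligase-catalyzed cyclization experiment converts the mechanics of a
~200-bp double helix into chemistry. Linear monomers M with cohesive ends
partition between unimolecular ring closure (rate k_C1, s⁻¹) and
bimolecular dimerization (rate k_D, nM⁻¹s⁻¹). Because both reactions pass
through the same ligatable nicked intermediate, the ratio

    J = k_C1 / k_D   (nM)

measures the effective concentration of one terminus, correctly aligned,
in the neighborhood of the other. J(L) across a window of lengths spanning
one helical turn is then interpreted with a wormlike-chain (WLC) model to
yield the bending persistence length P, the helical repeat γ₀, and the
torsional rigidity C.

The stoichiometry convention is fixed so that J equals the plain rate
ratio with no factor of two (dD/dt = k_D M², dM/dt loses 2k_D M²); the
bundled rate tables confirm this identity numerically. Note that part of
the cyclization literature defines J = 2k₁/k₂ — comparisons across studies
must check the convention.

## The J-factor model

The model factorizes the J-factor into a torsion-blind bending term and a
torsional (topoisomer) modulation:

    J(L) = J_bend(L; P) · F_twist(L; P, γ₀, C).

**Bending term.** The closed-form ring-closure factor for a WLC with
aligned ends,

    J_bend = 112.04 (L/P)⁻⁵ exp(−14.054 P/L + 0.246 L/P) / (2P)³

in molecules/nm³, converted to nM at the surface. The exponential carries
the elastic energy of the optimal closed (teardrop) configuration,
≈ 14.054 k_BT·P/L; the approximation is accurate in the stiff regime and
degrades for L/P ≳ 6, where the code emits a warning (fatal errors are
reserved for invalid domains). The absolute normalization — where the
Kuhn-length volume (2P)³ and Avogadro's number sit — was fixed by
requiring that forward-evaluating the bundled reference parameter sets
reproduces the corresponding measured J tables (the natural-DNA set agrees
point by point within its uncertainties; see Limitations). A per-P³
normalization, the other convention in circulation, over-predicts those
tables by roughly an order of magnitude and is rejected by the same check.

**Twist term.** Ring closure quantizes linking number. The probability
that the closing chain lands on integer Lk, relative to a torsionally
unconstrained closure, is a Gaussian sum over topoisomers:

    F_twist = Σ_Lk (2π σ²)^(−1/2) exp[−(Lk − Lk₀)² / (2σ²)],
    Lk₀ = n_bp/γ₀,    σ² = ⟨ΔTw²⟩ + ⟨ΔWr²⟩,

summed over the seven integers nearest Lk₀ (a config knob; widening to 15
changes J by < 10⁻⁴ relative for all realistic parameter sets, because
σ ≲ 0.35 turns at these lengths). The twist-fluctuation variance is the
linear-chain result ⟨ΔTw²⟩ = L k_BT/(4π²C) in turns².

**Writhe variance.** The writhe fluctuation of small relaxed circles,
⟨ΔWr²⟩, is taken from our own Monte Carlo of closed discrete wormlike
rings (`dnamech.ring_mc`): crankshaft Metropolis sampling of 64-segment
rings with discrete-WLC bending energy, writhe evaluated with the exact
pairwise Gauss-integral formula for polygons. Over reduced lengths
L/P ∈ [0.9, 3.2] the results follow

    ln⟨ΔWr²⟩ = −7.0429 + 2.2470 ln(L/P) + 0.0692 (L/P)

to within ~10% (⟨ΔWr²⟩ ≈ 0.0009 at L/P = 1 rising to 0.013 at 3.0);
the curve is frozen in `wlc_model.writhe_variance` and regenerable with
`scripts/calibrate_writhe.py`. Discretization was checked at 96 segments
(agreement within statistical error). For ~200-bp fragments the writhe
term is a small correction (3–10% of σ²), but it sets the floor of the
linking variance in the stiff-torsion limit. In the ideal-WLC reduction
⟨ΔWr²⟩ depends on L and P only through L/P.

## Fitting

The estimator minimizes the weighted sum of squares
Σ_m [(J_m − Ĵ_m(p))/σ_m]² over p = (P, γ₀, C) with bounded trust-region
least squares from multiple starts: the supplied initialization (default
P = 50 nm, γ₀ = 10.5, C = 2×10⁻¹⁹ erg·cm), a deterministic sweep of
helical-repeat candidates, and eight seeded Latin-hypercube draws. The
returned minimum is the best over all restarts; convergence tolerances are
xtol = ftol = 10⁻¹², with parameters scaled by (50, 1, 2).

**Helical-repeat identifiability.** On a narrow length window (six to
eleven lengths spanning ~one turn) the cost surface is near-periodic in γ₀
with period ≈ γ₀²/n ≈ 0.5 bp/turn: phase aliases near 10.0, 11.1 and 11.7
fit almost as well as (sometimes marginally better than) the B-form well
near 10.5, and are artifacts of the window, not physical solutions. The
default parameter box therefore restricts γ₀ to a single phase well,
[10.15, 10.85] bp/turn, which covers the full range reported for B-family
duplexes (≈10.27–10.76); the box is configurable for polymers expected
outside that family. P ∈ [10, 120] nm and C ∈ [0.05, 8]×10⁻¹⁹ erg·cm are
generous bounds that exclude pathological wells.

**Uncertainties.** Parametric Monte Carlo, following the original
analysis: draw J*_m ~ Normal(J_m, σ_m²) (negative draws are redrawn —
J is a concentration — and counted), refit warm-started from the point
estimate, and report the per-parameter standard deviation (ddof = 1), mean
and relative bias (mean/point-estimate − 1) over N_sim simulations
(default 10,000; the test suite uses 1,000). Identical seeds give
bit-identical results. On the natural-DNA dataset the maximum relative
bias is ≈ 0.1%, and the Monte Carlo sds (±0.25 nm on P, ±0.004 on γ₀,
±0.21×10⁻¹⁹ on C at N_sim = 10⁴) match the reference values.

Torsional rigidity converts to twist persistence length as
P_t = C/(k_B T) with T = 295.15 K (ligations run at ~22 °C); this
reproduces every bundled (C, P_t) pair within printing precision, which
also validates the temperature choice. Contour length uses an axial rise
of 0.34 nm/bp (standard B-DNA; configurable).

## Kinetic model

Mass-action scheme for species M, D, C_M, C_D with an optional lumped
sink for higher multimers (off by default; when on, one monomer and one
dimer are lost per sink event and the pool is tracked so monomer
equivalents M + 2D + C_M + 2C_D + pool are conserved to the integrator
tolerance, rtol = 10⁻⁹). Integration uses adaptive LSODA; fitting is
Levenberg-Marquardt on log-rates (positivity across decades), all species
weighted equally in concentration units, which matches band-quantitation
noise after per-lane normalization. Dimer cyclization k_C2 is fitted but
not tabulated in the reference data; the synthetic generator defaults it
to 10×k_C1, reflecting the much higher J of dimer-length chains. Fits
with no dimer or no circle signal are flagged non-identifiable rather
than returned silently. A delta-method standard error of J = k_C1/k_D is
derived from the residual covariance in log-rate space for downstream
weighting.

## Melting thermodynamics

Two-state van't Hoff analysis with linear folded/unfolded baselines fitted
jointly with (Tm, ΔH°): signal = base_f(T)(1−θ) + base_u(T)θ, where θ is
the dissociated fraction, K(T) = exp[−(ΔH°/R)(1/T − 1/Tm)], R = 1.987
cal mol⁻¹K⁻¹. The default treats the long-duplex melt as unimolecular
(K = θ/(1−θ), ΔS° = ΔH°/Tm); a bimolecular option adds the
strand-concentration term (K(Tm) = c₀, ΔS° = ΔH°/Tm + R ln c₀). ΔG°₃₇ =
ΔH° − 310.15·ΔS° holds exactly by construction. The initial Tm guess comes
from the extremum of the Savitzky-Golay-smoothed derivative; curves with
no transition above six baseline scatters raise an error. Tm is invariant
under affine rescaling of the signal. Dye-free parameters are ordinary
least-squares intercepts versus dye concentration (≥ 3 distinct levels
required), with intercept standard errors.

## CD helical diagnostics

HDR = Θ(290 nm)/Θ(201 nm), nearest grid point within ±0.5 nm, raw (not
smoothed) ellipticities. Classification bins partition (−1.5, 1.5],
half-open on the left: (0, 0.5] B-type, (−0.5, 0] B/Z-intermediate,
(−1.5, −0.5] Z-type, (0.5, 1.5] A-type; boundary values (0 → intermediate,
0.5 → B-type) are a documented total rule, since strict inequalities would
leave them undefined. Rank correlations of HDR against per-polymer
parameters use Spearman's ρ with average ranks for ties and two-sided
permutation p-values (exact enumeration for n ≤ 8, else 10⁴ seeded
permutations).

## Synthetic data: what it does and does not emulate

Generators reproduce the statistical structure the analysis assumes —
multiplicative Gaussian noise on J-factors (the same normal model the
uncertainty procedure resamples from, truncated at zero), additive
Gaussian noise on band concentrations (floored at zero) and melting signal,
a linear dye effect on Tm (slope +5 °C per 1× dye, chosen to shift Tm by
0.3–1 °C over the 0.06–0.2× design), and smooth CD spectra hitting target
HDRs exactly. Defaults follow the source protocol: 1 nM starting
material, lengths 201–211 bp, 1-min time points over 1–15 min, dye levels
in triplicate, melt curves every 0.1 °C from 50–100 °C, ΔH° = 150
kcal/mol for a cooperative long-duplex transition.

They do **not** emulate gel-quantitation systematics (background
subtraction, lane-to-lane normalization bias), instrument drift between
melt replicates (synthetic replicate Tm spreads are accordingly tighter
than experimental ones), dye-binding equilibria, sequence-dependent
elasticity, or CD band shapes beyond what the diagnostic ratio needs.
Passing closed-loop tests therefore demonstrates correctness of the
estimators under the assumed noise model, not robustness to real-world
systematics.

## Known limitations

* Fitting the bundled J-factor tables reproduces the reference parameter
  sets for natural DNA and variants 2, 3, 4 and 9 within the documented
  tolerances (P within ~3%, γ₀ within 0.01 bp/turn, C within ~5–15%). For
  variants 5–8 no parameter triple of this model family reproduces both
  the printed parameters and their own printed J data: the J levels of
  variants 7 and 8 (~10–15 nM) paired with large reference P values, and
  the very low J of variant 6 paired with a very soft reference C, are
  mutually inconsistent under any smooth bend(P)×twist(C) product model
  (a bending envelope cannot increase with stiffness). Our fits to those
  datasets are the model optima (cost 10–60× below the reference
  parameter sets on the same data) but differ from the reference values;
  consequently the package's nine-polymer twist-stiffness range comes out
  ≈ 4.5-fold rather than the reference 5-fold.
* The closed-form bending factor is an approximation, not the full
  series solution; it is used within its validity range here but should
  not be pushed to L/P > 6.
* The γ₀ estimate is conditional on the B-family phase well; data from a
  wider length range would be needed to resolve the helical repeat
  without that prior.
* The writhe-variance curve is calibrated for L/P ∈ [0.9, 3.2] and
  extrapolated smoothly outside.
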