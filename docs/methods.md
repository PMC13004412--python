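# Methods

This note documents the models implemented by `chronohelix`, their
assumptions, the parameters that matter, and the numerical and design
choices made where the design was genuinely open.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Sequence model and region partitioning

"Coding" is defined as the strand-insensitive union of CDS features;
overlapping features are merged, and the complement is "non-coding".  The
analysis always runs on the forward strand of the reported sequence — none
of the downstream statistics depend on reading frame or translation, only on
composition and ordering, so reverse-complementing would add machinery
without changing any modelled quantity.  GFF coordinates (1-based inclusive)
are converted to 0-based half-open intervals at the parser boundary and
never appear in any other convention internally: for a feature (a, b) the
image is [a−1, b) of length b−a+1.

Ambiguous bases (N) are retained in regions so coordinates stay aligned with
the genome; each downstream consumer decides its own handling (excluded from
entropy frequencies, zero amplitude in encodings, with a warning).

## Qubit encodings

The discrete mapping assigns A→|0⟩, T→|1⟩, C→(|0⟩+|1⟩)/√2 and G→|vac⟩, an
erasure state orthogonal to the qubit space represented computationally by
the zero vector: G sites contribute no projector and the density matrix is
renormalized over the N_eff non-vacuum sites.  The C state is stored
normalized; unnormalized superpositions would silently break the unit-trace
property the rest of the module depends on.  The Bloch-parameterised
generalisation cos(θ_b/2)|0⟩ + e^{iφ_b} sin(θ_b/2)|1⟩ is exposed through
configuration with defaults reproducing the discrete map at
(θ, φ) = (0, ·), (π, 0), (π/2, 0); no default table of
biochemical-descriptor-derived angles ships, because no validated numeric
table exists — the hook accepts user-supplied angles instead.

For dynamics, sequences map to site-basis amplitudes α(A)=1, α(T)=i,
α(C)=(1+i)/√2, α(G)=0, normalized to a unit vector.  An all-G (or all-N)
sequence has no valid encoding and is rejected explicitly rather than
propagated as NaN.

## Entropy and the region-pair statistic

Shannon entropy is compositional (nucleotide frequencies only), in bits,
bounded by 2 for the 4-letter alphabet.  Von Neumann entropy is computed
from density-matrix eigenvalues with a hard cutoff: eigenvalues below 1e-12
are treated as exact zeros, which makes pure states return exactly 0.0
rather than a sign-flipping epsilon.

Genome-level class means are computed per region and averaged unweighted
across regions by default ("a mean over regions"); a site-weighted variant
is available via `entropy_report(..., weighting="site")` since either
reading is defensible and the two differ whenever region lengths are skewed.

The region-pair statistic pairs the i-th coding region with the i-th
non-coding region in genomic order, i = 1..5 by default, using full region
sequences (no truncation to equal lengths — the construction is insensitive
to length imbalance because each side enters only through its own marginal).
The joint matrix (1/n₁n₂) ΣᵢΣⱼ |ψᵢ⊗φⱼ⟩⟨ψᵢ⊗φⱼ| factorizes exactly as
ρ_A ⊗ ρ_B, so the statistic labelled "entanglement entropy" is, by its own
construction, the marginal von Neumann entropy of the kept subsystem: no
quantum entanglement is generated anywhere in this pipeline.  The package
implements the statistic as defined, computes it by both routes (partial
trace of the joint; direct marginal) and asserts their agreement to 1e-9,
and names the corresponding test for what it is — a separability identity.

## Tight-binding dynamics

Each region is a chain with i.i.d. uniform on-site energies in
[0.01, 0.05] eV, nearest-neighbour coupling 0.025 eV, and (for coupled
systems) a single boundary element g = 0.01 eV joining the last non-coding
to the first coding site.  All energies convert eV→J through the single
constant 1.602176634e-19 at the propagation boundary, with
ℏ = 1.0545718e-34 J·s; one conversion point prevents silent unit bugs.

The drive is diagonal on the non-coding block,
λ·10^(dBi/10)·cos(2π f(t) t) with f(t) = f0 + k·t.  The chirp phase is
implemented literally as written — 2π(f0+kt)t, whose instantaneous frequency
is actually f0 + 2kt — with an `integrated_phase` flag providing the
conventional 2π(f0 t + k t²/2) alternative.  The default amplitude is
λ = 1e-4 eV, the value justified by the photon-energy scale at 34 GHz
(hf ≈ 1.4e-4 eV); other quoted amplitudes spanning tens of orders of
magnitude are accepted as configuration but are mutually inconsistent and
ship as presets only.

Two steppers are provided.  `exact_step` applies the one-step unitary
exp(−iH(tₙ)Δt/ℏ) via Hermitian eigendecomposition of the frozen Hamiltonian
(exact for time-independent H at any Δt, second-order for slowly varying
drives) and conserves the norm to floating-point roundoff — the recorded
norm log is asserted to 1e-9 over 1e5 steps.  `euler` is the first-order
explicit update followed by renormalization; without renormalization its
norm drift is positive and grows with Δt, which the test suite demonstrates
rather than hides.  The two agree to first order: over a fixed step count
the terminal-state difference shrinks by ~4× under Δt-halving.

A dimensional caveat the propagator enforces loudly: with on-site energies
up to 0.05 eV and Δt = 1e-13 s the per-step phase EΔt/ℏ ≈ 7.6 rad exceeds π,
i.e. that parameter combination undersamples the dynamics.  The propagator
emits a warning whenever the per-step phase crosses π; the package's default
experiment profiles use Δt = 1e-15 s, where the fastest phase advances
~0.08 rad per step.

## Spectral analysis

Block phase series are per-site unwrapped along time before averaging (a
circular-mean-aware aggregation; naive averaging of wrapped phases produces
branch-cut artifacts).  Detrending removes the least-squares linear trend.
The one-sided power spectrum convention is fixed: P_j = w_j|X_j|²/n with the
mean removed and interior bins doubled, so that Σ P_j = n·var(x) (Parseval,
asserted to 1e-6 relative on every tested spectrum).

The analysis band is the interval swept by the chirp,
[min(f0, f0+kT), max(f0, f0+kT)], padded by one spectral bin per side — no
principled band-edge definition exists for this statistic, so the choice is
pinned to the drive parameters and documented here.  Desk-scale profiles
place the drive frequency on the resolvable part of the grid (tens of bins
above DC over a 2–4k-step window); a 34 GHz carrier over a 10 ns window at
the headline sampling is unresolvable (and the dynamics at that Δt are
undersampled anyway), so the headline-parameter profile exists for
completeness and carries the aliasing warning.

The replicate experiment redraws the Hamiltonian diagonal per replicate
under named substream seeds, computes the non-coding/coding band-power
ratio per replicate for a real partition and for a falsely-split non-coding
control, and compares conditions by Welch's t and Mann–Whitney U (two-sided,
normal approximation).  No multiple-testing correction is applied; p-values
are reported raw with their seeds.

## Double-well proton model

The symmetric quartic well V(x) = V₀[(x/a)⁴ − 2(x/a)² + 1] with a = 1 Å and
V₀ = 0.065 eV (A–T/T–A) or 0.108 eV (G–C/C–G) is a deliberate toy: real
proton-transfer surfaces are asymmetric and environment-dependent, and
nothing here should be read as a quantitative tunneling rate.  Base pairs
are formed by complement from a single strand, so AT≡TA and GC≡CG share
parameters.

The initial state is a Gaussian packet of width σ = 5e-11 m at x₀ = −a,
normalized on the grid.  With this σ the initial right-half probability is
erfc(a/σ)/2 ≈ 0.0023 (the wavefunction convention ψ ∝ exp(−(x−x₀)²/2σ²)
puts the *density* width at σ/√2).

The drive is a linear tilt (λ_pert + ξ(t))·cos(2π f(t) t)·(x/a) with
λ_pert = e·E₀·a·10^(dBi/10).  Noise semantics: the quoted dimensionless
noise amplitude 0.05 is interpreted as the ratio std(ξ)/λ_pert — ξ is added
to λ_pert inside the envelope, so a relative scale is the only dimensionally
coherent reading; an absolute std in joules is also accepted.  ξ is redrawn
i.i.d. per time step (no stated correlation time exists; white noise is the
assumption-minimal choice, and a correlated-noise variant would need a
correlation-time parameter with no source).  Both the static shift f0+Δf
(Δf = 0.0008 Hz) and the chirp f0+kt are implemented; the static shift is
the default.

Propagation is Strang splitting exp(−iT̂Δt/2ℏ)·exp(−iV̂Δt/ℏ)·exp(−iT̂Δt/2ℏ)
with the kinetic factor applied in momentum space via FFT (hence
power-of-two grids).  Both factors are unitary, so the norm is conserved to
FFT roundoff — asserted at 1e-7 over 1e5 steps — and the scheme is
second-order in Δt, verified by a Richardson-style error-ratio test and by
agreement to 1e-4 in P_R with an independent dense Crank–Nicolson propagator
on a 64-point grid.  P_R integrates |ψ|² over x ≥ 0 with half weight at the
x = 0 grid point, which removes a grid-parity bias for symmetric states
(a symmetric packet then gives exactly 0.5).

Noise seeds for region experiments derive from (root seed, base index, pair
class) only — never from the region label — so a control whose pseudo-coding
and pseudo-non-coding segments are the same sequence produces bit-identical
traces and exactly zero paired differences, with noise on or off.  Region
averages weight base pairs equally, then runs equally.

## Closed-form calculators

E = hf, T = 1/f, Δf = f0·H0·Δt, and t = E_act/(n·flux).  H0 defaults to
70 km/s/Mpc (2.268e-18 s⁻¹), the value that reproduces a ~0.0008 Hz drift at
34 GHz over 3 hours.  The per-nucleotide flux (~1e-32 J/s) is an input
constant, not a derived quantity: it cannot be recovered dimensionally from
an energy density times a cross-sectional area alone, so the calculator
treats it as a given.  The additive-antenna assumption (contributions of n
nucleotides add linearly) is exactly that — an assumption the calculator
encodes, not a physical claim.

## Synthetic genomes: what they emulate and what they do not

The generator lays out alternating non-coding/coding blocks matching a
target length, GC content (default 0.65) and coding fraction (default 0.91),
with block counts split as evenly as feasibility allows.  Non-coding blocks
are i.i.d. at the genome GC.  Coding blocks get codon-position-dependent
composition: per position in the codon, probability is reallocated within
the GC pair and within the AT pair (G over C at positions 1 and 3, C over G
at position 2, and analogous A/T skews), scaled by `codon_bias_strength`.
Because the reallocation stays within each GC class, GC content is preserved
exactly at any strength — the knob changes compositional balance, not GC.

Design direction: skewing a composition away from the symmetric split can
only lower its entropy, so in this synthetic model the coding class has
*lower* compositional Shannon entropy than the non-coding baseline (a gap of
~0.09 bits at strength 1, comparable in magnitude to real coding/non-coding
class gaps).  Real genomes can show either sign depending on which class is
more skewed; tests built on this generator therefore check the mechanism —
a detectable, correctly-signed-by-design class difference, and an exact null
at strength 0 — not the sign observed in any particular organism.  At
strength 0 both classes are i.i.d. draws from the same distribution, which
makes the generator an exact null for type-I-error calibration.

What the generator does not emulate: real k-mer statistics, start/stop
codon structure, gene length distributions, strand asymmetries, repeat
content.  Passing tests on synthetic genomes therefore validate the
pipeline's computations and calibration, not any biological claim about a
real genome.

The null-calibration experiment (p-value uniformity across seeds) uses
coding_fraction = 0.5 so the two classes have comparable block lengths:
with strongly unequal lengths the finite-sample bias of plug-in entropy
(≈ −3/(2N ln 2) for a 4-letter alphabet) differs by class and shifts the
t-statistic even under a compositional null.  Equal-length calibration
isolates the property actually under test — that the statistics pipeline
does not manufacture significance.

## Problem sizes

Default experiment profiles are desk-scale, chosen so the full test suite
and pipeline run in seconds to a few minutes on one CPU: tight-binding
chains of 8–16 sites per block with 512–4096 steps at Δt = 1e-15 s;
tunneling on 256-point grids with ~2000 steps and 10–20 bp per region;
synthetic genomes of 1e4–1e5 bp.  Headline-parameter profiles (1e5 steps,
512-point grids, 100-bp windows, Δt = 1e-13 s for chain dynamics) are
available behind explicit flags and carry the undersampling warning above.

## Known limitations

* The "entanglement" statistic cannot exceed 1 bit and never measures
  entanglement (see the separability identity); it is reported because it is
  the defined statistic of this analysis family.
* The drive amplitudes quoted for the chain experiments span mutually
  inconsistent magnitudes across sources; the package defaults to the
  photon-energy-scale value and exposes the rest as presets without
  endorsing any single value as canonical.
* The literal chirp phase 2π(f0+kt)t doubles the effective chirp rate
  relative to the conventional integrated phase; both are available, the
  literal form is the default for fidelity to the construction being
  reproduced.
* Chain dynamics are closed-system (no decoherence); the double well is
  symmetric; none of the physical parameters are calibrated to real DNA.
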