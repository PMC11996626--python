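# Methods

This note documents the models, parameter choices and numerical decisions
behind `lanthascope`, and what the synthetic-data tests do and do not show
about real ocean data.

## The scientific object

PQQ-dependent dehydrogenases (PQQ-DHs) oxidise methanol, ethanol and sugars
in the bacterial periplasm. The metal cofactor that activates the PQQ
quinone is either Ca²⁺ or a trivalent lanthanide (Ln³⁺); the difference is
carried by a conserved active-site motif: a second aspartate two positions
downstream of the first (D-x-D) coordinates the lanthanide, while
D-x-{A,T,S} marks the calcium form. The pipeline classifies catalog proteins
by that motif, quantifies the per-sample lanthanide fraction of PQQ-DH
abundance (fLn), relates it to phosphate, and models the seawater chemistry
that couples lanthanide availability to pH and phosphate.

## Synthetic catalog generator

The generator stands in for a global ocean gene catalog and its
metatranscriptome companion. Its defaults are the study conditions:

| parameter | default | meaning / basis |
|---|---|---|
| `class_mix` | 0.61 / 0.125 / 0.265 / 0 | lanthanide / calcium / unknown / incomplete — the motif split observed across marine PQQ-DHs |
| `logit_intercept`, `logit_slope` | 2.0, −2.0 per (µmol/kg) | expected fLn declines logistically with phosphate; the negative slope mirrors the observed HNLC pattern. Over the phosphate range this spans fLn ≈ 0.87 → 0.05 |
| `phosphate_range` | 0.05–2.5 µmol/kg | typical open-ocean surface span, oligotrophic gyre to HNLC |
| `n_clades`, `refs_per_clade` | 5, 4 | desk-scale panel with family labels (XoxF5, XoxF4, ADH type 2b, GDH 1a, SDH) |
| `ref_length` | 400 aa | PQQ-DH-like length, safely above the 300-aa screen |
| `divergence`, `indel_rate` | 0.2, 0.02 | per-residue substitution / indel probability of queries relative to their source reference |
| `within_clade_divergence` | 0.08 | panel references vs their clade ancestor; keeps within-clade identity ≫ between-clade (~random) identity |
| `nb_dispersion` | 5 | negative-binomial size k, variance µ + µ²/k — typical metagenomic overdispersion; `inf` gives the Poisson limit |
| `library_size_range` | 0.5–2 × 10⁶ reads | mapped-library scale |

Mutations use a uniform substitution kernel over the 19 alternative
residues; "incomplete" genes are realised half by truncation before the
motif and half by deleting the motif residues, both of which occur in real
catalog fragments. Gene length for RPKM is 3 × protein length (nucleotide
catalog). Counts are drawn so that the *expected* RPKM-weighted lanthanide
fraction of complete-domain genes equals the logistic value per sample;
realised fractions then fluctuate with NB noise, which is exactly what the
recovery tests measure against.

All randomness flows from one seed through per-stage
`default_rng([seed, stage])` streams; outputs are byte-reproducible.

What the generator does **not** emulate: phylogenetically realistic
substitution processes (no rate matrices or trees), read-level simulation,
chimeras, compositional biases, or correlated environmental covariates
beyond a linear temperature–phosphate trend. Passing recovery tests
therefore demonstrate the pipeline's internal consistency under a known
generative model, not classifier performance on real catalogs.

## Screening

Identity is the number of identically aligned residue pairs under the
optimal BLOSUM62 affine-gap global alignment (gap open −11, extend −1, end
gaps penalised), normalised by the shorter sequence — the CD-HIT convention,
under which a contained fragment scores 1.0. When several alignments share
the optimal score the match-maximal one defines the count, making the value
well defined and symmetric. Under this definition random same-length
proteins score ≈ 0.05–0.15, comfortably below the 0.25 "twilight zone"
floor used for clade assignment. (The alternative reading — matches
maximised over *all* alignments, i.e. the LCS — puts random pairs at ≈ 0.42,
the combinatorial floor of a 20-letter alphabet, and was rejected for that
reason.)

The identity kernel is a Gotoh dynamic program (score, then matches,
lexicographically) compiled with numba. Dereplication prunes candidate
pairs with two exact upper bounds before running it — shared residue
composition, then LCS — both of which bound the match count from above
under any alignment, so the pruning cannot change the result.

Homology screening replaces an unpublished profile-HMM stage with best-hit
local alignment against the annotated panel (defaults: identity ≥ 0.25 over
≥ 50% of the reference). The thresholds are exposed; the defaults give
≥ 0.99 recall on synthetic queries at ≤ 0.3 divergence while rejecting
composition-matched shuffled decoys.

Greedy dereplication visits sequences longest-first (ties by id) and joins
the first representative at ≥ threshold identity — CD-HIT's semantics,
deterministic by construction. Representatives may still exceed the
threshold to one another; that is a property of the greedy rule, asserted
but not "fixed".

## Classification

Each query's motif is projected from its nearest reference only (motif
column position varies across families, so a family-matched anchor is
required), through a pairwise global alignment rather than one large MSA:
deterministic, per-query auditable, and with no alignment-trimming dialect
to reproduce. Tie-breaking among equal-score alignments follows the
aligner's fixed deterministic traceback.

The cofactor call is a pure function of the projected triplet: D-x-D →
lanthanide; D-x-{A,T,S} → calcium; a gap at either coordinating position →
incomplete; anything else — including an unresolved 'X', which is a residue,
not a gap — → unknown. The centre position is never consulted, so a
centre-gap triplet like "D-D" still calls lanthanide. The function is
exhaustively tested over the full 21³ triplet space against a literal
transcription of the rule.

Known limitation: a genuinely complete gene whose motif residues resemble
neither form ("unknown") has no anchor residue holding the alignment, so an
indel near the motif can occasionally project a gap and demote the call to
"incomplete". At the default generator settings this affects ≲ 1% of
queries (class accuracy ≈ 0.99 at n = 500, divergence 0.2).

## Abundance statistics

RPKM is the closed formula; percent-of-total normalises within a gene
subset per sample, reporting all-zero samples as missing rather than zero.

fLn excludes incomplete-domain genes entirely; the numerator is lanthanide
abundance, the denominator lanthanide + calcium + unknown (the documented
inclusion rule). Both an abundance-weighted (default) and a count-based
(presence) mode are implemented, and the unknown class can be excluded from
the denominator to match the alternative "functionally similar enzymes with
a different cofactor" reading. fLn is scale-invariant per sample by
construction.

The logistic fit treats fLn as a fractional response: IRLS on the
quasi-binomial score (working weights µ(1−µ)), converged when the maximum
coefficient change is < 1e-10 (≤ 100 iterations), with Wald standard errors
from the inverse information scaled by the Pearson dispersion. A derived
fraction is not Bernoulli data, so dispersion scaling is the honest default;
the fit agrees with a statsmodels quasi-binomial GLM to ≈ 1e-6 and that
agreement is pinned by a test. Degenerate designs (no variation in x or y)
are flagged non-identifiable and report no p-value.

Correspondence analysis follows the standard χ² geometry: P = X/n,
S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD of S, principal coordinates
F = D_r^{−1/2}UΣ and G = D_c^{−1/2}VΣ, total inertia Σσ² = χ²/n (tested to
1e-10 against a direct χ² computation). Axis signs are fixed by making the
first nonzero column loading positive. Environmental arrows are
mass-weighted correlations of standardised variables with the standardised
row scores; nitrate is dropped by default because of its collinearity with
phosphate. A nearest-neighbour grid join (mean of grid cells within a
1-degree radius) is provided for attaching external geochemistry to sample
coordinates; it is exercised on synthetic grids only.

## Seawater equilibrium model

Components: Na, K, Cl, Mg, Ca, SO₄, DIC, total P, total La; 26 aqueous
species (the free ions, the carbonate and phosphate protonation ladders,
LaOH²⁺, LaCO₃⁺, La(CO₃)₂⁻, LaHCO₃²⁺, LaSO₄⁺, and the MgCO₃, CaCO₃, MgSO₄,
CaSO₄, NaSO₄⁻ ion pairs) plus the mineral LaPO₄(s). Constants are 25 °C
log K values shipped as package data with sources per row: CODATA/PHREEQC
for water, carbonate and the ion pairs; NIST for phosphoric acid; Klungness
& Byrne (2000) for La hydrolysis; Schijf & Byrne (2004) for LaSO₄⁺; and the
LLNL/SUPCRT rare-earth compilation (Haas, Shock & Sassani 1995) for the La
carbonate complexes (log β₁ = 7.0, log β₂ = 12.0). Ksp(LaPO₄) = 10⁻²⁵·⁷
(Liu & Byrne 1997, rhabdophane), inside the accepted 10⁻²⁶–10⁻²⁵ range and
sanity-checked at load time. A van't Hoff correction moves constants to the
working temperature (default 15 °C) where enthalpies are available; the La
complexes, whose enthalpies are poorly constrained, stay at their 25 °C
values.

**Constants sensitivity (the one that matters).** The La carbonate pair
(β₁, β₂) controls where — and whether — the LaPO₄ solubility minimum falls
inside the realistic pH window. With the LLNL-family values above, the
dicarbonate complex rivals the monocarbonate near seawater carbonate
activity, the free-La fraction at pH ≈ 7.8 is ~14%, and the minimum sits at
pH ≈ 8.10 with modest rises either side. With the weaker experimental
seawater constants of Luo & Byrne (2004) (β₁ = 6.8, β₂ = 11.4) the
complexation slope never overtakes the phosphate slope below pH ≈ 9 and the
curve is monotone over 7.4–8.6. The qualitative monotonicities (pH falls
with CO₂; CO₃²⁻/DIC falls and free La³⁺ rises as pH falls) hold under both
sets; the minimum's location carries the database choice, which is why it is
quoted with a ±0.3 pH tolerance.

**Numerics.** Activities use the Davies equation (with the 0.3·I term),
temperature-interpolated Debye–Hückel A. Davies is stretched at seawater
ionic strength (I ≈ 0.64 here); it was chosen to keep the model
self-contained, and the pH-minimum tolerance absorbs the difference from the
HKF-class models used by full geochemical codes. The solver is nested: at
fixed proton activity the non-H component mass balances form a monotone
system solved by Newton iteration on log free concentrations (log-space
residuals, backtracking line search; converges in ~5 steps); Brent
root-finding on pH then closes the alkalinity condition; an outer loop
relaxes ionic strength. Solved states close every component mass balance to
< 1e-12 relative (1e-8 is enforced as a hard error bound).

**Alkalinity convention.** The proton condition uses per-species weights
w = 2ν_CO₃ − ν_H (CO₂/H₂O reference levels), so ion-paired carbonate
(MgCO₃, CaCO₃, LaCO₃⁺ …) counts as a proton acceptor exactly like free
CO₃²⁻ — the PHREEQC/Dickson convention. Restricted to free ions this is the
familiar [HCO₃⁻] + 2[CO₃²⁻] + [OH⁻] − [H⁺]; counting pairs keeps alkalinity
strictly monotone in pH (a free-ion-only definition acquires a spurious
high-pH root once pairs sequester carbonate). Phosphate alkalinity
(w = 2ν_PO₄ − ν_H, H₂PO₄⁻ reference) is negligible at ≤ 10⁻⁶ mol/kg total P
and excluded by default, switchable. Charge balance is *not* imposed: the
canonical recipe is imbalanced by +8.7·10⁻⁴ eq/kg as printed, and the model
reports that as a diagnostic. The recipe's 0.0023 mol/kg HCO₃⁻ is read as
both the DIC total and the carbonate alkalinity of the reference state (the
carbon enters as bicarbonate); the CO₂ sweep varies DIC about it at that
fixed alkalinity.

**Saturation quantities.** At each state, a(La³⁺)_sat = Ksp / a(PO₄³⁻) and
total La at saturation = m(La³⁺)_sat / f_free with f_free the state's
free-La molality fraction. The sweep's DIC grid is chosen by bisection so
the solved pH spans a requested window (default 7.4–8.6, 200 points); the
minimum is refined by quadratic interpolation through the three bracketing
grid points, and a boundary minimum is flagged "unbracketed" rather than
interpolated.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the whole
suite completes in minutes on one CPU: synthetic catalogs of 120–500
proteins against a 20-reference panel, 25–60 samples, dereplication oracles
at ≤ 50 sequences, equilibrium sweeps of 80–200 states. Per-sample fLn
error against generator truth scales roughly with the reciprocal of catalog
size (one miscalled gene carries ~1/n of the abundance weight), which is
why the end-to-end comparison uses the 500-gene catalog.

## Known limitations

* The profile-HMM screen of the original workflow is replaced by pairwise
  homology against the panel; sensitivity to families absent from the panel
  is therefore zero by construction.
* Nearest-reference clade assignment cannot discover new clades; queries
  below the identity floor are "unclassified", never novel.
* The equilibrium model omits Ce redox chemistry, pressure corrections,
  scavenging/adsorption kinetics, and Mg/Ca–phosphate ion pairs; the last
  shifts absolute PO₄³⁻ activities but moves the solubility minimum far less
  than the La-carbonate constants do.
* Davies activities above I ≈ 0.5 are an approximation; absolute speciation
  fractions should be read as indicative, the monotonic structure as robust.
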