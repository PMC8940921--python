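# Methods

`phycogradients` models the two nutrient gradients that organize
algal–bacterial co-culture in a porous microplate: dissolved organic
carbon (DOC) released by the alga, decreasing away from it, and
inorganic nitrate supplied by the medium, increasing away from it. The
same pair of opposed gradients exists at two scales — micrometres
around a single cell (the phycosphere) and millimetres across a well
array whose nanoporous HEMA–EDMA walls pass solutes but not cells —
and the package implements both, plus a synthetic co-culture generator
and the statistics used to quantify spatial responses.

## Phycosphere model

A cell of radius R releases DOC at Q (fmol C cell⁻¹ d⁻¹) and takes up
nitrate at up to U (fmol N cell⁻¹ d⁻¹). In the diffusion-dominated
regime (stirring number lv/D ≪ 1, Péclet number ≪ 1) the steady
spherically symmetric fields are

    C_DOC(r)  = C_∞ + Q / (4 π D r),
    C_NO3(r)  = max(0, C_∞ − U_eff / (4 π D r)),      r ≥ R,

with uptake saturated at the far-field concentration, U_eff =
U·C_∞/(C_∞+K_m). A full Robin boundary condition would couple uptake
to the local surface concentration; evaluating the Michaelis–Menten
factor at the far field instead keeps the solution closed-form and is
accurate when the self-depletion at the surface is small relative to
C_∞, which holds for all shipped parameter sets. Profiles are computed
on a log-spaced grid from R to 100 R (200 points) and normalized by
their maxima for cross-scale comparison.

The shipped species table (`data/species_presets.csv`) covers four
taxonomically diverse phytoplankton (a cyanobacterium, a haptophyte,
and two diatoms). Radii and per-cell rates are literature-scale
defaults (exudation a few percent of cellular carbon per day; nitrate
uptake consistent with growth-rate × N-quota), flagged as such in the
provenance column, not transcribed measurements. The far-field "bulk
DOC" is the ambient background of the same labile exudate compounds,
set in the nM range — fresh low-molecular-weight exudates are turned
over rapidly, so their standing background is far below total-DOC
levels. With these defaults the surface-to-far-field DOC fold-decrease
falls between 3.8 and 6.4 for every species and growth phase.
Stationary phase doubles both exudation and the labile background
(leaving folds unchanged) and zeroes nitrate.

## Microplate model

Wells are well-mixed compartments (the cultures are pipette-mixed at
sampling) joined by walls that pass solutes by Fickian diffusion,
J = D_eff·A·ΔC/L with wall thickness L = 0.9 mm and shared area A =
15 mm² (well depth × wall arc, stored explicitly per edge so geometry
assumptions are inspectable). The plate sits in a medium bath treated
as fixed-concentration by default (its ~25 ml dwarf the 75–100 µl
wells); a finite-volume reservoir is available for spent-medium
scenarios. Three presets ship: `hex7` (centre + six neighbours, all
algal, 75 µl), `isolate_rings` (central alga, two radial arms of
bacterial wells at 7/14/21 mm, 100 µl), and `community_layers`
(central alga, six layer-1 wells at 8 mm, six layer-2 wells at 16 mm).

The algal population grows on nitrate with Monod kinetics (µ_max =
0.5 d⁻¹, K_m = 1 µM) and draws nitrate in proportion to growth through
a fixed cell quota q_N = 70 fmol N cell⁻¹, so batch carrying capacity
emerges as C_NO3(0)/q_N ≈ 1.3 × 10⁷ cells ml⁻¹ in f/2-Si (nominal
nitrate 882 µM) rather than being imposed. DOC is exuded at 60 fmol C
cell⁻¹ d⁻¹. The initial density (10⁶ cells ml⁻¹, 10⁷ for the
pre-acclimated isolate runs) matches the experimental inocula, and
simulations start post-acclimation: the transient density drop that
real cultures show in the first two days on fresh copolymer is not
modelled. Evaporation is ignored (well volumes are stable over weeks)
and wells start pre-equilibrated with the medium, as the devices are
soaked in f/2-Si before inoculation.

### Wall conductances are calibrated, per solute

The effective diffusivities through the copolymer are the model's two
genuinely free constants; no direct measurement is available. They are
calibrated once, jointly, against the three headline behaviours of the
system: a ~5-fold DOC decrease from the centre to the outermost wells
of the community layout after 7 days, depletion of centre-well nitrate
(below 1% of initial) within 6 days despite reservoir resupply, and a
reservoir-driven carrying-capacity gain over sealed operation. The
defaults are

    D_eff(DOC)     = 6.0e-11 m² s⁻¹   (~0.09 × free solution)
    D_eff(nitrate) = 3.4e-12 m² s⁻¹   (~0.002 × free solution)

A single porosity/tortuosity factor cannot satisfy all three targets:
at uniform 0.3 × free-solution diffusivity a wall equilibrates a 100 µl
well in hours, which would erase the DOC gradient and resupply the
centre well faster than any plausible algal drawdown. The required
asymmetry — the anion crossing far more slowly relative to free
solution than the organic pool — is interpreted as partitioning:
D_eff here lumps hindered diffusion with solute partitioning into the
water-swollen copolymer, and charged solutes are additionally excluded
from the gel phase. We state this as the package's calibration choice;
the individual factors should not be read as measured membrane
properties.

The ODE system (per well: DOC, nitrate, algal density, plus one state
per bacterial taxon) is integrated with LSODA at rtol 1e-8, atol 1e-9
(tight enough that sealed-system mass is conserved to better than 1e-8
relative over 20 days), without clipping; integrated states are checked
against a scale-relative negativity floor before tiny numerical
undershoots are zeroed. Output is sampled on a fixed grid (0.05–0.5 d
depending on the pipeline).

## Synthetic co-culture generator

Bacteria are not part of the nutrient model above; they are the
synthetic-data layer that emulates what the co-culture experiments
measure. Each taxon grows as

    dB/dt = [ µ_C S_C/(K_C+S_C) + µ_N S_N/(K_N+S_N) ] B − m B,

with additive, substitutable resource terms and drawdown coupled
through fixed yields (cells per µmol). Two lifestyles span the niche
axis: *exudate specialists* (µ_N = 0) and *generalists* (both terms
active; the inorganic term implicitly carries the background carbon
that supports growth on mineral nutrients). The focal presets are an
Algoriphagus-like specialist (µ_C = 1.0 d⁻¹, K_C = 800 µM C, m =
0.1 d⁻¹, inoculum 4 × 10⁵ ml⁻¹) and a Marinobacter-like generalist
(µ_C = 0.7, K_C = 400 µM C, µ_N = 1.2 d⁻¹, K_N = 10 µM, m = 0.15 d⁻¹,
inoculum 4 × 10⁶ ml⁻¹, ten-fold above the specialist as in the
experimental inocula). All rates are calibration constants chosen once
to reproduce the qualitative spatial pattern of the isolate
experiment — late-phase decrease of both strains with distance from
the alga, a far steeper specialist response (~100-fold vs ~5-fold
between 7 and 21 mm), generalist dominance of the outermost well, and
an early outward-increasing generalist profile in alga-free controls —
not fitted to measurements. The eight-taxon community preset assigns
each genus a strategy matching the direction of its observed response
to algal proximity, with the same caveat.

Two measurement channels are emulated. Flow-cytometry sampling draws
Poisson bead and cell events around their expectations and
back-calculates density as (cells/beads) × bead density × dilution;
the estimator is unbiased to well under 2% at ≥10⁴ events. 16S-like
tables resample each sample's taxon proportions multinomially at a
configurable depth, with mean-one lognormal overdispersion factors so
expected proportions equal density proportions. Replicate-level
lognormal noise (default geometric SD 1.3) emulates between-well
variability. Every stochastic step requires an explicit seed; unseeded
stochastic calls raise.

What the generator does **not** emulate: attachment of bacteria to
algal cells (excluded by design — the device separates the organisms),
chemotaxis and motility, cross-feeding back to the alga (micronutrient
feedback is off by default), primer/chimera artefacts of real amplicon
sequencing, and compositional normalization pipelines. Passing tests
therefore demonstrate internal consistency of the model and its
statistics, not fidelity to any particular real community.

A known topological artefact: in the chain-like isolate layout the
middle well (14 mm) is doubly shadowed — upstream wells absorb the DOC
flux and the outermost well absorbs the reservoir's inorganic flux —
so late generalist profiles can dip at mid-distance while the
innermost–outermost contrast retains the observed direction. Ring
geometries with lateral mixing would soften this; the endpoint-based
fold statistics are insensitive to it.

## Statistics

Counts carry multiplicative error, so summaries are geometric
(geo-mean, geo-SD = exp(sd(log v))) and two-sample comparisons default
to log-transformed densities. Distance responses are summarized by the
innermost/outermost ratio of geometric means, with abundances clamped
to a detection floor (10³ cells ml⁻¹) so folds stay finite when outer
growth is negligible; a flag marks fully-clamped (lower-bound) folds.
The Welch t-test and the balanced two-way ANOVA (sums of squares;
SS_total = SS_A + SS_B + SS_AB + SS_err exactly in balanced designs)
are implemented from their defining formulas, with only the t/F tail
functions taken from scipy; both are cross-checked against independent
implementations in the test suite, and their null behaviour is
calibrated by simulation (type-I error within [0.04, 0.06] at α =
0.05). For small or unbalanced distance designs a permutation test of
the Spearman abundance–distance correlation is provided (two-sided,
p = (1+#{|ρ*|≥|ρ|})/(n_perm+1), n_perm ≥ 999); its discreteness makes
it mildly conservative at n = 8. Genus-level screens report
Benjamini–Hochberg adjusted p-values.

## Problem sizes and numerical choices

Default runs are deliberately small: 13-well community layout for 7
days (~10³ ODE steps), 7-well arrays for 20 days, 10⁴ null simulations
for test calibration, 200-point radial grids. The full analysis chain
(`analysis/01`–`05`) and the acceptance script each complete in well
under a minute on one core. Degenerate inputs are handled explicitly:
all-zero profiles normalize to zero with a warning, depleted far
fields yield flagged infinities, zero-variance ANOVA responses return
degenerate terms, and empty taxon lists or unseeded stochastic calls
raise immediately.
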