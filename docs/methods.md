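# Methods

This note records the model as implemented, the numerical choices, what the
individual-based simulator does and does not emulate, and the limitations a
user should know before trusting an output.

## Model and assumptions

One adult per site, one same-sex offspring per season, overlapping
generations, haploid genetics. The life cycle order is fixed: birth,
dispersal (of the parent under Bequeath, of the offspring under Stay),
lottery competition for every site, then survival. Competition is a single
weighted draw among everyone present — there is no prior-residency
advantage beyond the adult/juvenile weight ratio `C_A`, no site sharing, no
floaters, and no facultative switching. Habitat quality is uniform and
static; saturation (the residency rate `R`) emerges from the survival and
dispersal parameters rather than being imposed.

Fitness is inclusive at the household level: the member of the pair that
keeps/wins a site contributes its acquisition-and-survival probability,
discounted by the parent-offspring relatedness `ρ` when the beneficiary is
the partner rather than the focal strategy carrier. No weak-selection
approximation is involved; the expressions are exact expected growth rates
under the stated immigration laws.

## Parameters

| symbol | meaning | default | notes |
| --- | --- | --- | --- |
| `s_A`, `s_J` | adult/juvenile season survival | 1.0 | probabilities; `s < 1` opens habitat |
| `d_A`, `d_J` | adult/juvenile dispersal survival | 1.0 | typically `d_A > d_J` in nature |
| `C_A` | adult lottery weight relative to a juvenile | 2.0 | scanned on a log2 axis up to 2^10 |
| `ρ` | parent-offspring relatedness | 0.5 | 0.5 = sexual haploid, 1 = clonal/maternal |
| `p` | population frequency of Bequeath | 0.0 | state variable, not a rate |
| `N` | number of sites (simulator only) | 1000 | analytics work in the `N → ∞` limit |

Defaults describe the mortality-free baseline in which the comparative-
advantage logic is cleanest; every analysis sets the parameters it varies
explicitly.

## Immigration laws

Global dispersal: each of the `R`-fraction occupied sites emits one
disperser surviving with probability `p d_A + (1−p) d_J`; in the
large-population limit arrivals at a focal site are Poisson with mean
`λ = R (p d_A + (1−p) d_J)`, thinned into adults with probability
`π = p d_A / (p d_A + (1−p) d_J)` (defined as 0 when the pool is empty).
Because dispersal events are independent, the ambient field at a focal
disperser's away site is the same distribution.

Local dispersal (ring): at most two inbound slots exist. Each neighbour is
occupied with probability `R` and its disperser moves toward the focal site
half of the time, so the per-neighbour arrival probability is
`R (p d_A + (1−p) d_J) / 2` — the factor 1/2 is required by the coin-flip
construction and is what reproduces the 0.25 home / 0.5 away zero-arrival
probabilities and the 0.61 residency value. At an away site the focal
disperser occupies one slot, leaving a single Binomial(1, ·) coin. Local
analytics are restricted to monomorphic populations (`p ∈ {0,1}`): at
interior frequencies local dispersal builds spatial genotype correlations
that no site-independent immigration law can represent, and those cases are
delegated to the simulator.

## Numerical choices

- **Series truncation.** Poisson supports are enumerated up to the smallest
  total count whose upper-tail mass is below 1e-12 (cap 200); with `λ ≤ 1`
  in all regimes this truncates near n = 15 and the error is negligible
  against two-decimal targets. Truncated expectations were verified against
  the closed form `E[1/(n+k)] = ∫₀¹ x^{k−1} e^{λ(x−1)} dx` to 1e-10.
- **Residency fixed point.** Plain iteration of the recurrence from
  `R₀ = 1` to an absolute step below 1e-12 (cap 10^5), no damping; the map
  is a contraction toward the stable fixed point in all regimes exercised,
  and nonviable populations decay monotonically toward 0. A saturated,
  mortality-free habitat returns `R = 1` exactly.
- **ESS classification.** The selection differential `ΔW = W(B) − W(S)` is
  evaluated exactly at `p = 0` and `p = 1`, each at its own steady state; a
  measure-zero invader does not perturb `λ`, `π` or `R`. `|ΔW| < 1e-9` is
  reported as `boundary` (the exactly symmetric point `C_A = 1, ρ = 1`)
  rather than forced to a sign. The `nonviable` label follows the
  monomorphic-Stay persistence condition `s_A + d_J s_J > 1` (with
  `s_J + d_A s_A > 1` the Bequeath analogue, both exposed via
  `viability()`); these are expectation-level conditions and populations
  just above the threshold remain at high demographic risk.
- **Frequency dynamics.** The model fixes how `R` updates but not how `p`
  does; we adopt the discrete replicator normalisation
  `p' = p W(B) / (p W(B) + (1−p) W(S))` with both fitnesses evaluated at
  the current `(p, R)`. Any monotone dynamic with the same sign structure
  has the same isoclines and equilibria; trajectories, not endpoints,
  depend on this choice. Interior equilibria are roots of `ΔW(p, R_ss(p))`
  found by bisection to 1e-6 over a 41-point scan of `p ∈ [1e-4, 1−1e-4]`;
  the exactly neutral plane (`C_A = 1, ρ = 1`), where every frequency is an
  equilibrium, raises a degenerate-input error instead of returning an
  arbitrary root.
- **Region maps.** Deterministic cell-by-cell classification; 50×50 grids
  are used for the published-style maps and are configurable. Cells within
  tie tolerance are labelled `boundary`, never silently assigned.

## The individual-based simulator

The simulator realises the exact life cycle on `N` sites (global mixing or
ring), with one RNG per replicate (`seed + replicate_index`), synchronous
generations, and all contestants at a site resolved in one weighted lottery
(implemented as an exponential race, which reproduces the weighted-draw
probabilities exactly). Relatedness is realised as mixture transmission:
an offspring copies its mother's allele with probability `ρ` and otherwise
draws from the current occupant allele frequency (an ambient father pool).
This reproduces the parent-offspring allele correlation the analytic `ρ`
encodes; it is a transmission-genetic realisation of an inclusive-fitness
bookkeeping device, so agreement with the analytic region maps is expected
to be qualitative (direction of selection, bistability, mixtures) rather
than exact, and is reported as measured.

What the simulator does *not* emulate: age structure beyond the
adult/juvenile dichotomy, multiple offspring, diploid genetics, explicit
males (fathers are ambient), environmental variation, and distance kernels
between the global and nearest-neighbour extremes. Passing tests therefore
speak to the internal consistency of this model family, not to any broader
claim about real populations.

### Quantified mean-field error on the ring

The local residency recurrence treats each neighbour's occupancy as an
independent draw at the population rate `R`. The spatially explicit
simulation shows this is optimistic: occupancy is positively correlated
along the ring (vacancies cluster, because colonists can only come from
adjacent occupied sites), so true colonisation is less effective than the
mean-field rate. At `s_A = s_J = 0.75`, `d = 1` the mean-field fixed point
is `R ≈ 0.607` while the simulated ring equilibrates near `R ≈ 0.48`
(cross-checked against an independently coded per-site simulation; the two
agree within Monte-Carlo error). The global model shows no such gap — the
simulation matches `R ≈ 0.564` within Monte-Carlo error — because there the
independence assumption is exact in the large-`N` limit. Users should read
local-model residency values as the model's own mean-field quantities, not
as predictions of spatial occupancy; the ESS boundary comparisons between
global and local models inherit this caveat in proportion to how strongly
they depend on `R` (at `R = 1`, not at all).

### A boundary case the mean of the field does not settle

With zero relatedness the global model never stabilises Bequeath: the
adult's away prospect trails the evicting adult's home defence for every
`C_A`, the gap shrinking as O(1/C_A) but never changing sign. Under the
local construction the same arithmetic gives a different answer: because
the focal disperser consumes one of the two inbound slots and the away
defender at `p = 1` is a juvenile, a bequeathing adult with a large
advantage wins away ~3/4 of the time while a Stay invader's home defence
against up-to-two adult immigrants is worth only 7/12, so local `ΔW(p=1)`
turns positive for `C_A ≳ 4` even at `ρ = 0`. The package reports what the
expressions give; the zero-relatedness impossibility claim is asserted (and
tested) for the global model where it holds exactly.

## Problem sizes

Analytic results are exact up to the stated truncations and run in
milliseconds per parameter point; region maps use 50×50 grids. Simulation
checks use `N` = 1000–2000 sites, 300–400 generations for residency
equilibria (100-generation burn-in), 30–50 replicates for fixation
frequencies, and Wilson intervals for proportions. These sizes give
Monte-Carlo standard errors well below the effect sizes being checked.
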