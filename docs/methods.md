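# Methods

`poresim` is an individual-based model of a two-species bacterial community
— an obligate aerobe and an obligate anaerobe — colonizing a water-saturated
micrometric pore network that carries opposing sources of carbon and oxygen.
It couples three processes on a lattice of rectangular micro-channels:
implicit finite-volume diffusion of citrate, oxygen and nitrate; Monod
growth, division and death of individual cells; and chemotactic
run-and-tumble motility along channels.  This note records the model, its
numerical choices, and the limits of what simulations with it can show.

## Habitat: percolating channel lattices

The fully connected habitat is a triangular lattice (hexagonal node
arrangement, interior junctions joining six channels) of radius `rings`
channels.  Channels are rectangular, 200 um x 40 um x 15 um (L x W x H),
giving a cross-section A = 6e-10 m^2 and a volume of 1.2e-13 m^3 each.
Connectivity is reduced by visiting channels in a seeded random permutation
and deleting each one unless that would disconnect the network or strand a
junction, stopping once `round(f * N)` channels remain.  The procedure is
unbiased among feasible deletion sequences and deterministic per seed.  A
spanning tree of this lattice uses ~34.7% of its channels, so targets down
to 40% connectivity are always reachable; an explicit error is raised if a
target is not.

Percolation is defined strictly: every junction must be reachable from every
other through retained channels.  Five ports give access to the sealed
network: one central port and four peripheral ports chosen as the boundary
nodes nearest to 0/90/180/270 degrees.  Port nodes carry an extra well
volume (default 1e-9 m^3 = 1 uL, the scale of the physical access wells) on
top of the finite-volume rule below.

## Solute transport

Between junctions, solutes diffuse along channels by Fick's law; mass
balance at junction i gives

    V_i dC_i/dt = sum_j g_ij (C_j - C_i) - R_i,

with channel conductance g = D A / L (m^3/s), node volume V_i = half the
volume of incident channels (+ port volume), and R_i the local bacterial
consumption (mol/s).  Diffusivities: citrate 5.9e-10, oxygen 2e-9, nitrate
1.7e-9 m^2/s.  Concentrations are stored in mol/m^3, numerically equal to
mM, the unit of all kinetic constants.

The step is backward Euler; the operator is assembled and LU-factorized once
per run (geometry and dt are constant) and consumption enters explicitly
from the previous step, which matches the scheduler order below.  Dirichlet
ports are enforced by row replacement, which has the same fixed point as a
mirror-node construction.  Explicit sinks can transiently drive a node
negative; such nodes are clamped to zero and the removed mass is logged on
the run result (`clamped`), which stays at round-off levels in practice
because demands are capped by availability first (see below).

Boundary assignment in the counter-gradient scenario: citrate and nitrate
held at 10 mM at the central port (a nutrient plug), oxygen held at 0.27 mM
(Henry's-law equilibrium with air) at the four peripheral ports, zero flux
elsewhere; the central port is sealed for oxygen.  The collocated scenario
holds all three substrates at the peripheral ports instead.  Interior
concentrations start at zero for all substrates — the network is assembled
under vacuum-saturation, so the initial state is taken as nutrient-free and
anoxic (configurable).

## Growth, consumption, division, death

Each cell b carries a mass m_b evolving as dm_b/dt = (mu - mu_maint) m_b,
explicit Euler per 10 s step.  The growth rate mu is evaluated at the cell's
nearest junction:

    aerobe:    mu = mu_max * min( C_C/(K_C + C_C), C_O2/(K_O2 + C_O2) )
    anaerobe:  mu = mu_max * min( C_C/(K_C + C_C), K_inh/(K_inh + C_O2),
                                  C_N/(K_N + C_N) )

with mu_max = 6.9e-6 s^-1 (aerobe) and 5.4e-6 s^-1 (anaerobe), K_C = 0.05
mM, K_O2 = K_inh = 0.0063 mM, K_N = 0.0351 mM, and maintenance mu_maint =
0.1 mu_max.  Citrate demand over a step is mu m dt / Y with yield Y = 0.06
kg biomass per mol citrate; aerobes co-consume 2.2 mol O2 and anaerobes 10
mol NO3 per mol citrate.  Consumption is tied to gross growth mu, not to
mu - mu_maint: maintenance burns biomass only, keeping Y interpretable as a
true yield.

Demands are summed per junction; where a junction's demand exceeds the
dissolved mass C V available there, every co-located cell's demand *and*
growth increment are rescaled by the same availability factor, so biomass
gained always equals Y times citrate consumed, exactly.  Dirichlet nodes are
treated as inexhaustible.

Cells divide 50/50 on reaching m_max = 2 m0 / 1.433 (m0 = 1e-15 kg), with
one daughter's heading re-randomized, and are removed on shrinking to
m_crit = 0.2 m_max.  Inoculated masses are drawn uniformly from [m0, m_max)
to avoid fully synchronized first divisions (residual division waves remain,
because that interval covers only half of a doubling cycle in log-mass).

## Motility

Cells swim at v = 2e-5 m/s along the channel axis and reorient by tumbling
at rate

    p = p0 exp( -chi / (2 v mu_max) * dmu/dx ),    p0 = 0.25 s^-1,

with chemotactic sensitivity chi = 2e-8 m^2/s and dmu/dx the gradient of the
cell's own growth-rate function along its heading, evaluated between the two
junctions terminating its channel (the only stencil the discretization
offers).  Because mu depends on oxygen with opposite signs for the two
species, a single rule produces aerotaxis in the aerobe and oxygen avoidance
in the anaerobe.  An in-channel tumble reverses the heading with probability
1/2; reaching a junction forces a tumble with a uniformly random choice
among all incident channels, arrival channel included, and the run carries
its leftover distance into the chosen channel.

p is a rate, and p0 dt = 2.5 at the 10 s engine step, so motion is
integrated in substeps of 1 s with per-substep tumble probability
1 - exp(-p dt); v dt = 20 um per substep resolves the 200 um channels.
Because a tumble that does not reverse the heading leaves the trajectory
unchanged, the inner loop draws once against half the tumble probability.
The per-channel, per-direction, per-species probabilities are precomputed
each engine step; the substep loop is numba-compiled.

A note on v: reported run speeds for swimming soil pseudomonads are a few
tens of um/s.  The default of 2e-5 m/s (20 um/s) sits in that range and
traverses exactly one channel per 10 s engine step; it is configurable, and
results that hinge on absolute colonization speed should be checked against
a measured speed for the organism at hand.

## Scheduler

Each 10 s step executes, in order: (1) diffusion of all substrates with the
consumption sinks recorded in the previous step; (2) motility; (3) growth
and new consumption at the cells' current junctions; (4) division and death.
A golden-snapshot regression test pins this order.  All randomness (lattice
dilution, inoculation masses and placement, tumbling, junction choices,
division headings) flows from one seed per realization; realization k of an
ensemble uses seed + k, and identical (config, seed) reproduce runs
bit-exactly.

## Analysis conventions

Cells are attributed to their nearest junction; cells within 0.5 mm
(Euclidean) of any port are discarded, mirroring the imaging protocol the
analysis reproduces (port-wall artifacts).  Profiles are histograms along
the channel-weighted shortest-path distance from the central port, 20 equal
bins from zero to the network's maximum node distance, each bin divided by
its junction count (average cells per node); ensembles report the per-bin
mean and a per-bin envelope covering 95% of realization values (the
per-bin reading of the envelope is a choice; a global envelope would also be
defensible).  Species separation is summarized by the difference of
cell-weighted mean shortest-path distances (aerobe minus anaerobe; positive
means aerobes sit peripherally).  Cross-connectivity density comparisons use
the classic pooled two-sample two-tailed t-test (Welch optional).
Uniformity of a profile is tested by chi-square against an expectation
proportional to the summed node volume per bin, because an unbiased
run-and-tumble population equilibrates per unit channel volume, making
junction degree part of the null rather than a confounder.

## Well-mixed competition

The flask scenario is a single compartment (default 1 uL) with no motility:
oxygen clamped at 0.27 mM (oxic) or 0 (anoxic), citrate and nitrate starting
at 10 mM and depleting as batch resources, 72 h horizon.  Under oxygen the
anaerobe's inhibition term K_inh/(K_inh + 0.27) = 0.023 pushes it below
maintenance and the aerobe takes over monotonically; under anoxia the roles
reverse.  Exclusion directions emerge within hours; the 72 h default keeps
the slower anoxic takeover visible.

## Problem sizes

Default scenario lattices are 35 rings (~7 mm radius, 3781 junctions), the
scale of the etched networks the geometry mimics.  The bundled end-to-end
checks and the acceptance script run the same 7-day, 10 s-step protocol on
smaller lattices — 8 rings (~1.6 mm) in the test suite and 12 rings
(~2.4 mm) in the acceptance script, three realizations per connectivity —
because the community dynamics are set by growth kinetics and boundary
fluxes rather than lattice radius once the network is much larger than the
port-exclusion radius.  Populations grow from 1,000 to roughly 2-3 x 10^4
agents over the simulated week.

## Known limitations, and a quantitative caveat on anoxia

The model deliberately omits facultative metabolism (the real anaerobic
partner of the system it mimics is a facultative anaerobe), lag phases,
dormancy, mass release by dying cells, within-channel hydrodynamics, and
unsaturated (wetting/drying) transients.

One quantitative property deserves emphasis because it determines what the
default parameter set can and cannot reproduce.  With mu_max ~ 7e-6 s^-1
(28 h doubling), a community founded by ~10^3 cells reaches at most a few
times 10^4 cells in 7 days, and its peak oxygen consumption — at most
mu_max m S_O2 / Y ~ 3e-19 mol/s per cell — stays an order of magnitude below
the diffusive oxygen influx through the peripheral ports (~2e-14 mol/s for
millimetre-scale lattices).  Oxygen therefore floods the network within
hours regardless of bacterial activity, and because the anaerobe's
inhibition constant is tiny (0.0063 mM, 2.3% of air saturation), the
anaerobe is suppressed network-wide soon after.  Simulated communities under
the default counter-gradient conditions consequently end aerobe-dominated
(anaerobe share of order a few percent), with only weak spatial segregation;
self-sustained central anoxia would require either ~10^5+ respiring cells
from the start, order-of-magnitude faster growth, or order-of-magnitude
lower boundary oxygen conductance.  Experiments on such systems, whose real
populations grow ~50x faster than this parameterization, do maintain anoxia
and anaerobe-rich cores; reproducing that regime with this model requires
revisiting mu_max, the inoculum size, or the port oxygen supply, all of
which are exposed in the configuration.
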