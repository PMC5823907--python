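# poresim

Individual-based simulation of a two-species bacterial community — an
obligate aerobe and an obligate anaerobe — colonizing water-saturated
micrometric pore networks under opposing resource gradients (carbon supplied
at the center, oxygen at the periphery).

Microbial hotspots in soil, such as aggregates, are thought to organize
around exactly such counter-gradients: respiration at the oxic rim shields a
carbon-rich anoxic core, creating niches that let metabolically different
species coexist where a well-mixed culture would end in competitive
exclusion.  `poresim` provides a mechanistic sandbox for that hypothesis:
percolating lattices of rectangular micro-channels (200 um x 40 um x 15 um)
with controllable connectivity, diffusive transport of citrate, oxygen and
nitrate, Monod-growing motile agents, and the spatial statistics used to
quantify segregation.

## Model core

On a channel lattice, solute mass balance at junction *i* is

    V_i dC_i/dt = Σ_j g_ij (C_j − C_i) − R_i,        g = D·A/L,

solved with a factorized backward-Euler operator (Dirichlet ports pinned).
Each cell of species *s* grows as dm/dt = (μ_s − μ_maint) m with

    μ_aer = μ_max,aer · min( C_C/(K_C+C_C), C_O2/(K_O2+C_O2) )
    μ_ana = μ_max,ana · min( C_C/(K_C+C_C), K_inh/(K_inh+C_O2), C_N/(K_N+C_N) )

consuming citrate at μ m/Y plus oxygen (aerobes, 2.2 mol/mol) or nitrate
(anaerobes, 10 mol/mol), dividing at 2m₀/1.433 and dying at 20% of that.
Motility is a biased run-and-tumble along channels: cells swim at 20 um/s
and tumble at rate p = p₀ exp(−χ/(2vμ_max)·dμ/dx), so runs up their own
growth-rate gradient last longer — one rule that yields chemotaxis,
aerotaxis (aerobes) and oxygen avoidance (anaerobes).  A 10 s scheduler
interleaves diffusion, motility, growth/consumption, and division/death;
every run is bit-reproducible from (config, seed).

## Worked example

```python
import numpy as np
from poresim import ScenarioConfig, run_single
from poresim.analysis import (bin_by_shortest_path, relative_abundance,
                              segregation_metrics)

cfg = ScenarioConfig(scenario="counter_gradient", rings=8, connectivity=0.7,
                     inoculum=(500, 500), duration=2 * 86400.0, seed=7)
res = run_single(cfg, seed=7)
ab = relative_abundance(res.cells)
seg = segregation_metrics(bin_by_shortest_path(res.cells, res.net))
print(f"cells after 2 days: {len(res.cells)}")
print(f"anaerobe fraction:  {ab.fractions['anaerobe']:.3f}")
print(f"segregation (aerobe - anaerobe mean distance): "
      f"{seg['difference_m'] * 1e3:.3f} mm")
print(f"central-node O2:    {res.state.conc['oxygen'][res.net.central_port]:.3f} mM")
```

prints

```
cells after 2 days: 2510
anaerobe fraction:  0.203
segregation (aerobe - anaerobe mean distance): 0.038 mm
central-node O2:    0.176 mM
```

Interpretation: on a 70%-connectivity lattice seeded with 500 cells of each
species at the central carbon source, two days of growth roughly double the
community; anaerobes (20%) fall behind because oxygen diffusing from the
peripheral ports has already flooded the lattice (the central junction sits
at 0.176 mM of the 0.27 mM boundary value, far above the anaerobe's 0.0063
mM inhibition constant), while aerobes — the positive segregation value —
sit on average 0.04 mm closer to the oxygen-supplying periphery.  See
`docs/methods.md` for why self-sustained central anoxia is out of reach of
this parameterization and what that implies.

The same scenarios are scriptable from a shell, with `run.yaml` mirroring
the `ScenarioConfig` fields:

```yaml
# run.yaml
scenario: counter_gradient
rings: 8
connectivity: 0.7
inoculum: [500, 500]
duration: 172800.0
```

```bash
poresim make-network --rings 8 --connectivity 0.7 --seed 1 --out net.json
poresim simulate -c run.yaml -o results/ -r 3 -s 1
poresim analyze -i results/ -o analysis/
```

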