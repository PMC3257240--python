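# vtsim

Agent-based 4D simulation of intracellular vesicle transport in a virtual
cell: coat-mediated budding with saturating cargo/SNARE/motor loading,
diffusion and motor-driven transport along generated cytoskeleton
architectures, SNARE-governed docking and fusion with coat shielding,
recycling of the machinery components, clathrin-style endocytic clustering
at the plasma membrane with an actin boost, and an optional coupled
receptor/MAPK signaling layer.

Every molecule is an explicit agent; vesicles and compartments are sphere
agents with a well-mixed stochastic interior (multi-scale coupling).
Volume, surface area and every molecular species are exactly conserved
across budding and fusion.

## Quick start

```python
import vtsim

cfg = vtsim.two_compartment(style="dipole", t_end=200.0)
res = vtsim.run_simulation(cfg, seed=1)
m = res.metrics
print(m.n_fusions, m.n_forward, m.n_backward, m.mean_travel_time)
```

`style` selects the cytoskeleton architecture: `none` (diffusion only),
`random`, `direct` (filament bundle joining the two compartments),
`linear` (parallel filaments spanning the compartment axis), `dipole`
(field lines of two opposite point charges at the compartment centres),
`radial`, and `polarized` (radial with an angular bias toward a pole).

Presets: `two_compartment`, `endo_exo` (plasma membrane + central
endosome with endocytic coat clustering and exocytic recycling), and
`signaling_cell` (receptor-mediated endocytosis coupled to a one-stage
MAPK cascade with nucleus-surface shuttling).

## CLI

```bash
vtsim run two_compartment --style direct --seed 1 --t-end 200 --out-dir out/
vtsim run my_config.yaml --out-dir out/
vtsim presets
```

Outputs: `events.tsv` (append-only budding/fusion/endocytosis log with
timestamps, lineage and cargo manifests), `timeseries.tsv` (per-location
species counts), `filaments.tsv` (cytoskeleton polylines),
`resolved_config.yaml` (full config echo for provenance), `run_log.json`.

Custom scenarios are single YAML documents; see the serialized output of
any preset (`resolved_config.yaml`) for the schema: species definitions
(class, radius, diffusion coefficient or Stokes–Einstein scaling, initial
counts per location), interaction-rate tables (coat–cargo/SNARE/motor
matrices, symmetric SNARE pairing-strength matrix, catcher rates, on/off
rates, polymerization and fusion constants, class loading limits, shell
size), cell/cytoskeleton/compartment geometry, an optional signaling
block, and the simulation parameters.

**Units:** µm, s, molecule counts. Volume-phase bimolecular rate
constants are given in 1/(M·s) and converted internally
(V_r = k·dt·10¹⁵/N_A µm³); membrane-phase constants are in µm²/s per
molecule pair. All preset rate values are documented provisional
defaults — the parameter supplement of the original study is not public —
chosen so the machinery is functional at desk scale.

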