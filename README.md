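# paninsim

A multiscale simulator of pancreatic intraepithelial neoplasia (PanIN): a
delayed Hill-logic gene-regulatory network driven by a Lotka–Volterra
cytokine oscillator, coupled to a two-dimensional Voronoi tissue with
elastic mechanics, glucose transport, clock-driven cell division/death and a
tissue-level inflammation index with duct-elongation relief.

## Layout

| module | contents |
|---|---|
| `paninsim.grn_boolean` | exact Boolean dynamics of the 14-agent network (cancer + healthy variants), synchronous updates, exhaustive attractor enumeration |
| `paninsim.grn_dde` | continuous two-stage Hill translation with delays (RK4 method of steps, Hermite history), cytokine driver, stage-annotated phenotype profiles |
| `paninsim.tissue_mech` | bounded Voronoi tessellation (rectangle and U-shaped domains), vertex-model elastic energy, finite-difference and spring forces, damped relaxation |
| `paninsim.glucose_transport` | finite-volume diffusion on the adjacency graph, Dirichlet duct sources, uptake calibration |
| `paninsim.cell_fate` | glucose-paced cell-cycle clocks, division/death thresholds, daughter-cell bookkeeping |
| `paninsim.homeostasis` | inflammation index (demanded/realized area), classification, duct elongation |
| `paninsim.orchestrator` | scenario assembly and the half-cycle simulation loop |
| `paninsim.io_cli` | TOML config, JSON snapshots, fixtures, rendering, CLI |

## CLI

```sh
# healthy tissue, published defaults, desk-scale profile
panin run --scenario healthy --seed 1 --out out/healthy

# PanIN 2 starting with 14 seeded cancer cells
panin run --scenario panin2-14 --seed 1 --out out/p14

# custom configuration (empty file = all published defaults)
panin run --config cfg.toml --seed 42 --cycles 20 --out out/custom

# Boolean attractors of the cancer network at frozen inputs/delays
panin grn boolean-attractors --variant cancer --inputs 1 1 --delays 1 1

# continuous network trajectory as CSV
panin grn trajectory --variant cancer --cycles 10 --out traj.csv

# render a tissue snapshot
panin render out/p14/snapshot_00080.json --out p14.png
```

Outputs per run: `manifest.json`, `config.toml` (round-trippable),
`intervals.csv` (per-check cell counts, divisions, deaths, inflammation
index, stage), `events.csv`, and optional `snapshot_*.json` files.

## Notes on scales

Model time is measured in dimensionless units with 12 units per basal
cytokine cycle (T0 = 36 days); delays default to τ1 = 17.13 years and
τ2 = 13.82 years at 360-day years. The library default configuration is the
full 400-cycle (480-month) run; `paninsim.io_cli.profiles` provides the
desk-scale healthy and PanIN 2 profiles used by the test-suite.
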