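"""Generate the synthetic study landscape.

Writes the input bundle the downstream stages consume: ten spatially
autocorrelated environmental layers (two of them collinear on purpose),
80 presence points sampled from a known logistic suitability truth
driven by bio19, bio7 and bio17, six protected-area focal nodes, and
the scenario configuration for two shifted climate stacks.
"""

import json
from pathlib import Path

import yaml

import sdmconnect as sc
from sdmconnect.pipeline import simulate_inputs
from sdmconnect.raster import write_raster

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"

if __name__ == "__main__":
    cfg = sc.PipelineConfig(seed=1)
    stack, truth, occ, nodes, scenarios = simulate_inputs(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.layers.items():
        write_raster(grid, OUT / f"{name}.asc")
    occ.to_csv(OUT / "occurrences.csv")
    write_raster(nodes.as_grid(), OUT / "nodes.asc")
    (OUT / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    (OUT / "scenarios.yaml").write_text(
        yaml.safe_dump({k: s.to_dict() for k, s in scenarios.items()})
    )
    cfg.to_yaml(OUT / "config.yaml")
    print(
        f"landscape: {cfg.n_rows}x{cfg.n_cols} cells of {cfg.cell_size:.0f} m, "
        f"{len(stack)} layers -> {OUT}"
    )
    print(f"presences sampled: {len(occ)}; focal nodes: {len(nodes.node_ids)}")
    print(f"truth drivers: {dict(truth.betas)} (intercept {truth.beta0})")
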