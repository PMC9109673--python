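"""Export the network and a deterministic community-coloured layout.

Writes GraphML (weight + community attributes), a TSV edge list, an SVG
diagram and a coordinates CSV, all byte-stable for a fixed seed.
"""

from pathlib import Path

from themesort import (
    SyntheticConfig,
    build_network,
    compute_layout,
    detect_communities,
    export_network,
    generate_study,
)
from themesort.pipeline import save_layout

out = Path("example_out")
out.mkdir(exist_ok=True)

study = generate_study(SyntheticConfig(seed=5))
net = build_network(study.study)
partition = detect_communities(net, seed=5)

export_network(net, "graphml", out / "network.graphml", partition=partition)
export_network(net, "edge-tsv", out / "edges.tsv")
layout = compute_layout(net, partition, seed=5)
save_layout(layout, net, out / "layout.svg", out / "layout.csv")

print(f"wrote {sorted(p.name for p in out.iterdir())}")
print(f"edge widths encode 1..{max(layout.edge_widths.values())} raters pairing two quotes")
print(f"{partition.n_communities} communities colour the nodes")
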