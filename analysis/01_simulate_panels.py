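"""Generate the synthetic study panels every later step analyses.

The registry extract behind the original county-level analysis is not
public, so the study is reproduced on synthetic panels from the fixture
skeleton: a colorectal-like panel (decade rate 107.72 per 100k) and a
gastric-like panel (135.23 per 100k), each with spatially structured risk,
a smooth temporal trend and unstructured noise.  Into each panel we inject
the printed primary clusters' analogues: a RR 1.82 high-rate cylinder
(Tuyserkan + Hamadan, 2015-2019) for the colorectal panel and a RR 1.87
high-rate cylinder (Nahavand, 2010-2011) for the gastric panel.

Writes results/data/{crc,gc}_panel.csv, adjacency, centroids, and truth
summaries.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from stsir import panel_io, synthetic_data

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20251

skel, graph, cents = synthetic_data.hamadan_fixture()

lines = [f"{r}: " + " ".join(graph.region_ids[j] for j in graph.neighbors[i])
         for i, r in enumerate(graph.region_ids)]
(OUT / "adjacency.txt").write_text("\n".join(lines) + "\n")
pd.DataFrame({"region": cents.region_ids, "latitude": cents.latitude,
              "longitude": cents.longitude}).to_csv(OUT / "centroids.csv", index=False)

specs = {
    "crc": dict(rate=synthetic_data.CRC_DECADE_RATE, seed=SEED,
                inject=(["Tuyserkan", "Hamadan"], (2015, 2019), 1.82)),
    "gc": dict(rate=synthetic_data.GC_DECADE_RATE, seed=SEED + 1,
               inject=(["Nahavand"], (2010, 2011), 1.87)),
}

for name, cfg in specs.items():
    panel, truth = synthetic_data.simulate_panel(
        skel, graph, seed=cfg["seed"], baseline_rate=cfg["rate"])
    regions, window, rr = cfg["inject"]
    panel, truth = synthetic_data.inject_cluster(
        panel, truth, regions, window, rr, seed=cfg["seed"] + 500)
    panel_io.write_panel(panel, OUT / f"{name}_panel.csv")
    summary = {
        "seed": cfg["seed"],
        "total_cases": panel.total_cases,
        "injected": {"regions": regions, "window": window, "rr": rr},
        "theta_range": [float(truth.theta_true.min()), float(truth.theta_true.max())],
    }
    (OUT / f"{name}_truth.json").write_text(json.dumps(summary, indent=1))
    print(f"{name}: total cases {panel.total_cases}, "
          f"true RR range {summary['theta_range'][0]:.2f}-{summary['theta_range'][1]:.2f}, "
          f"injected {rr}x in {regions} {window}")

print(f"inputs written to {OUT}")
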