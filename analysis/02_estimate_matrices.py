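"""Estimate the 6-stage projection matrix for each diet.

Reads the simulated census/oviposition tables from results/data/ and
writes one matrix JSON per diet (interval transitions pooled over all
cohorts; adult survival pinned at 0.99 per interval; fertility from
the oviposition panel).
"""

from pathlib import Path

import numpy as np

from cohortdem import (
    AnalysisConfig,
    estimate_matrix,
    read_census,
    read_oviposition,
    write_matrix,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "matrices"
OUT.mkdir(parents=True, exist_ok=True)

config = AnalysisConfig()
for name in ("control", "penicillin", "tetracycline"):
    census = read_census(DATA / f"census_{name}.csv", config.schema)
    ovi = read_oviposition(DATA / f"oviposition_{name}.csv")
    m = estimate_matrix(census, ovi, config)
    write_matrix(m, OUT / f"matrix_{name}.json")
    print(f"{name}:")
    print(f"  P = {np.round(m.P, 3).tolist()}")
    print(f"  G = {np.round(m.G, 3).tolist()}")
    print(f"  F = {m.F:.3f} eggs/female/interval")
print(f"matrices written to {OUT}")
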