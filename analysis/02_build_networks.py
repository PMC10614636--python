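#!/usr/bin/env python
"""Build each group's age/sex-adjusted partial-correlation network.

Reads the tables written by 01, writes one labeled 61x61 matrix per group to
results/networks/, and summarises how strongly each group's regions covary.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np

import scnkit as sk
from study_config import RESULTS, load_tables

out = RESULTS / "networks"
out.mkdir(parents=True, exist_ok=True)

participants, volumes = load_tables()
networks = sk.build_group_networks(participants, volumes, ("age", "sex"))

print("group  n    mean|r|  max off-diag r")
for g, net in networks.items():
    sk.write_matrix(net.r, net.region_names, net.region_names, out / f"network_{g}.tsv")
    off = net.r[~np.eye(len(net.region_names), dtype=bool)]
    print(f"{g:5s} {net.n_subjects:4d}  {np.abs(off).mean():.3f}    {off.max():.3f}")
print(f"networks written to {out}")
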