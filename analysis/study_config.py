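"""Shared configuration of the synthetic replication study driven by scripts 01-04.

A 164-subject, 4-group cohort (54 HC / 17 SCH / 25 BD / 68 MDD) over the 61
packaged atlas regions, organised into six latent covariance blocks
(baseline within-block correlation 0.2).  Three blocks carry planted
group-specific covariance elevations (0.9) — block 0 in MDD, block 1 in BD,
block 2 in HC — so different diagnostic contrasts light up different region
sets, mirroring the diagnosis-specific cluster structure the analysis is
designed to expose.  The planted contrast (Fisher-z difference ~1.27) is
sized so the elevated blocks are detectable at alpha = 0.001 even in the
comparisons involving the smaller groups; weaker contrasts mainly probe the
well-powered MDD-HC comparison.
"""

from pathlib import Path

import scnkit as sk

RESULTS = Path(__file__).resolve().parent.parent / "results"

SEED = 20240901
ALPHA = 0.001
N_PERM = 4999  # minimum attainable p-value 2e-4 < alpha
K_RANGE = range(1, 11)
N_INIT = 100

SIMULATION = sk.SimulationConfig(
    group_sizes={"HC": 54, "SCH": 17, "BD": 25, "MDD": 68},
    n_regions=61,
    rho_within=0.2,
    block_rho={("MDD", 0): 0.9, ("BD", 1): 0.9, ("HC", 2): 0.9},
    seed=SEED,
)


def load_tables():
    """Re-read the tables written by 01_simulate_cohort.py."""
    out = RESULTS / "synthetic"
    participants = sk.read_participants(out / "participants.tsv")
    volumes = sk.read_roi_volumes(out / "roi_volumes.tsv", participants)
    return participants, volumes
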