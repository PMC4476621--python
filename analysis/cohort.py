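"""Synthetic nine-pair cohort shared by the analysis scripts.

The pairs span the observed behavioral regime: mean movement-cycle
durations from 1.7 s (fastest pair) to 5.9 s (slowest), i.e. rates of
0.17-0.60 Hz, with follower lags well inside the sub-215-ms accuracy all
real pairs attained.  Each pair is fully determined by its seed.
"""

from duomeg.synthgen import PairConfig

# (pair id, mean cycle s, cycle cv, lag mean ms, lag sd ms, seed)
COHORT = [
    ("pair1", 2.60, 0.12, 120.0, 35.0, 101),
    ("pair2", 3.40, 0.15, 160.0, 40.0, 102),
    ("pair3", 1.70, 0.10, 70.0, 20.0, 103),   # fastest, tightest pair
    ("pair4", 2.10, 0.14, 110.0, 30.0, 104),
    ("pair5", 4.50, 0.18, 180.0, 45.0, 105),
    ("pair6", 2.88, 0.15, 150.0, 40.0, 106),
    ("pair7", 5.90, 0.20, 200.0, 50.0, 107),  # slowest pair
    ("pair8", 3.00, 0.12, 130.0, 35.0, 108),
    ("pair9", 2.40, 0.16, 140.0, 40.0, 109),
]


def pair_config(row) -> PairConfig:
    _, mean_cycle, cv, lag_mean, lag_sd, seed = row
    return PairConfig(mean_cycle_s=mean_cycle, cycle_cv=cv,
                      lag_mean_ms=lag_mean, lag_sd_ms=lag_sd, seed=seed)
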