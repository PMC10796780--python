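"""Shared settings for the analysis drivers.

All drivers re-derive the cohort deterministically from SEED, so no
binary intermediates need to be committed; model checkpoints and other
large artifacts go to scratch/.
"""

from pathlib import Path

from hrfprobe.nn import Hyperparams
from hrfprobe.simulate import CohortConfig

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

#: the simulated study: two groups of 10, default patient HRF alterations
#: (peak x0.7, +2.5 s latency, undershoot x0.4), 16^3 common space
COHORT = CohortConfig(n_per_group=10)

#: classifier settings used by drivers 03-05 (small fixed budget; the
#: library's grid_search is available for a proper sweep)
HYPERPARAMS = Hyperparams(training_steps=80, batch_size=8,
                          learning_rate=0.02, momentum=0.9,
                          dropout_rate=0.2)


def load_cohort():
    from hrfprobe.simulate import simulate_cohort
    return simulate_cohort(COHORT, rng_seed=SEED)
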