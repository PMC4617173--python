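import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mircms.simulate import SimulationConfig, simulate_study  # noqa: E402


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """Desk-size study used by unit tests; the full-scale defaults are
    exercised by the recovery suite."""
    base = dict(seed=seed, genome_length=40_000, n_known_mirnas=5,
                n_novel_mirnas=5, n_transcripts=15,
                transcript_length_range=(400, 900), n_planted_targets=4,
                planted_log2fc=(-1.0, -1.0, 1.0, 1.0),
                planted_target_scores=(0.0, 0.0, 0.0, 0.0),
                srna_depth=60_000, degradome_depth=30_000,
                rnaseq_depth=300_000, n_degradome_background=3_000)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def small_result(small_study):
    from mircms.benchmark import run_pipeline

    return run_pipeline(small_study, n_shuffles=50)
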