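import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ticktx.pipeline import run_all
from ticktx.simulate import SimParams, simulate


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study (25 classes x 20 transcripts, 45 libraries)."""
    return simulate(SimParams(rng_seed=1))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline on the default synthetic study (shared: it is the
    expensive fixture every end-to-end check reads from)."""
    s = default_sim
    return run_all(s.transcripts, s.proteome, s.counts, s.design)


@pytest.fixture(scope="session")
def clean_signal_sim():
    """Small mutation-free, all-signal simulation for start-recovery checks."""
    sim = SimParams(
        transcripts_per_class=2,
        proteins_per_class=1,
        fraction_contaminant=0.0,
        fraction_signal_peptide=1.0,
        aa_mutation_rate=0.0,
        rng_seed=7,
    )
    return simulate(sim)


@pytest.fixture(scope="session")
def clean_signal_run(clean_signal_sim):
    s = clean_signal_sim
    return run_all(s.transcripts, s.proteome, s.counts, s.design)
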