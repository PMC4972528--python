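import numpy as np
import pytest

from wtitgh import CloneTree, SimConfig, TrueEvent, simulate_case


def branched_clone_tree() -> CloneTree:
    """Two-branch clone tree: truncal CNNLOH, then a gain branch and a
    loss+CNNLOH branch."""
    return CloneTree(
        parent={"root": None, "founder": "root", "A": "founder", "B": "founder"},
        events={
            "root": [],
            "founder": [TrueEvent("4", 100, 450, "cnnloh", 0)],
            "A": [TrueEvent("1", 100, 400, "gain", 0)],
            "B": [TrueEvent("2", 50, 300, "loss", 1), TrueEvent("3", 0, 250, "cnnloh", 1)],
        },
    )


def branched_config(seed: int = 0, purity: float = 1.0, lrr_sd: float = 0.0,
                    baf_sd: float = 0.0, wave_amplitude: float = 0.0) -> SimConfig:
    return SimConfig(
        clone_tree=branched_clone_tree(),
        sample_assignment={"R1": "A", "R2": "A", "R3": "B", "R4": "B"},
        n_chromosomes=4,
        probes_per_chrom=500,
        purity=purity,
        lrr_sd=lrr_sd,
        baf_sd=baf_sd,
        wave_amplitude=wave_amplitude,
        seed=seed,
    )


@pytest.fixture
def branched_case():
    """Noiseless pure branched 4-sample case."""
    return simulate_case(branched_config(seed=3))


@pytest.fixture
def noisy_branched_case():
    """Branched case at purity 0.8 with realistic noise and waves."""
    return simulate_case(branched_config(seed=7, purity=0.8, lrr_sd=0.12,
                                         baf_sd=0.03, wave_amplitude=0.05))


@pytest.fixture
def flat_case():
    """All tumor samples carry the same single clone."""
    tree = CloneTree(
        parent={"root": None, "clone": "root"},
        events={"root": [], "clone": [TrueEvent("1", 100, 400, "gain", 0)]},
    )
    config = SimConfig(
        clone_tree=tree,
        sample_assignment={"R1": "clone", "R2": "clone", "R3": "clone"},
        n_chromosomes=3,
        probes_per_chrom=400,
        seed=11,
    )
    return simulate_case(config)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
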