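import numpy as np
import pytest

from txdyn.simulate import SimConfig, simulate_counts


def planted_patterns(n_stable: int, n_up: int, n_down: int, k: int = 8, seed: int = 0):
    """Pattern map with all-M genes plus single-transition U and D genes."""
    rng = np.random.default_rng(seed)
    patterns = {f"m{i}": "M" * k for i in range(n_stable)}
    for i in range(n_up):
        p = ["M"] * k
        p[rng.integers(k)] = "U"
        patterns[f"u{i}"] = "".join(p)
    for i in range(n_down):
        p = ["M"] * k
        p[rng.integers(k)] = "D"
        patterns[f"d{i}"] = "".join(p)
    return patterns


@pytest.fixture
def small_sim():
    """9-timepoint NB simulation with planted single-transition genes."""
    patterns = planted_patterns(15, 5, 5, seed=11)
    config = SimConfig(
        pattern_assignments=patterns,
        baseline_means={g: 300.0 for g in patterns},
        dispersion=0.01,
        fold_step=8.0,
        seed=42,
    )
    counts, truth = simulate_counts(config)
    return counts, truth
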