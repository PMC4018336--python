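from __future__ import annotations

import numpy as np
import pytest

from defensinevo import SimConfig, simulate_family
from defensinevo.genetics import SENSE_CODONS
from defensinevo.simulate import make_synthetic_dimer


@pytest.fixture(scope="session")
def reference_dimer():
    return make_synthetic_dimer()


@pytest.fixture(scope="session")
def small_family():
    """A deterministic 12-leaf simulated family under the default regimes."""
    cfg = SimConfig(seed=20240501)
    aln, history = simulate_family(cfg)
    return cfg, aln, history


def random_codon_row(rng: np.random.Generator, n_codons: int) -> str:
    """Gap-free row of random sense codons."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def mutated_row(rng: np.random.Generator, row: str, n_mut: int) -> str:
    """Apply point mutations avoiding stop codons."""
    from defensinevo.genetics import BASES, is_stop

    out = list(row)
    done = 0
    while done < n_mut:
        i = int(rng.integers(len(out)))
        b = BASES[int(rng.integers(4))]
        if b == out[i]:
            continue
        old = out[i]
        out[i] = b
        codon_start = 3 * (i // 3)
        codon = "".join(out[codon_start : codon_start + 3])
        if is_stop(codon):
            out[i] = old
            continue
        done += 1
    return "".join(out)
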