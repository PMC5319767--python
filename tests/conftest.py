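import numpy as np
import pytest

from relaxdesign import (
    PulseEvent,
    PulseKind,
    PulseSequence,
    SPGRProtocol,
    spgr_default,
    tsi_optimized,
    tsi_original,
)


@pytest.fixture(scope="session")
def tsi_new() -> PulseSequence:
    return tsi_optimized()


@pytest.fixture(scope="session")
def tsi_orig() -> PulseSequence:
    return tsi_original()


@pytest.fixture(scope="session")
def spgr() -> SPGRProtocol:
    return spgr_default()


@pytest.fixture(scope="session")
def spgr_317() -> SPGRProtocol:
    """The {3°, 17°} clinical pair, used for closed-form DESPOT1 checks."""
    return SPGRProtocol(
        tr_ms=7.8, te_ms=2.4, flip_angles_deg=(3.0, 17.0), bandwidth_khz=31.3
    )


def make_random_sequence(rng: np.random.Generator) -> PulseSequence:
    """A random valid pulse train: 1-5 imaging pulses, 0-2 inversions."""
    n_imaging = int(rng.integers(1, 6))
    n_inversion = int(rng.integers(0, 3))
    n = n_imaging + n_inversion
    # draw strictly increasing times starting at 0 with gaps >= 50 ms
    gaps = rng.uniform(50.0, 1500.0, size=n - 1) if n > 1 else np.empty(0)
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    tr = times[-1] + rng.uniform(50.0, 3000.0)
    tail = [PulseKind.IMAGING] * (n_imaging - 1) + [PulseKind.INVERSION] * n_inversion
    order = rng.permutation(len(tail))
    kinds = [PulseKind.IMAGING] + [tail[i] for i in order]
    events = tuple(
        PulseEvent(
            t,
            180.0 if k is PulseKind.INVERSION else float(rng.uniform(0.0, 90.0)),
            k,
        )
        for t, k in zip(times, kinds)
    )
    return PulseSequence(tr_ms=float(tr), events=events)
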