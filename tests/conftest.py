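"""Shared fixtures: the two-mode nanocrescent study condition.

The canonical scenario used throughout the suite is the published
simulation regime: bulk sensitivities (325.25, 787.38) nm/RIU, analyte
contrast n_a - n_B = 1.43 - 1.33 = 0.1 RIU, true thickness 6 nm, and
shift noise (0.85, 1.3) nm so that each mode sees SNR = Δλ/σ_λ = 10.
Decay lengths are not tabulated anywhere; they are recovered by inverting
the saturating response at the (d = 6 nm, Δλ = 10 σ_λ) worked point, the
package's own documented calibration recipe.
"""

import numpy as np
import pytest

from adlayer import SensorMode, invert_decay_length

S_BULK = (325.25, 787.38)
SIGMA_LAMBDA = (0.85, 1.3)
CONTRAST = 0.1
N_B = 1.33
N_A = 1.43
D_TRUE = 6.0
SNR = 10.0
#: Shifts at the operating point implied by SNR 10: Δλ_i = 10 σ_λ,i.
SHIFTS = tuple(SNR * s for s in SIGMA_LAMBDA)
MAX_SHIFTS = tuple(sb * CONTRAST for sb in S_BULK)


@pytest.fixture(scope="session")
def decay_lengths():
    return tuple(
        invert_decay_length(dl, dlm, D_TRUE)
        for dl, dlm in zip(SHIFTS, MAX_SHIFTS)
    )


@pytest.fixture
def modes(decay_lengths):
    return [
        SensorMode(
            label=f"mode{i + 1}", s_bulk=sb, decay_length=ld, sigma_lambda=sg
        )
        for i, (sb, ld, sg) in enumerate(
            zip(S_BULK, decay_lengths, SIGMA_LAMBDA)
        )
    ]


@pytest.fixture
def r_lambda():
    return np.diag(np.square(SIGMA_LAMBDA))
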