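"""Built-in example matrices.

Published broad-sense (among-inbred-family) covariance matrices for four
interaction traits of field-grown *Medicago truncatula* -- nodule number,
insect herbivory (proportion of damaged leaves), root biomass and shoot
biomass -- estimated separately under full-sun and 50%-shade treatments
after all traits were scaled to an experiment-wide mean of 1.  The shade
estimates sat below the diagonal of the published table (and first in each
diagonal cell), the sun estimates above (and second); several variances are
boundary zeros next to nonzero covariances, the signature of
unconstrained-structure REML.

These matrices serve as realistic defaults for the simulator and as inputs
for matrix-comparison examples.
"""

from __future__ import annotations

import numpy as np

from .covmatrix import CovMatrix

__all__ = ["TRAITS", "ENVS", "family_g_shade", "family_g_sun", "study_family_matrices"]

TRAITS = ["nodules", "herbivory", "root", "shoot"]
ENVS = ["sun", "shade"]

# Number of families behind each estimate (those with >= 2 survivors per
# treatment in the field experiment).
_N_FAMILIES = 46

_G_SHADE = np.array(
    [
        [0.1195, 0.0448, 0.0303, -0.0003],
        [0.0448, 0.0000, 0.0192, 0.0174],
        [0.0303, 0.0192, 0.0565, 0.0396],
        [-0.0003, 0.0174, 0.0396, 0.0026],
    ]
)

_G_SUN = np.array(
    [
        [0.0151, 0.0419, -0.0787, -0.0494],
        [0.0419, 0.0000, 0.0021, -0.0063],
        [-0.0787, 0.0021, 0.0000, 0.0237],
        [-0.0494, -0.0063, 0.0237, 0.0871],
    ]
)


def family_g_shade() -> CovMatrix:
    """Among-family G matrix in the shade treatment (mean-scaled traits)."""
    return CovMatrix(list(TRAITS), _G_SHADE.copy(), n_effective=_N_FAMILIES)


def family_g_sun() -> CovMatrix:
    """Among-family G matrix in the sun treatment (mean-scaled traits)."""
    return CovMatrix(list(TRAITS), _G_SUN.copy(), n_effective=_N_FAMILIES)


def study_family_matrices() -> dict[str, CovMatrix]:
    """Both published family-level G matrices keyed by environment."""
    return {"sun": family_g_sun(), "shade": family_g_shade()}
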