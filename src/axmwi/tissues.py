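"""Single-pole Debye description of tissue dielectric response.

Every tissue in the axillary phantoms is characterised by a single-relaxation
Debye model with an added static-conductivity term,

    eps_r(omega) = eps_inf + delta_eps / (1 + j*omega*tau) + sigma_s / (j*omega*eps0)

under the engineering e^{+j omega t} time convention, so the imaginary part of
``eps_r`` is non-positive for a passive medium.  ``delta_eps = eps_s - eps_inf``
is the dispersion magnitude, ``sigma_s`` the static (DC) conductivity and
``tau`` the relaxation time.  The shipped :data:`TISSUE_LIBRARY` holds the
published values for skin, adipose/healthy background, muscle and the
surface / cross-section layers of healthy and metastasised axillary lymph
nodes; the relaxation constant (printed only for skin, 13 ps) is shared by all
tissues and is configurable per medium.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.constants import epsilon_0

__all__ = [
    "DebyeMedium",
    "TISSUE_LIBRARY",
    "tissue_library",
    "debye_permittivity",
]

#: Shared relaxation time constant, seconds (published only for skin).
DEFAULT_TAU = 13e-12


@dataclass(frozen=True)
class DebyeMedium:
    """Single-pole Debye medium with static conductivity.

    Parameters
    ----------
    eps_inf : float
        Relative permittivity at infinite frequency (>= 1).
    delta_eps : float
        Dispersion magnitude ``eps_s - eps_inf`` (>= 0, dimensionless).
    sigma_s : float
        Static conductivity in S/m (>= 0).
    tau : float
        Relaxation time in seconds (> 0).
    """

    eps_inf: float
    delta_eps: float
    sigma_s: float
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if self.eps_inf < 1:
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.delta_eps < 0:
            raise ValueError(f"delta_eps must be >= 0, got {self.delta_eps}")
        if self.sigma_s < 0:
            raise ValueError(f"sigma_s must be >= 0, got {self.sigma_s}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")

    @property
    def eps_s(self) -> float:
        """Static relative permittivity ``eps_inf + delta_eps``."""
        return self.eps_inf + self.delta_eps

    def with_tau(self, tau: float) -> "DebyeMedium":
        return replace(self, tau=tau)


# Published Debye parameters for the axillary region (eps_inf, delta_eps,
# sigma_s).  The healthy background tissue is dielectrically modelled after
# adipose tissue; lymph nodes carry distinct surface-layer and cross-section
# (interior) values.
TISSUE_LIBRARY: dict[str, DebyeMedium] = {
    "skin": DebyeMedium(15.93, 23.83, 0.83),
    "adipose": DebyeMedium(3.12, 1.59, 0.05),
    "muscle": DebyeMedium(21.66, 33.24, 0.89),
    "healthy_aln_surface": DebyeMedium(3.60, 1.71, 0.19),
    "healthy_aln_cross": DebyeMedium(10.34, 17.56, 0.57),
    "metastasized_aln_surface": DebyeMedium(6.86, 12.37, 0.67),
    "metastasized_aln_cross": DebyeMedium(8.81, 38.82, 1.15),
    "background_healthy": DebyeMedium(3.12, 1.59, 0.05),
}


def tissue_library(tau: float | None = None) -> dict[str, DebyeMedium]:
    """Return a copy of the default tissue library.

    Parameters
    ----------
    tau : float, optional
        Override the shared relaxation time (seconds) for every tissue.
    """
    lib = dict(TISSUE_LIBRARY)
    if tau is not None:
        lib = {k: m.with_tau(tau) for k, m in lib.items()}
    return lib


def debye_permittivity(medium: DebyeMedium, frequency):
    """Complex relative permittivity of a Debye medium at ``frequency`` (Hz).

    Evaluates ``eps_inf + delta_eps/(1 + j w tau) + sigma_s/(j w eps0)`` with
    ``w = 2 pi f`` under the e^{+jwt} convention (Im eps_r <= 0).  The static
    limit is exposed through :attr:`DebyeMedium.eps_s` rather than ``f = 0``.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be > 0; use DebyeMedium.eps_s for the static limit")
    w = 2.0 * np.pi * f
    eps = np.asarray(
        medium.eps_inf
        + medium.delta_eps / (1.0 + 1j * w * medium.tau)
        + medium.sigma_s / (1j * w * epsilon_0)
    )
    return eps if eps.ndim else complex(eps)
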