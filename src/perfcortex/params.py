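"""Acquisition and kinetic constants for single-delay pCASL quantification.

The defaults reproduce the acquisition used throughout the package: labeling
duration 1950 ms, initial post-labeling delay 1200 ms with a 70 ms per-slice
increment for the 2-D EPI readout, labeling efficiency 0.70 (background-
suppression losses folded in), blood T1 1650 ms and blood-brain partition
coefficient 0.9 ml/g — the latter two being the standard consensus values
for 3 T.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass

from .exceptions import ConfigurationError, DomainError

__all__ = ["AcqParams", "delta_m_scale"]


@dataclass(frozen=True)
class AcqParams:
    """Kinetic/acquisition constants of the single-compartment model.

    Attributes
    ----------
    ld : float
        Labeling duration, ms.
    pld0 : float
        Post-labeling delay of the first slice, ms.
    slice_dt : float
        Per-slice PLD increment of the 2-D readout, ms.
    alpha : float
        Labeling efficiency (0 < alpha <= 1), background suppression included.
    t1b : float
        Longitudinal relaxation time of arterial blood, ms.
    lam : float
        Blood-brain water partition coefficient, ml/g.
    n_pairs : int
        Number of control/label pairs acquired.
    noise_sd : float
        Additive Gaussian noise SD of the simulated series, in control-image
        units (used by the phantom only).
    """

    ld: float = 1950.0
    pld0: float = 1200.0
    slice_dt: float = 70.0
    alpha: float = 0.70
    t1b: float = 1650.0
    lam: float = 0.9
    n_pairs: int = 60
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.ld <= 0 or self.pld0 <= 0 or self.t1b <= 0:
            raise ConfigurationError("ld, pld0 and t1b must be positive")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.lam <= 0:
            raise ConfigurationError("lambda (lam) must be positive")
        if self.n_pairs < 1:
            raise ConfigurationError("n_pairs must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.slice_dt < 0:
            raise ConfigurationError("slice_dt must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def delta_m_scale(pld_ms: float, acq: AcqParams) -> float:
    """Kinetic scale k such that dM/M0 = k * CBF for the one-compartment model.

    k = 2*alpha*T1b*(1 - exp(-LD/T1b))*exp(-PLD/T1b) / (6000*lambda),
    with all times in seconds; CBF in ml*100g^-1*min^-1 (the 6000 factor
    converts ml*g^-1*s^-1 to those units).
    """
    if pld_ms < 0:
        raise DomainError(f"PLD must be non-negative, got {pld_ms}")
    t1b_s = acq.t1b / 1000.0
    ld_s = acq.ld / 1000.0
    pld_s = pld_ms / 1000.0
    return (
        2.0
        * acq.alpha
        * t1b_s
        * (1.0 - math.exp(-ld_s / t1b_s))
        * math.exp(-pld_s / t1b_s)
        / (6000.0 * acq.lam)
    )
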