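"""Modified FERTEX (mFX) herd reproductive-economics score.

The score converts two herd fertility outcomes into a single cost in pounds
per cow per year: days by which the herd's mean DIM at pregnancy exceeds a
60-day target, costed at the herd's price of an extra empty day, plus the
proportion of lactations reaching 300 DIM without conceiving (failure-to-
conceive culls, target zero) costed at the herd's price of an FTC cull.
Higher scores mean worse reproductive performance.  By default deviations
below target are *not* clamped, so a herd beating the 60-day target earns a
negative day-cost component (a credit); set ``clamp=True`` to floor each
component at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["MfxParameters", "mfx_score"]

#: Mean-DIM value used when a herd recorded no conceptions at all.
NO_CONCEPTION_DIM = 300.0


@dataclass
class MfxParameters:
    cost_per_empty_day: float
    cost_per_ftc_cull: float
    target_mean_dim: float = 60.0
    target_prop_ftc: float = 0.0
    clamp: bool = False

    def __post_init__(self) -> None:
        if self.cost_per_empty_day <= 0 or self.cost_per_ftc_cull <= 0:
            raise ValueError("unit costs must be positive")


def mfx_score(outcome, params: MfxParameters) -> float:
    """mFX score (pounds/cow/year) for a herd outcome.

    ``outcome`` is anything with ``mean_dim_at_pregnancy`` and ``prop_ftc``
    attributes, or a ``(mean_dim_at_pregnancy, prop_ftc)`` pair.  A missing
    (NaN) mean DIM — a herd with zero conceptions — is evaluated at 300 DIM.
    """
    if isinstance(outcome, tuple):
        mean_dim, prop_ftc = outcome
    else:
        mean_dim = outcome.mean_dim_at_pregnancy
        prop_ftc = outcome.prop_ftc
    if mean_dim is None or (isinstance(mean_dim, float) and math.isnan(mean_dim)):
        mean_dim = NO_CONCEPTION_DIM
    if not 0.0 <= prop_ftc <= 1.0:
        raise ValueError("prop_ftc must be in [0, 1]")
    day_dev = mean_dim - params.target_mean_dim
    ftc_dev = prop_ftc - params.target_prop_ftc
    if params.clamp:
        day_dev = max(day_dev, 0.0)
        ftc_dev = max(ftc_dev, 0.0)
    return (
        day_dev * params.cost_per_empty_day
        + ftc_dev * params.cost_per_ftc_cull
    )
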