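"""Equivalent dose in 2 Gy fractions (EQD2) under the linear-quadratic model.

For a voxel receiving total physical dose ``D`` in ``n`` equal fractions
(dose per fraction ``d = D / n``),

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)

so EQD2 equals D when d = 2 Gy, exceeds it for hypofractionated delivery
(d > 2 Gy) and tends to D as alpha/beta -> infinity.  Low alpha/beta values
(1 Gy is the default used for urinary endpoints) maximise the spread of EQD2
across fractionation schemes and hence the sensitivity of voxel-wise
dose-response analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import DoseSurfaceMap

__all__ = ["FractionationContext", "eqd2", "eqd2_dsm"]


@dataclass(frozen=True)
class FractionationContext:
    """Fractionation scheme plus the tissue alpha/beta ratio (Gy)."""

    n_fractions: int
    alpha_beta: float = 1.0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be positive")


def eqd2(total_dose, ctx: FractionationContext):
    """EQD2 of a total physical dose (scalar or array, Gy), element-wise.

    Assumes the voxel's total dose was delivered uniformly over
    ``ctx.n_fractions`` fractions.
    """
    d = np.asarray(total_dose, dtype=float)
    if np.any(d[np.isfinite(d)] < 0):
        raise ValueError("total dose must be non-negative")
    per_fraction = d / ctx.n_fractions
    out = d * (per_fraction + ctx.alpha_beta) / (2.0 + ctx.alpha_beta)
    if np.isscalar(total_dose) or np.ndim(total_dose) == 0:
        return float(out)
    return out


def eqd2_dsm(dsm: DoseSurfaceMap, ctx: FractionationContext) -> DoseSurfaceMap:
    """Apply the EQD2 conversion voxel-wise to a physical dose-surface map."""
    if dsm.dose_kind != "physical":
        raise ValueError("DSM is already EQD2-converted")
    doses = np.where(dsm.valid, eqd2(np.where(dsm.valid, dsm.doses, 0.0), ctx),
                     np.nan)
    return replace(dsm, doses=doses, dose_kind="EQD2")
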