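"""Two-compartment blood/tissue sodium mixture model.

A brain voxel is modelled as tissue plus a cerebral-blood-volume (CBV)
fraction of blood with elevated sodium concentration.  The forward model
gives the concentration that would be measured for a voxel containing a
given CBV; its inverse removes the blood contribution from a measured
tissue sodium concentration.  Literature anchors: whole blood ~87 mM,
CBV ~2.7% in white matter and ~5% in gray matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MixtureParams",
    "voxel_concentration",
    "remove_blood",
    "percent_reduction",
    "contribution_curve",
]


@dataclass(frozen=True)
class MixtureParams:
    """Constants of the blood/tissue mixture model.

    Attributes
    ----------
    na_blood_mM : sodium concentration of whole blood (mM).
    cbv_wm, cbv_gm : literature cerebral blood volume fractions for
        white and gray matter.
    cbv_range : CBV interval over which contribution curves are drawn
        (the approximate intra-subject range of vein partial volume).
    """

    na_blood_mM: float = 87.0
    cbv_wm: float = 0.027
    cbv_gm: float = 0.05
    cbv_range: tuple[float, float] = (0.0, 0.30)

    def __post_init__(self) -> None:
        if self.na_blood_mM <= 0:
            raise ValueError("blood concentration must be positive")
        lo, hi = self.cbv_range
        if not (0.0 <= lo < hi < 1.0):
            raise ValueError("cbv_range must satisfy 0 <= lo < hi < 1")
        for v in (self.cbv_wm, self.cbv_gm):
            if not (0.0 <= v < 1.0):
                raise ValueError("CBV fractions must lie in [0, 1)")


def voxel_concentration(tissue_mM: float, params: MixtureParams, cbv: float) -> float:
    """Forward mixture: concentration measured in a voxel with the given CBV.

    ``(1 - cbv) * tissue + cbv * blood``.
    """
    cbv = float(cbv)
    if not (0.0 <= cbv <= 1.0):
        raise ValueError(f"cbv must lie in [0, 1], got {cbv}")
    return (1.0 - cbv) * float(tissue_mM) + cbv * params.na_blood_mM


def remove_blood(measured_mM: float, params: MixtureParams, cbv: float) -> float:
    """Invert the mixture: tissue concentration with the blood contribution removed.

    ``(measured - cbv * blood) / (1 - cbv)``; exact algebraic inverse of
    :func:`voxel_concentration`.
    """
    cbv = float(cbv)
    if not (0.0 <= cbv < 1.0):
        raise ValueError(f"cbv must lie in [0, 1), got {cbv}")
    return (float(measured_mM) - cbv * params.na_blood_mM) / (1.0 - cbv)


def percent_reduction(measured_mM: float, corrected_mM: float) -> float:
    """Percent by which blood removal lowers the measured concentration."""
    if measured_mM <= 0:
        raise ValueError("measured concentration must be positive")
    return 100.0 * (float(measured_mM) - float(corrected_mM)) / float(measured_mM)


def contribution_curve(
    tissue_mM: float, params: MixtureParams, n_points: int = 61
) -> pd.DataFrame:
    """Tabulate voxel concentration and blood signal share over the CBV range.

    Returns a DataFrame with columns ``cbv``, ``voxel_mM`` and
    ``blood_pct`` (the blood compartment's share of the total voxel
    signal, in percent).  The voxel concentration is strictly monotone
    in CBV whenever blood and tissue concentrations differ.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    cbv = np.linspace(params.cbv_range[0], params.cbv_range[1], int(n_points))
    vox = (1.0 - cbv) * float(tissue_mM) + cbv * params.na_blood_mM
    blood_pct = 100.0 * cbv * params.na_blood_mM / vox
    return pd.DataFrame({"cbv": cbv, "voxel_mM": vox, "blood_pct": blood_pct})
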