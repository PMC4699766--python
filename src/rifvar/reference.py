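"""Published Co-60 reference statistics used for calibration and validation.

Two small tables of benchmark values for HUVEC populations irradiated with
a Co-60 gamma source:

* ``COBALT60_ENERGY_TABLE`` — descriptive statistics of specific-energy
  distributions computed for three target volumes (whole nucleus 293.7 um^3,
  6-Gbp DNA molecule 8.5 um^3, and the 1.6 um^3 matching volume) at 0.5, 1
  and 2 Gy, each generated with the same number of events as the biological
  experiments.
* ``COBALT60_RIF_TABLE`` — observed per-nucleus gamma-H2AX focus-count
  statistics for the pooled populations at 0, 0.5, 1 and 2 Gy.

The default beam model is calibrated on the energy table's 293.7 and
8.5 um^3 blocks; the 1.6 um^3 block is deliberately excluded so it can serve
as held-out validation of the fitted SD_rel(V, D) relation.
"""

from __future__ import annotations

from functools import lru_cache

import pandas as pd

from .energy import CalibrationResult, SpecificEnergyModel, calibrate

__all__ = [
    "COBALT60_ENERGY_TABLE",
    "COBALT60_RIF_TABLE",
    "NUCLEUS_VOLUME_UM3",
    "DNA_VOLUME_UM3",
    "MATCHED_VOLUME_UM3",
    "FOCI_PER_GRAY",
    "calibration_points",
    "default_cobalt60_calibration",
    "default_cobalt60_model",
]

NUCLEUS_VOLUME_UM3 = 293.7
DNA_VOLUME_UM3 = 8.5
#: target volume whose energy spread matches the observed RIF-count spread
MATCHED_VOLUME_UM3 = 1.6
#: mean RIF yield per gray from the replicate-level dose-response fit
FOCI_PER_GRAY = 15.5

# columns: volume_um3, dose_Gy, n, mean, median, var, sd, sd_rel
_ENERGY_ROWS = [
    (293.7, 0.5, 8242, 0.500, 0.501, 0.00047, 0.022, 0.043),
    (293.7, 1.0, 8993, 1.000, 1.001, 0.00095, 0.031, 0.031),
    (293.7, 2.0, 9010, 2.000, 2.001, 0.00190, 0.044, 0.022),
    (8.5, 0.5, 8242, 0.501, 0.502, 0.00867, 0.093, 0.186),
    (8.5, 1.0, 8993, 1.001, 1.003, 0.01736, 0.132, 0.132),
    (8.5, 2.0, 9010, 2.002, 2.004, 0.03473, 0.186, 0.093),
    (1.6, 0.5, 8242, 0.503, 0.504, 0.03400, 0.184, 0.367),
    (1.6, 1.0, 8993, 1.002, 1.005, 0.06814, 0.261, 0.260),
    (1.6, 2.0, 9010, 2.003, 2.007, 0.13627, 0.369, 0.184),
]

COBALT60_ENERGY_TABLE = pd.DataFrame(
    _ENERGY_ROWS,
    columns=["volume_um3", "dose_Gy", "n", "mean", "median", "var", "sd", "sd_rel"],
)

# columns: dose_Gy, n, mean, median, mode, var, sd, sd_rel
_RIF_ROWS = [
    (0.0, 25114, 0.6, 0, 0, 2.1, 1.5, 2.558),
    (0.5, 8242, 8.8, 9, 8, 10.2, 3.2, 0.363),
    (1.0, 8993, 17.6, 18, 17, 19.7, 4.4, 0.253),
    (2.0, 9010, 30.6, 31, 31, 30.9, 5.6, 0.182),
]

COBALT60_RIF_TABLE = pd.DataFrame(
    _RIF_ROWS,
    columns=["dose_Gy", "n", "mean", "median", "mode", "var", "sd", "sd_rel"],
)


def calibration_points(include_matched_volume: bool = False) -> list[tuple[float, float, float]]:
    """(V, D, sd_rel) triples from the energy table.

    By default only the 293.7 and 8.5 um^3 blocks are returned, keeping the
    1.6 um^3 block held out for validation.
    """
    tab = COBALT60_ENERGY_TABLE
    if not include_matched_volume:
        tab = tab[tab["volume_um3"] != MATCHED_VOLUME_UM3]
    return list(tab[["volume_um3", "dose_Gy", "sd_rel"]].itertuples(index=False, name=None))


@lru_cache(maxsize=1)
def default_cobalt60_calibration() -> CalibrationResult:
    """Calibration fitted on the nucleus and DNA-molecule volume blocks."""
    return calibrate(calibration_points(), beam_label="Co-60")


def default_cobalt60_model() -> SpecificEnergyModel:
    """Default Co-60 SD_rel(V, D) model (k1 ~ 0.32, k2 ~ 0.82)."""
    return default_cobalt60_calibration().model
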