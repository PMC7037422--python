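"""Experimental condition grid for nanomaterial x irradiation co-exposure.

A sample is described by the nanomaterial applied (if any), its surface
dose, whether the well was irradiated and at what photon dose, and the
post-treatment timepoint.  Surface dose (µg/cm²) is the canonical dose
metric; the matched volumetric concentrations (µg/mL) used when preparing
suspensions are kept as a fixed conversion table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class NMType(str, enum.Enum):
    """Nanomaterial identity: uncoated TiO2 or one of three coatings."""

    NONE = "none"
    TIO2 = "TiO2"
    SIO2TIO2 = "SiO2TiO2"
    AL2O3TIO2 = "Al2O3TiO2"
    ALSITIO2 = "AlSiTiO2"


#: Standard surface-dose grid, µg/cm² (0 = untreated control).
DOSE_GRID: tuple[float, ...] = (0.0, 6.0, 16.0, 32.0, 48.0, 64.0)

#: Fixed pairing of surface dose (µg/cm²) to suspension concentration (µg/mL).
SURFACE_TO_VOLUME_DOSE: dict[float, float] = {
    6.0: 10.0,
    16.0: 25.0,
    32.0: 50.0,
    48.0: 75.0,
    64.0: 100.0,
}

#: Photon dose applied to irradiated wells, Gy.
IR_DOSE_GY = 4.0


@dataclass(frozen=True)
class SampleCondition:
    """One cell of the condition grid.

    Parameters
    ----------
    nm_type : NMType
        Nanomaterial applied to the well.
    dose_surface : float
        Surface dose in µg/cm², >= 0.  Must be 0 when ``nm_type`` is NONE.
    irradiated : bool
        Whether the well received ionizing radiation.
    dose_gy : float
        Photon dose in Gy; positive iff ``irradiated``.
    timepoint_h : float
        Hours after treatment at which the readout is taken, >= 0.
    """

    nm_type: NMType = NMType.NONE
    dose_surface: float = 0.0
    irradiated: bool = False
    dose_gy: float = field(default=0.0)
    timepoint_h: float = 72.0

    def __post_init__(self) -> None:
        if self.dose_surface < 0:
            raise ValueError(
                f"dose_surface must be >= 0 µg/cm², got {self.dose_surface}"
            )
        if self.timepoint_h < 0:
            raise ValueError(f"timepoint_h must be >= 0, got {self.timepoint_h}")
        if self.nm_type == NMType.NONE and self.dose_surface > 0:
            raise ValueError("dose_surface must be 0 when no nanomaterial is applied")
        if self.irradiated and self.dose_gy <= 0:
            # default the photon dose for irradiated wells
            object.__setattr__(self, "dose_gy", IR_DOSE_GY)
        if not self.irradiated and self.dose_gy != 0:
            raise ValueError("dose_gy must be 0 for non-irradiated samples")
        if self.irradiated and self.dose_gy <= 0:
            raise ValueError("dose_gy must be > 0 for irradiated samples")

    @property
    def label(self) -> str:
        ir = f"IR{self.dose_gy:g}Gy" if self.irradiated else "NI"
        return f"{self.nm_type.value}_d{self.dose_surface:g}_{ir}_t{self.timepoint_h:g}h"
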