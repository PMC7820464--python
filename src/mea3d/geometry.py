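"""Device and tissue geometry for the 3D multifunctional MEA.

The standard device is an 18-shank probe arranged as a 3-row x 6-column
matrix (row pitch 500 μm, column pitch 360 μm) carrying 63 recording
microelectrodes (3 or 4 per shank, 85 μm vertical pitch).  One shank — the
multifunctional shank in a corner of the first somatic region — additionally
carries a thinned optical fiber and microfluidic channels.  The probe is
inserted in a compartmentalized collagen tissue (1.85 x 1 x 0.3 mm^3) built
as two somatic regions separated by a central neurite region.

Coordinate frame: x is the long tissue axis (somatic1 -> neurite ->
somatic2), y the short axis, z the depth, origin at a tissue corner with the
shank tips at z = 0.  All coordinates in μm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "Region",
    "ShankSpec",
    "Electrode",
    "ArrayLayout",
    "TissueSpec",
    "OpticalBudget",
    "ChannelSpec",
    "build_standard_array",
    "volume_occupancy",
    "electrode_density",
    "coupling_efficiency",
    "power_density",
    "led_output_power",
    "photon_rate",
    "channel_flow_rate",
]

PLANCK = 6.626_070_15e-34   # J s
LIGHT_SPEED = 2.997_924_58e8  # m/s


class Region(str, Enum):
    """Tissue compartment labels along the long (x) axis."""

    SOMATIC1 = "somatic1"
    NEURITE = "neurite"
    SOMATIC2 = "somatic2"


@dataclass(frozen=True)
class ShankSpec:
    """One probe shank: grid position and cross-section."""

    index: int                 # 1-based, region-major numbering
    row: int                   # 0..2 along y
    column: int                # 0..5 along x
    width: float               # μm
    thickness: float           # μm
    length: float = 6000.0     # μm
    is_multifunctional: bool = False

    def __post_init__(self) -> None:
        if self.width <= 0 or self.thickness <= 0 or self.length <= 0:
            raise ValueError("shank dimensions must be positive")


@dataclass(frozen=True)
class Electrode:
    """One recording site: id 1..63, parent shank, 3D position, region."""

    id: int
    shank_index: int
    position: Tuple[float, float, float]   # μm
    region: Region


@dataclass
class TissueSpec:
    """Engineered tissue block and its compartment boundaries along x."""

    dimensions: Tuple[float, float, float] = (1850.0, 1000.0, 300.0)  # μm
    region_boundaries: Tuple[float, float] = (1850.0 / 3, 2 * 1850.0 / 3)  # μm

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("tissue dimensions must be positive")
        b1, b2 = self.region_boundaries
        if not (0 < b1 < b2 < self.dimensions[0]):
            raise ValueError("region boundaries must be ordered within the x extent")

    @property
    def volume_mm3(self) -> float:
        x, y, z = self.dimensions
        return x * y * z * 1e-9

    def region_of(self, x: float) -> Region:
        b1, b2 = self.region_boundaries
        if x < b1:
            return Region.SOMATIC1
        if x < b2:
            return Region.NEURITE
        return Region.SOMATIC2


@dataclass
class ArrayLayout:
    """Full probe layout: shanks, electrodes, grid pitches."""

    shanks: List[ShankSpec]
    electrodes: List[Electrode]
    row_pitch: float = 500.0     # μm, along y
    column_pitch: float = 360.0  # μm, along x

    def __post_init__(self) -> None:
        ids = [e.id for e in self.electrodes]
        if len(ids) != len(set(ids)):
            raise ValueError("electrode ids must be unique")
        self._by_id = {e.id: e for e in self.electrodes}
        self._by_shank: Dict[int, List[Electrode]] = {}
        for e in self.electrodes:
            self._by_shank.setdefault(e.shank_index, []).append(e)

    @property
    def n_shanks(self) -> int:
        return len(self.shanks)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    @property
    def electrode_ids(self) -> List[int]:
        return sorted(self._by_id)

    def electrode(self, eid: int) -> Electrode:
        try:
            return self._by_id[eid]
        except KeyError:
            raise KeyError(f"unknown electrode id {eid}") from None

    def shank(self, index: int) -> ShankSpec:
        for s in self.shanks:
            if s.index == index:
                return s
        raise KeyError(f"unknown shank index {index}")

    def electrodes_on(self, shank_index: int) -> List[Electrode]:
        return sorted(self._by_shank.get(shank_index, []), key=lambda e: e.position[2])

    def positions(self) -> np.ndarray:
        """(n_electrodes, 3) positions in μm, ordered by electrode id."""
        return np.array([self._by_id[i].position for i in self.electrode_ids])

    @property
    def multifunctional_shank(self) -> ShankSpec:
        mf = [s for s in self.shanks if s.is_multifunctional]
        if len(mf) != 1:
            raise ValueError("layout must have exactly one multifunctional shank")
        return mf[0]

    # -- serialization ----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "units": "um",
            "row_pitch": self.row_pitch,
            "column_pitch": self.column_pitch,
            "shanks": [asdict(s) for s in self.shanks],
            "electrodes": [
                {
                    "id": e.id,
                    "shank_index": e.shank_index,
                    "position": list(e.position),
                    "region": e.region.value,
                }
                for e in self.electrodes
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ArrayLayout":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        shanks = [ShankSpec(**s) for s in payload["shanks"]]
        electrodes = [
            Electrode(
                id=e["id"],
                shank_index=e["shank_index"],
                position=tuple(e["position"]),
                region=Region(e["region"]),
            )
            for e in payload["electrodes"]
        ]
        return cls(
            shanks=shanks,
            electrodes=electrodes,
            row_pitch=payload.get("row_pitch", 500.0),
            column_pitch=payload.get("column_pitch", 360.0),
        )


@dataclass
class OpticalBudget:
    """Electrical-to-optical power budget of the LED-fiber assembly."""

    electrical_input: float = 1.0      # W
    luminous_efficiency: float = 0.0515  # fraction
    fiber_output: float = 0.15         # mW
    core_diameter: float = 50.0        # μm
    wavelength: float = 473.0          # nm

    def __post_init__(self) -> None:
        if not 0 < self.luminous_efficiency < 1:
            raise ValueError("luminous efficiency must be in (0, 1)")
        if self.fiber_output > self.electrical_input * self.luminous_efficiency * 1000:
            raise ValueError("fiber output exceeds the LED output power")


@dataclass
class ChannelSpec:
    """Rectangular microfluidic channel bundle embedded in the shank."""

    width: float = 20.0      # μm
    height: float = 12.0     # μm
    length: float = 6.0      # mm
    count: int = 3
    viscosity: float = 1.0e-3  # Pa s

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("channel count must be >= 1")
        if self.height > self.width:
            raise ValueError("rectangular-duct formula requires height <= width")
        if min(self.width, self.height, self.length, self.viscosity) <= 0:
            raise ValueError("channel dimensions must be positive")


# -- per-shank electrode counts of the standard layout -----------------------
#
# The device integrates 3 or 4 electrodes per shank summing to 63 (21 per
# region).  The assignment below places, relative to the stimulation
# electrode on shank 1 (corner of somatic region 1), 19 electrodes on the
# longitudinal row and 7 on the transverse column — the per-direction
# electrode counts of the evoked-latency analysis.
_ELECTRODE_COUNTS: Dict[Tuple[int, int], int] = {
    (0, 0): 4, (0, 1): 4, (0, 2): 3,
    (1, 0): 4, (1, 1): 3, (1, 2): 3,
    (2, 0): 4, (2, 1): 4, (2, 2): 3,
    (3, 0): 4, (3, 1): 3, (3, 2): 3,
    (4, 0): 4, (4, 1): 4, (4, 2): 3,
    (5, 0): 3, (5, 1): 4, (5, 2): 3,
}

ELECTRODE_PITCH = 85.0      # μm, adjacent electrodes on one shank
TIP_CLEARANCE = 10.0        # μm, lowest electrode above the shank tip
MULTIFUNCTIONAL_WIDTH = 145.0
RECORDING_WIDTH = 63.0
SHANK_THICKNESS = 40.0


def build_standard_array(tissue: Optional[TissueSpec] = None) -> ArrayLayout:
    """Build the standard 18-shank / 63-electrode layout.

    Shanks are numbered region-major (1-6 somatic1, 7-12 neurite,
    13-18 somatic2), within a region by column then row; electrode ids run
    1..63 along shanks, bottom to top.  Shank 1 (column 0, row 0) is the
    multifunctional shank; electrode 1 is its lowest site and serves as the
    optical stimulation reference.
    """
    tissue = tissue or TissueSpec()
    lx, ly, _ = tissue.dimensions
    col_pitch, row_pitch = 360.0, 500.0
    x0 = (lx - 5 * col_pitch) / 2.0
    y0 = (ly - 2 * row_pitch) / 2.0

    order = sorted(_ELECTRODE_COUNTS, key=lambda cr: (cr[0] // 2, cr[0], cr[1]))
    shanks: List[ShankSpec] = []
    electrodes: List[Electrode] = []
    eid = 1
    for sidx, (col, row) in enumerate(order, start=1):
        is_mf = sidx == 1
        shanks.append(
            ShankSpec(
                index=sidx,
                row=row,
                column=col,
                width=MULTIFUNCTIONAL_WIDTH if is_mf else RECORDING_WIDTH,
                thickness=SHANK_THICKNESS,
                is_multifunctional=is_mf,
            )
        )
        x = x0 + col * col_pitch
        y = y0 + row * row_pitch
        for k in range(_ELECTRODE_COUNTS[(col, row)]):
            z = TIP_CLEARANCE + k * ELECTRODE_PITCH
            electrodes.append(
                Electrode(
                    id=eid,
                    shank_index=sidx,
                    position=(x, y, z),
                    region=tissue.region_of(x),
                )
            )
            eid += 1
    layout = ArrayLayout(shanks=shanks, electrodes=electrodes,
                         row_pitch=row_pitch, column_pitch=col_pitch)
    assert layout.n_shanks == 18 and layout.n_electrodes == 63
    return layout


# -- device-level quantities -------------------------------------------------

def volume_occupancy(layout: ArrayLayout, tissue: TissueSpec,
                     insertion_depth: float) -> float:
    """Percent of the tissue volume displaced by the inserted shanks.

    ``insertion_depth`` in μm; returns
    ``100 * sum(width * thickness * depth) / tissue volume``.
    """
    if insertion_depth < 0:
        raise ValueError("insertion depth must be non-negative")
    if insertion_depth > tissue.dimensions[2]:
        raise ValueError("insertion depth exceeds the tissue z extent")
    shank_volume = sum(s.width * s.thickness * insertion_depth for s in layout.shanks)
    return 100.0 * shank_volume * 1e-9 / tissue.volume_mm3


def electrode_density(n_electrodes: int, volume_mm3: float,
                      rounding: str = "none") -> float:
    """Recording sites per mm^3; ``rounding`` in {'none', 'nearest'}."""
    if volume_mm3 <= 0:
        raise ValueError("volume must be positive")
    if n_electrodes < 0:
        raise ValueError("electrode count must be non-negative")
    density = n_electrodes / volume_mm3
    if rounding == "nearest":
        return float(round(density))
    if rounding == "none":
        return density
    raise ValueError(f"unknown rounding mode {rounding!r}")


def coupling_efficiency(source_power: float, delivered_power: float) -> float:
    """Percent of source optical power delivered at the fiber tip."""
    if source_power <= 0:
        raise ValueError("source power must be positive")
    if delivered_power < 0:
        raise ValueError("delivered power must be non-negative")
    return 100.0 * delivered_power / source_power


def power_density(power_mw: float, core_diameter_um: float) -> float:
    """Optical power density (mW/mm^2) over the fiber core cross-section."""
    if core_diameter_um <= 0:
        raise ValueError("core diameter must be positive")
    if power_mw < 0:
        raise ValueError("power must be non-negative")
    radius_mm = core_diameter_um / 2000.0
    return power_mw / (math.pi * radius_mm**2)


def led_output_power(electrical_input_w: float, efficiency: float) -> float:
    """LED optical output (mW) from electrical input (W) and efficiency."""
    if not 0 <= efficiency <= 1:
        raise ValueError("efficiency must be in [0, 1]")
    if electrical_input_w < 0:
        raise ValueError("electrical input must be non-negative")
    return electrical_input_w * efficiency * 1000.0


def photon_rate(power_mw: float, wavelength_nm: float) -> float:
    """Photons per millisecond carried by ``power_mw`` at ``wavelength_nm``.

    Uses the Planck relation E = hc/λ per photon.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    if power_mw < 0:
        raise ValueError("power must be non-negative")
    energy_per_photon = PLANCK * LIGHT_SPEED / (wavelength_nm * 1e-9)  # J
    return power_mw * 1e-3 * 1e-3 / energy_per_photon  # (J/ms) / (J/photon)


def channel_flow_rate(spec: ChannelSpec, pressure_kpa: float) -> float:
    """Pressure-driven flow through the channel bundle, in μL/min.

    Uses the rectangular-duct hydraulic resistance
    ``R = 12 μ L / (w h^3 (1 - 0.63 h/w))`` (valid for h <= w) and
    ``Q = count * ΔP / R``, linear in both pressure and channel count.
    """
    if pressure_kpa < 0:
        raise ValueError("pressure must be non-negative")
    w = spec.width * 1e-6      # m
    h = spec.height * 1e-6     # m
    length = spec.length * 1e-3  # m
    resistance = 12.0 * spec.viscosity * length / (w * h**3 * (1.0 - 0.63 * h / w))
    q_m3_s = spec.count * pressure_kpa * 1e3 / resistance
    return q_m3_s * 1e9 * 60.0  # m^3/s -> μL/min
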