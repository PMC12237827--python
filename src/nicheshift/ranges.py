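"""Geographic range dynamics: areas, RRI/RSI, conservatism, overlap maps.

Potential-range masks from the two populations' ensemble models are compared
by spherical area: the range ratio RRI = RI/RN measures expansion, the
Sorensen-style similarity RSI = 2*RS/(RI+RN) measures position shift, and
range conservatism holds when the introduced range is no larger (RRI < 1)
or remains in place (RSI > 0.5). The expanding range is the part of the
introduced range outside the native one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridError, RangeMask, great_circle_km


@dataclass
class RangeDynamics:
    rn_km2: float
    ri_km2: float
    rs_km2: float
    rri: float
    rsi: float
    expanding_area_km2: float
    expanding_mask: RangeMask
    verdict: str
    centroid_shift_km: float


def range_overlap(native: RangeMask, introduced: RangeMask) -> RangeDynamics:
    """Full range comparison of one species' two populations."""
    if not native.grid.same_lattice(introduced.grid):
        raise GridError("range masks must share the lattice")
    rn, ri = native.area_km2, introduced.area_km2
    if rn <= 0:
        raise ZeroDivisionError("native range is empty")
    shared = native.intersection(introduced)
    expanding = introduced.difference(native)
    rri = ri / rn
    rsi = 2.0 * shared.area_km2 / (ri + rn)
    return RangeDynamics(
        rn_km2=rn,
        ri_km2=ri,
        rs_km2=shared.area_km2,
        rri=rri,
        rsi=rsi,
        expanding_area_km2=expanding.area_km2,
        expanding_mask=expanding,
        verdict=range_conservatism_test(rri, rsi),
        centroid_shift_km=range_centroid_shift(native, introduced),
    )


def range_conservatism_test(rri: float, rsi: float) -> str:
    """'supported' iff the introduced range is no larger (RRI < 1) or keeps
    its position (RSI > 0.5); 'rejected' otherwise."""
    return "supported" if (rri < 1.0 or rsi > 0.5) else "rejected"


def overlap_stack(masks: list[RangeMask]) -> np.ndarray:
    """Cellwise count of overlapping ranges across species."""
    if not masks:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    for m in masks[1:]:
        if not m.grid.same_lattice(grid):
            raise GridError("overlap_stack requires a common lattice")
    return np.sum([m.values.astype(int) for m in masks], axis=0)


def range_centroid_shift(native: RangeMask, introduced: RangeMask) -> float:
    """Great-circle distance (km) between area-weighted range centroids."""
    lon_n, lat_n = native.centroid()
    lon_i, lat_i = introduced.centroid()
    return great_circle_km(lon_n, lat_n, lon_i, lat_i)
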