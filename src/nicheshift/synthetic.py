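"""Virtual landscapes and virtual species with known niche geometry.

Ground truth for the whole pipeline: smooth multi-layer climate fields and a
parametric Gaussian suitability surface in environment space, from which
"native" and "introduced" presences are sampled. The introduced population's
niche can be displaced (centroid shift) and widened/narrowed (breadth scale)
relative to the native one, so downstream niche- and range-shift estimates
can be compared with what was injected.

The Gaussian-in-environment-space suitability model is the standard virtual
species construction; presences sit at cell centres to keep thinning and
extraction unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ClimateStack, Grid
from .occurrences import OccurrenceSet


class DegenerateLandscapeError(ValueError):
    """All-zero suitability: the niche does not intersect the landscape."""


@dataclass(frozen=True)
class VirtualNiche:
    """Gaussian suitability surface in V-dimensional environment space.

    suitability(e) = peak_prevalence * exp(-1/2 (e-mu)' Sigma^-1 (e-mu))
    """

    centroid: np.ndarray  # (V,)
    covariance: np.ndarray  # (V, V), symmetric positive definite
    peak_prevalence: float = 1.0

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.centroid, dtype=float))
        sigma = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        object.__setattr__(self, "centroid", mu)
        object.__setattr__(self, "covariance", sigma)
        if sigma.shape != (mu.size, mu.size):
            raise ValueError("covariance shape must match centroid length")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(sigma).min() <= 0:
            raise ValueError("covariance must be positive definite")
        if not 0 < self.peak_prevalence <= 1:
            raise ValueError("peak_prevalence must lie in (0, 1]")

    @property
    def n_vars(self) -> int:
        return self.centroid.size

    def suitability(self, env: np.ndarray) -> np.ndarray:
        """Evaluate the suitability surface on an (n, V) environment matrix."""
        env = np.atleast_2d(np.asarray(env, dtype=float))
        d = env - self.centroid
        maha = np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.covariance), d)
        return self.peak_prevalence * np.exp(-0.5 * maha)


def generate_landscape(
    n_rows: int,
    n_cols: int,
    n_vars: int,
    smoothness: float = 4.0,
    seed: int = 0,
    *,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
    lat_gradient: float = 0.0,
    cell_size: float = 0.1,
    origin_lon: float | None = None,
    origin_lat: float | None = None,
) -> ClimateStack:
    """Smooth random climate fields on a lon-lat lattice.

    Each layer is white Gaussian noise convolved with a Gaussian kernel of
    width ``smoothness`` (cells), optionally plus a north-south gradient of
    strength ``lat_gradient`` (in post-rescale sd units across the extent),
    then rescaled to the requested per-variable mean and sd (defaults 0 / 1).
    Layers are named ``bio01..bioNN``. Deterministic for a fixed seed.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("n_rows and n_cols must be >= 8")
    if n_vars < 2:
        raise ValueError("n_vars must be >= 2")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    means = np.zeros(n_vars) if means is None else np.asarray(means, dtype=float)
    sds = np.ones(n_vars) if sds is None else np.asarray(sds, dtype=float)
    if means.shape != (n_vars,) or sds.shape != (n_vars,):
        raise ValueError("means/sds must have length n_vars")

    layers = []
    for v in range(n_vars):
        field = rng.standard_normal((n_rows, n_cols))
        field = ndimage.gaussian_filter(field, sigma=smoothness, mode="reflect")
        field = (field - field.mean()) / field.std()
        if lat_gradient:
            # row 0 is north; gradient expressed per full extent
            g = np.linspace(lat_gradient / 2, -lat_gradient / 2, n_rows)
            field = field + g[:, None]
            field = (field - field.mean()) / field.std()
        layers.append(means[v] + sds[v] * field)
    values = np.stack(layers)

    # centre the patch on the equator unless the caller places it
    if origin_lon is None:
        origin_lon = -n_cols * cell_size / 2
    if origin_lat is None:
        origin_lat = -n_rows * cell_size / 2
    grid = Grid(n_rows, n_cols, cell_size, origin_lon, origin_lat)
    names = [f"bio{v + 1:02d}" for v in range(n_vars)]
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    return ClimateStack(grid=grid, layer_names=names, values=values, nodata_mask=mask)


def suitability_map(niche: VirtualNiche, stack: ClimateStack) -> np.ndarray:
    """True suitability per cell (nodata cells get 0)."""
    if niche.n_vars != stack.n_vars:
        raise ValueError("niche dimension must equal stack layer count")
    s = np.zeros(stack.grid.shape)
    rows, cols = stack.valid_cells()
    s[rows, cols] = niche.suitability(stack.env_at(rows, cols))
    return s


def sample_occurrences(
    niche: VirtualNiche,
    stack: ClimateStack,
    n: int,
    status: str = "native",
    seed: int = 0,
    species: str = "virtualis",
) -> OccurrenceSet:
    """Draw ``n`` presence cells i.i.d. with probability proportional to
    suitability; each draw places one record at the drawn cell's centre.

    Duplicate cells are possible (as in real occurrence compilations) and
    are collapsed later by spatial rarefaction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = suitability_map(niche, stack)
    rows, cols = stack.valid_cells()
    w = s[rows, cols]
    total = w.sum()
    if total <= 0:
        raise DegenerateLandscapeError("suitability is zero everywhere on the landscape")
    rng = np.random.default_rng(seed)
    pick = rng.choice(w.size, size=n, replace=True, p=w / total)
    lon, lat = stack.grid.cell_center(rows[pick], cols[pick])
    df = pd.DataFrame(
        {
            "species": species,
            "longitude": lon,
            "latitude": lat,
            "status": status,
            "uncertainty_km": np.nan,
        }
    )
    return OccurrenceSet(df)


def make_shifted_population(
    niche: VirtualNiche,
    centroid_shift: np.ndarray | float = 0.0,
    breadth_scale: float = 1.0,
) -> VirtualNiche:
    """Introduced-population niche: centroid displaced by ``centroid_shift``
    (broadcast over variables) and covariance scaled by breadth_scale**2."""
    if breadth_scale <= 0:
        raise ValueError("breadth_scale must be positive")
    shift = np.broadcast_to(
        np.atleast_1d(np.asarray(centroid_shift, dtype=float)), (niche.n_vars,)
    ).copy() if np.ndim(centroid_shift) == 0 else np.asarray(centroid_shift, dtype=float)
    if shift.shape != (niche.n_vars,):
        raise ValueError("centroid_shift must have length V (or be scalar)")
    return VirtualNiche(
        centroid=niche.centroid + shift,
        covariance=breadth_scale**2 * niche.covariance,
        peak_prevalence=niche.peak_prevalence,
    )
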