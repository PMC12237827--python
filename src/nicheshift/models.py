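"""Top-level modelling surface: one species, native vs introduced.

:class:`NicheShiftModel` wires the whole comparison together in the style of
a statsmodels model object: construct it from an occurrence table and a
climate stack, call :meth:`fit`, and read the estimates off the returned
:class:`NicheShiftResults` (COUE partition, NBR/NSI, RRI/RSI, conservatism
verdicts, TPSR, centroid shifts) or print ``results.summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import occurrences as occmod
from .enm import EnsembleSDM, EnsembleSDMResults, DEFAULT_ALGORITHMS
from .grids import ClimateStack
from .niche import NicheDynamics, NicheGrid, PcaEnvResult, compare_niches
from .predictors import (
    ImportanceTable,
    collinearity_filter,
    correlation_matrix,
    extract_env,
    permutation_importance,
)
from .ranges import RangeDynamics, range_overlap
from .synthesis import SpeciesRecord, tpsr

logger = logging.getLogger(__name__)


class SpeciesExcludedError(RuntimeError):
    """Too few records after cleaning/rarefaction to model the species."""


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31 from one global seed."""
    import zlib

    return (seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class NicheShiftModel:
    """Native-vs-introduced niche and range shift analysis for one species.

    Parameters mirror the pipeline stages: coordinate-uncertainty cut-off and
    thinning cell (km), minimum records per population, collinearity
    threshold, ensemble algorithm set and reliability gates, and the niche
    occupancy-grid resolution.
    """

    occ: occmod.OccurrenceSet
    stack: ClimateStack
    max_uncertainty_km: float = 5.0
    rarefy_cell_km: float = 5.0
    n_min: int = 30
    corr_threshold: float = 0.7
    importance_iters: int = 5
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    n_pa_reps: int = 5
    k: int = 5
    auc_min: float = 0.8
    tss_min: float = 0.6
    niche_grid_r: int = 100
    occupancy_floor: float = 0.0
    screen_predictors: bool = True

    @classmethod
    def from_csv(cls, occ_path: str | Path, stack_dir: str | Path, **kwargs) -> "NicheShiftModel":
        return cls(
            occ=occmod.read_occurrences(occ_path),
            stack=ClimateStack.from_dir(stack_dir),
            **kwargs,
        )

    def fit(self, seed: int = 0) -> "NicheShiftResults":
        # 1. clean, thin, split
        occ = occmod.filter_uncertainty(self.occ, self.max_uncertainty_km)
        occ = occmod.spatial_rarefy(occ, self.rarefy_cell_km, stage_seed(seed, "rarefy"))
        native, introduced = occmod.split_by_status(occ)
        if not occmod.minimum_count_gate(native, introduced, self.n_min):
            raise SpeciesExcludedError(
                f"{occ.species}: <{self.n_min} records in a population after rarefaction"
            )

        # 2. predictor screening on the native population
        if self.screen_predictors and self.stack.n_vars > 2:
            variables, importance = self._screen(native, stage_seed(seed, "predictors"))
        else:
            variables, importance = list(self.stack.layer_names), None

        # 3. per-population ensemble models and range masks
        enm_native = EnsembleSDM(
            native, self.stack, variables, self.algorithms,
            self.n_pa_reps, self.k, self.auc_min, self.tss_min,
        ).fit(stage_seed(seed, "enm_native"))
        enm_introduced = EnsembleSDM(
            introduced, self.stack, variables, self.algorithms,
            self.n_pa_reps, self.k, self.auc_min, self.tss_min,
        ).fit(stage_seed(seed, "enm_introduced"))
        mask_native = enm_native.range_mask()
        mask_introduced = enm_introduced.range_mask()

        # 4. niche dynamics in PCA-env space (background = calibration stack)
        var_idx = [self.stack.layer_names.index(v) for v in variables]
        bg = self.stack.env_table()[:, var_idx]
        env_native = extract_env(native, self.stack)[:, var_idx]
        env_introduced = extract_env(introduced, self.stack)[:, var_idx]
        niche_dyn, grid_native, grid_introduced, pca = compare_niches(
            bg, bg, env_native, env_introduced, variables,
            r=self.niche_grid_r, occupancy_floor=self.occupancy_floor,
        )

        # 5. range dynamics
        range_dyn = range_overlap(mask_native, mask_introduced)

        # 6. top-predictor span ratio in native variable units
        tp = niche_dyn.top_predictor
        j = variables.index(tp)
        tpsr_value = tpsr(env_native[:, j], env_introduced[:, j])

        record = SpeciesRecord(
            species=occ.species or "species",
            tpsr=tpsr_value,
            nbr=niche_dyn.nbr,
            nsi=niche_dyn.nsi,
            rri=range_dyn.rri,
            rsi=range_dyn.rsi,
            niche_verdict=niche_dyn.verdict,
            range_verdict=range_dyn.verdict,
            expansion=niche_dyn.expansion,
            stability=niche_dyn.stability,
            unfilling=niche_dyn.unfilling,
            rn_km2=range_dyn.rn_km2,
            ri_km2=range_dyn.ri_km2,
            expanding_area_km2=range_dyn.expanding_area_km2,
            niche_centroid_shift=niche_dyn.centroid_shift,
            range_centroid_shift_km=range_dyn.centroid_shift_km,
            top_predictor=tp,
        )
        return NicheShiftResults(
            model=self,
            record=record,
            niche=niche_dyn,
            ranges=range_dyn,
            enm_native=enm_native,
            enm_introduced=enm_introduced,
            niche_grid_native=grid_native,
            niche_grid_introduced=grid_introduced,
            pca=pca,
            importance=importance,
            variables=variables,
            n_native=len(native),
            n_introduced=len(introduced),
        )

    def _screen(self, native, seed: int) -> tuple[list[str], ImportanceTable]:
        """Permutation importance from a preliminary model on native data,
        then the greedy collinearity filter."""
        from .enm import fit_member, generate_pseudo_absences

        env_pres = extract_env(native, self.stack)
        pa = generate_pseudo_absences(native, self.stack, n_reps=1, seed=seed)[0]
        x = np.vstack([env_pres, pa])
        y = np.concatenate([np.ones(len(env_pres)), np.zeros(len(pa))])
        prelim = fit_member(x, y, "glm", seed=seed)
        importance = permutation_importance(
            prelim, x, list(self.stack.layer_names), self.importance_iters, seed
        )
        corr, _ = correlation_matrix(x, list(self.stack.layer_names))
        variables = collinearity_filter(corr, importance, self.corr_threshold)
        if len(variables) < 2:  # PCA-env needs two axes
            ranked = importance.to_frame()["variable"].tolist()
            variables = sorted(set(variables) | set(ranked[:2]))
        return variables, importance


@dataclass
class NicheShiftResults:
    """Fitted niche- and range-shift comparison for one species."""

    model: NicheShiftModel
    record: SpeciesRecord
    niche: NicheDynamics
    ranges: RangeDynamics
    enm_native: EnsembleSDMResults
    enm_introduced: EnsembleSDMResults
    niche_grid_native: NicheGrid
    niche_grid_introduced: NicheGrid
    pca: PcaEnvResult
    importance: ImportanceTable | None
    variables: list[str]
    n_native: int
    n_introduced: int
    _extras: dict = field(default_factory=dict, repr=False)

    def summary(self) -> str:
        r, n, g = self.record, self.niche, self.ranges
        lines = [
            f"Niche and range shifts: {r.species}",
            "=" * 40,
            f"records (rarefied): native {self.n_native}, introduced {self.n_introduced}",
            f"predictors retained: {', '.join(self.variables)}",
            f"PCA axes explain {100 * n.variance_explained.sum():.1f}% of background climate",
            f"top predictor: {r.top_predictor}   TPSR = {r.tpsr:.3f}",
            "",
            f"niche:  E = {n.expansion:.3f}  S = {n.stability:.3f}  U = {n.unfilling:.3f}",
            f"        NBR = {r.nbr:.3f}  NSI = {r.nsi:.3f}  "
            f"centroid shift = {n.centroid_shift:.3f} (PCA units)",
            f"        conservatism: {r.niche_verdict}",
            f"range:  RN = {g.rn_km2:,.0f} km2  RI = {g.ri_km2:,.0f} km2  "
            f"RS = {g.rs_km2:,.0f} km2",
            f"        RRI = {r.rri:.3f}  RSI = {r.rsi:.3f}  "
            f"expanding = {g.expanding_area_km2:,.0f} km2  "
            f"centroid shift = {g.centroid_shift_km:,.0f} km",
            f"        conservatism: {r.range_verdict}",
        ]
        return "\n".join(lines)

    def plot(self, path=None):
        """Four-panel overview: the two populations' suitability surfaces in
        geographic space and occupancy grids in PCA-env space.

        Returns the matplotlib figure; saves to ``path`` when given.
        """
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 2, figsize=(9, 8))
        for ax, res, label in (
            (axes[0, 0], self.enm_native, "native"),
            (axes[0, 1], self.enm_introduced, "introduced"),
        ):
            smap = res.predict()
            g = smap.grid
            extent = (
                g.origin_lon, g.origin_lon + g.n_cols * g.cell_size,
                g.origin_lat, g.origin_lat + g.n_rows * g.cell_size,
            )
            im = ax.imshow(smap.values, extent=extent, vmin=0, vmax=1, cmap="viridis")
            t, _ = res.ensemble_mss()
            ax.contour(smap.values, levels=[t], extent=extent,
                       origin="upper", colors="white", linewidths=0.8)
            ax.set_title(f"{label} suitability (MSS {t:.2f})")
            fig.colorbar(im, ax=ax, shrink=0.8)
        for ax, grid, label in (
            (axes[1, 0], self.niche_grid_native, "native"),
            (axes[1, 1], self.niche_grid_introduced, "introduced"),
        ):
            x0, x1, y0, y1 = grid.extents
            im = ax.imshow(grid.z.T, extent=(x0, x1, y0, y1), origin="lower",
                           cmap="magma", aspect="auto")
            cx, cy = grid.centroid()
            ax.plot(cx, cy, "w+", markersize=10)
            ax.set_title(f"{label} niche occupancy (PCA-env)")
            ax.set_xlabel("PC1")
            ax.set_ylabel("PC2")
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.suptitle(f"{self.record.species}: niche and range comparison")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
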