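"""Cross-species synthesis: the per-species index table and its statistics.

Assembles one record per species (niche and range indices, conservatism
verdicts, top-predictor span ratio TPSR), then computes the study-level
summary: conservatism counts, group means with paired t-tests (species with
NBR > 1 vs NBR < 1), TPSR consistency percentages, and correlations between
niche and range shift indices (Pearson when both series pass Shapiro-Wilk
normality, Spearman otherwise).

A published per-species index table can be ingested directly
(:meth:`StudyTable.from_csv` / ``bypass`` mode), so the synthesis stage is
verifiable independently of the upstream spatial stages. The packaged
``data/worst_invasive_ants_indices.csv`` carries the published index values
for the 18 IUCN-recognised worst invasive ant species.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .niche import niche_conservatism_test
from .ranges import range_conservatism_test

logger = logging.getLogger(__name__)


def packaged_ant_table() -> Path:
    """Path to the published 18-species index table shipped with the package."""
    return Path(importlib.resources.files("nicheshift.data") / "worst_invasive_ants_indices.csv")


def tpsr(native_env: np.ndarray, introduced_env: np.ndarray) -> float:
    """Top-predictor span ratio: (max_I - min_I) / (max_N - min_N)."""
    native_env = np.asarray(native_env, dtype=float)
    introduced_env = np.asarray(introduced_env, dtype=float)
    if native_env.size < 2 or introduced_env.size < 2:
        raise ValueError("need at least 2 values per population")
    span_n = float(native_env.max() - native_env.min())
    if span_n <= 0:
        raise ZeroDivisionError("native span of the top predictor is zero")
    return float(introduced_env.max() - introduced_env.min()) / span_n


@dataclass
class SpeciesRecord:
    """One species' niche- and range-shift indices."""

    species: str
    tpsr: float
    nbr: float
    nsi: float
    rri: float
    rsi: float
    niche_verdict: str = ""
    range_verdict: str = ""
    expansion: float = np.nan
    stability: float = np.nan
    unfilling: float = np.nan
    rn_km2: float = np.nan
    ri_km2: float = np.nan
    expanding_area_km2: float = np.nan
    niche_centroid_shift: float = np.nan
    range_centroid_shift_km: float = np.nan
    top_predictor: str = ""

    def __post_init__(self) -> None:
        if not self.niche_verdict:
            self.niche_verdict = niche_conservatism_test(self.nbr, self.nsi)
        if not self.range_verdict:
            self.range_verdict = range_conservatism_test(self.rri, self.rsi)

    @property
    def br_lt_rr(self) -> bool:
        return self.nbr < self.rri

    @property
    def nsi_gt_rsi(self) -> bool:
        return self.nsi > self.rsi


def conservatism_counts(records: list[SpeciesRecord]) -> dict[str, int]:
    """Counts over the table: conservatism rejections and index tallies."""
    return {
        "n_species": len(records),
        "n_niche_rejected": sum(r.niche_verdict == "rejected" for r in records),
        "n_range_rejected": sum(r.range_verdict == "rejected" for r in records),
        "n_nbr_gt_1": sum(r.nbr > 1.0 for r in records),
        "n_rri_lt_1": sum(r.rri < 1.0 for r in records),
        "n_rsi_lt_0.5": sum(r.rsi < 0.5 for r in records),
    }


def _paired_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired t-test p-value; zero-variance differences give p = 1."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if d.size < 2:
        return float("nan")
    if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
        return 1.0
    if np.ptp(d) == 0:
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def group_paired_comparison(records: list[SpeciesRecord]) -> dict:
    """Group means and paired t-tests.

    Species are split at NBR > 1 vs NBR < 1 (NBR exactly 1 joins neither
    group); within each group RRI is compared with NBR by a paired t-test,
    and RSI with NSI over all species.
    """
    out: dict = {}
    groups = {
        "nbr_gt_1": [r for r in records if r.nbr > 1.0],
        "nbr_lt_1": [r for r in records if r.nbr < 1.0],
    }
    excluded = len(records) - sum(len(g) for g in groups.values())
    if excluded:
        logger.info("%d species with NBR exactly 1 fall in neither group", excluded)
    for name, grp in groups.items():
        if len(grp) < 2:
            logger.warning("group %s has < 2 members; skipped", name)
            continue
        rri = np.array([r.rri for r in grp])
        nbr = np.array([r.nbr for r in grp])
        out[name] = {
            "n": len(grp),
            "mean_rri": float(rri.mean()),
            "mean_nbr": float(nbr.mean()),
            "paired_t_p": _paired_t(rri, nbr),
        }
    rsi = np.array([r.rsi for r in records])
    nsi = np.array([r.nsi for r in records])
    out["overall"] = {
        "n": len(records),
        "mean_rsi": float(rsi.mean()),
        "mean_nsi": float(nsi.mean()),
        "paired_t_p": _paired_t(rsi, nsi),
    }
    return out


def tpsr_consistency(records: list[SpeciesRecord]) -> dict[str, float | None]:
    """Percent of niche-expanding (NBR > 1) and range-expanding (RRI > 1)
    species whose top predictor also spans more in the introduced range
    (TPSR > 1)."""
    out: dict[str, float | None] = {}
    for key, pred in (("pct_tpsr_gt_1_of_nbr_gt_1", lambda r: r.nbr > 1.0),
                      ("pct_tpsr_gt_1_of_rri_gt_1", lambda r: r.rri > 1.0)):
        grp = [r for r in records if pred(r)]
        if not grp:
            out[key] = None
            continue
        out[key] = 100.0 * sum(r.tpsr > 1.0 for r in grp) / len(grp)
    return out


def correlate(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[float, float, str]:
    """(coefficient, two-sided p, method): Pearson when both series pass
    Shapiro-Wilk normality at ``alpha``, Spearman otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series: correlation undefined")
    normal = stats.shapiro(x).pvalue > alpha and stats.shapiro(y).pvalue > alpha
    if normal:
        r, p = stats.pearsonr(x, y)
        return float(r), float(p), "pearson"
    r, p = stats.spearmanr(x, y)
    return float(r), float(p), "spearman"


@dataclass
class StudyTable:
    """Cross-species table with a recomputable summary block."""

    records: list[SpeciesRecord]
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = self.compute_summary()

    @classmethod
    def from_csv(cls, path: str | Path) -> "StudyTable":
        """Bypass mode: ingest a pre-computed per-species index table
        (columns species, tpsr, nbr, nsi, rri, rsi; verdicts recomputed)."""
        df = pd.read_csv(path)
        records = [
            SpeciesRecord(
                species=row["species"], tpsr=row["tpsr"], nbr=row["nbr"],
                nsi=row["nsi"], rri=row["rri"], rsi=row["rsi"],
            )
            for _, row in df.iterrows()
        ]
        table = cls(records)
        for col, attr, true_label in (
            ("nc_test", "niche_verdict", "supported"),
            ("rc_test", "range_verdict", "supported"),
        ):
            if col in df.columns:
                printed = df[col].map({"Y": "supported", "N": "rejected"})
                agree = int(
                    sum(getattr(r, attr) == p for r, p in zip(records, printed))
                )
                table.summary[f"{col}_agreement"] = f"{agree}/{len(records)}"
        return table

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.records])
        df["br_lt_rr"] = [r.br_lt_rr for r in self.records]
        df["nsi_gt_rsi"] = [r.nsi_gt_rsi for r in self.records]
        return df

    def compute_summary(self) -> dict:
        summary: dict = {"counts": conservatism_counts(self.records)}
        summary["group_comparison"] = group_paired_comparison(self.records)
        summary["tpsr_consistency"] = tpsr_consistency(self.records)
        corrs = {}
        series = {
            "tpsr": [r.tpsr for r in self.records],
            "nbr": [r.nbr for r in self.records],
            "nsi": [r.nsi for r in self.records],
            "rri": [r.rri for r in self.records],
            "rsi": [r.rsi for r in self.records],
        }
        for xk, yk in (("nbr", "tpsr"), ("rri", "tpsr"), ("nbr", "rri"), ("nsi", "rsi")):
            try:
                r, p, m = correlate(np.array(series[xk]), np.array(series[yk]))
                corrs[f"{xk}_vs_{yk}"] = {"r": r, "p": p, "method": m}
            except ValueError as exc:
                logger.warning("correlation %s vs %s skipped: %s", xk, yk, exc)
        summary["correlations"] = corrs
        return summary

    def write(self, table_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(table_path, index=False)
        if summary_path is not None:
            Path(summary_path).write_text(json.dumps(self.summary, indent=2))

    def summary_text(self) -> str:
        c = self.summary["counts"]
        g = self.summary["group_comparison"]
        t = self.summary["tpsr_consistency"]
        lines = [
            "Cross-species synthesis",
            "=======================",
            f"species: {c['n_species']}",
            f"niche conservatism rejected:  {c['n_niche_rejected']}",
            f"range conservatism rejected:  {c['n_range_rejected']}",
            f"NBR > 1: {c['n_nbr_gt_1']}   RRI < 1: {c['n_rri_lt_1']}   "
            f"RSI < 0.5: {c['n_rsi_lt_0.5']}",
        ]
        if "nbr_gt_1" in g:
            gg = g["nbr_gt_1"]
            lines.append(
                f"NBR>1 group (n={gg['n']}): mean RRI {gg['mean_rri']:.3f} vs "
                f"mean NBR {gg['mean_nbr']:.3f} (paired t p={gg['paired_t_p']:.3f})"
            )
        go = g["overall"]
        lines.append(
            f"overall: mean RSI {go['mean_rsi']:.3f} vs mean NSI "
            f"{go['mean_nsi']:.3f} (paired t p={go['paired_t_p']:.3f})"
        )
        if t["pct_tpsr_gt_1_of_nbr_gt_1"] is not None:
            lines.append(
                f"TPSR > 1 among NBR>1 species: {t['pct_tpsr_gt_1_of_nbr_gt_1']:.0f}%"
            )
        if t["pct_tpsr_gt_1_of_rri_gt_1"] is not None:
            lines.append(
                f"TPSR > 1 among RRI>1 species: {t['pct_tpsr_gt_1_of_rri_gt_1']:.0f}%"
            )
        return "\n".join(lines)


def build_report(records: list[SpeciesRecord], out_dir: str | Path | None = None) -> StudyTable:
    """Assemble the study table and optionally write study_table.csv and
    summary.json into ``out_dir``."""
    table = StudyTable(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.write(out_dir / "study_table.csv", out_dir / "summary.json")
    return table
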