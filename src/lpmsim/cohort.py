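"""Cross-patient aggregation of site collision records.

Regional prevalence is computed per patient (positive sites / sites in the
region, as a percentage) and summarized as mean and population standard
deviation across patients. Collision-free fractions are pooled over sites
("of the regional areas across the patient cases"), not averaged per
patient. Length trends are ordinary least squares of mean regional risk on
device length; device contrasts are paired t tests with Bonferroni
correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .implant import records_to_frame
from .mesh_io import StructureCategory
from .regional import RegionLabels, SeptalCoordinates, grid_resample

logger = logging.getLogger(__name__)

CAT = StructureCategory
STRUCTURE_COLUMNS = {"RV_WALL": "rv_wall", "PM": "pm", "TV": "tv", "COMBINED": "combined"}
ALL_SEPTUM = "ALL_SEPTUM"


@dataclass(frozen=True)
class RegionalRisk:
    region: str  # AHA segment id as str, LBBAP branch, or ALL_SEPTUM
    device: str
    structure: str  # RV_WALL | PM | TV | COMBINED
    mean: float  # %
    sd: float  # % (population SD across patients)
    n_patients: int


@dataclass(frozen=True)
class LengthTrend:
    region: str
    structure: str
    slope_per_5mm: float  # % per 5 mm
    pearson_r: float  # nan when risk is constant
    lengths: tuple[float, ...]


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def _label_frame(labels: dict[str, RegionLabels]) -> pd.DataFrame:
    rows = []
    for patient, lab in labels.items():
        rows.append(pd.DataFrame({
            "patient": patient,
            "node": lab.node_ids,
            "aha": lab.aha,
            "lbbap": lab.lbbap,
            "tv_band": lab.tv_band,
        }))
    return pd.concat(rows, ignore_index=True)


def _region_masks(df: pd.DataFrame) -> dict[str, pd.Series]:
    masks: dict[str, pd.Series] = {ALL_SEPTUM: pd.Series(True, index=df.index)}
    for seg in sorted(df["aha"].unique()):
        masks[str(seg)] = df["aha"] == seg
    for br in sorted(set(df["lbbap"].unique()) - {"none"}):
        masks[br] = df["lbbap"] == br
    return masks


def regional_stats(
    records,
    labels: dict[str, RegionLabels],
    device: str | None = None,
) -> list[RegionalRisk]:
    """Per-region mean +/- SD collision prevalence across patients.

    A patient with no sites in a region is omitted from that region (with a
    logged warning). SDs are population SDs (ddof=0).
    """
    df = _as_frame(records)
    if device is not None:
        df = df[df["device"] == device]
    df = df.merge(_label_frame(labels), on=["patient", "node"], validate="m:1")
    out: list[RegionalRisk] = []
    for dev, ddf in df.groupby("device"):
        for region, mask in _region_masks(ddf).items():
            sub = ddf[mask]
            if not len(sub):
                logger.warning("region %s empty for device %s", region, dev)
                continue
            for structure, col in STRUCTURE_COLUMNS.items():
                per_patient = sub.groupby("patient")[col].mean() * 100.0
                out.append(RegionalRisk(
                    region=region, device=dev, structure=structure,
                    mean=float(per_patient.mean()),
                    sd=float(per_patient.std(ddof=0)),
                    n_patients=int(per_patient.size),
                ))
        covered = set(ddf["patient"].unique())
        for region, mask in _region_masks(ddf).items():
            missing = covered - set(ddf.loc[mask, "patient"].unique())
            for p in missing:
                logger.warning("patient %s has no sites in region %s", p, region)
    return out


def risks_to_frame(risks: list[RegionalRisk]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in risks])


def length_trend(
    sweep_records,
    labels: dict[str, RegionLabels],
    structures: tuple[str, ...] = ("RV_WALL", "PM", "TV", "COMBINED"),
) -> list[LengthTrend]:
    """OLS of mean regional risk on device length, per region and structure.

    Slope is reported per 5 mm of device length together with Pearson r;
    a constant risk has an undefined r (reported as NaN) and zero slope.
    """
    df = _as_frame(sweep_records)
    df = df.merge(_label_frame(labels), on=["patient", "node"], validate="m:1")
    lengths = np.array(sorted(df["length_mm"].unique()), float)
    if len(lengths) < 3:
        raise ValueError("length trend needs at least 3 device lengths")
    out: list[LengthTrend] = []
    for region, mask in _region_masks(df).items():
        sub = df[mask]
        for structure in structures:
            col = STRUCTURE_COLUMNS[structure]
            y = np.array([
                sub[sub["length_mm"] == l].groupby("patient")[col].mean().mean() * 100.0
                for l in lengths
            ])
            if np.ptp(y) < 1e-12:
                out.append(LengthTrend(region, structure, 0.0, float("nan"),
                                       tuple(lengths)))
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.linregress(lengths, y)
            out.append(LengthTrend(region, structure, 5.0 * float(res.slope),
                                   float(res.rvalue), tuple(lengths)))
    return out


def collision_free_fraction(records, labels: dict[str, RegionLabels],
                            region: str) -> float:
    """Pooled % of region sites (across all patients) with no collision."""
    df = _as_frame(records)
    df = df.merge(_label_frame(labels), on=["patient", "node"], validate="m:1")
    mask = _region_masks(df)[region] if region in _region_masks(df) else None
    if mask is None or not mask.any():
        raise ValueError(f"region {region!r} is empty")
    sub = df[mask]
    return float(100.0 * (~sub["combined"]).mean())


@dataclass(frozen=True)
class PairwiseComparison:
    device_a: str
    device_b: str
    region: str
    structure: str
    mean_difference: float  # % (A - B)
    t_statistic: float
    p_adjusted: float  # Bonferroni
    degenerate: bool = False  # zero variance of paired differences


def pairwise_device_compare(
    records,
    labels: dict[str, RegionLabels],
    device_a: str,
    device_b: str,
    region: str = ALL_SEPTUM,
    structure: str = "COMBINED",
    n_comparisons: int = 1,
) -> PairwiseComparison:
    """Paired t test of per-patient regional risks between two devices."""
    df = _as_frame(records)
    df = df.merge(_label_frame(labels), on=["patient", "node"], validate="m:1")
    mask = _region_masks(df).get(region)
    if mask is None:
        raise ValueError(f"unknown region {region!r}")
    col = STRUCTURE_COLUMNS[structure]
    sub = df[mask]
    pa = sub[sub["device"] == device_a].groupby("patient")[col].mean() * 100
    pb = sub[sub["device"] == device_b].groupby("patient")[col].mean() * 100
    common = pa.index.intersection(pb.index)
    if len(common) < 2:
        raise ValueError("paired comparison needs at least 2 patients")
    diff = (pa[common] - pb[common]).to_numpy()
    if np.ptp(diff) < 1e-12 and abs(diff).max() < 1e-12:
        return PairwiseComparison(device_a, device_b, region, structure,
                                  0.0, 0.0, 1.0)
    if np.std(diff) < 1e-12:  # constant nonzero shift: degenerate t
        return PairwiseComparison(device_a, device_b, region, structure,
                                  float(diff.mean()), float("inf"), 0.0,
                                  degenerate=True)
    t, p = stats.ttest_rel(pa[common], pb[common])
    return PairwiseComparison(device_a, device_b, region, structure,
                              float(diff.mean()), float(t),
                              min(1.0, float(p) * n_comparisons))


def cohort_prevalence_map(
    records,
    coords: dict[str, SeptalCoordinates],
    resolution: tuple[int, int] = (50, 50),
    structure: str = "COMBINED",
    threshold: float = 0.5,
):
    """Standardized-grid prevalence: per-cell count of positive patients.

    Each patient's sites are resampled onto the shared (rho, phi) grid; a
    patient is positive at a cell if the majority of their sites binned
    there are positive. Returns ``(counts, coverage, proportion, overlay)``
    where ``overlay`` flags cells positive in more than ``threshold`` of the
    covering patients.
    """
    df = _as_frame(records)
    col = STRUCTURE_COLUMNS[structure]
    counts = np.zeros(resolution)
    coverage = np.zeros(resolution)
    for patient, sub in df.groupby("patient"):
        c = coords[patient]
        sub = sub.set_index("node").loc[c.node_ids]
        grid = grid_resample(c, sub[col].to_numpy(float), resolution)
        covered = ~grid.mask
        coverage += covered
        counts += np.where(covered, grid.filled(0.0) > 0.5, False)
    with np.errstate(invalid="ignore"):
        proportion = np.where(coverage > 0, counts / np.maximum(coverage, 1), np.nan)
    overlay = np.where(coverage > 0, proportion > threshold, False)
    return counts, coverage, proportion, overlay
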