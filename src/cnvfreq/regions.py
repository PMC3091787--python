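"""Dual-method marker selection and CNV-region construction.

The two frequency estimates per marker — Hardy-Weinberg-based (r_l, r_g)
and signal-intensity-based (l_si, g_si) — are combined by calibrating a
mean + k*SD threshold per metric over eligible autosomal markers and
keeping markers that exceed the thresholds of *both* methods for the same
CNV type.  Selected markers of one type that fall within a small distance
of each other are chained into CNV regions (CNVRs); regions can then be
checked against a catalog of previously documented CNV intervals.

Units: r_l and r_g columns are fractions (as produced by
:mod:`cnvfreq.hwe`), l_si and g_si are percent (as produced by
:mod:`cnvfreq.si_freq`); thresholds live in the same units as their metric
column.  Reported region frequencies are percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_DISTANCE = 500  # bp; CNVs can affect genes this far away
DEFAULT_PROXIMITY = 500  # bp; catalog-confirmation padding

REGION_COLUMNS = [
    "region_id", "chromosome", "start", "end", "cnv_type", "n_markers",
    "members", "frequency_pct", "freq_hwe_pct", "freq_si_pct",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Per-metric selection thresholds (mean + multiplier*SD over eligible
    markers).  t_rl/t_rg are fractions; t_lsi/t_gsi are percent."""

    t_rl: float
    t_lsi: float
    t_rg: float
    t_gsi: float


def merge_metrics(hwe_metrics: pd.DataFrame, si_metrics: pd.DataFrame) -> pd.DataFrame:
    """Join per-marker HWE metrics and SI frequencies on marker_id.

    Markers missing from either side are dropped (position-dependent steps
    need both); the SI side contributes chromosome/position.
    """
    merged = si_metrics.join(
        hwe_metrics[["r_l", "r_g", "chi2_p", "polymorphic", "nonautosomal_flag"]],
        how="inner",
    )
    return merged


def _eligible(metrics: pd.DataFrame) -> pd.Series:
    return metrics["polymorphic"] & ~metrics["nonautosomal_flag"]


def calibrate_thresholds(
    metrics: pd.DataFrame, multiplier: float = 1.0
) -> ThresholdSet:
    """Mean + multiplier*SD threshold per metric over eligible markers.

    Eligibility excludes monomorphic and non-autosomal-flagged markers;
    each metric additionally drops its own non-finite values (the
    hemizygous +inf sentinel never enters a mean).  Population SD (ddof=0).
    An all-equal metric yields SD 0 and threshold = mean, with a warning.
    """
    eligible = _eligible(metrics)
    values = {}
    for col in ("r_l", "l_si", "r_g", "g_si"):
        v = metrics.loc[eligible, col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(f"need >= 2 eligible markers to calibrate {col}")
        sd = float(np.std(v))  # population SD
        if sd == 0.0:
            logger.warning("metric %s has zero spread; threshold equals its mean", col)
        values[col] = float(np.mean(v)) + multiplier * sd
    return ThresholdSet(
        t_rl=values["r_l"], t_lsi=values["l_si"],
        t_rg=values["r_g"], t_gsi=values["g_si"],
    )


def select_markers(
    metrics: pd.DataFrame,
    thresholds: ThresholdSet,
    mode: str,
    rule: str = "and",
) -> pd.DataFrame:
    """Markers exceeding the calibrated thresholds for one CNV type.

    ``mode="loss"`` tests r_l against t_rl and l_si against t_lsi;
    ``mode="gain"`` tests r_g/g_si.  The default rule requires *both*
    methods to exceed their threshold (strict >); ``rule="or"`` accepts
    either.  Non-eligible (monomorphic or non-autosomal) markers are never
    selected.  A marker may be selected for both modes.
    """
    if mode not in ("loss", "gain"):
        raise ValueError("mode must be 'loss' or 'gain'")
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    if mode == "loss":
        hwe_hit = metrics["r_l"] > thresholds.t_rl
        si_hit = metrics["l_si"] > thresholds.t_lsi
    else:
        hwe_hit = metrics["r_g"] > thresholds.t_rg
        si_hit = metrics["g_si"] > thresholds.t_gsi
    hit = (hwe_hit & si_hit) if rule == "and" else (hwe_hit | si_hit)
    hit &= _eligible(metrics)
    return metrics.loc[hit.fillna(False)]


def cluster_regions(
    selected: pd.DataFrame,
    marker_map: pd.DataFrame,
    cnv_type: str,
    cluster_distance: int = DEFAULT_CLUSTER_DISTANCE,
) -> pd.DataFrame:
    """Chain selected markers of one type into CNV regions.

    Single-linkage on genomic distance: position-sorted markers on one
    chromosome join the same region while consecutive markers are at most
    *cluster_distance* bp apart.  Singleton regions are allowed (a region
    evident from one marker may be an indel shorter than 1 kb).  Region
    frequency is the mean of member-marker frequencies: the HWE metric
    (percent) as ``freq_hwe_pct`` and headline ``frequency_pct``, the SI
    metric as ``freq_si_pct``.

    Raises KeyError if a selected marker is missing from *marker_map*.
    """
    if cnv_type not in ("loss", "gain"):
        raise ValueError("cnv_type must be 'loss' or 'gain'")
    hwe_col, si_col = ("r_l", "l_si") if cnv_type == "loss" else ("r_g", "g_si")
    known = set(marker_map["marker_id"])
    missing = [m for m in selected.index if m not in known]
    if missing:
        raise KeyError(f"selected markers missing from map: {missing[:5]}")

    mm = marker_map.set_index("marker_id")
    df = selected.assign(
        chromosome=mm.loc[selected.index, "chromosome"].to_numpy(),
        position=mm.loc[selected.index, "position"].to_numpy(),
    )
    from .io_genotypes import sort_by_position

    df = sort_by_position(df.reset_index()).reset_index(drop=True)

    rows = []
    if len(df):
        chrom = df["chromosome"].to_numpy()
        pos = df["position"].to_numpy(dtype=np.int64)
        new_region = np.ones(len(df), dtype=bool)
        new_region[1:] = (chrom[1:] != chrom[:-1]) | (
            pos[1:] - pos[:-1] > cluster_distance
        )
        region_idx = np.cumsum(new_region) - 1
        for rid, grp in df.groupby(region_idx, sort=True):
            hwe_pct = 100.0 * grp[hwe_col].mean()
            si_pct = float(grp[si_col].mean())
            rows.append(
                {
                    "region_id": f"CNVR#{int(rid) + 1}",
                    "chromosome": grp["chromosome"].iloc[0],
                    "start": int(grp["position"].min()),
                    "end": int(grp["position"].max()),
                    "cnv_type": cnv_type,
                    "n_markers": len(grp),
                    "members": ",".join(grp["marker_id"]),
                    "frequency_pct": hwe_pct,
                    "freq_hwe_pct": hwe_pct,
                    "freq_si_pct": si_pct,
                }
            )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a catalog of documented CNV intervals.

    ``.bed`` files are parsed as standard 0-based half-open BED and
    converted to 1-based inclusive; anything else is a TSV of
    (chromosome, start, end[, label]) already 1-based inclusive.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str, skip_blank_lines=True,
    )
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: catalog needs >= 3 columns (chrom, start, end)")
    df = pd.DataFrame(
        {
            "chromosome": raw[0].astype(str),
            "start": raw[1].astype(np.int64),
            "end": raw[2].astype(np.int64),
            "label": raw[3].astype(str)
            if raw.shape[1] > 3
            else [f"catalog_{i}" for i in range(len(raw))],
        }
    )
    df["chromosome"] = df["chromosome"].str.removeprefix("chr")
    if path.suffix.lower() == ".bed":
        df["start"] = df["start"] + 1  # to 1-based inclusive
    return df.astype({"start": np.int64, "end": np.int64})


def confirm_against_catalog(
    regions: pd.DataFrame,
    catalog: pd.DataFrame,
    proximity: int = DEFAULT_PROXIMITY,
) -> tuple[pd.DataFrame, float]:
    """Mark each region confirmed if a documented interval lies within
    *proximity* bp.

    Confirmation is symmetric padded overlap on the same chromosome: the
    gap between the closest edges of the region and a catalog interval must
    be at most *proximity* (overlapping intervals have gap 0).  Returns the
    regions table with a boolean ``confirmed`` column plus the
    catalog-side confirmation rate (fraction of catalog entries within
    *proximity* of some region).
    """
    regions = regions.copy()
    confirmed = np.zeros(len(regions), dtype=bool)
    catalog_hit = np.zeros(len(catalog), dtype=bool)
    cat_by_chrom = {str(c): g for c, g in catalog.groupby("chromosome", sort=False)}
    for i, reg in enumerate(regions.itertuples(index=False)):
        grp = cat_by_chrom.get(str(reg.chromosome))
        if grp is None:
            continue
        hit = (grp["start"].to_numpy() <= reg.end + proximity) & (
            reg.start - proximity <= grp["end"].to_numpy()
        )
        if hit.any():
            confirmed[i] = True
            catalog_hit[grp.index.to_numpy()[hit]] = True
    regions["confirmed"] = confirmed
    rate = float(catalog_hit.mean()) if len(catalog) else float("nan")
    return regions, rate


def write_regions_tsv(regions: pd.DataFrame, path: str | Path) -> None:
    regions.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """BED5+1: chrom, 0-based half-open span, region id, score =
    frequency percent x10 rounded, CNV type."""
    with Path(path).open("w") as fh:
        for reg in regions.itertuples(index=False):
            score = int(round(10 * reg.frequency_pct))
            fh.write(
                f"{reg.chromosome}\t{reg.start - 1}\t{reg.end}\t"
                f"{reg.region_id}\t{score}\t{reg.cnv_type}\n"
            )
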