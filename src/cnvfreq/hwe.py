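"""Trinomial Hardy-Weinberg estimators of copy-loss and copy-gain frequency.

A segregating deletion (null) allele ``r`` makes heterozygous carriers look
like homozygotes and null homozygotes look like no-calls; a duplication
haplotype ``g`` carrying both SNP alleles makes its carriers look
heterozygote-like.  Generalising Hardy-Weinberg to three alleles via the
trinomial expansion ``(p + q + r)^2 = 1`` and inverting the expected
phenotype-class fractions gives closed-form frequency estimators from the
observed fractions of A-like homozygotes (``p_o``), B-like homozygotes
(``q_o``) and heterozygote-like calls (``pq_o``):

    r_l = sqrt(0.25 - 0.25*pq_o + p_o*q_o/pq_o) - 0.5        (null allele)
    r_g = sqrt(p_o + q_o + pq_o) - sqrt(p_o) - sqrt(q_o)      (gain allele)

Both are exact on model-expected fractions and zero under plain biallelic
HWE.  Negative values are retained: "negative loss" is evidence of gain and
vice versa, and the anti-symmetry of the two estimators on the opposite
model is itself a diagnostic signal.  A loss frequency above 100% cannot
arise on an autosome and marks a marker that behaves hemizygously — i.e. a
sex-chromosome marker misplaced onto an autosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_genotypes import COUNT_COLUMNS

DENOMINATORS = ("called", "total")

METRIC_COLUMNS = [
    "n_called", "n_nocall", "p_o", "q_o", "pq_o",
    "r_l", "r_g", "chi2", "chi2_p", "expected_nocalls",
    "polymorphic", "nonautosomal_flag",
]


class DegenerateMarkerError(ValueError):
    """Marker with no usable calls for the requested denominator."""


@dataclass(frozen=True)
class PhenotypeFrequencies:
    """Observed phenotype-class fractions at one marker.

    ``p_o``/``q_o``/``pq_o`` are fractions of the chosen denominator ``n``
    (called individuals by default, in which case they sum to 1 exactly).
    """

    p_o: float
    q_o: float
    pq_o: float
    n: int
    nocall_rate: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("p_o", "q_o", "pq_o"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_o + self.q_o + self.pq_o > 1 + 1e-9:
            raise ValueError("phenotype fractions sum above 1")


def phenotype_frequencies(
    counts, denominator: str = "called"
) -> PhenotypeFrequencies:
    """Phenotype-class fractions from genotype counts.

    *counts* is any mapping/Series with n_AA, n_AB, n_BB, n_nocall.  The
    default denominator is the number of successfully called individuals;
    ``denominator="total"`` divides by all sampled individuals instead
    (under a segregating null allele the called-only choice slightly
    inflates the loss estimate, since null homozygotes fall in the no-call
    class and shrink the denominator).
    """
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    n_aa, n_ab, n_bb, n_nc = (int(counts[c]) for c in COUNT_COLUMNS)
    n_called = n_aa + n_ab + n_bb
    n_total = n_called + n_nc
    n = n_called if denominator == "called" else n_total
    if n < 1:
        raise DegenerateMarkerError(
            f"no {'called individuals' if denominator == 'called' else 'samples'} at marker"
        )
    return PhenotypeFrequencies(
        p_o=n_aa / n,
        q_o=n_bb / n,
        pq_o=n_ab / n,
        n=n,
        nocall_rate=n_nc / n_total if n_total else 0.0,
    )


def estimate_loss(freqs: PhenotypeFrequencies) -> float:
    """Null-allele (copy-loss) frequency r_l from phenotype fractions.

    Returns ``+inf`` when no heterozygotes were observed but both
    homozygote classes were (the hemizygous signature — flagged, not an
    error) and ``nan`` for a monomorphic marker, where the estimator is
    undefined.  Negative values are meaningful (gain evidence) and are not
    clamped.
    """
    p_o, q_o, pq_o = freqs.p_o, freqs.q_o, freqs.pq_o
    if pq_o == 0.0:
        if p_o > 0.0 and q_o > 0.0:
            return float("inf")
        return float("nan")
    radicand = 0.25 - 0.25 * pq_o + p_o * q_o / pq_o
    # provably >= 0 for valid fractions: equals ((1-pq_o)/2)^2 + p_o*q_o/pq_o
    #   - pq_o*(1-pq_o)/4 + pq_o^2/4 ... kept guarded against rounding
    return float(np.sqrt(max(radicand, 0.0)) - 0.5)


def estimate_gain(freqs: PhenotypeFrequencies) -> float:
    """Gain-allele (duplication) frequency r_g from phenotype fractions.

    The gain model assumes the duplicated haplotype carries both SNP
    alleles, so every carrier presents heterozygote-like.  Negative values
    (loss evidence) are retained.
    """
    p_o, q_o, pq_o = freqs.p_o, freqs.q_o, freqs.pq_o
    if pq_o == 0.0 and (p_o == 0.0 or q_o == 0.0):
        return float("nan")
    return float(np.sqrt(p_o + q_o + pq_o) - np.sqrt(p_o) - np.sqrt(q_o))


def hwe_chi2(counts) -> tuple[float, float]:
    """Biallelic HWE goodness-of-fit chi-square (1 df) on called genotypes.

    Allele frequency p̂ = (2 n_AA + n_AB) / (2 n_called); expected class
    counts n_called * (p̂², 2p̂q̂, q̂²); no continuity correction.  A
    monomorphic marker returns (0.0, 1.0) — no test is possible.
    """
    n_aa, n_ab, n_bb = int(counts["n_AA"]), int(counts["n_AB"]), int(counts["n_BB"])
    n_called = n_aa + n_ab + n_bb
    if n_called < 1:
        raise DegenerateMarkerError("no called individuals")
    p_hat = (2 * n_aa + n_ab) / (2 * n_called)
    q_hat = 1.0 - p_hat
    if p_hat == 0.0 or q_hat == 0.0:
        return 0.0, 1.0
    expected = n_called * np.array([p_hat**2, 2 * p_hat * q_hat, q_hat**2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def expected_nocalls(r_l: float, n: int) -> float:
    """Expected count of null-homozygote no-calls, n * max(r_l, 0)^2.

    Under a segregating null allele at frequency r, rr homozygotes yield
    no signal, so the no-call count should be at least n*r^2; negative
    loss estimates are clamped (losses only).
    """
    if not np.isfinite(r_l):
        raise ValueError("r_l must be finite")
    return n * max(r_l, 0.0) ** 2


def marker_metrics(
    counts: pd.DataFrame, denominator: str = "called"
) -> pd.DataFrame:
    """Vectorised per-marker HWE metrics table.

    Input is the per-marker counts DataFrame (index marker_id, columns
    n_AA, n_AB, n_BB, n_nocall).  Output adds p_o/q_o/pq_o, r_l, r_g, the
    HWE chi-square and p-value, the expected no-call count, and the
    polymorphic / non-autosomal flags.  Monomorphic markers (fewer than two
    phenotype classes observed) get NaN estimators and are excluded from
    threshold calibration downstream; markers with r_l > 1 (including the
    no-heterozygote +inf sentinel) are flagged non-autosomal.
    """
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    n_aa = counts["n_AA"].to_numpy(dtype=float)
    n_ab = counts["n_AB"].to_numpy(dtype=float)
    n_bb = counts["n_BB"].to_numpy(dtype=float)
    n_nc = counts["n_nocall"].to_numpy(dtype=float)
    n_called = n_aa + n_ab + n_bb
    n_total = n_called + n_nc
    n = n_called if denominator == "called" else n_total

    with np.errstate(divide="ignore", invalid="ignore"):
        p_o = np.where(n > 0, n_aa / n, np.nan)
        q_o = np.where(n > 0, n_bb / n, np.nan)
        pq_o = np.where(n > 0, n_ab / n, np.nan)

        polymorphic = ((n_aa > 0).astype(int) + (n_ab > 0).astype(int)
                       + (n_bb > 0).astype(int)) >= 2

        # r_l: formula where hets observed; +inf sentinel where both hom
        # classes but no hets; NaN otherwise (monomorphic/degenerate)
        radicand = 0.25 - 0.25 * pq_o + p_o * q_o / pq_o
        r_l = np.sqrt(np.maximum(radicand, 0.0)) - 0.5
        hemi = (pq_o == 0) & (p_o > 0) & (q_o > 0)
        r_l = np.where(hemi, np.inf, r_l)
        r_l = np.where(polymorphic | hemi, r_l, np.nan)

        r_g = np.sqrt(p_o + q_o + pq_o) - np.sqrt(p_o) - np.sqrt(q_o)
        r_g = np.where(polymorphic, r_g, np.nan)

        # HWE chi-square on called genotypes
        p_hat = np.where(n_called > 0, (2 * n_aa + n_ab) / (2 * n_called), np.nan)
        q_hat = 1.0 - p_hat
        exp_aa = n_called * p_hat**2
        exp_ab = n_called * 2 * p_hat * q_hat
        exp_bb = n_called * q_hat**2
        stat = np.where(
            (p_hat > 0) & (q_hat > 0),
            (n_aa - exp_aa) ** 2 / exp_aa
            + (n_ab - exp_ab) ** 2 / exp_ab
            + (n_bb - exp_bb) ** 2 / exp_bb,
            0.0,
        )
        stat = np.where(n_called > 0, stat, np.nan)
        chi2_p = stats.chi2.sf(stat, df=1)
        chi2_p = np.where(stat == 0.0, 1.0, chi2_p)

        exp_nc = n * np.maximum(np.where(np.isfinite(r_l), r_l, 0.0), 0.0) ** 2

    out = counts[COUNT_COLUMNS].copy()
    out["n_called"] = n_called.astype(np.int64)
    out["p_o"] = p_o
    out["q_o"] = q_o
    out["pq_o"] = pq_o
    out["r_l"] = r_l
    out["r_g"] = r_g
    out["chi2"] = stat
    out["chi2_p"] = chi2_p
    out["expected_nocalls"] = exp_nc
    out["polymorphic"] = polymorphic
    out["nonautosomal_flag"] = np.where(np.isnan(r_l), False, r_l > 1.0)
    out.attrs["denominator"] = denominator
    return out


def flag_nonautosomal(metrics: pd.DataFrame, marker_map: pd.DataFrame) -> pd.DataFrame:
    """Group non-autosomal-flagged markers into contiguous runs.

    Markers with r_l > 100% are sex-chromosome candidates; when several
    flagged markers are adjacent in map order on one chromosome the run is
    reported as a single block, making clustered misplacements (a
    misassembled X fragment) visible.  Returns one row per run with
    chromosome, start/end bp, marker count and member ids.
    """
    merged = marker_map.merge(
        metrics[["nonautosomal_flag"]], left_on="marker_id", right_index=True,
        how="inner",
    )
    from .io_genotypes import sort_by_position

    merged = sort_by_position(merged).reset_index(drop=True)
    flagged = merged["nonautosomal_flag"].to_numpy(dtype=bool)
    # run breaks at chromosome changes or any unflagged marker between
    chrom = merged["chromosome"].to_numpy()
    run_id = np.full(len(merged), -1, dtype=np.int64)
    current = -1
    prev_flagged = False
    prev_chrom = None
    for i in range(len(merged)):
        if flagged[i]:
            if not (prev_flagged and chrom[i] == prev_chrom):
                current += 1
            run_id[i] = current
        prev_flagged = flagged[i]
        prev_chrom = chrom[i]
    rows = []
    sub = merged[run_id >= 0].assign(run=run_id[run_id >= 0])
    for rid, grp in sub.groupby("run", sort=True):
        rows.append(
            {
                "run_id": int(rid),
                "chromosome": grp["chromosome"].iloc[0],
                "start": int(grp["position"].min()),
                "end": int(grp["position"].max()),
                "n_markers": len(grp),
                "markers": ",".join(grp["marker_id"]),
            }
        )
    return pd.DataFrame(
        rows, columns=["run_id", "chromosome", "start", "end", "n_markers", "markers"]
    )


def write_metrics(
    metrics: pd.DataFrame, marker_map: pd.DataFrame | None, path, percent: bool = False
) -> None:
    """Write the per-marker metrics table as TSV, optionally with map columns
    and frequencies scaled to percent."""
    out = metrics.copy()
    if percent:
        for col in ("p_o", "q_o", "pq_o", "r_l", "r_g"):
            out[col] = out[col] * 100.0
    if marker_map is not None:
        out = marker_map.set_index("marker_id").join(out, how="right")
    out.to_csv(path, sep="\t", float_format="%.6g")
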