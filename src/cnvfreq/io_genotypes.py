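"""Genotype-call I/O and per-marker genotype counting.

Reads GenomeStudio-style "final report" files and plain sample x marker
genotype matrices, and reduces either to per-marker genotype counts
(``n_AA``, ``n_AB``, ``n_BB``, ``n_nocall``) — the sufficient statistic for
all downstream Hardy-Weinberg arithmetic.

Conventions
-----------
* Heterozygosity is decided on the unordered allele pair (``AG`` == ``GA``);
  no strand/TOP-BOT normalisation is performed, inputs are assumed
  strand-consistent.
* A call with one or both alleles missing (``-``) is a no-call.
* Per marker, the lexicographically smaller observed allele symbol is the
  "A" allele; the homozygote classes are symmetric for every statistic
  computed downstream, so this choice only fixes reporting order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["n_AA", "n_AB", "n_BB", "n_nocall"]

MISSING_ALLELE = "-"
VALID_ALLELES = frozenset({"A", "C", "G", "T", MISSING_ALLELE})

_REPORT_COLUMNS = ("SNP Name", "Sample ID")  # allele columns matched by prefix


class FinalReportError(ValueError):
    """Malformed or inconsistent final-report content."""


def read_marker_map(path: str | Path) -> pd.DataFrame:
    """Read a 3-column tab-delimited marker map (marker_id, chromosome, position).

    Positions are 1-based bp. Raises on duplicate marker ids or
    non-positive positions.
    """
    mm = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["marker_id", "chromosome", "position"],
        dtype={"marker_id": str, "chromosome": str, "position": np.int64},
        comment="#",
    )
    validate_marker_map(mm)
    return mm


def validate_marker_map(mm: pd.DataFrame) -> None:
    if mm["marker_id"].duplicated().any():
        dup = mm.loc[mm["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker_id in map: {dup!r}")
    if (mm["position"] < 1).any():
        raise ValueError("marker map positions must be >= 1 (1-based bp)")


def write_marker_map(mm: pd.DataFrame, path: str | Path) -> None:
    mm[["marker_id", "chromosome", "position"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def sort_by_position(mm: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by (chromosome, position); chromosome labels sort naturally
    (numeric labels numerically, then X and others lexicographically)."""
    key = mm["chromosome"].astype(str)
    numeric = pd.to_numeric(key, errors="coerce")
    return (
        mm.assign(_num=numeric.fillna(np.inf), _lab=key)
        .sort_values(["_num", "_lab", "position"], kind="stable")
        .drop(columns=["_num", "_lab"])
    )


def _classify_call(a1: str, a2: str) -> str | None:
    """Return 'hom'/'het' phenotype class or None for a no-call."""
    if a1 == MISSING_ALLELE or a2 == MISSING_ALLELE:
        return None
    return "hom" if a1 == a2 else "het"


def read_final_report(
    path: str | Path, marker_map: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read a GenomeStudio-style final report into per-marker genotype counts.

    The file is a header block terminated by a ``[Data]`` line, then a
    tab-delimited table whose columns include ``SNP Name``, ``Sample ID``
    and two allele columns (``Allele1 - Top`` / ``Allele2 - Top``, matched
    by prefix ``Allele1`` / ``Allele2``); ``-`` denotes a missing allele.

    Returns a DataFrame indexed by marker_id with columns
    ``n_AA, n_AB, n_BB, n_nocall`` plus the per-marker allele pair
    ``allele_a, allele_b``.  Markers present in the report but absent from
    *marker_map* (when given) are retained, listed in
    ``result.attrs["unknown_markers"]`` and logged as a warning — callers
    doing position-dependent work must drop them explicitly.

    Raises :class:`FinalReportError` on a duplicate (marker, sample) row
    (naming the first duplicate) or on a malformed line (with its number).
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()

    try:
        data_at = next(i for i, ln in enumerate(lines) if ln.strip() == "[Data]")
    except StopIteration:
        raise FinalReportError(f"{path}: no [Data] sentinel line found")
    header_at = data_at + 1
    if header_at >= len(lines):
        raise FinalReportError(f"{path}: no column header after [Data]")
    header = lines[header_at].split("\t")

    def _col(name_or_prefix: str, prefix: bool = False) -> int:
        for i, h in enumerate(header):
            if (prefix and h.startswith(name_or_prefix)) or h == name_or_prefix:
                return i
        raise FinalReportError(f"{path}: missing column {name_or_prefix!r}")

    i_snp = _col("SNP Name")
    i_sample = _col("Sample ID")
    i_a1 = _col("Allele1", prefix=True)
    i_a2 = _col("Allele2", prefix=True)
    ncols = len(header)

    seen: set[tuple[str, str]] = set()
    hom: dict[str, dict[str, int]] = {}  # marker -> allele -> homozygote count
    het: dict[str, int] = {}
    nocall: dict[str, int] = {}
    alleles_seen: dict[str, set[str]] = {}
    order: list[str] = []

    for lineno, ln in enumerate(lines[header_at + 1 :], start=header_at + 2):
        if not ln.strip():
            continue
        toks = ln.split("\t")
        if len(toks) != ncols:
            raise FinalReportError(
                f"{path}:{lineno}: expected {ncols} tab-separated fields, got {len(toks)}"
            )
        marker, sample = toks[i_snp], toks[i_sample]
        a1, a2 = toks[i_a1].strip(), toks[i_a2].strip()
        if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
            raise FinalReportError(
                f"{path}:{lineno}: invalid allele symbols {a1!r}/{a2!r}"
            )
        key = (marker, sample)
        if key in seen:
            raise FinalReportError(
                f"{path}:{lineno}: duplicate row for marker {marker!r}, sample {sample!r}"
            )
        seen.add(key)
        if marker not in het:
            order.append(marker)
            hom[marker] = {}
            het[marker] = 0
            nocall[marker] = 0
            alleles_seen[marker] = set()
        cls = _classify_call(a1, a2)
        if cls is None:
            nocall[marker] += 1
        elif cls == "het":
            het[marker] += 1
            alleles_seen[marker].update((a1, a2))
        else:
            hom[marker][a1] = hom[marker].get(a1, 0) + 1
            alleles_seen[marker].add(a1)

    rows = []
    for m in order:
        alleles = sorted(alleles_seen[m])
        if len(alleles) > 2:
            raise FinalReportError(
                f"{path}: marker {m!r} has >2 allele symbols {alleles}"
            )
        a = alleles[0] if alleles else ""
        b = alleles[1] if len(alleles) > 1 else ""
        n_aa = hom[m].get(a, 0) if a else 0
        n_bb = hom[m].get(b, 0) if b else 0
        rows.append((m, n_aa, het[m], n_bb, nocall[m], a, b))

    counts = pd.DataFrame(
        rows, columns=["marker_id", *COUNT_COLUMNS, "allele_a", "allele_b"]
    ).set_index("marker_id")

    unknown: list[str] = []
    if marker_map is not None:
        known = set(marker_map["marker_id"])
        unknown = [m for m in order if m not in known]
        if unknown:
            logger.warning(
                "%d markers in %s absent from marker map (retained in counts, "
                "excluded from position-dependent steps): %s%s",
                len(unknown), path, ", ".join(unknown[:5]),
                "..." if len(unknown) > 5 else "",
            )
    counts.attrs["unknown_markers"] = unknown
    return counts


def write_final_report(
    genotypes: pd.DataFrame,
    alleles: dict[str, tuple[str, str]],
    path: str | Path,
    project_name: str = "cnvfreq simulated panel",
) -> None:
    """Write a genotype code matrix as a GenomeStudio-style final report.

    *genotypes* is samples x markers with codes {0, 1, 2, NaN}; *alleles*
    maps each marker to its (allele_a, allele_b) nucleotide pair.
    """
    path = Path(path)
    markers = list(genotypes.columns)
    with path.open("w") as fh:
        fh.write("[Header]\n")
        fh.write(f"Project\t{project_name}\n")
        fh.write(f"Num Samples\t{len(genotypes)}\n")
        fh.write(f"Num SNPs\t{len(markers)}\n")
        fh.write("[Data]\n")
        fh.write("SNP Name\tSample ID\tAllele1 - Top\tAllele2 - Top\n")
        arr = genotypes.to_numpy(dtype=float)
        for j, m in enumerate(markers):
            a, b = alleles[m]
            for i, sample in enumerate(genotypes.index):
                code = arr[i, j]
                if np.isnan(code):
                    a1 = a2 = MISSING_ALLELE
                elif code == 0:
                    a1 = a2 = a
                elif code == 1:
                    a1, a2 = a, b
                elif code == 2:
                    a1 = a2 = b
                else:
                    raise ValueError(f"invalid genotype code {code!r} at ({sample}, {m})")
                fh.write(f"{m}\t{sample}\t{a1}\t{a2}\n")


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited genotype matrix (first column sample ID, cells in
    {0,1,2,NA}) into a samples x markers float DataFrame with NaN no-calls."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return df.astype(float)


def write_genotype_matrix(genotypes: pd.DataFrame, path: str | Path) -> None:
    out = genotypes.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def counts_from_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-marker genotype counts from a samples x markers code matrix.

    Codes: 0 = AA, 1 = AB, 2 = BB, NaN/NA = no-call.  Column (marker) order
    is preserved.  An empty matrix (0 samples) yields all-zero counts with
    ``attrs["degenerate"] = True``.
    """
    arr = matrix.to_numpy(dtype=float)
    bad = ~(np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype code {arr[i, j]!r} at sample "
            f"{matrix.index[i]!r}, marker {matrix.columns[j]!r}"
        )
    counts = pd.DataFrame(
        {
            "n_AA": (arr == 0.0).sum(axis=0),
            "n_AB": (arr == 1.0).sum(axis=0),
            "n_BB": (arr == 2.0).sum(axis=0),
            "n_nocall": np.isnan(arr).sum(axis=0),
        },
        index=pd.Index(matrix.columns, name="marker_id"),
        dtype=np.int64,
    )
    counts.attrs["degenerate"] = len(matrix) == 0
    return counts
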