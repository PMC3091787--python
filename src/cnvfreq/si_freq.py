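"""Signal-intensity CNV call lists: rawcnv parsing and per-marker frequencies.

Consumes per-sample CNV interval calls in the PennCNV "rawcnv" text dialect
(the HMM itself is out of scope — only its output format is handled) and
converts them to per-marker population loss/gain frequencies.  Every sample
without a covering call is assumed diploid (copy number 2) at that marker,
so with N_t total copies observed at a marker across n samples the percent
loss frequency in a pure-loss configuration equals 100*|1 - N_t/(2n)|.
Losses and gains are tallied separately (copies lost = max(0, 2-cn),
copies gained = max(0, cn-2)) so a mixed locus does not cancel to zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VALID_COPY_NUMBERS = (0, 1, 3, 4, 5)

# PennCNV hidden-state label per copy number (diploid state 3 never appears)
_STATE_FOR_CN = {0: 1, 1: 2, 3: 5, 4: 6, 5: 6}

_RAWCNV_RE = re.compile(
    r"^chr(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)"
    r"\s+numsnp=(?P<numsnp>\d+)"
    r"\s+length=(?P<length>[\d,]+)"
    r"\s+state(?P<state>\d+),cn=(?P<cn>\d+)"
    r"\s+(?P<sample>\S+)"
    r"\s+startsnp=(?P<startsnp>\S+)"
    r"\s+endsnp=(?P<endsnp>\S+)"
    r"(?:\s+conf=(?P<conf>\S+))?\s*$"
)


class RawCnvError(ValueError):
    """Malformed rawcnv line or inconsistent call set."""


@dataclass(frozen=True)
class CnvCall:
    """One per-sample CNV interval (1-based, fully closed coordinates)."""

    chromosome: str
    start: int
    end: int
    num_snps: int
    copy_number: int
    sample_id: str
    start_marker: str
    end_marker: str
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.copy_number not in VALID_COPY_NUMBERS:
            raise ValueError(
                f"copy number {self.copy_number} not in {VALID_COPY_NUMBERS}"
            )
        if self.num_snps < 1:
            raise ValueError("num_snps must be >= 1")


def _sample_id_from_token(token: str) -> str:
    """rawcnv names samples by their per-sample intensity file; strip the
    directory and one final extension (``data/bull42.txt`` -> ``bull42``)."""
    name = Path(token).name
    return name.rsplit(".", 1)[0] if "." in name else name


def parse_rawcnv(path: str | Path) -> list[CnvCall]:
    """Parse a rawcnv file into :class:`CnvCall` records.

    One call per line:
    ``chr<C>:<start>-<end>  numsnp=<k>  length=<L>  state<s>,cn=<c>
    <samplefile>  startsnp=<id>  endsnp=<id>  [conf=<x>]``
    (length may contain thousands-commas).  Raises :class:`RawCnvError`
    with the line number on a malformed line or a diploid (cn=2) call.
    """
    calls: list[CnvCall] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _RAWCNV_RE.match(line)
            if m is None:
                raise RawCnvError(f"{path}:{lineno}: malformed rawcnv line: {line!r}")
            cn = int(m["cn"])
            if cn == 2:
                raise RawCnvError(f"{path}:{lineno}: diploid call (cn=2) is not a CNV")
            try:
                calls.append(
                    CnvCall(
                        chromosome=m["chrom"],
                        start=int(m["start"]),
                        end=int(m["end"]),
                        num_snps=int(m["numsnp"]),
                        copy_number=cn,
                        sample_id=_sample_id_from_token(m["sample"]),
                        start_marker=m["startsnp"],
                        end_marker=m["endsnp"],
                        confidence=float(m["conf"]) if m["conf"] is not None else None,
                    )
                )
            except ValueError as exc:
                raise RawCnvError(f"{path}:{lineno}: {exc}") from exc
    return calls


def write_rawcnv(calls: list[CnvCall], path: str | Path) -> None:
    """Emit calls in the rawcnv dialect (inverse of :func:`parse_rawcnv`)."""
    with Path(path).open("w") as fh:
        for c in calls:
            conf = f" conf={c.confidence:g}" if c.confidence is not None else ""
            fh.write(
                f"chr{c.chromosome}:{c.start}-{c.end} numsnp={c.num_snps} "
                f"length={c.end - c.start + 1:,} "
                f"state{_STATE_FOR_CN[c.copy_number]},cn={c.copy_number} "
                f"{c.sample_id}.txt startsnp={c.start_marker} "
                f"endsnp={c.end_marker}{conf}\n"
            )


def marker_si_frequencies(
    calls: list[CnvCall], marker_map: pd.DataFrame, n_samples: int
) -> pd.DataFrame:
    """Per-marker percent loss/gain frequencies from CNV calls.

    A marker is inside a call iff the chromosome matches and
    start <= position <= end (endpoints inclusive, matching the
    startsnp/endsnp semantics).  Per marker, lost copies
    L = sum over samples of max(0, 2 - cn) and gained copies
    G = sum of max(0, cn - 2); frequencies are
    l_si = 100*L/(2*n_samples) and g_si = 100*G/(2*n_samples), and
    n_t = 2*n_samples - L + G is the total copy count.

    Raises :class:`RawCnvError` if two calls from one sample cover the same
    marker (ambiguous copy state).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mm = marker_map.reset_index(drop=True)
    lost = np.zeros(len(mm), dtype=np.int64)
    gained = np.zeros(len(mm), dtype=np.int64)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in mm.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        by_chrom[str(chrom)] = (pos[order], grp.index.to_numpy()[order])

    covered: dict[str, set[int]] = {}
    for call in calls:
        entry = by_chrom.get(call.chromosome)
        if entry is None:
            continue
        pos, idx = entry
        lo = np.searchsorted(pos, call.start, side="left")
        hi = np.searchsorted(pos, call.end, side="right")
        if hi <= lo:
            continue
        hit = idx[lo:hi]
        seen = covered.setdefault(call.sample_id, set())
        for i in hit:
            if i in seen:
                raise RawCnvError(
                    f"sample {call.sample_id!r}: overlapping calls give an "
                    f"ambiguous copy state at marker {mm['marker_id'].iloc[i]!r}"
                )
            seen.add(int(i))
        if call.copy_number < 2:
            lost[hit] += 2 - call.copy_number
        else:
            gained[hit] += call.copy_number - 2

    two_n = 2 * n_samples
    return pd.DataFrame(
        {
            "chromosome": mm["chromosome"].to_numpy(),
            "position": mm["position"].to_numpy(),
            "n_t": two_n - lost + gained,
            "l_si": 100.0 * lost / two_n,
            "g_si": 100.0 * gained / two_n,
        },
        index=pd.Index(mm["marker_id"], name="marker_id"),
    )
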