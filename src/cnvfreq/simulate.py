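"""Synthetic genotype panels with planted CNV truth.

Generates sample x marker genotype-code matrices plus matched per-sample
CNV call lists (rawcnv), emulating a Holstein-style AI-sire panel: ~900
samples, chip-like ~50 kb marker spacing, and markers drawn from one of
four single-marker inheritance models:

``hwe``
    plain biallelic Hardy-Weinberg, alleles (p, q), p + q = 1;
``null_allele``
    a third, silent allele r (p + q + r = 1): heterozygous carriers
    present as homozygotes of their visible allele, rr presents as no-call;
``gain_allele``
    a duplication haplotype g carrying both SNP alleles (p + q + g = 1):
    every carrier presents heterozygote-like;
``hemizygous_x``
    one gamete only (all-male X-like marker): homozygote phenotypes only.

Markers sharing a ``cluster_id`` share their CNV-carrier draws, so a
planted multi-marker CNV produces rawcnv calls spanning the whole cluster.
Technical no-calls are applied independently per cell afterwards.  There is
no linkage disequilibrium between markers: the estimators under test are
single-marker statistics.  All randomness is driven by the scenario seed;
identical specs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_genotypes
from .si_freq import CnvCall, write_rawcnv

MODELS = ("hwe", "null_allele", "gain_allele", "hemizygous_x")

_SIMPLEX_TOL = 1e-9
DEFAULT_ALLELE_PAIR = ("A", "G")


@dataclass(frozen=True)
class MarkerModel:
    """Planted truth for one marker.

    ``p``/``q`` are the visible-allele frequencies and ``cnv_freq`` the
    null (r) or gain (g) allele frequency; the applicable frequencies must
    sum to 1.  ``cluster_id`` groups markers spanned by one CNV event.
    """

    marker_id: str
    chromosome: str
    position: int
    model: str
    p: float
    q: float
    cnv_freq: float = 0.0
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        total = self.p + self.q + (
            self.cnv_freq if self.model in ("null_allele", "gain_allele") else 0.0
        )
        if self.model in ("hwe", "hemizygous_x") and self.cnv_freq != 0.0:
            raise ValueError(f"{self.model} marker cannot carry cnv_freq")
        if not (0 <= self.p <= 1 and 0 <= self.q <= 1 and 0 <= self.cnv_freq <= 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ValueError(
                f"marker {self.marker_id}: allele frequencies sum to {total}, not 1"
            )
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based bp)")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a synthetic panel; the seed determines everything."""

    markers: tuple[MarkerModel, ...]
    n_samples: int
    nocall_rate: float = 0.0
    si_detection_rate: float = 1.0
    si_false_positive_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("nocall_rate", "si_detection_rate", "si_false_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker_id in scenario")

    def marker_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": [m.marker_id for m in self.markers],
                "chromosome": [m.chromosome for m in self.markers],
                "position": [m.position for m in self.markers],
            }
        )

    def sample_ids(self) -> list[str]:
        return [f"bull{i:04d}" for i in range(self.n_samples)]


@dataclass
class SimulationResult:
    """Genotypes plus the bookkeeping needed to emit matched CNV calls."""

    spec: ScenarioSpec
    genotypes: pd.DataFrame  # samples x markers, codes {0,1,2,NaN}
    truth: pd.DataFrame  # per-marker planted parameters
    carriers: dict[str, dict] = field(repr=False, default_factory=dict)


def _cluster_key(m: MarkerModel) -> str:
    return m.cluster_id if m.cluster_id is not None else m.marker_id


def simulate_genotypes(spec: ScenarioSpec) -> SimulationResult:
    """Draw the genotype-code matrix and planted-truth table for a scenario.

    Per individual, two gametes are drawn i.i.d. from the marker's allele
    distribution (one for hemizygous markers); CNV-model markers in the
    same cluster reuse the cluster's carrier gametes so the planted event
    is a contiguous haplotype.  Technical no-calls are overlaid
    independently at ``nocall_rate``.
    """
    n = spec.n_samples
    rng = np.random.default_rng([spec.seed, 0])
    codes = np.empty((n, len(spec.markers)), dtype=float)
    carriers: dict[str, dict] = {}

    for j, m in enumerate(spec.markers):
        if m.model == "hwe":
            codes[:, j] = (rng.random(n) < m.q).astype(float) + (
                rng.random(n) < m.q
            )
            continue
        if m.model == "hemizygous_x":
            codes[:, j] = 2.0 * (rng.random(n) < m.q)
            continue
        key = _cluster_key(m)
        entry = carriers.get(key)
        if entry is None:
            entry = {
                "model": m.model,
                "c1": rng.random(n) < m.cnv_freq,
                "c2": rng.random(n) < m.cnv_freq,
                "markers": [],
            }
            carriers[key] = entry
        elif entry["model"] != m.model:
            raise ValueError(f"cluster {key!r} mixes models")
        entry["markers"].append(m)
        c1, c2 = entry["c1"], entry["c2"]
        # visible-allele draw per gamete, conditional on not carrying the CNV
        q_vis = m.q / (m.p + m.q) if (m.p + m.q) > 0 else 0.0
        b1 = (rng.random(n) < q_vis).astype(float)
        b2 = (rng.random(n) < q_vis).astype(float)
        if m.model == "null_allele":
            col = b1 + b2
            col = np.where(c1 & ~c2, 2.0 * b2, col)  # one null: hom of the other
            col = np.where(c2 & ~c1, 2.0 * b1, col)
            col = np.where(c1 & c2, np.nan, col)  # null homozygote: no-call
        else:  # gain_allele: any carrier presents heterozygote-like
            col = np.where(c1 | c2, 1.0, b1 + b2)
        codes[:, j] = col

    if spec.nocall_rate > 0.0:
        rng_nc = np.random.default_rng([spec.seed, 2])
        codes[rng_nc.random(codes.shape) < spec.nocall_rate] = np.nan

    genotypes = pd.DataFrame(
        codes,
        index=pd.Index(spec.sample_ids(), name="sample_id"),
        columns=[m.marker_id for m in spec.markers],
    )
    truth = pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in spec.markers],
            "chromosome": [m.chromosome for m in spec.markers],
            "position": [m.position for m in spec.markers],
            "model": [m.model for m in spec.markers],
            "p": [m.p for m in spec.markers],
            "q": [m.q for m in spec.markers],
            "cnv_freq": [m.cnv_freq for m in spec.markers],
            "cluster": [
                _cluster_key(m) if m.model in ("null_allele", "gain_allele") else ""
                for m in spec.markers
            ],
        }
    ).set_index("marker_id")
    return SimulationResult(spec=spec, genotypes=genotypes, truth=truth,
                            carriers=carriers)


def simulate_rawcnv(result: SimulationResult) -> list[CnvCall]:
    """Emit per-sample CNV calls for the planted carriers of a simulation.

    Null-model carriers yield cn=1 (one null gamete) or cn=0 (two); gain
    carriers yield cn=3.  Each carrier's call spans its whole cluster and
    is emitted with probability ``si_detection_rate``; non-carriers emit a
    spurious cn=1 call at ``si_false_positive_rate`` (default 0).  Calls
    are deterministic given the scenario seed.
    """
    spec = result.spec
    rng = np.random.default_rng([spec.seed, 1])
    samples = spec.sample_ids()
    calls: list[CnvCall] = []
    for key in sorted(result.carriers):
        entry = result.carriers[key]
        members = sorted(entry["markers"], key=lambda m: m.position)
        first, last = members[0], members[-1]
        n_gam = entry["c1"].astype(int) + entry["c2"].astype(int)
        if entry["model"] == "null_allele":
            cn = np.where(n_gam == 2, 0, np.where(n_gam == 1, 1, 2))
        else:
            cn = np.where(n_gam >= 1, 3, 2)
        detect = rng.random(spec.n_samples) < spec.si_detection_rate
        emit_cn = np.where(cn != 2, np.where(detect, cn, 2), 2)
        if spec.si_false_positive_rate > 0.0:
            fp = (cn == 2) & (rng.random(spec.n_samples) < spec.si_false_positive_rate)
            emit_cn = np.where(fp, 1, emit_cn)
        for i in np.flatnonzero(emit_cn != 2):
            calls.append(
                CnvCall(
                    chromosome=first.chromosome,
                    start=first.position,
                    end=last.position,
                    num_snps=len(members),
                    copy_number=int(emit_cn[i]),
                    sample_id=samples[i],
                    start_marker=first.marker_id,
                    end_marker=last.marker_id,
                    confidence=round(10.0 + 5.0 * int(emit_cn[i]), 1),
                )
            )
    return calls


def holstein_panel(
    n_samples: int = 912,
    n_background: int = 5000,
    n_loss_clusters: int = 10,
    n_gain_clusters: int = 10,
    markers_per_cluster: int = 5,
    cnv_freq: float = 0.15,
    intra_cluster_gap: int = 300,
    background_spacing: int = 50_000,
    nocall_rate: float = 0.016,
    si_detection_rate: float = 0.3,
    si_false_positive_rate: float = 0.0,
    n_chromosomes: int = 29,
    seed: int = 0,
) -> ScenarioSpec:
    """Study-scale scenario: a 912-sire panel with chip-like marker spacing.

    Background markers are plain-HWE SNPs with allele frequencies drawn
    uniformly from [0.05, 0.95], laid out every ~50 kb across 29 autosomes
    (the BovineSNP50 density).  Loss (null-allele) and gain clusters of
    *markers_per_cluster* markers with *intra_cluster_gap* bp spacing are
    planted between background markers; cluster visible alleles are
    symmetric, p = q = (1 - cnv_freq)/2.  The 1.6% default technical
    no-call rate matches an average of ~15 missing calls per marker in 912
    samples.
    """
    rng = np.random.default_rng([seed, 3])
    markers: list[MarkerModel] = []
    per_chrom = -(-n_background // n_chromosomes)  # ceil
    made = 0
    for c in range(1, n_chromosomes + 1):
        for i in range(per_chrom):
            if made >= n_background:
                break
            p = float(rng.uniform(0.05, 0.95))
            markers.append(
                MarkerModel(
                    marker_id=f"bg_c{c}_{i}",
                    chromosome=str(c),
                    position=background_spacing * (i + 1),
                    model="hwe",
                    p=p,
                    q=1.0 - p,
                )
            )
            made += 1

    def plant(kind: str, n_clusters: int, offset: int) -> None:
        model = "null_allele" if kind == "loss" else "gain_allele"
        pq = (1.0 - cnv_freq) / 2.0
        for k in range(n_clusters):
            chrom = str((k % n_chromosomes) + 1)
            base = background_spacing * (per_chrom + 2 + k // n_chromosomes) + offset
            for j in range(markers_per_cluster):
                markers.append(
                    MarkerModel(
                        marker_id=f"{kind}{k}_m{j}",
                        chromosome=chrom,
                        position=base + j * intra_cluster_gap,
                        model=model,
                        p=pq,
                        q=pq,
                        cnv_freq=cnv_freq,
                        cluster_id=f"{kind}{k}",
                    )
                )

    plant("loss", n_loss_clusters, offset=0)
    plant("gain", n_gain_clusters, offset=10_000)
    return ScenarioSpec(
        markers=tuple(markers),
        n_samples=n_samples,
        nocall_rate=nocall_rate,
        si_detection_rate=si_detection_rate,
        si_false_positive_rate=si_false_positive_rate,
        seed=seed,
    )


def write_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    doc = asdict(spec)
    doc["markers"] = [asdict(m) for m in spec.markers]
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_scenario(path: str | Path) -> ScenarioSpec:
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    markers = tuple(MarkerModel(**m) for m in doc.pop("markers"))
    return ScenarioSpec(markers=markers, **doc)


def write_outputs(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write the standard artifact set for a simulation: final report,
    genotype matrix, marker map, rawcnv and planted-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "final_report": outdir / "final_report.txt",
        "matrix": outdir / "genotypes.tsv",
        "marker_map": outdir / "markers.map",
        "rawcnv": outdir / "calls.rawcnv",
        "truth": outdir / "truth.tsv",
    }
    alleles = {m.marker_id: DEFAULT_ALLELE_PAIR for m in result.spec.markers}
    io_genotypes.write_final_report(result.genotypes, alleles, paths["final_report"])
    io_genotypes.write_genotype_matrix(result.genotypes, paths["matrix"])
    io_genotypes.write_marker_map(result.spec.marker_map(), paths["marker_map"])
    write_rawcnv(simulate_rawcnv(result), paths["rawcnv"])
    result.truth.to_csv(paths["truth"], sep="\t")
    return paths
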