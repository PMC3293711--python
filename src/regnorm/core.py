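"""Core data types and file I/O for two-channel regulation microarrays.

A regulation microarray (ChIP-on-chip or MeDIP-on-chip) hybridizes an
immunoprecipitated DNA sample (Cy5, red) against total input DNA (Cy3,
green).  The per-probe log2 ratio M = log2(red/green) measures enrichment;
A = (log2 red + log2 green)/2 is the average log intensity.  This module
defines the probe annotation, the two-channel array container, the MA
matrix that every normalization method transforms, plus readers/writers
for NimbleGen-style pair files, annotation TSVs, GFF p-value tracks and
BED region files.

Coordinate conventions: positions are 0-based half-open internally and in
BED output; GFF output is 1-based inclusive; pair-file POSITION columns
are treated as 1-based starts and converted on read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeCategory",
    "ProbeAnnotation",
    "TwoChannelArray",
    "ExperimentSet",
    "MAMatrix",
    "PairFormatError",
    "read_pair_file",
    "read_pair_files",
    "read_annotation",
    "write_annotation",
    "write_pair_file",
    "write_experiment",
    "read_experiment_dir",
    "compute_ma",
    "write_pvalue_gff",
    "write_regions_bed",
    "read_regions_bed",
]


class PairFormatError(ValueError):
    """A pair file does not conform to the expected dialect."""


class ProbeCategory(enum.Enum):
    """Functional class of a probe on the array.

    NEGATIVE_CONTROL probes have no genomic target and measure
    non-specific annealing and background fluorescence; they are the
    negative class of the separation metric.  PROMOTER probes target gene
    promoters (the positive class).  TILING probes tile a genomic region
    contiguously and are the substrate of sliding-window enrichment
    detection.
    """

    NEGATIVE_CONTROL = "NEGATIVE_CONTROL"
    PROMOTER = "PROMOTER"
    TILING = "TILING"


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe universe of an experiment: identity, location and category.

    Parameters
    ----------
    probe_id : unique probe identifiers.
    chrom : chromosome / sequence identifier per probe.
    position : 0-based genomic start coordinate (bp).
    probe_length : probe length (bp), > 0.
    category : :class:`ProbeCategory` per probe.
    """

    probe_id: np.ndarray
    chrom: np.ndarray
    position: np.ndarray
    probe_length: np.ndarray
    category: np.ndarray  # array of ProbeCategory

    def __post_init__(self) -> None:
        n = len(self.probe_id)
        for name in ("chrom", "position", "probe_length", "category"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"annotation field {name!r} length mismatch")
        if len(np.unique(self.probe_id)) != n:
            raise ValueError("probe_id values must be unique")
        if np.any(np.asarray(self.position) < 0):
            raise ValueError("probe positions must be >= 0")
        if np.any(np.asarray(self.probe_length) <= 0):
            raise ValueError("probe lengths must be > 0")

    def __len__(self) -> int:
        return len(self.probe_id)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeAnnotation":
        cats = np.array([ProbeCategory(c) for c in df["category"]], dtype=object)
        return cls(
            probe_id=df["probe_id"].to_numpy(dtype=object),
            chrom=df["chrom"].to_numpy(dtype=object),
            position=df["position"].to_numpy(dtype=np.int64),
            probe_length=df["length"].to_numpy(dtype=np.int64),
            category=cats,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_id,
                "chrom": self.chrom,
                "position": self.position,
                "length": self.probe_length,
                "category": [c.value for c in self.category],
            }
        )

    def category_mask(self, category: ProbeCategory) -> np.ndarray:
        return np.array([c is category for c in self.category], dtype=bool)


@dataclass
class TwoChannelArray:
    """Raw intensities of one microarray, aligned by index to an annotation.

    ``green`` holds the Cy3 (total/input DNA reference) intensities and
    ``red`` the Cy5 (immunoprecipitated, enriched DNA) intensities, in
    fluorescence units; both strictly positive.
    """

    array_id: str
    green: np.ndarray
    red: np.ndarray

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.shape != self.red.shape or self.green.ndim != 1:
            raise ValueError("green and red must be 1-D vectors of equal length")
        if np.any(self.green <= 0) or np.any(self.red <= 0):
            raise ValueError("intensities must be strictly positive")


@dataclass
class ExperimentSet:
    """A replicate group: one annotation shared by >= 1 two-channel arrays."""

    annotation: ProbeAnnotation
    arrays: list[TwoChannelArray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.arrays:
            raise ValueError("an ExperimentSet needs at least one array")
        n = len(self.annotation)
        for arr in self.arrays:
            if len(arr.green) != n:
                raise ValueError(
                    f"array {arr.array_id!r} has {len(arr.green)} probes, "
                    f"annotation has {n}"
                )

    @property
    def n_arrays(self) -> int:
        return len(self.arrays)

    @property
    def array_ids(self) -> list[str]:
        return [a.array_id for a in self.arrays]


@dataclass
class MAMatrix:
    """Per-probe, per-array log-ratios M and average log-intensities A.

    ``M[i, j] = log2(red[i, j]) - log2(green[i, j])`` and
    ``A[i, j] = (log2(red[i, j]) + log2(green[i, j])) / 2``.
    """

    M: np.ndarray
    A: np.ndarray
    array_ids: list[str]

    def __post_init__(self) -> None:
        self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if self.M.shape != self.A.shape:
            raise ValueError("M and A must share shape")
        if self.M.shape[1] != len(self.array_ids):
            raise ValueError("column count must match array_ids")

    @property
    def n_probes(self) -> int:
        return self.M.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.M.shape[1]


# ---------------------------------------------------------------------------
# Pair-file and annotation I/O
# ---------------------------------------------------------------------------

_PAIR_REQUIRED = ("PROBE_ID", "SEQ_ID", "POSITION", "PM")


def _read_pair_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in _PAIR_REQUIRED if c not in df.columns]
    if missing:
        raise PairFormatError(
            f"pair file {path} is missing required column(s): {', '.join(missing)}"
        )
    return df


def read_pair_file(
    path: str | Path,
    annotation: ProbeAnnotation,
    *,
    floor_at: float | None = None,
) -> np.ndarray:
    """Read one channel of a NimbleGen-style pair file.

    The file is tab-separated with a header naming at least PROBE_ID,
    SEQ_ID, POSITION and PM; lines starting with '#' are comments; extra
    columns are ignored.  Returns the PM intensities reordered to match
    ``annotation`` by probe_id.

    Non-positive intensities are rejected unless ``floor_at`` is given, in
    which case they are floored at that value (fluorescence units).
    """
    df = _read_pair_table(path)
    ids = df["PROBE_ID"].astype(str).to_numpy()
    known = set(annotation.probe_id.tolist())
    for pid in ids:
        if pid not in known:
            raise ValueError(
                f"pair file {path} contains probe {pid!r} absent from the annotation"
            )
    lookup = dict(zip(ids, df["PM"].to_numpy(dtype=float)))
    try:
        values = np.array([lookup[p] for p in annotation.probe_id], dtype=float)
    except KeyError as exc:
        raise ValueError(
            f"pair file {path} lacks annotation probe {exc.args[0]!r}"
        ) from None
    if floor_at is not None:
        values = np.maximum(values, float(floor_at))
    if np.any(values <= 0):
        bad = annotation.probe_id[values <= 0][0]
        raise ValueError(
            f"pair file {path}: non-positive intensity for probe {bad!r} "
            "(pass floor_at=... to floor instead of rejecting)"
        )
    return values


def read_pair_files(
    green_path: str | Path,
    red_path: str | Path,
    annotation: ProbeAnnotation,
    *,
    array_id: str | None = None,
    floor_at: float | None = None,
) -> TwoChannelArray:
    """Read a green/red pair-file pair into a :class:`TwoChannelArray`."""
    green = read_pair_file(green_path, annotation, floor_at=floor_at)
    red = read_pair_file(red_path, annotation, floor_at=floor_at)
    if array_id is None:
        array_id = Path(green_path).stem.removesuffix("_green")
    return TwoChannelArray(array_id=array_id, green=green, red=red)


def write_pair_file(
    path: str | Path, annotation: ProbeAnnotation, intensities: np.ndarray
) -> None:
    """Write one channel as a pair file (POSITION written 1-based)."""
    with open(path, "w") as fh:
        fh.write("# regnorm pair file\n")
        fh.write("PROBE_ID\tSEQ_ID\tPOSITION\tPM\n")
        for pid, chrom, pos, val in zip(
            annotation.probe_id, annotation.chrom, annotation.position, intensities
        ):
            fh.write(f"{pid}\t{chrom}\t{int(pos) + 1}\t{float(val)!r}\n")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read an annotation TSV (probe_id, chrom, position, length, category).

    Positions in the file are 0-based starts (the package's own format).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"probe_id", "chrom", "position", "length", "category"}
    missing = required - set(df.columns)
    if missing:
        raise PairFormatError(
            f"annotation {path} missing column(s): {', '.join(sorted(missing))}"
        )
    df["probe_id"] = df["probe_id"].astype(str)
    return ProbeAnnotation.from_frame(df)


def write_annotation(path: str | Path, annotation: ProbeAnnotation) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False)


def write_experiment(outdir: str | Path, experiment: ExperimentSet) -> None:
    """Write an experiment as annotation.tsv plus per-array pair files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_annotation(outdir / "annotation.tsv", experiment.annotation)
    for arr in experiment.arrays:
        write_pair_file(outdir / f"{arr.array_id}_green.pair", experiment.annotation, arr.green)
        write_pair_file(outdir / f"{arr.array_id}_red.pair", experiment.annotation, arr.red)


def read_experiment_dir(
    indir: str | Path,
    annotation: ProbeAnnotation | None = None,
    *,
    floor_at: float | None = None,
) -> ExperimentSet:
    """Read every ``*_green.pair`` / ``*_red.pair`` pair in a directory."""
    indir = Path(indir)
    if annotation is None:
        annotation = read_annotation(indir / "annotation.tsv")
    arrays = []
    for green in sorted(indir.glob("*_green.pair")):
        array_id = green.name.removesuffix("_green.pair")
        red = indir / f"{array_id}_red.pair"
        if not red.exists():
            raise FileNotFoundError(f"missing red channel for array {array_id!r}")
        arrays.append(
            read_pair_files(green, red, annotation, array_id=array_id, floor_at=floor_at)
        )
    if not arrays:
        raise FileNotFoundError(f"no *_green.pair files found in {indir}")
    return ExperimentSet(annotation=annotation, arrays=arrays)


# ---------------------------------------------------------------------------
# MA computation
# ---------------------------------------------------------------------------


def compute_ma(experiment: ExperimentSet) -> MAMatrix:
    """Compute the MA matrix of an experiment.

    M = log2(red) - log2(green); A = (log2(red) + log2(green)) / 2, per
    probe and array.  Raises on non-positive intensities.
    """
    greens = np.column_stack([a.green for a in experiment.arrays])
    reds = np.column_stack([a.red for a in experiment.arrays])
    if np.any(greens <= 0) or np.any(reds <= 0):
        raise ValueError("compute_ma requires strictly positive intensities")
    lg, lr = np.log2(greens), np.log2(reds)
    return MAMatrix(M=lr - lg, A=(lr + lg) / 2.0, array_ids=experiment.array_ids)


def ma_to_intensities(ma: MAMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Invert the MA transform: red = 2**(A + M/2), green = 2**(A - M/2)."""
    return 2.0 ** (ma.A + ma.M / 2.0), 2.0 ** (ma.A - ma.M / 2.0)


# ---------------------------------------------------------------------------
# Track / region writers
# ---------------------------------------------------------------------------


def write_pvalue_gff(
    annotation: ProbeAnnotation,
    pvalues: np.ndarray,
    path: str | Path,
    *,
    source: str = "regnorm",
    feature: str = "enrichment_pvalue",
) -> None:
    """Write per-probe enrichment p-values as a GFF2 track.

    Score is -log10(p) with 6 decimals; coordinates are 1-based inclusive
    per the GFF convention.  ``pvalues`` must align to ``annotation`` and
    lie in (0, 1].
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) != len(annotation):
        raise ValueError("pvalues must align to the annotation")
    if np.any(pvalues <= 0) or np.any(pvalues > 1):
        raise ValueError("p-values must lie in (0, 1]")
    scores = -np.log10(pvalues)
    with open(path, "w") as fh:
        fh.write("##gff-version 2\n")
        for pid, chrom, pos, length, score in zip(
            annotation.probe_id,
            annotation.chrom,
            annotation.position,
            annotation.probe_length,
            scores,
        ):
            start = int(pos) + 1
            end = int(pos) + int(length)
            fh.write(
                f"{chrom}\t{source}\t{feature}\t{start}\t{end}\t{score:.6f}\t.\t.\t"
                f"probe \"{pid}\"\n"
            )


def write_regions_bed(
    regions: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    """Write (chrom, start, end) regions as BED3 (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append((chrom, int(start), int(end)))
    return regions
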