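"""Readers and writers for the file formats the pipeline touches.

Supported formats:

* **TPS** landmark files (Rohlf dialect) with ``LM=`` records, optional
  ``CURVES=``/``POINTS=`` semilandmark curves, and optional ``IMAGE=``,
  ``ID=`` and ``SCALE=`` lines.  Curve points are flattened after the fixed
  landmarks in file order, so a record contributes ``k = fixed + sum(curve
  points)`` coordinates.
* **Sliders** files: one ``before slider after`` integer triplet per line
  (1-based landmark indices), the convention used to declare which points
  are semilandmarks and along which chord they may slide.
* **Label tables**: CSV with columns ``id, species, site, colony,
  replicate_id`` joined onto configuration ids.
* **Aligned FASTA** barcode alignments (via Biopython).

Coordinates are stored y-up in the usual mathematical convention; pass
``flip_y=True`` when reading files digitized in image coordinates (y grows
downward).  ``SCALE=`` factors are applied at read time by default so that
coordinates — and hence centroid sizes — are in physical units.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LandmarkConfiguration",
    "ShapeDataset",
    "SlidersSpec",
    "SequenceSet",
    "TpsParseError",
    "DatasetError",
    "read_tps",
    "write_tps",
    "read_sliders",
    "write_sliders",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "attach_labels",
]

LABEL_COLUMNS = ("species", "site", "colony", "replicate_id")

#: IUPAC nucleotide codes accepted in alignments (ambiguities other than N
#: are downgraded to N by the distance computation, not at read time).
ALLOWED_BASES = frozenset("ACGTUNRYSWKMBDHV-")


class TpsParseError(ValueError):
    """A TPS record could not be parsed (names the offending record)."""


class DatasetError(ValueError):
    """A dataset-level invariant is violated (e.g. inconsistent k)."""


@dataclass
class LandmarkConfiguration:
    """One digitized landmark configuration: an ordered set of 2-D points.

    Landmark index ``i`` refers to the same anatomical locus in every
    configuration of a dataset; the point order is semantically fixed.
    """

    id: str
    points: np.ndarray  # (k, 2) float
    scale: float | None = None
    image_name: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise DatasetError(f"configuration {self.id!r}: points must be (k, 2)")
        if self.points.shape[0] < 3:
            raise DatasetError(f"configuration {self.id!r}: needs k >= 3 landmarks")
        if not np.all(np.isfinite(self.points)):
            raise DatasetError(f"configuration {self.id!r}: non-finite coordinates")
        if self.scale is not None and not self.scale > 0:
            raise DatasetError(f"configuration {self.id!r}: scale must be positive")

    @property
    def k(self) -> int:
        return self.points.shape[0]


@dataclass
class ShapeDataset:
    """A set of landmark configurations sharing one landmark scheme."""

    configurations: list[LandmarkConfiguration]
    labels: pd.DataFrame | None = None  # indexed by configuration id

    def __post_init__(self) -> None:
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise DatasetError(f"inconsistent landmark counts across records: {sorted(ks)}")
        ids = [c.id for c in self.configurations]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DatasetError(f"duplicate configuration ids: {sorted(dupes)}")
        if self.labels is not None:
            self.labels = self.labels.copy()
            if "id" in self.labels.columns:
                self.labels = self.labels.set_index("id")
            self.labels.index = self.labels.index.astype(str)

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        if not self.configurations:
            return 0
        return self.configurations[0].k

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.configurations]

    def coords(self) -> np.ndarray:
        """Stack all configurations into an (n, k, 2) array."""
        return np.stack([c.points for c in self.configurations])

    def subset(self, ids: Iterable[str]) -> "ShapeDataset":
        wanted = set(ids)
        configs = [c for c in self.configurations if c.id in wanted]
        labels = None
        if self.labels is not None:
            labels = self.labels.loc[self.labels.index.isin(wanted)]
        return ShapeDataset(configs, labels)

    def label_vector(self, column: str) -> np.ndarray:
        """Label values for ``column`` in configuration order."""
        if self.labels is None:
            raise DatasetError("dataset has no label table")
        missing = [i for i in self.ids if i not in self.labels.index]
        if missing:
            raise DatasetError(f"ids missing from label table: {missing[:5]}")
        return self.labels.loc[self.ids, column].to_numpy()


@dataclass
class SlidersSpec:
    """Semilandmark slider declarations: (before, slider, after) triplets.

    Indices are 1-based as in the on-disk format; ``slider_indices0`` gives
    the 0-based slider set for array code.  Chained triplets such as
    (1,2,3),(2,3,4) are allowed and give the slider set {2,3}.
    """

    triplets: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.triplets:
            b, s, a = t
            if s == b or s == a:
                raise DatasetError(f"slider triplet {t}: slider equals a neighbour")

    def validate(self, k: int) -> None:
        for t in self.triplets:
            for idx in t:
                if not 1 <= idx <= k:
                    raise DatasetError(f"slider triplet {t}: index {idx} outside [1..{k}]")

    @property
    def slider_indices(self) -> set[int]:
        return {s for _, s, _ in self.triplets}

    @property
    def slider_indices0(self) -> np.ndarray:
        return np.array(sorted(self.slider_indices)) - 1

    def neighbours0(self) -> dict[int, tuple[int, int]]:
        """0-based slider index -> (before, after) 0-based neighbours."""
        return {s - 1: (b - 1, a - 1) for b, s, a in self.triplets}

    def __len__(self) -> int:
        return len(self.triplets)


@dataclass
class SequenceSet:
    """An aligned set of equal-length nucleotide sequences."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise DatasetError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise DatasetError("duplicate sequence ids")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise DatasetError(
                f"sequences are not aligned: lengths {sorted(lengths)} differ"
            )
        bad: dict[str, set[str]] = {}
        for sid, s in zip(self.ids, self.sequences):
            offenders = set(s) - ALLOWED_BASES
            if offenders:
                bad[sid] = offenders
        if bad:
            raise DatasetError(f"illegal characters in sequences: {bad}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def as_array(self) -> np.ndarray:
        """(n, L) array of single-byte codes for vectorized comparisons."""
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.length)


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

_KEYVAL = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def _parse_float_pair(line: str, record: str) -> tuple[float, float]:
    parts = line.split()
    if len(parts) != 2:
        raise TpsParseError(f"record {record!r}: expected 'x y' pair, got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise TpsParseError(f"record {record!r}: bad coordinate line {line!r}") from exc


def read_tps(
    path: str | Path,
    apply_scale: bool = True,
    flip_y: bool = False,
) -> ShapeDataset:
    """Read a TPS landmark file into a :class:`ShapeDataset`.

    Both dialects are accepted: flattened records (all points under ``LM=``)
    and curve records (``LM=`` fixed landmarks followed by ``CURVES=`` /
    ``POINTS=`` blocks); curve points are appended after the fixed landmarks
    in file order.  If ``apply_scale`` and a record carries ``SCALE=``, its
    coordinates are multiplied by the scale factor; records lacking a scale
    are flagged with a warning.  ``flip_y`` negates y for image-origin files.
    """
    path = Path(path)
    lines = path.read_text().replace("\r\n", "\n").replace("\r", "\n").split("\n")
    configs: list[LandmarkConfiguration] = []
    missing_scale: list[str] = []

    i = 0
    n_lines = len(lines)
    record_no = 0
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEYVAL.match(line)
        if not m or m.group(1).upper() != "LM":
            raise TpsParseError(f"line {i + 1}: expected LM= record start, got {line!r}")
        record_no += 1
        rec_name = f"#{record_no}"
        try:
            n_fixed = int(m.group(2))
        except ValueError as exc:
            raise TpsParseError(f"record {rec_name}: bad LM count {m.group(2)!r}") from exc
        i += 1

        points: list[tuple[float, float]] = []
        for _ in range(n_fixed):
            if i >= n_lines or _KEYVAL.match(lines[i].strip()) and not _is_pair(lines[i]):
                raise TpsParseError(
                    f"record {rec_name}: LM={n_fixed} but fewer coordinate lines found"
                )
            points.append(_parse_float_pair(lines[i].strip(), rec_name))
            i += 1

        # optional curves
        while i < n_lines:
            m2 = _KEYVAL.match(lines[i].strip())
            if not m2 or m2.group(1).upper() != "CURVES":
                break
            n_curves = int(m2.group(2))
            i += 1
            for _ in range(n_curves):
                m3 = _KEYVAL.match(lines[i].strip()) if i < n_lines else None
                if not m3 or m3.group(1).upper() != "POINTS":
                    raise TpsParseError(f"record {rec_name}: expected POINTS= line")
                n_pts = int(m3.group(2))
                i += 1
                for _ in range(n_pts):
                    if i >= n_lines:
                        raise TpsParseError(
                            f"record {rec_name}: POINTS={n_pts} but file ended"
                        )
                    points.append(_parse_float_pair(lines[i].strip(), rec_name))
                    i += 1

        image_name, rec_id, scale = "", None, None
        while i < n_lines:
            stripped = lines[i].strip()
            if not stripped:
                i += 1
                continue
            m4 = _KEYVAL.match(stripped)
            if not m4:
                raise TpsParseError(f"record {rec_name}: unexpected line {stripped!r}")
            key = m4.group(1).upper()
            if key == "LM":
                break
            if key == "IMAGE":
                image_name = m4.group(2)
            elif key == "ID":
                rec_id = m4.group(2)
            elif key == "SCALE":
                scale = float(m4.group(2))
            elif key in ("CURVES", "POINTS"):
                raise TpsParseError(f"record {rec_name}: CURVES after metadata lines")
            # other keys (COMMENT=, VARIABLES=...) are ignored
            i += 1

        pts = np.asarray(points, dtype=float)
        if flip_y:
            pts[:, 1] = -pts[:, 1]
        if apply_scale:
            if scale is not None:
                pts = pts * scale
            else:
                missing_scale.append(rec_id or image_name or rec_name)
        cid = rec_id if rec_id is not None else (image_name or rec_name)
        configs.append(
            LandmarkConfiguration(id=cid, points=pts, scale=scale, image_name=image_name)
        )

    if apply_scale and missing_scale:
        warnings.warn(
            f"{len(missing_scale)} TPS record(s) lack SCALE=; coordinates left "
            f"in digitizer units: {missing_scale[:5]}",
            stacklevel=2,
        )
    return ShapeDataset(configs)


def _is_pair(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
        return True
    except ValueError:
        return False


def write_tps(dataset: ShapeDataset, path: str | Path) -> None:
    """Write a dataset as a flattened TPS file (one ``LM=`` record each).

    Coordinates are written divided by the record's scale (when present) so
    that reading the file back with ``apply_scale=True`` round-trips.
    """
    path = Path(path)
    out: list[str] = []
    for c in dataset.configurations:
        pts = c.points / c.scale if c.scale is not None else c.points
        out.append(f"LM={c.k}")
        out.extend(f"{x:.6f} {y:.6f}" for x, y in pts)
        if c.image_name:
            out.append(f"IMAGE={c.image_name}")
        out.append(f"ID={c.id}")
        if c.scale is not None:
            out.append(f"SCALE={c.scale!r}")
    path.write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# Sliders
# ---------------------------------------------------------------------------

def read_sliders(path: str | Path, k: int) -> SlidersSpec:
    """Read a sliders file: one 1-based ``before slider after`` triplet per line."""
    triplets: list[tuple[int, int, int]] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 3:
            raise TpsParseError(f"sliders line {ln}: expected 3 integers, got {raw!r}")
        try:
            b, s, a = (int(p) for p in parts)
        except ValueError as exc:
            raise TpsParseError(f"sliders line {ln}: non-integer in {raw!r}") from exc
        triplets.append((b, s, a))
    spec = SlidersSpec(triplets)
    spec.validate(k)
    return spec


def write_sliders(spec: SlidersSpec, path: str | Path) -> None:
    Path(path).write_text("".join(f"{b} {s} {a}\n" for b, s, a in spec.triplets))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceSet:
    """Read an aligned FASTA file; sequences are upper-cased and validated."""
    records = list(SeqIO.parse(str(path), "fasta"))
    return SequenceSet(ids=[r.id for r in records], sequences=[str(r.seq) for r in records])


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(seqs.ids, seqs.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Label tables
# ---------------------------------------------------------------------------

def read_labels(
    path: str | Path,
    colony_regex: str | None = None,
    image_column: str = "id",
) -> pd.DataFrame:
    """Read a CSV label table (columns id, species, site, colony, replicate_id).

    ``colony_regex`` optionally derives a missing colony column from the id /
    image-name column (e.g. ``r"^(WW\\d+)"`` for colony codes embedded in
    image names).
    """
    df = pd.read_csv(path, dtype=str)
    if "id" not in df.columns:
        raise DatasetError("label table must have an 'id' column")
    if colony_regex is not None and "colony" not in df.columns:
        df["colony"] = df[image_column].str.extract(colony_regex, expand=False)
    return df.set_index("id")


def attach_labels(dataset: ShapeDataset, labels: pd.DataFrame) -> ShapeDataset:
    """Return a dataset with the label table joined on configuration id."""
    missing = [i for i in dataset.ids if i not in labels.index]
    if missing:
        raise DatasetError(f"label table does not cover ids: {missing[:5]}")
    return ShapeDataset(dataset.configurations, labels.loc[dataset.ids])
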