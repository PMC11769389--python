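"""On-disk contract and in-memory containers for sensor-array datasets.

One record is a 26-channel metal-oxide-semiconductor (MOS) sensor-array
response sampled at a fixed rate over a fixed window (defaults: 100 Hz for
60 s).  Records are stored as plain comma-separated matrices (one file per
record, header row ``S01..S26``) alongside a delimited-text manifest with
one row per record carrying the label and acquisition metadata.  Simulated
and real recordings share this contract.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Label taxonomy
# ---------------------------------------------------------------------------

N_CHANNELS = 26
CHANNEL_IDS: tuple[str, ...] = tuple(f"S{i + 1:02d}" for i in range(N_CHANNELS))

HEALTHY = "healthy"
PETROLEUM_CLASSES: tuple[str, ...] = ("gasoline", "diesel")
PESTICIDE_CLASSES: tuple[str, ...] = (
    "chlorpyrifos",
    "cyfluthrin",
    "deltamethrin",
    "dithane",
    "glyphosate",
    "mancozeb",
)
CLASS_IDS: tuple[str, ...] = (HEALTHY,) + PETROLEUM_CLASSES + PESTICIDE_CLASSES
CONDITIONS: tuple[str, ...] = ("healthy", "petroleum", "pesticide")

MANIFEST_COLUMNS = (
    "record_id",
    "file",
    "class_id",
    "condition",
    "concentration",
    "age_days",
    "seed",
)

_META_FILENAME = "dataset_meta.json"


def condition_for_class(class_id: str) -> str:
    """Map a 9-way class label onto its soil condition.

    Gasoline and diesel are petroleum pollution; the six pesticide names are
    pesticide pollution; healthy soil maps to itself.
    """
    if class_id == HEALTHY:
        return "healthy"
    if class_id in PETROLEUM_CLASSES:
        return "petroleum"
    if class_id in PESTICIDE_CLASSES:
        return "pesticide"
    raise ValueError(f"unknown class_id: {class_id!r}")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


class Violation(NamedTuple):
    """One structured invariant violation reported by :func:`validate_record`."""

    field: str
    message: str


@dataclass
class SensorArrayRecord:
    """One sample's multichannel response plus label and acquisition metadata.

    ``response`` is a time × channel matrix in sensor units; time is implicit
    through ``sampling_rate_hz``.  ``concentration`` is the relative pollutant
    dose (``None`` permitted for records where it is not applicable), and
    ``age_days`` the days elapsed between sample preparation and measurement.
    """

    record_id: str
    response: np.ndarray
    sampling_rate_hz: float
    class_id: str
    condition: str
    concentration: float | None = None
    age_days: float = 0.0
    flow_rate_ml_min: float = 300.0
    seed: int | None = None

    @property
    def n_points(self) -> int:
        return int(self.response.shape[0])


@dataclass
class LabeledDataset:
    """Ordered collection of records with a provenance note (config hash)."""

    records: list[SensorArrayRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record_ids in dataset: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.records[i] for i in indices], provenance=self.provenance
        )

    @property
    def class_ids(self) -> np.ndarray:
        return np.array([r.class_id for r in self.records])

    @property
    def conditions(self) -> np.ndarray:
        return np.array([r.condition for r in self.records])

    @property
    def record_ids(self) -> np.ndarray:
        return np.array([r.record_id for r in self.records])


def validate_record(record: SensorArrayRecord) -> list[Violation]:
    """Check every record invariant; return structured violations, never raise."""
    out: list[Violation] = []
    resp = np.asarray(record.response)
    if resp.ndim != 2:
        out.append(Violation("response", f"expected 2-D matrix, got ndim={resp.ndim}"))
        return out
    if resp.shape[1] != N_CHANNELS:
        out.append(
            Violation(
                "response",
                f"expected {N_CHANNELS} channels, got {resp.shape[1]}",
            )
        )
    bad = ~np.isfinite(resp)
    if bad.any():
        t, c = np.argwhere(bad)[0]
        out.append(
            Violation("response", f"non-finite value at time index {t}, channel {c}")
        )
    if record.class_id not in CLASS_IDS:
        out.append(Violation("class_id", f"unknown class_id {record.class_id!r}"))
    else:
        expected = condition_for_class(record.class_id)
        if record.condition != expected:
            out.append(
                Violation(
                    "condition",
                    f"condition {record.condition!r} inconsistent with "
                    f"class_id {record.class_id!r} (expected {expected!r})",
                )
            )
    if not (record.sampling_rate_hz > 0):
        out.append(
            Violation("sampling_rate_hz", f"must be > 0, got {record.sampling_rate_hz}")
        )
    if record.age_days < 0:
        out.append(Violation("age_days", f"must be >= 0, got {record.age_days}"))
    if record.concentration is not None and not (record.concentration > 0):
        out.append(
            Violation("concentration", f"must be > 0, got {record.concentration}")
        )
    return out


def provenance_hash(payload) -> str:
    """Short stable hash of a JSON-serialisable payload, for provenance notes."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_dataset(
    dataset: LabeledDataset, directory: str | Path, overwrite: bool = False
) -> Path:
    """Write one CSV matrix per record plus the manifest; return manifest path.

    Matrices are written with 12 significant digits so features recomputed
    after a round-trip match the originals.  Refuses to clobber existing
    record files unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rates = {r.sampling_rate_hz for r in dataset}
    flows = {r.flow_rate_ml_min for r in dataset}
    if len(rates) > 1:
        raise ValueError(f"heterogeneous sampling_rate_hz in dataset: {sorted(rates)}")

    filenames = [f"{r.record_id}.csv" for r in dataset]
    if not overwrite:
        existing = [f for f in filenames if (directory / f).exists()]
        if existing:
            raise FileExistsError(
                f"overwrite refused: {len(existing)} record file(s) already exist "
                f"in {directory} (first: {existing[0]})"
            )

    header = ",".join(CHANNEL_IDS)
    for rec, fname in zip(dataset, filenames):
        bad = validate_record(rec)
        if bad:
            raise ValueError(f"invalid record {rec.record_id}: {bad}")
        np.savetxt(
            directory / fname,
            np.asarray(rec.response, dtype=float),
            fmt="%.12g",
            delimiter=",",
            header=header,
            comments="",
        )

    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for rec, fname in zip(dataset, filenames):
            writer.writerow(
                [
                    rec.record_id,
                    fname,
                    rec.class_id,
                    rec.condition,
                    "" if rec.concentration is None else f"{rec.concentration:.12g}",
                    f"{rec.age_days:.12g}",
                    "" if rec.seed is None else str(rec.seed),
                ]
            )

    meta = {
        "sampling_rate_hz": (sorted(rates)[0] if rates else None),
        "flow_rate_ml_min": (sorted(flows)[0] if flows else None),
        "n_records": len(dataset),
        "provenance": dataset.provenance,
    }
    with open(directory / _META_FILENAME, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def read_dataset(manifest: str | Path) -> LabeledDataset:
    """Load a dataset in manifest order, validating every record."""
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    directory = manifest.parent

    meta_path = directory / _META_FILENAME
    sampling_rate = 100.0
    flow_rate = 300.0
    provenance = ""
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        sampling_rate = float(meta.get("sampling_rate_hz") or sampling_rate)
        flow_rate = float(meta.get("flow_rate_ml_min") or flow_rate)
        provenance = meta.get("provenance", "")

    records: list[SensorArrayRecord] = []
    with open(manifest, newline="") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing_cols:
            raise ValueError(
                f"manifest {manifest} missing columns: {sorted(missing_cols)}"
            )
        for row in reader:
            path = directory / row["file"]
            if not path.exists():
                raise FileNotFoundError(f"record file not found: {path}")
            matrix = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
            rec = SensorArrayRecord(
                record_id=row["record_id"],
                response=matrix,
                sampling_rate_hz=sampling_rate,
                class_id=row["class_id"],
                condition=row["condition"],
                concentration=(
                    float(row["concentration"]) if row["concentration"] else None
                ),
                age_days=float(row["age_days"] or 0.0),
                flow_rate_ml_min=flow_rate,
                seed=int(row["seed"]) if row["seed"] else None,
            )
            bad = validate_record(rec)
            if bad:
                raise ValueError(f"invalid record in {path}: {bad}")
            records.append(rec)
    return LabeledDataset(records, provenance=provenance)
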