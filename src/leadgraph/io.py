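"""Reading, writing and splitting multi-lead waveform cohorts.

A cohort is an ordered collection of :class:`WaveformRecord` objects that
share a lead montage (same lead names in the same order) and a class
universe.  Three on-disk layouts are supported:

``csv-dir``
    one UTF-8 CSV file per record, header row of lead names, one row per
    sample; a ``labels.csv`` sidecar with a ``record_id`` column plus either
    a ``class`` column (multi-class) or one 0/1 column per class name; a
    ``sampling_rate.csv`` sidecar with per-record rates.
``packed-array``
    a single HDF5 container with datasets ``signals`` (N x L x T),
    ``lead_names``, ``sampling_rate``, ``labels``, ``record_ids`` (and
    ``class_names`` when labels are present).
``wfdb``
    PhysioBank-style header/record pairs (read-only; format 16 samples).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WaveformRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "split_cohort",
]


@dataclass
class WaveformRecord:
    """One L-lead, T-sample waveform with metadata.

    ``labels`` is either ``None``, an integer class index (multi-class), or
    a 0/1 vector over the cohort's class universe (multi-label).
    """

    signal: np.ndarray  # shape (L, T), float
    lead_names: tuple[str, ...]
    sampling_rate: float
    record_id: str
    labels: int | np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.lead_names = tuple(str(n) for n in self.lead_names)
        if self.signal.ndim != 2:
            raise ValueError(f"record {self.record_id!r}: signal must be 2-D (leads x time)")
        L, T = self.signal.shape
        if L < 2:
            raise ValueError(f"record {self.record_id!r}: need at least 2 leads, got {L}")
        if T < 2:
            raise ValueError(f"record {self.record_id!r}: need at least 2 samples, got {T}")
        if len(self.lead_names) != L:
            raise ValueError(
                f"record {self.record_id!r}: {len(self.lead_names)} lead names for {L} leads"
            )
        if len(set(self.lead_names)) != L:
            raise ValueError(f"record {self.record_id!r}: lead names must be unique")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"record {self.record_id!r}: non-finite samples present")
        if not self.sampling_rate > 0:
            raise ValueError(f"record {self.record_id!r}: sampling_rate must be > 0")
        if isinstance(self.labels, (list, np.ndarray)):
            self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def lead(self, name: str) -> np.ndarray:
        return self.signal[self.lead_names.index(name)]

    def reorder(self, lead_names: tuple[str, ...]) -> "WaveformRecord":
        """Return a copy with leads permuted into the given name order."""
        missing = [n for n in lead_names if n not in self.lead_names]
        if missing:
            raise ValueError(f"record {self.record_id!r}: missing lead {missing[0]!r}")
        idx = [self.lead_names.index(n) for n in lead_names]
        return replace(self, signal=self.signal[idx], lead_names=tuple(lead_names))


@dataclass
class Cohort:
    """An ordered collection of records sharing lead order and class set."""

    records: list[WaveformRecord]
    class_names: tuple[str, ...] | None = None
    split_assignment: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.class_names is not None:
            self.class_names = tuple(str(c) for c in self.class_names)
        self.validate()

    def validate(self) -> None:
        if not self.records:
            return
        ref = self.records[0].lead_names
        rates = set()
        for rec in self.records:
            if rec.lead_names != ref:
                raise ValueError(
                    f"record {rec.record_id!r}: lead order {rec.lead_names} differs from "
                    f"cohort order {ref}"
                )
            rates.add(float(rec.sampling_rate))
            if isinstance(rec.labels, np.ndarray) and self.class_names is not None:
                if rec.labels.shape != (len(self.class_names),):
                    raise ValueError(
                        f"record {rec.record_id!r}: label vector length {rec.labels.shape} "
                        f"!= class count {len(self.class_names)}"
                    )
        if len(rates) > 1:
            logger.info("cohort mixes sampling rates %s (lag-0 correlation is rate-agnostic)", sorted(rates))
        if self.split_assignment is not None:
            if len(self.split_assignment) != len(self.records):
                raise ValueError("split_assignment length mismatch")
            bad = set(self.split_assignment) - {"train", "val", "test"}
            if bad:
                raise ValueError(f"unknown split tags {bad}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lead_names(self) -> tuple[str, ...]:
        if not self.records:
            raise ValueError("empty cohort has no lead names")
        return self.records[0].lead_names

    @property
    def n_leads(self) -> int:
        return len(self.lead_names)

    def subset(self, split: str) -> "Cohort":
        """Records carrying the given split tag, as a new cohort."""
        if self.split_assignment is None:
            raise ValueError("cohort has no split assignment; call split_cohort first")
        recs = [r for r, s in zip(self.records, self.split_assignment) if s == split]
        return Cohort(records=recs, class_names=self.class_names)

    def signals(self) -> np.ndarray:
        """All signals stacked into an (N, L, T) array; requires a shared T."""
        lengths = {r.n_samples for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"records have ragged lengths {sorted(lengths)}")
        return np.stack([r.signal for r in self.records])

    def labels_array(self) -> np.ndarray:
        if any(r.labels is None for r in self.records):
            raise ValueError("cohort has records without labels")
        return np.asarray([r.labels for r in self.records])

    @property
    def task(self) -> str:
        """``multi-class`` if labels are indices, ``multi-label`` for vectors."""
        first = self.records[0].labels
        return "multi-label" if isinstance(first, np.ndarray) else "multi-class"


# ---------------------------------------------------------------------------
# label sidecar


def _read_label_sidecar(path: Path) -> tuple[dict[str, int | np.ndarray], tuple[str, ...]]:
    df = pd.read_csv(path, dtype={"record_id": str})
    if "record_id" not in df.columns:
        raise ValueError(f"{path}: label sidecar needs a 'record_id' column")
    if "class" in df.columns:
        classes = tuple(sorted(df["class"].astype(str).unique()))
        lut = {c: i for i, c in enumerate(classes)}
        labels = {
            str(rid): lut[str(cls)]
            for rid, cls in zip(df["record_id"], df["class"])
        }
        return labels, classes
    classes = tuple(c for c in df.columns if c != "record_id")
    labels = {
        str(row["record_id"]): np.asarray([int(row[c]) for c in classes], dtype=np.int64)
        for _, row in df.iterrows()
    }
    return labels, classes


def _write_label_sidecar(cohort: Cohort, path: Path) -> None:
    if any(r.labels is None for r in cohort.records):
        return
    if cohort.task == "multi-class":
        names = cohort.class_names or tuple(
            str(i) for i in range(int(max(r.labels for r in cohort.records)) + 1)
        )
        df = pd.DataFrame(
            {"record_id": [r.record_id for r in cohort.records],
             "class": [names[int(r.labels)] for r in cohort.records]}
        )
    else:
        names = cohort.class_names or tuple(
            f"c{i}" for i in range(len(cohort.records[0].labels))
        )
        df = pd.DataFrame([r.labels for r in cohort.records], columns=list(names))
        df.insert(0, "record_id", [r.record_id for r in cohort.records])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# csv-dir


def _read_csv_dir(path: Path) -> Cohort:
    files = sorted(p for p in path.glob("*.csv") if p.name not in ("labels.csv", "sampling_rate.csv"))
    if not files:
        raise FileNotFoundError(f"no record CSVs in {path}")
    labels: dict[str, int | np.ndarray] = {}
    classes: tuple[str, ...] | None = None
    if (path / "labels.csv").exists():
        labels, classes = _read_label_sidecar(path / "labels.csv")
    rates: dict[str, float] = {}
    if (path / "sampling_rate.csv").exists():
        rdf = pd.read_csv(path / "sampling_rate.csv", dtype={"record_id": str})
        rates = dict(zip(rdf["record_id"], rdf["sampling_rate"].astype(float)))
    records = []
    for f in files:
        rid = f.stem
        df = pd.read_csv(f)
        records.append(
            WaveformRecord(
                signal=df.to_numpy().T,
                lead_names=tuple(df.columns),
                sampling_rate=rates.get(rid, 1.0),
                record_id=rid,
                labels=labels.get(rid),
            )
        )
    return _canonicalize(records, classes)


def _write_csv_dir(cohort: Cohort, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for rec in cohort.records:
        df = pd.DataFrame(rec.signal.T, columns=list(rec.lead_names))
        # 9 significant digits: reproducible round trips without bloated files
        df.to_csv(path / f"{rec.record_id}.csv", index=False, float_format="%.9g")
    pd.DataFrame(
        {"record_id": [r.record_id for r in cohort.records],
         "sampling_rate": [r.sampling_rate for r in cohort.records]}
    ).to_csv(path / "sampling_rate.csv", index=False)
    _write_label_sidecar(cohort, path / "labels.csv")


# ---------------------------------------------------------------------------
# packed-array (HDF5)

_STR = h5py.string_dtype(encoding="utf-8")


def _read_packed(path: Path) -> Cohort:
    with h5py.File(path, "r") as f:
        signals = f["signals"][...]
        lead_names = tuple(s.decode() if isinstance(s, bytes) else str(s) for s in f["lead_names"][...])
        rates = np.atleast_1d(f["sampling_rate"][...]).astype(float)
        record_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["record_ids"][...]]
        labels = f["labels"][...] if "labels" in f else None
        class_names = (
            tuple(s.decode() if isinstance(s, bytes) else str(s) for s in f["class_names"][...])
            if "class_names" in f
            else None
        )
    if rates.size == 1:
        rates = np.full(len(record_ids), rates[0])
    records = []
    for k, rid in enumerate(record_ids):
        lab: int | np.ndarray | None = None
        if labels is not None:
            lab = int(labels[k]) if labels.ndim == 1 else labels[k]
        records.append(
            WaveformRecord(signals[k], lead_names, float(rates[k]), rid, lab)
        )
    return _canonicalize(records, class_names)


def _write_packed(cohort: Cohort, path: Path) -> None:
    signals = cohort.signals()
    # track_times=False keeps the container byte-reproducible across reruns
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=signals, track_times=False)
        f.create_dataset("lead_names", data=np.array(list(cohort.lead_names), dtype=_STR), track_times=False)
        f.create_dataset("sampling_rate", data=np.array([r.sampling_rate for r in cohort.records]), track_times=False)
        f.create_dataset("record_ids", data=np.array([r.record_id for r in cohort.records], dtype=_STR), track_times=False)
        if all(r.labels is not None for r in cohort.records):
            f.create_dataset("labels", data=cohort.labels_array(), track_times=False)
            if cohort.class_names is not None:
                f.create_dataset("class_names", data=np.array(list(cohort.class_names), dtype=_STR), track_times=False)


# ---------------------------------------------------------------------------
# wfdb (read-only, format 16)


def _read_wfdb_header(hea: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    sigs = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1]
        if fmt.split("x")[0] != "16":
            raise ValueError(f"{hea}: only WFDB format 16 is supported, got {fmt}")
        gain = 200.0
        baseline = 0
        if len(tok) > 2:
            gspec = tok[2]
            if "(" in gspec:
                gain_s, rest = gspec.split("(", 1)
                baseline = int(rest.split(")")[0])
            else:
                gain_s = gspec
            gain_s = gain_s.split("/")[0]
            gain = float(gain_s) if float(gain_s) != 0 else 200.0
        desc = tok[8] if len(tok) > 8 else f"sig{len(sigs)}"
        sigs.append({"file": fname, "gain": gain, "baseline": baseline, "name": desc})
    return name, n_sig, fs, n_samp, sigs


def _read_wfdb_record(hea: Path) -> WaveformRecord:
    name, n_sig, fs, n_samp, sigs = _read_wfdb_header(hea)
    dat_files = {s["file"] for s in sigs}
    if len(dat_files) != 1:
        raise ValueError(f"{hea}: multi-file WFDB records are not supported")
    raw = np.fromfile(hea.parent / sigs[0]["file"], dtype="<i2")
    if n_samp:
        raw = raw[: n_samp * n_sig]
    frames = raw.reshape(-1, n_sig)  # interleaved samples
    signal = np.empty((n_sig, frames.shape[0]))
    for i, s in enumerate(sigs):
        signal[i] = (frames[:, i].astype(np.float64) - s["baseline"]) / s["gain"]
    return WaveformRecord(
        signal=signal,
        lead_names=tuple(s["name"] for s in sigs),
        sampling_rate=fs,
        record_id=name,
    )


def _read_wfdb_dir(path: Path) -> Cohort:
    heas = sorted(path.glob("*.hea"))
    if not heas:
        raise FileNotFoundError(f"no .hea headers in {path}")
    labels: dict[str, int | np.ndarray] = {}
    classes: tuple[str, ...] | None = None
    if (path / "labels.csv").exists():
        labels, classes = _read_label_sidecar(path / "labels.csv")
    records = []
    for hea in heas:
        rec = _read_wfdb_record(hea)
        rec.labels = labels.get(rec.record_id)
        records.append(rec)
    return _canonicalize(records, classes)


# ---------------------------------------------------------------------------
# public API


def _canonicalize(records: list[WaveformRecord], class_names) -> Cohort:
    """Enforce the first record's lead order on the rest, reordering by name."""
    canonical = records[0].lead_names
    records = [r if r.lead_names == canonical else r.reorder(canonical) for r in records]
    return Cohort(records=records, class_names=class_names)


_FORMATS = ("wfdb", "csv-dir", "packed-array")


def read_cohort(path: str | Path, format: str) -> Cohort:
    """Read a cohort from disk.

    Lead order is canonicalized to the first record's order; records missing
    a lead raise an error naming both the record and the lead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv-dir":
        return _read_csv_dir(path)
    if format == "packed-array":
        return _read_packed(path)
    if format == "wfdb":
        return _read_wfdb_dir(path)
    raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")


def write_cohort(cohort: Cohort, path: str | Path, format: str) -> None:
    """Write a cohort; packed-array round trips bit-exactly, csv-dir to 9 sig. digits."""
    if not cohort.records:
        raise ValueError("empty cohort")
    path = Path(path)
    if format == "csv-dir":
        _write_csv_dir(cohort, path)
    elif format == "packed-array":
        path.parent.mkdir(parents=True, exist_ok=True)
        _write_packed(cohort, path)
    else:
        raise ValueError(f"unknown writable format {format!r}; expected csv-dir or packed-array")


def split_cohort(cohort: Cohort, fractions=(0.7, 0.15, 0.15), seed: int = 0) -> Cohort:
    """Assign train/val/test tags by a seeded shuffle and contiguous slicing.

    Counts are floor-based for val and test with the remainder going to
    train; the default fractions are the conventional 70/15/15 split.
    Deterministic for a fixed seed: a pure function of (record order,
    fractions, seed).
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative reals")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(cohort.records)
    n_val = math.floor(n * fractions[1])
    n_test = math.floor(n * fractions[2])
    n_train = n - n_val - n_test
    order = np.random.default_rng(seed).permutation(n)
    tags = [""] * n
    for pos, rec_idx in enumerate(order):
        if pos < n_train:
            tags[rec_idx] = "train"
        elif pos < n_train + n_val:
            tags[rec_idx] = "val"
        else:
            tags[rec_idx] = "test"
    return Cohort(
        records=cohort.records,
        class_names=cohort.class_names,
        split_assignment=tags,
    )
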