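"""Record I/O, label filtering, class balancing, splitting and 1D conditioning.

Records travel as CSV (one column per lead, header row of lead names) with a
JSON sidecar holding the sampling rate, label and record id; a CSV without
its sidecar is rejected because the sampling rate would be unknown.  Lead
columns are reordered to the canonical I, II, III, aVR, aVL, aVF, V1-V6
order whenever all names are canonical.

Class balancing and the 4/5 train+validation vs 1/5 test split operate at
record level, so the partitions are record-disjoint ("inter-patient").
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import resample_poly

from rpaf.synthetic_ecg import STANDARD_12_LEADS, EcgRecord

log = logging.getLogger(__name__)

CANONICAL_ORDER = {name: i for i, name in enumerate(STANDARD_12_LEADS)}


@dataclass(frozen=True)
class PrepConfig:
    """Conditioning parameters: target rate, segment length, split and z-score."""

    target_fs: float = 300.0
    segment_len: float = 10.0  # seconds
    test_fraction: float = 0.2
    balance: bool = True
    balance_cap: int = 1200  # records per class after balancing
    zscore: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.target_fs <= 0:
            raise ValueError("target_fs must be positive")
        if self.segment_len <= 0:
            raise ValueError("segment_len must be positive")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.balance_cap < 1:
            raise ValueError("balance_cap must be >= 1")


@dataclass(frozen=True)
class LeadSegment:
    """A single-lead, fixed-length 1D segment ready for RP conversion."""

    samples: np.ndarray
    fs: float
    lead_name: str
    label: str
    record_id: str

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_record(record: EcgRecord, path: str | Path) -> Path:
    """Write a record as CSV (header = lead names) plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ",".join(record.lead_names)
    np.savetxt(path, record.signals.T, delimiter=",", header=header, comments="", fmt="%.6g")
    meta = {
        "fs": record.fs,
        "label": record.label,
        "record_id": record.record_id,
        "lead_names": list(record.lead_names),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _canonical_reorder(record: EcgRecord) -> EcgRecord:
    names = record.lead_names
    if len(set(names)) == len(names) and all(n in CANONICAL_ORDER for n in names):
        order = sorted(range(len(names)), key=lambda i: CANONICAL_ORDER[names[i]])
        if order != list(range(len(names))):
            record = EcgRecord(
                signals=record.signals[order],
                fs=record.fs,
                lead_names=tuple(names[i] for i in order),
                label=record.label,
                record_id=record.record_id,
            )
    return record


def load_record(path: str | Path) -> EcgRecord:
    """Load a CSV record (header row + JSON sidecar with fs/label/id).

    Leads are reordered to the canonical 12-lead order when all names are
    canonical.  WFDB .hea/.dat inputs are not supported; convert to CSV.
    """
    path = Path(path)
    if path.suffix.lower() in (".hea", ".dat"):
        raise ValueError("WFDB record/header input is not supported; provide CSV with a JSON sidecar")
    if path.suffix.lower() != ".csv":
        raise ValueError(f"unknown record format {path.suffix!r}; expected .csv")
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing sampling-rate metadata: sidecar {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError(f"sidecar {sidecar.name} lacks required key 'fs'")
    with open(path) as fh:
        header = fh.readline().strip()
    names = tuple(h.strip() for h in header.split(","))
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != len(names):
        raise ValueError(f"lead-count mismatch: header lists {len(names)} leads, data has {data.shape[1]} columns")
    record = EcgRecord(
        signals=data.T,
        fs=float(meta["fs"]),
        lead_names=names,
        label=str(meta.get("label", "")),
        record_id=str(meta.get("record_id", path.stem)),
    )
    return _canonical_reorder(record)


def load_records(directory: str | Path) -> list[EcgRecord]:
    """Load every .csv record under a directory, sorted by filename."""
    directory = Path(directory)
    return [load_record(p) for p in sorted(directory.glob("*.csv"))]


# ---------------------------------------------------------------------------
# Filtering, balancing, splitting


def select_single_label(records: Iterable[EcgRecord], allowed: Sequence[str] = ("AF", "NSR")) -> list[EcgRecord]:
    """Keep only records whose label set is exactly one allowed label.

    Multi-label records (e.g. "AF|PVC") are dropped so downstream stages see
    a clean two-class problem.
    """
    allowed_set = set(allowed)
    kept = []
    dropped = 0
    for rec in records:
        labels = rec.label_set()
        if len(labels) == 1 and next(iter(labels)) in allowed_set:
            kept.append(rec)
        else:
            dropped += 1
    log.info("select_single_label: kept %d, dropped %d", len(kept), dropped)
    return kept


def balance_and_split(records: Sequence[EcgRecord], cfg: PrepConfig) -> tuple[list[EcgRecord], list[EcgRecord]]:
    """Equalize class counts and split into (train+validation, test) by record.

    Per class, min(count, balance_cap) records are sampled; test_fraction of
    each class (rounded) goes to the test partition.  Deterministic per
    cfg.seed and record-disjoint by construction.
    """
    cfg.validate()
    by_label: dict[str, list[EcgRecord]] = {"AF": [], "NSR": []}
    for rec in records:
        labels = rec.label_set()
        if len(labels) == 1 and next(iter(labels)) in by_label:
            by_label[next(iter(labels))].append(rec)
    for label, recs in by_label.items():
        if not recs:
            raise ValueError(f"class {label} absent from input records")

    n_class = min(len(v) for v in by_label.values()) if cfg.balance else None
    rng = np.random.default_rng(cfg.seed)
    train_val: list[EcgRecord] = []
    test: list[EcgRecord] = []
    for label in ("AF", "NSR"):
        recs = sorted(by_label[label], key=lambda r: r.record_id)
        perm = rng.permutation(len(recs))
        take = len(recs) if n_class is None else min(n_class, cfg.balance_cap)
        chosen = [recs[i] for i in perm[:take]]
        n_test = int(round(take * cfg.test_fraction))
        test.extend(chosen[:n_test])
        train_val.extend(chosen[n_test:])
    log.info(
        "balance_and_split: train+val=%d, test=%d (per-class cap=%s)",
        len(train_val), len(test), n_class,
    )
    return train_val, test


# ---------------------------------------------------------------------------
# 1D conditioning


def resample_lead(samples: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Band-limited polyphase resampling from fs_in to fs_out.

    Output length is round(len * fs_out / fs_in).  The rational resampling
    factor is approximated to within 1/1000 when the rate ratio is not
    exactly rational.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(samples, dtype=float).ravel()
    if fs_in == fs_out:
        return x.copy()
    ratio = Fraction(fs_out) / Fraction(fs_in)
    ratio = ratio.limit_denominator(1000)
    y = resample_poly(x, ratio.numerator, ratio.denominator)
    n_target = int(round(len(x) * fs_out / fs_in))
    if len(y) > n_target:
        y = y[:n_target]
    elif len(y) < n_target:
        y = np.pad(y, (0, n_target - len(y)), mode="edge")
    return y


def take_segment(samples: np.ndarray, fs: float, seconds: float) -> np.ndarray:
    """Leading round(fs * seconds) samples (segments start at the first sample)."""
    x = np.asarray(samples).ravel()
    n = int(round(fs * seconds))
    if len(x) < n:
        raise ValueError(f"signal of {len(x)} samples shorter than requested {n}")
    return x[:n].copy()


def zscore(samples: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1; a constant input maps to all zeros.

    "Constant" is judged relative to the signal magnitude so that round-off
    noise on a flat trace does not get amplified to unit variance.
    """
    x = np.asarray(samples, dtype=float)
    sd = x.std()
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max(initial=0.0))):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def record_to_segments(
    record: EcgRecord,
    cfg: PrepConfig,
    leads: Sequence[str] | None = None,
) -> list[LeadSegment]:
    """Split a record into per-lead segments at the target rate and length.

    Optionally restricted to named leads.  Z-scoring is left to the RP
    conversion stage (its cfg.zscore flag) so that the segment retains
    physical units here.
    """
    cfg.validate()
    names = list(leads) if leads is not None else list(record.lead_names)
    out = []
    for name in names:
        x = record.lead(name)
        y = resample_lead(x, record.fs, cfg.target_fs)
        y = take_segment(y, cfg.target_fs, cfg.segment_len)
        out.append(
            LeadSegment(samples=y, fs=cfg.target_fs, lead_name=name, label=record.label, record_id=record.record_id)
        )
    return out
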