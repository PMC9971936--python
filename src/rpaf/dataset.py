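"""Per-lead RP-image dataset container shared by selection and pipelines."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from rpaf.recurrence import RpConfig, ecg_to_rp
from rpaf.signal_prep import PrepConfig, record_to_segments
from rpaf.synthetic_ecg import EcgRecord

LABEL_TO_INT = {"NSR": 0, "AF": 1}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}


@dataclass
class LeadImageDataset:
    """RP images indexed by lead name, plus integer labels (1 = AF).

    ``images[lead]`` has shape (n_records, 3, size, size); rows across leads
    are aligned by record, so any lead subset can be stacked channel-wise
    without re-rendering.
    """

    images: dict[str, np.ndarray]
    labels: np.ndarray
    record_ids: list[str]

    @property
    def leads(self) -> tuple[str, ...]:
        return tuple(self.images.keys())

    def __len__(self) -> int:
        return len(self.labels)

    def stack(self, leads: Sequence[str], fusion: str = "stack") -> np.ndarray:
        """Multi-lead input tensor.

        fusion="stack" concatenates per-lead RGB images along channels
        (n, 3*len(leads), size, size); fusion="mean" averages them into a
        single RGB image (n, 3, size, size), which keeps the network input
        width independent of the subset size.
        """
        missing = [l for l in leads if l not in self.images]
        if missing:
            raise KeyError(f"leads {missing} not in dataset ({self.leads})")
        stacked = [self.images[l] for l in leads]
        if fusion == "stack":
            return np.concatenate(stacked, axis=1)
        if fusion == "mean":
            return np.mean(stacked, axis=0, dtype=np.float32)
        raise ValueError(f"unknown fusion mode {fusion!r}")


def build_lead_image_dataset(
    records: Sequence[EcgRecord],
    leads: Sequence[str],
    prep_cfg: PrepConfig,
    rp_cfg: RpConfig,
) -> LeadImageDataset:
    """Prep each record's requested leads and render their RP images."""
    per_lead: dict[str, list[np.ndarray]] = {l: [] for l in leads}
    labels, ids = [], []
    for rec in records:
        segments = record_to_segments(rec, prep_cfg, leads=leads)
        for seg in segments:
            img = ecg_to_rp(seg.samples, seg.fs, rp_cfg)
            per_lead[seg.lead_name].append(img.to_chw())
        labels.append(LABEL_TO_INT[rec.label])
        ids.append(rec.record_id)
    images = {l: np.stack(v).astype(np.float32) for l, v in per_lead.items()}
    return LeadImageDataset(images=images, labels=np.asarray(labels, dtype=int), record_ids=ids)
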