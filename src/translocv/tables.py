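"""Descriptor tables: frames x contact distances, with per-column metadata.

The same container is used for synthetic surrogate descriptors and for
contact distances computed from structures; metadata entries are dataclasses
(:class:`~translocv.surrogate.DescriptorSpec` or
:class:`~translocv.contacts.ContactDefinition`) or plain dicts.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["DescriptorTable"]


class DescriptorTable:
    """A frames-by-descriptors distance table.

    Parameters
    ----------
    data:
        DataFrame with one column per descriptor id, one row per frame (Å).
    metadata:
        Mapping descriptor_id -> metadata record for every column.
    labels:
        Optional per-frame state labels (array of str).
    """

    def __init__(self, data: pd.DataFrame, metadata: dict | None = None, labels=None):
        self.data = data
        self.metadata = metadata or {}
        missing = [c for c in data.columns if c not in self.metadata]
        if self.metadata and missing:
            raise SchemaError(f"columns without metadata: {missing[:3]}...")
        self.labels = None if labels is None else np.asarray(labels)
        if self.labels is not None and len(self.labels) != len(data):
            raise SchemaError("labels length does not match frame count")

    # -- basic protocol ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def descriptor_ids(self) -> list[str]:
        return list(self.data.columns)

    def values(self, ids=None) -> np.ndarray:
        return (self.data if ids is None else self.data[list(ids)]).to_numpy()

    def select(self, ids) -> "DescriptorTable":
        ids = list(ids)
        return DescriptorTable(
            self.data[ids].copy(),
            {i: self.metadata[i] for i in ids} if self.metadata else {},
            self.labels,
        )

    def frames_for(self, state: str) -> "DescriptorTable":
        if self.labels is None:
            raise SchemaError("table carries no state labels")
        mask = self.labels == state
        return DescriptorTable(
            self.data.loc[mask].reset_index(drop=True), self.metadata, self.labels[mask]
        )

    # -- serialization -------------------------------------------------------
    def to_csv(self, path) -> None:
        """CSV with a '#meta' header block holding per-column metadata as JSON."""
        with open(path, "w") as fh:
            for col in self.data.columns:
                meta = self.metadata.get(col, {})
                if dataclasses.is_dataclass(meta):
                    meta = dataclasses.asdict(meta)
                fh.write(f"#meta {json.dumps({'id': col, **meta})}\n")
            if self.labels is not None:
                out = self.data.copy()
                out.insert(0, "state_label", self.labels)
            else:
                out = self.data
            out.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, spec_factory=None) -> "DescriptorTable":
        meta = {}
        n_header = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#meta "):
                    break
                n_header += 1
                rec = json.loads(line[len("#meta "):])
                cid = rec.pop("id")
                meta[cid] = spec_factory(**rec) if spec_factory else rec
        df = pd.read_csv(path, skiprows=n_header)
        labels = None
        if "state_label" in df.columns:
            labels = df.pop("state_label").to_numpy()
        return cls(df, meta or None, labels)
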