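"""Cohort tables: paired per-subject metric records.

A :class:`CohortTable` is a thin wrapper over a tidy DataFrame with one row
per (subject, state) and a provenance block saying whether the rows came
from the synthetic generator or from the packaged reference-study
transcription.  The statistics layer consumes the paired wide form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DomainError

__all__ = ["CohortTable"]

_KEY_COLS = ("subject_id", "state")


@dataclass
class CohortTable:
    """Rows keyed by (subject_id, state) plus a provenance dict."""

    rows: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _KEY_COLS if c not in self.rows.columns]
        if missing:
            raise DomainError(f"cohort table lacks key columns: {missing}")

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.rows["subject_id"]))

    def check_paired(self) -> None:
        """Every subject must have exactly one PREOP and one POSTOP row."""
        counts = self.rows.groupby(["subject_id", "state"]).size().unstack(fill_value=0)
        bad = [
            str(s)
            for s, row in counts.iterrows()
            if row.get("PREOP", 0) != 1 or row.get("POSTOP", 0) != 1
        ]
        if bad:
            raise DomainError(f"subjects without exactly one pre/post pair: {bad}")

    def state_frame(self, state: str) -> pd.DataFrame:
        """Rows of one state, indexed by subject in cohort order."""
        frame = self.rows[self.rows["state"] == state].set_index("subject_id")
        return frame.loc[self.subjects]

    def paired(self, column: str) -> pd.DataFrame:
        """Wide frame with 'pre' and 'post' columns for one metric."""
        self.check_paired()
        pre = self.state_frame("PREOP")[column]
        post = self.state_frame("POSTOP")[column]
        return pd.DataFrame({"pre": pre, "post": post})

    def write(self, csv_path: str | Path, provenance_path: str | Path | None = None) -> None:
        """CSV rows plus an optional JSON provenance sidecar."""
        self.rows.to_csv(csv_path, index=False)
        if provenance_path is not None:
            Path(provenance_path).write_text(json.dumps(self.provenance, indent=2, sort_keys=True))

    @classmethod
    def read(cls, csv_path: str | Path, provenance_path: str | Path | None = None) -> "CohortTable":
        prov = {}
        if provenance_path is not None and Path(provenance_path).exists():
            prov = json.loads(Path(provenance_path).read_text())
        return cls(pd.read_csv(csv_path), prov)
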