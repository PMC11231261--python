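"""Tabular results with provenance.

Every pipeline emits rows keyed by (egg id, assay, measurement); the
writer produces a CSV with a fixed column order that round-trips
losslessly and is byte-identical across runs for identical inputs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

COLUMNS = ["egg_id", "assay", "measurement", "value", "units", "config_hash", "seed"]


class ResultTable:
    """Result rows keyed by (egg_id, assay, measurement)."""

    def __init__(self) -> None:
        self._rows: list[dict] = []
        self._keys: set[tuple[str, str, str]] = set()

    def add(
        self,
        egg_id: str,
        assay: str,
        measurement: str,
        value: float,
        units: str = "a.u.",
        config_hash: str = "",
        seed: int = 0,
    ) -> None:
        key = (str(egg_id), assay, measurement)
        if key in self._keys:
            raise ValueError(f"duplicate result key {key}")
        self._keys.add(key)
        self._rows.append(
            {
                "egg_id": str(egg_id),
                "assay": assay,
                "measurement": measurement,
                "value": float(value),
                "units": units,
                "config_hash": config_hash,
                "seed": int(seed),
            }
        )

    def __len__(self) -> int:
        return len(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        # repr-precision floats so values round-trip exactly
        self.to_frame().to_csv(path, index=False, float_format=None)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ResultTable":
        frame = pd.read_csv(path, dtype={"egg_id": str}, keep_default_na=False)
        if list(frame.columns) != COLUMNS:
            raise ValueError(f"unexpected columns {list(frame.columns)}")
        table = cls()
        for row in frame.itertuples(index=False):
            table.add(
                row.egg_id,
                row.assay,
                row.measurement,
                row.value,
                row.units,
                row.config_hash,
                int(row.seed),
            )
        return table
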