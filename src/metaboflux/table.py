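"""Sample-by-metabolite concentration table, the pipeline's central exchange object.

The on-disk form is a plain CSV with the metadata columns
``sample_id, tissue, group, wet_weight_g`` followed by one column per
metabolite (µmol/g wet weight; glycogen in mobile-1H glucosyl-equivalents).
Missing values are empty fields, never sentinel numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["sample_id", "tissue", "group", "wet_weight_g"]


class TableSchemaError(ValueError):
    """Raised when a concentration table violates the documented schema."""


@dataclass
class ConcentrationTable:
    """Samples x metabolites matrix with tissue/group/wet-weight metadata.

    Parameters
    ----------
    data:
        DataFrame holding the meta columns plus metabolite columns.
    group_order:
        Group labels in design order, control first. Defaults to order of
        first appearance in ``data``.
    """

    data: pd.DataFrame
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise TableSchemaError(f"missing required columns: {missing}")
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise TableSchemaError(f"duplicate sample_id: {sorted(set(dup))}")
        if not self.group_order:
            self.group_order = list(dict.fromkeys(df["group"]))
        unknown = set(df["group"]) - set(self.group_order)
        if unknown:
            raise TableSchemaError(f"unknown group label: {sorted(unknown)}")
        conc = df[self.metabolites]
        if (conc.to_numpy(dtype=float) < 0).any():
            bad = [
                (df["sample_id"].iloc[i], conc.columns[j])
                for i, j in zip(*np.where(conc.to_numpy(dtype=float) < 0))
            ]
            raise TableSchemaError(f"negative concentrations at {bad}")
        ww = df["wet_weight_g"].to_numpy(dtype=float)
        if (ww <= 0).any() or np.isnan(ww).any():
            raise TableSchemaError("wet_weight_g must be positive and present")

    @property
    def metabolites(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def control_group(self) -> str:
        return self.group_order[0]

    def subset(self, tissue: str) -> "ConcentrationTable":
        sub = self.data[self.data["tissue"] == tissue].reset_index(drop=True)
        if sub.empty:
            raise TableSchemaError(f"no samples for tissue {tissue!r}")
        return ConcentrationTable(sub, group_order=list(self.group_order))

    def values(self, metabolite: str, tissue: str | None = None,
               group: str | None = None) -> np.ndarray:
        df = self.data
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        if group is not None:
            df = df[df["group"] == group]
        if metabolite not in self.data.columns:
            raise TableSchemaError(f"unknown metabolite column {metabolite!r}")
        return df[metabolite].to_numpy(dtype=float)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False, na_rep="")

    def __eq__(self, other: object) -> bool:  # round-trip equality
        if not isinstance(other, ConcentrationTable):
            return NotImplemented
        if self.group_order != other.group_order:
            return False
        a, b = self.data, other.data
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if c in META_COLUMNS and c != "wet_weight_g":
                if not (a[c].astype(str) == b[c].astype(str)).all():
                    return False
            else:
                x = a[c].to_numpy(dtype=float)
                y = b[c].to_numpy(dtype=float)
                both_nan = np.isnan(x) & np.isnan(y)
                if not np.all(both_nan | np.isclose(x, y, rtol=1e-12, atol=0)):
                    return False
        return True


def read_table(path, group_order: list[str] | None = None) -> ConcentrationTable:
    """Read a concentration table CSV, validating the schema.

    Violations are reported with row/column coordinates where applicable.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "tissue": str, "group": str})
    for col in META_COLUMNS:
        if col not in df.columns:
            raise TableSchemaError(f"{path}: missing column {col!r}")
    for col in df.columns:
        if col in ("sample_id", "tissue", "group"):
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise TableSchemaError(f"{path}: non-numeric value in column {col!r}: {exc}")
    return ConcentrationTable(df, group_order=group_order or [])


def write_table(table: ConcentrationTable, path) -> None:
    table.write_csv(path)
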