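"""Mixed-type maternal factor tables.

Maternal variables come in three declared types — binary, ordinal and
interval — and downstream association testing dispatches on those types.
The table is dyad-indexed (one row per mother–neonate pair) and tolerates
missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

VALID_TYPES = ("binary", "ordinal", "interval")


@dataclass
class FactorTable:
    """Dyad x variable table with per-variable declared types.

    Parameters
    ----------
    data : DataFrame
        Rows are dyads, columns are maternal variables. Binary variables
        hold 0/1 (at most two observed levels), ordinal variables hold
        level codes whose order follows ``ordinal_levels`` (or the sorted
        unique values if undeclared), interval variables hold reals.
        Missing cells are NaN.
    types : dict
        Variable name -> one of {"binary", "ordinal", "interval"}.
    ordinal_levels : dict
        Optional variable -> ordered list of levels (lowest first).
    block_labels : Series or None
        Ground-truth block membership per variable (synthetic cohorts only).
    block_scores : DataFrame or None
        Ground-truth latent block score per dyad (synthetic cohorts only).
    """

    data: pd.DataFrame
    types: dict
    ordinal_levels: dict = field(default_factory=dict)
    block_labels: pd.Series | None = None
    block_scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.types)
        if missing:
            raise ValueError(f"variables without a declared type: {sorted(missing)}")
        bad = {v: t for v, t in self.types.items() if t not in VALID_TYPES}
        if bad:
            raise ValueError(f"invalid variable types: {bad}")
        for var, t in self.types.items():
            if var not in self.data.columns:
                continue
            if t == "binary":
                levels = pd.unique(self.data[var].dropna())
                if len(levels) > 2:
                    raise ValueError(
                        f"binary variable {var!r} has {len(levels)} observed levels"
                    )

    @property
    def n_dyads(self) -> int:
        return self.data.shape[0]

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def numeric_codes(self, var: str) -> np.ndarray:
        """Numeric coding of a variable: 0/1 for binary, level rank for
        ordinal, raw values for interval. NaN preserved."""
        values = self.data[var]
        t = self.types[var]
        if t == "interval":
            return values.to_numpy(dtype=float)
        if t == "binary":
            levels = sorted(pd.unique(values.dropna()))
            mapping = {lv: float(i) for i, lv in enumerate(levels)}
            return values.map(mapping).to_numpy(dtype=float)
        levels = self.ordinal_levels.get(var)
        if levels is None:
            levels = sorted(pd.unique(values.dropna()))
        mapping = {lv: float(i) for i, lv in enumerate(levels)}
        return values.map(mapping).to_numpy(dtype=float)

    def encoded(self) -> pd.DataFrame:
        """All variables numerically coded (see :meth:`numeric_codes`)."""
        return pd.DataFrame(
            {v: self.numeric_codes(v) for v in self.data.columns},
            index=self.data.index,
        )

    def subset(self, variables) -> "FactorTable":
        variables = list(variables)
        return FactorTable(
            data=self.data[variables].copy(),
            types={v: self.types[v] for v in variables},
            ordinal_levels={
                v: self.ordinal_levels[v] for v in variables if v in self.ordinal_levels
            },
            block_labels=(
                self.block_labels.loc[variables] if self.block_labels is not None else None
            ),
            block_scores=self.block_scores,
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, data_path, types_path) -> None:
        self.data.to_csv(data_path, sep="\t", index_label="dyad_id")
        rows = []
        for v in self.data.columns:
            levels = self.ordinal_levels.get(v)
            rows.append(
                {
                    "variable": v,
                    "type": self.types[v],
                    "levels": "|".join(map(str, levels)) if levels else "",
                    "block": (
                        self.block_labels.loc[v]
                        if self.block_labels is not None
                        else ""
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(types_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, data_path, types_path) -> "FactorTable":
        data = pd.read_csv(data_path, sep="\t", index_col="dyad_id")
        tinfo = pd.read_csv(types_path, sep="\t", dtype=str).fillna("")
        types = dict(zip(tinfo["variable"], tinfo["type"]))
        ordinal_levels = {}
        for _, row in tinfo.iterrows():
            if row.get("levels", ""):
                ordinal_levels[row["variable"]] = [
                    _maybe_number(x) for x in row["levels"].split("|")
                ]
        block_labels = None
        if "block" in tinfo.columns and (tinfo["block"] != "").any():
            block_labels = pd.Series(
                [_maybe_number(b) for b in tinfo["block"]],
                index=tinfo["variable"],
                name="block",
            )
        return cls(
            data=data,
            types=types,
            ordinal_levels=ordinal_levels,
            block_labels=block_labels,
        )


def _maybe_number(x: str):
    try:
        f = float(x)
    except (TypeError, ValueError):
        return x
    return int(f) if f == int(f) else f
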