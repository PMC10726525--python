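"""Response-variable transforms.

The regression target is LN IC50.  For training the model the natural-log
value x is mapped onto (0, 1) via y = e^x followed by ŷ = 1/(1 + y^{-0.1}),
which collapses to a gentle logistic in x:

    scale(x) = 1 / (1 + e^{-0.1 x})

The -0.1 exponent spreads the typically small IC50 values more evenly over
(0, 1).  ``unscale_response`` is its exact closed-form inverse, used to
report predictions back on the LN scale.  ``zscore`` standardises a
prediction matrix prior to Euclidean clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResponseTable",
    "scale_response",
    "unscale_response",
    "zscore",
    "read_response_table",
    "write_response_table",
]


@dataclass
class ResponseTable:
    """Long-format (drug, cell line, LN IC50) records; NaN = unmeasured pair."""

    records: pd.DataFrame  # columns: drug_id, cell_line_id, ln_ic50
    scaled: bool = False

    def __post_init__(self):
        required = {"drug_id", "cell_line_id", "ln_ic50"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"response table needs columns {sorted(required)}")
        pairs = self.records[["drug_id", "cell_line_id"]]
        if pairs.duplicated().any():
            raise ValueError("duplicate (drug, cell line) pairs in response table")
        if self.scaled:
            vals = self.records["ln_ic50"].dropna()
            if ((vals <= 0) | (vals >= 1)).any():
                raise ValueError("scaled responses must lie in (0, 1)")

    @property
    def labeled(self) -> pd.DataFrame:
        return self.records.dropna(subset=["ln_ic50"])

    @property
    def n_labeled(self) -> int:
        return int(self.records["ln_ic50"].notna().sum())

    def scale(self) -> "ResponseTable":
        if self.scaled:
            raise ValueError("already scaled")
        out = self.records.copy()
        mask = out["ln_ic50"].notna()
        out.loc[mask, "ln_ic50"] = scale_response(out.loc[mask, "ln_ic50"].to_numpy())
        return ResponseTable(out, scaled=True)


def scale_response(x):
    """LN IC50 → (0, 1): 1/(1 + e^{-0.1 x}); strictly increasing in x."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("LN IC50 values must be finite")
    out = 1.0 / (1.0 + np.exp(-0.1 * x))
    return float(out) if out.ndim == 0 else out


def unscale_response(yhat):
    """Inverse transform: (0, 1) → LN IC50, 10·ln(ŷ/(1−ŷ))."""
    yhat = np.asarray(yhat, dtype=np.float64)
    if np.any(yhat <= 0) or np.any(yhat >= 1):
        raise ValueError("scaled responses must lie strictly inside (0, 1)")
    out = 10.0 * np.log(yhat / (1.0 - yhat))
    return float(out) if out.ndim == 0 else out


def zscore(matrix, axis: str = "rows", ddof: int = 0):
    """Standardise slices of a matrix to mean 0, sd 1 (population sd by default).

    axis='rows' standardises each row, 'columns' each column, 'all' the
    whole matrix.  A constant slice has no z-score and raises.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if axis not in {"rows", "columns", "all"}:
        raise ValueError("axis must be 'rows', 'columns' or 'all'")
    if axis == "all":
        sd = m.std(ddof=ddof)
        if sd == 0:
            raise ValueError("matrix is constant; z-score undefined")
        return (m - m.mean()) / sd
    ax = 1 if axis == "rows" else 0
    mu = m.mean(axis=ax, keepdims=True)
    sd = m.std(axis=ax, ddof=ddof, keepdims=True)
    flat = np.where(sd.ravel() == 0)[0]
    if flat.size:
        kind = "row" if axis == "rows" else "column"
        raise ValueError(f"constant {kind}(s) {flat.tolist()}; z-score undefined")
    return (m - mu) / sd


def read_response_table(path) -> ResponseTable:
    """CSV/TSV with columns drug_id, cell_line_id, ln_ic50 (blank = missing)."""
    from pathlib import Path

    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"drug_id": str, "cell_line_id": str})
    return ResponseTable(df[["drug_id", "cell_line_id", "ln_ic50"]])


def write_response_table(table: ResponseTable, path) -> None:
    table.records.to_csv(path, index=False)
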