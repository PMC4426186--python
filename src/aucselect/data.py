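"""Container for paired diagnostic-test measurements with a binary gold standard.

A within-subject ("paired") diagnostic design measures every candidate test on
every subject, so the d marker columns are correlated.  The gold standard splits
subjects into controls (status 0) and cases (status 1).  Measurements may be
continuous, discrete or ordered categorical; only their ordering is ever used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BiomarkerData", "read_biomarker_csv"]


@dataclass(frozen=True)
class BiomarkerData:
    """Subjects x markers measurement matrix plus case/control labels.

    Parameters
    ----------
    values : ndarray, shape (N, d)
        One row per subject, one column per diagnostic test.  Ordinal
        categories must already be coded numerically; any order-preserving
        coding is equivalent because all downstream statistics are rank based.
    status : ndarray, shape (N,)
        0 for controls, 1 for cases.
    marker_names : sequence of str, optional
        Column identifiers; defaults to ``marker_1 .. marker_d``.
    """

    values: np.ndarray
    status: np.ndarray
    marker_names: tuple = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        status = np.asarray(self.status)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-d (subjects x markers) array")
        if status.shape != (values.shape[0],):
            raise ValueError(
                f"status has shape {status.shape}, expected ({values.shape[0]},)"
            )
        if not np.isin(status, (0, 1)).all():
            raise ValueError("status must contain only 0 (control) and 1 (case)")
        status = status.astype(np.int8)
        object.__setattr__(self, "status", status)
        if np.isnan(values).any():
            rows, cols = np.nonzero(np.isnan(values))
            raise ValueError(
                "missing values are not supported in a within-subject design; "
                f"first offending cell: subject {rows[0]}, marker {cols[0]}"
            )
        n1 = int(status.sum())
        n0 = len(status) - n1
        if n0 < 2 or n1 < 2:
            raise ValueError(
                f"need at least 2 subjects per group (got {n0} controls, {n1} cases); "
                "the placement-variance estimators divide by n_i - 1"
            )
        names = self.marker_names
        if names is None:
            names = tuple(f"marker_{j + 1}" for j in range(values.shape[1]))
        else:
            names = tuple(str(n) for n in names)
            if len(names) != values.shape[1]:
                raise ValueError("marker_names length does not match values")
        object.__setattr__(self, "marker_names", names)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    @property
    def n_cases(self) -> int:
        return int((self.status == 1).sum())

    @property
    def controls(self) -> np.ndarray:
        """Measurements of the control group, shape (n0, d)."""
        return self.values[self.status == 0]

    @property
    def cases(self) -> np.ndarray:
        """Measurements of the case group, shape (n1, d)."""
        return self.values[self.status == 1]

    def swap_labels(self) -> "BiomarkerData":
        """Exchange the case/control roles (maps each AUC a to 1 - a)."""
        return BiomarkerData(self.values, 1 - self.status, self.marker_names)

    def to_frame(self, status_column: str = "status") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.marker_names))
        df.insert(0, status_column, self.status.astype(int))
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        status_column: str = "status",
        control_label="0",
        case_label="1",
    ) -> "BiomarkerData":
        """Build from a DataFrame with one status column and marker columns.

        ``control_label`` / ``case_label`` are compared against the string
        representation of the status column, so numeric and textual labels
        (e.g. ``"CF unlikely"`` / ``"CF"``) both work.
        """
        if status_column not in df.columns:
            raise ValueError(f"status column {status_column!r} not found")
        raw = df[status_column].astype(str).str.strip()
        control_label, case_label = str(control_label), str(case_label)
        unknown = sorted(set(raw) - {control_label, case_label})
        if unknown:
            raise ValueError(
                f"unknown status label(s) {unknown}; expected "
                f"{control_label!r} or {case_label!r}"
            )
        status = (raw == case_label).to_numpy().astype(np.int8)
        markers = df.drop(columns=[status_column])
        na = markers.isna()
        if na.to_numpy().any():
            cells = [
                f"row {i}, column {c!r}"
                for i, c in zip(*np.nonzero(na.to_numpy()))
                for c in [markers.columns[c]]
            ]
            raise ValueError("missing marker values at: " + "; ".join(cells[:10]))
        values = markers.apply(_to_numeric_codes).to_numpy(dtype=float)
        return cls(values, status, tuple(markers.columns.astype(str)))


def _to_numeric_codes(col: pd.Series) -> pd.Series:
    """Numeric columns pass through; categorical/text columns become order codes."""
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float)
    cat = col.astype("category")
    if not cat.cat.ordered:
        cat = cat.cat.as_ordered()  # lexicographic order; ranks only need an order
    return cat.cat.codes.astype(float)


def read_biomarker_csv(
    path,
    status_column: str = "status",
    control_label="0",
    case_label="1",
) -> BiomarkerData:
    """Read a subjects x markers CSV (header row, one status column).

    Marker column order follows file order, so reports are reproducible.
    """
    df = pd.read_csv(path)
    return BiomarkerData.from_frame(df, status_column, control_label, case_label)
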