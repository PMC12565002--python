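"""Design-annotated sample tables: soil indicators and community abundances.

The experimental unit throughout is a field plot identified by ``sample_id``
and assigned to exactly one treatment of a (by default) 2x2 factorial
inoculation design: control (CK), arbuscular mycorrhizal fungi only (AM),
*Trichoderma* only (TL), and the combined inoculation (AT).

Two table kinds are supported:

* :class:`IndicatorTable` — samples x soil chemistry / enzyme-activity
  indicators (pH, SOM, TN, TP, TK, AP, AK, AN, NO3-N, NH4-N, enzyme
  activities), each with a scoring direction ("ascending" = more is better).
* :class:`AbundanceTable` — samples x taxa relative abundances (rows sum
  to one) or raw non-negative abundances.

Files are plain delimited text (comma or tab, auto-detected) with a header
row and mandatory ``sample_id`` and ``treatment`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, DesignError, ValidationError

__all__ = [
    "TreatmentDesign",
    "IndicatorTable",
    "AbundanceTable",
    "read_indicator_table",
    "read_abundance_table",
    "zscore",
]

_META_COLUMNS = ("sample_id", "treatment", "replicate")


@dataclass(frozen=True)
class TreatmentDesign:
    """Treatment labels and their 2x2 factorial mapping.

    ``factors`` maps each treatment to ``(amf, trichoderma)`` inoculation
    booleans; the first treatment label is the control used for percent
    changes.
    """

    treatments: tuple[str, ...] = ("CK", "AM", "TL", "AT")
    replicates_per_treatment: int = 4
    factors: Mapping[str, tuple[bool, bool]] = field(
        default_factory=lambda: {
            "CK": (False, False),
            "AM": (True, False),
            "TL": (False, True),
            "AT": (True, True),
        }
    )

    def __post_init__(self) -> None:
        if self.replicates_per_treatment < 1:
            raise DesignError("replicates_per_treatment must be a positive integer")
        if len(set(self.treatments)) != len(self.treatments):
            raise DesignError("treatment labels must be unique")
        missing = [t for t in self.treatments if t not in self.factors]
        if missing:
            raise DesignError(f"treatments missing a factorial mapping: {missing}")
        combos = [tuple(self.factors[t]) for t in self.treatments]
        if len(set(combos)) != len(combos):
            raise DesignError("factorial mapping must be unique per treatment")

    @property
    def control(self) -> str:
        return self.treatments[0]

    def factor_levels(self, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Return (amf, trichoderma) boolean arrays for per-sample labels."""
        amf = np.array([self.factors[t][0] for t in labels], dtype=bool)
        tri = np.array([self.factors[t][1] for t in labels], dtype=bool)
        return amf, tri


class _DesignTable:
    """Shared validation / accessors for design-annotated tables."""

    def __init__(
        self,
        data: pd.DataFrame,
        treatments: pd.Series,
        design: TreatmentDesign | None = None,
    ) -> None:
        design = design if design is not None else TreatmentDesign()
        data = data.copy()
        treatments = treatments.reindex(data.index)

        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate column names: {dupes}")
        bad = ~treatments.isin(design.treatments)
        if bad.any():
            labels = sorted(set(treatments[bad]))
            raise DesignError(
                f"unknown treatment label(s) {labels}; design has {list(design.treatments)}"
            )
        if data.isna().any().any():
            cells = [
                (str(i), str(c))
                for i, row in data.isna().iterrows()
                for c in data.columns[row.values]
            ]
            raise ValidationError(f"missing value(s) at (sample, column): {cells}")
        counts = treatments.value_counts()
        thin = counts[counts < 2]
        if len(thin):
            raise ValidationError(
                f"treatments with fewer than 2 samples: {thin.index.tolist()}"
            )

        self.data = data.astype(float)
        self.treatments = treatments
        self.design = design

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def treatment_means(self) -> pd.DataFrame:
        """Per-treatment mean of every column, rows in design order."""
        means = self.data.groupby(self.treatments).mean()
        order = [t for t in self.design.treatments if t in means.index]
        return means.loc[order]

    def _meta_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "treatment", self.treatments)
        out.index.name = "sample_id"
        return out

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self._meta_frame().to_csv(path, sep=sep, encoding="utf-8")


class IndicatorTable(_DesignTable):
    """Samples x soil-indicator matrix with treatment metadata.

    Parameters
    ----------
    data
        Numeric DataFrame indexed by sample id, one column per indicator.
    treatments
        Per-sample treatment label aligned with ``data``.
    design
        The treatment design; defaults to the CK/AM/TL/AT factorial.
    directions
        Per-indicator scoring direction, ``"ascending"`` (more is better,
        the default for fertility and enzyme-activity measures) or
        ``"descending"``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        treatments: pd.Series,
        design: TreatmentDesign | None = None,
        directions: Mapping[str, str] | None = None,
    ) -> None:
        super().__init__(data, treatments, design)
        dirs = {name: "ascending" for name in self.data.columns}
        for name, d in (directions or {}).items():
            if name not in dirs:
                raise ValidationError(f"direction given for unknown indicator {name!r}")
            if d not in ("ascending", "descending"):
                raise ValidationError(f"direction must be ascending/descending, got {d!r}")
            dirs[name] = d
        self.directions = dirs

    @property
    def indicator_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def subset(self, indicators: Sequence[str]) -> "IndicatorTable":
        return IndicatorTable(
            self.data[list(indicators)],
            self.treatments,
            self.design,
            {k: self.directions[k] for k in indicators},
        )


class AbundanceTable(_DesignTable):
    """Samples x taxa table; when ``relative`` rows must sum to one."""

    def __init__(
        self,
        data: pd.DataFrame,
        treatments: pd.Series,
        design: TreatmentDesign | None = None,
        relative: bool = True,
    ) -> None:
        super().__init__(data, treatments, design)
        if (self.values < 0).any():
            raise ValidationError("abundances must be non-negative")
        if relative:
            sums = self.values.sum(axis=1)
            off = np.abs(sums - 1.0) > 1e-9
            if off.any():
                bad = [self.sample_ids[i] for i in np.flatnonzero(off)]
                raise ValidationError(f"relative-abundance rows not summing to 1: {bad}")
        self.relative = relative

    @property
    def taxa_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]


def _read_frame(path: str | Path) -> pd.DataFrame:
    # sep=None lets the csv sniffer pick comma vs tab
    frame = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    for col in ("sample_id", "treatment"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: required column {col!r} missing")
    return frame


def _split_meta(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    frame = frame.set_index("sample_id")
    treatments = frame["treatment"].astype(str)
    data = frame.drop(columns=[c for c in _META_COLUMNS if c in frame.columns])
    non_numeric = [
        c for c in data.columns if not np.issubdtype(np.asarray(data[c]).dtype, np.number)
    ]
    if non_numeric:
        for c in non_numeric:
            coerced = pd.to_numeric(data[c], errors="coerce")
            bad = coerced.isna() & data[c].notna()
            if bad.any():
                cells = [(str(i), str(c)) for i in data.index[bad]]
                raise ValidationError(f"non-numeric value(s) at (sample, column): {cells}")
            data[c] = coerced
    return data, treatments


def read_indicator_table(
    path: str | Path,
    design: TreatmentDesign | None = None,
    directions: Mapping[str, str] | None = None,
) -> IndicatorTable:
    """Read a delimited soil-indicator table, validating against ``design``.

    The file must have a header row with ``sample_id`` and ``treatment``
    columns (``replicate`` is accepted and ignored); every remaining column
    is taken as a numeric indicator. Sample order is preserved.
    """
    data, treatments = _split_meta(_read_frame(path))
    return IndicatorTable(data, treatments, design, directions)


def read_abundance_table(
    path: str | Path,
    design: TreatmentDesign | None = None,
    relative: bool = True,
) -> AbundanceTable:
    """Read a delimited samples x taxa abundance table."""
    data, treatments = _split_meta(_read_frame(path))
    return AbundanceTable(data, treatments, design, relative)


def zscore(table: IndicatorTable) -> IndicatorTable:
    """Standardize every indicator to mean 0, sample standard deviation 1.

    Uses the n-1 denominator so that downstream correlation-matrix PCA sees
    exactly unit-variance columns. Raises :class:`DegenerateDataError` for a
    constant indicator.
    """
    sd = table.data.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise DegenerateDataError(f"zero-variance indicator(s): {flat}")
    data = (table.data - table.data.mean()) / sd
    return IndicatorTable(data, table.treatments, table.design, table.directions)
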