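"""Quality filtering and spike-in normalisation of single-cell qRT-PCR Ct tables.

Raw Biomark-style exports report one cycle-threshold (Ct) value per
(cell, assay) reading plus a quality flag.  Two exogenous spike-in RNAs
("spike1", "spike4") are added at a fixed amount per cell and serve as the
per-cell normalisation reference: expression is quantified as

    dCt = geometric_mean(Ct_spike1, Ct_spike4) - Ct_gene

so that *higher dCt means higher expression*.  Values below the detection
floor (default -17 cycles), and genes that were not detected at all, are
assigned the floor value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RawCtTable",
    "ExpressionMatrix",
    "QCReport",
    "SpikeNormalizer",
    "qc_filter",
    "normalize",
    "DEFAULT_FLOOR",
    "SPIKE_ASSAYS",
]

DEFAULT_FLOOR = -17.0
SPIKE_ASSAYS = ("spike1", "spike4")

FLAG_OK = "OK"
FLAG_FAILED = "Failed"
FLAG_INCONSISTENT = "Inconsistent"
VALID_FLAGS = frozenset({FLAG_OK, FLAG_FAILED, FLAG_INCONSISTENT})


@dataclass
class RawCtTable:
    """Wide per-cell Ct readings with per-reading quality flags.

    Parameters
    ----------
    ct : DataFrame, cells x assays
        Ct values in cycles; NaN encodes a non-detected reading.  Assay
        columns include the gene panel plus the two spike channels.
    flags : DataFrame, same shape
        Per-reading quality flag, one of ``OK``, ``Failed``, ``Inconsistent``.
        Missing flags default to ``OK``.
    meta : DataFrame, optional
        Per-cell annotations (time point, condition, fraction, ...),
        indexed like ``ct``.
    """

    ct: pd.DataFrame
    flags: pd.DataFrame | None = None
    meta: pd.DataFrame | None = None
    spike_assays: tuple[str, str] = SPIKE_ASSAYS

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        if self.flags is None:
            self.flags = pd.DataFrame(
                FLAG_OK, index=self.ct.index, columns=self.ct.columns
            )
        self.flags = self.flags.reindex(
            index=self.ct.index, columns=self.ct.columns
        ).fillna(FLAG_OK)
        bad = set(np.unique(self.flags.to_numpy())) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown quality flags: {sorted(bad)}")
        if len(self.spike_assays) != 2:
            raise ValueError(
                "exactly two spike channels are supported; got "
                f"{self.spike_assays!r}"
            )
        missing = [s for s in self.spike_assays if s not in self.ct.columns]
        if missing:
            raise ValueError(f"spike assay columns missing from table: {missing}")
        if (self.ct.to_numpy() <= 0).any():
            raise ValueError("Ct values must be positive cycles when present")
        if self.meta is not None:
            self.meta = self.meta.reindex(self.ct.index)

    @property
    def cells(self) -> pd.Index:
        return self.ct.index

    @property
    def genes(self) -> list[str]:
        return [c for c in self.ct.columns if c not in self.spike_assays]

    def copy(self) -> "RawCtTable":
        return RawCtTable(
            self.ct.copy(),
            self.flags.copy(),
            None if self.meta is None else self.meta.copy(),
            self.spike_assays,
        )


@dataclass
class ExpressionMatrix:
    """Floored dCt expression values (cells x genes) with cell labels."""

    values: pd.DataFrame
    labels: pd.DataFrame | None = None
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if (self.values.to_numpy() < self.floor - 1e-9).any():
            raise ValueError("expression values below the configured floor")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.index)

    @property
    def cells(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    def detected(self) -> pd.DataFrame:
        """Boolean mask of readings strictly above the floor."""
        return self.values > self.floor


@dataclass
class QCReport:
    """Outcome of quality filtering and normalisation."""

    dropped_cells: list[str] = field(default_factory=list)
    masked_readings: list[tuple[str, str, str]] = field(default_factory=list)
    assigned_floor: list[tuple[str, str]] = field(default_factory=list)
    measured_below_floor: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_masked(self) -> int:
        return len(self.masked_readings)

    def to_dict(self) -> dict:
        return {
            "dropped_cells": list(self.dropped_cells),
            "masked_readings": [list(t) for t in self.masked_readings],
            "assigned_floor": [list(t) for t in self.assigned_floor],
            "measured_below_floor": [list(t) for t in self.measured_below_floor],
        }


class SpikeNormalizer(TransformerMixin, BaseEstimator):
    """Quality-filter raw Ct tables and convert them to floored dCt matrices.

    The transform applies, in order:

    1. per-reading QC: ``Failed`` / ``Inconsistent`` readings become missing;
    2. per-cell QC: a cell whose spike1 *or* spike4 reading is missing,
       ``Failed`` or ``Inconsistent`` is dropped entirely;
    3. normalisation: for each retained cell,
       ``dCt = sqrt(Ct_spike1 * Ct_spike4) - Ct_gene``;
    4. flooring: raw dCt below ``floor`` and non-detected genes are assigned
       ``floor``.

    Parameters
    ----------
    floor : float, default -17.0
        Detection floor in dCt cycles.
    spike_assays : pair of str
        Names of the two spike channels; exactly two are required (the
        geometric mean of two values is what the normalisation rule states).

    Attributes
    ----------
    qc_report_ : QCReport
        Dropped cells, masked readings and floor assignments from the most
        recent ``transform``.
    """

    def __init__(
        self,
        floor: float = DEFAULT_FLOOR,
        spike_assays: tuple[str, str] = SPIKE_ASSAYS,
    ) -> None:
        self.floor = floor
        self.spike_assays = spike_assays

    def fit(self, raw: RawCtTable, y=None) -> "SpikeNormalizer":
        if not isinstance(raw, RawCtTable):
            raise TypeError("SpikeNormalizer operates on RawCtTable inputs")
        missing = [s for s in self.spike_assays if s not in raw.ct.columns]
        if missing:
            raise ValueError(f"spike assay columns missing: {missing}")
        self.n_features_in_ = raw.ct.shape[1]
        return self

    def qc_filter(self, raw: RawCtTable) -> RawCtTable:
        """Apply per-reading and per-cell quality filtering."""
        self.fit(raw)
        report = QCReport()
        ct = raw.ct.copy()
        flags = raw.flags.copy()

        bad = flags.isin([FLAG_FAILED, FLAG_INCONSISTENT])
        for cell, gene in zip(*np.nonzero(bad.to_numpy())):
            report.masked_readings.append(
                (str(ct.index[cell]), str(ct.columns[gene]), flags.iat[cell, gene])
            )
        ct = ct.mask(bad)

        spikes = list(self.spike_assays)
        spike_ok = ct[spikes].notna().all(axis=1)
        report.dropped_cells = [str(c) for c in ct.index[~spike_ok]]
        keep = ct.index[spike_ok]

        self.qc_report_ = report
        return RawCtTable(
            ct.loc[keep],
            flags.loc[keep].mask(bad.loc[keep], FLAG_OK),
            None if raw.meta is None else raw.meta.loc[keep],
            tuple(self.spike_assays),
        )

    def transform(self, raw: RawCtTable) -> ExpressionMatrix:
        """QC-filter then normalise; returns the floored dCt matrix."""
        filtered = self.qc_filter(raw)
        report = self.qc_report_

        spikes = filtered.ct[list(self.spike_assays)]
        if (spikes.to_numpy() <= 0).any():
            raise ValueError("non-positive spike Ct: geometric mean undefined")
        geo = np.sqrt(spikes.iloc[:, 0] * spikes.iloc[:, 1])

        genes = filtered.genes
        ct = filtered.ct[genes]
        dct = geo.to_numpy()[:, None] - ct.to_numpy()

        undetected = np.isnan(dct)
        below = ~undetected & (dct < self.floor)
        for i, j in zip(*np.nonzero(undetected)):
            report.assigned_floor.append((str(ct.index[i]), str(genes[j])))
        for i, j in zip(*np.nonzero(below)):
            report.measured_below_floor.append((str(ct.index[i]), str(genes[j])))
        dct[undetected | below] = self.floor

        values = pd.DataFrame(dct, index=ct.index, columns=genes)
        return ExpressionMatrix(values, labels=filtered.meta, floor=self.floor)


def qc_filter(
    raw: RawCtTable, *, return_report: bool = False
) -> RawCtTable | tuple[RawCtTable, QCReport]:
    """Remove Failed/Inconsistent readings and cells with invalid spikes."""
    norm = SpikeNormalizer(spike_assays=raw.spike_assays)
    out = norm.qc_filter(raw)
    if return_report:
        return out, norm.qc_report_
    return out


def normalize(
    raw: RawCtTable,
    floor: float = DEFAULT_FLOOR,
    *,
    return_report: bool = False,
) -> ExpressionMatrix | tuple[ExpressionMatrix, QCReport]:
    """QC-filter and spike-normalise a raw Ct table to a floored dCt matrix."""
    norm = SpikeNormalizer(floor=floor, spike_assays=raw.spike_assays)
    matrix = norm.transform(raw)
    if return_report:
        return matrix, norm.qc_report_
    return matrix
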