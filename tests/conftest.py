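import numpy as np
import pandas as pd
import pytest

from scfate import (
    ExpressionSimConfig,
    MorphologyTrack,
    PedigreeSimConfig,
    RawCtTable,
)
from scfate.lineage import CellRecord, Pedigree


def make_raw_table(rows: dict[str, dict[str, float]], flags=None) -> RawCtTable:
    """Build a tiny RawCtTable from {cell: {assay: ct}} (NaN for missing)."""
    ct = pd.DataFrame(rows).T
    flag_df = None
    if flags:
        flag_df = pd.DataFrame("OK", index=ct.index, columns=ct.columns)
        for (cell, assay), value in flags.items():
            flag_df.loc[cell, assay] = value
    return RawCtTable(ct, flag_df)


def make_track(cell_id, intervals, end_event="division"):
    t_birth = intervals[0][0]
    t_end = intervals[-1][1]
    return MorphologyTrack(cell_id, intervals, t_birth, t_end, end_event)


def make_pedigree(clone_id, records):
    """records: list of (cell_id, parent_id, gen, t_birth, t_end, event, track)."""
    ped = Pedigree(clone_id)
    for cell_id, parent, gen, t0, t1, event, track in records:
        ped.add(CellRecord(cell_id, clone_id, parent, gen, t0, t1, event, track))
    return ped


@pytest.fixture(scope="session")
def two_lineage_matrix():
    """Normalised default two-lineage design: 100 cells per state, 90 genes."""
    from scfate import normalize, simulate_expression

    config = ExpressionSimConfig(seed=42)
    table, truth = simulate_expression(config, {"lineage1": 100, "lineage2": 100})
    return normalize(table), truth


@pytest.fixture(scope="session")
def default_pedigrees():
    """Default pedigree simulation, 450 clones (shared across tests)."""
    from scfate import simulate_pedigrees

    config = PedigreeSimConfig(n_clones=450, seed=11)
    return simulate_pedigrees(config)
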