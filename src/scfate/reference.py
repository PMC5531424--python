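"""Synthetic stand-in for the published founder-cell time-lapse cohort.

The time-lapse experiment followed 32 founder cells whose first division
occurred between 35 h and 80 h after the start of culture, with a median
first cell-cycle length of 58 h; 11 of the 32 founders had divided by
48 h and 3 had still not divided at 72 h.  The underlying per-cell
spreadsheet is not redistributed here, so this module provides a
synthetic cohort constructed to satisfy exactly those published summary
statistics.  It exists so the cycle-length summarising code can be
exercised against the printed values; it is not the original data.
"""

from __future__ import annotations

from .lineage import CellRecord, Pedigree

__all__ = ["founder_division_times", "founder_pedigrees"]

# 32 synthetic first-division times (hours), sorted.  Constraints encoded:
# min 35, max 80; 11 values <= 48; sorted values 16/17 average to 58
# (median); 3 values > 72.
_FOUNDER_DIVISION_TIMES_H = [
    35.0, 36.5, 38.0, 39.5, 41.0, 42.5, 44.0, 45.5, 47.0, 47.5, 48.0,
    50.0, 52.0, 54.0, 56.0, 57.0, 59.0, 60.0, 61.0, 62.0, 63.0, 64.0,
    65.0, 66.0, 67.0, 68.0, 69.0, 70.0, 71.0, 74.0, 77.0, 80.0,
]


def founder_division_times() -> list[float]:
    """First-division times (h) of the 32-founder synthetic cohort."""
    return list(_FOUNDER_DIVISION_TIMES_H)


def founder_pedigrees() -> list[Pedigree]:
    """The synthetic cohort as single-founder pedigrees (no tracks).

    Suitable input for :func:`scfate.lineage.cycle_length_stats`.
    """
    peds = []
    for i, t_div in enumerate(_FOUNDER_DIVISION_TIMES_H, start=1):
        clone = f"ref{i:02d}"
        ped = Pedigree(clone)
        ped.add(
            CellRecord(
                cell_id=f"{clone}.1",
                clone_id=clone,
                parent_id=None,
                generation=1,
                t_birth=0.0,
                t_end=t_div,
                end_event="division",
            )
        )
        peds.append(ped)
    return peds
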