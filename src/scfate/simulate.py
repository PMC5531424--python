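"""Stochastic generators for expression tables and clone pedigrees.

The expression generator samples per-cell dCt vectors from one of five
states (quiescent, multiprimed, lineage1, lineage2, transition), converts
them to raw Ct readings referenced to two simulated spike-in channels, and
returns a Biomark-style wide Ct table.  Module-correlated states share one
standard-normal latent factor per cell, so the population correlation
between two genes of the active module equals ``loading**2``.

The pedigree generator grows clone trees: a long first cell cycle
(truncated log-normal, median 58 h on [35, 80] h), ~21 h later cycles, a
heritable P/S/R dynamic phenotype drawn from a row-stochastic inheritance
matrix at each division, and a two-state continuous-time Markov morphology
path per cell, discretised to the imaging frame interval (1 min), with
right-censoring at the end of observation.

All randomness flows from the config seed through ``numpy`` SeedSequence
spawning, so per-clone streams are independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    EXPRESSION_STATES,
    PHENOTYPES,
    ExpressionSimConfig,
    PedigreeSimConfig,
)
from .lineage import CellRecord, MorphologyTrack, Pedigree
from .qpcr import RawCtTable

__all__ = [
    "GroundTruth",
    "simulate_expression",
    "simulate_pedigrees",
    "simulate_sorted_fractions",
]


@dataclass
class GroundTruth:
    """Generating truth for parameter-recovery tests."""

    cell_states: dict[str, str] = field(default_factory=dict)
    cell_phenotypes: dict[str, str] = field(default_factory=dict)
    inheritance: np.ndarray | None = None
    switch_rates: dict[str, tuple[float, float]] | None = None
    n_failed_readings: int = 0

    def to_dict(self) -> dict:
        return {
            "cell_states": dict(self.cell_states),
            "cell_phenotypes": dict(self.cell_phenotypes),
            "inheritance": None
            if self.inheritance is None
            else np.asarray(self.inheritance).tolist(),
            "switch_rates": None
            if self.switch_rates is None
            else {k: list(v) for k, v in self.switch_rates.items()},
            "n_failed_readings": self.n_failed_readings,
        }


# ---------------------------------------------------------------------------
# expression simulator
# ---------------------------------------------------------------------------


def _state_gene_params(
    config: ExpressionSimConfig, state: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene (detect_prob, mean, sd, loading) arrays for one state."""
    genes = config.genes
    sp = config.state_params[state]
    p = np.empty(len(genes))
    mean = np.empty(len(genes))
    sd = np.empty(len(genes))
    load = np.zeros(len(genes))
    if sp.module is None:
        p[:], mean[:], sd[:] = sp.detect_prob, sp.mean_dct, sp.sd_dct
    else:
        in_module = np.isin(genes, config.gene_modules[sp.module])
        base = config.baseline
        p[:] = np.where(in_module, sp.detect_prob, base.detect_prob)
        mean[:] = np.where(in_module, sp.mean_dct, base.mean_dct)
        sd[:] = np.where(in_module, sp.sd_dct, base.sd_dct)
        load[in_module] = sp.loading
    return p, mean, sd, load


def _sample_cells(
    config: ExpressionSimConfig,
    per_gene: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    n_cells: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (ct_matrix with NaN for undetected, spike Ct pairs)."""
    p, mean, sd, load = per_gene
    n_genes = len(p)
    z = rng.standard_normal(n_cells)  # one latent factor per cell
    eps = rng.standard_normal((n_cells, n_genes))
    resid = np.sqrt(np.clip(1.0 - load**2, 0.0, None))
    dct = mean + sd * (load * z[:, None] + resid * eps)
    detected = rng.random((n_cells, n_genes)) < p
    spikes = config.spike_mean_ct + config.spike_sd * rng.standard_normal((n_cells, 2))
    spikes = np.clip(spikes, 1e-3, None)
    geo = np.sqrt(spikes[:, 0] * spikes[:, 1])
    ct = geo[:, None] - dct
    ct = np.clip(ct, 1e-3, None)
    ct[~detected] = np.nan
    return ct, spikes


def simulate_expression(
    config: ExpressionSimConfig,
    n_cells_per_state: dict[str, int],
    *,
    labels: dict[str, dict] | None = None,
) -> tuple[RawCtTable, GroundTruth]:
    """Generate a raw wide Ct table with spike channels and quality flags.

    Parameters
    ----------
    n_cells_per_state : mapping state name -> number of cells (>= 1).
    labels : optional mapping state -> extra per-cell annotation columns
        (e.g. ``{"lineage1": {"time_point": "48h"}}``) recorded in the
        table's metadata.

    Returns the table plus the generating truth (per-cell state and the
    exact number of readings flagged ``Failed``).
    """
    config.validate()
    for state, n in n_cells_per_state.items():
        if state not in config.state_params:
            raise ValueError(f"unknown expression state {state!r}")
        if n < 1:
            raise ValueError(f"state {state!r}: need at least one cell")

    rng = np.random.default_rng(config.seed)
    genes = config.genes
    blocks, spike_blocks, ids, states = [], [], [], []
    meta_rows = []
    for state in EXPRESSION_STATES:
        if state not in n_cells_per_state:
            continue
        n = n_cells_per_state[state]
        ct, spikes = _sample_cells(config, _state_gene_params(config, state), n, rng)
        blocks.append(ct)
        spike_blocks.append(spikes)
        cell_ids = [f"{state}_{i + 1:04d}" for i in range(n)]
        ids.extend(cell_ids)
        states.extend([state] * n)
        extra = (labels or {}).get(state, {})
        meta_rows.extend({"state": state, **extra} for _ in cell_ids)

    ct = np.vstack(blocks)
    spikes = np.vstack(spike_blocks)
    table = pd.DataFrame(ct, index=pd.Index(ids, name="cell_id"), columns=genes)
    table["spike1"] = spikes[:, 0]
    table["spike4"] = spikes[:, 1]

    flags = pd.DataFrame("OK", index=table.index, columns=table.columns)
    n_failed = 0
    if config.dropout_fail_rate > 0:
        fail = rng.random((len(table), len(genes))) < config.dropout_fail_rate
        n_failed = int(fail.sum())
        gene_flags = flags[genes].to_numpy(dtype=object)
        gene_flags[fail] = "Failed"
        flags.loc[:, genes] = gene_flags

    meta = pd.DataFrame(meta_rows, index=table.index)
    truth = GroundTruth(
        cell_states=dict(zip(ids, states)), n_failed_readings=n_failed
    )
    return RawCtTable(table, flags, meta), truth


def simulate_sorted_fractions(
    config: ExpressionSimConfig,
    fraction: str,
    n_cells: int = 100,
    *,
    mixture_weight: float = 0.2,
) -> tuple[RawCtTable, GroundTruth]:
    """Emulate sorting by a surface marker into high / medium / low gates.

    ``high`` cells are drawn from the lineage1 state, ``low`` from
    lineage2; ``medium`` is an equal mixture of the two plus a
    ``mixture_weight`` fraction of cells with interpolated (intermediate)
    state parameters loading both lineage modules with one shared factor.
    """
    config.validate()
    if fraction == "high":
        return simulate_expression(config, {"lineage1": n_cells})
    if fraction == "low":
        return simulate_expression(config, {"lineage2": n_cells})
    if fraction != "medium":
        raise ValueError(f"unknown fraction label {fraction!r}")

    n_mid = int(round(n_cells * mixture_weight))
    n_side = n_cells - n_mid
    n1 = n_side // 2
    n2 = n_side - n1
    parts: list[RawCtTable] = []
    truth = GroundTruth()
    if n1 or n2:
        tab, tr = simulate_expression(
            config, {k: v for k, v in {"lineage1": n1, "lineage2": n2}.items() if v}
        )
        parts.append(tab)
        truth.cell_states.update(tr.cell_states)
        truth.n_failed_readings += tr.n_failed_readings

    if n_mid:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
        genes = config.genes
        l1 = config.state_params["lineage1"]
        l2 = config.state_params["lineage2"]
        base = config.baseline

        def mid(a: float, b: float) -> float:
            return 0.5 * (a + b)

        p = np.full(len(genes), base.detect_prob)
        mean = np.full(len(genes), base.mean_dct)
        sd = np.full(len(genes), base.sd_dct)
        load = np.zeros(len(genes))
        for sp in (l1, l2):
            mask = np.isin(genes, config.gene_modules[sp.module])
            p[mask] = mid(sp.detect_prob, base.detect_prob)
            mean[mask] = mid(sp.mean_dct, base.mean_dct)
            sd[mask] = sp.sd_dct
            load[mask] = mid(sp.loading, base.loading)
        ct, spikes = _sample_cells(config, (p, mean, sd, load), n_mid, rng)
        ids = [f"intermediate_{i + 1:04d}" for i in range(n_mid)]
        tab = pd.DataFrame(ct, index=pd.Index(ids, name="cell_id"), columns=genes)
        tab["spike1"] = spikes[:, 0]
        tab["spike4"] = spikes[:, 1]
        meta = pd.DataFrame({"state": "intermediate"}, index=tab.index)
        parts.append(RawCtTable(tab, None, meta))
        truth.cell_states.update({i: "intermediate" for i in ids})

    ct = pd.concat([p.ct for p in parts])
    flags = pd.concat([p.flags for p in parts])
    meta = pd.concat([p.meta for p in parts])
    return RawCtTable(ct, flags, meta), truth


# ---------------------------------------------------------------------------
# pedigree simulator
# ---------------------------------------------------------------------------


def _simulate_shape_path(
    rng: np.random.Generator,
    t_birth: float,
    t_end: float,
    rates: tuple[float, float],
    start_shape: str,
    frame_interval: float,
) -> list[tuple[float, float, str]]:
    """Two-state CTMC on [t_birth, t_end], observed at the frame grid.

    Exact jump times are simulated, then the path is sampled at frame
    times (as a time-lapse camera would); excursions shorter than one
    frame are unobservable by construction.
    """
    lam = {"polarised": rates[0], "round": rates[1]}
    other = {"polarised": "round", "round": "polarised"}
    jumps = []
    t, shape = t_birth, start_shape
    while True:
        rate = lam[shape]
        if rate <= 0:
            break
        t = t + rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        jumps.append(t)
        shape = other[shape]

    frames = np.arange(t_birth, t_end, frame_interval)
    if len(frames) == 0 or frames[-1] < t_end:
        frames = np.append(frames, t_end)
    # parity of the jump count before each frame gives the state
    n_before = np.searchsorted(jumps, frames, side="right")
    seq = np.where(n_before % 2 == 0, start_shape, other[start_shape])

    intervals: list[tuple[float, float, str]] = []
    run_start = frames[0]
    for i in range(1, len(frames)):
        if seq[i] != seq[i - 1]:
            intervals.append((run_start, frames[i], seq[i - 1]))
            run_start = frames[i]
    intervals.append((run_start, t_end, seq[-1]))
    # guard against zero-length tail when the last frame == t_end
    intervals = [(a, b, s) for a, b, s in intervals if b > a]
    return intervals


def simulate_pedigrees(
    config: PedigreeSimConfig,
) -> tuple[list[Pedigree], GroundTruth]:
    """Grow clone trees with heritable P/S/R morphology-switching phenotypes.

    Each founder's phenotype is drawn from ``initial_phenotype_dist``; at
    every division the two daughters draw phenotypes from the mother's
    inheritance row (independently, unless ``correlated_sisters`` makes
    them share one draw).  A cell's cycle length comes from the
    generation-appropriate law; cells alive at ``observation_end`` are
    right-censored.  Generation numbering starts at 1 (founders).
    """
    config.validate()
    pheno_idx = {p: i for i, p in enumerate(PHENOTYPES)}
    streams = np.random.SeedSequence(config.seed).spawn(config.n_clones)
    pedigrees: list[Pedigree] = []
    truth = GroundTruth(
        inheritance=config.phenotype_inheritance.copy(),
        switch_rates=dict(config.switch_rates),
    )

    for ci, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        clone_id = f"clone{ci + 1:04d}"
        ped = Pedigree(clone_id)
        founder_ph = rng.choice(PHENOTYPES, p=config.initial_phenotype_dist)
        # (cell_id, parent_id, generation, t_birth, phenotype)
        stack = [(f"{clone_id}.1", None, 1, 0.0, founder_ph)]
        while stack:
            cell_id, parent_id, gen, t_birth, ph = stack.pop()
            law = config.first_cycle_law if gen == 1 else config.later_cycle_law
            cycle = float(law.sample(rng, 1)[0])
            t_div = t_birth + cycle
            if t_div <= config.observation_end:
                t_end, event = t_div, "division"
            else:
                t_end, event = config.observation_end, "censored"
            track = MorphologyTrack(
                cell_id,
                _simulate_shape_path(
                    rng,
                    t_birth,
                    t_end,
                    config.switch_rates[ph],
                    config.initial_shape[ph],
                    config.frame_interval,
                ),
                t_birth,
                t_end,
                event,
            )
            ped.add(
                CellRecord(cell_id, clone_id, parent_id, gen, t_birth, t_end, event, track)
            )
            truth.cell_phenotypes[cell_id] = ph
            if event == "division" and gen < config.max_generations:
                row = config.phenotype_inheritance[pheno_idx[ph]]
                if config.correlated_sisters:
                    d_ph = rng.choice(PHENOTYPES, p=row)
                    daughters = [d_ph, d_ph]
                else:
                    daughters = [rng.choice(PHENOTYPES, p=row) for _ in range(2)]
                for j, dph in enumerate(daughters, start=1):
                    stack.append(
                        (f"{cell_id}.{j}", cell_id, gen + 1, t_end, dph)
                    )
        pedigrees.append(ped)
    return pedigrees, truth
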