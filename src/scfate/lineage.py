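"""Dynamic-phenotype analysis of time-lapse lineage trees.

Every tracked cell carries a :class:`MorphologyTrack` — an ordered sequence
of shape intervals (``round`` / ``polarised``) covering its observed
lifetime from birth to division or censoring.  Three parameters summarise
a cell's dynamic behaviour:

* **roundness** — fraction of the observed lifetime spent round
  (0 = always polarised, 1 = always round);
* **switch frequency** — morphology changes per hour of observation;
* **cycle length** — hours from birth to division (absent if censored).

Cells fall into three dynamic phenotypes: stable-polarised (P),
frequent-switcher (S) and stable-round (R).  This module classifies cells,
estimates the mother→daughter phenotype-inheritance matrix across
pedigrees, compares sister pairs, recovers two-state continuous-time
Markov switching rates, and tabulates cycle lengths per generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .config import PHENOTYPES

__all__ = [
    "MorphologyTrack",
    "CellRecord",
    "Pedigree",
    "CellDynamicsSummary",
    "PhenotypeTransitionMatrix",
    "SisterPairComparison",
    "summarize_cell",
    "summarize_pedigrees",
    "PhenotypeClassifier",
    "classify_phenotypes",
    "transition_frequencies",
    "sister_similarity",
    "SwitchRateEstimator",
    "estimate_switch_rates",
    "cycle_length_stats",
]

SHAPES = ("polarised", "round")


@dataclass
class MorphologyTrack:
    """Ordered shape intervals for one cell from birth to division/censoring.

    Intervals are (t_start, t_stop, shape) in hours, contiguous and
    non-overlapping, covering [birth, end]; consecutive intervals alternate
    shapes after normalisation.
    """

    cell_id: str
    intervals: list[tuple[float, float, str]]
    t_birth: float
    t_end: float
    end_event: str  # 'division' | 'censored'

    def __post_init__(self) -> None:
        if self.end_event not in ("division", "censored"):
            raise ValueError(f"unknown end event {self.end_event!r}")
        if not self.intervals:
            raise ValueError(f"track {self.cell_id}: empty interval list")
        self.intervals = [
            (float(a), float(b), s) for a, b, s in self.intervals
        ]
        for a, b, s in self.intervals:
            if s not in SHAPES:
                raise ValueError(f"track {self.cell_id}: unknown shape {s!r}")
            if b <= a:
                raise ValueError(f"track {self.cell_id}: empty/negative interval")

    def normalized(self, gap_tolerance: float = 1.0 / 60.0) -> "MorphologyTrack":
        """Merge consecutive same-shape intervals and close sub-frame gaps.

        Annotation artefacts (an interval split in two, or a gap shorter
        than one frame) must not inflate the switch count, so tracks are
        normalised before any summary is computed.
        """
        ivs = sorted(self.intervals)
        merged: list[list] = [list(ivs[0])]
        for a, b, s in ivs[1:]:
            prev = merged[-1]
            gap = a - prev[1]
            if gap > gap_tolerance + 1e-12:
                raise ValueError(
                    f"track {self.cell_id}: non-contiguous intervals "
                    f"(gap {gap:.3f} h at t={prev[1]:.3f})"
                )
            if gap > 0:  # close small gap by extending the earlier interval
                prev[1] = a
            if s == prev[2]:
                prev[1] = max(prev[1], b)
            else:
                merged.append([a, b, s])
        if abs(merged[0][0] - self.t_birth) > gap_tolerance + 1e-12 or abs(
            merged[-1][1] - self.t_end
        ) > gap_tolerance + 1e-12:
            raise ValueError(
                f"track {self.cell_id}: intervals do not cover [birth, end]"
            )
        merged[0][0] = self.t_birth
        merged[-1][1] = self.t_end
        return MorphologyTrack(
            self.cell_id,
            [tuple(iv) for iv in merged],
            self.t_birth,
            self.t_end,
            self.end_event,
        )


@dataclass
class CellRecord:
    """One cell of a pedigree: identity, lifetime and its morphology track."""

    cell_id: str
    clone_id: str
    parent_id: str | None
    generation: int
    t_birth: float
    t_end: float
    end_event: str
    track: MorphologyTrack | None = None


@dataclass
class Pedigree:
    """Rooted clone tree of tracked cells with parent links."""

    clone_id: str
    cells: dict[str, CellRecord] = field(default_factory=dict)

    def add(self, cell: CellRecord) -> None:
        self.cells[cell.cell_id] = cell

    @property
    def founder(self) -> CellRecord:
        roots = [c for c in self.cells.values() if c.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"clone {self.clone_id}: expected 1 founder, got {len(roots)}")
        return roots[0]

    def children(self, cell_id: str) -> list[CellRecord]:
        return sorted(
            (c for c in self.cells.values() if c.parent_id == cell_id),
            key=lambda c: c.cell_id,
        )

    def edges(self) -> list[tuple[str, str]]:
        """(mother, daughter) pairs; founders appear only as mothers."""
        out = []
        for c in sorted(self.cells.values(), key=lambda c: c.cell_id):
            if c.parent_id is not None:
                if c.parent_id not in self.cells:
                    raise ValueError(
                        f"clone {self.clone_id}: cell {c.cell_id} has unknown "
                        f"mother {c.parent_id}"
                    )
                out.append((c.parent_id, c.cell_id))
        return out

    def sister_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        by_parent: dict[str, list[str]] = {}
        for c in sorted(self.cells.values(), key=lambda c: c.cell_id):
            if c.parent_id is not None:
                by_parent.setdefault(c.parent_id, []).append(c.cell_id)
        for sibs in by_parent.values():
            if len(sibs) == 2:
                pairs.append((sibs[0], sibs[1]))
        return pairs


@dataclass
class CellDynamicsSummary:
    """(roundness, switch frequency, cycle length, generation) for one cell."""

    cell_id: str
    clone_id: str
    generation: int
    roundness: float
    switch_freq: float
    cycle_length: float | None
    censored: bool


def summarize_cell(
    track: MorphologyTrack,
    *,
    clone_id: str = "",
    generation: int = 0,
    trim_first_hours: float = 0.0,
) -> CellDynamicsSummary:
    """Compute the three dynamic parameters for one track.

    ``trim_first_hours`` optionally discards the start of the track
    (founder cells recover from isolation stress during their first hours);
    default 0 (off).
    """
    t = track.normalized()
    t0 = t.t_birth + trim_first_hours
    time_in = {"round": 0.0, "polarised": 0.0}
    switches = 0
    prev_shape = None
    for a, b, s in t.intervals:
        a, b = max(a, t0), b
        if b <= t0:
            continue
        time_in[s] += b - a
        if prev_shape is not None and s != prev_shape:
            switches += 1
        prev_shape = s
    observed = time_in["round"] + time_in["polarised"]
    if observed <= 0:
        raise ValueError(f"track {track.cell_id}: no observed time after trimming")
    return CellDynamicsSummary(
        cell_id=track.cell_id,
        clone_id=clone_id,
        generation=generation,
        roundness=time_in["round"] / observed,
        switch_freq=switches / observed,
        cycle_length=(t.t_end - t.t_birth) if t.end_event == "division" else None,
        censored=t.end_event == "censored",
    )


def summarize_pedigrees(
    pedigrees: list[Pedigree], *, trim_founder_hours: float = 0.0
) -> pd.DataFrame:
    """Per-cell dynamics table over a list of pedigrees.

    Columns: clone_id, cell_id, generation, roundness, switch_freq,
    cycle_length (NaN if censored), censored.
    """
    rows = []
    for ped in pedigrees:
        for cell in sorted(ped.cells.values(), key=lambda c: c.cell_id):
            if cell.track is None:
                continue
            trim = trim_founder_hours if cell.generation == 1 else 0.0
            s = summarize_cell(
                cell.track,
                clone_id=ped.clone_id,
                generation=cell.generation,
                trim_first_hours=trim,
            )
            rows.append(
                {
                    "clone_id": s.clone_id,
                    "cell_id": s.cell_id,
                    "generation": s.generation,
                    "roundness": s.roundness,
                    "switch_freq": s.switch_freq,
                    "cycle_length": np.nan if s.cycle_length is None else s.cycle_length,
                    "censored": s.censored,
                }
            )
    return pd.DataFrame(rows).set_index("cell_id") if rows else pd.DataFrame(
        columns=[
            "clone_id",
            "generation",
            "roundness",
            "switch_freq",
            "cycle_length",
            "censored",
        ]
    )


class PhenotypeClassifier(BaseEstimator):
    """Assign dynamic phenotypes P / S / R from per-cell summaries.

    ``method='kmeans3'`` (default) runs k-means with k=3 on standardized
    features and maps clusters to labels by centroid rules: the cluster
    with the highest mean switch frequency is S; of the remaining two, the
    lower-roundness one is P and the higher is R.  Because the R category
    denotes morphological *stability*, cells swept into the R cluster
    despite switching more often than ``switch_cutoff`` are relabelled S.
    ``method='thresholds'`` applies fixed cutoffs instead.

    Parameters
    ----------
    method : {'kmeans3', 'thresholds'}
    features : tuple of str
        Clustering features; default (roundness, switch_freq).  Cycle
        length may be added for a 3-feature mode.
    switch_cutoff, roundness_cutoff : float
        Cutoffs for the threshold mode: cells with switch_freq above
        ``switch_cutoff`` are S; otherwise roundness above
        ``roundness_cutoff`` marks R, below marks P.
    """

    def __init__(
        self,
        method: str = "kmeans3",
        features: tuple[str, ...] = ("roundness", "switch_freq"),
        switch_cutoff: float = 0.12,
        roundness_cutoff: float = 0.5,
        random_state: int | None = 0,
    ) -> None:
        self.method = method
        self.features = features
        self.switch_cutoff = switch_cutoff
        self.roundness_cutoff = roundness_cutoff
        self.random_state = random_state

    def fit_predict(self, summaries: pd.DataFrame, y=None) -> pd.Series:
        X = summaries.loc[:, list(self.features)].astype(float)
        if X.isna().any().any():
            raise ValueError("summaries contain NaN in clustering features")
        if self.method == "thresholds":
            labels = np.where(
                X["switch_freq"] > self.switch_cutoff,
                "S",
                np.where(X["roundness"] > self.roundness_cutoff, "R", "P"),
            )
            self.labels_ = pd.Series(labels, index=summaries.index, name="phenotype")
            return self.labels_
        if self.method != "kmeans3":
            raise ValueError(f"unknown method {self.method!r}")
        if len(X) < 6:
            raise ValueError("need at least 6 cells for k-means phenotyping")
        scale = X.std(ddof=0)
        if (scale < 1e-12).all():
            raise ValueError(
                "degenerate input: all cells identical in the clustering "
                "features; classification refused"
            )
        Z = (X - X.mean()) / scale.replace(0.0, 1.0)
        km = KMeans(n_clusters=3, n_init=25, random_state=self.random_state)
        cluster = km.fit_predict(Z.to_numpy())
        cent = (
            X.assign(_c=cluster).groupby("_c")[list(self.features)].mean()
        )
        s_cluster = cent["switch_freq"].idxmax()
        rest = cent.drop(index=s_cluster)
        p_cluster = rest["roundness"].idxmin()
        r_cluster = rest["roundness"].idxmax()
        mapping = {s_cluster: "S", p_cluster: "P", r_cluster: "R"}
        self.cluster_centers_ = cent
        labels = pd.Series(
            [mapping[c] for c in cluster], index=summaries.index, name="phenotype"
        )
        unstable = (labels == "R") & (X["switch_freq"] > self.switch_cutoff)
        labels[unstable] = "S"
        self.labels_ = labels
        return self.labels_


def classify_phenotypes(
    summaries: pd.DataFrame,
    method: str = "kmeans3",
    seed: int | None = 0,
    **kwargs,
) -> pd.Series:
    """Label each cell P, S or R from its dynamics summary row."""
    clf = PhenotypeClassifier(method=method, random_state=seed, **kwargs)
    return clf.fit_predict(summaries)


@dataclass
class PhenotypeTransitionMatrix:
    """Mother→daughter phenotype counts and row-normalised frequencies."""

    counts: pd.DataFrame
    frequencies: pd.DataFrame
    no_data_rows: list[str]

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.to_dict(),
            "frequencies": self.frequencies.to_dict(),
            "no_data_rows": list(self.no_data_rows),
        }


def transition_frequencies(
    pedigrees: list[Pedigree], labels: pd.Series | dict
) -> PhenotypeTransitionMatrix:
    """Estimate the phenotype-inheritance matrix from labelled pedigrees.

    Counts every mother→daughter edge whose two ends are labelled;
    founders enter only as mothers.  Rows with no observed edges are
    flagged ``no_data`` and left as NaN in the frequency table.
    """
    labels = pd.Series(labels)
    counts = pd.DataFrame(0, index=list(PHENOTYPES), columns=list(PHENOTYPES))
    for ped in pedigrees:
        for mother, daughter in ped.edges():
            if mother in labels.index and daughter in labels.index:
                counts.loc[labels[mother], labels[daughter]] += 1
    row_sums = counts.sum(axis=1)
    freqs = counts.div(row_sums.replace(0, np.nan), axis=0)
    no_data = [str(r) for r in counts.index[row_sums == 0]]
    return PhenotypeTransitionMatrix(counts, freqs, no_data)


@dataclass
class SisterPairComparison:
    """Distance between two sisters in standardized dynamics space."""

    pair_id: str
    cell_a: str
    cell_b: str
    distance: float
    cls: str  # 'similar' | 'divergent'


def sister_similarity(
    pedigrees: list[Pedigree],
    summaries: pd.DataFrame,
    seed: int | None = 0,
    *,
    standardize: bool = True,
) -> pd.DataFrame:
    """Split complete sister pairs into similar vs divergent dynamics.

    Cycle length, roundness and switch frequency are z-scored over all
    cells entering the comparison (cycle length in hours would otherwise
    dominate the two dimensionless parameters), the Euclidean distance is
    computed per pair, and k-means with k=2 on the distances labels the
    lower-centroid group ``similar``.  Pairs with a censored cycle length
    are excluded with a warning.
    """
    pairs = []
    for ped in pedigrees:
        for a, b in ped.sister_pairs():
            if a in summaries.index and b in summaries.index:
                pairs.append((ped.clone_id, a, b))
    feats = ["cycle_length", "roundness", "switch_freq"]
    complete, skipped = [], 0
    for clone, a, b in pairs:
        if summaries.loc[[a, b], "cycle_length"].isna().any():
            skipped += 1
            continue
        complete.append((clone, a, b))
    if skipped:
        warnings.warn(
            f"excluded {skipped} sister pair(s) with censored cycle length",
            stacklevel=2,
        )
    if len(complete) < 4:
        raise ValueError("need at least 4 complete sister pairs")
    used_cells = sorted({c for _, a, b in complete for c in (a, b)})
    X = summaries.loc[used_cells, feats].astype(float)
    if standardize:
        sd = X.std(ddof=0).replace(0.0, 1.0)
        X = (X - X.mean()) / sd
    dist = np.array(
        [np.linalg.norm(X.loc[a] - X.loc[b]) for _, a, b in complete]
    )
    km = KMeans(n_clusters=2, n_init=25, random_state=seed)
    grp = km.fit_predict(dist.reshape(-1, 1))
    similar_grp = int(np.argmin(km.cluster_centers_.ravel()))
    rows = [
        {
            "pair_id": f"{clone}:{a}|{b}",
            "clone_id": clone,
            "cell_a": a,
            "cell_b": b,
            "distance": d,
            "class": "similar" if g == similar_grp else "divergent",
        }
        for (clone, a, b), d, g in zip(complete, dist, grp)
    ]
    return pd.DataFrame(rows).set_index("pair_id")


class SwitchRateEstimator(BaseEstimator):
    """Maximum-likelihood two-state CTMC switching rates from tracks.

    For continuously observed interval data the MLE of each exit rate is
    (number of transitions out of a shape) / (total time spent in it), with
    standard error rate / sqrt(count).

    Attributes
    ----------
    rates_ : DataFrame indexed by group label with columns
        rate_PR (polarised→round, per h), rate_RP, se_PR, se_RP,
        n_PR, n_RP, time_polarised, time_round.  A direction with zero
        observed time in the source shape is reported as NaN (undefined).
    """

    def fit(self, tracks_by_group: dict[str, list[MorphologyTrack]]) -> "SwitchRateEstimator":
        rows = {}
        for label, tracks in tracks_by_group.items():
            if not tracks:
                raise ValueError(f"group {label!r}: no tracks")
            time_in = {"polarised": 0.0, "round": 0.0}
            n_out = {"polarised": 0, "round": 0}
            for tr in tracks:
                t = tr.normalized()
                for i, (a, b, s) in enumerate(t.intervals):
                    time_in[s] += b - a
                    if i + 1 < len(t.intervals):
                        n_out[s] += 1
            row = {}
            for src, key in (("polarised", "PR"), ("round", "RP")):
                if time_in[src] > 0:
                    rate = n_out[src] / time_in[src]
                    se = rate / np.sqrt(n_out[src]) if n_out[src] > 0 else 0.0
                else:
                    rate, se = np.nan, np.nan
                row[f"rate_{key}"] = rate
                row[f"se_{key}"] = se
                row[f"n_{key}"] = n_out[src]
            row["time_polarised"] = time_in["polarised"]
            row["time_round"] = time_in["round"]
            rows[label] = row
        self.rates_ = pd.DataFrame(rows).T
        return self


def estimate_switch_rates(
    tracks_by_group: dict[str, list[MorphologyTrack]],
) -> pd.DataFrame:
    """Per-group (λ_PR, λ_RP) MLEs with standard errors; see the estimator."""
    return SwitchRateEstimator().fit(tracks_by_group).rates_


def cycle_length_stats(pedigrees: list[Pedigree]) -> pd.DataFrame:
    """Per-generation cycle-length table (uncensored cells only).

    Columns: n, median, mean, min, q1, q3, max — the box-plot summary of
    cycle length per generation.
    """
    rows = []
    for ped in pedigrees:
        for cell in ped.cells.values():
            if cell.end_event == "division":
                rows.append(
                    {"generation": cell.generation, "cycle": cell.t_end - cell.t_birth}
                )
    if not rows:
        warnings.warn("all cells censored: empty cycle-length table", stacklevel=2)
        return pd.DataFrame(
            columns=["n", "median", "mean", "min", "q1", "q3", "max"]
        ).rename_axis("generation")
    df = pd.DataFrame(rows)
    g = df.groupby("generation")["cycle"]
    out = pd.DataFrame(
        {
            "n": g.size(),
            "median": g.median(),
            "mean": g.mean(),
            "min": g.min(),
            "q1": g.quantile(0.25),
            "q3": g.quantile(0.75),
            "max": g.max(),
        }
    )
    return out
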