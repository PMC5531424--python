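"""Configuration objects for the synthetic-data generators.

Two generators are configured here:

* :class:`ExpressionSimConfig` — single-cell qRT-PCR panels (default 90
  genes) sampled from one of five expression states: a *quiescent* sparse
  state, an uncorrelated *multiprimed* state (promiscuous, uncoordinated
  up-regulation), two module-correlated *lineage-primed* states, and a
  *transition* state with a transiently elevated gene–gene correlation.
* :class:`PedigreeSimConfig` — clonal pedigrees with a long first cell
  cycle (median 58 h, clipped to 35–80 h), ~21 h later cycles, and
  heritable morphology-switching phenotypes P/S/R (stable-polarised,
  frequent-switcher, stable-round) with round→round closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateParams",
    "ExpressionSimConfig",
    "CycleLaw",
    "PedigreeSimConfig",
    "PHENOTYPES",
    "EXPRESSION_STATES",
    "default_gene_modules",
]

PHENOTYPES = ("P", "S", "R")
EXPRESSION_STATES = ("quiescent", "multiprimed", "lineage1", "lineage2", "transition")

MODULE_NAMES = ("stem", "lineage1", "lineage2", "background")


def default_gene_modules(n_genes: int = 90) -> dict[str, list[str]]:
    """Partition ``n_genes`` into stem / lineage1 / lineage2 / background.

    Defaults to 10 stem genes, 15 per lineage module and the remainder as
    background, mirroring a hematopoietic panel in which a minority of
    assays are informative lineage regulators and the rest report overall
    transcriptional activity.
    """
    if n_genes < 8:
        raise ValueError("need at least 8 genes to form four modules")
    n_stem = max(2, round(n_genes * 10 / 90))
    n_lin = max(2, round(n_genes * 15 / 90))
    if n_stem + 2 * n_lin >= n_genes:
        n_stem, n_lin = 2, max(2, (n_genes - 3) // 3)
    sizes = {
        "stem": n_stem,
        "lineage1": n_lin,
        "lineage2": n_lin,
        "background": n_genes - n_stem - 2 * n_lin,
    }
    modules: dict[str, list[str]] = {}
    for name, size in sizes.items():
        prefix = {"stem": "STEM", "lineage1": "LIN1", "lineage2": "LIN2",
                  "background": "BG"}[name]
        modules[name] = [f"{prefix}{i + 1:02d}" for i in range(size)]
    return modules


@dataclass
class StateParams:
    """Per-state sampling law for dCt values.

    For a gene inside the state's active ``module`` the detected dCt is

        mean_dct + sd_dct * (loading * z_cell + sqrt(1 - loading^2) * eps)

    with one shared standard-normal latent factor ``z_cell`` per cell, so
    the population correlation between two module genes is ``loading**2``.
    Genes outside the module (or all genes, for states with ``module=None``)
    have loading 0 and are mutually independent.
    """

    detect_prob: float
    mean_dct: float
    sd_dct: float
    loading: float = 0.0
    module: str | None = None

    def validate(self, name: str, modules: dict[str, list[str]]) -> None:
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ValueError(f"{name}: detect_prob must be in [0, 1]")
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError(f"{name}: loading must be in [0, 1]")
        if self.sd_dct < 0:
            raise ValueError(f"{name}: sd_dct must be >= 0")
        if self.module is not None and self.module not in modules:
            raise ValueError(f"{name}: unknown module {self.module!r}")
        if self.module is None and self.loading > 0:
            raise ValueError(
                f"{name}: states without an active module are uncorrelated "
                "by construction and must have loading 0"
            )


def _default_state_params() -> dict[str, StateParams]:
    return {
        # sparse, low-level transcription; no coordination
        "quiescent": StateParams(0.15, -10.0, 2.0, 0.0, None),
        # promiscuous uncoordinated up-regulation across the whole panel
        "multiprimed": StateParams(0.70, -4.0, 3.0, 0.0, None),
        # two lineage-primed patterns: one strongly expressed, correlated
        # module.  Detection is 1.0 for the active module: strongly
        # expressed transcripts are essentially always detected, and a
        # single floor-valued dropout would otherwise dominate Pearson r.
        "lineage1": StateParams(1.0, 2.0, 2.0, 0.80, "lineage1"),
        "lineage2": StateParams(1.0, 2.0, 2.0, 0.80, "lineage2"),
        # pre-transition burst: same module as lineage1, stronger coupling
        "transition": StateParams(1.0, 2.0, 2.0, 0.95, "lineage1"),
    }


@dataclass
class ExpressionSimConfig:
    """Parameters of the single-cell qRT-PCR expression simulator."""

    n_genes: int = 90
    gene_modules: dict[str, list[str]] | None = None
    state_params: dict[str, StateParams] = field(default_factory=_default_state_params)
    #: law for genes outside a module-state's active module
    baseline: StateParams = field(
        default_factory=lambda: StateParams(0.30, -8.0, 2.0, 0.0, None)
    )
    spike_mean_ct: float = 13.5
    spike_sd: float = 0.25
    dropout_fail_rate: float = 0.02
    floor: float = -17.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_modules is None:
            self.gene_modules = default_gene_modules(self.n_genes)
        self.validate()

    def validate(self) -> None:
        all_genes = [g for genes in self.gene_modules.values() for g in genes]
        if len(all_genes) != len(set(all_genes)):
            raise ValueError("gene modules overlap: partition must be disjoint")
        if len(all_genes) != self.n_genes:
            raise ValueError(
                f"module partition covers {len(all_genes)} genes, "
                f"expected n_genes={self.n_genes}"
            )
        if not 0.0 <= self.dropout_fail_rate <= 1.0:
            raise ValueError("dropout_fail_rate must be in [0, 1]")
        if self.spike_mean_ct <= 0 or self.spike_sd < 0:
            raise ValueError("spike parameters must be positive")
        for name, params in self.state_params.items():
            params.validate(name, self.gene_modules)
        self.baseline.validate("baseline", self.gene_modules)

    @property
    def genes(self) -> list[str]:
        return [g for genes in self.gene_modules.values() for g in genes]


@dataclass
class CycleLaw:
    """Distribution spec for a cell-cycle length, in hours.

    ``kind='lognormal'`` is parameterised by its median and log-scale sigma,
    truncated to [minimum, maximum]; ``kind='normal'`` by mean and sd,
    truncated below at ``minimum``.
    """

    kind: str
    median: float | None = None
    sigma_log: float | None = None
    mean: float | None = None
    sd: float | None = None
    minimum: float = 0.0
    maximum: float = np.inf

    def validate(self) -> None:
        if self.kind == "lognormal":
            if self.median is None or self.sigma_log is None:
                raise ValueError("lognormal law needs median and sigma_log")
            if not self.minimum <= self.median <= self.maximum:
                raise ValueError("cycle law must satisfy min <= median <= max")
        elif self.kind == "normal":
            if self.mean is None or self.sd is None:
                raise ValueError("normal law needs mean and sd")
        else:
            raise ValueError(f"unknown cycle-law kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Truncated sampling by rejection (acceptance region is wide)."""
        out = np.empty(size)
        filled = 0
        while filled < size:
            m = size - filled
            if self.kind == "lognormal":
                draw = self.median * np.exp(self.sigma_log * rng.standard_normal(2 * m + 8))
            else:
                draw = self.mean + self.sd * rng.standard_normal(2 * m + 8)
            draw = draw[(draw >= self.minimum) & (draw <= self.maximum)][:m]
            out[filled : filled + len(draw)] = draw
            filled += len(draw)
        return out


def _default_inheritance() -> np.ndarray:
    # rows: mother P, S, R; cols: daughter P, S, R.
    # S->S = 0.25 (a quarter of switcher daughters conserve the phenotype)
    # and the absorbing R row encode the two empirically printed constraints;
    # the remaining entries are free defaults, overridable in config.
    return np.array(
        [
            [0.60, 0.25, 0.15],
            [0.00, 0.25, 0.75],
            [0.00, 0.00, 1.00],
        ]
    )


@dataclass
class PedigreeSimConfig:
    """Parameters of the clonal-pedigree / morphology-switching simulator."""

    n_clones: int = 32
    max_generations: int = 3
    first_cycle_law: CycleLaw = field(
        default_factory=lambda: CycleLaw(
            "lognormal", median=58.0, sigma_log=0.16, minimum=35.0, maximum=80.0
        )
    )
    later_cycle_law: CycleLaw = field(
        default_factory=lambda: CycleLaw("normal", mean=21.0, sd=2.0, minimum=8.0)
    )
    phenotype_inheritance: np.ndarray = field(default_factory=_default_inheritance)
    #: per-phenotype (rate polarised->round, rate round->polarised), per hour.
    #: Defaults reproduce the three archetypes: P ~ 0.02 roundness and 0.02
    #: switches/h, S ~ 0.5 and 0.5 (rapid switching, no stable intermediate),
    #: R absorbing round.
    switch_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "P": (0.01, 0.50),
            "S": (0.50, 0.50),
            "R": (0.00, 0.00),
        }
    )
    initial_phenotype_dist: tuple[float, float, float] = (0.85, 0.10, 0.05)
    #: initial morphology per phenotype at birth
    initial_shape: dict[str, str] = field(
        default_factory=lambda: {"P": "polarised", "S": "polarised", "R": "round"}
    )
    observation_end: float = 168.0
    frame_interval: float = 1.0 / 60.0
    correlated_sisters: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.phenotype_inheritance = np.asarray(self.phenotype_inheritance, float)
        self.validate()

    def validate(self) -> None:
        M = self.phenotype_inheritance
        if M.shape != (3, 3):
            raise ValueError("phenotype_inheritance must be 3x3 over (P, S, R)")
        if (M < 0).any() or not np.allclose(M.sum(axis=1), 1.0):
            raise ValueError("phenotype_inheritance rows must be stochastic")
        for label, (a, b) in self.switch_rates.items():
            if label not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {label!r}")
            if a < 0 or b < 0:
                raise ValueError("switch rates must be >= 0")
        if not np.isclose(sum(self.initial_phenotype_dist), 1.0):
            raise ValueError("initial_phenotype_dist must sum to 1")
        if self.frame_interval <= 0 or self.observation_end <= 0:
            raise ValueError("frame_interval and observation_end must be > 0")
        self.first_cycle_law.validate()
        self.later_cycle_law.validate()
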