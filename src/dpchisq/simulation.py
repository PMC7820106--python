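"""Multinomial table generation and significance / power experiments.

An experiment draws contingency tables from a multinomial over the I*J
cells, runs one or more mechanisms on every table, and reports the
fraction of correct decisions: under an independence-factorizing cell
distribution (truth = null) a correct decision is "fail to reject", so
``1 - correct_rate`` is the empirical type-I error; under an associated
distribution (truth = alternative) a correct decision is "reject" and
``correct_rate`` is the empirical power.

Design choices that mirror the study conditions: sample sizes default to
{100, 300, 500, 700, 900}, replicates to 1000 per grid point, and all
mechanisms are run on the *same* table within a replicate (a paired design
that removes table-to-table variance from mechanism comparisons).  Tables
with a zero row or column margin are resampled so every replicate is
testable; the resample count is reported rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .mechanisms import (
    TestOutcome,
    mc_indep,
    non_private_test,
    rand_chi,
    rand_chi_dist,
    rand_cell,
)
from .tables import ContingencyTable, build_table, min_cell_ok

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "MECHANISM_NAMES",
    "sample_multinomial_table",
    "effect_probs",
    "correlated_pair_probs",
    "run_experiment",
]

# Canonical order fixes each mechanism's noise substream, so the table
# sequence and every mechanism's noise are invariant to which subset of
# mechanisms a run requests.
MECHANISM_NAMES = ("nonprivate", "randchi", "randcell", "mcindep", "randchidist")

DEFAULT_SAMPLE_SIZES = (100, 300, 500, 700, 900)


def _probs_ok(cell_probs: np.ndarray) -> np.ndarray:
    arr = np.asarray(cell_probs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ConfigError("cell_probs must be a matrix with at least 2 rows and columns")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ConfigError("cell_probs entries must lie in [0, 1]")
    if abs(arr.sum() - 1.0) > 1e-12:
        raise ConfigError(f"cell_probs must sum to 1, got {arr.sum()!r}")
    return arr


def _factorizes(cell_probs: np.ndarray, tol: float = 1e-12) -> bool:
    rm = cell_probs.sum(axis=1)
    cm = cell_probs.sum(axis=0)
    return bool(np.max(np.abs(cell_probs - np.outer(rm, cm))) <= tol)


@dataclass
class SimulationConfig:
    """Declarative description of one significance or power experiment.

    ``truth`` is derived from whether ``cell_probs`` factorizes into the
    outer product of its margins; supplying a contradicting label is a
    configuration error, which catches mislabeled designs (e.g. a zero
    effect size declared as an alternative).
    """

    cell_probs: np.ndarray
    alpha: float
    epsilon: float
    mechanisms: tuple[str, ...]
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    replicates: int = 1000
    master_seed: int = 0
    min_cell_filter: bool = False
    truth: str = field(default="")
    n_mc_tables: int | None = None

    def __post_init__(self):
        self.cell_probs = _probs_ok(self.cell_probs)
        derived = "null" if _factorizes(self.cell_probs) else "alternative"
        if self.truth and self.truth != derived:
            raise ConfigError(
                f"declared truth={self.truth!r} but cell_probs imply {derived!r}"
            )
        self.truth = derived
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.epsilon > 0:
            raise ConfigError(f"epsilon must be > 0, got {self.epsilon}")
        self.mechanisms = tuple(self.mechanisms)
        if not self.mechanisms:
            raise ConfigError("mechanisms must be non-empty")
        for name in self.mechanisms:
            if name not in MECHANISM_NAMES:
                raise ConfigError(
                    f"unknown mechanism {name!r}; choose from {MECHANISM_NAMES}"
                )
        self.sample_sizes = tuple(int(n) for n in self.sample_sizes)
        if any(n < 1 for n in self.sample_sizes):
            raise ConfigError("sample sizes must be positive")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_probs.shape

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        known = {
            "cell_probs",
            "alpha",
            "epsilon",
            "mechanisms",
            "sample_sizes",
            "replicates",
            "master_seed",
            "min_cell_filter",
            "truth",
            "n_mc_tables",
        }
        required = {"cell_probs", "alpha", "epsilon", "mechanisms"}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        missing = required - raw.keys()
        if missing:
            raise ConfigError(f"missing config fields: {sorted(missing)}")
        unknown = raw.keys() - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**{k: raw[k] for k in raw})


@dataclass
class SimulationSummary:
    """Per-(mechanism, n) empirical rates with Monte Carlo standard errors."""

    table: pd.DataFrame
    config: SimulationConfig

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def rate(self, mechanism: str, n: int) -> float:
        row = self.table[
            (self.table.mechanism == mechanism) & (self.table.n == n)
        ]
        return float(row.correct_rate.iloc[0])


def sample_multinomial_table(
    cell_probs,
    n: int,
    rng: np.random.Generator,
    *,
    max_resamples: int = 10_000,
    return_resamples: bool = False,
):
    """One Multinomial(n, cell_probs) table, conditioned on positive margins.

    Tables with a zero row or column total (where the chi-squared statistic
    is undefined) are redrawn; the redraw count is available via
    ``return_resamples``.
    """
    probs = _probs_ok(cell_probs)
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    shape = probs.shape
    flat = probs.ravel()
    for attempt in range(max_resamples + 1):
        counts = rng.multinomial(n, flat).reshape(shape)
        if counts.sum(axis=1).min() > 0 and counts.sum(axis=0).min() > 0:
            table = build_table(counts)
            return (table, attempt) if return_resamples else table
    raise ConfigError(
        f"exceeded {max_resamples} resamples for n={n}; design is degenerate"
    )


def effect_probs(base, delta: float, pattern) -> np.ndarray:
    """Additively perturbed cell probabilities ``base + delta * pattern``.

    ``pattern`` entries must be in {-1, 0, +1} and sum to zero so the total
    probability is preserved; the result must stay inside [0, 1].
    """
    base = _probs_ok(base)
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != base.shape:
        raise ConfigError(
            f"pattern shape {pattern.shape} != base shape {base.shape}"
        )
    if not np.all(np.isin(pattern, (-1.0, 0.0, 1.0))):
        raise ConfigError("pattern entries must be -1, 0 or +1")
    if pattern.sum() != 0:
        raise ConfigError("pattern must sum to zero to preserve total probability")
    out = base + float(delta) * pattern
    if np.any(out < -1e-15) or np.any(out > 1 + 1e-15):
        raise ConfigError("perturbed probabilities leave [0, 1]")
    return np.clip(out, 0.0, 1.0)


def correlated_pair_probs(row_marginal, col_marginal, mixing: float) -> np.ndarray:
    """Synthetic correlated-pair cell probabilities.

    A stand-in for two-locus association tables: a ``mixing``-weighted
    blend of the independence outer product and a diagonal (same-category)
    coupling.  ``mixing = 0`` gives exact independence; larger values give
    strictly positive chi-squared noncentrality.
    """
    row = np.asarray(row_marginal, dtype=float)
    col = np.asarray(col_marginal, dtype=float)
    for name, v in (("row_marginal", row), ("col_marginal", col)):
        if v.ndim != 1 or v.size < 2 or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-12:
            raise ConfigError(f"{name} must be a probability vector of length >= 2")
    if not 0.0 <= mixing <= 1.0:
        raise ConfigError(f"mixing must be in [0, 1], got {mixing}")
    if mixing > 0 and row.size != col.size:
        raise ConfigError("diagonal association requires equal row/column counts")
    probs = (1.0 - mixing) * np.outer(row, col)
    if mixing > 0:
        probs[np.diag_indices(row.size)] += mixing * row
    return probs / probs.sum()


def _run_mechanism(
    name: str,
    table: ContingencyTable,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TestOutcome:
    if name == "nonprivate":
        return non_private_test(table, config.alpha)
    if name == "randchi":
        return rand_chi(table, config.epsilon, config.alpha, rng)
    if name == "randcell":
        return rand_cell(table, config.epsilon, config.alpha, rng)
    if name == "mcindep":
        return mc_indep(
            table, config.epsilon, config.alpha, rng, n_mc_tables=config.n_mc_tables
        )
    if name == "randchidist":
        return rand_chi_dist(table, config.epsilon, config.alpha, rng)
    raise ConfigError(f"unknown mechanism {name!r}")


def _table_stream_rng(master_seed: int, n_index: int, replicate: int):
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, n_index, replicate, 0])
    )


def _mechanism_rng(master_seed: int, n_index: int, replicate: int, name: str):
    stream = 1 + MECHANISM_NAMES.index(name)
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, n_index, replicate, stream])
    )


def run_experiment(config: SimulationConfig) -> SimulationSummary:
    """Run the full (mechanism x sample size x replicate) grid.

    Within a replicate every mechanism sees the same table but draws its
    noise from its own fixed substream, so results are deterministic given
    ``master_seed`` and unchanged by adding or removing other mechanisms
    from the run.  Mechanism failures are counted per cell, never silently
    dropped.
    """
    records = []
    want_reject = config.truth == "alternative"
    for n_index, n in enumerate(config.sample_sizes):
        rejects = {m: 0 for m in config.mechanisms}
        failures = {m: 0 for m in config.mechanisms}
        resamples = 0
        for rep in range(config.replicates):
            trng = _table_stream_rng(config.master_seed, n_index, rep)
            table, redraws = sample_multinomial_table(
                config.cell_probs, n, trng, return_resamples=True
            )
            resamples += redraws
            if config.min_cell_filter:
                while not min_cell_ok(table.counts):
                    table, redraws = sample_multinomial_table(
                        config.cell_probs, n, trng, return_resamples=True
                    )
                    resamples += redraws + 1
            for name in config.mechanisms:
                mrng = _mechanism_rng(config.master_seed, n_index, rep, name)
                try:
                    outcome = _run_mechanism(name, table, config, mrng)
                except Exception:
                    failures[name] += 1
                    continue
                if outcome.rejected:
                    rejects[name] += 1
        for name in config.mechanisms:
            n_ok = config.replicates - failures[name]
            reject_count = rejects[name]
            correct = (reject_count if want_reject else n_ok - reject_count)
            rate = correct / config.replicates
            records.append(
                {
                    "mechanism": name,
                    "n": n,
                    "correct_rate": rate,
                    "mc_standard_error": sqrt(rate * (1.0 - rate) / config.replicates),
                    "reject_count": reject_count,
                    "replicate_count": config.replicates,
                    "failures": failures[name],
                    "resamples": resamples,
                    "truth": config.truth,
                    "alpha": config.alpha,
                    "epsilon": config.epsilon,
                }
            )
    return SimulationSummary(table=pd.DataFrame.from_records(records), config=config)
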