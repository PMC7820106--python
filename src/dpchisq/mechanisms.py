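"""Decision procedures for private and non-private chi-squared testing.

Five mechanisms share one interface (table, epsilon, alpha, rng -> outcome):

* :func:`rand_chi_dist` -- the calibrated private test.  Adds Laplace noise
  scaled by the table's global sensitivity to the chi-squared statistic and
  compares against a threshold drawn from the noise-convolved null, so the
  type-I error stays at alpha despite the noise.  Also emits a private
  p-value from the same single noisy statistic.
* :func:`rand_chi` -- same noisy statistic, but compared against the
  classical chi-squared percentage point (no convolved null).  A baseline
  that shows why recalibration matters.
* :func:`rand_cell` -- per-cell Laplace noise with global sensitivity 2;
  the statistic is recomputed from the noisy table.  Applies the
  rule-of-thumb: if any noisy cell is below five the test refuses to
  reject.
* :func:`mc_indep` -- per-cell noise plus a Monte Carlo reference
  distribution: tables are resampled from the independence model estimated
  from the noisy table and the observed noisy statistic is compared to
  their empirical (1-alpha) quantile.
* :func:`non_private_test` -- the classical test, for reference.

Each mechanism consumes its full privacy budget epsilon in one invocation;
there is no hidden composition.  Every mechanism takes an explicit seeded
`numpy.random.Generator` so runs are reproducible and mechanisms are
comparable on shared tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.stats import chi2 as _chi2

from .exceptions import ConfigError
from .private_null import PrivateNull, critical_value, noisy_null_upper_tail
from .sensitivity import randchidist_sensitivity
from .tables import ContingencyTable, chi_squared

__all__ = [
    "TestOutcome",
    "sample_laplace",
    "rand_chi_dist",
    "rand_chi",
    "rand_cell",
    "mc_indep",
    "non_private_test",
    "REJECT",
    "FAIL_TO_REJECT",
]

REJECT = "reject"
FAIL_TO_REJECT = "fail_to_reject"


@dataclass(frozen=True)
class TestOutcome:
    """Result of one mechanism run on one table."""

    mechanism: str
    decision: str
    alpha: float
    noisy_statistic: float | None = None
    threshold: float | None = None
    p_value: float | None = None
    epsilon: float | None = None
    seed: int | None = None
    flag: str | None = None

    @property
    def rejected(self) -> bool:
        return self.decision == REJECT


def _laplace(scale: float, size, rng: np.random.Generator) -> np.ndarray:
    # Inverse-CDF on uniforms; log1p keeps precision near the median.
    u = rng.random(size) - 0.5
    return -scale * np.sign(u) * np.log1p(-2.0 * np.abs(u))


def sample_laplace(scale: float, rng: np.random.Generator) -> float:
    """One zero-mean Laplace variate via inverse-CDF on a single uniform."""
    if not scale > 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    return float(_laplace(scale, None, rng))


def _check_args(epsilon: float, alpha: float) -> None:
    if not epsilon > 0:
        raise ConfigError(f"epsilon must be > 0, got {epsilon}")
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")


def _chi2_of_matrix(mat: np.ndarray) -> float | None:
    """Chi-squared of a real-valued matrix using its own margins.

    Returns None when a margin (or the total) is non-positive, where the
    statistic is undefined.  Used only on noisy matrices; integer tables go
    through :func:`dpchisq.tables.chi_squared`.
    """
    rm = mat.sum(axis=1)
    cm = mat.sum(axis=0)
    total = mat.sum()
    if total <= 0 or np.any(rm <= 0) or np.any(cm <= 0):
        return None
    expected = np.outer(rm, cm) / total
    return float(((mat - expected) ** 2 / expected).sum())


def _chi2_of_matrices(mats: np.ndarray) -> np.ndarray:
    """Vectorized chi-squared over a (N, I, J) stack; undefined -> +inf.

    Tables whose noise pushed a margin non-positive have no finite
    statistic; mapping them to +inf keeps the Monte Carlo reference
    quantile conservative rather than silently dropping them.
    """
    rm = mats.sum(axis=2)
    cm = mats.sum(axis=1)
    total = mats.sum(axis=(1, 2))
    valid = (total > 0) & (rm > 0).all(axis=1) & (cm > 0).all(axis=1)
    out = np.full(mats.shape[0], np.inf)
    if valid.any():
        sub = mats[valid]
        expected = (
            rm[valid][:, :, None] * cm[valid][:, None, :] / total[valid][:, None, None]
        )
        out[valid] = ((sub - expected) ** 2 / expected).sum(axis=(1, 2))
    return out


def rand_chi_dist(
    table: ContingencyTable,
    epsilon: float,
    alpha: float,
    rng: np.random.Generator,
    seed: int | None = None,
) -> TestOutcome:
    """Calibrated private chi-squared test.

    Releases ``chi2 + Laplace(Delta_R/epsilon)`` and rejects when the noisy
    statistic reaches the threshold calibrated on the Laplace-convolved
    null, so rejecting iff ``p_value <= alpha`` gives the same decision.
    """
    _check_args(epsilon, alpha)
    res = chi_squared(table)
    sens = randchidist_sensitivity(table.row_margins, table.n_cols)
    null = PrivateNull(res.dof, sens.value, epsilon)
    noisy = res.statistic + sample_laplace(null.scale, rng)
    threshold = critical_value(null, alpha)
    p_value = noisy_null_upper_tail(noisy, null)
    return TestOutcome(
        mechanism="randchidist",
        decision=REJECT if noisy >= threshold else FAIL_TO_REJECT,
        alpha=alpha,
        noisy_statistic=noisy,
        threshold=threshold,
        p_value=p_value,
        epsilon=epsilon,
        seed=seed,
    )


def rand_chi(
    table: ContingencyTable,
    epsilon: float,
    alpha: float,
    rng: np.random.Generator,
    seed: int | None = None,
) -> TestOutcome:
    """Noisy statistic against the *classical* chi-squared percentage point.

    Ignores the noise when thresholding, so its type-I error inflates as
    epsilon shrinks; kept as the uncalibrated baseline.
    """
    _check_args(epsilon, alpha)
    res = chi_squared(table)
    sens = randchidist_sensitivity(table.row_margins, table.n_cols)
    noisy = res.statistic + sample_laplace(sens.value / epsilon, rng)
    threshold = float(_chi2.ppf(1.0 - alpha, res.dof))
    return TestOutcome(
        mechanism="randchi",
        decision=REJECT if noisy >= threshold else FAIL_TO_REJECT,
        alpha=alpha,
        noisy_statistic=noisy,
        threshold=threshold,
        p_value=float(_chi2.sf(noisy, res.dof)),
        epsilon=epsilon,
        seed=seed,
    )


def rand_cell(
    table: ContingencyTable,
    epsilon: float,
    alpha: float,
    rng: np.random.Generator,
    seed: int | None = None,
    *,
    cell_threshold: float = 5.0,
    use_true_margins: bool = False,
) -> TestOutcome:
    """Per-cell Laplace noise (global sensitivity 2), classical threshold.

    The rule-of-thumb check applies to the noisy cells: if any is below
    ``cell_threshold`` the mechanism fails to reject outright.  By default
    the statistic is recomputed from the noisy table's own margins;
    ``use_true_margins`` switches to the public row/column totals.
    """
    _check_args(epsilon, alpha)
    dof = (table.n_rows - 1) * (table.n_cols - 1)
    threshold = float(_chi2.ppf(1.0 - alpha, dof))
    noisy = table.counts + _laplace(2.0 / epsilon, table.counts.shape, rng)
    if np.any(noisy < cell_threshold):
        return TestOutcome(
            mechanism="randcell",
            decision=FAIL_TO_REJECT,
            alpha=alpha,
            threshold=threshold,
            epsilon=epsilon,
            seed=seed,
            flag="rule_of_thumb",
        )
    if use_true_margins:
        expected = np.outer(table.row_margins, table.col_margins) / table.total
        stat = float(((noisy - expected) ** 2 / expected).sum())
    else:
        stat = _chi2_of_matrix(noisy)
        if stat is None:
            return TestOutcome(
                mechanism="randcell",
                decision=FAIL_TO_REJECT,
                alpha=alpha,
                threshold=threshold,
                epsilon=epsilon,
                seed=seed,
                flag="degenerate_margins",
            )
    return TestOutcome(
        mechanism="randcell",
        decision=REJECT if stat >= threshold else FAIL_TO_REJECT,
        alpha=alpha,
        noisy_statistic=stat,
        threshold=threshold,
        p_value=float(_chi2.sf(stat, dof)),
        epsilon=epsilon,
        seed=seed,
    )


def mc_indep(
    table: ContingencyTable,
    epsilon: float,
    alpha: float,
    rng: np.random.Generator,
    seed: int | None = None,
    n_mc_tables: int | None = None,
) -> TestOutcome:
    """Monte Carlo independence test on the per-cell-noised table.

    Procedure: (1) noise every cell with Laplace(2/epsilon) -- the full
    budget goes to this one release; (2) estimate the independence
    multinomial from the noisy margins (floored at zero, renormalized) and
    a rounded noisy total; (3) sample ``n_mc_tables`` reference tables from
    it; (4) if any *sampled* table has a cell below five, refuse to reject
    (rule of thumb on the references); (5) otherwise perturb each reference
    with fresh same-scale Laplace noise so observed and reference
    statistics are comparable, and reject when the observed noisy
    chi-squared reaches their empirical (1-alpha) quantile.
    """
    _check_args(epsilon, alpha)
    if n_mc_tables is None:
        n_mc_tables = max(ceil(2.0 / alpha), 1000)
    if n_mc_tables < ceil(1.0 / alpha):
        raise ConfigError(
            f"n_mc_tables={n_mc_tables} must be at least ceil(1/alpha)="
            f"{ceil(1.0 / alpha)}"
        )
    shape = table.counts.shape
    noisy = table.counts + _laplace(2.0 / epsilon, shape, rng)
    observed = _chi2_of_matrix(noisy)
    n_tilde = max(int(round(noisy.sum())), 1)
    rm = np.clip(noisy.sum(axis=1), 0.0, None)
    cm = np.clip(noisy.sum(axis=0), 0.0, None)
    if observed is None or rm.sum() <= 0 or cm.sum() <= 0:
        return TestOutcome(
            mechanism="mcindep",
            decision=FAIL_TO_REJECT,
            alpha=alpha,
            epsilon=epsilon,
            seed=seed,
            flag="degenerate_margins",
        )
    probs = np.outer(rm / rm.sum(), cm / cm.sum()).ravel()
    samples = rng.multinomial(n_tilde, probs, size=n_mc_tables).reshape(
        n_mc_tables, *shape
    )
    if np.any(samples < 5):
        return TestOutcome(
            mechanism="mcindep",
            decision=FAIL_TO_REJECT,
            alpha=alpha,
            epsilon=epsilon,
            seed=seed,
            flag="rule_of_thumb",
        )
    references = samples + _laplace(2.0 / epsilon, samples.shape, rng)
    ref_stats = np.sort(_chi2_of_matrices(references))
    # empirical (1-alpha) quantile as an order statistic; avoids
    # interpolating with the +inf sentinels of degenerate references
    rank = min(max(int(np.ceil((1.0 - alpha) * n_mc_tables)) - 1, 0), n_mc_tables - 1)
    threshold = float(ref_stats[rank])
    return TestOutcome(
        mechanism="mcindep",
        decision=REJECT if observed >= threshold else FAIL_TO_REJECT,
        alpha=alpha,
        noisy_statistic=observed,
        threshold=threshold,
        epsilon=epsilon,
        seed=seed,
    )


def non_private_test(
    table: ContingencyTable, alpha: float, seed: int | None = None
) -> TestOutcome:
    """The classical chi-squared test of independence."""
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    res = chi_squared(table)
    threshold = float(_chi2.ppf(1.0 - alpha, res.dof))
    return TestOutcome(
        mechanism="nonprivate",
        decision=REJECT if res.statistic >= threshold else FAIL_TO_REJECT,
        alpha=alpha,
        noisy_statistic=res.statistic,
        threshold=threshold,
        p_value=float(_chi2.sf(res.statistic, res.dof)),
        seed=seed,
    )
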