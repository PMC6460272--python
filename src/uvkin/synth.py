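"""Synthetic data with the statistical structure of plate-count UV assays.

Three generators cover the pipeline's inputs:

* :func:`simulate_survival_series` — first-order kill with Poisson
  counting noise after a single multiplicative dilution, the standard
  plate-count noise model.  Defaults mirror a typical broth-culture
  irradiance design: control populations drawn uniformly from
  1.5–2.5 × 10^7 CFU, exposures at 0/15/30/45/60 min.
* :func:`simulate_isolate_table` — multinomial contingency tables whose
  cell probabilities are an independence outer product tilted by a
  log-linear association parameter (0 = exact independence).
* :func:`simulate_ae_grid` — balanced Poisson replicate grids around
  user-supplied cell means, for two-way ANOVA exercises.

Seeding contract: one root seed; each replicate gets its own child
stream spawned from it, so increasing ``replicates`` never perturbs the
replicates already generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .kinetics import SurvivalSeries
from .stats import ContingencyTable, TreatmentGrid

__all__ = [
    "SimSpec",
    "simulate_survival_series",
    "simulate_isolate_table",
    "simulate_ae_grid",
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a simulated survival experiment.

    Attributes
    ----------
    k_true : float
        Generating survival constant (1/min); 0 disables killing.
    n0_range : (float, float)
        Uniform range for the control population (CFU).
    times : tuple of float
        Exposure grid in minutes.
    dilution : float
        Plated fraction in (0, 1]; expected plate count is
        N0 * exp(-k t) * dilution.  The default 1e-5 puts counts from a
        ~2e7 CFU culture in the countable tens-to-hundreds range.
    replicates : int
        Number of independent series.
    seed : int
        Root seed; fixed seed + spec gives byte-identical output.
    poisson_ceiling : float
        Above this expected count the Poisson draw is replaced by the
        rounded expectation (overflow guard for dilution = 1 with huge
        populations; the relative sampling error there is negligible).
    """

    k_true: float = 0.035
    n0_range: tuple[float, float] = (1.5e7, 2.5e7)
    times: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0)
    dilution: float = 1e-5
    replicates: int = 1
    seed: int = 0
    poisson_ceiling: float = 1e12

    def __post_init__(self) -> None:
        if self.k_true < 0:
            raise ValidationError("k_true must be nonnegative")
        lo, hi = self.n0_range
        if not (0 < lo <= hi):
            raise ValidationError(f"invalid n0_range {self.n0_range}")
        if not 0 < self.dilution <= 1:
            raise ValidationError("dilution must lie in (0, 1]")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if len(self.times) < 2:
            raise ValidationError("need at least 2 exposure times")


def simulate_survival_series(spec: SimSpec) -> list[SurvivalSeries]:
    """Draw ``spec.replicates`` independent Poisson-noised survival series.

    Each series records the *known* plated control population
    ``N0 * dilution`` as its ``n0``, so downstream fits estimate k
    against the true counting scale.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.replicates)
    times = np.asarray(spec.times, dtype=float)
    out: list[SurvivalSeries] = []
    for child in children:
        rng = np.random.default_rng(child)
        n0 = rng.uniform(*spec.n0_range)
        mu = n0 * np.exp(-spec.k_true * times) * spec.dilution
        counts = np.where(
            mu <= spec.poisson_ceiling,
            rng.poisson(np.minimum(mu, spec.poisson_ceiling)),
            np.round(mu),
        ).astype(np.int64)
        out.append(SurvivalSeries(times=times, counts=counts, n0=n0 * spec.dilution))
    return out


def simulate_isolate_table(
    row_probs,
    col_probs,
    association: float = 0.0,
    n: int = 88,
    seed: int = 0,
    row_labels=None,
    col_labels=None,
) -> ContingencyTable:
    """Multinomial r×c isolate table with tunable row-column association.

    Cell probabilities are ``p_ij ∝ r_i c_j exp(association * u_i v_j)``
    with equally spaced scores u, v on [-1, 1]; ``association = 0``
    recovers exact independence, positive values concentrate mass on the
    diagonal-like corners.
    """
    row_probs = np.asarray(row_probs, dtype=float)
    col_probs = np.asarray(col_probs, dtype=float)
    for name, p in (("row_probs", row_probs), ("col_probs", col_probs)):
        if p.ndim != 1 or p.size < 2:
            raise DomainError(f"{name} must be a 1-d simplex with >= 2 entries")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise DomainError(f"{name} must be nonnegative and sum to 1 (±1e-9)")
    if n < 1:
        raise DomainError("n must be >= 1")
    u = np.linspace(-1.0, 1.0, row_probs.size)
    v = np.linspace(-1.0, 1.0, col_probs.size)
    cell = np.outer(row_probs, col_probs) * np.exp(association * np.outer(u, v))
    cell /= cell.sum()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draw = rng.multinomial(n, cell.ravel()).reshape(cell.shape)
    return ContingencyTable(draw, row_labels=row_labels, col_labels=col_labels)


def simulate_ae_grid(
    cell_means,
    replicates: int = 3,
    seed: int = 0,
    levels_a=None,
    levels_b=None,
) -> TreatmentGrid:
    """Balanced grid of Poisson counts around the given cell means.

    ``cell_means`` is (treatments × times); each cell receives
    ``replicates`` independent Poisson draws.  Two replicates are the
    minimum for the interaction term to be testable.
    """
    means = np.asarray(cell_means, dtype=float)
    if means.ndim != 2:
        raise ValidationError("cell_means must be a 2-d matrix")
    if (means < 0).any():
        raise ValidationError("cell means must be nonnegative")
    if replicates < 2:
        raise ValidationError("need >= 2 replicates per cell for interaction tests")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = rng.poisson(means[:, :, None], size=(*means.shape, replicates))
    return TreatmentGrid(values.astype(float), levels_a=levels_a, levels_b=levels_b)
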