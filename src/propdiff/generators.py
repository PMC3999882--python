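"""Two-sample response generators on the open unit interval.

The two sampling designs implemented here are

* independent beta draws in each group, with the beta law parameterized
  by its mean ``mu`` and dispersion (precision) ``phi``, and
* independent discrete draws on a fixed support inside (0,1) with
  group-specific probability vectors.

Both samplers are seeded and fully reproducible.  Built-in scenario
registries (:data:`BETA_GRID`, :data:`MULTINOMIAL_GRID`) expose every
cell of the shipped simulation grids by (table, row) index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "BetaParams",
    "BetaScenario",
    "MultinomialScenario",
    "TwoSampleData",
    "shape_from_mean_dispersion",
    "mean_dispersion_from_shape",
    "beta_moments",
    "beta_density",
    "draw_beta_two_sample",
    "draw_multinomial_two_sample",
    "beta_scenario",
    "multinomial_scenario",
    "write_scenario_config",
    "read_scenario_config",
    "BETA_GRID",
    "MULTINOMIAL_GRID",
    "GROUP_SIZES",
    "DECILE_SUPPORT",
]

#: smallest spacing used to keep draws strictly inside (0,1)
OPEN_UNIT_EPS = float(np.finfo(float).eps)

SeedLike = Union[int, np.integer, np.random.SeedSequence, np.random.Generator]


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def shape_from_mean_dispersion(mu: float, phi: float) -> tuple[float, float]:
    """Convert (mean, dispersion) to the two beta shape parameters.

    Parameters
    ----------
    mu : float
        Mean, strictly inside (0, 1).
    phi : float
        Dispersion (precision), strictly positive.

    Returns
    -------
    (p, q) : tuple of float
        First and second shape parameters ``p = mu*phi``,
        ``q = (1-mu)*phi``.
    """
    if not (0.0 < mu < 1.0):
        raise ValueError(f"mu must lie in (0,1), got {mu}")
    if not phi > 0.0:
        raise ValueError(f"phi must be positive, got {phi}")
    return mu * phi, (1.0 - mu) * phi


def mean_dispersion_from_shape(p: float, q: float) -> tuple[float, float]:
    """Inverse of :func:`shape_from_mean_dispersion`."""
    if p <= 0.0 or q <= 0.0:
        raise ValueError("shape parameters must be positive")
    return p / (p + q), p + q


@dataclass(frozen=True)
class BetaParams:
    """Beta law in mean--dispersion form.

    ``mu`` is the mean in (0,1); ``phi`` the dispersion (precision).
    The shape parameters are ``p = mu*phi`` and ``q = (1-mu)*phi``;
    the variance is ``mu*(1-mu)/(1+phi)``.
    """

    mu: float
    phi: float

    def __post_init__(self) -> None:
        shape_from_mean_dispersion(self.mu, self.phi)  # validates

    @property
    def p(self) -> float:
        return self.mu * self.phi

    @property
    def q(self) -> float:
        return (1.0 - self.mu) * self.phi

    @classmethod
    def from_shapes(cls, p: float, q: float) -> "BetaParams":
        mu, phi = mean_dispersion_from_shape(p, q)
        return cls(mu=mu, phi=phi)


def beta_moments(params: BetaParams) -> tuple[float, float]:
    """Mean and variance of the beta law in mean--dispersion form."""
    var = params.mu * (1.0 - params.mu) / (1.0 + params.phi)
    return params.mu, var


def beta_density(y, params: BetaParams):
    """Beta density at ``y`` (scalar or array), ``y`` strictly in (0,1)."""
    arr = np.asarray(y, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("density is defined on the open interval (0,1)")
    out = stats.beta.pdf(arr, params.p, params.q)
    return float(out) if np.isscalar(y) else out


@dataclass(frozen=True)
class BetaScenario:
    """Two-sample beta generating model."""

    group0: BetaParams
    group1: BetaParams
    n0: int
    n1: int

    def __post_init__(self) -> None:
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError("group sizes must be positive integers")

    @property
    def true_delta(self) -> float:
        """True average difference ``mu1 - mu0``."""
        return self.group1.mu - self.group0.mu


@dataclass(frozen=True)
class MultinomialScenario:
    """Two-sample discrete generating model on points inside (0,1)."""

    support: tuple[float, ...]
    probs0: tuple[float, ...]
    probs1: tuple[float, ...]
    n0: int
    n1: int

    def __post_init__(self) -> None:
        sup = np.asarray(self.support, dtype=float)
        if np.any(sup <= 0.0) or np.any(sup >= 1.0):
            raise ValueError("support points must lie strictly inside (0,1)")
        if np.any(np.diff(sup) <= 0.0):
            raise ValueError("support points must be strictly increasing")
        for name, probs in (("probs0", self.probs0), ("probs1", self.probs1)):
            arr = np.asarray(probs, dtype=float)
            if arr.shape != sup.shape:
                raise ValueError(f"{name} must align with the support")
            if np.any(arr < 0.0):
                raise ValueError(f"{name} must be non-negative")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {arr.sum()}")
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError("group sizes must be positive integers")

    @property
    def mean0(self) -> float:
        return float(np.dot(self.support, self.probs0))

    @property
    def mean1(self) -> float:
        return float(np.dot(self.support, self.probs1))

    @property
    def true_delta(self) -> float:
        return self.mean1 - self.mean0


@dataclass
class TwoSampleData:
    """Responses in (0,1) with an aligned binary group indicator."""

    y: np.ndarray
    x: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=int)
        if self.y.shape != self.x.shape:
            raise ValueError("y and x must be aligned")
        if np.any(self.y <= 0.0) or np.any(self.y >= 1.0):
            raise ValueError("responses must lie strictly inside (0,1)")
        if not np.all((self.x == 0) | (self.x == 1)):
            raise ValueError("group indicator must be 0/1")

    @property
    def n0(self) -> int:
        return int(np.sum(self.x == 0))

    @property
    def n1(self) -> int:
        return int(np.sum(self.x == 1))

    def group(self, g: int) -> np.ndarray:
        return self.y[self.x == g]


def _clamp_open(y: np.ndarray) -> tuple[np.ndarray, int]:
    # underflow to exactly 0/1 is possible for very skewed shapes; the
    # likelihoods require open-interval support, so clamp and count
    bad = (y <= 0.0) | (y >= 1.0)
    n_bad = int(bad.sum())
    if n_bad:
        y = np.clip(y, OPEN_UNIT_EPS, 1.0 - OPEN_UNIT_EPS)
    return y, n_bad


def draw_beta_two_sample(scenario: BetaScenario, seed: SeedLike) -> TwoSampleData:
    """Draw ``n0`` + ``n1`` independent beta responses, one group each."""
    rng = _as_rng(seed)
    y0 = rng.beta(scenario.group0.p, scenario.group0.q, size=scenario.n0)
    y1 = rng.beta(scenario.group1.p, scenario.group1.q, size=scenario.n1)
    y = np.concatenate([y0, y1])
    y, n_bad = _clamp_open(y)
    x = np.concatenate([np.zeros(scenario.n0, dtype=int), np.ones(scenario.n1, dtype=int)])
    return TwoSampleData(y=y, x=x, n_clamped=n_bad)


def draw_multinomial_two_sample(
    scenario: MultinomialScenario, seed: SeedLike
) -> TwoSampleData:
    """Draw independent discrete responses on the scenario support."""
    rng = _as_rng(seed)
    support = np.asarray(scenario.support, dtype=float)
    y0 = rng.choice(support, size=scenario.n0, p=np.asarray(scenario.probs0))
    y1 = rng.choice(support, size=scenario.n1, p=np.asarray(scenario.probs1))
    y = np.concatenate([y0, y1])
    x = np.concatenate([np.zeros(scenario.n0, dtype=int), np.ones(scenario.n1, dtype=int)])
    return TwoSampleData(y=y, x=x)


# ---------------------------------------------------------------------------
# Shipped scenario grids
# ---------------------------------------------------------------------------

#: group sizes used by the shipped grids (any positive integer is accepted
#: when building scenarios directly)
GROUP_SIZES = (25, 100, 250, 750)

#: 24 beta rows as (mu0, phi0, mu1, phi1); rows 1-12 are null scenarios,
#: rows 13-24 shift mu1 by +0.025
BETA_GRID: tuple[tuple[float, float, float, float], ...] = (
    # null scenarios
    (0.50, 5, 0.50, 5),
    (0.50, 5, 0.50, 10),
    (0.50, 100, 0.50, 100),
    (0.50, 100, 0.50, 200),
    (0.25, 5, 0.25, 5),
    (0.25, 5, 0.25, 10),
    (0.25, 100, 0.25, 100),
    (0.25, 100, 0.25, 200),
    (0.05, 5, 0.05, 5),
    (0.05, 5, 0.05, 10),
    (0.05, 100, 0.05, 100),
    (0.05, 100, 0.05, 200),
    # shifted scenarios
    (0.5, 5, 0.525, 5),
    (0.5, 5, 0.525, 10),
    (0.5, 100, 0.525, 100),
    (0.5, 100, 0.525, 200),
    (0.25, 5, 0.275, 5),
    (0.25, 5, 0.275, 10),
    (0.25, 100, 0.275, 100),
    (0.25, 100, 0.275, 200),
    (0.05, 5, 0.075, 5),
    (0.05, 5, 0.075, 10),
    (0.05, 100, 0.075, 100),
    (0.05, 100, 0.075, 200),
)

#: indices (1-based) of the null rows of the beta grid
BETA_NULL_ROWS = tuple(range(1, 13))
BETA_SHIFT_ROWS = tuple(range(13, 25))

DECILE_SUPPORT = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95)

_SYMMETRIC = (0.00, 0.025, 0.025, 0.15, 0.30, 0.30, 0.15, 0.025, 0.025, 0.00)
_ASYMMETRIC = (0.40, 0.20, 0.10, 0.10, 0.10, 0.05, 0.05, 0.00, 0.00, 0.00)
# shifted one support point upward
_SYMMETRIC_UP = (0.00,) + _SYMMETRIC[:-1]
_ASYMMETRIC_UP = (0.00,) + _ASYMMETRIC[:-1]

#: 4 discrete rows as (probs0, probs1); rows 1-2 null, rows 3-4 shifted
MULTINOMIAL_GRID: tuple[tuple[tuple[float, ...], tuple[float, ...]], ...] = (
    (_SYMMETRIC, _SYMMETRIC),
    (_ASYMMETRIC, _ASYMMETRIC),
    (_SYMMETRIC, _SYMMETRIC_UP),
    (_ASYMMETRIC, _ASYMMETRIC_UP),
)


def beta_scenario(row: int, n0: int, n1: int | None = None) -> BetaScenario:
    """Build the ``row``-th (1-based) beta grid scenario at group size ``n0``."""
    if not 1 <= row <= len(BETA_GRID):
        raise KeyError(f"beta grid row must be in 1..{len(BETA_GRID)}, got {row}")
    mu0, phi0, mu1, phi1 = BETA_GRID[row - 1]
    return BetaScenario(
        group0=BetaParams(mu0, phi0),
        group1=BetaParams(mu1, phi1),
        n0=n0,
        n1=n0 if n1 is None else n1,
    )


def multinomial_scenario(row: int, n0: int, n1: int | None = None) -> MultinomialScenario:
    """Build the ``row``-th (1-based) discrete grid scenario at size ``n0``."""
    if not 1 <= row <= len(MULTINOMIAL_GRID):
        raise KeyError(
            f"multinomial grid row must be in 1..{len(MULTINOMIAL_GRID)}, got {row}"
        )
    probs0, probs1 = MULTINOMIAL_GRID[row - 1]
    return MultinomialScenario(
        support=DECILE_SUPPORT,
        probs0=probs0,
        probs1=probs1,
        n0=n0,
        n1=n0 if n1 is None else n1,
    )


# ---------------------------------------------------------------------------
# Flat key=value scenario (de)serialization
# ---------------------------------------------------------------------------

Scenario = Union[BetaScenario, MultinomialScenario]


def scenario_to_config(scenario: Scenario) -> dict[str, str]:
    """Flatten a scenario into a key->value string mapping."""
    if isinstance(scenario, BetaScenario):
        return {
            "kind": "beta",
            "mu0": repr(scenario.group0.mu),
            "phi0": repr(scenario.group0.phi),
            "mu1": repr(scenario.group1.mu),
            "phi1": repr(scenario.group1.phi),
            "n0": str(scenario.n0),
            "n1": str(scenario.n1),
        }
    if isinstance(scenario, MultinomialScenario):
        return {
            "kind": "multinomial",
            "support": ",".join(repr(v) for v in scenario.support),
            "probs0": ",".join(repr(v) for v in scenario.probs0),
            "probs1": ",".join(repr(v) for v in scenario.probs1),
            "n0": str(scenario.n0),
            "n1": str(scenario.n1),
        }
    raise TypeError(f"unsupported scenario type: {type(scenario)!r}")


def scenario_from_config(mapping: dict[str, str]) -> Scenario:
    """Inverse of :func:`scenario_to_config`."""
    kind = mapping.get("kind")
    if kind == "beta":
        return BetaScenario(
            group0=BetaParams(float(mapping["mu0"]), float(mapping["phi0"])),
            group1=BetaParams(float(mapping["mu1"]), float(mapping["phi1"])),
            n0=int(mapping["n0"]),
            n1=int(mapping["n1"]),
        )
    if kind == "multinomial":
        return MultinomialScenario(
            support=tuple(float(v) for v in mapping["support"].split(",")),
            probs0=tuple(float(v) for v in mapping["probs0"].split(",")),
            probs1=tuple(float(v) for v in mapping["probs1"].split(",")),
            n0=int(mapping["n0"]),
            n1=int(mapping["n1"]),
        )
    raise ValueError(f"unknown scenario kind: {kind!r}")


def write_scenario_config(path, scenario: Scenario) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in scenario_to_config(scenario).items():
            fh.write(f"{key} = {value}\n")


def read_scenario_config(path) -> Scenario:
    mapping: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            mapping[key.strip()] = value.strip()
    return scenario_from_config(mapping)
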