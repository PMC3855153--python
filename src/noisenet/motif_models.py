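"""Linear structural-equation models of three-gene network motifs.

Three canonical three-node motifs are modelled as linear Gaussian (or
centered-lognormal) structural equation models over variables (x, y, z):

* ``common_effect``  x and y independently regulate z        (x -> z <- y)
* ``three_chain``    x regulates y, y regulates z            (x -> y -> z)
* ``ffl_type1``      coherent type-I feed-forward loop       (x -> y, x -> z, y -> z)

Each variable equals a coupling-weighted sum of its parents plus an
independent zero-mean, unit-variance disturbance scaled by a per-node
standard deviation.  Discrepancies in those per-node noise scales are the
object of study: they distort pairwise and conditional dependencies and,
downstream, constraint-based structure learning.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MotifKind",
    "NoiseFamily",
    "LinearMotif",
    "ExpressionMatrix",
    "build_motif",
    "implied_covariance",
    "simulate",
    "log_transform",
    "center_columns",
    "DEFAULT_COUPLING",
    "LARGE_NOISE_VARIANCE",
]

#: Shared regulator->target coupling used by the simulation experiments.
#: Held constant across all simulations; any value outside {0, 1} keeps all
#: three motifs faithful (at coupling 1 with equal noise the FFL's x-y
#: partial correlation given z cancels exactly).
DEFAULT_COUPLING: float = 2.0

#: Noise variance used for the "large noise" regimes.  Large enough that the
#: asymptotically vanishing correlations (of order 1/sigma) fall below the
#: detection power of an n = 2000 sample at conventional significance levels,
#: so finite-sample behaviour matches the analytic limits.
LARGE_NOISE_VARIANCE: float = 1e4

MOTIF_NODES = ("x", "y", "z")


class MotifKind(str, enum.Enum):
    COMMON_EFFECT = "common_effect"
    THREE_CHAIN = "three_chain"
    FFL_TYPE1 = "ffl_type1"


class NoiseFamily(str, enum.Enum):
    GAUSSIAN = "gaussian"
    CENTERED_LOGNORMAL = "centered_lognormal"


#: True directed edges of each motif in the fixed topological order (x, y, z).
MOTIF_EDGES: dict[MotifKind, tuple[tuple[str, str], ...]] = {
    MotifKind.COMMON_EFFECT: (("x", "z"), ("y", "z")),
    MotifKind.THREE_CHAIN: (("x", "y"), ("y", "z")),
    MotifKind.FFL_TYPE1: (("x", "y"), ("x", "z"), ("y", "z")),
}


@dataclass(frozen=True)
class LinearMotif:
    """A three-node linear SEM with per-node noise scales.

    ``coefficient_matrix`` B has ``B[i, j]`` = coefficient of variable j in
    the structural equation of variable i; it is strictly lower triangular
    under the topological order (x, y, z), hence the model is acyclic.
    """

    kind: MotifKind
    coupling: float
    noise_scales: tuple[float, float, float]
    noise_family: NoiseFamily = NoiseFamily.GAUSSIAN
    lognormal_shape: float = 1.0

    def __post_init__(self) -> None:
        if len(self.noise_scales) != 3:
            raise ValueError("noise_scales must be a triple (sigma_x, sigma_y, sigma_z)")
        if any(s <= 0 for s in self.noise_scales):
            raise ValueError(f"noise scales must be strictly positive, got {self.noise_scales}")

    @property
    def coefficient_matrix(self) -> np.ndarray:
        B = np.zeros((3, 3))
        idx = {n: i for i, n in enumerate(MOTIF_NODES)}
        for parent, child in MOTIF_EDGES[self.kind]:
            B[idx[child], idx[parent]] = self.coupling
        return B

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return MOTIF_EDGES[self.kind]

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind.value,
                "coupling": self.coupling,
                "noise_scales": list(self.noise_scales),
                "noise_family": self.noise_family.value,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearMotif":
        obj = json.loads(text)
        return build_motif(
            obj["kind"],
            obj["coupling"],
            tuple(obj["noise_scales"]),
            obj.get("noise_family", "gaussian"),
        )


@dataclass
class ExpressionMatrix:
    """n samples x p named variables of real values; the universal carrier."""

    values: np.ndarray
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (samples x variables)")
        n, p = self.values.shape
        if n < 1:
            raise ValueError("need at least one sample")
        if p < 2:
            raise ValueError("need at least two variables")
        if not self.variable_names:
            self.variable_names = [f"v{i}" for i in range(p)]
        if len(self.variable_names) != p:
            raise ValueError("variable_names length must match the number of columns")
        if len(set(self.variable_names)) != p:
            raise ValueError("variable names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing values)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.variable_names.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}; have {self.variable_names}") from None
        return self.values[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.variable_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def build_motif(
    kind: MotifKind | str,
    coupling: float = DEFAULT_COUPLING,
    noise_scales: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_family: NoiseFamily | str = NoiseFamily.GAUSSIAN,
) -> LinearMotif:
    """Construct a motif model, validating kind and noise scales."""
    return LinearMotif(
        kind=MotifKind(kind),
        coupling=float(coupling),
        noise_scales=tuple(float(s) for s in noise_scales),
        noise_family=NoiseFamily(noise_family),
    )


def implied_covariance(model: LinearMotif) -> np.ndarray:
    """Exact covariance Sigma = (I-B)^-1 D (I-B)^-T with D = diag(sigma^2).

    Depends only on second moments, hence is independent of the noise family.
    """
    B = model.coefficient_matrix
    A = np.linalg.inv(np.eye(3) - B)
    D = np.diag(np.square(model.noise_scales))
    return A @ D @ A.T


def _unit_variance_draws(
    rng: np.random.Generator, shape: tuple[int, ...], family: NoiseFamily, s: float
) -> np.ndarray:
    """I.i.d. zero-mean unit-variance disturbances from the requested family."""
    if family is NoiseFamily.GAUSSIAN:
        return rng.standard_normal(shape)
    # Lognormal LN(0, s), shifted to zero mean and rescaled to unit variance.
    raw = np.exp(s * rng.standard_normal(shape))
    mean = np.exp(s * s / 2.0)
    sd = np.sqrt((np.exp(s * s) - 1.0) * np.exp(s * s))
    return (raw - mean) / sd


def simulate(model: LinearMotif, n: int, seed: int | np.random.Generator) -> ExpressionMatrix:
    """Draw ``n`` i.i.d. samples from the motif SEM in topological order."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = _unit_variance_draws(rng, (n, 3), model.noise_family, model.lognormal_shape)
    eps *= np.asarray(model.noise_scales)
    B = model.coefficient_matrix
    X = np.empty((n, 3))
    for j in range(3):  # strictly lower-triangular B => ancestors already filled
        X[:, j] = X[:, :j] @ B[j, :j] + eps[:, j]
    return ExpressionMatrix(X, list(MOTIF_NODES))


def log_transform(data: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise natural log (the Box-Cox lambda -> 0 limiting transform)."""
    if np.any(data.values <= 0):
        i, j = np.argwhere(data.values <= 0)[0]
        raise ValueError(
            f"log transform requires strictly positive values; "
            f"row {i}, column {data.variable_names[j]!r} is {data.values[i, j]}"
        )
    return ExpressionMatrix(np.log(data.values), list(data.variable_names))


def center_columns(data: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each column's mean; correlations are unchanged."""
    return ExpressionMatrix(
        data.values - data.values.mean(axis=0, keepdims=True), list(data.variable_names)
    )
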