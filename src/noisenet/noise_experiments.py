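"""Scripted noise-regime experiments on the three motifs.

For each motif, three per-node noise-variance regimes are studied:

* ``baseline``   equal unit variance at every node;
* ``large_y``    large variance at y (the mediator / one cause), unit elsewhere;
* ``large_z``    large variance at z (the terminal / common-effect node).

The experiments report (a) Monte-Carlo averages of the six dependency
measures against their analytic values and (b) bootstrap edge confidences
from repeated structure learning, plus a verification of the asymptotic
dependency-limit table against its parameter-free entries and the
sign/magnitude relations that hold in the limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dependence
from .confidence import EdgeConfidenceTable, parametric_confidence
from .dependence import PROFILE_FIELDS, DependencyProfile, analytic_dependencies, asymptotic_limits
from .motif_models import (
    DEFAULT_COUPLING,
    LARGE_NOISE_VARIANCE,
    LinearMotif,
    MotifKind,
    build_motif,
    simulate,
)

__all__ = [
    "RegimeGrid",
    "REGIME_NAMES",
    "regime_scales",
    "run_dependency_grid",
    "run_structure_grid",
    "verify_table1",
]

REGIME_NAMES = ("baseline", "large_y", "large_z")

#: Significance level for tallying Fig-2-style dependency significance.
DEPENDENCE_ALPHA = 0.001
#: Significance level for structure learning.
STRUCTURE_ALPHA = 0.01


def regime_scales(regime: str, large_variance: float = LARGE_NOISE_VARIANCE) -> tuple[float, float, float]:
    """Per-node noise SDs (sigma_x, sigma_y, sigma_z) for a named regime."""
    s = float(np.sqrt(large_variance))
    table = {"baseline": (1.0, 1.0, 1.0), "large_y": (1.0, s, 1.0), "large_z": (1.0, 1.0, s)}
    if regime not in table:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIME_NAMES}")
    return table[regime]


@dataclass
class RegimeGrid:
    """One motif crossed with the three canonical noise regimes."""

    kind: MotifKind
    coupling: float = DEFAULT_COUPLING
    large_variance: float = LARGE_NOISE_VARIANCE
    n: int = 2000
    R: int = 200
    seed: int = 0
    regimes: tuple[str, ...] = REGIME_NAMES

    def model(self, regime: str) -> LinearMotif:
        return build_motif(self.kind, self.coupling, regime_scales(regime, self.large_variance))


@dataclass
class DependencySummary:
    regime: str
    analytic: DependencyProfile
    mean: DependencyProfile
    significant_fraction: dict[str, float] = field(default_factory=dict)


def run_dependency_grid(grid: RegimeGrid, alpha: float = DEPENDENCE_ALPHA) -> dict[str, DependencySummary]:
    """Average sample dependencies per regime over R simulated replicates.

    Also reports, per dependency, the fraction of replicates in which it was
    significant (exact t-test at ``alpha``; df = n-2 pairwise, n-3 partial).
    """
    out: dict[str, DependencySummary] = {}
    for regime in grid.regimes:
        model = grid.model(regime)
        streams = np.random.SeedSequence(grid.seed).spawn(grid.R)
        profiles = np.empty((grid.R, 6))
        signif = np.zeros(6)
        for r, s in enumerate(streams):
            data = simulate(model, grid.n, np.random.default_rng(s))
            prof = dependence.sample_dependencies(data)
            profiles[r] = prof.as_array()
            for j, name in enumerate(PROFILE_FIELDS):
                k = 0 if name.count("_") == 1 else 1
                _, _, p = dependence._t_test(profiles[r, j], grid.n, k)
                signif[j] += p <= alpha
        mean = DependencyProfile(**dict(zip(PROFILE_FIELDS, profiles.mean(axis=0))))
        out[regime] = DependencySummary(
            regime=regime,
            analytic=analytic_dependencies(model),
            mean=mean,
            significant_fraction=dict(zip(PROFILE_FIELDS, signif / grid.R)),
        )
    return out


def run_structure_grid(
    grid: RegimeGrid,
    alpha: float = STRUCTURE_ALPHA,
    algorithm: str = "gs",
    symmetry_rule: str = "AND",
) -> dict[str, EdgeConfidenceTable]:
    """Parametric-bootstrap edge confidences per noise regime."""
    out: dict[str, EdgeConfidenceTable] = {}
    for i, regime in enumerate(grid.regimes):
        out[regime] = parametric_confidence(
            grid.model(regime),
            n=grid.n,
            R=grid.R,
            alpha=alpha,
            algorithm=algorithm,
            symmetry_rule=symmetry_rule,
            seed=np.random.SeedSequence((grid.seed, i)).generate_state(1)[0] % (2**31),
        )
    return out


# ---------------------------------------------------------------------------
# Asymptotic-limit table verification
# ---------------------------------------------------------------------------

#: Parameter-free entries of the asymptotic dependency table: value, or None
#: where the limit remains a function of the coupling / finite noise scales.
TABLE1: dict[tuple[MotifKind, str], tuple[float | None, ...]] = {
    # Large noise at y: (rho_xy, rho_xz, rho_yz, rho_xy_z, rho_xz_y, rho_yz_x)
    (MotifKind.COMMON_EFFECT, "y"): (0.0, 0.0, 1.0, None, None, 1.0),
    (MotifKind.THREE_CHAIN, "y"): (0.0, 0.0, 1.0, 0.0, 0.0, 1.0),
    (MotifKind.FFL_TYPE1, "y"): (0.0, 0.0, 1.0, None, None, 1.0),
    # Large noise at z:
    (MotifKind.COMMON_EFFECT, "z"): (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    (MotifKind.THREE_CHAIN, "z"): (None, 0.0, 0.0, None, 0.0, 0.0),
    (MotifKind.FFL_TYPE1, "z"): (None, 0.0, 0.0, None, 0.0, 0.0),
}


def verify_table1(
    coupling: float = DEFAULT_COUPLING, finite_scales: tuple[float, float] = (1.0, 1.0)
) -> dict[str, bool]:
    """Check the asymptotic limits against the tabulated 0/1 entries and the
    limit relations: parameter-dependent cells must be nonzero at the supplied
    parameters, the common-effect large-at-y partials rho_xy.z and rho_xz.y
    must have equal magnitude and opposite signs, and the FFL limits must
    match the three-chain (large at y) / common-effect (large at z pattern)
    rows on every cell that is parameter-free in both."""
    report: dict[str, bool] = {}
    profiles = {}
    for (kind, node), expected in TABLE1.items():
        res = asymptotic_limits(kind, node, coupling, finite_scales)
        profiles[(kind, node)] = res
        vals = res.profile.as_array()
        for name, exp_val, got in zip(PROFILE_FIELDS, expected, vals):
            key = f"{kind.value}@{node}:{name}"
            if exp_val is None:
                report[key] = bool(res.parameter_dependent[name]) and abs(got) > 1e-12
            else:
                report[key] = abs(got - exp_val) < 1e-9 and not res.parameter_dependent[name]
    ce_y = profiles[(MotifKind.COMMON_EFFECT, "y")].profile
    report["common_effect@y:opposite_sign_partials"] = (
        abs(abs(ce_y.rho_xy_z) - abs(ce_y.rho_xz_y)) < 1e-9
        and np.sign(ce_y.rho_xy_z) == -np.sign(ce_y.rho_xz_y)
        and abs(ce_y.rho_xy_z) > 1e-12
    )
    for node, other in (("y", MotifKind.THREE_CHAIN), ("z", MotifKind.THREE_CHAIN)):
        ffl = TABLE1[(MotifKind.FFL_TYPE1, node)]
        ref = TABLE1[(other, node)]
        ok = True
        for name, f_exp, r_exp in zip(PROFILE_FIELDS, ffl, ref):
            if f_exp is None or r_exp is None:
                continue
            got_f = getattr(profiles[(MotifKind.FFL_TYPE1, node)].profile, name)
            got_r = getattr(profiles[(other, node)].profile, name)
            ok = ok and abs(got_f - got_r) < 1e-9
        report[f"ffl_type1@{node}:matches_{other.value}"] = ok
    return report
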