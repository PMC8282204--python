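"""Study design: parameter containers, ICC algebra and the condition grid.

The simulation studies a linear growth model with three nested levels:
repeated measures (level 1) within individuals (level 2) within groups
(level 3).  The intercept and the time slope vary randomly at levels 2
and 3, one standard-normal covariate X acts at the individual level and
one standard-normal covariate Z at the group level.

Variance components are anchored through intraclass correlations (ICCs)
of the *intercept pathway*: the proportions of the covariate-free
intercept variance attributable to each level.  The absolute scale is
pinned by fixing the level-2 random-intercept variance at 2.0, which
makes the total intercept-pathway variance ``2.0 / icc_level2``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

__all__ = [
    "FixedEffects",
    "VarianceComponents",
    "ICCSpec",
    "DesignCondition",
    "GenerationParams",
    "icc_to_variances",
    "theoretical_icc",
    "default_variance_components",
    "build_condition_grid",
    "ICC_SET_1",
    "ICC_SET_2",
]

#: Canonical ordering of the fixed effects; matches the columns of the
#: fixed-effect design matrix (1, z, x, t, t*z, t*x).
FIXED_EFFECT_NAMES = (
    "gamma_000",  # grand intercept
    "gamma_001",  # group covariate Z -> intercept
    "gamma_010",  # individual covariate X -> intercept
    "gamma_100",  # grand time slope
    "gamma_101",  # Z -> time slope
    "gamma_110",  # X -> time slope
)

#: Canonical ordering of the estimated variance components.
VARIANCE_NAMES = (
    "sigma2_e",    # level-1 residual variance
    "sigma2_r0",   # level-2 intercept variance
    "sigma2_r1",   # level-2 time-slope variance
    "sigma2_u00",  # level-3 intercept variance
    "sigma2_u01",  # level-3 variance of the X-on-intercept slope
    "sigma2_u10",  # level-3 time-slope variance
    "sigma2_u11",  # level-3 variance of the X-on-time-slope
)


class DesignError(ValueError):
    """Invalid design specification (ICCs, condition, variances)."""


@dataclass(frozen=True)
class FixedEffects:
    """Population regression coefficients of the combined growth model.

    Defaults follow the study conditions: 0.5 for the grand intercept
    and 0.3 (a medium effect size) for every regression slope.
    """

    gamma_000: float = 0.5
    gamma_001: float = 0.3
    gamma_010: float = 0.3
    gamma_100: float = 0.3
    gamma_101: float = 0.3
    gamma_110: float = 0.3

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in FIXED_EFFECT_NAMES)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in FIXED_EFFECT_NAMES}


@dataclass(frozen=True)
class VarianceComponents:
    """Variances (and optional covariances) of the random terms.

    ``sigma_r01`` is the level-2 intercept/slope covariance and
    ``sigma_u_offdiag`` the common value of all level-3 covariances;
    both are zero by default (the generating model uses uncorrelated
    residuals).
    """

    sigma2_e: float = 0.0
    sigma2_r0: float = 0.0
    sigma2_r1: float = 0.0
    sigma2_u00: float = 0.0
    sigma2_u01: float = 0.0
    sigma2_u10: float = 0.0
    sigma2_u11: float = 0.0
    sigma_r01: float = 0.0
    sigma_u_offdiag: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in VARIANCE_NAMES}

    def validate_for_generation(self) -> None:
        for name in VARIANCE_NAMES:
            if getattr(self, name) < 0.0:
                raise DesignError(
                    f"generation requires nonnegative variances; {name} < 0"
                )


@dataclass(frozen=True)
class ICCSpec:
    """Intercept-pathway ICC proportions for the three levels.

    ``anchor_variance`` pins the absolute scale.  By default it is read
    as the level-2 random-intercept variance (``anchor_level=2``); the
    alternative reading, where it is the level-1 residual variance, is
    available with ``anchor_level=1``.
    """

    icc_level1: float
    icc_level2: float
    icc_level3: float
    anchor_variance: float = 2.0
    anchor_level: int = 2

    def __post_init__(self) -> None:
        props = (self.icc_level1, self.icc_level2, self.icc_level3)
        if abs(sum(props) - 1.0) > 1e-12:
            raise DesignError(f"ICC proportions must sum to 1, got {props}")
        for p in props:
            if not (0.0 < p < 1.0):
                raise DesignError(f"each ICC proportion must lie in (0,1), got {p}")
        if self.anchor_variance <= 0.0:
            raise DesignError("anchor_variance must be positive")
        if self.anchor_level not in (1, 2):
            raise DesignError("anchor_level must be 1 or 2")

    @property
    def total_variance(self) -> float:
        """Total intercept-pathway variance implied by the anchor."""
        anchor_icc = self.icc_level2 if self.anchor_level == 2 else self.icc_level1
        return self.anchor_variance / anchor_icc

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.icc_level1, self.icc_level2, self.icc_level3)


#: The two ICC sets of the study grid.  Level-2 ICC is 0.5 in both; the
#: group-level ICC takes the low (0.05) and high (0.15) typical values.
ICC_SET_1 = ICCSpec(icc_level1=0.45, icc_level2=0.50, icc_level3=0.05)
ICC_SET_2 = ICCSpec(icc_level1=0.35, icc_level2=0.50, icc_level3=0.15)


def icc_to_variances(spec: ICCSpec) -> VarianceComponents:
    """Convert an ICC specification into intercept-pathway variances.

    Returns a :class:`VarianceComponents` with ``sigma2_e``,
    ``sigma2_r0`` and ``sigma2_u00`` set so that each equals its ICC
    proportion of the common total ``anchor_variance / anchor_icc``.
    Slope-pathway variances are left at zero; see
    :func:`default_variance_components` for the full generating set.
    """
    total = spec.total_variance
    return VarianceComponents(
        sigma2_e=spec.icc_level1 * total,
        sigma2_r0=spec.icc_level2 * total,
        sigma2_u00=spec.icc_level3 * total,
    )


def theoretical_icc(vc: VarianceComponents) -> tuple[float, float, float]:
    """Intercept-pathway ICCs implied by a set of variance components.

    Inverse of :func:`icc_to_variances`: each intercept-pathway variance
    divided by their sum.  The group-level ICC is defined conditionally
    on the covariates, i.e. from ``sigma2_u00`` alone.
    """
    parts = (vc.sigma2_e, vc.sigma2_r0, vc.sigma2_u00)
    total = sum(parts)
    if total <= 0.0:
        raise DesignError("intercept-pathway variances are all zero")
    return tuple(p / total for p in parts)


def default_variance_components(
    spec: ICCSpec,
    *,
    sigma2_r1: float = 0.5,
    sigma2_u01: float = 0.1,
    sigma2_u11: float = 0.1,
    sigma2_u10: float | None = None,
) -> VarianceComponents:
    """Full generating variance set: ICC-anchored intercepts plus slopes.

    The slope-pathway variances are free parameters of the design (they
    are not pinned down by the ICC specification).  Defaults: level-2
    slope variance 0.5; level-3 time-slope variance scaled from it by
    the level-3/level-2 ICC ratio; 0.1 for both group-level
    covariate-slope variances.
    """
    vc = icc_to_variances(spec)
    if sigma2_u10 is None:
        sigma2_u10 = sigma2_r1 * (spec.icc_level3 / spec.icc_level2)
    return replace(
        vc,
        sigma2_r1=sigma2_r1,
        sigma2_u01=sigma2_u01,
        sigma2_u10=sigma2_u10,
        sigma2_u11=sigma2_u11,
    )


@dataclass(frozen=True)
class DesignCondition:
    """One cell of the simulation grid.

    ``group_size_range`` is an inclusive integer interval; the number of
    individuals in each group is drawn uniformly from it (unbalanced
    design).
    """

    n_groups: int
    group_size_range: tuple[int, int]
    icc_spec: ICCSpec
    n_timepoints: int = 4
    n_replications: int = 500
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 3:
            raise DesignError(
                "a linear growth model needs at least 3 repeated measures"
            )
        lo, hi = self.group_size_range
        if lo < 1 or lo > hi:
            raise DesignError(f"invalid group_size_range {self.group_size_range}")
        if self.n_groups < 2:
            raise DesignError("need at least 2 groups")
        if self.n_replications < 1:
            raise DesignError("n_replications must be >= 1")

    @property
    def nominal_group_size(self) -> float:
        lo, hi = self.group_size_range
        return (lo + hi) / 2.0

    @property
    def label(self) -> str:
        icc3 = self.icc_spec.icc_level3
        return (
            f"icc3_{icc3:g}_J{self.n_groups}"
            f"_n{self.nominal_group_size:g}"
        )

    def seed_for_replication(self, r: int) -> int:
        """Deterministic per-replication seed (kept below 2**31)."""
        return (self.base_seed + r) % 2**31


@dataclass(frozen=True)
class GenerationParams:
    """True fixed effects and variance components driving generation."""

    fixed: FixedEffects = field(default_factory=FixedEffects)
    variances: VarianceComponents = field(
        default_factory=lambda: default_variance_components(ICC_SET_1)
    )

    def true_values(self) -> dict[str, float]:
        out = self.fixed.as_dict()
        out.update(self.variances.as_dict())
        return out


def _condition_seed(master_seed: int, index: int) -> int:
    # Spread conditions across the seed space; replication seeds are
    # consecutive offsets so streams never collide within a grid.
    return (master_seed * 1_000_003 + index * 1_048_576 + 12_345) % 2**31


def build_condition_grid(
    master_seed: int = 0,
    n_replications: int = 500,
    n_timepoints: int = 4,
) -> list[DesignCondition]:
    """The full 2 (ICC set) x 3 (groups) x 2 (group size) grid.

    Ordering is deterministic: ICC set 1 before set 2, then 30/50/100
    groups, then group-size range [5,15] before [15,45].  Each condition
    gets a distinct, reproducible seed derived from ``master_seed``.
    """
    grid = []
    combos = itertools.product(
        (ICC_SET_1, ICC_SET_2),
        (30, 50, 100),
        ((5, 15), (15, 45)),
    )
    for index, (icc, n_groups, size_range) in enumerate(combos):
        grid.append(
            DesignCondition(
                n_groups=n_groups,
                group_size_range=size_range,
                icc_spec=icc,
                n_timepoints=n_timepoints,
                n_replications=n_replications,
                base_seed=_condition_seed(master_seed, index),
            )
        )
    return grid
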