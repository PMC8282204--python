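"""Synthetic-data generation for the three-level growth model.

One dataset is a long-format table of repeated measures: occasions
``t = 0..T-1`` nested in individuals nested in groups.  The outcome is

    y_tij = (g000 + g001*z_j + u00_j) + (g010 + u01_j)*x_ij + r0_ij
            + [(g100 + g101*z_j + u10_j) + (g110 + u11_j)*x_ij + r1_ij]*t
            + e_tij

with X ~ N(0,1) at the individual level, Z ~ N(0,1) at the group level
and mean-zero normal random effects at every level.  Group sizes are
drawn independently from a discrete uniform on an inclusive range, so
the design is unbalanced.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    DesignCondition,
    DesignError,
    FixedEffects,
    VarianceComponents,
)

__all__ = ["LongDataset", "draw_group_sizes", "generate_dataset",
           "write_csv", "read_csv"]

COLUMNS = ("group_id", "individual_id", "time", "x", "z", "y")


@dataclass
class LongDataset:
    """Long-format observations plus provenance bookkeeping.

    ``data`` has one row per (group, individual, occasion) with columns
    ``group_id, individual_id, time, x, z, y``; ``individual_id`` is
    unique within its group, ``z`` constant within a group and ``x``
    constant within an individual.
    """

    data: pd.DataFrame
    n_timepoints: int
    condition_label: str = ""
    replication: int = -1
    seed: int | None = None

    @property
    def n_groups(self) -> int:
        return self.data["group_id"].nunique()

    @property
    def n_individuals(self) -> int:
        return len(self.data) // self.n_timepoints

    def validate(self) -> None:
        if list(self.data.columns) != list(COLUMNS):
            raise DesignError(f"expected columns {COLUMNS}")
        counts = self.data.groupby(["group_id", "individual_id"])["time"].agg(
            ["count", "min", "max"]
        )
        if not (counts["count"] == self.n_timepoints).all():
            raise DesignError("every individual must have exactly T occasions")
        if not ((counts["min"] == 0) & (counts["max"] == self.n_timepoints - 1)).all():
            raise DesignError("occasions must be coded 0..T-1")


def draw_group_sizes(condition: DesignCondition, rng: np.random.Generator) -> np.ndarray:
    """Independent discrete-uniform group sizes on the inclusive range."""
    lo, hi = condition.group_size_range
    return rng.integers(lo, hi + 1, size=condition.n_groups)


def generate_dataset(
    fx: FixedEffects,
    vc: VarianceComponents,
    condition: DesignCondition,
    seed: int,
    replication: int = -1,
) -> LongDataset:
    """Draw one replication of the generating model.

    The draw order is fixed (group sizes, Z, level-3 effects, X,
    level-2 effects, level-1 residuals) so the same seed always yields
    a bit-identical dataset.
    """
    vc.validate_for_generation()
    rng = np.random.default_rng(seed)
    T = condition.n_timepoints
    J = condition.n_groups

    sizes = draw_group_sizes(condition, rng)
    N = int(sizes.sum())

    z = rng.standard_normal(J)
    u = _draw_level3(vc, J, rng)                      # (J, 4): u00, u01, u10, u11
    x = rng.standard_normal(N)
    r = _draw_level2(vc, N, rng)                      # (N, 2): r0, r1
    e = np.sqrt(vc.sigma2_e) * rng.standard_normal(N * T)

    g_of_i = np.repeat(np.arange(J), sizes)           # group index per individual
    zi = z[g_of_i]
    intercept = (
        fx.gamma_000 + fx.gamma_001 * zi + u[g_of_i, 0]
        + (fx.gamma_010 + u[g_of_i, 1]) * x
        + r[:, 0]
    )
    slope = (
        fx.gamma_100 + fx.gamma_101 * zi + u[g_of_i, 2]
        + (fx.gamma_110 + u[g_of_i, 3]) * x
        + r[:, 1]
    )

    t = np.tile(np.arange(T), N)
    y = np.repeat(intercept, T) + np.repeat(slope, T) * t + e

    individual_id = np.concatenate([np.arange(n) for n in sizes])
    frame = pd.DataFrame(
        {
            "group_id": np.repeat(g_of_i, T),
            "individual_id": np.repeat(individual_id, T),
            "time": t,
            "x": np.repeat(x, T),
            "z": np.repeat(zi, T),
            "y": y,
        }
    )
    return LongDataset(
        data=frame,
        n_timepoints=T,
        condition_label=condition.label,
        replication=replication,
        seed=seed,
    )


def _draw_level3(vc: VarianceComponents, J: int, rng: np.random.Generator) -> np.ndarray:
    var = np.array([vc.sigma2_u00, vc.sigma2_u01, vc.sigma2_u10, vc.sigma2_u11])
    if vc.sigma_u_offdiag == 0.0:
        return np.sqrt(var) * rng.standard_normal((J, 4))
    cov = np.full((4, 4), vc.sigma_u_offdiag)
    np.fill_diagonal(cov, var)
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((J, 4)) @ chol.T


def _draw_level2(vc: VarianceComponents, N: int, rng: np.random.Generator) -> np.ndarray:
    var = np.array([vc.sigma2_r0, vc.sigma2_r1])
    if vc.sigma_r01 == 0.0:
        return np.sqrt(var) * rng.standard_normal((N, 2))
    cov = np.array([[vc.sigma2_r0, vc.sigma_r01], [vc.sigma_r01, vc.sigma2_r1]])
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((N, 2)) @ chol.T


def write_csv(dataset: LongDataset, path_or_buf) -> None:
    """Write the long table as CSV, exact to 17 significant digits."""
    dataset.data.to_csv(path_or_buf, index=False, float_format="%.17g")


def read_csv(path_or_buf, n_timepoints: int | None = None) -> LongDataset:
    """Read a long-format CSV back into a :class:`LongDataset`."""
    frame = pd.read_csv(path_or_buf, float_precision="round_trip")
    missing = set(COLUMNS) - set(frame.columns)
    if missing:
        raise DesignError(f"CSV is missing columns {sorted(missing)}")
    frame = frame.loc[:, list(COLUMNS)]
    if n_timepoints is None:
        n_timepoints = int(frame["time"].max()) + 1
    ds = LongDataset(data=frame, n_timepoints=n_timepoints)
    ds.validate()
    return ds


def to_csv_bytes(dataset: LongDataset) -> bytes:
    buf = io.StringIO()
    write_csv(dataset, buf)
    return buf.getvalue().encode()
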