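"""Per-group structural covariance networks as covariate-adjusted partial correlations.

A group's network is the Pearson correlation matrix of its subjects' ROI
volumes after removing the linear effects of nuisance covariates (age, sex)
from every region column.  This "pairwise correlation given covariates"
reading is deliberate: full inverse-covariance partialling over all p regions
is singular whenever p exceeds the group size (p = 61 regions vs groups as
small as n = 17 in the motivating cohort), so the covariate-residualization
form is the only estimable one at these sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .tabular_io import ParticipantTable, ROIVolumeTable

__all__ = ["GroupNetwork", "residualize", "partial_correlation_matrix", "build_group_networks"]


@dataclass(frozen=True)
class GroupNetwork:
    """One group's p x p partial-correlation matrix over named regions."""

    group: str
    r: np.ndarray = field(repr=False)
    n_subjects: int
    n_covariates: int
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        r = self.r
        if r.shape != (len(self.region_names),) * 2:
            raise ValidationError(f"group {self.group}: matrix shape {r.shape} does not match region count")
        if not np.array_equal(r, r.T):
            raise ValidationError(f"group {self.group}: correlation matrix is not exactly symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValidationError(f"group {self.group}: correlation diagonal is not 1")
        if np.abs(r).max() > 1 + 1e-12:
            raise ValidationError(f"group {self.group}: entries outside [-1, 1]")
        if self.n_subjects <= self.n_covariates + 2:
            raise ValidationError(
                f"group {self.group}: n={self.n_subjects} too small for {self.n_covariates} covariates"
            )

    @property
    def residual_dof(self) -> int:
        """Residual degrees of freedom after the intercept and covariates (n - c - 1)."""
        return self.n_subjects - self.n_covariates - 1


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of every column of ``values`` on [1, covariates].

    An intercept column is always included, so with no covariates the result
    is simply each column minus its mean.  Raises if the augmented design
    matrix is rank-deficient (e.g. a constant covariate colliding with the
    intercept) rather than silently dropping a column.
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        design = np.ones((n, 1))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n:
            raise ValidationError(f"covariates have {c.shape[0]} rows for {n} subjects")
        design = np.column_stack([np.ones(n), c])
    if n <= design.shape[1]:
        raise ValidationError(f"n={n} subjects cannot support {design.shape[1] - 1} covariates plus intercept")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValidationError(
            f"rank-deficient covariate design (rank {rank} < {design.shape[1]} columns); "
            "a covariate is constant or collinear"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_correlation_matrix(
    values: np.ndarray,
    covariates: np.ndarray | None,
    group: str,
    region_names: Sequence[str],
) -> GroupNetwork:
    """Covariate-adjusted partial-correlation network for one group."""
    resid = residualize(values, covariates)
    sd = resid.std(axis=0)
    dead = [region_names[j] for j in np.flatnonzero(sd < 1e-12)]
    if dead:
        raise ValidationError(f"zero-variance residual column(s) in group {group}: {dead}")
    r = np.corrcoef(resid, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    n_cov = 0 if covariates is None else np.atleast_2d(np.asarray(covariates).T).shape[0]
    return GroupNetwork(
        group=group,
        r=r,
        n_subjects=values.shape[0],
        n_covariates=n_cov,
        region_names=tuple(region_names),
    )


def build_group_networks(
    participants: ParticipantTable,
    volumes: ROIVolumeTable,
    covariate_columns: Sequence[str] = ("age", "sex"),
) -> Mapping[str, GroupNetwork]:
    """One partial-correlation network per group, in group first-appearance order."""
    if participants.subject_ids != volumes.subject_ids:
        raise ValidationError("participants and volumes are not row-aligned")
    cov = participants.covariates(covariate_columns) if covariate_columns else None
    vals = volumes.values
    nets = {}
    for g in participants.groups:
        idx = participants.group_indices(g)
        nets[g] = partial_correlation_matrix(
            vals[idx], None if cov is None else cov[idx], g, volumes.region_names
        )
    return nets
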