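"""Blend-model deconvolution of co-culture expression profiles.

When two cell types A and B are mixed in co-culture, most genes simply
reflect the proportional contribution of each cell type's mRNA to the pooled
transcript abundance.  For gene *n* with linear-scale expression ratios
``e_A``, ``e_B`` (the monocultures) and ``e_co`` (the co-culture), the model
is

    e_co[n] = (a * e_A[n] + (1 - a) * e_B[n]) * I[n]

where ``a`` in (0, 1) is the global mixing proportion and ``I[n] > 0`` is the
per-gene heterotypic interaction factor — the fold deviation of the observed
co-culture expression from the proportionally weighted blend.  The
identifying assumption is that the *average* gene is not affected by the
interaction (I = 1), so ``a`` is estimated by a one-parameter regression of
``e_co`` on the two monoculture profiles without per-gene terms, with Gamma
errors and identity link (expression ratios are positive and right-skewed,
with noise roughly proportional to the mean).  Given ``a``, the equations are
solved per gene for ``I``.

:class:`InteractionModel` is the statsmodels-style entry point; its
:meth:`~InteractionModel.fit` returns an :class:`InteractionResults` carrying
the estimate, its standard error, the per-gene interaction factors and a
``summary()`` table.  Profiles of log2 interaction factors across several
co-cultures can then be screened with :func:`missingness_filter` and
:func:`filter_interaction_factors` and analyzed exactly like ordinary
expression matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .io import ExperimentDesign

__all__ = [
    "CoCultureTriplet",
    "make_triplet",
    "InteractionModel",
    "InteractionResults",
    "UnidentifiableError",
    "interaction_profile",
    "missingness_filter",
    "filter_interaction_factors",
]

A_MIN, A_MAX = 1e-3, 1 - 1e-3


class UnidentifiableError(ValueError):
    """The mixing proportion cannot be identified from the given triplet."""


@dataclass
class CoCultureTriplet:
    """Replicate-averaged linear-scale expression for one co-culture experiment.

    All three vectors are aligned on ``gene_ids`` and strictly positive;
    genes missing in any role have been dropped (``n_dropped``,
    ``dropped_genes``).
    """

    gene_ids: pd.Index
    e_mono_a: np.ndarray
    e_mono_b: np.ndarray
    e_co: np.ndarray
    n_dropped: int = 0
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if not (len(self.e_mono_a) == len(self.e_mono_b) == len(self.e_co) == n):
            raise ValueError("triplet vectors must share the gene axis")
        for name in ("e_mono_a", "e_mono_b", "e_co"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"{name} must be finite and strictly positive")

    def __len__(self) -> int:
        return len(self.gene_ids)


def make_triplet(matrix: pd.DataFrame, design: ExperimentDesign) -> CoCultureTriplet:
    """Collapse replicates of a log2-ratio matrix into a linear-scale triplet.

    Replicate log2 ratios are averaged within each role and transformed to
    linear scale ``2**mean`` (a geometric mean of linear ratios).  Genes with
    a missing average in any role are dropped and counted.
    """
    design.require_all_roles()
    means = {}
    for role in ("monoculture_A", "monoculture_B", "coculture"):
        cols = design.samples(role)
        absent = [c for c in cols if c not in matrix.columns]
        if absent:
            raise ValueError(f"design sample(s) not in matrix: {absent}")
        means[role] = matrix[cols].mean(axis=1, skipna=False)
    stacked = pd.DataFrame(means)
    ok = stacked.notna().all(axis=1)
    dropped = list(stacked.index[~ok].astype(str))
    kept = stacked.loc[ok]
    return CoCultureTriplet(
        gene_ids=kept.index,
        e_mono_a=np.exp2(kept["monoculture_A"].to_numpy()),
        e_mono_b=np.exp2(kept["monoculture_B"].to_numpy()),
        e_co=np.exp2(kept["coculture"].to_numpy()),
        n_dropped=len(dropped),
        dropped_genes=dropped,
    )


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    # 2 * sum[(y - mu)/mu - log(y/mu)]; both y and mu strictly positive here
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


class InteractionModel:
    """One-parameter Gamma/identity blend regression for a co-culture triplet.

    Parameters
    ----------
    triplet
        Aligned positive expression vectors for the two monocultures
        (predictors) and the co-culture (response).
    min_genes
        Minimum number of genes required for a fit.
    collinearity_limit
        Pearson correlation between the two monoculture vectors above which
        the mixing proportion is declared unidentifiable.
    """

    def __init__(
        self,
        triplet: CoCultureTriplet,
        *,
        min_genes: int = 10,
        collinearity_limit: float = 0.999,
    ) -> None:
        if len(triplet) < min_genes:
            raise ValueError(
                f"need at least {min_genes} genes to fit, got {len(triplet)}"
            )
        r = np.corrcoef(triplet.e_mono_a, triplet.e_mono_b)[0, 1]
        if not np.isfinite(r) or abs(r) > collinearity_limit:
            raise UnidentifiableError(
                "monoculture profiles are (near-)proportional; "
                f"|r| = {abs(r):.6f} exceeds {collinearity_limit}"
            )
        self.triplet = triplet
        self._y = triplet.e_co
        self._xa = triplet.e_mono_a
        self._xb = triplet.e_mono_b

    # -- likelihood machinery -------------------------------------------------

    def blend(self, a: float | np.ndarray) -> np.ndarray:
        """Model mean a*e_A + (1-a)*e_B; vectorized over ``a``."""
        a = np.asarray(a, dtype=float)
        return np.multiply.outer(a, self._xa) + np.multiply.outer(1.0 - a, self._xb)

    def deviance(self, a: float | np.ndarray) -> float | np.ndarray:
        """Gamma deviance of the blend at mixing proportion(s) ``a``.

        For fixed dispersion, minimizing this deviance over ``a`` is the
        Gamma maximum-likelihood fit with identity link.
        """
        mu = self.blend(a)
        dev = 2.0 * np.sum((self._y - mu) / mu - np.log(self._y / mu), axis=-1)
        return float(dev) if np.isscalar(a) or np.ndim(a) == 0 else dev

    def fit(self) -> "InteractionResults":
        """Estimate the mixing proportion by bounded Gamma ML and solve for I."""
        res = optimize.minimize_scalar(
            self.deviance, bounds=(A_MIN, A_MAX), method="bounded",
            options={"xatol": 1e-10},
        )
        a_hat = float(np.clip(res.x, A_MIN, A_MAX))
        if a_hat <= A_MIN + 1e-9 or a_hat >= A_MAX - 1e-9:
            warnings.warn(
                f"mixing proportion estimate {a_hat:.4f} at the boundary of (0, 1); "
                "a pure monoculture blend is biologically implausible",
                stacklevel=2,
            )
        mu = self.blend(a_hat)
        # Pearson dispersion and observed information for identity-link Gamma
        n = len(self._y)
        pearson = np.sum(((self._y - mu) / mu) ** 2)
        dispersion = float(pearson / max(n - 1, 1))
        x = self._xa - self._xb
        info = np.sum(x * x / mu**2)
        se = float(np.sqrt(dispersion / info)) if info > 0 else np.nan
        return InteractionResults(
            model=self,
            a=a_hat,
            bse=se,
            deviance=float(res.fun),
            dispersion=dispersion,
            n_genes_fit=n,
            converged=bool(res.success),
            n_iterations=int(res.nfev),
        )


@dataclass
class InteractionResults:
    """Fitted blend model: mixing proportion, diagnostics and interaction factors."""

    model: InteractionModel
    a: float
    bse: float
    deviance: float
    dispersion: float
    n_genes_fit: int
    converged: bool
    n_iterations: int

    @property
    def gene_ids(self) -> pd.Index:
        return self.model.triplet.gene_ids

    @property
    def fittedvalues(self) -> pd.Series:
        """Blend prediction a*e_A + (1-a)*e_B per gene."""
        return pd.Series(self.model.blend(self.a), index=self.gene_ids, name="blend")

    @property
    def interaction_factors(self) -> pd.Series:
        """Per-gene interaction factor I = e_co / blend (positive)."""
        i = self.model.triplet.e_co / self.model.blend(self.a)
        return pd.Series(i, index=self.gene_ids, name="I")

    @property
    def log2_interaction_factors(self) -> pd.Series:
        out = np.log2(self.interaction_factors)
        out.name = "log2_I"
        return out

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Wald interval for the mixing proportion."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return (self.a - z * self.bse, self.a + z * self.bse)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Heterotypic interaction blend model (Gamma errors, identity link)",
            "=" * 66,
            f"genes fit            {self.n_genes_fit:>10d}",
            f"mixing proportion a  {self.a:>10.4f}  (SE {self.bse:.4f}, "
            f"95% CI [{lo:.4f}, {hi:.4f}])",
            f"deviance             {self.deviance:>10.4f}",
            f"dispersion (Pearson) {self.dispersion:>10.4f}",
            f"converged            {str(self.converged):>10s}  "
            f"({self.n_iterations} objective evaluations)",
            "-" * 66,
            "interaction factors I = e_co / (a*e_A + (1-a)*e_B):",
            f"  geometric mean {np.exp(np.mean(np.log(self.interaction_factors))):.4f}"
            f", median {self.interaction_factors.median():.4f}"
            f", max {self.interaction_factors.max():.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready fit report."""
        return {
            "a": self.a,
            "bse": self.bse,
            "deviance": self.deviance,
            "dispersion": self.dispersion,
            "n_genes_fit": self.n_genes_fit,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }


def interaction_profile(
    fits: Sequence[InteractionResults], names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Assemble log2 interaction factors across co-cultures into a matrix.

    Rows are the union of gene ids, columns one per co-culture; a gene absent
    from a given fit yields a missing cell.  The result can be clustered and
    filtered like any expression matrix.
    """
    if not fits:
        raise ValueError("no fits given")
    if names is None:
        names = [f"coculture_{i + 1}" for i in range(len(fits))]
    cols = {n: f.log2_interaction_factors for n, f in zip(names, fits)}
    profile = pd.DataFrame(cols)
    if len(fits) > 1 and int(profile.notna().sum(axis=1).max()) <= 1:
        raise ValueError("fits have pairwise disjoint gene sets; no shared universe")
    return profile


def missingness_filter(
    matrix: pd.DataFrame, max_missing_fraction: float = 0.2
) -> pd.DataFrame:
    """Drop genes missing in more than ``max_missing_fraction`` of the arrays."""
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    frac = matrix.isna().sum(axis=1) / matrix.shape[1]
    return matrix.loc[frac <= max_missing_fraction]


def filter_interaction_factors(
    profile: pd.DataFrame,
    sd_threshold: float = 2.0,
    min_cocultures: int = 2,
    mode: Literal["retain_extreme", "eliminate_within"] = "retain_extreme",
) -> list[str]:
    """Select interaction-responsive genes by per-co-culture spread.

    Within each co-culture column, a gene *qualifies* if its log2 interaction
    factor lies at least ``sd_threshold`` column standard deviations from the
    column mean (inclusive boundary).  ``mode='retain_extreme'`` keeps genes
    qualifying in at least ``min_cocultures`` columns; ``mode=
    'eliminate_within'`` instead drops genes that are *within* the threshold
    in at least ``min_cocultures`` columns.  The two readings differ for
    genes extreme in exactly one co-culture; the default keeps only genes
    showing a reproducible interaction response.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be > 0")
    if min_cocultures < 1:
        raise ValueError("min_cocultures must be >= 1")
    mean = profile.mean(axis=0, skipna=True)
    sd = profile.std(axis=0, ddof=1, skipna=True)
    z = (profile - mean).abs().div(sd.where(sd > 0), axis=1)
    extreme = (z >= sd_threshold).fillna(False)
    if mode == "retain_extreme":
        keep = extreme.sum(axis=1) >= min_cocultures
    elif mode == "eliminate_within":
        within = (~extreme) & profile.notna()
        keep = ~(within.sum(axis=1) >= min_cocultures)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return list(profile.index[keep])
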