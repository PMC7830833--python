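"""Environmental ordination: PCA of site-level habitat variables and
per-axis environmental distance matrices.

Riverine study sites are characterised by a panel of physicochemical and
topographic variables (flow, width, slope, altitude, conductivity, BOD,
suspended matter, nitrate, nitrite, orthophosphate, oxygen, pH, oxygen
saturation, temperature).  Because the variables mix units, the default
PCA standardises each variable (correlation PCA); the leading axes act as
synthetic environmental gradients, and the absolute difference in site
scores along one retained axis is that axis's environmental distance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn.decomposition import PCA

#: the canonical 14-variable panel (order is cosmetic; any >=2 variables work)
ENV_VARIABLES: tuple[str, ...] = (
    "flow", "width", "slope", "altitude", "conductivity", "bod", "sm",
    "nitrate", "nitrite", "orthophosphate", "oxygen", "ph",
    "oxygen_saturation", "temperature",
)


@dataclass
class PCAResult:
    """Loadings, site scores and variance fractions of an environmental PCA.

    Axis numbering is 1-based everywhere (``PC1`` is the leading axis).
    """

    loadings: pd.DataFrame          # variables x components
    scores: pd.DataFrame            # sites x components
    variance_fraction: np.ndarray   # per component, of the total variance
    retained: tuple[int, ...]       # 1-based retained axis indices
    scaled: bool

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)


def _validate_env(env: pd.DataFrame) -> None:
    if env.isna().any().any():
        raise ValueError("environmental table contains missing cells")
    if env.shape[0] < 3:
        raise ValueError("need at least 3 sites")
    if env.shape[1] < 2:
        raise ValueError("need at least 2 environmental variables")


def run_pca(env: pd.DataFrame, scale: bool = True) -> PCAResult:
    """Principal component analysis of a sites x variables table.

    With ``scale`` (the default) each variable is centred and divided by
    its sample standard deviation, i.e. a correlation-matrix PCA, which
    keeps variables on incommensurable units from dominating the axes.
    Components are ordered by decreasing variance and each loading column
    is sign-flipped so that its largest-magnitude entry is positive — PCA
    signs are arbitrary and this convention makes reports reproducible.
    """
    _validate_env(env)
    x = env.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"variable {env.columns[zero[0]]!r} has zero variance; "
                "cannot standardise (set scale=False or drop it)"
            )
        x = x / sd

    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # variables x components

    # deterministic sign convention
    for j in range(n_comp):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    total_var = x.var(axis=0, ddof=1).sum()
    frac = pca.explained_variance_ / total_var
    comps = [f"PC{j + 1}" for j in range(n_comp)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=env.columns, columns=comps),
        scores=pd.DataFrame(scores, index=env.index, columns=comps),
        variance_fraction=frac,
        retained=tuple(range(1, n_comp + 1)),
        scaled=scale,
    )


def retain_components(p: PCAResult, rule: dict | None = None) -> PCAResult:
    """Mark the retained axis set.

    ``rule`` is ``{"fixed_count": k}`` (default k=3) or
    ``{"cum_variance": q}`` which keeps the smallest leading set whose
    cumulative variance fraction reaches q.
    """
    rule = rule or {"fixed_count": 3}
    n = len(p.components)
    if "fixed_count" in rule:
        k = int(rule["fixed_count"])
        if not 1 <= k <= n:
            raise ValueError(f"fixed_count must be in [1, {n}], got {k}")
        retained = tuple(range(1, k + 1))
    elif "cum_variance" in rule:
        q = float(rule["cum_variance"])
        if not 0 < q <= 1:
            raise ValueError("cum_variance must be in (0, 1]")
        cum = np.cumsum(p.variance_fraction)
        k = int(np.searchsorted(cum, q - 1e-12) + 1)
        retained = tuple(range(1, min(k, n) + 1))
    else:
        raise ValueError("rule must contain 'fixed_count' or 'cum_variance'")
    return replace(p, retained=retained)


def component_distances(p: PCAResult, axis: int) -> DistanceMatrix:
    """One-dimensional Euclidean distance between sites along one axis.

    ``D(a, b) = |score(a, axis) - score(b, axis)|`` for a retained axis
    (1-based).  One matrix per retained axis gives the per-gradient
    environmental predictors.
    """
    if axis not in p.retained:
        raise ValueError(f"axis {axis} is not retained (retained: {p.retained})")
    s = p.scores[f"PC{axis}"].to_numpy()
    d = np.abs(s[:, None] - s[None, :])
    return DistanceMatrix(d, ids=[str(i) for i in p.scores.index])


def retained_distances(p: PCAResult) -> dict[int, DistanceMatrix]:
    """Environmental distance matrices for every retained axis."""
    return {axis: component_distances(p, axis) for axis in p.retained}
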