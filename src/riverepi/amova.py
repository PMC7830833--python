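"""Two-level distance-based analysis of molecular variance (AMOVA).

AMOVA partitions squared inter-individual molecular distances into
among-population and within-population variance components.  With
squared-Euclidean distances the decomposition is the classical nested
ANOVA identity written on pairwise distances:

    SS_total  = (1/N)   sum_{i<j}        d2_ij
    SS_within = sum_p (1/n_p) sum_{i<j in p} d2_ij
    SS_among  = SS_total - SS_within

    sigma2_w = SS_within / (N - P)
    sigma2_a = (SS_among/(P-1) - sigma2_w) / n0,
    n0 = (N - sum n_p^2 / N) / (P - 1)

Phi_st = sigma2_a / (sigma2_a + sigma2_w) is the fixation analogue, and
its significance comes from permuting individual population labels
(one-tailed: large Phi_st means more structure).  Only individual-level
markers enter: pooled SNP frequencies carry no within-population
component and are rejected by type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .msaflp import FourStateMatrix


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    sigma2_among: float
    sigma2_within: float
    pct_variation_among: float
    phi_st: float
    p_value: float
    n_permutations: int
    degenerate: bool = False

    def clamped(self) -> "AmovaResult":
        """Display variant with a negative among-population component set to 0."""
        if self.sigma2_among >= 0 or self.degenerate:
            return self
        return AmovaResult(
            self.df_among, self.df_within, self.ss_among, self.ss_within,
            self.ss_total, 0.0, self.sigma2_within, 0.0, 0.0,
            self.p_value, self.n_permutations,
        )

    def to_frame(self) -> pd.DataFrame:
        """One AMOVA table in the conventional report layout."""
        return pd.DataFrame(
            {
                "source": ["among_populations", "within_populations", "total"],
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "sum_of_squares": [self.ss_among, self.ss_within, self.ss_total],
                "variance_component": [self.sigma2_among, self.sigma2_within, np.nan],
                "pct_variation": [self.pct_variation_among,
                                  100.0 - self.pct_variation_among, np.nan],
                "phi_st": [self.phi_st, np.nan, np.nan],
                "p_value": [self.p_value, np.nan, np.nan],
            }
        )


def _epi4_squared_distances(m: FourStateMatrix) -> DistanceMatrix:
    # mismatch count over loci; one-hot matmuls keep this O(N^2 L) in BLAS
    from .msaflp import STATES

    vals = m.states.to_numpy(dtype=object)
    n, L = vals.shape
    scored = (~pd.isna(pd.DataFrame(vals))).to_numpy().astype(float)
    matches = np.zeros((n, n))
    for s in STATES:
        x = (vals == s).astype(float)
        matches += x @ x.T
    compared = scored @ scored.T
    return _finalise_mismatch(matches, compared, L, list(m.states.index))


def _microsat_squared_distances(g: pd.DataFrame) -> DistanceMatrix:
    # per-locus distance = 2 - shared allele copies, in {0, 1, 2}
    g = g.set_index("individual") if "individual" in g.columns else g
    allele_cols = [c for c in g.columns if c.endswith(("_a1", "_a2"))]
    loci = sorted({c[:-3] for c in allele_cols})
    if not loci:
        raise ValueError("no <locus>_a1/<locus>_a2 columns found")
    n = len(g.index)
    dist_sum = np.zeros((n, n))
    compared = np.zeros((n, n))
    for locus in loci:
        a1 = g[f"{locus}_a1"].astype("string")
        a2 = g[f"{locus}_a2"].astype("string")
        scored = ~(a1.isna() & a2.isna())
        alleles = sorted(set(a1.dropna()) | set(a2.dropna()))
        counts = np.zeros((n, len(alleles)))
        for k, al in enumerate(alleles):
            counts[:, k] = (a1 == al).to_numpy(dtype=float) + (a2 == al).to_numpy(dtype=float)
        shared = np.minimum(counts[:, None, :], counts[None, :, :]).sum(axis=2)
        both = np.outer(scored, scored).astype(float)
        dist_sum += both * (2.0 - shared)
        compared += both
    return _finalise_mismatch(None, compared, len(loci), list(g.index), raw=dist_sum)


def _finalise_mismatch(matches, compared, n_loci, ids, raw=None):
    if raw is None:
        raw = compared - matches
    off = ~np.eye(len(ids), dtype=bool)
    if (compared[off] == 0).any():
        i, j = np.argwhere((compared == 0) & off)[0]
        raise ValueError(f"individuals {ids[i]!r} and {ids[j]!r} share no scored locus")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(compared > 0, raw / compared * n_loci, 0.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry against float noise
    return DistanceMatrix(d, ids=[str(i) for i in ids])


def individual_distance_matrix(markers, metric: str | None = None) -> DistanceMatrix:
    """Squared inter-individual distance matrix for AMOVA.

    For a :class:`FourStateMatrix` (``epi4`` metric) the squared distance
    is the count of loci with differing methylation conditions; for a
    diploid genotype table (``microsat``) it is the per-locus count of
    non-shared allele copies (0, 1 or 2) summed over loci.  Both are
    squared-Euclidean on indicator codings, which is what licenses the
    ANOVA decomposition.  Pairs with missing loci use the mean per-locus
    distance over compared loci, rescaled to the full locus count.
    """
    if isinstance(markers, FourStateMatrix):
        if metric not in (None, "epi4"):
            raise ValueError("four-state matrices use the epi4 metric")
        if len(markers.individuals) < 2:
            raise ValueError("need at least 2 individuals")
        return _epi4_squared_distances(markers)
    if isinstance(markers, pd.DataFrame):
        if metric not in (None, "microsat"):
            raise ValueError("genotype tables use the microsat metric")
        if len(markers) < 2:
            raise ValueError("need at least 2 individuals")
        return _microsat_squared_distances(markers)
    raise TypeError(
        "AMOVA accepts only individual-level markers (four-state matrix or "
        "genotype table); population-level pooled frequencies carry no "
        "within-population component"
    )


def _ss_within(d: np.ndarray, z: np.ndarray, sizes: np.ndarray) -> float:
    w = d @ z
    return float(((z * w).sum(axis=0) / (2.0 * sizes)).sum())


def amova_two_level(
    d2: DistanceMatrix,
    populations: pd.Series,
    n_perm: int = 1000,
    seed=None,
) -> AmovaResult:
    """Two-level AMOVA with a one-tailed permutation test on Phi_st.

    ``d2`` holds *squared* distances.  The observed labelling is included
    in the permutation null (the +1 convention), so the p-value lies in
    (0, 1].  A negative among-population component is reported as
    computed; use :meth:`AmovaResult.clamped` for display.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    populations = pd.Series(populations)
    ids = list(d2.ids)
    missing = [i for i in ids if i not in populations.index]
    if missing:
        raise ValueError(f"individual {missing[0]!r} has no population label")
    labels = populations.loc[ids]
    pops = sorted(labels.unique())
    P, N = len(pops), len(ids)
    if P < 2:
        raise ValueError("need at least 2 populations")
    sizes = labels.value_counts().loc[pops].to_numpy(dtype=float)
    if (sizes < 2).any():
        small = pops[int(np.argmin(sizes))]
        raise ValueError(f"population {small!r} has fewer than 2 individuals")

    d = d2.data
    z = np.zeros((N, P))
    codes = pd.Categorical(labels, categories=pops).codes
    z[np.arange(N), codes] = 1.0

    ss_total = float(d.sum()) / (2.0 * N)
    df_among, df_within = P - 1, N - P
    n0 = (N - (sizes**2).sum() / N) / df_among

    def components(ssw: float) -> tuple[float, float, float]:
        s2w = ssw / df_within
        s2a = ((ss_total - ssw) / df_among - s2w) / n0
        tot = s2a + s2w
        phi = s2a / tot if tot != 0 else np.nan
        return s2w, s2a, phi

    ssw_obs = _ss_within(d, z, sizes)
    s2w, s2a, phi = components(ssw_obs)

    if d.max() == 0.0:
        return AmovaResult(
            df_among, df_within, ss_total - ssw_obs, ssw_obs, ss_total,
            0.0, 0.0, np.nan, np.nan, np.nan, n_perm, degenerate=True,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zp = z[rng.permutation(N)]
        _, _, phi_p = components(_ss_within(d, zp, sizes))
        if phi_p >= phi:
            count += 1
    p = (1 + count) / (n_perm + 1)

    tot = s2a + s2w
    pct = 100.0 * s2a / tot if tot != 0 else np.nan
    return AmovaResult(
        df_among, df_within, ss_total - ssw_obs, ssw_obs, ss_total,
        s2a, s2w, pct, phi, p, n_perm,
    )
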