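"""Per-population allele/state frequencies and pairwise Gst'' differentiation.

One frequency container and one Gst'' engine serve three marker systems:

* ``epi4`` — MS-AFLP epiloci treated as haploid four-allele loci (one
  methylation state per individual per locus);
* ``microsat`` — codominant diploid microsatellites counted as allele
  copies (n = 2 x scored individuals);
* ``snp_pool`` — pooled-sequencing SNPs, frequency-only (no individual
  genotypes, hence no sample-size correction possible).

Gst'' is the standardised differentiation measure of Meirmans & Hedrick:

    Gst'' = k (HT - HS) / ((k HT - HS)(1 - HS)),  k = number of populations

with per-locus HS the mean within-population gene diversity 1 - sum(p^2),
HT the gene diversity of the pooled mean frequencies, and HS/HT averaged
across loci *before* the ratio.  It reaches 1 for fixed differences even
at high within-population diversity, which makes the three marker systems
comparable on one scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .msaflp import STATES, FourStateMatrix


@dataclass
class FrequencyTable:
    """Populations x loci x states frequency array.

    ``freqs`` maps locus -> (populations x states) DataFrame whose rows sum
    to 1, or are all-NaN when the population was not scored at the locus.
    ``n`` maps locus -> per-population sample size (individuals for epi4,
    allele copies for microsatellites); ``None`` for pooled SNPs.
    """

    marker_kind: str  # epi4 | microsat | snp_pool
    freqs: dict[str, pd.DataFrame]
    n: dict[str, pd.Series] | None = None

    def __post_init__(self) -> None:
        if self.marker_kind not in ("epi4", "microsat", "snp_pool"):
            raise ValueError(f"unknown marker kind {self.marker_kind!r}")
        pops = None
        for locus, f in self.freqs.items():
            if pops is None:
                pops = list(f.index)
            elif list(f.index) != pops:
                raise ValueError(f"population set differs at locus {locus!r}")
            arr = f.to_numpy(dtype=float)
            scored = ~np.isnan(arr).all(axis=1)
            sums = arr[scored].sum(axis=1)
            if scored.any() and np.abs(sums - 1.0).max() > 1e-9:
                raise ValueError(f"frequencies at locus {locus!r} do not sum to 1")
            if scored.any() and ((arr[scored] < -1e-12) | (arr[scored] > 1 + 1e-12)).any():
                raise ValueError(f"frequency outside [0, 1] at locus {locus!r}")

    @property
    def populations(self) -> list[str]:
        first = next(iter(self.freqs.values()))
        return list(first.index)

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)


@dataclass
class GstComponents:
    """Diversity components behind one pairwise Gst'' value."""

    hs: float       # mean within-population gene diversity (across loci)
    ht: float       # total gene diversity of pooled frequencies (across loci)
    k: int          # number of populations in the comparison
    gst_dp: float   # Gst''


def condition_frequencies(m: FourStateMatrix) -> FrequencyTable:
    """Per-population four-state frequencies from an epilocus matrix.

    Haploid treatment: each individual contributes one state per locus;
    missing cells are dropped from the denominator.
    """
    pops = sorted(m.populations.unique())
    vals = m.states.to_numpy(dtype=object)
    z = np.zeros((len(m.states.index), len(pops)))
    codes = pd.Categorical(m.populations, categories=pops).codes
    z[np.arange(len(codes)), codes] = 1.0
    counts = np.stack([z.T @ (vals == s).astype(float) for s in STATES], axis=2)
    scored = counts.sum(axis=2)  # (pops, loci)
    if (scored.sum(axis=1) == 0).any():
        bad = pops[int(np.argmin(scored.sum(axis=1)))]
        raise ValueError(f"population {bad!r} has no scored individual at any locus")
    with np.errstate(invalid="ignore", divide="ignore"):
        table = np.where(scored[:, :, None] > 0,
                         counts / scored[:, :, None], np.nan)
    freqs = {
        locus: pd.DataFrame(table[:, j, :], index=pops, columns=list(STATES))
        for j, locus in enumerate(m.states.columns)
    }
    ns = {
        locus: pd.Series(scored[:, j].astype(int), index=pops)
        for j, locus in enumerate(m.states.columns)
    }
    return FrequencyTable("epi4", freqs, ns)


def genotype_frequencies(
    g: pd.DataFrame, populations: pd.Series | None = None
) -> FrequencyTable:
    """Allele frequencies from a diploid genotype table.

    ``g`` is long-on-individuals: columns ``individual``, ``population``
    (unless ``populations`` is given) and two columns ``<locus>_a1`` /
    ``<locus>_a2`` per locus; missing genotypes carry NA in both allele
    columns.  A half-recorded genotype (one allele NA) is rejected.
    """
    g = g.copy()
    if "individual" not in g.columns:
        raise ValueError("genotype table must have an 'individual' column")
    g = g.set_index("individual")
    if populations is None:
        if "population" not in g.columns:
            raise ValueError("genotype table needs a 'population' column or explicit mapping")
        populations = g["population"]
    populations = pd.Series(populations).loc[g.index]
    allele_cols = [c for c in g.columns if c.endswith(("_a1", "_a2"))]
    loci = sorted({c[:-3] for c in allele_cols})
    if not loci:
        raise ValueError("no <locus>_a1/<locus>_a2 columns found")
    pops = sorted(populations.unique())
    groups = {p: populations.index[populations == p] for p in pops}

    freqs: dict[str, pd.DataFrame] = {}
    ns: dict[str, pd.Series] = {}
    for locus in loci:
        a1, a2 = g[f"{locus}_a1"], g[f"{locus}_a2"]
        half = a1.isna() != a2.isna()
        if half.any():
            ind = half.index[half][0]
            raise ValueError(
                f"individual {ind!r} has a half genotype at locus {locus!r}"
            )
        alleles = sorted(set(a1.dropna().astype(str)) | set(a2.dropna().astype(str)))
        table = np.full((len(pops), len(alleles)), np.nan)
        n = pd.Series(0, index=pops, dtype=int)
        for i, p in enumerate(pops):
            stack = pd.concat([a1.loc[groups[p]], a2.loc[groups[p]]]).dropna().astype(str)
            if len(stack):
                counts = stack.value_counts()
                table[i] = [counts.get(a, 0) / len(stack) for a in alleles]
                n[p] = len(stack)
        freqs[locus] = pd.DataFrame(table, index=pops, columns=alleles)
        ns[locus] = n
    return FrequencyTable("microsat", freqs, ns)


def pool_frequencies(table: pd.DataFrame) -> FrequencyTable:
    """Population-level SNP frequencies from a pooled-sequencing table.

    ``table`` is populations x loci holding the reference-allele
    frequency in [0, 1]; the alternate frequency is its complement.
    """
    if ((table < -1e-12) | (table > 1 + 1e-12)).any().any():
        raise ValueError("pool frequencies must lie in [0, 1]")
    freqs = {
        str(locus): pd.DataFrame(
            {"ref": table[locus].to_numpy(dtype=float),
             "alt": 1.0 - table[locus].to_numpy(dtype=float)},
            index=table.index,
        )
        for locus in table.columns
    }
    return FrequencyTable("snp_pool", freqs)


def _stacked(f: FrequencyTable) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Zero-pad per-locus frequency tables into one (pops, loci, states) array."""
    pops = f.populations
    smax = max(fr.shape[1] for fr in f.freqs.values())
    arr = np.zeros((len(pops), len(f.freqs), smax))
    missing_mask = np.zeros((len(pops), len(f.freqs)), dtype=bool)
    for j, locus in enumerate(f.loci):
        a = f.freqs[locus].to_numpy(dtype=float)
        miss = np.isnan(a).all(axis=1)
        a = np.where(np.isnan(a), 0.0, a)
        arr[:, j, : a.shape[1]] = a
        missing_mask[:, j] = miss
    narr = None
    if f.n is not None:
        narr = np.column_stack([f.n[locus].to_numpy(dtype=float) for locus in f.loci])
    arr[missing_mask] = np.nan
    return arr, narr, pops


def gst_double_prime_pair(
    pa: np.ndarray,
    pb: np.ndarray,
    na: np.ndarray | None = None,
    nb: np.ndarray | None = None,
    estimator: str = "plugin",
    locus_aggregation: str = "across_loci",
) -> GstComponents:
    """Gst'' between two populations from (loci x states) frequency arrays.

    Loci where either population is unscored (all-NaN row) are excluded;
    loci monomorphic in both populations contribute HS = HT = 0 and stay
    in the across-locus averages.
    """
    ok = ~(np.isnan(pa).all(axis=1) | np.isnan(pb).all(axis=1))
    if not ok.any():
        raise ValueError("no locus scored in both populations")
    pa, pb = pa[ok], pb[ok]
    hs = 1.0 - 0.5 * ((pa**2).sum(axis=1) + (pb**2).sum(axis=1))
    pbar = 0.5 * (pa + pb)
    ht = 1.0 - (pbar**2).sum(axis=1)
    if estimator == "nei_unbiased":
        if na is None or nb is None:
            raise ValueError("nei_unbiased estimator needs per-population sample sizes")
        na, nb = na[ok], nb[ok]
        ntilde = 2.0 / (1.0 / na + 1.0 / nb)
        hs = ntilde / (ntilde - 1.0) * hs
        ht = ht + hs / (2.0 * ntilde)
    elif estimator != "plugin":
        raise ValueError(f"unknown estimator {estimator!r}")

    k = 2
    if locus_aggregation == "across_loci":
        HS, HT = float(hs.mean()), float(ht.mean())
        gst = _gst_ratio(HS, HT, k)
    elif locus_aggregation == "per_locus":
        defined = (k * ht - hs) * (1.0 - hs) > 0
        HS, HT = float(hs.mean()), float(ht.mean())
        gst = float(np.mean([_gst_ratio(h, t, k) for h, t in zip(hs[defined], ht[defined])])) if defined.any() else 0.0
    else:
        raise ValueError(f"unknown locus_aggregation {locus_aggregation!r}")
    return GstComponents(hs=HS, ht=HT, k=k, gst_dp=gst)


def _gst_ratio(hs: float, ht: float, k: int) -> float:
    if ht <= 0.0:
        warnings.warn(
            "degenerate pair: both populations fixed for the same state at "
            "every locus; Gst'' reported as 0",
            stacklevel=3,
        )
        return 0.0
    return k * (ht - hs) / ((k * ht - hs) * (1.0 - hs))


def pairwise_gst_double_prime(
    f: FrequencyTable,
    estimator: str = "plugin",
    locus_aggregation: str = "across_loci",
) -> tuple[DistanceMatrix, dict[tuple[str, str], GstComponents]]:
    """Symmetric matrix of pairwise Gst'' over all population pairs.

    The default plugin estimator uses the raw frequencies with no
    small-sample correction, so epilocus, microsatellite and pooled-SNP
    tables are treated identically; ``nei_unbiased`` applies the
    Nei-Chesson correction and needs sample sizes (not available for
    pools).
    """
    arr, narr, pops = _stacked(f)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    mat = np.zeros((len(pops), len(pops)))
    comps: dict[tuple[str, str], GstComponents] = {}
    for ia, ib in itertools.combinations(range(len(pops)), 2):
        na = narr[ia] if narr is not None else None
        nb = narr[ib] if narr is not None else None
        c = gst_double_prime_pair(
            arr[ia], arr[ib], na, nb,
            estimator=estimator, locus_aggregation=locus_aggregation,
        )
        comps[(pops[ia], pops[ib])] = c
        # clamp numerical negatives (unbiased estimator can dip below 0)
        mat[ia, ib] = mat[ib, ia] = max(c.gst_dp, 0.0)
    return DistanceMatrix(mat, ids=[str(p) for p in pops]), comps
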