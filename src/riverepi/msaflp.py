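"""Four-state methylation scoring from dual-enzyme MS-AFLP fragment profiles.

MS-AFLP compares two restriction digests of the same individual, one with
MspI and one with HpaII.  The two isoschizomers cut the CCGG motif with
different cytosine-methylation sensitivities, so the presence/absence of a
fragment in each profile classifies the locus into one of four methylation
conditions:

======  =====  ======  ==============================================
state   MspI   HpaII   interpretation
======  =====  ======  ==============================================
I       1      1       unmethylated
II      1      0       internal-cytosine (hemi)methylation
III     0      1       external-cytosine hemimethylation
IV      0      0       uninformative (hypermethylation or site loss)
======  =====  ======  ==============================================

Condition IV is kept as an ordinary fourth state throughout: it carries
information about methylation load even though its molecular origin is
ambiguous.  A separate missing code (``NaN`` in memory, ``NA`` on disk)
exists for individuals that were simply not scored at a locus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("riverepi")

#: canonical state labels, in (MspI, HpaII) presence order
STATES: tuple[str, ...] = ("I", "II", "III", "IV")

#: enzyme profile tags
PROFILES: tuple[str, str] = ("MSPI", "HPAII")

_CONDITION_CODE = {(1, 1): "I", (1, 0): "II", (0, 1): "III", (0, 0): "IV"}
_CONDITION_DECODE = {v: k for k, v in _CONDITION_CODE.items()}


@dataclass
class PresenceMatrix:
    """Binary individuals x loci presence matrix for one enzyme profile.

    Locus labels are fragment sizes in base pairs (stored as strings so
    they survive CSV round trips unchanged).
    """

    values: pd.DataFrame
    profile: str

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown enzyme profile {self.profile!r}; expected one of {PROFILES}")
        bad = ~self.values.isin([0, 1]).to_numpy()
        if bad.any():
            raise ValueError("presence matrix entries must be 0 or 1")

    @property
    def individuals(self) -> list[str]:
        return list(self.values.index)

    @property
    def loci(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FourStateMatrix:
    """Individuals x epiloci matrix over the four methylation conditions.

    ``states`` holds "I"/"II"/"III"/"IV" (or NaN for not-scored cells);
    ``populations`` maps each individual to its sampling-site label.
    """

    states: pd.DataFrame
    populations: pd.Series
    removal_log: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.populations = pd.Series(self.populations)
        missing = [i for i in self.states.index if i not in self.populations.index]
        if missing:
            raise ValueError(f"individual {missing[0]!r} has no population label")
        self.populations = self.populations.loc[self.states.index]
        vals = self.states.to_numpy(dtype=object)
        ok = np.isin(vals, STATES) | pd.isna(vals.astype(object))
        if not ok.all():
            bad = vals[~ok].ravel()[0]
            raise ValueError(f"invalid methylation state {bad!r}; expected one of {STATES} or NaN")

    @property
    def individuals(self) -> list[str]:
        return list(self.states.index)

    @property
    def loci(self) -> list[str]:
        return list(self.states.columns)

    @property
    def n_loci(self) -> int:
        return self.states.shape[1]


def call_presence(
    peaks: pd.DataFrame,
    rfu_threshold: float = 750.0,
    size_window: tuple[int, int] = (150, 500),
) -> tuple[PresenceMatrix, PresenceMatrix]:
    """Threshold a long-format peak table into per-profile presence matrices.

    Parameters
    ----------
    peaks:
        Long-format table with columns ``individual``, ``locus_size`` (bp),
        ``profile`` (MSPI or HPAII) and ``rfu`` (relative fluorescence
        units).  Sizes are assumed pre-binned to integers.
    rfu_threshold:
        Minimum peak height for a fragment to be called present
        (inclusive; default 750 RFU).
    size_window:
        Inclusive fragment-size window in bp (default 150-500, which
        limits size homoplasy).

    Returns
    -------
    (mspi, hpaii):
        Two presence matrices sharing the same individual set and the same
        locus set (the union of surviving fragment sizes over both
        profiles).
    """
    required = {"individual", "locus_size", "profile", "rfu"}
    if not required.issubset(peaks.columns):
        raise ValueError(f"peak table must have columns {sorted(required)}")
    if len(peaks) == 0:
        raise ValueError("empty peak table")
    lo, hi = size_window
    if not lo < hi:
        raise ValueError(f"size window must satisfy min < max, got {size_window}")
    if rfu_threshold <= 0:
        raise ValueError("rfu_threshold must be positive")

    peaks = peaks.copy()
    peaks["profile"] = peaks["profile"].str.upper()
    unknown = set(peaks["profile"]) - set(PROFILES)
    if unknown:
        raise ValueError(f"unknown enzyme profile(s) {sorted(unknown)}")
    if (peaks["rfu"] < 0).any():
        raise ValueError("negative RFU value in peak table")
    if (peaks["locus_size"] <= 0).any():
        raise ValueError("non-positive fragment size in peak table")

    dup = peaks.duplicated(["individual", "locus_size", "profile"], keep=False)
    if dup.any():
        n = int(peaks.loc[dup].groupby(["individual", "locus_size", "profile"]).ngroups)
        warnings.warn(
            f"{n} duplicated (individual, size, profile) peak(s); keeping max RFU",
            stacklevel=2,
        )
        peaks = (
            peaks.groupby(["individual", "locus_size", "profile"], as_index=False)["rfu"].max()
        )

    individuals = sorted(peaks["individual"].astype(str).unique())
    in_window = (peaks["locus_size"] >= lo) & (peaks["locus_size"] <= hi)
    called = peaks[in_window & (peaks["rfu"] >= rfu_threshold)]
    sizes = sorted(called["locus_size"].unique())
    loci = [str(int(s)) for s in sizes]

    out = []
    for prof in PROFILES:
        mat = pd.DataFrame(0, index=individuals, columns=loci, dtype=int)
        sub = called[called["profile"] == prof]
        for ind, size in zip(sub["individual"].astype(str), sub["locus_size"]):
            mat.loc[ind, str(int(size))] = 1
        out.append(PresenceMatrix(mat, prof))
    return out[0], out[1]


def code_conditions(
    mspi: PresenceMatrix,
    hpaii: PresenceMatrix,
    populations: Mapping[str, str] | pd.Series | None = None,
) -> FourStateMatrix:
    """Combine the two enzyme-profile presence matrices into four states.

    Cellwise mapping on (MspI, HpaII) presence: (1,1) -> I, (1,0) -> II,
    (0,1) -> III, (0,0) -> IV.  The two matrices must carry identical
    individual and locus labels.  ``populations`` assigns each individual
    to a site; if omitted every individual is labelled "unassigned".
    """
    if {mspi.profile, hpaii.profile} != set(PROFILES):
        raise ValueError("code_conditions needs one MSPI and one HPAII matrix")
    if mspi.profile == "HPAII":
        mspi, hpaii = hpaii, mspi
    for axis, a, b in (("individual", mspi.values.index, hpaii.values.index),
                       ("locus", mspi.values.columns, hpaii.values.columns)):
        sa, sb = set(a), set(b)
        if sa != sb:
            off = sorted(sa.symmetric_difference(sb))[0]
            raise ValueError(f"{axis} label {off!r} present in only one profile")
    hp = hpaii.values.loc[mspi.values.index, mspi.values.columns]
    m = mspi.values.to_numpy()
    h = hp.to_numpy()
    coded = np.empty(m.shape, dtype=object)
    for (mv, hv), state in _CONDITION_CODE.items():
        coded[(m == mv) & (h == hv)] = state
    states = pd.DataFrame(coded, index=mspi.values.index, columns=mspi.values.columns)
    if populations is None:
        populations = pd.Series("unassigned", index=states.index)
    else:
        populations = pd.Series(populations)
    return FourStateMatrix(states, populations)


def to_presence(m: FourStateMatrix) -> tuple[PresenceMatrix, PresenceMatrix]:
    """Decompose a four-state matrix back into its two presence matrices.

    Missing cells are not representable in a presence matrix, so the
    matrix must be fully scored.
    """
    if m.states.isna().any().any():
        raise ValueError("cannot decompose a four-state matrix with missing cells")
    vals = m.states.to_numpy(dtype=object)
    mspi = np.zeros(vals.shape, dtype=int)
    hpa = np.zeros(vals.shape, dtype=int)
    for state, (mv, hv) in _CONDITION_DECODE.items():
        where = vals == state
        mspi[where] = mv
        hpa[where] = hv
    idx, cols = m.states.index, m.states.columns
    return (
        PresenceMatrix(pd.DataFrame(mspi, index=idx, columns=cols), "MSPI"),
        PresenceMatrix(pd.DataFrame(hpa, index=idx, columns=cols), "HPAII"),
    )


def filter_loci(
    m: FourStateMatrix,
    max_iv_fraction: float = 0.95,
    drop_monomorphic: bool = False,
) -> FourStateMatrix:
    """Drop uninformative epiloci.

    A locus is removed iff its Condition-IV fraction (count of state IV
    over the number of individuals) is *strictly* greater than
    ``max_iv_fraction``; a locus at exactly the threshold is retained.
    With ``drop_monomorphic``, loci where all scored individuals share one
    state are removed as well, leaving only polymorphic loci.

    The returned matrix carries a ``removal_log`` DataFrame with one row
    per dropped locus and the reason.
    """
    if not 0 < max_iv_fraction <= 1:
        raise ValueError("max_iv_fraction must be in (0, 1]")
    n_ind = len(m.states.index)
    iv_frac = (m.states == "IV").sum(axis=0) / n_ind
    drop_iv = iv_frac > max_iv_fraction

    drop_mono = pd.Series(False, index=m.states.columns)
    if drop_monomorphic:
        n_states = m.states.nunique(axis=0, dropna=True)
        drop_mono = n_states <= 1

    reasons = []
    for locus in m.states.columns:
        if drop_iv[locus]:
            reasons.append((locus, "condition_iv_fraction", float(iv_frac[locus])))
        elif drop_mono[locus]:
            reasons.append((locus, "monomorphic", float(iv_frac[locus])))
    log = pd.DataFrame(reasons, columns=["locus", "reason", "iv_fraction"])

    keep = m.states.columns[~(drop_iv | drop_mono)]
    if len(keep) == 0:
        raise ValueError(
            "all loci removed by filtering; review max_iv_fraction "
            f"(={max_iv_fraction}) and the input matrix"
        )
    if len(log):
        logger.info("filter_loci removed %d of %d loci", len(log), m.n_loci)
    return FourStateMatrix(m.states[keep].copy(), m.populations, removal_log=log)
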