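"""CSV readers/writers and YAML configuration.

All tabular I/O is plain CSV: comma separator, dot decimal, UTF-8, header
row mandatory.  Dialects:

* peak table — long format, columns ``individual,locus_size,profile,rfu``;
* presence / four-state matrices — first column individual id, second
  column population label, remaining columns loci (states I/II/III/IV,
  missing = NA);
* genotype table — ``individual,population`` then ``<locus>_a1,<locus>_a2``
  columns, missing = NA;
* pool-frequency table — populations x loci, reference-allele frequency;
* environmental table — first column site label, variables as columns;
* distance matrix — square, identical row and column labels.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix

from .msaflp import FourStateMatrix, PresenceMatrix

DEFAULT_CONFIG: dict = {
    "inputs": {},
    "filters": {
        "rfu_threshold": 750.0,
        "size_min": 150,
        "size_max": 500,
        "max_iv_fraction": 0.95,
        "drop_monomorphic": False,
    },
    "pca": {"scale": True, "retain": 3},
    "tests": {
        "n_perm": 1000,
        "mantel_alternative": "greater",
        "include_microsat_predictor": False,
    },
    "seed": 0,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML run configuration, merged over the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        merge(cfg, user)
    if overrides:
        merge(cfg, overrides)
    return cfg


# ---------------------------------------------------------------- peak tables

def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"individual", "locus_size", "profile", "rfu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} lacks column(s) {sorted(missing)}")
    df["individual"] = df["individual"].astype(str)
    return df


# ------------------------------------------------- presence / four-state CSVs

def write_presence(m: PresenceMatrix, path: str | Path,
                   populations: pd.Series | None = None) -> None:
    pops = (pd.Series(populations).loc[m.values.index]
            if populations is not None
            else pd.Series("unassigned", index=m.values.index))
    out = m.values.copy()
    out.insert(0, "population", pops)
    out.index.name = "individual"
    out.to_csv(path)


def read_presence(path: str | Path, profile: str) -> tuple[PresenceMatrix, pd.Series]:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    pops = df.pop("population").astype(str)
    return PresenceMatrix(df.astype(int), profile.upper()), pops


def write_four_state(m: FourStateMatrix, path: str | Path) -> None:
    out = m.states.copy()
    out.insert(0, "population", m.populations)
    out.index.name = "individual"
    out.to_csv(path, na_rep="NA")


def read_four_state(path: str | Path) -> FourStateMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = None
    pops = df.pop("population").astype(str)
    return FourStateMatrix(df, pops)


# ------------------------------------------------------------ genotype tables

def write_genotypes(g: pd.DataFrame, path: str | Path) -> None:
    g.to_csv(path, index=False, na_rep="NA")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    if "individual" not in df.columns:
        raise ValueError(f"genotype table {path} lacks an 'individual' column")
    df["individual"] = df["individual"].astype(str)
    return df


# -------------------------------------------------------- pool frequency CSVs

def write_pool_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = "population"
    out.to_csv(path)


def read_pool_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df.astype(float)


# ------------------------------------------------------------------ env table

def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    out = env.copy()
    out.index.name = "site"
    out.to_csv(path)


def read_env_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df.astype(float)


# ----------------------------------------------------------- distance matrices

def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(d.data, index=d.ids, columns=d.ids).to_csv(path)


def read_square_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read and validate a labelled square distance matrix.

    Row and column labels must coincide; asymmetries up to 1e-9 are
    symmetrised, anything larger is an error, as are negative entries and
    a nonzero diagonal.
    """
    df = pd.read_csv(path, index_col=0)
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if len(set(rows)) != len(rows):
        raise ValueError(f"duplicate row label in {path}")
    if rows != cols:
        raise ValueError(f"row and column labels differ in {path}")
    a = df.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"matrix in {path} is not square")
    if np.isnan(a).any():
        raise ValueError(f"missing entry in {path}")
    if (a < 0).any():
        raise ValueError(f"negative entry in {path}")
    if np.abs(np.diag(a)).max() > 0:
        raise ValueError(f"nonzero diagonal in {path}")
    asym = np.abs(a - a.T).max()
    if asym > 1e-9:
        ij = np.unravel_index(np.argmax(np.abs(a - a.T)), a.shape)
        raise ValueError(
            f"asymmetric entries at ({rows[ij[0]]}, {rows[ij[1]]}) in {path}: "
            f"difference {asym:g}"
        )
    a = 0.5 * (a + a.T)
    return DistanceMatrix(a, ids=rows)
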