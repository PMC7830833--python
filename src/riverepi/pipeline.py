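"""End-to-end orchestration: from marker tables to the analysis report.

The full analysis, per species: (1) score/filter the four-state epilocus
matrix; (2) AMOVA on epiloci and microsatellites (pooled SNPs carry no
within-population component and are excluded by type); (3) pairwise Gst''
for all three marker systems; (4) simple Mantel tests between marker
systems and between each marker and the environmental/riparian distance
predictors; (5) MRM with epigenetic Gst'' as response and the three
environmental axes, riparian distance and SNP Gst'' as predictors.

Every randomised step draws from a named substream of one master seed,
so reruns with the same configuration are bitwise reproducible and
toggling one analysis never shifts another's p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.metadata import version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix

from . import io as rio
from .amova import AmovaResult, amova_two_level, individual_distance_matrix
from .assoc import mantel, mrm
from .diffstats import (FrequencyTable, condition_frequencies,
                        genotype_frequencies, pairwise_gst_double_prime,
                        pool_frequencies)
from .envspace import PCAResult, retain_components, retained_distances, run_pca
from .msaflp import FourStateMatrix, call_presence, code_conditions, filter_loci
from .seeding import named_rng
from .simulate import SimConfig, SyntheticDataset, simulate_dataset

logger = logging.getLogger("riverepi")

MARKERS = ("msaflp", "microsat", "snp")


@dataclass
class SpeciesInputs:
    """Individual- and population-level marker data for one species."""

    epi: FourStateMatrix
    genotypes: pd.DataFrame
    snp_pool: FrequencyTable


@dataclass
class ReportBundle:
    """All analysis tables for one run, labelled by species and marker."""

    pca: PCAResult
    env_distances: dict[int, DistanceMatrix]
    riparian: DistanceMatrix
    gst: dict[tuple[str, str], DistanceMatrix]                # (species, marker)
    amova: dict[tuple[str, str], AmovaResult]                 # (species, marker)
    marker_mantel: dict[str, pd.DataFrame]                    # r above / p below diag
    predictor_mantel: pd.DataFrame                            # long table
    mrm: dict[str, pd.DataFrame]                              # per species
    biplot: dict[str, pd.DataFrame]                           # per species
    run_log: dict = field(default_factory=dict)


def _predictor_set(env_d: dict[int, DistanceMatrix], riparian: DistanceMatrix):
    preds = {f"env_pc{axis}": d for axis, d in sorted(env_d.items())}
    preds["riparian"] = riparian
    return preds


def analyse_dataset(
    species_inputs: dict[str, SpeciesInputs],
    env: pd.DataFrame,
    riparian: DistanceMatrix,
    seed: int = 0,
    n_perm: int = 1000,
    pca_scale: bool = True,
    pca_retain: int = 3,
    max_iv_fraction: float = 0.95,
    drop_monomorphic: bool = False,
    mantel_alternative: str = "greater",
    include_microsat_predictor: bool = False,
) -> ReportBundle:
    """Run the full comparative analysis on in-memory inputs."""
    p = run_pca(env, scale=pca_scale)
    p = retain_components(p, {"fixed_count": pca_retain})
    env_d = retained_distances(p)
    predictors = _predictor_set(env_d, riparian)

    gst: dict[tuple[str, str], DistanceMatrix] = {}
    amova_res: dict[tuple[str, str], AmovaResult] = {}
    marker_mantel: dict[str, pd.DataFrame] = {}
    mrm_tables: dict[str, pd.DataFrame] = {}
    biplot: dict[str, pd.DataFrame] = {}
    pred_rows = []

    for sp, data in species_inputs.items():
        epi = filter_loci(data.epi, max_iv_fraction=max_iv_fraction,
                          drop_monomorphic=drop_monomorphic)

        # --- AMOVA (individual-level markers only)
        d_epi = individual_distance_matrix(epi)
        amova_res[(sp, "msaflp")] = amova_two_level(
            d_epi, epi.populations, n_perm=n_perm,
            seed=named_rng(seed, f"amova:{sp}:msaflp"))
        d_ms = individual_distance_matrix(data.genotypes, metric="microsat")
        ms_pops = data.genotypes.set_index("individual")["population"]
        amova_res[(sp, "microsat")] = amova_two_level(
            d_ms, ms_pops, n_perm=n_perm,
            seed=named_rng(seed, f"amova:{sp}:microsat"))

        # --- pairwise differentiation, one matrix per marker system
        gst[(sp, "msaflp")], _ = pairwise_gst_double_prime(condition_frequencies(epi))
        gst[(sp, "microsat")], _ = pairwise_gst_double_prime(
            genotype_frequencies(data.genotypes))
        gst[(sp, "snp")], _ = pairwise_gst_double_prime(data.snp_pool)

        # --- marker-vs-marker Mantel battery (r above, p below the diagonal)
        mm = pd.DataFrame(np.nan, index=list(MARKERS), columns=list(MARKERS))
        for i, ma in enumerate(MARKERS):
            for j, mb in enumerate(MARKERS):
                if i < j:
                    res = mantel(gst[(sp, ma)], gst[(sp, mb)], n_perm=n_perm,
                                 alternative=mantel_alternative,
                                 seed=named_rng(seed, f"mantel:{sp}:{ma}:{mb}"))
                    mm.loc[ma, mb] = res.r
                    mm.loc[mb, ma] = res.p_value
        marker_mantel[sp] = mm

        # --- marker-vs-predictor Mantel battery
        for marker in MARKERS:
            for pname, pd_mat in predictors.items():
                res = mantel(gst[(sp, marker)], pd_mat, n_perm=n_perm,
                             alternative=mantel_alternative,
                             seed=named_rng(seed, f"mantel:{sp}:{marker}:{pname}"))
                pred_rows.append((sp, marker, pname, res.r, res.p_value))

        # --- MRM: epigenetic differentiation on env + space + genetics
        mrm_preds = dict(predictors)
        mrm_preds["snp_gst"] = gst[(sp, "snp")]
        if include_microsat_predictor:
            mrm_preds["microsat_gst"] = gst[(sp, "microsat")]
        res = mrm(gst[(sp, "msaflp")], list(mrm_preds.values()), n_perm=n_perm,
                  seed=named_rng(seed, f"mrm:{sp}"),
                  predictor_names=list(mrm_preds))
        mrm_tables[sp] = pd.DataFrame({
            "term": list(res.coefficients),
            "coefficient": list(res.coefficients.values()),
            "p_value": list(res.coefficient_p.values()),
        }).assign(r_squared=res.r_squared, r_squared_p=res.r_squared_p)

        # --- biplot exports (pairwise x-y with a 1:1 reference-line flag)
        tri_i, tri_j = np.tril_indices(len(riparian.ids), k=-1)
        ids = gst[(sp, "snp")].ids
        epi_aligned = gst[(sp, "msaflp")].filter(ids).data
        biplot[sp] = pd.DataFrame({
            "site_a": [ids[i] for i in tri_i],
            "site_b": [ids[j] for j in tri_j],
            "snp_gst": gst[(sp, "snp")].data[tri_i, tri_j],
            "msaflp_gst": epi_aligned[tri_i, tri_j],
            "env_pc1_distance": predictors["env_pc1"].filter(ids).data[tri_i, tri_j],
        }).assign(one_to_one_line=True)

    bundle = ReportBundle(
        pca=p, env_distances=env_d, riparian=riparian, gst=gst,
        amova=amova_res, marker_mantel=marker_mantel,
        predictor_mantel=pd.DataFrame(
            pred_rows, columns=["species", "marker", "predictor", "r", "p_value"]),
        mrm=mrm_tables, biplot=biplot,
        run_log={
            "riverepi_version": version("riverepi"),
            "numpy_version": version("numpy"),
            "seed": seed,
            "n_perm": n_perm,
            "pca": {"scale": pca_scale, "retain": pca_retain},
            "filters": {"max_iv_fraction": max_iv_fraction,
                        "drop_monomorphic": drop_monomorphic},
            "mantel_alternative": mantel_alternative,
            "include_microsat_predictor": include_microsat_predictor,
            "species": sorted(species_inputs),
        },
    )
    return bundle


def dataset_to_inputs(ds: SyntheticDataset) -> dict[str, SpeciesInputs]:
    """Adapt a synthetic dataset to the analysis entry point."""
    return {
        name: SpeciesInputs(epi=sp.epi, genotypes=sp.genotypes, snp_pool=sp.snp_pool)
        for name, sp in ds.species.items()
    }


def _load_species(block: dict, filters: dict) -> SpeciesInputs:
    if "peaks" in block:
        peaks = rio.read_peak_table(block["peaks"])
        mspi, hpaii = call_presence(
            peaks, rfu_threshold=filters["rfu_threshold"],
            size_window=(filters["size_min"], filters["size_max"]))
        pops = None
        if "populations" in block:
            pops = pd.read_csv(block["populations"], index_col=0).iloc[:, 0].astype(str)
        epi = code_conditions(mspi, hpaii, populations=pops)
    elif "epi" in block:
        epi = rio.read_four_state(block["epi"])
    else:
        raise ValueError("species input block needs 'epi' or 'peaks'")
    for key in ("microsat", "snp_pool"):
        if key not in block:
            raise ValueError(f"species input block lacks {key!r}")
    genotypes = rio.read_genotypes(block["microsat"])
    snp_pool = pool_frequencies(rio.read_pool_table(block["snp_pool"]))
    return SpeciesInputs(epi=epi, genotypes=genotypes, snp_pool=snp_pool)


def run_full_analysis(config: str | Path | dict) -> ReportBundle:
    """Run the pipeline from a YAML configuration (or config dict).

    The configuration either names input files (``inputs`` block with
    ``env``, ``riparian`` and per-species marker files) or asks for a
    synthetic dataset (``simulate`` block with generator parameters).
    """
    cfg = config if isinstance(config, dict) else rio.load_config(config)
    cfg = rio.load_config(None, overrides=cfg)
    seed = int(cfg.get("seed", 0))
    filters = cfg["filters"]

    if "simulate" in cfg and cfg["simulate"] is not None:
        sim = dict(cfg["simulate"])
        overrides = sim.pop("species_overrides", None)
        ds = simulate_dataset(SimConfig(**sim), seed=seed,
                              species_overrides=overrides)
        species_inputs = dataset_to_inputs(ds)
        env, riparian = ds.env, ds.riparian
    else:
        inputs = cfg["inputs"]
        for key in ("env", "riparian", "species"):
            if key not in inputs:
                raise ValueError(f"config inputs block lacks {key!r}")
        env = rio.read_env_table(inputs["env"])
        riparian = rio.read_square_distance_matrix(inputs["riparian"])
        species_inputs = {
            name: _load_species(block, filters)
            for name, block in inputs["species"].items()
        }

    return analyse_dataset(
        species_inputs, env, riparian,
        seed=seed,
        n_perm=int(cfg["tests"]["n_perm"]),
        pca_scale=bool(cfg["pca"]["scale"]),
        pca_retain=int(cfg["pca"]["retain"]),
        max_iv_fraction=float(filters["max_iv_fraction"]),
        drop_monomorphic=bool(filters.get("drop_monomorphic", False)),
        mantel_alternative=cfg["tests"]["mantel_alternative"],
        include_microsat_predictor=bool(
            cfg["tests"].get("include_microsat_predictor", False)),
    )


def write_report_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write every report table as CSV plus a YAML run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle.pca.loadings.to_csv(out / "pca_loadings.csv")
    bundle.pca.scores.to_csv(out / "pca_scores.csv")
    pd.DataFrame({
        "component": bundle.pca.components,
        "variance_fraction": bundle.pca.variance_fraction,
        "retained": [k + 1 in bundle.pca.retained
                     for k in range(len(bundle.pca.components))],
    }).to_csv(out / "pca_variance.csv", index=False)

    rio.write_distance_matrix(bundle.riparian, out / "riparian_distances.csv")
    for axis, d in bundle.env_distances.items():
        rio.write_distance_matrix(d, out / f"env_pc{axis}_distances.csv")
    for (sp, marker), d in bundle.gst.items():
        rio.write_distance_matrix(d, out / f"gst_{sp}_{marker}.csv")
    for (sp, marker), res in bundle.amova.items():
        res.to_frame().to_csv(out / f"amova_{sp}_{marker}.csv", index=False)
    for sp, mm in bundle.marker_mantel.items():
        mm.to_csv(out / f"mantel_markers_{sp}.csv")
    bundle.predictor_mantel.to_csv(out / "mantel_predictors.csv", index=False)
    for sp, table in bundle.mrm.items():
        table.to_csv(out / f"mrm_{sp}.csv", index=False)
    for sp, table in bundle.biplot.items():
        table.to_csv(out / f"biplot_{sp}.csv", index=False)
    with open(out / "run_log.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(bundle.run_log, fh, sort_keys=True)
    logger.info("report bundle written to %s", out)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write a synthetic dataset in the pipeline's CSV dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_env_table(ds.env, out / "env.csv")
    rio.write_distance_matrix(ds.riparian, out / "riparian.csv")
    for name, sp in ds.species.items():
        from .msaflp import FourStateMatrix  # noqa: F401  (type context)
        rio.write_four_state(sp.epi, out / f"{name}_epi.csv")
        rio.write_genotypes(sp.genotypes, out / f"{name}_microsat.csv")
        pool = pd.DataFrame(
            {locus: sp.snp_pool.freqs[locus]["ref"] for locus in sp.snp_pool.loci})
        rio.write_pool_table(pool, out / f"{name}_snp_pool.csv")
    from .simulate import config_echo
    with open(out / "config_echo.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_echo(ds), fh, sort_keys=True)
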