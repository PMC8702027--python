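"""Pipeline orchestration and reporting.

``run_all`` executes the whole analysis on a synthetic study —
generation, POD fitting, ToxPi integration, Mantel screening, kriging,
cross-prediction, risk and remediation — and writes a deterministic set
of CSV tables plus a JSON run manifest with checksums.  CSV tables are
the contract; plots are optional conveniences.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .crosspred import cross_predict, prepare_bio_matrix, prepare_chem_matrix
from .doseresp import fit_pods
from .errors import PipelineError
from .remediate import dumbbell_table, remediation_table
from .risk import load_tox_params, risk_table
from .spatial import krige, mantel_screen
from .synth import default_design, generate_study
from .toxpi import cluster_order, toxpi_from_pods

logger = logging.getLogger("sedscreen")

_FLOAT_FMT = "%.12g"

STAGE_FILES = {
    "synth": ["sites.csv", "chemistry.csv", "plates.csv", "ground_truth.csv"],
    "doseresp": ["pods.csv"],
    "toxpi": ["toxpi.csv", "cluster_order.json"],
    "spatial": ["mantel.csv", "krige_toxpi_overall.csv", "krige_total_pah.csv"],
    "crosspred": ["crosspred_chem2bio.csv", "crosspred_bio2chem.csv",
                  "crosspred_summary.csv"],
    "risk": ["risk.csv"],
    "remediate": ["remediation.csv", "remediation_dumbbell.csv"],
    "report": ["region_summary.csv"],
}


@dataclass
class RunConfig:
    seed: int = 1
    design_seed: int = 0
    design_overrides: dict = field(default_factory=dict)
    n_perm: int = 10000
    grid: tuple = (100, 100)
    lag_size_km: float = 2.0
    tox_params_path: Optional[str] = None
    risk_scenario: str = "residential_soil"

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["grid"] = list(self.grid)
        return d


def load_config(path) -> RunConfig:
    """Read a TOML run configuration.

    Recognized tables/keys: [run] seed, design_seed, risk_scenario,
    tox_params_path; [design] any StudyDesign scalar field; [mantel]
    n_perm; [krige] nx, ny, lag_size_km.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    run = raw.get("run", {})
    cfg = RunConfig(
        seed=int(run.get("seed", 1)),
        design_seed=int(run.get("design_seed", 0)),
        design_overrides=dict(raw.get("design", {})),
        n_perm=int(raw.get("mantel", {}).get("n_perm", 10000)),
        grid=(int(raw.get("krige", {}).get("nx", 100)),
              int(raw.get("krige", {}).get("ny", 100))),
        lag_size_km=float(raw.get("krige", {}).get("lag_size_km", 2.0)),
        tox_params_path=run.get("tox_params_path"),
        risk_scenario=run.get("risk_scenario", "residential_soil"),
    )
    return cfg


def region_summary(toxpi: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Per-region distribution of the overall ToxPi score: mean,
    interquartile range, min and max."""
    merged = toxpi[["overall"]].merge(
        sites.set_index("sample_id")[["region"]],
        left_index=True, right_index=True,
    )
    rows = []
    for region, sub in merged.groupby("region", sort=True):
        v = sub["overall"].values
        rows.append({
            "region": region, "n": len(v), "mean": float(np.mean(v)),
            "q1": float(np.percentile(v, 25)), "q3": float(np.percentile(v, 75)),
            "min": float(np.min(v)), "max": float(np.max(v)),
        })
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT, lineterminator="\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(outdir, config: Optional[RunConfig] = None,
            seed: Optional[int] = None) -> dict:
    """Run the full pipeline and write all stage outputs to ``outdir``.

    Returns the manifest dict.  Deterministic: the same config and seed
    produce byte-identical CSV outputs.
    """
    cfg = config or RunConfig()
    if seed is not None:
        cfg.seed = seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    logger.info("generating synthetic study (seed=%d)", cfg.seed)
    design = default_design(cfg.design_seed, **cfg.design_overrides)
    study = generate_study(design, seed=cfg.seed)
    sites, chem, plates = study["sites"], study["chemistry"], study["plates"]
    _write_csv(sites, outdir / "sites.csv")
    _write_csv(chem.reset_index(), outdir / "chemistry.csv")
    _write_csv(plates, outdir / "plates.csv")
    _write_csv(study["truth"].to_frame(), outdir / "ground_truth.csv")

    logger.info("fitting concentration-response curves")
    pods = fit_pods(plates)
    _write_csv(pods, outdir / "pods.csv")

    logger.info("computing ToxPi scores")
    tox = toxpi_from_pods(pods)
    _write_csv(tox.reset_index(), outdir / "toxpi.csv")
    slice_cols = [c for c in tox.columns
                  if not c.startswith("celltype_") and c not in ("overall", "rank")]
    row_order, col_order = cluster_order(tox[slice_cols])
    (outdir / "cluster_order.json").write_text(json.dumps({
        "rows": [str(tox.index[i]) for i in row_order],
        "columns": [str(slice_cols[j]) for j in col_order],
    }, indent=1) + "\n")

    logger.info("Mantel screening (%d permutations)", cfg.n_perm)
    bio_feats = prepare_bio_matrix(pods)
    chem_feats = prepare_chem_matrix(chem)
    mantel_bio = mantel_screen(sites, bio_feats, n_perm=cfg.n_perm, seed=cfg.seed)
    mantel_bio.insert(0, "block", "bioactivity")
    mantel_chem = mantel_screen(sites, chem_feats, n_perm=cfg.n_perm,
                                seed=cfg.seed + 1)
    mantel_chem.insert(0, "block", "chemistry")
    _write_csv(pd.concat([mantel_bio, mantel_chem], ignore_index=True),
               outdir / "mantel.csv")

    logger.info("kriging maps")
    gtox, _ = krige(sites, tox["overall"].loc[sites["sample_id"]].values + 1e-6,
                    grid=cfg.grid, lag_size_km=cfg.lag_size_km)
    _write_csv(gtox, outdir / "krige_toxpi_overall.csv")
    gpah, _ = krige(sites, chem["total_pah"].loc[sites["sample_id"]].values,
                    grid=cfg.grid, lag_size_km=cfg.lag_size_km)
    _write_csv(gpah, outdir / "krige_total_pah.csv")

    logger.info("cross-prediction (LOOCV ridge)")
    c2b = cross_predict(chem_feats, bio_feats)
    b2c = cross_predict(bio_feats, chem_feats)
    _write_csv(c2b.predicted.reset_index(), outdir / "crosspred_chem2bio.csv")
    _write_csv(b2c.predicted.reset_index(), outdir / "crosspred_bio2chem.csv")
    summary = pd.concat([
        c2b.feature_stats.assign(direction="chem2bio", lambda_=c2b.lambda_),
        b2c.feature_stats.assign(direction="bio2chem", lambda_=b2c.lambda_),
    ], ignore_index=True)
    _write_csv(summary, outdir / "crosspred_summary.csv")

    logger.info("risk characterization")
    params = load_tox_params(cfg.tox_params_path)
    risks = risk_table(chem, params)
    _write_csv(risks, outdir / "risk.csv")

    logger.info("remediation comparison")
    remediation = remediation_table(pods, risks, scenario=cfg.risk_scenario)
    _write_csv(remediation, outdir / "remediation.csv")
    _write_csv(dumbbell_table(remediation), outdir / "remediation_dumbbell.csv")

    _write_csv(region_summary(tox, sites), outdir / "region_summary.csv")

    manifest = build_manifest(outdir, cfg)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    logger.info("done in %.1f s", manifest["elapsed_s"])
    return manifest


def build_manifest(outdir, cfg: RunConfig) -> dict:
    """Verify every stage output exists and checksum it; a missing file
    raises a PipelineError naming the stage."""
    outdir = Path(outdir)
    files = {}
    for stage, names in STAGE_FILES.items():
        for name in names:
            path = outdir / name
            if not path.exists():
                raise PipelineError(f"stage {stage!r} output missing: {name}")
            files[name] = _checksum(path)
    cfg_dict = cfg.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()
    return {
        "package_version": __version__,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "seed": cfg.seed,
        "files_sha256": files,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }


def setup_logging(verbose: bool = True, logfile: Optional[str] = None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True,
    )
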