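"""Synthetic sediment-screening study generator.

Emulates the statistical structure of a post-hurricane sediment survey:
46 sampling sites in three coastal clusters (Houston Ship Channel "HSC",
Mud & Clear Lakes "MCL", Galveston Bay "GB"), spatially autocorrelated
log-normal PAH chemistry (16 priority parents, 21 alkylated homologs and
3 totals = 40 analytes), and concentration-response screens of sediment
extracts in 34 phenotypic endpoints across 5 human cell types.

Chemistry is driven by a latent contamination field with exponential
spatial covariance.  Each bioactive endpoint's potency (EC50 on the
extract-dilution axis) decreases with a weighted chemical burden and,
for a subset of endpoints, with a non-PAH latent driver that is
independent of the measured chemistry — mirroring the real-world
situation where measured analytes explain only part of the observed
bioactivity.  Null endpoints emit flat curves.

Every generator is deterministic given (design, seed) and exports the
planted ground truth (latent field, analytic PODs, loading matrix) for
recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

# ---------------------------------------------------------------------------
# analyte panel
# ---------------------------------------------------------------------------

#: The 16 U.S. EPA priority PAH parents.
PRIORITY_PARENTS = (
    "naphthalene",
    "acenaphthylene",
    "acenaphthene",
    "fluorene",
    "phenanthrene",
    "anthracene",
    "fluoranthene",
    "pyrene",
    "benz[a]anthracene",
    "chrysene",
    "benzo[b]fluoranthene",
    "benzo[k]fluoranthene",
    "benzo[a]pyrene",
    "indeno[1,2,3-cd]pyrene",
    "dibenz[a,h]anthracene",
    "benzo[ghi]perylene",
)

#: Alkylated homolog series (21 analytes) keyed by parent.
HOMOLOG_SERIES = {
    "naphthalene": 4,       # C1..C4
    "fluorene": 3,
    "phenanthrene": 4,
    "anthracene": 2,
    "pyrene": 3,
    "fluoranthene": 2,
    "chrysene": 3,
}

TOTAL_IDS = ("total_parent_pah16", "total_alkylated", "total_pah")

VEHICLE_ID = "VEHICLE"


# ---------------------------------------------------------------------------
# design types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A spatial sampling cluster.

    ``latent_offset`` is the mean of the latent contamination field in
    this region (dimensionless log-scale units).
    """

    label: str
    center_lon: float
    center_lat: float
    spread_km: float
    sample_share: float
    latent_offset: float = 0.0


@dataclass(frozen=True)
class Analyte:
    analyte_id: str
    parent_id: Optional[str]  # None for parents and totals
    is_total: bool
    base_log10: float = 2.0       # log10 ng/g at latent = 0 (parents)
    latent_loading: float = 0.2   # slope on the latent field (parents)
    noise_sd: float = 0.8         # independent log10 noise (parents)
    homolog_fraction: Optional[float] = None  # fraction of parent (homologs)
    jitter_sd: float = 0.1        # lognormal jitter of homolog fraction (log10)


@dataclass(frozen=True)
class Endpoint:
    """One phenotypic readout in one cell type.

    ``chem_weights`` maps analyte ids to nonnegative sensitivity weights
    (None for null endpoints); ``chem_strength`` and ``nonpah_weight``
    scale the chemical-burden and non-PAH contributions to potency.
    ``amplitude`` is the signed asymptotic departure from the vehicle
    level (negative = response decreases with concentration).
    """

    endpoint_id: str
    cell_type: str
    direction: str  # "increase" | "decrease"
    chem_weights: Optional[tuple] = None  # tuple of (analyte_id, weight)
    chem_strength: float = 0.0
    nonpah_weight: float = 0.0
    base_log10_ec50: float = -1.2
    hill: float = 1.5
    amplitude: float = 0.0


@dataclass(frozen=True)
class StudyDesign:
    n_samples: int = 46
    regions: tuple = ()
    endpoints: tuple = ()
    analytes: tuple = ()
    dilution_ladder: tuple = tuple(3.0 ** -k for k in range(8))  # 1.0 down, 3-fold
    n_replicates: int = 3
    vehicle_wells: int = 12
    noise_sd: float = 0.05          # replicate/vehicle response SD (vehicle-relative)
    spatial_range_km: float = 15.0  # exponential covariance range of the latent field
    latent_sd: float = 1.0          # marginal SD of the latent field
    vehicle_mean: float = 1.0
    potency_scale: float = 0.6      # log10 EC50 shift per unit driver
    potency_jitter_sd: float = 0.25  # endpoint x sample potency noise (log10)
    burden_anchor: float = 2.0      # reference weighted log10 burden
    nonpah_colocation: float = 0.8  # corr of the non-PAH driver with PAH burden
    seed: int = 0                   # seed used to build the default design tables

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.n_samples < 3:
            raise ConfigurationError("need at least 3 samples")
        shares = [r.sample_share for r in self.regions]
        if not self.regions or not math.isclose(sum(shares), 1.0, abs_tol=1e-9):
            raise ConfigurationError("region sample shares must sum to 1")
        if any(s < 0 for s in shares):
            raise ConfigurationError("region sample shares must be nonnegative")
        lad = np.asarray(self.dilution_ladder, float)
        if lad[0] != 1.0 or np.any(np.diff(lad) >= 0) or np.any(lad <= 0):
            raise ConfigurationError(
                "dilution ladder must start at 1.0 and be strictly decreasing, positive"
            )
        if self.spatial_range_km <= 0:
            raise ConfigurationError("spatial_range_km must be positive")
        parents = {a.analyte_id for a in self.analytes if a.parent_id is None and not a.is_total}
        if not parents.issubset(set(PRIORITY_PARENTS)):
            raise ConfigurationError("parent analytes must be among the 16 priority PAHs")
        for a in self.analytes:
            if a.parent_id is not None and a.parent_id not in parents:
                raise ConfigurationError(
                    f"analyte {a.analyte_id}: parent chain does not terminate "
                    f"in a designated priority parent"
                )

    # -- convenience ----------------------------------------------------
    @property
    def measured_analytes(self) -> list:
        """Non-total analytes, in panel order."""
        return [a for a in self.analytes if not a.is_total]

    @property
    def analyte_ids(self) -> list:
        return [a.analyte_id for a in self.analytes]

    @property
    def endpoint_ids(self) -> list:
        return [e.endpoint_id for e in self.endpoints]

    def region_counts(self) -> dict:
        """Largest-remainder allocation of samples to regions."""
        raw = {r.label: self.n_samples * r.sample_share for r in self.regions}
        counts = {k: int(math.floor(v)) for k, v in raw.items()}
        leftover = self.n_samples - sum(counts.values())
        order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
        for k in order[:leftover]:
            counts[k] += 1
        return counts


@dataclass
class GroundTruth:
    """Planted truth exported by the generators."""

    latent: pd.Series  # per-sample latent contamination
    true_pod: Optional[pd.DataFrame] = None  # samples x endpoints; NaN = inactive
    chem_loading: Optional[pd.DataFrame] = None  # endpoints x analytes

    def to_frame(self) -> pd.DataFrame:
        """Long-format export used by ``ground_truth.csv``."""
        if self.true_pod is None:
            return pd.DataFrame({
                "sample_id": self.latent.index,
                "latent_contamination": self.latent.values,
            })
        long = self.true_pod.stack(future_stack=True).rename("true_pod").reset_index()
        long.columns = ["sample_id", "endpoint_id", "true_pod"]
        long["active"] = long["true_pod"].notna()
        long = long.merge(
            self.latent.rename("latent_contamination"),
            left_on="sample_id", right_index=True,
        )
        return long


# ---------------------------------------------------------------------------
# default design
# ---------------------------------------------------------------------------

_PHENOTYPES = {
    "iCell_hepatocyte": ["cell_number", "cell_mean_area", "mito_intensity",
                         "nuclear_intensity", "membrane_integrity", "atp_content",
                         "viability"],
    "iCell_neuron": ["neurite_length", "branch_points", "cell_body_count",
                     "viability", "mito_intensity", "calcium_oscillation_rate",
                     "network_burst_rate"],
    "iCell_cardiomyocyte": ["beat_rate", "peak_amplitude", "decay_to_rise",
                            "peak_spacing", "cell_index", "viability",
                            "calcium_flux"],
    "iCell_endothelial": ["tube_length", "branch_count", "mean_tube_area",
                          "viability", "mito_intensity", "cell_number"],
    "HUVEC": ["tube_length", "branch_count", "total_tube_area", "viability",
              "cell_number", "mito_intensity", "migration"],
}

# endpoint driver classes: (chem_strength, nonpah_weight); None = null endpoint.
# The mix plants chemistry-driven phenotypes (mostly cardiomyocyte/hepatocyte),
# non-PAH-driven phenotypes (endothelial/HUVEC heavy) and flat nulls.
_DRIVER_CLASSES = {
    "iCell_hepatocyte": ["chem", "chem", "chem", "chem", "nonpah", "nonpah", "nonpah"],
    "iCell_neuron": ["chem", "chem", "nonpah", "nonpah", "nonpah", "nonpah", "null"],
    "iCell_cardiomyocyte": ["chem", "chem", "chem", "chem", "chem", "nonpah", "nonpah"],
    "iCell_endothelial": ["nonpah", "nonpah", "nonpah", "nonpah", "nonpah", "null"],
    "HUVEC": ["nonpah", "nonpah", "nonpah", "nonpah", "nonpah", "null", "null"],
}

_CLASS_PARAMS = {"chem": (1.0, 0.25), "nonpah": (0.3, 1.0)}


def _default_regions() -> tuple:
    return (
        Region("HSC", -95.20, 29.72, spread_km=5.0, sample_share=16 / 46, latent_offset=0.8),
        Region("MCL", -95.05, 29.55, spread_km=4.0, sample_share=12 / 46, latent_offset=0.4),
        Region("GB", -94.85, 29.40, spread_km=12.0, sample_share=18 / 46, latent_offset=0.0),
    )


def _default_analytes(rng: np.random.Generator) -> tuple:
    analytes = []
    for pid in PRIORITY_PARENTS:
        analytes.append(Analyte(
            analyte_id=pid,
            parent_id=None,
            is_total=False,
            base_log10=float(rng.uniform(1.0, 2.6)),
            latent_loading=float(rng.uniform(0.12, 0.28)),
            noise_sd=0.45,
        ))
    for pid, n_homologs in HOMOLOG_SERIES.items():
        for k in range(1, n_homologs + 1):
            analytes.append(Analyte(
                analyte_id=f"C{k}-{pid}",
                parent_id=pid,
                is_total=False,
                homolog_fraction=float(rng.uniform(0.2, 0.9)),
            ))
    for tid in TOTAL_IDS:
        analytes.append(Analyte(analyte_id=tid, parent_id=None, is_total=True))
    return tuple(analytes)


def _default_endpoints(rng: np.random.Generator, analytes: Sequence[Analyte]) -> tuple:
    measured = [a.analyte_id for a in analytes if not a.is_total]
    endpoints = []
    for cell, phens in _PHENOTYPES.items():
        for phen, cls in zip(phens, _DRIVER_CLASSES[cell]):
            eid = f"{cell}:{phen}"
            direction = "decrease" if rng.random() < 0.7 else "increase"
            if cls == "null":
                endpoints.append(Endpoint(eid, cell, direction))
                continue
            chem_strength, nonpah_weight = _CLASS_PARAMS[cls]
            chosen = rng.choice(len(measured), size=6, replace=False)
            w = rng.dirichlet(np.full(6, 2.0))
            weights = tuple(sorted((measured[i], float(wi))
                                   for i, wi in zip(chosen, w)))
            amp = float(rng.uniform(0.4, 0.8))
            endpoints.append(Endpoint(
                endpoint_id=eid,
                cell_type=cell,
                direction=direction,
                chem_weights=weights,
                chem_strength=chem_strength,
                nonpah_weight=nonpah_weight,
                base_log10_ec50=float(rng.uniform(-0.9, 0.1)),
                hill=float(rng.uniform(1.0, 2.5)),
                amplitude=amp if direction == "increase" else -amp,
            ))
    return tuple(endpoints)


def default_design(seed: int = 0, **overrides) -> StudyDesign:
    """The default 46-sample / 34-endpoint / 40-analyte study design.

    ``seed`` fixes the randomized design tables (analyte bases, endpoint
    weights); keyword overrides replace any :class:`StudyDesign` field.
    """
    rng = np.random.default_rng(seed)
    analytes = _default_analytes(rng)
    endpoints = _default_endpoints(rng, analytes)
    design = StudyDesign(
        regions=_default_regions(),
        endpoints=endpoints,
        analytes=analytes,
        seed=seed,
    )
    if overrides:
        design = replace(design, **overrides)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

_KM_PER_DEG_LAT = 111.19492664455873  # 6371.0088 km * pi / 180


def _km_to_deg(lat_deg: float, dx_km: np.ndarray, dy_km: np.ndarray):
    """Local tangent-plane conversion of km offsets to lon/lat degrees."""
    dlat = dy_km / _KM_PER_DEG_LAT
    dlon = dx_km / (_KM_PER_DEG_LAT * math.cos(math.radians(lat_deg)))
    return dlon, dlat


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_sites(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Draw sampling sites around the region centers.

    Returns a table with columns sample_id, lon, lat, region; sites are
    Gaussian around each region center with SD ``spread_km``.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    counts = design.region_counts()
    rows = []
    for region in design.regions:
        n = counts[region.label]
        dx = rng.normal(0.0, region.spread_km, size=n)
        dy = rng.normal(0.0, region.spread_km, size=n)
        dlon, dlat = _km_to_deg(region.center_lat, dx, dy)
        for k in range(n):
            rows.append({
                "sample_id": f"{region.label}-{k + 1:02d}",
                "lon": region.center_lon + dlon[k],
                "lat": region.center_lat + dlat[k],
                "region": region.label,
            })
    return pd.DataFrame(rows)


def _latent_field(design: StudyDesign, sites: pd.DataFrame,
                  rng: np.random.Generator) -> pd.Series:
    """Exact MVN draw of the latent contamination field at the sites.

    Mean = region offset; covariance = latent_sd^2 exp(-d / range) with
    haversine distance d in km.  Direct Cholesky: n stays small.
    """
    from .spatial import geo_distances  # local import to avoid a cycle at import time

    d = geo_distances(sites).values
    cov = design.latent_sd ** 2 * np.exp(-d / design.spatial_range_km)
    cov[np.diag_indices_from(cov)] += 1e-10  # jitter for Cholesky
    offsets = {r.label: r.latent_offset for r in design.regions}
    mean = sites["region"].map(offsets).values.astype(float)
    L = np.linalg.cholesky(cov)
    z = mean + L @ rng.standard_normal(len(sites))
    return pd.Series(z, index=sites["sample_id"].values, name="latent_contamination")


def generate_chemistry(sites: pd.DataFrame, design: StudyDesign,
                       seed: int) -> tuple:
    """Generate the analyte concentration table (ng/g dry weight).

    Parent log10-concentrations are affine in the latent field plus
    independent noise; each alkylated homolog is a fixed fraction of its
    parent times lognormal jitter; totals are exact sums.

    Returns ``(chem, truth)`` where ``chem`` is a wide DataFrame indexed
    by sample_id and ``truth`` a :class:`GroundTruth` with the latent
    field.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    latent = _latent_field(design, sites, rng)
    n = len(sites)
    cols = {}
    parents = {a.analyte_id: a for a in design.analytes
               if a.parent_id is None and not a.is_total}
    for a in parents.values():
        log10c = a.base_log10 + a.latent_loading * latent.values \
            + rng.normal(0.0, a.noise_sd, size=n)
        cols[a.analyte_id] = 10.0 ** log10c
    for a in design.analytes:
        if a.parent_id is not None:
            jitter = rng.normal(0.0, a.jitter_sd, size=n)
            cols[a.analyte_id] = cols[a.parent_id] * a.homolog_fraction * 10.0 ** jitter
    chem = pd.DataFrame(cols, index=latent.index)
    # exact totals
    parent_ids = list(parents)
    homolog_ids = [a.analyte_id for a in design.analytes if a.parent_id is not None]
    if "total_parent_pah16" in design.analyte_ids:
        chem["total_parent_pah16"] = chem[parent_ids].sum(axis=1)
    if "total_alkylated" in design.analyte_ids:
        chem["total_alkylated"] = chem[homolog_ids].sum(axis=1)
    if "total_pah" in design.analyte_ids:
        chem["total_pah"] = chem[parent_ids + homolog_ids].sum(axis=1)
    chem = chem[design.analyte_ids]
    chem.index.name = "sample_id"
    return chem, GroundTruth(latent=latent)


def logistic_response(dilution, amplitude, log10_ec50, hill, vehicle_mean=1.0):
    """Noiseless response at ``dilution``: vehicle level plus a signed
    logistic departure that grows with extract concentration."""
    logd = np.log10(dilution)
    return vehicle_mean + amplitude / (1.0 + 10.0 ** (hill * (log10_ec50 - logd)))


def analytic_pod(amplitude, log10_ec50, hill, band, max_dilution=1.0):
    """Dilution where the noiseless curve crosses vehicle_mean +/- band.

    Returns NaN when the curve never leaves the band within
    (0, max_dilution] (inactive).
    """
    a = abs(amplitude)
    if band <= 0:
        # zero-width band: any non-flat curve departs at arbitrarily low dilution
        return math.nan if a == 0 else 0.0
    if a <= band:
        return math.nan
    log10_pod = log10_ec50 - math.log10(a / band - 1.0) / hill
    if log10_pod > math.log10(max_dilution):
        return math.nan
    return 10.0 ** log10_pod


def generate_bioactivity(chem: pd.DataFrame, design: StudyDesign,
                         seed: int, latent: Optional[pd.Series] = None) -> tuple:
    """Generate the long plate table and the planted POD ground truth.

    Potency per sample x endpoint:

        log10 EC50 = base - potency_scale * (chem_strength * (B - anchor)
                     + nonpah_weight * nu) + jitter

    where B is the endpoint's weighted mean log10 concentration, ``nu``
    a per-sample non-PAH latent (standard normal, shared across
    endpoints), and jitter endpoint x sample potency noise.  Responses
    are the logistic curve plus Gaussian replicate noise; vehicle wells
    are Normal(vehicle_mean, noise_sd).  The recorded true POD is the
    analytic crossing of the noiseless curve with vehicle_mean +/-
    noise_sd.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    samples = list(chem.index)
    n = len(samples)
    logc = np.log10(chem[[a.analyte_id for a in design.measured_analytes]].values)
    col_ix = {a.analyte_id: j for j, a in enumerate(design.measured_analytes)}
    # Non-PAH latent driver: unmeasured co-located contamination.  It is
    # correlated (``nonpah_colocation``) with the latent contamination
    # field — contamination sources overlap spatially — but its endpoint
    # effects cannot be explained by the measured analytes.  When the
    # latent field is not supplied (standalone call), the standardized
    # mean parent log-concentration stands in for it.
    if latent is not None and np.isfinite(latent.values).all():
        m = latent.loc[chem.index].values.astype(float)
    else:
        parent_ids = [a.analyte_id for a in design.measured_analytes
                      if a.parent_id is None]
        m = np.log10(chem[parent_ids].values).mean(axis=1)
    z_hat = (m - m.mean()) / (m.std() if m.std() > 0 else 1.0)
    rho = design.nonpah_colocation
    nu = rho * z_hat + math.sqrt(max(0.0, 1.0 - rho ** 2)) * rng.standard_normal(n)

    ladder = np.asarray(design.dilution_ladder, float)
    records = []
    pod_mat = np.full((n, len(design.endpoints)), np.nan)
    loading = pd.DataFrame(
        0.0, index=design.endpoint_ids,
        columns=[a.analyte_id for a in design.measured_analytes],
    )
    band = design.noise_sd  # one vehicle SD
    for j, ep in enumerate(design.endpoints):
        if ep.chem_weights is None and ep.nonpah_weight == 0.0 or ep.amplitude == 0.0:
            # null endpoint: flat at the vehicle level
            f = np.full((n, ladder.size), design.vehicle_mean)
        else:
            w = np.zeros(logc.shape[1])
            for aid, wi in (ep.chem_weights or ()):
                w[col_ix[aid]] = wi
                loading.loc[ep.endpoint_id, aid] = wi
            burden = logc @ w
            shift = design.potency_scale * (
                ep.chem_strength * (burden - design.burden_anchor)
                + ep.nonpah_weight * nu
            )
            jitter = rng.normal(0.0, design.potency_jitter_sd, size=n)
            log10_ec50 = ep.base_log10_ec50 - shift + jitter
            f = logistic_response(
                ladder[None, :], ep.amplitude, log10_ec50[:, None], ep.hill,
                design.vehicle_mean,
            )
            for i in range(n):
                pod_mat[i, j] = analytic_pod(
                    ep.amplitude, log10_ec50[i], ep.hill, band, ladder[0],
                )
        noise = rng.normal(0.0, design.noise_sd,
                           size=(n, ladder.size, design.n_replicates))
        resp = f[:, :, None] + noise
        nrep = design.n_replicates
        vehicle = rng.normal(design.vehicle_mean, design.noise_sd,
                             size=design.vehicle_wells)
        records.append(pd.DataFrame({
            "sample_id": np.concatenate([
                np.repeat(samples, ladder.size * nrep),
                np.repeat(VEHICLE_ID, design.vehicle_wells)]),
            "endpoint_id": ep.endpoint_id,
            "cell_type": ep.cell_type,
            "dilution": np.concatenate([
                np.tile(np.repeat(ladder, nrep), n),
                np.zeros(design.vehicle_wells)]),
            "replicate": np.concatenate([
                np.tile(np.arange(1, nrep + 1), n * ladder.size),
                np.arange(1, design.vehicle_wells + 1)]),
            "response": np.concatenate([resp.ravel(), vehicle]),
        }))
    plates = pd.concat(records, ignore_index=True)
    true_pod = pd.DataFrame(pod_mat, index=pd.Index(samples, name="sample_id"),
                            columns=design.endpoint_ids)
    if latent is None:
        latent = pd.Series(np.nan, index=samples, name="latent_contamination")
    truth = GroundTruth(latent=latent, true_pod=true_pod, chem_loading=loading)
    return plates, truth


def generate_study(design: Optional[StudyDesign] = None, seed: int = 1) -> dict:
    """Run all three generators; returns sites, chemistry, plates, truth.

    Sub-seeds are derived from ``seed`` so that the three stages use
    independent streams while the whole study stays reproducible.
    """
    if design is None:
        design = default_design()
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    sites = generate_sites(design, seeds[0])
    chem, truth = generate_chemistry(sites, design, seeds[1])
    plates, truth2 = generate_bioactivity(chem, design, seeds[2], latent=truth.latent)
    return {
        "design": design,
        "sites": sites,
        "chemistry": chem,
        "plates": plates,
        "truth": truth2,
    }
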