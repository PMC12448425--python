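"""Synthetic inputs for the pipeline.

Two generators:

* phantoms — voxelized solids (ball, spheroid, cube, lobulated ball,
  plane-clipped ball) paired with an enclosing brain mask and a record of
  their analytically known volume, surface area, dural-contact area, and
  sphericity index;
* cohorts — per-patient tables with configurable marginal distributions
  (median/quartile targets) and injected covariate -> outcome effects, so
  association analyses can be validated against known truth.

All randomness flows from one seeded generator per call.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import SchemaError, SpecValidationError
from .mask_io import SegmentationPair, VolumeGrid, validate_pair
from .shape_metrics import compute_shape_report, equal_volume_sphere_area

__all__ = [
    "PhantomSpec",
    "PhantomOracle",
    "CohortSpec",
    "make_phantom",
    "simulate_cohort",
    "cohort_from_phantoms",
    "spheroid_area",
    "radial_surface_oracle",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
    "COHORT_COLUMNS",
    "LOCATIONS",
    "DIAGNOSES",
]

PHANTOM_FAMILIES = ("ball", "ellipsoid", "cube", "lobulated_ball", "clipped_ball")


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one analytic phantom.

    ``clip_depth`` is the signed distance from the ball center to the
    brain-boundary plane (positive = center inside the brain); only the
    ``clipped_ball`` family uses it and the brain mask is then a
    half-space instead of an enclosing ball.
    """

    family: str = "ball"
    radius: float = 15.0
    semi_axes: tuple[float, float, float] = (20.0, 10.0, 10.0)
    side: float = 20.0
    clip_depth: float = 5.0
    n_bumps: int = 6
    bump_amplitude: float = 0.12
    bump_sigma: float = 0.45
    spacing: float = 1.0
    margin: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.family not in PHANTOM_FAMILIES:
            raise SpecValidationError(
                f"unknown phantom family {self.family!r}; choose from {PHANTOM_FAMILIES}"
            )
        if self.spacing <= 0:
            raise SpecValidationError(f"spacing must be > 0, got {self.spacing}")
        if self.margin <= 0:
            raise SpecValidationError(f"margin must be > 0, got {self.margin}")
        if self.family in ("ball", "lobulated_ball", "clipped_ball") and self.radius <= 0:
            raise SpecValidationError(f"radius must be > 0, got {self.radius}")
        if self.family == "cube" and self.side <= 0:
            raise SpecValidationError(f"side must be > 0, got {self.side}")
        if self.family == "ellipsoid":
            if any(a <= 0 for a in self.semi_axes):
                raise SpecValidationError(f"semi-axes must be > 0, got {self.semi_axes}")
            a, b, c = sorted(self.semi_axes)
            if not (math.isclose(a, b) or math.isclose(b, c)):
                raise SpecValidationError(
                    "ellipsoid needs two equal semi-axes for a closed-form area"
                )
        if self.family == "clipped_ball" and not abs(self.clip_depth) < self.radius:
            raise SpecValidationError("|clip_depth| must be < radius")
        if self.family == "lobulated_ball":
            if self.n_bumps < 1:
                raise SpecValidationError("n_bumps must be >= 1")
            if not 0 < self.bump_amplitude * self.n_bumps < 1:
                raise SpecValidationError(
                    "bump_amplitude * n_bumps must lie in (0, 1) to keep the "
                    "solid star-shaped"
                )
            if self.bump_sigma <= 0:
                raise SpecValidationError("bump_sigma must be > 0")


@dataclass(frozen=True)
class PhantomOracle:
    """Closed-form (or quadrature) truth for one phantom, in mm units."""

    volume_mm3: float
    total_area_mm2: float
    dural_area_mm2: float
    csa_mm2: float
    si: float

    def __post_init__(self):
        if not 0 <= self.dural_area_mm2 <= self.total_area_mm2:
            raise SpecValidationError("oracle must satisfy 0 <= B <= A")
        if self.si < 1.0 - 1e-9:
            raise SpecValidationError("oracle SI must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def spheroid_area(polar: float, equatorial: float) -> float:
    """Closed-form surface area of a spheroid.

    ``polar`` is the distinct semi-axis, ``equatorial`` the repeated one.
    """
    a, b = float(polar), float(equatorial)
    if a <= 0 or b <= 0:
        raise SpecValidationError("semi-axes must be positive")
    if math.isclose(a, b, rel_tol=1e-12):
        return 4.0 * math.pi * b * b
    if a > b:  # prolate
        e = math.sqrt(1.0 - (b / a) ** 2)
        return 2.0 * math.pi * b * b * (1.0 + a / (b * e) * math.asin(e))
    e = math.sqrt(1.0 - (a / b) ** 2)  # oblate
    return 2.0 * math.pi * b * b * (1.0 + (1.0 - e * e) / e * math.atanh(e))


def radial_surface_oracle(radial_fn, n_theta: int = 600, n_phi: int = 1200):
    """Area and volume of a star-shaped solid r = f(direction).

    Area from a dense triangulation of the parametric surface, volume by
    spherical quadrature of r^3/3.  ``radial_fn`` maps (n, 3) unit vectors
    to radii.
    """
    theta = np.linspace(0.0, math.pi, n_theta + 1)
    phi = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    # unit vectors on the (theta, phi) grid
    u = np.empty((n_theta + 1, n_phi, 3))
    u[..., 0] = st[:, None] * cp[None, :]
    u[..., 1] = st[:, None] * sp[None, :]
    u[..., 2] = ct[:, None] * np.ones_like(sp)[None, :]
    r = radial_fn(u.reshape(-1, 3)).reshape(n_theta + 1, n_phi)
    pts = r[..., None] * u

    # quads (i, j)-(i+1, j)-(i+1, j+1)-(i, j+1) with periodic phi
    p00 = pts[:-1, :]
    p10 = pts[1:, :]
    p11 = np.roll(pts[1:, :], -1, axis=1)
    p01 = np.roll(pts[:-1, :], -1, axis=1)
    a1 = 0.5 * np.linalg.norm(np.cross(p10 - p00, p11 - p00), axis=-1)
    a2 = 0.5 * np.linalg.norm(np.cross(p11 - p00, p01 - p00), axis=-1)
    area = float(a1.sum() + a2.sum())

    integrand = (r**3 / 3.0) * st[:, None]
    volume = float(np.trapezoid(integrand.sum(axis=1) * (2.0 * math.pi / n_phi), theta))
    return area, volume


def _lobulated_radial_fn(spec: PhantomSpec):
    """Radial function r(u) = r0 (1 + sum_i a_i exp(-angdist_i^2 / 2 sigma^2))."""
    rng = np.random.default_rng(spec.seed)
    centers = rng.standard_normal((spec.n_bumps, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)

    def radial(u: np.ndarray) -> np.ndarray:
        cosang = np.clip(u @ centers.T, -1.0, 1.0)
        ang = np.arccos(cosang)
        bumps = spec.bump_amplitude * np.exp(-(ang**2) / (2.0 * spec.bump_sigma**2))
        return spec.radius * (1.0 + bumps.sum(axis=1))

    return radial


def _lattice(half_extent: float, spacing: float):
    """Voxel-center axes symmetric about 0 with 0 on a voxel center."""
    n_half = int(math.ceil(half_extent / spacing))
    ax = np.arange(-n_half, n_half + 1) * spacing
    return ax


def make_phantom(spec: PhantomSpec) -> tuple[SegmentationPair, PhantomOracle]:
    """Voxelize an analytic solid and its brain mask; return the pair plus
    the closed-form oracle record.

    Voxelization is by voxel-center membership.  The brain mask is an
    enclosing ball (interior families, so B = 0) or the half-space below
    the clip plane (``clipped_ball``).
    """
    spec.validate()
    s = spec.spacing

    if spec.family == "ball":
        r = spec.radius
        solid_radius = r
        oracle = PhantomOracle(
            4.0 / 3.0 * math.pi * r**3, 4.0 * math.pi * r**2, 0.0,
            4.0 * math.pi * r**2, 1.0,
        )
        inside = lambda x, y, z: x**2 + y**2 + z**2 <= r**2
    elif spec.family == "cube":
        h = spec.side / 2.0
        solid_radius = h * math.sqrt(3.0)
        vol, area = spec.side**3, 6.0 * spec.side**2
        oracle = PhantomOracle(vol, area, 0.0, area, area / equal_volume_sphere_area(vol))
        # half-open membership so a lattice-aligned cube is voxel-exact
        inside = lambda x, y, z: (
            (-h <= x) & (x < h) & (-h <= y) & (y < h) & (-h <= z) & (z < h)
        )
    elif spec.family == "ellipsoid":
        a, b, c = spec.semi_axes
        solid_radius = max(spec.semi_axes)
        # identify the repeated (equatorial) axis
        if math.isclose(a, b):
            polar, equatorial = c, a
        elif math.isclose(b, c):
            polar, equatorial = a, b
        else:
            polar, equatorial = b, a  # a == c
        vol = 4.0 / 3.0 * math.pi * a * b * c
        area = spheroid_area(polar, equatorial)
        oracle = PhantomOracle(vol, area, 0.0, area, area / equal_volume_sphere_area(vol))
        inside = lambda x, y, z: (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    elif spec.family == "lobulated_ball":
        radial = _lobulated_radial_fn(spec)
        solid_radius = spec.radius * (1.0 + spec.n_bumps * spec.bump_amplitude)
        area, vol = radial_surface_oracle(radial)
        oracle = PhantomOracle(vol, area, 0.0, area, area / equal_volume_sphere_area(vol))

        def inside(x, y, z, _radial=radial):
            p = np.stack([x, y, z], axis=-1).reshape(-1, 3)
            rho = np.linalg.norm(p, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                u = np.where(rho[:, None] > 0, p / np.where(rho[:, None] > 0, rho[:, None], 1.0), [0.0, 0.0, 1.0])
            return (rho <= _radial(u)).reshape(x.shape)
    else:  # clipped_ball
        r, d = spec.radius, spec.clip_depth
        solid_radius = r
        cap_h = r - d
        vol = 4.0 / 3.0 * math.pi * r**3 - math.pi * cap_h**2 * (3.0 * r - cap_h) / 3.0
        zone = 2.0 * math.pi * r * (r + d)
        disc = math.pi * (r**2 - d**2)
        oracle = PhantomOracle(
            vol, zone + disc, disc, zone, (zone + disc) / equal_volume_sphere_area(vol)
        )
        inside = lambda x, y, z: (x**2 + y**2 + z**2 <= r**2) & (z <= d)

    ax = _lattice(solid_radius + spec.margin, s)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    tumor_data = inside(x, y, z)

    if spec.family == "clipped_ball":
        brain_data = z <= spec.clip_depth
    else:
        brain_r = solid_radius + spec.margin / 2.0
        brain_data = x**2 + y**2 + z**2 <= brain_r**2

    origin = (float(ax[0]),) * 3
    tumor = VolumeGrid.from_array(tumor_data, (s, s, s), origin, label="tumor")
    brain = VolumeGrid.from_array(brain_data, (s, s, s), origin, label="brain")
    pair = validate_pair(tumor, brain, provenance=f"phantom:{spec.family}:seed={spec.seed}")
    return pair, oracle


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

LOCATIONS = ("frontal", "temporal", "parietal", "occipital", "insula", "central_deep")
DIAGNOSES = ("astrocytoma", "oligodendroglioma", "not_analyzed")
SEXES = ("male", "female")

COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "location",
    "eloquent",
    "diagnosis",
    "pre_volume_cm3",
    "csa_cm2",
    "si",
    "biopsy_only",
    "eor",
    "focal_deficit",
]


@dataclass(frozen=True)
class CohortSpec:
    """Marginal targets and injected effects for the cohort simulator.

    Continuous marginals are parameterized by (median, Q1, Q3) and drawn
    from split log-normals through a Gaussian copula, so sample quartiles
    match the targets asymptotically.  EOR is a clamped linear model in
    the covariates with a point mass at 1.0 (the GTR subgroup); focal
    deficits follow a logistic model.
    """

    n_patients: int = 225
    seed: int = 0

    age_median: float = 39.0
    age_q1: float = 31.0
    age_q3: float = 51.0
    volume_median: float = 32.0
    volume_q1: float = 12.8
    volume_q3: float = 70.3
    csa_median: float = 60.9
    csa_q1: float = 32.4
    csa_q3: float = 119.7
    si_median: float = 1.57
    si_q1: float = 1.36
    si_q3: float = 1.93

    male_fraction: float = 0.60
    location_probs: tuple[float, ...] = (0.587, 0.204, 0.098, 0.018, 0.084, 0.009)
    eloquent_fraction: float = 0.61
    diagnosis_probs: tuple[float, float, float] = (0.37, 0.43, 0.20)
    biopsy_only_fraction: float = 24.0 / 225.0

    # Gaussian-copula correlations between (age, volume, csa, si) latents
    corr_age_volume: float = 0.10
    corr_age_csa: float = 0.15
    corr_age_si: float = 0.15
    corr_volume_csa: float = 0.80
    corr_volume_si: float = 0.15
    corr_csa_si: float = 0.45

    # EOR = clamp(linear predictor + N(0, sd), 0, 1), plus GTR point mass
    eor_intercept: float = 1.16
    eor_beta_age: float = -0.0018
    eor_beta_volume: float = 0.0
    eor_beta_csa: float = -0.0012
    eor_beta_si: float = -0.097
    eor_beta_eloquent: float = -0.10
    eor_noise_sd: float = 0.10
    gtr_fraction: float = 0.22

    # logit P(focal deficit) = linear predictor
    deficit_intercept: float = -4.25
    deficit_beta_age: float = 0.01
    deficit_beta_volume: float = 0.004
    deficit_beta_csa: float = 0.0
    deficit_beta_si: float = 0.8
    deficit_beta_eloquent: float = 0.7

    def validate(self) -> None:
        if self.n_patients < 0:
            raise SpecValidationError("n_patients must be >= 0")
        for name in ("male_fraction", "eloquent_fraction", "biopsy_only_fraction", "gtr_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecValidationError(f"{name} must lie in [0, 1], got {v}")
        if len(self.location_probs) != len(LOCATIONS):
            raise SpecValidationError("location_probs must have 6 entries")
        if any(p < 0 or p > 1 for p in self.location_probs):
            raise SpecValidationError("location_probs must lie in [0, 1]")
        if not math.isclose(sum(self.location_probs), 1.0, abs_tol=1e-6):
            raise SpecValidationError("location_probs must sum to 1")
        if any(p < 0 for p in self.diagnosis_probs) or not math.isclose(
            sum(self.diagnosis_probs), 1.0, abs_tol=1e-6
        ):
            raise SpecValidationError("diagnosis_probs must be nonnegative and sum to 1")
        for stem in ("age", "volume", "csa", "si"):
            q1, m, q3 = (getattr(self, f"{stem}_{k}") for k in ("q1", "median", "q3"))
            if not 0 < q1 < m < q3:
                raise SpecValidationError(
                    f"{stem} quartile targets must satisfy 0 < Q1 < median < Q3"
                )
        if self.si_q1 <= 1.0:
            raise SpecValidationError("si_q1 must be > 1 (SI >= 1 by construction)")
        if self.eor_noise_sd <= 0:
            raise SpecValidationError("eor_noise_sd must be > 0")
        np.linalg.cholesky(self._copula_corr())  # raises if not PD

    def _copula_corr(self) -> np.ndarray:
        c = np.eye(4)
        c[0, 1] = c[1, 0] = self.corr_age_volume
        c[0, 2] = c[2, 0] = self.corr_age_csa
        c[0, 3] = c[3, 0] = self.corr_age_si
        c[1, 2] = c[2, 1] = self.corr_volume_csa
        c[1, 3] = c[3, 1] = self.corr_volume_si
        c[2, 3] = c[3, 2] = self.corr_csa_si
        return c


_Z75 = norm.ppf(0.75)


def _split_lognormal(z: np.ndarray, median: float, q1: float, q3: float) -> np.ndarray:
    """Map standard-normal draws to a split log-normal hitting the target
    median and quartiles exactly (in distribution)."""
    sig_lo = math.log(median / q1) / _Z75
    sig_hi = math.log(q3 / median) / _Z75
    return median * np.exp(np.where(z < 0, sig_lo, sig_hi) * z)


def _outcomes(spec, rng, age, volume, csa, si, eloquent, biopsy_only):
    n = len(age)
    is_gtr = rng.random(n) < spec.gtr_fraction
    noise = rng.normal(0.0, spec.eor_noise_sd, n)
    lin = (
        spec.eor_intercept
        + spec.eor_beta_age * age
        + spec.eor_beta_volume * volume
        + spec.eor_beta_csa * csa
        + spec.eor_beta_si * si
        + spec.eor_beta_eloquent * eloquent
    )
    eor = np.clip(lin + noise, 0.0, 1.0)
    eor[is_gtr] = 1.0

    logit = (
        spec.deficit_intercept
        + spec.deficit_beta_age * age
        + spec.deficit_beta_volume * volume
        + spec.deficit_beta_csa * csa
        + spec.deficit_beta_si * si
        + spec.deficit_beta_eloquent * eloquent
    )
    deficit = (rng.random(n) < expit(logit)).astype(float)

    eor = eor.astype(float)
    eor[biopsy_only] = np.nan
    deficit[biopsy_only] = np.nan
    return eor, deficit


def _assemble_cohort(spec, rng, age, volume, csa, si) -> pd.DataFrame:
    n = len(age)
    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    location = rng.choice(LOCATIONS, size=n, p=spec.location_probs)
    eloquent = (rng.random(n) < spec.eloquent_fraction).astype(int)
    diagnosis = rng.choice(DIAGNOSES, size=n, p=spec.diagnosis_probs)
    biopsy_only = (rng.random(n) < spec.biopsy_only_fraction).astype(int)
    eor, deficit = _outcomes(
        spec, rng, age, volume, csa, si, eloquent, biopsy_only.astype(bool)
    )
    return pd.DataFrame(
        {
            "id": [f"p{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "location": location,
            "eloquent": eloquent,
            "diagnosis": diagnosis,
            "pre_volume_cm3": volume,
            "csa_cm2": csa,
            "si": si,
            "biopsy_only": biopsy_only,
            "eor": eor,
            "focal_deficit": deficit,
        },
        columns=COHORT_COLUMNS,
    )


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table; fully reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in COHORT_COLUMNS})
    chol = np.linalg.cholesky(spec._copula_corr())
    z = rng.standard_normal((n, 4)) @ chol.T
    age = _split_lognormal(z[:, 0], spec.age_median, spec.age_q1, spec.age_q3)
    volume = _split_lognormal(z[:, 1], spec.volume_median, spec.volume_q1, spec.volume_q3)
    csa = _split_lognormal(z[:, 2], spec.csa_median, spec.csa_q1, spec.csa_q3)
    si = 1.0 + _split_lognormal(
        z[:, 3], spec.si_median - 1.0, spec.si_q1 - 1.0, spec.si_q3 - 1.0
    )
    return _assemble_cohort(spec, rng, age, volume, csa, si)


def _random_phantom_spec(rng: np.random.Generator, spacing: float) -> PhantomSpec:
    family = rng.choice(PHANTOM_FAMILIES)
    r = float(rng.uniform(7.0, 14.0))
    axis_ratio = float(rng.uniform(1.2, 2.0))
    return PhantomSpec(
        family=str(family),
        radius=r,
        semi_axes=(r * axis_ratio, r, r),
        side=float(rng.uniform(10.0, 20.0)),
        clip_depth=float(rng.uniform(-0.5, 0.7)) * r,
        n_bumps=int(rng.integers(3, 8)),
        bump_amplitude=float(rng.uniform(0.04, 0.12)),
        bump_sigma=float(rng.uniform(0.3, 0.6)),
        spacing=spacing,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def cohort_from_phantoms(
    n: int,
    seed: int = 0,
    spacing: float = 1.0,
    clinical_spec: CohortSpec | None = None,
) -> pd.DataFrame:
    """End-to-end cohort: measure shape metrics on generated phantom pairs,
    then attach simulated clinical covariates and outcomes.

    The geometric columns (volume, CSA, SI) come from the measurement
    pipeline run on the voxelized phantoms, not from distribution draws.
    """
    if n < 1:
        raise SpecValidationError("n must be >= 1")
    spec = clinical_spec if clinical_spec is not None else CohortSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    volume, csa, si = np.empty(n), np.empty(n), np.empty(n)
    for i in range(n):
        pair, _ = make_phantom(_random_phantom_spec(rng, spacing))
        report = compute_shape_report(pair)
        volume[i] = report.volume_cm3
        csa[i] = report.csa_cm2
        si[i] = report.sphericity_index
    age = _split_lognormal(rng.standard_normal(n), spec.age_median, spec.age_q1, spec.age_q3)
    return _assemble_cohort(spec, rng, age, volume, csa, si)


# --------------------------------------------------------------------------
# cohort table I/O
# --------------------------------------------------------------------------

_COHORT_DTYPES = {
    "id": str,
    "sex": str,
    "location": str,
    "diagnosis": str,
    "eloquent": "int64",
    "biopsy_only": "int64",
    "age": float,
    "pre_volume_cm3": float,
    "csa_cm2": float,
    "si": float,
    "eor": float,
    "focal_deficit": float,
}


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 comma-separated CSV with header."""
    cohort.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read and schema-validate a cohort CSV."""
    df = pd.read_csv(path, dtype={k: v for k, v in _COHORT_DTYPES.items() if v is str})
    problems = validate_cohort(df)
    if problems:
        raise SchemaError(problems)
    return df


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Return a list of schema violations (empty when valid)."""
    problems = []
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing column {col!r}")
    if problems or not len(df):
        return problems
    if not set(df["sex"].unique()) <= set(SEXES):
        problems.append("sex must be male/female")
    if not set(df["location"].unique()) <= set(LOCATIONS):
        problems.append(f"location values must be among {LOCATIONS}")
    if not set(df["diagnosis"].unique()) <= set(DIAGNOSES):
        problems.append(f"diagnosis values must be among {DIAGNOSES}")
    for col in ("eloquent", "biopsy_only"):
        if not df[col].isin([0, 1]).all():
            problems.append(f"{col} must be 0/1")
    if (df["si"] < 1.0 - 1e-6).any():
        problems.append("si must be >= 1")
    if (df["csa_cm2"] < 0).any():
        problems.append("csa_cm2 must be >= 0")
    if (df["pre_volume_cm3"] <= 0).any():
        problems.append("pre_volume_cm3 must be > 0")
    eor = df["eor"]
    if ((eor < 0) | (eor > 1)).any():
        problems.append("eor must lie in [0, 1] where present")
    resection = df["biopsy_only"] == 0
    if eor[resection].isna().any() or eor[~resection].notna().any():
        problems.append("eor must be present iff biopsy_only is 0")
    fd = df["focal_deficit"]
    if fd[resection].isna().any() or fd[~resection].notna().any():
        problems.append("focal_deficit must be present iff biopsy_only is 0")
    if not fd[resection].isin([0.0, 1.0]).all():
        problems.append("focal_deficit must be 0/1 where present")
    return problems
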