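"""Synthetic multiparametric digital phantom with known ground truth.

Generates MT pairs, diffusion series, DSC time series and metabolic (RER)
records that emulate a four-group preclinical glioma study — male/female x
tumour/sham rats, n = 8 per group — on a 128 x 128 x 5 grid with 273 um
in-plane resolution and 1.5 mm slices. The lesion is an ellipsoidal
tumour (~90 mm^3, within the 75-100 mm^3 scan-trigger range) split into a
core and a 2-voxel periphery ring, placed off-centre in one hemisphere
with a mirrored contralateral reference region.

Ground truth is piecewise constant: background brain carries the sham
values of the matching sex, the core/periphery carry the group's values,
and the perfusion quantities are stored on the relative scale (reference
region = 1), so every downstream quantification stage can be checked
against exact known answers. Between-subject spread defaults to SEM *
sqrt(8), reconstructing the population SD from the reported standard
errors.

Noise is Rician for magnitude images (magnitude of a complex Gaussian
channel pair), with SNR defined as noiseless signal over the Gaussian
sigma.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dsc import DSCAcquisition, gamma_variate
from .dti import DiffusionScheme, default_scheme
from .mt import MTPair
from .volumes import ImageVolume, ROIMask

__all__ = [
    "GROUPS",
    "PARAMETERS",
    "PhantomGeometry",
    "GroupEffectTable",
    "PhantomTruth",
    "SubjectAcquisition",
    "default_effects",
    "make_truth",
    "tensor_from_md_fa",
    "tensor_field_from_maps",
    "add_rician_noise",
    "simulate_mt_pair",
    "simulate_dwi",
    "simulate_dsc",
    "simulate_cohort",
    "RERConfig",
    "simulate_rer",
    "simulate_rer_cohort",
]

GROUPS = ("male/tumour", "female/tumour", "male/sham", "female/sham")
PARAMETERS = ("MTR", "MD", "FA", "CBV", "CBF", "MTT")
_MAP_PARAMS = ("MTR", "MD", "FA")          # mapped per core/periphery
_PERF_PARAMS = ("CBV", "CBF", "MTT")       # whole-tumour, relative scale

N_PER_GROUP = 8                            # imaging cohort size per group


@dataclass(frozen=True)
class PhantomGeometry:
    """Grid and lesion geometry (distances in mm)."""

    matrix: tuple[int, int, int] = (128, 128, 5)
    in_plane_mm: float = 0.273
    slice_mm: float = 1.5
    brain_radius_mm: float = 14.0
    tumour_centre_mm: tuple[float, float, float] = (5.0, 1.5, 0.0)
    tumour_radius_mm: float = 2.78          # ~90 mm^3 ellipsoid
    periphery_ring_mm: float = 0.546        # 2 in-plane voxels

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", tuple(int(v) for v in self.matrix))
        object.__setattr__(self, "tumour_centre_mm",
                           tuple(float(v) for v in self.tumour_centre_mm))
        if self.in_plane_mm <= 0 or self.slice_mm <= 0:
            raise ValueError("voxel dimensions must be positive")
        if self.periphery_ring_mm >= self.tumour_radius_mm:
            raise ValueError("periphery ring must be thinner than the tumour")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return (self.in_plane_mm, self.in_plane_mm, self.slice_mm)

    @property
    def voxel_volume(self) -> float:
        return self.in_plane_mm**2 * self.slice_mm

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-centre coordinates (mm), origin at grid centre."""
        nx, ny, nz = self.matrix
        x = (np.arange(nx) - (nx - 1) / 2) * self.in_plane_mm
        y = (np.arange(ny) - (ny - 1) / 2) * self.in_plane_mm
        z = (np.arange(nz) - (nz - 1) / 2) * self.slice_mm
        return np.meshgrid(x, y, z, indexing="ij")

    def masks(self) -> dict[str, ROIMask]:
        """Brain, core, periphery, whole-tumour and mirrored reference masks.

        Cached per geometry (the instance is frozen): callers must treat
        the returned masks as read-only.
        """
        cached = getattr(self, "_masks_cache", None)
        if cached is not None:
            return cached
        xx, yy, zz = self.coordinates()
        cx, cy, cz = self.tumour_centre_mm
        brain = xx**2 + yy**2 <= self.brain_radius_mm**2
        dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2)
        tumour = (dist <= self.tumour_radius_mm) & brain
        core = (dist <= self.tumour_radius_mm - self.periphery_ring_mm) & brain
        periphery = tumour & ~core
        ref_dist = np.sqrt((xx + cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2)
        reference = (ref_dist <= self.tumour_radius_mm - self.periphery_ring_mm) \
            & brain & ~tumour
        vs = self.voxel_size
        out = {
            "brain": ROIMask(brain, vs, "brain"),
            "core": ROIMask(core, vs, "core"),
            "periphery": ROIMask(periphery, vs, "periphery"),
            "tumour": ROIMask(tumour, vs, "whole-tumour"),
            "reference": ROIMask(reference, vs, "reference"),
        }
        object.__setattr__(self, "_masks_cache", out)
        return out


def default_effects() -> pd.DataFrame:
    """The four-group effect table: mean and SEM per region and parameter.

    MTR (%), MD (um^2/s) and FA are given per tumour core and periphery;
    the perfusion quantities CBV, CBF and MTT are relative values over the
    whole tumour (the perfusion maps are too coarse to split the lesion).
    Columns: group, region, parameter, mean, sem.
    """
    rows: list[tuple[str, str, str, float, float]] = []

    def block(region: str, param: str, cells: list[tuple[float, float]]) -> None:
        for group, (mean, sem) in zip(GROUPS, cells):
            rows.append((group, region, param, mean, sem))

    block("core", "MTR", [(14.29, 0.35), (13.02, 0.07), (20.13, 0.23), (18.57, 0.22)])
    block("core", "MD", [(1200, 9), (1120, 5), (1028, 4), (988, 5)])
    block("core", "FA", [(0.244, 0.002), (0.224, 0.001), (0.348, 0.002), (0.314, 0.002)])
    block("periphery", "MTR", [(22.00, 0.16), (19.60, 0.12), (20.10, 0.20), (18.14, 0.22)])
    block("periphery", "MD", [(963, 5), (955, 4), (1036, 5), (1006, 5)])
    block("periphery", "FA", [(0.279, 0.002), (0.232, 0.001), (0.340, 0.002), (0.316, 0.002)])
    block("tumour", "CBV", [(1.44, 0.03), (1.55, 0.04), (0.81, 0.04), (0.97, 0.03)])
    block("tumour", "CBF", [(1.56, 0.03), (1.55, 0.03), (0.81, 0.04), (0.97, 0.03)])
    block("tumour", "MTT", [(1.077, 0.009), (0.934, 0.006), (0.933, 0.011), (0.953, 0.010)])
    return pd.DataFrame(rows, columns=["group", "region", "parameter", "mean", "sem"])


GroupEffectTable = pd.DataFrame  # alias: the effect table is a tidy DataFrame


def _lookup(effects: pd.DataFrame, group: str, region: str, param: str) -> float:
    sel = effects[(effects.group == group) & (effects.region == region)
                  & (effects.parameter == param)]
    if sel.empty:
        raise KeyError(f"effect table has no entry for ({group}, {region}, {param})")
    return float(sel["mean"].iloc[0])


def _validate_group(effects: pd.DataFrame, group: str) -> None:
    known = sorted(effects.group.unique())
    if group not in known:
        raise ValueError(f"unknown group {group!r}; valid groups: {known}")


@dataclass
class PhantomTruth:
    """Ground-truth parameter maps and masks for one simulated subject."""

    geometry: PhantomGeometry
    group: str
    maps: dict[str, np.ndarray]            # param -> 3D truth map
    masks: dict[str, ROIMask]
    orientation: np.ndarray                # (3,) principal diffusion axis
    seed: int
    region_values: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def sex(self) -> str:
        return self.group.split("/")[0]

    @property
    def condition(self) -> str:
        return self.group.split("/")[1]


def make_truth(geometry: PhantomGeometry, effects: pd.DataFrame, group: str,
               seed: int = 0,
               region_values: dict[tuple[str, str], float] | None = None,
               perturbation_sd: float = 0.0) -> PhantomTruth:
    """Build piecewise-constant ground-truth maps for one subject.

    Background brain carries the sham values of the matching sex (the
    perfusion background sits at the reference level 1.0); the tumour
    core/periphery carry the group's values. ``region_values`` overrides
    individual (region, parameter) cells — this is how per-subject draws
    enter. ``perturbation_sd`` adds an optional smooth multiplicative
    spatial field (relative SD); it is off by default so table-level
    round trips stay exact. Deterministic given ``seed``.
    """
    _validate_group(effects, group)
    sex = group.split("/")[0]
    sham = f"{sex}/sham"
    overrides = region_values or {}
    masks = geometry.masks()
    brain = masks["brain"].data
    rng = np.random.default_rng(seed)

    def value(region: str, param: str, fallback: float | None = None) -> float:
        if (region, param) in overrides:
            return float(overrides[(region, param)])
        try:
            return _lookup(effects, group, region, param)
        except KeyError:
            if fallback is None:
                raise
            return fallback                  # partial effect tables

    present = set(effects[effects.group == group].parameter)
    maps: dict[str, np.ndarray] = {}
    for param in _MAP_PARAMS:
        if param not in present:
            continue
        background = _lookup(effects, sham, "core", param)
        m = np.zeros(geometry.matrix)
        m[brain] = background
        m[masks["core"].data] = value("core", param, background)
        m[masks["periphery"].data] = value("periphery", param, background)
        maps[param] = m
    for param in _PERF_PARAMS:
        if param not in present:
            continue
        m = np.zeros(geometry.matrix)
        m[brain] = 1.0                      # reference level
        m[masks["tumour"].data] = value("tumour", param, 1.0)
        maps[param] = m

    if perturbation_sd > 0:
        # smooth multiplicative field: low-order cosine modes, seeded
        xx, yy, zz = geometry.coordinates()
        phase = rng.uniform(0, 2 * np.pi, size=3)
        wave = (np.cos(2 * np.pi * xx / 20.0 + phase[0])
                + np.cos(2 * np.pi * yy / 20.0 + phase[1])
                + np.cos(2 * np.pi * zz / 10.0 + phase[2])) / 3.0
        for param in _MAP_PARAMS:
            maps[param] = maps[param] * (1.0 + perturbation_sd * wave)

    return PhantomTruth(geometry=geometry, group=group, maps=maps, masks=masks,
                        orientation=np.array([0.0, 0.0, 1.0]), seed=seed,
                        region_values=dict(overrides))


# ---------------------------------------------------------------------------
# diffusion-tensor construction


def tensor_from_md_fa(md: float, fa: float, orientation=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Axially symmetric (prolate) tensor with prescribed MD and FA.

    For eigenvalues (MD + 2d, MD - d, MD - d) the standard FA closed form
    gives d = MD * FA / sqrt(3 - 2 FA^2), which stays non-negative-definite
    for all FA in [0, 1); FA = 1 (the stick limit) is excluded. The first
    eigenvector is ``orientation``.
    """
    if md <= 0:
        raise ValueError(f"MD must be positive, got {md}")
    if not (0 <= fa < 1):
        raise ValueError(
            f"FA must lie in [0, 1) for a cylindrically symmetric "
            f"non-negative spectrum, got {fa}"
        )
    n = np.asarray(orientation, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("orientation must be a non-zero vector")
    n = n / norm
    d = md * fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam_perp = md - d
    lam_par = md + 2.0 * d
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(n, n)


def tensor_field_from_maps(md: np.ndarray, fa: np.ndarray,
                           orientation: np.ndarray) -> np.ndarray:
    """Vectorized prolate tensor field from MD/FA maps (um^2/s).

    ``orientation`` is either one unit 3-vector for the whole field or a
    per-voxel (..., 3) array.
    """
    md = np.asarray(md, dtype=float)
    fa = np.asarray(fa, dtype=float)
    n = np.asarray(orientation, dtype=float)
    if n.ndim == 1:
        n = np.broadcast_to(n, md.shape + (3,))
    d = md * fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam_perp = md - d
    lam_par = md + 2.0 * d
    eye = np.eye(3)
    outer = n[..., :, None] * n[..., None, :]
    return lam_perp[..., None, None] * eye + (lam_par - lam_perp)[..., None, None] * outer


# ---------------------------------------------------------------------------
# noise and modality simulators


def add_rician_noise(signal: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + n1) + i n2 with n1, n2 ~ N(0, sigma)."""
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def _check_snr(snr) -> None:
    if snr is not None and snr <= 0:
        raise ValueError(f"SNR must be positive, got {snr}")


def simulate_mt_pair(truth: PhantomTruth, snr: float | None = None,
                     seed: int = 0, s0_reference: float = 1000.0) -> MTPair:
    """Render the MT-off/MT-on pair from the truth MTR map.

    Noiseless S0 is a flat reference intensity inside the brain and
    S_MT = S0 * (1 - MTR/100); with ``snr`` given, Rician noise with
    sigma = s0_reference / snr is applied to both volumes.
    """
    _check_snr(snr)
    mtr = truth.maps["MTR"]
    if np.any(mtr > 100):
        raise ValueError("truth MTR must not exceed 100%")
    brain = truth.masks["brain"].data
    s0 = np.where(brain, s0_reference, 0.0)
    smt = s0 * (1.0 - mtr / 100.0)
    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = s0_reference / snr
        s0 = add_rician_noise(s0, sigma, rng)
        smt = add_rician_noise(smt, sigma, rng)
    vs = truth.geometry.voxel_size
    return MTPair(s0=ImageVolume(s0, vs), smt=ImageVolume(smt, vs))


def simulate_dwi(truth: PhantomTruth, scheme: DiffusionScheme | None = None,
                 snr: float | None = None, seed: int = 0,
                 s0_reference: float = 1000.0) -> ImageVolume:
    """Render the diffusion series from the truth MD/FA maps.

    Per voxel, S = S0 * exp(-b g^T D g) with the prolate tensor field
    consistent with the MD/FA truth (principal axis = truth orientation);
    Rician noise with sigma = s0_reference / snr if requested.
    """
    _check_snr(snr)
    if scheme is None:
        scheme = default_scheme()
    brain = truth.masks["brain"].data
    tensors = tensor_field_from_maps(truth.maps["MD"], truth.maps["FA"],
                                     truth.orientation)
    n_vol = len(scheme)
    shape = truth.geometry.matrix
    series = np.zeros(shape + (n_vol,))
    for i, (b, g) in enumerate(zip(scheme.bvals, scheme.bvecs)):
        # b [s/mm^2] * D [um^2/s] * 1e-6 is dimensionless
        exponent = b * 1e-6 * np.einsum("...ij,i,j->...", tensors, g, g)
        series[..., i] = np.where(brain, s0_reference * np.exp(-exponent), 0.0)
    if snr is not None:
        rng = np.random.default_rng(seed)
        series = add_rician_noise(series, s0_reference / snr, rng)
    return ImageVolume(series, truth.geometry.voxel_size)


# reference-tissue bolus shape: alpha0, beta0 chosen so the reference MTT
# is beta0*(alpha0+1) = 3.6 s, a typical first-pass width; amplitudes are
# arbitrary units throughout (no AIF calibration exists)
_DSC_ALPHA0 = 2.0
_DSC_BETA0 = 1.2
_DSC_K0 = 100.0
_DSC_SBASE = 1000.0


def dsc_gamma_parameters(truth: PhantomTruth
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel (K, alpha, beta) realizing the relative CBV/MTT truth.

    alpha is held at the reference shape; beta scales with the relative
    MTT and K absorbs the relative CBV, so the analytic CBV and MTT of
    every voxel sit exactly at truth * reference value.
    """
    rel_cbv = truth.maps["CBV"]
    rel_mtt = truth.maps["MTT"]
    alpha = np.full(rel_cbv.shape, _DSC_ALPHA0)
    beta = _DSC_BETA0 * rel_mtt
    cbv_ref = _DSC_K0 * _DSC_BETA0 ** (_DSC_ALPHA0 + 1) * 2.0  # Gamma(3) = 2
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(beta > 0,
                     rel_cbv * cbv_ref /
                     np.where(beta > 0, beta, 1.0) ** (_DSC_ALPHA0 + 1) / 2.0,
                     0.0)
    return K, alpha, beta


def simulate_dsc(truth: PhantomTruth, acq: DSCAcquisition | None = None,
                 seed: int = 0, noise_sd: float | None = None) -> ImageVolume:
    """Render the DSC time series from the truth perfusion maps.

    Concentration follows the gamma-variate bolus model with arrival at
    the injection time; signal is S_base * exp(-TE * C(t)) with optional
    Gaussian noise on the signal.
    """
    if acq is None:
        acq = DSCAcquisition()
    t0 = acq.injection_time_s
    times = acq.times
    if t0 <= times[0] or t0 >= times[-1]:
        raise ValueError(
            f"bolus arrival {t0} s lies outside the acquisition window "
            f"[{times[0]}, {times[-1]}] s"
        )
    brain = truth.masks["brain"].data
    K, alpha, beta = dsc_gamma_parameters(truth)
    x = times[None, :] - t0                              # (1, T)
    Kv = K[brain][:, None]
    av = alpha[brain][:, None]
    bv = beta[brain][:, None]
    pos = x > 0
    conc = np.where(pos, Kv * np.where(pos, x, 1.0) ** av * np.exp(-x / bv), 0.0)
    sig = _DSC_SBASE * np.exp(-acq.te_s * conc)
    series = np.zeros(truth.geometry.matrix + (len(times),))
    series[brain] = sig
    if noise_sd is not None:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, noise_sd, series.shape)
        series[~brain] = 0.0
    return ImageVolume(series, truth.geometry.voxel_size)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SubjectAcquisition:
    """One simulated subject's truth and rendered acquisitions."""

    subject_id: str
    group: str
    truth: PhantomTruth
    mt_pair: MTPair | None = None
    dwi: ImageVolume | None = None
    dsc: ImageVolume | None = None


def simulate_cohort(effects: pd.DataFrame, n_per_group: int = N_PER_GROUP,
                    seed: int = 0, subject_sd: pd.DataFrame | str = "sem",
                    render: bool = False,
                    geometry: PhantomGeometry | None = None,
                    scheme: DiffusionScheme | None = None,
                    acq: DSCAcquisition | None = None,
                    snr: float | None = None,
                    groups: tuple[str, ...] = GROUPS
                    ) -> tuple[pd.DataFrame, list[SubjectAcquisition]]:
    """Draw a cohort of subjects around the group effect table.

    Subject-level region means are Normal(group mean, SD); by default the
    between-subject SD reconstructs the population SD from the reported
    standard errors as SEM * sqrt(8). ``subject_sd`` may instead be a
    DataFrame shaped like the effect table with an ``sd`` column (use 0
    for a deterministic cohort).

    Returns a tidy per-subject truth table (subject, sex, condition,
    group, region, parameter, value) and, when ``render`` is set, the
    per-subject image acquisitions for the full pipeline.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group (SEM undefined otherwise)")
    for g in groups:
        _validate_group(effects, g)
    geometry = geometry or PhantomGeometry()
    rng = np.random.default_rng(seed)

    if isinstance(subject_sd, str):
        if subject_sd != "sem":
            raise ValueError("subject_sd must be 'sem', or a DataFrame with an 'sd' column")
        sd_table = effects.assign(sd=effects["sem"] * np.sqrt(N_PER_GROUP))
    else:
        sd_table = subject_sd

    def sd_for(group: str, region: str, param: str) -> float:
        sel = sd_table[(sd_table.group == group) & (sd_table.region == region)
                       & (sd_table.parameter == param)]
        return float(sel["sd"].iloc[0]) if not sel.empty else 0.0

    rows = []
    subjects: list[SubjectAcquisition] = []
    counter = itertools.count(1)
    for group in groups:
        cells = effects[effects.group == group]
        for _ in range(n_per_group):
            sid = f"sub-{next(counter):03d}"
            draws: dict[tuple[str, str], float] = {}
            for _, cell in cells.iterrows():
                key = (cell.region, cell.parameter)
                val = rng.normal(cell["mean"], sd_for(group, *key))
                if cell.parameter in ("MD", "CBV", "CBF", "MTT"):
                    val = max(val, 1e-6)
                if cell.parameter == "FA":
                    val = float(np.clip(val, 0.0, 0.999))
                draws[key] = float(val)
                sex, condition = group.split("/")
                rows.append((sid, sex, condition, group, cell.region,
                             cell.parameter, val))
            if render:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                truth = make_truth(geometry, effects, group, seed=sub_seed,
                                   region_values=draws)
                subjects.append(SubjectAcquisition(
                    subject_id=sid, group=group, truth=truth,
                    mt_pair=simulate_mt_pair(truth, snr=snr, seed=sub_seed),
                    dwi=simulate_dwi(truth, scheme=scheme, snr=snr,
                                     seed=sub_seed + 1),
                    dsc=simulate_dsc(truth, acq=acq, seed=sub_seed + 2),
                ))
            else:
                subjects.append(SubjectAcquisition(
                    subject_id=sid, group=group,
                    truth=make_truth(geometry, effects, group, seed=0,
                                     region_values=draws)))
    table = pd.DataFrame(rows, columns=["subject", "sex", "condition", "group",
                                        "region", "parameter", "value"])
    return table, subjects


# ---------------------------------------------------------------------------
# metabolic (RER) simulation


@dataclass(frozen=True)
class RERConfig:
    """Circadian RER generator settings.

    Sham rats run a higher RER in the dark (active, feeding) phase than in
    the light phase; tumour groups are shifted down by sex-specific
    percentages of the sham level, separately per cycle. Values are
    dimensionless VCO2/VO2 ratios.
    """

    sham_day_mean: float = 0.88
    sham_night_mean: float = 0.97
    # percent change of the tumour groups vs sham, per sex and cycle
    tumour_day_offset_pct: dict = field(default_factory=lambda: {
        "male": -4.85, "female": -1.22})
    tumour_night_offset_pct: dict = field(default_factory=lambda: {
        "male": -4.11, "female": -1.99})
    bin_minutes: float = 30.0
    light_hours: float = 12.0          # light period length (starts at t = 0)
    bin_noise_sd: float = 0.01
    subject_sd_frac: float = 0.003     # multiplicative between-subject spread


def simulate_rer(group: str, hours: float = 60.0, seed: int = 0,
                 config: RERConfig | None = None) -> pd.DataFrame:
    """One subject's RER series in 30-min bins with light/dark labels.

    The underlying profile is a sinusoid whose light- and dark-phase means
    equal the configured day/night means (the half-cycle mean of a cosine
    is 2/pi of its amplitude, hence the pi/2 factor), plus Gaussian bin
    noise. Returns a DataFrame with columns time_h, rer, light.
    """
    if hours <= 0:
        raise ValueError("duration must be positive")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; valid groups: {sorted(GROUPS)}")
    cfg = config or RERConfig()
    sex, condition = group.split("/")
    day, night = cfg.sham_day_mean, cfg.sham_night_mean
    if condition == "tumour":
        day = day * (1.0 + cfg.tumour_day_offset_pct[sex] / 100.0)
        night = night * (1.0 + cfg.tumour_night_offset_pct[sex] / 100.0)

    rng = np.random.default_rng(seed)
    subject_factor = rng.normal(1.0, cfg.subject_sd_frac)
    n_bins = int(round(hours * 60.0 / cfg.bin_minutes))
    t = (np.arange(n_bins) + 0.5) * cfg.bin_minutes / 60.0      # bin centres, h
    period = 2.0 * cfg.light_hours
    light = (t % period) < cfg.light_hours
    mid = (day + night) / 2.0
    # pi/2 factor: the half-cycle mean of a cosine lobe is 2/pi of its
    # amplitude, so the light/dark bin means land exactly on day/night
    amp = (day - night) / 2.0 * (np.pi / 2.0)
    # cosine phased so its positive lobe spans the light phase [0, L)
    profile = mid + amp * np.cos(
        2.0 * np.pi * ((t % period) - cfg.light_hours / 2.0) / period)
    rer = subject_factor * profile + rng.normal(0.0, cfg.bin_noise_sd, n_bins)
    return pd.DataFrame({"time_h": t, "rer": rer, "light": light})


def simulate_rer_cohort(n_per_group: int = 5, hours: float = 60.0,
                        seed: int = 0, config: RERConfig | None = None,
                        groups: tuple[str, ...] = GROUPS) -> pd.DataFrame:
    """RER records for a whole cohort (tidy: one row per subject per bin)."""
    rng = np.random.default_rng(seed)
    frames = []
    counter = itertools.count(1)
    for group in groups:
        for _ in range(n_per_group):
            sid = f"met-{next(counter):03d}"
            rec = simulate_rer(group, hours=hours,
                               seed=int(rng.integers(0, 2**31 - 1)),
                               config=config)
            sex, condition = group.split("/")
            rec.insert(0, "subject", sid)
            rec.insert(1, "sex", sex)
            rec.insert(2, "condition", condition)
            rec.insert(3, "group", group)
            frames.append(rec)
    return pd.concat(frames, ignore_index=True)
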