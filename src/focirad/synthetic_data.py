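"""Forward model for repair-focus imaging experiments with known ground truth.

The generator emulates the structure of a nanoparticle radiosensitization
study: adherent cancer-cell nuclei imaged as ~40 confocal slices with 0.3 µm
z-step, γH2AX/53BP1 repair foci whose number rises after irradiation, peaks
between 30 min and 1 h post-irradiation (PI) and then decays, focus size
growing with repair time, early foci with low marker colocalization that
matures over time, and SMLM fields in which antibody tags cluster inside foci
at 10-20 nm localization precision.

Focus-count kinetics
--------------------
The expected colocalizable focus count per nucleus follows

    N(dose, t) = baseline + effect * alpha * dose * F(t) * D(t)
    F(t) = 1 - exp(-t / tau_form)                       (formation)
    D(t) = f * exp(-t / tau_fast) + (1 - f) * exp(-t / tau_slow)  (repair)

with a colocalization maturation probability
``p_coloc(t) = 1 - exp(-t / coloc_rise_tau)``: every true focus carries the
γH2AX marker, and with probability ``p_coloc`` also the 53BP1 marker. The
default time constants place the peak of the total count at ~38 min and the
peak of the colocalized (DSB) count at ~55 min PI, with ~12.5 induced foci
per nucleus per Gy at the formation plateau.

All randomness flows through one explicitly passed ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from focirad.datatypes import ConfocalStack, LocalizationSet, make_count_record

# Times of the study's fixation schedule, minutes PI (5 min ... 24 h; the 48 h
# point is available but rarely simulated).
STANDARD_TIME_GRID_MIN = (5.0, 30.0, 60.0, 120.0, 240.0, 480.0, 1440.0)


@dataclass
class ScenarioConfig:
    """Biological scenario: induction, repair kinetics and treatment effect.

    Parameters
    ----------
    alpha_induction:
        Induced foci per nucleus per Gy at the formation plateau (default
        12.5, the manual-count calibration scale).
    baseline_rate:
        Spontaneous foci per nucleus in unirradiated cells. 3.47 is the
        U87-like default; 2.03 is HeLa-like.
    tau_form_min, tau_fast_min, tau_slow_min, fast_fraction:
        Formation time constant and biexponential repair decay. Defaults put
        the total-count peak at ~38 min PI.
    coloc_rise_tau_min:
        Time constant of γH2AX/53BP1 colocalization maturation; early foci
        are mostly single-marker, mature foci colocalize.
    size_growth:
        ``(initial_radius_um, final_radius_um, growth_tau_min)`` — focus
        radius grows saturating-exponentially with time PI.
    treatment_effect:
        Multiplicative factor on the induction rate for treated cells.
        1.0 encodes the null scenario (nanoparticles change nothing).
    smlm_quadratic_coeff:
        Optional supra-linear term (tags/Gy²) on the SMLM dose-efficiency
        curve, active above ``smlm_quadratic_onset_gy``; 0 disables it.
    """

    alpha_induction: float = 12.5
    baseline_rate: float = 3.47
    tau_form_min: float = 15.0
    tau_fast_min: float = 100.0
    tau_slow_min: float = 1000.0
    fast_fraction: float = 0.6
    coloc_rise_tau_min: float = 20.0
    size_growth: tuple[float, float, float] = (0.25, 0.60, 300.0)
    treatment_effect: float = 1.0
    coloc_jitter_um: float = 0.15
    focus_min_separation_um: float = 0.7
    smlm_quadratic_coeff: float = 0.0
    smlm_quadratic_onset_gy: float = 2.0
    cell_line: str = "U87"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "alpha_induction",
            "baseline_rate",
            "tau_form_min",
            "tau_fast_min",
            "tau_slow_min",
            "coloc_rise_tau_min",
            "treatment_effect",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise ValueError("fast_fraction must lie in [0, 1]")
        r0, r1, tau = self.size_growth
        if r0 <= 0 or r1 <= 0 or tau <= 0:
            raise ValueError("size_growth entries must be positive")
        if r0 > r1:
            raise ValueError("initial focus radius must not exceed final radius")

    # -- kinetics helpers -------------------------------------------------
    def p_coloc(self, t_pi_min: float) -> float:
        """Probability that a focus carries both markers at time t."""
        t = np.asarray(t_pi_min, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be >= 0")
        return 1.0 - np.exp(-t / self.coloc_rise_tau_min)

    def focus_radius_um(self, t_pi_min: float) -> float:
        """Mean focus radius at time t (saturating growth)."""
        t = np.asarray(t_pi_min, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be >= 0")
        r0, r1, tau = self.size_growth
        return r0 + (r1 - r0) * (1.0 - np.exp(-t / tau))


def hela_like(**overrides) -> ScenarioConfig:
    """Scenario preset with the HeLa-like baseline focus rate."""
    overrides.setdefault("baseline_rate", 2.03)
    overrides.setdefault("cell_line", "HeLa")
    return ScenarioConfig(**overrides)


@dataclass
class ImagingConfig:
    """Confocal acquisition geometry and photon model."""

    n_slices: int = 40
    z_step_um: float = 0.3
    xy_pixel_um: float = 0.1
    psf_sigma_um: tuple[float, float] = (0.13, 0.35)  # (lateral, axial)
    background_level: float = 0.5
    nuclear_level: float = 0.35  # diffuse antibody signal inside the nucleus
    chromatin_level: float = 1.0
    focus_amplitude: float = 2.0
    photon_scale: float = 100.0
    read_noise_sd: float = 2.0
    noise_model: str = "poisson"  # or "poisson+gaussian"
    cell_spacing_um: float = 11.0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        for name in ("z_step_um", "xy_pixel_um", "photon_scale", "cell_spacing_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_model not in ("poisson", "poisson+gaussian"):
            raise ValueError("noise_model must be 'poisson' or 'poisson+gaussian'")


@dataclass
class SmlmConfig:
    """SMLM acquisition and labeling model.

    The within-focus tag multiplicity and blinking statistics are not
    constrained by published measurements; ``tags_per_focus``,
    ``blinks_per_tag_mean`` and ``cluster_sigma_nm`` are model placeholders,
    calibrated once so the mean nearest-neighbor distance of localizations
    falls in the reported 20-25 nm band.
    """

    frame_count: int = 4000  # drawn from 2000-6000 when frame_count_range used
    frame_count_range: tuple[int, int] = (2000, 6000)
    loc_precision_nm: tuple[float, float] = (10.0, 20.0)
    tags_per_focus: float = 30.0
    cluster_sigma_nm: float = 50.0
    blinks_per_tag_mean: float = 1.6
    background_density_per_um2: float = 2.0
    window_nm: tuple[float, float] = (5000.0, 5000.0)
    tag_intercept: float = 400.0  # expected tags at dose 0
    tag_slope_per_gy: float = 200.0  # expected extra tags per Gy

    def __post_init__(self) -> None:
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")
        lo, hi = self.loc_precision_nm
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("loc_precision_nm must be a positive (low, high) range")
        if self.background_density_per_um2 < 0:
            raise ValueError("background density must be >= 0")
        if self.blinks_per_tag_mean < 1:
            raise ValueError("blinks_per_tag_mean must be >= 1")
        w, h = self.window_nm
        if w <= 0 or h <= 0:
            raise ValueError("window must be positive")


@dataclass
class GroundTruth:
    """Generator truth against which pipeline recovery is scored.

    ``foci`` has one row per true focus: nucleus_id, center (z,y,x in µm),
    radius_um and channel membership (``gH2AX`` only, or ``both`` for a
    colocalized pair = one true DSB). ``per_nucleus`` carries total and
    colocalized truth counts; a colocalized focus appears once in the DSB
    count. For SMLM scenes, ``tags`` holds (x_nm, y_nm, n_blinks, cluster).
    """

    nucleus_masks: np.ndarray | None = None
    foci: pd.DataFrame | None = None
    per_nucleus: pd.DataFrame | None = None
    tags: pd.DataFrame | None = None
    n_clusters: int | None = None


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def expected_foci(dose_gy: float, t_pi_min: float, cfg: ScenarioConfig | None = None,
                  *, treated: bool = False):
    """Expected (Poisson-mean) focus count per nucleus at a dose and time PI.

    Continuous in ``t``; non-decreasing in dose at fixed ``t``. ``treated``
    applies the scenario's multiplicative treatment effect to the induced
    component.
    """
    cfg = cfg or ScenarioConfig()
    dose = np.asarray(dose_gy, dtype=float)
    t = np.asarray(t_pi_min, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    formation = 1.0 - np.exp(-t / cfg.tau_form_min)
    decay = cfg.fast_fraction * np.exp(-t / cfg.tau_fast_min) + (
        1.0 - cfg.fast_fraction
    ) * np.exp(-t / cfg.tau_slow_min)
    effect = cfg.treatment_effect if treated else 1.0
    out = cfg.baseline_rate + effect * cfg.alpha_induction * dose * formation * decay
    if out.ndim == 0:
        return float(out)
    return out


def expected_colocalized_foci(dose_gy, t_pi_min, cfg: ScenarioConfig | None = None,
                              *, treated: bool = False):
    """Expected count of foci carrying both markers (the DSB-callable mean)."""
    cfg = cfg or ScenarioConfig()
    return expected_foci(dose_gy, t_pi_min, cfg, treated=treated) * cfg.p_coloc(t_pi_min)


# ---------------------------------------------------------------------------
# Confocal stack simulation
# ---------------------------------------------------------------------------

def _nucleus_params(rng: np.random.Generator) -> dict:
    """Random ellipsoid nucleus: semi-axes, in-plane rotation, boundary ripple."""
    return {
        "semi_um": (
            rng.uniform(2.2, 3.0),  # axial (z)
            rng.uniform(2.8, 3.8),  # y
            rng.uniform(2.8, 3.8),  # x
        ),
        "theta": rng.uniform(0, 2 * np.pi),
        # low-frequency azimuthal perturbation of the boundary
        "ripple": [(m, rng.uniform(0.0, 0.05), rng.uniform(0, 2 * np.pi)) for m in (2, 3)],
    }


def _render_nucleus_mask(shape, voxel, center_um, params) -> tuple[np.ndarray, tuple]:
    """Boolean mask of one perturbed ellipsoid, computed on its subgrid only."""
    dz, dy, dx = voxel
    cz, cy, cx = center_um
    az, ay, ax_ = params["semi_um"]
    pad = 1.15  # room for the boundary ripple
    z0 = max(int((cz - az * pad) / dz), 0)
    z1 = min(int((cz + az * pad) / dz) + 2, shape[0])
    y0 = max(int((cy - ay * pad * 1.2) / dy), 0)
    y1 = min(int((cy + ay * pad * 1.2) / dy) + 2, shape[1])
    x0 = max(int((cx - ax_ * pad * 1.2) / dx), 0)
    x1 = min(int((cx + ax_ * pad * 1.2) / dx) + 2, shape[2])
    zz = (np.arange(z0, z1) * dz - cz)[:, None, None]
    yy = (np.arange(y0, y1) * dy - cy)[None, :, None]
    xx = (np.arange(x0, x1) * dx - cx)[None, None, :]
    ct, st = math.cos(params["theta"]), math.sin(params["theta"])
    xr = ct * xx + st * yy
    yr = -st * xx + ct * yy
    u2 = (xr / ax_) ** 2 + (yr / ay) ** 2 + (zz / az) ** 2
    phi = np.arctan2(yr, xr)
    scale = np.ones_like(u2)
    for m, eps, psi in params["ripple"]:
        scale += eps * np.cos(m * phi + psi)
    mask = u2 <= scale**2
    return mask, (slice(z0, z1), slice(y0, y1), slice(x0, x1))


def _sample_inside(rng, n, center_um, params, min_sep_um: float = 0.7):
    """Points inside the ellipsoid shrunk to 80% (strictly interior).

    Placement enforces a minimum pairwise separation (repair foci are
    micron-scale chromatin domains and do not interpenetrate); if a point
    cannot be placed after bounded retries the separation is waived for it.
    """
    az, ay, ax_ = params["semi_um"]
    ct, st = math.cos(params["theta"]), math.sin(params["theta"])

    def to_grid(p):
        z = p[0] * az
        yb = p[1] * ay
        xb = p[2] * ax_
        return np.array(
            [z + center_um[0], st * xb + ct * yb + center_um[1],
             ct * xb - st * yb + center_um[2]]
        )

    accepted: list[np.ndarray] = []
    for _ in range(n):
        placed = False
        for _try in range(100):
            cand = rng.uniform(-1, 1, 3)
            if np.sum(cand**2) > 0.8**2:
                continue
            g = to_grid(cand)
            if all(np.linalg.norm(g - q) >= min_sep_um for q in accepted):
                accepted.append(g)
                placed = True
                break
        if not placed:  # crowded nucleus: waive the separation for this focus
            while True:
                cand = rng.uniform(-1, 1, 3)
                if np.sum(cand**2) <= 0.8**2:
                    accepted.append(to_grid(cand))
                    break
    return np.array(accepted)


def _add_gaussian_spot(img, voxel, center_um, sigma_um, amplitude):
    """Add an anisotropic Gaussian spot to ``img`` on a local window."""
    dz, dy, dx = voxel
    sz, sxy = sigma_um
    cz, cy, cx = center_um
    ez = max(int(4 * sz / dz), 2)
    ey = max(int(4 * sxy / dy), 2)
    ex = max(int(4 * sxy / dx), 2)
    iz, iy, ix = int(round(cz / dz)), int(round(cy / dy)), int(round(cx / dx))
    z0, z1 = max(iz - ez, 0), min(iz + ez + 1, img.shape[0])
    y0, y1 = max(iy - ey, 0), min(iy + ey + 1, img.shape[1])
    x0, x1 = max(ix - ex, 0), min(ix + ex + 1, img.shape[2])
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz = (np.arange(z0, z1) * dz - cz)[:, None, None]
    yy = (np.arange(y0, y1) * dy - cy)[None, :, None]
    xx = (np.arange(x0, x1) * dx - cx)[None, None, :]
    img[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(
        -0.5 * ((zz / sz) ** 2 + (yy / sxy) ** 2 + (xx / sxy) ** 2)
    )


def simulate_stack(
    dose_gy: float,
    t_pi_min: float,
    n_nuclei: int,
    cfg: ScenarioConfig | None = None,
    img: ImagingConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    treated: bool = False,
    touching: bool = False,
) -> tuple[ConfocalStack, GroundTruth]:
    """Simulate one multi-channel confocal stack with ground truth.

    Nuclei are placed on a jittered grid (non-overlapping); with
    ``touching=True`` they are instead placed in pairs whose ellipsoids
    overlap slightly, which exercises the watershed splitting stage. Per
    nucleus the true focus count is Poisson with mean
    :func:`expected_foci`; every focus is rendered as a Gaussian spot in the
    γH2AX channel, and with probability ``p_coloc(t)`` also in the 53BP1
    channel (centroid jittered by ``coloc_jitter_um``). The chromatin
    channel is the smoothed nucleus body. Poisson photon noise is applied to
    every channel (optionally plus Gaussian read noise).
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    cfg = cfg or ScenarioConfig()
    img = img or ImagingConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)

    dz, dy, dx = img.z_step_um, img.z_step_um, img.xy_pixel_um
    voxel = (img.z_step_um, img.xy_pixel_um, img.xy_pixel_um)
    spacing = img.cell_spacing_um
    if touching:
        pair_w = 1.8 * spacing  # a touching pair spans nearly two nuclei
        ny = int(round(1.2 * spacing / img.xy_pixel_um))
        nx = int(round(n_nuclei * pair_w / img.xy_pixel_um))
    else:
        n_cols = math.ceil(math.sqrt(n_nuclei))
        n_rows = math.ceil(n_nuclei / n_cols)
        ny = int(round(n_rows * spacing / img.xy_pixel_um))
        nx = int(round(n_cols * spacing / img.xy_pixel_um))
    shape = (img.n_slices, ny, nx)
    depth_um = img.n_slices * img.z_step_um

    labels = np.zeros(shape, dtype=np.int32)
    signal = {
        "gH2AX": np.zeros(shape, dtype=np.float64),
        "p53bp1_tmp": np.zeros(shape, dtype=np.float64),
        "chromatin": np.zeros(shape, dtype=np.float64),
    }

    centers = []
    params_list = []
    if touching:
        # pairs of ellipsoids whose surfaces interpenetrate by ~20% of a radius
        n_pairs = n_nuclei
        for j in range(n_pairs):
            p1, p2 = _nucleus_params(rng), _nucleus_params(rng)
            cy = 0.6 * spacing
            cx0 = (j + 0.5) * pair_w
            gap = 0.8 * (p1["semi_um"][2] + p2["semi_um"][2])  # 20% overlap
            cz = depth_um / 2 + rng.uniform(-0.5, 0.5)
            centers.append((cz, cy, cx0 - gap / 2))
            params_list.append(p1)
            centers.append((cz, cy, cx0 + gap / 2))
            params_list.append(p2)
        n_total = 2 * n_pairs
    else:
        order = rng.permutation(n_rows * n_cols)[:n_nuclei]
        for cell in order:
            r, c = divmod(int(cell), n_cols)
            cz = depth_um / 2 + rng.uniform(-0.8, 0.8)
            cy = (r + 0.5) * spacing + rng.uniform(-0.8, 0.8)
            cx = (c + 0.5) * spacing + rng.uniform(-0.8, 0.8)
            centers.append((cz, cy, cx))
            params_list.append(_nucleus_params(rng))
        n_total = n_nuclei

    mean_count = expected_foci(dose_gy, t_pi_min, cfg, treated=treated)
    p_co = float(cfg.p_coloc(t_pi_min)) if t_pi_min > 0 else 0.0
    radius_t = float(cfg.focus_radius_um(t_pi_min))
    psf_lat, psf_ax = img.psf_sigma_um

    foci_rows = []
    per_nucleus = []
    for nid, (center, params) in enumerate(zip(centers, params_list), start=1):
        mask, box = _render_nucleus_mask(shape, voxel, center, params)
        region = labels[box]
        region[mask & (region == 0)] = nid
        signal["chromatin"][box][mask] = img.chromatin_level
        signal["gH2AX"][box][mask] += img.nuclear_level
        signal["p53bp1_tmp"][box][mask] += img.nuclear_level

        n_foci = int(rng.poisson(mean_count))
        if n_foci:
            pos = _sample_inside(rng, n_foci, center, params, cfg.focus_min_separation_um)
        else:
            pos = np.empty((0, 3))
        n_co = 0
        for k in range(n_foci):
            radius = max(radius_t * rng.lognormal(0.0, 0.15), 0.1)
            amp = img.focus_amplitude * rng.lognormal(0.0, 0.2)
            sig_lat = math.sqrt(psf_lat**2 + (radius / 1.5) ** 2)
            sig_ax = math.sqrt(psf_ax**2 + (radius / 1.5) ** 2)
            _add_gaussian_spot(signal["gH2AX"], voxel, pos[k], (sig_ax, sig_lat), amp)
            coloc = bool(rng.random() < p_co)
            if coloc:
                jit = rng.normal(0.0, cfg.coloc_jitter_um / math.sqrt(3), 3)
                norm = float(np.linalg.norm(jit))
                if norm > cfg.coloc_jitter_um:  # displacement capped in magnitude
                    jit *= cfg.coloc_jitter_um / norm
                _add_gaussian_spot(
                    signal["p53bp1_tmp"], voxel, pos[k] + jit, (sig_ax, sig_lat),
                    amp * rng.lognormal(0.0, 0.2),
                )
                n_co += 1
            foci_rows.append(
                {
                    "nucleus_id": nid,
                    "z_um": pos[k, 0],
                    "y_um": pos[k, 1],
                    "x_um": pos[k, 2],
                    "radius_um": radius,
                    "channel": "both" if coloc else "gH2AX",
                }
            )
        per_nucleus.append(
            {"nucleus_id": nid, "n_total": n_foci, "n_colocalized": n_co}
        )

    from scipy import ndimage as ndi

    # chromatin body softened to emulate optics
    signal["chromatin"] = ndi.gaussian_filter(
        signal["chromatin"], sigma=(psf_ax / dz, psf_lat / dy, psf_lat / dx)
    )

    channels = {}
    for role, key in (("gH2AX", "gH2AX"), ("p53BP1", "p53bp1_tmp"), ("chromatin", "chromatin")):
        intensity = (signal[key] + img.background_level) * img.photon_scale
        counts = rng.poisson(intensity).astype(np.float64)
        if img.noise_model == "poisson+gaussian":
            counts = counts + rng.normal(0.0, img.read_noise_sd, size=counts.shape)
        channels[role] = np.clip(np.round(counts), 0, 65535).astype(np.uint16)

    stack = ConfocalStack(
        channels,
        voxel,
        meta={
            "dose_gy": float(dose_gy),
            "t_pi_min": float(t_pi_min),
            "treatment": "NP" if treated else "none",
            "n_nuclei": n_total,
        },
    )
    truth = GroundTruth(
        nucleus_masks=labels,
        foci=pd.DataFrame(
            foci_rows,
            columns=["nucleus_id", "z_um", "y_um", "x_um", "radius_um", "channel"],
        ),
        per_nucleus=pd.DataFrame(per_nucleus, columns=["nucleus_id", "n_total", "n_colocalized"]),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# SMLM simulation
# ---------------------------------------------------------------------------

def expected_tags(dose_gy: float, cfg: ScenarioConfig, smlm: SmlmConfig) -> float:
    """Mean number of antibody tags in a nucleus window at a given dose."""
    if dose_gy < 0:
        raise ValueError("dose must be >= 0")
    mean = smlm.tag_intercept + smlm.tag_slope_per_gy * dose_gy
    if cfg.smlm_quadratic_coeff > 0 and dose_gy > cfg.smlm_quadratic_onset_gy:
        mean += cfg.smlm_quadratic_coeff * (dose_gy - cfg.smlm_quadratic_onset_gy) ** 2
    return mean


def simulate_smlm(
    dose_gy: float,
    cfg: ScenarioConfig | None = None,
    smlm: SmlmConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    treated: bool = False,
) -> tuple[LocalizationSet, GroundTruth]:
    """Simulate an SMLM localization table for one nucleus window.

    Tags are grouped into Gaussian clusters (foci); the total expected tag
    number is linear in dose (optionally supra-linear above 2 Gy via the
    scenario flag). Each tag emits a geometric number of blink
    localizations in a short frame burst, each displaced by its localization
    precision; background localizations are CSR over the window.
    """
    cfg = cfg or ScenarioConfig()
    smlm = smlm or SmlmConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    W, H = smlm.window_nm

    mean_tags = expected_tags(dose_gy, cfg, smlm)
    if treated:
        mean_tags = smlm.tag_intercept + cfg.treatment_effect * (
            mean_tags - smlm.tag_intercept
        )
    n_clusters = int(rng.poisson(mean_tags / smlm.tags_per_focus)) if mean_tags > 0 else 0

    margin = 3 * smlm.cluster_sigma_nm
    if margin * 2 >= min(W, H):
        raise ValueError("window too small for the configured cluster size")

    xs, ys, frames, precs = [], [], [], []
    tag_rows = []
    p_geom = 1.0 / smlm.blinks_per_tag_mean
    for c in range(n_clusters):
        center = rng.uniform([margin, margin], [W - margin, H - margin])
        n_tags = max(int(rng.poisson(smlm.tags_per_focus)), 1)
        tags = center + rng.normal(0.0, smlm.cluster_sigma_nm, (n_tags, 2))
        for tx, ty in tags:
            n_blinks = int(rng.geometric(p_geom))
            start = int(rng.integers(0, smlm.frame_count))
            gaps = 1 + rng.poisson(0.5, size=n_blinks - 1) if n_blinks > 1 else []
            f = np.concatenate([[start], start + np.cumsum(gaps)]) if n_blinks > 1 else np.array([start])
            f = np.minimum(f, smlm.frame_count - 1)
            prec = rng.uniform(*smlm.loc_precision_nm, size=n_blinks)
            bx = tx + rng.normal(0.0, 1.0, n_blinks) * prec
            by = ty + rng.normal(0.0, 1.0, n_blinks) * prec
            xs.append(bx)
            ys.append(by)
            frames.append(f)
            precs.append(prec)
            tag_rows.append({"x_nm": tx, "y_nm": ty, "n_blinks": n_blinks, "cluster": c})

    area_um2 = (W / 1000.0) * (H / 1000.0)
    n_bg = int(rng.poisson(smlm.background_density_per_um2 * area_um2))
    if n_bg:
        xs.append(rng.uniform(0, W, n_bg))
        ys.append(rng.uniform(0, H, n_bg))
        frames.append(rng.integers(0, smlm.frame_count, n_bg))
        precs.append(rng.uniform(*smlm.loc_precision_nm, n_bg))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        frame = np.concatenate(frames).astype(int)
        prec = np.concatenate(precs)
        inside = (x >= 0) & (x < W) & (y >= 0) & (y < H)
        x, y, frame, prec = x[inside], y[inside], frame[inside], prec[inside]
    else:
        x = y = prec = np.empty(0)
        frame = np.empty(0, dtype=int)

    locs = LocalizationSet(x, y, frame, prec, (W, H))
    truth = GroundTruth(
        tags=pd.DataFrame(tag_rows, columns=["x_nm", "y_nm", "n_blinks", "cluster"]),
        n_clusters=n_clusters,
    )
    return locs, truth


# ---------------------------------------------------------------------------
# Whole-experiment simulation (truth-level count records)
# ---------------------------------------------------------------------------

def simulate_experiment(
    time_points_min,
    doses_gy,
    treatments,
    n_nuclei: int,
    cfg: ScenarioConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    xy_pixel_um: float = 0.1,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a focus-counting experiment as truth-level count records.

    One row per nucleus and condition: the DSB count is the number of
    colocalized foci (Binomial thinning of a Poisson total by ``p_coloc``),
    and per-focus footprint areas follow the scenario's size-growth curve.
    With ``treatment_effect = 1.0`` the treated and untreated distributions
    are exchangeable (the null scenario).
    """
    time_points_min = list(time_points_min)
    doses_gy = list(doses_gy)
    treatments = list(treatments)
    if not time_points_min or not doses_gy or not treatments:
        raise ValueError("time, dose and treatment grids must be non-empty")
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    cfg = cfg or ScenarioConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)

    rows = []
    truth_rows = []
    nid = 0
    for t in time_points_min:
        p_co = float(cfg.p_coloc(t)) if t > 0 else 0.0
        mean_r = float(cfg.focus_radius_um(t))
        mean_area = np.pi * (mean_r / xy_pixel_um) ** 2
        for dose in doses_gy:
            for trt in treatments:
                treated = trt not in ("none", "untreated", "control")
                mean = expected_foci(dose, t, cfg, treated=treated)
                totals = rng.poisson(mean, size=n_nuclei)
                colocs = rng.binomial(totals, p_co)
                for i in range(n_nuclei):
                    nid += 1
                    k = int(colocs[i])
                    areas = np.round(
                        mean_area * rng.lognormal(0.0, 0.25, size=k)
                    ).astype(int)
                    areas = np.maximum(areas, 1)
                    rows.append(
                        make_count_record(
                            nid,
                            k,
                            areas.tolist(),
                            cell_line=cfg.cell_line,
                            dose_gy=dose,
                            t_pi_min=t,
                            treatment=trt,
                        )
                    )
                    truth_rows.append(
                        {
                            "nucleus_id": nid,
                            "t_pi_min": t,
                            "dose_gy": dose,
                            "treatment": trt,
                            "n_total": int(totals[i]),
                            "n_colocalized": k,
                        }
                    )
    records = pd.DataFrame(rows)
    truth = GroundTruth(per_nucleus=pd.DataFrame(truth_rows))
    return records, truth
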