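"""Synthetic study generator: AFM force curves/maps, TCSPC decays and lipid
tables with known ground truth.

Every input consumed by the analysis pipeline can be generated here from a
declared ground truth, so parameter recovery, topography round trips and the
planted cross-modality correlation structure are all testable end to end:

* ``simulate_plr_force_curve`` — forward Ting/PLR evaluation of a
  force-triggered triangular indentation ramp (fast force-volume operation)
  with additive Gaussian force noise;
* ``simulate_ffv_map`` — a spherical-cap cell phantom on a rigid, tilted
  substrate, each pixel carrying a finite-thickness (BEC-stiffened) curve;
* ``simulate_decay`` — Poisson photon statistics of a monoexponential decay,
  optionally convolved with a Gaussian IRF plus a uniform background;
* ``simulate_study`` / ``simulate_lipid_table`` — a multi-cell-line study
  with per-line microviscosity and stiffness levels and a planted line-level
  stiffness-viscosity correlation, mirroring a five-line colorectal carcinoma
  panel (fluid HT29 membranes through viscous SW480 membranes).

All generators are deterministic given (seed, configuration); the seed is
surfaced in the output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .afm_mechanics import (
    ForceCurve,
    ForceVolumeMap,
    IndentationHistory,
    PLRParams,
    ProbeGeometry,
    hertz_force,
    ting_force,
)
from .flim_viscosity import (
    DecayHistogram,
    REFERENCE_CALIBRATION_PAIRS,
    fit_fh_calibration,
    viscosity_to_lifetime,
)

#: Default base seed for all generators.
DEFAULT_SEED = 20231106

#: Planted per-component Pearson correlations of lipid yield vs line-level
#: membrane microviscosity (negative: the component fluidifies or tracks the
#: bulk-bilayer signal).
PLANTED_LIPID_CORRELATIONS = {
    "PC": -0.72,
    "SM": -0.72,
    "cholesterol": -0.62,
    "monounsaturated_FA": -0.59,
    "polyunsaturated_FA": -0.42,
}

#: Baseline ion yields (fraction of total ion count) per component and the
#: relative amplitude of the planted between-line variation.  Polyunsaturated
#: FA variation is kept below replicate noise: the lines do not differ
#: detectably on that component.
LIPID_BASE_YIELDS = {
    "PC": (0.050, 0.30),
    "SM": (0.020, 0.30),
    "cholesterol": (0.010, 0.30),
    "monounsaturated_FA": (0.015, 0.30),
    "polyunsaturated_FA": (0.008, 0.04),
    "saturated_FA": (0.030, 0.0),
}


@dataclass(frozen=True)
class RampProtocol:
    """Force-triggered triangular ramp of the fast force-volume mode."""

    ramp_distance_um: float = 3.0
    piezo_speed_um_s: float = 183.0
    trigger_force_nN: float = 0.8
    samples_per_phase: int = 512

    def __post_init__(self):
        if min(
            self.ramp_distance_um,
            self.piezo_speed_um_s,
            self.trigger_force_nN,
            self.samples_per_phase,
        ) <= 0:
            raise ValueError("all ramp parameters must be positive")

    @property
    def dt_s(self) -> float:
        return (self.ramp_distance_um / self.piezo_speed_um_s) / self.samples_per_phase


@dataclass(frozen=True)
class PLRGroundTruth:
    """Viscoelastic ground truth of a simulated pixel/curve: PLR scale E0
    (Pa, relaxation modulus at t = 1 s), power-law exponent alpha, Newtonian
    dashpot eta (Pa*s), local sample thickness (nm, inf for bulk)."""

    E0_Pa: float
    alpha: float = 0.0
    eta_Pa_s: float = 0.0
    thickness_nm: float = np.inf

    def __post_init__(self):
        if self.E0_Pa <= 0 or not 0.0 <= self.alpha < 1.0:
            raise ValueError("require E0 > 0 and 0 <= alpha < 1")
        if self.eta_Pa_s < 0 or self.thickness_nm <= 0:
            raise ValueError("require eta >= 0 and thickness > 0")


@dataclass(frozen=True)
class CellPhantom:
    """Spherical-cap cell on a flat rigid substrate."""

    center_um: tuple[float, float] = (20.0, 20.0)
    base_radius_um: float = 12.0
    cap_height_um: float = 6.0

    def height_um(self, x_um, y_um):
        """Cap height profile at scan coordinates (vectorized)."""
        h, a = self.cap_height_um, self.base_radius_um
        Rs = (a**2 + h**2) / (2.0 * h)  # sphere radius
        r2 = (np.asarray(x_um) - self.center_um[0]) ** 2 + (
            np.asarray(y_um) - self.center_um[1]
        ) ** 2
        inside = r2 < a**2
        z = np.where(inside, np.sqrt(np.clip(Rs**2 - r2, 0.0, None)) - (Rs - h), 0.0)
        return np.clip(z, 0.0, None)

    def half_height_radius_um(self) -> float:
        """Radius of the analytic disc where the cap is above half its peak."""
        h, a = self.cap_height_um, self.base_radius_um
        Rs = (a**2 + h**2) / (2.0 * h)
        return float(np.sqrt(Rs**2 - (Rs - h / 2.0) ** 2))


@dataclass(frozen=True)
class StudyDesign:
    """Multi-cell-line study layout with planted effect structure.

    Line-level microviscosity means/SDs follow the measured colorectal panel
    (fluid HT29 at 427 +/- 30 cP up to SW480 at 491 +/- 45 cP, n = 60 cells
    in 10 fields of view per line); stiffness line means are constructed to
    carry an exact sample Pearson correlation ``stiffness_viscosity_r`` with
    the viscosity means inside the 1-4 kPa band typical of these cells.
    """

    cell_lines: tuple[str, ...] = ("HT29", "Caco-2", "HCT116", "SW837", "SW480")
    viscosity_mean_cP: tuple[float, ...] = (427.0, 448.0, 456.0, 457.0, 491.0)
    viscosity_sd_cP: tuple[float, ...] = (30.0, 51.0, 33.0, 27.0, 45.0)
    stiffness_viscosity_r: float = 0.93
    stiffness_mean_kPa: float = 2.4
    stiffness_span_kPa: float = 1.55
    stiffness_map_cv: float = 0.20
    height_mean_um: tuple[float, ...] = (9.0, 4.5, 6.0, 8.0, 4.0)
    cells_per_line: int = 60
    fields_of_view: int = 10
    maps_per_line: int = 20
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        n = len(self.cell_lines)
        for name in ("viscosity_mean_cP", "viscosity_sd_cP", "height_mean_um"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per cell line")
        if not -1.0 <= self.stiffness_viscosity_r <= 1.0:
            raise ValueError("planted correlation must lie in [-1, 1]")
        if min(self.cells_per_line, self.fields_of_view, self.maps_per_line) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class StudyDataset:
    """Synthetic study: per-cell lifetimes, per-map mechanics, lipid table,
    and (at full detail) the raw decays and force-volume maps."""

    design: StudyDesign
    line_truth: pd.DataFrame
    cells: pd.DataFrame
    maps: pd.DataFrame
    lipids: pd.DataFrame
    decays: dict = field(default_factory=dict)
    raw_maps: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Force curves
# ---------------------------------------------------------------------------


def simulate_plr_force_curve(
    truth: PLRGroundTruth,
    probe: ProbeGeometry = ProbeGeometry(),
    ramp: RampProtocol = RampProtocol(),
    noise_sd_nN: float = 0.0,
    seed: int | None = DEFAULT_SEED,
    contact_fraction: float = 0.35,
    contact_jitter_nm: float = 0.0,
    z0_um: float = 1.5,
    bec: bool = True,
    rng: np.random.Generator | None = None,
) -> ForceCurve:
    """Forward-simulate one force-triggered indentation cycle.

    The indentation history is a symmetric triangular ramp at the piezo speed:
    the approach terminates at the first sample where the (noiseless) model
    force reaches the trigger, and the retract mirrors the approach.  The
    recorded piezo position is ``z = z0 + delta + F/k`` during contact (so
    that the analysis-side ``delta = (z - z0) - F/k`` recovers the driven
    history exactly), with a linear pre-contact/post-contact baseline of
    ``contact_fraction`` of the ramp on either side.

    Gaussian force noise of ``noise_sd_nN`` and optional Gaussian
    contact-point jitter are added.  A curve whose hereditary-integral
    evaluation fails is flagged in ``meta['flags']``, never silently NaN.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = ramp.samples_per_phase
    dt = ramp.dt_s
    step_nm = ramp.piezo_speed_um_s * dt * 1e3
    n_pre = max(5, int(round(contact_fraction * n)))
    n_contact_max = n - n_pre
    if n_contact_max < 10:
        raise ValueError("contact_fraction leaves too few contact samples")
    if contact_jitter_nm > 0:
        z0_um = z0_um + rng.normal(0.0, contact_jitter_nm) * 1e-3

    flags: list[str] = []
    # --- approach on the contact clock, truncated at the trigger force
    delta_app = step_nm * np.arange(n_contact_max + 1)  # nm
    t_app = dt * np.arange(n_contact_max + 1)
    params = PLRParams(E0_Pa=truth.E0_Pa, alpha=truth.alpha, eta_Pa_s=truth.eta_Pa_s)
    elastic = truth.alpha == 0.0 and truth.eta_Pa_s == 0.0

    def forward(t, delta, i_peak):
        if elastic:
            return hertz_force(delta, truth.E0_Pa, probe, truth.thickness_nm, bec=bec)
        hist = IndentationHistory(
            t_s=t, delta_nm=delta, force_nN=np.zeros_like(t), i_peak=i_peak,
            z0_um=z0_um, baseline_nN=0.0, contact_index=0,
        )
        return ting_force(hist, params, probe, thickness_nm=truth.thickness_nm, bec=bec)

    F_app = forward(t_app, delta_app, n_contact_max)
    over = np.nonzero(F_app >= ramp.trigger_force_nN)[0]
    if over.size:
        i_trig = max(int(over[0]), 5)
    else:
        i_trig = n_contact_max
        flags.append("trigger_not_reached")

    # --- full contact history: approach 0..i_trig, mirrored retract, tail
    delta_full = np.concatenate(
        [delta_app[: i_trig + 1], delta_app[:i_trig][::-1], np.zeros(n_pre)]
    )
    m = delta_full.size
    t_full = dt * np.arange(m)
    F_full = forward(t_full, delta_full, i_trig)
    if not np.all(np.isfinite(F_full)):
        flags.append("t1_nonconvergent")
        F_full = np.nan_to_num(F_full, nan=0.0)

    # --- assemble the recorded (t, z, F) curve with the pre-contact baseline
    F = np.concatenate([np.zeros(n_pre), F_full])
    deflection_um = F * 1e-3 / probe.spring_constant_N_m  # nm -> um via nN/(N/m)=nm
    z = np.empty_like(F)
    z[:n_pre] = z0_um - step_nm * 1e-3 * np.arange(n_pre, 0, -1)
    z[n_pre:] = z0_um + delta_full * 1e-3 + deflection_um[n_pre:]
    t = dt * np.arange(z.size)
    if noise_sd_nN > 0:
        F = F + rng.normal(0.0, noise_sd_nN, size=F.size)
    curve = ForceCurve(
        t_s=t,
        z_um=z,
        force_nN=F,
        probe=probe,
        n_approach=n_pre + i_trig + 1,
        meta={
            "seed": seed,
            "z0_um": z0_um,
            "truth": {
                "E0_Pa": truth.E0_Pa,
                "alpha": truth.alpha,
                "eta_Pa_s": truth.eta_Pa_s,
                "thickness_nm": truth.thickness_nm,
            },
            "ramp": {
                "ramp_distance_um": ramp.ramp_distance_um,
                "piezo_speed_um_s": ramp.piezo_speed_um_s,
                "trigger_force_nN": ramp.trigger_force_nN,
                "samples_per_phase": ramp.samples_per_phase,
            },
            "noise_sd_nN": noise_sd_nN,
            "flags": flags,
        },
    )
    curve.validate()
    return curve


# ---------------------------------------------------------------------------
# Force-volume maps
# ---------------------------------------------------------------------------


SUBSTRATE_TRUTH = PLRGroundTruth(E0_Pa=5.0e4, alpha=0.0, eta_Pa_s=0.0)


def simulate_ffv_map(
    phantom: CellPhantom,
    cell_truth: PLRGroundTruth,
    probe: ProbeGeometry = ProbeGeometry(),
    ramp: RampProtocol = RampProtocol(samples_per_phase=128),
    map_size_um: float = 40.0,
    n_pixels: int | tuple[int, int] = 32,
    tilt_nm_per_um: tuple[float, float] = (0.0, 0.0),
    substrate_truth: PLRGroundTruth = SUBSTRATE_TRUTH,
    noise_sd_nN: float = 0.0,
    seed: int = DEFAULT_SEED,
    z_offset_um: float = 10.0,
) -> ForceVolumeMap:
    """Simulate a fast force-volume map of a spherical-cap cell phantom.

    Each pixel's contact point follows the phantom height plus a planted
    tilt plane (``z0 = z_offset + a*x + b*y - height``, so taller features
    contact earlier); cell pixels use the cell ground truth with the local
    cap height as the BEC thickness, substrate pixels an effectively rigid
    elastic response.  The ramp is re-centred per pixel, as a force-triggered
    FFV controller does.
    """
    if isinstance(n_pixels, int):
        n_pixels = (n_pixels, n_pixels)
    ny, nx = n_pixels
    if ny < 2 or nx < 2:
        raise ValueError("map must be at least 2x2 pixels")
    pixel_um = map_size_um / max(ny, nx)
    rng = np.random.default_rng(seed)
    a_tilt, b_tilt = tilt_nm_per_um
    curves: list[list[ForceCurve]] = []
    heights = np.zeros((ny, nx))
    for i in range(ny):
        row = []
        for j in range(nx):
            x, y = j * pixel_um, i * pixel_um
            h_um = float(phantom.height_um(x, y))
            heights[i, j] = h_um * 1e3
            on_cell = h_um > 0
            truth = (
                PLRGroundTruth(
                    E0_Pa=cell_truth.E0_Pa,
                    alpha=cell_truth.alpha,
                    eta_Pa_s=cell_truth.eta_Pa_s,
                    thickness_nm=max(h_um * 1e3, 50.0),
                )
                if on_cell
                else substrate_truth
            )
            z0 = z_offset_um + (a_tilt * x + b_tilt * y) * 1e-3 - h_um
            row.append(
                simulate_plr_force_curve(
                    truth,
                    probe,
                    ramp,
                    noise_sd_nN=noise_sd_nN,
                    z0_um=z0,
                    rng=rng,
                    seed=None,
                )
            )
        curves.append(row)
    return ForceVolumeMap(
        curves=curves,
        pixel_size_um=pixel_um,
        probe=probe,
        meta={
            "seed": seed,
            "phantom_height_nm": heights,
            "tilt_nm_per_um": tilt_nm_per_um,
            "map_size_um": map_size_um,
            "cell_truth": cell_truth,
        },
    )


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------


def simulate_decay(
    tau_ns: float,
    n_photons: int = 5000,
    n_bins: int = 256,
    bin_width_ns: float = 12.5 / 256,
    irf_sigma_ns: float = 0.0,
    background_fraction: float = 0.0,
    seed: int | None = DEFAULT_SEED,
    mode: str = "poisson",
    irf_t0_ns: float | None = None,
    rng: np.random.Generator | None = None,
) -> DecayHistogram:
    """Photon decay histogram of a monoexponential emitter.

    Expected bin contents are exact integrals of ``exp(-t/tau)`` (convolved
    with a Gaussian IRF of ``irf_sigma_ns`` when given) over each bin,
    renormalized over the measurement window, plus a uniform background
    fraction.  ``mode="poisson"`` draws integer counts (total photons
    Poisson-distributed around ``n_photons``); ``mode="expectation"`` returns
    the noiseless expected (float) contents, useful for exactness tests.
    """
    if tau_ns <= 0 or n_photons < 1:
        raise ValueError("require tau > 0 and n_photons >= 1")
    if not 0.0 <= background_fraction < 1.0:
        raise ValueError("background fraction must lie in [0, 1)")
    window = n_bins * bin_width_ns
    if tau_ns > 5.0 * window:
        warnings.warn(
            "lifetime exceeds 5x the measurement window; tail unidentifiable",
            RuntimeWarning,
        )
    t = bin_width_ns * np.arange(n_bins)
    edges = bin_width_ns * np.arange(n_bins + 1)
    if irf_sigma_ns > 0:
        from scipy.stats import exponnorm

        t0 = irf_t0_ns if irf_t0_ns is not None else 5.0 * irf_sigma_ns
        cdf = exponnorm.cdf(edges, tau_ns / irf_sigma_ns, loc=t0, scale=irf_sigma_ns)
        p = np.diff(cdf)
    else:
        t0 = 0.0
        p = np.exp(-edges[:-1] / tau_ns) - np.exp(-edges[1:] / tau_ns)
    p = p / p.sum()
    p = (1.0 - background_fraction) * p + background_fraction / n_bins
    mu = n_photons * p
    if mode == "expectation":
        counts = mu
    elif mode == "poisson":
        if rng is None:
            rng = np.random.default_rng(seed)
        counts = rng.poisson(mu).astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DecayHistogram(
        t_ns=t,
        counts=counts,
        bin_width_ns=bin_width_ns,
        meta={
            "seed": seed,
            "tau_ns": tau_ns,
            "irf_sigma_ns": irf_sigma_ns,
            "irf_t0_ns": t0,
            "background_fraction": background_fraction,
            "mode": mode,
        },
    )


# ---------------------------------------------------------------------------
# Study-level generation
# ---------------------------------------------------------------------------


def _orthogonal_unit(base: np.ndarray, pattern_seed: int = 0) -> np.ndarray:
    """Deterministic centered unit vector orthogonal to ``base`` (and to the
    constant vector), used to plant exact sample correlations."""
    n = base.size
    bh = base - base.mean()
    bh = bh / np.linalg.norm(bh)
    rng = np.random.default_rng(1234 + pattern_seed)
    for _ in range(10):
        w = rng.standard_normal(n)
        w -= w.mean()
        w -= bh * (w @ bh)
        norm = np.linalg.norm(w)
        if norm > 1e-9:
            return w / norm
    raise RuntimeError("could not build an orthogonal direction")


def plant_correlated_values(
    base: np.ndarray, r: float, pattern_seed: int = 0
) -> np.ndarray:
    """Centered unit-norm vector whose sample Pearson correlation with
    ``base`` is exactly ``r`` (affine rescaling preserves it).

    With fewer than 3 entries no direction orthogonal to both the base and
    the constant vector exists; the correlation then degenerates to sign(r)
    and the collinear construction is used."""
    bh = base - base.mean()
    bh = bh / np.linalg.norm(bh)
    if base.size < 3:
        return np.sign(r) * bh if r != 0 else bh * 0.0
    w = _orthogonal_unit(base, pattern_seed)
    return r * bh + np.sqrt(max(0.0, 1.0 - r * r)) * w


def line_design(design: StudyDesign) -> pd.DataFrame:
    """Per-line ground-truth table derived from the study design.

    Stiffness (apparent Young's modulus) line means carry the planted
    correlation with the viscosity means; the PLR parameters follow the
    trends typical of adherent cells: E0 scales with stiffness, eta rises
    with stiffness (0.9-1.4 Pa*s), while the power-law exponent alpha runs
    opposite to stiffness (0.15-0.25, softer cells relax more).
    """
    v = np.asarray(design.viscosity_mean_cP, float)
    u = plant_correlated_values(v, design.stiffness_viscosity_r)
    E_hertz = (design.stiffness_mean_kPa + design.stiffness_span_kPa * u) * 1e3  # Pa
    if np.any(E_hertz <= 0):
        raise ValueError("stiffness design produced non-positive moduli")
    # alpha runs opposite to stiffness across 0.15-0.25, eta with stiffness
    # across 0.9-1.4 (midrange-centred affine maps keep the exact bands)
    tc = E_hertz - 0.5 * (E_hertz.max() + E_hertz.min())
    span = np.ptp(E_hertz) if np.ptp(E_hertz) > 0 else 1.0
    alpha = 0.20 - 0.10 * tc / span
    eta = 1.15 + 0.50 * tc / span
    calib = fit_fh_calibration(REFERENCE_CALIBRATION_PAIRS)
    tau = np.array([viscosity_to_lifetime(x, calib) for x in v])
    return pd.DataFrame(
        {
            "line": design.cell_lines,
            "viscosity_cP": v,
            "viscosity_sd_cP": design.viscosity_sd_cP,
            "tau_ns": tau,
            "E_hertz_Pa": E_hertz,
            "E0_Pa": 0.5 * E_hertz,
            "alpha": alpha,
            "eta_Pas": eta,
            "height_um": design.height_mean_um,
        }
    )


def simulate_lipid_table(
    design: StudyDesign,
    component_means: dict[str, np.ndarray] | None = None,
    noise_sd: float = 0.05,
    replicates_per_line: int = 5,
    seed: int | None = None,
    total_ion_count: float = 1.0e6,
) -> pd.DataFrame:
    """Per-line ToF-SIMS peak-intensity table with planted lipid-viscosity
    correlations.

    Component line means are affine images of unit vectors correlated with
    the viscosity design at the planted coefficients (PC/SM -0.72,
    cholesterol -0.62, monounsaturated -0.59, polyunsaturated -0.42 —
    recoverable by ``lipid_profile.correlate_lipids_viscosity``); explicit
    ``component_means`` (fractional yields per line) override the planting.
    ``noise_sd`` is the relative replicate noise on each yield.
    """
    rng = np.random.default_rng(design.seed + 7 if seed is None else seed)
    v = np.asarray(design.viscosity_mean_cP, float)
    n = v.size
    means: dict[str, np.ndarray] = {}
    if component_means is not None:
        for comp, arr in component_means.items():
            arr = np.asarray(arr, float)
            if np.any(arr < 0):
                raise ValueError(f"negative mean yield for component {comp!r}")
            means[comp] = arr
    else:
        for idx, (comp, (base, amp)) in enumerate(LIPID_BASE_YIELDS.items()):
            r = PLANTED_LIPID_CORRELATIONS.get(comp)
            if r is None or amp == 0.0:
                means[comp] = np.full(n, base)
            else:
                u = plant_correlated_values(v, r, pattern_seed=idx)
                means[comp] = base * (1.0 + amp * u / np.abs(u).max())
            if np.any(means[comp] < 0):
                raise ValueError(f"planted means negative for {comp!r}")
    rows = []
    for li, line in enumerate(design.cell_lines):
        for rep in range(replicates_per_line):
            tic = total_ion_count * (1.0 + rng.normal(0.0, 0.01))
            for comp, mm in means.items():
                y = mm[li] * max(0.0, 1.0 + (rng.normal(0.0, noise_sd) if noise_sd else 0.0))
                rows.append(
                    {
                        "line": line,
                        "replicate": rep,
                        "component": comp,
                        "raw_intensity": y * tic,
                        "total_ion_count": tic,
                    }
                )
    return pd.DataFrame(rows)


def simulate_study(
    design: StudyDesign = StudyDesign(),
    detail: str = "summary",
    probe: ProbeGeometry = ProbeGeometry(),
    n_decay_photons: int = 5000,
    full_map_pixels: int = 16,
    full_maps_per_line: int = 2,
) -> StudyDataset:
    """Generate a complete synthetic study.

    ``detail="summary"`` draws per-cell lifetimes and per-map mechanical
    parameters directly from the per-line design distributions (fast; used
    for many-seed statistical checks).  ``detail="full"`` additionally
    generates the raw TCSPC decay histograms for every cell and a small
    force-volume map set per line, so the complete pipeline can be run from
    raw inputs.
    """
    if detail not in {"summary", "full"}:
        raise ValueError(f"unknown detail level {detail!r}")
    if len(design.cell_lines) < 3:
        warnings.warn(
            "fewer than 3 cell lines: the correlation stage is disabled",
            RuntimeWarning,
        )
    rng = np.random.default_rng(design.seed)
    truth = line_design(design)
    calib = fit_fh_calibration(REFERENCE_CALIBRATION_PAIRS)

    # --- per-cell membrane microviscosity / lifetimes
    cell_rows = []
    for _, row in truth.iterrows():
        visc = rng.normal(
            row["viscosity_cP"],
            design.viscosity_sd_cP[list(design.cell_lines).index(row["line"])],
            size=design.cells_per_line,
        )
        visc = np.clip(visc, 50.0, None)
        tau = np.array([viscosity_to_lifetime(x, calib) for x in visc])
        fov = np.repeat(
            np.arange(design.fields_of_view),
            int(np.ceil(design.cells_per_line / design.fields_of_view)),
        )[: design.cells_per_line]
        for c in range(design.cells_per_line):
            cell_rows.append(
                {
                    "line": row["line"],
                    "cell_id": f"{row['line']}_c{c:03d}",
                    "fov": int(fov[c]),
                    "tau_ns": float(tau[c]),
                    "viscosity_true_cP": float(visc[c]),
                }
            )
    cells = pd.DataFrame(cell_rows)

    # --- per-map mechanics
    map_rows = []
    for _, row in truth.iterrows():
        for mmap in range(design.maps_per_line):
            E = rng.normal(row["E_hertz_Pa"], design.stiffness_map_cv * row["E_hertz_Pa"])
            E = max(E, 100.0)
            map_rows.append(
                {
                    "line": row["line"],
                    "map_id": f"{row['line']}_m{mmap:02d}",
                    "E_hertz_Pa": E,
                    "E0_Pa": 0.5 * E,
                    "alpha": float(np.clip(rng.normal(row["alpha"], 0.01), 0.0, 0.99)),
                    "eta_Pas": float(max(rng.normal(row["eta_Pas"], 0.1), 0.05)),
                    "height_nm": float(
                        max(rng.normal(row["height_um"] * 1e3, 0.1 * row["height_um"] * 1e3), 200.0)
                    ),
                }
            )
    maps = pd.DataFrame(map_rows)

    lipids = simulate_lipid_table(design)

    ds = StudyDataset(
        design=design,
        line_truth=truth,
        cells=cells,
        maps=maps,
        lipids=lipids,
        meta={"seed": design.seed, "detail": detail},
    )

    if detail == "full":
        for _, row in truth.iterrows():
            line = row["line"]
            taus = cells.loc[cells["line"] == line, "tau_ns"].to_numpy()
            ds.decays[line] = [
                simulate_decay(
                    tau_ns=float(t), n_photons=n_decay_photons, rng=rng, seed=None
                )
                for t in taus
            ]
            phantom = CellPhantom(
                center_um=(12.0, 12.0),
                base_radius_um=8.0,
                cap_height_um=float(row["height_um"]),
            )
            cell_truth = PLRGroundTruth(
                E0_Pa=float(row["E0_Pa"]),
                alpha=float(row["alpha"]),
                eta_Pa_s=float(row["eta_Pas"]),
            )
            ds.raw_maps[line] = [
                simulate_ffv_map(
                    phantom,
                    cell_truth,
                    probe=probe,
                    ramp=RampProtocol(samples_per_phase=128),
                    map_size_um=24.0,
                    n_pixels=full_map_pixels,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                for _ in range(full_maps_per_line)
            ]
    return ds
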