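"""Nanomechanical analysis of AFM force curves and fast force-volume (FFV) maps.

Implements the elastic and viscoelastic contact analysis used for whole-cell
indentation with spherical probes:

* apparent Young's modulus from the Hertz model,
  ``F = 4*sqrt(R)/(3*(1-nu^2)) * f_BEC(delta) * E_Hertz * delta^(3/2)``,
  with a multiplicative bottom-effect correction (BEC) for samples of finite
  thickness bonded to a rigid support;
* Ting's hereditary-integral model for arbitrary load/unload histories on a
  power-law-rheology (PLR) half-space with relaxation modulus
  ``E(t) = E0 * t^(-alpha) + eta * delta_D(t)`` (springpot in parallel with a
  Newtonian dashpot), including the auxiliary time ``t1(t)`` that governs the
  retract phase;
* map-level processing: per-pixel contact-point detection, topography with
  global tilt correction, background masking, central-region (top-50% height)
  selection and per-map aggregation.

Units follow AFM practice: forces in nN, piezo position in um, indentation
and heights in nm, moduli in Pa, time in s, the PLR dashpot eta in Pa*s.
All hereditary integrals are evaluated analytically per linear-in-time
segment of the indentation history, which avoids evaluating the singular
kernel ``t^(-alpha)`` at zero lag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Configuration constants
# ---------------------------------------------------------------------------

#: Bottom-effect-correction polynomial coefficients in chi = sqrt(R*delta)/h
#: for a spherical/paraboloidal tip on a sample bonded to a rigid support.
#: f_BEC = 1 + c1*chi + c2*chi^2 + c3*chi^3 + c4*chi^4.  The table is exposed
#: so an alternative coefficient set can be substituted.
BEC_COEFFICIENTS: Mapping[str, tuple[float, float, float, float]] = {
    "bonded": (1.133, 1.497, 1.469, 0.755),
}

#: chi beyond which the BEC series is extrapolating; values are clamped here.
BEC_CHI_MAX = 2.0

#: Default minimum local height (nm) separating cells from the substrate.
BACKGROUND_HEIGHT_NM = 200.0

#: Default minimum number of valid pixels for per-map aggregation.
MIN_AGGREGATE_PIXELS = 20

#: Fit bounds for the viscoelastic parameters (E0 Pa, alpha, eta Pa*s).
PLR_BOUNDS = ((1.0, 0.0, 0.0), (1.0e6, 0.99, 100.0))


class CurveRejected(ValueError):
    """A force curve could not be analysed; carries a short reason code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}" + (f": {detail}" if detail else ""))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeGeometry:
    """Spherical AFM probe: tip radius (nm), cantilever spring constant (N/m),
    sample Poisson ratio (time-independent, 0.5 for cells)."""

    tip_radius_nm: float = 70.0
    spring_constant_N_m: float = 0.1
    poisson_ratio: float = 0.5

    def __post_init__(self):
        if self.tip_radius_nm <= 0 or self.spring_constant_N_m <= 0:
            raise ValueError("tip radius and spring constant must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")


@dataclass
class ForceCurve:
    """One indentation cycle: time (s), piezo extension (um, grows toward the
    sample), force (nN), with the approach/retract split at ``n_approach``."""

    t_s: np.ndarray
    z_um: np.ndarray
    force_nN: np.ndarray
    probe: ProbeGeometry
    n_approach: int
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        t, z, f = map(np.asarray, (self.t_s, self.z_um, self.force_nN))
        if not (t.shape == z.shape == f.shape) or t.ndim != 1:
            raise ValueError("t, z, F must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("forces must be finite")
        if not 1 < self.n_approach < t.size:
            raise ValueError("curve must contain one approach->retract transition")

    @property
    def approach(self) -> slice:
        return slice(0, self.n_approach)

    @property
    def retract(self) -> slice:
        return slice(self.n_approach, len(self.t_s))


@dataclass
class IndentationHistory:
    """Contact-referenced indentation history of one curve.

    ``t_s`` starts at 0 at the contact point; ``delta_nm`` is the indentation
    depth (piezo travel past contact minus cantilever deflection F/k);
    ``force_nN`` is the baseline-subtracted measured force on the same
    samples.  ``i_peak`` indexes the maximum indentation (end of approach),
    so ``t_m_s = t_s[i_peak]``.
    """

    t_s: np.ndarray
    delta_nm: np.ndarray
    force_nN: np.ndarray
    i_peak: int
    z0_um: float
    baseline_nN: float
    contact_index: int
    #: unclipped depth (z - z0) - F/k including a pre-contact margin, kept so
    #: that model fits can refine the contact point; None disables refinement
    delta_raw_nm: np.ndarray | None = None

    @property
    def t_m_s(self) -> float:
        return float(self.t_s[self.i_peak])

    def shifted(self, dz_nm: float) -> "IndentationHistory":
        """History with the contact point moved by ``dz_nm`` (positive =
        contact deeper/later).  Leading zero-depth segments carry no
        indentation rate and do not contribute to the hereditary integral."""
        if self.delta_raw_nm is None:
            raise ValueError("history has no raw depth margin; cannot shift")
        delta = np.clip(self.delta_raw_nm - dz_nm, 0.0, None)
        return IndentationHistory(
            t_s=self.t_s,
            delta_nm=delta,
            force_nN=self.force_nN,
            i_peak=self.i_peak,
            z0_um=self.z0_um + dz_nm * 1e-3,
            baseline_nN=self.baseline_nN,
            contact_index=self.contact_index,
            delta_raw_nm=self.delta_raw_nm,
        )


@dataclass
class HertzResult:
    """Apparent Young's modulus fit of the approach phase."""

    E_hertz_Pa: float
    z0_um: float
    thickness_nm: float
    residual_rms_nN: float
    delta_range_nm: tuple[float, float]


@dataclass
class PLRParams:
    """Viscoelastic (PLR + dashpot) parameters with fit diagnostics.

    ``E0_Pa`` is the relaxation-modulus scale at t = 1 s, ``alpha`` the
    power-law exponent (0 solid-like .. 1 fluid-like), ``eta_Pa_s`` the
    Newtonian dashpot term.
    """

    E0_Pa: float
    alpha: float
    eta_Pa_s: float
    residual_norm: float = np.nan
    converged: bool = True
    message: str = ""
    n_evaluations: int = 0
    contact_shift_nm: float = 0.0

    def __post_init__(self):
        if self.E0_Pa <= 0:
            raise ValueError("E0 must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.eta_Pa_s < 0:
            raise ValueError("eta must be non-negative")


@dataclass
class ForceVolumeMap:
    """Grid of force curves acquired over a rectangular scan region."""

    curves: list  # nested list [row][col] of ForceCurve
    pixel_size_um: float
    probe: ProbeGeometry
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.curves), len(self.curves[0]))


@dataclass
class MapResult:
    """Processed force-volume map: per-pixel table, topography and masks."""

    table: pd.DataFrame
    height_nm: np.ndarray
    background_mask: np.ndarray
    central_mask: np.ndarray
    tilt_nm_per_um: tuple[float, float]
    aggregates: dict
    qc: dict


# ---------------------------------------------------------------------------
# Elastic contact (Hertz) with bottom-effect correction
# ---------------------------------------------------------------------------


def bec_factor(
    delta_nm,
    tip_radius_nm: float,
    thickness_nm: float,
    coefficients: Sequence[float] | str = "bonded",
):
    """Bottom-effect correction multiplier for finite sample thickness.

    Polynomial in ``chi = sqrt(R*delta)/h``; returns 1 for ``h = inf`` or
    ``delta = 0`` and grows monotonically as the indentation approaches the
    sample thickness.  ``chi`` beyond the series' validity range is clamped
    (with a warning), which bounds rather than extrapolates the stiffening.
    """
    delta = np.asarray(delta_nm, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be non-negative")
    if thickness_nm <= 0:
        raise ValueError("sample thickness must be positive")
    if isinstance(coefficients, str):
        coefficients = BEC_COEFFICIENTS[coefficients]
    if not np.isfinite(thickness_nm):
        return np.ones_like(delta) if delta.ndim else 1.0
    chi = np.sqrt(tip_radius_nm * delta) / thickness_nm
    if np.any(chi > BEC_CHI_MAX):
        warnings.warn(
            f"BEC argument sqrt(R*delta)/h exceeds {BEC_CHI_MAX}; clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        chi = np.minimum(chi, BEC_CHI_MAX)
    c1, c2, c3, c4 = coefficients
    f = 1.0 + chi * (c1 + chi * (c2 + chi * (c3 + chi * c4)))
    return f if delta.ndim else float(f)


def _hertz_prefactor_si(probe: ProbeGeometry) -> float:
    R = probe.tip_radius_nm * 1e-9
    return 4.0 * np.sqrt(R) / (3.0 * (1.0 - probe.poisson_ratio**2))


def hertz_force(
    delta_nm,
    E_Pa: float,
    probe: ProbeGeometry,
    thickness_nm: float = np.inf,
    bec: bool = True,
):
    """Closed-form (BEC-corrected) Hertz force in nN for a spherical tip."""
    delta = np.asarray(delta_nm, dtype=float)
    fb = bec_factor(delta, probe.tip_radius_nm, thickness_nm) if bec else 1.0
    F = _hertz_prefactor_si(probe) * E_Pa * fb * (delta * 1e-9) ** 1.5
    F_nN = F * 1e9
    return F_nN if delta.ndim else float(F_nN)


def fit_hertz(
    history: IndentationHistory,
    probe: ProbeGeometry,
    thickness_nm: float = np.inf,
    bec: bool = True,
    fit_range_nm: tuple[float, float] | None = None,
) -> HertzResult:
    """Least-squares apparent Young's modulus from the approach phase.

    The model is linear in ``E_Hertz`` so the fit is a single projection.
    ``fit_range_nm`` optionally restricts the indentation depths used.
    """
    sl = slice(0, history.i_peak + 1)
    delta = history.delta_nm[sl]
    F = history.force_nN[sl]
    use = delta > 0
    if fit_range_nm is not None:
        use &= (delta >= fit_range_nm[0]) & (delta <= fit_range_nm[1])
    if use.sum() < 5:
        raise CurveRejected("too_few_contact_samples")
    d = delta[use]
    fb = bec_factor(d, probe.tip_radius_nm, thickness_nm) if bec else 1.0
    m = _hertz_prefactor_si(probe) * fb * (d * 1e-9) ** 1.5 * 1e9  # nN per Pa
    denom = float(np.dot(m, m))
    E = float(np.dot(F[use], m)) / denom
    if E <= 0:
        raise CurveRejected("negative_modulus")
    resid = F[use] - E * m
    return HertzResult(
        E_hertz_Pa=E,
        z0_um=history.z0_um,
        thickness_nm=thickness_nm,
        residual_rms_nN=float(np.sqrt(np.mean(resid**2))),
        delta_range_nm=(float(d.min()), float(d.max())),
    )


# ---------------------------------------------------------------------------
# Contact-point detection
# ---------------------------------------------------------------------------


def detect_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.3,
    min_snr: float = 3.0,
    min_contact_samples: int = 10,
    pre_contact_margin: int = 25,
    thickness_nm: float = np.inf,
) -> IndentationHistory:
    """Locate the contact point of a force curve by Hertz-residual search.

    The baseline force is estimated from the first ``baseline_fraction`` of
    the approach.  Every approach sample is then tried as a candidate contact
    point ``z0``; for each candidate a linear Hertz fit is performed on the
    samples past it and the candidate minimising the total squared residual
    (pre-contact force plus Hertz misfit) is kept.  The indentation history is
    built as ``delta = (z - z0) - F/k``, i.e. with the cantilever deflection
    removed, and truncated on retract at the loss of contact.

    Raises
    ------
    CurveRejected
        If no pre-contact baseline / contact signal is detectable.
    """
    curve.validate()
    na = curve.n_approach
    if na < 50:
        raise CurveRejected("too_short", f"{na} approach samples")
    t = np.asarray(curve.t_s, float)
    z = np.asarray(curve.z_um, float)
    F = np.asarray(curve.force_nN, float)
    k = curve.probe.spring_constant_N_m

    nb = max(5, int(baseline_fraction * na))
    baseline = float(np.mean(F[:nb]))
    noise_sd = float(np.std(F[:nb]))
    F0 = F - baseline

    peak = float(np.max(F0[:na]))
    if peak <= 0 or (noise_sd > 0 and peak < min_snr * noise_sd):
        raise CurveRejected("no_contact", "no force signal above baseline noise")

    # Candidate grid: all approach samples that leave enough contact points.
    lo = 2
    hi = na - min_contact_samples
    if hi <= lo:
        raise CurveRejected("too_short")
    cand = np.arange(lo, hi)
    z_a, F_a = z[:na], F0[:na]
    # delta matrix (candidate x sample), upper-triangular region is contact
    D = (z_a[None, :] - z_a[cand][:, None]) * 1e3 - F_a[None, :] / k  # nm
    contact = (np.arange(na)[None, :] > cand[:, None]) & (D > 0)
    Dp = np.clip(D, 0, None)
    M = np.where(contact, Dp**1.5, 0.0)
    if np.isfinite(thickness_nm):
        # finite-thickness stiffening distorts the delta^{3/2} shape enough
        # to bias the contact search; include it when the thickness is known
        M = M * bec_factor(Dp, curve.probe.tip_radius_nm, thickness_nm)
    num = M @ F_a
    den = np.einsum("ij,ij->i", M, M)
    ok = den > 0
    score = np.where(ok, np.clip(num, 0, None) ** 2 / np.where(ok, den, 1.0), -1.0)
    c = int(cand[int(np.argmax(score))])
    if score.max() <= 0:
        raise CurveRejected("no_contact", "Hertz search found no positive stiffness")

    z0 = float(z[c])
    delta_raw = (z - z0) * 1e3 - F0 / k  # nm, full curve
    delta = np.clip(delta_raw, 0.0, None)
    delta[:c] = 0.0
    i_peak_global = c + int(np.argmax(delta[c:na]))
    # truncate retract at loss of contact (first non-positive depth past peak)
    post = np.nonzero(delta_raw[i_peak_global:] <= 0)[0]
    end = i_peak_global + int(post[0]) if post.size else len(delta)
    start = max(0, c - pre_contact_margin)
    sl = slice(start, end)
    hist = IndentationHistory(
        t_s=t[sl] - t[start],
        delta_nm=delta[sl],
        force_nN=F0[sl],
        i_peak=i_peak_global - start,
        z0_um=z0,
        baseline_nN=baseline,
        contact_index=c,
        delta_raw_nm=delta_raw[sl],
    )
    return hist


# ---------------------------------------------------------------------------
# Ting viscoelastic model (forward evaluation)
# ---------------------------------------------------------------------------


def _t1_si(tq, t, delta, i_peak, E0, alpha, eta):
    """Auxiliary unloading time t1 for query times ``tq`` (all > t_m).

    The defining condition is that the PLR-kernel-weighted integral of the
    indentation rate over [t1, t] vanishes; for a piecewise-linear history
    the integral is analytic per segment, so after a node-level bracket scan
    t1 is obtained by exact inversion inside one approach segment.  Returns
    ``(t1, detached)``; detached samples carry t1 = 0 (the tip has separated
    and the contact force is zero).
    """
    tq = np.atleast_1d(np.asarray(tq, float))
    one_m_a = 1.0 - alpha
    v = np.diff(delta) / np.diff(t)
    ti = tq[:, None]
    P = np.clip(ti - t[None, :], 0.0, None) ** one_m_a  # (M, N) node powers
    S = v[None, :] * (P[:, :-1] - P[:, 1:]) / one_m_a  # segment integrals
    # suffix sums: integral from node j to tq
    W = np.concatenate(
        [np.cumsum(S[:, ::-1], axis=1)[:, ::-1], np.zeros((tq.size, 1))], axis=1
    )
    # indentation rate at tq (containing segment; tq is on retract)
    seg = np.clip(np.searchsorted(t, tq, side="right") - 1, 0, v.size - 1)
    v_at = v[seg]
    Phi = E0 * W + eta * v_at[:, None]
    pos = Phi[:, : i_peak + 1] >= 0.0
    # out of contact (zero indentation at the query time) means detached,
    # whatever the near-zero integral says
    delta_at = np.interp(tq, t, delta)
    detached = ~pos[:, 0] | (delta_at <= 0.0)
    # Phi is non-increasing over the approach nodes: last non-negative node
    jstar = np.clip(pos.sum(axis=1) - 1, 0, i_peak - 1)
    rows = np.arange(tq.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhs = P[rows, jstar + 1] + one_m_a * (
            -eta * v_at / E0 - W[rows, jstar + 1]
        ) / v[jstar]
        t1 = tq - np.clip(rhs, 0.0, None) ** (1.0 / one_m_a)
    t1 = np.clip(t1, t[jstar], t[jstar + 1])
    # detachment is permanent; enforce monotone non-increasing t1
    detached = np.maximum.accumulate(detached)
    t1 = np.where(detached, 0.0, t1)
    t1 = np.minimum.accumulate(t1)
    return t1, detached


def solve_t1(
    t_query: float,
    history: IndentationHistory,
    params: PLRParams,
) -> float:
    """Auxiliary time t1 for a single retract time (seconds from contact).

    Returns 0.0 (the detachment sentinel) when the vanishing-integral
    condition has no root in [0, t_m]: the tip has fully separated.
    """
    if t_query <= history.t_m_s:
        return float(t_query) if t_query == history.t_m_s else _raise_pre_tm(t_query)
    t1, _ = _t1_si(
        np.array([t_query]),
        history.t_s,
        history.delta_nm * 1e-9,
        history.i_peak,
        params.E0_Pa,
        params.alpha,
        params.eta_Pa_s,
    )
    return float(t1[0])


def _raise_pre_tm(t_query):
    raise ValueError(f"solve_t1 requires t > t_m (got {t_query})")


def ting_force(
    history: IndentationHistory,
    params: PLRParams,
    probe: ProbeGeometry,
    thickness_nm: float = np.inf,
    bec: bool = True,
) -> np.ndarray:
    """Force trace (nN) of the Ting/PLR model on the given indentation history.

    On approach the hereditary integral runs to the current time (t1 = t);
    on retract the upper limit is the auxiliary time from the vanishing
    rate-integral condition.  The Dirac dashpot term contributes
    ``eta * d(delta^{3/2})/dt`` during approach only, and the force is
    identically zero after detachment (t1 = 0).
    """
    t = np.asarray(history.t_s, float)
    delta = np.asarray(history.delta_nm, float) * 1e-9
    i_peak = history.i_peak
    E0, alpha, eta = params.E0_Pa, params.alpha, params.eta_Pa_s
    if alpha >= 1.0:
        raise ValueError("alpha must be < 1 for a finite hereditary integral")
    C = _hertz_prefactor_si(probe)
    one_m_a = 1.0 - alpha
    N = t.size

    t1 = t.copy()
    if i_peak < N - 1:
        t1_r, _ = _t1_si(t[i_peak + 1 :], t, delta, i_peak, E0, alpha, eta)
        t1[i_peak + 1 :] = t1_r

    # Refined integration nodes: delta^{3/2} has unbounded curvature where
    # delta -> 0, so low-indentation segments are subdivided (delta is linear
    # in time within a segment, hence interpolation is exact).
    tr, dr = _refine_history(t, delta, refine_frac=0.12, refine_factor=8)
    h32 = dr**1.5
    g = np.diff(h32) / np.diff(tr)
    if bec and np.isfinite(thickness_nm):
        delta_mid_nm = 0.5 * (dr[:-1] + dr[1:]) * 1e9
        fb = bec_factor(delta_mid_nm, probe.tip_radius_nm, thickness_nm)
    else:
        fb = 1.0
    gb = g * fb

    clip = np.minimum(tr[None, :], t1[:, None])
    Q = np.clip(t[:, None] - clip, 0.0, None) ** one_m_a
    F = (C * E0 / one_m_a) * ((Q[:, :-1] - Q[:, 1:]) * gb).sum(axis=1)

    if eta > 0:
        # Dirac term: eta * f_BEC(delta(t)) * d(delta^{3/2})/dt, with the
        # exact backward-sided derivative 1.5*sqrt(delta)*v of the piecewise
        # linear history (approach only; on retract t1 < t excludes it).
        v = np.diff(delta) / np.diff(t)
        gd = np.zeros(N)
        gd[1 : i_peak + 1] = 1.5 * np.sqrt(delta[1 : i_peak + 1]) * v[:i_peak]
        if bec and np.isfinite(thickness_nm):
            fbn = bec_factor(history.delta_nm, probe.tip_radius_nm, thickness_nm)
            gd *= fbn
        F[: i_peak + 1] += C * eta * gd[: i_peak + 1]
    return F * 1e9  # nN


def _refine_history(t, delta, refine_frac=0.12, refine_factor=8, n_target=96):
    """Subdivide history segments for the hereditary integral: all moving
    segments are refined so that at least ``n_target`` sub-segments span the
    contact (curves triggered after very few samples stay well resolved), and
    low-indentation segments (where delta^{3/2} curves most) get at least
    ``refine_factor``-fold subdivision.  Linear interpolation of delta is
    exact for a piecewise-linear drive."""
    dpk = delta.max()
    if dpk <= 0:
        return t, delta
    lo = np.minimum(delta[:-1], delta[1:])
    moving = delta[:-1] != delta[1:]
    n_moving = int(moving.sum())
    m_uniform = max(1, int(np.ceil(n_target / max(n_moving, 1))))
    needs_extra = moving & (lo < refine_frac * dpk)
    m_per_seg = np.where(moving, m_uniform, 1)
    m_per_seg = np.where(needs_extra, np.maximum(m_per_seg, refine_factor), m_per_seg)
    if m_per_seg.max() <= 1:
        return t, delta
    pieces = [t[:1]]
    for j in range(t.size - 1):
        pieces.append(np.linspace(t[j], t[j + 1], m_per_seg[j] + 1)[1:])
    tr = np.concatenate(pieces)
    return tr, np.interp(tr, t, delta)


# ---------------------------------------------------------------------------
# Viscoelastic fitting
# ---------------------------------------------------------------------------


def _decimate_history(history: IndentationHistory, max_per_phase: int):
    """Subsample a history for fitting, always keeping contact/peak/end."""
    n = history.t_s.size
    ia = np.unique(np.linspace(0, history.i_peak, min(max_per_phase, history.i_peak + 1)).astype(int))
    nr = n - history.i_peak - 1
    if nr > 0:
        ir = np.unique(
            np.linspace(history.i_peak + 1, n - 1, min(max_per_phase, nr)).astype(int)
        )
        idx = np.concatenate([ia, ir])
    else:
        idx = ia
    return IndentationHistory(
        t_s=history.t_s[idx],
        delta_nm=history.delta_nm[idx],
        force_nN=history.force_nN[idx],
        i_peak=int(np.searchsorted(idx, history.i_peak)),
        z0_um=history.z0_um,
        baseline_nN=history.baseline_nN,
        contact_index=history.contact_index,
        delta_raw_nm=None
        if history.delta_raw_nm is None
        else history.delta_raw_nm[idx],
    )


def fit_viscoelastic(
    history: IndentationHistory,
    probe: ProbeGeometry,
    thickness_nm: float = np.inf,
    bec: bool = True,
    init: tuple[float, float, float] | None = None,
    fix_alpha: float | None = None,
    fix_eta: float | None = None,
    refine_contact: bool = True,
    contact_shift_bound_nm: float = 150.0,
    max_samples_per_phase: int = 160,
    bounds=PLR_BOUNDS,
    max_nfev: int = 400,
) -> PLRParams:
    """Trust-region least squares of the Ting/PLR model against a force curve.

    The residual is the joint approach+retract misfit with uniform weights.
    Initialisation defaults to (E_Hertz, 0.2, 1.0), the Hertz estimate and
    the centre of the parameter ranges typical for adherent cells.
    ``fix_alpha``/``fix_eta`` pin parameters (e.g. 0, 0 for the elastic
    nested model, which must then reproduce the Hertz fit).

    With ``refine_contact`` (default) the contact-point position is refined
    jointly with the material parameters: the grid-search detection minimises
    a Hertz (elastic) residual and is therefore biased by a few samples on
    strongly viscoelastic curves whose early-contact force does not rise as
    ``delta^{3/2}``.
    """
    if init is None:
        hz = fit_hertz(history, probe, thickness_nm=thickness_nm, bec=bec)
        init = (hz.E_hertz_Pa, 0.2, 1.0)
    hist = (
        _decimate_history(history, max_samples_per_phase)
        if history.t_s.size > 2 * max_samples_per_phase
        else history
    )
    F_meas = hist.force_nN
    refine = refine_contact and hist.delta_raw_nm is not None

    free = [fix_alpha is None, fix_eta is None]

    def unpack(x):
        E0 = x[0]
        i = 1
        if free[0]:
            a = x[i]
            i += 1
        else:
            a = fix_alpha
        if free[1]:
            e = x[i]
            i += 1
        else:
            e = fix_eta
        dz = x[i] if refine else 0.0
        return E0, a, e, dz

    def resid(x):
        E0, a, e, dz = unpack(x)
        p = PLRParams(E0_Pa=max(E0, 1e-6), alpha=min(max(a, 0.0), 0.99), eta_Pa_s=max(e, 0.0))
        h = hist.shifted(dz) if refine else hist
        return ting_force(h, p, probe, thickness_nm=thickness_nm, bec=bec) - F_meas

    x0 = [init[0]]
    lo, hi = [bounds[0][0]], [bounds[1][0]]
    scale = [max(init[0], 10.0)]
    if free[0]:
        x0.append(init[1]); lo.append(bounds[0][1]); hi.append(bounds[1][1]); scale.append(0.1)
    if free[1]:
        x0.append(init[2]); lo.append(bounds[0][2]); hi.append(bounds[1][2]); scale.append(1.0)
    if refine:
        x0.append(0.0); lo.append(-contact_shift_bound_nm); hi.append(contact_shift_bound_nm)
        scale.append(20.0)
    x0 = np.clip(x0, lo, hi)

    sol = optimize.least_squares(
        resid, x0, bounds=(lo, hi), x_scale=scale, method="trf", max_nfev=max_nfev
    )
    E0, a, e, dz = unpack(sol.x)
    return PLRParams(
        E0_Pa=float(E0),
        alpha=float(a),
        eta_Pa_s=float(e),
        residual_norm=float(np.sqrt(2.0 * sol.cost / F_meas.size)),
        converged=bool(sol.success),
        message=str(sol.message),
        n_evaluations=int(sol.nfev),
        contact_shift_nm=float(dz),
    )


# ---------------------------------------------------------------------------
# Map-level processing
# ---------------------------------------------------------------------------


def build_topography(
    z0_um: np.ndarray,
    pixel_size_um: float,
    background_height_nm: float = BACKGROUND_HEIGHT_NM,
    min_substrate_pixels: int = 10,
    n_iter: int = 10,
):
    """Topography from per-pixel contact points with global tilt correction.

    The raw surface level is ``-z0`` (an earlier contact means a taller
    feature).  A substrate plane is fitted iteratively: pixels within
    ``background_height_nm`` of the current substrate median are treated as
    substrate and the plane is refitted on them.  The returned heights have
    substrate median 0; the background mask keeps pixels at or above the
    height threshold.

    Returns ``(height_nm, background_mask, tilt_nm_per_um)``.
    """
    raw = -np.asarray(z0_um, float) * 1e3  # nm
    ny, nx = raw.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    x_um = xx.ravel() * pixel_size_um
    y_um = yy.ravel() * pixel_size_um
    A = np.column_stack([x_um, y_um, np.ones(x_um.size)])
    finite = np.isfinite(raw.ravel())
    if finite.sum() < 3:
        raise ValueError("not enough valid pixels for topography")
    inliers = finite.copy()
    coeffs = np.zeros(3)
    for _ in range(n_iter):
        if inliers.sum() < min_substrate_pixels:
            warnings.warn(
                "fewer than %d substrate pixels; tilt correction skipped"
                % min_substrate_pixels,
                RuntimeWarning,
            )
            coeffs = np.array([0.0, 0.0, np.nanmedian(raw)])
            break
        coeffs, *_ = np.linalg.lstsq(A[inliers], raw.ravel()[inliers], rcond=None)
        h = raw.ravel() - A @ coeffs
        med = np.median(h[inliers])
        new = finite & (h - med < background_height_nm)
        if new.sum() == inliers.sum() and np.all(new == inliers):
            inliers = new
            break
        inliers = new
    height = raw - (A @ coeffs).reshape(ny, nx)
    height -= np.median(height.ravel()[inliers])
    mask = np.isfinite(height) & (height >= background_height_nm)
    return height, mask, (float(coeffs[0]), float(coeffs[1]))


def select_central_region(height_nm: np.ndarray, background_mask: np.ndarray):
    """Central-cell mask: per connected component, keep pixels whose height is
    at least 50% of that component's maximum (the cell periphery, dominated by
    peripheral F-actin, is discarded)."""
    labels, n = ndimage.label(background_mask)
    central = np.zeros_like(background_mask, dtype=bool)
    for lab in range(1, n + 1):
        comp = labels == lab
        hmax = np.nanmax(height_nm[comp])
        sel = comp & (height_nm >= 0.5 * hmax)
        if not sel.any():
            logger.info("component %d empty after top-50%% thresholding; dropped", lab)
            continue
        central |= sel
    return central


def aggregate_cell_mechanics(
    table: pd.DataFrame,
    central_mask: np.ndarray,
    min_pixels: int = MIN_AGGREGATE_PIXELS,
) -> dict:
    """Arithmetic means of the mechanical parameters over the central mask.

    Rejected / non-converged pixels (``flag != 'ok'``) are excluded from the
    means and reported in the counts.  Raises ``ValueError`` when fewer than
    ``min_pixels`` valid pixels remain (the map is then excluded from group
    statistics).
    """
    in_mask = central_mask[
        table["pixel_i"].to_numpy(), table["pixel_j"].to_numpy()
    ]
    sub = table[in_mask]
    valid = sub[sub["flag"] == "ok"]
    if len(valid) < min_pixels:
        raise ValueError(
            f"only {len(valid)} valid central pixels (< {min_pixels}); map excluded"
        )
    out = {"n_pixels": int(len(valid)), "n_rejected": int(len(sub) - len(valid))}
    for col in ("E_hertz_Pa", "E0_Pa", "alpha", "eta_Pas", "height_nm"):
        if col in valid and valid[col].notna().any():
            out[f"mean_{col}"] = float(valid[col].mean(skipna=True))
    return out


def process_map(
    fv_map: ForceVolumeMap,
    mode: str = "hertz",
    thickness: str = "from-topography",
    bec: bool = True,
    min_pixels: int = MIN_AGGREGATE_PIXELS,
    max_samples_per_phase: int = 160,
) -> MapResult:
    """Full per-map pipeline: contact detection, topography, masking, fitting
    and aggregation.

    ``mode`` is ``"hertz"``, ``"ting"`` or ``"both"``; ``thickness`` is
    ``"from-topography"`` (local corrected height, cells on rigid glass) or
    ``"infinite"``.
    """
    if mode not in {"hertz", "ting", "both"}:
        raise ValueError(f"unknown mode {mode!r}")
    ny, nx = fv_map.shape
    if ny < 2 or nx < 2:
        raise ValueError("map must be at least 2x2")
    z0 = np.full((ny, nx), np.nan)
    hists: dict[tuple[int, int], IndentationHistory] = {}
    reject: dict[tuple[int, int], str] = {}
    for i in range(ny):
        for j in range(nx):
            try:
                h = detect_contact_point(fv_map.curves[i][j])
                hists[(i, j)] = h
                z0[i, j] = h.z0_um
            except CurveRejected as err:
                reject[(i, j)] = err.reason
    height, bg_mask, tilt = build_topography(z0, fv_map.pixel_size_um)
    central = select_central_region(height, bg_mask)

    rows = []
    for i in range(ny):
        for j in range(nx):
            row = {
                "pixel_i": i,
                "pixel_j": j,
                "height_nm": float(height[i, j]) if np.isfinite(height[i, j]) else np.nan,
                "E_hertz_Pa": np.nan,
                "E0_Pa": np.nan,
                "alpha": np.nan,
                "eta_Pas": np.nan,
                "flag": reject.get((i, j), "ok"),
            }
            hist = hists.get((i, j))
            if hist is not None and central[i, j]:
                h_nm = (
                    max(height[i, j], 1.0) if thickness == "from-topography" else np.inf
                )
                try:
                    if mode in {"hertz", "both"}:
                        row["E_hertz_Pa"] = fit_hertz(
                            hist, fv_map.probe, thickness_nm=h_nm, bec=bec
                        ).E_hertz_Pa
                    if mode in {"ting", "both"}:
                        p = fit_viscoelastic(
                            hist,
                            fv_map.probe,
                            thickness_nm=h_nm,
                            bec=bec,
                            max_samples_per_phase=max_samples_per_phase,
                        )
                        if not p.converged:
                            row["flag"] = "not_converged"
                        row["E0_Pa"], row["alpha"], row["eta_Pas"] = (
                            p.E0_Pa,
                            p.alpha,
                            p.eta_Pa_s,
                        )
                except CurveRejected as err:
                    row["flag"] = err.reason
            rows.append(row)
    table = pd.DataFrame(rows)
    try:
        aggregates = aggregate_cell_mechanics(table, central, min_pixels=min_pixels)
    except ValueError as err:
        aggregates = {"excluded": str(err)}
    qc = {
        "n_pixels": ny * nx,
        "n_rejected_curves": len(reject),
        "n_background": int((~bg_mask).sum()),
        "n_central": int(central.sum()),
    }
    return MapResult(
        table=table,
        height_nm=height,
        background_mask=bg_mask,
        central_mask=central,
        tilt_nm_per_um=tilt,
        aggregates=aggregates,
        qc=qc,
    )
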