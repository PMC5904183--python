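"""AFM force-spectroscopy processing: Hertz indentation fits for a
square pyramidal tip, deflection-sensitivity calibration, baseline
correction and per-region stiffness aggregation.

Unit conventions (chosen so no conversion constants appear in the model):
piezo extension ``z`` in µm (increasing during the approach, toward the
sample), force in nN, moduli in kPa — then ``kPa · µm² = nN`` exactly and
the four-sided pyramid contact model reads

    F(δ) = (tan θ / √2) · E / (1 − ν²) · δ²,   δ = (z − deflection) − z_c

with θ the face-to-axis half-angle, ν the Poisson ratio and z_c the
contact position on the tip-position axis ``s = z − deflection``.
Moduli are *effective* Young's moduli: the model assumes a homogeneous,
elastic sample and quasistatic indentation, so values are comparative,
not absolute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "ForceCurve",
    "FitParams",
    "HertzFitResult",
    "CalibrationResult",
    "RegionStats",
    "pyramid_prefactor",
    "calibrate_sensitivity",
    "preprocess_curve",
    "fit_hertz_pyramid",
    "aggregate_region",
    "HertzModel",
]


@dataclass
class ForceCurve:
    """A single force ramp.

    ``z`` is piezo extension (µm), strictly monotone within the segment
    and increasing toward the sample on the approach. ``signal`` is
    force (nN), deflection (nm) or raw photodiode deflection (V)
    according to ``mode``; raw/deflection modes need ``spring_constant``
    (N/m, = nN/nm) and raw additionally ``sensitivity_nm_per_V``.
    """

    z: np.ndarray
    signal: np.ndarray
    mode: str = "force"  # force | deflection_nm | deflection_V
    segment: str = "approach"
    spring_constant: float | None = None  # N/m
    sensitivity_nm_per_V: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.z.shape != self.signal.shape:
            raise ValueError("z and signal must have equal length")
        if self.z.size >= 2:
            dz = np.diff(self.z)
            if not (np.all(dz > 0) or np.all(dz < 0)):
                raise ValueError("z must be strictly monotone within a segment")
        if self.mode not in ("force", "deflection_nm", "deflection_V"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def force_nN(self) -> np.ndarray:
        """Signal converted to force (nN)."""
        if self.mode == "force":
            return self.signal.copy()
        if self.spring_constant is None:
            raise ValueError("spring_constant required to convert deflection to force")
        if self.mode == "deflection_nm":
            return self.signal * self.spring_constant
        if self.sensitivity_nm_per_V is None:
            raise ValueError("sensitivity_nm_per_V required for raw (volt) curves")
        return self.signal * self.sensitivity_nm_per_V * self.spring_constant


@dataclass
class FitParams:
    """Contact-model and preprocessing parameters.

    ``edge_angle_deg`` is interpreted per ``angle_convention``:
    "face" (default) takes it as the face-to-axis half-angle; "edge" as
    the edge-to-axis half-angle (tan θ_edge = √2 · tan θ_face).
    The 10° cantilever-tilt correction multiplies forces by 1/cos²(tilt)
    when enabled; the correction form is instrument-dependent, so it is
    off by default.
    """

    poisson_ratio: float = 0.5
    edge_angle_deg: float = 25.0
    angle_convention: str = "face"
    cantilever_tilt_deg: float = 10.0
    apply_tilt_correction: bool = False
    baseline_fraction: float = 0.6
    max_indentation_fraction: float = 1.0
    min_post_contact_points: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if not 0.0 < self.edge_angle_deg < 90.0:
            raise ValueError("edge_angle_deg must be in (0, 90)")
        if self.angle_convention not in ("face", "edge"):
            raise ValueError("angle_convention must be 'face' or 'edge'")


def pyramid_prefactor(params: FitParams) -> float:
    """Geometry/elasticity prefactor C with F = C · E · δ² (E in kPa,
    δ in µm, F in nN)."""
    theta = math.radians(params.edge_angle_deg)
    tan_face = math.tan(theta)
    if params.angle_convention == "edge":
        tan_face /= math.sqrt(2.0)
    c = (tan_face / math.sqrt(2.0)) / (1.0 - params.poisson_ratio**2)
    if params.apply_tilt_correction:
        c /= math.cos(math.radians(params.cantilever_tilt_deg)) ** 2
    return c


@dataclass
class CalibrationResult:
    sensitivity_nm_per_V: float
    slope_V_per_um: float
    window: tuple
    r_squared: float


def calibrate_sensitivity(rigid_curve: ForceCurve, contact_fraction: float = 0.3,
                          min_r_squared: float = 0.98) -> CalibrationResult:
    """Deflection sensitivity from a force ramp on a rigid substrate.

    On an effectively infinitely stiff surface the tip does not indent,
    so past contact the photodiode signal rises linearly with piezo
    extension; the inverse of that slope is the sensitivity (nm/V).
    The contact region is taken as the terminal ``contact_fraction`` of
    the approach; a linear fit below ``min_r_squared`` (or a flat curve)
    raises a calibration error.
    """
    if rigid_curve.mode != "deflection_V":
        raise ValueError("sensitivity calibration needs a raw (volt) curve")
    z, v = rigid_curve.z, rigid_curve.signal
    n = z.size
    i0 = int(round(n * (1.0 - contact_fraction)))
    i0 = min(max(i0, 0), n - 3)
    zs, vs = z[i0:], v[i0:]
    slope, intercept = np.polyfit(zs, vs, 1)
    pred = slope * zs + intercept
    ss_tot = float(np.sum((vs - vs.mean()) ** 2))
    ss_res = float(np.sum((vs - pred) ** 2))
    if ss_tot <= 0:
        raise RuntimeError("no contact region: signal is flat in the fit window")
    r2 = 1.0 - ss_res / ss_tot
    if r2 < min_r_squared or abs(slope) <= 0:
        raise RuntimeError(
            f"no linear contact region detected (R²={r2:.3f} < {min_r_squared})")
    return CalibrationResult(sensitivity_nm_per_V=1000.0 / abs(slope),
                             slope_V_per_um=float(slope),
                             window=(i0, n), r_squared=r2)


@dataclass
class ForceSeparationCurve:
    """Baseline-corrected force versus tip position s = z − deflection."""

    separation: np.ndarray  # µm, tip-position axis; contact at s = z_c
    force: np.ndarray  # nN, baseline-corrected
    baseline_offset: float
    baseline_slope: float
    noise_estimate: float


def preprocess_curve(curve: ForceCurve, params: FitParams | None = None,
                     min_baseline_fraction: float = 0.2) -> ForceSeparationCurve:
    """Correct a ramp for baseline position/slope and convert to a
    force-versus-separation curve.

    The linear baseline is estimated on the non-contact region (the first
    ``baseline_fraction`` of the approach), refined once after an initial
    contact estimate, and subtracted; deflection (force / spring constant)
    is subtracted from z to give the tip position. After correction the
    non-contact force is zero-mean within noise.
    """
    params = params or FitParams()
    if curve.segment != "approach":
        raise ValueError("preprocessing expects the approach segment")
    z = curve.z
    if z[0] > z[-1]:  # store approach with z increasing toward the sample
        z = z[::-1]
        force = curve.force_nN()[::-1]
    else:
        force = curve.force_nN()
    n = z.size
    nb = int(round(n * params.baseline_fraction))
    if nb < max(4, int(n * min_baseline_fraction)):
        raise RuntimeError("non-contact region too short for baseline estimation")

    def debaseline(idx):
        slope, offset = np.polyfit(z[idx], force[idx], 1)
        return force - (offset + slope * z), float(offset), float(slope)

    idx0 = np.arange(nb)
    f_corr, offset, slope = debaseline(idx0)
    noise = float(np.std(f_corr[idx0], ddof=1)) if nb > 2 else 0.0
    # refine: everything below a small force excursion is non-contact
    thr = max(5.0 * noise, 1e-3 * max(np.ptp(f_corr), 1e-30))
    noncontact = np.nonzero(f_corr > thr)[0]
    if noncontact.size:
        first_contact = int(noncontact[0])
        if first_contact >= max(4, int(n * min_baseline_fraction)):
            f_corr, offset, slope = debaseline(np.arange(first_contact))
            noise = float(np.std(f_corr[:first_contact], ddof=1))
        # a threshold-based window always swallows the sub-threshold tail
        # of the contact force, tilting the baseline; refine by fitting
        # baseline and contact term jointly on the whole approach
        c0 = z[first_contact]
        dmax = max(z[-1] - c0, 1e-9)
        amp0 = max((f_corr[-1]) / dmax**2, 1e-9)

        def resid(p):
            off, slp, amp, c = p
            d = np.clip(z - c, 0.0, None)
            return off + slp * z + amp * d * d - f_corr

        span = z[-1] - z[0]
        sol = optimize.least_squares(
            resid, x0=[0.0, 0.0, amp0, c0],
            bounds=([-np.inf, -np.inf, 0.0, z[0]],
                    [np.inf, np.inf, np.inf, z[-1] + 0.1 * span]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if sol.success:
            off, slp = sol.x[0], sol.x[1]
            f_corr = f_corr - (off + slp * z)
            offset += off
            slope += slp
            resid_pre = f_corr[z < sol.x[3]]
            if resid_pre.size > 2:
                noise = float(np.std(resid_pre, ddof=1))
    if curve.spring_constant is not None:
        deflection_um = (f_corr / curve.spring_constant) * 1e-3  # nN/(N/m)=nm
        sep = z - deflection_um
    else:
        sep = z.copy()
    return ForceSeparationCurve(separation=sep, force=f_corr,
                                baseline_offset=offset, baseline_slope=slope,
                                noise_estimate=noise)


@dataclass
class HertzFitResult:
    """Fitted effective Young's modulus for one approach curve."""

    E_eff_kPa: float
    contact_z_um: float
    baseline_offset: float
    baseline_slope: float
    rss: float
    n_points_fit: int
    converged: bool
    message: str = ""


def _hertz_force(s: np.ndarray, amp: float, contact: float) -> np.ndarray:
    delta = np.clip(s - contact, 0.0, None)
    return amp * delta * delta


def fit_hertz_pyramid(fsc: ForceSeparationCurve,
                      params: FitParams | None = None) -> HertzFitResult:
    """Least-squares Hertz fit with contact point as a free parameter.

    Fits F(s) = C·E·max(s − z_c, 0)² jointly in (E, z_c) from a
    threshold-based initial contact estimate; the fit window excludes
    indentations beyond ``max_indentation_fraction`` of the post-contact
    range. Non-convergence, E ≤ 0 or too few post-contact points flag the
    result non-converged (it is reported, never silently dropped).
    """
    params = params or FitParams()
    c_geom = pyramid_prefactor(params)
    s, f = fsc.separation, fsc.force
    thr = max(5.0 * fsc.noise_estimate, 0.02 * max(f.max(), 1e-30))
    above = np.nonzero(f > thr)[0]
    if above.size == 0:
        return HertzFitResult(np.nan, np.nan, fsc.baseline_offset,
                              fsc.baseline_slope, np.nan, 0, False,
                              "no contact detected")
    c0 = s[above[0]]
    post0 = s > c0
    if params.max_indentation_fraction < 1.0 and post0.any():
        dmax = (s[post0] - c0).max() * params.max_indentation_fraction
        keep = (s <= c0) | (s - c0 <= dmax)
    else:
        keep = np.ones_like(s, dtype=bool)
    s_fit, f_fit = s[keep], f[keep]
    n_post = int((s_fit > c0).sum())
    if n_post < params.min_post_contact_points:
        return HertzFitResult(np.nan, float(c0), fsc.baseline_offset,
                              fsc.baseline_slope, np.nan, n_post, False,
                              "too few post-contact points")
    dmax0 = max((s_fit - c0).max(), 1e-12)
    amp0 = max(f_fit.max() / dmax0**2, 1e-12)

    def resid(p):
        return _hertz_force(s_fit, p[0], p[1]) - f_fit

    span = s.max() - s.min()
    sol = optimize.least_squares(
        resid, x0=[amp0, c0],
        bounds=([0.0, s.min() - 0.1 * span], [np.inf, s.max()]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    amp, contact = sol.x
    e_eff = amp / c_geom
    rss = float(np.sum(sol.fun**2))
    ok = bool(sol.success) and e_eff > 0 and np.isfinite(e_eff)
    return HertzFitResult(float(e_eff), float(contact), fsc.baseline_offset,
                          fsc.baseline_slope, rss, int(s_fit.size), ok,
                          "" if ok else "optimizer failure or E <= 0")


@dataclass
class RegionStats:
    """Stiffness summary over the accepted fits of one region."""

    region: str
    n: int
    mean_E_kPa: float
    sem_E_kPa: float | None
    rejected: int
    rejection_reasons: list

    def to_dict(self) -> dict:
        return {"region": self.region, "n": self.n,
                "mean_E_kPa": self.mean_E_kPa, "sem_E_kPa": self.sem_E_kPa,
                "rejected": self.rejected,
                "rejection_reasons": list(self.rejection_reasons)}


def aggregate_region(fits: Sequence[HertzFitResult], regions: Sequence[str],
                     fold_pair: tuple[str, str] | None = None):
    """Mean ± s.e.m. effective modulus per region over converged fits.

    Returns ``(stats, fold)`` where ``stats`` maps region → RegionStats
    and ``fold`` is mean(region A) / mean(region B) for ``fold_pair``
    (defaults to the first two regions in order of appearance; None when
    fewer than two regions). Rejected (non-converged) fits are counted
    but never contribute to the mean.
    """
    if len(fits) != len(regions):
        raise ValueError("fits and regions must align")
    order: list[str] = []
    grouped: dict[str, list[HertzFitResult]] = {}
    for fit, reg in zip(fits, regions):
        if reg not in grouped:
            grouped[reg] = []
            order.append(reg)
        grouped[reg].append(fit)
    stats: dict[str, RegionStats] = {}
    for reg in order:
        accepted = [f.E_eff_kPa for f in grouped[reg] if f.converged]
        reasons = [f.message for f in grouped[reg] if not f.converged]
        if not accepted:
            raise RuntimeError(f"region {reg!r} has no converged fits")
        arr = np.asarray(accepted)
        sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size >= 2 else None
        stats[reg] = RegionStats(region=reg, n=arr.size,
                                 mean_E_kPa=float(arr.mean()), sem_E_kPa=sem,
                                 rejected=len(reasons), rejection_reasons=reasons)
    fold = None
    if fold_pair is None and len(order) >= 2:
        fold_pair = (order[0], order[1])
    if fold_pair is not None:
        a, b = fold_pair
        fold = stats[a].mean_E_kPa / stats[b].mean_E_kPa
    return stats, fold


class HertzModel:
    """Hertz contact model for one approach curve.

    statsmodels-style wrapper: construct from a :class:`ForceCurve` (or
    raw z/force arrays) plus :class:`FitParams`; ``fit()`` preprocesses
    the ramp and returns a :class:`HertzResults`.
    """

    def __init__(self, curve: ForceCurve, params: FitParams | None = None):
        self.curve = curve
        self.params = params or FitParams()

    @classmethod
    def from_arrays(cls, z_um, force_nN, **kwargs) -> "HertzModel":
        return cls(ForceCurve(z=z_um, signal=force_nN, mode="force"), **kwargs)

    def fit(self) -> "HertzResults":
        fsc = preprocess_curve(self.curve, self.params)
        res = fit_hertz_pyramid(fsc, self.params)
        return HertzResults(model=self, fsc=fsc, result=res)


@dataclass
class HertzResults:
    model: HertzModel
    fsc: ForceSeparationCurve
    result: HertzFitResult

    @property
    def E_eff_kPa(self) -> float:
        return self.result.E_eff_kPa

    @property
    def contact_z_um(self) -> float:
        return self.result.contact_z_um

    def fittedvalues(self) -> np.ndarray:
        c = pyramid_prefactor(self.model.params)
        return _hertz_force(self.fsc.separation, c * self.result.E_eff_kPa,
                            self.result.contact_z_um)

    def summary(self) -> str:
        r = self.result
        p = self.model.params
        lines = [
            "Hertz pyramidal indentation fit",
            "=" * 34,
            f"effective E:       {r.E_eff_kPa:.4g} kPa",
            f"contact point:     {r.contact_z_um:.4g} um",
            f"baseline offset:   {r.baseline_offset:.4g} nN",
            f"baseline slope:    {r.baseline_slope:.4g} nN/um",
            f"residual SS:       {r.rss:.4g} nN^2",
            f"points in fit:     {r.n_points_fit}",
            f"converged:         {r.converged}",
            f"nu = {p.poisson_ratio}, theta = {p.edge_angle_deg} deg"
            f" ({p.angle_convention}-to-axis)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Force–separation data with the fitted Hertz curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fsc.separation, self.fsc.force, ".", ms=3, label="data")
        ax.plot(self.fsc.separation, self.fittedvalues(), "-",
                label=f"fit, E={self.result.E_eff_kPa:.3g} kPa")
        ax.set_xlabel("tip position (µm)")
        ax.set_ylabel("force (nN)")
        ax.legend()
        return ax
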