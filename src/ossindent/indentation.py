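"""Oliver–Pharr reduction of Berkovich force–depth curves.

The chain implemented here turns one raw indentation record into tissue-level
nanomechanical properties:

1. phase segmentation (loading / creep hold / unloading / drift hold),
2. thermal-drift estimation on the low-load hold and removal,
3. power-law fit of the unloading branch, ``P = B (h - h_f)^m``,
4. Oliver–Pharr contact mechanics: contact depth, projected area, reduced
   and specimen modulus, contact hardness,
5. elastic–plastic decomposition of the loading branch into a resistance to
   plastic deformation ``H``,
6. trapezoidal work integrals giving the total, elastic and plastic
   indentation energies.

All loads are mN, depths nm, moduli GPa, energies pJ (1 mN·nm = 1 pJ).

:class:`IndentationModel` wraps the chain in a statsmodels-style model
object whose :meth:`~IndentationModel.fit` returns an
:class:`IndentationResults` carrying the estimates and diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .curves import IndentationCurve, PHASES
from .protocols import (
    GPA_PER_MN_NM2,
    MN_NM2_PER_GPA,
    IndentationProtocol,
    IndenterSpec,
)

__all__ = [
    "PhaseError",
    "UnloadFit",
    "MechanicalProperties",
    "segment_curve",
    "correct_drift",
    "fit_unloading",
    "oliver_pharr",
    "decompose_loading",
    "indentation_energies",
    "aggregate_specimen",
    "IndentationModel",
    "IndentationResults",
]

#: resistance-to-plastic-deformation values above this cap are reported as
#: "no measurable plasticity" (infinite H)
H_CAP_GPA = 100.0


class PhaseError(ValueError):
    """A required protocol phase is missing or unusable."""


# ---------------------------------------------------------------------------
# segmentation


def segment_curve(
    curve: IndentationCurve,
    protocol: IndentationProtocol | None = None,
    rate_threshold_frac: float = 0.10,
) -> IndentationCurve:
    """Assign protocol-phase labels to a raw curve.

    Phases are detected from sign changes of the load rate, in the fixed
    order loading -> hold -> unloading -> drift hold.  The creep hold may be
    empty (zero-duration holds are tolerated); a missing loading or
    unloading ramp raises :class:`PhaseError`.
    """
    if len(curve) < 50:
        raise PhaseError("curve too short to segment (< 50 samples)")
    t, P = curve.time, curve.load
    rate = np.gradient(P, t)
    thr = rate_threshold_frac * np.max(np.abs(rate))
    if thr <= 0:
        raise PhaseError("load signal is constant; no phases to segment")

    n = len(curve)
    # phase boundaries from first rate-state changes, in protocol order
    not_rising = rate <= thr
    i = int(np.argmax(not_rising)) if not_rising.any() else n
    if i == 0:
        raise PhaseError("missing loading ramp")
    falling = rate < -thr
    j = int(np.argmax(falling[i:])) + i if falling[i:].any() else n
    if j >= n:
        raise PhaseError("missing unloading")
    not_falling = rate[j:] >= -thr
    k = int(np.argmax(not_falling)) + j if not_falling.any() else n
    # remainder must be quiescent (the drift hold) or absent
    if k < n and np.any(np.abs(rate[k:]) > thr):
        # tolerate edge samples around the corner
        bad = np.flatnonzero(np.abs(rate[k:]) > thr)
        if bad.size > 2:
            raise PhaseError("load activity after unloading; cannot segment")

    phase = np.empty(n, dtype=object)
    phase[:i] = "loading"
    phase[i:j] = "hold"
    phase[j:k] = "unloading"
    phase[k:] = "drift_hold"

    out = curve.replace(phase=phase)
    out.meta["phase_bounds"] = {"loading_end": i, "hold_end": j, "unloading_end": k}
    return out


def max_point(curve: IndentationCurve) -> tuple[float, float]:
    """(P_max, h_max) at the hold->unloading boundary.

    P_max is the (noise-free, commanded) hold load; h_max the depth at
    unloading onset.  The depth is taken as the median of the last few hold
    samples to suppress acquisition noise; creep over that window is
    negligible.
    """
    hold = curve.phase_mask("hold")
    if hold.any():
        P_max = float(np.median(curve.load[hold]))
        # average the last ~1 s of the hold: creep is negligible there and
        # the depth noise shrinks by sqrt(n)
        t_hold = curve.time[hold]
        tail = max(int((t_hold >= t_hold[-1] - 1.0).sum()), 1)
        h_max = float(np.mean(curve.depth[hold][-tail:]))
    else:
        unl = curve.phase_mask("unloading")
        first = np.flatnonzero(unl)[0]
        P_max = float(curve.load[first])
        h_max = float(curve.depth[first])
    return P_max, h_max


# ---------------------------------------------------------------------------
# drift correction


def correct_drift(
    curve: IndentationCurve,
    exclude_s: float = 20.0,
) -> IndentationCurve:
    """Estimate thermal drift on the low-load hold and remove it.

    Depth is regressed on time over the drift hold, excluding its first
    ``exclude_s`` seconds (the standard settling window), and the fitted
    rate times elapsed time is subtracted from every depth sample.  When the
    drift hold is absent or shorter than the exclusion window the curve is
    returned unchanged and a warning is recorded.
    """
    if not curve.is_segmented:
        raise ValueError("segment the curve before drift correction")
    mask = curve.phase_mask("drift_hold")
    out = curve.replace()
    if mask.sum() < 10:
        warnings.warn("drift hold absent or too short; no drift correction")
        out.meta["drift_rate_nm_per_s"] = None
        return out
    t_d = curve.time[mask]
    keep = t_d >= t_d[0] + exclude_s
    if keep.sum() < 10:
        warnings.warn(
            "drift hold shorter than the exclusion window; no drift correction"
        )
        out.meta["drift_rate_nm_per_s"] = None
        return out
    rate, _ = np.polyfit(t_d[keep], curve.depth[mask][keep], 1)
    out = curve.replace(depth=curve.depth - rate * (curve.time - curve.time[0]))
    out.meta["drift_rate_nm_per_s"] = float(rate)
    return out


# ---------------------------------------------------------------------------
# unloading fit


@dataclass(frozen=True)
class UnloadFit:
    """Power-law unloading parameters ``P = B (h - h_f)^m``.

    ``rms`` is the residual RMS in depth (nm): the load channel is
    commanded and essentially noise-free under displacement control, so
    the least-squares residuals are taken on the measured depth,
    ``h = h_f + (P/B)^(1/m)``, which keeps the estimates free of
    errors-in-variables attenuation.
    """

    B: float              # mN / nm^m
    h_f: float            # nm
    m: float
    fit_fraction: float
    rms: float            # residual RMS in nm (depth channel)
    P_max: float          # mN
    h_max: float          # nm

    @property
    def S(self) -> float:
        """Unloading stiffness dP/dh at h_max (mN/nm)."""
        return self.B * self.m * (self.h_max - self.h_f) ** (self.m - 1.0)


_M_BOUNDS = (1.0, 2.5)
_M_STARTS = (1.2, 1.5, 2.0)


def fit_unloading(
    curve: IndentationCurve,
    fit_fraction: float = 0.8,
) -> UnloadFit:
    """Nonlinear least-squares power-law fit of the unloading branch.

    The fit spans the top ``fit_fraction`` of the unloading load range,
    counted downward from P_max.  The power law is anchored at the measured
    peak (h_max, P_max) — known to sub-nm precision from the hold average —
    leaving (h_f, m) free, and residuals are taken on the depth channel
    (see :class:`UnloadFit`).  Three starts on the exponent
    (m in {1.2, 1.5, 2.0}) guard against local minima; the lowest residual
    RMS wins.  m is constrained to [1, 2.5] and a warning is issued when the
    solution sits at a bound.
    """
    if not 0.0 < fit_fraction <= 1.0:
        raise ValueError("fit_fraction must be in (0, 1]")
    mask = curve.phase_mask("unloading")
    if mask.sum() < 10:
        raise PhaseError("unloading phase has fewer than 10 samples")
    P_max, h_max = max_point(curve)
    P_u = curve.load[mask]
    h_u = curve.depth[mask]
    lo = P_max - fit_fraction * (P_max - P_u.min())
    sel = P_u >= lo
    if sel.sum() < 5:
        sel = np.ones_like(P_u, dtype=bool)
    P_fit, h_fit = P_u[sel], h_u[sel]

    def model_h(P, h_f, m):
        # depth as a function of (clean) load, anchored at the peak:
        # h = h_f + (h_max - h_f) (P / P_max)^(1/m)
        return h_f + (h_max - h_f) * np.power(P / P_max, 1.0 / m)

    # linear compliance over the top of the span seeds h_f
    top = P_fit >= P_max - 0.3 * (P_max - P_fit.min())
    if top.sum() >= 3:
        dh_dP = np.polyfit(P_fit[top], h_fit[top], 1)[0]
        S0 = 1.0 / dh_dP if dh_dP > 0 else np.nan
    else:
        S0 = np.nan
    if not np.isfinite(S0) or S0 <= 0:
        S0 = (P_fit.max() - P_fit.min()) / max(h_fit.max() - h_fit.min(), 1e-9)

    best = None
    for m0 in _M_STARTS:
        h_f0 = min(h_max - m0 * P_max / S0, h_max - 1e-6)
        try:
            popt, _ = curve_fit(
                model_h,
                P_fit,
                h_fit,
                p0=(h_f0, m0),
                bounds=([-np.inf, _M_BOUNDS[0]], [h_max - 1e-9, _M_BOUNDS[1]]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = h_fit - model_h(P_fit, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
        if best is None or rms < best[1]:
            best = (popt, rms)
    if best is None:
        raise RuntimeError(
            f"unloading fit failed to converge for site "
            f"{curve.specimen}/{curve.site}"
        )
    (h_f, m), rms = best
    B = float(P_max / (h_max - h_f) ** m)
    if m <= _M_BOUNDS[0] + 1e-6 or m >= _M_BOUNDS[1] - 1e-6:
        warnings.warn(
            f"unloading exponent m={m:.3f} at a bound for site "
            f"{curve.specimen}/{curve.site}"
        )
    return UnloadFit(
        B=float(B), h_f=float(h_f), m=float(m),
        fit_fraction=fit_fraction, rms=rms, P_max=P_max, h_max=h_max,
    )


# ---------------------------------------------------------------------------
# Oliver-Pharr contact mechanics


def oliver_pharr(
    fit: UnloadFit,
    indenter: IndenterSpec | None = None,
    nu_s: float = 0.3,
) -> tuple[float, float, float, float, float]:
    """Oliver–Pharr reduction of an unloading fit.

    Returns ``(E_r, E, h_c, A, Hc)`` with moduli and hardness in GPa, the
    contact depth in nm and the projected area in nm^2:

    * ``h_c = h_max - epsilon * P_max / S``
    * ``A = A(h_c)`` from the indenter area function
    * ``E_r = sqrt(pi) / (2 beta) * S / sqrt(A)``
    * ``1/E_r = (1 - nu_s^2)/E + (1 - nu_i^2)/E_i``
    * ``Hc = P_max / A``
    """
    indenter = indenter or IndenterSpec()
    S = fit.S
    if S <= 0:
        raise ValueError("non-positive unloading stiffness")
    h_c = fit.h_max - indenter.epsilon * fit.P_max / S
    if h_c <= 0:
        raise ValueError("contact depth collapse (h_c <= 0)")
    A = indenter.area(h_c)
    E_r = math.sqrt(math.pi) / (2.0 * indenter.beta) * S / math.sqrt(A)
    E_r *= GPA_PER_MN_NM2
    E = indenter.specimen_modulus(E_r, nu_s)
    Hc = fit.P_max / A * GPA_PER_MN_NM2
    return E_r, E, h_c, A, Hc


# ---------------------------------------------------------------------------
# loading-branch elastic/plastic decomposition


def decompose_loading(
    curve: IndentationCurve,
    E_r: float,
    indenter: IndenterSpec | None = None,
    alpha1: float | None = None,
    min_depth_frac: float = 0.2,
    h_cap: float = H_CAP_GPA,
) -> float:
    """Resistance to plastic deformation H (GPa) from the loading branch.

    The loading curve of an elastic–plastic conical contact is a parabola
    ``P = K h^2`` whose curvature combines a purely elastic coefficient
    ``C_e = (2/pi) E_r tan(psi)`` and a plastic one ``C_p`` in series:

        ``1/sqrt(K) = 1/sqrt(C_e) + 1/sqrt(C_p)``

    ``H = C_p / alpha1`` with ``alpha1`` the leading area coefficient
    (24.5 for an ideal Berkovich), so that H reduces to the mean pressure
    over the plastic component of deformation.

    Returns ``inf`` ("no measurable plasticity") when the loading branch is
    elastic to within tolerance, and raises when it is stiffer than the
    purely elastic limit by more than noise allows.
    """
    indenter = indenter or IndenterSpec()
    if alpha1 is None:
        alpha1 = indenter.C0
    mask = curve.phase_mask("loading")
    if mask.sum() < 10:
        raise PhaseError("loading phase has fewer than 10 samples")
    h = curve.depth[mask]
    P = curve.load[mask]
    sel = h >= min_depth_frac * h.max()
    h, P = h[sel], P[sel]
    # least squares for h = sqrt(P/K) with residuals on the (noisy) depth
    # channel: linear in a = 1/sqrt(K)
    a = float(np.sum(h * np.sqrt(P)) / np.sum(P))
    K = 1.0 / a**2
    C_e = (2.0 / math.pi) * (E_r * MN_NM2_PER_GPA) * indenter.tan_psi
    if K >= C_e * 1.02:
        raise ValueError(
            "non-physical decomposition: loading stiffer than the elastic limit"
        )
    inv_sqrt_cp = 1.0 / math.sqrt(K) - 1.0 / math.sqrt(C_e)
    if inv_sqrt_cp <= 0:
        return math.inf
    C_p = inv_sqrt_cp**-2
    H = C_p * GPA_PER_MN_NM2 / alpha1
    return math.inf if H > h_cap else H


# ---------------------------------------------------------------------------
# work of indentation


def indentation_energies(curve: IndentationCurve) -> tuple[float, float, float]:
    """(U_total, Ue, Up) in pJ by trapezoidal integration of P dh.

    U_total integrates over loading plus the creep hold (depth keeps growing
    at constant load, so the hold does work); Ue is the magnitude of the
    area under the unloading branch; Up = U_total - Ue.
    """
    if not curve.is_segmented:
        raise ValueError("segment the curve before integrating energies")
    lm = curve.phase_mask("loading") | curve.phase_mask("hold")
    um = curve.phase_mask("unloading")
    h_l, P_l = curve.depth[lm], curve.load[lm]
    # the unloading path starts at the peak: include the last sample before
    # the unloading phase so the integral covers the full branch
    idx_u = np.flatnonzero(um)
    if idx_u.size and idx_u[0] > 0:
        idx_u = np.concatenate([[idx_u[0] - 1], idx_u])
    h_u, P_u = curve.depth[idx_u], curve.load[idx_u]
    for h_phase, name in ((h_l, "loading+hold"), (h_u, "unloading")):
        d = np.diff(h_phase)
        # tolerate sample-to-sample reversals at the acquisition-noise scale;
        # warn only on gross anomalies
        noise = float(np.median(np.abs(d)))
        tol = max(0.05 * (abs(h_phase[-1] - h_phase[0]) + 1e-12), 8.0 * noise)
        if name == "unloading":
            bad = d > tol
        else:
            bad = d < -tol
        if np.any(bad):
            warnings.warn(
                f"non-monotone depth within {name}; integrating in time order"
            )
            break
    U_total = float(np.trapezoid(P_l, h_l))
    Ue = float(-np.trapezoid(P_u, h_u))
    Up = U_total - Ue
    return U_total, Ue, Up


# ---------------------------------------------------------------------------
# per-site result container and specimen aggregation


@dataclass
class MechanicalProperties:
    """Reduced nanomechanical properties of a single indentation site."""

    E: float          # specimen elastic modulus, GPa
    Hc: float         # contact hardness, GPa
    H: float          # resistance to plastic deformation, GPa (inf = elastic)
    Ue: float         # elastic indentation energy, pJ
    Up: float         # plastic indentation energy, pJ
    S: float          # unloading stiffness, mN/nm
    h_c: float        # contact depth, nm
    P_max: float      # mN
    h_max: float      # nm
    E_r: float        # reduced modulus, GPa
    U_total: float = math.nan
    specimen: str = ""
    compartment: str = ""
    trabecula: str = ""
    site: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


PROPERTY_COLUMNS = ("E", "Hc", "H", "Ue", "Up")


def aggregate_specimen(
    site_properties,
    compartment: str,
    columns=PROPERTY_COLUMNS,
) -> dict:
    """Specimen-level summary of site properties.

    Cortical: plain mean and SD over valid sites.  Cancellous: each
    trabecula's sites are averaged first, then the mean and SD are taken
    across trabecula means, so unbalanced trabeculae still contribute one
    value each.  Sites whose reduction failed (NaN) are excluded and
    counted.
    """
    if isinstance(site_properties, pd.DataFrame):
        df = site_properties.copy()
    else:
        df = pd.DataFrame([p.to_dict() for p in site_properties])
    if df.empty:
        return {"n_valid": 0, "n_failed": 0, "missing": True}
    out: dict = {"missing": False}
    valid = df[columns[0]].notna()
    out["n_valid"] = int(valid.sum())
    out["n_failed"] = int((~valid).sum())
    if out["n_valid"] == 0:
        out["missing"] = True
        return out
    dfv = df[valid]
    for col in columns:
        x = pd.to_numeric(dfv[col], errors="coerce")
        x = x.replace([np.inf, -np.inf], np.nan)
        if compartment == "cancellous":
            if "trabecula" not in dfv.columns:
                raise ValueError("cancellous aggregation needs a trabecula column")
            means = x.groupby(dfv["trabecula"]).mean()
            out[f"{col}_mean"] = float(means.mean())
            out[f"{col}_sd"] = float(means.std(ddof=1)) if len(means) > 1 else 0.0
        else:
            out[f"{col}_mean"] = float(x.mean())
            out[f"{col}_sd"] = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    return out


# ---------------------------------------------------------------------------
# model / results facade


class IndentationModel:
    """Oliver–Pharr reduction model for one indentation site.

    Parameters
    ----------
    curve
        Raw or pre-segmented :class:`~ossindent.curves.IndentationCurve`.
    protocol, indenter
        Protocol and tip descriptions; defaults describe the bone protocol
        (500 nm, 0.25 mN/s, 60 s hold, 100 s drift hold at 10% P_max) and
        an ideal Berkovich diamond.
    nu_s
        Specimen Poisson ratio (0.3 for bone tissue by default).

    Examples
    --------
    >>> res = IndentationModel(curve).fit()
    >>> res.properties.E
    """

    def __init__(
        self,
        curve: IndentationCurve,
        protocol: IndentationProtocol | None = None,
        indenter: IndenterSpec | None = None,
        nu_s: float = 0.3,
    ):
        self.curve = curve
        self.protocol = protocol or IndentationProtocol()
        self.indenter = indenter or IndenterSpec()
        if not -1.0 < nu_s < 0.5:
            raise ValueError("nu_s outside the physically meaningful range")
        self.nu_s = nu_s

    def fit(
        self,
        fit_fraction: float = 0.8,
        drift_correction: bool = True,
        drift_exclude_s: float = 20.0,
    ) -> "IndentationResults":
        notes: list[str] = []
        curve = self.curve
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            if not curve.is_segmented:
                curve = segment_curve(curve, self.protocol)
            if drift_correction:
                curve = correct_drift(curve, exclude_s=drift_exclude_s)
            ufit = fit_unloading(curve, fit_fraction=fit_fraction)
            E_r, E, h_c, A, Hc = oliver_pharr(ufit, self.indenter, self.nu_s)
            H = decompose_loading(curve, E_r, self.indenter)
            U_total, Ue, Up = indentation_energies(curve)
        notes.extend(str(w.message) for w in wrec)
        if math.isinf(H):
            notes.append("no measurable plasticity (elastic loading)")
        props = MechanicalProperties(
            E=E, Hc=Hc, H=H, Ue=Ue, Up=Up, S=ufit.S, h_c=h_c,
            P_max=ufit.P_max, h_max=ufit.h_max, E_r=E_r, U_total=U_total,
            specimen=curve.specimen, compartment=curve.compartment,
            trabecula=str(curve.meta.get("trabecula", "")), site=curve.site,
        )
        return IndentationResults(
            model=self, curve=curve, properties=props, unload_fit=ufit,
            contact_area=A,
            drift_rate=curve.meta.get("drift_rate_nm_per_s"),
            warnings=notes,
        )


@dataclass
class IndentationResults:
    """Fitted per-site reduction: estimates, diagnostics, summary table."""

    model: IndentationModel
    curve: IndentationCurve
    properties: MechanicalProperties
    unload_fit: UnloadFit
    contact_area: float
    drift_rate: float | None
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        p = self.properties
        f = self.unload_fit
        lines = [
            "Oliver-Pharr indentation reduction",
            "==================================",
            f"site: {p.specimen or '-'} / {p.compartment or '-'} / {p.site or '-'}",
            f"P_max  {p.P_max:10.4f} mN    h_max {p.h_max:9.2f} nm",
            f"S      {p.S:10.6f} mN/nm h_c   {p.h_c:9.2f} nm",
            f"unload fit: B={f.B:.4g} mN/nm^m, h_f={f.h_f:.2f} nm, "
            f"m={f.m:.3f}, rms={f.rms:.2g} nm",
            f"E_r    {p.E_r:10.3f} GPa   E     {p.E:9.3f} GPa",
            f"Hc     {p.Hc:10.4f} GPa   H     "
            + (f"{p.H:9.4f} GPa" if math.isfinite(p.H) else "   elastic"),
            f"U_tot  {p.U_total:10.2f} pJ    Ue    {p.Ue:9.2f} pJ    "
            f"Up {p.Up:9.2f} pJ",
        ]
        if self.drift_rate is not None:
            lines.append(f"drift  {self.drift_rate:10.4f} nm/s (removed)")
        if self.warnings:
            lines.append("notes: " + "; ".join(self.warnings))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Force–depth diagnostic plot (phases, unloading fit, properties)."""
        from .plotting import plot_indentation

        return plot_indentation(self, ax=ax)
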