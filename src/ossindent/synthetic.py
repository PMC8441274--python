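"""Seeded synthetic biopsy-cohort generator.

Emulates the three inputs of the nested case-control pipeline so every
downstream stage is testable without patient data:

* **indentation curves** from an elastic–plastic conical contact forward
  model (series spring: ``h(P) = sqrt(P/C_e) + sqrt(P/C_p)``) with
  logarithmic creep during the load hold, linear thermal drift and
  additive Gaussian depth noise;
* **cohort tables** of subjects with AFF/non-AFF labels, treatment
  durations, and site-level nanomechanical properties following a
  subject-random-intercept model with configurable intraclass correlation;
  the AFF label may be linked to subject-mean cortical elastic modulus
  through a logistic model with a prescribed odds ratio per GPa;
* **histomorphometry primitives** (surface lengths, tetracycline label
  lengths, interlabel distances, thickness readings) whose derived indices
  match the published group summary statistics, including single-label-only
  and label-free envelopes to exercise the imputation rules.

All draws come from one :class:`numpy.random.Generator` per call, seeded
explicitly; the seed is recorded in every sidecar metadata file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .curves import IndentationCurve
from .histomorphometry import (
    ENVELOPES,
    EnvelopePrimitives,
    StructuralPrimitives,
)
from .protocols import MN_NM2_PER_GPA, IndentationProtocol, IndenterSpec

__all__ = [
    "MaterialTruth",
    "CohortSpec",
    "generate_curve",
    "generate_cohort",
    "generate_envelope_primitives",
    "generate_structural_primitives",
    "curves_for_sites",
    "write_curves",
    "write_table",
]

#: creep time constant of the logarithmic hold-phase creep model, s
CREEP_TAU_S = 10.0

#: unloading exponent approached in the fully plastic limit
M_PLASTIC = 1.35


@dataclass(frozen=True)
class MaterialTruth:
    """Generating truth for one indentation site.

    ``H_true`` may be ``inf`` for a purely elastic site, in which case the
    unloading branch retraces the elastic loading parabola exactly.
    """

    E_s: float                # specimen elastic modulus, GPa
    H_true: float             # resistance to plastic deformation, GPa
    nu_s: float = 0.3
    creep_amp: float = 5.0    # nm, hold-phase creep amplitude
    drift_rate: float = 0.05  # nm/s thermal drift
    noise_sd: float = 2.0     # nm additive depth noise

    def __post_init__(self) -> None:
        if self.E_s <= 0:
            raise ValueError("E_s must be positive")
        if self.H_true <= 0:
            raise ValueError("H_true must be positive")
        if not 0.0 <= self.nu_s < 0.5:
            raise ValueError("nu_s must be in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _contact_coefficients(
    truth: MaterialTruth, indenter: IndenterSpec
) -> tuple[float, float, float]:
    """(C_e, C_p, E_r_mN) in instrument units (mN/nm^2; E_r in mN/nm^2)."""
    er = indenter.reduced_modulus(truth.E_s, truth.nu_s) * MN_NM2_PER_GPA
    C_e = (2.0 / math.pi) * er * indenter.tan_psi
    if math.isinf(truth.H_true):
        C_p = math.inf
    else:
        C_p = truth.H_true * MN_NM2_PER_GPA * indenter.C0
    if C_p <= 0 or C_e <= 0:
        raise ValueError("non-physical truth: contact coefficients must be positive")
    return C_e, C_p, er


def _op_consistent_stiffness(
    er_mn: float, h_max: float, P_max: float, indenter: IndenterSpec
) -> float:
    """Unloading stiffness consistent with the Oliver–Pharr fixed point.

    Solves S = 2 beta E_r sqrt(C0/pi) * (h_max - eps P_max / S) in closed
    form (the larger quadratic root), so the reduction recovers E_r exactly
    on noise-free curves.
    """
    a = 2.0 * indenter.beta * er_mn * math.sqrt(indenter.C0 / math.pi)
    disc = (a * h_max) ** 2 - 4.0 * a * indenter.epsilon * P_max
    if disc <= 0:
        raise ValueError("no consistent unloading stiffness for this geometry")
    return 0.5 * (a * h_max + math.sqrt(disc))


def generate_curve(
    truth: MaterialTruth,
    protocol: IndentationProtocol | None = None,
    seed: int | np.random.Generator = 0,
    indenter: IndenterSpec | None = None,
    specimen: str = "",
    compartment: str = "",
    site: str = "",
) -> IndentationCurve:
    """Simulate one four-phase force–depth record.

    Phases: load at constant rate to the target depth, 60 s creep hold at
    P_max, unload at the same rate to the drift-hold load, 100 s drift
    hold.  Loading follows the elastic–plastic series model; the unloading
    power law is anchored so its tangent at maximum depth equals the
    elastic stiffness implied by the specimen modulus and the contact area
    at maximum load.  Depth carries linear drift and Gaussian noise; the
    commanded load is noise-free.
    """
    protocol = protocol or IndentationProtocol()
    indenter = indenter or IndenterSpec()
    rng = _rng(seed)

    C_e, C_p, er_mn = _contact_coefficients(truth, indenter)
    inv_root = 1.0 / math.sqrt(C_e) + (
        0.0 if math.isinf(C_p) else 1.0 / math.sqrt(C_p)
    )
    P_max = (protocol.target_depth / inv_root) ** 2
    rate = protocol.loading_rate
    frac = protocol.drift_hold_fraction

    t1 = P_max / rate                                  # loading end
    t2 = t1 + protocol.hold_s                          # hold end
    t3 = t2 + (1.0 - frac) * P_max / rate              # unloading end
    t4 = t3 + protocol.drift_hold_s
    dt = 1.0 / protocol.sample_hz
    t = np.arange(0.0, t4 + 0.5 * dt, dt)

    load = np.empty_like(t)
    depth = np.empty_like(t)

    in_load = t < t1
    in_hold = (t >= t1) & (t < t2)
    in_unl = (t >= t2) & (t < t3)
    in_drift = t >= t3

    load[in_load] = rate * t[in_load]
    depth[in_load] = np.sqrt(load[in_load]) * inv_root

    h_load_end = protocol.target_depth
    load[in_hold] = P_max
    depth[in_hold] = h_load_end + truth.creep_amp * np.log1p(
        (t[in_hold] - t1) / CREEP_TAU_S
    )
    h_max = h_load_end + truth.creep_amp * math.log1p(protocol.hold_s / CREEP_TAU_S)

    load[in_unl] = P_max - rate * (t[in_unl] - t2)
    if math.isinf(C_p):
        # purely elastic: unloading retraces the loading parabola
        unload_pars = {"elastic": True}
        depth[in_unl] = np.sqrt(load[in_unl] / C_e)
        h_unl_end = math.sqrt(frac * P_max / C_e)
    else:
        S = _op_consistent_stiffness(er_mn, h_max, P_max, indenter)
        f_p = (1.0 / math.sqrt(C_p)) / inv_root
        m = 2.0 - (2.0 - M_PLASTIC) * f_p
        h_f = h_max - m * P_max / S
        if h_f < 0.0:
            h_f = 0.0
            m = min(S * h_max / P_max, 2.5)
        B = P_max / (h_max - h_f) ** m
        unload_pars = {"elastic": False, "B": B, "h_f": h_f, "m": m, "S": S}
        depth[in_unl] = h_f + (load[in_unl] / B) ** (1.0 / m)
        h_unl_end = h_f + (frac * P_max / B) ** (1.0 / m)

    load[in_drift] = frac * P_max
    depth[in_drift] = h_unl_end

    depth = depth + truth.drift_rate * t
    if truth.noise_sd > 0:
        depth = depth + rng.normal(0.0, truth.noise_sd, size=depth.size)

    bounds = {
        "loading_end": int(in_load.sum()),
        "hold_end": int(in_load.sum() + in_hold.sum()),
        "unloading_end": int(in_load.sum() + in_hold.sum() + in_unl.sum()),
    }
    meta = {
        "truth": asdict(truth),
        "true_boundaries": bounds,
        "P_max_true": P_max,
        "h_max_true": h_max,
        "unload_pars": unload_pars,
    }
    return IndentationCurve(
        t, load, depth, specimen=specimen, compartment=compartment,
        site=site, meta=meta,
    )


# ---------------------------------------------------------------------------
# cohort generation

#: published per-envelope group summaries (mean, SD) for (non-AFF, AFF),
#: n = 16 per arm; used as the generating targets for primitives
TABLE2_TARGETS: dict[str, dict[str, tuple[tuple[float, float], tuple[float, float]]]] = {
    "cancellous": {
        "W_Th": ((33.6, 3.69), (29.8, 4.61)),
        "ES_BS": ((2.10, 1.80), (3.62, 3.22)),
        "OcS_BS": ((0.298, 0.328), (0.979, 1.21)),
        "OS_BS": ((1.96, 2.42), (5.21, 7.70)),
        "O_Th": ((8.08, 5.00), (7.40, 3.18)),
        "ObS_BS": ((0.357, 0.697), (1.05, 1.63)),
        "MAR": ((0.323, 0.148), (0.359, 0.179)),
        "BFR_BS": ((1.51, 2.35), (2.01, 2.81)),
    },
    "intracortical": {
        "W_Th": ((42.6, 4.66), (36.1, 4.22)),
        "ES_BS": ((2.26, 2.78), (3.57, 1.97)),
        "OcS_BS": ((0.288, 0.479), (0.567, 0.342)),
        "OS_BS": ((5.10, 3.98), (8.09, 6.35)),
        "O_Th": ((6.51, 2.34), (7.40, 3.32)),
        "ObS_BS": ((0.867, 1.16), (1.77, 2.22)),
        "MAR": ((0.331, 0.216), (0.356, 0.139)),
        "BFR_BS": ((5.02, 5.36), (5.10, 6.23)),
    },
    "endosteal": {
        "W_Th": ((37.2, 4.36), (33.3, 5.50)),
        "ES_BS": ((3.44, 3.70), (7.44, 8.66)),
        "OcS_BS": ((0.604, 0.932), (2.19, 2.72)),
        "OS_BS": ((5.18, 4.39), (7.75, 7.20)),
        "O_Th": ((5.38, 3.40), (5.87, 2.95)),
        "ObS_BS": ((0.803, 0.733), (2.41, 3.35)),
        "MAR": ((0.311, 0.263), (0.268, 0.129)),
        "BFR_BS": ((2.63, 3.58), (3.36, 5.43)),
    },
}

#: structural targets (mean, SD) for (non-AFF, AFF)
STRUCTURAL_TARGETS = {
    "BV_TV": ((15.2, 5.10), (14.1, 5.47)),      # %
    "Tb_Th": ((107.0, 24.5), (103.0, 25.9)),    # μm
    "Ct_Th": ((0.987, 0.278), (1.02, 0.302)),   # mm
}

#: nanomechanical generating targets per (compartment, property):
#: (non-AFF mean, AFF mean, between-subject SD).  Cortical means follow the
#: published representative curves; cancellous moduli are equal across
#: groups (no group difference was found there) and SDs are typical
#: between-subject spreads for human bone tissue.
MECH_TARGETS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("cortical", "E"): (16.2, 18.6, 2.0),
    ("cortical", "H"): (1.178, 1.63, 0.25),
    ("cortical", "Hc"): (0.77, 0.56, 0.12),
    ("cancellous", "E"): (16.2, 16.2, 2.0),
    ("cancellous", "H"): (2.0, 2.0, 0.3),
    ("cancellous", "Hc"): (0.8, 0.8, 0.12),
}

GROUPS = ("nonAFF", "AFF")


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters of a synthetic nested case-control cohort.

    Defaults mirror the published study: 16 subjects per arm, treatment
    durations 7.4 ± 4.8 y (non-AFF) vs 11.6 ± 4.9 y (AFF), 60 cortical
    indentation sites and 5 trabeculae × 12 sites per subject.

    Two label-generation modes:

    * ``or_per_gpa=None`` (default, observational): exactly n_per_group
      subjects per arm, every property drawn from its group-specific
      normal — this emulates the published group contrasts.
    * ``or_per_gpa`` numeric (mechanistic): subject-mean cortical elastic
      modulus is drawn from one pooled normal and the AFF label from a
      logistic model with slope ``log(or_per_gpa)`` per GPa (group sizes
      then vary around n_per_group); ``or_per_gpa=1`` makes the label an
      independent fair coin, the exact null.
    """

    n_per_group: int = 16
    duration_mean: tuple[float, float] = (7.4, 11.6)   # (nonAFF, AFF) years
    duration_sd: tuple[float, float] = (4.8, 4.9)
    mech_targets: dict = field(default_factory=lambda: dict(MECH_TARGETS))
    or_per_gpa: float | None = None
    icc: float = 0.5
    n_cortical_sites: int = 60
    n_trabeculae: int = 5
    sites_per_trabecula: int = 12
    fraction_no_label: float = 0.30
    fraction_single_label: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must be in [0, 1)")
        if self.or_per_gpa is not None and self.or_per_gpa <= 0:
            raise ValueError("or_per_gpa must be positive")
        if any(sd < 0 for sd in self.duration_sd):
            raise ValueError("duration SDs must be non-negative")
        for frac in (self.fraction_no_label, self.fraction_single_label):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("label-state fractions must be in [0, 1]")
        if self.fraction_no_label + self.fraction_single_label > 1.0:
            raise ValueError("label-state fractions must sum to <= 1")


def _within_sd(between_sd: float, icc: float) -> float:
    if icc <= 0:
        return between_sd
    return between_sd * math.sqrt((1.0 - icc) / icc)


def generate_cohort(
    spec: CohortSpec,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (cohort table, site-level property table).

    The site table has one row per indentation site (60 cortical plus
    5 × 12 cancellous per subject) with property values from a subject
    random-intercept model: the between-subject SD equals the published
    group SD and the within-subject SD follows from ``spec.icc``.  The
    cohort table carries the subject-level aggregates (cortical site mean;
    cancellous mean of per-trabecula means) together with group label and
    treatment duration.
    """
    rng = _rng(spec.seed if seed is None else seed)
    n = 2 * spec.n_per_group
    subjects = [f"S{i + 1:03d}" for i in range(n)]

    mu_e0, mu_e1, sd_e = spec.mech_targets[("cortical", "E")]
    if spec.or_per_gpa is not None:
        mu_pool = 0.5 * (mu_e0 + mu_e1)
        e_cort = rng.normal(mu_pool, sd_e, size=n)
        beta = math.log(spec.or_per_gpa)
        p_aff = 1.0 / (1.0 + np.exp(-beta * (e_cort - mu_pool)))
        is_aff = rng.random(n) < p_aff
        if is_aff.all() or not is_aff.any():
            # pathological draw; force one subject into the empty class
            is_aff[0] = not is_aff[0]
    else:
        is_aff = np.arange(n) >= spec.n_per_group
        e_cort = np.where(
            is_aff, rng.normal(mu_e1, sd_e, n), rng.normal(mu_e0, sd_e, n)
        )
    group = np.where(is_aff, "AFF", "nonAFF")
    gi = is_aff.astype(int)
    duration = np.clip(
        rng.normal(
            np.asarray(spec.duration_mean)[gi], np.asarray(spec.duration_sd)[gi]
        ),
        0.1,
        None,
    )

    # subject-level means for every (compartment, property)
    subj_means: dict[tuple[str, str], np.ndarray] = {}
    for (comp, prop), (m0, m1, sd) in spec.mech_targets.items():
        if (comp, prop) == ("cortical", "E"):
            subj_means[(comp, prop)] = e_cort
        else:
            subj_means[(comp, prop)] = rng.normal(np.where(is_aff, m1, m0), sd)

    comp_layout = {
        "cortical": (
            spec.n_cortical_sites,
            np.array([""] * spec.n_cortical_sites, dtype=object),
        ),
        "cancellous": (
            spec.n_trabeculae * spec.sites_per_trabecula,
            np.repeat(
                np.array(
                    [f"T{tr + 1}" for tr in range(spec.n_trabeculae)], dtype=object
                ),
                spec.sites_per_trabecula,
            ),
        ),
    }
    frames = []
    agg: dict[str, np.ndarray] = {}
    for comp, (ns, trab) in comp_layout.items():
        block = {
            "subject": np.repeat(subjects, ns),
            "group": np.repeat(group, ns),
            "duration": np.repeat(duration, ns),
            "compartment": comp,
            "trabecula": np.tile(trab, n),
            "site": np.tile(
                np.array([f"{comp[:4]}{k + 1:03d}" for k in range(ns)], dtype=object),
                n,
            ),
        }
        for prop in ("E", "H", "Hc"):
            key = (comp, prop)
            if key not in spec.mech_targets:
                continue
            sd_b = spec.mech_targets[key][2]
            sw = _within_sd(sd_b, spec.icc)
            means = subj_means[key]
            if spec.icc <= 0:
                m0, m1 = spec.mech_targets[key][:2]
                means = np.where(is_aff, m1, m0)
            draws = np.clip(
                rng.normal(means[:, None], sw, size=(n, ns)), 1e-3, None
            )
            block[prop] = draws.ravel()
            # subject aggregate: cortical site mean; cancellous mean of
            # per-trabecula means
            if comp == "cancellous":
                per_trab = draws.reshape(n, spec.n_trabeculae, spec.sites_per_trabecula)
                agg[f"{prop}_{comp}"] = per_trab.mean(axis=2).mean(axis=1)
            else:
                agg[f"{prop}_{comp}"] = draws.mean(axis=1)
        frames.append(pd.DataFrame(block))
    site_df = pd.concat(frames, ignore_index=True)

    cohort_df = pd.DataFrame(
        {"subject": subjects, "group": group, "duration": duration, **agg}
    )
    return cohort_df, site_df


# ---------------------------------------------------------------------------
# histomorphometry primitive generation

_BS_MM = {"cancellous": (25.0, 5.0), "intracortical": (15.0, 3.0), "endosteal": (8.0, 2.0)}


def _default_groups(spec: CohortSpec) -> np.ndarray:
    return np.array(
        ["nonAFF"] * spec.n_per_group + ["AFF"] * spec.n_per_group, dtype=object
    )


def generate_envelope_primitives(
    spec: CohortSpec,
    envelope: str,
    seed: int | np.random.Generator = 0,
    groups: Sequence[str] | None = None,
    subjects: Sequence[str] | None = None,
) -> list[EnvelopePrimitives]:
    """Per-subject primitive measurements for one bone envelope.

    Surface lengths, label lengths and reading lists are drawn so the
    derived indices land on the published group targets.  A fraction of
    subjects (``spec.fraction_no_label`` / ``spec.fraction_single_label``)
    is generated without any tetracycline label or with single labels only,
    exercising the MAR imputation rules downstream.
    """
    if envelope not in ENVELOPES:
        raise ValueError(f"unknown envelope {envelope!r}")
    rng = _rng(seed)
    targets = TABLE2_TARGETS[envelope]
    groups = np.asarray(groups if groups is not None else _default_groups(spec))
    if subjects is None:
        subjects = [f"S{i + 1:03d}" for i in range(len(groups))]

    def draw(var: str, gi: int, lo: float, hi: float) -> float:
        mean, sd = targets[var][gi]
        return float(np.clip(rng.normal(mean, sd), lo, hi))

    prims = []
    for subj, grp in zip(subjects, groups):
        gi = int(grp == "AFF")
        bs_mean, bs_sd = _BS_MM[envelope]
        BS = float(np.clip(rng.normal(bs_mean, bs_sd), 2.0, None))
        es = draw("ES_BS", gi, 0.0, 60.0)
        os_ = draw("OS_BS", gi, 0.0, 60.0)
        obs = draw("ObS_BS", gi, 0.0, 60.0)
        ocs = draw("OcS_BS", gi, 0.0, 60.0)
        o_th = draw("O_Th", gi, 1.0, 50.0)
        w_th = draw("W_Th", gi, 5.0, 80.0)
        mar = draw("MAR", gi, 0.05, 3.0)
        bfr = draw("BFR_BS", gi, 0.05, 50.0)

        u = rng.random()
        ms_frac = min(bfr / (mar * 365.0), 0.5)       # MS/BS as a fraction
        if u < spec.fraction_no_label:
            dLS = sLS = 0.0
            dists: list[float] = []
        elif u < spec.fraction_no_label + spec.fraction_single_label:
            dLS = 0.0
            sLS = min(2.0 * ms_frac * BS, 0.9 * BS)
            dists = []
        else:
            dLS = ms_frac * BS / 1.2
            sLS = 0.4 * dLS
            dists = list(
                np.clip(
                    rng.normal(mar * 14.0, 0.3, size=10), 0.5, None
                )
            )
        prims.append(
            EnvelopePrimitives(
                envelope=envelope,
                BS=BS,
                OS=min(os_ / 100.0 * BS, BS),
                ES=min(es / 100.0 * BS, BS),
                ObS=min(obs / 100.0 * BS, BS),
                OcS=min(ocs / 100.0 * BS, BS),
                o_th_readings=list(np.clip(rng.normal(o_th, 1.0, 4), 0.5, None)),
                w_th_readings=list(np.clip(rng.normal(w_th, 2.0, 8), 2.0, None)),
                dLS=dLS,
                sLS=sLS,
                interlabel_dists=dists,
                subject=str(subj),
                group=str(grp),
            )
        )
    return prims


def generate_structural_primitives(
    spec: CohortSpec,
    seed: int | np.random.Generator = 0,
    groups: Sequence[str] | None = None,
    subjects: Sequence[str] | None = None,
) -> list[StructuralPrimitives]:
    """Per-subject section-level structural measurements.

    Areas and perimeter are back-solved from the BV/TV and Tb.Th targets on
    a nominal 2 mm^2 tissue field; cortical-thickness readings scatter
    around the group Ct.Th target.
    """
    rng = _rng(seed)
    groups = np.asarray(groups if groups is not None else _default_groups(spec))
    if subjects is None:
        subjects = [f"S{i + 1:03d}" for i in range(len(groups))]
    prims = []
    for subj, grp in zip(subjects, groups):
        gi = int(grp == "AFF")
        bvtv = float(
            np.clip(rng.normal(*STRUCTURAL_TARGETS["BV_TV"][gi]), 2.0, 60.0)
        )
        tbth = float(
            np.clip(rng.normal(*STRUCTURAL_TARGETS["Tb_Th"][gi]), 30.0, 300.0)
        )
        ctth = float(
            np.clip(rng.normal(*STRUCTURAL_TARGETS["Ct_Th"][gi]), 0.2, 3.0)
        )
        tissue = float(np.clip(rng.normal(2.0, 0.3), 0.5, None))
        bone = bvtv / 100.0 * tissue
        perim = 2000.0 * bone / tbth
        prims.append(
            StructuralPrimitives(
                bone_area=bone,
                tissue_area=tissue,
                bone_perimeter=perim,
                ct_th_readings=list(np.clip(rng.normal(ctth, 0.05, 4), 0.05, None)),
                subject=str(subj),
                group=str(grp),
            )
        )
    return prims


# ---------------------------------------------------------------------------
# curve batches for a whole cohort


def curves_for_sites(
    site_df: pd.DataFrame,
    protocol: IndentationProtocol | None = None,
    indenter: IndenterSpec | None = None,
    nu_s: float = 0.3,
    creep_amp: float = 5.0,
    drift_rate: float = 0.05,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> Iterable[IndentationCurve]:
    """Yield one simulated curve per row of a site property table.

    Each site's E and H become the generating truth of its curve; child
    seeds are spawned deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(site_df))
    for child, (_, row) in zip(children, site_df.iterrows()):
        truth = MaterialTruth(
            E_s=float(row["E"]),
            H_true=float(row["H"]),
            nu_s=nu_s,
            creep_amp=creep_amp,
            drift_rate=drift_rate,
            noise_sd=noise_sd,
        )
        curve = generate_curve(
            truth,
            protocol=protocol,
            seed=np.random.default_rng(child),
            indenter=indenter,
            specimen=str(row["subject"]),
            compartment=str(row["compartment"]),
            site=str(row["site"]),
        )
        curve.meta["trabecula"] = str(row.get("trabecula", ""))
        yield curve


# ---------------------------------------------------------------------------
# writers (delimited text plus sidecar metadata)


def _sidecar(path: Path, seed, spec) -> None:
    meta = {
        "generator": "ossindent.synthetic",
        "version": _pkg_version,
        "seed": int(seed) if np.isscalar(seed) else str(seed),
        "spec": asdict(spec) if hasattr(spec, "__dataclass_fields__") else spec,
    }
    if isinstance(meta["spec"], dict):
        meta["spec"] = {
            (k if isinstance(k, str) else "/".join(map(str, k))): v
            for k, v in meta["spec"].items()
        }
        mt = meta["spec"].get("mech_targets")
        if isinstance(mt, dict):
            meta["spec"]["mech_targets"] = {
                "/".join(k): list(v) for k, v in mt.items()
            }
    path.write_text(yaml.safe_dump(meta, sort_keys=False))


def write_curves(
    curves: Iterable[IndentationCurve],
    outdir: str | Path,
    seed: int = 0,
    spec=None,
) -> pd.DataFrame:
    """Write per-site curve CSVs plus a manifest table and metadata sidecar.

    Returns the manifest (columns: specimen, compartment, trabecula, site,
    file).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, c in enumerate(curves):
        fname = f"curve_{c.specimen or 'X'}_{c.compartment or 'na'}_{c.site or i}.csv"
        c.to_csv(outdir / fname)
        rows.append(
            {
                "specimen": c.specimen,
                "compartment": c.compartment,
                "trabecula": str(c.meta.get("trabecula", "")),
                "site": c.site,
                "file": fname,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    _sidecar(outdir / "metadata.yaml", seed, spec or {})
    return manifest


def write_table(df: pd.DataFrame, path: str | Path, seed: int = 0, spec=None) -> None:
    """Write a delimited table with a sidecar metadata file alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    _sidecar(path.with_suffix(".meta.yaml"), seed, spec or {})
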