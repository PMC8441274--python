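"""ASBMR bone-histomorphometry indices on three bone envelopes.

Derives structural (BV/TV, Tb.Th, Tb.N, Ct.Th), static (ES/BS, OS/BS,
Ob.S/BS, Oc.S/BS, O.Th, W.Th) and tetracycline-based dynamic indices
(MS/BS, MAR, BFR/BS, Ac.f) from primitive measurements taken on transiliac
biopsy sections.

Dynamic-index imputation follows the severely-suppressed-turnover
convention: envelopes showing only a single tetracycline label are assigned
the minimum detectable MAR of 0.3 μm/day; envelopes with no label at all
get a missing MAR while MS/BS, BFR/BS and Ac.f are set to exactly zero.
A missing MAR is kept distinct from a true zero in every serialization
(empty field, never 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ENVELOPES = ("cancellous", "intracortical", "endosteal")

#: tetracycline administration interval used in the protocol, days
DEFAULT_LABEL_INTERVAL_D = 14.0

#: minimum detectable mineral apposition rate, μm/day, assigned to
#: single-label-only surfaces
MAR_FLOOR = 0.3


@dataclass
class EnvelopePrimitives:
    """Primitive measurements for one bone envelope of one subject.

    Lengths in mm, thickness readings and interlabel distances in μm.
    """

    envelope: str
    BS: float                      # total bone surface length, mm
    OS: float = 0.0                # osteoid surface, mm
    ES: float = 0.0                # eroded surface, mm
    ObS: float = 0.0               # osteoblast-covered surface, mm
    OcS: float = 0.0               # osteoclast-covered surface, mm
    o_th_readings: Sequence[float] = field(default_factory=list)   # μm
    w_th_readings: Sequence[float] = field(default_factory=list)   # μm
    dLS: float = 0.0               # double-label length, mm
    sLS: float = 0.0               # single-label length, mm
    interlabel_dists: Sequence[float] = field(default_factory=list)  # μm
    label_interval: float = DEFAULT_LABEL_INTERVAL_D               # days
    subject: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.envelope not in ENVELOPES:
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if self.BS <= 0:
            raise ValueError("BS must be positive")
        for name in ("OS", "ES", "ObS", "OcS", "dLS", "sLS"):
            v = getattr(self, name)
            if not 0.0 <= v <= self.BS + 1e-9:
                raise ValueError(f"{name} must lie in [0, BS]")
        if self.dLS + self.sLS > self.BS + 1e-9:
            raise ValueError("dLS + sLS exceeds total surface length")
        if self.label_interval <= 0:
            raise ValueError("label_interval must be positive")


@dataclass
class StructuralPrimitives:
    """Section-level structural measurements (areas mm^2, perimeter mm)."""

    bone_area: float
    tissue_area: float
    bone_perimeter: float
    ct_th_readings: Sequence[float] = field(default_factory=list)  # mm
    subject: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.tissue_area < 0 or self.bone_area < 0:
            raise ValueError("areas must be non-negative")
        if self.bone_area > self.tissue_area + 1e-12:
            raise ValueError("bone_area cannot exceed tissue_area")


@dataclass
class HistomorphometryIndices:
    """Derived indices for one subject-envelope.

    ``MAR`` is ``None`` when the envelope carried no tetracycline label
    (missing, not zero); MS/BS, BFR/BS and Ac.f are exactly zero in that
    case.
    """

    envelope: str
    ES_BS: float          # %
    OS_BS: float          # %
    ObS_BS: float         # %
    OcS_BS: float         # %
    O_Th: float           # μm
    W_Th: float           # μm
    MS_BS: float          # %
    MAR: float | None     # μm/day
    BFR_BS: float         # μm^3/μm^2/year
    Ac_f: float           # 1/year
    BV_TV: float = math.nan   # %
    Tb_Th: float = math.nan   # μm
    Tb_N: float = math.nan    # 1/mm
    Ct_Th: float = math.nan   # mm
    subject: str = ""
    group: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# index derivations


def structural_indices(prim: StructuralPrimitives) -> tuple[float, float, float, float]:
    """(BV/TV %, Tb.Th μm, Tb.N /mm, Ct.Th mm) from section measurements.

    Trabecular thickness uses the parallel-plate model,
    ``Tb.Th = 2 * bone_area / bone_perimeter`` (the factor 2000 converts
    mm to μm); Tb.N follows as (BV/TV) / Tb.Th.
    """
    if prim.tissue_area <= 0:
        raise ValueError("tissue_area must be positive")
    BV_TV = 100.0 * prim.bone_area / prim.tissue_area
    if prim.bone_perimeter <= 0:
        if prim.bone_area > 0:
            raise ValueError("positive bone area with zero perimeter")
        Tb_Th = math.nan
        Tb_N = math.nan
    else:
        Tb_Th = 2000.0 * prim.bone_area / prim.bone_perimeter        # μm
        Tb_N = (BV_TV / 100.0) / (Tb_Th / 1000.0) if Tb_Th > 0 else math.nan
    Ct_Th = float(np.mean(prim.ct_th_readings)) if len(prim.ct_th_readings) else math.nan
    return BV_TV, Tb_Th, Tb_N, Ct_Th


def static_indices(
    prim: EnvelopePrimitives,
) -> tuple[float, float, float, float, float, float]:
    """(ES/BS, OS/BS, Ob.S/BS, Oc.S/BS, O.Th, W.Th); fractions in %."""
    if prim.BS <= 0:
        raise ValueError("BS must be positive")
    ES_BS = 100.0 * prim.ES / prim.BS
    OS_BS = 100.0 * prim.OS / prim.BS
    ObS_BS = 100.0 * prim.ObS / prim.BS
    OcS_BS = 100.0 * prim.OcS / prim.BS
    O_Th = float(np.mean(prim.o_th_readings)) if len(prim.o_th_readings) else math.nan
    W_Th = float(np.mean(prim.w_th_readings)) if len(prim.w_th_readings) else math.nan
    return ES_BS, OS_BS, ObS_BS, OcS_BS, O_Th, W_Th


def dynamic_indices(
    prim: EnvelopePrimitives,
    W_Th: float,
) -> tuple[float, float | None, float, float]:
    """(MS/BS %, MAR μm/day or None, BFR/BS μm^3/μm^2/yr, Ac.f /yr).

    * MS/BS = 100 * (dLS + sLS/2) / BS (half-weighted single labels),
    * MAR = mean interlabel distance / label interval when double labels
      exist; 0.3 μm/day when only single labels exist; missing when no
      label exists (and then MS/BS = BFR/BS = Ac.f = 0 exactly),
    * BFR/BS = MAR * (MS/BS) annualized (×365),
    * Ac.f = (BFR/BS) / W.Th.
    """
    if W_Th is not None and not math.isnan(W_Th) and W_Th <= 0:
        raise ValueError("W_Th must be positive")
    dists = np.asarray(prim.interlabel_dists, dtype=float)
    if np.any(dists < 0):
        raise ValueError("negative interlabel distance")

    if prim.dLS <= 0 and prim.sLS <= 0:
        return 0.0, None, 0.0, 0.0

    MS_BS = 100.0 * (prim.dLS + prim.sLS / 2.0) / prim.BS
    if prim.dLS > 0:
        if dists.size == 0:
            raise ValueError("double labels present but no interlabel distances")
        MAR = float(np.mean(dists)) / prim.label_interval
    else:
        MAR = MAR_FLOOR
    BFR_BS = MAR * (MS_BS / 100.0) * 365.0
    Ac_f = BFR_BS / W_Th if (W_Th and not math.isnan(W_Th)) else math.nan
    return MS_BS, MAR, BFR_BS, Ac_f


def derive_indices(
    prim: EnvelopePrimitives,
    structural: StructuralPrimitives | None = None,
) -> HistomorphometryIndices:
    """All indices for one subject-envelope (structural ones optional)."""
    ES_BS, OS_BS, ObS_BS, OcS_BS, O_Th, W_Th = static_indices(prim)
    MS_BS, MAR, BFR_BS, Ac_f = dynamic_indices(prim, W_Th)
    idx = HistomorphometryIndices(
        envelope=prim.envelope,
        ES_BS=ES_BS, OS_BS=OS_BS, ObS_BS=ObS_BS, OcS_BS=OcS_BS,
        O_Th=O_Th, W_Th=W_Th, MS_BS=MS_BS, MAR=MAR, BFR_BS=BFR_BS, Ac_f=Ac_f,
        subject=prim.subject, group=prim.group,
    )
    if structural is not None:
        idx.BV_TV, idx.Tb_Th, idx.Tb_N, idx.Ct_Th = structural_indices(structural)
    return idx


def derive_table(
    primitives: Sequence[EnvelopePrimitives],
    structural: Sequence[StructuralPrimitives] | None = None,
) -> pd.DataFrame:
    """Per-subject long table of indices; one row per subject-envelope.

    Missing MAR is represented as NaN in memory and as an empty field on
    disk, never as zero.
    """
    struct_by_subject = {}
    if structural:
        struct_by_subject = {s.subject: s for s in structural}
    rows = []
    for p in primitives:
        idx = derive_indices(p, struct_by_subject.get(p.subject))
        d = idx.to_dict()
        if d["MAR"] is None:
            d["MAR"] = math.nan
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delimited-table I/O (one row per subject x envelope)

_LIST_FIELDS = ("o_th_readings", "w_th_readings", "interlabel_dists")


def _join(values: Sequence[float]) -> str:
    return ";".join(format(v, "g") for v in values)


def _split(cell) -> list[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return []
    return [float(tok) for tok in str(cell).split(";")]


def primitives_to_frame(primitives: Sequence[EnvelopePrimitives]) -> pd.DataFrame:
    rows = []
    for p in primitives:
        d = asdict(p)
        for f in _LIST_FIELDS:
            d[f] = _join(d[f])
        rows.append(d)
    return pd.DataFrame(rows)


def primitives_from_frame(df: pd.DataFrame) -> list[EnvelopePrimitives]:
    prims = []
    for _, row in df.iterrows():
        kw = row.to_dict()
        for f in _LIST_FIELDS:
            kw[f] = _split(kw.get(f))
        kw["subject"] = str(kw.get("subject", ""))
        kw["group"] = str(kw.get("group", ""))
        prims.append(EnvelopePrimitives(**kw))
    return prims


def read_primitives(path: str | Path) -> list[EnvelopePrimitives]:
    return primitives_from_frame(pd.read_csv(path, keep_default_na=False,
                                             na_values=[""]))


def write_primitives(primitives: Sequence[EnvelopePrimitives], path: str | Path) -> None:
    primitives_to_frame(primitives).to_csv(path, index=False)
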