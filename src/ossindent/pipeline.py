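"""End-to-end orchestration: simulate -> reduce -> histo -> stats.

A :class:`RunConfig` (YAML-serializable) drives the four stages and a run
directory collects every table, a manifest with seeds/config hash, and a
human-readable report.  All tables are comma-separated UTF-8 with "."
decimals; missing values are empty fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import IndentationCurve
from .histomorphometry import ENVELOPES, derive_table, primitives_to_frame
from .indentation import IndentationModel, aggregate_specimen
from .protocols import IndentationProtocol, IndenterSpec
from .stats import fit_or, group_summary, ttest_from_stats
from .synthetic import (
    CohortSpec,
    curves_for_sites,
    generate_cohort,
    generate_envelope_primitives,
    generate_structural_primitives,
    write_curves,
    write_table,
)

log = logging.getLogger("ossindent")

MECH_PROPS = ("E", "H", "Hc", "Ue", "Up")
HISTO_VARS = (
    "W_Th", "ES_BS", "OcS_BS", "OS_BS", "O_Th", "ObS_BS",
    "MS_BS", "MAR", "BFR_BS", "Ac_f",
)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 0
    outdir: str = "run"
    # cohort scale (demo default is a scaled-down cohort; the full study
    # layout is n_per_group=16, 60 cortical sites, 5 trabeculae x 12)
    n_per_group: int = 8
    n_cortical_sites: int = 12
    n_trabeculae: int = 3
    sites_per_trabecula: int = 4
    or_per_gpa: float | None = None
    icc: float = 0.5
    # curve simulation
    creep_amp: float = 5.0
    drift_rate: float = 0.05
    noise_sd: float = 2.0
    # reduction options
    nu_s: float = 0.3
    beta: float = 1.0
    fit_fraction: float = 0.8
    # stats
    stats_level: str = "subject"   # "site" | "subject"
    write_curve_files: bool = False

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_per_group=self.n_per_group,
            n_cortical_sites=self.n_cortical_sites,
            n_trabeculae=self.n_trabeculae,
            sites_per_trabecula=self.sites_per_trabecula,
            or_per_gpa=self.or_per_gpa,
            icc=self.icc,
            seed=self.seed,
        )

    def protocol(self) -> IndentationProtocol:
        return IndentationProtocol()

    def indenter(self) -> IndenterSpec:
        return IndenterSpec(beta=self.beta)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stages


def reduce_curves(
    curves,
    protocol: IndentationProtocol,
    indenter: IndenterSpec,
    nu_s: float = 0.3,
    fit_fraction: float = 0.8,
) -> pd.DataFrame:
    """Reduce an iterable of curves to a per-site property table.

    Sites whose reduction fails are kept as NaN rows with the error message
    in a ``note`` column rather than silently dropped.
    """
    rows = []
    for curve in curves:
        base = {
            "subject": curve.specimen,
            "compartment": curve.compartment,
            "trabecula": str(curve.meta.get("trabecula", "")),
            "site": curve.site,
        }
        try:
            res = IndentationModel(
                curve, protocol=protocol, indenter=indenter, nu_s=nu_s
            ).fit(fit_fraction=fit_fraction)
            p = res.properties
            base.update(
                E=p.E, H=p.H, Hc=p.Hc, Ue=p.Ue, Up=p.Up, S=p.S,
                h_c=p.h_c, P_max=p.P_max, h_max=p.h_max, E_r=p.E_r,
                note="; ".join(res.warnings),
            )
        except Exception as exc:  # failed site: recorded, not fatal
            log.warning("site %s/%s failed: %s", base["subject"], base["site"], exc)
            base.update({k: math.nan for k in ("E", "H", "Hc", "Ue", "Up")})
            base["note"] = f"failed: {exc}"
        rows.append(base)
    return pd.DataFrame(rows)


def specimen_table(site_props: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the per-site table to one row per subject x compartment."""
    rows = []
    for (subj, comp), grp in site_props.groupby(["subject", "compartment"]):
        agg = aggregate_specimen(grp, comp, columns=MECH_PROPS)
        rows.append({"subject": subj, "compartment": comp, **agg})
    return pd.DataFrame(rows)


def histo_stage(spec: CohortSpec, groups, subjects, seed: int):
    """Generate primitives for the three envelopes plus structural readings
    and derive the per-subject index table."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(len(ENVELOPES) + 1)
    all_prims = []
    for env, child in zip(ENVELOPES, seeds[:-1]):
        all_prims.extend(
            generate_envelope_primitives(
                spec, env, seed=np.random.default_rng(child),
                groups=groups, subjects=subjects,
            )
        )
    structural = generate_structural_primitives(
        spec, seed=np.random.default_rng(seeds[-1]),
        groups=groups, subjects=subjects,
    )
    indices = derive_table(all_prims, structural)
    return all_prims, structural, indices


def table2_layout(indices: pd.DataFrame) -> pd.DataFrame:
    """Variables x (envelope, group) summary table with t-test p-values."""
    blocks = []
    for env in ENVELOPES:
        sub = indices[indices["envelope"] == env]
        if sub.empty:
            continue
        summ = group_summary(sub, HISTO_VARS)
        summ = summ.set_index("variable")
        out = pd.DataFrame(index=summ.index)
        out[f"{env}_nonAFF"] = summ["nonAFF"]
        out[f"{env}_AFF"] = summ["AFF"]
        pvals = []
        for var in summ.index:
            r = summ.loc[var]
            if r["nonAFF_n"] >= 2 and r["AFF_n"] >= 2:
                p = ttest_from_stats(
                    r["nonAFF_mean"], r["nonAFF_sd"], int(r["nonAFF_n"]),
                    r["AFF_mean"], r["AFF_sd"], int(r["AFF_n"]),
                ).p
            else:
                p = math.nan
            pvals.append(p)
        out[f"{env}_p"] = np.round(pvals, 4)
        blocks.append(out)
    return pd.concat(blocks, axis=1)


def or_table(
    cohort: pd.DataFrame,
    site_df: pd.DataFrame | None,
    level: str = "subject",
) -> pd.DataFrame:
    """Supplemental-style OR table, cortical and cancellous separately."""
    rows = []
    for comp in ("cortical", "cancellous"):
        for prop in ("E", "H", "Hc", "Ue", "Up"):
            if level == "site" and site_df is not None:
                sub = site_df[site_df["compartment"] == comp]
                if prop not in sub.columns or sub[prop].isna().all():
                    continue
                res = fit_or(sub, property=prop, level="site")
            else:
                col = f"{prop}_{comp}"
                if col not in cohort.columns or cohort[col].isna().all():
                    continue
                res = fit_or(cohort, property=col, level="subject")
            d = res.to_dict()
            d["compartment"] = comp
            d["variable"] = prop
            rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run


def run_pipeline(config: RunConfig) -> Path:
    """Execute all four stages into ``config.outdir``; returns the path.

    The run is fully determined by the config (fixed seed): rerunning with
    the same config reproduces every table byte for byte.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: RunConfig, out: Path) -> Path:
    spec = config.cohort_spec()
    ss = np.random.SeedSequence(config.seed)
    s_cohort, s_curves, s_histo = ss.spawn(3)

    log.info("stage 1/4: synthetic cohort (seed=%d)", config.seed)
    cohort_truth, site_truth = generate_cohort(
        spec, seed=np.random.default_rng(s_cohort)
    )
    write_table(site_truth, out / "site_truth.csv", seed=config.seed, spec=spec)

    log.info("stage 2/4: curve simulation + reduction (%d sites)", len(site_truth))
    curves = list(
        curves_for_sites(
            site_truth,
            protocol=config.protocol(),
            indenter=config.indenter(),
            nu_s=config.nu_s,
            creep_amp=config.creep_amp,
            drift_rate=config.drift_rate,
            noise_sd=config.noise_sd,
            seed=int(s_curves.generate_state(1)[0] % (2**31)),
        )
    )
    if config.write_curve_files:
        write_curves(curves, out / "curves", seed=config.seed, spec=spec)
    site_props = reduce_curves(
        curves, config.protocol(), config.indenter(),
        nu_s=config.nu_s, fit_fraction=config.fit_fraction,
    )
    write_table(site_props, out / "site_properties.csv", seed=config.seed, spec=spec)
    spec_table = specimen_table(site_props)
    write_table(spec_table, out / "specimen_properties.csv", seed=config.seed, spec=spec)

    # subject-level cohort table: measured specimen aggregates + labels
    cohort = cohort_truth[["subject", "group", "duration"]].copy()
    for comp in ("cortical", "cancellous"):
        sub = spec_table[spec_table["compartment"] == comp].set_index("subject")
        for prop in MECH_PROPS:
            cohort[f"{prop}_{comp}"] = cohort["subject"].map(sub[f"{prop}_mean"])
    write_table(cohort, out / "cohort.csv", seed=config.seed, spec=spec)

    log.info("stage 3/4: histomorphometry")
    groups = cohort["group"].to_numpy()
    subjects = cohort["subject"].to_numpy()
    prims, structural, indices = histo_stage(
        spec, groups, subjects, seed=int(s_histo.generate_state(1)[0] % (2**31))
    )
    write_table(primitives_to_frame(prims), out / "primitives.csv",
                seed=config.seed, spec=spec)
    write_table(indices, out / "histo_indices.csv", seed=config.seed, spec=spec)
    t2 = table2_layout(indices)
    t2.to_csv(out / "table2_shaped.csv")

    log.info("stage 4/4: statistics (level=%s)", config.stats_level)
    mech_summary = group_summary(
        cohort, [f"{p}_{c}" for p in MECH_PROPS for c in ("cortical", "cancellous")]
    )
    write_table(mech_summary, out / "mech_summary.csv", seed=config.seed, spec=spec)
    site_for_or = site_props.merge(
        cohort[["subject", "group", "duration"]], on="subject", how="left"
    )
    ors = or_table(
        cohort,
        site_for_or if config.stats_level == "site" else None,
        level=config.stats_level,
    )
    write_table(ors, out / "odds_ratios.csv", seed=config.seed, spec=spec)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_sha256": config.digest(),
        "tables": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))

    report = [
        f"ossindent {__version__} pipeline run (seed={config.seed}, "
        f"config {config.digest()})",
        "",
        f"subjects: {len(cohort)} "
        f"({(cohort['group'] == 'AFF').sum()} AFF / "
        f"{(cohort['group'] == 'nonAFF').sum()} non-AFF)",
        f"indentation sites reduced: {len(site_props)} "
        f"({site_props['E'].notna().sum()} valid)",
        "",
        "Nanomechanical group summary (mean ± SD):",
        mech_summary[["variable", "nonAFF", "AFF"]].to_string(index=False),
        "",
        "Histomorphometry (variables x envelope/group):",
        t2.to_string(),
        "",
        "Odds ratios (per unit, adjusted for treatment duration):",
        ors.to_string(index=False) if len(ors) else "(none)",
        "",
    ]
    (out / "report.txt").write_text("\n".join(report))
    log.info("run complete: %s", out)
    return out
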