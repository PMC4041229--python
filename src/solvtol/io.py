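"""Readers, writers and the end-to-end assay report.

Tabular data is plain CSV (UTF-8, dot decimal); solvent constants are
TOML; the report is JSON.  The OD dialect is long-form with columns
``time_h, species, solvent, conc_mM, replicate, od600`` (plus optional
``is_blank``, or dose columns ``mode, volume_ul, stock_M`` in place of
``conc_mM``, resolved through the vial partitioning model).

`run_report` chains the whole analysis — growth fitting, percent-of-μ₀,
EC50 estimation, tolerance analytics — and logs every judgment call
(window choice, censoring, extrapolation, Henry-table clamping) so the
decisions behind each reported number can be audited.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import SolventDose, SolventSpec, VialSetup, partition_dose
from .doseresp import DoseResponseCurve, EC50Estimate, ec50_replicate_stats
from .growth import DEFAULT_R2_MIN, GrowthFit, ODSeries, fit_growth_rate
from .simulate import CONTROL_SOLVENT
from .tolerance import (
    SpeciesPanel,
    classify_free_phase_tolerance,
    normalized_tolerance_scores,
    percent_of_solubility,
    regress_ec50_vs_mu0,
    toxicity_ranking,
)

__all__ = [
    "DEFAULT_TEMPERATURES",
    "RunConfig",
    "ReportBundle",
    "read_solvents_toml",
    "read_od_csv",
    "write_od_csv",
    "od_frame_to_series",
    "run_report",
]

#: Per-species incubation temperatures (°C) of the reference assay design.
DEFAULT_TEMPERATURES: dict[str, float] = {
    "E. coli": 30.0,
    "P. aeruginosa": 37.0,
    "S. oneidensis": 30.0,
    "Klebsiella sp.": 26.0,
    "Paenibacillus sp.": 30.0,
    "Clostridium sp.": 24.0,
    "G. sulfurreducens": 30.0,
    "D. vulgaris": 30.0,
}

_OD_KEY = ["species", "solvent", "conc_mM", "replicate"]


def read_solvents_toml(path: str | Path | None = None) -> dict[str, SolventSpec]:
    """Load solvent constants from TOML (packaged defaults when ``path`` is None)."""
    if path is None:
        text = resources.files("solvtol.data").joinpath("solvents.toml").read_text()
    else:
        text = Path(path).read_text()
    raw = tomllib.loads(text)
    out: dict[str, SolventSpec] = {}
    for name, tbl in raw.items():
        out[name] = SolventSpec(
            name=name,
            molar_mass=tbl["molar_mass_g_mol"],
            liquid_density=tbl["density_g_ml"],
            log_pow=tbl["log_pow"],
            aqueous_solubility=tbl["solubility_mM"],
            henry_points=tuple((t, h) for t, h in tbl["henry"]),
        )
    return out


@dataclass(frozen=True)
class RunConfig:
    """Everything `run_report` needs besides the OD data itself.

    ``temperatures`` supplies per-species incubation temperatures used
    when doses must be converted to concentrations; unknown species fall
    back to ``default_temperature``.
    """

    solvents: Mapping[str, SolventSpec] = field(default_factory=read_solvents_toml)
    vial: VialSetup = VialSetup()
    temperatures: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TEMPERATURES))
    default_temperature: float = 30.0
    min_points: int = 3
    r2_min: float = DEFAULT_R2_MIN
    ec50_mode: str = "replicate_first"  # or "average_curve"
    include_control: bool = True
    reference: str = "max"
    out_dir: str | Path | None = None


def write_od_csv(od: pd.DataFrame, path: str | Path) -> None:
    """Write an OD table in the package CSV dialect (stable column order)."""
    cols = ["time_h", "species", "solvent", "conc_mM", "replicate", "od600"]
    extra = [c for c in od.columns if c not in cols]
    od[cols + extra].to_csv(path, index=False)


def _resolve_dose_columns(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Replace dose columns (mode, volume_ul, stock_M) with conc_mM."""
    df = df.copy()
    concs = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        solvent = config.solvents.get(row.solvent)
        if solvent is None:
            raise ValueError(
                f"row {i}: solvent {row.solvent!r} not in the constants table; "
                "cannot resolve dose to concentration"
            )
        temp = config.temperatures.get(row.species, config.default_temperature)
        vial = VialSetup(config.vial.liquid_volume, config.vial.headspace_volume, temp)
        stock = getattr(row, "stock_M", None)
        dose = SolventDose(row.mode, row.volume_ul,
                           None if stock is None or pd.isna(stock) else float(stock))
        part = partition_dose(solvent, vial, dose)
        # report on the nominal scale once free phase forms, else actual aqueous
        concs[i] = part.nominal_concentration if part.free_phase else part.aqueous_concentration
    df["conc_mM"] = concs
    return df.drop(columns=[c for c in ("mode", "volume_ul", "stock_M") if c in df])


def read_od_csv(path: str | Path, config: RunConfig | None = None) -> list[ODSeries]:
    """Read and validate an OD CSV into blank-corrected series.

    Blank rows (``is_blank`` truthy) are averaged per species × time
    point and subtracted from the matching readings.  Files using dose
    columns instead of ``conc_mM`` are resolved through the closed-vial
    partitioning model and need a :class:`RunConfig` with solvent
    constants.  Validation failures carry row numbers.
    """
    df = pd.read_csv(path)
    required = {"time_h", "species", "solvent", "replicate", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"OD CSV is missing required columns: {sorted(missing)}")
    has_conc = "conc_mM" in df.columns
    has_dose = {"mode", "volume_ul"} <= set(df.columns)
    if has_conc and has_dose:
        raise ValueError("OD CSV mixes conc_mM with dose columns (mode/volume_ul); use one")
    if not has_conc and not has_dose:
        raise ValueError("OD CSV needs either conc_mM or dose columns (mode, volume_ul)")

    if "is_blank" in df.columns:
        blanks = df[df["is_blank"].astype(bool)]
        df = df[~df["is_blank"].astype(bool)].drop(columns=["is_blank"])
        if not blanks.empty:
            per_time = blanks.groupby(["species", "time_h"])["od600"].mean()
            per_species = blanks.groupby("species")["od600"].mean()

            def _blank(row) -> float:
                key = (row.species, row.time_h)
                if key in per_time.index:
                    return float(per_time.loc[key])
                return float(per_species.get(row.species, 0.0))

            df = df.copy()
            df["od600"] = [r.od600 - _blank(r) for r in df.itertuples(index=False)]

    if has_dose:
        if config is None:
            raise ValueError("dose columns present: a RunConfig with solvent constants is required")
        df = _resolve_dose_columns(df, config)

    return od_frame_to_series(df)


def od_frame_to_series(df: pd.DataFrame) -> list[ODSeries]:
    """Split a long OD table into per-tube :class:`ODSeries`.

    Expects the dialect columns with ``conc_mM`` already resolved;
    rejects duplicated (condition, time) rows.
    """
    dup = df.duplicated(subset=_OD_KEY + ["time_h"])
    if dup.any():
        rows = df.index[dup][:5].tolist()
        raise ValueError(f"duplicated (condition, time) rows at index {rows}")
    series: list[ODSeries] = []
    for key, grp in df.groupby(_OD_KEY, sort=True):
        grp = grp.sort_values("time_h")
        sp, solv, conc, rep = key
        try:
            series.append(
                ODSeries(sp, solv, float(conc), str(rep),
                         grp["time_h"].to_numpy(float), grp["od600"].to_numpy(float))
            )
        except ValueError as err:
            raise ValueError(f"invalid series {key}: {err}") from err
    return series


@dataclass(frozen=True)
class ReportBundle:
    """Everything the end-to-end analysis produced."""

    ec50_table: pd.DataFrame
    panel: SpeciesPanel | None
    report: dict
    decision_log: tuple[str, ...]


def _is_control(s: ODSeries) -> bool:
    return s.concentration == 0 or s.solvent in (CONTROL_SOLVENT, "control", "")


def run_report(series: Sequence[ODSeries], config: RunConfig | None = None) -> ReportBundle:
    """Run growth → dose-response → tolerance on a set of OD series.

    Per species, the no-solvent control replicates define μ₀; per
    species × solvent, replicate-level percent-of-μ₀ curves feed the
    EC50 estimator (replicate-first by default); the resulting panel
    feeds the tolerance analytics.  Regressions needing ≥ 3 species are
    skipped with a logged reason rather than failing the whole report.

    Writes ``ec50.csv`` and ``report.json`` into ``config.out_dir`` when
    set.  Identical inputs give byte-identical outputs.
    """
    config = config or RunConfig()
    log: list[str] = []
    by_species: dict[str, list[ODSeries]] = {}
    for s in series:
        by_species.setdefault(s.species, []).append(s)

    rows: list[dict] = []
    mu0: dict[str, float] = {}
    ec50s: dict[str, dict[str, EC50Estimate]] = {}
    for sp, group in sorted(by_species.items()):
        controls = [s for s in group if _is_control(s)]
        treated = [s for s in group if not _is_control(s)]
        if not controls:
            log.append(f"{sp}: no no-solvent controls; species skipped")
            continue
        control_fits = [
            fit_growth_rate(s, min_points=config.min_points, r2_min=config.r2_min)
            for s in controls
        ]
        mu0_sp = float(np.mean([f.mu for f in control_fits]))
        if mu0_sp <= 0:
            log.append(f"{sp}: all controls scored zero growth; species skipped")
            continue
        mu0[sp] = mu0_sp
        by_solvent: dict[str, list[ODSeries]] = {}
        for s in treated:
            by_solvent.setdefault(s.solvent, []).append(s)
        for solv, sgroup in sorted(by_solvent.items()):
            fits: dict[tuple[float, str], GrowthFit] = {}
            for s in sgroup:
                f = fit_growth_rate(s, min_points=config.min_points, r2_min=config.r2_min)
                fits[(s.concentration, s.replicate)] = f
                if f.zero_growth:
                    log.append(f"{sp}/{solv} @ {s.concentration:g} mM rep {s.replicate}: zero growth")
            concs = sorted({c for c, _ in fits})
            reps = sorted({r for _, r in fits})
            scale = "aqueous"
            spec = config.solvents.get(solv)
            if spec is not None and concs and max(concs) > spec.aqueous_solubility:
                scale = "nominal"
                log.append(f"{sp}/{solv}: doses exceed solubility; nominal concentration scale")
            full_reps = [r for r in reps if all((c, r) in fits for c in concs)]
            if len(concs) < 2:
                log.append(f"{sp}/{solv}: fewer than 2 non-zero concentrations; skipped")
                continue
            if full_reps and config.ec50_mode == "replicate_first":
                curves = [
                    DoseResponseCurve(
                        sp, solv, np.array(concs),
                        np.array([100.0 * fits[(c, r)].mu / mu0_sp for c in concs]),
                        scale,
                    )
                    for r in full_reps
                ]
                est = ec50_replicate_stats(curves, mode="replicate_first",
                                           include_control=config.include_control)
            else:
                mean_pct = np.array([
                    float(np.mean([fits[k].mu for k in fits if k[0] == c])) * 100.0 / mu0_sp
                    for c in concs
                ])
                est = ec50_replicate_stats(
                    [DoseResponseCurve(sp, solv, np.array(concs), mean_pct, scale)],
                    mode="average_curve", include_control=config.include_control,
                )
                if config.ec50_mode == "replicate_first":
                    log.append(f"{sp}/{solv}: unbalanced replicates; fell back to average curve")
            for d in est.diagnostics:
                log.append(f"{sp}/{solv}: {d}")
            ec50s.setdefault(sp, {})[solv] = est
            rows.append(
                {
                    "species": sp, "solvent": solv,
                    "ec50_mM": est.value if est.value is not None else "",
                    "censoring": est.censoring,
                    "method": est.method,
                    "bound_mM": est.bound if est.bound is not None else "",
                    "sd_mM": est.sd if est.sd is not None else "",
                    "n_reps": est.n_replicates,
                    "concentration_scale": scale,
                }
            )

    ec50_table = pd.DataFrame(rows)
    report: dict = {"n_species": len(mu0), "n_conditions": len(rows), "mu0": mu0}
    panel: SpeciesPanel | None = None
    solvent_names = sorted({r["solvent"] for r in rows})
    known = {s: config.solvents[s] for s in solvent_names if s in config.solvents}
    if ec50s and known:
        panel = SpeciesPanel(mu0, ec50s, known)
        sol_rows = []
        for sp, by_solv in sorted(ec50s.items()):
            for solv, est in sorted(by_solv.items()):
                if solv not in known:
                    continue
                pct = percent_of_solubility(est, known[solv])
                sol_rows.append(
                    {
                        "species": sp, "solvent": solv,
                        "percent_of_solubility": pct.percent,
                        "rounded": pct.rounded, "relation": pct.relation,
                        "free_phase_tolerant": classify_free_phase_tolerance(est, known[solv]),
                    }
                )
        report["percent_of_solubility"] = sol_rows
        try:
            scores = normalized_tolerance_scores(panel, reference=config.reference)
            report["tolerance_scores"] = [
                {
                    "species": s.species, "average": s.average,
                    "per_solvent": dict(s.per_solvent),
                    "censored_solvents": list(s.censored_solvents),
                    "incomplete": s.incomplete,
                }
                for s in scores
            ]
        except ValueError as err:
            log.append(f"tolerance scores skipped: {err}")
        regs: dict[str, dict] = {}
        try:
            for solv, summ in regress_ec50_vs_mu0(panel, per_solvent=True).items():
                regs[solv] = {"slope": summ.slope, "intercept": summ.intercept,
                              "r2": summ.r2, "n": summ.n}
        except ValueError as err:
            log.append(f"per-solvent regression skipped: {err}")
        try:
            summ = regress_ec50_vs_mu0(panel, use="score", reference=config.reference)
            regs["averaged_score"] = {"slope": summ.slope, "intercept": summ.intercept,
                                      "r2": summ.r2, "n": summ.n}
        except ValueError as err:
            log.append(f"score regression skipped: {err}")
        if regs:
            report["regressions"] = regs
        report["toxicity_ranking"] = [
            {
                "species": r.species,
                "order": [[s, v, lp] for s, v, lp in r.order],
                "violations": [list(v) for v in r.violations],
                "consistent_with_log_pow": r.consistent_with_log_pow,
            }
            for r in toxicity_ranking(panel)
        ]
    report["decision_log"] = log

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ec50_table.to_csv(out / "ec50.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return ReportBundle(ec50_table, panel, report, tuple(log))
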