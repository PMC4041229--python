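"""Cross-solvent tolerance analytics.

Once EC50s exist for a panel of species × solvents, the comparative
questions become: how close does each EC50 sit to the solvent's aqueous
solubility ceiling (can the organism grow next to a free solvent
phase?), how do species rank when EC50s are normalized to a reference
species and averaged across solvents, does tolerance track the
unstressed growth rate μ₀, and does the per-species toxicity ordering
follow solvent hydrophobicity (log P_o/w)?

A curated fixture of published EC50 values for eight anaerobic bacteria
(four fermenters, four anaerobic respirers) against PCE, CT, CF and
1,2-DCA ships with the package; it transcribes only numbers printed in
the source study's text, with censored and range-only entries stored as
such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Mapping

import numpy as np
from scipy import stats

from .chem import SolventSpec
from .doseresp import EC50Estimate

__all__ = [
    "SpeciesPanel",
    "ToleranceScore",
    "RegressionSummary",
    "SolubilityPercent",
    "CuratedRecord",
    "percent_of_solubility",
    "classify_free_phase_tolerance",
    "normalized_tolerance_scores",
    "regress_ec50_vs_mu0",
    "toxicity_ranking",
    "load_curated_results",
    "curated_effective_values",
]


@dataclass(frozen=True)
class SpeciesPanel:
    """Per-species μ₀ and EC50s across solvents, plus solvent constants.

    ``ec50s`` maps species → solvent → :class:`EC50Estimate`; ``mu0`` is
    the no-solvent specific growth rate (h⁻¹, > 0) per species.
    """

    mu0: Mapping[str, float]
    ec50s: Mapping[str, Mapping[str, EC50Estimate]]
    solvents: Mapping[str, SolventSpec]

    def __post_init__(self) -> None:
        for sp, mu in self.mu0.items():
            if mu <= 0:
                raise ValueError(f"μ0 must be > 0 for included species ({sp}: {mu})")
        for sp in self.ec50s:
            if sp not in self.mu0:
                raise ValueError(f"species {sp!r} has EC50s but no μ0")

    @property
    def solvent_names(self) -> tuple[str, ...]:
        return tuple(self.solvents)

    def complete_species(self) -> tuple[str, ...]:
        """Species holding an estimate for every panel solvent."""
        return tuple(
            sp for sp, by_solv in self.ec50s.items()
            if all(s in by_solv for s in self.solvents)
        )


@dataclass(frozen=True)
class ToleranceScore:
    """Reference-normalized tolerance of one species.

    Per-solvent scores are 100·EC50/EC50_reference; the averaged score
    is their arithmetic mean.  Solvents where the species' estimate is
    censored (score computed from the bound) are listed in
    ``censored_solvents``.
    """

    species: str
    per_solvent: Mapping[str, float]
    average: float
    reference: str | Mapping[str, str]
    censored_solvents: tuple[str, ...] = ()
    incomplete: bool = False


@dataclass(frozen=True)
class RegressionSummary:
    """OLS summary for EC50 (or tolerance score) against μ₀."""

    slope: float
    intercept: float
    r2: float
    n: int
    stderr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 outside [0, 1]")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


@dataclass(frozen=True)
class SolubilityPercent:
    """An EC50 expressed as percent of the solvent's aqueous solubility.

    ``relation`` is ``"="`` for point estimates and ``"<"`` / ``">"``
    for left- / right-censored ones, where the percent is computed from
    the censoring bound and only bounds the true value.
    """

    percent: float
    rounded: int
    relation: Literal["=", "<", ">"]


@dataclass(frozen=True)
class CuratedRecord:
    """One transcribed literature EC50 entry.

    ``kind`` is ``point`` (printed value), ``left``/``right`` (censored
    at ``bound``), or ``range`` (known only to lie in [lo, hi]).  Every
    record carries a ``source`` locator describing where in the source
    text the number is printed; none are read off figures.
    """

    species: str
    solvent: str
    kind: Literal["point", "left", "right", "range"]
    value: float | None = None
    bound: float | None = None
    lo: float | None = None
    hi: float | None = None
    method: str | None = None
    flags: tuple[str, ...] = ()
    source: str = ""

    @property
    def effective_value(self) -> float:
        """Conservative numeric summary: the point value, the censoring
        bound, or the lower end of a range."""
        if self.kind == "point":
            return float(self.value)  # type: ignore[arg-type]
        if self.kind in ("left", "right"):
            return float(self.bound)  # type: ignore[arg-type]
        return float(self.lo)  # type: ignore[arg-type]


def percent_of_solubility(
    ec50: float | EC50Estimate, solvent: SolventSpec
) -> SolubilityPercent:
    """Express an EC50 as a percentage of the solvent's aqueous solubility.

    An EC50 near 100% means the organism tolerates nearly saturated
    solution — i.e. free-phase conditions.  Censored estimates yield an
    inequality annotation computed from their bound rather than a plain
    percentage.
    """
    if isinstance(ec50, EC50Estimate):
        if ec50.censoring == "point":
            val, rel = ec50.value, "="
        elif ec50.censoring == "left":
            val, rel = ec50.bound, "<"
        else:
            val, rel = ec50.bound, ">"
    else:
        val, rel = float(ec50), "="
    if val is None or val < 0:
        raise ValueError("EC50 value/bound must be a non-negative number")
    pct = 100.0 * val / solvent.aqueous_solubility
    return SolubilityPercent(pct, int(round(pct)), rel)  # type: ignore[arg-type]


def classify_free_phase_tolerance(ec50: EC50Estimate, solvent: SolventSpec) -> bool:
    """Can the species grow at ≥ 50% of μ₀ with a free solvent phase present?

    True iff the point estimate (or right-censored bound) strictly
    exceeds the aqueous solubility; such EC50s live on the nominal
    concentration scale.  Left-censored estimates classify False: their
    true EC50 lies below the bound.
    """
    if ec50.censoring == "point":
        return float(ec50.value) > solvent.aqueous_solubility  # type: ignore[arg-type]
    if ec50.censoring == "right":
        return float(ec50.bound) > solvent.aqueous_solubility  # type: ignore[arg-type]
    return False


def normalized_tolerance_scores(
    panel: SpeciesPanel,
    reference: str = "max",
    censored: Literal["bounds", "exclude"] = "bounds",
) -> list[ToleranceScore]:
    """Score species tolerance relative to a reference species.

    For each solvent the reference species' EC50 is set at 100% and all
    other species are expressed as percentages of it; the per-solvent
    scores are then averaged into a single tolerance score per species.
    ``reference="max"`` uses the per-solvent maximum-EC50 species (the
    most tolerant organism, which is how a fixed reference species
    behaves when it tops every solvent).  Censored species estimates
    enter via their bounds and are flagged (``censored="bounds"``,
    default) or dropped from the average (``"exclude"``).

    Species missing any solvent are marked ``incomplete`` and should be
    excluded from downstream regressions.
    """
    ref_by_solvent: dict[str, str] = {}
    for solv in panel.solvents:
        eligible = {
            sp: est[solv] for sp, est in panel.ec50s.items()
            if solv in est and est[solv].censoring in ("point", "right")
        }
        if not eligible:
            raise ValueError(f"no species has a point or right-censored estimate for {solv}")
        if reference == "max":
            ref_by_solvent[solv] = max(eligible, key=lambda sp: eligible[sp].effective_value)
        else:
            if reference not in eligible:
                raise ValueError(
                    f"reference species {reference!r} lacks a point/right-censored "
                    f"estimate for {solv}"
                )
            ref_by_solvent[solv] = reference
    scores: list[ToleranceScore] = []
    for sp, by_solv in panel.ec50s.items():
        per_solvent: dict[str, float] = {}
        flagged: list[str] = []
        for solv in panel.solvents:
            if solv not in by_solv:
                continue
            est = by_solv[solv]
            ref_val = panel.ec50s[ref_by_solvent[solv]][solv].effective_value
            if est.censoring != "point":
                if censored == "exclude":
                    continue
                flagged.append(solv)
            per_solvent[solv] = 100.0 * est.effective_value / ref_val
        incomplete = len(by_solv) < len(panel.solvents)
        avg = float(np.mean(list(per_solvent.values()))) if per_solvent else float("nan")
        ref_out: str | Mapping[str, str]
        ref_out = reference if reference != "max" else dict(ref_by_solvent)
        scores.append(ToleranceScore(sp, per_solvent, avg, ref_out, tuple(flagged), incomplete))
    return scores


def regress_ec50_vs_mu0(
    panel: SpeciesPanel,
    per_solvent: bool = True,
    use: Literal["ec50", "score"] = "ec50",
    include_censored: bool = False,
    reference: str = "max",
) -> dict[str, RegressionSummary] | RegressionSummary:
    """OLS regression of solvent tolerance on the no-solvent growth rate.

    With ``use="ec50"`` and ``per_solvent=True`` (default) one
    regression per solvent is fitted through species point estimates
    (censored bounds included only on request).  With ``use="score"``
    the averaged normalized tolerance score replaces the raw EC50 and a
    single regression is returned — the summary view collapsing all
    solvents into one tolerance-vs-growth-rate relationship.
    """
    if use == "score":
        scores = {
            s.species: s.average
            for s in normalized_tolerance_scores(panel, reference=reference)
            if not s.incomplete and np.isfinite(s.average)
        }
        x = np.array([panel.mu0[sp] for sp in scores])
        y = np.array(list(scores.values()))
        return _ols(x, y)
    out: dict[str, RegressionSummary] = {}
    for solv in panel.solvents:
        xs, ys = [], []
        for sp, by_solv in panel.ec50s.items():
            if solv not in by_solv:
                continue
            est = by_solv[solv]
            if est.censoring != "point" and not include_censored:
                continue
            xs.append(panel.mu0[sp])
            ys.append(est.effective_value)
        out[solv] = _ols(np.array(xs), np.array(ys))
    return out if per_solvent else _pooled(out)


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionSummary:
    if x.size < 3:
        raise ValueError(f"regression needs >= 3 species with estimates, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: no variance in μ0")
    fit = stats.linregress(x, y)
    return RegressionSummary(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2), int(x.size),
        float(fit.stderr),
    )


def _pooled(per_solvent: Mapping[str, RegressionSummary]) -> RegressionSummary:
    raise NotImplementedError(
        "pooled raw-EC50 regression mixes incommensurate concentration scales; "
        "use use='score' for the cross-solvent summary"
    )


@dataclass(frozen=True)
class SolventRank:
    """Toxicity ordering of the panel solvents for one species."""

    species: str
    order: tuple[tuple[str, float, float], ...]  # (solvent, effective EC50, log_pow), most toxic first
    violations: tuple[tuple[str, str], ...]  # (more_toxic, less_toxic) despite lower log_pow
    consistent_with_log_pow: bool


def toxicity_ranking(panel: SpeciesPanel) -> list[SolventRank]:
    """Rank solvents by toxicity per species and test the log P_o/w rule.

    More hydrophobic solvents (higher log P_o/w) are expected to be more
    toxic (lower EC50).  For each species with a complete panel, solvents
    are sorted by ascending effective EC50 (most toxic first) and every
    pair violating the hydrophobicity ordering — a solvent more toxic
    than another despite a *lower* log P_o/w — is reported.
    """
    ranks: list[SolventRank] = []
    for sp in panel.complete_species():
        by_solv = panel.ec50s[sp]
        entries = sorted(
            (
                (solv, by_solv[solv].effective_value, panel.solvents[solv].log_pow)
                for solv in panel.solvents
            ),
            key=lambda e: e[1],
        )
        violations = tuple(
            (a[0], b[0])
            for i, a in enumerate(entries)
            for b in entries[i + 1:]
            if a[1] < b[1] and a[2] < b[2]
        )
        ranks.append(SolventRank(sp, tuple(entries), violations, not violations))
    return ranks


def load_curated_results() -> list[CuratedRecord]:
    """Load the packaged curated panel of published EC50 results.

    Returns one record per species × solvent for the eight-species,
    four-solvent reference panel.  Values are exactly those printed in
    the source study's text; range-only and censored entries are stored
    as such rather than guessed, and no numbers are digitized from
    figures.
    """
    payload = json.loads(
        resources.files("solvtol.data").joinpath("curated_ec50.json").read_text()
    )
    records = []
    for row in payload["records"]:
        records.append(
            CuratedRecord(
                species=row["species"],
                solvent=row["solvent"],
                kind=row["kind"],
                value=row.get("value"),
                bound=row.get("bound"),
                lo=row.get("lo"),
                hi=row.get("hi"),
                method=row.get("method"),
                flags=tuple(row.get("flags", ())),
                source=row["source"],
            )
        )
    return records


def curated_effective_values() -> dict[str, dict[str, CuratedRecord]]:
    """Curated records re-keyed as species → solvent → record."""
    out: dict[str, dict[str, CuratedRecord]] = {}
    for rec in load_curated_results():
        out.setdefault(rec.species, {})[rec.solvent] = rec
    return out
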