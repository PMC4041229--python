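"""EC50 estimation from percent-of-control growth rates.

The EC50 is the solvent concentration halving the specific growth rate
relative to no-solvent controls.  Estimation is deliberately
model-free: percent-of-μ₀ is treated as piecewise linear in
concentration and the first downward crossing of 50% is located by
linear interpolation, with the implicit control point (0, 100%)
participating.  Two boundary cases mirror how tube assays are actually
read out:

* growth still above 50% at every tested concentration → a straight
  line is fitted through all points and extrapolated to 50%; if the fit
  does not decrease, the estimate is right-censored at the highest
  tested concentration;
* no growth at all at the lowest tested concentration → the EC50 is
  left-censored at that concentration (an interpolated value between 0
  and the first dose would be an artefact of the dose spacing).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = ["DoseResponseCurve", "EC50Estimate", "estimate_ec50", "ec50_replicate_stats"]

Censoring = Literal["point", "left", "right"]
Method = Literal["interpolated", "extrapolated", "assigned"]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Percent-of-μ₀ across a concentration series for one species × solvent.

    Concentrations are strictly increasing and non-zero; the control
    (0, 100%) is implicit.  ``concentration_scale`` records whether the
    axis is actual dissolved concentration or nominal (total/liquid
    volume, used once free phase is present).
    """

    species: str
    solvent: str
    concentrations: np.ndarray  # mmol L⁻¹, strictly increasing, > 0
    percents: np.ndarray  # percent of μ₀, capped below at 0
    concentration_scale: Literal["aqueous", "nominal"] = "aqueous"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        p = np.asarray(self.percents, dtype=float)
        if c.ndim != 1 or c.shape != p.shape:
            raise ValueError("concentrations and percents must be 1-D arrays of equal length")
        if np.unique(c[c > 0]).size < 2:
            raise ValueError("need at least 2 distinct non-zero concentrations")
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0 (the control at 0 is implicit)")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "percents", np.maximum(p, 0.0))


@dataclass(frozen=True)
class EC50Estimate:
    """A point or censored EC50.

    ``value`` is absent for censored estimates; ``bound`` then carries
    the lowest (left) or highest (right) tested concentration.  For
    replicate aggregates, ``sd`` is the sample SD over per-replicate
    point estimates (present only with ≥ 2 replicates).
    """

    value: float | None
    censoring: Censoring
    bound: float | None
    method: Method
    sd: float | None = None
    n_replicates: int = 1
    diagnostics: tuple[str, ...] = ()

    @property
    def effective_value(self) -> float:
        """Point value, or the censoring bound for censored estimates."""
        return self.value if self.value is not None else float(self.bound)  # type: ignore[arg-type]


def estimate_ec50(curve: DoseResponseCurve, include_control: bool = True) -> EC50Estimate:
    """Estimate the EC50 of one dose-response curve.

    See the module docstring for the interpolation, extrapolation and
    censoring rules.  With a non-monotone curve the first crossing from
    above 50% (scanning upward in concentration) is used, which is the
    conservative, lowest estimate.
    """
    c, p = curve.concentrations, curve.percents

    # no growth at the lowest tested dose: left-censored, before any
    # interpolation against the implicit control
    if p[0] == 0.0:
        return EC50Estimate(None, "left", float(c[0]), "assigned",
                            diagnostics=("no growth at lowest tested concentration",))

    if include_control:
        c = np.concatenate(([0.0], c))
        p = np.concatenate(([100.0], p))

    # first downward crossing of 50%
    for i in range(len(c)):
        if p[i] == 50.0:
            return EC50Estimate(float(c[i]), "point", None, "interpolated")
        if i + 1 < len(c) and p[i] > 50.0 > p[i + 1]:
            frac = (p[i] - 50.0) / (p[i] - p[i + 1])
            return EC50Estimate(float(c[i] + frac * (c[i + 1] - c[i])), "point", None, "interpolated")

    if np.all(p > 50.0):
        fit = stats.linregress(c, p)
        if fit.slope < 0:
            value = (50.0 - fit.intercept) / fit.slope
            return EC50Estimate(float(value), "point", None, "extrapolated",
                                diagnostics=("extrapolated beyond highest tested concentration",))
        return EC50Estimate(None, "right", float(curve.concentrations[-1]), "assigned",
                            diagnostics=("no decreasing trend; right-censored",))

    # only reachable with include_control=False and a first percent < 50
    return EC50Estimate(None, "left", float(curve.concentrations[0]), "assigned",
                        diagnostics=("below 50% at lowest tested concentration (control excluded)",))


def ec50_replicate_stats(
    per_replicate_curves: Sequence[DoseResponseCurve],
    mode: Literal["replicate_first", "average_curve"] = "replicate_first",
    include_control: bool = True,
) -> EC50Estimate:
    """Aggregate an EC50 over replicate dose-response curves.

    Default is replicate-first: estimate one EC50 per replicate curve,
    then report mean ± sample SD over the point estimates (error bars on
    the EC50 itself).  ``average_curve`` instead averages the percent
    values per concentration and estimates once.  When replicates
    disagree on censoring class, the majority class is reported and the
    conflict recorded in diagnostics.
    """
    if not per_replicate_curves:
        raise ValueError("at least one replicate curve is required")
    if mode == "average_curve":
        ref = per_replicate_curves[0]
        concs = ref.concentrations
        stack = []
        for cur in per_replicate_curves:
            if not np.array_equal(cur.concentrations, concs):
                raise ValueError("average_curve mode requires identical concentration series")
            stack.append(cur.percents)
        mean_curve = DoseResponseCurve(ref.species, ref.solvent, concs,
                                       np.mean(stack, axis=0), ref.concentration_scale)
        est = estimate_ec50(mean_curve, include_control=include_control)
        return EC50Estimate(est.value, est.censoring, est.bound, est.method,
                            None, len(per_replicate_curves),
                            est.diagnostics + ("average-curve mode",))

    ests = [estimate_ec50(cur, include_control=include_control) for cur in per_replicate_curves]
    classes = Counter(e.censoring for e in ests)
    majority, _ = classes.most_common(1)[0]
    diags: list[str] = []
    if len(classes) > 1:
        diags.append("replicates disagree in censoring class: "
                     + ", ".join(f"{k}×{v}" for k, v in sorted(classes.items())))
    members = [e for e in ests if e.censoring == majority]
    n = len(ests)
    if majority == "point":
        values = np.array([e.value for e in members], dtype=float)
        sd = float(values.std(ddof=1)) if values.size >= 2 else None
        methods = Counter(e.method for e in members)
        return EC50Estimate(float(values.mean()), "point", None,
                            methods.most_common(1)[0][0], sd, n, tuple(diags))
    bound = float(np.mean([e.bound for e in members]))
    return EC50Estimate(None, majority, bound, "assigned", None, n, tuple(diags))
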