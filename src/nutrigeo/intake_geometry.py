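"""Nutrient-rail geometry: rules of compromise and intake-array statistics.

In the geometric framework of nutrition, every fixed-composition diet confines
an animal's cumulative intake to a "nutrient rail" — the ray from the origin in
(AA, carbohydrate) intake space whose direction is the diet's (AA molarity,
sucrose molarity).  An animal with intake target T that cannot reach T on its
rail must compromise.  Three classical rules are implemented:

* **no-interaction** — regulate one nutrient to its target coordinate and
  ignore the other (separately for AA and for carbohydrate);
* **equal distance** — feed until the deficit in one nutrient equals the
  surplus in the other (the point where the rail meets the slope −1 line
  through T);
* **closest distance** — feed to the rail point nearest T (orthogonal
  projection).

The "intake array" connects per-diet mean intakes across a panel of imbalanced
diets.  Its fitted slope diagnoses the rule: exactly −1 under equal distance,
exactly 0 under carbohydrate-only regulation.  Slopes are compared with
hypothetical values via t = (beta_a − beta_h)/SE on n − 2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .diet_design import Diet

__all__ = [
    "RULES",
    "NutrientPoint",
    "Rail",
    "IntakeTarget",
    "IntakeArray",
    "SlopeTest",
    "RuleResult",
    "rail_from_diet",
    "project_no_interaction",
    "project_equal_distance",
    "project_closest",
    "project_rule",
    "fit_intake_array",
    "slope_test",
    "classify_rule",
    "aggregate_intake",
]

log = logging.getLogger(__name__)

Rule = Literal["no_interaction_aa", "no_interaction_c", "equal_distance", "closest_distance"]

#: Recognized rules of compromise, in the deterministic tie-break order used
#: by :func:`classify_rule` (ties go to the earlier entry).
RULES: tuple[Rule, ...] = (
    "equal_distance",
    "closest_distance",
    "no_interaction_aa",
    "no_interaction_c",
)

_ON_RAIL_TOL = 1e-9


class DegenerateRailError(ValueError):
    """Raised for a rail with zero direction (no nutrients in the diet)."""


@dataclass(frozen=True)
class NutrientPoint:
    """A point in (AA, carbohydrate) intake space, mmol per bee."""

    aa: float
    c: float

    def as_array(self) -> np.ndarray:
        return np.array([self.aa, self.c], dtype=float)


@dataclass(frozen=True)
class Rail:
    """A diet's nutrient rail through the origin.

    ``direction`` is proportional to the diet's (AA molarity, sucrose
    molarity); any realized intake of that diet lies on the ray s*direction,
    s >= 0.
    """

    diet_id: str
    u_aa: float
    u_c: float

    def __post_init__(self) -> None:
        if self.u_aa < 0 or self.u_c < 0:
            raise DegenerateRailError("rail direction components must be >= 0")
        if self.u_aa == 0 and self.u_c == 0:
            raise DegenerateRailError("rail direction must be non-zero")

    def point_at(self, s: float) -> NutrientPoint:
        return NutrientPoint(s * self.u_aa, s * self.u_c)

    def contains(self, p: NutrientPoint, tol: float = _ON_RAIL_TOL) -> bool:
        """Collinearity check: cross product of p and the direction ~ 0."""
        return abs(p.aa * self.u_c - p.c * self.u_aa) <= tol


@dataclass(frozen=True)
class IntakeTarget:
    """The intake target T: the blend an unconstrained animal would eat."""

    aa: float
    c: float

    def __post_init__(self) -> None:
        if self.aa <= 0 or self.c <= 0:
            raise ValueError("intake target coordinates must be positive")


@dataclass(frozen=True)
class SlopeTest:
    """t-test of a fitted array slope against a hypothetical slope."""

    beta_a: float
    beta_h: float
    se: float
    t_stat: float
    df: int
    p_two_tailed: float
    exact_fit: bool = False


@dataclass(frozen=True)
class IntakeArray:
    """Per-diet mean intake points with SEs plus the fitted OLS line."""

    points: pd.DataFrame  # diet_id, mean_aa_mmol, se_aa, mean_c_mmol, se_c
    slope: float
    intercept: float
    slope_se: float
    n_diets: int


@dataclass(frozen=True)
class RuleResult:
    """One rule's best-fitting target and its SSE against observed means."""

    rule: Rule
    estimated_target: IntakeTarget
    sse: float
    predicted: Mapping[str, NutrientPoint]
    rank: int
    n_rails_used: int


def rail_from_diet(diet: Diet) -> Rail:
    """The rail of a diet: direction (AA total molarity, sucrose molarity)."""
    return Rail(diet_id=diet.id, u_aa=diet.aa_total_molarity, u_c=diet.sucrose_molarity)


def project_no_interaction(
    T: IntakeTarget, rail: Rail, regulated: Literal["aa", "c"]
) -> NutrientPoint | None:
    """Feed until the regulated nutrient reaches its target coordinate.

    Returns ``None`` (undefined, not an error) when the rail has no component
    in the regulated nutrient, e.g. regulating AA on a sucrose-only rail.
    """
    if regulated == "aa":
        t_reg, u_reg = T.aa, rail.u_aa
    elif regulated == "c":
        t_reg, u_reg = T.c, rail.u_c
    else:
        raise ValueError(f"regulated must be 'aa' or 'c', got {regulated!r}")
    if u_reg == 0:
        return None
    return rail.point_at(t_reg / u_reg)


def project_equal_distance(T: IntakeTarget, rail: Rail) -> NutrientPoint:
    """The rail point where the deficit in one nutrient equals the surplus
    in the other: the intersection of the rail with the slope −1 line
    through T.  Unit-dependent by construction (axes are both in mmol)."""
    denom = rail.u_aa + rail.u_c
    if denom <= 0:
        raise DegenerateRailError("equal-distance projection needs u_aa + u_c > 0")
    return rail.point_at((T.aa + T.c) / denom)


def project_closest(T: IntakeTarget, rail: Rail) -> NutrientPoint:
    """Orthogonal projection of T onto the rail: the Euclidean-nearest
    feasible intake.  Rails and targets are non-negative, so the projection
    scalar is never negative."""
    uu = rail.u_aa**2 + rail.u_c**2
    s = (T.aa * rail.u_aa + T.c * rail.u_c) / uu
    return rail.point_at(s)


def project_rule(rule: Rule, T: IntakeTarget, rail: Rail) -> NutrientPoint | None:
    """Dispatch a rule label to its projection; ``None`` where undefined."""
    if rule == "equal_distance":
        return project_equal_distance(T, rail)
    if rule == "closest_distance":
        return project_closest(T, rail)
    if rule == "no_interaction_aa":
        return project_no_interaction(T, rail, "aa")
    if rule == "no_interaction_c":
        return project_no_interaction(T, rail, "c")
    raise ValueError(f"unknown rule {rule!r}")


def aggregate_intake(intake: pd.DataFrame, diet_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-diet mean ± SE of cumulative intake (the array.csv schema).

    ``intake`` follows the intake.csv schema (one row per cage).  SE is the
    standard error of the per-cage values; NaN for single-cage diets.
    """
    g = intake.groupby("diet_id")
    out = pd.DataFrame(
        {
            "mean_aa_mmol": g["aa_mmol_per_bee"].mean(),
            "se_aa": g["aa_mmol_per_bee"].sem(),
            "mean_c_mmol": g["c_mmol_per_bee"].mean(),
            "se_c": g["c_mmol_per_bee"].sem(),
        }
    )
    if diet_order is not None:
        out = out.reindex(list(diet_order))
    return out.reset_index()


def fit_intake_array(means: pd.DataFrame | Sequence[NutrientPoint]) -> IntakeArray:
    """OLS of mean carbohydrate intake on mean AA intake across diets.

    The regression uses the per-diet means (one point per diet), with the
    slope standard error from residual variance on n − 2 df.
    """
    if isinstance(means, pd.DataFrame):
        df = means.copy()
    else:
        df = pd.DataFrame(
            {
                "diet_id": [str(i) for i in range(len(means))],
                "mean_aa_mmol": [p.aa for p in means],
                "se_aa": np.nan,
                "mean_c_mmol": [p.c for p in means],
                "se_c": np.nan,
            }
        )
    x = df["mean_aa_mmol"].to_numpy(dtype=float)
    y = df["mean_c_mmol"].to_numpy(dtype=float)
    if len(x) < 3 or not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("slope fitting needs >= 3 diets with finite means")
    if np.ptp(x) == 0:
        raise ValueError("undefined slope: all AA means identical (vertical array)")
    res = stats.linregress(x, y)
    return IntakeArray(
        points=df,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        n_diets=len(x),
    )


def slope_test(beta_a: float, se: float, beta_h: float, n_diets: int) -> SlopeTest:
    """Test a fitted slope against a hypothetical one.

    t = (beta_a − beta_h)/SE on n_diets − 2 degrees of freedom, two-tailed.
    An exact fit (SE = 0) yields p = 1 when the slopes agree and p = 0
    otherwise, with ``exact_fit`` set.
    """
    df = n_diets - 2
    if df < 1:
        raise ValueError("slope test needs n_diets >= 3")
    if se < 0:
        raise ValueError("slope SE must be >= 0")
    if se == 0:
        same = beta_a == beta_h
        return SlopeTest(
            beta_a=beta_a,
            beta_h=beta_h,
            se=se,
            t_stat=0.0 if same else np.inf * np.sign(beta_a - beta_h),
            df=df,
            p_two_tailed=1.0 if same else 0.0,
            exact_fit=True,
        )
    t = (beta_a - beta_h) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return SlopeTest(beta_a=beta_a, beta_h=beta_h, se=se, t_stat=float(t), df=df, p_two_tailed=float(p))


def _rule_predictions(
    rule: Rule, ta: np.ndarray, tc: np.ndarray, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized rule projections.

    ``ta``/``tc`` are target coordinate arrays of shape (G,), ``u`` the rail
    directions of shape (R, 2).  Returns predicted points of shape (G, R, 2)
    and a boolean mask of shape (R,) marking rails where the rule is defined.
    """
    ua, uc = u[:, 0], u[:, 1]
    defined = np.ones(len(u), dtype=bool)
    if rule == "equal_distance":
        s = (ta[:, None] + tc[:, None]) / (ua + uc)
    elif rule == "closest_distance":
        s = (ta[:, None] * ua + tc[:, None] * uc) / (ua**2 + uc**2)
    elif rule == "no_interaction_aa":
        defined = ua > 0
        s = np.zeros((len(ta), len(u)))
        s[:, defined] = ta[:, None] / ua[defined]
    elif rule == "no_interaction_c":
        defined = uc > 0
        s = np.zeros((len(ta), len(u)))
        s[:, defined] = tc[:, None] / uc[defined]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    pred = np.stack([s * ua, s * uc], axis=-1)
    return pred, defined


def _rule_sse(rule: Rule, ta: np.ndarray, tc: np.ndarray, u: np.ndarray, obs: np.ndarray) -> np.ndarray:
    pred, defined = _rule_predictions(rule, ta, tc, u)
    resid = pred[:, defined, :] - obs[defined]
    return np.einsum("grk,grk->g", resid, resid)


def classify_rule(
    observed: pd.DataFrame | IntakeArray,
    rails: Sequence[Rail],
    grid_size: int = 200,
    span: tuple[float, float] = (0.25, 4.0),
    rules: Sequence[Rule] = RULES,
) -> list[RuleResult]:
    """Rank rules of compromise by how well any single target explains the
    observed per-diet means.

    For each rule the intake target minimizing the sum of squared distances
    between observed means and rule-predicted rail points is found by a
    log-spaced grid search (``grid_size`` per axis, spanning
    ``span[0]``–``span[1]`` times the observed intake range) followed by
    Nelder–Mead refinement in log-target space.  Rules are ranked by minimized
    SSE; ties break in the order of :data:`RULES`.  Rails on which a rule is
    undefined (no-interaction on an axis rail) are excluded from that rule's
    SSE with a logged note.
    """
    if isinstance(observed, IntakeArray):
        observed = observed.points
    df = observed.set_index("diet_id")
    rails = list(rails)
    ids = [r.diet_id for r in rails]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate rails in panel")
    if len(rails) < 3:
        raise ValueError("rule classification needs >= 3 rails")
    if grid_size < 2:
        raise ValueError("empty or degenerate target grid")
    obs = df.loc[ids, ["mean_aa_mmol", "mean_c_mmol"]].to_numpy(dtype=float)
    u = np.array([[r.u_aa, r.u_c] for r in rails], dtype=float)

    # Grid bounds from the observed intake range, per axis; AA may include a
    # sucrose-only diet at 0, so floor the low end at a small positive value.
    lo = np.maximum(obs.min(axis=0), 1e-12)
    hi = obs.max(axis=0)
    aa_grid = np.geomspace(max(span[0] * lo[0], 1e-9), span[1] * hi[0], grid_size)
    c_grid = np.geomspace(max(span[0] * lo[1], 1e-9), span[1] * hi[1], grid_size)
    TA, TC = np.meshgrid(aa_grid, c_grid, indexing="ij")
    ta, tc = TA.ravel(), TC.ravel()

    results: list[tuple[int, Rule, float, IntakeTarget, dict[str, NutrientPoint]]] = []
    for order, rule in enumerate(rules):
        _, defined = _rule_predictions(rule, ta[:1], tc[:1], u)
        if not defined.all():
            excluded = [ids[i] for i in np.flatnonzero(~defined)]
            log.info("rule %s undefined on rails %s; excluded from its SSE", rule, excluded)
        sse = _rule_sse(rule, ta, tc, u, obs)
        best = int(np.argmin(sse))

        def neg_log_obj(logT: np.ndarray, rule: Rule = rule) -> float:
            t = np.exp(logT)
            return float(_rule_sse(rule, t[:1], t[1:], u, obs)[0])

        opt = optimize.minimize(
            neg_log_obj,
            np.log([ta[best], tc[best]]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 400},
        )
        t_best = np.exp(opt.x)
        sse_best = min(float(opt.fun), float(sse[best]))
        if opt.fun > sse[best]:  # refinement should never lose to the grid
            t_best = np.array([ta[best], tc[best]])
        target = IntakeTarget(aa=float(t_best[0]), c=float(t_best[1]))
        pred, defined = _rule_predictions(rule, t_best[:1], t_best[1:], u)
        predicted = {
            ids[i]: NutrientPoint(*pred[0, i]) for i in range(len(rails)) if defined[i]
        }
        results.append((order, rule, sse_best, target, predicted))

    results.sort(key=lambda r: (r[2], r[0]))
    return [
        RuleResult(
            rule=rule,
            estimated_target=target,
            sse=sse,
            predicted=predicted,
            rank=rank + 1,
            n_rails_used=len(predicted),
        )
        for rank, (order, rule, sse, target, predicted) in enumerate(results)
    ]
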