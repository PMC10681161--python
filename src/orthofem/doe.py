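"""Design-of-experiments engine and population statistics.

The sensitivity study varies the four muscle stiffness parameters (left
and right members of a paired muscle share one value) over literature
ranges using a seeded maximin ("optimal space-filling") Latin hypercube
with 25 design points by default. For every design point the LeFort I
advancement is re-simulated and the total displacement of the four skin
landmarks recorded.

Local sensitivity of landmark L to muscle i is the signed percentage

    S_i(L) = 100 * [Y_L(x_i = max, others mid) - Y_L(x_i = min, others mid)]
                  / Y_L(all mid)

i.e. the output change over the parameter's full range, with the other
parameters held at mid-range, normalized by the all-mid response. A
positive value means the landmark moves further when the muscle
stiffens. Left/right cheek sensitivities are averaged into a single C
value before population aggregation.

Population inference uses the exact Wilcoxon signed-rank test (full
enumeration of sign assignments for n <= 12, normal approximation with
continuity correction beyond that).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import norm, rankdata

from .fem import (
    DEFAULT_ADVANCEMENT,
    DEFAULT_IMPACTION,
    RegionStiffnessCache,
    simulate_advancement,
)
from .materials import (
    DOE_STIFFNESS_RANGES,
    SOFT_TISSUE_E,
    MaterialMap,
    homogeneous_materials,
)
from .phantom import LabeledMesh, LandmarkSet

LANDMARKS_RAW = ("N", "UL", "LC", "RC")
LANDMARKS_AGG = ("N", "C", "UL")


class DoEError(ValueError):
    """Invalid design request or degenerate statistical input."""


class DegenerateSampleError(DoEError):
    """All differences are zero: the signed-rank test is undefined."""


# ---------------------------------------------------------------------------
# design generation


@dataclass(frozen=True)
class DoEDesign:
    """Maximin Latin-hypercube design over the muscle stiffness ranges."""

    parameter_names: tuple[str, ...]
    ranges: dict[str, tuple[float, float]]
    matrix: np.ndarray  # (n_points, n_params), MPa
    seed: int

    @property
    def n_points(self) -> int:
        return len(self.matrix)

    def point(self, i: int) -> dict[str, float]:
        return dict(zip(self.parameter_names, self.matrix[i]))

    def unit_matrix(self) -> np.ndarray:
        lo = np.array([self.ranges[p][0] for p in self.parameter_names])
        hi = np.array([self.ranges[p][1] for p in self.parameter_names])
        return (self.matrix - lo) / (hi - lo)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.parameter_names))


def _stratified_candidate(
    rng: np.random.Generator, n_points: int, n_params: int
) -> np.ndarray:
    """Unit-cube Latin hypercube: one point per stratum midpoint per column."""
    cols = [(rng.permutation(n_points) + 0.5) / n_points for _ in range(n_params)]
    return np.column_stack(cols)


def generate_osf_design(
    ranges: dict[str, tuple[float, float]] | None = None,
    n_points: int = 25,
    seed: int = 0,
    n_candidates: int = 200,
) -> DoEDesign:
    """Seeded maximin Latin hypercube ("optimal space-filling") design.

    ``n_candidates`` stratified designs are drawn; the one maximizing the
    minimum pairwise Euclidean distance in unit-scaled coordinates wins
    (first candidate on ties). Every column places exactly one point at
    each of the ``n_points`` stratum midpoints.
    """
    if ranges is None:
        ranges = dict(DOE_STIFFNESS_RANGES)
    if n_points < 2:
        raise DoEError(f"n_points must be >= 2, got {n_points}")
    for name, (lo, hi) in ranges.items():
        if not lo < hi:
            raise DoEError(f"invalid range for {name}: min {lo} >= max {hi}")
    names = tuple(ranges)
    rng = np.random.default_rng(seed)
    best = None
    best_score = -np.inf
    for _ in range(n_candidates):
        cand = _stratified_candidate(rng, n_points, len(names))
        score = pdist(cand).min()
        if score > best_score:
            best, best_score = cand, score
    lo = np.array([ranges[p][0] for p in names])
    hi = np.array([ranges[p][1] for p in names])
    return DoEDesign(
        parameter_names=names, ranges=dict(ranges), matrix=lo + best * (hi - lo), seed=seed
    )


# ---------------------------------------------------------------------------
# responses

H_ROW = "H"


def run_design(
    mesh: LabeledMesh,
    landmarks: LandmarkSet,
    design: DoEDesign,
    materials_base: MaterialMap | None = None,
    advancement: float = DEFAULT_ADVANCEMENT,
    impaction: float = DEFAULT_IMPACTION,
    cache: RegionStiffnessCache | None = None,
) -> pd.DataFrame:
    """Run the FE simulation at every design point, plus the H model.

    Returns the response table: one row per design point (index ``DP1``
    ...) with the muscle stiffnesses used and each landmark's total
    displacement [mm], and a final ``H`` row where every muscle carries
    the bulk soft-tissue stiffness.
    """
    if materials_base is None:
        materials_base = homogeneous_materials()
    if cache is None:
        cache = RegionStiffnessCache.for_materials(mesh, materials_base)
    rows = []
    index = []
    for i in range(design.n_points):
        stiffness = design.point(i)
        materials = materials_base.with_muscles(stiffness)
        try:
            _, totals = simulate_advancement(
                mesh, landmarks, materials, advancement, impaction, cache
            )
        except Exception as exc:
            raise DoEError(f"solver failed at design point {i + 1}: {exc}") from exc
        rows.append({**stiffness, **totals})
        index.append(f"DP{i + 1}")
    h_stiffness = {p: SOFT_TISSUE_E for p in design.parameter_names}
    _, h_totals = simulate_advancement(
        mesh, landmarks, materials_base.with_muscles(h_stiffness), advancement, impaction, cache
    )
    rows.append({**h_stiffness, **h_totals})
    index.append(H_ROW)
    return pd.DataFrame(rows, index=pd.Index(index, name="point"))


# ---------------------------------------------------------------------------
# local sensitivity


def sensitivity_from_evaluator(
    evaluate: Callable[[dict[str, float]], dict[str, float]],
    ranges: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Signed % sensitivities from a black-box response evaluator.

    ``evaluate`` maps a full parameter assignment to per-output responses.
    Requires 2 * n_params + 1 evaluations. Raises :class:`DoEError` when
    an all-mid response is zero (undefined normalization).
    """
    mid = {p: 0.5 * (lo + hi) for p, (lo, hi) in ranges.items()}
    y_mid = evaluate(mid)
    for out, value in y_mid.items():
        if value == 0:
            raise DoEError(f"all-mid response for {out!r} is zero: sensitivity undefined")
    table = {}
    for p, (lo, hi) in ranges.items():
        y_hi = evaluate({**mid, p: hi})
        y_lo = evaluate({**mid, p: lo})
        table[p] = {out: 100.0 * (y_hi[out] - y_lo[out]) / y_mid[out] for out in y_mid}
    return pd.DataFrame(table).T


def local_sensitivity(
    mesh: LabeledMesh,
    landmarks: LandmarkSet,
    ranges: dict[str, tuple[float, float]] | None = None,
    materials_base: MaterialMap | None = None,
    advancement: float = DEFAULT_ADVANCEMENT,
    impaction: float = DEFAULT_IMPACTION,
    cache: RegionStiffnessCache | None = None,
) -> pd.DataFrame:
    """Per-muscle signed % sensitivity of every landmark for one subject.

    Rows are muscle parameters, columns N, UL, LC, RC plus the averaged
    cheek column C = (LC + RC) / 2. A muscle whose region captures no
    elements changes nothing in the stiffness matrix, so its sensitivity
    is exactly zero.
    """
    if ranges is None:
        ranges = dict(DOE_STIFFNESS_RANGES)
    if materials_base is None:
        materials_base = homogeneous_materials()
    if cache is None:
        cache = RegionStiffnessCache.for_materials(mesh, materials_base)

    def evaluate(stiffness: dict[str, float]) -> dict[str, float]:
        materials = materials_base.with_muscles(stiffness)
        _, totals = simulate_advancement(
            mesh, landmarks, materials, advancement, impaction, cache
        )
        return totals

    table = sensitivity_from_evaluator(evaluate, ranges)
    table["C"] = 0.5 * (table["LC"] + table["RC"])
    return table


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int  # sample size after zero removal


def wilcoxon_signed_rank(
    values: Sequence[float],
    other: Sequence[float] | None = None,
    mu0: float = 0.0,
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test, exact by enumeration for small samples.

    One-sample against ``mu0`` by default; paired when ``other`` is given
    (differences ``values - other``). Zero differences are dropped before
    ranking; tied absolute differences receive average ranks. For n <=
    ``exact_max_n`` the null distribution of W+ is enumerated over all
    2^n sign assignments; otherwise a normal approximation with tie and
    continuity corrections is used. ``alternative`` is ``two-sided``,
    ``greater`` (median difference > 0) or ``less``.
    """
    x = np.asarray(values, dtype=float)
    if other is not None:
        d = x - np.asarray(other, dtype=float)
    else:
        d = x - mu0
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateSampleError("degenerate sample: all differences are zero")
    ranks = rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        W_all = masks @ ranks
        eps = 1e-9
        p_greater = float(np.mean(W_all >= W - eps))
        p_less = float(np.mean(W_all <= W + eps))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = float(((counts**3 - counts).sum())) / 48.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
        p_greater = float(norm.sf((W - mean - 0.5) / sd))
        p_less = float(norm.cdf((W - mean + 0.5) / sd))

    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    elif alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        raise DoEError(f"unknown alternative {alternative!r}")
    return WilcoxonResult(statistic=W, p_value=p, n_used=n)


# ---------------------------------------------------------------------------
# population aggregation


def aggregate_population(
    sensitivities: Sequence[pd.DataFrame], alternative: str = "two-sided"
) -> pd.DataFrame:
    """Population summary of per-subject sensitivity tables.

    Returns one row per landmark (N, C, UL) x muscle with the mean,
    sample SD (n-1), range and a one-sample Wilcoxon p-value against a
    zero median. A muscle that is identically zero in every subject has
    an undefined test: its p-value is reported as NaN.
    """
    if len(sensitivities) == 0:
        raise DoEError("no subjects to aggregate")
    if len(sensitivities) < 2:
        raise DoEError("population aggregation needs >= 2 subjects")
    rows = []
    muscles = list(sensitivities[0].index)
    for landmark in LANDMARKS_AGG:
        for muscle in muscles:
            vals = np.array([s.loc[muscle, landmark] for s in sensitivities], dtype=float)
            try:
                p = wilcoxon_signed_rank(vals, alternative=alternative).p_value
            except DegenerateSampleError:
                p = np.nan
            rows.append(
                {
                    "landmark": landmark,
                    "muscle": muscle,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1),
                    "min": vals.min(),
                    "max": vals.max(),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# comparison with the homogeneous model


@dataclass(frozen=True)
class ComparisonResult:
    """Extremes of the DoE responses vs the homogeneous model.

    ``table`` has one row per subject x landmark (N, UL, C) with the
    max/min displacement over design points, the H value and their
    differences; ``p_values`` has the per-landmark paired Wilcoxon tests
    of H against the max and min responses.
    """

    table: pd.DataFrame
    p_values: pd.DataFrame


def _with_cheek_average(responses: pd.DataFrame) -> pd.DataFrame:
    out = responses.copy()
    out["C"] = 0.5 * (out["LC"] + out["RC"])
    return out


def compare_with_homogeneous(
    responses_per_subject: Sequence[pd.DataFrame], alternative: str = "two-sided"
) -> ComparisonResult:
    """Fig-5-style comparison: DoE extremes against the H model.

    Each input is one subject's response table from :func:`run_design`
    (design-point rows plus the ``H`` row).
    """
    rows = []
    for s, resp in enumerate(responses_per_subject):
        if H_ROW not in resp.index:
            raise DoEError(f"subject {s}: response table is missing the H row")
        if len(resp.index) - 1 < 2:
            raise DoEError(f"subject {s}: need >= 2 design points")
        resp = _with_cheek_average(resp)
        dps = resp.drop(index=H_ROW)
        for landmark in LANDMARKS_AGG:
            mx = float(dps[landmark].max())
            mn = float(dps[landmark].min())
            h = float(resp.loc[H_ROW, landmark])
            rows.append(
                {
                    "subject": s,
                    "landmark": landmark,
                    "max": mx,
                    "min": mn,
                    "H": h,
                    "max_minus_H": mx - h,
                    "min_minus_H": mn - h,
                }
            )
    table = pd.DataFrame(rows)

    def _p(a, b):
        try:
            return wilcoxon_signed_rank(a, b, alternative=alternative).p_value
        except DegenerateSampleError:  # H coincides with the extreme everywhere
            return np.nan

    pvals = []
    for landmark in LANDMARKS_AGG:
        sub = table[table["landmark"] == landmark]
        pvals.append(
            {
                "landmark": landmark,
                "p_H_vs_max": _p(sub["H"].to_numpy(), sub["max"].to_numpy()),
                "p_H_vs_min": _p(sub["H"].to_numpy(), sub["min"].to_numpy()),
            }
        )
    return ComparisonResult(table=table, p_values=pd.DataFrame(pvals))
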