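"""Coalescence dating: the rho statistic, clock-constrained ML divergences,
and the purifying-selection-corrected molecular clock.

The rho statistic is the mean number of (masked) substitutions from a clade's
root haplotype to its sampled tips; its heuristic standard error weights each
edge's mutation count by the square of the number of descendant tips.  The ML
divergence maximises a Poisson likelihood for the observed edge counts on the
fixed tree topology under a molecular clock (all root-to-tip expectations
equal).  Both mutational distances are converted to calendar years with a
time-dependent clock: because purifying selection removes mildly deleterious
mutations only slowly, recent lineages accumulate observable substitutions
faster than old ones, so years-per-substitution grows with distance.

Two clock constructions are provided.  The default is *anchor-calibrated*: a
monotone interpolant through the published whole-mtDNA (distance, age) table
for the N1a1b/I and W clade system, which reproduces that table's arithmetic
at print precision.  The alternative fits the mutation-selection functional
form  rho(t) = mu * [(1-f) t + f (1 - e^(-s t)) / s]  (a neutral fraction
plus an exponentially purged deleterious fraction) to the same anchors,
giving a smooth parametric curve.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, least_squares

from .tree import CladePhylogeny, PhyloNode
from .variants import MtVariant

__all__ = [
    "RhoEstimate",
    "MlEstimate",
    "AgeResult",
    "ClockModel",
    "default_clock",
    "load_age_anchors",
    "rho_sigma",
    "ml_divergence",
    "clock_convert",
    "age_with_ci",
    "age_table",
]

Z95 = 1.96  # normal-theory multiplier for 95% intervals


# ---------------------------------------------------------------------------
# Estimates


@dataclass(frozen=True)
class RhoEstimate:
    clade: str
    n: int
    rho: float
    sigma: float

    def __post_init__(self) -> None:
        if self.n < 1 or self.rho < 0 or self.sigma < 0:
            raise ValueError("invalid rho estimate")


@dataclass(frozen=True)
class MlEstimate:
    clade: str
    n: int
    ml: float
    se: float  # NaN when undefined (single-tip clade)


@dataclass(frozen=True)
class AgeResult:
    clade: str
    method: Literal["rho", "ML"]
    distance: float
    dispersion: float
    age_ky: float
    ci_low_ky: float
    ci_high_ky: float


def _subtree_counts(node: PhyloNode) -> int:
    return sum(1 for v in node.edge_mutations if v.is_substitution)


def rho_sigma(tree: CladePhylogeny, clade_node: PhyloNode | str) -> RhoEstimate:
    """Rho and its heuristic standard error for the clade under a node.

    rho = (1/n) sum over tips of the substitution count on the path from the
    clade node; sigma^2 = (1/n^2) sum over edges of (tips below)^2 * (edge
    substitutions) — exactly the variance of rho if each edge count were an
    independent Poisson draw with its observed mean.
    """
    node = tree.find(clade_node) if isinstance(clade_node, str) else clade_node
    tips = node.tips() if not node.is_tip else [node]
    n = len(tips)
    if n == 0:
        raise ValueError("empty clade")
    total = 0.0
    var = 0.0
    for desc in node.walk():
        if desc is node:
            continue
        m = _subtree_counts(desc)
        n_e = len(desc.tips()) if not desc.is_tip else 1
        total += n_e * m
        var += n_e * n_e * m
    label = (node.label or node.name or "clade") if not isinstance(clade_node, str) else clade_node
    return RhoEstimate(label, n, total / n, math.sqrt(var) / n)


def ml_divergence(tree: CladePhylogeny, clade_node: PhyloNode | str) -> MlEstimate:
    """Clock-constrained Poisson ML divergence of the clade under a node.

    Free parameters are the internal node heights (expected substitutions
    above the tips); each edge's observed masked substitution count is
    Poisson with mean equal to its height span, and all tips sit at height
    zero (the clock constraint).  Returns the fitted root height and a
    profile-likelihood curvature standard error.
    """
    node = tree.find(clade_node) if isinstance(clade_node, str) else clade_node
    label = (node.label or node.name or "clade") if not isinstance(clade_node, str) else clade_node
    tips = node.tips() if not node.is_tip else [node]
    n = len(tips)
    if n == 1:
        k = sum(
            _subtree_counts(d) for d in node.walk() if d is not node
        )
        return MlEstimate(label, 1, float(k), float("nan"))

    internal = [m for m in node.walk() if not m.is_tip]  # preorder: [0] = root
    index = {id(m): i for i, m in enumerate(internal)}
    # per internal node: parent index (None for root), upward edge count,
    # child entries (child internal index or None for a tip, edge count)
    parent_ix: list[int | None] = []
    k_up: list[int] = []
    child_info: list[list[tuple[int | None, int]]] = []
    for m in internal:
        parent_ix.append(index[id(m.parent)] if m is not node else None)
        k_up.append(_subtree_counts(m) if m is not node else 0)
        child_info.append(
            [(index.get(id(c)), _subtree_counts(c)) for c in m.children]
        )
    if sum(k_up) + sum(k for ci in child_info for cj, k in ci if cj is None) == 0:
        return MlEstimate(label, n, 0.0, 0.0)

    m_internal = len(internal)

    def heights(x: np.ndarray, fixed_root: float | None) -> np.ndarray:
        # smooth clock parameterisation: h_root = exp(x0) (or fixed), each
        # other internal height a sigmoid fraction of its parent's height
        h = np.empty(m_internal)
        if fixed_root is None:
            h[0] = math.exp(x[0])
            fracs = x[1:]
        else:
            h[0] = fixed_root
            fracs = x
        from scipy.special import expit

        for i in range(1, m_internal):
            h[i] = h[parent_ix[i]] * expit(fracs[i - 1])
        return h

    def loglik_h(h: np.ndarray) -> float:
        ll = 0.0
        for i in range(m_internal):
            if parent_ix[i] is not None:
                ll += _pois_term(k_up[i], h[parent_ix[i]] - h[i])
            for cj, k in child_info[i]:
                if cj is None:
                    ll += _pois_term(k, h[i])
        return ll

    def heights0() -> np.ndarray:
        h = np.zeros(m_internal)
        for i in range(m_internal - 1, -1, -1):
            h[i] = max(
                (0.0 if cj is None else h[cj]) + max(k, 0.25)
                for cj, k in child_info[i]
            )
        for i in range(1, m_internal):
            h[i] = min(h[i], h[parent_ix[i]] * 0.999)
        return h

    def x_init(fixed_root: float | None) -> np.ndarray:
        h = heights0()
        if fixed_root is not None:
            h = h * min(1.0, fixed_root / max(h[0], 1e-12))
            h[0] = fixed_root
        fr = np.clip(
            [h[i] / max(h[parent_ix[i]], 1e-12) for i in range(1, m_internal)],
            1e-3,
            1 - 1e-3,
        )
        logit = np.log(fr / (1 - fr))
        if fixed_root is None:
            return np.concatenate([[math.log(max(h[0], 1e-6))], logit])
        return logit

    def fit(fixed_root: float | None = None) -> tuple[float, float]:
        from scipy.optimize import minimize

        x0 = x_init(fixed_root)
        if x0.size == 0:  # single internal node with fixed root
            return float(fixed_root), loglik_h(np.array([fixed_root]))

        def obj(x: np.ndarray) -> float:
            return -loglik_h(heights(x, fixed_root))

        res = minimize(
            obj, x0, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-10},
        )
        h = heights(res.x, fixed_root)
        return float(h[0]), -res.fun

    t_hat, ll_hat = fit()
    se = float("nan")
    step = max(0.2, 0.1 * t_hat)
    for _ in range(4):  # widen the stencil until the profile curvature is clean
        lo_t = max(t_hat - step, 1e-9)
        _, ll_lo = fit(lo_t)
        _, ll_hi = fit(t_hat + step)
        curv = (ll_lo - 2 * ll_hat + ll_hi) / step**2
        if curv < 0:
            se = math.sqrt(-1.0 / curv)
            break
        step *= 2
    return MlEstimate(label, n, t_hat, se)


def _pois_term(k: int, lam: float) -> float:
    if lam <= 0:
        return 0.0 if k == 0 else -1e12
    return k * math.log(lam) - lam


# ---------------------------------------------------------------------------
# The corrected molecular clock


def load_age_anchors() -> pd.DataFrame:
    """The packaged published age table for the N1a1b/I and W clades."""
    with resources.as_file(
        resources.files("mitophylo.data").joinpath("age_anchors.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def _tier1_knots(df: pd.DataFrame) -> list[tuple[float, float, float]]:
    """Point anchors: one (distance, age_ky, weight) per printed distance,
    collisions resolved toward the largest clade (rho column preferred),
    made monotone by weighted isotonic regression."""
    from scipy.optimize import isotonic_regression

    pts: dict[float, list[tuple[int, int, float]]] = {}
    for _, r in df.iterrows():
        pts.setdefault(round(float(r.rho), 3), []).append((int(r.n), 0, float(r.rho_age)))
        pts.setdefault(round(float(r.ml), 3), []).append((int(r.n), 1, float(r.ml_age)))
    ds = sorted(pts)
    ages, wts = [], []
    for d in ds:
        grp = sorted(pts[d], key=lambda t: (-t[0], t[1]))
        ages.append(grp[0][2])
        wts.append(float(sum(n for n, _, _ in grp)))
    iso = isotonic_regression(np.array(ages), weights=np.array(wts), increasing=True)
    fitted = iso.x
    # merge runs of equal fitted age into one knot at the weighted mean distance
    knots: list[tuple[float, float, float]] = []
    i = 0
    while i < len(ds):
        j = i
        while j + 1 < len(ds) and fitted[j + 1] == fitted[i]:
            j += 1
        w = sum(wts[i : j + 1])
        d = float(np.average(ds[i : j + 1], weights=wts[i : j + 1]))
        knots.append((d, float(fitted[i]), w))
        i = j + 1
    return knots


_SLOPE_BAND = (2.2, 3.2)  # plausible ky-per-substitution envelope


def _add_ci_knots(df: pd.DataFrame, knots: dict[float, float]) -> None:
    """Insert rho-column CI endpoints (distance = rho +/- 1.96 sigma, age =
    printed bound) where they respect strict monotonicity; endpoints whose
    implied mean rate falls outside the plausible clock band (print-rounding
    artefacts near the origin) are discarded."""
    cand = []
    for _, r in df.iterrows():
        if r.sigma <= 0:
            continue
        lo_d = float(r.rho) - Z95 * float(r.sigma)
        if lo_d > 0:
            cand.append((round(lo_d, 4), float(r.rho_lo), int(r.n)))
        cand.append((round(float(r.rho) + Z95 * float(r.sigma), 4), float(r.rho_hi), int(r.n)))
    cand.sort(key=lambda t: (-t[2], t[0]))
    for d, a, _ in cand:
        if not (_SLOPE_BAND[0] <= a / d <= _SLOPE_BAND[1]):
            continue
        ds = sorted(knots)
        i = bisect.bisect_left(ds, d)
        if i < len(ds) and abs(ds[i] - d) < 1e-9:
            continue
        if (i == 0 or knots[ds[i - 1]] < a) and (i == len(ds) or a < knots[ds[i]]):
            knots[d] = a


class ClockModel:
    """Monotone mapping between whole-mtDNA substitution distances and years.

    ``provenance`` records how the curve was obtained: ``anchor_calibrated``
    (monotone interpolant through the published age-table pairs) or
    ``selection_model`` (fitted neutral + purged-deleterious parametric
    form).  Mapping(0) = 0 and the curve is strictly increasing; distances
    beyond the last anchor extrapolate linearly.
    """

    def __init__(self, distances, ages_ky, provenance: str):
        d = np.asarray(distances, dtype=float)
        a = np.asarray(ages_ky, dtype=float)
        if d[0] != 0.0 or a[0] != 0.0:
            raise ValueError("clock curve must pass through the origin")
        if not (np.all(np.diff(d) > 0) and np.all(np.diff(a) > 0)):
            raise ValueError("clock anchors must be strictly increasing")
        self.provenance = provenance
        self.knot_distances = d
        self.knot_ages_ky = a
        self._f = PchipInterpolator(d, a)
        self._dmax = float(d[-1])
        self._amax = float(a[-1])
        self.slope0_ky = float(self._f.derivative()(0.0))
        self._end_slope = float(self._f.derivative()(self._dmax))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_anchors(cls, anchors: pd.DataFrame | None = None) -> "ClockModel":
        df = anchors if anchors is not None else load_age_anchors()
        tier1 = _tier1_knots(df)
        knots = {d: a for d, a, _ in tier1}
        knots[0.0] = 0.0
        _add_ci_knots(df, knots)
        ds = sorted(knots)
        return cls(ds, [knots[d] for d in ds], "anchor_calibrated")

    @classmethod
    def selection_model(cls, anchors: pd.DataFrame | None = None) -> "ClockModel":
        """Fit rho(t) = mu [(1-f) t + f (1-exp(-s t))/s] to the anchors."""
        df = anchors if anchors is not None else load_age_anchors()
        tier1 = _tier1_knots(df)
        d_obs = np.array([d for d, _, _ in tier1])
        a_obs = np.array([a for _, a, _ in tier1]) * 1000.0  # years
        w = np.sqrt(np.array([wt for _, _, wt in tier1]))

        def rho_of_t(t, mu, f, s):
            return mu * ((1 - f) * t + f * (1 - np.exp(-s * t)) / s)

        def resid(p):
            mu, f, s = p
            return w * (rho_of_t(a_obs, mu, f, s) - d_obs)

        fit = least_squares(
            resid,
            x0=[1 / 2500.0, 0.4, 1e-4],
            bounds=([1e-5, 0.0, 1e-7], [1e-2, 0.95, 1e-2]),
        )
        mu, f, s = fit.x
        t_grid = np.linspace(0, 60000.0, 601)
        d_grid = rho_of_t(t_grid, mu, f, s)
        model = cls(d_grid, t_grid / 1000.0, "selection_model")
        model.params = {"mu": mu, "f": f, "s": s}
        return model

    # -- evaluation ----------------------------------------------------------

    def to_years(self, distance: float, *, allow_negative: bool = False) -> float:
        if distance < 0:
            if not allow_negative:
                raise ValueError(f"negative mutational distance {distance}")
            return 1000.0 * self.slope0_ky * distance
        if distance > self._dmax:
            return 1000.0 * (self._amax + self._end_slope * (distance - self._dmax))
        return 1000.0 * float(self._f(distance))

    def to_distance(self, years: float) -> float:
        """Inverse mapping (substitutions expected after ``years``)."""
        ky = years / 1000.0
        if ky < 0:
            return ky / self.slope0_ky
        if ky >= self._amax:
            return self._dmax + (ky - self._amax) / self._end_slope
        return brentq(lambda d: float(self._f(d)) - ky, 0.0, self._dmax, xtol=1e-12)

    def local_slope_ky(self, distance: float) -> float:
        """ky of age accrued per substitution around ``distance``."""
        if distance <= 0:
            return self.slope0_ky
        if distance >= self._dmax:
            return self._end_slope
        return float(self._f.derivative()(distance))


_DEFAULT_CLOCK: ClockModel | None = None


def default_clock() -> ClockModel:
    global _DEFAULT_CLOCK
    if _DEFAULT_CLOCK is None:
        _DEFAULT_CLOCK = ClockModel.from_anchors()
    return _DEFAULT_CLOCK


def clock_convert(distance: float, model: ClockModel | None = None) -> float:
    """Convert a mutational distance (substitutions) to years."""
    model = model or default_clock()
    return model.to_years(distance)


def age_with_ci(
    est: RhoEstimate | MlEstimate, model: ClockModel | None = None
) -> AgeResult:
    """Normal-theory 95% interval on the distance scale, then converted.

    Bounds are clock images of distance +/- 1.96 * dispersion; a lower bound
    below zero distance is converted as-is (linearly through the origin),
    yielding the negative-age bounds the convention produces for
    high-dispersion clades.
    """
    model = model or default_clock()
    if isinstance(est, RhoEstimate):
        method, d, disp = "rho", est.rho, est.sigma
    else:
        method, d, disp = "ML", est.ml, est.se
    if not math.isnan(disp) and disp < 0:
        raise ValueError("dispersion must be >= 0")
    age = model.to_years(d) / 1000.0
    if math.isnan(disp):
        lo = hi = float("nan")
    else:
        lo = model.to_years(d - Z95 * disp, allow_negative=True) / 1000.0
        hi = model.to_years(d + Z95 * disp) / 1000.0
    return AgeResult(est.clade, method, d, disp, age, lo, hi)


def age_table(
    tree: CladePhylogeny,
    clade_nodes: Sequence[PhyloNode | str],
    model: ClockModel | None = None,
) -> pd.DataFrame:
    """Tabulate ML and rho ages (columns mirroring the published layout)."""
    model = model or default_clock()
    rows = []
    for cn in clade_nodes:
        r = rho_sigma(tree, cn)
        m = ml_divergence(tree, cn)
        ar = age_with_ci(r, model)
        am = age_with_ci(m, model)
        rows.append(
            {
                "clade": r.clade,
                "n": r.n,
                "ml": round(m.ml, 1),
                "se": round(m.se, 1) if not math.isnan(m.se) else float("nan"),
                "ml_age": round(am.age_ky, 1),
                "ml_lo": round(am.ci_low_ky, 1),
                "ml_hi": round(am.ci_high_ky, 1),
                "rho": round(r.rho, 1),
                "sigma": round(r.sigma, 1),
                "rho_age": round(ar.age_ky, 1),
                "rho_lo": round(ar.ci_low_ky, 1),
                "rho_hi": round(ar.ci_high_ky, 1),
            }
        )
    return pd.DataFrame(rows)
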