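"""Constrained three-component mixture designs and Scheffé response models.

The experimental region is the slice of the simplex defined by lower and
upper bounds on each component with the components summing to a fixed
variable total (the remainder of the formulation being fixed components).
Designs are selected from a candidate set (extreme vertices, edge
midpoints, centroid, axial points) by a point-exchange search minimizing
the I-criterion (average scaled prediction variance over the region,
approximated by Monte-Carlo integration).

Response models are Scheffé polynomials — no intercept, terms built from
components coded to sum to one.  L-pseudo coding
``(X_i - L_i) / (T - sum(L))`` is the default; real proportions
``X_i / T`` are available as an alternative.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MixtureConstraints",
    "DesignRun",
    "ResponseModel",
    "CollinearityError",
    "MODEL_ORDERS",
    "scheffe_terms",
    "pseudo_code",
    "decode_pseudo",
    "generate_candidates",
    "i_optimal_design",
    "i_criterion",
    "fit_scheffe",
    "predict",
]

MODEL_ORDERS = ("linear", "quadratic", "special_cubic", "full_cubic")


@dataclass(frozen=True)
class MixtureConstraints:
    """Bounds for the variable mixture components.

    Defaults describe a three-polymer gastroretentive blend: X1 in
    [34, 45]%, X2 in [0, 10]%, X3 in [5, 15]%, with 41% of the
    formulation fixed (drug 40% + lubricant 1%) so the variable total
    is T = 59%.
    """

    names: tuple[str, ...] = ("X1", "X2", "X3")
    lower: tuple[float, ...] = (34.0, 0.0, 5.0)
    upper: tuple[float, ...] = (45.0, 10.0, 15.0)
    fixed: dict[str, float] = field(
        default_factory=lambda: {"drug": 40.0, "lubricant": 1.0}
    )
    total: float = 59.0

    def __post_init__(self) -> None:
        k = len(self.names)
        if not (len(self.lower) == len(self.upper) == k):
            raise ValueError("names, lower and upper must have equal length")
        if any(lo > hi for lo, hi in zip(self.lower, self.upper)):
            raise ValueError("each lower bound must not exceed its upper bound")
        if not (sum(self.lower) <= self.total <= sum(self.upper)):
            raise ValueError(
                f"variable total {self.total} outside [{sum(self.lower)}, "
                f"{sum(self.upper)}] — empty region"
            )
        fixed_sum = sum(self.fixed.values())
        if abs(fixed_sum + self.total - 100.0) > 1e-9:
            raise ValueError(
                f"fixed components ({fixed_sum}%) plus variable total "
                f"({self.total}%) must equal 100%"
            )

    @property
    def n_components(self) -> int:
        return len(self.names)

    @property
    def pseudo_range(self) -> float:
        return self.total - sum(self.lower)

    def contains(self, x, tol: float = 1e-9) -> bool:
        x = np.asarray(x, dtype=float)
        if abs(x.sum() - self.total) > max(tol, 0.2):
            return False
        return bool(
            np.all(x >= np.array(self.lower) - tol)
            and np.all(x <= np.array(self.upper) + tol)
        )


@dataclass(frozen=True)
class DesignRun:
    label: str
    composition: tuple[float, ...]
    coded: tuple[float, ...]
    replicate_group: int = 0


def pseudo_code(composition, constraints: MixtureConstraints) -> np.ndarray:
    """L-pseudo coding: X_i' = (X_i - L_i) / (T - sum(L)); codes sum to 1."""
    x = np.asarray(composition, dtype=float)
    if abs(x.sum() - constraints.total) > 0.2:
        raise ValueError(
            f"composition sums to {x.sum()}, expected {constraints.total}"
        )
    lo = np.array(constraints.lower)
    hi = np.array(constraints.upper)
    if np.any(x < lo - 0.2) or np.any(x > hi + 0.2):
        raise ValueError(f"composition {tuple(x)} violates the bounds")
    rng = constraints.pseudo_range
    if rng <= 0:
        raise ValueError("degenerate region: lower bounds consume the total")
    coded = (x - lo) / rng
    return coded / coded.sum() if coded.sum() > 0 else coded


def real_code(composition, constraints: MixtureConstraints) -> np.ndarray:
    """Real-proportion coding: X_i' = X_i / T."""
    x = np.asarray(composition, dtype=float)
    return x / constraints.total


def decode_pseudo(coded, constraints: MixtureConstraints) -> np.ndarray:
    coded = np.asarray(coded, dtype=float)
    return np.array(constraints.lower) + coded * constraints.pseudo_range


def _code(composition, constraints: MixtureConstraints, coding: str) -> np.ndarray:
    if coding == "pseudo":
        return pseudo_code(composition, constraints)
    if coding == "real":
        return real_code(composition, constraints)
    raise ValueError(f"unknown coding {coding!r}; use 'pseudo' or 'real'")


# ---------------------------------------------------------------------------
# candidate geometry

def _extreme_vertices(constraints: MixtureConstraints) -> np.ndarray:
    """Extreme vertices of the bounded simplex slice (XVERT-style
    enumeration: fix each subset of components at a bound, solve the rest
    from the total, keep feasible unique points)."""
    k = constraints.n_components
    lo, hi, T = np.array(constraints.lower), np.array(constraints.upper), constraints.total
    verts: list[tuple[float, ...]] = []
    # for 3 components vertices have >= k-1 active constraints: enumerate
    # each component set at each bound combination, remaining one solved.
    for free in range(k):
        others = [j for j in range(k) if j != free]
        for bounds in itertools.product(*[[lo[j], hi[j]] for j in others]):
            x = np.empty(k)
            for j, b in zip(others, bounds):
                x[j] = b
            x[free] = T - sum(bounds)
            if lo[free] - 1e-9 <= x[free] <= hi[free] + 1e-9:
                verts.append(tuple(np.round(x, 10)))
    unique = sorted(set(verts))
    if not unique:
        raise ValueError("empty experimental region: no feasible vertices")
    return np.array(unique)


def _order_polygon(verts: np.ndarray) -> np.ndarray:
    """Order 3-component region vertices around their centroid (the region
    is a polygon in the simplex plane)."""
    if len(verts) <= 2:
        return verts
    c = verts.mean(axis=0)
    # project onto two in-plane axes
    u = np.array([1.0, -1.0, 0.0]) / math.sqrt(2)
    v = np.array([1.0, 1.0, -2.0]) / math.sqrt(6)
    ang = np.arctan2((verts - c) @ v, (verts - c) @ u)
    return verts[np.argsort(ang)]


def generate_candidates(constraints: MixtureConstraints) -> np.ndarray:
    """Candidate design points: extreme vertices, edge midpoints, overall
    centroid and axial check points (midway centroid-to-vertex)."""
    verts = _order_polygon(_extreme_vertices(constraints))
    points = [tuple(v) for v in verts]
    n = len(verts)
    centroid = verts.mean(axis=0)
    if n >= 2:
        for i in range(n):
            mid = (verts[i] + verts[(i + 1) % n]) / 2.0
            points.append(tuple(mid))
            if n == 2:
                break
    if n >= 3:
        points.append(tuple(centroid))
        for v in verts:
            points.append(tuple((v + centroid) / 2.0))
    uniq = sorted(set(tuple(np.round(p, 10)) for p in points))
    cands = np.array(uniq)
    keep = [constraints.contains(c, tol=1e-6) for c in cands]
    return cands[np.array(keep)]


# ---------------------------------------------------------------------------
# Scheffé model terms

def scheffe_terms(order: str, names=("X1", "X2", "X3")) -> list[str]:
    """Term labels for a 3-component Scheffé polynomial of the given order."""
    if order not in MODEL_ORDERS:
        raise ValueError(f"unknown model order {order!r}")
    a, b, c = names
    terms = [a, b, c]
    if order == "linear":
        return terms
    pairs = [(a, b), (a, c), (b, c)]
    terms += [f"{i}*{j}" for i, j in pairs]
    if order == "quadratic":
        return terms
    terms += [f"{a}*{b}*{c}"]
    if order == "special_cubic":
        return terms
    terms += [f"{i}*{j}*({i}-{j})" for i, j in pairs]
    return terms


def _design_matrix(coded: np.ndarray, order: str) -> np.ndarray:
    x = np.atleast_2d(np.asarray(coded, dtype=float))
    x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
    cols = [x1, x2, x3]
    if order in ("quadratic", "special_cubic", "full_cubic"):
        cols += [x1 * x2, x1 * x3, x2 * x3]
    if order in ("special_cubic", "full_cubic"):
        cols += [x1 * x2 * x3]
    if order == "full_cubic":
        cols += [
            x1 * x2 * (x1 - x2),
            x1 * x3 * (x1 - x3),
            x2 * x3 * (x2 - x3),
        ]
    return np.column_stack(cols)


def n_terms(order: str) -> int:
    return {"linear": 3, "quadratic": 6, "special_cubic": 7, "full_cubic": 10}[order]


# ---------------------------------------------------------------------------
# I-optimal point exchange

def _region_sample(
    constraints: MixtureConstraints, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample of feasible compositions (rejection from the Dirichlet
    parameterization of the pseudo simplex)."""
    out = np.empty((n, 3))
    filled = 0
    lo = np.array(constraints.lower)
    rngspan = constraints.pseudo_range
    while filled < n:
        m = max(2 * (n - filled), 64)
        coded = rng.dirichlet(np.ones(3), size=m)
        x = lo + coded * rngspan
        ok = np.array([constraints.contains(xi, tol=1e-9) for xi in x])
        take = x[ok][: n - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)
    return out


def i_criterion(
    design_coded: np.ndarray, sample_coded: np.ndarray, order: str
) -> float:
    """Average scaled prediction variance of a design over a region sample;
    +inf for singular moment matrices."""
    F = _design_matrix(design_coded, order)
    M = F.T @ F
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        return float("inf")
    if np.linalg.cond(M) > 1e12:
        return float("inf")
    G = _design_matrix(sample_coded, order)
    # n * f'(x) M^-1 f(x), averaged
    return float(len(F) * np.mean(np.einsum("ij,jk,ik->i", G, Minv, G)))


def i_optimal_design(
    constraints: MixtureConstraints,
    order: str = "quadratic",
    n_runs: int = 16,
    n_replicates: int = 0,
    seed: int = 0,
    candidates: np.ndarray | None = None,
    n_region_samples: int = 2000,
    max_passes: int = 50,
    coding: str = "pseudo",
) -> list[DesignRun]:
    """Select an I-optimal design by first-improvement point exchange.

    ``n_runs - n_replicates`` distinct support points are chosen from the
    candidate set; the ``n_replicates`` points with the highest prediction
    variance are then duplicated.  Deterministic for a fixed seed and
    candidate order.
    """
    p = n_terms(order)
    n_distinct = n_runs - n_replicates
    if n_distinct < p:
        raise ValueError(
            f"{n_distinct} distinct runs cannot estimate {p} model terms "
            f"({order} order)"
        )
    if candidates is None:
        candidates = generate_candidates(constraints)
    cand_coded = np.array([_code(c, constraints, coding) for c in candidates])
    rng = np.random.default_rng(seed)
    sample = _region_sample(constraints, n_region_samples, rng)
    sample_coded = np.array([_code(s, constraints, coding) for s in sample])

    nc = len(candidates)
    if n_distinct > nc:
        raise ValueError(f"need {n_distinct} distinct points but only {nc} candidates")
    idx = list(rng.choice(nc, size=n_distinct, replace=False))
    best = i_criterion(cand_coded[idx], sample_coded, order)
    # greedy restarts from random selections until invertible
    tries = 0
    while not math.isfinite(best) and tries < 200:
        idx = list(rng.choice(nc, size=n_distinct, replace=False))
        best = i_criterion(cand_coded[idx], sample_coded, order)
        tries += 1
    if not math.isfinite(best):
        raise ValueError("could not find a non-singular starting design")

    for _ in range(max_passes):
        improved = False
        for pos in range(n_distinct):
            for j in range(nc):
                if j in idx:
                    continue
                trial = list(idx)
                trial[pos] = j
                crit = i_criterion(cand_coded[trial], sample_coded, order)
                if crit < best - 1e-12:
                    idx, best = trial, crit
                    improved = True
                    break
        if not improved:
            break

    chosen = sorted(idx)
    F = _design_matrix(cand_coded[chosen], order)
    Minv = np.linalg.inv(F.T @ F)
    pv = np.einsum("ij,jk,ik->i", F, Minv, F)
    # replicate the highest-variance support points
    rep_order = np.argsort(-pv, kind="stable")
    rep_targets = [chosen[i] for i in rep_order[:n_replicates]]

    runs: list[DesignRun] = []
    group = 0
    for ci in chosen:
        group += 1
        comp = tuple(candidates[ci])
        coded = tuple(_code(comp, constraints, coding))
        runs.append(DesignRun(f"R{len(runs) + 1}", comp, coded, group))
        if ci in rep_targets:
            runs.append(DesignRun(f"R{len(runs) + 1}", comp, coded, group))
    return runs


# ---------------------------------------------------------------------------
# Scheffé model fitting

class CollinearityError(ValueError):
    """Raised when the term matrix is rank deficient; names aliased terms."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"rank-deficient Scheffé term matrix; aliased terms: {aliased}")


@dataclass(frozen=True)
class ResponseModel:
    """A fitted Scheffé polynomial for one response."""

    response: str
    order: str
    terms: tuple[str, ...]
    coefficients: tuple[float, ...]
    coding: str
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    residuals: tuple[float, ...]
    constraints: MixtureConstraints = field(default_factory=MixtureConstraints)

    def to_json(self, **kw) -> str:
        d = {
            "response": self.response,
            "order": self.order,
            "coding": self.coding,
            "terms": dict(zip(self.terms, self.coefficients)),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
        }
        return json.dumps(d, **kw)


def fit_scheffe(
    compositions,
    responses,
    order: str = "linear",
    constraints: MixtureConstraints | None = None,
    coding: str = "pseudo",
    response_name: str = "y",
    precoded: bool = False,
) -> ResponseModel:
    """Least-squares fit of a Scheffé polynomial (no intercept).

    ``compositions`` are raw percentages (coded internally) unless
    ``precoded`` is set.  R² is computed about the response mean, the
    convention used by mixture-design software for no-intercept models.
    """
    from scipy import stats

    if constraints is None:
        constraints = MixtureConstraints()
    y = np.asarray(responses, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    comps = np.atleast_2d(np.asarray(compositions, dtype=float))
    coded = comps if precoded else np.array(
        [_code(c, constraints, coding) for c in comps]
    )
    F = _design_matrix(coded, order)
    n, p = F.shape
    if n < p:
        raise ValueError(f"{n} runs cannot estimate {p} terms")
    rank = np.linalg.matrix_rank(F)
    labels = scheffe_terms(order)
    if rank < p:
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(F, pivoting=True)
        aliased = [labels[j] for j in piv[rank:]]
        raise CollinearityError(sorted(aliased))
    beta, _, _, _ = np.linalg.lstsq(F, y, rcond=None)
    fitted = F @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 1e-300:
        r2 = adj_r2 = float("nan")
        fstat = pval = float("nan")
    else:
        r2 = 1.0 - sse / sst
        adj_r2 = (
            1.0 - (sse / (n - p)) * (n - 1) / sst if n > p else float("nan")
        )
        if n > p and sse > 1e-300:
            fstat = ((sst - sse) / (p - 1)) / (sse / (n - p))
            pval = float(stats.f.sf(fstat, p - 1, n - p))
        else:
            fstat, pval = float("inf"), 0.0
    return ResponseModel(
        response=response_name,
        order=order,
        terms=tuple(labels),
        coefficients=tuple(float(b) for b in beta),
        coding=coding,
        r_squared=r2,
        adj_r_squared=adj_r2,
        f_statistic=float(fstat),
        f_pvalue=float(pval),
        residuals=tuple(float(r) for r in resid),
        constraints=constraints,
    )


def select_order(
    compositions, responses, constraints: MixtureConstraints | None = None,
    coding: str = "pseudo", response_name: str = "y",
) -> ResponseModel:
    """Fit every estimable order and keep the highest adjusted R²."""
    best: ResponseModel | None = None
    for order in MODEL_ORDERS:
        try:
            m = fit_scheffe(
                compositions, responses, order, constraints, coding, response_name
            )
        except (ValueError, CollinearityError):
            continue
        if not math.isfinite(m.adj_r_squared):
            continue
        if best is None or m.adj_r_squared > best.adj_r_squared:
            best = m
    if best is None:
        raise ValueError("no model order was estimable for this design")
    return best


def predict(model: ResponseModel, composition, precoded: bool = False) -> float:
    """Evaluate a fitted Scheffé polynomial at a composition (raw
    percentages unless ``precoded``)."""
    coded = (
        np.asarray(composition, dtype=float)
        if precoded
        else _code(composition, model.constraints, model.coding)
    )
    F = _design_matrix(coded, model.order)
    return float((F @ np.asarray(model.coefficients))[0])
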