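"""Design and penalty matrices for structured additive terms.

Every term of the latent predictor is represented by a
:class:`TermBlock`: a design matrix, a symmetric positive
semi-definite penalty whose quadratic form is the (improper) Gaussian
prior on the block coefficients, and bookkeeping for the penalty rank
and nullspace.  Block types:

``parametric``  dummy/linear columns, zero penalty (diffuse prior);
``pspline``     B-spline basis with a difference (random-walk) penalty;
``mrf``         zone incidence with the contiguity-graph Laplacian
                (intrinsic Gaussian Markov random field);
``tensor``      row-wise tensor product of two marginal B-spline bases
                with the Kronecker-sum difference penalty;
``iid``         zone incidence with an identity penalty (exchangeable
                Gaussian zone effects).

Sum-to-zero identifiability constraints are absorbed into the design by
an orthonormal reparameterization (:func:`absorb_constraint`), exactly
as done by standard additive-model software.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _replace

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "TermBlock",
    "bspline_design",
    "diff_penalty",
    "mrf_penalty",
    "tensor_design",
    "iid_block",
    "absorb_constraint",
    "penalty_rank",
    "penalty_nullspace",
]

_PSD_TOL = 1e-10


def penalty_rank(K: np.ndarray, tol: float = 1e-9) -> int:
    """Numerical rank of a symmetric PSD penalty."""
    if K.size == 0:
        return 0
    ev = np.linalg.eigvalsh((K + K.T) / 2)
    scale = max(ev.max(), 1.0)
    return int(np.sum(ev > tol * scale))


def penalty_nullspace(K: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Orthonormal basis (p x d) of the penalty nullspace."""
    ev, U = np.linalg.eigh((K + K.T) / 2)
    scale = max(ev.max(), 1.0)
    return U[:, ev <= tol * scale]


@dataclass
class TermBlock:
    """One additive term: design, penalty and prior bookkeeping.

    ``transform`` maps reduced (constrained) coefficients back to the
    original coefficient space; it is the identity until
    :func:`absorb_constraint` is applied.  ``tau2`` is the prior
    variance of the penalized coefficient increments; ``None`` marks an
    unpenalized (parametric) block.
    """

    name: str
    design: np.ndarray
    penalty: np.ndarray
    kind: str
    tau2: float | None = 1.0
    rank: int = -1
    nullspace_dim: int = -1
    transform: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.design = np.asarray(self.design, dtype=float)
        self.penalty = np.asarray(self.penalty, dtype=float)
        p = self.design.shape[1]
        if self.penalty.shape != (p, p):
            raise ValueError(
                f"term {self.name!r}: penalty shape {self.penalty.shape} "
                f"does not match {p} design columns"
            )
        if not np.allclose(self.penalty, self.penalty.T, atol=1e-8):
            raise ValueError(f"term {self.name!r}: penalty not symmetric")
        if p:
            ev_min = np.linalg.eigvalsh((self.penalty + self.penalty.T) / 2).min()
            if ev_min < -_PSD_TOL * max(1.0, abs(ev_min)):
                raise ValueError(f"term {self.name!r}: penalty not PSD (min eig {ev_min:g})")
        if self.rank < 0:
            self.rank = penalty_rank(self.penalty)
        if self.nullspace_dim < 0:
            self.nullspace_dim = p - self.rank

    @property
    def p(self) -> int:
        return self.design.shape[1]

    def full_coefficients(self, beta_reduced: np.ndarray) -> np.ndarray:
        """Map reduced coefficients to the original coefficient space."""
        if self.transform is None:
            return np.asarray(beta_reduced, dtype=float)
        return self.transform @ beta_reduced


def bspline_design(
    x: np.ndarray, n_knots: int = 20, degree: int = 3, knots: np.ndarray | None = None
):
    """B-spline basis on equally spaced knots spanning [min(x), max(x)].

    ``n_knots`` counts the distinct knots including both boundaries, so
    the basis has ``(n_knots - 1) + degree`` columns (22 for the
    defaults 20 knots / degree 3).  Returns ``(B, knots)`` where
    ``knots`` are the distinct interior+boundary knots (pass them back
    in to evaluate the same basis on a prediction grid).  Rows form a
    partition of unity on the closed interval.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if knots is None:
        lo, hi = float(x.min()), float(x.max())
        if not lo < hi:
            raise ValueError(
                "x is constant; a constant covariate cannot be smoothed - "
                "treat it parametrically"
            )
        if n_knots < 2:
            raise ValueError("need at least 2 knots")
        if degree >= 2 and n_knots < 4:
            raise ValueError("need at least 4 knots for a smooth basis")
        knots = np.linspace(lo, hi, n_knots)
    else:
        knots = np.asarray(knots, dtype=float)
        lo, hi = float(knots[0]), float(knots[-1])
    if x.min() < lo - 1e-12 or x.max() > hi + 1e-12:
        raise ValueError("x outside the knot range; extrapolation refused")
    t = np.concatenate([np.full(degree, lo), knots, np.full(degree, hi)])
    # clamp the right endpoint so the last basis function is evaluated
    # by its left-continuous limit (standard closed-interval convention)
    xe = np.clip(x, lo, np.nextafter(hi, lo)) if degree == 0 else np.clip(x, lo, hi)
    B = BSpline.design_matrix(xe, t, degree, extrapolate=False).toarray()
    return B, knots


def diff_penalty(p: int, order: int = 2) -> np.ndarray:
    """Random-walk penalty K = D'D with the order-th difference matrix D.

    Rank ``p - order``; the nullspace holds polynomials up to degree
    ``order - 1`` in the coefficient index (constants for order 1,
    constants and linear sequences for order 2).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if p <= order:
        raise ValueError(f"need p > order, got p={p}, order={order}")
    D = np.diff(np.eye(p), n=order, axis=0)
    return D.T @ D


def mrf_penalty(g) -> np.ndarray:
    """Graph Laplacian of the zone contiguity graph.

    ``K[i, i]`` is the number of neighbours of zone i and
    ``K[i, j] = -1`` iff zones i and j share a boundary.  Rank equals
    ``n_zones - n_components``; islands contribute zero rows.
    """
    A = g.adjacency()
    return np.diag(A.sum(axis=1)) - A


def tensor_design(
    lon: np.ndarray,
    lat: np.ndarray,
    n_knots: int = 8,
    degree: int = 3,
    order: int = 1,
):
    """Two-dimensional P-spline over (lon, lat).

    Coordinates are standardized to [0, 1] per axis before knot
    placement.  The design is the row-wise tensor (per-observation
    Kronecker) product of the marginal bases; the penalty is the
    Kronecker sum ``K_lon (x) I + I (x) K_lat`` with difference
    penalties of the given ``order`` on each margin (first-order
    random-walk by default).  Returns ``(B, K, meta)``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    for name, v in (("lon", lon), ("lat", lat)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite")
        if v.min() == v.max():
            raise ValueError(f"all centroids collinear on {name}; 2D smooth undefined")
    u = (lon - lon.min()) / (lon.max() - lon.min())
    v = (lat - lat.min()) / (lat.max() - lat.min())
    B1, k1 = bspline_design(u, n_knots=n_knots, degree=degree)
    B2, k2 = bspline_design(v, n_knots=n_knots, degree=degree)
    p, q = B1.shape[1], B2.shape[1]
    B = (B1[:, :, None] * B2[:, None, :]).reshape(len(lon), p * q)
    K = np.kron(diff_penalty(p, order), np.eye(q)) + np.kron(
        np.eye(p), diff_penalty(q, order)
    )
    meta = {
        "p_lon": p, "p_lat": q, "knots_lon": k1, "knots_lat": k2,
        "degree": degree, "order": order,
        "lon_range": (float(lon.min()), float(lon.max())),
        "lat_range": (float(lat.min()), float(lat.max())),
    }
    return B, K, meta


def iid_block(zone_of_record, g, name: str = "zone_iid") -> TermBlock:
    """Exchangeable Gaussian zone effects: incidence design, identity penalty."""
    idx = g.index()
    zones = list(zone_of_record)
    unknown = set(zones) - set(idx)
    if unknown:
        raise ValueError(f"records reference zones not in graph: {sorted(unknown)[:5]}")
    n, N = len(zones), g.n_zones
    design = np.zeros((n, N))
    design[np.arange(n), [idx[z] for z in zones]] = 1.0
    return TermBlock(
        name=name, design=design, penalty=np.eye(N), kind="iid",
        meta={"zones": list(g.zone_ids)},
    )


def absorb_constraint(block: TermBlock, constraint: np.ndarray | None = None) -> TermBlock:
    """Absorb a single linear constraint c'beta = 0 into the block.

    By default ``c = design' 1`` (the fitted term sums to zero over the
    observations); spatial blocks pass a zone-level constraint instead.
    The design is post-multiplied by an orthonormal basis Z of the
    nullspace of c', dropping exactly one column; the penalty becomes
    ``Z' K Z`` and ``transform`` accumulates Z so original-space
    coefficients remain recoverable.  A zero constraint vector (already
    absorbed) returns the block unchanged.
    """
    c = block.design.sum(axis=0) if constraint is None else np.asarray(constraint, float)
    if c.shape != (block.p,):
        raise ValueError(f"constraint length {c.shape} != {block.p} columns")
    nrm = np.linalg.norm(c)
    if nrm < 1e-12:
        return block
    Q, _ = np.linalg.qr(np.column_stack([c / nrm]), mode="complete")
    Z = Q[:, 1:]
    new_transform = Z if block.transform is None else block.transform @ Z
    Kz = Z.T @ block.penalty @ Z
    Kz = (Kz + Kz.T) / 2
    return _replace(
        block,
        design=block.design @ Z,
        penalty=Kz,
        transform=new_transform,
        rank=-1,
        nullspace_dim=-1,
        meta={**block.meta, "constrained": True},
    )
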