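"""Clustered-data designs, weighting schemes and contrast matrices.

The data model is a one-way layout with ``d`` independent samples (groups).
Each group consists of independent clusters (e.g. patients), and each cluster
holds one or more possibly correlated replicate observations (e.g. the two
brain hemispheres of one patient).  All inference downstream is rank-based, so
values may be metric, ordinal (numeric codes) or dichotomous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClusteredDesign",
    "WeightScheme",
    "ContrastMatrix",
    "DesignError",
    "build_design",
    "design_from_frame",
    "read_design_csv",
    "make_scheme",
    "contrast",
    "read_contrast_csv",
]


class DesignError(ValueError):
    """Invalid input data or weights."""


@dataclass(frozen=True)
class ClusteredDesign:
    """``d`` independent samples of independent clusters of observations.

    Attributes
    ----------
    groups : tuple
        Ordered group labels, length ``d``.
    clusters : tuple of tuples of ndarray
        ``clusters[i][j]`` is the 1-d array of the ``m_ij`` observations of
        cluster ``j`` in group ``i``.
    cluster_ids : tuple of tuples
        Parallel labels for the clusters (opaque; unique within a group).
    """

    groups: tuple
    clusters: tuple
    cluster_ids: tuple

    def __post_init__(self):
        if len(self.groups) < 2:
            raise DesignError("need >=2 groups")
        if len(self.groups) != len(self.clusters):
            raise DesignError("groups and clusters length mismatch")
        for i, gcl in enumerate(self.clusters):
            if len(gcl) < 1:
                raise DesignError(f"group {self.groups[i]!r} has no clusters")
            for j, vec in enumerate(gcl):
                if len(vec) < 1:
                    raise DesignError(
                        f"cluster {self.cluster_ids[i][j]!r} in group "
                        f"{self.groups[i]!r} is empty"
                    )
                if not np.all(np.isfinite(vec)):
                    raise DesignError(
                        f"non-finite value in group {self.groups[i]!r}, "
                        f"cluster {self.cluster_ids[i][j]!r}"
                    )

    # ------------------------------------------------------------------ counts
    @property
    def d(self) -> int:
        return len(self.groups)

    @property
    def n_i(self) -> np.ndarray:
        """Number of clusters per group."""
        return np.array([len(g) for g in self.clusters])

    @property
    def n(self) -> int:
        """Total number of clusters."""
        return int(self.n_i.sum())

    @property
    def m(self) -> tuple:
        """Cluster sizes ``m_ij`` as a tuple of arrays, one per group."""
        return tuple(np.array([len(v) for v in g]) for g in self.clusters)

    @property
    def M_i(self) -> np.ndarray:
        """Number of observations per group."""
        return np.array([sum(len(v) for v in g) for g in self.clusters])

    @property
    def M(self) -> int:
        """Total number of observations."""
        return int(self.M_i.sum())

    def transform(self, fn) -> "ClusteredDesign":
        """Apply an elementwise (typically strictly monotone) map to values."""
        new = tuple(
            tuple(np.asarray(fn(v), dtype=float) for v in g) for g in self.clusters
        )
        return ClusteredDesign(self.groups, new, self.cluster_ids)


def build_design(
    rows: Iterable[tuple],
    group_order: Optional[Sequence] = None,
) -> ClusteredDesign:
    """Assemble a :class:`ClusteredDesign` from long-format rows.

    Parameters
    ----------
    rows : iterable of (group, cluster_id, value)
        One entry per individual observation.
    group_order : sequence, optional
        Explicit group ordering; defaults to order of first appearance.
    """
    by_group: dict = {}
    order: list = []
    for idx, row in enumerate(rows):
        try:
            g, c, v = row
        except Exception as exc:  # malformed row
            raise DesignError(f"row {idx}: expected (group, cluster, value)") from exc
        v = float(v)
        if not np.isfinite(v):
            raise DesignError(f"row {idx}: non-finite value for group {g!r}, cluster {c!r}")
        if g not in by_group:
            by_group[g] = {}
            order.append(g)
        by_group[g].setdefault(c, []).append(v)
    if len(order) < 2:
        raise DesignError("need >=2 groups")
    if group_order is not None:
        missing = [g for g in order if g not in list(group_order)]
        if missing:
            raise DesignError(f"group_order does not cover groups {missing}")
        order = [g for g in group_order if g in by_group]
    clusters = tuple(
        tuple(np.asarray(by_group[g][c], dtype=float) for c in by_group[g])
        for g in order
    )
    ids = tuple(tuple(by_group[g].keys()) for g in order)
    return ClusteredDesign(tuple(order), clusters, ids)


def design_from_frame(
    df: pd.DataFrame,
    group: str = "group",
    cluster: str = "cluster",
    value: str = "value",
    group_order: Optional[Sequence] = None,
) -> ClusteredDesign:
    """Build a design from a long-format DataFrame."""
    for col in (group, cluster, value):
        if col not in df.columns:
            raise DesignError(f"missing column {col!r}")
    return build_design(
        zip(df[group].tolist(), df[cluster].tolist(), df[value].tolist()),
        group_order=group_order,
    )


def read_design_csv(path, **kwargs) -> ClusteredDesign:
    """Read a ``group,cluster,value`` CSV into a design."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DesignError(f"cannot parse {path}: {exc}") from exc
    return design_from_frame(df, **kwargs)


# ---------------------------------------------------------------------------
# weighting schemes


@dataclass(frozen=True)
class WeightScheme:
    """Weights defining the relative effect and its estimator.

    ``omega[i][j]`` weights observations within cluster ``(i, j)`` (sums to 1),
    ``psi[i]`` weights clusters within group ``i`` (sums to 1), ``theta``
    weights the group distributions in the reference mixture ``F_theta``
    (sums to 1), and ``g_n`` is the rate normalisation of the limit theorem
    (number of clusters ``n`` for the unweighted preset, total observation
    count ``M`` for the weighted one).
    """

    omega: tuple
    psi: tuple
    theta: np.ndarray
    g_n: float
    name: str = "custom"

    def __post_init__(self):
        tol = 1e-12
        th = np.asarray(self.theta, dtype=float)
        if np.any(th < -tol) or abs(th.sum() - 1.0) > 1e-8:
            raise DesignError("theta must be non-negative and sum to 1")
        for i, ps in enumerate(self.psi):
            ps = np.asarray(ps, dtype=float)
            if np.any(ps < -tol):
                raise DesignError(f"psi[{i}] has a negative entry")
            if abs(ps.sum() - 1.0) > 1e-8:
                raise DesignError(f"psi[{i}] does not sum to 1")
        for i, grp in enumerate(self.omega):
            for j, om in enumerate(grp):
                om = np.asarray(om, dtype=float)
                if np.any(om < -tol):
                    raise DesignError(f"omega[{i}][{j}] has a negative entry")
                if abs(om.sum() - 1.0) > 1e-8:
                    raise DesignError(f"omega[{i}][{j}] does not sum to 1")
        if not self.g_n > 0:
            raise DesignError("g_n must be positive")


def make_scheme(
    design: ClusteredDesign,
    preset: str = "unweighted",
    omega: Optional[Sequence] = None,
    psi: Optional[Sequence] = None,
    theta: Optional[Sequence] = None,
    g_n: Optional[float] = None,
) -> WeightScheme:
    """Construct a :class:`WeightScheme` for a design.

    ``preset="unweighted"`` (pseudo-rank): omega_ijk = 1/m_ij, psi_ij = 1/n_i,
    theta_i = 1/d, g_n = n.  ``preset="weighted"`` (classical ranks):
    omega_ijk = 1/m_ij, psi_ij = m_ij/M_i, theta_i = M_i/M, g_n = M.
    ``preset="custom"`` takes user weights, falling back to the unweighted
    choices for any component not supplied.
    """
    d = design.d
    n_i = design.n_i
    M_i = design.M_i
    m = design.m
    if preset == "unweighted":
        om = tuple(tuple(np.full(mm, 1.0 / mm) for mm in mi) for mi in m)
        ps = tuple(np.full(k, 1.0 / k) for k in n_i)
        th = np.full(d, 1.0 / d)
        g = float(design.n)
    elif preset == "weighted":
        om = tuple(tuple(np.full(mm, 1.0 / mm) for mm in mi) for mi in m)
        ps = tuple(mi / Mi for mi, Mi in zip(m, M_i))
        th = M_i / design.M
        g = float(design.M)
    elif preset == "custom":
        om = (
            tuple(tuple(np.asarray(o, float) for o in grp) for grp in omega)
            if omega is not None
            else tuple(tuple(np.full(mm, 1.0 / mm) for mm in mi) for mi in m)
        )
        ps = (
            tuple(np.asarray(p, float) for p in psi)
            if psi is not None
            else tuple(np.full(k, 1.0 / k) for k in n_i)
        )
        th = np.asarray(theta, float) if theta is not None else np.full(d, 1.0 / d)
        g = float(g_n) if g_n is not None else float(design.n)
    else:
        raise DesignError(f"unknown preset {preset!r}")
    # shape checks for custom input
    if len(ps) != d or any(len(ps[i]) != n_i[i] for i in range(d)):
        raise DesignError("psi shape does not match design")
    if len(om) != d or any(
        len(om[i]) != n_i[i] or any(len(om[i][j]) != m[i][j] for j in range(n_i[i]))
        for i in range(d)
    ):
        raise DesignError("omega shape does not match design")
    if len(th) != d:
        raise DesignError("theta length does not match design")
    return WeightScheme(om, ps, np.asarray(th, float), g, name=preset)


# ---------------------------------------------------------------------------
# contrast matrices


@dataclass(frozen=True)
class ContrastMatrix:
    """A ``q x d`` matrix of contrasts: rows sum to zero and are nonzero.

    The row rank may be smaller than ``q`` (the centering matrix and all-
    pairwise families are rank d-1 by construction); quadratic-form tests
    use pseudo-inverses and report the effective rank.
    """

    entries: np.ndarray
    kind: str = "custom"
    labels: tuple = ()

    def __post_init__(self):
        C = np.atleast_2d(np.asarray(self.entries, dtype=float))
        object.__setattr__(self, "entries", C)
        if np.max(np.abs(C.sum(axis=1))) > 1e-10:
            bad = int(np.argmax(np.abs(C.sum(axis=1))))
            raise DesignError(f"contrast row {bad} does not sum to zero")
        norms = np.linalg.norm(C, axis=1)
        if np.any(norms == 0):
            raise DesignError(f"contrast row {int(np.argmin(norms))} is all zero")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"c{l + 1}" for l in range(C.shape[0]))
            )

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.entries))

    @property
    def q(self) -> int:
        return self.entries.shape[0]

    @property
    def d(self) -> int:
        return self.entries.shape[1]

    @property
    def is_normed(self) -> bool:
        """Whether max |c_li| <= 1 (required for Fisher-scale intervals)."""
        return bool(np.max(np.abs(self.entries)) <= 1.0 + 1e-12)


def contrast(kind: str, d: int, control: int = 0, labels: Optional[Sequence] = None) -> ContrastMatrix:
    """Build a standard contrast matrix.

    ``centering``: ``I_d - (1/d) 11'`` (global hypothesis of equal effects).
    ``dunnett``: many-to-one comparisons against group ``control`` (0-based).
    ``tukey``: all d(d-1)/2 pairwise comparisons, row ``b - a`` for ``a < b``.
    """
    if d < 2:
        raise DesignError("need d >= 2")
    if kind == "centering":
        C = np.eye(d) - np.ones((d, d)) / d
        labs = tuple(f"{i + 1}-avg" for i in range(d))
    elif kind == "dunnett":
        if not 0 <= control < d:
            raise DesignError("control index out of range")
        rows, labs = [], []
        for i in range(d):
            if i == control:
                continue
            r = np.zeros(d)
            r[control] = -1.0
            r[i] = 1.0
            rows.append(r)
            labs.append(f"{i + 1}-{control + 1}")
        C, labs = np.array(rows), tuple(labs)
    elif kind == "tukey":
        rows, labs = [], []
        for a in range(d):
            for b in range(a + 1, d):
                r = np.zeros(d)
                r[a] = -1.0
                r[b] = 1.0
                rows.append(r)
                labs.append(f"{b + 1}-{a + 1}")
        C, labs = np.array(rows), tuple(labs)
    else:
        raise DesignError(f"unknown contrast kind {kind!r}")
    if labels is not None:
        labs = tuple(labels)
    return ContrastMatrix(C, kind=kind, labels=labs)


def read_contrast_csv(path) -> ContrastMatrix:
    """Read a q x d contrast matrix from a headerless CSV."""
    try:
        C = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))
    except Exception as exc:
        raise DesignError(f"cannot parse contrast file {path}: {exc}") from exc
    return ContrastMatrix(C, kind="custom")
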