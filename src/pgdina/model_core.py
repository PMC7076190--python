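"""Core data structures and likelihood of the reparameterized DINA model.

The DINA ("deterministic inputs, noisy AND gate") model is a conjunctive
latent-class model for binary test data.  Examinee ``i`` carries a binary
attribute-mastery pattern ``alpha_i`` of length ``K``; item ``j`` requires the
attributes flagged in row ``j`` of a binary Q-matrix.  The ideal response

    eta_ij = prod_k alpha_ik ** q_jk

is 1 iff the examinee masters every required attribute.  A correct response
then occurs with probability ``1 - s_j`` (slipping ``s_j``) when ``eta = 1``
and with probability ``g_j`` (guessing) when ``eta = 0``.  On the logit scale
this is a two-level logistic model,

    logit P(Y_ij = 1) = zeta_j + beta_j * eta_ij,

with intercept ``zeta_j = logit(g_j)`` and interaction
``beta_j = logit(1 - s_j) - logit(g_j) > 0``; the positivity constraint on
``beta_j`` encodes the monotonicity restriction ``1 - s_j > g_j`` (positive
item discrimination index).

All estimation code in this package works on the (zeta, beta) scale; the
probability-scale (s, g) parameters are available through
:func:`deparameterize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit as _logit, logsumexp

__all__ = [
    "QMatrix",
    "AttributePattern",
    "LatentClassSpace",
    "ItemParams",
    "ResponseMatrix",
    "ClassProbs",
    "reparameterize",
    "deparameterize",
    "ideal_response",
    "ideal_response_table",
    "response_prob",
    "class_loglik",
    "marginal_loglik",
]

#: probabilities are clipped into this open interval before any logit
PROB_EPS = 1e-12


def _as_binary_matrix(entries, name: str) -> np.ndarray:
    arr = np.asarray(entries)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        bad = vals[~np.isin(vals, (0, 1))]
        raise ValueError(f"{name} entries must be 0/1; found {bad[:5]}")
    return arr.astype(np.int8)


@dataclass(frozen=True)
class QMatrix:
    """J x K binary matrix; ``entries[j, k] = 1`` iff item j requires attribute k.

    Rows with no required attribute are rejected: for such an item ``eta`` is
    identically 1 and (zeta_j, beta_j) would be confounded.
    """

    entries: np.ndarray
    item_ids: tuple[str, ...] | None = None
    attribute_names: tuple[str, ...] | None = None

    def __post_init__(self):
        arr = _as_binary_matrix(self.entries, "Q-matrix")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("Q-matrix needs at least one item and one attribute")
        empty = np.flatnonzero(arr.sum(axis=1) == 0)
        if empty.size:
            raise ValueError(
                f"Q-matrix rows {empty + 1} require no attribute; every item "
                "must require at least one (otherwise zeta and beta are confounded)"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "entries", arr)

    @property
    def J(self) -> int:
        return self.entries.shape[0]

    @property
    def K(self) -> int:
        return self.entries.shape[1]

    @classmethod
    def from_csv(cls, path) -> "QMatrix":
        header, rows, ids = _read_binary_csv(path, "Q-matrix")
        return cls(rows, item_ids=ids, attribute_names=header)

    def to_csv(self, path) -> None:
        names = self.attribute_names or tuple(f"A{k+1}" for k in range(self.K))
        _write_binary_csv(path, names, self.entries)


@dataclass(frozen=True)
class AttributePattern:
    """Binary mastery pattern alpha for one latent class (length K)."""

    bits: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.bits)
        if arr.ndim != 1:
            raise ValueError("attribute pattern must be a 1-d vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("attribute pattern entries must be 0/1")
        arr = arr.astype(np.int8)
        arr.setflags(write=False)
        object.__setattr__(self, "bits", arr)

    @property
    def K(self) -> int:
        return self.bits.shape[0]


@dataclass(frozen=True)
class LatentClassSpace:
    """Canonical enumeration of the C = 2**K attribute patterns.

    Class ``c`` (0-based) is the K-bit binary expansion of ``c`` with the
    first attribute as the most significant bit, so class 0 is the all-zero
    (no mastery) pattern and class C-1 is full mastery.
    """

    K: int
    patterns: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        c = np.arange(2**self.K)[:, None]
        shifts = np.arange(self.K - 1, -1, -1)[None, :]
        pat = ((c >> shifts) & 1).astype(np.int8)
        pat.setflags(write=False)
        object.__setattr__(self, "patterns", pat)

    @property
    def C(self) -> int:
        return 2**self.K

    def index_of(self, bits) -> int:
        bits = np.asarray(bits, dtype=np.int64)
        return int(bits @ (2 ** np.arange(self.K - 1, -1, -1)))


@dataclass(frozen=True)
class ItemParams:
    """Per-item logit-scale parameters (zeta_j intercept, beta_j > 0 interaction)."""

    zeta: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        z = np.atleast_1d(np.asarray(self.zeta, dtype=float))
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if z.shape != b.shape or z.ndim != 1:
            raise ValueError("zeta and beta must be 1-d vectors of equal length")
        if not (np.isfinite(z).all() and np.isfinite(b).all()):
            raise ValueError("item parameters must be finite")
        if (b <= 0).any():
            raise ValueError("beta must be strictly positive (monotonicity restriction)")
        z.setflags(write=False)
        b.setflags(write=False)
        object.__setattr__(self, "zeta", z)
        object.__setattr__(self, "beta", b)

    @property
    def J(self) -> int:
        return self.zeta.shape[0]

    @classmethod
    def from_sg(cls, s, g) -> "ItemParams":
        zeta, beta = reparameterize(s, g)
        return cls(np.atleast_1d(zeta), np.atleast_1d(beta))

    def to_sg(self) -> tuple[np.ndarray, np.ndarray]:
        return deparameterize(self.zeta, self.beta)


@dataclass(frozen=True)
class ResponseMatrix:
    """N x J binary response matrix Y (rows: examinees, columns: items)."""

    entries: np.ndarray
    item_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        arr = _as_binary_matrix(self.entries, "response matrix")
        arr.setflags(write=False)
        object.__setattr__(self, "entries", arr)

    @property
    def N(self) -> int:
        return self.entries.shape[0]

    @property
    def J(self) -> int:
        return self.entries.shape[1]

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        header, rows, _ = _read_binary_csv(path, "response matrix", row_ids=False)
        return cls(rows, item_ids=header)

    def to_csv(self, path) -> None:
        names = self.item_ids or tuple(f"item{j+1}" for j in range(self.J))
        _write_binary_csv(path, names, self.entries)


@dataclass(frozen=True)
class ClassProbs:
    """Probability vector pi over the C latent classes (simplex)."""

    pi: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pi, dtype=float)
        if p.ndim != 1:
            raise ValueError("pi must be a 1-d vector")
        if (p < 0).any():
            raise ValueError("pi entries must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"pi must sum to 1 (got {p.sum()!r})")
        p.setflags(write=False)
        object.__setattr__(self, "pi", p)

    @property
    def C(self) -> int:
        return self.pi.shape[0]

    @classmethod
    def uniform(cls, C: int) -> "ClassProbs":
        return cls(np.full(C, 1.0 / C))


# ---------------------------------------------------------------------------
# parameter transforms and likelihood


def reparameterize(s, g):
    """Map slipping/guessing probabilities to the logit scale.

    Returns ``(zeta, beta) = (logit(g), logit(1-s) - logit(g))``.  Accepts
    scalars or arrays; both inputs must lie strictly inside (0, 1).
    """
    s = np.asarray(s, dtype=float)
    g = np.asarray(g, dtype=float)
    if ((s <= 0) | (s >= 1)).any() or ((g <= 0) | (g >= 1)).any():
        raise ValueError("s and g must lie strictly inside (0, 1)")
    zeta = _logit(g)
    beta = _logit(1.0 - s) - zeta
    return (float(zeta), float(beta)) if zeta.ndim == 0 else (zeta, beta)


def deparameterize(zeta, beta):
    """Inverse of :func:`reparameterize`: ``g = expit(zeta)``, ``s = 1 - expit(zeta+beta)``."""
    zeta = np.asarray(zeta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (np.isfinite(zeta).all() and np.isfinite(beta).all()):
        raise ValueError("zeta and beta must be finite")
    g = expit(zeta)
    s = 1.0 - expit(zeta + beta)
    return (float(s), float(g)) if zeta.ndim == 0 else (s, g)


def ideal_response(alpha, q_row) -> int:
    """eta = 1 iff every attribute required by the item is mastered.

    Empty product convention: an all-zero q_row (never produced by
    :class:`QMatrix`) yields 1.
    """
    a = np.asarray(getattr(alpha, "bits", alpha))
    q = np.asarray(q_row)
    if a.shape != q.shape:
        raise ValueError(f"length mismatch: alpha {a.shape} vs q {q.shape}")
    return int(np.all(a[q == 1] == 1))


def ideal_response_table(Q: QMatrix, space: LatentClassSpace) -> np.ndarray:
    """C x J table of ideal responses eta_cj for every (class, item) pair."""
    if Q.K != space.K:
        raise ValueError(f"Q has K={Q.K} but class space has K={space.K}")
    # eta_cj = 1 iff pattern c covers all attributes required by item j
    required = Q.entries.sum(axis=1)  # (J,)
    hits = space.patterns @ Q.entries.T  # (C, J) count of mastered-and-required
    return (hits == required[None, :]).astype(np.int8)


def response_prob(zeta, beta, eta):
    """P(Y=1 | eta) = expit(zeta + beta * eta); equals g + (1-s-g)*eta."""
    return expit(np.asarray(zeta, dtype=float) + np.asarray(beta, dtype=float) * np.asarray(eta))


def class_loglik(y_i, eta_row, params: ItemParams) -> float:
    """Bernoulli log-likelihood of one response vector given a latent class."""
    y = np.asarray(y_i, dtype=float)
    eta = np.asarray(eta_row, dtype=float)
    if y.shape != eta.shape or y.shape != params.zeta.shape:
        raise ValueError("Y_i, eta and item parameters must have equal length J")
    z = params.zeta + params.beta * eta
    # log p = y*z - log(1+e^z), stable via logaddexp
    return float(np.sum(y * z - np.logaddexp(0.0, z)))


def _all_class_loglik(Y: np.ndarray, params: ItemParams, eta_table: np.ndarray) -> np.ndarray:
    """N x C matrix of log p(Y_i | class c), vectorized."""
    Z = params.zeta[None, :] + params.beta[None, :] * eta_table  # (C, J)
    # sum_j [y*z - log(1+e^z)]
    return Y @ Z.T - np.logaddexp(0.0, Z).sum(axis=1)[None, :]


def marginal_loglik(Y: ResponseMatrix, params: ItemParams, pi: ClassProbs, Q: QMatrix) -> float:
    """Latent-class marginal log-likelihood sum_i log sum_c pi_c p(Y_i | c).

    Computed in the log domain with log-sum-exp over the 2**K classes.
    """
    space = LatentClassSpace(Q.K)
    if pi.C != space.C:
        raise ValueError(f"pi has {pi.C} classes but Q implies {space.C}")
    if Y.J != Q.J:
        raise ValueError(f"Y has J={Y.J} items but Q has J={Q.J}")
    eta = ideal_response_table(Q, space)
    ll = _all_class_loglik(Y.entries.astype(float), params, eta)  # (N, C)
    with np.errstate(divide="ignore"):
        logpi = np.log(pi.pi)
    return float(logsumexp(ll + logpi[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# CSV interface (header row of names, one row of 0/1 values per record)


def _read_binary_csv(path, name, row_ids=False):
    import csv

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a {name} CSV") from None
        header = tuple(h.strip() for h in header)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            try:
                vals = [int(c) for c in row]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer value in {name}") from None
            if any(v not in (0, 1) for v in vals):
                raise ValueError(f"{path}:{lineno}: {name} values must be 0 or 1")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows in {name}")
    return header, np.asarray(rows, dtype=np.int8), None


def _write_binary_csv(path, header, matrix):
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(np.asarray(matrix, dtype=int).tolist())
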