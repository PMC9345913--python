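"""First-order Takagi-Sugeno ANFIS with hybrid learning, from scratch.

The network is the classic six-stage Sugeno architecture: crisp inputs are
fuzzified through grid-partitioned membership functions; each rule's firing
strength is the product of one membership degree per input; strengths are
normalized to sum to 1; each rule contributes a linear (first-order TSK)
consequent p.x + r; the output is the normalized-strength-weighted sum of
the consequents.

Training is the hybrid scheme: per epoch, the consequent coefficients are
solved exactly by linear least squares with the premise (membership)
parameters frozen, then the premise parameters take one full-batch
normalized-gradient descent step on the training SSE, with the classic
step-length adaptation heuristic (grow after four consecutive error drops,
shrink after two up-down oscillations).  A held-out checking partition
selects the best epoch, guarding against over-fitting.

Membership-function families (canonical definitions):

==========  ========================  =====================================
family      parameters                curve
==========  ========================  =====================================
``trimf``   a <= b <= c               piecewise-linear triangle
``gaussmf`` sigma > 0, c              exp(-(x-c)^2 / (2 sigma^2))
``gbellmf`` a > 0, b > 0, c           1 / (1 + |(x-c)/a|^(2b))
``pimf``    a <= b <= c <= d          spline-based Pi curve (S up, Z down)
==========  ========================  =====================================
"""

from __future__ import annotations

import copy
import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import DegenerateInputError, InvalidConfigError, InvalidInputError

logger = logging.getLogger(__name__)

MF_FAMILIES = ("trimf", "gaussmf", "gbellmf", "pimf")


# ---------------------------------------------------------------------------
# membership functions
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Quadratic S-curve: 0 at a, 1 at b, C1-continuous."""
    if b <= a:
        return (x >= 0.5 * (a + b)).astype(float)
    u = (x - a) / (b - a)
    out = np.where(u < 0.5, 2.0 * u * u, 1.0 - 2.0 * (1.0 - u) ** 2)
    return np.where(u <= 0, 0.0, np.where(u >= 1, 1.0, out))


def _smoothstep_grad(x: np.ndarray, a: float, b: float):
    """(dS/da, dS/db) for the S-curve; zero at degeneracies and outside."""
    n = x.shape[0]
    if b <= a:
        return np.zeros(n), np.zeros(n)
    u = (x - a) / (b - a)
    inside = (u > 0) & (u < 1)
    ds_du = np.where(u < 0.5, 4.0 * u, 4.0 * (1.0 - u)) * inside
    du_da = (x - b) / (b - a) ** 2
    du_db = (a - x) / (b - a) ** 2
    return ds_du * du_da, ds_du * du_db


@dataclass
class MembershipFunction:
    """One membership function: family name plus its parameter vector.

    Parameter validity is checked at construction; evaluation then always
    maps the real line into [0, 1].
    """

    family: str
    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.validate()

    def validate(self) -> None:
        p = self.params
        if self.family == "trimf":
            if p.shape != (3,) or not (p[0] <= p[1] <= p[2]):
                raise InvalidInputError(f"trimf needs a <= b <= c, got {p}")
        elif self.family == "gaussmf":
            if p.shape != (2,) or p[0] <= 0:
                raise InvalidInputError(f"gaussmf needs sigma > 0, got {p}")
        elif self.family == "gbellmf":
            if p.shape != (3,) or p[0] <= 0 or p[1] <= 0:
                raise InvalidInputError(f"gbellmf needs a > 0, b > 0, got {p}")
        elif self.family == "pimf":
            if p.shape != (4,) or not (p[0] <= p[1] <= p[2] <= p[3]):
                raise InvalidInputError(f"pimf needs a <= b <= c <= d, got {p}")
        else:
            raise InvalidInputError(f"unknown mf family {self.family!r}")

    @property
    def center(self) -> float:
        if self.family == "trimf":
            return float(self.params[1])
        if self.family == "gaussmf":
            return float(self.params[1])
        if self.family == "gbellmf":
            return float(self.params[2])
        return float(0.5 * (self.params[1] + self.params[2]))

    # -- evaluation ---------------------------------------------------------

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        p = self.params
        if self.family == "trimf":
            a, b, c = p
            y = np.zeros_like(x)
            if b > a:
                m = (x > a) & (x < b)
                y[m] = (x[m] - a) / (b - a)
            if c > b:
                m = (x > b) & (x < c)
                y[m] = (c - x[m]) / (c - b)
            y[x == b] = 1.0
        elif self.family == "gaussmf":
            sigma, c = p
            y = np.exp(-((x - c) ** 2) / (2.0 * sigma**2))
        elif self.family == "gbellmf":
            a, b, c = p
            y = 1.0 / (1.0 + np.abs((x - c) / a) ** (2.0 * b))
        else:  # pimf
            a, b, c, d = p
            y = _smoothstep(x, a, b) * (1.0 - _smoothstep(x, c, d))
        return float(y[0]) if scalar else y

    # -- analytic parameter gradient ---------------------------------------

    def grad_params(self, x: np.ndarray) -> np.ndarray:
        """d mu / d theta, shape (n_params, n).

        At the kinks of the piecewise families the one-sided subgradient 0
        is used; the families are differentiable almost everywhere.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        p = self.params
        g = np.zeros((p.size, x.size))
        if self.family == "trimf":
            a, b, c = p
            if b > a:
                m = (x > a) & (x < b)
                g[0, m] = (x[m] - b) / (b - a) ** 2
                g[1, m] = -(x[m] - a) / (b - a) ** 2
            if c > b:
                m = (x > b) & (x < c)
                g[1, m] = (c - x[m]) / (c - b) ** 2
                g[2, m] = (x[m] - b) / (c - b) ** 2
        elif self.family == "gaussmf":
            sigma, c = p
            mu = self(x)
            g[0] = mu * (x - c) ** 2 / sigma**3
            g[1] = mu * (x - c) / sigma**2
        elif self.family == "gbellmf":
            a, b, c = p
            u = np.abs((x - c) / a)
            t = u ** (2.0 * b)
            mu = 1.0 / (1.0 + t)
            mu2t = mu * mu * t
            g[0] = 2.0 * b * mu2t / a
            pos = u > 0
            with np.errstate(divide="ignore", invalid="ignore"):
                g[1] = np.where(pos, -2.0 * mu2t * np.log(np.where(pos, u, 1.0)), 0.0)
                g[2] = np.where(x != c, 2.0 * b * mu2t / np.where(x != c, x - c, 1.0), 0.0)
        else:  # pimf
            a, b, c, d = p
            s_up = _smoothstep(x, a, b)
            s_dn = _smoothstep(x, c, d)
            da, db = _smoothstep_grad(x, a, b)
            dc, dd = _smoothstep_grad(x, c, d)
            g[0] = da * (1.0 - s_dn)
            g[1] = db * (1.0 - s_dn)
            g[2] = -s_up * dc
            g[3] = -s_up * dd
        return g

    def project(self) -> None:
        """Restore parameter validity in place after a gradient step."""
        p = self.params
        if self.family == "trimf":
            p.sort()
        elif self.family == "gaussmf":
            p[0] = max(abs(p[0]), 1e-8)
        elif self.family == "gbellmf":
            p[0] = max(abs(p[0]), 1e-8)
            p[1] = max(abs(p[1]), 1e-8)
        else:
            p.sort()


def eval_mf(mf: MembershipFunction, x):
    """Membership degree of ``x`` under ``mf`` (functional alias)."""
    return mf(x)


# ---------------------------------------------------------------------------
# fuzzy inputs and grid partition
# ---------------------------------------------------------------------------

@dataclass
class FuzzyInput:
    """One crisp input factor with its ordered membership functions."""

    name: str
    domain_min: float
    domain_max: float
    mfs: list[MembershipFunction]

    def __post_init__(self) -> None:
        if len(self.mfs) < 2:
            raise InvalidInputError("each input needs at least 2 membership functions")
        if self.domain_max <= self.domain_min:
            raise InvalidInputError(
                f"degenerate domain for {self.name!r}: "
                f"[{self.domain_min}, {self.domain_max}]"
            )
        lo, hi = self.domain_min, self.domain_max
        for mf in self.mfs:
            # centers start inside the observed range; training may drift
            # them slightly past it, which is legitimate refinement
            if not (lo - 1e-9 <= mf.center <= hi + 1e-9):
                logger.debug("mf center %g outside domain of %r",
                             mf.center, self.name)


def grid_partition(name: str, domain_min: float, domain_max: float,
                   n_mf: int, family: str) -> FuzzyInput:
    """Uniform grid partition: centers equally spaced over the domain,
    widths set so adjacent membership functions cross at degree ~0.5."""
    if family not in MF_FAMILIES:
        raise InvalidInputError(f"unknown mf family {family!r}")
    if n_mf < 2:
        raise InvalidInputError("grid partition needs n_mf >= 2")
    centers = np.linspace(domain_min, domain_max, n_mf)
    h = (domain_max - domain_min) / (n_mf - 1)
    mfs = []
    for c in centers:
        if family == "trimf":
            params = [c - h, c, c + h]
        elif family == "gaussmf":
            # adjacent Gaussians h apart cross at 0.5 when sigma = h / (2 sqrt(2 ln 2))
            params = [h / (2.0 * np.sqrt(2.0 * np.log(2.0))), c]
        elif family == "gbellmf":
            # half-width a = h/2 puts the 0.5 crossing at the midpoint for any b
            params = [h / 2.0, 2.0, c]
        else:  # pimf: ramps of width h on both sides, 0.5 crossings at c +/- h/2
            params = [c - h, c, c, c + h]
        mfs.append(MembershipFunction(family, np.asarray(params, dtype=float)))
    return FuzzyInput(name=name, domain_min=float(domain_min),
                      domain_max=float(domain_max), mfs=mfs)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class RuleBase:
    """Full Cartesian-product rule base with first-order TSK consequents."""

    rule_index: np.ndarray      # (n_rules, n_inputs) mf index per input
    consequents: np.ndarray     # (n_rules, n_inputs + 1): p_1..p_k, r

    @property
    def n_rules(self) -> int:
        return self.rule_index.shape[0]


@dataclass
class ANFISModel:
    """A constructed (and optionally trained) Sugeno fuzzy model.

    Models built with :meth:`from_data` work on internally normalized
    inputs: each factor is affinely mapped onto [0, 1] (the map is stored
    in ``input_offset``/``input_scale``), so membership functions of all
    factors live on comparable scales — without this, gradient steps and
    the minimum-norm consequent solution would be dominated by whichever
    factor has the largest raw units (drying time spans hundreds of
    minutes; blanching time single digits).  Manually constructed models
    default to the identity map and operate in raw coordinates.
    """

    inputs: list[FuzzyInput]
    rulebase: RuleBase
    trained: bool = False
    seed: int = 0
    min_firing: float = 1e-12
    input_offset: np.ndarray | None = None
    input_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.inputs)
        if self.input_offset is None:
            self.input_offset = np.zeros(k)
        if self.input_scale is None:
            self.input_scale = np.ones(k)
        self.input_offset = np.asarray(self.input_offset, dtype=float)
        self.input_scale = np.asarray(self.input_scale, dtype=float)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_grid(cls, names: list[str], domains: list[tuple[float, float]],
                  n_mf: int, family: str, seed: int = 0) -> "ANFISModel":
        inputs = [grid_partition(nm, lo, hi, n_mf, family)
                  for nm, (lo, hi) in zip(names, domains)]
        k = len(inputs)
        rule_index = np.array(
            list(itertools.product(*(range(len(fi.mfs)) for fi in inputs))),
            dtype=int,
        )
        consequents = np.zeros((rule_index.shape[0], k + 1))
        return cls(inputs=inputs, rulebase=RuleBase(rule_index, consequents),
                   seed=seed)

    @classmethod
    def from_data(cls, X: np.ndarray, names: list[str], n_mf: int,
                  family: str, seed: int = 0) -> "ANFISModel":
        """Grid partition over the observed data range, with each input
        normalized onto the unit interval internally."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo, hi = X.min(axis=0), X.max(axis=0)
        degen = [names[j] for j in range(X.shape[1]) if hi[j] <= lo[j]]
        if degen:
            raise InvalidInputError(f"constant input column(s): {degen}")
        model = cls.from_grid(names, [(0.0, 1.0)] * X.shape[1], n_mf, family,
                              seed=seed)
        model.input_offset = lo
        model.input_scale = hi - lo
        return model

    def _scale_inputs(self, X: np.ndarray) -> np.ndarray:
        return (X - self.input_offset) / self.input_scale

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_rules(self) -> int:
        return self.rulebase.n_rules

    # -- forward pass -------------------------------------------------------

    def membership_degrees(self, X: np.ndarray) -> list[np.ndarray]:
        X = self._scale_inputs(np.atleast_2d(np.asarray(X, dtype=float)))
        return [np.column_stack([mf(X[:, j]) for mf in fi.mfs])
                for j, fi in enumerate(self.inputs)]

    def firing_strengths(self, X: np.ndarray) -> np.ndarray:
        """Raw rule firing strengths, shape (n_samples, n_rules)."""
        degrees = self.membership_degrees(X)
        return _firing_from_degrees(degrees, self.rulebase.rule_index)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise InvalidInputError(
                f"expected {self.n_inputs} input columns, got {X.shape[1]}"
            )
        wbar = normalize(self.firing_strengths(X), min_firing=self.min_firing, x=X)
        f = _consequent_outputs(self._scale_inputs(X), self.rulebase.consequents)
        return (wbar * f).sum(axis=1)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "inputs": [
                {"name": fi.name, "domain_min": fi.domain_min,
                 "domain_max": fi.domain_max,
                 "mfs": [{"family": mf.family, "params": mf.params.tolist()}
                         for mf in fi.mfs]}
                for fi in self.inputs
            ],
            "rule_index": self.rulebase.rule_index.tolist(),
            "consequents": self.rulebase.consequents.tolist(),
            "trained": self.trained,
            "seed": self.seed,
            "min_firing": self.min_firing,
            "input_offset": self.input_offset.tolist(),
            "input_scale": self.input_scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ANFISModel":
        inputs = [
            FuzzyInput(
                name=fi["name"], domain_min=fi["domain_min"],
                domain_max=fi["domain_max"],
                mfs=[MembershipFunction(m["family"], np.asarray(m["params"]))
                     for m in fi["mfs"]],
            )
            for fi in d["inputs"]
        ]
        rb = RuleBase(np.asarray(d["rule_index"], dtype=int),
                      np.asarray(d["consequents"], dtype=float))
        return cls(inputs=inputs, rulebase=rb, trained=d["trained"],
                   seed=d["seed"], min_firing=d.get("min_firing", 1e-12),
                   input_offset=np.asarray(d["input_offset"]),
                   input_scale=np.asarray(d["input_scale"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ANFISModel":
        return cls.from_dict(json.loads(s))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ANFISModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _firing_from_degrees(degrees: list[np.ndarray],
                         rule_index: np.ndarray) -> np.ndarray:
    """Product over inputs of each rule's membership degrees."""
    w = np.ones((degrees[0].shape[0], rule_index.shape[0]))
    for j, d in enumerate(degrees):
        w *= d[:, rule_index[:, j]]
    return w


def _consequent_outputs(X: np.ndarray, consequents: np.ndarray) -> np.ndarray:
    """Per-rule linear outputs f_i = p_i . x + r_i, shape (n, n_rules)."""
    x_aug = np.column_stack([X, np.ones(X.shape[0])])
    return x_aug @ consequents.T


def firing_strengths(model: ANFISModel, x_vector) -> np.ndarray:
    """Raw firing strengths for a single input vector (functional alias)."""
    return model.firing_strengths(np.atleast_2d(x_vector))[0]


def normalize(w: np.ndarray, min_firing: float = 1e-12, x=None) -> np.ndarray:
    """Normalize firing strengths to sum to 1 per sample.

    A sample whose strengths are all exactly zero fires no rule and raises
    :class:`DegenerateInputError` (naming the offending input when given);
    positive sums below ``min_firing`` are floored to avoid 0/0 blow-up at
    extreme extrapolation.
    """
    w = np.asarray(w, dtype=float)
    single = w.ndim == 1
    w2 = np.atleast_2d(w)
    sums = w2.sum(axis=1)
    dead = sums <= 0
    if dead.any():
        idx = np.nonzero(dead)[0]
        detail = f" x={np.atleast_2d(x)[idx[0]]}" if x is not None else ""
        raise DegenerateInputError(
            f"no rule fires for {idx.size} input(s) (first at row {idx[0]}{detail})"
        )
    wbar = w2 / np.maximum(sums, min_firing)[:, None]
    return wbar[0] if single else wbar


def predict(model: ANFISModel, x_vector) -> np.ndarray | float:
    """Model output for one input vector or a batch (functional alias)."""
    x = np.asarray(x_vector, dtype=float)
    out = model.predict(np.atleast_2d(x))
    return float(out[0]) if x.ndim == 1 else out


# ---------------------------------------------------------------------------
# hybrid learning
# ---------------------------------------------------------------------------

def lse_consequents(model: ANFISModel, X: np.ndarray, y: np.ndarray,
                    ridge: float = 0.0) -> np.ndarray:
    """Optimal TSK consequents with the premise frozen.

    Solves min ||y - Phi theta||_2 where Phi stacks, rule-major, the
    normalized firing strength times the augmented (internally scaled)
    input [x, 1].  The system is solved after column equilibration with a
    numerically stable SVD least-squares routine, so a rank-deficient
    design (more rule coefficients than samples, the usual regime for
    5-mf rule bases) yields a minimum-norm solution with a warning.

    With ``ridge > 0`` a Tikhonov penalty ridge*||theta||^2 (in the
    equilibrated basis) is added, solved exactly in whichever of the
    primal/dual forms is smaller.  Hybrid training uses a small ridge by
    default: with a full Cartesian rule base the design has near-collinear
    columns (rules overlapping through membership tails), and the
    unpenalized interpolant swings wildly between training points.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    wbar = normalize(model.firing_strengths(X), min_firing=model.min_firing, x=X)
    xs = model._scale_inputs(X)
    x_aug = np.column_stack([xs, np.ones(X.shape[0])])
    n, r, kp1 = X.shape[0], model.n_rules, X.shape[1] + 1
    phi = (wbar[:, :, None] * x_aug[:, None, :]).reshape(n, r * kp1)
    col_scale = np.linalg.norm(phi, axis=0)
    col_scale[col_scale == 0] = 1.0
    a = phi / col_scale
    if ridge > 0:
        p = a.shape[1]
        if p > n:  # dual (kernel) form: theta = A^T (A A^T + ridge I)^-1 y
            alpha = scipy.linalg.solve(a @ a.T + ridge * np.eye(n), y,
                                       assume_a="pos")
            theta = a.T @ alpha
        else:
            theta = scipy.linalg.solve(a.T @ a + ridge * np.eye(p), a.T @ y,
                                       assume_a="pos")
    else:
        theta, _, rank, _ = np.linalg.lstsq(a, y, rcond=None)
        if rank < a.shape[1]:
            warnings.warn(
                f"rank-deficient consequent design ({rank} < {a.shape[1]}): "
                "minimum-norm solution used", stacklevel=2,
            )
    model.rulebase.consequents = (theta / col_scale).reshape(r, kp1)
    return model.rulebase.consequents


def _premise_gradient(model: ANFISModel, X: np.ndarray, y: np.ndarray
                      ) -> list[list[np.ndarray]]:
    """Gradient of the training SSE w.r.t. every premise parameter.

    Returns ``grads[j][m]`` = gradient vector for mf ``m`` of input ``j``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    xs = model._scale_inputs(X)
    degrees = self_degrees = model.membership_degrees(X)
    ridx = model.rulebase.rule_index
    w = _firing_from_degrees(degrees, ridx)
    sums = np.maximum(w.sum(axis=1), model.min_firing)
    wbar = w / sums[:, None]
    f = _consequent_outputs(xs, model.rulebase.consequents)
    yhat = (wbar * f).sum(axis=1)
    # dE/dw_r = 2 e * (f_r - yhat) / sum_w
    de_dw = 2.0 * (yhat - y)[:, None] * (f - yhat[:, None]) / sums[:, None]
    grads: list[list[np.ndarray]] = []
    for j, fi in enumerate(model.inputs):
        # product of degrees over all inputs except j, per rule
        w_excl = np.ones_like(w)
        for j2, d2 in enumerate(self_degrees):
            if j2 != j:
                w_excl *= d2[:, ridx[:, j2]]
        per_mf = []
        for m, mf in enumerate(fi.mfs):
            cols = ridx[:, j] == m
            gmu = (de_dw[:, cols] * w_excl[:, cols]).sum(axis=1)  # dE/dmu per sample
            dmu = mf.grad_params(xs[:, j])                         # (p, n)
            per_mf.append(dmu @ gmu)
        grads.append(per_mf)
    return grads


def backprop_premise(model: ANFISModel, X: np.ndarray, y: np.ndarray,
                     step: float) -> ANFISModel:
    """One normalized-gradient descent step on the premise parameters.

    ``step`` is the step length taken along the unit gradient direction
    (Jang's convention).  Non-finite gradient components are zeroed and
    logged; parameter validity is restored by projection after the step.
    """
    if step == 0:
        return model
    grads = _premise_gradient(model, X, y)
    flat = np.concatenate([g for per in grads for g in per])
    bad = ~np.isfinite(flat)
    if bad.any():
        logger.warning("backprop: zeroed %d non-finite gradient elements", bad.sum())
        flat[bad] = 0.0
    norm = np.linalg.norm(flat)
    if norm < 1e-10:
        # gradient indistinguishable from floating-point noise: taking a
        # full normalized step along it would undo a converged fit
        return model
    flat *= -step / norm
    pos = 0
    for fi, per in zip(model.inputs, grads):
        for mf, g in zip(fi.mfs, per):
            mf.params += flat[pos:pos + g.size]
            pos += g.size
            mf.project()
    return model


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hybrid-learning hyper-parameters.

    The default 60/15/25 train/check/test split follows common practice for
    neuro-fuzzy model development; the step schedule is the classic
    heuristic (x1.1 after 4 consecutive error decreases, x0.9 after 2
    up-down oscillations).
    """

    max_epochs: int = 100
    initial_step: float = 0.1
    step_increase: float = 1.1
    step_decrease: float = 0.9
    split: tuple[float, float, float] = (0.60, 0.15, 0.25)
    seed: int = 0
    min_firing: float = 1e-12
    ridge: float = 1e-3

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise InvalidConfigError("max_epochs must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9 or any(s < 0 for s in self.split):
            raise InvalidConfigError(f"split must be non-negative and sum to 1: {self.split}")
        if self.initial_step < 0 or self.ridge < 0:
            raise InvalidConfigError("initial_step and ridge must be non-negative")


@dataclass
class TrainResult:
    """Per-epoch error trajectories and the checking-selected best model."""

    train_rmse_per_epoch: np.ndarray
    check_rmse_per_epoch: np.ndarray
    best_epoch: int                      # 1-based epoch index
    model_at_best: ANFISModel
    test_rmse: float
    test_r2: float
    split_indices: dict = field(default_factory=dict, repr=False)


def split_dataset(n: int, split: tuple[float, float, float], seed: int):
    """Shuffle 0..n-1 with the given seed and cut contiguous
    train/check/test slices of the requested fractions."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(n * split[0])
    n_check = int(n * split[1])
    return perm[:n_train], perm[n_train:n_train + n_check], perm[n_train + n_check:]


def rmse(y, yhat) -> float:
    """Root mean squared prediction error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise InvalidInputError("rmse needs two equal-length vectors of >= 2 points")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SSE/SST.

    The squared Pearson correlation (which some tools report as R^2) is
    logged alongside for comparison.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise InvalidInputError("r_squared needs two equal-length vectors of >= 2 points")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise InvalidInputError("R^2 undefined for constant y")
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / sst
    if np.std(yhat) > 0:
        logger.debug("squared Pearson correlation: %.6f", np.corrcoef(y, yhat)[0, 1] ** 2)
    return r2


class _StepScheduler:
    """Jang's step-length heuristic over the training-error sequence."""

    def __init__(self, step, increase, decrease):
        self.step, self.increase, self.decrease = step, increase, decrease
        self.errors: list[float] = []

    def update(self, err: float) -> float:
        self.errors.append(err)
        e = self.errors
        if len(e) >= 5 and all(e[-i] < e[-i - 1] for i in range(1, 5)):
            self.step *= self.increase
            self.errors = [err]
        elif len(e) >= 5 and (
            e[-4] > e[-3] < e[-2] > e[-1] or e[-4] < e[-3] > e[-2] < e[-1]
        ):
            self.step *= self.decrease
            self.errors = [err]
        return self.step


def train(model: ANFISModel, X: np.ndarray, y: np.ndarray,
          config: TrainConfig | None = None) -> TrainResult:
    """Hybrid LSE/gradient training with checking-set epoch selection.

    Each epoch solves the consequents exactly (premise frozen), records the
    training and checking RMSE of that state, then takes one gradient step
    on the premise.  The returned model is the snapshot at the epoch with
    minimum checking RMSE (first occurrence on ties); test metrics are
    computed only on the held-out test partition with that snapshot.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    model.min_firing = config.min_firing
    model.seed = config.seed
    i_train, i_check, i_test = split_dataset(X.shape[0], config.split, config.seed)
    if min(i_train.size, i_check.size, i_test.size) < 2:
        raise InvalidConfigError(
            f"split sizes too small: {i_train.size}/{i_check.size}/{i_test.size}"
        )
    xt, yt = X[i_train], y[i_train]
    xc, yc = X[i_check], y[i_check]

    train_hist, check_hist = [], []
    best_check = np.inf
    best_snapshot = None
    best_epoch = 1
    sched = _StepScheduler(config.initial_step, config.step_increase,
                           config.step_decrease)
    for epoch in range(1, config.max_epochs + 1):
        lse_consequents(model, xt, yt, ridge=config.ridge)
        tr = rmse(yt, model.predict(xt))
        ck = rmse(yc, model.predict(xc))
        train_hist.append(tr)
        check_hist.append(ck)
        if ck < best_check:
            best_check, best_epoch = ck, epoch
            best_snapshot = copy.deepcopy(model)
        step = sched.update(tr)
        if epoch < config.max_epochs:
            # premise step, guarded: a step that leaves any observed input
            # firing no rule (compact-support mfs drifting apart) is
            # reverted and the step length shrunk
            saved = [mf.params.copy() for fi in model.inputs for mf in fi.mfs]
            backprop_premise(model, xt, yt, step)
            if np.any(model.firing_strengths(X).sum(axis=1) <= 0):
                for mf, p in zip((m for fi in model.inputs for m in fi.mfs),
                                 saved):
                    mf.params[:] = p
                sched.step *= config.step_decrease
                logger.debug("epoch %d: premise step reverted "
                             "(rule coverage lost)", epoch)
    assert best_snapshot is not None
    best_snapshot.trained = True
    yhat_test = best_snapshot.predict(X[i_test])
    result = TrainResult(
        train_rmse_per_epoch=np.asarray(train_hist),
        check_rmse_per_epoch=np.asarray(check_hist),
        best_epoch=best_epoch,
        model_at_best=best_snapshot,
        test_rmse=rmse(y[i_test], yhat_test),
        test_r2=r_squared(y[i_test], yhat_test),
        split_indices=dict(train=i_train, check=i_check, test=i_test),
    )
    logger.info(
        "train: %d epochs, best epoch %d (check RMSE %.5f), test RMSE %.5f R2 %.5f",
        config.max_epochs, best_epoch, best_check, result.test_rmse, result.test_r2,
    )
    return result
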