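"""Shape projection: decomposing a mechanism-agnostic binding model into
base readout and shape-sensitivity profiles.

Given a mono+dinucleotide free-energy model and linear sequence-to-shape
models, projection finds the shape-readout model (scoring matrix +
per-feature sensitivity profiles, boundary coefficients fixed at zero)
whose sequence-only representation best approximates the mechanism-
agnostic model.  Two losses are supported:

* affinity: sum over all k-mers of the squared difference of predicted
  affinities, sigma(2 b_agn) + sigma(2 b_seq) - 2 sigma(b_agn + b_seq);
* KL: the Kullback-Leibler divergence between the Boltzmann sequence
  distributions implied by the two models,
  (b_agn - b_seq) . grad sigma(b_agn)/sigma(b_agn)
  - ln(sigma(b_agn)/sigma(b_seq)).

Because base and shape readout are nearly collinear (most shape variance
is itself explained by mononucleotides), the unpenalized problem is
poorly conditioned.  A second, penalized stage therefore minimizes the
loss normalized by its unpenalized optimum plus p-norm penalties on the
scoring matrix and each sensitivity profile, each normalized by the
corresponding norm of the unpenalized solution (the scoring-matrix
reference norm is divided by 4).  Penalty "norms" are p-th-power sums
sum |x|^p, so p=2 penalties are smooth; p=1 is handled by an auxiliary-
variable bound formulation solved with SLSQP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .models import (
    MechanismAgnosticModel,
    ShapeReadoutModel,
    interior_positions,
    log_partition_vec,
    profile_length,
    to_sequence_representation,
)
from .seq2shape import Seq2ShapeModel, center_index


@dataclass
class ProjectionConfig:
    """Settings for penalized shape projection."""

    loss: str = "kl"  # "kl" | "affinity"
    p: int = 2  # penalty power (1 or 2)
    lambda_mono: float = 1.0
    lambda_shape: float = 1.0
    features: tuple[str, ...] | None = None  # default: all attached features
    joint: bool = True  # fit all features jointly
    mono_ref_quarter: bool = True  # divide the scoring-matrix reference norm by 4
    maxiter: int = 2000
    ftol: float = 1e-12
    gtol: float = 1e-9
    ref_norm_floor_per_param: float = 1e-8

    def __post_init__(self) -> None:
        if self.loss not in ("kl", "affinity"):
            raise ValueError("loss must be 'kl' or 'affinity'")
        if self.p not in (1, 2):
            raise ValueError("penalty power p must be 1 or 2")


@dataclass
class ProjectionResult:
    """Outcome of a (penalized) shape projection."""

    model: ShapeReadoutModel
    loss: float
    ref_loss: float
    ref_norms: dict[str, float]
    objective: float
    converged: bool
    message: str
    config: ProjectionConfig
    n_iter: int = 0

    @property
    def sequence_model(self) -> MechanismAgnosticModel:
        return to_sequence_representation(self.model)


# ---------------------------------------------------------------------------
# losses


def loss_kl(agn: MechanismAgnosticModel, seq: MechanismAgnosticModel) -> float:
    """KL divergence between the Boltzmann distributions of two models."""
    if agn.k != seq.k:
        raise ValueError("footprint mismatch")
    ls_a, grad_a = log_partition_vec(agn)
    ls_s, _ = log_partition_vec(seq)
    diff = agn.as_vector() - seq.as_vector()
    return float(diff @ grad_a - ls_a + ls_s)


def loss_affinity(agn: MechanismAgnosticModel, seq: MechanismAgnosticModel) -> float:
    """Sum over all k-mers of squared affinity differences (three DP sums)."""
    if agn.k != seq.k:
        raise ValueError("footprint mismatch")
    k = agn.k
    va, vs = agn.as_vector(), seq.as_vector()
    l1, _ = log_partition_vec(MechanismAgnosticModel.from_vector(k, 2 * va))
    l2, _ = log_partition_vec(MechanismAgnosticModel.from_vector(k, 2 * vs))
    l3, _ = log_partition_vec(MechanismAgnosticModel.from_vector(k, va + vs))
    return float(np.exp(l1) + np.exp(l2) - 2 * np.exp(l3))


class _KLLoss:
    """V_KL(seq; agn) and gradient w.r.t. the seq coefficient vector."""

    def __init__(self, agn: MechanismAgnosticModel):
        self.k = agn.k
        self.va = agn.as_vector()
        self.ls_a, self.grad_a = log_partition_vec(agn)

    def value_grad(self, vs: np.ndarray):
        ls_s, grad_s = log_partition_vec(MechanismAgnosticModel.from_vector(self.k, vs))
        v = (self.va - vs) @ self.grad_a - self.ls_a + ls_s
        return float(v), grad_s - self.grad_a


class _AffinityLoss:
    """V_affinity rescaled by exp(-log sigma(2 b_agn)) for overflow safety.

    The rescaling is a fixed positive factor, so optima and the normalized
    penalized objective are unchanged; ``scale`` converts back.
    """

    def __init__(self, agn: MechanismAgnosticModel):
        self.k = agn.k
        self.va = agn.as_vector()
        self.l1, _ = log_partition_vec(
            MechanismAgnosticModel.from_vector(self.k, 2 * self.va)
        )
        self.scale = float(np.exp(self.l1))

    def value_grad(self, vs: np.ndarray):
        l2, g2 = log_partition_vec(MechanismAgnosticModel.from_vector(self.k, 2 * vs))
        l3, g3 = log_partition_vec(
            MechanismAgnosticModel.from_vector(self.k, self.va + vs)
        )
        e2 = np.exp(l2 - self.l1)
        e3 = np.exp(l3 - self.l1)
        v = 1.0 + e2 - 2.0 * e3
        grad = 2.0 * e2 * g2 - 2.0 * e3 * g3
        return float(v), grad


# ---------------------------------------------------------------------------
# parameterization


class _ProjectionParam:
    """Linear map from free projection parameters to seq coefficient vectors.

    theta = [beta0?, beta1 (k*4), interior sensitivities per feature];
    the seq vector is A @ theta.  For the KL loss the intercept is a pure
    gauge direction and is excluded.
    """

    def __init__(
        self,
        k: int,
        seq2shape: dict[str, Seq2ShapeModel],
        features: tuple[str, ...],
        with_intercept: bool,
    ):
        self.k = k
        self.features = features
        self.seq2shape = seq2shape
        self.with_intercept = with_intercept
        nvec = 1 + 4 * k + 16 * (k - 1)
        cols = []
        self.slices: dict[str, slice] = {}
        at = 0
        if with_intercept:
            e = np.zeros(nvec)
            e[0] = 1.0
            cols.append(e[:, None])
            self.slices["beta0"] = slice(at, at + 1)
            at += 1
        B = np.zeros((nvec, 4 * k))
        for i in range(4 * k):
            B[1 + i, i] = 1.0
        cols.append(B)
        self.slices["beta1"] = slice(at, at + 4 * k)
        at += 4 * k
        self.interior: dict[str, np.ndarray] = {}
        for name in features:
            mdl = seq2shape[name]
            if mdl is None:
                raise ValueError(f"missing sequence-to-shape model for feature {name!r}")
            interior = interior_positions(k, mdl.kind)
            if interior.size == 0:
                raise ValueError(
                    f"footprint k={k} leaves no interior position for feature {name!r}"
                )
            self.interior[name] = interior
            F = np.zeros((nvec, interior.size))
            for col, pos in enumerate(interior):
                prof = np.zeros(profile_length(k, mdl.kind))
                prof[pos] = 1.0
                unit = ShapeReadoutModel(
                    k, 0.0, np.zeros((k, 4)), {name: prof}, {name: mdl}
                )
                F[:, col] = to_sequence_representation(unit).as_vector()
            cols.append(F)
            self.slices[name] = slice(at, at + interior.size)
            at += interior.size
        self.A = np.hstack(cols)
        self.n_params = at

    def to_model(self, theta: np.ndarray) -> ShapeReadoutModel:
        beta0 = float(theta[self.slices["beta0"]][0]) if self.with_intercept else 0.0
        beta1 = theta[self.slices["beta1"]].reshape(self.k, 4)
        profiles = {}
        for name in self.features:
            mdl = self.seq2shape[name]
            prof = np.zeros(profile_length(self.k, mdl.kind))
            prof[self.interior[name]] = theta[self.slices[name]]
            profiles[name] = prof
        return ShapeReadoutModel(
            self.k, beta0, beta1, profiles, {n: self.seq2shape[n] for n in self.features}
        )


def _resolve_features(seq2shape: dict[str, Seq2ShapeModel], cfg: ProjectionConfig):
    if cfg.features is None:
        return tuple(seq2shape.keys())
    missing = [f for f in cfg.features if f not in seq2shape]
    if missing:
        raise ValueError(f"no sequence-to-shape model for feature(s) {missing}")
    return tuple(cfg.features)


def _pnorm(x: np.ndarray, p: int) -> float:
    return float(np.sum(np.abs(x) ** p))


# ---------------------------------------------------------------------------
# optimization stages


def _minimize_unpenalized(lossfn, param: _ProjectionParam, cfg: ProjectionConfig, x0=None):
    A = param.A

    def fg(theta):
        v, g = lossfn.value_grad(A @ theta)
        return v, A.T @ g

    x0 = np.zeros(param.n_params) if x0 is None else x0
    res = minimize(
        fg,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": cfg.maxiter, "ftol": cfg.ftol, "gtol": cfg.gtol},
    )
    return res


def unpenalized_project(
    agn: MechanismAgnosticModel,
    seq2shape: dict[str, Seq2ShapeModel],
    cfg: ProjectionConfig | None = None,
) -> ProjectionResult:
    """Stage-1 projection: minimize the loss with no penalty.

    Exposed for diagnostics; the solution along near-null directions is
    not unique, only the achieved loss and the score-level predictions
    are stable.
    """
    cfg = cfg or ProjectionConfig()
    features = _resolve_features(seq2shape, cfg)
    param = _ProjectionParam(agn.k, seq2shape, features, cfg.loss == "affinity")
    lossfn = _KLLoss(agn) if cfg.loss == "kl" else _AffinityLoss(agn)
    res = _minimize_unpenalized(lossfn, param, cfg)
    model = param.to_model(res.x)
    loss = _true_loss(lossfn, res.fun, cfg)
    norms = _block_norms(res.x, param, cfg.p)
    return ProjectionResult(
        model=model,
        loss=loss,
        ref_loss=loss,
        ref_norms=norms,
        objective=float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
        config=cfg,
        n_iter=int(res.nit),
    )


def _true_loss(lossfn, internal_value: float, cfg: ProjectionConfig) -> float:
    if cfg.loss == "affinity":
        return float(internal_value * lossfn.scale)
    return float(internal_value)


def _block_norms(theta, param: _ProjectionParam, p: int) -> dict[str, float]:
    norms = {"beta1": _pnorm(theta[param.slices["beta1"]], p)}
    for name in param.features:
        norms[name] = _pnorm(theta[param.slices[name]], p)
    return norms


def project(
    agn: MechanismAgnosticModel,
    seq2shape: dict[str, Seq2ShapeModel],
    cfg: ProjectionConfig | None = None,
) -> ProjectionResult:
    """Two-stage penalized shape projection.

    Stage 1 minimizes the bare loss to obtain the reference loss and
    reference block norms; stage 2 minimizes

        V/V_ref + lambda_shape * sum_f ||b_f||_p / ||b_f,ref||_p
                + lambda_mono  * ||b_1||_p / (||b_1,ref||_p / 4)

    starting from the stage-1 solution.  Blocks whose reference norm
    falls below the floor have their penalty dropped with a warning.
    Single-feature (non-joint) mode projects each feature separately and
    merges the profiles into one model (scoring matrix from the last fit).
    """
    cfg = cfg or ProjectionConfig()
    features = _resolve_features(seq2shape, cfg)
    if not cfg.joint and len(features) > 1:
        merged_profiles = {}
        last = None
        for name in features:
            sub = ProjectionConfig(**{**cfg.__dict__, "features": (name,), "joint": True})
            last = project(agn, seq2shape, sub)
            merged_profiles[name] = last.model.profiles[name]
        model = ShapeReadoutModel(
            agn.k,
            last.model.beta0,
            last.model.beta1,
            merged_profiles,
            {n: seq2shape[n] for n in features},
        )
        return ProjectionResult(
            model=model,
            loss=last.loss,
            ref_loss=last.ref_loss,
            ref_norms=last.ref_norms,
            objective=last.objective,
            converged=last.converged,
            message="per-feature fits merged",
            config=cfg,
            n_iter=last.n_iter,
        )

    param = _ProjectionParam(agn.k, seq2shape, features, cfg.loss == "affinity")
    lossfn = _KLLoss(agn) if cfg.loss == "kl" else _AffinityLoss(agn)
    stage1 = _minimize_unpenalized(lossfn, param, cfg)
    ref_internal = float(stage1.fun)
    ref_loss = _true_loss(lossfn, ref_internal, cfg)
    ref_norms = _block_norms(stage1.x, param, cfg.p)

    # assemble penalty blocks: (slice, lambda / effective reference norm)
    blocks = []
    floor_m = cfg.ref_norm_floor_per_param
    if cfg.lambda_mono > 0:
        sl = param.slices["beta1"]
        ref = ref_norms["beta1"] / 4.0 if cfg.mono_ref_quarter else ref_norms["beta1"]
        if ref < floor_m * (sl.stop - sl.start):
            warnings.warn("scoring-matrix reference norm below floor; penalty dropped")
        else:
            blocks.append((sl, cfg.lambda_mono / ref))
    if cfg.lambda_shape > 0:
        for name in features:
            sl = param.slices[name]
            ref = ref_norms[name]
            if ref < floor_m * (sl.stop - sl.start):
                warnings.warn(
                    f"reference norm for feature {name!r} below floor; penalty dropped"
                )
            else:
                blocks.append((sl, cfg.lambda_shape / ref))

    vref = max(ref_internal, 1e-300)
    A = param.A
    n = param.n_params

    if cfg.p == 2 or not blocks:

        def fg(theta):
            v, g = lossfn.value_grad(A @ theta)
            f = v / vref
            grad = (A.T @ g) / vref
            for sl, w in blocks:
                x = theta[sl]
                f += w * float(x @ x)
                grad[sl] += 2.0 * w * x
            return f, grad

        res = minimize(
            fg,
            stage1.x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": cfg.maxiter, "ftol": cfg.ftol, "gtol": cfg.gtol},
        )
        theta = res.x
    else:
        # p=1: minimize V/Vref + sum w*t with -t <= theta <= t (SLSQP)
        pen_idx = np.concatenate([np.arange(sl.start, sl.stop) for sl, _ in blocks])
        wvec = np.concatenate([np.full(sl.stop - sl.start, w) for sl, w in blocks])
        m = pen_idx.size

        def fg(z):
            theta, t = z[:n], z[n:]
            v, g = lossfn.value_grad(A @ theta)
            f = v / vref + float(wvec @ t)
            grad = np.concatenate([(A.T @ g) / vref, wvec])
            return f, grad

        def cons_f(z):
            theta, t = z[:n], z[n:]
            x = theta[pen_idx]
            return np.concatenate([t - x, t + x])

        def cons_j(z):
            J = np.zeros((2 * m, n + m))
            rows = np.arange(m)
            J[rows, pen_idx] = -1.0
            J[rows, n + rows] = 1.0
            J[m + rows, pen_idx] = 1.0
            J[m + rows, n + rows] = 1.0
            return J

        z0 = np.concatenate([stage1.x, np.abs(stage1.x[pen_idx]) + 1e-9])
        res = minimize(
            fg,
            z0,
            jac=True,
            method="SLSQP",
            constraints=[{"type": "ineq", "fun": cons_f, "jac": cons_j}],
            options={"maxiter": cfg.maxiter, "ftol": cfg.ftol},
        )
        theta = res.x[:n]

    model = param.to_model(theta)
    v_final, _ = lossfn.value_grad(A @ theta)
    return ProjectionResult(
        model=model,
        loss=_true_loss(lossfn, v_final, cfg),
        ref_loss=ref_loss,
        ref_norms=ref_norms,
        objective=float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
        config=cfg,
        n_iter=int(res.nit),
    )
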