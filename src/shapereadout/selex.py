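"""Desk-scale SELEX simulation and biophysical binding-model inference.

A SELEX experiment starts from a library of probes with an L-bp random
region between fixed flanks.  Round-zero reads sample the (biased) input
library; round-one reads sample probes in proportion to input frequency
times probe selection kappa_i, the total binding affinity summed over all
footprint offsets and orientations plus a non-specific term:

    p_i0 = w_i / Z0,      w_i = exp( sum_phi beta0_phi X_i,phi )
    p_i1 = p_i0 kappa_i / Z1
    kappa_i = exp(beta_NS) + sum_v exp( view score at offset/strand v )

Counts in each round are multinomial.  Inference maximizes the round-zero
multinomial likelihood over the k-mer bias coefficients and then the
round-one likelihood over the non-specific term and the binding model
(mononucleotide, mono+dinucleotide, or mononucleotide plus table-derived
shape predictors = direct shape regression).

This implementation is deliberately desk-scale: the probe space is
enumerated exactly (L <= 12), which makes the partition sums and their
gradients exact and lets every quantity be cross-checked by brute force.
Views are aggregated by their footprint-context k-mer, so the per-
iteration cost is governed by 4^(context width), not by the probe count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm, pearsonr

from ._seq import (
    all_kmer_codes,
    decode,
    encode,
    revcomp_index_permutation,
    windows_to_indices,
)
from .models import MechanismAgnosticModel
from .seq2shape import center_index
from .tables import BASE_CENTERED, KmerShapeTable

MAX_ENUM_L = 12  # largest variable region enumerated exactly


def _codes_from_indices(idx: np.ndarray, L: int) -> np.ndarray:
    idx = np.asarray(idx, dtype=np.int64)
    cols = [((idx >> (2 * (L - 1 - j))) & 3) for j in range(L)]
    return np.stack(cols, axis=1).astype(np.int8)


@dataclass
class SelexDataset:
    """Round-0 and round-1 probe counts over an L-bp variable region.

    Probes are stored as lexicographic indices of the variable region;
    flanks are shared constants.
    """

    L: int
    left_flank: str = ""
    right_flank: str = ""
    r0_probes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    r0_counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    r1_probes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    r1_counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        for attr in ("r0_probes", "r0_counts", "r1_probes", "r1_counts"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=np.int64))
        if np.any(self.r0_counts <= 0) or np.any(self.r1_counts <= 0):
            raise ValueError("probe counts must be positive integers")

    @property
    def n0(self) -> int:
        return int(self.r0_counts.sum())

    @property
    def n1(self) -> int:
        return int(self.r1_counts.sum())

    def probe_seq(self, idx: int) -> str:
        return decode(_codes_from_indices(np.array([idx]), self.L)[0])

    def save_tsv(self, path_r0, path_r1) -> None:
        for path, probes, counts in (
            (path_r0, self.r0_probes, self.r0_counts),
            (path_r1, self.r1_probes, self.r1_counts),
        ):
            with open(path, "w") as fh:
                fh.write(f"# L={self.L} left={self.left_flank} right={self.right_flank}\n")
                codes = _codes_from_indices(probes, self.L)
                for row, c in zip(codes, counts):
                    fh.write(f"{decode(row)}\t{int(c)}\n")


def read_probe_counts(path) -> tuple[list[str], np.ndarray]:
    """Read probes from SEQ<TAB>COUNT text, FASTA, or FASTQ.

    FASTA/FASTQ records count 1 each; identical sequences are aggregated.
    """
    seqs: dict[str, int] = {}
    text = open(path).read(1024)
    if text.startswith(">") or text.startswith("@"):
        from Bio import SeqIO

        fmt = "fasta" if text.startswith(">") else "fastq"
        for rec in SeqIO.parse(path, fmt):
            s = str(rec.seq).upper()
            seqs[s] = seqs.get(s, 0) + 1
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                s = parts[0].upper()
                c = int(parts[1]) if len(parts) > 1 else 1
                seqs[s] = seqs.get(s, 0) + c
    names = list(seqs.keys())
    return names, np.array([seqs[s] for s in names], dtype=np.int64)


def dataset_from_sequences(
    r0: tuple[list[str], np.ndarray],
    r1: tuple[list[str], np.ndarray],
    left_flank: str = "",
    right_flank: str = "",
) -> SelexDataset:
    def to_idx(seqs):
        L = len(seqs[0])
        idx = np.empty(len(seqs), dtype=np.int64)
        for n, s in enumerate(seqs):
            codes = encode(s)
            if codes.size != L:
                raise ValueError("probes must share one variable-region length")
            v = 0
            for c in codes:
                v = v * 4 + int(c)
            idx[n] = v
        return L, idx

    L0, i0 = to_idx(r0[0])
    L1, i1 = to_idx(r1[0])
    if L0 != L1:
        raise ValueError("round-0 and round-1 probe lengths differ")
    return SelexDataset(L0, left_flank, right_flank, i0, r0[1], i1, r1[1])


# ---------------------------------------------------------------------------
# bias model


@dataclass
class BiasModel:
    """Round-zero sequencing-bias model: one coefficient per k_bias-mer.

    log w_i is the sum of coefficients over all k_bias windows of the
    variable region (flanks are constant and absorbed by normalization).
    """

    k_bias: int
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (4**self.k_bias,):
            raise ValueError(f"bias model needs {4 ** self.k_bias} coefficients")

    def log_w(self, codes: np.ndarray) -> np.ndarray:
        win = windows_to_indices(codes, self.k_bias)
        return self.beta[win].sum(axis=1)

    def gauge_fixed(self) -> "BiasModel":
        return BiasModel(self.k_bias, self.beta - self.beta.mean())


def uniform_bias(k_bias: int = 1) -> BiasModel:
    return BiasModel(k_bias, np.zeros(4**k_bias))


# ---------------------------------------------------------------------------
# selection model


@dataclass
class SelectionModel:
    """Probe selection: non-specific term plus footprint views.

    ``model`` scores the k-bp footprint (mono or mono+di).  Optional
    ``shape_coefs`` add table-derived shape predictors: coefficient
    profile per feature (one entry per base position or step of the
    footprint) multiplying the mean-centered table value of the shape
    window centered there, with context taken from the neighboring probe
    or flank bases.
    """

    beta_ns: float
    model: MechanismAgnosticModel
    shape_coefs: dict[str, np.ndarray] = field(default_factory=dict)
    shape_tables: dict[str, KmerShapeTable] = field(default_factory=dict)
    rc_symmetric: bool = False
    log_likelihood: float | None = None
    converged: bool | None = None

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def uses_shape(self) -> bool:
        return bool(self.shape_coefs)

    def context_pad(self) -> int:
        return 2 if self.uses_shape else 0

    def view_scores(self, ctx_codes: np.ndarray) -> np.ndarray:
        """Scores of footprint views given (n, k + 2*pad) context codes."""
        pad = self.context_pad()
        core = ctx_codes[:, pad : pad + self.k] if pad else ctx_codes
        s = self.model.score_codes(core)
        for name, coef in self.shape_coefs.items():
            tbl = self.shape_tables[name]
            w, c = tbl.k, center_index(tbl.k, tbl.kind)
            centered = tbl.values - tbl.values.mean()
            win = windows_to_indices(ctx_codes, w)
            for pos in np.nonzero(coef)[0]:
                start = pad + pos - c
                s += coef[pos] * centered[win[:, start]]
        return s

    def kappa(self, full_codes: np.ndarray) -> np.ndarray:
        """kappa for full probe sequences (flank + variable + flank)."""
        full_codes = np.atleast_2d(full_codes)
        pad = self.context_pad()
        T = full_codes.shape[1]
        out = np.full(full_codes.shape[0], np.exp(self.beta_ns))
        from ._seq import revcomp_codes

        for o in range(pad, T - self.k - pad + 1):
            ctx = full_codes[:, o - pad : o + self.k + pad]
            out += np.exp(self.view_scores(ctx))
            out += np.exp(self.view_scores(revcomp_codes(ctx)))
        return out


# ---------------------------------------------------------------------------
# probe-space enumeration helpers


class _ProbeSpace:
    def __init__(self, L: int, left_flank: str, right_flank: str):
        if L > MAX_ENUM_L:
            raise ValueError(
                f"variable region L={L} exceeds the desk-scale enumeration limit "
                f"({MAX_ENUM_L}); downsample or shorten the design"
            )
        self.L = L
        self.left = encode(left_flank) if left_flank else np.empty(0, dtype=np.int64)
        self.right = encode(right_flank) if right_flank else np.empty(0, dtype=np.int64)
        self.T = self.left.size + L + self.right.size

    def full_codes(self, probe_idx: np.ndarray | None = None) -> np.ndarray:
        if probe_idx is None:
            var = all_kmer_codes(self.L)
        else:
            var = _codes_from_indices(probe_idx, self.L)
        n = var.shape[0]
        parts = []
        if self.left.size:
            parts.append(np.broadcast_to(self.left.astype(np.int8), (n, self.left.size)))
        parts.append(var)
        if self.right.size:
            parts.append(np.broadcast_to(self.right.astype(np.int8), (n, self.right.size)))
        return np.concatenate(parts, axis=1)


def simulate_selex(
    bias: BiasModel,
    sel: SelectionModel,
    L: int,
    n0: int,
    n1: int,
    seed: int,
    left_flank: str = "",
    right_flank: str = "",
) -> SelexDataset:
    """Draw a two-round dataset by exact multinomial sampling.

    The probe space is enumerated, round-0 probabilities computed from the
    bias model, round-1 probabilities as p0 * kappa / Z1, and counts drawn
    multinomially.
    """
    space = _ProbeSpace(L, left_flank, right_flank)
    var_codes = all_kmer_codes(L)
    log_w = bias.log_w(var_codes)
    log_w -= log_w.max()
    p0 = np.exp(log_w)
    p0 /= p0.sum()
    kap = sel.kappa(space.full_codes())
    p1 = p0 * kap
    p1 /= p1.sum()
    rng = np.random.default_rng(seed)
    c0 = rng.multinomial(n0, p0)
    c1 = rng.multinomial(n1, p1)
    nz0, nz1 = np.nonzero(c0)[0], np.nonzero(c1)[0]
    return SelexDataset(
        L, left_flank, right_flank, nz0, c0[nz0], nz1, c1[nz1]
    )


def split_heldout(
    data: SelexDataset, seed: int, frac: float = 0.5
) -> tuple[SelexDataset, tuple[np.ndarray, np.ndarray]]:
    """Split round-1 reads into training and held-out halves.

    Each read is assigned independently (binomial thinning of the count
    vector with a fixed seed).  Returns the training dataset and the
    held-out (probes, counts) pair.
    """
    rng = np.random.default_rng(seed)
    held = rng.binomial(data.r1_counts, frac)
    train = data.r1_counts - held
    keep_t = train > 0
    keep_h = held > 0
    train_ds = SelexDataset(
        data.L,
        data.left_flank,
        data.right_flank,
        data.r0_probes,
        data.r0_counts,
        data.r1_probes[keep_t],
        train[keep_t],
    )
    return train_ds, (data.r1_probes[keep_h], held[keep_h])


# ---------------------------------------------------------------------------
# round-0 fit


def fit_bias(
    probes: np.ndarray,
    counts: np.ndarray,
    L: int,
    k_bias: int,
    maxiter: int = 500,
) -> BiasModel:
    """Maximize the round-zero multinomial likelihood over k-mer bias
    coefficients (zero-sum gauge applied to the result)."""
    if not 1 <= k_bias <= 4:
        raise ValueError("desk-scale bias models support k_bias in 1..4")
    nb = 4**k_bias
    all_win = windows_to_indices(all_kmer_codes(L), k_bias)  # (4^L, L-kb+1)
    obs_win = windows_to_indices(_codes_from_indices(probes, L), k_bias)
    n = float(counts.sum())
    obs_counts = np.zeros(nb)
    for j in range(obs_win.shape[1]):
        np.add.at(obs_counts, obs_win[:, j], counts)

    def negll(beta):
        log_w = beta[all_win].sum(axis=1)
        m = log_w.max()
        ew = np.exp(log_w - m)
        Z = ew.sum()
        f = -(obs_counts @ beta) + n * (m + np.log(Z))
        expect = np.zeros(nb)
        for j in range(all_win.shape[1]):
            expect += np.bincount(all_win[:, j], weights=ew, minlength=nb)
        grad = -obs_counts + n * expect / Z
        return f, grad

    res = minimize(
        negll,
        np.zeros(nb),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
    )
    if not res.success:
        gnorm = float(np.linalg.norm(res.jac))
        raise RuntimeError(
            f"bias fit did not converge: {res.message} (|grad| = {gnorm:.3g})"
        )
    return BiasModel(k_bias, res.x - res.x.mean()).gauge_fixed()


# ---------------------------------------------------------------------------
# round-1 fit


class _ViewSystem:
    """Aggregated view bookkeeping for one dataset + footprint.

    Views are footprint placements (offset, strand) within the full
    sequence; each view of each probe is summarized by the index of its
    context window (footprint +- 2 bp when shape predictors are used).
    Minus-strand views reuse the plus-strand window through the
    reverse-complement index permutation, so one score table over 4^m
    context k-mers drives both strands.
    """

    def __init__(
        self,
        space: _ProbeSpace,
        k: int,
        pad: int,
        probes: np.ndarray,
        weights_all: np.ndarray,
    ):
        self.k = k
        self.pad = pad
        self.m = k + 2 * pad
        self.nctx = 4**self.m
        rc = revcomp_index_permutation(self.m)
        full_all = space.full_codes()
        full_obs = space.full_codes(probes)
        win_all = windows_to_indices(full_all, self.m)
        win_obs = windows_to_indices(full_obs, self.m)
        offsets = range(pad, space.T - k - pad + 1)
        self.obs_ctx = []  # per view: (n_obs,) effective context indices
        self.W = np.zeros(self.nctx)  # bias-weighted context incidence, all probes
        for o in offsets:
            col = o - pad
            for strand in (0, 1):
                a = win_all[:, col] if strand == 0 else rc[win_all[:, col]]
                b = win_obs[:, col] if strand == 0 else rc[win_obs[:, col]]
                self.W += np.bincount(a, weights=weights_all, minlength=self.nctx)
                self.obs_ctx.append(b)
        self.n_views = len(self.obs_ctx)
        self.ctx_codes = all_kmer_codes(self.m).astype(np.int64)

    def kappa_obs(self, es: np.ndarray, e_ns: float) -> np.ndarray:
        kap = np.full(self.obs_ctx[0].size, e_ns)
        for ctx in self.obs_ctx:
            kap += es[ctx]
        return kap

    def data_bincount(self, weights: np.ndarray) -> np.ndarray:
        out = np.zeros(self.nctx)
        for ctx in self.obs_ctx:
            out += np.bincount(ctx, weights=weights, minlength=self.nctx)
        return out


class _SelectionParam:
    """Flattened parameter vector for the round-1 fit.

    Layout: [beta_ns, beta0, beta1 (k*4), beta2 ((k-1)*16, mono+di only),
    shape coefficients per feature].  RC symmetry, when requested, is
    imposed by averaging the parameters with their reverse-complement
    image before scoring (shape profiles are mirror-averaged; the tables
    themselves are RC-symmetric).
    """

    def __init__(self, k, features, shape_tables, rc_symmetric):
        self.k = k
        self.with_di = features == "mono+di"
        self.shape_names = tuple(shape_tables.keys()) if features == "mono+shape" else ()
        self.shape_tables = shape_tables
        self.rc = rc_symmetric
        at = 2  # beta_ns, beta0
        self.sl_b1 = slice(at, at + 4 * k)
        at = self.sl_b1.stop
        self.sl_b2 = slice(at, at + (16 * (k - 1) if self.with_di else 0))
        at = self.sl_b2.stop
        self.sl_shape = {}
        for name in self.shape_names:
            ln = k if shape_tables[name].kind == BASE_CENTERED else k - 1
            self.sl_shape[name] = slice(at, at + ln)
            at += ln
        self.n = at

    def symmetrize(self, theta: np.ndarray) -> np.ndarray:
        if not self.rc:
            return theta
        out = theta.copy()
        k = self.k
        b1 = theta[self.sl_b1].reshape(k, 4)
        out[self.sl_b1] = (0.5 * (b1 + b1[::-1, ::-1])).ravel()
        if self.with_di:
            from .models import _rc_dinuc_perm

            b2 = theta[self.sl_b2].reshape(k - 1, 16)
            out[self.sl_b2] = (0.5 * (b2 + b2[::-1][:, _rc_dinuc_perm()])).ravel()
        for name, sl in self.sl_shape.items():
            prof = theta[sl]
            out[sl] = 0.5 * (prof + prof[::-1])
        return out

    def symmetrize_grad(self, grad: np.ndarray) -> np.ndarray:
        # the symmetrizer is a symmetric idempotent linear map
        return self.symmetrize(grad)

    def to_selection_model(self, theta: np.ndarray) -> SelectionModel:
        theta = self.symmetrize(theta)
        k = self.k
        b2 = (
            theta[self.sl_b2].reshape(k - 1, 16)
            if self.with_di
            else np.zeros((k - 1, 16))
        )
        model = MechanismAgnosticModel(
            k, float(theta[1]), theta[self.sl_b1].reshape(k, 4), b2
        )
        coefs = {name: theta[sl].copy() for name, sl in self.sl_shape.items()}
        return SelectionModel(
            beta_ns=float(theta[0]),
            model=model,
            shape_coefs=coefs,
            shape_tables={n: self.shape_tables[n] for n in self.shape_names},
            rc_symmetric=self.rc,
        )


def fit_selection(
    data: SelexDataset,
    bias: BiasModel,
    k: int,
    features: str = "mono",
    shape_tables: dict[str, KmerShapeTable] | None = None,
    rc_symmetric: bool = False,
    beta_ns_init: float = -10.0,
    maxiter: int = 1000,
    seed: int = 0,
) -> SelectionModel:
    """Maximize the round-one multinomial likelihood.

    ``features`` selects the binding-model predictors: "mono",
    "mono+di", or "mono+shape" (direct shape regression; requires
    ``shape_tables``, whose values are centered to zero mean over all
    k-mers before use).  Binding parameters start near zero with a small
    seed-controlled perturbation (the likelihood is invariant under
    strand swap, so the exactly-zero start is a stationary point of that
    symmetry and would trap the optimizer on the symmetric manifold);
    the non-specific term starts at ``beta_ns_init``.  The fitted model
    is reported in the orientation found; strand orientation is not
    identifiable without external information.
    """
    if features not in ("mono", "mono+di", "mono+shape"):
        raise ValueError(f"unknown feature set {features!r}")
    if features == "mono+shape" and not shape_tables:
        raise ValueError("mono+shape requires shape_tables")
    if data.r1_probes.size < 2:
        raise ValueError("degenerate round-1 data: need at least two distinct probes")
    shape_tables = shape_tables or {}
    space = _ProbeSpace(data.L, data.left_flank, data.right_flank)
    pad = 2 if features == "mono+shape" else 0
    if space.T < k + 2 * pad:
        raise ValueError("probe plus flanks too short to hold a single view")
    log_w = bias.log_w(all_kmer_codes(data.L))
    w_all = np.exp(log_w - log_w.max())
    sys = _ViewSystem(space, k, pad, data.r1_probes, w_all)
    W0 = float(w_all.sum())
    counts = data.r1_counts.astype(float)
    n1 = float(counts.sum())

    param = _SelectionParam(k, features, shape_tables, rc_symmetric)
    m = sys.m
    codes = sys.ctx_codes
    # per-position base codes and adjacent-dinucleotide codes of the context
    core = codes[:, pad : pad + k]
    di = core[:, :-1] * 4 + core[:, 1:]
    # shape predictor matrix: centered table value of the window centered at
    # each footprint position/step
    shape_X = {}
    for name in param.shape_names:
        tbl = shape_tables[name]
        w, c = tbl.k, center_index(tbl.k, tbl.kind)
        centered = tbl.values - tbl.values.mean()
        win = windows_to_indices(codes, w)
        npos = k if tbl.kind == BASE_CENTERED else k - 1
        cols = [centered[win[:, pad + p - c]] for p in range(npos)]
        shape_X[name] = np.stack(cols, axis=1)  # (4^m, npos)

    def context_scores(theta):
        s = np.full(sys.nctx, theta[1])
        b1 = theta[param.sl_b1].reshape(k, 4)
        for p in range(k):
            s += b1[p, core[:, p]]
        if param.with_di:
            b2 = theta[param.sl_b2].reshape(k - 1, 16)
            for j in range(k - 1):
                s += b2[j, di[:, j]]
        for name, sl in param.sl_shape.items():
            s += shape_X[name] @ theta[sl]
        return s

    def negll(theta_free):
        theta = param.symmetrize(theta_free)
        score = context_scores(theta)
        shift = max(float(score.max()), theta[0])
        es = np.exp(score - shift)
        e_ns = np.exp(theta[0] - shift)
        kap = sys.kappa_obs(es, e_ns)
        Zk = e_ns * W0 + float(sys.W @ es)
        f = -(counts @ np.log(kap)) + n1 * np.log(Zk)  # shift cancels
        # d f / d es_c and d f / d e_ns
        D = sys.data_bincount(counts / kap)
        T = es * (n1 * sys.W / Zk - D)
        g_ns = e_ns * (n1 * W0 / Zk - float((counts / kap).sum()))
        grad = np.zeros(param.n)
        grad[0] = g_ns
        grad[1] = float(T.sum())
        g1 = np.empty((k, 4))
        for p in range(k):
            g1[p] = np.bincount(core[:, p], weights=T, minlength=4)
        grad[param.sl_b1] = g1.ravel()
        if param.with_di:
            g2 = np.empty((k - 1, 16))
            for j in range(k - 1):
                g2[j] = np.bincount(di[:, j], weights=T, minlength=16)
            grad[param.sl_b2] = g2.ravel()
        for name, sl in param.sl_shape.items():
            grad[sl] = shape_X[name].T @ T
        return f, param.symmetrize_grad(grad)

    x0 = np.random.default_rng(seed).normal(0.0, 0.05, param.n)
    x0[0] = beta_ns_init
    x0[1] = 0.0
    res = minimize(
        negll,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    sel = param.to_selection_model(res.x)
    sel.log_likelihood = float(-res.fun)
    sel.converged = bool(res.success)
    return sel


def round1_log_likelihood(
    data: SelexDataset, bias: BiasModel, sel: SelectionModel
) -> float:
    """Round-one multinomial log-likelihood of a selection model (up to the
    bias-only constant), for comparing fitted and generating models."""
    space = _ProbeSpace(data.L, data.left_flank, data.right_flank)
    log_w = bias.log_w(all_kmer_codes(data.L))
    w_all = np.exp(log_w - log_w.max())
    kap_all = sel.kappa(space.full_codes())
    kap_obs = sel.kappa(space.full_codes(data.r1_probes))
    Zk = float(w_all @ kap_all)
    return float(data.r1_counts @ np.log(kap_obs)) - data.n1 * np.log(Zk)


# ---------------------------------------------------------------------------
# partition-sum cross-checks (flankless probes)


def partition_sums_bruteforce(
    bias: BiasModel, sel: SelectionModel, L: int
) -> tuple[float, float]:
    """(Z0, sum_i w_i kappa_i) by enumerating all 4^L flankless probes."""
    space = _ProbeSpace(L, "", "")
    w = np.exp(bias.log_w(all_kmer_codes(L)))
    kap = sel.kappa(space.full_codes())
    return float(w.sum()), float(w @ kap)


def partition_sums_dp(bias: BiasModel, sel: SelectionModel, L: int) -> tuple[float, float]:
    """(Z0, sum_i w_i kappa_i) by transfer-matrix dynamic programming.

    Each term is a product of local window factors (bias k-mers, view
    mono/di/shape windows), summed over sequences by carrying partial sums
    over suffix states.  Flankless probes only; exists as the O(L)
    alternative to enumeration and as its cross-check.
    """
    k = sel.k
    pad = sel.context_pad()

    def weight_sum(extra_factors):
        factors = [(s, bias.k_bias, np.exp(bias.beta)) for s in range(L - bias.k_bias + 1)]
        factors += extra_factors
        wmax = max(w for _, w, _ in factors)
        nstate = 4 ** (wmax - 1)
        states = np.arange(nstate)
        # initialize on the first wmax-1 bases
        prefix = all_kmer_codes(wmax - 1).astype(np.int64)
        V = np.ones(nstate)
        for start, w, tab in factors:
            if start + w <= wmax - 1:
                idx = windows_to_indices(prefix, w)[:, start]
                V = V * tab[idx]
        for t in range(wmax - 1, L):
            newV = np.zeros(nstate)
            for b in range(4):
                ext = states * 4 + b  # last wmax bases
                fac = np.ones(nstate)
                for start, w, tab in factors:
                    if start + w - 1 == t:
                        fac = fac * tab[ext % (4**w)]
                np.add.at(newV, ext % nstate, V * fac)
            V = newV
        return float(V.sum())

    Z0 = weight_sum([])
    total = np.exp(sel.beta_ns) * Z0
    rc = revcomp_index_permutation(k + 2 * pad)
    # score table over context windows, as one factor of width k + 2*pad
    ctx_codes = all_kmer_codes(k + 2 * pad)
    es_plus = np.exp(sel.view_scores(ctx_codes))
    es_minus = es_plus[rc]
    for o in range(pad, L - k - pad + 1):
        for es in (es_plus, es_minus):
            total += weight_sum([(o - pad, k + 2 * pad, es)])
    return Z0, total


# ---------------------------------------------------------------------------
# performance quantification


def kmer_performance(
    sel: SelectionModel,
    bias: BiasModel,
    heldout: tuple[np.ndarray, np.ndarray],
    L: int,
    left_flank: str = "",
    right_flank: str = "",
    m: int = 10,
    min_count: int = 100,
):
    """Pearson r between log observed and log expected m-mer counts.

    Observed counts tabulate all m-bp windows of the held-out reads.
    Expected counts slide the same window over every probe weighted by the
    model's round-one probe probability times the held-out read total.
    m-mers with observed count below ``min_count`` are dropped.  Returns
    (r, n_retained, observed, expected) with the count arrays aligned.
    """
    probes, counts = heldout
    space = _ProbeSpace(L, left_flank, right_flank)
    n_held = float(counts.sum())
    obs = np.zeros(4**m)
    win_obs = windows_to_indices(space.full_codes(probes), m)
    for j in range(win_obs.shape[1]):
        np.add.at(obs, win_obs[:, j], counts)
    log_w = bias.log_w(all_kmer_codes(L))
    w_all = np.exp(log_w - log_w.max())
    kap = sel.kappa(space.full_codes())
    p1 = w_all * kap
    p1 /= p1.sum()
    exp_counts = np.zeros(4**m)
    win_all = windows_to_indices(space.full_codes(), m)
    for j in range(win_all.shape[1]):
        exp_counts += np.bincount(win_all[:, j], weights=p1, minlength=4**m)
    exp_counts *= n_held
    keep = obs >= min_count
    n_kept = int(keep.sum())
    if n_kept < 3:
        raise ValueError(
            f"only {n_kept} {m}-mers reach count {min_count}; not enough for a correlation"
        )
    o, e = obs[keep], np.maximum(exp_counts[keep], 1e-12)
    r = float(pearsonr(np.log(o), np.log(e))[0])
    return r, n_kept, o, e


def compare_r_fisher(r1: float, r2: float, n_effective: int) -> float:
    """Two-tailed p-value for a difference of correlations via Fisher's
    r-to-z transformation."""
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n_effective <= 3:
        raise ValueError("effective sample size must exceed 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(2.0 / (n_effective - 3))
    return float(2.0 * (1.0 - norm.cdf(abs(z1 - z2) / se)))
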