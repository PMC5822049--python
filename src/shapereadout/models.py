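"""Free-energy models of TF binding and their partition sums.

Two model classes are provided.  The mechanism-agnostic model scores a
k-mer with an intercept, a position-specific scoring matrix, and adjacent
dinucleotide terms, all in -ddG/RT units (larger = stronger binding).
The shape-readout model replaces the dinucleotide block with per-position
shape-sensitivity coefficients (-ddG/RT per unit shape) that multiply the
shape value predicted by an attached sequence-to-shape model; because a
mono+di sequence-to-shape model is itself linear in mono and dinucleotide
indicators, every shape-readout model has an exact mechanism-agnostic
"sequence-only" representation, computed by convolving each sensitivity
profile with the sequence-to-shape regression coefficients.

Partition sums sigma(beta) = sum_s exp(score(s)) over all 4^k k-mers are
evaluated by a left-to-right transfer recursion in log space, with the
gradient obtained from forward-backward marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """Stable log-sum-exp over one axis (lean replacement for scipy's,
    which dominates runtime at these tiny array sizes)."""
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)

from ._seq import all_kmer_codes, encode, revcomp_codes
from .seq2shape import Seq2ShapeModel, center_index
from .tables import BASE_CENTERED, STEP_CENTERED

_RC_DINUC = None


def _rc_dinuc_perm() -> np.ndarray:
    """perm[d] = index of the reverse complement of dinucleotide d."""
    global _RC_DINUC
    if _RC_DINUC is None:
        d = np.arange(16)
        a, b = d // 4, d % 4
        _RC_DINUC = (3 - b) * 4 + (3 - a)
    return _RC_DINUC


@dataclass
class MechanismAgnosticModel:
    """Mono + adjacent-dinucleotide free-energy model over a k-bp footprint."""

    k: int
    beta0: float = 0.0
    beta1: np.ndarray | None = None  # (k, 4)
    beta2: np.ndarray | None = None  # (k-1, 16)

    def __post_init__(self) -> None:
        if self.beta1 is None:
            self.beta1 = np.zeros((self.k, 4))
        if self.beta2 is None:
            self.beta2 = np.zeros((max(self.k - 1, 0), 16))
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        if self.beta1.shape != (self.k, 4):
            raise ValueError(f"beta1 must be ({self.k}, 4)")
        if self.beta2.shape != (max(self.k - 1, 0), 16):
            raise ValueError(f"beta2 must be ({self.k - 1}, 16)")

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
        if codes.shape[1] != self.k:
            raise ValueError(f"expected {self.k}-mers")
        s = np.full(codes.shape[0], self.beta0)
        for i in range(self.k):
            s += self.beta1[i, codes[:, i]]
        for j in range(self.k - 1):
            s += self.beta2[j, codes[:, j] * 4 + codes[:, j + 1]]
        return s

    def score(self, kmer: str) -> float:
        return float(self.score_codes(encode(kmer)[None, :])[0])

    def score_all(self) -> np.ndarray:
        return self.score_codes(all_kmer_codes(self.k))

    def reverse_complemented(self) -> "MechanismAgnosticModel":
        """The model scoring the reverse-complement strand."""
        b1 = self.beta1[::-1, ::-1].copy()
        b2 = self.beta2[::-1][:, _rc_dinuc_perm()].copy()
        return MechanismAgnosticModel(self.k, self.beta0, b1, b2)

    def rc_symmetrized(self) -> "MechanismAgnosticModel":
        rc = self.reverse_complemented()
        return MechanismAgnosticModel(
            self.k, self.beta0, 0.5 * (self.beta1 + rc.beta1), 0.5 * (self.beta2 + rc.beta2)
        )

    def is_rc_symmetric(self, tol: float = 1e-9) -> bool:
        rc = self.reverse_complemented()
        return bool(
            np.allclose(self.beta1, rc.beta1, atol=tol)
            and np.allclose(self.beta2, rc.beta2, atol=tol)
        )

    def as_vector(self) -> np.ndarray:
        return np.concatenate(([self.beta0], self.beta1.ravel(), self.beta2.ravel()))

    @classmethod
    def from_vector(cls, k: int, vec: np.ndarray) -> "MechanismAgnosticModel":
        vec = np.asarray(vec, dtype=float)
        b0 = float(vec[0])
        b1 = vec[1 : 1 + 4 * k].reshape(k, 4)
        b2 = vec[1 + 4 * k :].reshape(k - 1, 16)
        return cls(k, b0, b1, b2)

    def gauge_fixed(self) -> "MechanismAgnosticModel":
        """Shift per-position/per-step means into the intercept (display gauge)."""
        b1 = self.beta1 - self.beta1.mean(axis=1, keepdims=True)
        b2 = self.beta2 - self.beta2.mean(axis=1, keepdims=True)
        b0 = self.beta0 + self.beta1.mean(axis=1).sum() + self.beta2.mean(axis=1).sum()
        return MechanismAgnosticModel(self.k, b0, b1, b2)

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "beta0": self.beta0,
            "beta1": self.beta1.tolist(),
            "beta2": self.beta2.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MechanismAgnosticModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["k"], float(d["beta0"]), np.asarray(d["beta1"]), np.asarray(d["beta2"])
        )


def read_scoring_matrix(path) -> MechanismAgnosticModel:
    """Import a plain position-specific free-energy matrix.

    Tab-separated text, one row per footprint position with four columns
    (A, C, G, T) in -ddG/RT; '#' comment lines allowed.  Returns a model
    with zero dinucleotide terms.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 columns (A C G T), got {len(parts)}"
                )
            rows.append([float(x) for x in parts])
    if not rows:
        raise ValueError(f"{path}: empty scoring matrix")
    b1 = np.asarray(rows)
    return MechanismAgnosticModel(b1.shape[0], 0.0, b1, None)


def interior_positions(k: int, kind: str) -> np.ndarray:
    """Positions where a shape-sensitivity coefficient may be nonzero.

    Base-centered features need a full pentamer inside the footprint, so
    the first two and last two base positions are excluded; step-centered
    features need a full tetramer, excluding the first and last step.
    """
    if kind == BASE_CENTERED:
        return np.arange(2, k - 2)
    return np.arange(1, k - 2)


def profile_length(k: int, kind: str) -> int:
    return k if kind == BASE_CENTERED else k - 1


@dataclass
class ShapeReadoutModel:
    """Scoring matrix plus per-feature shape-sensitivity profiles.

    ``profiles[name]`` has one entry per base position (base-centered
    features) or per step (step-centered); entries outside the interior
    window must be zero.  ``seq2shape[name]`` supplies the linear
    sequence-to-shape model used to evaluate the feature.
    """

    k: int
    beta0: float = 0.0
    beta1: np.ndarray | None = None
    profiles: dict[str, np.ndarray] = field(default_factory=dict)
    seq2shape: dict[str, Seq2ShapeModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beta1 is None:
            self.beta1 = np.zeros((self.k, 4))
        self.beta1 = np.asarray(self.beta1, dtype=float)
        if self.beta1.shape != (self.k, 4):
            raise ValueError(f"beta1 must be ({self.k}, 4)")
        for name, prof in self.profiles.items():
            self.profiles[name] = prof = np.asarray(prof, dtype=float)
            if name not in self.seq2shape:
                raise ValueError(f"no sequence-to-shape model attached for feature {name!r}")
            mdl = self.seq2shape[name]
            expect = profile_length(self.k, mdl.kind)
            if prof.shape != (expect,):
                raise ValueError(
                    f"profile for {name!r} must have length {expect}, got {prof.shape}"
                )
            interior = interior_positions(self.k, mdl.kind)
            mask = np.ones(expect, dtype=bool)
            mask[interior] = False
            if np.any(prof[mask] != 0.0):
                raise ValueError(
                    f"profile for {name!r} must vanish at boundary positions"
                )

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
        if codes.shape[1] != self.k:
            raise ValueError(f"expected {self.k}-mers")
        s = np.full(codes.shape[0], self.beta0)
        for i in range(self.k):
            s += self.beta1[i, codes[:, i]]
        for name, prof in self.profiles.items():
            mdl = self.seq2shape[name]
            w = mdl.k
            c = center_index(w, mdl.kind)
            for pos in np.nonzero(prof)[0]:
                window = codes[:, pos - c : pos - c + w]
                s += prof[pos] * mdl.predict_codes(window)
        return s

    def score(self, kmer: str) -> float:
        return float(self.score_codes(encode(kmer)[None, :])[0])

    def score_all(self) -> np.ndarray:
        return self.score_codes(all_kmer_codes(self.k))


def to_sequence_representation(srm: ShapeReadoutModel) -> MechanismAgnosticModel:
    """Exact mono+di representation of a shape-readout model.

    Each sensitivity coefficient contributes the attached model's intercept
    to beta0, its mononucleotide coefficients to the scoring matrix at the
    covered positions, and its dinucleotide coefficients to the covered
    steps.  Scores agree with the shape-readout model on every k-mer.
    """
    k = srm.k
    beta0 = srm.beta0
    beta1 = srm.beta1.copy()
    beta2 = np.zeros((k - 1, 16))
    for name, prof in srm.profiles.items():
        mdl = srm.seq2shape[name]
        if mdl.order not in ("mono", "mono+di"):
            raise ValueError(
                "sequence-only representation requires a mono or mono+di "
                f"sequence-to-shape model for feature {name!r}"
            )
        w = mdl.k
        c = center_index(w, mdl.kind)
        g1 = mdl.gamma1  # (w, 4), window position-indexed
        g2 = mdl.gamma2  # (w-1, 16)
        for pos in np.nonzero(prof)[0]:
            amp = prof[pos]
            beta0 += amp * mdl.gamma0
            start = pos - c  # footprint position of window position 0
            for wp in range(w):
                beta1[start + wp] += amp * g1[wp]
            for ws in range(w - 1):
                beta2[start + ws] += amp * g2[ws]
    return MechanismAgnosticModel(k, beta0, beta1, beta2)


def log_partition(model: MechanismAgnosticModel):
    """log sigma(beta) and the gradient of log sigma by transfer recursion.

    Returns ``(log_sigma, (g0, G1, G2))`` where the gradient components
    are d log sigma / d beta0 (= 1), d/d beta1 (the marginal base
    probabilities under p(s) ~ exp(score)), and d/d beta2 (the marginal
    adjacent-dinucleotide probabilities).
    """
    k = model.k
    b1 = model.beta1
    b2r = model.beta2.reshape(k - 1, 4, 4)
    la = np.empty((k, 4))
    la[0] = b1[0]
    for i in range(1, k):
        # la[i, c] = logsumexp_b(la[i-1, b] + b2[i-1, b*4+c]) + b1[i, c]
        la[i] = _lse(la[i - 1][:, None] + b2r[i - 1], axis=0) + b1[i]
    log_inner = _lse(la[-1], axis=0)
    log_sigma = model.beta0 + log_inner
    lb = np.empty((k, 4))
    lb[-1] = 0.0
    for i in range(k - 2, -1, -1):
        lb[i] = _lse(b2r[i] + (b1[i + 1] + lb[i + 1])[None, :], axis=1)
    G1 = np.exp(la + lb - log_inner)
    M = la[:-1, :, None] + b2r + (b1[1:] + lb[1:])[:, None, :]
    G2 = np.exp(M - log_inner).reshape(k - 1, 16)
    return log_sigma, (1.0, G1, G2)


def log_partition_vec(model: MechanismAgnosticModel):
    """As :func:`log_partition` but with the gradient flattened to match
    :meth:`MechanismAgnosticModel.as_vector` layout."""
    log_sigma, (g0, G1, G2) = log_partition(model)
    return log_sigma, np.concatenate(([g0], G1.ravel(), G2.ravel()))


def partition_sum(model: MechanismAgnosticModel):
    """sigma(beta) = sum_s exp(score(s)) and its gradient nabla sigma.

    Evaluated from the log-space transfer recursion; suitable for the
    moderate scores used in tests and projection (use
    :func:`log_partition` directly for large footprints/coefficients).
    """
    log_sigma, (g0, G1, G2) = log_partition(model)
    sigma = float(np.exp(log_sigma))
    return sigma, (sigma * g0, sigma * G1, sigma * G2)


def scale_model(model: MechanismAgnosticModel, factor: float) -> MechanismAgnosticModel:
    return MechanismAgnosticModel(
        model.k, factor * model.beta0, factor * model.beta1, factor * model.beta2
    )


def add_models(a: MechanismAgnosticModel, b: MechanismAgnosticModel) -> MechanismAgnosticModel:
    if a.k != b.k:
        raise ValueError("footprint mismatch")
    return MechanismAgnosticModel(a.k, a.beta0 + b.beta0, a.beta1 + b.beta1, a.beta2 + b.beta2)
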