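"""Linear sequence-to-shape models.

A k-mer shape table can be compressed into a linear regression on local
sequence features: an intercept, mononucleotide indicators (one per window
position and base), adjacent-dinucleotide indicators, and optionally
indicators for all (also non-adjacent) position pairs.  The indicator
design is deliberately redundant (each position's four indicators sum to
one), so coefficients are identified only up to gauge; predictions are
gauge-invariant and are computed from the minimum-norm least-squares
solution.

Degrees of freedom are counted as nonzero eigenvalues of the (optionally
reverse-complement-projected) normal matrix; for the RC-symmetric designs
the counts obey the closed forms ceil((3k+1)/2) for the mononucleotide
model and 4*floor(3k/2)-2 for the dinucleotide model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._seq import (
    BASES,
    all_kmer_codes,
    encode,
    rc_class_representatives,
    revcomp_index_permutation,
)
from .tables import BASE_CENTERED, STEP_CENTERED, KmerShapeTable

MONO = "mono"
MONO_DI = "mono+di"
DI_ONLY = "di-only"
ALL_PAIRS = "all-pairs"
_ORDERS = (MONO, MONO_DI, DI_ONLY, ALL_PAIRS)

#: relative eigenvalue / squared-singular-value cutoff for the pseudoinverse
EIG_RTOL = 1e-9

DINUCS = [a + b for a in BASES for b in BASES]


def center_index(k: int, kind: str) -> int:
    """Window position of the central base (base-centered) or of the left
    base of the central step (step-centered)."""
    if kind == BASE_CENTERED:
        return (k - 1) // 2
    return k // 2 - 1


@dataclass
class DesignLayout:
    """Column bookkeeping for a sequence-feature design matrix."""

    k: int
    order: str
    mono_positions: tuple[int, ...]
    n_cols: int
    mono_slice: slice
    di_slice: slice
    pair_blocks: dict[tuple[int, int], slice] = field(default_factory=dict)


def _layout(k: int, order: str, mono_positions=None) -> DesignLayout:
    if order not in _ORDERS:
        raise ValueError(f"unknown design order {order!r}; expected one of {_ORDERS}")
    if order != MONO and k < 2:
        raise ValueError("dinucleotide designs require k >= 2")
    if mono_positions is None:
        mono_positions = tuple(range(k)) if order != DI_ONLY else ()
    else:
        if order != MONO:
            raise ValueError("mono_positions restriction is only supported for order='mono'")
        mono_positions = tuple(mono_positions)
    col = 1  # intercept
    mono_slice = slice(col, col + 4 * len(mono_positions))
    col = mono_slice.stop
    n_steps = (k - 1) if order in (MONO_DI, DI_ONLY, ALL_PAIRS) else 0
    di_slice = slice(col, col + 16 * n_steps)
    col = di_slice.stop
    pair_blocks: dict[tuple[int, int], slice] = {}
    if order == ALL_PAIRS:
        for i in range(k):
            for j in range(i + 2, k):
                pair_blocks[(i, j)] = slice(col, col + 16)
                col += 16
    return DesignLayout(k, order, mono_positions, col, mono_slice, di_slice, pair_blocks)


def design_rows(codes: np.ndarray, layout: DesignLayout) -> np.ndarray:
    """Design-matrix rows for the given k-mer code matrix (n, k)."""
    codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
    n = codes.shape[0]
    X = np.zeros((n, layout.n_cols))
    X[:, 0] = 1.0
    rows = np.arange(n)
    for m, pos in enumerate(layout.mono_positions):
        X[rows, layout.mono_slice.start + 4 * m + codes[:, pos]] = 1.0
    if layout.di_slice.stop > layout.di_slice.start:
        for s in range(layout.k - 1):
            d = codes[:, s] * 4 + codes[:, s + 1]
            X[rows, layout.di_slice.start + 16 * s + d] = 1.0
    for (i, j), sl in layout.pair_blocks.items():
        d = codes[:, i] * 4 + codes[:, j]
        X[rows, sl.start + d] = 1.0
    return X


def build_design(k: int, order: str, mono_positions=None) -> tuple[np.ndarray, DesignLayout]:
    """Full design matrix over all 4^k k-mers in lexicographic row order."""
    layout = _layout(k, order, mono_positions)
    return design_rows(all_kmer_codes(k), layout), layout


@dataclass
class Seq2ShapeModel:
    """Fitted linear model predicting a shape parameter from local sequence."""

    feature_name: str
    k: int
    kind: str
    order: str
    coef: np.ndarray
    layout: DesignLayout
    units: str = "arbitrary"
    r2_insample: float | None = None

    @property
    def gamma0(self) -> float:
        return float(self.coef[0])

    @property
    def gamma1(self) -> np.ndarray:
        """(k, 4) mononucleotide coefficients by window position."""
        g = np.zeros((self.k, 4))
        block = self.coef[self.layout.mono_slice]
        for m, pos in enumerate(self.layout.mono_positions):
            g[pos] = block[4 * m : 4 * m + 4]
        return g

    @property
    def gamma2(self) -> np.ndarray:
        """(k-1, 16) adjacent-dinucleotide coefficients by window step."""
        block = self.coef[self.layout.di_slice]
        if block.size == 0:
            return np.zeros((self.k - 1, 16))
        return block.reshape(self.k - 1, 16)

    def predict_codes(self, codes: np.ndarray) -> np.ndarray:
        return design_rows(codes, self.layout) @ self.coef

    def predict_all(self) -> np.ndarray:
        """Predictions for all 4^k k-mers in lexicographic order."""
        return self.predict_codes(all_kmer_codes(self.k))

    def predict(self, kmer: str) -> float:
        return float(self.predict_codes(encode(kmer)[None, :])[0])

    def to_json_dict(self) -> dict:
        return {
            "feature": self.feature_name,
            "k": self.k,
            "kind": self.kind,
            "order": self.order,
            "units": self.units,
            "gamma0": self.gamma0,
            "gamma1": self.gamma1.tolist(),
            "gamma2": self.gamma2.tolist(),
            "coef": self.coef.tolist(),
            "r2_insample": self.r2_insample,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Seq2ShapeModel":
        with open(path) as fh:
            d = json.load(fh)
        layout = _layout(d["k"], d["order"])
        return cls(
            feature_name=d["feature"],
            k=d["k"],
            kind=d["kind"],
            order=d["order"],
            coef=np.asarray(d["coef"], dtype=float),
            layout=layout,
            units=d.get("units", "arbitrary"),
            r2_insample=d.get("r2_insample"),
        )


def make_model(
    feature_name: str,
    k: int,
    kind: str,
    gamma0: float = 0.0,
    gamma1: np.ndarray | None = None,
    gamma2: np.ndarray | None = None,
) -> Seq2ShapeModel:
    """Construct a mono+di model directly from coefficient arrays."""
    layout = _layout(k, MONO_DI)
    coef = np.zeros(layout.n_cols)
    coef[0] = gamma0
    if gamma1 is not None:
        coef[layout.mono_slice] = np.asarray(gamma1, dtype=float).reshape(-1)
    if gamma2 is not None:
        coef[layout.di_slice] = np.asarray(gamma2, dtype=float).reshape(-1)
    return Seq2ShapeModel(feature_name, k, kind, MONO_DI, coef, layout)


def _pinv_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimum-norm least squares via SVD with a relative eigenvalue cutoff."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s**2 > EIG_RTOL * s[0] ** 2
    return Vt[keep].T @ ((U[:, keep].T @ y) / s[keep])


_SVD_CACHE: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}


def _cached_svd(k: int, order: str) -> tuple[np.ndarray, np.ndarray]:
    """(pinv, U_keep) of the full k-mer design, cached — the design is
    fixed given (k, order), and repeated fits (null ensembles, LOO) would
    otherwise redo the SVD."""
    key = (k, order)
    if key not in _SVD_CACHE:
        X, _ = build_design(k, order)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        keep = s**2 > EIG_RTOL * s[0] ** 2
        pinv = Vt[keep].T / s[keep] @ U[:, keep].T
        _SVD_CACHE[key] = (pinv, U[:, keep])
    return _SVD_CACHE[key]


def fit(table: KmerShapeTable, order: str) -> Seq2ShapeModel:
    """Fit a sequence-to-shape model to a complete k-mer table."""
    layout = _layout(table.k, order)
    pinv, _ = _cached_svd(table.k, order)
    coef = pinv @ table.values
    X, _ = build_design(table.k, order)
    pred = X @ coef
    ss_tot = float(np.sum((table.values - table.values.mean()) ** 2))
    ss_res = float(np.sum((table.values - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return Seq2ShapeModel(
        feature_name=table.feature_name,
        k=table.k,
        kind=table.kind,
        order=order,
        coef=coef,
        layout=layout,
        units=table.units,
        r2_insample=r2,
    )


def loo_cv_r2(table: KmerShapeTable, order: str, brute_force: bool = False) -> float:
    """Leave-one-class-out cross-validated R^2.

    Each reverse-complement pair {s, revcomp(s)} (palindromes: singleton)
    is held out together, the model refit on the remaining k-mers, and the
    held-out values predicted.  The fast path uses the block leave-out
    identity on the hat matrix; ``brute_force=True`` refits explicitly and
    exists as a cross-check.
    """
    X, layout = build_design(table.k, order)
    y = table.values
    reps, class_of = rc_class_representatives(table.k)
    perm = revcomp_index_permutation(table.k)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = 0.0
    if brute_force:
        for rep in reps:
            members = np.unique([rep, perm[rep]])
            mask = np.ones(y.size, dtype=bool)
            mask[members] = False
            coef = _pinv_fit(X[mask], y[mask])
            pred = X[members] @ coef
            ss_res += float(np.sum((y[members] - pred) ** 2))
    else:
        _, U = _cached_svd(table.k, order)
        resid = y - U @ (U.T @ y)
        for rep in reps:
            members = np.unique([rep, perm[rep]])
            Us = U[members]
            A = np.eye(members.size) - Us @ Us.T
            e_loo = np.linalg.solve(A, resid[members])
            ss_res += float(e_loo @ e_loo)
    return 1.0 - ss_res / ss_tot


def count_dof(
    k: int, order: str, rc_symmetric: bool = True, mono_positions=None
) -> int:
    """Number of independent parameters of a sequence-feature design.

    Counts eigenvalues of X^T P_RC X (or X^T X when ``rc_symmetric`` is
    false) above the relative cutoff, where P_RC orthogonally projects
    k-mer value vectors onto the reverse-complement-symmetric subspace.
    """
    X, _ = build_design(k, order, mono_positions)
    if rc_symmetric:
        perm = revcomp_index_permutation(k)
        PX = 0.5 * (X + X[perm])
        M = X.T @ PX
    else:
        M = X.T @ X
    M = 0.5 * (M + M.T)
    w = np.linalg.eigvalsh(M)
    return int(np.sum(w > EIG_RTOL * w[-1]))


def predict_profile(sequence: str, model_or_table) -> np.ndarray:
    """Per-position shape profile along a sequence.

    For base-centered features, position i (0-based) carries the value of
    the window centered there; the first two and last two positions are
    NaN.  For step-centered features the returned array has length L-1,
    entry j being the value at the step between bases j and j+1; the
    first and last steps are NaN.
    """
    codes = encode(sequence)
    obj = model_or_table
    k, kind = obj.k, obj.kind
    L = codes.size
    if L < k:
        raise ValueError(f"sequence shorter than the {k}-mer window")
    if isinstance(obj, KmerShapeTable):
        from ._seq import windows_to_indices

        win_vals = obj.values[windows_to_indices(codes, k)[0]]
    else:
        nwin = L - k + 1
        windows = np.stack([codes[j : j + k] for j in range(nwin)])
        win_vals = obj.predict_codes(windows)
    c = center_index(k, kind)
    if kind == BASE_CENTERED:
        out = np.full(L, np.nan)
        out[c : c + win_vals.size] = win_vals
    else:
        out = np.full(L - 1, np.nan)
        out[c : c + win_vals.size] = win_vals
    return out
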