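"""Complexity-matched random shape tables and empirical significance of
shape-readout attribution.

A naive null for "is this shape table special?" permutes table values,
but permutation destroys the low-order structure of real shape tables
(their variance is mostly explained by mono- and dinucleotide features
localized near the window center).  The complexity-matched null instead
draws random mono+di sequence-to-shape coefficients, reverse-complement
symmetrizes, and rescales per-position coefficient blocks so that the
expected conditional variance matrix

    C_ij = E_{c,d} Var_s[ phi(s) | s_i = c, s_j = d ]

matches the reference table's.  Rerunning shape projection with many such
tables yields a per-position null distribution of sensitivity
coefficients, from which two-sided empirical p-values and Benjamini-
Hochberg q-values are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from statsmodels.stats.multitest import multipletests

from ._seq import all_kmer_codes, revcomp_index_permutation
from .models import MechanismAgnosticModel, interior_positions
from .projection import (
    ProjectionConfig,
    ProjectionResult,
    _AffinityLoss,
    _KLLoss,
    project,
)
from .seq2shape import MONO_DI, Seq2ShapeModel, fit as fit_seq2shape
from .tables import KmerShapeTable

PERCENTILES = (2.5, 25.0, 75.0, 97.5)


@dataclass
class ConditionalVarianceMatrix:
    """Expected conditional variances C_ij for all window position pairs."""

    feature_name: str
    k: int
    C: np.ndarray  # (k, k), symmetric

    @property
    def total_variance(self) -> float:
        """C under empty conditioning equals the table variance; stored
        separately for convenience checks."""
        return float(self._total)

    _total: float = 0.0


def _pair_groups(k: int):
    """Group index arrays for all position pairs i <= j."""
    codes = all_kmer_codes(k).astype(np.int64)
    groups = {}
    for i in range(k):
        for j in range(i, k):
            if i == j:
                groups[(i, j)] = (codes[:, i], 4)
            else:
                groups[(i, j)] = (codes[:, i] * 4 + codes[:, j], 16)
    return groups


def conditional_variance(table: KmerShapeTable) -> ConditionalVarianceMatrix:
    """C_ij by exact enumeration over all k-mers.

    Within each of the 16 (4 on the diagonal) conditioning assignments the
    population variance of matching k-mer values is computed; C_ij is the
    equal-weight average over assignments.
    """
    k = table.k
    y = table.values
    C = np.zeros((k, k))
    for (i, j), (grp, ngrp) in _pair_groups(k).items():
        cnt = np.bincount(grp, minlength=ngrp).astype(float)
        s1 = np.bincount(grp, weights=y, minlength=ngrp)
        s2 = np.bincount(grp, weights=y * y, minlength=ngrp)
        var = s2 / cnt - (s1 / cnt) ** 2
        C[i, j] = C[j, i] = var.mean()
    out = ConditionalVarianceMatrix(table.feature_name, k, C)
    out._total = float(np.var(y))
    return out


class _MatchedTableDraw:
    """One U(0,1) coefficient draw with analytic C(alpha) quadratic forms.

    The candidate table is sum_t alpha_t * comp_t(s) over RC-symmetrized,
    mirror-tied mono and dinucleotide component tables, so each C_ij is
    the quadratic form alpha^T M_ij alpha with precomputable M_ij.
    """

    def __init__(self, k: int, rng: np.random.Generator):
        self.k = k
        codes = all_kmer_codes(k).astype(np.int64)
        perm = revcomp_index_permutation(k)
        g1 = rng.uniform(size=(k, 4))
        g2 = rng.uniform(size=(k - 1, 16))
        comps = []
        raw = [g1[i, codes[:, i]] for i in range(k)]
        raw += [g2[j, codes[:, j] * 4 + codes[:, j + 1]] for j in range(k - 1)]
        sym = [0.5 * (v + v[perm]) for v in raw]
        mono_sym, di_sym = sym[:k], sym[k:]
        self.n_mono_free = (k + 1) // 2
        for i in range(self.n_mono_free):
            m = k - 1 - i
            comps.append(mono_sym[i] if m == i else mono_sym[i] + mono_sym[m])
        self.n_di_free = k // 2  # number of free step scales, steps 0..k-2
        for j in range(self.n_di_free):
            m = k - 2 - j
            comps.append(di_sym[j] if m == j else di_sym[j] + di_sym[m])
        self.comps = np.stack(comps)  # (n_comp, 4^k)
        n_comp = self.comps.shape[0]
        self.M = {}
        for (i, j), (grp, ngrp) in _pair_groups(k).items():
            cnt = np.bincount(grp, minlength=ngrp).astype(float)
            means = np.stack(
                [np.bincount(grp, weights=c, minlength=ngrp) / cnt for c in self.comps]
            )  # (n_comp, ngrp)
            M = np.empty((n_comp, n_comp))
            for a in range(n_comp):
                for b in range(a, n_comp):
                    e_fg = (
                        np.bincount(grp, weights=self.comps[a] * self.comps[b], minlength=ngrp)
                        / cnt
                    )
                    cov = e_fg - means[a] * means[b]
                    M[a, b] = M[b, a] = cov.mean()
            self.M[(i, j)] = M

    def C_of(self, alpha: np.ndarray) -> np.ndarray:
        C = np.zeros((self.k, self.k))
        for (i, j), M in self.M.items():
            C[i, j] = C[j, i] = alpha @ M @ alpha
        return C

    def objective(self, alpha: np.ndarray, C_ref: np.ndarray):
        d = 0.0
        grad = np.zeros_like(alpha)
        for (i, j), M in self.M.items():
            w = 1.0 if i == j else 2.0
            Ma = M @ alpha
            r = alpha @ Ma - C_ref[i, j]
            d += w * r * r
            grad += w * 4.0 * r * Ma
        return d, grad

    def table_values(self, alpha: np.ndarray) -> np.ndarray:
        return alpha @ self.comps


def random_matched_table(
    reference: KmerShapeTable,
    seed: int,
    max_retries: int = 5,
) -> tuple[KmerShapeTable, float]:
    """Draw a random table whose conditional-variance structure matches
    ``reference``.

    Mono and dinucleotide coefficients are drawn from U(0,1), the implied
    component tables RC-symmetrized, and per-position scale factors
    (tied between mirror positions, constrained nonnegative) optimized to
    minimize D = sum_ij (C_ij(ref) - C_ij(candidate))^2.  Returns the
    table and the relative matching error ||C - C_ref||_F / ||C_ref||_F.
    """
    if not reference.is_rc_symmetric(tol=1e-9):
        raise ValueError("reference table must be reverse-complement symmetric")
    C_ref = conditional_variance(reference).C
    ref_norm = float(np.linalg.norm(C_ref))
    rng = np.random.default_rng(seed)
    last_err = None
    for _ in range(max_retries):
        draw = _MatchedTableDraw(reference.k, rng)
        n_comp = draw.comps.shape[0]
        c1 = draw.C_of(np.ones(n_comp))
        tot1 = float(c1.sum())
        scale = math.sqrt(max(C_ref.sum(), 0.0) / tot1) if tot1 > 0 else 1.0
        x0 = np.full(n_comp, scale)
        res = minimize(
            lambda a: draw.objective(a, C_ref),
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * n_comp,
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if not res.success and res.status != 1:  # status 1 = maxiter, still usable
            last_err = res.message
            continue
        values = draw.table_values(res.x)
        table = KmerShapeTable(
            feature_name=f"matched-{reference.feature_name}",
            k=reference.k,
            kind=reference.kind,
            values=values,
            units=reference.units,
        )
        err = float(np.linalg.norm(conditional_variance(table).C - C_ref))
        rel = err / ref_norm if ref_norm > 0 else err
        return table, rel
    raise RuntimeError(f"matched-table scaling failed after {max_retries} draws: {last_err}")


@dataclass
class NullEnsemble:
    """Shape-sensitivity profiles from N complexity-matched random tables."""

    N: int
    profiles: dict[str, np.ndarray]  # feature -> (N, profile_len)
    bands: dict[str, np.ndarray] = field(default_factory=dict)  # (4, profile_len)
    matching_errors: dict[str, np.ndarray] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)

    def percentile_bands(self) -> dict[str, np.ndarray]:
        return {
            name: np.percentile(prof, PERCENTILES, axis=0)
            for name, prof in self.profiles.items()
        }


def null_bands(
    agn: MechanismAgnosticModel,
    reference_tables: dict[str, KmerShapeTable],
    cfg: ProjectionConfig,
    N: int,
    seed: int,
) -> NullEnsemble:
    """Project ``agn`` against N sets of complexity-matched random tables.

    For each draw, every feature's reference table is replaced by a
    matched random table, a mono+di sequence-to-shape model is fit to it,
    and the projection is rerun with the identical configuration; the
    resulting sensitivity profiles form the null ensemble.
    """
    if N <= 0:
        raise ValueError("null ensemble size N must be positive")
    features = tuple(cfg.features) if cfg.features else tuple(reference_tables.keys())
    rng = np.random.default_rng(seed)
    prof_lists: dict[str, list] = {f: [] for f in features}
    err_lists: dict[str, list] = {f: [] for f in features}
    kinds = {f: reference_tables[f].kind for f in features}
    for _ in range(N):
        s2s = {}
        for f in features:
            tbl, rel = random_matched_table(reference_tables[f], int(rng.integers(2**31)))
            s2s[f] = fit_seq2shape(tbl, MONO_DI)
            err_lists[f].append(rel)
        res = project(agn, s2s, cfg)
        for f in features:
            prof_lists[f].append(res.model.profiles[f])
    profiles = {f: np.stack(v) for f, v in prof_lists.items()}
    ens = NullEnsemble(
        N=N,
        profiles=profiles,
        matching_errors={f: np.asarray(v) for f, v in err_lists.items()},
        kinds=kinds,
    )
    ens.bands = ens.percentile_bands()
    return ens


def position_fdr(
    observed: dict[str, np.ndarray],
    ensemble: NullEnsemble,
    k: int,
) -> dict[str, dict[str, np.ndarray]]:
    """Empirical two-sided p-values and BH q-values per interior position.

    p_i = (1 + #{n : |beta_null,n,i| >= |beta_obs,i|}) / (N + 1); the
    Benjamini-Hochberg step-up is applied across interior positions
    within each feature separately.
    """
    if ensemble.N <= 0:
        raise ValueError("empty null ensemble")
    out = {}
    for name, obs in observed.items():
        nulls = ensemble.profiles[name]
        interior = interior_positions(k, ensemble.kinds[name])
        pvals = np.empty(interior.size)
        for m, pos in enumerate(interior):
            exceed = np.sum(np.abs(nulls[:, pos]) >= np.abs(obs[pos]))
            pvals[m] = (1.0 + exceed) / (ensemble.N + 1.0)
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        out[name] = {"positions": interior, "p": pvals, "q": qvals}
    return out
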