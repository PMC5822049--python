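"""What shape preferences does a scoring matrix encode?

Even a pure mononucleotide scoring matrix implies shape preferences: the
high-affinity sequences it selects have a characteristic average shape.
To visualize this, sequences are sampled uniformly within bins of the
free-energy score W(s) = sum_j w_{j,s_j} and the mean shape profile of
each bin computed.  Extreme bins are far too rare to reach by uniform
sampling, so a Metropolis-Hastings chain samples the Boltzmann
distribution p(s) ~ exp(beta_T W(s)) on a grid of inverse temperatures
(positive and negative), and rejection sampling flattens each (bin,
temperature) cell back to the uniform-within-bin distribution before
pooling across temperatures.

Also provided: alignment of high-affinity SELEX probes via an m-mer
affinity table, for computing mean shape profiles of real binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import all_kmer_codes, decode, encode, revcomp_codes, windows_to_indices
from .seq2shape import predict_profile
from .selex import SelexDataset, _codes_from_indices


@dataclass
class EnergyBinnedSample:
    """Sequences sampled uniformly within free-energy bins.

    Scores are shifted so the best sequence scores 0; ``bin_edges`` spans
    [W_min, 0] in equal intervals.  ``sequences[b]`` is an (n_b, k) code
    matrix (possibly empty) and ``scores[b]`` the matching shifted scores.
    """

    k: int
    bin_edges: np.ndarray
    sequences: list[np.ndarray]
    scores: list[np.ndarray]
    empty_bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_bins(self) -> int:
        return len(self.sequences)


def _matrix_scores(matrix: np.ndarray, states: np.ndarray) -> np.ndarray:
    k = matrix.shape[0]
    s = np.zeros(states.shape[0])
    for j in range(k):
        s += matrix[j, states[:, j]]
    return s


def boltzmann_chain(
    matrix: np.ndarray,
    beta_T: float,
    n_steps: int,
    seed: int,
    burn_in: int = 1_000,
    thin: int = 10,
) -> np.ndarray:
    """One Metropolis-Hastings chain targeting p(s) ~ exp(beta_T W(s)).

    Proposals substitute a uniformly chosen base at a uniformly chosen
    position.  Returns thinned post-burn-in states as an (n, k) code
    matrix.  At beta_T = 0 every proposal is accepted and the samples are
    uniform over all 4^k sequences.
    """
    matrix = np.asarray(matrix, dtype=float)
    k = matrix.shape[0]
    rng = np.random.default_rng(seed)
    state = rng.integers(0, 4, size=k)
    W = float(matrix[np.arange(k), state].sum())
    kept = []
    for step in range(n_steps):
        pos = int(rng.integers(0, k))
        new = (state[pos] + int(rng.integers(1, 4))) % 4
        dW = matrix[pos, new] - matrix[pos, state[pos]]
        if np.log(rng.uniform()) < beta_T * dW:
            state[pos] = new
            W += dW
        if step >= burn_in and (step - burn_in) % thin == 0:
            kept.append(state.copy())
    return np.asarray(kept)


def sample_by_bin(
    matrix: np.ndarray,
    n_bins: int = 10,
    n_temps: int = 13,
    per_bin_target: int = 500,
    seed: int = 0,
    n_steps: int = 100_000,
    burn_in: int = 1_000,
    thin: int = 10,
) -> EnergyBinnedSample:
    """Sample sequences uniformly within free-energy bins of a scoring matrix.

    ``matrix`` is (k, 4) in -ddG/RT units.  One MH chain per inverse
    temperature on a grid of ``n_temps`` uniformly spaced values spanning
    (log 4^k / -W_min) * [-2, 2] runs for ``n_steps`` single-base-
    substitution proposals; thinned post-burn-in states are rejection-
    filtered to the uniform distribution within each (bin, temperature)
    cell and pooled per bin, then subsampled to ``per_bin_target``.
    Bins that receive no samples are flagged in ``empty_bins``.
    """
    matrix = np.asarray(matrix, dtype=float)
    k = matrix.shape[0]
    shifted = matrix - matrix.max(axis=1, keepdims=True)  # best sequence -> 0
    w_min = float(shifted.min(axis=1).sum())
    edges = np.linspace(w_min, 0.0, n_bins + 1)
    rng = np.random.default_rng(seed)
    if w_min == 0.0:
        # degenerate matrix: every sequence scores 0 -> single occupied bin
        n = min(per_bin_target, 4**k)
        seqs = rng.integers(0, 4, size=(n, k))
        out = [np.empty((0, k), dtype=np.int64) for _ in range(n_bins)]
        sc = [np.empty(0) for _ in range(n_bins)]
        out[-1], sc[-1] = seqs, np.zeros(n)
        return EnergyBinnedSample(
            k, edges, out, sc, np.asarray([b for b in range(n_bins - 1)])
        )
    beta_scale = np.log(4.0**k) / (-w_min)
    betas = np.linspace(-2.0, 2.0, n_temps) * beta_scale

    states = rng.integers(0, 4, size=(n_temps, k))
    W = _matrix_scores(shifted, states)
    kept_states: list[list[np.ndarray]] = [[] for _ in range(n_temps)]
    kept_W: list[list[float]] = [[] for _ in range(n_temps)]
    rows = np.arange(n_temps)
    for step in range(n_steps):
        pos = rng.integers(0, k, size=n_temps)
        shiftb = rng.integers(1, 4, size=n_temps)
        old = states[rows, pos]
        new = (old + shiftb) % 4
        dW = shifted[pos, new] - shifted[pos, old]
        accept = np.log(rng.uniform(size=n_temps)) < betas * dW
        states[rows[accept], pos[accept]] = new[accept]
        W[accept] += dW[accept]
        if step >= burn_in and (step - burn_in) % thin == 0:
            for t in range(n_temps):
                kept_states[t].append(states[t].copy())
                kept_W[t].append(W[t])

    # rejection to uniform within each (bin, temperature) cell, pool per bin
    per_bin_seqs: list[list[np.ndarray]] = [[] for _ in range(n_bins)]
    per_bin_W: list[list[np.ndarray]] = [[] for _ in range(n_bins)]
    for t in range(n_temps):
        seqs = np.asarray(kept_states[t])
        Ws = np.asarray(kept_W[t])
        bins = np.clip(np.digitize(Ws, edges) - 1, 0, n_bins - 1)
        logu = -betas[t] * Ws  # unnormalized log weight restoring uniformity
        for b in range(n_bins):
            m = bins == b
            if not m.any():
                continue
            lw = logu[m] - logu[m].max()
            acc = np.log(rng.uniform(size=lw.size)) < lw
            if acc.any():
                per_bin_seqs[b].append(seqs[m][acc])
                per_bin_W[b].append(Ws[m][acc])
    sequences, scores, empty = [], [], []
    for b in range(n_bins):
        if per_bin_seqs[b]:
            s = np.concatenate(per_bin_seqs[b])
            w = np.concatenate(per_bin_W[b])
            if s.shape[0] > per_bin_target:
                pick = rng.choice(s.shape[0], per_bin_target, replace=False)
                s, w = s[pick], w[pick]
            sequences.append(s.astype(np.int64))
            scores.append(w)
        else:
            sequences.append(np.empty((0, k), dtype=np.int64))
            scores.append(np.empty(0))
            empty.append(b)
    return EnergyBinnedSample(k, edges, sequences, scores, np.asarray(empty, dtype=int))


def mean_shape_by_bin(
    sample: EnergyBinnedSample, tables: dict
) -> dict[str, np.ndarray]:
    """Per-bin, per-position mean shape profiles.

    ``tables`` maps feature name to a KmerShapeTable (or fitted
    sequence-to-shape model).  Positions whose shape window extends past
    the sequence are NaN, as are bins without samples.
    """
    out = {}
    for name, tbl in tables.items():
        profs = []
        for b in range(sample.n_bins):
            seqs = sample.sequences[b]
            if seqs.shape[0] == 0:
                ref = predict_profile("A" * max(sample.k, tbl.k), tbl)
                profs.append(np.full_like(ref[: sample.k if tbl.kind == "base-centered" else sample.k - 1], np.nan))
                continue
            rows = np.stack([predict_profile(decode(s), tbl) for s in seqs])
            profs.append(rows.mean(axis=0))
        out[name] = np.stack(profs)
    return out


def mmer_affinity_table(data: SelexDataset, m: int = 10) -> dict[str, tuple[int, float]]:
    """m-mer counts and relative affinities from a two-round dataset.

    Relative affinity is the ratio of round-1 to round-0 m-mer frequency,
    normalized so the top m-mer has affinity 1 (a deliberately simple
    count-ratio estimator).  Returns {m-mer: (round-1 count, affinity)}.
    """
    n_tot = 4**m

    def win_counts(probes, counts, L):
        out = np.zeros(n_tot)
        win = windows_to_indices(_codes_from_indices(probes, L), m)
        for j in range(win.shape[1]):
            np.add.at(out, win[:, j], counts)
        return out

    c0 = win_counts(data.r0_probes, data.r0_counts, data.L)
    c1 = win_counts(data.r1_probes, data.r1_counts, data.L)
    f0 = (c0 + 0.5) / (c0.sum() + 0.5 * n_tot)
    f1 = c1 / max(c1.sum(), 1.0)
    ratio = np.where(c1 > 0, f1 / f0, 0.0)
    top = ratio.max()
    if top <= 0:
        raise ValueError("no m-mer observed in round 1")
    ratio /= top
    keep = np.nonzero(c1)[0]
    codes = _codes_from_indices(keep, m)
    return {
        decode(codes[i]): (int(c1[keep[i]]), float(ratio[keep[i]]))
        for i in range(keep.size)
    }


@dataclass
class AlignedProbes:
    """High-affinity probes aligned to a common m-bp frame."""

    m: int
    top_mmer: str
    frequency_matrix: np.ndarray  # (m, 4)
    windows: list[str]
    offsets: np.ndarray
    strands: np.ndarray  # 0 = as given, 1 = reverse complement


def align_high_affinity_probes(
    probes: list[str],
    affinity_kmers: dict[str, tuple[int, float]],
    min_count: int = 100,
    min_affinity: float = 0.1,
) -> AlignedProbes:
    """Align probes containing a high-affinity m-mer to a common frame.

    m-mers passing both the count and relative-affinity filters are
    oriented to the top m-mer (the strand maximizing base matches), a
    base-frequency matrix is built from them, and each probe containing a
    retained m-mer is assigned the offset and strand maximizing the
    frequency-matrix log-score; the covered m-bp window is extracted.
    """
    retained = {
        s: (c, a)
        for s, (c, a) in affinity_kmers.items()
        if c >= min_count and a >= min_affinity
    }
    if not retained:
        import warnings

        warnings.warn("no m-mer passes the count/affinity filters; empty alignment")
        m = len(next(iter(affinity_kmers))) if affinity_kmers else 0
        return AlignedProbes(m, "", np.zeros((m, 4)), [], np.empty(0, int), np.empty(0, int))
    top = max(retained, key=lambda s: retained[s][1])
    m = len(top)
    top_codes = encode(top)
    freq = np.zeros((m, 4))
    oriented = []
    for s in retained:
        codes = encode(s)
        rc = revcomp_codes(codes)
        use = codes if (codes == top_codes).sum() >= (rc == top_codes).sum() else rc
        oriented.append(use)
        for j in range(m):
            freq[j, use[j]] += 1
    logf = np.log((freq + 0.5) / (freq + 0.5).sum(axis=1, keepdims=True))

    retained_set = set(retained)
    windows, offsets, strands = [], [], []
    for probe in probes:
        codes = encode(probe)
        has = any(
            probe[i : i + m] in retained_set for i in range(len(probe) - m + 1)
        )
        if not has:
            from ._seq import revcomp_str

            rp = revcomp_str(probe)
            has = any(rp[i : i + m] in retained_set for i in range(len(rp) - m + 1))
        if not has:
            continue
        best = (-np.inf, 0, 0)
        for strand, cd in ((0, codes), (1, revcomp_codes(codes))):
            for o in range(cd.size - m + 1):
                sc = float(logf[np.arange(m), cd[o : o + m]].sum())
                if sc > best[0]:
                    best = (sc, o, strand)
        _, o, strand = best
        cd = codes if strand == 0 else revcomp_codes(codes)
        windows.append(decode(cd[o : o + m]))
        offsets.append(o)
        strands.append(strand)
    if not windows:
        import warnings

        warnings.warn("no probe contains a retained m-mer; empty alignment")
    return AlignedProbes(
        m,
        top,
        freq,
        windows,
        np.asarray(offsets, dtype=int),
        np.asarray(strands, dtype=int),
    )
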