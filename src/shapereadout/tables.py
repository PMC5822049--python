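"""k-mer shape tables: I/O, symmetrization, step recentering, permutation,
and synthesis.

A shape table maps every DNA k-mer to one structural parameter value.
Base-pair parameters (minor groove width MGW, propeller twist ProT) use
pentamers centered on a base pair; base-pair-step parameters (Roll, helix
twist HelT) are recentered onto tetramers centered on the step between
window offsets 0 and +1.  Because the two DNA strands are physically
equivalent, a meaningful table satisfies value(s) == value(revcomp(s)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import (
    all_kmer_codes,
    decode,
    encode,
    rc_class_representatives,
    revcomp_index_permutation,
)

BASE_CENTERED = "base-centered"
STEP_CENTERED = "step-centered"

#: conventional units of the four standard features
STANDARD_UNITS = {"MGW": "angstrom", "ProT": "degrees", "Roll": "degrees", "HelT": "degrees"}


@dataclass
class KmerShapeTable:
    """Complete mapping from all 4^k k-mers to one shape-parameter value.

    ``values[i]`` is the value of the k-mer with lexicographic index ``i``.
    ``kind`` records the window convention: base-centered windows span
    offsets -2..+2 around the central base (k=5), step-centered windows
    span base offsets -1..+2 around the central step (k=4).
    """

    feature_name: str
    k: int
    kind: str
    values: np.ndarray
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4**self.k,):
            raise ValueError(
                f"table for k={self.k} needs {4**self.k} values, got {self.values.shape}"
            )
        if self.kind not in (BASE_CENTERED, STEP_CENTERED):
            raise ValueError(f"unknown table kind {self.kind!r}")

    def value_of(self, kmer: str) -> float:
        codes = encode(kmer)
        if codes.size != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        idx = 0
        for c in codes:
            idx = idx * 4 + int(c)
        return float(self.values[idx])

    def is_rc_symmetric(self, tol: float = 1e-12) -> bool:
        perm = revcomp_index_permutation(self.k)
        return bool(np.allclose(self.values, self.values[perm], atol=tol, rtol=0))


@dataclass
class RawPentamerStepTable:
    """Raw step-parameter table: two values per pentamer.

    ``first_step[i]`` is the parameter at the step between pentamer
    positions 2 and 3 (1-based), ``second_step[i]`` between positions
    3 and 4, for the pentamer with index ``i``.
    """

    feature_name: str
    first_step: np.ndarray
    second_step: np.ndarray
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.first_step = np.asarray(self.first_step, dtype=float)
        self.second_step = np.asarray(self.second_step, dtype=float)
        if self.first_step.shape != (1024,) or self.second_step.shape != (1024,):
            raise ValueError("raw pentamer step table needs 1024 values per step")


def read_table(path, kind: str, feature_name: str | None = None) -> KmerShapeTable:
    """Read a k-mer table from two-column text (KMER<TAB>VALUE).

    '#'-prefixed lines are comments.  k is inferred from the k-mer length;
    the table must be complete and duplicate-free.
    """
    entries: dict[int, float] = {}
    k = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'KMER VALUE', got {line!r}")
            kmer, val = parts
            try:
                codes = encode(kmer.upper())
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-ACGT character in k-mer {kmer!r}"
                ) from None
            if k is None:
                k = codes.size
            elif codes.size != k:
                raise ValueError(
                    f"{path}: line {lineno}: inconsistent k-mer length ({codes.size} vs {k})"
                )
            idx = 0
            for c in codes:
                idx = idx * 4 + int(c)
            if idx in entries:
                raise ValueError(f"{path}: line {lineno}: duplicate k-mer {kmer!r}")
            try:
                entries[idx] = float(val)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: bad value {val!r}") from None
    if k is None:
        raise ValueError(f"{path}: empty table")
    n_missing = 4**k - len(entries)
    if n_missing:
        raise ValueError(f"{path}: incomplete table: {n_missing} of {4**k} k-mers missing")
    values = np.empty(4**k)
    for idx, val in entries.items():
        values[idx] = val
    name = feature_name if feature_name is not None else "unnamed"
    units = STANDARD_UNITS.get(name, "arbitrary")
    return KmerShapeTable(feature_name=name, k=k, kind=kind, values=values, units=units)


def write_table(table: KmerShapeTable, path, fmt: str = "%.6g") -> None:
    """Write a table as tab-separated KMER<TAB>VALUE text."""
    codes = all_kmer_codes(table.k)
    with open(path, "w") as fh:
        fh.write(f"# feature: {table.feature_name}  kind: {table.kind}  units: {table.units}\n")
        for i in range(4**table.k):
            fh.write(f"{decode(codes[i])}\t{fmt % table.values[i]}\n")


def reverse_complement_symmetrize(table: KmerShapeTable) -> KmerShapeTable:
    """Average each k-mer's value with its reverse complement's."""
    perm = revcomp_index_permutation(table.k)
    return replace(table, values=0.5 * (table.values + table.values[perm]))


def center_step_table(raw: RawPentamerStepTable) -> KmerShapeTable:
    """Recenter a raw two-values-per-pentamer step table onto tetramers.

    The raw tables report, for pentamer p1..p5, the step value at (p2,p3)
    and at (p3,p4).  For tetramer t: the first-step value is averaged over
    the right-most base of pentamers t1 t2 t3 t4 b, the second-step value
    over the left-most base of pentamers b t1 t2 t3 t4; the two marginal
    tetramer tables are averaged and the result symmetrized.
    """
    pent = all_kmer_codes(5).astype(np.int64)
    powers4 = 4 ** np.arange(3, -1, -1, dtype=np.int64)
    # first step of pentamer p sits between p2,p3 -> aligned tetramer p1..p4
    tet_first = pent[:, :4] @ powers4
    # second step between p3,p4 -> aligned tetramer p2..p5
    tet_second = pent[:, 1:] @ powers4
    first = np.zeros(256)
    second = np.zeros(256)
    np.add.at(first, tet_first, raw.first_step)
    np.add.at(second, tet_second, raw.second_step)
    values = 0.5 * (first / 4.0 + second / 4.0)
    table = KmerShapeTable(
        feature_name=raw.feature_name, k=4, kind=STEP_CENTERED, values=values, units=raw.units
    )
    return reverse_complement_symmetrize(table)


def permute_table(table: KmerShapeTable, seed: int) -> KmerShapeTable:
    """Randomly permute values among reverse-complement equivalence classes.

    Each class {s, revcomp(s)} carries a single value (the input must be
    RC-symmetric); the multiset of class values is preserved and the output
    remains RC-symmetric.  Palindromic k-mers form singleton classes and
    are permuted among all classes like any other.
    """
    if not table.is_rc_symmetric(tol=1e-9):
        raise ValueError("permute_table requires a reverse-complement-symmetric table")
    reps, class_of = rc_class_representatives(table.k)
    class_values = table.values[reps]
    rng = np.random.default_rng(seed)
    shuffled = class_values[rng.permutation(class_values.size)]
    return replace(table, values=shuffled[class_of])


def synthesize_table(
    k: int,
    kind: str,
    gamma,
    noise_sd: float,
    seed: int,
    feature_name: str = "synthetic",
) -> KmerShapeTable:
    """Build a table from a sequence-to-shape model plus Gaussian noise.

    ``gamma`` is a fitted/constructed :class:`~shapereadout.seq2shape.Seq2ShapeModel`
    (or any object with ``predict_all(k)``).  Independent N(0, noise_sd^2)
    noise is added per k-mer before the final RC symmetrization, mimicking
    measurement noise on the underlying table; symmetrization halves the
    noise variance on non-palindromic k-mers.
    """
    pred = gamma.predict_all()
    if pred.shape != (4**k,):
        raise ValueError("gamma model is not dimensioned for this k")
    rng = np.random.default_rng(seed)
    values = pred + rng.normal(0.0, noise_sd, size=4**k)
    table = KmerShapeTable(feature_name=feature_name, k=k, kind=kind, values=values)
    return reverse_complement_symmetrize(table)
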