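"""Synthetic study fixtures: structured shape tables, planted-readout
binding models, and two-round SELEX datasets.

Every generator is deterministic in (spec, seed).  A single global seed
fans out to per-component seeds through numpy SeedSequences keyed by a
component tag, so adding a fixture never perturbs existing ones.

The table generator controls the variance decomposition directly: a
random RC-symmetric mono model and a dinucleotide component
orthogonalized against the mononucleotide design span are standardized
and mixed so that the mono fraction, the dinucleotide fraction, and the
noise fraction of the final table variance match the requested split.
The defaults (0.65 / 0.30 / 0.05) emulate the structure of the real
pentamer shape tables, where mononucleotides explain roughly two-thirds
of the variance and adjacent dinucleotides almost all of the rest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .models import (
    MechanismAgnosticModel,
    ShapeReadoutModel,
    interior_positions,
    profile_length,
    to_sequence_representation,
)
from .selex import BiasModel, SelectionModel, SelexDataset, simulate_selex
from .seq2shape import MONO, MONO_DI, _cached_svd, fit as fit_seq2shape, make_model
from .tables import (
    BASE_CENTERED,
    KmerShapeTable,
    reverse_complement_symmetrize,
    synthesize_table,
)

_COMPONENT_TAGS = {"table": 101, "binding": 202, "selex": 303, "bias": 404}


def component_rng(seed: int, component: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _COMPONENT_TAGS[component], int(index)])
    )


@dataclass
class TableSpec:
    k: int = 5
    kind: str = BASE_CENTERED
    frac_mono: float = 0.65
    frac_di: float = 0.30
    frac_noise: float = 0.05
    scale: float = 1.0
    feature_name: str = "synthetic-MGW"

    def __post_init__(self) -> None:
        fr = (self.frac_mono, self.frac_di, self.frac_noise)
        if any(f < 0 for f in fr) or sum(fr) > 1 + 1e-9:
            raise ValueError("variance fractions must be nonnegative and sum to <= 1")


@dataclass
class BindingSpec:
    footprint: int = 8
    base_scale: float = 0.5
    #: planted shape readout: (feature_name, position, amplitude in
    #: -ddG/RT per unit shape)
    planted: tuple = ()


@dataclass
class SelexSpec:
    L: int = 10
    left_flank: str = "ACCG"
    right_flank: str = "CGGT"
    n0: int = 200_000
    n1: int = 200_000
    k_bias: int = 2
    bias_scale: float = 0.15


@dataclass
class FixtureSpec:
    seed: int = 0
    table: TableSpec = field(default_factory=TableSpec)
    binding: BindingSpec = field(default_factory=BindingSpec)
    selex: SelexSpec = field(default_factory=SelexSpec)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FixtureSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            seed=d.get("seed", 0),
            table=TableSpec(**d.get("table", {})),
            binding=BindingSpec(
                **{
                    **d.get("binding", {}),
                    "planted": tuple(
                        tuple(p) for p in d.get("binding", {}).get("planted", ())
                    ),
                }
            ),
            selex=SelexSpec(**d.get("selex", {})),
        )


def _rc_symmetric_gamma(rng, k: int):
    g1 = rng.normal(size=(k, 4))
    g2 = rng.normal(size=(k - 1, 16))
    from .models import _rc_dinuc_perm

    g1 = 0.5 * (g1 + g1[::-1, ::-1])
    g2 = 0.5 * (g2 + g2[::-1][:, _rc_dinuc_perm()])
    return g1, g2


def make_table(spec: TableSpec, seed: int, index: int = 0) -> KmerShapeTable:
    """Synthesize a table with the requested variance decomposition.

    The mono and dinucleotide signal components are RC-symmetric by
    construction; Gaussian noise is added per k-mer and the table
    RC-symmetrized, which halves the noise variance on non-palindromic
    k-mers (the noise scale is pre-compensated accordingly).
    """
    rng = component_rng(seed, "table", index)
    k = spec.k
    g1, g2 = _rc_symmetric_gamma(rng, k)
    mono_model = make_model(spec.feature_name, k, spec.kind, 0.0, g1, None)
    di_model = make_model(spec.feature_name, k, spec.kind, 0.0, None, g2)
    m_vals = mono_model.predict_all()
    d_vals = di_model.predict_all()
    # orthogonalize the di component against the mono design span so the
    # mono fraction of variance is exactly frac_mono
    _, U = _cached_svd(k, MONO)
    d_vals = d_vals - U @ (U.T @ d_vals)
    m_vals = m_vals - m_vals.mean()

    def unit(v):
        sd = v.std()
        return v / sd if sd > 0 else v

    signal = spec.scale * (
        np.sqrt(spec.frac_mono) * unit(m_vals) + np.sqrt(spec.frac_di) * unit(d_vals)
    )
    gamma = fit_seq2shape(
        KmerShapeTable(spec.feature_name, k, spec.kind, signal), MONO_DI
    )
    noise_sd = spec.scale * np.sqrt(2.0 * spec.frac_noise)
    return synthesize_table(
        k,
        spec.kind,
        gamma,
        noise_sd,
        int(rng.integers(2**31)),
        feature_name=spec.feature_name,
    )


def make_planted_model(
    spec: BindingSpec,
    tables: dict[str, KmerShapeTable],
    seed: int,
) -> tuple[ShapeReadoutModel, MechanismAgnosticModel]:
    """A shape-readout model with planted sensitivities and its exact
    mechanism-agnostic (sequence-only) representation."""
    rng = component_rng(seed, "binding")
    k = spec.footprint
    beta1 = rng.normal(0.0, spec.base_scale, size=(k, 4))
    beta1 -= beta1.mean(axis=1, keepdims=True)
    profiles: dict[str, np.ndarray] = {}
    s2s = {}
    for name, tbl in tables.items():
        s2s[name] = fit_seq2shape(tbl, MONO_DI)
    for name, pos, amp in spec.planted:
        if name not in s2s:
            raise ValueError(f"planted feature {name!r} has no table")
        kind = tables[name].kind
        if name not in profiles:
            profiles[name] = np.zeros(profile_length(k, kind))
        if pos not in interior_positions(k, kind):
            raise ValueError(f"planted position {pos} not interior for {name!r}")
        profiles[name][pos] = amp
    used = {n: s2s[n] for n in profiles}
    srm = ShapeReadoutModel(k, 0.0, beta1, profiles, used)
    return srm, to_sequence_representation(srm)


def make_selex(
    spec: SelexSpec,
    sel: SelectionModel,
    seed: int,
) -> tuple[SelexDataset, BiasModel]:
    """Simulate a two-round dataset under a random k-mer bias model."""
    rng = component_rng(seed, "bias")
    beta = rng.normal(0.0, spec.bias_scale, size=4**spec.k_bias)
    bias = BiasModel(spec.k_bias, beta - beta.mean())
    data = simulate_selex(
        bias,
        sel,
        spec.L,
        spec.n0,
        spec.n1,
        seed=int(component_rng(seed, "selex").integers(2**31)),
        left_flank=spec.left_flank,
        right_flank=spec.right_flank,
    )
    return data, bias
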