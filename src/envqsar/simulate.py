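"""Synthetic descriptor data emulating the QSAR reference sets and drug panel.

The real reference compilations (fish bioconcentration, soil sorption, and
rat unbound brain-to-plasma data) and the descriptor panel of the studied
antiparasitic drugs are not redistributable, so every pipeline stage is
exercised on synthetic tables instead: descriptor vectors drawn independently
from realistic ranges, with responses generated from the built-in published
equations plus Gaussian noise at a level giving training R² in the high 0.8s
typical of such fits.

Defaults reproduce the study conditions: split sizes 500/132 (log Koc),
400/156 (log BCF) and 60/14 (log Kp,uu); log P spanning −2.2 to +9.9;
noise standard deviations 0.4 log units (0.3 for log Kp,uu, whose response
range is narrower). What the generator does *not* emulate is the joint
correlation structure of real descriptors — columns are independent unless a
``collinear_spec`` injects a known correlation — so tests on this data probe
algorithmic correctness, not real-data performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    COUNT_DESCRIPTORS,
    CompoundRecord,
    DescriptorVector,
    EnvQsarError,
    PropertyModelSpec,
    ReferenceDataset,
)
from .published import EQ1_KOC, EQ2_BCF, EQ3_KPUU

__all__ = [
    "SyntheticConfig",
    "default_config",
    "gen_reference_dataset",
    "gen_collinear_block",
    "gen_drug_panel",
    "DEFAULT_RANGES",
    "DEFAULT_FAMILY_SPEC",
]

#: Default descriptor sampling ranges per property (closed intervals; count
#: descriptors are integer uniforms over the inclusive range).
DEFAULT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "logKoc": {
        "nRot": (0, 20),
        "nHet": (0, 15),
        "nRing": (0, 6),
        "PAMPA": (0.0, 1.0),
        "logS": (-10.0, 1.0),
        "logP": (-2.2, 9.9),
    },
    "logBCF": {
        "nRot": (0, 20),
        "MaxRing": (0, 18),
        "PAMPA": (0.0, 1.0),
        "logS": (-10.0, 1.0),
        "logD": (-4.0, 8.0),
    },
    "logKpuu": {
        "TPSA": (0.0, 250.0),
        "nHet": (0, 20),
        "Fsp3": (0.0, 1.0),
        "MDCK": (-6.0, -4.0),
        "logVDss": (-1.0, 1.5),
    },
}

_PAPER_SPLITS = {"logKoc": (500, 132), "logBCF": (400, 156), "logKpuu": (60, 14)}
_DEFAULT_NOISE = {"logKoc": 0.4, "logBCF": 0.4, "logKpuu": 0.3}
_DEFAULT_MODEL = {"logKoc": EQ1_KOC, "logBCF": EQ2_BCF, "logKpuu": EQ3_KPUU}


@dataclass
class SyntheticConfig:
    """Recipe for one synthetic reference dataset."""

    property: str
    generating_model: PropertyModelSpec
    n_train: int
    n_test: int
    n_validation: int = 0
    noise_sd: float = 0.4
    seed: int = 0
    descriptor_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    collinear_spec: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_test, self.n_validation) < 0:
            raise ValueError("split sizes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name, (lo, hi) in self.descriptor_ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {name}: low must be < high")
        missing = set(self.generating_model.terms) - set(self.descriptor_ranges)
        if missing:
            raise ValueError(
                f"no sampling range configured for model term(s): {sorted(missing)}"
            )
        for a, b, r in self.collinear_spec:
            if abs(r) >= 1:
                raise ValueError(f"infeasible collinearity target r={r} for ({a},{b})")


def default_config(prop: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Study-condition defaults for one property (paper split sizes, ranges,
    generating equation and noise level); keyword overrides are applied last."""
    if prop not in _PAPER_SPLITS:
        raise EnvQsarError(f"unknown property {prop!r}")
    n_train, n_test = _PAPER_SPLITS[prop]
    cfg = dict(
        property=prop,
        generating_model=_DEFAULT_MODEL[prop],
        n_train=n_train,
        n_test=n_test,
        noise_sd=_DEFAULT_NOISE[prop],
        seed=seed,
        descriptor_ranges=dict(DEFAULT_RANGES[prop]),
    )
    cfg.update(overrides)
    return SyntheticConfig(**cfg)


def _draw_column(rng: np.random.Generator, name: str, lo, hi, n: int) -> np.ndarray:
    if name in COUNT_DESCRIPTORS:
        return rng.integers(int(lo), int(hi) + 1, size=n).astype(float)
    return rng.uniform(lo, hi, size=n)


def _copula_map(z: np.ndarray, name: str, lo, hi) -> np.ndarray:
    """Map standard-normal draws onto the configured marginal (Gaussian copula)."""
    u = stats.norm.cdf(z)
    if name in COUNT_DESCRIPTORS:
        k = int(hi) - int(lo) + 1
        return (np.floor(u * k).clip(0, k - 1) + int(lo)).astype(float)
    return lo + u * (hi - lo)


def gen_reference_dataset(cfg: SyntheticConfig) -> ReferenceDataset:
    """Draw a synthetic reference dataset from the configured recipe.

    Descriptors are drawn independently within their ranges (integer uniforms
    for counts, continuous uniforms otherwise); pairs named in
    ``collinear_spec`` are drawn through a Gaussian copula so their
    correlation approximates the target while marginals stay in range. The
    response is the generating model's value plus ``Normal(0, noise_sd)``
    noise, and ids are randomly assigned to train/test(/validation) splits of
    the configured sizes. Fully reproducible under ``seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_train + cfg.n_test + cfg.n_validation
    cols: dict[str, np.ndarray] = {}
    correlated = {name for pair in cfg.collinear_spec for name in pair[:2]}
    for a, b, r in cfg.collinear_spec:
        z1 = rng.standard_normal(n)
        z2 = r * z1 + np.sqrt(1 - r * r) * rng.standard_normal(n)
        la, ha = cfg.descriptor_ranges[a]
        lb, hb = cfg.descriptor_ranges[b]
        cols[a] = _copula_map(z1, a, la, ha)
        cols[b] = _copula_map(z2, b, lb, hb)
    for name, (lo, hi) in cfg.descriptor_ranges.items():
        if name not in correlated:
            cols[name] = _draw_column(rng, name, lo, hi, n)

    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    width = len(str(n))
    compounds, response = [], {}
    for i in range(n):
        cid = f"c{i + 1:0{width}d}"
        desc = DescriptorVector({name: float(cols[name][i]) for name in cols})
        compounds.append(CompoundRecord(id=cid, name=cid, descriptors=desc))
        response[cid] = float(cfg.generating_model.predict(desc) + noise[i])

    order = rng.permutation(n)
    split: dict[str, str] = {}
    for rank, idx in enumerate(order):
        cid = compounds[idx].id
        if rank < cfg.n_train:
            split[cid] = "train"
        elif rank < cfg.n_train + cfg.n_test:
            split[cid] = "test"
        else:
            split[cid] = "validation"
    return ReferenceDataset(
        compounds=compounds, response=response, split=split, property=cfg.property
    )


def gen_collinear_block(n: int, r_target: float, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal columns with correlation close to ``r_target``.

    At n ≥ 500 the sample correlation lands within about ±0.03 of the target.
    """
    if n < 10:
        raise ValueError("collinear block needs n >= 10")
    if abs(r_target) >= 1:
        raise ValueError("|r_target| must be < 1")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = r_target * z1 + np.sqrt(1 - r_target**2) * rng.standard_normal(n)
    return z1, z2


#: Base descriptor ranges for the synthetic antiparasitic panel — every input
#: needed by the four built-in equations and every classifier.
_PANEL_RANGES: dict[str, tuple[float, float]] = {
    "nRot": (0, 15),
    "nHet": (0, 15),
    "nRing": (0, 5),
    "MaxRing": (0, 12),
    "PAMPA": (0.0, 1.0),
    "logS": (-8.0, 0.0),
    "logP": (-1.0, 6.0),
    "logD": (-2.0, 5.0),
    "TPSA": (20.0, 180.0),
    "Fsp3": (0.0, 1.0),
    "MDCK": (-6.0, -4.0),
    "caco2": (-6.0, -4.0),
    "HIA": (20.0, 100.0),
    "MLOGP": (-1.0, 6.0),
    "MW": (150.0, 700.0),
    "nHA": (0, 12),
    "nHD": (0, 6),
    "HeavyAtoms": (10, 50),
    "HBD": (0, 6),
    "MR": (40.0, 150.0),
    "iLOGP": (0.0, 5.0),
    "logVDss": (-1.0, 1.5),
}

#: Default family mix: fractions and additive descriptor offsets reflecting
#: the broad physicochemical character of each antiparasitic family
#: (salicylanilides/pyrethroids lipophilic and poorly soluble, sulfonamides
#: polar and soluble).
DEFAULT_FAMILY_SPEC: dict[str, tuple[float, dict[str, float]]] = {
    "benzimidazole": (0.25, {}),
    "organophosphate": (0.20, {"logP": 0.5, "logD": 0.5}),
    "pyrethroid": (0.20, {"logP": 1.5, "logD": 1.2, "logS": -1.5}),
    "salicylanilide": (0.15, {"logP": 2.0, "logD": 1.8, "logS": -2.0}),
    "sulfonamide": (0.20, {"logP": -1.5, "logD": -1.2, "logS": 1.0}),
}


def gen_drug_panel(
    n: int = 86,
    family_spec: Mapping[str, tuple[float, Mapping[str, float]]] | None = None,
    seed: int = 0,
) -> list[CompoundRecord]:
    """Synthetic drug panel with family-specific descriptor offsets.

    Emulates a mixed panel of antiparasitics: ``n`` compounds are allocated to
    families by the given fractions (largest-remainder rounding, at least one
    per family when n allows), descriptors drawn from the base panel ranges
    and shifted by each family's additive offsets. Offsets are never applied
    to counts, unit-interval or percentage descriptors, so every record
    passes table validation.
    """
    spec = dict(family_spec or DEFAULT_FAMILY_SPEC)
    fracs = {fam: f for fam, (f, _) in spec.items()}
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ValueError("family fractions must sum to 1")
    rng = np.random.default_rng(seed)

    families = list(spec)
    raw = {fam: fracs[fam] * n for fam in families}
    counts = {fam: int(raw[fam]) for fam in families}
    if n >= len(families):
        for fam in families:
            counts[fam] = max(counts[fam], 1)
    remainder = n - sum(counts.values())
    by_frac = sorted(families, key=lambda f: raw[f] - int(raw[f]), reverse=True)
    i = 0
    while remainder != 0:
        fam = by_frac[i % len(families)]
        step = 1 if remainder > 0 else -1
        if counts[fam] + step >= (1 if n >= len(families) else 0):
            counts[fam] += step
            remainder -= step
        i += 1

    protected = COUNT_DESCRIPTORS | {"PAMPA", "Fsp3", "HIA", "PPB", "Fu"}
    records: list[CompoundRecord] = []
    idx = 0
    for fam in families:
        _, offsets = spec[fam]
        for _ in range(counts[fam]):
            idx += 1
            desc = DescriptorVector()
            for name, (lo, hi) in _PANEL_RANGES.items():
                v = float(_draw_column(rng, name, lo, hi, 1)[0])
                if name in offsets and name not in protected:
                    v += offsets[name]
                desc[name] = v
            records.append(
                CompoundRecord(
                    id=f"drug{idx:03d}", name=f"{fam}-{idx:03d}", family=fam,
                    descriptors=desc,
                )
            )
    return records
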