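"""Core domain types for descriptor-based QSAR of environmental fate and CNS exposure.

The package predicts three log-scale properties of small molecules from
pre-computed molecular and membrane-permeability descriptors:

* ``logKoc`` — soil–water partition coefficient normalised to organic carbon
  (soil mobility; low values mean mobile, high values mean sorbed).
* ``logBCF`` — fish bioconcentration factor (bioaccumulation potential).
* ``logKpuu`` — unbound brain-to-plasma partition ratio (CNS exposure).

All logarithms are base 10. Descriptors are *inputs*: nothing here parses a
structure or computes a descriptor from SMILES.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "FAMILIES",
    "RECOGNIZED_DESCRIPTORS",
    "COUNT_DESCRIPTORS",
    "UNIT_INTERVAL_DESCRIPTORS",
    "PERCENT_DESCRIPTORS",
    "DescriptorVector",
    "CompoundRecord",
    "PropertyModelSpec",
    "ReferenceDataset",
    "FittedMLR",
    "PermeationMeasurement",
    "PampaMeasurement",
    "ClassificationResult",
    "EnvQsarError",
    "DuplicateIdError",
    "MissingDescriptorError",
    "ValidationReport",
    "validate_table",
]


class EnvQsarError(Exception):
    """Base class for all package-specific errors."""


class DuplicateIdError(EnvQsarError):
    """Two compound records share an id within one table."""


class MissingDescriptorError(EnvQsarError, KeyError):
    """An operation required a descriptor absent from the compound's vector."""


#: Integer count descriptors (must be non-negative integers).
COUNT_DESCRIPTORS: frozenset[str] = frozenset(
    {"nHA", "nHD", "nRot", "nRing", "MaxRing", "nHet", "nRig", "HeavyAtoms", "HBD"}
)

#: Descriptors constrained to the closed unit interval.
UNIT_INTERVAL_DESCRIPTORS: frozenset[str] = frozenset({"PAMPA", "Fsp3"})

#: Percentage descriptors, constrained to [0, 100].
PERCENT_DESCRIPTORS: frozenset[str] = frozenset({"PPB", "Fu", "HIA"})

#: Derived ratios checked for consistency when their constituents are present.
_RATIO_DESCRIPTORS: dict[str, tuple[str, str]] = {
    "Dense": ("MW", "Vol"),   # density = MW / van der Waals volume
    "Flex": ("nRot", "nRig"),  # flexibility = rotatable / rigid bond counts
}

_RATIO_TOL = 1e-9

#: Every descriptor name the package recognises, with units where applicable.
RECOGNIZED_DESCRIPTORS: frozenset[str] = frozenset(
    {
        "MW",        # molecular weight, g/mol
        "Vol",       # van der Waals volume
        "Dense",     # MW / Vol
        "nHA",       # H-bond acceptor count
        "nHD",       # H-bond donor count
        "nRot",      # rotatable bond count
        "nRing",     # ring count
        "MaxRing",   # atoms in the largest ring
        "nHet",      # heteroatom count
        "nRig",      # rigid bond count
        "Flex",      # nRot / nRig
        "logS",      # log10 aqueous solubility, mol/L
        "logP",      # log10 octanol/water partition coefficient
        "logD",      # log10 octanol/water distribution coefficient at pH 7.4
        "Fsp3",      # fraction of sp3 carbons, 0-1
        "TPSA",      # topological polar surface area, A^2
        "caco2",     # predicted log apparent permeability, Caco-2 monolayer
        "MDCK",      # predicted log apparent permeability, MDCK monolayer
        "PAMPA",     # probability of high PAMPA permeability, 0-1
        "logVDss",   # log10 steady-state volume of distribution, L/kg
        "PPB",       # plasma protein binding, %
        "Fu",        # fraction unbound in plasma, %
        "HIA",       # human intestinal absorption, %
        "MLOGP",     # Moriguchi log P
        "HeavyAtoms",  # heavy atom count
        "HBD",       # H-bond donor count (drug-likeness convention)
        "MR",        # molar refractivity
        "iLOGP",     # iLOGP lipophilicity estimate
    }
)

#: Controlled vocabulary for antiparasitic chemical families.
FAMILIES: frozenset[str] = frozenset(
    {
        "benzimidazole",
        "organophosphate",
        "pyrethroid",
        "salicylanilide",
        "sulfonamide",
        "other",
    }
)


class DescriptorVector(dict):
    """Sparse map of descriptor name to numeric value for one compound.

    A plain ``dict`` subclass: absent descriptors are simply absent — they are
    never imputed, and any operation that needs a missing descriptor raises
    :class:`MissingDescriptorError` naming it.

    Use :meth:`problems` to list invariant violations (negative counts,
    out-of-range probabilities or percentages, inconsistent derived ratios).
    """

    def require(self, names: Iterable[str]) -> None:
        """Raise :class:`MissingDescriptorError` if any of *names* is absent."""
        missing = [n for n in names if n not in self]
        if missing:
            raise MissingDescriptorError(
                f"missing descriptor(s): {', '.join(sorted(missing))}"
            )

    def problems(self) -> list[str]:
        """Return human-readable invariant violations (empty list = valid)."""
        issues: list[str] = []
        for name, value in self.items():
            if not isinstance(value, (int, float)):
                issues.append(f"{name}: non-numeric value {value!r}")
                continue
            if value != value:  # NaN
                issues.append(f"{name}: NaN value")
                continue
            if name in COUNT_DESCRIPTORS:
                if value < 0 or float(value) != int(value):
                    issues.append(f"{name}: count must be a non-negative integer, got {value}")
            elif name in UNIT_INTERVAL_DESCRIPTORS:
                if not 0.0 <= value <= 1.0:
                    issues.append(f"{name}: must lie in [0, 1], got {value}")
            elif name in PERCENT_DESCRIPTORS:
                if not 0.0 <= value <= 100.0:
                    issues.append(f"{name}: percentage must lie in [0, 100], got {value}")
        for ratio, (num, den) in _RATIO_DESCRIPTORS.items():
            if ratio in self and num in self and den in self and self[den] != 0:
                expected = self[num] / self[den]
                if abs(self[ratio] - expected) > _RATIO_TOL:
                    issues.append(
                        f"{ratio}: inconsistent with {num}/{den} "
                        f"({self[ratio]} vs {expected})"
                    )
        return issues


@dataclass
class CompoundRecord:
    """One compound: identity, family tag, and its descriptor vector.

    ``smiles`` is carried through for provenance only and never parsed.
    """

    id: str
    name: str = ""
    family: str = "other"
    smiles: str | None = None
    descriptors: DescriptorVector = field(default_factory=DescriptorVector)

    def __post_init__(self) -> None:
        if not isinstance(self.descriptors, DescriptorVector):
            self.descriptors = DescriptorVector(self.descriptors)


@dataclass(frozen=True)
class PropertyModelSpec:
    """A fixed-coefficient linear QSAR model: intercept plus named terms.

    Coefficients are stored exactly as published; :meth:`predict` evaluates
    ``intercept + sum(coef * descriptor)``. Serialisation keeps full binary
    precision (floats survive a JSON round trip bit-exactly via ``repr``).
    """

    property: str  # logKoc | logBCF | logKpuu
    intercept: float
    terms: Mapping[str, float]
    term_se: Mapping[str, float] | None = None
    intercept_se: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.terms) - RECOGNIZED_DESCRIPTORS
        if unknown:
            raise ValueError(f"unrecognized descriptor term(s): {sorted(unknown)}")
        object.__setattr__(self, "terms", dict(self.terms))
        if self.term_se is not None:
            object.__setattr__(self, "term_se", dict(self.term_se))

    def predict(self, descriptors: Mapping[str, float]) -> float:
        """Evaluate the model on one descriptor mapping.

        Raises :class:`MissingDescriptorError` if any model term is absent.
        """
        missing = [t for t in self.terms if t not in descriptors]
        if missing:
            raise MissingDescriptorError(
                f"{self.property} model needs descriptor(s): {', '.join(sorted(missing))}"
            )
        return self.intercept + sum(c * descriptors[t] for t, c in self.terms.items())

    def to_json(self) -> str:
        payload = {
            "property": self.property,
            "intercept": self.intercept,
            "terms": dict(self.terms),
            "term_se": dict(self.term_se) if self.term_se is not None else None,
            "intercept_se": self.intercept_se,
            "provenance": self.provenance,
        }
        # repr-round-trip floats: json keeps shortest repr, which is bit-exact
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PropertyModelSpec":
        d = json.loads(text)
        return cls(
            property=d["property"],
            intercept=d["intercept"],
            terms=d["terms"],
            term_se=d.get("term_se"),
            intercept_se=d.get("intercept_se"),
            provenance=d.get("provenance", ""),
        )


@dataclass
class ReferenceDataset:
    """Compounds with observed property values and a train/test(/validation) split.

    ``response`` and ``split`` must cover every compound id; split labels are
    ``train``, ``test`` and (for neural-network fixtures) ``validation``.
    """

    compounds: list[CompoundRecord]
    response: dict[str, float]
    split: dict[str, str]
    property: str

    _VALID_SPLITS = frozenset({"train", "test", "validation"})

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError("duplicate compound ids in reference dataset")
        for cid in ids:
            if cid not in self.response:
                raise EnvQsarError(f"no response value for compound {cid!r}")
            if cid not in self.split:
                raise EnvQsarError(f"no split label for compound {cid!r}")
            if self.split[cid] not in self._VALID_SPLITS:
                raise EnvQsarError(f"bad split label {self.split[cid]!r} for {cid!r}")

    def split_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cid in self.split:
            sizes[self.split[cid]] = sizes.get(self.split[cid], 0) + 1
        return sizes

    def subset(self, label: str) -> "ReferenceDataset":
        keep = [c for c in self.compounds if self.split[c.id] == label]
        ids = {c.id for c in keep}
        return ReferenceDataset(
            compounds=keep,
            response={i: self.response[i] for i in ids},
            split={i: self.split[i] for i in ids},
            property=self.property,
        )

    def frame(self, columns: Iterable[str], label: str | None = None):
        """Return ``(X, y)`` as a pandas DataFrame/Series for the given split.

        ``label=None`` uses every compound. Missing descriptors raise.
        """
        import pandas as pd

        columns = list(columns)
        rows, ys, index = [], [], []
        for c in self.compounds:
            if label is not None and self.split[c.id] != label:
                continue
            c.descriptors.require(columns)
            rows.append([float(c.descriptors[col]) for col in columns])
            ys.append(self.response[c.id])
            index.append(c.id)
        X = pd.DataFrame(rows, columns=columns, index=index)
        y = pd.Series(ys, index=index, name=self.property)
        return X, y


@dataclass
class FittedMLR:
    """Result of a forward-stepwise MLR fit: coefficients, trace, metrics."""

    property: str
    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    intercept_se: float
    step_trace: list[tuple[str, float, float]]  # (descriptor, F-to-enter, cumulative R2)
    r2: float
    r2_adj: float
    q2: float | None
    rmse_pred: float | None
    n_train: int
    n_test: int

    def __post_init__(self) -> None:
        r2s = [r for _, _, r in self.step_trace]
        if any(b < a - 1e-12 for a, b in zip(r2s, r2s[1:])):
            raise EnvQsarError("step trace cumulative R2 must be non-decreasing")
        if self.rmse_pred is not None and self.rmse_pred < 0:
            raise EnvQsarError("RMSE_pred cannot be negative")

    def as_spec(self) -> PropertyModelSpec:
        return PropertyModelSpec(
            property=self.property,
            intercept=self.intercept,
            terms=dict(self.coefficients),
            term_se=dict(self.standard_errors),
            intercept_se=self.intercept_se,
            provenance="forward stepwise MLR fit",
        )


@dataclass(frozen=True)
class PermeationMeasurement:
    """Cell-monolayer flux measurement for apparent permeability (Papp).

    ``dQdt`` is the permeation rate (amount/time), ``C0`` the donor
    concentration at time zero, ``A`` the monolayer area.
    """

    dQdt: float
    C0: float
    A: float

    def __post_init__(self) -> None:
        if self.C0 <= 0:
            raise ValueError("donor concentration C0 must be positive")
        if self.A <= 0:
            raise ValueError("monolayer area A must be positive")


@dataclass(frozen=True)
class PampaMeasurement:
    """PAMPA assay geometry and endpoint for effective permeability (Pe).

    ``acceptor_fraction`` is [drug]_acceptor / [drug]_equilibrium and must be
    strictly below 1 (equilibrium can only be approached).
    """

    VD: float
    VA: float
    Area: float
    Time: float
    acceptor_fraction: float

    def __post_init__(self) -> None:
        for fname in ("VD", "VA", "Area", "Time"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be positive")
        if not 0.0 <= self.acceptor_fraction < 1.0:
            raise ValueError("acceptor_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class ClassificationResult:
    """All threshold-derived risk categories for one compound."""

    mobility_class: str | None = None
    bioaccumulation: bool | None = None
    bcf_threshold: float | None = None
    bbb_category: str | None = None
    hia_flag: bool | None = None
    caco2_flag: str | None = None
    ro5_violations: int | None = None
    drug_like: bool | None = None
    ro5_skipped: tuple[str, ...] = ()


@dataclass
class ValidationReport:
    """Outcome of validating a compound table against required descriptors."""

    passed: bool
    record_issues: dict[str, list[str]]  # id -> problem strings
    unusable_ids: list[str]

    @property
    def n_issues(self) -> int:
        return sum(len(v) for v in self.record_issues.values())


def validate_table(
    records: list[CompoundRecord], required: Iterable[str] = ()
) -> ValidationReport:
    """Validate a compound table: id uniqueness, descriptor invariants, coverage.

    Duplicate ids are a hard error (:class:`DuplicateIdError`). A record with a
    missing required descriptor or an invariant violation is listed and marked
    unusable — values are never imputed. The table passes iff no record has
    issues.
    """
    required = list(required)
    seen: set[str] = set()
    issues: dict[str, list[str]] = {}
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate compound id {rec.id!r}")
        seen.add(rec.id)
        probs = rec.descriptors.problems()
        missing = [n for n in required if n not in rec.descriptors]
        if missing:
            probs = probs + [f"missing required descriptor(s): {', '.join(missing)}"]
        unknown = set(rec.descriptors) - RECOGNIZED_DESCRIPTORS
        if unknown:
            # unknown names are carried but reported; they never fail the table
            probs = probs + [f"unrecognized descriptor(s) carried: {sorted(unknown)}"]
        if rec.family not in FAMILIES:
            probs = probs + [f"family {rec.family!r} not in controlled vocabulary"]
        if probs:
            issues[rec.id] = probs
    unusable = [
        i
        for i, p in issues.items()
        if any(not s.startswith("unrecognized") for s in p)
    ]
    return ValidationReport(
        passed=not unusable, record_issues=issues, unusable_ids=unusable
    )
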