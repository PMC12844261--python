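"""Published fixed-coefficient QSAR predictors and threshold classifiers.

Four multiple-linear-regression models are shipped as constants with their
coefficients exactly as published:

* :data:`EQ1_KOC` — soil–water partition, log Koc, from nRot, nHet, nRing,
  PAMPA, log S, log P (n_train = 500).
* :data:`EQ2_BCF` — fish bioconcentration, log BCF, from nRot, MaxRing,
  PAMPA, log S, log D (n_train = 400).
* :data:`EQ3_KPUU` — unbound brain-to-plasma ratio, log Kp,uu, from TPSA,
  nHet, Fsp3, MDCK (n_train = 60).
* :data:`EQ4_KPUU_COMPARISON` — an earlier literature log Kp,uu model from
  heavy-atom count, H-bond donors, molar refractivity and iLOGP, used for
  cross-model comparison only.

Alongside them live the in-vitro permeability formulas (apparent permeability
Papp from cell-monolayer flux, effective permeability Pe from PAMPA
compartment geometry) and every threshold classifier: EPA soil-mobility
classes, bioaccumulation cut-offs, the 30% HIA absorption cut-off, Caco-2
permeability flags, blood–brain-barrier exposure categories, and a
Lipinski-style drug-likeness check with Moriguchi logP / molecular-weight
limits.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

from .core import (
    ClassificationResult,
    DescriptorVector,
    MissingDescriptorError,
    PampaMeasurement,
    PermeationMeasurement,
    PropertyModelSpec,
)

__all__ = [
    "EQ1_KOC",
    "EQ2_BCF",
    "EQ3_KPUU",
    "EQ4_KPUU_COMPARISON",
    "BUILTIN_MODELS",
    "evaluate_model",
    "apparent_permeability",
    "effective_permeability",
    "classify_mobility",
    "flag_bioaccumulation",
    "classify_bbb",
    "flag_hia",
    "flag_caco2",
    "ro5_check",
    "classify_compound",
    "MOBILITY_CLASSES",
    "BBB_CATEGORIES",
]

EQ1_KOC = PropertyModelSpec(
    property="logKoc",
    intercept=0.921,
    terms={
        "nRot": -0.0441,
        "nHet": 0.0309,
        "nRing": 0.152,
        "PAMPA": -0.272,
        "logS": -0.201,
        "logP": 0.356,
    },
    term_se={
        "nRot": 0.0091,
        "nHet": 0.0109,
        "nRing": 0.029,
        "PAMPA": 0.074,
        "logS": 0.033,
        "logP": 0.034,
    },
    intercept_se=0.067,
    provenance="published stepwise MLR, soil-water partition (log Koc), n_train=500",
)

EQ2_BCF = PropertyModelSpec(
    property="logBCF",
    intercept=0.668,
    terms={
        "nRot": -0.130,
        "MaxRing": -0.0901,
        "PAMPA": -0.543,
        "logS": -0.251,
        "logD": 0.493,
    },
    term_se={
        "nRot": 0.011,
        "MaxRing": 0.0138,
        "PAMPA": 0.128,
        "logS": 0.040,
        "logD": 0.075,
    },
    intercept_se=0.133,
    provenance="published stepwise MLR, fish bioconcentration (log BCF), n_train=400",
)

EQ3_KPUU = PropertyModelSpec(
    property="logKpuu",
    intercept=6.81,
    terms={
        "TPSA": -0.0118,
        "nHet": -0.0971,
        "Fsp3": 0.670,
        "MDCK": 1.31,
    },
    term_se={
        "TPSA": 0.0034,
        "nHet": 0.0373,
        "Fsp3": 0.329,
        "MDCK": 0.30,
    },
    intercept_se=1.37,
    provenance="published stepwise MLR, unbound brain-to-plasma ratio (log Kp,uu), n_train=60",
)

EQ4_KPUU_COMPARISON = PropertyModelSpec(
    property="logKpuu",
    intercept=0.866,
    terms={
        "HeavyAtoms": -0.211,
        "HBD": -0.250,
        "MR": 0.0272,
        "iLOGP": 0.483,
    },
    provenance="earlier literature log Kp,uu model, used for cross-model comparison",
)

#: Built-in models keyed by the short names used on the command line.
BUILTIN_MODELS: dict[str, PropertyModelSpec] = {
    "eq1": EQ1_KOC,
    "eq2": EQ2_BCF,
    "eq3": EQ3_KPUU,
    "eq4": EQ4_KPUU_COMPARISON,
}


def evaluate_model(spec: PropertyModelSpec, d: Mapping[str, float]) -> float:
    """Evaluate a fixed-coefficient linear model on one descriptor mapping.

    Pure function: returns ``intercept + sum(coef * descriptor)``. Raises
    :class:`~envqsar.core.MissingDescriptorError` naming any absent term.
    """
    return spec.predict(d)


def apparent_permeability(m: PermeationMeasurement) -> float:
    """Apparent permeability Papp = (dQ/dt) / (C0 * A) from a cell assay.

    Units follow the inputs: (amount/time) / (concentration * area).
    """
    return m.dQdt / (m.C0 * m.A)


def effective_permeability(m: PampaMeasurement) -> float:
    """Effective PAMPA permeability Pe = -C * ln(1 - acceptor_fraction).

    ``C = VD*VA / ((VD+VA) * Area * Time)`` combines the compartment volumes
    and membrane geometry. The leading minus sign follows the standard PAMPA
    convention so that Pe is non-negative and increases with the fraction of
    drug found in the acceptor compartment; Pe diverges as the acceptor
    approaches equilibrium.
    """
    C = (m.VD * m.VA) / ((m.VD + m.VA) * m.Area * m.Time)
    return -C * math.log(1.0 - m.acceptor_fraction)


#: EPA soil-mobility classes, most mobile first, with lower-inclusive bounds.
MOBILITY_CLASSES: tuple[tuple[float, str], ...] = (
    (1.0, "very_mobile"),
    (2.0, "mobile"),
    (3.0, "moderately_mobile"),
    (4.0, "slightly_mobile"),
    (5.0, "hardly_mobile"),
    (math.inf, "immobile"),
)


def _check_finite(x: float, what: str) -> None:
    if x != x or math.isinf(x):
        raise ValueError(f"{what} must be finite, got {x}")


def classify_mobility(log_koc: float) -> str:
    """EPA soil mobility class for a log Koc value.

    Bands are half-open, lower-inclusive: [1, 2) is ``mobile``, [2, 3)
    ``moderately_mobile``, and so on; values below 1 are ``very_mobile`` and
    values of 5 or more ``immobile``.
    """
    _check_finite(log_koc, "log Koc")
    for upper, label in MOBILITY_CLASSES:
        if log_koc < upper:
            return label
    return "immobile"  # pragma: no cover — inf upper bound always matches


def flag_bioaccumulation(log_bcf: float, threshold: float = 3.3) -> bool:
    """True iff log BCF strictly exceeds the bioaccumulation cut-off.

    The two regulatory cut-offs in use are 3.3 (default, the conservative
    choice) and 3.7; any other threshold is accepted with a warning.
    """
    _check_finite(log_bcf, "log BCF")
    if threshold not in (3.3, 3.7):
        warnings.warn(
            f"non-standard bioaccumulation threshold {threshold} "
            "(regulatory cut-offs are 3.3 and 3.7)",
            stacklevel=2,
        )
    return log_bcf > threshold


#: Brain-exposure categories from most to least permeable, with their
#: half-open lower bounds (right-inclusive at the lower edge).
BBB_CATEGORIES: tuple[tuple[float, str], ...] = (
    (-0.3, "high"),
    (-0.52, "moderate"),
    (-2.0, "low"),
    (-math.inf, "very_low"),
)


def classify_bbb(log_kpuu: float) -> str:
    """Brain-penetration category from log Kp,uu.

    ``high`` above -0.3 (the compound partitions nearly freely into brain),
    ``moderate`` in (-0.52, -0.3], ``low`` in (-2, -0.52], ``very_low`` at or
    below -2. The -0.52 to -0.3 band reflects the spread of literature
    cut-offs for easy brain penetration.
    """
    _check_finite(log_kpuu, "log Kp,uu")
    for lower, label in BBB_CATEGORIES:
        if log_kpuu > lower:
            return label
    return "very_low"


def flag_hia(hia_percent: float) -> bool:
    """True iff predicted human intestinal absorption strictly exceeds 30%."""
    if not 0.0 <= hia_percent <= 100.0:
        raise ValueError(f"HIA must lie in [0, 100], got {hia_percent}")
    return hia_percent > 30.0


def flag_caco2(caco2: float) -> str:
    """Caco-2 permeability flag from the predicted log Papp score.

    ``permeable`` at or above the -5.15 cut-off; ``borderline`` in
    [-5.5, -5.15), just below the threshold; ``impaired`` below -5.5.
    """
    _check_finite(caco2, "caco2")
    if caco2 >= -5.15:
        return "permeable"
    if caco2 >= -5.5:
        return "borderline"
    return "impaired"


def ro5_check(d: Mapping[str, float]) -> tuple[int, bool, tuple[str, ...]]:
    """Drug-likeness check merging Moriguchi-logP/MW limits with H-bond rules.

    Counts violations among MLOGP > 4.15, MW > 500, nHA > 10, nHD > 5.
    MW and MLOGP are required; nHA/nHD are skipped when absent (the skip is
    recorded, never treated as zero). A compound is drug-like with at most one
    violation.

    Returns ``(violations, drug_like, skipped_rules)``.
    """
    missing = [k for k in ("MW", "MLOGP") if k not in d]
    if missing:
        raise MissingDescriptorError(
            f"drug-likeness check needs descriptor(s): {', '.join(missing)}"
        )
    violations = 0
    skipped: list[str] = []
    if d["MLOGP"] > 4.15:
        violations += 1
    if d["MW"] > 500:
        violations += 1
    for name, limit in (("nHA", 10), ("nHD", 5)):
        if name in d:
            if d[name] > limit:
                violations += 1
        else:
            skipped.append(name)
    return violations, violations <= 1, tuple(skipped)


def classify_compound(
    d: Mapping[str, float],
    predictions: Mapping[str, float],
    bcf_threshold: float = 3.3,
    require: tuple[str, ...] = (),
) -> ClassificationResult:
    """Consolidate every threshold classifier into one result.

    ``predictions`` maps property tags (``logKoc``, ``logBCF``, ``logKpuu``)
    to predicted values; descriptor-based flags (HIA, caco2, drug-likeness)
    use ``d`` directly and are filled only when their inputs are present.
    Anything listed in ``require`` must be computable — a missing input there
    raises a per-compound :class:`~envqsar.core.MissingDescriptorError`.
    Deterministic; errors from individual classifiers propagate per compound.
    """
    for prop in require:
        pool = predictions if prop.startswith("log") else d
        if prop not in pool:
            raise MissingDescriptorError(
                f"classification requested {prop} but no value is available"
            )
    kwargs: dict = {}
    if "logKoc" in predictions:
        kwargs["mobility_class"] = classify_mobility(predictions["logKoc"])
    if "logBCF" in predictions:
        kwargs["bioaccumulation"] = flag_bioaccumulation(
            predictions["logBCF"], bcf_threshold
        )
        kwargs["bcf_threshold"] = bcf_threshold
    if "logKpuu" in predictions:
        kwargs["bbb_category"] = classify_bbb(predictions["logKpuu"])
    if "HIA" in d:
        kwargs["hia_flag"] = flag_hia(d["HIA"])
    if "caco2" in d:
        kwargs["caco2_flag"] = flag_caco2(d["caco2"])
    if "MW" in d and "MLOGP" in d:
        violations, drug_like, skipped = ro5_check(d)
        kwargs["ro5_violations"] = violations
        kwargs["drug_like"] = drug_like
        kwargs["ro5_skipped"] = skipped
    return ClassificationResult(**kwargs)


def require_prediction(predictions: Mapping[str, float], prop: str) -> float:
    """Fetch a required property prediction, raising a per-compound error."""
    if prop not in predictions:
        raise MissingDescriptorError(f"prediction for {prop} required but absent")
    return predictions[prop]
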