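"""Cross-model agreement, per-family summaries, and applicability-domain checks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CompoundRecord, EnvQsarError, ReferenceDataset

__all__ = [
    "pearson_matrix",
    "consensus_predict",
    "family_summary",
    "applicability_check",
    "ApplicabilityReport",
]


def pearson_matrix(predictions: Mapping[str, Sequence[float]] | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix across model prediction vectors.

    ``predictions`` maps model labels to equal-length vectors aligned by
    compound (or is a DataFrame with one column per model). The result is
    symmetric with unit diagonal. A zero-variance vector has an undefined
    correlation: its row and column are reported as NaN sentinels rather than
    silently dropped.
    """
    frame = pd.DataFrame(dict(predictions)) if not isinstance(predictions, pd.DataFrame) else predictions.copy()
    if len(frame) < 3:
        raise EnvQsarError("pearson_matrix needs at least 3 compounds")
    labels = list(frame.columns)
    arr = frame.to_numpy(dtype=float)
    stds = arr.std(axis=0)
    out = np.full((len(labels), len(labels)), np.nan)
    for i in range(len(labels)):
        for j in range(i, len(labels)):
            if stds[i] == 0 or stds[j] == 0:
                continue  # undefined — NaN sentinel
            r = float(np.corrcoef(arr[:, i], arr[:, j])[0, 1])
            out[i, j] = out[j, i] = r
        if stds[i] > 0:
            out[i, i] = 1.0
    return pd.DataFrame(out, index=labels, columns=labels)


def consensus_predict(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-compound consensus over models: mean, min, max, sd, and a flag.

    ``predictions`` has compounds as rows and models as columns (at least
    two). A compound missing any model's prediction is flagged and excluded
    from the consensus statistics (its summary columns are NaN). The standard
    deviation is the sample (ddof=1) value.
    """
    frame = pd.DataFrame(predictions)
    if frame.shape[1] < 2:
        raise EnvQsarError("consensus needs at least 2 models")
    complete = frame.notna().all(axis=1)
    out = pd.DataFrame(index=frame.index)
    out["mean"] = frame.mean(axis=1).where(complete)
    out["min"] = frame.min(axis=1).where(complete)
    out["max"] = frame.max(axis=1).where(complete)
    out["sd"] = frame.std(axis=1, ddof=1).where(complete)
    out["flagged"] = ~complete
    return out


def family_summary(
    records: Iterable[CompoundRecord],
    values: Mapping[str, float],
) -> tuple[pd.DataFrame, dict[str, list[float]]]:
    """Grouped summary of a per-compound value by chemical family.

    Returns ``(summary, family_values)`` where the summary table carries n,
    mean, median, min, max and quartiles per family (families with no
    compounds are omitted), and ``family_values`` holds the raw per-family
    value lists needed to draw violin plots.
    """
    buckets: dict[str, list[float]] = {}
    for rec in records:
        if rec.id in values:
            buckets.setdefault(rec.family, []).append(float(values[rec.id]))
    rows = []
    for fam in sorted(buckets):
        v = np.asarray(buckets[fam], dtype=float)
        rows.append(
            {
                "family": fam,
                "n": len(v),
                "mean": v.mean(),
                "median": float(np.median(v)),
                "min": v.min(),
                "max": v.max(),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            }
        )
    return pd.DataFrame(rows), buckets


@dataclass
class ApplicabilityReport:
    """Per-descriptor range coverage of a query set against a reference set."""

    per_descriptor: pd.DataFrame  # ref_min, ref_max, coverage, n_out
    out_of_range: dict[str, list[str]]  # descriptor -> out-of-range query ids
    in_domain: dict[str, bool]  # query id -> inside every descriptor range


def applicability_check(
    reference: ReferenceDataset,
    query: Sequence[CompoundRecord],
    descriptors: Sequence[str],
) -> ApplicabilityReport:
    """Range-based applicability-domain check.

    For each model descriptor the reference min/max (over all reference
    compounds) is compared with the query compounds; a query compound is in
    domain iff every listed descriptor lies inside the reference range. This
    is a pure range-overlap check — no leverage or distance measure.
    """
    ref_rows = {
        d: [float(c.descriptors[d]) for c in reference.compounds]
        for d in descriptors
    }
    rows = []
    out_ids: dict[str, list[str]] = {}
    in_domain = {q.id: True for q in query}
    for d in descriptors:
        lo, hi = (min(ref_rows[d]), max(ref_rows[d])) if ref_rows[d] else (np.nan, np.nan)
        outs = []
        for q in query:
            q.descriptors.require([d])
            v = float(q.descriptors[d])
            if not lo <= v <= hi:
                outs.append(q.id)
                in_domain[q.id] = False
        coverage = 1.0 - len(outs) / len(query) if query else np.nan
        rows.append(
            {"descriptor": d, "ref_min": lo, "ref_max": hi, "coverage": coverage, "n_out": len(outs)}
        )
        out_ids[d] = outs
    return ApplicabilityReport(
        per_descriptor=pd.DataFrame(rows).set_index("descriptor"),
        out_of_range=out_ids,
        in_domain=in_domain,
    )
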