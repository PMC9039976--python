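"""ToxPi scoring: min-max component scaling, slice scores, overall scores.

The ToxPi index compresses heterogeneous raw factors into dimensionless
scores on [0, 1]:

* each raw component column is min-max scaled across records, so 0 is the
  minimum observed value and 1 the maximum (inverted components are negated
  first, mapping the raw minimum to 1);
* a slice score is the unweighted mean of its scaled components, itself
  min-max rescaled across records so every slice spans [0, 1];
* the overall score is the slice-weighted sum, renormalized by its maximum
  so the highest-scoring record is exactly 1 ("more filled area means
  higher vulnerability").

Policies: a constant (zero-range) vector scores 0 everywhere, since it
carries no ranking information; missing raw values score 0 after scaling
(no evidence of risk) and the count is logged.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import StatisticalError, ValidationError
from .model_io import ScoredTable, Slice, SourceTable, ToxPiModel

logger = logging.getLogger(__name__)


def _minmax(values: np.ndarray) -> np.ndarray:
    """Min-max rescale finite entries to [0, 1]; constant input -> all zeros.

    NaNs are preserved (callers decide the missing policy).
    """
    out = np.full(values.shape, np.nan)
    finite = np.isfinite(values)
    if not finite.any():
        return out
    lo = values[finite].min()
    hi = values[finite].max()
    if hi == lo:  # degenerate range: no ranking information
        out[finite] = 0.0
    else:
        out[finite] = (values[finite] - lo) / (hi - lo)
    return out


def scale_component(values, invert: bool = False) -> np.ndarray:
    """Scale one raw component vector to [0, 1].

    The minimum non-missing value maps to 0 and the maximum to 1 (reversed
    when *invert* is true). Missing entries (NaN) score 0 after scaling.

    Raises :class:`StatisticalError` if every entry is missing.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise StatisticalError("component column is entirely missing")
    scaled = _minmax(np.negative(x) if invert else x)
    n_missing = int((~finite).sum())
    if n_missing:
        logger.info("scale_component: %d missing value(s) scored 0", n_missing)
    scaled[~finite] = 0.0
    return scaled


def slice_score(table: SourceTable, slc: Slice) -> np.ndarray:
    """Score one slice for every record of *table*.

    Each component is min-max scaled (honouring its invert flag), the
    per-record unweighted mean is taken, and the mean vector is min-max
    rescaled across records so the slice spans [0, 1].
    """
    missing = [c.column for c in slc.components if c.column not in table.raw.columns]
    if missing:
        raise ValidationError(f"slice {slc.name!r}: missing columns {missing}")
    try:
        scaled = np.column_stack([
            scale_component(table.raw[c.column].to_numpy(), invert=c.invert)
            for c in slc.components
        ])
    except StatisticalError as exc:
        raise StatisticalError(f"slice {slc.name!r}: {exc}") from exc
    return _minmax(scaled.mean(axis=1))


def overall_scores(slice_scores, weights) -> np.ndarray:
    """Weighted sum of slice scores renormalized so the maximum record is 1.

    An all-zero weighted sum yields all-zero overall scores.
    """
    s = np.asarray(slice_scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.ndim != 2 or s.shape[1] != w.shape[0]:
        raise ValidationError(
            f"shape mismatch: scores {s.shape} vs {w.shape[0]} weights")
    if (w <= 0).any():
        raise ValidationError("slice weights must all be > 0")
    raw = s @ w
    top = raw.max() if raw.size else 0.0
    if top == 0:
        return np.zeros_like(raw)
    return raw / top


def score_table(table: SourceTable, model: ToxPiModel) -> ScoredTable:
    """Run the full scoring pipeline for *model* over *table*.

    Record ids, weights, and locations pass through unchanged; the raw
    component columns are carried along for downstream feature popups.
    """
    scores = np.column_stack([slice_score(table, s) for s in model.slices])
    overall = overall_scores(scores, model.weights)
    return ScoredTable(
        ids=list(table.ids),
        slice_names=model.slice_names,
        slice_scores=scores,
        overall=overall,
        weights=model.weights,
        lon=np.array(table.lon, dtype=float),
        lat=np.array(table.lat, dtype=float),
        join_key=list(table.join_key),
        raw=table.raw.copy(),
    )
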