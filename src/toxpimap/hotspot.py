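"""Getis-Ord Gi* hotspot analysis with distance-band spatial weights.

The Gi* statistic asks, for each feature *i*, whether the values within its
neighborhood (features within a fixed distance band, *including i itself* —
the asterisk) are higher or lower than expected if values were assigned to
locations completely at random. For values ``x`` and binary weights
``w_ij``:

    z_i = (sum_j w_ij x_j - Xbar W_i)
          / ( S * sqrt( (n W_i - W_i^2) / (n - 1) ) )

with ``W_i = sum_j w_ij``, ``Xbar = sum(x)/n`` and
``S = sqrt(sum(x^2)/n - Xbar^2)`` (for binary weights
``sum_j w_ij^2 = W_i``). A saturated neighborhood (``W_i = n``) leaves the
statistic undefined; the convention here is ``z_i = 0`` — no local
deviation from the global mean.

Two-sided normal p-values follow, optionally Benjamini-Hochberg adjusted
(the default, mirroring "optimized" hotspot tooling), and each feature is
placed in one of seven confidence bins ``Gi_Bin``: |bin| 3/2/1 at the
99/95/90% levels, sign + for hotspots, - for coldspots, 0 not significant.

The distance band defaults to 50 miles (80 467.2 m), applied as Euclidean
distance in a projected, meter-unit CRS.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import false_discovery_control, norm

from .errors import StatisticalError, ValidationError
from .model_io import BoundaryLayer, ScoredTable

METERS_PER_MILE = 1609.344
DEFAULT_BAND_M = 50 * METERS_PER_MILE  # the 50-mile county-scale band

#: Two-sided p-value thresholds for |Gi_Bin| = 3, 2, 1.
BIN_LEVELS = ((3, 0.01), (2, 0.05), (1, 0.10))


@dataclass
class WeightsMatrix:
    """Binary, symmetric distance-band weights with self-inclusion."""

    n: int
    w: np.ndarray  # n x n in {0, 1}
    band: float  # meters

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (self.n, self.n):
            raise ValidationError("weights matrix shape mismatch")

    def neighbor_counts(self) -> np.ndarray:
        return self.w.sum(axis=1)


@dataclass
class HotspotResult:
    """Per-feature Gi* z-score, p-value, optional FDR-adjusted p, and bin."""

    ids: list[str]
    z: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray | None
    bin: np.ndarray  # integers in {-3..3}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "z": self.z, "p": self.p,
            "p_adj": self.p_adj if self.p_adj is not None else np.nan,
            "gi_bin": self.bin,
        })

    def bin_lookup(self) -> dict[str, int]:
        return {rid: int(b) for rid, b in zip(self.ids, self.bin)}


def distance_band_weights(anchors, band: float) -> WeightsMatrix:
    """Binary weights: ``w_ij = 1`` iff Euclidean distance(i, j) <= band.

    *anchors* are projected (x, y) pairs in meters; the diagonal is always 1
    (a feature neighbors itself — this is what makes the statistic Gi*).
    """
    xy = np.atleast_2d(np.asarray(anchors, dtype=float))
    if xy.shape[0] < 2:
        raise ValidationError("distance-band weights need at least 2 features")
    if not np.isfinite(xy).all():
        raise ValidationError("non-finite anchor coordinates")
    if band <= 0:
        raise ValidationError(f"distance band must be > 0 m, got {band}")
    w = (cdist(xy, xy) <= band).astype(float)
    np.fill_diagonal(w, 1.0)
    return WeightsMatrix(n=xy.shape[0], w=w, band=float(band))


def gi_star(x, W: WeightsMatrix) -> np.ndarray:
    """Vector of Gi* z-scores for values *x* under weights *W*."""
    v = np.asarray(x, dtype=float)
    n = v.shape[0]
    if n != W.n:
        raise ValidationError(f"{n} values vs {W.n}-feature weights matrix")
    if n < 3:
        raise ValidationError("Gi* needs at least 3 features")
    if not np.isfinite(v).all():
        raise ValidationError("non-finite values passed to gi_star")
    xbar = v.mean()
    s = np.sqrt((v ** 2).mean() - xbar ** 2)
    if s == 0:
        raise StatisticalError(
            "values have zero variance; spatial-randomness testing is "
            "meaningless on a constant field")
    wi = W.w.sum(axis=1)
    numer = W.w @ v - xbar * wi
    bracket = (n * wi - wi ** 2) / (n - 1)  # binary weights: sum w^2 = W_i
    z = np.zeros(n)
    ok = bracket > 0
    z[ok] = numer[ok] / (s * np.sqrt(bracket[ok]))
    return z


def significance(z) -> np.ndarray:
    """Two-sided standard-normal p-values: ``p = 2 * (1 - Phi(|z|))``."""
    return 2.0 * norm.sf(np.abs(np.asarray(z, dtype=float)))


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if (arr < 0).any() or (arr > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return false_discovery_control(arr, method="bh")


def classify_bins(z, p_eff) -> np.ndarray:
    """Seven-bin confidence classification of hotspot/coldspot strength.

    ``|bin|`` is 3, 2, 1 for effective p <= 0.01, 0.05, 0.10 and 0
    otherwise; the sign follows the z-score (+ hotspot, - coldspot).
    """
    zv = np.asarray(z, dtype=float)
    pv = np.asarray(p_eff, dtype=float)
    if zv.shape != pv.shape:
        raise ValidationError("z and p vectors differ in length")
    mag = np.zeros(zv.shape, dtype=int)
    for level, cutoff in sorted(BIN_LEVELS, key=lambda t: t[1]):
        mag[(mag == 0) & (pv <= cutoff)] = level
    return mag * np.sign(zv).astype(int)


def optimized_hotspot(
    scored: ScoredTable,
    band: float = DEFAULT_BAND_M,
    crs: int = 3857,
    use_fdr: bool = True,
    value: str = "overall",
    boundaries: BoundaryLayer | None = None,
) -> HotspotResult:
    """Full pipeline: project anchors, build weights, Gi*, p-values, bins.

    *value* selects the analysed field: ``"overall"`` or ``"slice:<name>"``
    to hotspot a single factor. With *use_fdr* (default) the bin
    classification uses Benjamini-Hochberg adjusted p-values; without it,
    the textbook raw-p statistic.
    """
    from .layers import resolve_anchors  # deferred: avoids import cycle

    if len(scored) < 3:
        raise ValidationError("hotspot analysis needs at least 3 records")
    if value == "overall":
        x = np.asarray(scored.overall, dtype=float)
    elif value.startswith("slice:"):
        x = scored.slice_column(value.split(":", 1)[1])
    else:
        raise ValidationError(
            f"value selector must be 'overall' or 'slice:<name>', got {value!r}")
    anchors = resolve_anchors(scored, crs, boundaries)
    W = distance_band_weights(anchors, band)
    lonely = int((W.neighbor_counts() == 1).sum())
    if lonely:
        import logging
        logging.getLogger(__name__).warning(
            "%d feature(s) have only themselves as neighbor at band %.0f m",
            lonely, band)
    z = gi_star(x, W)
    p = significance(z)
    p_adj = fdr_adjust(p) if use_fdr else None
    bins = classify_bins(z, p_adj if use_fdr else p)
    return HotspotResult(ids=list(scored.ids), z=z, p=p, p_adj=p_adj,
                         bin=bins)


def write_hotspot_csv(result: HotspotResult, path: str | os.PathLike) -> None:
    """Write the result as CSV with columns id, z, p, p_adj, gi_bin."""
    result.to_frame().to_csv(path, index=False)
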