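"""Distance matrices and Mantel / partial Mantel permutation tests.

Geographic distances are great-circle (haversine) kilometres; linguistic
distances use the ordinal scheme 0 (same language), 1 (same branch of a
family), 2 (different branches of the same family), 3 (different
families); genetic distances are typically Slatkin-linearized F_ST,
F_ST / (1 - F_ST).

The Mantel statistic is the Pearson correlation of the off-diagonal
upper-triangle entries of two labelled distance matrices; significance
comes from jointly permuting the rows/columns of one matrix. P-values are
one-sided (positive association) and use the add-one estimator
p = (1 + #{r_perm >= r_obs}) / (n_perm + 1), so p is never zero. For n <= 7
the permutation distribution is enumerated exhaustively.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Optional, Sequence

import numpy as np

from .core import DistanceMatrix, InvalidArgument, MantelResult
from .formats_io import PopulationMeta

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
EXHAUSTIVE_N_MAX = 7


# ---------------------------------------------------------------------------
# Distance-matrix constructors
# ---------------------------------------------------------------------------

def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = (math.sin(dphi / 2) ** 2
         + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def great_circle_matrix(metadata: Sequence[PopulationMeta]) -> DistanceMatrix:
    """Great-circle distances (km) between sampled sites."""
    for m in metadata:
        if not (-90 <= m.lat <= 90 and -180 <= m.lon <= 180):
            raise InvalidArgument(f"coordinates out of range for {m.label}")
    n = len(metadata)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(metadata[i].lat, metadata[i].lon,
                             metadata[j].lat, metadata[j].lon)
            out[i, j] = out[j, i] = d
    return DistanceMatrix([m.label for m in metadata], out)


def linguistic_matrix(metadata: Sequence[PopulationMeta]) -> DistanceMatrix:
    """Ordinal linguistic distances under the 0/1/2/3 scheme."""
    for m in metadata:
        if not (m.language_family and m.language_branch and m.language):
            raise InvalidArgument(f"incomplete language fields for {m.label}")
    n = len(metadata)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = metadata[i], metadata[j]
            if a.language == b.language:
                d = 0
            elif (a.language_family == b.language_family
                  and a.language_branch == b.language_branch):
                d = 1
            elif a.language_family == b.language_family:
                d = 2
            else:
                d = 3
            out[i, j] = out[j, i] = d
    return DistanceMatrix([m.label for m in metadata], out)


def slatkin_linearize(fst: float) -> float:
    """Slatkin's linearized F_ST: fst / (1 - fst); negative inputs clip to 0."""
    if fst >= 1:
        raise InvalidArgument("F_ST must be < 1 for linearization")
    if fst < 0:
        logger.warning("negative F_ST %.4g clipped to 0 before linearization",
                       fst)
        return 0.0
    return fst / (1.0 - fst)


def slatkin_matrix(fst_matrix: DistanceMatrix) -> DistanceMatrix:
    vals = np.vectorize(slatkin_linearize)(np.maximum(fst_matrix.values, 0.0))
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(fst_matrix.labels), vals)


def variance_explained(r: float) -> float:
    """Percent of variance explained: 100 * r^2."""
    if abs(r) > 1:
        raise InvalidArgument("|r| must be <= 1")
    return 100.0 * r * r


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def _check_pair(X: DistanceMatrix, Y: DistanceMatrix, min_n: int) -> None:
    if X.labels != Y.labels:
        raise InvalidArgument("distance matrices must share labels and order")
    if X.n < min_n:
        raise InvalidArgument(f"need at least {min_n} items")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise InvalidArgument("zero variance in distance entries")
    return float(xc @ yc) / denom


def _permutations(n: int, n_perm: int, seed: Optional[int],
                  exhaustive: Optional[bool]):
    """Yield (permutations iterable, n_used, exhaustive_flag)."""
    if exhaustive is None:
        exhaustive = n <= EXHAUSTIVE_N_MAX
    if exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        return perms, len(perms), True
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_perm)]
    return perms, n_perm, False


def mantel(X: DistanceMatrix, Y: DistanceMatrix, n_perm: int = 100_000,
           seed: Optional[int] = None,
           exhaustive: Optional[bool] = None) -> MantelResult:
    """Mantel test of matrix association (one-sided, positive).

    Permutes the row/column labels of ``Y`` jointly. With ``exhaustive``
    (default for n <= 7) all n! label permutations are enumerated and the
    p-value is exact: p = #{r_perm >= r_obs} / n!.
    """
    _check_pair(X, Y, min_n=3)
    iu = np.triu_indices(X.n, k=1)
    x = X.values[iu]
    r_obs = _pearson(x, Y.values[iu])

    perms, n_used, was_exhaustive = _permutations(X.n, n_perm, seed, exhaustive)
    count = 0
    for perm in perms:
        yp = Y.values[np.ix_(perm, perm)][iu]
        if _pearson(x, yp) >= r_obs - 1e-12:
            count += 1
    if was_exhaustive:
        p = count / n_used  # identity permutation included: exact, never 0
    else:
        p = (1 + count) / (n_used + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_used, exhaustive=was_exhaustive)


def _partial_r(rxy: float, rxz: float, ryz: float) -> float:
    denom = math.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
    if denom == 0:
        raise InvalidArgument("degenerate input: |r_xz| or |r_yz| = 1")
    return (rxy - rxz * ryz) / denom


def partial_mantel(X: DistanceMatrix, Y: DistanceMatrix, Z: DistanceMatrix,
                   n_perm: int = 100_000, seed: Optional[int] = None,
                   exhaustive: Optional[bool] = None) -> MantelResult:
    """Partial Mantel test of X-Y association controlling for Z.

    Statistic: first-order partial correlation
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    Significance by permuting Y's labels and recomputing the partial
    statistic (r_xz is unaffected by the permutation).
    """
    _check_pair(X, Y, min_n=4)
    _check_pair(X, Z, min_n=4)
    iu = np.triu_indices(X.n, k=1)
    x, y, z = X.values[iu], Y.values[iu], Z.values[iu]
    if np.ptp(z) == 0:
        # constant control matrix: collapses to the simple Mantel statistic
        return MantelResult(
            **{**mantel(X, Y, n_perm=n_perm, seed=seed,
                        exhaustive=exhaustive).__dict__,
               "partial": True, "controlled_labels": "constant"})
    rxz = _pearson(x, z)
    r_obs = _partial_r(_pearson(x, y), rxz, _pearson(y, z))

    perms, n_used, was_exhaustive = _permutations(X.n, n_perm, seed, exhaustive)
    count = 0
    for perm in perms:
        yp = Y.values[np.ix_(perm, perm)][iu]
        try:
            r_p = _partial_r(_pearson(x, yp), rxz, _pearson(yp, z))
        except InvalidArgument:
            continue
        if r_p >= r_obs - 1e-12:
            count += 1
    p = count / n_used if was_exhaustive else (1 + count) / (n_used + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_used, partial=True,
                        exhaustive=was_exhaustive)
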