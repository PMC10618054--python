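"""Contact-probability matrices and the Hi-C-style observables computed from them.

A :class:`ContactMap` holds a symmetric locus-by-locus matrix of contact
probabilities for a genomic region binned at fixed resolution (100 kb in the
reference workflow).  The module covers text I/O (dense and triples dialects),
the adjacent-loci normalization convention ``P[i, i±1] = 1``, the
distance-decay expectation, insulation scores and TAD boundary calling,
observed/expected enhanced contacts at coarse resolution, and the compartment
profile (PC1 of the enhanced map).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenomicRegion",
    "ContactMap",
    "InsulationProfile",
    "EnhancedMap",
    "CompartmentProfile",
    "read_contact_map",
    "write_contact_map",
    "normalize_adjacent",
    "expected_by_distance",
    "enhanced_contacts",
    "insulation_profile",
    "tad_boundaries",
    "compartment_profile",
    "synthetic_region",
]

_SYMMETRY_ATOL = 1e-12


@dataclass(frozen=True)
class GenomicRegion:
    """A contiguous genomic interval binned at a fixed resolution.

    Bins are fenceposts: every bin whose start coordinate lies in
    ``[start_mb, end_mb]`` inclusive counts, so a 20.5–71.4 Mb region at
    100 kb resolution has 510 loci.
    """

    chromosome: str
    start_mb: float
    end_mb: float
    resolution_kb: float

    def __post_init__(self) -> None:
        if not self.start_mb < self.end_mb:
            raise ValueError(f"start ({self.start_mb}) must be < end ({self.end_mb})")
        if self.resolution_kb <= 0:
            raise ValueError("resolution must be positive")

    @property
    def locus_count(self) -> int:
        span_kb = (self.end_mb - self.start_mb) * 1000.0
        return int(math.floor(span_kb / self.resolution_kb + 1e-9)) + 1

    def coarsened(self, coarse_resolution_kb: float) -> "GenomicRegion":
        return GenomicRegion(
            self.chromosome, self.start_mb, self.end_mb, coarse_resolution_kb
        )


def synthetic_region(n_loci: int, resolution_kb: float = 100.0) -> GenomicRegion:
    """Region metadata for a map that has no real genomic provenance."""
    if n_loci < 2:
        raise ValueError("need at least 2 loci")
    end_mb = (n_loci - 1) * resolution_kb / 1000.0
    return GenomicRegion("chrS", 0.0, end_mb, resolution_kb)


@dataclass
class ContactMap:
    """Symmetric matrix of pairwise contact probabilities with region metadata."""

    region: GenomicRegion
    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {P.shape}")
        if P.size == 0:
            raise ValueError("empty contact matrix")
        n = self.region.locus_count
        if P.shape[0] != n:
            raise ValueError(
                f"matrix side {P.shape[0]} does not match the region's "
                f"{n} loci"
            )
        if not np.allclose(P, P.T, atol=_SYMMETRY_ATOL, rtol=0.0):
            raise ValueError("contact matrix must be symmetric")
        if np.any(P < 0):
            i, j = np.argwhere(P < 0)[0]
            raise ValueError(f"negative contact probability at ({i}, {j})")
        self.P = P

    @property
    def n_loci(self) -> int:
        return self.P.shape[0]

    def copy(self) -> "ContactMap":
        return ContactMap(self.region, self.P.copy())


@dataclass
class InsulationProfile:
    """Per-locus insulation scores, log2 relative to the chromosome-wide mean.

    Loci within half a window of either end (and loci whose raw window mean is
    non-positive) are masked undefined.
    """

    scores: np.ndarray  # NaN where undefined
    window_kb: float
    defined: np.ndarray  # boolean mask, True where the score is defined

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.scores[self.defined])):
            raise ValueError("defined insulation scores must be finite")


@dataclass
class EnhancedMap:
    """log2(P_obs / P_exp) at coarse resolution, masked where either term is 0."""

    matrix: np.ndarray  # NaN where undefined
    defined: np.ndarray
    region: GenomicRegion

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CompartmentProfile:
    """Signed per-coarse-bin loading vector (PC1 of the enhanced map).

    Unit Euclidean norm.  The sign convention orients the vector so the bin
    class with higher mean short-range enhanced contact is positive.
    """

    loadings: np.ndarray
    sign_convention: str = "short-range-dense-positive"


# ---------------------------------------------------------------------------
# I/O


def read_contact_map(path, region: GenomicRegion) -> ContactMap:
    """Read a dense square matrix or (i, j, value) triples text file.

    Dense files must be exactly ``locus_count`` rows by ``locus_count``
    columns.  Triples use 0-based bin indices within the region and are
    mirrored to enforce symmetry.  A file whose shape matches neither dialect
    is rejected.
    """
    n = region.locus_count
    raw = np.loadtxt(path, ndmin=2)
    if raw.shape == (n, n):
        P = raw
        if not np.allclose(P, P.T, atol=_SYMMETRY_ATOL, rtol=0.0):
            raise ValueError(f"{path}: dense matrix is not symmetric")
    elif raw.shape[1] == 3:
        P = np.zeros((n, n))
        for rec, (fi, fj, v) in enumerate(raw):
            i, j = int(round(fi)), int(round(fj))
            if abs(fi - i) > 1e-9 or abs(fj - j) > 1e-9:
                raise ValueError(f"{path}: record {rec}: non-integer bin index")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(
                    f"{path}: record {rec}: index ({i}, {j}) out of range for "
                    f"{n} loci"
                )
            if v < 0:
                raise ValueError(f"{path}: record {rec}: negative value {v}")
            P[i, j] = v
            P[j, i] = v
    elif raw.shape[0] == raw.shape[1]:
        raise ValueError(
            f"{path}: dense matrix is {raw.shape[0]}x{raw.shape[1]} but the "
            f"region has {n} loci"
        )
    else:
        raise ValueError(
            f"{path}: shape {raw.shape} is neither a {n}x{n} dense matrix nor "
            "3-column triples"
        )
    return ContactMap(region, P)


def write_contact_map(cmap: ContactMap, path, dialect: str = "dense") -> None:
    """Write a map in the dense or triples text dialect.

    The ``%.17g`` format round-trips float64 bit-exactly through
    :func:`read_contact_map`.
    """
    if dialect == "dense":
        np.savetxt(path, cmap.P, fmt="%.17g")
    elif dialect == "triples":
        i_idx, j_idx = np.nonzero(np.triu(cmap.P != 0.0))
        with open(path, "w") as fh:
            for i, j in zip(i_idx, j_idx):
                fh.write(f"{i} {j} {cmap.P[i, j]:.17g}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Normalization and distance decay


def normalize_adjacent(cmap: ContactMap) -> ContactMap:
    """Rescale so adjacent loci are always in contact: ``P[i, i±1] = 1``.

    The whole matrix is divided by the mean first-off-diagonal value, entries
    above 1 are clipped to 1, and both first off-diagonals are then pinned to
    exactly 1.  Idempotent, symmetry-preserving.
    """
    P = cmap.P
    adjacent = np.diagonal(P, offset=1)
    anchor = float(adjacent.mean())
    if anchor <= 0:
        raise ValueError(
            "cannot normalize: first off-diagonal mean is zero (no adjacent "
            "contacts to anchor on)"
        )
    out = np.clip(P / anchor, None, 1.0)
    n = out.shape[0]
    idx = np.arange(n - 1)
    out[idx, idx + 1] = 1.0
    out[idx + 1, idx] = 1.0
    return ContactMap(cmap.region, out)


def expected_by_distance(cmap: ContactMap) -> np.ndarray:
    """Mean contact probability per genomic separation.

    Returns an array of length ``n_loci - 1`` whose entry ``s - 1`` is the
    mean of ``P[i, i+s]`` over all valid ``i`` (separations ``s >= 1``; the
    diagonal carries no structural information and is excluded).
    """
    P = cmap.P
    n = P.shape[0]
    return np.array([np.diagonal(P, offset=s).mean() for s in range(1, n)])


# ---------------------------------------------------------------------------
# Enhanced contacts (observed / expected) at coarse resolution


def enhanced_contacts(cmap: ContactMap, coarse_resolution_kb: float = 1000.0) -> EnhancedMap:
    """Observed/expected contact enhancement, log2 scale, at coarse bins.

    ``P_obs[I, J]`` sums the fine-scale probabilities inside the I x J coarse
    block (fine diagonal excluded); ``P_exp`` is the coarse-distance
    expectation of ``P_obs``.  Invariant under global rescaling of the input.
    """
    factor_f = coarse_resolution_kb / cmap.region.resolution_kb
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"coarse resolution {coarse_resolution_kb} kb is not an integer "
            f"multiple of the map resolution {cmap.region.resolution_kb} kb"
        )
    P = cmap.P.copy()
    np.fill_diagonal(P, 0.0)
    n = P.shape[0]
    n_coarse = int(math.ceil(n / factor))
    obs = np.zeros((n_coarse, n_coarse))
    for I in range(n_coarse):
        rows = slice(I * factor, min((I + 1) * factor, n))
        for J in range(I, n_coarse):
            cols = slice(J * factor, min((J + 1) * factor, n))
            obs[I, J] = obs[J, I] = P[rows, cols].sum()

    # coarse-scale expectation, including s = 0 so a pure distance-decay map
    # yields log-ratio 0 everywhere it is defined
    exp_by_s = np.array(
        [np.diagonal(obs, offset=s).mean() for s in range(n_coarse)]
    )
    S = np.abs(np.subtract.outer(np.arange(n_coarse), np.arange(n_coarse)))
    exp = exp_by_s[S]
    defined = (obs > 0) & (exp > 0)
    matrix = np.full((n_coarse, n_coarse), np.nan)
    matrix[defined] = np.log2(obs[defined] / exp[defined])
    return EnhancedMap(matrix, defined, cmap.region.coarsened(coarse_resolution_kb))


# ---------------------------------------------------------------------------
# Insulation score and TAD boundaries


def insulation_profile(cmap: ContactMap, window_kb: float = 500.0) -> InsulationProfile:
    """Sliding-window insulation score (Crane-style), log2 vs chromosome mean.

    The raw score at locus ``i`` is the mean contact probability over the
    ``w x w`` block of pairs straddling ``i`` (rows ``i-w..i-1``, columns
    ``i+1..i+w`` with ``w = window / resolution``); dips mark TAD boundaries.
    """
    w_f = window_kb / cmap.region.resolution_kb
    w = int(round(w_f))
    if abs(w_f - w) > 1e-9 or w < 1:
        raise ValueError(
            f"window {window_kb} kb is not a positive integer multiple of the "
            f"resolution {cmap.region.resolution_kb} kb"
        )
    P = cmap.P
    n = P.shape[0]
    if n <= 2 * w:
        raise ValueError(f"window of {w} loci too large for a {n}-locus map")
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        raw[i] = P[i - w : i, i + 1 : i + w + 1].mean()
    interior = np.isfinite(raw)
    mean_raw = raw[interior].mean()
    defined = interior & (raw > 0) & (mean_raw > 0)
    scores = np.full(n, np.nan)
    if mean_raw > 0:
        scores[defined] = np.log2(raw[defined] / mean_raw)
    return InsulationProfile(scores, window_kb, defined)


def tad_boundaries(
    profile: InsulationProfile, strength_threshold: float = 0.1
) -> list[int]:
    """Loci at local insulation minima whose boundary strength clears the threshold.

    Boundary strength is the mean of the flanking local maxima minus the
    minimum value (one-sided near the profile ends).  Returned sorted by
    position; an empty list is a valid result.
    """
    idx = np.flatnonzero(profile.defined)
    if idx.size < 3:
        return []
    y = profile.scores[idx]
    m = y.size

    def _extrema(sign: float) -> list[int]:
        # plateau-tolerant: a run of equal values strictly better than its
        # differing neighbours on both sides counts once, at its centre
        out = []
        k = 0
        while k < m:
            end = k
            while end + 1 < m and y[end + 1] == y[k]:
                end += 1
            interior = k > 0 and end < m - 1
            if interior and sign * y[k] < sign * y[k - 1] \
                    and sign * y[k] < sign * y[end + 1]:
                out.append((k + end) // 2)
            k = end + 1
        return out

    minima = _extrema(+1.0)
    maxima = _extrema(-1.0)
    out: list[int] = []
    for k in minima:
        left_max = [y[j] for j in maxima if j < k]
        right_max = [y[j] for j in maxima if j > k]
        flank: list[float] = []
        if left_max:
            flank.append(left_max[-1])
        else:
            flank.append(float(y[:k].max()))
        if right_max:
            flank.append(right_max[0])
        else:
            flank.append(float(y[k + 1 :].max()))
        strength = float(np.mean(flank)) - float(y[k])
        if strength >= strength_threshold:
            out.append(int(idx[k]))
    return sorted(out)


# ---------------------------------------------------------------------------
# Compartment profile


def compartment_profile(emap: EnhancedMap) -> CompartmentProfile:
    """First principal axis of the enhanced map: the A/B compartment signal.

    Coarse bins are the observations; undefined entries are imputed to 0 for
    the decomposition.  The loading vector has unit norm and a deterministic
    sign: the bin class with higher mean short-range enhanced contact
    (|I - J| <= 1 within class) is oriented positive.
    """
    if int(emap.defined.any(axis=1).sum()) < 3:
        raise ValueError("need at least 3 defined rows for a compartment profile")
    X = np.where(emap.defined, emap.matrix, 0.0)
    if not np.any(X):
        raise ValueError("degenerate (all-zero) enhanced map")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("degenerate (rank-0) enhanced map")
    # PC1 of bins-as-observations = leading right singular vector
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    v = vt[0]
    v = v / np.linalg.norm(v)

    def _class_density(sign: int) -> float:
        members = np.flatnonzero(np.sign(v) == sign)
        if members.size == 0:
            return -np.inf
        vals = []
        for i in members:
            for j in members:
                if abs(i - j) <= 1:
                    vals.append(X[i, j])
        return float(np.mean(vals)) if vals else -np.inf

    if _class_density(-1) > _class_density(+1):
        v = -v
    elif _class_density(-1) == _class_density(+1) and v[np.argmax(np.abs(v))] < 0:
        v = -v
    return CompartmentProfile(v)
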