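"""Microstate segmentation: GFP, peak picking, polarity-invariant modified
K-means with a global-explained-variance (GEV) criterion, canonical A-D
labeling, and backfitting to a per-sample label sequence.

Conventions
-----------
* Topographic maps are average-referenced (zero channel mean); templates
  additionally have unit Euclidean norm.
* All comparisons between maps are polarity invariant: spontaneous EEG
  topographies are meaningful only up to sign, so similarity is absolute
  (or squared) spatial correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GFPSeries",
    "PeakSet",
    "TemplateSet",
    "Segmentation",
    "compute_gfp",
    "detect_gfp_peaks",
    "spatial_correlation",
    "extract_peak_maps",
    "concatenate_peaks",
    "modified_kmeans",
    "compute_gev",
    "assign_canonical_labels",
    "backfit_labels",
]


@dataclass
class GFPSeries:
    """Per-sample global field power, in microvolts."""

    values: np.ndarray = field(repr=False)
    fs: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("GFP values must be nonnegative")


@dataclass
class PeakSet:
    """Topographies at GFP local maxima.

    ``maps`` is ``(n_peaks, n_channels)`` with zero channel mean per row;
    ``gfp`` holds the peak GFP values, ``indices`` the sample positions
    (meaningful within a single epoch; pooled sets keep them for
    provenance only).
    """

    indices: np.ndarray
    maps: np.ndarray = field(repr=False)
    gfp: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.maps = np.asarray(self.maps, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if self.maps.ndim != 2 or len(self.maps) != len(self.indices):
            raise ValueError("maps must be (n_peaks, n_channels)")
        self.maps = self.maps - self.maps.mean(axis=1, keepdims=True)

    @property
    def n_peaks(self) -> int:
        return len(self.indices)


@dataclass
class TemplateSet:
    """K unit-norm, average-referenced microstate templates."""

    maps: np.ndarray = field(repr=False)  # (K, n_channels)
    labels: tuple[str, ...] = ()
    gev: float = float("nan")
    n_restarts: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.maps = self.maps - self.maps.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(norms == 0):
            raise ValueError("templates must be non-constant")
        self.maps = self.maps / norms[:, None]
        if not self.labels:
            self.labels = tuple(f"M{i + 1}" for i in range(len(self.maps)))
        if len(self.labels) != len(self.maps):
            raise ValueError("one label per template required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("template labels must be unique")

    @property
    def k(self) -> int:
        return len(self.maps)


@dataclass
class Segmentation:
    """Backfitting result for one epoch."""

    sample_labels: np.ndarray = field(repr=False)  # int index per sample
    peak_indices: np.ndarray = field(repr=False)
    peak_labels: np.ndarray = field(repr=False)
    peak_correlations: np.ndarray = field(repr=False)  # absolute |r|
    gev: float
    labels: tuple[str, ...]  # template label alphabet

    def letter_labels(self) -> np.ndarray:
        return np.array(self.labels)[self.sample_labels]


def compute_gfp(frames: np.ndarray) -> np.ndarray | float:
    """Global field power: spatial RMS about the channel mean.

    ``GFP(t) = sqrt( sum_i (V_i(t) - Vmean(t))^2 / N )``.

    Accepts a single channels-long vector or a ``(channels, samples)``
    array; returns a scalar or a per-sample array accordingly.
    """
    a = np.asarray(frames, dtype=float)
    scalar = a.ndim == 1
    if scalar:
        a = a[:, None]
    if a.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    dev = a - a.mean(axis=0, keepdims=True)
    g = np.sqrt(np.mean(dev**2, axis=0))
    return float(g[0]) if scalar else g


def detect_gfp_peaks(gfp: np.ndarray | GFPSeries) -> np.ndarray:
    """Indices of local maxima of the GFP curve.

    A sample ``i`` is a peak when ``g[i-1] < g[i] >= g[i+1]``; the first
    sample of a flat plateau gets the credit, and the series endpoints are
    never peaks.
    """
    g = gfp.values if isinstance(gfp, GFPSeries) else np.asarray(gfp, dtype=float)
    if g.size < 3:
        raise ValueError("need at least 3 samples to detect peaks")
    inner = (g[1:-1] > g[:-2]) & (g[1:-1] >= g[2:])
    return np.flatnonzero(inner) + 1


def _center_normalize(maps: np.ndarray) -> np.ndarray:
    m = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant map has no topography")
    return m / norms


def spatial_correlation(
    map1: np.ndarray, map2: np.ndarray, polarity_invariant: bool = True
) -> float:
    """Pearson correlation across channels of two average-referenced maps.

    With ``polarity_invariant`` (the default for spontaneous EEG) the
    absolute value is returned.
    """
    a = np.asarray(map1, dtype=float)
    b = np.asarray(map2, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("maps must share a channel count >= 3")
    r = float(_center_normalize(a[None, :])[0] @ _center_normalize(b[None, :])[0])
    r = max(-1.0, min(1.0, r))
    return abs(r) if polarity_invariant else r


def _corr_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """(n_maps, K) signed spatial correlations."""
    return np.clip(
        _center_normalize(maps) @ _center_normalize(templates).T, -1.0, 1.0
    )


def extract_peak_maps(data: np.ndarray, fs: float = 0.0) -> PeakSet:
    """GFP-peak topographies of one ``(channels, samples)`` epoch."""
    g = compute_gfp(data)
    idx = detect_gfp_peaks(g)
    return PeakSet(indices=idx, maps=data[:, idx].T, gfp=g[idx])


def concatenate_peaks(peak_sets: list[PeakSet]) -> PeakSet:
    """Pool peaks across epochs/subjects into one clustering substrate."""
    if not peak_sets:
        raise ValueError("no peak sets to concatenate")
    return PeakSet(
        indices=np.concatenate([p.indices for p in peak_sets]),
        maps=np.vstack([p.maps for p in peak_sets]),
        gfp=np.concatenate([p.gfp for p in peak_sets]),
    )


def compute_gev(
    peaks: PeakSet, assignments: np.ndarray, templates: TemplateSet | np.ndarray
) -> float:
    """GFP-weighted fraction of topographic variance explained.

    ``GEV = sum_t (GFP_t * r_t)^2 / sum_t GFP_t^2`` where ``r_t`` is the
    spatial correlation between peak map ``t`` and its assigned template.
    """
    tmaps = templates.maps if isinstance(templates, TemplateSet) else np.asarray(templates)
    assignments = np.asarray(assignments, dtype=int)
    if assignments.shape != (peaks.n_peaks,):
        raise ValueError("one assignment per peak required")
    corr = _corr_matrix(peaks.maps, tmaps)
    r = corr[np.arange(peaks.n_peaks), assignments]
    denom = float(np.sum(peaks.gfp**2))
    if denom == 0:
        return 0.0
    return float(np.sum((peaks.gfp * r) ** 2) / denom)


def _principal_map(maps: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of the outer-product sum of (centered) maps.

    Using the raw (not GFP-normalized) maps weights each peak by its
    squared GFP, which is exactly the weighting under which the
    assignment/update alternation monotonically increases GEV.
    """
    cov = maps.T @ maps
    _, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    v = v - v.mean()
    v = v / np.linalg.norm(v)
    # deterministic sign: strongest channel positive
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v


def modified_kmeans(
    peaks: PeakSet,
    k: int = 4,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | None = 0,
) -> tuple[TemplateSet, np.ndarray]:
    """Polarity-invariant modified K-means over GFP-peak topographies.

    Each peak map is assigned to the template with maximal squared spatial
    correlation; each template is then replaced by the principal
    eigenvector of the outer-product sum of its assigned maps. Iteration
    stops when the relative GEV change falls below ``tol`` or after
    ``max_iter`` sweeps. The procedure restarts ``n_restarts`` times from
    random peak maps and the restart with the highest GEV wins; everything
    is deterministic given ``seed``.

    Returns the winning :class:`TemplateSet` (generic labels ``M1..Mk``;
    see :func:`assign_canonical_labels`) and the per-peak assignments.
    """
    if peaks.n_peaks < k:
        raise ValueError(f"need at least k={k} peaks, got {peaks.n_peaks}")
    rng = np.random.default_rng(seed)
    maps = peaks.maps
    denom = float(np.sum(peaks.gfp**2))

    best_gev = -1.0
    best_templates = None
    best_assign = None
    for _ in range(n_restarts):
        init = rng.choice(peaks.n_peaks, size=k, replace=False)
        templates = _center_normalize(maps[init])
        prev_gev = -np.inf
        assign = None
        for _ in range(max_iter):
            corr = _corr_matrix(maps, templates)
            assign = np.argmax(corr**2, axis=1)
            # re-seed empty clusters from the worst-explained peak
            for j in range(k):
                if not np.any(assign == j):
                    best_r2 = np.max(corr**2, axis=1)
                    worst = int(np.argmin(best_r2))
                    templates[j] = _center_normalize(maps[[worst]])[0]
                    assign[worst] = j
            for j in range(k):
                members = maps[assign == j]
                if len(members):
                    templates[j] = _principal_map(members)
            corr = _corr_matrix(maps, templates)
            assign = np.argmax(corr**2, axis=1)
            r = corr[np.arange(peaks.n_peaks), assign]
            gev = float(np.sum((peaks.gfp * r) ** 2) / denom) if denom else 0.0
            if abs(gev - prev_gev) < tol * max(abs(gev), 1e-12):
                prev_gev = gev
                break
            prev_gev = gev
        if prev_gev > best_gev:
            best_gev = prev_gev
            best_templates = templates.copy()
            best_assign = assign.copy()

    ts = TemplateSet(
        maps=best_templates, gev=best_gev, n_restarts=n_restarts, seed=seed
    )
    return ts, best_assign


def assign_canonical_labels(
    templates: TemplateSet, canon: np.ndarray, labels: tuple[str, ...] = ("A", "B", "C", "D")
) -> TemplateSet:
    """Relabel templates A-D by best match to four canonical maps.

    All 24 permutations are scored by the summed absolute spatial
    correlation to the canonical maps; the winning permutation (first in
    lexicographic order on ties) determines the ordering. The returned
    TemplateSet has its rows reordered so row ``i`` carries ``labels[i]``.
    """
    canon = np.asarray(canon, dtype=float)
    if templates.k != 4 or canon.shape[0] != 4:
        raise ValueError("canonical labeling is defined for K = 4")
    if canon.shape[1] != templates.maps.shape[1]:
        raise ValueError("canonical maps are on a different montage")
    corr = np.abs(_corr_matrix(canon, templates.maps))  # (4 canon, 4 templ)
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(4)):
        score = sum(corr[i, perm[i]] for i in range(4))
        if score > best_score + 1e-15:
            best_score, best_perm = score, perm
    order = np.array(best_perm)
    return TemplateSet(
        maps=templates.maps[order], labels=tuple(labels),
        gev=templates.gev, n_restarts=templates.n_restarts,
        seed=templates.seed,
    )


def backfit_labels(epoch: np.ndarray, templates: TemplateSet) -> Segmentation:
    """Label every sample of a preprocessed epoch via its GFP peaks.

    Each GFP peak is labeled by maximal absolute spatial correlation with
    the templates; every other sample inherits the label of its nearest
    peak (the boundary between consecutive peaks sits at their midpoint,
    with the earlier peak keeping the midpoint sample; leading/trailing
    samples take the first/last peak's label).
    """
    epoch = np.asarray(epoch, dtype=float)
    g = compute_gfp(epoch)
    peak_idx = detect_gfp_peaks(g)
    if peak_idx.size == 0:
        raise ValueError("epoch has no GFP peaks")
    peak_maps = epoch[:, peak_idx].T
    corr = np.abs(_corr_matrix(peak_maps, templates.maps))
    peak_labels = np.argmax(corr, axis=1)
    peak_r = corr[np.arange(len(peak_idx)), peak_labels]

    n = epoch.shape[1]
    sample_labels = np.empty(n, dtype=np.int32)
    bounds = [0]
    for a, b in zip(peak_idx[:-1], peak_idx[1:]):
        bounds.append((a + b) // 2 + 1)  # midpoint sample stays with peak a
    bounds.append(n)
    for i in range(len(peak_idx)):
        sample_labels[bounds[i] : bounds[i + 1]] = peak_labels[i]

    peaks = PeakSet(indices=peak_idx, maps=peak_maps, gfp=g[peak_idx])
    gev = compute_gev(peaks, peak_labels, templates)
    return Segmentation(
        sample_labels=sample_labels, peak_indices=peak_idx,
        peak_labels=peak_labels, peak_correlations=peak_r,
        gev=gev, labels=templates.labels,
    )
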