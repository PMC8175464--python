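"""Sample-level morphometry of skeleton networks.

The quantities mirror how traced vessel networks are summarized in
microvascular studies:

* the *diameter distribution* — the fraction of total traced length whose
  local outer diameter falls into each 0.4 µm bin;
* a *capillary* classification — unbranched segments whose length-weighted
  mean outer diameter is below 15 µm;
* length-weighted means of diameter, curvature and torsion, with standard
  errors from the ratio-variance (Cochran ratio-estimator) approximation,
  which treats both the weighted sum and the total weight as random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .geometry import PathGeometry, path_geometry
from .io import SkeletonGraph, UnbranchedPath, decompose_paths

__all__ = [
    "MorphometryConfig",
    "DiameterDistribution",
    "SampleSummary",
    "weighted_mean",
    "diameter_distribution",
    "classify_capillaries",
    "summarize_sample",
]

#: Defaults used throughout: 0.4 µm diameter bins, <15 µm capillary rule,
#: 1.0 µm resampling step (near the µm-scale resolution of the source images).
DEFAULT_BIN_WIDTH_UM = 0.4
DEFAULT_CAPILLARY_THRESHOLD_UM = 15.0
DEFAULT_RESAMPLE_STEP_UM = 1.0


@dataclass(frozen=True)
class MorphometryConfig:
    """Parameters of the morphometry pipeline (all lengths in µm)."""

    bin_width_um: float = DEFAULT_BIN_WIDTH_UM
    capillary_threshold_um: float = DEFAULT_CAPILLARY_THRESHOLD_UM
    resample_step_um: float | None = DEFAULT_RESAMPLE_STEP_UM
    smoothing_window_um: float = 0.0
    #: bin local (per-point) diameters; False bins each path at its mean diameter
    local_diameters: bool = True

    def __post_init__(self):
        if self.bin_width_um <= 0:
            raise ParameterError("bin_width_um must be > 0")
        if self.capillary_threshold_um <= 0:
            raise ParameterError("capillary_threshold_um must be > 0")
        if self.resample_step_um is not None and self.resample_step_um <= 0:
            raise ParameterError("resample_step_um must be > 0 or None")
        if self.smoothing_window_um < 0:
            raise ParameterError("smoothing_window_um must be >= 0")


def weighted_mean(values, weights) -> tuple[float, float]:
    """Length-weighted mean with its ratio-variance standard error.

    The mean is Σwᵢxᵢ/Σwᵢ.  Its standard error follows the ratio-estimator
    (ratio variance) approximation, in which both numerator and denominator
    are treated as random:

        SE² = n/((n−1)(Σw)²) · [ Σ(wᵢxᵢ − w̄·x̄_w)²
                                 − 2·x̄_w·Σ(wᵢ−w̄)(wᵢxᵢ − w̄·x̄_w)
                                 + x̄_w²·Σ(wᵢ−w̄)² ]

    with w̄ the mean weight and x̄_w the weighted mean.  With equal weights
    this reduces exactly to the classical s/√n.  For a single observation
    the mean is returned with SE = NaN (flagged undefined).
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1:
        raise ParameterError("values and weights must be 1-D of equal length")
    if np.any(w < 0):
        raise ParameterError("weights must be non-negative")
    sw = w.sum()
    if sw <= 0:
        raise InsufficientDataError("total weight is zero; mean undefined")
    n = len(x)
    mean = float(np.dot(w, x) / sw)
    if n == 1:
        return mean, float("nan")
    wx = w * x
    w_bar = w.mean()
    d_wx = wx - w_bar * mean
    d_w = w - w_bar
    s2 = (n / ((n - 1) * sw ** 2)) * (
        np.dot(d_wx, d_wx) - 2.0 * mean * np.dot(d_w, d_wx)
        + mean ** 2 * np.dot(d_w, d_w))
    return mean, float(math.sqrt(max(s2, 0.0)))


@dataclass
class DiameterDistribution:
    """Length-fraction histogram of local outer diameters.

    ``bin_edges`` are uniform, half-open ``[lo, hi)`` bins starting at 0;
    ``length_um[k]`` is the traced length whose diameter falls in bin k and
    sums to ``total_length_um``; ``fraction`` divides by the total (NaN when
    the distribution is empty — flagged by ``empty``).
    """

    bin_edges: np.ndarray
    length_um: np.ndarray

    @property
    def total_length_um(self) -> float:
        return float(self.length_um.sum())

    @property
    def empty(self) -> bool:
        return self.total_length_um == 0.0

    @property
    def fraction(self) -> np.ndarray:
        total = self.total_length_um
        if total == 0:
            return np.full_like(self.length_um, np.nan)
        return self.length_um / total

    @property
    def peak_bin_um(self) -> float:
        """Lower edge of the modal bin (NaN for an empty distribution)."""
        if self.empty:
            return float("nan")
        return float(self.bin_edges[int(np.argmax(self.length_um))])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "bin_lo_um": self.bin_edges[:-1],
            "bin_hi_um": self.bin_edges[1:],
            "length_um": self.length_um,
            "fraction": self.fraction,
        })


def diameter_distribution(geometries: list[PathGeometry],
                          bin_width: float = DEFAULT_BIN_WIDTH_UM,
                          local_diameters: bool = True) -> DiameterDistribution:
    """Length-fraction diameter distribution over a set of paths.

    Each point's arc-length weight accrues to the half-open bin containing
    its local outer diameter; with ``local_diameters=False`` every point of
    a path is binned at the path's length-weighted mean diameter instead.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    diam_parts, weight_parts = [], []
    for g in geometries:
        w = g.weights
        d = g.diameters if local_diameters else np.full(len(w), g.mean_diameter)
        diam_parts.append(d)
        weight_parts.append(w)
    if diam_parts:
        d = np.concatenate(diam_parts)
        w = np.concatenate(weight_parts)
    else:
        d = np.zeros(0)
        w = np.zeros(0)
    n_bins = max(1, int(np.max(d) // bin_width) + 2 if len(d) else 1)
    edges = np.arange(n_bins + 1) * bin_width
    # half-open [lo, hi) bins with edge values assigned upward
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    length = np.zeros(n_bins)
    np.add.at(length, idx, w)
    return DiameterDistribution(bin_edges=edges, length_um=length)


def classify_capillaries(geometries: list[PathGeometry],
                         threshold: float = DEFAULT_CAPILLARY_THRESHOLD_UM
                         ) -> tuple[list[PathGeometry], list[PathGeometry]]:
    """Partition paths into (capillary, non-capillary).

    A path is a capillary iff its length-weighted mean outer diameter is
    strictly below ``threshold`` (µm).
    """
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    capillary = [g for g in geometries if g.mean_diameter < threshold]
    other = [g for g in geometries if not (g.mean_diameter < threshold)]
    return capillary, other


def _aggregate(geometries: list[PathGeometry], attr: str, wattr: str
               ) -> tuple[float, float]:
    values = np.concatenate([getattr(g, attr) for g in geometries]) \
        if geometries else np.zeros(0)
    weights = np.concatenate([getattr(g, wattr) for g in geometries]) \
        if geometries else np.zeros(0)
    keep = weights > 0
    if not np.any(keep):
        return float("nan"), float("nan")
    return weighted_mean(values[keep], weights[keep])


@dataclass
class SampleSummary:
    """Length-weighted summary of one traced sample (one network)."""

    sample_id: str
    area: str
    group: str
    kind: str
    n_paths: int
    n_capillary_paths: int
    total_length_um: float          # sum of raw edge lengths
    capillary_length_um: float      # arc length of capillary paths (resampled)
    mean_diameter_um: float
    se_diameter_um: float
    peak_diameter_bin_um: float
    mean_capillary_diameter_um: float
    se_capillary_diameter_um: float
    mean_capillary_curvature: float       # µm⁻¹
    se_capillary_curvature: float
    mean_capillary_torsion: float         # µm⁻¹, signed
    se_capillary_torsion: float
    mean_capillary_abs_torsion: float     # µm⁻¹

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_sample(graph: SkeletonGraph,
                     config: MorphometryConfig | None = None) -> SampleSummary:
    """Run the whole morphometry pipeline on one skeleton network.

    Decomposes the network into unbranched segments, resamples each,
    computes diameter/curvature/torsion profiles, classifies capillaries by
    the mean-diameter rule, and aggregates length-weighted statistics.
    Total length is computed on the raw (unresampled) edges.  When the
    network has no capillary segments the capillary fields are NaN, not 0.
    """
    config = config or MorphometryConfig()
    graph.merge_zero_length_edges()
    if graph.n_edges == 0:
        raise InsufficientDataError("graph has no edges after cleanup")
    paths = decompose_paths(graph)
    geometries = []
    for p in paths:
        if len(p) < 2 and not p.closed:
            continue
        geometries.append(path_geometry(
            p.points(graph), p.radii(graph), closed=p.closed,
            resample_step=config.resample_step_um,
            smoothing_window=config.smoothing_window_um))

    dist = diameter_distribution(geometries, config.bin_width_um,
                                 local_diameters=config.local_diameters)
    capillary, _ = classify_capillaries(geometries, config.capillary_threshold_um)

    mean_d, se_d = _aggregate(geometries, "diameters", "weights")
    mean_cd, se_cd = _aggregate(capillary, "diameters", "weights")
    mean_ck, se_ck = _aggregate(capillary, "curvature", "curvature_weights")
    mean_ct, se_ct = _aggregate(capillary, "torsion", "torsion_weights")
    if capillary:
        abs_geoms = [g for g in capillary]
        tau_abs = np.concatenate([np.abs(g.torsion) for g in abs_geoms]) \
            if abs_geoms else np.zeros(0)
        tau_w = np.concatenate([g.torsion_weights for g in abs_geoms]) \
            if abs_geoms else np.zeros(0)
        keep = tau_w > 0
        mean_cat = weighted_mean(tau_abs[keep], tau_w[keep])[0] if np.any(keep) \
            else float("nan")
    else:
        mean_cat = float("nan")

    meta = graph.metadata
    return SampleSummary(
        sample_id=str(meta.get("sample_id", "")),
        area=str(meta.get("area", "")),
        group=str(meta.get("group", "")),
        kind=str(meta.get("kind", "vessel")),
        n_paths=len(geometries),
        n_capillary_paths=len(capillary),
        total_length_um=graph.total_length(),
        capillary_length_um=float(sum(g.arc_length for g in capillary))
        if capillary else float("nan"),
        mean_diameter_um=mean_d,
        se_diameter_um=se_d,
        peak_diameter_bin_um=dist.peak_bin_um,
        mean_capillary_diameter_um=mean_cd,
        se_capillary_diameter_um=se_cd,
        mean_capillary_curvature=mean_ck,
        se_capillary_curvature=se_ck,
        mean_capillary_torsion=mean_ct,
        se_capillary_torsion=se_ct,
        mean_capillary_abs_torsion=mean_cat,
    )
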