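"""Synthetic skeleton networks and cohorts with known ground truth.

Traced capillary datasets of the kind this package analyses are rarely
released, so validation relies on generated inputs with analytically or
statistically known answers:

* **Analytic fixtures** — circles and helices, whose curvature and torsion
  have closed forms (κ = r/(r²+c²), τ = c/(r²+c²) for a helix of radius r
  and pitch parameter c; a circle is the c = 0 case).
* **Tortuous networks** — correlated random walks emulating Golgi-stained
  capillary beds: step directions are drawn from a von Mises–Fisher
  distribution around the previous direction, so a single concentration
  ("persistence") parameter controls the realized mean curvature; diameters
  follow a log-normal law (median 8 µm, σ_log 0.1) peaking in the 7–9 µm
  capillary range; the azimuth of each turn is uniform by default, which
  makes the walk achiral (zero-mean torsion).
* **Cohorts** — paired capillary/neurite per-sample tables with a planted
  monotone association between neurite curvature and capillary curvature
  and with capillary diameter independent of neurite thickness, mirroring
  the qualitative structure of the case/control study design
  (8 cases × 2 brain areas).

The persistence → curvature mapping depends on the step length and is
calibrated empirically; a pre-computed sweep table ships with the package
(see :func:`persistence_curvature_sweep`, :func:`persistence_for_curvature`).

All randomness flows through one :class:`numpy.random.Generator` seeded
from the spec, so identical specs produce identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import SkeletonGraph, SkeletonNode

__all__ = [
    "GeneratorSpec",
    "CohortSpec",
    "HelixFixture",
    "make_helix",
    "make_circle_graph",
    "make_tortuous_network",
    "make_cohort",
    "persistence_curvature_sweep",
    "persistence_for_curvature",
]

_SWEEP_RESOURCE = "_persistence_sweep.json"


# ---------------------------------------------------------------------------
# Analytic fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixFixture:
    """A sampled helix with its exact differential-geometry ground truth."""

    points: np.ndarray
    radii: np.ndarray
    kappa_true: float   # µm⁻¹
    tau_true: float     # µm⁻¹ (signed; 0 for a circle)

    def to_graph(self, sample_id: str = "helix") -> SkeletonGraph:
        g = SkeletonGraph(metadata={"sample_id": sample_id, "kind": "vessel"})
        for i, (p, r) in enumerate(zip(self.points, self.radii), start=1):
            g.add_node(SkeletonNode(i, p, r))
            if i > 1:
                g.add_edge(i - 1, i)
        return g


def make_helix(radius: float, pitch_param: float, n_points: int,
               step: float = 1.0, tube_radius: float = 4.0) -> HelixFixture:
    """Sample a helix x = r·cos t, y = r·sin t, z = c·t at uniform arc steps.

    Ground truth: κ = r/(r²+c²), τ = c/(r²+c²).  ``pitch_param`` c = 0
    yields a circle (κ = 1/r, τ = 0); negative c gives a left-handed helix
    with negative torsion.
    """
    if radius <= 0:
        raise ParameterError("helix radius must be > 0")
    if n_points < 4:
        raise ParameterError("need at least 4 points")
    r, c = float(radius), float(pitch_param)
    dt = step / math.hypot(r, c)
    t = np.arange(n_points) * dt
    points = np.column_stack([r * np.cos(t), r * np.sin(t), c * t])
    radii = np.full(n_points, float(tube_radius))
    denom = r * r + c * c
    return HelixFixture(points=points, radii=radii,
                        kappa_true=r / denom, tau_true=c / denom)


def make_circle_graph(radius: float, step: float = 1.0, diameter: float = 8.0,
                      sample_id: str = "circle", **metadata) -> SkeletonGraph:
    """A closed circular loop of given radius, sampled at ~``step`` µm arcs.

    The returned network is a single isolated cycle with uniform outer
    diameter; summarizing it must recover mean curvature 1/radius and zero
    torsion.  Used as the curvature↔radius reciprocity fixture.
    """
    if radius <= 0 or step <= 0 or diameter <= 0:
        raise ParameterError("radius, step and diameter must be > 0")
    n = max(4, int(round(2 * math.pi * radius / step)))
    theta = 2 * math.pi * np.arange(n) / n
    g = SkeletonGraph(metadata={"sample_id": sample_id, "kind": "vessel",
                                **metadata})
    for i in range(n):
        pos = np.array([radius * math.cos(theta[i]),
                        radius * math.sin(theta[i]), 0.0])
        g.add_node(SkeletonNode(i + 1, pos, diameter / 2.0))
        if i:
            g.add_edge(i, i + 1)
    g.add_edge(n, 1)
    return g


# ---------------------------------------------------------------------------
# Correlated-random-walk networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the tortuous-network generator (lengths in µm).

    ``persistence`` is the von Mises–Fisher concentration of each step
    direction about the previous one; higher persistence → straighter paths
    (realized mean curvature is monotone decreasing in it).  Setting
    ``target_mean_curvature`` instead derives the persistence from the
    calibration sweep.  ``torsion_bias`` = 0 makes the walk achiral; a
    nonzero value drifts the turn azimuth, planting handedness of the
    corresponding sign.
    """

    seed: int = 0
    n_paths: int = 40
    mean_path_length_um: float = 150.0
    step_um: float = 1.0
    persistence: float | None = None
    target_mean_curvature: float | None = 0.03   # µm⁻¹
    diameter_median_um: float = 8.0
    diameter_sigma_log: float = 0.1
    taper_amplitude: float = 0.05
    branch_probability: float = 0.1
    torsion_bias: float = 0.0        # rad per step of azimuth drift
    box_size_um: float = 300.0

    def __post_init__(self):
        for name in ("mean_path_length_um", "step_um", "diameter_median_um",
                     "box_size_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.n_paths < 0:
            raise ParameterError("n_paths must be >= 0")
        if self.diameter_sigma_log < 0 or self.taper_amplitude < 0:
            raise ParameterError("diameter_sigma_log and taper_amplitude must be >= 0")
        if not (0 <= self.branch_probability <= 1):
            raise ParameterError("branch_probability must be in [0, 1]")
        if self.persistence is None and self.target_mean_curvature is None:
            raise ParameterError(
                "one of persistence / target_mean_curvature is required")
        if self.persistence is not None and self.persistence <= 0:
            raise ParameterError("persistence must be > 0")


def _sample_vmf_cos(rng: np.random.Generator, kappa: float, size: int) -> np.ndarray:
    """cos(θ) of deviations from the mean direction, vMF on the sphere."""
    u = rng.random(size)
    u = np.clip(u, 1e-300, 1.0)
    # exact inverse-CDF for the vMF polar angle (numerically stable for large κ)
    expm2k = math.exp(-2.0 * kappa) if kappa < 350 else 0.0
    w = 1.0 + np.log(u + (1.0 - u) * expm2k) / kappa
    return np.clip(w, -1.0, 1.0)


def _walk_paths(rng: np.random.Generator, n_paths: int, n_steps: np.ndarray,
                kappa: float, step: float, box: float, torsion_bias: float
                ) -> list[np.ndarray]:
    """Generate correlated-random-walk centerlines, vectorized over paths."""
    if n_paths == 0:
        return []
    max_steps = int(n_steps.max())
    pos = rng.uniform(0, box, size=(n_paths, 3))
    # isotropic initial directions
    t = rng.normal(size=(n_paths, 3))
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    # initial normal frame vector perpendicular to t
    a = np.where(np.abs(t[:, [0]]) < 0.9,
                 np.tile([1.0, 0.0, 0.0], (n_paths, 1)),
                 np.tile([0.0, 1.0, 0.0], (n_paths, 1)))
    nrm = np.cross(t, a)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    phi = rng.uniform(-math.pi, math.pi, size=n_paths)

    traj = np.empty((n_paths, max_steps + 1, 3))
    traj[:, 0] = pos
    for k in range(max_steps):
        w = _sample_vmf_cos(rng, kappa, n_paths)
        sin_theta = np.sqrt(np.maximum(0.0, 1.0 - w * w))
        if torsion_bias == 0.0:
            phi = rng.uniform(-math.pi, math.pi, size=n_paths)
        else:
            phi = phi + torsion_bias + rng.normal(0.0, 0.3, size=n_paths)
        b = np.cross(t, nrm)
        t_new = (w[:, None] * t
                 + sin_theta[:, None] * (np.cos(phi)[:, None] * nrm
                                         + np.sin(phi)[:, None] * b))
        t_new /= np.linalg.norm(t_new, axis=1, keepdims=True)
        # parallel-transport the normal to the new tangent
        nrm = nrm - np.einsum("ij,ij->i", nrm, t_new)[:, None] * t_new
        bad = np.linalg.norm(nrm, axis=1) < 1e-9
        if np.any(bad):
            nrm[bad] = np.cross(t_new[bad], np.tile([1.0, 0.0, 0.0],
                                                    (int(bad.sum()), 1)))
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        t = t_new
        pos = pos + step * t
        traj[:, k + 1] = pos
    return [traj[i, :n_steps[i] + 1] for i in range(n_paths)]


def make_tortuous_network(spec: GeneratorSpec) -> SkeletonGraph:
    """Generate a tortuous capillary-like network from a :class:`GeneratorSpec`.

    Each path is a correlated random walk with per-path log-normal diameter
    and a smooth linear taper; with probability ``branch_probability`` a
    path is rooted at an interior node of an earlier path instead of a free
    position, producing degree-3 branch points.  Bit-reproducible for a
    fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    kappa = spec.persistence if spec.persistence is not None else \
        persistence_for_curvature(spec.target_mean_curvature, spec.step_um)

    g = SkeletonGraph(metadata={"sample_id": f"synthetic-{spec.seed}",
                                "kind": "vessel",
                                "generator": "make_tortuous_network"})
    if spec.n_paths == 0:
        return g
    # path lengths: gamma with shape 3 (moderate spread, strictly positive)
    lengths = rng.gamma(3.0, spec.mean_path_length_um / 3.0, size=spec.n_paths)
    n_steps = np.maximum(3, np.round(lengths / spec.step_um).astype(int))
    trajs = _walk_paths(rng, spec.n_paths, n_steps, kappa, spec.step_um,
                        spec.box_size_um, spec.torsion_bias)

    diam = spec.diameter_median_um * np.exp(
        spec.diameter_sigma_log * rng.normal(size=spec.n_paths))
    branch_on = rng.random(spec.n_paths) < spec.branch_probability

    next_id = 1
    path_node_ids: list[list[int]] = []
    for i, pts in enumerate(trajs):
        n = len(pts)
        taper = 1.0 + spec.taper_amplitude * np.linspace(-1.0, 1.0, n) \
            * (1 if rng.random() < 0.5 else -1)
        radii = 0.5 * diam[i] * taper
        ids = []
        anchor = None
        if branch_on[i] and path_node_ids:
            host = path_node_ids[int(rng.integers(len(path_node_ids)))]
            if len(host) > 2:
                anchor = host[int(rng.integers(1, len(host) - 1))]
                # translate the walk to start at the anchor node
                pts = pts - pts[0] + g.position(anchor)
        for j in range(n):
            if j == 0 and anchor is not None:
                ids.append(anchor)
                continue
            g.add_node(SkeletonNode(next_id, pts[j], float(max(radii[j], 0.1))))
            ids.append(next_id)
            next_id += 1
        for j in range(n - 1):
            g.add_edge(ids[j], ids[j + 1])
        path_node_ids.append(ids)
    return g


# ---------------------------------------------------------------------------
# Persistence ↔ curvature calibration
# ---------------------------------------------------------------------------

def persistence_curvature_sweep(persistences=None, *, seed: int = 20210603,
                                n_paths: int = 30,
                                mean_path_length_um: float = 200.0,
                                step_um: float = 1.0) -> pd.DataFrame:
    """Measure realized mean capillary curvature across persistence values.

    Runs the full generate → summarize pipeline at each concentration and
    returns a (persistence, mean_curvature) table.  The packaged calibration
    table was produced by this function with its default arguments.
    """
    from .morphometry import MorphometryConfig, summarize_sample

    if persistences is None:
        persistences = np.geomspace(150.0, 40000.0, 14)
    rows = []
    cfg = MorphometryConfig(resample_step_um=step_um)
    for i, k in enumerate(persistences):
        spec = GeneratorSpec(seed=seed + i, n_paths=n_paths,
                             mean_path_length_um=mean_path_length_um,
                             step_um=step_um, persistence=float(k),
                             target_mean_curvature=None,
                             branch_probability=0.0)
        summary = summarize_sample(make_tortuous_network(spec), cfg)
        rows.append({"persistence": float(k),
                     "mean_curvature": summary.mean_capillary_curvature})
    return pd.DataFrame(rows)


def _load_sweep() -> pd.DataFrame:
    with resources.files("vesselmorph").joinpath(_SWEEP_RESOURCE).open() as fh:
        doc = json.load(fh)
    return pd.DataFrame(doc["table"])


def persistence_for_curvature(target: float, step_um: float = 1.0) -> float:
    """Invert the calibration sweep: concentration giving a target mean κ.

    Interpolates log-log in the packaged sweep table (measured at a 1 µm
    step).  For other step lengths the small-angle scaling κ_real ∝
    1/(step·√persistence) is applied.  Targets outside the swept range are
    extrapolated with the same power law.
    """
    if target <= 0:
        raise ParameterError("target mean curvature must be > 0")
    table = _load_sweep()
    logk = np.log(table["persistence"].to_numpy())
    logc = np.log(table["mean_curvature"].to_numpy())
    order = np.argsort(logc)
    logc, logk = logc[order], logk[order]
    # mean turn angle ≈ √(π/2κ): curvature at step s scales as 1/s for fixed κ
    target_at_unit_step = target * (step_um / 1.0)
    lt = math.log(target_at_unit_step)
    if lt <= logc[0]:
        slope = (logk[1] - logk[0]) / (logc[1] - logc[0])
        return float(math.exp(logk[0] + slope * (lt - logc[0])))
    if lt >= logc[-1]:
        slope = (logk[-1] - logk[-2]) / (logc[-1] - logc[-2])
        return float(math.exp(logk[-1] + slope * (lt - logc[-1])))
    return float(math.exp(np.interp(lt, logc, logk)))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic case/control cohort (8 cases × 2 areas default).

    The planted model: per sample×area, mean neurite curvature x is drawn
    uniformly from ``neurite_curvature_range``; the target mean capillary
    curvature is ``intercept + slope·x + ε`` with ε ~ N(0, noise_sd), and a
    network is generated whose persistence is calibrated to that target.
    Defaults plant a population Spearman correlation of ≈ 0.63 between the
    two curvatures, while capillary diameter and neurite thickness radius
    are drawn independently (no association).  ``area_spread_ratio``
    multiplies the noise SD in the first listed area, emulating a wider
    between-case variance there; 1 means equal variances.
    """

    seed: int = 0
    n_cases: int = 8
    areas: tuple[str, ...] = ("BA22", "BA24")
    slope: float = 0.02
    intercept: float = 0.005
    noise_sd: float = 0.0057
    neurite_curvature_range: tuple[float, float] = (0.8, 1.6)
    neurite_radius_mean_um: float = 0.30
    neurite_radius_sd_um: float = 0.05
    area_spread_ratio: float = 1.0
    curvature_bounds: tuple[float, float] = (0.012, 0.06)
    # network size per sample
    n_paths: int = 10
    mean_path_length_um: float = 150.0
    step_um: float = 1.0
    diameter_median_um: float = 8.0
    diameter_sigma_log: float = 0.1

    def __post_init__(self):
        if self.n_cases * len(self.areas) < 4:
            raise ParameterError("cohort needs at least 4 sample×area rows")
        if self.noise_sd < 0 or self.area_spread_ratio <= 0:
            raise ParameterError("noise_sd must be >= 0 and area_spread_ratio > 0")


def make_cohort(spec: CohortSpec, keep_graphs: bool = False
                ) -> tuple[pd.DataFrame, dict[str, SkeletonGraph]]:
    """Generate a cohort table by running the full pipeline per sample.

    Returns the cohort table (columns of
    :data:`vesselmorph.groups.COHORT_COLUMNS` plus ground-truth columns
    ``target_capillary_curvature`` and ``persistence``) and, when
    ``keep_graphs`` is true, the per-sample networks keyed by
    ``"<case>-<area>"``.
    """
    from .morphometry import MorphometryConfig, summarize_sample

    rng = np.random.default_rng(spec.seed)
    cfg = MorphometryConfig(resample_step_um=spec.step_um)
    lo, hi = spec.neurite_curvature_range
    rows = []
    graphs: dict[str, SkeletonGraph] = {}
    for case_idx in range(spec.n_cases):
        group = "schizophrenia" if case_idx < spec.n_cases // 2 else "control"
        case = f"{'S' if group == 'schizophrenia' else 'N'}{case_idx % max(1, spec.n_cases // 2) + 1}"
        for ai, area in enumerate(spec.areas):
            x = rng.uniform(lo, hi)
            sd = spec.noise_sd * (spec.area_spread_ratio if ai == 0 else 1.0)
            target = spec.intercept + spec.slope * x + rng.normal(0.0, sd)
            target = float(np.clip(target, *spec.curvature_bounds))
            k = persistence_for_curvature(target, spec.step_um)
            net_spec = GeneratorSpec(
                seed=int(rng.integers(2**31 - 1)), n_paths=spec.n_paths,
                mean_path_length_um=spec.mean_path_length_um,
                step_um=spec.step_um, persistence=k,
                target_mean_curvature=None,
                diameter_median_um=spec.diameter_median_um,
                diameter_sigma_log=spec.diameter_sigma_log,
                branch_probability=0.0)
            graph = make_tortuous_network(net_spec)
            graph.metadata.update(sample_id=f"{case}-{area}", area=area,
                                  group=group)
            summary = summarize_sample(graph, cfg)
            rows.append({
                "sample_id": f"{case}-{area}",
                "area": area,
                "group": group,
                "capillary_curvature": summary.mean_capillary_curvature,
                "capillary_diameter": summary.mean_capillary_diameter_um,
                "neurite_curvature": x,
                "neurite_radius": rng.normal(spec.neurite_radius_mean_um,
                                             spec.neurite_radius_sd_um),
                "target_capillary_curvature": target,
                "persistence": k,
            })
            if keep_graphs:
                graphs[f"{case}-{area}"] = graph
    return pd.DataFrame(rows), graphs
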