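"""Seeded generators for every input the analysis pipeline consumes.

Every generator is a pure function of its parameters and a seed: same seed,
same output.  The statistical structure matches what the analysis assumes:

* force-extension curves sampled from the WLC model with measurement noise
  on the force readout,
* extension-vs-time traces from closed-form exponential decays, piecewise
  two-regime decays, or the mechanistic condensation simulator,
* 2-D worm-like-chain backbone traces with optional inserted sharp bends and
  ~150-bp micro-loops (ground truth recorded in the trace annotations),
* hemispherical condensate height maps,
* whole synthetic study populations written to disk with a ground-truth
  manifest.

2-D chain convention: successive heading increments are independent
Gaussians with variance (segment / persistence), so the tangent correlation
decays as exp(-s / 2P) -- the operational definition of the trace's
persistence length used throughout (adsorption physics mapping 3-D chains to
the surface is out of scope; persistence-recovery tests are internal to this
convention).
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .wlc import WLCParameters, ForceExtensionCurve, wlc_extension_at_force
from .kinetics import ExtensionTimeSeries
from .afm import PolylineTrace, CondensateMap, NM_PER_BP
from .condensation import RateTable, GeometryConstants, simulate_ode

__all__ = [
    "NoiseModel",
    "gen_force_extension",
    "gen_extension_timeseries",
    "gen_trace2d",
    "insert_bend",
    "insert_microloop",
    "gen_condensate",
    "gen_population",
]


@dataclass
class NoiseModel:
    """Measurement-noise description.

    ``kind`` is "additive-gaussian" (sigma in the units of the target
    quantity) or "multiplicative-gaussian" (sigma as a fraction).
    """

    kind: str = "additive-gaussian"
    sigma: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("additive-gaussian", "multiplicative-gaussian"):
            raise ValueError(
                "kind must be 'additive-gaussian' or 'multiplicative-gaussian'")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return np.asarray(values, dtype=float).copy()
        g = rng.standard_normal(np.shape(values))
        if self.kind == "additive-gaussian":
            return values + self.sigma * g
        return values * (1.0 + self.sigma * g)


def _rng(seed: Optional[int], noise: Optional[NoiseModel] = None):
    if seed is None and noise is not None:
        seed = noise.seed
    return np.random.default_rng(seed)


def gen_force_extension(
    params: WLCParameters,
    n_points: int = 40,
    force_range_pN: tuple = (0.05, 6.0),
    noise: NoiseModel = NoiseModel(),
    seed: Optional[int] = None,
) -> ForceExtensionCurve:
    """Synthetic force-extension curve of a WLC molecule.

    Forces are log-spaced over ``force_range_pN``; extensions are the exact
    WLC inversions, and the noise model perturbs the *force* readout (the
    noisy channel in constant-extension sampling).
    """
    lo, hi = force_range_pN
    if not (0 < lo < hi <= 20):
        raise ValueError("force range must satisfy 0 < lo < hi <= 20 pN")
    if n_points < 6:
        raise ValueError("need at least 6 points")
    rng = _rng(seed, noise)
    forces = np.geomspace(lo, hi, n_points)
    ext = np.array([wlc_extension_at_force(f, params) for f in forces])
    forces_obs = np.clip(noise.apply(forces, rng), 1e-6, None)
    return ForceExtensionCurve(ext, forces_obs)


def _closed_form_series(spec: dict, t: np.ndarray) -> np.ndarray:
    plateau = float(spec.get("plateau", 0.0))
    amps = np.atleast_1d(np.asarray(spec["amplitudes"], dtype=float))
    taus = np.atleast_1d(np.asarray(spec["time_constants"], dtype=float))
    if amps.shape != taus.shape:
        raise ValueError("amplitudes and time_constants must match in length")
    if np.any(taus <= 0):
        raise ValueError("time constants must be positive")
    y = np.full_like(t, plateau)
    for A, T in zip(amps, taus):
        y = y + A * np.exp(-t / T)
    return y


def gen_extension_timeseries(
    spec: Union[dict, tuple],
    sampling_interval_min: float = 1.0,
    duration_min: float = 600.0,
    noise: NoiseModel = NoiseModel(),
    seed: Optional[int] = None,
    label: Optional[dict] = None,
) -> ExtensionTimeSeries:
    """Synthetic extension-vs-time trace.

    ``spec`` is one of

    * ``{"plateau", "amplitudes", "time_constants"}`` -- closed-form
      exponential decay (one or more components),
    * ``{"head": {...}, "tail": {"plateau", "time_constant"},
      "breakpoint_min": t*}`` -- two-regime trace: the head decay before the
      breakpoint, then a single-exponential tail whose amplitude is matched
      to the head value at the breakpoint (continuous construction),
    * ``(rates, geometry, concentration_uM, force_pN)`` -- run the
      condensation simulator and sample its extension channel.
    """
    if not duration_min > 0:
        raise ValueError("duration must be > 0")
    rng = _rng(seed, noise)
    t = np.arange(0.0, duration_min + 0.5 * sampling_interval_min,
                  sampling_interval_min)
    if isinstance(spec, tuple):
        rates, geometry, conc, force = spec
        trace = simulate_ode(rates, geometry, concentration_uM=conc,
                             force_pN=force, duration_min=duration_min,
                             step_min=sampling_interval_min)
        y = np.interp(t, trace.times_min, trace.extensions_um)
    elif "head" in spec:
        head, tail = spec["head"], spec["tail"]
        t_star = float(spec["breakpoint_min"])
        if not 0 < t_star < duration_min:
            raise ValueError("breakpoint must lie inside the duration")
        y = _closed_form_series(head, t)
        T_tail = float(tail["time_constant"])
        plateau_tail = float(tail.get("plateau", 0.0))
        L_star = float(_closed_form_series(head, np.array([t_star]))[0])
        A_tail = L_star - plateau_tail
        mask = t >= t_star
        y[mask] = plateau_tail + A_tail * np.exp(-(t[mask] - t_star) / T_tail)
    else:
        y = _closed_form_series(spec, t)
    y_obs = np.clip(noise.apply(y, rng), 1e-9, None)
    return ExtensionTimeSeries(t, y_obs, label=label)


def gen_trace2d(
    contour_nm: float = 680.0,
    persistence_nm: float = 50.0,
    segment_nm: float = 2.0,
    seed: Optional[int] = None,
) -> PolylineTrace:
    """2-D worm-like-chain backbone trace.

    Heading increments are i.i.d. Gaussian with variance
    segment/persistence; the tangent correlation of the resulting ensemble
    decays as exp(-s / 2P).  The default 680 nm contour is a 2-kb fragment
    at 0.34 nm/bp.
    """
    if segment_nm >= persistence_nm:
        raise ValueError("segment must be much smaller than persistence")
    n_seg = int(round(contour_nm / segment_nm))
    if n_seg < 2:
        raise ValueError("contour too short for the segment length")
    rng = np.random.default_rng(seed)
    increments = rng.normal(0.0, np.sqrt(segment_nm / persistence_nm), n_seg)
    increments[0] = rng.uniform(0, 2 * np.pi)  # random initial heading
    headings = np.cumsum(increments)
    steps = segment_nm * np.column_stack([np.cos(headings), np.sin(headings)])
    points = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return PolylineTrace(points, segment_nm, annotations={"bends": [],
                                                          "loops": []})


def _headings_of(trace: PolylineTrace) -> np.ndarray:
    d = np.diff(trace.points, axis=0)
    return np.arctan2(d[:, 1], d[:, 0])


def _rebuild(trace: PolylineTrace, headings: np.ndarray,
             annotations: dict) -> PolylineTrace:
    steps = trace.segment_nm * np.column_stack(
        [np.cos(headings), np.sin(headings)])
    points = np.vstack([trace.points[:1], trace.points[0] +
                        np.cumsum(steps, axis=0)])
    return PolylineTrace(points, trace.segment_nm, annotations=annotations)


def insert_bend(trace: PolylineTrace, vertex_index: int,
                angle_deg: float) -> PolylineTrace:
    """Rotate the downstream arm by ``angle_deg`` at an interior vertex.

    Contour length is conserved exactly; on an otherwise straight trace the
    deflection at the vertex equals the inserted angle.
    """
    n = len(trace)
    if not 0 < vertex_index < n - 1:
        raise ValueError("vertex_index must be interior")
    headings = _headings_of(trace)
    headings[vertex_index:] += np.radians(angle_deg)
    ann = {k: list(v) for k, v in trace.annotations.items()}
    ann.setdefault("bends", []).append((int(vertex_index), float(angle_deg)))
    ann.setdefault("loops", [])
    return _rebuild(trace, headings, ann)


def insert_microloop(trace: PolylineTrace, start_index: int,
                     loop_bp: float = 150.0) -> PolylineTrace:
    """Replace a contour span by a closed circular detour (a micro-loop).

    The span of ``loop_bp * 0.34 nm`` of contour starting at ``start_index``
    is replaced by a regular polygon with side equal to the segment length:
    the backbone turns through a full 2*pi and returns exactly to the loop
    start, after which the original downstream headings continue.  Segment
    lengths (hence total contour) are conserved; the loop start/end pair is
    the zero-distance contact the loop detector keys on.
    """
    n_loop = int(round(loop_bp * NM_PER_BP / trace.segment_nm))
    if n_loop < 3:
        raise ValueError("loop too small for the segment length")
    headings = _headings_of(trace)
    if start_index < 1 or start_index + n_loop > headings.size:
        raise ValueError("loop does not fit in the remaining contour")
    h0 = headings[start_index]
    loop_headings = h0 + 2 * np.pi * np.arange(n_loop) / n_loop
    new_headings = headings.copy()
    new_headings[start_index:start_index + n_loop] = loop_headings
    ann = {k: list(v) for k, v in trace.annotations.items()}
    actual_bp = n_loop * trace.segment_nm / NM_PER_BP
    ann.setdefault("loops", []).append((int(start_index), float(actual_bp)))
    ann.setdefault("bends", [])
    return _rebuild(trace, new_headings, ann)


def gen_condensate(
    volume_nm3: float,
    pixel_size_nm: float = 2.0,
    noise: NoiseModel = NoiseModel(),
    seed: Optional[int] = None,
) -> CondensateMap:
    """Hemispherical condensate height map of prescribed true volume.

    The hemisphere radius is r = (3V / 2 pi)^(1/3); heights are rendered on
    the pixel grid with optional additive noise (clipped at zero -- the
    substrate).  Warns when the grid is too coarse (r / pixel < 5).
    """
    if not volume_nm3 > 0:
        raise ValueError("volume must be > 0")
    r = (3.0 * volume_nm3 / (2.0 * np.pi)) ** (1.0 / 3.0)
    if r / pixel_size_nm < 5:
        import warnings
        warnings.warn("pixel size too coarse for the condensate radius "
                      "(r / pixel < 5)", RuntimeWarning, stacklevel=2)
    rng = _rng(seed, noise)
    half = int(np.ceil(r / pixel_size_nm)) + 3
    coords = (np.arange(-half, half + 1) + 0.5) * pixel_size_nm
    xx, yy = np.meshgrid(coords, coords)
    h = np.sqrt(np.maximum(r**2 - xx**2 - yy**2, 0.0))
    h_obs = np.clip(noise.apply(h, rng), 0.0, None)
    return CondensateMap(h_obs, pixel_size_nm)


# ---------------------------------------------------------------------------
# population factory

def _derive_seed(master_seed: int, counter: int) -> int:
    """Documented per-object seed scheme: (master * 1_000_003 + counter) mod 2^31."""
    return int((master_seed * 1_000_003 + counter) % 2**31)


def gen_population(recipe: dict, out_dir, overwrite: bool = False) -> dict:
    """Write a synthetic study population to disk with a ground-truth manifest.

    ``recipe`` schema::

        {"master_seed": int,
         "condensates": [{"group": str, "count": int, "mean_volume_nm3": float,
                          "cv": float, "pixel_size_nm": float}, ...],
         "traces": [{"group": str, "count": int, "contour_nm": float,
                     "persistence_nm": float, "loops_bp": [..],
                     "bends_deg": [..]}, ...],
         "curves": [{"group": str, "count": int, "persistence_nm": float,
                     "contour_um": float, "force_noise": float}, ...],
         "series": [{"group": str, "count": int, "spec": {...},
                     "duration_min": float, "noise_um": float}, ...]}

    Every object gets a seed derived from the master seed by a counter
    scheme, recorded in the manifest together with the generator parameters
    (the ground truth), so regenerating with the same master seed is
    byte-identical.  Raises ``FileExistsError`` on collision with an
    existing manifest unless ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    master = int(recipe.get("master_seed", 0))
    counter = 0
    manifest = {"master_seed": master, "objects": []}

    def fmt(x):
        return float(np.round(x, 10))

    for entry in recipe.get("condensates", []):
        group = entry.get("group", "all")
        cv = float(entry.get("cv", 0.0))
        mean_v = float(entry["mean_volume_nm3"])
        px = float(entry.get("pixel_size_nm", 2.0))
        for i in range(int(entry["count"])):
            seed = _derive_seed(master, counter); counter += 1
            rng = np.random.default_rng(seed)
            if cv > 0:
                sigma = np.sqrt(np.log(1 + cv**2))
                v = mean_v * np.exp(rng.normal(-0.5 * sigma**2, sigma))
            else:
                v = mean_v
            cmap = gen_condensate(v, pixel_size_nm=px, seed=seed + 1)
            path = out_dir / f"condensate_{group}_{i:04d}.csv"
            np.savetxt(path, cmap.heights_nm, delimiter=",", fmt="%.6g")
            manifest["objects"].append({
                "kind": "condensate", "group": group, "path": path.name,
                "seed": seed, "pixel_size_nm": px,
                "true_volume_nm3": fmt(v)})

    for entry in recipe.get("traces", []):
        group = entry.get("group", "all")
        for i in range(int(entry["count"])):
            seed = _derive_seed(master, counter); counter += 1
            tr = gen_trace2d(entry.get("contour_nm", 680.0),
                             entry.get("persistence_nm", 50.0),
                             entry.get("segment_nm", 2.0), seed=seed)
            rng = np.random.default_rng(seed + 1)
            n = len(tr)
            for bp in entry.get("loops_bp", []):
                start = int(rng.integers(n // 4, n // 2))
                tr = insert_microloop(tr, start, bp)
            for ang in entry.get("bends_deg", []):
                v = int(rng.integers(n // 4, 3 * n // 4))
                tr = insert_bend(tr, v, ang)
            path = out_dir / f"trace_{group}_{i:04d}.csv"
            np.savetxt(path, tr.points, delimiter=",", fmt="%.6g",
                       header="x_nm,y_nm")
            manifest["objects"].append({
                "kind": "trace", "group": group, "path": path.name,
                "seed": seed, "segment_nm": tr.segment_nm,
                "annotations": tr.annotations})

    for entry in recipe.get("curves", []):
        group = entry.get("group", "all")
        params = WLCParameters(entry["persistence_nm"], entry["contour_um"])
        for i in range(int(entry["count"])):
            seed = _derive_seed(master, counter); counter += 1
            curve = gen_force_extension(
                params,
                noise=NoiseModel("multiplicative-gaussian",
                                 entry.get("force_noise", 0.0)),
                seed=seed)
            path = out_dir / f"curve_{group}_{i:04d}.tsv"
            from .io import write_force_extension
            write_force_extension(path, curve)
            manifest["objects"].append({
                "kind": "curve", "group": group, "path": path.name,
                "seed": seed, "persistence_nm": entry["persistence_nm"],
                "contour_um": entry["contour_um"]})

    for entry in recipe.get("series", []):
        group = entry.get("group", "all")
        for i in range(int(entry["count"])):
            seed = _derive_seed(master, counter); counter += 1
            ts = gen_extension_timeseries(
                entry["spec"],
                duration_min=entry.get("duration_min", 600.0),
                noise=NoiseModel("additive-gaussian",
                                 entry.get("noise_um", 0.0)),
                seed=seed)
            path = out_dir / f"series_{group}_{i:04d}.tsv"
            from .io import write_timeseries
            write_timeseries(path, ts)
            manifest["objects"].append({
                "kind": "series", "group": group, "path": path.name,
                "seed": seed, "spec": entry["spec"]})

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
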