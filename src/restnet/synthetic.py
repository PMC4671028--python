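"""Synthetic cohort and reference-network generators.

The rest of the pipeline is exercised end-to-end on data produced here:
ROI time series with planted modular, small-world correlation structure
and hub nodes, motion traces with isolated displacement spikes,
reference graphs of known topology, and degree sequences drawn from the
three candidate distribution families.

Time-series model
-----------------
Each ROI series is a linear factor mixture:

* a global latent signal (amplitude calibrated so the mean
  between-module correlation hits ``between_module_r``),
* one latent signal per module (block structure, with per-node loading
  jitter so modules are dense but not uniform cliques),
* ring-harmonic latents producing a spatially graded correlation kernel
  (nearby ROIs correlate more strongly, as in spatially embedded
  cortical parcellations) — this is what gives thresholded graphs their
  lattice-plus-shortcuts small-world character,
* hub ROIs trade part of their local kernel loading for an elevated
  global loading, which makes them long-range bridges (high degree and
  betweenness at sparse thresholds),
* white noise.

Amplitudes are solved so that, at ``noise_sd = 1``, the mean Pearson
correlation is ``within_module_r`` inside modules and
``between_module_r`` across them.  ``noise_sd`` scales all
node-idiosyncratic variation (white noise, spatial gradation, loading
jitter, hub elevation): at ``noise_sd = 0`` a single-module cohort
collapses onto one shared latent and every pairwise correlation is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graphs import BinaryGraph
from .nulls import lattice_graph, scale_free_graph

__all__ = [
    "SyntheticCohortSpec",
    "MotionTrace",
    "Subject",
    "Cohort",
    "generate_cohort",
    "generate_motion",
    "generate_reference_graph",
    "generate_degree_sequence",
]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort; defaults emulate the study design.

    ``within_module_r`` / ``between_module_r`` are mean-correlation
    targets (hit at ``noise_sd = 1``).  ``spatial_weight`` is the
    fraction of the within-minus-between contrast carried by the
    ring-distance kernel rather than the module block term; at 0 the
    cohort is a pure block model ("strong within-block"), near 1 it is
    dominated by spatial gradation.
    """

    n_subjects: int = 60
    n_rois: int = 90
    n_frames: int = 196
    module_sizes: tuple[int, ...] = (26, 26, 18, 20)
    within_module_r: float = 0.29
    between_module_r: float = 0.0
    hub_fraction: float = 0.1
    noise_sd: float = 1.0
    tr_seconds: float = 2.0
    band_limited: bool = False
    # spatial-kernel shape (see module docstring)
    spatial_weight: float = 0.60
    kernel_lobe: int = 8
    kernel_tail_decay: float = 0.3
    kernel_tail_weight: float = 0.25
    n_harmonics: int = 16
    module_loading_jitter: float = 0.8
    hub_strength: float = 0.40
    hub_local_scale: float = 0.35
    motion_spike_prob: float = 0.04
    motion_spike_mm: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) != self.n_rois:
            raise ValueError(
                f"module_sizes sum {sum(self.module_sizes)} != n_rois {self.n_rois}"
            )
        if not 0 <= self.between_module_r < self.within_module_r < 1:
            raise ValueError(
                "require 0 <= between_module_r < within_module_r < 1, got "
                f"{self.between_module_r}, {self.within_module_r}"
            )
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0 <= self.hub_fraction < 1:
            raise ValueError("hub_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.spatial_weight <= 1:
            raise ValueError("spatial_weight must be in [0, 1]")


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters plus a per-frame outlier fraction."""

    params: np.ndarray  # (n_frames, 6): 3 translations mm, 3 rotations rad
    outlier_fraction: np.ndarray  # (n_frames,) in [0, 1]

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.outlier_fraction = np.asarray(self.outlier_fraction, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion params must be (n_frames, 6), got {self.params.shape}")
        if self.outlier_fraction.shape != (self.params.shape[0],):
            raise ValueError("outlier_fraction length must equal n_frames")
        if np.any((self.outlier_fraction < 0) | (self.outlier_fraction > 1)):
            raise ValueError("outlier_fraction values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class Subject:
    timeseries: np.ndarray  # (n_frames, n_rois)
    motion: MotionTrace
    subject_id: str


@dataclass
class Cohort:
    spec: SyntheticCohortSpec
    subjects: list[Subject]
    roi_labels: list[str]
    module_labels: np.ndarray  # planted module id per ROI
    hub_nodes: np.ndarray  # planted hub ROI indices
    loadings: np.ndarray  # (n_rois, n_factors) structural factor loadings

    def population_correlation(self) -> np.ndarray:
        """The correlation matrix subject matrices converge to (noise_sd=1)."""
        C = self.loadings @ self.loadings.T
        np.fill_diagonal(C, 1.0)
        return C


def _band_limited_signals(
    rng: np.random.Generator, n_frames: int, n_signals: int, tr: float,
    low: float = 0.01, high: float = 0.1,
) -> np.ndarray:
    """Unit-variance signals built from in-band Fourier components only."""
    freqs = np.fft.rfftfreq(n_frames, d=tr)
    keep = (freqs > low) & (freqs < high)
    t = np.arange(n_frames) * tr
    out = np.zeros((n_frames, n_signals))
    for s in range(n_signals):
        sig = np.zeros(n_frames)
        for f in freqs[keep]:
            amp = rng.normal()
            phase = rng.uniform(0, 2 * math.pi)
            sig += amp * np.sin(2 * math.pi * f * t + phase)
        sd = sig.std()
        out[:, s] = sig / sd if sd > 0 else sig
    return out


def generate_motion(
    n_frames: int, spike_prob: float, spike_mm: float, seed: int | None = None
) -> MotionTrace:
    """Motion trace with near-zero baseline and isolated displacement spikes.

    Spikes alternate sign so that consecutive spiked frames still
    produce frame-to-frame displacement of at least ``spike_mm``.
    Outlier fractions sit near zero except at spiked frames.
    """
    if spike_mm < 0:
        raise ValueError("spike_mm must be >= 0")
    rng = np.random.default_rng(seed)
    params = np.zeros((n_frames, 6))
    outliers = rng.uniform(0.0, 0.02, size=n_frames)
    spikes = rng.random(n_frames) < spike_prob
    spikes[0] = False  # FD is undefined at frame 0; keep it clean
    sign = 1.0
    for t in np.flatnonzero(spikes):
        params[t, 0] = sign * spike_mm
        sign = -sign
        outliers[t] = min(1.0, outliers[t] + 0.15)
    return MotionTrace(params=params, outlier_fraction=outliers)


def _structural_loadings(spec: SyntheticCohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Factor-loading matrix realizing the spec's correlation targets.

    Returns (loadings, module_labels, hub_nodes).  Column layout:
    [global | one per module | cos/sin pairs per harmonic].
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    n = spec.n_rois
    n_mod = len(spec.module_sizes)
    module_labels = np.repeat(np.arange(n_mod), spec.module_sizes)
    theta = 2.0 * np.pi * np.arange(n) / n
    s = min(1.0, spec.noise_sd)  # idiosyncratic-structure scale

    # ring kernel: flat harmonic band (main lobe) + geometric tail
    f = np.arange(1, spec.n_harmonics + 1)
    lobe = (f <= spec.kernel_lobe).astype(float) / spec.kernel_lobe
    tail = spec.kernel_tail_decay ** f
    tail = tail / tail.sum() if tail.sum() > 0 else tail
    wf = (1 - spec.kernel_tail_weight) * lobe + spec.kernel_tail_weight * tail
    wf /= wf.sum()
    D = np.abs(theta[:, None] - theta[None, :])
    D = np.minimum(D, 2 * np.pi - D)
    K = sum(wf[k - 1] * np.cos(k * D) for k in f)
    same = module_labels[:, None] == module_labels[None, :]
    off_diag = ~np.eye(n, dtype=bool)
    kappa_win = K[same & off_diag].mean() if (same & off_diag).any() else 0.0
    kappa_btw = K[~same].mean() if (~same).any() else 0.0

    # solve amplitudes for the correlation targets (at noise_sd = 1);
    # spatial_weight is the fraction of the within-between contrast
    # carried by the kernel: b2 * (kappa_win - kappa_btw) = sw * (w - b)
    w_t, b_t = spec.within_module_r, spec.between_module_r
    kappa_gap = kappa_win - kappa_btw
    b2 = spec.spatial_weight * (w_t - b_t) * s * s / kappa_gap if kappa_gap > 1e-9 else 0.0
    if kappa_win < 1.0:
        b2 = min(b2, max(0.0, (0.95 - w_t) / (1.0 - kappa_win)))
    b0 = b_t - b2 * kappa_btw
    b1 = w_t - b0 - b2 * kappa_win
    if b1 < 0:  # kernel carries too much of the contrast; shrink it
        b2 = (w_t - b_t) / max(kappa_win - kappa_btw, 1e-9)
        b0 = b_t - b2 * kappa_btw
        b1 = 0.0
    b0 = max(b0, 0.0)

    # jitter kept inside the per-node variance budget
    jitter = spec.module_loading_jitter * s
    if b1 > 0:
        cap = math.sqrt(max(0.0, 0.95 - b0 - b2) / b1)
        jitter = min(jitter, max(0.0, 2.0 * (cap - 1.0)))
    u = 1.0 + jitter * (rng.random(n) - 0.5)

    # hubs: evenly spread on the ring, elevated global loading
    n_hubs = int(round(spec.hub_fraction * n))
    if n_hubs > 0:
        hubs = (np.round(np.linspace(0, n, n_hubs, endpoint=False)).astype(int)
                + rng.integers(0, 3, n_hubs)) % n
        hubs = np.unique(hubs).astype(np.intp)
    else:
        hubs = np.array([], dtype=np.intp)
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True
    hub_amp = b0 + (spec.hub_strength - b0) * s * s
    hub_amp = min(hub_amp, 0.95 - b1 * (1 + jitter / 2) ** 2 - b2 * spec.hub_local_scale)
    hub_amp = max(hub_amp, b0)

    cols: list[np.ndarray] = [np.where(is_hub, math.sqrt(hub_amp), math.sqrt(b0))]
    for m in range(n_mod):
        v = np.zeros(n)
        sel = module_labels == m
        v[sel] = math.sqrt(b1) * u[sel]
        cols.append(v)
    hub_scale = 1.0 - (1.0 - math.sqrt(spec.hub_local_scale)) * s
    scale = np.where(is_hub, hub_scale, 1.0)
    for k in f:
        amp = math.sqrt(b2 * wf[k - 1])
        cols.append(amp * np.cos(k * theta) * scale)
        cols.append(amp * np.sin(k * theta) * scale)
    L = np.column_stack(cols)
    v2 = (L ** 2).sum(axis=1)
    over = v2 > 0.97
    if over.any():  # extreme parameter corner: renormalize offending rows
        L[over] *= np.sqrt(0.97 / v2[over])[:, None]
    return L, module_labels, hubs


def generate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Generate one cohort of (time series, motion) pairs.

    Deterministic for a fixed spec (the seed lives in the spec).  The
    structural loadings — module labels, hub placement, spatial kernel —
    are shared across subjects; latent signals and noise are drawn
    independently per subject.
    """
    L, module_labels, hub_nodes = _structural_loadings(spec)
    labels = [f"ROI{i:03d}" for i in range(spec.n_rois)]
    n_factors = L.shape[1]
    noise_sd_per_roi = spec.noise_sd * np.sqrt(np.maximum(0.0, 1.0 - (L ** 2).sum(axis=1)))

    subjects: list[Subject] = []
    for s in range(spec.n_subjects):
        sub_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1000 + s]))
        if spec.band_limited:
            latents = _band_limited_signals(sub_rng, spec.n_frames, n_factors, spec.tr_seconds)
            noise = _band_limited_signals(sub_rng, spec.n_frames, spec.n_rois, spec.tr_seconds)
        else:
            latents = sub_rng.standard_normal((spec.n_frames, n_factors))
            noise = sub_rng.standard_normal((spec.n_frames, spec.n_rois))
        ts = latents @ L.T + noise * noise_sd_per_roi
        motion = generate_motion(
            spec.n_frames,
            spec.motion_spike_prob,
            spec.motion_spike_mm,
            seed=int(np.random.default_rng(np.random.SeedSequence([spec.seed, 2000 + s])).integers(2**31)),
        )
        subjects.append(Subject(timeseries=ts, motion=motion, subject_id=f"sub{s:03d}"))

    return Cohort(
        spec=spec,
        subjects=subjects,
        roi_labels=labels,
        module_labels=module_labels,
        hub_nodes=hub_nodes,
        loadings=L,
    )


def _ring_lattice_even(n: int, k: int) -> np.ndarray:
    """Adjacency of a ring where each node links to k/2 neighbors each side."""
    if k % 2 or not 0 <= k < n:
        raise ValueError("ring lattice needs even k with 0 <= k < n")
    A = np.zeros((n, n), dtype=np.uint8)
    for ring in range(1, k // 2 + 1):
        for i in range(n):
            j = (i + ring) % n
            A[i, j] = A[j, i] = 1
    return A


def generate_reference_graph(
    kind: str, n: int, params: dict | None = None, seed: int | None = None
) -> BinaryGraph:
    """Fixture graphs of known topology.

    Supported kinds: ``ring_lattice`` (param k), ``ws_small_world``
    (params k, p), ``er_random`` (param p or edges), ``ba_scale_free``
    (param m or density), ``star``, ``complete``, ``path``.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if n < 1:
        raise ValueError("n must be >= 1")

    if kind == "complete":
        A = np.ones((n, n), dtype=np.uint8)
        np.fill_diagonal(A, 0)
    elif kind == "star":
        A = np.zeros((n, n), dtype=np.uint8)
        A[0, 1:] = A[1:, 0] = 1
    elif kind == "path":
        A = np.zeros((n, n), dtype=np.uint8)
        idx = np.arange(n - 1)
        A[idx, idx + 1] = A[idx + 1, idx] = 1
    elif kind == "ring_lattice":
        A = _ring_lattice_even(n, int(params.get("k", 4)))
    elif kind == "ws_small_world":
        k = int(params.get("k", 4))
        p = float(params.get("p", 0.1))
        A = _ring_lattice_even(n, k)
        # Watts–Strogatz: rewire each lattice edge's far endpoint with prob p
        for i in range(n):
            for ring in range(1, k // 2 + 1):
                j = (i + ring) % n
                if rng.random() < p:
                    choices = np.flatnonzero((A[i] == 0))
                    choices = choices[choices != i]
                    if choices.size == 0:
                        continue
                    new_j = int(rng.choice(choices))
                    A[i, j] = A[j, i] = 0
                    A[i, new_j] = A[new_j, i] = 1
    elif kind == "er_random":
        max_edges = n * (n - 1) // 2
        if "edges" in params:
            m = int(params["edges"])
            if m > max_edges:
                raise ValueError(f"edges {m} exceeds maximum {max_edges}")
            iu = np.triu_indices(n, k=1)
            chosen = rng.choice(max_edges, size=m, replace=False)
            A = np.zeros((n, n), dtype=np.uint8)
            A[iu[0][chosen], iu[1][chosen]] = 1
            A = np.maximum(A, A.T)
        else:
            p = float(params.get("p", 0.1))
            U = rng.random((n, n))
            A = (np.triu(U, 1) < p).astype(np.uint8)
            A = np.maximum(A, A.T)
    elif kind == "ba_scale_free":
        if "m" in params:
            density = 2 * int(params["m"]) / (n - 1)
        else:
            density = float(params.get("density", 0.1))
        return scale_free_graph(n, density, seed=seed)
    else:
        raise ValueError(f"unknown reference graph kind: {kind!r}")
    g = BinaryGraph(A, provenance={"kind": kind, "params": params, "seed": seed})
    return g


def generate_degree_sequence(
    model: str, params: dict, n: int, seed: int | None = None
) -> np.ndarray:
    """Integer degree sequence (all >= 1) drawn from one of three laws.

    ``power_law``: p(k) ~ k^-alpha (params: alpha > 1, optional kmin).
    ``exponential``: p(k) ~ e^(-rate*k) (params: rate > 0).
    ``truncated_power_law``: p(k) ~ k^(alpha-1) e^(-k/kc)
    (params: alpha, kc > 0) — drawn by rejection from the power law.
    """
    rng = np.random.default_rng(seed)
    kmin = int(params.get("kmin", 1))
    if model == "power_law":
        alpha = float(params["alpha"])
        if alpha <= 1:
            raise ValueError("power law needs alpha > 1")
        u = rng.random(n)
        ks = np.floor(kmin * (1 - u) ** (-1.0 / (alpha - 1.0))).astype(np.int64)
        return np.maximum(ks, kmin)
    if model == "exponential":
        rate = float(params["rate"])
        if rate <= 0:
            raise ValueError("exponential needs rate > 0")
        ks = kmin + np.floor(rng.exponential(1.0 / rate, size=n)).astype(np.int64)
        return ks
    if model == "truncated_power_law":
        alpha = float(params["alpha"])
        kc = float(params["kc"])
        if kc <= 0:
            raise ValueError("truncated power law needs kc > 0")
        # rejection: proposal p(k) ~ k^-(1-alpha) is awkward for alpha>1,
        # so propose from a bounded-support discrete law directly
        kmax = int(params.get("kmax", max(int(20 * kc), 10 * kmin)))
        support = np.arange(kmin, kmax + 1, dtype=np.float64)
        weights = support ** (alpha - 1.0) * np.exp(-support / kc)
        weights /= weights.sum()
        return rng.choice(support.astype(np.int64), size=n, p=weights)
    raise ValueError(f"unknown degree-sequence model: {model!r}")


# re-export for convenience: matched lattice fixture builder
generate_lattice = lattice_graph
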