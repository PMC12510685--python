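"""Dictionary-based morphometric inversion of ADC time dependencies.

Randomly branched cell graphs (soma-free trees of zero-radius segments)
are generated from five morphometric statistics, intracellular diffusion
is simulated by 1-D Brownian walkers on the graph with phase accumulation
under rectangular PGSE gradients, and the resulting ADC-vs-diffusion-time
curves form a dictionary. An ensemble of regression trees (200 trees,
depth 20, squared-error loss) is trained on the dictionary to invert
measured ADC(t_d) series for the morphometric parameters; with realistic
noise only L_segment and D_intra are recovered robustly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit
from scipy.interpolate import PchipInterpolator
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor

from .scheme import DiffusionScheme, make_scheme_table

logger = logging.getLogger(__name__)

__all__ = [
    "MorphometricParams",
    "PARAM_BOUNDS",
    "PARAM_NAMES",
    "CellGraph",
    "Dictionary",
    "generate_cell_graph",
    "simulate_walkers",
    "build_dictionary",
    "MorphometricRegressor",
    "train_regressor",
    "predict_morphometry",
    "save_dictionary",
    "load_dictionary",
]

PARAM_NAMES = ("D_intra", "N_branch", "L_segment", "SDN_branch", "SDL_segment")
PARAM_BOUNDS = {
    "D_intra": (0.1, 1.0),
    "N_branch": (2.0, 25.0),
    "L_segment": (5.0, 100.0),
    "SDN_branch": (2.0, 3.0),
    "SDL_segment": (5.0, 10.0),
}


@dataclass(frozen=True)
class MorphometricParams:
    """Generative statistics of a randomly branched cell.

    D_intra in µm²/ms; N_branch the mean number of bifurcation generations
    per root-to-tip path; L_segment / SDL_segment the mean/SD segment
    length in µm; SDN_branch the SD of the generation count.
    """

    D_intra: float
    N_branch: float
    L_segment: float
    SDN_branch: float
    SDL_segment: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])


@dataclass
class CellGraph:
    """Branched-neurite tree: nodes in 3D, segments between them.

    ``seg_node_a`` is the proximal (root-side) node of each segment and
    ``seg_node_b`` the distal node; ``seg_dir`` the unit vector a→b.
    Connected and acyclic by construction.
    """

    nodes: np.ndarray  # (n_nodes, 3) µm
    seg_node_a: np.ndarray
    seg_node_b: np.ndarray
    seg_length: np.ndarray
    seg_dir: np.ndarray
    generation: np.ndarray  # bifurcations on path from root, per segment
    params: MorphometricParams | None = None
    truncated: bool = False

    @property
    def n_segments(self) -> int:
        return len(self.seg_length)

    @property
    def seg_start(self) -> np.ndarray:
        return self.nodes[self.seg_node_a]

    @property
    def total_length(self) -> float:
        return float(np.sum(self.seg_length))

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Node → incident segments, CSR layout for the walker kernel."""
        n_nodes = len(self.nodes)
        counts = np.zeros(n_nodes, dtype=np.int64)
        np.add.at(counts, self.seg_node_a, 1)
        np.add.at(counts, self.seg_node_b, 1)
        off = np.zeros(n_nodes + 1, dtype=np.int64)
        np.cumsum(counts, out=off[1:])
        segs = np.empty(off[-1], dtype=np.int64)
        cursor = off[:-1].copy()
        for s in range(self.n_segments):
            for node in (self.seg_node_a[s], self.seg_node_b[s]):
                segs[cursor[node]] = s
                cursor[node] += 1
        return off, segs


def _random_rotation_about(parent_dir: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Unit vector at polar angle theta, azimuth phi, relative to parent_dir."""
    # orthonormal frame around the parent direction
    a = np.array([1.0, 0.0, 0.0]) if abs(parent_dir[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(parent_dir, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(parent_dir, e1)
    return (
        np.cos(theta) * parent_dir
        + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    )


def generate_cell_graph(
    params: MorphometricParams,
    seed: int,
    min_segment: float = 0.5,
    max_segments: int = 4095,
    branch_angle_deg: tuple[float, float] = (10.0, 80.0),
) -> CellGraph:
    """Grow a random binary tree from a root.

    The number of bifurcation generations per path is drawn once per cell
    from Normal(N_branch, SDN_branch) truncated at >= 1; segment lengths are
    Normal(L_segment, SDL_segment) truncated at > ``min_segment`` µm.
    Daughter directions take a random azimuth and a polar angle uniform in
    ``branch_angle_deg`` relative to the parent. Growth is breadth-first
    and capped at ``max_segments`` (binary trees grow as 2^generations);
    capped graphs carry ``truncated=True`` — structure beyond the cap lies
    past the diffusion horizon of the study's longest mixing time for the
    admissible segment lengths.

    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        g = rng.normal(params.N_branch, params.SDN_branch)
        if g >= 1:
            generations = int(round(g))
            break
    else:
        raise ValueError("cannot draw >= 1 bifurcation generations from the given params")

    def draw_length() -> float:
        for _ in range(1000):
            ln = rng.normal(params.L_segment, params.SDL_segment)
            if ln > min_segment:
                return float(ln)
        raise ValueError("cannot draw a segment length above the minimum")

    nodes = [np.zeros(3)]
    seg_a, seg_b, seg_len, seg_dir, seg_gen = [], [], [], [], []
    # root segment in a random direction
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    length = draw_length()
    nodes.append(nodes[0] + length * v)
    seg_a.append(0)
    seg_b.append(1)
    seg_len.append(length)
    seg_dir.append(v)
    seg_gen.append(0)

    lo_th, hi_th = np.deg2rad(branch_angle_deg)
    queue = [(1, v, 0)]  # (tip node, direction, bifurcations so far)
    truncated = False
    while queue:
        node, pdir, gen = queue.pop(0)
        if gen >= generations:
            continue
        if len(seg_len) + 2 > max_segments:
            truncated = True
            break
        for _ in range(2):
            theta = rng.uniform(lo_th, hi_th)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            d = _random_rotation_about(pdir, theta, phi)
            ln = draw_length()
            nodes.append(nodes[node] + ln * d)
            child = len(nodes) - 1
            seg_a.append(node)
            seg_b.append(child)
            seg_len.append(ln)
            seg_dir.append(d)
            seg_gen.append(gen + 1)
            queue.append((child, d, gen + 1))

    return CellGraph(
        nodes=np.asarray(nodes),
        seg_node_a=np.asarray(seg_a, dtype=np.int64),
        seg_node_b=np.asarray(seg_b, dtype=np.int64),
        seg_length=np.asarray(seg_len),
        seg_dir=np.asarray(seg_dir),
        generation=np.asarray(seg_gen, dtype=np.int64),
        params=params,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# walker engine


@njit(cache=True, fastmath=True)
def _walk_kernel(
    seg_a, seg_b, seg_len, seg_start, seg_dir,
    node_off, node_segs,
    start_seg, start_x, steps_noise,
    sigma, dt, coef, any_coef, n_steps, seed, J,
):  # pragma: no cover - exercised through simulate_walkers
    np.random.seed(seed)  # branch-choice stream only
    n_walkers = start_seg.shape[0]
    n_tm = coef.shape[1]
    for w in range(n_walkers):
        s = start_seg[w]
        x = start_x[w]
        for i in range(n_steps):
            x += sigma * steps_noise[w, i]
            guard = 0
            while x < 0.0 or x > seg_len[s]:
                guard += 1
                if guard > 200:
                    if x < 0.0:
                        x = 0.0
                    else:
                        x = seg_len[s]
                    break
                if x < 0.0:
                    node = seg_a[s]
                    over = -x
                else:
                    node = seg_b[s]
                    over = x - seg_len[s]
                deg = node_off[node + 1] - node_off[node]
                if deg == 1:
                    # dead end (tip or root): elastic reflection
                    if x < 0.0:
                        x = over
                    else:
                        x = seg_len[s] - over
                else:
                    # uniform choice among the other incident segments
                    k = np.random.randint(0, deg - 1)
                    cnt = 0
                    s2 = -1
                    for j in range(node_off[node], node_off[node + 1]):
                        cand = node_segs[j]
                        if cand == s:
                            continue
                        if cnt == k:
                            s2 = cand
                            break
                        cnt += 1
                    if seg_a[s2] == node:
                        x = over
                    else:
                        x = seg_len[s2] - over
                    s = s2
            if any_coef[i]:
                px = seg_start[s, 0] + x * seg_dir[s, 0]
                py = seg_start[s, 1] + x * seg_dir[s, 1]
                pz = seg_start[s, 2] + x * seg_dir[s, 2]
                for k in range(n_tm):
                    c = coef[i, k]
                    if c != 0:
                        J[w, k, 0] += c * px * dt
                        J[w, k, 1] += c * py * dt
                        J[w, k, 2] += c * pz * dt


def _fibonacci_directions(n: int) -> np.ndarray:
    """n near-uniform unit vectors (deterministic Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def simulate_walkers(
    graph: CellGraph,
    D_intra: float,
    schemes: list[DiffusionScheme],
    n_walkers: int = 10_000,
    dt: float | None = None,
    seed: int = 0,
    n_directions: int = 16,
    check_step: bool = True,
) -> dict[float, dict[str, float]]:
    """Powder-averaged attenuation and two-point ADC per mixing time.

    Walkers perform 1-D Brownian motion along the graph's segments with
    elastic reflection at tips and uniform branch choice at nodes (the
    incoming segment excluded); their 3D trajectory accrues spin phase
    under rectangular PGSE pulses (δ, Δ) for every scheme simultaneously,
    and signals are averaged over ``n_directions`` uniformly spread
    gradient directions. The ADC uses each scheme's (b0, b0 + 3) pair,
    exactly as in the acquisition.

    Returns {mixing_time: {"E0", "E1", "adc", "t_d"}}.
    """
    if not D_intra > 0:
        raise ValueError("D_intra must be > 0")
    delta = schemes[0].delta
    if any(s.delta != delta for s in schemes):
        raise ValueError("all schemes must share the gradient duration")
    if dt is None:
        dt = delta / 10.0
    step = np.sqrt(2.0 * D_intra * dt)
    min_seg = float(np.min(graph.seg_length))
    if check_step and step > min_seg / 5.0:
        raise ValueError(
            f"rms step {step:.3f} µm exceeds shortest segment/5 "
            f"({min_seg / 5.0:.3f} µm); reduce dt below "
            f"{(min_seg / 5.0) ** 2 / (2 * D_intra):.4f} ms or regrow the "
            "graph with a larger minimum segment length"
        )

    T = max(s.Delta for s in schemes) + delta
    n_steps = int(np.ceil(T / dt))
    n_tm = len(schemes)
    centers = (np.arange(n_steps) + 0.5) * dt
    coef = np.zeros((n_steps, n_tm), dtype=np.int8)
    for k, s in enumerate(schemes):
        coef[centers < s.delta, k] = 1
        coef[(centers >= s.Delta) & (centers < s.Delta + s.delta), k] = -1
    any_coef = np.any(coef != 0, axis=1)

    rng = np.random.default_rng(seed)
    p = graph.seg_length / graph.total_length
    start_seg = rng.choice(graph.n_segments, size=n_walkers, p=p).astype(np.int64)
    start_x = rng.uniform(0.0, graph.seg_length[start_seg])
    node_off, node_segs = graph.adjacency_csr()

    # step noise is generated chunkwise with numpy's PCG64 (fast ziggurat);
    # the kernel only draws branch choices from its own seeded stream
    J = np.zeros((n_walkers, n_tm, 3))
    chunk = 1000
    seg_start = np.ascontiguousarray(graph.seg_start)
    seg_dir = np.ascontiguousarray(graph.seg_dir)
    for w0 in range(0, n_walkers, chunk):
        w1 = min(w0 + chunk, n_walkers)
        noise = rng.standard_normal((w1 - w0, n_steps), dtype=np.float32)
        _walk_kernel(
            graph.seg_node_a, graph.seg_node_b, graph.seg_length,
            seg_start, seg_dir,
            node_off, node_segs,
            start_seg[w0:w1], start_x[w0:w1], noise,
            step, dt, coef, any_coef, n_steps,
            (int(seed) + w0) % (2**31 - 1), J[w0:w1],
        )

    dirs = _fibonacci_directions(n_directions)
    out: dict[float, dict[str, float]] = {}
    for k, s in enumerate(schemes):
        b0, b1 = s.b_pair
        proj = J[:, k, :] @ dirs.T  # (n_walkers, n_dirs)
        E = {}
        floor = 1.0 / np.sqrt(n_walkers * n_directions)  # MC noise scale
        for b in (b0, b1):
            gamma_g = np.sqrt(b / (s.delta**2 * (s.Delta - s.delta / 3.0)))
            Eb = float(np.mean(np.cos(gamma_g * proj)))
            if Eb < floor:
                logger.info("E(b=%.3f) at MC noise floor; clipping to %.1e", b, floor)
                Eb = floor
            E[b] = Eb
        adc = -np.log(E[b1] / E[b0]) / (b1 - b0)
        out[s.mixing_time] = {"E0": E[b0], "E1": E[b1], "adc": float(adc), "t_d": s.t_d}
    return out


# ---------------------------------------------------------------------------
# dictionary


@dataclass
class Dictionary:
    """Morphometric parameter sets and their simulated ADC(t_d) vectors."""

    params: np.ndarray  # (n_entries, 5) in PARAM_NAMES order
    adcs: np.ndarray  # (n_entries, len(t_d))
    t_d: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.params.shape[0] != self.adcs.shape[0]:
            raise ValueError("params/adcs row mismatch")
        if np.any(~np.isfinite(self.adcs)):
            raise ValueError("dictionary contains missing ADC values")

    @property
    def n_entries(self) -> int:
        return self.params.shape[0]


def sample_param_grid(n_entries: int, seed: int) -> np.ndarray:
    """Latin-hypercube sample over the bounded 5-dim morphometric space."""
    sampler = qmc.LatinHypercube(d=5, seed=seed)
    unit = sampler.random(n_entries)
    lo = np.array([PARAM_BOUNDS[n][0] for n in PARAM_NAMES])
    hi = np.array([PARAM_BOUNDS[n][1] for n in PARAM_NAMES])
    return qmc.scale(unit, lo, hi)


def build_dictionary(
    param_grid: np.ndarray | int = 512,
    schemes: dict[float, DiffusionScheme] | None = None,
    n_walkers: int = 10_000,
    seed: int = 0,
    simulate_all: bool = True,
    min_segment: float = 2.5,
    max_segments: int = 4095,
    n_directions: int = 16,
) -> Dictionary:
    """Simulate the ADC(t_d) dictionary over a morphometric parameter grid.

    By default every mixing time is simulated directly: all four share one
    walk (the gradient-pulse windows just tap the same trajectories), so
    this costs no extra simulation time and keeps the short-TM entries
    honest. With ``simulate_all=False`` only TM = 500 and 1000 ms are
    simulated and the TM = 100 and 750 ms ADCs are predicted by monotone
    (PCHIP) interpolation of ADC versus diffusion time — with two support
    points the TM = 100 value is a linear extrapolation, which washes out
    the segment-length information carried by the short diffusion time.
    Graphs are drawn with a ``min_segment`` floor of 2.5 µm and the walker
    time step is set per entry from min(δ/10, (min_segment/5)²/(2·D)) so the
    step-stability guard always holds. Failed entries are recorded and
    excluded, never silently dropped.
    """
    if schemes is None:
        schemes = make_scheme_table()
    if np.ndim(param_grid) == 0:
        param_grid = sample_param_grid(int(param_grid), seed)
    param_grid = np.asarray(param_grid, dtype=float)
    tms_all = sorted(schemes)
    tms_sim = tms_all if simulate_all else [500.0, 1000.0]
    sim_schemes = [schemes[t] for t in tms_sim]
    td_all = np.array([schemes[t].t_d for t in tms_all])

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(param_grid))]

    rows, kept, failures = [], [], []
    for i, row in enumerate(param_grid):
        p = MorphometricParams(**dict(zip(PARAM_NAMES, row)))
        dt = min(
            sim_schemes[0].delta / 10.0,
            (min_segment / 5.0) ** 2 / (2.0 * p.D_intra),
        )
        try:
            graph = generate_cell_graph(
                p, seed=child_seeds[i], min_segment=min_segment, max_segments=max_segments
            )
            res = simulate_walkers(
                graph, p.D_intra, sim_schemes, n_walkers=n_walkers, dt=dt,
                seed=child_seeds[i], n_directions=n_directions,
            )
        except (ValueError, FloatingPointError) as exc:
            logger.warning("dictionary entry %d failed: %s", i, exc)
            failures.append((i, str(exc)))
            continue
        td_sim = np.array([res[t]["t_d"] for t in tms_sim])
        adc_sim = np.array([res[t]["adc"] for t in tms_sim])
        if simulate_all:
            adc_full = adc_sim
        else:
            interp = PchipInterpolator(td_sim, adc_sim, extrapolate=True)
            adc_full = interp(td_all)
        rows.append(adc_full)
        kept.append(i)

    return Dictionary(
        params=param_grid[kept],
        adcs=np.asarray(rows),
        t_d=td_all,
        meta={
            "n_walkers": n_walkers,
            "seed": seed,
            "simulate_all": simulate_all,
            "min_segment": min_segment,
            "max_segments": max_segments,
            "failures": failures,
            "mixing_times": tms_all,
        },
    )


def save_dictionary(path: str, d: Dictionary) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("params", data=d.params)
        h5.create_dataset("adcs", data=d.adcs)
        h5.create_dataset("t_d", data=d.t_d)
        for k, v in d.meta.items():
            if k != "failures":
                h5.attrs[k] = v


def load_dictionary(path: str) -> Dictionary:
    with h5py.File(path, "r") as h5:
        return Dictionary(
            params=h5["params"][()],
            adcs=h5["adcs"][()],
            t_d=h5["t_d"][()],
            meta=dict(h5.attrs),
        )


# ---------------------------------------------------------------------------
# regressor


class MorphometricRegressor(BaseEstimator, RegressorMixin):
    """Ensemble-of-trees inversion of ADC(t_d) for morphometric parameters.

    A random forest (default 200 trees of depth 20, squared-error loss)
    maps the 4-point ADC time dependency to the 5 generative parameters.
    Predictions are clamped to the physical bounds; predictions pinned at
    a bound are flagged in ``pinned_``.
    """

    def __init__(self, n_trees: int = 200, max_depth: int = 20, seed: int = 0):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.seed = seed

    def fit(self, dictionary: Dictionary) -> "MorphometricRegressor":
        if dictionary.n_entries < 50:
            raise ValueError("need at least 50 dictionary entries")
        if np.any(np.ptp(dictionary.params, axis=0) == 0):
            warnings.warn("a target parameter is constant across the dictionary")
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            criterion="squared_error",
            oob_score=True,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )
        self.forest_.fit(dictionary.adcs, dictionary.params)
        oob = self.forest_.oob_prediction_
        self.oob_mse_ = np.mean((oob - dictionary.params) ** 2, axis=0)
        self.t_d_ = dictionary.t_d.copy()
        self.dictionary_adcs_ = dictionary.adcs.copy()
        self.dictionary_params_ = dictionary.params.copy()
        return self

    def predict(self, adc: np.ndarray, t_d: np.ndarray | None = None) -> np.ndarray:
        """Predict morphometric parameters from ADC vectors.

        ``adc`` is (n, len(t_d)) or a single vector on the dictionary's
        diffusion-time grid. Missing (NaN) entries are imputed from the
        dictionary entry nearest in the observed coordinates (flagged in
        ``imputed_``); a wrong t_d grid raises.
        """
        adc = np.atleast_2d(np.asarray(adc, dtype=float))
        if t_d is not None and not np.allclose(np.asarray(t_d), self.t_d_, rtol=1e-6):
            raise ValueError(f"ADC series must be on the dictionary t_d grid {self.t_d_}")
        if adc.shape[1] != len(self.t_d_):
            raise ValueError(f"expected {len(self.t_d_)} ADC values per series")
        self.imputed_ = np.zeros(adc.shape[0], dtype=bool)
        filled = adc.copy()
        for i in range(adc.shape[0]):
            miss = ~np.isfinite(adc[i])
            if np.all(miss):
                raise ValueError("ADC series has no observed values")
            if np.any(miss):
                self.imputed_[i] = True
                d2 = np.sum((self.dictionary_adcs_[:, ~miss] - adc[i, ~miss]) ** 2, axis=1)
                filled[i, miss] = self.dictionary_adcs_[np.argmin(d2)][miss]
        pred = self.forest_.predict(filled)
        lo = np.array([PARAM_BOUNDS[n][0] for n in PARAM_NAMES])
        hi = np.array([PARAM_BOUNDS[n][1] for n in PARAM_NAMES])
        clipped = np.clip(pred, lo, hi)
        self.pinned_ = np.any((clipped <= lo) | (clipped >= hi), axis=1)
        if np.any(self.pinned_):
            logger.info("%d prediction(s) pinned at a parameter bound", int(self.pinned_.sum()))
        return clipped


def train_regressor(dictionary: Dictionary, n_trees: int = 200, max_depth: int = 20,
                    seed: int = 0) -> MorphometricRegressor:
    """Functional wrapper over :class:`MorphometricRegressor`."""
    return MorphometricRegressor(n_trees=n_trees, max_depth=max_depth, seed=seed).fit(dictionary)


def predict_morphometry(regressor: MorphometricRegressor, adc: np.ndarray,
                        t_d: np.ndarray | None = None) -> MorphometricParams:
    """Invert one measured ADC(t_d) series to morphometric parameters."""
    row = regressor.predict(np.atleast_2d(adc), t_d=t_d)[0]
    return MorphometricParams(**dict(zip(PARAM_NAMES, row)))
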