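"""Stochastic Boolean simulation of logical models.

Two update schemes are provided.  *Synchronous*: every node is rewritten
simultaneously by its rule.  *Asynchronous* (general asynchronous
semantics): one node, chosen uniformly at random per step, is rewritten;
one step therefore equals one single-node update.  Input nodes can be
clamped: a clamp probability p means the input is resampled ON with
probability p at every step, so p=1 holds the stimulus permanently ON and
p=0 silences it.

Activity levels are windowed ON-fractions: trajectories are cut into
non-overlapping windows, each node's mean within the window is averaged
over an ensemble of independently seeded runs.  On small models the full
asynchronous state-transition graph can be enumerated and its attractors
(fixed points and terminal strongly connected components) extracted
exactly, which serves as the oracle for the stochastic engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .logic import And, Lit, LogicExpr, LogicModel, Not, Or
from .phenotype import MarkerConfig

EXHAUSTIVE_NODE_LIMIT = 20


class ConfigError(ValueError):
    """Simulation configuration violates its contract."""


class StateError(ValueError):
    """A state does not cover the model's nodes or is not binary."""


class ModelSizeError(ValueError):
    """Model too large for exhaustive state enumeration."""


# ---------------------------------------------------------------------------
# rule compilation


def _compile(expr: LogicExpr, index: Mapping[str, int]) -> Callable[[np.ndarray], int]:
    if isinstance(expr, Lit):
        i = index[expr.name]
        return lambda s: int(s[i])
    if isinstance(expr, Not):
        f = _compile(expr.child, index)
        return lambda s: 1 - f(s)
    fns = [_compile(c, index) for c in expr.children]
    if isinstance(expr, And):
        return lambda s: int(all(f(s) for f in fns))
    return lambda s: int(any(f(s) for f in fns))


class CompiledModel:
    """Index-based rule evaluators over a fixed node order."""

    def __init__(self, model: LogicModel):
        self.model = model
        self.node_order = list(model.node_order)
        self.index = {n: i for i, n in enumerate(self.node_order)}
        self.fns = [_compile(model.rules[n].expr, self.index) for n in self.node_order]

    def state_array(self, state: Mapping[str, int]) -> np.ndarray:
        missing = [n for n in self.node_order if n not in state]
        if missing:
            raise StateError(f"state missing node(s): {missing[:5]}")
        arr = np.zeros(len(self.node_order), dtype=np.uint8)
        for n, i in self.index.items():
            v = int(state[n])
            if v not in (0, 1):
                raise StateError(f"node {n} has non-binary value {state[n]!r}")
            arr[i] = v
        return arr

    def state_dict(self, arr: np.ndarray) -> dict[str, int]:
        return {n: int(arr[i]) for n, i in self.index.items()}


# ---------------------------------------------------------------------------
# configuration and containers


@dataclass
class SimulationConfig:
    """Scheme, length, clamps, initial condition and seed of one run."""

    scheme: str = "asynchronous"
    n_steps: int = 1000
    clamps: dict[str, float] = field(default_factory=dict)
    initial: str | Mapping[str, int] = "epithelial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("synchronous", "asynchronous"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        for node, p in self.clamps.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"clamp probability for {node} outside [0, 1]: {p}")
        if isinstance(self.initial, str) and self.initial not in ("epithelial", "random"):
            raise ConfigError(f"unknown initial preset {self.initial!r}")


@dataclass
class Trajectory:
    """One simulated time course (states include the initial state)."""

    node_order: list[str]
    array: np.ndarray  # (n_steps + 1, n_nodes) uint8
    updated_node_log: list[str | None]
    config: SimulationConfig

    def __len__(self) -> int:
        return self.array.shape[0]

    def state_at(self, i: int) -> dict[str, int]:
        return {n: int(self.array[i, j]) for j, n in enumerate(self.node_order)}

    @property
    def states(self) -> list[dict[str, int]]:
        return [self.state_at(i) for i in range(len(self))]

    @property
    def final_state(self) -> dict[str, int]:
        return self.state_at(len(self) - 1)

    def series(self, node: str) -> np.ndarray:
        return self.array[:, self.node_order.index(node)].astype(float)


@dataclass
class ActivityProfile:
    """Per-node windowed ON-fractions averaged over an ensemble of runs."""

    node_order: list[str]
    values: np.ndarray  # (n_windows, n_nodes) float in [0, 1]
    window_size: int
    ensemble_size: int
    scheme: str
    base_seed: int = 0

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def profile(self, node: str) -> np.ndarray:
        return self.values[:, self.node_order.index(node)]

    def binarized(self, threshold: float = 0.5) -> list[dict[str, int]]:
        return [
            {n: int(self.values[w, j] >= threshold) for j, n in enumerate(self.node_order)}
            for w in range(self.n_windows)
        ]


# ---------------------------------------------------------------------------
# initial states


def resolve_initial(
    model: LogicModel,
    config: SimulationConfig,
    markers: MarkerConfig | None,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Build the initial state for a run.

    ``epithelial`` preset: epithelial markers ON, mesenchymal markers OFF,
    all other non-input nodes OFF, inputs drawn at their clamp probability
    (unclamped inputs OFF).
    """
    if isinstance(config.initial, Mapping):
        return {n: int(config.initial[n]) for n in model.node_order}
    if config.initial == "random":
        state = {n: int(rng.integers(0, 2)) for n in model.node_order}
    else:  # epithelial
        if markers is None:
            raise ConfigError("epithelial preset requires a MarkerConfig")
        for m in (*markers.epithelial_markers, *markers.mesenchymal_markers):
            if m not in model.rules:
                raise ConfigError(f"marker {m!r} does not resolve in the model")
        state = {n: 0 for n in model.node_order}
        for m in markers.epithelial_markers:
            state[m] = 1
    for node in model.inputs:
        p = config.clamps.get(node)
        if p is not None:
            state[node] = int(rng.random() < p)
    return state


# ---------------------------------------------------------------------------
# stepping and simulation


def sync_step(
    model: LogicModel,
    state: Mapping[str, int],
    clamps: Mapping[str, float] | None = None,
    compiled: CompiledModel | None = None,
) -> dict[str, int]:
    """One synchronous update: all rules applied to the input state at once.

    Clamped inputs keep their current value (resampling is the simulator's
    job, not the step function's).
    """
    cm = compiled or CompiledModel(model)
    arr = cm.state_array(state)
    new = np.array([f(arr) for f in cm.fns], dtype=np.uint8)
    if clamps:
        for node in clamps:
            i = cm.index[node]
            new[i] = arr[i]
    return cm.state_dict(new)


def _check_clamps(model: LogicModel, clamps: Mapping[str, float]) -> None:
    for node in clamps:
        if node not in model.rules:
            raise ConfigError(f"clamped node {node!r} is not in the model")
        if node not in model.inputs:
            raise ConfigError(f"clamped node {node!r} is not an input")


def simulate(
    model: LogicModel,
    config: SimulationConfig,
    markers: MarkerConfig | None = None,
) -> Trajectory:
    """Run one seeded trajectory under the configured scheme."""
    _check_clamps(model, config.clamps)
    cm = CompiledModel(model)
    rng = np.random.default_rng(config.seed)
    state = cm.state_array(resolve_initial(model, config, markers, rng))
    n = len(cm.node_order)
    out = np.empty((config.n_steps + 1, n), dtype=np.uint8)
    out[0] = state
    log: list[str | None] = []
    clamp_idx = [(cm.index[k], p) for k, p in config.clamps.items()]
    if config.scheme == "synchronous":
        for step in range(1, config.n_steps + 1):
            for i, p in clamp_idx:
                state[i] = 1 if rng.random() < p else 0
            new = np.array([f(state) for f in cm.fns], dtype=np.uint8)
            for i, p in clamp_idx:
                new[i] = state[i]
            state = new
            out[step] = state
            log.append(None)
    else:
        clamped = {i for i, _ in clamp_idx}
        for step in range(1, config.n_steps + 1):
            for i, p in clamp_idx:
                state[i] = 1 if rng.random() < p else 0
            j = int(rng.integers(0, n))
            if j not in clamped:
                state[j] = cm.fns[j](state)
            out[step] = state
            log.append(cm.node_order[j])
    return Trajectory(node_order=list(cm.node_order), array=out, updated_node_log=log, config=config)


def activity_profile(
    model: LogicModel,
    config: SimulationConfig,
    window: int,
    ensemble: int,
    markers: MarkerConfig | None = None,
) -> ActivityProfile:
    """Windowed ON-fractions averaged over ``ensemble`` seeded runs.

    Run r uses seed ``config.seed + r``; the result is reproducible for a
    fixed base seed.  Windows are non-overlapping and cover steps 1..n_steps
    (the initial state is not part of any window).
    """
    if window < 1:
        raise ConfigError("window must be >= 1")
    if ensemble < 1:
        raise ConfigError("ensemble must be >= 1")
    if window > config.n_steps:
        raise ConfigError(f"window ({window}) exceeds n_steps ({config.n_steps})")
    n_windows = config.n_steps // window
    n = len(model.node_order)
    acc = np.zeros((n_windows, n), dtype=float)
    for r in range(ensemble):
        run_cfg = SimulationConfig(
            scheme=config.scheme,
            n_steps=config.n_steps,
            clamps=dict(config.clamps),
            initial=config.initial,
            seed=config.seed + r,
        )
        traj = simulate(model, run_cfg, markers)
        body = traj.array[1 : n_windows * window + 1].astype(float)
        acc += body.reshape(n_windows, window, n).mean(axis=1)
    return ActivityProfile(
        node_order=list(model.node_order),
        values=acc / ensemble,
        window_size=window,
        ensemble_size=ensemble,
        scheme=config.scheme,
        base_seed=config.seed,
    )


# ---------------------------------------------------------------------------
# exhaustive attractor analysis


@dataclass(frozen=True)
class Attractor:
    type: str  # fixed_point | cycle | complex
    states: frozenset[int]  # states as bitmasks over the model's node order


@dataclass
class AttractorSet:
    attractors: list[Attractor]
    scheme: str
    node_order: list[str]

    def decode(self, bitmask: int) -> dict[str, int]:
        return {n: (bitmask >> i) & 1 for i, n in enumerate(self.node_order)}

    @property
    def fixed_points(self) -> list[dict[str, int]]:
        return [
            self.decode(next(iter(a.states)))
            for a in self.attractors
            if a.type == "fixed_point"
        ]


def _apply_all(cm: CompiledModel, bitmask: int, n: int) -> int:
    arr = np.array([(bitmask >> i) & 1 for i in range(n)], dtype=np.uint8)
    out = 0
    for i, f in enumerate(cm.fns):
        out |= f(arr) << i
    return out


def attractors_exhaustive(model: LogicModel, scheme: str = "asynchronous") -> AttractorSet:
    """Exact attractors by full state-space enumeration (≤ 20 nodes).

    Synchronous: cycles of the deterministic update map.  Asynchronous:
    terminal strongly connected components of the single-node-flip
    transition graph.  Every single-state attractor is a verified fixed
    point f(s) = s.
    """
    n = len(model.node_order)
    if n > EXHAUSTIVE_NODE_LIMIT:
        raise ModelSizeError(
            f"{n} nodes exceeds the 2^n enumeration limit ({EXHAUSTIVE_NODE_LIMIT}); use simulate() instead"
        )
    cm = CompiledModel(model)
    size = 1 << n
    # evaluate all rules on all states once
    images = np.empty(size, dtype=np.int64)
    arr = np.empty(n, dtype=np.uint8)
    per_node = np.empty((size, n), dtype=np.uint8)
    for s in range(size):
        for i in range(n):
            arr[i] = (s >> i) & 1
        img = 0
        for i, f in enumerate(cm.fns):
            v = f(arr)
            per_node[s, i] = v
            img |= v << i
        images[s] = img

    attractors: list[Attractor] = []
    if scheme == "synchronous":
        color = np.zeros(size, dtype=np.int8)  # 0 unseen, 1 on stack, 2 done
        for start in range(size):
            if color[start]:
                continue
            path = []
            s = start
            while color[s] == 0:
                color[s] = 1
                path.append(s)
                s = int(images[s])
            if color[s] == 1:  # found a new cycle
                cyc = path[path.index(s) :]
                attractors.append(
                    Attractor(
                        "fixed_point" if len(cyc) == 1 else "cycle",
                        frozenset(cyc),
                    )
                )
            for v in path:
                color[v] = 2
    elif scheme == "asynchronous":
        G = nx.DiGraph()
        G.add_nodes_from(range(size))
        for s in range(size):
            for i in range(n):
                v = int(per_node[s, i])
                t = (s & ~(1 << i)) | (v << i)
                if t != s:
                    G.add_edge(s, t)
        for comp in nx.attracting_components(G):
            states = frozenset(int(x) for x in comp)
            if len(states) == 1:
                s = next(iter(states))
                assert int(images[s]) == s, "single-state terminal SCC must be a fixed point"
                attractors.append(Attractor("fixed_point", states))
            else:
                simple_cycle = all(G.out_degree(s) == 1 for s in states)
                attractors.append(Attractor("cycle" if simple_cycle else "complex", states))
    else:
        raise ConfigError(f"unknown scheme {scheme!r}")
    return AttractorSet(attractors=attractors, scheme=scheme, node_order=list(model.node_order))


# ---------------------------------------------------------------------------
# oscillation detection


@dataclass(frozen=True)
class OscillationSummary:
    node: str
    oscillating: bool
    eps: float
    burn_in_windows: int
    n_windows_checked: int
    min_activity: float
    max_activity: float
    monotone: bool


def detect_oscillation(
    profile: ActivityProfile,
    node: str,
    eps: float = 0.05,
    burn_in_fraction: float = 0.2,
) -> OscillationSummary:
    """Flag a node whose post-burn-in window means stay strictly inside
    (eps, 1−eps) and are non-monotone.

    Sustained oscillators keep hovering in the open band; nodes that settle
    hit 0 or 1 (or drift monotonically) and are not flagged.
    """
    if node not in profile.node_order:
        raise KeyError(f"unknown node {node!r}")
    if profile.n_windows < 3:
        raise ConfigError("need at least 3 windows to assess oscillation")
    burn = int(profile.n_windows * burn_in_fraction)
    series = profile.profile(node)[burn:]
    in_band = bool(np.all((series > eps) & (series < 1 - eps)))
    diffs = np.diff(series)
    monotone = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
    return OscillationSummary(
        node=node,
        oscillating=in_band and not monotone,
        eps=eps,
        burn_in_windows=burn,
        n_windows_checked=len(series),
        min_activity=float(series.min()),
        max_activity=float(series.max()),
        monotone=monotone,
    )
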