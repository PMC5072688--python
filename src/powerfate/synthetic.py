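"""Synthetic data generators for every pipeline input.

Four generators, each a pure function of its seed and parameters:

- :func:`simulate_boolean` — a generalized (weighted, probabilistic) Boolean
  network producing saturating cumulative-activation trajectories, emulating
  stochastic signal-transduction simulators on the 7-node cell-death
  regulation network (:func:`cell_death_network`).
- :func:`generate_powerlaw_dataset` — observation tables drawn exactly from
  the power-law fate model P = e^beta0 * prod x_i^beta_i + eps with
  lognormal signals and multiplicative lognormal noise, with known ground
  truth for parameter-recovery tests.
- :func:`generate_influence_dataset` — control/drugged table pairs from a
  power-law influence DAG, the drugged table having one node
  pharmacologically blocked; used for knock-down recovery experiments.
- :func:`simulate_cascade_ode` — a small deterministic mass-action apoptosis
  cascade (receptor -> initiator caspase -> effector caspase -> cumulative
  death) standing in for large kinetic ODE models of extrinsic apoptosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .datamodel import ObservationTable

ACTIVATE = "activate"
INHIBIT = "inhibit"


@dataclass(frozen=True)
class BooleanNetwork:
    """Weighted signed network with probabilistic inputs.

    ``edges`` are (source, target, sign, weight) with sign in
    {"activate", "inhibit"} and weight in [0, 1]; ``inputs`` maps input
    nodes to their per-step activation probability in [0, 1].  Self-loops
    are rejected.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str, float], ...]
    inputs: dict[str, float]

    def __post_init__(self) -> None:
        for src, dst, sign, w in self.edges:
            if src == dst:
                raise ValueError(f"self-loop on {src!r}")
            if sign not in (ACTIVATE, INHIBIT):
                raise ValueError(f"bad sign {sign!r}")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"edge weight {w} outside [0, 1]")
            if src not in self.nodes or dst not in self.nodes:
                raise ValueError(f"edge {src}->{dst} references unknown node")
        for node, level in self.inputs.items():
            if node not in self.nodes:
                raise ValueError(f"unknown input node {node!r}")
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"input level {level} outside [0, 1]")


def cell_death_network(weight: float = 0.8, input_level: float = 0.8) -> BooleanNetwork:
    """The 7-node cell-death regulation network used throughout.

    Death is enhanced by DNA damage and inhibited by EGFR signaling (via the
    oncogenic survival signature suppressing initiator caspase-8); the
    caspase cascade 8 -> 9 -> 3 executes apoptosis.  Default edge weights
    and input levels are 0.8.
    """
    nodes = ("EGFR", "DNADamage", "OncogenicSignature",
             "Casp8", "Casp9", "Casp3", "CellDeath")
    w = weight
    edges = (
        ("EGFR", "OncogenicSignature", ACTIVATE, w),
        ("OncogenicSignature", "Casp8", INHIBIT, w),
        ("DNADamage", "Casp8", ACTIVATE, w),
        ("Casp8", "Casp9", ACTIVATE, w),
        ("Casp9", "Casp3", ACTIVATE, w),
        ("Casp3", "CellDeath", ACTIVATE, w),
        ("DNADamage", "CellDeath", ACTIVATE, w),
    )
    return BooleanNetwork(nodes=nodes, edges=edges,
                          inputs={"EGFR": input_level, "DNADamage": input_level})


def simulate_boolean(
    network: BooleanNetwork,
    n_steps: int = 100,
    seed: int = 0,
    absorbing: bool = True,
    n_cells: int = 5000,
    rate_scale: float = 0.05,
) -> pd.DataFrame:
    """Simulate the generalized Boolean network over a cell population;
    returns cumulative activation frequencies (n_steps x nodes, in [0, 1]).

    Each of ``n_cells`` cells carries binary node states, initially
    inactive, updated synchronously.  An inactive non-input node activates
    with probability clamp01(sum of activating w*s - sum of inhibiting
    w*s) * rate_scale; input nodes fire each step with probability
    input level * rate_scale.  ``rate_scale`` is the simulator's time
    resolution: per-step weighted sums act as rates, so trajectories
    saturate over the default 100-step horizon instead of within a few
    steps.  With ``absorbing=True`` (default) an activated node stays
    active, yielding monotone saturating curves; with ``absorbing=False``
    states are redrawn every step.  The reported trajectory at step t is
    the per-cell running activation frequency over steps 1..t, averaged
    over the population.  Seeded and reproducible.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0.0 < rate_scale <= 1.0:
        raise ValueError("rate_scale must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    nodes = network.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    act_w = np.zeros((n, n))
    inh_w = np.zeros((n, n))
    for src, dst, sign, w in network.edges:
        target = act_w if sign == ACTIVATE else inh_w
        target[idx[dst], idx[src]] += w
    input_idx = np.array([idx[k] for k in network.inputs], dtype=int)
    input_lv = np.array(list(network.inputs.values()), dtype=float)
    state = np.zeros((n_cells, n), dtype=bool)
    counts = np.zeros((n_cells, n))
    freq = np.zeros((n_steps, n))
    for t in range(n_steps):
        p = np.clip(state @ act_w.T - state @ inh_w.T, 0.0, 1.0)
        p[:, input_idx] = input_lv
        draws = rng.random((n_cells, n)) < p * rate_scale
        state = (state | draws) if absorbing else draws
        counts += state
        freq[t] = (counts / (t + 1)).mean(axis=0)
    return pd.DataFrame(freq, columns=list(nodes),
                        index=pd.RangeIndex(1, n_steps + 1, name="step"))


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters behind a synthetic dataset."""

    beta0: float = 0.0
    beta: np.ndarray | None = None
    epsilon: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    lam: np.ndarray | None = None
    blocked_node: int | None = None


def generate_powerlaw_dataset(
    n_obs: int,
    n_proteins: int,
    beta=None,
    beta0: float = -1.5,
    epsilon: float = 1e-4,
    noise_sd: float = 0.05,
    seed: int = 0,
    signal_sigma: float = 0.5,
) -> tuple[ObservationTable, GroundTruth]:
    """Observation table drawn exactly from the power-law fate model.

    Signals are lognormal(0, ``signal_sigma``); the fate is
    ``exp(beta0 + sum beta_i ln x_i + N(0, noise_sd)) + epsilon``
    (multiplicative lognormal noise).  When ``beta`` is omitted, exponents
    are drawn uniformly from [-0.5, 0.5] from the same seed.
    """
    if n_obs < n_proteins + 2:
        raise ValueError("need n_obs >= n_proteins + 2")
    rng = np.random.default_rng(seed)
    if beta is None:
        beta = rng.uniform(-0.5, 0.5, size=n_proteins)
    beta = np.asarray(beta, dtype=float)
    if len(beta) != n_proteins:
        raise ValueError("beta length must equal n_proteins")
    X = rng.lognormal(0.0, signal_sigma, size=(n_obs, n_proteins))
    noise = rng.normal(0.0, noise_sd, size=n_obs) if noise_sd > 0 else 0.0
    P = np.exp(beta0 + np.log(X) @ beta + noise) + epsilon
    if (P <= epsilon).any():
        raise ValueError("parameters produced fates <= epsilon")
    names = tuple(f"prot{j}" for j in range(n_proteins))
    df = pd.DataFrame(X, columns=list(names))
    df["death"] = P
    table = ObservationTable(df, names, ("death",))
    truth = GroundTruth(beta0=beta0, beta=beta, epsilon=epsilon,
                        noise_sd=noise_sd, seed=seed)
    return table, truth


def default_influence_system() -> tuple[np.ndarray, np.ndarray, int]:
    """A 6-protein influence DAG with a mid-layer hub, and the fate exponents.

    Layout: two driver proteins (0, 1) feed a hub (2); the hub drives two
    reporters (3, 4); a bypass reporter (5) responds to driver 0 directly.
    The fate loads on the hub and the reporters.  Returns
    (lambda matrix, fate beta, hub index) — the hub is the canonical
    blocked node for recovery experiments.
    """
    n = 6
    lam = np.zeros((n, n))
    lam[2, 0] = 0.8
    lam[2, 1] = 0.5
    lam[3, 2] = 0.9
    lam[4, 2] = 0.8
    lam[5, 0] = 0.7
    beta = np.array([0.0, 0.0, 0.4, 0.5, 0.4, 0.5])
    return lam, beta, 2


def _topological_order(lam: np.ndarray) -> list[int]:
    n = lam.shape[0]
    parents = [set(np.nonzero(lam[i])[0]) for i in range(n)]
    order: list[int] = []
    done: set[int] = set()
    while len(order) < n:
        progress = False
        for i in range(n):
            if i not in done and parents[i] <= done:
                order.append(i)
                done.add(i)
                progress = True
        if not progress:
            raise ValueError("cyclic lambda without a root ordering")
    return order


def generate_influence_dataset(
    n_obs: int,
    lam=None,
    blocked_node: int | None = None,
    seed: int = 0,
    beta=None,
    beta0: float = -1.5,
    epsilon: float = 1e-4,
    lam0=None,
    noise_sd: float = 0.05,
    root_sigma: float = 0.7,
    basal_sd: float = 0.3,
    fate_noise_sd: float = 0.05,
) -> tuple[ObservationTable, ObservationTable]:
    """Generate a paired control/drugged observation-table pair.

    Control: exogenous lognormal root signals propagate through the
    power-law influence relations x_i = exp(lam0_i + sum_j lam_ij ln x_j +
    noise); the fate follows the power-law fate model over the realised
    signals.  Drugged: identical random draws, but ``blocked_node``'s
    signaling function is abolished — its measured value is basal lognormal
    noise decoupled from its parents, its downstream targets no longer
    respond to it, and its direct fate contribution is removed.  With
    ``blocked_node=None`` the two tables are identical (same seed, no
    intervention).

    ``lam``/``beta`` default to :func:`default_influence_system`.
    """
    if lam is None or beta is None:
        d_lam, d_beta, _ = default_influence_system()
        lam = d_lam if lam is None else lam
        beta = d_beta if beta is None else beta
    lam = np.asarray(lam, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = lam.shape[0]
    if not np.allclose(np.diag(lam), 0.0):
        raise ValueError("lambda must have a zero diagonal")
    if lam0 is None:
        lam0 = np.zeros(n)
    lam0 = np.asarray(lam0, dtype=float)
    order = _topological_order(lam)
    rng = np.random.default_rng(seed)
    # Draw all random inputs up front so control and drugged are paired.
    root_draws = rng.normal(0.0, root_sigma, size=(n_obs, n))
    node_noise = rng.normal(0.0, noise_sd, size=(n_obs, n))
    basal_draws = rng.normal(0.0, basal_sd, size=n_obs)
    fate_noise = rng.normal(0.0, fate_noise_sd, size=n_obs)

    def assemble(blocked: int | None) -> ObservationTable:
        X = np.zeros((n_obs, n))
        for i in order:
            parents = np.nonzero(lam[i])[0]
            if blocked is not None and i == blocked:
                X[:, i] = np.exp(lam0[i] + basal_draws)
            elif len(parents) == 0:
                X[:, i] = np.exp(root_draws[:, i])
            else:
                w = lam[i].copy()
                if blocked is not None:
                    w[blocked] = 0.0  # downstream targets lose the blocked input
                cols = np.nonzero(w)[0]
                contrib = np.log(X[:, cols]) @ w[cols] if len(cols) else 0.0
                X[:, i] = np.exp(lam0[i] + contrib + node_noise[:, i])
        b = beta.copy()
        if blocked is not None:
            b[blocked] = 0.0
        P = np.exp(beta0 + np.log(X) @ b + fate_noise) + epsilon
        names = tuple(f"prot{j}" for j in range(n))
        df = pd.DataFrame(X, columns=list(names))
        df["death"] = P
        return ObservationTable(df, names, ("death",))

    return assemble(None), assemble(blocked_node)


DEFAULT_CASCADE_PARAMS = {
    "stimulus": 1.0,   # extracellular death-ligand dose (a.u.)
    "k_r": 0.8,        # receptor activation rate (1/h per unit stimulus)
    "d_r": 0.1,        # receptor deactivation rate (1/h)
    "k_c8": 1.0,       # initiator caspase activation by receptor (1/h)
    "d_c8": 0.2,
    "k_c3": 1.2,       # effector caspase activation by initiator (1/h)
    "d_c3": 0.2,
    "k_d": 0.6,        # death commitment rate by effector caspase (1/h)
}

CASCADE_SPECIES = ("Receptor", "Casp8", "Casp3", "Death")


def simulate_cascade_ode(params: dict | None = None, t_grid=None) -> pd.DataFrame:
    """Deterministic mass-action apoptosis cascade.

    Receptor engagement drives initiator caspase (Casp8), which drives the
    effector caspase (Casp3); death is the cumulative committed fraction,
    dD/dt = k_d * C3 * (1 - D), hence monotone non-decreasing in time and in
    the stimulus dose.  All species are fractions in [0, 1].
    """
    p = dict(DEFAULT_CASCADE_PARAMS)
    if params:
        p.update(params)
    if any(v < 0 for v in p.values()):
        raise ValueError("rates must be non-negative")
    if t_grid is None:
        t_grid = np.linspace(0.0, 20.0, 100)
    t_grid = np.asarray(t_grid, dtype=float)
    if (np.diff(t_grid) <= 0).any():
        raise ValueError("t_grid must be strictly increasing")

    def rhs(_t, y):
        r, c8, c3, d = y
        return [
            p["k_r"] * p["stimulus"] * (1 - r) - p["d_r"] * r,
            p["k_c8"] * r * (1 - c8) - p["d_c8"] * c8,
            p["k_c3"] * c8 * (1 - c3) - p["d_c3"] * c3,
            p["k_d"] * c3 * (1 - d),
        ]

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [0.0, 0.0, 0.0, 0.0],
                    t_eval=t_grid, rtol=1e-8, atol=1e-10, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return pd.DataFrame(sol.y.T, columns=list(CASCADE_SPECIES),
                        index=pd.Index(t_grid, name="time"))


def subsample_every(trajectories: pd.DataFrame, step: int) -> pd.DataFrame:
    """Keep every ``step``-th row (the every-200th-of-20000 selection)."""
    if step < 1:
        raise ValueError("step must be >= 1")
    return trajectories.iloc[step - 1 :: step]


def trajectories_to_table(
    trajectories: pd.DataFrame,
    fate_column: str,
    floor: float = 1e-9,
) -> ObservationTable:
    """View simulator trajectories as an observation table.

    ``fate_column`` becomes the fate; every other column a signal.  Values
    are floored at ``floor`` so the table is usable by the power-law model
    (which needs strictly positive values) without a separate filter pass.
    """
    if fate_column not in trajectories.columns:
        raise ValueError(f"unknown fate column {fate_column!r}")
    df = trajectories.clip(lower=floor).reset_index()
    time_col = df.columns[0]
    df = df.rename(columns={time_col: "time_point"})
    signals = tuple(c for c in trajectories.columns if c != fate_column)
    return ObservationTable(df, signals, (fate_column,),
                            metadata_names=("time_point",))
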