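"""Toggle-switch + repressilator model of inducible miR-520c-3p expression.

The circuit couples a three-gene repressor ring (repressor1 -| repressor2 -|
LacR -| repressor1) to a Lac-operon style output stage: active (IPTG-free)
LacR represses a single promoter transcribing miR-520c-3p and GFP together,
and IPTG sequesters LacR by instantaneous equilibrium binding, flipping the
output ON.  Each gene follows

    d[x]/dt = alpha0 + alpha * Kd^n / (Kd^n + [repressor_free]^n) - delta*[x]

with free LacR = LacR_total / (1 + (IPTG/K_I)^h).  Trajectories report the
*active* (free) LacR concentration - the quantity the downstream readouts
(binarization, network inference) respond to; total LacR is internal
bookkeeping.

Ring operators are weak (Kd = 100) and the LacR operator on the output
promoter tight (Kd = 1): with the nominal rates (alpha = 50, alpha0 = 0.05,
n = 2, delta = 1) this makes the composite circuit monostable per input
level rather than oscillatory, giving the clean two-state (OFF with LacR
active / ON with miR+GFP high) switching behaviour the design targets.

The qualitative stage binarizes trajectories at per-species midrange
thresholds, infers a synchronous Boolean network by exhaustive best-fit
truth-table search, and enumerates attractors with basin sizes over the
full state space per frozen input condition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

SPECIES = ("repressor1", "repressor2", "lacR", "mir520c", "gfp")
INPUTS = ("iptg",)

THETA_LOW = 0.1
THETA_HIGH = 0.5


@dataclass(frozen=True)
class GeneParams:
    """Promoter/decay parameters of one gene; ``kd`` is the dissociation
    constant of the repressor acting on this gene's promoter."""
    alpha: float = 50.0
    alpha0: float = 0.05
    n: float = 2.0
    kd: float = 10.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha0", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")
        if self.kd <= 0:
            raise ValueError("Kd must be > 0")

    def hill(self, repressor: float) -> float:
        return self.kd ** self.n / (self.kd ** self.n + max(repressor, 0.0) ** self.n)


@dataclass(frozen=True)
class CircuitModel:
    genes: dict[str, GeneParams] = field(default_factory=dict)
    k_iptg: float = 1.0
    h: float = 2.0

    def __post_init__(self) -> None:
        if self.k_iptg <= 0:
            raise ValueError("K_I must be > 0")
        if self.h < 1:
            raise ValueError("IPTG cooperativity h must be >= 1")
        missing = set(SPECIES) - set(self.genes)
        if missing:
            raise ValueError(f"missing gene parameters for {sorted(missing)}")

    def free_lacr(self, lacr_total: float, iptg: float) -> float:
        return lacr_total / (1.0 + (max(iptg, 0.0) / self.k_iptg) ** self.h)


def build_default_circuit(overrides: Mapping[str, Mapping[str, float]] | None = None,
                          k_iptg: float = 1.0, h: float = 2.0) -> CircuitModel:
    """The default five-gene circuit (weak ring, tight output operator).

    ``overrides`` maps species name -> GeneParams fields to replace, e.g.
    ``{"gfp": {"delta": 0.5}}``.
    """
    genes = {
        "repressor1": GeneParams(kd=100.0),
        "repressor2": GeneParams(kd=100.0),
        "lacR": GeneParams(kd=100.0),
        "mir520c": GeneParams(kd=1.0),
        "gfp": GeneParams(kd=1.0),
    }
    for name, fields_ in (overrides or {}).items():
        if name not in genes:
            raise ValueError(f"unknown species {name!r}")
        genes[name] = replace(genes[name], **dict(fields_))
    return CircuitModel(genes=genes, k_iptg=k_iptg, h=h)


@dataclass
class Trajectory:
    """Sampled concentrations: ``data`` has one column per species (lacR =
    free/active LacR), on a strictly increasing time grid."""
    time: np.ndarray
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.time)


def _rhs(model: CircuitModel):
    g = model.genes

    def fn(t, y, iptg):
        r1, r2, lac_tot, mir, gfp = y
        lac_free = model.free_lacr(lac_tot, iptg)
        return [
            g["repressor1"].alpha0 + g["repressor1"].alpha * g["repressor1"].hill(lac_free) - g["repressor1"].delta * r1,
            g["repressor2"].alpha0 + g["repressor2"].alpha * g["repressor2"].hill(r1) - g["repressor2"].delta * r2,
            g["lacR"].alpha0 + g["lacR"].alpha * g["lacR"].hill(r2) - g["lacR"].delta * lac_tot,
            g["mir520c"].alpha0 + g["mir520c"].alpha * g["mir520c"].hill(lac_free) - g["mir520c"].delta * mir,
            g["gfp"].alpha0 + g["gfp"].alpha * g["gfp"].hill(lac_free) - g["gfp"].delta * gfp,
        ]

    return fn


def _integrate(model: CircuitModel, t_span, t_eval, y0, iptg, rtol) -> np.ndarray:
    sol = solve_ivp(_rhs(model), t_span, y0, t_eval=t_eval, args=(iptg,),
                    method="LSODA", rtol=rtol, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T          # (time, species), raw (lacR = total)


def _report(model: CircuitModel, times: np.ndarray, raw: np.ndarray,
            iptg_per_point: np.ndarray, metadata: dict) -> Trajectory:
    out = raw.copy()
    out[:, 2] = [model.free_lacr(tot, i) for tot, i in zip(raw[:, 2], iptg_per_point)]
    out = np.clip(out, 0.0, None)
    df = pd.DataFrame(out, columns=list(SPECIES))
    df["iptg"] = iptg_per_point
    return Trajectory(time=times, data=df, metadata=metadata)


def simulate(model: CircuitModel, t_end: float = 100.0, n_points: int = 100,
             initial: Sequence[float] | None = None, iptg: float = 0.0,
             rtol: float = 1e-8) -> Trajectory:
    """Deterministic simulation sampled at ``n_points`` equally spaced times."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    y0 = np.zeros(len(SPECIES)) if initial is None else np.asarray(initial, float)
    times = np.linspace(0.0, t_end, n_points)
    raw = _integrate(model, (0.0, t_end), times, y0, iptg, rtol)
    return _report(model, times, raw, np.full(n_points, float(iptg)),
                   {"iptg": iptg, "rtol": rtol, "case": None})


def simulate_switch(model: CircuitModel, t_end: float = 100.0, n_points: int = 100,
                    t_switch: float | None = None, iptg_off: float = 0.0,
                    iptg_on: float | None = None, rtol: float = 1e-8) -> Trajectory:
    """One trajectory spanning an OFF-to-ON IPTG step at ``t_switch``
    (default: midpoint)."""
    if t_switch is None:
        t_switch = t_end / 2.0
    if not 0.0 < t_switch < t_end:
        raise ValueError("t_switch must lie inside (0, t_end)")
    if iptg_on is None:
        iptg_on = 100.0 * model.k_iptg
    times = np.linspace(0.0, t_end, n_points)
    first = times <= t_switch
    y0 = np.zeros(len(SPECIES))
    eval1 = np.append(times[first], t_switch)
    raw1 = _integrate(model, (0.0, t_switch), eval1, y0, iptg_off, rtol)
    raw2 = _integrate(model, (t_switch, t_end), np.append(t_switch, times[~first]),
                      raw1[-1], iptg_on, rtol)
    raw = np.vstack([raw1[:-1], raw2[1:]])
    iptg_col = np.where(first, iptg_off, iptg_on)
    return _report(model, times, raw, iptg_col,
                   {"iptg_off": iptg_off, "iptg_on": iptg_on,
                    "t_switch": t_switch, "rtol": rtol, "case": "switch"})


# ---------------------------------------------------------------------------
# ON/OFF case analysis
# ---------------------------------------------------------------------------

def run_case(model: CircuitModel, case: str, *, t_end: float = 100.0,
             n_points: int = 100, theta_low: float = THETA_LOW,
             theta_high: float = THETA_HIGH) -> tuple[Trajectory, str]:
    """Simulate one induction case and label the steady state.

    ``off_case1``: IPTG = 0 (LacR fully active); OFF when steady GFP <
    theta_low * alpha/delta.  ``on_case2``: IPTG = 100*K_I; ON when steady
    GFP > theta_high * alpha/delta.  An in-between steady level returns the
    explicit label "indeterminate".
    """
    if theta_low > theta_high:
        raise ValueError("theta_low must be <= theta_high")
    if case == "off_case1":
        iptg = 0.0
    elif case == "on_case2":
        iptg = 100.0 * model.k_iptg
    else:
        raise ValueError(f"unknown case {case!r}")
    traj = simulate(model, t_end=t_end, n_points=n_points, iptg=iptg)
    gp = model.genes["gfp"]
    scale = gp.alpha / gp.delta
    steady = float(traj.data["gfp"].iloc[-1])
    if steady < theta_low * scale:
        label = "OFF"
    elif steady > theta_high * scale:
        label = "ON"
    else:
        label = "indeterminate"
    traj.metadata["case"] = case
    traj.metadata["steady_gfp"] = steady
    return traj, label


def steady_state(model: CircuitModel, iptg: float = 0.0,
                 t_end: float = 400.0) -> dict[str, float]:
    traj = simulate(model, t_end=t_end, n_points=50, iptg=iptg)
    return {s: float(traj.data[s].iloc[-1]) for s in SPECIES}


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def binarize(traj: Trajectory | pd.DataFrame,
             thresholds: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Per-species midrange binarization: threshold = (min+max)/2.

    Species whose range is below 1e-9 * max are treated as constant at their
    rounded level (clipped to {0, 1}).  Explicit ``thresholds`` override the
    midrange rule (used for joint binarization of several runs).
    """
    df = traj.data if isinstance(traj, Trajectory) else traj
    if len(df) < 2:
        raise ValueError("need at least 2 time points")
    out = {}
    for col in df.columns:
        x = df[col].to_numpy(float)
        if thresholds is not None and col in thresholds:
            out[col] = (x > thresholds[col]).astype(int)
            continue
        lo, hi = x.min(), x.max()
        if hi - lo < 1e-9 * max(abs(hi), 1e-300):
            out[col] = np.full(len(x), int(np.clip(round(x[0]), 0, 1)))
        else:
            out[col] = (x > (lo + hi) / 2.0).astype(int)
    return pd.DataFrame(out, columns=df.columns)


def binarize_runs(trajs: Sequence[Trajectory]) -> list[pd.DataFrame]:
    """Binarize several runs against shared (global midrange) thresholds so
    states are comparable across conditions."""
    if not trajs:
        raise ValueError("no trajectories given")
    stacked = pd.concat([t.data for t in trajs], ignore_index=True)
    thresholds = {}
    for col in stacked.columns:
        x = stacked[col].to_numpy(float)
        lo, hi = x.min(), x.max()
        thresholds[col] = (lo + hi) / 2.0 if hi - lo >= 1e-9 * max(abs(hi), 1e-300) else max(abs(hi), 1.0)
    return [binarize(t, thresholds=thresholds) for t in trajs]


# ---------------------------------------------------------------------------
# Boolean best-fit and attractors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanRule:
    inputs: tuple[str, ...]
    table: tuple[int, ...]        # indexed by input bits, first input most significant

    def evaluate(self, state: Mapping[str, int]) -> int:
        idx = 0
        for name in self.inputs:
            idx = (idx << 1) | int(state[name])
        return self.table[idx]


@dataclass(frozen=True)
class BooleanNetwork:
    variables: tuple[str, ...]
    externals: tuple[str, ...]
    rules: dict[str, BooleanRule]

    def step(self, state: Mapping[str, int]) -> dict[str, int]:
        return {v: self.rules[v].evaluate(state) for v in self.variables}


@dataclass(frozen=True)
class Attractor:
    states: tuple[tuple[int, ...], ...]   # cycle, canonical rotation
    basin: int

    @property
    def length(self) -> int:
        return len(self.states)


def bestfit_boolean(series: Sequence[pd.DataFrame] | pd.DataFrame,
                    variables: Sequence[str] | None = None,
                    externals: Sequence[str] = (), max_inputs: int = 3) -> BooleanNetwork:
    """Exhaustive best-fit Boolean network from binary time series.

    ``series`` is one binary DataFrame or a list of runs (transitions are
    counted within each run only).  For every variable all input sets of
    size <= max_inputs over variables + externals are searched; the winning
    truth table minimizes transition mismatches, with ties broken by fewer
    inputs, then lexicographically smallest input index set, then fewest
    1-entries.  Unobserved input combinations map to 0.
    """
    runs = [series] if isinstance(series, pd.DataFrame) else list(series)
    if not runs or any(len(r) < 2 for r in runs):
        raise ValueError("each run needs at least 2 time points")
    cols = list(runs[0].columns)
    externals = tuple(externals)
    if variables is None:
        variables = tuple(c for c in cols if c not in externals)
    else:
        variables = tuple(variables)
    if max_inputs < 1:
        raise ValueError("max_inputs must be >= 1")
    max_inputs = min(max_inputs, len(cols))

    col_index = {c: i for i, c in enumerate(cols)}
    rules: dict[str, BooleanRule] = {}
    for var in variables:
        best = None
        for k in range(0, max_inputs + 1):
            for combo in itertools.combinations(cols, k):
                counts: dict[tuple[int, ...], list[int]] = {}
                for run in runs:
                    arr = run.to_numpy(int)
                    vi = col_index[var]
                    ci = [col_index[c] for c in combo]
                    for t in range(len(arr) - 1):
                        key = tuple(arr[t, j] for j in ci)
                        nxt = arr[t + 1, vi]
                        counts.setdefault(key, [0, 0])[nxt] += 1
                table = []
                mismatches = 0
                ones = 0
                for idx in range(2 ** k):
                    bits = tuple((idx >> (k - 1 - j)) & 1 for j in range(k))
                    c0, c1 = counts.get(bits, [0, 0])
                    # majority vote; ties and unobserved combos go to 0
                    out = 1 if c1 > c0 else 0
                    mismatches += c0 if out == 1 else c1
                    ones += out
                    table.append(out)
                key = (mismatches, k, tuple(col_index[c] for c in combo), ones)
                if best is None or key < best[0]:
                    best = (key, combo, tuple(table))
        rules[var] = BooleanRule(inputs=best[1], table=best[2])
    return BooleanNetwork(variables=variables, externals=externals, rules=rules)


def attractors(bn: BooleanNetwork, frozen_inputs: Mapping[str, int] | None = None) -> list[Attractor]:
    """Exhaustive synchronous attractor enumeration with basin sizes.

    External inputs must be frozen; the union of basins equals the state
    space size 2^|variables|.  Capacity-guarded at 2^20 states.
    """
    frozen = dict(frozen_inputs or {})
    missing = set(bn.externals) - set(frozen)
    if missing:
        raise ValueError(f"external inputs must be frozen: {sorted(missing)}")
    n = len(bn.variables)
    if 2 ** n > 2 ** 20:
        raise ValueError("state space exceeds exhaustive-mode capacity (2^20); "
                         "reduce the network or sample instead")

    def step_idx(idx: int) -> int:
        state = {v: (idx >> (n - 1 - i)) & 1 for i, v in enumerate(bn.variables)}
        state.update(frozen)
        nxt = bn.step(state)
        out = 0
        for v in bn.variables:
            out = (out << 1) | nxt[v]
        return out

    succ = [step_idx(i) for i in range(2 ** n)]
    attr_of = [-1] * len(succ)              # state -> attractor id
    cycles: list[tuple[int, ...]] = []
    for start in range(len(succ)):
        if attr_of[start] >= 0:
            continue
        path = []
        seen_at = {}
        v = start
        while attr_of[v] < 0 and v not in seen_at:
            seen_at[v] = len(path)
            path.append(v)
            v = succ[v]
        if attr_of[v] >= 0:
            aid = attr_of[v]
        else:
            cyc = tuple(path[seen_at[v]:])
            k = cyc.index(min(cyc))
            cycles.append(cyc[k:] + cyc[:k])
            aid = len(cycles) - 1
        for u in path:
            attr_of[u] = aid

    basins = [0] * len(cycles)
    for aid in attr_of:
        basins[aid] += 1

    def unpack(idx: int) -> tuple[int, ...]:
        return tuple((idx >> (n - 1 - i)) & 1 for i in range(n))

    result = [Attractor(states=tuple(unpack(s) for s in cyc), basin=b)
              for cyc, b in zip(cycles, basins)]
    result.sort(key=lambda a: a.states[0])
    return result


def two_condition_attractors(model: CircuitModel, *, t_end: float = 100.0,
                             n_points: int = 100, max_inputs: int = 3
                             ) -> dict[int, list[Attractor]]:
    """Full qualitative validation chain: simulate both induction cases,
    binarize jointly, fit the Boolean network, enumerate attractors per
    frozen IPTG level.  Returns {0: attractors at IPTG low, 1: at IPTG high}."""
    off, _ = run_case(model, "off_case1", t_end=t_end, n_points=n_points)
    on, _ = run_case(model, "on_case2", t_end=t_end, n_points=n_points)
    runs = binarize_runs([off, on])
    bn = bestfit_boolean(runs, variables=SPECIES, externals=INPUTS,
                         max_inputs=max_inputs)
    return {lvl: attractors(bn, frozen_inputs={"iptg": lvl}) for lvl in (0, 1)}
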