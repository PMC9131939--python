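"""Seeded synthetic-data generators for every input the pipeline consumes.

The study's own 91-miRNA network, sequencing data and expression profiles
are not deposited anywhere, so these generators emulate the *printed* scale
and structure of those inputs with known ground truth: a bipartite
miRNA-target network at the 804-node / 1278-edge scale with heavy-tailed
target degrees; UTR sequences with implanted seed sites of known type and
coordinates (guaranteed free of spurious sites); two-class expression
matrices with one known enriched gene set; and circuit time series (clean
or with Gaussian observation noise) from the ODE model.

Every generator is a pure function of its arguments including the seed:
the same call yields byte-identical output, and all draws flow from one
seeded NumPy generator per call.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import circuit as _circuit
from . import seedmatch as _seedmatch
from .netcore import BipartiteNetwork

RNA_ALPHABET = ("A", "C", "G", "U")


# ---------------------------------------------------------------------------
# bipartite network
# ---------------------------------------------------------------------------

def make_bipartite_network(n_mirna: int, n_target: int, n_edges: int,
                           degree_skew: float = 1.5, seed: int = 0) -> BipartiteNetwork:
    """Random bipartite miRNA->target network with heavy-tailed target degrees.

    Targets are drawn with weight proportional to rank^(-degree_skew)
    (Zipf-like), miRNAs uniformly; duplicate edges are rejected until
    ``n_edges`` distinct edges exist.  Default scale arguments reproduce the
    804-node / 1278-edge published summary when called as
    ``make_bipartite_network(91, 713, 1278)``.
    """
    if n_mirna < 1 or n_target < 1 or n_edges < 1:
        raise ValueError("counts must be >= 1")
    if n_edges > n_mirna * n_target:
        raise ValueError(f"cannot place {n_edges} distinct edges in a "
                         f"{n_mirna}x{n_target} bipartite graph")
    if degree_skew <= 0:
        raise ValueError("degree_skew must be > 0")
    rng = np.random.default_rng(seed)
    mirnas = [f"m{i + 1:03d}" for i in range(n_mirna)]
    targets = [f"g{i + 1:04d}" for i in range(n_target)]
    weights = np.arange(1, n_target + 1, dtype=float) ** (-degree_skew)
    weights /= weights.sum()

    edges: set[tuple[int, int]] = set()
    ordered: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 200 * n_edges + 1000
    while len(edges) < n_edges and attempts < max_attempts:
        mi = int(rng.integers(n_mirna))
        ti = int(rng.choice(n_target, p=weights))
        attempts += 1
        if (mi, ti) not in edges:
            edges.add((mi, ti))
            ordered.append((mi, ti))
    if len(edges) < n_edges:
        # dense corner: fill deterministically with the missing pairs
        for mi in range(n_mirna):
            for ti in range(n_target):
                if (mi, ti) not in edges:
                    edges.add((mi, ti))
                    ordered.append((mi, ti))
                    if len(edges) == n_edges:
                        break
            if len(edges) == n_edges:
                break
    net = BipartiteNetwork(mirnas=mirnas, targets=targets)
    for mi, ti in ordered:
        net.add_edge(mirnas[mi], targets[ti])
    return net


# ---------------------------------------------------------------------------
# UTR sets with implanted seed sites
# ---------------------------------------------------------------------------

def make_utr_set(n_seqs: int, length_range: tuple[int, int],
                 implant_table: Sequence[tuple[int, int, str]],
                 mirna: _seedmatch.MatureMiRNA, seed: int = 0,
                 max_tries: int = 500) -> tuple[dict[str, str], pd.DataFrame]:
    """Random UTRs with implanted seed sites and an exact truth table.

    ``implant_table`` rows are (0-based sequence index, 1-based start
    position, site type).  Background is uniform A/C/G/U, rejection-sampled
    so that scanning each sequence recovers *exactly* the implanted sites -
    no spurious occurrence of any of the four canonical site types survives.
    Returns ({sequence id: sequence}, truth table with 1-based inclusive
    coordinates).
    """
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    lo, hi = length_range
    if lo < 8 or hi < lo:
        raise ValueError("invalid length range")
    patterns = _seedmatch.seed_patterns(mirna)
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_seqs)

    by_seq: dict[int, list[tuple[int, str]]] = {i: [] for i in range(n_seqs)}
    for si, pos, site_type in implant_table:
        if site_type not in _seedmatch.SITE_TYPES:
            raise ValueError(f"unknown site type {site_type!r}")
        if not 0 <= si < n_seqs:
            raise ValueError(f"sequence index {si} out of range")
        end = pos + _seedmatch.len_of(site_type) - 1
        if pos < 1 or end > lengths[si]:
            raise ValueError(f"implant at {pos} ({site_type}) overflows sequence {si}")
        for p0, t0 in by_seq[si]:
            e0 = p0 + _seedmatch.len_of(t0) - 1
            if pos <= e0 and end >= p0:
                raise ValueError(f"implant collision in sequence {si}: "
                                 f"{pos}-{end} overlaps {p0}-{e0}")
        by_seq[si].append((pos, site_type))

    seqs: dict[str, str] = {}
    rows = []
    for i in range(n_seqs):
        name = f"utr{i + 1:03d}"
        expected = sorted(
            (pos, pos + _seedmatch.len_of(t) - 1, t) for pos, t in by_seq[i])
        for _ in range(max_tries):
            chars = rng.choice(len(RNA_ALPHABET), size=lengths[i])
            seq = list("".join(RNA_ALPHABET[c] for c in chars))
            for pos, site_type in by_seq[i]:
                seq[pos - 1:pos - 1 + len(patterns[site_type])] = patterns[site_type]
            candidate = "".join(seq)
            found = _seedmatch.scan_utr(mirna, candidate, transcript=name,
                                        include_6mer=True, with_features=False)
            if sorted((s.start, s.end, s.site_type) for s in found) == expected:
                seqs[name] = candidate
                rows.extend((name, s, e, t) for s, e, t in expected)
                break
        else:
            raise RuntimeError(f"could not generate a spurious-site-free "
                               f"sequence {name} in {max_tries} tries")
    truth = pd.DataFrame(rows, columns=["seq_id", "start", "end", "site_type"])
    return seqs, truth


# ---------------------------------------------------------------------------
# two-class expression with one enriched set
# ---------------------------------------------------------------------------

def make_expression(n_genes: int, n_samples_per_class: int,
                    enriched_set: Sequence[str] | int | None = None,
                    shift: float = 0.0, sigma: float = 1.0, seed: int = 0,
                    class_names: tuple[str, str] = ("classA", "classB")
                    ) -> tuple[pd.DataFrame, list[str], dict[str, tuple[str, list[str]]]]:
    """Two-class expression matrix with a known enriched gene set.

    Background genes are i.i.d. Normal(0, sigma) in both classes; genes in
    ``enriched_set`` (a list of ids, or an int meaning the first k genes)
    get +``shift`` in class 1.  Returns (genes x samples matrix, per-sample
    labels, GMT-style {set name: (description, members)}).
    """
    if n_samples_per_class < 3:
        raise ValueError("need at least 3 samples per class")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]
    if enriched_set is None:
        members: list[str] = []
    elif isinstance(enriched_set, int):
        if enriched_set > n_genes:
            raise ValueError("enriched set larger than the gene universe")
        members = genes[:enriched_set]
    else:
        members = list(enriched_set)
        if len(set(members)) != len(members):
            raise ValueError("duplicate gene ids in enriched set")
        unknown = set(members) - set(genes)
        if unknown:
            raise ValueError(f"enriched genes outside the universe: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n_cols = 2 * n_samples_per_class
    data = rng.normal(0.0, sigma, size=(n_genes, n_cols))
    member_idx = [genes.index(g) for g in members]
    data[member_idx, :n_samples_per_class] += shift
    cols = ([f"{class_names[0]}_{k + 1}" for k in range(n_samples_per_class)]
            + [f"{class_names[1]}_{k + 1}" for k in range(n_samples_per_class)])
    expr = pd.DataFrame(data, index=genes, columns=cols)
    labels = [class_names[0]] * n_samples_per_class + [class_names[1]] * n_samples_per_class
    gmt = {"ENRICHED_SET": ("synthetic enriched set", members)} if members else {}
    return expr, labels, gmt


def make_gene_sets(universe: Sequence[str], n_sets: int,
                   size_range: tuple[int, int] = (10, 40),
                   seed: int = 0) -> dict[str, tuple[str, list[str]]]:
    """Random annotation (term -> member genes) over a universe, GMT-style."""
    if not universe:
        raise ValueError("empty universe")
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    hi = min(hi, len(universe))
    lo = min(lo, hi)
    out = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(universe), size=size, replace=False)
        out[f"TERM{k + 1:03d}"] = ("synthetic term", sorted(universe[i] for i in idx))
    return out


# ---------------------------------------------------------------------------
# circuit time series
# ---------------------------------------------------------------------------

def make_circuit_series(model: _circuit.CircuitModel | None = None,
                        n_points: int = 100, noise_sigma: float = 0.0,
                        seed: int = 0, *, t_end: float = 100.0,
                        iptg: float = 0.0, switch: bool = False,
                        t_switch: float | None = None) -> _circuit.Trajectory:
    """Deterministic circuit simulation plus i.i.d. Gaussian observation noise.

    With ``switch`` the run spans an OFF-to-ON IPTG step (midpoint by
    default); otherwise IPTG is held at ``iptg``.  noise_sigma = 0
    reproduces the simulator output exactly; two seeds share the clean part
    and differ only in noise.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if model is None:
        model = _circuit.build_default_circuit()
    if switch:
        traj = _circuit.simulate_switch(model, t_end=t_end, n_points=n_points,
                                        t_switch=t_switch)
    else:
        traj = _circuit.simulate(model, t_end=t_end, n_points=n_points, iptg=iptg)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        species = list(_circuit.SPECIES)
        noise = rng.normal(0.0, noise_sigma, size=(len(traj), len(species)))
        traj.data[species] = traj.data[species].to_numpy() + noise
    traj.metadata["noise_sigma"] = noise_sigma
    traj.metadata["seed"] = seed
    return traj


def make_linear_system_series(n_genes: int = 3, edge: tuple[int, int] = (0, 1),
                              coefficient: float = 0.9, noise_sigma: float = 0.1,
                              n_points: int = 100, seed: int = 0) -> pd.DataFrame:
    """Lag-1 linear test system with one true edge for recovery studies.

    Gene ``edge[1]`` follows coefficient * gene ``edge[0]`` at the previous
    time point plus noise; all other genes are independent white noise.
    """
    if not (0 <= edge[0] < n_genes and 0 <= edge[1] < n_genes) or edge[0] == edge[1]:
        raise ValueError("edge endpoints must be distinct valid gene indices")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, size=(n_points, n_genes))
    src, dst = edge
    for t in range(1, n_points):
        x[t, dst] = coefficient * x[t - 1, src] + rng.normal(0.0, noise_sigma)
    return pd.DataFrame(x, columns=[f"g{j}" for j in range(n_genes)])
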