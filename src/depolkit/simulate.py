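"""Seeded generators for every input the analysis stages consume.

All generators are pure functions of (config, seed): sequence evolution along
a tree under the WAG model with optional block deletions, Poisson-arrival
dwell events with frame quantization and movie-end censoring, piecewise
linear depolymerization traces with optional internal breaks, and ATPase
progress curves in both assay modes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError
from .kinetics import (
    ATPaseAssay,
    BreakRecord,
    DwellEvent,
    DwellTimeSet,
    LengthTrace,
    NADH_EXTINCTION,
    DEFAULT_FRAME_RATE,
)
from .model import SubstitutionModel, build_wag, transition_matrix
from .seqio import AA_ALPHABET, GAP, PhyloTree, ProteinAlignment, TreeNode


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for all generators; the seed fixes every output."""

    seed: int = 0
    # sequence evolution
    root_length: int = 350
    root_sequence: str | None = None
    indel_rate: float = 0.0  # block deletions per site-free unit branch length
    mean_deletion_length: float = 3.0
    branch_scale: float = 1.0
    # single-molecule movie
    k_off_end: float = 1.23
    k_off_lattice: float = 1.36
    k_on: float = 62.4  # nM^-1 s^-1 um^-1
    concentration_nM: float = 0.04
    mt_length_um: float = 5.0
    movie_length_s: float = 23.0
    frame_rate_hz: float = DEFAULT_FRAME_RATE
    end_fraction: float = 0.5  # share of arrivals landing at the end
    # depolymerization traces
    v_depol: float = 23.05  # um/min
    initial_length_um: float = 10.0
    trace_interval_s: float = 5.0
    length_noise_um: float = 0.2
    addition_time_s: float = 10.0
    break_rate_per_um: float = 0.0
    # ATPase
    k_atpase: float = 8.07  # s^-1
    motor_uM: float = 0.1
    atpase_mode: str = "nadh_coupled"
    atpase_duration_s: float = 60.0
    atpase_points: int = 13
    signal_noise: float = 0.002  # absorbance units (coupled) or uM (hplc)
    nadh_start_A: float = 1.0
    # replicates
    n_traces: int = 12


# ---------------------------------------------------------------------------
# Fixture trees
# ---------------------------------------------------------------------------


def _balanced_clade(labels: list[str], depth_lengths: list[float], rng) -> TreeNode:
    if len(labels) == 1:
        return TreeNode(label=labels[0], length=_jitter(depth_lengths[0], rng))
    half = len(labels) // 2
    node = TreeNode(length=_jitter(depth_lengths[0], rng))
    node.add_child(_balanced_clade(labels[:half], depth_lengths[1:], rng))
    node.add_child(_balanced_clade(labels[half:], depth_lengths[1:], rng))
    return node


def _jitter(x: float, rng) -> float:
    return float(x * rng.uniform(0.7, 1.3))


def fixture_tree(n_leaves: int = 16, seed: int = 0, scale: float = 1.0) -> PhyloTree:
    """Two-clade fixture tree with mean root-to-tip depth near ``scale``.

    The 16-leaf default mirrors a small A/B split; n_leaves=75 mirrors the
    full-alignment taxon count.
    """
    if n_leaves < 2:
        raise DataError("fixture tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    n_a = n_leaves // 2
    labels_a = [f"A{i + 1}" for i in range(n_a)]
    labels_b = [f"B{i + 1}" for i in range(n_leaves - n_a)]
    root = TreeNode(length=0.0)
    for labels in (labels_a, labels_b):
        depth = max(int(np.ceil(np.log2(max(len(labels), 2)))), 1)
        per_level = 0.8 * scale / (depth + 1)
        lengths = [0.2 * scale + per_level] + [per_level] * depth
        root.add_child(_balanced_clade(labels, lengths, rng))
    return PhyloTree(root)


def scale_branch_lengths(tree: PhyloTree, factor: float) -> PhyloTree:
    out = tree.copy()
    for node in out.postorder():
        node.length *= factor
    return out


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _sample_children(states: np.ndarray, P: np.ndarray, rng) -> np.ndarray:
    out = np.empty_like(states)
    for s in range(P.shape[0]):
        mask = states == s
        k = int(mask.sum())
        if k:
            out[mask] = rng.choice(P.shape[1], size=k, p=P[s])
    return out


def evolve_alignment(
    config: SimulationConfig,
    tree: PhyloTree | None = None,
    model: SubstitutionModel | None = None,
) -> tuple[ProteinAlignment, PhyloTree, str]:
    """Evolve sequences down a tree; returns (alignment, tree, root truth).

    Sites evolve independently by sampling rows of P(t); an optional indel
    process deletes contiguous blocks (Poisson per branch, geometric block
    length), and deletions are inherited by descendants.  Without insertions
    the alignment columns correspond one-to-one to root positions.
    """
    if config.root_length < 1 and not config.root_sequence:
        raise DataError("root sequence length must be positive")
    rng = np.random.default_rng(config.seed)
    model = model or build_wag()
    tree = tree or fixture_tree(seed=config.seed)
    if config.branch_scale != 1.0:
        tree = scale_branch_lengths(tree, config.branch_scale)
    if config.root_sequence:
        root_states = np.array(
            [AA_ALPHABET.index(c) for c in config.root_sequence]
        )
    else:
        root_states = rng.choice(20, size=config.root_length, p=model.pi)
    n = root_states.size

    states: dict[int, np.ndarray] = {tree.root.uid: root_states}
    present: dict[int, np.ndarray] = {tree.root.uid: np.ones(n, dtype=bool)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        P = transition_matrix(model, node.length)
        states[node.uid] = _sample_children(states[node.parent.uid], P, rng)
        mask = present[node.parent.uid].copy()
        if config.indel_rate > 0 and node.length > 0:
            n_del = rng.poisson(config.indel_rate * node.length * n)
            for _ in range(n_del):
                start = rng.integers(0, n)
                length = int(rng.geometric(1.0 / config.mean_deletion_length))
                mask[start : start + length] = False
        present[node.uid] = mask

    names, rows = [], []
    for leaf in tree.leaves():
        s = states[leaf.uid]
        m = present[leaf.uid]
        rows.append(
            "".join(AA_ALPHABET[s[j]] if m[j] else GAP for j in range(n))
        )
        names.append(leaf.label)
    aln = ProteinAlignment(names, rows)
    # drop columns deleted in every leaf (unobservable positions)
    keep = [j for j in range(n) if any(r[j] != GAP for r in rows)]
    if len(keep) < n:
        aln = ProteinAlignment(
            names, ["".join(r[j] for j in keep) for r in rows]
        )
        root_truth = "".join(AA_ALPHABET[root_states[j]] for j in keep)
    else:
        root_truth = "".join(AA_ALPHABET[s] for s in root_states)
    return aln, tree, root_truth


# ---------------------------------------------------------------------------
# Single-molecule dwells
# ---------------------------------------------------------------------------


def simulate_dwells(config: SimulationConfig) -> DwellTimeSet:
    """Poisson arrivals, exponential residences, frame quantization, censoring."""
    if config.k_off_end <= 0 or config.k_off_lattice <= 0:
        raise DataError("off-rates must be positive")
    rng = np.random.default_rng(config.seed)
    T = config.movie_length_s
    dt = 1.0 / config.frame_rate_hz
    mean_events = (
        config.k_on * config.mt_length_um * config.concentration_nM * T
    )
    n = int(rng.poisson(mean_events)) if T > 0 else 0
    events = []
    for _ in range(n):
        start = rng.uniform(0.0, T)
        at_end = rng.random() < config.end_fraction
        k = config.k_off_end if at_end else config.k_off_lattice
        duration = rng.exponential(1.0 / k)
        censored = start + duration > T
        if censored:
            duration = T - start
        frames = max(int(np.ceil(duration / dt - 1e-12)), 1)
        events.append(
            DwellEvent(frames * dt, "end" if at_end else "lattice", censored)
        )
    return DwellTimeSet(
        tuple(events),
        movie_length_s=T,
        frame_interval_s=dt,
        mt_length_um=config.mt_length_um,
        concentration_nM=config.concentration_nM,
        observation_time_s=T,
    )


# ---------------------------------------------------------------------------
# Depolymerization traces
# ---------------------------------------------------------------------------


def simulate_length_traces(
    config: SimulationConfig,
) -> tuple[list[LengthTrace], list[BreakRecord]]:
    """Linear shrinkage traces with Gaussian length noise, optional breaks."""
    if config.v_depol < 0:
        raise DataError("depolymerization rate must be non-negative")
    rng = np.random.default_rng(config.seed)
    v_um_s = config.v_depol / 60.0
    traces: list[LengthTrace] = []
    breaks: list[BreakRecord] = []
    for i in range(config.n_traces):
        L0 = config.initial_length_um
        t_add = config.addition_time_s
        t_end = t_add + (L0 / v_um_s if v_um_s > 0 else 10 * t_add)
        times = np.arange(0.0, t_end + config.trace_interval_s, config.trace_interval_s)
        true_len = np.where(
            times < t_add, L0, np.maximum(L0 - v_um_s * (times - t_add), 0.0)
        )
        noisy = np.maximum(
            true_len + rng.normal(0.0, config.length_noise_um, times.size), 0.0
        )
        traces.append(
            LengthTrace(
                mt_id=f"mt{i + 1}",
                times_s=tuple(times),
                lengths_um=tuple(noisy),
                addition_time_s=t_add,
                interval_s=config.trace_interval_s,
            )
        )
        n_breaks = (
            int(rng.poisson(config.break_rate_per_um * L0))
            if config.break_rate_per_um > 0
            else 0
        )
        breaks.append(BreakRecord(L0, n_breaks))
    return traces, breaks


# ---------------------------------------------------------------------------
# ATPase progress curves
# ---------------------------------------------------------------------------


def simulate_atpase(config: SimulationConfig) -> ATPaseAssay:
    """[ADP](t) = k * [motor] * t, reported directly or via NADH absorbance."""
    if config.k_atpase < 0:
        raise DataError("ATPase rate must be non-negative")
    rng = np.random.default_rng(config.seed)
    times = np.linspace(0.0, config.atpase_duration_s, config.atpase_points)
    adp_uM = config.k_atpase * config.motor_uM * times
    if config.atpase_mode == "hplc_adp":
        signal = adp_uM + rng.normal(0.0, config.signal_noise, times.size)
    elif config.atpase_mode == "nadh_coupled":
        absorbance = (
            config.nadh_start_A
            - adp_uM * 1e-6 * NADH_EXTINCTION * 1.0
            + rng.normal(0.0, config.signal_noise, times.size)
        )
        signal = absorbance
    else:
        raise DataError(f"unknown atpase_mode {config.atpase_mode!r}")
    return ATPaseAssay(
        mode=config.atpase_mode,
        times_s=tuple(times),
        signal=tuple(signal),
        motor_uM=config.motor_uM,
        extinction_M_cm=NADH_EXTINCTION,
        path_cm=1.0,
    )


# ---------------------------------------------------------------------------
# Published-parameter presets
# ---------------------------------------------------------------------------

#: generating parameters mirroring the reference measurement tables
PAPER_PRESETS: dict[str, SimulationConfig] = {
    "paper-anc13": SimulationConfig(
        v_depol=23.05,
        n_traces=12,
        k_off_end=1.23,
        k_off_lattice=1.36,
        k_on=62.4,
        concentration_nM=0.04,
        k_atpase=8.07,
        motor_uM=0.1,
    ),
    "paper-mcak": SimulationConfig(
        v_depol=2.12,
        n_traces=18,
        k_off_end=0.98,
        k_off_lattice=2.90,
        k_on=0.52,
        concentration_nM=8.0,
        k_atpase=3.69,
        motor_uM=0.1,
    ),
}


def preset(name: str, seed: int = 0) -> SimulationConfig:
    try:
        base = PAPER_PRESETS[name]
    except KeyError:
        raise DataError(f"unknown preset {name!r}") from None
    return replace(base, seed=seed)
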