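"""Consensus grouping by modularity-based community detection.

The consensus step scores a candidate grouping of quotes by weighted
modularity with resolution gamma:

    Q = sum_c [ W_c/(2m) - gamma * (S_c/(2m))^2 ]

where W_c counts intra-community co-occurrence weight in both orders,
S_c is the summed node strength of community c and m the total edge
weight. Maximising Q keeps together the quote pairs most raters grouped
together, while the degree-based null term discounts pairs that co-occur
only because the quotes sit in large groups.

Detection is a two-phase greedy maximisation (Louvain-style): seeded
sweeps of single-node moves until no move improves Q, then aggregation of
communities into super-nodes, repeated to convergence. Tie-breaking and
sweep order are fully determined by the seed, so results are reproducible
bit-for-bit. For networks of at most 12 nodes an exact oracle enumerates
every partition (restricted-growth strings) and returns the global
optimum.

Human-led refinement of the detected grouping (moving quotes, creating or
renaming themes) is recorded action-by-action with rationales in a
:class:`ThemeSet`, so the audit trail from algorithmic output to final
themes is preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .errors import ConfigError, CoverageError, ReferenceError_, SizeError
from .network import CooccurrenceNetwork

_EPS = 1e-12


@dataclass
class ConsensusPartition:
    """A community assignment of quote ids, with its modularity score.

    Community ids are contiguous integers from 1, ordered by descending
    community size (ties: smallest member quote id), so labelling is
    stable across runs.
    """

    assignment: dict[int, int]
    modularity_value: float
    resolution: float
    seed: int
    method: str

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for q, c in self.assignment.items():
            out.setdefault(c, set()).add(q)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignment": {str(q): c for q, c in sorted(self.assignment.items())},
            "n_communities": self.n_communities,
            "modularity": self.modularity_value,
            "resolution": self.resolution,
            "seed": self.seed,
            "method": self.method,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def _canonical_labels(groups: Mapping[int, set[int]]) -> dict[int, int]:
    """Relabel community ids 1..K by descending size, ties by smallest member."""
    order = sorted(groups, key=lambda c: (-len(groups[c]), min(groups[c])))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    out: dict[int, int] = {}
    for c, members in groups.items():
        for q in members:
            out[q] = relabel[c]
    return out


def modularity(
    partition: Mapping[int, int],
    net: CooccurrenceNetwork,
    resolution: float = 1.0,
) -> float:
    """Weighted modularity Q of a partition of the network's nodes.

    ``partition`` must cover every node; by convention Q = 0 when the
    network has no edges (m = 0).
    """
    if resolution <= 0:
        raise ConfigError(f"resolution must be > 0, got {resolution}")
    for node in net.graph.nodes:
        if node not in partition:
            raise CoverageError(f"partition does not cover node {node}")
    m = net.total_weight
    if m == 0:
        return 0.0
    two_m = 2.0 * m
    w_in: dict[int, float] = {}
    s_tot: dict[int, float] = {}
    for node in net.graph.nodes:
        c = partition[node]
        s_tot[c] = s_tot.get(c, 0.0) + net.strength(node)
        w_in.setdefault(c, 0.0)
    for i, j, d in net.graph.edges(data=True):
        if partition[i] == partition[j]:
            w_in[partition[i]] += 2.0 * d["weight"]
    return sum(
        w_in[c] / two_m - resolution * (s_tot[c] / two_m) ** 2 for c in s_tot
    )


# ---------------------------------------------------------------------------
# greedy two-phase detection
# ---------------------------------------------------------------------------


def _local_move_phase(
    nodes: list,
    adj: dict,
    loops: dict,
    strength: dict,
    two_m: float,
    resolution: float,
    rng: np.random.Generator,
) -> dict:
    """Sweep seeded-random node orders, greedily moving nodes between
    communities until no single move improves Q. Returns node -> community.

    Communities are keyed by their founding node's index so that "lowest
    community id wins" is a deterministic tie-break.
    """
    index = {v: i for i, v in enumerate(nodes)}
    comm = {v: index[v] for v in nodes}
    tot = {index[v]: float(strength[v]) for v in nodes}
    next_comm_id = len(nodes)

    improved = True
    while improved:
        improved = False
        order = rng.permutation(len(nodes))
        for pos in order:
            v = nodes[pos]
            a = comm[v]
            s_v = float(strength[v])
            # weight from v to each neighbouring community (single order)
            k = {}
            for u, w in adj[v].items():
                if u is v or u == v:
                    continue
                k[comm[u]] = k.get(comm[u], 0.0) + w
            k_a = k.get(a, 0.0)
            remove_cost = -k_a / two_m + resolution * s_v * (tot[a] - s_v) / (
                two_m * two_m
            )
            best_gain = _EPS
            best_comm = None
            for b in sorted(k):
                if b == a:
                    continue
                gain = remove_cost + k[b] / two_m - resolution * s_v * tot[b] / (
                    two_m * two_m
                )
                if gain > best_gain + _EPS:
                    best_gain = gain
                    best_comm = b
            # detaching into a brand-new community (helps weakly attached nodes)
            detach_gain = remove_cost
            if detach_gain > best_gain + _EPS and (tot[a] - s_v) > 0:
                best_gain = detach_gain
                best_comm = -1
            if best_comm is not None:
                tot[a] -= s_v
                if best_comm == -1:
                    best_comm = next_comm_id
                    next_comm_id += 1
                    tot[best_comm] = 0.0
                comm[v] = best_comm
                tot[best_comm] = tot.get(best_comm, 0.0) + s_v
                improved = True
    return comm


def detect_communities(
    net: CooccurrenceNetwork,
    resolution: float = 1.0,
    seed: int = 0,
) -> ConsensusPartition:
    """Greedy two-phase modularity maximisation over the weighted network.

    Deterministic given (network, resolution, seed). Isolated quotes end
    as singleton communities; with no edges at all (m = 0) the
    all-singletons partition is returned with Q = 0.
    """
    if resolution <= 0:
        raise ConfigError(f"resolution must be > 0, got {resolution}")
    if net.n_nodes == 0:
        raise ConfigError("cannot detect communities in an empty network")
    rng = np.random.default_rng(seed)
    quote_ids = net.node_ids
    m = net.total_weight
    if m == 0:
        assignment = _canonical_labels({i: {q} for i, q in enumerate(quote_ids)})
        return ConsensusPartition(assignment, 0.0, resolution, seed, "greedy-two-phase")
    two_m = 2.0 * m

    # level-0 graph state: membership maps each current super-node to the
    # original quote ids it contains
    nodes: list[int] = list(quote_ids)
    membership: dict[int, set[int]] = {v: {v} for v in quote_ids}
    adj: dict[int, dict[int, float]] = {v: {} for v in nodes}
    for i, j, d in net.graph.edges(data=True):
        adj[i][j] = float(d["weight"])
        adj[j][i] = float(d["weight"])
    loops: dict[int, float] = {v: 0.0 for v in nodes}
    strength: dict[int, float] = {
        v: loops[v] + sum(adj[v].values()) for v in nodes
    }

    while True:
        comm = _local_move_phase(nodes, adj, loops, strength, two_m, resolution, rng)
        groups: dict[int, list] = {}
        for v in nodes:
            groups.setdefault(comm[v], []).append(v)
        if len(groups) == len(nodes):
            break  # no merges: converged
        # aggregate each community into a super-node
        new_nodes = []
        new_membership: dict[int, set[int]] = {}
        new_adj: dict[int, dict[int, float]] = {}
        new_loops: dict[int, float] = {}
        for idx, c in enumerate(sorted(groups)):
            members = groups[c]
            new_membership[idx] = set().union(*(membership[v] for v in members))
            new_nodes.append(idx)
        node_to_new = {}
        for idx, c in enumerate(sorted(groups)):
            for v in groups[c]:
                node_to_new[v] = idx
        for idx in new_nodes:
            new_adj[idx] = {}
            new_loops[idx] = 0.0
        for idx, c in enumerate(sorted(groups)):
            for v in groups[c]:
                new_loops[idx] += loops[v]
                for u, w in adj[v].items():
                    tgt = node_to_new[u]
                    if tgt == idx:
                        new_loops[idx] += w  # both orders accumulate over v,u
                    else:
                        new_adj[idx][tgt] = new_adj[idx].get(tgt, 0.0) + w
        nodes = new_nodes
        membership = new_membership
        adj = new_adj
        loops = new_loops
        strength = {v: loops[v] + sum(adj[v].values()) for v in nodes}

    final_groups = {}
    for v in nodes:
        final_groups[v] = membership[v]
    # merge super-nodes sharing a community label from the last (no-merge) phase
    # (len(groups) == len(nodes) means each is its own community already)
    assignment = _canonical_labels(final_groups)
    q = modularity(assignment, net, resolution)
    return ConsensusPartition(assignment, q, resolution, seed, "greedy-two-phase")


# ---------------------------------------------------------------------------
# exact oracle
# ---------------------------------------------------------------------------


def _restricted_growth_strings(n: int):
    """Yield all set partitions of range(n) as label arrays, lex order."""
    labels = [0] * n
    maxes = [0] * n

    def rec(i: int):
        if i == n:
            yield list(labels)
            return
        for c in range(maxes[i - 1] + 2 if i else 1):
            labels[i] = c
            maxes[i] = max(maxes[i - 1], c) if i else 0
            yield from rec(i + 1)

    yield from rec(0)


def exact_max_modularity(
    net: CooccurrenceNetwork, resolution: float = 1.0
) -> ConsensusPartition:
    """Globally optimal partition by exhaustive enumeration (<= 12 nodes).

    Every set partition is scored; ties go to the lexicographically
    smallest restricted-growth string. Intended as a validation oracle for
    the greedy detector, not for production-size networks.
    """
    if resolution <= 0:
        raise ConfigError(f"resolution must be > 0, got {resolution}")
    n = net.n_nodes
    if n == 0:
        raise ConfigError("cannot optimise an empty network")
    if n > 12:
        raise SizeError(f"exact enumeration limited to 12 nodes, got {n}")
    quote_ids = net.node_ids
    m = net.total_weight
    if m == 0:
        assignment = _canonical_labels({i: {q} for i, q in enumerate(quote_ids)})
        return ConsensusPartition(assignment, 0.0, resolution, 0, "exact")
    two_m = 2.0 * m
    w = np.zeros((n, n))
    pos = {q: i for i, q in enumerate(quote_ids)}
    for i, j, d in net.graph.edges(data=True):
        w[pos[i], pos[j]] = w[pos[j], pos[i]] = d["weight"]
    s = w.sum(axis=1)
    b = (w - resolution * np.outer(s, s) / two_m) / two_m

    best_q = -np.inf
    best_labels: list[int] | None = None
    chunk: list[list[int]] = []

    def flush():
        nonlocal best_q, best_labels
        if not chunk:
            return
        lab = np.asarray(chunk, dtype=np.int8)
        same = lab[:, :, None] == lab[:, None, :]
        qs = np.einsum("bij,ij->b", same, b)
        k = int(np.argmax(qs))  # first max: lex-smallest RGS wins ties
        if qs[k] > best_q + _EPS:
            best_q = float(qs[k])
            best_labels = chunk[k]
        chunk.clear()

    for labels in _restricted_growth_strings(n):
        chunk.append(labels)
        if len(chunk) >= 8192:
            flush()
    flush()

    assert best_labels is not None
    groups: dict[int, set[int]] = {}
    for i, c in enumerate(best_labels):
        groups.setdefault(c, set()).add(quote_ids[i])
    assignment = _canonical_labels(groups)
    q = modularity(assignment, net, resolution)
    return ConsensusPartition(assignment, q, resolution, 0, "exact")


# ---------------------------------------------------------------------------
# refinement bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CreateTheme:
    label: str
    rationale: str = ""


@dataclass(frozen=True)
class MoveQuote:
    quote_id: int
    to_theme: str
    rationale: str = ""


@dataclass(frozen=True)
class RenameTheme:
    old_label: str
    new_label: str
    rationale: str = ""


@dataclass(frozen=True)
class RetainTheme:
    """Mark a theme as kept in the output even if later emptied."""

    label: str
    rationale: str = ""


RefinementAction = Union[CreateTheme, MoveQuote, RenameTheme, RetainTheme]


@dataclass
class ThemeSet:
    """Final named themes with the ordered provenance of every edit."""

    themes: dict[str, set[int]]
    provenance: list[RefinementAction] = field(default_factory=list)
    modularity_value: float | None = None

    @property
    def assignment(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for label, members in self.themes.items():
            for q in members:
                out[q] = label
        return out

    @property
    def n_themes(self) -> int:
        return len(self.themes)

    def covered(self) -> set[int]:
        return set(self.assignment)

    def to_csv(self, path: str | Path) -> None:
        import csv as _csv

        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = _csv.writer(fh, lineterminator="\n")
            writer.writerow(["quote_id", "theme_label"])
            for q, label in sorted(self.assignment.items()):
                writer.writerow([q, label])

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {
            "themes": {
                label: sorted(members) for label, members in self.themes.items()
            },
            "provenance": [
                {"action": type(a).__name__, **a.__dict__} for a in self.provenance
            ],
            "modularity": self.modularity_value,
            **extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def theme_set_from_partition(
    partition: ConsensusPartition, label_format: str = "Group {i}"
) -> ThemeSet:
    """Default labelling of detected communities: "Group 1".."Group K"."""
    comms = partition.communities()
    themes = {
        label_format.format(i=c): set(members) for c, members in sorted(comms.items())
    }
    return ThemeSet(themes=themes)


def apply_refinement(
    base: ConsensusPartition,
    actions: Sequence[RefinementAction],
    net: CooccurrenceNetwork | None = None,
) -> ThemeSet:
    """Apply recorded human edits to a detected partition.

    The result partitions exactly the quote set of ``base``; every action
    is kept, in order, in the provenance list. A theme emptied by moves is
    dropped unless a :class:`RetainTheme` action marked it kept. When the
    network is supplied, the modularity of the refined grouping is
    recomputed and stored (it may be lower than the detected optimum —
    refinement is human-led).
    """
    ts = theme_set_from_partition(base)
    retained: set[str] = set()
    for action in actions:
        if isinstance(action, CreateTheme):
            if action.label in ts.themes:
                raise ReferenceError_(f"theme {action.label!r} already exists")
            ts.themes[action.label] = set()
            retained.add(action.label)
        elif isinstance(action, RetainTheme):
            if action.label not in ts.themes:
                raise ReferenceError_(f"cannot retain unknown theme {action.label!r}")
            retained.add(action.label)
        elif isinstance(action, RenameTheme):
            if action.old_label not in ts.themes:
                raise ReferenceError_(f"cannot rename unknown theme {action.old_label!r}")
            if action.new_label in ts.themes:
                raise ReferenceError_(f"theme {action.new_label!r} already exists")
            ts.themes[action.new_label] = ts.themes.pop(action.old_label)
            if action.old_label in retained:
                retained.discard(action.old_label)
                retained.add(action.new_label)
        elif isinstance(action, MoveQuote):
            if action.to_theme not in ts.themes:
                raise ReferenceError_(
                    f"cannot move quote {action.quote_id} to unknown theme "
                    f"{action.to_theme!r} (create it first)"
                )
            src = None
            for label, members in ts.themes.items():
                if action.quote_id in members:
                    src = label
                    break
            if src is None:
                raise ReferenceError_(f"unknown quote id {action.quote_id}")
            if src != action.to_theme:
                ts.themes[src].discard(action.quote_id)
                ts.themes[action.to_theme].add(action.quote_id)
                if not ts.themes[src] and src not in retained:
                    del ts.themes[src]
        else:
            raise ConfigError(f"unknown refinement action {action!r}")
        ts.provenance.append(action)
    # empty created themes that never received quotes stay (they are retained)
    if net is not None:
        labels = {label: i + 1 for i, label in enumerate(ts.themes)}
        assignment = {q: labels[lab] for q, lab in ts.assignment.items()}
        ts.modularity_value = modularity(assignment, net, base.resolution)
    return ts
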