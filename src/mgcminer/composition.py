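"""Magnetite-vs-greigite composition prediction from Mam-protein distances.

Genomes from phyla where magnetotactic bacteria were never seen before
carry no mineralogical record, but the distances among their concatenated
essential Mam proteins (the six-family MamA/B/K/M/P/Q set by convention) do
carry a signal: ordinating the distance matrix by principal coordinates
(classical multidimensional scaling) and clustering the points recovers a
characteristic three-group structure — one group anchored by known
greigite producers and two groups of magnetite producers. A query genome
inherits the composition label that dominates the labeled members of its
group.

The group→label mapping is entirely data-driven (majority vote of labeled
members); nothing about which group is greigite is hard-coded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

#: The conventional concatenation set for composition prediction.
COMPOSITION_FAMILIES = ("mamA", "mamB", "mamK", "mamM", "mamP", "mamQ")

DEFAULT_K_GROUPS = 3


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix."""

    ids: list[str]
    coordinates: np.ndarray  # (n, k) scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per returned axis, of positive mass
    n_negative: int  # negative eigenvalues (their axes are dropped)


@dataclass
class CompositionPrediction:
    """Predicted magnetosome chemistry for one genome."""

    genome_id: str
    coordinates: tuple[float, ...]
    assigned_group: int
    predicted_label: str
    nearest_labeled_neighbors: list[str]


def _as_dm(dm) -> DistanceMatrix:
    if isinstance(dm, DistanceMatrix):
        return dm
    labels, M = dm
    return DistanceMatrix(np.asarray(M, dtype=float), ids=list(labels))


def principal_coordinates(dm, k: int = 2) -> PcoaResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    The doubly centered Gower matrix ``-1/2 J D^2 J`` is
    eigendecomposed; the top-``k`` positive axes are returned, scaled by the
    square root of their eigenvalues, so Euclidean distances between rows
    approximate the input distances (exactly, for Euclidean input).
    Negative eigenvalues are counted and their axes dropped. The sign
    convention — first nonzero loading of each axis positive — makes the
    embedding deterministic.
    """
    dm = _as_dm(dm)
    n = len(dm.ids)
    if n < 3:
        raise ValueError("principal coordinates need at least 3 points")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}]")
    D2 = dm.data ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(abs(eigvals[0]), 1.0)
    n_negative = int((eigvals < -tol).sum())
    n_positive = int((eigvals > tol).sum())
    axes = min(k, n_positive)
    coords = np.zeros((n, axes))
    for a in range(axes):
        v = eigvecs[:, a] * np.sqrt(eigvals[a])
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if nz.size and v[nz[0]] < 0:
            v = -v
        coords[:, a] = v
    pos_mass = eigvals[:n_positive].sum() if n_positive else 1.0
    prop = eigvals[:axes] / pos_mass if n_positive else np.zeros(0)
    return PcoaResult(list(dm.ids), coords, eigvals, prop, n_negative)


def _k_medoids(points: np.ndarray, k: int, rng: np.random.Generator,
               max_iter: int = 100, n_init: int = 10) -> np.ndarray:
    """Alternating k-medoids on Euclidean distances between rows of
    ``points``, restarted from ``n_init`` seeded initializations (lowest
    total cost wins). Deterministic given the rng state; ties go to the
    lower medoid index."""
    n = points.shape[0]
    D = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    best_assign, best_cost = None, np.inf
    for _ in range(n_init):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        for _ in range(max_iter):
            assign = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for g in range(k):
                members = np.nonzero(assign == g)[0]
                if members.size == 0:
                    continue
                costs = D[np.ix_(members, members)].sum(axis=0)
                new_medoids[g] = members[np.argmin(costs)]
            new_medoids = np.sort(new_medoids)
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
        assign = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), medoids[assign]].sum()
        if cost < best_cost - 1e-12:
            best_assign, best_cost = assign, cost
    return best_assign


def assign_composition(
    dm,
    reference_labels: dict[str, str],
    k_groups: int = DEFAULT_K_GROUPS,
    seed: int | None = 0,
    k_axes: int = 2,
) -> list[CompositionPrediction]:
    """Cluster all genomes in principal-coordinate space and propagate
    composition labels from labeled references to their group mates.

    Points are partitioned into ``k_groups`` by seeded k-medoids; each
    group's label is the majority composition label among its labeled
    members (ties → ``unknown`` with a warning; a group without any labeled
    member leaves its queries ``unassigned``). Input order never matters:
    ids are canonically sorted internally.
    """
    dm = _as_dm(dm)
    order = sorted(dm.ids)
    dm = dm.filter(order)
    labeled = set(reference_labels) & set(order)
    if len(labeled) < 1:
        raise ValueError("need at least one labeled reference in the matrix")
    if len(labeled) < k_groups:
        logger.warning("fewer labeled references (%d) than groups (%d)",
                       len(labeled), k_groups)
    res = principal_coordinates(dm, k=k_axes)
    rng = np.random.default_rng(seed)
    assign = _k_medoids(res.coordinates, k_groups, rng)
    # renumber groups deterministically by their smallest member id
    group_order = sorted(range(k_groups),
                         key=lambda g: min((order[i] for i in range(len(order))
                                            if assign[i] == g), default="~"))
    renum = {g: r + 1 for r, g in enumerate(group_order)}
    group_of = {order[i]: renum[assign[i]] for i in range(len(order))}
    labels_by_group: dict[int, str] = {}
    for g in range(1, k_groups + 1):
        members = [i for i in order if group_of[i] == g and i in labeled]
        if not members:
            labels_by_group[g] = "unassigned"
            continue
        votes: dict[str, int] = {}
        for m in members:
            votes[reference_labels[m]] = votes.get(reference_labels[m], 0) + 1
        top = max(votes.values())
        winners = sorted(l for l, v in votes.items() if v == top)
        if len(winners) > 1:
            warnings.warn(f"group {g}: tied composition vote {winners}; "
                          f"labeling 'unknown'", stacklevel=2)
            labels_by_group[g] = "unknown"
        else:
            labels_by_group[g] = winners[0]
    preds = []
    for idx, gid in enumerate(order):
        neighbors = sorted((l for l in labeled if l != gid),
                           key=lambda l: (dm[gid, l], l))[:3]
        preds.append(CompositionPrediction(
            genome_id=gid,
            coordinates=tuple(float(x) for x in res.coordinates[idx]),
            assigned_group=group_of[gid],
            predicted_label=labels_by_group[group_of[gid]],
            nearest_labeled_neighbors=neighbors,
        ))
    return preds


def write_predictions_tsv(preds: list[CompositionPrediction],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tPCo1\tPCo2\tgroup\tlabel\tnearest_labeled\n")
        for p in preds:
            c1 = f"{p.coordinates[0]:.6f}" if len(p.coordinates) > 0 else ""
            c2 = f"{p.coordinates[1]:.6f}" if len(p.coordinates) > 1 else ""
            fh.write(f"{p.genome_id}\t{c1}\t{c2}\t{p.assigned_group}\t"
                     f"{p.predicted_label}\t{','.join(p.nearest_labeled_neighbors)}\n")


def plot_composition(preds: list[CompositionPrediction], path: str | Path) -> None:
    """Scatter of the first two principal coordinates, colored by predicted
    label (optional diagnostic plot)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    labels = sorted({p.predicted_label for p in preds})
    for lab in labels:
        xs = [p.coordinates[0] for p in preds if p.predicted_label == lab]
        ys = [p.coordinates[1] if len(p.coordinates) > 1 else 0.0
              for p in preds if p.predicted_label == lab]
        ax.scatter(xs, ys, label=lab, s=30)
    ax.set_xlabel("PCo1")
    ax.set_ylabel("PCo2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
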