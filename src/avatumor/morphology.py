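"""Morphology analysis of emergent tumor regions.

A grown tumor organizes into concentric zones: a pure necrotic core Omega_N
(inside radius U_N), a mixed necrotic/quiescent annulus Omega_A carrying
scattered necrotic agglomerations (U_N..U_Q1), a pure quiescent annulus
Omega_Q (U_Q1..U_Q2), and an outer mixed proliferating/quiescent rim out to
the tumor edge U_T.  This module recovers those radii from a cell snapshot
by radial-shell composition analysis, finds satellite necrotic
agglomerations as connected components, and generates synthetic snapshots
with known ground truth for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .cells import DEFAULT_RADIUS, CellPopulation
from .errors import InvalidParameterError
from .mechanics import neighbor_pairs
from .metabolism import CellState

__all__ = [
    "RegionReport",
    "classify_regions",
    "find_agglomerations",
    "find_tumor_islands",
    "generate_fixture",
]

#: Shell composition threshold above which a shell counts as "pure".
PURITY = 0.95


@dataclass
class RegionReport:
    """Radial region structure of one snapshot.

    ``shells`` tabulates, per concentric shell from the tumor centroid, the
    cell-state composition (fractions summing to 1).  Boundary radii are in
    cm and None when the region is absent.  When all four are present they
    order U_N <= U_Q1 <= U_Q2 <= U_T.
    """

    centroid: np.ndarray
    shells: pd.DataFrame
    u_n: float | None = None
    u_q1: float | None = None
    u_q2: float | None = None
    u_t: float = 0.0
    agglomeration_count: int = 0
    agglomeration_sizes: list = field(default_factory=list)

    @property
    def radii(self) -> dict:
        return {"U_N": self.u_n, "U_Q1": self.u_q1, "U_Q2": self.u_q2, "U_T": self.u_t}

    def to_dict(self) -> dict:
        return {
            "centroid": [float(x) for x in self.centroid],
            "radii": {k: (None if v is None else float(v)) for k, v in self.radii.items()},
            "agglomeration_count": int(self.agglomeration_count),
            "agglomeration_sizes": [int(s) for s in self.agglomeration_sizes],
            "shells": self.shells.to_dict(orient="records"),
        }


def classify_regions(pop: CellPopulation, shell_width: float | None = None) -> RegionReport:
    """Radial-shell composition analysis of a snapshot.

    Shells of width one cell diameter (default) around the centroid of all
    cells; a shell is labeled by its dominant state when that state holds at
    least 95 % of its cells, else "mixed".  U_N is the outer edge of the
    contiguous pure-necrotic core, U_Q1..U_Q2 bound the pure-quiescent
    annulus, U_T is the outermost cell distance plus its radius.  Absent
    regions yield None radii.
    """
    if len(pop) == 0:
        raise InvalidParameterError("snapshot must contain at least one cell")
    if shell_width is None:
        shell_width = 2.0 * float(np.median(pop.radii))
    centroid = pop.positions.mean(axis=0)
    dist = np.linalg.norm(pop.positions - centroid, axis=1)
    u_t = float((dist + pop.radii).max())
    n_shells = max(int(np.ceil(u_t / shell_width)), 1)
    edges = np.arange(n_shells + 1) * shell_width
    which = np.minimum((dist / shell_width).astype(int), n_shells - 1)

    rows = []
    labels = []
    for s in range(n_shells):
        in_shell = which == s
        total = int(in_shell.sum())
        frac = {}
        for st in CellState:
            frac[st.name.lower()] = (
                float(np.sum(pop.states[in_shell] == int(st))) / total if total else 0.0)
        if total == 0:
            label = "empty"
        else:
            top = max(frac, key=frac.get)
            label = top if frac[top] >= PURITY else "mixed"
        labels.append(label)
        rows.append({"shell": s, "r_inner": edges[s], "r_outer": edges[s + 1],
                     "n_cells": total, **frac, "label": label})
    shells = pd.DataFrame(rows)

    # contiguous necrotic core from the center; shells emptied by the
    # dissolution of long-dead necrotic bodies count as part of the core
    u_n = None
    s = 0
    while s < n_shells and labels[s] in ("necrotic", "empty"):
        s += 1
    if s > 0 and any(lbl == "necrotic" for lbl in labels[:s]):
        u_n = float(edges[s])
    # pure quiescent annulus: first contiguous run of "quiescent" shells
    u_q1 = u_q2 = None
    run_start = None
    best = (0, None, None)
    for s in range(n_shells):
        if labels[s] == "quiescent":
            if run_start is None:
                run_start = s
        else:
            if run_start is not None:
                length = s - run_start
                if length > best[0]:
                    best = (length, run_start, s)
                run_start = None
    if run_start is not None and n_shells - run_start > best[0]:
        best = (n_shells - run_start, run_start, n_shells)
    if best[0] > 0:
        u_q1, u_q2 = float(edges[best[1]]), float(edges[best[2]])

    count, sizes = _agglomeration_summary(pop, centroid)
    return RegionReport(centroid=centroid, shells=shells, u_n=u_n, u_q1=u_q1,
                        u_q2=u_q2, u_t=u_t, agglomeration_count=count,
                        agglomeration_sizes=sizes)


def _necrotic_components(pop: CellPopulation, linkage_factor: float = 1.2):
    """Connected components of necrotic cells under center-distance adjacency."""
    nec_idx = np.flatnonzero(pop.states == int(CellState.NECROTIC))
    if len(nec_idx) == 0:
        return nec_idx, np.empty(0, dtype=int), 0
    pos = pop.positions[nec_idx]
    radii = pop.radii[nec_idx]
    if len(nec_idx) == 1:
        return nec_idx, np.zeros(1, dtype=int), 1
    i, j, _ = neighbor_pairs(pos, linkage_factor * radii)
    n = len(nec_idx)
    adj = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    return nec_idx, labels, n_comp


def find_agglomerations(pop: CellPopulation, linkage_factor: float = 1.2,
                        core_reach_factor: float = 2.0):
    """Satellite necrotic agglomerations outside the contiguous core.

    Necrotic cells are linked when their center distance is at most
    ``linkage_factor`` x summed radii; the component reaching the tumor
    centroid (any member within ``core_reach_factor`` x its radius) is the
    core and excluded.  Returns (count, member_id_lists).
    """
    nec_idx, labels, n_comp = _necrotic_components(pop, linkage_factor)
    if n_comp == 0:
        return 0, []
    centroid = pop.positions.mean(axis=0)
    dist_c = np.linalg.norm(pop.positions[nec_idx] - centroid, axis=1)
    clusters = []
    for c in range(n_comp):
        members = nec_idx[labels == c]
        reach = dist_c[labels == c].min()
        is_core = reach <= core_reach_factor * pop.radii[members].max()
        if not is_core:
            clusters.append([int(pop.ids[m]) for m in members])
    return len(clusters), clusters


def _agglomeration_summary(pop, centroid):
    count, clusters = find_agglomerations(pop)
    return count, [len(c) for c in clusters]


def find_tumor_islands(pop: CellPopulation, linkage_factor: float = 1.5,
                       living_only: bool = True):
    """Connected components of (living) cells — separate tumor islands.

    Returns a list of index arrays (into the population), largest first.
    """
    mask = pop.living_mask if living_only else np.ones(len(pop), dtype=bool)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    if len(idx) == 1:
        return [idx]
    pos = pop.positions[idx]
    i, j, _ = neighbor_pairs(pos, linkage_factor * pop.radii[idx])
    adj = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(len(idx), len(idx)))
    n_comp, labels = connected_components(adj, directed=False)
    comps = [idx[labels == c] for c in range(n_comp)]
    return sorted(comps, key=len, reverse=True)


def _packed_disk(radius: float, cell_radius: float, dim: int, center) -> np.ndarray:
    """Deterministic near-close-packed positions filling a ball."""
    spacing = 2.0 * cell_radius
    if dim == 2:
        # hexagonal rows
        dy = spacing * np.sqrt(3) / 2
        rows = int(np.ceil(radius / dy))
        pts = []
        for r in range(-rows, rows + 1):
            y = r * dy
            xoff = (r % 2) * spacing / 2
            cols = int(np.ceil(radius / spacing)) + 1
            for c in range(-cols, cols + 1):
                x = c * spacing + xoff
                if x * x + y * y <= radius * radius:
                    pts.append((x, y))
        pts = np.asarray(pts) if pts else np.zeros((0, 2))
    else:
        cols = int(np.ceil(radius / spacing)) + 1
        grid = np.arange(-cols, cols + 1) * spacing
        xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
        pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    return pts + np.asarray(center, dtype=float)


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0) -> CellPopulation:
    """Deterministic synthetic snapshots with known ground truth.

    Kinds
    -----
    layered_tumor : necrotic core (r_n), quiescent annulus (r_q), proliferating
        rim (r_t) around ``center``; compositions exactly pure per annulus.
    random_gas : ``n`` proliferating cells uniform in a box of side ``extent``.
    planted_clusters : ``k`` compact necrotic clusters of ``cluster_size``
        cells planted in a quiescent disk sea.
    two_tumors : two layered tumors separated by ``separation`` (the
        stem-cell secondary-tumor scenario).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    dim = int(params.pop("dim", 2))
    cr = float(params.pop("cell_radius", DEFAULT_RADIUS))
    pop = CellPopulation(dim=dim)

    def add_layered(center, r_n, r_q, r_t):
        pts = _packed_disk(r_t, cr, dim, center)
        d = np.linalg.norm(pts - np.asarray(center), axis=1)
        states = np.where(d < r_n, int(CellState.NECROTIC),
                          np.where(d < r_q, int(CellState.QUIESCENT),
                                   int(CellState.PROLIFERATING))).astype(np.int8)
        health = np.where(states == int(CellState.NECROTIC), 0.25,
                          np.where(states == int(CellState.QUIESCENT), 1.0, 1.8))
        nt = np.where(states == int(CellState.NECROTIC), 0.0, np.nan)
        pop.add(pts, states, health, necrosis_times=nt, radii=cr)

    if kind == "layered_tumor":
        r_n = params.pop("r_n", 0.01)
        r_q = params.pop("r_q", 0.02)
        r_t = params.pop("r_t", 0.03)
        center = params.pop("center", np.full(dim, r_t * 2.0))
        if not 0 <= r_n <= r_q <= r_t:
            raise InvalidParameterError("require 0 <= r_n <= r_q <= r_t")
        add_layered(center, r_n, r_q, r_t)
    elif kind == "random_gas":
        n = int(params.pop("n", 100))
        extent = float(params.pop("extent", 0.1))
        if n > 0:
            pts = rng.uniform(0, extent, size=(n, dim))
            pop.add(pts, int(CellState.PROLIFERATING), 1.8, radii=cr)
    elif kind == "planted_clusters":
        k = int(params.pop("k", 3))
        cluster_size = int(params.pop("cluster_size", 8))
        sea_radius = float(params.pop("sea_radius", 0.05))
        center = np.full(dim, sea_radius * 1.5)
        pts = _packed_disk(sea_radius, cr, dim, center)
        pop.add(pts, int(CellState.QUIESCENT), 1.0, radii=cr)
        # plant clusters at well-separated angles, away from the centroid
        from scipy.spatial import cKDTree

        ring = sea_radius * 0.6
        for c in range(k):
            theta = 2 * np.pi * c / max(k, 1)
            offset = np.zeros(dim)
            offset[0] = ring * np.cos(theta)
            offset[1] = ring * np.sin(theta)
            cpts = _packed_disk(cr * (np.sqrt(cluster_size) + 1), cr, dim, center + offset)
            order = np.argsort(np.linalg.norm(cpts - (center + offset), axis=1))
            cpts = cpts[order[:cluster_size]]
            # evict sea cells underneath so the planted cluster is isolated
            tree = cKDTree(pop.positions)
            evict = set()
            for p in cpts:
                evict.update(tree.query_ball_point(p, 2.5 * cr))
            if evict:
                mask = np.ones(len(pop), dtype=bool)
                mask[list(evict)] = False
                pop.keep(mask)
            pop.add(cpts, int(CellState.NECROTIC), 0.25, necrosis_times=0.0, radii=cr)
    elif kind == "two_tumors":
        r_n = params.pop("r_n", 0.008)
        r_q = params.pop("r_q", 0.015)
        r_t = params.pop("r_t", 0.022)
        separation = params.pop("separation", 0.08)
        base = np.full(dim, r_t * 2.0)
        add_layered(base, r_n, r_q, r_t)
        second = base.copy()
        second[0] += separation
        add_layered(second, 0.0, r_q * 0.5, r_t * 0.6)
    else:
        raise InvalidParameterError(f"unknown fixture kind {kind!r}")
    if params:
        raise InvalidParameterError(f"unknown fixture parameters {sorted(params)}")
    return pop
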