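"""Cell placement and stochastic distance-dependent wiring of the BL model.

The full model places 27,000 neurons (64% adapting PNs, 26% continuous PNs,
10% FSIs) uniformly at random in a 1.4 x 1.4 x 1.4 mm cuboid with a minimum
intersoma spacing of 25 um, and wires them with independent Bernoulli edges:

* PN->PN probability binned by intersoma distance: 3% (<50 um), 2%
  (50-100), 1% (100-200), 0.5% (200-600), zero beyond 600 um.
* PN-FSI pairs within ~300 um realize one mutually exclusive outcome:
  FSI->PN only (34%), PN->FSI only (12%), reciprocal (16%), none (38%).
* FSI-FSI pairs within ~300 um are electrically coupled with 8%
  probability; chemical connectivity is conditioned on coupling (coupled:
  50% unidirectional / 25% bidirectional; uncoupled: 19% / 3%).
* 1,800 extrinsic afferents each contact 40 random PNs, plus each FSI
  within 300 um of any of those PNs with probability 0.3%.

Axonal conduction delays are distance dependent,
delay = distance / v + mini_del + fluc + dt with v = 1 mm/ms, mini_del =
0.8 ms, fluc ~ U(-0.1, 0.1) ms and dt = 0.05 ms.  Autapses never form.

Reduced-scale recipes keep all probabilities and spatial ranges and shrink
counts and box edge together so the volume density is preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Recipe",
    "Placement",
    "ConnectivityGraph",
    "full_recipe",
    "reduced_recipe",
    "place_cells",
    "wire_intrinsic",
    "wire_afferents",
    "conduction_delay",
    "build_network",
    "EDGE_TYPES",
]

EDGE_TYPES = ("PN_PN", "PN_FSI", "FSI_PN", "FSI_FSI", "GAP", "AFF_PN", "AFF_FSI")

_PROPORTIONS = (0.64, 0.26, 0.10)  # PN_A, PN_C, FSI

CONDUCTION_VELOCITY_UM_PER_MS = 1000.0
MINI_DELAY_MS = 0.8
DELAY_FLUCTUATION_MS = 0.1
DT_MS = 0.05


@dataclass(frozen=True)
class Recipe:
    n_pn_a: int
    n_pn_c: int
    n_fsi: int
    box_um: float
    min_spacing_um: float = 25.0
    # PN->PN distance bins: (upper edge um, probability)
    pn_pn_bins: tuple = ((50.0, 0.03), (100.0, 0.02), (200.0, 0.01), (600.0, 0.005))
    fsi_range_um: float = 300.0
    p_fsi_pn: float = 0.34
    p_pn_fsi: float = 0.12
    p_reciprocal: float = 0.16
    p_gap: float = 0.08
    p_chem_coupled_uni: float = 0.50
    p_chem_coupled_bi: float = 0.25
    p_chem_uncoupled_uni: float = 0.19
    p_chem_uncoupled_bi: float = 0.03
    n_afferents: int = 1800
    afferent_fan_out: int = 40
    p_afferent_fsi: float = 0.003

    @property
    def n_pn(self) -> int:
        return self.n_pn_a + self.n_pn_c

    @property
    def n_cells(self) -> int:
        return self.n_pn + self.n_fsi

    @property
    def density_per_mm3(self) -> float:
        return self.n_cells / (self.box_um / 1000.0) ** 3


def full_recipe() -> Recipe:
    return Recipe(n_pn_a=17280, n_pn_c=7020, n_fsi=2700, box_um=1400.0)


def reduced_recipe(n_cells: int = 1000, n_afferents: int | None = None) -> Recipe:
    """Density-preserving reduced recipe: counts scale with n_cells, the box
    edge with n_cells^(1/3); probabilities and ranges are untouched."""
    full = full_recipe()
    scale = n_cells / full.n_cells
    n_fsi = int(round(_PROPORTIONS[2] * n_cells))
    n_pn_c = int(round(_PROPORTIONS[1] * n_cells))
    n_pn_a = n_cells - n_fsi - n_pn_c
    if n_afferents is None:
        n_afferents = max(1, int(round(full.n_afferents * scale)))
    return Recipe(
        n_pn_a=n_pn_a,
        n_pn_c=n_pn_c,
        n_fsi=n_fsi,
        box_um=full.box_um * scale ** (1.0 / 3.0),
        n_afferents=n_afferents,
    )


@dataclass
class Placement:
    archetypes: np.ndarray  # of {"PN_A","PN_C","FSI"}
    positions: np.ndarray  # (n, 3) um
    orientations: np.ndarray  # (n, 3) unit vectors
    box_um: float
    min_spacing_um: float

    @property
    def n_cells(self) -> int:
        return len(self.archetypes)

    @property
    def is_pn(self) -> np.ndarray:
        return self.archetypes != "FSI"

    @property
    def pn_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_pn)

    @property
    def fsi_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_pn)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n_cells),
                "type": self.archetypes,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "ox": self.orientations[:, 0],
                "oy": self.orientations[:, 1],
                "oz": self.orientations[:, 2],
            }
        )

    @classmethod
    def from_table(cls, df: pd.DataFrame, box_um: float,
                   min_spacing_um: float = 25.0) -> "Placement":
        df = df.sort_values("id")
        return cls(
            archetypes=df["type"].to_numpy(),
            positions=df[["x", "y", "z"]].to_numpy(float),
            orientations=df[["ox", "oy", "oz"]].to_numpy(float),
            box_um=box_um,
            min_spacing_um=min_spacing_um,
        )


@dataclass
class ConnectivityGraph:
    """Typed directed edges plus the extrinsic afferent map.

    ``edges`` columns: src, dst, type, weight, weight_nmda, delay_ms.  For
    chemical edges ``weight`` is the AMPA (excitatory) or GABA_A
    (inhibitory) weight; excitatory edges carry a separate NMDA weight.
    GAP edges are undirected (stored once, src < dst) with the conductance
    in ``weight``.  Afferent sources are indexed separately from cells.
    """

    edges: pd.DataFrame
    n_cells: int
    n_afferents: int = 0

    def of_type(self, etype: str) -> pd.DataFrame:
        return self.edges[self.edges["type"] == etype]

    def in_degree(self, etype: str, n_targets: int | None = None) -> np.ndarray:
        sub = self.of_type(etype)
        n = self.n_cells if n_targets is None else n_targets
        return np.bincount(sub["dst"].to_numpy(), minlength=n)[:n]

    def without_type(self, etype: str) -> "ConnectivityGraph":
        return ConnectivityGraph(
            edges=self.edges[self.edges["type"] != etype].reset_index(drop=True),
            n_cells=self.n_cells,
            n_afferents=self.n_afferents,
        )

    def to_table(self) -> pd.DataFrame:
        return self.edges.copy()

    @classmethod
    def from_table(cls, df: pd.DataFrame, n_cells: int,
                   n_afferents: int = 0) -> "ConnectivityGraph":
        return cls(edges=df.reset_index(drop=True), n_cells=n_cells,
                   n_afferents=n_afferents)


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def place_cells(recipe: Recipe, seed: int) -> Placement:
    """Uniform rejection-sampled placement honoring the minimum spacing.

    Deterministic under seed.  Raises RuntimeError if the packing is
    infeasible within a bounded number of attempts."""
    rng = np.random.default_rng(seed)
    n = recipe.n_cells
    box = recipe.box_um
    spacing = recipe.min_spacing_um
    cell = spacing  # uniform-grid bucket edge
    nb = max(1, int(math.ceil(box / cell)))
    grid: dict[tuple, list[int]] = {}
    pos = np.empty((n, 3))
    placed = 0
    attempts = 0
    max_attempts = 2000 * n
    sp2 = spacing * spacing
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placement infeasible: {placed}/{n} cells after {attempts} draws"
            )
        cand = rng.uniform(0.0, box, size=3)
        attempts += 1
        key = tuple((cand // cell).astype(int))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        d = cand - pos[j]
                        if d @ d <= sp2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pos[placed] = cand
            grid.setdefault(key, []).append(placed)
            placed += 1

    archetypes = np.array(
        ["PN_A"] * recipe.n_pn_a + ["PN_C"] * recipe.n_pn_c + ["FSI"] * recipe.n_fsi
    )
    rng.shuffle(archetypes)
    # isotropic random dendrite orientations
    vec = rng.normal(size=(n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return Placement(
        archetypes=archetypes,
        positions=pos,
        orientations=vec,
        box_um=box,
        min_spacing_um=spacing,
    )


# ---------------------------------------------------------------------------
# Delays
# ---------------------------------------------------------------------------

def conduction_delay(distance_um, rng: np.random.Generator | None = None):
    """Distance-dependent axonal delay in ms (vectorized).

    delay = distance/v + 0.8 + U(-0.1, 0.1) + dt."""
    d = np.asarray(distance_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative distance")
    fluc = 0.0 if rng is None else rng.uniform(
        -DELAY_FLUCTUATION_MS, DELAY_FLUCTUATION_MS, size=d.shape
    )
    return d / CONDUCTION_VELOCITY_UM_PER_MS + MINI_DELAY_MS + fluc + DT_MS


# ---------------------------------------------------------------------------
# Intrinsic wiring
# ---------------------------------------------------------------------------

def _pn_pn_prob(dist: np.ndarray, bins) -> np.ndarray:
    p = np.zeros_like(dist)
    lower = 0.0
    for upper, prob in bins:
        p[(dist > lower) & (dist <= upper)] = prob
        lower = upper
    return p


def wire_intrinsic(placement: Placement, recipe: Recipe, seed: int) -> ConnectivityGraph:
    """Realize all intrinsic chemical and electrical edges.

    Independent Bernoulli draws per candidate pair; PN-FSI pairs draw one
    categorical outcome so the printed unidirectional/reciprocal
    percentages are mutually exclusive.  Deterministic under seed."""
    rng = np.random.default_rng(seed)
    pos = placement.positions
    pn_idx = placement.pn_index
    fsi_idx = placement.fsi_index

    src_all: list[np.ndarray] = []
    dst_all: list[np.ndarray] = []
    type_all: list[np.ndarray] = []

    def add(src, dst, etype):
        src = np.asarray(src, dtype=np.int64)
        if src.size == 0:
            return
        src_all.append(src)
        dst_all.append(np.asarray(dst, dtype=np.int64))
        type_all.append(np.full(src.size, etype, dtype=object))

    # ---- PN -> PN, distance-binned Bernoulli in both directions
    pn_pos = pos[pn_idx]
    tree = cKDTree(pn_pos)
    max_r = recipe.pn_pn_bins[-1][0]
    pairs = tree.query_pairs(r=max_r, output_type="ndarray")
    chunk = 5_000_000
    for k in range(0, len(pairs), chunk):
        pp = pairs[k:k + chunk]
        d = np.linalg.norm(pn_pos[pp[:, 0]] - pn_pos[pp[:, 1]], axis=1)
        prob = _pn_pn_prob(d, recipe.pn_pn_bins)
        draw = rng.random((len(pp), 2))
        fwd = draw[:, 0] < prob
        bwd = draw[:, 1] < prob
        add(pn_idx[pp[fwd, 0]], pn_idx[pp[fwd, 1]], "PN_PN")
        add(pn_idx[pp[bwd, 1]], pn_idx[pp[bwd, 0]], "PN_PN")

    # ---- PN - FSI categorical outcomes within range
    fsi_pos = pos[fsi_idx]
    if len(fsi_idx):
        fsi_tree = cKDTree(fsi_pos)
        neighbor_lists = fsi_tree.query_ball_point(pn_pos, r=recipe.fsi_range_um)
        pn_of_pair = np.repeat(
            np.arange(len(pn_idx)), [len(x) for x in neighbor_lists]
        )
        fsi_of_pair = np.fromiter(
            (j for lst in neighbor_lists for j in lst), dtype=np.int64,
            count=len(pn_of_pair),
        )
        u = rng.random(len(pn_of_pair))
        p1 = recipe.p_fsi_pn
        p2 = p1 + recipe.p_pn_fsi
        p3 = p2 + recipe.p_reciprocal
        fsi_to_pn = u < p1
        pn_to_fsi = (u >= p1) & (u < p2)
        recip = (u >= p2) & (u < p3)
        add(fsi_idx[fsi_of_pair[fsi_to_pn | recip]],
            pn_idx[pn_of_pair[fsi_to_pn | recip]], "FSI_PN")
        add(pn_idx[pn_of_pair[pn_to_fsi | recip]],
            fsi_idx[fsi_of_pair[pn_to_fsi | recip]], "PN_FSI")

        # ---- FSI - FSI: gap junctions then conditioned chemical edges
        fpairs = fsi_tree.query_pairs(r=recipe.fsi_range_um, output_type="ndarray")
        if len(fpairs):
            coupled = rng.random(len(fpairs)) < recipe.p_gap
            add(fsi_idx[fpairs[coupled, 0]], fsi_idx[fpairs[coupled, 1]], "GAP")
            u = rng.random(len(fpairs))
            uni_p = np.where(coupled, recipe.p_chem_coupled_uni,
                             recipe.p_chem_uncoupled_uni)
            bi_p = np.where(coupled, recipe.p_chem_coupled_bi,
                            recipe.p_chem_uncoupled_bi)
            uni = u < uni_p
            bi = (u >= uni_p) & (u < uni_p + bi_p)
            direction = rng.random(len(fpairs)) < 0.5
            a, b = fsi_idx[fpairs[:, 0]], fsi_idx[fpairs[:, 1]]
            s_uni = np.where(direction, a, b)[uni]
            d_uni = np.where(direction, b, a)[uni]
            add(s_uni, d_uni, "FSI_FSI")
            add(a[bi], b[bi], "FSI_FSI")
            add(b[bi], a[bi], "FSI_FSI")

    if src_all:
        src = np.concatenate(src_all)
        dst = np.concatenate(dst_all)
        etype = np.concatenate(type_all)
    else:
        src = dst = np.empty(0, dtype=np.int64)
        etype = np.empty(0, dtype=object)

    dist = np.linalg.norm(pos[src] - pos[dst], axis=1) if src.size else np.empty(0)
    delay = np.where(
        etype == "GAP", 0.0, conduction_delay(dist, rng) if src.size else dist
    )
    edges = pd.DataFrame(
        {
            "src": src,
            "dst": dst,
            "type": etype,
            "weight": np.nan,
            "weight_nmda": np.nan,
            "delay_ms": delay,
        }
    )
    assert not np.any(edges["src"].to_numpy() == edges["dst"].to_numpy()), "autapse"
    return ConnectivityGraph(edges=edges, n_cells=placement.n_cells)


# ---------------------------------------------------------------------------
# Extrinsic afferents
# ---------------------------------------------------------------------------

def wire_afferents(placement: Placement, recipe: Recipe, seed: int) -> pd.DataFrame:
    """Afferent map: each afferent targets ``fan_out`` uniformly drawn PNs
    and, with probability ``p_afferent_fsi`` per pair, each FSI within the
    FSI range of any of those PNs.  Returns an edge table with afferent
    source ids (0..n_afferents-1) in ``src``."""
    rng = np.random.default_rng(seed)
    pn_idx = placement.pn_index
    fsi_idx = placement.fsi_index
    fsi_tree = cKDTree(placement.positions[fsi_idx]) if len(fsi_idx) else None

    src: list[int] = []
    dst: list[int] = []
    etype: list[str] = []
    fan = min(recipe.afferent_fan_out, len(pn_idx))
    for a in range(recipe.n_afferents):
        targets = rng.choice(pn_idx, size=fan, replace=False)
        src.extend([a] * fan)
        dst.extend(targets.tolist())
        etype.extend(["AFF_PN"] * fan)
        if fsi_tree is not None:
            lists = fsi_tree.query_ball_point(
                placement.positions[targets], r=recipe.fsi_range_um
            )
            cand = np.unique(np.fromiter(
                (j for lst in lists for j in lst), dtype=np.int64
            ))
            if cand.size:
                hit = cand[rng.random(cand.size) < recipe.p_afferent_fsi]
                src.extend([a] * len(hit))
                dst.extend(fsi_idx[hit].tolist())
                etype.extend(["AFF_FSI"] * len(hit))

    n = len(src)
    delay = conduction_delay(np.zeros(n), rng) if n else np.empty(0)
    return pd.DataFrame(
        {
            "src": np.asarray(src, dtype=np.int64),
            "dst": np.asarray(dst, dtype=np.int64),
            "type": np.asarray(etype, dtype=object),
            "weight": np.nan,
            "weight_nmda": np.nan,
            "delay_ms": delay,
        }
    )


def build_network(recipe: Recipe, seed: int,
                  with_afferents: bool = True) -> tuple[Placement, ConnectivityGraph]:
    """Placement + intrinsic wiring + afferent map under one master seed."""
    placement = place_cells(recipe, seed)
    graph = wire_intrinsic(placement, recipe, seed + 1)
    if with_afferents:
        aff = wire_afferents(placement, recipe, seed + 2)
        graph = ConnectivityGraph(
            edges=pd.concat([graph.edges, aff], ignore_index=True),
            n_cells=placement.n_cells,
            n_afferents=recipe.n_afferents,
        )
    return placement, graph
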