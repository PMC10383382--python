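"""Topological and physicochemical descriptors for the binding models.

Implements, from first principles on the hydrogen-depleted graph, the
seven descriptors appearing in the two frozen albumin-binding models:

========  =============================================================
X4A       average Kier–Hall path connectivity index of order 4
DECC      eccentric index — mean absolute deviation of vertex
          eccentricities
Eig12     12th-largest eigenvalue of the bond-order-augmented edge
          adjacency matrix (``Eig12_AEA_bo``)
MATS8m    Moran autocorrelation, topological lag 8, mass-weighted
GATS8v    Geary autocorrelation, topological lag 8, van-der-Waals-
          volume-weighted
PDI       packing density index, McGowan volume / total VSA surface
QED       quantitative estimate of drug-likeness
========  =============================================================

plus the PDI building blocks ``Vx`` (McGowan characteristic volume) and
``SAtot`` (total Labute-style VSA surface).  Autocorrelation weights are
scaled relative to carbon before centering (Dragon convention); the
unscaled variant is available through ``scale_to_carbon=False``.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph import MolecularGraph, build_graph

MODELED_DESCRIPTORS = ("X4A", "DECC", "Eig12_AEA_bo", "PDI", "MATS8m", "GATS8v", "QED")

# McGowan characteristic-volume atomic increments, cm^3/mol (Abraham &
# McGowan 1987); Vx subtracts 6.56 per bond, hydrogens included.
MCGOWAN_INCREMENTS = {
    "H": 8.71, "B": 18.32, "C": 16.35, "N": 14.39, "O": 12.43, "F": 10.48,
    "Si": 26.83, "P": 24.87, "S": 22.91, "Cl": 20.95, "Ge": 31.02,
    "As": 29.42, "Se": 27.81, "Br": 26.21, "Sn": 39.35, "Sb": 37.74,
    "Te": 36.14, "I": 34.53,
}
MCGOWAN_BOND_TERM = 6.56


def _as_graph(mol: MolecularGraph | str) -> MolecularGraph:
    return build_graph(mol) if isinstance(mol, str) else mol


# ---------------------------------------------------------------------------
# connectivity


def _simple_paths_with_edges(g: MolecularGraph, n_edges: int):
    """Yield all simple paths of ``n_edges`` edges, each direction once."""
    adj: list[list[int]] = [[] for _ in range(g.n_atoms)]
    for i, j, _ in g.bonds:
        adj[i].append(j)
        adj[j].append(i)

    def extend(path: list[int], visited: set[int]):
        if len(path) == n_edges + 1:
            yield tuple(path)
            return
        for nxt in adj[path[-1]]:
            if nxt not in visited:
                path.append(nxt)
                visited.add(nxt)
                yield from extend(path, visited)
                visited.remove(nxt)
                path.pop()

    for start in range(g.n_atoms):
        yield from extend([start], {start})


def avg_connectivity_index(mol: MolecularGraph | str, order: int) -> float:
    """Average Kier–Hall path connectivity index of the given order.

    Sum over simple paths of ``order`` edges of ``prod(delta)**-0.5``
    (vertex degrees along the path), divided by the path count.  Returns
    0 when no path of that order exists.
    """
    g = _as_graph(mol)
    if order < 0:
        raise ValueError("order must be >= 0")
    deg = g.degrees
    if order == 0:
        if g.n_atoms == 0:
            return 0.0
        terms = [1.0 / math.sqrt(d) for d in deg if d > 0]
        return sum(terms) / len(terms) if terms else 0.0
    total = 0.0
    count = 0
    for path in _simple_paths_with_edges(g, order):
        if path[0] > path[-1]:  # count each undirected path once
            continue
        total += 1.0 / math.sqrt(math.prod(deg[v] for v in path))
        count += 1
    return total / count if count else 0.0


# ---------------------------------------------------------------------------
# eccentricity


def eccentric_deviation(mol: MolecularGraph | str) -> float:
    """Mean absolute deviation of vertex eccentricities (DECC).

    ``(1/A) * sum_i |eta_i - mean(eta)|`` on the heavy-atom graph.
    Raises for a disconnected graph (eccentricity undefined).
    """
    g = _as_graph(mol)
    if g.n_atoms == 0:
        return 0.0
    if g.n_atoms == 1:
        return 0.0
    nxg = g.to_networkx()
    if not nx.is_connected(nxg):
        raise ValueError("eccentricities undefined for a disconnected graph")
    ecc = nx.eccentricity(nxg)
    values = np.array([ecc[i] for i in range(g.n_atoms)], dtype=float)
    return float(np.mean(np.abs(values - values.mean())))


# ---------------------------------------------------------------------------
# edge adjacency


def edge_adjacency_matrix(mol: MolecularGraph | str, augmented: bool = True) -> np.ndarray:
    """Edge-adjacency matrix; with ``augmented`` the diagonal holds bond orders."""
    g = _as_graph(mol)
    m = g.n_bonds
    E = np.zeros((m, m))
    for a in range(m):
        ia, ja, order = g.bonds[a]
        if augmented:
            E[a, a] = order
        for b in range(a + 1, m):
            ib, jb, _ = g.bonds[b]
            if len({ia, ja} & {ib, jb}) > 0:
                E[a, b] = E[b, a] = 1.0
    return E


def augmented_edge_adjacency_eigenvalue(mol: MolecularGraph | str, k: int) -> float:
    """k-th largest eigenvalue of the bond-order-augmented edge adjacency.

    Eigenvalues are ordered descending by algebraic value; molecules with
    fewer than ``k`` bonds return 0 (deterministic padding).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    g = _as_graph(mol)
    if g.n_bonds < k:
        return 0.0
    eig = np.linalg.eigvalsh(edge_adjacency_matrix(g))
    return float(np.sort(eig)[::-1][k - 1])


# ---------------------------------------------------------------------------
# 2D autocorrelations


def _distance_matrix(g: MolecularGraph) -> np.ndarray:
    nxg = g.to_networkx()
    n = g.n_atoms
    D = np.full((n, n), np.inf)
    for i, lengths in nx.all_pairs_shortest_path_length(nxg):
        for j, d in lengths.items():
            D[i, j] = d
    return D


def _autocorr_setup(
    mol: MolecularGraph | str, weight, scale_to_carbon: bool
) -> tuple[MolecularGraph, np.ndarray, np.ndarray]:
    g = _as_graph(mol)
    if isinstance(weight, str):
        w = np.array(g.weights(weight, scale_to_carbon=scale_to_carbon))
    else:
        w = np.asarray(weight, dtype=float)
        if w.shape != (g.n_atoms,):
            raise ValueError("weight vector length must equal atom count")
    return g, w, _distance_matrix(g)


def moran_autocorrelation(
    mol: MolecularGraph | str,
    lag: int,
    weight: str | Sequence[float] = "mass",
    scale_to_carbon: bool = True,
) -> float:
    """Moran spatial autocorrelation at a topological lag.

    ``I(d) = [sum_{d(i,j)=d} (w_i - wbar)(w_j - wbar) / Delta] /
    [sum_i (w_i - wbar)^2 / A]`` with ``Delta`` the number of ordered
    atom pairs at distance ``d``.  Returns 0 when no pair sits at the lag
    or when the weights have zero variance.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    g, w, D = _autocorr_setup(mol, weight, scale_to_carbon)
    if g.n_atoms == 0:
        return 0.0
    c = w - w.mean()
    denom = float(c @ c) / g.n_atoms
    mask = D == lag  # ordered pairs: both (i,j) and (j,i) counted
    delta = int(mask.sum())
    if delta == 0 or denom == 0.0:
        return 0.0
    num = float(np.outer(c, c)[mask].sum()) / delta
    return num / denom


def geary_autocorrelation(
    mol: MolecularGraph | str,
    lag: int,
    weight: str | Sequence[float] = "vdw_volume",
    scale_to_carbon: bool = True,
) -> float:
    """Geary spatial autocorrelation at a topological lag.

    ``c(d) = [sum_{d(i,j)=d} (w_i - w_j)^2 / (2*Delta)] /
    [sum_i (w_i - wbar)^2 / (A - 1)]``; zero conventions as for Moran.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    g, w, D = _autocorr_setup(mol, weight, scale_to_carbon)
    if g.n_atoms < 2:
        return 0.0
    c = w - w.mean()
    denom = float(c @ c) / (g.n_atoms - 1)
    mask = D == lag
    delta = int(mask.sum())
    if delta == 0 or denom == 0.0:
        return 0.0
    diff2 = (w[:, None] - w[None, :]) ** 2
    num = float(diff2[mask].sum()) / (2 * delta)
    return num / denom


# ---------------------------------------------------------------------------
# volumes and surfaces


def mcgowan_volume(mol: MolecularGraph | str) -> float:
    """McGowan characteristic volume Vx, in (cm^3/mol)/100.

    Sum of atomic increments (hydrogens included) minus 6.56 per bond
    (bonds to hydrogen included), divided by 100.  Raises for elements
    without a tabulated increment.
    """
    g = _as_graph(mol)
    total = 0.0
    n_h = 0
    for atom in g.atoms:
        try:
            total += MCGOWAN_INCREMENTS[atom.element]
        except KeyError:
            raise ValueError(f"no McGowan increment for element {atom.element!r}") from None
        n_h += atom.n_hydrogens
    total += n_h * MCGOWAN_INCREMENTS["H"]
    n_bonds = g.n_bonds + n_h
    return (total - MCGOWAN_BOND_TERM * n_bonds) / 100.0


def vsa_total(mol: MolecularGraph | str) -> float:
    """Total Van-der-Waals surface area (Labute VSA), heavy atoms summed."""
    g = _as_graph(mol)
    if g.rdkit_mol is None:
        raise ValueError("vsa_total requires a graph built from SMILES (needs RDKit mol)")
    from rdkit.Chem import rdMolDescriptors

    contribs, _h_contrib = rdMolDescriptors._CalcLabuteASAContribs(g.rdkit_mol)
    return float(sum(contribs))


def packing_density_index(mol: MolecularGraph | str) -> float:
    """Packing density index PDI = Vx / SAtot."""
    g = _as_graph(mol)
    sa = vsa_total(g)
    if sa <= 0:
        raise ValueError("total VSA surface must be positive")
    return mcgowan_volume(g) / sa


# ---------------------------------------------------------------------------
# drug-likeness (QED)

# Asymmetric-double-sigmoid desirability constants of the original QED
# parameterization (Bickerton et al. 2012): A, B, C, D, E, F, DMAX per
# property.
QED_ADS_PARAMS = {
    "MW": (2.817065973, 392.5754953, 290.7489764, 2.419764353, 49.22325677,
           65.37051707, 104.9805561),
    "ALOGP": (3.172690585, 137.8624751, 2.534937431, 4.581497897, 0.822739154,
              0.576295591, 131.3186604),
    "HBA": (2.948620388, 160.4605972, 3.615294657, 4.435986202, 0.290141953,
            1.300669958, 148.7763046),
    "HBD": (1.618662227, 1010.051101, 0.985094388, 0.000000001, 0.713820843,
            0.920922555, 258.1632616),
    "PSA": (1.876861559, 125.2232657, 62.90773554, 87.83366614, 12.01999824,
            28.51324732, 104.5686167),
    "ROTB": (0.01, 272.4121427, 2.55837997, 1.565547684, 1.271567166,
             2.758063707, 105.4420403),
    "AROM": (3.21778897, 957.7374108, 2.274627939, 0.000000001, 1.317690384,
             0.375760881, 312.337261),
    "ALERTS": (0.01, 1199.094025, -0.09002883, 0.000000001, 0.185904477,
               0.875193782, 417.725314),
}

QED_PROPERTY_ORDER = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")

QED_WEIGHT_SETS = {
    "unit": (1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
    "mean": (0.66, 0.46, 0.05, 0.61, 0.06, 0.65, 0.48, 0.95),
    "max": (0.50, 0.25, 0.00, 0.50, 0.00, 0.50, 0.25, 1.00),
}


def ads_desirability(x: float, params: tuple[float, ...]) -> float:
    """Asymmetric double sigmoid desirability, normalized to its maximum."""
    a, b, c, d, e, f, dmax = params
    s1 = 1.0 + math.exp(-(x - c + d / 2.0) / e)
    s2 = 1.0 + math.exp(-(x - c - d / 2.0) / f)
    return (a + b / s1 * (1.0 - 1.0 / s2)) / dmax


def qed_properties(mol: MolecularGraph | str) -> dict[str, float]:
    """The eight molecular properties underlying QED, via RDKit."""
    g = _as_graph(mol)
    if g.rdkit_mol is None:
        raise ValueError("qed requires a graph built from SMILES (needs RDKit mol)")
    from rdkit.Chem import QED as _RDQED

    p = _RDQED.properties(g.rdkit_mol)
    return dict(zip(QED_PROPERTY_ORDER, tuple(p)))


def qed(
    mol: MolecularGraph | str,
    weights: str | Sequence[float] = "unit",
    properties: Optional[dict[str, float]] = None,
) -> float:
    """Quantitative estimate of drug-likeness, in (0, 1].

    Weighted geometric mean ``exp(sum(w_i * ln d_i) / sum(w_i))`` of the
    eight desirability values.  Default weights are the unweighted
    ("QEDw,u") set; ``'mean'`` and ``'max'`` select the published
    alternatives, or pass eight explicit weights.
    """
    props = properties if properties is not None else qed_properties(mol)
    w = QED_WEIGHT_SETS[weights] if isinstance(weights, str) else tuple(weights)
    if len(w) != 8:
        raise ValueError("need exactly 8 weights")
    t = sum(
        wi * math.log(ads_desirability(props[name], QED_ADS_PARAMS[name]))
        for wi, name in zip(w, QED_PROPERTY_ORDER)
    )
    return math.exp(t / sum(w))


# ---------------------------------------------------------------------------
# batch table


def compute_descriptor(mol: MolecularGraph | str, name: str) -> float:
    """Compute one named descriptor for one molecule."""
    g = _as_graph(mol)
    if name == "X4A":
        return avg_connectivity_index(g, 4)
    if name == "DECC":
        return eccentric_deviation(g)
    if name == "Eig12_AEA_bo":
        return augmented_edge_adjacency_eigenvalue(g, 12)
    if name == "PDI":
        return packing_density_index(g)
    if name == "MATS8m":
        return moran_autocorrelation(g, 8, "mass")
    if name == "GATS8v":
        return geary_autocorrelation(g, 8, "vdw_volume")
    if name == "QED":
        return qed(g)
    if name == "Vx":
        return mcgowan_volume(g)
    if name == "SAtot":
        return vsa_total(g)
    raise ValueError(
        f"unknown descriptor {name!r}; valid names: "
        f"{MODELED_DESCRIPTORS + ('Vx', 'SAtot')}"
    )


def descriptor_table(
    dataset,
    names: Sequence[str] = MODELED_DESCRIPTORS,
) -> pd.DataFrame:
    """Descriptor matrix for a dataset: one row per compound, id-indexed.

    ``dataset`` may be a :class:`~pfasbind.dataset.QSARDataset` or a list
    of ``(smiles, id)`` pairs.  Per-compound failures do not abort the
    batch: the failing row is filled with NaN and recorded in
    ``df.attrs['failures']`` as ``{id: message}``.
    """
    for name in names:
        if name not in MODELED_DESCRIPTORS + ("Vx", "SAtot"):
            raise ValueError(
                f"unknown descriptor {name!r}; valid names: "
                f"{MODELED_DESCRIPTORS + ('Vx', 'SAtot')}"
            )
    if hasattr(dataset, "records"):
        pairs = [(rec.smiles, rec.id) for rec in dataset.records]
    else:
        pairs = list(dataset)
    rows = {}
    failures: dict[str, str] = {}
    for smiles, cid in pairs:
        try:
            g = build_graph(smiles)
            rows[cid] = [compute_descriptor(g, n) for n in names]
        except Exception as exc:  # noqa: BLE001 - collect and report
            rows[cid] = [math.nan] * len(names)
            failures[cid] = str(exc)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(names))
    df.index.name = "id"
    df.attrs["failures"] = failures
    return df
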