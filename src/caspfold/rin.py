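"""Typed residue-interaction networks and centrality analysis.

Residues are nodes; edges are non-covalent atom-pair contacts within a
distance cutoff (default 4 A), typed as electrostatic, hydrophobic or van
der Waals, and aggregated over ensemble frames: the per-frame edge weight is
the number of contacting atom pairs (the "sum") and the stored edge weight
is its average over frames.  Degree centrality (DC) is the weighted degree —
the total mean contact count a residue makes — and betweenness centrality
(BC) is unnormalized node betweenness on the graph with edge length
1/mean_weight, so stronger contacts give shorter paths.

Contact-typing rules (this package's operational definitions, overridable
via the module constants):

* electrostatic — one atom is a sidechain carboxylate oxygen of Asp/Glu and
  the other a sidechain nitrogen of Lys/Arg/His (oppositely charged
  formal-charge groups);
* hydrophobic — both atoms are sidechain carbons of apolar residues
  (Ala, Val, Leu, Ile, Pro, Phe, Met, Trp);
* vdw — any other heavy-atom pair within the cutoff.

Hydrogens are excluded, as are residue pairs adjacent in the chain
(|i - j| <= 1 on the same chain) so covalent geometry never counts as a
non-covalent interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial import cKDTree

from .ensemble import ConformationalEnsemble

DEFAULT_CUTOFF = 4.0

ACIDIC_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
BASIC_N = {
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

EDGE_TYPES = ("vdw", "hydrophobic", "electrostatic")


def _atom_classes(atoms: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-atom boolean flags (charged-negative, charged-positive, apolar-C)."""
    if atoms["element"].isna().any() or (atoms["element"] == "").any():
        raise ValueError("atom table has missing element metadata")
    if atoms["atom_name"].isna().any() or (atoms["atom_name"] == "").any():
        raise ValueError("atom table has missing atom-name metadata")
    pairs = list(zip(atoms["residue_name"], atoms["atom_name"]))
    neg = np.array([p in ACIDIC_O for p in pairs])
    pos = np.array([p in BASIC_N for p in pairs])
    apolar = (
        atoms["residue_name"].isin(APOLAR_RESIDUES).to_numpy()
        & (atoms["element"] == "C").to_numpy()
        & ~atoms["atom_name"].isin(BACKBONE_ATOMS).to_numpy()
    )
    return neg, pos, apolar


def detect_contacts(
    coords: np.ndarray, atoms: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Typed heavy-atom contacts in one frame.

    Returns a DataFrame with columns ``atom_i, atom_j, res_i, res_j, type,
    distance`` where ``res_i < res_j`` or the residues are on different
    chains.  Pairs from chain-adjacent residues are excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] != len(atoms):
        raise ValueError("coords must be (n_atoms, 3) matching the atom table")
    neg, pos, apolar = _atom_classes(atoms)
    heavy = (atoms["element"] != "H").to_numpy()
    res_idx = atoms["residue_index"].to_numpy()
    chain = atoms["chain_id"].to_numpy()

    heavy_ids = np.flatnonzero(heavy)
    tree = cKDTree(coords[heavy_ids])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pd.DataFrame(
            columns=["atom_i", "atom_j", "res_i", "res_j", "type", "distance"]
        )
    ai = heavy_ids[pairs[:, 0]]
    aj = heavy_ids[pairs[:, 1]]
    same_chain = chain[ai] == chain[aj]
    sep = np.abs(res_idx[ai] - res_idx[aj])
    keep = (~same_chain) | (sep >= 2)
    ai, aj = ai[keep], aj[keep]

    elec = (neg[ai] & pos[aj]) | (pos[ai] & neg[aj])
    hydro = apolar[ai] & apolar[aj] & ~elec
    types = np.where(elec, "electrostatic", np.where(hydro, "hydrophobic", "vdw"))
    dist = np.linalg.norm(coords[ai] - coords[aj], axis=1)

    ri, rj = res_idx[ai], res_idx[aj]
    swap = ri > rj
    ri2 = np.where(swap, rj, ri)
    rj2 = np.where(swap, ri, rj)
    return pd.DataFrame(
        {
            "atom_i": np.where(swap, aj, ai),
            "atom_j": np.where(swap, ai, aj),
            "res_i": ri2,
            "res_j": rj2,
            "type": types,
            "distance": dist,
        }
    )


@dataclass
class ResidueInteractionNetwork:
    """Frame-averaged typed contact graph over residues.

    ``edges`` has columns ``res_i, res_j, type, mean_weight, occupancy``:
    mean_weight is the mean atom-pair contact count per frame and occupancy
    the fraction of frames with at least one contact of that type.
    """

    edges: pd.DataFrame
    residues: np.ndarray
    n_frames: int
    cutoff: float = DEFAULT_CUTOFF

    def pooled_graph(self) -> nx.Graph:
        """Undirected graph with per-pair weights pooled over contact types."""
        g = nx.Graph()
        g.add_nodes_from(int(r) for r in self.residues)
        pooled = self.edges.groupby(["res_i", "res_j"])["mean_weight"].sum()
        for (i, j), w in pooled.items():
            g.add_edge(int(i), int(j), weight=float(w), length=1.0 / float(w))
        return g

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.pooled_graph(), str(path))


def build_rin(
    ensemble: ConformationalEnsemble, cutoff: float = DEFAULT_CUTOFF
) -> ResidueInteractionNetwork:
    """Aggregate per-frame typed contacts into a residue network."""
    if ensemble.n_frames < 1:
        raise ValueError("ensemble has no frames")
    totals: dict[tuple[int, int, str], float] = {}
    frames_hit: dict[tuple[int, int, str], int] = {}
    for f in range(ensemble.n_frames):
        contacts = detect_contacts(ensemble.coords[f], ensemble.atoms, cutoff)
        if contacts.empty:
            continue
        counts = contacts.groupby(["res_i", "res_j", "type"]).size()
        for key, c in counts.items():
            key = (int(key[0]), int(key[1]), str(key[2]))
            totals[key] = totals.get(key, 0.0) + float(c)
            frames_hit[key] = frames_hit.get(key, 0) + 1
    rows = [
        {
            "res_i": k[0],
            "res_j": k[1],
            "type": k[2],
            "mean_weight": totals[k] / ensemble.n_frames,
            "occupancy": frames_hit[k] / ensemble.n_frames,
        }
        for k in sorted(totals)
    ]
    edges = pd.DataFrame(rows, columns=["res_i", "res_j", "type", "mean_weight", "occupancy"])
    return ResidueInteractionNetwork(
        edges=edges, residues=ensemble.residue_indices, n_frames=ensemble.n_frames,
        cutoff=cutoff,
    )


def degree_centrality(
    rin: ResidueInteractionNetwork, weighted: bool = True
) -> pd.Series:
    """Weighted degree per residue: the sum of incident mean contact counts.

    With ``weighted=False``, counts distinct neighbor residues instead
    (unit edges).
    """
    g = rin.pooled_graph()
    if weighted:
        dc = dict(g.degree(weight="weight"))
    else:
        dc = dict(g.degree())
    return pd.Series({int(r): float(dc.get(int(r), 0.0)) for r in rin.residues}).sort_index()


def betweenness_centrality(
    rin: ResidueInteractionNetwork, weighted: bool = True
) -> pd.Series:
    """Unnormalized node betweenness with edge length 1/mean_weight.

    BC(v) sums sigma_st(v)/sigma_st over unordered pairs s < t (s, t != v);
    disconnected pairs contribute zero.
    """
    if (rin.edges["mean_weight"] <= 0).any():
        raise ValueError("all edge weights must be positive")
    g = rin.pooled_graph()
    bc = nx.betweenness_centrality(
        g, normalized=False, weight="length" if weighted else None
    )
    return pd.Series({int(r): float(bc.get(int(r), 0.0)) for r in rin.residues}).sort_index()


# --------------------------------------------------------------------------
# Conservation binning and hub classification
# --------------------------------------------------------------------------

CONSERVATION_BINS = {"high": (8, 9), "intermediate": (6, 7), "variable": (1, 5)}


def bin_conservation(grade: int) -> str:
    """Map a ConSurf grade 1-9 to high (8-9) / intermediate (6-7) / variable (1-5).

    Grade 5 is grouped with the variable bin.
    """
    g = int(grade)
    if not 1 <= g <= 9:
        raise ValueError(f"conservation grade {g} outside 1-9")
    if g >= 8:
        return "high"
    if g >= 6:
        return "intermediate"
    return "variable"


@dataclass
class HubClassification:
    hubs: set[int]
    quadrant_counts: dict[str, int]
    dc_threshold: float
    bc_threshold: float


def classify_hubs(
    records: pd.DataFrame,
    dc_threshold: float = 20.0,
    bc_threshold: float = 1000.0,
) -> HubClassification:
    """Hubs are residues with DC and BC both above their thresholds.

    ``records`` needs columns ``residue``, ``DC`` and ``BC``.  The returned
    quadrant counts partition all residues by which thresholds they exceed.
    """
    if dc_threshold <= 0 or bc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    hi_dc = records["DC"] > dc_threshold
    hi_bc = records["BC"] > bc_threshold
    hubs = set(records.loc[hi_dc & hi_bc, "residue"].astype(int))
    counts = {
        "both_high": int((hi_dc & hi_bc).sum()),
        "dc_only": int((hi_dc & ~hi_bc).sum()),
        "bc_only": int((~hi_dc & hi_bc).sum()),
        "both_low": int((~hi_dc & ~hi_bc).sum()),
    }
    return HubClassification(hubs, counts, dc_threshold, bc_threshold)


def residue_metric_records(
    rin: ResidueInteractionNetwork,
    conservation: pd.DataFrame | None = None,
    regions: pd.DataFrame | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-residue table of DC, BC, conservation grade/bin and region class."""
    dc = degree_centrality(rin, weighted=weighted)
    bc = betweenness_centrality(rin, weighted=weighted)
    rec = pd.DataFrame({"residue": dc.index, "DC": dc.values, "BC": bc.reindex(dc.index).values})
    if conservation is not None:
        grade = conservation.set_index("position")["grade"]
        rec["grade"] = rec["residue"].map(grade)
        rec["conservation_bin"] = rec["grade"].map(lambda g: bin_conservation(g) if pd.notna(g) else None)
    if regions is not None:
        region = regions.set_index("position")["region"]
        rec["region"] = rec["residue"].map(region)
    return rec


def metric_distributions(
    records: pd.DataFrame, group_by: str, value: str = "DC"
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Partition metric values by region or conservation bin.

    Returns the raw per-group value arrays (for violin plots) and a summary
    with median, quartiles and counts.  The partition is exhaustive and
    disjoint over the records.
    """
    if group_by not in ("region", "conservation_bin"):
        raise ValueError("group_by must be 'region' or 'conservation_bin'")
    if group_by not in records.columns or records[group_by].isna().any():
        raise ValueError(f"records are missing the {group_by!r} attribute")
    groups = {str(k): g[value].to_numpy() for k, g in records.groupby(group_by, sort=True)}
    summary = pd.DataFrame(
        {
            "group": list(groups),
            "n": [len(v) for v in groups.values()],
            "median": [float(np.median(v)) for v in groups.values()],
            "q1": [float(np.percentile(v, 25)) for v in groups.values()],
            "q3": [float(np.percentile(v, 75)) for v in groups.values()],
        }
    )
    return groups, summary


# --------------------------------------------------------------------------
# Family averaging over a master alignment
# --------------------------------------------------------------------------


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def average_over_family(
    tables: dict[str, pd.DataFrame],
    alignment: dict[str, str],
    sequences: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Average per-residue DC/BC across homologs on master-alignment columns.

    ``tables`` maps protein name to its per-residue metric records (columns
    ``residue``, ``DC``, ``BC``; residue indices 1-based and consecutive in
    sequence order).  Each protein's ungapped alignment row must have exactly
    one character per record; if ``sequences`` is given the ungapped row must
    also match that sequence.  Gap positions are excluded from both the
    numerator and denominator of the column mean.
    """
    cols: dict[int, dict[str, list[float]]] = {}
    contrib: dict[int, int] = {}
    for name, table in tables.items():
        if name not in alignment:
            raise ValueError(f"protein {name!r} missing from the alignment")
        row = alignment[name]
        ungapped = row.replace("-", "").replace(".", "")
        if len(ungapped) != len(table):
            raise ValueError(
                f"protein {name!r}: alignment row has {len(ungapped)} residues "
                f"but the metric table has {len(table)}"
            )
        if sequences is not None and ungapped != sequences[name].upper():
            raise ValueError(f"protein {name!r}: alignment sequence does not match")
        table = table.sort_values("residue").reset_index(drop=True)
        res_pos = 0
        for col, ch in enumerate(row, start=1):
            if ch in "-.":
                continue
            rec = table.iloc[res_pos]
            res_pos += 1
            slot = cols.setdefault(col, {"DC": [], "BC": []})
            slot["DC"].append(float(rec["DC"]))
            slot["BC"].append(float(rec["BC"]))
            contrib[col] = contrib.get(col, 0) + 1
    rows = [
        {
            "column": col,
            "mean_DC": float(np.mean(cols[col]["DC"])),
            "mean_BC": float(np.mean(cols[col]["BC"])),
            "n_proteins": contrib[col],
        }
        for col in sorted(cols)
    ]
    return pd.DataFrame(rows)
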