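"""Energy frameworks: cylinder graphs over molecular centroids.

An energy framework joins the centers of mass of interacting molecules by
cylinders whose radius is proportional to the magnitude of a pairwise energy
component (electrostatic, dispersion or total).  Edges below a cutoff are
omitted; destabilizing (positive) electrostatic/total interactions get their
own colour so cation–cation or dipole-parallel repulsions stand out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .crystal_io import (
    Crystal,
    ValidationError,
    assign_species,
    build_cluster,
    perceive_molecules,
    unique_pairs,
)
from .electronic_structure import WavefunctionCache, compute_wavefunction
from .energy_terms import (
    CE_HF_MODEL,
    DispersionParams,
    EnergyModel,
    PairEnergy,
    PolarizabilityTable,
    pair_energy,
)

__all__ = [
    "FrameworkGraph",
    "DEFAULT_COLORS",
    "DEFAULT_CUTOFF",
    "DEFAULT_CYLINDER_SCALE",
    "pair_energy_table",
    "build_framework",
    "export_scene",
    "import_scene",
]

COMPONENTS = ("ele", "dis", "tot")
#: red = electrostatic, green = dispersion, blue = total,
#: yellow = destabilizing (positive) electrostatic/total.
DEFAULT_COLORS = {"ele": "red", "dis": "green", "tot": "blue", "destabilizing": "yellow"}
DEFAULT_CUTOFF = 15.0  # kJ/mol, the conventional omission threshold
DEFAULT_CYLINDER_SCALE = 150.0  # larger scale -> thinner cylinders

SCENE_FORMAT_VERSION = 1


@dataclass
class FrameworkGraph:
    """Cylinder scene: nodes at molecular centers of mass, energy edges."""

    component: str
    cylinder_scale: float
    cutoff: float
    nodes: list = field(default_factory=list)  # {"id", "label", "position"}
    edges: list = field(default_factory=list)  # {"nodes", "energy", "radius", "color"}
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph(
            component=self.component,
            cylinder_scale=self.cylinder_scale,
            cutoff=self.cutoff,
        )
        for node in self.nodes:
            g.add_node(node["id"], label=node["label"], position=tuple(node["position"]))
        for edge in self.edges:
            i, j = edge["nodes"]
            g.add_edge(i, j, energy=edge["energy"], radius=edge["radius"], color=edge["color"])
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def pair_energy_table(
    crystal: Crystal,
    model: EnergyModel = CE_HF_MODEL,
    contact_radius: float = 3.8,
    config: dict | None = None,
    polarizabilities: PolarizabilityTable | None = None,
    dispersion: DispersionParams | None = None,
) -> list[PairEnergy]:
    """One PairEnergy per symmetry-unique pair per unique molecule.

    Deterministic ordering: (central label, descending |E_tot|, centroid
    distance).  Pair multiplicities are attached so lattice-type sums can be
    reconstructed from the table.
    """
    species = assign_species(perceive_molecules(crystal), config)
    cache = WavefunctionCache()
    table: list[PairEnergy] = []
    polarizabilities = polarizabilities or PolarizabilityTable()
    dispersion = dispersion or DispersionParams()
    for central in species:
        neighbors = build_cluster(crystal, central, contact_radius, species=species)
        pairs = unique_pairs(central, neighbors)
        wfn_central = compute_wavefunction(central, model.theory, cache=cache)
        for dp in pairs:
            wfn_nb = compute_wavefunction(dp.molecule_b, model.theory, cache=cache)
            pe = pair_energy(
                wfn_central,
                wfn_nb,
                model=model,
                polarizabilities=polarizabilities,
                dispersion=dispersion,
                label=f"{central.label}|{dp.molecule_b.label}",
                symmetry=dp.molecule_b.origin,
            )
            pe.centroid_distance = dp.centroid_distance
            pe.multiplicity_count = dp.multiplicity_count
            pe.position_a = tuple(central.center_of_mass)
            pe.position_b = tuple(dp.molecule_b.center_of_mass)
            table.append(pe)
    table.sort(key=lambda pe: (pe.label.split("|")[0], -abs(pe.e_tot), pe.centroid_distance))
    return table


def build_framework(
    pairs: list,
    component: str = "tot",
    cylinder_scale: float = DEFAULT_CYLINDER_SCALE,
    cutoff: float = DEFAULT_CUTOFF,
    colors: dict | None = None,
    positions: list | None = None,
) -> FrameworkGraph:
    """Build the cylinder graph for one energy component.

    ``pairs`` are :class:`PairEnergy` records; node positions default to the
    centres of mass of the underlying pair geometry when available and can
    be supplied explicitly via ``positions`` (one (pos_a, pos_b) per pair)
    for synthetic tables.  Cylinder radius is |E|/cylinder_scale; edges with
    |E| < cutoff are omitted; positive ele/tot edges are coloured with the
    destabilizing colour.
    """
    if component not in COMPONENTS:
        raise ValidationError(f"unknown component {component!r}; one of {COMPONENTS}")
    if cylinder_scale <= 0:
        raise ValidationError("cylinder scale must be positive")
    colors = {**DEFAULT_COLORS, **(colors or {})}
    graph = FrameworkGraph(
        component=component, cylinder_scale=cylinder_scale, cutoff=cutoff, colors=colors
    )
    node_ids: dict[tuple, int] = {}

    def node_for(pos, label: str) -> int:
        key = tuple(np.round(np.asarray(pos, dtype=float), 6))
        if key not in node_ids:
            node_ids[key] = len(graph.nodes)
            graph.nodes.append(
                {"id": node_ids[key], "label": label, "position": [float(x) for x in key]}
            )
        return node_ids[key]

    for idx, pe in enumerate(pairs):
        value = {"ele": pe.e_ele, "dis": pe.e_dis, "tot": pe.e_tot}[component]
        if abs(value) < cutoff:
            continue
        if positions is not None:
            pos_a, pos_b = positions[idx]
        else:
            pos_a = getattr(pe, "position_a", (0.0, 0.0, 0.0))
            pos_b = getattr(pe, "position_b", (0.0, 0.0, float(pe.centroid_distance)))
        color = colors[component]
        if value > 0 and component in ("ele", "tot"):
            color = colors["destabilizing"]
        labels = (pe.label.split("|") + ["", ""])[:2]
        i = node_for(pos_a, labels[0])
        j = node_for(pos_b, labels[1] or labels[0])
        graph.edges.append(
            {
                "nodes": [i, j],
                "component": component,
                "energy": float(value),
                "radius": abs(float(value)) / cylinder_scale,
                "color": color,
            }
        )
    return graph


# ---------------------------------------------------------------------------
# scene export


def _cylinder_mesh(p0, p1, radius, nsides=8):
    """Vertices and faces of a closed prism approximating a cylinder."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length < 1e-12:
        axis = np.array([0.0, 0.0, 1.0])
        length = 1e-12
    axis = axis / length
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    verts = []
    for center in (p0, p1):
        for k in range(nsides):
            t = 2.0 * np.pi * k / nsides
            verts.append(center + radius * (np.cos(t) * u + np.sin(t) * v))
    faces = []
    for k in range(nsides):
        k2 = (k + 1) % nsides
        faces.append((k, k2, nsides + k2, nsides + k))
    return verts, faces


def export_scene(graph: FrameworkGraph, path, format: str = "json") -> None:
    """Write the framework scene; ``json`` round-trips losslessly, ``obj``
    contains one cylinder mesh per edge."""
    if format == "json":
        payload = {
            "format": "cepair-framework",
            "version": SCENE_FORMAT_VERSION,
            "component": graph.component,
            "cylinder_scale": graph.cylinder_scale,
            "cutoff": graph.cutoff,
            "colors": graph.colors,
            "nodes": graph.nodes,
            "edges": graph.edges,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    elif format == "obj":
        lines = ["# cepair energy-framework scene"]
        offset = 1  # OBJ indices are 1-based
        positions = {n["id"]: n["position"] for n in graph.nodes}
        for k, edge in enumerate(graph.edges):
            i, j = edge["nodes"]
            verts, faces = _cylinder_mesh(positions[i], positions[j], edge["radius"])
            lines.append(f"o cylinder_{k}")
            for vx in verts:
                lines.append(f"v {vx[0]:.6f} {vx[1]:.6f} {vx[2]:.6f}")
            for fc in faces:
                lines.append("f " + " ".join(str(offset + idx) for idx in fc))
            offset += len(verts)
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown scene format {format!r} (json or obj)")


def import_scene(path) -> FrameworkGraph:
    """Read back a JSON scene written by :func:`export_scene`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "cepair-framework":
        raise ValidationError("not a cepair framework scene file")
    return FrameworkGraph(
        component=payload["component"],
        cylinder_scale=payload["cylinder_scale"],
        cutoff=payload["cutoff"],
        nodes=payload["nodes"],
        edges=payload["edges"],
        colors=payload["colors"],
    )
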