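"""Root System Markup Language (RSML) export of final architectures."""

from __future__ import annotations

from datetime import date

import numpy as np
from lxml import etree

from .rootsys import RootSystem

__all__ = ["write_rsml"]


def _root_polylines(system: RootSystem) -> dict[int, np.ndarray]:
    """Ordered 3-D point chains per root from the segment blocks."""
    pts: dict[int, list[np.ndarray]] = {}
    for block in system.seg_blocks:
        for base, tip, rid in zip(block["base"], block["tip"], block["root_id"]):
            rid = int(rid)
            chain = pts.setdefault(rid, [base])
            chain.append(tip)
    return {rid: np.asarray(chain) for rid, chain in pts.items()}


def write_rsml(system: RootSystem, path: str, label: str = "stopsignal run") -> None:
    """Write the architecture as an RSML document (laterals nested under axes)."""
    rsml = etree.Element("rsml")
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "cm"
    etree.SubElement(meta, "resolution").text = "1"
    etree.SubElement(meta, "last-modified").text = date.today().isoformat()
    etree.SubElement(meta, "software").text = "stopsignal"
    scene = etree.SubElement(rsml, "scene")
    plant = etree.SubElement(scene, "plant", id="1", label=label)

    chains = _root_polylines(system)
    root_elems: dict[int, etree._Element] = {}
    for rid in sorted(chains):
        parent_rid = int(system.r_parent[rid])
        container = root_elems.get(parent_rid, plant)
        cls = system.class_names[system.r_class[rid]]
        el = etree.SubElement(
            container, "root", id=str(rid + 1), label=f"{cls}_{rid}",
            accession=cls,
        )
        geom = etree.SubElement(el, "geometry")
        poly = etree.SubElement(geom, "polyline")
        for p in chains[rid]:
            etree.SubElement(
                poly, "point", x=f"{p[0]:.4f}", y=f"{p[1]:.4f}", z=f"{p[2]:.4f}"
            )
        root_elems[rid] = el

    etree.ElementTree(rsml).write(
        path, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
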