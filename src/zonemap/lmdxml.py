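"""Export and re-import cutting contours in a Leica-LMD-style XML dialect.

The laser microdissector consumes an ``ImageData`` document holding three
stage-calibration reference points followed by one ``Shape_N`` record per
contour (vertex lists as ``X_i``/``Y_i`` tags).  ``CapID`` carries the cell
id so a written document round-trips losslessly through :func:`read_lmd_xml`.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .tissue import CellContour

__all__ = ["export_lmd_xml", "read_lmd_xml"]


def export_lmd_xml(
    contours: list[CellContour],
    reference_points: list[tuple[float, float]],
    path: str | Path | None = None,
) -> str:
    """Serialize contours plus exactly three calibration points.

    Returns the XML text; also writes it to ``path`` when given.
    """
    if len(reference_points) != 3:
        raise ValueError("exactly 3 reference points are required")
    root = ET.Element("ImageData")
    ET.SubElement(root, "GlobalCoordinates").text = "1"
    for i, (x, y) in enumerate(reference_points, start=1):
        ET.SubElement(root, f"X_CalibrationPoint_{i}").text = repr(float(x))
        ET.SubElement(root, f"Y_CalibrationPoint_{i}").text = repr(float(y))
    ET.SubElement(root, "ShapeCount").text = str(len(contours))
    for n, cell in enumerate(contours, start=1):
        shape = ET.SubElement(root, f"Shape_{n}")
        ET.SubElement(shape, "PointCount").text = str(len(cell.vertices))
        ET.SubElement(shape, "CapID").text = cell.id
        for i, (x, y) in enumerate(cell.vertices, start=1):
            ET.SubElement(shape, f"X_{i}").text = repr(float(x))
            ET.SubElement(shape, f"Y_{i}").text = repr(float(y))
    ET.indent(root)
    text = ET.tostring(root, encoding="unicode", xml_declaration=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_lmd_xml(source: str | Path) -> tuple[list[CellContour], list[tuple[float, float]]]:
    """Parse a document written by :func:`export_lmd_xml`.

    ``source`` may be a path or the XML text itself.
    """
    text = str(source)
    if not text.lstrip().startswith("<"):
        text = Path(source).read_text()
    root = ET.fromstring(text)
    refs = []
    for i in range(1, 4):
        x = root.findtext(f"X_CalibrationPoint_{i}")
        y = root.findtext(f"Y_CalibrationPoint_{i}")
        if x is None or y is None:
            raise ValueError(f"calibration point {i} missing")
        refs.append((float(x), float(y)))
    n_shapes = int(root.findtext("ShapeCount", "0"))
    contours: list[CellContour] = []
    for n in range(1, n_shapes + 1):
        shape = root.find(f"Shape_{n}")
        if shape is None:
            raise ValueError(f"Shape_{n} declared but missing")
        m = int(shape.findtext("PointCount"))
        cid = shape.findtext("CapID") or f"shape_{n}"
        xy = np.array(
            [[float(shape.findtext(f"X_{i}")), float(shape.findtext(f"Y_{i}"))]
             for i in range(1, m + 1)]
        )
        contours.append(CellContour.from_vertices(cid, xy))
    return contours, refs
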