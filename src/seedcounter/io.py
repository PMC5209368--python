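"""Readers and writers: images, measurement TSV/XML, label-map PNG.

TSV is the primary interchange format (one row per grain); an XML export
with the same content is available and validates against the schema shipped
as :data:`XML_SCHEMA` (also written next to each XML file on request).
Millimetre values are printed with 3 decimals, angles in degrees.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree
from PIL import Image

from .errors import InvalidInputError
from .segmentation import CalibrationProfile

__all__ = [
    "read_image",
    "write_image",
    "write_labelmap_png",
    "read_labelmap_png",
    "measurements_to_frame",
    "write_measurements_tsv",
    "write_measurements_xml",
    "validate_measurements_xml",
    "save_profile",
    "load_profile",
    "XML_SCHEMA",
]

MEASUREMENT_COLUMNS = [
    "image_id", "grain_id", "length_mm", "width_mm", "area_mm2",
    "centroid_offset_mm", "orientation_deg", "x_mm", "y_mm",
]

XML_SCHEMA = """\
<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:element name="seedcounter_run">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="image" maxOccurs="unbounded" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="grain" maxOccurs="unbounded" minOccurs="0">
                <xs:complexType>
                  <xs:attribute name="id" type="xs:integer" use="required"/>
                  <xs:attribute name="length_mm" type="xs:string"/>
                  <xs:attribute name="width_mm" type="xs:string"/>
                  <xs:attribute name="area_mm2" type="xs:string"/>
                  <xs:attribute name="centroid_offset_mm" type="xs:string"/>
                  <xs:attribute name="orientation_deg" type="xs:string"/>
                  <xs:attribute name="x_mm" type="xs:string"/>
                  <xs:attribute name="y_mm" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="count" type="xs:integer" use="required"/>
            <xs:attribute name="paper" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
"""


def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB image (PNG/JPEG) as a (H, W, 3) uint8 array."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except (OSError, ValueError) as exc:
        raise InvalidInputError(f"cannot read image {path}: {exc}") from exc


def write_image(path, array: np.ndarray) -> None:
    Image.fromarray(np.asarray(array, np.uint8)).save(path)


def write_labelmap_png(path, labels: np.ndarray) -> None:
    """Store a label raster as 16-bit grayscale PNG."""
    arr = np.asarray(labels)
    if arr.max() > np.iinfo(np.uint16).max:
        raise InvalidInputError("more than 65535 labels cannot go into 16-bit PNG")
    Image.fromarray(arr.astype(np.uint16)).save(path)


def read_labelmap_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im, dtype=np.int32)


def measurements_to_frame(measurements, image_id: str = "image") -> pd.DataFrame:
    """One row per grain; None shape fields become NaN."""
    rows = []
    for m in measurements:
        rows.append({
            "image_id": image_id,
            "grain_id": m.grain_id,
            "length_mm": m.length_mm,
            "width_mm": m.width_mm,
            "area_mm2": m.area_mm2,
            "centroid_offset_mm": m.centroid_offset_mm,
            "orientation_deg": (
                np.degrees(m.orientation_rad)
                if m.orientation_rad is not None else None
            ),
            "x_mm": m.centroid_xy_mm[0] if m.centroid_xy_mm else None,
            "y_mm": m.centroid_xy_mm[1] if m.centroid_xy_mm else None,
        })
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements_tsv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.3f")


def write_measurements_xml(path, per_image: dict, paper_name: str = "") -> None:
    """``per_image`` maps image_id -> measurement DataFrame."""
    root = etree.Element("seedcounter_run", version="1")
    for image_id, frame in per_image.items():
        img_el = etree.SubElement(
            root, "image", id=str(image_id), count=str(len(frame)),
            paper=paper_name,
        )
        for _, row in frame.iterrows():
            attrs = {"id": str(int(row["grain_id"]))}
            for col in MEASUREMENT_COLUMNS[2:]:
                val = row[col]
                if pd.notna(val):
                    attrs[col] = f"{val:.3f}"
            etree.SubElement(img_el, "grain", **attrs)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def validate_measurements_xml(path) -> bool:
    schema = etree.XMLSchema(etree.fromstring(XML_SCHEMA.encode()))
    doc = etree.parse(str(path))
    schema.assertValid(doc)
    return True


def write_contours_tsv(path, labelmap) -> None:
    """Export per-grain contours as polygon vertex lists.

    One row per vertex: grain_id, vertex_index, x_px, y_px.
    """
    rows = []
    for k, contour in labelmap.contours.items():
        for i, (x, y) in enumerate(contour):
            rows.append((k, i, x, y))
    frame = pd.DataFrame(rows, columns=["grain_id", "vertex", "x_px", "y_px"])
    frame.to_csv(path, sep="\t", index=False, float_format="%.2f")


def save_profile(path, profile: CalibrationProfile) -> None:
    Path(path).write_text(json.dumps(profile.to_dict(), indent=1))


def load_profile(path) -> CalibrationProfile:
    return CalibrationProfile.from_dict(json.loads(Path(path).read_text()))
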