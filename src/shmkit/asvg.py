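"""Annotated-SVG (aSVG) document model.

An aSVG is an ordinary SVG 1.1 file in which the drawable elements (or
groups of drawables) that represent anatomical *spatial features* --
organs, tissues, cell layers -- carry unique ``id`` attributes.  This
module parses such files into an editable in-memory document
(:class:`SVGDoc`), supports subsetting, tiling several anatomies into
one canvas, per-layer transparency edits, and lossless writing back to
standalone SVG.

Conventions
-----------
* Coordinates are kept in the SVG-native frame: user units, *y grows
  downward*.  Renderers that need a mathematical y-up frame flip at
  draw time.
* Any drawable (``path``, ``rect``, ``circle``, ``ellipse``,
  ``polygon``, ``polyline``, ``line``) **with an id** is a feature.  A
  ``g`` element with an id is also a feature; it "covers" descendant
  drawables that lack ids (they render with the group's fill), while
  id-bearing descendants become features of their own.  This matches
  the structure of EBI-anatomogram-style files where not every path is
  annotated.
* Layer index is document order: 0 = bottom-most feature.
"""

from __future__ import annotations

import copy
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .errors import DimensionError, SVGParseError, ValidationError

SVG_NS = "http://www.w3.org/2000/svg"
XLINK_NS = "http://www.w3.org/1999/xlink"

DRAWABLE_TAGS = frozenset(
    {"path", "rect", "circle", "ellipse", "polygon", "polyline", "line"}
)

#: presentation attributes promoted into :class:`FeatureStyle`
_STYLE_KEYS = ("fill", "stroke", "stroke-width", "opacity")

_NUM_RE = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")


def _fmt(x: float) -> str:
    """Fixed, locale-independent float formatting for deterministic output."""
    if isinstance(x, float) and x.is_integer():
        return str(int(x))
    return format(float(x), ".6g")


def _local(tag) -> str:
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


@dataclass
class Shape:
    """A single drawable primitive: its tag plus raw attributes.

    Geometry stays in the verbatim SVG attribute encoding so writing is
    lossless; :func:`shape_points` decodes it on demand for bounding
    boxes and rasterization.
    """

    tag: str
    attrs: dict[str, str] = field(default_factory=dict)


@dataclass
class FeatureStyle:
    fill: str | None = None
    stroke: str | None = None
    stroke_width: float | None = None
    opacity: float = 1.0
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.opacity <= 1.0:
            raise ValidationError(f"opacity {self.opacity} outside [0, 1]")


@dataclass
class SpatialFeature:
    """A colorable anatomical element identified by a unique id."""

    id: str
    shapes: list[Shape]
    layer_index: int
    style: FeatureStyle = field(default_factory=FeatureStyle)
    group_path: list[str] = field(default_factory=list)
    is_group: bool = False
    #: translation applied on write (set by :func:`combine_docs`)
    offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("feature id must be non-empty")
        if not self.shapes:
            raise ValidationError(f"feature {self.id!r} has no geometry")

    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in canvas coordinates, offset applied.

        For ``path`` shapes the box is taken over end *and* control
        points, a tight-enough conservative hull for feature placement.
        """
        xs: list[float] = []
        ys: list[float] = []
        for shp in self.shapes:
            for x, y in shape_points(shp):
                xs.append(x)
                ys.append(y)
        if not xs:
            raise ValidationError(f"feature {self.id!r}: no decodable geometry")
        dx, dy = self.offset
        return (min(xs) + dx, min(ys) + dy, max(xs) + dx, max(ys) + dy)


@dataclass
class SVGDoc:
    """Parsed anatomical image: ordered features on a fixed canvas."""

    features: list[SpatialFeature] = field(default_factory=list)
    width: float = 0.0
    height: float = 0.0
    source_paths: list[str] = field(default_factory=list)
    raster_path: str | None = None
    raster_opacity: float = 1.0
    raster_grayscale: bool = False
    #: decorative top-level drawables without ids (kept for fidelity)
    background: list[Shape] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise DimensionError(
                f"canvas dimensions must be positive, got {self.width}x{self.height}"
            )
        ids = [f.id for f in self.features]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate feature ids: {dupes}")
        if self.raster_path is not None and not Path(self.raster_path).is_file():
            raise ValidationError(f"raster file not found: {self.raster_path}")

    # -- convenience ---------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return [f.id for f in self.features]

    def __getitem__(self, fid: str) -> SpatialFeature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def copy(self) -> "SVGDoc":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# geometry decoding
# ---------------------------------------------------------------------------

def _floats(text: str) -> list[float]:
    return [float(m) for m in _NUM_RE.findall(text or "")]


def parse_path_points(d: str) -> list[tuple[float, float]]:
    """Decode an SVG path ``d`` string into its vertex and control points.

    Supports the full SVG 1.1 command set (M L H V C S Q T A Z, absolute
    and relative).  Arc commands contribute their endpoints only; curve
    control points are included, giving a conservative hull.
    """
    tokens = re.findall(r"[MmLlHhVvCcSsQqTtAaZz]|" + _NUM_RE.pattern, d or "")
    pts: list[tuple[float, float]] = []
    cx = cy = 0.0  # current point
    sx = sy = 0.0  # subpath start
    i = 0
    cmd = ""

    def take(n: int) -> list[float]:
        nonlocal i
        vals = [float(t) for t in tokens[i : i + n]]
        if len(vals) < n:
            raise ValidationError(f"truncated path data near token {i}: {d[:40]!r}")
        i += n
        return vals

    while i < len(tokens):
        t = tokens[i]
        if t.isalpha():
            cmd = t
            i += 1
            if cmd in "Zz":
                cx, cy = sx, sy
                continue
        elif not cmd:
            raise ValidationError("path data does not start with a command")
        rel = cmd.islower()
        c = cmd.upper()
        if c == "M":
            x, y = take(2)
            cx, cy = (cx + x, cy + y) if rel else (x, y)
            sx, sy = cx, cy
            pts.append((cx, cy))
            cmd = "l" if rel else "L"  # subsequent pairs are implicit lineto
        elif c == "L":
            x, y = take(2)
            cx, cy = (cx + x, cy + y) if rel else (x, y)
            pts.append((cx, cy))
        elif c == "H":
            (x,) = take(1)
            cx = cx + x if rel else x
            pts.append((cx, cy))
        elif c == "V":
            (y,) = take(1)
            cy = cy + y if rel else y
            pts.append((cx, cy))
        elif c == "C":
            x1, y1, x2, y2, x, y = take(6)
            if rel:
                x1, y1, x2, y2, x, y = (
                    cx + x1, cy + y1, cx + x2, cy + y2, cx + x, cy + y,
                )
            pts.extend([(x1, y1), (x2, y2), (x, y)])
            cx, cy = x, y
        elif c == "S":
            x2, y2, x, y = take(4)
            if rel:
                x2, y2, x, y = cx + x2, cy + y2, cx + x, cy + y
            pts.extend([(x2, y2), (x, y)])
            cx, cy = x, y
        elif c == "Q":
            x1, y1, x, y = take(4)
            if rel:
                x1, y1, x, y = cx + x1, cy + y1, cx + x, cy + y
            pts.extend([(x1, y1), (x, y)])
            cx, cy = x, y
        elif c == "T":
            x, y = take(2)
            cx, cy = (cx + x, cy + y) if rel else (x, y)
            pts.append((cx, cy))
        elif c == "A":
            _rx, _ry, _rot, _laf, _sf, x, y = take(7)
            cx, cy = (cx + x, cy + y) if rel else (x, y)
            pts.append((cx, cy))
        else:  # pragma: no cover - regex admits only the above
            raise ValidationError(f"unsupported path command {cmd!r}")
    return pts


def shape_points(shape: Shape) -> list[tuple[float, float]]:
    """Representative outline points of a primitive (for bboxes/rendering)."""
    a = shape.attrs
    g = lambda k, d=0.0: float(a.get(k, d))  # noqa: E731
    tag = shape.tag
    if tag == "rect":
        x, y, w, h = g("x"), g("y"), g("width"), g("height")
        return [(x, y), (x + w, y), (x + w, y + h), (x, y + h)]
    if tag == "circle":
        cx, cy, r = g("cx"), g("cy"), g("r")
        return [(cx - r, cy - r), (cx + r, cy + r)]
    if tag == "ellipse":
        cx, cy, rx, ry = g("cx"), g("cy"), g("rx"), g("ry")
        return [(cx - rx, cy - ry), (cx + rx, cy + ry)]
    if tag == "line":
        return [(g("x1"), g("y1")), (g("x2"), g("y2"))]
    if tag in ("polygon", "polyline"):
        nums = _floats(a.get("points", ""))
        return list(zip(nums[0::2], nums[1::2]))
    if tag == "path":
        return parse_path_points(a.get("d", ""))
    raise ValidationError(f"unknown shape tag {tag!r}")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_style(attrs: dict[str, str]) -> FeatureStyle:
    """Promote presentation attributes + inline ``style`` to a style record.

    Inline ``style`` declarations override presentation attributes;
    unknown inline keys are preserved verbatim in ``extra``.
    """
    merged: dict[str, str] = {k: attrs[k] for k in _STYLE_KEYS if k in attrs}
    extra: dict[str, str] = {}
    for decl in (attrs.get("style") or "").split(";"):
        if ":" not in decl:
            continue
        k, v = decl.split(":", 1)
        k, v = k.strip(), v.strip()
        if k in _STYLE_KEYS:
            merged[k] = v
        elif k:
            extra[k] = v
    sw = merged.get("stroke-width")
    op = merged.get("opacity")
    return FeatureStyle(
        fill=merged.get("fill"),
        stroke=merged.get("stroke"),
        stroke_width=float(_floats(sw)[0]) if sw else None,
        opacity=float(op) if op is not None else 1.0,
        extra=extra,
    )


def _geometry_attrs(el, strip_style: bool = False) -> dict[str, str]:
    """Attributes to carry on a Shape.

    ``strip_style=True`` (used for id-bearing drawables) removes the
    presentation attributes promoted into FeatureStyle, so styling has a
    single source of truth and writing is byte-stable.
    """
    skip = {"id", "style"}
    if strip_style:
        skip |= set(_STYLE_KEYS)
    return {
        k: v
        for k, v in el.attrib.items()
        if _local(k) not in skip and not _local(k).startswith("xlink")
    }


def _canvas_size(root) -> tuple[float, float]:
    def dim(name: str) -> float | None:
        v = root.get(name)
        if v is None:
            return None
        nums = _floats(v)
        return nums[0] if nums else None

    w, h = dim("width"), dim("height")
    if w is None or h is None:
        vb = _floats(root.get("viewBox", ""))
        if len(vb) == 4:
            w = w if w is not None else vb[2]
            h = h if h is not None else vb[3]
    if w is None or h is None:
        raise DimensionError(
            "SVG root carries neither width/height nor a viewBox"
        )
    return w, h


def parse_asvg(path: str | Path) -> SVGDoc:
    """Parse an annotated SVG file into an :class:`SVGDoc`.

    Every drawable or group element bearing an ``id`` becomes a
    :class:`SpatialFeature`; document order defines ``layer_index``.

    Raises
    ------
    SVGParseError
        malformed XML (message names the offending line) or non-SVG root.
    ValidationError
        duplicate feature ids.
    DimensionError
        no width/height and no viewBox on the root.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SVGParseError(f"{path}: malformed XML at line {exc.lineno}: {exc.msg}") from exc
    root = tree.getroot()
    if _local(root.tag) != "svg":
        raise SVGParseError(f"{path}: root element is <{_local(root.tag)}>, not <svg>")
    width, height = _canvas_size(root)

    features: list[SpatialFeature] = []
    background: list[Shape] = []

    def anonymous_shapes(gel) -> list[Shape]:
        """Descendant drawables lacking ids, skipping id-bearing subtrees."""
        out: list[Shape] = []
        for child in gel:
            tag = _local(child.tag)
            if child.get("id"):
                continue  # becomes (or contains) its own feature(s)
            if tag in DRAWABLE_TAGS:
                out.append(Shape(tag, _geometry_attrs(child)))
            elif tag == "g":
                out.extend(anonymous_shapes(child))
        return out

    def walk(el, group_path: list[str]) -> None:
        for child in el:
            tag = _local(child.tag)
            fid = child.get("id")
            if tag == "g":
                if fid:
                    shapes = anonymous_shapes(child)
                    if shapes:
                        features.append(
                            SpatialFeature(
                                id=fid,
                                shapes=shapes,
                                layer_index=len(features),
                                style=_parse_style(dict(child.attrib)),
                                group_path=list(group_path),
                                is_group=True,
                            )
                        )
                    walk(child, group_path + [fid])
                else:
                    walk(child, group_path)
            elif tag in DRAWABLE_TAGS:
                if fid:
                    features.append(
                        SpatialFeature(
                            id=fid,
                            shapes=[Shape(tag, _geometry_attrs(child, strip_style=True))],
                            layer_index=len(features),
                            style=_parse_style(dict(child.attrib)),
                            group_path=list(group_path),
                        )
                    )
                elif not group_path:
                    background.append(Shape(tag, _geometry_attrs(child)))

    walk(root, [])

    ids = [f.id for f in features]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate feature ids: {dupes}")
    if not features:
        warnings.warn(f"{path}: no id-bearing drawable elements found", stacklevel=2)

    return SVGDoc(
        features=features,
        width=width,
        height=height,
        source_paths=[str(path)],
        background=background,
    )


# ---------------------------------------------------------------------------
# editing operations (pure: inputs are never mutated)
# ---------------------------------------------------------------------------

def subset_features(doc: SVGDoc, ids: Iterable[str]) -> SVGDoc:
    """Return a new document containing exactly the named features.

    Original order and styles are preserved; layer indices are re-packed
    to stay contiguous from 0.
    """
    wanted = set(ids)
    missing = sorted(wanted - set(doc.feature_ids))
    if missing:
        raise ValidationError(f"unknown feature ids: {missing}")
    out = doc.copy()
    out.features = [f for f in out.features if f.id in wanted]
    for k, f in enumerate(out.features):
        f.layer_index = k
    return out


def combine_docs(
    docs: Sequence[SVGDoc],
    arrangement: str = "horizontal",
    gap: float | None = None,
) -> SVGDoc:
    """Tile several anatomies onto one canvas.

    Canvases are laid out left-to-right (``horizontal``) or
    top-to-bottom (``vertical``) separated by ``gap`` user units
    (default: 2% of the largest canvas dimension across inputs).
    Feature ids colliding with an earlier document are suffixed
    ``__k`` where *k* is the 2-based document position.
    """
    if len(docs) < 2:
        raise ValidationError("combine_docs needs at least 2 documents")
    if arrangement not in ("horizontal", "vertical"):
        raise ValidationError(f"unknown arrangement {arrangement!r}")
    if gap is None:
        gap = 0.02 * max(max(d.width, d.height) for d in docs)

    seen: set[str] = set()
    merged: list[SpatialFeature] = []
    background: list[Shape] = []
    sources: list[str] = []
    ox = oy = 0.0
    for k, doc in enumerate(docs, start=1):
        part = doc.copy()
        for f in part.features:
            if f.id in seen:
                new_id = f"{f.id}__{k}"
                if new_id in seen:
                    raise ValidationError(f"id collision not resolvable: {new_id!r}")
                f.id = new_id
            seen.add(f.id)
            f.offset = (f.offset[0] + ox, f.offset[1] + oy)
            f.layer_index = len(merged)
            merged.append(f)
        background.extend(part.background)
        sources.extend(part.source_paths)
        if arrangement == "horizontal":
            ox += doc.width + gap
        else:
            oy += doc.height + gap

    if arrangement == "horizontal":
        width = sum(d.width for d in docs) + gap * (len(docs) - 1)
        height = max(d.height for d in docs)
    else:
        width = max(d.width for d in docs)
        height = sum(d.height for d in docs) + gap * (len(docs) - 1)
    return SVGDoc(
        features=merged,
        width=width,
        height=height,
        source_paths=sources,
        background=background,
    )


def set_layer_opacity(
    doc: SVGDoc,
    alpha: float,
    ids: Iterable[str] | None = None,
    layers: tuple[int, int] | None = None,
) -> SVGDoc:
    """Set the opacity of selected features (by id set or layer range).

    ``layers`` is an inclusive ``(low, high)`` range of layer indices.
    Exactly one selector must be given; others keep their opacity.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha {alpha} outside [0, 1]")
    if (ids is None) == (layers is None):
        raise ValidationError("give exactly one of ids= or layers=")
    out = doc.copy()
    if ids is not None:
        wanted = set(ids)
        missing = sorted(wanted - set(out.feature_ids))
        if missing:
            raise ValidationError(f"unknown feature ids: {missing}")
        hit = [f for f in out.features if f.id in wanted]
    else:
        lo, hi = layers
        hit = [f for f in out.features if lo <= f.layer_index <= hi]
    for f in hit:
        f.style.opacity = alpha
    return out


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _style_to_attrs(el, style: FeatureStyle) -> None:
    if style.fill is not None:
        el.set("fill", style.fill)
    if style.stroke is not None:
        el.set("stroke", style.stroke)
    if style.stroke_width is not None:
        el.set("stroke-width", _fmt(style.stroke_width))
    el.set("opacity", _fmt(style.opacity))
    if style.extra:
        el.set("style", ";".join(f"{k}:{v}" for k, v in sorted(style.extra.items())))


def _grayscale_sidecar(raster: str, out_dir: Path) -> str:
    from PIL import Image

    src = Path(raster)
    dst = out_dir / f"{src.stem}__gray.png"
    Image.open(src).convert("L").convert("RGB").save(dst)
    return dst.name


def write_svg(doc: SVGDoc, path: str | Path) -> None:
    """Write a standalone SVG 1.1 file.

    ``parse_asvg`` of the output reproduces feature ids, layer order and
    styles exactly; geometry round-trips verbatim (it is stored in its
    source encoding).  A raster reference, when present, is embedded as
    an ``<image>`` element *below* all vector layers.
    """
    path = Path(path)
    root = etree.Element(
        f"{{{SVG_NS}}}svg",
        nsmap={None: SVG_NS, "xlink": XLINK_NS},
    )
    root.set("version", "1.1")
    root.set("width", _fmt(doc.width))
    root.set("height", _fmt(doc.height))
    root.set("viewBox", f"0 0 {_fmt(doc.width)} {_fmt(doc.height)}")

    if doc.raster_path is not None:
        href = doc.raster_path
        if doc.raster_grayscale:
            href = _grayscale_sidecar(doc.raster_path, path.parent)
        img = etree.SubElement(root, f"{{{SVG_NS}}}image")
        img.set("x", "0")
        img.set("y", "0")
        img.set("width", _fmt(doc.width))
        img.set("height", _fmt(doc.height))
        img.set(f"{{{XLINK_NS}}}href", str(href))
        img.set("opacity", _fmt(doc.raster_opacity))
        img.set("preserveAspectRatio", "none")

    for shp in doc.background:
        el = etree.SubElement(root, f"{{{SVG_NS}}}{shp.tag}")
        for k, v in shp.attrs.items():
            el.set(k, v)

    for f in sorted(doc.features, key=lambda f: f.layer_index):
        if f.is_group:
            el = etree.SubElement(root, f"{{{SVG_NS}}}g")
            for shp in f.shapes:
                sub = etree.SubElement(el, f"{{{SVG_NS}}}{shp.tag}")
                for k, v in shp.attrs.items():
                    sub.set(k, v)
        else:
            shp = f.shapes[0]
            el = etree.SubElement(root, f"{{{SVG_NS}}}{shp.tag}")
            for k, v in shp.attrs.items():
                el.set(k, v)
        el.set("id", f.id)
        if f.offset != (0.0, 0.0):
            el.set("transform", f"translate({_fmt(f.offset[0])},{_fmt(f.offset[1])})")
        _style_to_attrs(el, f.style)

    data = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    try:
        Path(path).write_bytes(data)
    except OSError as exc:
        raise ShmkitIOError(str(exc)) from exc


class ShmkitIOError(OSError):
    """Raised when an output path cannot be written."""
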