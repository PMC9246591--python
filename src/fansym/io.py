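"""Plain-text and portable-binary readers/writers for grids, sinograms, specs.

Plain text is the canonical interchange (diff-able); binary (NumPy ``.npy``
with a JSON sidecar) is an optional size optimization.

Formats
-------
* Image grid (text): comment header ``# fansym-image n=<n> pixel_size=<p>``
  followed by ``n`` rows of ``n`` whitespace-separated reals.
* Image grid (PGM): ASCII ``P2`` with a comment line
  ``# scale <min> <max> pixel_size <p>`` recording the affine mapping from
  stored integers back to physical values; 8- or 16-bit.
* Sinogram (text): comment header carrying the geometry
  (``D``, ``n_views``, ``n_bins``, ``bin_spacing``) followed by one row per
  view.
* Phantom spec: YAML with ``bounding_radius`` and one mapping per ellipse.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .phantom import Ellipse, ImageGrid, PhantomSpec
from .projection import FanBeamGeometry, Sinogram

__all__ = [
    "read_image",
    "write_image",
    "read_pgm",
    "write_pgm",
    "read_sinogram",
    "write_sinogram",
    "read_phantom_spec",
    "write_phantom_spec",
]


class FormatError(ValueError):
    """Malformed file content, reported with location information."""


# ---------------------------------------------------------------- image text

def write_image(path, grid: ImageGrid) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fansym-image n={grid.n} pixel_size={grid.pixel_size!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_image(path) -> ImageGrid:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# fansym-image"):
        raise FormatError(f"{path}: line 1: missing '# fansym-image' header")
    header = dict(tok.split("=", 1) for tok in lines[0].split()[2:])
    try:
        n = int(header["n"])
        pixel_size = float(header["pixel_size"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: line 1: bad header ({exc})") from exc
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        toks = line.split()
        vals = []
        for colno, tok in enumerate(toks, start=1):
            try:
                vals.append(float(tok))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}, column {colno}: non-numeric token {tok!r}"
                ) from None
        rows.append(vals)
    arr = np.array(rows)
    if arr.shape != (n, n):
        raise FormatError(f"{path}: expected {n}x{n} values, got {arr.shape}")
    return ImageGrid(arr, pixel_size)


# ----------------------------------------------------------------- image PGM

def write_pgm(path, grid: ImageGrid, bits: int = 8) -> None:
    """ASCII PGM with the value->integer scaling recorded in a comment line."""
    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    maxval = (1 << bits) - 1
    v = grid.values
    if np.all(v == np.round(v)) and v.min() >= 0 and v.max() <= maxval:
        # integer-valued grid already in range: store verbatim (exact round trip)
        lo, hi = 0.0, float(maxval)
        ints = v.astype(int)
    else:
        lo, hi = float(v.min()), float(v.max())
        scale = (hi - lo) or 1.0
        ints = np.round((v - lo) / scale * maxval).astype(int)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("P2\n")
        fh.write(f"# scale {lo!r} {hi!r} pixel_size {grid.pixel_size!r}\n")
        fh.write(f"{grid.n} {grid.n}\n{maxval}\n")
        for row in ints:
            fh.write(" ".join(str(v) for v in row) + "\n")


def read_pgm(path) -> ImageGrid:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "P2":
        raise FormatError(f"{path}: line 1: expected ASCII PGM magic 'P2'")
    lo = hi = None
    pixel_size = 1.0
    body: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        stripped = line.strip()
        if stripped.startswith("#"):
            toks = stripped.split()
            if len(toks) >= 3 and toks[1] == "scale":
                try:
                    lo, hi = float(toks[2]), float(toks[3])
                    if len(toks) >= 6 and toks[4] == "pixel_size":
                        pixel_size = float(toks[5])
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}: line {lineno}: bad scale comment") from exc
            continue
        if stripped:
            body.append(stripped)
    toks = " ".join(body).split()
    try:
        w, h, maxval = int(toks[0]), int(toks[1]), int(toks[2])
        ints = np.array([int(t) for t in toks[3:]]).reshape(h, w)
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed PGM body ({exc})") from exc
    if lo is None:
        lo, hi = 0.0, float(maxval)
    span = (hi - lo) or 1.0
    return ImageGrid(ints / maxval * span + lo, pixel_size)


# ------------------------------------------------------------------ sinogram

def write_sinogram(path, sino: Sinogram, fmt: str = "text") -> None:
    path = Path(path)
    g = sino.geometry
    meta = {
        "D": g.D,
        "n_views": g.n_views,
        "n_bins": g.n_bins,
        "bin_spacing": g.bin_spacing,
    }
    if fmt == "text":
        with path.open("w") as fh:
            fh.write(
                f"# fansym-sinogram D={g.D!r} n_views={g.n_views} "
                f"n_bins={g.n_bins} bin_spacing={g.bin_spacing!r}\n"
            )
            for row in sino.values:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    elif fmt == "npy":
        np.save(path, sino.values)
        Path(str(path) + ".json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unknown sinogram format {fmt!r}; expected 'text' or 'npy'")


def read_sinogram(path, fmt: str = "text") -> Sinogram:
    path = Path(path)
    if fmt == "npy":
        meta = json.loads(Path(str(path) + ".json").read_text())
        geom = FanBeamGeometry(
            D=meta["D"],
            n_views=meta["n_views"],
            n_bins=meta["n_bins"],
            bin_spacing=meta["bin_spacing"],
        )
        return Sinogram(geom, np.load(path))
    if fmt != "text":
        raise ValueError(f"unknown sinogram format {fmt!r}; expected 'text' or 'npy'")
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# fansym-sinogram"):
        raise FormatError(f"{path}: line 1: missing '# fansym-sinogram' header")
    header = dict(tok.split("=", 1) for tok in lines[0].split()[2:])
    try:
        geom = FanBeamGeometry(
            D=float(header["D"]),
            n_views=int(header["n_views"]),
            n_bins=int(header["n_bins"]),
            bin_spacing=float(header["bin_spacing"]),
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: line 1: bad header ({exc})") from exc
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        toks = line.split()
        if len(toks) != geom.n_bins:
            raise FormatError(
                f"{path}: line {lineno}: {len(toks)} values but header says "
                f"n_bins={geom.n_bins}"
            )
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric token ({exc})") from None
    arr = np.array(rows)
    if arr.shape[0] != geom.n_views:
        raise FormatError(
            f"{path}: {arr.shape[0]} view rows but header says n_views={geom.n_views}"
        )
    return Sinogram(geom, arr)


# -------------------------------------------------------------- phantom spec

def write_phantom_spec(path, spec: PhantomSpec) -> None:
    doc = {
        "bounding_radius": spec.bounding_radius,
        "ellipses": [
            {
                "cx": e.cx, "cy": e.cy, "a": e.a, "b": e.b,
                "theta_deg": e.theta_deg, "value": e.value,
            }
            for e in spec.ellipses
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_phantom_spec(path) -> PhantomSpec:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    try:
        ellipses = tuple(
            Ellipse(
                cx=float(e["cx"]), cy=float(e["cy"]),
                a=float(e["a"]), b=float(e["b"]),
                theta_deg=float(e.get("theta_deg", 0.0)),
                value=float(e["value"]),
            )
            for e in doc["ellipses"]
        )
        return PhantomSpec(ellipses, float(doc["bounding_radius"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed phantom spec ({exc})") from exc
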