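"""Readers/writers: plain-text free-energy grids, HDF5 containers, XYZ.

The text grid format is self-describing and bit-stable at 12 significant
digits: header lines ``# dim <name> <min> <max> <nbins> <periodic>`` (one
per dimension), then one line per bin in row-major order with the
multi-index, bin-center coordinates, count, P, W and U.
"""

from __future__ import annotations

import numpy as np

from .bias import BiasGrid, DimSpec, GridSpec

__all__ = ["write_fev", "read_fev", "write_fev_h5", "read_fev_h5",
           "write_xyz", "read_xyz", "write_table"]

_FMT = "%.12g"


class FormatError(ValueError):
    pass


def write_fev(path, grid: BiasGrid) -> None:
    """Write a bias/free-energy grid in the plain-text format."""
    spec = grid.spec
    with open(path, "w") as fh:
        fh.write("# FEV grid, %d dimension(s), temperature_K %s\n"
                 % (spec.ndim, _FMT % grid.temperature))
        for d in spec.dims:
            fh.write("# dim %s %s %s %d %d\n"
                     % (d.name, _FMT % d.min, _FMT % d.max, d.n_bins,
                        int(d.periodic)))
        fh.write("# columns: " + " ".join(
            [f"i{k}" for k in range(spec.ndim)]
            + [d.name for d in spec.dims] + ["count", "P", "W", "U"]) + "\n")
        counts = grid.counts if grid.counts is not None else np.zeros(spec.shape)
        P = grid.P if grid.P is not None else np.zeros(spec.shape)
        W = grid.W if grid.W is not None else np.zeros(spec.shape)
        U = grid.U if grid.U is not None else np.zeros(spec.shape)
        centers = [d.centers for d in spec.dims]
        for mi in np.ndindex(*spec.shape):
            row = [str(i) for i in mi]
            row += [_FMT % centers[k][mi[k]] for k in range(spec.ndim)]
            row += [_FMT % counts[mi], _FMT % P[mi], _FMT % W[mi], _FMT % U[mi]]
            fh.write(" ".join(row) + "\n")


def read_fev(path) -> BiasGrid:
    """Read a plain-text grid written by :func:`write_fev`."""
    dims = []
    temperature = 300.0
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["dim"]:
                    if len(parts) != 6:
                        raise FormatError(f"malformed dim header: {line!r}")
                    dims.append(DimSpec(parts[1], float(parts[2]),
                                        float(parts[3]), int(parts[4]),
                                        bool(int(parts[5]))))
                elif "temperature_K" in parts:
                    temperature = float(parts[parts.index("temperature_K") + 1])
                continue
            rows.append(line.split())
    if not dims:
        raise FormatError("no dimension headers found")
    spec = GridSpec(tuple(dims))
    n = int(np.prod(spec.shape))
    if len(rows) != n:
        raise FormatError(f"expected {n} bins, found {len(rows)}")
    d = spec.ndim
    counts = np.empty(spec.shape)
    P = np.empty(spec.shape)
    W = np.empty(spec.shape)
    U = np.empty(spec.shape)
    for row in rows:
        if len(row) != 2 * d + 4:
            raise FormatError(f"malformed bin row: {row!r}")
        mi = tuple(int(v) for v in row[:d])
        try:
            counts[mi], P[mi], W[mi], U[mi] = (float(v) for v in row[2 * d:])
        except IndexError as exc:
            raise FormatError(f"bin index {mi} out of range") from exc
    return BiasGrid(spec, temperature=temperature, counts=counts, P=P, W=W, U=U)


def write_fev_h5(path, grid: BiasGrid) -> None:
    """Same content as the text format, in an HDF5 container."""
    import h5py
    with h5py.File(path, "w") as f:
        f.attrs["temperature_K"] = grid.temperature
        for k, d in enumerate(grid.spec.dims):
            g = f.create_group(f"dim{k}")
            g.attrs.update({"name": d.name, "min": d.min, "max": d.max,
                            "n_bins": d.n_bins, "periodic": d.periodic})
        for name in ("counts", "P", "W", "U"):
            arr = getattr(grid, name)
            if arr is not None:
                f.create_dataset(name, data=arr)


def read_fev_h5(path) -> BiasGrid:
    import h5py
    with h5py.File(path, "r") as f:
        dims = []
        k = 0
        while f"dim{k}" in f:
            a = f[f"dim{k}"].attrs
            dims.append(DimSpec(str(a["name"]), float(a["min"]),
                                float(a["max"]), int(a["n_bins"]),
                                bool(a["periodic"])))
            k += 1
        if not dims:
            raise FormatError("no dimensions in container")
        arrays = {name: f[name][()] if name in f else None
                  for name in ("counts", "P", "W", "U")}
        return BiasGrid(GridSpec(tuple(dims)),
                        temperature=float(f.attrs["temperature_K"]), **arrays)


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def write_xyz(path, trajectory, elements, comments=None, mode="w") -> None:
    """Standard XYZ: frames (n_frames, n_atoms, 3), element symbols per atom.

    ``comments`` (one per frame) conventionally carries the time in fs and
    the RC values.  Coordinates are printed at 6 decimals.
    """
    frames = np.asarray(trajectory, float)
    if frames.ndim == 2:
        frames = frames[None]
    n_atoms = frames.shape[1]
    if len(elements) != n_atoms:
        raise ValueError("one element symbol per atom required")
    with open(path, mode) as fh:
        for fi, frame in enumerate(frames):
            fh.write(f"{n_atoms}\n")
            fh.write((comments[fi] if comments is not None else f"frame {fi}")
                     .replace("\n", " ") + "\n")
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path):
    """Read an XYZ file; returns (frames (n, n_atoms, 3), elements, comments)."""
    frames, comments = [], []
    elements = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"bad atom count line {i + 1}: {lines[i]!r}") from exc
        if i + 1 + n >= len(lines) + 1:
            raise FormatError("truncated XYZ frame")
        comments.append(lines[i + 1])
        frame, els = [], []
        for ln in lines[i + 2:i + 2 + n]:
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"malformed XYZ atom line: {ln!r}")
            els.append(parts[0])
            frame.append([float(v) for v in parts[1:4]])
        if elements is None:
            elements = els
        elif els != elements:
            raise FormatError("inconsistent elements across frames")
        frames.append(frame)
        i += 2 + n
    if not frames:
        raise FormatError("empty XYZ file")
    return np.array(frames), elements, comments


def write_table(path, columns: dict, header: str | None = None) -> None:
    """Tab-separated numeric table with a ``# name1\\tname2...`` header."""
    names = list(columns)
    arrs = [np.asarray(columns[n]).ravel() for n in names]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("columns differ in length")
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# " + "\t".join(names) + "\n")
        for i in range(n):
            fh.write("\t".join(_FMT % a[i] for a in arrs) + "\n")
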