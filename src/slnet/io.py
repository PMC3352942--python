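"""Readers and writers for recordings, matrices, edge lists and tables.

Delimited recording layout (tab-separated): a header line
``# fs=<Hz> labels=<comma-separated>`` followed by one row of samples per
channel. Connectivity matrices are written as labeled tab-delimited text;
edge lists as two columns of vertex labels. EDF input goes through mne; a
minimal 16-bit EDF writer is provided for round trips and cohort export.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import ConfigurationError, Recording
from .sl import ConnectivityMatrix, SLParams


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# delimited recordings


def write_recording(rec: Recording, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={rec.fs:g} labels={','.join(rec.labels)}")
        if rec.substituted:
            fh.write(f" substituted={','.join(sorted(rec.substituted))}")
        fh.write("\n")
        for row in rec.data:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def _read_delimited_recording(path: Path) -> Recording:
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ParseError(f"{path}:1: expected '# fs=... labels=...' header")
        fields = dict(
            item.split("=", 1) for item in header.lstrip("# ").split() if "=" in item
        )
        try:
            fs = float(fields["fs"])
            labels = fields["labels"].split(",")
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}:1: malformed header ({exc})") from exc
        substituted = frozenset(
            fields.get("substituted", "").split(",")) - frozenset({""})
        rows = []
        width = None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(parts)} values, "
                    f"expected {width})"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if len(rows) != len(labels):
        raise ParseError(
            f"{path}: {len(rows)} channel rows for {len(labels)} labels")
    return Recording(data=np.array(rows), fs=fs, labels=labels,
                     substituted=substituted)


# ---------------------------------------------------------------------------
# EDF (European Data Format), 16-bit continuous


def write_edf(rec: Recording, path) -> None:
    """Minimal EDF export: one data record spanning the whole recording,
    int16 samples scaled to the physical range of each channel."""
    path = Path(path)
    n_ch = rec.n_channels
    n_samp = rec.n_samples
    duration = n_samp / rec.fs

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    # physical limits rounded outward so they print exactly in 8 ascii chars
    phys_min = np.floor(rec.data.min(axis=1) * 100) / 100
    phys_max = np.ceil(rec.data.max(axis=1) * 100) / 100
    phys_max = np.where(phys_max - phys_min == 0, phys_min + 1, phys_max)
    if max(abs(phys_min).max(), abs(phys_max).max()) >= 10000:
        raise ConfigurationError("EDF export supports amplitudes below 1e4 uV")

    header = b"".join([
        pad("0", 8), pad("synthetic", 80), pad("synthetic", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8), pad("", 44), pad("1", 8),
        pad(f"{duration:g}", 8), pad(str(n_ch), 4),
    ])
    header += b"".join(pad(lab, 16) for lab in rec.labels)
    header += b"".join(pad("AgAgCl electrode", 80) for _ in range(n_ch))
    header += b"".join(pad("uV", 8) for _ in range(n_ch))
    header += b"".join(pad(f"{phys_min[i]:.2f}", 8) for i in range(n_ch))
    header += b"".join(pad(f"{phys_max[i]:.2f}", 8) for i in range(n_ch))
    header += b"".join(pad("-32768", 8) for _ in range(n_ch))
    header += b"".join(pad("32767", 8) for _ in range(n_ch))
    header += b"".join(pad("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(pad(str(n_samp), 8) for _ in range(n_ch))
    header += b"".join(pad("", 32) for _ in range(n_ch))  # per-signal reserved

    with path.open("wb") as fh:
        fh.write(header)
        for i in range(n_ch):
            scaled = (rec.data[i] - phys_min[i]) / (phys_max[i] - phys_min[i])
            dig = np.round(scaled * 65535.0 - 32768.0).astype("<i2")
            fh.write(dig.tobytes())


def _read_edf(path: Path) -> Recording:
    import mne  # heavy import, deferred

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # mne converts EDF physical units (uV) to volts; convert back
    return Recording(data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                     labels=list(raw.ch_names))


def read_recording(path, format: str | None = None) -> Recording:
    """Read a Recording from an EDF or delimited text file.

    ``format`` is "edf" or "delimited"; by default it is inferred from the
    file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_delimited_recording(path)
    raise ConfigurationError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# matrices, edge lists, tables


def write_matrix(conn: ConnectivityMatrix, path, provenance: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        p = conn.params
        fh.write(f"# sl-params m={p.m} l={p.l} p_ref={p.p_ref} w1={p.w1} w2={p.w2}\n")
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("\t" + "\t".join(conn.labels) + "\n")
        for lab, row in zip(conn.labels, conn.values):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_matrix(path) -> ConnectivityMatrix:
    path = Path(path)
    params = None
    lines = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("# sl-params"):
                fields = dict(item.split("=") for item in line.split()[2:])
                params = SLParams(m=int(fields["m"]), l=int(fields["l"]),
                                  p_ref=float(fields["p_ref"]),
                                  w1=int(fields["w1"]), w2=int(fields["w2"]))
            elif not line.startswith("#"):
                lines.append(line)
    if params is None:
        raise ParseError(f"{path}: missing '# sl-params' header")
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t", index_col=0)
    return ConnectivityMatrix(values=df.to_numpy(dtype=float),
                              labels=list(df.columns), params=params)


def write_edge_list(graph, labels, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_vertices={graph.n}\n")
        for u, v in sorted(graph.edges):
            fh.write(f"{labels[u]}\t{labels[v]}\n")


def read_edge_list(path, labels) -> "BinaryGraph":
    from .graphs import BinaryGraph

    path = Path(path)
    index = {lab: i for i, lab in enumerate(labels)}
    edges = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two labels")
            try:
                edges.append((index[parts[0]], index[parts[1]]))
            except KeyError as exc:
                raise ParseError(f"{path}:{lineno}: unknown label {exc}") from exc
    return BinaryGraph.from_edges(len(labels), edges)


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Tab-delimited table with a commented provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
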