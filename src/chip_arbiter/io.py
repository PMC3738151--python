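"""Readers, writers and core containers for probe tracks and annotation.

All coordinates are held internally as 0-based half-open intervals.  GFF3
input (1-based inclusive) is converted at the boundary; BED and bedGraph are
already in the internal convention.  Tracks are single-sequence: one bacterial
chromosome per :class:`ProbeTrack`.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chip_arbiter")

__all__ = [
    "ProbeTrack",
    "GeneAnnotation",
    "CoordinateTable",
    "read_probe_track",
    "read_probe_tracks",
    "write_probe_track",
    "read_annotation",
    "write_annotation",
    "read_coordinate_table",
    "write_table",
    "read_table",
]


class ValidationError(ValueError):
    """Input violates a structural contract (ordering, bounds, pairing)."""


@dataclass(frozen=True)
class ProbeTrack:
    """Ordered per-probe signal values for one replicate on one sequence.

    Parameters
    ----------
    sequence_id
        Chromosome / replicon name.
    starts, ends
        Probe intervals, 0-based half-open, sorted by start.
    values
        One signal value per probe (arbitrary units).
    label
        Study/replicate identifier, e.g. ``"A_rep1"``.
    n_dropped
        Number of NaN/blank probes removed at load time.
    """

    sequence_id: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    label: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "values", values)
        if not (len(starts) == len(ends) == len(values)):
            raise ValidationError("starts, ends and values must have equal length")
        if len(starts) == 0:
            raise ValidationError(f"track {self.label!r} is empty")
        if np.any(np.diff(starts) <= 0):
            raise ValidationError(f"track {self.label!r}: probe starts not strictly increasing")
        if np.any(ends <= starts):
            raise ValidationError(f"track {self.label!r}: probe end <= start")
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"track {self.label!r}: non-finite values after loading")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        """Probe midpoints in bp (integer division)."""
        return (self.starts + self.ends) // 2


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene intervals on one sequence plus the total genome length.

    ``genes`` is a DataFrame with columns sequence_id, start, end, strand,
    name (0-based half-open, strand in {+, -}), sorted by start.
    """

    genes: pd.DataFrame
    genome_length: int

    def __post_init__(self) -> None:
        required = ["sequence_id", "start", "end", "strand", "name"]
        genes = self.genes.loc[:, required].copy()
        genes["start"] = genes["start"].astype(np.int64)
        genes["end"] = genes["end"].astype(np.int64)
        genes = genes.sort_values(["start", "end"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "genes", genes)
        if self.genome_length <= 0:
            raise ValidationError("genome_length must be positive")
        if len(genes):
            if (genes["start"] < 0).any() or (genes["end"] > self.genome_length).any():
                raise ValidationError("gene interval outside [0, genome_length]")
            if (genes["start"] >= genes["end"]).any():
                raise ValidationError("gene with start >= end")
            bad = set(genes["strand"]) - {"+", "-"}
            if bad:
                raise ValidationError(f"unknown strand symbol(s): {sorted(bad)}")
            if genes["name"].duplicated().any():
                dups = genes.loc[genes["name"].duplicated(), "name"].tolist()
                raise ValidationError(f"duplicate gene names: {dups}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class CoordinateTable:
    """Named single-bp coordinates (e.g. disputed-target peak positions)."""

    records: pd.DataFrame  # columns: sequence_id, position, name [, flags]

    def __post_init__(self) -> None:
        rec = self.records.copy()
        if "flags" not in rec.columns:
            rec["flags"] = ""
        rec = rec.loc[:, ["sequence_id", "position", "name", "flags"]]
        rec["position"] = rec["position"].astype(np.int64)
        object.__setattr__(self, "records", rec.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> np.ndarray:
        return self.records["position"].to_numpy()

    def validate_against(self, ann: GeneAnnotation) -> None:
        pos = self.positions
        if len(pos) and ((pos < 0).any() or (pos >= ann.genome_length).any()):
            raise ValidationError("coordinate outside [0, genome_length)")


# ---------------------------------------------------------------------------
# bedGraph

def _parse_bedgraph(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 4:
                raise ValidationError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            seq, s, e, v = parts
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if v.strip() in ("", "NA", "NaN", "nan", "."):
                value = np.nan
            else:
                try:
                    value = float(v)
                except ValueError as exc:
                    raise ValidationError(f"{path}: line {lineno}: unparsable value {v!r}") from exc
            rows.append((seq, start, end, value))
    if not rows:
        raise ValidationError(f"{path}: empty bedGraph")
    return pd.DataFrame(rows, columns=["sequence_id", "start", "end", "value"])


def read_probe_tracks(path: str | Path, label: str = "") -> dict[str, ProbeTrack]:
    """Read a bedGraph file, returning one :class:`ProbeTrack` per sequence.

    NaN/blank values are dropped with a logged count; probes are sorted by
    start.  Overlapping probe intervals raise :class:`ValidationError`.
    """
    df = _parse_bedgraph(path)
    label = label or Path(path).stem
    out: dict[str, ProbeTrack] = {}
    for seq, grp in df.groupby("sequence_id", sort=True):
        n_nan = int(grp["value"].isna().sum())
        if n_nan:
            logger.warning("%s [%s]: dropped %d NaN/blank probe value(s)", path, seq, n_nan)
        grp = grp.dropna(subset=["value"])
        if len(grp) == 0:
            raise ValidationError(f"{path} [{seq}]: no probes left after NaN filtering")
        if not grp["start"].is_monotonic_increasing:
            logger.warning("%s [%s]: probes were not sorted by start; sorting", path, seq)
            grp = grp.sort_values("start", kind="stable")
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"{path} [{seq}]: overlapping probe intervals")
        out[seq] = ProbeTrack(
            sequence_id=str(seq),
            starts=starts,
            ends=ends,
            values=grp["value"].to_numpy(np.float64),
            label=label,
            n_dropped=n_nan,
        )
    return out


def read_probe_track(path: str | Path, label: str = "") -> ProbeTrack:
    """Read a single-sequence bedGraph track (the common case)."""
    tracks = read_probe_tracks(path, label=label)
    if len(tracks) != 1:
        raise ValidationError(
            f"{path}: expected a single sequence, found {sorted(tracks)}; "
            "use read_probe_tracks() to split"
        )
    return next(iter(tracks.values()))


def write_probe_track(track: ProbeTrack, path: str | Path, values: np.ndarray | None = None) -> None:
    """Write a track (or the same grid with substitute ``values``) as bedGraph."""
    vals = track.values if values is None else np.asarray(values, dtype=float)
    if len(vals) != len(track):
        raise ValidationError("values length does not match track")
    with open(path, "w") as fh:
        for s, e, v in zip(track.starts, track.ends, vals):
            fh.write(f"{track.sequence_id}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# annotation

def read_annotation(path: str | Path, genome_length: int | None = None) -> GeneAnnotation:
    """Read gene annotation from GFF3 or BED.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    ``genome_length`` is taken from a ``##sequence-region`` directive when
    present, otherwise it must be passed explicitly.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path, genome_length)
    if path.suffix.lower() == ".bed":
        return _read_bed(path, genome_length)
    raise ValidationError(f"{path}: unrecognised annotation extension (use .gff3/.gff/.bed)")


def _read_gff3(path: Path, genome_length: int | None) -> GeneAnnotation:
    directive_length = None
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    directive_length = int(parts[3])
            elif line.startswith("#") or not line.strip():
                continue
            else:
                body.append(line)
    length = genome_length if genome_length is not None else directive_length
    if length is None:
        raise ValidationError(f"{path}: no ##sequence-region directive; pass genome_length")
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    if body:
        df = pd.read_csv(_io.StringIO("".join(body)), sep="\t", names=cols, dtype=str)
    else:
        df = pd.DataFrame(columns=cols)
    df = df[df["type"].str.lower() == "gene"] if len(df) else df
    names = []
    for attrs in df.get("attributes", []):
        fields = dict(kv.split("=", 1) for kv in str(attrs).split(";") if "=" in kv)
        names.append(fields.get("Name", fields.get("ID", f"gene{len(names)}")))
    genes = pd.DataFrame(
        {
            "sequence_id": df["seqid"].to_numpy() if len(df) else [],
            "start": df["start"].astype(np.int64) - 1 if len(df) else [],  # GFF3 -> half-open
            "end": df["end"].astype(np.int64) if len(df) else [],
            "strand": df["strand"].to_numpy() if len(df) else [],
            "name": names,
        }
    )
    return GeneAnnotation(genes=genes, genome_length=int(length))


def _read_bed(path: Path, genome_length: int | None) -> GeneAnnotation:
    if genome_length is None:
        raise ValidationError(f"{path}: BED carries no genome length; pass genome_length")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ValidationError(f"{path}: BED needs 6 columns (chrom start end name score strand)")
    genes = pd.DataFrame(
        {
            "sequence_id": df[0],
            "start": df[1].astype(np.int64),
            "end": df[2].astype(np.int64),
            "strand": df[5],
            "name": df[3],
        }
    )
    return GeneAnnotation(genes=genes, genome_length=int(genome_length))


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    """Write annotation as GFF3 with a ##sequence-region directive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        seq = ann.genes["sequence_id"].iloc[0] if len(ann) else "chr"
        fh.write(f"##sequence-region {seq} 1 {ann.genome_length}\n")
        for _, g in ann.genes.iterrows():
            fh.write(
                f"{g.sequence_id}\tchip_arbiter\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g['name']};Name={g['name']}\n"
            )


# ---------------------------------------------------------------------------
# generic tables

def write_table(records: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write tabular results as TSV with a header row.

    Floats are written at 6 significant digits; an empty record list yields a
    header-only file (the frame's columns are preserved).
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def read_coordinate_table(path: str | Path) -> CoordinateTable:
    """Read a TSV of named coordinates (columns sequence_id, position, name)."""
    df = read_table(path)
    missing = {"sequence_id", "position", "name"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    return CoordinateTable(records=df)
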