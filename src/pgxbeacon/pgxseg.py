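"""Reading and writing CNV segment files: `.seg` and `.pgxseg` dialects.

`.seg` is the tab-separated output dialect of circular binary segmentation
pipelines: a header row, then one segment per line with 1-based inclusive
coordinates.  `.pgxseg` is the Progenetix dialect: the same tabular segment
body (interbase, i.e. 0-based half-open coordinates) preceded by ``#``
metadata lines carrying per-sample annotations as ``#key=value;key=value``.

Internally all coordinates are 0-based half-open regardless of source
dialect; `.seg` export shifts back to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Segment",
    "SegmentFile",
    "SegfileParseError",
    "CHROMOSOMES",
    "read_segfile",
    "write_pgxseg",
    "write_seg",
    "split_segmentfile",
]

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}

STATES = ("gain", "loss", "neutral", "unknown")

# accepted spellings in segment tables (headers vary across exports)
_SAMPLE_COLS = ("biosample_id", "sample_id", "sample", "id")
_CHROM_COLS = ("chromosome", "reference_name", "chro", "chrom")
_START_COLS = ("start", "loc.start")
_END_COLS = ("end", "loc.end")
_LOG2_COLS = ("log2", "value", "mean", "seg.mean")
_STATE_COLS = ("state", "variant_type")
_PROBES_COLS = ("n_probes", "num.mark", "probes")

#: textual state labels and CNV ontology terms mapped onto the 3-state model
STATE_VOCAB: dict[str, str] = {
    "gain": "gain",
    "dup": "gain",
    "duplication": "gain",
    "EFO:0030070": "gain",  # copy number gain
    "EFO:0030071": "gain",  # low-level gain
    "EFO:0030072": "gain",  # high-level gain / amplification
    "loss": "loss",
    "del": "loss",
    "deletion": "loss",
    "EFO:0030067": "loss",  # copy number loss
    "EFO:0030068": "loss",  # low-level loss
    "EFO:0030069": "loss",  # complete genomic deletion
    "neutral": "neutral",
    "normal": "neutral",
}


class SegfileParseError(ValueError):
    """Raised on structurally invalid segment files, naming the line."""


@dataclass(frozen=True)
class Segment:
    """One CNV call: half-open interval on one chromosome of one sample."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    log2: float | None = None
    state: str = "unknown"
    n_probes: int | None = None

    def __post_init__(self) -> None:
        if self.chromosome not in _CHROM_ORDER:
            raise ValueError(f"chromosome {self.chromosome!r} not in 1-22, X, Y")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for "
                f"{self.sample_id}:{self.chromosome}"
            )
        if self.state not in STATES:
            raise ValueError(f"state {self.state!r} not in {STATES}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentFile:
    """Segments plus per-sample metadata, as parsed from one file."""

    segments: list[Segment] = field(default_factory=list)
    metadata: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["sample_id"]))
    dialect: str = "pgxseg"
    comments: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def sample_ids(self) -> list[str]:
        """All known samples: metadata roster first, then segment-only ids."""
        seen: dict[str, None] = {}
        if "sample_id" in self.metadata.columns:
            for s in self.metadata["sample_id"]:
                seen.setdefault(str(s))
        for seg in self.segments:
            seen.setdefault(seg.sample_id)
        return list(seen)


def _pick(header: Sequence[str], candidates: Sequence[str]) -> int | None:
    lowered = [h.strip().lower() for h in header]
    for cand in candidates:
        if cand in lowered:
            return lowered.index(cand)
    return None


def _norm_chrom(raw: str) -> str:
    c = raw.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    elif c == "24":
        c = "Y"
    return c


def normalize_state(raw: str | None) -> str:
    if raw is None or str(raw).strip() == "":
        return "unknown"
    token = str(raw).strip()
    return STATE_VOCAB.get(token, STATE_VOCAB.get(token.lower(), "unknown"))


def _sniff_dialect(path: str) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                return "pgxseg" if line.startswith("#") else "seg"
    return "seg"


def read_segfile(path: str, dialect: str | None = None) -> SegmentFile:
    """Parse a `.seg` or `.pgxseg` file into a :class:`SegmentFile`.

    The dialect is sniffed from the filename/content when not given:
    ``.pgxseg`` suffix or a ``#`` preamble selects pgxseg.  `.seg`
    coordinates (1-based inclusive) are shifted to 0-based half-open.
    """
    if dialect is None:
        dialect = "pgxseg" if str(path).endswith(".pgxseg") else _sniff_dialect(path)
    if dialect not in ("seg", "pgxseg"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'seg' or 'pgxseg'")

    meta_rows: list[dict[str, str]] = []
    comments: list[str] = []
    warnings: list[str] = []
    segments: list[Segment] = []
    header: list[str] | None = None
    idx: dict[str, int | None] = {}

    offset = 1 if dialect == "seg" else 0

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                row = _parse_meta_line(line)
                if row is None:
                    comments.append(line)
                else:
                    meta_rows.append(row)
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                idx = {
                    "sample": _pick(header, _SAMPLE_COLS),
                    "chrom": _pick(header, _CHROM_COLS),
                    "start": _pick(header, _START_COLS),
                    "end": _pick(header, _END_COLS),
                    "log2": _pick(header, _LOG2_COLS),
                    "state": _pick(header, _STATE_COLS),
                    "probes": _pick(header, _PROBES_COLS),
                }
                missing = [k for k in ("sample", "chrom", "start", "end") if idx[k] is None]
                if missing:
                    raise SegfileParseError(
                        f"{path}:{lineno}: header lacks mandatory column(s) "
                        f"{missing} in {header!r}"
                    )
                continue
            try:
                start = int(fields[idx["start"]]) - offset  # type: ignore[index]
                end = int(fields[idx["end"]])  # type: ignore[index]
            except (ValueError, IndexError):
                raise SegfileParseError(f"{path}:{lineno}: non-numeric coordinates in {line!r}")
            log2: float | None = None
            if idx["log2"] is not None and idx["log2"] < len(fields):
                token = fields[idx["log2"]].strip()
                if token not in ("", ".", "NA", "nan"):
                    try:
                        log2 = float(token)
                    except ValueError:
                        raise SegfileParseError(f"{path}:{lineno}: non-numeric log2 {token!r}")
            state = "unknown"
            if idx["state"] is not None and idx["state"] < len(fields):
                state = normalize_state(fields[idx["state"]])
            n_probes: int | None = None
            if idx["probes"] is not None and idx["probes"] < len(fields):
                token = fields[idx["probes"]].strip()
                if token not in ("", ".", "NA"):
                    n_probes = int(float(token))
            try:
                segments.append(
                    Segment(
                        sample_id=fields[idx["sample"]],  # type: ignore[index]
                        chromosome=_norm_chrom(fields[idx["chrom"]]),  # type: ignore[index]
                        start=start,
                        end=end,
                        log2=log2,
                        state=state,
                        n_probes=n_probes,
                    )
                )
            except ValueError as exc:
                raise SegfileParseError(f"{path}:{lineno}: {exc}")

    metadata = _meta_frame(meta_rows)
    known = set(metadata["sample_id"]) if len(metadata) else set()
    if dialect == "pgxseg" and known:
        orphans = sorted({s.sample_id for s in segments} - known)
        for orphan in orphans:
            warnings.append(f"segment sample {orphan!r} missing from metadata")
    return SegmentFile(
        segments=segments,
        metadata=metadata,
        dialect=dialect,
        comments=comments,
        warnings=warnings,
    )


def _parse_meta_line(line: str) -> dict[str, str] | None:
    """`#key=value;key=value` sample annotation, or None for a plain comment."""
    body = line.lstrip("#").strip()
    if "=" not in body:
        return None
    row: dict[str, str] = {}
    for chunk in body.split(";"):
        if not chunk.strip():
            continue
        if "=" not in chunk:
            return None
        key, _, value = chunk.partition("=")
        row[key.strip()] = value.strip()
    for alias in ("sample_id", "biosample_id", "sample"):
        if alias in row:
            row["sample_id"] = row.pop(alias)
            return row
    return None  # annotation without a sample identifier -> file-level comment


def _meta_frame(rows: list[dict[str, str]]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=["sample_id"])
    frame = pd.DataFrame(rows, dtype=object)
    cols = ["sample_id"] + [c for c in frame.columns if c != "sample_id"]
    frame = frame[cols].where(pd.notna(frame), None)
    dupes = frame["sample_id"][frame["sample_id"].duplicated()].tolist()
    if dupes:
        raise SegfileParseError(f"duplicate metadata sample ids: {dupes}")
    return frame


def sort_segments(segments: Iterable[Segment]) -> list[Segment]:
    """Canonical order: sample, then chromosome 1..22,X,Y, then start."""
    return sorted(
        segments, key=lambda s: (s.sample_id, _CHROM_ORDER[s.chromosome], s.start, s.end)
    )


_HEADER = ["biosample_id", "chromosome", "start", "end", "log2", "state", "n_probes"]


def write_pgxseg(data: SegmentFile, path: str) -> None:
    """Write the pgxseg dialect: ``#`` metadata preamble, then the segment table.

    Output is canonical (sorted segments, fixed header), so a read/write cycle
    is the identity on canonical files.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for comment in data.comments:
            fh.write(comment.rstrip("\n") + "\n")
        meta = data.metadata
        for _, row in meta.iterrows():
            parts = [f"sample_id={row['sample_id']}"]
            parts += [
                f"{k}={row[k]}" for k in meta.columns if k != "sample_id" and row[k] is not None
            ]
            fh.write("#" + ";".join(parts) + "\n")
        fh.write("\t".join(_HEADER) + "\n")
        for seg in sort_segments(data.segments):
            fh.write(
                "\t".join(
                    [
                        seg.sample_id,
                        seg.chromosome,
                        str(seg.start),
                        str(seg.end),
                        "" if seg.log2 is None else repr(seg.log2),
                        seg.state,
                        "" if seg.n_probes is None else str(seg.n_probes),
                    ]
                )
                + "\n"
            )


def write_seg(data: SegmentFile, path: str) -> None:
    """Write the plain `.seg` dialect (1-based inclusive, no metadata lines)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["sample_id", "chromosome", "start", "end", "log2", "state"]) + "\n")
        for seg in sort_segments(data.segments):
            fh.write(
                "\t".join(
                    [
                        seg.sample_id,
                        seg.chromosome,
                        str(seg.start + 1),
                        str(seg.end),
                        "" if seg.log2 is None else repr(seg.log2),
                        seg.state,
                    ]
                )
                + "\n"
            )


def split_segmentfile(data: SegmentFile) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into (segment table, metadata table) data frames."""
    seg_table = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chromosome": s.chromosome,
                "start": s.start,
                "end": s.end,
                "log2": s.log2,
                "state": s.state,
            }
            for s in data.segments
        ],
        columns=["sample_id", "chromosome", "start", "end", "log2", "state"],
    )
    return seg_table, data.metadata.copy()
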