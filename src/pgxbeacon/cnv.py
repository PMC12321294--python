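"""Cohort CNV statistics over segmented copy-number calls.

Given already-segmented CNV calls (one interval per sample with a log2 ratio
and/or categorical state), this module

* classifies segments into a 3-state model (gain / loss / neutral) from
  explicit state labels or log2 thresholds,
* tiles the genome into fixed-size bins (Progenetix-style 1 Mb by default),
* computes per-bin cohort frequencies — the percentage of samples carrying at
  least one gain (loss) segment overlapping the bin — and per-sample genome
  fractions covered by gains/losses,
* renders the mirrored gain/loss frequency plot.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pgxseg import CHROMOSOMES, STATE_VOCAB, Segment, SegmentFile

__all__ = [
    "GenomeBins",
    "CNVFrequencyTrack",
    "CNVFraction",
    "load_chromosome_lengths",
    "make_bins",
    "classify_segments",
    "seg_to_freq",
    "cnv_fraction",
    "plot_frequency",
]

DEFAULT_BIN_SIZE = 1_000_000
DEFAULT_GAIN_THRESHOLD = 0.15
DEFAULT_LOSS_THRESHOLD = -0.15

_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}


def load_chromosome_lengths(path: str | None = None) -> dict[str, int]:
    """Chromosome→length map; the packaged hg38 table when *path* is None."""
    if path is None:
        ref = resources.files("pgxbeacon.data").joinpath("hg38_chromosomes.tsv")
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    return {str(r.chromosome): int(r.length) for r in frame.itertuples()}


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-size tiling of a genome.

    Bins tile each chromosome without gaps or overlaps; the last bin of a
    chromosome may be shorter than ``bin_size``.
    """

    assembly: str
    lengths: Mapping[str, int]
    bin_size: int
    bins: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def make_bins(
    lengths: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    assembly: str = "custom",
) -> GenomeBins:
    """Tile each chromosome into half-open bins of ``bin_size`` bases."""
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    if not lengths:
        raise ValueError("empty chromosome length map")
    rows = []
    ordered = sorted(lengths, key=lambda c: _CHROM_ORDER.get(str(c), 99))
    for chrom in ordered:
        length = int(lengths[chrom])
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")
        for start in range(0, length, bin_size):
            rows.append((str(chrom), start, min(start + bin_size, length)))
    bins = pd.DataFrame(rows, columns=["chromosome", "start", "end"])
    return GenomeBins(assembly=assembly, lengths=dict(lengths), bin_size=bin_size, bins=bins)


def classify_segments(
    segments: Iterable[Segment],
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    state_vocab: Mapping[str, str] | None = None,
) -> list[Segment]:
    """Assign gain/loss/neutral states.

    An explicit, recognized state label wins over the log2 thresholds; a
    segment with neither a usable label nor a log2 value stays ``unknown``.
    """
    if not gain_threshold > loss_threshold:
        raise ValueError(
            f"gain_threshold ({gain_threshold}) must exceed loss_threshold ({loss_threshold})"
        )
    vocab = dict(STATE_VOCAB)
    if state_vocab:
        vocab.update(state_vocab)
    out = []
    for seg in segments:
        state = seg.state if seg.state in ("gain", "loss", "neutral") else "unknown"
        if state == "unknown":
            if seg.log2 is None:
                state = "unknown"
            elif seg.log2 >= gain_threshold:
                state = "gain"
            elif seg.log2 <= loss_threshold:
                state = "loss"
            else:
                state = "neutral"
        out.append(
            Segment(
                sample_id=seg.sample_id,
                chromosome=seg.chromosome,
                start=seg.start,
                end=seg.end,
                log2=seg.log2,
                state=state,
                n_probes=seg.n_probes,
            )
        )
    return out


@dataclass(frozen=True)
class CNVFrequencyTrack:
    """Per-bin gain/loss percentages over one cohort."""

    bins: GenomeBins
    gain_percent: np.ndarray
    loss_percent: np.ndarray
    n_samples: int
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        frame = self.bins.bins.copy()
        frame["gain_percent"] = self.gain_percent
        frame["loss_percent"] = self.loss_percent
        frame["n_samples"] = self.n_samples
        frame["group"] = self.group
        return frame

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _collect_samples(
    segments: Sequence[Segment], samples: Sequence[str] | None
) -> list[str]:
    if samples is not None:
        roster = list(dict.fromkeys(samples))
    else:
        roster = list(dict.fromkeys(s.sample_id for s in segments))
    return roster

def seg_to_freq(
    segments: Sequence[Segment] | SegmentFile,
    bins: GenomeBins,
    min_overlap: int = 1,
    samples: Sequence[str] | None = None,
    group: str = "",
) -> CNVFrequencyTrack:
    """Cohort CNV frequency per genomic bin.

    For each bin and each state in {gain, loss}:
    ``percent = 100 * n_samples_with_an_overlapping_segment / n_samples``,
    where overlap must span at least ``min_overlap`` bases and a sample counts
    at most once per bin per state regardless of how many of its segments
    overlap.  The denominator is the full roster: pass ``samples`` (or a
    :class:`SegmentFile`, whose metadata supplies the roster) so samples with
    zero CNV segments still dilute the frequencies.
    """
    if isinstance(segments, SegmentFile):
        if samples is None:
            samples = segments.sample_ids()
        segments = segments.segments
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1 base")
    roster = _collect_samples(segments, samples)
    if not roster:
        raise ValueError("no samples: cannot form a frequency denominator")
    sample_idx = {s: i for i, s in enumerate(roster)}
    n_bins = bins.n_bins

    starts = bins.bins["start"].to_numpy()
    bin_index: dict[str, tuple[int, np.ndarray, np.ndarray]] = {}
    offset = 0
    for chrom, block in bins.bins.groupby("chromosome", sort=False):
        bin_index[chrom] = (offset, block["start"].to_numpy(), block["end"].to_numpy())
        offset += len(block)

    hit = {
        "gain": np.zeros((len(roster), n_bins), dtype=bool),
        "loss": np.zeros((len(roster), n_bins), dtype=bool),
    }
    for seg in segments:
        if seg.state not in ("gain", "loss"):
            continue
        if seg.sample_id not in sample_idx or seg.chromosome not in bin_index:
            continue
        off, bstart, bend = bin_index[seg.chromosome]
        overlap = np.minimum(seg.end, bend) - np.maximum(seg.start, bstart)
        which = np.nonzero(overlap >= min_overlap)[0]
        hit[seg.state][sample_idx[seg.sample_id], off + which] = True

    n = len(roster)
    return CNVFrequencyTrack(
        bins=bins,
        gain_percent=100.0 * hit["gain"].sum(axis=0) / n,
        loss_percent=100.0 * hit["loss"].sum(axis=0) / n,
        n_samples=n,
        group=group,
    )


@dataclass(frozen=True)
class CNVFraction:
    """Per-sample fraction of the genome covered by gains/losses."""

    sample_id: str
    gain_fraction: float
    loss_fraction: float
    total_fraction: float
    scope: str = "genome"


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for start, end in sorted(intervals):
        if start > last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def cnv_fraction(
    segments: Sequence[Segment] | SegmentFile,
    lengths: Mapping[str, int],
    samples: Sequence[str] | None = None,
) -> list[CNVFraction]:
    """Genome fraction covered by gain/loss segments, per sample.

    Overlapping same-state intervals are merged before summation, so the
    result is invariant to how segments are split.
    """
    if isinstance(segments, SegmentFile):
        if samples is None:
            samples = segments.sample_ids()
        segments = segments.segments
    genome = sum(int(v) for v in lengths.values())
    if genome <= 0:
        raise ValueError("genome length must be positive")
    roster = _collect_samples(segments, samples)
    per_sample: dict[str, dict[str, dict[str, list[tuple[int, int]]]]] = {
        s: {"gain": {}, "loss": {}} for s in roster
    }
    for seg in segments:
        if seg.state not in ("gain", "loss") or seg.sample_id not in per_sample:
            continue
        if seg.chromosome not in lengths:
            continue
        per_sample[seg.sample_id][seg.state].setdefault(seg.chromosome, []).append(
            (seg.start, min(seg.end, int(lengths[seg.chromosome])))
        )
    out = []
    for sample in roster:
        gain_bp = sum(_union_length(iv) for iv in per_sample[sample]["gain"].values())
        loss_bp = sum(_union_length(iv) for iv in per_sample[sample]["loss"].values())
        out.append(
            CNVFraction(
                sample_id=sample,
                gain_fraction=gain_bp / genome,
                loss_fraction=loss_bp / genome,
                total_fraction=(gain_bp + loss_bp) / genome,
            )
        )
    return out


def _genome_offsets(bins: GenomeBins) -> dict[str, int]:
    offsets: dict[str, int] = {}
    running = 0
    for chrom in bins.bins["chromosome"].drop_duplicates():
        offsets[chrom] = running
        running += int(bins.lengths[chrom])
    return offsets


def plot_frequency(
    tracks: CNVFrequencyTrack | Sequence[CNVFrequencyTrack],
    layout: str = "genome",
    chromosomes: Sequence[str] | None = None,
    out: str | None = None,
):
    """Mirrored gain/loss frequency plot.

    Gains are drawn upward and losses downward on a ±100 percent axis, one
    panel per track (genome layout) or per chromosome.  Returns
    ``(figure, plot_table)`` where the table holds the exact coordinates
    drawn, so rendering is testable without pixel comparison.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(tracks, CNVFrequencyTrack):
        tracks = [tracks]
    if not tracks:
        raise ValueError("at least one frequency track required")
    if layout not in ("genome", "by-chromosome"):
        raise ValueError(f"unknown layout {layout!r}")

    known = list(tracks[0].bins.bins["chromosome"].drop_duplicates())
    if chromosomes is not None:
        bad = [c for c in chromosomes if c not in known]
        if bad:
            raise ValueError(f"unknown chromosome(s) {bad}; available: {known}")
    plot_rows = []
    for track in tracks:
        offsets = _genome_offsets(track.bins)
        frame = track.to_frame()
        if chromosomes is not None:
            frame = frame[frame["chromosome"].isin(chromosomes)]
        frame = frame.assign(
            x=frame["start"] + frame["chromosome"].map(offsets),
            group=track.group,
        )
        plot_rows.append(frame)
    table = pd.concat(plot_rows, ignore_index=True)

    if layout == "genome":
        fig, axes = plt.subplots(
            len(tracks), 1, figsize=(12, 2.6 * len(tracks)), squeeze=False, sharex=True
        )
        for ax, track, frame in zip(axes[:, 0], tracks, plot_rows):
            width = track.bins.bin_size
            ax.bar(frame["x"], frame["gain_percent"], width=width, align="edge", color="#d6604d")
            ax.bar(frame["x"], -frame["loss_percent"], width=width, align="edge", color="#4393c3")
            ax.set_ylim(-100, 100)
            ax.axhline(0.0, color="black", lw=0.5)
            ax.set_ylabel("loss %  /  gain %")
            ax.set_title(track.group or f"{track.n_samples} samples", fontsize=9)
            for chrom, off in _genome_offsets(track.bins).items():
                ax.axvline(off, color="grey", lw=0.3)
        axes[-1, 0].set_xlabel("genome position (bp, chromosomes concatenated)")
    else:
        chroms = list(chromosomes) if chromosomes is not None else known
        fig, axes = plt.subplots(
            len(tracks), len(chroms), figsize=(3.2 * len(chroms), 2.6 * len(tracks)),
            squeeze=False, sharey=True,
        )
        for i, (track, frame) in enumerate(zip(tracks, plot_rows)):
            width = track.bins.bin_size
            for j, chrom in enumerate(chroms):
                sub = frame[frame["chromosome"] == chrom]
                ax = axes[i, j]
                ax.bar(sub["start"], sub["gain_percent"], width=width, align="edge", color="#d6604d")
                ax.bar(sub["start"], -sub["loss_percent"], width=width, align="edge", color="#4393c3")
                ax.set_ylim(-100, 100)
                ax.axhline(0.0, color="black", lw=0.5)
                if i == len(tracks) - 1:
                    ax.set_xlabel(f"chr{chrom}")
                if j == 0:
                    ax.set_ylabel(track.group or "loss % / gain %")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out)
    return fig, table
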