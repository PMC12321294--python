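"""Canned-response fixture export and per-base truth frequencies.

``export_fixture_files`` writes one Beacon envelope JSON per endpoint (the
layout :class:`pgxbeacon.client.FixtureTransport` reads), the cohort's CNV
segments as a ``.pgxseg`` file, and a truth TSV with the per-bin gain/loss
frequencies counted base-by-base from the generator's own segments — an
oracle deliberately computed by brute force (per-base boolean occupancy
arrays) rather than by the interval arithmetic of
:func:`pgxbeacon.cnv.seg_to_freq`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..pgxseg import Segment, SegmentFile, write_pgxseg
from .generate import MockDataset

__all__ = ["dataset_segments", "per_base_frequencies", "export_fixture_files"]


def dataset_segments(dataset: MockDataset) -> SegmentFile:
    """The cohort's CNV calls as a SegmentFile (metadata = full sample roster)."""
    segments = [
        Segment(
            sample_id=v["biosampleId"],
            chromosome=v["referenceName"],
            start=int(v["start"]),
            end=int(v["end"]),
            log2=v.get("log2"),
            state="gain" if v["variantState"]["id"] == "EFO:0030070" else "loss",
        )
        for v in dataset.variants
    ]
    metadata = pd.DataFrame(
        [
            {
                "sample_id": bs["id"],
                "individual_id": bs["individualId"],
                "group_id": bs["histologicalDiagnosis"]["id"],
            }
            for bs in dataset.biosamples
        ]
    )
    return SegmentFile(segments=segments, metadata=metadata, dialect="pgxseg")


def per_base_frequencies(
    segments: Sequence[Segment],
    lengths: Mapping[str, int],
    bin_size: int,
    samples: Sequence[str],
) -> pd.DataFrame:
    """Per-bin gain/loss percentages by literal per-base counting.

    For every sample and chromosome a boolean occupancy array over all bases
    is filled from the segment intervals; a bin counts the sample when any
    base of the bin is occupied.  O(genome) per sample — only for toy genomes.
    """
    samples = list(dict.fromkeys(samples))
    n = len(samples)
    if n == 0:
        raise ValueError("empty sample roster")
    by_sample: dict[str, list[Segment]] = {s: [] for s in samples}
    for seg in segments:
        if seg.sample_id in by_sample:
            by_sample[seg.sample_id].append(seg)
    rows = []
    for chrom, length in lengths.items():
        length = int(length)
        starts = list(range(0, length, bin_size))
        gain_counts = np.zeros(len(starts), dtype=int)
        loss_counts = np.zeros(len(starts), dtype=int)
        for sample in samples:
            occupied = {
                "gain": np.zeros(length, dtype=bool),
                "loss": np.zeros(length, dtype=bool),
            }
            touched = False
            for seg in by_sample[sample]:
                if seg.chromosome != chrom or seg.state not in ("gain", "loss"):
                    continue
                occupied[seg.state][seg.start : min(seg.end, length)] = True
                touched = True
            if not touched:
                continue
            for b, start in enumerate(starts):
                stop = min(start + bin_size, length)
                if occupied["gain"][start:stop].any():
                    gain_counts[b] += 1
                if occupied["loss"][start:stop].any():
                    loss_counts[b] += 1
        for b, start in enumerate(starts):
            rows.append(
                {
                    "chromosome": chrom,
                    "start": start,
                    "end": min(start + bin_size, length),
                    "gain_percent": 100.0 * gain_counts[b] / n,
                    "loss_percent": 100.0 * loss_counts[b] / n,
                    "n_samples": n,
                }
            )
    return pd.DataFrame(rows)


def export_fixture_files(
    dataset: MockDataset, directory: str, domain: str = "mock.local"
) -> dict[str, str]:
    """Write canned JSON envelopes, the cohort `.pgxseg`, and the truth TSV.

    Returns a name→path map of everything written.  Deterministic: identical
    datasets produce byte-identical files.
    """
    root = Path(directory)
    dom_dir = root / domain
    dom_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    for entity in ("individuals", "biosamples", "analyses", "g_variants"):
        records = dataset.entity(entity)
        doc = {
            "meta": {"beaconId": "org.pgxbeacon.mock", "returnedGranularity": "record"},
            "responseSummary": {"exists": bool(records), "numTotalResults": len(records)},
            "response": {
                "resultSets": [
                    {
                        "id": "mock",
                        "setType": "dataset",
                        "exists": bool(records),
                        "resultsCount": len(records),
                        "results": records,
                    }
                ]
            },
        }
        path = dom_dir / f"{entity}.json"
        path.write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")
        written[entity] = str(path)

    terms_doc = {
        "meta": {"beaconId": "org.pgxbeacon.mock", "returnedGranularity": "record"},
        "response": {
            "filteringTerms": [
                {"id": t.id, "label": t.label, "scope": t.scope, "type": t.type}
                for t in dataset.filtering_terms
            ]
        },
    }
    path = dom_dir / "filtering_terms.json"
    path.write_text(json.dumps(terms_doc, indent=1, sort_keys=True), encoding="utf-8")
    written["filtering_terms"] = str(path)

    segfile = dataset_segments(dataset)
    seg_path = root / "cohort.pgxseg"
    write_pgxseg(segfile, str(seg_path))
    written["pgxseg"] = str(seg_path)

    spec = dataset.truth["spec"]
    truth = per_base_frequencies(
        segfile.segments,
        spec["chromosome_lengths"],
        spec["bin_size"],
        segfile.sample_ids(),
    )
    truth_path = root / "truth_frequencies.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    written["truth_frequencies"] = str(truth_path)
    return written
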