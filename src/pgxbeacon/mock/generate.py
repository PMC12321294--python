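"""Synthetic Beacon v2 cohorts with known ground truth.

The generator emulates the data shape of a CNV-centric beacon (Progenetix
style): four cross-referenced entities (individual → biosample → analysis →
variants), ontology-tagged phenotypes queryable as CURIE filters, per-sample
CNV segments, and exponential survival times.

The generating model, deliberately simple enough that every cohort property
can be recomputed by hand:

* each individual draws a sex term (Male/Female, 50/50) and carries each
  extra CURIE of ``filter_assignment`` independently with its stated
  probability (carried terms are stored as disease codes, so filter matching
  is purely structural — no hidden state);
* the genome is a small multi-chromosome toy genome tiled into fixed bins;
  per sample and per bin a single uniform draw assigns gain (probability
  ``per_bin_gain_prob``) or loss (``per_bin_loss_prob``), so the per-bin gain
  indicator is exactly Bernoulli(per_bin_gain_prob); maximal runs of
  same-state bins are merged into segments with one log2 value each;
* survival time is exponential with a per-sex hazard, censored by an
  independent exponential censoring time.

Everything is driven by one ``numpy.random.Generator`` seeded from
``CohortSpec.seed``: identical specs give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..client import FilteringTerm

__all__ = ["CohortSpec", "MockDataset", "generate_cohort", "DEFAULT_TERM_LABELS"]

MALE = "NCIT:C20197"
FEMALE = "NCIT:C16576"

#: labels for every CURIE the generator can emit (also the /filtering_terms list)
DEFAULT_TERM_LABELS: dict[str, str] = {
    MALE: "Male",
    FEMALE: "Female",
    "NCIT:C3512": "Lung Adenocarcinoma",
    "NCIT:C4349": "Colon Carcinoma",
    "NCIT:C3058": "Glioblastoma",
    "NCIT:C3262": "Neoplasm",
}

_DIAGNOSIS_PALETTE = ("NCIT:C3512", "NCIT:C4349", "NCIT:C3058")

DEAD = {"id": "NCIT:C28554", "label": "dead"}
ALIVE = {"id": "NCIT:C37987", "label": "alive"}
GAIN_STATE = {"id": "EFO:0030070", "label": "copy number gain"}
LOSS_STATE = {"id": "EFO:0030067", "label": "copy number loss"}


def _default_genome() -> dict[str, int]:
    # 5 toy chromosomes of 5 Mb: 25 bins at the default 1 Mb binning —
    # large enough for cohort statistics, small enough for per-base oracles
    return {str(i): 5_000_000 for i in range(1, 6)}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_individuals: int = 100
    filter_assignment: Mapping[str, float] = field(
        default_factory=lambda: {"NCIT:C3512": 0.5}
    )
    chromosome_lengths: Mapping[str, int] = field(default_factory=_default_genome)
    bin_size: int = 1_000_000
    per_bin_gain_prob: float = 0.30
    per_bin_loss_prob: float = 0.15
    survival_hazards: Mapping[str, float] = field(
        default_factory=lambda: {MALE: 0.002, FEMALE: 0.002}  # events per day
    )
    censoring_hazard: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for curie, p in self.filter_assignment.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"inclusion probability for {curie} out of [0,1]: {p}")
        for p, name in (
            (self.per_bin_gain_prob, "per_bin_gain_prob"),
            (self.per_bin_loss_prob, "per_bin_loss_prob"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {p}")
        if self.per_bin_gain_prob + self.per_bin_loss_prob > 1.0:
            raise ValueError("per_bin_gain_prob + per_bin_loss_prob must be <= 1")
        if self.censoring_hazard < 0:
            raise ValueError("censoring_hazard must be >= 0")


@dataclass
class MockDataset:
    """One generated cohort: entity documents plus the generating truth."""

    individuals: list[dict]
    biosamples: list[dict]
    analyses: list[dict]
    variants: list[dict]
    filtering_terms: list[FilteringTerm]
    truth: dict

    def entity(self, name: str) -> list[dict]:
        try:
            return getattr(self, "variants" if name == "g_variants" else name)
        except AttributeError:
            raise KeyError(f"unknown entity {name!r}")

    def carried_terms(self, individual_id: str) -> set[str]:
        """CURIEs structurally present on an individual (sex + disease codes)."""
        ind = self._individual_index()[individual_id]
        carried = {ind["sex"]["id"]}
        carried.update(d["diseaseCode"]["id"] for d in ind.get("diseases", []))
        return carried

    def individual_of(self, record: dict, entity: str) -> str:
        if entity == "individuals":
            return record["id"]
        if entity == "biosamples":
            return record["individualId"]
        if entity in ("analyses", "g_variants"):
            return self._biosample_index()[record["biosampleId"]]["individualId"]
        raise KeyError(f"unknown entity {entity!r}")

    def matching_records(self, entity: str, filters: list[str]) -> list[dict]:
        """AND-combined filter match, computed directly on the documents."""
        out = []
        for record in self.entity(entity):
            carried = self.carried_terms(self.individual_of(record, entity))
            if all(f in carried for f in filters):
                out.append(record)
        return out

    def _individual_index(self) -> dict[str, dict]:
        if not hasattr(self, "_ind_idx"):
            self._ind_idx = {d["id"]: d for d in self.individuals}
        return self._ind_idx

    def _biosample_index(self) -> dict[str, dict]:
        if not hasattr(self, "_bs_idx"):
            self._bs_idx = {d["id"]: d for d in self.biosamples}
        return self._bs_idx


def generate_cohort(spec: CohortSpec) -> MockDataset:
    """Generate a cohort; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    individuals, biosamples, analyses, variants = [], [], [], []
    chroms = list(spec.chromosome_lengths)

    for i in range(spec.n_individuals):
        ind_id = f"pgxind-{i + 1:06d}"
        bs_id = f"pgxbs-{i + 1:06d}"
        ana_id = f"pgxana-{i + 1:06d}"
        sex_id = MALE if rng.random() < 0.5 else FEMALE
        carried = [c for c, p in spec.filter_assignment.items() if rng.random() < p]
        diagnosis = next((c for c in carried if c in _DIAGNOSIS_PALETTE), "NCIT:C3262")

        hazard = spec.survival_hazards.get(sex_id, 0.002)
        t_event = rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
        t_censor = (
            rng.exponential(1.0 / spec.censoring_hazard)
            if spec.censoring_hazard > 0
            else np.inf
        )
        time = float(min(t_event, t_censor))
        dead = bool(t_event <= t_censor)

        individuals.append(
            {
                "id": ind_id,
                "sex": {"id": sex_id, "label": DEFAULT_TERM_LABELS[sex_id]},
                "vitalStatus": dict(DEAD if dead else ALIVE),
                "followupTime": round(time, 1),
                "diseases": [
                    {
                        "diseaseCode": {
                            "id": c,
                            "label": DEFAULT_TERM_LABELS.get(c, c),
                        }
                    }
                    for c in carried
                ],
            }
        )
        biosamples.append(
            {
                "id": bs_id,
                "individualId": ind_id,
                "histologicalDiagnosis": {
                    "id": diagnosis,
                    "label": DEFAULT_TERM_LABELS.get(diagnosis, diagnosis),
                },
                "biosampleStatus": {"id": "EFO:0009656", "label": "neoplastic sample"},
                "externalReferences": [{"id": f"geo:GSM{100000 + i}"}],
            }
        )
        analyses.append(
            {
                "id": ana_id,
                "biosampleId": bs_id,
                "individualId": ind_id,
                "platformModel": {
                    "id": "geo:GPL6801",
                    "label": "Genome-Wide Human SNP Array 6.0",
                },
                "pipelineName": "mock-cnv-seg",
            }
        )

        # bin-wise CNV states, merged into maximal same-state runs
        var_no = 0
        for chrom in chroms:
            length = int(spec.chromosome_lengths[chrom])
            n_bins = -(-length // spec.bin_size)
            u = rng.random(n_bins)
            states = np.where(
                u < spec.per_bin_gain_prob,
                1,
                np.where(u < spec.per_bin_gain_prob + spec.per_bin_loss_prob, -1, 0),
            )
            b = 0
            while b < n_bins:
                state = states[b]
                run_end = b
                while run_end + 1 < n_bins and states[run_end + 1] == state:
                    run_end += 1
                if state != 0:
                    var_no += 1
                    start = b * spec.bin_size
                    end = min((run_end + 1) * spec.bin_size, length)
                    log2 = float(
                        rng.normal(0.5, 0.1) if state == 1 else rng.normal(-0.5, 0.1)
                    )
                    variants.append(
                        {
                            "id": f"pgxvar-{i + 1:06d}-{var_no:04d}",
                            "analysisId": ana_id,
                            "biosampleId": bs_id,
                            "referenceName": chrom,
                            "start": start,
                            "end": end,
                            "variantState": dict(GAIN_STATE if state == 1 else LOSS_STATE),
                            "log2": round(log2, 4),
                        }
                    )
                b = run_end + 1

    terms = [
        FilteringTerm(id=curie, label=label, scope="individuals", type="ontologyTerm")
        for curie, label in DEFAULT_TERM_LABELS.items()
    ]
    truth = {
        "spec": {
            "n_individuals": spec.n_individuals,
            "filter_assignment": dict(spec.filter_assignment),
            "chromosome_lengths": dict(spec.chromosome_lengths),
            "bin_size": spec.bin_size,
            "per_bin_gain_prob": spec.per_bin_gain_prob,
            "per_bin_loss_prob": spec.per_bin_loss_prob,
            "survival_hazards": dict(spec.survival_hazards),
            "censoring_hazard": spec.censoring_hazard,
            "seed": spec.seed,
        }
    }
    return MockDataset(
        individuals=individuals,
        biosamples=biosamples,
        analyses=analyses,
        variants=variants,
        filtering_terms=terms,
        truth=truth,
    )
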