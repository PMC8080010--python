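"""Complex I presence/absence calling from mitochondrial genome annotations.

The seven mitochondrially encoded complex I (CI) subunits (ND1-ND6 and
ND4L; KEGG orthologue clusters K03878-K03884) are essentially always
co-lost with the rest of the complex, so their joint absence from a
mitochondrial genome is a reliable proxy for loss of the whole complex.
This module implements the screening rules:

* a subunit is *present* in a genome if it is annotated, or if a
  homology-based gene prediction covers at least 50% of its
  protein-coding region;
* genomes with fewer than three CDS annotations are considered
  incomplete and discarded; at most ``max_per_species`` genomes are
  retained per species (random subsample, seeded);
* a genome supports CI loss when it lacks at least 5 of the 7 subunits;
  a species is called ``absent`` only when every retained genome does,
  ``present`` when every retained genome misses at most 2 subunits, and
  ``conflicting`` otherwise (conflicting species are excluded from
  downstream analyses, mirroring a manual-curation step).
"""

from __future__ import annotations

import logging
import zlib
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBUNITS",
    "KO_TO_SUBUNIT",
    "SubunitEvidence",
    "GenomeRecord",
    "CIStatus",
    "call_subunit_presence",
    "filter_genomes",
    "call_ci_status",
    "subunit_count_histogram",
    "read_genomes_tsv",
    "write_genomes_tsv",
    "write_status_tsv",
]

logger = logging.getLogger(__name__)

#: The seven mitochondrially encoded CI subunits, in canonical order.
SUBUNITS: tuple[str, ...] = ("ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6")

#: KEGG orthologue cluster ids for the mitochondrial CI subunits.
KO_TO_SUBUNIT: dict[str, str] = {
    "K03878": "ND1",
    "K03879": "ND2",
    "K03880": "ND3",
    "K03881": "ND4",
    "K03882": "ND4L",
    "K03883": "ND5",
    "K03884": "ND6",
}

#: Minimum fraction of the protein-coding region a homology prediction
#: must cover for a non-annotated subunit to count as present.
MIN_PREDICTION_COVERAGE = 0.5

#: A genome supports CI loss when it misses at least this many subunits.
MIN_MISSING_FOR_LOSS = 5

#: Genomes with fewer CDS annotations than this are incomplete.
MIN_CDS = 3


@dataclass(frozen=True)
class SubunitEvidence:
    """Annotation and homology-prediction evidence for one subunit."""

    subunit_id: str
    annotated: bool
    prediction_coverage: float

    def __post_init__(self) -> None:
        if self.subunit_id not in SUBUNITS:
            raise ValueError(f"unknown subunit_id {self.subunit_id!r}")
        if not 0.0 <= self.prediction_coverage <= 1.0:
            raise ValueError(
                f"prediction_coverage must be in [0, 1], got "
                f"{self.prediction_coverage!r}"
            )


@dataclass(frozen=True)
class GenomeRecord:
    """One mitochondrial genome: CDS count plus per-subunit evidence."""

    genome_id: str
    species_id: str
    n_cds: int
    evidence: tuple[SubunitEvidence, ...]

    def __post_init__(self) -> None:
        if self.n_cds < 0:
            raise ValueError("n_cds must be non-negative")
        seen = tuple(ev.subunit_id for ev in self.evidence)
        if sorted(seen) != sorted(SUBUNITS):
            raise ValueError(
                "a GenomeRecord needs exactly one evidence entry per subunit"
            )

    def n_present(self) -> int:
        return sum(call_subunit_presence(ev) for ev in self.evidence)

    def n_missing(self) -> int:
        return len(SUBUNITS) - self.n_present()


@dataclass(frozen=True)
class CIStatus:
    """Species-level CI call aggregated over retained genomes."""

    species_id: str
    status: str  # present | absent | conflicting | no_data
    n_missing_subunits: int
    genomes_used: int


def call_subunit_presence(evidence: SubunitEvidence) -> bool:
    """A subunit is present if annotated or covered >= 50% by a prediction."""
    return evidence.annotated or (
        evidence.prediction_coverage >= MIN_PREDICTION_COVERAGE
    )


def _species_rng(seed: int, species_id: str) -> np.random.Generator:
    # Per-species stream so the subsample is independent of input ordering.
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(species_id.encode())])
    )


def filter_genomes(
    records: Sequence[GenomeRecord],
    max_per_species: int = 50,
    seed: int = 0,
) -> list[GenomeRecord]:
    """Drop incomplete genomes and subsample abundant species.

    Genomes with fewer than three CDS annotations are removed. When a
    species has more than ``max_per_species`` complete genomes, a
    uniform random subsample of exactly ``max_per_species`` is retained;
    the draw is reproducible for a given ``seed`` and does not depend on
    the input ordering. Applying the filter twice (same seed) is a
    no-op the second time.
    """
    complete = [rec for rec in records if rec.n_cds >= MIN_CDS]
    by_species: dict[str, list[int]] = {}
    for i, rec in enumerate(complete):
        by_species.setdefault(rec.species_id, []).append(i)
    keep: set[int] = set()
    for species_id, idx in by_species.items():
        if len(idx) <= max_per_species:
            keep.update(idx)
        else:
            rng = _species_rng(seed, species_id)
            ordered = sorted(idx, key=lambda i: complete[i].genome_id)
            chosen = rng.choice(len(ordered), size=max_per_species, replace=False)
            keep.update(ordered[int(j)] for j in chosen)
    return [rec for i, rec in enumerate(complete) if i in keep]


def _genome_supports_loss(record: GenomeRecord) -> bool:
    missing = record.n_missing()
    if 2 < missing < MIN_MISSING_FOR_LOSS:
        # The >=5/7 rule is one-sided; intermediate genomes are treated as
        # CI-bearing but flagged for curation.
        logger.warning(
            "genome %s misses %d/7 subunits (between the presence and "
            "absence regimes); treated as CI-bearing",
            record.genome_id,
            missing,
        )
    return missing >= MIN_MISSING_FOR_LOSS


def call_ci_status(records: Iterable[GenomeRecord]) -> dict[str, CIStatus]:
    """Aggregate per-genome subunit counts into species-level CI calls.

    A species is ``absent`` only when *all* retained genomes miss at
    least 5/7 subunits, ``present`` when all genomes miss at most 2, and
    ``conflicting`` otherwise. ``records`` should already have passed
    :func:`filter_genomes`.
    """
    missing_by_species: dict[str, list[int]] = {}
    for rec in records:
        _genome_supports_loss(rec)  # emit curation warnings
        missing_by_species.setdefault(rec.species_id, []).append(rec.n_missing())
    out: dict[str, CIStatus] = {}
    for species_id, missing in missing_by_species.items():
        if all(m >= MIN_MISSING_FOR_LOSS for m in missing):
            status = "absent"
        elif all(m <= len(SUBUNITS) - MIN_MISSING_FOR_LOSS for m in missing):
            status = "present"
        else:
            status = "conflicting"
        out[species_id] = CIStatus(
            species_id=species_id,
            status=status,
            n_missing_subunits=min(missing),
            genomes_used=len(missing),
        )
    return out


def subunit_count_histogram(records: Iterable[GenomeRecord]) -> dict[int, int]:
    """Histogram of present-subunit counts (0..7) over genomes.

    On real data this distribution is strongly bimodal: genomes either
    retain (nearly) all seven subunits or almost none, which is what
    licenses the >=5/7-missing loss rule.
    """
    counts = Counter(rec.n_present() for rec in records)
    return {k: counts.get(k, 0) for k in range(len(SUBUNITS) + 1)}


# -- TSV interchange ----------------------------------------------------

_GENOME_COLUMNS = [
    "genome_id",
    "species_id",
    "n_cds",
    "subunit",
    "annotated",
    "coverage",
]


def write_genomes_tsv(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write genome records in long format (one row per subunit)."""
    rows = []
    for rec in records:
        for ev in rec.evidence:
            rows.append(
                {
                    "genome_id": rec.genome_id,
                    "species_id": rec.species_id,
                    "n_cds": rec.n_cds,
                    "subunit": ev.subunit_id,
                    "annotated": int(ev.annotated),
                    "coverage": round(ev.prediction_coverage, 6),
                }
            )
    pd.DataFrame(rows, columns=_GENOME_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genomes_tsv(path: str | Path) -> list[GenomeRecord]:
    """Read the distilled long-format genome TSV back into records."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for (genome_id, species_id, n_cds), grp in df.groupby(
        ["genome_id", "species_id", "n_cds"], sort=False
    ):
        evidence = tuple(
            SubunitEvidence(
                subunit_id=row.subunit,
                annotated=bool(row.annotated),
                prediction_coverage=float(row.coverage),
            )
            for row in grp.itertuples()
        )
        records.append(
            GenomeRecord(
                genome_id=str(genome_id),
                species_id=str(species_id),
                n_cds=int(n_cds),
                evidence=evidence,
            )
        )
    return records


def write_status_tsv(statuses: Mapping[str, CIStatus], path: str | Path) -> None:
    rows = [
        {
            "species_id": st.species_id,
            "status": st.status,
            "n_missing_subunits": st.n_missing_subunits,
            "genomes_used": st.genomes_used,
        }
        for st in statuses.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
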