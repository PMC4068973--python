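"""Readers and writers for the on-disk artifacts, plus the core domain types.

Everything downstream works with four in-memory objects defined here:

* :class:`Probe` / :class:`Platform` — a microarray platform is an ordered
  collection of probes, each carrying a gene label and a nucleotide sequence.
  The probe order in the annotation file is the canonical index order used by
  the similarity matrix and by every expression matrix on that platform.
* :class:`Identifier` — the ``PF-P-G`` triple (platform, probe, gene) that
  names one candidate biomarker.
* :class:`ExpressionDataset` — a probe-by-sample intensity matrix with binary
  tumor/normal labels.

On disk: probe sequences are FASTA, probe annotation is a two-column TSV
(``probe_id``, ``gene_id``), expression is a TSV with probe rows and sample
columns, labels are a two-column TSV (``sample_id``, ``tumor``/``normal``),
and the probe similarity matrix is a square TSV with a two-row
(platform, probe) header. Intensities are taken as-is: no cross-platform
normalisation is applied, because model coefficients are always re-fitted
within a single dataset.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Probe",
    "Platform",
    "Identifier",
    "ExpressionDataset",
    "read_platform",
    "write_platform",
    "read_expression",
    "write_expression",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "write_clm_json",
]

_VALID_BASES = frozenset("ACGTN")

#: symmetry tolerance for stored similarity matrices
SYMMETRY_TOL = 1e-6


@dataclass(frozen=True)
class Probe:
    """A single probe: its platform-local ID, gene label and sequence."""

    probe_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ValueError("probe_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"probe {self.probe_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"probe {self.probe_id!r}: invalid bases {sorted(bad)!r} "
                "(expected A/C/G/T/N)"
            )


@dataclass(frozen=True)
class Identifier:
    """The platform/probe/gene triple naming one candidate biomarker."""

    platform_id: str
    probe_id: str
    gene_id: str

    def __str__(self) -> str:  # e.g. "PF1-P3-G3"
        return f"{self.platform_id}-{self.probe_id}-{self.gene_id}"


class Platform:
    """An ordered collection of probes; order defines the canonical index."""

    def __init__(self, platform_id: str, probes: Sequence[Probe]):
        if not platform_id:
            raise ValueError("platform_id must be non-empty")
        if not probes:
            raise ValueError(f"platform {platform_id!r} has no probes")
        seen: set[str] = set()
        for p in probes:
            if p.probe_id in seen:
                raise ValueError(
                    f"platform {platform_id!r}: duplicate probe_id {p.probe_id!r}"
                )
            seen.add(p.probe_id)
        self.platform_id = platform_id
        self.probes: tuple[Probe, ...] = tuple(probes)
        self._index: dict[str, int] = {
            p.probe_id: i for i, p in enumerate(self.probes)
        }

    def __len__(self) -> int:
        return len(self.probes)

    def __repr__(self) -> str:
        return f"Platform({self.platform_id!r}, {len(self)} probes)"

    def probe_index(self, probe_id: str) -> int:
        return self._index[probe_id]

    def probe(self, probe_id: str) -> Probe:
        return self.probes[self._index[probe_id]]

    def identifier(self, probe_id: str) -> Identifier:
        p = self.probe(probe_id)
        return Identifier(self.platform_id, p.probe_id, p.gene_id)

    def identifiers(self) -> list[Identifier]:
        return [
            Identifier(self.platform_id, p.probe_id, p.gene_id)
            for p in self.probes
        ]

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(p.gene_id for p in self.probes)

    def probes_for_gene(self, gene_id: str) -> list[Probe]:
        return [p for p in self.probes if p.gene_id == gene_id]


@dataclass
class ExpressionDataset:
    """Probe-by-sample intensities with binary tumor(1)/normal(0) labels.

    Rows follow the platform's canonical probe order; ``intensities`` has
    shape ``(n_probes, n_samples)``.
    """

    dataset_id: str
    platform_id: str
    sample_ids: tuple[str, ...]
    labels: np.ndarray
    intensities: np.ndarray
    probe_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (probes x samples)")
        n_probes, n_samples = self.intensities.shape
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match intensity columns")
        if self.labels.shape != (n_samples,):
            raise ValueError("labels length does not match sample count")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (1=tumor, 0=normal)")
        if self.probe_ids and len(self.probe_ids) != n_probes:
            raise ValueError("probe_ids length does not match intensity rows")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def predictor_matrix(self, probe_indices: Sequence[int]) -> np.ndarray:
        """Samples-by-predictors design matrix for the given probe rows."""
        return self.intensities[list(probe_indices), :].T


# ---------------------------------------------------------------------------
# platform I/O


def read_platform(
    fasta_path: str | Path, annotation_path: str | Path, platform_id: str | None = None
) -> Platform:
    """Read a platform from a probe FASTA and a probe→gene annotation TSV.

    FASTA record IDs are probe IDs; the annotation TSV must have columns
    ``probe_id`` and ``gene_id`` and one row per FASTA record. Probes are
    ordered as in the annotation file and sequences are upper-cased.
    If *platform_id* is omitted, the FASTA file stem is used.
    """
    fasta_path = Path(fasta_path)
    annotation_path = Path(annotation_path)
    if platform_id is None:
        platform_id = fasta_path.stem

    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in sequences:
            raise ValueError(
                f"platform {platform_id!r}: duplicate probe_id {rec.id!r} in FASTA"
            )
        sequences[rec.id] = str(rec.seq).upper()

    probes: list[Probe] = []
    with open(annotation_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {
            "probe_id",
            "gene_id",
        } <= set(reader.fieldnames):
            raise ValueError(
                f"{annotation_path}: annotation must have columns probe_id, gene_id"
            )
        for row in reader:
            pid = row["probe_id"].strip()
            gid = row["gene_id"].strip()
            if pid not in sequences:
                raise ValueError(
                    f"platform {platform_id!r}: annotated probe {pid!r} has no "
                    "FASTA sequence"
                )
            probes.append(Probe(pid, gid, sequences[pid]))

    if not probes:
        raise ValueError(f"{annotation_path}: annotation file has no probes")
    annotated = {p.probe_id for p in probes}
    missing = set(sequences) - annotated
    if missing:
        raise ValueError(
            f"platform {platform_id!r}: FASTA records without annotation: "
            f"{sorted(missing)!r}"
        )
    return Platform(platform_id, probes)


def write_platform(
    platform: Platform, fasta_path: str | Path, annotation_path: str | Path
) -> None:
    """Write a platform back to FASTA + annotation TSV (round-trip inverse)."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.probe_id, description="")
        for p in platform.probes
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(annotation_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["probe_id", "gene_id"])
        for p in platform.probes:
            writer.writerow([p.probe_id, p.gene_id])


# ---------------------------------------------------------------------------
# expression I/O

_LABEL_CODES = {"tumor": 1, "normal": 0}


def read_expression(
    tsv_path: str | Path,
    labels_path: str | Path,
    platform: Platform,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Read an intensity TSV plus a labels TSV into an ExpressionDataset.

    The TSV header row holds sample IDs, the first column probe IDs. Rows are
    re-ordered to the platform's canonical probe order; a platform probe
    missing from the file is a hard error (no imputation).
    """
    tsv_path = Path(tsv_path)
    if dataset_id is None:
        dataset_id = tsv_path.stem

    with open(tsv_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if not header or len(header) < 2:
            raise ValueError(f"{tsv_path}: expected a header with sample IDs")
        sample_ids = tuple(s.strip() for s in header[1:])
        rows: dict[str, list[float]] = {}
        for r, row in enumerate(reader, start=2):
            pid = row[0].strip()
            if len(row) - 1 != len(sample_ids):
                raise ValueError(
                    f"{tsv_path}:{r}: expected {len(sample_ids)} values, "
                    f"got {len(row) - 1}"
                )
            values: list[float] = []
            for c, cell in enumerate(row[1:], start=2):
                try:
                    values.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{tsv_path}: non-numeric intensity at row {r}, "
                        f"column {c} ({cell!r})"
                    ) from None
            rows[pid] = values

    matrix = np.empty((len(platform), len(sample_ids)))
    for i, probe in enumerate(platform.probes):
        if probe.probe_id not in rows:
            raise ValueError(
                f"{tsv_path}: platform probe {probe.probe_id!r} missing from "
                "expression matrix"
            )
        matrix[i] = rows[probe.probe_id]

    label_map: dict[str, int] = {}
    with open(labels_path, newline="") as fh:
        for r, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].strip().lower() == "sample_id":
                continue
            sid, cls = row[0].strip(), row[1].strip().lower()
            if cls not in _LABEL_CODES:
                raise ValueError(
                    f"{labels_path}:{r}: class must be tumor/normal, got {cls!r}"
                )
            label_map[sid] = _LABEL_CODES[cls]
    unknown = set(label_map) - set(sample_ids)
    if unknown:
        raise ValueError(
            f"{labels_path}: labels for unknown samples {sorted(unknown)!r}"
        )
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise ValueError(f"{labels_path}: no label for samples {missing!r}")
    labels = np.array([label_map[s] for s in sample_ids], dtype=int)

    return ExpressionDataset(
        dataset_id=dataset_id,
        platform_id=platform.platform_id,
        sample_ids=sample_ids,
        labels=labels,
        intensities=matrix,
        probe_ids=tuple(p.probe_id for p in platform.probes),
    )


def write_expression(
    dataset: ExpressionDataset, tsv_path: str | Path, labels_path: str | Path
) -> None:
    """Write intensities and labels back to the two-file TSV layout."""
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["probe_id", *dataset.sample_ids])
        for pid, row in zip(dataset.probe_ids, dataset.intensities):
            writer.writerow([pid, *(format(v, ".6g") for v in row)])
    with open(labels_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "class"])
        for sid, y in zip(dataset.sample_ids, dataset.labels):
            writer.writerow([sid, "tumor" if y == 1 else "normal"])


# ---------------------------------------------------------------------------
# similarity-matrix I/O
#
# Layout: optional '#key=value' comment lines, then a two-row header
# (platform IDs, probe IDs), then one row per probe prefixed by its
# (platform_id, probe_id) pair. The full square matrix is stored; on read the
# upper triangle is authoritative and symmetry is validated to 1e-6.


def write_similarity_matrix(matrix, path: str | Path) -> Path:
    """Write a SimilarityMatrix as a square TSV with a two-row header."""
    path = Path(path)
    index = matrix.index
    with open(path, "w", newline="") as fh:
        fh.write(f"#model={matrix.model}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["", ""] + [pf for pf, _ in index])
        writer.writerow(["", ""] + [pid for _, pid in index])
        for (pf, pid), row in zip(index, matrix.values):
            writer.writerow([pf, pid] + [format(v, ".6f") for v in row])
    return path


def read_similarity_matrix(path: str | Path):
    """Read a similarity matrix TSV written by :func:`write_similarity_matrix`."""
    from .similarity import SimilarityMatrix  # deferred: avoids import cycle

    path = Path(path)
    model = "JC69"
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("#model="):
                    model = line.split("=", 1)[1]
                continue
            rows.append(line.split("\t"))
    if len(rows) < 3:
        raise ValueError(f"{path}: expected two header rows plus data")
    platforms_row, probes_row = rows[0][2:], rows[1][2:]
    index = list(zip(platforms_row, probes_row))
    n = len(index)
    values = np.empty((n, n))
    for i, row in enumerate(rows[2:]):
        if (row[0], row[1]) != index[i]:
            raise ValueError(
                f"{path}: row label {(row[0], row[1])!r} does not match header "
                f"{index[i]!r}"
            )
        values[i] = [float(v) for v in row[2:]]
    if len(rows) - 2 != n:
        raise ValueError(f"{path}: matrix is not square")
    if np.max(np.abs(values - values.T)) > SYMMETRY_TOL:
        raise ValueError(f"{path}: stored matrix is asymmetric beyond {SYMMETRY_TOL}")
    if values.min() < -SYMMETRY_TOL or values.max() > 1 + SYMMETRY_TOL:
        raise ValueError(f"{path}: similarity values outside [0, 1]")
    # upper triangle is authoritative; mirror it and pin the diagonal
    values = np.triu(values, 1) + np.triu(values, 1).T + np.diag(np.diag(values))
    if np.max(np.abs(np.diag(values) - 1.0)) > SYMMETRY_TOL:
        raise ValueError(f"{path}: diagonal entries must be 1.0")
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(index=index, values=np.clip(values, 0.0, 1.0), model=model)


# ---------------------------------------------------------------------------
# mined-model JSON


def write_clm_json(
    clm, path: str | Path, config: Mapping | None = None, seed: int | None = None
) -> Path:
    """Serialize a mined common logit model (panel, per-dataset fits, scores)."""
    path = Path(path)
    payload = clm.to_dict()
    payload["config"] = dict(config) if config else {}
    payload["seed"] = seed
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
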